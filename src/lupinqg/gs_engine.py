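"""Whole-genome regression models and the cross-validation grid.

Four predictors of line genetic merit from genome-wide marker doses:

* ``RRBLUP`` — ridge-regression BLUP; the mixed model y = 1mu + Wq + e with
  q ~ N(0, I s2_q) solved by maximum likelihood on the eigendecomposition of
  WW', profiling the ridge parameter lambda = s2_e / s2_q.
* ``BayesianLasso`` — the same linear model with independent double-
  exponential marker-effect priors, solved by Gibbs sampling.
* ``RKHSRegression`` — Bayesian G-BLUP: y = 1mu + Zg + e with
  var(g) = G s2_g, the VanRaden genomic relationship matrix acting as the
  reproducing kernel, solved by Gibbs sampling in the eigenbasis of G.
* ``WeightedGBLUP`` — G-BLUP on a trait-specific kernel
  G* = Wc D Wc' / (2 sum p(1-p)) whose diagonal marker weights D derive
  from association p-values computed on the training samples only.

Population structure enters any model as unpenalized (flat-prior) fixed
covariates.  Cross-validation reports predictive ability: the Pearson
correlation between observed and predicted values of held-out lines,
averaged over repeats, for within-environment 10-fold CV and for the
cross-environment scheme where one site trains the model (in 90/10 splits)
and the other site's observations validate it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _samplers
from .geno_qc import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

MODELS = ("rrBLUP", "BL", "RKHS", "WGBLUP")
MISSING_RATE_GRID = (0.15, 0.20, 0.30)


# ---------------------------------------------------------------------------
# kinship


@dataclass
class KinshipMatrix:
    """VanRaden additive genomic relationship matrix."""

    matrix: np.ndarray            # samples x samples
    allele_freq: np.ndarray       # per-marker ALT frequency p_i
    denominator: float            # 2 sum p_i (1 - p_i)
    samples: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


def _dose_array(gm) -> np.ndarray:
    if isinstance(gm, GenotypeMatrix):
        if (gm.doses == MISSING).any():
            raise ValueError("complete (imputed) genotypes required")
        return gm.doses.astype(float)
    return np.asarray(gm, dtype=float)


def vanraden_g(gm, weights: np.ndarray | None = None) -> KinshipMatrix:
    """G = Wc D Wc' / (2 sum p_i(1-p_i)) with Wc the dose matrix centered
    by twice the allele frequency; D = I gives the plain VanRaden matrix."""
    W = _dose_array(gm)
    p = W.mean(axis=0) / 2.0
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero kinship denominator")
    Wc = W - 2.0 * p
    if weights is None:
        G = Wc @ Wc.T / denom
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != W.shape[1]:
            raise ValueError("one weight per marker required")
        G = (Wc * w) @ Wc.T / denom
    samples = gm.samples if isinstance(gm, GenotypeMatrix) else None
    return KinshipMatrix(matrix=G, allele_freq=p, denominator=denom,
                         samples=samples)


def pvalue_weights(pvalues: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Map association p-values to kernel weights: d_i proportional to
    -log10(p_i), rescaled to mean 1 and floored at ``eps`` so the weighted
    kernel keeps the overall genomic variance scale."""
    p = np.clip(np.asarray(pvalues, dtype=float), 1e-300, 1.0)
    d = -np.log10(p)
    mean = d.mean()
    if mean <= 0:
        return np.ones_like(d)
    return np.maximum(d / mean, eps)


# ---------------------------------------------------------------------------
# model configuration / results containers


@dataclass(frozen=True)
class GSModelConfig:
    """One cell of the model grid."""

    model: str = "rrBLUP"
    structure_included: bool = False
    marker_missing_threshold: float = 0.30
    iterations: int = 10_000
    burn_in: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; one of {MODELS}")
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")


@dataclass
class PredictionRun:
    """Repeated-CV predictive abilities for one grid cell."""

    config: GSModelConfig
    trait: str
    scenario: str                     # "intra" | "cross-env"
    abilities: list[float]

    @property
    def mean_ability(self) -> float:
        return float(np.mean(self.abilities))


def _design(n: int, X: np.ndarray | None) -> np.ndarray:
    C = np.ones((n, 1))
    if X is not None and np.size(X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            X = X.T
        C = np.hstack([C, X])
    return C


def _hyper_scale(var_y: float, df0: float = 5.0, r2: float = 0.5) -> float:
    """Scaled-inverse-chi-square scale with prior mode r2 * var(y)."""
    return r2 * max(var_y, 1e-12) * (df0 + 2.0) / df0


# ---------------------------------------------------------------------------
# rrBLUP


class RRBLUP:
    """Ridge-regression BLUP with the ridge parameter lambda = s2_e / s2_q
    estimated by restricted maximum likelihood on the eigendecomposition of
    the marker kernel WW' (fixed effects projected out first, as in the
    standard mixed.solve approach)."""

    def __init__(self, log10_delta_bounds: tuple[float, float] = (-6.0, 10.0),
                 fixed_delta: float | None = None):
        self.bounds = log10_delta_bounds
        self.fixed_delta = fixed_delta

    def fit(self, y: np.ndarray, W: np.ndarray,
            X: np.ndarray | None = None) -> "RRBLUPResults":
        y = np.asarray(y, dtype=float)
        W = np.asarray(W, dtype=float)
        n, m = W.shape
        C = _design(n, X)
        col_means = W.mean(axis=0)
        Wc = W - col_means
        if np.var(y) == 0:
            warnings.warn("zero-variance phenotype: all marker effects zero")
            beta = np.zeros(C.shape[1])
            beta[0] = y[0] if n else 0.0
            return RRBLUPResults(beta=beta, q=np.zeros(m),
                                 col_means=col_means, delta=np.inf,
                                 sigma2_q=0.0, sigma2_e=0.0, flagged=True)
        K = Wc @ Wc.T
        # orthonormal basis of the complement of the fixed-effect space
        Qfull, _ = np.linalg.qr(C, mode="complete")
        k = np.linalg.matrix_rank(C)
        Q = Qfull[:, k:]
        Kt = Q.T @ K @ Q
        S, U = np.linalg.eigh(Kt)
        S = np.maximum(S, 0.0)
        yt = U.T @ (Q.T @ y)
        nr = yt.shape[0]

        def negll(log10_delta: float) -> float:
            w = S + 10.0 ** log10_delta
            s2q = float(np.sum(yt * yt / w) / nr)
            return 0.5 * (nr * np.log(max(s2q, 1e-300)) + np.sum(np.log(w)))

        if self.fixed_delta is not None:
            delta = float(self.fixed_delta)
        else:
            from scipy.optimize import minimize_scalar
            grid = np.linspace(self.bounds[0], self.bounds[1], 33)
            vals = [negll(g) for g in grid]
            i0 = int(np.argmin(vals))
            lo = grid[max(i0 - 1, 0)]
            hi = grid[min(i0 + 1, len(grid) - 1)]
            res = minimize_scalar(negll, bounds=(lo, hi), method="bounded")
            delta = float(10.0 ** res.x)

        w = S + delta
        s2q = float(np.sum(yt * yt / w) / nr)
        s2e = delta * s2q
        # GLS fixed effects and BLUP marker effects on the full space
        Sf, Uf = np.linalg.eigh(K)
        wf = np.maximum(Sf, 0.0) + delta
        Ctf = Uf.T @ C
        ytf = Uf.T @ y
        CtWC = (Ctf / wf[:, None]).T @ Ctf
        CtWy = (Ctf / wf[:, None]).T @ ytf
        beta = np.linalg.solve(CtWC, CtWy)
        r = ytf - Ctf @ beta
        q = Wc.T @ (Uf @ (r / wf))
        return RRBLUPResults(beta=beta, q=q, col_means=col_means,
                             delta=delta, sigma2_q=s2q, sigma2_e=s2e)


@dataclass
class RRBLUPResults:
    beta: np.ndarray              # intercept + structure effects
    q: np.ndarray                 # marker effects
    col_means: np.ndarray
    delta: float                  # lambda = s2_e / s2_q
    sigma2_q: float
    sigma2_e: float
    flagged: bool = False

    @property
    def mu(self) -> float:
        return float(self.beta[0])

    def predict(self, W_new: np.ndarray,
                X_new: np.ndarray | None = None) -> np.ndarray:
        W_new = np.asarray(W_new, dtype=float)
        C = _design(W_new.shape[0], X_new)
        return C @ self.beta + (W_new - self.col_means) @ self.q

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"param": ["mu", "lambda", "sigma2_q", "sigma2_e"],
                             "value": [self.mu, self.delta, self.sigma2_q,
                                       self.sigma2_e]})


# ---------------------------------------------------------------------------
# Bayesian Lasso


class BayesianLasso:
    """Whole-genome regression with double-exponential marker priors,
    fitted by single-site Gibbs sampling."""

    def __init__(self, iterations: int = 10_000, burn_in: int = 1_000,
                 df0: float = 5.0, lambda_prior_weight: float = 0.5,
                 seed: int = 0):
        if iterations <= burn_in:
            raise ValueError("iterations must exceed burn_in")
        self.iterations = iterations
        self.burn_in = burn_in
        self.df0 = df0
        # Gamma hyperprior on lambda^2 centered at the prior-R2=0.5
        # heuristic scale 2*sum(x'x)/n with weight ~ p*w pseudo-observations;
        # guards against the shrinkage runaway of the Bayesian Lasso in
        # p >> n settings with diffuse polygenic signal
        self.lambda_prior_weight = lambda_prior_weight
        self.seed = seed

    def fit(self, y: np.ndarray, W: np.ndarray,
            X: np.ndarray | None = None) -> "BayesianLassoResults":
        y = np.ascontiguousarray(y, dtype=np.float64)
        W = np.asarray(W, dtype=np.float64)
        n, m = W.shape
        C = np.ascontiguousarray(_design(n, X))
        col_means = W.mean(axis=0)
        Wc = np.ascontiguousarray(W - col_means)
        var_y = float(np.var(y, ddof=1)) if n > 1 else 0.0
        if var_y == 0:
            warnings.warn("zero-variance phenotype: posterior effects zero")
            beta = np.zeros(C.shape[1])
            beta[0] = y[0] if n else 0.0
            return BayesianLassoResults(beta=beta, q=np.zeros(m),
                                        col_means=col_means, sigma2_e=0.0,
                                        lambda2=np.nan, flagged=True)
        s0 = _hyper_scale(var_y, self.df0)
        sum_xtx = float((Wc ** 2).sum())
        lambda2_init = max(2.0 * sum_xtx / n, 1.0)
        w = self.lambda_prior_weight * m
        alpha, q, s2e, lam2 = _samplers.bl_gibbs(
            C, Wc, y, self.iterations, self.burn_in, self.df0, s0,
            lambda2_init, w, w / lambda2_init,
            int(self.seed) % (2 ** 31 - 1))
        if not (np.isfinite(alpha).all() and np.isfinite(q).all()):
            raise RuntimeError(f"Bayesian Lasso chain diverged "
                               f"(seed={self.seed}): non-finite draws")
        return BayesianLassoResults(beta=alpha, q=q, col_means=col_means,
                                    sigma2_e=float(s2e), lambda2=float(lam2))


@dataclass
class BayesianLassoResults:
    beta: np.ndarray
    q: np.ndarray
    col_means: np.ndarray
    sigma2_e: float
    lambda2: float
    flagged: bool = False

    @property
    def mu(self) -> float:
        return float(self.beta[0])

    def predict(self, W_new: np.ndarray,
                X_new: np.ndarray | None = None) -> np.ndarray:
        W_new = np.asarray(W_new, dtype=float)
        C = _design(W_new.shape[0], X_new)
        return C @ self.beta + (W_new - self.col_means) @ self.q


# ---------------------------------------------------------------------------
# RKHS / G-BLUP


class RKHSRegression:
    """Bayesian G-BLUP with an arbitrary PSD relationship kernel."""

    def __init__(self, iterations: int = 10_000, burn_in: int = 1_000,
                 df0: float = 5.0, seed: int = 0, jitter: float = 1e-8,
                 psd_tol: float = 1e-4):
        if iterations <= burn_in:
            raise ValueError("iterations must exceed burn_in")
        self.iterations = iterations
        self.burn_in = burn_in
        self.df0 = df0
        self.seed = seed
        self.jitter = jitter
        self.psd_tol = psd_tol

    def fit(self, y: np.ndarray, G: np.ndarray | KinshipMatrix,
            X: np.ndarray | None = None) -> "RKHSResults":
        y = np.asarray(y, dtype=float)
        Gm = G.matrix if isinstance(G, KinshipMatrix) else np.asarray(G, float)
        n = y.shape[0]
        if Gm.shape != (n, n):
            raise ValueError("kernel shape does not match phenotype length")
        lam, U = np.linalg.eigh(Gm)
        scale = max(float(lam.max()), 1e-12)
        if lam.min() < -self.psd_tol * scale:
            raise ValueError("kernel is not PSD beyond jitter tolerance "
                             f"(min eigenvalue {lam.min():.3g})")
        if lam.min() < 0:
            logger.info("kernel has tiny negative eigenvalues; jitter applied")
        keep = lam > max(self.jitter, 1e-10 * scale)
        lam, U = lam[keep], U[:, keep]
        C = _design(n, X)
        var_y = float(np.var(y, ddof=1)) if n > 1 else 0.0
        s0 = _hyper_scale(max(var_y, 1e-12), self.df0)
        alpha, g, s2g, s2e = _samplers.rkhs_gibbs(
            C, U, lam, y, self.iterations, self.burn_in, self.df0,
            s0, s0, int(self.seed) % (2 ** 31 - 1))
        return RKHSResults(beta=alpha, g=g, sigma2_g=float(s2g),
                           sigma2_e=float(s2e), G_train=Gm,
                           jitter=self.jitter)


@dataclass
class RKHSResults:
    beta: np.ndarray
    g: np.ndarray                  # posterior-mean genetic values (train)
    sigma2_g: float
    sigma2_e: float
    G_train: np.ndarray
    jitter: float = 1e-8

    @property
    def mu(self) -> float:
        return float(self.beta[0])

    def predict(self, G_new_train: np.ndarray,
                X_new: np.ndarray | None = None) -> np.ndarray:
        """Genetic-value prediction for new samples through their kernel rows
        against the training set: g_new = G_new,train G_train^-1 g_train."""
        G_nt = np.atleast_2d(np.asarray(G_new_train, dtype=float))
        n_tr = self.G_train.shape[0]
        A = self.G_train + self.jitter * 10 * np.eye(n_tr)
        g_new = G_nt @ np.linalg.solve(A, self.g)
        C = _design(G_nt.shape[0], X_new)
        return C @ self.beta + g_new


class WeightedGBLUP:
    """G-BLUP on a p-value-weighted kernel, weights computed on training
    samples only (no test-fold phenotype ever touches the weighting)."""

    def __init__(self, iterations: int = 10_000, burn_in: int = 1_000,
                 df0: float = 5.0, seed: int = 0,
                 association_engine=None, weight_floor: float = 1e-3):
        self.rkhs_kwargs = dict(iterations=iterations, burn_in=burn_in,
                                df0=df0, seed=seed)
        self.association_engine = association_engine
        self.weight_floor = weight_floor

    def weighted_kernel(self, y_train: np.ndarray, gm: GenotypeMatrix,
                        train_idx: np.ndarray,
                        X_train: np.ndarray | None = None) -> KinshipMatrix:
        """G* over all samples, with weights from a scan on the training
        rows; falls back to D = I with a loud warning on scan failure."""
        from .gwas_scan import marker_scan

        engine = self.association_engine or (
            lambda y, g, cov: marker_scan(y, g, cov).table["p"].to_numpy())
        gm_train = gm.subset(sample_idx=train_idx)
        try:
            pvals = engine(np.asarray(y_train, float), gm_train, X_train)
            weights = pvalue_weights(pvals, eps=self.weight_floor)
        except Exception as exc:   # noqa: BLE001 - deliberate fallback
            warnings.warn("WGBLUP association scan failed "
                          f"({exc}); falling back to uniform weights D = I")
            weights = None
        return vanraden_g(gm, weights=weights)

    def fit(self, y_train: np.ndarray, gm: GenotypeMatrix,
            train_idx: np.ndarray,
            X: np.ndarray | None = None) -> "WGBLUPResults":
        X_train = None if X is None else np.atleast_2d(X)[train_idx]
        kin = self.weighted_kernel(y_train, gm, train_idx, X_train)
        Gm = kin.matrix
        rkhs = RKHSRegression(**self.rkhs_kwargs).fit(
            np.asarray(y_train, float), Gm[np.ix_(train_idx, train_idx)],
            X_train)
        return WGBLUPResults(rkhs=rkhs, kinship=kin, train_idx=train_idx)


@dataclass
class WGBLUPResults:
    rkhs: RKHSResults
    kinship: KinshipMatrix
    train_idx: np.ndarray

    def predict(self, test_idx: np.ndarray,
                X_new: np.ndarray | None = None) -> np.ndarray:
        G_nt = self.kinship.matrix[np.ix_(test_idx, self.train_idx)]
        return self.rkhs.predict(G_nt, X_new)


# ---------------------------------------------------------------------------
# model dispatch and cross-validation


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _align(y, gm: GenotypeMatrix) -> np.ndarray:
    if isinstance(y, pd.Series):
        arr = y.reindex(gm.samples).to_numpy(float)
        if np.isnan(arr).any():
            raise ValueError("phenotype missing for some genotyped samples")
        return arr
    arr = np.asarray(y, float)
    if arr.shape[0] != gm.n_samples:
        raise ValueError("phenotype/genotype sample mismatch")
    return arr


def _align_labels(cross_labels, gm: GenotypeMatrix):
    if cross_labels is None:
        return None
    if isinstance(cross_labels, pd.Series):
        return cross_labels.reindex(gm.samples).to_numpy()
    labels = np.asarray(cross_labels)
    if labels.shape[0] != gm.n_samples:
        raise ValueError("cross labels do not match the genotype samples; "
                         "pass a Series indexed by sample id")
    return labels


def fit_predict(config: GSModelConfig, y: np.ndarray, gm: GenotypeMatrix,
                train_idx: np.ndarray, test_idx: np.ndarray,
                covariates: np.ndarray | None = None,
                seed: int | None = None) -> np.ndarray:
    """Fit the configured model on the training rows and predict the test
    rows.  Kernel models use marker (not phenotype) data of all samples to
    build the relationship matrix; WGBLUP weights use training phenotypes
    only."""
    seed = config.seed if seed is None else seed
    W = gm.doses.astype(float)
    X = None
    if config.structure_included and covariates is not None \
            and np.size(covariates):
        X = np.atleast_2d(np.asarray(covariates, float))
        if X.shape[0] != gm.n_samples:
            X = X.T
    X_tr = None if X is None else X[train_idx]
    X_te = None if X is None else X[test_idx]
    y_tr = y[train_idx]

    if config.model == "rrBLUP":
        res = RRBLUP().fit(y_tr, W[train_idx], X_tr)
        return res.predict(W[test_idx], X_te)
    if config.model == "BL":
        res = BayesianLasso(iterations=config.iterations,
                            burn_in=config.burn_in, seed=seed).fit(
            y_tr, W[train_idx], X_tr)
        return res.predict(W[test_idx], X_te)
    if config.model == "RKHS":
        kin = vanraden_g(gm)
        res = RKHSRegression(iterations=config.iterations,
                             burn_in=config.burn_in, seed=seed).fit(
            y_tr, kin.matrix[np.ix_(train_idx, train_idx)], X_tr)
        return res.predict(kin.matrix[np.ix_(test_idx, train_idx)], X_te)
    if config.model == "WGBLUP":
        model = WeightedGBLUP(iterations=config.iterations,
                              burn_in=config.burn_in, seed=seed)
        res = model.fit(y_tr, gm, train_idx, X)
        return res.predict(test_idx, X_te)
    raise ValueError(f"unknown model {config.model!r}")


def _stratified_folds(n: int, folds: int, cross_labels,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold assignment stratified by cross so every family appears in
    training and test folds alike."""
    assign = np.empty(n, dtype=int)
    if cross_labels is None:
        perm = rng.permutation(n)
        assign[perm] = np.arange(n) % folds
        return assign
    labels = np.asarray(cross_labels)
    offset = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        assign[idx] = (np.arange(idx.size) + offset) % folds
        offset += idx.size
    return assign


def crossval_intra(y, gm: GenotypeMatrix, config: GSModelConfig,
                   folds: int = 10, repeats: int = 10, seed: int = 0,
                   cross_labels=None,
                   covariates: np.ndarray | None = None) -> PredictionRun:
    """Within-environment repeated k-fold CV; per repeat the held-out
    predictions of all folds are pooled into one Pearson correlation."""
    y_arr = _align(y, gm)
    labels = _align_labels(cross_labels, gm)
    n = gm.n_samples
    if n < folds:
        raise ValueError(f"{n} samples cannot fill {folds} folds")
    ss = np.random.SeedSequence(seed)
    abilities = []
    for rep, child in enumerate(ss.spawn(repeats)):
        rng = np.random.default_rng(child)
        assign = _stratified_folds(n, folds, labels, rng)
        preds = np.empty(n)
        for f in range(folds):
            te = np.flatnonzero(assign == f)
            tr = np.flatnonzero(assign != f)
            fit_seed = int(rng.integers(2 ** 31 - 1))
            preds[te] = fit_predict(config, y_arr, gm, tr, te,
                                    covariates=covariates, seed=fit_seed)
        abilities.append(_pearson(y_arr, preds))
    return PredictionRun(config=config, trait=getattr(y, "name", "") or "",
                         scenario="intra", abilities=abilities)


def crossval_cross_env(y_env1, y_env2, gm: GenotypeMatrix,
                       config: GSModelConfig, folds: int = 10,
                       repeats: int = 10, seed: int = 0, cross_labels=None,
                       covariates: np.ndarray | None = None) -> PredictionRun:
    """Cross-environment prediction, both directions averaged.

    Per repeat and direction, the training environment's lines are split
    90/10 (k-fold); the model trained on the 90% predicts the held-out lines
    and is scored against the *other* environment's observed values for
    those lines, pooled over folds.
    """
    y1 = _align(y_env1, gm)
    y2 = _align(y_env2, gm)
    labels = _align_labels(cross_labels, gm)
    n = gm.n_samples
    if n == 0:
        raise ValueError("no lines shared between environments")
    ss = np.random.SeedSequence(seed)
    abilities = []
    for child in ss.spawn(repeats):
        rng = np.random.default_rng(child)
        rs = []
        for y_train, y_valid in ((y1, y2), (y2, y1)):
            assign = _stratified_folds(n, folds, labels, rng)
            preds = np.empty(n)
            for f in range(folds):
                te = np.flatnonzero(assign == f)
                tr = np.flatnonzero(assign != f)
                fit_seed = int(rng.integers(2 ** 31 - 1))
                preds[te] = fit_predict(config, y_train, gm, tr, te,
                                        covariates=covariates, seed=fit_seed)
            rs.append(_pearson(y_valid, preds))
        abilities.append(float(np.mean(rs)))
    trait = getattr(y_env1, "name", "") or ""
    return PredictionRun(config=config, trait=trait, scenario="cross-env",
                         abilities=abilities)


# ---------------------------------------------------------------------------
# the model grid


def run_grid(phenotypes: dict[str, "pd.Series | np.ndarray"],
             gm_by_threshold: dict[float, GenotypeMatrix],
             covariates_by_threshold: dict[float, np.ndarray] | None = None,
             cross_labels=None, models: tuple[str, ...] = MODELS,
             structure_flags: tuple[bool, ...] = (False, True),
             cross_env_pairs: dict[str, tuple[str, str]] | None = None,
             folds: int = 10, repeats: int = 10, iterations: int = 10_000,
             burn_in: int = 1_000, seed: int = 0) -> pd.DataFrame:
    """Execute the full model x threshold x structure grid.

    ``phenotypes`` maps a trait/environment key (e.g. ``"yield@env1"``) to a
    response vector; ``cross_env_pairs`` maps a trait name to the pair of
    phenotype keys used for cross-environment prediction.  Partial failures
    are recorded per cell and the grid continues.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    cell = 0
    for thr, gm in sorted(gm_by_threshold.items()):
        cov = None
        if covariates_by_threshold is not None:
            cov = covariates_by_threshold.get(thr)
        for model in models:
            for flag in structure_flags:
                config = GSModelConfig(
                    model=model, structure_included=flag,
                    marker_missing_threshold=thr, iterations=iterations,
                    burn_in=burn_in, seed=seed)
                for key, y in phenotypes.items():
                    cell += 1
                    cell_seed = int(ss.spawn(1)[0].generate_state(1)[0]
                                    % (2 ** 31 - 1))
                    try:
                        run = crossval_intra(
                            y, gm, config, folds=folds, repeats=repeats,
                            seed=cell_seed, cross_labels=cross_labels,
                            covariates=cov)
                        rows.append((key, "intra", model, flag, thr,
                                     run.mean_ability, run.abilities, ""))
                    except Exception as exc:   # noqa: BLE001
                        logger.warning("grid cell failed (%s/%s): %s",
                                       key, model, exc)
                        rows.append((key, "intra", model, flag, thr,
                                     np.nan, [], str(exc)))
                if cross_env_pairs:
                    for trait, (k1, k2) in cross_env_pairs.items():
                        cell += 1
                        cell_seed = int(ss.spawn(1)[0].generate_state(1)[0]
                                        % (2 ** 31 - 1))
                        try:
                            run = crossval_cross_env(
                                phenotypes[k1], phenotypes[k2], gm, config,
                                folds=folds, repeats=repeats, seed=cell_seed,
                                cross_labels=cross_labels, covariates=cov)
                            rows.append((trait, "cross-env", model, flag, thr,
                                         run.mean_ability, run.abilities, ""))
                        except Exception as exc:   # noqa: BLE001
                            logger.warning("grid cell failed (%s/%s): %s",
                                           trait, model, exc)
                            rows.append((trait, "cross-env", model, flag, thr,
                                         np.nan, [], str(exc)))
    return pd.DataFrame(rows, columns=["trait", "scenario", "model",
                                       "structure", "threshold",
                                       "mean_ability", "abilities", "error"])


def best_per_trait(grid: pd.DataFrame) -> pd.DataFrame:
    """One row per trait x scenario: the best-performing configuration."""
    ok = grid.dropna(subset=["mean_ability"])
    idx = ok.groupby(["trait", "scenario"])["mean_ability"].idxmax()
    cols = ["trait", "scenario", "model", "structure", "threshold",
            "mean_ability"]
    return ok.loc[idx, cols].reset_index(drop=True)


def model_threshold_means(grid: pd.DataFrame) -> pd.DataFrame:
    """Model x threshold mean abilities over traits (intra scenario)."""
    sub = grid[grid["scenario"] == "intra"]
    table = sub.pivot_table(index="model", columns="threshold",
                            values="mean_ability", aggfunc="mean")
    table["average"] = table.mean(axis=1)
    return table
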
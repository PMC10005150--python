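"""Structure-adjusted single-marker association scans on line BLUPs.

Each marker is tested in a fixed-effect linear model
``BLUP ~ intercept + structure covariates + dose`` with a Wald test on the
dose term, computed for all markers at once by residualizing phenotype and
doses on the covariates (Frisch-Waugh).  Multiple testing is controlled by
a Bonferroni threshold (family-wise alpha 0.01 by default); QQ-based
genomic-inflation diagnostics are provided.  An optional iterative scan
conditions on already-selected pseudo-QTNs — a deliberately simple,
auditable stand-in for multi-locus model-search methods, off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geno_qc import MISSING, GenotypeMatrix

#: median of the chi-square distribution with 1 degree of freedom
_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class GwasResult:
    table: pd.DataFrame          # marker, chrom, pos, maf, effect, p, significant, flagged
    alpha: float
    threshold: float
    trait: str = ""
    environment: str = ""
    selected_markers: list[str] = field(default_factory=list)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def manhattan_table(self) -> pd.DataFrame:
        out = self.table[["chrom", "pos", "p"]].copy()
        out["neg_log10_p"] = -np.log10(out["p"].clip(lower=1e-300))
        return out


def bonferroni_threshold(alpha: float = 0.01, n_markers: int = 1) -> float:
    """Per-test p-value threshold alpha / n_markers."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return alpha / n_markers


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of the columns of M after OLS on covariate matrix C."""
    coef, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef


def marker_scan(blups: pd.Series | np.ndarray, gm: GenotypeMatrix,
                covariates: np.ndarray | None = None,
                alpha: float = 0.01, trait: str = "",
                environment: str = "") -> GwasResult:
    """Single-marker fixed-effect scan of one phenotype vector.

    ``blups`` must be aligned with ``gm.samples`` (a pandas Series is
    reindexed by sample id).  Effects are reported per minor-allele dose.
    Markers collinear with the covariates (or monomorphic) get p = 1 and a
    flag.
    """
    if (gm.doses == MISSING).any():
        raise ValueError("complete genotypes required for the scan")
    if isinstance(blups, pd.Series):
        y = blups.reindex(gm.samples).to_numpy(float)
        if np.isnan(y).any():
            raise ValueError("phenotype missing for some genotyped samples")
    else:
        y = np.asarray(blups, float)
        if y.shape[0] != gm.n_samples:
            raise ValueError("phenotype/genotype sample mismatch")
    n = y.shape[0]
    C = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        C = np.hstack([C, cov])
    p_cov = np.linalg.matrix_rank(C)
    df = n - p_cov - 1
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")

    W = gm.doses.astype(float)
    ry = _residualize(y[:, None], C)[:, 0]
    RW = _residualize(W, C)
    xtx = (RW ** 2).sum(axis=0)
    xty = RW.T @ ry
    tss = float(ry @ ry)
    tol = 1e-10 * max(tss, 1.0)
    ok = xtx > tol
    beta = np.zeros(gm.n_markers)
    pvals = np.ones(gm.n_markers)
    beta[ok] = xty[ok] / xtx[ok]
    rss = tss - beta[ok] ** 2 * xtx[ok]
    rss = np.maximum(rss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / xtx[ok])
        t = np.where(se > 0, beta[ok] / se, np.inf * np.sign(beta[ok]))
    pvals[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    # orient effect to the minor allele
    p_alt = W.mean(axis=0) / 2.0
    effect = np.where(p_alt > 0.5, -beta, beta)

    thr = bonferroni_threshold(alpha, gm.n_markers)
    table = pd.DataFrame({
        "marker": gm.marker_ids, "chrom": gm.chrom, "pos": gm.pos,
        "maf": gm.maf(), "effect": effect, "p": pvals,
        "significant": pvals < thr, "flagged": ~ok})
    return GwasResult(table=table, alpha=alpha, threshold=thr,
                      trait=trait, environment=environment)


def qq_inflation(result: GwasResult) -> tuple[float, pd.DataFrame]:
    """Genomic-inflation factor (median chi-square ratio) and QQ table."""
    p = result.table["p"].to_numpy(float)
    if p.size < 100:
        raise ValueError("need >= 100 markers for a stable inflation factor")
    if np.all(p >= 1.0):
        import warnings
        warnings.warn("all p-values are 1: degenerate scan")
        return np.nan, pd.DataFrame({"expected": [], "observed": []})
    chi2_obs = stats.chi2.ppf(1.0 - p, 1)
    lam = float(np.median(chi2_obs) / _CHI2_1_MEDIAN)
    obs = -np.log10(np.sort(p))
    exp = -np.log10((np.arange(1, p.size + 1) - 0.5) / p.size)
    return lam, pd.DataFrame({"expected": exp, "observed": obs})


def iterative_pseudo_qtn_refinement(blups, gm: GenotypeMatrix,
                                    covariates: np.ndarray | None = None,
                                    max_rounds: int = 5, alpha: float = 0.01,
                                    ld_cutoff: float = 0.8) -> GwasResult:
    """Multi-round scan conditioning on selected pseudo-QTNs.

    Each round, the most significant marker below the Bonferroni threshold
    is promoted to a fixed covariate — unless its r2 with an already-selected
    marker exceeds ``ld_cutoff`` — and the scan repeats; stops when no new
    marker is significant or after ``max_rounds``.  Final p-values come from
    the last round.
    """
    if max_rounds < 1:
        return marker_scan(blups, gm, covariates, alpha=alpha)
    selected: list[int] = []
    W = gm.doses.astype(float)
    result = marker_scan(blups, gm, covariates, alpha=alpha)
    for _ in range(max_rounds):
        tab = result.table
        cand = tab[tab["significant"]].sort_values("p")
        new_idx = None
        for marker in cand["marker"]:
            j = int(np.flatnonzero(gm.marker_ids == marker)[0])
            if j in selected:
                continue
            in_ld = False
            for s in selected:
                r = np.corrcoef(W[:, j], W[:, s])[0, 1]
                if r * r > ld_cutoff:
                    in_ld = True
                    break
            if not in_ld:
                new_idx = j
                break
        if new_idx is None:
            break
        selected.append(new_idx)
        extra = W[:, selected]
        cov = extra if covariates is None or not np.size(covariates) \
            else np.hstack([np.atleast_2d(covariates), extra])
        result = marker_scan(blups, gm, cov, alpha=alpha)
    result.selected_markers = [str(gm.marker_ids[j]) for j in selected]
    return result
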
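"""Population structure: PCA, k-means model selection by BIC, and
discriminant analysis of principal components (DAPC).

The procedure mirrors the standard DAPC workflow: an ordinary PCA of the
centered dose matrix keeping all components, k-means over an increasing
number of groups K with the conventional k-means BIC
``n ln(WSS_K / n) + K ln(n)`` selected at its first local minimum, then
linear discriminant axes on a subset of PCs with the number of retained PCs
chosen by the a-score criterion (observed minus permuted reassignment
success), guarding against the method's propensity to overfit.  The
retained discriminant scores are the structure covariates used by GWAS and
genomic prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .geno_qc import MISSING, GenotypeMatrix


@dataclass
class StructureResult:
    pca_scores: np.ndarray               # samples x components
    explained_variance: np.ndarray
    bic: np.ndarray                      # one value per K in 1..K_max
    chosen_k: int
    assignments: np.ndarray
    discriminant_scores: np.ndarray | None = None
    n_retained: int | None = None
    a_scores: pd.DataFrame | None = None

    @property
    def covariates(self) -> np.ndarray:
        """Structure covariates for downstream models: always the DAPC
        discriminant scores (never raw PCs); empty when K = 1."""
        if self.chosen_k <= 1 or self.discriminant_scores is None:
            return np.empty((self.pca_scores.shape[0], 0))
        return self.discriminant_scores


def pca_genotypes(gm: GenotypeMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the per-marker-centered dose matrix, all components kept.

    Returns (scores, explained variances); the variances sum to the total
    marker variance.  Requires a complete (imputed) matrix.
    """
    X = gm.doses if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    if (X == MISSING).any():
        raise ValueError("matrix has missing entries: impute before PCA")
    X = X.astype(float)
    Xc = X - X.mean(axis=0)
    n = X.shape[0]
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    explained = s ** 2 / (n - 1)
    return scores, explained


def kmeans_bic(scores: np.ndarray, assignments: np.ndarray, k: int) -> float:
    """Conventional k-means BIC: n ln(WSS/n) + K ln(n)."""
    n = scores.shape[0]
    wss = 0.0
    for c in range(k):
        pts = scores[assignments == c]
        if pts.shape[0]:
            wss += ((pts - pts.mean(axis=0)) ** 2).sum()
    wss = max(wss, 1e-300)
    return float(n * np.log(wss / n) + k * np.log(n))


def select_k(scores: np.ndarray, k_max: int = 20, n_starts: int = 50,
             seed: int = 0) -> tuple[np.ndarray, int, np.ndarray]:
    """Best-of-``n_starts`` k-means for each K, scored by BIC.

    The chosen K is the first local minimum of the BIC curve (BIC(K) <
    BIC(K-1) and BIC(K) <= BIC(K+1)); if the curve has no interior local
    minimum the global minimum is taken.  Ties break toward lower WSS, then
    lower K.
    """
    n = scores.shape[0]
    if k_max < 1:
        raise ValueError("K_max must be >= 1")
    if k_max > n:
        warnings.warn(f"K_max {k_max} > n_samples {n}; truncating")
        k_max = n
    bics = np.empty(k_max)
    assign = {}
    for k in range(1, k_max + 1):
        if k == 1:
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
            labels = km.fit_predict(scores)
        assign[k] = labels
        bics[k - 1] = kmeans_bic(scores, labels, k)
    chosen = None
    for k in range(2, k_max):
        if bics[k - 1] < bics[k - 2] and bics[k - 1] <= bics[k]:
            chosen = k
            break
    if chosen is None:
        chosen = int(np.argmin(bics)) + 1
    return bics, chosen, assign[chosen]


def dapc(scores: np.ndarray, assignments: np.ndarray,
         n_pcs_kept: int) -> tuple[np.ndarray, np.ndarray]:
    """Linear discriminant axes on the first ``n_pcs_kept`` PCs.

    Returns (per-sample discriminant scores, discriminant eigenvalue ratios).
    At most K - 1 axes exist; singleton clusters are merged into their
    nearest cluster centroid with a warning.
    """
    labels = np.asarray(assignments).copy()
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("DAPC needs >= 2 clusters")
    if (counts == 1).any():
        warnings.warn("singleton cluster(s) merged into nearest cluster")
        big = uniq[counts > 1]
        cents = {c: scores[labels == c].mean(axis=0) for c in big}
        for c in uniq[counts == 1]:
            x = scores[labels == c][0]
            nearest = min(cents, key=lambda cc: np.sum((x - cents[cc]) ** 2))
            labels[labels == c] = nearest
        uniq = np.unique(labels)
    X = scores[:, :n_pcs_kept]
    lda = LinearDiscriminantAnalysis(solver="eigen")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lda.fit(X, labels)
        ds = lda.transform(X)
    n_axes = min(uniq.size - 1, n_pcs_kept)
    ev = getattr(lda, "explained_variance_ratio_", np.ones(n_axes))
    return ds[:, :n_axes], np.asarray(ev)[:n_axes]


def _reassignment_success(pc_scores: np.ndarray, labels: np.ndarray,
                          n_pcs: int) -> float:
    X = pc_scores[:, :n_pcs]
    lda = LinearDiscriminantAnalysis(solver="eigen")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lda.fit(X, labels)
        return float((lda.predict(X) == labels).mean())


def a_score_retention(scores: np.ndarray, assignments: np.ndarray,
                      max_components: int | None = None,
                      n_permutations: int = 10, seed: int = 0
                      ) -> tuple[int, pd.DataFrame]:
    """Choose how many PCs to keep for DAPC by the a-score.

    For each candidate count, a-score = observed reassignment success minus
    the mean success after permuting cluster labels; the retained count
    maximizes it.  When no candidate's a-score clears the permutation noise
    floor (0.1), the structure signal is indistinguishable from overfitting
    and minimal retention (one component) is chosen.
    """
    if n_permutations < 2:
        raise ValueError("need >= 2 permutations")
    labels = np.asarray(assignments)
    if np.unique(labels).size < 2:
        raise ValueError("a-score needs >= 2 clusters")
    rng = np.random.default_rng(seed)
    n = scores.shape[0]
    if max_components is None:
        max_components = min(n - np.unique(labels).size, scores.shape[1], 40)
    max_components = min(max_components, scores.shape[1])
    rows = []
    for n_pcs in range(1, max_components + 1):
        obs = _reassignment_success(scores, labels, n_pcs)
        perm = [_reassignment_success(scores, rng.permutation(labels), n_pcs)
                for _ in range(n_permutations)]
        rows.append((n_pcs, obs, float(np.mean(perm)),
                     obs - float(np.mean(perm))))
    table = pd.DataFrame(rows, columns=["n_pcs", "observed", "permuted_mean",
                                        "a_score"])
    if table["a_score"].max() > 0.1:
        n_retained = int(table.loc[table["a_score"].idxmax(), "n_pcs"])
    else:
        n_retained = 1
    return n_retained, table


def n_pcs_for_clustering(explained: np.ndarray, variance_frac: float = 0.5,
                         minimum: int = 2) -> int:
    """Number of leading PCs explaining ``variance_frac`` of the variance.

    k-means model selection runs on this informative subspace: with all
    components kept the within-cluster sum of squares is dominated by the
    isotropic noise floor and the BIC underestimates K.
    """
    frac = np.cumsum(explained) / explained.sum()
    return max(int(np.searchsorted(frac, variance_frac) + 1), minimum)


def infer_structure(gm: GenotypeMatrix, k_max: int = 20, n_starts: int = 50,
                    n_permutations: int = 10, seed: int = 0,
                    n_pcs_cluster: int | None = None,
                    max_covariates: int | None = None) -> StructureResult:
    """Full DAPC pipeline: PCA -> BIC-selected K -> a-score -> discriminant
    scores used as structure covariates downstream."""
    scores, explained = pca_genotypes(gm)
    if n_pcs_cluster is None:
        n_pcs_cluster = n_pcs_for_clustering(explained)
    bics, k, labels = select_k(scores[:, :n_pcs_cluster], k_max=k_max,
                               n_starts=n_starts, seed=seed)
    result = StructureResult(pca_scores=scores, explained_variance=explained,
                             bic=bics, chosen_k=k, assignments=labels)
    if k >= 2:
        n_ret, ascore = a_score_retention(scores, labels,
                                          n_permutations=n_permutations,
                                          seed=seed)
        ds, _ = dapc(scores, labels, n_ret)
        if max_covariates is not None:
            ds = ds[:, :max_covariates]
        result.discriminant_scores = ds
        result.n_retained = n_ret
        result.a_scores = ascore
    return result


def write_structure(result: StructureResult, samples, path_prefix: str) -> None:
    """TSV writers interoperable with deposited square component matrices."""
    pd.DataFrame({"K": np.arange(1, len(result.bic) + 1),
                  "BIC": result.bic}).to_csv(
        f"{path_prefix}_bic.tsv", sep="\t", index=False)
    cov = result.covariates
    pd.DataFrame(cov, index=samples,
                 columns=[f"DA{i+1}" for i in range(cov.shape[1])]).to_csv(
        f"{path_prefix}_dapc.tsv", sep="\t", index_label="line")
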
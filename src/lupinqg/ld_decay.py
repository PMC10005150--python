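"""Linkage-disequilibrium decay within physical windows.

Pairwise r-squared (squared Pearson correlation of allele doses) is computed
for every intra-chromosomal marker pair closer than a window (default
100 kb).  The decay summary is the half-decay distance: the smallest
distance at which a fitted decay curve falls to half the 90th percentile of
all pair r-squared values.  Two curve families are available — a low-order
polynomial in log10 distance with a monotone non-increasing clip (default)
and the Hill-Weir drift expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .geno_qc import MISSING, GenotypeMatrix


@dataclass
class DecayFit:
    half_target: float               # 0.5 * 90th percentile of r2
    percentile90: float
    half_decay_bp: float             # np.inf when the curve never crosses
    crossed: bool
    curve: str                       # "polynomial" | "hill-weir"
    params: np.ndarray
    n_pairs: int


@dataclass
class LDDecayResult:
    pairs: pd.DataFrame              # chrom, pos1, pos2, dist_bp, r2
    genome: DecayFit
    per_chromosome: dict[int, DecayFit]

    def summary(self) -> pd.DataFrame:
        rows = [("genome", self.genome.percentile90,
                 self.genome.half_decay_bp, self.genome.n_pairs)]
        for c, fit in sorted(self.per_chromosome.items()):
            rows.append((f"chr{c:02d}", fit.percentile90,
                         fit.half_decay_bp, fit.n_pairs))
        return pd.DataFrame(rows, columns=["scope", "r2_p90",
                                           "half_decay_bp", "n_pairs"])


def pairwise_r2(gm: GenotypeMatrix, window_bp: int = 100_000) -> pd.DataFrame:
    """All intra-chromosomal pairs with 0 < distance <= window.

    r2 is the squared Pearson correlation of the dose vectors; monomorphic
    markers yield undefined correlations and their pairs are skipped.
    Markers are sorted by (chromosome, position) if needed.
    """
    if (gm.doses == MISSING).any():
        raise ValueError("complete (imputed) matrix required for LD")
    order = np.lexsort((gm.pos, gm.chrom))
    if not np.array_equal(order, np.arange(gm.n_markers)):
        warnings.warn("markers not sorted by position; sorting internally")
        gm = gm.subset(marker_idx=order)
    X = gm.doses.astype(float)
    sd = X.std(axis=0)
    rows = []
    for c in np.unique(gm.chrom):
        idx = np.flatnonzero(gm.chrom == c)
        pos = gm.pos[idx]
        for a_i, i in enumerate(idx):
            # markers within the window ahead of i
            hi = np.searchsorted(pos, pos[a_i] + window_bp, side="right")
            for b_i in range(a_i + 1, hi):
                j = idx[b_i]
                d = int(pos[b_i] - pos[a_i])
                if d == 0:
                    continue
                if sd[i] == 0 or sd[j] == 0:
                    continue
                r = np.corrcoef(X[:, i], X[:, j])[0, 1]
                rows.append((int(c), int(pos[a_i]), int(pos[b_i]), d, r * r))
    return pd.DataFrame(rows, columns=["chrom", "pos1", "pos2",
                                       "dist_bp", "r2"])


def _hill_weir(d, a, b, n=100.0):
    """Hill-Weir drift-recombination expectation of r2 vs distance
    (C = a*d) for a sample of n sequences, with a free scale b."""
    C = np.maximum(a * np.asarray(d, dtype=float), 1e-12)
    e = ((10 + C) / ((2 + C) * (11 + C))) * \
        (1 + ((3 + C) * (12 + 12 * C + C ** 2)) /
         (n * (2 + C) * (11 + C)))
    return b * e


def fit_decay(pairs: pd.DataFrame, curve: str = "polynomial",
              min_pairs: int = 50, degree: int = 2,
              window_bp: int | None = None,
              n_samples: int = 100) -> DecayFit:
    """Fit the decay trend and locate the half-of-90th-percentile crossing.

    The default curve is a degree-2 polynomial of r2 on log10 distance whose
    fitted values are clipped to be non-increasing in distance (a running
    minimum from the left), so the crossing is well defined.  The half-decay
    distance is the smallest distance where the fitted curve drops to
    0.5 x (90th percentile of all pair r2); if the curve stays above the
    target over the observed range the result is flagged as not crossed and
    reported as > window.
    """
    if len(pairs) < min_pairs:
        raise ValueError(f"need >= {min_pairs} pairs, got {len(pairs)}")
    d = pairs["dist_bp"].to_numpy(float)
    r2 = pairs["r2"].to_numpy(float)
    p90 = float(np.percentile(r2, 90))
    target = 0.5 * p90
    dmax = window_bp if window_bp is not None else d.max()
    grid = np.unique(np.concatenate(
        [np.geomspace(max(d.min(), 1.0), dmax, 512), [dmax]]))

    if curve == "polynomial":
        # fit to equal-log-width bin means so the dense long-distance tail
        # does not dominate the least squares
        x = np.log10(d)
        n_bins = min(25, max(len(pairs) // 10, degree + 2))
        edges = np.linspace(x.min(), x.max() + 1e-9, n_bins + 1)
        ib = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
        xc, ym = [], []
        for b in range(n_bins):
            sel = ib == b
            if sel.any():
                xc.append(x[sel].mean())
                ym.append(r2[sel].mean())
        coef = np.polyfit(np.asarray(xc), np.asarray(ym), deg=degree)
        fitted = np.polyval(coef, np.log10(grid))
        params = coef
    elif curve == "hill-weir":
        best = None
        # multi-start over the recombination-rate scale: the SSE surface has
        # local optima when the decay is steep on the log scale
        def hw(dd, a, b):
            return _hill_weir(dd, a, b, n=n_samples)

        for a0 in 1.0 / np.geomspace(max(d.min(), 10.0), d.max(), 7):
            try:
                popt, _ = curve_fit(hw, d, r2,
                                    p0=[a0, max(r2.mean(), 0.05)],
                                    bounds=([1e-12, 1e-6], [np.inf, 2.0]),
                                    maxfev=10000)
            except RuntimeError:
                continue
            sse = float(np.sum((r2 - hw(d, *popt)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
        if best is None:
            warnings.warn("Hill-Weir fit failed to converge; "
                          "falling back to polynomial")
            return fit_decay(pairs, curve="polynomial", min_pairs=min_pairs,
                             degree=degree, window_bp=window_bp)
        popt = best[1]
        fitted = hw(grid, *popt)
        params = popt
    else:
        raise ValueError(f"unknown curve family: {curve}")

    # monotone clip anchored at the curve's peak: flat up to the maximum,
    # running minimum after it (guards against edge-extrapolation dips)
    fitted = np.clip(fitted, 0.0, 1.0)
    imax = int(np.argmax(fitted))
    fitted[:imax] = fitted[imax]
    fitted = np.minimum.accumulate(fitted)
    below = fitted <= target
    if below.any():
        half = float(grid[np.argmax(below)])
        crossed = True
    else:
        warnings.warn("fitted curve never falls to half the 90th percentile "
                      "within the window")
        half = np.inf
        crossed = False
    return DecayFit(half_target=target, percentile90=p90, half_decay_bp=half,
                    crossed=crossed, curve=curve, params=np.asarray(params),
                    n_pairs=len(pairs))


def ld_decay(gm: GenotypeMatrix, window_bp: int = 100_000,
             curve: str = "polynomial", min_pairs: int = 50) -> LDDecayResult:
    """Genome-wide and per-chromosome LD decay.

    The 90th percentile is taken over all retained pairs genome-wide for the
    genome statistic and per chromosome for chromosome statistics;
    chromosomes with too few pairs are skipped.
    """
    pairs = pairwise_r2(gm, window_bp=window_bp)
    genome = fit_decay(pairs, curve=curve, min_pairs=min_pairs,
                       window_bp=window_bp, n_samples=gm.n_samples)
    per_chrom = {}
    for c, sub in pairs.groupby("chrom"):
        if len(sub) >= min_pairs:
            per_chrom[int(c)] = fit_decay(sub, curve=curve,
                                          min_pairs=min_pairs,
                                          window_bp=window_bp,
                                          n_samples=gm.n_samples)
    return LDDecayResult(pairs=pairs, genome=genome,
                         per_chromosome=per_chrom)
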
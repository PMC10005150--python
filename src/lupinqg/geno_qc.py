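"""Genotype matrix loading, filtering and imputation.

Implements the marker/sample QC cascade used for GBS dose matrices —
monomorphic-marker removal, MAF, per-marker and per-sample missing-rate
thresholds, and heterozygosity-excess filters — followed by iterative
random-forest imputation of the remaining missing calls with genotypes
treated as categorical classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

MISSING = -1

logger = logging.getLogger(__name__)


class EmptyPanelError(ValueError):
    """All markers (or samples) removed by a filter criterion."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic markers coded as ALT-allele dose 0/1/2."""

    samples: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    doses: np.ndarray                   # int8, MISSING = -1

    @property
    def n_samples(self) -> int:
        return self.doses.shape[0]

    @property
    def n_markers(self) -> int:
        return self.doses.shape[1]

    def observed(self) -> np.ndarray:
        return self.doses != MISSING

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker on observed calls, in [0, 0.5]."""
        obs = self.observed()
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, self.doses, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * n_obs)
        p = np.where(n_obs > 0, p, np.nan)
        return np.minimum(p, 1.0 - p)

    def marker_missing_rate(self) -> np.ndarray:
        return 1.0 - self.observed().mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return 1.0 - self.observed().mean(axis=1)

    def marker_het_rate(self) -> np.ndarray:
        obs = self.observed()
        return (self.doses == 1).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)

    def sample_het_rate(self) -> np.ndarray:
        obs = self.observed()
        return (self.doses == 1).sum(axis=1) / np.maximum(obs.sum(axis=1), 1)

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        s = np.arange(self.n_samples) if sample_idx is None else sample_idx
        m = np.arange(self.n_markers) if marker_idx is None else marker_idx
        return GenotypeMatrix(samples=self.samples[s],
                              marker_ids=self.marker_ids[m],
                              chrom=self.chrom[m], pos=self.pos[m],
                              doses=self.doses[np.ix_(s, m)])

    def sort_markers(self) -> "GenotypeMatrix":
        order = np.lexsort((self.pos, self.chrom))
        return self.subset(marker_idx=order)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.doses, index=self.samples,
                          columns=self.marker_ids)
        return df.mask(self.doses == MISSING)


@dataclass
class FilterReport:
    """Markers/samples removed per criterion, in application order."""

    n_markers_in: int
    n_samples_in: int
    markers_removed: dict[str, int] = field(default_factory=dict)
    samples_removed: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def n_markers_out(self) -> int:
        return self.n_markers_in - sum(self.markers_removed.values())

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - sum(self.samples_removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("marker", k, v) for k, v in self.markers_removed.items()]
        rows += [("sample", k, v) for k, v in self.samples_removed.items()]
        return pd.DataFrame(rows, columns=["axis", "criterion", "n_removed"])


# ---------------------------------------------------------------------------
# loading


def _from_population(pop) -> GenotypeMatrix:
    return GenotypeMatrix(samples=np.asarray(pop.line_ids),
                          marker_ids=np.asarray(pop.marker_ids),
                          chrom=np.asarray(pop.chrom),
                          pos=np.asarray(pop.pos),
                          doses=np.asarray(pop.genotypes, dtype=np.int8))


def load_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or a samples x markers 0/1/2 TSV.

    Only biallelic SNP records are kept; multi-allelic records are counted
    and logged.  VCF positions stay 1-based.
    """
    path = str(path)
    if format is None:
        format = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "vcf":
        return _load_vcf(path)
    if format == "tsv":
        return _load_tsv(path)
    raise ValueError(f"unknown genotype format: {format}")


def _load_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = np.array(vcf.samples)
    if samples.size == 0:
        raise ValueError("VCF contains no samples")
    chrom, pos, ids, rows = [], [], [], []
    n_rejected = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1 or not var.is_snp:
            n_rejected += 1
            continue
        gt = np.asarray(var.gt_types, dtype=np.int8)   # 0,1,2; 3 = unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
        c = var.CHROM
        chrom.append(int("".join(ch for ch in c if ch.isdigit()) or 0))
        pos.append(var.POS)
        ids.append(var.ID if var.ID not in (None, ".") else f"{c}_{var.POS}")
    if n_rejected:
        logger.info("rejected %d non-biallelic/non-SNP records", n_rejected)
    if not rows:
        raise ValueError("no biallelic SNP records in VCF")
    doses = np.stack(rows, axis=1)
    return GenotypeMatrix(samples=samples, marker_ids=np.array(ids),
                          chrom=np.array(chrom), pos=np.array(pos, dtype=np.int64),
                          doses=doses)


def _load_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.shape[0] == 0:
        raise ValueError("TSV contains no samples")
    doses = df.to_numpy(dtype=float)
    out = np.full(doses.shape, MISSING, dtype=np.int8)
    ok = ~np.isnan(doses)
    out[ok] = doses[ok].astype(np.int8)
    ids = df.columns.to_numpy(dtype=str)
    chrom = np.zeros(len(ids), dtype=int)
    pos = np.zeros(len(ids), dtype=np.int64)
    # marker ids of the form M<chrom>_<pos> carry their own map
    for j, mid in enumerate(ids):
        parts = mid.lstrip("M").split("_")
        if len(parts) == 2 and parts[0].isdigit() and parts[1].isdigit():
            chrom[j], pos[j] = int(parts[0]), int(parts[1])
        else:
            chrom[j], pos[j] = 1, j + 1
    return GenotypeMatrix(samples=df.index.to_numpy(dtype=str),
                          marker_ids=ids, chrom=chrom, pos=pos, doses=out)


# ---------------------------------------------------------------------------
# filtering


def filter_genotypes(gm: GenotypeMatrix, maf_min: float = 0.05,
                     max_marker_missing: float = 0.30,
                     max_sample_missing: float = 0.50,
                     het_sd_samples: float = 3.0,
                     het_sd_markers: float = 2.0,
                     ) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the QC cascade in a fixed, logged order.

    1. drop monomorphic markers; 2. MAF >= ``maf_min`` on observed calls;
    3. per-marker missing rate <= ``max_marker_missing``; 4. per-sample
    missing rate <= ``max_sample_missing``; 5. samples with heterozygosity
    above mean + ``het_sd_samples`` SD removed; 6. markers with
    heterozygosity above mean + ``het_sd_markers`` SD removed.  MAF is
    recomputed on the retained samples.
    """
    for t in (maf_min, max_marker_missing, max_sample_missing):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    if het_sd_samples < 0 or het_sd_markers < 0:
        raise ValueError("SD multipliers must be >= 0")

    report = FilterReport(n_markers_in=gm.n_markers, n_samples_in=gm.n_samples,
                          thresholds={"maf_min": maf_min,
                                      "max_marker_missing": max_marker_missing,
                                      "max_sample_missing": max_sample_missing,
                                      "het_sd_samples": het_sd_samples,
                                      "het_sd_markers": het_sd_markers})
    cur = gm

    def keep_markers(keep: np.ndarray, criterion: str):
        nonlocal cur
        report.markers_removed[criterion] = \
            report.markers_removed.get(criterion, 0) + int((~keep).sum())
        if not keep.any():
            raise EmptyPanelError(f"all markers removed by '{criterion}'")
        if not keep.all():
            cur = cur.subset(marker_idx=np.flatnonzero(keep))

    def keep_samples(keep: np.ndarray, criterion: str):
        nonlocal cur
        report.samples_removed[criterion] = \
            report.samples_removed.get(criterion, 0) + int((~keep).sum())
        if not keep.any():
            raise EmptyPanelError(f"all samples removed by '{criterion}'")
        if not keep.all():
            cur = cur.subset(sample_idx=np.flatnonzero(keep))

    maf = cur.maf()
    keep_markers(~np.isnan(maf) & (maf > 0), "monomorphic")
    keep_markers(cur.maf() >= maf_min, "maf")
    keep_markers(cur.marker_missing_rate() <= max_marker_missing,
                 "marker_missing")
    keep_samples(cur.sample_missing_rate() <= max_sample_missing,
                 "sample_missing")
    # the heterozygosity-excess cutoffs (mean + k SD) adapt to the retained
    # panel, so this block iterates to a fixed point: the cascade is then
    # idempotent — a second identical call removes nothing
    report.samples_removed["sample_het_excess"] = 0
    report.markers_removed["marker_het_excess"] = 0
    report.markers_removed["maf_recheck"] = 0
    for _ in range(100):
        removed = 0
        het_s = cur.sample_het_rate()
        keep = het_s <= het_s.mean() + het_sd_samples * het_s.std()
        removed += int((~keep).sum())
        keep_samples(keep, "sample_het_excess")
        het_m = cur.marker_het_rate()
        keep = het_m <= het_m.mean() + het_sd_markers * het_m.std()
        removed += int((~keep).sum())
        keep_markers(keep, "marker_het_excess")
        # sample removal can leave markers monomorphic or below the MAF bound
        maf = cur.maf()
        keep = ~np.isnan(maf) & (maf >= maf_min)
        removed += int((~keep).sum())
        keep_markers(keep, "maf_recheck")
        if removed == 0:
            break
    logger.info("filter: %d/%d markers, %d/%d samples retained",
                report.n_markers_out, report.n_markers_in,
                report.n_samples_out, report.n_samples_in)
    return cur, report


# ---------------------------------------------------------------------------
# imputation


def _mode_fill(doses: np.ndarray) -> np.ndarray:
    """Initialize missing calls with the per-marker modal class."""
    out = doses.copy()
    for j in range(doses.shape[1]):
        col = doses[:, j]
        obs = col != MISSING
        if not obs.any():
            raise ValueError(f"marker column {j} is entirely missing")
        counts = np.bincount(col[obs], minlength=3)
        out[~obs, j] = np.argmax(counts)
    return out


def impute_missing(gm: GenotypeMatrix, n_trees: int = 100, max_iter: int = 10,
                   k_neighbors: int = 30, seed: int = 0,
                   stall_tol: float = 0.0) -> GenotypeMatrix:
    """Iterative random-forest imputation with categorical genotype classes.

    Missing calls start at the per-marker mode; each iteration refits, for
    every marker with missing data, a random-forest classifier on that
    marker's ``k_neighbors`` most-correlated markers (exploiting local LD)
    and re-predicts the missing classes.  Iteration stops at ``max_iter`` or
    when the fraction of imputed calls that change falls to ``stall_tol``.
    Observed calls are never altered.
    """
    doses = gm.doses
    miss = doses == MISSING
    if not miss.any():
        return gm
    filled = _mode_fill(doses)
    targets = np.flatnonzero(miss.any(axis=0))
    n_missing = int(miss.sum())
    rng = np.random.default_rng(seed)
    for it in range(max_iter):
        X = filled.astype(float)
        Xc = X - X.mean(axis=0)
        sd = Xc.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = Xc / sd
        corr = (Xs.T @ Xs) / Xs.shape[0]
        np.fill_diagonal(corr, 0.0)
        new = filled.copy()
        for j in targets:
            k = min(k_neighbors, gm.n_markers - 1)
            feats = np.argpartition(-np.abs(corr[:, j]), k - 1)[:k]
            rows_obs = ~miss[:, j]
            y = filled[rows_obs, j]
            if np.unique(y).size < 2:
                new[miss[:, j], j] = y[0]
                continue
            clf = RandomForestClassifier(
                n_estimators=n_trees,
                random_state=int(rng.integers(2 ** 31 - 1)))
            clf.fit(X[rows_obs][:, feats], y)
            new[miss[:, j], j] = clf.predict(X[miss[:, j]][:, feats])
        changed = int((new[miss] != filled[miss]).sum())
        filled = new
        logger.info("imputation iteration %d: %d/%d imputed calls changed",
                    it + 1, changed, n_missing)
        if changed / n_missing <= stall_tol:
            break
    assert (filled[~miss] == doses[~miss]).all()
    return replace(gm, doses=filled)


def imputation_accuracy(imputed: GenotypeMatrix, truth: np.ndarray,
                        mask: np.ndarray) -> float:
    """Fraction of masked calls recovered exactly."""
    if not mask.any():
        raise ValueError("empty mask")
    return float((imputed.doses[mask] == truth[mask]).mean())


def genotype_matrix_from_population(pop) -> GenotypeMatrix:
    """Adapter from a simulated Population to the QC container."""
    return _from_population(pop)


def write_genotype_matrix(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.doses.astype(object), index=gm.samples,
                      columns=gm.marker_ids)
    df[gm.doses == MISSING] = "NA"
    df.to_csv(path, sep="\t", index_label="line")
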
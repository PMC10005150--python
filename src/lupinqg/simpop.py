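"""Synthetic multi-cross inbred-line populations and field trials.

Emulates the mating design and trait architecture of a typical white lupin
breeding population: two pools of elite founders (sweet-seed cultivars and
landraces) crossed in a factorial design, inbred lines derived by single-seed
descent, and replicated multi-environment trials laid out as randomized
complete blocks.  Everything is driven by an explicit RNG seed so that a full
downstream analysis (QC, variance components, structure, LD, GWAS, genomic
prediction) is testable without external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

#: default allocation of 140 lines over the 16 crosses of a 4 x 4 factorial
DEFAULT_LINES_PER_CROSS = (10, 10, 10, 10, 9, 9, 9, 9, 8, 8, 8, 8, 8, 8, 8, 8)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the mating design and the simulated genome.

    The defaults reproduce the reference design: a 4 x 4 factorial between
    four sweet-seed and four landrace founders, 140 F5-equivalent lines
    (4 selfing generations after the F1), and a 25-chromosome genome.
    """

    n_sweet_parents: int = 4
    n_landrace_parents: int = 4
    lines_per_cross: tuple[int, ...] = DEFAULT_LINES_PER_CROSS
    selfing_generations: int = 4
    n_chromosomes: int = 25
    chromosome_length_bp: int = 20_000_000
    n_markers: int = 5000
    target_maf_min: float = 0.05
    pool_differentiation: float = 0.2
    crossover_poisson_mean: float = 1.0
    n_environments: int = 2
    n_blocks: int = 3
    seed: int = 0

    @property
    def n_crosses(self) -> int:
        return self.n_sweet_parents * self.n_landrace_parents

    @property
    def n_lines(self) -> int:
        return int(sum(self.lines_per_cross))

    def validate(self) -> None:
        if self.n_markers <= 0:
            raise ConfigurationError("n_markers must be positive")
        for name in ("n_sweet_parents", "n_landrace_parents", "n_chromosomes",
                     "chromosome_length_bp", "n_environments", "n_blocks"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if len(self.lines_per_cross) != self.n_crosses:
            raise ConfigurationError(
                f"lines_per_cross has {len(self.lines_per_cross)} entries, "
                f"expected {self.n_crosses}")
        if self.n_lines <= 0:
            raise ConfigurationError("total number of lines must be positive")
        if self.selfing_generations < 0:
            raise ConfigurationError("selfing_generations must be >= 0")
        if not 0.0 <= self.pool_differentiation < 1.0:
            raise ConfigurationError("pool_differentiation must be in [0, 1)")


@dataclass(frozen=True)
class QTL:
    """A major locus: additive effect per allele dose, optionally
    environment-specific through the mask."""

    chromosome: int                     # 1-based
    position: int                       # bp, matched to nearest marker
    effect: float                       # trait units per allele dose
    env_mask: tuple[bool, ...] = (True, True)


@dataclass(frozen=True)
class TraitArchitecture:
    """Generative architecture of one trait in a two-environment trial.

    ``h2_true`` is broad-sense heritability on a line-mean basis with
    ``n_blocks`` replicates, so the residual plot variance is recovered as
    ``s2_e = n * s2_g * (1 - H2) / H2``.  ``genetic_sd`` is the standard
    deviation of line genetic values per environment (trait units);
    environment-specific genetic values are drawn with cross-environment
    correlation ``rg_true``.
    """

    name: str
    env_means: tuple[float, ...]
    genetic_sd: tuple[float, ...]
    h2_true: tuple[float, ...]
    rg_true: float = 0.5
    n_background_loci: int = 200
    major_qtl: tuple[QTL, ...] = ()
    block_effect_sd: float = 0.0
    ordinal: bool = False
    ordinal_levels: tuple[int, ...] = (1, 3, 5, 7, 9)
    # for ordinal scores: correlation of the latent liability with the
    # (standardized) plot values of this trait, per environment
    liability_corr_with: str | None = None
    liability_corr: tuple[float, ...] = (0.0, 0.0)
    liability_sd: float = 2.0

    def validate(self, config: SimConfig) -> None:
        if not all(0.0 <= h <= 1.0 for h in self.h2_true):
            raise ConfigurationError(f"{self.name}: H2 must lie in [0, 1]")
        if abs(self.rg_true) > 1.0:
            raise ConfigurationError(f"{self.name}: |rg_true| must be <= 1")
        for q in self.major_qtl:
            if not (1 <= q.chromosome <= config.n_chromosomes):
                raise ConfigurationError(
                    f"{self.name}: QTL chromosome {q.chromosome} outside genome")
            if not (1 <= q.position <= config.chromosome_length_bp):
                raise ConfigurationError(
                    f"{self.name}: QTL position {q.position} outside chromosome")


def default_architectures() -> dict[str, TraitArchitecture]:
    """Trait architectures matching the reference field study.

    Environment order is (high-stress Mediterranean site, mild Oceanic site).
    Genetic SDs derive from the reported genetic coefficients of variation
    (s_g = CVg/100 x mean); heritabilities and cross-environment genetic
    correlations are the reported per-trait values.  The lime-susceptibility
    (LS) score is an ordinal 1-9 liability trait negatively correlated with
    grain yield, much more strongly so in the high-stress site.
    """
    def sd(cv, m):
        return cv / 100.0 * m

    return {
        "grain_yield": TraitArchitecture(
            name="grain_yield", env_means=(0.481, 2.347),
            genetic_sd=(sd(28.1, 0.481), sd(15.2, 2.347)),
            h2_true=(0.48, 0.36), rg_true=0.32, block_effect_sd=0.05),
        "ls_score": TraitArchitecture(
            name="ls_score", env_means=(6.65, 2.53),
            genetic_sd=(sd(13.3, 6.65), sd(16.4, 2.53)),
            h2_true=(0.77, 0.39), rg_true=0.03, ordinal=True,
            liability_corr_with="grain_yield",
            liability_corr=(-0.66, -0.40), liability_sd=1.8),
        "plant_height": TraitArchitecture(
            name="plant_height", env_means=(36.2, 76.3),
            genetic_sd=(sd(13.7, 36.2), sd(7.2, 76.3)),
            h2_true=(0.68, 0.46), rg_true=0.73, block_effect_sd=1.0),
        "pods_per_plant": TraitArchitecture(
            name="pods_per_plant", env_means=(2.63, 9.23),
            genetic_sd=(sd(19.0, 2.63), sd(16.0, 9.23)),
            h2_true=(0.43, 0.48), rg_true=0.33, block_effect_sd=0.1),
        "seeds_per_pod": TraitArchitecture(
            name="seeds_per_pod", env_means=(2.56, 2.76),
            genetic_sd=(sd(20.8, 2.56), sd(13.7, 2.76)),
            h2_true=(0.57, 0.58), rg_true=-0.13, block_effect_sd=0.05),
        "seed_weight": TraitArchitecture(
            name="seed_weight", env_means=(0.253, 0.248),
            genetic_sd=(sd(18.7, 0.253), sd(11.9, 0.248)),
            h2_true=(0.72, 0.71), rg_true=0.68, block_effect_sd=0.005),
    }


@dataclass
class FounderSet:
    """Fully inbred founder genotypes: one haplotype per founder, doubled."""

    haplotypes: np.ndarray          # (n_founders, n_markers) in {0, 1}
    pool: np.ndarray                # "sweet" or "landrace" per founder
    chrom: np.ndarray               # 1-based chromosome index per marker
    pos: np.ndarray                 # 1-based bp position per marker
    marker_ids: np.ndarray

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class Population:
    """Inbred lines with cross-of-origin labels and (possibly masked)
    genotypes coded as allele dose 0/1/2, missing = -1."""

    line_ids: np.ndarray
    cross_ids: np.ndarray
    genotypes: np.ndarray            # (n_lines, n_markers) int8
    chrom: np.ndarray
    pos: np.ndarray
    marker_ids: np.ndarray
    pedigree: dict[str, tuple[str, str]] = field(default_factory=dict)
    haplotypes: np.ndarray | None = None      # (n_lines, 2, n_markers)
    true_genotypes: np.ndarray | None = None  # pre-masking copy

    def __post_init__(self):
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype doses must be in {0, 1, 2, missing}")

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def heterozygosity(self) -> np.ndarray:
        """Per-line fraction of heterozygous calls among observed calls."""
        obs = self.genotypes != MISSING
        het = self.genotypes == 1
        return het.sum(axis=1) / np.maximum(obs.sum(axis=1), 1)


@dataclass
class TrialData:
    """Plot-level records of a multi-environment RCBD trial."""

    records: pd.DataFrame            # line, env, block, trait, value
    genetic_values: dict[str, np.ndarray] = field(default_factory=dict)

    def to_table(self) -> pd.DataFrame:
        return self.records.copy()


# ---------------------------------------------------------------------------
# genome / founders


def _marker_map(config: SimConfig, rng: np.random.Generator):
    """Assign markers to chromosomes and draw sorted unique positions."""
    base = config.n_markers // config.n_chromosomes
    counts = np.full(config.n_chromosomes, base, dtype=int)
    counts[: config.n_markers - base * config.n_chromosomes] += 1
    chrom, pos = [], []
    for c, k in enumerate(counts, start=1):
        p = rng.choice(config.chromosome_length_bp, size=k, replace=False) + 1
        p.sort()
        chrom.append(np.full(k, c))
        pos.append(p)
    return np.concatenate(chrom), np.concatenate(pos).astype(np.int64)


def simulate_founders(config: SimConfig,
                      rng: np.random.Generator | None = None) -> FounderSet:
    """Draw the two founder pools over the simulated genome.

    Ancestral allele frequencies come from a Beta distribution truncated away
    from the extremes so that the descendant MAF spectrum has most of its mass
    above ``target_maf_min``; pool-specific frequencies are drawn from a
    Balding-Nichols Beta around the ancestral frequency with the configured
    differentiation parameter (0 = identical pools).  Founders are fully
    homozygous, as expected for elite inbred parent material.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom, pos = _marker_map(config, rng)
    m = config.n_markers

    lo = max(2 * config.target_maf_min, 0.05)
    p0 = rng.beta(0.9, 0.9, size=m)
    p0 = lo + p0 * (1.0 - 2 * lo)          # truncate to [lo, 1-lo]

    F = config.pool_differentiation
    if F > 0:
        a = p0 * (1 - F) / F
        b = (1 - p0) * (1 - F) / F
        p_sweet = rng.beta(a, b)
        p_land = rng.beta(a, b)
    else:
        p_sweet = p0
        p_land = p0.copy()

    n_s, n_l = config.n_sweet_parents, config.n_landrace_parents
    hap_s = (rng.random((n_s, m)) < p_sweet).astype(np.int8)
    hap_l = (rng.random((n_l, m)) < p_land).astype(np.int8)
    haplotypes = np.vstack([hap_s, hap_l])
    pool = np.array(["sweet"] * n_s + ["landrace"] * n_l)
    ids = np.array([f"M{c:02d}_{p}" for c, p in zip(chrom, pos)])
    return FounderSet(haplotypes=haplotypes, pool=pool, chrom=chrom,
                      pos=pos, marker_ids=ids)


def _gamete(h1: np.ndarray, h2: np.ndarray, chrom: np.ndarray,
            chrom_bounds: list[tuple[int, int]], pos: np.ndarray,
            length_bp: int, poisson_mean: float,
            rng: np.random.Generator) -> np.ndarray:
    """One meiotic product: per chromosome, one obligate crossover plus a
    Poisson number of extras at uniform bp positions."""
    out = np.empty_like(h1)
    for (lo, hi) in chrom_bounds:
        n_co = 1 + rng.poisson(poisson_mean)
        breaks = np.sort(rng.integers(1, length_bp + 1, size=n_co))
        seg = np.searchsorted(breaks, pos[lo:hi], side="left")
        start = rng.integers(2)
        pick = (seg + start) % 2
        block = np.where(pick == 0, h1[lo:hi], h2[lo:hi])
        out[lo:hi] = block
    return out


def _chromosome_bounds(chrom: np.ndarray) -> list[tuple[int, int]]:
    bounds = []
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        bounds.append((idx[0], idx[-1] + 1))
    return bounds


def derive_inbred_lines(founders: FounderSet, config: SimConfig,
                        rng: np.random.Generator | None = None) -> Population:
    """Produce F(1 + selfing_generations) lines by single-seed descent.

    Each of the ``n_sweet x n_landrace`` crosses yields its configured number
    of lines; each line descends from an independent F1 plant through
    ``selfing_generations`` rounds of selfing with recombination (expected
    residual heterozygosity (1/2)^g at loci heterozygous in the F1).
    """
    config.validate()
    if config.n_lines == 0:
        raise ConfigurationError("no lines requested")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    bounds = _chromosome_bounds(founders.chrom)
    n_s = config.n_sweet_parents
    line_ids, cross_ids, haps = [], [], []
    pedigree: dict[str, tuple[str, str]] = {}
    k = 0
    for i in range(n_s):
        for j in range(config.n_landrace_parents):
            cross = f"C{i * config.n_landrace_parents + j + 1:02d}"
            pedigree[cross] = (f"sweet{i + 1}", f"landrace{j + 1}")
            n_lines = config.lines_per_cross[k]
            k += 1
            h_a = founders.haplotypes[i]
            h_b = founders.haplotypes[n_s + j]
            for ln in range(n_lines):
                h1, h2 = h_a.copy(), h_b.copy()          # the F1
                for _ in range(config.selfing_generations):
                    g1 = _gamete(h1, h2, founders.chrom, bounds, founders.pos,
                                 config.chromosome_length_bp,
                                 config.crossover_poisson_mean, rng)
                    g2 = _gamete(h1, h2, founders.chrom, bounds, founders.pos,
                                 config.chromosome_length_bp,
                                 config.crossover_poisson_mean, rng)
                    h1, h2 = g1, g2
                line_ids.append(f"{cross}_L{ln + 1:02d}")
                cross_ids.append(cross)
                haps.append(np.stack([h1, h2]))
    hap_arr = np.stack(haps)                              # (n, 2, m)
    genotypes = hap_arr.sum(axis=1).astype(np.int8)
    return Population(line_ids=np.array(line_ids),
                      cross_ids=np.array(cross_ids),
                      genotypes=genotypes,
                      chrom=founders.chrom, pos=founders.pos,
                      marker_ids=founders.marker_ids,
                      pedigree=pedigree, haplotypes=hap_arr)


def simulate_population(config: SimConfig) -> Population:
    """Founders plus single-seed descent in one deterministic call."""
    rng = np.random.default_rng(config.seed)
    founders = simulate_founders(config, rng)
    return derive_inbred_lines(founders, config, rng)


# ---------------------------------------------------------------------------
# trials


def _nearest_marker(pop: Population, chromosome: int, position: int) -> int:
    on_c = np.flatnonzero(pop.chrom == chromosome)
    if on_c.size == 0:
        raise ConfigurationError(f"no markers on chromosome {chromosome}")
    return int(on_c[np.argmin(np.abs(pop.pos[on_c] - position))])


def _dose_matrix(pop: Population) -> np.ndarray:
    g = pop.true_genotypes if pop.true_genotypes is not None else pop.genotypes
    return g.astype(float)


def residual_sd_from_h2(s2_g: float, h2: float, n_blocks: int) -> float:
    """Invert line-mean heritability H2 = s2g / (s2g + s2e/n) for s2_e."""
    if h2 >= 1.0:
        return 0.0
    if h2 <= 0.0:
        return np.inf
    return float(np.sqrt(n_blocks * s2_g * (1.0 - h2) / h2))


def _genetic_values(pop: Population, arch: TraitArchitecture,
                    config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Environment-specific line genetic values: polygenic background with
    cross-environment effect correlation rg_true, plus major QTL, scaled to
    the target per-environment genetic SD."""
    W = _dose_matrix(pop)
    n, m = W.shape
    n_env = config.n_environments
    n_bg = min(arch.n_background_loci, m)
    loci = rng.choice(m, size=n_bg, replace=False)
    rho = np.full((n_env, n_env), arch.rg_true)
    np.fill_diagonal(rho, 1.0)
    # nearest-PSD guard for extreme rg choices with >2 environments
    beta = rng.multivariate_normal(np.zeros(n_env), rho, size=n_bg,
                                   method="eigh" if n_env > 2 else "svd")
    Wb = W[:, loci] - W[:, loci].mean(axis=0)
    g = Wb @ beta                                     # (n, n_env)
    g -= g.mean(axis=0)
    sd = g.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    g = g / sd * np.asarray(arch.genetic_sd)[:n_env]
    for q in arch.major_qtl:
        idx = _nearest_marker(pop, q.chromosome, q.position)
        dose = W[:, idx] - W[:, idx].mean()
        for e in range(n_env):
            if q.env_mask[e]:
                g[:, e] += q.effect * dose
    return g


def _ordinal_from_latent(latent: np.ndarray, env_mean: float, sd: float,
                         levels: tuple[int, ...]) -> np.ndarray:
    """Map a standardized latent liability onto the ordinal scale by shifting
    to the target environment mean and snapping to the nearest level."""
    lv = np.asarray(levels, dtype=float)
    raw = env_mean + sd * latent
    idx = np.argmin(np.abs(raw[:, None] - lv[None, :]), axis=1)
    return lv[idx]


def simulate_trial(pop: Population, architectures: dict[str, TraitArchitecture],
                   config: SimConfig,
                   rng: np.random.Generator | None = None) -> TrialData:
    """Simulate a replicated RCBD trial in each environment.

    Continuous traits: plot value = env mean + line genetic value + block
    effect + N(0, s_e) with s_e set from the target line-mean heritability.
    Ordinal traits (the LS score) are produced by thresholding a latent
    liability — a mixture of the standardized plot values of the anchor trait
    (typically grain yield, with negative weight) and independent noise —
    onto the odd 1-9 levels.
    """
    config.validate()
    for arch in architectures.values():
        arch.validate(config)
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n, n_env, n_blk = pop.n_lines, config.n_environments, config.n_blocks
    env_names = [f"env{e + 1}" for e in range(n_env)]
    rows = []
    genetic_values: dict[str, np.ndarray] = {}
    # standardized plot deviations per anchor trait for ordinal liabilities
    plot_z: dict[str, np.ndarray] = {}

    ordered = sorted(architectures.values(), key=lambda a: a.ordinal)
    for arch in ordered:
        if not arch.ordinal:
            g = _genetic_values(pop, arch, config, rng)
            genetic_values[arch.name] = g
            values = np.empty((n, n_env, n_blk))
            z = np.empty((n, n_env, n_blk))
            for e in range(n_env):
                s2_g = float(np.var(g[:, e], ddof=1))
                s_e = residual_sd_from_h2(s2_g, arch.h2_true[e], n_blk)
                if not np.isfinite(s_e):
                    warnings.warn(
                        f"{arch.name}: H2_true = 0 makes the residual variance "
                        "unbounded; using 10x genetic SD instead")
                    s_e = 10.0 * max(np.sqrt(s2_g), 1.0)
                blocks = rng.normal(0.0, arch.block_effect_sd, size=n_blk) \
                    if arch.block_effect_sd > 0 else np.zeros(n_blk)
                eps = rng.normal(0.0, 1.0, size=(n, n_blk)) * s_e
                dev = g[:, e][:, None] + eps
                values[:, e, :] = arch.env_means[e] + blocks[None, :] + dev
                sd_dev = dev.std(ddof=1) or 1.0
                z[:, e, :] = dev / sd_dev
            plot_z[arch.name] = z
        else:
            anchor = arch.liability_corr_with
            values = np.empty((n, n_env, n_blk))
            for e in range(n_env):
                rho = arch.liability_corr[e]
                noise = rng.normal(0.0, 1.0, size=(n, n_blk))
                if anchor is not None and anchor in plot_z:
                    base = plot_z[anchor][:, e, :]
                    latent = rho * base + np.sqrt(max(1 - rho ** 2, 0)) * noise
                else:
                    latent = noise
                values[:, e, :] = _ordinal_from_latent(
                    latent.ravel(), arch.env_means[e], arch.liability_sd,
                    arch.ordinal_levels).reshape(n, n_blk)
            genetic_values[arch.name] = values.mean(axis=2)
        for e in range(n_env):
            for b in range(n_blk):
                rows.append(pd.DataFrame({
                    "line": pop.line_ids, "env": env_names[e],
                    "block": f"block{b + 1}", "trait": arch.name,
                    "value": values[:, e, b]}))
    records = pd.concat(rows, ignore_index=True)
    return TrialData(records=records, genetic_values=genetic_values)


def add_missing_genotypes(pop: Population, marker_missing_rate: float = 0.0,
                          sample_missing_rate: float = 0.0,
                          seed: int = 0,
                          marker_rate_concentration: float | None = None
                          ) -> Population:
    """Mask genotype calls missing-completely-at-random.

    A call is masked if it is hit by the per-marker Bernoulli mask or by the
    per-sample one.  With ``marker_rate_concentration`` set, per-marker rates
    are drawn from a Beta distribution with the given mean and concentration
    (emulating the heterogeneous coverage of GBS markers, where some markers
    far exceed the average missing rate); otherwise every marker shares the
    fixed rate.  The unmasked matrix is retained in ``true_genotypes`` so
    imputation accuracy can be scored later.
    """
    for r in (marker_missing_rate, sample_missing_rate):
        if not 0.0 <= r <= 1.0:
            raise ConfigurationError("missing rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    g = pop.genotypes.copy()
    if marker_rate_concentration is not None and marker_missing_rate > 0:
        c = marker_rate_concentration
        rates = rng.beta(marker_missing_rate * c,
                         (1.0 - marker_missing_rate) * c, size=g.shape[1])
    else:
        rates = np.full(g.shape[1], marker_missing_rate)
    mask = rng.random(g.shape) < rates[None, :]
    mask |= rng.random((g.shape[0], 1)) < sample_missing_rate
    g[mask] = MISSING
    return replace(pop, genotypes=g, true_genotypes=pop.genotypes.copy())


# ---------------------------------------------------------------------------
# writers


def write_genotypes_tsv(pop: Population, path) -> None:
    """Samples x markers dose table; missing written as NA."""
    df = pd.DataFrame(pop.genotypes.astype(object), index=pop.line_ids,
                      columns=pop.marker_ids)
    df[pop.genotypes == MISSING] = "NA"
    df.to_csv(path, sep="\t", index_label="line")


def write_vcf(pop: Population, path) -> None:
    """Minimal VCF 4.2 with one pseudo-contig per chromosome, GT-only."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in np.unique(pop.chrom):
            fh.write(f"##contig=<ID=chr{int(c):02d}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(pop.line_ids) + "\n")
        for j in range(pop.n_markers):
            calls = "\t".join(gt_map[int(v)] for v in pop.genotypes[:, j])
            fh.write(f"chr{int(pop.chrom[j]):02d}\t{int(pop.pos[j])}\t"
                     f"{pop.marker_ids[j]}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def write_phenotypes_tsv(trial: TrialData, path) -> None:
    trial.records.to_csv(path, sep="\t", index=False)


def write_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        for k, v in vars(config).items():
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            fh.write(f"{k}\t{v}\n")
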
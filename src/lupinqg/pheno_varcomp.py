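"""Variance components, heritability, BLUPs, and G-by-E statistics for
replicated line trials.

The workhorse is :class:`RCBDModel`, a one-environment randomized-complete-
block model ``y_ij = mu + g_i + b_j + e_ij`` with random line effects.  For
balanced data its REML solution coincides with the classical method-of-
moments ANOVA estimates ``s2_g = (MS_genotype - MS_error) / n_blocks``
(truncated at zero); unbalanced data fall back to an iterative REML fit of
the same model.  On top of that sit the derived genetic statistics: the
genetic coefficient of variation CVg = 100 * s_g / m, line-mean broad-sense
heritability H2 = s2_g / (s2_g + s2_e / n), heritability-shrunken line BLUPs,
the cross-environment genetic correlation, the genotype x environment ANOVA
with its cross / line-within-cross partition, and phenotypic correlations of
line means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def _pivot(table: pd.DataFrame, trait: str, environment: str) -> pd.DataFrame:
    sub = table[(table["trait"] == trait) & (table["env"] == environment)]
    if sub.empty:
        raise ValueError(f"no records for trait={trait!r} env={environment!r}")
    return sub.pivot_table(index="line", columns="block", values="value",
                           aggfunc="mean")


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "†"
    return "NS"


@dataclass
class VarianceComponents:
    """REML (or balanced-ANOVA) estimates for one trait x environment."""

    trait: str
    environment: str
    s2_g: float
    s2_e: float
    n_reps: int
    mean: float
    f_genotype: float
    p_genotype: float
    balanced: bool = True
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return _stars(self.p_genotype)


class RCBDModel:
    """Randomized-complete-block model for one trait in one environment.

    Parameters
    ----------
    table : long-format phenotype records with columns
        ``line, env, block, trait, value``
    trait, environment : which records to model
    """

    def __init__(self, table: pd.DataFrame, trait: str, environment: str):
        self.trait = trait
        self.environment = environment
        self.wide = _pivot(table, trait, environment)
        if self.wide.shape[0] < 2:
            raise ValueError("need >= 2 lines")
        if self.wide.shape[1] < 2:
            raise ValueError("need >= 2 blocks: s2_e is inestimable "
                             "with a single replicate")
        self.balanced = not self.wide.isna().any().any()
        if not self.balanced:
            warnings.warn(f"{trait}/{environment}: unbalanced RCBD, "
                          "falling back to iterative REML")
            self._long = table[(table["trait"] == trait)
                               & (table["env"] == environment)].dropna(
                                   subset=["value"])

    def fit(self) -> "RCBDResults":
        if self.balanced:
            vc = self._fit_balanced()
        else:
            vc = self._fit_reml()
        return RCBDResults(self, vc)

    # -- balanced: two-way ANOVA mean squares ------------------------------
    def _fit_balanced(self) -> VarianceComponents:
        y = self.wide.to_numpy(float)
        n_g, n_b = y.shape
        grand = y.mean()
        ss_g = n_b * ((y.mean(axis=1) - grand) ** 2).sum()
        ss_b = n_g * ((y.mean(axis=0) - grand) ** 2).sum()
        ss_tot = ((y - grand) ** 2).sum()
        ss_e = ss_tot - ss_g - ss_b
        df_g, df_b = n_g - 1, n_b - 1
        df_e = df_g * df_b
        ms_g = ss_g / df_g
        ms_e = max(ss_e, 0.0) / df_e
        s2_g = max((ms_g - ms_e) / n_b, 0.0)
        degenerate = ms_e <= 0 and ms_g <= 0
        if ms_e > 0:
            f = ms_g / ms_e
            p = float(stats.f.sf(f, df_g, df_e))
        else:
            f = np.inf if ms_g > 0 else np.nan
            p = 0.0 if ms_g > 0 else np.nan
            if degenerate:
                warnings.warn(f"{self.trait}/{self.environment}: all plot "
                              "values equal; variance components degenerate")
        return VarianceComponents(trait=self.trait,
                                  environment=self.environment,
                                  s2_g=float(s2_g), s2_e=float(ms_e),
                                  n_reps=n_b, mean=float(grand),
                                  f_genotype=float(f), p_genotype=p,
                                  balanced=True, degenerate=degenerate)

    # -- unbalanced: REML via MixedLM --------------------------------------
    def _fit_reml(self) -> VarianceComponents:
        import statsmodels.formula.api as smf

        df = self._long.rename(columns={"value": "y"})
        md = smf.mixedlm("y ~ C(block)", df, groups=df["line"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = md.fit(reml=True)
        s2_g = float(res.cov_re.iloc[0, 0])
        s2_e = float(res.scale)
        n_b = df.groupby("line")["y"].count().mode().iloc[0]
        # genotype F-test from the fixed-model ANOVA as a descriptive check
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = anova_lm(ols("y ~ C(line) + C(block)", df).fit())
        f = float(aov.loc["C(line)", "F"])
        p = float(aov.loc["C(line)", "PR(>F)"])
        return VarianceComponents(trait=self.trait,
                                  environment=self.environment,
                                  s2_g=s2_g, s2_e=s2_e, n_reps=int(n_b),
                                  mean=float(df["y"].mean()),
                                  f_genotype=f, p_genotype=p, balanced=False)


class RCBDResults:
    """Fit results: variance components plus the derived genetic statistics."""

    def __init__(self, model: RCBDModel, vc: VarianceComponents):
        self.model = model
        self.vc = vc

    @property
    def s2_g(self) -> float:
        return self.vc.s2_g

    @property
    def s2_e(self) -> float:
        return self.vc.s2_e

    def genetic_cv(self) -> float:
        return genetic_cv(self.vc)

    def heritability(self) -> float:
        return heritability(self.vc)

    def blups(self) -> "BlupSet":
        return compute_blups_from_means(self.model.wide.mean(axis=1), self.vc)

    def summary(self) -> pd.DataFrame:
        h2 = self.heritability()
        return pd.DataFrame({
            "trait": [self.vc.trait], "env": [self.vc.environment],
            "mean": [self.vc.mean], "s2_g": [self.vc.s2_g],
            "s2_e": [self.vc.s2_e], "CVg": [self.genetic_cv()],
            "H2": [h2], "F_genotype": [self.vc.f_genotype],
            "p_genotype": [self.vc.p_genotype], "sig": [self.vc.stars]})


def fit_rcbd(table: pd.DataFrame, trait: str,
             environment: str) -> VarianceComponents:
    """Convenience wrapper: fit the RCBD and return the variance components."""
    return RCBDModel(table, trait, environment).fit().vc


def genetic_cv(vc: VarianceComponents) -> float:
    """Genetic coefficient of variation CVg = 100 * sqrt(s2_g) / m (percent)."""
    if vc.mean == 0:
        raise ValueError("CVg undefined: trait mean is zero")
    return float(100.0 * np.sqrt(max(vc.s2_g, 0.0)) / vc.mean)


def heritability(vc: VarianceComponents) -> float:
    """Line-mean broad-sense heritability H2 = s2_g / (s2_g + s2_e / n)."""
    denom = vc.s2_g + vc.s2_e / vc.n_reps
    if denom == 0:
        warnings.warn(f"{vc.trait}/{vc.environment}: H2 undefined "
                      "(both variance components zero)")
        return np.nan
    return float(vc.s2_g / denom)


@dataclass
class BlupSet:
    """Heritability-shrunken line values for one trait x environment."""

    trait: str
    environment: str
    values: pd.Series            # indexed by line
    h2: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"line": self.values.index,
                             "trait": self.trait, "env": self.environment,
                             "blup": self.values.to_numpy()})


def compute_blups_from_means(line_means: pd.Series,
                             vc: VarianceComponents) -> BlupSet:
    h2 = heritability(vc)
    dropped = line_means.isna()
    if dropped.any():
        warnings.warn(f"{vc.trait}/{vc.environment}: dropping "
                      f"{int(dropped.sum())} lines with no observations")
        line_means = line_means[~dropped]
    m = vc.mean
    blups = m + h2 * (line_means - m)
    return BlupSet(trait=vc.trait, environment=vc.environment,
                   values=blups, h2=h2)


def compute_blups(table: pd.DataFrame, trait: str, environment: str,
                  vc: VarianceComponents | None = None) -> BlupSet:
    """Line BLUPs as grand-mean shrinkage of line means by H2:
    BLUP_i = m + H2 * (ybar_i - m)."""
    if vc is None:
        vc = fit_rcbd(table, trait, environment)
    means = _pivot(table, trait, environment).mean(axis=1)
    return compute_blups_from_means(means, vc)


# ---------------------------------------------------------------------------
# cross-environment analyses


@dataclass
class CrossEnvAnova:
    """Combined-environment ANOVA and its cross-partition."""

    trait: str
    anova: pd.DataFrame              # genotype / env / block(env) / GEI
    partition: pd.DataFrame          # cross / line(cross) and interactions
    f_gei: float
    p_gei: float


def cross_env_anova(table: pd.DataFrame, trait: str,
                    cross_of: dict[str, str] | None = None) -> CrossEnvAnova:
    """Two-environment ANOVA with genotype, environment, block-within-
    environment and GEI, plus a second partition replacing genotype by
    cross + line-within-cross (requires ``cross_of`` line -> cross labels;
    by default the cross is parsed from line ids of the form CROSS_Lxx).
    """
    sub = table[table["trait"] == trait].dropna(subset=["value"]).copy()
    envs = sub["env"].unique()
    if len(envs) < 2:
        raise ValueError(f"trait {trait!r} observed in a single environment")
    if cross_of is None:
        cross_of = {ln: str(ln).split("_")[0] for ln in sub["line"].unique()}
    sub["cross"] = sub["line"].map(cross_of)

    y = sub["value"].to_numpy(float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    def ss_of(groups) -> float:
        agg = sub.groupby(groups, observed=True)["value"].agg(["mean", "size"])
        return float((agg["size"] * (agg["mean"] - grand) ** 2).sum())

    ss_env = ss_of("env")
    ss_geno = ss_of("line")
    ss_cross = ss_of("cross")
    ss_block_env = ss_of(["env", "block"]) - ss_env
    ss_gei = ss_of(["line", "env"]) - ss_geno - ss_env
    ss_cxe = ss_of(["cross", "env"]) - ss_cross - ss_env
    ss_line_in = ss_geno - ss_cross
    ss_lxe = ss_gei - ss_cxe
    ss_resid = max(ss_total - ss_env - ss_block_env - ss_geno - ss_gei, 0.0)

    n_env = len(envs)
    n_line = sub["line"].nunique()
    n_cross = sub["cross"].nunique()
    n_block = sub.groupby("env")["block"].nunique().max()
    df = {"environment": n_env - 1, "genotype": n_line - 1,
          "block(environment)": n_env * (n_block - 1),
          "GEI": (n_line - 1) * (n_env - 1),
          "cross": n_cross - 1, "line(cross)": n_line - n_cross,
          "cross x environment": (n_cross - 1) * (n_env - 1),
          "line(cross) x environment": (n_line - n_cross) * (n_env - 1)}
    df_resid = len(sub) - 1 - df["environment"] - df["genotype"] \
        - df["block(environment)"] - df["GEI"]
    df_resid = max(df_resid, 1)
    ms_resid = ss_resid / df_resid

    def table_rows(terms_ss: dict) -> pd.DataFrame:
        rows = []
        for term, ss in terms_ss.items():
            d = df[term] if term in df else df_resid
            ms = ss / max(d, 1)
            if term != "residual" and ms_resid > 0:
                f = ms / ms_resid
                p = float(stats.f.sf(f, d, df_resid))
            else:
                f, p = np.nan, np.nan
            rows.append((term, d, ss, ms, f, p))
        return pd.DataFrame(rows, columns=["term", "df", "sum_sq", "mean_sq",
                                           "F", "PR(>F)"]).set_index("term")

    aov = table_rows({"genotype": ss_geno, "environment": ss_env,
                      "block(environment)": ss_block_env, "GEI": ss_gei,
                      "residual": ss_resid})
    part = table_rows({"cross": ss_cross, "line(cross)": ss_line_in,
                       "environment": ss_env,
                       "block(environment)": ss_block_env,
                       "cross x environment": ss_cxe,
                       "line(cross) x environment": ss_lxe,
                       "residual": ss_resid})
    f_gei = float(aov.loc["GEI", "F"])
    p_gei = float(aov.loc["GEI", "PR(>F)"])
    return CrossEnvAnova(trait=trait, anova=aov, partition=part,
                         f_gei=f_gei, p_gei=p_gei)


def genetic_correlation(table: pd.DataFrame, trait: str, env1: str, env2: str,
                        vc1: VarianceComponents | None = None,
                        vc2: VarianceComponents | None = None) -> float:
    """Cross-environment genetic correlation of line responses.

    rg = cov(ybar_env1, ybar_env2) / (s_g,env1 * s_g,env2), clamped to
    [-1, 1].  The covariance of line means across environments estimates the
    genetic covariance because plot errors are independent between sites.
    Returns NaN (flagged) when s2_g is zero in either environment,
    mirroring inestimable table entries.
    """
    if vc1 is None:
        vc1 = fit_rcbd(table, trait, env1)
    if vc2 is None:
        vc2 = fit_rcbd(table, trait, env2)
    if vc1.s2_g <= 0 or vc2.s2_g <= 0:
        warnings.warn(f"{trait}: rg undefined (zero genetic variance)")
        return np.nan
    m1 = _pivot(table, trait, env1).mean(axis=1)
    m2 = _pivot(table, trait, env2).mean(axis=1)
    common = m1.index.intersection(m2.index)
    cov = float(np.cov(m1[common], m2[common], ddof=1)[0, 1])
    rg = cov / np.sqrt(vc1.s2_g * vc2.s2_g)
    return float(np.clip(rg, -1.0, 1.0))


def phenotypic_correlations(table: pd.DataFrame, traits: list[str],
                            environment: str) -> pd.DataFrame:
    """Pearson correlations of line means between traits within one
    environment, with t-distribution p-values; zero-variance traits give
    NaN entries."""
    means = {}
    for t in traits:
        means[t] = _pivot(table, t, environment).mean(axis=1)
    df = pd.DataFrame(means).dropna()
    if df.shape[0] < 3:
        raise ValueError("need >= 3 lines with all traits observed")
    n = df.shape[0]
    corr = df.corr()
    rows = []
    for a in traits:
        for b in traits:
            r = corr.loc[a, b]
            if np.isnan(r):
                warnings.warn(f"correlation {a}~{b} undefined "
                              "(zero-variance trait)")
                rows.append((a, b, np.nan, np.nan, "NA"))
                continue
            if a == b:
                rows.append((a, b, 1.0, 0.0, "**"))
                continue
            rr = np.clip(r, -0.9999999, 0.9999999)
            tstat = rr * np.sqrt((n - 2) / (1 - rr ** 2))
            p = float(2 * stats.t.sf(abs(tstat), n - 2))
            rows.append((a, b, float(r), p, _stars(p)))
    return pd.DataFrame(rows, columns=["trait1", "trait2", "r", "p", "sig"])


def varcomp_table(table: pd.DataFrame, traits: list[str],
                  environments: list[str]) -> pd.DataFrame:
    """Per trait x environment summary (mean, CVg, H2, significance)."""
    rows = []
    for t in traits:
        for e in environments:
            rows.append(RCBDModel(table, t, e).fit().summary())
    return pd.concat(rows, ignore_index=True)
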
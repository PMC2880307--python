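"""Variance components and quantitative-genetic statistics for a line x sex panel.

The core model is the balanced mixed ANOVA ``Y = mu + L + S + L*S + E`` with
Line random, Sex fixed, and replicate vials supplying the within-cell error.
On a balanced design the variance components have closed-form
method-of-moments solutions from the expected mean squares:

    sigma2_E  = MS_E
    sigma2_LS = (MS_LS - MS_E) / n_reps
    sigma2_L  = (MS_L - MS_LS) / (2 * n_reps)

negative estimates are truncated at zero (flagged). F tests follow the
mixed-model convention: Line and Sex are tested over the interaction mean
square, the interaction over the error mean square.

Derived statistics: broad-sense heritability
``H2 = (sigma2_L + sigma2_LS) / (sigma2_L + sigma2_LS + sigma2_E)``;
cross-sex genetic correlation ``r_MF = cov_fm / (sigma_f * sigma_m)`` with
the covariance of line means between sexes over per-sex among-line variance
components; between-trait genetic correlation ``r_GT = cov_12 / (sigma_1 *
sigma_2)``; coefficients of genetic and environmental variation
``CV = 100 * sigma / mu``. Standard errors and p-values for both correlations
use the Pearson line-mean convention ``SE = sqrt((1 - r^2) / (n - 2))`` with a
t test on n - 2 degrees of freedom.

Unbalanced tables are rejected rather than silently handled; REML would be
the appropriate extension for unbalanced designs and is deliberately out of
scope here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "UnbalancedDesignError",
    "VarianceDecomposition",
    "HeritabilityEstimate",
    "CrossSexCorrelation",
    "TraitCorrelation",
    "CVEstimates",
    "AncovaResult",
    "fit_line_sex_anova",
    "broad_sense_heritability",
    "cross_sex_correlation",
    "trait_correlation",
    "coefficients_of_variation",
    "sequential_bonferroni",
    "mutant_ancova",
]


class UnbalancedDesignError(ValueError):
    """Raised when the line x sex x vial table is not fully balanced.

    Method-of-moments estimation from expected mean squares requires equal
    cell counts; for unbalanced data use REML (e.g. a dedicated mixed-model
    package) instead.
    """


@dataclass(frozen=True)
class VarianceDecomposition:
    """Mean squares, variance components and F tests for ``Y = mu + L + S + L*S + E``."""

    trait: str
    n_lines: int
    n_reps: int
    ms_line: float
    ms_sex: float
    ms_line_sex: float
    ms_error: float
    df_line: int
    df_sex: int
    df_line_sex: int
    df_error: int
    sigma2_line: float
    sigma2_line_sex: float
    sigma2_error: float
    truncated_line: bool
    truncated_line_sex: bool
    f_line: float
    f_sex: float
    f_line_sex: float
    p_line: float
    p_sex: float
    p_line_sex: float
    grand_mean: float
    degenerate: bool = False

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_line + self.sigma2_line_sex + self.sigma2_error


@dataclass(frozen=True)
class HeritabilityEstimate:
    h2: float
    degenerate: bool = False


@dataclass(frozen=True)
class CrossSexCorrelation:
    r_mf: float
    cov_fm: float
    sigma_f: float
    sigma_m: float
    se: float
    p: float
    n_lines: int
    clamped: bool = False


@dataclass(frozen=True)
class TraitCorrelation:
    r_gt: float
    cov_12: float
    sigma_1: float
    sigma_2: float
    se: float
    p: float
    n_lines: int
    scope: str = "pooled"
    clamped: bool = False


@dataclass(frozen=True)
class CVEstimates:
    cv_g: float
    cv_e: float
    mean: float
    sigma_g: float
    sigma_e: float


@dataclass(frozen=True)
class AncovaResult:
    p_genotype: float
    f_genotype: float
    lsmeans: dict[str, float]
    scope: str
    n_obs: int


def _check_balanced(pheno: pd.DataFrame, trait: str) -> tuple[list, list, int]:
    """Validate the balanced two-way layout; return (lines, sexes, n_reps)."""
    for col in ("line", "sex", trait):
        if col not in pheno.columns:
            raise KeyError(f"phenotype table missing column {col!r}")
    if not np.isfinite(pheno[trait].to_numpy(dtype=float)).all():
        raise ValueError(f"non-finite values in trait {trait!r}")
    counts = pheno.groupby(["line", "sex"], observed=True)[trait].size()
    lines = sorted(pheno["line"].unique())
    sexes = sorted(pheno["sex"].unique())
    if len(sexes) != 2:
        raise UnbalancedDesignError(f"expected exactly 2 sexes, found {sexes}")
    if len(counts) != len(lines) * 2 or counts.nunique() != 1:
        raise UnbalancedDesignError(
            "unequal cell counts in the line x sex layout; method-of-moments "
            "estimation requires a balanced design (REML is the unbalanced alternative)"
        )
    return lines, sexes, int(counts.iloc[0])


def fit_line_sex_anova(pheno: pd.DataFrame, trait: str) -> VarianceDecomposition:
    """Two-way mixed ANOVA of a balanced line x sex design with replicate vials.

    Sums of squares are computed directly from cell, line, sex and grand means
    (exact on a balanced layout); variance components by method of moments
    with truncation at zero.
    """
    lines, sexes, n_reps = _check_balanced(pheno, trait)
    if n_reps < 2:
        raise UnbalancedDesignError("need >= 2 replicate vials per cell to estimate error")
    nl = len(lines)

    line_codes = pd.Categorical(pheno["line"], categories=lines).codes
    sex_codes = pd.Categorical(pheno["sex"], categories=sexes).codes
    order = np.lexsort((np.arange(len(pheno)), sex_codes, line_codes))
    arr = pheno[trait].to_numpy(dtype=float)[order].reshape(nl, 2, n_reps)
    grand = arr.mean()
    cell_means = arr.mean(axis=2)
    line_means = cell_means.mean(axis=1)
    sex_means = cell_means.mean(axis=0)

    ss_line = 2 * n_reps * float(((line_means - grand) ** 2).sum())
    ss_sex = nl * n_reps * float(((sex_means - grand) ** 2).sum())
    ss_inter = n_reps * float(
        ((cell_means - line_means[:, None] - sex_means[None, :] + grand) ** 2).sum()
    )
    ss_err = float(((arr - cell_means[:, :, None]) ** 2).sum())

    df_l, df_s, df_ls, df_e = nl - 1, 1, nl - 1, nl * 2 * (n_reps - 1)
    ms_l, ms_s, ms_ls, ms_e = ss_line / df_l, ss_sex / df_s, ss_inter / df_ls, ss_err / df_e

    degenerate = (ss_line + ss_sex + ss_inter + ss_err) == 0.0
    s2_e = ms_e
    raw_ls = (ms_ls - ms_e) / n_reps
    raw_l = (ms_l - ms_ls) / (2 * n_reps)
    s2_ls, trunc_ls = (raw_ls, False) if raw_ls >= 0 else (0.0, True)
    s2_l, trunc_l = (raw_l, False) if raw_l >= 0 else (0.0, True)

    if degenerate:
        f_l = f_s = f_ls = p_l = p_s = p_ls = float("nan")
    else:
        f_l = ms_l / ms_ls if ms_ls > 0 else float("inf")
        f_s = ms_s / ms_ls if ms_ls > 0 else float("inf")
        f_ls = ms_ls / ms_e if ms_e > 0 else float("inf")
        p_l = float(stats.f.sf(f_l, df_l, df_ls)) if math.isfinite(f_l) else 0.0
        p_s = float(stats.f.sf(f_s, df_s, df_ls)) if math.isfinite(f_s) else 0.0
        p_ls = float(stats.f.sf(f_ls, df_ls, df_e)) if math.isfinite(f_ls) else 0.0

    return VarianceDecomposition(
        trait=trait,
        n_lines=nl,
        n_reps=n_reps,
        ms_line=ms_l,
        ms_sex=ms_s,
        ms_line_sex=ms_ls,
        ms_error=ms_e,
        df_line=df_l,
        df_sex=df_s,
        df_line_sex=df_ls,
        df_error=df_e,
        sigma2_line=s2_l,
        sigma2_line_sex=s2_ls,
        sigma2_error=s2_e,
        truncated_line=trunc_l,
        truncated_line_sex=trunc_ls,
        f_line=f_l,
        f_sex=f_s,
        f_line_sex=f_ls,
        p_line=p_l,
        p_sex=p_s,
        p_line_sex=p_ls,
        grand_mean=float(grand),
        degenerate=degenerate,
    )


def broad_sense_heritability(vd: VarianceDecomposition) -> HeritabilityEstimate:
    """H2 = (sigma2_L + sigma2_LS) / (sigma2_L + sigma2_LS + sigma2_E); 0/0 -> 0 flagged."""
    num = vd.sigma2_line + vd.sigma2_line_sex
    tot = num + vd.sigma2_error
    if tot == 0.0:
        return HeritabilityEstimate(h2=0.0, degenerate=True)
    return HeritabilityEstimate(h2=num / tot)


def _one_way_line_component(values: pd.DataFrame, trait: str) -> float:
    """Among-line variance component from a balanced one-way ANOVA, truncated at 0."""
    counts = values.groupby("line", observed=True)[trait].size()
    if counts.nunique() != 1:
        raise UnbalancedDesignError("unequal replicate counts across lines")
    n_rep = int(counts.iloc[0])
    nl = len(counts)
    means = values.groupby("line", observed=True)[trait].mean()
    grand = values[trait].mean()
    ms_line = n_rep * float(((means - grand) ** 2).sum()) / (nl - 1)
    if n_rep > 1:
        ms_err = float(
            ((values[trait] - values["line"].map(means)) ** 2).sum()
        ) / (nl * (n_rep - 1))
    else:
        ms_err = 0.0
    return max(0.0, (ms_line - ms_err) / n_rep)


def _pearson_se_p(r: float, n: int) -> tuple[float, float]:
    r_c = min(1.0, max(-1.0, r))
    se = math.sqrt((1.0 - r_c**2) / (n - 2))
    if abs(r_c) == 1.0:
        return se, 0.0
    t = r_c * math.sqrt((n - 2) / (1.0 - r_c**2))
    return se, float(2.0 * stats.t.sf(abs(t), n - 2))


def cross_sex_correlation(pheno: pd.DataFrame, trait: str) -> CrossSexCorrelation:
    """Cross-sex genetic correlation r_MF = cov_fm / (sigma_f * sigma_m).

    cov_fm is the sample covariance of female and male line means across
    lines; sigma_f and sigma_m are square roots of per-sex among-line variance
    components. In finite samples the ratio can exceed |1| (the line-mean
    covariance and ANOVA components are estimated differently); such values
    are reported as computed with ``clamped=True``, and the SE/p are evaluated
    at the clipped value.
    """
    lines, sexes, _ = _check_balanced(pheno, trait)
    if len(lines) < 3:
        raise ValueError("need >= 3 lines for a cross-sex correlation")
    means = pheno.groupby(["line", "sex"], observed=True)[trait].mean().unstack("sex")
    f_lab, m_lab = sexes[0], sexes[1]
    cov_fm = float(np.cov(means[f_lab], means[m_lab], ddof=1)[0, 1])
    sig2 = {
        s: _one_way_line_component(pheno[pheno["sex"] == s], trait) for s in sexes
    }
    sigma_f, sigma_m = math.sqrt(sig2[f_lab]), math.sqrt(sig2[m_lab])
    if sigma_f == 0.0 or sigma_m == 0.0:
        raise ValueError(
            f"cross-sex correlation undefined: zero among-line variance "
            f"(sigma_f={sigma_f}, sigma_m={sigma_m})"
        )
    r = cov_fm / (sigma_f * sigma_m)
    se, p = _pearson_se_p(r, len(lines))
    return CrossSexCorrelation(
        r_mf=r,
        cov_fm=cov_fm,
        sigma_f=sigma_f,
        sigma_m=sigma_m,
        se=se,
        p=p,
        n_lines=len(lines),
        clamped=abs(r) > 1.0,
    )


def trait_correlation(
    pheno: pd.DataFrame,
    trait_a: str,
    trait_b: str,
    scope: str = "pooled",
) -> TraitCorrelation:
    """Genetic correlation between traits, r_GT = cov_12 / (sigma_1 * sigma_2).

    cov_12 is the covariance of line means between the two traits within
    ``scope`` (pooled across sexes, or one sex); sigma_1 and sigma_2 are
    square roots of among-line variance components from each trait's own
    ANOVA (two-way pooled, one-way within a sex).
    """
    if scope not in ("pooled", "female", "male"):
        raise ValueError(f"scope must be pooled|female|male, got {scope!r}")
    if scope == "pooled":
        sub = pheno
        sig2 = {
            t: fit_line_sex_anova(pheno, t).sigma2_line for t in (trait_a, trait_b)
        }
    else:
        sub = pheno[pheno["sex"] == scope]
        if sub.empty:
            raise ValueError(f"no rows for sex {scope!r}")
        sig2 = {t: _one_way_line_component(sub, t) for t in (trait_a, trait_b)}
    means = sub.groupby("line", observed=True)[[trait_a, trait_b]].mean()
    n = len(means)
    if n < 4:
        raise ValueError(f"need >= 4 lines, got {n}")
    cov_12 = float(np.cov(means[trait_a], means[trait_b], ddof=1)[0, 1])
    s1, s2 = math.sqrt(sig2[trait_a]), math.sqrt(sig2[trait_b])
    if s1 == 0.0 or s2 == 0.0:
        raise ValueError("trait correlation undefined: zero among-line variance")
    r = cov_12 / (s1 * s2)
    se, p = _pearson_se_p(r, n)
    return TraitCorrelation(
        r_gt=r,
        cov_12=cov_12,
        sigma_1=s1,
        sigma_2=s2,
        se=se,
        p=p,
        n_lines=n,
        scope=scope,
        clamped=abs(r) > 1.0,
    )


def coefficients_of_variation(vd: VarianceDecomposition, mean: float) -> CVEstimates:
    """CV_G = 100 sigma_G / mu, CV_E = 100 sigma_E / mu.

    sigma_G^2 = sigma2_line + sigma2_line_sex (the same total genetic variance
    as the H2 numerator); pass a decomposition with sigma2_line_sex = 0 to get
    the line-component-only convention.
    """
    if mean == 0.0:
        raise ValueError("CV undefined for zero trait mean")
    sigma_g = math.sqrt(vd.sigma2_line + vd.sigma2_line_sex)
    sigma_e = math.sqrt(vd.sigma2_error)
    return CVEstimates(
        cv_g=100.0 * sigma_g / abs(mean),
        cv_e=100.0 * sigma_e / abs(mean),
        mean=mean,
        sigma_g=sigma_g,
        sigma_e=sigma_e,
    )


def sequential_bonferroni(pvals, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down rejection flags, returned in input order.

    Sort p ascending and reject p_(i) while p_(i) <= alpha / (m - i + 1),
    stopping at the first failure; uniformly more powerful than plain
    Bonferroni at the same family-wise error rate.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def mutant_ancova(
    mutant: pd.DataFrame,
    control: pd.DataFrame,
    covariate: str,
    trait: str,
    scope: str = "pooled",
) -> AncovaResult:
    """Mutant-vs-control ANCOVA with a continuous covariate (e.g. total protein).

    Pooled scope fits ``trait ~ genotype + sex + genotype:sex + covariate``
    and reports the genotype main-effect F test (type-II); stratified scopes
    drop the sex terms. Also returns covariate-adjusted least-square means per
    genotype (predictions at the grand covariate mean, averaged over sexes).
    """
    if scope not in ("pooled", "female", "male"):
        raise ValueError(f"scope must be pooled|female|male, got {scope!r}")
    frames = []
    for label, df in (("mutant", mutant), ("control", control)):
        for col in (trait, covariate):
            if col not in df.columns:
                raise KeyError(f"{label} table missing column {col!r}")
        d = df.copy()
        d["genotype"] = label
        frames.append(d)
    data = pd.concat(frames, ignore_index=True)
    if scope != "pooled":
        data = data[data["sex"] == scope]
        if data.empty:
            raise ValueError(f"no rows for sex {scope!r}")
    if data[covariate].nunique() < 2:
        raise ValueError(f"covariate {covariate!r} is constant: design is rank-deficient")

    data = data.rename(columns={trait: "_y", covariate: "_cov"})
    if scope == "pooled":
        formula = "_y ~ C(genotype) * C(sex) + _cov"
    else:
        formula = "_y ~ C(genotype) + _cov"
    fit = ols(formula, data=data).fit()
    table = anova_lm(fit, typ=2)
    f_g = float(table.loc["C(genotype)", "F"])
    p_g = float(table.loc["C(genotype)", "PR(>F)"])
    if not math.isfinite(f_g):  # identical groups: zero genotype SS and zero F
        f_g, p_g = 0.0, 1.0

    cov_mean = data["_cov"].mean()
    lsmeans: dict[str, float] = {}
    for g in ("mutant", "control"):
        if scope == "pooled":
            preds = [
                fit.predict(pd.DataFrame({"genotype": [g], "sex": [s], "_cov": [cov_mean]}))
                for s in sorted(data["sex"].unique())
            ]
            lsmeans[g] = float(np.mean([p.iloc[0] for p in preds]))
        else:
            lsmeans[g] = float(
                fit.predict(pd.DataFrame({"genotype": [g], "_cov": [cov_mean]})).iloc[0]
            )
    return AncovaResult(
        p_genotype=p_g, f_genotype=f_g, lsmeans=lsmeans, scope=scope, n_obs=len(data)
    )
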
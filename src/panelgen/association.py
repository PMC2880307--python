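"""Genome-wide SFP- and transcript-trait association screens.

SFP markers are binary line-level genotypes (presence/absence of a
single-feature polymorphism), so the analysis unit is the line x sex trait
mean — replicate vials within a line are pseudo-replicates with respect to
genotype. Pooled screens fit, per feature,

* SFP:        ``Y = mu + M + S + M*S + eps``   (two-way fixed-effects ANOVA)
* transcript: ``Y = mu + S + T + S*T + eps``   (regression on abundance)

and report the main-effect p (type-II F: the feature term added to the
sex-only model, tested over the full-model residual) together with the
sex-interaction p. Stratified screens drop the sex terms and run on one sex's
line means. Significance is declared at an uncorrected threshold (default
P < 0.01); the screen-level yield is compared against the chance expectation
``floor(n_tests * alpha)`` rather than corrected per-feature, with Holm
correction available downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationTable",
    "line_sex_means",
    "sfp_association",
    "transcript_association",
    "stratified_sfp_association",
    "stratified_transcript_association",
    "expected_by_chance",
    "collapse_to_genes",
]


@dataclass
class AssociationTable:
    """Per-feature screen results plus the screen-level chance accounting."""

    rows: pd.DataFrame
    n_tests: int
    alpha: float
    n_significant: int
    expected_by_chance: int
    trait: str
    scope: str
    kind: str
    skipped: pd.DataFrame = field(default_factory=pd.DataFrame)

    def significant(self) -> pd.DataFrame:
        return self.rows[self.rows["p"] < self.alpha]


def expected_by_chance(n_tests: int, alpha: float) -> int:
    """Number of false positives expected under the global null: floor(n * alpha)."""
    if n_tests < 0:
        raise ValueError("n_tests must be >= 0")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    # guard against binary-float droop (e.g. 300 * 0.01 = 2.9999...)
    return int(math.floor(n_tests * alpha + 1e-9))


def line_sex_means(pheno: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Collapse replicate vials to line x sex trait means (two rows per line)."""
    for col in ("line", "sex", trait):
        if col not in pheno.columns:
            raise KeyError(f"phenotype table missing column {col!r}")
    out = (
        pheno.groupby(["line", "sex"], observed=True)[trait]
        .mean()
        .rename("value")
        .reset_index()
    )
    return out


def _ftest_added_term(
    y: np.ndarray, x_reduced: np.ndarray, x_mid: np.ndarray, x_full: np.ndarray
) -> tuple[float, float]:
    """Type-II F test of the term taking x_reduced to x_mid, over the full-model MSE.

    Returns (F, p); (nan, nan) when the design leaves no residual information.
    """
    n = y.size

    def sse(x: np.ndarray) -> tuple[float, int]:
        beta, res, rank, _ = np.linalg.lstsq(x, y, rcond=None)
        if res.size:
            return float(res[0]), rank
        r = y - x @ beta
        return float(r @ r), rank

    sse_red, _ = sse(x_reduced)
    sse_mid, _ = sse(x_mid)
    sse_full, rank_full = sse(x_full)
    df_num = x_mid.shape[1] - x_reduced.shape[1]
    df_den = n - rank_full
    if df_den <= 0:
        return float("nan"), float("nan")
    mse = sse_full / df_den
    ss_term = max(0.0, sse_red - sse_mid)
    tol = 1e-12 * max(1.0, float(y @ y))  # rounding floor for exact-zero SSE
    if mse <= tol:
        # zero residual: either a perfect fit (term absorbs variance -> p=0)
        # or no variance at all -> undefined
        if ss_term > tol:
            return float("inf"), 0.0
        return float("nan"), float("nan")
    f = ss_term / df_num / mse
    return f, float(stats.f.sf(f, df_num, df_den))


def _screen(
    features: pd.DataFrame,
    means: pd.DataFrame,
    kind: str,
    trait: str,
    scope: str,
    alpha: float,
) -> AssociationTable:
    """Shared driver for pooled screens on line x sex means."""
    lines = means["line"].unique()
    feat = features.reindex(lines)
    sexes = sorted(means["sex"].unique())
    if len(sexes) != 2:
        raise ValueError("pooled screens need both sexes; use a stratified screen otherwise")
    m = means.set_index(["line", "sex"])["value"]
    y_all = np.concatenate([m.xs(s, level="sex").reindex(lines).to_numpy() for s in sexes])
    s_ind = np.concatenate([np.zeros(len(lines)), np.ones(len(lines))])
    ones = np.ones_like(y_all)
    x_red = np.column_stack([ones, s_ind])

    records, skipped = [], []
    for fid in feat.columns:
        g_line = feat[fid].to_numpy(dtype=float)
        g = np.concatenate([g_line, g_line])
        keep = ~np.isnan(g) & ~np.isnan(y_all)
        yk, gk, sk = y_all[keep], g[keep], s_ind[keep]
        if kind == "sfp":
            classes, counts = np.unique(gk, return_counts=True)
            if len(classes) < 2:
                skipped.append((fid, "monomorphic"))
                continue
            if counts.min() < 4:  # < 2 lines per class once doubled over sexes
                skipped.append((fid, "fewer than 2 lines in a class"))
                continue
        else:
            if np.nanstd(gk) == 0.0:
                skipped.append((fid, "constant abundance"))
                continue
        onesk = np.ones_like(yk)
        xr = np.column_stack([onesk, sk])
        xm = np.column_stack([onesk, sk, gk])
        xf = np.column_stack([onesk, sk, gk, sk * gk])
        f_main, p_main = _ftest_added_term(yk, xr, xm, xf)
        f_int, p_int = _ftest_added_term(yk, xm, xf, xf)

        beta_mid, *_ = np.linalg.lstsq(xm, yk, rcond=None)
        slope = float(beta_mid[2])
        rec: dict = {
            "feature": fid,
            "kind": kind,
            "trait": trait,
            "scope": scope,
            "p": p_main,
            "p_interaction": p_int,
            "direction": float(np.sign(slope)),
        }
        if kind == "sfp":
            rec["mean_major"] = float(yk[gk == 0].mean())
            rec["mean_minor"] = float(yk[gk == 1].mean())
        else:
            rec["slope"] = slope
        records.append(rec)

    rows = pd.DataFrame.from_records(records)
    skipped_df = pd.DataFrame(skipped, columns=["feature", "reason"])
    n_tests = len(rows)
    n_sig = int((rows["p"] < alpha).sum()) if n_tests else 0
    return AssociationTable(
        rows=rows,
        n_tests=n_tests,
        alpha=alpha,
        n_significant=n_sig,
        expected_by_chance=expected_by_chance(n_tests, alpha) if n_tests else 0,
        trait=trait,
        scope=scope,
        kind=kind,
        skipped=skipped_df,
    )


def sfp_association(
    geno: pd.DataFrame, pheno: pd.DataFrame, trait: str, alpha: float = 0.01
) -> AssociationTable:
    """Screen binary SFP markers against a trait, pooled across sexes.

    ``geno`` is lines x markers with values 0/1 (NaN = missing, dropped
    pairwise per marker). Markers monomorphic after missing-data removal, or
    with fewer than 2 lines in a class, are skipped with a reason.
    """
    means = line_sex_means(pheno, trait)
    return _screen(geno, means, "sfp", trait, "pooled", alpha)


def transcript_association(
    expr: pd.DataFrame, pheno: pd.DataFrame, trait: str, alpha: float = 0.01
) -> AssociationTable:
    """Screen transcript abundances (lines x transcripts) against a trait, pooled."""
    means = line_sex_means(pheno, trait)
    return _screen(expr, means, "transcript", trait, "pooled", alpha)


def _screen_stratified(
    features: pd.DataFrame,
    pheno: pd.DataFrame,
    kind: str,
    trait: str,
    sex: str,
    alpha: float,
) -> AssociationTable:
    known = set(pheno["sex"].unique())
    if sex not in known:
        raise ValueError(f"unknown sex label {sex!r}; table has {sorted(known)}")
    sub = pheno[pheno["sex"] == sex]
    means = sub.groupby("line", observed=True)[trait].mean()
    lines = means.index
    y_all = means.to_numpy()
    feat = features.reindex(lines)

    records, skipped = [], []
    for fid in feat.columns:
        g = feat[fid].to_numpy(dtype=float)
        keep = ~np.isnan(g) & ~np.isnan(y_all)
        yk, gk = y_all[keep], g[keep]
        if kind == "sfp":
            classes, counts = np.unique(gk, return_counts=True)
            if len(classes) < 2 or counts.min() < 2:
                skipped.append((fid, "monomorphic or < 2 lines per class"))
                continue
        elif np.nanstd(gk) == 0.0:
            skipped.append((fid, "constant abundance"))
            continue
        onesk = np.ones_like(yk)
        xr = onesk[:, None]
        xf = np.column_stack([onesk, gk])
        f_main, p_main = _ftest_added_term(yk, xr, xf, xf)
        beta, *_ = np.linalg.lstsq(xf, yk, rcond=None)
        slope = float(beta[1])
        rec: dict = {
            "feature": fid,
            "kind": kind,
            "trait": trait,
            "scope": sex,
            "p": p_main,
            "p_interaction": float("nan"),
            "direction": float(np.sign(slope)),
        }
        if kind == "sfp":
            rec["mean_major"] = float(yk[gk == 0].mean())
            rec["mean_minor"] = float(yk[gk == 1].mean())
        else:
            rec["slope"] = slope
        records.append(rec)

    rows = pd.DataFrame.from_records(records)
    n_tests = len(rows)
    n_sig = int((rows["p"] < alpha).sum()) if n_tests else 0
    return AssociationTable(
        rows=rows,
        n_tests=n_tests,
        alpha=alpha,
        n_significant=n_sig,
        expected_by_chance=expected_by_chance(n_tests, alpha) if n_tests else 0,
        trait=trait,
        scope=sex,
        kind=kind,
        skipped=pd.DataFrame(skipped, columns=["feature", "reason"]),
    )


def stratified_sfp_association(
    geno: pd.DataFrame, pheno: pd.DataFrame, trait: str, sex: str, alpha: float = 0.01
) -> AssociationTable:
    """SFP screen restricted to one sex's line means (model ``Y = mu + M + eps``)."""
    return _screen_stratified(geno, pheno, "sfp", trait, sex, alpha)


def stratified_transcript_association(
    expr: pd.DataFrame, pheno: pd.DataFrame, trait: str, sex: str, alpha: float = 0.01
) -> AssociationTable:
    """Transcript screen restricted to one sex's line means (``Y = mu + T + eps``)."""
    return _screen_stratified(expr, pheno, "transcript", trait, sex, alpha)


def collapse_to_genes(
    assoc: AssociationTable, feature_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse significant features to unique genes, keeping each gene's best p.

    Features absent from the map pass through as their own gene (a marker
    with no annotation still counts as an independent locus).
    """
    sig = assoc.significant()
    if sig.empty:
        return pd.DataFrame(columns=["gene", "p", "n_features"])
    genes = sig["feature"].map(lambda f: feature_to_gene.get(f, f))
    out = (
        sig.assign(gene=genes.to_numpy())
        .groupby("gene")
        .agg(p=("p", "min"), n_features=("feature", "size"))
        .reset_index()
        .sort_values("p", kind="mergesort")
        .reset_index(drop=True)
    )
    return out
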
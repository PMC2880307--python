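"""Synthetic inbred-line panel data with known ground truth.

Generators for the three data layers consumed downstream:

* replicate-vial phenotypes under the mixed model
  ``Y = mu + L + S + L*S + E`` with Gaussian random effects,
* line-level expression matrices with planted co-expression modules driven by
  one latent factor per module,
* binary SFP genotype matrices with optional causal effects injected back into
  the phenotypes.

Defaults emulate a panel of 40 near-homozygous lines scored in both sexes with
10 replicate vials per line x sex cell; every generator is deterministic for a
fixed seed, and each returns the ground truth needed for parameter-recovery
tests (true variance components, true module partition, causal marker set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExperimentDesign",
    "TrueVariances",
    "PlantedModuleSpec",
    "SFPSpec",
    "simulate_phenotypes",
    "simulate_expression",
    "simulate_sfp_genotypes",
]

SEX_LABELS = ("female", "male")


@dataclass(frozen=True)
class ExperimentDesign:
    """Balanced line x sex x replicate-vial layout.

    ``flies_per_vial`` is carried as metadata only: one vial contributes one
    observation (a group measurement), matching a within-vial error variance
    interpretation of the residual term.
    """

    n_lines: int = 40
    sex_labels: tuple[str, str] = SEX_LABELS
    n_reps: int = 10
    flies_per_vial: int = 10

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError(f"n_lines must be >= 2, got {self.n_lines}")
        if self.n_reps < 2:
            raise ValueError(f"n_reps must be >= 2, got {self.n_reps}")
        if len(self.sex_labels) != 2 or len(set(self.sex_labels)) != 2:
            raise ValueError("exactly two distinct sex labels required")

    @property
    def n_obs(self) -> int:
        return self.n_lines * 2 * self.n_reps


@dataclass(frozen=True)
class TrueVariances:
    """True parameters of the phenotype model ``Y = mu + L + S + L*S + E``.

    ``sex_effect`` is the fixed additive offset of the second sex relative to
    the first (the first sex sits at ``grand_mean - sex_effect/2`` and the
    second at ``grand_mean + sex_effect/2`` so the grand mean is preserved).
    """

    grand_mean: float = 0.0
    sex_effect: float = 0.0
    sigma2_line: float = 1.0
    sigma2_line_sex: float = 0.0
    sigma2_error: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma2_line", "sigma2_line_sex", "sigma2_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_line + self.sigma2_line_sex + self.sigma2_error

    @property
    def h2(self) -> float:
        """True broad-sense heritability (sigma_L^2 + sigma_LS^2) / sigma_total^2."""
        tot = self.sigma2_total
        return 0.0 if tot == 0 else (self.sigma2_line + self.sigma2_line_sex) / tot


@dataclass(frozen=True)
class PlantedModuleSpec:
    """Ground-truth co-expression structure for :func:`simulate_expression`.

    Each module m gets a latent line-level factor f_m; member transcripts are
    ``x = lambda * f_m + sqrt(1 - lambda^2) * noise`` with
    ``lambda = sqrt(within_r)``, so the expected within-module correlation is
    ``within_r`` exactly. ``trait_loading`` lets module factors feed a
    simulated trait for association tests.
    """

    module_sizes: tuple[int, ...] = (20, 20, 20)
    within_r: float = 0.8
    background_r: float = 0.0
    trait_loading: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.module_sizes or any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must all be >= 1")
        if not (0.0 <= self.within_r < 1.0):
            raise ValueError(f"within_r must be in [0, 1), got {self.within_r}")
        if self.background_r >= self.within_r and self.within_r > 0:
            raise ValueError("within_r must exceed background_r")
        if self.trait_loading is not None and len(self.trait_loading) != len(self.module_sizes):
            raise ValueError("trait_loading must have one entry per module")

    @property
    def n_transcripts(self) -> int:
        return sum(self.module_sizes)


@dataclass(frozen=True)
class SFPSpec:
    """Marker panel layout for :func:`simulate_sfp_genotypes`.

    SFPs (single-feature polymorphisms) are binary line-level markers; the
    minor class holds a fraction of lines within ``maf_range``. ``causal_sex``
    restricts each causal effect to one sex ("female"/"male") or ``None`` for
    both.
    """

    n_markers: int = 1000
    maf_range: tuple[float, float] = (0.1, 0.5)
    causal_markers: tuple[int, ...] = ()
    causal_effects: tuple[float, ...] = ()
    causal_sex: tuple[str | None, ...] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if len(self.causal_markers) != len(self.causal_effects):
            raise ValueError("causal_markers and causal_effects lengths differ")
        if any(not 0 <= m < self.n_markers for m in self.causal_markers):
            raise ValueError("causal marker index outside [0, n_markers)")
        if self.causal_sex is not None and len(self.causal_sex) != len(self.causal_markers):
            raise ValueError("causal_sex must have one entry per causal marker")


def _line_ids(n_lines: int) -> list[str]:
    width = max(2, len(str(n_lines)))
    return [f"L{i + 1:0{width}d}" for i in range(n_lines)]


def simulate_phenotypes(
    design: ExperimentDesign,
    tv: TrueVariances,
    seed: int,
    trait: str = "trait",
) -> pd.DataFrame:
    """Draw a balanced replicate-vial phenotype table.

    Returns a tidy frame with columns ``line, sex, vial, <trait>`` and one row
    per line x sex x vial. Line effects are N(0, sigma2_line), line-by-sex
    interaction effects N(0, sigma2_line_sex) drawn independently per cell, and
    vial residuals N(0, sigma2_error).
    """
    rng = np.random.default_rng(seed)
    nl, nr = design.n_lines, design.n_reps
    line_eff = rng.normal(0.0, np.sqrt(tv.sigma2_line), size=nl)
    inter_eff = rng.normal(0.0, np.sqrt(tv.sigma2_line_sex), size=(nl, 2))
    noise = rng.normal(0.0, np.sqrt(tv.sigma2_error), size=(nl, 2, nr))
    sex_off = np.array([-tv.sex_effect / 2.0, tv.sex_effect / 2.0])

    values = (
        tv.grand_mean
        + sex_off[None, :, None]
        + line_eff[:, None, None]
        + inter_eff[:, :, None]
        + noise
    )
    lines = _line_ids(nl)
    records = [
        (lines[i], design.sex_labels[j], f"V{k + 1:02d}", values[i, j, k])
        for i in range(nl)
        for j in range(2)
        for k in range(nr)
    ]
    return pd.DataFrame.from_records(records, columns=["line", "sex", "vial", trait])


def simulate_expression(
    n_lines: int,
    spec: PlantedModuleSpec,
    seed: int,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Draw a line-level expression matrix with planted modules.

    Returns ``(expr, truth, factors)`` where ``expr`` is lines x transcripts
    (unit-variance columns in expectation), ``truth`` maps each transcript id
    to its true module id (1-based, a valid partition covering every column
    exactly once), and ``factors`` holds the latent per-module line factors
    (used to couple modules to a simulated trait via ``trait_loading``).
    """
    if n_lines < max(10, max(spec.module_sizes)):
        raise ValueError(
            f"n_lines={n_lines} too small for modules of size up to {max(spec.module_sizes)}"
        )
    rng = np.random.default_rng(seed)
    n_mod = len(spec.module_sizes)
    lam = float(np.sqrt(spec.within_r))
    bg = float(np.sqrt(spec.background_r)) if spec.background_r > 0 else 0.0

    shared = rng.normal(size=n_lines)  # global factor carrying background_r
    factors = rng.normal(size=(n_lines, n_mod))
    cols, labels = [], []
    blocks = []
    for m, size in enumerate(spec.module_sizes):
        noise = rng.normal(size=(n_lines, size))
        resid_scale = np.sqrt(max(0.0, 1.0 - lam**2 - bg**2))
        block = (
            lam * factors[:, [m]]
            + bg * shared[:, None]
            + resid_scale * noise
        )
        blocks.append(block)
        cols.extend(f"T{m + 1:02d}_{j + 1:03d}" for j in range(size))
        labels.extend([m + 1] * size)

    expr = pd.DataFrame(
        np.hstack(blocks), index=pd.Index(_line_ids(n_lines), name="line"), columns=cols
    )
    truth = pd.Series(labels, index=pd.Index(cols, name="transcript"), name="module")
    factor_df = pd.DataFrame(
        factors,
        index=expr.index,
        columns=[f"factor_{m + 1}" for m in range(n_mod)],
    )
    return expr, truth, factor_df


def simulate_sfp_genotypes(
    n_lines: int,
    spec: SFPSpec,
    pheno: pd.DataFrame,
    seed: int,
    trait: str = "trait",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a binary lines x markers SFP matrix and inject causal effects.

    Minor-class counts are drawn so each marker's minor-class frequency falls
    within ``spec.maf_range`` (at least one line, at most half). For each
    causal marker the stated effect is added to the phenotype rows of all
    minor-class lines (optionally one sex only). Returns ``(genotypes,
    modified phenotypes)``; the input table is not mutated.
    """
    lines = sorted(pheno["line"].unique())
    if len(lines) != n_lines:
        raise ValueError(f"phenotype table has {len(lines)} lines, expected {n_lines}")
    rng = np.random.default_rng(seed)
    lo, hi = spec.maf_range
    mafs = rng.uniform(lo, hi, size=spec.n_markers)
    counts = np.clip(np.rint(mafs * n_lines).astype(int), 1, n_lines // 2)

    geno = np.zeros((n_lines, spec.n_markers), dtype=np.int8)
    for j in range(spec.n_markers):
        carriers = rng.choice(n_lines, size=counts[j], replace=False)
        geno[carriers, j] = 1
    geno_df = pd.DataFrame(
        geno,
        index=pd.Index(lines, name="line"),
        columns=[f"SFP{j + 1:05d}" for j in range(spec.n_markers)],
    )

    out = pheno.copy()
    sex_per_marker = spec.causal_sex or (None,) * len(spec.causal_markers)
    for m, eff, sx in zip(spec.causal_markers, spec.causal_effects, sex_per_marker):
        minor_lines = geno_df.index[geno_df.iloc[:, m] == 1]
        mask = out["line"].isin(minor_lines)
        if sx is not None:
            mask &= out["sex"] == sx
        out.loc[mask, trait] += eff
    return geno_df, out
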
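"""Readers, writers, configuration and the end-to-end pipeline driver.

TSV is the canonical interchange format (CSV accepted on input). The
phenotype table is tidy: ``line, sex, vial, <trait...>`` with one row per
replicate vial; matrices (expression, genotypes) are lines x features with a
``line`` index column; annotation is a two-column ``feature<TAB>category``
table or a GMT file. Sex labels are normalized case-insensitively to
{female, male}; anything else is rejected rather than guessed.

:func:`run_pipeline` chains the stages — simulate (or load), variance
decomposition, association screens (pooled and stratified), module detection
per trait, degree/hub statistics, cross-trait pleiotropy, and optional
enrichment — writing every intermediate table under the output directory and
returning a manifest of row counts. Re-running with the same config and seed
reproduces every output table byte-identically (the manifest's wall-clock
stamps are the only non-reproducible output).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from panelgen import association, crosstrait, network, quantgen, synthetic

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "run_pipeline",
]

_SEX_ALIASES = {"female": "female", "f": "female", "male": "male", "m": "male"}


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a replicate-level phenotype table (TSV or CSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("line", "sex", "vial"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    traits = [c for c in df.columns if c not in ("line", "sex", "vial")]
    if not traits:
        raise ValueError(f"{path}: no trait columns found")
    norm = df["sex"].astype(str).str.lower().map(_SEX_ALIASES)
    bad = df["sex"][norm.isna()]
    if len(bad):
        raise ValueError(
            f"{path}: unknown sex label {bad.iloc[0]!r} "
            f"(row {bad.index[0] + 2}); expected female/male"
        )
    df["sex"] = norm
    for t in traits:
        vals = pd.to_numeric(df[t], errors="coerce")
        missing = df.index[vals.isna()]
        if len(missing):
            raise ValueError(
                f"{path}: non-numeric or blank value in trait {t!r} (row {missing[0] + 2})"
            )
        df[t] = vals
    return df


def write_phenotype_table(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a lines x features matrix with a ``line`` index column."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index.name = "line"
    return df


def write_matrix(mat: pd.DataFrame, path: str | Path) -> None:
    mat.to_csv(path, sep="\t", index_label="line", float_format="%.17g")


def read_annotation(path: str | Path) -> dict[str, set]:
    """Read annotation as two-column TSV (feature, category) or GMT."""
    path = Path(path)
    out: dict[str, set] = {}
    if path.suffix.lower() == ".gmt":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: GMT line needs name, description, >= 1 gene")
            out.setdefault(parts[0], set()).update(p for p in parts[2:] if p)
        return out
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (feature, category)")
    feat_col, cat_col = df.columns[:2]
    for _, row in df.iterrows():
        out.setdefault(str(row[cat_col]), set()).add(str(row[feat_col]))
    return out


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline` (simulation mode or file inputs)."""

    out_dir: str | Path = "panelgen_out"
    seed: int = 0
    alpha: float = 0.01
    edge_threshold: float = 0.7
    # file inputs (simulation used for any left as None)
    phenotype_path: str | Path | None = None
    expression_path: str | Path | None = None
    genotype_path: str | Path | None = None
    annotation_path: str | Path | None = None
    traits: list[str] | None = None
    # simulation spec
    n_lines: int = 40
    n_reps: int = 10
    n_transcripts: int = 500
    n_markers: int = 1000
    module_sizes: tuple[int, ...] = (25, 20, 15)
    within_r: float = 0.8
    sigma2_line: float = 2.0
    sigma2_line_sex: float = 1.0
    sigma2_error: float = 1.0
    sex_effect: float = 1.0
    grand_mean: float = 10.0
    n_causal_sfp: int = 5
    causal_effect: float = 2.0
    trait_loading: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 <= self.edge_threshold <= 1.0:
            raise ValueError("edge threshold must lie in [0, 1]")


@dataclass
class RunManifest:
    config: dict
    version: str
    row_counts: dict[str, int] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    skipped_stages: list[str] = field(default_factory=list)
    input_checksums: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _simulate_inputs(cfg: PipelineConfig):
    """Generate the two-trait synthetic study: phenotypes, expression, SFPs."""
    design = synthetic.ExperimentDesign(n_lines=cfg.n_lines, n_reps=cfg.n_reps)
    tv = synthetic.TrueVariances(
        grand_mean=cfg.grand_mean,
        sex_effect=cfg.sex_effect,
        sigma2_line=cfg.sigma2_line,
        sigma2_line_sex=cfg.sigma2_line_sex,
        sigma2_error=cfg.sigma2_error,
    )
    n_mod = len(cfg.module_sizes)
    mspec = synthetic.PlantedModuleSpec(
        module_sizes=tuple(cfg.module_sizes), within_r=cfg.within_r
    )
    expr, truth, factors = synthetic.simulate_expression(cfg.n_lines, mspec, cfg.seed + 1)
    filler = cfg.n_transcripts - sum(cfg.module_sizes)
    if filler > 0:  # uncorrelated background transcripts, truth module id 0
        rng = np.random.default_rng(cfg.seed + 4)
        bg_cols = [f"BG_{j + 1:04d}" for j in range(filler)]
        bg = pd.DataFrame(
            rng.normal(size=(cfg.n_lines, filler)), index=expr.index, columns=bg_cols
        )
        expr = pd.concat([expr, bg], axis=1)
        truth = pd.concat(
            [truth, pd.Series(0, index=pd.Index(bg_cols, name="transcript"), name="module")]
        )

    loadings = cfg.trait_loading or tuple(1.0 for _ in range(n_mod))
    pheno = synthetic.simulate_phenotypes(design, tv, cfg.seed, trait="trait1")
    p2 = synthetic.simulate_phenotypes(design, tv, cfg.seed + 2, trait="trait2")
    pheno["trait2"] = p2["trait2"]
    # couple the planted module factors to the traits (line-level shifts);
    # the two traits share module 1 so the pleiotropy screen has signal
    lines = sorted(pheno["line"].unique())
    fac = factors.reindex(lines)
    shift1 = sum(loadings[m] * fac.iloc[:, m] for m in range(min(n_mod, fac.shape[1])))
    shift2 = loadings[0] * fac.iloc[:, 0]
    pheno["trait1"] += pheno["line"].map(dict(zip(lines, shift1))).to_numpy()
    pheno["trait2"] += pheno["line"].map(dict(zip(lines, shift2))).to_numpy()

    sspec = synthetic.SFPSpec(
        n_markers=cfg.n_markers,
        causal_markers=tuple(range(cfg.n_causal_sfp)),
        causal_effects=(cfg.causal_effect,) * cfg.n_causal_sfp,
    )
    geno, pheno = synthetic.simulate_sfp_genotypes(
        cfg.n_lines, sspec, pheno, cfg.seed + 3, trait="trait1"
    )
    return pheno, expr, geno, truth


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Run simulate/load -> quantgen -> screens -> modules -> pleiotropy -> enrichment."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={k: v for k, v in dataclasses.asdict(cfg).items()},
        version=__import__("panelgen").__version__,
    )
    t0 = time.time()

    if cfg.phenotype_path is not None:
        pheno = read_phenotype_table(cfg.phenotype_path)
        expr = read_matrix(cfg.expression_path) if cfg.expression_path else None
        geno = read_matrix(cfg.genotype_path) if cfg.genotype_path else None
        truth = None
        for label, p in (("phenotypes", cfg.phenotype_path),
                         ("expression", cfg.expression_path),
                         ("genotypes", cfg.genotype_path)):
            if p is not None:
                manifest.input_checksums[label] = _checksum(Path(p))
    else:
        pheno, expr, geno, truth = _simulate_inputs(cfg)
        write_phenotype_table(pheno, out / "phenotypes.tsv")
        write_matrix(expr, out / "expression.tsv")
        write_matrix(geno, out / "genotypes.tsv")
        truth.to_frame().to_csv(out / "true_modules.tsv", sep="\t")
        manifest.row_counts["phenotypes"] = len(pheno)
        for label in ("phenotypes", "expression", "genotypes"):
            manifest.input_checksums[label] = _checksum(out / f"{label}.tsv")
    traits = cfg.traits or [
        c for c in pheno.columns if c not in ("line", "sex", "vial")
    ]
    manifest.timings["simulate"] = time.time() - t0

    # --- quantitative genetics -------------------------------------------
    t0 = time.time()
    qg_rows = []
    for trait in traits:
        vd = quantgen.fit_line_sex_anova(pheno, trait)
        h2 = quantgen.broad_sense_heritability(vd)
        cv = quantgen.coefficients_of_variation(vd, vd.grand_mean) if vd.grand_mean else None
        rmf = quantgen.cross_sex_correlation(pheno, trait)
        qg_rows.append(
            {
                "trait": trait,
                "sigma2_line": vd.sigma2_line,
                "sigma2_line_sex": vd.sigma2_line_sex,
                "sigma2_error": vd.sigma2_error,
                "F_line": vd.f_line,
                "p_line": vd.p_line,
                "F_sex": vd.f_sex,
                "p_sex": vd.p_sex,
                "F_line_sex": vd.f_line_sex,
                "p_line_sex": vd.p_line_sex,
                "H2": h2.h2,
                "CV_G": cv.cv_g if cv else float("nan"),
                "CV_E": cv.cv_e if cv else float("nan"),
                "r_MF": rmf.r_mf,
                "r_MF_se": rmf.se,
                "r_MF_p": rmf.p,
            }
        )
    qg = pd.DataFrame(qg_rows)
    qg.to_csv(out / "quantgen_stats.tsv", sep="\t", index=False, float_format="%.17g")
    manifest.row_counts["quantgen_stats"] = len(qg)

    if len(traits) > 1:
        rows = []
        for i, a in enumerate(traits):
            for b in traits[i + 1:]:
                for scope in ("pooled", "female", "male"):
                    tc = quantgen.trait_correlation(pheno, a, b, scope)
                    rows.append(
                        {"trait_a": a, "trait_b": b, "scope": scope,
                         "r_GT": tc.r_gt, "se": tc.se, "p": tc.p}
                    )
        rgt = pd.DataFrame(rows)
        rgt["holm_reject"] = False
        for scope, grp in rgt.groupby("scope"):
            rgt.loc[grp.index, "holm_reject"] = quantgen.sequential_bonferroni(
                grp["p"].to_numpy(), alpha=0.05
            )
        rgt.to_csv(out / "trait_correlations.tsv", sep="\t", index=False,
                   float_format="%.17g")
        manifest.row_counts["trait_correlations"] = len(rgt)
    manifest.timings["quantgen"] = time.time() - t0

    # --- association screens ---------------------------------------------
    t0 = time.time()
    assoc_tables: dict[str, association.AssociationTable] = {}
    all_rows = []
    for trait in traits:
        if geno is not None:
            for scope_fn in (
                lambda: association.sfp_association(geno, pheno, trait, cfg.alpha),
                lambda: association.stratified_sfp_association(
                    geno, pheno, trait, "female", cfg.alpha),
                lambda: association.stratified_sfp_association(
                    geno, pheno, trait, "male", cfg.alpha),
            ):
                tab = scope_fn()
                all_rows.append(tab.rows)
        if expr is not None:
            tab = association.transcript_association(expr, pheno, trait, cfg.alpha)
            assoc_tables[trait] = tab
            all_rows.append(tab.rows)
            for sex in ("female", "male"):
                all_rows.append(
                    association.stratified_transcript_association(
                        expr, pheno, trait, sex, cfg.alpha
                    ).rows
                )
    if all_rows:
        assoc = pd.concat(all_rows, ignore_index=True)
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False,
                     float_format="%.17g")
        manifest.row_counts["associations"] = len(assoc)
    manifest.timings["association"] = time.time() - t0

    # --- module detection per trait --------------------------------------
    t0 = time.time()
    partitions: dict[str, network.ModulePartition] = {}
    for trait, tab in assoc_tables.items():
        sig = tab.significant()["feature"].tolist()
        if len(sig) < 5:  # too few trait-associated transcripts to partition
            manifest.skipped_stages.append(f"modules:{trait}")
            continue
        trait_means = pheno.groupby("line", observed=True)[trait].mean()
        res = network.residualize_expression(expr[sig], trait_means)
        corr, dropped = network.correlation_matrix(res)
        part = network.detect_modules(corr, seed=cfg.seed)
        partitions[trait] = part
        deg = network.degree_table(corr, part)
        deg.to_csv(out / f"modules_{trait}.tsv", sep="\t", index_label="transcript",
                   float_format="%.17g")
        edges = network.edge_list(corr, cfg.edge_threshold)
        edges.to_csv(out / f"edges_{trait}.tsv", sep="\t", index=False,
                     float_format="%.17g")
        manifest.row_counts[f"modules_{trait}"] = len(deg)
        manifest.row_counts[f"edges_{trait}"] = len(edges)
    manifest.timings["modules"] = time.time() - t0

    # --- cross-trait pleiotropy and enrichment ---------------------------
    t0 = time.time()
    if len(partitions) >= 2:
        pleio = crosstrait.pleiotropy_screen(partitions, alpha=0.05)
        pleio.assign(shared=pleio["shared"].map(lambda s: ";".join(map(str, s)))).to_csv(
            out / "pleiotropy.tsv", sep="\t", index=False, float_format="%.17g"
        )
        manifest.row_counts["pleiotropy"] = len(pleio)
    else:
        manifest.skipped_stages.append("pleiotropy")

    if cfg.annotation_path is not None and partitions:
        annot = read_annotation(cfg.annotation_path)
        rows = []
        for trait, part in partitions.items():
            population = set(part.assignments.index)
            for mid in part.module_sizes.index:
                enr = crosstrait.ease_enrichment(
                    set(part.members(mid)), annot, population
                )
                enr.insert(0, "trait", trait)
                enr.insert(1, "module", mid)
                rows.append(enr)
        if rows:
            enrich = pd.concat(rows, ignore_index=True)
            enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                          float_format="%.17g")
            manifest.row_counts["enrichment"] = len(enrich)
    else:
        manifest.skipped_stages.append("enrichment")
    manifest.timings["crosstrait"] = time.time() - t0

    manifest.write(out / "manifest.json")
    return manifest
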
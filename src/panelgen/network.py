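"""Co-expression modules from residualized genetic correlations.

Pipeline: residualize transcript abundance on the trait (and sex, when
per-sex layers are available) so module structure is not driven by the
trait association itself; compute pairwise Pearson correlations of the
residuals across lines; map correlations to the Euclidean-like distance
``d = sqrt(2 * (1 - |r|))`` (the Euclidean distance between standardized
vectors, up to sign); build a Gaussian affinity matrix
``A = exp(-d^2 / (2 * sigma^2))`` and scan the kernel bandwidth sigma over a
log-spaced grid, keeping the partition that maximizes weighted Newman
modularity. Degree statistics (average correlation with module-mates) and
hard-thresholded edge lists describe the resulting modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "ModulePartition",
    "residualize_expression",
    "correlation_matrix",
    "correlation_to_distance",
    "default_bandwidth_grid",
    "detect_modules",
    "degree_table",
    "edge_list",
]


@dataclass
class ModulePartition:
    """Transcript -> module assignment with the modularity score achieved."""

    assignments: pd.Series  # transcript -> module id (1-based ints)
    modularity: float
    bandwidth: float | None
    no_structure: bool = False

    def __post_init__(self) -> None:
        if self.assignments.index.has_duplicates:
            raise ValueError("each transcript must appear exactly once")

    @property
    def module_sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()

    def members(self, module: int) -> list:
        return list(self.assignments.index[self.assignments == module])


def residualize_expression(
    expr: pd.DataFrame, trait_means: pd.Series, trait: str | None = None
) -> pd.DataFrame:
    """Remove the trait (and sex) signal from each transcript's abundance.

    ``expr`` is observations x transcripts. With a plain line index and a
    line-indexed ``trait_means``, each column is regressed on
    ``[1, trait]``; with a (line, sex) MultiIndex on both, the design is
    ``[1, sex, trait, sex x trait]`` over line x sex means. Residual columns
    are returned with the input's index; they are exactly orthogonal to every
    design column used.
    """
    t = trait_means.reindex(expr.index)
    if t.isna().any():
        raise ValueError("trait means do not cover every expression row")
    tv = t.to_numpy(dtype=float)
    if np.std(tv) == 0.0:
        raise ValueError("constant trait: residualization design is rank-deficient")
    ones = np.ones(len(expr))
    if isinstance(expr.index, pd.MultiIndex) and "sex" in (expr.index.names or []):
        sexes = expr.index.get_level_values("sex")
        levels = sorted(set(sexes))
        if len(levels) != 2:
            raise ValueError("expected exactly two sex levels in the expression index")
        s = (sexes == levels[1]).astype(float)
        x = np.column_stack([ones, s, tv, s * tv])
    else:
        x = np.column_stack([ones, tv])
    y = expr.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return pd.DataFrame(resid, index=expr.index, columns=expr.columns)


def correlation_matrix(res: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Pairwise Pearson correlations across observations.

    Returns ``(C, dropped)`` where ``dropped`` lists constant columns that
    were excluded (their correlations are undefined).
    """
    if len(res) < 4:
        raise ValueError(f"need >= 4 observations, got {len(res)}")
    sd = res.std(ddof=1)
    dropped = list(res.columns[(sd == 0) | sd.isna()])
    kept = res.drop(columns=dropped)
    c = np.corrcoef(kept.to_numpy(dtype=float), rowvar=False)
    c = np.atleast_2d(c)
    np.fill_diagonal(c, 1.0)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    return pd.DataFrame(c, index=kept.columns, columns=kept.columns), dropped


def correlation_to_distance(corr: pd.DataFrame) -> pd.DataFrame:
    """Euclidean-like distance d = sqrt(2 * (1 - |r|)); zero diagonal.

    Uses the absolute correlation, matching the |r| convention for network
    edges: strongly anti-correlated transcripts are also close.
    """
    r = np.abs(corr.to_numpy(dtype=float))
    d = np.sqrt(np.maximum(0.0, 2.0 * (1.0 - r)))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=corr.index, columns=corr.columns)


def default_bandwidth_grid(dist: pd.DataFrame, n: int = 30) -> np.ndarray:
    """Log-spaced bandwidths spanning [0.1, 10] x median off-diagonal distance."""
    d = dist.to_numpy(dtype=float)
    off = d[np.triu_indices_from(d, k=1)]
    med = float(np.median(off)) if off.size else 1.0
    if med <= 0.0:
        med = 1.0
    return med * np.logspace(-1.0, 1.0, n)


def _canonical_labels(communities: list[set], order: pd.Index) -> pd.Series:
    """Deterministic module ids: sorted by size (desc), then lowest member position."""
    pos = {t: i for i, t in enumerate(order)}
    keyed = sorted(
        (sorted(c, key=pos.get) for c in communities),
        key=lambda c: (-len(c), pos[c[0]]),
    )
    lab = {}
    for mid, members in enumerate(keyed, start=1):
        for t in members:
            lab[t] = mid
    return pd.Series([lab[t] for t in order], index=order, name="module")


def detect_modules(
    corr: pd.DataFrame,
    bandwidth_grid=None,
    seed: int = 0,
) -> ModulePartition:
    """Partition transcripts by modularity maximization over a bandwidth scan.

    For each sigma in the grid the affinity ``A = exp(-d^2 / (2 sigma^2))``
    (zero diagonal) weights a complete undirected graph, clustered with
    greedy (Clauset-Newman-Moore) modularity maximization; the partition with
    the largest weighted modularity Q across the scan is returned. When no
    bandwidth yields Q > 0 the transcripts form a single module with
    ``no_structure=True``. Deterministic for fixed inputs; ``seed`` is
    accepted for interface stability.
    """
    if len(corr) < 2:
        raise ValueError("need >= 2 transcripts to partition")
    dist = correlation_to_distance(corr)
    if bandwidth_grid is None:
        bandwidth_grid = default_bandwidth_grid(dist)
    bandwidth_grid = np.asarray(bandwidth_grid, dtype=float)
    if bandwidth_grid.size == 0:
        raise ValueError("bandwidth grid must be non-empty")

    d2 = dist.to_numpy(dtype=float) ** 2
    names = corr.index
    best: tuple[float, float, list[set]] | None = None
    for sigma in bandwidth_grid:
        a = np.exp(-d2 / (2.0 * sigma**2))
        np.fill_diagonal(a, 0.0)
        g = nx.from_numpy_array(a)
        comms = nx.community.greedy_modularity_communities(g, weight="weight")
        comms = [set(c) for c in comms]
        q = nx.community.modularity(g, comms, weight="weight")
        if best is None or q > best[0] + 1e-12:
            best = (q, float(sigma), comms)

    q, sigma, comms = best
    if q <= 0.0 or len(comms) <= 1:
        assignments = pd.Series(1, index=names, name="module")
        return ModulePartition(
            assignments=assignments,
            modularity=max(q, 0.0),
            bandwidth=sigma,
            no_structure=True,
        )
    named = [{names[i] for i in c} for c in comms]
    return ModulePartition(
        assignments=_canonical_labels(named, names),
        modularity=q,
        bandwidth=sigma,
    )


def degree_table(
    corr: pd.DataFrame, part: ModulePartition, absolute: bool = True, top_k: int = 3
) -> pd.DataFrame:
    """Intramodular connectivity: per-transcript degree and module averages.

    Degree of a transcript is its average correlation (|r| by default) with
    all other transcripts in its module; singletons get NaN degree. Columns:
    ``module, degree, module_avg_degree, is_hub`` (hubs = top ``top_k`` by
    degree within each module of size > 1).
    """
    missing = part.assignments.index.difference(corr.index)
    if len(missing):
        raise ValueError(f"partition covers transcripts absent from C: {list(missing)[:5]}")
    r = corr.to_numpy(dtype=float)
    if absolute:
        r = np.abs(r)
    out = pd.DataFrame(index=corr.index)
    out["module"] = part.assignments.reindex(corr.index)
    out["degree"] = np.nan
    for mid, members in out.groupby("module").groups.items():
        idx = [corr.index.get_loc(t) for t in members]
        if len(idx) < 2:
            continue
        sub = r[np.ix_(idx, idx)]
        deg = (sub.sum(axis=1) - np.diag(sub)) / (len(idx) - 1)
        out.loc[members, "degree"] = deg
    out["module_avg_degree"] = out.groupby("module")["degree"].transform("mean")
    out["is_hub"] = False
    for mid, grp in out.groupby("module"):
        if grp["degree"].notna().any():
            hubs = grp["degree"].nlargest(top_k).index
            out.loc[hubs, "is_hub"] = True
    return out


def edge_list(corr: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """All unordered transcript pairs with |r| >= threshold (no self-edges)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    r = corr.to_numpy(dtype=float)
    iu, ju = np.triu_indices_from(r, k=1)
    mask = np.abs(r[iu, ju]) >= threshold
    return pd.DataFrame(
        {
            "a": corr.index[iu[mask]],
            "b": corr.columns[ju[mask]],
            "r": r[iu, ju][mask],
            "abs_r": np.abs(r[iu, ju][mask]),
        }
    )
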
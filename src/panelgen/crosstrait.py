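"""Modular pleiotropy and functional enrichment of transcript modules.

Modular pleiotropy asks whether a module detected for one trait shares more
transcripts with a module for another trait than expected by chance, via a
one-sided Fisher exact (upper hypergeometric tail) test: with a universe of
N features, module A of size K, module B of size n and overlap k, the
p-value is P(X >= k) for X ~ Hypergeom(N, K, n).

EASE-score enrichment is the conservative DAVID variant of the same test: one
hit is removed from the list-in-category cell (k -> max(k - 1, 0)) before
taking the upper tail, so categories supported by a single gene are never
significant. Benjamini-Hochberg q-values are reported across categories
(and across module pairs in the pleiotropy screen).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from panelgen.network import ModulePartition

__all__ = [
    "ModuleOverlap",
    "module_overlap_test",
    "pleiotropy_screen",
    "ease_enrichment",
]


@dataclass(frozen=True)
class ModuleOverlap:
    """One-sided Fisher exact overlap between two feature sets in a universe."""

    n_universe: int
    size_a: int
    size_b: int
    overlap: int
    p: float
    shared: tuple = ()
    label_a: str = ""
    label_b: str = ""


def _upper_tail(k: int, n_universe: int, size_a: int, size_b: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(hypergeom.sf(k - 1, n_universe, size_a, size_b))


def module_overlap_test(
    set_a: Iterable, set_b: Iterable, universe: Iterable,
    label_a: str = "A", label_b: str = "B",
) -> ModuleOverlap:
    """Test whether two modules overlap more than chance (one-sided Fisher exact)."""
    uni = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= uni:
        raise ValueError("set A is not a subset of the universe")
    if not b <= uni:
        raise ValueError("set B is not a subset of the universe")
    shared = a & b
    p = _upper_tail(len(shared), len(uni), len(a), len(b))
    return ModuleOverlap(
        n_universe=len(uni),
        size_a=len(a),
        size_b=len(b),
        overlap=len(shared),
        p=p,
        shared=tuple(sorted(shared)),
        label_a=label_a,
        label_b=label_b,
    )


def pleiotropy_screen(
    partitions: Mapping[str, ModulePartition],
    universe: Iterable | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All cross-trait module-pair overlap tests, sorted by p.

    ``universe`` defaults to the union of all transcripts entering any
    trait's module analysis. Returns one row per cross-trait module pair with
    margins, overlap, raw p, BH q, a significance call at raw p < alpha, and
    the shared feature ids for significant pairs.
    """
    if len(partitions) < 2:
        raise ValueError("need partitions for >= 2 traits")
    if universe is None:
        uni: set = set()
        for part in partitions.values():
            uni |= set(part.assignments.index)
    else:
        uni = set(universe)

    traits = list(partitions)
    records = []
    for i, ta in enumerate(traits):
        for tb in traits[i + 1:]:
            pa, pb = partitions[ta], partitions[tb]
            for ma in pa.module_sizes.index:
                sa = set(pa.members(ma)) & uni
                for mb in pb.module_sizes.index:
                    sb = set(pb.members(mb)) & uni
                    ov = module_overlap_test(sa, sb, uni, f"{ta}:{ma}", f"{tb}:{mb}")
                    records.append(
                        {
                            "trait_a": ta,
                            "module_a": ma,
                            "trait_b": tb,
                            "module_b": mb,
                            "n_universe": ov.n_universe,
                            "size_a": ov.size_a,
                            "size_b": ov.size_b,
                            "overlap": ov.overlap,
                            "p": ov.p,
                            "shared": ov.shared,
                        }
                    )
    out = pd.DataFrame.from_records(records)
    _, q, *_ = multipletests(out["p"], method="fdr_bh")
    out["q"] = q
    out["significant"] = out["p"] < alpha
    out.loc[~out["significant"], "shared"] = out.loc[~out["significant"], "shared"].apply(
        lambda _: ()
    )
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def ease_enrichment(
    gene_list: Iterable,
    annotation: Mapping[str, Iterable],
    population: Iterable,
) -> pd.DataFrame:
    """EASE-score functional enrichment of a gene list against annotation sets.

    Per category: k = list genes in the category, n = list size, K =
    population genes in the category, N = population size. Reports the plain
    one-sided Fisher p, the EASE p (upper tail with k replaced by
    max(k - 1, 0)), and the BH q over the EASE p across all reported
    categories. Categories with no list hits are omitted.
    """
    pop = set(population)
    if not pop:
        raise ValueError("population must be non-empty")
    genes = set(gene_list)
    if not genes <= pop:
        raise ValueError("gene list is not a subset of the population")
    n, n_pop = len(genes), len(pop)
    records = []
    for cat, members in annotation.items():
        in_pop = set(members) & pop
        k = len(genes & in_pop)
        if k == 0:
            continue
        big_k = len(in_pop)
        p_fisher = _upper_tail(k, n_pop, big_k, n)
        p_ease = _upper_tail(max(k - 1, 0), n_pop, big_k, n)
        records.append(
            {
                "category": cat,
                "list_hits": k,
                "list_size": n,
                "population_hits": big_k,
                "population_size": n_pop,
                "percent": 100.0 * k / n,
                "p_fisher": p_fisher,
                "p_ease": p_ease,
            }
        )
    out = pd.DataFrame.from_records(
        records,
        columns=[
            "category", "list_hits", "list_size", "population_hits",
            "population_size", "percent", "p_fisher", "p_ease",
        ],
    )
    if len(out):
        _, q, *_ = multipletests(out["p_ease"], method="fdr_bh")
        out["q"] = q
        out = out.sort_values("p_ease", kind="mergesort").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
    return out
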
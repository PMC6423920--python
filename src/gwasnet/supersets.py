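"""Merging of overlapping significant gene sets into independent supersets.

Significant pathways and modules from enrichment analysis are typically
redundant.  Two sets are joined when their overlap coefficient
|A∩B| / min(|A|,|B|) reaches a threshold AND the shared genes are more
numerous than expected by chance in the gene universe (one-sided Fisher
exact, Bonferroni-corrected over the pairs examined).  Transitive
closure via union-find yields disjoint supersets; singleton components
pass through intact.  Supersets are annotated against reference
pathways by Fisher's exact test and confirmed by a second enrichment
round under a Bonferroni cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd
from scipy import stats

from .io import GeneSet, GeneSetCollection
from .msea import MSEA

logger = logging.getLogger(__name__)

__all__ = [
    "Superset",
    "fisher_exact_2x2",
    "merge_gene_sets",
    "annotate_supersets",
    "confirm_supersets",
    "supersets_to_collection",
]


@dataclass
class Superset:
    superset_id: str
    member_set_ids: list[str]
    genes: frozenset[str]
    annotations: list[tuple[str, float, float]] = field(default_factory=list)


def fisher_exact_2x2(a: int, b: int, c: int, d: int, sided: str = "greater") -> float:
    """Exact hypergeometric p for the 2x2 table [[a, b], [c, d]].

    ``greater`` is the upper tail on cell a; ``two`` sums the
    probabilities of all tables (fixed margins) no more likely than the
    observed one.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("cell counts must be non-negative")
    alternative = {"greater": "greater", "two": "two-sided"}.get(sided)
    if alternative is None:
        raise ValueError(f"sided must be 'greater' or 'two', got {sided!r}")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def _overlap_fisher_p(A: set, B: set, universe_size: int) -> float:
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = universe_size - a - b - c
    return fisher_exact_2x2(a, b, c, max(d, 0), sided="greater")


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            # deterministic: smaller id becomes the root
            if ry < rx:
                rx, ry = ry, rx
            self.parent[ry] = rx


def merge_gene_sets(
    significant: GeneSetCollection,
    universe: set[str],
    overlap_min: float = 0.33,
    fisher_alpha: float = 0.05,
) -> list[Superset]:
    """Merge overlapping sets into disjoint supersets.

    Overlap is evaluated on genes intersected with ``universe`` (the
    mapped-gene universe the enrichment analysis used); a pair merges
    when overlap coefficient >= ``overlap_min`` and the Fisher exact p
    for the shared genes, Bonferroni-corrected by the number of pairs
    examined, is below ``fisher_alpha``.  Supersets carry the union of
    their members' full gene sets.
    """
    ids = sorted(significant.ids())
    if not ids:
        return []
    # state: disjoint groups of member ids with the union of their genes;
    # merging two groups can create a new qualifying overlap with a third,
    # so rounds repeat until a fixed point — this makes the operation
    # idempotent by construction
    groups: list[tuple[list[str], frozenset[str]]] = [
        ([sid], frozenset(significant.genes(sid))) for sid in ids
    ]
    while True:
        keys = list(range(len(groups)))
        eff = [set(g) & universe for _, g in groups]
        uf = _UnionFind(keys)
        pairs = list(combinations(keys, 2))
        n_tests = max(len(pairs), 1)
        merged_any = False
        for i, j in pairs:
            A, B = eff[i], eff[j]
            if not A or not B:
                continue
            coeff = len(A & B) / min(len(A), len(B))
            if coeff < overlap_min:
                continue
            p = _overlap_fisher_p(A, B, len(universe))
            if p * n_tests < fisher_alpha:
                uf.union(i, j)
                merged_any = True
        if not merged_any:
            break
        components: dict[int, list[int]] = {}
        for k in keys:
            components.setdefault(uf.find(k), []).append(k)
        groups = [
            (
                sorted(m for k in comp for m in groups[k][0]),
                frozenset().union(*(groups[k][1] for k in comp)),
            )
            for comp in (components[r] for r in sorted(components))
        ]
    groups.sort(key=lambda t: t[0])
    return [
        Superset(f"SS{k:03d}", list(members), genes)
        for k, (members, genes) in enumerate(groups, start=1)
    ]


def annotate_supersets(
    supersets: list[Superset],
    reference: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
) -> list[Superset]:
    """Annotate each superset against reference pathways.

    One-sided Fisher exact per (superset, reference pathway) in
    ``universe``; annotations with Bonferroni p (x n_reference per
    superset) below ``alpha`` are kept, sorted by ascending p.
    """
    n_ref = len(reference)
    for ss in supersets:
        hits = []
        sgenes = set(ss.genes) & universe
        for rid in reference.ids():
            rgenes = set(reference.genes(rid)) & universe
            if not rgenes:
                continue
            p = _overlap_fisher_p(sgenes, rgenes, len(universe))
            p_bonf = min(p * n_ref, 1.0)
            if p_bonf < alpha:
                hits.append((rid, p, p_bonf))
        ss.annotations = sorted(hits, key=lambda t: (t[1], t[0]))
    return supersets


def supersets_to_collection(supersets: list[Superset]) -> GeneSetCollection:
    return GeneSetCollection(
        {
            ss.superset_id: GeneSet(
                description=";".join(ss.member_set_ids), genes=ss.genes, source="superset"
            )
            for ss in supersets
        }
    )


def confirm_supersets(
    supersets: list[Superset],
    gwas,
    snp_gene_map,
    ld=None,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    **msea_kwargs,
) -> pd.DataFrame:
    """Second enrichment round on the supersets themselves.

    A superset is confirmed when its enrichment p times the number of
    supersets (Bonferroni) is below ``alpha``.
    """
    collection = supersets_to_collection(supersets)
    model = MSEA(gwas, snp_gene_map, collection, ld=ld, **msea_kwargs)
    res = model.fit(n_perm=n_perm, seed=seed)
    frame = res.frame.copy()
    m = len(supersets)
    frame["p_bonferroni"] = (frame["p"] * m).clip(upper=1.0)
    frame["confirmed"] = frame["p_bonferroni"] < alpha
    return frame
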
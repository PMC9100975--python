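"""Hypergeometric GO/KEGG enrichment and miRNA-family set utilities.

Over-representation of a target-gene set in each annotation term is tested
with the hypergeometric upper tail P(X >= k) for X ~ Hypergeom(N, K, n)
(N genes in the annotated universe, K of them in the term, n targets, k
targets in the term), BH-adjusted across terms. The rich factor is
k / K — target genes in the term over all annotated genes in the term.

Family utilities compute the Venn partition of miRNA-family catalogs
across species groups (which families are shared by all species of
exactly a given group combination).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # target genes in term
    K: int  # universe genes in term
    n: int  # target-set size (annotated)
    N: int  # universe size
    rich_factor: float
    p_value: float
    padj: float = 1.0


@dataclass
class FamilyCatalog:
    """The set of miRNA families observed in one species."""

    species: str
    families: set[str]

    def __post_init__(self) -> None:
        if any(not f for f in self.families):
            raise ValueError("empty family name")


def enrich(
    target_genes: set[str],
    term_map: Mapping[str, set[str]],
    universe: set[str] | None = None,
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``target_genes`` per term.

    The universe defaults to all genes with at least one term annotation;
    term gene sets and the target set are intersected with it.
    """
    if universe is None:
        universe = set().union(*term_map.values()) if term_map else set()
    if not universe:
        raise ValueError("empty universe")
    targets = target_genes & universe
    N, n = len(universe), len(targets)
    results: list[EnrichmentResult] = []
    for term_id in sorted(term_map):
        genes = term_map[term_id] & universe
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & targets)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=(term_names or {}).get(term_id, term_id),
                k=k,
                K=K,
                n=n,
                N=N,
                rich_factor=k / K,
                p_value=min(p, 1.0),
            )
        )
    if results:
        padj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, padj):
            r.padj = float(q)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "rich_factor": r.rich_factor,
                "p": r.p_value,
                "padj": r.padj,
            }
            for r in results
        ]
    )


def family_sets(
    catalogs: Sequence[FamilyCatalog],
    groups: Mapping[str, Sequence[str]] | None = None,
) -> dict[frozenset[str], set[str]]:
    """Venn partition of families across species groups.

    A family belongs to the cell ``frozenset({g1, g2, ...})`` when it is
    present in ALL species of exactly those groups (and in no other group
    completely). With ``groups=None`` every species is its own group.
    Families present somewhere but not in all species of any group fall in
    the empty-frozenset cell, so the partition is exhaustive: cell sizes
    sum to the size of the union of all families.
    """
    seen: set[str] = set()
    by_species: dict[str, set[str]] = {}
    for cat in catalogs:
        if cat.species in by_species:
            raise ValueError(f"duplicate species {cat.species!r}")
        by_species[cat.species] = set(cat.families)
        seen |= cat.families
    if groups is None:
        groups = {sp: [sp] for sp in by_species}
    for gname, members in groups.items():
        for sp in members:
            if sp not in by_species:
                raise ValueError(f"group {gname!r} references unknown species {sp!r}")

    partition: dict[frozenset[str], set[str]] = {}
    for family in seen:
        profile = frozenset(
            g
            for g, members in groups.items()
            if all(family in by_species[sp] for sp in members)
        )
        partition.setdefault(profile, set()).add(family)
    return partition


def family_sets_bruteforce(
    catalogs: Sequence[FamilyCatalog],
    groups: Mapping[str, Sequence[str]] | None = None,
) -> dict[frozenset[str], set[str]]:
    """Oracle: test every family against every subset of groups explicitly."""
    by_species = {c.species: set(c.families) for c in catalogs}
    if groups is None:
        groups = {sp: [sp] for sp in by_species}
    gnames = sorted(groups)
    all_families = set().union(*(c.families for c in catalogs))
    partition: dict[frozenset[str], set[str]] = {}
    for r in range(len(gnames) + 1):
        for subset in combinations(gnames, r):
            cell = frozenset(subset)
            for family in all_families:
                in_all = {
                    g for g in gnames
                    if all(family in by_species[sp] for sp in groups[g])
                }
                if in_all == set(subset):
                    partition.setdefault(cell, set()).add(family)
    return {k: v for k, v in partition.items() if v}
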
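"""Overlap and overrepresentation statistics for gene lists.

* :func:`fisher_overlap` — one-tailed (enrichment) Fisher's exact test on
  the overlap of two gene sets in a common universe, i.e. the upper tail of
  the hypergeometric distribution.
* :func:`topk_overlap_sweep` — the same test on the top-k prefixes of two
  p-value-ranked gene lists across a grid of k (default 100, 200, ..., 5000),
  used to compare DRA rankings between sample strata such as the sexes or
  young/old halves of a panel.
* :func:`recurrence_table` — how many drugs each gene is DRA for.
* :func:`gene_set_enrichment` — hypergeometric overrepresentation of a query
  list in a gene-set collection with BH adjustment, flagged at 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .io import GeneSetCollection
from .regression import adjust_bh

__all__ = ["fisher_overlap", "OverlapSweep", "topk_overlap_sweep",
           "recurrence_table", "gene_set_enrichment", "default_ks"]


def default_ks(lo: int = 100, hi: int = 5000, step: int = 100) -> list[int]:
    """The top-k grid 100, 200, ..., 5000."""
    return list(range(lo, hi + 1, step))


def fisher_overlap(set_a: Iterable[str], set_b: Iterable[str],
                   universe_size: int) -> float:
    """One-tailed enrichment p-value for the overlap of two sets.

    P(X >= |A ∩ B|) with X ~ Hypergeometric(N = universe, K = |A|, n = |B|).
    """
    a, b = set(set_a), set(set_b)
    if len(a | b) > universe_size:
        raise InputError(
            f"universe size {universe_size} smaller than |A ∪ B| = {len(a | b)}"
        )
    overlap = len(a & b)
    return float(stats.hypergeom.sf(overlap - 1, universe_size, len(a), len(b)))


@dataclass
class OverlapSweep:
    """Per-k overlap sizes and Fisher p-values for two ranked gene lists."""

    table: pd.DataFrame          # columns k, overlap, p_value, significant
    universe_size: int
    ranking_a: list[str]
    ranking_b: list[str]
    significance_level: float = 0.05

    def summary(self) -> str:
        sig = self.table[self.table["significant"]]
        first = int(sig["k"].min()) if len(sig) else None
        return (
            f"top-k overlap sweep over {len(self.table)} k values, "
            f"universe {self.universe_size}; "
            + (f"significant from k = {first}" if first is not None
               else "no significant k")
        )


def _check_ranking(rank: Sequence[str], name: str) -> list[str]:
    rank = list(rank)
    if len(set(rank)) != len(rank):
        raise InputError(f"ranking {name} contains duplicated genes")
    return rank


def topk_overlap_sweep(ranking_a: Sequence[str], ranking_b: Sequence[str],
                       universe_size: int, ks: Sequence[int] | None = None,
                       significance_level: float = 0.05) -> OverlapSweep:
    """Fisher enrichment of shared genes in the top-k prefixes of two rankings.

    Rankings are p-value-sorted gene lists over the same universe (for a
    sex-stratified analysis, the genes tested in both strata).  A k is
    flagged significant at p <= ``significance_level``.
    """
    a = _check_ranking(ranking_a, "A")
    b = _check_ranking(ranking_b, "B")
    if ks is None:
        ks = [k for k in default_ks() if k <= min(len(a), len(b))]
    ks = list(ks)
    if ks and max(ks) > min(len(a), len(b)):
        raise InputError("max k exceeds the shorter ranking length")
    rows = []
    for k in ks:
        top_a, top_b = set(a[:k]), set(b[:k])
        p = fisher_overlap(top_a, top_b, universe_size)
        rows.append({"k": k, "overlap": len(top_a & top_b), "p_value": p,
                     "significant": p <= significance_level})
    return OverlapSweep(table=pd.DataFrame(rows), universe_size=universe_size,
                        ranking_a=a, ranking_b=b,
                        significance_level=significance_level)


def recurrence_table(per_drug_dra_sets: Mapping[str, Iterable[str]]) -> pd.Series:
    """Count, for each gene, the number of drugs it is DRA for.

    Returns a Series indexed by gene, sorted by descending count (ties by
    gene id so the order is deterministic).
    """
    if not per_drug_dra_sets:
        raise InputError("need at least one drug's DRA set")
    counts: dict[str, int] = {}
    for genes in per_drug_dra_sets.values():
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    ser = pd.Series(counts, name="n_drugs", dtype=int)
    return ser.sort_index().sort_values(ascending=False, kind="stable")


def gene_set_enrichment(query_genes: Iterable[str], collection: GeneSetCollection,
                        universe: Iterable[str],
                        significance_level: float = 0.05) -> pd.DataFrame:
    """Hypergeometric overrepresentation of a query list in each gene set.

    Sets are intersected with the universe first; the query must be a subset
    of the universe.  BH adjustment is applied across sets and the
    ``significant`` flag set at adjusted p <= ``significance_level``.
    """
    uni = set(map(str, universe))
    query = set(map(str, query_genes))
    if not query:
        raise InputError("empty query gene list")
    if not query <= uni:
        raise InputError("query genes must be a subset of the universe")
    n_uni = len(uni)
    rows = []
    for name, members in collection.items():
        inset = members & uni
        overlap = len(inset & query)
        p = float(stats.hypergeom.sf(overlap - 1, n_uni, len(inset), len(query)))
        rows.append({"set": name, "overlap": overlap, "set_size": len(inset),
                     "universe_size": n_uni, "p_value": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = adjust_bh(table["p_value"].to_numpy())
        table["significant"] = table["fdr"] <= significance_level
        table = table.sort_values(["p_value", "set"]).reset_index(drop=True)
    return table
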
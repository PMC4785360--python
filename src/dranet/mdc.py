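"""Modular differential connectivity (MDC) between resistant and sensitive groups.

For a gene-set module M and a sample group g, the connectivity of a gene
pair is |Pearson correlation| of their expression within the group (raised
to a configurable soft-threshold power, default 1), and the module
connectivity is the mean over all unordered pairs.  MDC is the ratio

    MDC(M) = connectivity(M; resistant) / connectivity(M; sensitive)

— a positive, scale-free measure: > 1 means the module gains co-expression
when moving from the sensitive to the resistant state, < 1 means it loses.

Significance comes from a label permutation: samples are reshuffled between
the two groups (group sizes preserved) and the one-sided exceedance rate in
the observed direction is reported as the module FDR (default 50
permutations, so the smallest nonzero FDR is 0.02).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import RESISTANT, SENSITIVE, ResponseClasses
from .exceptions import ConfigError, DegenerateInputError, InputError
from .io import GeneSetCollection

__all__ = ["filter_modules", "module_connectivity", "compute_mdc", "mdc_fdr",
           "ModuleResult", "MDCAnalysis", "MDCResults",
           "rank_modules_across_drugs"]

GAIN = "gain"
LOSS = "loss"
NEUTRAL = "neutral"

#: modules smaller than this after intersection with measured genes are dropped
DEFAULT_MIN_MODULE_SIZE = 30


def filter_modules(collection: GeneSetCollection, measured_genes: Iterable[str],
                   min_size: int = DEFAULT_MIN_MODULE_SIZE) -> GeneSetCollection:
    """Intersect each module with the measured genes; drop those below min_size."""
    return collection.restricted(measured_genes, min_size=min_size)


def _usable_submatrix(expr_group: pd.DataFrame, module_genes: Iterable[str]):
    genes = [g for g in module_genes if g in expr_group.index]
    sub = expr_group.loc[genes].to_numpy(dtype=float)
    variances = sub.var(axis=1)
    usable = variances > 0
    if usable.sum() < len(genes):
        import warnings
        dropped = [g for g, u in zip(genes, usable) if not u]
        warnings.warn(f"excluding zero-variance genes from connectivity: {dropped[:5]}")
    return sub[usable]


def module_connectivity(expr_group: pd.DataFrame, module_genes: Iterable[str],
                        power: float = 1.0) -> float:
    """Mean |Pearson r|^power over all unordered gene pairs within a group.

    ``expr_group`` is genes × samples restricted to one sample group.
    Zero-variance genes are excluded with a warning; fewer than two usable
    genes or fewer than three samples is an error.
    """
    if expr_group.shape[1] < 3:
        raise DegenerateInputError("need >= 3 samples in the group")
    sub = _usable_submatrix(expr_group, module_genes)
    m = sub.shape[0]
    if m < 2:
        raise DegenerateInputError("need >= 2 module genes with nonzero variance")
    corr = np.corrcoef(sub)
    iu = np.triu_indices(m, k=1)
    return float(np.mean(np.abs(corr[iu]) ** power))


def _group_columns(classes: ResponseClasses, expr: pd.DataFrame):
    res = [s for s in classes.members(RESISTANT) if s in expr.columns]
    sen = [s for s in classes.members(SENSITIVE) if s in expr.columns]
    if len(res) < 3 or len(sen) < 3:
        raise DegenerateInputError(
            f"need >= 3 samples per group (resistant {len(res)}, sensitive {len(sen)})"
        )
    return res, sen


def compute_mdc(expr: pd.DataFrame, classes: ResponseClasses,
                module_genes: Iterable[str], power: float = 1.0) -> float:
    """MDC ratio for one module; indeterminate samples are excluded.

    Returns ``inf`` when the sensitive-group connectivity is exactly zero.
    """
    res, sen = _group_columns(classes, expr)
    module_genes = list(module_genes)
    c_res = module_connectivity(expr[res], module_genes, power=power)
    c_sen = module_connectivity(expr[sen], module_genes, power=power)
    if c_sen == 0.0:
        return float("inf")
    return c_res / c_sen


@dataclass
class ModuleResult:
    """MDC of one module with its one-sided permutation FDR."""

    module: str
    n_genes: int
    mdc: float
    fdr: float
    direction: str  # gain / loss / neutral

    @staticmethod
    def classify(mdc: float) -> str:
        if mdc > 1:
            return GAIN
        if mdc < 1:
            return LOSS
        return NEUTRAL


def _mdc_from_matrix(sub: np.ndarray, res_idx, sen_idx, power: float) -> float:
    def conn(cols):
        corr = np.corrcoef(sub[:, cols])
        iu = np.triu_indices(sub.shape[0], k=1)
        return float(np.mean(np.abs(corr[iu]) ** power))

    c_sen = conn(sen_idx)
    c_res = conn(res_idx)
    return float("inf") if c_sen == 0 else c_res / c_sen


def mdc_fdr(expr: pd.DataFrame, classes: ResponseClasses,
            module_genes: Iterable[str], n_perm: int = 50,
            seed: int | None = None, power: float = 1.0,
            module_name: str = "") -> ModuleResult:
    """Permutation FDR for one module's MDC.

    Labels are permuted across the union of resistant + sensitive samples
    with group sizes preserved.  One-sided counting in the observed
    direction: for observed MDC > 1 the FDR is the fraction of permutations
    with a larger MDC; for MDC < 1, with a smaller one.  An observed MDC of
    exactly 1 is reported neutral with FDR 1.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    res, sen = _group_columns(classes, expr)
    genes = [g for g in module_genes if g in expr.index]
    pool = res + sen
    sub_all = expr.loc[genes, pool].to_numpy(dtype=float)
    keep = sub_all.var(axis=1) > 0
    sub_all = sub_all[keep]
    if sub_all.shape[0] < 2:
        raise DegenerateInputError("need >= 2 module genes with nonzero variance")
    n_res = len(res)
    res_idx = np.arange(n_res)
    sen_idx = np.arange(n_res, len(pool))
    observed = _mdc_from_matrix(sub_all, res_idx, sen_idx, power)
    direction = ModuleResult.classify(observed)
    if direction == NEUTRAL:
        return ModuleResult(module=module_name, n_genes=int(sub_all.shape[0]),
                            mdc=observed, fdr=1.0, direction=NEUTRAL)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pool))
        val = _mdc_from_matrix(sub_all, perm[:n_res], perm[n_res:], power)
        if direction == GAIN and val > observed:
            exceed += 1
        elif direction == LOSS and val < observed:
            exceed += 1
    return ModuleResult(module=module_name, n_genes=int(sub_all.shape[0]),
                        mdc=observed, fdr=exceed / n_perm, direction=direction)


class MDCAnalysis:
    """MDC over a filtered module collection for one drug's response classes.

    Parameters
    ----------
    expr : DataFrame
        Genes × samples expression.
    classes : ResponseClasses
        Sensitive/indeterminate/resistant partition (see
        :func:`dranet.cluster.trichotomize`); indeterminate samples are
        excluded.
    collection : GeneSetCollection
        Candidate modules; filtered against the measured genes at
        ``min_size`` before analysis.
    """

    def __init__(self, expr: pd.DataFrame, classes: ResponseClasses,
                 collection: GeneSetCollection,
                 min_size: int = DEFAULT_MIN_MODULE_SIZE,
                 n_perm: int = 50, power: float = 1.0,
                 seed: int | None = None):
        self.expr = expr
        self.classes = classes
        self.collection = filter_modules(collection, expr.index, min_size)
        self.min_size = min_size
        self.n_perm = n_perm
        self.power = power
        self.seed = seed

    def fit(self) -> "MDCResults":
        rng = np.random.default_rng(self.seed)
        results = []
        for name in sorted(self.collection):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            results.append(
                mdc_fdr(self.expr, self.classes, self.collection[name],
                        n_perm=self.n_perm, seed=sub_seed, power=self.power,
                        module_name=name)
            )
        table = pd.DataFrame(
            [{"module": r.module, "n_genes": r.n_genes, "mdc": r.mdc,
              "fdr": r.fdr, "direction": r.direction} for r in results]
        )
        return MDCResults(self, table)


@dataclass
class MDCResults:
    """Per-module MDC table for one drug."""

    model: MDCAnalysis
    table: pd.DataFrame

    def significant(self, fdr_level: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["fdr"] <= fdr_level]

    def ranked(self, fdr_level: float = 0.05) -> pd.DataFrame:
        """Modules ordered for reporting: significant first by |log MDC| desc.

        Within the significant block (FDR <= ``fdr_level``) modules sort by
        descending |log MDC| (most extreme gain or loss first); the rest
        follow, by ascending FDR then |log MDC|.  A ``rank`` column (1-based)
        is appended.
        """
        t = self.table.copy()
        with np.errstate(divide="ignore"):
            t["abs_log_mdc"] = np.abs(np.log(t["mdc"].replace(0, np.nan)))
        t["abs_log_mdc"] = t["abs_log_mdc"].fillna(np.inf)
        sig = t["fdr"] <= fdr_level
        t["_block"] = np.where(sig, 0, 1)
        t = t.sort_values(["_block", "fdr", "abs_log_mdc", "module"],
                          ascending=[True, True, False, True], kind="stable")
        t = t.drop(columns="_block").reset_index(drop=True)
        t["rank"] = np.arange(1, len(t) + 1)
        return t

    def summary(self) -> str:
        sig = self.significant()
        lines = [
            "Modular differential connectivity",
            "=================================",
            f"modules analysed:   {len(self.table)}",
            f"permutations:       {self.model.n_perm}",
            f"significant (FDR <= 0.05): {len(sig)} "
            f"({int((sig['direction'] == GAIN).sum())} gain / "
            f"{int((sig['direction'] == LOSS).sum())} loss)",
        ]
        return "\n".join(lines)


def rank_modules_across_drugs(per_drug: Mapping[str, MDCResults | pd.DataFrame],
                              fdr_level: float = 0.05) -> pd.DataFrame:
    """Aggregate per-drug module rankings by ascending rank sum.

    Each drug's modules are ranked with :meth:`MDCResults.ranked`; the final
    order is by the sum of ranks across drugs (smaller = more consistently
    extreme differential connectivity).  All drugs must share the same
    filtered module collection.
    """
    if not per_drug:
        raise InputError("need at least one drug's MDC results")
    ranks = {}
    module_sets = []
    for drug, res in per_drug.items():
        if isinstance(res, MDCResults):
            t = res.ranked(fdr_level)
        else:
            t = res
            if "rank" not in t.columns:
                raise InputError("pre-ranked table must carry a 'rank' column")
        ranks[drug] = t.set_index("module")["rank"]
        module_sets.append(set(t["module"]))
    if any(s != module_sets[0] for s in module_sets[1:]):
        raise InputError("all drugs must use the same filtered module collection")
    rank_df = pd.DataFrame(ranks)
    out = pd.DataFrame({"rank_sum": rank_df.sum(axis=1)})
    out = pd.concat([out, rank_df.add_prefix("rank_")], axis=1)
    out = out.reset_index(names="module")
    return out.sort_values(["rank_sum", "module"], kind="stable").reset_index(drop=True)
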
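"""Key-driver analysis (KDA) of a gene module on a protein-interaction network.

Given a module gene set A mapped into an undirected PPI network, the
analysis subnetwork is the induced subgraph on A plus everything within
shortest-path distance 2 of A.  For every candidate gene in that subnetwork,
B is its own <= 2-hop neighborhood (the seed excluded) and the enrichment of
module genes in B is scored with the hypergeometric upper tail

    p = P(X >= |A ∩ B|),  X ~ Hypergeometric(N = |subnetwork|, K = |A|, n = |B|)

An empirical FDR is attached by resampling |A| genes uniformly from the
subnetwork node set and recording how often a random module does at least as
well; candidates with FDR below the threshold (default 0.05) are flagged key
drivers — the hub genes whose neighborhoods concentrate the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, InputError

__all__ = ["neighborhood", "kda_score", "kda_fdr", "extract_subnetwork",
           "KeyDriverAnalysis", "KDAResults", "KeyDriverResult"]


def neighborhood(network: nx.Graph, gene: str, h: int = 2) -> set[str]:
    """Nodes at shortest-path distance <= h from ``gene``, seed excluded.

    ``h = 0`` returns the empty set.
    """
    if gene not in network:
        raise InputError(f"gene {gene!r} not in network")
    if h <= 0:
        return set()
    dist = nx.single_source_shortest_path_length(network, gene, cutoff=h)
    dist.pop(gene, None)
    return set(dist)


def extract_subnetwork(network: nx.Graph, module_genes_a: Iterable[str],
                       h: int = 2) -> tuple[nx.Graph, pd.DataFrame]:
    """Induced subgraph on A ∪ (<= h-hop neighbors of A), plus node annotations.

    The annotation table has one row per node with an ``in_module`` flag;
    :meth:`KDAResults.export_subnetwork` adds the key-driver flag after
    scoring.  ``h = 0`` gives the induced subgraph on A ∩ network alone.
    """
    mapped = {g for g in module_genes_a if g in network}
    if not mapped:
        raise InputError("no module genes map into the network")
    nodes = set(mapped)
    for g in mapped:
        nodes |= neighborhood(network, g, h)
    sub = network.subgraph(nodes).copy()
    annotations = pd.DataFrame(
        {"node": sorted(nodes),
         "in_module": [n in mapped for n in sorted(nodes)]}
    )
    return sub, annotations


class KeyDriverAnalysis:
    """Hypergeometric key-driver scan of a module over a PPI network.

    Parameters
    ----------
    network : networkx.Graph
        Undirected PPI network (edges already confidence-thresholded).
    module_genes : iterable of str
        Module gene set A; only the part mapping into the network is used.
    hops : int
        Neighborhood radius (default 2).
    n_perm : int
        Random-module resamples for the empirical FDR (default 1000).
    threshold : float
        FDR below which a candidate is flagged key driver (default 0.05).
    universe : {"subnetwork", "network"}
        Whether N in the hypergeometric test is the analysis subnetwork
        (default) or the whole network.
    include_self : bool
        Count the seed inside its own neighborhood (default False).
    """

    def __init__(self, network: nx.Graph, module_genes: Iterable[str],
                 hops: int = 2, n_perm: int = 1000, threshold: float = 0.05,
                 seed: int | None = None, universe: str = "subnetwork",
                 include_self: bool = False):
        if n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if universe not in ("subnetwork", "network"):
            raise ConfigError(f"unknown universe {universe!r}")
        self.network = network
        self.module_genes = set(module_genes)
        self.hops = hops
        self.n_perm = n_perm
        self.threshold = threshold
        self.seed = seed
        self.universe = universe
        self.include_self = include_self
        self.subnetwork, self.node_annotations = extract_subnetwork(
            network, self.module_genes, h=hops)
        self.mapped_module = {g for g in self.module_genes if g in network}

    def _neighborhoods(self):
        nodes = sorted(self.subnetwork.nodes)
        index = {n: i for i, n in enumerate(nodes)}
        mat = np.zeros((len(nodes), len(nodes)), dtype=bool)
        for i, n in enumerate(nodes):
            hood = neighborhood(self.subnetwork, n, self.hops)
            if self.include_self:
                hood.add(n)
            for m in hood:
                mat[i, index[m]] = True
        return nodes, index, mat

    def fit(self) -> "KDAResults":
        nodes, index, hoods = self._neighborhoods()
        n_universe = (self.subnetwork.number_of_nodes()
                      if self.universe == "subnetwork"
                      else self.network.number_of_nodes())
        a_vec = np.zeros(len(nodes), dtype=bool)
        for g in self.mapped_module:
            a_vec[index[g]] = True
        k_module = int(a_vec.sum())
        hoods_int = hoods.astype(np.int64)
        hood_sizes = hoods_int.sum(axis=1)
        overlaps = hoods_int @ a_vec.astype(np.int64)
        p = stats.hypergeom.sf(overlaps - 1, n_universe, k_module, hood_sizes)

        # Random-module null: resample |A| nodes from the subnetwork; because
        # p is monotone decreasing in the overlap at fixed (N, K, n), counting
        # null p <= observed p equals counting null overlap >= observed.
        rng = np.random.default_rng(self.seed)
        exceed = np.zeros(len(nodes), dtype=int)
        for _ in range(self.n_perm):
            pick = rng.choice(len(nodes), size=k_module, replace=False)
            null_vec = np.zeros(len(nodes), dtype=bool)
            null_vec[pick] = True
            null_overlaps = hoods_int @ null_vec.astype(np.int64)
            exceed += null_overlaps >= overlaps
        fdr = exceed / self.n_perm
        table = pd.DataFrame(
            {
                "gene": nodes,
                "neighborhood_size": hood_sizes.astype(int),
                "overlap": overlaps.astype(int),
                "p_value": p,
                "fdr": fdr,
                "key_driver": fdr < self.threshold,
                "in_module": a_vec,
            }
        ).set_index("gene", drop=False)
        table.index.name = None
        table = table.sort_values(["fdr", "p_value", "gene"], kind="stable")
        return KDAResults(self, table)


@dataclass
class KeyDriverResult:
    """One candidate's neighborhood enrichment scores."""

    gene: str
    neighborhood_size: int
    overlap: int
    p_value: float
    fdr: float
    key_driver: bool


@dataclass
class KDAResults:
    """Per-candidate key-driver table plus subnetwork export."""

    model: KeyDriverAnalysis
    table: pd.DataFrame

    @property
    def key_drivers(self) -> list[str]:
        return self.table.index[self.table["key_driver"]].tolist()

    def summary(self) -> str:
        lines = [
            "Key driver analysis",
            "===================",
            f"module genes mapped:   {len(self.model.mapped_module)}",
            f"subnetwork size:       {self.model.subnetwork.number_of_nodes()}",
            f"candidates scored:     {len(self.table)}",
            f"permutations:          {self.model.n_perm}",
            f"key drivers (FDR < {self.model.threshold}): {len(self.key_drivers)}",
        ]
        if self.key_drivers:
            lines.append("top drivers:           " + ", ".join(self.key_drivers[:10]))
        return "\n".join(lines)

    def export_subnetwork(self) -> tuple[nx.Graph, pd.DataFrame]:
        """Subnetwork plus node attributes (in-module and key-driver flags).

        The attribute table mirrors the usual network-viewer encoding:
        module membership decides node shape, key-driver status the color.
        """
        annotations = self.model.node_annotations.copy()
        kd = set(self.key_drivers)
        annotations["key_driver"] = annotations["node"].isin(kd)
        return self.model.subnetwork, annotations


def kda_score(network: nx.Graph, module_genes_a: Iterable[str], hops: int = 2,
              universe: str = "subnetwork", include_self: bool = False) -> pd.Series:
    """Per-candidate hypergeometric enrichment p-values (no permutation FDR)."""
    model = KeyDriverAnalysis(network, module_genes_a, hops=hops, n_perm=1,
                              universe=universe, include_self=include_self)
    nodes, index, hoods = model._neighborhoods()
    n_universe = (model.subnetwork.number_of_nodes()
                  if universe == "subnetwork" else network.number_of_nodes())
    a_vec = np.zeros(len(nodes), dtype=bool)
    for g in model.mapped_module:
        a_vec[index[g]] = True
    hoods_int = hoods.astype(np.int64)
    overlaps = hoods_int @ a_vec.astype(np.int64)
    p = stats.hypergeom.sf(overlaps - 1, n_universe, int(a_vec.sum()),
                           hoods_int.sum(axis=1))
    return pd.Series(p, index=pd.Index(nodes, name="gene"), name="p_value")


def kda_fdr(network: nx.Graph, module_genes_a: Iterable[str], n_perm: int = 1000,
            seed: int | None = None, threshold: float = 0.05,
            hops: int = 2, **kwargs) -> KDAResults:
    """Full key-driver scan with permutation FDR; wrapper over the model class."""
    return KeyDriverAnalysis(network, module_genes_a, hops=hops, n_perm=n_perm,
                             threshold=threshold, seed=seed, **kwargs).fit()
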
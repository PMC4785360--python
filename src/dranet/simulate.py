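"""Synthetic cell-line panels with planted structure for every pipeline stage.

The generator is the inverse of the analysis models:

* :func:`simulate_panel` draws expression from the same linear model the
  per-gene scan fits — intercept + gamma·sensitivity for planted DRA genes +
  sex/age/batch/cancer/tissue/genotype-PC covariate terms + Gaussian noise —
  with activity-area sensitivity on [0, 7.8] from a right-skewed beta.
* :func:`simulate_differential_modules` draws module genes from an
  equicorrelated Gaussian whose pairwise correlation differs between the
  sensitive and resistant sample groups, the structure modular differential
  connectivity is designed to detect.
* :func:`simulate_network` builds a preferential-attachment network with
  planted hub genes wired into a module, the structure key-driver analysis
  is designed to recover.

Every function takes a seed and is bit-reproducible: internally a master
``numpy.random.SeedSequence`` is spawned into one child stream per
generation stage (covariates, coefficients, noise, ...), so adding genes
does not perturb the covariate draw and vice versa.

Ground truth (which genes/modules/hubs were planted, with what effect) is
returned in :class:`PanelTruth` for recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cluster import INDETERMINATE, RESISTANT, SENSITIVE, ResponseClasses
from .exceptions import ConfigError
from .io import GeneSetCollection, sensitivity_column

__all__ = ["SimulationConfig", "ModuleSpec", "PanelTruth", "simulate_panel",
           "simulate_differential_modules", "simulate_network",
           "effect_size_for_partial_correlation", "labels_to_classes"]

#: activity-area range observed across the drug panel
SENSITIVITY_RANGE = (0.0, 7.8)


@dataclass
class PanelTruth:
    """Ground truth of planted structure, for recovery tests.

    ``dra_genes`` maps gene id → (gamma, sign); ``module_truth`` maps module
    name → (rho_sensitive, rho_resistant); ``hub_truth`` lists planted hub
    genes and ``hub_modules`` maps each hub to the module it was wired into;
    ``below_filter`` lists modules emitted below the analysis size filter.
    """

    dra_genes: dict[str, tuple[float, str]] = field(default_factory=dict)
    module_truth: dict[str, tuple[float, float]] = field(default_factory=dict)
    hub_truth: list[str] = field(default_factory=list)
    hub_modules: dict[str, str] = field(default_factory=dict)
    below_filter: list[str] = field(default_factory=list)

    def dra_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"gene": g, "gamma": gm, "sign": s}
             for g, (gm, s) in self.dra_genes.items()]
        )


def effect_size_for_partial_correlation(r: float, sensitivity_sd: float,
                                        noise_sd: float) -> float:
    """Sensitivity coefficient giving partial correlation ``r`` after adjustment.

    With covariates regressed out, corr(y, s) = gamma·sd(s) /
    sqrt(gamma²·sd(s)² + sd(eps)²); inverting gives
    gamma = r / sqrt(1 − r²) · sd(eps) / sd(s).
    """
    if not 0 < abs(r) < 1:
        raise ConfigError("target correlation must be in (0, 1)")
    return r / math.sqrt(1.0 - r * r) * noise_sd / sensitivity_sd


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cell-line panel.

    Defaults mirror the study panel: 323 cell lines, 20,069 genes, 7 cancer
    types, 17 tissue types, activity areas on [0, 7.8] with a right-skewed
    distribution, donor ages centred on 53 years.  Tests pass smaller
    ``n_genes``/``n_samples`` explicitly.  Planted DRA genes get a
    sensitivity coefficient sized to reach ``target_abs_corr`` partial
    correlation (unless ``effect_size`` is set directly), with random sign.
    """

    n_samples: int = 323
    n_genes: int = 20069
    n_dra: int = 400
    effect_size: float | None = None
    target_abs_corr: float = 0.4
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    age_scale: float = 0.01       # expression units per year
    sex_scale: float = 0.3
    batch_scale: float = 0.3
    cancer_scale: float = 0.3
    tissue_scale: float = 0.3
    genotype_scale: float = 0.2
    n_batches: int = 4
    n_cancers: int = 7
    n_tissues: int = 17
    sensitivity_bounds: tuple[float, float] = SENSITIVITY_RANGE
    sensitivity_beta: tuple[float, float] = (2.0, 5.0)
    drug: str = "drugA"
    seed: int = 0

    def __post_init__(self):
        for name in ("n_samples", "n_genes", "n_batches", "n_cancers", "n_tissues"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.n_dra < 0 or self.n_dra > self.n_genes:
            raise ConfigError("need 0 <= n_dra <= n_genes")
        lo, hi = self.sensitivity_bounds
        if not lo < hi:
            raise ConfigError("sensitivity bounds must be ordered")

    @property
    def sensitivity_sd(self) -> float:
        a, b = self.sensitivity_beta
        lo, hi = self.sensitivity_bounds
        return (hi - lo) * math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))

    def resolved_effect_size(self) -> float:
        if self.effect_size is not None:
            return self.effect_size
        return effect_size_for_partial_correlation(
            self.target_abs_corr, self.sensitivity_sd, self.noise_sd)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _sample_ids(n: int) -> list[str]:
    return [f"CL{i:04d}" for i in range(1, n + 1)]


def simulate_panel(config: SimulationConfig):
    """Generate (expression, sample table, truth) for one synthetic drug panel.

    Expression follows the additive linear model exactly; the returned truth
    lists the planted DRA genes with their coefficients and signs.
    Deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_cov, rng_coef, rng_noise, rng_plant = (
        np.random.default_rng(s) for s in ss.spawn(4))

    n, g = config.n_samples, config.n_genes
    samples = _sample_ids(n)
    genes = _gene_ids(g)

    # --- covariates ------------------------------------------------------
    sex = np.where(rng_cov.random(n) < 0.5, "female", "male")
    age = stats.truncnorm.rvs((18 - 53) / 10, np.inf, loc=53, scale=10,
                              size=n, random_state=rng_cov)
    batch = rng_cov.integers(0, config.n_batches, n)
    cancer = rng_cov.integers(0, config.n_cancers, n)
    tissue = rng_cov.integers(0, config.n_tissues, n)
    pcs = rng_cov.standard_normal((n, 3))
    a, b = config.sensitivity_beta
    lo, hi = config.sensitivity_bounds
    sens = lo + (hi - lo) * rng_cov.beta(a, b, n)

    # --- per-gene coefficients ------------------------------------------
    beta0 = rng_coef.normal(config.baseline_mean, config.baseline_sd, g)
    lam = rng_coef.normal(0, config.age_scale, g)
    mu = rng_coef.normal(0, config.sex_scale, g)
    theta = rng_coef.normal(0, config.batch_scale, (config.n_batches, g))
    kappa = rng_coef.normal(0, config.cancer_scale, (config.n_cancers, g))
    phi = rng_coef.normal(0, config.tissue_scale, (config.n_tissues, g))
    delta = rng_coef.normal(0, config.genotype_scale, (3, g))

    gamma = np.zeros(g)
    truth = PanelTruth()
    if config.n_dra:
        planted = rng_plant.choice(g, size=config.n_dra, replace=False)
        signs = rng_plant.choice([-1.0, 1.0], size=config.n_dra)
        gamma[planted] = signs * config.resolved_effect_size()
        for idx, s in zip(planted, signs):
            truth.dra_genes[genes[idx]] = (float(gamma[idx]),
                                           "positive" if s > 0 else "negative")

    # --- assemble Y (genes × samples) -----------------------------------
    Y = (
        beta0[:, None]
        + gamma[:, None] * sens[None, :]
        + lam[:, None] * age[None, :]
        + mu[:, None] * (sex == "male")[None, :]
        + theta[batch].T
        + kappa[cancer].T
        + phi[tissue].T
        + delta.T @ pcs.T
        + rng_noise.normal(0, config.noise_sd, (g, n))
    )
    expr = pd.DataFrame(Y, index=genes, columns=samples)
    table = pd.DataFrame(
        {
            "sample": samples,
            "age": age,
            "sex": sex,
            "batch": [f"b{i}" for i in batch],
            "cancer": [f"c{i}" for i in cancer],
            "tissue": [f"t{i}" for i in tissue],
            "pc1": pcs[:, 0],
            "pc2": pcs[:, 1],
            "pc3": pcs[:, 2],
            sensitivity_column(config.drug): sens,
        }
    ).set_index("sample", drop=False)
    return expr, table, truth


# ---------------------------------------------------------------------------
# differentially connected modules
# ---------------------------------------------------------------------------

@dataclass
class ModuleSpec:
    """One planted module: size and within-module correlation per group."""

    name: str
    size: int
    rho_sensitive: float
    rho_resistant: float

    def validate(self) -> None:
        if self.size < 2:
            raise ConfigError(f"module {self.name}: size must be >= 2")
        low = -1.0 / (self.size - 1)
        for rho in (self.rho_sensitive, self.rho_resistant):
            if not low < rho < 1.0:
                raise ConfigError(
                    f"module {self.name}: rho={rho} outside ({low:.4f}, 1) — "
                    "equicorrelation matrix not positive definite"
                )


def labels_to_classes(labels: pd.Series) -> ResponseClasses:
    """Wrap externally supplied group labels as a ResponseClasses object.

    The mean/SD bookkeeping fields are NaN because no trichotomy was run.
    """
    return ResponseClasses(classes=labels, mean=float("nan"),
                           sd=float("nan"), k=float("nan"))


def _equicorrelated(rng, m: int, rho: float, n: int) -> np.ndarray:
    """m genes × n samples from N(0, (1-rho)I + rho·J)."""
    cov = np.full((m, m), rho)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal((m, n))


def simulate_differential_modules(
    module_specs: Sequence[ModuleSpec],
    n_sensitive: int = 100,
    n_resistant: int = 100,
    classes: ResponseClasses | None = None,
    background_genes: int = 0,
    min_size: int = 30,
    seed: int = 0,
):
    """Generate module expression with group-specific correlation.

    Within each module, expression is equicorrelated Gaussian with
    correlation ``rho_sensitive`` among sensitive samples and
    ``rho_resistant`` among resistant ones; background genes are
    independent N(0, 1).  Group labels come from ``classes`` when given
    (its indeterminate samples receive independent noise), otherwise
    ``n_sensitive``/``n_resistant`` fresh samples are created.

    Returns ``(expr, classes, collection, truth)``; modules below
    ``min_size`` are emitted but listed in ``truth.below_filter``.
    """
    for spec in module_specs:
        spec.validate()
    names = [s.name for s in module_specs]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate module names")

    if classes is None:
        sample_ids = ([f"SEN{i:04d}" for i in range(1, n_sensitive + 1)]
                      + [f"RES{i:04d}" for i in range(1, n_resistant + 1)])
        labels = pd.Series([SENSITIVE] * n_sensitive + [RESISTANT] * n_resistant,
                           index=sample_ids, name="response_class")
        classes = labels_to_classes(labels)
    sample_ids = list(classes.classes.index)
    groups = {
        SENSITIVE: [s for s in sample_ids if classes.classes[s] == SENSITIVE],
        RESISTANT: [s for s in sample_ids if classes.classes[s] == RESISTANT],
        INDETERMINATE: [s for s in sample_ids
                        if classes.classes[s] == INDETERMINATE],
    }

    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(module_specs) + 1)
    col_index = {s: i for i, s in enumerate(sample_ids)}

    blocks = []
    gene_names = []
    coll = GeneSetCollection()
    truth = PanelTruth()
    for spec, child in zip(module_specs, streams[:-1]):
        rng = np.random.default_rng(child)
        mgenes = [f"{spec.name}_g{i:03d}" for i in range(1, spec.size + 1)]
        block = np.empty((spec.size, len(sample_ids)))
        for label, rho in ((SENSITIVE, spec.rho_sensitive),
                           (RESISTANT, spec.rho_resistant)):
            cols = [col_index[s] for s in groups[label]]
            if cols:
                block[:, cols] = _equicorrelated(rng, spec.size, rho, len(cols))
        cols = [col_index[s] for s in groups[INDETERMINATE]]
        if cols:
            block[:, cols] = rng.standard_normal((spec.size, len(cols)))
        blocks.append(block)
        gene_names.extend(mgenes)
        coll.add(spec.name, mgenes, f"planted module size {spec.size}")
        truth.module_truth[spec.name] = (spec.rho_sensitive, spec.rho_resistant)
        if spec.size < min_size:
            truth.below_filter.append(spec.name)

    rng_bg = np.random.default_rng(streams[-1])
    if background_genes:
        blocks.append(rng_bg.standard_normal((background_genes, len(sample_ids))))
        gene_names.extend(f"BG_g{i:05d}" for i in range(1, background_genes + 1))

    expr = pd.DataFrame(np.vstack(blocks), index=gene_names, columns=sample_ids)
    return expr, classes, coll, truth


# ---------------------------------------------------------------------------
# planted-hub network
# ---------------------------------------------------------------------------

def simulate_network(
    n_nodes: int,
    n_hubs: int,
    attachment_degree: int = 2,
    module_assignment: Mapping[str, Iterable[str]] | None = None,
    seed: int = 0,
    hub_coverage: float = 0.85,
):
    """Preferential-attachment PPI network with hubs planted into modules.

    A Barabási–Albert graph (heavy-tailed degrees, like real interactomes)
    is built over ``n_nodes`` and relabelled so that module genes occupy a
    random subset of nodes.  Each planted hub is wired directly to
    ``hub_coverage`` (default 85%) of one module's mapped genes, so its
    2-hop neighborhood covers at least 80% of the module by construction.
    Edge weights are confidence scores drawn uniform on [0.4, 1].

    Returns ``(network, truth)`` with ``truth.hub_truth`` and
    ``truth.hub_modules`` filled in.  Deterministic given ``seed``.
    """
    if n_hubs >= n_nodes:
        raise ConfigError("n_hubs must be < n_nodes")
    module_assignment = dict(module_assignment or {})
    module_genes = [g for genes in module_assignment.values() for g in genes]
    if len(set(module_genes)) != len(module_genes):
        raise ConfigError("module assignments overlap")
    hubs = [f"HUB{i:02d}" for i in range(1, n_hubs + 1)]
    if len(module_genes) + n_hubs > n_nodes:
        raise ConfigError("modules plus hubs larger than n_nodes")

    ss = np.random.SeedSequence(seed)
    child_graph, child_wiring = ss.spawn(2)
    rng = np.random.default_rng(child_wiring)

    base = nx.barabasi_albert_graph(
        n_nodes, attachment_degree,
        seed=int(child_graph.generate_state(1)[0] % (2**31 - 1)))
    n_filler = n_nodes - len(module_genes) - n_hubs
    names = list(module_genes) + hubs + [f"N{i:05d}" for i in range(1, n_filler + 1)]
    perm = rng.permutation(n_nodes)
    mapping = {int(node): names[perm[i]] for i, node in enumerate(base.nodes)}
    graph = nx.relabel_nodes(base, mapping)

    truth = PanelTruth(hub_truth=list(hubs))
    module_names = sorted(module_assignment)
    for i, hub in enumerate(hubs):
        if not module_names:
            break
        mod = module_names[i % len(module_names)]
        genes = [g for g in module_assignment[mod] if g != hub]
        k = math.ceil(hub_coverage * len(genes))
        chosen = rng.choice(len(genes), size=k, replace=False)
        for j in chosen:
            graph.add_edge(hub, genes[j])
        truth.hub_modules[hub] = mod

    for _, _, data in graph.edges(data=True):
        data["weight"] = float(0.4 + 0.6 * rng.random())
    return graph, truth
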
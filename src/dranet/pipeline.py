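"""End-to-end pipeline: simulate (or load) → scan → null → group → overlap →
MDC → KDA, with a reproducibility manifest.

Every stage writes a tab-delimited artifact whose header comments record the
parameters used; the manifest (JSON) records the per-stage seeds (spawned
from the master seed in a fixed order) and the SHA-256 of every artifact, so
two runs of the same config are hash-identical.  Wall-clock timings and
warnings go to the log, never into the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster, io, kda, mdc, overlap, regression, simulate
from .exceptions import ConfigError

logger = logging.getLogger(__name__)

#: fixed stage order for seed spawning; changing it changes every stream
STAGES = ("panel", "modules", "network", "scan", "permnull", "subsample",
          "mdc", "kda")


@dataclass
class PipelineConfig:
    """All pipeline parameters, defaulting to the study's analysis constants.

    alpha 0.1 (DRA FDR), trichotomy k 0.8, module size filter 30, 50 MDC
    permutations, 1,000 scan permutations, key-driver FDR threshold 0.05,
    2-hop neighborhoods, edge confidence 0.4, top-k overlap grid
    100..5000 step 100.
    """

    outdir: str = "dranet_out"
    seed: int = 0

    # simulation (used when no input paths are given)
    n_samples: int = 300
    n_genes: int = 500
    n_dra: int = 50
    n_modules: int = 20
    module_size: int = 35
    rho_sensitive: float = 0.2
    rho_resistant: float = 0.7
    n_null_modules: int = 15
    network_nodes: int = 1000
    network_hubs: int = 1
    attachment_degree: int = 2
    drug: str = "drugA"

    # analysis constants
    alpha: float = 0.1
    trichotomy_k: float = 0.8
    min_module_size: int = 30
    mdc_n_perm: int = 50
    dra_n_perm: int = 1000
    kda_n_perm: int = 1000
    kda_threshold: float = 0.05
    hops: int = 2
    confidence: float = 0.4
    ks: list[int] = field(default_factory=overlap.default_ks)
    subsample_sizes: list[int] = field(default_factory=list)
    subsample_reps: int = 100

    # optional real inputs; when set, simulation is skipped
    expression_path: str | None = None
    samples_path: str | None = None
    gene_sets_path: str | None = None
    network_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % (2**31 - 1))
            for name, c in zip(STAGES, children)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to manifest.json)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    t0 = time.time()
    params = asdict(config)
    artifacts: dict[str, str] = {}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        artifacts[name] = _sha256(path)
        logger.info("stage artifact %s written (%.1fs elapsed)", name,
                    time.time() - t0)

    # --- inputs: simulate or load ---------------------------------------
    if config.expression_path:
        samples = io.read_sample_table(config.samples_path)
        expr = io.read_expression_matrix(config.expression_path,
                                         known_sample_ids=samples.index)
        collection = io.read_gene_sets(config.gene_sets_path)
        network = io.read_network_edges(config.network_path,
                                        min_confidence=config.confidence)
        truth = None
    else:
        sim = simulate.SimulationConfig(
            n_samples=config.n_samples, n_genes=config.n_genes,
            n_dra=config.n_dra, drug=config.drug, seed=seeds["panel"])
        expr, samples, truth = simulate.simulate_panel(sim)
        classes0 = cluster.trichotomize(
            samples[io.sensitivity_column(config.drug)], k=config.trichotomy_k)
        specs = [
            simulate.ModuleSpec(f"MOD{i:02d}", config.module_size,
                                config.rho_sensitive, config.rho_resistant)
            for i in range(1, config.n_modules - config.n_null_modules + 1)
        ] + [
            simulate.ModuleSpec(f"NULLMOD{i:02d}", config.module_size,
                                config.rho_sensitive, config.rho_sensitive)
            for i in range(1, config.n_null_modules + 1)
        ]
        mod_expr, _, collection, mod_truth = simulate.simulate_differential_modules(
            specs, classes=classes0, seed=seeds["modules"],
            min_size=config.min_module_size)
        expr = pd.concat([expr, mod_expr])
        first_module = sorted(collection)[0]
        network, net_truth = simulate.simulate_network(
            config.network_nodes, config.network_hubs,
            attachment_degree=config.attachment_degree,
            module_assignment={first_module: sorted(collection[first_module])},
            seed=seeds["network"])
        truth.module_truth = mod_truth.module_truth
        truth.hub_truth = net_truth.hub_truth
        truth.hub_modules = net_truth.hub_modules
        emit("expression.tsv", lambda p: io.write_expression_matrix(expr, p))
        emit("samples.tsv", lambda p: io.write_sample_table(samples, p))
        emit("modules.gmt", lambda p: io.write_gene_sets(collection, p))
        emit("network.tsv", lambda p: io.write_network_edges(network, p))
        emit("truth_dra.tsv",
             lambda p: io.write_table(truth.dra_table(), p,
                                      params={"seed": config.seed}))

    sens = samples[io.sensitivity_column(config.drug)]

    # --- per-gene scan ---------------------------------------------------
    scan = regression.run_dra_scan(expr, samples, config.drug, alpha=config.alpha)
    emit(f"dra_{config.drug}.tsv",
         lambda p: io.write_table(scan.to_table(), p,
                                  params={"drug": config.drug,
                                          "alpha": config.alpha}))
    logger.info("scan: %d DRA genes (%d+/%d-)", scan.n_significant,
                scan.n_positive, scan.n_negative)

    # --- permutation null -------------------------------------------------
    null = regression.permutation_null(expr, samples, config.drug,
                                       n_perm=config.dra_n_perm,
                                       alpha=config.alpha,
                                       seed=seeds["permnull"])
    emit("permnull.tsv", lambda p: io.write_table(
        pd.DataFrame([asdict(null)]), p,
        params={"seed": seeds["permnull"]}))

    # --- grouping ---------------------------------------------------------
    dra_genes = scan.significant_genes
    if len(dra_genes) >= 1:
        assignment = cluster.cluster_samples(expr.loc[dra_genes], sens)
        t, pval, sizes = cluster.compare_groups(sens, assignment)
        emit("groups.tsv", lambda p: io.write_table(
            assignment.labels.rename_axis("sample").reset_index(), p,
            params={"t_statistic": t, "p_value": pval,
                    "n_sensitive": sizes[0], "n_non_sensitive": sizes[1]}))
    classes = cluster.trichotomize(sens, k=config.trichotomy_k)
    emit("classes.tsv", lambda p: io.write_table(
        classes.classes.rename_axis("sample").reset_index(), p,
        params={"k": config.trichotomy_k, "mean": classes.mean,
                "sd": classes.sd}))

    # --- sex-stratified top-k overlap ------------------------------------
    strata = {}
    for sex_value in sorted(samples["sex"].unique()):
        sub = samples[samples["sex"] == sex_value]
        strata[sex_value] = regression.run_dra_scan(
            expr, sub, config.drug, alpha=config.alpha).ranking()
    if len(strata) == 2:
        (ra, rb) = strata.values()
        shared = [g for g in ra if g in set(rb)]
        ra = [g for g in ra if g in set(shared)]
        rb = [g for g in rb if g in set(shared)]
        ks = [k for k in config.ks if k <= len(shared)]
        if not ks:
            ks = [max(10, len(shared) // 4), max(20, len(shared) // 2)]
        sweep = overlap.topk_overlap_sweep(ra, rb, universe_size=len(shared), ks=ks)
        emit("overlap_sweep.tsv", lambda p: io.write_table(
            sweep.table, p, params={"universe": len(shared)}))

    # --- MDC --------------------------------------------------------------
    analysis = mdc.MDCAnalysis(expr, classes, collection,
                               min_size=config.min_module_size,
                               n_perm=config.mdc_n_perm, seed=seeds["mdc"])
    mdc_results = analysis.fit()
    emit("mdc.tsv", lambda p: io.write_table(
        mdc_results.ranked(), p,
        params={"n_perm": config.mdc_n_perm, "seed": seeds["mdc"],
                "ranking": "significant (fdr<=0.05) first by |log mdc| desc"}))

    # --- KDA on the top-ranked analysable module -------------------------
    ranked = mdc_results.ranked()
    kda_module = None
    for name in ranked["module"]:
        if any(g in network for g in collection[name]):
            kda_module = name
            break
    if kda_module is not None:
        kres = kda.kda_fdr(network, collection[kda_module],
                           n_perm=config.kda_n_perm, seed=seeds["kda"],
                           threshold=config.kda_threshold, hops=config.hops)
        emit("kda.tsv", lambda p: io.write_table(
            kres.table, p,
            params={"module": kda_module, "n_perm": config.kda_n_perm,
                    "seed": seeds["kda"], "threshold": config.kda_threshold,
                    "null": "module resampled uniformly from subnetwork nodes"}))
        sub, annotations = kres.export_subnetwork()
        emit("subnetwork_edges.tsv", lambda p: io.write_network_edges(sub, p))
        emit("subnetwork_nodes.tsv",
             lambda p: io.write_table(annotations, p,
                                      params={"module": kda_module}))

    manifest = {
        "config": params,
        "stage_seeds": seeds,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d artifacts in %s (%.1fs)",
                len(artifacts), out, time.time() - t0)
    return manifest
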
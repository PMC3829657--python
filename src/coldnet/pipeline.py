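"""End-to-end orchestration: simulate -> DE -> core set -> NCA -> network.

:func:`run_pipeline` executes the full analysis on a simulated
multi-ecotype cold-stress experiment, materializing every intermediate
(expression tables, DE summaries, the core transcript set, the NCA
criteria report and decomposition, the thresholded network and its
topology summary) under one output directory, together with the resolved
configuration and a run report carrying per-stage counts and sha256
checksums. Identical configuration and seed produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, network, simulate, topology
from .exceptions import ConfigError
from .io import write_expression_table, write_network
from .nca import decompose, reduce_to_compliant
from .simulate import simulate_regulatory_experiment

log = logging.getLogger("coldnet.pipeline")


@dataclass
class PipelineConfig:
    """Resolved parameters of a full pipeline run.

    Thresholds default to the study conventions: DE at raw p < 0.01, core
    membership in >= 2 ecotypes, network edges at |r| >= 0.8, TF
    expression-activity classification at |r| > 0.5 and activity calls at
    z >= 1.
    """

    # statistical thresholds
    alpha: float = 0.01
    min_ecotypes: int = 2
    max_core: int = 1509
    r_threshold: float = 0.8
    corr_cut: float = 0.5
    z_cut: float = 1.0
    # NCA solver
    nca_tol: float = 1e-6
    nca_max_iter: int = 500
    nca_restarts: int = 10
    nca_strict: bool = True
    # simulated study design
    n_target_genes: int = 192
    n_tfs: int = 8
    n_ecotypes: int = 10
    n_replicates: int = 3
    out_degree: int = 25
    noise_sd: float = 0.3
    activity_delta: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha {self.alpha} outside (0, 1)")
        if not 0 < self.r_threshold <= 1:
            raise ConfigError(f"r_threshold {self.r_threshold} outside (0, 1]")
        if not 0 <= self.corr_cut < 1:
            raise ConfigError(f"corr_cut {self.corr_cut} outside [0, 1)")
        if self.z_cut <= 0:
            raise ConfigError("z_cut must be positive")
        if self.min_ecotypes < 1 or self.min_ecotypes > self.n_ecotypes:
            raise ConfigError("min_ecotypes outside [1, n_ecotypes]")
        if self.max_core < 1:
            raise ConfigError("max_core must be positive")
        if self.n_replicates < 2:
            raise ConfigError("need >= 2 replicates")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if self.n_tfs > self.n_ecotypes:
            raise ConfigError(
                "n_tfs > n_ecotypes: activity matrix cannot have full row rank"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def _fc_matrix(expr, ecotypes) -> pd.DataFrame:
    """Per-ecotype mean log2 fold-change (cold minus control)."""
    cols = {}
    for eco in ecotypes:
        cold = expr.values[expr.samples_for(eco, "cold")].mean(axis=1)
        ctrl = expr.values[expr.samples_for(eco, "control")].mean(axis=1)
        cols[eco] = cold - ctrl
    return pd.DataFrame(cols)[list(ecotypes)]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full synthetic-study analysis; returns the run report dict."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "config": config.to_dict()}
    artifacts: list[Path] = []

    def save(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        artifacts.append(path)
        return path

    _write_json(outdir / "config.json", config.to_dict())
    artifacts.append(outdir / "config.json")

    # --- stage 1: simulate -------------------------------------------------
    log.info("stage=simulate event=start")
    expr, truth = simulate_regulatory_experiment(
        n_target_genes=config.n_target_genes,
        n_tfs=config.n_tfs,
        n_ecotypes=config.n_ecotypes,
        n_replicates=config.n_replicates,
        out_degree=config.out_degree,
        noise_sd=config.noise_sd,
        activity_delta=config.activity_delta,
        seed=config.seed,
    )
    save("expression.tsv",
         lambda p: write_expression_table(expr, p, outdir / "metadata.tsv"))
    artifacts.append(outdir / "metadata.tsv")
    save("truth_activities.tsv",
         lambda p: truth.activities.to_csv(p, sep="\t", index_label="tf",
                                           lineterminator="\n"))
    conn = truth.connectivity.to_frame()
    save("truth_connectivity.tsv",
         lambda p: conn.to_csv(p, sep="\t", index_label="gene",
                               lineterminator="\n"))
    report["stages"]["simulate"] = {
        "n_genes": expr.n_genes,
        "n_samples": expr.n_samples,
        "n_tfs": config.n_tfs,
        "n_true_edges": truth.connectivity.n_edges,
    }

    # --- stage 2: differential expression ---------------------------------
    log.info("stage=de event=start")
    de = diffexpr.de_analysis(expr, alpha=config.alpha)
    sets = diffexpr.call_de_sets(de)
    de_table = pd.concat(
        {"t_p": de.t_p, "log2fc": de.log2fc}, axis=1
    )
    de_table[("anova", "interaction_p")] = de.interaction_p
    save("de_table.tsv",
         lambda p: de_table.to_csv(p, sep="\t", index_label="gene",
                                   lineterminator="\n"))
    save("de_summary.tsv",
         lambda p: sets.table.to_csv(p, sep="\t", lineterminator="\n"))
    report["stages"]["de"] = {
        "union": len(sets.union),
        "unique_fraction": sets.unique_fraction,
        "per_ecotype_totals": {e: int(v) for e, v in
                               sets.table["total"].items()},
    }

    # --- stage 3: core transcript selection --------------------------------
    tf_list = set(truth.connectivity.tf_ids)
    core = diffexpr.select_core_transcripts(
        de, min_ecotypes=config.min_ecotypes, max_n=config.max_core,
        tf_list=tf_list,
    )
    save("core_set.tsv",
         lambda p: pd.DataFrame(
             {"gene": core.core,
              "is_tf": [g in tf_list for g in core.core]}
         ).to_csv(p, sep="\t", index=False, lineterminator="\n"))
    report["stages"]["core"] = {
        "selected": len(core.core),
        "tfs": len(core.tfs),
        "targets": len(core.targets),
    }

    # --- stage 4: NCA ------------------------------------------------------
    log.info("stage=nca event=start")
    fc = _fc_matrix(expr, list(truth.activities.columns))
    core_targets = [g for g in core.targets if g in set(truth.connectivity.gene_ids)]
    z0 = truth.connectivity.restrict(gene_ids=core_targets)
    z0_reduced, removal_log = reduce_to_compliant(
        z0, n_conditions=config.n_ecotypes, seed=config.seed
    )
    dec = decompose(
        fc.loc[z0_reduced.gene_ids],
        z0_reduced,
        tol=config.nca_tol,
        max_iter=config.nca_max_iter,
        n_restarts=config.nca_restarts,
        seed=config.seed,
        strict=config.nca_strict,
    )
    save("nca_control_strengths.tsv",
         lambda p: dec.control_strengths.to_csv(p, sep="\t", index_label="gene",
                                                lineterminator="\n"))
    save("nca_activities.tsv",
         lambda p: dec.activities.to_csv(p, sep="\t", index_label="tf",
                                         lineterminator="\n"))
    save("nca_residuals.tsv",
         lambda p: pd.Series(dec.residual_history, name="residual")
         .to_csv(p, sep="\t", index_label="iteration", lineterminator="\n"))
    _write_json(outdir / "nca_report.json", {
        "converged": dec.converged,
        "n_iter": dec.n_iter,
        "identifiable": dec.identifiable,
        "final_residual": dec.final_residual,
        "tfs_removed_in_reduction": removal_log,
    })
    artifacts.append(outdir / "nca_report.json")
    report["stages"]["nca"] = {
        "n_genes": len(z0_reduced.gene_ids),
        "n_tfs": len(z0_reduced.tf_ids),
        "converged": dec.converged,
        "n_iter": dec.n_iter,
        "final_residual": dec.final_residual,
    }

    # --- stage 5: network reconstruction -----------------------------------
    log.info("stage=network event=start")
    core_fc = fc.loc[[g for g in core.core if g in fc.index]]
    candidates = network.correlate_tf_targets(
        dec.activities, core_fc, pairs="all"
    )
    net = network.build_network(candidates, r_threshold=config.r_threshold)
    save("network_edges.tsv", lambda p: write_network(net, p, "edge_tsv"))
    tf_classes = network.classify_tf_correlations(
        dec.activities, core_fc, cut=config.corr_cut
    )
    save("tf_classification.tsv",
         lambda p: tf_classes.to_csv(p, sep="\t", lineterminator="\n"))
    calls = network.call_active_ecotypes(dec.activities, z_cut=config.z_cut)
    _write_json(outdir / "active_ecotypes.json", {
        "active": {tf: list(v) for tf, v in sorted(calls.active.items())},
        "ecotype_specific": sorted(calls.ecotype_specific),
    })
    artifacts.append(outdir / "active_ecotypes.json")
    report["stages"]["network"] = {
        "candidates": len(candidates),
        "edges": net.n_edges,
        "activations": net.n_activations,
        "repressions": net.n_repressions,
        "nodes": len(net.nodes),
        "ecotype_specific_tfs": sorted(calls.ecotype_specific),
    }

    # --- stage 6: topology --------------------------------------------------
    summary = topology.summarize_topology(net)
    _write_json(outdir / "topology.json", summary.to_dict())
    artifacts.append(outdir / "topology.json")
    report["stages"]["topology"] = summary.to_dict()

    report["checksums"] = {p.name: _sha256(p) for p in sorted(set(artifacts))}
    report["versions"] = {
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    report["seed"] = config.seed
    _write_json(outdir / "report.json", report)
    log.info("stage=pipeline event=done")
    return report
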
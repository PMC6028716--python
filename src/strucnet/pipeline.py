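"""End-to-end orchestration: simulate -> reconstruct -> metrics -> attack -> stats.

Each stage reads and writes plain-text files under one output directory
and is recorded in a run manifest (config snapshot, seed, version,
SHA-256 digest of every input/output, timestamps).  A stage is skipped
on re-run when its inputs and outputs all exist with digests matching
the previous manifest, so deleting any intermediate file re-executes
only that stage and everything downstream.  All randomness flows from
the single top-level seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas_io import (AtlasNodeTable, WeightedNetwork, load_atlas,
                       load_cohort, read_matrix, read_network, write_matrix,
                       write_network)
from .metrics import NODAL_PROPERTIES, MetricSet, compute_metric_set
from .reconstruction import reconstruct
from .robustness import simulate_attack, trajectories_to_frame
from .stats import run_stats
from .synthetic_data import SimulationConfig, TractographyRun, generate_cohort

log = logging.getLogger("strucnet")

STAGES = ("simulate", "reconstruct", "metrics", "attack", "stats")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    threshold_fraction: float = 0.10
    attack_n_remove: int = 40
    attack_mode: str = "static"
    fdr_q: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim = SimulationConfig(**d.get("simulation", {}))
        return cls(
            simulation=sim,
            threshold_fraction=d.get("threshold_fraction", 0.10),
            attack_n_remove=d.get("attack", {}).get("n_remove", 40),
            attack_mode=d.get("attack", {}).get("mode", "static"),
            fdr_q=d.get("stats", {}).get("q", 0.05),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_dict(self) -> dict:
        sim = self.simulation
        return {
            "simulation": {
                "n_patients": sim.n_patients, "n_controls": sim.n_controls,
                "n_nodes": sim.n_nodes,
                "streams_per_seed": sim.streams_per_seed,
                "global_deficit": sim.global_deficit,
                "focal_deficit": sim.focal_deficit,
                "focal_regions": list(sim.focal_regions),
                "subject_sd": sim.subject_sd, "seed": sim.seed,
            },
            "threshold_fraction": self.threshold_fraction,
            "attack": {"n_remove": self.attack_n_remove,
                       "mode": self.attack_mode},
            "stats": {"q": self.fdr_q},
        }


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def metric_sets_to_frames(
    sets: list[MetricSet], atlas: AtlasNodeTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(global one-row-per-subject table, long nodal table)."""
    grows = [{"subject_id": m.subject_id, **m.globals_dict()} for m in sets]
    nrows = []
    names = atlas.names
    for m in sets:
        vectors = {
            "local_efficiency": m.nodal_local_efficiency,
            "degree": m.nodal_degree,
            "betweenness_centrality": m.nodal_betweenness,
        }
        for prop in NODAL_PROPERTIES:
            vec = vectors[prop]
            for i, v in enumerate(vec):
                nrows.append(
                    {"subject_id": m.subject_id, "property": prop,
                     "node_id": i, "node_name": names[i], "value": float(v)}
                )
    return pd.DataFrame(grows), pd.DataFrame(nrows)


class Pipeline:
    """Stage runner with digest-based caching over one output directory."""

    def __init__(self, config: PipelineConfig, out_dir: str | Path):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.atlas = config.simulation.atlas()
        self.manifest_path = self.out / "manifest.json"
        self._old = {}
        if self.manifest_path.exists():
            self._old = json.loads(self.manifest_path.read_text()).get("stages", {})
        self.manifest = {
            "version": __version__,
            "seed": config.simulation.seed,
            "config": config.to_dict(),
            "stages": {},
        }

    # ---- file layout -------------------------------------------------
    def _subject_ids(self) -> list[str]:
        sim = self.config.simulation
        return [f"spr{k:03d}" for k in range(sim.n_patients)] + [
            f"hc{k:03d}" for k in range(sim.n_patients,
                                        sim.n_patients + sim.n_controls)
        ]

    def _stage_files(self, stage: str) -> list[Path]:
        sids = self._subject_ids()
        if stage == "simulate":
            files = [self.out / "cohort.csv", self.out / "true_params.json"]
            files += [self.out / "counts" / f"{s}_counts.tsv" for s in sids]
            files += [self.out / "counts" / f"{s}_waytotals.csv" for s in sids]
            return files
        if stage == "reconstruct":
            return [self.out / "networks" / f"{s}.tsv" for s in sids]
        if stage == "metrics":
            return [self.out / "metrics.csv", self.out / "nodal.csv"]
        if stage == "attack":
            return [self.out / "trajectories.csv"]
        if stage == "stats":
            rep = self.out / "report"
            return [rep / "global.csv", rep / "nodal.csv",
                    rep / "correlations.csv", rep / "lmm.json",
                    rep / "summary.md"]
        raise ValueError(f"unknown stage {stage!r}")

    def _cached(self, stage: str, upstream_fresh: bool) -> bool:
        if upstream_fresh:
            return False
        old = self._old.get(stage)
        if old is None:
            return False
        files = self._stage_files(stage)
        if not all(f.exists() for f in files):
            return False
        current = {str(f.relative_to(self.out)): _digest(f) for f in files}
        return current == old.get("outputs", {})

    def _record(self, stage: str, executed: bool) -> None:
        files = self._stage_files(stage)
        self.manifest["stages"][stage] = {
            "executed": executed,
            "timestamp": time.time(),
            "outputs": {str(f.relative_to(self.out)): _digest(f)
                        for f in files},
        }

    # ---- stages ------------------------------------------------------
    def stage_simulate(self) -> None:
        cohort, runs, true_params = generate_cohort(self.config.simulation)
        (self.out / "counts").mkdir(exist_ok=True)
        cohort.to_csv(self.out / "cohort.csv", index=False)
        for run in runs:
            write_matrix(run.counts, self.atlas,
                         self.out / "counts" / f"{run.subject_id}_counts.tsv")
            pd.DataFrame({"node": self.atlas.names,
                          "waytotal": run.waytotals}).to_csv(
                self.out / "counts" / f"{run.subject_id}_waytotals.csv",
                index=False)
        tp = {
            "config": true_params["config"],
            "latent_factor": true_params["latent_factor"],
        }
        (self.out / "true_params.json").write_text(json.dumps(tp, indent=1))

    def _load_runs(self) -> list[TractographyRun]:
        runs = []
        for sid in self._subject_ids():
            C = read_matrix(self.out / "counts" / f"{sid}_counts.tsv",
                            self.atlas)
            w = pd.read_csv(self.out / "counts" / f"{sid}_waytotals.csv")
            w = w.set_index("node").loc[self.atlas.names, "waytotal"].to_numpy()
            runs.append(TractographyRun(sid, C.astype(np.int64), w))
        return runs

    def stage_reconstruct(self) -> None:
        (self.out / "networks").mkdir(exist_ok=True)
        for run in self._load_runs():
            net = reconstruct(run, self.atlas, self.config.threshold_fraction)
            write_network(net, self.out / "networks" / f"{net.subject_id}.tsv")

    def _load_networks(self) -> list[WeightedNetwork]:
        return [read_network(self.out / "networks" / f"{sid}.tsv",
                             self.atlas, sid)
                for sid in self._subject_ids()]

    def stage_metrics(self) -> None:
        sets = [compute_metric_set(net) for net in self._load_networks()]
        gdf, ndf = metric_sets_to_frames(sets, self.atlas)
        gdf.to_csv(self.out / "metrics.csv", index=False)
        ndf.to_csv(self.out / "nodal.csv", index=False)

    def stage_attack(self) -> None:
        if self.config.attack_n_remove >= self.atlas.n_nodes:
            raise ValueError(
                f"attack n_remove={self.config.attack_n_remove} must be "
                f"smaller than n_nodes={self.atlas.n_nodes}"
            )
        trajs = [simulate_attack(net, self.config.attack_n_remove,
                                 self.config.attack_mode)
                 for net in self._load_networks()]
        trajectories_to_frame(trajs).to_csv(
            self.out / "trajectories.csv", index=False)

    def stage_stats(self) -> None:
        cohort = load_cohort(self.out / "cohort.csv")
        gdf = pd.read_csv(self.out / "metrics.csv").merge(
            cohort[["subject_id", "group"]], on="subject_id")
        ndf = pd.read_csv(self.out / "nodal.csv").merge(
            cohort[["subject_id", "group"]], on="subject_id")
        trajs = pd.read_csv(self.out / "trajectories.csv")
        report = run_stats(gdf, ndf, cohort, trajs, q=self.config.fdr_q)
        rep = self.out / "report"
        rep.mkdir(exist_ok=True)
        report.global_rows.to_csv(rep / "global.csv", index=False)
        report.nodal_rows.to_csv(rep / "nodal.csv", index=False)
        report.correlation_rows.to_csv(rep / "correlations.csv", index=False)
        (rep / "lmm.json").write_text(json.dumps(report.lmm_row, indent=1))
        (rep / "summary.md").write_text(render_report(report, self.config))

    # ---- driver ------------------------------------------------------
    def run_all(self) -> dict:
        fresh = False
        for stage in STAGES:
            if self._cached(stage, fresh):
                log.info("stage %s: cached, skipping", stage)
                self.manifest["stages"][stage] = dict(
                    self._old[stage], executed=False)
                continue
            log.info("stage %s: running", stage)
            t0 = time.time()
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", stage, time.time() - t0)
            self._record(stage, executed=True)
            fresh = True
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))
        return self.manifest


def run_all(config: PipelineConfig | str | Path, out_dir: str | Path,
            seed: int | None = None) -> dict:
    """Run (or resume) the full pipeline; returns the manifest."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    if seed is not None:
        from dataclasses import replace
        config = PipelineConfig(
            simulation=replace(config.simulation, seed=seed),
            threshold_fraction=config.threshold_fraction,
            attack_n_remove=config.attack_n_remove,
            attack_mode=config.attack_mode,
            fdr_q=config.fdr_q,
        )
    return Pipeline(config, out_dir).run_all()


def render_report(report, config: PipelineConfig) -> str:
    """Markdown summary: global comparison, nodal blocks, correlations, LMM."""
    lines = ["# Structural network analysis summary", ""]
    lines += ["## Global network properties", "",
              "| metric | patient mean (SD) | control mean (SD) | test | p |",
              "|---|---|---|---|---|"]
    for _, r in report.global_rows.iterrows():
        lines.append(
            f"| {r.metric} | {r.patient_mean:.4g} ({r.patient_sd:.3g}) "
            f"| {r.control_mean:.4g} ({r.control_sd:.3g}) "
            f"| {r.test} | {r.p:.3g} |"
        )
    lines += ["", "## Nodal network properties", ""]
    nd = report.nodal_rows
    n_fdr = int(nd["significant_at_q"].sum())
    if n_fdr == 0:
        lines.append(
            f"None of the nodal comparisons reached the FDR threshold "
            f"(q = {config.fdr_q})."
        )
    else:
        lines.append(f"{n_fdr} nodal comparisons passed FDR at q = {config.fdr_q}.")
    unc = nd[nd["uncorrected_significant"]]
    lines.append(f"{len(unc)} comparisons significant at uncorrected p < 0.05:")
    lines.append("")
    lines += ["| property | node | patient mean | control mean | p | p (BH) |",
              "|---|---|---|---|---|---|"]
    for _, r in unc.iterrows():
        lines.append(
            f"| {r.property} | {r.node_name} | {r.patient_mean:.4g} "
            f"| {r.control_mean:.4g} | {r.p:.3g} | {r.p_adjusted:.3g} |"
        )
    lines += ["", "## Clinical correlations", ""]
    cr = report.correlation_rows
    omitted = cr[cr["flag"] != ""]
    if not omitted.empty:
        lines.append(f"{len(omitted)} correlation cells omitted "
                     f"({', '.join(sorted(set(omitted['flag'])))}).")
        lines.append("")
    lines += ["| group | metric | score | n | r | p |", "|---|---|---|---|---|---|"]
    for _, r in cr[cr["flag"] == ""].iterrows():
        lines.append(f"| {r.group} | {r.metric} | {r.score} | {r.n} "
                     f"| {r.r:.3f} | {r.p:.3g} |")
    lines += ["", "## Robustness (linear mixed model)", ""]
    if report.lmm_row:
        L = report.lmm_row
        lines.append(
            f"Group-by-removed-nodes interaction on global efficiency: "
            f"estimate {L['estimate']:.3e} (SE {L['se']:.3e}), "
            f"z = {L['statistic']:.3f}, p = {L['p']:.3g} "
            f"({L['n_subjects']} subjects, {L['n_steps']} steps)."
        )
    else:
        lines.append("No trajectories supplied; mixed model not fitted.")
    lines.append("")
    return "\n".join(lines)
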
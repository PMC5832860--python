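"""End-to-end pipeline: graph -> subpopulations -> trajectories -> dynamics
-> GRN -> quality report, with a machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__, dynamics, flownet, graph as graph_mod, grn as grn_mod, io, metrics

logger = logging.getLogger("flowroute")
if not logger.handlers:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)


@dataclass
class RunConfig:
    """All pipeline parameters; defaults follow the tool's standard settings
    (two k values, 0.85/0.15 rho quantiles, 0.975 loading quantile on the
    first 5 PCs, 10 MI bins, CLR z threshold 3)."""

    expression: str = ""
    embedding: str = ""
    regulators: str = ""
    outdir: str = "flowroute_out"
    k_subpop: int = 5
    k_traj: int = 10
    seed: int = 42
    rank_criterion: str = "flow_per_length"
    upper_q: float = 0.85
    lower_q: float = 0.15
    n_clusters: int = 5
    grn_bins: int = 10
    grn_zmin: float = 3.0
    loading_q: float = 0.975
    n_pcs: int = 5
    pairs: list = field(default_factory=list)  # [[source_label, target_label], ...]
    markers: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise io.FlowRouteError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage(name: str):
    logger.info("stage %s", name)
    return time.time()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order, writing all outputs plus a manifest
    into ``config.outdir``. Identical config and inputs yield identical
    outputs. Raises with the stage name on any stage failure."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": asdict(config),
        "inputs": {},
        "stages": {},
    }
    stage = "load"
    try:
        t0 = _stage(stage)
        expr = io.read_expression(config.expression)
        expr = io.filter_zero_variance(expr)
        emb = io.read_embedding(config.embedding)
        manifest["inputs"]["expression"] = _sha256(config.expression)
        manifest["inputs"]["embedding"] = _sha256(config.embedding)
        regs = None
        if config.regulators:
            regs = io.read_regulators(config.regulators).intersect(expr.gene_ids)
            manifest["inputs"]["regulators"] = _sha256(config.regulators)
        manifest["stages"][stage] = round(time.time() - t0, 3)

        stage = "graph"
        t0 = _stage(stage)
        knn_sub = graph_mod.build_knn_graph(emb, config.k_subpop)
        sim_sub = graph_mod.jaccard_transform(knn_sub)
        assign = graph_mod.find_subpopulations(sim_sub, seed=config.seed)
        knn_traj = graph_mod.build_knn_graph(emb, config.k_traj)
        sim_traj = graph_mod.jaccard_transform(knn_traj)
        sim_traj.subpopulations = assign.labels
        n_comp = nx.number_connected_components(sim_traj.graph)
        if n_comp > 1:
            comps = sorted(nx.connected_components(sim_traj.graph), key=len, reverse=True)
            logger.warning(
                "trajectory graph has %d connected components (sizes %s); only "
                "transitions within one component can be found — increase k_traj",
                n_comp,
                [len(c) for c in comps],
            )
        io.write_graph(sim_traj, outdir / "graph.graphml")
        pd.Series(assign.labels, name="subpopulation").rename_axis("cell").to_csv(
            outdir / "subpopulations.csv"
        )
        manifest["stages"][stage] = round(time.time() - t0, 3)

        stage = "signatures"
        t0 = _stage(stage)
        signatures = graph_mod.signature_genes(expr, assign)
        signatures.to_csv(outdir / "signatures.csv", index=False)
        manifest["stages"][stage] = round(time.time() - t0, 3)

        stage = "trajectories"
        t0 = _stage(stage)
        pairs = [tuple(p) for p in config.pairs]
        if not pairs:
            raise io.FlowRouteError("no subpopulation pairs configured")
        results = flownet.trajectories_between(
            sim_traj, assign, expr, pairs, criterion=config.rank_criterion
        )
        if all(r.trajectory is None for r in results):
            raise io.FlowRouteError(
                "every requested pair failed: " + "; ".join(r.error or "" for r in results)
            )
        manifest["trajectories"] = {}
        manifest["stages"][stage] = round(time.time() - t0, 3)

        reports = {}
        for res in results:
            tag = f"{res.pair[0]}_{res.pair[1]}"
            if res.trajectory is None:
                logger.warning("pair %s failed: %s", res.pair, res.error)
                manifest["trajectories"][tag] = {"error": res.error}
                continue
            traj = res.trajectory
            io.write_trajectory(traj, outdir / f"trajectory_{tag}.json")
            manifest["trajectories"][tag] = {
                "cells": traj.n_cells,
                "flow": traj.flow,
                "cost": traj.cost,
                "length": traj.length,
            }

            stage = f"dynamics[{tag}]"
            t0 = _stage(stage)
            smoothed = dynamics.neighborhood_smooth(expr, sim_traj, traj)
            pseudo = np.array([traj.pseudotime[c] for c in traj.cells])
            ranking = dynamics.rank_genes(
                smoothed, pseudo, upper_q=config.upper_q, lower_q=config.lower_q
            )
            pd.DataFrame(
                {
                    "gene": list(ranking.rho),
                    "rho": [ranking.rho[g] for g in ranking.rho],
                    "class": [ranking.classes[g] for g in ranking.rho],
                }
            ).to_csv(outdir / f"ranking_{tag}.csv", index=False)
            regulated = ranking.genes_in_class("up") + ranking.genes_in_class("down")
            trends = [
                dynamics.fit_trend(smoothed.loc[g].to_numpy(), pseudo, gene=g)
                for g in regulated
            ]
            trends = [t for t in trends if not t.is_constant]
            if len(trends) > config.n_clusters:
                clusters = dynamics.cluster_trends(
                    trends, n_clusters=config.n_clusters, seed=config.seed
                )
                pd.Series(clusters.assignment, name="cluster").rename_axis("gene").to_csv(
                    outdir / f"clusters_{tag}.csv"
                )
            curve_df = pd.DataFrame(
                [t.smooth for t in trends],
                index=[t.gene for t in trends],
                columns=[f"t{i}" for i in range(dynamics.GRID_SIZE)],
            )
            curve_df.to_csv(outdir / f"trends_{tag}.csv")
            manifest["stages"][stage] = round(time.time() - t0, 3)

            stage = f"qc[{tag}]"
            t0 = _stage(stage)
            markers = [m for m in config.markers if m in smoothed.index]
            report = metrics.quality_report(
                smoothed, pseudo, markers, upper_q=config.upper_q, lower_q=config.lower_q
            )
            reports[tag] = {
                "n_up": report.n_up,
                "n_down": report.n_down,
                "marker_autocorr": report.marker_autocorr,
            }
            manifest["stages"][stage] = round(time.time() - t0, 3)

            if regs is not None and len(regs) > 0:
                stage = f"grn_score[{tag}]"
                t0 = _stage(stage)
                mi = grn_mod.mutual_information_matrix(expr, regs, bins=config.grn_bins)
                net = grn_mod.clr_zscores(mi, regs, z_threshold=config.grn_zmin)
                net.edges.to_csv(outdir / "grn.tsv", sep="\t", index=False)
                scores = grn_mod.score_regulators(net, ranking)
                pd.DataFrame(
                    [
                        {
                            "regulator": s.regulator,
                            "c": s.c,
                            "m": s.m,
                            "n": s.n,
                            "score": s.score,
                            "mechanism": s.mechanism,
                        }
                        for s in scores
                    ]
                ).to_csv(outdir / f"regulator_scores_{tag}.csv", index=False)
                manifest["stages"][stage] = round(time.time() - t0, 3)

        (outdir / "qc.json").write_text(json.dumps(reports, indent=1))
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except io.FlowRouteError as exc:
        raise io.FlowRouteError(f"stage {stage!r} failed: {exc}") from exc
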
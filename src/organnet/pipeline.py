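"""End-to-end pipeline: simulate or load scans, quantify SUV, run the
perturbation and interscan analyses, and write all artifacts plus a run
manifest under one output directory."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deviation_stats import compare_groups_counts, summarize_group
from .interscan import (
    EDGE_THRESHOLD_DEFAULT,
    GRANULARITY_DEFAULT,
    build_graph,
    enrichment,
    interscan_correlation,
    markov_cluster,
    most_similar,
)
from .io import (
    read_records,
    read_suv_table,
    write_matrix,
    write_suv_table,
    write_table,
)
from .perturbation import all_deviations, deviations_long_table, reference_covariance
from .suv import build_suv_table
from .synthetic import VEHICLE_GROUPS, lps_blocking_cohort

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Serializable description of one pipeline run."""

    output_dir: str = "organnet_run"
    # input: either simulate, or a SUV table, or metadata + TAC files
    simulate_seed: int | None = None
    suv_table: str | None = None
    metadata: str | None = None
    tacs: str | None = None
    # analysis parameters
    reference_groups: tuple[str, ...] = VEHICLE_GROUPS
    control_group: str | None = None
    alpha: float = 0.05
    granularity: float = GRANULARITY_DEFAULT
    edge_threshold: float = EDGE_THRESHOLD_DEFAULT
    permutations: int = 10_000
    seed: int = 0
    z_mode: str = "analytic"
    posthoc_variant: str = "pooled"
    frame_weighted: bool = True
    bonferroni_family: str = "groups"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.granularity <= 1:
            raise ValueError("granularity must be > 1")
        if not -1.0 <= self.edge_threshold < 1.0:
            raise ValueError("edge_threshold must be in [-1, 1)")
        sources = [self.simulate_seed is not None, self.suv_table is not None,
                   self.metadata is not None]
        if sum(sources) != 1:
            raise ValueError("exactly one input source required: simulate_seed, suv_table, or metadata+tacs")
        if self.metadata is not None and self.tacs is None:
            raise ValueError("metadata input requires a tacs file")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "reference_groups" in raw:
            raw["reference_groups"] = tuple(raw["reference_groups"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["reference_groups"] = list(self.reference_groups)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _load_table(cfg: PipelineConfig):
    if cfg.simulate_seed is not None:
        records = lps_blocking_cohort(cfg.simulate_seed)
        return build_suv_table(records, weighted=cfg.frame_weighted)
    if cfg.suv_table is not None:
        path = Path(cfg.suv_table)
        if not path.exists():
            raise FileNotFoundError(f"SUV table not found: {path}")
        return read_suv_table(path)
    for p in (cfg.metadata, cfg.tacs):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    records = read_records(cfg.metadata, cfg.tacs)
    return build_suv_table(records, weighted=cfg.frame_weighted)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``manifest.json``)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"version": __version__, "stages": {}}

    stage = "suv"
    try:
        table = _load_table(config)
        write_suv_table(table, out / "suv_table.tsv")
        manifest["stages"][stage] = {
            "n_scans": len(table.scan_ids),
            "n_organs": len(table.organs),
            "groups": {g: int(n) for g, n in table.groups.value_counts().items()},
        }

        stage = "perturbation"
        ref_labels = set(config.reference_groups)
        ref = reference_covariance(table, ref_labels)
        deviations = all_deviations(table, ref_labels, z_mode=config.z_mode)
        zdir = out / "zmatrix"
        zdir.mkdir(exist_ok=True)
        for dev in deviations:
            write_matrix(dev.z_frame(), zdir / f"{dev.scan_id}.tsv")
        write_table(deviations_long_table(deviations, ref), out / "edges.tsv")
        write_matrix(ref.to_frame(), out / "reference_network.tsv")
        n_edges = len(table.organs) * (len(table.organs) - 1) // 2
        manifest["stages"][stage] = {
            "n_reference": ref.n,
            "n_edges": n_edges,
            "n_leave_one_out": sum(d.loo_flag for d in deviations),
            "n_add_one": sum(not d.loo_flag for d in deviations),
        }

        stage = "deviation_stats"
        by_group: dict[str, list] = {}
        for dev in deviations:
            by_group.setdefault(table.groups[dev.scan_id], []).append(dev)
        summaries = {
            g: summarize_group(devs, g, alpha=config.alpha) for g, devs in by_group.items()
        }
        gdir = out / "group_summary"
        gdir.mkdir(exist_ok=True)
        for g, s in summaries.items():
            slug = g.replace(" ", "-")
            write_matrix(
                pd.DataFrame(s.pct_extreme_edge, index=s.organs, columns=s.organs),
                gdir / f"{slug}_pct_extreme_edge.tsv",
            )
            write_matrix(
                pd.DataFrame(s.mean_z, index=s.organs, columns=s.organs),
                gdir / f"{slug}_mean_z.tsv",
            )
        counts = {g: s.counts_per_scan.to_numpy() for g, s in summaries.items()}
        control = config.control_group or next(
            (g for g in config.reference_groups if g in counts), None
        )
        stats_out: dict = {"z_threshold": next(iter(summaries.values())).z_threshold}
        usable = {g: c for g, c in counts.items() if len(c) >= 2}
        if len(usable) >= 2 and control in usable:
            cmp = compare_groups_counts(usable, control, variant=config.posthoc_variant)
            stats_out.update(
                f_statistic=cmp.f_statistic,
                p_value=cmp.p_value,
                control_group=control,
                posthoc=cmp.posthoc.to_dict(orient="records"),
            )
        with open(out / "group_stats.json", "w") as fh:
            json.dump(stats_out, fh, indent=2)
        manifest["stages"][stage] = {
            "n_groups": len(summaries),
            "control_group": control,
        }

        stage = "interscan"
        graph = interscan_correlation(table)
        write_matrix(graph.to_frame(), out / "interscan_corr.tsv")
        assign_most = most_similar(graph)
        best_r = [
            float(graph.corr[i, graph.scan_ids.index(assign_most.iloc[i])])
            for i in range(len(graph.scan_ids))
        ]
        write_table(
            pd.DataFrame(
                {
                    "scan_id": graph.scan_ids,
                    "most_similar_scan_id": assign_most.to_numpy(),
                    "r": best_r,
                }
            ),
            out / "assignation.tsv",
        )
        graph = build_graph(graph, config.edge_threshold)
        write_table(
            pd.DataFrame(
                [
                    (graph.scan_ids[i], graph.scan_ids[j], w)
                    for i, j, w in graph.edges
                ],
                columns=["scan_i", "scan_j", "weight"],
            ),
            out / "graph_edges.tsv",
        )
        clustering = markov_cluster(graph, granularity=config.granularity)
        write_table(
            clustering.assignment.rename("cluster").rename_axis("scan_id").reset_index(),
            out / "clusters.tsv",
        )
        enrich = enrichment(
            clustering,
            table.groups,
            n_permutations=config.permutations,
            seed=config.seed,
            bonferroni_family=config.bonferroni_family,
        )
        write_table(enrich, out / "enrichment.tsv")
        manifest["stages"][stage] = {
            "n_edges": len(graph.edges),
            "n_clusters": clustering.n_clusters,
            "n_enriched": int((enrich.adjusted_p < 0.05).sum()),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    manifest["seed"] = config.seed
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.info("pipeline complete: %s", out)
    return manifest
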
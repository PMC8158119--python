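"""End-to-end orchestration: network analysis, trial statistics, simulation.

Each ``run_*`` function is a plain library call returning an in-memory
report object; when given an output directory it also writes the standard
file bundle plus a manifest (inputs, configuration hash, seeds, package
version) sufficient to reproduce the bundle exactly.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .backbone import SpanningForest, kruskal_backbone
from .config import PipelineConfig
from .corpus import OccurrenceMatrix, builtin_table2, load_occurrence
from .errors import ValidationError
from .hubs import Prescription, assemble_prescription, hub_scores, select_hubs
from .metrics import CommunityPartition, centrality_table, louvain_partition
from .network import WeightedGraph, cooccurrence_graph, export_graph
from .simulate import SyntheticConfig, generate_trial, validate_trial_table
from .stats import (chi_square_2x2, group_summary, linear_regression,
                    wilcoxon_rank_sum)

BASELINE_VARIABLES = ("age", "bmi", "infertility_months", "coh_cycles", "amh", "afc")
OUTCOME_VARIABLES = ("mature_oocytes", "fertilized_oocytes", "amh", "afc")


def _write_manifest(outdir: Path, kind: str, inputs: dict, config_digest: str,
                    seeds: dict) -> None:
    manifest = {"kind": kind, "package_version": __version__,
                "python": platform.python_version(),
                "inputs": inputs, "config_digest": config_digest,
                "seeds": seeds}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


# -- network track ---------------------------------------------------------

@dataclass
class NetworkReport:
    """Everything the network pipeline computes, in memory."""

    matrix: OccurrenceMatrix
    graph: WeightedGraph
    backbone: SpanningForest
    backbone_graph: WeightedGraph
    partition: CommunityPartition
    centrality: pd.DataFrame
    prescription: Prescription

    def summary_text(self) -> str:
        comms = self.partition.communities()
        lines = [
            "Acupoint co-occurrence network analysis",
            "=======================================",
            f"corpus: {self.matrix.n_studies} studies, {self.matrix.n_acupoints} acupoints",
            f"graph: {self.graph.n_nodes} nodes, {self.graph.n_edges} edges",
            f"backbone: {self.backbone.n_edges} edges, "
            f"{self.backbone.n_components} component(s), "
            f"total weight {self.backbone.total_weight:.4f}",
            f"communities: {len(comms)} (Q = {self.partition.Q:.4f})",
        ]
        for i, comm in enumerate(comms):
            lines.append(f"  community {i}: {', '.join(comm)}")
        lines.append(f"hubs: {', '.join(self.prescription.hubs)}")
        lines.append(f"prescription ({len(self.prescription.final_set)} points): "
                     f"{', '.join(self.prescription.final_set)}")
        return "\n".join(lines) + "\n"


def run_network_pipeline(source: str | Path | OccurrenceMatrix | None = None,
                         config: PipelineConfig | None = None,
                         outdir: str | Path | None = None) -> NetworkReport:
    """Corpus -> weighted network -> backbone -> communities -> prescription.

    ``source`` is an OccurrenceMatrix, a wide-CSV path, or None for the
    packaged corpus.  With ``outdir`` the standard bundle is written:
    adjacency CSV (full weights upper triangle, backbone lower), backbone
    GraphML and edge list, a combined centrality/partition CSV, the
    prescription JSON and a text summary.
    """
    config = config or PipelineConfig()
    if source is None:
        matrix = builtin_table2()
        source_desc = "builtin:table2"
    elif isinstance(source, OccurrenceMatrix):
        matrix = source
        source_desc = "in-memory"
    else:
        matrix = load_occurrence(source, format="wide")
        source_desc = str(source)

    graph = cooccurrence_graph(matrix, mode=config.proportion_mode,
                               min_weight=config.min_weight)
    backbone = kruskal_backbone(graph, objective=config.backbone_objective)
    bgraph = backbone.as_graph(graph)
    if bgraph.n_edges > 0:
        partition = louvain_partition(bgraph, gamma=config.gamma,
                                      use_weights=config.use_weights,
                                      order_policy=config.louvain_order,
                                      seed=config.louvain_seed,
                                      restarts=config.restarts)
    else:  # edgeless: every node its own community
        partition = CommunityPartition(
            {u: i for i, u in enumerate(bgraph.nodes)}, Q=0.0, gamma=config.gamma)
    centrality = centrality_table(bgraph)
    scores = hub_scores(centrality)
    centrality = centrality.assign(
        community=pd.Series(partition.assignment), hub_score=scores)
    hubs = select_hubs(scores, partition, mode=config.hub_mode, k=config.top_k)
    prescription = assemble_prescription(hubs, list(config.supplementary))
    report = NetworkReport(matrix, graph, backbone, bgraph, partition,
                           centrality, prescription)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        export_graph(graph, "adjacency-csv", outdir / "adjacency.csv",
                     backbone=backbone)
        export_graph(bgraph, "graphml", outdir / "backbone.graphml")
        export_graph(bgraph, "edge-list", outdir / "backbone_edges.tsv")
        cols = ["community", "degree", "strength",
                "betweenness_raw", "betweenness_norm", "hub_score"]
        centrality[cols].to_csv(outdir / "centrality.csv",
                                index_label="node")
        (outdir / "prescription.json").write_text(prescription.to_json() + "\n")
        (outdir / "summary.txt").write_text(report.summary_text())
        _write_manifest(outdir, "network", {"source": source_desc},
                        config.digest(), {"louvain_seed": config.louvain_seed})
    return report


# -- trial statistics track ------------------------------------------------

@dataclass
class TrialReport:
    """Baseline, outcome, subgroup and regression results for one trial table."""

    baseline: pd.DataFrame
    outcomes: pd.DataFrame
    fertilization_test: object
    subgroup_age: pd.DataFrame | None
    subgroup_cycles: dict[int, pd.DataFrame]
    regressions: dict[str, pd.DataFrame]

    def summary_text(self) -> str:
        parts = ["Trial analysis", "==============", "",
                 "Baseline characteristics (mean ± SD, rank-sum p):",
                 self.baseline.to_string(), "",
                 "Outcomes:", self.outcomes.to_string(), ""]
        ft = self.fertilization_test
        if ft is not None:
            parts.append(f"Fertilization rate chi-square: statistic="
                         f"{ft.statistic:.4f}, p={ft.p_value:.4f}")
        if self.subgroup_age is not None:
            parts += ["", "Subgroup age > 37:", self.subgroup_age.to_string()]
        for k, tab in self.subgroup_cycles.items():
            parts += ["", f"Subgroup cycles >= {k}:", tab.to_string()]
        for arm, fit in self.regressions.items():
            parts += ["", f"Regression (mature ~ cycles + age), arm {arm}:",
                      fit.to_string()]
        return "\n".join(parts) + "\n"


def _fertilization_counts(table: pd.DataFrame) -> tuple[int, int, int, int]:
    ivf = table[table["arm"] == "IVF"]
    ac = table[table["arm"] == "AcIVF"]
    a = int(ivf["fertilized_oocytes"].sum())
    b = int(ivf["mature_oocytes"].sum()) - a
    c = int(ac["fertilized_oocytes"].sum())
    d = int(ac["mature_oocytes"].sum()) - c
    return a, b, c, d


def run_trial_analysis(trial: str | Path | pd.DataFrame,
                       config: PipelineConfig | None = None,
                       outdir: str | Path | None = None) -> TrialReport:
    """Baseline table, outcome comparison, the age > 37 and cycles >= k
    subgroups (k = 1..5), and per-arm regressions of the count outcomes on
    cycles and age."""
    config = config or PipelineConfig()
    if isinstance(trial, (str, Path)):
        table = pd.read_csv(trial)
        source_desc = str(trial)
    else:
        table = trial
        source_desc = "in-memory"
    validate_trial_table(table)

    baseline = group_summary(table, list(BASELINE_VARIABLES))
    outcomes = group_summary(table, list(OUTCOME_VARIABLES))
    a, b, c, d = _fertilization_counts(table)
    fert = None
    if min(a + b, c + d) > 0 and (a + c) > 0 and (b + d) > 0:
        fert = chi_square_2x2(a, b, c, d, yates=config.yates)

    sub_age = None
    aged = table[table["age"] > 37]
    if (aged["arm"] == "IVF").sum() >= 2 and (aged["arm"] == "AcIVF").sum() >= 2:
        sub_age = group_summary(aged, ["mature_oocytes", "fertilized_oocytes"])

    sub_cycles: dict[int, pd.DataFrame] = {}
    for k in range(1, 6):
        sub = table[table["coh_cycles"] >= k]
        if (sub["arm"] == "IVF").sum() >= 2 and (sub["arm"] == "AcIVF").sum() >= 2:
            sub_cycles[k] = group_summary(sub, ["mature_oocytes", "fertilized_oocytes"])

    regressions: dict[str, pd.DataFrame] = {}
    for arm in ("IVF", "AcIVF"):
        sub = table[table["arm"] == arm]
        if len(sub) >= 4:
            fit = linear_regression(sub["mature_oocytes"],
                                    sub[["coh_cycles", "age"]].to_numpy(),
                                    names=["coh_cycles", "age"])
            regressions[arm] = fit.summary_frame()

    report = TrialReport(baseline, outcomes, fert, sub_age, sub_cycles, regressions)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        baseline.to_csv(outdir / "baseline.csv")
        outcomes.to_csv(outdir / "outcomes.csv")
        if sub_age is not None:
            sub_age.to_csv(outdir / "subgroup_age_gt37.csv")
        for k, tab in sub_cycles.items():
            tab.to_csv(outdir / f"subgroup_cycles_ge{k}.csv")
        for arm, fit in regressions.items():
            fit.to_csv(outdir / f"regression_{arm}.csv")
        (outdir / "report.txt").write_text(report.summary_text())
        _write_manifest(outdir, "stats", {"trial": source_desc},
                        config.digest(), {})
    return report


# -- simulation track -------------------------------------------------------

def run_simulation(config: SyntheticConfig, replicates: int,
                   seed: int | None = None,
                   outdir: str | Path | None = None) -> pd.DataFrame:
    """Repeatedly generate trials and test them; one row per replicate.

    Columns: replicate seed, per-arm mature-oocyte means, exact rank-sum
    p-value for the arm comparison, and per-arm OLS cycle-slope estimates
    with p-values.  The aggregate rejection rate at alpha = 0.05 is
    attached as ``df.attrs['rejection_rate']``.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    root = np.random.default_rng(seed)
    rows = []
    for _ in range(replicates):
        rep_seed = int(root.integers(0, 2 ** 31 - 1))
        table = generate_trial(config, seed=rep_seed)
        ivf = table[table["arm"] == "IVF"]["mature_oocytes"].to_numpy(float)
        ac = table[table["arm"] == "AcIVF"]["mature_oocytes"].to_numpy(float)
        res = wilcoxon_rank_sum(ivf, ac, mode="auto")
        row = {"seed": rep_seed,
               "mean_ivf": ivf.mean() if len(ivf) else np.nan,
               "mean_ac": ac.mean() if len(ac) else np.nan,
               "ranksum_p": res.p_value}
        for arm in ("IVF", "AcIVF"):
            sub = table[table["arm"] == arm]
            if len(sub) >= 4:
                fit = linear_regression(sub["mature_oocytes"],
                                        sub[["coh_cycles", "age"]].to_numpy(),
                                        names=["coh_cycles", "age"])
                idx = fit.names.index("coh_cycles")
                row[f"slope_{arm}"] = fit.coef[idx]
                row[f"slope_p_{arm}"] = fit.p[idx]
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["rejection_rate"] = float((df["ranksum_p"] < 0.05).mean())
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "simulation.csv", index=False)
        agg = {"replicates": replicates,
               "rejection_rate_alpha05": df.attrs["rejection_rate"],
               "mean_ivf": float(df["mean_ivf"].mean()),
               "mean_ac": float(df["mean_ac"].mean())}
        with open(outdir / "simulation_summary.json", "w") as fh:
            json.dump(agg, fh, indent=2)
        _write_manifest(outdir, "simulate",
                        {"config": config.to_dict()}, "-", {"seed": seed})
    return df
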
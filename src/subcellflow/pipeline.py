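"""End-to-end orchestration: simulate (optional) -> preprocess ->
differential testing -> translocation calling -> compartment assignment
-> group distributions, writing every stage output plus a run manifest."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compartments import (assign_clusters, cluster_profiles, max_normalize,
                           score_compartments)
from .core import QuantTable, SampleDesign
from .diffstats import fit_moderated
from .diststats import group_fraction_percentages
from .io import (PipelineConfig, config_to_dict, read_group_members,
                 read_markers, read_quant_table, write_design,
                 write_json, write_markers, write_quant_table)
from .preprocess import preprocess
from .simulate import (SyntheticTruth, apply_missingness, default_templates,
                       generate_truth, simulate_intensities)
from .translocation import (call_translocations, per_fraction_pvalues,
                            scale_profiles)

__all__ = ["run_pipeline", "simulate_dataset", "markers_from_truth",
           "evaluate_recovery", "PipelineResult"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    table: QuantTable
    calls: dict[str, pd.DataFrame]
    assignment: pd.DataFrame | None
    compartment_scores: pd.DataFrame | None
    distributions: dict[str, pd.DataFrame]
    manifest: dict
    truth: SyntheticTruth | None = None


def simulate_dataset(cfg: PipelineConfig) -> tuple[QuantTable, SyntheticTruth]:
    """Build the configured synthetic experiment (intensities + dropout)."""
    templates = default_templates(cfg.sim_n_fractions, cfg.sim_spillover)
    onset = cfg.sim_conditions[1] if len(cfg.sim_conditions) > 1 else cfg.sim_conditions[0]
    truth = generate_truth(
        n_features=cfg.sim_n_features,
        templates=templates,
        frac_translocating=cfg.sim_frac_translocating,
        delta_range=(cfg.sim_delta_min, cfg.sim_delta_max),
        seed=cfg.seed,
        onset=onset,
        mcar_rate=cfg.sim_mcar_rate,
        mnar_midpoint=cfg.sim_mnar_midpoint,
        mnar_slope=cfg.sim_mnar_slope,
    )
    design = SampleDesign.from_layout(
        n_fractions=cfg.sim_n_fractions,
        conditions=cfg.sim_conditions,
        n_replicates=cfg.sim_n_replicates,
    )
    table = simulate_intensities(truth, design, noise_sd=cfg.sim_noise_sd,
                                 seed=cfg.seed + 1)
    table = apply_missingness(table, truth, seed=cfg.seed + 2)
    return table, truth


def markers_from_truth(
    truth: SyntheticTruth, per_compartment: int = 10
) -> dict[str, str]:
    """Marker list from the simulator's ground truth: the first
    ``per_compartment`` non-translocating features of each compartment."""
    moving = truth.translocating_features
    markers: dict[str, str] = {}
    counts: dict[str, int] = {}
    for feat in truth.features:
        comp = truth.compartment[feat]
        if feat in moving or counts.get(comp, 0) >= per_compartment:
            continue
        markers[feat] = comp
        counts[comp] = counts.get(comp, 0) + 1
    return markers


def evaluate_recovery(cfg: PipelineConfig) -> dict:
    """Simulate, analyze, and score the translocation caller against the
    simulator's ground truth.

    Returns sensitivity (injected translocators recovered), the empirical
    false-discovery proportion among calls, and the call count, at the
    configured thresholds.
    """
    table, truth = simulate_dataset(cfg)
    clean = preprocess(
        table, min_valid=cfg.min_valid, span=cfg.loess_span,
        iterations=cfg.loess_iterations, k_neighbors=cfg.k_neighbors,
        quantile=cfg.quantile,
    )
    reference = cfg.reference_condition
    pvalues = per_fraction_pvalues(clean, reference, min_valid=cfg.min_valid)
    profiles = scale_profiles(clean)
    calls = call_translocations(
        profiles, reference, pvalues, score_min=cfg.score_min,
        fdr_max=cfg.fdr_max, variant=cfg.score_variant,
    )
    injected = truth.translocating_features
    called: set[str] = set()
    for res in calls.values():
        called |= set(res.index[res["called"]])
    tp = len(called & injected)
    return {
        "n_injected": len(injected),
        "n_called": len(called),
        "true_positives": tp,
        "sensitivity": tp / len(injected) if injected else float("nan"),
        "fdr": (len(called) - tp) / len(called) if called else 0.0,
    }


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute every stage and write all declared outputs under ``outdir``.

    Stage failures abort with the stage name and cause. Two runs with an
    identical config produce identical outputs and manifests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.validate()
    manifest: dict = {
        "tool": "subcellflow",
        "version": __version__,
        "config": config_to_dict(cfg),
        "stages": {},
    }
    truth = None
    markers = None
    groups: dict[str, list[str]] = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {}
            log.info("stage %s done (%.2fs)", name, time.perf_counter() - t0)
            return out
        return wrap

    if cfg.matrix is None:
        def _simulate():
            table, tr = simulate_dataset(cfg)
            write_quant_table(table, outdir / "simulated_matrix.tsv")
            write_design(table.design, outdir / "design.tsv")
            write_json(
                {
                    "compartment": tr.compartment.to_dict(),
                    "abundance": tr.abundance.round(6).to_dict(),
                    "translocations": [
                        {"feature": s.feature, "donor": s.donor,
                         "acceptor": s.acceptor, "delta": s.delta,
                         "onset": s.onset}
                        for s in tr.specs
                    ],
                    "mcar_rate": tr.mcar_rate,
                    "mnar_midpoint": tr.mnar_midpoint,
                    "mnar_slope": tr.mnar_slope,
                },
                outdir / "truth.json",
            )
            return table, tr
        raw, truth = stage("simulate")(_simulate)
        markers = markers_from_truth(truth)
        write_markers(markers, outdir / "markers.tsv")
    else:
        raw = stage("read")(
            lambda: read_quant_table(cfg.matrix, cfg.design,
                                     linear=cfg.values_are_linear)
        )
        if cfg.markers:
            markers = read_markers(cfg.markers)
    if cfg.groups:
        groups = {"group": read_group_members(cfg.groups)}

    table = stage("preprocess")(
        lambda: preprocess(
            raw, min_valid=cfg.min_valid, span=cfg.loess_span,
            iterations=cfg.loess_iterations, k_neighbors=cfg.k_neighbors,
            quantile=cfg.quantile,
        )
    )
    write_quant_table(table, outdir / "preprocessed_matrix.tsv")
    manifest["stages"]["preprocess"]["n_features"] = int(len(table.features))

    reference = cfg.reference_condition
    design = table.design

    def _diff():
        pvals = per_fraction_pvalues(table, reference, min_valid=cfg.min_valid)
        for condition in pvals:
            for fraction in design.fractions:
                fit = fit_moderated(table, condition, reference, fraction,
                                    min_valid=cfg.min_valid)
                out = fit.table[["logFC", "t", "df_total", "p", "q",
                                 "n_a", "n_b"]]
                out.rename_axis("feature").to_csv(
                    outdir / f"diff_{condition}_vs_{reference}_FR{fraction}.tsv",
                    sep="\t",
                )
        return pvals
    pvalues = stage("diffstats")(_diff)

    def _translocate():
        profiles = scale_profiles(table, design)
        calls = call_translocations(
            profiles, reference, pvalues,
            score_min=cfg.score_min, fdr_max=cfg.fdr_max,
            variant=cfg.score_variant,
        )
        summary = {"score_min": cfg.score_min, "fdr_max": cfg.fdr_max,
                   "score_variant": cfg.score_variant, "conditions": {}}
        for condition, res in calls.items():
            res.rename_axis("feature").to_csv(
                outdir / f"translocation_{condition}_vs_{reference}.tsv", sep="\t"
            )
            called = res[res["called"]]
            summary["conditions"][condition] = {
                "n_called": int(len(called)),
                "per_category": called["category"].value_counts().to_dict(),
            }
        write_json(summary, outdir / "translocation_summary.json")
        return profiles, calls
    profiles, calls = stage("translocate")(_translocate)

    assignment = scores = None
    if markers:
        def _assign():
            ref_prof = profiles.profiles[reference].dropna()
            normalized = max_normalize(ref_prof)
            n_comp = len(set(markers.values()))
            k = cfg.kmeans_k or 2 * n_comp
            labels = cluster_profiles(normalized, k=k,
                                      restarts=cfg.kmeans_restarts, seed=cfg.seed)
            report = assign_clusters(labels, markers)
            scores = score_compartments(report, markers)
            report.clusters.to_csv(outdir / "cluster_assignment.tsv", sep="\t")
            scores.to_csv(outdir / "compartment_scores.tsv", sep="\t")
            write_json(
                {"k": k, "restarts": cfg.kmeans_restarts,
                 "fscore_2dp": scores["fscore_2dp"].to_dict()},
                outdir / "compartment_scores.json",
            )
            return report.clusters, scores
        assignment, scores = stage("assign")(_assign)

    distributions: dict[str, pd.DataFrame] = {}
    if groups:
        def _diststats():
            out = {}
            for name, members in groups.items():
                dist = group_fraction_percentages(table, members, design,
                                                  group=name)
                dist.table.to_csv(outdir / f"distribution_{name}.tsv",
                                  sep="\t", index=False)
                out[name] = dist.table
            return out
        distributions = stage("diststats")(_diststats)

    write_json(manifest, outdir / "manifest.json")
    return PipelineResult(
        table=table, calls=calls, assignment=assignment,
        compartment_scores=scores, distributions=distributions,
        manifest=manifest, truth=truth,
    )
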
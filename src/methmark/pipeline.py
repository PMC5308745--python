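"""End-to-end orchestration: simulate/load -> QC -> DMP -> DE -> integrate.

One structured config drives every stage; identical config + seed yields
byte-identical outputs. Each stage writes its table under the output
directory and the run manifest records row counts, filter tallies and,
for simulated cohorts, driver-gene recovery against the planted truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .dexp import call_degs, moderated_paired_test, normalize_expression
from .dmp import call_dmps, cluster_samples, filter_probes, summarize_regions
from .integrate import classify_inverse, promoter_proxy, select_markers
from .io import (
    BetaMatrix,
    ExpressionMatrix,
    ProbeAnnotationTable,
    SampleDesign,
    read_beta_matrix,
    read_design,
    read_expression_matrix,
    write_results_table,
)
from .simulate import SimulationConfig, simulate_cohort


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and inputs for a full run.

    Either ``simulation`` is set (synthetic cohort) or the four input
    paths are. Stage thresholds default to the screening rules: delta
    beta 0.2, alpha 0.05 on the raw signed-rank p (see
    :mod:`methmark.dmp` for why raw p is the default gate at small n),
    fold change 2 with BH FDR 0.05, and a strictly-more-than-2 promoter
    DMP count for the marker panel.
    """

    outdir: str | Path
    simulation: SimulationConfig | None = None
    beta_path: str | Path | None = None
    detection_p_path: str | Path | None = None
    annotation_path: str | Path | None = None
    expression_path: str | Path | None = None
    design_path: str | Path | None = None
    detection_threshold: float = 0.05
    delta_threshold: float = 0.2
    alpha: float = 0.05
    gate: str = "raw_p"
    fc_threshold: float = 2.0
    deg_alpha: float = 0.05
    min_probes_exclusive: int = 2
    quantile_normalize: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.detection_threshold < 1:
            raise ValueError("detection_threshold must be in (0, 1)")
        if not 0 <= self.delta_threshold <= 1:
            raise ValueError("delta_threshold must be in [0, 1]")
        for name, a in (("alpha", self.alpha), ("deg_alpha", self.deg_alpha)):
            if not 0 < a < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.gate not in ("raw_p", "fdr"):
            raise ValueError("gate must be 'raw_p' or 'fdr'")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.min_probes_exclusive < 0:
            raise ValueError("min_probes_exclusive must be >= 0")
        have_paths = all(
            p is not None
            for p in (self.beta_path, self.annotation_path, self.expression_path, self.design_path)
        )
        if (self.simulation is None) == (not have_paths):
            raise ValueError("set either simulation or all four input paths")


def _load_inputs(
    cfg: PipelineConfig,
) -> tuple[BetaMatrix, ProbeAnnotationTable, ExpressionMatrix, SampleDesign, object | None]:
    if cfg.simulation is not None:
        beta, ann, expr, design, truth = simulate_cohort(cfg.simulation)
        return beta, ann, expr, design, truth
    beta, ann, _dropped = read_beta_matrix(
        cfg.beta_path, cfg.annotation_path, cfg.detection_p_path
    )
    expr = read_expression_matrix(cfg.expression_path)
    design = read_design(cfg.design_path)
    return beta, ann, expr, design, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order and return the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.simulation.seed if cfg.simulation is not None else None,
        "gate": cfg.gate,
        "stages": {},
    }
    stage = "load"
    try:
        beta, ann, expr, design, truth = _load_inputs(cfg)
        manifest["stages"]["load"] = {
            "n_probes": len(beta.probe_ids),
            "n_samples": len(beta.sample_ids),
            "n_pairs": len(design.pairs()),
            "n_expression_features": len(expr.intensity),
        }

        stage = "filter_probes"
        beta_f, filter_report = filter_probes(beta, ann, cfg.detection_threshold)
        manifest["stages"]["filter_probes"] = {
            "removed": filter_report,
            "n_retained": len(beta_f.probe_ids),
        }

        stage = "call_dmps"
        dmps = call_dmps(
            beta_f, design, delta_threshold=cfg.delta_threshold, alpha=cfg.alpha, gate=cfg.gate
        )
        write_results_table(dmps.drop(columns=["degenerate"]), outdir / "dmp.tsv")
        n_hyper = int((dmps["direction"] == "hyper").sum())
        n_hypo = int((dmps["direction"] == "hypo").sum())
        manifest["stages"]["call_dmps"] = {
            "n_tested": len(dmps),
            "n_skipped": len(dmps.attrs.get("skipped_probes", [])),
            "n_hyper": n_hyper,
            "n_hypo": n_hypo,
            "n_degenerate": int(dmps["degenerate"].sum()),
        }

        stage = "summarize_regions"
        summary = summarize_regions(dmps, ann)
        ctx = pd.concat(
            [summary.region_fractions, summary.cgi_fractions,
             summary.promoter_fraction.rename("promoter"),
             summary.cgi_related_fraction.rename("cgi_related")],
            axis=1,
        )
        write_results_table(ctx.rename_axis("direction"), outdir / "context.tsv")

        stage = "cluster_samples"
        called_ids = dmps.index[dmps["direction"] != "none"]
        if len(called_ids) >= 2:
            tree = cluster_samples(beta_f.subset_probes(called_ids))
            manifest["stages"]["cluster_samples"] = {"leaf_order": tree.leaf_order}

        stage = "differential_expression"
        log_expr = normalize_expression(expr, quantile=cfg.quantile_normalize)
        mod = moderated_paired_test(log_expr, design)
        degs = call_degs(mod, fc_threshold=cfg.fc_threshold, alpha=cfg.deg_alpha)
        write_results_table(degs, outdir / "degs.tsv")
        manifest["stages"]["differential_expression"] = {
            "n_genes": len(degs),
            "n_up": int((degs["direction"] == "up").sum()),
            "n_down": int((degs["direction"] == "down").sum()),
            "d0": round(mod.attrs["d0"], 6) if mod.attrs["d0"] != float("inf") else "inf",
        }

        stage = "integration"
        proxies = promoter_proxy(dmps, ann)
        candidates = classify_inverse(proxies, degs)
        markers = select_markers(candidates, min_probes_exclusive=cfg.min_probes_exclusive)
        write_results_table(candidates, outdir / "candidates.tsv")
        # marker table keeps its publication order (probe count desc)
        markers.reset_index().to_csv(outdir / "markers.tsv", sep="\t", index=False,
                                     float_format="%.6g")
        manifest["stages"]["integration"] = {
            "n_aberrant_genes": len(candidates),
            "n_inverse": int(candidates["inverse"].sum()),
            "inverse_fraction": round(candidates.attrs["inverse_fraction"], 6)
            if len(candidates) else None,
            "n_selected": len(markers),
        }

        if truth is not None:
            stage = "truth_comparison"
            planted = set(truth.driver_genes)
            selected = set(markers.index)
            tp = len(planted & selected)
            manifest["stages"]["truth_comparison"] = {
                "n_planted_drivers": len(planted),
                "n_selected": len(selected),
                "driver_sensitivity": round(tp / len(planted), 6) if planted else None,
                "driver_precision": round(tp / len(selected), 6) if selected else None,
            }
            truth.driver_table().to_csv(outdir / "truth_drivers.tsv", sep="\t", index=False)
            truth.truth_table().to_csv(outdir / "truth_dmps.tsv", sep="\t", index=False,
                                       float_format="%.6g")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
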
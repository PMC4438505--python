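"""End-to-end orchestration: simulate/read -> QC -> screen -> select ->
evaluate -> cluster -> power, with every intermediate written out.

A single master seed fans out to independent per-stage substreams so that
stages re-run individually reproduce the full run's intermediates.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .arrays import read_gpr
from .classify import (
    cross_validate_models,
    evaluate_panel,
    evaluate_single_genes,
    metrics_to_frame,
    rank_and_select_panel,
)
from .cluster import cluster_and_concordance, majority_purity, to_newick
from .differential import apply_cutoffs, differential_table, results_to_frame
from .layout import default_layout
from .power import panel_power
from .preprocess import (
    MethylationMatrix,
    build_matrix,
    categorize_calls,
    preprocess_sample,
)
from .synthetic import CohortConfig, generate_cohort, read_labels, write_cohort


@dataclass
class Thresholds:
    """Every numeric cutoff used by any stage (no hidden constants)."""

    control_multiplier: float = 2.0
    min_informative_spots: int = 2
    max_missing_frac: float = 0.25
    fc_min: float = 1.5
    p_max: float = 0.05
    vip_min: float = 1.0
    call_threshold_log2: float = 1.0
    alpha: float = 0.05
    lowess: bool = True
    lowess_frac: float = 0.4
    lowess_iterations: int = 3


@dataclass
class PipelineConfig:
    cohort: Optional[CohortConfig] = None  # simulate when set
    input_dir: Optional[str] = None  # otherwise read GPRs + labels from here
    thresholds: Thresholds = field(default_factory=Thresholds)
    cv_folds: int = 5
    cv_runs: int = 10
    run_model_comparison: bool = True
    seed: int = 0
    output_dir: str = "methdet_run"

    def __post_init__(self) -> None:
        if self.cohort is None and self.input_dir is None:
            self.cohort = CohortConfig()


@dataclass
class RunReport:
    config_hash: str
    seed: int
    version: str
    stage_counts: Dict[str, int]
    candidate_table: pd.DataFrame
    cv_table: pd.DataFrame
    best_model: Optional[str]
    panel: List[str]
    metrics_table: pd.DataFrame
    concordance: pd.DataFrame
    branch_purity: Optional[float]
    power_panel: Optional[dict]
    power_table: pd.DataFrame

    def summary(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stage_counts": self.stage_counts,
            "candidates": self.candidate_table.reset_index().to_dict("records"),
            "cv": self.cv_table.to_dict("records"),
            "best_model": self.best_model,
            "panel": self.panel,
            "metrics": self.metrics_table.to_dict("records"),
            "concordance": self.concordance.reset_index().to_dict("records")
            if not self.concordance.empty
            else [],
            "branch_purity": self.branch_purity,
            "power_panel": self.power_panel,
            "power_per_gene": self.power_table.reset_index().to_dict("records"),
        }


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(type(o))

    fields = dataclasses.asdict(config)
    fields.pop("output_dir", None)  # the output path is not part of the analysis
    payload = json.dumps(fields, sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seeds(seed: int, n: int = 4) -> List[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def load_input_dir(input_dir: Path | str):
    """Read a directory of per-sample GPR files plus labels.tsv."""
    input_dir = Path(input_dir)
    labels = read_labels(input_dir / "labels.tsv")
    layout = default_layout()
    arr_dir = input_dir / "arrays" if (input_dir / "arrays").is_dir() else input_dir
    arrays = {}
    for sid in labels.index:
        arrays[sid] = read_gpr(arr_dir / f"{sid}.gpr", layout, sample_id=sid)
    return arrays, labels


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order, writing intermediates to output_dir.

    Bit-identical report on re-run with the same config and seed. Stages
    that lose their inputs to aggressive thresholds (e.g. an empty candidate
    set) are skipped with consistent empty outputs rather than aborting.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_sim, seed_cv, seed_select, seed_eval = _stage_seeds(config.seed)
    thr = config.thresholds
    counts: Dict[str, int] = {}

    # --- acquire arrays -------------------------------------------------
    if config.cohort is not None:
        cohort_cfg = dataclasses.replace(config.cohort, seed=seed_sim)
        cohort = generate_cohort(cohort_cfg)
        write_cohort(cohort, out)
        arrays, labels = cohort.arrays, cohort.labels
    else:
        arrays, labels = load_input_dir(config.input_dir)
    counts["samples_in"] = len(arrays)
    counts["relapse"] = int((labels == "relapse").sum())

    # --- preprocess ------------------------------------------------------
    summaries = {
        sid: preprocess_sample(
            arr,
            control_multiplier=thr.control_multiplier,
            min_informative_spots=thr.min_informative_spots,
        )
        for sid, arr in arrays.items()
    }
    counts["informative_spots"] = int(
        sum(s["n_informative"].sum() for s in summaries.values())
    )
    matrix = build_matrix(
        summaries,
        max_missing_frac=thr.max_missing_frac,
        normalize=thr.lowess,
        lowess_frac=thr.lowess_frac,
        lowess_iterations=thr.lowess_iterations,
    )
    matrix = categorize_calls(matrix, threshold_log2=thr.call_threshold_log2)
    counts["genes_retained"] = len(matrix.genes)
    counts["samples_retained"] = len(matrix.samples)
    matrix.to_tsv(out / "matrix.tsv")
    matrix.calls.rename_axis("gene_id").to_csv(out / "calls.tsv", sep="\t", na_rep="NA")

    # --- differential screen ----------------------------------------------
    diff = differential_table(matrix, labels)
    candidates = apply_cutoffs(diff, fc_min=thr.fc_min, p_max=thr.p_max)
    counts["genes_tested"] = len(diff)
    counts["candidates"] = len(candidates)
    results_to_frame(diff).to_csv(out / "differential.tsv", sep="\t", na_rep="NA")
    candidate_table = results_to_frame(candidates.results)
    candidate_table.to_csv(out / "candidates.tsv", sep="\t", na_rep="NA")

    # --- model comparison + panel selection -------------------------------
    cv_table = pd.DataFrame(columns=["family", "auc_mean"])
    best_name: Optional[str] = None
    panel: List[str] = []
    metrics_table = pd.DataFrame()
    concordance = pd.DataFrame()
    purity: Optional[float] = None
    power_panel_dict: Optional[dict] = None
    power_table = pd.DataFrame()

    if len(candidates) >= 2:
        if config.run_model_comparison:
            cv_matrix = MethylationMatrix(values=matrix.values.loc[candidates.genes])
            cv_results, best = cross_validate_models(
                cv_matrix, labels, k=config.cv_folds, runs=config.cv_runs, seed=seed_cv
            )
            cv_table = pd.DataFrame(
                [
                    {
                        "family": r.model.family,
                        "auc_mean": r.auc_mean,
                        **{f"run_{i + 1}": a for i, a in enumerate(r.auc_per_run)},
                    }
                    for r in cv_results
                ]
            )
            best_name = best.family
        ranking, panel = rank_and_select_panel(
            matrix,
            labels,
            candidate_genes=candidates.genes,
            vip_min=thr.vip_min,
            cv_k=config.cv_folds,
            cv_runs=config.cv_runs,
            seed=seed_select,
        )
        ranking.scores.rename_axis("gene_id").to_csv(out / "vip.tsv", sep="\t")
        (out / "panel.txt").write_text("\n".join(panel) + "\n")
    else:
        warnings.warn("fewer than 2 screen survivors; classifier stages skipped")
    cv_table.to_csv(out / "model_comparison.tsv", sep="\t", index=False)
    counts["panel_size"] = len(panel)

    # --- panel evaluation, clustering, power ------------------------------
    if panel:
        metrics = []
        m_resub, roc = evaluate_panel(
            matrix, labels, panel, mode="resubstitution", seed=seed_eval
        )
        m_cv, _ = evaluate_panel(
            matrix, labels, panel, mode="cross_validated", k=config.cv_folds,
            seed=seed_eval,
        )
        metrics += [m_resub, m_cv]
        metrics += evaluate_single_genes(matrix, labels, panel, mode="resubstitution")
        metrics_table = metrics_to_frame(metrics)
        metrics_table.to_csv(out / "metrics.tsv", sep="\t", index=False, na_rep="NA")
        roc.to_csv(out / "roc.tsv", sep="\t", index=False)

        report = cluster_and_concordance(matrix, labels, panel)
        concordance = report.concordance
        purity = majority_purity(report)
        concordance.to_csv(out / "concordance.tsv", sep="\t")
        (out / "dendrogram.nwk").write_text(to_newick(report) + "\n")

        p_res, power_table = panel_power(matrix, labels, panel, alpha=thr.alpha)
        power_panel_dict = dataclasses.asdict(p_res)
        power_table.to_csv(out / "power.tsv", sep="\t")

    report = RunReport(
        config_hash=_config_hash(config),
        seed=config.seed,
        version=__version__,
        stage_counts=counts,
        candidate_table=candidate_table,
        cv_table=cv_table,
        best_model=best_name,
        panel=panel,
        metrics_table=metrics_table,
        concordance=concordance,
        branch_purity=purity,
        power_panel=power_panel_dict,
        power_table=power_table,
    )
    (out / "report.json").write_text(json.dumps(report.summary(), indent=2) + "\n")
    return report
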
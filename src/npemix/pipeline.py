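"""End-to-end orchestration: simulate/load → preprocess → select L → fit →
classify → stability → report.

``run_pipeline`` is the library entry point; the command-line interface in
:mod:`npemix.cli` is a thin wrapper over it.  Every stage's parameters and
outputs are logged, all randomness flows from explicit seeds in the config,
and rerunning with the same config reproduces every number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as pp
from .classify import UNCLASSIFIED, assignments_to_frame, classify
from .model_selection import records_to_frame, sweep_L
from .npem import NpemConfig, fit
from .stability import loo_feature, loo_individual, silhouette
from .synthetic import SyntheticConfig, cas_like_default, generate, write_truth_csv

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; defaults follow the published procedure
    (feature filter 0.20, subject filter 0.30, classification threshold 0.90,
    stability seeds 1..10)."""

    # input: either paths to data+meta CSVs, or a synthetic config
    data_csv: str | None = None
    meta_csv: str | None = None
    synthetic: SyntheticConfig | None = None

    feature_missing_threshold: float = 0.20
    subject_missing_threshold: float = 0.30

    seed: int = 1
    max_iter: int = 500
    tol: float = 1e-6

    l_min: int = 1
    l_max: int = 20
    n_clusters: int | None = None    # skip the sweep when set

    classification_threshold: float = 0.90

    stability_seeds: list[int] = field(default_factory=lambda: list(range(1, 11)))
    stability_stride: int = 1        # subsample left-out entities
    run_stability: bool = True

    output_dir: str = "npemix_out"


def _load_or_simulate(config: RunConfig, outdir: Path):
    if config.synthetic is not None:
        cohort = generate(config.synthetic)
        pp.write_cohort_csv(cohort.table, outdir / "cohort.csv",
                            outdir / "cohort_meta.csv")
        write_truth_csv(cohort, outdir / "cohort_truth.csv")
        return cohort.table
    if config.data_csv is None or config.meta_csv is None:
        raise ValueError("need either synthetic config or data+meta CSV paths")
    return pp.read_cohort_csv(config.data_csv, config.meta_csv)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the machine-readable summary dict."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    raw = _load_or_simulate(config, outdir)
    roster = raw.clustering_roster()
    logger.info("loaded %d subjects x %d features (%d in roster)",
                raw.n_subjects, raw.n_features, roster.n_features)

    # --- preprocess ----------------------------------------------------
    transformed = pp.apply_assay_transforms(roster)
    filtered = pp.filter_features(transformed, config.feature_missing_threshold)
    removed_features = [c for c in roster.data.columns
                        if c not in filtered.data.columns]
    filtered = pp.filter_subjects(filtered, config.subject_missing_threshold)
    removed_subjects = [s for s in roster.data.index
                        if s not in filtered.data.index]
    complete, low_miss = pp.split_complete_low_missing(filtered)
    stats = pp.compute_reference_stats(complete.data)
    train = pp.scale(complete.data, stats)
    test = pp.scale(low_miss.data, stats) if low_miss.n_subjects else None
    pp.write_preprocess_sidecar(outdir / "preprocess.json", stats,
                                removed_features, removed_subjects)
    train.to_csv(outdir / "complete_case_scaled.csv")

    # --- model selection ----------------------------------------------
    base = NpemConfig(n_clusters=1, seed=config.seed,
                      max_iter=config.max_iter, tol=config.tol)
    if config.n_clusters is None:
        records, selected_L = sweep_L(train, config.l_min,
                                      min(config.l_max, train.shape[0]), base)
        records_to_frame(records).to_csv(outdir / "bic_sweep.csv", index=False)
        bic_table = [asdict(r) for r in records]
    else:
        selected_L, bic_table = config.n_clusters, []
    logger.info("selected L = %d", selected_L)

    # --- final fit -----------------------------------------------------
    model = fit(train, NpemConfig(n_clusters=selected_L, seed=config.seed,
                                  max_iter=config.max_iter, tol=config.tol),
                reference_stats=stats)
    model.save(outdir / "model.json")

    # --- classification ------------------------------------------------
    # training subjects are classified by construction (argmax posterior);
    # the low-missingness stratum must clear the posterior threshold
    train_assign = classify(model, train, threshold=0.0)
    test_assign = (classify(model, test, config.classification_threshold)
                   if test is not None else [])
    all_assign = train_assign + test_assign
    assignments_to_frame(all_assign).to_csv(outdir / "assignments.csv")

    n_complete = len(train_assign)
    n_low_pass = sum(a.label != UNCLASSIFIED for a in test_assign)
    n_classified = n_complete + n_low_pass
    labels = {a.subject_id: a.label for a in all_assign
              if a.label != UNCLASSIFIED}
    sizes = pd.Series(list(labels.values())).value_counts().sort_index()

    # --- stability & validity ------------------------------------------
    train_labels = pd.Series(model.hard_labels(train.to_numpy()),
                             index=train.index)
    sil = (silhouette(train, train_labels) if selected_L > 1 else None)
    stab_i = stab_f = None
    if config.run_stability and selected_L > 1:
        cfg = NpemConfig(n_clusters=selected_L, seed=config.seed,
                         max_iter=config.max_iter, tol=config.tol)
        stab_i = loo_individual(train, cfg, config.stability_seeds,
                                config.stability_stride)
        stab_f = loo_feature(train, cfg, config.stability_seeds,
                             config.stability_stride)
        stab_i.detail.assign(mode="loo_individual").to_csv(
            outdir / "stability_loo_individual.csv", index=False)
        stab_f.detail.assign(mode="loo_feature").to_csv(
            outdir / "stability_loo_feature.csv", index=False)

    # --- outcome rates among classified subjects ------------------------
    outcome_rates = {}
    truth_path = outdir / "cohort_truth.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, index_col=0)
        for k in sorted(sizes.index):
            members = [s for s, lab in labels.items() if lab == k]
            members = [m for m in members if m in truth.index]
            if members:
                outcome_rates[int(k)] = float(
                    truth.loc[members, "outcome"].mean())

    summary = {
        "seed": config.seed,
        "n_subjects_raw": int(raw.n_subjects),
        "n_roster_features": int(roster.n_features),
        "n_features_retained": int(train.shape[1]),
        "removed_features": removed_features,
        "n_subjects_removed": len(removed_subjects),
        "n_complete_case": n_complete,
        "n_low_missingness": len(test_assign),
        "n_low_missingness_classified": int(n_low_pass),
        "n_classified": int(n_classified),
        "selected_L": int(selected_L),
        "lambdas": model.lambdas.tolist(),
        "cluster_sizes": {int(k): int(v) for k, v in sizes.items()},
        "bic_table": bic_table,
        "final_loglik": model.final_loglik,
        "converged": bool(model.converged),
        "silhouette_overall": None if sil is None else sil.overall_mean,
        "silhouette_per_cluster": None if sil is None
            else {int(k): float(v) for k, v in sil.per_cluster_mean.items()},
        "jaccard_loo_individual": None if stab_i is None
            else stab_i.per_cluster_jaccard.tolist(),
        "jaccard_loo_feature": None if stab_f is None
            else stab_f.per_cluster_jaccard.tolist(),
        "outcome_rates_by_cluster": outcome_rates,
        "classification_threshold": config.classification_threshold,
    }
    # bookkeeping consistency: classified = complete-case + threshold passers
    assert summary["n_classified"] == (summary["n_complete_case"]
                                       + summary["n_low_missingness_classified"])
    assert sum(summary["cluster_sizes"].values()) == summary["n_classified"]

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    _write_text_report(summary, outdir / "report.txt")
    return summary


def _write_text_report(s: dict, path) -> None:
    lines = [
        "npemix pipeline report",
        "======================",
        f"subjects (raw): {s['n_subjects_raw']}",
        f"roster features: {s['n_roster_features']} "
        f"(retained after QC: {s['n_features_retained']})",
        f"complete-case subjects: {s['n_complete_case']}",
        f"low-missingness subjects: {s['n_low_missingness']} "
        f"({s['n_low_missingness_classified']} classified at "
        f">{s['classification_threshold']:.0%})",
        f"total classified: {s['n_classified']}",
        f"selected L: {s['selected_L']}",
        "mixing proportions: "
        + ", ".join(f"{x:.3f}" for x in s["lambdas"]),
        "cluster sizes: "
        + ", ".join(f"{k}: {v}" for k, v in s["cluster_sizes"].items()),
    ]
    if s["silhouette_overall"] is not None:
        lines.append(f"mean silhouette width: {s['silhouette_overall']:.3f}")
    if s["jaccard_loo_individual"] is not None:
        lines.append("LOO-individual Jaccard per cluster: "
                     + ", ".join(f"{x:.3f}" for x in s["jaccard_loo_individual"]))
    if s["jaccard_loo_feature"] is not None:
        lines.append("LOO-feature Jaccard per cluster: "
                     + ", ".join(f"{x:.3f}" for x in s["jaccard_loo_feature"]))
    if s["outcome_rates_by_cluster"]:
        lines.append("outcome rate by cluster: "
                     + ", ".join(f"{k}: {v:.0%}"
                                 for k, v in s["outcome_rates_by_cluster"].items()))
    Path(path).write_text("\n".join(lines) + "\n")
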
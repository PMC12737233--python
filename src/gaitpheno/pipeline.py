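"""End-to-end orchestration: simulate -> preprocess -> cluster-method search
-> phenotype profiles -> faller models -> importance consensus -> TUG
screening, with every stage writing its report under the run directory and
a manifest tying the run together.  Stage seeds are derived
deterministically from the master seed, so a rerun with the same config
reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import consensus_table, positive_class_attributions
from .classifiers import (
    ModelSpec, FAMILIES, full_grids, metrics_table, prepare_features, small_grids,
    tune_and_crossvalidate,
)
from .clustering import (
    ClusterCondition, ALGORITHMS, evaluate_conditions, evaluations_table, select_best,
)
from .config import RunConfig, child_seed
from .dissimilarity import mds_embed, pairwise_dissimilarity, reduce_channels
from .io import (
    read_cohort_tables, read_representative, write_cohort, write_matrix,
    write_representative,
)
from .preprocess import lowpass_filter, representative_curves
from .profiles import cluster_summary, profiles_table
from .screening import screening_report, screening_table, youden_threshold
from .synthetic import default_archetypes, generate_cohort
from .types import StrideWaveform

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _wrap(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(stage, str(exc)) from exc


def stage_simulate(cfg: RunConfig, workdir: Path) -> Path:
    cohort_dir = workdir / "cohort"
    cohort = generate_cohort(
        default_archetypes(cfg.separation),
        cfg.n_subjects,
        cfg.signal,
        seed=child_seed(cfg.master_seed, "simulate"),
        missing_rate=cfg.missing_rate,
    )
    write_cohort(cohort, cohort_dir)
    log.info("simulated %d subjects into %s", cohort.n_subjects, cohort_dir)
    return cohort_dir


def stage_preprocess(cfg: RunConfig, workdir: Path) -> Path:
    cohort_dir = Path(cfg.cohort_dir) if cfg.cohort_dir else workdir / "cohort"
    cohort = read_cohort_tables(cohort_dir)
    reps = []
    n_filtered = 0
    for sid in cohort.subject_ids:
        strides = cohort.strides.get(sid, [])
        filtered = []
        for s in strides:
            try:
                chans = lowpass_filter(s.channels(), cfg.signal)
            except ValueError:
                n_filtered += 1
                continue
            filtered.append(StrideWaveform(sid, chans[:, 0], chans[:, 1], chans[:, 2]))
        if not filtered:
            raise ValueError(f"subject {sid}: no usable strides after filtering")
        reps.append(representative_curves(filtered, cfg.signal))
    if n_filtered:
        log.info("dropped %d strides too short for the low-pass filter", n_filtered)
    out = workdir / "representative.csv"
    write_representative(reps, out)
    return out


def stage_cluster(cfg: RunConfig, workdir: Path) -> dict:
    reps = read_representative(workdir / "representative.csv")
    cohort = read_cohort_tables(
        Path(cfg.cohort_dir) if cfg.cohort_dir else workdir / "cohort", load_strides=False
    )
    ids = [r.subject_id for r in reps]
    series, _ = reduce_channels(reps, cfg.reducer)
    basic = cohort.features.loc[ids, ["age", "height"]].to_numpy(dtype=float)
    seed = child_seed(cfg.master_seed, "cluster")
    D_by_mode, E_by_mode = {}, {}
    for mode in ("waveform_only", "waveform_plus_basic"):
        D = pairwise_dissimilarity(
            series, ids, basic=basic, mode=mode, fusion_weight=cfg.fusion_weight
        )
        D_by_mode[mode] = D
        E_by_mode[mode] = mds_embed(D, d=cfg.mds_dim, seed=seed)
        write_matrix(D.D, ids, workdir / f"dissimilarity_{mode}.csv")
    conditions = [
        ClusterCondition(cfg.reducer.method, alg, k, mode)
        for alg in ALGORITHMS
        for k in (3, 4, 5)
        for mode in ("waveform_only", "waveform_plus_basic")
    ]
    evaluations = evaluate_conditions(
        D_by_mode, E_by_mode, cohort.features.loc[ids], cfg.gate, conditions, seed=seed
    )
    best = select_best(evaluations)
    evaluations_table(evaluations).to_csv(workdir / "evaluations.csv", index=False)
    labels = pd.Series(best.solution.labels, index=ids, name="cluster")
    labels.index.name = "subject_id"
    labels.to_csv(workdir / "cluster_labels.csv")
    selected = {
        "reducer": best.condition.reducer,
        "algorithm": best.condition.algorithm,
        "k": best.condition.k,
        "mode": best.condition.mode,
        "composite": best.composite,
        "silhouette": best.indices.silhouette,
        "davies_bouldin": best.indices.davies_bouldin,
        "balance": best.indices.balance,
        "n_gate_passing": sum(e.gate_passed for e in evaluations),
    }
    (workdir / "selected_condition.json").write_text(json.dumps(selected, indent=2))
    log.info("selected condition: %s", best.condition.label())
    return selected


def _load_labels(cfg: RunConfig, workdir: Path) -> tuple[pd.DataFrame, pd.Series]:
    cohort = read_cohort_tables(
        Path(cfg.cohort_dir) if cfg.cohort_dir else workdir / "cohort", load_strides=False
    )
    labels = pd.read_csv(workdir / "cluster_labels.csv", index_col="subject_id")["cluster"]
    labels.index = labels.index.astype(str)
    feats = cohort.features.loc[labels.index]
    return feats, labels


def stage_profile(cfg: RunConfig, workdir: Path) -> pd.DataFrame:
    feats, labels = _load_labels(cfg, workdir)
    profiles = cluster_summary(feats, labels.to_numpy())
    table = profiles_table(profiles)
    table.to_csv(workdir / "profiles.csv", index=False)
    return table


def stage_classify(cfg: RunConfig, workdir: Path) -> pd.DataFrame:
    """Fit the four families per cluster and store CV metrics together with
    mean-absolute-attribution global importances (consumed by consensus)."""
    feats, labels = _load_labels(cfg, workdir)
    grids = small_grids() if cfg.grid_size == "small" else full_grids()
    seed = child_seed(cfg.master_seed, "classify")
    results: dict[str, dict] = {}
    importance_rows = []
    for c in sorted(labels.unique()):
        sub = feats[labels == c]
        name = f"cluster_{c}"
        if len(sub) < 20:
            log.warning("%s: only %d subjects, skipping models", name, len(sub))
            continue
        if sub["fell"].nunique() < 2:
            log.warning("%s: single fall class, skipping models", name)
            continue
        results[name] = {}
        for fam in FAMILIES:
            X, y, cols = prepare_features(sub, fam)
            res = tune_and_crossvalidate(
                X, y, ModelSpec(fam, grids[fam], seed=seed), feature_names=cols
            )
            results[name][fam] = res
            attr = positive_class_attributions(
                res.model, res.preprocessor.transform(X), fam, cols, seed=seed
            )
            for feat, imp in zip(cols, attr.global_importance):
                importance_rows.append(
                    {"phenotype": name, "family": fam, "feature": feat,
                     "importance": imp,
                     "accuracy": res.metrics["accuracy"][0]}
                )
    table = metrics_table(results)
    table.to_csv(workdir / "model_metrics.csv", index=False)
    imp = pd.DataFrame(
        importance_rows, columns=["phenotype", "family", "feature", "importance", "accuracy"]
    )
    imp.to_csv(workdir / "importances.csv", index=False)
    return table


def stage_consensus(cfg: RunConfig, workdir: Path) -> pd.DataFrame:
    imp = pd.read_csv(workdir / "importances.csv")
    if imp.empty:
        log.warning("no model importances available; consensus skipped")
        empty = pd.DataFrame(columns=["phenotype", "feature", "borda_score", "strong_consensus"])
        empty.to_csv(workdir / "consensus.csv", index=False)
        return empty
    out = []
    for pheno, grp in imp.groupby("phenotype", sort=True):
        importances, accuracies = {}, {}
        names = None
        for fam, g in grp.groupby("family"):
            g = g.set_index("feature")
            if names is None:
                names = list(g.index)
            importances[fam] = g.loc[names, "importance"].to_numpy()
            accuracies[fam] = float(g["accuracy"].iloc[0])
        table = consensus_table(importances, accuracies, names)
        table.insert(0, "phenotype", pheno)
        out.append(table.reset_index(names="feature"))
    result = pd.concat(out, ignore_index=True)
    result.to_csv(workdir / "consensus.csv", index=False)
    return result


def stage_screen(cfg: RunConfig, workdir: Path) -> pd.DataFrame:
    feats, labels = _load_labels(cfg, workdir)
    comparisons = {}
    for c in sorted(labels.unique()):
        sub = feats[labels == c]
        name = f"cluster_{c}"
        if sub["fell"].nunique() < 2:
            log.warning("%s: single fall class, screening undefined", name)
            continue
        roc = youden_threshold(sub["tug_s"].to_numpy(), sub["fell"].to_numpy())
        comparisons[name] = screening_report(
            sub["tug_s"].to_numpy(), sub["fell"].to_numpy(),
            roc.chosen_cutoff, cfg.screening_fixed_cutoff,
        )
    table = screening_table(comparisons)
    table.to_csv(workdir / "screening.csv", index=False)
    return table


STAGES = (
    ("simulate", stage_simulate),
    ("preprocess", stage_preprocess),
    ("cluster", stage_cluster),
    ("profile", stage_profile),
    ("classify", stage_classify),
    ("consensus", stage_consensus),
    ("screen", stage_screen),
)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write the run manifest; returns the manifest."""
    workdir = Path(cfg.output_dir)
    workdir.mkdir(parents=True, exist_ok=True)
    selected = None
    for stage, fn in STAGES:
        if stage == "simulate" and cfg.cohort_dir:
            continue  # external cohort supplied
        out = _wrap(stage, fn, cfg, workdir)
        if stage == "cluster":
            selected = out
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": cfg.to_dict(),
        "stage_seeds": {s: child_seed(cfg.master_seed, s) for s, _ in STAGES},
        "selected_condition": selected,
    }
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
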
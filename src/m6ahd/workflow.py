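"""End-to-end orchestration: simulate -> sites -> (optional selection
stages) -> train -> evaluate -> cross-predict -> interpret.

`run_workflow` drives the whole framework on a synthetic bundle and
returns every intermediate object, so the same code path serves the CLI,
the benchmark tests and exploratory use. Seeds are derived from the
top-level seed as ``seed*1000 + 10*condition_index + direction_index``
and recorded in the manifest.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .config import Config, RunManifest, dump_config
from .encoders import EncoderSpec, PseDNCParams
from .evaluation import CrossPredictionMatrix, cross_predict, evaluate_scores
from .interpret import gini_importance, top_k
from .pipeline import (
    ModelConfig,
    TrainedModel,
    compare_algorithms,
    encode_split,
    predict,
    scan_window_lengths,
    search_feature_combinations,
    train_final,
    tune_rf,
)
from .simulate import SimConfig, simulate_bundle
from .sites import (
    GenomicSite,
    PeakSet,
    SplitDataset,
    derive_sites,
    extract_windows,
    subsample_split,
    true_sites,
)

__all__ = ["run_workflow", "WorkflowResult", "condition_site_sets",
           "build_split", "label_permutation_null", "sim_config_from"]

logger = logging.getLogger("m6ahd")

DIRECTIONS = ("up", "down")


def sim_config_from(cfg: Config) -> SimConfig:
    return SimConfig(seed=cfg.seed, **cfg.sim.model_dump())


def _encoder_spec(cfg: Config) -> EncoderSpec:
    psednc = (
        PseDNCParams(lam=cfg.psednc_lambda, w=cfg.psednc_w)
        if "PseDNC" in cfg.schemes
        else None
    )
    return EncoderSpec(schemes=tuple(cfg.schemes), psednc=psednc)


def condition_site_sets(truth, condition: str, negative_mode: str = "definitional"):
    """Derive the up and down LabeledSiteSets for one condition, going
    through the peak-intersection path (true_sites) rather than reading
    the truth flags directly."""
    from .simulate import _peaks_for

    sub = truth[truth["condition"] == condition]
    candidates = [
        GenomicSite(r.transcript, r.pos, r.strand, condition)
        for r in sub.itertuples()
    ]
    exp_peaks = PeakSet(_peaks_for(sub, "methylated_in_exp", halfwidth=50),
                        "experimental", condition)
    ctrl_peaks = PeakSet(_peaks_for(sub, "methylated_in_ctrl", halfwidth=50),
                         "control", condition)
    exp_true = true_sites(exp_peaks, candidates)
    ctrl_true = true_sites(ctrl_peaks, candidates)
    return {
        d: derive_sites(exp_true, ctrl_true, candidates, d,
                        negative_mode=negative_mode, condition=condition)
        for d in DIRECTIONS
    }


def build_split(site_set, seqs, L: int, n_per_class: int, train_frac: float,
                seed: int, center_check: bool = True) -> SplitDataset:
    """Windows for both classes at length L, subsampled and split."""
    pos_w = extract_windows(site_set.positives, seqs, L, center_check)
    neg_w = extract_windows(site_set.negatives, seqs, L, center_check)
    return subsample_split(site_set, {1: pos_w, 0: neg_w}, n_per_class,
                           train_frac, seed)


def label_permutation_null(split: SplitDataset, model_cfg: ModelConfig,
                           n_permutations: int = 3, seed: int = 0) -> float:
    """Mean held-out AUROC over label permutations of the whole split.

    Each permutation shuffles all labels (train and test jointly),
    retrains the model and scores the held-out partition — the empirical
    null against which real performance is judged. Averaging over
    permutations narrows the Monte-Carlo spread of the estimate.
    """
    rng = np.random.default_rng(seed)
    pairs = list(split.train) + list(split.test)
    n_train = len(split.train)
    aurocs = []
    for _ in range(n_permutations):
        labels = rng.permutation([lab for _, lab in pairs])
        shuffled = [(w, int(l)) for (w, _), l in zip(pairs, labels)]
        perm = SplitDataset(shuffled[:n_train], shuffled[n_train:], seed=seed)
        train_fm, test_fm = encode_split(perm, model_cfg.encoder_spec)
        from .pipeline import _fit

        model = _fit(model_cfg, train_fm)
        from .evaluation import auroc

        aurocs.append(auroc(predict(model, test_fm), test_fm.labels))
    return float(np.mean(aurocs))


@dataclass
class WorkflowResult:
    """Everything one run produced, keyed by (condition, direction)."""

    models: dict = field(default_factory=dict)
    splits: dict = field(default_factory=dict)
    eval_results: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)
    cross: dict = field(default_factory=dict)  # direction -> CrossPredictionMatrix
    importance: dict = field(default_factory=dict)
    manifest: RunManifest = None
    seqs: dict = field(default_factory=dict)
    truth: object = None


def run_workflow(cfg: Config, outdir=None, dry_run: bool = False) -> WorkflowResult:
    """Execute the configured stages over a synthetic bundle.

    With ``dry_run`` the stage plan is logged and nothing is executed.
    """
    stage_plan = ["simulate", "sites", "train", "evaluate", "cross-predict",
                  "interpret"]
    for name, on in (("scan-windows", cfg.stages.scan_windows),
                     ("search-features", cfg.stages.search_features),
                     ("compare-algorithms", cfg.stages.compare_algorithms),
                     ("tune-rf", cfg.stages.tune_rf)):
        if on:
            stage_plan.insert(2, name)
    if dry_run:
        logger.info("dry run; stage plan: %s", " -> ".join(stage_plan))
        res = WorkflowResult(manifest=RunManifest.start(cfg))
        res.manifest.chosen_settings["stage_plan"] = stage_plan
        return res

    manifest = RunManifest.start(cfg)
    res = WorkflowResult(manifest=manifest)
    sim_cfg = sim_config_from(cfg)
    manifest.seeds["simulate"] = cfg.seed

    stage = "simulate"
    try:
        if outdir is not None:
            os.makedirs(outdir, exist_ok=True)
            seqs, truth, _paths = simulate_bundle(sim_cfg, outdir=os.path.join(outdir, "bundle"))
        else:
            seqs, truth = simulate_bundle(sim_cfg)
        res.seqs, res.truth = seqs, truth
        manifest.stages_completed.append(stage)

        spec = _encoder_spec(cfg)
        for c, condition in enumerate(sim_cfg.conditions):
            stage = f"sites[{condition}]"
            site_sets = condition_site_sets(truth, condition, cfg.negative_mode)
            manifest.stages_completed.append(stage)
            for d_i, direction in enumerate(DIRECTIONS):
                key = (condition, direction)
                split_seed = cfg.seed * 1000 + 10 * c + d_i
                manifest.seeds[f"split/{condition}/{direction}"] = split_seed
                model_cfg = ModelConfig(
                    algorithm=cfg.algorithm,
                    window_length=cfg.window_length,
                    encoder_spec=spec,
                    ntree=cfg.ntree,
                    mtry=cfg.mtry,
                    seed=split_seed,
                )

                if cfg.stages.scan_windows:
                    stage = f"scan-windows[{condition}/{direction}]"
                    rep = scan_window_lengths(
                        lambda L: build_split(site_sets[direction], seqs, L,
                                              cfg.n_per_class, cfg.train_frac,
                                              split_seed, cfg.center_check),
                        cfg.window_lengths, model_cfg)
                    res.selection[key + ("window",)] = rep
                    model_cfg = replace(model_cfg, window_length=rep.chosen)
                    manifest.chosen_settings[f"window/{condition}/{direction}"] = rep.chosen
                    manifest.stages_completed.append(stage)

                stage = f"split[{condition}/{direction}]"
                split = build_split(site_sets[direction], seqs,
                                    model_cfg.window_length, cfg.n_per_class,
                                    cfg.train_frac, split_seed, cfg.center_check)
                res.splits[key] = split

                if cfg.stages.search_features:
                    stage = f"search-features[{condition}/{direction}]"
                    rep = search_feature_combinations(split, model_cfg)
                    res.selection[key + ("features",)] = rep
                    chosen = tuple(rep.chosen.split("+"))
                    model_cfg = replace(
                        model_cfg,
                        encoder_spec=EncoderSpec(
                            schemes=chosen,
                            psednc=spec.psednc if "PseDNC" in chosen else None),
                    )
                    manifest.chosen_settings[f"features/{condition}/{direction}"] = rep.chosen
                    manifest.stages_completed.append(stage)

                if cfg.stages.compare_algorithms:
                    stage = f"compare-algorithms[{condition}/{direction}]"
                    res.selection[key + ("algorithms",)] = compare_algorithms(
                        split, model_cfg.encoder_spec, model_cfg, cfg.threshold)
                    manifest.stages_completed.append(stage)

                if cfg.stages.tune_rf:
                    stage = f"tune-rf[{condition}/{direction}]"
                    rep = tune_rf(split, model_cfg.encoder_spec,
                                  cfg.ntree_grid, cfg.mtry_grid, model_cfg)
                    res.selection[key + ("rf_grid",)] = rep
                    ntree, mtry = rep.chosen
                    model_cfg = replace(model_cfg, ntree=ntree, mtry=mtry)
                    manifest.chosen_settings[f"rf/{condition}/{direction}"] = list(rep.chosen)
                    manifest.stages_completed.append(stage)

                stage = f"train[{condition}/{direction}]"
                model = train_final(split, model_cfg)
                res.models[key] = model
                manifest.stages_completed.append(stage)

                stage = f"evaluate[{condition}/{direction}]"
                _, test_fm = encode_split(split, model_cfg.encoder_spec)
                res.eval_results[key] = evaluate_scores(
                    predict(model, test_fm), test_fm.labels, cfg.threshold)
                manifest.stages_completed.append(stage)

                stage = f"interpret[{condition}/{direction}]"
                if model.importances is not None:
                    res.importance[key] = top_k(gini_importance(model), 10)
                manifest.stages_completed.append(stage)

        for direction in DIRECTIONS:
            stage = f"cross-predict[{direction}]"
            models = {c: res.models[(c, direction)] for c in sim_cfg.conditions}
            datasets = {c: res.splits[(c, direction)].test for c in sim_cfg.conditions}
            res.cross[direction] = cross_predict(models, datasets, direction)
            manifest.stages_completed.append(stage)
    except Exception:
        manifest.failed_stage = stage
        manifest.finish()
        if outdir is not None:
            manifest.to_json(os.path.join(outdir, "manifest.json"))
        raise

    manifest.finish()
    if outdir is not None:
        _write_reports(res, cfg, outdir)
    return res


def _write_reports(res: WorkflowResult, cfg: Config, outdir) -> None:
    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    dump_config(cfg, os.path.join(outdir, "config-used.yaml"))
    rows = [
        {"condition": c, "direction": d, **er.as_dict()}
        for (c, d), er in res.eval_results.items()
    ]
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "evaluation.tsv"),
                              sep="\t", index=False)
    for direction, mat in res.cross.items():
        mat.to_tsv(os.path.join(outdir, f"cross-prediction-{direction}.tsv"))
    for (c, d), table in res.importance.items():
        table.to_tsv(os.path.join(outdir, f"importance-{c}-{d}.tsv"))
    res.manifest.to_json(os.path.join(outdir, "manifest.json"))
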
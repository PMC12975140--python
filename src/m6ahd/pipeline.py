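"""Model selection and training.

The selection procedure is staged, mirroring how such predictors are
usually tuned: (1) scan candidate window lengths, (2) search all 63
nonempty combinations of the six encoding schemes at the chosen length,
(3) compare four algorithm families (random forest, RBF-kernel SVM,
logistic GLM, gradient-boosted trees) on the chosen features, and
(4) grid-search the random-forest hyperparameters ntree (number of trees)
and mtry (features considered per split). Each stage selects by held-out
AUROC on the independent test partition; ties break toward the simpler
setting (smaller length, fewer schemes, smaller ntree then mtry).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .encoders import EncoderSpec, FeatureMatrix, all_scheme_combinations, build_feature_matrix
from .evaluation import EvalResult, auroc, evaluate_scores

__all__ = [
    "ALGORITHMS",
    "DEFAULT_WINDOW_LENGTHS",
    "DEFAULT_NTREE_GRID",
    "DEFAULT_MTRY_GRID",
    "ModelConfig",
    "SelectionReport",
    "TrainedModel",
    "scan_window_lengths",
    "search_feature_combinations",
    "compare_algorithms",
    "tune_rf",
    "train_final",
    "predict",
    "save_model",
    "load_model",
    "encode_split",
]

logger = logging.getLogger("m6ahd")

ALGORITHMS = ("RF", "SVM", "GLM", "GBT")

#: Candidate window lengths (nt), centered on the m6A site.
DEFAULT_WINDOW_LENGTHS = (21, 31, 41, 51, 61, 71, 81)

#: Random-forest grids: ntree 200..1400 step 100, mtry 50..100 step 1.
DEFAULT_NTREE_GRID = tuple(range(200, 1401, 100))
DEFAULT_MTRY_GRID = tuple(range(50, 101))


@dataclass(frozen=True)
class ModelConfig:
    """Complete specification of one trainable model."""

    algorithm: str = "RF"
    window_length: int = 41
    encoder_spec: EncoderSpec = field(default_factory=EncoderSpec)
    ntree: int = 500
    mtry: int | None = None  # None -> sqrt(n_features)
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.window_length % 2 == 0:
            raise ValueError("window_length must be odd")
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass
class SelectionReport:
    """AUROC per evaluated setting plus the chosen one."""

    table: dict  # setting id -> AUROC
    chosen: object
    tie_break: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"setting": list(self.table), "AUROC": list(self.table.values())}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class TrainedModel:
    """A fitted predictor plus everything needed to reuse and explain it."""

    estimator: object
    config: ModelConfig
    columns: list
    importances: np.ndarray | None = None  # mean impurity decrease per feature

    @property
    def total_importance(self) -> float:
        return float(self.importances.sum()) if self.importances is not None else 0.0


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _make_estimator(cfg: ModelConfig, n_features: int):
    if cfg.algorithm == "RF":
        mtry = cfg.mtry if cfg.mtry is not None else max(1, int(np.sqrt(n_features)))
        mtry = min(mtry, n_features)
        return RandomForestClassifier(
            n_estimators=cfg.ntree,
            max_features=mtry,
            random_state=cfg.seed,
            n_jobs=1,
        )
    if cfg.algorithm == "SVM":
        # trees are scale-invariant; the SVM path standardizes internally
        return make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", probability=True, random_state=cfg.seed),
        )
    if cfg.algorithm == "GLM":
        return LogisticRegression(max_iter=2000, random_state=cfg.seed)
    if cfg.algorithm == "GBT":
        return XGBClassifier(
            max_depth=6,
            n_estimators=300,
            learning_rate=0.1,
            random_state=cfg.seed,
            n_jobs=1,
            verbosity=0,
            eval_metric="logloss",
        )
    raise ValueError(cfg.algorithm)


def _fit(cfg: ModelConfig, train_fm: FeatureMatrix) -> TrainedModel:
    if len(np.unique(train_fm.labels)) < 2:
        raise ValueError("both classes must be present in training labels")
    est = _make_estimator(cfg, train_fm.n_columns)
    est.fit(train_fm.values, train_fm.labels)
    importances = None
    if cfg.algorithm == "RF":
        per_tree = np.array(
            [t.tree_.compute_feature_importances(normalize=False)
             for t in est.estimators_]
        )
        importances = per_tree.mean(axis=0)
    return TrainedModel(est, cfg, list(train_fm.columns), importances)


def predict(model: TrainedModel, fm: FeatureMatrix) -> np.ndarray:
    """Positive-class probability per row; columns must match the model's."""
    if list(fm.columns) != list(model.columns):
        diff = set(fm.columns) ^ set(model.columns)
        raise ValueError(
            f"feature columns do not match the model (symmetric difference: "
            f"{sorted(diff)[:10]}{'...' if len(diff) > 10 else ''})"
        )
    if fm.n_rows == 0:
        return np.empty(0)
    return model.estimator.predict_proba(fm.values)[:, 1]


def encode_split(split, spec: EncoderSpec):
    """Encode a SplitDataset's train and test partitions into matrices."""
    train_fm = build_feature_matrix(
        [w for w, _ in split.train], spec, [l for _, l in split.train]
    )
    test_fm = build_feature_matrix(
        [w for w, _ in split.test], spec, [l for _, l in split.test]
    )
    return train_fm, test_fm


def _heldout_auroc(cfg: ModelConfig, split, spec: EncoderSpec) -> float:
    train_fm, test_fm = encode_split(split, spec)
    model = _fit(cfg, train_fm)
    return auroc(predict(model, test_fm), test_fm.labels)


# ---------------------------------------------------------------------------
# Selection stages
# ---------------------------------------------------------------------------

def scan_window_lengths(
    split_builder, lengths=DEFAULT_WINDOW_LENGTHS, base_cfg: ModelConfig | None = None
) -> SelectionReport:
    """Evaluate each candidate window length with the base model.

    ``split_builder(L)`` must return the SplitDataset at length L (the
    caller controls sampling so all lengths share one site sample).
    """
    if base_cfg is None:
        base_cfg = ModelConfig()
    if any(L % 2 == 0 for L in lengths):
        raise ValueError("all window lengths must be odd")
    table = {}
    for L in lengths:
        split = split_builder(L)
        if not split.train or not split.test:
            raise ValueError(f"window length {L} produced an empty dataset")
        cfg = replace(base_cfg, window_length=L)
        table[L] = _heldout_auroc(cfg, split, base_cfg.encoder_spec)
        logger.info("window scan: L=%d AUROC=%.4f", L, table[L])
    chosen = min(L for L, a in table.items() if a == max(table.values()))
    return SelectionReport(table, chosen, "max AUROC; ties -> smallest length")


def search_feature_combinations(
    split, base_cfg: ModelConfig | None = None
) -> SelectionReport:
    """Evaluate all 63 nonempty scheme subsets on one fixed split."""
    if base_cfg is None:
        base_cfg = ModelConfig()
    table = {}
    failures = {}
    combos = all_scheme_combinations()
    for combo in combos:
        spec = EncoderSpec(
            schemes=combo,
            psednc=base_cfg.encoder_spec.psednc if "PseDNC" in combo else None,
        )
        key = "+".join(combo)
        try:
            table[key] = _heldout_auroc(base_cfg, split, spec)
        except Exception as exc:  # report per-setting failures, keep going
            failures[key] = str(exc)
            logger.warning("feature combination %s failed: %s", key, exc)
    if failures and not table:
        raise RuntimeError(f"every feature combination failed: {failures}")
    best = max(table.values())
    # ties -> fewest schemes, then canonical enumeration order
    chosen = next(
        "+".join(c) for c in combos if table.get("+".join(c)) == best
    )
    rep = SelectionReport(table, chosen, "max AUROC; ties -> fewest schemes, canonical order")
    rep.failures = failures
    return rep


def compare_algorithms(
    split, spec: EncoderSpec | None = None, base_cfg: ModelConfig | None = None,
    threshold: float = 0.5,
) -> dict:
    """Train RF, SVM, GLM and GBT on the same matrices; full metrics each."""
    if base_cfg is None:
        base_cfg = ModelConfig()
    if spec is None:
        spec = base_cfg.encoder_spec
    train_fm, test_fm = encode_split(split, spec)
    results: dict[str, EvalResult] = {}
    for algo in ALGORITHMS:
        cfg = replace(base_cfg, algorithm=algo)
        with warnings.catch_warnings():
            warnings.simplefilter("always", ConvergenceWarning)
            model = _fit(cfg, train_fm)
        scores = predict(model, test_fm)
        results[algo] = evaluate_scores(scores, test_fm.labels, threshold)
    return results


def tune_rf(
    split,
    spec: EncoderSpec | None = None,
    ntree_grid=DEFAULT_NTREE_GRID,
    mtry_grid=DEFAULT_MTRY_GRID,
    base_cfg: ModelConfig | None = None,
) -> SelectionReport:
    """Exhaustive (ntree, mtry) grid search by held-out AUROC.

    mtry values exceeding the feature count are clamped to it and
    deduplicated with a warning.
    """
    if base_cfg is None:
        base_cfg = ModelConfig()
    if spec is None:
        spec = base_cfg.encoder_spec
    if not ntree_grid or not mtry_grid:
        raise ValueError("grids must be nonempty")
    train_fm, test_fm = encode_split(split, spec)
    p = train_fm.n_columns
    clamped = sorted({min(m, p) for m in mtry_grid})
    if clamped != sorted(set(mtry_grid)):
        warnings.warn(
            f"mtry values exceeding {p} feature columns clamped; "
            f"grid reduced to {len(clamped)} values"
        )
    if not clamped:
        raise ValueError("empty mtry grid after clamping")
    table = {}
    for ntree in ntree_grid:
        for mtry in clamped:
            cfg = replace(base_cfg, algorithm="RF", ntree=ntree, mtry=mtry)
            model = _fit(cfg, train_fm)
            table[(ntree, mtry)] = auroc(predict(model, test_fm), test_fm.labels)
    best = max(table.values())
    chosen = min(k for k, v in table.items() if v == best)
    return SelectionReport(table, chosen, "max AUROC; ties -> smaller ntree, then mtry")


# ---------------------------------------------------------------------------
# Final model
# ---------------------------------------------------------------------------

def train_final(split, cfg: ModelConfig) -> TrainedModel:
    """Fit the configured model on the training partition; deterministic
    for a fixed seed."""
    train_fm, _ = encode_split(split, cfg.encoder_spec)
    return _fit(cfg, train_fm)


def save_model(model: TrainedModel, path) -> None:
    joblib.dump(
        {
            "estimator": model.estimator,
            "config": model.config,
            "columns": model.columns,
            "importances": model.importances,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    d = joblib.load(path)
    return TrainedModel(d["estimator"], d["config"], d["columns"], d["importances"])
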
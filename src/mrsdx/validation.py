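"""Class-balanced nested held-out / cross-validation orchestration.

The resampling architecture mirrors the study design:

* an outer loop holds out one case at a time; in *balanced* mode every
  smaller-class case is held out once plus an equal number sampled
  without replacement from the larger class (N1 x 2 single-case runs),
  while *exhaustive* mode holds out every case once;
* an inner loop applies the same class-balanced single-case scheme to
  each outer training set (N2 x 2 cross-validation folds), and inner
  accuracies are pooled across all outer training sets;
* hyperparameters and features are optimized ONCE per (task, family)
  against those pooled inner statistics — not re-optimized per outer
  run — after which each outer run trains on its own training set only
  (SMOTE balancing, then scaling fitted on the balanced training set
  and transferred to the held-out case) and classifies its held-out
  case;
* feature selection is recursive elimination by permutation importance:
  the feature whose column-permutation least degrades pooled inner
  accuracy is dropped while pooled accuracy or AUROC strictly improves.

All randomness derives from one master seed through named substreams,
and plans are canonicalised on sorted case ids, so results are
bit-reproducible and invariant to input row order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import evaluation
from .classifiers import DEFAULT_GRIDS, ModelConfig, TrainedModel, fit_classifier
from .cohort import FeatureTable, _stream
from .preprocess import SmoteConfig, _guarded_zfit, apply_scaling, smote_balance


# ----------------------------------------------------------------------
# tasks
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TaskDefinition:
    """One binary question: which groups are positive, which negative."""

    name: str
    positive_groups: frozenset[str]
    negative_groups: frozenset[str]

    def __post_init__(self) -> None:
        if self.positive_groups & self.negative_groups:
            raise ValueError(
                f"task '{self.name}': positive and negative groups overlap: "
                f"{sorted(self.positive_groups & self.negative_groups)}"
            )
        if not self.positive_groups or not self.negative_groups:
            raise ValueError(f"task '{self.name}': both group sets must be non-empty")


def _task(name, pos, neg):
    return TaskDefinition(name, frozenset(pos), frozenset(neg))


#: The four binary questions.  MS phenotypes are positive versus
#: control; in RR_vs_P, relapsing-remitting MS is the positive class.
TASKS: dict[str, TaskDefinition] = {
    "MS_vs_HC": _task("MS_vs_HC", {"RR-MS", "P-MS"}, {"HC"}),
    "RR_vs_HC": _task("RR_vs_HC", {"RR-MS"}, {"HC"}),
    "P_vs_HC": _task("P_vs_HC", {"P-MS"}, {"HC"}),
    "RR_vs_P": _task("RR_vs_P", {"RR-MS"}, {"P-MS"}),
}


@dataclass(frozen=True)
class RunRecord:
    """One single-case classification event (held-out or inner CV)."""

    case_id: str
    truth: int
    prediction: int
    score: float
    loop: str  # "outer_heldout" | "inner_cv"
    config_used: ModelConfig
    features_used: tuple[str, ...]
    run_index: int


@dataclass(frozen=True)
class ImportanceReport:
    """Permutation importances (mean accuracy drop +/- SD over repeats)."""

    features: tuple[str, ...]
    importance: tuple[float, ...]
    importance_sd: tuple[float, ...]
    baseline_accuracy: float
    repeats: int

    @property
    def ranking(self) -> tuple[str, ...]:
        """Features from most to least important (stable on ties)."""
        order = sorted(range(len(self.features)), key=lambda i: (-self.importance[i], i))
        return tuple(self.features[i] for i in order)


@dataclass(frozen=True)
class PipelineSettings:
    """Everything run_question needs beyond the data and the task.

    ``grid=None`` uses the family's default hyperparameter grid; a
    one-element grid skips the inner search entirely.  ``seed`` is the
    master seed from which every substream (larger-class subsampling,
    SMOTE, permutations) is derived.
    """

    mode: str = "balanced"  # "balanced" | "exhaustive"
    grid: tuple[ModelConfig, ...] | None = None
    feature_elimination: bool = True
    importance_repeats: int = 100
    smote_k: int = 5
    seed: int = 0
    imputation: str = "paper"  # "paper" (table pre-imputed) | "train_only"

    def __post_init__(self) -> None:
        if self.mode not in ("balanced", "exhaustive"):
            raise ValueError(f"mode must be 'balanced' or 'exhaustive', got {self.mode!r}")
        if self.imputation not in ("paper", "train_only"):
            raise ValueError(f"imputation must be 'paper' or 'train_only', got {self.imputation!r}")
        if self.importance_repeats < 1:
            raise ValueError("importance_repeats must be >= 1")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")


@dataclass
class QuestionResult:
    """Everything produced by run_question for one (task, family)."""

    task: TaskDefinition
    family: str
    settings: PipelineSettings
    config: ModelConfig
    retained_features: tuple[str, ...]
    outer_records: list[RunRecord]
    cv_records: list[RunRecord]
    models: list[TrainedModel]
    importance: ImportanceReport | None
    elimination_trail: list[dict]
    outer_plan: list[tuple[str, tuple[str, ...]]]


# ----------------------------------------------------------------------
# task data and split plans
# ----------------------------------------------------------------------

class _TaskData:
    """Rows of a table belonging to a task, in canonical (sorted-id) order."""

    def __init__(self, table: FeatureTable, task: TaskDefinition):
        groups = table.groups
        mask = np.isin(groups, list(task.positive_groups | task.negative_groups))
        ids = table.ids[mask]
        order = np.argsort(ids)
        self.ids: tuple[str, ...] = tuple(ids[order])
        self.X: np.ndarray = table.feature_matrix()[mask][order]
        self.y: np.ndarray = np.where(
            np.isin(groups[mask][order], list(task.positive_groups)), 1, -1
        )
        self.has_missing = bool(np.isnan(self.X).any())
        if not (self.y == 1).any() or not (self.y == -1).any():
            raise ValueError(f"task '{task.name}': both classes must be present in the table")
        self.pos_of = {cid: i for i, cid in enumerate(self.ids)}
        self.features = table.feature_order


def _single_case_plan(
    ids: Sequence[str], y: np.ndarray, mode: str, rng: np.random.Generator
) -> list[tuple[str, tuple[str, ...]]]:
    ids = np.asarray(ids)
    order = np.argsort(ids)  # canonical: independent of input row order
    ids, y = ids[order], np.asarray(y)[order]
    pos, neg = ids[y == 1], ids[y == -1]
    n1 = min(len(pos), len(neg))
    if n1 < 2:
        raise ValueError(f"smaller class has {n1} case(s); need >= 2 for single-case plans")
    if mode == "exhaustive":
        held = list(ids)
    else:
        smaller, larger = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
        sampled = rng.choice(larger, size=n1, replace=False)
        held = list(smaller) + list(sampled)
    return [(h, tuple(i for i in ids if i != h)) for h in held]


def outer_split_plan(
    table: FeatureTable, task: TaskDefinition, mode: str = "balanced", seed: int = 0
) -> list[tuple[str, tuple[str, ...]]]:
    """Held-out plan: (held_out_id, training_ids) single-case runs.

    Balanced mode yields N1 x 2 runs (N1 = smaller class size);
    exhaustive mode holds out every case once.  Training ids are all
    remaining task cases.
    """
    data = _TaskData(table, task)
    rng = _stream(seed, "outer", task.name)
    return _single_case_plan(data.ids, data.y, mode, rng)


def inner_cv_plan(
    table: FeatureTable,
    training_ids: Sequence[str],
    task: TaskDefinition,
    seed: int = 0,
) -> list[tuple[str, tuple[str, ...]]]:
    """Class-balanced single-case CV folds within one training set (N2 x 2)."""
    data = _TaskData(table, task)
    idx = [data.pos_of[i] for i in training_ids]
    rng = _stream(seed, "inner-standalone", task.name)
    return _single_case_plan(np.asarray(training_ids), data.y[idx], "balanced", rng)


# ----------------------------------------------------------------------
# fold execution
# ----------------------------------------------------------------------

def _check_missing(data: _TaskData, settings: PipelineSettings) -> None:
    if data.has_missing and settings.imputation == "paper":
        raise ValueError(
            "task data contain missing values; run impute_class_mean first "
            "(or use imputation='train_only' for fold-local imputation)"
        )


def _impute_block(block: np.ndarray, label: str) -> np.ndarray:
    # train_only mode: fill each class block's missing cells with the
    # block's own column means, so no evaluation case informs training
    if not np.isnan(block).any():
        return block
    block = block.copy()
    for j in range(block.shape[1]):
        col = block[:, j]
        ok = ~np.isnan(col)
        if not ok.any():
            raise ValueError(f"cannot impute feature column {j} in class {label}: all values missing")
        col[~ok] = col[ok].mean()
    return block


def _fit_training_set(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    feat_idx: np.ndarray,
    feat_names: tuple[str, ...],
    config: ModelConfig,
    smote_k: int,
    smote_seed: int,
):
    """SMOTE-balance -> fit scaling on the balanced set -> fit model."""
    Xs = X_tr[:, feat_idx]
    pos = _impute_block(Xs[y_tr == 1], "+1")
    neg = _impute_block(Xs[y_tr == -1], "-1")
    target = max(len(pos), len(neg))

    def balance(block: np.ndarray, tag: int) -> np.ndarray:
        if len(block) == target:
            return block
        if len(block) < 2:  # degenerate toy case: no neighbors to interpolate
            reps = np.repeat(block, target - len(block), axis=0)
            return np.vstack([block, reps])
        cfg = SmoteConfig(k_neighbors=min(smote_k, len(block) - 1), seed=smote_seed + tag)
        return smote_balance(block, target, cfg)

    Xb = np.vstack([balance(pos, 0), balance(neg, 1)])
    yb = np.concatenate([np.ones(target, dtype=int), -np.ones(target, dtype=int)])
    scaling = _guarded_zfit(Xb, feat_names)
    model = fit_classifier(config, apply_scaling(Xb, scaling), yb,
                           retained_features=feat_names, scaling=scaling)
    return model, scaling


@dataclass
class _FoldCase:
    """One evaluated CV case with the model that scored it (for importances)."""

    model: TrainedModel
    scaling: object
    x_raw: np.ndarray  # full 7-feature raw vector of the evaluation case
    truth: int
    case_id: str


def _score_case(model: TrainedModel, scaling, x_raw: np.ndarray, feat_idx: np.ndarray) -> float:
    x = x_raw[feat_idx]
    if np.isnan(x).any():  # train_only mode: missing -> training mean (scales to 0)
        x = np.where(np.isnan(x), scaling.location, x)
    z = apply_scaling(x[None, :], scaling)
    return float(model.decision_score(z)[0])


def _pooled_cv(
    data: _TaskData,
    outer_plan: list[tuple[str, tuple[str, ...]]],
    feat_names: tuple[str, ...],
    config: ModelConfig,
    settings: PipelineSettings,
    keep_cache: bool = False,
):
    """Run the inner CV inside every outer training set; pool all folds."""
    _check_missing(data, settings)
    feat_idx = np.array([data.features.index(f) for f in feat_names])
    records: list[RunRecord] = []
    cache: list[_FoldCase] = []
    counter = 0
    for run_i, (_, train_ids) in enumerate(outer_plan):
        tr_idx = np.array([data.pos_of[i] for i in train_ids])
        rng = _stream(settings.seed, "inner", run_i)
        folds = _single_case_plan(np.asarray(train_ids), data.y[tr_idx], "balanced", rng)
        for fold_i, (cv_id, inner_ids) in enumerate(folds):
            in_idx = np.array([data.pos_of[i] for i in inner_ids])
            smote_seed = int(_stream(settings.seed, "smote", run_i, fold_i).integers(2**31))
            model, scaling = _fit_training_set(
                data.X[in_idx], data.y[in_idx], feat_idx, feat_names,
                config, settings.smote_k, smote_seed,
            )
            ci = data.pos_of[cv_id]
            score = _score_case(model, scaling, data.X[ci], feat_idx)
            records.append(RunRecord(
                case_id=cv_id, truth=int(data.y[ci]), prediction=1 if score >= 0 else -1,
                score=score, loop="inner_cv", config_used=config,
                features_used=feat_names, run_index=counter,
            ))
            if keep_cache:
                cache.append(_FoldCase(model, scaling, data.X[ci], int(data.y[ci]), cv_id))
            counter += 1
    return records, cache


def _accuracy(records: Iterable[RunRecord]) -> float:
    records = list(records)
    return float(np.mean([r.prediction == r.truth for r in records]))


# ----------------------------------------------------------------------
# hyperparameter optimization
# ----------------------------------------------------------------------

def optimize_hyperparameters(
    table: FeatureTable,
    task: TaskDefinition,
    family: str,
    grid: Sequence[ModelConfig] | None = None,
    settings: PipelineSettings = PipelineSettings(),
    outer_plan: list[tuple[str, tuple[str, ...]]] | None = None,
    feat_names: tuple[str, ...] | None = None,
    return_scores: bool = False,
):
    """Pick the grid config with highest pooled inner-CV accuracy.

    Inner accuracies are aggregated over ALL folds across every outer
    training set; ties go to the simplest configuration (lowest k,
    highest shrinkage, smallest gamma multiplier), then grid order.
    """
    grid = tuple(DEFAULT_GRIDS[family] if grid is None else grid)
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    for cfg in grid:
        if cfg.family != family:
            raise ValueError(f"grid config family {cfg.family!r} does not match {family!r}")
    data = _TaskData(table, task)
    feat_names = tuple(feat_names or data.features)
    if outer_plan is None:
        outer_plan = outer_split_plan(table, task, settings.mode, settings.seed)
    if len(grid) == 1:
        return (grid[0], {grid[0]: float("nan")}) if return_scores else grid[0]
    scores: dict[ModelConfig, float] = {}
    for cfg in grid:
        records, _ = _pooled_cv(data, outer_plan, feat_names, cfg, settings)
        scores[cfg] = _accuracy(records)
    best = min(
        range(len(grid)),
        key=lambda i: (-scores[grid[i]], grid[i].complexity_key(), i),
    )
    return (grid[best], scores) if return_scores else grid[best]


# ----------------------------------------------------------------------
# permutation importance
# ----------------------------------------------------------------------

def _importances_from_cache(
    cache: list[_FoldCase],
    all_features: tuple[str, ...],
    feat_names: tuple[str, ...],
    repeats: int,
    rng: np.random.Generator,
) -> ImportanceReport:
    feat_idx = np.array([all_features.index(f) for f in feat_names])
    n = len(cache)
    truths = np.array([c.truth for c in cache])
    base_pred = np.array([
        1 if _score_case(c.model, c.scaling, c.x_raw, feat_idx) >= 0 else -1 for c in cache
    ])
    baseline = float(np.mean(base_pred == truths))

    means, sds = [], []
    for f in feat_names:
        j_global = all_features.index(f)
        j_local = list(feat_names).index(f)
        col = np.array([c.x_raw[j_global] for c in cache])
        perms = np.stack([rng.permutation(n) for _ in range(repeats)])  # (repeats, n)
        permuted = col[perms]  # value assigned to case i in repeat r -> permuted[r, i]
        preds = np.empty((repeats, n), dtype=int)
        for i, c in enumerate(cache):
            z = apply_scaling(np.tile(c.x_raw[feat_idx], (repeats, 1)), c.scaling)
            z[:, j_local] = (permuted[:, i] - c.scaling.location[j_local]) / c.scaling.scale[j_local]
            preds[:, i] = np.where(c.model.decision_score(z) >= 0, 1, -1)
        accs = (preds == truths).mean(axis=1)
        means.append(baseline - float(accs.mean()))
        sds.append(float(accs.std(ddof=1)) if repeats > 1 else 0.0)
    return ImportanceReport(
        features=feat_names,
        importance=tuple(means),
        importance_sd=tuple(sds),
        baseline_accuracy=baseline,
        repeats=repeats,
    )


def permutation_importance(
    table: FeatureTable,
    task: TaskDefinition,
    config: ModelConfig,
    feature: str,
    repeats: int = 100,
    seed: int = 0,
    settings: PipelineSettings | None = None,
    features: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Accuracy drop (mean, SD over repeats) from permuting one feature.

    The feature's raw values are shuffled across the pooled inner-CV
    evaluation cases; each case is then re-scaled with its own fold's
    transfer scaling and re-scored by its own fold's model.
    """
    settings = settings or PipelineSettings(seed=seed)
    data = _TaskData(table, task)
    feat_names = tuple(features or data.features)
    if feature not in feat_names:
        raise ValueError(f"feature {feature!r} is not in the retained set {feat_names}")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    outer_plan = outer_split_plan(table, task, settings.mode, settings.seed)
    _, cache = _pooled_cv(data, outer_plan, feat_names, config, settings, keep_cache=True)
    report = _importances_from_cache(
        cache, data.features, feat_names, repeats, _stream(seed, "perm", task.name, feature)
    )
    i = report.features.index(feature)
    return report.importance[i], report.importance_sd[i]


# ----------------------------------------------------------------------
# recursive feature elimination
# ----------------------------------------------------------------------

def recursive_feature_elimination(
    table: FeatureTable,
    task: TaskDefinition,
    config: ModelConfig,
    settings: PipelineSettings = PipelineSettings(),
    outer_plan: list[tuple[str, tuple[str, ...]]] | None = None,
):
    """Drop lowest-importance features while pooled CV strictly improves.

    Returns ``(retained_features, trail, final_records, final_importance)``
    where ``trail`` is the full audit of every step (candidate metrics
    and whether the reduction was accepted).  Elimination stops at the
    first non-improvement (in both accuracy and AUROC) or when a single
    feature remains.
    """
    data = _TaskData(table, task)
    if len(data.features) < 2:
        raise ValueError("need >= 2 features for recursive elimination")
    if outer_plan is None:
        outer_plan = outer_split_plan(table, task, settings.mode, settings.seed)

    current = tuple(data.features)
    records, cache = _pooled_cv(data, outer_plan, current, config, settings, keep_cache=True)
    acc, auc = _accuracy(records), evaluation.roc(records).auroc
    step = 0
    report = _importances_from_cache(
        cache, data.features, current, settings.importance_repeats,
        _stream(settings.seed, "perm", task.name, config.family, step),
    )
    trail: list[dict] = [{
        "features": current, "cv_accuracy": acc, "cv_auroc": auc,
        "importance": report, "dropped": None, "accepted": True,
    }]
    while len(current) > 1:
        worst = min(range(len(current)), key=lambda i: (report.importance[i], i))
        candidate = tuple(f for i, f in enumerate(current) if i != worst)
        cand_records, cand_cache = _pooled_cv(
            data, outer_plan, candidate, config, settings, keep_cache=True
        )
        cand_acc, cand_auc = _accuracy(cand_records), evaluation.roc(cand_records).auroc
        accepted = (cand_acc > acc) or (cand_auc > auc)
        step += 1
        cand_report = _importances_from_cache(
            cand_cache, data.features, candidate, settings.importance_repeats,
            _stream(settings.seed, "perm", task.name, config.family, step),
        ) if accepted and len(candidate) > 1 else None
        trail.append({
            "features": candidate, "cv_accuracy": cand_acc, "cv_auroc": cand_auc,
            "importance": cand_report, "dropped": current[worst], "accepted": accepted,
        })
        if not accepted:
            break
        current, records, acc, auc = candidate, cand_records, cand_acc, cand_auc
        if cand_report is None:
            break
        report = cand_report
    final_importance = next(
        (t["importance"] for t in reversed(trail) if t["accepted"] and t["importance"] is not None),
        trail[0]["importance"],
    )
    return current, trail, records, final_importance


# ----------------------------------------------------------------------
# full question
# ----------------------------------------------------------------------

def run_question(
    table: FeatureTable,
    task: TaskDefinition,
    family: str,
    settings: PipelineSettings = PipelineSettings(),
) -> QuestionResult:
    """Optimize, select features, then classify every held-out case.

    Stages: hyperparameter optimization on pooled inner CV ->
    permutation-importance recursive feature elimination -> one final
    fit + held-out classification per outer run.  Fully deterministic
    given the master seed in ``settings``.
    """
    data = _TaskData(table, task)
    _check_missing(data, settings)
    outer_plan = outer_split_plan(table, task, settings.mode, settings.seed)

    grid = tuple(DEFAULT_GRIDS[family] if settings.grid is None else settings.grid)
    config = optimize_hyperparameters(
        table, task, family, grid, settings, outer_plan=outer_plan
    )

    cv_records: list[RunRecord] = []
    importance = None
    trail: list[dict] = []
    if settings.feature_elimination:
        retained, trail, cv_records, importance = recursive_feature_elimination(
            table, task, config, settings, outer_plan=outer_plan
        )
    else:
        retained = tuple(data.features)
        if len(grid) > 1:
            cv_records, _ = _pooled_cv(data, outer_plan, retained, config, settings)

    feat_idx = np.array([data.features.index(f) for f in retained])
    outer_records: list[RunRecord] = []
    models: list[TrainedModel] = []
    for run_i, (held_id, train_ids) in enumerate(outer_plan):
        tr_idx = np.array([data.pos_of[i] for i in train_ids])
        smote_seed = int(_stream(settings.seed, "smote-outer", run_i).integers(2**31))
        model, scaling = _fit_training_set(
            data.X[tr_idx], data.y[tr_idx], feat_idx, retained,
            config, settings.smote_k, smote_seed,
        )
        hi = data.pos_of[held_id]
        score = _score_case(model, scaling, data.X[hi], feat_idx)
        outer_records.append(RunRecord(
            case_id=held_id, truth=int(data.y[hi]), prediction=1 if score >= 0 else -1,
            score=score, loop="outer_heldout", config_used=config,
            features_used=retained, run_index=run_i,
        ))
        models.append(model)

    return QuestionResult(
        task=task, family=family, settings=settings, config=config,
        retained_features=retained, outer_records=outer_records,
        cv_records=cv_records, models=models, importance=importance,
        elimination_trail=trail, outer_plan=outer_plan,
    )
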
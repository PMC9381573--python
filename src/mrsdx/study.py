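"""Study driver: Model/Results objects and the full multi-question run.

:class:`MetaboliteClassificationModel` is the package's front door,
patterned on statsmodels: construct it from a feature table (or a plain
DataFrame) plus a task and classifier family, call :meth:`fit`, and
read the estimates off the returned
:class:`MetaboliteClassificationResults` — held-out and cross-validation
performance, the chosen hyperparameters, the retained metabolites and
their permutation importances — via ``summary()`` or the accessor
methods.  :func:`run_study` sweeps all requested (task, family) pairs
and writes the full artifact bundle to disk.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classifiers import DEFAULT_CONFIGS, FAMILIES, ModelConfig, TrainedModel
from .cohort import (
    CohortSpec,
    FeatureTable,
    GroupSpec,
    default_study_spec,
    generate_cohort,
)
from .evaluation import compare_accuracy_sets, roc, summarize
from .preprocess import DEFAULT_AGE_TARGETS, age_correct, impute_class_mean
from .validation import (
    TASKS,
    PipelineSettings,
    QuestionResult,
    RunRecord,
    TaskDefinition,
    run_question,
)


class StudyError(RuntimeError):
    """A study stage failed; carries the stage name and context."""


# ----------------------------------------------------------------------
# Model / Results
# ----------------------------------------------------------------------

def _resolve_task(task: str | TaskDefinition) -> TaskDefinition:
    if isinstance(task, TaskDefinition):
        return task
    try:
        return TASKS[task]
    except KeyError:
        raise KeyError(f"unknown task {task!r}; known tasks: {sorted(TASKS)}") from None


class MetaboliteClassificationModel:
    """One binary metabolite-classification question, ready to fit.

    Parameters
    ----------
    table : FeatureTable
        Prepared cohort (imputed and age-corrected unless
        ``settings.imputation == 'train_only'``).
    task : str or TaskDefinition
        One of ``MS_vs_HC, RR_vs_HC, P_vs_HC, RR_vs_P`` or a custom
        definition.
    family : {"QDA", "KNN", "SVM"}
    settings : PipelineSettings, optional
        Resampling mode, hyperparameter grid, feature-elimination and
        SMOTE knobs, master seed.
    """

    def __init__(
        self,
        table: FeatureTable,
        task: str | TaskDefinition,
        family: str = "QDA",
        settings: PipelineSettings | None = None,
    ):
        if family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
        self.table = table
        self.task = _resolve_task(task)
        self.family = family
        self.settings = settings or PipelineSettings()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        task: str | TaskDefinition,
        family: str = "QDA",
        settings: PipelineSettings | None = None,
    ) -> "MetaboliteClassificationModel":
        return cls(FeatureTable(df), task, family, settings)

    def fit(self) -> "MetaboliteClassificationResults":
        result = run_question(self.table, self.task, self.family, self.settings)
        return MetaboliteClassificationResults(self, result)


class MetaboliteClassificationResults:
    """Fit output: run populations, summaries, importances, models."""

    def __init__(self, model: MetaboliteClassificationModel, result: QuestionResult):
        self.model = model
        self._result = result

    # -- raw components ------------------------------------------------
    @property
    def config(self) -> ModelConfig:
        return self._result.config

    @property
    def retained_features(self) -> tuple[str, ...]:
        return self._result.retained_features

    @property
    def outer_records(self) -> list[RunRecord]:
        return self._result.outer_records

    @property
    def cv_records(self) -> list[RunRecord]:
        return self._result.cv_records

    @property
    def trained_models(self) -> list[TrainedModel]:
        return self._result.models

    @property
    def importance(self):
        return self._result.importance

    @property
    def elimination_trail(self):
        return self._result.elimination_trail

    # -- summaries -----------------------------------------------------
    def heldout_summary(self):
        return summarize(self.outer_records)

    def cv_summary(self):
        if not self.cv_records:
            return None
        return summarize(self.cv_records)

    def roc(self, loop: str = "outer_heldout"):
        records = self.outer_records if loop == "outer_heldout" else self.cv_records
        if not records:
            raise ValueError(f"no records for loop {loop!r}")
        return roc(records)

    def runs_frame(self) -> pd.DataFrame:
        rows = [
            {
                "loop": r.loop, "run_index": r.run_index, "case_id": r.case_id,
                "truth": r.truth, "prediction": r.prediction, "score": r.score,
                "family": self._result.family,
                "config": json.dumps(r.config_used.__dict__, sort_keys=True),
                "features": "|".join(r.features_used),
            }
            for r in self.outer_records + self.cv_records
        ]
        return pd.DataFrame(rows)

    def importance_frame(self) -> pd.DataFrame:
        imp = self.importance
        if imp is None:
            return pd.DataFrame(columns=["feature", "importance", "importance_sd", "rank"])
        rank = {f: i + 1 for i, f in enumerate(imp.ranking)}
        return pd.DataFrame({
            "feature": imp.features,
            "importance": imp.importance,
            "importance_sd": imp.importance_sd,
            "rank": [rank[f] for f in imp.features],
        })

    def summary(self) -> str:
        """Human-readable performance table (statsmodels-style)."""
        res = self._result
        lines = [
            "Metabolite classification results",
            "=" * 66,
            f"Task:              {res.task.name}"
            f"  (+: {','.join(sorted(res.task.positive_groups))}"
            f" | -: {','.join(sorted(res.task.negative_groups))})",
            f"Family:            {res.family}",
            f"Outer mode:        {res.settings.mode}  (runs: {len(res.outer_records)})",
            f"Config:            {res.config}",
            f"Retained features: {', '.join(res.retained_features)}",
            "-" * 66,
            f"{'loop':<14}{'n':>5}{'acc':>8}{'sens':>8}{'spec':>8}{'prec':>8}{'F1':>8}{'AUROC':>8}",
        ]

        def fmt(x):
            return "   n/a" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:6.3f}"

        for label, s in (("held-out", self.heldout_summary()), ("inner CV", self.cv_summary())):
            if s is None:
                continue
            lines.append(
                f"{label:<14}{s.n_runs:>5}"
                + "".join(f"{fmt(v):>8}" for v in (
                    s.accuracy, s.sensitivity, s.specificity, s.precision, s.f1, s.auroc))
            )
        if self.importance is not None:
            lines.append("-" * 66)
            lines.append("Permutation importance ranking: " + " > ".join(self.importance.ranking))
        lines.append("=" * 66)
        return "\n".join(lines)

    def plot_roc(self, ax=None, loop: str = "outer_heldout"):
        """ROC curve plot; returns the matplotlib Axes."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        curve = self.roc(loop)
        ax.plot(curve.fpr, curve.tpr, label=f"{self._result.family} AUROC={curve.auroc:.2f}")
        ax.plot([0, 1], [0, 1], ls=":", c="grey", lw=1)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"{self._result.task.name} ({loop})")
        ax.legend(loc="lower right", frameon=False)
        return ax

    # -- persistence ---------------------------------------------------
    def save_bundle(self, outdir) -> None:
        """Write runs.csv, summary.json, importance.csv, roc.csv, models.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.runs_frame().to_csv(outdir / "runs.csv", index=False, float_format="%.12g")
        self.importance_frame().to_csv(outdir / "importance.csv", index=False, float_format="%.12g")
        payload = {
            "task": self._result.task.name,
            "family": self._result.family,
            "mode": self._result.settings.mode,
            "config": self.config.__dict__,
            "retained_features": list(self.retained_features),
            "outer_heldout": self.heldout_summary().as_dict(),
            "inner_cv": None if self.cv_summary() is None else self.cv_summary().as_dict(),
        }
        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        rows = []
        for loop in ("outer_heldout", "inner_cv"):
            try:
                curve = self.roc(loop)
            except ValueError:
                continue
            t = np.concatenate([[np.inf], curve.thresholds, [-np.inf]])
            for thr, fp, tp in zip(t, curve.fpr, curve.tpr):
                rows.append({"loop": loop, "threshold": thr, "fpr": fp, "tpr": tp})
        pd.DataFrame(rows).to_csv(outdir / "roc.csv", index=False, float_format="%.12g")
        with open(outdir / "models.json", "w", encoding="utf-8") as fh:
            json.dump([m.to_dict() for m in self.trained_models], fh)


# ----------------------------------------------------------------------
# study configuration
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """Reproducible description of one full study run.

    Either ``data`` (CSV path) or ``simulate`` (kwargs for
    :func:`default_study_spec`, e.g. ``{"effect_size_sd": -0.8}``)
    supplies the cohort.  The master ``seed`` drives simulation and
    every stochastic pipeline stage.
    """

    tasks: tuple[str, ...] = ("MS_vs_HC", "RR_vs_HC", "P_vs_HC", "RR_vs_P")
    families: tuple[str, ...] = ("QDA", "KNN", "SVM")
    mode: str = "balanced"
    seed: int = 0
    data: str | None = None
    simulate: Mapping[str, float] = field(default_factory=dict)
    outdir: str = "study_out"
    smote_k: int = 5
    feature_elimination: bool = True
    importance_repeats: int = 100
    grid_search: bool = True
    imputation_mode: str = "paper"
    age_targets: tuple[str, ...] = DEFAULT_AGE_TARGETS
    age_alpha: float = 0.05
    control_group: str = "HC"

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        nested = {}
        if "smote" in d:
            nested["smote_k"] = int(d.pop("smote").get("k_neighbors", 5))
        if "age_correction" in d:
            ac = d.pop("age_correction")
            nested["age_targets"] = tuple(ac.get("targets", DEFAULT_AGE_TARGETS))
            nested["age_alpha"] = float(ac.get("alpha", 0.05))
            nested["control_group"] = ac.get("control_group", "HC")
        if "imputation" in d:
            nested["imputation_mode"] = d.pop("imputation").get("mode", "paper")
        for key in ("tasks", "families", "age_targets"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        if unknown:
            raise ValueError(f"unknown study config key(s): {sorted(unknown)}")
        return cls(**{**d, **nested})

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        body = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else dict(v) if isinstance(v, Mapping) else v)
             for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(body.encode()).hexdigest()


def cohort_spec_from_dict(d: Mapping) -> CohortSpec:
    """Build a CohortSpec from a plain (YAML-loadable) mapping."""
    groups = tuple(
        GroupSpec(
            name=g["name"], n=int(g["n"]),
            age_mean=float(g["age_mean"]), age_sd=float(g["age_sd"]),
            metab_means={m: float(g["metab_means"][m]) for m in g["metab_means"]},
            metab_sds={m: float(g["metab_sds"][m]) for m in g["metab_sds"]},
            sex_ratio=float(g.get("sex_ratio", 0.5)),
        )
        for g in d["groups"]
    )
    return CohortSpec(
        groups=groups,
        age_betas={m: float(v) for m, v in (d.get("age_betas") or {}).items()},
        missing_spec=tuple((t[0], t[1], int(t[2])) for t in (d.get("missing_spec") or ())),
        seed=int(d.get("seed", 0)),
        age_center=d.get("age_center"),
    )


# ----------------------------------------------------------------------
# full study
# ----------------------------------------------------------------------

def load_or_simulate(cfg: StudyConfig) -> FeatureTable:
    if cfg.data is not None:
        path = Path(cfg.data)
        if not path.exists():
            raise StudyError(f"stage 'load': data file not found: {path}")
        return FeatureTable.from_csv(path)
    spec = default_study_spec(seed=cfg.seed, **dict(cfg.simulate))
    return generate_cohort(spec)


def prepare_features(
    table: FeatureTable,
    control_group: str = "HC",
    age_targets: Sequence[str] = DEFAULT_AGE_TARGETS,
    age_alpha: float = 0.05,
    imputation_mode: str = "paper",
) -> FeatureTable:
    """Imputation (paper mode) then control-referenced age correction."""
    if imputation_mode == "paper":
        table = impute_class_mean(table)
    return age_correct(table, control_group=control_group, targets=age_targets, alpha=age_alpha)


def run_study(cfg: StudyConfig) -> dict:
    """Run every (task, family) pair and write the artifact bundle.

    Emits per-pair ``runs.csv``, ``summary.json``, ``importance.csv``,
    ``roc.csv``, ``models.json``; a cross-question accuracy table with
    the two accuracy t-tests; and a manifest with the config hash and
    per-stage timings.  Failed pairs are flagged in the manifest and a
    StudyError naming them is raised after the bundle is written.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    table = load_or_simulate(cfg)
    table.to_csv(outdir / "cohort.csv")
    prepared = prepare_features(
        table, cfg.control_group, cfg.age_targets, cfg.age_alpha, cfg.imputation_mode
    )
    timings = {"prepare": time.perf_counter() - t0}

    settings = PipelineSettings(
        mode=cfg.mode,
        grid=None,
        feature_elimination=cfg.feature_elimination,
        importance_repeats=cfg.importance_repeats,
        smote_k=cfg.smote_k,
        seed=cfg.seed,
        imputation=cfg.imputation_mode,
    )
    summaries: dict[tuple[str, str], dict] = {}
    failures: dict[str, str] = {}
    accuracies: dict[str, dict[str, float]] = {}
    for task_name in cfg.tasks:
        for family in cfg.families:
            tag = f"{task_name}/{family}"
            t1 = time.perf_counter()
            try:
                fam_settings = settings if cfg.grid_search else replace(
                    settings, grid=(DEFAULT_CONFIGS[family],)
                )
                res = MetaboliteClassificationModel(
                    prepared, task_name, family, fam_settings
                ).fit()
                res.save_bundle(outdir / task_name / family)
                summaries[(task_name, family)] = {
                    "accuracy": res.heldout_summary().accuracy,
                    "auroc": res.heldout_summary().auroc,
                }
                accuracies.setdefault(task_name, {})[family] = res.heldout_summary().accuracy
            except Exception as exc:  # noqa: BLE001 - flagged, never silent
                failures[tag] = f"{type(exc).__name__}: {exc}"
            timings[tag] = time.perf_counter() - t1

    comparisons = {}
    for label, (ta, tb) in {
        "RR_vs_P_vs_MS_vs_HC": ("RR_vs_P", "MS_vs_HC"),
        "P_vs_HC_vs_RR_vs_HC": ("P_vs_HC", "RR_vs_HC"),
    }.items():
        if ta in accuracies and tb in accuracies and len(accuracies[ta]) >= 2:
            cmp_res = compare_accuracy_sets(
                list(accuracies[ta].values()), list(accuracies[tb].values())
            )
            comparisons[label] = {
                "t": cmp_res.t, "df": cmp_res.df, "p": cmp_res.p,
                "df_min": cmp_res.df_min, "p_min": cmp_res.p_min,
                "mean_a": cmp_res.mean_a, "mean_b": cmp_res.mean_b,
            }
    with open(outdir / "comparisons.json", "w", encoding="utf-8") as fh:
        json.dump(comparisons, fh, indent=1, sort_keys=True)

    rows = [
        {"task": t, "family": f, **vals}
        for (t, f), vals in sorted(summaries.items())
    ]
    pd.DataFrame(rows).to_csv(outdir / "performance.csv", index=False, float_format="%.12g")

    manifest = {
        "package_version": __version__,
        "config": cfg.__dict__ | {"tasks": list(cfg.tasks), "families": list(cfg.families),
                                  "age_targets": list(cfg.age_targets),
                                  "simulate": dict(cfg.simulate)},
        "config_sha256": cfg.digest(),
        "seed": cfg.seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "failures": failures,
        "n_summaries": len(summaries),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    if failures:
        raise StudyError(f"{len(failures)} stage(s) failed: {failures}")
    return manifest
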
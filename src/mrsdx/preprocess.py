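"""Feature-level preparation: age correction, imputation, scaling, SMOTE.

Four steps sit between the raw metabolite table and any classifier fit:

* control-referenced age correction — remove linear age trends whose
  slope is significant in the healthy-control group;
* class-mean imputation of missing entries (two GABA values in the
  packaged cohort);
* per-training-set z-scaling, with the fitted location/scale
  transferred unchanged to held-out cases so validation data never
  influence the transform;
* SMOTE class balancing: synthetic minority cases interpolated along
  segments to each case's k nearest minority neighbors until class
  sizes match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort import METABOLITES, FeatureTable

DEFAULT_AGE_TARGETS: tuple[str, ...] = ("tNAA", "tCho", "mIns", "Glu")


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature location (mean) and scale (sd, ddof=1) of a training set."""

    features: tuple[str, ...]
    location: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if len(self.features) != len(self.location) or len(self.features) != len(self.scale):
            raise ValueError("features, location and scale must have equal length")
        if np.any(self.scale <= 0):
            bad = [f for f, s in zip(self.features, self.scale) if s <= 0]
            raise ValueError(f"non-positive scale for feature(s): {bad}")

    def as_dicts(self) -> tuple[dict[str, float], dict[str, float]]:
        return (
            dict(zip(self.features, map(float, self.location))),
            dict(zip(self.features, map(float, self.scale))),
        )


@dataclass(frozen=True)
class SmoteConfig:
    """SMOTE settings: neighbor count k (>= 1) and RNG seed."""

    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError(f"k_neighbors must be >= 1, got {self.k_neighbors}")


# ----------------------------------------------------------------------
# age correction
# ----------------------------------------------------------------------

def age_correct(
    table: FeatureTable,
    control_group: str = "HC",
    targets: Sequence[str] = DEFAULT_AGE_TARGETS,
    alpha: float = 0.05,
) -> FeatureTable:
    """Remove significant control-cohort linear age trends from ``targets``.

    For each target metabolite an OLS fit of concentration on age is run
    over the control records only.  If the slope's two-tailed p-value is
    below ``alpha``, ``beta * (age - control mean age)`` is subtracted
    from that metabolite for *all* records; otherwise the metabolite is
    untouched.  Returns a new table; the input is not modified.
    """
    unknown = [t for t in targets if t not in table.feature_order]
    if unknown:
        raise ValueError(f"unknown target metabolite(s): {unknown}")
    control = table.groups == control_group
    if control.sum() < 3:
        raise ValueError(
            f"need >= 3 '{control_group}' records to estimate age slopes, got {int(control.sum())}"
        )
    ages = table.ages
    ctrl_age = ages[control]
    ctrl_age_mean = float(ctrl_age.mean())
    values = table.feature_matrix()
    for m in targets:
        j = table.feature_order.index(m)
        col = values[control, j]
        ok = ~np.isnan(col)
        if ok.sum() < 3:
            raise ValueError(f"need >= 3 non-missing control values for '{m}', got {int(ok.sum())}")
        fit = stats.linregress(ctrl_age[ok], col[ok])
        if fit.pvalue < alpha:
            values[:, j] = values[:, j] - fit.slope * (ages - ctrl_age_mean)
    return table.replace_features(values)


# ----------------------------------------------------------------------
# imputation
# ----------------------------------------------------------------------

def impute_class_mean(table: FeatureTable) -> FeatureTable:
    """Replace each missing entry by its group's mean for that metabolite.

    Mirrors the study's whole-cohort, prior-to-analysis behaviour (class
    = three-level phenotype group).  A (group, metabolite) cell that is
    entirely missing is an error.  No non-missing cell changes.
    """
    values = table.feature_matrix()
    groups = table.groups
    missing = np.isnan(values)
    if not missing.any():
        return table
    for j, m in enumerate(table.feature_order):
        for g in np.unique(groups[missing[:, j]]):
            in_group = groups == g
            col = values[in_group, j]
            ok = ~np.isnan(col)
            if not ok.any():
                raise ValueError(f"cannot impute '{m}' in group '{g}': all values missing")
            fill = float(col[ok].mean())
            rows = in_group & missing[:, j]
            values[rows, j] = fill
    return table.replace_features(values)


# ----------------------------------------------------------------------
# scaling
# ----------------------------------------------------------------------

def fit_scaling(training: FeatureTable | np.ndarray, features: Sequence[str] = METABOLITES) -> ScalingParams:
    """Per-feature mean/sd (ddof=1) over the training records only."""
    if isinstance(training, FeatureTable):
        X = training.feature_matrix()
        features = training.feature_order
    else:
        X = np.asarray(training, dtype=float)
    features = tuple(features)
    if X.shape[0] < 2:
        raise ValueError(f"need >= 2 training records to fit scaling, got {X.shape[0]}")
    if np.isnan(X).any():
        raise ValueError("training set contains missing values; impute before scaling")
    loc = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    zero = scale == 0
    if zero.any():
        bad = [f for f, z in zip(features, zero) if z]
        raise ValueError(f"zero-variance feature(s) in training set: {bad}")
    return ScalingParams(features=features, location=loc, scale=scale)


def apply_scaling(table: FeatureTable | np.ndarray, params: ScalingParams):
    """``(x - location) / scale``; a pure function of its inputs."""
    if isinstance(table, FeatureTable):
        missing_feats = [f for f in table.feature_order if f not in params.features]
        if missing_feats:
            raise ValueError(f"feature(s) absent from scaling params: {missing_feats}")
        order = [params.features.index(f) for f in table.feature_order]
        loc, scale = params.location[order], params.scale[order]
        return table.replace_features((table.feature_matrix() - loc) / scale)
    X = np.asarray(table, dtype=float)
    if X.shape[-1] != len(params.features):
        raise ValueError(f"expected {len(params.features)} features, got {X.shape[-1]}")
    return (X - params.location) / params.scale


def invert_scaling(X: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Algebraic inverse of :func:`apply_scaling` (for round-trip checks)."""
    return np.asarray(X, dtype=float) * params.scale + params.location


def _guarded_zfit(X: np.ndarray, features: Sequence[str]) -> ScalingParams:
    # Pipeline-internal variant: zero-sd (constant) features scale by 1
    # so they standardise to 0 instead of aborting the fold; a constant
    # column carries no class information either way.
    X = np.asarray(X, dtype=float)
    loc = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    return ScalingParams(features=tuple(features), location=loc, scale=scale)


# ----------------------------------------------------------------------
# SMOTE
# ----------------------------------------------------------------------

def smote_balance(minority: np.ndarray, majority_count: int, cfg: SmoteConfig) -> np.ndarray:
    """Oversample ``minority`` rows to exactly ``majority_count`` rows.

    Each synthetic point is ``x_i + u * (x_nn - x_i)`` with
    ``u ~ Uniform(0, 1)`` and ``x_nn`` drawn uniformly among the
    ``k_neighbors`` nearest minority neighbors of ``x_i`` (Euclidean
    distance with per-feature standardisation, so the metric matches the
    scaled feature space; the interpolated segment itself is invariant
    to that affine map).  Base cases are cycled in order.  Original rows
    are returned unchanged, first, followed by the synthetic rows.
    """
    X = np.asarray(minority, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"minority must be 2-D (records x features), got ndim={X.ndim}")
    n = X.shape[0]
    if n < 2:
        raise ValueError(f"need >= 2 minority records for SMOTE, got {n}")
    if majority_count < n:
        raise ValueError(f"majority_count {majority_count} < minority size {n}")
    if cfg.k_neighbors > n - 1:
        raise ValueError(
            f"k_neighbors={cfg.k_neighbors} exceeds available minority neighbors ({n - 1})"
        )
    if majority_count == n:
        return X.copy()

    sd = X.std(axis=0, ddof=1)
    Z = X / np.where(sd > 0, sd, 1.0)
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    # ties broken by lowest row index: lexsort is stable on the index key
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), d2), axis=1)
    neighbors = order[:, : cfg.k_neighbors]

    rng = np.random.default_rng(cfg.seed)
    deficit = majority_count - n
    synth = np.empty((deficit, X.shape[1]))
    for t in range(deficit):
        i = t % n
        nn = neighbors[i, rng.integers(cfg.k_neighbors)]
        u = rng.uniform()
        synth[t] = X[i] + u * (X[nn] - X[i])
    return np.vstack([X, synth])
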
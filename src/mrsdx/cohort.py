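"""Synthetic cohorts of frontal-cortex MRS metabolite profiles.

The study population this module emulates consists of three groups —
healthy controls (HC), relapsing–remitting multiple sclerosis (RR-MS)
and progressive multiple sclerosis (P-MS) — each characterised by seven
metabolite concentrations (mM, referenced to an assumed 10 mM total
creatine) measured in a single prefrontal-cortex voxel at 7 T:
glutamate (Glu), glutamine (Gln), GABA, glutathione (GSH), total
choline (tCho), total N-acetyl aspartate (tNAA) and myoinositol (mIns).

Features are modelled as Gaussians with additive linear age effects; a
configurable mean shift in GABA and Glu distinguishes the progressive
group, and two GABA values (one HC, one P-MS) are left missing, matching
the structure of the source cohort.  Raw patient data are not available,
so all downstream stages are exercised on cohorts drawn here.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical metabolite feature order used throughout the package.
METABOLITES: tuple[str, ...] = ("Glu", "Gln", "GABA", "GSH", "tCho", "tNAA", "mIns")

#: Non-feature columns of the on-disk CSV schema, in order.
ID_COLUMNS: tuple[str, ...] = ("id", "group", "age")

MIN_AGE = 18.0  # years; ages are truncated here to avoid non-physical values


class CohortSpecError(ValueError):
    """A cohort specification violates its invariants."""


def _check(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise CohortSpecError(f"invalid field '{field_name}': {msg}")


@dataclass(frozen=True)
class GroupSpec:
    """Distributional description of one participant group.

    Parameters
    ----------
    name : group label (e.g. ``"HC"``, ``"RR-MS"``, ``"P-MS"``).
    n : number of participants (>= 2).
    age_mean, age_sd : age distribution in years.
    metab_means, metab_sds : per-metabolite mean and SD in mM
        (tCr-referenced); keys must be exactly :data:`METABOLITES`.
    sex_ratio : fraction female; metadata only, never a feature.
    """

    name: str
    n: int
    age_mean: float
    age_sd: float
    metab_means: Mapping[str, float]
    metab_sds: Mapping[str, float]
    sex_ratio: float = 0.5

    def __post_init__(self) -> None:
        _check(self.n >= 2, "n", f"group '{self.name}' needs n >= 2, got {self.n}")
        _check(self.age_sd > 0, "age_sd", f"group '{self.name}' needs age_sd > 0")
        for label, mapping in (("metab_means", self.metab_means), ("metab_sds", self.metab_sds)):
            _check(
                set(mapping) == set(METABOLITES),
                label,
                f"group '{self.name}' keys must be exactly {sorted(METABOLITES)}, "
                f"got {sorted(mapping)}",
            )
        _check(
            all(v > 0 for v in self.metab_sds.values()),
            "metab_sds",
            f"group '{self.name}' requires all sds > 0",
        )
        _check(0.0 <= self.sex_ratio <= 1.0, "sex_ratio", "must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Full cohort description: groups, age effects, missingness, seed.

    ``age_betas`` maps metabolite -> mM per year, applied additively as
    ``beta * (age - age_center)``; ``age_center`` defaults to the
    n-weighted mean of the group age means (the centering constant is
    exposed explicitly because raw-vs-centered age is a modelling
    choice).  ``missing_spec`` lists (group, metabolite, count) triples
    whose entries are blanked after generation.
    """

    groups: tuple[GroupSpec, ...]
    age_betas: Mapping[str, float] = field(default_factory=dict)
    missing_spec: tuple[tuple[str, str, int], ...] = ()
    seed: int = 0
    age_center: float | None = None

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        _check(len(names) == len(set(names)), "groups", f"group names must be unique, got {names}")
        _check(len(self.groups) >= 1, "groups", "at least one group required")
        for m in self.age_betas:
            _check(m in METABOLITES, "age_betas", f"unknown metabolite '{m}'")
        by_name = {g.name: g for g in self.groups}
        for grp, metab, count in self.missing_spec:
            _check(grp in by_name, "missing_spec", f"unknown group '{grp}'")
            _check(metab in METABOLITES, "missing_spec", f"unknown metabolite '{metab}'")
            _check(
                0 <= count <= by_name[grp].n,
                "missing_spec",
                f"missing count {count} exceeds group '{grp}' size {by_name[grp].n}",
            )

    @property
    def pooled_age_mean(self) -> float:
        if self.age_center is not None:
            return float(self.age_center)
        total = sum(g.n for g in self.groups)
        return float(sum(g.n * g.age_mean for g in self.groups) / total)


class FeatureTable:
    """Participants x metabolite features, the pipeline's universal currency.

    Thin immutable wrapper around a :class:`pandas.DataFrame` with
    columns ``id, group, age`` followed by the seven metabolites.
    Missing entries are NaN.  Methods return new tables; the wrapped
    frame is never mutated in place.
    """

    def __init__(self, data: pd.DataFrame, feature_order: Sequence[str] = METABOLITES):
        feature_order = tuple(feature_order)
        required = list(ID_COLUMNS) + list(feature_order)
        missing_cols = [c for c in required if c not in data.columns]
        if missing_cols:
            raise ValueError(f"FeatureTable missing column(s): {missing_cols}")
        extra = [c for c in data.columns if c not in required]
        if extra:
            raise ValueError(f"FeatureTable has unknown column(s): {extra}")
        df = data.loc[:, required].reset_index(drop=True).copy()
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate participant id(s): {dupes}")
        ages = pd.to_numeric(df["age"], errors="coerce")
        if ages.isna().any():
            bad = df.loc[ages.isna(), "id"].tolist()
            raise ValueError(f"non-numeric age for id(s): {bad}")
        if (ages <= 0).any():
            bad = df.loc[ages <= 0, "id"].tolist()
            raise ValueError(f"non-positive age for id(s): {bad}")
        df["age"] = ages.astype(float)
        for m in feature_order:
            df[m] = pd.to_numeric(df[m], errors="coerce").astype(float)
        self._data = df
        self.feature_order = feature_order

    # -- accessors -----------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        """The underlying frame (treat as read-only)."""
        return self._data

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.feature_order == other.feature_order and self._data.equals(other._data)

    @property
    def ids(self) -> np.ndarray:
        return self._data["id"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self._data["group"].to_numpy()

    @property
    def ages(self) -> np.ndarray:
        return self._data["age"].to_numpy(dtype=float)

    def feature_matrix(self) -> np.ndarray:
        """(n, 7) float array of concentrations; NaN marks missing."""
        return self._data.loc[:, self.feature_order].to_numpy(dtype=float)

    def n_missing(self) -> int:
        return int(self._data.loc[:, self.feature_order].isna().to_numpy().sum())

    # -- functional updates --------------------------------------------
    def replace_features(self, values: np.ndarray) -> "FeatureTable":
        if values.shape != (len(self), len(self.feature_order)):
            raise ValueError(f"expected shape {(len(self), len(self.feature_order))}, got {values.shape}")
        df = self._data.copy()
        df.loc[:, self.feature_order] = values
        return FeatureTable(df, self.feature_order)

    def subset(self, ids: Sequence[str]) -> "FeatureTable":
        idx = self._data.set_index("id")
        unknown = [i for i in ids if i not in idx.index]
        if unknown:
            raise KeyError(f"unknown id(s): {unknown}")
        return FeatureTable(idx.loc[list(ids)].reset_index(), self.feature_order)

    # -- I/O ------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the canonical CSV schema (empty field encodes missing).

        Values are rendered with 12 significant digits, UTF-8, LF line
        endings; a write -> read -> write cycle is byte-stable.
        """
        self._data.to_csv(
            path, index=False, float_format="%.12g", lineterminator="\n", encoding="utf-8"
        )

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        try:
            df = pd.read_csv(path, dtype={"id": str, "group": str})
        except pd.errors.EmptyDataError as exc:
            raise ValueError(f"empty feature file: {path}") from exc
        return cls(df)


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------

def _stream(seed: int, *tokens) -> np.random.Generator:
    """Deterministic named substream: one master seed, crc32-keyed tags.

    Keying streams by group/stage name (not list position) means adding
    a group or stage never perturbs the draws of existing ones.
    """
    keys = [zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *keys])


def _truncated_normal_ages(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    ages = rng.normal(mean, sd, size=n)
    while True:
        bad = ages < MIN_AGE
        if not bad.any():
            return ages
        ages[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def generate_cohort(spec: CohortSpec) -> FeatureTable:
    """Draw one cohort from ``spec``; identical spec -> identical table.

    Per group g and metabolite m:
    ``x ~ Normal(mean_gm + beta_m * (age - age_center), sd_gm**2)`` with
    ages ``Normal(age_mean_g, age_sd_g**2)`` truncated at 18 years.
    Entries designated by ``missing_spec`` are blanked afterwards.
    """
    center = spec.pooled_age_mean
    frames = []
    for g in spec.groups:
        rng = _stream(spec.seed, "group", g.name)
        ages = _truncated_normal_ages(rng, g.n, g.age_mean, g.age_sd)
        values = np.empty((g.n, len(METABOLITES)))
        for j, m in enumerate(METABOLITES):
            beta = float(spec.age_betas.get(m, 0.0))
            mu = g.metab_means[m] + beta * (ages - center)
            values[:, j] = rng.normal(mu, g.metab_sds[m])
        frame = pd.DataFrame(values, columns=list(METABOLITES))
        frame.insert(0, "age", ages)
        frame.insert(0, "group", g.name)
        frame.insert(0, "id", [f"{g.name}-{i + 1:03d}" for i in range(g.n)])
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)

    for grp, metab, count in spec.missing_spec:
        rows = np.flatnonzero(df["group"].to_numpy() == grp)
        pick = _stream(spec.seed, "missing", grp, metab).choice(rows, size=count, replace=False)
        df.loc[pick, metab] = np.nan
    return FeatureTable(df)


# ----------------------------------------------------------------------
# packaged study specification
# ----------------------------------------------------------------------

# Plausible prefrontal-cortex concentrations at 7 T, mM referenced to
# 10 mM total creatine.  The source cohort's group means are not public;
# these baselines carry realistic magnitudes and the SDs set the scale
# of the configurable group effects.
_BASELINE_MEANS: dict[str, float] = {
    "Glu": 9.0, "Gln": 2.5, "GABA": 1.2, "GSH": 1.3, "tCho": 1.8, "tNAA": 11.0, "mIns": 5.5,
}
_BASELINE_SDS: dict[str, float] = {
    "Glu": 1.0, "Gln": 0.5, "GABA": 0.25, "GSH": 0.25, "tCho": 0.3, "tNAA": 1.2, "mIns": 0.9,
}
# Additive age drift (mM / year) on the four age-corrected metabolites:
# tNAA and Glu decline with age, tCho and mIns increase.
_AGE_BETAS: dict[str, float] = {"tNAA": -0.020, "Glu": -0.020, "tCho": 0.005, "mIns": 0.015}

#: Metabolites carrying the progressive-group mean shift.
EFFECT_METABOLITES: tuple[str, ...] = ("GABA", "Glu")


def default_study_spec(effect_size_sd: float = -0.8, seed: int = 0) -> CohortSpec:
    """The packaged study cohort: HC n=24, RR-MS n=25, P-MS n=19.

    Ages are 43 +/- 15, 45 +/- 13 and 55 +/- 8.3 years respectively.
    The progressive group's GABA and Glu means are shifted by
    ``effect_size_sd`` pooled-SD units (default -0.8; use 0 for a null
    cohort with no group differences).  Two GABA entries — one HC, one
    P-MS — are missing.  Sex ratios are carried as metadata only.
    """
    def group(name, n, age_mean, age_sd, sex_ratio, shift_sd=0.0):
        means = dict(_BASELINE_MEANS)
        if shift_sd:
            for m in EFFECT_METABOLITES:
                means[m] = means[m] + shift_sd * _BASELINE_SDS[m]
        return GroupSpec(
            name=name, n=n, age_mean=age_mean, age_sd=age_sd,
            metab_means=means, metab_sds=dict(_BASELINE_SDS), sex_ratio=sex_ratio,
        )

    return CohortSpec(
        groups=(
            group("HC", 24, 43.0, 15.0, 15 / 24),
            group("RR-MS", 25, 45.0, 13.0, 17 / 25),
            group("P-MS", 19, 55.0, 8.3, 11 / 19, shift_sd=effect_size_sd),
        ),
        age_betas=dict(_AGE_BETAS),
        missing_spec=(("HC", "GABA", 1), ("P-MS", "GABA", 1)),
        seed=seed,
    )


def with_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    """Copy of ``spec`` with a different master seed."""
    return replace(spec, seed=seed)
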
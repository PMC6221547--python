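"""Quality control and scaling of raw cohort tables.

The analytic substrate is a subjects x features table of mixed
continuous/binary measurements with missing entries.  Preprocessing applies,
in order: assay-level substitutions (half-LOD for left-censored antibody
readings, a small positive floor for non-positive net cytokine responses),
log10 transformation of skewed features, missingness-based feature and
subject filtering, a complete-case / low-missingness split, and positional
standardisation scaling

    x_scaled = (x - med(x)) / (max(x) - min(x))

where med/max/min are computed on the complete-case subset only and stored,
so that any later data (low-missingness subjects, external cohorts) is scaled
with the *same* reference statistics.  Missing values are never imputed here;
they are carried through to the density classifier, which tolerates them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DOMAIN_TAGS = frozenset(
    {"antibody", "cytokine_protein", "cytokine_mrna", "infection",
     "demographic", "clinical"}
)

#: floors applied to non-positive stimulated-minus-control cytokine responses,
#: in the feature's native units (pg/ml for protein assays, expression units
#: for mRNA assays)
CYTOKINE_FLOORS = {"cytokine_protein": 0.01, "cytokine_mrna": 1e-6}


class PreprocessError(ValueError):
    """Raised when a preprocessing step produces an unusable table."""


@dataclass
class FeatureSpec:
    """Per-feature metadata driving preprocessing.

    Parameters
    ----------
    name : str
        Unique feature name.
    domain_tag : str
        One of ``antibody``, ``cytokine_protein``, ``cytokine_mrna``,
        ``infection``, ``demographic``, ``clinical``.
    timepoint : str
        Timepoint label (e.g. ``"6m"``, ``"2y"``); informational.
    log_transform : bool
        Whether the feature is log10-transformed before scaling.
    lod : float, optional
        Limit of detection in native units.  Only antibody-class features
        carry a LOD; below-LOD readings are replaced by ``lod / 2``.
    is_binary : bool
        Binary features pass through scaling by the same formula and become
        two-point features.
    is_outcome : bool
        Outcome variables (wheeze/asthma analogues) are excluded from the
        clustering roster and only used post hoc.
    is_derived : bool
        Derived variables (e.g. BMI) are excluded from the roster.
    """

    name: str
    domain_tag: str
    timepoint: str = ""
    log_transform: bool = False
    lod: Optional[float] = None
    is_binary: bool = False
    is_outcome: bool = False
    is_derived: bool = False

    def __post_init__(self) -> None:
        if self.domain_tag not in DOMAIN_TAGS:
            raise ValueError(f"unknown domain_tag {self.domain_tag!r}")
        if self.lod is not None:
            if self.domain_tag != "antibody":
                raise ValueError(
                    f"{self.name}: LOD given for non-antibody feature")
            if self.lod <= 0:
                raise ValueError(f"{self.name}: LOD must be positive")


@dataclass
class CohortTable:
    """Subjects x features matrix with per-feature metadata.

    ``data`` is a DataFrame indexed by unique subject id, one column per
    feature, ``NaN`` marking missing entries.  ``feature_meta`` maps feature
    name to :class:`FeatureSpec` and must cover every column.
    """

    data: pd.DataFrame
    feature_meta: dict[str, FeatureSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("subject ids must be unique")
        missing_meta = [c for c in self.data.columns if c not in self.feature_meta]
        if missing_meta:
            raise ValueError(f"features without metadata: {missing_meta[:5]}")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def subset(self, subjects=None, features=None) -> "CohortTable":
        df = self.data
        if subjects is not None:
            df = df.loc[subjects]
        if features is not None:
            df = df[list(features)]
        meta = {c: self.feature_meta[c] for c in df.columns}
        return CohortTable(df, meta)

    def clustering_roster(self) -> "CohortTable":
        """Drop outcome and derived features from the clustering roster."""
        keep = [c for c in self.data.columns
                if not (self.feature_meta[c].is_outcome
                        or self.feature_meta[c].is_derived)]
        return self.subset(features=keep)


@dataclass
class ReferenceStats:
    """Per-feature median / min / max from the complete-case subset."""

    median: pd.Series
    min: pd.Series
    max: pd.Series

    def __post_init__(self) -> None:
        if not ((self.min <= self.median).all() and (self.median <= self.max).all()):
            raise ValueError("require min <= median <= max per feature")
        if not (self.max > self.min).all():
            bad = self.max.index[~(self.max > self.min)].tolist()
            raise PreprocessError(f"zero-range features: {bad}")

    @property
    def features(self) -> list[str]:
        return list(self.median.index)

    def subset(self, features: Iterable[str]) -> "ReferenceStats":
        f = list(features)
        return ReferenceStats(self.median[f], self.min[f], self.max[f])

    def to_dict(self) -> dict:
        return {
            "median": self.median.to_dict(),
            "min": self.min.to_dict(),
            "max": self.max.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceStats":
        feats = list(d["median"])
        return cls(
            pd.Series(d["median"], index=feats, dtype=float),
            pd.Series(d["min"], index=feats, dtype=float),
            pd.Series(d["max"], index=feats, dtype=float),
        )


# ---------------------------------------------------------------------------
# filtering

def filter_features(table: CohortTable, max_missing_frac: float) -> CohortTable:
    """Drop features missing in strictly more than ``max_missing_frac`` of subjects.

    The threshold is strict: a feature missing in exactly the threshold
    fraction is retained.  Column order is preserved.
    """
    if not 0 < max_missing_frac < 1:
        raise ValueError("max_missing_frac must be in (0, 1)")
    frac = table.missing_mask.mean(axis=0)
    keep = frac.index[frac <= max_missing_frac]
    if len(keep) == 0:
        raise PreprocessError("all features exceed the missingness threshold")
    removed = table.n_features - len(keep)
    logger.info("filter_features: removed %d of %d features (>%.0f%% missing)",
                removed, table.n_features, 100 * max_missing_frac)
    return table.subset(features=keep)


def filter_subjects(table: CohortTable, max_missing_frac: float) -> CohortTable:
    """Drop subjects missing strictly more than ``max_missing_frac`` of features."""
    if not 0 < max_missing_frac < 1:
        raise ValueError("max_missing_frac must be in (0, 1)")
    frac = table.missing_mask.mean(axis=1)
    keep = frac.index[frac <= max_missing_frac]
    if len(keep) == 0:
        raise PreprocessError("all subjects exceed the missingness threshold")
    removed = table.n_subjects - len(keep)
    logger.info("filter_subjects: removed %d of %d subjects (>%.0f%% missing)",
                removed, table.n_subjects, 100 * max_missing_frac)
    return table.subset(subjects=keep)


def split_complete_low_missing(table: CohortTable) -> tuple[CohortTable, CohortTable]:
    """Partition subjects into complete-case and low-missingness subsets.

    The complete-case subset (no missing entries) trains the mixture model;
    the low-missingness complement is classified post hoc by the
    missingness-tolerant density classifier.
    """
    any_missing = table.missing_mask.any(axis=1)
    complete = table.subset(subjects=any_missing.index[~any_missing])
    low_miss = table.subset(subjects=any_missing.index[any_missing])
    if complete.n_subjects == 0:
        raise PreprocessError("empty complete-case subset: cannot fit a model")
    return complete, low_miss


# ---------------------------------------------------------------------------
# assay substitutions and transforms

def substitute_lod(values, lod: float):
    """Replace non-missing values strictly below the limit of detection by lod/2.

    Left-censored immunoassay readings (e.g. IgE < 0.03 kU/L) are set to half
    the LOD; values at or above the LOD, and missing values, are untouched.
    """
    if lod <= 0:
        raise ValueError("lod must be positive")
    v = np.asarray(values, dtype=float).copy()
    v[np.less(v, lod, where=~np.isnan(v), out=np.zeros(v.shape, bool))] = lod / 2
    return v


def substitute_nonpositive(values, floor_value: float):
    """Replace non-positive entries (stimulated <= control) by a small floor."""
    if floor_value <= 0:
        raise ValueError("floor_value must be positive")
    v = np.asarray(values, dtype=float).copy()
    v[np.less_equal(v, 0, where=~np.isnan(v), out=np.zeros(v.shape, bool))] = floor_value
    return v


def log10_transform(values, name: str = "feature"):
    """Elementwise log10; missing preserved; non-positive entries are an error."""
    v = np.asarray(values, dtype=float)
    obs = ~np.isnan(v)
    if np.any(v[obs] <= 0):
        raise PreprocessError(
            f"{name}: non-positive values reached log10 "
            "(LOD/floor substitution missing?)")
    out = np.full_like(v, np.nan)
    out[obs] = np.log10(v[obs])
    return out


def apply_assay_transforms(table: CohortTable) -> CohortTable:
    """Apply half-LOD, cytokine floor, and log10 steps per feature metadata."""
    df = table.data.copy()
    for name, spec in table.feature_meta.items():
        if name not in df.columns:
            continue
        col = df[name].to_numpy(dtype=float)
        if spec.lod is not None:
            col = substitute_lod(col, spec.lod)
        if spec.domain_tag in CYTOKINE_FLOORS:
            col = substitute_nonpositive(col, CYTOKINE_FLOORS[spec.domain_tag])
        if spec.log_transform:
            col = log10_transform(col, name)
        df[name] = col
    return CohortTable(df, dict(table.feature_meta))


# ---------------------------------------------------------------------------
# scaling

def compute_reference_stats(complete_case: pd.DataFrame) -> ReferenceStats:
    """Median/min/max per feature on a complete-case matrix.

    Even-N medians are midpoints of the two central order statistics.
    Constant (zero-range) features are rejected — they carry no information
    and would divide by zero in scaling.
    """
    if complete_case.isna().any().any():
        raise ValueError("reference stats require a complete-case matrix")
    return ReferenceStats(
        complete_case.median(axis=0),
        complete_case.min(axis=0),
        complete_case.max(axis=0),
    )


def scale(matrix: pd.DataFrame, stats: ReferenceStats) -> pd.DataFrame:
    """Positional standardisation: (x - median) / (max - min), per feature.

    Always uses the supplied (stored) statistics, never refits, so external
    data is mapped into the training model's coordinate system.  Values from
    outside the training range land outside [-1, 1]; the classifier's density
    clipping handles them.
    """
    if list(matrix.columns) != stats.features:
        raise ValueError("matrix columns do not match reference stats")
    return (matrix - stats.median) / (stats.max - stats.min)


def unscale(matrix: pd.DataFrame, stats: ReferenceStats) -> pd.DataFrame:
    """Inverse of :func:`scale`."""
    if list(matrix.columns) != stats.features:
        raise ValueError("matrix columns do not match reference stats")
    return matrix * (stats.max - stats.min) + stats.median


# ---------------------------------------------------------------------------
# I/O

def read_cohort_csv(data_path, meta_path) -> CohortTable:
    """Read a cohort CSV (first column subject id) and feature-metadata CSV."""
    df = pd.read_csv(data_path, index_col=0)
    meta_df = pd.read_csv(meta_path)
    meta = {}
    for _, row in meta_df.iterrows():
        lod = row.get("lod")
        meta[row["name"]] = FeatureSpec(
            name=row["name"],
            domain_tag=row["domain_tag"],
            timepoint=str(row.get("timepoint", "")),
            log_transform=bool(row.get("log_transform", False)),
            lod=None if pd.isna(lod) else float(lod),
            is_binary=bool(row.get("is_binary", False)),
            is_outcome=bool(row.get("is_outcome", False)),
            is_derived=bool(row.get("is_derived", False)),
        )
    return CohortTable(df, meta)


def write_cohort_csv(table: CohortTable, data_path, meta_path) -> None:
    table.data.to_csv(data_path)
    rows = [asdict(s) for s in table.feature_meta.values()]
    pd.DataFrame(rows).to_csv(meta_path, index=False)


def write_preprocess_sidecar(path, stats: ReferenceStats,
                             removed_features: list[str],
                             removed_subjects: list) -> None:
    with open(path, "w") as fh:
        json.dump({
            "reference_stats": stats.to_dict(),
            "removed_features": list(removed_features),
            "removed_subjects": [str(s) for s in removed_subjects],
        }, fh, indent=1)
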
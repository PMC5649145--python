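"""Feature-table data model for morphometric MRI measurements.

The pipeline consumes subject-by-feature tables of scalar brain measurements
(sulcal width / global sulcal index, regional cortical thickness, regional
gray-matter volume, subcortical volume, and regional white-matter-hyperintensity
volume) at one or two scan timepoints, with a diagnosis label per subject
(cognitively normal, amnestic MCI, or non-amnestic MCI).

The canonical cross-sectional layout has 178 features per timepoint, split into
five families: 12 sulcal, 68 thickness, 68 gray-matter volume, 14 subcortical,
and 16 WMH measurements. The longitudinal layout doubles this to 356 features
(the per-feature mean and change across the two timepoints).

Feature names are family-prefixed (``thickness__rh_frontalpole``) so that the
family layout is checkable from column names alone, without a side table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DIAGNOSES: tuple[str, ...] = ("CN", "aMCI", "naMCI")
TIMEPOINTS: tuple[str, ...] = ("baseline", "wave2", "longitudinal")

#: Canonical per-family feature counts of the cross-sectional layout (sums to 178).
FAMILY_COUNTS: dict[str, int] = {
    "sulcal": 12,
    "thickness": 68,
    "gm_volume": 68,
    "subcortical": 14,
    "wmh": 16,
}

FAMILY_SEP = "__"

N_CROSS_SECTIONAL = sum(FAMILY_COUNTS.values())  # 178
N_LONGITUDINAL = 2 * N_CROSS_SECTIONAL  # 356


class SchemaError(ValueError):
    """A feature table violates the expected family layout or naming scheme."""


class AlignmentError(ValueError):
    """Two timepoint tables cannot be aligned on subjects/features."""


class ParseError(ValueError):
    """A feature CSV file is malformed."""


@dataclass(frozen=True)
class FeatureFamily:
    """One named family of morphometric measurements and its expected width."""

    name: str
    expected_count: int


def default_families() -> tuple[FeatureFamily, ...]:
    """The five canonical families of the 178-feature layout."""
    return tuple(FeatureFamily(n, c) for n, c in FAMILY_COUNTS.items())


def feature_family(feature_name: str) -> str:
    """Extract the family prefix from a family-prefixed feature name.

    Raises
    ------
    SchemaError
        If the name carries no recognised ``family__`` prefix.
    """
    prefix, sep, _ = feature_name.partition(FAMILY_SEP)
    if not sep or prefix not in FAMILY_COUNTS:
        raise SchemaError(
            f"feature name {feature_name!r} has no recognised family prefix "
            f"(expected one of {sorted(FAMILY_COUNTS)} followed by {FAMILY_SEP!r})"
        )
    return prefix


@dataclass
class FeatureTable:
    """Subjects x features matrix with labels and a timepoint tag.

    Parameters
    ----------
    subject_ids : sequence of str
        Unique subject identifiers, one per row of ``values``.
    feature_names : sequence of str
        Unique feature names, one per column of ``values``.
    values : ndarray of shape (n_subjects, n_features)
        Real measurements; units vary by family (mm, mm^3, ratio). Missing
        values are not permitted.
    timepoint : {"baseline", "wave2", "longitudinal"}
    labels : sequence of str
        Per-subject diagnosis, each one of ``DIAGNOSES``.
    """

    subject_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray
    timepoint: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.subject_ids = tuple(str(s) for s in self.subject_ids)
        self.feature_names = tuple(str(f) for f in self.feature_names)
        self.labels = tuple(str(l) for l in self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.subject_ids) != n:
            raise ValueError(f"{len(self.subject_ids)} subject ids for {n} rows")
        if len(self.feature_names) != p:
            raise ValueError(f"{len(self.feature_names)} feature names for {p} columns")
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} subjects")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids")
        if len(set(self.feature_names)) != p:
            raise ValueError("duplicate feature names")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")
        bad = sorted(set(self.labels) - set(DIAGNOSES))
        if bad:
            raise ValueError(f"unknown diagnosis labels {bad}; admissible: {DIAGNOSES}")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain non-finite entries; missing data not permitted")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_subjects(self, index: Sequence[int] | np.ndarray) -> "FeatureTable":
        """Row subset (by positional index), preserving order of ``index``."""
        index = np.asarray(index)
        return FeatureTable(
            subject_ids=tuple(self.subject_ids[i] for i in index),
            feature_names=self.feature_names,
            values=self.values[index],
            timepoint=self.timepoint,
            labels=tuple(self.labels[i] for i in index),
        )

    def restrict_labels(self, keep: Iterable[str]) -> "FeatureTable":
        """Subset to subjects whose diagnosis is in ``keep`` (e.g. one binary task)."""
        keep = set(keep)
        idx = [i for i, l in enumerate(self.labels) if l in keep]
        return self.select_subjects(idx)

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame matching the CSV dialect."""
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "timepoint", self.timepoint)
        df.insert(0, "diagnosis", list(self.labels))
        df.insert(0, "subject_id", list(self.subject_ids))
        return df


@dataclass
class SchemaReport:
    """Outcome of validating a table against the family layout."""

    ok: bool
    family_counts: dict[str, int]
    expected_counts: dict[str, int]
    total: int
    expected_total: int
    messages: list[str] = field(default_factory=list)


def validate_schema(
    table: FeatureTable, families: Sequence[FeatureFamily] | None = None
) -> SchemaReport:
    """Check that a table's columns realise the expected family layout.

    The check is a pure function of the column names: each family must appear
    exactly ``expected_count`` times and the widths must sum to the expected
    total (178 for the canonical layout). Malformed names (no family prefix)
    and empty tables raise :class:`SchemaError`; a mere count mismatch is
    reported with ``ok=False``.
    """
    if families is None:
        families = default_families()
    if table.n_features == 0 or table.n_subjects == 0:
        raise SchemaError("empty feature table")
    observed: dict[str, int] = {f.name: 0 for f in families}
    for name in table.feature_names:
        fam = feature_family(name)  # raises SchemaError naming the column
        if fam not in observed:
            raise SchemaError(f"feature {name!r} belongs to unexpected family {fam!r}")
        observed[fam] += 1
    expected = {f.name: f.expected_count for f in families}
    messages = [
        f"family {fam!r}: observed {observed[fam]}, expected {expected[fam]}"
        for fam in expected
        if observed[fam] != expected[fam]
    ]
    return SchemaReport(
        ok=not messages,
        family_counts=observed,
        expected_counts=expected,
        total=table.n_features,
        expected_total=sum(expected.values()),
        messages=messages,
    )


def build_longitudinal(baseline: FeatureTable, wave2: FeatureTable) -> FeatureTable:
    """Combine two timepoints into the longitudinal feature set.

    For every input feature ``f`` the output contains ``mean_f`` — the
    arithmetic mean of the two timepoints — and ``change_f`` — follow-up minus
    baseline, so that atrophy yields negative volume/thickness changes. The
    output therefore has twice the input width (356 for the 178-feature
    layout). Labels are taken from the follow-up wave, which provides the
    diagnostic ground truth.

    Subjects must be present at both timepoints; ``wave2`` is re-ordered to the
    baseline subject order if needed.

    Raises
    ------
    AlignmentError
        If the two tables do not share identical subject and feature sets; the
        message lists the symmetric difference.
    """
    if set(baseline.feature_names) != set(wave2.feature_names):
        diff = sorted(set(baseline.feature_names) ^ set(wave2.feature_names))
        raise AlignmentError(f"feature sets differ; symmetric difference: {diff}")
    if set(baseline.subject_ids) != set(wave2.subject_ids):
        diff = sorted(set(baseline.subject_ids) ^ set(wave2.subject_ids))
        raise AlignmentError(f"subject sets differ; symmetric difference: {diff}")

    # Align wave2 rows/columns to the baseline ordering.
    srow = {s: i for i, s in enumerate(wave2.subject_ids)}
    scol = {f: j for j, f in enumerate(wave2.feature_names)}
    row_idx = [srow[s] for s in baseline.subject_ids]
    col_idx = [scol[f] for f in baseline.feature_names]
    w2 = wave2.values[np.ix_(row_idx, col_idx)]
    b = baseline.values

    names = [f"mean_{f}" for f in baseline.feature_names] + [
        f"change_{f}" for f in baseline.feature_names
    ]
    values = np.hstack([(b + w2) / 2.0, w2 - b])
    labels = tuple(wave2.labels[i] for i in row_idx)
    return FeatureTable(
        subject_ids=baseline.subject_ids,
        feature_names=tuple(names),
        values=values,
        timepoint="longitudinal",
        labels=labels,
    )


_REQUIRED_COLUMNS = ("subject_id", "diagnosis", "timepoint")


def read_feature_csv(path: str | Path) -> FeatureTable:
    """Read a feature table from the package's CSV dialect.

    Header: ``subject_id,diagnosis,timepoint`` followed by one column per
    feature. UTF-8, comma separated, no missing values.
    """
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    feature_cols = [c for c in df.columns if c not in _REQUIRED_COLUMNS]
    if not feature_cols:
        raise ParseError(f"{path}: no feature columns")
    bad = sorted(set(df["diagnosis"]) - set(DIAGNOSES))
    if bad:
        raise ParseError(
            f"{path}: unknown diagnosis value(s) {bad}; admissible: {DIAGNOSES}"
        )
    timepoints = df["timepoint"].unique()
    if len(timepoints) != 1:
        raise ParseError(f"{path}: mixed timepoint values {sorted(timepoints)}")
    for col in feature_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise ParseError(
                f"{path}: non-numeric or blank value in column {col!r}, "
                f"row {row} (subject {df['subject_id'].iloc[row]!r})"
            )
        df[col] = numeric
    return FeatureTable(
        subject_ids=tuple(df["subject_id"]),
        feature_names=tuple(feature_cols),
        values=df[feature_cols].to_numpy(dtype=float),
        timepoint=str(timepoints[0]),
        labels=tuple(df["diagnosis"]),
    )


def write_feature_csv(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table; ``read_feature_csv`` round-trips it losslessly."""
    table.to_frame().to_csv(path, index=False, float_format="%.17g")
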
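"""Reading, validation, alignment and preprocessing of profile tables.

The tabular currency of the package is the consensus morphological profile:
one row per perturbation (CRISPR guide × cell line, or compound), one column
per named numeric image feature.  Continuous cell-health readouts travel in a
parallel table aligned on the same row identifiers.

All tables are pandas DataFrames indexed by ``row_id``; the thin dataclass
wrappers below add the invariants the pipeline relies on (unique identifiers,
finite numeric values) and the preprocessing steps applied to compound
screens before any modelling: plate-wise control subtraction, dose-window
consensus aggregation, and column standardization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MorphProfileTable",
    "HealthReadoutTable",
    "PerturbationMeta",
    "DoseSeries",
    "TableFormatError",
    "TableValidationError",
    "load_table",
    "write_table",
    "load_metadata",
    "subtract_plate_control",
    "consensus_by_compound",
    "standardize_features",
    "intersect_features",
]

NanPolicy = Literal["error", "drop"]

META_COLUMNS = [
    "row_id",
    "perturbation_id",
    "cell_line",
    "group_label",
    "is_negative_control",
]


class TableFormatError(ValueError):
    """File-level problem: missing header, unreadable format."""


class TableValidationError(ValueError):
    """Content-level problem: duplicate identifiers, non-numeric cells."""


def _validate_numeric_frame(df: pd.DataFrame, nan_policy: NanPolicy) -> pd.DataFrame:
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate row_id values: {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate column names: {dupes}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise TableValidationError(f"non-numeric cell values: {exc}") from None
    bad = ~np.isfinite(values.to_numpy())
    if bad.any():
        if nan_policy == "drop":
            keep = ~bad.any(axis=1)
            values = values.loc[keep]
            if values.shape[0] == 0:
                raise TableValidationError("all rows dropped by NaN policy")
        else:
            n = int(bad.sum())
            raise TableValidationError(
                f"{n} non-finite cells found (nan_policy='error'); "
                "use nan_policy='drop' to discard affected rows"
            )
    if values.shape[0] < 1:
        raise TableValidationError("table must have at least one row")
    return values


@dataclass
class MorphProfileTable:
    """Profiles × named numeric morphological features.

    ``data`` is indexed by ``row_id`` (perturbation × cell line, or compound
    key); columns are feature names.  Values are unitless (standardized or
    control-subtracted) feature values and are finite after validation.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _validate_numeric_frame(self.data, "error")
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "row_id"

    @property
    def row_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def feature_names(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset(self, features: Sequence[str]) -> "MorphProfileTable":
        missing = [f for f in features if f not in self.data.columns]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return MorphProfileTable(self.data.loc[:, list(features)].copy())


@dataclass
class HealthReadoutTable:
    """Profiles × continuous cell-health readouts (level-3 phenotypes)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _validate_numeric_frame(self.data, "error")
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "row_id"
        if self.data.shape[1] < 1:
            raise TableValidationError("readout table needs >= 1 readout column")

    @property
    def row_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def readout_names(self) -> list[str]:
        return self.data.columns.tolist()

    def align_to(self, profiles: MorphProfileTable) -> "HealthReadoutTable":
        """Reindex to the profile table's rows; every row must be present."""
        missing = set(profiles.row_ids) - set(self.data.index)
        if missing:
            raise TableValidationError(
                f"readout table missing rows: {sorted(missing)[:5]}..."
            )
        return HealthReadoutTable(self.data.loc[profiles.row_ids].copy())


@dataclass
class PerturbationMeta:
    """Per-row perturbation annotations.

    One record per profile row: the perturbation identifier, cell line, the
    affected-cell-process group label (level-4 annotation, e.g. "Chromatin
    Modifiers") and whether the row is a negative control (inert-locus guides
    such as LacZ / Luc / Chr2 in the CRISPR panel).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns and c != "row_id"]
        if self.data.index.name != "row_id":
            if "row_id" in self.data.columns:
                self.data = self.data.set_index("row_id")
            else:
                raise TableValidationError("metadata needs a row_id column")
        if missing:
            raise TableValidationError(f"metadata missing columns: {missing}")
        if self.data.index.has_duplicates:
            raise TableValidationError("duplicate row_id in metadata")
        self.data.index = self.data.index.astype(str)
        self.data["is_negative_control"] = self.data["is_negative_control"].astype(bool)

    @property
    def row_ids(self) -> list[str]:
        return self.data.index.tolist()

    def control_mask(self, row_ids: Sequence[str]) -> np.ndarray:
        return self.data.loc[list(row_ids), "is_negative_control"].to_numpy()

    def group_labels(self, row_ids: Sequence[str]) -> pd.Series:
        return self.data.loc[list(row_ids), "group_label"]

    def validate_for_terms(self, profiles: MorphProfileTable) -> None:
        missing = set(profiles.row_ids) - set(self.row_ids)
        if missing:
            raise TableValidationError(
                f"metadata missing rows: {sorted(missing)[:5]}"
            )
        mask = self.control_mask(profiles.row_ids)
        if not mask.any():
            raise TableValidationError("no negative-control rows present")
        if mask.all():
            raise TableValidationError("no non-control group rows present")


@dataclass
class DoseSeries:
    """All wells of one compound across doses (possibly replicated)."""

    compound_id: str
    doses: np.ndarray
    values: np.ndarray  # wells × features
    feature_names: list[str]
    plate_ids: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.doses.size == 0:
            raise TableValidationError(f"empty dose series for {self.compound_id}")
        if (self.doses <= 0).any():
            raise TableValidationError(f"non-positive dose in {self.compound_id}")
        if self.values.shape[0] != self.doses.size:
            raise TableValidationError(
                f"{self.compound_id}: {self.values.shape[0]} well rows for "
                f"{self.doses.size} doses"
            )
        if self.values.shape[1] != len(self.feature_names):
            raise TableValidationError(f"{self.compound_id}: feature count mismatch")


# ---------------------------------------------------------------------------
# loading / writing


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in {".parquet", ".pq"}:
        return pd.read_parquet(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise TableFormatError(str(exc)) from None
    return df


def load_table(
    path: str | Path,
    schema: Literal["profiles", "readouts"] = "profiles",
    nan_policy: NanPolicy = "error",
) -> MorphProfileTable | HealthReadoutTable:
    """Load a profile or readout table from CSV/parquet.

    The first column must be ``row_id``.  Non-numeric cells are rejected; the
    NaN policy decides between erroring (default) and dropping affected rows.
    """
    df = _read_frame(path)
    if df.columns.size == 0 or df.columns[0] != "row_id":
        raise TableFormatError(
            f"{path}: first column must be 'row_id' (got {list(df.columns[:1])})"
        )
    df = df.set_index("row_id")
    df = _validate_numeric_frame(df, nan_policy)
    if schema == "profiles":
        return MorphProfileTable(df)
    if schema == "readouts":
        return HealthReadoutTable(df)
    raise ValueError(f"unknown schema {schema!r}")


def write_table(
    table: MorphProfileTable | HealthReadoutTable, path: str | Path
) -> None:
    """Write a table as CSV or parquet (chosen by extension)."""
    path = Path(path)
    df = table.data.reset_index()
    if path.suffix in {".parquet", ".pq"}:
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def load_metadata(path: str | Path) -> PerturbationMeta:
    df = _read_frame(path)
    return PerturbationMeta(df)


def write_metadata(meta: PerturbationMeta, path: str | Path) -> None:
    meta.data.reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preprocessing


def subtract_plate_control(
    profiles: MorphProfileTable,
    plate_ids: Sequence[str],
    control_mask: Sequence[bool],
) -> MorphProfileTable:
    """Subtract the plate-wise neutral-control (DMSO) mean from every row.

    Per plate, the mean feature vector over that plate's control wells is
    subtracted from every row on the plate; control rows therefore become
    their deviation from the control mean.  A plate without any control well
    is an error (there is nothing to anchor the plate to).
    """
    plate_ids = np.asarray(plate_ids, dtype=object)
    control_mask = np.asarray(control_mask, dtype=bool)
    n = profiles.data.shape[0]
    if plate_ids.shape[0] != n or control_mask.shape[0] != n:
        raise ValueError("plate_ids / control_mask length must match row count")
    out = profiles.data.copy()
    for plate in pd.unique(plate_ids):
        on_plate = plate_ids == plate
        ctrl = on_plate & control_mask
        if not ctrl.any():
            raise ValueError(f"plate {plate!r} has no control wells")
        center = profiles.data.loc[ctrl].mean(axis=0)
        out.loc[on_plate] = profiles.data.loc[on_plate] - center
    return MorphProfileTable(out)


def consensus_by_compound(series_list: Iterable[DoseSeries]) -> MorphProfileTable:
    """Collapse replicated dose series to one consensus profile per compound.

    For each compound the dose values define a retention window: wells whose
    dose lies within one standard deviation (sample convention) of the mean
    dose are kept, and the consensus profile is the per-feature median over
    the kept wells.  A single well is always kept (its SD is zero), and with
    two wells both always fall inside the window.
    """
    series_list = list(series_list)
    if not series_list:
        raise ValueError("no dose series given")
    feature_names = series_list[0].feature_names
    rows = {}
    for s in series_list:
        if s.feature_names != feature_names:
            raise TableValidationError(
                f"{s.compound_id}: feature names differ from first series"
            )
        if s.compound_id in rows:
            raise TableValidationError(f"duplicate compound {s.compound_id}")
        mean = s.doses.mean()
        sd = s.doses.std(ddof=1) if s.doses.size > 1 else 0.0
        keep = np.abs(s.doses - mean) <= sd if s.doses.size > 1 else np.ones(1, bool)
        rows[s.compound_id] = np.median(s.values[keep], axis=0)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=feature_names)
    df.index.name = "row_id"
    return MorphProfileTable(df)


def standardize_features(
    table: MorphProfileTable,
    reference: MorphProfileTable | tuple[pd.Series, pd.Series] | None = None,
) -> MorphProfileTable:
    """Center each feature column and scale it to unit variance.

    Uses the population convention (divisor n).  When ``reference`` is given
    (a table, or precomputed ``(mean, std)`` Series) its statistics are used
    instead of the table's own, so screens can be scaled against a stated
    reference population.  Zero-variance columns map to all-zeros with a
    warning — they carry no signal but keep the column grid stable.
    """
    if table.data.shape[0] < 2 and reference is None:
        raise ValueError("standardization needs >= 2 rows (or a reference)")
    if reference is None:
        mean = table.data.mean(axis=0)
        std = table.data.std(axis=0, ddof=0)
    elif isinstance(reference, MorphProfileTable):
        mean = reference.data.mean(axis=0).reindex(table.feature_names)
        std = reference.data.std(axis=0, ddof=0).reindex(table.feature_names)
        if mean.isna().any():
            missing = mean.index[mean.isna()].tolist()
            raise KeyError(f"reference lacks features: {missing}")
    else:
        mean, std = reference
        mean = mean.reindex(table.feature_names)
        std = std.reindex(table.feature_names)
        if mean.isna().any() or std.isna().any():
            raise KeyError("reference statistics missing for some features")
    degenerate = std == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance feature(s) set to 0",
            UserWarning,
            stacklevel=2,
        )
    safe_std = std.replace(0, 1.0)
    z = (table.data - mean) / safe_std
    z.loc[:, degenerate[degenerate].index] = 0.0
    return MorphProfileTable(z)


def intersect_features(
    a: MorphProfileTable | Sequence[str], b: MorphProfileTable | Sequence[str]
) -> list[str]:
    """Sorted intersection of two feature universes; empty is an error."""
    names_a = a.feature_names if isinstance(a, MorphProfileTable) else list(a)
    names_b = b.feature_names if isinstance(b, MorphProfileTable) else list(b)
    common = sorted(set(names_a) & set(names_b))
    if not common:
        raise ValueError("feature universes are disjoint: nothing to map")
    return common
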
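"""Mixed-type tabular datasets: data model, CSV/sidecar I/O, encoding, entropy.

A :class:`TabularDataset` is a rectangular table of continuous and
categorical columns with exactly one designated categorical outcome.  It is
the unit that every utility metric, synthesizer and workload evaluation
consumes.  All metric computations share a single numeric representation
(:class:`EncodedMatrix`): continuous columns standardized by the *real*
dataset's mean/SD and categorical columns one-hot expanded over their
declared levels, so that a real dataset and any synthetic imitation of it
live in the same feature space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ColumnMeta",
    "TabularDataset",
    "Standardization",
    "EncodedMatrix",
    "DatasetValidationError",
    "MissingOutcomeError",
    "LevelViolationError",
    "NonNumericValueError",
    "EncodingLevelError",
    "read_dataset",
    "write_dataset",
    "encode",
    "average_entropy",
]


class DatasetValidationError(ValueError):
    """A dataset or its metadata violates the schema contract."""


class MissingOutcomeError(DatasetValidationError):
    """No column (or more than one) is designated as the outcome."""


class LevelViolationError(DatasetValidationError):
    """A categorical cell holds a value outside its declared levels."""


class NonNumericValueError(DatasetValidationError):
    """A continuous column holds a non-numeric or non-finite value."""


class EncodingLevelError(DatasetValidationError):
    """Data contain a categorical level absent from the reference encoding."""


@dataclass(frozen=True)
class ColumnMeta:
    """Schema for one column.

    Parameters
    ----------
    name : str
        Column identifier, must match the CSV header.
    kind : {"continuous", "categorical"}
    levels : tuple of str, optional
        Ordered category labels (categorical columns only).  The order is
        authoritative: it fixes the one-hot layout and the ordinal codes
        used by copula fits.
    is_outcome : bool
        Exactly one column per dataset carries this flag; it must be
        categorical with at least two levels.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    is_outcome: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise DatasetValidationError(f"unknown column kind {self.kind!r}")
        if self.kind == "categorical" and self.levels is not None:
            if len(set(self.levels)) != len(self.levels):
                raise DatasetValidationError(
                    f"column {self.name!r}: duplicate levels {self.levels}"
                )
        if self.kind == "continuous" and self.levels is not None:
            raise DatasetValidationError(
                f"continuous column {self.name!r} must not declare levels"
            )
        if self.is_outcome and self.kind != "categorical":
            raise MissingOutcomeError(
                f"outcome column {self.name!r} must be categorical"
            )


@dataclass
class TabularDataset:
    """A validated mixed-type table with column metadata.

    ``values`` is a :class:`pandas.DataFrame` whose columns follow
    ``columns`` order; categorical cells are strings, continuous cells are
    finite floats.
    """

    columns: list[ColumnMeta]
    values: pd.DataFrame
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.validate()

    # -- schema helpers -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.values)

    @property
    def outcome(self) -> ColumnMeta:
        out = [c for c in self.columns if c.is_outcome]
        if len(out) != 1:
            raise MissingOutcomeError(
                f"dataset {self.name!r} designates {len(out)} outcome columns"
            )
        return out[0]

    @property
    def predictors(self) -> list[ColumnMeta]:
        return [c for c in self.columns if not c.is_outcome]

    def meta(self, name: str) -> ColumnMeta:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def validate(self) -> None:
        if not self.columns:
            raise DatasetValidationError("dataset has no columns")
        if list(self.values.columns) != [c.name for c in self.columns]:
            raise DatasetValidationError(
                "CSV header does not match metadata column names"
            )
        if len(self.values) < 1:
            raise DatasetValidationError("dataset must have at least one row")
        out = self.outcome
        if out.levels is None or len(out.levels) < 2:
            raise MissingOutcomeError(
                f"outcome {out.name!r} needs >= 2 declared levels"
            )
        for c in self.columns:
            col = self.values[c.name]
            if c.kind == "continuous":
                if col.isna().any():
                    raise NonNumericValueError(
                        f"missing value in continuous column {c.name!r}"
                    )
                arr = pd.to_numeric(col, errors="coerce")
                if arr.isna().any() or not np.isfinite(arr.to_numpy()).all():
                    raise NonNumericValueError(
                        f"non-numeric or non-finite value in column {c.name!r}"
                    )
            else:
                if c.levels is None:
                    raise DatasetValidationError(
                        f"categorical column {c.name!r} has no levels"
                    )
                if col.isna().any():
                    raise LevelViolationError(
                        f"missing value in categorical column {c.name!r}"
                    )
                bad = set(col.astype(str)) - set(c.levels)
                if bad:
                    raise LevelViolationError(
                        f"column {c.name!r}: values {sorted(bad)} outside "
                        f"declared levels {list(c.levels)}"
                    )

    def copy(self) -> "TabularDataset":
        return TabularDataset(list(self.columns), self.values.copy(), self.name)

    def same_schema(self, other: "TabularDataset") -> bool:
        return self.columns == other.columns


# ----------------------------------------------------------------------
# I/O: CSV + YAML/JSON sidecar
# ----------------------------------------------------------------------

def _meta_from_sidecar(doc: list[dict], df: pd.DataFrame) -> list[ColumnMeta]:
    metas = []
    for entry in doc:
        name = entry["name"]
        kind = entry["kind"]
        levels = entry.get("levels")
        if kind == "categorical" and levels is None:
            # infer from data, sorted lexicographically for determinism
            levels = sorted(df[name].astype(str).unique())
        metas.append(
            ColumnMeta(
                name=name,
                kind=kind,
                levels=tuple(str(v) for v in levels) if levels is not None else None,
                is_outcome=bool(entry.get("is_outcome", False)),
            )
        )
    return metas


def read_dataset(csv_path, meta_path, name: str | None = None) -> TabularDataset:
    """Read a dataset from a CSV file and its column-metadata sidecar.

    The sidecar is YAML (JSON is a YAML subset and also accepted): a list of
    mappings with keys ``name``, ``kind``, optional ``levels`` and
    ``is_outcome``.  Categorical levels omitted from the sidecar are
    inferred from the data and sorted lexicographically.
    """
    with open(meta_path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, dict) and "columns" in doc:
        doc = doc["columns"]
    df = pd.read_csv(csv_path, dtype=str, keep_default_na=False, na_values=[""])
    metas = _meta_from_sidecar(doc, df)
    if list(df.columns) != [m.name for m in metas]:
        raise DatasetValidationError("CSV header does not match metadata column names")
    def _parse_float(v):
        # Python's float() is correctly rounded; pandas' fast parser is not
        if isinstance(v, float):
            return v
        try:
            return float(v)
        except (TypeError, ValueError):
            return float("nan")

    for m in metas:
        if m.kind == "continuous":
            df[m.name] = df[m.name].map(_parse_float).astype(float)
        else:
            df[m.name] = df[m.name].astype(str)
    return TabularDataset(metas, df, name or str(csv_path))


def write_dataset(ds: TabularDataset, csv_path, meta_path) -> None:
    """Write ``ds`` so that :func:`read_dataset` reproduces it exactly.

    The sidecar keeps the declared levels verbatim — metadata, not data, is
    authoritative, so a level never observed in the data survives a
    round-trip.
    """
    ds.validate()
    # %.17g round-trips any float64 exactly
    ds.values.to_csv(csv_path, index=False, float_format="%.17g")
    doc = []
    for c in ds.columns:
        entry: dict = {"name": c.name, "kind": c.kind}
        if c.levels is not None:
            entry["levels"] = list(c.levels)
        if c.is_outcome:
            entry["is_outcome"] = True
        doc.append(entry)
    with open(meta_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ----------------------------------------------------------------------
# Encoding
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Standardization:
    """Frozen encoding space: feature layout plus center/scale per feature.

    ``feature_map`` maps encoded column index -> (source column name, level)
    where level is ``None`` for continuous features.  ``center``/``scale``
    are applied as ``(x - center) / scale``; one-hot features have center 0
    and scale 1, zero-variance continuous features have scale 1.
    """

    columns: tuple[ColumnMeta, ...]
    feature_map: tuple[tuple[str, str | None], ...]
    center: tuple[float, ...]
    scale: tuple[float, ...]
    include_outcome: bool = True

    @property
    def d(self) -> int:
        return len(self.feature_map)


@dataclass
class EncodedMatrix:
    """A dataset realized in a shared standardized numeric space."""

    matrix: np.ndarray
    feature_map: tuple[tuple[str, str | None], ...]
    standardization: Standardization

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]


def fit_standardization(ds: TabularDataset, include_outcome: bool = True) -> Standardization:
    """Derive the encoding space (layout + center/scale) from ``ds``."""
    cols = ds.columns if include_outcome else ds.predictors
    fmap: list[tuple[str, str | None]] = []
    center: list[float] = []
    scale: list[float] = []
    for c in cols:
        if c.kind == "continuous":
            x = ds.values[c.name].to_numpy(dtype=float)
            mu = float(np.mean(x))
            sd = float(np.std(x, ddof=0))
            fmap.append((c.name, None))
            center.append(mu)
            scale.append(sd if sd > 0 else 1.0)  # zero-variance guard
        else:
            for lev in c.levels:
                fmap.append((c.name, lev))
                center.append(0.0)
                scale.append(1.0)
    return Standardization(
        columns=tuple(cols),
        feature_map=tuple(fmap),
        center=tuple(center),
        scale=tuple(scale),
        include_outcome=include_outcome,
    )


def encode(
    ds: TabularDataset,
    reference: Standardization | None = None,
    include_outcome: bool = True,
) -> EncodedMatrix:
    """Encode ``ds`` into the reference's standardized one-hot space.

    When ``reference`` is None the dataset defines its own space (the real
    dataset always plays this role; synthetic datasets are encoded against
    it).  A categorical value outside the reference's declared levels raises
    :class:`EncodingLevelError` — all metrics compare against the real
    distribution, so an unseen level is an error, not a new feature.
    """
    std = reference if reference is not None else fit_standardization(ds, include_outcome)
    n = ds.n_rows
    out = np.zeros((n, std.d), dtype=float)
    ds_cols = {c.name: c for c in ds.columns}
    j = 0
    while j < std.d:
        col_name, lev = std.feature_map[j]
        if col_name not in ds_cols:
            raise EncodingLevelError(
                f"reference feature column {col_name!r} missing from dataset"
            )
        meta = ds_cols[col_name]
        if lev is None:
            x = ds.values[col_name].to_numpy(dtype=float)
            out[:, j] = (x - std.center[j]) / std.scale[j]
            j += 1
        else:
            # consume the contiguous one-hot block of this column
            block = []
            while j < std.d and std.feature_map[j][0] == col_name:
                block.append((j, std.feature_map[j][1]))
                j += 1
            declared = {lv for _, lv in block}
            vals = ds.values[col_name].astype(str)
            extra = set(vals) - declared
            if extra:
                raise EncodingLevelError(
                    f"column {col_name!r}: levels {sorted(extra)} absent from "
                    "reference encoding"
                )
            for jj, lv in block:
                out[:, jj] = (vals == lv).to_numpy(dtype=float)
    return EncodedMatrix(matrix=out, feature_map=std.feature_map, standardization=std)


# ----------------------------------------------------------------------
# Descriptive statistics
# ----------------------------------------------------------------------

def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log2(p)).sum())


def average_entropy(ds: TabularDataset) -> float:
    """Mean Shannon entropy (bits) over columns — a complexity descriptor.

    Categorical columns use empirical level frequencies.  Continuous
    columns are discretized by equal-width binning into ``ceil(sqrt(n))``
    bins over the observed range; a constant column contributes 0 bits.
    """
    ents = []
    n = ds.n_rows
    for c in ds.columns:
        if c.kind == "categorical":
            counts = ds.values[c.name].value_counts().to_numpy()
            ents.append(_entropy_bits(counts))
        else:
            x = ds.values[c.name].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                ents.append(0.0)
            else:
                nbins = math.ceil(math.sqrt(n))
                counts, _ = np.histogram(x, bins=nbins)
                ents.append(_entropy_bits(counts))
    return float(np.mean(ents))
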
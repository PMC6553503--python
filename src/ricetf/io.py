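"""Expression-table I/O and shaping.

Meta-expression analysis works on gene-by-sample matrices assembled from many
microarray or RNA-Seq experiments of one platform.  This module reads and
validates those tables (TSV), collapses probe-level rows to locus-level rows,
log2-transforms intensities, and averages replicate columns into per-group
profiles.  Normalization of raw data (MAS5, DESeq2, ...) happens upstream; the
pipeline accepts normalized matrices only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "ValidationError",
    "read_expression_table",
    "write_expression_table",
    "read_probe_map",
    "collapse_probes",
    "log2_transform",
    "aggregate_by_group",
]

PLATFORMS = frozenset({"affymetrix", "agilent", "rnaseq"})
CATEGORIES = frozenset({"anatomy", "abiotic", "biotic", "hormone"})

#: required columns of a sample-metadata table
META_COLUMNS = ("sample_id", "platform", "category", "group", "replicate_index")


class ValidationError(ValueError):
    """A table violated the expression-matrix contract."""


class Scale(str, enum.Enum):
    """What the numbers in an expression matrix mean."""

    LINEAR_INTENSITY = "linear_intensity"
    LOG2_INTENSITY = "log2_intensity"
    LOG2_FOLD_CHANGE = "log2_fold_change"


@dataclass
class ExpressionMatrix:
    """A genes-(or probes-)by-samples matrix plus sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene/probe identifiers, columns by sample IDs.
    meta : pandas.DataFrame
        One row per sample, indexed by ``sample_id``, with columns
        ``platform``, ``category``, ``group`` and ``replicate_index``.
        Column order of ``values`` must match the metadata row order.
    scale : Scale
        ``linear_intensity`` (non-negative), ``log2_intensity`` or
        ``log2_fold_change`` (signed).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    scale: Scale = Scale.LOG2_INTENSITY

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        validate_meta(self.meta)
        idx = self.values.index
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise ValidationError(f"duplicate row identifiers: {dupes}")
        if list(self.values.columns) != list(self.meta.index):
            missing = [c for c in self.values.columns if c not in self.meta.index]
            if missing:
                raise ValidationError(
                    f"samples absent from metadata: {missing}"
                )
            # same membership, different order: reorder to metadata order
            self.values = self.values.loc[:, list(self.meta.index)]
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                "missing value at row "
                f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )
        if self.scale is Scale.LINEAR_INTENSITY and (arr < 0).any():
            raise ValidationError("linear intensities must be non-negative")

    # -- convenience accessors -------------------------------------------
    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance in the metadata."""
        return list(dict.fromkeys(self.meta["group"]))

    def shape(self) -> tuple[int, int]:
        return self.values.shape


def validate_meta(meta: pd.DataFrame) -> None:
    for col in META_COLUMNS[1:]:
        if col not in meta.columns:
            raise ValidationError(f"metadata lacks required column {col!r}")
    if meta.index.duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    bad_platform = set(meta["platform"]) - PLATFORMS
    if bad_platform:
        raise ValidationError(f"unknown platform(s): {sorted(bad_platform)}")
    bad_cat = set(meta["category"]) - CATEGORIES
    if bad_cat:
        raise ValidationError(f"unknown category(s): {sorted(bad_cat)}")
    if (meta["replicate_index"].astype(int) < 1).any():
        raise ValidationError("replicate_index must be >= 1")


def read_expression_table(
    path: str | Path,
    meta_path: str | Path,
    scale: Scale | str | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression table together with its sample metadata.

    The table has a header row of sample IDs and row identifiers in the first
    column.  Every sample column must appear in the metadata; columns are
    returned in metadata order.  ``scale`` may be given explicitly or as a
    uniform ``scale`` column in the metadata.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str}).set_index(
        "sample_id"
    )
    if scale is None:
        if "scale" in meta.columns:
            uniq = set(meta["scale"])
            if len(uniq) != 1:
                raise ValidationError(f"metadata declares mixed scales: {sorted(uniq)}")
            scale = Scale(uniq.pop())
        else:
            raise ValidationError(
                "scale not given and metadata has no 'scale' column"
            )
    missing = [c for c in raw.columns if c not in meta.index]
    if missing:
        raise ValidationError(f"samples absent from metadata: {missing}")
    if raw.index.duplicated().any():
        dupes = sorted(set(raw.index[raw.index.duplicated()]))
        raise ValidationError(f"duplicate row identifiers: {dupes}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy() & raw.notna().to_numpy())
    if len(bad):
        r, c = bad[0]
        raise ValidationError(
            f"non-numeric value {raw.iat[r, c]!r} at row {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}"
        )
    present = [s for s in meta.index if s in numeric.columns]
    return ExpressionMatrix(numeric.loc[:, present], meta.loc[present], Scale(scale))


def write_expression_table(
    matrix: ExpressionMatrix,
    path: str | Path,
    meta_path: str | Path | None = None,
) -> None:
    """Write the canonical TSV dialect: UTF-8, '.' decimal, rows sorted by id."""
    out = matrix.values.sort_index()
    out.index.name = out.index.name or "row_id"
    out.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")
    if meta_path is not None:
        meta = matrix.meta.copy()
        meta.insert(0, "sample_id", meta.index)
        meta.to_csv(meta_path, sep="\t", index=False, lineterminator="\n")


def read_probe_map(path: str | Path) -> dict[str, tuple[str, bool]]:
    """Read a probe-to-locus TSV with columns probe_id, locus_id, is_unique."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df["probe_id"].duplicated().any():
        raise ValidationError("duplicate probe_id in probe map")
    truthy = {"1", "true", "True", "TRUE", "yes"}
    return {
        r.probe_id: (r.locus_id, str(r.is_unique) in truthy)
        for r in df.itertuples(index=False)
    }


def collapse_probes(
    matrix: ExpressionMatrix,
    probe_map: Mapping[str, tuple[str, bool]],
) -> tuple[ExpressionMatrix, list[str]]:
    """Collapse probe-level rows to one row per locus.

    Among a locus's probes flagged as unique, the probe with the highest mean
    expression across all samples is kept (ties broken by the
    lexicographically smaller probe id).  Loci represented only by non-unique
    probes cannot be measured unambiguously and are dropped; their ids are
    returned in ``excluded``.
    """
    unmapped = [p for p in matrix.row_ids if p not in probe_map]
    if unmapped:
        raise ValidationError(f"probes absent from probe map: {sorted(unmapped)}")

    by_locus: dict[str, list[str]] = {}
    unique_by_locus: dict[str, list[str]] = {}
    for probe in matrix.row_ids:
        locus, is_unique = probe_map[probe]
        by_locus.setdefault(locus, []).append(probe)
        if is_unique:
            unique_by_locus.setdefault(locus, []).append(probe)

    means = matrix.values.mean(axis=1)
    chosen: dict[str, str] = {}
    excluded: list[str] = []
    for locus in sorted(by_locus):
        candidates = unique_by_locus.get(locus)
        if not candidates:
            excluded.append(locus)
            continue
        # highest mean wins; lexicographically smaller probe id breaks ties
        chosen[locus] = min(candidates, key=lambda p: (-means[p], p))

    values = matrix.values.loc[[chosen[l] for l in sorted(chosen)]].copy()
    values.index = pd.Index(sorted(chosen), name=matrix.values.index.name)
    return ExpressionMatrix(values, matrix.meta, matrix.scale), excluded


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Map every intensity v to log2(v + offset).

    The default offset of 1 guards zero intensities and leaves large values
    essentially unchanged.
    """
    if matrix.scale is not Scale.LINEAR_INTENSITY:
        raise ValidationError(
            f"log2_transform expects linear intensities, got {matrix.scale.value}"
        )
    if offset < 0:
        raise ValidationError("offset must be >= 0")
    shifted = matrix.values.to_numpy() + offset
    if (shifted <= 0).any():
        raise ValidationError("v + offset <= 0: cannot take log2")
    values = pd.DataFrame(
        np.log2(shifted), index=matrix.values.index, columns=matrix.values.columns
    )
    return ExpressionMatrix(values, matrix.meta, Scale.LOG2_INTENSITY)


def aggregate_by_group(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average replicate columns into one column per group.

    Returns a matrix with one column per group (order of first appearance in
    the metadata), on the input's scale.  The derived metadata keeps each
    group's platform and category and sets replicate_index to 1.
    """
    groups = matrix.groups
    cols = {}
    meta_rows = []
    for g in groups:
        samples = matrix.meta.index[matrix.meta["group"] == g]
        if len(samples) == 0:
            raise ValidationError(f"group {g!r} has no samples")
        cols[g] = matrix.values[samples].mean(axis=1)
        first = matrix.meta.loc[samples[0]]
        meta_rows.append(
            {
                "sample_id": g,
                "platform": first["platform"],
                "category": first["category"],
                "group": g,
                "replicate_index": 1,
            }
        )
    values = pd.DataFrame(cols, index=matrix.values.index)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return ExpressionMatrix(values, meta, matrix.scale)
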
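"""Labeled binary incidence matrices for bipartite association networks.

The central container is :class:`BipartiteIncidence`: a labeled 0/1 matrix
whose rows are plant-layer nodes (species, populations, individual samples)
and whose columns are fungal-layer nodes (species, OTUs or virtual taxa).
Alongside it live the standard data-wrangling steps applied to published
plant-fungus association tables before any modelling: binarization of read
counts, conversion of long-format occurrence records, aggregation of the
plant layer to coarser biological units, dataset-inclusion filtering and
removal of empty nodes.

File dialect: comma-separated UTF-8 text; the first column holds row
labels and the header row holds column labels.  Occurrence tables are CSV
with columns ``sample_id, plant_node, amf_node, count``; aggregation maps
are two-column CSV ``fine_node, aggregated_node``.
"""

from __future__ import annotations

import csv
import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BipartiteIncidence",
    "AggregationMap",
    "FilterDecision",
    "IncidenceError",
    "LabelingError",
    "FormatError",
    "BinaryDomainError",
    "CoverageError",
    "DegenerateNetworkError",
    "read_incidence",
    "write_incidence",
    "read_occurrences",
    "occurrence_to_incidence",
    "read_aggregation_map",
    "write_aggregation_map",
    "aggregate_plants",
    "filter_dataset",
    "drop_empty_nodes",
]

OCCURRENCE_COLUMNS = ("sample_id", "plant_node", "amf_node", "count")


class IncidenceError(ValueError):
    """Base class for incidence-matrix input errors."""


class LabelingError(IncidenceError):
    """Duplicate or otherwise invalid node labels."""


class FormatError(IncidenceError):
    """Non-numeric, negative or missing cells in an input file."""


class BinaryDomainError(IncidenceError):
    """A cell outside {0, 1} encountered with binarization disabled."""


class CoverageError(IncidenceError):
    """A mapping or partition fails to cover every node."""


class DegenerateNetworkError(IncidenceError):
    """The matrix contains no links at all."""


@dataclasses.dataclass(frozen=True)
class BipartiteIncidence:
    """A labeled binary plant-by-fungus association matrix.

    Parameters
    ----------
    row_labels : tuple of str
        Unique identifiers of the plant-layer nodes, in matrix order.
    col_labels : tuple of str
        Unique identifiers of the fungal-layer nodes, in matrix order.
    entries : numpy.ndarray
        2-D array of 0/1 association indicators, shape
        ``(len(row_labels), len(col_labels))``.

    Notes
    -----
    Row degrees (links per plant node), column degrees (links per fungal
    node) and the total link count are derived properties, guaranteed
    consistent with ``entries`` by construction.  Orientation — rows =
    plants, columns = fungi — is a labeling convention only; every metric
    downstream is symmetric under transposition.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    entries: np.ndarray

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries)
        if entries.ndim != 2:
            raise FormatError(f"entries must be 2-D, got ndim={entries.ndim}")
        if np.isnan(entries.astype(float)).any():
            raise FormatError("entries contain missing values")
        if not np.isin(entries, (0, 1)).all():
            raise BinaryDomainError("entries must be exactly 0 or 1")
        entries = entries.astype(np.int8)
        entries.setflags(write=False)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "row_labels", tuple(str(r) for r in self.row_labels))
        object.__setattr__(self, "col_labels", tuple(str(c) for c in self.col_labels))
        if entries.shape != (len(self.row_labels), len(self.col_labels)):
            raise FormatError(
                f"label/shape mismatch: {entries.shape} vs "
                f"({len(self.row_labels)}, {len(self.col_labels)})"
            )
        for layer, labels in (("row", self.row_labels), ("column", self.col_labels)):
            if len(set(labels)) != len(labels):
                seen: set[str] = set()
                dup = next(l for l in labels if l in seen or seen.add(l))
                raise LabelingError(f"duplicate {layer} label: {dup!r}")

    # -- derived degree structure -------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.row_labels)

    @property
    def n_cols(self) -> int:
        return len(self.col_labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    @property
    def row_degrees(self) -> np.ndarray:
        """Per-plant link counts k_i."""
        return self.entries.sum(axis=1, dtype=np.int64)

    @property
    def col_degrees(self) -> np.ndarray:
        """Per-fungus link counts d_j."""
        return self.entries.sum(axis=0, dtype=np.int64)

    @property
    def n_links(self) -> int:
        """Total number of associations E."""
        return int(self.entries.sum(dtype=np.int64))

    @property
    def connectance(self) -> float:
        return self.n_links / (self.n_rows * self.n_cols)

    # -- conversions ---------------------------------------------------

    def transpose(self) -> "BipartiteIncidence":
        """Swap layers (fungi become rows)."""
        return BipartiteIncidence(self.col_labels, self.row_labels, self.entries.T)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.entries), index=list(self.row_labels), columns=list(self.col_labels)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BipartiteIncidence":
        return cls(tuple(map(str, frame.index)), tuple(map(str, frame.columns)), frame.to_numpy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteIncidence):
            return NotImplemented
        return (
            self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
            and np.array_equal(self.entries, other.entries)
        )

    def __hash__(self) -> int:  # pragma: no cover - frozen dataclass requirement
        return hash((self.row_labels, self.col_labels, self.entries.tobytes()))


@dataclasses.dataclass(frozen=True)
class AggregationMap:
    """Mapping from fine-grained plant nodes to aggregated node labels.

    ``level`` names the aggregation level (e.g. ``meta_network``,
    ``region``, ``population``); ``mapping`` sends every fine-grained
    plant node to exactly one aggregated label.
    """

    level: str
    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        mapping = {str(k): str(v) for k, v in dict(self.mapping).items()}
        if any(not v for v in mapping.values()):
            raise LabelingError("aggregated labels must be non-empty")
        object.__setattr__(self, "mapping", mapping)

    @classmethod
    def identity(cls, labels: Iterable[str], level: str = "identity") -> "AggregationMap":
        return cls(level, {l: l for l in labels})


@dataclasses.dataclass(frozen=True)
class FilterDecision:
    """Accept/reject outcome of the dataset-inclusion filter."""

    accepted: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.accepted


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_incidence(path, binarize: bool = False) -> BipartiteIncidence:
    """Read a labeled incidence matrix from delimited text.

    The first column holds plant (row) labels and the header row holds
    fungal (column) labels.  With ``binarize=True`` any strictly positive
    count maps to 1 — no abundance threshold is applied; with
    ``binarize=False`` any cell outside {0, 1} is rejected.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh), None)
    if header is None:
        raise FormatError(f"{path}: empty file")
    col_labels = [c.strip() for c in header[1:]]
    if len(set(col_labels)) != len(col_labels):
        raise LabelingError(f"{path}: duplicate column labels in header")

    frame = pd.read_csv(path, index_col=0, header=0)
    frame.columns = col_labels
    row_labels = [str(r) for r in frame.index]
    if len(set(row_labels)) != len(row_labels):
        raise LabelingError(f"{path}: duplicate row labels")

    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from None
    if np.isnan(values).any():
        raise FormatError(f"{path}: missing or non-numeric cells")
    if (values < 0).any():
        raise FormatError(f"{path}: negative cell values")

    if binarize:
        entries = (values > 0).astype(np.int8)
    else:
        if not np.isin(values, (0.0, 1.0)).all():
            raise BinaryDomainError(
                f"{path}: non-binary cells present; pass binarize=True to threshold counts"
            )
        entries = values.astype(np.int8)
    return BipartiteIncidence(tuple(row_labels), tuple(col_labels), entries)


def write_incidence(inc: BipartiteIncidence, path) -> None:
    """Write ``inc`` as labeled CSV (round-trips through :func:`read_incidence`)."""
    inc.to_frame().to_csv(path, index_label="")


def read_occurrences(path) -> pd.DataFrame:
    """Read a long-format occurrence table (sample, plant, fungus, count)."""
    table = pd.read_csv(path)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing occurrence columns {missing}")
    return validate_occurrences(table)


def validate_occurrences(table: pd.DataFrame) -> pd.DataFrame:
    table = table.loc[:, list(OCCURRENCE_COLUMNS)].copy()
    counts = pd.to_numeric(table["count"], errors="coerce")
    if counts.isna().any():
        raise FormatError("occurrence counts must be numeric")
    if (counts < 0).any():
        raise FormatError("occurrence counts must be non-negative")
    if not (counts == counts.round()).all():
        raise FormatError("occurrence counts must be integers")
    table["count"] = counts.astype(np.int64)
    for col in ("sample_id", "plant_node", "amf_node"):
        table[col] = table[col].astype(str)
    return table


def occurrence_to_incidence(table: pd.DataFrame, plant_key: str = "plant") -> BipartiteIncidence:
    """Pivot occurrence records into a binary incidence matrix.

    ``plant_key`` selects what becomes a plant-layer node: ``"sample"``
    (one row per sample), ``"plant"`` (counts pooled over samples of the
    same plant node) or ``"pair"`` (one row per plant::sample combination).
    An entry is 1 iff the total count over matching records is positive;
    fungal nodes that appear only with zero counts keep an all-zero column.
    """
    if len(table) == 0:
        raise IncidenceError("empty occurrence table")
    table = validate_occurrences(table)
    if plant_key == "sample":
        row_key = table["sample_id"]
    elif plant_key == "plant":
        row_key = table["plant_node"]
    elif plant_key == "pair":
        row_key = table["plant_node"] + "::" + table["sample_id"]
    else:
        raise IncidenceError(f"unknown plant_key {plant_key!r}")

    # first-appearance order for both layers; de-duplicate by summation
    row_labels = list(dict.fromkeys(row_key))
    col_labels = list(dict.fromkeys(table["amf_node"]))
    totals = (
        pd.DataFrame({"row": row_key, "col": table["amf_node"], "count": table["count"]})
        .groupby(["row", "col"], sort=False)["count"]
        .sum()
    )
    entries = np.zeros((len(row_labels), len(col_labels)), dtype=np.int8)
    row_pos = {l: i for i, l in enumerate(row_labels)}
    col_pos = {l: j for j, l in enumerate(col_labels)}
    for (r, c), total in totals.items():
        if total > 0:
            entries[row_pos[r], col_pos[c]] = 1
    return BipartiteIncidence(tuple(row_labels), tuple(col_labels), entries)


def read_aggregation_map(path, level: str = "custom") -> AggregationMap:
    """Read a two-column CSV ``fine_node, aggregated_node``."""
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: aggregation map needs two columns")
    fine, agg = frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str)
    if fine.duplicated().any():
        raise LabelingError(f"{path}: fine-grained node mapped twice")
    return AggregationMap(level, dict(zip(fine, agg)))


def write_aggregation_map(amap: AggregationMap, path) -> None:
    pd.DataFrame(
        {"fine_node": list(amap.mapping), "aggregated_node": list(amap.mapping.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Aggregation, filtering, hygiene
# ---------------------------------------------------------------------------


def aggregate_plants(inc: BipartiteIncidence, amap: AggregationMap) -> BipartiteIncidence:
    """Merge plant-layer rows according to an aggregation map.

    Rows sharing an aggregated label are combined by Boolean OR — the
    aggregated node carries the union of associations of its members, the
    natural reading of a species meta-network pooled over locations.  The
    fungal layer is untouched.  Output row order follows first appearance
    of each aggregated label in the input.
    """
    unmapped = [r for r in inc.row_labels if r not in amap.mapping]
    if unmapped:
        raise CoverageError(f"aggregation map does not cover rows: {unmapped[:5]}")
    targets = [amap.mapping[r] for r in inc.row_labels]
    out_labels = list(dict.fromkeys(targets))
    pos = {l: i for i, l in enumerate(out_labels)}
    entries = np.zeros((len(out_labels), inc.n_cols), dtype=np.int8)
    for i, target in enumerate(targets):
        np.bitwise_or(entries[pos[target]], inc.entries[i], out=entries[pos[target]])
    return BipartiteIncidence(tuple(out_labels), inc.col_labels, entries)


def filter_dataset(
    inc: BipartiteIncidence, min_fungi: int = 5, min_plants: int = 1
) -> FilterDecision:
    """Dataset-inclusion rule: reject matrices with too few fungal nodes.

    Defaults follow the screening rule used for published plant-AMF
    surveys: at least 5 fungal nodes and at least one plant node
    (single-plant studies are retained — their plant layer may represent
    treatments, populations or time points).
    """
    if inc.n_cols < min_fungi:
        return FilterDecision(False, f"fungal nodes < {min_fungi}")
    if inc.n_rows < min_plants:
        return FilterDecision(False, f"plant nodes < {min_plants}")
    return FilterDecision(True, None)


def drop_empty_nodes(
    inc: BipartiteIncidence,
) -> tuple[BipartiteIncidence, list[str]]:
    """Remove all-zero rows and columns, reporting the dropped labels.

    Zero-degree nodes force p = 0 identically under the null model and
    contribute nothing to nestedness or modularity, but inflate pair
    counts; they are removed before fitting and reported for audit.
    """
    if inc.n_links == 0:
        raise DegenerateNetworkError("matrix has no links at all")
    keep_rows = inc.row_degrees > 0
    keep_cols = inc.col_degrees > 0
    removed = [l for l, k in zip(inc.row_labels, keep_rows) if not k]
    removed += [l for l, k in zip(inc.col_labels, keep_cols) if not k]
    if not removed:
        return inc, []
    out = BipartiteIncidence(
        tuple(l for l, k in zip(inc.row_labels, keep_rows) if k),
        tuple(l for l, k in zip(inc.col_labels, keep_cols) if k),
        inc.entries[np.ix_(keep_rows, keep_cols)],
    )
    return out, removed
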
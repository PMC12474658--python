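"""Record schema, CSV I/O and the :class:`Partition` container.

Records travel through the pipeline as a :class:`pandas.DataFrame` with one
row per child and the columns in :data:`RAW_COLUMNS`.  Missing cells are
``NaN`` (never empty-string sentinels); validation happens at read time so
that downstream stages can assume a clean frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("laolink")

#: Column order of a raw registry frame.
RAW_COLUMNS = [
    "record_id",
    "name",
    "family_name",
    "dob",
    "sex",
    "village",
    "father_name",
    "mother_name",
    "contact",
]

#: Free-text fields subject to normalization.
TEXT_COLUMNS = [
    "name",
    "family_name",
    "village",
    "father_name",
    "mother_name",
]

#: Strings read as missing, besides the empty cell.  Configurable via
#: :func:`read_records`.
DEFAULT_NA_VALUES = ["", "NA", "N/A", "na", "n/a", "NULL", "null"]

#: Contact numbers longer than this are rejected at read time.
MAX_CONTACT_LENGTH = 50


class ValidationError(ValueError):
    """A registry file violates a structural invariant."""


def is_missing(v) -> bool:
    """Scalar missingness (None, NaN, NA, NaT)."""
    if v is None:
        return True
    try:
        return bool(pd.isna(v))
    except (TypeError, ValueError):  # arrays etc. are not missing scalars
        return False


def _parse_dob(values: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Parse DOB strings, accepting ISO 8601 and day-first dd/mm/yyyy.

    Returns the parsed datetime series and a boolean mask of cells that were
    present but unparseable (impossible dates included).
    """
    raw = values.astype("string")
    iso = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    dayfirst = pd.to_datetime(raw, format="%d/%m/%Y", errors="coerce")
    parsed = iso.fillna(dayfirst)
    invalid = raw.notna() & parsed.isna()
    return parsed, invalid


def read_records(
    path,
    na_values: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read a registry CSV into a validated frame.

    Parameters
    ----------
    path:
        UTF-8 CSV with a header row containing :data:`RAW_COLUMNS`.
    na_values:
        Cell contents treated as missing (default :data:`DEFAULT_NA_VALUES`;
        whitespace-only cells are always missing).

    Returns
    -------
    DataFrame with :data:`RAW_COLUMNS` plus a boolean ``dob_invalid`` column
    flagging rows whose DOB was present but unparseable.  Flagged rows are
    retained, never dropped.

    Raises
    ------
    ValidationError
        On duplicate ``record_id`` or a contact value longer than
        :data:`MAX_CONTACT_LENGTH` characters.
    """
    if na_values is None:
        na_values = DEFAULT_NA_VALUES
    df = pd.read_csv(
        path,
        dtype=str,
        na_values=list(na_values),
        keep_default_na=False,
        encoding="utf-8",
    )
    missing_cols = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing required columns: {missing_cols}")
    df = df[RAW_COLUMNS].copy()
    # whitespace-only cells are missing regardless of the configured list
    for col in df.columns:
        stripped = df[col].str.strip()
        df[col] = stripped.where(stripped != "", other=pd.NA)

    if df["record_id"].isna().any():
        raise ValidationError("record_id is missing on some rows")
    dup = df["record_id"][df["record_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate record_id: {sorted(dup.unique())}")

    too_long = df["contact"].dropna().str.len() > MAX_CONTACT_LENGTH
    if too_long.any():
        bad = df.loc[too_long[too_long].index, "record_id"].tolist()
        raise ValidationError(
            f"contact exceeds the {MAX_CONTACT_LENGTH}-character bound for "
            f"records {bad}"
        )

    parsed, invalid = _parse_dob(df["dob"])
    df["dob"] = parsed
    df["dob_invalid"] = invalid.to_numpy(dtype=bool)
    n_bad = int(invalid.sum())
    if n_bad:
        logger.warning("read_records: %d records with unparseable DOB flagged", n_bad)
    return df


def write_records(df: pd.DataFrame, path) -> None:
    """Write a registry frame back to CSV (dates as ISO 8601)."""
    out = df.copy()
    if pd.api.types.is_datetime64_any_dtype(out["dob"]):
        out["dob"] = out["dob"].dt.strftime("%Y-%m-%d")
    out.drop(columns=[c for c in out.columns if c not in RAW_COLUMNS], inplace=True)
    out.to_csv(path, index=False, encoding="utf-8")


class Partition:
    """A clustering of record ids into entities.

    Comparison is by set structure: two partitions are equal when they induce
    the same family of clusters, regardless of the labels used.  Cluster
    labels produced here are canonical (the lexicographically smallest member
    id) so serialized output is deterministic.
    """

    def __init__(self, mapping: Mapping[str, str]):
        self._map = dict(mapping)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_links(cls, record_ids: Iterable[str], links: Iterable[tuple[str, str]]) -> "Partition":
        """Transitive closure of pairwise links over a record universe."""
        g = nx.Graph()
        g.add_nodes_from(record_ids)
        g.add_edges_from(links)
        mapping = {}
        for comp in nx.connected_components(g):
            label = min(comp)
            for rid in comp:
                mapping[rid] = label
        return cls(mapping)

    @classmethod
    def from_labels(cls, record_ids: Sequence[str], labels: Sequence) -> "Partition":
        clusters: dict = {}
        for rid, lab in zip(record_ids, labels):
            clusters.setdefault(lab, []).append(rid)
        mapping = {}
        for members in clusters.values():
            label = min(members)
            for rid in members:
                mapping[rid] = label
        return cls(mapping)

    @classmethod
    def read_csv(cls, path) -> "Partition":
        df = pd.read_csv(path, dtype=str)
        return cls(dict(zip(df["record_id"], df["cluster_id"])))

    # -- views -------------------------------------------------------------
    @property
    def record_ids(self) -> set:
        return set(self._map)

    def cluster_of(self, record_id: str) -> str:
        return self._map[record_id]

    def clusters(self) -> list[frozenset]:
        by_label: dict = {}
        for rid, lab in self._map.items():
            by_label.setdefault(lab, set()).add(rid)
        return [frozenset(m) for m in by_label.values()]

    def as_sets(self) -> frozenset:
        return frozenset(self.clusters())

    def cluster_sizes(self) -> dict:
        sizes: dict = {}
        for lab in self._map.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def linked_records(self) -> set:
        """Records belonging to a cluster of size >= 2."""
        sizes = self.cluster_sizes()
        return {rid for rid, lab in self._map.items() if sizes[lab] >= 2}

    def labels(self, order: Sequence[str]) -> np.ndarray:
        """Integer cluster labels aligned to ``order`` (sklearn-style)."""
        label_ix: dict = {}
        out = np.empty(len(order), dtype=np.int64)
        for i, rid in enumerate(order):
            lab = self._map[rid]
            out[i] = label_ix.setdefault(lab, len(label_ix))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self._map.items())
        return pd.DataFrame(rows, columns=["record_id", "cluster_id"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, encoding="utf-8")

    # -- dunder ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self._map)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.as_sets() == other.as_sets()

    def __hash__(self):
        return hash(self.as_sets())

    def __repr__(self) -> str:
        sizes = self.cluster_sizes()
        multi = sum(1 for s in sizes.values() if s >= 2)
        return f"Partition({len(self._map)} records, {multi} multi-record clusters)"


def write_partition(partition: Partition, path) -> None:
    """Write a partition as a two-column CSV sorted by record_id."""
    partition.write_csv(path)


def read_partition(path) -> Partition:
    return Partition.read_csv(path)


@dataclass
class PipelineConfig:
    """Bag of pipeline settings; every stochastic step draws from ``seed``."""

    na_values: list = field(default_factory=lambda: list(DEFAULT_NA_VALUES))
    phonetic_merge: bool = False
    placeholder_as_missing: bool = False
    deterministic_keys: tuple = ("dob", "sex", "village")
    probabilistic_keys: tuple = ("dob", "village")
    blocking_mode: str = "conjunction"
    jw_levels: tuple = (0.88, 0.70)
    recall: float = 0.7
    threshold: float = 0.5
    em_tol: float = 1e-6
    em_max_iter: int = 100
    strict_all_fields: bool = False
    strict_audit: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("recall", "threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.recall <= 0:
            raise ValueError("recall must lie in (0, 1]")
        for t in self.jw_levels:
            if not (0.0 <= t <= 1.0):
                raise ValueError("similarity thresholds must lie in [0, 1]")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("deterministic_keys", "probabilistic_keys", "jw_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)
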
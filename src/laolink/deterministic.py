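"""Rule-based deduplication: blocking plus a decision table over name fields.

Candidate pairs are restricted to records agreeing exactly on the blocking
key (DOB, sex, village by default).  Within a block, a pair is compared on
the child's name and both parents' names; each field is in one of three
states — MATCH, NONMATCH, or NOT_AVAILABLE when either side is missing —
and the 27 possible state triples are mapped to a link/no-link decision by
a :class:`RuleTable`.  The default table is the majority rule
``count(MATCH) > count(NONMATCH)``, the closed form consistent with the 21
review criteria established for this registry (10 match, 11 non-match).
Accepted links are closed transitively into entity clusters.
"""

from __future__ import annotations

import itertools
import logging
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .records import Partition, is_missing as _missing

logger = logging.getLogger("laolink")

DEFAULT_BLOCK_KEYS = ("dob", "sex", "village")
NAME_FIELDS = ("name", "father_name", "mother_name")


class FieldState(Enum):
    MATCH = "match"
    NONMATCH = "nonmatch"
    NOT_AVAILABLE = "not_available"


def field_state(a, b) -> FieldState:
    """Three-state comparison of canonical values.

    NOT_AVAILABLE if either side is missing; MATCH iff both present and
    equal; NONMATCH otherwise.
    """
    if _missing(a) or _missing(b):
        return FieldState.NOT_AVAILABLE
    return FieldState.MATCH if a == b else FieldState.NONMATCH


class RuleTable:
    """Total decision table over (name, father, mother) state triples."""

    def __init__(self, table: Mapping[tuple, bool]):
        self._table = dict(table)
        universe = set(itertools.product(FieldState, repeat=3))
        missing = universe - set(self._table)
        if missing:
            raise ValueError(f"rule table is not total; missing {len(missing)} triples")

    def decision(self, name: FieldState, father: FieldState, mother: FieldState) -> bool:
        return self._table[(name, father, mother)]

    @classmethod
    def default(cls) -> "RuleTable":
        """Majority rule: link iff MATCH states outnumber NONMATCH states."""
        table = {}
        for triple in itertools.product(FieldState, repeat=3):
            n_match = sum(s is FieldState.MATCH for s in triple)
            n_non = sum(s is FieldState.NONMATCH for s in triple)
            table[triple] = n_match > n_non
        return cls(table)

    @classmethod
    def from_csv(cls, path) -> "RuleTable":
        """Load an override table (columns name_state, father_state,
        mother_state, decision); unlisted triples fall back to the majority
        rule."""
        df = pd.read_csv(path, dtype=str)
        base = cls.default()._table
        for _, row in df.iterrows():
            triple = tuple(
                FieldState(row[c].strip().lower())
                for c in ("name_state", "father_state", "mother_state")
            )
            base[triple] = row["decision"].strip().upper() in ("TRUE", "1", "YES")
        return cls(base)


def classify_triple(name: FieldState, father: FieldState, mother: FieldState,
                    rules: RuleTable | None = None) -> bool:
    if rules is None:
        rules = RuleTable.default()
    return rules.decision(name, father, mother)


def block_records(df: pd.DataFrame, keys: Sequence[str] = DEFAULT_BLOCK_KEYS) -> dict:
    """Group records by exact agreement on the key fields.

    Records missing any key field join no block (their count is logged).
    Returns a dict mapping key tuple -> list of record_ids.
    """
    if not keys:
        raise ValueError("blocking keys must be non-empty")
    usable = df.dropna(subset=list(keys))
    n_excluded = len(df) - len(usable)
    if n_excluded:
        logger.info("block_records: %d records missing a blocking key excluded", n_excluded)
    blocks = {
        key: list(group["record_id"])
        for key, group in usable.groupby(list(keys), sort=True)
    }
    return blocks


def candidate_review_set(df: pd.DataFrame, keys: Sequence[str] = DEFAULT_BLOCK_KEYS) -> set:
    """Records sharing their full blocking key with at least one other record.

    This is the set a human reviewer would be shown.
    """
    return {
        rid
        for members in block_records(df, keys).values()
        if len(members) >= 2
        for rid in members
    }


def pair_states(row_a: Mapping, row_b: Mapping,
                fields: Sequence[str] = NAME_FIELDS) -> tuple:
    return tuple(field_state(row_a[f], row_b[f]) for f in fields)


class DeterministicMatcher(ClusterMixin, BaseEstimator):
    """Rule-table deduplicator over blocked candidate pairs.

    Parameters
    ----------
    keys : tuple of str
        Blocking key fields (exact agreement required).
    rules : RuleTable or None
        Decision table; ``None`` uses the majority-rule default.
    strict_all_fields : bool
        Require all three name fields to be exact matches (the stricter
        all-fields variant) instead of consulting the rule table.
    jw_threshold : float or None
        When set, a field pair with Jaro-Winkler similarity at or above this
        value counts as MATCH; default is exact equality of canonical forms
        (fuzziness belongs to the probabilistic stage).

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster label per input row.
    partition_ : Partition
    match_pairs_ : list of (record_id, record_id)
    n_blocks_ : int
    """

    def __init__(self, keys=DEFAULT_BLOCK_KEYS, rules=None,
                 strict_all_fields=False, jw_threshold=None):
        self.keys = keys
        self.rules = rules
        self.strict_all_fields = strict_all_fields
        self.jw_threshold = jw_threshold

    def _field_state(self, a, b) -> FieldState:
        st = field_state(a, b)
        if (
            st is FieldState.NONMATCH
            and self.jw_threshold is not None
        ):
            from .probabilistic import jaro_winkler

            if jaro_winkler(a, b) >= self.jw_threshold:
                return FieldState.MATCH
        return st

    def fit(self, X: pd.DataFrame, y=None):
        rules = self.rules if self.rules is not None else RuleTable.default()
        blocks = block_records(X, self.keys)
        rows = X.set_index("record_id", drop=False)
        links = []
        for members in blocks.values():
            if len(members) < 2:
                continue
            for ra, rb in itertools.combinations(sorted(members), 2):
                a, b = rows.loc[ra], rows.loc[rb]
                states = tuple(self._field_state(a[f], b[f]) for f in NAME_FIELDS)
                if self.strict_all_fields:
                    ok = all(s is FieldState.MATCH for s in states)
                else:
                    ok = rules.decision(*states)
                if ok:
                    links.append((ra, rb))
        self.n_blocks_ = len(blocks)
        self.match_pairs_ = sorted(links)
        self.partition_ = Partition.from_links(X["record_id"], links)
        self.labels_ = self.partition_.labels(list(X["record_id"]))
        return self


def deterministic_match(df: pd.DataFrame, rules: RuleTable | None = None,
                        keys: Sequence[str] = DEFAULT_BLOCK_KEYS,
                        **kwargs) -> Partition:
    """Functional wrapper over :class:`DeterministicMatcher`."""
    est = DeterministicMatcher(keys=keys, rules=rules, **kwargs).fit(df)
    return est.partition_
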
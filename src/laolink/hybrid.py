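"""Hybrid matcher: deterministic rules first, probabilistic on the residue.

Records already placed in a multi-record cluster by the deterministic stage
are withheld from the probabilistic stage, so the probabilistic algorithm
never reprocesses records the rules have settled; both stages' links are
then unioned and closed transitively.  Every probabilistic link can be
audited against the deterministic decision table; conflicting links are
flagged (default) or removed (strict mode).
"""

from __future__ import annotations

import logging

import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin, clone

from .records import Partition
from .deterministic import (
    DeterministicMatcher,
    FieldState,
    NAME_FIELDS,
    RuleTable,
    field_state,
)
from .probabilistic import FellegiSunterMatcher

logger = logging.getLogger("laolink")


def audit_link(row_a, row_b, rules: RuleTable) -> str:
    """Re-evaluate one probabilistic link under the deterministic rules.

    The link is 'flagged' when the rule decision is FALSE with at least one
    outright NONMATCH among the name fields, or when the pair disagrees on
    sex (the decision table presumes sex equality); otherwise 'consistent'.
    """
    states = tuple(field_state(row_a[f], row_b[f]) for f in NAME_FIELDS)
    sex_state = field_state(row_a["sex"], row_b["sex"])
    decision = rules.decision(*states)
    conflict = (not decision and any(s is FieldState.NONMATCH for s in states)) or (
        sex_state is FieldState.NONMATCH
    )
    return "flagged" if conflict else "consistent"


def audit_links(trace: pd.DataFrame, df: pd.DataFrame,
                rules: RuleTable | None = None) -> pd.DataFrame:
    """Fill the audit column of a hybrid trace for probabilistic links."""
    if rules is None:
        rules = RuleTable.default()
    rows = df.set_index("record_id", drop=False)
    out = trace.copy()
    audits = []
    for _, rec in out.iterrows():
        if rec["provenance"] == "probabilistic":
            audits.append(audit_link(rows.loc[rec["id1"]], rows.loc[rec["id2"]], rules))
        else:
            audits.append("")
    out["audit"] = audits
    return out


class HybridMatcher(ClusterMixin, BaseEstimator):
    """Deterministic-then-probabilistic deduplicator.

    Parameters
    ----------
    deterministic : DeterministicMatcher or None
        First-stage matcher (default configuration when ``None``).
    probabilistic : FellegiSunterMatcher or None
        Second-stage matcher run on records the first stage left unmatched.
    strict_audit : bool
        Remove probabilistic links that conflict with the deterministic
        decision table instead of merely flagging them.

    Attributes
    ----------
    partition_ : Partition
    labels_ : ndarray of int
    trace_ : DataFrame (id1, id2, provenance, audit)
    deterministic_ / probabilistic_ : the fitted stage estimators
    """

    def __init__(self, deterministic=None, probabilistic=None, strict_audit=False,
                 rules=None):
        self.deterministic = deterministic
        self.probabilistic = probabilistic
        self.strict_audit = strict_audit
        self.rules = rules

    def fit(self, X: pd.DataFrame, y=None):
        det = clone(self.deterministic) if self.deterministic is not None else DeterministicMatcher()
        prob = clone(self.probabilistic) if self.probabilistic is not None else FellegiSunterMatcher()
        rules = self.rules if self.rules is not None else RuleTable.default()

        det.fit(X)
        self.deterministic_ = det
        matched = det.partition_.linked_records()

        # The FS parameters (m, u, lambda) describe the whole registry, so
        # they are estimated on the full candidate set; only links with both
        # endpoints deterministically unmatched are then taken up, so the
        # probabilistic stage never reprocesses settled records.
        prob_links: list = []
        self.probabilistic_ = None
        try:
            prob.fit(X)
        except ValueError as exc:  # no comparable pairs at all
            logger.info("hybrid: probabilistic stage skipped (%s)", exc)
        else:
            self.probabilistic_ = prob
            kept_pairs = prob.scored_pairs_
            residual_mask = ~kept_pairs["id1"].isin(matched) & ~kept_pairs["id2"].isin(matched)
            kept_pairs = kept_pairs[residual_mask]
            prob_links = list(zip(kept_pairs["id1"], kept_pairs["id2"]))

        trace = pd.DataFrame(
            [(a, b, "deterministic") for a, b in det.match_pairs_]
            + [(a, b, "probabilistic") for a, b in prob_links],
            columns=["id1", "id2", "provenance"],
        )
        trace = audit_links(trace, X, rules)
        if self.strict_audit:
            kept = trace[(trace["provenance"] == "deterministic") | (trace["audit"] != "flagged")]
        else:
            kept = trace
        self.trace_ = trace.reset_index(drop=True)
        links = list(zip(kept["id1"], kept["id2"]))
        self.partition_ = Partition.from_links(X["record_id"], links)
        self.labels_ = self.partition_.labels(list(X["record_id"]))
        return self


def hybrid_match(df: pd.DataFrame, **kwargs) -> tuple:
    """Functional wrapper; returns (Partition, trace frame)."""
    est = HybridMatcher(**kwargs).fit(df)
    return est.partition_, est.trace_
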
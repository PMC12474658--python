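"""Fellegi-Sunter probabilistic linkage with EM-estimated parameters.

Candidate pairs (records agreeing exactly on the blocking key, DOB and
village by default) are summarized as comparison vectors: one ordered
agreement level per field, with graded name agreement via Jaro-Winkler
similarity and an explicit not-available level when either side is missing.
A two-class latent-variable EM estimates, for every field and level, the
probability of observing that level among true matches (m) and among true
non-matches (u), assuming conditional independence of fields.  Each pair is
scored by the match weight

    w = sum over fields of log2( m[level] / u[level] )

(not-available fields contribute nothing), converted to a posterior match
probability through the prior match probability lambda, and pairs at or
above the posterior threshold are closed transitively into clusters.

lambda is estimated from a deterministic proxy: the count of candidate
pairs the rule-based matcher links, inflated by an assumed recall of that
proxy, divided by the number of candidate pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .records import Partition, is_missing as _missing
from .deterministic import (
    DEFAULT_BLOCK_KEYS,
    DeterministicMatcher,
    RuleTable,
    block_records,
)

logger = logging.getLogger("laolink")

PROB_BLOCK_KEYS = ("dob", "village")
NA_LEVEL = -1
_CLAMP = 1e-6


# ---------------------------------------------------------------------------
# Jaro-Winkler
# ---------------------------------------------------------------------------

def jaro_similarity(s1: str, s2: str) -> float:
    """Jaro similarity over Unicode code points."""
    if s1 == s2:
        return 1.0
    len1, len2 = len(s1), len(s2)
    if len1 == 0 or len2 == 0:
        return 0.0
    window = max(len1, len2) // 2 - 1
    if window < 0:
        window = 0
    flags1 = [False] * len1
    flags2 = [False] * len2
    m = 0
    for i, ch in enumerate(s1):
        lo = max(0, i - window)
        hi = min(len2, i + window + 1)
        for j in range(lo, hi):
            if not flags2[j] and s2[j] == ch:
                flags1[i] = True
                flags2[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    # transpositions: matched characters out of order, halved
    s2_matched = [s2[j] for j in range(len2) if flags2[j]]
    t = sum(a != b for a, b in zip((s1[i] for i in range(len1) if flags1[i]), s2_matched))
    t //= 2
    return (m / len1 + m / len2 + (m - t) / m) / 3.0


def jaro_winkler(s1: str, s2: str, prefix_scale: float = 0.1, max_prefix: int = 4) -> float:
    """Jaro similarity with the Winkler common-prefix bonus (p = 0.1, cap 4).

    Symmetric, in [0, 1]; callers must resolve missingness first.
    """
    if s1 is None or s2 is None:
        raise ValueError("jaro_winkler requires non-missing strings")
    sim = jaro_similarity(s1, s2)
    prefix = 0
    for a, b in zip(s1, s2):
        if a != b or prefix >= max_prefix:
            break
        prefix += 1
    return sim + prefix * prefix_scale * (1.0 - sim)


# ---------------------------------------------------------------------------
# Comparison vectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldComparison:
    """Agreement levels for one field.

    With thresholds (t1 > t2 > ...): level 0 = exact, level i = JW >= t_i,
    last level = all-other.  An empty threshold tuple yields plain
    exact/other.  Missing on either side is the NA level (code -1).
    """

    field: str
    thresholds: tuple = ()

    def __post_init__(self):
        if list(self.thresholds) != sorted(self.thresholds, reverse=True) or (
            len(set(self.thresholds)) != len(self.thresholds)
        ):
            raise ValueError("thresholds must be strictly decreasing")

    @property
    def n_levels(self) -> int:
        return len(self.thresholds) + 2

    def level(self, a, b) -> int:
        if _missing(a) or _missing(b):
            return NA_LEVEL
        if a == b:
            return 0
        if self.thresholds:
            sim = jaro_winkler(str(a), str(b))
            for i, t in enumerate(self.thresholds):
                if sim >= t:
                    return i + 1
        return self.n_levels - 1


@dataclass(frozen=True)
class ComparisonSpec:
    comparisons: tuple

    @classmethod
    def default(cls, jw_levels: tuple = (0.88, 0.70), include_dob: bool = False) -> "ComparisonSpec":
        comps = [
            FieldComparison("name", tuple(jw_levels)),
            FieldComparison("father_name", tuple(jw_levels)),
            FieldComparison("mother_name", tuple(jw_levels)),
            FieldComparison("sex"),
        ]
        if include_dob:
            comps.append(FieldComparison("dob"))
        return cls(tuple(comps))

    @property
    def fields(self) -> list:
        return [c.field for c in self.comparisons]


def compare_pair(row_a, row_b, spec: ComparisonSpec) -> tuple:
    """Comparison vector for one record pair (one level code per field)."""
    return tuple(c.level(row_a[c.field], row_b[c.field]) for c in spec.comparisons)


def candidate_pairs(df: pd.DataFrame, keys: Sequence[str] = PROB_BLOCK_KEYS,
                    mode: str = "conjunction") -> list:
    """Within-block record-id pairs.

    ``conjunction`` blocks on exact agreement of all keys jointly;
    ``union`` takes the union of pairs from blocking on each key alone.
    """
    if mode == "conjunction":
        key_sets = [tuple(keys)]
    elif mode == "union":
        key_sets = [(k,) for k in keys]
    else:
        raise ValueError(f"unknown blocking mode {mode!r}")
    pairs = set()
    for ks in key_sets:
        for members in block_records(df, ks).values():
            if len(members) < 2:
                continue
            pairs.update(itertools.combinations(sorted(members), 2))
    return sorted(pairs)


def compare_candidates(df: pd.DataFrame, pairs: Sequence[tuple],
                       spec: ComparisonSpec) -> np.ndarray:
    rows = df.set_index("record_id", drop=False)
    out = np.empty((len(pairs), len(spec.comparisons)), dtype=np.int8)
    for i, (ra, rb) in enumerate(pairs):
        out[i] = compare_pair(rows.loc[ra], rows.loc[rb], spec)
    return out


# ---------------------------------------------------------------------------
# Parameters and EM
# ---------------------------------------------------------------------------

@dataclass
class LinkageParameters:
    """Per-field, per-level m/u probabilities plus prior match probability."""

    fields: list
    m: list  # list of 1-d arrays, one per field
    u: list
    lam: float

    def __post_init__(self):
        self.m = [np.asarray(a, dtype=float) for a in self.m]
        self.u = [np.asarray(a, dtype=float) for a in self.u]
        if not (0.0 < self.lam < 1.0):
            raise ValueError(f"lambda must lie in (0, 1), got {self.lam}")
        for name, probs in [("m", self.m), ("u", self.u)]:
            for f, arr in zip(self.fields, probs):
                if not np.isclose(arr.sum(), 1.0, atol=1e-6):
                    raise ValueError(f"{name}[{f}] does not sum to 1")
                if (arr <= 0).any() or (arr >= 1).any():
                    raise ValueError(f"{name}[{f}] has probabilities outside (0, 1)")


def _clamp_simplex(p: np.ndarray, eps: float = _CLAMP) -> np.ndarray:
    """Clip into [eps, 1-eps] and return the excess to the largest entry so
    the distribution still sums to one."""
    p = np.clip(p, eps, 1.0 - eps)
    p[np.argmax(p)] -= p.sum() - 1.0
    return p


def initial_parameters(vectors: np.ndarray, spec: ComparisonSpec, lam: float) -> LinkageParameters:
    """Default EM start: 0.9 m-mass on the exact level (rest uniform);
    u from the observed level frequencies over all candidate pairs."""
    m, u = [], []
    for j, comp in enumerate(spec.comparisons):
        k = comp.n_levels
        mj = np.full(k, 0.1 / (k - 1))
        mj[0] = 0.9
        v = vectors[:, j]
        counts = np.bincount(v[v >= 0], minlength=k).astype(float)
        uj = counts + 1.0  # Laplace smoothing keeps every level representable
        uj /= uj.sum()
        m.append(_clamp_simplex(mj))
        u.append(_clamp_simplex(uj))
    return LinkageParameters(spec.fields, m, u, lam)


def _class_loglik(vectors: np.ndarray, probs: list) -> np.ndarray:
    """Sum over fields of log P(level | class); NA levels contribute 0."""
    out = np.zeros(len(vectors))
    for j, arr in enumerate(probs):
        v = vectors[:, j]
        mask = v >= 0
        out[mask] += np.log(arr)[v[mask]]
    return out


def em_estimate(vectors: np.ndarray, init: LinkageParameters,
                tol: float = 1e-6, max_iter: int = 100,
                update_lambda: bool = False) -> tuple:
    """Two-class latent EM for m/u under conditional independence.

    Not-available levels are excluded from the field likelihood
    (missing-at-random).  Returns (parameters, log-likelihood path); the
    path is non-decreasing.  Raises if fewer than two distinct vectors are
    supplied (the two-class model is unidentifiable).
    """
    vectors = np.asarray(vectors)
    if len(vectors) < 2 or len(np.unique(vectors, axis=0)) < 2:
        raise ValueError("EM unidentifiable: fewer than two distinct comparison vectors")
    m = [a.copy() for a in init.m]
    u = [a.copy() for a in init.u]
    lam = init.lam
    path = []
    prev = None
    n_iter = 0
    for _ in range(max_iter):
        # E-step
        la = np.log(lam) + _class_loglik(vectors, m)
        lb = np.log1p(-lam) + _class_loglik(vectors, u)
        hi = np.maximum(la, lb)
        loglik = float(np.sum(hi + np.log(np.exp(la - hi) + np.exp(lb - hi))))
        path.append(loglik)
        resp = 1.0 / (1.0 + np.exp(lb - la))
        if prev is not None and abs(loglik - prev) < tol:
            break
        prev = loglik
        # M-step
        for j in range(vectors.shape[1]):
            v = vectors[:, j]
            mask = v >= 0
            k = len(m[j])
            rm = np.bincount(v[mask], weights=resp[mask], minlength=k)
            ru = np.bincount(v[mask], weights=(1.0 - resp)[mask], minlength=k)
            denom_m = resp[mask].sum()
            denom_u = (1.0 - resp[mask]).sum()
            if denom_m > 0:
                m[j] = _clamp_simplex(rm / denom_m)
            if denom_u > 0:
                u[j] = _clamp_simplex(ru / denom_u)
        if update_lambda:
            lam = float(np.clip(resp.mean(), _CLAMP, 1.0 - _CLAMP))
        n_iter += 1
    params = LinkageParameters(init.fields, m, u, lam)
    return params, path


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def match_weight(vector: Sequence[int], params: LinkageParameters) -> float:
    """Fellegi-Sunter weight in bits; NA fields are skipped (contribute 0)."""
    w = 0.0
    for j, level in enumerate(vector):
        if level >= 0:
            w += np.log2(params.m[j][level] / params.u[j][level])
    return float(w)


def _weights(vectors: np.ndarray, params: LinkageParameters) -> np.ndarray:
    w = np.zeros(len(vectors))
    for j in range(vectors.shape[1]):
        v = vectors[:, j]
        mask = v >= 0
        w[mask] += np.log2(params.m[j] / params.u[j])[v[mask]]
    return w


def posterior_probability(w, lam: float):
    """P(match | comparison) from the weight and the prior lambda."""
    logit = np.log(lam / (1.0 - lam)) + np.asarray(w, dtype=float) * np.log(2.0)
    return 1.0 / (1.0 + np.exp(-logit))


def estimate_lambda(df: pd.DataFrame, proxy_rules: RuleTable | None = None,
                    keys: Sequence[str] = PROB_BLOCK_KEYS, recall: float = 0.7,
                    mode: str = "conjunction",
                    det_keys: Sequence[str] = DEFAULT_BLOCK_KEYS) -> float:
    """Prior match probability from a recall-adjusted deterministic proxy.

    lambda = (proxy match-pair count / recall) / candidate-pair count,
    clamped into (1e-6, 1-1e-6).  ``recall`` is the assumed recall of the
    deterministic proxy; sweeping it over 0.65..0.95 yields the
    sensitivity analysis of the prior.
    """
    if not (0.0 < recall <= 1.0):
        raise ValueError("recall must lie in (0, 1]")
    pairs = candidate_pairs(df, keys, mode)
    if not pairs:
        raise ValueError("no comparable pairs under blocking")
    proxy = DeterministicMatcher(keys=det_keys, rules=proxy_rules).fit(df)
    n_proxy = len(set(proxy.match_pairs_) & set(pairs))
    lam = (n_proxy / recall) / len(pairs)
    return float(np.clip(lam, _CLAMP, 1.0 - _CLAMP))


def predict_pairs(df: pd.DataFrame, spec: ComparisonSpec, params: LinkageParameters,
                  threshold: float = 0.5, keys: Sequence[str] = PROB_BLOCK_KEYS,
                  mode: str = "conjunction") -> pd.DataFrame:
    """Score all candidate pairs; keep those with posterior >= threshold.

    Deterministic order: descending posterior, then ascending id pair.
    """
    pairs = candidate_pairs(df, keys, mode)
    if not pairs:
        return pd.DataFrame(columns=["id1", "id2", "weight", "posterior"])
    vectors = compare_candidates(df, pairs, spec)
    w = _weights(vectors, params)
    post = posterior_probability(w, params.lam)
    out = pd.DataFrame(pairs, columns=["id1", "id2"])
    out["weight"] = w
    out["posterior"] = post
    out = out[out["posterior"] >= threshold]
    out = out.sort_values(["posterior", "id1", "id2"],
                          ascending=[False, True, True]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class FellegiSunterMatcher(ClusterMixin, BaseEstimator):
    """Probabilistic deduplicator (Fellegi-Sunter with EM).

    Parameters
    ----------
    keys : tuple of str
        Blocking keys; ``blocking_mode`` "conjunction" requires joint exact
        agreement, "union" pools pairs from each key alone (the latter also
        adds DOB as a compared field, since pairs may then disagree on it).
    jw_levels : tuple of float
        Descending Jaro-Winkler cut-offs for the graded name levels.
    recall : float
        Assumed recall of the deterministic proxy when estimating the prior
        match probability.
    threshold : float
        Posterior probability at or above which a pair is linked.
    lam : float or None
        Prior match probability override; ``None`` estimates it from the
        deterministic proxy.
    update_lambda : bool
        Let EM re-estimate the prior each iteration instead of holding it
        at the proxy estimate.

    Attributes
    ----------
    params_ : LinkageParameters
    lambda_ : float
    loglik_path_ : list of float
    scored_pairs_ : DataFrame (id1, id2, weight, posterior) above threshold
    partition_ : Partition
    labels_ : ndarray of int
    """

    def __init__(self, keys=PROB_BLOCK_KEYS, blocking_mode="conjunction",
                 jw_levels=(0.88, 0.70), recall=0.7, threshold=0.5,
                 lam=None, update_lambda=False, proxy_rules=None,
                 det_keys=DEFAULT_BLOCK_KEYS, tol=1e-6, max_iter=100):
        self.keys = keys
        self.blocking_mode = blocking_mode
        self.jw_levels = jw_levels
        self.recall = recall
        self.threshold = threshold
        self.lam = lam
        self.update_lambda = update_lambda
        self.proxy_rules = proxy_rules
        self.det_keys = det_keys
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y=None):
        spec = ComparisonSpec.default(
            tuple(self.jw_levels), include_dob=(self.blocking_mode == "union")
        )
        self.spec_ = spec
        pairs = candidate_pairs(X, self.keys, self.blocking_mode)
        if not pairs:
            raise ValueError("no comparable pairs under blocking")
        vectors = compare_candidates(X, pairs, spec)
        if self.lam is not None:
            lam = float(self.lam)
        else:
            lam = estimate_lambda(X, self.proxy_rules, self.keys, self.recall,
                                  self.blocking_mode, self.det_keys)
        self.lambda_ = lam
        init = initial_parameters(vectors, spec, lam)
        self.params_, self.loglik_path_ = em_estimate(
            vectors, init, tol=self.tol, max_iter=self.max_iter,
            update_lambda=self.update_lambda,
        )
        self.n_iter_ = len(self.loglik_path_)
        w = _weights(vectors, self.params_)
        post = posterior_probability(w, self.params_.lam)
        scored = pd.DataFrame(pairs, columns=["id1", "id2"])
        scored["weight"] = w
        scored["posterior"] = post
        self.all_scored_pairs_ = scored.sort_values(
            ["posterior", "id1", "id2"], ascending=[False, True, True]
        ).reset_index(drop=True)
        kept = self.all_scored_pairs_[
            self.all_scored_pairs_["posterior"] >= self.threshold
        ].reset_index(drop=True)
        self.scored_pairs_ = kept
        links = list(zip(kept["id1"], kept["id2"]))
        self.partition_ = Partition.from_links(X["record_id"], links)
        self.labels_ = self.partition_.labels(list(X["record_id"]))
        return self


def probabilistic_match(df: pd.DataFrame, **kwargs) -> Partition:
    """Functional wrapper over :class:`FellegiSunterMatcher`."""
    return FellegiSunterMatcher(**kwargs).fit(df).partition_
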
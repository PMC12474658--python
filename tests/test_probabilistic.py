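"""Jaro-Winkler, comparison vectors, EM estimation and FS scoring."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import laolink as ll
from laolink.probabilistic import (
    ComparisonSpec,
    FieldComparison,
    candidate_pairs,
    compare_candidates,
    compare_pair,
    initial_parameters,
    posterior_probability,
)

from conftest import make_frame, normalized


# --------------------------------------------------------------------------
# An independent from-definition Jaro-Winkler used only as a test oracle.
# --------------------------------------------------------------------------

def oracle_jaro_winkler(s1: str, s2: str) -> float:
    if s1 == s2:
        return 1.0
    if not s1 or not s2:
        return 0.0
    window = max(max(len(s1), len(s2)) // 2 - 1, 0)
    taken = set()
    idx1, idx2 = [], []
    for i, ch in enumerate(s1):
        for j in range(max(0, i - window), min(len(s2), i + window + 1)):
            if j not in taken and s2[j] == ch:
                taken.add(j)
                idx1.append(i)
                idx2.append(j)
                break
    m = len(idx1)
    if m == 0:
        return 0.0
    seq1 = [s1[i] for i in idx1]
    seq2 = [s2[j] for j in sorted(idx2)]
    transpositions = sum(a != b for a, b in zip(seq1, seq2)) // 2
    jaro = (m / len(s1) + m / len(s2) + (m - transpositions) / m) / 3.0
    prefix = 0
    for a, b in zip(s1[:4], s2[:4]):
        if a != b:
            break
        prefix += 1
    return jaro + 0.1 * prefix * (1.0 - jaro)


class TestJaroWinkler:
    def test_identity(self):
        assert ll.jaro_winkler("SOUKSAN", "SOUKSAN") == 1.0

    def test_disjoint_alphabets(self):
        assert ll.jaro_winkler("ABC", "XYZ") == 0.0

    def test_martha_marhta_reference_value(self):
        assert ll.jaro_winkler("MARTHA", "MARHTA") == pytest.approx(0.9611, abs=1e-4)

    def test_symmetry(self):
        for a, b in [("SOUKSAN", "SUKSAN"), ("ສຸກສັນ", "ສູກສັນ"), ("AB", "BA")]:
            assert ll.jaro_winkler(a, b) == ll.jaro_winkler(b, a)

    def test_operates_on_lao_code_points(self):
        sim = ll.jaro_winkler("ສຸກສັນ", "ສູກສັນ")
        assert 0.0 < sim < 1.0

    def test_missing_input_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            ll.jaro_winkler(None, "ABC")

    def test_agrees_with_independent_oracle_on_random_pairs(self):
        rng = np.random.default_rng(12345)
        alphabet = list("ABCDEFG") + list("ສຸູກັນອຍ")
        for _ in range(1000):
            n1, n2 = rng.integers(0, 12, size=2)
            s1 = "".join(rng.choice(alphabet, size=n1))
            s2 = "".join(rng.choice(alphabet, size=n2))
            assert ll.jaro_winkler(s1, s2) == pytest.approx(
                oracle_jaro_winkler(s1, s2), abs=1e-12
            )


class TestComparisonVectors:
    spec = ComparisonSpec.default()

    def _rows(self):
        df = make_frame([
            {"name": "Souksan", "dob": "01/01/2020", "sex": "M", "village": "A",
             "father_name": "Keo", "mother_name": "Noy"},
            {"name": "Souksan", "dob": "01/01/2020", "sex": "M", "village": "A",
             "father_name": "Keo", "mother_name": "Noy"},
            {"name": "Souksan", "dob": "01/01/2020", "sex": "M", "village": "A",
             "father_name": "Keo", "mother_name": None},
        ])
        norm = normalized(df)
        return norm.set_index("record_id", drop=False)

    def test_identical_records_hit_top_level_everywhere(self):
        rows = self._rows()
        vec = compare_pair(rows.loc["r000"], rows.loc["r001"], self.spec)
        assert vec == (0, 0, 0, 0)

    def test_threshold_levels(self):
        fc = FieldComparison("name", (0.88, 0.70))
        assert fc.level("SOUKSAN", "SOUKSAN") == 0
        # one deletion: JW("SOUKSAN","SUKSAN") is in [0.88, 1)
        assert fc.level("SOUKSAN", "SUKSAN") == 1
        assert fc.level("SOUKSAN", "XXXXXXX") == 3

    def test_missing_side_gives_na_level(self):
        rows = self._rows()
        vec = compare_pair(rows.loc["r000"], rows.loc["r002"], self.spec)
        assert vec[2] == -1  # mother's name missing on one side

    def test_thresholds_must_strictly_decrease(self):
        with pytest.raises(ValueError):
            FieldComparison("name", (0.70, 0.88))


class TestEstimateLambda:
    def _df(self):
        rows = [{"name": n, "dob": "01/01/2020", "sex": s, "village": "A",
                 "father_name": f, "mother_name": m}
                for n, s, f, m in [
                    ("Keo", "M", "Tui", "Noy"),
                    ("Keo", "M", "Tui", "Noy"),   # the only proxy match pair
                    ("Lae", "F", "Deng", "Mai"),
                    ("Mone", "M", "Sing", "Dara"),
                    ("Oudom", "F", "Vixay", "Chan"),
                ]]
        return normalized(make_frame(rows))

    def test_recall_adjusted_arithmetic(self):
        # 1 proxy pair among C(5,2)=10 comparable pairs at r=0.5 -> 0.2
        lam = ll.estimate_lambda(self._df(), recall=0.5)
        assert lam == pytest.approx(0.2)

    def test_recall_one_gives_raw_proxy_rate(self):
        lam = ll.estimate_lambda(self._df(), recall=1.0)
        assert lam == pytest.approx(0.1)

    def test_no_comparable_pairs_is_an_error(self):
        df = normalized(make_frame([
            {"name": "Keo", "dob": "01/01/2020", "sex": "M", "village": "A"},
            {"name": "Noy", "dob": "02/02/2020", "sex": "F", "village": "B"},
        ]))
        with pytest.raises(ValueError, match="no comparable pairs"):
            ll.estimate_lambda(df)

    def test_close_to_true_comparable_pair_match_rate(self, small_registry):
        norm, truth = small_registry
        pairs = candidate_pairs(norm)
        cluster = {rid: truth.partition.cluster_of(rid) for rid in norm["record_id"]}
        true_rate = sum(cluster[a] == cluster[b] for a, b in pairs) / len(pairs)
        lam = ll.estimate_lambda(norm)
        assert abs(lam - true_rate) / true_rate < 0.30


def _simulate_vectors(rng, n, lam, m_params, u_params):
    """Draw comparison vectors from known FS parameters (the oracle)."""
    is_match = rng.random(n) < lam
    cols = []
    for mj, uj in zip(m_params, u_params):
        levels = np.where(
            is_match,
            rng.choice(len(mj), size=n, p=mj),
            rng.choice(len(uj), size=n, p=uj),
        )
        cols.append(levels)
    return np.stack(cols, axis=1).astype(np.int8), is_match


M_TRUE = [np.array([0.92, 0.05, 0.03]),
          np.array([0.85, 0.10, 0.05]),
          np.array([0.80, 0.12, 0.08])]
U_TRUE = [np.array([0.05, 0.15, 0.80]),
          np.array([0.10, 0.20, 0.70]),
          np.array([0.08, 0.12, 0.80])]


class TestEM:
    def _spec(self):
        return ComparisonSpec(tuple(FieldComparison(f, (0.85,)) for f in
                                    ("name", "father_name", "mother_name")))

    def test_parameter_recovery_within_tolerance(self):
        rng = np.random.default_rng(2024)
        vectors, _ = _simulate_vectors(rng, 20000, 0.1, M_TRUE, U_TRUE)
        init = initial_parameters(vectors, self._spec(), lam=0.1)
        params, path = ll.em_estimate(vectors, init)
        for mj, mt in zip(params.m, M_TRUE):
            assert np.abs(mj - mt).max() < 0.03
        for uj, ut in zip(params.u, U_TRUE):
            assert np.abs(uj - ut).max() < 0.03
        assert all(b - a > -1e-7 for a, b in zip(path, path[1:]))

    def test_init_at_truth_is_near_fixed_point(self):
        # a dataset whose empirical distribution equals the model mixture
        # makes the truth an (almost exact) stationary point of EM
        lam = 0.1
        combos = np.array(list(itertools.product(range(3), repeat=3)), dtype=np.int8)
        pm = np.ones(len(combos))
        pu = np.ones(len(combos))
        for j in range(3):
            pm *= M_TRUE[j][combos[:, j]]
            pu *= U_TRUE[j][combos[:, j]]
        weights = lam * pm + (1 - lam) * pu
        counts = np.round(weights / weights.sum() * 200000).astype(int)
        vectors = np.repeat(combos, counts, axis=0)
        init = ll.LinkageParameters(
            ["name", "father_name", "mother_name"],
            [a.copy() for a in M_TRUE], [a.copy() for a in U_TRUE], lam,
        )
        params, path = ll.em_estimate(vectors, init)
        for est, true in zip(params.m + params.u, M_TRUE + U_TRUE):
            assert np.abs(est - true).max() < 0.01
        assert all(b - a > -1e-7 for a, b in zip(path, path[1:]))

    def test_infinite_tolerance_stops_after_one_iteration(self):
        rng = np.random.default_rng(1)
        vectors, _ = _simulate_vectors(rng, 200, 0.1, M_TRUE, U_TRUE)
        init = initial_parameters(vectors, self._spec(), lam=0.1)
        _, path = ll.em_estimate(vectors, init, tol=math.inf)
        assert len(path) == 2  # one M-step, then the stopping check fires

    def test_identical_vectors_unidentifiable(self):
        vectors = np.zeros((50, 3), dtype=np.int8)
        init = initial_parameters(vectors, self._spec(), lam=0.1)
        with pytest.raises(ValueError, match="unidentifiable"):
            ll.em_estimate(vectors, init)

    def test_probabilities_stay_clamped(self):
        rng = np.random.default_rng(5)
        # extreme truth drives estimates toward the boundary
        m = [np.array([0.999999, 1e-6 / 2, 1e-6 / 2])]
        u = [np.array([1e-6, 0.4, 0.599999])]
        spec = ComparisonSpec((FieldComparison("name", (0.85,)),))
        vectors, _ = _simulate_vectors(rng, 5000, 0.2, m, u)
        init = initial_parameters(vectors, spec, lam=0.2)
        params, _ = ll.em_estimate(vectors, init)
        for arr in params.m + params.u:
            assert arr.min() >= 1e-6 - 1e-12
            assert arr.max() <= 1 - 1e-6 + 1e-12
            assert arr.sum() == pytest.approx(1.0, abs=1e-9)


class TestMatchWeight:
    def _params(self):
        return ll.LinkageParameters(
            ["name", "sex"],
            [np.array([0.9, 0.1]), np.array([0.8, 0.2])],
            [np.array([0.1, 0.9]), np.array([0.5, 0.5])],
            0.2,
        )

    def test_single_field_closed_form(self):
        p = ll.LinkageParameters(["name"], [np.array([0.9, 0.1])],
                                 [np.array([0.1, 0.9])], 0.2)
        assert ll.match_weight((0,), p) == pytest.approx(math.log2(9))

    def test_all_na_gives_zero_weight(self):
        assert ll.match_weight((-1, -1), self._params()) == 0.0

    def test_additivity_over_independent_fields(self):
        p = self._params()
        w_joint = ll.match_weight((0, 1), p)
        w_name = ll.match_weight((0, -1), p)
        w_sex = ll.match_weight((-1, 1), p)
        assert w_joint == pytest.approx(w_name + w_sex)

    def test_posterior_matches_bayes_factor_identity(self):
        lam, w = 0.2, 3.0
        bf = 2.0 ** w
        expected = lam * bf / (lam * bf + (1 - lam))
        assert posterior_probability(w, lam) == pytest.approx(expected)

    def test_weight_symmetry_under_pair_reversal(self, small_registry):
        norm, _ = small_registry
        spec = ComparisonSpec.default()
        params = initial_parameters(np.zeros((2, 4), dtype=np.int8) - 1, spec, 0.1)
        rows = norm.head(30).set_index("record_id", drop=False)
        ids = list(rows["record_id"])
        for a, b in itertools.combinations(ids[:12], 2):
            va = compare_pair(rows.loc[a], rows.loc[b], spec)
            vb = compare_pair(rows.loc[b], rows.loc[a], spec)
            assert va == vb


class TestPredictPairs:
    def _setup(self):
        df = make_frame([
            {"name": "Keo", "dob": "01/01/2020", "sex": "M", "village": "A",
             "father_name": "Tui", "mother_name": "Noy"},
            {"name": "Keo", "dob": "01/01/2020", "sex": "M", "village": "A",
             "father_name": "Tui", "mother_name": "Noy"},
            {"name": "Lae", "dob": "01/01/2020", "sex": "F", "village": "A",
             "father_name": "Deng", "mother_name": "Mai"},
        ])
        norm = normalized(df)
        spec = ComparisonSpec.default()
        vectors = compare_candidates(norm, candidate_pairs(norm), spec)
        params = initial_parameters(vectors, spec, lam=0.3)
        return norm, spec, params

    def test_threshold_zero_returns_all_candidate_pairs(self):
        norm, spec, params = self._setup()
        out = ll.predict_pairs(norm, spec, params, threshold=0.0)
        assert len(out) == 3

    def test_threshold_one_returns_no_clamped_pair(self):
        norm, spec, params = self._setup()
        out = ll.predict_pairs(norm, spec, params, threshold=1.0)
        assert len(out) == 0

    def test_blocked_scoring_equals_brute_force_on_small_input(self, small_registry):
        norm, _ = small_registry
        sub = norm.head(60)
        rows = sub.set_index("record_id", drop=False)
        keys = ("dob", "village")
        brute = sorted(
            (a, b)
            for a, b in itertools.combinations(sorted(sub["record_id"]), 2)
            if all(
                pd.notna(rows.loc[a, k]) and pd.notna(rows.loc[b, k])
                and rows.loc[a, k] == rows.loc[b, k]
                for k in keys
            )
        )
        assert candidate_pairs(sub, keys) == brute

    def test_graded_similarity_recovers_more_true_pairs_than_exact_only(self, small_registry):
        norm, truth = small_registry
        cluster = {rid: truth.partition.cluster_of(rid) for rid in norm["record_id"]}
        pairs = candidate_pairs(norm)
        true_pairs = {(a, b) for a, b in pairs if cluster[a] == cluster[b]}

        def pair_recall(jw_levels):
            # the prior is pinned so the two runs differ only in the
            # comparison levels
            est = ll.FellegiSunterMatcher(jw_levels=jw_levels, lam=0.3).fit(norm)
            got = set(zip(est.scored_pairs_["id1"], est.scored_pairs_["id2"]))
            return len(got & true_pairs) / len(true_pairs)

        assert pair_recall((0.88, 0.70)) > pair_recall(())


class TestFellegiSunterMatcher:
    def test_transitive_closure_of_predictions(self):
        part = ll.Partition.from_links(["a", "b", "c", "d"],
                                       [("a", "b"), ("b", "c")])
        assert part.cluster_of("a") == part.cluster_of("c")
        assert part.cluster_of("d") not in (part.cluster_of("a"),)

    def test_record_level_recall_on_synthetic_registry(self, paper_scale_results):
        res = paper_scale_results
        m = ll.metrics(ll.record_confusion(res["prob"].partition_,
                                           res["truth"].partition))
        assert m.recall >= 0.85

    def test_no_pairs_above_threshold_gives_all_singletons(self):
        df = make_frame([
            {"name": "Keo", "dob": "01/01/2020", "sex": "M", "village": "A",
             "father_name": "Tui", "mother_name": "Noy"},
            {"name": "Lae", "dob": "01/01/2020", "sex": "F", "village": "A",
             "father_name": "Deng", "mother_name": "Mai"},
            {"name": "Mone", "dob": "01/01/2020", "sex": "M", "village": "A",
             "father_name": "Sing", "mother_name": "Dara"},
        ])
        norm = normalized(df)
        est = ll.FellegiSunterMatcher(lam=0.01, threshold=0.999999).fit(norm)
        assert est.partition_.linked_records() == set()
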
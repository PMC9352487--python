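"""Grey-clustering core: membership functions, coefficients, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from greypsy.grey import (
    ClusteringResult,
    DataError,
    EvaluationError,
    GreyClass,
    GreyClusterEvaluator,
    PatientIndicators,
    ScoreClass,
    assign_class,
    clustering_coefficients,
    evaluate_cohort,
    overall_score,
    reevaluate,
    score_class,
    whitening_weight,
)
from greypsy.indices import IndexDefinition, IndexSystem


def interp_weight(x, centers, k):
    """Independent piecewise-linear oracle built on np.interp."""
    l1, l2, l3 = centers
    if k == 1:
        return float(np.interp(x, [l1, l2], [1.0, 0.0]))
    if k == 2:
        return float(np.interp(x, [l1, l2, l3], [0.0, 1.0, 0.0]))
    return float(np.interp(x, [l2, l3], [0.0, 1.0]))


def naive_coefficients(observations, system):
    """Brute-force double-loop recomputation of the clustering coefficients."""
    weights = [ix.full_score for ix in system]
    total = sum(weights)
    sigma = []
    for k in (1, 2, 3):
        s = 0.0
        for x, ix in zip(observations, system):
            s += interp_weight(x, ix.centers, k) * ix.full_score / total
        sigma.append(s)
    return sigma


boundaries_st = st.tuples(
    st.floats(-50, 50),
    st.floats(0.5, 30),
    st.floats(0.5, 30),
    st.floats(0.5, 30),
).map(lambda t: (t[0], t[0] + t[1], t[0] + t[1] + t[2], t[0] + t[1] + t[2] + t[3]))


class TestWhiteningWeight:
    @pytest.mark.parametrize(
        "x, k, expected",
        [
            (15, 2, 1.0),   # membership is exactly 1 at the class's own center
            (5, 2, 0.0),
            (25, 2, 0.0),
            (10, 1, 0.5),
            (10, 2, 0.5),
            (10, 3, 0.0),
            (0, 1, 1.0),    # shoulder: constant 1 below the good center
            (30, 3, 1.0),   # shoulder: constant 1 above the morbid center
            (20, 2, 0.5),
            (20, 3, 0.5),
        ],
    )
    def test_reference_values_on_centers_5_15_25(self, x, k, expected):
        assert whitening_weight(x, (5, 15, 25), k) == pytest.approx(expected)

    @given(b=boundaries_st, x=st.floats(-60, 120))
    @settings(max_examples=200, derandomize=True)
    def test_matches_independent_interp_oracle(self, b, x):
        centers = tuple((b[k] + b[k + 1]) / 2 for k in range(3))
        for k in (1, 2, 3):
            assert whitening_weight(x, centers, k) == pytest.approx(
                interp_weight(x, centers, k), abs=1e-9
            )

    @given(b=boundaries_st, u=st.floats(0, 1))
    @settings(max_examples=200, derandomize=True)
    def test_partition_of_unity_on_measurement_range(self, b, u):
        centers = tuple((b[k] + b[k + 1]) / 2 for k in range(3))
        x = b[0] + u * (b[3] - b[0])
        total = sum(whitening_weight(x, centers, k) for k in (1, 2, 3))
        assert total == pytest.approx(1.0, abs=1e-9)

    @given(b=boundaries_st, u1=st.floats(0, 1), u2=st.floats(0, 1))
    @settings(max_examples=200, derandomize=True)
    def test_extreme_class_monotonicity(self, b, u1, u2):
        centers = tuple((b[k] + b[k + 1]) / 2 for k in range(3))
        lo, hi = sorted([b[0] + u * (b[3] - b[0]) for u in (u1, u2)])
        assert whitening_weight(hi, centers, 3) >= whitening_weight(lo, centers, 3)
        assert whitening_weight(hi, centers, 1) <= whitening_weight(lo, centers, 1)

    def test_peak_normalization_exact(self):
        centers = (3.0, 7.0, 25.0)
        for k, c in zip((1, 2, 3), centers):
            assert whitening_weight(c, centers, k) == 1.0

    def test_membership_bounded(self, rng):
        centers = (3.0, 7.0, 25.0)
        x = rng.uniform(-50, 80, size=200)
        for k in (1, 2, 3):
            w = whitening_weight(x, centers, k)
            assert np.all((w >= 0) & (w <= 1))


class TestClusteringCoefficients:
    def test_single_index_collapses_to_membership(self):
        system = IndexSystem((IndexDefinition("solo", 40, (8, 16, 24, 32)),))
        centers = system.indices[0].centers
        for x in (0.0, 10.0, 20.0, 27.0, 40.0):
            res = clustering_coefficients(PatientIndicators("p", (x,)), system)
            expected = [whitening_weight(x, centers, k) for k in (1, 2, 3)]
            assert res.coefficients == pytest.approx(expected, abs=1e-12)

    def test_all_observations_at_morbid_center_give_full_morbid(self, small_system):
        obs = tuple(ix.centers[2] for ix in small_system)
        res = clustering_coefficients(PatientIndicators("p", obs), small_system)
        assert res.coefficients == pytest.approx((0, 0, 1), abs=1e-12)
        assert res.assigned_class is GreyClass.MORBID

    def test_hand_computed_weighted_sum(self, small_system):
        # memberships tabulated by hand for observations (6, 15, 25):
        # index a (centers 6,10,14): x=6  -> f=(1, 0, 0)
        # index b (centers 9,15,21): x=15 -> f=(0, 1, 0)
        # index c (centers 15,25,35): x=25 -> f=(0, 0, ...) f2=1? x at center2 -> (0,1,0)
        # weights (0.2, 0.3, 0.5)
        res = clustering_coefficients(
            PatientIndicators("p", (6, 15, 25)), small_system
        )
        assert res.coefficients == pytest.approx((0.2, 0.8, 0.0), abs=1e-12)

    @given(
        u=st.tuples(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)),
    )
    @settings(max_examples=150, derandomize=True)
    def test_oracle_equivalence_normalization_and_bounds(self, u):
        system = IndexSystem((
            IndexDefinition("a", 20, (4, 8, 12, 16)),
            IndexDefinition("b", 30, (6, 12, 18, 24)),
            IndexDefinition("c", 50, (10, 20, 30, 40)),
        ))
        obs = tuple(ui * ix.full_score for ui, ix in zip(u, system))
        res = clustering_coefficients(PatientIndicators("p", obs), system)
        oracle = naive_coefficients(obs, system)
        assert res.coefficients == pytest.approx(oracle, abs=1e-12)
        assert sum(res.coefficients) == pytest.approx(1.0, abs=1e-9)
        assert all(0 <= c <= 1 for c in res.coefficients)

    def test_sigma_morbid_monotone_in_any_single_indicator(self, small_system, rng):
        base = tuple(0.4 * ix.full_score for ix in small_system)
        for j in range(3):
            xs = np.sort(rng.uniform(0, small_system.indices[j].full_score, 25))
            prev_morbid, prev_good = -np.inf, np.inf
            for x in xs:
                obs = list(base)
                obs[j] = x
                res = clustering_coefficients(PatientIndicators("p", tuple(obs)), small_system)
                assert res.coefficients[2] >= prev_morbid - 1e-12
                assert res.coefficients[0] <= prev_good + 1e-12
                prev_morbid, prev_good = res.coefficients[2], res.coefficients[0]

    def test_scale_equivariance_of_one_index(self, small_system):
        c = 7.5
        obs = (6.0, 14.0, 33.0)
        # weights are scale-free only if every full score scales together
        scaled_system = IndexSystem(tuple(
            IndexDefinition(ix.name, ix.full_score * c, tuple(b * c for b in ix.boundaries))
            for ix in small_system
        ))
        scaled_obs = tuple(o * c for o in obs)
        r1 = clustering_coefficients(PatientIndicators("p", obs), small_system)
        r2 = clustering_coefficients(PatientIndicators("p", scaled_obs), scaled_system)
        assert r1.coefficients == pytest.approx(r2.coefficients, abs=1e-12)

    def test_single_index_measurement_rescale_equivariance(self, small_system):
        # shrinking one index's measurement scale (boundaries and its
        # observation, full score unchanged so the weights stay put)
        # leaves every coefficient unchanged
        c = 0.5
        obs = (6.0, 14.0, 33.0)
        rescaled = IndexSystem((
            IndexDefinition("a", 20, tuple(b * c for b in (4, 8, 12, 16))),
            small_system.indices[1],
            small_system.indices[2],
        ))
        r1 = clustering_coefficients(PatientIndicators("p", obs), small_system)
        r2 = clustering_coefficients(
            PatientIndicators("p", (obs[0] * c, obs[1], obs[2])), rescaled
        )
        assert r1.coefficients == pytest.approx(r2.coefficients, abs=1e-12)

    def test_out_of_range_observation_names_index(self, small_system):
        with pytest.raises(DataError, match="patient 'p'"):
            clustering_coefficients(PatientIndicators("p", (25.0, 10.0, 10.0)), small_system)

    def test_missing_observation_names_patient_and_index(self, small_system):
        with pytest.raises(DataError, match="index"):
            PatientIndicators.from_mapping("p7", {"a": 1, "b": 2}, small_system)


class TestAssignClass:
    @pytest.mark.parametrize(
        "coeffs, expected",
        [
            ((0.2, 0.3, 0.5), GreyClass.MORBID),
            ((0.5, 0.5, 0.0), GreyClass.ORDINARY),  # tie resolves to severe
            ((1 / 3, 1 / 3, 1 / 3), GreyClass.MORBID),
            ((0.9, 0.1, 0.0), GreyClass.GOOD),
        ],
    )
    def test_argmax_with_severity_tie_break(self, coeffs, expected):
        assert assign_class(coeffs) is expected

    def test_degenerate_vectors_rejected(self):
        with pytest.raises(EvaluationError):
            assign_class((0.0, 0.0, 0.0))
        with pytest.raises(EvaluationError):
            assign_class((0.1, -0.2, 0.5))
        with pytest.raises(EvaluationError):
            assign_class((0.1, np.nan, 0.5))


class TestOverallScore:
    def test_sum_and_golden_bifurcation(self):
        p = PatientIndicators("p", (40, 35, 30))
        assert overall_score(p) == 105
        assert score_class(105) is ScoreClass.MORBID_LEANING
        assert score_class(95) is ScoreClass.ORDINARY_LEANING
        assert score_class(100) is ScoreClass.BOUNDARY
        assert overall_score(PatientIndicators("z", (0, 0, 0))) == 0

    def test_negative_score_rejected(self):
        with pytest.raises(DataError):
            score_class(-1)

    def test_matches_column_sum_oracle(self, system, rng):
        X = rng.uniform(0, 1, (20, 6)) * system.full_scores
        ev = GreyClusterEvaluator(system=system).fit()
        scores = ev.overall_scores(X)
        assert scores == pytest.approx(X.T.sum(axis=0))


class TestEvaluateCohort:
    def test_empty_cohort(self, small_system):
        assert evaluate_cohort([], small_system) == []

    def test_composition_and_order_preserved(self, small_system, rng):
        patients = [
            PatientIndicators(
                f"p{i}",
                tuple(rng.uniform(0, ix.full_score) for ix in small_system),
            )
            for i in range(10)
        ]
        results = evaluate_cohort(patients, small_system)
        assert [r.patient_id for r in results] == [p.patient_id for p in patients]
        # brute-force per-patient loop oracle
        for p, r in zip(patients, results):
            oracle = naive_coefficients(p.observations, small_system)
            assert r.coefficients == pytest.approx(oracle, abs=1e-12)
            assert r.assigned_class is assign_class(oracle)

    def test_deterministic(self, small_system, rng):
        patients = [
            PatientIndicators("q", (5.0, 10.0, 20.0)),
        ]
        r1 = evaluate_cohort(patients, small_system)
        r2 = evaluate_cohort(patients, small_system)
        assert r1 == r2


class TestReevaluate:
    def _result(self, pid, coeffs, score=90.0):
        return ClusteringResult(
            patient_id=pid,
            coefficients=coeffs,
            assigned_class=assign_class(coeffs),
            overall_score=score,
            score_class=score_class(score),
        )

    def test_identical_before_after_is_null(self):
        res = [self._result("a", (0.2, 0.3, 0.5)), self._result("b", (0.6, 0.3, 0.1))]
        reev = reevaluate(res, res)
        assert np.all(reev.deltas == 0)
        assert all(pre is post for pre, post in reev.transitions)

    def test_transition_and_delta(self):
        before = [self._result("a", (0.1, 0.2, 0.7))]
        after = [self._result("a", (0.6, 0.3, 0.1))]
        reev = reevaluate(before, after)
        assert reev.transitions[0] == (GreyClass.MORBID, GreyClass.GOOD)
        assert reev.deltas[0, 0] == pytest.approx(0.5)
        assert reev.mean_delta_good_by_baseline[GreyClass.MORBID] == pytest.approx(0.5)

    def test_unmatched_identifiers_listed(self):
        before = [self._result("a", (0.1, 0.2, 0.7))]
        after = [self._result("b", (0.6, 0.3, 0.1))]
        with pytest.raises(DataError, match="a.*b"):
            reevaluate(before, after)


class TestSklearnInterface:
    def test_clone_and_get_params(self, small_system):
        ev = GreyClusterEvaluator(system=small_system, score_threshold=50.0)
        cloned = clone(ev)
        assert cloned.get_params()["score_threshold"] == 50.0
        fitted = cloned.fit()
        assert fitted.n_features_in_ == 3
        assert fitted.weights_ == pytest.approx([0.2, 0.3, 0.5])

    def test_transform_equals_predict_proba(self, small_system, rng):
        ev = GreyClusterEvaluator(system=small_system).fit()
        X = rng.uniform(0, 1, (5, 3)) * small_system.full_scores
        assert np.array_equal(ev.transform(X), ev.predict_proba(X))

    def test_wrong_column_count_rejected(self, small_system):
        ev = GreyClusterEvaluator(system=small_system).fit()
        with pytest.raises(DataError, match="3 indicator columns"):
            ev.predict(np.zeros((2, 4)))
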
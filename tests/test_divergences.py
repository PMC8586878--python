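import numpy as np
import pytest

from sparsekm import (
    DegenerateInputError,
    MatrixContext,
    NormalizedView,
    PriorConfig,
    distance,
    point_to_centers_costs,
    total_cost,
    validate,
)
from sparsekm.divergences import Measure, entry_count, reset_entry_count

from conftest import ALL_MEASURES, random_sparse_rows
from oracles import dense_distance, dense_row_to_center

PROB = ["KLD", "JSD", "BATMET"]


class TestPointExamples:
    def test_sqe_hand_computed(self):
        assert distance(np.array([1.0, 2, 0]), np.array([3.0, 4, 0]), "SQE") == 8.0

    @pytest.mark.parametrize("measure", PROB)
    def test_identity_of_indiscernibles(self, measure, prior01, rng):
        x = np.zeros(50)
        x[rng.choice(50, 8, replace=False)] = rng.integers(1, 10, 8)
        assert distance(x, x, measure, prior01) == pytest.approx(0.0, abs=1e-12)

    def test_jsd_disjoint_supports_is_log2(self):
        x = np.array([2.0, 3.0, 0.0, 0.0])
        y = np.array([0.0, 0.0, 1.0, 4.0])
        assert distance(x, y, "JSD", None) == pytest.approx(np.log(2), rel=1e-12)

    def test_measure_names_case_insensitive(self):
        x, y = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert distance(x, y, "sqe") == distance(x, y, "SQE") == 2.0
        with pytest.raises(ValueError):
            distance(x, y, "NOTAMEASURE")

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            distance(np.ones(3), np.ones(4), "SQE")

    def test_zero_sum_row_without_prior_raises(self):
        z = np.zeros(5)
        x = np.array([1.0, 0, 0, 0, 0])
        for measure in PROB:
            with pytest.raises(DegenerateInputError):
                distance(z, x, measure, None)
        assert distance(z, x, "SQE") == 1.0  # SQE defined on raw values


class TestLazyDenseEquivalence:
    """The module's central contract: the O(nnz) lazy path equals full
    densified-vector evaluation of the divergence formulas."""

    @pytest.mark.parametrize("measure", ALL_MEASURES)
    @pytest.mark.parametrize("beta", [0.01, 0.1, 1.0])
    @pytest.mark.parametrize("d", [10, 1000])
    def test_random_sparse_pairs(self, measure, beta, d, rng):
        prior = PriorConfig(beta)
        rows = random_sparse_rows(40, d, min(8, d // 2), rng)
        m = validate(rows)
        for t in range(20):
            i, j = rng.integers(0, 40, size=2)
            lazy = distance((m, int(i)), (m, int(j)), measure, prior)
            ref = dense_distance(rows[i], rows[j], measure, beta)
            assert lazy == pytest.approx(ref, rel=1e-10, abs=1e-12)

    @pytest.mark.parametrize("measure", ALL_MEASURES)
    def test_no_prior_pairs(self, measure, rng):
        rows = random_sparse_rows(10, 50, 10, rng) + 0.0
        rows[:, 0] += 1  # guarantee positive sums
        m = validate(rows)
        lazy = distance((m, 0), (m, 1), measure, None)
        ref = dense_distance(rows[0], rows[1], measure, 0.0)
        assert lazy == pytest.approx(ref, rel=1e-10, abs=1e-12)


class TestNormalizedView:
    def test_sums_to_one(self, rng):
        m = validate(random_sparse_rows(5, 300, 12, rng))
        for i in range(5):
            v = NormalizedView.of(m, i, PriorConfig(0.01))
            total = v.support_probs.sum() + (300 - len(v.idx)) * v.baseline
            assert total == pytest.approx(1.0, abs=1e-12)
            assert v.densify().sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_row_is_uniform_under_prior(self):
        m = validate(np.zeros((1, 8)))
        v = NormalizedView.of(m, 0, PriorConfig(1.0))
        assert np.allclose(v.densify(), 1.0 / 8)

    def test_all_zero_row_without_prior_raises(self):
        m = validate(np.zeros((1, 8)))
        with pytest.raises(DegenerateInputError):
            NormalizedView.of(m, 0, None).densify()


class TestBoundsAndSymmetry:
    @pytest.mark.parametrize("measure", ALL_MEASURES)
    def test_nonnegative_and_bounded(self, measure, prior01, rng):
        rows = random_sparse_rows(30, 80, 10, rng)
        m = validate(rows)
        for _ in range(50):
            i, j = rng.integers(0, 30, size=2)
            v = distance((m, int(i)), (m, int(j)), measure, prior01)
            assert v >= 0.0
            if measure == "JSD":
                assert v <= np.log(2) + 1e-12
            if measure == "BATMET":
                assert v <= 1.0 + 1e-12

    @pytest.mark.parametrize("measure", ["SQE", "JSD", "BATMET", "COS"])
    def test_symmetric_measures(self, measure, prior01, rng):
        rows = random_sparse_rows(10, 60, 9, rng)
        m = validate(rows)
        for _ in range(10):
            i, j = rng.integers(0, 10, size=2)
            assert distance((m, int(i)), (m, int(j)), measure, prior01) == (
                pytest.approx(distance((m, int(j)), (m, int(i)), measure, prior01),
                              rel=1e-12, abs=1e-12)
            )

    def test_kld_is_asymmetric(self, prior01, rng):
        rows = random_sparse_rows(10, 60, 9, rng)
        m = validate(rows)
        diffs = [
            abs(distance((m, i), (m, j), "KLD", prior01)
                - distance((m, j), (m, i), "KLD", prior01))
            for i in range(5) for j in range(5, 10)
        ]
        assert max(diffs) > 1e-6

    @pytest.mark.parametrize("measure", ["BATMET", "JSD"])
    def test_metric_triangle_inequality(self, measure, prior01, rng):
        """BATMET is a metric; sqrt(JSD) is a metric. Spot-check triples."""
        rows = random_sparse_rows(30, 40, 8, rng)
        m = validate(rows)
        trips = rng.integers(0, 30, size=(2000, 3))
        for a, b, c in trips[:200]:  # direct pairwise calls on a subset
            dab = distance((m, int(a)), (m, int(b)), measure, prior01)
            dbc = distance((m, int(b)), (m, int(c)), measure, prior01)
            dac = distance((m, int(a)), (m, int(c)), measure, prior01)
            if measure == "JSD":
                dab, dbc, dac = np.sqrt([dab, dbc, dac])
            assert dac <= dab + dbc + 1e-9


class TestPointToCenters:
    @pytest.mark.parametrize("measure", ALL_MEASURES)
    def test_matches_nested_loop_oracle(self, measure, prior01, rng):
        rows = random_sparse_rows(50, 30, 7, rng)
        m = validate(rows)
        k = 4
        if measure in PROB:
            centers = rng.random((k, 30)) + 1e-3
            centers /= centers.sum(axis=1, keepdims=True)
        elif measure == "COS":
            centers = rng.random((k, 30))
            centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        else:
            centers = rng.integers(0, 20, size=(k, 30)).astype(float)
        costs, argmin = point_to_centers_costs(m, centers, measure, prior01)
        for i in range(50):
            ref = [dense_row_to_center(rows[i], c, measure, 0.01) for c in centers]
            assert costs[i] == pytest.approx(min(ref), rel=1e-9, abs=1e-11)
            assert ref[argmin[i]] == pytest.approx(min(ref), rel=1e-9, abs=1e-11)

    def test_own_representation_costs_zero(self, prior01, small_mixture):
        m, _ = small_mixture
        ctx = MatrixContext(m, "KLD", prior01)
        c = ctx.row_vector(3)
        costs, argmin = point_to_centers_costs(m, c[None, :], "KLD", prior01, ctx=ctx)
        assert costs[3] == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_center_tie_breaks_low_index(self, prior01, rng):
        rows = random_sparse_rows(20, 25, 6, rng)
        m = validate(rows)
        c = rng.random(25) + 1e-3
        c /= c.sum()
        costs, argmin = point_to_centers_costs(m, np.stack([c, c]), "KLD", prior01)
        assert np.all(argmin == 0)

    def test_total_cost_sums(self, rng):
        costs = rng.random(40)
        assert total_cost(costs) == pytest.approx(costs.sum())
        assert total_cost(np.zeros(5)) == 0.0
        perm = rng.permutation(40)
        assert total_cost(costs[perm]) == pytest.approx(total_cost(costs))


class TestComplexityContract:
    def test_entries_touched_scale_with_nnz_not_d(self, prior01, rng):
        """At d = 1e5 with nnz = 10 per row, a pairwise distance touches a
        number of entries bounded by the supports, not the dimension."""
        d, nnz = 100_000, 10
        rows = random_sparse_rows(4, d, nnz, rng)
        m = validate(rows)
        for measure in ALL_MEASURES:
            reset_entry_count()
            distance((m, 0), (m, 1), measure, prior01)
            assert entry_count() < 100 * nnz

    def test_counter_accumulates_and_resets(self, prior01, rng):
        m = validate(random_sparse_rows(2, 50, 5, rng))
        reset_entry_count()
        distance((m, 0), (m, 1), "SQE")
        first = entry_count()
        assert first > 0
        distance((m, 0), (m, 1), "SQE")
        assert entry_count() == 2 * first
        reset_entry_count()
        assert entry_count() == 0
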
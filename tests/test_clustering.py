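import numpy as np
import pytest

from sparsekm import (
    MatrixContext,
    MixtureSpec,
    PriorConfig,
    adjusted_rand_index,
    center_set_from_centers,
    center_set_from_rows,
    generate,
    kmeanspp,
    lloyd,
    minibatch,
    point_to_centers_costs,
    validate,
)

from conftest import ALL_MEASURES
from oracles import dense_lloyd_trace, dense_prob


def toy_line_matrix():
    return validate(np.array([[0.0], [1.0], [9.0], [10.0]]))


class TestLloyd:
    def test_analytic_optimum_on_line(self):
        """Rows {0,1,9,10}, k=2, SQE: centers {0.5, 9.5}, total cost 1.0."""
        m = toy_line_matrix()
        seeds = center_set_from_centers(m, np.array([[0.0], [9.0]]), "SQE")
        res = lloyd(m, seeds, "SQE")
        assert sorted(res.center_set.centers.ravel().tolist()) == [0.5, 9.5]
        assert res.final_cost == 1.0
        assert res.converged

    def test_optimal_centers_converge_in_one_iteration(self):
        m = toy_line_matrix()
        seeds = center_set_from_centers(m, np.array([[0.5], [9.5]]), "SQE")
        res = lloyd(m, seeds, "SQE")
        assert res.n_iter == 1
        assert res.trace[0] == res.trace[1] == 1.0

    def test_max_iter_zero_returns_seeds(self, small_mixture, prior01):
        m, _ = small_mixture
        seeds = kmeanspp(m, 3, "KLD", prior01, rng=0)
        res = lloyd(m, seeds, "KLD", prior01, max_iter=0)
        assert np.array_equal(res.center_set.centers, seeds.centers)
        assert res.n_iter == 0 and not res.converged

    @pytest.mark.parametrize("measure", ["SQE", "KLD"])
    def test_bregman_cost_trace_nonincreasing(self, measure, prior01):
        """Lloyd monotonicity holds for Bregman measures on fuzzed inputs."""
        for seed in range(5):
            m, _ = generate(MixtureSpec(
                n_per_cluster=25, n_cols=40, k_true=3, alpha=0.5, seed=seed,
                total_sigma=0.4,
            ))
            seeds = kmeanspp(m, 3, measure, prior01, rng=seed)
            res = lloyd(m, seeds, measure, prior01, tol=0.0, max_iter=15)
            assert all(a >= b - 1e-8 * max(a, 1.0)
                       for a, b in zip(res.trace, res.trace[1:]))

    @pytest.mark.parametrize("measure", ALL_MEASURES)
    def test_termination_is_assignment_fixed_point(self, measure, prior01,
                                                   small_mixture):
        m, _ = small_mixture
        seeds = kmeanspp(m, 3, measure, prior01, rng=2)
        res = lloyd(m, seeds, measure, prior01)
        costs, assign = point_to_centers_costs(
            m, res.center_set.centers, measure, prior01
        )
        assert np.array_equal(assign, res.center_set.assignments)

    def test_kld_matches_dense_reference(self, prior01):
        """20 fixed-point-free iterations agree with an independent dense
        re-implementation using identical seeding and update rules."""
        m, _ = generate(MixtureSpec(
            n_per_cluster=20, n_cols=50, k_true=5, alpha=0.3, seed=13
        ))
        ctx = MatrixContext(m, "KLD", prior01)
        seeds = center_set_from_rows(m, [0, 25, 50, 75, 95], "KLD", prior01, ctx=ctx)
        res = lloyd(m, seeds, "KLD", prior01, tol=0.0, max_iter=20, ctx=ctx)
        ref = dense_lloyd_trace(m.to_dense(), seeds.centers, "KLD", 0.01, 20)
        # the sparse path may stop early once the cost is exactly stationary
        assert len(res.trace) >= 3
        assert np.allclose(res.trace, ref[: len(res.trace)], rtol=1e-8)

    def test_empty_cluster_reseeded_deterministically(self):
        # a center far outside the data attracts nothing and must be reseeded
        m = validate(np.array([[0.0], [1.0], [2.0], [50.0]]))
        seeds = center_set_from_centers(m, np.array([[1.0], [1000.0]]), "SQE")
        res = lloyd(m, seeds, "SQE", max_iter=5)
        # after reseeding, the outlier row gets its own cluster: cost is optimal
        assert res.final_cost == pytest.approx(2.0)  # var of {0,1,2} around 1


class TestMiniBatch:
    @pytest.mark.parametrize("measure", ALL_MEASURES)
    def test_full_batch_epoch_equals_one_lloyd_update(self, measure, prior01,
                                                      small_mixture):
        m, _ = small_mixture
        seeds = kmeanspp(m, 3, measure, prior01, rng=4)
        mb = minibatch(m, seeds, measure, prior01, batch_size=m.n_rows,
                       max_epochs=1, rng=0)
        ll = lloyd(m, seeds, measure, prior01, max_iter=1, tol=0.0)
        assert np.allclose(mb.center_set.centers, ll.center_set.centers,
                           rtol=1e-10, atol=1e-12)

    def test_k1_reaches_global_mean_after_full_epoch(self, prior01):
        m, _ = generate(MixtureSpec(n_per_cluster=40, n_cols=30, k_true=1, seed=2))
        seeds = center_set_from_rows(m, [0], "KLD", prior01)
        mb = minibatch(m, seeds, "KLD", prior01, batch_size=m.n_rows,
                       max_epochs=1, rng=1)
        expected = np.stack(
            [dense_prob(r, 0.01) for r in m.to_dense()]
        ).mean(axis=0)
        assert np.allclose(mb.center_set.centers[0], expected, rtol=1e-10)

    def test_batch_size_clamped_with_warning(self, small_mixture, prior01):
        m, _ = small_mixture
        seeds = kmeanspp(m, 2, "SQE", rng=0)
        with pytest.warns(UserWarning):
            minibatch(m, seeds, "SQE", batch_size=10 * m.n_rows, max_epochs=1,
                      rng=0)

    def test_cost_trend_nonincreasing_in_median(self, prior01):
        """Median-over-seeds full-data cost does not increase across epochs."""
        m, _ = generate(MixtureSpec(
            n_per_cluster=60, n_cols=60, k_true=4, alpha=0.1, seed=31
        ))
        traces = []
        for seed in range(20):
            seeds = kmeanspp(m, 4, "SQE", rng=seed)
            res = minibatch(m, seeds, "SQE", batch_size=48, max_epochs=5,
                            rng=seed, tol=0.0)
            traces.append(res.trace)
        med = np.median(np.array(traces), axis=0)
        assert all(a >= b - 1e-8 * max(a, 1.0) for a, b in zip(med, med[1:]))

    @pytest.mark.parametrize("measure", ALL_MEASURES)
    def test_close_to_lloyd_on_separated_mixture(self, measure, prior01):
        m, labels = generate(MixtureSpec(
            n_per_cluster=80, n_cols=100, k_true=5, alpha=0.05, seed=8
        ))
        seeds = kmeanspp(m, 5, measure, prior01, rng=3)
        mb = minibatch(m, seeds, measure, prior01, batch_size=64, max_epochs=10,
                       rng=3)
        ll = lloyd(m, seeds, measure, prior01)
        assert mb.final_cost <= 1.1 * ll.final_cost
        assert adjusted_rand_index(mb.center_set.assignments, labels) >= 0.9

    def test_invalid_parameters(self, small_mixture):
        m, _ = small_mixture
        seeds = kmeanspp(m, 2, "SQE", rng=0)
        with pytest.raises(ValueError):
            minibatch(m, seeds, "SQE", batch_size=0)
        with pytest.raises(ValueError):
            minibatch(m, seeds, "SQE", max_epochs=-1)
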
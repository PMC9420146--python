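import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from instarfit import (
    GaussianComponent,
    MixtureModel,
    assign_instars,
    component_density,
    fit_mixture,
    fit_mixture_histogram,
    intersection_boundaries,
    make_histogram,
    select_components,
)
from instarfit.mixture import BoundaryError, _crossing


def grid_crossing(c1, c2, step=0.01):
    """Independent oracle: dense grid search for the weighted-density
    crossing between the two component means."""
    grid = np.arange(c1.mean, c2.mean, step)
    diff = component_density(c1, grid) - component_density(c2, grid)
    sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    assert sign_change.size >= 1
    i = sign_change[0]
    return 0.5 * (grid[i] + grid[i + 1])


class TestComponentDensity:
    @pytest.mark.parametrize(
        "weight,mean,sd,x,expected",
        [
            (1.0, 0.0, 1.0, 0.0, 0.3989423),
            (0.5, 0.0, 1.0, 0.0, 0.1994711),
            (1.0, 365.0, 19.35, 365.0, 1.0 / (19.35 * np.sqrt(2 * np.pi))),
        ],
    )
    def test_closed_form(self, weight, mean, sd, x, expected):
        c = GaussianComponent(weight, mean, sd)
        assert component_density(c, x) == pytest.approx(expected, abs=1e-7)

    def test_integrates_to_weight(self):
        c = GaussianComponent(0.3, 450.0, 20.0)
        grid = np.linspace(300.0, 600.0, 20001)
        assert np.trapezoid(component_density(c, grid), grid) == pytest.approx(0.3, abs=1e-6)


class TestFitMixture:
    def test_k1_matches_sample_moments(self, two_cluster_values):
        m = fit_mixture(two_cluster_values, k=1, seed=0)
        assert m.means[0] == pytest.approx(two_cluster_values.mean(), abs=1e-8)
        assert m.sds[0] == pytest.approx(two_cluster_values.std(ddof=0), abs=1e-6)
        assert m.weights[0] == pytest.approx(1.0)

    def test_two_separated_clusters_recovered(self, two_cluster_values):
        m = fit_mixture(two_cluster_values, k=2, seed=0)
        assert m.means[0] == pytest.approx(100.0, abs=1.0)
        assert m.means[1] == pytest.approx(500.0, abs=1.0)
        np.testing.assert_allclose(m.weights, [0.5, 0.5], atol=0.02)

    def test_table1_preset_recovery(self, table1_sample):
        m = fit_mixture(table1_sample.dataset, k=3, seed=1)
        for est, truth in zip(m.means, [365.0, 473.7, 578.0]):
            assert est == pytest.approx(truth, rel=0.02)

    def test_loglik_monotone_on_every_fit(self, table1_sample, two_cluster_values):
        """EM never decreases the log-likelihood across iterations."""
        for data, k in [
            (table1_sample.dataset.values, 1),
            (table1_sample.dataset.values, 3),
            (table1_sample.dataset.values, 5),
            (two_cluster_values, 2),
        ]:
            trace = np.array(fit_mixture(data, k=k, seed=3).loglik_trace)
            assert np.all(np.diff(trace) >= -1e-7)

    def test_n_too_small_rejected(self):
        with pytest.raises(ValueError, match="3k"):
            fit_mixture(np.array([300.0, 400.0, 500.0, 600.0]), k=2)

    def test_seed_determinism(self, table1_sample):
        a = fit_mixture(table1_sample.dataset, k=3, seed=11)
        b = fit_mixture(table1_sample.dataset, k=3, seed=11)
        np.testing.assert_array_equal(a.means, b.means)
        assert a.loglik == b.loglik


class TestSelectComponents:
    def test_single_cluster_selects_k1(self):
        rng = np.random.default_rng(0)
        values = rng.normal(400.0, 2.0, 100)
        m = select_components(values, 1, 4, seed=0)
        assert m.k == 1

    def test_two_clusters_select_k2(self, two_cluster_values):
        m = select_components(two_cluster_values, 1, 4, seed=0)
        assert m.k == 2

    def test_table1_preset_selects_k3(self, table1_sample):
        m = select_components(table1_sample.dataset, 1, 5, seed=1)
        assert m.k == 3

    def test_selection_table_attached(self, table1_sample):
        m = select_components(table1_sample.dataset, 1, 4, seed=1)
        ks = [row["k"] for row in m.selection_table]
        assert ks == [1, 2, 3, 4]
        bics = [row["bic"] for row in m.selection_table if row["bic"] is not None]
        assert min(bics) == pytest.approx(m.bic)


class TestSklearnCrossCheck:
    def test_em_agrees_with_sklearn_on_preset(self, table1_sample):
        """Independent route: sklearn's GaussianMixture finds the same
        optimum on the well-separated three-instar sample."""
        from sklearn.mixture import GaussianMixture

        x = table1_sample.dataset.values.reshape(-1, 1)
        gm = GaussianMixture(n_components=3, n_init=5, random_state=0).fit(x)
        ours = fit_mixture(table1_sample.dataset, k=3, seed=1)
        theirs = np.sort(gm.means_.ravel())
        np.testing.assert_allclose(ours.means, theirs, atol=2.0)


class TestIntersectionBoundaries:
    def test_symmetric_pair_midpoint(self):
        m = MixtureModel(
            components=(
                GaussianComponent(0.5, 100.0, 10.0),
                GaussianComponent(0.5, 200.0, 10.0),
            ),
            n=10, loglik=0.0, converged=True,
        )
        b = intersection_boundaries(m)
        assert b[0] == pytest.approx(150.0, abs=1e-9)

    def test_grid_oracle_on_paperlike_pair(self):
        c1 = GaussianComponent(0.5, 365.0, 19.34)
        c2 = GaussianComponent(0.5, 473.7, 24.92)
        assert _crossing(c1, c2) == pytest.approx(grid_crossing(c1, c2), abs=0.01)

    def test_grid_oracle_on_random_pairs(self):
        """Analytic crossings match a 0.01 μm grid search within 0.1 μm
        on 100 random valid component pairs."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            sd1, sd2 = rng.uniform(10.0, 30.0, 2)
            w1 = rng.uniform(0.2, 0.8)
            mu1 = rng.uniform(100.0, 400.0)
            mu2 = mu1 + rng.uniform(3.0 * max(sd1, sd2), 300.0)
            c1 = GaussianComponent(w1, mu1, sd1)
            c2 = GaussianComponent(1.0 - w1, mu2, sd2)
            x = _crossing(c1, c2)
            assert mu1 < x < mu2
            assert x == pytest.approx(grid_crossing(c1, c2), abs=0.1)

    def test_boundaries_interleave_means(self, table1_sample):
        m = fit_mixture(table1_sample.dataset, k=3, seed=1)
        b = intersection_boundaries(m)
        assert m.means[0] < b[0] < m.means[1] < b[1] < m.means[2]

    def test_no_root_raises(self):
        # overwhelming weight imbalance: the heavy curve dominates everywhere
        c1 = GaussianComponent(1e-12, 100.0, 10.0)
        c2 = GaussianComponent(1.0 - 1e-12, 140.0, 10.0)
        with pytest.raises(BoundaryError):
            _crossing(c1, c2)

    def test_unweighted_mode_ignores_weights(self):
        c1 = GaussianComponent(0.9, 100.0, 10.0)
        c2 = GaussianComponent(0.1, 200.0, 10.0)
        m = MixtureModel(components=(c1, c2), n=10, loglik=0.0, converged=True)
        assert intersection_boundaries(m, weighted=False)[0] == pytest.approx(150.0)
        assert intersection_boundaries(m, weighted=True)[0] > 150.0

    def test_k1_has_no_boundaries(self, two_cluster_values):
        m = fit_mixture(two_cluster_values, k=1)
        with pytest.raises(ValueError):
            intersection_boundaries(m)


class TestAssignInstars:
    def test_interior_points(self):
        part = assign_instars(np.array([365.0, 474.0, 578.0]), [420.0, 530.0])
        np.testing.assert_array_equal(part.assignments, [1, 2, 3])

    def test_boundary_value_joins_lower_instar(self):
        part = assign_instars(np.array([420.0, 420.0000001]), [420.0, 530.0])
        np.testing.assert_array_equal(part.assignments, [1, 2])

    def test_preset_counts_near_truth(self, table1_sample):
        m = fit_mixture(table1_sample.dataset, k=3, seed=1)
        part = assign_instars(table1_sample.dataset, intersection_boundaries(m))
        np.testing.assert_allclose(part.counts(), [65, 145, 191], atol=8)

    @given(
        st.lists(st.floats(min_value=250.0, max_value=700.0), min_size=1, max_size=300),
        st.lists(
            st.floats(min_value=300.0, max_value=650.0), min_size=1, max_size=4, unique=True
        ),
    )
    def test_partition_completeness(self, values, raw_bounds):
        """Every individual gets exactly one label; counts sum to n."""
        bounds = np.sort(np.array(raw_bounds))
        part = assign_instars(np.array(values), bounds)
        assert part.counts().sum() == len(values)
        assert part.assignments.min() >= 1
        assert part.assignments.max() <= len(bounds) + 1


class TestHistogramMode:
    def test_histogram_fit_recovers_preset_means(self, table1_sample):
        hist = make_histogram(table1_sample.dataset, bin_width=10.0)
        m = fit_mixture_histogram(hist, k=3)
        for est, truth in zip(m.means, [365.0, 473.7, 578.0]):
            assert est == pytest.approx(truth, rel=0.03)
        assert m.weights.sum() == pytest.approx(1.0)


class TestModelSerialization:
    def test_json_round_trip(self, table1_sample, tmp_path):
        m = fit_mixture(table1_sample.dataset, k=3, seed=1)
        p = tmp_path / "model.json"
        m.to_json(p, seed=1)
        back = MixtureModel.from_json(p)
        np.testing.assert_array_equal(back.means, m.means)
        np.testing.assert_array_equal(back.sds, m.sds)
        assert back.loglik == m.loglik
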
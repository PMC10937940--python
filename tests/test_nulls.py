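"""Surrogate null models and the statistics built on them."""

import itertools

import numpy as np
import pytest
import scipy.stats

from neurogsp import (RegionalTimeSeries, cfd_localization,
                      class_concentration_test, dice, make_coordinates,
                      moran_surrogates, morans_i, nonhomolog_null,
                      rewire_graph, spearman_surrogate_test,
                      spectral_randomization, variogram,
                      variogram_surrogates)
from neurogsp.gsp import SpectralCoefficients, gft, igft, mean_esd
from neurogsp.nulls import binomial_critical_count


class TestRewiredGraph:
    def test_degree_sequences_preserved(self, study_graph):
        out = rewire_graph(study_graph, swaps_per_edge=5, seed=3)
        a, b = study_graph.weights > 0, out.weights > 0
        np.testing.assert_array_equal(a.sum(axis=0), b.sum(axis=0))
        np.testing.assert_array_equal(a.sum(axis=1), b.sum(axis=1))

    def test_weight_multiset_preserved(self, study_graph):
        out = rewire_graph(study_graph, swaps_per_edge=5, seed=4)
        np.testing.assert_array_equal(
            np.sort(study_graph.weights[study_graph.weights > 0]),
            np.sort(out.weights[out.weights > 0]))

    def test_actually_randomizes_dense_graph(self, study_graph):
        out = rewire_graph(study_graph, swaps_per_edge=5, seed=5)
        assert np.any((study_graph.weights > 0) != (out.weights > 0))

    def test_three_cycle_stays_admissible(self):
        # the two directed 3-cycles are the only degree-preserving
        # configurations, and no double swap leaves the starting one
        from neurogsp import build_graph
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 2] = w[2, 0] = 1.0
        g = build_graph(w, labels=["a", "b", "c"])
        out = rewire_graph(g, swaps_per_edge=3, seed=0)
        bin_out = out.weights > 0
        assert np.array_equal(bin_out.sum(axis=0), np.ones(3))
        assert np.array_equal(bin_out.sum(axis=1), np.ones(3))
        assert np.all(np.diag(out.weights) == 0)

    def test_deterministic_given_seed(self, study_graph):
        a = rewire_graph(study_graph, swaps_per_edge=2, seed=9)
        b = rewire_graph(study_graph, swaps_per_edge=2, seed=9)
        np.testing.assert_array_equal(a.weights, b.weights)


class TestSpectralRandomization:
    def test_mean_esd_preserved_exactly(self, small_basis, rng):
        ts = RegionalTimeSeries(labels=small_basis.labels,
                                values=rng.standard_normal((20, 64)))
        # at the coefficient level sign flips preserve ESD exactly
        w = gft(small_basis, ts).w
        s = np.where(np.arange(20) % 2 == 0, -1.0, 1.0)
        np.testing.assert_array_equal(((s[:, None] * w) ** 2).mean(axis=1),
                                      (w ** 2).mean(axis=1))
        # after reconstructing the surrogate signal and re-transforming,
        # only float round-trip error remains
        surr = spectral_randomization(small_basis, ts, seed=1)
        np.testing.assert_allclose(mean_esd(gft(small_basis, surr)),
                                   mean_esd(gft(small_basis, ts)),
                                   rtol=1e-12)

    def test_total_energy_preserved(self, small_basis, rng):
        ts = RegionalTimeSeries(labels=small_basis.labels,
                                values=rng.standard_normal((20, 64)))
        surr = spectral_randomization(small_basis, ts, seed=2)
        assert abs(np.linalg.norm(surr.values)
                   - np.linalg.norm(ts.values)) < 1e-10

    def test_permutation_scheme_preserves_energy_multiset(self, small_basis,
                                                          rng):
        ts = RegionalTimeSeries(labels=small_basis.labels,
                                values=rng.standard_normal((20, 64)))
        surr = spectral_randomization(small_basis, ts, seed=3,
                                      scheme="permute")
        np.testing.assert_allclose(
            np.sort(mean_esd(gft(small_basis, surr))),
            np.sort(mean_esd(gft(small_basis, ts))), atol=1e-10)

    def test_randomizes_localization(self, small_basis, rng):
        ts = RegionalTimeSeries(labels=small_basis.labels,
                                values=rng.standard_normal((20, 64)))
        surr = spectral_randomization(small_basis, ts, seed=4)
        assert not np.allclose(surr.values, ts.values)


class TestMoranSurrogates:
    def test_morans_i_preserved(self):
        # smooth synthetic map on sphere coordinates; weights = 1/distance
        xyz, dist = make_coordinates(40, seed=5)
        W = 1.0 / (dist + np.eye(40))
        np.fill_diagonal(W, 0.0)
        x = xyz[:, 0] + 0.5 * xyz[:, 1]  # spatially smooth by construction
        surr = moran_surrogates(W, x, n_draws=50, seed=6)
        i_obs = morans_i(x, W)
        i_surr = np.array([morans_i(s, W) for s in surr])
        assert np.max(np.abs(i_surr - i_obs)) < 0.1

    def test_mean_and_variance_preserved(self):
        xyz, dist = make_coordinates(30, seed=7)
        W = np.exp(-dist)
        np.fill_diagonal(W, 0.0)
        rng = np.random.default_rng(0)
        x = xyz[:, 2] + 0.1 * rng.standard_normal(30)
        surr = moran_surrogates(W, x, n_draws=100, seed=8)
        np.testing.assert_allclose(surr.mean(axis=1), x.mean(), atol=1e-10)
        assert np.all(np.abs(surr.std(axis=1) / x.std() - 1) < 0.1)

    def test_asymmetric_weights_rejected(self, rng):
        W = rng.random((10, 10))
        with pytest.raises(ValueError, match="symmetric"):
            moran_surrogates(W, rng.standard_normal(10), n_draws=1)

    def test_invalid_draw_count(self):
        xyz, dist = make_coordinates(10, seed=1)
        with pytest.raises(ValueError, match="n_draws"):
            moran_surrogates(np.exp(-dist), xyz[:, 0], n_draws=0)


@pytest.fixture(scope="module")
def smooth_map():
    xyz, dist = make_coordinates(45, seed=9)
    x = np.sin(2 * xyz[:, 0]) + xyz[:, 1]
    return x, dist


class TestVariogramSurrogates:
    def test_value_distribution_exact(self, smooth_map):
        x, dist = smooth_map
        surr = variogram_surrogates(x, dist, n_draws=5, seed=10)
        for s in surr:
            np.testing.assert_array_equal(np.sort(s), np.sort(x))

    def test_better_variogram_fit_than_plain_permutation(self, smooth_map):
        x, dist = smooth_map
        _, ref = variogram(x, dist)
        rng = np.random.default_rng(11)
        surr = variogram_surrogates(x, dist, n_draws=40, seed=12)

        def obj(v):
            _, g = variogram(v, dist)
            m = np.isfinite(ref) & np.isfinite(g)
            return ((g[m] - ref[m]) ** 2).sum()

        wins = 0
        for s in surr:
            perm = x[rng.permutation(len(x))]
            if obj(s) <= obj(perm):
                wins += 1
        assert wins >= 0.95 * len(surr)

    def test_deterministic_given_seed(self, smooth_map):
        x, dist = smooth_map
        a = variogram_surrogates(x, dist, n_draws=3, seed=13)
        b = variogram_surrogates(x, dist, n_draws=3, seed=13)
        np.testing.assert_array_equal(a, b)

    def test_degenerate_distances_rejected(self):
        x = np.arange(6.0)
        D = np.ones((6, 6)) - np.eye(6)
        with pytest.raises(ValueError, match="degenerate"):
            variogram_surrogates(x, D, n_draws=1)


class TestClassConcentrationTest:
    def _setup(self, n=12, n_draws=1000):
        labels = [f"r{i}" for i in range(n)]
        cmap = {l: ("A" if i < 6 else "B") for i, l in enumerate(labels)}
        return labels, cmap

    def test_extreme_rank_p_values(self):
        labels, cmap = self._setup()
        obs = np.ones(12)
        obs[:6] = 10.0  # class A far above any surrogate
        surr = np.ones((1000, 12))
        df = class_concentration_test(obs, labels, cmap, surr)
        pa = df.set_index("class").loc["A", "p"]
        pb = df.set_index("class").loc["B", "p"]
        assert pa == pytest.approx(1 / 1001)
        assert pb == 1.0  # observed equal to all surrogates, one-sided

    def test_bh_correction_by_hand(self):
        # BH step-up on sorted p at q=0.05 compares p_(i) <= i/m * q:
        # thresholds (0.0167, 0.0333, 0.05).  0.04 > 0.0333, so only the
        # smallest p survives; with p_2 = 0.03 both of the first two do.
        from statsmodels.stats.multitest import multipletests
        rej, _, _, _ = multipletests([0.001, 0.04, 0.9], alpha=0.05,
                                     method="fdr_bh")
        assert list(rej) == [True, False, False]
        rej2, _, _, _ = multipletests([0.001, 0.03, 0.9], alpha=0.05,
                                      method="fdr_bh")
        assert list(rej2) == [True, True, False]

    def test_empty_class_rejected(self):
        labels, cmap = self._setup()
        cmap = dict(cmap)
        del cmap["r0"]
        with pytest.raises(ValueError, match="r0"):
            class_concentration_test(np.ones(12), labels, cmap,
                                     np.ones((10, 12)))


class TestCfdLocalization:
    def test_attained_level_with_19_surrogates(self):
        rng = np.random.default_rng(21)
        per_scan = rng.standard_normal((5, 8))
        surr = rng.standard_normal((5, 19, 8))
        df = cfd_localization(per_scan, surr, [f"r{i}" for i in range(8)])
        assert df.attrs["attained_per_scan_level"] == pytest.approx(0.05)

    def test_fewer_surrogates_warns(self):
        rng = np.random.default_rng(22)
        with pytest.warns(UserWarning, match="exceeds 0.05"):
            cfd_localization(rng.standard_normal((3, 4)),
                             rng.standard_normal((3, 9, 4)),
                             [f"r{i}" for i in range(4)])

    def test_unanimous_tail_labelled(self):
        n_scans, n_s, n = 30, 19, 6
        surr = np.zeros((n_scans, n_s, n))
        per_scan = np.zeros((n_scans, n))
        per_scan[:, 0] = 1.0   # every scan flags region 0 decoupled
        per_scan[:, 1] = -1.0  # every scan flags region 1 coupled
        per_scan[:, 2:] = 0.0  # never outside the surrogate range
        df = cfd_localization(per_scan, surr, [f"r{i}" for i in range(n)])
        assert df.loc[0, "label"] == "decoupled"
        assert df.loc[1, "label"] == "coupled"
        assert set(df.loc[2:, "label"]) == {"ns"}

    def test_critical_count_matches_enumeration_oracle(self):
        # exact tail summation of Bin(100, 0.05) pmf
        n_tests, alpha = 100, 0.05
        level = 0.05 / 55 / 2
        k = binomial_critical_count(n_tests, alpha, level)

        def tail(j):
            return sum(scipy.stats.binom.pmf(i, n_tests, alpha)
                       for i in range(j, n_tests + 1))

        assert tail(k) <= level < tail(k - 1)


class TestSpearmanSurrogateTest:
    def test_identity_and_monotone_transform(self, rng):
        x = rng.standard_normal(30)
        surr = np.array([rng.permutation(x) for _ in range(99)])
        res = spearman_surrogate_test(x, x, surr)
        assert res.statistic == pytest.approx(1.0)
        res2 = spearman_surrogate_test(x, np.exp(x), surr)
        assert res2.statistic == pytest.approx(1.0)
        assert res2.p_value >= 1 / 100

    def test_closed_form_oracle_no_ties(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        d = np.array([1, 1, 1, 1, 0])
        rho_closed = 1 - 6 * (d ** 2).sum() / (5 * (25 - 1))
        surr = np.array([np.roll(x, k) for k in range(5)] * 4)
        res = spearman_surrogate_test(x, y, surr)
        assert res.statistic == pytest.approx(rho_closed)

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            spearman_surrogate_test(np.arange(4.0), np.arange(4.0),
                                    np.zeros((3, 4)))


class TestDice:
    @pytest.mark.parametrize("a,b,expected", [
        ({"x", "y"}, {"x", "y"}, 1.0),
        ({"x"}, {"y"}, 0.0),
        ({1, 2, 3}, {2, 3, 4}, 4 / 6),
    ])
    def test_formula(self, a, b, expected):
        assert dice(a, b) == pytest.approx(expected)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            dice(set(), set())


class TestNonhomologNull:
    def _setup(self, study_graph, study_basis, rng, planted=True):
        from neurogsp import directed_laplacian, eigenmodes, subgraph, \
            transition_model
        homologs = list(study_graph.labels[:11])
        sub = subgraph(study_graph, homologs)
        basis11 = eigenmodes(
            directed_laplacian(transition_model(sub, teleport_alpha=0.01)),
            sub.labels)
        t = 200
        vals = rng.standard_normal((55, t))
        if planted:
            # homolog rows carry signal living on the first modes of the
            # homolog basis; everything else is noise
            w = np.zeros((11, t))
            w[:5] = 3.0 * rng.standard_normal((5, t))
            vals[:11] = basis11.modes @ w + 0.1 * rng.standard_normal((11, t))
        ts = RegionalTimeSeries(labels=study_graph.labels, values=vals)
        return homologs, basis11, ts

    def test_draws_avoid_homologs_and_count(self, study_graph, study_basis,
                                            rng):
        homologs, basis11, ts = self._setup(study_graph, study_basis, rng,
                                            planted=False)
        null = nonhomolog_null(ts, homologs, basis11, k=5, n_draws=25,
                               seed=31)
        assert null.shape == (25, 2)
        assert np.all(np.isfinite(null))

    def test_planted_signal_beats_null(self, study_graph, study_basis, rng):
        from neurogsp import cross_basis_reconstruction
        homologs, basis11, ts = self._setup(study_graph, study_basis, rng)
        mapping = dict(zip(basis11.labels, homologs))
        obs_act, _ = cross_basis_reconstruction(basis11, ts, 5, mapping)
        null = nonhomolog_null(ts, homologs, basis11, k=5, n_draws=100,
                               seed=32)
        assert obs_act > np.percentile(null[:, 0], 95)

    def test_insufficient_pool_rejected(self, small_basis, rng):
        ts = RegionalTimeSeries(labels=small_basis.labels,
                                values=rng.standard_normal((20, 16)))
        with pytest.raises(ValueError, match="non-homolog"):
            nonhomolog_null(ts, list(small_basis.labels[:15]), small_basis,
                            k=2, n_draws=1)


class TestCalibration:
    def test_class_test_type_one_error(self, small_basis, rng):
        """When the observed map is itself a null draw, rejection at the
        nominal level should occur at that level (exchangeability)."""
        ts = RegionalTimeSeries(labels=small_basis.labels,
                                values=rng.standard_normal((20, 96)))
        labels = list(small_basis.labels)
        cmap = {l: ("A" if i < 10 else "B") for i, l in enumerate(labels)}
        w = gft(small_basis, ts).w
        M = w @ w.T
        modes = small_basis.modes

        def concentration_of_signs(s):
            B = modes * s[None, :]
            return np.sqrt(np.einsum("ij,jk,ik->i", B, M, B))

        reps, n_draws = 500, 99
        rejections = 0
        rng2 = np.random.default_rng(77)
        idx_a = np.arange(10)
        for _ in range(reps):
            signs = rng2.choice([-1.0, 1.0], size=(n_draws + 1, 20))
            maps = np.array([concentration_of_signs(s) for s in signs])
            obs, null = maps[0], maps[1:]
            stat = obs[idx_a].mean()
            p = (1 + (null[:, idx_a].mean(axis=1) >= stat).sum()) / (1 + n_draws)
            if p <= 0.05:
                rejections += 1
        rate = rejections / reps
        # 3 sigma Monte-Carlo band around 0.05 with 500 repetitions
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)
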
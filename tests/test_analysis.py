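"""Analysis operations against closed-form, sampling and hand oracles."""

import numpy as np
import pytest
from scipy import stats

import sorn
from sorn import analysis as an
from sorn.engine import SynapseEvent, ALIVE, INITIAL
from sorn.fixtures import (lognormal_sample, powerlaw_sample,
                           random_walk_lifetimes)


class TestIsiCv:
    def test_regular_train_has_zero_cv(self):
        raster = np.zeros((1000, 1), np.uint8)
        raster[::10, 0] = 1
        st_ = an.isi_cv_stats(raster, washout=0)
        assert st_.cv[0] == 0.0
        assert st_.rates[0] == pytest.approx(0.1)

    def test_geometric_isi_cv_matches_closed_form(self):
        """Bernoulli(p) spiking has geometric ISIs with CV -> sqrt(1-p)."""
        p = 0.2
        gen = np.random.default_rng(21)
        raster = (gen.random((100_000, 1)) < p).astype(np.uint8)
        st_ = an.isi_cv_stats(raster, washout=0)
        assert st_.cv[0] == pytest.approx(np.sqrt(1 - p), abs=0.02)

    def test_silent_and_sparse_units_flagged(self):
        raster = np.zeros((100, 2), np.uint8)
        raster[[5, 50], 1] = 1      # one ISI only
        st_ = an.isi_cv_stats(raster, washout=0)
        assert 0 in st_.silent_units
        assert set(st_.excluded_units) == {0, 1}
        assert np.isnan(st_.cv).all()


class TestCorrelations:
    def test_diagonal_is_one_and_independent_trains_uncorrelated(self):
        gen = np.random.default_rng(3)
        raster = (gen.random((100_000, 2)) < 0.1).astype(np.uint8)
        corr = an.pairwise_correlations(raster, washout=0)
        assert corr[0, 0] == pytest.approx(1.0)
        assert abs(corr[0, 1]) < 0.02

    def test_constant_train_flagged_nan(self):
        raster = np.zeros((50, 2), np.uint8)
        raster[::2, 0] = 1
        corr = an.pairwise_correlations(raster, washout=0)
        assert np.isnan(corr[:, 1]).all() and np.isnan(corr[1, :]).all()
        assert not np.isnan(corr[0, 0])


class TestWeightHistogram:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_density_times_width_sums_to_count(self, seed):
        w = np.random.default_rng(seed).lognormal(-3, 1, 500)
        h = an.weight_histogram(w, exclusion=1e-4, n_bins=20)
        assert np.sum(h.density * h.widths) == pytest.approx(h.n_included,
                                                             abs=1e-9)

    def test_identical_weights_land_in_one_bin(self):
        h = an.weight_histogram(np.full(17, 0.25), exclusion=1e-4)
        assert h.counts.sum() == 17
        assert (h.counts > 0).sum() == 1

    def test_exclusion_threshold(self):
        h = an.weight_histogram(np.array([1e-6, 0.1]), exclusion=1e-4)
        assert h.n_included == 1
        with pytest.raises(an.EmptyDataError):
            an.weight_histogram(np.array([1e-6, 1e-5]), exclusion=1e-4)


class TestLognormalFit:
    def test_parameter_recovery(self):
        w = lognormal_sample(mu=-3, sigma=1, n=10_000, seed=5)
        fit = an.fit_lognormal(w, exclusion=0.0)
        assert fit.params["mu"] == pytest.approx(-3, abs=0.05)
        assert fit.params["sigma"] == pytest.approx(1, abs=0.05)

    def test_equals_gaussian_fit_of_logs(self):
        w = lognormal_sample(n=500, seed=6)
        fit = an.fit_lognormal(w, exclusion=0.0)
        assert fit.params["mu"] == pytest.approx(np.log(w).mean())
        assert fit.params["sigma"] == pytest.approx(np.log(w).std())

    def test_insufficient_data(self):
        with pytest.raises(an.InsufficientDataError):
            an.fit_lognormal(np.full(5, 0.1), exclusion=0.0)


class TestTopShare:
    def test_uniform_weights(self):
        assert an.top_share(np.ones(100), 0.5) == pytest.approx(0.5, abs=0.01)

    def test_hand_accumulation(self):
        assert an.top_share(np.array([6, 1, 1, 1, 1.0]), 0.5) == 0.2

    def test_all_zero_rejected(self):
        with pytest.raises(an.EmptyDataError):
            an.top_share(np.zeros(5), 0.5)


class TestPhaseClassify:
    def test_monotone_series_is_single_decay(self):
        cf = np.linspace(0.1, 0.05, 5000)
        segs = an.phase_classify(cf, window=1000)
        assert [s["label"] for s in segs] == ["decay"]

    def test_constant_series_is_single_stable(self):
        segs = an.phase_classify(np.full(5000, 0.07), window=1000)
        assert [s["label"] for s in segs] == ["stable"]


class TestLifetimes:
    def test_definitions_and_censoring(self):
        events = [
            SynapseEvent(0, 1, 100, 103, "stdp_elimination"),
            SynapseEvent(0, 2, INITIAL, 150, "stdp_elimination"),
            SynapseEvent(1, 2, 200, ALIVE, "structural_birth"),
            SynapseEvent(2, 0, 300, 5000, "stdp_elimination"),
        ]
        lt = an.lifetimes(events, horizon=1000)
        assert lt.tolist() == [3]          # initial, alive, beyond horizon out
        assert an.lifetimes(events, horizon=6000).tolist() == [3, 4700]


class TestPowerLawFit:
    def test_discrete_mle_recovery(self):
        x = powerlaw_sample(alpha=1.5, n=10_000, seed=9)
        fit = an.fit_power_law(x, xmin=1)
        assert fit.params["alpha_mle"] == pytest.approx(1.5, abs=0.1)

    def test_random_walk_first_passage_exponent(self):
        """First-passage lifetimes of a symmetric random walk follow the
        -3/2 law."""
        fpt = random_walk_lifetimes(100_000, 10_000, seed=3)
        fit = an.fit_power_law(fpt, xmin=1)
        assert fit.params["alpha_mle"] == pytest.approx(1.5, abs=0.15)
        assert fit.params["alpha_lsq"] == pytest.approx(1.5, abs=0.15)

    def test_insufficient_data(self):
        with pytest.raises(an.InsufficientDataError):
            an.fit_power_law(np.arange(1, 50), xmin=1)


class TestWeightChanges:
    def test_identity_snapshots(self):
        a = np.array([[0, 0.5], [0.3, 0]])
        out = an.weight_change_stats(a, a.copy(), mode="relative")
        assert np.allclose(out["persisting_change"], 1.0)
        assert out["n_eliminated"] == 0 and out["n_newborn"] == 0

    def test_populations(self):
        a = np.array([[0, 0.05], [0.3, 0]])
        b = np.array([[0, 0.0], [0.6, 0]])
        b[0, 0] = 0.0
        out = an.weight_change_stats(a, b, mode="absolute")
        assert out["eliminated_w_a"].tolist() == [0.05]
        assert out["persisting_change"].tolist() == [pytest.approx(0.3)]
        out2 = an.weight_change_stats(a, a + np.array([[0, 0], [0, 0]]))
        assert out2["n_newborn"] == 0


class TestReturnMap:
    def test_all_silent(self):
        rm = an.activity_return_map(np.zeros((100, 10), np.uint8), washout=0)
        assert rm["max_activity"] == 0.0
        assert rm["n_silent_steps"] == 100
        assert np.all(rm["a_t"] == 0) and np.all(rm["a_next"] == 0)

    def test_all_active(self):
        rm = an.activity_return_map(np.ones((100, 10), np.uint8), washout=0)
        assert rm["min_activity"] == 1.0
        assert rm["n_silent_steps"] == 0


class TestGibrat:
    def test_zero_growth_sd_is_constant(self, rng):
        traj = an.gibrat_null(50, 100, 0.0, normalize=False, rng=rng)
        assert np.allclose(traj, traj[0])

    def test_unnormalized_log_variance_grows_linearly(self, rng):
        """Proportionate growth: var(log w) = sd^2 * t, within 10%."""
        sd = 0.05
        traj = an.gibrat_null(1000, 10_000, sd, normalize=False, rng=rng,
                              record_every=500)
        var = np.var(np.log(traj), axis=1)
        t = np.arange(0, 10_001, 500)
        slope = np.polyfit(t, var, 1)[0]
        assert slope == pytest.approx(sd**2, rel=0.1)

    def test_normalized_version_stays_lognormal(self, rng):
        traj = an.gibrat_null(2000, 10_000, 0.05, normalize=True, rng=rng,
                              record_every=10_000)
        w = traj[-1]
        assert w.sum() == pytest.approx(1.0)
        fit = an.fit_lognormal(w, exclusion=0.0)
        assert fit.gof < 0.05    # KS screen: consistent with lognormal


class TestRunBasedStatistics:
    """Emergent-statistics checks on the shared default 10k-step run."""

    def test_rich_get_richer_potentiation_rises_with_weight(
            self, default_record_10k):
        rec = default_record_10k
        bins = np.linspace(0, 0.2, 15)
        curves = an.stdp_conditional_curves(rec.stdp_log, rec.snapshots, bins)
        ok = ~np.isnan(curves["pot_fraction"])
        assert ok.sum() >= 5
        rho = stats.spearmanr(curves["bin_centers"][ok],
                              curves["pot_fraction"][ok]).statistic
        assert rho > 0
        pot, dep = curves["pot_fraction"][ok], curves["dep_fraction"][ok]
        assert np.all((pot >= 0) & (pot <= 1)) and np.all(pot + dep <= 1)

    def test_empty_bin_flagged(self, default_record_10k):
        rec = default_record_10k
        bins = np.array([10.0, 11.0, 12.0])    # far above any weight
        curves = an.stdp_conditional_curves(rec.stdp_log, rec.snapshots, bins)
        assert np.isnan(curves["pot_fraction"]).all()

    def test_fluctuations_grow_with_weight(self, default_record_10k):
        rec = default_record_10k
        bins = np.linspace(0, 0.2, 11)
        fl = an.fluctuation_vs_weight(rec.snapshots, bins)
        ok = fl["counts"] >= 50
        slope = np.polyfit(fl["bin_centers"][ok],
                           fl["mean_abs_change"][ok], 1)[0]
        assert slope > 0

    def test_strong_synapses_fluctuate_relatively_less(
            self, default_record_10k):
        rec = default_record_10k
        out = an.weight_change_stats(rec.snapshots[7000],
                                     rec.snapshots[10_000], mode="relative")
        w_a, change = out["persisting_w_a"], out["persisting_change"]
        lo, hi = np.quantile(w_a, [0.1, 0.9])
        sd_low = change[w_a <= lo].std()
        sd_high = change[w_a >= hi].std()
        assert sd_high < sd_low

    def test_gibrat_fluctuation_slope_positive(self, rng):
        """Null-model check: under proportionate growth the mean absolute
        change grows linearly through the origin."""
        traj = an.gibrat_null(2000, 1000, 0.05, normalize=True, rng=rng,
                              record_every=200)
        snaps = {200 * k: traj[k] for k in range(len(traj))}
        starts = np.concatenate([traj[k] for k in range(len(traj) - 1)])
        bins = np.unique(np.quantile(starts, np.linspace(0, 1, 8)))
        fl = an.fluctuation_vs_weight(snaps, bins)
        ok = fl["counts"] > 20
        coeffs = np.polyfit(fl["bin_centers"][ok], fl["mean_abs_change"][ok], 1)
        assert coeffs[0] > 0
        # intercept small relative to the range of mean changes
        assert abs(coeffs[1]) < 0.5 * np.nanmax(fl["mean_abs_change"])
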
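"""Dynamic PDA: window slicing, histogram prediction, kinetic fitting."""

import numpy as np
import pytest

from chromofret import burst as bm
from chromofret import kinetics as kin
from chromofret import pda
from chromofret import synthetic as syn

from conftest import make_single_species_model


def tvd(a, b):
    return 0.5 * np.abs(np.asarray(a) / np.sum(a) - np.asarray(b) / np.sum(b)).sum()


class TestWindowSlicing:
    def test_window_count_floor(self, pair568):
        m = make_single_species_model(pair568, 0.5)
        stream, _ = syn.simulate_bursts(
            m, syn.ConfocalSimConfig(burst_count=60, mean_burst_duration=3e-3, seed=1)
        )
        bursts = bm.burst_search(stream)
        data = pda.slice_time_windows(bursts, stream, 1e-3)
        expect = sum(int((b.stop - b.start) / 1e-3) for b in bursts)
        assert len(data) == expect

    def test_conservation_and_index_oracle(self, pair568):
        m = make_single_species_model(pair568, 0.5)
        stream, _ = syn.simulate_bursts(
            m, syn.ConfocalSimConfig(burst_count=40, mean_burst_duration=4e-3, seed=2)
        )
        bursts = bm.burst_search(stream)
        dt = 1e-3
        data = pda.slice_time_windows(bursts, stream, dt)
        # brute-force index arithmetic oracle
        sg_o, sr_o = [], []
        for b in bursts:
            t = stream.macro_time[b.index_start : b.index_stop] - b.start
            ch = stream.channel[b.index_start : b.index_stop]
            n_win = int((b.stop - b.start) / dt)
            for w in range(n_win):
                m_ = (t >= w * dt) & (t < (w + 1) * dt)
                sg_o.append((ch[m_] == 0).sum())
                sr_o.append((ch[m_] == 1).sum())
        np.testing.assert_array_equal(data.s_g, sg_o)
        np.testing.assert_array_equal(data.s_r, sr_o)
        # retained spans conserve photon counts
        total_kept = sum(
            ((stream.macro_time[b.index_start : b.index_stop] - b.start) < int((b.stop - b.start) / dt) * dt).sum()
            for b in bursts
        )
        assert data.totals.sum() == total_kept

    def test_35ms_burst_gives_three_windows(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 3.5e-3, 400))
        stream = syn.PhotonStream(t, np.zeros(400), np.zeros(400, np.int8),
                                  np.full(400, -1, np.int8))
        b = bm.Burst(0.0, 3.5e-3, 0, 400)
        data = pda.slice_time_windows([b], stream, 1e-3)
        assert len(data) == 3


class TestPrediction:
    def test_static_binomial_exact(self, pair568):
        pm = pda.PDAModel(make_single_species_model(pair568, 0.8))
        edges = np.linspace(0, 1, 42)
        n = 40
        pred = pda.pda_predict_histogram(pm, 1e-3, {n: 1.0}, edges)
        from scipy.stats import binom

        kl = np.ceil(edges * n - 1e-9).astype(int)
        exact = np.zeros(41)
        r = np.arange(n + 1)
        idx = np.clip(np.searchsorted(kl, r, side="right") - 1, 0, 40)
        np.add.at(exact, idx, binom.pmf(r, n, 0.8))
        np.testing.assert_allclose(pred, exact, atol=1e-12)
        assert pred.sum() == pytest.approx(1.0, abs=1e-9)

    def test_slow_exchange_limit_population_weighted(self, species_pair):
        hi, lo = species_pair
        m = kin.two_state_model(hi, lo, relaxation_time=1.0, population0=0.3)
        pm = pda.PDAModel(m)
        totals = {35: 1.0}
        pred = pda.pda_predict_histogram(pm, 1e-4, totals)
        p_hi = pda.pda_predict_histogram(pda.PDAModel(make_static(hi)), 1e-4, totals)
        p_lo = pda.pda_predict_histogram(pda.PDAModel(make_static(lo)), 1e-4, totals)
        assert tvd(pred, 0.3 * p_hi + 0.7 * p_lo) < 0.01

    def test_fast_exchange_limit_mean_probability(self, species_pair):
        hi, lo = species_pair
        m = kin.two_state_model(hi, lo, relaxation_time=1e-6, population0=0.3)
        pm = pda.PDAModel(m)
        totals = {35: 1.0}
        pred = pda.pda_predict_histogram(pm, 1e-2, totals)
        e_mean = 0.3 * hi.efficiency + 0.7 * lo.efficiency
        mixed = kin.FRETSpecies("mix", hi.pair, efficiency=e_mean)
        p_mix = pda.pda_predict_histogram(pda.PDAModel(make_static(mixed)), 1e-2, totals)
        assert tvd(pred, p_mix) < 0.01

    @pytest.mark.parametrize("relax", [10e-3, 1e-3, 0.1e-3])
    def test_matches_bruteforce_monte_carlo(self, species_pair, relax):
        hi, lo = species_pair
        m = kin.two_state_model(hi, lo, relaxation_time=relax, population0=0.4)
        pm = pda.PDAModel(m)
        data = pda.simulate_windows(pm, 1e-3, 10**5, seed=3)
        hist, edges, totals = pda.window_histogram(data)
        pred = pda.pda_predict_histogram(pm, 1e-3, totals, edges)
        assert tvd(hist, pred) < 0.01

    def test_three_state_mc_path_matches_oracle(self, pair568):
        sp = [kin.FRETSpecies(n, pair568, efficiency=e) for n, e in
              [("A", 0.8), ("C", 0.45), ("D", 0.05)]]
        k = np.zeros((3, 3))
        k[0, 1] = k[1, 0] = 2000.0
        k[1, 2] = k[2, 1] = 400.0
        m = kin.KineticModel(sp, k)
        pm = pda.PDAModel(m, mc_samples=20000, seed=5)
        data = pda.simulate_windows(pm, 1e-3, 10**5, seed=6)
        hist, edges, totals = pda.window_histogram(data)
        pred = pda.pda_predict_histogram(pm, 1e-3, totals, edges)
        assert tvd(hist, pred) < 0.015

    def test_donor_only_and_static_components(self, species_pair):
        hi, lo = species_pair
        m = kin.two_state_model(hi, lo, relaxation_time=1e-3, population0=0.4,
                                static_fraction=0.3)
        pm = pda.PDAModel(m, donor_only_fraction=0.2,
                          calibration=syn.CalibrationConfig(alpha=0.03))
        data = pda.simulate_windows(pm, 1e-3, 10**5, seed=7)
        hist, edges, totals = pda.window_histogram(data)
        pred = pda.pda_predict_histogram(pm, 1e-3, totals, edges)
        assert tvd(hist, pred) < 0.01


def make_static(sp):
    return kin.KineticModel([sp], np.zeros((1, 1)))


class TestFitting:
    def test_two_state_rate_recovery(self, species_pair):
        hi, lo = species_pair
        truth = kin.two_state_model(hi, lo, relaxation_time=3.7e-3, population0=0.6)
        pm = pda.PDAModel(truth)
        datasets = [
            pda.simulate_windows(pm, dt, 8000, mean_total=max(dt * 4e4, 15), seed=10 + i)
            for i, dt in enumerate([1e-3, 2e-3, 4e-3])
        ]
        tmpl = pda.PDAModel(kin.two_state_model(hi, lo, relaxation_time=1e-3, population0=0.5))
        fit = pda.fit_kinetic_model(datasets, tmpl, pda.FitSpec(n_starts=4), seed=1)
        t_r = fit.relaxation_times()["component_0"][0]
        assert t_r == pytest.approx(3.7e-3, rel=0.2)
        k01, k10 = fit.params["rate_0_1"], fit.params["rate_1_0"]
        assert k01 == pytest.approx(0.4 / 3.7e-3, rel=0.2)
        assert k10 == pytest.approx(0.6 / 3.7e-3, rel=0.2)

    def test_static_data_fitted_with_exchange_pins_rates(self, species_pair):
        hi, lo = species_pair
        static = kin.two_state_model(hi, lo, relaxation_time=1.0, population0=0.5,
                                     static_fraction=1.0)
        pm_truth = pda.PDAModel(static)
        data = [pda.simulate_windows(pm_truth, 1e-3, 8000, seed=20)]
        tmpl = pda.PDAModel(kin.two_state_model(hi, lo, relaxation_time=1e-3, population0=0.5))
        fit = pda.fit_kinetic_model(data, tmpl, pda.FitSpec(n_starts=4, rate_bounds=(1.0, 1e6)), seed=2)
        t_r = fit.relaxation_times()["component_0"][0]
        # exchange must come out far slower than the window (no dynamics)
        assert t_r > 10e-3
        assert fit.redchi < 1.6

    def test_self_consistency_refit(self, species_pair):
        hi, lo = species_pair
        truth = kin.two_state_model(hi, lo, relaxation_time=2e-3, population0=0.5)
        pm = pda.PDAModel(truth)
        data = [pda.simulate_windows(pm, dt, 6000, seed=30 + i) for i, dt in enumerate([1e-3, 3e-3])]
        tmpl = pda.PDAModel(kin.two_state_model(hi, lo, relaxation_time=5e-4, population0=0.4))
        fit1 = pda.fit_kinetic_model(data, tmpl, pda.FitSpec(n_starts=3), seed=3)
        data2 = [pda.simulate_windows(fit1.pda_model, dt, 6000, seed=40 + i) for i, dt in enumerate([1e-3, 3e-3])]
        fit2 = pda.fit_kinetic_model(data2, tmpl, pda.FitSpec(n_starts=3), seed=4)
        for k in fit1.params:
            assert fit2.params[k] == pytest.approx(fit1.params[k], rel=0.25)

    def test_identical_templates_equal_chi2_and_deterministic(self, species_pair):
        hi, lo = species_pair
        truth = kin.two_state_model(hi, lo, relaxation_time=2e-3, population0=0.5)
        data = [pda.simulate_windows(pda.PDAModel(truth), 1e-3, 5000, seed=50)]
        tmpl = lambda: pda.PDAModel(kin.two_state_model(hi, lo, relaxation_time=1e-3, population0=0.5))
        r1 = pda.compare_models(data, [("a", tmpl(), None), ("b", tmpl(), None)], seed=5)
        r2 = pda.compare_models(data, [("a", tmpl(), None), ("b", tmpl(), None)], seed=5)
        assert r1["redchi"].iloc[0] == pytest.approx(r1["redchi"].iloc[1], rel=1e-6)
        assert list(r1["model"]) == list(r2["model"])
        np.testing.assert_array_equal(r1["redchi"].values, r2["redchi"].values)


class TestSubsampling:
    def test_sd_shrinks_with_window_count(self, species_pair):
        hi, lo = species_pair
        truth = kin.two_state_model(hi, lo, relaxation_time=2e-3, population0=0.5)
        pm = pda.PDAModel(truth)
        tmpl = pda.PDAModel(kin.two_state_model(hi, lo, relaxation_time=1e-3, population0=0.5))
        spec = pda.FitSpec(n_starts=2)
        small = [pda.simulate_windows(pm, 1.5e-3, 2000, seed=60)]
        large = [pda.simulate_windows(pm, 1.5e-3, 8000, seed=61)]
        sub_s = pda.subsample_uncertainty(small, tmpl, spec, replicates=3, seed=6)
        sub_l = pda.subsample_uncertainty(large, tmpl, spec, replicates=3, seed=6)
        sd_s = sub_s["relaxation_time_sd"]["component_0"][0]
        sd_l = sub_l["relaxation_time_sd"]["component_0"][0]
        assert sd_l < 0.7 * sd_s

    def test_defaults_match_protocol(self):
        import inspect

        sig = inspect.signature(pda.subsample_uncertainty)
        assert sig.parameters["fraction"].default == 0.7
        assert sig.parameters["replicates"].default == 3


class TestPopulations:
    def test_all_static_model(self, species_pair):
        hi, lo = species_pair
        m = kin.two_state_model(hi, lo, relaxation_time=1e-3, population0=0.5,
                                static_fraction=1.0)
        m.static_weights = np.array([0.2, 0.8])
        pm = pda.PDAModel(m)
        np.testing.assert_allclose(pm.species_populations(), [0.2, 0.8], atol=1e-12)

    def test_pure_exchange_equals_stationary(self, species_pair):
        hi, lo = species_pair
        m = kin.two_state_model(hi, lo, relaxation_time=1e-3, population0=0.35)
        pm = pda.PDAModel(m)
        np.testing.assert_allclose(pm.species_populations(), [0.35, 0.65], atol=1e-9)

    def test_summary_rows_sum_to_one(self, species_pair):
        hi, lo = species_pair
        fits = {}
        for i, p0 in enumerate([0.2, 0.5, 0.8]):
            m = kin.two_state_model(hi, lo, relaxation_time=1e-3, population0=p0,
                                    static_fraction=0.3)
            fits[f"cond{i}"] = pda.PDAModel(m)
        df = pda.species_population_summary(fits)
        tots = df[["compact", "open"]].sum(axis=1)
        np.testing.assert_allclose(tots, 1.0, atol=1e-6)
        # monotone scenario: compact population follows the construction
        assert df["compact"].is_monotonic_increasing
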
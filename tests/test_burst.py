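"""Burst search, corrected MFD indicators, and FRET lines."""

import numpy as np
import pytest

from chromofret import burst as bm
from chromofret import kinetics as kin
from chromofret import synthetic as syn

from conftest import make_single_species_model


def _toy_stream(times, channels=None, micro=None):
    n = len(times)
    return syn.PhotonStream(
        np.asarray(times, float),
        np.zeros(n) if micro is None else np.asarray(micro, float),
        np.zeros(n, np.int8) if channels is None else np.asarray(channels, np.int8),
        np.full(n, syn.SLOT_NONE, np.int8),
    )


class TestBurstSearch:
    def test_pure_background_no_bursts(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 10.0, 10_000))  # 1 kHz
        bursts = bm.burst_search(_toy_stream(t), window=500e-6, min_photons_in_window=20)
        assert bursts == []

    def test_single_cluster_found(self):
        rng = np.random.default_rng(1)
        bg = np.sort(rng.uniform(0, 1.0, 500))
        cluster = np.sort(rng.uniform(0.5, 0.502, 200))
        t = np.sort(np.concatenate([bg, cluster]))
        bursts = bm.burst_search(_toy_stream(t), window=500e-6,
                                 min_photons_in_window=15, min_total_photons=60)
        assert len(bursts) == 1
        b = bursts[0]
        inside = (cluster >= b.start) & (cluster <= b.stop)
        assert inside.mean() >= 0.95

    def test_two_separated_clusters(self):
        rng = np.random.default_rng(2)
        c1 = np.sort(rng.uniform(0.100, 0.102, 200))
        c2 = np.sort(rng.uniform(0.152, 0.154, 200))
        bg = np.sort(rng.uniform(0, 0.3, 150))
        t = np.sort(np.concatenate([c1, c2, bg]))
        bursts = bm.burst_search(_toy_stream(t), window=500e-6,
                                 min_photons_in_window=15, min_total_photons=60)
        assert len(bursts) == 2

    def test_empty_stream(self):
        assert bm.burst_search(_toy_stream([])) == []

    def test_matches_bruteforce_qualification(self):
        rng = np.random.default_rng(3)
        t = np.sort(np.concatenate([
            rng.uniform(0, 0.05, 300), rng.uniform(0.02, 0.021, 150)
        ]))
        w, m = 500e-6, 15
        # O(n^2) oracle for the neighbor count
        ok_oracle = np.array([
            ((t >= ti - w / 2) & (t < ti + w / 2)).sum() >= m for ti in t
        ])
        lo = np.searchsorted(t, t - w / 2, side="left")
        hi = np.searchsorted(t, t + w / 2, side="right")
        np.testing.assert_array_equal((hi - lo) >= m, ok_oracle)


class TestIndicators:
    def test_correction_arithmetic(self):
        # S_G = 100, S_R = 55, alpha = 0.05, gamma = 1 -> F_D = 100, F_A = 50, E = 1/3
        t = np.linspace(0, 1e-3, 155)
        chan = np.array([0] * 100 + [1] * 55, np.int8)
        stream = _toy_stream(t, chan)
        calib = syn.CalibrationConfig(alpha=0.05, gamma=1.0)
        b = bm.Burst(start=0.0, stop=1e-3, index_start=0, index_stop=155)
        b = bm.burst_indicators(b, stream, calib, kin.ALEXA568_647)
        assert b.f_d == pytest.approx(100.0)
        assert b.f_a == pytest.approx(50.0)
        assert b.efficiency == pytest.approx(1.0 / 3.0)

    def test_equal_counts_half_efficiency(self):
        t = np.linspace(0, 1e-3, 200)
        chan = np.array([0, 1] * 100, np.int8)
        b = bm.Burst(0.0, 1e-3, 0, 200)
        b = bm.burst_indicators(b, _toy_stream(t, chan), syn.CalibrationConfig(), kin.ALEXA568_647)
        assert b.efficiency == pytest.approx(0.5)

    def test_zero_signal_flag(self):
        t = np.linspace(0, 1e-3, 10)
        calib = syn.CalibrationConfig(background_donor=1e5, background_acceptor=1e5)
        b = bm.Burst(0.0, 1e-3, 0, 10)
        b = bm.burst_indicators(b, _toy_stream(t), calib, kin.ALEXA568_647)
        assert "zero_signal" in b.flags

    def test_donor_only_stoichiometry_near_one(self, pair568):
        m = make_single_species_model(pair568, 0.5)
        calib = syn.CalibrationConfig(donor_only_fraction=0.5)
        cfg = syn.ConfocalSimConfig(burst_count=400, seed=10, pie=True, calibration=calib)
        stream, truth = syn.simulate_bursts(m, cfg)
        bursts = bm.analyze_bursts(stream, calib, pair568)
        # match bursts to ground-truth molecules by midpoint
        tt = truth.table()
        correct = total = 0
        for b in bursts:
            mid = (b.start + b.stop) / 2
            row = tt[(tt.t_start <= mid) & (tt.t_stop >= mid)]
            if len(row) != 1 or b.stoichiometry is None:
                continue
            is_d0 = bool(row.donor_only.iloc[0])
            total += 1
            if (b.stoichiometry > 0.8) == is_d0:
                correct += 1
        assert total > 100
        assert correct / total > 0.99


class TestLifetimeEstimator:
    def test_delta_at_offset(self):
        mt = np.full(100, 2.5)
        assert bm.mean_fluorescence_lifetime(mt, irf_offset_ns=2.5) == pytest.approx(0.0)

    def test_single_exponential_mean(self):
        rng = np.random.default_rng(4)
        mt = rng.exponential(2.0, 10**5)
        est = bm.mean_fluorescence_lifetime(mt)
        assert abs(est - 2.0) < 3 * 2.0 / np.sqrt(10**5)

    def test_mixture_is_fluorescence_weighted(self):
        # equal amplitudes tau = 1, 3 -> <tau>_F = (1 + 9) / (1 + 3) = 2.5
        rng = np.random.default_rng(5)
        n = 4 * 10**5
        comp = rng.random(n) < 0.25  # photon shares prop. to amplitudes*tau
        mt = np.where(comp, rng.exponential(1.0, n), rng.exponential(3.0, n))
        est = bm.mean_fluorescence_lifetime(mt)
        assert est == pytest.approx(2.5, abs=3 * 3.0 / np.sqrt(n))

    def test_too_few_photons(self):
        assert bm.mean_fluorescence_lifetime(np.ones(5)) is None


class TestFRETLines:
    def test_static_line_anchors(self, pair568):
        line = bm.static_fret_line(pair568)
        tau0 = pair568.donor_lifetime
        assert line.efficiency(tau0) == pytest.approx(0.0)
        assert line.efficiency(0.0) == pytest.approx(1.0)
        assert line.efficiency(tau0 / 2) == pytest.approx(0.5)

    def test_dynamic_line_formula_and_endpoints(self):
        pair = kin.DyePair(82.0, 4.0)
        s1 = kin.FRETSpecies("a", pair, efficiency=1 - 3.2 / 4.0)  # tau 3.2
        s2 = kin.FRETSpecies("b", pair, efficiency=1 - 0.8 / 4.0)  # tau 0.8
        line = bm.dynamic_fret_line(s1, s2, pair)
        assert line.efficiency(2.0) == pytest.approx(1 - 2.56 / 8.0)  # 0.68
        assert line.efficiency(3.2) == pytest.approx(s1.efficiency)
        assert line.efficiency(0.8) == pytest.approx(s2.efficiency)
        with pytest.raises(kin.DomainError):
            line.efficiency(3.5)

    def test_static_population_centroid_on_line(self, pair568):
        m = make_single_species_model(pair568, 0.5)
        calib = syn.CalibrationConfig(alpha=0.02, background_donor=500, background_acceptor=400)
        stream, _ = syn.simulate_bursts(m, syn.ConfocalSimConfig(burst_count=2000, seed=11, calibration=calib))
        bursts = bm.analyze_bursts(stream, calib, pair568)
        assert len(bursts) >= 1000
        es = np.array([b.efficiency for b in bursts if b.mean_lifetime is not None])
        taus = np.array([b.mean_lifetime for b in bursts if b.mean_lifetime is not None])
        line = bm.static_fret_line(pair568)
        assert abs(es.mean() - line.efficiency(taus.mean())) < 0.02
        # corrected E and lifetime recover ground truth
        assert abs(es.mean() - 0.5) < 0.01
        assert taus.mean() == pytest.approx(pair568.donor_lifetime * 0.5, rel=0.03)

    def test_fast_exchange_centroid_on_dynamic_line(self, species_pair, pair568):
        hi, lo = species_pair
        m = kin.two_state_model(hi, lo, relaxation_time=20e-6, population0=0.5)
        stream, _ = syn.simulate_bursts(m, syn.ConfocalSimConfig(burst_count=1500, seed=12))
        bursts = bm.analyze_bursts(stream, syn.CalibrationConfig(), pair568)
        es = np.array([b.efficiency for b in bursts if b.mean_lifetime is not None])
        taus = np.array([b.mean_lifetime for b in bursts if b.mean_lifetime is not None])
        line = bm.dynamic_fret_line(hi, lo, pair568)
        assert abs(es.mean() - line.efficiency(np.clip(taus.mean(), hi.donor_lifetime, lo.donor_lifetime))) < 0.03


class TestHistogramAndSelection:
    def test_histogram_conservation(self, pair568):
        m = make_single_species_model(pair568, 0.4)
        stream, _ = syn.simulate_bursts(m, syn.ConfocalSimConfig(burst_count=300, seed=13))
        bursts = bm.analyze_bursts(stream, syn.CalibrationConfig(), pair568)
        h = bm.mfd_histogram2d(bursts)
        assert h["grid"].sum() + h["overflow"] == len(bursts)
        assert h["marginal_e"].sum() == h["grid"].sum()

    def test_empty_histogram(self):
        h = bm.mfd_histogram2d([])
        assert h["grid"].sum() == 0

    def test_subensemble_selection_matches_linear_scan(self, pair568):
        rng = np.random.default_rng(6)
        bursts = []
        for i in range(200):
            b = bm.Burst(i * 1e-3, i * 1e-3 + 5e-4, 0, 1)
            b.efficiency = rng.uniform(0, 1)
            bursts.append(b)
        sel = bm.select_subensemble(bursts, 0.065)
        oracle = [b for b in bursts if b.efficiency > 0.065]
        assert sel == oracle
        assert bm.select_subensemble(bursts, 0.0) == [b for b in bursts if b.efficiency > 0]
        low = [b for b in bursts if b.efficiency < 0.05]
        assert bm.select_subensemble(low, 0.065) == []
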
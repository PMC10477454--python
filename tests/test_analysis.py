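"""PSTH estimation, two-site statistics and channel-width reading.

Estimator checks use synthetic spike records with known statistics, so no
circuit simulation is involved.
"""

import numpy as np
import pytest

from stngpe.analysis import (ModulationSurface, channel_width, compute_psth,
                             count_modes, l_base, l_re, rate_distribution,
                             spatiotemporal_map, window_average_response)
from stngpe.engine import SpikeRecord


def make_record(spikes_by_nucleus, coords, duration):
    spikes = {}
    for nuc, (ids, times) in spikes_by_nucleus.items():
        order = np.argsort(times, kind="stable")
        spikes[nuc] = (np.asarray(ids)[order], np.asarray(times)[order])
    for nuc in coords:
        spikes.setdefault(nuc, (np.array([], int), np.array([], float)))
    return SpikeRecord(spikes=spikes, coords=coords, duration=duration,
                       dt=0.05, stim_events=[], meta={})


@pytest.fixture
def coords10():
    return {"STN": np.linspace(-0.5, 0.5, 10)}


class TestPSTH:
    def test_single_spike_at_each_onset(self, coords10):
        onsets = np.arange(100.0, 2000.0, 200.0)
        rec = make_record({"STN": (np.zeros(len(onsets), int),
                                   onsets + 0.5)}, coords10, 2100.0)
        p = compute_psth(rec, "STN", onsets, subset=np.array([0]))
        bin0 = np.flatnonzero((p.edges[:-1] <= 0.5) & (p.edges[1:] > 0.5))[0]
        assert p.prob[0, bin0] == pytest.approx(1.0)
        other = np.delete(p.prob[0], bin0)
        assert np.all(other == 0.0)

    def test_flat_for_homogeneous_poisson(self, coords10):
        # stationary Poisson at rate r: every 1 ms bin estimates r*1ms
        rng = np.random.default_rng(0)
        r = 0.02  # 20 Hz in 1/ms
        dur = 300_000.0
        n_spk = rng.poisson(r * dur)
        times = np.sort(rng.uniform(0, dur, n_spk))
        rec = make_record({"STN": (np.zeros(n_spk, int), times)},
                          coords10, dur)
        onsets = np.arange(500.0, dur - 500.0, 1700.0)
        p = compute_psth(rec, "STN", onsets, subset=np.array([0]))
        se = np.sqrt(r / len(onsets))
        assert abs(p.prob[0].mean() - r) < 3 * se / np.sqrt(p.prob.shape[1])
        assert np.all(np.abs(p.prob[0] - r) < 5 * se)

    def test_unbiased_for_inhomogeneous_poisson(self, coords10):
        # stimulus-locked rate profile: lambda(lag) = base + bump; the PSTH
        # recovers the profile within 3 SE in every bin
        rng = np.random.default_rng(1)
        onsets = np.arange(500.0, 800_000.0, 800.0)
        base, bump = 0.01, 0.08
        times = []
        for t0 in onsets:
            n = rng.poisson(base * 700)
            times.extend(rng.uniform(t0 - 100, t0 + 600, n))
            n2 = rng.poisson(bump * 20)
            times.extend(rng.uniform(t0 + 5, t0 + 25, n2))
        times = np.sort(np.array(times))
        rec = make_record({"STN": (np.zeros(len(times), int), times)},
                          coords10, 801_000.0)
        p = compute_psth(rec, "STN", onsets, subset=np.array([0]),
                         window=(-50.0, 100.0))
        lag = p.lags
        expected = base + bump * ((lag >= 5) & (lag < 25))
        se = np.sqrt(np.maximum(expected, base) / len(onsets))
        assert np.all(np.abs(p.prob[0] - expected) < 4 * se)

    def test_trial_averaging_averages_per_trial_psths(self, coords10):
        onsets = np.array([100.0, 300.0])
        r1 = make_record({"STN": (np.array([0, 0]), onsets + 0.5)},
                         coords10, 500.0)
        r2 = make_record({"STN": (np.array([0]), onsets[:1] + 0.5)},
                         coords10, 500.0)
        p = compute_psth([r1, r2], "STN", onsets, subset=np.array([0]))
        bin0 = np.flatnonzero((p.edges[:-1] <= 0.5) & (p.edges[1:] > 0.5))[0]
        assert p.prob[0, bin0] == pytest.approx(0.5 * (1.0 + 0.5))

    def test_onsets_outside_record_rejected(self, coords10):
        rec = make_record({}, coords10, 100.0)
        with pytest.raises(ValueError):
            compute_psth(rec, "STN", np.array([200.0]))


class TestRates:
    def test_poisson_control_concentrates_at_rate(self, coords10):
        rng = np.random.default_rng(2)
        dur = 41_000.0
        ids, times = [], []
        for i in range(10):
            n = rng.poisson(20.0 * dur / 1000.0)
            ids.extend([i] * n)
            times.extend(rng.uniform(0, dur, n))
        rec = make_record({"STN": (np.array(ids), np.array(times))},
                          {"STN": coords10["STN"]}, dur)
        h = rate_distribution([rec], "STN", subset=np.arange(10))
        assert h.rates.mean() == pytest.approx(20.0, rel=0.1)
        assert count_modes(h.rates) == 1

    def test_count_modes_separates_bimodal_sample(self):
        rng = np.random.default_rng(3)
        uni = rng.normal(30.0, 2.0, 800)
        bi = np.concatenate([rng.normal(8.0, 1.5, 400),
                             rng.normal(30.0, 2.0, 400)])
        assert count_modes(uni) == 1
        assert count_modes(bi) == 2


class TestMap:
    def test_locked_response_appears_in_correct_coordinate_bin(self):
        coords = {"STN": np.linspace(-0.5, 0.5, 101)}
        onsets = np.arange(100.0, 50_000.0, 500.0)
        target = 60  # s ~ 0.1
        ids = np.full(len(onsets), target)
        rec = make_record({"STN": (ids, onsets + 2.5)}, coords, 51_000.0)
        m = spatiotemporal_map([rec], "STN", onsets, window=(-10.0, 10.0))
        row = np.searchsorted(m.coord_edges, coords["STN"][target]) - 1
        lagbin = np.searchsorted(m.lag_edges, 2.5) - 1
        assert m.rate[row, lagbin] == pytest.approx(1.0)
        assert m.rate.sum() == pytest.approx(1.0)


class TestTwoSiteStatistics:
    def test_zero_for_identical_responses(self):
        lags = np.arange(-200.0, 210.0) + 0.5
        F = np.random.default_rng(0).random(len(lags))
        assert l_base(F, F, lags) == 0.0
        assert l_re(F, F, lags) == 0.0

    def test_constant_offset_closed_form(self):
        lags = np.arange(-200.0, 210.0) + 0.5
        F = np.full(len(lags), 0.02)
        delta = 0.005
        assert l_base(F + delta, F, lags) == pytest.approx(delta ** 2 * 190.0)
        assert l_re(F + delta, F, lags) == pytest.approx(delta ** 2 * 200.0)

    def test_quadratic_scaling_in_offset(self):
        lags = np.arange(-200.0, 210.0) + 0.5
        F = np.zeros(len(lags))
        l1 = l_base(F + 1e-3, F, lags)
        l2 = l_base(F + 2e-3, F, lags)
        assert l2 == pytest.approx(4 * l1)

    def test_riemann_matches_trapezoid_on_smooth_fixture(self):
        lags = np.arange(-200.0, 210.0) + 0.5
        F = 0.02 + 0.01 * np.sin(lags / 40.0)
        G = 0.02 + 0.012 * np.sin(lags / 40.0 + 0.3)
        m = (lags >= -190.0) & (lags < 0.0)
        riemann = l_base(G, F, lags)
        trap = np.trapezoid((G - F)[m] ** 2, lags[m])
        assert riemann == pytest.approx(trap, rel=1e-2)

    def test_misaligned_series_rejected(self):
        lags = np.arange(-200.0, 210.0) + 0.5
        with pytest.raises(ValueError):
            l_base(np.zeros(10), np.zeros(len(lags)), lags)
        with pytest.raises(ValueError):
            l_base(np.zeros(len(lags)), np.zeros(len(lags)),
                   lags + 1000.0)


class TestWindowAverage:
    def test_single_neuron_window_returns_its_psth(self):
        coords = np.linspace(-0.5, 0.5, 11)
        prob = np.arange(33).reshape(11, 3).astype(float)

        class P:
            pass

        p = P()
        p.subset = np.arange(11)
        p.prob = prob
        out = window_average_response(p, coords, site=0.0, a_width=0.05)
        assert np.array_equal(out, prob[5])

    def test_empty_window_rejected(self):
        coords = np.linspace(-0.5, 0.5, 11)

        class P:
            subset = np.arange(11)
            prob = np.zeros((11, 3))

        with pytest.raises(ValueError):
            window_average_response(P, coords, site=0.44, a_width=0.01)


class TestChannelWidth:
    def _surface(self, lb_row, ds):
        return ModulationSurface(delta_t=np.array([100.0]),
                                 delta_s=np.asarray(ds),
                                 l_base=np.array([lb_row]),
                                 l_re=np.array([lb_row]), nucleus="STN")

    def test_decaying_statistic_crosses_floor(self):
        ds = np.array([0.02, 0.05, 0.1, 0.2])
        surf = self._surface([1.0, 0.3, 1e-4, 1e-4], ds)
        floor = np.full(4, 1e-4)
        out = channel_width(surf, floor)
        assert not out["unbounded"]
        assert out["width"] == pytest.approx(0.1)

    def test_zero_priming_everywhere_gives_zero_width(self):
        ds = np.array([0.02, 0.05, 0.1])
        floor = np.array([1e-4, 1.2e-4, 0.9e-4])
        surf = self._surface(floor.tolist(), ds)
        out = channel_width(surf, floor)
        assert out["width"] == 0.0 and not out["unbounded"]

    def test_no_crossing_flags_unbounded(self):
        ds = np.array([0.02, 0.05, 0.1])
        surf = self._surface([1.0, 0.9, 0.8], ds)
        out = channel_width(surf, np.full(3, 1e-4))
        assert out["unbounded"] and out["width"] == pytest.approx(0.1)
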
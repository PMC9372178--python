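"""Morlet TFR, phase locking, induced/evoked power, ASSR pipeline."""

import numpy as np
import pytest

from eegmarkers.assr import (ASSRPipelineConfig, TFRConfig, evoked_power,
                             induced_power, morlet_tfr,
                             phase_locking_factor, run_assr,
                             summarize_assr)
from eegmarkers.designs import AssrDesign, SubjectProfile
from eegmarkers.schedules import generate_click_schedule
from eegmarkers.simulate import simulate_assr_session

FS = 512.0


def _cosine(freq, n_s=4.0, phase=0.0, amp=1.0):
    t = np.arange(int(n_s * FS)) / FS
    return amp * np.cos(2 * np.pi * freq * t + phase)


class TestMorlet:
    def test_unit_sinusoid_normalization(self):
        tfr = morlet_tfr(_cosine(40.0), FS, np.array([40.0]))
        core = tfr[0, int(FS): int(3 * FS)]
        assert np.abs(core).mean() == pytest.approx(1.0, abs=0.02)

    def test_off_frequency_suppression(self):
        # 6-cycle wavelet at 20 Hz barely responds to a 40 Hz tone
        tfr = morlet_tfr(_cosine(40.0), FS, np.array([20.0]))
        core = tfr[0, int(FS): int(3 * FS)]
        assert np.abs(core).max() <= 0.01

    def test_linearity(self):
        x = _cosine(40.0)
        y = _cosine(43.0, phase=1.0, amp=0.5)
        freqs = np.array([39.0, 40.0, 41.0])
        lhs = morlet_tfr(x + y, FS, freqs)
        rhs = morlet_tfr(x, FS, freqs) + morlet_tfr(y, FS, freqs)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="support"):
            morlet_tfr(np.zeros(100), FS, np.array([4.0]))


class TestPhaseLocking:
    def test_identical_phases_give_one(self):
        tfrs = np.stack([np.full((2, 10), 0.5 * np.exp(1j * 0.7))
                         for _ in range(8)])
        np.testing.assert_allclose(phase_locking_factor(tfrs), 1.0)

    def test_four_quadrature_phases_cancel(self):
        tfrs = np.stack([np.full((1, 4), np.exp(1j * ph))
                         for ph in (0, np.pi / 2, np.pi, 3 * np.pi / 2)])
        np.testing.assert_allclose(phase_locking_factor(tfrs), 0.0,
                                   atol=1e-12)

    def test_amplitude_invariance(self, rng):
        phases = rng.uniform(0, 2 * np.pi, size=(30, 3, 7))
        amps = rng.uniform(0.1, 10.0, size=(30, 3, 7))
        a = phase_locking_factor(np.exp(1j * phases))
        b = phase_locking_factor(amps * np.exp(1j * phases))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_bounds_and_uniform_phase_expectation(self, rng):
        """E[PLF] for uniform phases ~ sqrt(pi)/(2 sqrt(N))."""
        n_epochs, n_rep = 150, 1000
        phases = rng.uniform(0, 2 * np.pi, size=(n_epochs, 1, n_rep))
        plf = phase_locking_factor(np.exp(1j * phases))
        assert plf.min() >= 0.0 and plf.max() <= 1.0
        expect = np.sqrt(np.pi) / (2 * np.sqrt(n_epochs))
        se = expect / np.sqrt(n_rep)   # loose MC error scale
        assert plf.mean() == pytest.approx(expect, abs=5 * se)

    def test_single_epoch_rejected(self):
        with pytest.raises(ValueError):
            phase_locking_factor(np.ones((1, 2, 2), dtype=complex))


class TestPower:
    def _tfr_set(self, ratio, n_epochs=6, rng=None):
        """Epochs whose post-stimulus power is `ratio` x baseline."""
        times = np.linspace(-1.3, 1.75, 200)
        base = np.ones((1, times.size))
        gain = np.where(times >= 0, np.sqrt(ratio), 1.0)
        rng = rng or np.random.default_rng(0)
        tfrs = np.stack([base * gain * np.exp(1j * rng.uniform(0, 2 * np.pi))
                         for _ in range(n_epochs)])
        return tfrs, times

    def test_equal_power_gives_zero_db(self):
        tfrs, times = self._tfr_set(1.0)
        _, db = induced_power(tfrs, times, (-0.5, -0.1))
        np.testing.assert_allclose(db, 0.0, atol=1e-9)

    def test_tenfold_power_gives_ten_db(self):
        tfrs, times = self._tfr_set(10.0)
        _, db = induced_power(tfrs, times, (-0.5, -0.1))
        post = times >= 0.0
        np.testing.assert_allclose(db[:, post], 10.0, atol=1e-9)

    def test_induced_invariant_to_phase_shuffle(self, rng):
        tfrs, times = self._tfr_set(4.0, rng=rng)
        shuffled = tfrs * np.exp(
            1j * rng.uniform(0, 2 * np.pi, size=(tfrs.shape[0], 1, 1)))
        a, _ = induced_power(tfrs, times, (-0.5, -0.1))
        b, _ = induced_power(shuffled, times, (-0.5, -0.1))
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_evoked_random_phase_cancels(self, rng):
        """Phase-shuffling collapses evoked power (~10 log10 N) while
        induced power is untouched."""
        n = int(3.05 * FS)
        t = np.arange(n) / FS - 1.3
        n_ep = 40

        def session(locked):
            return np.stack([
                np.where((t >= 0) & (t < 0.5), 1.0, 0.0)
                * np.cos(2 * np.pi * 40 * t
                         + (0.0 if locked else rng.uniform(0, 2 * np.pi)))
                + rng.standard_normal(n) * 0.5
                for _ in range(n_ep)])

        freqs = np.array([40.0])
        post = (t >= 0.1) & (t < 0.5)
        locked = session(True)
        random = session(False)
        _, ev_locked = evoked_power(locked, FS, freqs, t, (-0.5, -0.1))
        _, ev_random = evoked_power(random, FS, freqs, t, (-0.5, -0.1))
        drop = ev_locked[:, post].mean() - ev_random[:, post].mean()
        assert drop > 0.5 * 10 * np.log10(n_ep)
        ind_locked, _ = induced_power(
            np.stack([morlet_tfr(x, FS, freqs) for x in locked]),
            t, (-0.5, -0.1))
        ind_random, _ = induced_power(
            np.stack([morlet_tfr(x, FS, freqs) for x in random]),
            t, (-0.5, -0.1))
        assert ind_random[:, post].mean() == pytest.approx(
            ind_locked[:, post].mean(), rel=0.1)


class TestSummarize:
    def _maps(self, value, snr_ratio):
        cfg = TFRConfig()
        freqs = cfg.band_frequencies()
        times = np.linspace(-1.3, 1.75, 1000)
        const = np.full((freqs.size, times.size), value)
        raw = np.ones_like(const)
        raw[:, times >= 0.0] = snr_ratio
        return const, raw, times, freqs, cfg

    def test_constant_map_summary(self):
        const, raw, times, freqs, cfg = self._maps(0.42, 10.0)
        res = summarize_assr(const, const, const, raw, times, freqs, cfg)
        assert res.plf == pytest.approx(0.42)
        assert res.induced_power_db == pytest.approx(0.42)
        assert len(res.per_bin["plf"]) == 4

    def test_snr_gate_boundary(self):
        const, raw, times, freqs, cfg = self._maps(0.3, 4.0)
        res = summarize_assr(const, const, const, raw, times, freqs, cfg)
        assert res.snr == pytest.approx(4.0)
        assert not res.qc_pass and res.reason == "snr"
        const, raw, times, freqs, cfg = self._maps(0.3, 4.01)
        res = summarize_assr(const, const, const, raw, times, freqs, cfg)
        assert res.qc_pass


class TestRunAssr:
    def test_noiseless_locked_session(self, small_click_schedule):
        prof = SubjectProfile("S1", true_plf=1.0, blink_rate_per_min=0.0)
        rec = simulate_assr_session(small_click_schedule, prof, seed=31,
                                    background_rms=0.0, alpha_rms=0.0)
        res = run_assr(rec, small_click_schedule)
        assert res.plf == pytest.approx(1.0, abs=0.01)
        assert res.qc_pass
        assert res.evoked_power_db == pytest.approx(res.induced_power_db,
                                                    abs=0.5)

    def test_evoked_never_exceeds_induced(self):
        """Raw power of the average never exceeds average power (Jensen)."""
        sched = generate_click_schedule(
            AssrDesign(n_trains=20, rates_tested=(40.0,)), seed=32)
        prof = SubjectProfile("S1", true_plf=0.5)
        rec = simulate_assr_session(sched, prof, seed=33,
                                    background_rms=10.0)
        cfg = TFRConfig()
        es = __import__("eegmarkers.preprocess", fromlist=["epoch"]).epoch(
            rec, sched.trains_at_rate(40.0), cfg.time_domain_s)
        traces = es.data[:, es.channel_index("Fz"), :]
        freqs = cfg.band_frequencies()
        tfrs = np.stack([morlet_tfr(tr, FS, freqs) for tr in traces])
        induced_raw = np.mean(np.abs(tfrs) ** 2, axis=0)
        evoked_raw = np.abs(
            morlet_tfr(traces.mean(axis=0), FS, freqs)) ** 2
        assert (evoked_raw <= induced_raw + 1e-9).all()

    def test_30hz_band_recentred(self):
        sched = generate_click_schedule(
            AssrDesign(n_trains=24, rates_tested=(30.0,)), seed=34)
        prof = SubjectProfile("S1", true_plf=1.0, blink_rate_per_min=0.0)
        rec = simulate_assr_session(sched, prof, seed=35,
                                    background_rms=0.0, alpha_rms=0.0)
        res = run_assr(rec, sched, rate_hz=30.0)
        assert res.plf == pytest.approx(1.0, abs=0.01)
        cfg = TFRConfig().recentred(30.0)
        assert cfg.target_band_hz == (29.0, 31.0)

    def test_too_few_trains_qc_fail(self, small_click_schedule):
        prof = SubjectProfile("S1", true_plf=0.5, blink_rate_per_min=0.0)
        rec = simulate_assr_session(small_click_schedule, prof, seed=36,
                                    background_rms=0.0, alpha_rms=0.0)
        empty = small_click_schedule.trains_at_rate(25.0)
        res = run_assr(rec, empty, rate_hz=25.0)
        assert not res.qc_pass and res.reason == "too_few_trains"

    def test_plf_monotone_in_concentration(self):
        """Measured PLF rises with generator concentration kappa."""
        from scipy import special
        means = []
        for kappa in (0.5, 2.0, 8.0, 32.0):
            r = float(special.i1e(kappa) / special.i0e(kappa))
            vals = []
            for seed in range(3):
                sched = generate_click_schedule(
                    AssrDesign(n_trains=30, rates_tested=(40.0,)),
                    seed=500 + seed)
                prof = SubjectProfile("S1", true_plf=r,
                                      blink_rate_per_min=5.0)
                rec = simulate_assr_session(sched, prof, seed=600 + seed,
                                            background_rms=5.0,
                                            alpha_rms=1.0)
                vals.append(run_assr(rec, sched).plf)
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))
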
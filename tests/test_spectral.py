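"""PSTH binning, smoothing, power spectra, normalization and peak fitting."""

import numpy as np
import pytest

import v1micro as vm
from v1micro.spectral import PSTH


def make_record(times, n_pyr=10, duration=3000.0):
    times = np.asarray(times, dtype=float)
    return vm.SpikeRecord(
        neuron_ids=np.zeros(len(times), np.int32),
        times=times,
        sizes=vm.PopulationSizes(n_pyr, 2, 2, 2),
        duration=duration,
    )


def synth_psth(x, bin_width=2.0, lo=500.0):
    x = np.asarray(x, dtype=float)
    return PSTH(x, bin_width, (lo, lo + len(x) * bin_width))


class TestComputePsth:
    def test_paper_window_has_1250_bins(self):
        p = vm.compute_psth(make_record([]), "PYR")
        assert p.n_bins == 1250
        assert np.all(p.counts == 0)

    def test_half_open_binning(self):
        p = vm.compute_psth(make_record([501.0, 501.9, 503.0]), "PYR")
        assert p.counts[0] == 2
        assert p.counts[1] == 1
        assert p.counts.sum() == 3

    def test_count_conservation(self, tiny_record):
        p = vm.compute_psth(tiny_record, "PYR", window=(500.0, 1000.0))
        _, t = tiny_record.spikes_of("PYR")
        assert p.counts.sum() == ((t >= 500.0) & (t < 1000.0)).sum()

    def test_indivisible_window_raises(self):
        with pytest.raises(ValueError, match="divide"):
            vm.compute_psth(make_record([]), "PYR", bin_width=3.0,
                            window=(500.0, 3000.0))

    def test_window_outside_duration_raises(self):
        with pytest.raises(ValueError):
            vm.compute_psth(make_record([], duration=1000.0), window=(500.0, 1500.0))


class TestSmoothing:
    def test_zero_in_zero_out(self):
        s = vm.smooth_psth(synth_psth(np.zeros(100)))
        assert np.all(s.counts == 0)

    def test_impulse_gives_unit_mass_kernel(self):
        x = np.zeros(201)
        x[100] = 1.0
        s = vm.smooth_psth(synth_psth(x))
        assert s.counts.sum() == pytest.approx(1.0, abs=1e-9)
        assert s.counts[100] == s.counts.max()
        assert np.all(s.counts >= 0)

    def test_white_noise_variance_reduction(self, rng):
        x = rng.normal(size=200_000)
        s = vm.smooth_psth(synth_psth(x))
        # linear filter: output variance = input variance * sum(k^2)
        sd_bins = np.sqrt(5.0) / 2.0
        r = int(np.ceil(4 * sd_bins))
        k = np.exp(-0.5 * (np.arange(-r, r + 1) / sd_bins) ** 2)
        k /= k.sum()
        expected = np.sum(k**2)
        assert s.counts.var() / x.var() == pytest.approx(expected, rel=0.02)

    def test_invalid_variance(self):
        with pytest.raises(ValueError):
            vm.smooth_psth(synth_psth(np.zeros(10)), gaussian_var=0.0)


class TestPowerSpectrum:
    def test_constant_signal_zero_power(self):
        s = vm.power_spectrum(synth_psth(np.full(1250, 7.0)))
        assert np.allclose(s.power, 0.0, atol=1e-18)

    def test_pure_tone_peak_location(self):
        t = np.arange(1250) / 500.0
        s = vm.power_spectrum(synth_psth(np.sin(2 * np.pi * 40.0 * t)))
        assert s.freqs[np.argmax(s.power)] == pytest.approx(40.0, abs=0.4)

    def test_two_tones_two_maxima(self):
        t = np.arange(1250) / 500.0
        x = np.sin(2 * np.pi * 16.0 * t) + np.sin(2 * np.pi * 40.0 * t)
        s = vm.power_spectrum(synth_psth(x))
        top2 = s.freqs[np.argsort(s.power)[-2:]]
        assert sorted(np.round(top2, 1).tolist()) == [16.0, 40.0]

    def test_parseval_consistency(self, rng):
        x = rng.normal(size=1250)
        s = vm.power_spectrum(synth_psth(x))
        # one-sided |rfft|^2 sums to N * sum((x - mean)^2) up to the
        # double-counted interior bins
        xs = x - x.mean()
        full = np.sum(np.abs(np.fft.fft(xs)) ** 2)
        one_sided = 2 * s.power.sum() - s.power[0] - s.power[-1]
        assert one_sided == pytest.approx(full, rel=1e-9)

    def test_trial_averaging(self, rng):
        a = synth_psth(rng.normal(size=100))
        b = synth_psth(rng.normal(size=100))
        avg = vm.power_spectrum([a, b])
        assert avg.n_trials_averaged == 2
        np.testing.assert_allclose(
            avg.power,
            (vm.power_spectrum(a).power + vm.power_spectrum(b).power) / 2,
        )


class TestNormalization:
    def _spectra(self, powers):
        freqs = np.arange(0.0, 101.0, 1.0)
        return {
            k: vm.PowerSpectrum(freqs, np.asarray(p, dtype=float))
            for k, p in powers.items()
        }

    def test_two_values_map_to_unit_interval_ends(self):
        freqs = np.array([10.0])
        spectra = {
            "a": vm.PowerSpectrum(freqs, np.array([1.0])),
            "b": vm.PowerSpectrum(freqs, np.array([3.0])),
        }
        out = vm.normalize_across_conditions(spectra, [(10.0, 10.0)])
        assert out[(10.0, 10.0)]["a"][0] == 0.0
        assert out[(10.0, 10.0)]["b"][0] == 1.0

    def test_range_and_order_preserved(self, rng):
        spectra = self._spectra({i: rng.random(101) + i for i in range(4)})
        out = vm.normalize_across_conditions(spectra, [(10.0, 60.0)])
        block = np.vstack(list(out[(10.0, 60.0)].values()))
        assert block.min() == 0.0
        assert block.max() == 1.0
        assert np.all((block >= 0) & (block <= 1))
        # monotone conditions stay ordered after the affine map
        at_bin = block[:, 5]
        assert np.all(np.diff(at_bin) > 0)

    def test_invariant_to_common_rescaling(self, rng):
        base = {i: rng.random(101) for i in range(3)}
        out1 = vm.normalize_across_conditions(self._spectra(base), [(0.0, 100.0)])
        scaled = {k: 7.3 * v for k, v in base.items()}
        out2 = vm.normalize_across_conditions(self._spectra(scaled), [(0.0, 100.0)])
        for k in base:
            np.testing.assert_allclose(
                out1[(0.0, 100.0)][k], out2[(0.0, 100.0)][k], atol=1e-12
            )

    def test_degenerate_panel_warns_and_returns_half(self):
        spectra = self._spectra({"a": np.ones(101), "b": np.ones(101)})
        with pytest.warns(UserWarning, match="degenerate"):
            out = vm.normalize_across_conditions(spectra, [(0.0, 50.0)])
        assert np.all(out[(0.0, 50.0)]["a"] == 0.5)

    def test_single_condition_raises(self):
        spectra = self._spectra({"a": np.ones(101)})
        with pytest.raises(ValueError):
            vm.normalize_across_conditions(spectra, [(0.0, 50.0)])


def power_law_spectrum(freqs, offset, exponent, bumps=()):
    """Synthetic spectrum: log10 P = offset - exponent*log10 f + Gaussians
    in linear frequency (the generative family the fitter assumes)."""
    logp = offset - exponent * np.log10(freqs)
    for c, h, w in bumps:
        logp = logp + h * np.exp(-0.5 * ((freqs - c) / w) ** 2)
    return vm.PowerSpectrum(freqs, 10.0**logp)


class TestPeakFitting:
    freqs = np.arange(1.0, 126.0, 0.4)

    def test_pure_power_law(self):
        spec = power_law_spectrum(self.freqs, 2.0, 2.0)
        ps = vm.fit_aperiodic_and_peaks(spec)
        assert ps.n_peaks == 0
        assert ps.aperiodic[1] == pytest.approx(2.0, rel=0.01)

    def test_single_bump_recovery(self):
        spec = power_law_spectrum(self.freqs, 1.0, 1.5, [(25.0, 0.8, 3.0)])
        ps = vm.fit_aperiodic_and_peaks(spec)
        assert ps.n_peaks == 1
        c, h, w = ps.peaks[0]
        assert abs(c - 25.0) < 2.0
        assert abs(h - 0.8) / 0.8 < 0.15

    def test_three_bumps_in_frequency_order(self):
        bumps = [(14.0, 0.6, 2.0), (27.0, 0.8, 3.0), (44.0, 0.5, 4.0)]
        spec = power_law_spectrum(self.freqs, 1.5, 1.0, bumps)
        ps = vm.fit_aperiodic_and_peaks(spec)
        assert ps.n_peaks == 3
        assert np.all(np.diff(ps.centers) > 0)
        for (c_true, _, _), c_fit in zip(bumps, ps.centers):
            assert abs(c_fit - c_true) < 2.0

    def test_random_spectra_center_recovery(self, rng):
        """Across random aperiodic exponents and 1-3 bumps, at least 90% of
        injected peak centers are recovered within 3 Hz."""
        hits = total = 0
        for _ in range(40):
            exponent = rng.uniform(0.5, 3.0)
            n_bumps = rng.integers(1, 4)
            centers = np.sort(rng.uniform(8.0, 90.0, size=n_bumps))
            while np.any(np.diff(centers) < 12.0):
                centers = np.sort(rng.uniform(8.0, 90.0, size=n_bumps))
            bumps = [
                (c, rng.uniform(0.4, 1.2), rng.uniform(1.5, 4.0)) for c in centers
            ]
            spec = power_law_spectrum(self.freqs, rng.uniform(0, 3), exponent, bumps)
            ps = vm.fit_aperiodic_and_peaks(spec)
            for c, _, _ in bumps:
                total += 1
                if ps.n_peaks and np.min(np.abs(ps.centers - c)) <= 3.0:
                    hits += 1
        assert hits / total >= 0.9

    def test_noisy_spectrum_exponent(self, rng):
        spec = power_law_spectrum(self.freqs, 2.0, 1.2, [(30.0, 0.7, 3.0)])
        noisy = vm.PowerSpectrum(
            spec.freqs, spec.power * 10 ** rng.normal(0, 0.02, len(spec.freqs))
        )
        ps = vm.fit_aperiodic_and_peaks(noisy)
        assert ps.aperiodic[1] == pytest.approx(1.2, abs=0.1)
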
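"""PSTHs and their oscillatory content.

Population activity is summarized as a peristimulus time histogram (2 ms
bins, analysis window after the transient discard), smoothed with a narrow
Gaussian kernel, and decomposed by FFT into a one-sided power spectrum of
the mean-removed signal.  Cross-condition comparisons use joint min-max
normalization per frequency band.  Oscillatory peak strengths are measured
above the aperiodic (1/f-like) background with a compact spectral
parameterization: a robust log-log linear aperiodic fit, iterative Gaussian
peak extraction on the residual, and a final aperiodic refit on the
peak-removed spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .params import CellClass
from .simulate import SpikeRecord

__all__ = [
    "PSTH",
    "PowerSpectrum",
    "PeakSet",
    "compute_psth",
    "smooth_psth",
    "power_spectrum",
    "normalize_across_conditions",
    "fit_aperiodic_and_peaks",
]


@dataclass
class PSTH:
    """Binned population spike counts of one class over one trial."""

    counts: np.ndarray  # per-bin spike counts (smoothed PSTHs hold floats)
    bin_width: float  # ms
    window: tuple[float, float]  # ms
    cell_class: CellClass = CellClass.PYR

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def fs(self) -> float:
        """Sampling rate of the binned signal, Hz."""
        return 1000.0 / self.bin_width

    @property
    def times(self) -> np.ndarray:
        """Left edge of each bin, ms."""
        return self.window[0] + np.arange(self.n_bins) * self.bin_width


def compute_psth(
    rec: SpikeRecord,
    cell_class: "CellClass | str" = CellClass.PYR,
    bin_width: float = 2.0,
    window: "tuple[float, float] | None" = None,
) -> PSTH:
    """Histogram the spikes of one class into half-open bins [lo, lo+w).

    The default window is [discard, duration] = [500, duration] ms; with the
    full 3 s trial and 2 ms bins this gives exactly 1250 bins.
    """
    cell_class = CellClass.from_name(cell_class)
    if window is None:
        window = (500.0, rec.duration)
    lo, hi = window
    if not (0.0 <= lo < hi <= rec.duration):
        raise ValueError("window must lie within [0, duration]")
    span = hi - lo
    n_bins_f = span / bin_width
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9:
        raise ValueError(f"bin width {bin_width} must divide window length {span}")
    _, times = rec.spikes_of(cell_class)
    times = times[(times >= lo) & (times < hi)]
    counts = np.bincount(((times - lo) / bin_width).astype(np.int64), minlength=n_bins)
    return PSTH(
        counts=counts.astype(np.float64),
        bin_width=bin_width,
        window=window,
        cell_class=cell_class,
    )


def smooth_psth(p: PSTH, gaussian_var: float = 5.0) -> PSTH:
    """Convolve with a unit-sum Gaussian kernel of variance ``gaussian_var``
    (ms^2), truncated at +/-4 SD and zero-padded at the edges."""
    if gaussian_var <= 0:
        raise ValueError("variance must be positive")
    sd_bins = np.sqrt(gaussian_var) / p.bin_width
    radius = max(1, int(np.ceil(4.0 * sd_bins)))
    x = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (x / sd_bins) ** 2)
    kernel /= kernel.sum()
    smoothed = np.convolve(p.counts, kernel, mode="same")
    return PSTH(
        counts=smoothed,
        bin_width=p.bin_width,
        window=p.window,
        cell_class=p.cell_class,
    )


@dataclass
class PowerSpectrum:
    """One-sided amplitude-squared spectrum, possibly trial-averaged."""

    freqs: np.ndarray  # Hz
    power: np.ndarray  # |FFT|^2 of the mean-removed signal
    n_trials_averaged: int = 1

    def band_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.freqs >= lo) & (self.freqs <= hi)


def power_spectrum(psths: "PSTH | list[PSTH]") -> PowerSpectrum:
    """Spectrum of one PSTH, or the arithmetic mean of per-trial spectra.

    The DC component is removed before the transform, so a constant signal
    has zero power at every frequency.
    """
    if isinstance(psths, PSTH):
        psths = [psths]
    if not psths:
        raise ValueError("need at least one PSTH")
    n = psths[0].n_bins
    fs = psths[0].fs
    if any(p.n_bins != n or p.fs != fs for p in psths):
        raise ValueError("all PSTHs must share length and bin width")
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    acc = np.zeros(len(freqs))
    for p in psths:
        x = p.counts - p.counts.mean()
        acc += np.abs(np.fft.rfft(x)) ** 2
    return PowerSpectrum(
        freqs=freqs, power=acc / len(psths), n_trials_averaged=len(psths)
    )


def normalize_across_conditions(
    spectra: "dict[object, PowerSpectrum]",
    bands: "list[tuple[float, float]]",
    per_bin: bool = False,
) -> "dict[tuple[float, float], dict[object, np.ndarray]]":
    """Min-max normalize powers to [0, 1] across conditions, per band panel.

    By default the affine map is fitted jointly over every (condition,
    frequency-bin) value inside a band, so each panel's minimum maps to 0 and
    its maximum to 1.  ``per_bin=True`` instead normalizes each frequency bin
    across conditions independently.
    """
    if len(spectra) < 2:
        raise ValueError("need at least two conditions to normalize across")
    items = list(spectra.items())
    f0 = items[0][1].freqs
    if any(not np.array_equal(s.freqs, f0) for _, s in items):
        raise ValueError("all spectra must share the same frequency grid")

    out: dict[tuple[float, float], dict[object, np.ndarray]] = {}
    for lo, hi in bands:
        mask = items[0][1].band_mask(lo, hi)
        block = np.vstack([s.power[mask] for _, s in items])
        if per_bin:
            mn = block.min(axis=0)
            mx = block.max(axis=0)
        else:
            mn = block.min()
            mx = block.max()
        rng = mx - mn
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = (block - mn) / rng
        if np.isscalar(rng) and rng == 0 or (not np.isscalar(rng) and np.any(rng == 0)):
            warnings.warn("degenerate (all-equal) power values in a band panel")
            norm = np.where(np.isfinite(norm), norm, 0.5)
        out[(lo, hi)] = {k: norm[i] for i, (k, _) in enumerate(items)}
    return out


@dataclass
class PeakSet:
    """Periodic peaks above the aperiodic background of one spectrum.

    ``peaks`` holds (center Hz, strength in log10-power units above the
    aperiodic curve, bandwidth Hz) sorted by center frequency;
    ``aperiodic`` is (offset, exponent) of log10 P = offset - exponent *
    log10 f.
    """

    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    aperiodic: tuple[float, float] = (0.0, 0.0)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def centers(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def strengths(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])


def _gaussian(f: np.ndarray, center: float, height: float, width: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((f - center) / width) ** 2)


def _robust_aperiodic_fit(
    logf: np.ndarray, logp: np.ndarray, n_iter: int = 3
) -> tuple[float, float]:
    """Linear fit of logp on logf biased toward the lower envelope: points
    with large positive residuals (oscillatory peaks) are dropped and the
    fit repeated."""
    slope, offset = np.polyfit(logf, logp, 1)
    for _ in range(n_iter):
        resid = logp - (offset + slope * logf)
        thresh = max(np.std(resid), 1e-12)
        keep = resid <= thresh
        if keep.sum() < 3:
            break
        slope, offset = np.polyfit(logf[keep], logp[keep], 1)
    return offset, -slope


def fit_aperiodic_and_peaks(
    spec: PowerSpectrum,
    max_peaks: int = 3,
    fit_range: tuple[float, float] = (3.0, 100.0),
    peak_threshold_sd: float = 2.0,
    min_peak_height: float = 0.05,
    max_peak_width: float = 12.0,
) -> PeakSet:
    """Separate a spectrum into aperiodic background and periodic peaks.

    Procedure: (1) robust log-log linear fit of the aperiodic component;
    (2) up to ``max_peaks`` times, locate the largest positive residual and,
    if it exceeds both ``peak_threshold_sd`` residual SDs and
    ``min_peak_height`` log10 units, fit and subtract a Gaussian (center,
    height, width in linear frequency); (3) refit the aperiodic component on
    the peak-removed spectrum.  Peak strengths are the fitted Gaussian
    heights in log10-power units above the final aperiodic curve.
    """
    mask = spec.band_mask(*fit_range) & (spec.freqs > 0)
    f = spec.freqs[mask]
    if len(f) < 8:
        raise ValueError("fit range contains too few frequency bins")
    floor = np.max(spec.power[mask]) * 1e-12 + np.finfo(float).tiny
    logp = np.log10(np.maximum(spec.power[mask], floor))
    logf = np.log10(f)

    offset, exponent = _robust_aperiodic_fit(logf, logp)
    resid = logp - (offset - exponent * logf)

    peaks: list[tuple[float, float, float]] = []
    for _ in range(max_peaks):
        idx = int(np.argmax(resid))
        height0 = resid[idx]
        if height0 < max(peak_threshold_sd * np.std(resid), min_peak_height):
            break
        center0 = f[idx]
        try:
            popt, _ = curve_fit(
                _gaussian,
                f,
                np.maximum(resid, 0.0),
                p0=(center0, height0, 2.0),
                bounds=(
                    (fit_range[0], 0.0, 0.25),
                    (fit_range[1], 3 * height0 + 1.0, max_peak_width),
                ),
                maxfev=5000,
            )
        except RuntimeError:
            break
        center, height, width = popt
        peaks.append((float(center), float(height), float(width)))
        resid = resid - _gaussian(f, *popt)

    # alternate aperiodic refits on the peak-removed spectrum with joint
    # Gaussian refits of all peaks until the decomposition settles
    if peaks:
        def _multi_gauss(f, *theta):
            out = np.zeros_like(f)
            for j in range(0, len(theta), 3):
                out += _gaussian(f, theta[j], theta[j + 1], theta[j + 2])
            return out

        for _ in range(3):
            peak_model = _multi_gauss(f, *np.ravel(peaks))
            slope, offset = np.polyfit(logf, logp - peak_model, 1)
            exponent = -slope
            resid = logp - (offset - exponent * logf)
            p0 = np.ravel(peaks)
            lo = [fit_range[0], 0.0, 0.25] * len(peaks)
            hi = [fit_range[1], np.inf, max_peak_width] * len(peaks)
            try:
                popt, _ = curve_fit(
                    _multi_gauss, f, resid, p0=p0, bounds=(lo, hi), maxfev=5000
                )
                peaks = [tuple(map(float, popt[j : j + 3]))
                         for j in range(0, len(popt), 3)]
            except RuntimeError:
                break

        # final fully joint fit: aperiodic line and all Gaussians together,
        # which resolves the trade-off between low-frequency peak tails and
        # the aperiodic slope that alternation alone cannot settle
        def _full_model(f, b, chi, *theta):
            return b - chi * np.log10(f) + _multi_gauss(f, *theta)

        p0 = np.concatenate([[offset, exponent], np.ravel(peaks)])
        lo = [-np.inf, -np.inf] + [fit_range[0], 0.0, 0.25] * len(peaks)
        hi = [np.inf, np.inf] + [fit_range[1], np.inf, max_peak_width] * len(peaks)
        try:
            popt, _ = curve_fit(
                _full_model, f, logp, p0=p0, bounds=(lo, hi), maxfev=10000
            )
            offset, exponent = float(popt[0]), float(popt[1])
            peaks = [tuple(map(float, popt[2 + j : 2 + j + 3]))
                     for j in range(0, len(popt) - 2, 3)]
        except RuntimeError:
            pass
    peaks.sort(key=lambda p: p[0])
    return PeakSet(peaks=peaks, aperiodic=(float(offset), float(exponent)))
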
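"""Directed information flow between population signals.

Two population PSTHs are z-scored, band-pass filtered (4th-order Butterworth,
forward-backward so the filter is zero-phase), and converted to instantaneous
phase via the analytic signal.  The wrapped phase difference
dPhi(t) = Phi_inh(t) - Phi_pyr(t) then yields

    dPLI = < H(dPhi) >     with H(0) = 1/2,
    PLI  = | < sign(dPhi) > |   with sign(0) = 0,

so PLI = 2 |0.5 - dPLI| holds exactly.  dPLI > 0.5 means the inhibitory
population's phase leads the pyramidal population in that band; 0.5 means no
consistent lead.  The first and last 5% of samples are excluded from the
averages to avoid Hilbert edge artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .spectral import PSTH

__all__ = [
    "BandSpec",
    "PhaseSeries",
    "FlowMetrics",
    "preprocess",
    "bandpass",
    "hilbert_phase",
    "dpli",
    "pli",
    "band_sweep",
    "default_bands",
]

EDGE_FRACTION = 0.05


@dataclass(frozen=True)
class BandSpec:
    """A frequency band [f_lo, f_hi] in Hz."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0.0 < self.f_lo < self.f_hi:
            raise ValueError("need 0 < f_lo < f_hi")

    def validate(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(f"f_hi {self.f_hi} must lie below Nyquist ({fs / 2})")

    def as_tuple(self) -> tuple[float, float]:
        return (self.f_lo, self.f_hi)


def default_bands(
    lo: float = 10.0, hi: float = 80.0, step: float = 5.0
) -> list[BandSpec]:
    """Contiguous analysis bands, e.g. [10,15], [15,20], ..., [75,80].

    ``step=10`` gives the coarser 10 Hz-wide variant.
    """
    edges = np.arange(lo, hi + step / 2, step)
    return [BandSpec(a, b) for a, b in zip(edges[:-1], edges[1:])]


def preprocess(psth: "PSTH | np.ndarray") -> np.ndarray:
    """Z-score a PSTH (zero mean, unit variance)."""
    x = psth.counts if isinstance(psth, PSTH) else np.asarray(psth, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a zero-variance signal")
    return (x - x.mean()) / sd


def bandpass(x: np.ndarray, band: BandSpec, fs: float = 500.0, order: int = 4):
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    band.validate(fs)
    sos = sps.butter(order, band.as_tuple(), btype="bandpass", fs=fs, output="sos")
    # forward-backward filtering needs a few filter lengths of signal
    padlen = 3 * (2 * order + 1)
    if len(x) <= 3 * padlen:
        raise ValueError(
            f"signal too short ({len(x)} samples) for order-{order} band-pass; "
            "use a longer window or a lower filter order"
        )
    return sps.sosfiltfilt(sos, x)


@dataclass
class PhaseSeries:
    """Instantaneous phase and amplitude from the analytic signal."""

    phase: np.ndarray  # radians, in (-pi, pi]
    amplitude: np.ndarray
    fs: float = 500.0
    edge_fraction: float = EDGE_FRACTION

    def interior(self) -> np.ndarray:
        """Phase with the edge samples (Hilbert artifacts) dropped."""
        k = int(np.floor(self.edge_fraction * len(self.phase)))
        return self.phase[k : len(self.phase) - k] if k else self.phase


def hilbert_phase(x: np.ndarray, fs: float = 500.0) -> PhaseSeries:
    """Analytic-signal phase and envelope of a real signal."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    analytic = sps.hilbert(x)
    return PhaseSeries(
        phase=np.angle(analytic), amplitude=np.abs(analytic), fs=fs
    )


def _wrap(dphi: np.ndarray) -> np.ndarray:
    """Wrap phase differences into (-pi, pi]."""
    out = np.mod(dphi + np.pi, 2.0 * np.pi) - np.pi
    out[out == -np.pi] = np.pi
    return out


def _phase_pair(
    a: "PhaseSeries | np.ndarray", b: "PhaseSeries | np.ndarray"
) -> np.ndarray:
    pa = a.interior() if isinstance(a, PhaseSeries) else np.asarray(a, dtype=float)
    pb = b.interior() if isinstance(b, PhaseSeries) else np.asarray(b, dtype=float)
    if len(pa) != len(pb):
        raise ValueError("phase series must have equal length")
    return _wrap(pa - pb)


def dpli(
    phase_inh: "PhaseSeries | np.ndarray", phase_pyr: "PhaseSeries | np.ndarray"
) -> float:
    """Directed phase lag index: mean Heaviside of the wrapped phase
    difference, with H(0) = 0.5.  Value > 0.5 means the first (inhibitory)
    signal leads."""
    d = _phase_pair(phase_inh, phase_pyr)
    return float(np.mean((d > 0) + 0.5 * (d == 0)))


def pli(
    phase_inh: "PhaseSeries | np.ndarray", phase_pyr: "PhaseSeries | np.ndarray"
) -> float:
    """Phase lag index: |mean sign of the wrapped phase difference|; 0 for
    no consistent lag, 1 for perfect locking at a nonzero lag."""
    d = _phase_pair(phase_inh, phase_pyr)
    return float(np.abs(np.mean(np.sign(d))))


@dataclass
class FlowMetrics:
    """Per-trial dPLI/PLI in one band, with a one-sample test against 0.5."""

    band: BandSpec
    pair: tuple[str, str]  # (leading candidate, reference), e.g. ("PV", "PYR")
    dpli_per_trial: np.ndarray
    pli_per_trial: np.ndarray
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dpli_per_trial = np.asarray(self.dpli_per_trial, dtype=float)
        self.pli_per_trial = np.asarray(self.pli_per_trial, dtype=float)
        self.mean_dpli = float(np.mean(self.dpli_per_trial))
        self.mean_pli = float(np.mean(self.pli_per_trial))
        n = len(self.dpli_per_trial)
        if n < 2:
            self.t_statistic = np.nan
            self.p_value = np.nan
            self.flags.append("too-few-trials")
        elif np.std(self.dpli_per_trial) == 0:
            self.t_statistic = np.nan
            self.p_value = np.nan
            self.flags.append("zero-variance")
        else:
            t, p = stats.ttest_1samp(self.dpli_per_trial, 0.5)
            self.t_statistic = float(t)
            self.p_value = float(p)

    @property
    def significance(self) -> str:
        """Asterisk tier of the test against 0.5 (**: p<0.01, *: p<0.05,
        -: p<0.1)."""
        p = self.p_value
        if np.isnan(p):
            return ""
        return "**" if p < 0.01 else "*" if p < 0.05 else "-" if p < 0.1 else ""


def band_sweep(
    psths_inh: "list[PSTH | np.ndarray]",
    psths_pyr: "list[PSTH | np.ndarray]",
    bands: "list[BandSpec] | None" = None,
    fs: float = 500.0,
    pair: tuple[str, str] = ("INH", "PYR"),
) -> list[FlowMetrics]:
    """Per-band flow metrics from paired per-trial population signals.

    Each trial's signals are z-scored, band-passed, Hilbert-transformed, and
    reduced to dPLI/PLI over the interior samples.
    """
    if len(psths_inh) != len(psths_pyr):
        raise ValueError("need the same number of inhibitory and Pyr trials")
    if not psths_inh:
        raise ValueError("need at least one trial")
    if len(psths_inh) < 2:
        warnings.warn("fewer than 2 trials: no t-test will be computed")
    bands = bands if bands is not None else default_bands()

    z_inh = [preprocess(p) for p in psths_inh]
    z_pyr = [preprocess(p) for p in psths_pyr]
    out = []
    for band in bands:
        d_vals, p_vals = [], []
        for xi, xp in zip(z_inh, z_pyr):
            ph_i = hilbert_phase(bandpass(xi, band, fs), fs)
            ph_p = hilbert_phase(bandpass(xp, band, fs), fs)
            d_vals.append(dpli(ph_i, ph_p))
            p_vals.append(pli(ph_i, ph_p))
        out.append(
            FlowMetrics(
                band=band,
                pair=pair,
                dpli_per_trial=np.array(d_vals),
                pli_per_trial=np.array(p_vals),
            )
        )
    return out
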
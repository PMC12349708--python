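"""Network integration: LIF dynamics, conductance synapses, Poisson drive.

The membrane equation per neuron is

    dV/dt = -(V - E_l)/tau_m + I_syn(t)/C_m

with I_syn the sum over afferent channels of conductance-based currents
g * s * (E_rev - V); excitatory and external channels reverse at 0 mV,
inhibitory channels at -70 mV.  Synaptic gates s obey ds/dt = -s/tau plus a
unit increment per presynaptic spike arriving after its axonal delay.
Integration is fourth-order Runge-Kutta at a fixed step (0.1 ms by default)
with gates advanced by exact exponential decay; spikes reset V to -60 mV and
clamp the neuron for its class refractory period.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _kernel
from .network import NetworkModel, PopulationSizes
from .params import (
    CellClass,
    ExternalInputSpec,
    Parameters,
    SimulationConfig,
    V_E,
    V_I,
    default_parameters,
)

__all__ = [
    "SpikeRecord",
    "FeedforwardWiring",
    "poisson_train",
    "update_gate",
    "synaptic_current",
    "build_feedforward_wiring",
    "integrate_trial",
    "compute_rates",
]


def poisson_train(
    rate: float,
    duration: float,
    rng: "np.random.Generator | int | None" = None,
) -> np.ndarray:
    """Sorted event times (ms) of a homogeneous Poisson process.

    ``rate`` is in Hz and ``duration`` in ms, so the expected count is
    ``rate * duration / 1000``.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(rng)
    n = rng.poisson(rate * duration / 1000.0)
    return np.sort(rng.uniform(0.0, duration, size=n))


def update_gate(s: float, tau: float, dt: float, n_arrivals: int = 0) -> float:
    """One gate step: exact exponential decay plus unit delta increments."""
    if s < 0:
        raise ValueError("gate value must be non-negative")
    if tau <= 0:
        raise ValueError("tau must be positive")
    return s * np.exp(-dt / tau) + n_arrivals


def synaptic_current(
    V: float,
    gates: np.ndarray,
    weights: np.ndarray,
    reversal: float,
) -> float:
    """Channel current I = sum_j g_j (V - E_rev) s_j in pA (nS x mV).

    This is the printed form of the conductance current; in the membrane
    equation it enters with the sign that makes excitatory input (E_rev = 0)
    depolarize and inhibitory input (E_rev = -70 mV) pull V toward -70 mV.
    """
    gates = np.asarray(gates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if gates.shape != weights.shape:
        raise ValueError("gates and weights must be aligned per afferent")
    return float(np.sum(weights * gates) * (V - reversal))


@dataclass(frozen=True)
class FeedforwardWiring:
    """Fiber-to-neuron wiring of the stimulus drive (CSR over fibers)."""

    indptr: np.ndarray
    post: np.ndarray
    n_fibers: int


def build_feedforward_wiring(
    sizes: PopulationSizes,
    spec: "ExternalInputSpec | None" = None,
    scale: float = 1.0,
    rng: "np.random.Generator | int | None" = None,
) -> FeedforwardWiring:
    """Bernoulli-connect stimulus fibers to the network.

    The fiber count scales with the network (``round(n_fibers * scale)``);
    connection probabilities are class-specific and unscaled.
    """
    spec = spec or default_parameters().feedforward
    rng = np.random.default_rng(rng)
    n_fibers = int(round(spec.n_fibers * scale))
    n = sizes.n_total
    cls = sizes.class_of()
    p_of_neuron = np.asarray(spec.connection_probability)[cls]
    hits = rng.random((n_fibers, n)) < p_of_neuron[None, :]
    counts = hits.sum(axis=1)
    indptr = np.zeros(n_fibers + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    post = np.nonzero(hits)[1].astype(np.int32)
    return FeedforwardWiring(indptr=indptr, post=post, n_fibers=n_fibers)


@dataclass
class SpikeRecord:
    """All spikes of one trial: parallel (neuron_id, time) arrays."""

    neuron_ids: np.ndarray  # int32
    times: np.ndarray  # float64 ms, strictly within (0, duration]
    sizes: PopulationSizes
    duration: float
    trial_seed: "int | None" = None

    def __post_init__(self) -> None:
        self.class_of = self.sizes.class_of()

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def spikes_of(self, cls: "CellClass | str") -> tuple[np.ndarray, np.ndarray]:
        """(neuron_ids, times) restricted to one cell class."""
        cls = CellClass.from_name(cls)
        mask = self.class_of[self.neuron_ids] == int(cls)
        return self.neuron_ids[mask], self.times[mask]

    def isi_by_neuron(self) -> dict[int, np.ndarray]:
        """Inter-spike intervals per neuron (for refractory checks)."""
        order = np.lexsort((self.times, self.neuron_ids))
        ids = self.neuron_ids[order]
        ts = self.times[order]
        out: dict[int, np.ndarray] = {}
        for i in np.unique(ids):
            t = ts[ids == i]
            if len(t) > 1:
                out[int(i)] = np.diff(t)
        return out

    def to_tsv(self, path: "str | Path", trial: int = 0) -> None:
        meta = {
            "sizes": self.sizes.as_tuple(),
            "duration": self.duration,
            "trial_seed": self.trial_seed,
        }
        names = np.array([c.name for c in CellClass])
        with open(path, "w") as fh:
            fh.write(f"# {json.dumps(meta)}\n")
            fh.write("trial\tneuron_id\tclass\ttime_ms\n")
            for i, t in zip(self.neuron_ids, self.times):
                fh.write(f"{trial}\t{i}\t{names[self.class_of[i]]}\t{t:.4f}\n")


def _pair_tau_table(params: Parameters) -> np.ndarray:
    """(4, 4) decay constants indexed [post_class, pre_class]; 1.0 ms filler
    for non-existent projections (their channels never receive arrivals)."""
    tab = np.ones((4, 4))
    for r in params.rules:
        tab[int(r.post), int(r.pre)] = r.tau_decay
    return tab


def integrate_trial(
    net: NetworkModel,
    cfg: "SimulationConfig | None" = None,
    trial_seed: int = 0,
    params: "Parameters | None" = None,
    ff_wiring: "FeedforwardWiring | None" = None,
    max_rate_cap: float = 250.0,
    g_const: "np.ndarray | None" = None,
    monitor_neuron: "int | None" = None,
) -> SpikeRecord:
    """Integrate one trial of the network and record all spikes.

    Background drive is one independent Poisson train per neuron at its
    class rate, active throughout; feedforward drive starts at the stimulus
    onset.  If ``ff_wiring`` is omitted it is sampled from the trial seed.
    ``max_rate_cap`` (Hz, population average) bounds the spike buffer.

    ``g_const`` adds a per-neuron constant excitatory conductance (nS), and
    ``monitor_neuron`` records that neuron's membrane trajectory into the
    returned record's ``v_trace`` (one sample per step, starting at t=0);
    both are diagnostic hooks used for validating the integrator.
    """
    params = params or default_parameters()
    cfg = cfg or params.simulation
    sizes = net.sizes
    n = sizes.n_total
    dt = cfg.dt

    cls = net.class_of.astype(np.int8)
    tau_m = np.array([params.neurons[c].tau_m for c in CellClass])
    tau_ref = np.array([params.neurons[c].tau_ref for c in CellClass])
    some = params.neurons[CellClass.PYR]
    inv_tau_m = (1.0 / tau_m)[cls]
    ref_steps = np.round(tau_ref / dt).astype(np.int64)[cls]

    # per-neuron, per-channel decay factors
    pair_tau = _pair_tau_table(params)
    tau_nc = np.empty((n, _kernel.N_CHANNELS))
    tau_nc[:, :4] = pair_tau[cls, :]
    tau_nc[:, _kernel.CH_BACKGROUND] = params.background.tau_d
    tau_nc[:, _kernel.CH_FEEDFORWARD] = params.feedforward.tau_d
    decay = np.exp(-dt / tau_nc)
    half_decay = np.exp(-dt / (2.0 * tau_nc))
    erev = np.array([V_E, V_I, V_I, V_I, V_E, V_E])

    # recurrent CSR (edges are sorted by presynaptic id)
    indptr = np.searchsorted(net.pre, np.arange(n + 1)).astype(np.int64)
    delay_steps = np.maximum(1, np.round(net.delay / dt)).astype(np.int64)
    buf_len = int(delay_steps.max(initial=1)) + 2

    ss = np.random.SeedSequence(trial_seed)
    if ff_wiring is None:
        ff_wiring = build_feedforward_wiring(
            sizes, params.feedforward, cfg.scale, np.random.default_rng(ss.spawn(1)[0])
        )

    bg_lam = (np.asarray(params.background.rates)[cls]) * dt / 1000.0
    ff_lam = params.feedforward.rates[0] * dt / 1000.0
    onset_step = int(round(cfg.stimulus_onset / dt))

    kernel_seed = int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF
    max_spikes = int(n * cfg.duration / 1000.0 * max_rate_cap) + 10_000

    spike_id, spike_t, status, v_trace = _kernel.run_network(
        cfg.n_steps,
        dt,
        buf_len,
        cls,
        inv_tau_m,
        some.E_l,
        some.V_thr,
        some.V_reset,
        1.0 / some.C_m,
        decay,
        half_decay,
        erev,
        ref_steps,
        indptr,
        net.post,
        net.weight,
        delay_steps,
        bg_lam,
        params.background.g,
        ff_wiring.indptr,
        ff_wiring.post,
        params.feedforward.g,
        ff_lam,
        onset_step,
        kernel_seed,
        max_spikes,
        np.zeros(n) if g_const is None else np.asarray(g_const, dtype=float),
        -1 if monitor_neuron is None else int(monitor_neuron),
    )
    if status == _kernel.NONFINITE:
        raise RuntimeError(
            "membrane potential became non-finite (parameter blow-up); "
            f"last recorded spike at t={spike_t[-1] if len(spike_t) else 0.0} ms"
        )
    if status == _kernel.SPIKE_OVERFLOW:
        raise RuntimeError(
            f"spike buffer exhausted: population rate exceeded {max_rate_cap} Hz"
        )
    rec = SpikeRecord(
        neuron_ids=spike_id,
        times=spike_t,
        sizes=sizes,
        duration=cfg.duration,
        trial_seed=trial_seed,
    )
    rec.v_trace = v_trace if monitor_neuron is not None else None
    return rec


def compute_rates(
    rec: SpikeRecord,
    window: "tuple[float, float] | None" = None,
) -> dict[CellClass, float]:
    """Mean firing rate (Hz) per class over an analysis window.

    Per class: total in-window spikes / (number of neurons x window length).
    """
    if window is None:
        window = (0.0, rec.duration)
    lo, hi = window
    if not (0.0 <= lo < hi <= rec.duration):
        raise ValueError("window must lie within [0, duration]")
    win_s = (hi - lo) / 1000.0
    # half-open [lo, hi), but closed at the trial end so the final-step
    # spikes are not dropped
    in_win = (rec.times >= lo) & (
        (rec.times <= hi) if hi == rec.duration else (rec.times < hi)
    )
    cls_of_spike = rec.class_of[rec.neuron_ids[in_win]]
    rates: dict[CellClass, float] = {}
    for c in CellClass:
        n_c = rec.sizes.count(c)
        if n_c == 0:
            warnings.warn(f"class {c.name} is empty; rate reported as 0")
            rates[c] = 0.0
        else:
            rates[c] = float((cls_of_spike == int(c)).sum() / (n_c * win_s))
    return rates
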
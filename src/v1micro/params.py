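"""Model parameters for the V1 layer-2/3 microcircuit.

The microcircuit couples one excitatory pyramidal (Pyr) population with three
inhibitory interneuron subtypes (PV, SOM, VIP).  All constants here are the
published operating point of the model: leaky integrate-and-fire membrane
parameters per cell class, class-pair connection probabilities with
subtype-specific weighting factors, synaptic conductances and decay time
constants per (pre, post) class pair, and the background / feedforward
external drive.

Every table can be exported to (and re-loaded from) a YAML file so that runs
carry their full parameterization with them; ``default_parameters()`` returns
the shipped operating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from enum import IntEnum
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "CellClass",
    "NeuronParams",
    "ConnectivityRule",
    "LogNormalWeightParams",
    "ExternalInputSpec",
    "SimulationConfig",
    "Parameters",
    "default_parameters",
    "load_parameters",
    "CONTROL_SIZES",
    "TOTAL_NEURONS",
]


class CellClass(IntEnum):
    """Neuron classes; integer values index per-class arrays throughout."""

    PYR = 0
    PV = 1
    SOM = 2
    VIP = 3

    @classmethod
    def from_name(cls, name: "str | CellClass") -> "CellClass":
        if isinstance(name, CellClass):
            return name
        return cls[str(name).upper()]


#: Control-condition census (E/I ratio ~3.5:1): Pyr, PV, SOM, VIP.
CONTROL_SIZES = (10341, 1341, 875, 700)

#: Total network size, held constant across all E/I conditions.
TOTAL_NEURONS = 13257

#: Excitatory and inhibitory synaptic reversal potentials (mV).
V_E = 0.0
V_I = -70.0

#: Spike threshold and post-spike reset (mV), shared by all classes.
V_THR = -50.0
V_RESET = -60.0


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire parameters of one cell class."""

    tau_m: float  # membrane time constant, ms
    tau_ref: float  # absolute refractory period, ms
    C_m: float = 200.0  # membrane capacitance, pF
    E_l: float = -70.0  # leak reversal potential, mV
    V_thr: float = V_THR
    V_reset: float = V_RESET

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.C_m <= 0:
            raise ValueError("tau_m and C_m must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")
        if self.V_reset >= self.V_thr:
            raise ValueError("V_reset must lie below V_thr")


# PV cells are fast-spiking: much shorter membrane time constant than the
# regular-spiking classes, and half their refractory period.
NEURON_PARAMS: dict[CellClass, NeuronParams] = {
    CellClass.PYR: NeuronParams(tau_m=10.5, tau_ref=2.0),
    CellClass.PV: NeuronParams(tau_m=3.1, tau_ref=1.0),
    CellClass.SOM: NeuronParams(tau_m=11.8, tau_ref=1.0),
    CellClass.VIP: NeuronParams(tau_m=10.9, tau_ref=1.0),
}


@dataclass(frozen=True)
class LogNormalWeightParams:
    """Log-normal law for Pyr->Pyr conductances (long-tailed EPSP amplitudes).

    The scale parameter is tied to the location through
    ``sigma**2 = mu - log(0.10)``, i.e. ``mu = sigma**2 + log(0.10)``;
    with ``sigma = 1`` the median conductance is ``exp(mu) ~ 0.272 nS``.
    """

    sigma: float = 1.0
    mu: float = 1.0 + math.log(0.10)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @classmethod
    def from_sigma(cls, sigma: float) -> "LogNormalWeightParams":
        return cls(sigma=sigma, mu=sigma**2 + math.log(0.10))


@dataclass(frozen=True)
class ConnectivityRule:
    """One allowed (pre-class, post-class) projection."""

    pre: CellClass
    post: CellClass
    probability: float  # effective Bernoulli connection probability
    tau_decay: float  # postsynaptic decay time constant, ms
    weight_law: str = "gaussian"  # "gaussian" | "log_normal"
    g_mean: float = 0.0  # Gaussian conductance mean, nS
    g_sd: float = 0.0  # Gaussian conductance SD, nS

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        if self.tau_decay <= 0:
            raise ValueError("tau_decay must be positive")
        if self.weight_law not in ("gaussian", "log_normal"):
            raise ValueError(f"unknown weight law {self.weight_law!r}")
        if self.weight_law == "gaussian" and (self.g_mean <= 0 or self.g_sd < 0):
            raise ValueError("gaussian law needs g_mean > 0 and g_sd >= 0")


# Class-level base connection probabilities.
P_EE = 0.1009
P_EI = 0.1346
P_IE = 0.1689
P_II = 0.1371

# Subtype weighting factors applied multiplicatively to the base
# inhibitory-to-inhibitory probability (PV-PV : SOM-PV : VIP-SOM : SOM-VIP).
W_PV_PV = 1.0
W_SOM_PV = 0.857
W_VIP_SOM = 0.625
W_SOM_VIP = 1.0

_P = CellClass.PYR
_V = CellClass.PV
_S = CellClass.SOM
_I = CellClass.VIP

#: The ten allowed projections.  Any (pre, post) pair absent here carries no
#: synapses (notably VIP->Pyr, PV->SOM, PV->VIP, SOM->SOM, VIP->VIP...).
CONNECTIVITY_RULES: tuple[ConnectivityRule, ...] = (
    ConnectivityRule(_P, _P, P_EE, tau_decay=2.0, weight_law="log_normal"),
    ConnectivityRule(_P, _V, P_EI, tau_decay=2.0, g_mean=0.95, g_sd=0.095),
    ConnectivityRule(_P, _S, P_EI, tau_decay=2.0, g_mean=0.29, g_sd=0.029),
    ConnectivityRule(_P, _I, P_EI, tau_decay=2.0, g_mean=0.27, g_sd=0.027),
    ConnectivityRule(_V, _P, P_IE, tau_decay=6.4, g_mean=4.32, g_sd=0.432),
    ConnectivityRule(_V, _V, P_II * W_PV_PV, tau_decay=4.6, g_mean=3.51, g_sd=0.351),
    ConnectivityRule(_S, _P, P_IE, tau_decay=13.1, g_mean=1.26, g_sd=0.126),
    ConnectivityRule(_S, _V, P_II * W_SOM_PV, tau_decay=5.2, g_mean=1.22, g_sd=0.122),
    ConnectivityRule(_S, _I, P_II * W_SOM_VIP, tau_decay=10.2, g_mean=1.18, g_sd=0.118),
    ConnectivityRule(_I, _S, P_II * W_VIP_SOM, tau_decay=13.1, g_mean=0.32, g_sd=0.032),
)

#: Synaptic-delay law: Gaussian with mean d0 and variance d0/10 (ms), truncated
#: strictly positive; d0 = 2.0 ms for excitatory presynaptic cells, 1.0 ms for
#: all inhibitory subtypes.
DELAY_D0 = {
    CellClass.PYR: 2.0,
    CellClass.PV: 1.0,
    CellClass.SOM: 1.0,
    CellClass.VIP: 1.0,
}


@dataclass(frozen=True)
class ExternalInputSpec:
    """Poisson external drive (AMPA-type, reversal 0 mV).

    ``background`` drive is one independent train per neuron at a
    class-specific rate, on for the whole trial.  ``feedforward`` drive
    models the stimulus: a bank of fibers firing at ``rate`` from ``onset``
    onwards, Bernoulli-connected to each class with class-specific
    probability.
    """

    kind: str  # "background" | "feedforward"
    rates: tuple[float, float, float, float]  # Hz per class (Pyr, PV, SOM, VIP)
    g: float  # conductance per arrival, nS
    tau_d: float = 2.0  # decay time constant, ms
    n_fibers: int = 0  # feedforward only
    connection_probability: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    onset: float = 0.0  # ms

    def __post_init__(self) -> None:
        if self.kind not in ("background", "feedforward"):
            raise ValueError(f"unknown input kind {self.kind!r}")
        if any(r < 0 for r in self.rates) or self.onset < 0:
            raise ValueError("rates and onset must be non-negative")


BACKGROUND_INPUT = ExternalInputSpec(
    kind="background", rates=(190.0, 770.0, 100.0, 150.0), g=10.0
)

FEEDFORWARD_INPUT = ExternalInputSpec(
    kind="feedforward",
    rates=(25.0, 25.0, 25.0, 25.0),
    g=2.5,
    n_fibers=500,
    connection_probability=(0.1, 0.01, 0.01, 0.01),
    onset=100.0,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Integration protocol for one experimental run."""

    dt: float = 0.1  # ms, RK4 step
    duration: float = 3000.0  # ms per trial
    stimulus_onset: float = 100.0  # ms
    discard: float = 500.0  # ms of initial transient dropped from analysis
    n_trials: int = 50
    master_seed: int = 0
    scale: float = 1.0  # multiplies population counts and fiber count

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.discard < self.duration:
            raise ValueError("discard must be smaller than duration")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def analysis_window(self) -> tuple[float, float]:
        return (self.discard, self.duration)


@dataclass(frozen=True)
class Parameters:
    """Complete parameterization of the model (all tables in one object)."""

    neurons: Mapping[CellClass, NeuronParams] = field(
        default_factory=lambda: dict(NEURON_PARAMS)
    )
    rules: tuple[ConnectivityRule, ...] = CONNECTIVITY_RULES
    ee_weights: LogNormalWeightParams = LogNormalWeightParams()
    delay_d0: Mapping[CellClass, float] = field(default_factory=lambda: dict(DELAY_D0))
    background: ExternalInputSpec = BACKGROUND_INPUT
    feedforward: ExternalInputSpec = FEEDFORWARD_INPUT
    simulation: SimulationConfig = SimulationConfig()

    def rule_for(self, pre: CellClass, post: CellClass) -> "ConnectivityRule | None":
        for r in self.rules:
            if r.pre == pre and r.post == post:
                return r
        return None

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "neurons": {c.name: asdict(p) for c, p in self.neurons.items()},
            "rules": [
                {**asdict(r), "pre": r.pre.name, "post": r.post.name}
                for r in self.rules
            ],
            "ee_weights": asdict(self.ee_weights),
            "delay_d0": {c.name: d for c, d in self.delay_d0.items()},
            "background": asdict(self.background),
            "feedforward": asdict(self.feedforward),
            "simulation": asdict(self.simulation),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Parameters":
        return cls(
            neurons={
                CellClass.from_name(k): NeuronParams(**v)
                for k, v in d["neurons"].items()
            },
            rules=tuple(
                ConnectivityRule(
                    **{
                        **r,
                        "pre": CellClass.from_name(r["pre"]),
                        "post": CellClass.from_name(r["post"]),
                    }
                )
                for r in d["rules"]
            ),
            ee_weights=LogNormalWeightParams(**d["ee_weights"]),
            delay_d0={CellClass.from_name(k): v for k, v in d["delay_d0"].items()},
            background=ExternalInputSpec(
                **{
                    **d["background"],
                    "rates": tuple(d["background"]["rates"]),
                    "connection_probability": tuple(
                        d["background"]["connection_probability"]
                    ),
                }
            ),
            feedforward=ExternalInputSpec(
                **{
                    **d["feedforward"],
                    "rates": tuple(d["feedforward"]["rates"]),
                    "connection_probability": tuple(
                        d["feedforward"]["connection_probability"]
                    ),
                }
            ),
            simulation=SimulationConfig(**d["simulation"]),
        )

    def save(self, path: "str | Path") -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def default_parameters() -> Parameters:
    """The shipped operating point of the microcircuit."""
    return Parameters()


def load_parameters(path: "str | Path") -> Parameters:
    """Load a :class:`Parameters` object from a YAML file."""
    return Parameters.from_dict(yaml.safe_load(Path(path).read_text()))
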
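"""Experiment orchestration: the E/I-ratio grid, seeds, and result tables.

A *series* disrupts the E/I balance by trading neurons between the Pyr
population and one interneuron subtype ("pv" or "som") at constant network
size; each *condition* is one target E/I ratio in that series.  For every
condition the runner builds a network realization, integrates independent
trials, and reduces them to firing rates, the trial-averaged Pyr power
spectrum with its periodic peaks, and per-band directed flow metrics
(dPLI/PLI) from PV and SOM to Pyr.

Seeding is hierarchical and counter-based: a master seed plus (series,
condition, trial) indices deterministically derive every stream, so adding
trials or conditions never changes earlier results.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import spectral
from .flow import BandSpec, FlowMetrics, band_sweep, default_bands
from .network import NetworkModel, PopulationSizes, build_connectivity, size_populations
from .params import CellClass, Parameters, SimulationConfig, default_parameters
from .simulate import build_feedforward_wiring, compute_rates, integrate_trial

__all__ = [
    "ExperimentPlan",
    "ConditionResult",
    "ResultBundle",
    "PROFILES",
    "condition_sizes",
    "run_condition",
    "run_experiment",
    "summarize_flow_reversal",
]

#: Power bands of the cross-condition normalization panels (Hz).
NORMALIZATION_BANDS = [(10.0, 20.0), (20.0, 35.0), (35.0, 60.0), (60.0, 100.0)]

#: Named run profiles: full published protocol vs. a scaled-down desk profile.
PROFILES = {
    "paper": dict(scale=1.0, n_trials=50, duration=3000.0),
    "desk": dict(scale=0.25, n_trials=10, duration=2000.0),
}


@dataclass(frozen=True)
class ExperimentPlan:
    """One series of the experiment grid."""

    series: str  # "pv" | "som"
    ratios: tuple[float, ...] = (3.0, 3.5, 4.0, 4.5)
    n_trials: int = 50
    scale: float = 1.0
    duration: float = 3000.0
    master_seed: int = 0
    output_dir: "str | None" = None

    def __post_init__(self) -> None:
        if self.series not in ("pv", "som"):
            raise ValueError("series must be 'pv' or 'som'")
        if not self.ratios:
            raise ValueError("ratios must be non-empty")
        if 3.5 not in self.ratios:
            warnings.warn(
                "control ratio 3.5 not included; normalization panels will "
                "lack the control reference"
            )
        if not 0 < self.scale <= 1:
            raise ValueError("scale must lie in (0, 1]")

    @classmethod
    def from_profile(cls, series: str, profile: str = "desk", **kw) -> "ExperimentPlan":
        return cls(series=series, **{**PROFILES[profile], **kw})

    def config(self) -> SimulationConfig:
        return SimulationConfig(
            duration=self.duration,
            n_trials=self.n_trials,
            master_seed=self.master_seed,
            scale=self.scale,
        )

    def provenance_hash(self, params: "Parameters | None" = None) -> str:
        params = params or default_parameters()
        blob = json.dumps(
            {"plan": asdict(self), "params": params.to_dict()}, sort_keys=True
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def condition_sizes(series: str, ratio: float, scale: float = 1.0) -> PopulationSizes:
    """Census of one condition: sizing at full network size, then scaled."""
    varied = CellClass.PV if series == "pv" else CellClass.SOM
    return size_populations(ratio, varied).scaled(scale)


def _condition_key(series: str, ratio: float) -> tuple[int, int]:
    return (0 if series == "pv" else 1, int(round(ratio * 10)))


def _trial_seed(master: int, key: tuple[int, int], trial: int) -> int:
    ss = np.random.SeedSequence((master, *key, 1000 + trial))
    return int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


@dataclass
class ConditionResult:
    """All reduced measurements of one (series, ratio) condition."""

    series: str
    ratio: float
    sizes: PopulationSizes
    rates_per_trial: dict[str, np.ndarray]  # class name -> (n_trials,) Hz
    spectrum: spectral.PowerSpectrum  # trial-averaged Pyr spectrum
    peaks: spectral.PeakSet
    flow: dict[str, list[FlowMetrics]]  # "PV"/"SOM" -> per-band metrics
    psths: "dict[str, list[spectral.PSTH]] | None" = None  # raw per-trial
    provenance: dict = field(default_factory=dict)

    @property
    def mean_rates(self) -> dict[str, float]:
        return {k: float(np.mean(v)) for k, v in self.rates_per_trial.items()}

    def mean_dpli(self, pair: str, f_lo: float, f_hi: float) -> float:
        """Trial- and band-averaged dPLI over bands inside [f_lo, f_hi]."""
        vals = [
            m.mean_dpli
            for m in self.flow[pair]
            if m.band.f_lo >= f_lo and m.band.f_hi <= f_hi
        ]
        if not vals:
            raise ValueError(f"no analysis bands inside [{f_lo}, {f_hi}] Hz")
        return float(np.mean(vals))


@dataclass
class ResultBundle:
    """Results of one series, keyed by E/I ratio."""

    series: str
    conditions: dict[float, ConditionResult]
    normalized_panels: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def flow_table(self) -> "list[dict]":
        rows = []
        for ratio, cond in sorted(self.conditions.items()):
            for pair, metrics in cond.flow.items():
                for m in metrics:
                    for trial, (d, p) in enumerate(
                        zip(m.dpli_per_trial, m.pli_per_trial)
                    ):
                        rows.append(
                            dict(
                                condition=f"{self.series}_{ratio}",
                                pair=f"{pair}->Pyr",
                                band_lo=m.band.f_lo,
                                band_hi=m.band.f_hi,
                                trial=trial,
                                dpli=d,
                                pli=p,
                            )
                        )
        return rows

    def summary_table(self) -> "list[dict]":
        rows = []
        for ratio, cond in sorted(self.conditions.items()):
            for pair, metrics in cond.flow.items():
                for m in metrics:
                    rows.append(
                        dict(
                            condition=f"{self.series}_{ratio}",
                            pair=f"{pair}->Pyr",
                            band_lo=m.band.f_lo,
                            band_hi=m.band.f_hi,
                            mean_dpli=m.mean_dpli,
                            mean_pli=m.mean_pli,
                            t=m.t_statistic,
                            p=m.p_value,
                            significance=m.significance,
                        )
                    )
        return rows


def run_condition(
    series: str,
    ratio: float,
    cfg: SimulationConfig,
    master_seed: int = 0,
    params: "Parameters | None" = None,
    bands: "list[BandSpec] | None" = None,
    keep_psths: bool = True,
    network: "NetworkModel | None" = None,
) -> ConditionResult:
    """Simulate and analyze one condition of the grid."""
    params = params or default_parameters()
    bands = bands if bands is not None else default_bands()
    key = _condition_key(series, ratio)
    sizes = condition_sizes(series, ratio, cfg.scale)

    net_rng = np.random.default_rng(np.random.SeedSequence((master_seed, *key, 0)))
    if network is None:
        network = build_connectivity(sizes, params=params, seed=net_rng)
    ff = build_feedforward_wiring(sizes, params.feedforward, cfg.scale, net_rng)

    window = cfg.analysis_window
    psths: dict[str, list[spectral.PSTH]] = {"PYR": [], "PV": [], "SOM": []}
    rates: dict[str, list[float]] = {c.name: [] for c in CellClass}
    for trial in range(cfg.n_trials):
        rec = integrate_trial(
            network, cfg, _trial_seed(master_seed, key, trial), params, ff_wiring=ff
        )
        for c, r in compute_rates(rec, window).items():
            rates[c.name].append(r)
        for name in psths:
            psths[name].append(
                spectral.compute_psth(rec, cell_class=name, window=window)
            )

    smoothed = [spectral.smooth_psth(p) for p in psths["PYR"]]
    spectrum = spectral.power_spectrum(smoothed)
    peaks = spectral.fit_aperiodic_and_peaks(spectrum)
    flow = {
        pair: band_sweep(
            psths[pair], psths["PYR"], bands=bands, fs=psths["PYR"][0].fs,
            pair=(pair, "PYR"),
        )
        for pair in ("PV", "SOM")
    }
    return ConditionResult(
        series=series,
        ratio=ratio,
        sizes=sizes,
        rates_per_trial={k: np.asarray(v) for k, v in rates.items()},
        spectrum=spectrum,
        peaks=peaks,
        flow=flow,
        psths=psths if keep_psths else None,
        provenance=dict(master_seed=master_seed, condition_key=key),
    )


def run_experiment(
    plan: ExperimentPlan,
    params: "Parameters | None" = None,
    bands: "list[BandSpec] | None" = None,
) -> ResultBundle:
    """Run every condition of a plan and assemble the result bundle.

    Deterministic for a fixed master seed; conditions use independent
    derived seed streams.  If ``plan.output_dir`` is set, per-condition
    summary JSON files stamped with the provenance hash are written as each
    condition completes, and conditions whose stamp already matches are
    skipped and reloaded at the summary level.
    """
    params = params or default_parameters()
    cfg = plan.config()
    prov_hash = plan.provenance_hash(params)
    out_dir = Path(plan.output_dir) if plan.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    conditions: dict[float, ConditionResult] = {}
    for ratio in plan.ratios:
        cond = run_condition(
            plan.series, ratio, cfg, plan.master_seed, params, bands
        )
        cond.provenance["hash"] = prov_hash
        conditions[ratio] = cond
        if out_dir:
            _write_condition_summary(out_dir, plan.series, ratio, cond)

    bundle = ResultBundle(
        series=plan.series,
        conditions=conditions,
        provenance=dict(master_seed=plan.master_seed, hash=prov_hash),
    )
    if len(conditions) >= 2:
        bundle.normalized_panels = spectral.normalize_across_conditions(
            {r: c.spectrum for r, c in conditions.items()}, NORMALIZATION_BANDS
        )
    if out_dir:
        _write_tables(out_dir, bundle)
    return bundle


def _write_condition_summary(
    out_dir: Path, series: str, ratio: float, cond: ConditionResult
) -> None:
    payload = dict(
        series=series,
        ratio=ratio,
        sizes=cond.sizes.as_tuple(),
        mean_rates=cond.mean_rates,
        aperiodic=cond.peaks.aperiodic,
        peaks=cond.peaks.peaks,
        provenance=cond.provenance,
    )
    (out_dir / f"{series}_{ratio}_summary.json").write_text(
        json.dumps(payload, indent=1)
    )


def _write_tables(out_dir: Path, bundle: ResultBundle) -> None:
    import pandas as pd

    pd.DataFrame(bundle.flow_table()).to_csv(
        out_dir / f"{bundle.series}_flow.tsv", sep="\t", index=False
    )
    pd.DataFrame(bundle.summary_table()).to_csv(
        out_dir / f"{bundle.series}_flow_summary.tsv", sep="\t", index=False
    )


def summarize_flow_reversal(
    bundles: "dict[str, ResultBundle]",
    ratio: float = 4.5,
    f_lo: float = 20.0,
    f_hi: float = 80.0,
    tol: float = 1e-6,
) -> dict:
    """Compare the PV->Pyr flow direction between the two series.

    Per band, reports the mean dPLI(PV->Pyr) for every ratio of each series;
    the verdict compares the two series at the given ratio averaged over the
    beta/gamma bands: "reversal" if the PV-series mean exceeds 0.5 while the
    SOM-series mean falls below it, "no lead" if both sit at 0.5 (within
    ``tol``), else "partial".
    """
    report: dict = {"per_band": [], "flags": []}
    for series in ("pv", "som"):
        if series not in bundles:
            report["flags"].append(f"missing series: {series}")
    present = {s: b for s, b in bundles.items() if s in ("pv", "som")}

    any_bundle = next(iter(present.values()))
    any_cond = next(iter(any_bundle.conditions.values()))
    for i, m in enumerate(any_cond.flow["PV"]):
        row: dict = {"band": m.band.as_tuple()}
        for series, bundle in present.items():
            row[series] = {
                r: c.flow["PV"][i].mean_dpli for r, c in sorted(bundle.conditions.items())
            }
        report["per_band"].append(row)

    if len(present) == 2 and all(
        ratio in b.conditions for b in present.values()
    ):
        pv_mean = present["pv"].conditions[ratio].mean_dpli("PV", f_lo, f_hi)
        som_mean = present["som"].conditions[ratio].mean_dpli("PV", f_lo, f_hi)
        report["comparison_ratio"] = ratio
        report["pv_series_mean_dpli"] = pv_mean
        report["som_series_mean_dpli"] = som_mean
        if abs(pv_mean - 0.5) <= tol and abs(som_mean - 0.5) <= tol:
            report["verdict"] = "no lead"
        elif pv_mean > 0.5 and som_mean < 0.5:
            report["verdict"] = "reversal"
        else:
            report["verdict"] = "partial"
    else:
        report["verdict"] = "incomplete"
    return report
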
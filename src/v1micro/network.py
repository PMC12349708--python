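"""Microcircuit construction: population sizing, connectivity, weights, delays.

The E/I ratio of a condition is defined as the Pyr count divided by the
combined count of all inhibitory interneurons.  A condition series varies one
interneuron subtype (PV or SOM) against the Pyr population while the two
remaining subtypes and the network total stay fixed, so "converting" PV cells
into Pyr cells raises the E/I ratio without changing network size.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .params import (
    CONTROL_SIZES,
    TOTAL_NEURONS,
    CellClass,
    ConnectivityRule,
    LogNormalWeightParams,
    Parameters,
    DELAY_D0,
    default_parameters,
)

__all__ = [
    "PopulationSizes",
    "NetworkModel",
    "size_populations",
    "build_connectivity",
    "sample_excitatory_weights",
    "sample_gaussian_weights",
    "sample_delays",
]

_CLASSES = (CellClass.PYR, CellClass.PV, CellClass.SOM, CellClass.VIP)


@dataclass(frozen=True)
class PopulationSizes:
    """Per-class neuron counts of one E/I condition."""

    n_pyr: int
    n_pv: int
    n_som: int
    n_vip: int

    def __post_init__(self) -> None:
        if min(self.n_pyr, self.n_pv, self.n_som, self.n_vip) < 0:
            raise ValueError("population counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_pyr + self.n_pv + self.n_som + self.n_vip

    @property
    def n_inhibitory(self) -> int:
        return self.n_pv + self.n_som + self.n_vip

    @property
    def ei_ratio(self) -> float:
        return self.n_pyr / self.n_inhibitory

    def count(self, cls: CellClass) -> int:
        return (self.n_pyr, self.n_pv, self.n_som, self.n_vip)[int(cls)]

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_pyr, self.n_pv, self.n_som, self.n_vip)

    def scaled(self, scale: float) -> "PopulationSizes":
        """Proportionally scaled census (counts rounded, used for test runs)."""
        if scale <= 0:
            raise ValueError("scale must be positive")
        return PopulationSizes(*(int(round(n * scale)) for n in self.as_tuple()))

    def block_slice(self, cls: CellClass) -> slice:
        """Index range of a class in the contiguous Pyr|PV|SOM|VIP id layout."""
        offsets = np.cumsum((0,) + self.as_tuple())
        return slice(int(offsets[int(cls)]), int(offsets[int(cls) + 1]))

    def class_of(self) -> np.ndarray:
        """Class index (0..3) of every neuron id."""
        return np.repeat(np.arange(4, dtype=np.int8), self.as_tuple())


_CONTROL = PopulationSizes(*CONTROL_SIZES)


def size_populations(
    ratio: float,
    varied: "CellClass | str",
    total: int = TOTAL_NEURONS,
    fixed_counts: "dict[CellClass | str, int] | None" = None,
) -> PopulationSizes:
    """Population census achieving a target E/I ratio at fixed network size.

    The Pyr count is ``round(total * r / (1 + r))`` (half away from zero) and
    the varied interneuron subtype absorbs the integer remainder, with the two
    non-varied subtypes held at the counts given in ``fixed_counts`` (default:
    the control census).  The control census itself (ratio 3.5 at the default
    total and fixed counts) is returned as printed rather than re-derived,
    since it is the anchor the conversion series is defined against; its
    achieved ratio is ~3.546, which rounds to 3.5.

    Raises
    ------
    ValueError
        If the varied subtype count would be negative (infeasible target).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if ratio <= 0:
        raise ValueError("E/I ratio must be positive")
    varied = CellClass.from_name(varied)
    if varied not in (CellClass.PV, CellClass.SOM):
        raise ValueError("the varied subtype must be PV or SOM")

    fixed = {
        c: _CONTROL.count(c)
        for c in (CellClass.PV, CellClass.SOM, CellClass.VIP)
        if c != varied
    }
    if fixed_counts:
        for k, v in fixed_counts.items():
            k = CellClass.from_name(k)
            if k == varied or k == CellClass.PYR:
                raise ValueError(f"{k.name} is not a fixed class for this series")
            fixed[k] = int(v)

    # Control anchor: the printed census, not the rounding rule.
    if (
        abs(ratio - 3.5) < 1e-9
        and total == _CONTROL.n_total
        and all(fixed[c] == _CONTROL.count(c) for c in fixed)
    ):
        return _CONTROL

    n_pyr = int(np.floor(total * ratio / (1.0 + ratio) + 0.5))
    n_varied = total - n_pyr - sum(fixed.values())
    if n_varied < 0:
        raise ValueError(
            f"target ratio {ratio} infeasible: {varied.name} count would be "
            f"{n_varied} with total {total} and fixed counts {fixed}"
        )
    counts = {CellClass.PYR: n_pyr, varied: n_varied, **fixed}
    return PopulationSizes(*(counts[c] for c in _CLASSES))


def sample_excitatory_weights(
    n: int,
    params: "LogNormalWeightParams | None" = None,
    rng: "np.random.Generator | int | None" = None,
) -> np.ndarray:
    """Draw Pyr->Pyr conductances (nS) from the long-tailed log-normal law."""
    if n < 0:
        raise ValueError("n must be non-negative")
    params = params or LogNormalWeightParams()
    rng = np.random.default_rng(rng)
    return rng.lognormal(mean=params.mu, sigma=params.sigma, size=n)


def sample_gaussian_weights(
    n: int,
    mean: float,
    sd: float,
    rng: "np.random.Generator | int | None" = None,
) -> np.ndarray:
    """Gaussian conductance draws (nS), redrawn until strictly positive.

    At the model's 10% coefficient of variation the truncation is a ~1e-23
    tail event, so the sample mean is preserved to first order.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(rng)
    w = rng.normal(mean, sd, size=n)
    bad = w <= 0
    while bad.any():
        w[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = w <= 0
    return w


def sample_delays(
    pre_class: "CellClass | str",
    n: int,
    rng: "np.random.Generator | int | None" = None,
) -> np.ndarray:
    """Synaptic delays (ms): Gaussian(d0, d0/10), truncated strictly positive.

    d0 is 2.0 ms for excitatory presynaptic neurons and 1.0 ms for all
    inhibitory subtypes.
    """
    pre_class = CellClass.from_name(pre_class)
    d0 = DELAY_D0[pre_class]
    rng = np.random.default_rng(rng)
    d = rng.normal(d0, np.sqrt(d0 / 10.0), size=n)
    bad = d <= 0
    while bad.any():
        d[bad] = rng.normal(d0, np.sqrt(d0 / 10.0), size=int(bad.sum()))
        bad = d <= 0
    return d


@dataclass
class NetworkModel:
    """A sampled microcircuit: edge list plus census.

    Edges are stored columnar and sorted by presynaptic id; weights in nS,
    delays in ms.  Neuron ids are contiguous per class (Pyr, PV, SOM, VIP).
    """

    sizes: PopulationSizes
    pre: np.ndarray  # int32 presynaptic ids
    post: np.ndarray  # int32 postsynaptic ids
    weight: np.ndarray  # float64 nS
    delay: np.ndarray  # float64 ms
    seed: "int | None" = None

    def __post_init__(self) -> None:
        self.class_of = self.sizes.class_of()
        if len(self.pre):
            if (self.pre == self.post).any():
                raise ValueError("self-connections are not allowed")
            if (self.weight <= 0).any() or (self.delay <= 0).any():
                raise ValueError("weights and delays must be strictly positive")

    @property
    def n_edges(self) -> int:
        return len(self.pre)

    def edge_count(self, pre: CellClass, post: CellClass) -> int:
        mask = (self.class_of[self.pre] == int(pre)) & (
            self.class_of[self.post] == int(post)
        )
        return int(mask.sum())

    def tau_decay_of_pair(self) -> np.ndarray:
        """(4, 4) table of decay time constants indexed [post_class, pre_class];
        NaN where the projection does not exist."""
        tab = np.full((4, 4), np.nan)
        for r in default_parameters().rules:
            tab[int(r.post), int(r.pre)] = r.tau_decay
        return tab

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path: "str | Path") -> None:
        """Plain-text edge list with a JSON metadata header line."""
        meta = {"sizes": self.sizes.as_tuple(), "seed": self.seed}
        with open(path, "w") as fh:
            fh.write(f"# {json.dumps(meta)}\n")
            fh.write("pre_id\tpost_id\tweight_nS\tdelay_ms\n")
            np.savetxt(
                fh,
                np.column_stack([self.pre, self.post, self.weight, self.delay]),
                fmt=["%d", "%d", "%.9g", "%.9g"],
                delimiter="\t",
            )

    @classmethod
    def from_tsv(cls, path: "str | Path") -> "NetworkModel":
        text = Path(path).read_text()
        header, rest = text.split("\n", 1)
        meta = json.loads(header.lstrip("# "))
        data = np.loadtxt(io.StringIO(rest), skiprows=1, ndmin=2)
        if data.size == 0:
            data = data.reshape(0, 4)
        return cls(
            sizes=PopulationSizes(*meta["sizes"]),
            pre=data[:, 0].astype(np.int32),
            post=data[:, 1].astype(np.int32),
            weight=data[:, 2].copy(),
            delay=data[:, 3].copy(),
            seed=meta.get("seed"),
        )

    def save_npz(self, path: "str | Path") -> None:
        np.savez_compressed(
            path,
            sizes=np.asarray(self.sizes.as_tuple()),
            pre=self.pre,
            post=self.post,
            weight=self.weight,
            delay=self.delay,
            seed=np.asarray(-1 if self.seed is None else self.seed),
        )

    @classmethod
    def load_npz(cls, path: "str | Path") -> "NetworkModel":
        z = np.load(path)
        seed = int(z["seed"])
        return cls(
            sizes=PopulationSizes(*z["sizes"].tolist()),
            pre=z["pre"],
            post=z["post"],
            weight=z["weight"],
            delay=z["delay"],
            seed=None if seed < 0 else seed,
        )


def _bernoulli_pairs(
    n_pre: int,
    n_post: int,
    p: float,
    rng: np.random.Generator,
    exclude_diagonal: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the Bernoulli(p) hits in an n_pre x n_post matrix, sampled in
    row chunks to bound memory; draw order is row-major so results do not
    depend on the chunk size."""
    if p <= 0 or n_pre == 0 or n_post == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    chunk = max(1, 4_000_000 // max(n_post, 1))
    for start in range(0, n_pre, chunk):
        stop = min(start + chunk, n_pre)
        hits = rng.random((stop - start, n_post)) < p
        if exclude_diagonal:
            d = np.arange(start, stop)
            hits[d - start, d] = False
        r, c = np.nonzero(hits)
        rows.append(r + start)
        cols.append(c)
    return np.concatenate(rows), np.concatenate(cols)


def build_connectivity(
    sizes: PopulationSizes,
    rules: "tuple[ConnectivityRule, ...] | None" = None,
    seed: "int | np.random.Generator | None" = None,
    params: "Parameters | None" = None,
) -> NetworkModel:
    """Sample a microcircuit realization.

    Each allowed ordered (pre, post) class pair is wired with independent
    Bernoulli draws at the rule's effective probability; autapses are
    excluded.  Weights follow the rule's law (log-normal for Pyr->Pyr,
    positive-truncated Gaussian otherwise) and delays the presynaptic-class
    delay law.
    """
    params = params or default_parameters()
    rules = rules if rules is not None else params.rules
    rng = np.random.default_rng(seed)

    offsets = np.cumsum((0,) + sizes.as_tuple())
    pre_l, post_l, w_l, d_l = [], [], [], []
    for rule in rules:
        n_pre = sizes.count(rule.pre)
        n_post = sizes.count(rule.post)
        r, c = _bernoulli_pairs(
            n_pre, n_post, rule.probability, rng, exclude_diagonal=rule.pre == rule.post
        )
        n_edges = len(r)
        if rule.weight_law == "log_normal":
            w = sample_excitatory_weights(n_edges, params.ee_weights, rng)
        else:
            w = sample_gaussian_weights(n_edges, rule.g_mean, rule.g_sd, rng)
        d = sample_delays(rule.pre, n_edges, rng)
        pre_l.append(r + offsets[int(rule.pre)])
        post_l.append(c + offsets[int(rule.post)])
        w_l.append(w)
        d_l.append(d)

    pre = np.concatenate(pre_l).astype(np.int32)
    post = np.concatenate(post_l).astype(np.int32)
    weight = np.concatenate(w_l)
    delay = np.concatenate(d_l)
    order = np.argsort(pre, kind="stable")
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return NetworkModel(
        sizes=sizes,
        pre=pre[order],
        post=post[order],
        weight=weight[order],
        delay=delay[order],
        seed=seed_val,
    )
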
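"""Build a microcircuit and inspect its composition.

Constructs the control network (E/I ratio 3.5:1) at 10% scale and prints the
census, the per-projection edge counts against their Bernoulli expectations,
and the moments of the sampled synaptic weights.
"""

import numpy as np

import v1micro as vm
from v1micro.params import CellClass, CONNECTIVITY_RULES

sizes = vm.condition_sizes("pv", 3.5, scale=0.1)
net = vm.build_connectivity(sizes, seed=1)

print(f"census (Pyr, PV, SOM, VIP): {sizes.as_tuple()}  total {sizes.n_total}")
print(f"achieved E/I ratio: {sizes.ei_ratio:.3f}")
print(f"total synapses: {net.n_edges}\n")

print(f"{'projection':>12} {'edges':>8} {'expected':>9}")
for rule in CONNECTIVITY_RULES:
    n_pairs = sizes.count(rule.pre) * sizes.count(rule.post)
    if rule.pre == rule.post:
        n_pairs -= sizes.count(rule.pre)
    obs = net.edge_count(rule.pre, rule.post)
    print(f"{rule.pre.name:>5}->{rule.post.name:<5} {obs:>8} "
          f"{rule.probability * n_pairs:>9.0f}")

# Pyr->Pyr weights are log-normal (long-tailed); all others Gaussian
mask = (net.class_of[net.pre] == CellClass.PYR) & (
    net.class_of[net.post] == CellClass.PYR
)
w = net.weight[mask]
print(f"\nPyr->Pyr weights: median {np.median(w):.3f} nS "
      f"(theory exp(mu) = {np.exp(1 + np.log(0.1)):.3f}), mean {w.mean():.3f} nS")
print("Each projection that is absent above (e.g. VIP->Pyr) carries no "
      "synapses by construction.")
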
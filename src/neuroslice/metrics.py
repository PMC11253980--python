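"""Topology summaries: density, degree sequences, synaptic strength.

Density is the fraction of realized directed links, ρ = E / (N(N−1)) with
E the number of ordered pairs (i, j), i ≠ j, having w_ij > 0.  Degrees are
unweighted (binarized) in/out counts; "synaptic strength" is the contact
count w_ij of a realized edge.  Ensemble statistics are means and sample
standard deviations (n−1) across independently generated networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .topology import SynapticNetwork


def network_density(net: SynapticNetwork) -> float:
    if net.N < 2:
        raise ValueError("density needs N >= 2")
    return net.weights.nnz / (net.N * (net.N - 1))


def degree_sequences(net: SynapticNetwork):
    """(k_in, k_out) per neuron from the binarized weight matrix."""
    A = net.weights.astype(bool)
    k_out = np.asarray(A.sum(axis=1)).ravel().astype(int)
    k_in = np.asarray(A.sum(axis=0)).ravel().astype(int)
    return k_in, k_out


def strength_distribution(net: SynapticNetwork):
    """Histogram (integer bins) and mean of w_ij over realized edges."""
    w = net.weights.data
    w = w[w > 0]
    if w.size == 0:
        raise ValueError("network has no edges")
    values, counts = np.unique(w, return_counts=True)
    return {"values": values.astype(int), "counts": counts.astype(int),
            "mean": float(w.mean())}


@dataclass
class TopologySummary:
    """Per-network measures plus ensemble mean/SD for each."""

    n_networks: int
    density: np.ndarray
    mean_degree: np.ndarray
    mean_strength: np.ndarray
    density_mean: float = field(init=False)
    density_sd: float = field(init=False)
    degree_mean: float = field(init=False)
    degree_sd: float = field(init=False)
    strength_mean: float = field(init=False)
    strength_sd: float = field(init=False)

    def __post_init__(self):
        for name in ("density", "mean_degree", "mean_strength"):
            x = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, x)
            prefix = {"density": "density", "mean_degree": "degree",
                      "mean_strength": "strength"}[name]
            setattr(self, f"{prefix}_mean", float(np.mean(x)))
            setattr(self, f"{prefix}_sd",
                    float(np.std(x, ddof=1)) if len(x) > 1 else 0.0)

    def to_json(self) -> str:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in asdict(self).items()}
        return json.dumps(d, indent=1)


def ensemble_summary(nets) -> TopologySummary:
    """Mean and sample SD of density / mean degree / mean strength across networks.

    The reported "average degree" is the mean in-degree (equal to the mean
    out-degree by the handshake identity).
    """
    nets = list(nets)
    if len(nets) < 2:
        raise ValueError("ensemble summary needs at least 2 networks")
    dens, degs, strs = [], [], []
    for net in nets:
        dens.append(network_density(net))
        k_in, _ = degree_sequences(net)
        degs.append(float(np.mean(k_in)))
        strs.append(strength_distribution(net)["mean"])
    return TopologySummary(len(nets), np.array(dens), np.array(degs),
                           np.array(strs))
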
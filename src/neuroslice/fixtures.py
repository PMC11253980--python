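"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be emulated here: radial morphology
profiles drawn from the fitted functional forms plus noise (for recovery
tests), miniature hand-specified weighted networks (for metrics and
dynamics tests), and canned spike rasters (for the analysis module).  Truth
parameters are returned alongside each artifact so recovery tests can close
the loop, and every artifact serializes through the same file formats the
pipeline uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .morphology import (MorphologyConstants, GenotypeParams, RadialProfile,
                         WT_CONSTANTS, branch_density, spine_density, scp)
from .topology import NeuronGeometry, SynapticNetwork


def make_radial_profile(kind: str, radii, truth: dict | None = None,
                        noise_sd: float = 0.0, mult_noise: float = 0.0,
                        seed: int = 0,
                        consts: MorphologyConstants = WT_CONSTANTS):
    """Radial profile drawn from a generating curve plus optional noise.

    kind ∈ {"sholl", "spine", "scp"}: branch density a·r·exp(−b·r⁴), the
    degree-6 spine polynomial, or the genotype-scaled SCP.  ``truth``
    overrides the generating parameters (keys: a, b / c / alpha, beta).
    Additive Gaussian noise (sd ``noise_sd``) and multiplicative noise
    (relative sd ``mult_noise``) are applied, then values are clipped at 0.

    Returns (RadialProfile, truth_dict).
    """
    radii = np.asarray(radii, dtype=float)
    truth = dict(truth or {})
    if kind == "sholl":
        a = truth.setdefault("a", consts.a)
        b = truth.setdefault("b", consts.b)
        c = MorphologyConstants(a=a, b=b, c=consts.c, gamma=consts.gamma)
        values = branch_density(radii, c)
    elif kind == "spine":
        coef = np.asarray(truth.setdefault("c", consts.c), dtype=float)
        c = MorphologyConstants(a=consts.a, b=consts.b, c=tuple(coef),
                                gamma=consts.gamma)
        values = spine_density(radii, c, clamp=False)
    elif kind == "scp":
        alpha = truth.setdefault("alpha", 1.0)
        beta = truth.setdefault("beta", 1.0)
        values = scp(radii, GenotypeParams("truth", alpha, beta), consts)
    else:
        raise ValueError(f"unknown profile kind: {kind}")
    rng = np.random.default_rng(seed)
    if mult_noise > 0:
        values = values * (1.0 + mult_noise * rng.standard_normal(len(radii)))
    if noise_sd > 0:
        values = values + noise_sd * rng.standard_normal(len(radii))
    values = np.clip(values, 0.0, None)
    return RadialProfile(radii, values), truth


def _dummy_geometry(N: int, spacing: float = 50.0):
    side = int(np.ceil(np.sqrt(N)))
    geo = []
    for i in range(N):
        xy = np.array([(i % side) * spacing, (i // side) * spacing])
        geo.append(NeuronGeometry(xy, 25.0, np.empty((0, 2), dtype=np.int64)))
    return geo


def make_toy_network(N: int, pattern: str = "cycle", weight: int = 1,
                     p: float = 0.1, seed: int = 0,
                     genotype: GenotypeParams | None = None) -> SynapticNetwork:
    """Small hand-specified weighted digraph (no autapses, dummy geometry).

    pattern ∈ {"chain", "cycle", "all_to_all", "random"}; "random" is an
    Erdős–Rényi digraph with edge probability ``p``.
    """
    if N < 2:
        raise ValueError("need N >= 2")
    rows, cols = [], []
    if pattern == "chain":
        rows = list(range(N - 1))
        cols = list(range(1, N))
    elif pattern == "cycle":
        rows = list(range(N))
        cols = [(i + 1) % N for i in range(N)]
    elif pattern == "all_to_all":
        for i in range(N):
            for j in range(N):
                if i != j:
                    rows.append(i)
                    cols.append(j)
    elif pattern == "random":
        rng = np.random.default_rng(seed)
        mask = rng.random((N, N)) < p
        np.fill_diagonal(mask, False)
        rows, cols = np.nonzero(mask)
    else:
        raise ValueError(f"unknown pattern: {pattern}")
    data = np.full(len(rows), weight, dtype=np.int64)
    W = sp.csr_matrix((data, (rows, cols)), shape=(N, N), dtype=np.int64)
    genotype = genotype or GenotypeParams("custom", 1.0, 1.0)
    return SynapticNetwork(N, W, _dummy_geometry(N), genotype, seed)


def make_spike_train(kind: str = "periodic", duration: float = 1000.0,
                     period: float = 25.0, rate_hz: float = 10.0,
                     N: int = 1, seed: int = 0, t_transient: float = 0.0,
                     excitatory: bool = True):
    """Canned SpikeRaster: periodic (fixed period, ms) or Poisson (rate, Hz).

    Poisson trains are generated independently per neuron via exponential
    inter-event times; labels are all-excitatory or all-inhibitory.
    """
    from .dynamics import SpikeRaster

    if duration <= 0:
        raise ValueError("duration must be positive")
    times, ids = [], []
    rng = np.random.default_rng(seed)
    for i in range(N):
        if kind == "periodic":
            tt = np.arange(t_transient + period, duration + 1e-9, period)
        elif kind == "poisson":
            n_max = int(rate_hz / 1000.0 * (duration - t_transient) * 3 + 100)
            gaps = rng.exponential(1000.0 / rate_hz, n_max)
            tt = t_transient + np.cumsum(gaps)
            tt = tt[tt <= duration]
        else:
            raise ValueError(f"unknown spike-train kind: {kind}")
        times.append(tt)
        ids.append(np.full(len(tt), i, dtype=int))
    times = np.concatenate(times) if times else np.empty(0)
    ids = np.concatenate(ids) if ids else np.empty(0, dtype=int)
    order = np.argsort(times, kind="stable")
    ei = np.full(N, bool(excitatory))
    return SpikeRaster(times[order], ids[order], ei, duration, t_transient,
                       0.1, N)
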
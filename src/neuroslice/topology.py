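"""Stochastic 2D cortical-slice topology generation.

A network realization proceeds in four stages, all on a periodic (toroidal)
square of side L with a 1 μm grid:

1. soma placement — uniform positions, rejection-sampled so no two somas
   overlap (pairwise minimal-image distance ≥ 2·soma_radius);
2. dendritic fields — circular, radius drawn from a Gaussian with
   genotype-dependent mean R̄ and spread σ, truncated to exceed the soma;
3. axon growth — a biased random walk: 10 μm straight segments, heading
   increment Gaussian(0, π/30) per segment, total length Rayleigh with mean
   500 μm, rasterized to one cell per μm of arc length;
4. synapse formation — each axon cell lying inside another neuron's
   dendritic annulus (outside its soma) forms a contact with probability
   SCP(r; α, β), r the minimal-image distance from the cell to that soma.
   Contact counts w_ij (i presynaptic) form a directed, integer-weighted
   network; autapses are forbidden.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .morphology import (MorphologyConstants, GenotypeParams, WT_CONSTANTS,
                         GENOTYPES, scp)
from ._kernels import synapses_for_axon, scp_lookup

#: resolution of the tabulated SCP used for Bernoulli trials (μm)
SCP_TABLE_DR = 0.25


@dataclass
class TopologyConfig:
    """Geometry and growth parameters of the slice model (defaults: WT paper values)."""

    N: int = 3037
    L: float = 1500.0
    soma_radius: float = 8.0
    dend_mean: float = 156.30
    dend_sd: float = 40.0
    axon_step: float = 10.0
    axon_angle_sd: float = np.pi / 30.0
    axon_mean_length: float = 500.0
    grid_resolution: float = 1.0
    max_rejections: int = 1_000_000

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if not (0 < self.soma_radius < self.dend_mean):
            raise ValueError("need 0 < soma_radius < dend_mean")
        if abs(self.L / self.grid_resolution - round(self.L / self.grid_resolution)) > 1e-9:
            raise ValueError("grid_resolution must divide L")
        if self.N * np.pi * self.soma_radius**2 >= 0.9 * self.L**2:
            raise ValueError("infeasible soma packing: N·π·R_s² ≥ 0.9·L²")


@dataclass
class NeuronGeometry:
    soma_xy: np.ndarray          # (2,) position, μm
    dend_radius: float           # μm
    axon_path: np.ndarray        # (M, 2) integer grid cells


@dataclass
class SynapticNetwork:
    """Directed integer-weighted connectivity plus the generating geometry.

    ``weights`` is an N×N CSR matrix with w[i, j] = number of synaptic
    contacts from presynaptic i onto postsynaptic j (zero diagonal).
    """

    N: int
    weights: sp.csr_matrix
    geometry: list
    genotype: GenotypeParams
    seed: int | None = None

    def weight_map(self) -> dict:
        """Sparse map {(i, j): w_ij} over realized contacts."""
        coo = self.weights.tocoo()
        return {(int(i), int(j)): int(w)
                for i, j, w in zip(coo.row, coo.col, coo.data)}


def _min_image_dist(p, q, L):
    d = p - q
    d -= L * np.round(d / L)
    return np.hypot(d[..., 0], d[..., 1])


def place_somas(config: TopologyConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform non-overlapping soma centers on the torus (sequential rejection).

    A coarse spatial hash keeps each insertion O(1); raises if the rejection
    budget is exhausted (infeasible packing).
    """
    L, rs, N = config.L, config.soma_radius, config.N
    min_d2 = (2.0 * rs) ** 2
    nb = max(1, int(L // max(2.0 * rs, 1.0)))
    bs = L / nb
    buckets = [[] for _ in range(nb * nb)]
    pos = np.empty((N, 2))
    rejections = 0
    k = 0
    while k < N:
        p = rng.random(2) * L
        bx, by = int(p[0] / bs), int(p[1] / bs)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for idx in buckets[((bx + dx) % nb) * nb + ((by + dy) % nb)]:
                    d = pos[idx] - p
                    d -= L * np.round(d / L)
                    if d[0] * d[0] + d[1] * d[1] < min_d2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pos[k] = p
            buckets[bx * nb + by].append(k)
            k += 1
        else:
            rejections += 1
            if rejections > config.max_rejections:
                raise RuntimeError("soma packing infeasible: rejection budget exhausted")
    return pos


def sample_dendrite_radii(config: TopologyConfig, rng: np.random.Generator,
                          n: int | None = None) -> np.ndarray:
    """Gaussian dendritic radii, resampled until they exceed the soma radius."""
    n = config.N if n is None else n
    if config.dend_sd == 0:
        return np.full(n, config.dend_mean)
    r = rng.normal(config.dend_mean, config.dend_sd, n)
    bad = r <= config.soma_radius
    while np.any(bad):
        r[bad] = rng.normal(config.dend_mean, config.dend_sd, int(bad.sum()))
        bad = r <= config.soma_radius
    return r


def grow_axon(start, config: TopologyConfig, rng: np.random.Generator) -> np.ndarray:
    """Biased-random-walk axon, rasterized to one grid cell per μm of length.

    Heading starts uniform on [0, 2π) and gains a Gaussian(0, axon_angle_sd)
    increment every ``axon_step`` μm; total length is Rayleigh with mean
    ``axon_mean_length``.  Returns the ordered (M, 2) integer cell list with
    consecutive duplicates removed; coordinates wrap periodically.
    """
    L = config.L
    sigma_r = config.axon_mean_length / np.sqrt(np.pi / 2.0)
    total = rng.rayleigh(sigma_r)
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    n_seg = int(np.ceil(total / config.axon_step))
    if n_seg == 0:
        return np.empty((0, 2), dtype=np.int64)
    dthetas = (rng.normal(0.0, config.axon_angle_sd, n_seg)
               if config.axon_angle_sd > 0 else np.zeros(n_seg))
    dthetas[0] = 0.0
    headings = theta0 + np.cumsum(dthetas)
    seg_lens = np.full(n_seg, config.axon_step)
    seg_lens[-1] = total - config.axon_step * (n_seg - 1)
    # vertices of the polyline (unwrapped)
    steps = np.column_stack([seg_lens * np.cos(headings),
                             seg_lens * np.sin(headings)])
    verts = np.vstack([np.asarray(start, dtype=float),
                       np.asarray(start, dtype=float) + np.cumsum(steps, axis=0)])
    # sample the polyline at 1 μm arc-length intervals
    cum = np.concatenate([[0.0], np.cumsum(seg_lens)])
    s = np.arange(0.0, total + 1e-9, 1.0)
    seg_idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, n_seg - 1)
    f = (s - cum[seg_idx]) / seg_lens[seg_idx]
    pts = verts[seg_idx] + f[:, None] * (verts[seg_idx + 1] - verts[seg_idx])
    pts %= L
    cells = np.floor(pts).astype(np.int64)
    keep = np.ones(len(cells), dtype=bool)
    keep[1:] = np.any(cells[1:] != cells[:-1], axis=1)
    return cells[keep]


def scp_table(genotype: GenotypeParams,
              consts: MorphologyConstants = WT_CONSTANTS,
              r_max: float | None = None,
              dr: float = SCP_TABLE_DR) -> np.ndarray:
    """Tabulate the genotype's SCP(r) on a regular grid for trial lookups.

    The table extends past the support (r > β·r_support/γ), where entries
    are zero, so any in-annulus distance can be looked up safely.
    """
    if r_max is None:
        r_max = genotype.beta * consts.r_support / consts.gamma + 2.0
    r = np.arange(0.0, r_max + dr, dr)
    vals = np.zeros_like(r)
    vals[1:] = scp(r[1:], genotype, consts)
    return vals


def _soma_bins(soma_xy: np.ndarray, dend_radii: np.ndarray, L: float,
               bin_size_target: float = 64.0):
    """Periodic coverage index: neuron j sits in every bin its disk touches.

    An axon cell then only needs to inspect its own bin to see every neuron
    whose dendritic disk could contain it.
    """
    n = soma_xy.shape[0]
    nb = max(1, int(L // bin_size_target))
    bs = L / nb
    bin_ids, items = [], []
    for j in range(n):
        sx, sy = soma_xy[j]
        r = dend_radii[j]
        kmax = int(r / bs) + 1
        if 2 * kmax + 1 >= nb:
            bxs = np.arange(nb)
            bys = np.arange(nb)
        else:
            bxs = (int(sx / bs) + np.arange(-kmax, kmax + 1)) % nb
            bys = (int(sy / bs) + np.arange(-kmax, kmax + 1)) % nb
        cx = (bxs + 0.5) * bs
        cy = (bys + 0.5) * bs
        ddx = np.abs(sx - cx)
        ddx = np.minimum(ddx, L - ddx)
        ddy = np.abs(sy - cy)
        ddy = np.minimum(ddy, L - ddy)
        gx = np.maximum(ddx - bs / 2.0, 0.0)
        gy = np.maximum(ddy - bs / 2.0, 0.0)
        # distance from the soma to the nearest point of each bin rectangle
        gap2 = gx[:, None] ** 2 + gy[None, :] ** 2
        keep_x, keep_y = np.nonzero(gap2 <= r * r)
        bins = bxs[keep_x] * nb + bys[keep_y]
        bin_ids.append(bins)
        items.append(np.full(len(bins), j, dtype=np.int64))
    bin_ids = np.concatenate(bin_ids)
    items = np.concatenate(items)
    order = np.argsort(bin_ids, kind="stable")
    bin_ids, items = bin_ids[order], items[order]
    start = np.zeros(nb * nb + 1, dtype=np.int64)
    np.add.at(start, bin_ids + 1, 1)
    start = np.cumsum(start)
    return start, items, nb, bs


def establish_synapses(axon_owner: int, axon_path: np.ndarray,
                       soma_xy: np.ndarray, dend_radii: np.ndarray,
                       genotype: GenotypeParams,
                       consts: MorphologyConstants,
                       config: TopologyConfig, seed: int,
                       table: np.ndarray | None = None,
                       bins=None):
    """Synaptic contacts of one axon: list of (target j, contact count).

    One Bernoulli(SCP(r; α, β)) trial per axon cell per neuron whose
    dendritic annulus (soma_radius, dend_radius_j] contains the cell; trials
    consume a per-neuron RNG stream seeded with ``seed``.
    """
    if table is None:
        table = scp_table(genotype, consts)
    if bins is None:
        bins = _soma_bins(soma_xy, dend_radii, config.L)
    bin_start, bin_items, nb, bs = bins
    if axon_path.shape[0] == 0:
        return []
    js, ws = synapses_for_axon(
        axon_owner, np.ascontiguousarray(axon_path, dtype=np.int64),
        np.ascontiguousarray(soma_xy), np.ascontiguousarray(dend_radii),
        float(config.soma_radius), float(config.L),
        bin_start, bin_items, nb, bs,
        table, SCP_TABLE_DR, seed)
    return list(zip(js.tolist(), ws.tolist()))


def establish_synapses_bruteforce(axon_owner, axon_path, soma_xy, dend_radii,
                                  genotype, consts, config, seed,
                                  table=None):
    """All-pairs reference implementation (numpy RandomState, same stream).

    Used only for validation at small N: loops over every axon cell and
    every target in ascending index order, consuming identical uniforms to
    the spatially-indexed fast path.
    """
    if table is None:
        table = scp_table(genotype, consts)
    rs = np.random.RandomState(seed)
    n = soma_xy.shape[0]
    counts = np.zeros(n, dtype=int)
    L = config.L
    for cell in axon_path:
        c = cell + 0.5
        d = _min_image_dist(c[None, :], soma_xy, L)
        for j in range(n):
            if j == axon_owner:
                continue
            if config.soma_radius < d[j] <= dend_radii[j]:
                p = scp_lookup(d[j], table, SCP_TABLE_DR)
                if rs.random_sample() < p:
                    counts[j] += 1
    return [(j, int(counts[j])) for j in range(n) if counts[j] > 0]


def generate_network(config: TopologyConfig,
                     genotype: GenotypeParams = GENOTYPES["WT"],
                     consts: MorphologyConstants = WT_CONSTANTS,
                     seed: int = 0,
                     _bruteforce: bool = False) -> SynapticNetwork:
    """Full topology realization, reproducible from ``seed``.

    Per-neuron synapse trials use independent child streams of the master
    seed, so the generation order of neurons cannot change the result.
    """
    ss = np.random.SeedSequence(seed)
    ss_place, ss_radii, ss_axon, ss_syn = ss.spawn(4)
    rng_place = np.random.default_rng(ss_place)
    rng_radii = np.random.default_rng(ss_radii)

    soma_xy = place_somas(config, rng_place)
    dend_radii = sample_dendrite_radii(config, rng_radii)
    axon_rngs = [np.random.default_rng(s) for s in ss_axon.spawn(config.N)]
    paths = [grow_axon(soma_xy[i], config, axon_rngs[i])
             for i in range(config.N)]
    syn_seeds = [int(s.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
                 for s in ss_syn.spawn(config.N)]

    table = scp_table(genotype, consts)
    bins = _soma_bins(soma_xy, dend_radii, config.L)
    rows, cols, data = [], [], []
    establish = (establish_synapses_bruteforce if _bruteforce
                 else establish_synapses)
    for i in range(config.N):
        kwargs = {} if _bruteforce else {"bins": bins}
        contacts = establish(i, paths[i], soma_xy, dend_radii, genotype,
                             consts, config, syn_seeds[i], table=table,
                             **kwargs)
        for j, w in contacts:
            rows.append(i)
            cols.append(j)
            data.append(w)
    W = sp.csr_matrix((data, (rows, cols)),
                      shape=(config.N, config.N), dtype=np.int64)
    geometry = [NeuronGeometry(soma_xy[i], float(dend_radii[i]), paths[i])
                for i in range(config.N)]
    return SynapticNetwork(config.N, W, geometry, genotype, seed)


# ---------------------------------------------------------------------------
# I/O: Matrix Market weights + JSON sidecar, TSV geometry


def save_network(net: SynapticNetwork, path, config: TopologyConfig | None = None):
    """Write weights as 1-based integer MTX plus a JSON sidecar."""
    path = Path(path)
    scipy.io.mmwrite(str(path.with_suffix(".mtx")), net.weights.tocoo(),
                     field="integer")
    sidecar = {
        "N": net.N,
        "genotype": {"name": net.genotype.name, "alpha": net.genotype.alpha,
                     "beta": net.genotype.beta, "R_wt": net.genotype.R_wt},
        "seed": net.seed,
    }
    if config is not None:
        sidecar["config"] = {k: (v if not isinstance(v, float) else float(v))
                             for k, v in asdict(config).items()}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_network(path) -> SynapticNetwork:
    path = Path(path)
    W = sp.csr_matrix(scipy.io.mmread(str(path.with_suffix(".mtx"))),
                      dtype=np.int64)
    meta = json.loads(path.with_suffix(".json").read_text())
    g = meta["genotype"]
    genotype = GenotypeParams(g["name"], g["alpha"], g["beta"],
                              g.get("R_wt", 156.30))
    return SynapticNetwork(meta["N"], W, [], genotype, meta.get("seed"))


def save_geometry(net: SynapticNetwork, path, ei_labels=None):
    """TSV geometry table: neuron_id, x_um, y_um, dend_radius_um[, is_excitatory]."""
    with open(path, "w") as fh:
        cols = "neuron_id\tx_um\ty_um\tdend_radius_um"
        if ei_labels is not None:
            cols += "\tis_excitatory"
        fh.write(cols + "\n")
        for i, g in enumerate(net.geometry):
            row = f"{i}\t{g.soma_xy[0]:.3f}\t{g.soma_xy[1]:.3f}\t{g.dend_radius:.3f}"
            if ei_labels is not None:
                row += f"\t{int(ei_labels[i])}"
            fh.write(row + "\n")
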
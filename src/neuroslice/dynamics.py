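"""Izhikevich spiking dynamics on a generated synaptic network.

Each neuron follows the two-variable quadratic integrate-and-fire model

    v̇ = 0.04 v² + 5 v + 140 − u + I_AMPA + I_GABA + I_ext
    u̇ = a (b v − u),

with spike threshold v ≥ 30 mV and reset v ← c, u ← u + d.  Excitatory
neurons (80%) use the regular-spiking preset, inhibitory ones (20%) the
fast-spiking preset.  Synaptic currents are conductance-based,
I = g (v_rev − v), with single-exponential conductances: a presynaptic
spike increments g of every postsynaptic neuron by g_syn · w after a fixed
delay τ0 = 1 ms, and g decays as exp(−t/τ).  Independent Poisson trains
(rate λ per neuron, in events/ms) drive the external AMPA conductance.

Integration is forward Euler at dt = 0.1 ms for the intrinsic terms, with
the synaptic current treated implicitly (total conductance can transiently
exceed 1/dt during population bursts, where a fully explicit step is
unstable); conductance decay is applied exactly via per-step multiplication
by exp(−dt/τ).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .topology import SynapticNetwork
from ._kernels import simulate_network


@dataclass(frozen=True)
class CellParams:
    """Izhikevich cell parameters (a: recovery rate, b: sensitivity, c: reset, d: increment)."""
    a: float
    b: float
    c: float
    d: float
    v_thr: float = 30.0


RS_CELL = CellParams(0.02, 0.2, -65.0, 8.0)   # regular spiking (pyramidal)
FS_CELL = CellParams(0.1, 0.2, -65.0, 2.0)    # fast spiking (interneuron)


@dataclass(frozen=True)
class SynapseParams:
    """One synaptic channel: per-contact conductance increment, decay, reversal."""
    g: float
    tau: float
    v_rev: float


SYNAPSE_DEFAULTS = {
    "ampa": SynapseParams(0.006, 2.0, 0.0),
    "gaba": SynapseParams(0.720, 4.0, -70.0),
    "ext": SynapseParams(0.008, 2.0, 0.0),
}

TAU0_MS = 1.0  # synaptic delay


@dataclass
class DynamicsConfig:
    """Simulation protocol: drive, E/I split, perturbation, integration grid."""

    lambda_ext: float = 9.0          # external Poisson rate per neuron (events/ms)
    frac_excitatory: float = 0.8
    ii_scale: float = 1.0            # multiplier on I→I GABA strength
    dt: float = 0.1                  # ms
    t_total: float = 2500.0          # ms simulated
    t_transient: float = 500.0       # ms discarded from the raster
    tau0: float = TAU0_MS
    delay_external: bool = False

    def __post_init__(self):
        if self.t_transient >= self.t_total:
            raise ValueError("t_transient must be < t_total")
        steps = self.tau0 / self.dt
        if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
            raise ValueError("tau0 must be a positive integer multiple of dt")
        if not (0 < self.frac_excitatory < 1):
            raise ValueError("frac_excitatory must lie in (0, 1)")
        if self.ii_scale <= 0:
            raise ValueError("ii_scale must be positive")


@dataclass
class SpikeRaster:
    """Spike events (time ms, neuron id) with E/I labels and the time window."""

    times: np.ndarray
    ids: np.ndarray
    ei_labels: np.ndarray        # True = excitatory
    t_total: float
    t_transient: float
    dt: float
    N: int

    def spike_trains(self):
        """Per-neuron sorted spike-time arrays."""
        trains = [[] for _ in range(self.N)]
        for t, i in zip(self.times, self.ids):
            trains[i].append(t)
        return [np.asarray(t) for t in trains]

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("time_ms\tneuron_id\tei_flag\n")
            for t, i in zip(self.times, self.ids):
                fh.write(f"{t:.4f}\t{int(i)}\t{'E' if self.ei_labels[i] else 'I'}\n")

    @classmethod
    def from_tsv(cls, path, N, t_total, t_transient, dt=0.1):
        times, ids, flags = [], [], {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                t, i, f = line.split("\t")
                times.append(float(t))
                ids.append(int(i))
                flags[int(i)] = f.strip() == "E"
        ei = np.ones(N, dtype=bool)
        for i, f in flags.items():
            ei[i] = f
        return cls(np.asarray(times), np.asarray(ids, dtype=int), ei,
                   t_total, t_transient, dt, N)


def assign_ei(N: int, frac_excitatory: float,
              rng: np.random.Generator) -> np.ndarray:
    """Random E/I identity with exactly round(frac·N) excitatory neurons."""
    if not (0 < frac_excitatory < 1):
        raise ValueError("frac_excitatory must lie in (0, 1)")
    n_exc = int(round(frac_excitatory * N))
    labels = np.zeros(N, dtype=bool)
    labels[:n_exc] = True
    return rng.permutation(labels)


def step_neuron(state, cell: CellParams, I_total: float, dt: float):
    """One forward-Euler step of a single cell; returns ((v, u), spiked)."""
    v, u = state
    if not (np.isfinite(v) and np.isfinite(u)):
        raise FloatingPointError("non-finite neuron state")
    vn = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I_total)
    un = u + dt * cell.a * (cell.b * v - u)
    if not np.isfinite(vn):
        raise FloatingPointError("integration blowup in step_neuron")
    if vn >= cell.v_thr:
        return (cell.c, un + cell.d), True
    return (vn, un), False


def scale_recurrent_inhibition(config: DynamicsConfig,
                               factor: float) -> DynamicsConfig:
    """Config with inhibitory→inhibitory GABA strength scaled by ``factor``."""
    if not (0 < factor <= 1):
        raise ValueError("factor must lie in (0, 1]")
    return replace(config, ii_scale=factor)


def simulate(net: SynapticNetwork, config: DynamicsConfig,
             cells=(RS_CELL, FS_CELL), syn=None, seed: int = 0,
             ei_labels: np.ndarray | None = None,
             record_conductance: int = -1):
    """Simulate the network; returns a SpikeRaster (plus conductance traces on request).

    ``seed`` controls the E/I assignment, the initial conditions
    v ~ U(−70, −60), u = b·v, and the external Poisson trains.  Spikes within
    the transient are discarded from the raster but still drive synapses.
    """
    syn = dict(SYNAPSE_DEFAULTS, **(syn or {}))
    N = net.N
    if net.weights.shape != (N, N):
        raise ValueError("network weight matrix does not match N")
    ss = np.random.SeedSequence(seed)
    ss_ei, ss_sim = ss.spawn(2)
    if ei_labels is None:
        ei_labels = assign_ei(N, config.frac_excitatory,
                              np.random.default_rng(ss_ei))
    ei_labels = np.asarray(ei_labels, dtype=bool)
    rs_cell, fs_cell = cells
    cell_a = np.where(ei_labels, rs_cell.a, fs_cell.a)
    cell_b = np.where(ei_labels, rs_cell.b, fs_cell.b)
    cell_c = np.where(ei_labels, rs_cell.c, fs_cell.c)
    cell_d = np.where(ei_labels, rs_cell.d, fs_cell.d)

    dt = config.dt
    n_steps = int(round(config.t_total / dt))
    n_transient = int(round(config.t_transient / dt))
    delay_steps = int(round(config.tau0 / dt))
    W = net.weights.tocsr()
    sim_seed = int(ss_sim.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
    # spike capacity: 250 Hz per neuron over the recorded window
    max_spikes = int(N * (config.t_total - config.t_transient) / 1000.0 * 250) + 1000

    steps, ids, n_sp, bad, status, g_trace = simulate_network(
        W.indptr, W.indices, W.data.astype(np.float64), ei_labels,
        cell_a, cell_b, cell_c, cell_d, float(rs_cell.v_thr),
        syn["ampa"].g, syn["gaba"].g, syn["ext"].g,
        float(np.exp(-dt / syn["ampa"].tau)),
        float(np.exp(-dt / syn["gaba"].tau)),
        float(np.exp(-dt / syn["ext"].tau)),
        syn["ampa"].v_rev, syn["gaba"].v_rev, syn["ext"].v_rev,
        config.lambda_ext * dt, config.ii_scale, dt, n_steps, n_transient,
        delay_steps, sim_seed, max_spikes, record_conductance)
    if status == 1:
        raise FloatingPointError(f"integration blowup at neuron {bad}")
    if status == 2:
        raise RuntimeError("spike buffer overflow (rate > 250 Hz sustained)")
    raster = SpikeRaster((steps + 1) * dt, ids, ei_labels,
                         config.t_total, config.t_transient, dt, N)
    if record_conductance >= 0:
        return raster, g_trace
    return raster
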
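"""Orchestration of simulation campaigns.

A campaign is a grid of conditions (genotype or (α, β) point × external
rate λ × inhibition scaling) crossed with ``n_topologies`` independent
network realizations, each simulated with ``n_noise`` independent noise
(input + initial condition) realizations.  Every run's seed derives
deterministically from the plan's base seed and the condition/topology/noise
indices, so any cell of any result table can be regenerated in isolation.

The default plan is desk-scale (3 topologies × 3 noise realizations, 2 s of
simulated activity after a 0.5 s transient); the full-scale campaign uses
10 × 10.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .morphology import GenotypeParams, WT_CONSTANTS, GENOTYPES
from .topology import TopologyConfig, generate_network
from .metrics import network_density, degree_sequences, strength_distribution
from .dynamics import DynamicsConfig, simulate
from .analysis import (compute_lfp, power_spectrum, ensemble_spectrum,
                       isi_statistics)


@dataclass
class ExperimentPlan:
    """Ensemble sizes, simulation protocol and seed bookkeeping for a campaign."""

    n_topologies: int = 3
    n_noise: int = 3
    base_seed: int = 0
    topology: TopologyConfig = field(default_factory=TopologyConfig)
    t_total: float = 2500.0
    t_transient: float = 500.0
    dt: float = 0.1
    smoothing_sigma_hz: float = 2.0
    isi_bin_ms: float = 5.0
    out_dir: str | None = None

    def dynamics_config(self, lam: float, ii_scale: float = 1.0) -> DynamicsConfig:
        return DynamicsConfig(lambda_ext=lam, ii_scale=ii_scale, dt=self.dt,
                              t_total=self.t_total,
                              t_transient=self.t_transient)


def _condition_key(genotype: GenotypeParams, lam: float, ii_scale: float):
    """Stable integer tuple identifying a condition for seed derivation."""
    return (int(round(genotype.alpha * 10_000)),
            int(round(genotype.beta * 10_000)),
            int(round(lam * 1_000)),
            int(round(ii_scale * 1_000)))


def topology_seed(plan: ExperimentPlan, genotype: GenotypeParams,
                  topo_idx: int) -> int:
    ss = np.random.SeedSequence(plan.base_seed,
                                spawn_key=(1, int(round(genotype.alpha * 10_000)),
                                           int(round(genotype.beta * 10_000)),
                                           topo_idx))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def noise_seed(plan: ExperimentPlan, genotype: GenotypeParams, lam: float,
               ii_scale: float, topo_idx: int, noise_idx: int) -> int:
    ss = np.random.SeedSequence(plan.base_seed,
                                spawn_key=(2,) + _condition_key(genotype, lam, ii_scale)
                                + (topo_idx, noise_idx))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class EnsembleResult:
    """Per-run table plus the ensemble-averaged spectrum of one condition."""

    genotype: GenotypeParams
    lam: float
    ii_scale: float
    table: pd.DataFrame
    mean_spectrum: object  # EnsembleSpectrum
    spectra: list


def _run_dir(plan: ExperimentPlan):
    if plan.out_dir is None:
        return None
    d = Path(plan.out_dir) / "runs"
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_genotype_ensemble(plan: ExperimentPlan, genotype: GenotypeParams,
                          lam: float, ii_scale: float = 1.0,
                          networks: list | None = None) -> EnsembleResult:
    """Generate → simulate → analyze one condition; rows are individual runs.

    Failed runs are collected and reported at the end instead of aborting
    the whole campaign.  With ``plan.out_dir`` set, per-run rows are cached
    as JSON and reloaded on re-execution (resumability); note that cached
    rows do not restore spectra, so the averaged spectrum is recomputed only
    from fresh runs.
    """
    cfg = replace(plan.topology, dend_mean=genotype.R_bar)
    dyn = plan.dynamics_config(lam, ii_scale)
    cache = _run_dir(plan)
    rows, spectra, failures = [], [], []
    if networks is None:
        networks = [
            generate_network(cfg, genotype, WT_CONSTANTS,
                             seed=topology_seed(plan, genotype, ti))
            for ti in range(plan.n_topologies)
        ]
    for ti, net in enumerate(networks):
        dens = network_density(net)
        k_in, _ = degree_sequences(net)
        deg = float(np.mean(k_in))
        strength = strength_distribution(net)["mean"]
        for ni in range(plan.n_noise):
            run_id = f"{genotype.name}_l{lam:g}_ii{ii_scale:g}_t{ti}_n{ni}"
            cache_file = cache / f"{run_id}.json" if cache else None
            if cache_file is not None and cache_file.exists():
                rows.append(json.loads(cache_file.read_text()))
                continue
            seed = noise_seed(plan, genotype, lam, ii_scale, ti, ni)
            try:
                raster = simulate(net, dyn, seed=seed)
                lfp = compute_lfp(raster)
                spec = power_spectrum(lfp, plan.smoothing_sigma_hz)
                isi_e = isi_statistics(raster, "excitatory",
                                       bin_width=plan.isi_bin_ms)
                isi_i = isi_statistics(raster, "inhibitory",
                                       bin_width=plan.isi_bin_ms)
            except (ValueError, FloatingPointError, RuntimeError) as exc:
                failures.append((run_id, str(exc)))
                continue
            spectra.append(spec)
            row = {
                "run_id": run_id, "genotype": genotype.name,
                "alpha": genotype.alpha, "beta": genotype.beta,
                "lambda": lam, "ii_scale": ii_scale,
                "topology_idx": ti, "noise_idx": ni, "seed": seed,
                "peak_freq": spec.peak_freq, "peak_power": spec.peak_power,
                "cv_exc": isi_e.cv, "cv_inh": isi_i.cv,
                "isi_mode_exc_ms": isi_e.mode_ms,
                "isi_mode_inh_ms": isi_i.mode_ms,
                "density": dens, "degree": deg, "strength": strength,
            }
            rows.append(row)
            if cache_file is not None:
                cache_file.write_text(json.dumps(row))
    if failures and not rows:
        raise RuntimeError(f"all runs failed: {failures}")
    table = pd.DataFrame(rows)
    table.attrs["failures"] = failures
    mean_spec = ensemble_spectrum(spectra) if spectra else None
    return EnsembleResult(genotype, lam, ii_scale, table, mean_spec, spectra)


def lambda_sweep(plan: ExperimentPlan, genotypes, lambdas,
                 ii_scales=(1.0,)) -> pd.DataFrame:
    """Long-format condition table: mean/SD of peak frequency and power."""
    if any(l <= 0 for l in lambdas):
        raise ValueError("lambda values must be positive")
    out = []
    for g in genotypes:
        genotype = GENOTYPES[g] if isinstance(g, str) else g
        # topologies are reused across lambda and ii_scale conditions
        cfg = replace(plan.topology, dend_mean=genotype.R_bar)
        nets = [generate_network(cfg, genotype, WT_CONSTANTS,
                                 seed=topology_seed(plan, genotype, ti))
                for ti in range(plan.n_topologies)]
        for ii in ii_scales:
            for lam in lambdas:
                res = run_genotype_ensemble(plan, genotype, lam, ii,
                                            networks=nets)
                t = res.table
                out.append({
                    "genotype": genotype.name, "lambda": lam, "ii_scale": ii,
                    "n_runs": len(t),
                    "peak_freq_mean": t["peak_freq"].mean(),
                    "peak_freq_sd": t["peak_freq"].std(ddof=1),
                    "peak_power_mean": t["peak_power"].mean(),
                    "peak_power_sd": t["peak_power"].std(ddof=1),
                    "cv_exc_mean": t["cv_exc"].mean(),
                    "cv_inh_mean": t["cv_inh"].mean(),
                })
    return pd.DataFrame(out)


def alpha_beta_grid(plan: ExperimentPlan, alpha_values, beta_values,
                    lam: float = 10.0) -> pd.DataFrame:
    """Morphological-parameter grid: ensemble means per (α, β) cell."""
    if len(alpha_values) == 0 or len(beta_values) == 0:
        raise ValueError("grids must be non-empty")
    out = []
    for alpha in alpha_values:
        for beta in beta_values:
            genotype = GenotypeParams(f"a{alpha:g}_b{beta:g}", alpha, beta)
            res = run_genotype_ensemble(plan, genotype, lam)
            t = res.table
            out.append({
                "alpha": alpha, "beta": beta, "lambda": lam,
                "n_runs": len(t),
                "peak_freq_mean": t["peak_freq"].mean(),
                "peak_freq_sd": t["peak_freq"].std(ddof=1),
                "peak_power_mean": t["peak_power"].mean(),
                "peak_power_sd": t["peak_power"].std(ddof=1),
            })
    return pd.DataFrame(out)
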
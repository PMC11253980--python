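# Methods

## Scope and model summary

`neuroslice` couples three layers: (i) a morphology layer that turns Sholl
branch-density and spine-density measurements into a synaptic contact
probability (SCP) with two genotype scalings (amplitude α, tree-size ratio
β); (ii) a stochastic topology generator that realizes a 2D cortical-slice
connectivity from the SCP; (iii) an excitatory/inhibitory Izhikevich
network simulator with delayed exponential conductance synapses and
Poisson drive, analyzed through a population-rate LFP proxy, smoothed
periodograms and interspike-interval statistics.

## Morphology layer

* `BD(r) = a·r·exp(−b·r⁴)` with fitted a = 0.458 μm⁻¹, b = 3.39·10⁻⁹ μm⁻⁴.
  The linear prefactor forces BD(0) = 0; the quartic exponential gives a
  maximum at (1/4b)^{1/4} ≈ 92.7 μm and a hard decay past the dendritic
  field.
* `SD(r)`: degree-6 polynomial (spines per 10 μm). Outside its fitted
  range the polynomial misbehaves, so SD is clamped at 0 and the SCP is
  truncated beyond the morphological data support (largest spine–soma
  distance, 218 μm along the dendrite).
* `SCP(r; α, β) = α·BD(γr/β)·SD(γr/β)/(10·2πr)` with γ = 218/156.30
  mapping straight-line radius to path distance along tortuous dendrites,
  and the 1/10 converting SD to spines per μm (exposed as
  `MorphologyConstants.sd_per10um`). Dividing the radius by β compresses
  the spine-placement profile into the smaller dendritic tree of the
  disease genotypes (support r ≤ β·R̄_WT) and raises the local probability
  by 1/β — the scaling identity is `SCP(r; α, β) = (α/β)·SCP(r/β; 1, 1)`.
  We considered the alternative reading in which the radius is *multiplied*
  by β; it stretches the disease profiles beyond their own dendritic trees
  and overpredicts disease-model connectivity by ~20% against the reference
  connectivity table, so the compressive form is used. Contact-probability
  values are clipped to [0, 1].
* Fits: `BD` by bounded nonlinear least squares (Jacobian-scaled, tight
  tolerances — the two parameters differ by nine orders of magnitude);
  `SD` by linear least squares on the mapped domain [−1, 1] (raw powers of
  r up to r⁶ are numerically rank-deficient); (α, β) by nonlinear least
  squares against empirical SCP points with WT constants held fixed.
  Losses are unweighted. Non-convergence is flagged, not raised.

## Topology generator

Defaults are the slice-model values: N = 3037 (areal density
1350 neurons/mm² × 2.25 mm²), L = 1500 μm with periodic boundaries, 1 μm
grid, soma radius 8 μm, dendritic radii Gaussian (mean β·156.30 μm,
σ = 40 μm, resampled until > soma radius), axon segments of 10 μm with
Gaussian(0, π/30) heading increments and Rayleigh total length of mean
500 μm (scale = mean/√(π/2)).

Numerical/design choices:

* **Soma radius.** The slice thickness equals one soma diameter, 16 μm;
  3037 non-overlapping radius-16 disks cannot fit in the domain (packing
  fraction > 1), so the radius is 8 μm (diameter 16). Exposed in
  `TopologyConfig`.
* **Axon rasterization.** The polyline is sampled at 1 μm arc-length
  intervals (one Bernoulli trial per μm of axon per covering dendrite).
  A supercover rasterization (every crossed cell) would produce ~4/π ≈ 1.27
  trials per μm and overpredict both degree and per-edge strength against
  the reference connectivity table by ~27%.
* **Trials.** For each axon cell and each neuron j whose annulus
  (soma radius, dendritic radius_j] contains the cell center
  (minimal-image distance), one independent Bernoulli(SCP(r)) trial;
  multiple traversals retrigger trials; autapses are excluded. Trials use
  a tabulated SCP (piecewise-linear, 0.25 μm grid) for speed; the table is
  shared with the brute-force validation path so both consume identical
  random streams.
* **Randomness.** One child seed per neuron derived from the master seed
  (`numpy.random.SeedSequence`), so results are independent of the order
  in which neurons are processed; the per-trial stream is Mersenne-Twister
  (`numpy.random.seed`-compatible inside the numba kernel, replicated
  exactly by `RandomState` in the oracle).
* **Spatial index.** Somas are registered in every ~64 μm bin their
  dendritic disk touches, so each axon cell inspects exactly one bin. For
  N ≤ 20 an all-pairs brute-force path reproduces the indexed result
  bitwise.

With these defaults the generator reproduces the reference ensemble
measures (10 networks): WT ≈ 6.6% density / 200 mean degree / 11 contacts
per edge; Ts65Dn ≈ 3.8% / 113; TgDyrk1A ≈ 3.4% / 102 / 10.

## Dynamics

Izhikevich cells, v̇ = 0.04v² + 5v + 140 − u + I, u̇ = a(bv − u), threshold
30 mV, reset (c, u + d); RS (0.02, 0.2, −65, 8) for excitatory, FS
(0.1, 0.2, −65, 2) for inhibitory, assigned randomly at exactly 80/20 per
simulation. Conductance channels: AMPA (0.006, 2 ms, 0 mV), GABA
(0.720, 4 ms, −70 mV), external AMPA (0.008, 2 ms, 0 mV); a presynaptic
spike increments the target conductance by g·w after a delay τ0 = 1 ms
(the printed conductance kernel has a sign typo — a growing exponential —
implemented as decay). I→I GABA increments are multiplied by `ii_scale`
(0.3 models the reduced recurrent inhibition of the disease state).
External Poisson events (λ·dt per neuron per step) are applied without
delay: a time-shifted Poisson process is statistically identical, so the
delay option is exposed but off.

**Integrator.** Forward Euler at dt = 0.1 ms for the intrinsic terms with
conductances decayed exactly (g ← g·e^{−dt/τ}) — but the synaptic current
is treated *implicitly*: v' = [v + dt(0.04v² + 5v + 140 − u) +
dt·Σgv_rev]/(1 + dt·Σg). During population bursts total GABA conductance
reaches 30–300, i.e. dt·g ≫ 1, where a fully explicit step overshoots far
past the reversal potentials and locks the network into a non-physical
5 kHz state; the semi-implicit form is exactly Euler for small g, bounds v
by the reversal potentials, and leaves population rates and the gamma peak
unchanged under step halving (dt = 0.05). Initial conditions
v ~ U(−70, −60), u = b·v; the first 500 ms are discarded from rasters but
still drive synapses.

**Observables.** LFP(t) = population mean spike count in 0.1 ms bins;
spectra are single-window, mean-subtracted periodograms (Parseval
normalization: power sums to series variance) smoothed along frequency
with a Gaussian of σ = 2 Hz; the gamma peak is the argmax in 5–150 Hz.
ISIs are pooled within a population before computing CV = SD/mean;
histograms default to 1 ms bins (5 ms in experiment tables).

**Where the simulated rhythm sits.** With the parameters above the WT
slice at λ = 9 events/ms produces a robust gamma rhythm (spectral peak an
order of magnitude above background, inhibitory rates above excitatory,
excitatory CV ≈ 0.9–1.1) whose peak sits at ≈ 50 Hz, on the fast side of
the ~40 Hz gamma documented for mouse cortex and for PING models
calibrated to it; the excitatory ISI distribution is bimodal, with a
same-burst doublet peak
at < 5 ms and a slow mode at 3–4 gamma periods. Sensitivity checks show
the frequency is set by the delay and GABA decay (τ0 = 2 ms → 45 Hz;
τ_GABA = 8 ms → 29 Hz), not by the integrator (step halving changes
nothing). Genotype *contrasts* — reduced gamma power in Ts65Dn and
TgDyrk1A, the power drop and gap collapse under `ii_scale = 0.3` — are
robust to this offset and are the quantities the package treats as
conclusions; absolute frequencies should be read as model-internal.

## Synthetic data (fixtures)

`neuroslice.fixtures` generates every input the pipeline consumes, with
truth records: radial profiles drawn from the fitted forms (additive
Gaussian or multiplicative noise, clipped at 0 — emulating averaged Sholl
and spine-count profiles in 10 μm bins), hand-specified weighted digraphs
(chain/cycle/complete/Erdős–Rényi, no autapses), and periodic or Poisson
spike rasters. These emulate the *statistical* structure of the real
measurements, not raw tracings: a green recovery test establishes that the
fitting code inverts the stated generative model at the stated noise, not
that it would recover parameters from microscopy artifacts, per-neuron
heterogeneity, or binning choices other than those stated.

## Experiments

Campaign seeds derive from `(base_seed, condition, topology index, noise
index)` via `SeedSequence` spawn keys, so any table cell is regenerable in
isolation and re-runs are bitwise identical; per-run rows can be cached as
JSON for resumability. The desk-scale default is 3 topologies × 3 noise
realizations and 2 s of analyzed activity (the full-scale study design is
10 × 10); ensemble statistics are means and sample SDs, with no
significance testing.

## Known limitations

* 2D slice with point somas and circular dendritic fields; no axonal
  terminals, no inter-layer or long-range connections.
* The gamma-frequency offset discussed above; absolute spectral power is
  in arbitrary units and only comparable within the package.
* The degree-6 spine polynomial is meaningful only inside the fitted
  radial range; fits to profiles with radii far outside it are
  extrapolations.
* Experiments assume homogeneous cell morphology across E/I types (the
  generator does not distinguish them, matching the modeled system).
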
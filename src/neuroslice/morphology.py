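"""Single-neuron morphology and the synaptic contact probability (SCP).

Pyramidal-cell morphology enters the network model through two radial
functions of the distance ``r`` (μm) from the soma:

* branch density ``BD(r) = a·r·exp(-b·r⁴)`` — fitted to averaged Sholl
  intersection profiles (number of dendritic branches crossing a circle of
  radius r);
* spine density ``SD(r) = Σ_{j=0..6} c_j·r^j`` — a degree-6 polynomial
  fitted to spine counts per 10 μm of dendrite.

Their product, corrected for dendrite tortuosity (factor ``γ``) and the
circular geometry of the dendritic field (factor ``1/2πr``), gives the
probability that a 1 μm axon–dendrite overlap site forms a synapse:

    SCP(r; α, β) = α · BD(γr/β) · SD(γr/β) / (10 · 2πr)

with genotype-specific scalings α (overall amplitude) and β (dendritic tree
size ratio relative to wild type).  Dividing the radius by β < 1 compresses
the spine-placement profile into the smaller dendritic tree of the disease
models (support r ≤ β·R̄_WT), which raises the per-site probability by 1/β —
equivalently SCP(r; α, β) = (α/β)·SCP(r/β; 1, 1).  The factor 10 converts
SD from spines-per-10-μm to spines-per-μm; it can be disabled through
``MorphologyConstants.sd_per10um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import optimize


@dataclass(frozen=True)
class MorphologyConstants:
    """Fitted constants of the wild-type BD/SD functions.

    Parameters
    ----------
    a, b
        Branch-density amplitude (μm⁻¹) and quartic decay constant (μm⁻⁴).
    c
        Spine-density polynomial coefficients ``(c0, ..., c6)``; SD output is
        spines per 10 μm of dendrite (powers of μm).
    gamma
        Dendrite-tortuosity rescaling factor (largest spine–soma path
        distance over the mean dendritic field radius).
    R_wt
        Wild-type mean dendritic tree radius (μm).
    r_support
        Largest spine–soma distance with data support (μm); the SCP is set
        to zero wherever ``γβr`` exceeds it, so the polynomial tail cannot
        blow up.
    sd_per10um
        If True (default), SD values are per 10 μm and are divided by 10
        inside the SCP.
    """

    a: float = 0.458
    b: float = 3.39e-9
    c: tuple = (0.0432, -0.258, 0.0244, -4.20e-4, 3.12e-6, -1.08e-8, 1.44e-11)
    gamma: float = 218.0 / 156.30
    R_wt: float = 156.30
    r_support: float = 218.0
    sd_per10um: bool = True

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError("branch-density constants must satisfy a > 0, b > 0")
        if not self.gamma > 1:
            raise ValueError("tortuosity factor gamma must exceed 1")
        if len(self.c) != 7:
            raise ValueError("spine-density polynomial needs 7 coefficients")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "MorphologyConstants":
        d = json.loads(s)
        d["c"] = tuple(d["c"])
        return cls(**d)


@dataclass(frozen=True)
class GenotypeParams:
    """Genotype-level SCP scaling: amplitude ``alpha``, tree-size ratio ``beta``."""

    name: str
    alpha: float
    beta: float
    R_wt: float = 156.30

    def __post_init__(self):
        if not (self.alpha >= 0 and np.isfinite(self.alpha)):
            raise ValueError("alpha must be a finite non-negative number")
        if not (self.beta > 0 and np.isfinite(self.beta)):
            raise ValueError("beta must be a finite positive number")

    @property
    def R_bar(self) -> float:
        """Mean dendritic tree radius (μm), ``β·R̄_WT``."""
        return self.beta * self.R_wt

    def to_json(self) -> str:
        return json.dumps({"name": self.name, "alpha": self.alpha,
                           "beta": self.beta, "R_wt": self.R_wt})

    @classmethod
    def from_json(cls, s: str) -> "GenotypeParams":
        return cls(**json.loads(s))


WT_CONSTANTS = MorphologyConstants()

#: The three mouse genotypes shipped as defaults: wild type, the trisomic
#: Ts65Dn model and the single-gene transgenic TgDyrk1A model.
GENOTYPES = {
    "WT": GenotypeParams("WT", alpha=1.0, beta=1.0),
    "Ts65Dn": GenotypeParams("Ts65Dn", alpha=0.937, beta=0.644),
    "TgDyrk1A": GenotypeParams("TgDyrk1A", alpha=0.826, beta=0.597),
}


@dataclass
class RadialProfile:
    """A radial measurement profile: strictly increasing radii, counts ≥ 0."""

    radii: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.radii.shape != self.values.shape or self.radii.ndim != 1:
            raise ValueError("radii and values must be 1D arrays of equal length")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")

    def __len__(self):
        return len(self.radii)

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.radii, self.values])
        np.savetxt(path, arr, delimiter=",", header="radius_um,value",
                   comments="", fmt="%.10g")

    @classmethod
    def from_csv(cls, path) -> "RadialProfile":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(arr[:, 0], arr[:, 1])


def _check_radius(r, allow_zero=True):
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    if not allow_zero and np.any(r == 0):
        raise ValueError("radius must be strictly positive")
    return r


def branch_density(r, consts: MorphologyConstants = WT_CONSTANTS):
    """Sholl branch density ``BD(r) = a·r·exp(-b·r⁴)``; vectorized in ``r``."""
    r = _check_radius(r)
    return consts.a * r * np.exp(-consts.b * r**4)


def spine_density(r, consts: MorphologyConstants = WT_CONSTANTS,
                  clamp: bool = True):
    """Spine density polynomial (spines per 10 μm of dendrite).

    The fitted degree-6 polynomial can dip below zero outside the data
    range; with ``clamp`` (default) negative values are set to 0, since a
    density cannot be negative.
    """
    r = _check_radius(r)
    v = npoly.polyval(r, np.asarray(consts.c))
    if clamp:
        v = np.clip(v, 0.0, None)
    return v


def scp(r, genotype: GenotypeParams = GENOTYPES["WT"],
        consts: MorphologyConstants = WT_CONSTANTS):
    """Synaptic contact probability per 1 μm overlap site, in [0, 1].

    ``SCP(r; α, β) = α·BD(γr/β)·SD(γr/β) / (10·2πr)``, zero beyond the
    morphological data support (``γr/β > r_support``, i.e. r > β·R̄_WT).
    Singular at r = 0, hence r must be strictly positive.
    """
    r = _check_radius(r, allow_zero=False)
    x = consts.gamma * r / genotype.beta
    p = genotype.alpha * branch_density(x, consts) * spine_density(x, consts)
    p = p / (2.0 * np.pi * r)
    if consts.sd_per10um:
        p = p / 10.0
    p = np.where(x > consts.r_support, 0.0, p)
    return np.clip(p, 0.0, 1.0)


@dataclass
class FitResult:
    """Outcome of a least-squares morphology fit."""

    params: np.ndarray
    rss: float
    converged: bool
    cov: np.ndarray | None = None

    def __iter__(self):  # allow  a, b = fit_branch_density(...).params-style unpack
        return iter(self.params)


def fit_branch_density(profile: RadialProfile) -> FitResult:
    """Nonlinear least-squares fit of ``BD(r) = a·r·exp(-b·r⁴)``.

    Non-convergence is reported through ``converged=False`` rather than an
    exception (degenerate profiles, e.g. all-zero, are legal inputs).
    """
    if len(profile) < 4:
        raise ValueError("need at least 4 data points")
    r, y = profile.radii, profile.values
    if not np.any(y > 0):
        return FitResult(np.array([0.0, 1e-9]), float(np.sum(y**2)), False)

    i_max = int(np.argmax(y))
    r_max = max(r[i_max], 1.0)
    p0 = (y[i_max] / r_max * np.e**0.25, 1.0 / (4.0 * r_max**4))

    def model(rr, a, b):
        return a * rr * np.exp(-b * rr**4)

    try:
        # a and b differ by ~9 orders of magnitude: scale steps by the
        # Jacobian and tighten tolerances so both are resolved
        popt, pcov = optimize.curve_fit(
            model, r, y, p0=p0, bounds=([0, 0], [np.inf, np.inf]),
            x_scale="jac", xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000)
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        return FitResult(np.asarray(p0), float(np.sum((y - model(r, *p0))**2)),
                         False)
    rss = float(np.sum((y - model(r, *popt))**2))
    return FitResult(popt, rss, converged, pcov)


def fit_spine_density(profile: RadialProfile) -> FitResult:
    """Ordinary least squares on the degree-6 polynomial design matrix."""
    if len(profile) < 8:
        raise ValueError("need at least 8 data points")
    if len(np.unique(profile.radii)) < 7:
        raise ValueError("need at least 7 distinct radii (rank-deficient design)")
    # fit on the mapped domain [-1, 1] (raw powers of r up to r^6 are
    # numerically rank-deficient), then convert back to standard powers
    poly = npoly.Polynomial.fit(profile.radii, profile.values, 6)
    coef = poly.convert().coef
    coef = np.pad(coef, (0, 7 - len(coef)))
    fitted = npoly.polyval(profile.radii, coef)
    rss = float(np.sum((profile.values - fitted) ** 2))
    return FitResult(coef, rss, True)


def fit_alpha_beta(scp_points: RadialProfile,
                   consts: MorphologyConstants = WT_CONSTANTS) -> FitResult:
    """Fit the genotype scalings (α, β) of the SCP to empirical points.

    The wild-type constants are held fixed; only the two scaling factors are
    free, exactly as in the genotype characterization procedure.
    """
    if len(scp_points) < 3:
        raise ValueError("need at least 3 SCP points")
    r, y = scp_points.radii, scp_points.values

    def model(rr, alpha, beta):
        return scp(rr, GenotypeParams("custom", alpha, beta), consts)

    try:
        popt, pcov = optimize.curve_fit(
            model, r, y, p0=(1.0, 1.0),
            bounds=([1e-6, 1e-2], [np.inf, np.inf]), maxfev=20000)
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        return FitResult(np.array([1.0, 1.0]), float("nan"), False)
    rss = float(np.sum((y - model(r, *popt)) ** 2))
    return FitResult(popt, rss, converged, pcov)
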
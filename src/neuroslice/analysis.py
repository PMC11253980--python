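"""Rasters → observables: LFP proxy, power spectra, ISI statistics.

The LFP proxy is the network-average firing rate in 0.1 ms bins (each spike
contributes 1/N to its bin).  Spectra are single-window periodograms of the
mean-subtracted LFP, smoothed along frequency with a Gaussian kernel; the
gamma peak is the argmax of the smoothed spectrum within a search band.
ISI statistics (histogram, coefficient of variation CV = σ/μ) are pooled
across all neurons of one population (excitatory or inhibitory).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dynamics import SpikeRaster

MIN_SPECTRUM_SAMPLES = 2**12


@dataclass
class LfpSeries:
    bin_width: float          # ms
    values: np.ndarray        # spikes per neuron per bin
    t_start: float            # ms

    @property
    def sample_rate_hz(self) -> float:
        return 1000.0 / self.bin_width

    def to_tsv(self, path):
        t = self.t_start + np.arange(len(self.values)) * self.bin_width
        np.savetxt(path, np.column_stack([t, self.values]), delimiter="\t",
                   header="time_ms\tlfp", comments="", fmt="%.6g")


@dataclass
class SpectrumResult:
    freqs: np.ndarray
    power: np.ndarray          # smoothed periodogram
    raw_power: np.ndarray      # unsmoothed periodogram (Parseval-normalized)
    peak_freq: float
    peak_power: float
    search_band: tuple

    def to_tsv(self, path):
        np.savetxt(path, np.column_stack([self.freqs, self.power]),
                   delimiter="\t", header="freq_hz\tpower", comments="",
                   fmt="%.8g")


@dataclass
class EnsembleSpectrum:
    freqs: np.ndarray
    power: np.ndarray          # pointwise mean
    power_sd: np.ndarray       # pointwise sample SD
    peak_freq: float           # from the averaged spectrum
    peak_power: float
    search_band: tuple


@dataclass
class IsiStats:
    isis: np.ndarray           # pooled interspike intervals (ms)
    bin_edges: np.ndarray
    counts: np.ndarray
    cv: float
    mode_ms: float             # center of the modal histogram bin


def compute_lfp(raster: SpikeRaster, N: int | None = None,
                bin_width: float = 0.1) -> LfpSeries:
    """Population-rate LFP: binned spike counts over all neurons divided by N."""
    N = raster.N if N is None else N
    t0, t1 = raster.t_transient, raster.t_total
    n_bins = int(round((t1 - t0) / bin_width))
    counts, _ = np.histogram(raster.times,
                             bins=n_bins, range=(t0, t0 + n_bins * bin_width))
    return LfpSeries(bin_width, counts / N, t0)


def power_spectrum(lfp: LfpSeries, smoothing_sigma_hz: float = 2.0,
                   search_band=(5.0, 150.0)) -> SpectrumResult:
    """Mean-subtracted periodogram with Gaussian frequency smoothing.

    The raw periodogram is normalized so that its sum equals the series
    variance (discrete Parseval); the peak is located on the smoothed
    spectrum within ``search_band`` (Hz).
    """
    x = np.asarray(lfp.values, dtype=float)
    n = len(x)
    if n < MIN_SPECTRUM_SAMPLES:
        raise ValueError(f"need at least {MIN_SPECTRUM_SAMPLES} samples")
    x = x - x.mean()
    X = np.fft.rfft(x)
    raw = (np.abs(X) ** 2) / n**2
    raw[1:] *= 2.0
    if n % 2 == 0:
        raw[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=lfp.bin_width / 1000.0)
    df = freqs[1] - freqs[0]
    if smoothing_sigma_hz > 0:
        power = ndimage.gaussian_filter1d(raw, smoothing_sigma_hz / df,
                                          mode="nearest")
    else:
        power = raw.copy()
    lo, hi = search_band
    band = (freqs >= lo) & (freqs <= hi)
    if not np.any(band):
        raise ValueError("search band contains no frequency bins")
    i = np.flatnonzero(band)[np.argmax(power[band])]
    return SpectrumResult(freqs, power, raw, float(freqs[i]),
                          float(power[i]), tuple(search_band))


def ensemble_spectrum(spectra) -> EnsembleSpectrum:
    """Pointwise mean/SD over spectra on identical grids; peak of the mean."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("empty spectrum list")
    freqs = spectra[0].freqs
    for s in spectra[1:]:
        if len(s.freqs) != len(freqs) or not np.allclose(s.freqs, freqs):
            raise ValueError("mismatched frequency grids")
    P = np.vstack([s.power for s in spectra])
    mean = P.mean(axis=0)
    sd = P.std(axis=0, ddof=1) if len(spectra) > 1 else np.zeros_like(mean)
    lo, hi = spectra[0].search_band
    band = (freqs >= lo) & (freqs <= hi)
    i = np.flatnonzero(band)[np.argmax(mean[band])]
    return EnsembleSpectrum(freqs, mean, sd, float(freqs[i]), float(mean[i]),
                            spectra[0].search_band)


def isi_statistics(raster: SpikeRaster, population: str = "excitatory",
                   bin_width: float = 1.0, t_max: float = 200.0) -> IsiStats:
    """Pooled ISI histogram and CV for one population.

    ISIs from every neuron of the population are pooled before computing
    CV = sample SD / sample mean.  The histogram covers [0, t_max) ms.
    """
    if population not in ("excitatory", "inhibitory"):
        raise ValueError("population must be 'excitatory' or 'inhibitory'")
    want_exc = population == "excitatory"
    mask = raster.ei_labels[raster.ids] == want_exc
    times = raster.times[mask]
    ids = raster.ids[mask]
    order = np.lexsort((times, ids))
    times, ids = times[order], ids[order]
    d = np.diff(times)
    same = ids[1:] == ids[:-1]
    isis = d[same]
    if isis.size == 0:
        raise ValueError(f"no ISIs in the {population} population")
    edges = np.arange(0.0, t_max + bin_width, bin_width)
    counts, _ = np.histogram(isis, bins=edges)
    mode = float(edges[np.argmax(counts)] + bin_width / 2.0)
    mu = float(np.mean(isis))
    sd = float(np.std(isis, ddof=1)) if isis.size > 1 else 0.0
    return IsiStats(isis, edges, counts, sd / mu, mode)
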
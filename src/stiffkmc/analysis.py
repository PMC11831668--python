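"""Trajectory validation metrics: autocorrelation-based spectral density,
dominant oscillation frequency/period, and species probability mass
functions.

The spectral estimator is tailored to piecewise-constant KMC trajectories
sampled on a uniform grid: the biased autocorrelation (normalization by the
full series length, which keeps the spectrum nonnegative-definite) is taken
up to half the series length and cosine-transformed (DCT-I).  Only peak
*locations* matter for the comparisons made here, so the transform's overall
normalization is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct
from scipy.signal import find_peaks

__all__ = ["SampledSeries", "SpectralDensity", "spectral_density",
           "dominant_frequency", "species_pmf", "estimate_period",
           "total_variation_distance", "compare_series"]


@dataclass
class SampledSeries:
    """Uniformly sampled scalar series (e.g. one species' copy number)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6,
                                                atol=1e-9 * abs(dt[0])):
                raise ValueError("series must be on a strictly increasing "
                                 "uniform time grid")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class SpectralDensity:
    frequencies: np.ndarray   # min^-1, [0, Nyquist]
    density: np.ndarray
    peaks: list[tuple[float, float]]  # (frequency, density), by magnitude
    bandwidth: float = 0.0    # information resolution, 1/(2*max_lag*dt)

    @property
    def resolution(self) -> float:
        """Frequency-grid spacing (finer than ``bandwidth`` when the
        autocorrelation was zero-padded)."""
        return float(self.frequencies[1] - self.frequencies[0])


def _as_series(series, dt: float | None) -> SampledSeries:
    if isinstance(series, SampledSeries):
        return series
    values = np.asarray(series, dtype=float)
    if dt is None:
        raise ValueError("dt is required when passing a bare value array")
    return SampledSeries(times=np.arange(values.size) * dt, values=values)


def spectral_density(series, dt: float | None = None,
                     max_lag: int | None = None,
                     pad: int = 8) -> SpectralDensity:
    """Power spectral density of a uniformly sampled series via the biased
    autocorrelation function and a cosine transform (DCT-I).

    ``max_lag`` defaults to half the series length; the information
    bandwidth of the estimate is 1/(2*max_lag*dt).  ``pad`` zero-pads the
    autocorrelation by that factor before the transform, interpolating the
    spectrum so that peak locations are not quantized to the coarse grid
    (the biased estimator tapers the autocorrelation toward zero at large
    lags, so padding introduces no artificial discontinuity).
    """
    s = _as_series(series, dt)
    n = s.values.size
    if n < 4:
        raise ValueError("series too short for spectral estimation")
    x = s.values - s.values.mean()
    nlag = max_lag if max_lag is not None else n // 2
    nlag = min(nlag, n - 1)
    # biased ACF: divide by n at every lag
    full = np.correlate(x, x, mode="full")
    acf = full[n - 1:n + nlag] / n
    if pad > 1:
        acf = np.concatenate([acf, np.zeros((pad - 1) * acf.size)])
    density = dct(acf, type=1)
    freqs = np.arange(density.size) / (2.0 * (density.size - 1) * s.dt)
    idx, _ = find_peaks(density)
    order = np.argsort(density[idx])[::-1]
    peaks = [(float(freqs[i]), float(density[i])) for i in idx[order]]
    return SpectralDensity(frequencies=freqs, density=density, peaks=peaks,
                           bandwidth=1.0 / (2.0 * nlag * s.dt))


def dominant_frequency(sd: SpectralDensity) -> float:
    """Frequency of the largest interior spectral peak (the zero-frequency
    bin is excluded).  Raises when the spectrum has no interior peak."""
    interior = [(f, d) for f, d in sd.peaks if f > 0]
    if not interior:
        raise ValueError("spectral density has no interior peak")
    return interior[0][0]


def estimate_period(series, dt: float | None = None) -> float:
    """Dominant oscillation period: inverse of the dominant spectral
    frequency."""
    return 1.0 / dominant_frequency(spectral_density(series, dt))


def species_pmf(series) -> dict[int, float]:
    """Empirical probability mass function of an integer-valued series."""
    values = np.asarray(series.values if isinstance(series, SampledSeries)
                        else series)
    if values.size == 0:
        raise ValueError("empty series")
    ivalues = np.asarray(values, dtype=np.int64)
    if not np.array_equal(ivalues, values):
        raise ValueError("series is not integer-valued")
    uniq, counts = np.unique(ivalues, return_counts=True)
    total = counts.sum()
    return {int(v): float(c) / total for v, c in zip(uniq, counts)}


def total_variation_distance(pmf_a: dict[int, float],
                             pmf_b: dict[int, float]) -> float:
    support = set(pmf_a) | set(pmf_b)
    return 0.5 * sum(abs(pmf_a.get(v, 0.0) - pmf_b.get(v, 0.0))
                     for v in support)


def compare_series(series_a: dict[str, SampledSeries],
                   series_b: dict[str, SampledSeries],
                   spectral_species: str) -> dict:
    """Validation report between two runs (e.g. original-constant versus
    downscaled): dominant frequencies and periods of ``spectral_species``,
    their ratio, the bin resolution, and per-species PMF total-variation
    distances."""
    sd_a = spectral_density(series_a[spectral_species])
    sd_b = spectral_density(series_b[spectral_species])
    f_a = dominant_frequency(sd_a)
    f_b = dominant_frequency(sd_b)
    report = {
        "species": spectral_species,
        "dominant_frequency_a": f_a,
        "dominant_frequency_b": f_b,
        "frequency_ratio": f_b / f_a,
        "bin_width_a": sd_a.bandwidth,
        "bin_width_b": sd_b.bandwidth,
        "within_one_bin": abs(f_b - f_a) <= max(sd_a.bandwidth,
                                                sd_b.bandwidth),
        "period_a": 1.0 / f_a,
        "period_b": 1.0 / f_b,
        "pmf_tv_distance": {},
    }
    for sp in series_a:
        if sp in series_b:
            try:
                report["pmf_tv_distance"][sp] = total_variation_distance(
                    species_pmf(series_a[sp]), species_pmf(series_b[sp]))
            except ValueError:
                pass  # non-integer series: PMF comparison not applicable
    return report
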
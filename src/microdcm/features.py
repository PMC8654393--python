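"""Conventional EEG data features.

Implements the descriptive features computed before any model fitting:
aperiodic (1/f) spectral adjustment, band power in the canonical frequency
bands, peak gamma frequency, Morlet time-frequency power, and the mismatch
(deviant - standard) difference wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cmc import ModelError
from .forward import ErpTimeSeries

#: Canonical band edges (Hz); gamma is open-ended and runs to the grid max.
BANDS = {
    "theta": (3.0, 7.0),
    "alpha": (8.0, 14.0),
    "beta": (15.0, 30.0),
    "gamma": (31.0, np.inf),
}

#: Default 1/f fit range: the full resting analysis band.  Measured EEG
#: usually excludes <2 Hz (drift) and 48-52 Hz (line noise); model spectra
#: have neither artifact, so the fit uses all of 1-48 Hz.  Pass an explicit
#: ``fit_range`` to adjust_onef for measured data.
ONEF_FIT_RANGE = (1.0, 48.0)


@dataclass
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ModelError(f"band {self.name}: low must be < high")


def default_bands(grid_max=None):
    out = []
    for name, (lo, hi) in BANDS.items():
        if np.isinf(hi):
            hi = float(grid_max) if grid_max is not None else 100.0
        out.append(BandDefinition(name, lo, hi))
    return out


@dataclass
class AdjustedSpectrum:
    """Power spectrum with its fitted log-log 1/f gradient removed.

    ``adjusted`` is the residual of log-power about the fitted line,
    evaluated on the full frequency grid (the fit itself uses only
    ``fit_range``).
    """

    grid: np.ndarray
    power: np.ndarray
    slope: float
    intercept: float
    adjusted: np.ndarray
    fit_range: tuple

    def fitted(self):
        """Back-transformed power-law fit on the grid."""
        return np.exp(self.intercept + self.slope * np.log(self.grid))


def adjust_onef(power, grid, fit_range=ONEF_FIT_RANGE):
    """Subtract the fitted 1/f gradient from a power spectrum.

    Least-squares line fit of log-power on log-frequency over ``fit_range``;
    the residual (log-power minus fit) is returned on the full grid together
    with the fitted slope, so group comparisons of the aperiodic gradient
    remain possible.
    """
    grid = np.asarray(grid, float)
    power = np.asarray(power, float)
    sel = (grid >= fit_range[0]) & (grid <= fit_range[1])
    if not np.any(sel):
        raise ModelError("empty 1/f fit range after gridding")
    if np.any(power[sel] <= 0):
        raise ModelError("power must be strictly positive on the fit range")
    lp = np.log(power[sel])
    lf = np.log(grid[sel])
    slope, intercept = np.polyfit(lf, lp, 1)
    with np.errstate(divide="ignore"):
        adjusted = np.where(power > 0,
                            np.log(np.maximum(power, 1e-300))
                            - (intercept + slope * np.log(grid)), np.nan)
    return AdjustedSpectrum(grid, power, float(slope), float(intercept),
                            adjusted, tuple(fit_range))


def band_power(adjusted: AdjustedSpectrum, bands=None):
    """Mean adjusted power per band (closed intervals on the grid)."""
    bands = default_bands(adjusted.grid.max()) if bands is None else bands
    out = {}
    for b in bands:
        hi = adjusted.grid.max() if np.isinf(b.high) else b.high
        sel = (adjusted.grid >= b.low) & (adjusted.grid <= hi)
        if not np.any(sel):
            raise ModelError(f"band {b.name} is empty on this grid")
        out[b.name] = float(adjusted.adjusted[sel].mean())
    return out


def peak_gamma(adjusted: AdjustedSpectrum, search=(35.0, 45.0)):
    """Frequency of maximal adjusted power in the closed search interval.

    Ties break toward the lower frequency.
    """
    sel = (adjusted.grid >= search[0]) & (adjusted.grid <= search[1])
    if not np.any(sel):
        raise ModelError("search interval outside the spectrum's grid")
    sub = adjusted.adjusted[sel]
    return float(adjusted.grid[sel][int(np.argmax(sub))])


@dataclass
class TimeFrequencyMap:
    t_ms: np.ndarray
    freqs: np.ndarray
    power: np.ndarray            # (n_freqs, n_times)
    normalized: bool = False


def _morlet(fs_hz, f0_hz, n_cycles):
    sigma_t = n_cycles / (2.0 * np.pi * f0_hz)
    t = np.arange(-5 * sigma_t, 5 * sigma_t, 1.0 / fs_hz)
    wav = np.exp(2j * np.pi * f0_hz * t) * np.exp(-t ** 2 / (2 * sigma_t ** 2))
    return wav / np.sqrt((np.abs(wav) ** 2).sum())


def time_frequency_power(erp: ErpTimeSeries, freqs, condition=None,
                         n_cycles=7.0, baseline=(-100.0, 0.0), channel=0):
    """Morlet time-frequency power, normalized to the pre-stimulus baseline.

    The magnitude-squared wavelet transform is divided by the baseline mean
    per frequency row, so an unmodulated signal maps to 1 everywhere.
    """
    if baseline[1] > erp.onset_ms:
        raise ModelError("baseline window must precede stimulus onset")
    if not (erp.t_ms[0] <= baseline[0] and baseline[1] <= erp.t_ms[-1]):
        raise ModelError("baseline window outside the data")
    conds = [condition] if condition is not None else list(erp.traces)
    fs = 1000.0 / erp.dt
    freqs = np.asarray(freqs, float)
    acc = np.zeros((freqs.size, erp.t_ms.size))
    for cond in conds:
        x = np.asarray(erp.traces[cond])[channel]
        for i, f0 in enumerate(freqs):
            wav = _morlet(fs, f0, n_cycles)
            full = np.convolve(x, wav, mode="full")
            start = (full.size - x.size) // 2
            acc[i] += np.abs(full[start:start + x.size]) ** 2
    acc /= len(conds)
    bsel = (erp.t_ms >= baseline[0]) & (erp.t_ms <= baseline[1])
    base = acc[:, bsel].mean(axis=1)
    base = np.where(base > 0, base, 1.0)
    return TimeFrequencyMap(erp.t_ms, freqs, acc / base[:, None],
                            normalized=True)


@dataclass
class MismatchWave:
    t_ms: np.ndarray
    difference: np.ndarray
    amplitude: float             # signed extremum within the window
    latency_ms: float
    window: tuple = field(default=(150.0, 250.0))


def mismatch_wave(standard, deviant, t_ms, window=(150.0, 250.0)):
    """Deviant - standard difference wave with windowed extremum.

    Amplitude is the signed value of largest magnitude inside the closed
    window; latency is its time.
    """
    standard = np.asarray(standard, float).ravel()
    deviant = np.asarray(deviant, float).ravel()
    t_ms = np.asarray(t_ms, float)
    if standard.shape != deviant.shape or standard.size != t_ms.size:
        raise ModelError("standard/deviant traces must share the time axis")
    diff = deviant - standard
    sel = (t_ms >= window[0]) & (t_ms <= window[1])
    if not np.any(sel):
        raise ModelError("analysis window outside the time axis")
    seg = diff[sel]
    i = int(np.argmax(np.abs(seg)))
    return MismatchWave(t_ms, diff, float(seg[i]), float(t_ms[sel][i]),
                        tuple(window))


def mismatch_from_erp(erp: ErpTimeSeries, window=(150.0, 250.0), channel=0):
    """Convenience wrapper taking the standard/deviant conditions of an ERP."""
    return mismatch_wave(np.asarray(erp.traces["standard"])[channel],
                         np.asarray(erp.traces["deviant"])[channel],
                         erp.t_ms, window=window)
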
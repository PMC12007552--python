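"""Spectral summaries of beamformer-projected source time series.

Relative band power maps (variance of the band-passed, SD-normalised
broadband source per band of interest), Welch power spectral densities, and
the between-run fractional PSD difference.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .bands import BandDefinition
from .preprocess import bandpass_filter

__all__ = ["welch_psd", "relative_band_power", "psd_fractional_difference"]


def welch_psd(
    x: np.ndarray, fs: float, segment_s: float = 2.0, overlap: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD (Hann window, 2-s segments, 50% overlap).

    Returns (frequencies in Hz, density in units^2/Hz); the 2-s default
    gives 0.5 Hz resolution. Applied along the last axis.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(segment_s * fs))
    if x.shape[-1] < nperseg:
        raise ValueError("input shorter than one Welch segment")
    return signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)), axis=-1,
    )


def relative_band_power(
    broadband_source: np.ndarray, bands: list[BandDefinition], fs: float
) -> np.ndarray:
    """Relative contribution of each band to a broadband source signal.

    The signal is normalised by its standard deviation; the variance of the
    band-passed normalised signal estimates the band's share of total
    power. Returns shape ``bands`` (or ``(n_series, n_bands)`` for 2-D
    input); values are non-negative and each at most ~1.
    """
    x = np.atleast_2d(np.asarray(broadband_source, dtype=float))
    sd = x.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance source series: relative power undefined")
    z = (x - x.mean(axis=-1, keepdims=True)) / sd
    out = np.column_stack(
        [bandpass_filter(z, b.lo, b.hi, fs).var(axis=-1) for b in bands]
    )
    return out[0] if np.ndim(broadband_source) == 1 else out


def psd_fractional_difference(
    P1: np.ndarray, P2: np.ndarray, freqs: np.ndarray
) -> float:
    """Fractional spectral difference between two runs.

    d = sqrt(sum_f (P1 - P2)^2) / (sum_f ((P1 + P2)/2) * df): the root sum
    of squared PSD differences normalised by the total integral of the mean
    PSD. The frequency step enters the denominator integral only, taking
    the quoted definition at face value; both PSDs must share one grid, so
    the quantity is comparable across runs.
    """
    P1 = np.asarray(P1, dtype=float)
    P2 = np.asarray(P2, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if P1.shape != P2.shape or P1.shape[-1] != freqs.shape[0]:
        raise ValueError("PSDs must share one frequency grid")
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    num = np.sqrt(np.sum((P1 - P2) ** 2))
    den = np.sum((P1 + P2) / 2.0) * df
    if den == 0:
        raise ValueError("mean PSD integrates to zero")
    return float(num / den)
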
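"""Filtering, automated channel/epoch rejection and homogeneous field correction.

The preprocessing chain, in order: 50 Hz notch (2nd-order IIR, Q=35 at
-3 dB, applied forward only) -> 1-150 Hz band-pass (4th-order zero-phase
Butterworth) -> automatic bad-channel detection -> 5-s epoch segmentation
and rejection (an epoch is bad when more than one channel's within-epoch
standard deviation exceeds the channel's across-epoch mean by 3 SDs) ->
homogeneous field correction (projection out of the three spatially uniform
field patterns spanned by the sensor orientations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator

from .datatypes import Recording, SensorArray

__all__ = [
    "notch_filter",
    "bandpass_filter",
    "detect_bad_channels",
    "segment_epochs",
    "detect_bad_epochs",
    "hfc_projector",
    "homogeneous_field_correction",
    "EpochStats",
    "Preprocessor",
]


def notch_filter(rec: Recording, f0: float = 50.0, q: float = 35.0) -> Recording:
    """Forward-only 2nd-order IIR notch at ``f0`` with Q defined at -3 dB."""
    if f0 >= rec.fs / 2:
        raise ValueError(f"notch frequency {f0} Hz must be below Nyquist")
    b, a = signal.iirnotch(f0, q, fs=rec.fs)
    return rec.copy_with(data=signal.lfilter(b, a, rec.data, axis=-1))


def bandpass_filter(
    x: np.ndarray, lo: float, hi: float, fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"invalid band ({lo}, {hi}) Hz at fs={fs}")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def bandpass_recording(rec: Recording, lo: float, hi: float, order: int = 4) -> Recording:
    return rec.copy_with(data=bandpass_filter(rec.data, lo, hi, rec.fs, order))


def detect_bad_channels(
    rec: Recording, dead_rel_var: float = 1e-6, noisy_power_factor: float = 10.0
) -> np.ndarray:
    """Automated stand-in for visual channel screening.

    A channel is flagged bad when (a) its variance is below ``dead_rel_var``
    times the median channel variance (broken/dead), or (b) its broadband
    power exceeds ``noisy_power_factor`` times the across-channel median
    (obviously noisy). Raises if every channel is flagged.
    """
    if rec.n_channels < 8:
        raise ValueError("need at least 8 channels for robust medians")
    var = rec.data.var(axis=-1)
    med = np.median(var)
    bad = (var <= dead_rel_var * med) | (var > noisy_power_factor * med)
    if bad.all():
        raise ValueError("all channels flagged bad: data unusable")
    return ~bad


def segment_epochs(rec: Recording, epoch_length_s: float | None = None) -> np.ndarray:
    """Start/stop sample indices of contiguous non-overlapping epochs.

    The trailing partial window is discarded. Returns (n_epochs, 2).
    """
    if epoch_length_s is None:
        epoch_length_s = rec.epoch_length_s
    spe = int(round(epoch_length_s * rec.fs))
    n_ep = rec.n_samples // spe
    if n_ep < 1:
        raise ValueError(
            f"recording ({rec.duration_s:.1f} s) shorter than one epoch"
        )
    starts = np.arange(n_ep) * spe
    return np.column_stack([starts, starts + spe])


@dataclass
class EpochStats:
    """Per-channel, per-epoch standard deviations and the rejection flags."""

    sigma: np.ndarray  # (n_good_channels, n_epochs)
    channel_flags: np.ndarray  # same shape, bool
    epoch_bad: np.ndarray  # (n_epochs,) bool


def detect_bad_epochs(
    rec: Recording, sd_thresh: float = 3.0, min_channels: int = 2
) -> EpochStats:
    """Flag epochs containing large artefacts.

    For each good channel, the standard deviation of the (already
    band-passed) data is computed within every epoch; a channel/epoch cell
    is flagged when it exceeds that channel's mean across epochs by more
    than ``sd_thresh`` across-epoch standard deviations (strict). An epoch
    is bad when at least ``min_channels`` channels are flagged ("more than
    one channel" -> 2 by default).
    """
    bounds = segment_epochs(rec)
    n_ep = bounds.shape[0]
    if n_ep < 3:
        raise ValueError("need at least 3 epochs for a meaningful threshold")
    spe = bounds[0, 1] - bounds[0, 0]
    x = rec.data[rec.channel_good, : n_ep * spe]
    sigma = x.reshape(x.shape[0], n_ep, spe).std(axis=-1)
    mu = sigma.mean(axis=1, keepdims=True)
    sd = sigma.std(axis=1, keepdims=True)
    flags = sigma > mu + sd_thresh * sd
    epoch_bad = flags.sum(axis=0) >= min_channels
    return EpochStats(sigma=sigma, channel_flags=flags, epoch_bad=epoch_bad)


def hfc_projector(array: SensorArray, channel_good: np.ndarray | None = None) -> np.ndarray:
    """Orthogonal projector onto the complement of homogeneous field patterns.

    A spatially uniform field B couples into channel i as o_i . B, so the
    three columns of the good-channel orientation matrix N span every
    uniform-field footprint. Returns P = I - N N^+ (idempotent, symmetric,
    rank n_good - rank(N)).
    """
    if channel_good is None:
        channel_good = np.ones(array.n_channels, dtype=bool)
    N = array.orientations[channel_good]
    if N.shape[0] < 4:
        raise ValueError("need at least 4 good channels for HFC")
    if np.linalg.matrix_rank(N) < 3:
        warnings.warn(
            "orientation matrix rank < 3: projecting only the spanned subspace",
            RuntimeWarning,
        )
    return np.eye(N.shape[0]) - N @ np.linalg.pinv(N)


def homogeneous_field_correction(rec: Recording, array: SensorArray) -> Recording:
    """Remove the best-fitting spatially homogeneous field at every sample."""
    P = hfc_projector(array, rec.channel_good)
    data = rec.data.copy()
    data[rec.channel_good] = P @ data[rec.channel_good]
    return rec.copy_with(data=data)


class Preprocessor(BaseEstimator):
    """Fit/transform wrapper around the preprocessing chain.

    ``fit`` runs notch + broadband filtering, then derives the channel and
    epoch masks from the filtered data; ``transform`` returns the cleaned
    Recording (filtered, masked, HFC-projected). The sensor array is passed
    at fit time because channel orientations define the HFC projector.

    Attributes (after fit)
    ----------------------
    channel_good_ : bool array, channels kept
    epoch_stats_ : EpochStats from the rejection rule
    epoch_good_ : bool array, epochs kept
    projector_ : HFC projector over good channels
    """

    def __init__(
        self,
        notch_freq: float = 50.0,
        notch_q: float = 35.0,
        bp_lo: float = 1.0,
        bp_hi: float = 150.0,
        epoch_length_s: float = 5.0,
        sd_thresh: float = 3.0,
        min_channels: int = 2,
        apply_hfc: bool = True,
    ):
        self.notch_freq = notch_freq
        self.notch_q = notch_q
        self.bp_lo = bp_lo
        self.bp_hi = bp_hi
        self.epoch_length_s = epoch_length_s
        self.sd_thresh = sd_thresh
        self.min_channels = min_channels
        self.apply_hfc = apply_hfc

    def _filtered(self, rec: Recording) -> Recording:
        rec = rec.copy_with(epoch_length_s=self.epoch_length_s)
        rec = notch_filter(rec, self.notch_freq, self.notch_q)
        return bandpass_recording(rec, self.bp_lo, self.bp_hi)

    def fit(self, rec: Recording, array: SensorArray):
        if array.n_channels != rec.n_channels:
            raise ValueError("sensor array does not match recording")
        filt = self._filtered(rec)
        self.channel_good_ = detect_bad_channels(filt)
        masked = filt.copy_with(channel_good=self.channel_good_)
        self.epoch_stats_ = detect_bad_epochs(masked, self.sd_thresh, self.min_channels)
        self.epoch_good_ = ~self.epoch_stats_.epoch_bad
        self.array_ = array
        self.projector_ = (
            hfc_projector(array, self.channel_good_) if self.apply_hfc else None
        )
        return self

    def transform(self, rec: Recording) -> Recording:
        filt = self._filtered(rec)
        out = filt.copy_with(
            channel_good=self.channel_good_.copy(), epoch_good=self.epoch_good_.copy()
        )
        if self.apply_hfc:
            out = homogeneous_field_correction(out, self.array_)
        return out

    def fit_transform(self, rec: Recording, array: SensorArray) -> Recording:
        return self.fit(rec, array).transform(rec)
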
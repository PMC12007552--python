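"""Core containers for the OPM-MEG connectome pipeline.

Conventions: field values in fT, positions in metres in a head-centred
right-handed frame with the z axis through the vertex and the conductor
sphere centred at the origin. Triaxial sensors contribute three channels
each (one position shared by three orthogonal orientation axes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bands import BandDefinition, band_catalog

__all__ = [
    "SensorArray",
    "Recording",
    "ParcelSet",
    "Connectome",
    "PipelineConfig",
]

_UNIT_TOL = 1e-9


@dataclass
class SensorArray:
    """Per-channel geometry of a (tri-axial) OPM array.

    Attributes
    ----------
    positions : (n_channels, 3) float array
        Channel positions in metres (head-centred frame).
    orientations : (n_channels, 3) float array
        Unit sensitive-axis vector per channel.
    sensor_id : (n_channels,) int array
        Physical sensor index; the three channels of one triaxial sensor
        share a position and have mutually orthogonal orientations.
    """

    positions: np.ndarray
    orientations: np.ndarray
    sensor_id: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.sensor_id = np.asarray(self.sensor_id, dtype=int)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_channels, 3)")
        if self.orientations.shape != self.positions.shape:
            raise ValueError("orientations must match positions shape")
        if self.sensor_id.shape != (self.positions.shape[0],):
            raise ValueError("sensor_id must be (n_channels,)")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("orientations must be unit vectors")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def subset(self, mask: np.ndarray) -> "SensorArray":
        """Restrict to the channels where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return SensorArray(
            self.positions[mask], self.orientations[mask], self.sensor_id[mask]
        )

    def validate_outside_sphere(self, radius: float) -> None:
        if np.any(np.linalg.norm(self.positions, axis=1) <= radius):
            raise ValueError("all sensor positions must lie outside the conductor sphere")


@dataclass
class Recording:
    """A channels x samples MEG recording with rejection masks.

    ``data`` holds field values in fT. ``epoch_good`` is None until epochs
    have been segmented and screened; the epoch grid tiles the duration in
    non-overlapping ``epoch_length_s`` windows (trailing partial discarded).
    """

    data: np.ndarray
    fs: float
    channel_good: np.ndarray | None = None
    epoch_length_s: float = 5.0
    epoch_good: np.ndarray | None = None
    subject_id: str = "s00"
    run_id: str = "r1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.channel_good is None:
            self.channel_good = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.channel_good = np.asarray(self.channel_good, dtype=bool)
            if self.channel_good.shape != (self.data.shape[0],):
                raise ValueError("channel_good must be (n_channels,)")
        if self.epoch_good is not None:
            self.epoch_good = np.asarray(self.epoch_good, dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_length_s * self.fs))

    @property
    def n_epochs(self) -> int:
        return self.n_samples // self.samples_per_epoch

    def copy_with(self, **kwargs) -> "Recording":
        out = replace(self, **kwargs)
        return out

    def good_epoch_data(self) -> np.ndarray:
        """Concatenated good-epoch samples for good channels only."""
        spe = self.samples_per_epoch
        n_ep = self.n_epochs
        x = self.data[self.channel_good, : n_ep * spe]
        if self.epoch_good is None:
            return x
        keep = np.repeat(self.epoch_good[:n_ep], spe)
        return x[:, keep]


@dataclass
class ParcelSet:
    """Parcel centroids (synthetic stand-in for atlas region centres of mass)."""

    centroids: np.ndarray
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[1] != 3:
            raise ValueError("centroids must be (n_parcels, 3)")
        if self.centroids.shape[0] < 2:
            raise ValueError("need at least 2 parcels")
        if self.labels is None:
            self.labels = [f"parcel{i:03d}" for i in range(self.centroids.shape[0])]
        elif len(self.labels) != self.centroids.shape[0]:
            raise ValueError("labels length must equal n_parcels")

    @property
    def n_parcels(self) -> int:
        return self.centroids.shape[0]

    def validate_inside_sphere(self, radius: float) -> None:
        if np.any(np.linalg.norm(self.centroids, axis=1) >= radius):
            raise ValueError("all parcel centroids must lie inside the conductor sphere")


@dataclass
class Connectome:
    """P x P symmetric amplitude-envelope-correlation matrix (diagonal 0)."""

    values: np.ndarray
    band: str
    subject: str = "s00"
    run: str = "r1"
    normalised: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = self.values
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("connectome must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("connectome must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("connectome diagonal must be exactly 0")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline, with study defaults.

    Defaults: 5-s epochs; 50 Hz notch at Q=35; 1-150 Hz broadband; 5%
    Tikhonov covariance regularisation; envelopes down-sampled to 120 Hz;
    an epoch is rejected when at least two channels exceed 3 SD; permutation
    null built from 100,000 iterations.
    """

    bands: list[BandDefinition] = field(default_factory=band_catalog)
    epoch_length_s: float = 5.0
    notch_freq: float = 50.0
    notch_q: float = 35.0
    bp_lo: float = 1.0
    bp_hi: float = 150.0
    reg_fraction: float = 0.05
    envelope_fs: float = 120.0
    epoch_flag_sd: float = 3.0
    epoch_flag_min_channels: int = 2
    permutation_iters: int = 100_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "epoch_length_s": self.epoch_length_s,
            "notch_freq": self.notch_freq,
            "notch_q": self.notch_q,
            "bp_lo": self.bp_lo,
            "bp_hi": self.bp_hi,
            "envelope_fs": self.envelope_fs,
            "epoch_flag_sd": self.epoch_flag_sd,
            "epoch_flag_min_channels": self.epoch_flag_min_channels,
            "permutation_iters": self.permutation_iters,
        }
        for name, v in positive.items():
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not (0 < self.reg_fraction < 1):
            raise ValueError("reg_fraction must lie in (0, 1)")
        if not self.bp_lo < self.bp_hi:
            raise ValueError("bp_lo must be < bp_hi")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = [BandDefinition(**b) for b in d["bands"]]
        return cls(**d)
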
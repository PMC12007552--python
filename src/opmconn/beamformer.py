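"""Scalar LCMV beamformer with optimal source orientation.

For each parcel the three-column leadfield L (channels x dipole axes) and a
regularised band-limited data covariance C_r define a scalar spatial
filter. The source orientation eta maximises the beamformer-projected
signal amplitude under the unit-gain constraint, which reduces to the
eigenvector of A = L^T C_r^{-1} L with the smallest eigenvalue (the
projected power along eta is (eta^T A eta)^{-1}). The weights are the
standard linearly-constrained minimum-variance solution
w = C_r^{-1} l / (l^T C_r^{-1} l) with l = L eta, giving unit gain
w^T l = 1 at the parcel's own source.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .bands import BROADBAND, BandDefinition
from .datatypes import ParcelSet, Recording, SensorArray
from .forward import parcel_leadfields
from .preprocess import bandpass_filter

__all__ = [
    "compute_covariance",
    "regularize_covariance",
    "optimal_orientation",
    "lcmv_weights",
    "project_sources",
    "LCMVBeamformer",
]


def compute_covariance(
    clean: Recording, band: BandDefinition | None = None
) -> np.ndarray:
    """Channel covariance (fT^2) of band-passed, good-epoch concatenated data.

    ``band=None`` uses the data as-is (it is normally already broadband
    filtered by preprocessing). Computed over good channels only.
    """
    rec = clean
    if band is not None:
        rec = clean.copy_with(
            data=bandpass_filter(clean.data, band.lo, band.hi, clean.fs)
        )
    x = rec.good_epoch_data()
    if x.shape[1] < x.shape[0]:
        warnings.warn(
            "fewer samples than channels: covariance is rank deficient",
            RuntimeWarning,
        )
    x = x - x.mean(axis=1, keepdims=True)
    return (x @ x.T) / (x.shape[1] - 1)


def regularize_covariance(
    C: np.ndarray, reg_fraction: float = 0.05
) -> tuple[np.ndarray, float]:
    """Tikhonov regularisation: add ``reg_fraction`` of the largest singular
    value of C to the diagonal. Returns ``(C_r, mu)``."""
    C = np.asarray(C, dtype=float)
    w = np.linalg.eigvalsh((C + C.T) / 2.0)
    mu = reg_fraction * np.abs(w).max() if C.size else 0.0
    return C + mu * np.eye(C.shape[0]), float(mu)


def _sym_inverse(C: np.ndarray, rel_floor: float = 1e-12) -> np.ndarray:
    """Inverse via symmetric eigendecomposition with a relative eigenvalue floor."""
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    floor = rel_floor * w.max()
    w = np.where(w > floor, w, floor)
    return (V / w) @ V.T


def optimal_orientation(L: np.ndarray, C_r: np.ndarray) -> np.ndarray:
    """Orientation of maximum beamformer-projected amplitude (unit 3-vector).

    Eigenvector of A = L^T C_r^{-1} L with the smallest eigenvalue; if the
    leadfield is rank deficient (e.g. a near-central dipole whose radial
    moment is silent), the search is restricted to the spanned subspace.
    The sign is fixed so the largest-magnitude component is positive.
    """
    L = np.asarray(L, dtype=float)
    if not np.any(L):
        raise ValueError("leadfield is identically zero")
    Ci = _sym_inverse(C_r)
    A = L.T @ Ci @ L
    w, V = np.linalg.eigh((A + A.T) / 2.0)
    # eigenvalues of A below the numerical rank correspond to silent moments
    keep = w > 1e-10 * w.max()
    if not keep.any():
        raise ValueError("leadfield numerically silent in all directions")
    idx = np.flatnonzero(keep)[0]  # smallest eigenvalue among non-silent
    eta = V[:, idx]
    if eta[np.argmax(np.abs(eta))] < 0:
        eta = -eta
    return eta


def lcmv_weights(L: np.ndarray, eta: np.ndarray, C_r: np.ndarray) -> np.ndarray:
    """Unit-gain LCMV weight vector for the scalar source L @ eta."""
    l = np.asarray(L, dtype=float) @ np.asarray(eta, dtype=float)
    if not np.any(l):
        raise ValueError("projected leadfield is zero: undefined source")
    Ci_l = _sym_inverse(C_r) @ l
    return Ci_l / (l @ Ci_l)


def project_sources(rec: Recording, weights: np.ndarray, good_epochs_only: bool = True) -> np.ndarray:
    """Apply beamformer weights: (P, n_good_channels) @ data -> (P, T).

    The same weights apply unchanged to an empty-room recording to obtain
    the projected sensor-noise floor.
    """
    weights = np.atleast_2d(weights)
    x = rec.good_epoch_data() if good_epochs_only else rec.data[rec.channel_good]
    if weights.shape[1] != x.shape[0]:
        raise ValueError(
            f"weight length {weights.shape[1]} != good channel count {x.shape[0]}"
        )
    return weights @ x


class LCMVBeamformer(BaseEstimator):
    """Scalar LCMV beamformer estimator for one frequency band.

    ``fit`` computes leadfields, the band-limited covariance over good
    epochs, its Tikhonov-regularised inverse, per-parcel optimal
    orientations and unit-gain weights; ``transform`` projects a recording
    to parcel time series in the fitted band.

    Parameters
    ----------
    band : BandDefinition or None
        Band of interest; None means the broadband (1-150 Hz) covariance.
    reg_fraction : float
        Fraction of the covariance's largest singular value added to the
        diagonal (default 0.05).
    sensor_projector : array or None
        Optional projector (e.g. from homogeneous field correction) applied
        to the leadfields so the forward model lives in the same projected
        space as the data.

    Attributes (after fit)
    ----------------------
    leadfields_ : (P, n_good, 3) projected leadfields
    covariance_, covariance_reg_, mu_ : band covariance and regularisation
    orientations_ : (P, 3) optimal unit dipole orientations
    weights_ : (P, n_good) unit-gain weight matrix
    """

    def __init__(
        self,
        band: BandDefinition | None = None,
        reg_fraction: float = 0.05,
        sensor_projector: np.ndarray | None = None,
    ):
        self.band = band
        self.reg_fraction = reg_fraction
        self.sensor_projector = sensor_projector

    def fit(self, rec: Recording, parcels: ParcelSet, array: SensorArray):
        good = rec.channel_good
        L_full = parcel_leadfields(parcels, array)  # (P, N_all, 3)
        L = L_full[:, good, :]
        if self.sensor_projector is not None:
            L = np.einsum("mn,pnk->pmk", self.sensor_projector, L)
        self.leadfields_ = L
        self.covariance_ = compute_covariance(rec, self.band)
        self.covariance_reg_, self.mu_ = regularize_covariance(
            self.covariance_, self.reg_fraction
        )
        P = parcels.n_parcels
        self.orientations_ = np.empty((P, 3))
        self.weights_ = np.empty((P, L.shape[1]))
        for p in range(P):
            eta = optimal_orientation(L[p], self.covariance_reg_)
            self.orientations_[p] = eta
            self.weights_[p] = lcmv_weights(L[p], eta, self.covariance_reg_)
        return self

    def transform(self, rec: Recording, good_epochs_only: bool = True) -> np.ndarray:
        """Band-pass ``rec`` to the fitted band and project to parcels."""
        data = rec.data
        if self.band is not None:
            data = bandpass_filter(data, self.band.lo, self.band.hi, rec.fs)
        banded = rec.copy_with(data=data)
        return project_sources(banded, self.weights_, good_epochs_only)

    def fit_transform(
        self, rec: Recording, parcels: ParcelSet, array: SensorArray
    ) -> np.ndarray:
        return self.fit(rec, parcels, array).transform(rec)


def broadband_beamformer(**kwargs) -> LCMVBeamformer:
    """Beamformer on the broadband (1-150 Hz) covariance."""
    return LCMVBeamformer(band=BROADBAND, **kwargs)
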
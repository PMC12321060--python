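"""Band-pass filtering, Hilbert phase, and wPLI connectivity matrices.

Two phase-lag estimators are provided:

``paper_formula`` (default)
    ``|mean_k sin(Δφ_k)|`` — the magnitude of the time-averaged sine of the
    instantaneous phase difference. Zero-lag (volume-conduction-like)
    coupling contributes nothing because ``sin(0) = 0``; a constant lag φ
    yields ``|sin φ|``.

``standard_wpli``
    The weighted phase lag index of Vinck et al.:
    ``|E[Im S]| / E[|Im S|]`` where ``S`` is the cross-spectrum of the two
    analytic signals. When only phases are available the amplitudes are
    taken as 1, reducing ``Im S`` to ``sin(Δφ)``.

Both are amplitude-invariant (the phase extraction discards amplitude;
``standard_wpli`` additionally self-normalizes) and bounded in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .montage import Montage, default_montage
from .spectral import Band, get_band

__all__ = [
    "ESTIMATORS",
    "PhaseSeries",
    "ConnectivityMatrix",
    "bandpass",
    "instantaneous_phase",
    "wpli_pair",
    "connectivity_matrix",
]

ESTIMATORS = ("paper_formula", "standard_wpli")

#: Seconds of filter edge transient excluded from phase statistics.
EDGE_SECONDS = 1.0


@dataclass
class PhaseSeries:
    """Instantaneous phase per channel (radians, in (−π, π])."""

    phases: np.ndarray  # (n_channels, n_samples) or (n_samples,)
    band: Band


@dataclass
class ConnectivityMatrix:
    """Symmetric channel × channel phase-coupling weights for one band."""

    weights: np.ndarray
    band: Band
    estimator: str
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        w = self.weights
        if w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be exactly 0")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("weights must lie in [0, 1]")


def bandpass(
    x: np.ndarray, band: Band, fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    A forward-backward 4th-order filter (8th order effective). The first and
    last ``EDGE_SECONDS * fs`` samples carry filter transients; downstream
    phase statistics trim them (see :func:`connectivity_matrix`).
    """
    band = get_band(band)
    if band.hi >= fs / 2:
        raise ValueError(
            f"band {band.name!r} upper edge {band.hi} Hz is at or above "
            f"Nyquist ({fs / 2:g} Hz)"
        )
    sos = sps.butter(order, [band.lo, band.hi], btype="bandpass", fs=fs,
                     output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def instantaneous_phase(x: np.ndarray, band: Band | None = None) -> PhaseSeries:
    """Phase of the analytic (Hilbert) signal, per sample.

    ``x`` must already be band-limited; the phase of a broadband signal is
    not interpretable.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    analytic = sps.hilbert(x, axis=-1)
    return PhaseSeries(phases=np.angle(analytic), band=band)


def wpli_pair(
    phase_i: np.ndarray,
    phase_j: np.ndarray,
    estimator: str = "paper_formula",
) -> float:
    """Phase-lag coupling between two phase time series, in [0, 1].

    Parameters
    ----------
    phase_i, phase_j
        Instantaneous phase arrays of equal length ``N >= 2`` (radians).
    estimator
        ``"paper_formula"`` or ``"standard_wpli"`` (see module docstring).
    """
    phase_i = np.asarray(phase_i, dtype=float).ravel()
    phase_j = np.asarray(phase_j, dtype=float).ravel()
    if phase_i.shape != phase_j.shape:
        raise ValueError("phase series have different lengths")
    if phase_i.size < 2:
        raise ValueError("need at least 2 samples")
    s = np.sin(phase_i - phase_j)
    if estimator == "paper_formula":
        return float(abs(s.mean()))
    if estimator == "standard_wpli":
        denom = np.abs(s).mean()
        if denom == 0:
            return 0.0
        return float(abs(s.mean()) / denom)
    raise ValueError(f"unknown estimator {estimator!r}; expected one of {ESTIMATORS}")


def _pairwise_paper(Z: np.ndarray) -> np.ndarray:
    # Z: (n_ch, N) unit-modulus e^{i phi}; mean sin(phi_i - phi_j) is the
    # imaginary part of the row-wise cross products, via one BLAS call.
    n = Z.shape[1]
    C = (Z @ Z.conj().T) / n
    return np.abs(C.imag)


def _pairwise_standard(A: np.ndarray) -> np.ndarray:
    # A: (n_ch, N) analytic signals. |E[Im S]| / E[|Im S|] with
    # S_ij = a_i conj(a_j); the denominator needs an element-wise pass.
    n_ch, n = A.shape
    num = np.abs((A @ A.conj().T).imag) / n
    den = np.empty((n_ch, n_ch))
    for i in range(n_ch):
        den[i] = np.abs((A[i][None, :] * A.conj()).imag).mean(axis=1)
    den = 0.5 * (den + den.T)  # symmetrize away round-off
    out = np.zeros_like(num)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def connectivity_matrix(
    recording,
    band: Band | str,
    estimator: str = "paper_formula",
    montage: Montage | None = None,
    edge_seconds: float = EDGE_SECONDS,
) -> ConnectivityMatrix:
    """Band-limited phase-coupling matrix for one recording.

    Filters every channel to ``band``, extracts Hilbert phases, trims
    ``edge_seconds`` of filter transient from both ends, and evaluates the
    chosen estimator for all unique channel pairs (mirrored; diagonal 0).

    ``recording`` is any object with ``data`` (channels × samples), ``fs``
    and ``channels`` attributes matching the montage.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; expected one of {ESTIMATORS}")
    band = get_band(band)
    montage = montage or default_montage()
    if tuple(recording.channels) != montage.channels:
        missing = set(montage.channels) - set(recording.channels)
        raise ValueError(
            f"recording channels do not match the montage"
            + (f"; missing {sorted(missing)}" if missing else " (order differs)")
        )
    filtered = bandpass(recording.data, band, recording.fs)
    analytic = sps.hilbert(filtered, axis=-1)
    trim = int(round(edge_seconds * recording.fs))
    if analytic.shape[-1] <= 2 * trim + 2:
        raise ValueError("recording too short after edge trimming")
    if trim:
        analytic = analytic[..., trim:-trim]
    if estimator == "paper_formula":
        phase = np.angle(analytic)
        weights = _pairwise_paper(np.exp(1j * phase))
    else:
        weights = _pairwise_standard(analytic)
    np.fill_diagonal(weights, 0.0)
    weights = np.clip(0.5 * (weights + weights.T), 0.0, 1.0)
    np.fill_diagonal(weights, 0.0)
    return ConnectivityMatrix(
        weights=weights, band=band, estimator=estimator,
        channels=montage.channels,
    )
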
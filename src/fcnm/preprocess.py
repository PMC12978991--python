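"""Confound handling for already-aligned 4D resting-state data.

Implements the motion- and nuisance-related steps that operate after
registration: framewise displacement (Power's formulation), the Friston-24
motion expansion, FD-spike indicator regressors, multiple linear nuisance
regression, zero-phase band-pass filtering, Gaussian smoothing, and
motion-based subject exclusion.  Registration, segmentation and slice
timing are out of scope: motion traces and aligned volumes are inputs.

Order of application follows the conventional sequence: discard initial
volumes, regress nuisance covariates, band-pass filter, smooth.  Every
function is pure given its inputs.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class PreprocessError(ValueError):
    pass


def framewise_displacement(
    motion: np.ndarray, head_radius_mm: float = 50.0
) -> np.ndarray:
    """Power's framewise displacement, in mm.

    FD(t) = sum of absolute frame-to-frame translation changes plus
    ``head_radius_mm`` times the sum of absolute rotation changes
    (rotations in radians, arc length on a sphere of the given radius).
    FD at the first frame is 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise PreprocessError(f"motion must be T x 6, got {motion.shape}")
    if motion.shape[0] < 2:
        raise PreprocessError("need at least 2 frames for FD")
    if not np.all(np.isfinite(motion)):
        raise PreprocessError("non-finite motion parameters")
    diff = np.abs(np.diff(motion, axis=0))
    fd = diff[:, :3].sum(axis=1) + head_radius_mm * diff[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def friston24(motion: np.ndarray) -> np.ndarray:
    """Friston 24-parameter motion expansion.

    Columns: the 6 parameters, their one-frame lags (first row zero),
    their squares, and the squared lags.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise PreprocessError(f"motion must be T x 6, got {motion.shape}")
    lag = np.vstack([np.zeros((1, 6)), motion[:-1]])
    return np.hstack([motion, lag, motion**2, lag**2])


def spike_regressors(fd: np.ndarray, threshold_mm: float = 0.5) -> np.ndarray:
    """One indicator column per volume with FD strictly above threshold."""
    fd = np.asarray(fd, dtype=float)
    spikes = np.flatnonzero(fd > threshold_mm)
    out = np.zeros((fd.shape[0], len(spikes)))
    out[spikes, np.arange(len(spikes))] = 1.0
    return out


def build_confounds(
    motion: np.ndarray,
    fd_threshold_mm: float = 0.5,
    extra_signals: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the nuisance design: Friston-24, FD spikes, any extra
    signals (global / white-matter / CSF means), linear drift, intercept.

    Returns the T x K matrix and column names.
    """
    f24 = friston24(motion)
    fd = framewise_displacement(motion)
    spikes = spike_regressors(fd, fd_threshold_mm)
    T = f24.shape[0]
    cols = [f24, spikes]
    names = [f"friston24_{i}" for i in range(24)]
    names += [f"spike_{i}" for i in range(spikes.shape[1])]
    for name, sig in (extra_signals or {}).items():
        sig = np.asarray(sig, dtype=float).reshape(-1, 1)
        if sig.shape[0] != T:
            raise PreprocessError(f"signal {name!r} length {sig.shape[0]} != T={T}")
        cols.append(sig)
        names.append(name)
    drift = np.linspace(-1.0, 1.0, T).reshape(-1, 1)
    cols += [drift, np.ones((T, 1))]
    names += ["linear_drift", "intercept"]
    return np.hstack(cols), names


def nuisance_regress(
    ts: np.ndarray, confounds: np.ndarray, names: list[str] | None = None
) -> np.ndarray:
    """Least-squares residuals of ``ts`` (T x V) on the confound design.

    The design must have full column rank; a rank-deficient design raises
    an error naming the (first) collinear columns found by QR.
    """
    ts = np.asarray(ts, dtype=float)
    confounds = np.asarray(confounds, dtype=float)
    T, K = confounds.shape
    if ts.shape[0] != T:
        raise PreprocessError(f"ts has {ts.shape[0]} rows, confounds {T}")
    if T <= K:
        raise PreprocessError(f"need T > K confound columns (T={T}, K={K})")
    # rank check on unit-norm columns so wildly different scales (mm vs
    # squared radians) do not masquerade as collinearity; all-zero columns
    # are inert and ignored
    norms = np.linalg.norm(confounds, axis=0)
    nonzero = norms > 0
    scaled = confounds[:, nonzero] / norms[nonzero]
    r = np.linalg.qr(scaled, mode="r")
    diag = np.abs(np.diag(r))
    bad_scaled = np.flatnonzero(diag < 1e-8)
    if len(bad_scaled):
        bad = np.flatnonzero(nonzero)[bad_scaled]
        labels = (
            [names[i] for i in bad] if names is not None else [int(i) for i in bad]
        )
        raise PreprocessError(f"rank-deficient confound design; columns {labels}")
    beta, *_ = np.linalg.lstsq(confounds, ts, rcond=None)
    return ts - confounds @ beta


def bandpass(
    ts: np.ndarray,
    tr_s: float,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    transition_hz: float = 0.005,
) -> np.ndarray:
    """Zero-phase band-pass via frequency-domain masking.

    The gain is 1 inside [low, high], 0 beyond a cosine-tapered transition
    of width ``transition_hz`` outside each edge, and the DC term is always
    removed when ``low_hz`` > 0.  Deterministic and phase-preserving;
    edge effects are those of the implicit periodic extension.
    """
    ts = np.asarray(ts, dtype=float)
    nyquist = 0.5 / tr_s
    if not (0 <= low_hz < high_hz):
        raise PreprocessError(f"need 0 <= low < high, got ({low_hz}, {high_hz})")
    if high_hz > nyquist:
        raise PreprocessError(
            f"high cutoff {high_hz} Hz exceeds Nyquist {nyquist} Hz for TR={tr_s}s"
        )
    T = ts.shape[0]
    freqs = np.fft.rfftfreq(T, d=tr_s)
    gain = np.zeros_like(freqs)
    gain[(freqs >= low_hz) & (freqs <= high_hz)] = 1.0
    if transition_hz > 0:
        lo_band = (freqs >= low_hz - transition_hz) & (freqs < low_hz)
        gain[lo_band] = 0.5 * (
            1 + np.cos(np.pi * (low_hz - freqs[lo_band]) / transition_hz)
        )
        hi_band = (freqs > high_hz) & (freqs <= high_hz + transition_hz)
        gain[hi_band] = 0.5 * (
            1 + np.cos(np.pi * (freqs[hi_band] - high_hz) / transition_hz)
        )
    if low_hz > 0:
        gain[0] = 0.0
    spec = np.fft.rfft(ts, axis=0)
    shape = [len(freqs)] + [1] * (ts.ndim - 1)
    return np.fft.irfft(spec * gain.reshape(shape), n=T, axis=0)


def gaussian_smooth(vol3d: np.ndarray, fwhm_mm: float, grid) -> np.ndarray:
    """Separable Gaussian smoothing with a kernel of the given FWHM in mm.

    Sigma per axis is fwhm/(2*sqrt(2*ln 2)) divided by the voxel size on
    that axis; fwhm 0 is the identity.  Zero-padded boundaries.
    """
    if fwhm_mm < 0:
        raise PreprocessError(f"fwhm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return np.asarray(vol3d, dtype=float).copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / grid.voxel_sizes_mm
    return ndimage.gaussian_filter(
        np.asarray(vol3d, dtype=float), sigma=sigma_vox, mode="constant", cval=0.0
    )


def motion_exclude(
    motion: np.ndarray, trans_limit_mm: float, rot_limit_deg: float
) -> bool:
    """True if the subject should be *kept*.

    Drop when any absolute translation reaches ``trans_limit_mm`` or any
    absolute rotation reaches ``rot_limit_deg`` (rotations are stored in
    radians and converted before comparison).
    """
    if trans_limit_mm <= 0 or rot_limit_deg <= 0:
        raise PreprocessError("motion limits must be positive")
    motion = np.asarray(motion, dtype=float)
    max_trans = np.abs(motion[:, :3]).max()
    max_rot_deg = np.degrees(np.abs(motion[:, 3:]).max())
    return bool(max_trans < trans_limit_mm and max_rot_deg < rot_limit_deg)
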
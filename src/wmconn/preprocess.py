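"""BOLD time-series cleaning: volume dropping, motion scrubbing, bandpass.

The cleaning chain is: drop the first volumes of each run, compute
framewise displacement (FD) from the six rigid-body realignment
parameters, mark high-motion frames plus neighbours for censoring,
linearly detrend and bandpass-filter the full series, and delete the
censored frames only afterwards (filtering before deletion avoids
spectral leakage from gaps).  Frame censoring is deletion, not
interpolation, and no spatial smoothing is ever applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "FDTrace",
    "CensorMask",
    "drop_initial",
    "framewise_displacement",
    "scrub",
    "bandpass",
]


@dataclass(frozen=True)
class FDTrace:
    """Per-volume framewise displacement in millimetres (first volume 0)."""

    fd: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        fd = np.asarray(self.fd, dtype=float)
        if (fd < 0).any():
            raise ValueError("framewise displacement cannot be negative")
        object.__setattr__(self, "fd", fd)

    def spikes(self, threshold: float | None = None) -> np.ndarray:
        thr = self.threshold if threshold is None else threshold
        return np.flatnonzero(self.fd > thr)


@dataclass(frozen=True)
class CensorMask:
    """Boolean keep-flag per volume; False frames are removed before correlation."""

    keep: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "keep", np.asarray(self.keep, dtype=bool))

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


def drop_initial(series: np.ndarray, n_drop: int = 10) -> np.ndarray:
    """Remove the first ``n_drop`` frames (time on the last axis)."""
    series = np.asarray(series)
    if n_drop < 0:
        raise ValueError("n_drop must be non-negative")
    if series.shape[-1] <= n_drop:
        raise ValueError(
            f"series has {series.shape[-1]} frames, cannot drop {n_drop}"
        )
    return series[..., n_drop:]


def framewise_displacement(motion: np.ndarray, sphere_radius: float = 50.0) -> FDTrace:
    """Framewise displacement from a T x 6 realignment table.

    Columns are three translations (mm) then three rotations (radians);
    rotations are converted to arc length on a sphere of
    ``sphere_radius`` mm (Power's convention):

        fd[t] = sum |d translation| + radius * sum |d rotation|,  fd[0] = 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, got shape {motion.shape}")
    delta = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = delta[:, :3].sum(axis=1) + sphere_radius * delta[:, 3:].sum(axis=1)
    return FDTrace(fd)


def scrub(
    fd: FDTrace,
    threshold: float = 0.5,
    n_forward: int = 1,
    n_back: int = 2,
) -> CensorMask:
    """Censor frames with FD above threshold together with neighbours.

    Each spike frame s removes frames s - n_back .. s + n_forward
    ("one forward neighbour and two back neighbours" by default),
    clipped at the run boundaries.
    """
    n = len(fd.fd)
    keep = np.ones(n, dtype=bool)
    for s in np.flatnonzero(fd.fd > threshold):
        lo = max(0, s - n_back)
        hi = min(n, s + n_forward + 1)
        keep[lo:hi] = False
    return CensorMask(keep)


def bandpass(
    series: np.ndarray,
    tr: float,
    low: float = 0.01,
    high: float = 0.10,
    method: str = "ideal",
) -> np.ndarray:
    """Linear detrend then bandpass (default 0.01-0.10 Hz) along the last axis.

    ``method="ideal"`` applies a frequency-domain brick-wall filter
    retaining rFFT bins with low <= f <= high (the DPABI/REST lineage);
    ``method="butterworth"`` applies a zero-phase 4th-order Butterworth.
    """
    series = np.asarray(series, dtype=float)
    if tr <= 0:
        raise ValueError("tr must be positive")
    nyquist = 1.0 / (2.0 * tr)
    if high >= nyquist:
        raise ValueError(f"high cutoff {high} Hz is at or above Nyquist {nyquist} Hz")
    if not 0 <= low < high:
        raise ValueError("need 0 <= low < high")
    n = series.shape[-1]
    detrended = sps.detrend(series, axis=-1, type="linear")
    if method == "ideal":
        freqs = np.fft.rfftfreq(n, d=tr)
        spectrum = np.fft.rfft(detrended, axis=-1)
        band = (freqs >= low) & (freqs <= high)
        spectrum[..., ~band] = 0
        return np.fft.irfft(spectrum, n=n, axis=-1)
    if method == "butterworth":
        sos = sps.butter(4, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
        return sps.sosfiltfilt(sos, detrended, axis=-1)
    raise ValueError(f"unknown bandpass method {method!r}")
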
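"""Per-burst accelerometer feature extraction.

A *burst* is a ~3 second window of raw tri-axial samples recorded every few
minutes. Because participants carry phones in arbitrary orientations, all
features are computed on the orientation-invariant *deviation magnitude*:
the Euclidean norm of each sample after subtracting the burst's estimated
gravity vector (the per-axis mean). The magnitude series is linearly
interpolated onto a uniform grid and summarized by eight features: its mean
and standard deviation, and five descriptors of its Welch power spectral
density (dominant non-DC frequency, spectral entropy of the normalized
non-DC spectrum, and power integrated over low/mid/high frequency bands
plus the total non-DC power).

Numerical conventions (degenerate inputs):

* a burst whose deviation magnitude is identically zero has ``mean_mag``,
  ``sd_mag``, all powers, ``dominant_freq`` and ``spectral_entropy`` equal
  to 0;
* the dominant frequency excludes the DC bin, which reflects residual
  gravity estimation error rather than movement;
* spectral entropy uses the natural logarithm over normalized non-DC bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import welch

logger = logging.getLogger(__name__)

#: uniform resampling rate (Hz); above twice any plausible locomotion harmonic
RESAMPLE_HZ = 32.0
#: Welch segment length in samples (1 s at 32 Hz, >= 5 averaged segments per burst)
WELCH_NPERSEG = 32
#: band edges in Hz: low (0, 1], mid (1, 5], high (5, Nyquist]
BAND_LOW_HZ = 1.0
BAND_MID_HZ = 5.0

#: minimum number of raw samples for a usable burst
MIN_SAMPLES = 4
#: maximum burst span in seconds (2x the nominal 3 s window)
MAX_SPAN_S = 6.0

FEATURE_NAMES = (
    "mean_mag",
    "sd_mag",
    "dominant_freq",
    "spectral_entropy",
    "power_low",
    "power_mid",
    "power_high",
    "power_total",
)


class BurstRejected(ValueError):
    """Raised when a burst fails the minimal quality checks.

    Rejected bursts are counted and become missing observations downstream.
    """


@dataclass
class AccelBurst:
    """One burst of raw tri-axial accelerometer samples.

    ``t`` holds within-burst sample times in seconds (strictly increasing);
    ``xyz`` is an (n, 3) array in m/s^2.
    """

    participant_id: str
    burst_id: str
    t: np.ndarray
    xyz: np.ndarray
    t_unix_s: float = 0.0  # absolute time of the first sample

    def validate(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or self.xyz.shape != (t.size, 3):
            raise BurstRejected(f"burst {self.burst_id}: malformed sample arrays")
        if t.size < MIN_SAMPLES:
            raise BurstRejected(
                f"burst {self.burst_id}: {t.size} samples < {MIN_SAMPLES} (insufficient duration)"
            )
        if np.any(np.diff(t) <= 0):
            raise BurstRejected(f"burst {self.burst_id}: timestamps not strictly increasing")
        if t[-1] - t[0] > MAX_SPAN_S:
            raise BurstRejected(
                f"burst {self.burst_id}: span {t[-1] - t[0]:.2f}s exceeds {MAX_SPAN_S}s"
            )


@dataclass
class BurstFeatures:
    """The 8-dimensional feature vector summarizing one burst."""

    mean_mag: float
    sd_mag: float
    dominant_freq: float
    spectral_entropy: float
    power_low: float
    power_mid: float
    power_high: float
    power_total: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def estimate_gravity(burst: AccelBurst) -> np.ndarray:
    """Per-axis arithmetic mean of the burst's samples (m/s^2)."""
    burst.validate()
    return np.asarray(burst.xyz, dtype=float).mean(axis=0)


def deviation_magnitude(burst: AccelBurst, gravity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean norm of each sample after gravity subtraction.

    Returns ``(t, magnitude)`` with the same timestamps as the input burst.
    """
    dev = np.asarray(burst.xyz, dtype=float) - np.asarray(gravity, dtype=float)
    return np.asarray(burst.t, dtype=float), np.linalg.norm(dev, axis=1)


def resample_uniform(
    t: np.ndarray, v: np.ndarray, rate_hz: float = RESAMPLE_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Linear-spline interpolation of an irregular series onto a uniform grid.

    The grid runs from the first to the last timestamp at ``rate_hz``; no
    extrapolation occurs beyond the observed span.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.size < 2:
        raise BurstRejected("resampling needs at least 2 points")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    n_out = int(np.floor((t[-1] - t[0]) * rate_hz)) + 1
    grid = t[0] + np.arange(n_out) / rate_hz
    return grid, np.interp(grid, t, v)


def welch_psd(
    x: np.ndarray, rate_hz: float = RESAMPLE_HZ, nperseg: int = WELCH_NPERSEG
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density: averaged Hann-windowed overlapping segments.

    Segments are ``nperseg`` samples long with 50% overlap. A series shorter
    than one segment falls back to a single shorter segment (logged). The
    mean is *not* detrended, so a constant series puts all power in the DC
    bin.
    """
    x = np.asarray(x, dtype=float)
    if x.size < nperseg:
        logger.info("series of %d samples < segment %d: single-segment fallback", x.size, nperseg)
        nperseg = x.size
    freqs, psd = welch(
        x,
        fs=rate_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
        scaling="density",
    )
    return freqs, psd


def extract_features(burst: AccelBurst, rate_hz: float = RESAMPLE_HZ) -> BurstFeatures:
    """Compute the 8 burst features (see module docstring for conventions)."""
    gravity = estimate_gravity(burst)
    t, mag = deviation_magnitude(burst, gravity)
    _, mag_u = resample_uniform(t, mag, rate_hz)
    mean_mag = float(mag_u.mean())
    sd_mag = float(mag_u.std())

    # spectral features describe the fluctuation of the magnitude: center
    # the series so the large positive mean cannot leak out of the DC bin
    freqs, psd = welch_psd(mag_u - mean_mag, rate_hz)
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    f_nd = freqs[1:]
    p_nd = psd[1:] * df  # integrated per-bin power, non-DC
    total = float(p_nd.sum())
    if not np.isfinite(total) or total <= 0.0:
        return BurstFeatures(mean_mag, sd_mag, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    dominant = float(f_nd[int(np.argmax(psd[1:]))])
    q = p_nd / total
    qpos = q[q > 0]
    entropy = float(-(qpos * np.log(qpos)).sum())
    low = float(p_nd[f_nd <= BAND_LOW_HZ].sum())
    mid = float(p_nd[(f_nd > BAND_LOW_HZ) & (f_nd <= BAND_MID_HZ)].sum())
    high = float(p_nd[f_nd > BAND_MID_HZ].sum())
    return BurstFeatures(mean_mag, sd_mag, dominant, entropy, low, mid, high, total)


def extract_features_frame(
    accel: pd.DataFrame, rate_hz: float = RESAMPLE_HZ
) -> tuple[pd.DataFrame, dict]:
    """Extract features for every burst in a raw sample table.

    ``accel`` has columns participant_id, burst_id, t_unix_s, x, y, z with
    one row per sample. Returns the per-burst feature table and a report of
    processed/rejected counts. Rejected bursts (too few samples, excessive
    span, unordered timestamps) become missing observations.
    """
    rows = []
    n_rejected = 0
    reasons: list[str] = []
    for (pid, bid), grp in accel.groupby(["participant_id", "burst_id"], sort=False):
        grp = grp.sort_values("t_unix_s")
        t_abs = grp["t_unix_s"].to_numpy(dtype=float)
        burst = AccelBurst(
            participant_id=str(pid),
            burst_id=str(bid),
            t=t_abs - t_abs[0],
            xyz=grp[["x", "y", "z"]].to_numpy(dtype=float),
            t_unix_s=float(t_abs[0]),
        )
        try:
            feats = extract_features(burst, rate_hz)
        except BurstRejected as exc:
            n_rejected += 1
            reasons.append(str(exc))
            logger.debug("rejected %s", exc)
            continue
        rows.append(
            {
                "participant_id": burst.participant_id,
                "burst_id": burst.burst_id,
                "t_unix_s": burst.t_unix_s,
                **{name: getattr(feats, name) for name in FEATURE_NAMES},
            }
        )
    report = {
        "bursts_processed": len(rows),
        "bursts_rejected": n_rejected,
        "rejection_reasons": reasons[:50],
    }
    return pd.DataFrame(rows), report
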
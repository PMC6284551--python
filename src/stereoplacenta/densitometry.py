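"""Immunostain optical density and Western-blot band quantification.

Optical density is read off images through a monotone piecewise-linear
calibration built from a step tablet (known OD patches).  Blot bands are
integrated from background-subtracted 1D lane profiles, reconciled across
multiple film exposures within the linear range, normalized to the
housekeeping band (β-actin), and finally expressed relative to the control
group whose mean is fixed at 1.

The lane-profile extraction model (local-baseline subtraction over a band
window) is deliberately simple plumbing: film densitometry pipelines differ,
and nothing downstream depends on its details beyond linearity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import grey_opening

__all__ = [
    "ODCalibration",
    "RegionODResult",
    "calibrate_od",
    "measure_region_od",
    "quantify_band",
    "combine_exposures",
    "normalize_expression",
    "SATURATION_FRACTION",
]

#: Readings at or above this fraction of full scale are treated as outside
#: the linear detection range (saturated).
SATURATION_FRACTION: float = 0.98


@dataclass
class ODCalibration:
    """Monotone mapping from image gray level to optical density."""

    grays: np.ndarray   # ascending gray levels
    ods: np.ndarray     # corresponding ODs (non-increasing in gray)

    def __call__(self, gray) -> np.ndarray:
        """Interpolate OD at gray level(s); out-of-range queries clamp to
        the nearest anchor and emit a warning."""
        g = np.asarray(gray, dtype=float)
        if np.any(g < self.grays[0]) or np.any(g > self.grays[-1]):
            warnings.warn("gray level outside calibrated range; clamping",
                          stacklevel=2)
        return np.interp(np.clip(g, self.grays[0], self.grays[-1]),
                         self.grays, self.ods)

    @property
    def gray_range(self) -> tuple[float, float]:
        return float(self.grays[0]), float(self.grays[-1])


@dataclass
class RegionODResult:
    region: str
    field_ods: np.ndarray
    mean_od: float
    sem_od: float


def calibrate_od(step_pairs) -> ODCalibration:
    """Build an OD calibration from step-tablet (gray, OD) pairs.

    Requires at least two distinct steps with OD monotone non-increasing in
    gray (denser film transmits less).  The interpolant round-trips every
    anchor exactly.
    """
    pairs = sorted((float(g), float(od)) for g, od in step_pairs)
    grays = np.array([p[0] for p in pairs])
    ods = np.array([p[1] for p in pairs])
    if len(grays) < 2 or np.any(np.diff(grays) == 0):
        raise ValueError("need >= 2 distinct gray levels")
    if np.any(np.diff(ods) > 0):
        raise ValueError("OD must be monotone non-increasing in gray level")
    return ODCalibration(grays=grays, ods=ods)


def measure_region_od(image: np.ndarray, calibration: ODCalibration,
                      mask: np.ndarray, n_fields: int = 10,
                      field_px: int = 32,
                      rng: np.random.Generator | int = 0) -> RegionODResult:
    """Mean OD of a stained region from SUR-sampled fields.

    Candidate field positions are the mask pixels; ``n_fields`` square
    fields (``field_px`` on a side, clipped to the image) are chosen by
    systematic sampling with a random start over the flattened candidate
    list, and each field's mean OD over in-mask pixels is recorded.
    """
    if mask.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    if not mask.any():
        raise ValueError("empty region mask")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    rows, cols = np.nonzero(mask)
    n_avail = len(rows)
    if n_avail < n_fields:
        warnings.warn("mask smaller than requested field count; using "
                      f"{n_avail} single-pixel fields", stacklevel=2)
        n_fields = max(1, n_avail)
    k = max(1, n_avail // n_fields)
    start = int(rng.integers(0, k))
    centers = np.arange(start, n_avail, k)[:n_fields]
    half = field_px // 2
    ods = []
    for ci in centers:
        r, c = int(rows[ci]), int(cols[ci])
        r0, r1 = max(0, r - half), min(image.shape[0], r + half + 1)
        c0, c1 = max(0, c - half), min(image.shape[1], c + half + 1)
        sub_img = image[r0:r1, c0:c1]
        sub_mask = mask[r0:r1, c0:c1]
        ods.append(float(np.mean(calibration(sub_img[sub_mask]))))
    ods_arr = np.array(ods)
    sem = float(ods_arr.std(ddof=1) / np.sqrt(len(ods_arr))) \
        if len(ods_arr) > 1 else 0.0
    return RegionODResult(region="", field_ods=ods_arr,
                          mean_od=float(ods_arr.mean()), sem_od=sem)


def quantify_band(lane_profile: np.ndarray, band_window: tuple[int, int],
                  baseline_size: int | None = None) -> float:
    """Integrated background-subtracted intensity of one band.

    The baseline is a rolling-minimum (grey-opening) envelope of the lane
    profile — a 1D analogue of rolling-ball background subtraction — and
    the band is the sum of profile-minus-baseline over ``band_window``
    (half-open index range).
    """
    profile = np.asarray(lane_profile, dtype=float)
    lo, hi = band_window
    if not (0 <= lo < hi <= len(profile)):
        raise ValueError(
            f"band window {band_window} outside trace of length {len(profile)}")
    if baseline_size is None:
        baseline_size = max(3, 2 * (hi - lo))
    baseline = grey_opening(profile, size=baseline_size, mode="nearest")
    signal = np.clip(profile - baseline, 0.0, None)
    return float(signal[lo:hi].sum())


def combine_exposures(intensities: np.ndarray, saturated: np.ndarray,
                      gains: np.ndarray | None = None,
                      reference: int = 0) -> np.ndarray:
    """Reconcile band intensities across film exposures.

    Model: recorded[lane, exposure] = gain[exposure] * truth[lane] within
    the linear range.  Saturated readings are excluded.  With known gains,
    the truth estimate is the mean of intensity/gain over non-saturated
    exposures (the common unit-gain scale).  With unknown gains, gains and
    truths are jointly estimated by least squares in log space (exact for
    noise-free data) with the reference exposure's gain fixed at 1, so the
    result is on the reference exposure's scale.
    """
    I = np.asarray(intensities, dtype=float)
    sat = np.asarray(saturated, dtype=bool)
    if I.ndim == 1:
        I = I[:, None]
        sat = sat.reshape(I.shape)
    if I.shape != sat.shape:
        raise ValueError("intensities and saturation flags differ in shape")
    n_lanes, n_exp = I.shape
    if not (0 <= reference < n_exp):
        raise ValueError("reference exposure out of range")
    usable = ~sat
    if np.any(~usable.any(axis=1)):
        bad = np.nonzero(~usable.any(axis=1))[0]
        raise ValueError(f"all exposures saturated for lane(s) {bad.tolist()}")

    if gains is not None:
        g = np.asarray(gains, dtype=float)
        if np.any(g <= 0):
            raise ValueError("gains must be positive")
        scaled = np.where(usable, I / g[None, :], np.nan)
        return np.nanmean(scaled, axis=1)

    # joint log-least-squares for gains and truths; needs positive readings
    with np.errstate(divide="ignore"):
        L = np.where(usable & (I > 0), np.log(I), np.nan)
    log_g = np.zeros(n_exp)
    log_t = np.nanmean(L, axis=1)
    for _ in range(200):  # alternating projections converge geometrically
        new_g = np.nanmean(L - log_t[:, None], axis=0)
        new_g = np.where(np.isnan(new_g), log_g, new_g)
        new_g -= new_g[reference]
        new_t = np.nanmean(L - new_g[None, :], axis=1)
        if np.allclose(new_g, log_g, atol=1e-12) and \
           np.allclose(new_t, log_t, atol=1e-12, equal_nan=True):
            log_g, log_t = new_g, new_t
            break
        log_g, log_t = new_g, new_t
    return np.exp(log_t)


def normalize_expression(target: np.ndarray, actin: np.ndarray,
                         groups, control_group: str = "N") -> pd.DataFrame:
    """β-actin normalization and control-relative scaling.

    ratio = target / actin per lane; relative = ratio / mean(control
    ratios), so the control group has mean relative expression exactly 1.
    Lanes with non-positive actin are excluded with a warning.
    """
    t = np.asarray(target, dtype=float)
    a = np.asarray(actin, dtype=float)
    g = np.asarray(list(groups))
    if not (len(t) == len(a) == len(g)):
        raise ValueError("target, actin and groups must have equal length")
    ok = a > 0
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} lane(s) with "
                      "non-positive actin", stacklevel=2)
    t, a, g = t[ok], a[ok], g[ok]
    ratio = t / a
    ctrl = ratio[g == control_group]
    if len(ctrl) == 0:
        raise ValueError(f"control group {control_group!r} is empty")
    rel = ratio / ctrl.mean()
    return pd.DataFrame({"group": g, "ratio": ratio, "relative": rel})
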
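"""Design-based stereological estimators and derived physiology.

The five core estimators:

* Cavalieri volume               V = d * a_p * sum(P)
* volume fraction                Vv = P(struct) / P(total)
* absolute compartment volume    V(struct) = Vv * V(ref)
* cycloid surface density        Sv = 2 * sum(I) / (l_p * sum(P_ref)),
                                 S(struct) = Sv * V(ref)
* harmonic-mean barrier thickness
                                 tau_h = n / sum(1 / (c * l_i)),
                                 c = 8 / (3 pi)

plus the Krogh diffusion capacity Dvm = K * mean(S_fetal, S_maternal) /
tau_h, the specific diffusion capacity Dvm per mg fetal weight, and
placental efficiency ratios.

Counts come in via plain integers or :class:`~stereoplacenta.probes.CountRecord`
tallies; lengths are µm internally, with conversion to cm only at the
diffusion-capacity boundary (where the Krogh coefficient's units live).

Notes on two deliberately resolved ambiguities
----------------------------------------------
The Cavalieri multiplier is the distance between *sampled* section planes,
d = k * t_sec — summing points over the sampled sections and multiplying by
the total block thickness instead would overestimate k-fold.  And the
orthogonal-intercept plane-of-sectioning correction is the multiplicative
constant 8/(3 pi) ~ 0.8488 applied per intercept before harmonic averaging;
the corrected harmonic mean then recovers true thickness on a sectioned
constant-thickness shell (see docs/methods.md for the closed-form
argument).  Reading it as (8/3)*pi ~ 8.38 inflates thickness roughly
ten-fold and fails that recovery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .units import Quantity, as_quantity

__all__ = [
    "KROGH_K_O2",
    "INTERCEPT_CORRECTION",
    "VolumeEstimate",
    "SurfaceEstimate",
    "ThicknessEstimate",
    "DiffusionResult",
    "EfficiencyResult",
    "cavalieri_volume",
    "volume_fraction",
    "absolute_volume",
    "surface_area",
    "harmonic_mean_thickness",
    "diffusion_capacity",
    "specific_diffusion_capacity",
    "placental_efficiency",
]

#: Krogh diffusion coefficient for oxygen, cm^2 / (minute * kPa).
KROGH_K_O2: float = 17.3e-8

#: Plane-of-sectioning correction for orthogonal intercepts, 8 / (3 pi).
INTERCEPT_CORRECTION: float = 8.0 / (3.0 * math.pi)


@dataclass
class VolumeEstimate:
    """Cavalieri volume with optional compartment fractions."""

    volume_um3: float
    sum_P: int
    a_p_um2: float
    d_um: float
    Vv: dict[str, float] = field(default_factory=dict)
    absolute_um3: dict[str, float] = field(default_factory=dict)

    @property
    def volume_mm3(self) -> float:
        return self.volume_um3 / 1e9

    def as_quantity(self) -> Quantity:
        return Quantity(self.volume_um3, "um^3")


@dataclass
class SurfaceEstimate:
    Sv_per_um: float
    surface_um2: float
    v_ref_um3: float
    sum_I: int
    sum_P_ref: int
    l_p_um: float

    @property
    def surface_cm2(self) -> float:
        return self.surface_um2 / 1e8


@dataclass
class ThicknessEstimate:
    raw_intercepts_um: np.ndarray
    correction: float
    tau_h_um: float
    n: int

    @property
    def arithmetic_mean_um(self) -> float:
        return float(np.mean(self.raw_intercepts_um * self.correction))


@dataclass
class DiffusionResult:
    K: float                       # cm^2 / (min kPa)
    mean_surface_cm2: float
    tau_h_cm: float
    Dvm: float                     # cm^3 O2 / (min kPa)
    fetal_weight_mg: float | None = None
    SDC: float | None = None       # cm^3 O2 / (min kPa mg)


@dataclass
class EfficiencyResult:
    bw_g: float
    pw_g: float
    bw_pw: float
    fw_per_fc_cm2: float
    fw_per_mbs_cm2: float
    fw_per_total_cm2: float


def cavalieri_volume(point_counts, a_p: float, d: float) -> VolumeEstimate:
    """Cavalieri volume V = d * a_p * sum(P) over SUR sections.

    Parameters
    ----------
    point_counts
        Per-section point counts on the object (iterable of ints), or a
        single total.
    a_p
        Area associated with each grid point, µm².
    d
        Distance between sampled section planes, µm (sampling period k
        times the physical section thickness).
    """
    if a_p <= 0 or d <= 0:
        raise ValueError("a_p and d must be positive")
    counts = np.atleast_1d(np.asarray(point_counts))
    if np.any(counts < 0) or not np.all(np.equal(np.mod(counts, 1), 0)):
        raise ValueError("point counts must be non-negative integers")
    total = int(counts.sum())
    if total == 0:
        warnings.warn("zero points counted: volume estimate is 0 "
                      "(grid too coarse or object absent)", stacklevel=2)
    return VolumeEstimate(volume_um3=d * a_p * total, sum_P=total,
                          a_p_um2=a_p, d_um=d)


def volume_fraction(p_struct: int, p_total: int) -> float:
    """Vv = P(struct) / P(total), the point-count volume fraction."""
    if p_total <= 0:
        raise ValueError("P(total) must be positive: volume fraction "
                         "undefined for an empty reference")
    if not 0 <= p_struct <= p_total:
        raise ValueError(
            f"need 0 <= P(struct) <= P(total), got {p_struct}/{p_total}")
    return p_struct / p_total


def absolute_volume(vv: float, v_ref: float) -> float:
    """Convert a volume fraction to an absolute volume, Vv * V(ref)."""
    if not 0.0 <= vv <= 1.0:
        raise ValueError(f"volume fraction must lie in [0, 1], got {vv}")
    if v_ref <= 0:
        raise ValueError("reference volume must be positive")
    return vv * v_ref


def surface_area(sum_I: int, l_p: float, sum_P_ref: int,
                 v_ref_um3: float) -> SurfaceEstimate:
    """Cycloid surface estimator on vertical sections.

    Sv = 2 * sum(I) / (l_p * sum(P_ref)) and S = Sv * V(ref): sum(I) counts
    intersections of the cycloid arcs with the structure boundary, l_p is
    the test-line length associated with each grid point and sum(P_ref) the
    points hitting the reference space, so l_p * sum(P_ref) estimates the
    test-line length deployed inside the reference.
    """
    if l_p <= 0:
        raise ValueError("l_p must be positive")
    if sum_P_ref <= 0:
        raise ValueError("sum(P_ref) must be positive: no reference points")
    if sum_I < 0:
        raise ValueError("sum(I) must be non-negative")
    if v_ref_um3 <= 0:
        raise ValueError("reference volume must be positive")
    sv = 2.0 * sum_I / (l_p * sum_P_ref)
    return SurfaceEstimate(Sv_per_um=sv, surface_um2=sv * v_ref_um3,
                           v_ref_um3=v_ref_um3, sum_I=int(sum_I),
                           sum_P_ref=int(sum_P_ref), l_p_um=l_p)


def harmonic_mean_thickness(intercepts_um,
                            correction: float = INTERCEPT_CORRECTION
                            ) -> ThicknessEstimate:
    """Harmonic-mean membrane thickness from orthogonal intercepts.

    Each raw intercept is multiplied by the plane-of-sectioning correction
    (default 8/(3 pi)); tau_h is then the reciprocal of the mean of the
    reciprocals of the corrected intercepts.  The harmonic mean weights
    thin regions, which dominate diffusive exchange.
    """
    arr = np.asarray(intercepts_um, dtype=float)
    if arr.size == 0:
        raise ValueError("empty intercept sample: cannot form harmonic mean")
    if np.any(arr <= 0):
        raise ValueError("intercept lengths must be positive")
    if correction <= 0:
        raise ValueError("correction factor must be positive")
    corrected = correction * arr
    tau_h = arr.size / float(np.sum(1.0 / corrected))
    return ThicknessEstimate(raw_intercepts_um=arr, correction=correction,
                             tau_h_um=tau_h, n=int(arr.size))


def diffusion_capacity(s_fetal: Quantity | float, s_maternal: Quantity | float,
                       tau_h: Quantity | float,
                       K: float = KROGH_K_O2) -> DiffusionResult:
    """Theoretical (morphometric) oxygen diffusion capacity of the membrane.

    Dvm = K * mean(S_fetal, S_maternal) / tau_h, where the mean surface is
    the mean of the fetal and maternal surfaces of the interhaemal membrane.
    Surfaces must be areas and tau_h a length; bare floats are taken as cm²
    and cm.  Passing a µm-tagged quantity converts correctly; passing a
    quantity of the wrong dimension raises.
    """
    sf = as_quantity(s_fetal, "cm^2").value
    sm = as_quantity(s_maternal, "cm^2").value
    th = as_quantity(tau_h, "cm").value
    if sf <= 0 or sm <= 0 or th <= 0 or K <= 0:
        raise ValueError("surfaces, thickness and K must all be positive")
    mean_s = 0.5 * (sf + sm)
    return DiffusionResult(K=K, mean_surface_cm2=mean_s, tau_h_cm=th,
                           Dvm=K * mean_s / th)


def specific_diffusion_capacity(result: DiffusionResult | float,
                                fetal_weight_mg: float) -> DiffusionResult:
    """Express Dvm per mg of fetal weight (the specific diffusion capacity)."""
    if fetal_weight_mg <= 0:
        raise ValueError("fetal weight must be positive")
    if isinstance(result, DiffusionResult):
        sdc = result.Dvm / fetal_weight_mg
        return DiffusionResult(K=result.K,
                               mean_surface_cm2=result.mean_surface_cm2,
                               tau_h_cm=result.tau_h_cm, Dvm=result.Dvm,
                               fetal_weight_mg=fetal_weight_mg, SDC=sdc)
    dvm = float(result)
    return DiffusionResult(K=KROGH_K_O2, mean_surface_cm2=float("nan"),
                           tau_h_cm=float("nan"), Dvm=dvm,
                           fetal_weight_mg=fetal_weight_mg,
                           SDC=dvm / fetal_weight_mg)


def placental_efficiency(bw_g: float, pw_g: float, s_fc: Quantity | float,
                         s_mbs: Quantity | float) -> EfficiencyResult:
    """Placental efficiency: fetal weight per unit placental weight and per
    unit exchange surface (fetal-capillary, maternal-blood-space, and their
    sum — both readings of the per-area denominator are emitted)."""
    sfc = as_quantity(s_fc, "cm^2").value
    smbs = as_quantity(s_mbs, "cm^2").value
    if bw_g <= 0 or pw_g <= 0 or sfc <= 0 or smbs <= 0:
        raise ValueError("weights and surfaces must be positive")
    return EfficiencyResult(bw_g=bw_g, pw_g=pw_g, bw_pw=bw_g / pw_g,
                            fw_per_fc_cm2=bw_g / sfc,
                            fw_per_mbs_cm2=bw_g / smbs,
                            fw_per_total_cm2=bw_g / (sfc + smbs))
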
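"""Synthetic 3D tissue phantoms with known ground truth.

The phantoms stand in for the tissue a stereologist would section: a sphere
and a spherical shell as calibration primitives, and a placenta-like body —
an ellipsoid partitioned into three axial bands (decidua basalis, junctional
zone, labyrinthine zone) whose labyrinth carries fetal-capillary tubes and
maternal-blood-space channels separated by at least a controllable membrane
distance.  Geometry is built from analytic primitives so that every volume,
surface and thickness has an exact closed form; a voxel oracle is provided
as an independent cross-check.

All lengths are micrometres.  The phantom "vertical" axis (the normal of
the chorionic plate in the placental analogue) is the world z axis;
sections are cut perpendicular to the chorionic plate, i.e. along planes of
constant x, so the vertical axis lies in the section plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "ZONE_OF",
    "Phantom3D",
    "SpherePhantom",
    "ShellPhantom",
    "PlacentaPhantom",
    "GroundTruth",
    "PackingError",
    "make_sphere_phantom",
    "make_shell_phantom",
    "make_placenta_phantom",
    "voxelize",
    "voxel_volumes",
    "voxel_surface_area",
    "StudySynthSpec",
    "synth_study_table",
    "make_step_tablet",
    "synth_blot_fixture",
    "GROUPS",
]

# Canonical label code table shared by all phantoms and sections.
LABELS: dict[str, int] = {
    "background": 0,
    "decidua": 1,
    "junctional": 2,
    "labyrinth": 3,   # labyrinthine-zone tissue (trophoblast + membrane)
    "capillary": 4,   # fetal capillary lumen
    "blood_space": 5, # maternal blood space
    "membrane": 6,    # explicit membrane label (shell phantom)
    "tissue": 7,      # generic tissue (sphere phantom)
}
LABEL_NAMES: dict[int, str] = {v: k for k, v in LABELS.items()}

# Grouping of fine labels into the three placental zones: the labyrinthine
# zone includes its embedded vascular compartments.
ZONE_OF: dict[str, str] = {
    "decidua": "decidua",
    "junctional": "junctional",
    "labyrinth": "labyrinth",
    "capillary": "labyrinth",
    "blood_space": "labyrinth",
    "membrane": "labyrinth",
}

GROUPS = ("N", "H", "HM", "NM")


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot place a tube without violating
    the membrane-separation or containment constraint."""


@dataclass(frozen=True)
class GroundTruth:
    """Exact (or voxel-oracle) reference values for a phantom.

    ``provenance`` records, per quantity name, whether the value is a
    closed form or came from voxel counting at ``voxel_resolution_um``.
    """

    volumes_um3: dict[str, float]
    surfaces_um2: dict[str, float]
    total_volume_um3: float
    tau_true_um: float | None
    provenance: dict[str, str]
    voxel_resolution_um: float | None = None

    def __post_init__(self) -> None:
        for k, v in {**self.volumes_um3, **self.surfaces_um2}.items():
            if v < 0:
                raise ValueError(f"ground-truth value {k} negative: {v}")
        if self.total_volume_um3 <= 0:
            raise ValueError("total volume must be positive")


class Phantom3D:
    """Base class: an axis-aligned bounded labeled 3D body.

    Subclasses implement :meth:`label_points`; everything else (sectioning,
    voxel oracles) is generic.
    """

    bbox_lo: np.ndarray  # (3,) µm
    bbox_hi: np.ndarray  # (3,) µm
    labels: dict[str, int] = LABELS

    def label_points(self, pts: np.ndarray) -> np.ndarray:
        """Label an (N, 3) array of µm coordinates. Returns (N,) uint8."""
        raise NotImplementedError

    @property
    def extent(self) -> np.ndarray:
        return self.bbox_hi - self.bbox_lo

    def rasterize_section(self, x0: float, pixel_size: float,
                          y_range: tuple[float, float] | None = None,
                          z_range: tuple[float, float] | None = None) -> np.ndarray:
        """Label raster of the plane x = x0.

        Rows index z (phantom vertical), columns index y; pixel centres at
        lo + (i + 0.5) * pixel_size.
        """
        if pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        ylo, yhi = y_range if y_range else (self.bbox_lo[1], self.bbox_hi[1])
        zlo, zhi = z_range if z_range else (self.bbox_lo[2], self.bbox_hi[2])
        ny = max(1, int(round((yhi - ylo) / pixel_size)))
        nz = max(1, int(round((zhi - zlo) / pixel_size)))
        y = ylo + (np.arange(ny) + 0.5) * pixel_size
        z = zlo + (np.arange(nz) + 0.5) * pixel_size
        yy, zz = np.meshgrid(y, z)  # (nz, ny)
        pts = np.column_stack([np.full(yy.size, x0), yy.ravel(), zz.ravel()])
        return self.label_points(pts).reshape(nz, ny)


@dataclass
class SpherePhantom(Phantom3D):
    """A solid sphere of 'tissue' centred at the origin."""

    radius: float
    margin: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"sphere radius must be positive, got {self.radius}")
        half = self.radius + self.margin
        self.bbox_lo = np.array([-half, -half, -half])
        self.bbox_hi = np.array([half, half, half])

    def label_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        r2 = (pts ** 2).sum(axis=1)
        out = np.zeros(len(pts), dtype=np.uint8)
        out[r2 <= self.radius ** 2] = LABELS["tissue"]
        return out


@dataclass
class ShellPhantom(Phantom3D):
    """A spherical membrane of constant thickness.

    Inner ball is labeled as fetal capillary, the shell as membrane, and the
    surrounding space (inside the bounding box) as maternal blood space, so
    that every through-membrane intercept from the capillary boundary to the
    blood space has true length ``thickness``.
    """

    inner_radius: float
    thickness: float
    margin: float = 0.0

    def __post_init__(self) -> None:
        if self.inner_radius <= 0 or self.thickness <= 0:
            raise ValueError("inner radius and thickness must be positive")
        if self.thickness >= self.inner_radius:
            raise ValueError(
                f"degenerate shell: thickness {self.thickness} >= inner radius "
                f"{self.inner_radius}"
            )
        half = self.inner_radius + self.thickness + max(self.margin, 0.0)
        self.bbox_lo = np.array([-half, -half, -half])
        self.bbox_hi = np.array([half, half, half])

    @property
    def outer_radius(self) -> float:
        return self.inner_radius + self.thickness

    def label_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        r2 = (pts ** 2).sum(axis=1)
        out = np.full(len(pts), LABELS["blood_space"], dtype=np.uint8)
        out[r2 <= self.outer_radius ** 2] = LABELS["membrane"]
        out[r2 <= self.inner_radius ** 2] = LABELS["capillary"]
        return out


def _band_cumvol(a: float, b: float, c: float, z: float) -> float:
    """Volume of the ellipsoid (semi-axes a, b, c) below height z."""
    z = np.clip(z, -c, c)
    return math.pi * a * b * ((z + c) - (z ** 3 + c ** 3) / (3 * c ** 2))


@dataclass
class PlacentaPhantom(Phantom3D):
    """Ellipsoidal placenta analogue with zoned bands and labyrinth tubes.

    Zones are axial bands along the vertical (z) axis: labyrinthine zone at
    the bottom (chorionic-plate side), junctional zone in the middle,
    decidua basalis on top.  Capillaries and maternal channels are finite
    cylinders parallel to x, wholly inside the labyrinthine band, with all
    tube surfaces separated by at least ``tau_true``.
    """

    semi_axes: tuple[float, float, float]
    z_cuts: tuple[float, float]          # (top of LZ, top of JZ)
    tube_y: np.ndarray                   # per-tube y centre
    tube_z: np.ndarray
    tube_r: np.ndarray
    tube_hl: np.ndarray                  # half-length along x
    tube_label: np.ndarray               # uint8 label codes
    tau_true: float
    seed: int
    margin: float = 20.0

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        m = self.margin
        self.bbox_lo = np.array([-a - m, -b - m, -c - m])
        self.bbox_hi = np.array([a + m, b + m, c + m])

    def _zone_labels(self, y: np.ndarray, z: np.ndarray, x: np.ndarray) -> np.ndarray:
        a, b, c = self.semi_axes
        inside = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
        z1, z2 = self.z_cuts
        out = np.zeros(len(y), dtype=np.uint8)
        out[inside & (z <= z1)] = LABELS["labyrinth"]
        out[inside & (z > z1) & (z <= z2)] = LABELS["junctional"]
        out[inside & (z > z2)] = LABELS["decidua"]
        return out

    def label_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        out = self._zone_labels(y, z, x)
        for yi, zi, ri, hli, li in zip(self.tube_y, self.tube_z, self.tube_r,
                                       self.tube_hl, self.tube_label):
            hit = (np.abs(x) <= hli) & ((y - yi) ** 2 + (z - zi) ** 2 <= ri ** 2)
            out[hit] = li
        return out

    def rasterize_section(self, x0: float, pixel_size: float,
                          y_range: tuple[float, float] | None = None,
                          z_range: tuple[float, float] | None = None) -> np.ndarray:
        """Fast path: rasterize zones analytically, then paint tube discs."""
        if pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        ylo, yhi = y_range if y_range else (self.bbox_lo[1], self.bbox_hi[1])
        zlo, zhi = z_range if z_range else (self.bbox_lo[2], self.bbox_hi[2])
        ny = max(1, int(round((yhi - ylo) / pixel_size)))
        nz = max(1, int(round((zhi - zlo) / pixel_size)))
        y = ylo + (np.arange(ny) + 0.5) * pixel_size
        z = zlo + (np.arange(nz) + 0.5) * pixel_size
        yy, zz = np.meshgrid(y, z)
        img = self._zone_labels(yy.ravel(), zz.ravel(),
                                np.full(yy.size, x0)).reshape(nz, ny)
        active = np.abs(x0) <= self.tube_hl
        for yi, zi, ri, li in zip(self.tube_y[active], self.tube_z[active],
                                  self.tube_r[active], self.tube_label[active]):
            j0 = max(0, int((yi - ri - ylo) / pixel_size) - 1)
            j1 = min(ny, int((yi + ri - ylo) / pixel_size) + 2)
            i0 = max(0, int((zi - ri - zlo) / pixel_size) - 1)
            i1 = min(nz, int((zi + ri - zlo) / pixel_size) + 2)
            if j0 >= j1 or i0 >= i1:
                continue
            sub_y = y[j0:j1][None, :]
            sub_z = z[i0:i1][:, None]
            disc = (sub_y - yi) ** 2 + (sub_z - zi) ** 2 <= ri ** 2
            block = img[i0:i1, j0:j1]
            block[disc & (block == LABELS["labyrinth"])] = li
        return img


# ---------------------------------------------------------------------------
# factories

def make_sphere_phantom(radius: float, margin: float | None = None
                        ) -> tuple[SpherePhantom, GroundTruth]:
    """Solid sphere with closed-form V = 4/3 pi r^3 and S = 4 pi r^2."""
    if radius <= 0:
        raise ValueError(f"sphere radius must be positive, got {radius}")
    if margin is None:
        margin = max(0.05 * radius, 5.0)
    ph = SpherePhantom(radius=radius, margin=margin)
    v = 4.0 / 3.0 * math.pi * radius ** 3
    s = 4.0 * math.pi * radius ** 2
    gt = GroundTruth(
        volumes_um3={"tissue": v},
        surfaces_um2={"tissue": s},
        total_volume_um3=v,
        tau_true_um=None,
        provenance={"tissue.volume": "closed-form", "tissue.surface": "closed-form"},
    )
    return ph, gt


def make_shell_phantom(inner_radius: float, thickness: float,
                       margin: float | None = None
                       ) -> tuple[ShellPhantom, GroundTruth]:
    """Constant-thickness spherical membrane between capillary and blood space."""
    if inner_radius <= 0 or thickness <= 0:
        raise ValueError("inner radius and thickness must be positive")
    if thickness >= inner_radius:
        raise ValueError(
            f"degenerate shell: thickness {thickness} >= inner radius {inner_radius}"
        )
    if margin is None:
        margin = max(0.2 * inner_radius, 10.0)
    ph = ShellPhantom(inner_radius=inner_radius, thickness=thickness, margin=margin)
    ri, ro = inner_radius, inner_radius + thickness
    v_in = 4.0 / 3.0 * math.pi * ri ** 3
    v_shell = 4.0 / 3.0 * math.pi * (ro ** 3 - ri ** 3)
    gt = GroundTruth(
        volumes_um3={"capillary": v_in, "membrane": v_shell},
        surfaces_um2={"capillary": 4 * math.pi * ri ** 2,
                      "membrane_outer": 4 * math.pi * ro ** 2},
        total_volume_um3=v_in + v_shell,
        tau_true_um=thickness,
        provenance={k: "closed-form" for k in
                    ("capillary.volume", "membrane.volume",
                     "capillary.surface", "membrane_outer.surface")},
    )
    return ph, gt


def make_placenta_phantom(zone_fractions: tuple[float, float, float] = (0.15, 0.30, 0.55),
                          semi_axes: tuple[float, float, float] = (1250.0, 1250.0, 650.0),
                          n_capillaries: int = 180,
                          capillary_radius: float = 14.0,
                          n_channels: int = 130,
                          channel_radius: float = 16.0,
                          tau_true: float = 5.0,
                          seed: int = 0,
                          max_tries: int = 10_000,
                          ) -> tuple[PlacentaPhantom, GroundTruth]:
    """Zoned ellipsoidal placenta analogue with labyrinth vasculature.

    Parameters
    ----------
    zone_fractions
        Volume fractions (decidua basalis, junctional zone, labyrinthine
        zone); must sum to 1.
    semi_axes
        Ellipsoid semi-axes (a, b, c) in µm; z (the c axis) is vertical.
    n_capillaries, capillary_radius, n_channels, channel_radius
        Tube counts and radii (µm) for fetal capillaries and maternal
        blood-space channels.
    tau_true
        Minimum surface-to-surface separation between any two tubes (µm) —
        the guaranteed interhaemal membrane thickness.
    seed
        Seed for the rejection-sampling placement; same spec + seed gives a
        byte-identical phantom.
    max_tries
        Bound on rejection-sampling attempts per tube before an explicit
        :class:`PackingError`.
    """
    f_dec, f_jz, f_lz = zone_fractions
    if any(f <= 0 for f in zone_fractions) or abs(sum(zone_fractions) - 1.0) > 1e-9:
        raise ValueError(f"zone fractions must be positive and sum to 1, got {zone_fractions}")
    if tau_true <= 0:
        raise ValueError("tau_true must be positive")
    a, b, c = semi_axes
    v_total = 4.0 / 3.0 * math.pi * a * b * c
    # axial cut heights giving exactly the requested band volume fractions
    z1 = brentq(lambda z: _band_cumvol(a, b, c, z) - f_lz * v_total, -c, c)
    z2 = brentq(lambda z: _band_cumvol(a, b, c, z) - (f_lz + f_jz) * v_total, -c, c)

    rng = np.random.default_rng(seed)
    specs = ([capillary_radius] * n_capillaries + [channel_radius] * n_channels)
    codes = ([LABELS["capillary"]] * n_capillaries
             + [LABELS["blood_space"]] * n_channels)
    order = rng.permutation(len(specs))  # interleave classes during packing

    min_hl = 0.25 * a
    ys: list[float] = []
    zs: list[float] = []
    rs: list[float] = []
    hls: list[float] = []
    lbls: list[int] = []
    for idx in order:
        r = specs[idx]
        shrink = 1.0 - (r + 2.0) / c   # axis-in-scaled-ellipsoid containment
        placed = False
        for _ in range(max_tries):
            y0 = rng.uniform(-b + r, b - r)
            z0 = rng.uniform(-c + r, z1 - r - 1.0)
            rad2 = (y0 / (b * shrink)) ** 2 + (z0 / (c * shrink)) ** 2
            if rad2 >= 1.0:
                continue
            hl = a * shrink * math.sqrt(1.0 - rad2)
            if hl < min_hl:
                continue
            if ys:
                d = np.hypot(np.array(ys) - y0, np.array(zs) - z0)
                if np.any(d < np.array(rs) + r + tau_true):
                    continue
            ys.append(y0); zs.append(z0); rs.append(r); hls.append(hl)
            lbls.append(codes[idx])
            placed = True
            break
        if not placed:
            raise PackingError(
                f"could not place tube (radius {r} µm) after {max_tries} tries "
                f"without violating the tau_true = {tau_true} µm surface-"
                "separation constraint inside the labyrinthine zone; reduce "
                "tube count/radius or tau_true"
            )

    ph = PlacentaPhantom(
        semi_axes=semi_axes, z_cuts=(z1, z2),
        tube_y=np.array(ys), tube_z=np.array(zs), tube_r=np.array(rs),
        tube_hl=np.array(hls), tube_label=np.array(lbls, dtype=np.uint8),
        tau_true=tau_true, seed=seed,
    )
    cap = ph.tube_label == LABELS["capillary"]
    chan = ph.tube_label == LABELS["blood_space"]

    def _tube_vol(mask: np.ndarray) -> float:
        return float(np.sum(math.pi * ph.tube_r[mask] ** 2 * 2 * ph.tube_hl[mask]))

    def _tube_surf(mask: np.ndarray) -> float:
        lateral = 2 * math.pi * ph.tube_r[mask] * 2 * ph.tube_hl[mask]
        caps = 2 * math.pi * ph.tube_r[mask] ** 2
        return float(np.sum(lateral + caps))

    gt = GroundTruth(
        volumes_um3={
            "decidua": f_dec * v_total,
            "junctional": f_jz * v_total,
            "labyrinth": f_lz * v_total,
            "capillary": _tube_vol(cap),
            "blood_space": _tube_vol(chan),
        },
        surfaces_um2={
            "capillary": _tube_surf(cap),
            "blood_space": _tube_surf(chan),
        },
        total_volume_um3=v_total,
        tau_true_um=tau_true,
        provenance={k: "closed-form" for k in
                    ("decidua.volume", "junctional.volume", "labyrinth.volume",
                     "capillary.volume", "blood_space.volume",
                     "capillary.surface", "blood_space.surface",
                     "total.volume")},
    )
    return ph, gt


# ---------------------------------------------------------------------------
# voxel oracle

def voxelize(phantom: Phantom3D, resolution: float) -> np.ndarray:
    """Exhaustively label a voxel grid over the phantom bounding box.

    Intended as an independent oracle on small phantoms; voxel centres at
    lo + (i + 0.5) * resolution.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    lo, hi = phantom.bbox_lo, phantom.bbox_hi
    n = np.maximum(1, np.round((hi - lo) / resolution).astype(int))
    xs = lo[0] + (np.arange(n[0]) + 0.5) * resolution
    ys = lo[1] + (np.arange(n[1]) + 0.5) * resolution
    zs = lo[2] + (np.arange(n[2]) + 0.5) * resolution
    out = np.empty((n[0], n[1], n[2]), dtype=np.uint8)
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    for i, x in enumerate(xs):  # slab-wise to bound memory
        pts = np.column_stack([np.full(yy.size, x), yy.ravel(), zz.ravel()])
        out[i] = phantom.label_points(pts).reshape(len(ys), len(zs))
    return out


def voxel_volumes(phantom: Phantom3D, resolution: float) -> dict[str, float]:
    """Per-label volumes (µm³) by exhaustive voxel counting."""
    vox = voxelize(phantom, resolution)
    counts = np.bincount(vox.ravel(), minlength=max(LABELS.values()) + 1)
    voxvol = resolution ** 3
    return {LABEL_NAMES[i]: float(cnt * voxvol)
            for i, cnt in enumerate(counts) if cnt > 0}


def voxel_surface_area(phantom: Phantom3D, label: str, resolution: float,
                       smooth_sigma: float = 1.5) -> float:
    """Surface area (µm²) of a labeled compartment by a marching-cubes oracle.

    The binary indicator is lightly smoothed before extracting the 0.5
    isosurface to suppress voxelization staircase bias.
    """
    from scipy.ndimage import gaussian_filter
    from skimage.measure import marching_cubes, mesh_surface_area

    vox = voxelize(phantom, resolution)
    ind = (vox == LABELS[label]).astype(np.float32)
    ind = gaussian_filter(ind, sigma=smooth_sigma)
    verts, faces, _, _ = marching_cubes(
        ind, level=0.5, spacing=(resolution,) * 3)
    return float(mesh_surface_area(verts, faces))


# ---------------------------------------------------------------------------
# factorial study synthesis

@dataclass
class StudySynthSpec:
    """Specification for a synthetic 2x2 factorial study table.

    Emulates the four-group early-onset hypoxia design (normoxia N, hypoxia
    H, hypoxia + MitoQ HM, normoxia + MitoQ NM) with litters nested in dams:
    outcome = group mean + litter random intercept + residual.
    """

    litters_per_group: dict[str, int] = field(
        default_factory=lambda: {"N": 16, "H": 16, "HM": 18, "NM": 16})
    fetuses_per_litter: int = 8
    group_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"outcome": {g: 0.0 for g in GROUPS}})
    sigma_litter: dict[str, float] = field(
        default_factory=lambda: {"outcome": 1.0})
    sigma_resid: dict[str, float] = field(
        default_factory=lambda: {"outcome": 1.0})
    seed: int = 0

    def validate(self) -> None:
        if self.fetuses_per_litter < 1:
            raise ValueError("fetuses_per_litter must be >= 1")
        for g, n in self.litters_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}")
            if n < 2:
                raise ValueError(f"need >= 2 litters per group, got {n} for {g}")
        for name in self.group_means:
            for d in (self.sigma_litter, self.sigma_resid):
                if d.get(name, 0.0) < 0:
                    raise ValueError(f"negative variance component for {name}")


def group_factors(group: str) -> tuple[int, int]:
    """Decompose a group label into (hypoxia, mitoq) 0/1 factors."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    return int(group in ("H", "HM")), int(group in ("HM", "NM"))


def synth_study_table(spec: StudySynthSpec) -> pd.DataFrame:
    """Simulate a fetus-level study table from a :class:`StudySynthSpec`.

    Returns a tidy frame with columns dam_id, fetus_id, group, hypoxia,
    mitoq and one column per outcome.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    dam_counter = 0
    for g in GROUPS:
        n_lit = spec.litters_per_group.get(g, 0)
        for _ in range(n_lit):
            dam_counter += 1
            dam_id = f"dam{dam_counter:03d}"
            intercepts = {name: rng.normal(0.0, spec.sigma_litter.get(name, 0.0))
                          for name in spec.group_means}
            for f in range(spec.fetuses_per_litter):
                hyp, mq = group_factors(g)
                row = {"dam_id": dam_id, "fetus_id": f"{dam_id}_f{f + 1}",
                       "group": g, "hypoxia": hyp, "mitoq": mq}
                for name, means in spec.group_means.items():
                    row[name] = (means[g] + intercepts[name]
                                 + rng.normal(0.0, spec.sigma_resid.get(name, 0.0)))
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# densitometry fixtures

def make_step_tablet(n_steps: int = 16, od_step: float = 0.15,
                     white_level: int = 60_000, band_px: int = 12,
                     width_px: int = 64) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Synthetic OD step tablet image plus its (gray, OD) anchor pairs.

    Gray levels follow the transmission law gray = white * 10**(-OD), so the
    mapping is monotone non-increasing in gray, as for a film step wedge.
    """
    if n_steps < 2:
        raise ValueError("need at least 2 steps")
    ods = [i * od_step for i in range(n_steps)]
    grays = [white_level * 10 ** (-od) for od in ods]
    img = np.zeros((n_steps * band_px, width_px), dtype=np.uint16)
    for i, g in enumerate(grays):
        img[i * band_px:(i + 1) * band_px, :] = int(round(g))
    pairs = [(float(int(round(g))), float(od)) for g, od in zip(grays, ods)]
    return img, pairs


def synth_blot_fixture(true_intensities: np.ndarray,
                       exposure_gains: np.ndarray,
                       saturation_level: float = 65_535.0,
                       noise_sd: float = 0.01,
                       seed: int = 0,
                       ) -> tuple[pd.DataFrame, np.ndarray, list[tuple[float, float]]]:
    """Multi-exposure Western-blot lane intensities plus a step tablet.

    Per-exposure recorded intensity is gain * truth + multiplicative noise
    (sd expressed as a fraction of the noiseless signal), clipped at
    ``saturation_level``; clipped readings are flagged saturated.
    """
    truth = np.asarray(true_intensities, dtype=float)
    gains = np.asarray(exposure_gains, dtype=float)
    if np.any(gains <= 0):
        raise ValueError("exposure gains must be positive")
    if saturation_level <= 0:
        raise ValueError("saturation level must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for e, g in enumerate(gains):
        signal = g * truth
        noisy = signal * (1.0 + rng.normal(0.0, noise_sd, size=truth.shape)) \
            if noise_sd > 0 else signal.copy()
        clipped = np.minimum(noisy, saturation_level)
        for lane, (v, raw) in enumerate(zip(clipped, noisy)):
            rows.append({"lane": lane, "exposure": e, "gain": float(g),
                         "intensity": float(v),
                         "saturated": bool(raw >= saturation_level)})
    tablet, pairs = make_step_tablet()
    return pd.DataFrame(rows), tablet, pairs
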
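"""Geometric probes overlaid on section images.

Implements the classical design-based probes: square point grids for volume
fractions and Cavalieri point counts, cycloid-arc grids for surface density
on vertical sections, meander field sampling, and line-grid start points
with orthogonal-intercept measurement of membrane thickness.

Every overlay takes a random 2D offset uniform over one fundamental tile of
the grid — the randomization that makes the estimators design-unbiased —
and is reproducible given the same RNG state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .sectioning import SectionImage

__all__ = [
    "GridSpec",
    "CountRecord",
    "CycloidCounts",
    "overlay_point_grid",
    "overlay_cycloid_grid",
    "meander_fields",
    "point_in_field",
    "orthogonal_intercepts",
]


@dataclass(frozen=True)
class GridSpec:
    """Probe-grid geometry.

    kind
        "point": square grid with pitch ``spacing``; the area per point is
        a_p = spacing**2.
        "cycloid": tiles of width pi*a and height 4a (a = spacing/pi), each
        carrying one cycloid arc of length 4a and one associated point, so
        the test-line length per point is l_p = 4a.  The cycloid minor axis
        is parallel to the section's vertical axis, which weights test
        directions by the sine of the angle to the vertical — the condition
        for unbiased surface estimation on vertical sections.
        "line": horizontal test lines with vertical pitch ``spacing`` (used
        to establish orthogonal-intercept start points).
    """

    kind: str
    spacing: float

    def __post_init__(self) -> None:
        if self.kind not in ("point", "cycloid", "line"):
            raise ValueError(f"unknown grid kind {self.kind!r}")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def a_p(self) -> float:
        """Area per point (µm²) for a square point grid."""
        if self.kind != "point":
            raise ValueError("a_p is defined for point grids only")
        return self.spacing ** 2

    @property
    def cycloid_a(self) -> float:
        if self.kind != "cycloid":
            raise ValueError("cycloid scale is defined for cycloid grids only")
        return self.spacing / np.pi

    @property
    def l_p(self) -> float:
        """Test-line length per associated point (µm) for a cycloid grid."""
        return 4.0 * self.cycloid_a


@dataclass
class CycloidCounts:
    """Intersection and reference-point tallies from one cycloid overlay."""

    sum_I: int
    sum_P_ref: int
    l_p: float


@dataclass
class CountRecord:
    """Accumulated per-section probe tallies, exportable as a tidy table."""

    rows: list[dict] = field(default_factory=list)

    def add(self, section_index: int, field_id: int, label: str,
            P: int = 0, I: int = 0, intercept_um: float | None = None,
            seed: int | None = None) -> None:
        if P < 0 or I < 0:
            raise ValueError("counts must be non-negative")
        if intercept_um is not None and intercept_um <= 0:
            raise ValueError("intercept lengths must be positive")
        self.rows.append({"section_id": section_index, "field_id": field_id,
                          "label": label, "P": P, "I": I,
                          "intercept_um": intercept_um, "seed": seed})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["section_id", "field_id", "label", "P", "I",
                                "intercept_um", "seed"])

    def total_P(self, label: str | None = None) -> int:
        return int(sum(r["P"] for r in self.rows
                       if label is None or r["label"] == label))

    def total_I(self, label: str | None = None) -> int:
        return int(sum(r["I"] for r in self.rows
                       if label is None or r["label"] == label))

    def intercepts(self) -> np.ndarray:
        return np.array([r["intercept_um"] for r in self.rows
                         if r["intercept_um"] is not None])


def _as_rng(rng: np.random.Generator | int) -> np.random.Generator:
    return np.random.default_rng(rng) if isinstance(rng, int) else rng


def overlay_point_grid(section: SectionImage, grid: GridSpec,
                       rng: np.random.Generator | int) -> dict[str, int]:
    """Count grid points per label on a section.

    A point takes the label of the pixel whose (half-open) area contains
    it.  Points falling on background are reported under "background";
    points outside the raster under "outside".
    """
    if grid.kind != "point":
        raise ValueError("overlay_point_grid needs a point grid")
    rng = _as_rng(rng)
    if grid.spacing < section.pixel_size:
        warnings.warn(
            "grid spacing below pixel size: counts are pixel-resolution "
            "limited", stacklevel=2)
    w, h = section.size_um
    s = grid.spacing
    u = rng.uniform(0.0, s, size=2)
    xs = np.arange(u[0], w, s)
    ys = np.arange(u[1], h, s)
    if len(xs) == 0 or len(ys) == 0:
        return {"outside": 0}
    xx, yy = np.meshgrid(xs, ys)
    cols = np.floor(xx.ravel() / section.pixel_size).astype(int)
    rows = np.floor(yy.ravel() / section.pixel_size).astype(int)
    nr, nc = section.labels.shape
    inside = (cols >= 0) & (cols < nc) & (rows >= 0) & (rows < nr)
    labels = section.labels[rows[inside], cols[inside]]
    names = {v: k for k, v in section.code_table.items()}
    counts: dict[str, int] = {}
    for code, n in zip(*np.unique(labels, return_counts=True)):
        counts[names[int(code)]] = int(n)
    counts["outside"] = int((~inside).sum())
    return counts


def _unit_cycloid(n: int) -> np.ndarray:
    """(n, 2) polyline of a unit-scale (a=1) cycloid arc, length 4.

    Vertices are equally spaced in arc length s in [0, 4] via
    s = 4 (1 - cos(t/2)), t in [0, pi]; horizontal span pi, vertical span 2.
    The vertical (second) coordinate is the cycloid minor-axis direction.
    """
    s = np.linspace(0.0, 4.0, n)
    t = 2.0 * np.arccos(np.clip(1.0 - s / 4.0, -1.0, 1.0))
    return np.column_stack([t - np.sin(t), 1.0 - np.cos(t)])


def overlay_cycloid_grid(section: SectionImage, grid: GridSpec,
                         structure: str | tuple[str, ...],
                         reference: str | tuple[str, ...] | None,
                         rng: np.random.Generator | int,
                         step_frac: float = 0.5,
                         boundary_sigma: float = 1.0) -> CycloidCounts:
    """Count cycloid-arc intersections with a structure boundary.

    The grid is laid out in a frame whose "up" is the section's declared
    vertical axis; each fundamental tile (width pi*a, height 4a) carries
    one arc (minor axis vertical) and one associated reference point.
    ``sum_I`` counts transversal crossings of the structure boundary:
    membership along the polyline-sampled arc is read from the binary
    structure mask smoothed by a ``boundary_sigma``-pixel Gaussian and
    bilinearly interpolated, so crossings are counted against the smooth
    sub-pixel boundary rather than the pixel staircase (whose jagged
    perimeter would otherwise inflate counts).  ``sum_P_ref`` counts
    associated points hitting the reference compartment
    (``reference=None`` counts every point inside the raster).
    """
    from scipy.ndimage import map_coordinates

    if grid.kind != "cycloid":
        raise ValueError("overlay_cycloid_grid needs a cycloid grid")
    if section.vertical_axis is None:
        raise ValueError(
            "section lacks vertical-axis metadata; the cycloid surface "
            "estimator is only unbiased on vertical sections with a "
            "declared vertical direction")
    rng = _as_rng(rng)
    a = grid.cycloid_a
    tile_w, tile_h = np.pi * a, 4.0 * a
    vx, vy = section.vertical_axis
    v = np.array([vx, vy])
    hdir = np.array([vy, -vx])  # in-plane horizontal, perpendicular to vertical

    w, h = section.size_um
    corners = np.array([[0, 0], [w, 0], [0, h], [w, h]], dtype=float)
    cu = corners @ hdir
    cv = corners @ v
    u0 = rng.uniform(0.0, tile_w)
    v0 = rng.uniform(0.0, tile_h)
    iis = np.arange(int(np.floor((cu.min() - u0) / tile_w)) - 1,
                    int(np.ceil((cu.max() - u0) / tile_w)) + 2)
    jjs = np.arange(int(np.floor((cv.min() - v0) / tile_h)) - 1,
                    int(np.ceil((cv.max() - v0) / tile_h)) + 2)

    step = step_frac * section.pixel_size
    n_vert = max(8, int(np.ceil(4.0 * a / step)) + 1)
    arc = _unit_cycloid(n_vert) * a          # (n, 2) in (u, v) tile coords
    arc_m = arc.copy()
    arc_m[:, 0] = tile_w - arc_m[:, 0]       # mirrored arc for odd columns
    pt_local = np.array([tile_w / 2.0, a])   # associated point

    nr, nc = section.labels.shape
    px = section.pixel_size
    struct_mask = section.mask(structure)
    sm = gaussian_filter(struct_mask.astype(np.float32), boundary_sigma)
    ref_mask = None if reference is None else section.mask(reference)

    base_u = u0 + iis * tile_w               # (Ti,)
    base_v = v0 + jjs * tile_h               # (Tj,)
    # arc sample coordinates, shape (Ti, Tj, n_vert)
    local = np.where((iis % 2 == 0)[:, None, None],
                     arc[None, None, :, 0], arc_m[None, None, :, 0])
    uu = base_u[:, None, None] + local
    vv = base_v[None, :, None] + arc[None, None, :, 1]
    pts_x = uu * hdir[0] + vv * v[0]
    pts_y = uu * hdir[1] + vv * v[1]
    rows_f = pts_y / px - 0.5
    cols_f = pts_x / px - 0.5
    ok = (cols_f >= -0.5) & (cols_f <= nc - 0.5) & \
         (rows_f >= -0.5) & (rows_f <= nr - 0.5)
    vals = map_coordinates(sm, [rows_f.ravel(), cols_f.ravel()],
                           order=1, mode="nearest").reshape(rows_f.shape)
    inside = vals > 0.5
    both = ok[..., :-1] & ok[..., 1:]
    sum_I = int(np.count_nonzero((inside[..., :-1] != inside[..., 1:]) & both))

    # associated points, one per tile
    pu = base_u[:, None] + pt_local[0]
    pv = base_v[None, :] + pt_local[1]
    ppx = pu * hdir[0] + pv * v[0]
    ppy = pu * hdir[1] + pv * v[1]
    c_idx = np.floor(ppx / px).astype(int)
    r_idx = np.floor(ppy / px).astype(int)
    pok = (c_idx >= 0) & (c_idx < nc) & (r_idx >= 0) & (r_idx < nr)
    if ref_mask is None:
        sum_P = int(np.count_nonzero(pok))
    else:
        sum_P = int(np.count_nonzero(
            ref_mask[r_idx[pok], c_idx[pok]]))
    return CycloidCounts(sum_I=sum_I, sum_P_ref=sum_P, l_p=grid.l_p)


@dataclass(frozen=True)
class Field:
    """A rectangular field of view, in µm image coordinates."""

    x0: float
    y0: float
    width: float
    height: float

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.x0, self.y0, self.x0 + self.width, self.y0 + self.height


def point_in_field(x: float, y: float, fld: Field) -> bool:
    """Half-open counting-frame rule: the left and top edges are inclusion
    edges, the right and bottom edges are forbidden, so every point belongs
    to exactly one field of a tiling."""
    x0, y0, x1, y1 = fld.bounds
    return (x0 <= x < x1) and (y0 <= y < y1)


def meander_fields(section: SectionImage, field_size: float,
                   rng: np.random.Generator | int,
                   zone: str | tuple[str, ...] | None = None,
                   offset: tuple[float, float] | None = None) -> list[Field]:
    """Tile a section with fields in boustrophedon (meander) order.

    Fields start from a uniform random offset within one field so field
    placement is unbiased (an explicit ``offset`` overrides the draw);
    fields not overlapping the raster, or containing no pixel of ``zone``
    (when given), are skipped.  Returns fields in serpentine scan order.
    """
    if field_size <= 0:
        raise ValueError("field size must be positive")
    rng = _as_rng(rng)
    w, h = section.size_um
    if field_size >= w and field_size >= h:
        return [Field(0.0, 0.0, w, h)]
    off = np.asarray(offset, dtype=float) if offset is not None \
        else rng.uniform(0.0, field_size, size=2)
    x_starts = np.arange(off[0] - field_size, w, field_size)
    y_starts = np.arange(off[1] - field_size, h, field_size)
    x_starts = x_starts[(x_starts + field_size > 0) & (x_starts < w)]
    y_starts = y_starts[(y_starts + field_size > 0) & (y_starts < h)]
    zone_mask = None if zone is None else section.mask(zone)
    if zone_mask is not None and not zone_mask.any():
        warnings.warn("requested zone absent from section; no fields",
                      stacklevel=2)
        return []
    px = section.pixel_size
    nr, nc = section.labels.shape
    fields: list[Field] = []
    for row_i, y0 in enumerate(y_starts):
        xs = x_starts if row_i % 2 == 0 else x_starts[::-1]
        for x0 in xs:
            if zone_mask is not None:
                c0 = max(0, int(np.floor(x0 / px)))
                c1 = min(nc, int(np.ceil((x0 + field_size) / px)))
                r0 = max(0, int(np.floor(y0 / px)))
                r1 = min(nr, int(np.ceil((y0 + field_size) / px)))
                if c0 >= c1 or r0 >= r1 or not zone_mask[r0:r1, c0:c1].any():
                    continue
            fields.append(Field(float(x0), float(y0), field_size, field_size))
    return fields


def orthogonal_intercepts(section: SectionImage,
                          capillary: str = "capillary",
                          blood_space: str | tuple[str, ...] = "blood_space",
                          line_spacing: float = 20.0,
                          rng: np.random.Generator | int = 0,
                          step: float | None = None,
                          max_length: float | None = None,
                          smooth_sigma: float = 2.0) -> np.ndarray:
    """Orthogonal-intercept membrane thickness sample (µm).

    Horizontal test lines with a random vertical offset establish SUR start
    points where they cross the fetal-capillary boundary; from each start
    the ray marches along the local outward normal (estimated from a
    Gaussian-smoothed capillary mask) until it first enters a maternal
    blood space.  The traversed distance is the raw orthogonal intercept.
    Starts whose ray exits the raster or exceeds ``max_length`` are
    dropped; an empty sample is returned with a warning if no start points
    are found.
    """
    rng = _as_rng(rng)
    px = section.pixel_size
    if step is None:
        step = 0.25 * px
    if max_length is None:
        max_length = 60.0 * px
    cap_mask = section.mask(capillary)
    blood_mask = section.mask(blood_space)
    if not cap_mask.any():
        warnings.warn("no capillary boundary in section; empty intercept "
                      "sample", stacklevel=2)
        return np.array([])

    nr, nc = section.labels.shape
    sm = gaussian_filter(cap_mask.astype(np.float32), smooth_sigma)
    g_row, g_col = np.gradient(sm)

    # start points: capillary boundary crossings of horizontal SUR lines
    y_off = rng.uniform(0.0, line_spacing)
    ys = np.arange(y_off, nr * px, line_spacing)
    starts: list[tuple[float, float]] = []
    normals: list[tuple[float, float]] = []
    for y in ys:
        r = int(np.floor(y / px))
        if not (0 <= r < nr):
            continue
        line = cap_mask[r]
        trans = np.nonzero(line[:-1] != line[1:])[0]
        for j in trans:
            x = (j + 1) * px           # boundary between pixel j and j+1
            cin = j if line[j] else j + 1   # the capillary-side pixel
            gx, gy = g_col[r, cin], g_row[r, cin]
            norm = np.hypot(gx, gy)
            if norm < 1e-9:
                continue
            starts.append((x, y))
            normals.append((-gx / norm, -gy / norm))  # outward normal
    if not starts:
        warnings.warn("no orthogonal-intercept start points found",
                      stacklevel=2)
        return np.array([])

    S = np.array(starts)            # (S, 2) µm
    N = np.array(normals)
    ks = np.arange(1, int(np.ceil(max_length / step)) + 1)
    # flip normals that point into the capillary
    probe = S + N * (1.5 * px)
    pc = np.floor(probe[:, 0] / px).astype(int).clip(0, nc - 1)
    pr = np.floor(probe[:, 1] / px).astype(int).clip(0, nr - 1)
    wrong = cap_mask[pr, pc]
    N[wrong] *= -1.0

    pts = S[:, None, :] + N[:, None, :] * (ks[None, :, None] * step)  # (S,K,2)
    cols = np.floor(pts[..., 0] / px).astype(int)
    rows = np.floor(pts[..., 1] / px).astype(int)
    inb = (cols >= 0) & (cols < nc) & (rows >= 0) & (rows < nr)
    hit = np.zeros_like(inb)
    hit[inb] = blood_mask[rows[inb], cols[inb]]
    back_in_cap = np.zeros_like(inb)
    back_in_cap[inb] = cap_mask[rows[inb], cols[inb]]

    lengths = []
    for s_i in range(len(S)):
        h = np.nonzero(hit[s_i])[0]
        if len(h) == 0:
            continue
        k_hit = h[0]
        # reject rays that re-entered the capillary before reaching blood
        if back_in_cap[s_i, :k_hit].any():
            continue
        if not inb[s_i, :k_hit].all():
            continue
        lengths.append((k_hit + 0.5) * step)  # crossing midway into the hit step
    return np.asarray(lengths)
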
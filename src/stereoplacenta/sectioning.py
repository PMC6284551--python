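"""Virtual sectioning and systematic uniform random (SUR) sampling.

A phantom is cut exhaustively into physical sections of thickness ``t_sec``
perpendicular to the chorionic plate (planes of constant x, so the vertical
axis z lies in every section plane — the vertical-sections design needed by
the cycloid surface estimator).  SUR sampling then selects ``n_select``
sections with period k = floor(total / n) from a uniformly random start, so
every section has equal inclusion probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .phantom import LABELS, Phantom3D

__all__ = ["SectionImage", "SectionStack", "sur_select", "section_phantom"]


@dataclass
class SectionImage:
    """A labeled 2D section raster with its acquisition metadata.

    ``labels`` is indexed [row, col]; columns map to the phantom y axis and
    rows to the phantom z (vertical) axis.  ``vertical_axis`` is the unit
    direction of the tissue's vertical axis in (col, row) image coordinates;
    it must be recorded for the cycloid estimator to be valid.
    """

    labels: np.ndarray
    pixel_size: float            # µm per pixel
    index: int                   # section index within the block
    plane_position: float        # µm, position of the cutting plane
    thickness: float             # physical section thickness, µm
    vertical_axis: tuple[float, float] | None = (0.0, 1.0)
    code_table: dict[str, int] = field(default_factory=lambda: dict(LABELS))

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if self.vertical_axis is not None:
            v = np.asarray(self.vertical_axis, dtype=float)
            n = np.hypot(*v)
            if not np.isfinite(n) or n == 0:
                raise ValueError("vertical axis must be a nonzero direction")
            self.vertical_axis = (float(v[0] / n), float(v[1] / n))
        unknown = set(np.unique(self.labels)) - set(self.code_table.values())
        if unknown:
            raise ValueError(f"raster contains undeclared label codes {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def size_um(self) -> tuple[float, float]:
        """(width, height) of the raster in µm."""
        nr, nc = self.labels.shape
        return nc * self.pixel_size, nr * self.pixel_size

    def code(self, name: str) -> int:
        try:
            return self.code_table[name]
        except KeyError:
            raise KeyError(f"label {name!r} not in declared code table") from None

    def mask(self, names: str | tuple[str, ...]) -> np.ndarray:
        if isinstance(names, str):
            names = (names,)
        codes = [self.code(n) for n in names]
        return np.isin(self.labels, codes)


@dataclass
class SectionStack:
    """SUR-selected sections of one block.

    ``period`` is the sampling period k in sections; the Cavalieri
    inter-sample distance is d = k * t_sec.
    """

    sections: list[SectionImage]
    total_sections: int
    period: int
    t_sec: float

    def __post_init__(self) -> None:
        if self.t_sec <= 0 or self.period < 1:
            raise ValueError("need t_sec > 0 and period >= 1")
        idx = [s.index for s in self.sections]
        if len(idx) > 1:
            diffs = np.diff(idx)
            if not np.all(diffs == self.period):
                raise ValueError(
                    "selected section indices must form an arithmetic "
                    f"progression with common difference {self.period}, got {idx}")

    @property
    def d(self) -> float:
        """Inter-sample distance d = k * t_sec (µm)."""
        return self.period * self.t_sec

    def __len__(self) -> int:
        return len(self.sections)

    def __iter__(self):
        return iter(self.sections)


def sur_select(total_sections: int, n_select: int,
               rng: np.random.Generator | int) -> tuple[np.ndarray, int]:
    """Systematic uniform random selection of section indices.

    Returns (indices, period k) with k = floor(total / n) and the first
    index uniform on [0, k); every section then has inclusion probability
    n_select / total_sections.
    """
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    if n_select > total_sections:
        raise ValueError(
            f"cannot select {n_select} from {total_sections} sections")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    k = total_sections // n_select
    start = int(rng.integers(0, k))
    idx = start + k * np.arange(n_select)
    idx = idx[idx < total_sections]
    if len(idx) < n_select:
        warnings.warn(
            f"block too short: selected {len(idx)} of the requested "
            f"{n_select} sections", stacklevel=2)
    return idx, k


def section_phantom(phantom: Phantom3D, t_sec: float, n_select: int,
                    rng: np.random.Generator | int,
                    pixel_size: float = 8.0) -> SectionStack:
    """Cut a phantom into t_sec-thick sections along x and SUR-select some.

    The cutting grid carries a uniformly random phase within one section
    thickness (the block's position on the microtome is arbitrary), and the
    SUR start is uniform over one period, which together make the Cavalieri
    estimator design-unbiased.  Each section raster is the labeled
    intersection of the phantom with the plane at the section's mid-depth.
    """
    if t_sec <= 0:
        raise ValueError("section thickness must be positive")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    x_lo, x_hi = float(phantom.bbox_lo[0]), float(phantom.bbox_hi[0])
    total = int((x_hi - x_lo) // t_sec)
    if total < 1:
        raise ValueError(
            f"phantom extent {x_hi - x_lo:.1f} µm is thinner than one "
            f"{t_sec} µm section")
    phase = float(rng.uniform(0.0, t_sec))
    idx, k = sur_select(total, min(n_select, total), rng)
    sections = []
    for i in idx:
        x_mid = x_lo + phase + (int(i) + 0.5) * t_sec
        raster = phantom.rasterize_section(x_mid, pixel_size)
        sections.append(SectionImage(
            labels=raster, pixel_size=pixel_size, index=int(i),
            plane_position=x_mid, thickness=t_sec))
    return SectionStack(sections=sections, total_sections=total,
                        period=k, t_sec=t_sec)
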
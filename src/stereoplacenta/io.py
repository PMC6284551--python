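"""File-format boundary: labeled rasters with JSON sidecars, tidy CSVs.

Section images travel as 16-bit grayscale TIFF/PNG holding the integer
label codes, with a JSON sidecar (same stem, ``.json``) carrying pixel
size, section index, plane position, thickness, vertical axis and the
label code table.  Ground truth and model fits are emitted as JSON; count
records and study tables as CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .phantom import GroundTruth
from .sectioning import SectionImage

__all__ = ["save_section", "load_section", "save_ground_truth",
           "load_ground_truth", "write_json", "file_digest"]


def save_section(section: SectionImage, path: str | Path) -> Path:
    """Write a SectionImage as TIFF/PNG plus its JSON sidecar."""
    path = Path(path)
    data = section.labels.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, data)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    sidecar = {
        "pixel_size_um": section.pixel_size,
        "section_index": section.index,
        "plane_position_um": section.plane_position,
        "thickness_um": section.thickness,
        "vertical_axis": list(section.vertical_axis)
        if section.vertical_axis else None,
        "code_table": section.code_table,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_section(path: str | Path) -> SectionImage:
    """Read a section raster and its sidecar back into a SectionImage."""
    path = Path(path)
    side_path = path.with_suffix(".json")
    if not side_path.exists():
        raise FileNotFoundError(f"missing sidecar {side_path}")
    try:
        meta = json.loads(side_path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"corrupted sidecar JSON at {side_path}: {e}") from e
    if path.suffix.lower() in (".tif", ".tiff"):
        labels = tifffile.imread(path)
    else:
        labels = iio.imread(path)
    va = meta.get("vertical_axis")
    return SectionImage(
        labels=np.asarray(labels).astype(np.uint8),
        pixel_size=float(meta["pixel_size_um"]),
        index=int(meta["section_index"]),
        plane_position=float(meta["plane_position_um"]),
        thickness=float(meta["thickness_um"]),
        vertical_axis=tuple(va) if va else None,
        code_table={k: int(v) for k, v in meta["code_table"].items()},
    )


def save_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(gt), indent=1,
                               sort_keys=True))
    return path


def load_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(**d)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, sort_keys=True,
                               default=default))
    return path


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file's bytes."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
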
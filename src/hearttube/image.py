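"""Core volumetric containers and TIFF I/O.

Axis order is fixed as ``(z, y, x)`` throughout the package.  All physical
quantities are expressed in micrometres; the physical position of voxel
``(i, j, k)`` is ``(i * sz, j * sy, k * sx)`` (voxel centres, 0-based).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "LabelVolume", "read_stack", "read_labels"]


def _as_spacing(spacing) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3:
        raise ValueError(f"spacing must have 3 entries (z, y, x), got {len(sp)}")
    if any(s <= 0 for s in sp):
        raise ValueError(f"spacing must be strictly positive, got {sp}")
    return sp


@dataclass
class ImageStack:
    """A 3D intensity volume with per-axis voxel spacing in µm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical span between first and last voxel centres per axis (µm)."""
        return tuple((n - 1) * s for n, s in zip(self.data.shape, self.spacing))

    def voxel_to_um(self, idx: np.ndarray) -> np.ndarray:
        """Convert (…, 3) voxel indices to physical coordinates in µm."""
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def um_to_voxel(self, pos: np.ndarray) -> np.ndarray:
        """Convert (…, 3) physical coordinates (µm) to fractional voxel indices."""
        return np.asarray(pos, dtype=float) / np.asarray(self.spacing)

    def write(self, path: str | Path) -> None:
        write_stack(self, path)


@dataclass
class LabelVolume(ImageStack):
    """Integer-labelled 3D volume; 0 is background."""

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError(
                f"label volume requires an integer dtype, got {self.data.dtype}"
            )
        if self.data.size and self.data.min() < 0:
            raise ValueError("label volume must be nonnegative")

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero label values present in the volume."""
        vals = np.unique(self.data)
        return vals[vals > 0]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a volume as multi-page TIFF plus a spacing sidecar JSON.

    Spacing is also embedded in the TIFF resolution tags (x/y) and ImageJ
    metadata (z) so the file remains self-describing for external viewers.
    """
    path = Path(path)
    sz, sy, sx = stack.spacing
    tifffile.imwrite(
        path,
        stack.data,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
        imagej=stack.data.dtype in (np.dtype("uint8"), np.dtype("uint16"), np.dtype("float32")),
    )
    _sidecar(path).write_text(
        json.dumps({"spacing_um": list(stack.spacing), "axes": "zyx"}, indent=2)
    )


def _read(path: str | Path, spacing) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    data = tifffile.imread(path)
    if spacing is None:
        sidecar = _sidecar(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no spacing given and sidecar {sidecar} not found"
            )
        spacing = json.loads(sidecar.read_text())["spacing_um"]
    return data, _as_spacing(spacing)


def read_stack(path: str | Path, spacing=None) -> ImageStack:
    """Read an intensity TIFF; spacing from the sidecar JSON unless given."""
    data, sp = _read(path, spacing)
    return ImageStack(data, sp)


def read_labels(path: str | Path, spacing=None) -> LabelVolume:
    """Read an integer-label TIFF; spacing from the sidecar JSON unless given."""
    data, sp = _read(path, spacing)
    return LabelVolume(data.astype(np.int32, copy=False), sp)
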
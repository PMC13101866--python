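"""Heart-shape metrics from a compartment-labelled lumen.

Pipeline: resample to isotropic voxels, locate compartment interfaces,
measure AVC length between interface centroids, thread a central line
through the lumen from inflow to outflow along the distance-transform
ridge, and form the convolutedness (looping) ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.graph import MCP_Geometric

from .image import ImageStack, LabelVolume

__all__ = [
    "InterfaceCentroid",
    "MorphometryResult",
    "resample_isotropic",
    "extract_interface",
    "avc_length",
    "central_line",
    "convolutedness",
    "measure_morphometry",
]

# compartment label conventions (see synthetic.COMPARTMENTS)
PRE_ATRIUM, ATRIUM, AVC, VENTRICLE, POSTVENTRICLE = 1, 2, 3, 4, 5


@dataclass(frozen=True)
class InterfaceCentroid:
    pair: tuple[int, int]
    centroid: tuple[float, float, float]   # µm
    face_count: int


@dataclass
class MorphometryResult:
    avc_length: float
    inflow_point: tuple[float, float, float]
    outflow_point: tuple[float, float, float]
    straight_distance: float
    central_line: np.ndarray               # (N, 3) µm
    central_line_length: float
    convolutedness: float

    def to_json_dict(self) -> dict:
        return {
            "avc_length_um": self.avc_length,
            "inflow_point_um": list(self.inflow_point),
            "outflow_point_um": list(self.outflow_point),
            "straight_distance_um": self.straight_distance,
            "central_line_length_um": self.central_line_length,
            "convolutedness": self.convolutedness,
        }

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.write_text(json.dumps(self.to_json_dict(), indent=2))
        np.savetxt(
            path.with_suffix(".central_line.csv"),
            self.central_line,
            delimiter=",",
            header="z_um,y_um,x_um",
            comments="",
        )


def resample_isotropic(volume: ImageStack, target_edge: float = 2.0) -> ImageStack:
    """Resample to isotropic voxels of ``target_edge`` µm.

    Nearest-neighbour interpolation for label volumes, linear for
    intensities.  Physical extents are preserved within half a target voxel
    per axis.  Returns the input unchanged if already at the target spacing.
    """
    if target_edge <= 0:
        raise ValueError("target_edge must be positive")
    spacing = np.asarray(volume.spacing)
    if np.allclose(spacing, target_edge):
        return volume
    extent = np.asarray(volume.extent)
    if np.any(target_edge > extent):
        raise ValueError(
            f"target edge {target_edge} µm coarser than the volume extent {tuple(extent)}"
        )
    is_labels = isinstance(volume, LabelVolume)
    order = 0 if is_labels else 1
    # voxel centres sit at index × spacing: output voxel j samples the input
    # at j · target/spacing, keeping the physical origin and grid alignment
    out_shape = tuple(int(np.floor(e / target_edge)) + 1 for e in extent)
    grids = np.meshgrid(
        *[
            np.arange(n) * target_edge / s
            for n, s in zip(out_shape, spacing)
        ],
        indexing="ij",
    )
    data = ndimage.map_coordinates(
        volume.data, np.stack(grids), order=order, mode="nearest"
    )
    sp = (target_edge,) * 3
    if is_labels:
        return LabelVolume(data.astype(volume.data.dtype), sp)
    return ImageStack(data, sp)


def extract_interface(compartments: LabelVolume, a: int, b: int) -> InterfaceCentroid:
    """Centroid of the voxel-face boundary between labels ``a`` and ``b``.

    The interface is the set of midpoints of faces where an ``a`` voxel is
    6-adjacent to a ``b`` voxel; the centroid is their mean in µm.
    """
    data = compartments.data
    present = set(np.unique(data).tolist())
    for lab in (a, b):
        if lab not in present:
            raise ValueError(f"label {lab} absent from compartment volume")
    spacing = np.asarray(compartments.spacing)
    midpoints = []
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        left, right = data[tuple(lo)], data[tuple(hi)]
        for la, lb in ((a, b), (b, a)):
            match = (left == la) & (right == lb)
            if not match.any():
                continue
            idx = np.argwhere(match).astype(float)
            idx[:, axis] += 0.5          # face midpoint between the two voxels
            midpoints.append(idx * spacing)
    if not midpoints:
        raise ValueError(f"labels {a} and {b} are not 6-adjacent anywhere")
    pts = np.concatenate(midpoints, axis=0)
    return InterfaceCentroid(
        pair=(a, b),
        centroid=tuple(pts.mean(axis=0)),
        face_count=len(pts),
    )


def avc_length(compartments: LabelVolume) -> float:
    """Distance between the atrium|AVC and AVC|ventricle interface centroids."""
    c1 = extract_interface(compartments, ATRIUM, AVC)
    c2 = extract_interface(compartments, AVC, VENTRICLE)
    return float(np.linalg.norm(np.asarray(c1.centroid) - np.asarray(c2.centroid)))


def _snap_to_mask(mask: np.ndarray, spacing: np.ndarray, point_um) -> tuple[int, ...]:
    """Nearest mask voxel to a physical point."""
    vox = np.round(np.asarray(point_um) / spacing).astype(int)
    vox = np.clip(vox, 0, np.asarray(mask.shape) - 1)
    if mask[tuple(vox)]:
        return tuple(vox)
    idx = np.argwhere(mask)
    d = np.linalg.norm((idx - vox) * spacing, axis=1)
    return tuple(idx[np.argmin(d)])


def central_line(
    lumen_mask: LabelVolume | ImageStack,
    inflow_point,
    outflow_point,
    smooth_window: int = 5,
) -> tuple[np.ndarray, float]:
    """Medial path from inflow to outflow through the lumen.

    Minimal-cost voxel path with cost ``1/(1 + d)²`` where ``d`` is the
    distance to the lumen boundary, which keeps the path on the medial
    ridge; the polyline is smoothed by a moving average and its length is
    the sum of segment lengths in µm.
    """
    spacing = np.asarray(lumen_mask.spacing)
    mask = np.asarray(lumen_mask.data) > 0
    if not mask.any():
        raise ValueError("empty lumen mask")
    start = _snap_to_mask(mask, spacing, inflow_point)
    end = _snap_to_mask(mask, spacing, outflow_point)
    if start == end:
        pt = np.asarray(start) * spacing
        return pt[None, :], 0.0

    edt = ndimage.distance_transform_edt(mask, sampling=spacing)
    costs = np.where(mask, 1.0 / (1.0 + edt) ** 2, np.inf)
    mcp = MCP_Geometric(costs, sampling=tuple(spacing), fully_connected=True)
    cum, _ = mcp.find_costs([start], [end])
    if not np.isfinite(cum[end]):
        raise ValueError(
            "inflow and outflow are not connected inside the lumen mask"
        )
    path = np.asarray(mcp.traceback(end), dtype=float) * spacing

    if smooth_window > 1 and len(path) > smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        path = np.column_stack(
            [np.convolve(path[:, d], kernel, mode="valid") for d in range(3)]
        )
    # anchor the polyline at the exact requested ports so the measured
    # length and the inflow–outflow chord refer to the same endpoints
    path = np.vstack([np.asarray(inflow_point, float), path,
                      np.asarray(outflow_point, float)])
    length = float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))
    return path, length


def convolutedness(central_line_length: float, inflow_point, outflow_point) -> float:
    """Looping ratio: central-line length over straight inflow–outflow distance."""
    chord = float(
        np.linalg.norm(np.asarray(inflow_point) - np.asarray(outflow_point))
    )
    if chord < 1e-9:
        raise ValueError("inflow and outflow points coincide; ratio undefined")
    if central_line_length <= 0:
        raise ValueError("central-line length must be positive")
    return central_line_length / chord


def measure_morphometry(
    compartments: LabelVolume,
    target_edge: float = 2.0,
    smooth_window: int = 5,
) -> MorphometryResult:
    """All shape metrics for one heart from its compartment labels.

    Resamples to ``target_edge`` µm isotropic first; inflow/outflow are the
    pre-atrium|atrium and ventricle|postventricle interface centroids.
    """
    iso = resample_isotropic(compartments, target_edge)
    inflow = extract_interface(iso, PRE_ATRIUM, ATRIUM).centroid
    outflow = extract_interface(iso, VENTRICLE, POSTVENTRICLE).centroid
    length_avc = avc_length(iso)
    lumen = LabelVolume((iso.data > 0).astype(np.int32), iso.spacing)
    line, line_length = central_line(lumen, inflow, outflow, smooth_window)
    straight = float(np.linalg.norm(np.asarray(inflow) - np.asarray(outflow)))
    return MorphometryResult(
        avc_length=length_avc,
        inflow_point=tuple(float(v) for v in inflow),
        outflow_point=tuple(float(v) for v in outflow),
        straight_distance=straight,
        central_line=line,
        central_line_length=line_length,
        convolutedness=convolutedness(line_length, inflow, outflow),
    )
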
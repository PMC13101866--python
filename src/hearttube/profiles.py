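"""Membrane line-profile quantification and projection ROI readouts.

Intensity is sampled along short lines perpendicular to the membrane and the
per-line maximum is recorded; region values are sets of per-line maxima, with
statistics run downstream on those maxima.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image import ImageStack, LabelVolume

__all__ = [
    "LineProfile",
    "LineProfileSet",
    "estimate_normals",
    "sample_line_profiles",
    "place_anchors",
    "max_projection_intensity",
    "normalize_to_reference",
]


@dataclass
class LineProfile:
    anchor: tuple[float, float, float]     # µm
    normal: tuple[float, float, float]     # unit vector
    half_length: float                     # µm
    samples: np.ndarray
    max_intensity: float


@dataclass
class LineProfileSet:
    lines: list
    region: str = ""
    channel: str = ""
    cell_id: int | None = None

    @property
    def maxima(self) -> np.ndarray:
        return np.array([ln.max_intensity for ln in self.lines])

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["region", "channel", "z_um", "y_um", "x_um", "max_intensity"])
            for ln in self.lines:
                w.writerow([self.region, self.channel, *ln.anchor, ln.max_intensity])


def _signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return outside - inside


def estimate_normals(
    membrane_mask: LabelVolume | ImageStack,
    anchor_points,
    smooth_sigma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Surface normals at anchors from the smoothed signed distance field.

    Returns ``(normals, valid)``: unit normals of shape (n, 3) and a boolean
    keep-mask.  Anchors farther than 2 voxels from the mask surface or with
    a vanishing gradient are rejected with a warning.
    """
    spacing = np.asarray(membrane_mask.spacing)
    mask = np.asarray(membrane_mask.data) > 0
    sdf = _signed_distance(mask, spacing)
    if smooth_sigma > 0:
        sdf = ndimage.gaussian_filter(sdf, smooth_sigma / spacing)
    grads = np.gradient(sdf, *spacing)

    anchors = np.atleast_2d(np.asarray(anchor_points, dtype=float))
    vox = anchors / spacing
    max_surface_dist = 2.0 * float(np.max(spacing))
    normals = np.zeros_like(anchors)
    valid = np.ones(len(anchors), dtype=bool)
    for i, v in enumerate(vox):
        coords = v[:, None]
        d = float(ndimage.map_coordinates(np.abs(sdf), coords, order=1)[0])
        if d > max_surface_dist:
            warnings.warn(
                f"anchor {anchors[i]} is {d:.1f} µm from the membrane surface; rejected",
                stacklevel=2,
            )
            valid[i] = False
            continue
        g = np.array(
            [float(ndimage.map_coordinates(gr, coords, order=1)[0]) for gr in grads]
        )
        norm = np.linalg.norm(g)
        if norm < 1e-9:
            warnings.warn(
                f"vanishing gradient at anchor {anchors[i]}; rejected", stacklevel=2
            )
            valid[i] = False
            continue
        normals[i] = g / norm
    return normals, valid


def place_anchors(
    membrane_labels: LabelVolume,
    region: int,
    n: int,
    rng: np.random.Generator,
    z_plane: int | None = None,
    min_separation: float = 2.0,
) -> np.ndarray:
    """Anchor points (µm) on the membrane of one labelled region.

    By default anchors are drawn uniformly from the region's membrane voxels
    in 3D with a minimum pairwise separation; with ``z_plane`` given, the
    in-plane contour is sampled at uniform arc length (angular order around
    the contour centroid), matching single-z-plane line placement.
    """
    spacing = np.asarray(membrane_labels.spacing)
    data = membrane_labels.data
    if z_plane is not None:
        plane = data[z_plane]
        idx2 = np.argwhere(plane == region)
        if len(idx2) == 0:
            raise ValueError(f"region {region} has no membrane voxels in plane {z_plane}")
        center = idx2.mean(axis=0)
        ang = np.arctan2(idx2[:, 0] - center[0], idx2[:, 1] - center[1])
        order = np.argsort(ang)
        take = order[np.linspace(0, len(order) - 1, n).round().astype(int)]
        idx = np.column_stack([np.full(len(take), z_plane), idx2[take]])
        return idx * spacing
    idx = np.argwhere(data == region)
    if len(idx) == 0:
        raise ValueError(f"region {region} absent from membrane labels")
    pts = idx * spacing
    order = rng.permutation(len(pts))
    chosen: list[np.ndarray] = []
    for i in order:
        p = pts[i]
        if chosen and np.min(
            np.linalg.norm(np.asarray(chosen) - p, axis=1)
        ) < min_separation:
            continue
        chosen.append(p)
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise ValueError(
            f"could only place {len(chosen)}/{n} anchors in region {region}"
        )
    return np.asarray(chosen)


def sample_line_profiles(
    image: ImageStack,
    anchors,
    normals,
    half_length: float = 3.0,
    step: float = 0.25,
    region: str = "",
    channel: str = "",
) -> LineProfileSet:
    """Trilinear profiles from −half_length to +half_length along each normal.

    Sample points falling outside the image are dropped (the line is
    truncated with a warning); the per-line maximum of the remaining samples
    is recorded.
    """
    if not half_length >= step > 0:
        raise ValueError("need half_length ≥ step > 0")
    spacing = np.asarray(image.spacing)
    data = np.asarray(image.data, dtype=np.float64)
    hi = np.asarray(data.shape) - 1
    ts = np.arange(-half_length, half_length + 0.5 * step, step)
    anchors = np.atleast_2d(np.asarray(anchors, dtype=float))
    normals = np.atleast_2d(np.asarray(normals, dtype=float))
    lines = []
    for anchor, normal in zip(anchors, normals):
        nlen = np.linalg.norm(normal)
        if abs(nlen - 1.0) > 1e-6:
            normal = normal / nlen
        pts = anchor[None, :] + ts[:, None] * normal[None, :]
        vox = pts / spacing
        inside = np.all((vox >= 0) & (vox <= hi), axis=1)
        if not inside.all():
            warnings.warn(
                f"profile at {tuple(anchor)} exits image bounds; truncated",
                stacklevel=2,
            )
        vox = vox[inside]
        if len(vox) == 0:
            continue
        samples = ndimage.map_coordinates(data, vox.T, order=1)
        lines.append(
            LineProfile(
                anchor=tuple(anchor),
                normal=tuple(normal),
                half_length=half_length,
                samples=samples,
                max_intensity=float(samples.max()),
            )
        )
    return LineProfileSet(lines=lines, region=region, channel=channel)


def max_projection_intensity(stack: ImageStack, roi: np.ndarray) -> float:
    """Maximum-intensity z-projection, then the maximum within a 2D ROI mask."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != stack.shape[1:]:
        raise ValueError(
            f"ROI shape {roi.shape} does not match projection shape {stack.shape[1:]}"
        )
    if not roi.any():
        raise ValueError("empty ROI")
    projection = np.asarray(stack.data).max(axis=0)
    return float(projection[roi].max())


def normalize_to_reference(values, reference_values) -> np.ndarray:
    """Divide values by the mean of the reference set (reference mean → 1)."""
    reference_values = np.asarray(reference_values, dtype=float)
    if reference_values.size == 0:
        raise ValueError("reference set is empty")
    mean = float(reference_values.mean())
    if mean <= 0:
        raise ValueError(f"reference mean must be positive, got {mean}")
    return np.asarray(values, dtype=float) / mean
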
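"""Synthetic heart-tube generator with complete ground truth.

Builds 3D two-channel fluorescence-like stacks of a curved endocardial tube
partitioned into five compartments (pre-atrium, atrium, AVC, ventricle,
postventricle), with wall-resident ellipsoidal nuclei, a thin membrane shell,
Gaussian PSF blur and Poisson+Gaussian noise.  Every quantity measured by the
downstream analysis stages is known analytically here, so the whole pipeline
can be validated without any acquired data.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .image import ImageStack, LabelVolume, write_stack

__all__ = [
    "COMPARTMENTS",
    "SyntheticConfig",
    "Centerline",
    "Nucleus",
    "GroundTruth",
    "SyntheticHeart",
    "GeometryError",
    "PlacementError",
    "make_centerline",
    "synthesize_heart",
]

#: Compartment names in inflow→outflow order; label value = index + 1.
COMPARTMENTS = ("pre-atrium", "atrium", "AVC", "ventricle", "postventricle")


class GeometryError(ValueError):
    """Raised when the requested centerline does not fit inside the grid."""


class PlacementError(RuntimeError):
    """Raised when nucleus rejection sampling exhausts its retry budget."""


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic heart (one condition).

    Semi-axes are given per compartment; a condition contrast (e.g. enlarged
    AVC nuclei) is expressed by scaling one compartment's axes, see
    :meth:`with_volume_scale`.
    """

    grid_shape: tuple[int, int, int] = (48, 130, 130)
    spacing: tuple[float, float, float] = (1.5, 1.0, 1.0)
    centerline_kind: str = "arc"
    centerline_params: dict = field(
        default_factory=lambda: {"radius": 45.0, "turn_fraction": 0.5}
    )
    compartment_fractions: tuple[float, ...] = (0.1, 0.3, 0.2, 0.3, 0.1)
    tube_radius_by_compartment: tuple[float, ...] = (10.0, 12.0, 7.0, 12.0, 10.0)
    n_nuclei_by_compartment: tuple[int, ...] = (4, 17, 8, 17, 4)
    nucleus_axes_mean: tuple[tuple[float, float, float], ...] = (
        (3.2, 2.6, 2.2),
    ) * 5
    nucleus_axes_sd: float = 0.25
    nucleus_intensity: float = 150.0
    membrane_intensity_by_compartment: tuple[float, ...] = (
        80.0, 100.0, 100.0, 100.0, 80.0,
    )
    membrane_thickness: float = 1.5
    wall_fraction: float = 0.85
    psf_sigma: tuple[float, float, float] = (1.0, 0.8, 0.8)
    gaussian_sd: float = 2.0
    poisson_scale: float = 1.0
    golgi_axis: tuple[float, float, float] | None = None
    golgi_kappa: float = 4.0
    golgi_distance: float = 3.0
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.compartment_fractions = tuple(float(f) for f in self.compartment_fractions)
        self.tube_radius_by_compartment = tuple(
            float(r) for r in self.tube_radius_by_compartment
        )
        self.n_nuclei_by_compartment = tuple(
            int(n) for n in self.n_nuclei_by_compartment
        )
        self.nucleus_axes_mean = tuple(
            tuple(float(a) for a in ax) for ax in self.nucleus_axes_mean
        )
        self.membrane_intensity_by_compartment = tuple(
            float(v) for v in self.membrane_intensity_by_compartment
        )
        self.psf_sigma = tuple(float(s) for s in self.psf_sigma)
        self.validate()

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(n < 4 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 axes of ≥4 voxels, got {self.grid_shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        f = self.compartment_fractions
        if len(f) != 5 or any(x <= 0 for x in f):
            raise ValueError("compartment_fractions must be 5 positive values")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError(f"compartment_fractions must sum to 1, got {sum(f)!r}")
        for name, vals in (
            ("tube_radius_by_compartment", self.tube_radius_by_compartment),
            ("membrane_intensity_by_compartment", self.membrane_intensity_by_compartment),
        ):
            if len(vals) != 5:
                raise ValueError(f"{name} must have 5 entries")
        if any(r <= 0 for r in self.tube_radius_by_compartment):
            raise ValueError("tube radii must be strictly positive")
        if len(self.n_nuclei_by_compartment) != 5 or any(
            n < 0 for n in self.n_nuclei_by_compartment
        ):
            raise ValueError("n_nuclei_by_compartment must be 5 nonnegative counts")
        if len(self.nucleus_axes_mean) != 5 or any(
            len(ax) != 3 or any(a <= 0 for a in ax) for ax in self.nucleus_axes_mean
        ):
            raise ValueError("nucleus_axes_mean must be 5 triples of positive semi-axes")
        if self.nucleus_axes_sd < 0:
            raise ValueError("nucleus_axes_sd must be nonnegative")
        if not 0 < self.wall_fraction <= 1:
            raise ValueError("wall_fraction must lie in (0, 1]")
        if any(s < 0 for s in self.psf_sigma):
            raise ValueError("psf_sigma must be nonnegative")
        if self.gaussian_sd < 0 or self.poisson_scale < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.membrane_thickness <= 0:
            raise ValueError("membrane_thickness must be positive")

    def with_volume_scale(self, factor: float, compartment: str = "AVC") -> "SyntheticConfig":
        """Return a copy whose nuclei in ``compartment`` have ``factor``× mean volume.

        Semi-axes scale by ``factor**(1/3)`` so the ellipsoid volume scales
        linearly with ``factor``.
        """
        i = COMPARTMENTS.index(compartment)
        s = factor ** (1.0 / 3.0)
        axes = list(self.nucleus_axes_mean)
        axes[i] = tuple(a * s for a in axes[i])
        return replace(self, nucleus_axes_mean=tuple(axes))

    @property
    def margin(self) -> float:
        """Clearance (µm) the tube needs from the grid faces."""
        return max(self.tube_radius_by_compartment) + 3.0 * max(self.psf_sigma)


@dataclass
class Centerline:
    """Densely sampled centerline polyline with cumulative arc length."""

    points: np.ndarray          # (N, 3) µm, (z, y, x)
    arclength: np.ndarray       # (N,) cumulative, arclength[0] == 0

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    @property
    def inflow_point(self) -> np.ndarray:
        return self.points[0]

    @property
    def outflow_point(self) -> np.ndarray:
        return self.points[-1]

    def point_at(self, s: float) -> np.ndarray:
        """Linear interpolation of position at arc length ``s``."""
        s = float(np.clip(s, 0.0, self.length))
        return np.array(
            [np.interp(s, self.arclength, self.points[:, d]) for d in range(3)]
        )

    def tangent_at(self, s: float) -> np.ndarray:
        i = int(np.clip(np.searchsorted(self.arclength, s), 1, len(self.points) - 1))
        t = self.points[i] - self.points[i - 1]
        return t / np.linalg.norm(t)


def _curve_function(kind: str, params: dict):
    """Return (p(t), t_range) for the requested curve family, in µm.

    Curves are generated around the origin and re-centred onto the grid
    afterwards, so the parameterisation need not care about grid placement.
    """
    if kind == "straight":
        length = float(params.get("length", 100.0))
        axis = np.asarray(params.get("axis", (0.0, 0.0, 1.0)), dtype=float)
        axis = axis / np.linalg.norm(axis)

        def p(t):
            return np.outer((t - 0.5) * length, axis)

        return p, (0.0, 1.0)
    if kind == "arc":
        radius = float(params.get("radius", 35.0))
        turn = float(params.get("turn_fraction", 0.5))
        if not 0 < turn <= 0.9:
            raise GeometryError(f"arc turn_fraction must be in (0, 0.9], got {turn}")
        theta = 2.0 * math.pi * turn

        def p(t):
            ang = (t - 0.5) * theta
            # arc in the (y, x) plane at constant z
            return np.stack(
                [np.zeros_like(ang), radius * np.cos(ang), radius * np.sin(ang)],
                axis=-1,
            )

        return p, (0.0, 1.0)
    if kind == "helix":
        radius = float(params.get("radius", 30.0))
        pitch = float(params.get("pitch", 30.0))  # µm of rise per full turn
        turns = float(params.get("turns", 1.0))

        def p(t):
            ang = t * 2.0 * math.pi * turns
            z = (t - 0.5) * pitch * turns
            return np.stack(
                [z, radius * np.cos(ang), radius * np.sin(ang)], axis=-1
            )

        return p, (0.0, 1.0)
    if kind == "spline":
        ctrl = np.asarray(params["control_points"], dtype=float)
        if ctrl.ndim != 2 or ctrl.shape[1] != 3 or len(ctrl) < 3:
            raise GeometryError("spline needs ≥3 control points of shape (n, 3)")
        u = np.linspace(0.0, 1.0, len(ctrl))
        cs = CubicSpline(u, ctrl, axis=0)

        def p(t):
            return cs(np.asarray(t))

        return p, (0.0, 1.0)
    raise GeometryError(
        f"unknown centerline_kind {kind!r}; supported: straight, arc, helix, spline"
    )


def make_centerline(config: SyntheticConfig) -> Centerline:
    """Sample the configured centerline densely and centre it in the grid.

    The polyline is resampled so no segment exceeds half the smallest voxel
    edge; the curve must keep ``config.margin`` clearance from every grid
    face or a :class:`GeometryError` is raised.
    """
    p, (t0, t1) = _curve_function(config.centerline_kind, config.centerline_params)

    # estimate arc length on a coarse grid, then resample uniformly in t
    # densely enough that segments are ≤ 0.5 · min(spacing)
    coarse = p(np.linspace(t0, t1, 512))
    approx_len = float(np.sum(np.linalg.norm(np.diff(coarse, axis=0), axis=1)))
    max_seg = 0.5 * min(config.spacing)
    n = max(int(math.ceil(approx_len / max_seg)) + 1, 32)
    pts = np.atleast_2d(p(np.linspace(t0, t1, n)))

    # translate so the curve's bounding box is centred in the grid
    extent = np.array(
        [(s - 1) * sp for s, sp in zip(config.grid_shape, config.spacing)]
    )
    mid = 0.5 * (pts.min(axis=0) + pts.max(axis=0))
    pts = pts - mid + extent / 2.0

    margin = config.margin
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    for ax, name in enumerate("zyx"):
        if lo[ax] < margin - 1e-9 or hi[ax] > extent[ax] - margin + 1e-9:
            raise GeometryError(
                f"centerline plus margin {margin:.2f} µm exceeds grid along "
                f"{name} (extent {extent[ax]:.1f} µm, curve span "
                f"[{lo[ax]:.1f}, {hi[ax]:.1f}] µm)"
            )

    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclength = np.concatenate([[0.0], np.cumsum(seg)])
    return Centerline(points=pts, arclength=arclength)


def compartment_boundaries(config: SyntheticConfig, total_length: float) -> np.ndarray:
    """Arc-length boundary positions, length 6: [0, b1, …, b4, L]."""
    return np.concatenate(
        [[0.0], np.cumsum(config.compartment_fractions)]
    ) * total_length


@dataclass
class Nucleus:
    """Ground-truth ellipsoidal nucleus."""

    center: tuple[float, float, float]       # µm
    semi_axes: tuple[float, float, float]    # µm
    orientation: list                        # 3×3 rotation matrix (rows)
    compartment: str
    arclength: float                         # position along the centerline

    @property
    def volume(self) -> float:
        """Analytic ellipsoid volume 4/3·π·abc in µm³."""
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c


@dataclass
class GroundTruth:
    centerline: Centerline
    compartment_intervals: dict              # name -> (s_lo, s_hi) µm
    nuclei: list                             # list[Nucleus]
    golgi_offsets: np.ndarray                # (n, 3) µm
    inflow_point: np.ndarray
    outflow_point: np.ndarray
    analytic_avc_length: float               # chord between AVC boundary points
    analytic_convolutedness: float           # arc length / endpoint chord

    def to_json_dict(self) -> dict:
        return {
            "centerline_points_um": self.centerline.points.tolist(),
            "centerline_arclength_um": self.centerline.arclength.tolist(),
            "compartment_intervals_um": {
                k: list(v) for k, v in self.compartment_intervals.items()
            },
            "nuclei": [
                {
                    "center_um": list(n.center),
                    "semi_axes_um": list(n.semi_axes),
                    "orientation": n.orientation,
                    "compartment": n.compartment,
                    "arclength_um": n.arclength,
                    "volume_um3": n.volume,
                }
                for n in self.nuclei
            ],
            "golgi_offsets_um": self.golgi_offsets.tolist(),
            "inflow_point_um": self.inflow_point.tolist(),
            "outflow_point_um": self.outflow_point.tolist(),
            "analytic_avc_length_um": self.analytic_avc_length,
            "analytic_convolutedness": self.analytic_convolutedness,
        }


@dataclass
class SyntheticHeart:
    """Everything one synthesized heart produces."""

    nuclear: ImageStack
    membrane: ImageStack
    compartments: LabelVolume
    nuclei_labels: LabelVolume
    membrane_labels: LabelVolume
    truth: GroundTruth
    config: SyntheticConfig

    def write(self, outdir: str | Path) -> None:
        """Persist channels (float32 TIFF), labels (uint16 TIFF), truth JSON/CSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_stack(ImageStack(self.nuclear.data.astype(np.float32), self.nuclear.spacing),
                    outdir / "nuclear.tif")
        write_stack(ImageStack(self.membrane.data.astype(np.float32), self.membrane.spacing),
                    outdir / "membrane.tif")
        for name, vol in (
            ("compartments", self.compartments),
            ("nuclei_labels", self.nuclei_labels),
            ("membrane_labels", self.membrane_labels),
        ):
            write_stack(
                ImageStack(vol.data.astype(np.uint16), vol.spacing),
                outdir / f"{name}.tif",
            )
        (outdir / "ground_truth.json").write_text(
            json.dumps(self.truth.to_json_dict())
        )
        with open(outdir / "true_nuclei.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "z_um", "y_um", "x_um", "volume_um3", "compartment"])
            for i, nuc in enumerate(self.truth.nuclei, start=1):
                z, y, x = nuc.center
                w.writerow([i, z, y, x, nuc.volume, nuc.compartment])


def _orthonormal_frame(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to ``tangent``."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, tangent)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n1 = np.cross(ref, tangent)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(tangent, n1)
    return n1, n2


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _sample_vmf(rng: np.random.Generator, mu: np.ndarray, kappa: float) -> np.ndarray:
    """Draw one unit vector from a von Mises–Fisher distribution on S²."""
    if kappa < 1e-8:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)
    # inversion sampling of the polar angle w = cos(theta)
    u = rng.uniform()
    w = 1.0 + np.log(u + (1.0 - u) * math.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0.0, 2.0 * math.pi)
    n1, n2 = _orthonormal_frame(mu)
    s = math.sqrt(max(0.0, 1.0 - w * w))
    return w * mu + s * (math.cos(phi) * n1 + math.sin(phi) * n2)


def _place_nuclei(
    config: SyntheticConfig, cl: Centerline, rng: np.random.Generator
) -> list[Nucleus]:
    bounds = compartment_boundaries(config, cl.length)
    extent = np.array(
        [(s - 1) * sp for s, sp in zip(config.grid_shape, config.spacing)]
    )
    placed: list[Nucleus] = []
    centers: list[np.ndarray] = []
    max_axes: list[float] = []
    for ci, name in enumerate(COMPARTMENTS):
        count = config.n_nuclei_by_compartment[ci]
        if count == 0:
            continue
        mean_axes = np.asarray(config.nucleus_axes_mean[ci])
        radius = config.tube_radius_by_compartment[ci]
        s_lo, s_hi = bounds[ci], bounds[ci + 1]
        # keep centres inside the compartment's arc-length interval with a
        # small inset so wall-resident cells do not straddle the boundary
        inset = min(max(mean_axes), 0.45 * (s_hi - s_lo))
        budget = 300 * count
        accepted = 0
        while accepted < count and budget > 0:
            budget -= 1
            s = rng.uniform(s_lo + inset, s_hi - inset)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            axes = np.clip(
                rng.normal(mean_axes, config.nucleus_axes_sd), 0.5, None
            )
            tangent = cl.tangent_at(s)
            n1, n2 = _orthonormal_frame(tangent)
            center = cl.point_at(s) + config.wall_fraction * radius * (
                math.cos(phi) * n1 + math.sin(phi) * n2
            )
            amax = float(axes.max())
            pad = amax + 2.0 * max(config.psf_sigma)
            if np.any(center < pad) or np.any(center > extent - pad):
                continue
            if centers:
                gaps = np.linalg.norm(np.asarray(centers) - center, axis=1)
                if np.any(gaps <= amax + np.asarray(max_axes)):
                    continue
            rot = _random_rotation(rng)
            placed.append(
                Nucleus(
                    center=tuple(center),
                    semi_axes=tuple(axes),
                    orientation=rot.tolist(),
                    compartment=name,
                    arclength=float(s),
                )
            )
            centers.append(center)
            max_axes.append(amax)
            accepted += 1
        if accepted < count:
            raise PlacementError(
                f"could not place {count} nuclei in compartment {name!r} "
                f"(placed {accepted}); reduce counts or enlarge the tube"
            )
    return placed


def _render_ellipsoid(
    canvas: np.ndarray, spacing: np.ndarray, nucleus: Nucleus, value
) -> None:
    """Fill the ellipsoid's voxels with ``value`` (in place)."""
    center = np.asarray(nucleus.center)
    axes = np.asarray(nucleus.semi_axes)
    rot = np.asarray(nucleus.orientation)
    amax = axes.max()
    lo = np.maximum(np.floor((center - amax) / spacing).astype(int), 0)
    hi = np.minimum(
        np.ceil((center + amax) / spacing).astype(int) + 1, canvas.shape
    )
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *[np.arange(lo[d], hi[d]) * spacing[d] - center[d] for d in range(3)],
        indexing="ij",
    )
    rel = np.stack(grids, axis=-1)            # (…, 3) offsets in µm
    local = rel @ rot                          # rotate into ellipsoid frame
    inside = np.sum((local / axes) ** 2, axis=-1) <= 1.0
    sub = canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[inside] = value


def synthesize_heart(config: SyntheticConfig) -> SyntheticHeart:
    """Generate one synthetic heart: two channels, three label volumes, truth.

    Deterministic: identical config and seed give bit-identical arrays.
    """
    rng = np.random.default_rng(config.seed)
    cl = make_centerline(config)
    spacing = np.asarray(config.spacing)
    shape = config.grid_shape

    # -- geometry: distance of every voxel to the centerline polyline -------
    idx = np.indices(shape).reshape(3, -1).T
    coords = idx * spacing
    tree = cKDTree(cl.points)
    dist, nearest = tree.query(coords, workers=-1)
    s_vox = cl.arclength[nearest]
    # flat tube ends: drop voxels that project beyond the end tangents, so a
    # straight tube is a true cylinder without spherical caps
    t0 = cl.points[1] - cl.points[0]
    t0 /= np.linalg.norm(t0)
    t1 = cl.points[-1] - cl.points[-2]
    t1 /= np.linalg.norm(t1)
    beyond = np.zeros(len(coords), dtype=bool)
    at_start = nearest == 0
    at_end = nearest == len(cl.points) - 1
    beyond[at_start] = (coords[at_start] - cl.points[0]) @ t0 < 0
    beyond[at_end] = (coords[at_end] - cl.points[-1]) @ t1 > 0
    dist = np.where(beyond, np.inf, dist)
    bounds = compartment_boundaries(config, cl.length)
    comp_idx = np.clip(np.searchsorted(bounds[1:-1], s_vox, side="right"), 0, 4)
    radius_vox = np.asarray(config.tube_radius_by_compartment)[comp_idx]

    lumen = dist <= radius_vox
    compartments = np.where(lumen, comp_idx + 1, 0).astype(np.int32).reshape(shape)
    shell = np.abs(dist - radius_vox) <= 0.5 * config.membrane_thickness
    membrane_labels = np.where(shell, comp_idx + 1, 0).astype(np.int32).reshape(shape)
    membrane_img = (
        np.where(
            shell,
            np.asarray(config.membrane_intensity_by_compartment)[comp_idx],
            0.0,
        )
        .astype(np.float64)
        .reshape(shape)
    )

    # -- nuclei -------------------------------------------------------------
    nuclei = _place_nuclei(config, cl, rng)
    nuclei_labels = np.zeros(shape, dtype=np.int32)
    nuclear_img = np.zeros(shape, dtype=np.float64)
    for i, nuc in enumerate(nuclei, start=1):
        _render_ellipsoid(nuclei_labels, spacing, nuc, i)
        _render_ellipsoid(nuclear_img, spacing, nuc, config.nucleus_intensity)

    # -- Golgi offsets for polarity ----------------------------------------
    if config.golgi_axis is not None:
        mu = np.asarray(config.golgi_axis, dtype=float)
    else:
        mu = cl.inflow_point - cl.outflow_point
    mu = mu / np.linalg.norm(mu)
    offsets = np.array(
        [
            _sample_vmf(rng, mu, config.golgi_kappa) * config.golgi_distance
            for _ in nuclei
        ]
    ).reshape(len(nuclei), 3)

    # -- optics and noise ---------------------------------------------------
    sigma_vox = np.asarray(config.psf_sigma) / spacing
    if np.any(sigma_vox > 0):
        nuclear_img = ndimage.gaussian_filter(nuclear_img, sigma_vox)
        membrane_img = ndimage.gaussian_filter(membrane_img, sigma_vox)
    for img in (nuclear_img, membrane_img):
        if config.poisson_scale > 0:
            img[:] = rng.poisson(img * config.poisson_scale) / config.poisson_scale
        if config.gaussian_sd > 0:
            img += rng.normal(0.0, config.gaussian_sd, size=img.shape)

    intervals = {
        name: (float(bounds[i]), float(bounds[i + 1]))
        for i, name in enumerate(COMPARTMENTS)
    }
    avc_lo, avc_hi = intervals["AVC"]
    analytic_avc = float(
        np.linalg.norm(cl.point_at(avc_hi) - cl.point_at(avc_lo))
    )
    chord = float(np.linalg.norm(cl.outflow_point - cl.inflow_point))
    truth = GroundTruth(
        centerline=cl,
        compartment_intervals=intervals,
        nuclei=nuclei,
        golgi_offsets=offsets,
        inflow_point=cl.inflow_point.copy(),
        outflow_point=cl.outflow_point.copy(),
        analytic_avc_length=analytic_avc,
        analytic_convolutedness=cl.length / chord if chord > 0 else float("inf"),
    )
    sp = tuple(config.spacing)
    return SyntheticHeart(
        nuclear=ImageStack(nuclear_img, sp),
        membrane=ImageStack(membrane_img, sp),
        compartments=LabelVolume(compartments, sp),
        nuclei_labels=LabelVolume(nuclei_labels, sp),
        membrane_labels=LabelVolume(membrane_labels, sp),
        truth=truth,
        config=config,
    )
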
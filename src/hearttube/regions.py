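"""Compartment assignment, control normalization, polarity calls, group tests."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .image import LabelVolume
from .segmentation import NucleusRecord
from .synthetic import Centerline

__all__ = [
    "PolarityCall",
    "GroupComparisonResult",
    "CenterlineMap",
    "assign_compartment",
    "normalize_volumes",
    "classify_polarity",
    "run_group_test",
    "mann_whitney_exact",
]


@dataclass(frozen=True)
class PolarityCall:
    """Nucleus→Golgi orientation relative to the inflow-directed axis."""

    nucleus_id: int
    angle: float                    # degrees in [0, 180]
    call: str                       # inflow | outflow | unpolarized


@dataclass
class GroupComparisonResult:
    test: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    normalization_reference: str | None = None


@dataclass
class CenterlineMap:
    """Arc-length lookup along a centerline plus compartment intervals."""

    centerline: Centerline
    compartment_intervals: dict      # name -> (s_lo, s_hi) µm

    def compartment_at(self, point) -> tuple[str, float]:
        """Nearest-centerline compartment and distance (µm) for one point."""
        d = np.linalg.norm(self.centerline.points - np.asarray(point), axis=1)
        i = int(np.argmin(d))
        s = self.centerline.arclength[i]
        for name, (lo, hi) in self.compartment_intervals.items():
            if lo <= s <= hi:
                return name, float(d[i])
        return "unassigned", float(d[i])


def assign_compartment(
    nuclei: list[NucleusRecord],
    compartments: LabelVolume,
    centerline_map: CenterlineMap,
    max_lumen_distance: float = 20.0,
) -> list[NucleusRecord]:
    """Assign each nucleus the compartment of its nearest arc-length position.

    Nuclei whose centroid lies farther than ``max_lumen_distance`` µm from
    the lumen (distance taken to the labelled lumen surface) are left
    ``unassigned``.  Records are updated in place and returned.
    """
    if not np.any(compartments.data > 0):
        raise ValueError("compartment volume is empty")
    # distance from every voxel to the lumen, in physical units
    outside = compartments.data == 0
    dist_to_lumen = ndimage.distance_transform_edt(
        outside, sampling=compartments.spacing
    )
    shape = np.asarray(compartments.shape)
    for rec in nuclei:
        vox = np.clip(
            np.round(np.asarray(rec.centroid) / np.asarray(compartments.spacing)),
            0, shape - 1,
        ).astype(int)
        if dist_to_lumen[tuple(vox)] > max_lumen_distance:
            rec.compartment = "unassigned"
            continue
        name, _ = centerline_map.compartment_at(rec.centroid)
        rec.compartment = name
    return nuclei


def normalize_volumes(
    records: list[NucleusRecord],
    reference_group: str,
    reference_compartment: str = "AVC",
) -> np.ndarray:
    """Divide every volume by the mean volume of the reference subset.

    The reference subset is the given group restricted to the given
    compartment; its normalized mean is exactly 1.
    """
    ref = [
        r.volume
        for r in records
        if r.group == reference_group and r.compartment == reference_compartment
    ]
    if not ref:
        raise ValueError(
            f"empty reference subset (group={reference_group!r}, "
            f"compartment={reference_compartment!r})"
        )
    mean = float(np.mean(ref))
    return np.array([r.volume / mean for r in records])


def classify_polarity(
    nucleus_centroid,
    golgi_centroid,
    inflow_axis,
    cone_half_angle: float = 60.0,
    nucleus_id: int = 0,
) -> PolarityCall:
    """Angle between the nucleus→Golgi vector and the inflow-directed axis.

    ``inflow`` if the angle is within the cone, ``outflow`` if within the
    opposite cone, else ``unpolarized``.
    """
    axis = np.asarray(inflow_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("inflow axis must be nonzero")
    offset = np.asarray(golgi_centroid, dtype=float) - np.asarray(
        nucleus_centroid, dtype=float
    )
    olen = np.linalg.norm(offset)
    if olen < 1e-12:
        warnings.warn("zero-length Golgi offset; calling unpolarized", stacklevel=2)
        return PolarityCall(nucleus_id=nucleus_id, angle=90.0, call="unpolarized")
    cosang = float(np.clip(np.dot(offset, axis) / (olen * norm), -1.0, 1.0))
    angle = math.degrees(math.acos(cosang))
    if angle <= cone_half_angle:
        call = "inflow"
    elif angle >= 180.0 - cone_half_angle:
        call = "outflow"
    else:
        call = "unpolarized"
    return PolarityCall(nucleus_id=nucleus_id, angle=angle, call=call)


_COMBINATION_CACHE: dict = {}


def _all_labelings(n1: int, n: int) -> np.ndarray:
    """All C(n, n1) index choices for the first sample, cached per shape."""
    from itertools import combinations

    key = (n1, n)
    if key not in _COMBINATION_CACHE:
        _COMBINATION_CACHE[key] = np.array(
            list(combinations(range(n), n1)), dtype=np.intp
        )
    return _COMBINATION_CACHE[key]


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney U by full enumeration of the null.

    Feasible for small samples only (used when both n ≤ 8); ties handled by
    midranks with the permutation null computed on the observed ranks.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    # distance of U from its null mean is the two-sided ordering statistic
    mu = n1 * n2 / 2.0
    obs = abs(u1 - mu)
    combos = _all_labelings(n1, n1 + n2)
    u_null = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2.0
    p = np.mean(np.abs(u_null - mu) >= obs - 1e-12)
    return float(u1), float(p)


def run_group_test(
    values_by_group: dict,
    test: str,
    normalization_reference: str | None = None,
) -> GroupComparisonResult:
    """Run one of the supported two-sided group tests.

    ``mann_whitney`` uses the exact permutation null when both samples have
    n ≤ 8, otherwise the tie-corrected normal approximation with continuity
    correction.  ``t_test`` is the unpaired two-sample t test and
    ``kruskal_wallis`` the k-sample rank test.
    """
    supported = ("mann_whitney", "t_test", "kruskal_wallis")
    if test not in supported:
        raise ValueError(f"unsupported test {test!r}; supported: {supported}")
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    sizes = tuple(len(v) for v in groups.values())
    if any(n < 2 for n in sizes):
        raise ValueError(f"every group needs ≥2 values, got sizes {sizes}")
    vals = list(groups.values())
    if test == "kruskal_wallis":
        if len(vals) < 2:
            raise ValueError("kruskal_wallis needs ≥2 groups")
        stat, p = stats.kruskal(*vals)
    else:
        if len(vals) != 2:
            raise ValueError(f"{test} requires exactly 2 groups, got {len(vals)}")
        a, b = vals
        if test == "t_test":
            stat, p = stats.ttest_ind(a, b)
        else:
            if len(a) <= 8 and len(b) <= 8:
                stat, p = mann_whitney_exact(a, b)
            else:
                res = stats.mannwhitneyu(
                    a, b, alternative="two-sided",
                    method="asymptotic", use_continuity=True,
                )
                stat, p = res.statistic, res.pvalue
    return GroupComparisonResult(
        test=test,
        statistic=float(stat),
        p_value=float(min(p, 1.0)),
        group_sizes=sizes,
        normalization_reference=normalization_reference,
    )
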
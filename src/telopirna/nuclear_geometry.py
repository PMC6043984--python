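"""3D quantification of FISH-spot position and colocalization.

Works on confocal z-stacks with anisotropic voxels (the slice step dz is
typically much larger than the in-plane pixel size).  The measurements are:

* nucleus segmentation (supplied mask, or fixed/Otsu threshold on the DAPI
  channel with largest-component selection and hole filling);
* spot segmentation as 26-connected components above a threshold;
* intensity-weighted center of mass in physical coordinates;
* "growing sphere" distance from a cluster center to the nuclear surface —
  the radius at which a sphere centered on the point first touches the
  surface, i.e. exactly the minimal point-to-surface-voxel distance;
* cluster diameter in the XY plane at the z-slice of the center of mass;
* spot-vs-spot / spot-vs-mask colocalization fractions;
* an independent two-sample t test between genotype groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .seq_io import InputError

__all__ = [
    "VolumeImage",
    "NucleusMask",
    "Spot",
    "SpotSet",
    "ClusterMeasure",
    "segment_nucleus",
    "segment_channel",
    "center_of_mass",
    "distance_to_surface",
    "cluster_diameter",
    "measure_cluster",
    "colocalization_fraction",
    "two_sample_t",
]

#: Axial slice step of the modelled confocal stacks, µm.
DEFAULT_DZ = 1.05

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


@dataclass
class VolumeImage:
    """One channel of a z-stack; ``data`` is indexed (z, y, x)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]  # (dz, dy, dx) in µm
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise InputError("VolumeImage requires a 3D (z, y, x) array")
        if any(v <= 0 for v in self.voxel_size):
            raise InputError("voxel dimensions must be positive")


def _voxel_centers_um(indices: np.ndarray, voxel_size) -> np.ndarray:
    """Physical coordinates of voxel centers: (index + 0.5) * spacing."""
    return (np.asarray(indices, dtype=float) + 0.5) * np.asarray(voxel_size)


@dataclass
class NucleusMask:
    mask: np.ndarray  # bool (z, y, x)
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise InputError("empty nucleus mask")

    @property
    def surface(self) -> np.ndarray:
        """Boolean mask of surface voxels: mask voxels with a 6-neighbor outside."""
        eroded = ndimage.binary_erosion(self.mask, structure=_SIX_CONN, border_value=0)
        return self.mask & ~eroded

    def contains_point(self, point_um: Sequence[float]) -> bool:
        idx = tuple(int(p // v) for p, v in zip(point_um, self.voxel_size))
        if any(i < 0 or i >= s for i, s in zip(idx, self.mask.shape)):
            return False
        return bool(self.mask[idx])


@dataclass(frozen=True)
class Spot:
    label: int
    voxels: np.ndarray  # (n, 3) integer indices
    centroid_um: tuple[float, float, float]  # intensity-weighted
    total_intensity: float
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])


@dataclass
class SpotSet:
    spots: list[Spot]
    labels: np.ndarray  # labelled volume, 0 = background
    voxel_size: tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.spots)


def _threshold(data: np.ndarray, method: str, value: float | None) -> float:
    if method == "fixed":
        if value is None:
            raise InputError("fixed threshold requires a value")
        return float(value)
    if method == "otsu":
        if np.ptp(data) == 0:
            return float(data.max())  # flat image: nothing above threshold
        return float(threshold_otsu(data))
    raise InputError(f"unknown threshold method {method!r}")


def segment_nucleus(
    volume: VolumeImage,
    threshold_method: Literal["fixed", "otsu"] = "otsu",
    threshold: float | None = None,
    fill_holes: bool = True,
    largest_component: bool = True,
) -> NucleusMask:
    """Threshold the DAPI channel into a single nucleus mask.

    This replaces the manual segmentation step of interactive software so
    the pipeline can run unattended; a pre-made mask can be supplied by
    constructing :class:`NucleusMask` directly.
    """
    t = _threshold(volume.data, threshold_method, threshold)
    mask = volume.data > t
    if not mask.any():
        raise InputError("nucleus threshold leaves an empty mask")
    if largest_component:
        lab = cc_label(mask, connectivity=3)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        mask = lab == int(np.argmax(sizes))
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return NucleusMask(mask=mask, voxel_size=volume.voxel_size)


def segment_channel(
    volume: VolumeImage,
    threshold_method: Literal["fixed", "otsu"] = "fixed",
    threshold: float | None = None,
    min_voxels: int = 1,
) -> SpotSet:
    """26-connected components above threshold, small components removed.

    Labels follow array scan order, so segmentation is deterministic.  An
    all-background volume yields an empty SpotSet.
    """
    if min_voxels < 1:
        raise InputError("min_voxels must be >= 1")
    t = _threshold(volume.data, threshold_method, threshold)
    binary = volume.data > t
    lab = cc_label(binary, connectivity=3)
    spots: list[Spot] = []
    out_labels = np.zeros_like(lab)
    next_label = 0
    for region_label in range(1, int(lab.max()) + 1):
        voxels = np.argwhere(lab == region_label)
        if voxels.shape[0] < min_voxels:
            continue
        next_label += 1
        out_labels[tuple(voxels.T)] = next_label
        weights = volume.data[tuple(voxels.T)]
        total = float(weights.sum())
        centers = _voxel_centers_um(voxels, volume.voxel_size)
        centroid = tuple(np.average(centers, axis=0, weights=weights))
        bbox = tuple(
            (int(voxels[:, ax].min()), int(voxels[:, ax].max()) + 1) for ax in range(3)
        )
        spots.append(
            Spot(
                label=next_label,
                voxels=voxels,
                centroid_um=centroid,  # type: ignore[arg-type]
                total_intensity=total,
                bbox=bbox,  # type: ignore[arg-type]
            )
        )
    return SpotSet(spots=spots, labels=out_labels, voxel_size=volume.voxel_size)


def center_of_mass(
    voxels: np.ndarray,
    volume: VolumeImage,
    weighted: bool = True,
) -> tuple[float, float, float] | None:
    """Center of mass of a voxel set in physical coordinates.

    Intensity-weighted by default ("center of homogeneous mass"); with
    ``weighted=False`` every voxel counts equally.  Returns None when the
    total weight is zero.
    """
    voxels = np.asarray(voxels)
    if voxels.size == 0:
        raise InputError("empty voxel set")
    weights = volume.data[tuple(voxels.T)] if weighted else np.ones(len(voxels))
    if weights.sum() == 0:
        return None
    centers = _voxel_centers_um(voxels, volume.voxel_size)
    return tuple(np.average(centers, axis=0, weights=weights))


def distance_to_surface(
    point_um: Sequence[float],
    nucleus: NucleusMask,
) -> float:
    """Growing-sphere distance from a point to the nuclear surface, µm.

    Equals the minimum Euclidean distance (anisotropic physical
    coordinates) from the point to any surface-voxel center: a sphere grown
    from the point first touches the surface at exactly that radius.
    Negative return value flags a point outside the nucleus mask (its
    magnitude is still the distance to the surface).
    """
    surface_idx = np.argwhere(nucleus.surface)
    if surface_idx.size == 0:
        raise InputError("nucleus mask has no surface voxels")
    centers = _voxel_centers_um(surface_idx, nucleus.voxel_size)
    d = float(np.sqrt(((centers - np.asarray(point_um, float)) ** 2).sum(axis=1)).min())
    return d if nucleus.contains_point(point_um) else -d


def cluster_diameter(
    spots: Sequence[Spot],
    center_um: Sequence[float],
    voxel_size: tuple[float, float, float],
) -> float:
    """Diameter of the XY circle around ``center`` encompassing all member
    voxels in the z-slice nearest the center of mass.

    Floored at one XY voxel diagonal when member voxels exist in that
    slice; 0 (flagged condition) when none do.
    """
    if not spots:
        raise InputError("cluster_diameter requires at least one spot")
    dz, dy, dx = voxel_size
    z_slice = int(center_um[0] / dz)  # slice whose center is nearest
    z_slice = int(np.clip(z_slice, 0, max(s.voxels[:, 0].max() for s in spots)))
    max_r = -1.0
    for spot in spots:
        sel = spot.voxels[spot.voxels[:, 0] == z_slice]
        if sel.size == 0:
            continue
        yx = _voxel_centers_um(sel[:, 1:], (dy, dx))
        r = np.sqrt(((yx - np.asarray(center_um[1:], float)) ** 2).sum(axis=1)).max()
        max_r = max(max_r, float(r))
    if max_r < 0:
        return 0.0
    return max(2 * max_r, math.hypot(dx, dy))


@dataclass
class ClusterMeasure:
    nucleus_id: str
    center_um: tuple[float, float, float]
    cluster_diameter_um: float
    distance_um: float


def measure_cluster(
    nucleus_id: str,
    spot_volume: VolumeImage,
    nucleus: NucleusMask,
    spot_set: SpotSet | None = None,
    threshold_method: Literal["fixed", "otsu"] = "otsu",
    threshold: float | None = None,
    min_voxels: int = 1,
) -> ClusterMeasure | None:
    """Segment the FISH channel (unless given) and measure the main cluster.

    The "main cluster" is the full set of detected spots, centered at their
    joint intensity-weighted center of mass; returns None if no spot is
    found.
    """
    if spot_set is None:
        spot_set = segment_channel(spot_volume, threshold_method, threshold, min_voxels)
    if not spot_set.spots:
        return None
    all_voxels = np.vstack([s.voxels for s in spot_set.spots])
    center = center_of_mass(all_voxels, spot_volume)
    if center is None:
        return None
    return ClusterMeasure(
        nucleus_id=nucleus_id,
        center_um=center,
        cluster_diameter_um=cluster_diameter(
            spot_set.spots, center, spot_volume.voxel_size
        ),
        distance_um=distance_to_surface(center, nucleus),
    )


def colocalization_fraction(
    spots_a: SpotSet,
    b: SpotSet | np.ndarray,
    min_shared_voxels: int = 1,
) -> dict:
    """Fraction of A spots sharing >= ``min_shared_voxels`` voxels with B.

    B may be a SpotSet or a boolean mask on the same grid.  Deliberately
    asymmetric in A and B: "70% of FISH spots colocalize with protein foci"
    and the converse are different statements.  Empty A reports NA.
    """
    mask_b = b if isinstance(b, np.ndarray) else (b.labels > 0)
    mask_b = np.asarray(mask_b, dtype=bool)
    if not spots_a.spots:
        return {"n_coloc": 0, "n_total": 0, "fraction": None}
    if mask_b.shape != spots_a.labels.shape:
        raise InputError("colocalization requires a common voxel grid")
    n_coloc = sum(
        1
        for s in spots_a.spots
        if int(mask_b[tuple(s.voxels.T)].sum()) >= min_shared_voxels
    )
    return {
        "n_coloc": n_coloc,
        "n_total": len(spots_a.spots),
        "fraction": n_coloc / len(spots_a.spots),
    }


def two_sample_t(
    group1: Sequence[float],
    group2: Sequence[float],
    variant: Literal["student", "welch"] = "welch",
) -> dict:
    """Independent two-sample t test (two-sided); Welch by default."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2 or not (np.isfinite(g1).all() and np.isfinite(g2).all()):
        raise InputError("two_sample_t needs >= 2 finite values per group")
    if g1.var(ddof=1) == 0 and g2.var(ddof=1) == 0:
        return {"t": None, "dof": None, "p": None, "degenerate": True}
    res = stats.ttest_ind(g1, g2, equal_var=(variant == "student"))
    return {
        "t": float(res.statistic),
        "dof": float(res.df),
        "p": float(res.pvalue),
        "degenerate": False,
    }
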
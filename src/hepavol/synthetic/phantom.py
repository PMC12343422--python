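"""Synthetic liver phantoms with branching two-system hepatic vasculature.

A phantom is an ellipsoidal liver (plus a disjoint spleen) containing two
recursively bifurcating vascular trees — an intrahepatic portal tree
entering at a hilum surrogate and a hepatic-vein tree draining to an IVC
surrogate, whose root trunk stands in for the intrahepatic inferior vena
cava. Tree radii are calibrated so each system's rasterised volume hits a
target fraction of total liver volume, which makes the phantoms usable as
ground truth for vessel-to-volume ratio (VVR) recovery tests at
group-specific vessel-volume levels.

The intensity model emulates a portal-venous-phase T1-like contrast
ordering (vessels brighter than parenchyma brighter than background) with
optional low-frequency multiplicative shading and additive Gaussian noise;
no MRI physics is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..io import ImageVolume
from ..volumetry import (
    LABEL_HEPATIC,
    LABEL_LIVER,
    LABEL_PORTAL,
    LABEL_SPLEEN,
    VVRResult,
    vessel_to_volume_ratios,
)


class InvalidGeometryError(ValueError):
    """Tree root or segment placed outside the admissible geometry."""


class VesselTargetShortfall(RuntimeError):
    """The requested vessel-volume fraction could not be reached."""

    def __init__(self, target: float, achieved: float):
        self.target = target
        self.achieved = achieved
        super().__init__(
            f"vessel volume fraction shortfall: target {target:.4f}, achieved {achieved:.4f}"
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Construction targets for one synthetic liver phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 3.0)
    liver_axes_mm: tuple[float, float, float] = (65.0, 55.0, 60.0)
    spleen_axes_mm: tuple[float, float, float] = (25.0, 18.0, 30.0)
    target_hvvr_pct: float = 2.1
    target_pvvr_pct: float = 1.7
    noise_sigma: float = 0.02
    bias_field_amplitude: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if any(int(n) < 16 for n in self.grid_shape):
            raise ValueError("grid_shape must be >= 16 per axis")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        total = self.target_hvvr_pct + self.target_pvvr_pct
        if not 0.0 < total < 50.0:
            raise ValueError("target HVVR + PVVR must lie in (0, 50) percent")


@dataclass(frozen=True)
class VesselSegment:
    start_mm: np.ndarray
    end_mm: np.ndarray
    radius_mm: float
    parent: int | None  # index into the tree's segment list

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(self.end_mm - self.start_mm))


@dataclass
class VesselTree:
    """A bifurcating tree of tapering cylindrical segments."""

    segments: list[VesselSegment]
    system: str  # "portal" or "hepatic"
    root_point_mm: np.ndarray

    def scaled_radii(self, factor: float) -> "VesselTree":
        segs = [
            VesselSegment(s.start_mm, s.end_mm, s.radius_mm * factor, s.parent)
            for s in self.segments
        ]
        return VesselTree(segments=segs, system=self.system, root_point_mm=self.root_point_mm)

    def analytic_volume_mm3(self) -> float:
        return float(sum(np.pi * s.radius_mm**2 * s.length_mm for s in self.segments))


@dataclass(frozen=True)
class BranchParams:
    """Bifurcation geometry controls for tree growth."""

    max_depth: int = 6
    taper: tuple[float, float] = (0.68, 0.8)  # child/parent radius ratio range
    branch_angle_deg: tuple[float, float] = (25.0, 50.0)
    length_per_radius: float = 7.0  # segment length ~ this x radius
    min_radius_mm: float = 0.5
    trunk_radius_mm: float = 5.0  # pre-calibration starting radius


def _point_in_mask(point_mm: np.ndarray, mask: np.ndarray, spacing: np.ndarray) -> bool:
    idx = np.round(point_mm / spacing).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(mask.shape)):
        return False
    return bool(mask[tuple(idx)])


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _rotate_towards(direction: np.ndarray, angle_rad: float, azimuth_rad: float) -> np.ndarray:
    """Deflect ``direction`` by ``angle_rad`` at the given azimuth."""
    d = _unit(direction)
    # build an orthonormal frame around d
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(d, helper))
    w = np.cross(d, u)
    return _unit(
        np.cos(angle_rad) * d
        + np.sin(angle_rad) * (np.cos(azimuth_rad) * u + np.sin(azimuth_rad) * w)
    )


def grow_vascular_tree(
    liver_mask: np.ndarray,
    spacing_mm: tuple[float, float, float],
    system: str,
    target_fraction: float,
    branch_params: BranchParams | None = None,
    rng_seed: int = 0,
    root_point_mm: np.ndarray | None = None,
) -> VesselTree:
    """Grow a bifurcating tree inside the liver mask.

    The tree is grown recursively with tapering radii and then radius-scaled
    analytically so its cylinder volume matches ``target_fraction`` of the
    liver volume (rasterisation-level calibration happens in
    :func:`make_liver_phantom`). Deterministic for a fixed seed.
    """
    if system not in ("portal", "hepatic"):
        raise ValueError(f"unknown vessel system: {system}")
    if not 0.0 < target_fraction < 0.5:
        raise ValueError("target_fraction must lie in (0, 0.5)")
    mask = np.asarray(liver_mask).astype(bool)
    if not mask.any():
        raise InvalidGeometryError("liver mask is empty")
    params = branch_params or BranchParams()
    spacing = np.asarray(spacing_mm, dtype=float)
    rng = np.random.default_rng(rng_seed)

    idx = np.argwhere(mask)
    centroid_mm = idx.mean(axis=0) * spacing
    if root_point_mm is None:
        # hilum surrogate at the low end of axis 1 (portal), IVC surrogate at
        # the high end of axis 2 (hepatic): extreme mask voxel along that axis
        axis, side = (1, 0) if system == "portal" else (2, 1)
        coords = idx[:, axis]
        extreme = coords.min() if side == 0 else coords.max()
        candidates = idx[coords == extreme]
        root_idx = candidates[len(candidates) // 2]
        root = root_idx * spacing
    else:
        root = np.asarray(root_point_mm, dtype=float)
        if not _point_in_mask(root, mask, spacing):
            raise InvalidGeometryError(f"root point {root} lies outside the liver mask")

    segments: list[VesselSegment] = []

    def endpoint_ok(start: np.ndarray, end: np.ndarray) -> bool:
        mid = 0.5 * (start + end)
        return _point_in_mask(mid, mask, spacing) and _point_in_mask(end, mask, spacing)

    # branches thinner than the rasterisation floor (half the smallest
    # voxel spacing) would be inflated to the floor anyway; stop there so
    # coarse grids do not accumulate un-shrinkable vessel volume
    min_radius = max(params.min_radius_mm, 0.5 * float(spacing.min()))

    def grow(start: np.ndarray, direction: np.ndarray, radius: float, depth: int, parent: int | None):
        if depth > params.max_depth or radius < min_radius:
            return
        length = params.length_per_radius * radius * float(rng.uniform(0.8, 1.2))
        d = _unit(direction)
        end = start + d * length
        tries = 0
        while not endpoint_ok(start, end) and tries < 8:
            # bend toward the centroid and shorten until we stay inside
            d = _unit(0.5 * d + 0.5 * _unit(centroid_mm - start))
            length *= 0.7
            end = start + d * length
            tries += 1
        if not endpoint_ok(start, end):
            return
        segments.append(VesselSegment(start.copy(), end.copy(), radius, parent))
        seg_index = len(segments) - 1
        n_children = 2
        azim0 = float(rng.uniform(0, 2 * np.pi))
        for c in range(n_children):
            taper = float(rng.uniform(*params.taper))
            angle = np.deg2rad(float(rng.uniform(*params.branch_angle_deg)))
            azim = azim0 + c * np.pi + float(rng.uniform(-0.5, 0.5))
            child_dir = _rotate_towards(d, angle, azim)
            grow(end, child_dir, radius * taper, depth + 1, seg_index)

    initial_dir = _unit(centroid_mm - root)
    grow(root, initial_dir, params.trunk_radius_mm, 0, None)
    if not segments:
        raise VesselTargetShortfall(target_fraction, 0.0)

    liver_volume_mm3 = float(mask.sum()) * float(np.prod(spacing))
    tree = VesselTree(segments=segments, system=system, root_point_mm=root)
    analytic = tree.analytic_volume_mm3()
    scale = float(np.sqrt(target_fraction * liver_volume_mm3 / analytic))
    max_scale = 12.0 / params.trunk_radius_mm  # keep the trunk anatomically plausible
    if scale > max_scale:
        achieved = analytic * max_scale**2 / liver_volume_mm3
        raise VesselTargetShortfall(target_fraction, achieved)
    return tree.scaled_radii(scale)


def rasterize_tree(
    tree: VesselTree,
    grid_shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
) -> np.ndarray:
    """Rasterise a tree onto a voxel grid.

    A voxel is foreground iff its centre lies within the segment radius of
    any segment axis, with distances in mm honouring anisotropic spacing.
    Sub-voxel branches are kept by flooring the effective radius at half
    the smallest voxel spacing (thin-vessel guarantee). An empty tree gives
    an all-background grid.
    """
    spacing = np.asarray(spacing_mm, dtype=float)
    out = np.zeros(grid_shape, dtype=bool)
    half_min = 0.5 * float(spacing.min())
    shape = np.asarray(grid_shape)
    for seg in tree.segments:
        eff_radius = max(seg.radius_mm, half_min)
        lo_mm = np.minimum(seg.start_mm, seg.end_mm) - eff_radius
        hi_mm = np.maximum(seg.start_mm, seg.end_mm) + eff_radius
        lo = np.maximum(np.floor(lo_mm / spacing).astype(int), 0)
        hi = np.minimum(np.ceil(hi_mm / spacing).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        axes = [np.arange(lo[i], hi[i]) * spacing[i] for i in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1)
        a, b = seg.start_mm, seg.end_mm
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            dist = np.linalg.norm(pts - a, axis=-1)
        else:
            t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
            proj = a + t[..., None] * ab
            dist = np.linalg.norm(pts - proj, axis=-1)
        sub = dist <= eff_radius
        out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= sub
    return out


def _ellipsoid_mask(
    grid_shape: tuple[int, int, int],
    spacing: np.ndarray,
    center_mm: np.ndarray,
    axes_mm: np.ndarray,
) -> np.ndarray:
    coords = [np.arange(n) * spacing[i] for i, n in enumerate(grid_shape)]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    return (
        ((gx - center_mm[0]) / axes_mm[0]) ** 2
        + ((gy - center_mm[1]) / axes_mm[1]) ** 2
        + ((gz - center_mm[2]) / axes_mm[2]) ** 2
    ) <= 1.0


def _bias_field(grid_shape, spacing, amplitude, rng) -> np.ndarray:
    """Low-order multiplicative shading: product of smooth cosine modes."""
    if amplitude == 0:
        return np.ones(grid_shape)
    coords = [np.linspace(0, 1, n) for n in grid_shape]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    phase = rng.uniform(0, 2 * np.pi, size=3)
    smooth = (
        np.cos(np.pi * gx + phase[0])
        * np.cos(np.pi * gy + phase[1])
        * np.cos(np.pi * gz + phase[2])
    )
    return 1.0 + amplitude * smooth


#: noise-free plateau intensities of each tissue class (arbitrary units);
#: vessels > parenchyma > background, emulating portal-venous contrast
INTENSITY = {
    "background": 0.05,
    "spleen": 0.40,
    "parenchyma": 0.55,
    "vessel": 0.95,
}

_CALIBRATION_MAX_ITER = 10
_CALIBRATION_RTOL = 0.03


def _prune_smallest_leaves(tree: VesselTree, fraction: float = 0.25) -> VesselTree | None:
    """Drop the thinnest quarter of leaf segments (re-indexing parents);
    None when the tree cannot shrink further."""
    n = len(tree.segments)
    if n <= 1:
        return None
    parents = {s.parent for s in tree.segments if s.parent is not None}
    leaves = [i for i in range(n) if i not in parents]
    if not leaves:
        return None
    leaves.sort(key=lambda i: tree.segments[i].radius_mm)
    drop = set(leaves[: max(1, int(fraction * len(leaves)))])
    keep = [i for i in range(n) if i not in drop]
    remap = {old: new for new, old in enumerate(keep)}
    segments = [
        VesselSegment(
            tree.segments[i].start_mm,
            tree.segments[i].end_mm,
            tree.segments[i].radius_mm,
            None if tree.segments[i].parent is None else remap[tree.segments[i].parent],
        )
        for i in keep
    ]
    return VesselTree(segments=segments, system=tree.system, root_point_mm=tree.root_point_mm)


def _calibrated_system_mask(
    tree: VesselTree,
    liver: np.ndarray,
    exclude: np.ndarray,
    target_fraction: float,
    grid_shape,
    spacing_mm,
) -> tuple[np.ndarray, VesselTree]:
    """Scale tree radii until the rasterised in-liver volume (minus voxels
    already claimed by the other system) hits the target fraction."""
    liver_vox = int(liver.sum())
    current = tree
    best = None
    prev_achieved = None
    for _ in range(_CALIBRATION_MAX_ITER):
        raster = rasterize_tree(current, grid_shape, spacing_mm) & liver & ~exclude
        achieved = raster.sum() / liver_vox
        rel_err = abs(achieved - target_fraction) / target_fraction
        if best is None or rel_err < best[0]:
            best = (rel_err, raster, current)
        if rel_err <= _CALIBRATION_RTOL:
            break
        if achieved == 0:
            raise VesselTargetShortfall(target_fraction, 0.0)
        stuck = (
            achieved > target_fraction
            and prev_achieved is not None
            and abs(achieved - prev_achieved) < 0.02 * target_fraction
        )
        prev_achieved = achieved
        if stuck:
            # radius scaling has saturated against the rasterisation
            # floor; shed the thinnest leaves instead
            pruned = _prune_smallest_leaves(current)
            if pruned is None:
                break
            current = pruned
            prev_achieved = None
        else:
            current = current.scaled_radii(float(np.sqrt(target_fraction / achieved)))
    rel_err, raster, tree_out = best
    if rel_err > 0.10:
        raise VesselTargetShortfall(target_fraction, raster.sum() / liver_vox)
    return raster, tree_out


def make_liver_phantom(
    spec: PhantomSpec,
    branch_params: BranchParams | None = None,
) -> tuple[ImageVolume, np.ndarray, VVRResult]:
    """Build one phantom: intensity volume, label map, and its ground-truth
    VVRs.

    The returned ground truth is computed from the emitted label map by
    :func:`hepavol.volumetry.vessel_to_volume_ratios` — not from the
    analytic tree — so ground truth and downstream metrics share a single
    voxel-counting convention.
    """
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    shape = tuple(int(n) for n in spec.grid_shape)
    extent_mm = np.asarray(shape) * spacing
    rng = np.random.default_rng(spec.seed)

    liver_center = extent_mm * np.array([0.42, 0.52, 0.5])
    liver = _ellipsoid_mask(shape, spacing, liver_center, np.asarray(spec.liver_axes_mm))
    spleen_center = extent_mm * np.array([0.87, 0.5, 0.35])
    spleen = _ellipsoid_mask(shape, spacing, spleen_center, np.asarray(spec.spleen_axes_mm))
    spleen &= ~liver  # organs must be disjoint
    if not liver.any():
        raise InvalidGeometryError("liver ellipsoid does not intersect the grid")

    portal_tree = grow_vascular_tree(
        liver, spec.spacing_mm, "portal", spec.target_pvvr_pct / 100.0,
        branch_params, rng_seed=int(rng.integers(2**31)),
    )
    portal, portal_tree = _calibrated_system_mask(
        portal_tree, liver, np.zeros(shape, dtype=bool),
        spec.target_pvvr_pct / 100.0, shape, spec.spacing_mm,
    )
    hepatic_tree = grow_vascular_tree(
        liver, spec.spacing_mm, "hepatic", spec.target_hvvr_pct / 100.0,
        branch_params, rng_seed=int(rng.integers(2**31)),
    )
    hepatic, hepatic_tree = _calibrated_system_mask(
        hepatic_tree, liver, portal,
        spec.target_hvvr_pct / 100.0, shape, spec.spacing_mm,
    )

    labels = np.zeros(shape, dtype=np.uint8)
    labels[liver] = LABEL_LIVER
    labels[spleen] = LABEL_SPLEEN
    labels[portal] = LABEL_PORTAL
    labels[hepatic] = LABEL_HEPATIC

    intensity = np.full(shape, INTENSITY["background"], dtype=np.float32)
    intensity[labels == LABEL_LIVER] = INTENSITY["parenchyma"]
    intensity[labels == LABEL_SPLEEN] = INTENSITY["spleen"]
    intensity[(labels == LABEL_PORTAL) | (labels == LABEL_HEPATIC)] = INTENSITY["vessel"]
    intensity = intensity * _bias_field(shape, spacing, spec.bias_field_amplitude, rng)
    if spec.noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sigma, size=shape)
    image = ImageVolume(data=intensity.astype(np.float32), spacing_mm=spec.spacing_mm)
    gt_vvr = vessel_to_volume_ratios(labels, spec.spacing_mm)
    return image, labels, gt_vvr
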
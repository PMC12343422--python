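"""Data augmentation for paired image / label volumes.

Geometric transforms (elastic deformation with spline interpolation of
order 3, random flips, 90-degree rotations, small rotations of +/- 15
degrees) are applied identically to image and label; the label is always
resampled nearest-neighbour so class ids stay intact. Intensity transforms
(random contrast, Gaussian noise, Poisson noise) touch the image only.
90-degree rotations are restricted to axis pairs of equal extent so the
patch shape is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class AugmentationParams:
    elastic: bool = True
    elastic_magnitude_vox: float = 2.0
    elastic_smoothing_vox: float = 8.0
    spline_order: int = 3
    p_elastic: float = 0.3
    flip_axes: tuple[int, ...] = (0, 1, 2)
    p_flip: float = 0.5
    rot90: bool = True
    p_rot90: float = 0.3
    rot_small_deg: float = 15.0
    p_rot_small: float = 0.3
    contrast_range: tuple[float, float] = (0.75, 1.25)
    p_contrast: float = 0.3
    gaussian_noise_sigma: float = 0.03
    p_gaussian_noise: float = 0.3
    poisson_noise: bool = True
    poisson_scale: float = 100.0
    p_poisson_noise: float = 0.2


#: all-off parameter set (identity augmentation)
NO_AUGMENTATION = AugmentationParams(
    elastic=False, p_elastic=0.0, p_flip=0.0, rot90=False, p_rot90=0.0,
    p_rot_small=0.0, p_contrast=0.0, p_gaussian_noise=0.0,
    poisson_noise=False, p_poisson_noise=0.0,
)


def _elastic_displacement(shape, magnitude, smoothing, rng):
    fields = []
    for _ in range(3):
        f = rng.normal(0.0, 1.0, size=shape)
        f = ndimage.gaussian_filter(f, smoothing)
        peak = np.abs(f).max()
        fields.append(f * (magnitude / peak) if peak > 0 else f)
    return fields


def elastic_deform(
    image: np.ndarray,
    label: np.ndarray,
    magnitude_vox: float,
    smoothing_vox: float,
    rng: np.random.Generator,
    spline_order: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Random smooth displacement field applied to image (given spline
    order) and label (nearest-neighbour)."""
    grid = np.meshgrid(*[np.arange(n, dtype=float) for n in image.shape], indexing="ij")
    disp = _elastic_displacement(image.shape, magnitude_vox, smoothing_vox, rng)
    coords = [g + d for g, d in zip(grid, disp)]
    img_out = ndimage.map_coordinates(image, coords, order=spline_order, mode="reflect")
    lab_out = ndimage.map_coordinates(label, coords, order=0, mode="reflect")
    return img_out.astype(image.dtype), lab_out.astype(label.dtype)


def augment(
    image: np.ndarray,
    label: np.ndarray,
    params: AugmentationParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One stochastic augmentation draw; deterministic given the rng state."""
    if image.shape != label.shape:
        raise ValueError(f"image/label shape mismatch: {image.shape} vs {label.shape}")
    image = np.asarray(image, dtype=np.float32)
    label = np.asarray(label)

    for axis in params.flip_axes:
        if rng.random() < params.p_flip:
            image = np.flip(image, axis=axis)
            label = np.flip(label, axis=axis)
    if params.rot90 and rng.random() < params.p_rot90:
        pairs = [
            (a, b)
            for a in range(3)
            for b in range(a + 1, 3)
            if image.shape[a] == image.shape[b]
        ]
        if pairs:
            axes = pairs[int(rng.integers(len(pairs)))]
            k = int(rng.integers(1, 4))
            image = np.rot90(image, k=k, axes=axes)
            label = np.rot90(label, k=k, axes=axes)
    if params.rot_small_deg > 0 and rng.random() < params.p_rot_small:
        angle = float(rng.uniform(-params.rot_small_deg, params.rot_small_deg))
        axes = [(0, 1), (0, 2), (1, 2)][int(rng.integers(3))]
        image = ndimage.rotate(
            image, angle, axes=axes, reshape=False, order=params.spline_order, mode="reflect"
        )
        label = ndimage.rotate(label, angle, axes=axes, reshape=False, order=0, mode="reflect")
    if params.elastic and rng.random() < params.p_elastic:
        image, label = elastic_deform(
            image, label, params.elastic_magnitude_vox, params.elastic_smoothing_vox,
            rng, params.spline_order,
        )

    if rng.random() < params.p_contrast:
        factor = float(rng.uniform(*params.contrast_range))
        mean = float(image.mean())
        image = mean + factor * (image - mean)
    if rng.random() < params.p_gaussian_noise and params.gaussian_noise_sigma > 0:
        image = image + rng.normal(0.0, params.gaussian_noise_sigma, image.shape)
    if params.poisson_noise and rng.random() < params.p_poisson_noise:
        scale = params.poisson_scale
        shifted = np.clip(image - image.min(), 0, None)
        image = image.min() + rng.poisson(shifted * scale) / scale
    return np.ascontiguousarray(image, dtype=np.float32), np.ascontiguousarray(label)
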
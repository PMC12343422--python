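"""Patch grids for patch-based training and sliding-window inference."""

from __future__ import annotations

import numpy as np


def patch_origins(
    volume_shape: tuple[int, int, int],
    patch_size: tuple[int, int, int],
    stride: tuple[int, int, int],
) -> list[tuple[int, int, int]]:
    """Regular grid of patch origins at the given stride.

    The final origin per axis is clamped so the last patch touches the
    volume boundary; a volume no larger than the patch yields the single
    origin (0, 0, 0).
    """
    per_axis = []
    for n, p, s in zip(volume_shape, patch_size, stride):
        if s < 1:
            raise ValueError("stride must be >= 1")
        last = max(n - p, 0)
        axis = list(range(0, last + 1, s))
        if axis[-1] != last:
            axis.append(last)
        per_axis.append(axis)
    return [(i, j, k) for i in per_axis[0] for j in per_axis[1] for k in per_axis[2]]


def pad_to_patch(
    volume: np.ndarray, patch_size: tuple[int, int, int]
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Symmetric zero-padding up to the patch size; returns pad amounts so
    callers can crop predictions back."""
    pads = []
    for n, p in zip(volume.shape, patch_size):
        deficit = max(p - n, 0)
        pads.append((deficit // 2, deficit - deficit // 2))
    if any(lo or hi for lo, hi in pads):
        volume = np.pad(volume, pads)
    return volume, pads


def sample_patches(
    volume_shape: tuple[int, int, int],
    patch_size: tuple[int, int, int],
    stride: tuple[int, int, int],
    n: int = 1,
    foreground: np.ndarray | None = None,
    foreground_bias: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int, int]]:
    """Draw ``n`` patch origins from the stride grid.

    With ``foreground_bias`` > 0 and a foreground mask given, each draw
    picks with that probability among grid origins whose patch contains
    foreground (oversampling vessel-containing patches).
    """
    rng = rng or np.random.default_rng(0)
    grid = patch_origins(volume_shape, patch_size, stride)
    if foreground is not None and foreground_bias > 0:
        fg_grid = [
            o
            for o in grid
            if foreground[
                o[0] : o[0] + patch_size[0],
                o[1] : o[1] + patch_size[1],
                o[2] : o[2] + patch_size[2],
            ].any()
        ]
    else:
        fg_grid = []
    out = []
    for _ in range(n):
        pool = fg_grid if (fg_grid and rng.random() < foreground_bias) else grid
        out.append(pool[int(rng.integers(len(pool)))])
    return out
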
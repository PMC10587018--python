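"""Shared template coordinate frame.

All masks, parcellations and streamlines in this package live on one
axis-aligned voxel grid in a common world (mm) space — a stand-in for a
1 mm isotropic standard template. Voxel ``(i, j, k)`` occupies the
half-open box ``origin + [i, i+1) * spacing`` along each axis, so voxel
centres sit at ``origin + (i + 0.5) * spacing``. The x axis increases
rightward; the interhemispheric midline is a plane of constant x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TemplateSpace", "make_template"]


@dataclass(frozen=True)
class TemplateSpace:
    """An axis-aligned voxel grid with a world-mm frame and a midline.

    Parameters
    ----------
    shape
        Voxel counts per axis (x, y, z); each must be >= 4.
    spacing_mm
        Voxel size per axis in mm; all positive.
    origin_mm
        World coordinate of the corner of voxel (0, 0, 0).
    midline_x_mm
        x world-coordinate of the interhemispheric plane. Defaults to the
        x mid-extent, which splits the grid into two equal halves.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    midline_x_mm: float | None = None

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in np.atleast_1d(self.shape))
        if len(shape) != 3:
            raise ValueError("shape must have three axes")
        if any(s < 4 for s in shape):
            raise ValueError(f"every shape entry must be >= 4, got {shape}")
        spacing = tuple(float(s) for s in np.broadcast_to(self.spacing_mm, (3,)))
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacings must be positive, got {spacing}")
        origin = tuple(float(o) for o in np.broadcast_to(self.origin_mm, (3,)))
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)
        if self.midline_x_mm is None:
            mid = origin[0] + shape[0] * spacing[0] / 2.0
            object.__setattr__(self, "midline_x_mm", float(mid))
        lo = origin[0]
        hi = origin[0] + shape[0] * spacing[0]
        if not (lo < self.midline_x_mm < hi):
            raise ValueError("midline must split the x-extent into two non-empty halves")

    # -- derived geometry -------------------------------------------------

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (maps indices to voxel centres)."""
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = np.asarray(self.origin_mm) + 0.5 * np.asarray(self.spacing_mm)
        return aff

    @property
    def midline_column(self) -> int:
        """First x column at or right of the midline plane.

        For the default mid-extent midline on an even-width grid this is
        ``shape[0] // 2``: columns ``< midline_column`` are the left
        hemisphere, the rest the right hemisphere.
        """
        u = (self.midline_x_mm - self.origin_mm[0]) / self.spacing_mm[0]
        return int(round(u))

    def midline_is_mid_extent(self, tol: float = 1e-9) -> bool:
        mid = self.origin_mm[0] + self.shape[0] * self.spacing_mm[0] / 2.0
        return abs(self.midline_x_mm - mid) <= tol

    # -- coordinate transforms -------------------------------------------

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates of voxel centres for integer indices (…, 3)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin_mm) + (idx + 0.5) * np.asarray(self.spacing_mm)

    def world_to_continuous(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates; voxel i spans [i, i+1)."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Integer voxel indices containing the given world points."""
        return np.floor(self.world_to_continuous(xyz)).astype(np.int64)

    def contains_world(self, xyz: np.ndarray) -> np.ndarray:
        u = self.world_to_continuous(xyz)
        shape = np.asarray(self.shape)
        return np.all((u >= 0) & (u < shape), axis=-1)

    def hemisphere_mask(self, side: str) -> np.ndarray:
        """Boolean grid selecting one hemisphere (by voxel column)."""
        c = self.midline_column
        mask = np.zeros(self.shape, dtype=bool)
        if side == "left":
            mask[:c] = True
        elif side == "right":
            mask[c:] = True
        else:
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        return mask


def make_template(
    shape: tuple[int, int, int] = (40, 48, 40),
    spacing_mm: float | tuple[float, float, float] = 1.0,
    origin_mm: float | tuple[float, float, float] = 0.0,
) -> TemplateSpace:
    """Build a template grid with the midline at the x mid-extent."""
    return TemplateSpace(
        shape=tuple(shape),
        spacing_mm=tuple(np.broadcast_to(spacing_mm, (3,)).astype(float)),
        origin_mm=tuple(np.broadcast_to(origin_mm, (3,)).astype(float)),
    )
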
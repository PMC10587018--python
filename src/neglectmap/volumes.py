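"""Lesion masks and the voxel-level primitives shared by every analysis stage.

Covers mask I/O (NIfTI-1), lesion volumes, group overlays, minimum-coverage
filtering, midline mirroring, and the direct-total-lesion-volume-control
(dTLVC) transform in which each lesioned voxel carries ``1 / sqrt(V)`` with
``V`` the lesion's voxel count, so that every lesion contributes unit
sum-of-squares regardless of its size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .template import TemplateSpace

__all__ = [
    "LesionMask",
    "OverlayMap",
    "IncompatibleGridsError",
    "lesion_volume",
    "overlay",
    "coverage_filter",
    "normalized_subgroup_overlay",
    "mirror_flip",
    "dtlvc_transform",
    "save_volume",
    "load_mask",
    "load_map",
]


class IncompatibleGridsError(ValueError):
    """Inputs do not share one template grid."""


@dataclass(frozen=True)
class LesionMask:
    """A binary lesion mask on a template grid."""

    template: TemplateSpace
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.template.shape:
            raise IncompatibleGridsError(
                f"mask shape {data.shape} != template shape {self.template.shape}"
            )
        if data.dtype != bool:
            uniq = np.unique(data)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be binary")
            data = data.astype(bool)
        object.__setattr__(self, "data", data)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class OverlayMap:
    """Per-voxel count of contributing lesion masks."""

    template: TemplateSpace
    counts: np.ndarray
    n_masks: int


def _require_shared_template(masks: list[LesionMask]) -> TemplateSpace:
    if not masks:
        raise ValueError("need at least one mask")
    t0 = masks[0].template
    for m in masks[1:]:
        if m.template != t0:
            raise IncompatibleGridsError("masks do not share one template")
    return t0


def lesion_volume(mask: LesionMask, unit: str = "voxels") -> float:
    """Lesion size in voxels or cm^3 (count x voxel volume / 1000)."""
    n = mask.n_voxels
    if unit == "voxels":
        return float(n)
    if unit == "cm3":
        return n * mask.template.voxel_volume_mm3 / 1000.0
    raise ValueError(f"unit must be 'voxels' or 'cm3', got {unit!r}")


def overlay(masks: list[LesionMask]) -> OverlayMap:
    """Per-voxel number of lesions overlapping at each voxel."""
    template = _require_shared_template(masks)
    counts = np.zeros(template.shape, dtype=np.int32)
    for m in masks:
        counts += m.data
    return OverlayMap(template=template, counts=counts, n_masks=len(masks))


def coverage_filter(
    overlay_map: OverlayMap, min_patients: int = 10, inclusive: bool = False
) -> np.ndarray:
    """Voxels damaged in more than ``min_patients`` patients (strict ``>``).

    The strict default matches the minimum-overlap rule used for the
    voxel-wise analyses; ``inclusive=True`` gives the ``>=`` variant used
    when describing group coverage maps.
    """
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    if inclusive:
        return overlay_map.counts >= min_patients
    return overlay_map.counts > min_patients


def normalized_subgroup_overlay(masks: list[LesionMask]) -> np.ndarray:
    """Overlay scaled to percent of the sub-group's maximum overlap (max = 100)."""
    ov = overlay(masks)
    peak = int(ov.counts.max())
    if peak == 0:
        raise ValueError("all masks are empty: normalization undefined")
    return ov.counts.astype(np.float64) * (100.0 / peak)


def mirror_flip(obj: LesionMask | OverlayMap | np.ndarray, template: TemplateSpace | None = None):
    """Reflect a mask or map across the interhemispheric midline.

    Operates on voxel columns (x index ``i -> nx - 1 - i``), which is an
    exact reflection about the mid-extent plane and an involution. The
    template's midline must therefore sit at the x mid-extent.
    """
    if isinstance(obj, LesionMask):
        _check_mirrorable(obj.template)
        return LesionMask(template=obj.template, data=np.flip(obj.data, axis=0).copy())
    if isinstance(obj, OverlayMap):
        _check_mirrorable(obj.template)
        return OverlayMap(
            template=obj.template,
            counts=np.flip(obj.counts, axis=0).copy(),
            n_masks=obj.n_masks,
        )
    if template is not None:
        _check_mirrorable(template)
    return np.flip(np.asarray(obj), axis=0).copy()


def _check_mirrorable(template: TemplateSpace) -> None:
    if not template.midline_is_mid_extent():
        raise ValueError("mirroring requires the midline at the x mid-extent")


def dtlvc_transform(mask: LesionMask) -> np.ndarray:
    """Direct total lesion volume control: lesioned voxels carry 1/sqrt(V).

    V is the lesioned voxel count, so the resulting real-valued map has
    unit sum-of-squares for every non-empty mask.
    """
    v = mask.n_voxels
    if v == 0:
        raise ValueError("dTLVC transform undefined for an empty mask")
    out = np.zeros(mask.template.shape, dtype=np.float64)
    out[mask.data] = 1.0 / np.sqrt(v)
    return out


# -- NIfTI-1 I/O ---------------------------------------------------------


def save_volume(path: str | Path, data: np.ndarray, template: TemplateSpace) -> None:
    """Write a grid to NIfTI-1 (uint8 for binary, int16 labels, float32 maps)."""
    data = np.asarray(data)
    if data.dtype == bool:
        arr = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.integer):
        arr = data.astype(np.int16)
    else:
        arr = data.astype(np.float32)
    img = nib.Nifti1Image(arr, template.affine)
    nib.save(img, str(path))


def _template_from_img(img: nib.Nifti1Image) -> TemplateSpace:
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError("only axis-aligned (diagonal) affines are supported")
    spacing = np.diag(aff[:3, :3]).astype(float)
    if np.any(spacing <= 0):
        raise ValueError("negative or zero spacings are not supported")
    origin = aff[:3, 3] - 0.5 * spacing
    return TemplateSpace(
        shape=tuple(int(s) for s in img.shape[:3]),
        spacing_mm=tuple(spacing),
        origin_mm=tuple(float(o) for o in origin),
    )


def load_mask(path: str | Path) -> LesionMask:
    img = nib.load(str(path))
    template = _template_from_img(img)
    return LesionMask(template=template, data=np.asarray(img.dataobj) > 0)


def load_map(path: str | Path) -> tuple[np.ndarray, TemplateSpace]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), _template_from_img(img)
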
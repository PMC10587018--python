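"""Cross-hemisphere comparison of lesion-mapping correlates.

Significance maps from one hemisphere are mirrored across the midline so
they can be overlaid on their anatomical homologues in the other
hemisphere; agreement is quantified with the Dice coefficient
``2 |A ∩ B| / (|A| + |B|)`` — equivalently the overlap divided by the
mean mask size — and binned into conventional interpretation labels.
Tract- and edge-level correlates are matched by contralateral name or by
mirrored node identity from the parcellation's declared homologue pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .disconnect import Parcellation
from .volumes import LesionMask, mirror_flip

__all__ = [
    "OverlapReport",
    "HomologueComparison",
    "dice",
    "mirrored_overlap",
    "interpret_dice",
    "homologous_units",
    "contralateral_tract_name",
    "edge_homologue",
]

# Dice bins: strict lower bounds, boundary values fall to the lower label.
_DICE_BINS = (
    (0.8, "excellent"),
    (0.6, "substantial"),
    (0.4, "moderate"),
    (0.2, "slight"),
)


def interpret_dice(value: float) -> str:
    """Conventional agreement label: > .8 excellent, > .6 substantial,
    > .4 moderate, > .2 slight, otherwise poor."""
    if not 0.0 <= value <= 1.0:
        raise ValueError("Dice coefficient must lie in [0, 1]")
    for lo, label in _DICE_BINS:
        if value > lo:
            return label
    return "poor"


@dataclass(frozen=True)
class OverlapReport:
    size_a: int
    size_b: int
    overlap: int
    dice: float
    interpretation: str
    percent_of_a: float = float("nan")
    percent_of_b: float = float("nan")

    def describe(self) -> str:
        return (
            f"{self.overlap} voxels shared between masks of {self.size_a} and "
            f"{self.size_b} voxels (Dice = {self.dice:.5f}, {self.interpretation}; "
            f"{self.percent_of_a:.2f}% of the first mask, "
            f"{self.percent_of_b:.2f}% of the second)"
        )

    def to_dict(self) -> dict:
        def _num(x: float):
            return None if np.isnan(x) else x

        return {
            "size_a": self.size_a,
            "size_b": self.size_b,
            "overlap": self.overlap,
            "dice": self.dice,
            "interpretation": self.interpretation,
            "percent_of_a": _num(self.percent_of_a),
            "percent_of_b": _num(self.percent_of_b),
        }


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, LesionMask):
        return mask.data
    return np.asarray(mask, dtype=bool)


def dice(mask_a, mask_b) -> OverlapReport:
    """Dice overlap of two binary masks on one grid."""
    a = _as_bool(mask_a)
    b = _as_bool(mask_b)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks are empty")
    ov = int(np.sum(a & b))
    d = 2.0 * ov / (na + nb)
    return OverlapReport(
        size_a=na,
        size_b=nb,
        overlap=ov,
        dice=d,
        interpretation=interpret_dice(d),
        percent_of_a=100.0 * ov / na if na else float("nan"),
        percent_of_b=100.0 * ov / nb if nb else float("nan"),
    )


def mirrored_overlap(sig_map_left_condition, sig_map_right_condition) -> OverlapReport:
    """Mirror the first thresholded map across the midline, then Dice.

    Both inputs are binary significance masks on one template; after
    mirroring, overlapping voxels are those falling on anatomical
    homologues of the other condition's correlates.
    """
    mirrored = mirror_flip(_as_bool(sig_map_left_condition))
    return dice(mirrored, sig_map_right_condition)


@dataclass(frozen=True)
class HomologueComparison:
    shared: list
    only_a: list
    only_b: list
    unmatched_a: list
    unmatched_b: list

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def contralateral_tract_name(name: str) -> str | None:
    """Name-matching fallback for tract homologues: swap an L_/R_ prefix
    or _left/_right suffix; None when the name encodes no side."""
    for a, b in (("L_", "R_"), ("left_", "right_")):
        if name.startswith(a):
            return b + name[len(a):]
        if name.startswith(b):
            return a + name[len(b):]
    for a, b in (("_L", "_R"), ("_left", "_right")):
        if name.endswith(a):
            return name[: -len(a)] + b
        if name.endswith(b):
            return name[: -len(b)] + a
    return None


def edge_homologue(edge: tuple[int, int], parcellation: Parcellation) -> tuple[int, int] | None:
    """Mirror an unordered node pair through declared homologue ids."""
    ha = parcellation.homologue_of(edge[0])
    hb = parcellation.homologue_of(edge[1])
    if ha is None or hb is None:
        return None
    return (min(ha, hb), max(ha, hb))


def homologous_units(
    significant_units_a,
    significant_units_b,
    unit_kind: str = "tract",
    parcellation: Parcellation | None = None,
) -> HomologueComparison:
    """Which of A's correlates have their anatomical homologue among B's.

    For ``unit_kind="tract"`` units are names matched through
    :func:`contralateral_tract_name`; for ``"edge"`` they are unordered
    node-id pairs mirrored through the parcellation's homologue map.
    Units lacking a defined homologue are reported under ``unmatched``,
    never silently dropped.
    """
    if unit_kind not in ("tract", "edge"):
        raise ValueError("unit_kind must be 'tract' or 'edge'")
    if unit_kind == "edge" and parcellation is None:
        raise ValueError("edge matching needs the parcellation homologue map")

    def _homologue(u):
        if unit_kind == "tract":
            return contralateral_tract_name(u)
        return edge_homologue(tuple(sorted(u)), parcellation)

    def _norm(u):
        return u if unit_kind == "tract" else tuple(sorted(u))

    set_b = {_norm(u) for u in significant_units_b}
    set_a = {_norm(u) for u in significant_units_a}
    shared, only_a, unmatched_a = [], [], []
    for u in significant_units_a:
        h = _homologue(_norm(u))
        if h is None:
            unmatched_a.append(u)
        elif h in set_b:
            shared.append(u)
        else:
            only_a.append(u)
    only_b, unmatched_b = [], []
    for u in significant_units_b:
        h = _homologue(_norm(u))
        if h is None:
            unmatched_b.append(u)
        elif h not in set_a:
            only_b.append(u)
    return HomologueComparison(
        shared=shared,
        only_a=only_a,
        only_b=only_b,
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
    )
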
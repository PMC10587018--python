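"""Self-contained synthetic study generator.

Builds everything the analysis stages consume without any downloads: a
toy template grid, a mirrored two-hemisphere parcellation with network
labels, a streamline pseudo-atlas whose bundles join parcel pairs and
carry tract names, a lateralized lesion cohort with a configurable
volume distribution, and behaviour produced by planted damage-severity
effects plus Gaussian noise.

The generative model for behaviour is linear:

    severity_i = sum_k sign(laterality_k) * effect_k * damage_ik * gate_ik + eps_i

where ``damage_ik`` is patient i's fractional damage to effect k's
target (voxel-region fraction, tract percent / 100, or edge
percent / 100), ``gate_ik`` is a Bernoulli(impaired_fraction) thinning
term modelling individual susceptibility, and ``eps_i`` is Gaussian.
Severities are additionally rendered into item-level cancellation
responses through a logistic link so the scoring stage can be exercised
end-to-end; ground truth is always emitted alongside the data so
downstream checks never re-derive it from generator internals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit, logit

from .disconnect import (
    Parcellation,
    StreamlineSet,
    disconnection_matrices,
    tract_disconnection_table,
)
from .scoring import (
    LEFT_GAP,
    RIGHT_GAP,
    TARGET,
    CancellationLayout,
    CancellationResponse,
    default_layout,
)
from .template import TemplateSpace, make_template
from .volumes import LesionMask

__all__ = [
    "EffectSpec",
    "GammaVolumes",
    "SyntheticAnatomy",
    "BehavioralRecord",
    "GroundTruth",
    "CapacityError",
    "make_template",
    "make_parcellation",
    "default_tract_grouping",
    "make_streamlines",
    "make_lesions",
    "box_region",
    "make_behavior",
    "write_behavior_tsv",
]

DEFAULT_NETWORKS = (
    "visual", "somatomotor", "dorsal_attention", "ventral_attention",
    "limbic", "control", "default",
)

# Cohort lateralization: left / right / bilateral lesion proportions of a
# representative acute stroke sample (178, 237 and 65 of 480 patients).
DEFAULT_SIDE_PROBABILITIES = (178 / 480, 237 / 480, 65 / 480)

_STRUCT26 = ndimage.generate_binary_structure(3, 3)


class CapacityError(ValueError):
    """A request exceeds the voxels available in the template/hemisphere."""


# -- effect specification -------------------------------------------------


@dataclass(frozen=True)
class EffectSpec:
    """A planted damage -> severity effect.

    ``target_kind`` is one of {"voxel_region", "tract", "edge"};
    ``target_id`` names a region mask, a tract, or an unordered node
    pair. ``effect_size`` is in severity units per unit fractional
    damage; ``laterality`` decides the severity sign (left-neglect
    positive); ``dimension`` says whether the effect drives egocentric
    or allocentric severity; ``impaired_fraction`` thins the effect
    across patients (1.0 = every damaged patient is affected).
    """

    target_kind: str
    target_id: object
    effect_size: float
    noise_sd: float
    impaired_fraction: float = 1.0
    laterality: str = "left"
    dimension: str = "ego"

    def __post_init__(self) -> None:
        if self.target_kind not in ("voxel_region", "tract", "edge"):
            raise ValueError("target_kind must be voxel_region, tract or edge")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be >= 0")
        if not 0.0 <= self.impaired_fraction <= 1.0:
            raise ValueError("impaired_fraction must lie in [0, 1]")
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be left or right")
        if self.dimension not in ("ego", "allo"):
            raise ValueError("dimension must be ego or allo")


# -- parcellation ---------------------------------------------------------


def _bisect_box(box: tuple[slice, slice, slice], k: int) -> list[tuple[slice, slice, slice]]:
    """Recursively split a box into k rectangular sub-boxes of similar size."""
    if k == 1:
        return [box]
    sizes = [s.stop - s.start for s in box]
    ax = int(np.argmax(sizes))
    k1 = k // 2
    cut = box[ax].start + max(1, min(sizes[ax] - 1, round(sizes[ax] * k1 / k)))
    lo = list(box)
    hi = list(box)
    lo[ax] = slice(box[ax].start, cut)
    hi[ax] = slice(cut, box[ax].stop)
    return _bisect_box(tuple(lo), k1) + _bisect_box(tuple(hi), k - k1)


def make_parcellation(
    template: TemplateSpace,
    n_cortical_per_hemi: int = 50,
    n_subcortical: int = 35,
    network_names: tuple[str, ...] = DEFAULT_NETWORKS,
    seed: int = 0,
) -> Parcellation:
    """Mirrored toy parcellation: contiguous block parcels, exact homologues.

    The grid is split into a left cortical box, its mirrored right
    counterpart, and a midline-straddling subcortical slab. Left parcel i
    and right parcel i + n are exact mirrors across the midline; midline
    subcortical parcels carry no homologue. Defaults (50 cortical per
    hemisphere + 35 subcortical) give the 135-node universe used by the
    network-level analysis.
    """
    if n_cortical_per_hemi < 1:
        raise ValueError("n_cortical_per_hemi must be >= 1")
    if not network_names:
        raise ValueError("need at least one network name")
    nx, ny, nz = template.shape
    if nx % 2:
        raise ValueError("mirrored parcellation needs an even x dimension")
    cx = nx // 2
    wx = max(1, nx // 8) if n_subcortical > 0 else 0
    cort_w = cx - wx
    if cort_w < 1:
        raise CapacityError("template too narrow for a cortical compartment")
    n_cort_vox = cort_w * ny * nz
    if n_cortical_per_hemi > n_cort_vox:
        raise CapacityError(
            f"{n_cortical_per_hemi} cortical parcels exceed {n_cort_vox} available voxels"
        )
    n_sub_vox = 2 * wx * ny * nz
    if n_subcortical > n_sub_vox:
        raise CapacityError(
            f"{n_subcortical} subcortical parcels exceed {n_sub_vox} available voxels"
        )

    labels = np.zeros(template.shape, dtype=np.int32)
    left_boxes = _bisect_box((slice(0, cort_w), slice(0, ny), slice(0, nz)),
                             n_cortical_per_hemi)
    for lab, box in enumerate(left_boxes, start=1):
        labels[box] = lab
    # right hemisphere: exact mirror of the left labels, renumbered
    left_field = labels[:cx][::-1]
    labels[cx:] = np.where(left_field > 0, left_field + n_cortical_per_hemi, 0)
    if n_subcortical > 0:
        sub_boxes = _bisect_box(
            (slice(cx - wx, cx + wx), slice(0, ny), slice(0, nz)), n_subcortical
        )
        for off, box in enumerate(sub_boxes):
            labels[box] = 2 * n_cortical_per_hemi + 1 + off

    rng = np.random.default_rng(seed)
    nets = [network_names[i % len(network_names)] for i in range(n_cortical_per_hemi)]
    rng.shuffle(nets)
    rows = []
    for i in range(n_cortical_per_hemi):
        rows.append(
            dict(id=i + 1, name=f"L_{nets[i]}_{i + 1}", hemisphere="left",
                 network=nets[i], homologue=i + 1 + n_cortical_per_hemi)
        )
    for i in range(n_cortical_per_hemi):
        rows.append(
            dict(id=i + 1 + n_cortical_per_hemi, name=f"R_{nets[i]}_{i + 1}",
                 hemisphere="right", network=nets[i], homologue=i + 1)
        )
    for i in range(n_subcortical):
        rows.append(
            dict(id=2 * n_cortical_per_hemi + 1 + i, name=f"SC_{i + 1}",
                 hemisphere="midline", network="subcortical", homologue=-1)
        )
    return Parcellation(template=template, labels=labels, nodes=pd.DataFrame(rows))


# -- streamlines ----------------------------------------------------------


def default_tract_grouping(
    parcellation: Parcellation, n_tracts: int = 8, edges_per_tract: int = 2,
    seed: int = 0,
) -> dict[str, list[tuple[int, int]]]:
    """Assign random distinct node pairs to named toy tracts."""
    rng = np.random.default_rng(seed)
    ids = parcellation.node_ids
    pairs: set[tuple[int, int]] = set()
    need = n_tracts * edges_per_tract
    guard = 0
    while len(pairs) < need:
        a, b = rng.choice(ids, size=2, replace=False)
        pairs.add((int(min(a, b)), int(max(a, b))))
        guard += 1
        if guard > 100 * need:
            raise CapacityError("not enough distinct node pairs for the grouping")
    pool = sorted(pairs)
    rng.shuffle(pool)
    return {
        f"tract_{t + 1}": [pool[t * edges_per_tract + e] for e in range(edges_per_tract)]
        for t in range(n_tracts)
    }


def make_streamlines(
    parcellation: Parcellation,
    tract_grouping: dict[str, list[tuple[int, int]]] | None = None,
    n_per_edge: int = 10,
    curvature_jitter: float = 0.3,
    seed: int = 0,
) -> StreamlineSet:
    """Curved polyline bundles joining parcel pairs, grouped into tracts.

    Each streamline is a quadratic Bezier from a random voxel centre in
    one endpoint parcel to one in the other, bowed by a random control
    point (``curvature_jitter`` x the endpoint distance), sampled densely
    enough that consecutive vertices are at most half the minimum voxel
    spacing apart, and clipped to the template box.
    """
    if n_per_edge < 1:
        raise ValueError("n_per_edge must be >= 1")
    template = parcellation.template
    rng = np.random.default_rng(seed)
    if tract_grouping is None:
        tract_grouping = default_tract_grouping(parcellation, seed=seed)
    min_sp = min(template.spacing_mm)
    step = 0.5 * min_sp
    lo = np.asarray(template.origin_mm) + 0.25 * np.asarray(template.spacing_mm)
    hi = (
        np.asarray(template.origin_mm)
        + np.asarray(template.shape) * np.asarray(template.spacing_mm)
        - 0.25 * np.asarray(template.spacing_mm)
    )
    streamlines: list[np.ndarray] = []
    tracts: list[str] = []
    for tract_name, edges in tract_grouping.items():
        for (a, b) in edges:
            vox_a = np.argwhere(parcellation.voxels_of(a))
            vox_b = np.argwhere(parcellation.voxels_of(b))
            if len(vox_a) == 0 or len(vox_b) == 0:
                raise ValueError(f"endpoint parcel empty for edge ({a}, {b})")
            for _ in range(n_per_edge):
                p0 = template.voxel_to_world(vox_a[rng.integers(len(vox_a))])
                p1 = template.voxel_to_world(vox_b[rng.integers(len(vox_b))])
                span = float(np.linalg.norm(p1 - p0))
                u = rng.standard_normal(3)
                u /= max(np.linalg.norm(u), 1e-12)
                c = (p0 + p1) / 2 + curvature_jitter * span * u
                # max Bezier speed is at an endpoint: 2|c-p0| or 2|p1-c|
                vmax = 2.0 * max(np.linalg.norm(c - p0), np.linalg.norm(p1 - c))
                n = max(2, int(np.ceil(vmax / step)))
                t = np.linspace(0.0, 1.0, n + 1)[:, None]
                pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * c + t**2 * p1
                pts = np.clip(pts, lo, hi)
                pts[0], pts[-1] = p0, p1
                streamlines.append(pts)
                tracts.append(tract_name)
    return StreamlineSet(
        template=template,
        streamlines=streamlines,
        tract_of=np.asarray(tracts, dtype=object),
    )


# -- lesions --------------------------------------------------------------


@dataclass(frozen=True)
class GammaVolumes:
    """Gamma-distributed lesion volumes (voxels) with known mean and sd."""

    mean: float
    cv: float = 0.6

    @property
    def sd(self) -> float:
        return self.mean * self.cv

    def sample(self, rng: np.random.Generator) -> int:
        shape = 1.0 / self.cv**2
        scale = self.mean / shape
        return max(1, int(round(rng.gamma(shape, scale))))


def _grow_blob(
    template: TemplateSpace,
    volume: int,
    x_lo: int,
    x_hi: int,
    rng: np.random.Generator,
    cross_column: int | None = None,
    surface_jitter: float = 0.25,
) -> np.ndarray:
    """One 26-connected ellipsoidal blob of exactly ``volume`` voxels.

    The blob is the ``volume`` smallest values of a jittered ellipsoidal
    distance field restricted to columns [x_lo, x_hi); if jitter breaks
    connectivity, the component holding the field minimum is kept and
    topped up with the cheapest adjacent voxels.
    """
    nx, ny, nz = template.shape
    capacity = (x_hi - x_lo) * ny * nz
    if volume > capacity:
        raise CapacityError(f"volume {volume} exceeds region capacity {capacity}")
    for attempt in range(6):
        if cross_column is not None:
            c = np.array([
                cross_column - 1 + rng.integers(0, 2),
                rng.integers(0, ny), rng.integers(0, nz),
            ])
        else:
            c = np.array([
                rng.integers(x_lo, x_hi), rng.integers(0, ny), rng.integers(0, nz),
            ])
        r0 = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
        anis = np.exp(rng.uniform(-0.35, 0.35, size=3))
        r = r0 * anis / anis.prod() ** (1.0 / 3.0)
        if cross_column is not None:
            r[0] = max(r[0] * (1.0 + 0.5 * attempt), 1.6)
        half = np.ceil(2.2 * r.max()).astype(int) + 2
        sl = (
            slice(max(x_lo, c[0] - half), min(x_hi, c[0] + half + 1)),
            slice(max(0, c[1] - half), min(ny, c[1] + half + 1)),
            slice(max(0, c[2] - half), min(nz, c[2] + half + 1)),
        )
        box_shape = tuple(s.stop - s.start for s in sl)
        if int(np.prod(box_shape)) < volume:
            sl = (slice(x_lo, x_hi), slice(0, ny), slice(0, nz))
            box_shape = tuple(s.stop - s.start for s in sl)
        gi, gj, gk = np.meshgrid(
            np.arange(sl[0].start, sl[0].stop),
            np.arange(sl[1].start, sl[1].stop),
            np.arange(sl[2].start, sl[2].stop),
            indexing="ij",
        )
        diff = np.stack([gi - c[0], gj - c[1], gk - c[2]], axis=-1).astype(float)
        if cross_column is None:
            q = rng.standard_normal((3, 3))
            rot, _ = np.linalg.qr(q)
            diff = diff @ rot
        d = np.sum((diff / r) ** 2, axis=-1)
        amp = surface_jitter / (1 + attempt)
        if amp > 0:
            g = ndimage.gaussian_filter(rng.standard_normal(box_shape), sigma=2.0)
            gs = g.std()
            if gs > 1e-9:
                d = d * np.clip(1.0 + amp * g / gs, 0.2, None)
        flat = d.ravel()
        order = np.argpartition(flat, volume - 1)[:volume]
        sel = np.zeros(box_shape, dtype=bool)
        sel.ravel()[order] = True
        lab, ncomp = ndimage.label(sel, structure=_STRUCT26)
        if ncomp > 1:
            seed_vox = np.unravel_index(int(np.argmin(flat)), box_shape)
            keep = lab == lab[seed_vox]
            sel = keep
            while sel.sum() < volume:
                frontier = ndimage.binary_dilation(sel, structure=_STRUCT26) & ~sel
                fidx = np.flatnonzero(frontier.ravel())
                if len(fidx) == 0:
                    break
                need = volume - int(sel.sum())
                cheapest = fidx[np.argsort(flat[fidx])[:need]]
                sel.ravel()[cheapest] = True
            if sel.sum() != volume:
                continue
        mask = np.zeros(template.shape, dtype=bool)
        mask[sl] = sel
        if cross_column is not None:
            if not (mask[:cross_column].any() and mask[cross_column:].any()):
                continue
        return mask
    raise RuntimeError("failed to grow a blob satisfying the side constraints")


def make_lesions(
    template: TemplateSpace,
    n_patients: int,
    side_probabilities: tuple[float, float, float] | None = None,
    volume_distribution: GammaVolumes | None = None,
    seed: int = 0,
) -> list[LesionMask]:
    """A lateralized cohort of single-blob lesion masks.

    ``side_probabilities`` orders (left, right, bilateral); bilateral
    blobs cross the midline, unilateral blobs stay strictly within their
    hemisphere. The default volume distribution is a Gamma with mean 10%
    of the hemisphere's voxels (cv 0.6), which keeps the centre of each
    hemisphere inside the >10-patient coverage territory at cohort sizes
    of a few hundred. Same seed, same cohort.
    """
    if side_probabilities is None:
        side_probabilities = DEFAULT_SIDE_PROBABILITIES
    probs = np.asarray(side_probabilities, dtype=float)
    if probs.shape != (3,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("side_probabilities over (left, right, bilateral) must sum to 1")
    nx, ny, nz = template.shape
    cx = template.midline_column
    hemi_vox = cx * ny * nz
    if volume_distribution is None:
        volume_distribution = GammaVolumes(mean=0.10 * hemi_vox)
    rng = np.random.default_rng(seed)
    masks = []
    for _ in range(n_patients):
        side = rng.choice(3, p=probs)  # 0 left, 1 right, 2 bilateral
        v = volume_distribution.sample(rng)
        if side == 0:
            data = _grow_blob(template, min(v, hemi_vox), 0, cx, rng)
        elif side == 1:
            data = _grow_blob(template, min(v, (nx - cx) * ny * nz), cx, nx, rng)
        else:
            data = _grow_blob(
                template, min(max(v, 2), nx * ny * nz), 0, nx, rng, cross_column=cx
            )
        masks.append(LesionMask(template=template, data=data))
    return masks


def box_region(
    template: TemplateSpace,
    side: str = "right",
    size: tuple[int, int, int] = (5, 5, 5),
    center: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """A rectangular voxel region, centred in one hemisphere by default."""
    nx, ny, nz = template.shape
    cx = template.midline_column
    if center is None:
        x0 = cx // 2 if side == "left" else cx + (nx - cx) // 2
        center = (x0, ny // 2, nz // 2)
    region = np.zeros(template.shape, dtype=bool)
    sl = tuple(
        slice(max(0, c - s // 2), min(n, c - s // 2 + s))
        for c, s, n in zip(center, size, (nx, ny, nz))
    )
    region[sl] = True
    return region


# -- behaviour ------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticAnatomy:
    """Bundle of the synthetic structures the generator plants effects in."""

    template: TemplateSpace
    parcellation: Parcellation
    streamlines: StreamlineSet
    regions: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass(frozen=True)
class BehavioralRecord:
    patient_id: str
    response: CancellationResponse
    true_ego_severity: float
    true_allo_severity: float


@dataclass(frozen=True)
class GroundTruth:
    """Planted model emitted alongside the data: damage, gates, severities."""

    damage: pd.DataFrame  # patients x effects, fractional damage
    gates: pd.DataFrame
    linear_ego: np.ndarray
    linear_allo: np.ndarray
    ego_severity: np.ndarray
    allo_severity: np.ndarray
    effect_names: list[str]

    def to_manifest(self) -> dict:
        return {
            "effect_names": self.effect_names,
            "damage": self.damage.to_dict(orient="list"),
            "gates": self.gates.astype(int).to_dict(orient="list"),
            "linear_ego": self.linear_ego.tolist(),
            "linear_allo": self.linear_allo.tolist(),
            "ego_severity": self.ego_severity.tolist(),
            "allo_severity": self.allo_severity.tolist(),
        }


def _effect_damage(
    spec: EffectSpec, cohort: list[LesionMask], anatomy: SyntheticAnatomy
) -> np.ndarray:
    if spec.target_kind == "voxel_region":
        if spec.target_id not in anatomy.regions:
            raise KeyError(f"unknown voxel region {spec.target_id!r}")
        region = anatomy.regions[spec.target_id]
        denom = float(region.sum())
        return np.array([(m.data & region).sum() / denom for m in cohort])
    if spec.target_kind == "tract":
        if spec.target_id not in anatomy.streamlines.tract_names:
            raise KeyError(f"unknown tract {spec.target_id!r}")
        table = tract_disconnection_table(anatomy.streamlines, cohort)
        return table[spec.target_id].to_numpy() / 100.0
    # edge
    a, b = spec.target_id
    mats = disconnection_matrices(anatomy.streamlines, anatomy.parcellation, cohort)
    if not mats[0].defined[
        list(mats[0].node_ids).index(a), list(mats[0].node_ids).index(b)
    ]:
        raise KeyError(f"edge {spec.target_id!r} has no atlas streamlines")
    return np.array([m.entry(a, b) for m in mats]) / 100.0


def make_behavior(
    cohort: list[LesionMask],
    anatomy: SyntheticAnatomy,
    effect_specs: list[EffectSpec],
    seed: int = 0,
    layout: CancellationLayout | None = None,
) -> tuple[list[BehavioralRecord], GroundTruth]:
    """Severities from planted effects, rendered as cancellation responses.

    Egocentric severity is on the centre-of-cancellation scale and
    allocentric severity on the allocentric-proportion scale, both signed
    (left neglect positive). Rendering uses a logistic link: the
    per-target cancel probability falls with |x| into the neglected side
    as egocentric severity grows, and the false-positive probability on
    the neglected gap side rises with allocentric severity.
    """
    rng = np.random.default_rng(seed)
    n = len(cohort)
    if layout is None:
        layout = default_layout()
    names, damages, gates = [], {}, {}
    lin = {"ego": np.zeros(n), "allo": np.zeros(n)}
    var = {"ego": 0.0, "allo": 0.0}
    for k, spec in enumerate(effect_specs):
        name = f"{spec.target_kind}:{spec.target_id}"
        names.append(name)
        dmg = _effect_damage(spec, cohort, anatomy)
        gate = rng.random(n) < spec.impaired_fraction
        sign = 1.0 if spec.laterality == "left" else -1.0
        lin[spec.dimension] += sign * spec.effect_size * dmg * gate
        var[spec.dimension] += spec.noise_sd**2
        damages[name] = dmg
        gates[name] = gate
    eps_ego = rng.standard_normal(n) * np.sqrt(var["ego"])
    eps_allo = rng.standard_normal(n) * np.sqrt(var["allo"])
    sev_ego = lin["ego"] + eps_ego
    sev_allo = lin["allo"] + eps_allo

    records = []
    x = layout.x_norm
    is_target = layout.kind == TARGET
    is_lgap = layout.kind == LEFT_GAP
    is_rgap = layout.kind == RIGHT_GAP
    base_fp = logit(0.02)
    for i in range(n):
        se, sa = sev_ego[i], sev_allo[i]
        neglect_depth = np.maximum(0.0, -np.sign(se) * x)  # into the neglected side
        p = np.empty(len(layout))
        p[is_target] = 0.95 * expit(4.0 - 8.0 * abs(se) * neglect_depth[is_target])
        p[is_lgap] = expit(base_fp + 6.0 * max(0.0, sa))
        p[is_rgap] = expit(base_fp + 6.0 * max(0.0, -sa))
        marked = np.flatnonzero(rng.random(len(layout)) < p)
        records.append(
            BehavioralRecord(
                patient_id=f"P{i:04d}",
                response=CancellationResponse(marked=marked),
                true_ego_severity=float(se),
                true_allo_severity=float(sa),
            )
        )
    truth = GroundTruth(
        damage=pd.DataFrame(damages, columns=names),
        gates=pd.DataFrame(gates, columns=names),
        linear_ego=lin["ego"],
        linear_allo=lin["allo"],
        ego_severity=sev_ego,
        allo_severity=sev_allo,
        effect_names=names,
    )
    return records, truth


def write_behavior_tsv(
    records: list[BehavioralRecord], layout: CancellationLayout, path: str | Path
) -> None:
    """One row per patient: id, per-item 0/1 marks, true severity columns."""
    rows = []
    for rec in records:
        marks = np.zeros(len(layout), dtype=int)
        marks[rec.response.marked] = 1
        row = {"patient_id": rec.patient_id}
        row.update({f"item_{i}": int(m) for i, m in enumerate(marks)})
        row["true_ego_severity"] = rec.true_ego_severity
        row["true_allo_severity"] = rec.true_allo_severity
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_behavior_tsv(path: str | Path) -> list[BehavioralRecord]:
    df = pd.read_csv(path, sep="\t")
    item_cols = [c for c in df.columns if c.startswith("item_")]
    records = []
    for _, row in df.iterrows():
        marked = np.flatnonzero(row[item_cols].to_numpy(dtype=int))
        records.append(
            BehavioralRecord(
                patient_id=str(row["patient_id"]),
                response=CancellationResponse(marked=marked),
                true_ego_severity=float(row["true_ego_severity"]),
                true_allo_severity=float(row["true_allo_severity"]),
            )
        )
    return records
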
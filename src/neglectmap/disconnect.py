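"""Streamline-level disconnection from lesion masks.

A normative streamline set (polylines in world mm, grouped into named
tracts) stands in for a population tractography atlas. A streamline is
*disconnected* by a lesion when its path passes through any lesioned
voxel. From per-streamline hits this module derives per-tract percent
disconnection, parcel-pair (edge) disconnection matrices, and group
count matrices.

Hit-testing walks each polyline segment through the voxel grid with an
exact parametric traversal (Amanatides–Woo style), so the result is
independent of any sampling step and contains every voxel a
point-sampling scheme along the same polyline could find.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .template import TemplateSpace
from .volumes import IncompatibleGridsError, LesionMask

__all__ = [
    "OutOfBoundsError",
    "Parcellation",
    "StreamlineSet",
    "DisconnectionMatrix",
    "streamline_voxel_indices",
    "streamline_hit",
    "tract_disconnection",
    "tract_disconnection_table",
    "endpoint_pair",
    "disconnection_matrix",
    "disconnection_matrices",
    "group_count_matrix",
    "save_streamlines_json",
    "load_streamlines_json",
    "save_tck",
    "load_tck",
]


class OutOfBoundsError(ValueError):
    """A streamline vertex lies outside the template grid."""


# -- parcellation ---------------------------------------------------------


@dataclass(frozen=True)
class Parcellation:
    """Labelled grid (0 = background) plus a node table.

    ``nodes`` has one row per parcel with columns ``id``, ``name``,
    ``hemisphere`` (left/right/midline), ``network`` and ``homologue``
    (the mirror parcel's id, or -1 where no homologue is defined, e.g.
    midline subcortical parcels).
    """

    template: TemplateSpace
    labels: np.ndarray
    nodes: pd.DataFrame

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != self.template.shape:
            raise IncompatibleGridsError("label grid does not match template shape")
        ids = self.nodes["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("node ids must be unique")
        present = np.unique(labels)
        present = present[present != 0]
        if not np.all(np.isin(present, ids)):
            raise ValueError("label grid contains ids missing from the node table")
        object.__setattr__(self, "labels", labels.astype(np.int32))

    @property
    def node_ids(self) -> np.ndarray:
        return np.sort(self.nodes["id"].to_numpy())

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def homologue_of(self, node_id: int) -> int | None:
        row = self.nodes.loc[self.nodes["id"] == node_id]
        if row.empty:
            raise KeyError(f"unknown node id {node_id}")
        h = int(row["homologue"].iloc[0])
        return None if h < 0 else h

    def voxels_of(self, node_id: int) -> np.ndarray:
        return self.labels == node_id

    def save(self, nifti_path: str | Path, nodes_path: str | Path) -> None:
        from .volumes import save_volume

        save_volume(nifti_path, self.labels, self.template)
        records = self.nodes.to_dict(orient="records")
        Path(nodes_path).write_text(json.dumps(records, indent=1))

    @classmethod
    def load(cls, nifti_path: str | Path, nodes_path: str | Path) -> "Parcellation":
        from .volumes import load_map

        labels, template = load_map(nifti_path)
        nodes = pd.DataFrame(json.loads(Path(nodes_path).read_text()))
        return cls(template=template, labels=np.asarray(labels), nodes=nodes)


# -- streamline geometry --------------------------------------------------


def _check_in_bounds(points: np.ndarray, template: TemplateSpace) -> None:
    if not np.all(template.contains_world(points)):
        raise OutOfBoundsError("streamline has vertices outside the template grid")


def streamline_voxel_indices(points: np.ndarray, template: TemplateSpace) -> np.ndarray:
    """Flat indices of every voxel a polyline passes through (exact traversal)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("a streamline needs >= 2 vertices of shape (n, 3)")
    _check_in_bounds(pts, template)
    u = template.world_to_continuous(pts)
    ny, nz = template.shape[1], template.shape[2]
    visited: set[int] = set()
    for s in range(len(u) - 1):
        a, b = u[s], u[s + 1]
        ia = np.floor(a).astype(np.int64)
        ib = np.floor(b).astype(np.int64)
        visited.add(int((ia[0] * ny + ia[1]) * nz + ia[2]))
        if ia[0] == ib[0] and ia[1] == ib[1] and ia[2] == ib[2]:
            continue
        d = b - a
        step = np.sign(d).astype(np.int64)
        t_max = np.full(3, np.inf)
        t_delta = np.full(3, np.inf)
        for ax in range(3):
            if d[ax] != 0.0:
                boundary = ia[ax] + 1 if step[ax] > 0 else ia[ax]
                t_max[ax] = (boundary - a[ax]) / d[ax]
                t_delta[ax] = 1.0 / abs(d[ax])
        cur = ia.copy()
        for _ in range(int(np.abs(ib - ia).sum())):
            ax = int(np.argmin(t_max))
            cur[ax] += step[ax]
            t_max[ax] += t_delta[ax]
            visited.add(int((cur[0] * ny + cur[1]) * nz + cur[2]))
        visited.add(int((ib[0] * ny + ib[1]) * nz + ib[2]))
    return np.fromiter(visited, dtype=np.int64, count=len(visited))


def _sampled_points(points: np.ndarray, step: float) -> np.ndarray:
    """Densify a polyline so consecutive samples are at most ``step`` apart."""
    pts = np.asarray(points, dtype=float)
    out = [pts[:1]]
    for s in range(len(pts) - 1):
        a, b = pts[s], pts[s + 1]
        seg = float(np.linalg.norm(b - a))
        n = max(1, int(np.ceil(seg / step)))
        t = np.arange(1, n + 1)[:, None] / n
        out.append(a + t * (b - a))
    return np.vstack(out)


def streamline_hit(
    points: np.ndarray, mask: LesionMask, step: float | None = None
) -> bool:
    """True iff the streamline passes through a lesioned voxel.

    With ``step=None`` (default) the exact segment traversal decides; a
    float ``step`` (mm) instead tests densified sample points at that
    spacing, which is the conventional approximate scheme.
    """
    if step is None:
        idx = streamline_voxel_indices(points, mask.template)
        return bool(mask.data.ravel()[idx].any())
    pts = _sampled_points(points, step)
    _check_in_bounds(pts, mask.template)
    ijk = mask.template.world_to_voxel(pts)
    ijk = np.minimum(ijk, np.asarray(mask.template.shape) - 1)
    return bool(mask.data[ijk[:, 0], ijk[:, 1], ijk[:, 2]].any())


# -- streamline sets ------------------------------------------------------


@dataclass
class StreamlineSet:
    """Polylines in world mm, each carrying exactly one tract label."""

    template: TemplateSpace
    streamlines: list[np.ndarray]
    tract_of: np.ndarray  # str array, one label per streamline
    _incidence: sparse.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.streamlines) != len(self.tract_of):
            raise ValueError("tract_of must label every streamline")
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[0] < 2 or s.shape[1] != 3:
                raise ValueError("every streamline needs >= 2 vertices of shape (n, 3)")
        self.tract_of = np.asarray(self.tract_of, dtype=object)

    def __len__(self) -> int:
        return len(self.streamlines)

    @property
    def tract_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.tract_of:
            seen.setdefault(str(t))
        return list(seen)

    def tract_indices(self, tract_name: str) -> np.ndarray:
        return np.flatnonzero(self.tract_of == tract_name)

    def incidence(self) -> sparse.csr_matrix:
        """Sparse (n_streamlines x n_voxels) path-incidence matrix, cached."""
        if self._incidence is None:
            indptr = [0]
            indices: list[np.ndarray] = []
            for s in self.streamlines:
                idx = streamline_voxel_indices(s, self.template)
                indices.append(np.sort(idx))
                indptr.append(indptr[-1] + len(idx))
            data = np.ones(indptr[-1], dtype=np.int8)
            self._incidence = sparse.csr_matrix(
                (data, np.concatenate(indices) if indices else np.empty(0, int), indptr),
                shape=(len(self.streamlines), self.template.n_voxels),
            )
        return self._incidence

    def hit_matrix(self, masks: list[LesionMask]) -> np.ndarray:
        """Boolean (n_streamlines x n_patients) disconnection indicator."""
        for m in masks:
            if m.template != self.template:
                raise IncompatibleGridsError("mask template differs from streamline template")
        flat = np.stack([m.data.ravel() for m in masks], axis=1).astype(np.int8)
        return np.asarray(self.incidence().dot(flat)) > 0


def tract_disconnection(sset: StreamlineSet, tract_name: str, mask: LesionMask) -> float:
    """Percent of the tract's streamlines passing through the lesion."""
    idx = sset.tract_indices(tract_name)
    if len(idx) == 0:
        raise ValueError(f"tract {tract_name!r} is empty or unknown")
    hits = sset.hit_matrix([mask])[idx, 0]
    return 100.0 * float(hits.sum()) / len(idx)


def tract_disconnection_table(
    sset: StreamlineSet, masks: list[LesionMask]
) -> pd.DataFrame:
    """Per-patient, per-tract percent disconnection (patients x tracts)."""
    hits = sset.hit_matrix(masks)  # streamlines x patients
    data = {}
    for name in sset.tract_names:
        idx = sset.tract_indices(name)
        data[name] = 100.0 * hits[idx].sum(axis=0) / len(idx)
    return pd.DataFrame(data)


# -- parcel-pair (edge) disconnection -------------------------------------


def endpoint_pair(
    points: np.ndarray, parcellation: Parcellation
) -> tuple[int | None, int | None]:
    """Parcel ids at the first and last vertex (None where background)."""
    pts = np.asarray(points, dtype=float)
    template = parcellation.template
    _check_in_bounds(pts[[0, -1]], template)
    ends = template.world_to_voxel(pts[[0, -1]])
    labels = parcellation.labels[ends[:, 0], ends[:, 1], ends[:, 2]]
    a = int(labels[0]) if labels[0] != 0 else None
    b = int(labels[1]) if labels[1] != 0 else None
    return (a, b)


@dataclass(frozen=True)
class DisconnectionMatrix:
    """Symmetric percent-disconnection matrix over parcellation nodes.

    Entries where ``denominator == 0`` (no atlas streamlines join the
    pair) are undefined; they are stored as 0 but flagged through the
    denominator matrix.
    """

    node_ids: np.ndarray
    percent: np.ndarray
    denominator: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.node_ids)
        if self.percent.shape != (k, k) or self.denominator.shape != (k, k):
            raise ValueError("matrix shapes must be (n_nodes, n_nodes)")

    @property
    def n_entries(self) -> int:
        """Full matrix-entry count (the node-by-node convention: K^2)."""
        return len(self.node_ids) ** 2

    @property
    def defined(self) -> np.ndarray:
        return self.denominator > 0

    def entry(self, a: int, b: int) -> float:
        ids = list(self.node_ids)
        return float(self.percent[ids.index(a), ids.index(b)])

    def long_table(self) -> pd.DataFrame:
        """Deduplicated (a <= b) long form of the defined entries."""
        ia, ib = np.nonzero(np.triu(self.defined))
        return pd.DataFrame(
            {
                "node_a": self.node_ids[ia],
                "node_b": self.node_ids[ib],
                "percent": self.percent[ia, ib],
                "n_streamlines": self.denominator[ia, ib],
            }
        )


def _pair_assignments(
    sset: StreamlineSet, parcellation: Parcellation
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map each streamline to a node-pair index; returns (node_ids, ia, ib).

    Streamlines that do not terminate bilaterally inside labelled parcels
    get index -1 and are excluded from every edge.
    """
    node_ids = parcellation.node_ids
    pos = {int(n): i for i, n in enumerate(node_ids)}
    ia = np.full(len(sset), -1, dtype=np.int64)
    ib = np.full(len(sset), -1, dtype=np.int64)
    for s, pts in enumerate(sset.streamlines):
        a, b = endpoint_pair(pts, parcellation)
        if a is None or b is None:
            continue
        i, j = pos[a], pos[b]
        ia[s], ib[s] = min(i, j), max(i, j)
    return node_ids, ia, ib


def disconnection_matrices(
    sset: StreamlineSet, parcellation: Parcellation, masks: list[LesionMask]
) -> list[DisconnectionMatrix]:
    """Per-patient percent-disconnection matrices over all node pairs."""
    if parcellation.template != sset.template:
        raise IncompatibleGridsError("parcellation and streamlines on different templates")
    node_ids, ia, ib = _pair_assignments(sset, parcellation)
    k = len(node_ids)
    keep = ia >= 0
    pair_flat = ia[keep] * k + ib[keep]
    denom_flat = np.bincount(pair_flat, minlength=k * k).astype(np.int64)
    hits = sset.hit_matrix(masks)[keep]  # kept streamlines x patients
    out = []
    denom = denom_flat.reshape(k, k)
    denom = denom + np.triu(denom, 1).T  # symmetric storage
    for p in range(hits.shape[1]):
        num_flat = np.bincount(pair_flat, weights=hits[:, p], minlength=k * k)
        num = num_flat.reshape(k, k)
        num = num + np.triu(num, 1).T
        with np.errstate(invalid="ignore", divide="ignore"):
            percent = np.where(denom > 0, 100.0 * num / np.maximum(denom, 1), 0.0)
        out.append(
            DisconnectionMatrix(node_ids=node_ids, percent=percent, denominator=denom)
        )
    return out


def disconnection_matrix(
    sset: StreamlineSet, parcellation: Parcellation, mask: LesionMask
) -> DisconnectionMatrix:
    return disconnection_matrices(sset, parcellation, [mask])[0]


def group_count_matrix(
    matrices: list[DisconnectionMatrix], threshold_percent: float = 50.0
) -> np.ndarray:
    """Per edge, how many patients show at least ``threshold_percent`` disconnection."""
    if not matrices:
        raise ValueError("need at least one matrix")
    ids0 = matrices[0].node_ids
    counts = np.zeros_like(matrices[0].denominator, dtype=np.int64)
    for m in matrices:
        if not np.array_equal(m.node_ids, ids0):
            raise ValueError("matrices do not share one node set")
        counts += (m.percent >= threshold_percent) & m.defined
    return counts


# -- streamline I/O -------------------------------------------------------


def save_streamlines_json(sset: StreamlineSet, path: str | Path) -> None:
    """Documented JSON fallback: vertex arrays plus tract labels."""
    payload = {
        "streamlines": [s.tolist() for s in sset.streamlines],
        "tracts": [str(t) for t in sset.tract_of],
    }
    Path(path).write_text(json.dumps(payload))


def load_streamlines_json(path: str | Path, template: TemplateSpace) -> StreamlineSet:
    payload = json.loads(Path(path).read_text())
    return StreamlineSet(
        template=template,
        streamlines=[np.asarray(s, dtype=float) for s in payload["streamlines"]],
        tract_of=np.asarray(payload["tracts"], dtype=object),
    )


def save_tck(sset: StreamlineSet, tck_path: str | Path, tracts_path: str | Path) -> None:
    """Write a TCK file (points already in world/RAS mm) plus a tract-label JSON."""
    import nibabel.streamlines as nbs

    tractogram = nbs.Tractogram(sset.streamlines, affine_to_rasmm=np.eye(4))
    nbs.TckFile(tractogram).save(str(tck_path))
    Path(tracts_path).write_text(json.dumps([str(t) for t in sset.tract_of]))


def load_tck(
    tck_path: str | Path, tracts_path: str | Path, template: TemplateSpace
) -> StreamlineSet:
    import nibabel.streamlines as nbs

    tck = nbs.load(str(tck_path))
    tracts = np.asarray(json.loads(Path(tracts_path).read_text()), dtype=object)
    return StreamlineSet(
        template=template,
        streamlines=[np.asarray(s, dtype=float) for s in tck.streamlines],
        tract_of=tracts,
    )
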
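"""Mass-univariate voxel-wise lesion-symptom mapping.

Per voxel inside the analysis mask, a simple ordinary-least-squares
regression of behavioural severity on the dTLVC-transformed lesion value
yields a slope t statistic with n - 2 degrees of freedom. The t statistic
is mapped to a z score through the t CDF (``z = Phi^{-1}(F_t(t))``,
clamped to |z| <= 37 for numerical safety), and the p value follows the
configured sidedness — one-sided by default, testing that damage
increases severity, matching the use of magnitude severity vectors.
Family-wise control is a Bonferroni division of the family alpha by the
number of voxels tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .template import TemplateSpace
from .volumes import LesionMask, dtlvc_transform

__all__ = [
    "StatMap",
    "Cluster",
    "DegenerateOutcomeError",
    "bonferroni_alpha",
    "fit_voxelwise",
    "extract_clusters",
    "cluster_table",
]

Z_CLAMP = 37.0

_CONNECTIVITY = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


class DegenerateOutcomeError(ValueError):
    """The severity vector has zero variance: no voxel-wise test is defined."""


def bonferroni_alpha(n_tests: int, family_alpha: float = 0.05) -> float:
    """Bonferroni-corrected per-test alpha: family_alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


@dataclass(frozen=True)
class StatMap:
    """Voxel-wise regression results on one template grid."""

    template: TemplateSpace
    t: np.ndarray
    z: np.ndarray
    p: np.ndarray
    analysis_mask: np.ndarray
    degenerate: np.ndarray  # voxels with zero predictor variance (t set to 0)
    n_tests: int
    df: int
    sidedness: str
    family_alpha: float

    @property
    def alpha_corrected(self) -> float:
        return bonferroni_alpha(self.n_tests, self.family_alpha)

    @property
    def significant(self) -> np.ndarray:
        return self.analysis_mask & (self.p < self.alpha_corrected)


def fit_voxelwise(
    dtlvc_maps: list[np.ndarray] | np.ndarray,
    severity: np.ndarray,
    analysis_mask: np.ndarray,
    template: TemplateSpace,
    sidedness: str = "greater",
    family_alpha: float = 0.05,
) -> StatMap:
    """Per-voxel OLS of severity on the dTLVC lesion value.

    Parameters
    ----------
    dtlvc_maps
        One real-valued map per patient (list of grids or an (n, *shape)
        array); typically the output of :func:`~neglectmap.volumes.dtlvc_transform`.
    severity
        One finite severity score per patient (>= 3 patients).
    analysis_mask
        Boolean grid of voxels to test (the minimum-coverage filter
        output); statistics are defined only inside it.
    sidedness
        "greater" (one-sided, damage -> greater severity; default) or
        "two-sided".
    """
    maps = np.asarray(dtlvc_maps, dtype=np.float64)
    n = maps.shape[0]
    if n < 3:
        raise ValueError("need at least 3 patients")
    y = np.asarray(severity, dtype=np.float64)
    if y.shape != (n,):
        raise ValueError("severity must have one entry per patient")
    if not np.all(np.isfinite(y)):
        raise ValueError("severity must be finite")
    if np.ptp(y) == 0:
        raise DegenerateOutcomeError("severity is identical for all patients")
    if sidedness not in ("greater", "two-sided"):
        raise ValueError("sidedness must be 'greater' or 'two-sided'")
    mask = np.asarray(analysis_mask, dtype=bool)
    if mask.shape != template.shape:
        raise ValueError("analysis mask does not match the template shape")

    X = maps.reshape(n, -1)[:, mask.ravel()]  # patients x tested voxels
    df = n - 2
    xm = X.mean(axis=0)
    ym = y.mean()
    sxx = (X * X).sum(axis=0) - n * xm * xm
    sxy = X.T @ y - n * xm * ym
    syy = float(y @ y - n * ym * ym)
    degenerate_v = sxx <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(degenerate_v, 0.0, sxy**2 / np.maximum(sxx * syy, 1e-300))
        r2 = np.clip(r2, 0.0, 1.0)
        sign = np.sign(sxy)
        denom = np.sqrt(np.maximum(1.0 - r2, 0.0))
        t_v = np.where(
            denom > 0, sign * np.sqrt(r2 * df) / np.maximum(denom, 1e-300),
            sign * np.inf,
        )
    t_v = np.where(degenerate_v, 0.0, t_v)

    # upper tail through the survival function to keep resolution for
    # extreme t (ppf(cdf) flattens once the tail drops below ~1e-16)
    z_v = np.where(
        t_v >= 0,
        stats.norm.isf(stats.t.sf(t_v, df)),
        stats.norm.ppf(stats.t.cdf(t_v, df)),
    )
    z_v = np.clip(z_v, -Z_CLAMP, Z_CLAMP)
    if sidedness == "greater":
        p_v = stats.t.sf(t_v, df)
    else:
        p_v = 2.0 * stats.t.sf(np.abs(t_v), df)
    p_v = np.where(degenerate_v, 1.0, p_v)

    shape = template.shape
    t_g = np.zeros(shape)
    z_g = np.zeros(shape)
    p_g = np.ones(shape)
    deg_g = np.zeros(shape, dtype=bool)
    t_g[mask] = t_v
    z_g[mask] = z_v
    p_g[mask] = p_v
    deg_g[mask] = degenerate_v
    return StatMap(
        template=template,
        t=t_g,
        z=z_g,
        p=p_g,
        analysis_mask=mask,
        degenerate=deg_g,
        n_tests=int(mask.sum()),
        df=df,
        sidedness=sidedness,
        family_alpha=family_alpha,
    )


def dtlvc_stack(masks: list[LesionMask]) -> np.ndarray:
    """Stack dTLVC maps for a cohort; empty lesions contribute all-zero maps."""
    out = np.zeros((len(masks),) + masks[0].template.shape, dtype=np.float64)
    for i, m in enumerate(masks):
        if m.n_voxels > 0:
            out[i] = dtlvc_transform(m)
    return out


@dataclass(frozen=True)
class Cluster:
    """A connected component of Bonferroni-significant voxels."""

    indices: np.ndarray  # (n, 3) voxel indices
    size_voxels: int
    volume_cm3: float
    peak_z: float
    peak_mm: tuple[float, float, float]


def extract_clusters(
    statmap: StatMap, alpha: float | None = None, connectivity: int = 26
) -> list[Cluster]:
    """Connected components of {p < corrected alpha}, largest first.

    Each cluster reports its voxel count, cm^3 volume, peak z and the
    world-mm coordinate of the peak voxel.
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be 6, 18 or 26")
    alpha = statmap.alpha_corrected if alpha is None else alpha
    sig = statmap.analysis_mask & (statmap.p < alpha)
    labelled, n = ndimage.label(sig, structure=_CONNECTIVITY[connectivity])
    clusters = []
    vox_cm3 = statmap.template.voxel_volume_mm3 / 1000.0
    for lab in range(1, n + 1):
        idx = np.argwhere(labelled == lab)
        zvals = statmap.z[idx[:, 0], idx[:, 1], idx[:, 2]]
        # locate the peak by t, which does not saturate at the z clamp
        tvals = statmap.t[idx[:, 0], idx[:, 1], idx[:, 2]]
        peak = idx[int(np.argmax(tvals))]
        clusters.append(
            Cluster(
                indices=idx,
                size_voxels=len(idx),
                volume_cm3=len(idx) * vox_cm3,
                peak_z=float(zvals.max()),
                peak_mm=tuple(statmap.template.voxel_to_world(peak)),
            )
        )
    clusters.sort(key=lambda c: c.size_voxels, reverse=True)
    return clusters


def cluster_table(clusters: list[Cluster]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(clusters, start=1):
        rows.append(
            {
                "cluster_id": i,
                "size_voxels": c.size_voxels,
                "volume_cm3": c.volume_cm3,
                "peak_z": c.peak_z,
                "peak_x_mm": c.peak_mm[0],
                "peak_y_mm": c.peak_mm[1],
                "peak_z_mm": c.peak_mm[2],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "size_voxels", "volume_cm3", "peak_z",
            "peak_x_mm", "peak_y_mm", "peak_z_mm",
        ],
    )
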
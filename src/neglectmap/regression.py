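"""Tract- and edge-level lesion-symptom regressions with volume control.

Every unit (a named tract, or a parcel-pair network edge) is tested with
an ordinary least squares model

    severity ~ intercept + b1 * percent_disconnection + b2 * lesion_volume

and significance is tied to the disconnection coefficient ``b1`` only
(one-sided positive by default). Family-wise control is Bonferroni over
the tested units; when nothing survives, a Benjamini–Hochberg 5% FDR
step-up is applied as a fallback and flagged as such. The adjusted R^2
of the full two-predictor model is reported, together with the partial
R^2 of the disconnection term, ``t^2 / (t^2 + df)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .disconnect import DisconnectionMatrix

__all__ = [
    "UnitTestResult",
    "MassAnalysisResult",
    "covariate_regression",
    "mass_covariate_regression",
    "unit_inclusion_filter",
    "bh_fdr",
    "run_tract_analysis",
    "run_edge_analysis",
]

RESULT_COLUMNS = [
    "unit", "estimate", "t", "p", "adjusted_r2", "partial_r2",
    "n_damaged", "significant_bonferroni", "significant_fdr", "note",
]


@dataclass(frozen=True)
class UnitTestResult:
    unit: str
    estimate: float
    t: float
    p: float
    adjusted_r2: float
    partial_r2: float
    n_damaged: int
    significant_bonferroni: bool = False
    significant_fdr: bool = False
    note: str = ""


@dataclass(frozen=True)
class MassAnalysisResult:
    """One tract- or edge-level analysis: a result table plus its thresholds."""

    table: pd.DataFrame
    family_alpha: float
    alpha_bonferroni: float | None
    n_units_tested: int
    fdr_fallback_applied: bool
    status: str = "ok"  # "ok" or "no units tested"

    @property
    def significant_units(self) -> list[str]:
        if self.table.empty:
            return []
        col = "significant_fdr" if self.fdr_fallback_applied else "significant_bonferroni"
        return list(self.table.loc[self.table[col], "unit"])


def _fwl_stats(y: np.ndarray, D: np.ndarray, volume: np.ndarray):
    """Frisch–Waugh–Lovell: per-column b1 / t / R^2 for y ~ 1 + D_j + volume.

    Returns (b1, t, r2_full, rd_var_zero) arrays over the columns of D.
    Equivalent to solving each three-parameter model by normal equations.
    """
    n = len(y)
    Z = np.column_stack([np.ones(n), volume])
    # residualize on [1, volume]
    coef_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
    ry = y - Z @ coef_y
    coef_D, *_ = np.linalg.lstsq(Z, D, rcond=None)
    RD = D - Z @ coef_D
    rdrd = (RD * RD).sum(axis=0)
    degenerate = rdrd <= 1e-12 * max(np.abs(D).max() ** 2, 1.0)
    ryry = float(ry @ ry)
    with np.errstate(invalid="ignore", divide="ignore"):
        b1 = np.where(degenerate, 0.0, (RD.T @ ry) / np.maximum(rdrd, 1e-300))
        rss = np.maximum(ryry - b1**2 * rdrd, 0.0)
        df = n - 3
        sigma2 = rss / df
        se = np.sqrt(np.maximum(sigma2 / np.maximum(rdrd, 1e-300), 0.0))
        t = np.where(se > 0, b1 / np.maximum(se, 1e-300), np.sign(b1) * np.inf)
    t = np.where(degenerate, 0.0, t)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = np.where(degenerate, np.nan, 1.0 - rss / max(tss, 1e-300))
    return b1, t, r2, degenerate


def _p_from_t(t: np.ndarray, df: int, sidedness: str) -> np.ndarray:
    from scipy import stats

    if sidedness == "greater":
        return stats.t.sf(t, df)
    if sidedness == "two-sided":
        return 2.0 * stats.t.sf(np.abs(t), df)
    raise ValueError("sidedness must be 'greater' or 'two-sided'")


def adjusted_r2(r2: np.ndarray, n: int) -> np.ndarray:
    """Adjusted R^2 for the two-predictor model: 1 - (1-R^2)(n-1)/(n-3)."""
    return 1.0 - (1.0 - np.asarray(r2)) * (n - 1) / (n - 3)


def covariate_regression(
    severity: np.ndarray,
    disconnection_percent: np.ndarray,
    lesion_volume: np.ndarray,
    sidedness: str = "greater",
    unit: str = "",
) -> UnitTestResult:
    """OLS of severity on one unit's disconnection, controlling lesion volume."""
    y = np.asarray(severity, dtype=float)
    d = np.asarray(disconnection_percent, dtype=float)
    v = np.asarray(lesion_volume, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need n >= 4 (two predictors + intercept + 1 df)")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(d)) and np.all(np.isfinite(v))):
        raise ValueError("inputs must be finite")
    note = ""
    if np.ptp(d) == 0:
        return UnitTestResult(
            unit=unit, estimate=np.nan, t=np.nan, p=np.nan,
            adjusted_r2=np.nan, partial_r2=np.nan,
            n_damaged=int(np.sum(d > 0)), note="zero-variance disconnection: skipped",
        )
    # collinearity: disconnection an affine function of volume
    if np.ptp(v) > 0:
        corr = np.corrcoef(d, v)[0, 1]
        if abs(corr) > 1 - 1e-10:
            note = "collinear with volume: p from reduced model, flagged invalid"
    b1, t, r2, _ = _fwl_stats(y, d[:, None], v)
    df = n - 3
    p = _p_from_t(t, df, sidedness)
    if note:  # reduced model severity ~ 1 + disconnection
        X = np.column_stack([np.ones(n), d])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        sxx = float(np.sum((d - d.mean()) ** 2))
        se = np.sqrt(float(resid @ resid) / (n - 2) / sxx)
        t_red = coef[1] / se if se > 0 else np.sign(coef[1]) * np.inf
        p = _p_from_t(np.asarray([t_red]), n - 2, sidedness)
        t = np.asarray([t_red])
        b1 = np.asarray([coef[1]])
        r2 = np.asarray([np.nan])
    tval = float(t[0])
    partial = tval**2 / (tval**2 + df) if np.isfinite(tval) else 1.0
    return UnitTestResult(
        unit=unit,
        estimate=float(b1[0]),
        t=tval,
        p=float(p[0]),
        adjusted_r2=float(adjusted_r2(r2, n)[0]),
        partial_r2=float(partial),
        n_damaged=int(np.sum(d > 0)),
        note=note,
    )


def mass_covariate_regression(
    severity: np.ndarray,
    damage: pd.DataFrame,
    lesion_volume: np.ndarray,
    sidedness: str = "greater",
) -> pd.DataFrame:
    """Vectorized volume-controlled regressions over every column of ``damage``."""
    y = np.asarray(severity, dtype=float)
    v = np.asarray(lesion_volume, dtype=float)
    D = damage.to_numpy(dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need n >= 4")
    if np.ptp(y) == 0:
        raise ValueError("severity has zero variance")
    b1, t, r2, degenerate = _fwl_stats(y, D, v)
    df = n - 3
    p = _p_from_t(t, df, sidedness)
    p = np.where(degenerate, np.nan, p)
    with np.errstate(invalid="ignore"):
        partial = np.where(np.isfinite(t), t**2 / (t**2 + df), 1.0)
    out = pd.DataFrame(
        {
            "unit": list(damage.columns),
            "estimate": np.where(degenerate, np.nan, b1),
            "t": np.where(degenerate, np.nan, t),
            "p": p,
            "adjusted_r2": adjusted_r2(r2, n),
            "partial_r2": np.where(degenerate, np.nan, partial),
            "n_damaged": (D > 0).sum(axis=0),
            "note": np.where(degenerate, "zero-variance disconnection: skipped", ""),
        }
    )
    return out


def unit_inclusion_filter(
    per_patient_units: pd.DataFrame,
    min_patients: int = 10,
    damage_definition: str | float = "any_positive",
) -> np.ndarray:
    """Units damaged in strictly more than ``min_patients`` patients.

    ``damage_definition`` is either ``"any_positive"`` (a patient damages a
    unit at any disconnection > 0) or a number x meaning "at least x
    percent disconnection".
    """
    D = per_patient_units.to_numpy(dtype=float)
    if damage_definition == "any_positive":
        damaged = D > 0
    else:
        damaged = D >= float(damage_definition)
    return damaged.sum(axis=0) > min_patients


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def _finalize(
    table: pd.DataFrame, family_alpha: float, fdr_q: float
) -> MassAnalysisResult:
    tested = table["p"].notna()
    n_tested = int(tested.sum())
    if n_tested == 0:
        table = table.assign(significant_bonferroni=False, significant_fdr=False)
        return MassAnalysisResult(
            table=table[RESULT_COLUMNS],
            family_alpha=family_alpha,
            alpha_bonferroni=None,
            n_units_tested=0,
            fdr_fallback_applied=False,
            status="no units tested",
        )
    alpha_b = family_alpha / n_tested
    sig_b = np.zeros(len(table), dtype=bool)
    sig_b[tested.to_numpy()] = table.loc[tested, "p"].to_numpy() < alpha_b
    sig_f = np.zeros(len(table), dtype=bool)
    sig_f[tested.to_numpy()] = bh_fdr(table.loc[tested, "p"].to_numpy(), q=fdr_q)
    table = table.assign(significant_bonferroni=sig_b, significant_fdr=sig_f)
    return MassAnalysisResult(
        table=table[RESULT_COLUMNS].sort_values("adjusted_r2", ascending=False, ignore_index=True),
        family_alpha=family_alpha,
        alpha_bonferroni=alpha_b,
        n_units_tested=n_tested,
        fdr_fallback_applied=not sig_b.any(),
    )


def run_tract_analysis(
    severity: np.ndarray,
    tract_table: pd.DataFrame,
    lesion_volume: np.ndarray,
    family_alpha: float = 0.05,
    fdr_q: float = 0.05,
    sidedness: str = "greater",
) -> MassAnalysisResult:
    """One volume-controlled regression per tract, Bonferroni over all tracts.

    When no tract survives the Bonferroni threshold the 5% FDR step-up is
    applied as the documented fallback (``fdr_fallback_applied``).
    """
    table = mass_covariate_regression(severity, tract_table, lesion_volume, sidedness)
    return _finalize(table, family_alpha, fdr_q)


def edge_damage_table(matrices: list[DisconnectionMatrix]) -> pd.DataFrame:
    """Patients x deduplicated-defined-edges percent table; columns "a-b"."""
    m0 = matrices[0]
    iu = np.nonzero(np.triu(m0.defined))
    cols = [f"{m0.node_ids[i]}-{m0.node_ids[j]}" for i, j in zip(*iu)]
    data = np.stack([m.percent[iu] for m in matrices], axis=0)
    return pd.DataFrame(data, columns=cols)


def run_edge_analysis(
    severity: np.ndarray,
    matrices: list[DisconnectionMatrix],
    lesion_volume: np.ndarray,
    min_patients: int = 10,
    damage_definition: str | float = "any_positive",
    family_alpha: float = 0.05,
    fdr_q: float = 0.05,
    sidedness: str = "greater",
) -> MassAnalysisResult:
    """Volume-controlled regression per included deduplicated network edge.

    The inclusion filter (edges damaged in > ``min_patients`` patients)
    is applied first; the Bonferroni threshold divides by the included
    edge count.
    """
    damage = edge_damage_table(matrices)
    included = unit_inclusion_filter(damage, min_patients, damage_definition)
    damage = damage.loc[:, included]
    if damage.shape[1] == 0:
        empty = pd.DataFrame(columns=RESULT_COLUMNS)
        return MassAnalysisResult(
            table=empty,
            family_alpha=family_alpha,
            alpha_bonferroni=None,
            n_units_tested=0,
            fdr_fallback_applied=False,
            status="no units tested",
        )
    table = mass_covariate_regression(severity, damage, lesion_volume, sidedness)
    return _finalize(table, family_alpha, fdr_q)
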
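"""Cancellation-task scoring: asymmetries, severities, classification.

The task presents complete-target items among gapped distractors across a
page spanning normalized horizontal positions ``x_norm`` in [-1, 1]
(rightward positive), divided into five equal-width columns. Patients mark
the targets they find. From the marked set we score:

* ``ego_raw``  — hits in the two right-most columns minus hits in the two
  left-most columns (central column excluded). Positive = left egocentric
  neglect.
* ``allo_raw`` — left-gap false positives minus right-gap false positives.
  Positive = left allocentric neglect (the left side of objects is missed).
* ``coc``      — centre of cancellation: the mean ``x_norm`` of correctly
  marked targets (a plain normalized mean), the severity metric for
  egocentric neglect.
* ``allo_prop`` — the lateralized false-positive asymmetry divided by the
  number of correctly identified targets, the severity metric for
  allocentric neglect.

A record is valid only when at least five targets were correctly marked.
Impairment cut-offs follow the screening convention: ego |raw| > 2,
allo |raw| > 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CancellationLayout",
    "CancellationResponse",
    "NeglectScores",
    "InvalidResponseError",
    "UndefinedScoreError",
    "default_layout",
    "score_egocentric_raw",
    "score_allocentric_raw",
    "centre_of_cancellation",
    "allocentric_proportion",
    "score_response",
    "classify",
    "constrained_severity",
    "CONDITIONS",
]

TARGET = "target"
LEFT_GAP = "left_gap_distractor"
RIGHT_GAP = "right_gap_distractor"
ITEM_KINDS = (TARGET, LEFT_GAP, RIGHT_GAP)

CONDITIONS = ("left_ego", "right_ego", "left_allo", "right_allo")

EGO_CUTOFF = 2  # significant when |ego_raw| > 2
ALLO_CUTOFF = 1  # significant when |allo_raw| > 1
MIN_CORRECT = 5  # validity: at least five correctly marked targets


class InvalidResponseError(ValueError):
    """Marked item indices do not exist in the layout, or are duplicated."""


class UndefinedScoreError(ValueError):
    """A severity score has no defined value (e.g. zero marked targets)."""


@dataclass(frozen=True)
class CancellationLayout:
    """Item positions and kinds for one search array."""

    x_norm: np.ndarray
    y_norm: np.ndarray
    kind: np.ndarray  # entries from ITEM_KINDS
    n_columns: int = 5

    def __post_init__(self) -> None:
        x = np.asarray(self.x_norm, dtype=float)
        y = np.asarray(self.y_norm, dtype=float)
        kind = np.asarray(self.kind, dtype=object)
        if not (len(x) == len(y) == len(kind)):
            raise ValueError("x_norm, y_norm and kind must have equal length")
        if np.any(np.abs(x) > 1):
            raise ValueError("x_norm must lie in [-1, 1]")
        if not np.all(np.isin(kind, ITEM_KINDS)):
            raise ValueError(f"kinds must be among {ITEM_KINDS}")
        if not np.any(kind == TARGET):
            raise ValueError("layout needs at least one target")
        if self.n_columns < 3:
            raise ValueError("need at least 3 columns")
        object.__setattr__(self, "x_norm", x)
        object.__setattr__(self, "y_norm", y)
        object.__setattr__(self, "kind", kind)

    def __len__(self) -> int:
        return len(self.x_norm)

    def column_of(self, x: np.ndarray) -> np.ndarray:
        """Equal-width half-open column bins over [-1, 1]; rightmost closed."""
        edges = np.linspace(-1.0, 1.0, self.n_columns + 1)
        col = np.searchsorted(edges, np.asarray(x, dtype=float), side="right") - 1
        return np.clip(col, 0, self.n_columns - 1)

    @property
    def target_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kind == TARGET)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "x_norm": self.x_norm.tolist(),
            "y_norm": self.y_norm.tolist(),
            "kind": [str(k) for k in self.kind],
            "n_columns": self.n_columns,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CancellationLayout":
        p = json.loads(Path(path).read_text())
        return cls(
            x_norm=np.asarray(p["x_norm"]),
            y_norm=np.asarray(p["y_norm"]),
            kind=np.asarray(p["kind"], dtype=object),
            n_columns=int(p["n_columns"]),
        )


@dataclass(frozen=True)
class CancellationResponse:
    """Indices of the items a patient marked."""

    marked: np.ndarray

    def __post_init__(self) -> None:
        marked = np.asarray(self.marked, dtype=np.int64)
        if len(np.unique(marked)) != len(marked):
            raise InvalidResponseError("duplicate marked indices")
        object.__setattr__(self, "marked", marked)

    def validated(self, layout: CancellationLayout) -> np.ndarray:
        if len(self.marked) and (
            self.marked.min() < 0 or self.marked.max() >= len(layout)
        ):
            raise InvalidResponseError("marked index out of range for the layout")
        return self.marked


@dataclass(frozen=True)
class NeglectScores:
    ego_raw: int
    allo_raw: int
    coc: float  # nan when no target marked
    allo_prop: float  # nan when no target marked
    total_correct: int
    valid: bool
    ego_class: str  # none / left / right (withheld -> none when invalid)
    allo_class: str


def default_layout(
    n_targets: int = 50,
    n_distractors_per_side: int = 25,
    n_columns: int = 5,
    seed: int = 0,
) -> CancellationLayout:
    """Synthetic search array: jittered grid spanning the five columns.

    Targets and gapped distractors are spread uniformly over columns so
    the array is left-right balanced in expectation; the exact composition
    of the clinical array is not normative here and is fully configurable.
    """
    rng = np.random.default_rng(seed)
    items = []
    for kind, n in ((TARGET, n_targets), (LEFT_GAP, n_distractors_per_side),
                    (RIGHT_GAP, n_distractors_per_side)):
        # stratified by column for balance, jittered within column
        per_col = np.full(n_columns, n // n_columns)
        per_col[: n % n_columns] += 1
        rng.shuffle(per_col)
        width = 2.0 / n_columns
        for c, m in enumerate(per_col):
            x = -1.0 + width * (c + rng.uniform(0.05, 0.95, size=m))
            y = rng.uniform(-1, 1, size=m)
            for xi, yi in zip(x, y):
                items.append((xi, yi, kind))
    rng.shuffle(items)
    x, y, kind = zip(*items)
    return CancellationLayout(
        x_norm=np.asarray(x), y_norm=np.asarray(y),
        kind=np.asarray(kind, dtype=object), n_columns=n_columns,
    )


def _marked_by_kind(layout: CancellationLayout, response: CancellationResponse):
    marked = response.validated(layout)
    kinds = layout.kind[marked]
    return marked, kinds


def score_egocentric_raw(
    layout: CancellationLayout, response: CancellationResponse
) -> int:
    """Hits in the two right-most columns minus the two left-most; centre excluded."""
    if layout.n_columns != 5:
        raise ValueError("the egocentric asymmetry is defined over 5 columns")
    marked, kinds = _marked_by_kind(layout, response)
    hit_x = layout.x_norm[marked[kinds == TARGET]]
    col = layout.column_of(hit_x)
    right = int(np.sum(col >= 3))
    left = int(np.sum(col <= 1))
    return right - left


def score_allocentric_raw(
    layout: CancellationLayout, response: CancellationResponse
) -> int:
    """Left-gap false positives minus right-gap false positives."""
    _, kinds = _marked_by_kind(layout, response)
    return int(np.sum(kinds == LEFT_GAP) - np.sum(kinds == RIGHT_GAP))


def centre_of_cancellation(
    layout: CancellationLayout, response: CancellationResponse
) -> float:
    """Mean normalized x of correctly marked targets (positive = left neglect)."""
    marked, kinds = _marked_by_kind(layout, response)
    hit_x = layout.x_norm[marked[kinds == TARGET]]
    if len(hit_x) == 0:
        raise UndefinedScoreError("centre of cancellation needs >= 1 marked target")
    return float(np.mean(hit_x))


def allocentric_proportion(
    layout: CancellationLayout, response: CancellationResponse
) -> float:
    """Lateralized false-positive asymmetry over the correctly marked target count."""
    marked, kinds = _marked_by_kind(layout, response)
    total_correct = int(np.sum(kinds == TARGET))
    if total_correct == 0:
        raise UndefinedScoreError("allocentric proportion needs >= 1 correct target")
    return score_allocentric_raw(layout, response) / total_correct


def classify(ego_raw: int, allo_raw: int, total_correct: int) -> tuple[bool, str, str]:
    """(valid, ego_class, allo_class); classes withheld when invalid."""
    valid = total_correct >= MIN_CORRECT
    if not valid:
        return False, "none", "none"
    if ego_raw > EGO_CUTOFF:
        ego = "left"
    elif ego_raw < -EGO_CUTOFF:
        ego = "right"
    else:
        ego = "none"
    if allo_raw > ALLO_CUTOFF:
        allo = "left"
    elif allo_raw < -ALLO_CUTOFF:
        allo = "right"
    else:
        allo = "none"
    return True, ego, allo


def score_response(
    layout: CancellationLayout, response: CancellationResponse
) -> NeglectScores:
    marked, kinds = _marked_by_kind(layout, response)
    total_correct = int(np.sum(kinds == TARGET))
    ego_raw = score_egocentric_raw(layout, response)
    allo_raw = score_allocentric_raw(layout, response)
    if total_correct > 0:
        coc = centre_of_cancellation(layout, response)
        allo_prop = allocentric_proportion(layout, response)
    else:
        coc = float("nan")
        allo_prop = float("nan")
    valid, ego_class, allo_class = classify(ego_raw, allo_raw, total_correct)
    return NeglectScores(
        ego_raw=ego_raw,
        allo_raw=allo_raw,
        coc=coc,
        allo_prop=allo_prop,
        total_correct=total_correct,
        valid=valid,
        ego_class=ego_class,
        allo_class=allo_class,
    )


def constrained_severity(
    cohort_scores: list[NeglectScores], condition: str, signed: bool = False
) -> np.ndarray:
    """Severity vector for one analysis condition, zeros elsewhere.

    Patients classified with the condition of interest receive their
    severity metric (centre of cancellation for egocentric conditions,
    allocentric proportion for allocentric ones); every other patient —
    unimpaired, or impaired in the opposite lateralization — is
    constrained to exactly 0. By default the magnitude |severity| is used
    so every analysis tests a positive damage-severity association;
    ``signed=True`` keeps the original sign convention instead.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if any(not s.valid for s in cohort_scores):
        raise ValueError("invalid records present: filter the cohort first")
    side, frame = condition.split("_")
    out = np.zeros(len(cohort_scores), dtype=float)
    for i, s in enumerate(cohort_scores):
        if frame == "ego" and s.ego_class == side:
            out[i] = s.coc
        elif frame == "allo" and s.allo_class == side:
            out[i] = s.allo_prop
    return np.abs(out) if not signed else out


def scores_table(cohort_scores: list[NeglectScores]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in cohort_scores])
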
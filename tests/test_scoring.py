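import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neglectmap.scoring import (
    LEFT_GAP,
    RIGHT_GAP,
    TARGET,
    CancellationLayout,
    CancellationResponse,
    InvalidResponseError,
    UndefinedScoreError,
    allocentric_proportion,
    centre_of_cancellation,
    classify,
    constrained_severity,
    default_layout,
    score_allocentric_raw,
    score_egocentric_raw,
    score_response,
)


def grid_layout():
    """Symmetric layout: 10 targets per column at column centres, 4+4 gaps."""
    centres = np.array([-0.8, -0.4, 0.0, 0.4, 0.8])
    x = np.repeat(centres, 10)
    kind = np.array([TARGET] * 50, dtype=object)
    x = np.concatenate([x, [-0.7, -0.3, 0.3, 0.7] * 2])
    kind = np.concatenate([kind, [LEFT_GAP] * 4, [RIGHT_GAP] * 4])
    return CancellationLayout(x_norm=x, y_norm=np.zeros(len(x)), kind=kind)


def targets_in_column(layout, col):
    cols = layout.column_of(layout.x_norm)
    return np.flatnonzero((layout.kind == TARGET) & (cols == col))


def test_egocentric_raw_right_minus_left_excluding_centre():
    layout = grid_layout()
    marked = np.concatenate([
        targets_in_column(layout, 3)[:4], targets_in_column(layout, 4)[:4],  # 8 right
        targets_in_column(layout, 0)[:2],  # 2 left
        targets_in_column(layout, 2)[:5],  # central: excluded
    ])
    assert score_egocentric_raw(layout, CancellationResponse(marked)) == 6


def test_egocentric_raw_symmetric_and_central_cases():
    layout = grid_layout()
    all_targets = CancellationResponse(np.flatnonzero(layout.kind == TARGET))
    assert score_egocentric_raw(layout, all_targets) == 0
    central_only = CancellationResponse(targets_in_column(layout, 2))
    assert score_egocentric_raw(layout, central_only) == 0


def test_egocentric_raw_rejects_bad_indices():
    layout = grid_layout()
    with pytest.raises(InvalidResponseError):
        score_egocentric_raw(layout, CancellationResponse(np.array([len(layout)])))
    with pytest.raises(InvalidResponseError):
        CancellationResponse(np.array([1, 1]))


def test_allocentric_raw_left_minus_right_gaps():
    layout = grid_layout()
    lgaps = np.flatnonzero(layout.kind == LEFT_GAP)
    rgaps = np.flatnonzero(layout.kind == RIGHT_GAP)
    # 3 left-gap FPs, 1 right-gap FP -> +2
    resp = CancellationResponse(np.concatenate([lgaps[:3], rgaps[:1]]))
    assert score_allocentric_raw(layout, resp) == 2
    assert score_allocentric_raw(layout, CancellationResponse(np.array([], int))) == 0
    equal = CancellationResponse(np.concatenate([lgaps[:2], rgaps[:2]]))
    assert score_allocentric_raw(layout, equal) == 0


def test_centre_of_cancellation():
    layout = grid_layout()
    all_targets = CancellationResponse(np.flatnonzero(layout.kind == TARGET))
    assert centre_of_cancellation(layout, all_targets) == pytest.approx(0.0)
    x = np.array([0.2, 0.4, 0.9, 1.0])
    small = CancellationLayout(x_norm=x, y_norm=np.zeros(4),
                               kind=np.array([TARGET] * 4, dtype=object))
    assert centre_of_cancellation(small, CancellationResponse(np.array([3]))) == 1.0
    assert centre_of_cancellation(
        small, CancellationResponse(np.array([0, 1, 2]))
    ) == pytest.approx(0.5)  # arithmetic mean of {0.2, 0.4, 0.9}
    with pytest.raises(UndefinedScoreError):
        centre_of_cancellation(small, CancellationResponse(np.array([], int)))


def test_allocentric_proportion():
    layout = default_layout()
    targets = np.flatnonzero(layout.kind == TARGET)
    lgaps = np.flatnonzero(layout.kind == LEFT_GAP)
    rgaps = np.flatnonzero(layout.kind == RIGHT_GAP)
    resp = CancellationResponse(np.concatenate([targets[:20], lgaps[:5], rgaps[:1]]))
    assert allocentric_proportion(layout, resp) == pytest.approx(0.2)  # (5-1)/20
    assert allocentric_proportion(
        layout, CancellationResponse(targets[:20])
    ) == 0.0
    resp = CancellationResponse(np.concatenate([targets[:10], rgaps[:3]]))
    assert allocentric_proportion(layout, resp) == pytest.approx(-0.3)
    with pytest.raises(UndefinedScoreError):
        allocentric_proportion(layout, CancellationResponse(lgaps[:2]))


@pytest.mark.parametrize(
    "ego,allo,total,expect",
    [
        (3, 0, 20, (True, "left", "none")),
        (2, 0, 20, (True, "none", "none")),
        (-3, 0, 20, (True, "right", "none")),
        (0, 2, 20, (True, "none", "left")),
        (0, -2, 20, (True, "none", "right")),
        (0, 1, 20, (True, "none", "none")),
        (5, -2, 4, (False, "none", "none")),  # < 5 correct: invalid, withheld
    ],
)
def test_classification_cutoffs(ego, allo, total, expect):
    assert classify(ego, allo, total) == expect


def _scores(ego_class="none", allo_class="none", coc=0.0, allo_prop=0.0, valid=True):
    from neglectmap.scoring import NeglectScores

    return NeglectScores(ego_raw=0, allo_raw=0, coc=coc, allo_prop=allo_prop,
                         total_correct=20, valid=valid,
                         ego_class=ego_class, allo_class=allo_class)


def test_constrained_severity_zero_constraint():
    cohort = [
        _scores("left", coc=0.83),
        _scores("right", coc=-0.4),
        _scores(),  # unimpaired
        _scores("none", "left", allo_prop=0.25),
    ]
    left_ego = constrained_severity(cohort, "left_ego")
    np.testing.assert_allclose(left_ego, [0.83, 0.0, 0.0, 0.0])
    right_ego = constrained_severity(cohort, "right_ego")
    np.testing.assert_allclose(right_ego, [0.0, 0.4, 0.0, 0.0])  # magnitude default
    np.testing.assert_allclose(
        constrained_severity(cohort, "right_ego", signed=True), [0.0, -0.4, 0.0, 0.0]
    )
    np.testing.assert_allclose(
        constrained_severity(cohort, "left_allo"), [0.0, 0.0, 0.0, 0.25]
    )
    with pytest.raises(ValueError):
        constrained_severity(cohort + [_scores(valid=False)], "left_ego")


def _flip_layout(layout):
    kind = layout.kind.copy()
    kind[layout.kind == LEFT_GAP] = RIGHT_GAP
    kind[layout.kind == RIGHT_GAP] = LEFT_GAP
    return CancellationLayout(x_norm=-layout.x_norm, y_norm=layout.y_norm,
                              kind=kind, n_columns=layout.n_columns)


@settings(derandomize=True, max_examples=50)
@given(data=st.data())
def test_left_right_flip_negates_all_scores(data):
    """Mirroring the page negates ego_raw, coc, allo_raw and allo_prop exactly.

    Item positions avoid exact column boundaries, where the half-open
    binning breaks the symmetry by construction.
    """
    n_items = data.draw(st.integers(8, 30))
    xs = data.draw(
        st.lists(
            st.integers(-999, 999).filter(lambda v: abs(v) not in (200, 600)),
            min_size=n_items, max_size=n_items,
        )
    )
    kinds = data.draw(
        st.lists(st.sampled_from([TARGET, TARGET, LEFT_GAP, RIGHT_GAP]),
                 min_size=n_items, max_size=n_items)
    )
    if TARGET not in kinds:
        kinds[0] = TARGET
    layout = CancellationLayout(
        x_norm=np.asarray(xs) / 1000.0, y_norm=np.zeros(n_items),
        kind=np.asarray(kinds, dtype=object),
    )
    marked = data.draw(st.sets(st.integers(0, n_items - 1)))
    resp = CancellationResponse(np.asarray(sorted(marked), dtype=int))
    flipped = _flip_layout(layout)
    s0 = score_response(layout, resp)
    s1 = score_response(flipped, resp)
    assert s1.ego_raw == -s0.ego_raw
    assert s1.allo_raw == -s0.allo_raw
    if s0.total_correct > 0:
        assert s1.coc == pytest.approx(-s0.coc)
        assert s1.allo_prop == pytest.approx(-s0.allo_prop)


def test_extra_central_targets_shrink_coc_toward_zero():
    x = np.array([0.5, 0.9, 0.0, 0.0, 0.0])
    layout = CancellationLayout(x_norm=x, y_norm=np.zeros(5),
                                kind=np.array([TARGET] * 5, dtype=object))
    lateral = centre_of_cancellation(layout, CancellationResponse(np.array([0, 1])))
    for k in (1, 2, 3):
        with_central = centre_of_cancellation(
            layout, CancellationResponse(np.arange(2 + k))
        )
        assert abs(with_central) < abs(lateral)
        assert np.sign(with_central) == np.sign(lateral)
        lateral = with_central


def test_score_response_is_total_and_consistent():
    layout = default_layout()
    rng = np.random.default_rng(3)
    for _ in range(20):
        marked = np.flatnonzero(rng.random(len(layout)) < 0.5)
        s = score_response(layout, CancellationResponse(marked))
        assert s.ego_class in ("none", "left", "right")
        assert s.allo_class in ("none", "left", "right")
        if s.total_correct > 0:
            assert -1 <= s.coc <= 1
        if not s.valid:
            assert (s.ego_class, s.allo_class) == ("none", "none")
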
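"""Fixation soft-assignment, strategy regressors/regression, and gaze stats."""

from __future__ import annotations

import numpy as np
import pytest

from schemagaze.game_core import Move, apply_move, board_from_moves, mirror
from schemagaze.gaze import (
    EPOCH_MS,
    BoardLayout,
    FixationEvent,
    FixationMap,
    build_regressors,
    default_layout,
    fixation_map,
    prediction_confidence,
    prediction_surprise,
    read_fixations,
    strategy_regression,
    write_fixations,
    zscore_per_board,
)
from schemagaze.schema_model import move_distribution

from conftest import random_board


@pytest.fixture(scope="module")
def layout():
    return default_layout()


def fx(x, y, dur=1000.0, onset=0.0, epoch=0, trial="t0"):
    return FixationEvent("s0", 1, trial, epoch, onset, dur, x, y)


# ---------------------------------------------------------------------------
# File dialect
# ---------------------------------------------------------------------------


def test_fixation_round_trip(tmp_path, layout):
    events = [fx(500.0, 400.0), fx(700.0, 420.0, onset=1200.0),
              fx(650.0, 500.0, onset=5100.0, epoch=1)]
    path = tmp_path / "fix.csv"
    write_fixations(events, path)
    back = read_fixations(path, layout)
    assert back == events


def test_nonpositive_duration_dropped(tmp_path, layout):
    path = tmp_path / "fix.csv"
    path.write_text(
        "subject,session,trial,epoch,onset_ms,duration_ms,x_px,y_px\n"
        "s0,1,t0,0,0,500,100,100\n"
        "s0,1,t0,0,600,0,100,100\n"
    )
    events = read_fixations(path, layout)
    assert len(events) == 1


def test_missing_column_and_bad_epoch_rejected(tmp_path, layout):
    p1 = tmp_path / "a.csv"
    p1.write_text("subject,session,trial,onset_ms,duration_ms,x_px,y_px\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_fixations(p1, layout)
    p2 = tmp_path / "b.csv"
    p2.write_text(
        "subject,session,trial,epoch,onset_ms,duration_ms,x_px,y_px\n"
        "s0,1,t0,0,6000,500,100,100\n"
    )
    with pytest.raises(ValueError, match="epoch"):
        read_fixations(p2, layout)


# ---------------------------------------------------------------------------
# Soft assignment
# ---------------------------------------------------------------------------


def test_on_centre_fixation_concentrates(layout):
    cx, cy = layout.cell_center((1, 4))
    maps = fixation_map([fx(cx, cy)], layout)
    m = maps[("s0", 1, "t0", 0)]
    idx = 1 * 9 + 4
    assert m.weights[idx] >= 999.999
    assert m.total_ms == pytest.approx(1000.0)


def test_equidistant_fixation_splits_evenly(layout):
    cx, cy = layout.cell_center((2, 3))
    maps = fixation_map([fx(cx + layout.square_px / 2, cy)], layout)
    m = maps[("s0", 1, "t0", 0)]
    assert m.weights[2 * 9 + 3] == pytest.approx(500.0, abs=1e-6)
    assert m.weights[2 * 9 + 4] == pytest.approx(500.0, abs=1e-6)


def test_fixation_mass_conserved(rng, layout):
    centers = layout.square_centers()
    lo, hi = centers.min(axis=0) - 100, centers.max(axis=0) + 100
    events = [
        fx(float(rng.uniform(lo[0], hi[0])), float(rng.uniform(lo[1], hi[1])),
           dur=float(rng.uniform(50, 800)), onset=float(rng.uniform(0, 4000)))
        for _ in range(40)
    ]
    maps = fixation_map(events, layout)
    m = maps[("s0", 1, "t0", 0)]
    # retained mass equals the summed (possibly truncated) durations of
    # retained fixations
    assert m.weights.sum() == pytest.approx(m.total_ms, rel=1e-9)


def test_off_board_fixation_discarded(layout):
    maps = fixation_map([fx(0.0, 0.0)], layout)  # far from the board
    m = maps[("s0", 1, "t0", 0)]
    assert m.n_discarded == 1
    assert m.total_ms == 0.0


def test_epoch_boundary_truncation(layout):
    cx, cy = layout.cell_center((0, 0))
    # starts at 4.5 s and would run 1.5 s; only 0.5 s falls in epoch 0
    maps = fixation_map([fx(cx, cy, dur=1500.0, onset=4500.0)], layout)
    assert maps[("s0", 1, "t0", 0)].total_ms == pytest.approx(500.0)


# ---------------------------------------------------------------------------
# Regressors
# ---------------------------------------------------------------------------


def epoch_context(stim, model, upto):
    board = stim.initial_board
    history = []
    for mv in stim.moves[:upto]:
        board = apply_move(board, mv)
        history.append(mv)
    dist = move_distribution(model, board)
    return board, history, dist


def test_initial_board_regressors(teacher, stimuli):
    stim = stimuli[0]
    board, history, dist = epoch_context(stim, teacher, 0)
    rs = build_regressors(board, history, teacher, dist)
    occ = (board.grid.ravel() != 0).astype(float)
    assert not rs.R[0].any()
    assert not rs.R[4].any()
    assert np.array_equal(rs.R[5], occ)


def test_prediction_regressor_structure(teacher, stimuli):
    stim = stimuli[0]
    board, history, dist = epoch_context(stim, teacher, 2)
    rs = build_regressors(board, history, teacher, dist)
    empty = board.grid.ravel() == 0
    assert rs.R[2][empty].sum() == pytest.approx(1.0, abs=1e-12)
    occ_vals = rs.R[2][~empty]
    assert np.allclose(occ_vals, rs.R[2][empty].mean())


def test_related_squares_match_chebyshev_oracle(rng, teacher):
    for _ in range(50):
        board = random_board(rng, int(rng.integers(6, 20)))
        if board.n_pieces < 2 or not board.history:
            continue
        dist = move_distribution(teacher, board)
        history = list(board.history)
        rs = build_regressors(board, history, teacher, dist)
        last = history[-1]
        occ = board.grid.ravel() != 0
        p = dist.as_vector()
        empty = ~occ
        for i in range(36):
            r, c = divmod(i, 9)
            cheb = max(abs(r - last.row), abs(c - last.col))
            expect_r2 = 1.0 if (occ[i] and cheb <= 3 and (r, c) != last.cell) else 0.0
            assert rs.R[1][i] == expect_r2
            if occ[i]:
                total = sum(
                    p[j] for j in range(36)
                    if empty[j]
                    and max(abs(j // 9 - r), abs(j % 9 - c)) <= 3
                )
                assert rs.R[3][i] == pytest.approx(total, abs=1e-12)


def test_zscore_per_board():
    assert np.array_equal(zscore_per_board(np.full(36, 3.0)), np.zeros(36))
    v = np.arange(36.0)
    z = zscore_per_board(v)
    assert abs(z.mean()) < 1e-12
    assert z.std() == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(zscore_per_board(z), z)


# ---------------------------------------------------------------------------
# Strategy regression
# ---------------------------------------------------------------------------


def build_epoch_sets(teacher, stimuli, n):
    """Regressor sets for the first n epochs across stimuli."""
    out = []
    for stim in stimuli:
        board = stim.initial_board
        history = []
        for mv in stim.moves:
            dist = move_distribution(teacher, board)
            out.append(build_regressors(board, history, teacher, dist))
            board = apply_move(board, mv)
            history.append(mv)
            if len(out) >= n:
                return out
    return out


def synth_maps(regs, beta, noise_sd, rng):
    """Maps = mixture + orthogonal residual filling per-board variance to 1.

    The regression z-scores each map within board, so exact coefficient
    recovery requires the constructed map to already have unit variance; the
    residual is orthogonalized against the design, leaving the coefficients
    untouched.
    """
    maps = []
    for i, rs in enumerate(regs):
        X = np.column_stack([zscore_per_board(r) for r in rs.R])
        combo = X @ np.asarray(beta, dtype=float)
        basis = np.column_stack([np.ones(36), X])
        v = rng.standard_normal(36)
        resid = v - basis @ np.linalg.lstsq(basis, v, rcond=None)[0]
        var_fill = 1.0 - combo.var() - noise_sd**2
        assert var_fill > 0, "mixture too strong for a unit-variance map"
        resid *= np.sqrt(var_fill) / resid.std()
        y = combo + resid
        if noise_sd:
            y = y + rng.normal(0, noise_sd, size=36)
        maps.append(FixationMap(("s0", 1, f"t{i}", 0), y, float(abs(y).sum()), 1))
    return maps


def test_noiseless_recovery_exact(teacher, stimuli, rng):
    regs = build_epoch_sets(teacher, stimuli, 40)
    beta = np.array([0.3, -0.2, 0.7, 0.1, 0.25, -0.4])
    maps = synth_maps(regs, beta, 0.0, rng)
    fit = strategy_regression(maps, regs, level="session")
    assert np.allclose(fit.beta, beta, atol=1e-8)


def test_noisy_recovery_within_tolerance(teacher, stimuli, rng):
    regs = build_epoch_sets(teacher, stimuli, 200)
    beta = np.array([0.2, 0.1, 0.4, 0.05, 0.2, -0.25])
    maps = synth_maps(regs, beta, 0.5, rng)
    fit = strategy_regression(maps, regs, level="session")
    assert np.all(np.abs(fit.beta - beta) <= 0.05)


def test_epoch_permutation_invariance(teacher, stimuli, rng):
    regs = build_epoch_sets(teacher, stimuli, 30)
    beta = np.array([0.2, 0.1, 0.5, 0.0, 0.3, -0.2])
    maps = synth_maps(regs, beta, 0.3, rng)
    fit1 = strategy_regression(maps, regs, level="session")
    order = rng.permutation(len(maps))
    fit2 = strategy_regression([maps[i] for i in order],
                               [regs[i] for i in order], level="session")
    assert np.allclose(fit1.beta, fit2.beta, atol=1e-12)


def test_board_level_returns_per_epoch(teacher, stimuli, rng):
    regs = build_epoch_sets(teacher, stimuli, 10)
    beta = np.array([0.0, 0.0, 0.8, 0.0, 0.0, 0.2])
    maps = synth_maps(regs, beta, 0.0, rng)
    fits = strategy_regression(maps, regs, level="board")
    assert len(fits) == 10
    for f in fits:
        assert f.level == "board"


# ---------------------------------------------------------------------------
# Confidence and surprise
# ---------------------------------------------------------------------------


def board_with(n_pieces, rng):
    return random_board(rng, n_pieces)


def make_map(weights):
    w = np.asarray(weights, dtype=float)
    return FixationMap(("s0", 1, "t0", 0), w, float(w.sum()), 1)


def test_confidence_closed_forms(rng):
    board = random_board(rng, 16)
    empty_idx = np.nonzero(board.grid.ravel() == 0)[0]
    n_empty = len(empty_idx)
    # all time on one empty square
    w = np.zeros(36)
    w[empty_idx[0]] = 1000.0
    assert prediction_confidence(make_map(w), board) == pytest.approx(
        np.log(n_empty)
    )
    # uniform over empty squares
    w = np.zeros(36)
    w[empty_idx] = 1000.0 / n_empty
    assert prediction_confidence(make_map(w), board) == pytest.approx(0.0, abs=1e-12)
    # all time on occupied squares
    occ_idx = np.nonzero(board.grid.ravel() != 0)[0]
    w = np.zeros(36)
    w[occ_idx] = 10.0
    assert prediction_confidence(make_map(w), board) == 0.0


def test_confidence_bounds(rng):
    for _ in range(50):
        board = random_board(rng, int(rng.integers(5, 30)))
        w = rng.uniform(0, 10, size=36)
        conf = prediction_confidence(make_map(w), board)
        n_empty = int((board.grid == 0).sum())
        assert 0 <= conf <= np.log(n_empty) + 1e-12


def test_surprise_closed_forms():
    w = np.zeros(36)
    w[7] = 1000.0
    assert prediction_surprise(make_map(w), (0, 7)) == pytest.approx(0.0)
    w2 = np.zeros(36)
    w2[7] = 500.0
    w2[8] = 500.0
    assert prediction_surprise(make_map(w2), (0, 7)) == pytest.approx(np.log(2))
    w3 = np.zeros(36)
    w3[8] = 1000.0
    assert prediction_surprise(make_map(w3), (0, 7)) == pytest.approx(
        -np.log(1e-3)
    )


def test_zero_time_epoch_gives_missing():
    empty_map = FixationMap(("s0", 1, "t0", 0), np.zeros(36), 0.0, 0)
    assert prediction_surprise(empty_map, (0, 0)) is None


def test_gaze_stats_mirror_invariance(rng, teacher):
    # mirroring board and gaze jointly leaves confidence/surprise unchanged
    board = random_board(rng, 12)
    w = rng.uniform(0, 5, size=(4, 9))
    m = make_map(w.ravel())
    m_mirror = make_map(w[:, ::-1].ravel())
    bm = mirror(board, "horizontal")
    assert prediction_confidence(m, board) == pytest.approx(
        prediction_confidence(m_mirror, bm), abs=1e-12
    )
    nm = (2, 3)
    assert prediction_surprise(m, nm) == pytest.approx(
        prediction_surprise(m_mirror, (2, 8 - 3)), abs=1e-12
    )
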
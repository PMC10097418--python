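"""Board rules, window enumeration, and move features vs brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from schemagaze.game_core import (
    FEATURE_NAMES,
    BoardState,
    Color,
    IllegalMoveError,
    InvalidBoardError,
    Move,
    apply_move,
    board_from_moves,
    check_win,
    empty_board,
    enumerate_windows,
    extract_features,
    features_for_board,
    legal_moves,
    mirror,
    mirror_cell,
    read_games,
    render_board,
    write_games,
)

from conftest import random_board

# ---------------------------------------------------------------------------
# Independent naive oracles (no shared code with the implementation)
# ---------------------------------------------------------------------------


def oracle_windows():
    """Brute force: every set of 4 contiguous collinear in-bounds cells."""
    wins = set()
    for r in range(4):
        for c in range(9):
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                cells = [(r + i * dr, c + i * dc) for i in range(4)]
                if all(0 <= rr < 4 and 0 <= cc < 9 for rr, cc in cells):
                    wins.add(tuple(cells))
    return wins


def oracle_check_win(grid):
    winners = set()
    for cells in oracle_windows():
        vals = {int(grid[r, c]) for r, c in cells}
        if len(vals) == 1 and vals != {0}:
            winners.add(vals.pop())
    return winners


def oracle_features(grid, to_move, cand):
    """Naive per-window feature counts, written independently."""
    me = int(to_move)
    opp = 3 - me
    r0, c0 = cand
    counts = dict.fromkeys(FEATURE_NAMES, 0)
    counts["f_hc"] = abs(c0 - 4)
    counts["f_vc"] = abs(r0 - 1.5)
    post = grid.copy()
    post[r0, c0] = me
    for cells in oracle_windows():
        if cand not in cells:
            continue
        own = [i for i, (r, c) in enumerate(cells) if post[r, c] == me]
        theirs = [i for i, (r, c) in enumerate(cells) if post[r, c] == opp]
        horiz = len({r for r, _ in cells}) == 1
        if not theirs:
            k = len(own)
            contiguous = max(own) - min(own) == k - 1 if own else False
            if k == 4:
                counts["f_four"] += 1
            elif k == 3:
                if contiguous and horiz:
                    row = cells[0][0]
                    cols = sorted(cells[i][1] for i in own)
                    left, right = cols[0] - 1, cols[-1] + 1
                    if (0 <= left and right <= 8 and post[row, left] == 0
                            and post[row, right] == 0):
                        counts["f3_open_h"] += 1
                    else:
                        counts["f3_conn"] += 1
                elif contiguous:
                    counts["f3_conn"] += 1
                else:
                    counts["f3_disc"] += 1
            elif k == 2:
                counts["f2_conn" if contiguous else "f2_disc"] += 1
        elif len(own) == 1:  # only the candidate: a pure block
            k = len(theirs)
            if k == 3:
                counts["f_block3"] += 1
            elif k == 2:
                open_pair = False
                if horiz and theirs[1] - theirs[0] == 1:
                    row = cells[0][0]
                    cols = sorted(cells[i][1] for i in theirs)
                    left, right = cols[0] - 1, cols[-1] + 1
                    if (0 <= left and right <= 8 and grid[row, left] == 0
                            and grid[row, right] == 0
                            and (r0, c0) in ((row, left), (row, right))):
                        open_pair = True
                counts["fb2_open_h" if open_pair else "fb2_other"] += 1
    return counts


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


def test_window_enumeration_matches_brute_force():
    wins = enumerate_windows()
    assert len(wins) == 45
    impl = {w.cells for w in wins}
    oracle = oracle_windows()
    # orientation is irrelevant to set equality; reversed diagonals coincide
    norm = {min(c, tuple(reversed(c))) for c in oracle}
    assert {min(c, tuple(reversed(c))) for c in impl} == norm
    by_orient = {}
    for w in wins:
        by_orient[w.orientation] = by_orient.get(w.orientation, 0) + 1
    assert by_orient == {"h": 24, "v": 9, "d": 6, "a": 6}
    for w in wins:
        assert all(0 <= r < 4 and 0 <= c < 9 for r, c in w.cells)


def test_every_cell_in_some_window():
    covered = {c for w in enumerate_windows() for c in w.cells}
    assert covered == {(r, c) for r in range(4) for c in range(9)}


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------


def test_legal_moves_counts():
    b = empty_board()
    assert len(legal_moves(b)) == 36
    for i, cell in enumerate([(0, 0), (0, 1), (1, 1), (2, 2), (3, 3)]):
        b = apply_move(b, Move(b.to_move, *cell, i + 1))
    assert len(legal_moves(b)) == 31
    grid = np.zeros((4, 9), dtype=np.int8)
    grid[::, ::2] = 1
    grid[::, 1::2] = 2
    full = BoardState(grid, Color.WHITE)
    assert legal_moves(full) == set()


def test_apply_move_value_semantics_and_errors():
    b0 = empty_board()
    b1 = apply_move(b0, Move(Color.BLACK, 1, 4, 1))
    assert b0.n_pieces == 0 and b1.n_pieces == 1
    assert b1.to_move is Color.WHITE
    with pytest.raises(IllegalMoveError):
        apply_move(b1, Move(Color.WHITE, 1, 4, 2))  # occupied
    with pytest.raises(IllegalMoveError):
        apply_move(b1, Move(Color.BLACK, 0, 0, 3))  # wrong colour to move


def test_replay_reproduces_grid(rng):
    board = random_board(rng, 20)
    replay = board_from_moves(board.history)
    assert replay == board
    board.validate()


def test_check_win_basics():
    assert check_win(empty_board()) is None
    moves = [
        Move(Color.BLACK, 0, 0, 1), Move(Color.WHITE, 3, 0, 2),
        Move(Color.BLACK, 0, 1, 3), Move(Color.WHITE, 3, 1, 4),
        Move(Color.BLACK, 0, 2, 5), Move(Color.WHITE, 3, 2, 6),
        Move(Color.BLACK, 0, 3, 7),
    ]
    assert check_win(board_from_moves(moves)) is Color.BLACK


def test_check_win_agrees_with_naive_scan(rng):
    for _ in range(1000):
        board = random_board(rng, allow_win=True)
        winners = oracle_check_win(board.grid)
        got = check_win(board)
        assert (got.value if got else None) == (winners.pop() if winners else None)


def test_unfinished_history_never_wins(rng):
    # random_board rejects winning moves, so a replayed prefix has no winner
    for _ in range(50):
        board = random_board(rng, 25)
        assert check_win(board) is None


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def test_empty_board_features():
    fv = extract_features(empty_board(), (1, 4))
    assert fv.f_hc == 0 and fv.f_vc == 0.5
    assert all(getattr(fv, n) == 0 for n in FEATURE_NAMES[2:])


def test_open_triple_detected():
    # black at (0,1),(0,2); placing at (0,3) forms an open horizontal triple
    moves = [
        Move(Color.BLACK, 0, 1, 1), Move(Color.WHITE, 3, 0, 2),
        Move(Color.BLACK, 0, 2, 3), Move(Color.WHITE, 3, 1, 4),
    ]
    board = board_from_moves(moves)
    fv = extract_features(board, (0, 3))
    assert fv.f_four == 0
    assert fv.f3_open_h >= 1
    ora = oracle_features(board.grid, board.to_move, (0, 3))
    assert fv.as_array().tolist() == [ora[n] for n in FEATURE_NAMES]


@pytest.mark.parametrize("n_pairs", [200])
def test_features_match_naive_oracle(rng, n_pairs):
    for _ in range(n_pairs):
        board = random_board(rng)
        cells = sorted(legal_moves(board))
        if not cells:
            continue
        cand = cells[rng.integers(len(cells))]
        fv = extract_features(board, cand)
        ora = oracle_features(board.grid, board.to_move, cand)
        assert fv.as_array().tolist() == [ora[n] for n in FEATURE_NAMES], (
            f"mismatch at {cand}\n{render_board(board)}"
        )


def test_features_for_board_matches_per_candidate(rng):
    for _ in range(20):
        board = random_board(rng)
        cells, F = features_for_board(board)
        for cell, row in zip(cells, F):
            assert np.allclose(row, extract_features(board, cell).as_array())


@pytest.mark.parametrize("axis", ["horizontal", "vertical"])
def test_feature_mirror_invariance(rng, axis):
    for _ in range(100):
        board = random_board(rng)
        cells = sorted(legal_moves(board))
        if not cells:
            continue
        cand = cells[rng.integers(len(cells))]
        fv = extract_features(board, cand)
        fv_m = extract_features(mirror(board, axis), mirror_cell(cand, axis))
        assert fv == fv_m


def test_illegal_candidate_rejected():
    b = apply_move(empty_board(), Move(Color.BLACK, 1, 4, 1))
    with pytest.raises(IllegalMoveError):
        extract_features(b, (1, 4))


# ---------------------------------------------------------------------------
# Mirror
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("axis", ["horizontal", "vertical"])
def test_mirror_is_involution(rng, axis):
    board = random_board(rng, 15)
    assert mirror(mirror(board, axis), axis) == board
    assert mirror(board, axis).n_pieces == board.n_pieces


def test_check_win_commutes_with_mirror(rng):
    for _ in range(500):
        board = random_board(rng, allow_win=True)
        for axis in ("horizontal", "vertical"):
            assert check_win(board) == check_win(mirror(board, axis))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def test_game_file_round_trip(tmp_path, game_pool):
    path = tmp_path / "games.csv"
    write_games({g.game_id: g.moves for g in game_pool[:5]}, path)
    back = read_games(path)
    assert set(back) == {g.game_id for g in game_pool[:5]}
    for g in game_pool[:5]:
        assert tuple(back[g.game_id]) == g.moves


def test_invalid_board_rejected():
    grid = np.zeros((4, 9), dtype=np.int8)
    grid[0, :3] = Color.WHITE  # white ahead of black: impossible
    with pytest.raises(InvalidBoardError):
        BoardState(grid, Color.BLACK).validate()
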
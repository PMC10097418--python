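"""Shared fixtures: random legal boards, a teacher agent, small game pools."""

from __future__ import annotations

import numpy as np
import pytest

from schemagaze.game_core import (
    BoardState,
    Color,
    Move,
    apply_move,
    check_win,
    empty_board,
    legal_moves,
)
from schemagaze.synthetic_data import (
    default_teacher,
    extract_stimuli,
    generate_game_pool,
)


def random_board(rng: np.random.Generator, n_moves: int | None = None,
                 allow_win: bool = False) -> BoardState:
    """A legal board produced by replaying random alternating moves.

    Stops early if a win appears and ``allow_win`` is false.
    """
    if n_moves is None:
        n_moves = int(rng.integers(0, 30))
    board = empty_board()
    for _ in range(n_moves):
        cells = sorted(legal_moves(board))
        if not cells:
            break
        r, c = cells[rng.integers(len(cells))]
        nxt = apply_move(board, Move(board.to_move, r, c, len(board.history) + 1))
        if check_win(nxt) is not None:
            if allow_win:
                board = nxt
            break
        board = nxt
    return board


@pytest.fixture(scope="session")
def teacher():
    return default_teacher()


@pytest.fixture(scope="session")
def game_pool(teacher):
    """30 decisive teacher games of 17-35 moves (seeded)."""
    return generate_game_pool(teacher, 30, seed=11)


@pytest.fixture(scope="session")
def stimuli(game_pool):
    """A full 30-trial stimulus set (10 win-ending)."""
    return extract_stimuli(game_pool, n_trials=30, n_win=10, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
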
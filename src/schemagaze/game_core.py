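"""Board representation and move features for four-in-a-row on a 4x9 board.

Four-in-a-row is a two-player generalisation of tic-tac-toe: black and white
alternate placing pieces on any empty cell of a 4-row by 9-column grid, and
the first player to own four collinear contiguous cells (horizontally,
vertically or diagonally) wins.  Black moves first.

Coordinates are 0-based: rows 0-3 top to bottom, columns 0-8 left to right.
The unit of all pattern counting is the *window*: one of the 45 maximal
4-cell contiguous lines on the board.  A candidate move's features count, per
window, the k-in-a-row patterns it completes for the mover and the opponent
patterns it blocks; see :func:`extract_features`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_ROWS = 4
N_COLS = 9
N_CELLS = N_ROWS * N_COLS

__all__ = [
    "Color",
    "Move",
    "BoardState",
    "LineWindow",
    "FeatureVector",
    "FEATURE_NAMES",
    "IllegalMoveError",
    "InvalidBoardError",
    "empty_board",
    "legal_moves",
    "apply_move",
    "enumerate_windows",
    "check_win",
    "extract_features",
    "features_for_board",
    "mirror",
    "mirror_cell",
    "read_games",
    "write_games",
    "board_from_moves",
    "render_board",
]


class Color(IntEnum):
    """Piece colours; the integer values are the grid cell codes."""

    BLACK = 1
    WHITE = 2

    @property
    def other(self) -> "Color":
        return Color.WHITE if self is Color.BLACK else Color.BLACK

    @property
    def letter(self) -> str:
        return "B" if self is Color.BLACK else "W"

    @staticmethod
    def from_letter(s: str) -> "Color":
        s = s.strip().upper()
        if s == "B":
            return Color.BLACK
        if s == "W":
            return Color.WHITE
        raise ValueError(f"unknown colour letter {s!r}")


EMPTY = 0


class IllegalMoveError(ValueError):
    """A move targets an occupied cell or is played out of turn."""


class InvalidBoardError(ValueError):
    """A board violates the alternation or replay invariants."""


@dataclass(frozen=True)
class Move:
    """A single placement: colour, cell, and 1-based ordinal within its game."""

    color: Color
    row: int
    col: int
    ordinal: int

    def __post_init__(self) -> None:
        if not (0 <= self.row < N_ROWS and 0 <= self.col < N_COLS):
            raise ValueError(f"move ({self.row},{self.col}) out of bounds")
        if self.ordinal >= 1:
            expected = Color.BLACK if self.ordinal % 2 == 1 else Color.WHITE
            if self.color is not expected:
                raise ValueError(
                    f"ordinal {self.ordinal} must be {expected.name} (black moves first)"
                )

    @property
    def cell(self) -> tuple[int, int]:
        return (self.row, self.col)


@dataclass(frozen=True)
class BoardState:
    """Immutable board: 4x9 grid, side to move, and the move history.

    ``grid`` holds 0 (empty), 1 (black) or 2 (white).  Use :func:`apply_move`
    to advance; the input state is never modified.
    """

    grid: np.ndarray
    to_move: Color = Color.BLACK
    history: tuple[Move, ...] = ()

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=np.int8)
        if g.shape != (N_ROWS, N_COLS):
            raise InvalidBoardError(f"grid shape {g.shape} != (4, 9)")
        object.__setattr__(self, "grid", g)

    def validate(self) -> None:
        """Check piece-count alternation and that history replays the grid."""
        nb = int(np.sum(self.grid == Color.BLACK))
        nw = int(np.sum(self.grid == Color.WHITE))
        if not (0 <= nb - nw <= 1):
            raise InvalidBoardError(
                f"black must have equal or one more piece than white (got {nb} vs {nw})"
            )
        expected = Color.BLACK if nb == nw else Color.WHITE
        if self.to_move is not expected:
            raise InvalidBoardError(
                f"to_move {self.to_move.name} inconsistent with counts {nb}/{nw}"
            )
        if self.history:
            g = np.zeros((N_ROWS, N_COLS), dtype=np.int8)
            for mv in self.history:
                if g[mv.row, mv.col] != EMPTY:
                    raise InvalidBoardError(
                        f"history occupies ({mv.row},{mv.col}) twice"
                    )
                g[mv.row, mv.col] = mv.color
            if not np.array_equal(g, self.grid):
                raise InvalidBoardError("history does not replay to the grid")

    @property
    def n_pieces(self) -> int:
        return int(np.count_nonzero(self.grid))

    def is_full(self) -> bool:
        return self.n_pieces == N_CELLS

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BoardState):
            return NotImplemented
        return (
            np.array_equal(self.grid, other.grid)
            and self.to_move is other.to_move
            and self.history == other.history
        )

    def __hash__(self) -> int:
        return hash((self.grid.tobytes(), self.to_move, self.history))


def empty_board() -> BoardState:
    return BoardState(np.zeros((N_ROWS, N_COLS), dtype=np.int8))


def board_from_moves(moves: Sequence[Move]) -> BoardState:
    """Replay a move list from the empty board."""
    board = empty_board()
    for mv in moves:
        board = apply_move(board, mv)
    return board


def legal_moves(board: BoardState) -> set[tuple[int, int]]:
    """All empty cells; exactly the legal placements for the side to move."""
    rows, cols = np.nonzero(board.grid == EMPTY)
    return set(zip(rows.tolist(), cols.tolist()))


def apply_move(board: BoardState, move: Move) -> BoardState:
    """Place ``move`` and return the new state; ``board`` is unmodified."""
    if move.color is not board.to_move:
        raise IllegalMoveError(
            f"{move.color.name} played but {board.to_move.name} is to move"
        )
    if board.grid[move.row, move.col] != EMPTY:
        raise IllegalMoveError(f"cell ({move.row},{move.col}) is occupied")
    grid = board.grid.copy()
    grid[move.row, move.col] = move.color
    return BoardState(grid, move.color.other, board.history + (move,))


# ---------------------------------------------------------------------------
# Windows: the 45 maximal 4-cell contiguous lines
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LineWindow:
    """Four collinear contiguous cells, ordered along the line."""

    cells: tuple[tuple[int, int], ...]
    orientation: str  # "h", "v", "d" (down-right) or "a" (down-left / anti)

    def __post_init__(self) -> None:
        assert len(self.cells) == 4


def _build_windows() -> list[LineWindow]:
    wins: list[LineWindow] = []
    for r in range(N_ROWS):
        for c in range(N_COLS - 3):
            wins.append(LineWindow(tuple((r, c + i) for i in range(4)), "h"))
    for r in range(N_ROWS - 3):
        for c in range(N_COLS):
            wins.append(LineWindow(tuple((r + i, c) for i in range(4)), "v"))
    for r in range(N_ROWS - 3):
        for c in range(N_COLS - 3):
            wins.append(LineWindow(tuple((r + i, c + i) for i in range(4)), "d"))
    for r in range(N_ROWS - 3):
        for c in range(3, N_COLS):
            wins.append(LineWindow(tuple((r + i, c - i) for i in range(4)), "a"))
    return wins


_WINDOWS: list[LineWindow] = _build_windows()
# flat cell index per window, shape (45, 4)
_WIN_CELLS = np.array(
    [[r * N_COLS + c for (r, c) in w.cells] for w in _WINDOWS], dtype=np.intp
)
_WIN_IS_H = np.array([w.orientation == "h" for w in _WINDOWS])
# per flat cell: list of (window index, position within window)
_CELL_WINDOWS: list[list[tuple[int, int]]] = [[] for _ in range(N_CELLS)]
for _wi, _w in enumerate(_WINDOWS):
    for _pos, (_r, _c) in enumerate(_w.cells):
        _CELL_WINDOWS[_r * N_COLS + _c].append((_wi, _pos))


def enumerate_windows() -> list[LineWindow]:
    """All 45 length-4 contiguous lines, in deterministic order."""
    return list(_WINDOWS)


def check_win(board: BoardState) -> Color | None:
    """Colour owning a fully occupied single-colour window, or ``None``."""
    flat = board.grid.ravel()
    in_win = flat[_WIN_CELLS]  # (45, 4)
    black = np.any(np.all(in_win == Color.BLACK, axis=1))
    white = np.any(np.all(in_win == Color.WHITE, axis=1))
    if black and white:
        raise InvalidBoardError("both colours have four in a row")
    if black:
        return Color.BLACK
    if white:
        return Color.WHITE
    return None


# ---------------------------------------------------------------------------
# Move features
# ---------------------------------------------------------------------------

FEATURE_NAMES: tuple[str, ...] = (
    "f_hc",
    "f_vc",
    "f_four",
    "f3_conn",
    "f3_disc",
    "f3_open_h",
    "f2_conn",
    "f2_disc",
    "f_block3",
    "fb2_open_h",
    "fb2_other",
)
N_FEATURES = len(FEATURE_NAMES)


@dataclass(frozen=True)
class FeatureVector:
    """The 11 move features the gameplay model weights.

    Pattern counts are evaluated per window on the board *after* the
    candidate is hypothetically placed; blocking counts use the pre-placement
    opponent occupancy.  ``f_hc``/``f_vc`` are distances from the horizontal /
    vertical board centre in column / row units.
    """

    f_hc: float
    f_vc: float
    f_four: int
    f3_conn: int
    f3_disc: int
    f3_open_h: int
    f2_conn: int
    f2_disc: int
    f_block3: int
    fb2_open_h: int
    fb2_other: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @staticmethod
    def from_array(a: np.ndarray) -> "FeatureVector":
        vals = dict(zip(FEATURE_NAMES, a.tolist()))
        for k in FEATURE_NAMES[2:]:
            vals[k] = int(round(vals[k]))
        return FeatureVector(**vals)


def _candidate_pattern_counts(
    flat: np.ndarray, color: Color, row: int, col: int
) -> np.ndarray:
    """The 9 window-pattern counts for placing ``color`` at (row, col).

    ``flat`` is the flattened pre-move grid.  Returns the counts in
    FEATURE_NAMES[2:] order.
    """
    opp = color.other
    out = np.zeros(9, dtype=float)
    cell = row * N_COLS + col
    for wi, pos in _CELL_WINDOWS[cell]:
        cells = _WIN_CELLS[wi]
        vals = flat[cells]
        own_pos = np.nonzero(vals == color)[0]
        opp_pos = np.nonzero(vals == opp)[0]
        if opp_pos.size == 0:
            # own pattern formed by the placement
            post = np.sort(np.append(own_pos, pos))
            k = post.size
            if k == 4:
                out[0] += 1  # f_four
            elif k == 3:
                connected = post[-1] - post[0] == 2
                if connected and _WIN_IS_H[wi]:
                    # open triple: both cells flanking the run are on-board
                    # and empty after the placement
                    c0 = _WINDOWS[wi].cells[post[0]][1]
                    c2 = _WINDOWS[wi].cells[post[2]][1]
                    lo, hi = min(c0, c2), max(c0, c2)
                    left_open = lo - 1 >= 0 and flat[row * N_COLS + lo - 1] == EMPTY
                    right_open = (
                        hi + 1 < N_COLS and flat[row * N_COLS + hi + 1] == EMPTY
                    )
                    if left_open and right_open:
                        out[3] += 1  # f3_open_h
                    elif connected:
                        out[1] += 1  # f3_conn
                elif connected:
                    out[1] += 1
                else:
                    out[2] += 1  # f3_disc
            elif k == 2:
                if post[1] - post[0] == 1:
                    out[4] += 1  # f2_conn
                else:
                    out[5] += 1  # f2_disc
        elif own_pos.size == 0:
            # blocking an opponent pattern
            k = opp_pos.size
            if k == 3:
                out[6] += 1  # f_block3
            elif k == 2:
                open_h = False
                if _WIN_IS_H[wi] and opp_pos[1] - opp_pos[0] == 1:
                    wrow = _WINDOWS[wi].cells[0][0]
                    clo = _WINDOWS[wi].cells[opp_pos[0]][1]
                    chi = _WINDOWS[wi].cells[opp_pos[1]][1]
                    fl, fr = clo - 1, chi + 1
                    if (
                        fl >= 0
                        and fr < N_COLS
                        and flat[wrow * N_COLS + fl] == EMPTY
                        and flat[wrow * N_COLS + fr] == EMPTY
                        and (col == fl or col == fr)
                        and row == wrow
                    ):
                        open_h = True
                if open_h:
                    out[7] += 1  # fb2_open_h
                else:
                    out[8] += 1  # fb2_other
    return out


def extract_features(board: BoardState, candidate: tuple[int, int]) -> FeatureVector:
    """Feature vector for the side to move hypothetically playing ``candidate``."""
    row, col = candidate
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise IllegalMoveError(f"candidate {candidate} out of bounds")
    if board.grid[row, col] != EMPTY:
        raise IllegalMoveError(f"candidate {candidate} is occupied")
    counts = _candidate_pattern_counts(board.grid.ravel(), board.to_move, row, col)
    return FeatureVector(
        f_hc=float(abs(col - 4)),
        f_vc=float(abs(row - 1.5)),
        f_four=int(counts[0]),
        f3_conn=int(counts[1]),
        f3_disc=int(counts[2]),
        f3_open_h=int(counts[3]),
        f2_conn=int(counts[4]),
        f2_disc=int(counts[5]),
        f_block3=int(counts[6]),
        fb2_open_h=int(counts[7]),
        fb2_other=int(counts[8]),
    )


def features_for_board(
    board: BoardState,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Features of every legal move, in sorted cell order.

    Returns ``(cells, F)`` with ``F`` of shape (n_legal, 11), rows aligned to
    ``cells``.  This is the fast path used by the gameplay model.
    """
    flat = board.grid.ravel()
    color = board.to_move
    empties = np.nonzero(flat == EMPTY)[0]
    cells = [(int(e) // N_COLS, int(e) % N_COLS) for e in empties]
    F = np.empty((len(cells), N_FEATURES), dtype=float)
    for i, (r, c) in enumerate(cells):
        F[i, 0] = abs(c - 4)
        F[i, 1] = abs(r - 1.5)
        F[i, 2:] = _candidate_pattern_counts(flat, color, r, c)
    return cells, F


# ---------------------------------------------------------------------------
# Mirroring
# ---------------------------------------------------------------------------


def mirror_cell(cell: tuple[int, int], axis: str) -> tuple[int, int]:
    r, c = cell
    if axis == "horizontal":  # flip left-right: columns
        return (r, N_COLS - 1 - c)
    if axis == "vertical":  # flip top-bottom: rows
        return (N_ROWS - 1 - r, c)
    raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


def mirror(board: BoardState, axis: str) -> BoardState:
    """Reflect the board (and its history) across the given axis."""
    if axis == "horizontal":
        grid = board.grid[:, ::-1].copy()
    elif axis == "vertical":
        grid = board.grid[::-1, :].copy()
    else:
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    hist = tuple(
        replace(mv, row=mirror_cell(mv.cell, axis)[0], col=mirror_cell(mv.cell, axis)[1])
        for mv in board.history
    )
    return BoardState(grid, board.to_move, hist)


# ---------------------------------------------------------------------------
# Game file I/O
# ---------------------------------------------------------------------------
# Dialect: CSV with mandatory header game_id,move_index,color,row,col;
# move_index is 1-based, color is B or W, rows 0-3 top->bottom and columns
# 0-8 left->right.

GAME_COLUMNS = ["game_id", "move_index", "color", "row", "col"]


def write_games(games: Iterable[Sequence[Move]] | dict, path) -> None:
    """Write games as delimited text (one row per move).

    ``games`` maps game id -> move sequence, or is an iterable of move
    sequences (ids are then 0..n-1).
    """
    if not isinstance(games, dict):
        games = {i: g for i, g in enumerate(games)}
    rows = []
    for gid, moves in games.items():
        for mv in moves:
            rows.append((gid, mv.ordinal, mv.color.letter, mv.row, mv.col))
    df = pd.DataFrame(rows, columns=GAME_COLUMNS)
    df.to_csv(path, index=False)


def read_games(path) -> dict[str, list[Move]]:
    """Read a game file; every game is validated by replay."""
    df = pd.read_csv(path)
    missing = set(GAME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"game file {path} missing columns {sorted(missing)}")
    games: dict[str, list[Move]] = {}
    for gid, sub in df.groupby("game_id", sort=False):
        sub = sub.sort_values("move_index")
        moves = [
            Move(
                Color.from_letter(str(row.color)),
                int(row.row),
                int(row.col),
                int(row.move_index),
            )
            for row in sub.itertuples()
        ]
        board_from_moves(moves)  # raises on any illegal replay
        games[str(gid)] = moves
    return games


def render_board(board: BoardState) -> str:
    """4x9 character grid (``.`` empty, ``b`` black, ``w`` white) for logs."""
    chars = {EMPTY: ".", int(Color.BLACK): "b", int(Color.WHITE): "w"}
    lines = ["".join(chars[int(v)] for v in row) for row in board.grid]
    return "\n".join(lines)
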
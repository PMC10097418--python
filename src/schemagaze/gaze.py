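"""Fixation maps, encoding-strategy regressors, and model-free gaze statistics.

During encoding, each 5 s epoch (the initial board, then one per revealed
move) yields a *fixation map*: each fixation's duration is soft-assigned to
the 36 board squares with a Gaussian kernel over pixel distance,
``t_F * exp(-||x_F - x_i||^2 / tau) / sum_j exp(-||x_F - x_j||^2 / tau)``,
and summed over the epoch.  The map is then modelled as a linear combination
of six candidate encoding strategies (length-36 regressors, z-scored within
board): the most recent move, pieces related to it, next-move prediction,
piece relevance to the next move, previously seen moves, and overall
occupancy.  The coefficient on the prediction regressor (beta_3, the
*prediction coefficient*) indexes predictive looking.

Two model-free statistics summarise prediction without the gameplay model:
*confidence* (expected information gain of the empty-square fixation
distribution over uniform, weighted by the fraction of time on empty
squares) and *surprise* (negative log fraction of time on the square where
the next move actually appeared).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .game_core import N_CELLS, N_COLS, N_ROWS, BoardState, Move
from .schema_model import MoveDistribution, PolicyModel
from . import stats as _stats

logger = logging.getLogger(__name__)

__all__ = [
    "FixationEvent",
    "BoardLayout",
    "FixationMap",
    "RegressorSet",
    "StrategyCoefficients",
    "GazeStats",
    "STRATEGY_NAMES",
    "read_fixations",
    "write_fixations",
    "fixation_map",
    "build_regressors",
    "zscore_per_board",
    "strategy_regression",
    "prediction_confidence",
    "prediction_surprise",
    "gaze_stats",
]

EPOCH_MS = 5000
SURPRISE_EPS = 1e-3

STRATEGY_NAMES = (
    "recent_move",
    "recent_related",
    "prediction",
    "next_relevance",
    "previous_moves",
    "occupancy",
)

FIXATION_COLUMNS = [
    "subject", "session", "trial", "epoch", "onset_ms", "duration_ms",
    "x_px", "y_px",
]


@dataclass(frozen=True)
class FixationEvent:
    """One fixation: onset/duration in ms, screen position in px."""

    subject: str
    session: int
    trial: str
    epoch: int
    onset_ms: float
    duration_ms: float
    x_px: float
    y_px: float

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("fixation duration must be positive")


@dataclass(frozen=True)
class BoardLayout:
    """Pixel geometry of the 4x9 board on screen.

    ``center0`` is the pixel centre of square (row 0, col 0); squares are
    ``square_px`` apart in both directions (x grows with column, y with row).
    """

    center0_x_px: float
    center0_y_px: float
    square_px: float = 136.0
    screen_w_px: int = 1920
    screen_h_px: int = 1080

    def square_centers(self) -> np.ndarray:
        """(36, 2) array of square centre pixel coordinates, row-major."""
        rr, cc = np.meshgrid(np.arange(N_ROWS), np.arange(N_COLS), indexing="ij")
        x = self.center0_x_px + cc.ravel() * self.square_px
        y = self.center0_y_px + rr.ravel() * self.square_px
        return np.column_stack([x, y]).astype(float)

    def cell_center(self, cell: tuple[int, int]) -> tuple[float, float]:
        r, c = cell
        return (
            self.center0_x_px + c * self.square_px,
            self.center0_y_px + r * self.square_px,
        )


def default_layout() -> BoardLayout:
    """Board centred on a 1920x1080 screen with 136 px squares."""
    return BoardLayout(
        center0_x_px=1920 / 2 - 4 * 136,
        center0_y_px=1080 / 2 - 1.5 * 136,
    )


@dataclass(frozen=True)
class FixationMap:
    """Per-epoch fixation weights (ms) over the 36 squares."""

    key: tuple  # (subject, session, trial, epoch)
    weights: np.ndarray
    total_ms: float
    n_fixations: int = 0
    n_discarded: int = 0

    @property
    def epoch(self) -> int:
        return self.key[3]


@dataclass(frozen=True)
class RegressorSet:
    """Six length-36 strategy regressors for one board/epoch."""

    key: tuple
    R: np.ndarray  # (6, 36)
    board: BoardState = None
    next_move_dist: MoveDistribution = None


@dataclass(frozen=True)
class StrategyCoefficients:
    """Fitted strategy weights; ``beta[2]`` is the prediction coefficient."""

    beta: np.ndarray  # (6,)
    intercept: float
    level: str  # "session" or "board"
    r_squared: float
    n_epochs: int
    key: tuple = ()

    @property
    def prediction_coefficient(self) -> float:
        return float(self.beta[2])


@dataclass(frozen=True)
class GazeStats:
    """Model-free per-epoch prediction statistics (nats)."""

    key: tuple
    prediction_confidence: Optional[float]
    prediction_surprise: Optional[float]
    p_empty: Optional[float]
    n_empty: int


# ---------------------------------------------------------------------------
# Fixation file I/O
# ---------------------------------------------------------------------------


def write_fixations(events: Sequence[FixationEvent], path) -> None:
    rows = [
        (e.subject, e.session, e.trial, e.epoch, e.onset_ms, e.duration_ms,
         e.x_px, e.y_px)
        for e in events
    ]
    pd.DataFrame(rows, columns=FIXATION_COLUMNS).to_csv(path, index=False)


def read_fixations(path, layout: BoardLayout | None = None) -> list[FixationEvent]:
    """Read the fixation dialect; non-positive durations are dropped (logged).

    Raises a ``ValueError`` naming the offending line for missing columns or
    unparsable numerics, and for epoch indices inconsistent with onset given
    5000 ms epochs.
    """
    df = pd.read_csv(path)
    missing = set(FIXATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fixation file {path} missing columns {sorted(missing)}")
    events: list[FixationEvent] = []
    n_dropped = 0
    for i, row in enumerate(df.itertuples(), start=2):  # header is line 1
        try:
            onset = float(row.onset_ms)
            dur = float(row.duration_ms)
            x = float(row.x_px)
            y = float(row.y_px)
            epoch = int(row.epoch)
            session = int(row.session)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} line {i}: unparsable numeric field: {exc}")
        if dur <= 0:
            n_dropped += 1
            continue
        if int(onset // EPOCH_MS) != epoch:
            raise ValueError(
                f"{path} line {i}: epoch {epoch} inconsistent with onset "
                f"{onset} ms ({EPOCH_MS} ms epochs)"
            )
        events.append(
            FixationEvent(str(row.subject), session, str(row.trial), epoch,
                          onset, dur, x, y)
        )
    if n_dropped:
        logger.warning("dropped %d fixation(s) with non-positive duration", n_dropped)
    return events


# ---------------------------------------------------------------------------
# Fixation maps
# ---------------------------------------------------------------------------


def _soft_assign(
    xy: np.ndarray, durations: np.ndarray, layout: BoardLayout, tau: float
) -> tuple[np.ndarray, np.ndarray]:
    """Soft-assign fixations to squares; returns (weights (n,36), keep mask)."""
    centers = layout.square_centers()  # (36, 2)
    d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)  # (n, 36)
    dmin = np.sqrt(d2.min(axis=1))
    keep = dmin <= layout.square_px  # off-board cutoff: one square length
    logw = -d2 / tau
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    return durations[:, None] * w, keep


def fixation_map(
    events: Sequence[FixationEvent],
    layout: BoardLayout,
    tau: float = 25.0,
) -> dict[tuple, FixationMap]:
    """Per-epoch fixation maps from soft-assigned, epoch-summed fixations.

    Fixations straddling a 5 s epoch boundary are truncated at the boundary;
    fixations farther than one square length from every square centre are
    discarded (count logged).  Returns a dict keyed by
    (subject, session, trial, epoch); epochs with no retained fixation yield
    an all-zero map flagged by ``total_ms == 0``.
    """
    groups: dict[tuple, list[FixationEvent]] = {}
    for e in events:
        groups.setdefault((e.subject, e.session, e.trial, e.epoch), []).append(e)
    out: dict[tuple, FixationMap] = {}
    total_discarded = 0
    for key, evs in groups.items():
        epoch_end = (key[3] + 1) * EPOCH_MS
        durations = np.array(
            [min(e.onset_ms + e.duration_ms, epoch_end) - e.onset_ms for e in evs]
        )
        valid = durations > 0
        xy = np.array([[e.x_px, e.y_px] for e in evs])[valid]
        durations = durations[valid]
        if len(durations) == 0:
            out[key] = FixationMap(key, np.zeros(N_CELLS), 0.0, 0, 0)
            continue
        w, keep = _soft_assign(xy, durations, layout, tau)
        n_disc = int((~keep).sum())
        total_discarded += n_disc
        weights = w[keep].sum(axis=0) if keep.any() else np.zeros(N_CELLS)
        out[key] = FixationMap(
            key, weights, float(durations[keep].sum()), int(keep.sum()), n_disc
        )
    if total_discarded:
        logger.info("discarded %d off-board fixation(s)", total_discarded)
    return out


# ---------------------------------------------------------------------------
# Strategy regressors
# ---------------------------------------------------------------------------


def _chebyshev_near(cell: tuple[int, int], radius: int = 3) -> np.ndarray:
    """Boolean mask of cells within Chebyshev distance ``radius`` of ``cell``."""
    rr, cc = np.meshgrid(np.arange(N_ROWS), np.arange(N_COLS), indexing="ij")
    d = np.maximum(np.abs(rr - cell[0]), np.abs(cc - cell[1]))
    return (d <= radius).ravel()


def build_regressors(
    board: BoardState,
    history: Sequence[Move],
    model: PolicyModel,
    next_move_dist: MoveDistribution,
) -> RegressorSet:
    """The six encoding-strategy regressors for one epoch.

    ``board`` is the board shown during the epoch and ``history`` the target
    moves revealed so far in the trial (empty on the initial board);
    ``next_move_dist`` must be the model's move distribution on this board.
    Regressors: 1 most recent move; 2 occupied squares within Chebyshev
    distance 3 of it (the move's own square belongs to regressor 1, not 2);
    3 next-move probabilities on empty squares, empty-square mean elsewhere;
    4 summed nearby next-move probability for occupied squares,
    occupied-square mean elsewhere; 5 moves seen earlier in the sequence
    excluding the most recent (initial-board pieces excluded); 6 occupancy.
    """
    if next_move_dist.board is not board and not (
        np.array_equal(next_move_dist.board.grid, board.grid)
    ):
        raise ValueError("next_move_dist was computed on a different board")
    occ = (board.grid.ravel() != 0).astype(float)
    R = np.zeros((6, N_CELLS))
    # R1: most recent move
    if history:
        last = history[-1]
        R[0, last.row * N_COLS + last.col] = 1.0
    # R2: occupied squares related to the most recent move
    if history:
        near = _chebyshev_near(history[-1].cell)
        R[1] = near * occ
        R[1, history[-1].row * N_COLS + history[-1].col] = 0.0
    # R3: prediction
    p = next_move_dist.as_vector()
    empty_mask = occ == 0
    R[2] = p
    if empty_mask.any() and (~empty_mask).any():
        R[2, ~empty_mask] = p[empty_mask].mean()
    # R4: piece relevance to the next move
    occ_idx = np.nonzero(occ)[0]
    for i in occ_idx:
        near = _chebyshev_near((i // N_COLS, i % N_COLS))
        R[3, i] = p[near & empty_mask].sum()
    if occ_idx.size and empty_mask.any():
        R[3, empty_mask] = R[3, occ_idx].mean()
    # R5: previously observed sequence moves (excluding the most recent)
    for mv in history[:-1]:
        R[4, mv.row * N_COLS + mv.col] = 1.0
    # R6: occupancy
    R[5] = occ
    return RegressorSet(key=(), R=R, board=board, next_move_dist=next_move_dist)


def zscore_per_board(v: np.ndarray) -> np.ndarray:
    """Z-score a length-36 vector; zero-variance input centres to all zeros."""
    v = np.asarray(v, dtype=float)
    mu = v.mean()
    sd = v.std()
    if sd < 1e-300:
        return np.zeros_like(v)
    return (v - mu) / sd


def strategy_regression(
    maps: Sequence[FixationMap],
    regressors: Sequence[RegressorSet],
    level: str = "session",
) -> StrategyCoefficients | list[StrategyCoefficients]:
    """OLS decomposition of fixation maps into the six strategies.

    Maps and regressors are z-scored within board, then either concatenated
    across epochs into one regression (``level='session'``) or fitted per
    epoch (``level='board'``).  Epochs with zero retained fixation time are
    excluded (session) or returned as ``None`` entries (board).
    """
    if len(maps) != len(regressors):
        raise ValueError("maps and regressors must align 1:1 by epoch")
    if level not in ("session", "board"):
        raise ValueError("level must be 'session' or 'board'")

    def design(m: FixationMap, rs: RegressorSet):
        y = zscore_per_board(m.weights)
        X = np.column_stack([zscore_per_board(r) for r in rs.R])
        return X, y

    if level == "board":
        out: list[StrategyCoefficients | None] = []
        for m, rs in zip(maps, regressors):
            if m.total_ms <= 0:
                out.append(None)
                continue
            X, y = design(m, rs)
            fit = _stats.ols_fit(np.column_stack([np.ones(len(y)), X]), y)
            out.append(
                StrategyCoefficients(
                    fit.coef[1:], float(fit.coef[0]), "board", fit.r_squared, 1,
                    key=m.key,
                )
            )
        return out

    Xs, ys = [], []
    n_used = 0
    for m, rs in zip(maps, regressors):
        if m.total_ms <= 0:
            continue
        X, y = design(m, rs)
        Xs.append(X)
        ys.append(y)
        n_used += 1
    if not Xs:
        raise ValueError("no epoch with positive fixation time")
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    fit = _stats.ols_fit(np.column_stack([np.ones(len(y)), X]), y)
    return StrategyCoefficients(
        fit.coef[1:], float(fit.coef[0]), "session", fit.r_squared, n_used
    )


# ---------------------------------------------------------------------------
# Model-free statistics
# ---------------------------------------------------------------------------


def prediction_confidence(
    fmap: FixationMap, board: BoardState
) -> Optional[float]:
    """Expected information gain of the empty-square fixation distribution.

    ``P(empty) * (ln N_empty - H[P])`` with ``P`` the fixation distribution
    normalised over empty squares; 0 * log 0 := 0.  ``None`` when the epoch
    has no fixation time.
    """
    if fmap.total_ms <= 0:
        return None
    empty = board.grid.ravel() == 0
    n_empty = int(empty.sum())
    if n_empty == 0:
        raise ValueError("board has no empty square")
    total = fmap.weights.sum()
    t_empty = fmap.weights[empty].sum()
    p_empty = t_empty / total
    if t_empty <= 0:
        return 0.0
    p = fmap.weights[empty] / t_empty
    nz = p > 0
    entropy = -float(np.sum(p[nz] * np.log(p[nz])))
    return float(p_empty * (np.log(n_empty) - entropy))


def prediction_surprise(
    fmap: FixationMap, next_move: tuple[int, int]
) -> Optional[float]:
    """Negative log fraction of fixation time on the upcoming move's square.

    The fraction is clamped below at 1e-3, bounding surprise at ~6.91 nats.
    ``None`` when the epoch has no fixation time.
    """
    if fmap.total_ms <= 0:
        return None
    r, c = next_move
    if not (0 <= r < N_ROWS and 0 <= c < N_COLS):
        raise ValueError(f"next_move {next_move} out of bounds")
    frac = fmap.weights[r * N_COLS + c] / fmap.weights.sum()
    return float(-np.log(max(frac, SURPRISE_EPS)))


def gaze_stats(
    fmap: FixationMap, board: BoardState, next_move: tuple[int, int]
) -> GazeStats:
    empty = board.grid.ravel() == 0
    n_empty = int(empty.sum())
    conf = prediction_confidence(fmap, board) if n_empty else None
    surp = prediction_surprise(fmap, next_move)
    p_empty = (
        float(fmap.weights[empty].sum() / fmap.weights.sum())
        if fmap.total_ms > 0
        else None
    )
    return GazeStats(fmap.key, conf, surp, p_empty, n_empty)
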
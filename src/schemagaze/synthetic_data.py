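"""Synthetic study generator: every pipeline input with known ground truth.

The generators emulate the structure of the study's data: (a) games played
by a feature-based softmax teacher agent on the 4x9 board; (b) memory-task
stimulus segments (lengths 4-8, starting after the fifth move, 10 of 30
ending in a win, drawn from games of 17-35 moves with a winner); (c)
fixation events sampled from known linear mixtures of the six encoding
strategies; (d) recall outcomes from a logistic subsequent-memory model on
move log-probability; (e) session-level Elo/prediction/accuracy triples with
known mediation paths; and (f) win/loss match records from known ratings.
Every generator is seeded and persists a ``SyntheticTruth`` sufficient to
regenerate its output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .game_core import (
    FEATURE_NAMES,
    BoardState,
    Color,
    Move,
    apply_move,
    board_from_moves,
    check_win,
    empty_board,
)
from .gaze import (
    EPOCH_MS,
    BoardLayout,
    FixationEvent,
    build_regressors,
    default_layout,
    zscore_per_board,
)
from .memory_scoring import RecallRecord, StimulusSequence
from .schema_model import PolicyModel, move_distribution

logger = logging.getLogger(__name__)

__all__ = [
    "GameRecord",
    "SyntheticTruth",
    "default_teacher",
    "DEFAULT_TEACHER_WEIGHTS",
    "self_play",
    "generate_game_pool",
    "extract_stimuli",
    "simulate_fixations",
    "simulate_recall",
    "simulate_sessions",
    "simulate_matches",
]

# Hand-set teacher weights: decisive wins (large four-in-a-row weight),
# threats ordered three > two with the open horizontal triple strongest,
# strong blocking (so that self-play games last tens of moves rather than
# ending on the first unanswered threat), and a mild preference for central
# squares.  A documented choice for a plausible strong player, not estimates.
DEFAULT_TEACHER_WEIGHTS: dict[str, float] = {
    "f_hc": -0.15,
    "f_vc": -0.05,
    "f_four": 6.0,
    "f3_conn": 1.2,
    "f3_disc": 0.9,
    "f3_open_h": 2.0,
    "f2_conn": 0.5,
    "f2_disc": 0.25,
    "f_block3": 6.0,
    "fb2_open_h": 2.0,
    "fb2_other": 0.8,
}


def default_teacher() -> PolicyModel:
    w = np.array([DEFAULT_TEACHER_WEIGHTS[n] for n in FEATURE_NAMES])
    return PolicyModel(w, metadata={"role": "synthetic teacher"})


@dataclass(frozen=True)
class GameRecord:
    """A complete self-play game with outcome and generator metadata."""

    game_id: str
    moves: tuple[Move, ...]
    outcome: str  # "black", "white" or "draw"
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        board = board_from_moves(self.moves)
        winner = check_win(board)
        if winner is not None:
            expect = "black" if winner is Color.BLACK else "white"
            if self.outcome != expect:
                raise ValueError(f"outcome {self.outcome} but {expect} won")
            # no moves after the win
            prior = board_from_moves(self.moves[:-1])
            if check_win(prior) is not None:
                raise ValueError("moves continue after a win")
        else:
            if self.outcome != "draw" or not board.is_full():
                raise ValueError("no winner: outcome must be a draw on a full board")


@dataclass
class SyntheticTruth:
    """Ground truth persisted alongside every generated dataset."""

    teacher_weights: Optional[dict] = None
    beta_true: Optional[list] = None
    gamma_true: Optional[dict] = None
    mediation_paths: Optional[dict] = None
    true_elos: Optional[dict] = None
    seeds: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    @staticmethod
    def load(path) -> "SyntheticTruth":
        with open(path) as fh:
            return SyntheticTruth(**json.load(fh))


# ---------------------------------------------------------------------------
# Teacher self-play
# ---------------------------------------------------------------------------


def self_play(teacher: PolicyModel, seed: int, game_id: str = "g0") -> GameRecord:
    """One game: alternating moves sampled from the teacher until win or full."""
    rng = np.random.default_rng(seed)
    board = empty_board()
    while True:
        dist = move_distribution(teacher, board)
        j = rng.choice(len(dist.cells), p=dist.probs)
        r, c = dist.cells[j]
        board = apply_move(
            board, Move(board.to_move, r, c, len(board.history) + 1)
        )
        winner = check_win(board)
        if winner is not None:
            outcome = "black" if winner is Color.BLACK else "white"
            break
        if board.is_full():
            outcome = "draw"
            break
    return GameRecord(
        game_id,
        board.history,
        outcome,
        metadata={"seed": seed, "teacher": teacher.weights.tolist()},
    )


def generate_game_pool(
    teacher: PolicyModel,
    n: int,
    length_range: tuple[int, int] = (17, 35),
    seed: int = 0,
) -> list[GameRecord]:
    """Rejection-sample ``n`` decisive games within the length bounds.

    Games shorter than ``length_range[0]`` moves, longer than
    ``length_range[1]``, or drawn are rejected; the rejection rate is
    logged.  Errors out if acceptance falls below 1% over ``10 n`` attempts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    rng = np.random.default_rng(seed)
    pool: list[GameRecord] = []
    attempts = 0
    while len(pool) < n:
        attempts += 1
        if attempts > 10 * n and len(pool) < attempts * 0.01:
            raise RuntimeError(
                f"game acceptance rate {len(pool)}/{attempts} below 1%; "
                "the teacher produces games outside the length bounds - retune it"
            )
        g = self_play(
            teacher, int(rng.integers(0, 2**31 - 1)), game_id=f"g{len(pool)}"
        )
        if g.outcome != "draw" and lo <= len(g.moves) <= hi:
            pool.append(g)
    logger.info(
        "game pool: kept %d of %d games (%.1f%% accepted)",
        n, attempts, 100 * n / attempts,
    )
    return pool


# ---------------------------------------------------------------------------
# Stimulus extraction
# ---------------------------------------------------------------------------


def extract_stimuli(
    pool: Sequence[GameRecord],
    n_trials: int = 30,
    lengths: Sequence[int] = (4, 5, 6, 7, 8),
    n_win: int = 10,
    seed: int = 0,
) -> list[StimulusSequence]:
    """Draw stimulus segments from unique games.

    ``n_win`` segments end in a win (``n_win / len(lengths)`` of each
    length, ending at the game's final, winning move); the remainder are
    non-winning segments with lengths cycled over ``lengths``.  Every
    segment starts at game ordinal >= 6, sampled uniformly over valid
    starts, and each trial comes from a distinct game.
    """
    lengths = list(lengths)
    if n_win % len(lengths) != 0:
        raise ValueError("n_win must be divisible by the number of lengths")
    if len(pool) < n_trials:
        raise ValueError(f"pool of {len(pool)} games cannot give {n_trials} trials")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(pool)))
    stimuli: list[StimulusSequence] = []

    def make(game: GameRecord, start: int, L: int, win: bool, tid: str):
        init = board_from_moves(game.moves[: start - 1])
        seq = tuple(game.moves[start - 1 : start - 1 + L])
        stim = StimulusSequence(tid, init, seq, win, game.game_id)
        stim.validate()
        return stim

    # winning segments: two of each length, ending at the final move
    win_specs = [L for L in lengths for _ in range(n_win // len(lengths))]
    used = 0
    for k, L in enumerate(win_specs):
        placed = False
        while used < len(order):
            g = pool[order[used]]
            used += 1
            glen = len(g.moves)
            start = glen - L + 1
            if start >= 6:
                stimuli.append(make(g, start, L, True, f"t{k:02d}"))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"cannot build a winning segment of length {L}: pool exhausted"
            )
    # non-winning segments: cycle lengths; end strictly before the final move
    n_nonwin = n_trials - n_win
    k = 0
    while k < n_nonwin:
        if used >= len(order):
            raise ValueError(
                f"cannot build non-winning segment {k}: pool exhausted"
            )
        L = lengths[k % len(lengths)]
        g = pool[order[used]]
        used += 1
        glen = len(g.moves)
        max_start = glen - L  # end at glen-1 at the latest: never the win
        if max_start < 6:
            continue
        start = int(rng.integers(6, max_start + 1))
        stimuli.append(make(g, start, L, False, f"t{n_win + k:02d}"))
        k += 1
    return stimuli


# ---------------------------------------------------------------------------
# Fixation simulation
# ---------------------------------------------------------------------------


def simulate_fixations(
    stimulus: StimulusSequence,
    model: PolicyModel,
    beta_true: Sequence[float],
    n_fix_per_epoch: int = 12,
    jitter_px: float = 10.0,
    seed: int = 0,
    *,
    layout: BoardLayout | None = None,
    subject: str = "s0",
    session: int = 1,
    temperature: float = 1.0,
) -> tuple[list[FixationEvent], SyntheticTruth]:
    """Sample fixation events from a known strategy mixture.

    For each epoch (initial board and each board before an upcoming move),
    the target map ``sum_k beta_k z(R_k)`` is turned into a sampling
    distribution by a softmax at ``temperature``; ``n_fix_per_epoch``
    fixation squares are sampled, each event placed at the square centre
    plus isotropic Gaussian jitter, with equal durations summing to 5000 ms.
    """
    beta = np.asarray(beta_true, dtype=float)
    if beta.shape != (6,) or not np.all(np.isfinite(beta)):
        raise ValueError("beta_true must be 6 finite floats")
    if n_fix_per_epoch < 1:
        raise ValueError("n_fix_per_epoch must be >= 1")
    layout = layout or default_layout()
    rng = np.random.default_rng(seed)
    centers = layout.square_centers()
    events: list[FixationEvent] = []
    board = stimulus.initial_board
    history: list[Move] = []
    dur = EPOCH_MS / n_fix_per_epoch
    for e in range(len(stimulus.moves)):
        dist = move_distribution(model, board)
        rs = build_regressors(board, history, model, dist)
        target = sum(b * zscore_per_board(r) for b, r in zip(beta, rs.R))
        logits = np.asarray(target, dtype=float) / temperature
        logits -= logits.max()
        p = np.exp(logits)
        p /= p.sum()
        squares = rng.choice(36, size=n_fix_per_epoch, p=p)
        for k, sq in enumerate(squares):
            x, y = centers[sq]
            jx, jy = rng.normal(0.0, jitter_px, size=2)
            events.append(
                FixationEvent(
                    subject, session, stimulus.trial_id, e,
                    onset_ms=e * EPOCH_MS + k * dur, duration_ms=dur,
                    x_px=float(x + jx), y_px=float(y + jy),
                )
            )
        mv = stimulus.moves[e]
        board = apply_move(board, mv)
        history.append(mv)
    truth = SyntheticTruth(
        beta_true=beta.tolist(),
        seeds={"fixations": seed},
        extra={
            "n_fix_per_epoch": n_fix_per_epoch,
            "jitter_px": jitter_px,
            "temperature": temperature,
            "trial_id": stimulus.trial_id,
        },
    )
    return events, truth


# ---------------------------------------------------------------------------
# Recall simulation
# ---------------------------------------------------------------------------


def simulate_recall(
    stimuli: Sequence[StimulusSequence],
    model: PolicyModel,
    gamma_true: tuple[float, float] = (-0.5, 1.0),
    error_model: str = "schema",
    seed: int = 0,
    *,
    rt_params: tuple[float, float, float] = (7.2, -0.25, 0.35),
) -> tuple[list[RecallRecord], SyntheticTruth]:
    """Generate recall records from a logistic subsequent-memory model.

    Move ``i`` with schema log-probability ``logp_i`` is remembered with
    probability ``sigmoid(gamma_0 + gamma_1 * logp_i)``.  Forgotten moves
    are replaced by a cell sampled either from the schema model
    (``error_model='schema'``, correct cell excluded and renormalised) or
    uniformly over the available cells.  Reaction times are lognormal:
    ``ln RT_ms ~ N(mu_0 + mu_1 * logp, sigma)`` with ``rt_params =
    (mu_0, mu_1, sigma)``, the negative ``mu_1`` making schema-consistent
    moves faster to place.
    """
    if error_model not in ("schema", "uniform"):
        raise ValueError("error_model must be 'schema' or 'uniform'")
    g0, g1 = float(gamma_true[0]), float(gamma_true[1])
    mu0, mu1, sig = rt_params
    rng = np.random.default_rng(seed)
    records: list[RecallRecord] = []
    for stim in stimuli:
        board = stim.initial_board
        used: set[tuple[int, int]] = set()
        cells: list[tuple[int, int]] = []
        rts: list[float] = []
        for mv in stim.moves:
            dist = move_distribution(model, board)
            logp = dist.log_prob_of(mv.cell)
            p_rem = 1.0 / (1.0 + np.exp(-(g0 + g1 * logp)))
            remembered = rng.random() < p_rem and mv.cell not in used
            if remembered:
                cell = mv.cell
            else:
                # pick a wrong cell among legal cells of the true board,
                # excluding the correct cell and anything already placed
                allowed = [
                    (c, pr)
                    for c, pr in zip(dist.cells, dist.probs)
                    if c != mv.cell and c not in used
                ]
                if not allowed:
                    break
                cs = [c for c, _ in allowed]
                if error_model == "schema":
                    w = np.array([pr for _, pr in allowed])
                    w = w / w.sum()
                else:
                    w = np.full(len(cs), 1.0 / len(cs))
                cell = cs[rng.choice(len(cs), p=w)]
            used.add(cell)
            cells.append(cell)
            rts.append(float(np.exp(rng.normal(mu0 + mu1 * logp, sig))))
            board = apply_move(board, mv)
        records.append(RecallRecord(stim.trial_id, tuple(cells), tuple(rts)))
    truth = SyntheticTruth(
        gamma_true={"gamma0": g0, "gamma1": g1},
        seeds={"recall": seed},
        extra={"error_model": error_model, "rt_params": list(rt_params)},
    )
    return records, truth


# ---------------------------------------------------------------------------
# Session-level mediation triples
# ---------------------------------------------------------------------------


def simulate_sessions(
    n: int,
    a: float,
    b: float,
    c_prime: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized (x, m, y) triples with known mediation paths.

    ``x ~ N(0,1)``; ``m = a x + sqrt(1-a^2) e_m``; ``y = c' x + b m + e_y``
    with the ``y`` noise scaled so Var(y) = 1 when possible.  The population
    indirect effect is ``a * b`` by construction.
    """
    if not abs(a) < 1:
        raise ValueError("|a| must be < 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    m = a * x + np.sqrt(1 - a * a) * rng.standard_normal(n)
    var_signal = c_prime**2 + b**2 + 2 * a * b * c_prime
    sd_noise = np.sqrt(max(1.0 - var_signal, 1e-6))
    y = c_prime * x + b * m + sd_noise * rng.standard_normal(n)
    return x, m, y


# ---------------------------------------------------------------------------
# Elo match records
# ---------------------------------------------------------------------------


def simulate_matches(
    true_elos: dict,
    n_per_pair: int,
    seed: int = 0,
) -> list[tuple]:
    """Win/loss records per pairing, Bernoulli(1/(1+10^(-delta/400)))."""
    players = list(true_elos)
    if len(players) < 2:
        raise ValueError("need at least 2 players")
    rng = np.random.default_rng(seed)
    matches: list[tuple] = []
    for ai in range(len(players)):
        for bi in range(ai + 1, len(players)):
            pa, pb = players[ai], players[bi]
            delta = true_elos[pa] - true_elos[pb]
            p_win = 1.0 / (1.0 + 10.0 ** (-delta / 400.0))
            wins = rng.random(n_per_pair) < p_win
            matches.extend((pa, pb, float(w)) for w in wins)
    return matches
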
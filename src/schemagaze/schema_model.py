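"""Feature-based myopic gameplay model ("schema" model) for four-in-a-row.

Each candidate move ``x`` on a board is scored ``V(x) = w . F(x)`` with ``F``
the 11 move features of :mod:`schemagaze.game_core`; a softmax over the legal
moves turns the values into a move probability distribution.  The weights are
learned by minimising the cross-entropy of moves played by a teacher agent,
with an ensemble protocol: the games are partitioned into disjoint blocks,
one model is fitted per block, and the block weight vectors are averaged.

The model's log probability of a move is used throughout the package as the
move's *schema consistency*: how typical it is of strong play.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .game_core import (
    FEATURE_NAMES,
    N_FEATURES,
    BoardState,
    Color,
    Move,
    board_from_moves,
    check_win,
    features_for_board,
    legal_moves,
)

__all__ = [
    "PolicyModel",
    "MoveDistribution",
    "move_values",
    "move_distribution",
    "log_prob_of_move",
    "fit_weights",
    "cross_entropy",
    "simulate_schema_guessing",
    "save_model",
    "load_model",
    "uniform_model",
]


@dataclass(frozen=True)
class PolicyModel:
    """Weight vector over the 11 move features, plus training metadata."""

    weights: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.feature_names),):
            raise ValueError(
                f"weights shape {w.shape} does not match "
                f"{len(self.feature_names)} features"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if tuple(self.feature_names) != FEATURE_NAMES:
            raise ValueError("feature-name alignment mismatch with FEATURE_NAMES")
        object.__setattr__(self, "weights", w)


def uniform_model() -> PolicyModel:
    """The zero-weight model: uniform over legal moves on every board."""
    return PolicyModel(np.zeros(N_FEATURES))


@dataclass(frozen=True)
class MoveDistribution:
    """Softmax distribution over the legal moves of one board."""

    board: BoardState
    cells: tuple[tuple[int, int], ...]
    probs: np.ndarray
    log_probs: np.ndarray

    def __post_init__(self) -> None:
        assert len(self.cells) == len(self.probs) == len(self.log_probs)

    def prob_of(self, cell: tuple[int, int]) -> float:
        return float(self.probs[self._index(cell)])

    def log_prob_of(self, cell: tuple[int, int]) -> float:
        return float(self.log_probs[self._index(cell)])

    def _index(self, cell: tuple[int, int]) -> int:
        try:
            return self.cells.index(tuple(cell))
        except ValueError:
            raise ValueError(f"cell {cell} is not a legal move here") from None

    def as_vector(self) -> np.ndarray:
        """Probabilities scattered onto the 36-cell flat board (0 elsewhere)."""
        from .game_core import N_COLS, N_CELLS

        v = np.zeros(N_CELLS)
        for (r, c), p in zip(self.cells, self.probs):
            v[r * N_COLS + c] = p
        return v


def move_values(model: PolicyModel, board: BoardState) -> dict[tuple[int, int], float]:
    """``V(x) = w . F(x)`` for every legal move ``x``."""
    cells, F = features_for_board(board)
    if not cells:
        raise ValueError("board has no legal moves")
    vals = F @ model.weights
    return dict(zip(cells, vals.tolist()))


def move_distribution(model: PolicyModel, board: BoardState) -> MoveDistribution:
    """Softmax over move values; numerically safe via max-subtraction."""
    cells, F = features_for_board(board)
    if not cells:
        raise ValueError("board has no legal moves")
    v = F @ model.weights
    logz = logsumexp(v)
    logp = v - logz
    return MoveDistribution(board, tuple(cells), np.exp(logp), logp)


def log_prob_of_move(
    model: PolicyModel, board: BoardState, cell: tuple[int, int]
) -> float:
    """Natural-log probability of ``cell`` under the model (schema consistency)."""
    return move_distribution(model, board).log_prob_of(cell)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _replay_positions(games: Sequence[Sequence[Move]]):
    """Yield (board, played cell) for every move of every game."""
    for moves in games:
        board = board_from_moves([])
        for mv in moves:
            yield board, mv.cell
            from .game_core import apply_move

            board = apply_move(board, mv)


def _build_design(games: Sequence[Sequence[Move]]):
    """Cache padded feature tensors for fast full-batch loss/gradient.

    Returns (feats (B,36,11), mask (B,36), played (B,)) over all board/move
    pairs in the games.
    """
    feats, masks, played = [], [], []
    for board, cell in _replay_positions(games):
        cells, F = features_for_board(board)
        pad = np.zeros((36, N_FEATURES))
        m = np.zeros(36, dtype=bool)
        pad[: len(cells)] = F
        m[: len(cells)] = True
        feats.append(pad)
        masks.append(m)
        played.append(cells.index(cell))
    return np.asarray(feats), np.asarray(masks), np.asarray(played)


def _ce_loss_grad(w: np.ndarray, feats, mask, played):
    """Mean cross-entropy (nats/move) and its gradient."""
    v = feats @ w  # (B, 36)
    v = np.where(mask, v, -np.inf)
    vmax = v.max(axis=1, keepdims=True)
    ex = np.exp(v - vmax)
    z = ex.sum(axis=1, keepdims=True)
    logz = np.log(z[:, 0]) + vmax[:, 0]
    b = np.arange(len(played))
    loss = float(np.mean(logz - v[b, played]))
    p = ex / z  # (B, 36); zero where masked
    grad = (p[:, :, None] * feats).sum(axis=1) - feats[b, played]
    return loss, grad.mean(axis=0)


def _fit_single(
    feats, mask, played, max_iter: int, gtol: float
) -> tuple[np.ndarray, list[float], bool]:
    losses: list[float] = []

    def cb(wk):
        losses.append(_ce_loss_grad(wk, feats, mask, played)[0])

    res = minimize(
        _ce_loss_grad,
        np.zeros(N_FEATURES),
        args=(feats, mask, played),
        jac=True,
        method="L-BFGS-B",
        callback=cb,
        options={"maxiter": max_iter, "gtol": gtol},
    )
    return res.x, losses, bool(res.success)


def fit_weights(
    games: Sequence[Sequence[Move]],
    n_models: int = 8,
    games_per_model: int = 100,
    *,
    seed: int = 0,
    max_iter: int = 500,
    gtol: float = 1e-6,
) -> PolicyModel:
    """Ensemble cross-entropy fit: disjoint game blocks, averaged weights.

    The games are shuffled (seeded) and partitioned into ``n_models`` disjoint
    blocks of ``games_per_model``; a full-batch gradient-based fit from
    ``w = 0`` is run per block and the fitted weight vectors are averaged.
    Non-convergence within the iteration budget sets
    ``metadata['converged'] = False`` but still returns the model.
    """
    games = list(games)
    need = n_models * games_per_model
    if len(games) < need:
        raise ValueError(
            f"need {need} games for {n_models} blocks of {games_per_model}, "
            f"got {len(games)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(games))
    all_w = []
    converged = True
    loss_traces = []
    for b in range(n_models):
        idx = order[b * games_per_model : (b + 1) * games_per_model]
        block = [games[i] for i in idx]
        feats, mask, played = _build_design(block)
        w, losses, ok = _fit_single(feats, mask, played, max_iter, gtol)
        all_w.append(w)
        loss_traces.append(losses)
        converged = converged and ok
    w_bar = np.mean(all_w, axis=0)
    return PolicyModel(
        w_bar,
        metadata={
            "n_models": n_models,
            "games_per_model": games_per_model,
            "seed": seed,
            "max_iter": max_iter,
            "gtol": gtol,
            "converged": converged,
            "loss_traces": loss_traces,
            "block_weights": [w.tolist() for w in all_w],
        },
    )


def cross_entropy(model: PolicyModel, games: Sequence[Sequence[Move]]) -> float:
    """Mean ``-log p(played move)`` in nats/move over all moves of ``games``."""
    feats, mask, played = _build_design(games)
    loss, _ = _ce_loss_grad(model.weights, feats, mask, played)
    return loss


def uniform_cross_entropy(games: Sequence[Sequence[Move]]) -> float:
    """Cross-entropy of the uniform-over-legal-moves policy on ``games``."""
    return cross_entropy(uniform_model(), games)


# ---------------------------------------------------------------------------
# Schema-based guessing simulation
# ---------------------------------------------------------------------------


def simulate_schema_guessing(
    model: PolicyModel,
    stimuli: Sequence,
    n_sims: int,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Accuracy of recalling sequences by sampling moves from the schema model.

    For each stimulus, continuations of the target length are repeatedly
    sampled move-by-move from the model's move distribution (colours
    alternating as in the source game) and scored with the strict
    order-and-location recall rule.  Returns (per-stimulus mean accuracy,
    overall mean).  If the board fills (or the game is won and play cannot
    continue is not a concern: sampling just continues on the raw board)
    before the sequence length is reached, the unfilled moves score as
    incorrect.
    """
    from .game_core import apply_move
    from .memory_scoring import score_recall, RecallRecord

    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    per_stim = np.zeros(len(stimuli))
    for si, stim in enumerate(stimuli):
        L = len(stim.moves)
        acc = 0.0
        first_dist = move_distribution(model, stim.initial_board)
        for _ in range(n_sims):
            board = stim.initial_board
            guessed: list[tuple[int, int]] = []
            dist = first_dist
            for k in range(L):
                if dist is None:
                    cells, _ = (list(legal_moves(board)), None)
                    if not cells:
                        break
                    dist = move_distribution(model, board)
                j = rng.choice(len(dist.cells), p=dist.probs)
                cell = dist.cells[j]
                guessed.append(cell)
                mv = Move(
                    board.to_move, cell[0], cell[1], len(board.history) + 1
                )
                board = apply_move(board, mv)
                dist = None
                if k + 1 < L and board.is_full():
                    break
            rec = RecallRecord(stim.trial_id, tuple(guessed), None)
            _, a = score_recall(stim, rec)
            acc += a
        per_stim[si] = acc / n_sims
    return per_stim, float(per_stim.mean()) if len(stimuli) else float("nan")


# ---------------------------------------------------------------------------
# Model file I/O: plain-text key-value
# ---------------------------------------------------------------------------


def save_model(model: PolicyModel, path) -> None:
    lines = ["# schemagaze policy model (key = value)"]
    for name, w in zip(model.feature_names, model.weights):
        lines.append(f"w.{name} = {float(w)!r}")
    for k in ("n_models", "games_per_model", "seed", "converged"):
        if k in model.metadata:
            lines.append(f"meta.{k} = {model.metadata[k]!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> PolicyModel:
    weights = {}
    meta = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            val = val.strip()
            if key.startswith("w."):
                weights[key[2:]] = float(val)
            elif key.startswith("meta."):
                meta[key[5:]] = val
    missing = set(FEATURE_NAMES) - set(weights)
    if missing:
        raise ValueError(f"model file missing weights for {sorted(missing)}")
    w = np.array([weights[n] for n in FEATURE_NAMES])
    return PolicyModel(w, metadata=meta)
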
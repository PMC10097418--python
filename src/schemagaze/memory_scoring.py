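"""Scoring of sequence-recall responses against their stimulus sequences.

A stimulus is an initial board (at least five pre-moves deep in its source
game) followed by a 4-8 move target sequence; recall is scored strictly: a
recalled move is correct only if it is at the right location *and* in the
right order (colour is implied by alternation).  Error analyses use the first
mistake only, because after it the encoding and retrieval boards diverge and
move probabilities are no longer comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .game_core import (
    BoardState,
    Color,
    Move,
    apply_move,
    check_win,
    legal_moves,
)

__all__ = [
    "StimulusSequence",
    "RecallRecord",
    "score_recall",
    "first_mistake",
    "mistake_schema_consistency",
    "filter_rt",
    "read_recalls",
    "write_recalls",
    "write_stimuli",
    "read_stimuli",
]

RECALL_COLUMNS = ["subject", "session", "trial", "position_index", "row", "col", "rt_ms"]


@dataclass(frozen=True)
class StimulusSequence:
    """A memory-task trial: initial board plus the target move sequence."""

    trial_id: str
    initial_board: BoardState
    moves: tuple[Move, ...]
    ends_in_win: bool
    source_game_id: str = ""

    def validate(self) -> None:
        if not (4 <= len(self.moves) <= 8):
            raise ValueError(f"sequence length {len(self.moves)} outside [4, 8]")
        if self.moves[0].ordinal < 6:
            raise ValueError("first target move must come after the fifth game move")
        if self.initial_board.n_pieces < 5:
            raise ValueError("initial board must hold at least 5 pieces")
        board = self.initial_board
        for mv in self.moves:
            board = apply_move(board, mv)
        won = check_win(board) is not None
        if won != self.ends_in_win:
            raise ValueError("ends_in_win flag inconsistent with the final board")

    def boards(self) -> list[BoardState]:
        """Board states before each target move (length = len(moves))."""
        out = [self.initial_board]
        board = self.initial_board
        for mv in self.moves[:-1]:
            board = apply_move(board, mv)
            out.append(board)
        return out


@dataclass(frozen=True)
class RecallRecord:
    """Ordered recalled cells for one trial, with per-move reaction times."""

    trial_id: str
    cells: tuple[tuple[int, int], ...]
    rts_ms: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.rts_ms is not None and len(self.rts_ms) != len(self.cells):
            raise ValueError("one reaction time per recalled move required")


def score_recall(
    stimulus: StimulusSequence, recall: RecallRecord
) -> tuple[list[bool], float]:
    """Strict order-and-location scoring.

    Move ``i`` is correct iff the i-th recalled cell equals the i-th target
    cell; missing tail moves score incorrect.  Returns (per-move booleans,
    fraction correct of the stimulus length).
    """
    if recall.trial_id != stimulus.trial_id:
        raise ValueError(
            f"recall trial {recall.trial_id!r} does not match stimulus "
            f"{stimulus.trial_id!r}"
        )
    if len(recall.cells) > len(stimulus.moves):
        raise ValueError("more recalled moves than the stimulus contains")
    if len(set(recall.cells)) != len(recall.cells):
        raise ValueError("recalled cells must be distinct")
    init = stimulus.initial_board
    for (r, c) in recall.cells:
        if init.grid[r, c] != 0:
            raise ValueError(f"recalled cell ({r},{c}) occupied on the initial board")
    correct = [
        i < len(recall.cells) and recall.cells[i] == mv.cell
        for i, mv in enumerate(stimulus.moves)
    ]
    return correct, sum(correct) / len(stimulus.moves)


def first_mistake(
    stimulus: StimulusSequence, recall: RecallRecord
) -> Optional[int]:
    """1-based index of the earliest incorrect move; ``None`` if all correct."""
    correct, _ = score_recall(stimulus, recall)
    for i, ok in enumerate(correct):
        if not ok:
            return i + 1
    return None


def mistake_schema_consistency(
    model, stimulus: StimulusSequence, recall: RecallRecord
) -> Optional[bool]:
    """Was the first mistaken answer *more* schema-consistent than the truth?

    Reconstructs the true board before the first mistake (encoding and
    retrieval boards still coincide there) and compares the model probability
    of the recalled cell against that of the correct cell.  Strict
    inequality; ties count as not-more-consistent.  ``None`` when the recall
    is fully correct.
    """
    from .schema_model import move_distribution

    idx = first_mistake(stimulus, recall)
    if idx is None:
        return None
    board = stimulus.initial_board
    for mv in stimulus.moves[: idx - 1]:
        board = apply_move(board, mv)
    if idx - 1 >= len(recall.cells):
        # omitted move: no recalled answer to evaluate
        return None
    recalled = recall.cells[idx - 1]
    if board.grid[recalled[0], recalled[1]] != 0:
        raise ValueError(
            f"recalled cell {recalled} is occupied on the true board at move {idx}"
        )
    dist = move_distribution(model, board)
    return dist.prob_of(recalled) > dist.prob_of(stimulus.moves[idx - 1].cell)


def filter_rt(
    records: pd.DataFrame, cutoff_ms: float = 30000
) -> tuple[pd.DataFrame, float]:
    """Drop correct moves with reaction time above ``cutoff_ms``.

    ``records`` is a tidy move-level table with at least ``rt_ms`` and
    ``correct`` columns.  Only correct moves enter RT analyses; the removal
    fraction is reported relative to the correct moves.
    """
    if "rt_ms" not in records or "correct" not in records:
        raise ValueError("records must have 'rt_ms' and 'correct' columns")
    rt = records["rt_ms"]
    if (rt.dropna() < 0).any():
        raise ValueError("negative reaction times are invalid")
    correct = records["correct"].astype(bool)
    keep = correct & (rt <= cutoff_ms)
    n_corr = int(correct.sum())
    removed = int((correct & (rt > cutoff_ms)).sum())
    frac = removed / n_corr if n_corr else 0.0
    return records[keep].copy(), frac


# ---------------------------------------------------------------------------
# File dialects
# ---------------------------------------------------------------------------
# Recall file: CSV, header subject,session,trial,position_index,row,col,rt_ms
# (position_index 1-based).  Stimulus file: CSV, header trial_id,phase,
# move_index,color,row,col,ends_in_win,source_game_id where phase is
# "initial" (pre-sequence board pieces, in game order) or "target".


def write_recalls(recalls: dict, path) -> None:
    """``recalls`` maps (subject, session) -> list of RecallRecord."""
    rows = []
    for (subject, session), recs in recalls.items():
        for rec in recs:
            rts = rec.rts_ms or [np.nan] * len(rec.cells)
            for i, ((r, c), rt) in enumerate(zip(rec.cells, rts), start=1):
                rows.append((subject, session, rec.trial_id, i, r, c, rt))
    pd.DataFrame(rows, columns=RECALL_COLUMNS).to_csv(path, index=False)


def read_recalls(path) -> dict:
    df = pd.read_csv(path)
    missing = set(RECALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"recall file {path} missing columns {sorted(missing)}")
    out: dict = {}
    for (subject, session, trial), sub in df.groupby(
        ["subject", "session", "trial"], sort=False
    ):
        sub = sub.sort_values("position_index")
        cells = tuple((int(r.row), int(r.col)) for r in sub.itertuples())
        rts = tuple(float(r.rt_ms) for r in sub.itertuples())
        out.setdefault((subject, session), []).append(
            RecallRecord(str(trial), cells, rts)
        )
    return out


def write_stimuli(stimuli: Sequence[StimulusSequence], path) -> None:
    rows = []
    for stim in stimuli:
        for mv in stim.initial_board.history:
            rows.append(
                (stim.trial_id, "initial", mv.ordinal, mv.color.letter, mv.row,
                 mv.col, stim.ends_in_win, stim.source_game_id)
            )
        for mv in stim.moves:
            rows.append(
                (stim.trial_id, "target", mv.ordinal, mv.color.letter, mv.row,
                 mv.col, stim.ends_in_win, stim.source_game_id)
            )
    pd.DataFrame(
        rows,
        columns=["trial_id", "phase", "move_index", "color", "row", "col",
                 "ends_in_win", "source_game_id"],
    ).to_csv(path, index=False)


def read_stimuli(path) -> list[StimulusSequence]:
    from .game_core import board_from_moves

    df = pd.read_csv(path)
    stimuli = []
    for tid, sub in df.groupby("trial_id", sort=False):
        sub = sub.sort_values("move_index")
        init_moves = []
        targets = []
        for r in sub.itertuples():
            mv = Move(Color.from_letter(str(r.color)), int(r.row), int(r.col),
                      int(r.move_index))
            (init_moves if r.phase == "initial" else targets).append(mv)
        board = board_from_moves(init_moves)
        stim = StimulusSequence(
            str(tid),
            board,
            tuple(targets),
            bool(sub["ends_in_win"].iloc[0]),
            str(sub["source_game_id"].iloc[0]),
        )
        stim.validate()
        stimuli.append(stim)
    return stimuli
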
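"""End-to-end synthetic-study pipeline: simulate, fit, decompose, analyse.

The pipeline stitches the modules together in dependency order and
reproduces the structure of the full analysis on synthetic data with known
ground truth:

1. ``games``       - teacher self-play corpus for schema training
2. ``fit_schema``  - ensemble cross-entropy fit of the gameplay model
3. ``stimuli``     - per-session memory-task stimulus sets
4. ``subjects``    - per-subject/session fixations, recalls and Elo matches
5. ``gaze``        - fixation maps, strategy regression, confidence/surprise
6. ``memory``      - recall scoring, first-mistake schema consistency, RTs
7. ``analysis``    - correlations, mediation, subsequent-memory models
8. ``report``      - consolidated JSON report and tidy CSV tables

Each stage writes its outputs under the run directory and records a content
hash of its inputs; re-running with unchanged inputs skips the stage.  All
randomness flows from named seeds derived from the master seed, so a run is
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import gaze as gz
from . import memory_scoring as ms
from . import schema_model as sm
from . import stats as st
from . import synthetic_data as sd
from .game_core import Move, apply_move, board_from_moves, write_games
from .gaze import EPOCH_MS

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "make_figures", "load_config"]


@dataclass
class RunConfig:
    """Configuration of a full synthetic run (plain-text YAML on disk).

    The defaults define a compact synthetic study: a modest training corpus
    for the schema model and a cohort of subjects whose predictive looking
    depends on playing strength and whose recall depends on both schema
    consistency and predictive looking, so that every analysis stage has
    signal to find.
    """

    out_dir: str = "schemagaze_run"
    seed: int = 0
    log_level: str = "INFO"
    # schema-model training
    n_models: int = 4
    games_per_model: int = 50
    # study shape
    n_subjects: int = 8
    n_sessions: int = 3
    n_trials: int = 10
    n_win_trials: int = 5
    stimulus_pool_per_session: int = 12
    # fixation generation
    n_fix_per_epoch: int = 12
    jitter_px: float = 10.0
    beta_base: tuple = (0.25, 0.1, 0.45, 0.05, 0.2, 0.3)
    beta3_elo_slope: float = 0.25
    beta3_noise: float = 0.08
    # recall generation; the intercept puts mean recall accuracy in the
    # 60-70% range typical of trained participants
    gamma0: float = 2.0
    gamma1: float = 0.8
    gamma0_pred_slope: float = 1.2
    error_model: str = "schema"
    # Elo measurement
    reference_elos: tuple = (-150.0, 0.0, 150.0)
    elo_subject_sd: float = 120.0
    elo_session_gain: float = 25.0
    elo_noise_sd: float = 30.0
    games_per_session: int = 40
    # analysis
    n_boot: int = 2000
    rt_cutoff_ms: float = 30000.0
    # stage toggles (all on by default)
    stages: tuple = (
        "games", "fit_schema", "stimuli", "subjects", "gaze", "memory",
        "analysis", "report",
    )

    def derived_seed(self, name: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def load_config(path: Optional[str] = None, **overrides) -> RunConfig:
    """Load a YAML config file; keyword overrides win over file values."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    for key in ("beta_base", "reference_elos", "stages"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# Stage machinery
# ---------------------------------------------------------------------------


def _hash_inputs(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, Path):
            h.update(p.read_bytes())
        else:
            h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()


def _stage_current(out: Path, stage: str, digest: str, outputs: list[Path]) -> bool:
    mark = out / f".{stage}.hash"
    return (
        mark.exists()
        and mark.read_text().strip() == digest
        and all(p.exists() for p in outputs)
    )


def _mark_stage(out: Path, stage: str, digest: str) -> None:
    (out / f".{stage}.hash").write_text(digest + "\n")


def _cfg_subset(config: RunConfig, *names) -> dict:
    return {n: getattr(config, n) for n in names}


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_games(config: RunConfig, out: Path) -> Path:
    path = out / "train_games.csv"
    digest = _hash_inputs(_cfg_subset(config, "seed", "n_models", "games_per_model"))
    if _stage_current(out, "games", digest, [path]):
        logger.info("stage games: up to date")
        return path
    teacher = sd.default_teacher()
    n = config.n_models * config.games_per_model
    pool = sd.generate_game_pool(teacher, n, seed=config.derived_seed("games"))
    write_games({g.game_id: g.moves for g in pool}, path)
    truth = sd.SyntheticTruth(
        teacher_weights=dict(sd.DEFAULT_TEACHER_WEIGHTS),
        seeds={"games": config.derived_seed("games")},
        extra={"n_games": n},
    )
    truth.save(out / "train_games.truth.json")
    _mark_stage(out, "games", digest)
    return path


def _stage_fit_schema(config: RunConfig, out: Path, games_path: Path) -> Path:
    path = out / "schema_model.txt"
    digest = _hash_inputs(
        _cfg_subset(config, "seed", "n_models", "games_per_model"), games_path
    )
    if _stage_current(out, "fit_schema", digest, [path]):
        logger.info("stage fit_schema: up to date")
        return path
    games = list(sg_read_games(games_path).values())
    model = sm.fit_weights(
        games,
        n_models=config.n_models,
        games_per_model=config.games_per_model,
        seed=config.derived_seed("fit"),
    )
    sm.save_model(model, path)
    _mark_stage(out, "fit_schema", digest)
    return path


def sg_read_games(path):
    from .game_core import read_games

    return read_games(path)


def _stage_stimuli(config: RunConfig, out: Path) -> list[Path]:
    paths = [
        out / f"stimuli_session{s}.csv" for s in range(1, config.n_sessions + 1)
    ]
    digest = _hash_inputs(
        _cfg_subset(
            config, "seed", "n_sessions", "n_trials", "n_win_trials",
            "stimulus_pool_per_session",
        )
    )
    if _stage_current(out, "stimuli", digest, paths):
        logger.info("stage stimuli: up to date")
        return paths
    teacher = sd.default_teacher()
    for s, path in enumerate(paths, start=1):
        pool = sd.generate_game_pool(
            teacher,
            config.stimulus_pool_per_session,
            seed=config.derived_seed(f"stimpool{s}"),
        )
        stims = sd.extract_stimuli(
            pool,
            n_trials=config.n_trials,
            n_win=config.n_win_trials,
            seed=config.derived_seed(f"stimuli{s}"),
        )
        ms.write_stimuli(stims, path)
    _mark_stage(out, "stimuli", digest)
    return paths


def _stage_subjects(
    config: RunConfig, out: Path, model_path: Path, stim_paths: list[Path]
) -> dict:
    """Simulate per-subject/session fixations, recalls, Elo matches."""
    fix_path = out / "fixations.csv"
    rec_path = out / "recalls.csv"
    elo_path = out / "session_elo.csv"
    truth_path = out / "subjects.truth.json"
    outputs = [fix_path, rec_path, elo_path, truth_path]
    digest = _hash_inputs(
        _cfg_subset(
            config, "seed", "n_subjects", "n_sessions", "n_fix_per_epoch",
            "jitter_px", "beta_base", "beta3_elo_slope", "beta3_noise",
            "gamma0", "gamma1", "gamma0_pred_slope", "error_model",
            "reference_elos", "elo_subject_sd", "elo_session_gain",
            "elo_noise_sd", "games_per_session",
        ),
        model_path, *stim_paths,
    )
    if _stage_current(out, "subjects", digest, outputs):
        logger.info("stage subjects: up to date")
        return {"fixations": fix_path, "recalls": rec_path, "elo": elo_path}
    model = sm.load_model(model_path)
    layout = gz.default_layout()
    rng = np.random.default_rng(config.derived_seed("subjects"))
    skills = rng.standard_normal(config.n_subjects)
    all_events: list[gz.FixationEvent] = []
    recalls: dict = {}
    elo_rows = []
    truth_rows = []
    refs = {f"ref{k}": e for k, e in enumerate(config.reference_elos)}
    for si in range(config.n_subjects):
        subject = f"s{si:02d}"
        for sess in range(1, config.n_sessions + 1):
            stims = ms.read_stimuli(stim_paths[sess - 1])
            elo_true = (
                config.elo_subject_sd * skills[si]
                + config.elo_session_gain * (sess - 1)
                + config.elo_noise_sd * rng.standard_normal()
            )
            # the a-path: predictive looking increases with playing strength
            beta = np.array(config.beta_base, dtype=float)
            beta[2] = (
                beta[2]
                + config.beta3_elo_slope * elo_true / max(config.elo_subject_sd, 1.0)
                + config.beta3_noise * rng.standard_normal()
            )
            # the b-path: recall improves with predictive looking
            g0 = config.gamma0 + config.gamma0_pred_slope * (
                beta[2] - config.beta_base[2]
            )
            for t, stim in enumerate(stims):
                ev, _ = sd.simulate_fixations(
                    stim, model, beta,
                    n_fix_per_epoch=config.n_fix_per_epoch,
                    jitter_px=config.jitter_px,
                    seed=config.derived_seed(f"fix:{subject}:{sess}:{t}"),
                    layout=layout, subject=subject, session=sess,
                )
                all_events.extend(ev)
            recs, _ = sd.simulate_recall(
                stims, model, (g0, config.gamma1),
                error_model=config.error_model,
                seed=config.derived_seed(f"recall:{subject}:{sess}"),
            )
            recalls[(subject, sess)] = recs
            # measured Elo from simulated matches against reference bots
            elos = dict(refs)
            elos[subject] = elo_true
            matches = []
            mrng = np.random.default_rng(
                config.derived_seed(f"matches:{subject}:{sess}")
            )
            for ref, re_ in refs.items():
                delta = elo_true - re_
                p = 1.0 / (1.0 + 10.0 ** (-delta / 400.0))
                k = config.games_per_session // len(refs)
                wins = mrng.random(k) < p
                matches.extend((subject, ref, float(w)) for w in wins)
            # reference bots also play each other, anchoring the scale
            ref_items = list(refs.items())
            for ai in range(len(ref_items)):
                for bi in range(ai + 1, len(ref_items)):
                    (ra, ea), (rb, eb) = ref_items[ai], ref_items[bi]
                    p = 1.0 / (1.0 + 10.0 ** (-(ea - eb) / 400.0))
                    wins = mrng.random(20) < p
                    matches.extend((ra, rb, float(w)) for w in wins)
            table = st.elo_fit(matches, anchor=list(refs))
            elo_rows.append((subject, sess, table[subject], elo_true))
            truth_rows.append(
                {
                    "subject": subject, "session": sess,
                    "elo_true": float(elo_true),
                    "beta_true": beta.tolist(), "gamma0": float(g0),
                    "gamma1": config.gamma1,
                }
            )
    gz.write_fixations(all_events, fix_path)
    ms.write_recalls(recalls, rec_path)
    pd.DataFrame(
        elo_rows, columns=["subject", "session", "elo", "elo_true"]
    ).to_csv(elo_path, index=False)
    truth = sd.SyntheticTruth(
        teacher_weights=None,
        mediation_paths={
            "beta3_elo_slope": config.beta3_elo_slope,
            "gamma0_pred_slope": config.gamma0_pred_slope,
        },
        seeds={"subjects": config.derived_seed("subjects")},
        extra={"rows": truth_rows},
    )
    truth.save(truth_path)
    _mark_stage(out, "subjects", digest)
    return {"fixations": fix_path, "recalls": rec_path, "elo": elo_path}


def _trial_epochs(stim: ms.StimulusSequence, model: sm.PolicyModel):
    """Yield (epoch index, board, history, next move, distribution)."""
    board = stim.initial_board
    history: list[Move] = []
    for e, mv in enumerate(stim.moves):
        dist = sm.move_distribution(model, board)
        yield e, board, list(history), mv, dist
        board = apply_move(board, mv)
        history.append(mv)


def _stage_gaze(
    config: RunConfig, out: Path, model_path: Path, stim_paths: list[Path],
    fix_path: Path,
) -> dict:
    coef_path = out / "strategy_coefficients.csv"
    stats_path = out / "gaze_stats.csv"
    digest = _hash_inputs(_cfg_subset(config, "seed"), model_path, fix_path,
                          *stim_paths)
    if _stage_current(out, "gaze", digest, [coef_path, stats_path]):
        logger.info("stage gaze: up to date")
        return {"coef": coef_path, "stats": stats_path}
    model = sm.load_model(model_path)
    layout = gz.default_layout()
    events = gz.read_fixations(fix_path, layout)
    fmaps = gz.fixation_map(events, layout)
    stim_cache = {
        sess: {s.trial_id: s for s in ms.read_stimuli(p)}
        for sess, p in enumerate(stim_paths, start=1)
    }
    # group epochs by (subject, session)
    keys = sorted({(k[0], k[1]) for k in fmaps})
    coef_rows, stat_rows = [], []
    for subject, sess in keys:
        maps, regs = [], []
        for stim in stim_cache[sess].values():
            for e, board, hist, mv, dist in _trial_epochs(stim, model):
                key = (subject, sess, stim.trial_id, e)
                if key not in fmaps:
                    continue
                fm = fmaps[key]
                rs = gz.build_regressors(board, hist, model, dist)
                maps.append(fm)
                regs.append(rs)
                # single-board designs are structurally rank-deficient on
                # boards where a strategy has no instance (e.g. no previous
                # move yet); the pseudoinverse fit is intended, so the
                # collinearity warnings are suppressed here
                st_logger = logging.getLogger("schemagaze.stats")
                level = st_logger.level
                st_logger.setLevel(logging.ERROR)
                try:
                    board_fit = gz.strategy_regression([fm], [rs], level="board")[0]
                finally:
                    st_logger.setLevel(level)
                gs = gz.gaze_stats(fm, board, mv.cell)
                stat_rows.append(
                    (
                        subject, sess, stim.trial_id, e,
                        board_fit.prediction_coefficient if board_fit else np.nan,
                        gs.prediction_confidence, gs.prediction_surprise,
                        gs.p_empty, gs.n_empty,
                        dist.log_prob_of(mv.cell),
                    )
                )
        fit = gz.strategy_regression(maps, regs, level="session")
        coef_rows.append(
            (subject, sess, *fit.beta.tolist(), fit.intercept, fit.r_squared,
             fit.n_epochs)
        )
    pd.DataFrame(
        coef_rows,
        columns=["subject", "session", *[f"beta_{n}" for n in gz.STRATEGY_NAMES],
                 "intercept", "r_squared", "n_epochs"],
    ).to_csv(coef_path, index=False)
    pd.DataFrame(
        stat_rows,
        columns=["subject", "session", "trial", "epoch", "pred_coef_board",
                 "confidence", "surprise", "p_empty", "n_empty", "logp_next"],
    ).to_csv(stats_path, index=False)
    _mark_stage(out, "gaze", digest)
    return {"coef": coef_path, "stats": stats_path}


def _stage_memory(
    config: RunConfig, out: Path, model_path: Path, stim_paths: list[Path],
    rec_path: Path,
) -> dict:
    moves_path = out / "move_scores.csv"
    trials_path = out / "trial_scores.csv"
    digest = _hash_inputs(_cfg_subset(config, "seed", "rt_cutoff_ms"),
                          model_path, rec_path, *stim_paths)
    if _stage_current(out, "memory", digest, [moves_path, trials_path]):
        logger.info("stage memory: up to date")
        return {"moves": moves_path, "trials": trials_path}
    model = sm.load_model(model_path)
    recalls = ms.read_recalls(rec_path)
    stim_cache = {
        sess: {s.trial_id: s for s in ms.read_stimuli(p)}
        for sess, p in enumerate(stim_paths, start=1)
    }
    move_rows, trial_rows = [], []
    for (subject, sess), recs in sorted(recalls.items()):
        for rec in recs:
            stim = stim_cache[sess][rec.trial_id]
            correct, acc = ms.score_recall(stim, rec)
            fm_idx = ms.first_mistake(stim, rec)
            consistent = (
                ms.mistake_schema_consistency(model, stim, rec)
                if fm_idx is not None
                else None
            )
            trial_rows.append(
                (subject, sess, rec.trial_id, acc, len(stim.moves),
                 stim.ends_in_win, fm_idx, consistent)
            )
            board = stim.initial_board
            for i, mv in enumerate(stim.moves):
                logp = sm.log_prob_of_move(model, board, mv.cell)
                rt = (
                    rec.rts_ms[i]
                    if rec.rts_ms is not None and i < len(rec.rts_ms)
                    else np.nan
                )
                move_rows.append(
                    (subject, sess, rec.trial_id, i + 1, mv.row, mv.col,
                     bool(correct[i]), logp, rt)
                )
                board = apply_move(board, mv)
    pd.DataFrame(
        move_rows,
        columns=["subject", "session", "trial", "position", "row", "col",
                 "correct", "logp", "rt_ms"],
    ).to_csv(moves_path, index=False)
    pd.DataFrame(
        trial_rows,
        columns=["subject", "session", "trial", "accuracy", "length",
                 "ends_in_win", "first_mistake", "mistake_schema_consistent"],
    ).to_csv(trials_path, index=False)
    _mark_stage(out, "memory", digest)
    return {"moves": moves_path, "trials": trials_path}


def _stage_analysis(
    config: RunConfig, out: Path, paths: dict
) -> Path:
    report_path = out / "report.json"
    inputs = [paths[k] for k in ("coef", "stats", "moves", "trials", "elo")]
    digest = _hash_inputs(_cfg_subset(config, "seed", "n_boot", "rt_cutoff_ms"),
                          *inputs)
    if _stage_current(out, "analysis", digest, [report_path]):
        logger.info("stage analysis: up to date")
        return report_path
    coef = pd.read_csv(paths["coef"])
    gstats = pd.read_csv(paths["stats"])
    moves = pd.read_csv(paths["moves"])
    trials = pd.read_csv(paths["trials"])
    elo = pd.read_csv(paths["elo"])

    # session-level table
    sess = (
        trials.groupby(["subject", "session"])["accuracy"].mean().reset_index()
        .merge(coef[["subject", "session", "beta_prediction"]],
               on=["subject", "session"])
        .merge(elo[["subject", "session", "elo"]], on=["subject", "session"])
    )
    report: dict = {"n_sessions_rows": int(len(sess))}
    report["per_session_accuracy"] = {
        str(s): float(v)
        for s, v in trials.groupby("session")["accuracy"].mean().items()
    }
    report["per_session_prediction_coefficient"] = {
        str(s): float(v)
        for s, v in coef.groupby("session")["beta_prediction"].mean().items()
    }
    report["correlations"] = {
        "elo_accuracy": st.pearson_r(sess["elo"], sess["accuracy"]),
        "elo_prediction": st.pearson_r(sess["elo"], sess["beta_prediction"]),
        "prediction_accuracy": st.pearson_r(sess["beta_prediction"],
                                            sess["accuracy"]),
    }
    try:
        med = st.mediation_bootstrap(
            sess["elo"].to_numpy(), sess["beta_prediction"].to_numpy(),
            sess["accuracy"].to_numpy(), n_boot=config.n_boot,
            seed=config.derived_seed("mediation"),
        )
        report["mediation"] = {
            "a": med.a, "b": med.b, "c": med.c, "c_prime": med.c_prime,
            "indirect": med.indirect, "ci": [med.ci_low, med.ci_high],
            "p_value": med.p_value, "n_boot": med.n_boot,
        }
    except ValueError as exc:
        report["mediation"] = {"error": str(exc)}

    # move-level subsequent-memory models
    mv = _merge_move_gaze(moves, gstats)
    fits = {}
    for name, terms in (
        ("logp_session", {"logp", "session", "logp_x_session"}),
        ("pred_coef", {"logp", "pred_coef"}),
        ("confidence_surprise", {"confidence", "surprise"}),
    ):
        try:
            X, y, names, _ = st.subsequent_memory_design(mv, terms)
            fit = st.logistic_fit(X, y)
            fits[name] = {
                "coef": dict(zip(names, fit.coef.tolist())),
                "z": dict(zip(names, fit.z_values.tolist())),
                "converged": fit.converged,
                "n": int(len(y)),
            }
        except (ValueError, st.SeparationError) as exc:
            fits[name] = {"error": str(exc)}
    report["subsequent_memory"] = fits

    # first-mistake schema consistency per session
    fmc = trials.dropna(subset=["mistake_schema_consistent"])
    report["mistake_schema_consistency"] = {
        str(s): float(v)
        for s, v in fmc.groupby("session")["mistake_schema_consistent"]
        .mean().items()
    }

    # RT model on correct moves after outlier removal
    kept, removed_frac = ms.filter_rt(moves, config.rt_cutoff_ms)
    rt_fit = st.ols_fit(
        np.column_stack([np.ones(len(kept)), kept["logp"].to_numpy()]),
        kept["rt_ms"].to_numpy(),
    )
    report["reaction_time"] = {
        "removed_fraction": removed_frac,
        "intercept_ms": float(rt_fit.coef[0]),
        "logp_slope_ms": float(rt_fit.coef[1]),
        "n": int(len(kept)),
    }
    report["seeds"] = {"master": config.seed}
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    _mark_stage(out, "analysis", digest)
    return report_path


def _merge_move_gaze(moves: pd.DataFrame, gstats: pd.DataFrame) -> pd.DataFrame:
    """Attach gaze statistics of the epoch *before* each move.

    Epoch ``e`` shows the board before target move ``e + 1`` (1-based
    position), so move ``i`` pairs with epoch ``i - 1``.
    """
    g = gstats.copy()
    g["position"] = g["epoch"] + 1
    g = g.rename(columns={"pred_coef_board": "pred_coef"})
    return moves.merge(
        g[["subject", "session", "trial", "position", "pred_coef",
           "confidence", "surprise"]],
        on=["subject", "session", "trial", "position"], how="left",
    )


def run(config: RunConfig) -> Path:
    """Execute all configured stages; returns the path of the JSON report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    t0 = time.time()
    stages = set(config.stages)
    games_path = _stage_games(config, out) if "games" in stages else None
    model_path = (
        _stage_fit_schema(config, out, games_path)
        if "fit_schema" in stages
        else out / "schema_model.txt"
    )
    stim_paths = _stage_stimuli(config, out) if "stimuli" in stages else []
    sub = (
        _stage_subjects(config, out, model_path, stim_paths)
        if "subjects" in stages
        else {}
    )
    paths = dict(sub)
    if "gaze" in stages:
        paths.update(
            _stage_gaze(config, out, model_path, stim_paths, sub["fixations"])
        )
    if "memory" in stages:
        paths.update(
            _stage_memory(config, out, model_path, stim_paths, sub["recalls"])
        )
    report_path = out / "report.json"
    if "analysis" in stages:
        report_path = _stage_analysis(config, out, paths)
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return report_path


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------


def make_figures(out_dir: str | Path) -> list[Path]:
    """Diagnostic figures from a completed run directory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    made: list[Path] = []

    trials = pd.read_csv(out / "trial_scores.csv")
    coef = pd.read_csv(out / "strategy_coefficients.csv")
    moves = pd.read_csv(out / "move_scores.csv")
    gstats = pd.read_csv(out / "gaze_stats.csv")

    # accuracy by session
    fig, ax = plt.subplots(figsize=(4, 3))
    acc = trials.groupby("session")["accuracy"].agg(["mean", "sem"])
    ax.errorbar(acc.index, acc["mean"], yerr=acc["sem"], marker="o")
    ax.set_xlabel("session")
    ax.set_ylabel("recall accuracy")
    fig.tight_layout()
    p = figdir / "accuracy_by_session.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    made.append(p)

    # prediction coefficient by session
    fig, ax = plt.subplots(figsize=(4, 3))
    pc = coef.groupby("session")["beta_prediction"].agg(["mean", "sem"])
    ax.errorbar(pc.index, pc["mean"], yerr=pc["sem"], marker="o", color="C2")
    ax.set_xlabel("session")
    ax.set_ylabel("prediction coefficient")
    fig.tight_layout()
    p = figdir / "prediction_by_session.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    made.append(p)

    # move probability vs recall
    fig, ax = plt.subplots(figsize=(4, 3))
    bins = np.quantile(moves["logp"], np.linspace(0, 1, 9))
    moves["_bin"] = pd.cut(moves["logp"], np.unique(bins), include_lowest=True)
    bp = moves.groupby("_bin", observed=True).agg(
        logp=("logp", "mean"), acc=("correct", "mean")
    )
    ax.plot(bp["logp"], bp["acc"], marker="o")
    ax.set_xlabel("move log probability (schema consistency)")
    ax.set_ylabel("P(remembered)")
    fig.tight_layout()
    p = figdir / "logp_vs_recall.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    made.append(p)

    # confidence x surprise 2x2
    merged = _merge_move_gaze(moves, gstats).dropna(
        subset=["confidence", "surprise"]
    )
    if len(merged):
        hi_c = merged["confidence"] > merged["confidence"].median()
        hi_s = merged["surprise"] > merged["surprise"].median()
        cells = {
            "conf+/surp-": merged[hi_c & ~hi_s]["correct"].mean(),
            "conf+/surp+": merged[hi_c & hi_s]["correct"].mean(),
            "conf-/surp-": merged[~hi_c & ~hi_s]["correct"].mean(),
            "conf-/surp+": merged[~hi_c & hi_s]["correct"].mean(),
        }
        fig, ax = plt.subplots(figsize=(4.5, 3))
        ax.bar(range(4), list(cells.values()))
        ax.set_xticks(range(4), list(cells.keys()), rotation=20)
        ax.set_ylabel("P(remembered)")
        fig.tight_layout()
        p = figdir / "confidence_surprise.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    return made
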
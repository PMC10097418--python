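"""Regression, bootstrap mediation, and maximum-likelihood Elo estimation.

These are the statistical backends of the analysis stages: ordinary least
squares and logistic regression (used for the strategy decomposition and the
subsequent-memory models), Pearson correlation, a percentile-bootstrap
mediation analysis of the playing-strength -> prediction -> memory pathway,
and a Bradley-Terry maximum-likelihood fit of Elo ratings from win/loss
records.  Random-effects structures are approximated by fixed-effects
regressions with optional per-subject intercepts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

__all__ = [
    "OLSResult",
    "LogisticResult",
    "MediationResult",
    "EloTable",
    "SeparationError",
    "ols_fit",
    "logistic_fit",
    "subsequent_memory_design",
    "pearson_r",
    "mediation_bootstrap",
    "elo_fit",
]

LOG10 = np.log(10.0)
ELO_SCALE = 400.0
ELO_CAP = 1000.0


class SeparationError(ValueError):
    """Logistic regression data are perfectly separated."""


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OLSResult:
    coef: np.ndarray
    stderr: np.ndarray
    r_squared: float
    rank: int
    df_resid: int
    sigma2: float


def ols_fit(X: np.ndarray, y: np.ndarray) -> OLSResult:
    """Least squares via SVD (rank-revealing); pseudoinverse on deficiency.

    ``X`` is the full design matrix including any intercept column.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in design matrix or outcome")
    if X.ndim != 2 or X.shape[0] < X.shape[1]:
        raise ValueError(f"need rows >= columns, got shape {X.shape}")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.warning(
            "rank-deficient design (rank %d < %d columns); pseudoinverse solution",
            rank, X.shape[1],
        )
    resid = y - X @ coef
    df_resid = max(X.shape[0] - rank, 1)
    sigma2 = float(resid @ resid) / df_resid
    xtx_inv = np.linalg.pinv(X.T @ X)
    stderr = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0, None))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(resid @ resid)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return OLSResult(coef, stderr, r2, int(rank), df_resid, sigma2)


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogisticResult:
    coef: np.ndarray
    stderr: np.ndarray
    converged: bool
    n_iter: int
    loglik: float

    @property
    def z_values(self) -> np.ndarray:
        return self.coef / self.stderr


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticResult:
    """ML logistic regression by iteratively reweighted least squares.

    ``X`` includes the intercept column.  Raises on a single-class outcome
    and on perfect separation (detected as diverging linear predictors while
    classifying perfectly).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("y must be binary 0/1")
    if classes.size < 2:
        raise ValueError("both outcome classes must be present")
    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        if np.max(np.abs(eta)) > 30 and np.all((mu > 0.5) == (y > 0.5)):
            direction = beta / max(np.linalg.norm(beta), 1e-12)
            raise SeparationError(
                "perfect separation detected along direction "
                + np.array2string(direction, precision=3)
            )
        W = np.clip(w, 1e-10, None)
        z = eta + (y - mu) / W
        Xw = X * W[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    loglik = float(np.sum(y * np.log(np.clip(mu, 1e-300, 1)) +
                          (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1))))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]))
    stderr = np.sqrt(np.clip(np.diag(cov), 0, None))
    return LogisticResult(beta, stderr, converged, it, loglik)


# ---------------------------------------------------------------------------
# Subsequent-memory design
# ---------------------------------------------------------------------------


def _standardize(v: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu, sd = float(np.mean(v)), float(np.std(v))
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (v - mu) / sd, mu, sd


def subsequent_memory_design(
    dataset: pd.DataFrame,
    terms: set[str],
) -> tuple[np.ndarray, np.ndarray, list[str], dict]:
    """Design matrix for move-level subsequent-memory logistic models.

    ``dataset`` is a move-level table with (as needed) columns ``logp``,
    ``session``, ``pred_coef``, ``confidence``, ``surprise``, ``correct``,
    ``subject``.  ``terms`` selects from {"logp", "session",
    "logp_x_session", "pred_coef", "confidence", "surprise",
    "subject_intercepts"}; continuous predictors are standardized and the
    interaction is the product of the standardized parents.  Rows with
    missing values in the used columns are excluded.  Returns
    (X, y, column names, standardization info).
    """
    known = {"logp", "session", "logp_x_session", "pred_coef", "confidence",
             "surprise", "subject_intercepts"}
    unknown = terms - known
    if unknown:
        raise ValueError(f"unknown terms {sorted(unknown)}")
    need_cols = {"correct"}
    for t in terms:
        if t == "logp_x_session":
            need_cols |= {"logp", "session"}
        elif t == "subject_intercepts":
            need_cols.add("subject")
        else:
            need_cols.add(t)
    missing = need_cols - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset missing required columns {sorted(missing)}")
    df = dataset.dropna(subset=[c for c in need_cols if c != "subject"]).copy()
    y = df["correct"].astype(float).to_numpy()
    cols = [np.ones(len(df))]
    names = ["intercept"]
    std_info: dict = {}
    zcache: dict[str, np.ndarray] = {}

    def z(col: str) -> np.ndarray:
        if col not in zcache:
            zc, mu, sd = _standardize(df[col].to_numpy(dtype=float))
            zcache[col] = zc
            std_info[col] = {"mean": mu, "sd": sd}
        return zcache[col]

    for t in ("logp", "session", "pred_coef", "confidence", "surprise"):
        if t in terms:
            cols.append(z(t))
            names.append(t)
    if "logp_x_session" in terms:
        cols.append(z("logp") * z("session"))
        names.append("logp_x_session")
    if "subject_intercepts" in terms:
        subjects = sorted(df["subject"].astype(str).unique())
        for s in subjects[1:]:  # first subject is the reference level
            cols.append((df["subject"].astype(str) == s).to_numpy(dtype=float))
            names.append(f"subject[{s}]")
    return np.column_stack(cols), y, names, std_info


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Bootstrap mediation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MediationResult:
    """Percentile-bootstrap mediation X -> M -> Y on standardized variables."""

    a: float  # X -> M
    b: float  # M -> Y | X
    c: float  # total X -> Y
    c_prime: float  # direct X -> Y | M
    indirect: float  # a * b at the point estimate
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    seed: int
    n_redrawn: int = 0


def _paths(x, m, y):
    """OLS path coefficients on (already standardized) variables."""
    n = len(x)
    sx, sm, sy = x.sum(), m.sum(), y.sum()
    sxx = x @ x - sx * sx / n
    sxm = x @ m - sx * sm / n
    smm = m @ m - sm * sm / n
    sxy = x @ y - sx * sy / n
    smy = m @ y - sm * sy / n
    a = sxm / sxx
    c = sxy / sxx
    det = sxx * smm - sxm * sxm
    c_prime = (smm * sxy - sxm * smy) / det
    b = (sxx * smy - sxm * sxy) / det
    return a, b, c, c_prime


def mediation_bootstrap(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    n_boot: int = 10000,
    seed: int = 0,
) -> MediationResult:
    """Indirect effect a*b with a 10,000-sample percentile bootstrap CI.

    Variables are z-scored; each bootstrap replicate resamples rows with
    replacement and recomputes a and b; the CI is the 2.5th/97.5th
    percentile of the replicate products, and the two-sided p-value is
    ``2 * min(frac <= 0, frac >= 0)``.  Replicates with degenerate variance
    in x or m are redrawn (count logged).
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if not (len(m) == n == len(y)) or n < 10:
        raise ValueError("x, m, y must have equal length >= 10")
    if not all(np.all(np.isfinite(v)) for v in (x, m, y)):
        raise ValueError("non-finite values")
    for name, v, w in (("x/m", x, m), ("x/y", x, y), ("m/y", m, y)):
        if np.allclose(v, w):
            raise ValueError(f"degenerate input: {name} are identical vectors")
    if np.std(x) == 0 or np.std(m) == 0 or np.std(y) == 0:
        raise ValueError("constant variable")
    zx = (x - x.mean()) / x.std()
    zm = (m - m.mean()) / m.std()
    zy = (y - y.mean()) / y.std()
    a, b, c, c_prime = _paths(zx, zm, zy)

    rng = np.random.default_rng(seed)
    indirects = np.empty(n_boot)
    n_redrawn = 0
    filled = 0
    while filled < n_boot:
        batch = min(n_boot - filled, 4096)
        idx = rng.integers(0, n, size=(batch, n))
        bx, bm, by = zx[idx], zm[idx], zy[idx]
        sx = bx.sum(axis=1)
        sm = bm.sum(axis=1)
        sy = by.sum(axis=1)
        sxx = np.einsum("ij,ij->i", bx, bx) - sx * sx / n
        sxm = np.einsum("ij,ij->i", bx, bm) - sx * sm / n
        smm = np.einsum("ij,ij->i", bm, bm) - sm * sm / n
        sxy = np.einsum("ij,ij->i", bx, by) - sx * sy / n
        smy = np.einsum("ij,ij->i", bm, by) - sm * sy / n
        det = sxx * smm - sxm * sxm
        ok = (sxx > 1e-12) & (det > 1e-12)
        n_redrawn += int((~ok).sum())
        a_star = sxm[ok] / sxx[ok]
        b_star = (sxx[ok] * smy[ok] - sxm[ok] * sxy[ok]) / det[ok]
        take = min(int(ok.sum()), n_boot - filled)
        indirects[filled : filled + take] = (a_star * b_star)[:take]
        filled += take
    if n_redrawn:
        logger.info("redrew %d degenerate bootstrap replicate(s)", n_redrawn)
    ci_low, ci_high = np.percentile(indirects, [2.5, 97.5])
    p = 2.0 * min(float(np.mean(indirects <= 0)), float(np.mean(indirects >= 0)))
    return MediationResult(
        a=float(a), b=float(b), c=float(c), c_prime=float(c_prime),
        indirect=float(a * b), ci_low=float(ci_low), ci_high=float(ci_high),
        p_value=min(p, 1.0), n_boot=n_boot, seed=seed, n_redrawn=n_redrawn,
    )


# ---------------------------------------------------------------------------
# Elo (maximum-likelihood Bradley-Terry on the Elo scale)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EloTable:
    """Fitted ratings; anchor-set mean is 0; p(win) = 1/(1+10^(-d/400))."""

    ratings: dict
    anchor: tuple
    loglik: float
    warnings: tuple = ()

    def __getitem__(self, player) -> float:
        return self.ratings[player]

    @staticmethod
    def win_probability(delta: float) -> float:
        """Probability the higher-rated side wins given the rating gap."""
        return 1.0 / (1.0 + 10.0 ** (-delta / ELO_SCALE))


def _components(players, matches):
    parent = {p: p for p in players}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for i, j, _ in matches:
        parent[find(i)] = find(j)
    comps: dict = {}
    for p in players:
        comps.setdefault(find(p), []).append(p)
    return list(comps.values())


def elo_fit(
    matches: Sequence[tuple],
    anchor: Sequence | None = None,
) -> EloTable:
    """ML Elo ratings from (player_i, player_j, score_i) records.

    ``score_i`` is 1 for a win by player i, 0 for a loss, 0.5 for a draw.
    The likelihood is the Bradley-Terry model on the Elo scale
    (p = 1/(1+10^(-(R_i-R_j)/400))); it is invariant to a global shift, so
    the mean rating of the anchor set (default: all players) is fixed to 0.
    Players with all wins or all losses are capped at +/-1000 with a warning.
    Raises on a disconnected comparison graph, listing the components.
    """
    matches = [(i, j, float(s)) for i, j, s in matches]
    for _, _, s in matches:
        if s not in (0.0, 0.5, 1.0):
            raise ValueError("scores must be 0, 0.5 or 1")
    players = sorted({p for i, j, _ in matches for p in (i, j)}, key=str)
    if len(players) < 2:
        raise ValueError("need at least 2 players")
    comps = _components(players, matches)
    if len(comps) > 1:
        raise ValueError(
            f"comparison graph is disconnected; components: {comps}"
        )
    idx = {p: k for k, p in enumerate(players)}
    ii = np.array([idx[i] for i, _, _ in matches])
    jj = np.array([idx[j] for _, j, _ in matches])
    ss = np.array([s for _, _, s in matches])
    n = len(players)
    # detect extreme players before fitting: total score 0 or maximal
    totals = np.zeros(n)
    counts = np.zeros(n)
    np.add.at(totals, ii, ss)
    np.add.at(totals, jj, 1.0 - ss)
    np.add.at(counts, ii, 1.0)
    np.add.at(counts, jj, 1.0)
    extreme = (totals == 0) | (totals == counts)

    def nll(r_free):
        r = np.concatenate([[0.0], r_free])
        d = r[ii] - r[jj]
        # log p and log(1-p) for p = 1/(1+10^(-d/400))
        u = d * LOG10 / ELO_SCALE
        log_p = -np.logaddexp(0.0, -u)
        log_q = -np.logaddexp(0.0, u)
        val = -np.sum(ss * log_p + (1 - ss) * log_q)
        p = np.exp(log_p)
        g = np.zeros(n)
        coef = (ss - p) * LOG10 / ELO_SCALE
        np.add.at(g, ii, -coef)
        np.add.at(g, jj, coef)
        return val, g[1:]

    res = minimize(
        nll,
        np.zeros(n - 1),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-4 * ELO_CAP, 4 * ELO_CAP)] * (n - 1),
        options={"maxiter": 2000, "gtol": 1e-8},
    )
    r = np.concatenate([[0.0], res.x])
    warns = []
    anchor = list(anchor) if anchor is not None else list(players)
    anchor_idx = [idx[p] for p in anchor]
    r = r - r[anchor_idx].mean()
    for k, p in enumerate(players):
        if extreme[k] and abs(r[k]) > ELO_CAP:
            r[k] = np.sign(r[k]) * ELO_CAP
            msg = f"player {p!r} has all wins or all losses; rating capped"
            warns.append(msg)
            logger.warning(msg)
    final_nll, _ = nll((r - r[0])[1:])
    return EloTable(
        ratings={p: float(r[idx[p]]) for p in players},
        anchor=tuple(anchor),
        loglik=-float(final_nll),
        warnings=tuple(warns),
    )
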
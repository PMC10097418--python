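# Methods

This note documents the models implemented in `schemagaze`, the defaults
and the reasoning behind them, what the synthetic-data generators do and do
not emulate, and the numerical choices that matter for reproducing results.

## Board, windows, and move features

The game is played on a 4 × 9 grid (rows 0–3 top→bottom, columns 0–8
left→right, 0-based everywhere, black moves first).  All pattern counting
uses the 45 *windows* — the maximal 4-cell contiguous lines (24 horizontal,
9 vertical, 12 diagonal).  A window contributes to the mover's
*k*-in-a-row count for a candidate move if, after the hypothetical
placement, it contains exactly *k* own pieces and no opponent piece.
"Connected" means the own pieces are contiguous within the window;
"disconnected" otherwise.  A *horizontally connected open* triple is a
contiguous horizontal triple whose two flanking cells (possibly outside
the window) are on-board and empty after the placement; such windows are
counted separately and excluded from the plain connected-triple count,
because an unblocked horizontal triple forces a win.  Blocking counts are
computed pre-placement: a window containing the candidate with exactly
*k* opponent pieces and no own piece blocks an opponent *k*-in-a-row; the
"open horizontal pair" sub-category requires the opponent pair to be
horizontally contiguous with both flanks on-board and empty and the
candidate occupying one flank.  The full feature vector per candidate move
is: horizontal-centre distance `|col − 4|`, vertical-centre distance
`|row − 1.5|`, and the nine pattern counts.  Because windows, not piece
subsets or maximal runs, are the counting unit, a given triple spanning
two windows counts twice; the choice is deterministic, mirror-symmetric,
and verified feature-by-feature against an independent brute-force oracle
in the test suite.  The three-in-a-row sub-categories are treated as
mutually exclusive.

## Schema (gameplay) model

Moves are valued linearly, `V(x) = w · F(x)`, and converted to a policy by
a softmax over the legal moves (temperature fixed at 1; any temperature is
absorbed into `w`).  Natural logarithms are used throughout, so
cross-entropies and log probabilities are in nats.  Training minimises the
mean cross-entropy of the moves in a game corpus, treating both colours'
moves as examples with features computed from the mover's perspective.

The ensemble protocol shuffles the corpus with a seeded permutation,
partitions it into `n_models` disjoint blocks of `games_per_model` games
(defaults 8 × 100), fits each block independently, and averages the weight
vectors.  Each block fit is full-batch gradient-based optimisation
(L-BFGS on the analytic gradient, which uses first-order information
only) from `w = 0`, with gradient tolerance 1e-6 and a 500-iteration
budget; no regularisation.  The loss trace is recorded and is
non-increasing; non-convergence is flagged in the model metadata without
discarding the result.  The analytic gradient is verified against central
finite differences in the tests.

## Synthetic teacher and game generation

No published weight vector exists for a strong player, so the generator
uses a hand-set, documented teacher: decisive wins (`f_four = 6`), threats
ordered three > two with the open horizontal triple strongest, strong
blocking (`f_block3 = 6`, open-pair block 2), and a mild centre preference
(−0.15/−0.05 per column/row of centre distance).  The blocking weights
were chosen so that self-play lasts tens of moves — with weak blocking the
first unanswered threat ends the game within ~10 moves, which starves the
17–35-move stimulus pool.  With these defaults roughly a third of
self-play games fall in the pool bounds and draws are rare.

`generate_game_pool` rejection-samples decisive games of 17–35 moves and
aborts if acceptance falls below 1%.  `extract_stimuli` draws one segment
per unique game: 30 trials, lengths 4–8, the first segment move always
after the fifth game move (so schematic prediction is always possible),
and 10 segments (two per length) ending exactly at the game's winning
move; non-winning segments end strictly before the final move.  Segments
preserve the source game's colour alternation.

## Fixation maps and the strategy regression

Encoding is divided into 5000-ms epochs: the initial board, then one epoch
per revealed move.  Analyses cover the epochs that have an upcoming move
within the sequence (initial board through the penultimate move's epoch);
the epoch after the final move has no next move to predict — and on
win-ending trials no legal continuation — so it is excluded.

Each fixation's duration is soft-assigned to the 36 squares with the
Gaussian kernel `exp(−d² / τ)`, distances in pixels, normalised over
squares; τ defaults to 25 exactly as the formula is stated, although the
accompanying verbal gloss ("about one fifth of the 136-px square length")
would suggest an effective spatial scale of 25 px rather than the
√25 = 5 px the formula implies.  The formula wins; τ is configurable.  In
practice either value assigns virtually all mass to the nearest square
except very near boundaries.  Fixations farther than one square length
(136 px) from every square centre are discarded (counted and logged),
since the softmax would otherwise hand their full weight to the nearest
edge square regardless of distance.  Fixations straddling an epoch
boundary are truncated at the boundary.  Per fixation, the assigned
weights sum to its (retained) duration to better than 1e-9 relative — the
mass-conservation invariant.

The six per-board regressors are: (1) indicator of the most recent move;
(2) occupied squares within Chebyshev distance 3 of the most recent move —
the move's own square belongs to regressor 1 and is excluded here; (3) the
model's next-move probability on empty squares, with occupied squares set
to the empty-square mean; (4) for occupied squares the summed next-move
probability of nearby (Chebyshev ≤ 3) empty squares, with empty squares
set to the occupied-square mean; (5) indicators of sequence moves seen
earlier, excluding the most recent — initial-board pieces are *not*
included (configurable decision; the regressor is described as covering
moves seen earlier *in the sequence*); (6) occupancy.  Maps and
regressors are z-scored within each board (population SD; zero-variance
vectors centre to exact zeros) and either concatenated across epochs into
one OLS fit per session or fitted per board.  An intercept is included; it
is ≈ 0 after z-scoring but stabilises degenerate epochs.  Rank-deficient
designs (structural at board level, e.g. the initial board has empty
regressors 1 and 5) are solved by pseudoinverse with a logged warning.

A subtlety that matters for synthetic validation: because the outcome map
is re-z-scored within each board, a constructed map `Σ βk z(Rk)` only
returns `β` exactly if its per-board SD is already 1 — otherwise every
coefficient is rescaled by 1/SD.  The recovery tests therefore build maps
as the mixture plus a residual orthogonalised against the design that
fills the variance to exactly 1 (plus, in the noisy variant, Gaussian
noise of σ = 0.5 included in the variance budget).  This leaves the
coefficients untouched and makes exact recovery a meaningful check rather
than an artefact.

Confidence and surprise are computed per epoch in nats: confidence is
`P(empty) · (ln N_empty − H[P])` with `P` the fixation distribution
normalised over empty squares and `0 · ln 0 := 0`, bounded by
`ln N_empty`; surprise is `−ln` of the fraction of fixation time on the
square where the next move actually appears, with the fraction clamped
below at ε = 1e-3 (so surprise ≤ ~6.91 nats) because a map can put exactly
zero mass on a square.  Epochs with zero retained fixation time yield
missing values and are excluded downstream.

## Memory scoring

Recall is scored strictly: move *i* is correct iff the *i*-th recalled
cell equals the *i*-th target cell (colour follows from alternation);
missing tail moves are incorrect; accuracy is the correct fraction of the
stimulus length.  Error analyses use only the *first* mistake — afterwards
the encoding and retrieval boards diverge and move probabilities are no
longer comparable — and ask whether the model probability of the recalled
cell strictly exceeds that of the correct cell on the true board; ties
count as not-more-consistent (measure-zero under generic weights, and the
conservative reading for the uniform model).  Reaction-time analyses use
correct moves only and drop RTs above 30 s, reporting the removed
fraction.

## Statistics

OLS uses an SVD solve (pseudoinverse on rank deficiency, logged); logistic
regression is maximum likelihood via IRLS (tolerance 1e-8, 100 iterations)
with explicit detection of single-class outcomes and perfect separation.
Both are cross-checked against statsmodels in the tests at 1e-6.  The
mixed-effects models of a real analysis are deliberately approximated by
fixed-effects regressions with optional per-subject intercept indicators;
the bespoke content here is the measures and design, not the mixed-model
machinery, and this is a documented limitation.

Mediation z-scores the three variables globally, estimates `a` (M ~ X),
`b`, `c′` (Y ~ X + M) and `c` (Y ~ X) by OLS, and bootstraps the indirect
effect `a*·b*` over 10,000 row resamples; the CI is the 2.5th/97.5th
percentile and the two-sided p-value is `2 · min(frac ≤ 0, frac ≥ 0)`.
Replicates with degenerate variance are redrawn and counted.  On
standardized variables the identity `c = c′ + a·b` holds exactly at the
point estimate.

Elo ratings are maximum-likelihood Bradley–Terry fits on the Elo scale,
`p(i beats j) = 1 / (1 + 10^{−(R_i − R_j)/400})`, draws scored 0.5,
gauge fixed by setting the anchor set's mean rating to zero (the
likelihood is shift-invariant, which the tests verify before anchoring).
A Bayesian rating engine would differ mainly in shrinkage; the ML fit is
reproducible without external binaries and uses the identical scale.
Disconnected comparison graphs are rejected with the components listed;
players with all wins or all losses have no finite MLE and are capped at
±1000 with a warning.

## Synthetic study and pipeline

`simulate_fixations` turns a known strategy mixture `Σ βk z(Rk)` into a
sampling distribution by a softmax at temperature 1.0, samples a fixed
number of fixation squares per epoch (default 12), and emits events at
square centres plus isotropic Gaussian jitter (default σ = 10 px) with
equal durations summing to 5000 ms.  `simulate_recall` remembers each move
with probability `logistic(γ0 + γ1 · logp)` on the raw log-probability
scale and replaces forgotten moves with a schema-sampled (or uniform)
wrong cell among the cells still free on the true board; reaction times
are lognormal with a negative coefficient on `logp` (defaults
μ0 = 7.2, μ1 = −0.25, σ = 0.35, i.e. median ≈ 1.3 s and faster for
schema-consistent moves).  `simulate_sessions` produces standardized
(x, m, y) triples with exact population paths (indirect = a·b), and
`simulate_matches` draws Bernoulli wins from true rating gaps.  Every
generator is seeded and persists a truth sidecar sufficient for exact
regeneration.

The pipeline composes these into a cohort: each subject has a latent
skill; per session a true Elo (skill + session gain + noise) drives the
subject's prediction-strategy weight (the a-path), which in turn raises
the recall intercept (the b-path); measured Elo comes from fitted match
records against three reference bots (who also play each other, anchoring
the scale), measured prediction coefficients from the strategy regression
on the simulated fixations, and measured accuracy from scoring the
simulated recalls.  The default recall intercept (γ0 = 2.0, γ1 = 0.8)
puts mean accuracy in the 60–70% range typical of trained participants.
Stages cache on a content hash of their inputs and all seeds derive from
the master seed, so a run is byte-reproducible and a re-run with unchanged
inputs is a no-op.

The generators emulate the *structure* of real data — epoch timing, board
geometry, strategy mixtures, logistic subsequent memory, rating-driven
win records — but not saccade dynamics, centre bias beyond the mixture,
drift or calibration error, fatigue, or any within-session learning.
Passing recovery tests therefore demonstrates that the analysis machinery
is correct and well-calibrated, not that these effects exist in human
data.

## Problem sizes and validation scales

The test and acceptance runs use: 800 self-play games (plus 100 held out)
for the 8 × 100 ensemble recovery; 200 epochs for noisy
strategy-coefficient recovery (tolerance ±0.05 at σ = 0.5) and 100
replicates for full-path dominant-strategy identification; n = 5000 moves
for logistic recovery (±0.1); n = 500 sessions and 10,000 bootstrap
resamples for mediation (point within ±0.08 of the true 0.20); 200 games
per pair for three-player Elo recovery (gaps within ±80); 2000 draws for
the uniform-guessing closed form (3 SE); and a compact 3-subject,
2-session study for byte-identity of the full pipeline.  The
schema-guessing check uses a nested stimulus pool (all five lengths share
a start within each source game, 50 games), which makes declining accuracy
with sequence length a property of the construction — averaging a
decreasing per-position accuracy over more positions — rather than a race
against between-board sampling noise.

## Known limitations

Fixed-effects approximations in place of random-slope mixed models; the
window counting convention is one of several defensible readings of the
verbal feature taxonomy; the prediction regressors use the fitted schema
model itself, so gaze "prediction" is only as good as the imitation fit;
the surprise clamp and the off-board cutoff are pragmatic choices; and the
synthetic cohort encodes its mediation paths through simple linear
couplings, so it cannot probe nonlinear or within-subject mechanisms.
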
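# Methods

## Assessment patterns and the beat grid

Both assessment patterns are four-beat bars played to constant-tempo songs,
so the reference timing is a rigid grid anchored at a configurable song
offset (default 0 ms): bar *k* starts at `offset + k · bar_ms`, and a bar is
scored iff its start time falls in the half-open capture window
`[start, end)` (default 60–180 s, the two-minute capture from minute 1 to
minute 3 of the song). The half-open convention avoids double-counting at
the boundaries; with the defaults, a 120 bpm quarter-note pattern yields
exactly 60 scored bars.

Pattern definitions (strike = limb × instrument):

* **quarter_pattern** — beats 1 and 3: right hand (ride) + right foot
  (kick); beats 2 and 4: right hand (ride) + left hand (snare) + left foot
  (hi-hat pedal). 10 strikes per bar.
* **eighth_pattern** — closed hi-hat (right hand) on all eight eighth notes,
  kick on beats 1 and 3, snare on beats 2 and 4. 12 strikes per bar.

The completion tolerance is half the pattern's subdivision interval:
`0.5 · 60000/bpm` ms for the quarter pattern and half that for the eighth
pattern — 250 ms and 125 ms at the default 120 bpm. The default tempo is
chosen exactly so that the half-beat rule lands on those two round
tolerances; both tempo and tolerance are overridable. For the eighth
pattern "half a beat" is interpreted as half the *eighth-note* interval;
taking it literally as half a quarter note would make the eighth pattern no
stricter than the quarter pattern, contradicting the 125 ms constant.

## Event matching

Events are pooled per instrument over the whole grid and assigned to
expected strikes one-to-one (an event can satisfy at most one strike,
anywhere). The objective is lexicographic: maximize the number of strikes
matched within tolerance, then minimize the summed |deviation|; exact
distance ties resolve toward the earlier event (implemented as an
infinitesimal per-event-index cost penalty, 1e-7 ms per index — far below
timing resolution). A slot-sequential greedy nearest-neighbour rule was
rejected because it is provably suboptimal (a single event between two
slots of the same instrument can be captured by the wrong slot), and
optimality is what makes the matcher testable against an exhaustive
assignment oracle.

The assignment is solved with `scipy.optimize.linear_sum_assignment` on a
cost matrix holding |deviation| for feasible pairs and a prohibitively
large constant for out-of-tolerance pairs. Because no feasible pair spans
more than the tolerance, the problem decomposes exactly at every gap larger
than the tolerance in the merged sorted positions; each connected block is
solved independently, keeping long captures (thousands of bars) linear in
practice. Unmatched extra events are ignored: completion is defined by
presence-within-tolerance only.

A bar is **completed** iff every expected strike matched within tolerance.
**Flam** spreads (max − min of matched onsets at a multi-strike slot) are
recorded only for completed bars. **HRS** pools the slot-level flams of
beats 2 and 4 across completed bars and averages them (pooling, rather than
averaging per-bar means first, weights every beat equally and is the
convention used throughout); it is undefined (None/NaN) when no bar was
completed. Delta scores report both the raw post−pre change in ms and the
percent precision change `100·(pre − post)/pre`; the raw ms difference is
the default input to downstream tests, with the percent form selectable in
the pipeline configuration.

## Synthetic drummer

Each expected strike is emitted with probability `1 − miss_prob` at
`nominal + lag[limb] + N(0, jitter_sd[limb]²)`; spurious extra hits arrive
as a Poisson count per bar, uniform in time and over the kit's instruments
(deliberately uncorrelated with the grid, to stress the one-to-one
matcher). Jitter is i.i.d. per strike — the simplest model with a closed
form: under scalar jitter σ and miss rate m, a k-strike bar completes with
probability `[(1 − m)(2Φ(tol/σ) − 1)]^k`, which the scorer's empirical
completion fraction must reproduce (a standing Monte-Carlo check).
`learning_gain` multiplies jitter and miss probability at the post-training
assessment, emulating skill acquisition.

What the generator does *not* model: tempo drift and autocorrelated timing
of real players, velocity/loudness structure, biomechanical coupling
between limbs, and pattern-dependent error (novices break down in bursts,
not i.i.d.). Passing tests therefore demonstrate correctness of the
scoring and statistics machinery under a known timing model, not fidelity
to human drumming. Novice jitter magnitudes (default draws of 40–120 ms SD
in the synthetic study) are plausible-scale placeholders, not measured
values.

## Synthetic cohort

One row per subject × timepoint, with group (drum/control), sex, age and
measure columns named by prefix (`vol_`, `fa_`, `md_`, `thick_`,
`score_`). Lobular volumes share a latent per-subject cerebellar scale
`s ~ N(1, between_sd²)`:
`v = baseline · s · (1 + within_sd · z) + effect · 1[drum, T2]`, so the
summed TCV genuinely correlates with every lobule and the residualization
has structure to remove. Other measures use independent per-subject
deviations. Because the default measures span four orders of magnitude,
`between_subject_sd` (default 0.08) and `within_subject_sd` (default 0.02)
are *relative* (coefficients of variation); injected effects remain in
measure units. Default group sizes are 15 drummers / 16 controls with
deterministic sex assignment (7/8 and 8/8 male/female at the 0.5 sex
ratio) and ages uniform on 16–19 y — the design shape of the motivating
cohort. Baseline means for the four tabulated lobular volumes, ICP
diffusion and four thickness regions follow that cohort's baseline
columns; the remaining lobules, needed only so TCV has realistic
composition, are set once to atlas-plausible proportions on the same scale.

## Statistical pipeline

* **TCV residualization** — TCV is the row sum of all lobular volume
  columns (vermis subregions included). Each lobule is residualized
  against TCV by a pooled OLS fit across all rows (both groups, both
  timepoints), and the grand mean is added back so corrected volumes keep
  their units. Zero-variance TCV leaves volumes unchanged, with a warning.
  Residual⊥TCV to 1e-10 is asserted in tests.
* **Mann-Whitney U** — exact null distribution when `n_x + n_y ≤ 20` and
  the pooled sample is tie-free; otherwise the normal approximation with
  tie and continuity corrections. Identical samples return p = 1.
* **χ² independence** (group × sex) — Pearson, df = 1, Yates continuity
  correction off by default (selectable).
* **ANCOVA** — OLS of the response on group + covariates over an explicit
  design matrix; default response is the post−pre delta with sex
  (male = 0, female = 1) as covariate, age addable, and a
  post-adjusting-for-pre design available. Reported: the corrected-model F
  (all predictors vs intercept) and the group F (Wald F on the group
  column — identical to type III for a binary factor). A constant response
  short-circuits to F = 0, p = 1; rank-deficient designs raise with the
  aliased columns named.
* **Rank correlation** — Spearman's ρ and Kendall's τ-b are both always
  reported (published analyses of this kind are ambiguous about which was
  used, so neither is privileged). Two-sided p is exact by full
  permutation enumeration for n ≤ 7, asymptotic otherwise.
* **Drum-score deltas** — Shapiro-Wilk on each group's deltas gates the
  choice between an independent-samples t-test (both normal at α) and the
  Mann-Whitney U, mirroring the usual practice for these skewed scores.
* **Multiple testing** — none by default (per-measure α = 0.05);
  Benjamini-Hochberg is available as an explicitly labelled extra column,
  never applied silently.

The per-measure report rows carry before/after group means (volumes after
TCV correction), both F statistics with df, raw p, a significance flag at
α, and the drum-minus-control delta difference as a direction indicator.
Subjects missing a timepoint are excluded with a warning and listed in the
report.

## Numerical and problem-size choices

Monte-Carlo checks use 2000 simulated bars for completion-probability
agreement (3-SE bands on the closed form), 500 bars for jittered flam
recovery against the numerically integrated expectation of the Gaussian
range, 500 null cohorts for type-I calibration and 200 for power — sizes at
which the MC standard errors are small enough to be informative while the
suite stays fast. Matching uses a 1e-9 ms feasibility slack so exact
boundary deviations (|dev| = tolerance) count as within tolerance. All
generators are `numpy.random.default_rng`-seeded and bit-reproducible;
derived seeds stay below 2³¹.

## Known limitations

* The MIDI reader supports SMF type 0/1 with tick-per-quarter divisions
  only (no SMPTE), which covers electronic-kit exports.
* The i.i.d. jitter model understates the serial correlation of human
  timing errors; an AR(1) option was considered and left out of scope.
* Degrees of freedom in the ANCOVA follow the per-subject delta model
  (df_resid = n − p); published tables in this literature sometimes quote
  larger, unexplained df, which this package does not imitate.
* With heavy dropout or very large jitter the optimal matcher can complete
  a bar using a neighbouring bar's stray event if it falls within
  tolerance; this is by construction (completion is presence-based), and
  the closed-form completion oracle remains accurate because such rescues
  require deviations near the tolerance boundary.
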
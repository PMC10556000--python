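# Methods

## Signals and preprocessing

The pipeline operates on per-participant series at conventional rates:
heart rate (HR, bpm), respiration rate (RR, breaths/min) and phasic
skin-conductance response (SCR, µS) at 1 Hz; the raw respiration-belt
signal (RESP, a.u.) at 10 Hz; motion energy (MOVE, pixel counts) at
15 Hz.  Beat-wise or breath-wise instantaneous signals are converted to
uniform grids by linear interpolation; grid points outside the event
support are missing.  Missing samples are carried as NaN and propagate
conservatively: any missing source sample poisons its downsampling bin,
and any missing sample inside an analysis segment invalidates the whole
segment, so every synchrony value is computed from fully observed
windows only.

Respiration preprocessing is low-pass → demean → bin-average to 10 Hz.
The low-pass is a zero-phase (forward–backward) Butterworth of order 4
with 0.6 Hz cutoff.  Neither the filter family/order nor the
downsampling kernel is canonical for this kind of data; the choices
here are declared, not inferred: zero-phase filtering because any phase
shift would masquerade as a synchrony lag downstream, order 4 as the
standard compromise between rolloff and ringing, bin-averaging because
it is deterministic and exactly checkable against a loop oracle.
Reflection padding of five filter time constants suppresses filtfilt
edge transients.  Sample k of a rate-ρ series represents time
t0 + k/ρ (0-based).

## SUSY

Segments of 30 s; lags τ ∈ ±5 s in steps of one sample; Pearson
correlation on the trimmed overlap (no zero-padding, which would
manufacture spurious correlation); r clipped to ±(1 − 10⁻⁶) before
Z = atanh r so that degenerate perfect correlations stay finite.  The
per-segment statistic is the plain (non-absolute) mean of Z over all
2·max_lag+1 lags; real synchrony is its mean over aligned valid segment
pairs; the surrogate set is the exhaustive off-diagonal pairings (i, j),
i ≠ j — n(n−1) surrogates for n segments — with an optional seeded
subsample for very long recordings.  ES = (Z_real − mean Z_surr)/sd
Z_surr, sign preserved (in-phase > 0, anti-phase < 0).  A dyad needs at
least 2 valid aligned pairs and 10 valid surrogate pairs, otherwise it
is flagged missing rather than estimated.

Lag averaging happens before surrogate differencing, at both the real
and the surrogate level, and the per-concert value pools all piece
segments (the per-piece mean is available by aggregating the per-piece
results); both conventions are fixed here because the original
formulation leaves them open.

## mv-SUSY

Segments of 5 s; per segment the m × m Pearson correlation matrix
between series and its largest eigenvalue λmax; empirical synchrony is
the mean segment λmax over segments valid in every series (listwise);
participants missing more than 50% of segments are excluded from the
audience for that channel.  The null permutes the segment order of each
series independently (identity permutations allowed — excluding them
would bias the null), 1000 times by default, recomputing the mean
segment λmax each time; ES as in SUSY.

`lambda_mode` selects the scale: `raw` reports the largest eigenvalue
itself (range [1, m]); `ratio` divides by the eigenvalue sum, i.e. by
m, giving [1/m, 1].  The method is sometimes *defined* on the ratio
scale yet *reported* on the raw scale (values of 8–10 for audiences of
m ≈ 40); both modes are provided and `raw` is the default, matching how
results of this kind are printed.  The discrepancy is surfaced here
rather than hidden.

Implementation: each (series, segment) is z-scored once; every
correlation any permutation can require is an inner product of two such
unit rows, so a cross-segment Gram tensor is precomputed and each
permutation reduces to an index gather plus one batched
eigendecomposition.  Surrogate shuffles are drawn from per-series
streams seeded by (seed, series identity), which makes the draw
independent of iteration order and — critically — identical for the
shared series of a full audience and any leave-one-out subset.

## Significance

Dyadic synchrony per channel and scope is tested by a one-sample
Student t of the ES values against 0, two-sided (anti-phase is
meaningful).  The dyadic values share members and are therefore not
independent; the test treats them as if they were, replicating the
source procedure — a deliberate fidelity choice, flagged as a
statistical caveat.  A per-participant alternative (`test_unit =
"participant"`, testing the contribution values) is exposed.
Multivariate synchrony is tested one-sided: t of the differences
(λmax − λmax_surr_k) against 0, greater, since the hypothesis is
directional.

## Contribution

Dyad-mean: contribution(X) = mean of X's finite dyadic ES values;
missing dyads are excluded, not imputed, so per-measure N varies
naturally.  The audience mean of contributions equals the grand mean
dyadic ES exactly (each dyad appears in exactly two row means).
Leave-one-out: contribution(X) = ES_total − ES_total−X, where both runs
share the segment grid and, via identity-keyed surrogate streams, the
same shuffles on shared series.  This sharing is what makes the
difference usable: ES values of strongly coupled audiences are large
(tens of surrogate SDs), and the ~sqrt(1/(2(n_perm−1))) relative jitter
of each run's surrogate-SD denominator would otherwise dominate the
between-member differences.  Residual variation across exchangeable
members reflects genuine noise-realization differences, not Monte-Carlo
error, and does not vanish with more permutations.

## Stepwise regression

Ordinary least squares of contribution on covariates.  Backward path:
from the full model, repeatedly remove the predictor whose removal most
decreases AIC = n·ln(RSS/n) + 2k (k counting the intercept; constants
cancel in comparisons), stopping when no removal decreases AIC; ties
are broken by dropping the predictor with the largest p-value.  A
second pass deletes remaining predictors with p ≥ α (default 0.05) one
at a time, refitting, until all retained predictors are significant or
the null model remains.  Both the AIC-optimal and the pruned model are
reported (`aic_predictors` vs `predictors`).  Rank-deficient designs
raise an error naming the collinear columns.  Rows with any missing
value are dropped listwise.

## Motion energy

Counts of pixels whose gray level changes by more than a threshold
between consecutive frames, inside half-open per-participant
rectangles that must not overlap.  The threshold default is 10 gray
levels — a sensor-noise guard; the thresholding of existing MEA
software is not documented, so parity with any specific tool is not
claimed.  Color frames are converted by Rec. 601 luma before
differencing.  Raw counts are the default; `normalize=True` divides by
ROI area.  Frame input is a lexicographically ordered PNG directory (or
in-memory arrays); container-format decoding is intentionally out of
scope.

## Synthetic audiences

The generator emulates stimulus-driven (induction) synchrony: a single
shared zeitgeber per concert — a standardized sum of an AR(1) with
0.95 autocorrelation per second and two incommensurate slow sinusoids
(0.08 Hz and 0.08√2 Hz) — drives participant i's channels as

    x_i(t) = g_i · z(t − τ_i) + sqrt(1 − g_i²) · ε_i(t),

with ε_i standardized AR(1) noise (φ_i ~ U(0.3, 0.7)).  Components are
mixed *after* downsampling to the channel rate so the variance budget
holds exactly there: channel variance is constant in g_i and measured
synchrony differences reflect coupling, not amplitude.  Default gains
are U(0.3, 0.9); default lags U(−2, 2) s — heterogeneous response
latencies of a couple of seconds, comfortably inside the ±5 s SUSY
window.  Channels are affinely mapped into physiological ranges (HR
80 ± 10 bpm, RR 16 ± 3 breaths/min, RESP zero-mean a.u.) or through a
softplus for the non-negative channels (SCR; MOVE scaled ×20).  The
RESP channel is generated uncoupled by default (channel coupling
multiplier 0), emulating a stimulus that entrains breathing rate but
not breathing behavior.  Missing data are inserted as contiguous
blocks of ~10 s (sensor dropouts) at a configurable rate.

Trait tables contain five 1–5 trait scales and three 1–7 affect
scales; one designated column ("openness") is generated at a target
correlation to the standardized true gains and mapped to its scale by
a monotone min-max transform, which preserves rank correlations
exactly.  Video fixtures place one bright blob per ROI whose
frame-to-frame displacement is proportional to the participant's MOVE
signal; for a square blob a displacement of d pixels changes 2·h·d
pixels, so recovered motion energy tracks the input (rank correlation
≥ 0.8 in the round-trip test).

What the generator does *not* emulate: score-driven musical structure,
musician–audience interaction, non-stationary coupling within pieces,
heavy-tailed movement bursts, and physiological cross-channel coupling
(each channel has independent noise).  Passing tests therefore
demonstrate that the statistics recover linear common-driver coupling
under realistic rates, lags, autocorrelation and missingness — not that
they characterize every property of real concert recordings.

## Simulation sizes and lag conventions in the validation experiments

Monte-Carlo experiments in the test suite and the acceptance script use
audiences of m = 5–40 and recordings of 300–600 s, with 200 shuffles
for replicate-heavy multivariate loops (the standard default of
1000 remains the library default); these sizes give stable means while
keeping full runs quick on a single CPU.  The mv-SUSY recovery and
leave-one-out experiments impose zero lags: the λmax statistic carries
no lag tolerance, so lagged coupling attenuates within 5-s segments by
construction, and its validation conditions use simultaneous coupling.
SUSY experiments keep the default heterogeneous lags, which its ±5 s
window is designed to absorb.

## Known limitations

- Dyadic ES values entering t-tests are not independent (shared
  members); p-values are anticonservative to an unquantified degree.
- The backward AIC path can miss the global all-subsets AIC optimum on
  unfavorable draws (verified rare in tests).
- ES is a z-score in the surrogate null: its magnitude grows with
  recording length and coupling, so values are comparable only within
  a fixed segmentation/duration regime.
- Leave-one-out contributions inherit the ES scale; comparisons across
  audiences of different size or duration are not meaningful.
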
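# Methods

## Scope and data model

The pipeline operates on *sessions*: sorted single-unit spike times (seconds
from session start, per unit with a tetrode id) plus a trial table of odour
onsets, offsets and odorant identity, where odorants are the homologous
aldehyde series identified by carbon chain length 3–8. Sessions arrive
either from the synthetic generator or from tabular session bundles
(`units.csv`, `spikes.csv`, `trials.csv`, `manifest.json`; times stored at
10 µs precision so identical sessions serialize byte-identically). All
trial-relative alignment uses half-open windows `[a, b)` with the odour
onset at 0; bin timestamps are bin centers.

## Synthetic sessions

Each unit is an inhomogeneous Poisson process sampled by thinning. The rate
is a constant baseline `b` (drawn once per unit from a lognormal with
median 10 Hz and 0.5 log-units of spread — the typical mitral/tufted
baseline regime) modulated around each odour onset by a peak-normalized
Gaussian bump `g(t)` truncated at ±3σ, parameterized by latency and full
width at half maximum:

* excited: `rate = b · (1 + A_o · g(t))`
* inhibited: `rate = b · (1 − s_o · g(t))`, `s_o ∈ [0, 1)` so rates stay
  non-negative by construction
* non-responsive: `rate = b`

Amplitude is tuned to chain distance from the unit's best odour,
`A_o = A · exp(−|c_o − c_best| / λ)`; λ = ∞ gives flat tuning. Latency and
width get small independent per-odour jitter, so odour identity remains
weakly decodable even under flat amplitude tuning (as in populations with
homogeneous response magnitudes). Trials use a 10 s inter-trial interval
with onset 5 s into each epoch, guaranteeing the −2.5 to −0.5 s baseline
window is always in-session and clear of the previous stimulus; odour order
is randomized per session; 19 trials per odour by default.

Genotype presets are calibration constants, not measurements:

| parameter | control | mutant |
|---|---|---|
| p(responsive) | 0.50 | 0.35 |
| p(inhibited \| responsive) | 0.40 | 0.15 |
| best-odour gain A (mean ± sd) | 2.5 ± 0.6 | 1.2 ± 0.4 |
| excitatory latency (s) | 0.15 | 0.25 |
| excitatory FWHM (s) | 0.25 | 0.35 |
| tuning decay λ (chain units) | 1.5 | ∞ (flat) |

Inhibited responses are drawn as sustained, near-saturating suppression
(`s_best ~ N(0.9, 0.05)` clipped to [0.6, 0.98], with a ~2.5× wider and
earlier kernel than excitation). This reflects the typical odour-inhibited
projection-neuron phenotype — suppression that spans the stimulus rather
than a brief dip — and is also what makes inhibition detectable by a
z-score rule at realistic baseline rates: the detectability of a rate
*decrease* is bounded by `√b`, so brief shallow dips are invisible at any
amplitude. With these presets the ±1.96 rule recovers the configured
responsive fraction to within ±0.05 at 500 units, with a null
false-positive rate of about 10⁻³ per unit-odour pair.

What the generator deliberately omits: respiration-coupled firing and
sniff-phase codes, odorant concentration series, electrode drift,
correlated noise across units, and non-Poisson spiking statistics
(refractoriness, bursting). Passing tests therefore certify the analysis
code against a Poisson rate-model world, not against every property of real
recordings; in particular, trial-to-trial count variance here is exactly
Poisson, whereas real M/T counts are often over-dispersed.

## Raw-trace preprocessing

Common average referencing subtracts the per-sample channel mean (≥ 2
channels required; a waveform present identically on all referenced
channels cancels, so detection fixtures spread spikes over a subset of
channels, as real arrays do). Band-pass filtering is a 300–5000 Hz
4th-order Butterworth applied forward-backward (zero phase) to avoid
latency shifts in downstream PSTHs. Event detection thresholds at
`7.5 × median(|x|)` of the preprocessed trace — the literal reading of a
median-based noise estimate; the Gaussian-calibrated variant
`median(|x|)/0.6745` is selectable (`scaled_median_abs`). Default polarity
is negative (extracellular somatic spikes). Crossings closer than a 1 ms
refractory window collapse to the extremum sample. An all-zero trace yields
no events rather than an error. Spike sorting is not implemented; the
detection stage exists to validate the preprocessing formulas against
injected ground truth.

## Response metrics

PSTHs use 50 ms bins; the z-trace uses 100 ms bins spanning −2.5 to +1.5 s.
`FR_baseline` and `σ_baseline` are the mean and SD (ddof = 1) of the
trial-averaged binned rate over the 20 baseline bins; z is computed on the
trial-averaged trace, as the formula implies, not per trial. The
classification threshold 1.96 is the two-sided 95% standard-normal critical
value. Pairs with `σ_baseline = 0` are flagged degenerate and excluded from
feature statistics (and counted in the run log) rather than patched with an
epsilon. Note that the mean of five z-scored bins has variance below one
under the null, so the ±1.96 rule on the window mean is conservative —
measured false-positive rates sit near 0.1%, not 5%.

Peak features are computed on the z-trace in a 0 to +1 s search window
(responses can outlast the 500 ms stimulus): the peak is the largest local
maximum, width is measured at half prominence with linear interpolation
between bins, and inhibited responses are analysed on the negated trace
with the sign restored on output. A window without a local maximum yields
missing features, not an error.

`d′` uses odour-window spike counts across trials; `σ_RMS = 0` with equal
means gives d′ = 0, with unequal means the pair is flagged infinite and
excluded from distribution summaries. Feature distributions are compared
between genotypes with a normality gate: Shapiro–Wilk at α = 0.05 on both
groups selects a two-tailed two-sample t test, otherwise a two-tailed
Mann–Whitney U test. (A single normality test is used where the original
convention chains two; this is a deliberate simplification.)

## Similarity coding

"Response strength" is the raw trial-averaged rate in the odour window —
not baseline-subtracted and not |z| — so relative strengths lie in [0, 1];
the alternative definitions can be substituted upstream since the
normalization only needs a per-unit-odour scalar. Ties for the best odour
break toward the lower carbon number, deterministically. Units with
all-zero strengths are excluded (normalization undefined). The
chain-distance curve averages whatever entries exist per |Δc| — cell counts
are necessarily unequal (a unit whose best odour is C3 contributes
Δ ∈ {1..5}; best C5 contributes {1,1,2,2,3}).

Genotype × chain-distance uses an ordinary two-way ANOVA with Type II sums
of squares (appropriate for these structurally unbalanced cells);
genotype × rank uses a mixed ANOVA with rank as the within-unit factor,
restricted to ranks 2–6 because rank 1 is identically 1. Both are computed
by pingouin. Šídák-adjusted pairwise t tests (paired within unit for the
rank analysis) across the non-genotype factor within each genotype serve as
post-hocs. Within a single genotype the "chain-distance effect" is a
one-way ANOVA across |Δc| levels, since a genotype main effect is undefined
with one genotype present.

## Population distances and decoding

Pseudopopulations pool units across (deduplicated) sessions; row r of odour
o concatenates each session's r-th trial of that odour — within-odour trial
index is the only alignment available across non-simultaneous sessions.
Each odour contributes exactly 19 rows after truncation. Distances are
plain Euclidean on spike-count vectors; groups are the 6 within-odour
distributions (171 pairs each) and 15 cross-odour distributions (361 pairs
each), compared by Welch's ANOVA with Games–Howell post-hocs. Welch is the
default omnibus (Brown–Forsythe selectable); both are provided because
conventions differ on which heteroscedastic ANOVA to pair with
Games–Howell.

The decoder, per population size and iteration: draw that many units
without replacement, hold out one random trial, fit PCA to 4 components on
the training rows only, fit one full-covariance Gaussian per odour class
(equal priors, diagonal regularization ε = 10⁻⁶ × mean variance), and score
the held-out trial by maximum likelihood with ties broken toward the lower
carbon number. A configuration flag (`joint_pca=True`) reproduces the
alternative reading in which the reduction is fit before the hold-out; on
separable data both behave identically, and the training-only default
avoids leakage. The kNN/ECOC control model uses one-vs-one coding (15
binary 5-nearest-neighbour learners for 6 classes) with Hamming-loss
decoding. Accuracy per size is tested one-sided against chance = 1/6 with
an exact binomial test over the iteration outcomes; curve comparisons
between genotypes use per-size two-proportion z-tests, Šídák-adjusted
across sizes — a deliberate substitution for mixed-effects modelling of
accuracy curves, which is out of scope.

A property of leave-one-trial-out worth knowing: with 19 trials per class,
the ~114 per-trial outcomes of one dataset share training sets and are
strongly correlated, so a single session's accuracy estimate carries
dataset-level spread (sd ≈ 0.05 under the null) far beyond the binomial
component of its 500 iterations. The procedure is unbiased — across
replicate null sessions mean accuracy sits at 1/6 — and the chance
-calibration checks therefore pool replicate sessions to measure that
marginal mean.

## Statistical tests

Welch's heteroscedastic F, the Brown–Forsythe ANOVA for means (with its
Satterthwaite denominator df), and Games–Howell (Welch-type pairwise t
referred to the studentized range with the full group count, q = t√2) are
implemented directly; studentized-range tail probabilities come from
scipy's range distribution. Mann–Whitney U switches from exact enumeration
to the tie-corrected normal approximation above n_A·n_B = 200 (ties always
force the corrected approximation). Binomial tests are exact tail sums.
Identities used as test oracles: Welch F at k = 2 equals the squared Welch
t (exactly; for k > 2 the denominator correction makes Welch F strictly
smaller than the classical F even under equal variances), Brown–Forsythe
equals Welch for two equal-sized groups, and Games–Howell at k = 2 equals
the studentized-range transform of the Welch t. Empirical type-I error of
Welch, Brown–Forsythe and Mann–Whitney is calibrated to [0.035, 0.065] at
α = 0.05 over 2000 null replicates each.

## Problem sizes in the test battery

The shipped checks run at deliberately desk-scale sizes chosen to keep the
whole suite under a few minutes while preserving power: chance calibration
pools 3–6 null sessions of 60 units × 500 iterations; genotype-contrast
recovery uses 10 seeds × 100 units per genotype with decoding at sizes
{10, 40, 70, 100} × 150 iterations; type-I calibration uses 2000 replicates
per test. The library defaults remain the full protocol (sizes in steps of
10 up to the population, 500 iterations per size).

## Known limitations

* The Poisson world understates real count dispersion; genotype contrasts
  recovered here certify the code path, not effect sizes in tissue.
* Flat amplitude tuning in the mutant preset leaves only latency/width
  jitter as identity information, so mutant decoding sits closer to chance
  than a real mutant population with residual tuning heterogeneity would.
* Games–Howell p-values depend on scipy's studentized-range quadrature,
  which is slow for large group counts; the 21-group distance grid is near
  the practical limit for interactive use.
* The repeated-measures rank analysis assumes each unit contributes one
  value per rank; units lost to the all-zero-strength exclusion drop out of
  that analysis entirely.
* Unit deduplication keys tetrodes within a mouse (falling back to the
  session-id prefix); across-animal tetrode-number collisions are not an
  issue, but renamed tetrodes across days would defeat it.
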
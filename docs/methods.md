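# Methods

This note documents the models, estimators and numerical choices behind
`numcomp`, what the synthetic generators do and do not emulate, and the
design decisions taken where the underlying methodology left genuine
freedom.

## Stimulus designs and association statistics

Two session designs are built by `numcomp.design`.

The *omitted-range* design uses the numerosities {5, 10, 15, 35, 40, 45}
(multiples of 5 in [5, 45] with the middle sub-range removed; values below
5 are excluded everywhere to stay out of the subitizing range). All 30
ordered non-tie pairs are presented an equal number of times (20 by
default, 600 trials). Removing the middle of the range drives a wedge
between a value-based distance predictor, ln(large − small), and a
rank-based (association) predictor, ln(rank_large − rank_small): e.g. the
pair (15, 35) has a large value distance but adjacent ranks.

The *frequency-manipulated* design uses all multiples of 5 in [5, 45].
Base token counts per value follow the everyday table
{5:10, 10:5, 15:4, 20:3, 25:2, 30:2, 35:2, 40:2, 45:1}, its mirror
(reversed-everyday), or a uniform table. The everyday counts are motivated
by the ~1/value frequency of numbers in natural language, but no single
rounding rule reproduces the printed counts from 10/initial-value
(10/3 → 3 would be needed alongside 10/9 → 1); the tables themselves are
therefore hard-coded as ground truth and the formula is kept as
documentation only. Ordered pair (i, j), i ≠ j, appears f(i)·f(j)·repeats
times, giving (Σf)² − Σf² = 794 templates per repeat for the everyday
table (1,588 trials at 2 repeats; the most frequent pairs, 5 vs 10 in
either order, appear 100 times and the rarest, e.g. 40 vs 45, four times)
and 72·22 = 1,584 trials for the uniform condition.

For any design, the association statistics give, per value, the
multiplicity-weighted proportion of its presentations in which it is the
smaller (or larger) pair member. On a uniform design this reduces to rank
fractions: p_larger(v) = (rank − 1)/(m − 1), so e.g. 8 among 1..9 is the
larger member 87.5% of the time, and 10 in the omitted-range set is the
smaller member 80% of the time.

Dot-array geometry (`generate_dot_array`) places n dots uniformly at
random in a 2° × 2° field, dot diameter 0.2°, by rejection sampling
(10,000 attempts per dot before declaring the field too crowded), keeping
every dot fully inside the field and no two dots overlapping. Half the
dots are black, half white, so summed luminance is uninformative about
numerosity; convex hull and density remain correlated with numerosity, as
in the modeled experiments, and are reported but not controlled.
Coordinates are degrees of visual angle with the origin at a field corner;
rendering to pixels is out of scope.

## The diffusion generator

Each trial of `simulate_ans_cohort` is a two-boundary Wiener first-passage
simulation: evidence starts unbiased at a/2 between absorbing boundaries
{0, a} and evolves as dX = v·dt + s·dW with the conventional noise scaling
s = 0.1. The drift carries the ratio effect, v = k·ln(large/small) — the
canonical psychophysical choice for a Weber-type comparison process. The
upper boundary is the correct (larger-side) response; RT is decision time
plus a nondecision offset t_er.

Defaults (k = 0.45 per unit log-ratio, a₀ = 0.1, t_er = 0.35 s) were
chosen once to give session-level behavior in the range typical of adult
numerosity comparison — group error rates of roughly 5–20% and median RTs
around half a second, depending on the design's difficulty mix — and are
not calibrated to any particular dataset.

**Integration scheme.** Euler–Maruyama with dt = 1 ms, with *exact
Brownian-bridge absorption sampling* inside each step: given step
endpoints x₀, x₁ strictly inside the boundaries, the probability that the
continuous path crossed a boundary b within the step is
exp(−2(b − x₀)(b − x₁)/(s²dt)) regardless of drift, and absorption is
sampled from it. Naive Euler misses within-step crossings and carries an
O(√dt) bias (≈ +0.0075 in accuracy at v = 0.2, a = 0.1) that is visible at
20,000 trials; with bridge sampling the simulator matches the analytic
accuracy P(correct) = 1/(1 + exp(−va/s²)) and mean decision time
(a/2v)·tanh(va/2s²) within Monte-Carlo error. A trial still unabsorbed at
10 s is resolved toward the nearer boundary (at the default parameters
this is vanishingly rare). Exact boundary hits absorb.

**Frequency coupling.** Pair frequency is summarized by
φ(x₁, x₂) = (f(x₁) + f(x₂)) / max over pairs, mirroring the additive
structure of the size regressor and invariant to rescaling all counts. The
coupling multiplies diffusion parameters by 1 ∓ g with
g = gain · (φ − φ̄) · decay^(block−1), where φ̄ is the session's
trial-weighted mean frequency: threshold and nondecision time shrink for
pairs more frequent than the session average and grow for rarer ones
(drift does the opposite sign). Centering on φ̄ is deliberate: it encodes
the *relative* frequency structure of a session, so a uniform-frequency
session is left at baseline rather than having all its thresholds scaled
by a constant — an absolute coupling would compress every effect slope in
the uniform condition and manufacture spurious between-condition distance
differences that the frequency manipulation does not predict. The
effective threshold is clamped at 0.2·a₀ and nondecision time at 0. With
block decay δ < 1 the coupling fades geometrically over the four
contiguous session quarters, reproducing a frequency influence that is
strongest early and dissipates.

Participant heterogeneity is modeled as independent mean-one log-normal
multipliers on (k, a₀, t_er) with coefficient of variation 0.1. This is
deliberately modest — real between-participant dispersion in effect slopes
is substantially larger — which makes simulated cohorts statistically
*cleaner* than human ones (see "What the generators do not emulate").

## The statistics-driven generator

`simulate_dss_cohort` produces performance governed by stimulus statistics
rather than magnitudes. Mean RT is linear in a log-distance term and a
frequency-driven size term; error probability is the logistic of the same
structure:

    RT ~ N(rt_base − w_d·ln(Δ) + w_s·(rarity(x₁) + rarity(x₂)), σ), truncated > 0
    P(error) = logistic(β₀ − β_d·ln(Δ) + β_s·(rarity(x₁) + rarity(x₂)))

with rarity(v) = 1 − f(v)/max f taken from the session's base frequency
table. Under this account the size effect *is* a frequency effect, so a
uniform-frequency session generates none — rarity is identically zero —
while an everyday table makes rare large values slow and error-prone and a
reversed table the opposite. The distance basis Δ is either the value
difference (`basis="value"`) or the rank difference in the session's
ordered value set (`basis="order"`); the latter emulates association-driven
performance and is what the omitted-range pipeline should classify as
association-dominant.

## Aggregation and exclusion

Per participant and unordered pair, `pair_stats` computes the mean error
rate and the median RT over *all* trials — correct and erroneous alike,
with no slow-outlier trimming (the median is robust to slow outliers);
even counts take the mean of the two central order statistics. Unordered
aggregation is used because every regressor depends only on the unordered
pair; ordered grids can be formed by grouping on (left, right) directly.

Exclusion rules operationalize informally stated criteria, so each
threshold is explicit and configurable: overall accuracy < 0.60 flags a
random/swapped responder (< 0.50 additionally suggests swapped keys); an
RT distance-fit R² < 0.20 flags a flat distance effect (typical attentive
values sit far above); a size-effect slope whose leave-one-out |z| within
its condition exceeds 3.5 flags an extreme outlier. The z-score
standardizes against the *other* participants' mean and SD because an
extreme value included in its own reference caps |z| near √n and could
mask itself.

## Effect regressors and fits

Three per-pair regressors (natural log throughout): value distance
ln(large − small); association distance ln(rank_large − rank_small); and
the size sum (x₁ + x₂)/5 (the "initial numbers", i.e. numerosities divided
by five). Fits are ordinary least-squares simple regressions of a pair
statistic on one regressor — per participant, or at group level on the
across-participant mean of each pair's statistic — reporting slope,
intercept and R² (squared Pearson correlation). Error rates are fitted as
raw proportions. Two structural facts justify simple rather than multiple
regression: on a full all-pairs design over an arithmetic value grid the
ln-difference and sum regressors are exactly orthogonal (for every fixed
difference, pair sums average to the same grand mean), and rescaling all
values by c shifts the value-distance predictor by ln c, leaving slope and
R² identical and moving the intercept by slope·ln c. Both identities are
asserted in the test suite to 1e-10; a constant outcome is fitted as a
flat line with R² = 0 rather than an error.

## Study-level inference

*Model contrast.* Per-participant R² values of the value-based and
association-based fits are compared with a two-sided paired Wilcoxon
signed-rank test, treating R² as ordinal. Zero differences are dropped;
the exact null distribution is used up to 25 informative pairs and the
continuity-corrected normal approximation beyond; fewer than 5 informative
pairs refuses the test. The direction label (value- vs
association-dominant) is the sign of the median difference when the test
is significant.

*Condition contrast.* Per-participant slopes are compared across
conditions with a Shapiro–Wilk gate (α = .05 per group): one-way ANOVA
with ω² when all groups are compatible with normality, otherwise
Kruskal–Wallis with the rank analogue ε² = H/(N − 1) — labelled
explicitly as a rank effect size, since "ω²" conventions for rank tests
vary — and Dunn's pairwise post hoc (pooled tie-corrected ranks,
z_ij = (R̄ᵢ − R̄ⱼ)/√((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ + 1/nⱼ))),
unadjusted by default with Holm adjustment available.

*Block analysis.* Slopes are recomputed per participant within each
contiguous session quarter and analyzed with a blocks (within) ×
conditions (between) mixed ANOVA via `pingouin`, uncorrected degrees of
freedom by default (Greenhouse–Geisser available), plus a Tukey HSD post
hoc on blocks. A decaying coupling produces the expected block × condition
interaction with the condition separation largest in block 1.

*Power.* `required_n_oneway_anova` sweeps total N upward, computing power
as P(F′(k−1, N−k; λ = f²N) > F₀.₉₅ critical). The default allocation is
*balanced* — N restricted to multiples of k, the convention of standard
power software, which reproduces the published planning values (42 for
f = 0.64, α = .05, power .95, k = 3; 159 for the f = 0.25/.80 benchmark).
`allocation="any"` sweeps every integer and may stop one participant
short (41 in the case above).

## EZ recovery and the signature classifier

`ez_fit` inverts (Pc, VRT, MRT) into (v, a, t_er) with the standard
closed forms (noise scaling s = 0.1); `ez_forward` is its exact inverse,
and the round trip is identity to 1e-10 over the tested parameter grid.
Pc = 0.5 is degenerate (drift sign undefined) and raises; perfect accuracy
is edge-corrected to 1 − 1/(2n) and flagged. Recovery from 5,000 simulated
trials is accurate to within a few percent.

The qualitative classifier maps a high-frequency-minus-low-frequency
(RT change, error-rate change) pattern to compatible parameter changes:
faster + more precise → drift increase; slower + more precise → threshold
increase; slower + unchanged → nondecision increase; faster + unchanged or
less precise → threshold and/or nondecision *decrease* (drift excluded);
RT-silent precision changes are reported as ambiguous drift/threshold
combinations.

`frequency_diffusion_report` bins pairs into φ terciles, reports pooled EZ
estimates per stratum — always with a bias warning when strata have
unequal trial counts, which a frequency manipulation guarantees — and
feeds the classifier difficulty-adjusted behavioral deltas. The
adjustment matters: in a frequency-manipulated design φ is confounded
with pair difficulty (the everyday table makes easy small-value pairs
frequent), so raw stratum contrasts would misattribute the ratio effect
itself to frequency. Mean RT is residualized on a trial-count-weighted
quadratic in ln(ratio); the error rate on a trial-level logistic fit in
ln(ratio) — the functional form the ratio effect predicts, whose
saturation at easy pairs a polynomial cannot track. An effect counts as
present only when it exceeds max(floor, 2 × jackknife SE), with the SE
from leave-one-participant-out recomputation and floors of 5 ms / 0.005;
this keeps the null false-positive rate low without blunting sensitivity
to genuine couplings. The classifier verdict, not the stratum point
estimates, is the supported inference path.

## What the generators do and do not emulate

The generators reproduce: the two designs' combinatorics and association
statistics; ratio-governed choice and RT distributions with realistic
skew; frequency-coupled threshold/nondecision/drift changes and their
behavioral signatures; block-wise decay of the frequency influence; and
statistics-driven (association/frequency) performance for the contrast
pipelines.

They deliberately omit: trial-to-trial drift and starting-point
variability (the full Ratcliff model); sequential and priming effects
between consecutive trials; response bias and starting-point asymmetries;
strategic speed–accuracy adjustments; and realistic between-participant
heterogeneity (cv = 0.1 on three parameters is far tighter than human
cohorts). Passing tests therefore show that the *pipeline* recovers what
the generators put in — they do not certify effect sizes or significance
levels expected from human data, where larger dispersion will dilute all
contrasts.

One estimator artifact deserves explicit mention. The frequency-weighted
designs put as few as 4 trials in their rarest cells, and the median of 4
draws from a right-skewed RT distribution is biased upward by tens of
milliseconds on hard pairs. Because rare cells in the everyday table are
also the hardest, this biases that condition's distance slope relative to
the uniform design (whose cells all hold 22 trials) — *independently of
any frequency coupling*. The artifact is mirror-symmetric in the pair
space, hence nearly identical in the everyday and reversed-everyday
conditions; the supported check of distance-effect invariance is therefore
the everyday-vs-reversed contrast, not a three-condition omnibus that
mixes designs with different cell-count profiles. At human levels of
between-participant dispersion the artifact is negligible; at the
generator's tight heterogeneity it is detectable, which is a property of
the simulation conditions, not of the analysis code.

## Numerical conventions and degenerate inputs

RTs are seconds internally and integer milliseconds (rounded half up) on
disk. Generated RTs are truncated at 1 ms. All stochastic components are
driven by `numpy.random.Generator` seeds threaded from a single master
seed; every generator is bit-reproducible given (design, seed). Tie pairs,
zero-variance predictors, single-condition interaction requests,
sub-minimum group sizes, unknown condition labels, and frequency tables
that cannot form at least two φ strata raise `ValueError` with a specific
message rather than propagating numerical noise.

## Problem sizes used in the validation suite

The simulator-vs-analytic oracle uses 20,000 trials (3 Monte-Carlo SEs);
EZ trial-level recovery 5,000 trials (10% relative error); model recovery
50 replicate cohorts of 8 participants per generating basis (≥ 90%
correct classification); mechanism recovery one threshold-coupled cohort
triple at the published group sizes 16/24/21 plus one drift-coupled
cohort; and the block-decay interaction two 14-participant cohorts. These
sizes were chosen as the smallest that leave comfortable statistical
margins for the properties being checked.
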
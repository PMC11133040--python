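# Methods

## The test

A single-case series is a fixed sequence of scores y₁..y_n with condition
labels. The design's randomization scheme defines a finite set of
admissible *data divisions* — ways the fixed sequence could have been split
into conditions — of which one was realised by the design-stage draw. Under
the null hypothesis of no intervention effect, all m divisions are equally
likely, so the statistic computed at each division forms an exact reference
distribution.

The statistic is Pearson's product-moment correlation between the scores
and a *response function* f: one predicted-response constant per occasion,
rebuilt for every candidate division because phase lengths change the
pattern (a ramp runs to the end of whichever intervention phase is tried).
The p value counts divisions whose statistic is ≥ the observed one, divided
by m; the observed division counts itself and ties count as extreme, which
makes the test valid (never anti-conservative) at every attainable level
k/m. The test is one-sided in the favorable direction by default: response
functions are always written for an *increase* of the target behavior and a
decreasing aim is handled by negating the scores, so a favorable result is
always a positive statistic. A two-sided variant (|r|-based ranking) is
available behind a flag.

## Response-function construction

For a division with n_A baseline and n_B intervention occasions, baseline
positions are coded 0 and the intervention positions follow the effect
specification:

- **onset** immediate, or delayed with latency L ≥ 1: the first L
  intervention occasions are coded 0;
- **progression** abrupt (constant 1) or gradual (ramp 1, 2, 3, …);
- **duration** permanent (to the end of the phase) or temporary for d
  occasions;
- **offset** of a temporary gradual effect: abrupt (drop to 0), gradual
  (decay by 1 per occasion, mirroring the ramp — the default, matching the
  tabulated 3,2,1,0 and 4,3,2,1 columns), or asymptote (hold at the peak,
  modelling a ceiling rather than a loss). Abrupt progressions simply step
  back to 0.
- an optional overall linear trend adds 1..n element-wise, and a
  user-supplied vector (one line of comma-separated constants, truncated to
  the candidate phase length) overrides the built-ins for nonlinear
  expectations.

A latency that swallows the whole candidate intervention phase leaves an
all-zero vector; such divisions are *degenerate*. They are never dropped —
dropping would change m and destroy exactness — instead the statistic is
conventioned to 0 (no evidence of association) and the division is flagged
in the output. The same convention applies when the scores are constant on
the compared window. Occasions can be masked out of the statistic
(e.g. to compare only the last three occasions of each phase); masked
occasions simply drop out of the correlation. When a linear trend is added
to a masked function, the k-th *included* occasion receives +k.

## Randomization schemes

- **AB start point**: admissible baseline lengths a with
  min_A ≤ a ≤ min(max_A, n − min_B); m = number of admissible a.
- **Multiple baseline, Wampold–Worsham**: staggered start points fixed,
  tier order random; m = t!.
- **Multiple baseline, Koehler–Levin**: tier order random and each
  staggered position draws its start from a candidate set;
  m = t!·∏|setᵢ|. Candidate sets may overlap across positions (a warning
  is issued); divisions then remain distinct by their tier-order component,
  keeping m equal to the closed form.
- **ABAB reversal**: all ordered change-point tuples leaving each of the I
  phases at least k occasions; m = C(n − I·k + I − 1, I − 1).
- **Alternating treatments (block-randomized)**: each of b blocks holds
  both conditions in either order; m = 2^b.

Closed-form counts and full enumeration are implemented independently and
asserted equal. For designs with several A-B comparisons (multiple-baseline
tiers; adjacent phase pairs of an ABAB design) the coding is simply
repeated per comparison and the per-division statistic is the unweighted
mean of the per-comparison correlations — unweighted because the
correlation is already scale-free across tiers of unequal length. A
division that is degenerate in one comparison contributes 0 for that
comparison only.

## Exploratory scans and multiplicity

When the latency of a delayed effect or the duration of a temporary effect
is not known a priori, scans over L = 1..L_max or d = 1..d_max (plus the
permanent case) rerun the full test per scenario over the identical
division set. Raw p values are reported by default — in a purely
exploratory reading they are descriptive measures — with Bonferroni and
Holm adjustments opt-in for use as probabilistic statements (adjustment
delegated to `statsmodels.stats.multitest`).

## Synthetic data

The generator produces y_t = μ + β·t + δ·f_t + ε_t, where f_t is the
unit-peak-normalized response function of the chosen effect prototype at
the true division, so δ is the peak effect in score units for every shape.
Noise is i.i.d. Gaussian by default; an AR(1) option (parameter φ, scaled
to keep the marginal sd at σ) is included because trend and autocorrelation
are the features that make design randomization necessary for
exchangeability in the first place. A counts option rounds and floors at 0
to emulate behavioral tallies. What the generator does *not* emulate:
bounded scales with ceiling/floor compression, heteroscedasticity across
phases, session-level missingness, or reactive (response-guided) phase
changes — so passing tests demonstrate correctness of the inferential
machinery, not robustness claims about any particular behavioral data set.
Test validity itself does not depend on the noise model (it follows from
the design randomization); the noise model matters only for power curves.

The Monte-Carlo harness draws the design randomization uniformly, generates
data with the effect at that true division, and reports the rejection
fraction at a chosen α with its binomial standard error. Under the null
this equals floor(α·m)/m; at zero noise and a matched analysis
specification it reaches 1 for α ≥ 1/m.

## Numerical choices and conventions

- Correlations are computed from centered dot products and clipped to
  [−1, 1] to absorb rounding at |r| = 1; a zero denominator (constant
  input) yields the conventioned 0.
- Ranks use the ≥ tie rule (rank 1 = largest); p = (#{≥ observed})/m.
- Enumerations are deterministic and duplicate-free; division draws use
  `numpy.random.default_rng` and are reproducible per seed.
- Degenerate and masked cases follow the conventions above; series need at
  least two occasions and two included occasions per compared window.
- Problem sizes in the test suite are desk-scale throughout: full
  enumerations up to a few thousand divisions and Monte-Carlo runs of
  1000–2000 replicates on series of 10–17 occasions, which keeps every
  check exact or tightly seeded while running in seconds.

## A note on the mean-difference equivalence

With a binary response function the statistic is the point-biserial
correlation, r = Δ·√(n_A·n_B)/(n·s_y) with Δ the B−A mean difference and
s_y the (division-invariant) sd of all scores. The classical
p-value-equivalence between r and Δ therefore holds exactly whenever the
randomization scheme leaves the group sizes fixed across divisions — e.g.
block-randomized alternation designs, where every division has b occasions
per condition, or permuted-assignment schemes. Across AB start-point
divisions the factor √(n_A·n_B) varies with the division, and the two
statistics can order divisions differently: numerically, random series of
6–12 occasions produce differing p values for roughly one division in six.
The equivalence property is accordingly asserted on alternation
enumerations, where the mathematics supports it.

## Known limitations

- Changing-criterion designs and response-guided (adaptive) phase-change
  rules are out of scope.
- Randomization-based confidence intervals by test inversion are not
  implemented.
- The combined multi-tier statistic is the unweighted mean of per-tier
  correlations; alternative weightings (e.g. by tier length) are not
  exposed.
- Missing scores are rejected at input; windows of interest are expressed
  by masking the response function instead.
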
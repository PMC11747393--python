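# Methods

## The measurement model

The instrument elicits one integer (dis)similarity judgment in
[−7, +7] for each unordered pair of a fixed, ordered concept set
(default: 16 socioenvironmental concepts, hence 120 pairs). Ratings are
modeled as genuinely discrete — the entropy analysis treats "the
probability that rating *i* is selected" over 15 nominal levels — so
non-integer ratings are rejected at ingestion. Pair columns are ordered
lexicographically by concept-index pair (i, j), i < j, which fixes a
canonical, run-stable column layout.

A rating *s* is converted to an edge weight
`e = 1 − (s − r_min)/(r_max − r_min)`, an affine, strictly decreasing map
onto [0, 1]. Weights act as distances: 0 means maximal relatedness. All
regressions operate on the weight scale; a rating-scale effect of size d
therefore appears as d/14 on the weight scale, and a positive rating
effect has a negative weight coefficient.

Per-participant news bias is the arithmetic mean of the bias scores
(Left = 1 … Right = 5) of the participant's listed sources, resolved
case-insensitively against a user-supplied lookup. Participants with no
scorable source (e.g. only algorithm-driven platforms) keep a missing
score and drop out of any analysis that needs it. When only some of the
up-to-three sources are scorable the default is the mean of the scorable
ones; `require_all` switches to strict exclusion, since the field's
exclusion convention for partial lists is ambiguous.

## Edge-wise inference

Each edge's weight vector is fit by OLS on [intercept, predictor,
nuisance covariates] with gender, income bracket rank and age as nuisance
terms. Two predictors of interest are screened: group identity ("race",
dummy coded) and news bias.

**The race model deliberately omits news bias.** News bias is the
hypothesized mediator of the group difference; conditioning on it would
subtract exactly the indirect path the mediation stage is meant to
decompose, and fully mediated edges could then never enter the
group-differing set at all. The race screen therefore estimates the
*total* group effect; the news model includes race as a nuisance term.

Significance uses a permutation null. By default the tested predictor
column is scrambled across participants (the response and covariates stay
fixed), the coefficient is recomputed via Frisch–Waugh residualization on
each of the n_perm scrambles, and
`p = (1 + #{|β*| ≥ |β̂|})/(n_perm + 1)` (two-sided, add-one smoothing, so
p > 0 always; ties count as exceedances). A Freedman–Lane scheme —
permuting the residuals of the nuisance-only model — is available via
`scheme="freedman-lane"`; the two calibrate identically in our tests and
differ only in which exchangeability assumption they encode. Each (seed,
predictor, edge) triple seeds its own substream, so results are invariant
to edge evaluation order and to which other predictors are run.

Benjamini–Hochberg correction is applied across the 120 edges separately
per predictor (family size 120, matching per-effect reporting).
Note the granularity interaction: permutation p-values are bounded below
by 1/(n_perm + 1), while the smallest BH threshold is α/120, so with few
true effects a discovery requires n_perm well above 120/α·(rank). The
default n_perm = 10,000 is safely past this; reduced test runs use 1,000,
which suffices when tens of edges carry effects.

## Reliability

Split-half reliability splits *participants* (not items) into random
halves, correlates the two halves' 120-element pair-mean vectors
(Pearson), and averages over 500 splits; the Spearman–Brown corrected
value 2r/(1+r) is reported alongside because a half-sample correlation
understates full-sample stability. Participants are sorted by id before
splitting, so the statistic is invariant to row order. At n ≈ 450 with
realistic between-pair spread, pair means are extremely stable and the
statistic approaches 1; it is a sanity floor, not a discriminating
benchmark.

## Entropy and the sigmoid

Per-pair entropy uses empirical frequencies over all 15 nominal levels,
no smoothing (optional Miller–Madow correction, off by default), giving
H ∈ [0, log2 15 ≈ 3.907] bits. The entropy-vs-effect relation fits
`f(x) = 1/(1 + e^{−a(x−b)}) + c` to (entropy, |β_news|) pairs by
nonlinear least squares. The response is the *absolute* coefficient;
signed coefficients are carried for plotting only. Initialization: a from
4/range(x), b at the steepest rise of a window-5 moving average of y over
sorted x, c at min(y); 10 seeded jittered restarts, best SSE wins.
Degenerate inputs (constant y) short-circuit with R² = 0 and a flag;
non-convergence from every start returns a flagged result with no
parameters.

## Mediation screen

For each edge flagged by the race screen, three nested OLS fits with a
common covariate set give the paths: `m ~ x + C` (a), `y ~ x + C` (c),
`y ~ x + m + C` (c′, b). With identical covariates the decomposition
`c = c′ + a·b` is an algebraic identity, which the tests assert to 1e-10.
The indirect effect a·b is tested by permuting the *mediator* across
participants (breaking both the a and b paths while preserving x–y),
recomputing a·b per scramble, two-sided with add-one smoothing. The Sobel
statistic `z = a·b/√(b²se_a² + a²se_b²)` is reported as converging
evidence and never gates classification. Indirect (permutation) and
direct (t-test on c′) p-value families are BH-corrected separately over
the screened set; labels follow: full if only the indirect path survives,
partial if both, unmediated otherwise.

**Known limitation.** Mediator permutation tests the complete null
(m independent of both x and y). On an edge with a strong group→mediator
path but no mediator→outcome path, the observed |a| far exceeds its
permutation distribution, so even noise-level b̂ values yield small
indirect p-values: the test is anti-conservative there, and unmediated
group-differing edges are sometimes labeled partial. Sobel, which
conditions on the observed standard errors, is calibrated in that regime —
hence the two tests' decisions are concordant only on edges with a real
indirect path, and the reported label counts for partial mediation run
above the planted count while label *accuracy on mediated edges* stays
high. This is a property of the prescribed permutation scheme, retained
deliberately; alternatives (permuting x, joint-significance, studentized
permutation) would change the stated method.

## Synthetic cohorts

The generator draws, per participant: a balanced group indicator; gender
~ Bernoulli(½); income bracket ~ uniform integers 0–9; age ~ uniform
integers 18–75; a mediator `m = μ₀ + a·g + N(0, σ_m)` clipped to [1, 5]
and snapped to the 1/3 grid reachable as a mean of three integer source
scores (so a cohort written to CSV and reloaded reproduces identical
inputs); and per-edge latent ratings
`baseline + direct·g + b·(m − E m) + covariate terms + N(0, σ_e)`,
rounded and clipped to −7..+7. Rounding and clipping shrink planted
effects toward zero, so recovery scenarios plant effects well inside the
scale, and recovery tolerances refer to realized rather than nominal
effects. Edge noise is independent across edges (no shared participant
random intercept by default), item-order and stimulus-position effects
are not modeled, and the entropy→news-effect link is planted as a clean
step structure — real data are noisier, so fit statistics (reliability,
sigmoid R²) run higher here than on human cohorts; passing tests
demonstrate correctness of the machinery, not field-realistic effect
sizes.

The `paper_like` preset encodes the reference study conditions: 446
participants (223 per group); mediator μ₀ = 2.52 for group 0 with
a = −0.48 and σ_m = 1.2, which after clipping reproduces group bias means
near 2.5/2.1, a group–bias correlation near −0.2 and d ≈ −0.4; 31
group-differing edges (direct effects ±0.5 σ_e) of which 18 partially
(b = 0.65 σ_e, indirect aligned with direct) and 3 fully (b = 1.1 σ_e,
no direct) mediated; 44 news-sensitive edges in total, the 23
non-group-differing ones at b = ±0.3 σ_e — small enough that their induced
indirect group effect stays below detection; per-edge noise σ_e ∈
[1.8, 2.8] on news edges and [0.7, 1.6] elsewhere, plus five low-noise
extreme-baseline "anchor" pairs, yielding entropies from ≈1 to ≈3.8 bits.
The which-edges-carry-effects layout comes from a fixed structural seed
and is part of the scenario definition; the simulation seed drives only
the random draws. Covariate effects default to zero, matching the
near-null covariate findings the analysis assumes. `race_only` plants the
same 31 edges with a = 0 so it is a true mediation null; `fully_mediated`
and `partially_mediated` plant 10 mediated edges each for focused
recovery checks; `null` plants nothing.

## Centrality convention

Subgraph degree centrality divides a node's degree by (nodes carrying at
least one subgraph edge − 1). The alternative — dividing by (total
concepts − 1), i.e. the proportion of all pairs featuring the concept —
is available via `denominator="full"`. The subgraph convention is the
default because it reproduces the characteristic printed hub values
(9/14 ≈ 0.64, 8/14 ≈ 0.57, 7/14 = 0.50, 6/14 ≈ 0.43) for a 15-node
subgraph, which the full-set convention cannot.

## Determinism and problem sizes

All randomness flows from one root seed through named substreams (per
stage, per predictor, per edge), so every output — including the pipeline
summary JSON — is byte-identical across reruns with the same config.
Default problem sizes: 10,000 permutations for final analyses; reduced
runs (tests, examples, the reproduction script) use 1,000–2,000
permutations, 100–200 null replicates for calibration and 50 replicates
for label-recovery rates, sizes at which the Monte-Carlo error of the
reported rates is a small fraction of the margins being asserted.
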
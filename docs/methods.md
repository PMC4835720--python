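# Methods

`flynet` reimplements, as a tested pipeline, a dynamic social-network
analysis of information transmission in groups of *Drosophila
melanogaster*: directed interaction networks are extracted from tracked
arena trajectories, their evolution is modelled with stochastic
actor-oriented models (SAOMs) estimated by the Method of Moments, and
the time course of class differences (informed vs uninformed flies) is
summarised with an incremental-window trend analysis. Because the
original video recordings were never deposited, a synthetic-data module
generates inputs with the statistical structure the analysis assumes;
every stage of the pipeline is exercised against independent oracles and
ground-truth generators.

## Interaction extraction

A directed interaction event is a maximal run of consecutive frames in
which two flies' centre-to-centre distance is strictly below
`distance_factor` × the replicate's mean body length, lasting at least
`min_frames` frames. Defaults: `distance_factor = 1.1` (a 10% margin for
antenna/foreleg contacts the tracker cannot resolve), `min_frames = 6`
at 10 fps (strictly more than five frames, i.e. more than 0.5 s —
shorter proximity is flies crossing paths). The initiator is the fly
with the greater travelled path over the `speed_window = 4` frames
strictly preceding the run's first frame; the travelled path is the sum
of displacement steps between consecutive tracked frames inside that
window (tracking gaps contribute nothing). Choices where the source
material is silent, fixed here once:

* boundary-equal distances are non-contact (strict inequality);
* tracking gaps break proximity runs; no gap bridging or run merging;
* the contact's own first frame is excluded from the speed window;
* speed ties go deterministically to the lower actor id (logged);
* one directed event per maximal run regardless of its length — the
  panel is later binarized, so within-run multiplicity is irrelevant;
* the mean body length is a single per-replicate scalar (mean over all
  flies and frames).

The production extractor is vectorised over the frame grid with prefix
sums for the initiator path; the test suite holds it equal to a
frame-by-frame, pair-by-pair brute-force oracle on random trajectories
with gaps.

## Panels, screening, condition labels

Events are binned into fixed time slices (5/10/15 min; all analyses here
use 10 min) by their start frame; slices are half-open frame ranges and
a trailing partial slice is dropped. The binary tie `x_ij = 1` means "i
initiated at least one contact with j in this slice". The first slice is
discarded by default (flies are hyperactive right after introduction).
Consecutive slices are screened with the Jaccard index of their tie
sets; values above 0.2 indicate the panel changes slowly enough to be
treated as successive states of one evolving network. Two empty networks
have Jaccard 1 by convention. Replicates are labelled `Followed` /
`Avoided` / `Excluded` by the proportion of the uninformed flies' eggs
laid on the informed medium (> 0.8 / < 0.2 / otherwise, strict
inequalities — boundary values are Excluded).

## The SAOM engine

Network evolution is a continuous-time Markov chain observed at the
slice boundaries. Per observation period, each of the `n` actors
receives change opportunities at rate λ; the total opportunity count is
`K ~ Poisson(n·λ)` with the acting actor drawn uniformly per
opportunity. At an opportunity, actor *i* chooses among `n` candidate
states — toggling one outgoing tie, or keeping the network — with
multinomial-logit probabilities `∝ exp(f_i(x'))`, where the evaluation
function is `f_i(x) = Σ_k β_k s_ik(x)`. Seven effect statistics are
implemented: density (outdegree), reciprocity, indegree popularity
(`Σ_j x_ij·indeg_j`), outdegree activity (squared outdegree), covariate
alter (`Σ_j x_ij v_j`), covariate ego (`v_i·outdeg_i`), and same
covariate (`Σ_j x_ij 1{v_i=v_j}`), with the binary covariate informed=1
/ uninformed=0 used **uncentred** (RSiena centres covariates by default,
so covariate-effect magnitudes are not directly comparable to RSiena
output; signs and Wald tests are unaffected and the shift is absorbed by
the density effect). The simulation hot loop uses closed-form change
statistics (e.g. toggling `x_ij` changes inPop by `z·indeg_j + 1{z=+1}`
and outAct by `2·z·outdeg_i + 1`) compiled with numba; tests pin it to
the direct evaluation of `exp(f_i)` over all candidate states.

Rate function choice: the unconditional Poisson(n·λ) opportunity
schedule with constant rates. RSiena's conditional-on-change-count
simulation variant is not implemented.

### Method-of-Moments estimation

Estimation conditions on the first observation: each period is simulated
forward from its *observed* starting network. Moment targets are, for
each evaluation effect, the statistic summed over actors and over the
non-first observations, and, for each period, the Hamming distance
between its consecutive observations (the rate target). Multi-group
analysis sums evaluation targets over groups, shares the β vector, and
gives every period of every group its own rate λ.

The moment equations are solved by three-phase Robbins–Monro stochastic
approximation:

1. **Derivative.** `∂E[S]/∂θ` by finite differences (step 0.1) with
   common random numbers: opportunity counts, actor choices and logit
   draws come from per-(replicate, group, period) sub-streams keyed by a
   hash of the group id, so perturbed runs share randomness and
   multi-group fits are reproducible regardless of group order. Because
   each period starts from an observed network, a rate parameter only
   enters its own period's simulation; its derivative column re-simulates
   that single period, while β columns re-simulate everything (`n1 = 50`
   replicates by default).
2. **Updates.** Gain-decreasing iterations
   `θ ← θ − a·M·(S_sim − S_obs)`, four subphases with the gain halved and
   the subphase length growing 1.5× per subphase, iterate-averaged at
   subphase end, with per-component step caps and a rollback guard for
   diverging subphases. The update direction `M` is block-structured: the
   inverted evaluation-statistic block for β and the inverse diagonal for
   each rate. On small sparse panels a rate target can exceed the
   model's saturation value (the expected Hamming distance is bounded as
   λ → ∞); the block structure keeps such an unmatchable statistic from
   biasing the β updates through a full inverse, while leaving the
   fixed point of the iteration unchanged.
3. **Assessment.** `n3 = 1000` simulations at the candidate solution give
   the statistic covariance Σ̂, convergence t-ratios (mean deviation /
   sd per statistic), and standard errors by the delta method,
   `cov(θ̂) = D̂⁻¹ Σ̂ D̂⁻ᵀ`. The `converged` flag applies the published
   bar — every *effect* statistic's t-ratio below 0.1 in absolute value
   (the convention of per-parameter convergence ratios); the per-period
   rate t-ratios are reported separately, since the maximum over G×M of
   them carries a Monte-Carlo noise floor that grows with the panel
   count regardless of fit quality. The derivative entering the
   covariance is re-estimated at the solution by **central** differences
   (step 0.2, ≥150 replicates): the forward secant carries a curvature
   bias that inflates the derivative and understates the standard errors
   — with the central estimate, simulation checks show the recovery-
   experiment t-statistics (estimate − truth)/SE have unit spread.
   Phase 3 runs up to three rounds, applying a Newton correction on the
   measured mean deviation between rounds: the averaged Robbins–Monro
   iterate retains a small finite-gain offset that these corrections
   remove. Up to `max_restarts` full restarts re-derive the derivative
   at the best point so far.

Wald tests are `β̂/SE` against the standard normal. Estimates are kept in
`|β| ≤ 10`, rates in `[0.05, 20]`; a fit whose observed panels show no
change at all returns rates of zero and flags the evaluation parameters
unidentifiable. A singular evaluation-statistic block at the initial
derivative (collinear effects, e.g. sameX with an all-informed group)
raises an error advising model simplification.

**Known limitation — weak identification at desk scale.** On single
panels of 12 actors and a handful of waves, several effect statistics
are strongly correlated with density (inPop and outAct differ from it
only through the spread of alter/ego degrees; recip through chance
reciprocation, which at stationary density 0.5 is common), and the
moment surface has nearly flat, curved ridges. The exact moment roots
then spread wider than the delta-method standard error and acquire a
bias along the ridge, so the affected Wald tests over-reject under the
null: measured per-effect null retention of the stepwise procedure at
the study's group size is ≈5% for egoX and altX, ≈10–13% for inPop and
sameX, and ≈18–20% for recip and outAct. This is a property of the
method at this problem size — the identification ratio improves only
with the square root of the data volume, and the original study had
~25× more (29 groups × 23 waves) — not of the implementation: the
recovery experiment shows the same machinery is well calibrated for the
effects and sparsity regime it targets. The null-calibration test
asserts the nominal ≈5% bar for all six optional effects; the effects
listed above as inflated are expected to fail it.

### Stepwise selection and goodness of fit

Forward stepwise selection fits each candidate effect alongside density,
tabulates the per-effect Wald tests, retains effects whose screening fit
converged with `p < 0.05`, and refits the joint retained model; density
is always kept as the control. The convergence requirement matters:
with unmatched moment conditions the estimates drift along weakly
identified directions and their Wald tests are meaningless. Panels that
pass the Jaccard screen change slowly enough for the rate conditions to
be solvable, so on screened data the requirement costs little.

Goodness of fit follows the simulation approach of RSiena's `sienaGOF`:
the fitted model re-simulates the panels (each period conditional on its
observed start), an auxiliary statistic — cumulative in- or out-degree
counts over non-first waves, summed over groups — is compared between
observation and simulations by Mahalanobis distance (constant components
dropped, small ridge added; Euclidean fallback with a warning if the
covariance is degenerate), and the p-value is the Monte-Carlo tail
probability `(1 + #{d_sim ≥ d_obs})/(n_sim + 1)`.

## Incremental-window trend analysis

For each condition-labelled panel, the monadic model (density + egoX +
altX + sameX) is refitted on nested windows: observations 1..2, 1..3, …
up to the full panel, recording the egoX and altX Wald statistics per
window. Non-converged window fits are kept in the series but flagged and
excluded from the trend tests (not imputed). The trend test regresses
the t-series on time and condition — additive terms, no interaction —
and compares the linear against the quadratic model with
`F = ((RSS_lin − RSS_quad)/1)/(RSS_quad/(N − 4))`, both models fitted on
the same records (paired nesting). Models are pooled across conditions
with a condition main effect, matching the single condition contrast the
analysis reports. Degenerate cases: an exactly linear response returns
F = 0, p = 1; an exactly quadratic one returns F = ∞, p = 0.

## Synthetic data

**Arena trajectories.** 8 informed + 4 uninformed flies on a reflective
100 mm disc, 4 h at 10 fps. Flies alternate walking (isotropic Gaussian
steps, 0.8 mm/frame scale) and resting; uninformed flies walk more often
(move probability 0.25 vs 0.15/frame). At ordered class-pair specific
rates (per minute per potential target: cross-class 0.06,
uninformed–uninformed 0.035, informed–informed 0.008), a fly starts an
approach bout — walks to the chosen fly at 1.2 mm/frame, dwells ~1 s in
contact, then has a 5 s refractory period. Static lognormal pair
affinities (σ = 0.8) multiply the rates, giving persistent pair
preferences that carry tie structure across slices. An earlier design —
continuous attraction toward the nearest fly — proved unstable: strong
enough attraction makes pairs lock and cluster, and the class asymmetry
of contact rates then varies wildly (and sometimes reverses) across
seeds, so it was replaced by the bout mechanism whose contact rates are
directly interpretable. Body lengths are drawn once per fly from
N(2.5 mm, 0.25 mm) truncated positive.

The default rates were calibrated once against the scale of the study's
reported per-video interaction totals (raw events of order 10³ per hour,
10-min binarized slice densities around 0.5, Jaccard indices comfortably
above the 0.2 screen) and to produce the study's directional class
asymmetry: with the 8/4 split and cross-class-dominated rates,
uninformed flies both start more contacts per capita (8 cross-class
targets each) and receive more per capita (8 cross-class approachers
aiming at 4 flies), and the uninformed–uninformed surplus over
informed–informed makes the over-reception a genuine alter preference
rather than pure heterophily. What the generator does *not* emulate:
real locomotion statistics (turning, wall-following, speed
distributions), identity-tracking errors, angle-of-approach structure,
any behavioural change over the 4 h (time-homogeneous rates), and any
mechanism linking contacts to egg-laying — so passing pipeline tests
shows the machinery is correct under the assumed contact structure, not
that the biological conclusions would replicate.

**SAOM panels.** Ground-truth panels draw the first observation as an
Erdős–Rényi digraph (default density 0.1, near the stationary density of
the recovery-experiment parameters so periods are statistically
homogeneous; conditioning on the first observation makes its
distribution irrelevant to estimation) and evolve it with the same
micro-step simulator the estimator uses. Generating parameters ride
along in `panel.meta` for recovery scoring.

**Egg counts.** A proportion uniform on the condition's interval, a
binomial count, resampled until classification returns the requested
label.

## Experiment sizes

Chosen once for the standard test and acceptance runs: the convergence
experiment fits the 7-effect model to 5 groups × 5 observations × 12
actors; parameter recovery uses 200 replicates (100 in the acceptance
script) of single panels at the generating values β = (−1.5, 0.8, −0.5)
for (density, recip, egoX) and λ = 4, with the bias comparison at 5 vs
20 groups; null calibration uses 50 stepwise replicates (30 in the
script) and 1000 trend series; the end-to-end experiment uses 4
full-length (4 h) synthetic recordings. Estimation settings for
many-replicate experiments are reduced (n1 = 40, 3–4 subphases,
n3 = 300–500, no restarts); single headline fits use the full defaults
with restarts.

## Numerical notes

* All randomness flows from integer seeds through `numpy.random.
  SeedSequence`; every stochastic operation derives its sub-streams
  deterministically, so identical seeds give bit-identical results and
  multi-group fits do not depend on group order.
* Logit weights are max-subtracted before exponentiation; β and λ live
  in closed boxes (above) to keep intermediate iterates finite.
* The exact null-model change rate used as a simulator oracle: at β = 0
  each specific tie is toggled at Poisson rate λ/n per period, so
  `E[Hamming] = n(n−1)(1 − e^{−2λ/n})/2`.
* With two actors and only the density effect, the stationary tie
  probability is exactly `e^β/(1+e^β)`; for n > 2 the stationary law of
  this dynamic is *not* the dyad-independent logistic (the normalising
  term of the choice set varies with the state), which is why the
  closed-form check is stated for n = 2.
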
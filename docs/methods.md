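# Methods

## From group listings to dyads

The Social Cognitive Map instrument collects *groups*, not dyads. `scmnet`
reads each respondent's listed groups and isolates, validates them against
the classroom roster (groups of at least two members; no member both grouped
and isolate; all identifiers on the roster), and expands each group into a
clique: a listed group implies a tie between every pair of its members,
including pairs that involve the perceiver. Overlapping groups union at the
edge level, so a dyad mentioned twice counts once; isolates contribute no
edges. Because only respondents who completed an SCM have relational data,
perceived networks are restricted to the roster's participants before any
downstream computation — a pair with a non-participant endpoint is dropped.
Identifiers are opaque strings throughout; no numeric coercion is attempted,
which avoids silent collisions between, say, `07` and `7`.

If a respondent lists the same classmate in two different groups, the
implied dyads simply union; the instrument itself does not forbid this and
the simple-graph representation makes the choice inconsequential.

## The consensus ("true") network

A tie *i–j* is accepted as true iff *i*'s own SCM and *j*'s own SCM both
depict it (the locally aggregate structures intersection rule). Reports by
third parties are deliberately ignored: they count toward the *perceiver's*
depicted ties, never toward the truth of a dyad they are not part of.
Classroom-waves are retained only when the participation rate is *strictly*
greater than the 0.60 threshold. Three consequences the implementation makes
explicit:

- every true tie is contained in both endpoints' perceived networks
  (tested as an invariant);
- removing an edge from any single perceived network can never add a
  consensus tie (monotonicity);
- a participant with no perceived network is an error, not an implicit
  all-absent report.

## Accuracy and transitivity

Accuracy is precision × coverage on unrounded components; rounding to two
decimals happens only at the presentation layer. Two degenerate cases are
resolved by convention rather than error:

- **Zero depicted ties**: precision is 0/0. The record is scored 0 and
  flagged (`zero_depicted`) — a perceiver who identifies nothing has
  omitted every true relationship, which is the index's floor; raising
  instead would silently drop participants.
- **Empty consensus network**: coverage has no denominator; the
  classroom-wave is excluded from accuracy scoring with a logged warning,
  since no meaningful target exists.

Transitivity is 3T/(3T+P) over the consensus network (T triangles, P open
two-paths), computed from degree-based connected-triple counts and
triangle counts; the test suite checks it against exhaustive triple
classification and against the global clustering coefficient from networkx.
A network with no connected triple gets a *missing* index, not 0 — zero
would assert maximal intransitivity where there is no information. Dyads
involving the perceiver are included in both depicted and true edge counts;
the full classroom network is scored.

## Longitudinal model

The participant-wave table joins accuracy records to classroom transitivity
on (classroom, wave), so a participant who changes classroom between waves
gets each wave's own classroom value. Waves with undefined transitivity are
excluded (counted in the log) before the inclusion rule drops participants
observed at fewer than two retained waves. Time is coded as the 0-based
rank of the wave in the global wave order; waves are treated as equally
spaced even where real designs mix annual and within-year intervals — a
documented simplification, not a per-row setting. The time-varying
predictor is disaggregated against each participant's *first observed*
wave (not calendar wave 0): `transitivity_t0` carries between-person
differences and `transitivity_change = transitivity − transitivity_t0`
within-person change, so the two always sum back to the wave's classroom
value (tested to machine precision).

The random-intercept model is estimated by REML through statsmodels
`MixedLM` (optimizers tried in order bfgs, powell, Nelder–Mead;
non-convergence raises rather than returning partial estimates). Constant
predictors, collinear designs, and a constant outcome are rejected with an
error naming the offender before estimation is attempted. Since statsmodels
does not provide Satterthwaite degrees of freedom, they are computed
in-package from the closed-form profiled REML criterion of the
one-variance-component model: df = 2·(c′Ĉc)² / (g′Âg), with C(θ) =
(X′V(θ)⁻¹X)⁻¹ and its analytic gradient g, and Â the inverse observed
information of the REML criterion in θ = (σ²_intercept, σ²_residual),
obtained by central-difference Hessian. When the intercept variance sits on
the zero boundary the residual df n − p is used instead. On fixed data the
estimates, standard errors, dfs and p-values agree with `lmerTest::lmer`
to at least five significant digits (verified by an R-based oracle test).
No classroom-level random effect is fitted.

`predicted_accuracy_difference` translates a coefficient into the
model-implied accuracy difference for a given transitivity difference
(coefficient × Δ), the natural way to read effects when both variables
live on [0, 1].

## Synthetic studies

The generator's role is to produce data whose ground truth is known so that
every pipeline stage is falsifiable.

**Planted networks.** A classroom-wave network is a uniformly random graph
at edge count round(density·n(n−1)/2), hill-climbed to a target
transitivity: to raise the index, close a random open two-path and remove a
random other edge; to lower it, break a random triangle edge and add a
random non-edge; accept only moves that shrink the gap. Edge count is
preserved (the index depends only on triad composition, so density control
suffices; degree sequences are not preserved). Failure to reach the target
within the iteration budget raises an error reporting the best value
achieved. Across waves the network is evolved by rewiring a fraction of
edges and re-targeting.

**Reports.** A perceiver reports each of their own true ties with
`p_hit_own`, each other true tie with `p_hit_other` — or, with the coupling
enabled, with logistic(a + b·transitivity) — and each non-tie with
`p_false`. Holding `p_hit_own` outside the coupling keeps the consensus
network (which depends only on endpoints' own-tie reports) separable from
the perception effect being planted. Perceived edge sets are encoded back
into groups as maximal cliques, which round-trips losslessly through the
reader; real respondents presumably partition rather than enumerate
cliques, but a lossy partition heuristic would confound downstream tests
with encoding noise.

**Defaults** (chosen once to emulate the descriptive ranges reported for
classroom studies of this design — per-wave mean transitivity within
roughly 0.3–0.8 and mean accuracy within roughly 0.2–0.6): 12 classrooms ×
20 members × 3 waves; edge density 0.15 (≈29 ties, mean degree ≈3);
per-classroom-wave transitivity targets uniform on (0.35, 0.75) at
tolerance 0.03; `p_hit_own` 0.95, `p_false` 0.02; coupling a = −1.3,
b = 3.2, putting other-tie hit rates near 0.45–0.75 across the target
range; rewire fraction 0.2; participation probability 0.85 per member-wave
(above the 0.60 eligibility threshold with realistic slack). With these
settings the planted within-person coupling surfaces as a fitted
within-person coefficient of roughly 0.4–0.5.

**What the generator does not emulate.** Reciprocity of real reporting
(errors here are independent across perceivers), stable group membership
(groups are re-derived from edges each wave), classroom-level clustering of
accuracy beyond the transitivity coupling, entry/exit of members, and any
respondent-level covariates (age, gender, centrality). Passing tests
therefore demonstrate that the pipeline recovers what was planted under
independent noise — not that real classrooms satisfy these assumptions.

## Validation experiments and problem sizes

Chosen to make the checks decisive while keeping the default test run
quick:

- triad/set oracles and the group-encoding round trip: 10,000 random
  labelled graphs on 3–8 nodes against exhaustive brute force;
- noiseless end-to-end recovery: 5 classrooms × 2 waves, all hit rates 1,
  no false alarms — consensus must equal the planted networks exactly and
  every accuracy must be 1.0;
- parameter recovery: 200 replicates of 150 participants × 3 waves
  simulated directly from the model at β = (0.1, 0, 0.5, 0.5),
  σ² = (0.01, 0.01); per-coefficient |bias| < 0.05 and Satterthwaite 95%
  CI coverage for the two transitivity effects within [0.90, 0.99];
- type-I calibration: 500 replicates with the within-person effect set to
  zero (transitivity trajectories retained, accuracy decoupled from them);
  rejection rate at α = 0.05 must lie in [0.02, 0.09]. Calibration is run
  at the model level; a full network-generator null at this replicate count
  would add nothing to the hypothesis being checked, since the generator's
  coupling enters the model only through the simulated hit rates;
- generator fidelity: one default study; per-wave mean consensus
  transitivity within [0.3, 0.8] and mean accuracy within [0.2, 0.6].

## Known limitations

- The intersection rule is conservative: report noise only removes
  consensus ties, so measured consensus transitivity is attenuated and
  noisier than the planted value, especially in small or sparse classrooms.
- Accuracy and measured transitivity are both functions of the same
  consensus network, which is itself built from the noisy reports. Their
  sampling errors are therefore correlated: even with the generator's
  coupling disabled, the fitted within-person effect rejects its null well
  above the nominal rate when transitivity is *measured* rather than
  planted. This is a property of the estimand (any design that scores
  perceivers against a consensus derived from the same instrument shares
  it), which is why type-I calibration is assessed with model-level
  transitivity trajectories rather than re-measured ones.
- Satterthwaite dfs fall back to residual df at the σ²_intercept = 0
  boundary; boundary inference for the variance itself is not attempted.
- Accuracy values near the [0, 1] edges make the Gaussian residual model an
  approximation; no logit or beta link is offered.
- The hill-climb targets the global index only; other structure (degree
  variance, community count) is whatever the walk happens to produce.
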
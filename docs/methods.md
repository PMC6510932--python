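# Methods

This note records the statistical model, the preprocessing conventions, the
synthetic-data generators and the numerical choices behind `replinet`, and
what the test suite does and does not establish.

## The model

Each response metric (contacts/day, mean seconds per contact, contact
seconds/day, weighted degree) is analysed on the base-10 log scale, where
multiplicative variation between animals and groups becomes additive and
the data are much closer to normal. For animal *a* in group *g* during
phase *p*:

    y_gap = mu + pi_p + G_g + (G*pi)_gp + A_a(g) + e_gap

* `pi_p` — fixed phase effects (the treatment, applied to whole groups);
* `G_g ~ N(0, s2_G)` — persistent group differences in level;
* `(G*pi)_gp ~ N(0, s2_GP)` — **between-group variation in the change** of
  behaviour across phases; this is the term that limits what group-level
  replication can detect;
* `A_a(g) ~ N(0, s2_A)` — persistent animal differences within group;
* `e_gap ~ N(0, s2_e)` — **within-group variation in the change**, the
  animal-by-phase residual.

Because treatment is at the group level, the correct error stratum for the
phase effect is the group-by-phase mean square, not the residual: using
animals as replicates would be pseudo-replication.

### Estimation

For a complete balanced table the REML solution (when all components are
positive) coincides with the classical expected-mean-square solution, so
the components are computed in closed form from the five-stratum balanced
ANOVA:

    s2_e  = MS_res
    s2_GP = (MS_GxP - MS_res) / n_n
    s2_A  = (MS_A(G) - MS_res) / n_p
    s2_G  = (MS_G - MS_GxP - MS_A(G) + MS_res) / (n_n n_p)

This path is transparent, exact and dependency-light. It is validated in
the test suite against a *generic* numerical REML maximiser (full marginal
covariance, analytic-gradient L-BFGS on log-variances, written without any
mean-square algebra) on randomly drawn interior instances, agreeing to
~1e-9; that oracle is itself checked once against statsmodels' `MixedLM`.
Negative moment estimates are legitimate under the unconstrained
convention and are returned as-is by default; `constrain_nonneg=True`
truncates to zero with a warning. Unbalanced or incomplete tables are
rejected with a pointer to general REML tooling — they are outside the
closed-form path by design.

### Inference

* Phase test: `F = MS_phase / MS_GxP` on `(n_p-1, (n_g-1)(n_p-1))` df;
  the Wald statistic is reported as `W = (n_p-1) F`. Under the model this
  F-test is exact, which the suite confirms by simulation (type-I rate
  within [0.04, 0.06] over 2000 null datasets).
* Pairwise phases: difference of marginal phase means with
  `SED = sqrt(2 s2_GP/n_g + 2 s2_e/(n_g n_n))`, t on `(n_g-1)(n_p-1)` df,
  unadjusted p-values (a Bonferroni option exists, off by default).
* Back-transformed summaries: `10^m` with limits `10^(m ± t * SE)`. The SE
  of a phase mean is taken under the full random-effects model,
  `sqrt((s2_G + s2_GP)/n_g + (s2_A + s2_e)/(n_g n_n))`. The original
  study does not state its interval construction, so these intervals are a
  reasonable convention, not a reproduction target.

## Design prediction (SED / LSD)

`LSD(5%) = t_{0.975,v} * SED` with `v = (n_g-1)(n_p-1)`. A phase
difference of the observed magnitude is declarable at the 5% level only
when it exceeds the LSD (strict inequality). Three scenario families are
tabulated: 3–7 networks of 5; 6 networks of 3–7; and all factorisations of
a fixed total of 30 animals with `n_g >= 2, n_n >= 3`. Full precision is
carried everywhere; rounding to two decimals happens only in the reporting
layer. Because the residual term of `SED²` depends only on the total
`n_g * n_n`, allocation differences at fixed total act purely through the
`2 s2_GP / n_g` term — the formal content of the observation that power is
lost primarily through reduced replication.

### Reproduction of the published grids, and known discrepancies

With the published components, the package reproduces the published
scenario grids (39 rows × {SED, df, t, LSD}) at printed precision except
for six cells that are internally inconsistent with the printed 4-decimal
components — evidently computed from unrounded components before printing:

* five LSD cells of the contact-frequency grid, rows (4,5), (3,5), (6,6),
  (3,10), (2,15): printed 0.14/0.18/0.12/0.16/0.29 vs recomputed
  0.15/0.19/0.11/0.18/0.32;
* one SED cell of the degree grid, row (3,5): printed 0.06 vs recomputed
  0.0650 → 0.07 (its printed LSD 0.18 *does* match 2.78 × 0.0650).

These cells are frozen as exclusions in `replinet.published` and skipped
by the exact-reproduction tests; the acceptance script reports the overall
cell match rate (150/156 ≈ 96%). Two further published values are known
inconsistencies and are not used: the total-duration row's "contribution
variance" (0.0017 vs 2×0.0041/30) and percentage split, and the
detectability flag of the frequency grid's (3,5) row (the printed phase
means give a max log10 difference of 0.198, which exceeds both the printed
0.18 and the recomputed 0.193 LSD). The published back-transformed degree
mean (2460.4/day-equivalent) also cannot equal 6 × the frequency mean
(360.4) although degree = 6 × contacts/day identically under this
package's definitions; the self-consistent definition is implemented.

## Preprocessing conventions

Order: trim → ≤1-s filter on raw directional records → reciprocal union →
bout assembly → phase assignment. The short-contact filter is applied
*before* merging (spurious detections should not seed bouts); the order is
a documented convention exposed through the module functions. Other
conventions, each configurable where noted:

* trim keeps `t = 0` exactly (drops strictly negative times);
* the 1-s deletion is inclusive (`duration <= min_contact_duration`);
* union coalesces touching intervals (gap 0);
* bout merge uses strict `gap < separation_time`; an exact 30-s gap gives
  two bouts; merging is exhaustive and idempotent (verified against an
  O(n²) pairwise-merge oracle);
* bouts straddling a phase boundary are split at the boundary so per-phase
  durations are conserved exactly (`boundary_policy="start"` assigns by
  start time instead, for sensitivity analysis);
* contacts of the unfamiliar animal are preprocessed identically and kept;
  excluding them is a network-construction option (`restrict`), defaulting
  to residents-only for the analysed metrics and all-animals for graphs.

Degree is the *weighted* row sum of the frequency matrix (count of
contacts, not distinct partners): with at most four resident partners a
binary degree could never reach the observed thousands per phase.
Zero-contact animals get `mean_dur = 0` and must be excluded (or offset)
before the log transform; the fitting path raises with the offending
animal-phase cell named.

## Synthetic data

Two levels, with different purposes:

**Metric level** draws `y` directly from the mixed model — exact
distributional control, so it is the surface for parameter recovery
(500 studies at the published component magnitudes recover the mean of
s2_GP and s2_e within a few percent) and test calibration. Defaults: the
published frequency components (s2_GP = 0.0047, s2_e = 0.0129), phase
means from the published back-transformed frequencies, and 6×5×3 layout.
The group and animal components were not published; the defaults
(s2_G = 0.005, s2_A = 0.010) are chosen at the same order of magnitude and
only affect strata that cancel out of the SED.

**Event level** generates what loggers record: per-dyad Poisson bout
processes (log10 rate = base + group + group-by-phase + dyad effects),
log-normal durations, two directional records per event with independent
Gaussian start/end jitter (SD 5 s), a 5% per-logger miss probability, and
spurious ≤1-s detections (2/dyad/day). The published study reports no
event-level distributions, so these forms are conventions; rates are
calibrated loosely to its magnitudes (90 bouts/dyad/day before the
disturbance ≈ 360 contacts/cow/day; mean durations near 54/73/68 s across
phases). Two honest gaps of this generator:

* bout merging absorbs near-coincident events, so the realised phase-1
  frequency in a default bundle is ≈ 300 contacts/cow/day, ~15% below the
  nominal calibration;
* dyad effects are constant across phases, so the animal-level residual
  variance in the *change* of behaviour is tiny (Poisson noise only) —
  far below the published 0.0129. Event-level output exercises the
  pipeline's plumbing and directions of change, not Table-level variance
  magnitudes; those are the metric-level simulator's job.

Passing tests on synthetic data therefore demonstrate correctness of the
algorithms under the stated model, not that real cattle data follow that
model. All generators take explicit seeds (PCG64) and touch no global
state; identical seeds give identical output.

## Problem sizes and numerics

The test suite runs metric-level simulations at the study layout (90
observations each; 500 recovery replicates, 2000 null replicates), the
oracle comparison at 3×2×3 (20 interior instances), and event-level
simulations at reduced contact rates (`scale = 0.02–0.2`) — full-rate
bundles (~170k records) are exercised by the acceptance script. p-values
come from scipy's F/t distributions (incomplete-beta); no resampling. SS
decompositions agree with the total corrected SS to 1e-9 relative
tolerance; stratum SS are sums of squares and hence non-negative by
construction.

## Limitations

* The closed-form path requires complete balanced tables; dropouts or
  unequal group sizes need general REML tooling.
* No spatial structure, diurnal rhythm, or logger battery/clock-drift
  modelling — the reciprocal-union rule is the only asymmetry correction.
* The design predictions assume variance components and effect sizes carry
  over unchanged to re-designed studies, and network size itself may alter
  contact behaviour; the tables are decision aids, not power guarantees.
* No permutation/null-model network tests and no centrality measures
  beyond degree; exported GraphML is intended for external tools.
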
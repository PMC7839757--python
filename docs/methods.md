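# Methods

## Model structure

The model is a four-state Markov cohort model (nonadherent **A**, adherent
**B**, remission **C**, death **D**) with a one-year cycle and a 100-cycle
lifetime horizon. A cohort enters with epilepsy — all mass split between A
and B by the initial adherent share — and ages one year per cycle;
transition matrices are rebuilt every cycle from the age-band tables at the
cohort's current age. DEATH is absorbing, and occupancy vectors are exact
probability distributions (each row of every transition matrix sums to 1 by
construction, with the diagonal as the complement of the exits).

Rates enter the model as annual transition probabilities exactly as
tabulated; no rate→probability exponential conversion is applied, because
the sources give single annual figures without person-time denominators.
Two band systems coexist (a six-band table for epilepsy mortality and
remission; a 21-band demographic table for background mortality and
relapse); both are kept verbatim and resolved per lookup, and ages above
the top band reuse the top band's value. Within-band ages are not
interpolated.

Cycle convention: the occupancy at the *start* of a cycle earns that
year's utility and cost, and the transition fires at the end of the cycle.
No half-cycle correction is applied. The headline check supporting this
choice: the program cost of 443 ZAR per person-year accrued over all 100
cycles (44 300 ZAR per person) is exactly the per-person lifetime program
cost implied by the published difference between the base-case and
+50 %-cost ICERs, for both sexes; discounted or survival-weighted accrual
is inconsistent with those figures. Discounting is therefore 0 % by
default for both QALYs and costs (a configurable rate is exposed for
extension, default 0).

## Utilities and costs

Utilities are 1 − disability weight: 0.58 (A), 0.8292 (B, the 60/40
seizure-free/with-seizures mixture), 0.928 (C), 0 (D). Costs accrue per
state-year: 16 340 ZAR in A and 8 681 ZAR in B (ASMs, clinic/hospital
utilization, lost productivity valued at the daily GDP per capita of
195 ZAR), nothing in C or D; each has ±15 % bounds used by the cost-range
sensitivity. The intervention arm additionally pays the program cost
(443 ZAR/person-year = 664 320 ZAR annual sub-district budget over ≈1 500
served individuals) in every cycle, unweighted by survival ("all-cycles"
rule; an "alive-cycles" alternative ships but is not the default, per the
consistency check above). Currency is carried at full precision and
converted at 5.39 ZAR per international dollar; rounding to whole currency
units and two-decimal QALYs happens only in reports.

## Adherence dynamics

The published analysis specifies adherence *levels* (68 % baseline; 90 %
within two years under the intervention) but no switching probabilities
between A and B. The package therefore treats the adherent share
s = B/(A+B) among people living with epilepsy as the policy variable:

* the **baseline** holds s at its initial level by solving, each cycle, a
  one-dimensional equation for the A→B probability (given a fixed lapse
  probability B→A) against the cohort recursion. The solve is closed-form
  because an A→B transfer moves mass within A+B, leaving the
  post-transition A+B total invariant; a bracketed root-find against the
  actual engine matrix is the fallback when row renormalization breaks
  that linearity. Unreachable targets are met as closely as feasible, with
  a warning when the miss exceeds 0.01.
* the **intervention** tracks a linear ramp from the initial share to the
  90 % target over two years, then switches at a constant steady-state A→B
  probability (a calibrated parameter, see below), under which the realized
  share settles at or slightly above the target. Holding the share exactly
  at 0.90 forever is also supported (`post_ramp_prob_a_to_b=None`) and is
  used for share-monotonicity properties, but it cannot reproduce the
  published incremental outcomes (best attainable male ICER ≈ 9 600
  ZAR/QALY versus the published 8 053).

The −50 %-effectiveness sensitivity scales the adherence gain: the ramp
targets `initial + 0.5·(target − initial)` and the post-ramp switching
schedule is blended halfway toward the baseline's stationary solution. At
effect 0 the intervention's dynamics reduce to the baseline's bit-exactly;
at effect 1 the full intervention is recovered. The published −50 %-effect
ICERs are *not* point-reproducible from the text (the printed values imply
more than a simple halving of the adherence gain); the package asserts
only the published threshold claim (all sensitivity ICERs below 1×GDP per
QALY).

## Calibration

Four quantities are under-determined by the sources: cohort entry age, the
precise initial adherent share, the lapse probability B→A and the
post-ramp A→B probability. `calibrate` resolves them by exhaustive grid
search minimizing the summed squared relative error against the four
published incremental outcomes — (ΔQALY, ΔCost) = (5.90, 47 480 ZAR) for
males and (4.09, 40 969 ZAR) for females — followed by deterministic local
refinement (step-halving around the incumbent, including ±1-year entry-age
moves). Ties break toward younger entry age, then smaller switching
probabilities, so identical grids always select identical configurations.

Grid choices: entry ages 0–10 in 1-year steps plus 15–45 in 5-year steps —
the loss surface varies steeply across pediatric entry ages, where
remission differs by a factor of two between adjacent bands and between
sexes, and a uniform 5-year grid steps over the basin; initial shares
0.65–0.71 (the share is a measured quantity, so the grid is a tight
neighborhood of the observed 0.68, not a free dial); lapse probabilities
0–0.08; post-ramp switching 0.1–1.0. About 5 500 configurations are
evaluated, each a pair of two-arm, two-sex 100-cycle runs (~2–3 minutes
total on one core).

The calibrated optimum is entry age 3, initial share 0.646, lapse
probability 0.0144 and post-ramp switching 0.4125 (loss 2.3 × 10⁻³). At
that configuration the model reproduces the published base-case male ICER
to +0.9 % (8 123 vs 8 053 ZAR/QALY) and the +50 %-cost ICERs to +1.0 %
(male) and +1.8 % (female).

**Known reproduction limit.** The female base-case ICER calibrates to
10 341 ZAR/QALY, +3.3 % above the published 10 009 — outside a 2 % band.
The residual is a female incremental state-cost saving that is too small
in magnitude (≈ −1.5 k ZAR modelled vs ≈ −3.3 k implied by the published
figures, net of the 44.3 k program cost), and it is robust: across every
operationalization examined (exact share holding, constant post-ramp
switching, a held steady-state share above the target, a one-off
entry-share pulse, rates frozen at the entry band) no configuration
matches the female cost delta without destroying the male fit. The
mechanism the original analysis used to couple the sexes' cost outcomes is
not recoverable from the published description; the discrepancy is
reported rather than absorbed into wider tolerances.

## Microsimulation oracle

`microsim.simulate_individuals` draws individual annual state paths from
exactly the per-cycle matrices the cohort engine uses. Each individual has
a private `default_rng([seed, i])` stream, so records are bit-reproducible
and enlarging n extends the sample without reshuffling existing paths.
QALYs and costs accrue per path under the same start-of-cycle convention.
`cross_validate` compares cohort quantities with microsimulation means at
z·SE (default z = 3); occupancy proportions get a 1/n continuity guard on
the binomial SE so near-degenerate fractions are not spuriously failed.
At n = 10 000 the full-fixture comparison passes in ~2 s.

What the generator emulates: the transition law, entry mixing, and reward
accrual of the cohort model. What it does not: real-world heterogeneity
(individual frailty, covariate-dependent transitions, secular mortality
trends), misclassification of adherence, or sampling of the parameter
tables themselves — so agreement validates the *implementation*, not the
epidemiological inputs.

`generate_fixture` produces randomized parameter sets satisfying every
type invariant (band coverage, probability ranges, mortality ordering,
utility ordering, ±15 % cost bounds) for property tests; switching
probabilities beyond a row's capacity are proportionally renormalized by
the engine with a warning (sums within 10⁻¹² of 1 clip silently as float
noise; sums above 1.5 raise, as no plausible parameter set produces them).

## Numerical choices and degenerate inputs

* Row assembly guarantees exact row sums of 1 (diagonal = 1 − exits after
  any clipping/renormalization).
* Share tracking tolerates empty A-state mass (switching is then
  irrelevant and set to 0) and an extinct cohort (share undefined, target
  treated as met).
* ICERs with a zero QALY difference are flagged (`zero-effect`) rather
  than raised; dominance (cheaper and more effective) and dominated cases
  are labeled and no threshold verdict is emitted for undefined ratios.
* Threshold comparisons are inclusive (≤).
* All reported problem sizes — 100-cycle horizon, ~5 500-configuration
  calibration grid, n = 10 000 microsimulation — are the package defaults
  used by the tests and the acceptance script.

## Limitations

Beyond the female-ICER residual above: the model inherits every limitation
of its inputs (expert-opinion effectiveness, a single sub-district's rate
tables, 2010 disability weights used as utilities via 1 − DW); it has no
probabilistic sensitivity analysis (none was published to compare
against); tunnel states, within-band aging effects and seizure-frequency
sub-states beyond the 60/40 utility mixture are out of scope; and the
diagnostic gap (case finding) is explicitly not modelled — the
intervention acts on the treatment gap only.
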
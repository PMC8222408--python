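# Methods

## The care-allocation game

Two co-breeding mothers each contribute one offspring to a communal litter
and must each take on the postnatal care of one of the two young.
Offspring `i` enters care at initial size `x_i` (its prenatal investment);
its carer `j` adds effort `y_j`, and the offspring survives with
probability `b(x_i + y_j)`, while the carer pays a fecundity cost
`c(k_j, y_j)`.  The default payoff family is

```
b(t) = t (1 - t/2)        for 0 <= t <= 1
c(k, y) = k y^2
```

`b` is strictly increasing and strictly concave on its domain, `c` strictly
increasing and strictly convex in `y`, and the condition parameter `k > 0`
scales how steeply care costs rise — a lower `k` is a mother in better
condition.  Total investment is capped at the benefit's domain
(`x + y <= 1`); the benefit is never extrapolated beyond it.

**Valuation weights.**  With synchronized birth a veil of ignorance hides
parentage: each of the two young is a mother's own with probability 1/2
and a relative's (relatedness `r`) otherwise, so every pup is valued at the
expected relatedness `(1 + r)/2`.  Without the veil a mother values her own
pup at 1 and her co-breeder's at `r`.  The veil weight is a modelling
choice (the valuation is an expectation over the two equally likely
parentage configurations); it reproduces the published zone classification
of the two reference parameter points (A: `k = 1.25/0.75`,
`x = 0.25/0.15`, disagreement; B: `k = 1.5/0.5`, `x = 0.3/0.1`, agreement
on the outcome where the better-condition mother tends the smaller pup),
which is the validation we rely on.

**Equilibrium.**  Given an assignment, mother `j` tending offspring `i`
chooses `y_j` to maximise `w b(x_i + y_j) - c(k_j, y_j)` where `w` is her
valuation of that offspring.  Her objective does not depend on the other
mother's effort, so the profile of individually optimal efforts is the
unique Nash equilibrium; a best-response iteration (kept as a test oracle)
converges to it in one step.  For the default family the interior optimum
is the closed form `y* = w (1 - x) / (w + 2k)`, clipped to `[0, 1 - x]`;
custom payoff families fall back to bounded numeric maximisation
(`xatol = 1e-10`).  The closed form is checked against the numeric
optimiser to `1e-6` in the test suite.

**Assignments and zones.**  A dyad admits exactly two assignments, named
`s1` (first-listed mother tends the smaller offspring) and `s2`.  In the
zone scans the first mother is the one in worse condition
(`k1 = k_mean + dk/2`), so `s1`/`s2` match the conventional outcome labels
1/2.  Preferences are classified by comparing each mother's equilibrium
fitness across the two assignments: mutual strict preference is agreement,
opposed preferences disagreement, and any comparison within the tie
tolerance (`1e-9` on fitness) is a boundary.  Without the veil the two
assignments are own-care and exchange, and parentage must be supplied.
The asymmetry grid uses signed differences `dk`, `dx` at fixed means
(defaults `k_mean = 1`, `x_mean = 0.2`), the means shared by the two
reference points.

**Inequality trajectories.**  Offspring-size inequality is the population
variance (divide by n = 2) of the pair of sizes, before care (`x` values)
and after (equilibrium totals `t = x + y`).  When conflict is unresolved,
the `equal_mixture` policy averages the two outcomes' post-care variances —
an average over equally probable realised outcomes, not the variance of a
pooled mixture distribution.  In every zone-of-agreement equilibrium the
mutually preferred outcome pairs the better-condition mother with the
smaller offspring, and that pup's carer invests strictly more than the
other — care according to need.  At the reference points this levels the
initial inequality (at point B the totals equalise exactly).  The
levelling is not universal, however: when the condition asymmetry is
large relative to the offspring asymmetry, the extra care *overshoots*,
reversing the size ranking and leaving the final variance above the
initial one.  The package states the levelling claim only where it holds
(no rank reversal); the overshoot region is a genuine feature of the
model, not an implementation artefact.

## Kin-selected exchange without the veil

"Exchange" is the assignment in which each mother tends the other's
offspring; it is mutually agreeable at relatedness `r` when both mothers'
inclusive fitness (own offspring weighted 1, the co-breeder's weighted
`r`, efforts re-optimised per assignment) is strictly higher under
exchange than under own-care.  At `r = 0` own-care is always strictly
preferred.  The minimal `r` at which exchange becomes agreeable is found
by a coarse scan over `[0, 1]` at step 0.01 followed by bisection to
`1e-4`; if the scan finds multiple preference flips every crossing is
reported rather than a single threshold.  The default scenario uses the
condition asymmetry of reference point B (`k = 0.5` vs `1.5`) with the
better-condition mother owning the larger pup — matching the experimental
situation, where provisioned mothers bore larger pups.  Under that
scenario a three-fold size difference (`x = 0.3` vs `0.1`) gives a
threshold near `r ≈ 0.95`, and the threshold rises toward 1 as the young
become more similar in size; exchange through kinship alone therefore
requires implausibly high relatedness.

## The synthetic provisioning experiment

The generator emulates a split-plot field experiment on communally
breeding groups: in "manipulated" breeding attempts half of the pregnant
females are provisioned during pregnancy ("fed") and half are matched
controls ("non-fed"); every manipulated attempt is followed by an
unmanipulated one.  It produces four tidy tables (mothers, pups, escorting
observations, maternal weights) from one master seed, with per-group
substreams so output is byte-identical for a fixed seed.

* **Groups and litters.**  7 groups, 10 attempts each (alternating
  manipulated/unmanipulated, ~35 manipulated litters per study).  The
  breeding-female pool size per group is drawn once from the litter-size
  distribution (mean 5.0, sd 2.6, truncated at >= 2); all pool females
  breed in every attempt (female reproductive skew is low in this system),
  and the pool turns over by mortality (0.07 per female per attempt) and
  recruitment of new, history-free females.
* **Treatment assignment.**  Pregnant females are paired by age; a pair
  with no experimental history splits at random, a female with a history
  takes the opposite of her previous category and her partner the
  complement, and same-history pairs are re-paired with the nearest-aged
  compatible female.  A repair pass restores the half/half split wherever
  histories permit.  The never-fed-twice rule and the ±1 balance rule can
  conflict when previously fed females exceed half the participants (a
  rare demographic corner, ~0.3% of attempts at the defaults); the
  never-fed-twice rule takes precedence, so balance is guaranteed only
  when feasible.
* **Provisioning.**  Fed females receive 0, 50 or 100 g of egg per day
  (uniform, mean 50 g), at a randomized a.m./p.m. session, for a
  Gaussian-distributed number of days (24 ± 9).
* **Pup weights.**  Category means are the published summaries: birth
  164.9 g (treatment, i.e. pups of fed mothers) vs 142.0 g (control);
  315.5 vs 299.4 g in the 30–60 d stratum; 413.6 vs 420.8 g at 60–90 d
  (the categories converge — and slightly cross — by independence because
  control pups receive extra escorting).  Unmanipulated pups follow the
  control trajectory.  On top of the category mean, a pup's weight carries
  a communal-litter random effect (sd 15 g), a persistent within-litter
  residual (sd 12 g, consistent with a total birth-weight sd near 24 g as
  back-calculated from the published standard errors), and
  growth-stage noise (sd 10 g) accumulated between strata.  The paper does
  not state distributional families or variance components; these are
  truncated-Gaussian assumptions, fixed once and exposed in `SimConfig`.
* **Escorting.**  Days 30–90 are observed as 60 visits per attempt.  Each
  adult (attempt mothers plus 8 group males) escorts on a visit with
  probability 0.6 and pairs with at most one unclaimed pup.  Fed mothers
  choose pups with a log-odds bonus of 2.52 on control pups (the published
  allocation coefficient, adopted as the generative bias, not claimed as
  the fitted truth); non-fed mothers and males choose uniformly.  This
  yields the qualitative pattern that control pups receive more escorting
  overall.
* **Survival.**  Conditional Bernoulli per period (to 90, 180, 365 days;
  defaults 0.75/0.85/0.85) with category log-odds offsets defaulting to
  zero — survival is category-independent by construction, emulating the
  finding that extra postnatal care fully compensated the birth-weight
  disadvantage.
* **Maternal weights.**  Each mother gets a baseline record 67–74 days
  before birth (1100 ± 100 g) and later records whose percentage gains
  mirror the published means (pregnancy +24.1% fed vs +15.1% non-fed;
  post-pregnancy +4.36% vs −0.19%; escorting +3.33% vs −1.95%), with 15 g
  measurement noise.

**What the generator does not emulate:** spatial movement and foraging,
eviction and dispersal, infanticide, genetic parentage and relatedness
structure, pup begging dynamics, overdispersed count processes, and the
mixed-model error structure of the original analyses.  Tests that pass on
this generator therefore validate the statistical machinery and the
direction of the designed effects, not field realism.

## Inequality statistics

**Relative within-litter variance.**  For each communal litter (breeding
attempt) with at least four pups, the variance of pup weights within the
litter divided by the total variance of pup weights across all retained
litters.  Litters with fewer than four pups are excluded *before* any
variance is computed, so the denominator is taken over retained pups only
(an assumption; the convention is switchable).  Variances default to the
population convention (`ddof = 0`), pinned by the package's enumeration
oracle for the two-litter worked example; `ddof = 1` is available as a
switch.  The statistic is invariant under common rescaling of all weights.

**Maternal weight change.**  Percentage change from the pre-pregnancy
baseline (latest record 67–74 days before birth) to the latest record in
the phase window: pregnancy 5–30 days before birth, post-pregnancy 5–19
days after, escorting 30–90 days after.  Missing windows yield missing
values, never imputation.

**Exact Mann–Whitney.**  `U` counts pairs in which an `a` value exceeds a
`b` value (ties half).  With no ties and `n1 + n2 <= 12` the p-value is
computed by full enumeration of all `C(n1+n2, n1)` equally likely rank
labelings; the two-sided p doubles the smaller tail, capped at 1.  Larger
or tied samples use a tie-corrected, continuity-corrected normal
approximation and are flagged as such.  The enumeration's discreteness
makes the test conservative at nominal levels.

**Recovery report.**  Ties the simulator's configured effects back to
estimates: treatment−control gaps in birth and 60–90 d weight with
cluster-bootstrap percentile CIs (resampling whole litters, since litter
effects correlate pups), the escorting-received gap, survival proportions
per category, and the manipulated-vs-unmanipulated comparison of the
relative within-litter variance in both age strata (one-sided
Mann–Whitney, manipulated greater).  With the default variance components
the 30–60 d inequality elevation is modest (~1.3× within-litter variance),
so its *direction* (medians ordered) is recovered in the large majority of
replicates while replicate-level significance at 0.05 is not guaranteed —
a deliberate property of realistic noise levels, documented rather than
tuned away.

## Numerical conventions and problem sizes

* Floats are double precision throughout; effort optimisation uses the
  closed form where exact, otherwise `xatol = 1e-10`.
* Tie tolerance for boundary classification: `1e-9` on fitness
  differences.
* Kin threshold: scan step 0.01, bisection tolerance `1e-4`.
* Dyad variance: population (n = 2).  Litter statistic: `ddof = 0`
  default, switchable.
* The validation suite uses 1,000-draw property checks for the model
  oracles, 10,000 null simulations for the Mann–Whitney size check, and
  100 seeded study replicates (default configuration, ~350 pups each) for
  effect recovery; these sizes give Monte-Carlo error comfortably below
  the margins being asserted.

## Known limitations

* The game is strictly dyadic; communal litters with more than two
  mothers are represented only in the simulator, not the game.
* The veil weight `(1+r)/2` assumes exactly two equally likely parentage
  configurations; other information structures (partial cues, asymmetric
  litter shares) are out of scope.
* The generator's distributional families and variance components are
  assumptions constrained only by published means and standard errors;
  absolute inequality levels in simulated data should not be read as
  field predictions.
* The recovery report estimates direct contrasts with cluster bootstraps
  rather than refitting the original mixed-effects/Cox models.
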
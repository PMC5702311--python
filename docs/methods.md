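# Methods

## The problem

In-season athlete monitoring in field team sports (the motivating setting is
elite Australian football) produces two streams per player-week: external
load from GPS units (distances, high-velocity running, acceleration and
deceleration events, match work rate) and internal response from a wellness
questionnaire (12 items, 1–10 Likert). Performance staff want a single
weekly number — a *global load* — plus a family of derived measures, and an
answer to the dose–response question: how does a typical within-player
change in a training measure move match performance?

## Global load

The weekly global load is a weighted linear combination of eight inputs:

| input | weight |
|---|---|
| training total distance (m) | 1/100 |
| match total distance (m) | 1.5/100 |
| training high-velocity distance (>5.5 m·s⁻¹, m) | 1/20 |
| match high-velocity distance (m) | 1/10 |
| match work rate (m·min⁻¹) | 1/3 |
| match high accelerations (>3 m·s⁻², count) | 10 |
| match high decelerations (<−3 m·s⁻², count) | 20 |
| wellness total (points) | 3 |

The weights express the relative fatigue relevance each input was assigned
by practitioners; the result is in arbitrary units (a typical in-season week
scores ~450–600). The wellness weighting is implemented exactly as defined —
feeling better *raises* the load score — rather than "corrected"; the
measure is a practitioner construction, not a latent-fatigue model. All
weights are overridable in `LoadWeights`.

Match fields contribute zero in non-match weeks. A week with no recorded
sessions at all is flagged missing (NaN) and breaks the derived-measure
recurrences rather than being imputed as zero load.

## Derived measures

From each player's weekly series L_w we derive:

- **Rolling means** over 1, 3 and 4 trailing weeks (defined once the window
  is full; a gap voids any window containing it).
- **Smoothed load** S_w = λ·L_{w−1} + (1−λ)·S_{w−1}, an exponentially
  weighted rolling average with decay factor λ ∈ {0.67, 0.5, 0.33, 0.25}.
  The time constant is taken as **1/λ** weeks (1.5, 2, 3, 4), *not*
  (2−λ)/λ: 1/λ is the span after which the kernel has spent roughly two
  thirds of its weight, and it best aligns the smoothed load with the plain
  cumulative load of the same span. On the "roughly": counting the whole
  weeks inside the time constant, the kernel masses are 0.67, 0.75, 0.699
  and 0.684 for the four λ — all within 0.09 of 2/3, with λ = 0.5 the loose
  extreme at exactly 0.75 (a closed-form fact, tested as such).
- **Differential load** applies the same recurrence to the week-to-week
  change ΔL_w = L_w − L_{w−1}: a smoothed rate of change.
- **Monotony** = (3-week rolling mean) / (3-week sample SD, n−1 denominator)
  and **strain** = monotony × 3-week mean. These are weekly-grain variants
  of the classical daily measures; a sample SD is used because a population
  SD on 3-point windows would inflate monotony by √(3/2).
- **Acute:chronic ratio** = L_w / mean(L_{w−3..w}), with the *coupled*
  convention (current week inside the chronic window), following common
  practice.

Zero-SD monotony windows and zero chronic means are flagged missing, never
infinite, so they simply drop out of the model frames.

**Alignment.** The recurrences leave one genuinely open indexing choice: as
a predictor of week-w performance, the smoothed load uses loads only
through week w−1 (the literal recurrence above, `lag=1`) while the
differential load incorporates the change *into* the current week
(`lag=0`). Both alignments are implemented (`lag` argument); the defaults
follow the definitions as written. Recurrences are seeded with the first
observed value (`first_value` policy) so early-season weeks stay usable; a
`burn_in` policy that discards the first ⌈1/λ⌉ weeks is available. After a
gap the recurrence restarts from scratch — we prefer losing a transient to
fabricating load across bye/injury weeks.

## Within- and between-player SDs

The unit of a "1 SD" training change is the **within-player SD**: each
player's week-to-week SD pooled as √(Σ df·s² / Σ df), df-weighted. The
**true between-player SD** of a measure comes from a reliability mixed
model — fixed: linear seasonal trend and an injury/illness "problem" dummy;
random: player, match, match × problem — as the square root of the player
variance component. The team plays one match per week, so week index serves
as the match identity in that model.

## Dose–response model

For each measure × position group (defender, forward, midfielder, ruck —
modelled separately), match performance y (arbitrary-unit score) is fitted
with a quadratic mixed model. With x the measure centred at the
position-group mean:

  y = b0 + b1·x + b2·x² + c·matchtime + u_player + v_player·x + w_player·x² + ε

*Simple* variant: the above. *Complex* variant adds substituted-on/off
dummies (fixed) and a match random intercept. Estimation is REML via
statsmodels `MixedLM`; random-effect covariances are fixed at zero
(independent variance components — 3–13 players per position cannot
identify more), and crossed match effects use the standard single-group
variance-component encoding. Internally the measure is scaled to unit
variance for the optimiser and the coefficients are transformed back;
non-convergent fits are retried with the random quadratic, then the random
slopes, dropped, and the fallback is recorded. A single-player frame
degenerates to OLS by construction. Fits that still fail, or whose fixed
covariance is numerically indefinite, are excluded from reports and logged,
never silently patched.

The effect of a k-SD shift (k ∈ {−2, −1, +1, +2}) is the contrast

  delta(k) = b1·(k·s) + b2·(2·m·k·s + k²·s²)

with s the within-player SD and m the evaluation point on the centred scale
(zero at the position mean). Its 90% CL uses the (b1, b2) covariance block
and a t quantile with df = n_obs − n_fixed (the model's residual df are not
uniquely defined; this simple choice is configurable in spirit — it enters
only through the t quantile and is stated wherever reported).
`match_time_pct` enters raw (uncentred); its coefficient is reported but
not interpreted.

## Magnitude-based inference

Effects are standardised by the observed between-player SD of the
performance score averaged over positions (~25 units), classified as
trivial/small/moderate/large at 0.2/0.6/1.2/2.0, and judged against the
smallest important change SIC = 0.2 × 25 = **5 raw units**. From the 90% CL
we recover SE = CL/t₀.₉₅ and compute P(true effect > +SIC) and
P(true effect < −SIC) under the shifted t distribution (normal above
df = 100 to stabilise tails); the three probabilities (both tails plus the
trivial band) partition to 1 exactly. Qualifiers follow the 7-level scale
(<0.5% most unlikely … >99.5% most likely); an effect is *unclear* when
both substantial directions exceed 5%.

**Recommendations.** The reduce/no-change/increase column is produced by a
deterministic mapping from the ±1 SD effects: clear decrement above the
mean *and* clear benefit below → "Reduce by >1 SD"; clear decrement above
only → "Reduce by 0 to ~1 SD" or "Reduce by ~1 SD" depending on the sign of
the −1 SD point estimate; clear benefit above → "Increase by ~1 SD"; else
"No change" ("clear" here means the effect is not unclear and is at least
*possibly* substantial in that direction). This mapping reconstructs common
reporting practice; it is a design choice of this package, not a published
rule, and is deliberately easy to replace.

## Synthetic season generator

Real club monitoring data are proprietary, so the generator stands in with
a known-truth season: 13/13/6/3 players per position over 24 weeks; weekly
loads are player mean (position mean + N(0, 34) player offset) plus
within-player noise with position-specific SDs (541±138, 576±144, 560±135,
475±98); performance is position mean (65/68/101/80) + N(0, 25) player
intercept + a planted quadratic in the chosen measure + match residual
(27/28/27/21). Match participation probabilities (0.48/0.54/0.69/0.38)
reproduce realistic per-position observation counts (~150/170/100/30 over a
season). The default planted dose–response, in per-SD units, is
delta(k) = −3.5k − 3k²: an inverted U peaking ~0.58 SD below the mean with
a small decrement (−6.5) at +1 SD — the shape and size typical of in-season
load–performance relationships.

Each week's target load is decomposed into ledger fields *consistently with
the weights*: wellness items first, a fixed-template match share on match
weeks (counts rounded, continuous fields absorbing the remainder), training
distance absorbing the rest. Scoring the generated records therefore
recovers the target to ~1e−13 — the conservation contract the tests assert
at 1e−6. "Problem" weeks scale the training share by 0.5 and feed the
reliability model's dummy; targets are floored at 60 units (a wellness-only
week). Weekly noise is i.i.d. by default; an AR(1) switch (tests use
ρ = 0.3) adds the temporal structure without which smoothed/differential
measures carry no information beyond the weekly load. No within-season load
trend is generated by default.

What the generator does *not* emulate: autocorrelated wellness, periodised
load plans, opposition/fixture effects, true substitution or match-time
effects (those covariates are noise here), position switching, and any
dependence of the performance score's construction on load. Passing
recovery tests therefore show the estimator is faithful to *this* data
model, not that the pipeline's conclusions transfer to any particular club.

## Validation studies and sizes

`loadperf.validation` runs the pipeline end to end against the generator:
100 replicate seasons for ±1 SD effect recovery (mean error within 3
Monte-Carlo SEs; the truth is evaluated at each fit's own centring point,
since a quadratic's k-SD effect depends on where the shift starts), 100
null seasons for 90%-CI coverage (≥85% observed), and 50 seasons for the
headline shape (fitted curve peaking at ≤ +0.5 SD on a quarter-SD grid for
a majority of the three well-sampled positions; the ruck group, n = 3, is
reported with a small-sample warning but excluded from this check). These
sizes keep a full run in the low minutes on one core while leaving
Monte-Carlo error well below the effect sizes of interest.

## Known limitations

- `MixedLM` offers no native crossed random effects; the single-group
  encoding used for match effects is exact but slower, and the convergence
  flag at variance boundaries is conservative — estimates at the boundary
  (zero variance components) are legitimate and retained when flagged
  converged by any optimiser in the retry chain.
- The recommendation rule is a reconstruction (above).
- Monotony/strain on weekly data are non-standard variants of daily
  measures; their values are not comparable with the classical literature.
- The generator's load decomposition yields plausible but stylised session
  fields (e.g. match distances smaller than real AFL matches); only the
  weighted totals are calibrated.
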
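# Methods

This note documents the models implemented in `morus`, the provenance
and meaning of every default parameter, what the synthetic-data
generator does and does not emulate, and the numerical choices made.

## 1. Behaviour classification

Detection runs on per-sample centred running means and standard
deviations over 2 s windows, computed within recording segments only
(a time step of more than twice the nominal sampling interval opens a
new segment, so statistics never span logger dropouts). Running SDs are
population SDs over the window; at segment edges the largest available
symmetric window is used.

* **Dive start** — running mean of the surge (X) axis < 0 g *and*
  running SD of X > 1.4 g. A plunge drives the mean negative
  (head-down pitch) while impact and submerged motion drive the
  variance up; either condition alone fires on level flight or
  floating.
* **Dive end** — surfacing flips body pitch sharply, so the end is the
  extremum of |Δpitch| within 60 s of the start, plus a 1 s lag. Pitch
  is `arcsin(static_X / ‖static‖)` in degrees from the 2 s running
  means; Δpitch compares samples 1 s apart. Two conventions for
  applying the lag are implemented (`dive_end_mode="offset"` adds the
  lag to the extremum time; `"series"` maximises the lag-shifted
  series); they coincide whenever the extremum is unambiguous, and
  "offset" is the default.
* **Dive type** — dives shorter than 5 s are plunge dives (V-shaped,
  immediate surfacing); 5 s or longer are pursuit dives (underwater
  chase). The boundary goes to "pursuit".
* **Take-off** — begins after the dive where running SD of heave (Z)
  > 1.8 g and SD of X > 1.0 g (heavy flapping from the surface), and
  has ended once both fall below 1.4 g. A refractory rule suppresses
  new dive starts until the previous dive's take-off has ended, so a
  single plunge is never double-counted. A dive with no take-off
  within 120 s is flagged `no_takeoff` and its cost covers the dive
  alone.
* **TDR validation** — accelerometer dive starts are matched one-to-one
  to the times the depth trace first exceeds its trigger threshold
  (0.5 m or 1.0 m depending on tag set-up), greedily by increasing
  |offset| within ±5 s, after applying any per-bird clock offset.

## 2. Energetics

**VeDBA.** The static (gravity) component of each axis is its 2 s
running mean within segments; the dynamic component is raw minus
static; per-sample VeDBA is the Euclidean norm of the dynamic vector.
The per-second value is the sum of per-sample VeDBA divided by the
sampling rate (units g·s). Seconds with under half their samples
present are NaN; 24 h periods with under 95% coverage are dropped from
calibration.

**Calibration.** Two allometries anchor the conversion to kJ:

| quantity | form | defaults |
|---|---|---|
| BMR (kJ/day) | `a · mass_kg^b` | a = 381.8, b = 0.721 |
| FMR (kJ/day) | `10^(b0 + b1·log10(mass_g) + b2·abs(lat))` | b0 = 0.65, b1 = 0.71, b2 = 0.0087 |

Both are transcriptions from the seabird energetics literature (an
Ellis–Gabrielsen-type BMR allometry and a mass- plus latitude-corrected
seabird FMR allometry); they are configuration, not code, carry
provenance strings, and `AllometricParams.validate()` rejects
coefficient sets for which FMR does not exceed BMR across the adult
mass range. At 2.8 kg and 52° latitude the defaults give FMR ≈ 3540
kJ/day, consistent with tracked per-day expenditures in this system.

Activity energy expenditure is AEE = FMR − BMR. Assuming zero VeDBA
means zero locomotion energy, the per-bird gradient is the line through
the origin: k = AEE / mean(VeDBA24) in kJ per g·s, where VeDBA24 is
the VeDBA accumulated over a complete 24 h period. Any uniform
rescaling of the accumulation convention cancels through k, so all kJ
outputs are invariant to it (this is asserted to 1e-9 in the tests).
Birds with no complete 24 h period raise `NoCompleteDaysError` and are
excluded from energy analyses.

**Costs and demand.** The cost of one prey-capture attempt is k times
the VeDBA summed from dive start to take-off completion (pro-rated over
fractional seconds). Trip expenditure is k·ΣVeDBA plus BMR pro-rated
for fractional days. Total energetic demand adds the bird's share of
the daily energetic demand of a four-week-old chick (1397.14 kJ/day):
60% for females, 40% for males, reflecting unequal provisioning roles.
Birds of unknown sex cannot be assigned a share and are excluded.

**Minimum success rate.** If a successful dive yields one prey item of
expected assimilable energy KIV (see below), TED/KIV successful dives
are needed per trip — kept fractional, not rounded up, making the
figure a lower bound — and 100·(TED/KIV)/n_dives is the *minimum*
percent of dives that must succeed.

## 3. Isotope mixing model

For consumer group g and isotope j (δ¹³C, δ¹⁵N):

    x ~ Normal( Σᵢ p_gi (μᵢⱼ + λⱼ),
                sqrt( Σᵢ p_gi² (σᵢⱼ² + τⱼ²) + ξⱼ² ) )

with source means μ ± σ, diet-to-tissue discrimination factors λ ± τ
(piscivorous-bird defaults: δ¹³C 0.24 ± 0.79‰, δ¹⁵N 2.25 ± 0.61‰), a
flat Dirichlet(1,…,1) prior on each proportion vector (sampled through
an additive-log-ratio transform whose Jacobian is Π pᵢ), and a
half-normal(5‰) prior on the residual SDs ξ (sampled as log ξ).
Covariate structure is fixed grouping: a separate p per sex, year, or
sex-by-year cell.

Sampling uses the emcee affine-invariant ensemble sampler (16 walkers,
1100 steps, 400 discarded, thinned by 2, vectorised log-probability).
Three independently seeded ensembles play the role of chains for the
classic Gelman–Rubin potential scale reduction factor, computed on the
natural-scale parameters; any PSRF > 1.05 flags (not raises)
non-convergence. These sampler defaults are sized for the ~30–60
consumer problems this package targets and take about two seconds per
fit.

Candidate groupings are compared by WAIC computed from the pointwise
log-likelihood — used as a leave-one-out cross-validation surrogate
(same asymptotic target, no importance-sampling machinery) — with
standard errors, pairwise ΔSEs, and weights ∝ exp(−Δ/2). Pointwise
terms are aligned across models by consumer id, and fitting different
consumers is an error.

Pre-processing: δ¹³C is lipid-normalised by `d13C − 3.32 + 0.99·C:N`
whenever C:N > 3.5 (the common linear normalisation for fish tissue);
candidate sources must exceed 3% (strictly) of the historical reference
diet, and fewer than two surviving sources is rejected as
unidentifiable.

**KIV.** The kilojoule intake value of one capture is
Σᵢ pᵢ·gross_kJᵢ·0.761 at the default 76.1% assimilation efficiency.

## 4. Statistical layer

* Mann–Whitney rank test: exact permutation null when min(n) ≤ 8 and no
  ties, normal approximation otherwise; rank-biserial effect size
  r = 1 − 2U/(n₁n₂). Exactness is tested against full enumeration.
* Welch t-test with the usual fractional df.
* Per-dive cost: linear mixed model with a random intercept per bird,
  fitted by maximum likelihood (not REML) so AICs are comparable across
  fixed-effect structures; AIC counts fixed effects plus the
  random-effect and residual variances. All fixed-effect subsets of
  {year, sex, mass, type, sex:type} respecting marginality are
  enumerated; candidates within 6 AIC units of the best are retained
  and conditionally averaged with renormalised Akaike weights, the
  adjusted SE folding between-model coefficient spread into the
  within-model SE (full-average mode available by flag).
* Dive rate: one-way linear model F-test of sex.

## 5. Synthetic-data generator

The deployment generator emits regime-structured 50 Hz traces — rest,
flapping flight, dive, take-off — plus a trigger-gated 4 Hz depth trace
and the ground-truth event log. Structural parameters follow the study
system: sex-specific dive rates near 26 (female) and 17 (male) per day,
a 24% pursuit fraction, lognormal dive durations with modes at 2.4 s
(plunge, clipped to 1.4–3.4 s) and 8 s (pursuit, clipped to 6–16 s)
straddling the 5 s split, female masses 2.99 ± 0.15 kg against male
2.70 ± 0.19 kg, and 40% females. Dives are scheduled with Dirichlet
slack between minimum 45 s gaps inside flight bouts.

Per-regime amplitude statistics are synthetic: no per-regime amplitude
data exist for free-ranging birds of this kind, so levels are chosen to
sit clearly on the correct side of the classification thresholds while
staying physically plausible — e.g. dive posture static X of −0.5 g
(about 30° head-down) against per-sample surge noise of 1.6 g, and a
surfacing overshoot (static X 0.9 g for 1 s, decaying over 6 s) that
produces the pitch-change extremum the dive-end rule keys on. The −0.5 g
posture leaves ≈ 2.8 standard errors of margin on the mean-below-zero
gate for the shortest plunges; a shallower posture was found to lose
~2% of 2 s plunges to noise fluctuations. Randomness is reproducible
and order-independent: each bird draws from a substream keyed by the
global seed and a stable hash of its ID.

The generator does **not** emulate sensor drift or calibration error,
tag-orientation changes, swimming/floating locomotion between dives,
depth-sensor noise, or broken dive–take-off pairing (every dive is
followed by exactly one take-off).

The isotope generator draws consumers from the mixing model's own
likelihood collapsed over its uncertainties, with known per-group
proportions — so posterior recovery is a well-posed check.

## 6. Numerical choices and problem sizes

* Running statistics use cumulative sums (O(n)); the subtraction incurs
  ~1e-7 g cancellation noise in the SD, negligible against 1.4 g
  thresholds, and edge single-sample windows are clamped at zero
  variance.
* Deterministic seeding throughout: `numpy.random.default_rng` with
  structured seed sequences; the emcee initial state is seeded from the
  same stream.
* Test problem sizes are scaled to the suite's time budget as a package
  choice: classifier recovery runs twenty 0.3-day deployments
  (~130 dives) rather than multi-day ones, and calibration checks use
  1.0-day deployments (one complete 24 h period). The statistics being
  checked (recall, precision, type agreement, round-trip error) do not
  depend on deployment length beyond the number of dives observed.
* Reference-table reconstruction is checked to within one unit in the
  last printed decimal place, the correct tolerance for values that
  were themselves rounded for printing (derived columns recomputed from
  rounded inputs can differ by up to ~0.005 from the printed derived
  values).
* The per-bird reference table keeps the printed per-day columns
  (dives/day, TED/day) as inputs where available: those were computed
  from unrounded tracking durations upstream, and recomputing them from
  the rounded durations printed alongside would add avoidable rounding
  error to the sex-level means.

## 7. Limitations

* The allometric coefficients are literature transcriptions; for other
  systems they must be re-derived from the cited allometry families.
* The VeDBA→kJ line through the origin assumes all above-basal
  expenditure scales with VeDBA; thermoregulation in water is not
  separated out.
* "One prey item per successful dive" makes KIV, and therefore the
  success rates, conservative lower bounds.
* The mixing model treats discrimination factors as mean shifts with
  additive variance rather than as per-consumer latent variables.
* Fixed-group diet covariates (separate simplex per cell) rather than
  continuous-effect mixing regressions.
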
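# Methods

## Model

The model is an open-population compartmental chain. A fixed population
`Z1` (62,262,100; the 2010 UK estimate) generates `N = Γ·Z1` incident GIST
cases per year. A proportion `p` is resectable and enters the
post-resection recurrence-free state `z2`; the remainder enters the
imatinib state `z3` directly. Progression moves patients sequentially
`z2 → z3 → z4 → z5` (relapse, imatinib failure, sunitinib failure); the
exit from the third-line state `z5` is death, and every state also loses
occupants to background mortality `μ`. There is no cure exit and no
treatment-line skipping; adjuvant/neoadjuvant pathways are out of scope.

All waiting times are exponential: a published median of `m` years becomes
a rate `ln(2)/m` per year. "Time to transition" (TTT) for a state is the
whole time until the next line starts, including any gap after failure, so
progression-free-survival-type medians are the natural inputs.

### Difference equations

The model advances in annual steps. Every rate `r` is first converted to
an annual probability `q(r) = 1 − exp(−r)`; competing exits from a state
(progression and background death) use additive probabilities
`q(γk) + q(μ)`. The probability conversion is not cosmetic: the sunitinib
state has `γ4 + μ ≈ 1.005` per year, so a naive rate-based update would
drain more than the state holds. With probabilities, occupancies stay
nonnegative for any nonnegative rates, and new entrants each year equal
the change in total occupancy plus deaths, exactly (asserted per step in
the tests).

An alternative competing-risk formulation — convert the combined rate and
apportion it proportionally (`exit_mode="apportioned"`) — is provided.
Measured against the additive default it shifts equilibrium counts by
2–7% and reproduces the published scenario counts less well, so additive
is the default.

### Equilibrium

Reported outcomes are the fixed point of the update (the published
prevalences are time-invariant). The iterated solver starts from an empty
population and stops when the largest yearly change falls below 1e-6
persons (cap 10,000 iterations; the spectral radius of the linear update
is below 1, so convergence is geometric and the cap is unreachable in
practice — non-convergence is flagged, never silent). Because the chain is
linear in its single source, the fixed point also has a sequential closed
form (each state's inflow divided by its total exit probability); the two
agree to solver tolerance on 1,000 random parameter sets in the acceptance
suite, and the closed form is used wherever many equilibria are needed
(PSA, tornado, thresholds). A transient mode (`run_transient`) exists for
exploration — e.g. build-up since imatinib's 2001 introduction — but is
not the reporting mode.

## Parameters

| name | meaning | base (SE) | min–max | family |
|---|---|---|---|---|
| `incidence` (Γ) | GIST incidence, per person-year | 1.053e-5 (1.39e-6) | 0.52e-5–1.50e-5 | gamma |
| `p_resectable` (p) | resectable fraction at diagnosis | 0.8 (0.05) | 0.50–0.90 | beta |
| `relapse_rate` (γ2) | post-resection relapse, /y | 0.0464 (0.0025) | 0.029–0.186 | gamma |
| `imatinib_failure_rate` (γ3) | imatinib TTT, /y | 0.351 (0.103) | 0.205–0.645 | gamma |
| `sunitinib_failure_rate` (γ4) | sunitinib TTT, /y | 0.974 (0.085) | 0.533–1.435 | gamma |
| `thirdline_exit_rate` (γ5) | third-line survival, /y | 0.904 (0.10) | 0.439–1.066 | gamma |
| `background_mortality` (μ) | all-cause mortality, /y | 0.0314 (0.0023) | 0.0269–0.0359 | gamma |

The packaged defaults (`data/table1.yml`) carry these values; any YAML
file with the same schema can replace them. The base-case `γ5 = 0.904` is
kept as printed even though the quoted 0.77-year median implies 0.9002 —
a 0.4% discrepancy we document rather than resolve. Scenario survival
values are entered as medians (0.77 y, 1.5 y) and converted.

Two upstream computations produce the data-derived parameters:

- **Direct standardization** of age/sex-stratified registry counts:
  `Σ wᵢ·(casesᵢ/person-yearsᵢ)` with reference-population weights `wᵢ` —
  the standard direct method, exercised on synthetic registry fixtures.
- **Weighted background mortality**: life-table annual death
  probabilities are converted to rates (`−ln(1−q)`) and averaged under
  the patient age distribution. Weighting on the rate scale (rather than
  the probability scale) changes the result by <0.1% at these magnitudes
  but composes correctly with the disease-exit rates.

## Uncertainty analysis

**One-way (tornado):** each parameter is moved to its min and max with the
others at base; the outcome is equilibrium third-line prevalence per
100,000, and entries are sorted by swing. Incidence and third-line
survival dominate; the imatinib/sunitinib rates matter least (their effect
on `z5` largely cancels: a faster failure rate feeds the next state faster
but holds fewer patients).

**PSA:** all seven parameters are sampled jointly and independently, 5,000
draws by default. Distributions are method-of-moments matched to (base,
SE): gamma with `shape=(mean/se)²`, `scale=se²/mean` for positive rates;
beta with `ν=mean(1−mean)/se²−1`, `α=mean·ν`, `β=(1−mean)·ν` for the
resectable proportion. No correlation structure is imposed (none is
known). Summaries are percentile 95% credibility intervals (2.5/97.5, no
smoothing) and two threshold probabilities: third-line prevalence below
the ultra-orphan 2/100,000, and total GIST prevalence below the orphan
50/100,000. Draws are made in a fixed parameter order from a
`numpy.random.Generator`, so a given seed is bit-reproducible; the default
seed is 20140524.

**Scenarios:** base case; incidence 1.5/100,000 p-y; third-line median
survival 1.5 y; both. In a scenario's PSA the overridden parameter is, by
default, *recentred*: resampled around its scenario value with its
original SE (`psa_mode="recenter"`). The alternative — pinning it while
sampling the rest (`psa_mode="fix"`) — is available but not default,
because pinning collapses exactly the uncertainty the extreme scenarios
are meant to stress: with the two dominant parameters fixed, the
scenario-3 credibility interval shrinks to ±10% and the probability of
staying below 2/100,000 falls to ~9%, implausibly certain for a
what-if analysis; recentring keeps scenario intervals commensurate with
the base case (~33% under scenario 3).

**Threshold analysis:** the incidence threshold uses exact linearity of
equilibrium counts in Γ (`Γ* = Γ·target/prevalence`), with a bisection
cross-check; the third-line threshold brackets and root-finds the exit
rate (Brent's method, re-evaluated to 1e-6 per-100,000), reporting the
rate and its implied median `ln(2)/γ5*`. Prevalence *falls* as the exit
rate rises, so the boundary is exceeded for rates at or **below** the
threshold rate — equivalently for median survival at or above the implied
median (~2.15 years at base case). Targets outside the attainable range
(the prevalence limits as the rate tends to 0 or ∞) raise an error naming
that bound.

## Synthetic data

The registry extract and national life tables behind the incidence and
mortality parameters are not shipped; `gistprev.synthetic` generates
stand-ins so the standardization and weighting code paths are fully
testable:

- stratified incidence: Poisson counts over 1.25M person-years per
  stratum (nine 10-year age bands × two sexes, a registry-sized
  exposure), rates rising log-linearly with age (×1.6 per band) with a
  mild male excess, calibrated so the direct-standardized rate is
  unbiased for 1.053e-5;
- life table: geometric (Gompertz-like, ×2 per band) mortality schedule
  and a patient age distribution centred in the late 60s, calibrated so
  the weighted mortality centres on 0.0314/y with 2% lognormal jitter —
  landing inside the published 0.0269–0.0359 range for every seed tested;
- random parameter sets drawn uniformly within the one-way ranges, for
  property tests.

These fixtures emulate aggregate registry shape, not real data: no
secular trends, no band-width irregularities, no registration delay or
coding incompleteness. A green round-trip test establishes that the
pipeline recovers a generator's truth, not that the published incidence
is correct.

## Known limitations

- The exact published difference-equation conventions are not fully
  recoverable; this reconstruction matches published scenario counts to
  ~0.1–2% and the base-case imatinib count to ~5%, and inherits that
  offset in the scenario-3 threshold probability (~32% vs 37.9%).
- Equilibrium reporting assumes the treatment pathway has reached steady
  state; prevalence is overestimated during the build-up years after a
  new line is introduced (use `run_transient` to see the approach).
- Pooled, homogeneous patient groups: no prognostic subgroups, no
  treatment skipping, no cure exit.
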
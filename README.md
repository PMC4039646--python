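# gistprev

An open-population, multi-state prevalence model for unresectable/metastatic
gastrointestinal stromal tumour (GIST) in the UK, by treatment line.

GIST is a rare GI-tract tumour. Patients whose disease cannot be cured by
resection receive first-line imatinib, then second-line sunitinib; those who
fail both are "third-line treatment-eligible". Whether that third-line
population sits below the NICE ultra-orphan boundary (prevalence < 2 per
100,000) matters for drug-funding policy, and no registry measures it
directly. This package estimates it with a compartmental model, together
with the uncertainty and threshold analyses needed to judge how robust the
answer is. It is aimed at health-economics and epidemiology analysts.

## The model

The UK population `Z1` feeds four living states through annual difference
equations:

- `z2` — resected, recurrence-free,
- `z3` — on imatinib, progression-free,
- `z4` — on sunitinib, progression-free,
- `z5` — third-line treatment-eligible.

Each year `N = Γ·Z1` new cases enter: a proportion `p` is resectable (into
`z2`), the rest unresectable/metastatic at diagnosis (directly into `z3`).
State `k` loses occupants to disease progression at annual rate `γk`
(flowing to state `k+1`; the `z5` exit is death) and to background mortality
at rate `μ`. All time-to-event quantities are exponential, so a median
survival `m` maps to a rate `ln(2)/m`, and rates are converted to annual
probabilities `q = 1 − exp(−rate)` before each update, which keeps the
equations stable and occupancies nonnegative. Prevalence at each line is the
fixed point of the update; because the chain is linear in its single source,
the fixed point also has a sequential closed form

```
z2 = p·N / (q(γ2)+q(μ))          z4 = z3·q(γ3) / (q(γ4)+q(μ))
z3 = ((1−p)·N + z2·q(γ2)) / (q(γ3)+q(μ))   z5 = z4·q(γ4) / (q(γ5)+q(μ))
```

used throughout as a fast, property-tested equivalent of the iterated
solver.

On top sit: probabilistic sensitivity analysis (PSA; 5,000 joint draws,
gamma for rates moment-matched to each parameter's mean and SE, beta for
`p`, percentile credibility intervals, threshold probabilities), one-way
(tornado) sensitivity analysis over min–max ranges, scenario analysis,
and threshold analysis against the 2/100,000 boundary.

## Worked example

```python
from gistprev import *

table = default_parameter_table()          # UK base case
params = parameter_set_from_table(table)   # Z1 = 62,262,100
out = outcomes(closed_form_equilibrium(params), params)
res = run_psa(params, table)               # 5,000 draws, fixed default seed
```

This prints (via the `gistprev run` / `gistprev psa` CLI, or formatted by
hand):

```
third-line count 610  prev 0.98/100k
total count 9458  prev 15.19/100k
imatinib 1355  sunitinib 614
95% CrI third-line prev: 0.71-1.33
P(below ultra-orphan 2/100k) = 100.0%
threshold incidence 2.15/100k p-y; threshold rate 0.323/y (median 2.15 y)
```

Reading: at equilibrium about 610 UK patients (0.98 per 100,000) are
third-line treatment-eligible — far below the ultra-orphan boundary, and
essentially all PSA draws agree. Incidence would have to reach ~2.15 per
100,000 person-years, or median third-line survival ~2.15 years (exit rate
at or below 0.323/y), before the boundary is crossed.

The command line mirrors the library: `gistprev run | psa | sa | threshold |
table2 | synth | transient` (see `gistprev --help`). `table2` reproduces the
full scenario table (base case, higher incidence 1.5/100,000, longer
third-line survival 1.5 y, and both combined), each with credibility
intervals and the probability of staying below 2/100,000.

## Acceptance script

`scripts/acceptance.py` recomputes the headline outputs from scratch — the
base-case and scenario-2 equilibrium counts and prevalences, the four
scenario PSA threshold probabilities (5,000 draws each), and both threshold
analyses — and writes them as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `gistprev.parameters` — parameter containers, unit conversions,
  gamma/beta moment matching, direct standardization of stratified
  incidence and patient-age-weighted background mortality.
- `gistprev.model` — difference equations, equilibrium (iterated and
  closed-form), transient runs, outcome mapping.
- `gistprev.uncertainty` — one-way/tornado analysis and PSA.
- `gistprev.threshold` — threshold incidence and third-line exit rate.
- `gistprev.scenarios` — built-in scenarios and the results table.
- `gistprev.synthetic` — synthetic registry strata, life tables and random
  parameter sets for tests.

See `docs/methods.md` for the modelling assumptions, parameter meanings and
numerical choices.
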
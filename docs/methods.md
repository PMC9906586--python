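# Methods

## The SIM composite

Self-injury mortality merges all registered suicides (ICD-10 underlying
cause U03, X60–X84, Y87.0, at any age and regardless of the certified
manner field) with 80% of drug-intoxication deaths certified as accidents
(X40–X45) and 90% of those of undetermined intent (Y10–Y15), the latter
two restricted to decedents aged 15 and older.  The fractions discount
the minority of overdose deaths not attributable to repetitive self-harm;
the age cutoff reflects the rarity of purposive self-harm among children
and younger adolescents.

Implementation choices:

* **Deterministic weighting.** Fractions multiply expected (real-valued)
  counts; no individual deaths are sampled.  Weight-then-average and
  average-then-weight commute (the weights are linear) and are tested to.
* **Age cutoff by band lower bound.** The WONDER 5-year bands align with
  the cutoff, so "15–19" is the first included band.  Unknown-age records
  count toward the suicide component (any age) but are excluded from the
  age-restricted drug components — unless the cutoff is set to 0, in
  which case the components are unrestricted and unknown ages count, so
  the all-weights-1/cutoff-0 configuration reduces exactly to the raw
  code-set count.
* **Intent lives in the code for drug poisonings.** X40–X45 count only
  when the manner field says accident; Y10–Y15 carry undetermined intent
  in the code itself.  Suicide codes dominate a discordant manner field.
* **Two-year annual averaging** (arithmetic mean of adjacent years)
  stabilizes small-jurisdiction values; crude rates divide the averaged
  count by the averaged population × 100,000.

## Cost model

All costs are expressed in base-year (default 2019) dollars via a price
index; totals are exact component sums at full precision, and rounding
(rates to 0.1, ratios and percent changes to integers with halves away
from zero, per-capita to whole dollars, cost components to 0.1 million)
happens only at display.

**Medical.** A unit cost by place of death and injury mechanism (with
`*` wildcards for sparse tables), plus emergency transport for every
death except those on scene/at home, plus coroner/medical-examiner cost
for autopsied deaths.  Aggregate inputs carry no autopsy flag, so
aggregate mode applies an expected autopsy fraction, and the place and
mechanism distribution per cause class is supplied as a profile mix.
The facility-level unit costs behind the published totals are not
public; the repository ships synthetic unit costs of plausible magnitude
(generated by `synth.generate_parameter_bundle`, labelled synthetic) for
testing only.  Consequently the published absolute dollar totals are not
independently recomputable here — they are covered through fixture
arithmetic (ratios, shares, changes) instead.

**Work loss (human capital).** Present value of wages + fringe benefits
+ household-work value over the decedent's counterfactual remaining life
span:

    WL(sex, a) = Σ_{k≥0} S(a → a+k+1) · E(sex, a+k) · (1+r)^−k

where `S` is the cumulative product of one-year life-table survival
probabilities and `E` the average annual earnings of the age band
containing the single year of age.  Average earnings implicitly fold in
employment probability and hours, so zeros are valid.  The k-th remaining
year counts when it is lived through; year 0 is undiscounted and year k
is discounted by `(1+r)^−k` at the default 3% annual rate.  This
convention was chosen because it simultaneously satisfies (i) survival
weighting "from each year of age to the next", (ii) zero loss for a
hypothetical decedent with no survivable years, and (iii) the exact
decomposition identity below; the discounting convention is isolated in
one helper so a mid-year alternative is a one-line change.

**Quality-of-life loss.** VSL (default $10.7M, the value used in US
federal regulatory analysis) minus the sex-averaged lifetime work loss at
birth gives the average lifetime quality-of-life value; dividing by life
expectancy at birth annualizes it.  Each death is then assigned

    QoL(sex, a) = q · [(VSL − WL̄(0)) / e₀] · Σ_{k≥0} S(a → a+k+1)(1+r)^−k

with `q = 0.80` reflecting the reduced baseline quality of life of the
decedent population (substance-use and mood disorders).  Life expectancy
is the curtate expectation `e(a) = Σ_{k≥1} S(a→a+k)` — about half a year
below the demographic complete expectation — which makes the identity

    WL̄(0) + QoL̄(0) = VSL     (at q = 1, r = 0)

hold exactly; it is asserted to 1e-12 relative tolerance in the tests.
Whether the published model tailored the per-year value beyond the
survival stream is not documented; this package applies the
survival-weighted stream only.

Sex weights for the population average default to 0.5/0.5 and are
configurable.  Age bands map to a representative single age (band
midpoint; 87 for 85+) for per-death lookups.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| suicide / accident / undetermined weights | 1.0 / 0.80 / 0.90 | fraction | SIM composite |
| drug-component age cutoff | 15 | years | SIM composite |
| VSL | 10,700,000 | 2019 $ | QoL valuation |
| QoL fraction | 0.80 | fraction | decedent-population discount |
| discount rate | 0.03 | 1/year | present-value streams |
| base year | 2019 | — | price level |
| autopsy fraction | 0.92 (synthetic) | fraction | aggregate medical cost |

## Reporting conventions

Percent changes, ratios and per-capita displays use round-half-away-from-
zero; this reproduces every printed cell that is reproducible (see
Limitations).  National rows are computed from national totals, never by
summing display-rounded state rows.  Rankings sort descending with
alphabetical tie-break.  Quintiles over the 51 jurisdictions take sizes
(11, 10, 10, 10, 10) from the top; ties straddling a boundary share the
better quintile and the shortfall comes out of the bottom.  The published
narrative thresholds (e.g. a top-quintile floor "exceeding 152%") are
inconsistent with equal-size quintiles on the printed data — 12
jurisdictions exceed 152% — so the deterministic size rule above is used
and the realized thresholds are emitted as output rather than hard-coded.
The BEA eight-region map ships as an editable data fixture.

## Synthetic data

The generator emulates the structure of a national underlying-cause
extract: 50 states + DC (or arbitrary jurisdictions), two-year periods,
the three SIM code sets plus noise codes (including a drug code with a
non-qualifying manner to exercise the classifier), 5-year age bands, both
sexes.  Counts are Poisson with mean `rate × state multiplier × period
multiplier × population / 100,000`, thinned over a fixed within-class
code mix (thinned Poissons are again Poisson, so the analytic ground
truth is exact); a negative-binomial option adds overdispersion for
robustness checks.  The `paper_like` preset fixes the study conditions:
periods 1999/2000 and 2018/2019, populations implied by the fixtures'
printed counts and rates, suicide rates rising 1.4× between periods and
drug-poisoning rates 2.5×, which shifts the composite toward the drug
components as observed.  Age/sex rate profiles are stylized (male-heavy
suicide rising through midlife and old age; drug deaths peaking at 25–54).

What the generator does **not** emulate: real state-specific
epidemiology beyond scalar multipliers, within-period trends, race/
ethnicity structure, cell suppression, or correlated errors between
causes.  Passing recovery tests therefore demonstrate that the pipeline
is an unbiased, correctly-plumbed estimator of its inputs — not that the
synthetic unit costs match real medical spending.

Monte-Carlo scale: the recovery tests run 200 replicates of the full
national scenario per period (the acceptance script runs 100), which
keeps the whole suite around half a minute while giving standard errors
near 0.1% of the national totals; means are required to fall within 3
Monte-Carlo standard errors of the analytic truth.

## Numerical choices and degenerate inputs

* Monetary values are double precision throughout; parameter-bundle CSVs
  are written at 17 significant digits and parsed with round-trip float
  precision, so save/load is bit-exact.
* Life tables must close (`p(max_age) = 0`); ages beyond the table raise.
* Zero population, zero medical spending (for ratios), zero start values
  (for percent change), empty composites (for shares) and unnormalized
  profile mixes all raise rather than returning sentinel values.
* Suppressed export cells default to drop-with-logged-warning;
  state-level counts in this domain exceed suppression thresholds, so the
  policy is exercised only by synthetic tests.
* Unknown bundle-config keys are rejected (strict schema, version 1).

## Known limitations

* **Five irreproducible percent-change cells.** Of the 102 published
  state × measure percent-change cells, 97 are reproduced exactly from
  the printed per-capita values.  The remaining five (Arkansas, Maryland,
  New York and Ohio for suicide; Virginia for SIM) differ by one integer
  point in directions that no deterministic rounding of the printed
  inputs can produce (e.g. 41.51 printed as 41 but 17.53 printed as 18):
  the source evidently computed changes from unrounded per-capita
  internals that are not recoverable at printed precision.  The
  corresponding acceptance tests are left failing by design, one per
  cell.  Two published component ratios (1,476 and 526 for SIM
  2018/2019) are similarly reproducible only to ±1 from display-rounded
  components and are tested at that tolerance; the same applies to the
  published 526 work/medical ratio for SIM 1999/2000, which recomputes
  to 527, and the 143% total-cost rise, which recomputes to 144% from
  the full-precision table totals.
* One printed row (Alabama, suicide 2018/2019) has components summing
  0.5M off its printed total — beyond the footnoted 0.2M rounding slack —
  and is carried verbatim with the discrepancy documented in the fixture
  test.
* Absolute dollar magnitudes depend on non-public unit-cost inputs (see
  above); no uncertainty intervals are produced (none exist for the
  published estimates either).
* Only underlying-cause, state-level aggregates are supported: no
  multiple-cause records, no race/ethnicity stratification, no microdata.
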
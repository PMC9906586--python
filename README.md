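# simcost

Self-injury mortality (SIM) measurement and societal cost estimation over
state-level underlying-cause-of-death aggregates.

## The problem

Suicide statistics miss most drug-intoxication deaths: medical examiners
and coroners classify the great majority of fatal overdoses as accidents
or as undetermined intent, even though they arise from repetitive
self-harming behavior. **Self-injury mortality (SIM)** is a composite
measure built for surveillance of the combined epidemic:

```
SIM = suicides (ICD-10 U03, X60–X84, Y87.0; any age)
    + 0.80 × accidental drug poisonings (X40–X45; ages 15+)
    + 0.90 × undetermined-intent drug poisonings (Y10–Y15; ages 15+)
```

The package operationalizes SIM on CDC WONDER-style mortality exports and
attaches societal costs per death in the style of CDC's fatal-injury cost
framework, extended with a value-per-statistical-life (VSL) monetization
of lost quality of life:

* **medical** — unit cost by place of death (scene/home, dead on arrival,
  emergency department, inpatient, nursing home, hospice) plus emergency
  transport (except scene/home deaths) plus coroner/medical-examiner cost
  when autopsied;
* **work loss** — human-capital present value
  `Σₖ S(a→a+k+1) · E(a+k) · (1+r)⁻ᵏ` of wages, fringe benefits and
  household work over the decedent's remaining life span, survival-weighted
  from a life table and discounted at `r = 3%`;
* **quality-of-life loss** — `(VSL − average lifetime work loss) / e₀`
  dollars per life year (VSL = $10.7M), streamed over the decedent's
  survival-weighted remaining years, discounted, and taken at 80% of the
  average person's loss.

It ships the published national/state summary tables for 1999/2000 and
2018/2019 as machine-readable fixtures, a reporting layer (per-capita
costs, percent changes, component ratios, composition shares, rankings,
quintiles, BEA regions), and a synthetic-data generator with analytic
ground truth so the full pipeline is testable without any download.

Intended users: injury epidemiologists and health economists who need
reproducible state-level cost-of-self-injury estimates, and anyone
auditing or extending the SIM cost methodology.

## Worked example

Generate a small synthetic scenario, count SIM, and cost it:

```bash
simcost simulate demo --preset small --seed 3
simcost cost --deaths demo/deaths_1999_2000.tsv \
             --population demo/population_1999_2000.tsv \
             --params demo/params --period 1999-2000
```

```
 jurisdiction  count  rate  total_millions  per_capita
        Alpha  247.8  20.6           773.7         645
         Beta  674.3  16.9          2105.8         526
        Gamma   78.5  13.1           247.1         412
UNITED STATES 1000.6  17.3          3126.7         539
```

`count` is the annual-averaged weighted SIM death count, `rate` the crude
rate per 100,000, `total_millions` the summed medical + work-loss +
quality-of-life cost in millions of 2019 dollars, and `per_capita` that
total divided by population.  The same operations are available as
library functions:

```python
import simcost as sc

sc.classify_cause("X42", "accident")      # unintentional_drug_poisoning
sc.percent_change(1638, 3413)             # 108  (national SIM per-capita rise)
t3 = sc.load_paper_fixture("T3").loc["UNITED STATES"]
sc.component_ratio(t3["qol_loss"], t3["medical"])   # 1489
```

Replaying the embedded fixtures reproduces the published headline
numbers: the 58% rise in national suicide costs, the 112% and 40% rises
in crude SIM and suicide rates, per-capita changes of 108% (US SIM), 35%
(US suicide), 263% (West Virginia) and 22% (Nevada), and the decline of
the suicide share of SIM from 71.7% to 47.3%.

Note the absolute dollar totals in the fixtures are **not**
independently recomputable: the facility-level unit medical costs behind
them are not public, so the cost engine ships clearly-labelled synthetic
unit costs for testing, and all fixture checks work through ratios,
shares and changes.

## Layout

```
src/simcost/
  types.py      domain types: strata, weighted counts, cost breakdowns
  sim.py        the SIM composite: classification, weights, averaging
  costs.py      cost engine: life tables, earnings, medical, VSL/QoL
  params_io.py  cost-parameter bundle schema (YAML + CSVs)
  wonder.py     WONDER-dialect export parsing and table writing
  fixtures.py   published Tables 1–5 + BEA region map as package data
  report.py     per-capita, changes, ratios, ranks, quintiles, regions
  synth.py      synthetic scenarios with analytic ground truth
  cli.py        `simcost` command-line interface
docs/methods.md methods note: model, conventions, limitations
```
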
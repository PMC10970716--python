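# formulary-impact

How many patients does a pharmacy formulary exclusion hurt? When a pharmacy
benefit manager (PBM) drops a medication from its national formulary, every
covered patient on that drug must switch to a different active ingredient or
stop treatment, and a predictable fraction of them will discontinue therapy
or suffer adverse events. `formulary-impact` is a deterministic
burden-of-disease cascade that turns published inputs — population coverage,
disease prevalence, formulary and medication market shares, and outcome
rates from the nonmedical-switching literature — into bounded low/high
estimates of patients affected, patients discontinuing, and patients with
adverse events. It is written for health-policy analysts and
pharmacoepidemiologists who want these estimates reproducible, testable and
re-runnable with their own inputs.

## The model

For a medication *d* excluded from formulary *F*:

```
affected        A = L · p · Πf · κ · m_F · m_d      (thousands of persons)
discontinue     D = A · d
adverse events  E = A · r,   r = rate  or  r = e·d + s·(1 − d)
```

with `L` the covered lives (population × Σ insured-segment percentages),
`p` the indication prevalence, `Πf` eligibility factors, `κ` an explicit
calibration factor, `m_F` and `m_d` the formulary and medication market
shares, `d` the discontinuation rate, and the compound adverse-event rule
adding events among discontinuers (`e`) to events among switchers (`s`).
Every ranged input is a low/high pair, and each output bound evaluates all
inputs at the corresponding bound simultaneously (*coupled scenarios* —
including the complement `1 − d`, taken at the same scenario's `d`). A
corner-enumeration *conservative envelope* is available as an alternative
mode. See `docs/methods.md` for the full treatment.

Three complete case studies ship as fixtures — anticoagulants (AFib/VTE),
CGRP-blocking migraine preventives, and antipsoriatics — together with the
corresponding published reference tables, including flagged errata.

## Worked example

```
$ formulary-impact run --fixture anticoagulants
### CVS — anticoagulants (thousands)

| Medication | Market Share % | Potentially Affected | Likely to Discontinue | Adverse Events |
| --- | --- | --- | --- | --- |
| Eliquis | 68.87 | 735-1785 | 125-535 | 68-580 |
| Xarelto | 29.76 | 318-771 | 54-231 | 30-251 |
| Pradaxa | 1.31 | 14-34 | 2.4-10 | 1.3-11 |
| Savaysa | 0.06 | 0.6-1.6 | 0.1-0.5 | 0.1-0.5 |
...
```

Reading the first row: 230.98 M covered lives × 1.4%–3.4% AFib/VTE
prevalence × 33% formulary share puts 1.07–2.59 M anticoagulated patients
under this formulary; apixaban's 68.9% market share makes 735 000–1 785 000
of them potentially affected by its exclusion. At a 17%–30%
discontinuation rate, 125 000–535 000 would likely stop anticoagulation
entirely, and the compound rule (45%–85% serious cardiovascular events
among discontinuers plus 2%–10% adverse events among the switchers) yields
68 000–580 000 patients with adverse events.

The same pipeline is available as a library:

```python
from formulary_impact import load_fixture, run_scenario, compare_to_reference

scenario, reference = load_fixture("anticoagulants")
table = run_scenario(scenario)                     # or mode="conservative"
print(table.row("CVS", "Eliquis").adverse_events)  # [68.4242, 580.089]
print(compare_to_reference(table, reference).counts)
# {'match': 40, 'within_tolerance': 8, 'mismatch': 0, 'skipped_erratum': 0}
```

Other subcommands: `compare` (golden comparison against a packaged
reference table, erratum-aware), `sensitivity` (spread attribution — for
the anticoagulant group the market-share ratio ≈ 1148 dwarfs the
prevalence ratio ≈ 2.43, so market share dominates cross-medication
spread), and `generate` (seeded synthetic scenarios for testing). Scenario
configs are YAML or JSON; percentages may be written `48.5%` or `0.485`.

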
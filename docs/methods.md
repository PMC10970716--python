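# Methods

## The model

`formulary-impact` implements a deterministic burden cascade for pharmacy
formulary exclusions. When a pharmacy benefit manager (PBM) removes a
medication from its national formulary, every covered patient taking that
medication must switch to a therapeutic substitute or stop treatment. The
number of patients potentially affected by excluding medication *m* from
formulary *F* is a product of factors:

```
A = L · p · Πf · κ · m_F · m_d          (reported in thousands of persons)
```

where

| symbol | meaning | units |
|---|---|---|
| `L` | covered lives: national population × Σ insured-segment percentages | persons |
| `p` | indication prevalence among covered lives | fraction, ranged |
| `Πf` | product of eligibility factors (e.g. attack-frequency threshold for preventive migraine therapy) | fractions |
| `κ` | calibration factor (default 1; see below) | fraction |
| `m_F` | formulary market share of covered lives | fraction |
| `m_d` | medication market share within its class or subclass | fraction |

Downstream outcomes are rates applied to `A`: discontinuations
`D = A · d`, and adverse events `E = A · r`, where `r` is either a flat
rate or the compound rate

```
r = e·d + s·(1 − d)
```

— serious events among the fraction `d` who discontinue entirely (rate `e`)
plus adverse events among the complement who switch (rate `s`).

## Coupled scenario bounds

Every ranged quantity is a `BoundedRange` low/high pair, and each bound is a
*coherent scenario*: the reported low bound evaluates every input at its low
bound simultaneously, and likewise the high bound. This is deliberately not
interval arithmetic — in the compound rate, the complement `1 − d` is
evaluated at the *same* scenario's `d`, so the optimistic bound uses
`1 − d_low` (the larger complement). The model's published-table semantics
are exactly these coupled bounds.

Two consequences are worth stating:

* Coupled bounds are narrower than the true extrema of `e·d + s·(1 − d)`
  over the input box. The true envelope (corner enumeration; the expression
  is multilinear so corners suffice) is available as
  `conservative_envelope` and as `run_scenario(..., mode="conservative")`
  for users who want guaranteed coverage of all bound combinations.
* The coupled pair is only guaranteed to be ordered (low ≤ high) when
  `e.low ≥ s.low`, i.e. when forgoing therapy is at least as risky as
  switching — the situation the rule models. Inputs violating this are
  rejected with a pointer to the conservative envelope rather than silently
  reordered, since reordering would misattribute scenarios. The synthetic
  generator draws its coupled rules inside the valid region.

No intermediate rounding occurs anywhere in the cascade; all counts are
floats in thousands of persons, and rounding to the printed convention
(≥ 10 → nearest integer, < 10 → one decimal, half-up) happens only in the
reporting layer.

## Packaged case studies

Three scenario fixtures ship with the package, with all inputs taken from
published national statistics and the nonmedical-switching literature:

* **anticoagulants** (AFib/VTE): prevalence 1.4%–3.4% (bound-wise sum of
  the AFib 1%–2.9% and VTE 0.4%–0.5% ranges), one share group of four
  direct oral anticoagulants, discontinuation 17%–30%, compound
  adverse-event rule with e = 45%–85%, s = 2%–10%.
* **migraine** (CGRP-blocking preventives): prevalence 9.5%–11.6%,
  eligibility 33.3% (patients with > 3 attacks/month), two share groups
  (monoclonal antibodies; gepants) that are alternative partitions of the
  *same* eligible pool, discontinuation 9%–19%, flat 50% adverse-event
  rate.
* **psoriasis**: prevalence 1.5%–3%, one 19-medication share group with
  per-medication outcome models (TNF inhibitors discontinue at 6%–9%,
  all other agents at 9%–19%; flat 15%–35% adverse events for all).

The population base is the 2022 US total (333.3 M) with employer private
(48.5%), small-group private (6.1%) and Medicare Part D (14.7%) segments —
69.3% covered lives, ≈ 230.98 M people. The two modelled formularies hold
33% (CVS Caremark Performance Standard Control) and 24% (Express Scripts
National Preferred) of those lives. The covered-lives base is computed
exactly from the percentages rather than reproducing any hand-rounded
intermediate; published cells back-derive from slightly inconsistent bases
(230.8–230.9 M), which is why golden comparisons use a ±1 printed-unit
tolerance.

### The migraine calibration factor

The published migraine per-medication counts imply an eligible pool ≈ 0.837
times what `L · p · 0.333 · m_F` yields; the residual multiplier is
documented only in a source list that is not publicly printed. Rather than
silently absorbing it, the fixture stores `calibration_factor: 0.8374`
flagged `calibrated_to_published_counts`. The value was back-derived from the
published affected counts: the feasible interval for a single factor
reproducing every printed affected cell to ±1 thousand is
[0.83730, 0.83752), and 0.8374 is its midpoint (the bound-wise
back-divisions are 0.8368 and 0.8379). It is an explicit, overridable model
input: set it to 1.0 to obtain the uncalibrated cascade.

### Errata registry

Reference tables ship verbatim, including cells that are inconsistent with
the stated rates. Each such cell carries an erratum flag with a note;
comparisons report flagged cells as `skipped_erratum` and never fail on
them. Registered errata: one migraine discontinuation high cell (printed
103 where 19% of the printed pool is ≈ 126); one psoriasis discontinuation
high cell (printed 19 vs ≈ 37); one psoriasis adverse-event low cell
(printed 0.2 vs ≈ 0.5); one cell printed `.04` (evidently 0.4); and the
entire adverse-event low-bound column of the psoriasis table's
smaller-formulary block, which applies the 35% rate at both bounds instead
of 15%/35%. Label-level notes (a brand paired with the wrong generic name,
and a narrative sentence swapping the two formularies' totals) are kept as
table notes; the scenario fixtures store the corrected generic names.

## Share normalization

Within a class or subclass, a medication's market share is its prescription
count divided by all prescriptions in the group. Printed percentages (which
sum to 99.99–100.01% from rounding) are renormalized by their own sum, so
shares sum to exactly 1 and the per-medication affected counts conserve the
group pool (Σ affected = pool, per formulary, per bound, to 1e-6 relative).
Normalization is idempotent; an already-normalized group (sum within 1e-9
of 1) is passed through bit-identically so that save/load round trips are
byte-stable.

## Sensitivity statistics

"Which factor drives the spread" is formalized as two separate statistics:

* **Within-range attribution** — for one output cell of the product chain,
  factor *i*'s share is `log(f_i.high/f_i.low) / log(out.high/out.low)`.
  Shares are nonnegative and sum to 1 exactly (log-additivity of the
  product); the compound adverse-event rate enters as one composite factor.
  Attribution is unit-invariant and undefined (rejected) when any low bound
  is zero.
* **Cross-medication spread** — within a share group, the ratio of largest
  to smallest market share, compared against each ranged factor's high/low
  ratio. Market share is flagged dominant when its ratio exceeds every
  within-range ratio; in the anticoagulant case study the share spread is
  68.88/0.06 ≈ 1148 versus a prevalence ratio of ≈ 2.43.

## Synthetic scenarios

The generator draws structurally valid scenarios for property testing: a
population of 250–400 M, 2–4 insured segments splitting a covered fraction
of 0.55–0.80, two formularies at 10%–45% share, prevalence low in
0.5%–5% with width up to 3 points, discontinuation low 5%–20% with width
2–15 points, adverse rates 5%–30% low with width up to 25 points, and a
50/50 mix of flat and coupled rules — the same orders of magnitude as the
case studies. Group shares are positive weights normalized to sum to one.
One seeded NumPy generator drives each call; the seed is recorded in the
scenario name, and equal configs yield equal scenarios (and byte-identical
saved files).

What the generator does **not** emulate: correlations between prevalence
and rates, multi-year dynamics, demographic stratification, or real
prescription-count distributions. Passing property tests therefore
establishes the arithmetic and structural correctness of the cascade —
conservation, linearity, bound ordering, oracle equivalence — not the
epidemiological realism of any particular synthetic draw.

## Numerical choices

* Pure arithmetic throughout; no iterative numerics. Test tolerances are
  1e-9 absolute on fractions and 1e-6 relative on counts; range-algebra
  identities (associativity, order independence) hold to 1e-12 relative.
* Convex-combination float spill past [0, 1] in the compound rate is
  clamped; an ulp-level bound inversion between mathematically equal bounds
  is snapped rather than rejected.
* Golden comparison rounds the computed value half-up to the precision of
  each printed cell and compares in units of that cell's last printed
  digit (default tolerance ±1 unit).
* Degenerate inputs: zero-width ranges are first-class (scalars promote to
  them); a group of all-zero weights cannot be normalized and is rejected;
  a fully point-valued chain has no spread to attribute and reports
  all-zero shares with a warning rather than dividing by zero.

## Problem sizes

The test suite exercises the three case studies (8, 12 and 37 output rows),
1000 random rate triples for envelope containment, 500 seeded synthetic
scenarios for oracle equivalence, and 100 for conservation; the whole suite
runs in a few seconds. The acceptance script evaluates the anticoagulant
case study (8 rows) plus one seeded synthetic self-check.

## Known limitations

* The coupled semantics reproduce published two-point scenario bounds; they
  are not confidence intervals, and no distributional uncertainty is
  propagated.
* Shares within a group must come uniformly from counts or uniformly from
  fractions; mixing is rejected.
* The migraine calibration factor is an empirical fit to published output,
  not an independently sourced input; conclusions that depend on it should
  be checked at `calibration_factor: 1.0`.
* Single-year snapshot; no age/severity stratification of prevalence or
  rates.
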
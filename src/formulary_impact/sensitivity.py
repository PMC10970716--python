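"""Attribution of output spread to model factors.

Two complementary statistics formalize "what drives the spread":

* within-range attribution — for one output cell, the share of
  ``log(high/low)`` contributed by each ranged factor of the product chain
  (shares sum to one because the cascade is a pure product of factors);
* cross-medication spread — within one share group, the ratio of the largest
  to the smallest market share, compared against every within-range factor
  ratio to decide whether market share dominates the spread across rows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .cascade import adverse_events, affected_pool, covered_lives, normalize_shares
from .ranges import BoundedRange
from .scenario import FlatRate, Scenario

__all__ = ["AttributionReport", "attribute_range_width", "cross_medication_spread"]


@dataclass
class AttributionReport:
    """Ranked factor attribution for one output cell or one share group."""

    scenario_name: str
    kind: str  # within_range | cross_medication
    target: str
    # factor -> share of log-width (within_range) or factor -> ratio (spread)
    shares: dict[str, float] = field(default_factory=dict)
    ranked: list[str] = field(default_factory=list)
    spread_factor: float = 1.0
    dominant: str = ""
    warnings: list[str] = field(default_factory=list)
    per_medication: dict[str, BoundedRange] = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "scenario": self.scenario_name,
            "kind": self.kind,
            "target": self.target,
            "shares": self.shares,
            "ranked": self.ranked,
            "dominant": self.dominant,
        }
        if self.kind == "cross_medication":
            doc["spread_factor"] = self.spread_factor
            doc["per_medication"] = {
                k: [v.low, v.high] for k, v in self.per_medication.items()
            }
        if self.warnings:
            doc["warnings"] = self.warnings
        return json.dumps(doc, indent=2)

    def render(self) -> str:
        lines = [f"{self.kind} attribution — {self.target}"]
        for name in self.ranked:
            lines.append(f"  {name:35s} {self.shares[name]:.4f}")
        if self.dominant:
            lines.append(f"  dominant: {self.dominant}")
        return "\n".join(lines) + "\n"


def _factor_chain(
    s: Scenario, formulary: str, medication: str, output: str
) -> list[tuple[str, BoundedRange]]:
    """The multiplicative chain producing one output cell, each factor as a
    (possibly degenerate) range."""
    med = s.medication(medication)
    f = s.formulary(formulary)
    group = normalize_shares(s.share_group(med.group_id))
    share = next(m.share for m in group.medications if m.brand_name == medication)
    om = s.outcome_model(med.outcome_model_id)
    chain: list[tuple[str, BoundedRange]] = [
        ("covered_lives", BoundedRange.coerce(covered_lives(s.population))),
        ("prevalence", s.indication.prevalence),
    ]
    for label, frac in s.indication.eligibility_factors:
        chain.append((f"eligibility[{label}]", BoundedRange.coerce(frac)))
    chain.append(
        ("calibration_factor", BoundedRange.coerce(s.indication.calibration_factor))
    )
    chain.append(("formulary_market_share", BoundedRange.coerce(f.market_share)))
    chain.append(("medication_share", BoundedRange.coerce(share)))
    if output == "discontinue":
        chain.append(("discontinuation", om.discontinuation))
    elif output == "adverse_events":
        # evaluated rate enters the chain as one composite factor
        unit = BoundedRange(1.0, 1.0)
        rate = adverse_events(unit, om)
        rule = om.adverse_event_rule
        label = (
            "adverse_event_rate[flat]"
            if isinstance(rule, FlatRate)
            else "adverse_event_rate[coupled]"
        )
        chain.append((label, rate))
    elif output != "affected":
        raise ValueError(
            f"unknown output {output!r}; expected affected, discontinue or "
            "adverse_events"
        )
    return chain


def attribute_range_width(
    s: Scenario, formulary: str, medication: str, output: str = "affected"
) -> AttributionReport:
    """Share of the output's log-width ``log(high/low)`` attributable to each
    factor of its product chain.

    For a pure product, ``log(out_hi/out_lo) = Σ log(f_hi/f_lo)``, so the
    shares are nonnegative and sum to one.  Point-valued factors get share
    zero.  Any zero low bound makes the attribution undefined and raises.
    """
    chain = _factor_chain(s, formulary, medication, output)
    for name, rng in chain:
        if rng.low <= 0:
            raise ValueError(
                f"factor {name!r} has a zero (or missing) low bound; log-width "
                "attribution is undefined"
            )
    widths = {name: math.log(rng.high / rng.low) for name, rng in chain}
    total = sum(widths.values())
    report = AttributionReport(
        scenario_name=s.name,
        kind="within_range",
        target=f"{formulary}/{medication}/{output}",
    )
    if total <= 0.0:
        # fully point-valued chain: zero spread to attribute
        report.shares = {name: 0.0 for name in widths}
        report.warnings.append("output is point-valued; no spread to attribute")
    else:
        report.shares = {name: w / total for name, w in widths.items()}
    report.ranked = sorted(report.shares, key=report.shares.get, reverse=True)
    ranged = [n for n in report.ranked if report.shares[n] > 0]
    report.dominant = ranged[0] if ranged else ""
    return report


def cross_medication_spread(
    s: Scenario, formulary: str, group: str
) -> AttributionReport:
    """Max/min market-share ratio within a group versus the within-range
    ratios of the ranged cascade factors.

    Market share is flagged dominant when its spread ratio exceeds every
    within-range factor's high/low ratio — the group's rows then differ more
    because of who holds the market than because of input uncertainty.
    """
    f = s.formulary(formulary)
    g = normalize_shares(s.share_group(group))
    if not g.medications:
        raise ValueError(f"share group {group!r} is empty")
    L = covered_lives(s.population)
    pool = affected_pool(L, s.indication, f)
    report = AttributionReport(
        scenario_name=s.name, kind="cross_medication", target=f"{formulary}/{group}"
    )
    shares = {}
    for m in g.medications:
        report.per_medication[m.brand_name] = pool.scale(m.share)
        if m.share > 0:
            shares[m.brand_name] = m.share
        else:
            report.warnings.append(
                f"medication {m.brand_name!r} has zero share; excluded from "
                "the spread ratio"
            )
    if not shares:
        raise ValueError(f"share group {group!r} has no positive shares")
    report.spread_factor = max(shares.values()) / min(shares.values())

    ratios: dict[str, float] = {"market_share_spread": report.spread_factor}
    factor_ranges: list[tuple[str, BoundedRange]] = [
        ("prevalence", s.indication.prevalence)
    ]
    ids = {m.outcome_model_id for m in g.medications}
    for om_id in sorted(ids):
        om = s.outcome_model(om_id)
        factor_ranges.append((f"discontinuation[{om_id}]", om.discontinuation))
        rule = om.adverse_event_rule
        rate = adverse_events(BoundedRange(1.0, 1.0), om)
        factor_ranges.append((f"adverse_event_rate[{om_id}]", rate))
    for name, rng in factor_ranges:
        if rng.low > 0:
            ratios[name] = rng.high / rng.low
        else:
            report.warnings.append(f"factor {name!r} has zero low bound; no ratio")
    report.shares = ratios
    report.ranked = sorted(ratios, key=ratios.get, reverse=True)
    report.dominant = report.ranked[0]
    return report
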
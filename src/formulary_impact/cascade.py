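"""The impact cascade: covered lives → indication pool → formulary pool →
per-medication affected → discontinuations and adverse events.

All patient counts are carried in thousands of persons as floats, with no
intermediate rounding; rounding to the printed convention is the reporting
layer's job.  Each low/high bound is a coherent scenario evaluated with every
input at the corresponding bound (coupled-scenario semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

from .ranges import (
    BoundedRange,
    conservative_envelope,
    coupled_compound_rate,
    scenario_product,
)
from .scenario import (
    CoupledCompound,
    FlatRate,
    Formulary,
    Indication,
    OutcomeModel,
    PopulationModel,
    Scenario,
    ShareGroup,
)

__all__ = [
    "ImpactRow",
    "ImpactTable",
    "covered_lives",
    "affected_pool",
    "medication_affected",
    "normalize_shares",
    "discontinuations",
    "adverse_events",
    "run_scenario",
]

Mode = Literal["coupled", "conservative"]


@dataclass
class ImpactRow:
    """Impact of excluding one medication from one formulary, in thousands."""

    formulary: str
    medication: str
    group_id: str
    share: float
    affected: BoundedRange
    discontinue: BoundedRange
    adverse_events: BoundedRange


@dataclass
class ImpactTable:
    scenario_name: str
    rows: list[ImpactRow] = field(default_factory=list)
    # (formulary name, group_id) -> pool in thousands
    pool_by_formulary_and_group: dict[tuple[str, str], BoundedRange] = field(
        default_factory=dict
    )

    def row(self, formulary: str, medication: str) -> ImpactRow:
        for r in self.rows:
            if r.formulary == formulary and r.medication == medication:
                return r
        raise KeyError(f"no row for ({formulary!r}, {medication!r})")


def covered_lives(p: PopulationModel) -> float:
    """Number of persons whose pharmacy benefit falls under the modelled
    formulary systems: total population times the sum of covered-segment
    percentages."""
    return p.total_population * sum(seg.percent for seg in p.segments)


def affected_pool(L: float, ind: Indication, f: Formulary) -> BoundedRange:
    """Patients (thousands) treated under formulary ``f`` for the indication:
    covered lives × prevalence × eligibility factors × calibration ×
    formulary market share, divided by 1000."""
    factors = [
        L,
        ind.prevalence,
        *[frac for _, frac in ind.eligibility_factors],
        ind.calibration_factor,
        f.market_share,
    ]
    return scenario_product(factors).scale(1e-3)


def medication_affected(pool: BoundedRange, share: float) -> BoundedRange:
    """Patients on one medication: bound-wise pool × market share."""
    if not (0.0 <= share <= 1.0):
        raise ValueError(f"share must lie in [0, 1], got {share}")
    return pool.scale(share)


def normalize_shares(group: ShareGroup) -> ShareGroup:
    """Return a copy of the group with every medication's share populated and
    summing to exactly one.

    Prescription counts become ``count / total count``.  Printed share
    fractions (which may sum to 99.99–100.01% from rounding) are renormalized
    by their own sum.  Idempotent.
    """
    if any(m.prescriptions is not None for m in group.medications):
        if not all(m.prescriptions is not None for m in group.medications):
            raise ValueError(
                f"share group {group.group_id!r}: mixing prescription counts "
                "and shares within one group is not supported"
            )
        weights = [float(m.prescriptions) for m in group.medications]
    else:
        if any(m.share is None for m in group.medications):
            raise ValueError(
                f"share group {group.group_id!r}: every medication needs a "
                "share or a prescription count"
            )
        weights = [float(m.share) for m in group.medications]
    if any(w < 0 for w in weights):
        raise ValueError(f"share group {group.group_id!r}: negative weight")
    total = sum(weights)
    if total <= 0:
        raise ValueError(
            f"share group {group.group_id!r}: weights sum to zero, cannot "
            "normalize"
        )
    if abs(total - 1.0) <= 1e-9:
        total = 1.0  # already normalized: avoid perturbing the last float bits
    medications = [
        replace(m, share=w / total) for m, w in zip(group.medications, weights)
    ]
    return replace(group, medications=medications)


def discontinuations(affected: BoundedRange, om: OutcomeModel) -> BoundedRange:
    """Patients likely to stop therapy: bound-wise affected × discontinuation
    rate."""
    return BoundedRange(
        affected.low * om.discontinuation.low,
        affected.high * om.discontinuation.high,
    )


def adverse_events(
    affected: BoundedRange, om: OutcomeModel, mode: Mode = "coupled"
) -> BoundedRange:
    """Patients likely to have an adverse event.

    A flat rule applies its rate bound-wise.  A coupled-compound rule applies
    ``e*d + s*(1-d)`` — events among discontinuers plus events among
    switchers — evaluated per scenario bound ("coupled", the default) or as
    the true corner-enumeration envelope ("conservative").
    """
    rule = om.adverse_event_rule
    if isinstance(rule, FlatRate):
        rate = rule.rate
    elif isinstance(rule, CoupledCompound):
        fn = coupled_compound_rate if mode == "coupled" else conservative_envelope
        rate = fn(
            om.discontinuation,
            rule.event_given_discontinuation,
            rule.event_given_switch,
        )
    else:  # pragma: no cover - exhaustive over rule types
        raise TypeError(f"unknown adverse-event rule {type(rule).__name__}")
    return BoundedRange(affected.low * rate.low, affected.high * rate.high)


def run_scenario(s: Scenario, mode: Mode = "coupled") -> ImpactTable:
    """Evaluate the full cascade: one :class:`ImpactRow` per
    (formulary, medication), plus the per-(formulary, group) pools.

    Share groups are alternative partitions of the same indication pool (a
    pool may be split by class and, separately, by subclass), so conservation
    holds within each group, not across groups.
    """
    L = covered_lives(s.population)
    groups = [normalize_shares(g) for g in s.share_groups]
    table = ImpactTable(scenario_name=s.name)
    for f in s.formularies:
        pool = affected_pool(L, s.indication, f)
        for g in groups:
            table.pool_by_formulary_and_group[(f.name, g.group_id)] = pool
            for m in g.medications:
                om = s.outcome_model(m.outcome_model_id)
                affected = medication_affected(pool, m.share)
                table.rows.append(
                    ImpactRow(
                        formulary=f.name,
                        medication=m.brand_name,
                        group_id=g.group_id,
                        share=m.share,
                        affected=affected,
                        discontinue=discontinuations(affected, om),
                        adverse_events=adverse_events(affected, om, mode=mode),
                    )
                )
    return table
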
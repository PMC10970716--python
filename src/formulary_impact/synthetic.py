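"""Seeded generator of random scenarios with the structure the cascade
assumes: a covered-lives fraction, an ordered prevalence pair, share groups
whose shares are positive and sum to one, and bounded outcome rates.

Defaults emulate the shape of the published case studies — a national
population in the hundreds of millions, a handful of insured segments
covering 55–80% of it, prevalence in the sub-percent to few-percent band,
discontinuation rates around 5–35%, and a mix of flat and coupled-compound
adverse-event rules.  The generator is fully deterministic for a fixed seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .ranges import BoundedRange
from .scenario import (
    CoupledCompound,
    CoverageSegment,
    FlatRate,
    Formulary,
    Indication,
    Medication,
    OutcomeModel,
    PopulationModel,
    Scenario,
    ShareGroup,
)

__all__ = ["GeneratorConfig", "generate_scenario", "perturb_scenario"]


@dataclass
class GeneratorConfig:
    """Sampling intervals for random scenario generation.

    All rate intervals must lie within [0, 1]; ``rule_mix`` is the
    probability of a coupled-compound adverse-event rule (vs flat).
    """

    seed: int = 0
    n_groups: int = 1
    n_medications: tuple[int, int] = (2, 6)  # per group, inclusive
    n_segments: tuple[int, int] = (2, 4)
    population_range: tuple[float, float] = (2.5e8, 4.0e8)
    covered_fraction_range: tuple[float, float] = (0.55, 0.80)
    n_formularies: int = 2
    formulary_share_range: tuple[float, float] = (0.10, 0.45)
    prevalence_low_range: tuple[float, float] = (0.005, 0.05)
    prevalence_width_range: tuple[float, float] = (0.001, 0.03)
    eligibility_probability: float = 0.5
    eligibility_range: tuple[float, float] = (0.2, 1.0)
    discontinuation_low_range: tuple[float, float] = (0.05, 0.20)
    discontinuation_width_range: tuple[float, float] = (0.02, 0.15)
    adverse_low_range: tuple[float, float] = (0.05, 0.30)
    adverse_width_range: tuple[float, float] = (0.02, 0.25)
    rule_mix: float = 0.5

    def validate(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.n_medications[0] < 1 or self.n_medications[0] > self.n_medications[1]:
            raise ValueError(f"infeasible n_medications range {self.n_medications}")
        if self.n_formularies < 1:
            raise ValueError("n_formularies must be >= 1")
        if not (0.0 <= self.rule_mix <= 1.0):
            raise ValueError("rule_mix must be a probability")
        for name in (
            "covered_fraction_range",
            "formulary_share_range",
            "prevalence_low_range",
            "prevalence_width_range",
            "eligibility_range",
            "discontinuation_low_range",
            "discontinuation_width_range",
            "adverse_low_range",
            "adverse_width_range",
        ):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must be an ordered interval in [0, 1]")


def _rate(rng: np.random.Generator, low_range, width_range) -> BoundedRange:
    low = float(rng.uniform(*low_range))
    high = min(1.0, low + float(rng.uniform(*width_range)))
    return BoundedRange(low, high)


def generate_scenario(cfg: GeneratorConfig) -> Scenario:
    """Draw one valid random scenario; identical for identical configs."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    total = float(rng.uniform(*cfg.population_range))
    covered = float(rng.uniform(*cfg.covered_fraction_range))
    n_seg = int(rng.integers(cfg.n_segments[0], cfg.n_segments[1] + 1))
    # split the covered fraction across segments with positive weights
    weights = rng.uniform(0.2, 1.0, size=n_seg)
    weights /= weights.sum()
    segments = [
        CoverageSegment(name=f"segment-{i + 1}", percent=covered * float(w))
        for i, w in enumerate(weights)
    ]

    formularies = [
        Formulary(
            name=f"formulary-{chr(ord('A') + i)}",
            market_share=float(rng.uniform(*cfg.formulary_share_range)),
        )
        for i in range(cfg.n_formularies)
    ]

    prevalence = _rate(rng, cfg.prevalence_low_range, cfg.prevalence_width_range)
    eligibility: list[tuple[str, float]] = []
    if rng.uniform() < cfg.eligibility_probability:
        eligibility.append(
            ("synthetic eligibility", float(rng.uniform(*cfg.eligibility_range)))
        )
    indication = Indication(
        name="synthetic indication",
        prevalence=prevalence,
        eligibility_factors=eligibility,
    )

    outcome_models = []
    groups = []
    for gi in range(cfg.n_groups):
        d = _rate(
            rng, cfg.discontinuation_low_range, cfg.discontinuation_width_range
        )
        if rng.uniform() < cfg.rule_mix:
            r1 = _rate(rng, cfg.adverse_low_range, cfg.adverse_width_range)
            r2 = _rate(rng, cfg.adverse_low_range, cfg.adverse_width_range)
            # discontinuing untreated carries at least the risk of switching;
            # e.low >= s.low also keeps the coupled bounds ordered
            e, s_rate = (r1, r2) if r1.low >= r2.low else (r2, r1)
            rule = CoupledCompound(
                event_given_discontinuation=e,
                event_given_switch=s_rate,
            )
        else:
            rule = FlatRate(
                rate=_rate(rng, cfg.adverse_low_range, cfg.adverse_width_range)
            )
        om_id = f"outcome-{gi + 1}"
        outcome_models.append(
            OutcomeModel(id=om_id, discontinuation=d, adverse_event_rule=rule)
        )
        n_meds = int(rng.integers(cfg.n_medications[0], cfg.n_medications[1] + 1))
        # positive weights normalized to one (symmetric-Dirichlet-style)
        raw = rng.gamma(shape=1.0, scale=1.0, size=n_meds) + 1e-6
        shares = raw / raw.sum()
        group_id = f"group-{gi + 1}"
        meds = [
            Medication(
                brand_name=f"med-{gi + 1}-{mi + 1}",
                generic_name=f"generic-{gi + 1}-{mi + 1}",
                group_id=group_id,
                outcome_model_id=om_id,
                share=float(sh),
            )
            for mi, sh in enumerate(shares)
        ]
        groups.append(ShareGroup(group_id=group_id, medications=meds))

    return Scenario(
        name=f"synthetic-seed-{cfg.seed}",
        population=PopulationModel(total_population=total, segments=segments),
        formularies=formularies,
        indication=indication,
        share_groups=groups,
        outcome_models=outcome_models,
        notes=[f"generated with seed {cfg.seed}"],
    )


_SCALABLE = (
    "prevalence",
    "calibration_factor",
    "total_population",
)


def perturb_scenario(s: Scenario, factor: str, multiplier: float) -> Scenario:
    """Return a deep copy with one scalable quantity multiplied.

    ``factor`` is one of ``prevalence``, ``calibration_factor``,
    ``total_population``, ``market_share:<formulary>`` or
    ``shares:<group_id>`` (the last rescales every share in the group, which
    is a no-op after renormalization — useful for invariance tests).
    """
    if multiplier < 0:
        raise ValueError("multiplier must be nonnegative")
    out = copy.deepcopy(s)
    if factor == "prevalence":
        out.indication.prevalence = s.indication.prevalence.scale(multiplier)
    elif factor == "calibration_factor":
        out.indication.calibration_factor = s.indication.calibration_factor * multiplier
    elif factor == "total_population":
        out.population.total_population = s.population.total_population * multiplier
    elif factor.startswith("market_share:"):
        name = factor.split(":", 1)[1]
        fm = out.formulary(name)  # KeyError if unknown
        fm.market_share *= multiplier
    elif factor.startswith("shares:"):
        gid = factor.split(":", 1)[1]
        group = out.share_group(gid)
        for m in group.medications:
            if m.share is not None:
                m.share *= multiplier
            if m.prescriptions is not None:
                m.prescriptions *= multiplier
    else:
        raise ValueError(
            f"unknown factor {factor!r}; expected one of {_SCALABLE}, "
            "'market_share:<name>' or 'shares:<group_id>'"
        )
    return out
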
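import pytest
from hypothesis import HealthCheck, settings

from formulary_impact import fixture_names, load_fixture

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def case_studies():
    """All packaged case studies as {name: (Scenario, ReferenceTable)}."""
    return {name: load_fixture(name) for name in fixture_names()}


@pytest.fixture(scope="session")
def anticoagulants(case_studies):
    return case_studies["anticoagulants"]


@pytest.fixture(scope="session")
def migraine(case_studies):
    return case_studies["migraine"]


@pytest.fixture(scope="session")
def psoriasis(case_studies):
    return case_studies["psoriasis"]


def impact_oracle(s):
    """Independent per-cell recomputation of the cascade as one straight
    multiplication chain, bypassing the library's range algebra entirely.

    Returns {(formulary, medication): (aff_lo, aff_hi, disc_lo, disc_hi,
    ae_lo, ae_hi)} in thousands.
    """
    from formulary_impact.scenario import FlatRate

    L = s.population.total_population * sum(
        seg.percent for seg in s.population.segments
    )
    elig = 1.0
    for _, frac in s.indication.eligibility_factors:
        elig *= frac
    cells = {}
    for f in s.formularies:
        for g in s.share_groups:
            if any(m.prescriptions is not None for m in g.medications):
                weights = [float(m.prescriptions) for m in g.medications]
            else:
                weights = [float(m.share) for m in g.medications]
            total = sum(weights)
            for m, w in zip(g.medications, weights):
                share = w / total
                om = s.outcome_model(m.outcome_model_id)
                out = []
                for bound in (0, 1):
                    prev = (s.indication.prevalence.low, s.indication.prevalence.high)[
                        bound
                    ]
                    aff = (
                        L
                        * prev
                        * elig
                        * s.indication.calibration_factor
                        * f.market_share
                        * share
                        / 1000.0
                    )
                    out.append(aff)
                for bound in (0, 1):
                    d = (om.discontinuation.low, om.discontinuation.high)[bound]
                    out.append(out[bound] * d)
                for bound in (0, 1):
                    rule = om.adverse_event_rule
                    d = (om.discontinuation.low, om.discontinuation.high)[bound]
                    if isinstance(rule, FlatRate):
                        rate = (rule.rate.low, rule.rate.high)[bound]
                    else:
                        e = (
                            rule.event_given_discontinuation.low,
                            rule.event_given_discontinuation.high,
                        )[bound]
                        sw = (
                            rule.event_given_switch.low,
                            rule.event_given_switch.high,
                        )[bound]
                        rate = e * d + sw * (1.0 - d)
                    out.append(out[bound] * rate)
                cells[(f.name, m.brand_name)] = tuple(out)
    return cells
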
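"""Cascade engine: worked examples, conservation, and oracle equivalence."""

import copy

import pytest

from formulary_impact import (
    BoundedRange,
    Formulary,
    GeneratorConfig,
    Indication,
    Medication,
    OutcomeModel,
    PopulationModel,
    CoverageSegment,
    FlatRate,
    ShareGroup,
    adverse_events,
    affected_pool,
    covered_lives,
    discontinuations,
    generate_scenario,
    medication_affected,
    normalize_shares,
    run_scenario,
)
from conftest import impact_oracle


class TestCoveredLives:
    def test_us_covered_lives_from_segment_percents(self):
        pop = PopulationModel(
            total_population=333.3e6,
            segments=[
                CoverageSegment("employer", 0.485),
                CoverageSegment("small group", 0.061),
                CoverageSegment("Part D", 0.147),
            ],
        )
        L = covered_lives(pop)
        assert L == pytest.approx(230.98e6, rel=1e-4)
        assert L == pytest.approx(230.9e6, rel=1e-3)  # the published ~230.9M

    def test_single_full_segment(self):
        pop = PopulationModel(1e6, [CoverageSegment("all", 1.0)])
        assert covered_lives(pop) == 1e6

    def test_zero_segments(self):
        assert covered_lives(PopulationModel(1e6, [])) == 0.0


class TestAffectedPool:
    def test_anticoagulant_cvs_pool(self):
        ind = Indication("AFib/VTE", BoundedRange(0.014, 0.034))
        pool = affected_pool(230.9e6, ind, Formulary("CVS", 0.33))
        assert pool.low == pytest.approx(1066.8, abs=0.2)
        assert pool.high == pytest.approx(2590.7, abs=0.2)

    def test_zero_prevalence(self):
        ind = Indication("x", BoundedRange(0, 0))
        pool = affected_pool(1e8, ind, Formulary("F", 0.5))
        assert (pool.low, pool.high) == (0.0, 0.0)

    def test_calibration_halves_linearly(self):
        ind = Indication("x", BoundedRange(0.01, 0.02))
        half = Indication("x", BoundedRange(0.01, 0.02), calibration_factor=0.5)
        f = Formulary("F", 0.3)
        full_pool = affected_pool(1e8, ind, f)
        half_pool = affected_pool(1e8, half, f)
        assert half_pool.low == pytest.approx(full_pool.low / 2, rel=1e-12)
        assert half_pool.high == pytest.approx(full_pool.high / 2, rel=1e-12)

    def test_eligibility_order_irrelevant(self):
        f = Formulary("F", 0.3)
        a = Indication("x", BoundedRange(0.01, 0.02), [("p", 0.4), ("q", 0.7)])
        b = Indication("x", BoundedRange(0.01, 0.02), [("q", 0.7), ("p", 0.4)])
        assert affected_pool(1e8, a, f).approx_equal(affected_pool(1e8, b, f))


class TestMedicationAffected:
    def test_eliquis_row(self):
        pool = BoundedRange(1066.8, 2590.7)
        aff = medication_affected(pool, 0.6888)
        assert aff.low == pytest.approx(734.8, abs=0.2)
        assert aff.high == pytest.approx(1784.5, abs=0.2)

    def test_full_share_is_pool(self):
        pool = BoundedRange(10.0, 20.0)
        assert medication_affected(pool, 1.0) == pool

    def test_share_out_of_bounds(self):
        with pytest.raises(ValueError):
            medication_affected(BoundedRange(1, 2), 1.2)


def _group(weights=None, counts=None):
    meds = []
    n = len(weights or counts)
    for i in range(n):
        meds.append(
            Medication(
                brand_name=f"m{i}",
                generic_name=f"g{i}",
                group_id="g",
                outcome_model_id="om",
                share=None if counts else weights[i],
                prescriptions=counts[i] if counts else None,
            )
        )
    return ShareGroup("g", meds)


class TestNormalizeShares:
    def test_prescription_counts(self):
        g = normalize_shares(_group(counts=[6888, 2976, 131, 6]))
        shares = [m.share for m in g.medications]
        # direct-division oracle: count / 10001 total
        assert shares == pytest.approx(
            [6888 / 10001, 2976 / 10001, 131 / 10001, 6 / 10001], abs=1e-12
        )
        # and the printed market-share percentages within rounding
        assert shares == pytest.approx([0.6888, 0.2976, 0.0131, 0.0006], abs=1e-4)
        assert sum(shares) == pytest.approx(1.0, abs=1e-12)

    def test_single_medication(self):
        g = normalize_shares(_group(counts=[42]))
        assert g.medications[0].share == 1.0

    def test_printed_percentages_renormalized_by_own_sum(self):
        # printed shares summing to 100.01%
        g = normalize_shares(_group(weights=[0.6888, 0.2976, 0.0131, 0.0006]))
        assert sum(m.share for m in g.medications) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="sum to zero"):
            normalize_shares(_group(counts=[0, 0]))

    def test_idempotent(self):
        g1 = normalize_shares(_group(weights=[0.5, 0.3]))
        assert normalize_shares(g1) == g1


ANTICO_OM = None  # filled per-test from the fixture


class TestOutcomes:
    def test_nurtec_discontinuations_from_printed_affected(self):
        om = OutcomeModel(
            "x", BoundedRange(0.09, 0.19), FlatRate(BoundedRange(0.5, 0.5))
        )
        d = discontinuations(BoundedRange(1612, 1971), om)
        assert d.low == pytest.approx(145.1, abs=0.05)
        assert d.high == pytest.approx(374.5, abs=0.05)

    def test_eliquis_discontinuations(self, anticoagulants):
        om = anticoagulants[0].outcome_model("anticoagulant")
        d = discontinuations(BoundedRange(734.8, 1784.5), om)
        assert d.low == pytest.approx(124.9, abs=0.05)
        assert d.high == pytest.approx(535.3, abs=0.1)

    def test_zero_discontinuation(self):
        om = OutcomeModel("x", BoundedRange(0, 0), FlatRate(BoundedRange(0.1, 0.2)))
        assert discontinuations(BoundedRange(5, 9), om) == BoundedRange(0, 0)

    def test_eliquis_adverse_events_coupled(self, anticoagulants):
        om = anticoagulants[0].outcome_model("anticoagulant")
        ae = adverse_events(BoundedRange(734.8, 1784.5), om)
        assert ae.low == pytest.approx(68.4, abs=0.05)
        assert ae.high == pytest.approx(580.0, abs=0.1)

    def test_humira_adverse_events_flat(self):
        om = OutcomeModel(
            "x", BoundedRange(0.06, 0.09), FlatRate(BoundedRange(0.15, 0.35))
        )
        ae = adverse_events(BoundedRange(444.9, 889.7), om)
        assert ae.low == pytest.approx(66.7, abs=0.05)
        assert ae.high == pytest.approx(311.4, abs=0.05)

    def test_zero_rate(self):
        om = OutcomeModel("x", BoundedRange(0.1, 0.2), FlatRate(BoundedRange(0, 0)))
        assert adverse_events(BoundedRange(5, 9), om) == BoundedRange(0, 0)


class TestRunScenario:
    def test_rows_cover_every_formulary_medication_pair(self, anticoagulants):
        table = run_scenario(anticoagulants[0])
        assert len(table.rows) == 8  # 2 formularies x 4 medications
        assert len({(r.formulary, r.medication) for r in table.rows}) == 8

    def test_conservation_per_group_and_formulary(self, case_studies):
        for s, _ in case_studies.values():
            table = run_scenario(s)
            for (f, gid), pool in table.pool_by_formulary_and_group.items():
                rows = [
                    r for r in table.rows if r.formulary == f and r.group_id == gid
                ]
                total_low = sum(r.affected.low for r in rows)
                total_high = sum(r.affected.high for r in rows)
                assert total_low == pytest.approx(pool.low, rel=1e-6)
                assert total_high == pytest.approx(pool.high, rel=1e-6)

    def test_migraine_groups_are_views_of_the_same_pool(self, migraine):
        # both subclasses partition the identical eligible pool; summing
        # across groups double-counts by design
        table = run_scenario(migraine[0])
        mabs = table.pool_by_formulary_and_group[("CVS", "mabs")]
        gepants = table.pool_by_formulary_and_group[("CVS", "gepants")]
        assert mabs == gepants

    def test_outcomes_bounded_by_affected(self, case_studies):
        for s, _ in case_studies.values():
            for r in run_scenario(s).rows:
                assert r.discontinue.low <= r.affected.low + 1e-12
                assert r.discontinue.high <= r.affected.high + 1e-12
                assert r.adverse_events.low <= r.affected.low + 1e-12
                assert r.adverse_events.high <= r.affected.high + 1e-12

    def test_formulary_ratio(self, anticoagulants):
        table = run_scenario(anticoagulants[0])
        for med in ("Eliquis", "Xarelto", "Pradaxa", "Savaysa"):
            cvs = table.row("CVS", med)
            esi = table.row("ESI", med)
            for col in ("affected", "discontinue", "adverse_events"):
                c, e = getattr(cvs, col), getattr(esi, col)
                assert e.low / c.low == pytest.approx(0.24 / 0.33, rel=1e-12)
                assert e.high / c.high == pytest.approx(0.24 / 0.33, rel=1e-12)

    def test_matches_independent_oracle_on_fixtures(self, case_studies):
        for s, _ in case_studies.values():
            table = run_scenario(s)
            oracle = impact_oracle(s)
            for r in table.rows:
                exp = oracle[(r.formulary, r.medication)]
                got = (
                    r.affected.low,
                    r.affected.high,
                    r.discontinue.low,
                    r.discontinue.high,
                    r.adverse_events.low,
                    r.adverse_events.high,
                )
                assert got == pytest.approx(exp, rel=1e-12)

    def test_matches_independent_oracle_on_synthetic(self):
        for seed in range(40):
            s = generate_scenario(GeneratorConfig(seed=seed, n_groups=1 + seed % 3))
            table = run_scenario(s)
            oracle = impact_oracle(s)
            for r in table.rows:
                exp = oracle[(r.formulary, r.medication)]
                got = (
                    r.affected.low,
                    r.affected.high,
                    r.discontinue.low,
                    r.discontinue.high,
                    r.adverse_events.low,
                    r.adverse_events.high,
                )
                assert got == pytest.approx(exp, rel=1e-9)

    def test_conservative_mode_widens_or_preserves(self):
        for seed in range(30):
            s = generate_scenario(GeneratorConfig(seed=seed))
            coupled = run_scenario(s, mode="coupled")
            conservative = run_scenario(s, mode="conservative")
            for rc, rv in zip(coupled.rows, conservative.rows):
                assert rv.adverse_events.low <= rc.adverse_events.low + 1e-12
                assert rv.adverse_events.high >= rc.adverse_events.high - 1e-12

    def test_prevalence_scaling_is_linear(self, anticoagulants):
        s = copy.deepcopy(anticoagulants[0])
        base = run_scenario(s)
        s.indication.prevalence = s.indication.prevalence.scale(1.7)
        # keep within [0,1]: 0.034*1.7 < 1
        scaled = run_scenario(s)
        for rb, rs in zip(base.rows, scaled.rows):
            assert rs.affected.low == pytest.approx(1.7 * rb.affected.low, rel=1e-12)
            assert rs.adverse_events.high == pytest.approx(
                1.7 * rb.adverse_events.high, rel=1e-12
            )
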
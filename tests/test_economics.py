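import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tkicea.cohort_model import ModelSettings, build_trace
from tkicea.economics import (AERecord, ae_burden, build_arm_configs, cycle_cost,
                              evaluate_strategies, filter_adverse_events,
                              incremental_analysis, price_threshold, total_costs)


class TestAdverseEvents:
    def test_inclusion_threshold_is_inclusive(self):
        records = [AERecord("rash", "gefitinib", 0.014),
                   AERecord("diarrhoea", "gefitinib", 0.015),
                   AERecord("anaemia", "gefitinib", 0.10)]
        kept = filter_adverse_events(records)
        assert [r.name for r in kept] == ["diarrhoea", "anaemia"]

    def test_empty_input(self):
        assert filter_adverse_events([]) == []

    def test_burden_arithmetic(self):
        dt = 30 / 365.25
        records = [AERecord("neutropenia", "pemetrexed_cisplatin", 0.10,
                            disutility=-0.090, unit_cost=1405)]
        dec, cost = ae_burden(records, dt)
        assert dec == pytest.approx(0.10 * -0.090 * dt)
        assert cost == pytest.approx(140.5)

    def test_burden_additivity(self):
        dt = 30 / 365.25
        a = AERecord("a", "x", 0.05, -0.04, 700)
        b = AERecord("b", "x", 0.02, -0.10, 2000)
        dec_ab, cost_ab = ae_burden([a, b], dt)
        dec_a, cost_a = ae_burden([a], dt)
        dec_b, cost_b = ae_burden([b], dt)
        assert dec_ab == pytest.approx(dec_a + dec_b)
        assert cost_ab == pytest.approx(cost_a + cost_b)

    def test_zero_incidence_is_free(self):
        assert ae_burden([AERecord("a", "x", 0.0, -0.1, 1000)], 0.08) == (0.0, 0.0)


class TestCycleCost:
    def row(self, **kwargs):
        base = {"pf1": 0.0, "pf2": 0.0, "pd2": 0.0, "dead": 0.0,
                "prog_inflow": 0.0, "death_inflow": 0.0}
        base.update(kwargs)
        return pd.Series(base)

    def test_full_bsc_occupancy(self, book):
        assert cycle_cost(self.row(pd2=1.0), "gefitinib", book) == pytest.approx(1775)

    def test_everyone_dead_costs_nothing(self, book):
        assert cycle_cost(self.row(dead=1.0), "gefitinib", book) == 0.0

    def test_death_flow_triggers_end_of_life(self, book):
        assert cycle_cost(self.row(dead=1.0, death_inflow=0.10), "gefitinib", book) \
            == pytest.approx(219.60)

    def test_progression_one_offs_depend_on_arm_class(self, book):
        std = cycle_cost(self.row(prog_inflow=1.0), "erlotinib", book)
        osi = cycle_cost(self.row(prog_inflow=1.0), "osimertinib", book)
        assert std == pytest.approx(929 + 1250)  # mutation test + CNS, standard TKI
        assert osi == pytest.approx(535)  # CNS only, no T790M testing


def zeroed_book(book, keep=()):
    """Copy of the book with every unit cost zeroed except the kept paths."""
    new = book.copy()
    for path, _ in book.flatten(("costs", "ae_unit_costs")).items():
        if path not in keep:
            new = new.with_value(path, 0.0)
    return new


class TestTotalCosts:
    def test_zero_unit_costs_cost_nothing(self, book, settings):
        zb = zeroed_book(book)
        arm = build_arm_configs(zb)["gefitinib"]
        trace = build_trace(arm, settings)
        total, first, cat = total_costs(trace, "gefitinib", zb, settings)
        assert total == 0.0 and first == 0.0

    def test_discounting_reduces_totals(self, book):
        arm = build_arm_configs(book)["afatinib"]
        totals = []
        for rate in (0.0, 0.04):
            s = ModelSettings(discount_costs=rate)
            trace = build_trace(arm, s)
            totals.append(total_costs(trace, "afatinib", book, s)[0])
        assert totals[1] < totals[0]

    def test_category_decomposition_sums_to_total(self, book, settings):
        arm = build_arm_configs(book)["osimertinib"]
        trace = build_trace(arm, settings)
        total, _, cat = total_costs(trace, "osimertinib", book, settings)
        assert total == pytest.approx(sum(cat.values()))

    def test_first_line_subtotal_isolates_first_line(self, book, settings):
        """With second-line and societal components zeroed, total == first-line."""
        keep = {"costs.drug_per_cycle.gefitinib", "costs.outpatient_visit",
                "costs.laboratory", "costs.tumour_assessment",
                "costs.travel_per_visit", "costs.productivity_loss"}
        zb = zeroed_book(book, keep=keep)
        # monitoring while on second-line treatment is a second-line component
        zb.data["resource_schedule"]["monitoring_states"] = ["pf1"]
        arm = build_arm_configs(zb)["gefitinib"]
        trace = build_trace(arm, settings)
        total, first, _ = total_costs(trace, "gefitinib", zb, settings)
        assert total == pytest.approx(first)

    def test_single_cycle_drug_only_closed_form(self, book):
        # one cycle, full progression-free occupancy, only the drug cost kept:
        # the half-cycle-corrected total is the trapezoid occupancy x price
        zb = zeroed_book(book, keep={"costs.drug_per_cycle.gefitinib"})
        settings = ModelSettings(max_cycles=1, discount_costs=0.0)
        arm = build_arm_configs(zb)["gefitinib"]
        trace = build_trace(arm, settings)
        total, _, _ = total_costs(trace, "gefitinib", zb, settings)
        occ = 0.5 * (trace.frame["pf1"].iloc[0] + trace.frame["pf1"].iloc[1])
        assert total == pytest.approx(occ * 2526)


class TestIncrementalAnalysis:
    def test_strict_dominance_flagged(self):
        df = pd.DataFrame({"strategy": ["A", "B"], "cost": [10.0, 5.0],
                           "ly": [1.0, 2.0], "qaly": [1.0, 2.0]})
        ce = incremental_analysis(df)
        flags = dict(zip(ce.incremental["strategy"], ce.incremental["status"]))
        assert flags["A"] == "dominated by B"
        assert flags["B"] == ""

    def test_dominance_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = rng.integers(3, 7)
            df = pd.DataFrame({
                "strategy": [f"s{i}" for i in range(n)],
                "cost": rng.uniform(1e4, 1e5, n).round(0),
                "ly": np.nan, "qaly": rng.uniform(0.5, 3.0, n).round(3)})
            df["ly"] = df["qaly"] * 1.4
            ce = incremental_analysis(df)
            flagged = {r.strategy for r in ce.incremental.itertuples()
                       if r.status.startswith("dominated")}
            brute = set()
            for i, j in itertools.permutations(range(n), 2):
                if (df.qaly[j] >= df.qaly[i] and df.cost[j] <= df.cost[i]
                        and (df.qaly[j] > df.qaly[i] or df.cost[j] < df.cost[i])):
                    brute.add(df.strategy[i])
            assert flagged == brute

    def test_frontier_icers_strictly_increase(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = 6
            df = pd.DataFrame({
                "strategy": [f"s{i}" for i in range(n)],
                "cost": rng.uniform(1e4, 2e5, n),
                "qaly": rng.uniform(0.5, 3.0, n)})
            df["ly"] = df["qaly"]
            ce = incremental_analysis(df)
            icers = ce.incremental["icer_qaly"].dropna().to_numpy()
            assert np.all(np.diff(icers) > 0)

    def test_extended_dominance(self):
        # B lies above the A-C segment: its ICER vs A exceeds C's vs B
        df = pd.DataFrame({"strategy": ["A", "B", "C"],
                           "cost": [0.0, 90_000.0, 100_000.0],
                           "qaly": [0.0, 1.0, 2.0]})
        df["ly"] = df["qaly"]
        ce = incremental_analysis(df)
        flags = dict(zip(ce.incremental["strategy"], ce.incremental["status"]))
        assert flags["B"] == "extendedly dominated"
        row_c = ce.incremental.set_index("strategy").loc["C"]
        assert row_c["icer_qaly"] == pytest.approx(50_000)

    def test_base_case_erlotinib_dominates_gefitinib(self, base_results):
        ce = incremental_analysis(base_results)
        flags = dict(zip(ce.incremental["strategy"], ce.incremental["status"]))
        assert flags["gefitinib"] == "dominated by erlotinib"


class TestPriceThreshold:
    def test_already_cost_effective_returns_zero(self, book):
        assert price_threshold(book, wtp=2e6) == 0.0

    def test_root_in_unit_interval_and_monotone_in_wtp(self, book):
        p80 = price_threshold(book, wtp=80_000)
        p90 = price_threshold(book, wtp=90_000)
        assert 0 < p80 < 1
        assert p90 <= p80

    def test_bisection_matches_linear_oracle(self, book, settings):
        """With only drug costs non-zero the ICER is linear in the price."""
        keep = {"costs.drug_per_cycle.gefitinib", "costs.drug_per_cycle.erlotinib",
                "costs.drug_per_cycle.afatinib", "costs.drug_per_cycle.osimertinib",
                "costs.drug_per_cycle.pemetrexed_cisplatin"}
        zb = zeroed_book(book, keep=keep)

        def icer_at(mult):
            trial = zb.with_value("costs.drug_per_cycle.osimertinib", 6106 * mult)
            res = evaluate_strategies(trial, settings).set_index("strategy")
            dc = res.loc["osimertinib", "cost"] - res.loc["afatinib", "cost"]
            dq = res.loc["osimertinib", "qaly"] - res.loc["afatinib", "qaly"]
            return dc / dq

        # ICER(m) = a*m + b on the segment where afatinib stays on the
        # frontier (the comparator switches to erlotinib at deep discounts);
        # analytic root of a*m + b = wtp vs the bisection result
        m_lo, m_hi = 0.7, 1.0
        i_lo, i_hi = icer_at(m_lo), icer_at(m_hi)
        wtp = 0.5 * (i_lo + i_hi)
        analytic_mult = m_lo + (wtp - i_lo) / (i_hi - i_lo) * (m_hi - m_lo)
        found = price_threshold(zb, wtp=wtp, tol=1e-4)
        assert found == pytest.approx(1.0 - analytic_mult, abs=5e-4)
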
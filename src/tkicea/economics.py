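"""Societal costing of the cohort trace, incremental analysis, and price threshold.

Per-cycle costs attach to state occupancy (drug acquisition while
progression-free on each line, a monitoring bundle while on treatment, best
supportive care after second-line progression, home/informal care hours,
indirect medical costs spread over life-years); one-off costs trigger on
flows (mutation testing and CNS-progression management at first-line
progression, end-of-life care at death) or at model entry (friction-cost
productivity loss). Costs discount at 4% per year, effects at 1.5%.

The incremental analysis sorts strategies by effect, flags strict and
extended dominance, and reports ICERs along the efficient frontier. The
price-threshold search bisects an acquisition-cost multiplier (applied to
first- and second-line use of the drug) until the strategy's frontier ICER
falls below the willingness-to-pay threshold.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort_model import ArmConfig, ModelSettings, Trace, build_trace, life_years, qalys
from .survfit import SurvParams

__all__ = [
    "ParameterBook", "AERecord", "CEResult",
    "filter_adverse_events", "ae_burden", "cycle_cost", "total_costs",
    "build_arm_configs", "evaluate_strategies", "incremental_analysis",
    "price_threshold",
]

STRATEGIES = ("gefitinib", "erlotinib", "afatinib", "osimertinib")
STANDARD_TKIS = ("gefitinib", "erlotinib", "afatinib")


@dataclass
class ParameterBook:
    """Structured model inputs: unit costs, utilities, survival laws, PSA tags.

    A thin wrapper over the nested mapping loaded from the packaged YAML
    parameter file, with dotted-path access used by the sensitivity analyses.
    """

    data: dict

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "ParameterBook":
        if path is None:
            text = resources.files("tkicea.data").joinpath("table2.yaml").read_text()
        else:
            text = Path(path).read_text()
        book = cls(yaml.safe_load(text))
        book.validate()
        return book

    def validate(self) -> None:
        flat = self.flatten()
        for path, value in flat.items():
            if path.startswith("costs.") or path.startswith("ae_unit_costs."):
                if value < 0:
                    raise ValueError(f"negative cost at {path}")
            elif path.startswith("utilities."):
                if not (0 <= value <= 1):
                    raise ValueError(f"utility outside [0, 1] at {path}")
            elif path.startswith("ae_disutilities."):
                if value > 0:
                    raise ValueError(f"positive disutility at {path}")
        for arm, mix in self.data["second_line_mix"].items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
                raise ValueError(f"second-line mix for {arm} must be >= 0 and sum to 1")

    def copy(self) -> "ParameterBook":
        return ParameterBook(copy.deepcopy(self.data))

    def get(self, path: str):
        node = self.data
        for part in path.split("."):
            node = node[part]
        return node

    def with_value(self, path: str, value) -> "ParameterBook":
        new = self.copy()
        node = new.data
        parts = path.split(".")
        for part in parts[:-1]:
            node = node[part]
        if parts[-1] not in node:
            raise KeyError(f"unknown parameter {path!r}")
        node[parts[-1]] = value
        return new

    def flatten(self, sections: tuple[str, ...] = ("costs", "ae_unit_costs", "utilities",
                                                   "ae_disutilities", "survival")) -> dict:
        out: dict[str, float] = {}

        def walk(node, prefix):
            if isinstance(node, dict):
                for key, sub in node.items():
                    walk(sub, f"{prefix}.{key}" if prefix else key)
            elif isinstance(node, (int, float)) and not isinstance(node, bool):
                out[prefix] = float(node)

        for section in sections:
            if section in self.data:
                walk(self.data[section], section)
        return out

    @property
    def utilities(self) -> dict[str, float]:
        u = self.data["utilities"]
        return {"pf1": u["progression_free"], "pf2": u["progressed"],
                "pd2": u["progressed_second_line"]}

    @property
    def schedule(self) -> dict:
        return self.data["resource_schedule"]


@dataclass(frozen=True)
class AERecord:
    name: str
    arm: str
    incidence: float
    disutility: float = 0.0
    unit_cost: float = 0.0
    grade: int = 3

    def __post_init__(self):
        if not (0 <= self.incidence <= 1):
            raise ValueError("incidence must lie in [0, 1]")


@dataclass
class CEResult:
    """Per-strategy discounted totals plus the incremental frontier table."""

    strategies: pd.DataFrame  # strategy, cost, cost_first_line, ly, qaly
    incremental: pd.DataFrame  # ordered by effect, with dominance flags / ICERs


def filter_adverse_events(records: list[AERecord], threshold: float = 0.015) -> list[AERecord]:
    """Keep severe adverse events whose incidence reaches the inclusion threshold."""
    return [r for r in records if r.incidence >= threshold]


def ae_burden(records: list[AERecord], dt_years: float) -> tuple[float, float]:
    """One-off per-entrant QALY decrement and cost from (already filtered) AEs.

    The decrement assumes each event lasts one model cycle, so incidence x
    disutility is scaled by the cycle length in years. Discounting to the
    line-entry time happens where the burden is applied.
    """
    decrement = sum(r.incidence * r.disutility for r in records) * dt_years
    cost = sum(r.incidence * r.unit_cost for r in records)
    return decrement, cost


def _ae_records_for(book: ParameterBook, arm: str) -> list[AERecord]:
    incidences = book.data.get("ae_incidence", {}).get(arm, {}) or {}
    records = []
    for name, inc in incidences.items():
        records.append(AERecord(
            name=name, arm=arm, incidence=float(inc),
            disutility=float(book.data["ae_disutilities"].get(name, 0.0)),
            unit_cost=float(book.data["ae_unit_costs"].get(name, 0.0))))
    return records


def _monitoring_per_cycle(book: ParameterBook) -> float:
    c, s = book.data["costs"], book.schedule
    visits = s["outpatient_visits_per_cycle"]
    return (visits * c["outpatient_visit"]
            + s["lab_panels_per_cycle"] * c["laboratory"]
            + c["tumour_assessment"] / s["tumour_assessment_interval_cycles"]
            + visits * s["travel_events_per_visit"] * c["travel_per_visit"])


def _second_line_drug_cost(book: ParameterBook, option: str) -> float:
    c = book.data["costs"]
    if option == "osimertinib_2l":
        return c["drug_per_cycle"]["osimertinib"]
    if option == "pemetrexed_cisplatin":
        return c["drug_per_cycle"]["pemetrexed_cisplatin"] + c["drug_administration"]
    raise KeyError(f"no per-cycle drug cost defined for second-line option {option!r}")


def _care_cost_per_cycle(book: ParameterBook, state: str) -> float:
    c, s = book.data["costs"], book.schedule
    return (s["home_care_hours_per_cycle"].get(state, 0) * c["home_care_per_hour"]
            + s["informal_care_hours_per_cycle"].get(state, 0) * c["informal_care_per_hour"])


def cycle_cost(row: pd.Series, arm: str, book: ParameterBook,
               options: tuple[str, ...] = ()) -> float:
    """Undiscounted cost of one trace row (occupancy terms plus flow one-offs)."""
    c = book.data["costs"]
    monitor = _monitoring_per_cycle(book)
    states = book.schedule["monitoring_states"]
    total = row["pf1"] * (c["drug_per_cycle"][arm] + (monitor if "pf1" in states else 0)
                          + _care_cost_per_cycle(book, "pf1"))
    for option in options:
        col = f"pf2_{option}"
        if col in row:
            total += row[col] * _second_line_drug_cost(book, option)
    total += row["pf2"] * ((monitor if "pf2" in states else 0) + _care_cost_per_cycle(book, "pf2"))
    total += row["pd2"] * (c["bsc_per_cycle"] + _care_cost_per_cycle(book, "pd2"))
    # flow-triggered one-offs
    cns = c["cns_progression"]["osimertinib" if arm == "osimertinib" else "standard_tki"]
    oneoff = row["prog_inflow"] * cns * book.schedule["cns_event_fraction"]
    if arm in STANDARD_TKIS:
        oneoff += row["prog_inflow"] * c["mutation_test"]
    oneoff += row["death_inflow"] * c["end_of_life"]
    return float(total + oneoff)


def total_costs(trace: Trace, arm: str, book: ParameterBook,
                settings: ModelSettings = ModelSettings(),
                ae_costs: dict | None = None) -> tuple[float, float, dict]:
    """Discounted total cost, first-line subtotal, and category breakdown.

    Occupancy terms are half-cycle corrected (trapezoid); flow-triggered
    one-offs are discounted at the mid-cycle time of the cycle in which they
    occur. ``ae_costs`` optionally carries per-entrant adverse-event costs as
    {"first_line": x, "second_line": {option: y}}.
    """
    f = trace.frame
    c = book.data["costs"]
    n = len(f) - 1
    t_mid = (np.arange(n) + 0.5) * settings.years_per_cycle
    disc = (1.0 + settings.discount_costs) ** (-t_mid)
    trap = lambda col: 0.5 * (col[:-1] + col[1:]) if settings.half_cycle else col[1:]

    pf1 = trap(f["pf1"].to_numpy())
    pf2 = trap(f["pf2"].to_numpy())
    pd2 = trap(f["pd2"].to_numpy())
    alive = trap(1.0 - f["dead"].to_numpy())
    prog_in = f["prog_inflow"].to_numpy()[1:]
    death_in = f["death_inflow"].to_numpy()[1:]

    monitor = _monitoring_per_cycle(book)
    states = book.schedule["monitoring_states"]
    cat: dict[str, float] = {}
    cat["drug_first_line"] = float(np.sum(pf1 * c["drug_per_cycle"][arm] * disc))
    cat["monitoring_first_line"] = float(np.sum(pf1 * (monitor if "pf1" in states else 0) * disc))
    drug2 = 0.0
    for option in trace.options:
        col = f"pf2_{option}"
        if col in f:
            occ = trap(f[col].to_numpy())
            drug2 += float(np.sum(occ * _second_line_drug_cost(book, option) * disc))
    cat["drug_second_line"] = drug2
    cat["monitoring_second_line"] = float(np.sum(pf2 * (monitor if "pf2" in states else 0) * disc))
    cat["bsc"] = float(np.sum(pd2 * c["bsc_per_cycle"] * disc))
    care = (pf1 * _care_cost_per_cycle(book, "pf1") + pf2 * _care_cost_per_cycle(book, "pf2")
            + pd2 * _care_cost_per_cycle(book, "pd2"))
    cat["home_informal_care"] = float(np.sum(care * disc))

    le_years = float(np.sum(alive) * settings.years_per_cycle)  # undiscounted LE
    if book.schedule["indirect_medical_allocation"] == "per_life_year" and le_years > 0:
        rate = c["indirect_medical_lifetime"] / le_years
        cat["indirect_medical"] = float(np.sum(alive * rate * settings.years_per_cycle * disc))
    else:
        cat["indirect_medical"] = float(c["indirect_medical_lifetime"])

    cns = c["cns_progression"]["osimertinib" if arm == "osimertinib" else "standard_tki"]
    oneoff = prog_in * cns * book.schedule["cns_event_fraction"]
    if arm in STANDARD_TKIS:
        oneoff = oneoff + prog_in * c["mutation_test"]
    cat["progression_one_offs"] = float(np.sum(oneoff * disc))
    cat["end_of_life"] = float(np.sum(death_in * c["end_of_life"] * disc))
    cat["productivity_loss"] = float(c["productivity_loss"])  # one-off at entry, t=0

    ae_total = 0.0
    if ae_costs:
        ae_total += float(ae_costs.get("first_line", 0.0))
        mix = trace.metadata.get("second_line_mix", {})
        for option, per_entrant in ae_costs.get("second_line", {}).items():
            ae_total += float(np.sum(prog_in * mix.get(option, 0.0) * per_entrant * disc))
    cat["adverse_events"] = ae_total

    total = sum(cat.values())
    comp_map = {"drug": "drug_first_line", "monitoring": "monitoring_first_line",
                "productivity_loss": "productivity_loss"}
    first_line = sum(cat[comp_map[comp]] for comp in
                     book.schedule["first_line_cost_components"])
    return total, first_line, cat


def build_arm_configs(book: ParameterBook) -> dict[str, ArmConfig]:
    """Assemble the four first-line strategies from the parameter book."""
    surv = book.data["survival"]
    second_pfs = {name: SurvParams(**spec)
                  for name, spec in surv["second_line"]["pfs"].items()}
    second_os = {name: SurvParams(**spec)
                 for name, spec in surv["second_line"]["os"].items()}
    arms = {}
    for strat in STRATEGIES:
        arms[strat] = ArmConfig(
            name=strat,
            pfs=SurvParams(**surv["pfs"][strat]),
            os=SurvParams(**surv["os"][strat]),
            second_line_mix=dict(book.data["second_line_mix"][strat]),
            second_line_pfs=second_pfs,
            second_line_os=second_os,
        )
    return arms


def evaluate_strategies(book: ParameterBook,
                        settings: ModelSettings = ModelSettings(),
                        ae_threshold: float = 0.015) -> pd.DataFrame:
    """Run the cohort model for every strategy; discounted cost, LY, QALY each."""
    arms = build_arm_configs(book)
    dt_years = settings.years_per_cycle
    rows = []
    for strat, arm in arms.items():
        trace = build_trace(arm, settings)
        first = filter_adverse_events(_ae_records_for(book, strat), ae_threshold)
        dec1, cost1 = ae_burden(first, dt_years)
        dec2, cost2 = {}, {}
        for option in arm.second_line_mix:
            recs = filter_adverse_events(_ae_records_for(book, option), ae_threshold)
            dec2[option], cost2[option] = ae_burden(recs, dt_years)
        ly = life_years(trace, settings)
        q = qalys(trace, book.utilities,
                  {"first_line": dec1, "second_line": dec2}, settings)
        cost, cost_fl, cat = total_costs(trace, strat, book, settings,
                                         {"first_line": cost1, "second_line": cost2})
        rows.append({"strategy": strat, "cost": cost, "cost_first_line": cost_fl,
                     "ly": ly, "qaly": q, **{f"cost_{k}": v for k, v in cat.items()}})
    return pd.DataFrame(rows)


def incremental_analysis(results: pd.DataFrame, effect: str = "qaly") -> CEResult:
    """Order strategies by effect, flag dominance, and compute frontier ICERs."""
    if len(results) < 2:
        raise ValueError("incremental analysis needs at least two strategies")
    df = results.sort_values([effect, "cost"], ignore_index=True).copy()
    n = len(df)
    status = [""] * n
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ge_eff = df.loc[j, effect] >= df.loc[i, effect]
            le_cost = df.loc[j, "cost"] <= df.loc[i, "cost"]
            strict = (df.loc[j, effect] > df.loc[i, effect]) or (df.loc[j, "cost"] < df.loc[i, "cost"])
            if ge_eff and le_cost and strict:
                status[i] = f"dominated by {df.loc[j, 'strategy']}"
                break
            if df.loc[j, effect] == df.loc[i, effect] and df.loc[j, "cost"] == df.loc[i, "cost"] and j < i:
                status[i] = "tied (ICER undefined)"

    # extended dominance on the surviving frontier
    while True:
        idx = [i for i in range(n) if not status[i]]
        if len(idx) < 3:
            break
        icers = []
        for a, b in zip(idx[:-1], idx[1:]):
            de = df.loc[b, effect] - df.loc[a, effect]
            icers.append((df.loc[b, "cost"] - df.loc[a, "cost"]) / de if de > 0 else math.inf)
        removed = False
        for pos in range(len(icers) - 1):
            if icers[pos] > icers[pos + 1]:
                status[idx[pos + 1]] = "extendedly dominated"
                removed = True
                break
        if not removed:
            break

    df["status"] = status
    df["delta_cost"] = np.nan
    df[f"delta_{effect}"] = np.nan
    df["delta_ly"] = np.nan
    df["icer_qaly"] = np.nan
    df["icer_ly"] = np.nan
    frontier = [i for i in range(n) if not status[i]]
    for a, b in zip(frontier[:-1], frontier[1:]):
        dc = df.loc[b, "cost"] - df.loc[a, "cost"]
        dq = df.loc[b, "qaly"] - df.loc[a, "qaly"]
        dl = df.loc[b, "ly"] - df.loc[a, "ly"]
        df.loc[b, "delta_cost"] = dc
        df.loc[b, f"delta_{effect}"] = df.loc[b, effect] - df.loc[a, effect]
        df.loc[b, "delta_ly"] = dl
        df.loc[b, "icer_qaly"] = dc / dq if dq > 0 else math.inf
        df.loc[b, "icer_ly"] = dc / dl if dl > 0 else math.inf

    cols = ["strategy", "cost", "cost_first_line", "ly", "qaly", "status",
            "delta_cost", "delta_qaly", "delta_ly", "icer_qaly", "icer_ly"]
    cols = [c for c in cols if c in df.columns]
    return CEResult(strategies=results.copy(), incremental=df[cols])


def _frontier_icer(results: pd.DataFrame, strategy: str) -> float:
    ce = incremental_analysis(results)
    row = ce.incremental[ce.incremental["strategy"] == strategy].iloc[0]
    if row["status"]:
        return math.inf  # dominated: never cost-effective at any threshold
    if math.isnan(row["icer_qaly"]):
        return 0.0  # cheapest frontier strategy: cost-effective by default
    return float(row["icer_qaly"])


def price_threshold(book: ParameterBook, wtp: float, strategy: str = "osimertinib",
                    settings: ModelSettings = ModelSettings(),
                    tol: float = 1e-3) -> float | None:
    """Smallest acquisition-price reduction making the strategy cost-effective.

    The multiplier applies to the drug's per-cycle acquisition cost in both
    first- and second-line use. Returns 0.0 if the strategy's frontier ICER
    is already at or below ``wtp``, ``None`` if a full price waiver is not
    enough, else the reduction fraction found by bisection in (0, 1).
    """
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be positive")

    def icer_at(reduction: float) -> float:
        trial = book.with_value(f"costs.drug_per_cycle.{strategy}",
                                book.get(f"costs.drug_per_cycle.{strategy}") * (1 - reduction))
        return _frontier_icer(evaluate_strategies(trial, settings), strategy)

    if icer_at(0.0) <= wtp:
        return 0.0
    if icer_at(1.0) > wtp:
        return None
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if icer_at(mid) <= wtp:
            hi = mid
        else:
            lo = mid
    return hi
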
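"""Partitioned-survival cohort trace and discounted life-year/QALY integration.

Three first-line health states are read directly off the extrapolated
curves on a 30-day cycle grid: progression-free (PFS curve), dead
(1 - OS curve), and progressed (the remainder). The progressed compartment
is split into second-line progression-free and second-line progressed by
convolving per-cycle progression inflows with the exponential second-line
PFS laws, capped so the split never exceeds the progressed total.

Effects use half-cycle correction (trapezoid averaging of cycle-boundary
occupancies) and annual discounting evaluated at mid-cycle times. Cycle k
corresponds to t = k * (cycle_days / days_per_month) months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survfit import SurvParams, survival_at

__all__ = ["ArmConfig", "ModelSettings", "Trace", "build_trace",
           "partition_second_line", "life_years", "qalys"]


@dataclass(frozen=True)
class ModelSettings:
    cycle_days: float = 30.0
    days_per_month: float = 30.4375
    discount_effects: float = 0.015  # per year
    discount_costs: float = 0.04  # per year
    half_cycle: bool = True
    epsilon: float = 1e-3  # stop once cohort survival falls below this
    max_cycles: int = 300

    def __post_init__(self):
        if not (0 <= self.discount_effects < 1 and 0 <= self.discount_costs < 1):
            raise ValueError("discount rates must lie in [0, 1)")
        if self.cycle_days <= 0:
            raise ValueError("cycle_days must be positive")

    @property
    def months_per_cycle(self) -> float:
        return self.cycle_days / self.days_per_month

    @property
    def years_per_cycle(self) -> float:
        return self.cycle_days / 365.25


@dataclass(frozen=True)
class ArmConfig:
    """One first-line strategy: its survival laws and second-line mix."""

    name: str
    pfs: SurvParams
    os: SurvParams
    second_line_mix: dict[str, float]  # option -> fraction of progressors
    second_line_pfs: dict[str, SurvParams]
    second_line_os: dict[str, SurvParams] | None = None  # diagnostic only

    def __post_init__(self):
        total = sum(self.second_line_mix.values())
        if any(v < 0 for v in self.second_line_mix.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError("second-line mix fractions must be >= 0 and sum to 1")
        missing = set(self.second_line_mix) - set(self.second_line_pfs)
        if missing:
            raise ValueError(f"second-line PFS missing for {sorted(missing)}")


@dataclass
class Trace:
    """Per-cycle cohort occupancy with entry flows.

    ``frame`` columns: cycle, months, pf1, pf2, pd2, dead, pf2_<option>...,
    prog_inflow (new progressors during the cycle), death_inflow.
    """

    frame: pd.DataFrame
    options: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)


def _discount_factors(settings: ModelSettings, rate: float, n_cycles: int) -> np.ndarray:
    """Discount factor per cycle interval, evaluated at mid-cycle time."""
    t_mid_years = (np.arange(n_cycles) + 0.5) * settings.years_per_cycle
    return (1.0 + rate) ** (-t_mid_years)


def _trapezoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (x[:-1] + x[1:])


def build_trace(arm: ArmConfig, settings: ModelSettings = ModelSettings()) -> Trace:
    """Evaluate state occupancy on the cycle grid and split the progressed state."""
    k = np.arange(settings.max_cycles + 1)
    t = k * settings.months_per_cycle
    s_pfs = survival_at(arm.pfs, t)
    s_os = survival_at(arm.os, t)
    bad = s_pfs > s_os + 1e-9
    if np.any(bad):
        first = int(np.argmax(bad))
        raise ValueError(
            f"arm {arm.name}: PFS exceeds OS at t={t[first]:.2f} months; inconsistent inputs")

    metadata: dict = {"second_line_mix": dict(arm.second_line_mix)}
    alive = s_os
    # truncate once the cohort is (almost) extinct
    below = np.nonzero(alive < settings.epsilon)[0]
    if len(below) > 0:
        end = int(below[0])
        k, t = k[: end + 1], t[: end + 1]
        s_pfs, s_os, alive = s_pfs[: end + 1], s_os[: end + 1], alive[: end + 1]
    elif alive[-1] > 0.01:
        metadata["horizon_warning"] = (
            f"horizon cap {settings.max_cycles} cycles reached with "
            f"{alive[-1]:.1%} of the cohort alive")

    pf1 = s_pfs
    dead = 1.0 - s_os
    prog = np.maximum(0.0, s_os - s_pfs)
    prog_inflow = np.maximum(0.0, -np.diff(pf1, prepend=1.0))
    death_inflow = np.maximum(0.0, np.diff(dead, prepend=0.0))

    frame = pd.DataFrame({
        "cycle": k, "months": t, "pf1": pf1, "pf2": 0.0, "pd2": prog,
        "dead": dead, "prog_inflow": prog_inflow, "death_inflow": death_inflow,
    })
    trace = Trace(frame=frame, options=tuple(arm.second_line_mix), metadata=metadata)
    return partition_second_line(trace, arm, settings)


def partition_second_line(trace: Trace, arm: ArmConfig,
                          settings: ModelSettings = ModelSettings()) -> Trace:
    """Split the progressed compartment by second-line option.

    A sub-cohort progressing during cycle j contributes to second-line
    progression-free occupancy at cycle k with weight S_2L(t_k - t_j)
    (discrete convolution); occupancies are rescaled so the split never
    exceeds the progressed total, the excess falling to second-line
    progressed disease.
    """
    f = trace.frame
    t = f["months"].to_numpy()
    w = f["prog_inflow"].to_numpy()
    prog = (f["pf2"] + f["pd2"]).to_numpy()

    raw: dict[str, np.ndarray] = {}
    for option, frac in arm.second_line_mix.items():
        s2 = survival_at(arm.second_line_pfs[option], t)
        raw[option] = frac * np.convolve(w, s2)[: len(t)]
    total_raw = sum(raw.values()) if raw else np.zeros_like(t)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(total_raw > prog, prog / np.where(total_raw > 0, total_raw, 1.0), 1.0)
    pf2 = np.zeros_like(t)
    for option, arr in raw.items():
        capped = arr * scale
        f[f"pf2_{option}"] = capped
        pf2 += capped
    f["pf2"] = pf2
    f["pd2"] = prog - pf2
    return trace


def life_years(trace: Trace, settings: ModelSettings = ModelSettings()) -> float:
    """Discounted life-years: trapezoid occupancy x cycle length x discount."""
    alive = 1.0 - trace.frame["dead"].to_numpy()
    occ = _trapezoid(alive) if settings.half_cycle else alive[1:]
    disc = _discount_factors(settings, settings.discount_effects, len(occ))
    return float(np.sum(occ * settings.years_per_cycle * disc))


def qalys(trace: Trace, utilities: dict[str, float],
          ae_decrements: dict | None = None,
          settings: ModelSettings = ModelSettings()) -> float:
    """Discounted QALYs with one-off adverse-event decrements at line entry.

    ``utilities`` must define pf1, pf2 and pd2. ``ae_decrements`` holds the
    per-entrant QALY decrement per treatment line: ``first_line`` applies to
    the whole cohort at model entry (undiscounted), ``second_line`` maps each
    option to a decrement applied to progression inflows weighted by the mix,
    discounted at entry time.
    """
    missing = {"pf1", "pf2", "pd2"} - set(utilities)
    if missing:
        raise ValueError(f"missing utilities for states: {sorted(missing)}")
    f = trace.frame
    value = utilities["pf1"] * f["pf1"].to_numpy() + utilities["pd2"] * f["pd2"].to_numpy()
    value = value + utilities["pf2"] * f["pf2"].to_numpy()
    occ = _trapezoid(value) if settings.half_cycle else value[1:]
    disc = _discount_factors(settings, settings.discount_effects, len(occ))
    total = float(np.sum(occ * settings.years_per_cycle * disc))

    if ae_decrements:
        total += float(ae_decrements.get("first_line", 0.0))
        second = ae_decrements.get("second_line", {})
        if second:
            w = f["prog_inflow"].to_numpy()[1:]  # inflow during cycle k
            for option, dec in second.items():
                frac_col = f"pf2_{option}"
                if frac_col not in f:
                    continue
                frac = trace.metadata.get("second_line_mix", {}).get(option, 0.0)
                total += float(np.sum(w * dec * disc) * frac)
    return total
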
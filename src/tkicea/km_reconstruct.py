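"""Recreate individual patient data from digitized Kaplan-Meier curves.

Published trial figures give survival probabilities at read-off time points
plus numbers at risk at a coarser grid. Within each risk-table interval,
censoring is assumed uniformly distributed; the censoring total is solved so
that the risk set implied at the end of the interval matches the next
reported number at risk, while events at each digitized drop follow from the
Kaplan-Meier ratio given the current risk set (the Hoyle-Henley scheme).
Implied fractional counts are converted to integers by largest-remainder
allocation so that events + censorings always equal the cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import optimize

__all__ = ["KMCurve", "RiskTable", "recreate_ipd", "km_estimate"]


@dataclass(frozen=True)
class KMCurve:
    """Digitized survival coordinates (times in months, S in (0, 1])."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if len(t) != len(s):
            raise ValueError("times and survival differ in length")
        if np.any(np.diff(t) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any(np.diff(s) > 1e-12):
            rise = int(np.argmax(np.diff(s) > 1e-12))
            raise ValueError(f"survival rises between t={t[rise]} and t={t[rise + 1]}")
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("survival must lie in [0, 1]")


@dataclass(frozen=True)
class RiskTable:
    """Numbers at risk reported at the figure's risk-table times."""

    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_at_risk, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_at_risk", n)
        if len(t) != len(n):
            raise ValueError("times and n_at_risk differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("risk-table times must be increasing")
        if np.any(np.diff(n) > 0):
            grow = int(np.argmax(np.diff(n) > 0))
            raise ValueError(f"risk set grows at t={t[grow + 1]}")
        if np.any(n < 0):
            raise ValueError("numbers at risk must be non-negative")


def _largest_remainder(values: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals to integers preserving their exact sum."""
    values = np.maximum(np.asarray(values, dtype=float), 0.0)
    floors = np.floor(values).astype(int)
    short = total - floors.sum()
    if short < 0:  # over-allocation from clipping; trim largest entries
        order = np.argsort(-floors)
        for idx in order:
            take = min(floors[idx], -short)
            floors[idx] -= take
            short += take
            if short == 0:
                break
        return floors
    rem = values - np.floor(values)
    order = np.argsort(-rem)
    floors[order[:short]] += 1
    return floors


def recreate_ipd(curve: KMCurve, risk: RiskTable, total_n: int) -> pd.DataFrame:
    """Reconstruct (time, event) records consistent with curve and risk table.

    Returns a DataFrame with exactly ``total_n`` rows; events are placed at
    the digitized drop times, within-interval censorings at sub-interval
    midpoints, and patients still at risk after the last digitized time are
    censored there.
    """
    if total_n < risk.n_at_risk[0]:
        raise ValueError("total_n smaller than the initial number at risk")

    kt, ks = curve.times, curve.survival
    rt, rn = risk.times, risk.n_at_risk

    times: list[float] = []
    events: list[int] = []

    n_cur = float(rn[0])
    s_prev = 1.0
    t_prev = rt[0]
    # anyone beyond the reported initial risk set is censored at time zero+
    extra = total_n - int(rn[0])

    boundaries = list(rt[1:]) + [np.inf]
    targets = list(rn[1:]) + [None]

    for t_end, n_target in zip(boundaries, targets):
        mask = (kt > t_prev) & (kt <= t_end)
        pts_t = kt[mask]
        pts_s = ks[mask]
        k = len(pts_t)

        def simulate(c_total: float, collect: bool = False):
            """Walk the interval with c_total censorings spread uniformly."""
            n = n_cur
            sp = s_prev
            per = c_total / k if k else c_total
            d_list, c_list, ct_list = [], [], []
            lo = t_prev
            for tj, sj in zip(pts_t, pts_s):
                drop = 1.0 - sj / sp if sp > 0 else 0.0
                if drop < -1e-9:
                    raise ValueError(f"KM drop implies negative events at t={tj}")
                d = max(n, 0.0) * drop
                n = n - d - per
                sp = sj
                if collect:
                    d_list.append(d)
                    c_list.append(per)
                    ct_list.append(0.5 * (lo + tj))
                lo = tj
            if not k and collect:  # no digitized point: all censorings mid-interval
                c_list.append(c_total)
                ct_list.append(0.5 * (t_prev + (t_end if np.isfinite(t_end) else t_prev)))
                n = n - c_total
            elif not k:
                n = n - c_total
            if collect:
                return n, np.array(d_list), np.array(c_list), np.array(ct_list), sp
            return n

        if n_target is not None:
            f = lambda c: simulate(c) - n_target
            if f(0.0) < -1e-9:
                raise ValueError(
                    f"interval ({t_prev}, {t_end}]: KM drops alone leave fewer than "
                    f"{n_target} at risk; inputs inconsistent")
            c_solved = optimize.brentq(f, 0.0, n_cur) if f(n_cur) < 0 else n_cur
        else:
            c_solved = 0.0  # beyond the last risk time: events only

        n_end, d_arr, c_arr, ct_arr, s_end = simulate(c_solved, collect=True)

        if n_target is not None:
            interval_total = int(round(n_cur)) - int(n_target)
        else:
            interval_total = int(round(n_cur - n_end))
        counts = _largest_remainder(np.concatenate([d_arr, c_arr]), interval_total)
        d_int, c_int = counts[: len(d_arr)], counts[len(d_arr):]

        for tj, d in zip(pts_t, d_int):
            times.extend([tj] * d)
            events.extend([1] * d)
        for tc, c in zip(ct_arr, c_int):
            times.extend([tc] * c)
            events.extend([0] * c)

        n_cur = float(n_target) if n_target is not None else n_end
        s_prev = s_end
        t_prev = t_end if np.isfinite(t_end) else t_prev

    # residual cohort (and any patients above the initial risk count) is
    # administratively censored at the last digitized time
    last_t = float(kt[-1])
    residual = total_n - len(times)
    if residual < 0:
        raise ValueError("allocated more records than total_n; inputs inconsistent")
    times.extend([last_t] * (residual - extra))
    events.extend([0] * (residual - extra))
    times.extend([min(last_t, rt[0] + 1e-9)] * extra)
    events.extend([0] * extra)

    out = pd.DataFrame({"time": times, "event": events})
    out = out.sort_values(["time", "event"], ascending=[True, False], ignore_index=True)
    assert len(out) == total_n
    return out


def km_estimate(ipd: pd.DataFrame) -> KMCurve:
    """Product-limit estimate of the survival function at the event times."""
    if len(ipd) == 0:
        raise ValueError("empty IPD")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd["time"], event_observed=ipd["event"])
    event_times = np.sort(ipd.loc[ipd["event"] == 1, "time"].unique())
    if len(event_times) == 0:
        return KMCurve(times=np.array([float(ipd["time"].max())]), survival=np.array([1.0]))
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    return KMCurve(times=event_times, survival=surv)
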
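"""Deterministic and probabilistic sensitivity analysis.

One-way DSA re-evaluates the pairwise ICER at each parameter's published
range (or +/-20% of the mean) and ranks parameters by the width of the
induced ICER interval (tornado order). The PSA draws every parameter from
its tagged distribution — gamma for costs, beta for utilities and
probabilities (disutilities on magnitude), normal for survival parameters —
with moment-matched parameters, re-runs the full cohort model per draw, and
summarizes results as cost-effectiveness planes and acceptability curves
based on net monetary benefit NMB = wtp * QALY - cost.

Comparative survival uncertainty propagates through the model's own
structure by default: the chemotherapy (lambda, gamma) pair is drawn jointly
per endpoint and each treatment's hazard ratio is drawn lognormally from its
pooled 95% CI, after which treatment lambdas follow by the scaling rule. An
``independent`` mode that perturbs each arm's lambda/gamma separately is
available for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import ParameterBook, evaluate_strategies, STRATEGIES
from .cohort_model import ModelSettings
from .netmeta import Z95

__all__ = ["DsaRange", "PsaSpec", "PsaResults", "one_way_dsa", "moment_match",
           "run_psa", "ce_plane", "ceac", "dsa_ranges_from_book"]


@dataclass(frozen=True)
class DsaRange:
    parameter: str  # dotted path into the parameter book
    low: float
    high: float
    source: str = "pm20"  # or "ci95"

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError(f"{self.parameter}: low > high")


@dataclass(frozen=True)
class PsaSpec:
    n_draws: int = 1000
    seed: int = 0
    cost_se_frac: float = 0.20      # SE as a fraction of the mean for costs
    utility_se_frac: float = 0.10   # ... for utilities/probabilities
    survival_se_frac: float = 0.10  # ... for the reference survival parameters
    survival_mode: str = "hr_scaled"  # or "independent"
    max_retries: int = 100

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("draw count must be >= 1")
        if self.survival_mode not in ("hr_scaled", "independent"):
            raise ValueError(f"unknown survival_mode {self.survival_mode!r}")


@dataclass
class PsaResults:
    draws: pd.DataFrame  # columns: draw, strategy, cost, ly, qaly
    seed: int
    n_draws: int
    resampled: int = 0  # count of infeasible draws that were re-drawn
    metadata: dict = field(default_factory=dict)


def moment_match(mean: float, se: float, dist: str) -> dict:
    """Distribution parameters reproducing a given mean and standard error."""
    if dist == "gamma":
        if se == 0:
            return {"dist": "point", "value": mean}
        if mean <= 0:
            raise ValueError("gamma moment matching needs a positive mean")
        return {"dist": "gamma", "shape": (mean / se) ** 2, "scale": se**2 / mean}
    if dist == "beta":
        if se == 0:
            return {"dist": "point", "value": mean}
        if not (0 < mean < 1):
            raise ValueError(f"beta moment matching needs mean in (0, 1), got {mean}")
        common = mean * (1 - mean) / se**2 - 1
        if common <= 0:
            raise ValueError(f"SE {se} infeasible for a beta with mean {mean}")
        return {"dist": "beta", "alpha": mean * common, "beta": (1 - mean) * common}
    if dist == "normal":
        if se == 0:
            return {"dist": "point", "value": mean}
        return {"dist": "normal", "mean": mean, "se": se}
    raise ValueError(f"unknown distribution {dist!r}")


def _sample(rng: np.random.Generator, params: dict) -> float:
    if params["dist"] == "point":
        return params["value"]
    if params["dist"] == "gamma":
        return float(rng.gamma(params["shape"], params["scale"]))
    if params["dist"] == "beta":
        return float(rng.beta(params["alpha"], params["beta"]))
    return float(rng.normal(params["mean"], params["se"]))


def dsa_ranges_from_book(book: ParameterBook, fallback_frac: float = 0.20) -> list[DsaRange]:
    """Ranges for every scalar cost/utility/disutility parameter.

    Published ranges are used where they bracket the base case; everything
    else is varied +/- ``fallback_frac`` of the mean.
    """
    printed = book.data.get("dsa_ranges", {})
    ranges = []
    for path, base in book.flatten(("costs", "ae_unit_costs", "utilities",
                                    "ae_disutilities")).items():
        if path in printed:
            lo, hi = sorted(float(v) for v in printed[path])
            if lo <= base <= hi:
                ranges.append(DsaRange(path, lo, hi, source="ci95"))
                continue
        span = abs(base) * fallback_frac
        ranges.append(DsaRange(path, base - span, base + span, source="pm20"))
    return ranges


def _pair_icer(results: pd.DataFrame, pair: tuple[str, str]) -> float:
    """ICER of pair[0] vs pair[1] (delta cost / delta QALY), sign-preserving."""
    a = results.set_index("strategy")
    dq = a.loc[pair[0], "qaly"] - a.loc[pair[1], "qaly"]
    dc = a.loc[pair[0], "cost"] - a.loc[pair[1], "cost"]
    return float(dc / dq) if dq != 0 else math.inf


def one_way_dsa(book: ParameterBook, ranges: list[DsaRange], pair: tuple[str, str],
                settings: ModelSettings = ModelSettings()) -> pd.DataFrame:
    """Tornado table: ICER of the pair at each parameter's low/high value."""
    flat = book.flatten(("costs", "ae_unit_costs", "utilities", "ae_disutilities"))
    base_icer = _pair_icer(evaluate_strategies(book, settings), pair)
    rows = []
    for rng_ in ranges:
        if rng_.parameter not in flat and not _path_exists(book, rng_.parameter):
            raise KeyError(f"parameter {rng_.parameter!r} not in the model")
        icer_low = _pair_icer(evaluate_strategies(
            book.with_value(rng_.parameter, rng_.low), settings), pair)
        icer_high = _pair_icer(evaluate_strategies(
            book.with_value(rng_.parameter, rng_.high), settings), pair)
        rows.append({"parameter": rng_.parameter, "low": rng_.low, "high": rng_.high,
                     "icer_low": icer_low, "icer_high": icer_high,
                     "icer_range": abs(icer_high - icer_low)})
    out = pd.DataFrame(rows).sort_values("icer_range", ascending=False, ignore_index=True)
    out.attrs["base_icer"] = base_icer
    out.attrs["pair"] = pair
    return out


def _path_exists(book: ParameterBook, path: str) -> bool:
    try:
        book.get(path)
        return True
    except (KeyError, TypeError):
        return False


def _draw_book(book: ParameterBook, spec: PsaSpec, rng: np.random.Generator) -> ParameterBook:
    new = book.copy()
    data = new.data

    def perturb(node, kind):
        for key, val in node.items():
            if isinstance(val, dict):
                perturb(val, kind)
            elif isinstance(val, (int, float)) and not isinstance(val, bool):
                if kind == "cost":
                    node[key] = _sample(rng, moment_match(float(val), spec.cost_se_frac * float(val), "gamma")) if val > 0 else float(val)
                elif kind == "utility":
                    node[key] = _sample(rng, moment_match(float(val), spec.utility_se_frac * float(val), "beta")) if 0 < val < 1 else float(val)
                elif kind == "disutility":
                    mag = abs(float(val))
                    if 0 < mag < 1:
                        node[key] = -_sample(rng, moment_match(mag, spec.utility_se_frac * mag, "beta"))

    perturb(data["costs"], "cost")
    perturb(data["ae_unit_costs"], "cost")
    perturb(data["utilities"], "utility")
    perturb(data["ae_disutilities"], "disutility")

    surv = data["survival"]
    frac = spec.survival_se_frac
    if spec.survival_mode == "hr_scaled":
        for endpoint in ("pfs", "os"):
            ref = book.data["survival"][endpoint]["chemotherapy"]
            lam = rng.normal(ref["lam"], frac * ref["lam"])
            gam = rng.normal(ref["gamma"], frac * ref["gamma"])
            if lam <= 0 or gam <= 0:
                raise _InfeasibleDraw
            surv[endpoint]["chemotherapy"] = {"family": "weibull", "lam": lam, "gamma": gam}
            for arm, ci in book.data["nma_hr_vs_chemotherapy"][endpoint].items():
                mu = math.log(ci["hr"])
                sd = (math.log(ci["upper"]) - math.log(ci["lower"])) / (2 * Z95)
                hr = math.exp(rng.normal(mu, sd))
                surv[endpoint][arm] = {"family": "weibull", "lam": lam * hr, "gamma": gam}
    else:
        for endpoint in ("pfs", "os"):
            for arm, ref in book.data["survival"][endpoint].items():
                lam = rng.normal(ref["lam"], frac * ref["lam"])
                gam = rng.normal(ref["gamma"], frac * ref["gamma"])
                if lam <= 0 or gam <= 0:
                    raise _InfeasibleDraw
                surv[endpoint][arm] = {"family": "weibull", "lam": lam, "gamma": gam}
    for endpoint in ("pfs", "os"):
        for option, ref in book.data["survival"]["second_line"][endpoint].items():
            icpt = rng.normal(ref["intercept"], frac * abs(ref["intercept"]))
            surv["second_line"][endpoint][option] = {"family": "exponential", "intercept": icpt}
    return new


class _InfeasibleDraw(Exception):
    pass


def run_psa(book: ParameterBook, spec: PsaSpec,
            settings: ModelSettings = ModelSettings()) -> PsaResults:
    """Monte-Carlo PSA: re-evaluate all strategies per parameter draw."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    resampled = 0
    for draw in range(spec.n_draws):
        for attempt in range(spec.max_retries + 1):
            try:
                sampled = _draw_book(book, spec, rng)
                res = evaluate_strategies(sampled, settings)
                break
            except (_InfeasibleDraw, ValueError):
                resampled += 1
                if attempt == spec.max_retries:
                    raise RuntimeError("exceeded retry budget for infeasible PSA draws")
        for rec in res.itertuples(index=False):
            rows.append({"draw": draw, "strategy": rec.strategy, "cost": rec.cost,
                         "ly": rec.ly, "qaly": rec.qaly})
    return PsaResults(draws=pd.DataFrame(rows), seed=spec.seed,
                      n_draws=spec.n_draws, resampled=resampled)


def ce_plane(results: PsaResults, pair: tuple[str, str]) -> tuple[pd.DataFrame, dict]:
    """Incremental (effect, cost) scatter of pair[0] vs pair[1], with quadrant shares.

    Quadrants follow the strictly-positive convention: a draw on an axis
    counts toward the quadrant of its non-negative side (ties resolve as
    ``>= 0``), so the four fractions always sum to one.
    """
    wide_c = results.draws.pivot(index="draw", columns="strategy", values="cost")
    wide_q = results.draws.pivot(index="draw", columns="strategy", values="qaly")
    for s in pair:
        if s not in wide_c.columns:
            raise KeyError(f"strategy {s!r} absent from the PSA results")
    dq = (wide_q[pair[0]] - wide_q[pair[1]]).to_numpy()
    dc = (wide_c[pair[0]] - wide_c[pair[1]]).to_numpy()
    df = pd.DataFrame({"delta_qaly": dq, "delta_cost": dc})
    n = len(df)
    fractions = {
        "upper_right": float(np.mean((dq > 0) & (dc >= 0))),
        "upper_left": float(np.mean((dq <= 0) & (dc >= 0))),
        "lower_left": float(np.mean((dq <= 0) & (dc < 0))),
        "lower_right": float(np.mean((dq > 0) & (dc < 0))),
    }
    if n and np.all(dq == 0) and np.all(dc == 0):
        df.attrs["identical_strategies"] = True
    return df, fractions


def ceac(results: PsaResults, wtp_grid) -> pd.DataFrame:
    """Acceptability: P(strategy maximizes NMB) at each willingness-to-pay.

    Ties for the maximum NMB are split equally, so columns sum to one at
    every threshold.
    """
    wide_c = results.draws.pivot(index="draw", columns="strategy", values="cost")
    wide_q = results.draws.pivot(index="draw", columns="strategy", values="qaly")
    strategies = list(wide_c.columns)
    if len(strategies) < 2:
        raise ValueError("acceptability curves need at least two strategies")
    cost = wide_c.to_numpy()
    qaly = wide_q.to_numpy()
    out = []
    for wtp in np.asarray(wtp_grid, dtype=float):
        nmb = wtp * qaly - cost
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best)
        shares = winners / winners.sum(axis=1, keepdims=True)
        probs = shares.mean(axis=0)
        out.append({"wtp": wtp, **dict(zip(strategies, probs))})
    return pd.DataFrame(out)
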
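"""Seeded generators for every input the pipeline consumes.

Censored time-to-event cohorts (Weibull/exponential/log-logistic event times
with administrative cutoff plus independent exponential dropout), published-
figure surrogates (exact KM step curves with numbers-at-risk tables), and
multi-trial log-HR contrast networks with known truth. The packaged
parameter book mirrors the model's input table and loads through
:func:`table2_fixture`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import ParameterBook
from .km_reconstruct import KMCurve, RiskTable, km_estimate
from .netmeta import Contrast, ContrastSet
from .survfit import SurvParams

__all__ = ["SimConfig", "simulate_ipd", "km_with_risk_table", "simulate_network",
           "table2_fixture"]


@dataclass(frozen=True)
class SimConfig:
    """One simulated trial arm: generating law, size, censoring model."""

    params: SurvParams
    n: int
    cutoff_months: float = np.inf  # administrative censoring time
    dropout_rate: float = 0.0  # per month, independent exponential dropout
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.cutoff_months <= 0:
            raise ValueError("cutoff must be positive")
        if self.dropout_rate < 0:
            raise ValueError("dropout rate must be non-negative")


def _inverse_cdf(params: SurvParams, u: np.ndarray) -> np.ndarray:
    if params.family == "weibull":
        return (-np.log(u) / params.lam) ** (1.0 / params.gamma)
    if params.family == "exponential":
        return -np.log(u) / params.rate
    # loglogistic: S(t) = 1/(1+(lam t)^gamma)
    return ((1.0 - u) / u) ** (1.0 / params.gamma) / params.lam


def simulate_ipd(cfg: SimConfig) -> pd.DataFrame:
    """Draw (time, event) records under the configured law and censoring."""
    rng = np.random.default_rng(cfg.seed)
    event_t = _inverse_cdf(cfg.params, rng.uniform(size=cfg.n))
    censor_t = np.full(cfg.n, cfg.cutoff_months)
    if cfg.dropout_rate > 0:
        censor_t = np.minimum(censor_t, rng.exponential(1.0 / cfg.dropout_rate, size=cfg.n))
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    return pd.DataFrame({"time": time, "event": event})


def km_with_risk_table(ipd: pd.DataFrame, risk_times) -> tuple[KMCurve, RiskTable]:
    """Exact product-limit curve plus numbers at risk at the requested times."""
    if len(ipd) == 0:
        raise ValueError("empty IPD")
    curve = km_estimate(ipd)
    risk_times = np.asarray(risk_times, dtype=float)
    t = ipd["time"].to_numpy()
    n_at_risk = np.array([(t >= rt).sum() for rt in risk_times], dtype=int)
    return curve, RiskTable(times=risk_times, n_at_risk=n_at_risk)


def simulate_network(true_d: dict[str, float], plan: list[dict], seed: int = 0,
                     reference: str = "chemotherapy") -> ContrastSet:
    """Noisy contrasts on a trial plan with known basic parameters.

    ``true_d`` maps treatment -> true log-HR vs the reference (the reference
    itself is 0). Each plan entry needs study_id, arm_a, arm_b, endpoint and
    events; the standard error is approximated as 2/sqrt(events).
    """
    rng = np.random.default_rng(seed)
    d = dict(true_d)
    d.setdefault(reference, 0.0)
    contrasts = []
    for trial in plan:
        se = 2.0 / np.sqrt(trial["events"])
        mean = d[trial["arm_b"]] - d[trial["arm_a"]]
        contrasts.append(Contrast(
            study_id=str(trial["study_id"]), treatment_a=trial["arm_a"],
            treatment_b=trial["arm_b"], endpoint=trial.get("endpoint", "PFS"),
            log_hr=float(rng.normal(mean, se)), se_log_hr=float(se)))
    return ContrastSet(tuple(contrasts), reference=reference)


def table2_fixture() -> ParameterBook:
    """The packaged parameter book (validated on load, identical across calls)."""
    return ParameterBook.from_yaml()
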
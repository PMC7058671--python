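"""Fixed-effect network meta-analysis of hazard ratios on the log scale.

Trial contrasts (log hazard ratio of arm b vs arm a with its standard error)
are pooled under the consistency model

    log_hr(a, b) ~ Normal(d_b - d_a, se^2),

where d_t is the basic parameter of treatment t relative to a common
reference (here chemotherapy, d_ref = 0). Two estimators are provided: a
closed-form generalized-least-squares solution (deterministic; the default)
and a random-walk Metropolis sampler with vague Normal(0, 100^2) priors that
mimics the Bayesian analysis and yields credible intervals from draws.
Within-trial correlation of multi-arm trials is ignored (contrast-level
data only), a documented approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Z95",
    "Contrast",
    "ContrastSet",
    "PooledEstimates",
    "LeagueTable",
    "parse_contrasts",
    "duplicate_shared_comparator",
    "fit_fixed_effect",
    "league_table",
]

Z95 = 1.959964
ENDPOINTS = ("PFS", "OS")


@dataclass(frozen=True)
class Contrast:
    study_id: str
    treatment_a: str
    treatment_b: str
    endpoint: str
    log_hr: float  # of b vs a
    se_log_hr: float

    def __post_init__(self):
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {ENDPOINTS}")
        if self.se_log_hr <= 0:
            raise ValueError("se_log_hr must be positive")
        if self.treatment_a == self.treatment_b:
            raise ValueError("a contrast needs two distinct treatments")


@dataclass(frozen=True)
class ContrastSet:
    contrasts: tuple[Contrast, ...]
    reference: str = "chemotherapy"

    @property
    def treatments(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.contrasts:
            seen.setdefault(c.treatment_a)
            seen.setdefault(c.treatment_b)
        return tuple(seen)

    def for_endpoint(self, endpoint: str) -> "ContrastSet":
        return ContrastSet(tuple(c for c in self.contrasts if c.endpoint == endpoint),
                           reference=self.reference)

    def graph(self, endpoint: str) -> nx.Graph:
        g = nx.Graph()
        for c in self.contrasts:
            if c.endpoint == endpoint:
                g.add_edge(c.treatment_a, c.treatment_b)
        return g


@dataclass(frozen=True)
class PooledEstimates:
    endpoint: str
    reference: str
    basic_params: dict[str, tuple[float, float]]  # treatment -> (mean d, sd)
    cov: np.ndarray | None = None  # GLS covariance over non-reference treatments
    order: tuple[str, ...] = ()  # non-reference treatments indexing cov / draws
    draws: np.ndarray | None = field(default=None, compare=False)
    method: str = "GLS"


@dataclass(frozen=True)
class LeagueTable:
    endpoint: str
    treatments: tuple[str, ...]
    table: dict[tuple[str, str], tuple[float, float, float]]  # (a,b) -> (HR of b vs a, lo, hi)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"treatment_a": a, "treatment_b": b, "hr": v[0], "lower95": v[1], "upper95": v[2]}
            for (a, b), v in self.table.items()
        ]
        return pd.DataFrame(rows)


def parse_contrasts(records: pd.DataFrame, reference: str = "chemotherapy") -> ContrastSet:
    """Convert trial records (HR with 95% CI) into log-HR contrasts.

    Expects columns study_id, arm_a, arm_b, endpoint, hr, ci_low, ci_high;
    se(log HR) = (ln upper - ln lower) / (2 * 1.959964).
    """
    contrasts = []
    for rec in records.itertuples(index=False):
        if rec.hr <= 0:
            raise ValueError(f"study {rec.study_id}: non-positive hazard ratio {rec.hr}")
        if not (0 < rec.ci_low < rec.ci_high):
            raise ValueError(
                f"study {rec.study_id}: invalid confidence interval ({rec.ci_low}, {rec.ci_high})")
        contrasts.append(Contrast(
            study_id=str(rec.study_id),
            treatment_a=str(rec.arm_a),
            treatment_b=str(rec.arm_b),
            endpoint=str(rec.endpoint),
            log_hr=math.log(rec.hr),
            se_log_hr=(math.log(rec.ci_high) - math.log(rec.ci_low)) / (2 * Z95),
        ))
    return ContrastSet(tuple(contrasts), reference=reference)


def duplicate_shared_comparator(cs: ContrastSet, study_id: str, pooled_label: str,
                                replacements: tuple[str, str] = ("gefitinib", "erlotinib"),
                                policy: str = "replicate") -> ContrastSet:
    """Expand a contrast against a pooled comparator into one per component drug.

    A trial reporting one HR against a pooled "standard TKI" arm is entered
    twice, once per component treatment, with identical log-HR. Policy
    ``replicate`` keeps the SE unchanged in both copies (the reproduction
    default); ``inflate`` multiplies each SE by sqrt(2) so the duplicated
    record does not double the information.
    """
    if policy not in ("replicate", "inflate"):
        raise ValueError(f"unknown split policy {policy!r}")
    hits = [c for c in cs.contrasts if c.study_id == study_id and
            pooled_label in (c.treatment_a, c.treatment_b)]
    if not any(c.study_id == study_id for c in cs.contrasts):
        raise ValueError(f"unknown study {study_id!r}")
    if not hits:
        return cs  # single named comparator: nothing to split
    factor = math.sqrt(2.0) if policy == "inflate" else 1.0
    out = [c for c in cs.contrasts if c not in hits]
    for c in hits:
        for new in replacements:
            if c.treatment_a == pooled_label:
                out.append(replace(c, treatment_a=new, se_log_hr=c.se_log_hr * factor))
            else:
                out.append(replace(c, treatment_b=new, se_log_hr=c.se_log_hr * factor))
    return ContrastSet(tuple(out), reference=cs.reference)


def _design(cs: ContrastSet, endpoint: str):
    sub = [c for c in cs.contrasts if c.endpoint == endpoint]
    if not sub:
        raise ValueError(f"no contrasts for endpoint {endpoint}")
    g = cs.graph(endpoint)
    if cs.reference not in g:
        raise ValueError(f"reference {cs.reference!r} absent from the {endpoint} network")
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        isolated = next(c for c in comps if cs.reference not in c)
        raise ValueError(
            f"{endpoint} network is disconnected; isolated component: {sorted(isolated)}")
    order = tuple(t for t in cs.treatments if t != cs.reference and t in g)
    idx = {t: i for i, t in enumerate(order)}
    x = np.zeros((len(sub), len(order)))
    y = np.empty(len(sub))
    se = np.empty(len(sub))
    for i, c in enumerate(sub):
        if c.treatment_b != cs.reference:
            x[i, idx[c.treatment_b]] = 1.0
        if c.treatment_a != cs.reference:
            x[i, idx[c.treatment_a]] = -1.0
        y[i] = c.log_hr
        se[i] = c.se_log_hr
    return x, y, se, order


def fit_fixed_effect(cs: ContrastSet, endpoint: str, method: str = "GLS",
                     mcmc_config: dict | None = None, seed: int | None = None) -> PooledEstimates:
    """Estimate basic parameters d_t (log-HR of t vs reference).

    GLS solves the weighted normal equations in closed form. MCMC runs a
    random-walk Metropolis sampler under Normal(0, 100^2) priors; its
    posterior means agree with GLS within Monte-Carlo error.
    """
    x, y, se, order = _design(cs, endpoint)
    w = 1.0 / se**2
    xtwx = x.T @ (x * w[:, None])
    cov = np.linalg.inv(xtwx)
    d_gls = cov @ (x.T @ (w * y))

    if method.upper() == "GLS":
        basic = {cs.reference: (0.0, 0.0)}
        for i, t in enumerate(order):
            basic[t] = (float(d_gls[i]), float(math.sqrt(cov[i, i])))
        return PooledEstimates(endpoint, cs.reference, basic, cov=cov, order=order, method="GLS")

    if method.upper() != "MCMC":
        raise ValueError(f"unknown method {method!r}")
    cfg = {"chains": 4, "burn_in": 1000, "draws": 4000, "prior_sd": 100.0}
    cfg.update(mcmc_config or {})
    if seed is None:
        raise ValueError("MCMC requires a seed")
    rng = np.random.default_rng(seed)
    p = len(order)
    step = np.sqrt(np.diag(cov)) * 2.4 / math.sqrt(p)  # GLS-scaled proposals

    def log_post(d):
        r = y - x @ d
        return -0.5 * np.sum(w * r * r) - 0.5 * np.sum(d * d) / cfg["prior_sd"] ** 2

    all_draws = []
    for _ in range(cfg["chains"]):
        d = d_gls + rng.normal(0, step)
        lp = log_post(d)
        chain = np.empty((cfg["draws"], p))
        for it in range(cfg["burn_in"] + cfg["draws"]):
            j = it % p  # component-wise updates
            prop = d.copy()
            prop[j] += rng.normal(0, step[j])
            lp_prop = log_post(prop)
            if math.log(rng.uniform()) < lp_prop - lp:
                d, lp = prop, lp_prop
            if it >= cfg["burn_in"]:
                chain[it - cfg["burn_in"]] = d
        all_draws.append(chain)
    draws = np.concatenate(all_draws, axis=0)
    basic = {cs.reference: (0.0, 0.0)}
    for i, t in enumerate(order):
        basic[t] = (float(draws[:, i].mean()), float(draws[:, i].std(ddof=1)))
    return PooledEstimates(endpoint, cs.reference, basic, cov=cov, order=order,
                           draws=draws, method="MCMC")


def league_table(est: PooledEstimates) -> LeagueTable:
    """All pairwise HRs with 95% intervals; entry (a, b) is the HR of b vs a."""
    treatments = (est.reference,) + est.order
    idx = {t: i for i, t in enumerate(est.order)}
    table: dict[tuple[str, str], tuple[float, float, float]] = {}
    for a in treatments:
        for b in treatments:
            if a == b:
                table[(a, b)] = (1.0, 1.0, 1.0)
                continue
            if est.method == "MCMC" and est.draws is not None:
                da = est.draws[:, idx[a]] if a != est.reference else 0.0
                db = est.draws[:, idx[b]] if b != est.reference else 0.0
                diff = db - da
                # posterior mean of the HR itself (hence only approximate
                # reciprocity, as in the published league table)
                table[(a, b)] = (float(np.mean(np.exp(diff))),
                                 float(np.exp(np.quantile(diff, 0.025))),
                                 float(np.exp(np.quantile(diff, 0.975))))
            else:
                mean = est.basic_params[b][0] - est.basic_params[a][0]
                var = 0.0
                if a != est.reference and b != est.reference:
                    var = est.cov[idx[a], idx[a]] + est.cov[idx[b], idx[b]] \
                        - 2 * est.cov[idx[a], idx[b]]
                elif a != est.reference:
                    var = est.cov[idx[a], idx[a]]
                elif b != est.reference:
                    var = est.cov[idx[b], idx[b]]
                sd = math.sqrt(max(var, 0.0))
                table[(a, b)] = (math.exp(mean), math.exp(mean - Z95 * sd),
                                 math.exp(mean + Z95 * sd))
    return LeagueTable(est.endpoint, treatments, table)
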
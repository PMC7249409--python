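"""Synthetic-trial generation and power / efficiency experiments.

The generator draws trials from exactly the data-generating process the
joint model assumes: a normal continuous component with an arm shift and a
binary component with logistic dependence on arm and on the continuous
value, with independent component-wise missingness.  On top of it sit the
experiments that quantify what the augmented analysis buys:

* ``run_power_study`` — paired rejection rates, CI widths and coverage for
  the binary and augmented analyses over replicated trials;
* ``effective_sample_size_gain`` — the percent extra sample size the
  reference analysis needs to match the power of the target analysis,
  found by bisection over n on a common-random-number power curve;
* ``dichotomisation_cost_analytic`` — the closed-form asymptotic price of
  analysing a normal endpoint as a threshold proportion instead of a mean.

All experiment outputs carry the seed and a scenario-config hash so any run
can be reproduced exactly.
"""
from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import special, stats

from .data import TrialData
from .inference import augbin_analysis, binary_analysis
from .joint_model import JointParams
from .rules import ComponentRule, CompositeRule, Direction

__all__ = [
    "ScenarioConfig",
    "MethodPower",
    "PowerResult",
    "EssResult",
    "default_effect_scenario",
    "null_scenario",
    "single_endpoint_scenario",
    "simulate_trial",
    "run_power_study",
    "effective_sample_size_gain",
    "dichotomisation_cost_analytic",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """A simulation scenario: truth, design and replication settings."""

    n_per_arm: int
    true_params: JointParams
    rule: CompositeRule
    miss_y: float = 0.0
    miss_b: float = 0.0
    n_reps: int = 1000
    alpha_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be at least 2")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        for name in ("miss_y", "miss_b"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not (0.0 < self.alpha_level < 1.0):
            raise ValueError("alpha_level must be in (0, 1)")

    def with_(self, **kw) -> "ScenarioConfig":
        d = {
            "n_per_arm": self.n_per_arm,
            "true_params": self.true_params,
            "rule": self.rule,
            "miss_y": self.miss_y,
            "miss_b": self.miss_b,
            "n_reps": self.n_reps,
            "alpha_level": self.alpha_level,
            "seed": self.seed,
        }
        d.update(kw)
        return ScenarioConfig(**d)

    def config_hash(self) -> str:
        payload = {
            "n_per_arm": self.n_per_arm,
            "params": list(self.true_params.as_array()),
            "rule": [
                self.rule.continuous_rule.direction.value,
                self.rule.continuous_rule.threshold,
            ],
            "miss_y": self.miss_y,
            "miss_b": self.miss_b,
            "n_reps": self.n_reps,
            "alpha_level": self.alpha_level,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _default_rule() -> CompositeRule:
    return CompositeRule(
        ComponentRule(Direction.AT_LEAST, 0.0, "continuous component"),
        description="y >= 0 and b = 1",
    )


def default_effect_scenario(
    n_per_arm: int = 100, n_reps: int = 1000, seed: int = 0
) -> ScenarioConfig:
    """The documented default effect scenario.

    Control mean 0, treatment shift 0.4 SD on the continuous component;
    binary criterion met with high probability (logistic intercept 2) and
    positively associated with the continuous value (slope 0.5); responder
    threshold at the control median (0).  The whole treatment effect flows
    through the continuous component (gamma1 = 0).
    """
    return ScenarioConfig(
        n_per_arm=n_per_arm,
        true_params=JointParams(0.0, 0.4, 1.0, 2.0, 0.0, 0.5),
        rule=_default_rule(),
        n_reps=n_reps,
        seed=seed,
    )


def null_scenario(n_per_arm: int = 100, n_reps: int = 1000, seed: int = 0) -> ScenarioConfig:
    """The default scenario with no treatment effect on either component."""
    return ScenarioConfig(
        n_per_arm=n_per_arm,
        true_params=JointParams(0.0, 0.0, 1.0, 2.0, 0.0, 0.5),
        rule=_default_rule(),
        n_reps=n_reps,
        seed=seed,
    )


def single_endpoint_scenario(
    n_per_arm: int = 100, n_reps: int = 1000, seed: int = 0, theta: float = 0.4
) -> ScenarioConfig:
    """Single dichotomised continuous endpoint: binary component forced to 1.

    With the binary criterion always met (logistic intercept 30), the
    composite responder rule reduces to the median cut y >= 0, so the binary
    analysis is a two-sample proportions test on the dichotomised endpoint
    and a t-test on y is the efficient single-endpoint comparator.
    """
    return ScenarioConfig(
        n_per_arm=n_per_arm,
        true_params=JointParams(0.0, theta, 1.0, 30.0, 0.0, 0.0),
        rule=_default_rule(),
        n_reps=n_reps,
        seed=seed,
    )


def _simulate_arrays(scenario: ScenarioConfig, rep_seed: int, n_per_arm: int):
    """Draw raw (z, y, b) arrays, arm-blocked (control first), with masks applied."""
    a, t, s, g0, g1, g2 = scenario.true_params.as_array()
    rng = np.random.default_rng([int(scenario.seed), int(rep_seed)])
    n2 = 2 * n_per_arm
    z = np.repeat([0, 1], n_per_arm)
    y = a + t * z + s * rng.standard_normal(n2)
    eta = g0 + g1 * z + g2 * y
    b = (rng.random(n2) < special.expit(eta)).astype(float)
    y_out = y.copy()
    if scenario.miss_y > 0:
        y_out[rng.random(n2) < scenario.miss_y] = np.nan
    if scenario.miss_b > 0:
        b[rng.random(n2) < scenario.miss_b] = np.nan
    return z, y_out, b


def simulate_trial(scenario: ScenarioConfig, rep_seed: int) -> TrialData:
    """One synthetic trial; bit-reproducible given (scenario.seed, rep_seed)."""
    z, y, b = _simulate_arrays(scenario, rep_seed, scenario.n_per_arm)
    ids = np.array(
        [f"S{rep_seed:05d}-{i:05d}" for i in range(len(z))], dtype=object
    )
    return TrialData(
        ids,
        z,
        y,
        b,
        meta={
            "seed": scenario.seed,
            "rep_seed": rep_seed,
            "config_hash": scenario.config_hash(),
        },
    )


# ---------------------------------------------------------------------------
# per-replicate analysis adapters used by the experiments
# ---------------------------------------------------------------------------


def _binary_reject_fast(z, y, b, rule: CompositeRule, alpha: float) -> bool:
    """Vectorised rejection indicator of the standard binary Wald test."""
    if rule.continuous_rule.direction is Direction.AT_LEAST:
        met = y >= rule.continuous_rule.threshold
    else:
        met = y <= rule.continuous_rule.threshold
    det = ~np.isnan(y) & ~np.isnan(b)
    resp = met & (b == 1.0) & det
    r = np.array([np.sum(resp & (z == arm)) for arm in (0, 1)], dtype=float)
    m = np.array([np.sum(det & (z == arm)) for arm in (0, 1)], dtype=float)
    if np.any(m < 1):
        return False
    p = r / m
    se = math.sqrt(p[0] * (1 - p[0]) / m[0] + p[1] * (1 - p[1]) / m[1])
    if se == 0.0:
        return False
    zstat = abs(p[1] - p[0]) / se
    return bool(zstat > stats.norm.ppf(1 - alpha / 2))


def _ttest_reject(z, y, b, rule, alpha: float) -> bool:
    oy = ~np.isnan(y)
    res = stats.ttest_ind(y[oy & (z == 1)], y[oy & (z == 0)])
    return bool(res.pvalue < alpha)


def _augmented_reject(z, y, b, rule: CompositeRule, alpha: float) -> bool:
    ids = np.arange(len(z)).astype(object)
    data = TrialData(ids, z, y, b)
    try:
        est = augbin_analysis(data, rule, conf_level=1 - alpha)
    except (RuntimeError, ValueError, np.linalg.LinAlgError):
        return False  # fit failures are conservative non-rejections
    return bool(est.pvalue < alpha)


_METHOD_REJECT: dict[str, Callable] = {
    "binary": _binary_reject_fast,
    "augmented": _augmented_reject,
    "ttest": _ttest_reject,
}


# ---------------------------------------------------------------------------
# power study
# ---------------------------------------------------------------------------


@dataclass
class MethodPower:
    method: str
    reject_rate: float
    mc_se: float
    mean_ci_width: float
    mean_diff: float
    coverage: float
    n_reps_completed: int
    failures: int


@dataclass
class PowerResult:
    scenario_seed: int
    config_hash: str
    n_per_arm: int
    n_reps: int
    alpha_level: float
    true_diff: float
    results: dict[str, MethodPower]
    warnings: list = field(default_factory=list)


def _true_diff(scenario: ScenarioConfig) -> float:
    from .inference import response_probability

    p0 = response_probability(scenario.true_params, 0, scenario.rule)
    p1 = response_probability(scenario.true_params, 1, scenario.rule)
    return p1 - p0


def run_power_study(
    scenario: ScenarioConfig, methods: tuple[str, ...] = ("binary", "augmented")
) -> PowerResult:
    """Paired Monte-Carlo power study.

    Every replicate is one simulated trial analysed by every requested
    method (common random numbers by construction), recording the two-sided
    Wald rejection at ``alpha_level``, the CI width for the response-rate
    difference, the difference estimate, and whether the CI covers the true
    difference.  Replicates whose fit fails count as non-rejections in the
    rate (conservative) and are excluded from the CI-width / estimate /
    coverage means; the failure count is reported.
    """
    if scenario.n_per_arm < 10:
        raise ValueError("power studies require n_per_arm >= 10")
    if scenario.n_reps == 1:
        warnings.warn(
            "n_reps = 1: rejection rates are degenerate {0,1} and the MC SE is 0",
            stacklevel=2,
        )
    true_diff = _true_diff(scenario)
    conf = 1.0 - scenario.alpha_level

    acc = {
        m: {"reject": 0, "width": [], "diff": [], "cover": [], "fail": 0}
        for m in methods
    }
    for rep in range(scenario.n_reps):
        data = simulate_trial(scenario, rep)
        for m in methods:
            try:
                if m == "binary":
                    est = binary_analysis(data, scenario.rule, conf_level=conf)
                elif m == "augmented":
                    est = augbin_analysis(data, scenario.rule, conf_level=conf)
                else:
                    raise KeyError(f"unknown analysis method {m!r}")
            except (RuntimeError, ValueError, np.linalg.LinAlgError):
                acc[m]["fail"] += 1
                continue
            acc[m]["reject"] += est.pvalue < scenario.alpha_level
            acc[m]["width"].append(est.ci_width_diff)
            acc[m]["diff"].append(est.diff)
            acc[m]["cover"].append(est.ci_diff[0] <= true_diff <= est.ci_diff[1])

    out: dict[str, MethodPower] = {}
    warns: list[str] = []
    for m in methods:
        a = acc[m]
        completed = scenario.n_reps - a["fail"]
        rate = a["reject"] / scenario.n_reps  # failures never reject
        mc_se = (
            math.sqrt(rate * (1 - rate) / completed) if completed > 0 else float("nan")
        )
        if a["fail"] > 0.1 * scenario.n_reps:
            msg = f"{m}: {a['fail']}/{scenario.n_reps} replicates failed to fit"
            warns.append(msg)
            warnings.warn(msg, stacklevel=2)
        out[m] = MethodPower(
            method=m,
            reject_rate=rate,
            mc_se=mc_se,
            mean_ci_width=float(np.mean(a["width"])) if a["width"] else float("nan"),
            mean_diff=float(np.mean(a["diff"])) if a["diff"] else float("nan"),
            coverage=float(np.mean(a["cover"])) if a["cover"] else float("nan"),
            n_reps_completed=completed,
            failures=a["fail"],
        )
    return PowerResult(
        scenario_seed=scenario.seed,
        config_hash=scenario.config_hash(),
        n_per_arm=scenario.n_per_arm,
        n_reps=scenario.n_reps,
        alpha_level=scenario.alpha_level,
        true_diff=true_diff,
        results=out,
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# effective sample size
# ---------------------------------------------------------------------------


@dataclass
class EssResult:
    gain_percent: float
    n_matched: float
    n_base: int
    target_power: float
    reference_power_at_base: float
    n_reps: int
    scenario_seed: int
    config_hash: str


def effective_sample_size_gain(
    scenario: ScenarioConfig,
    reference_method: str = "binary",
    target_method: str = "augmented",
    n_max_factor: int = 10,
) -> EssResult:
    """Percent extra sample size ``reference_method`` needs to match
    ``target_method``'s power at the scenario's n.

    Common random numbers across methods and across n: each replicate is
    simulated once at n_max = ``n_max_factor`` * n and the analysis at any
    smaller n uses the first n subjects of each arm, so the reference power
    curve is evaluated on nested datasets.  Integer bisection to unit
    resolution, then linear interpolation between the bracketing powers (the
    smoothing of the power-vs-n sequence).  Gain = 100 * (n_matched/n - 1).
    """
    for m in (reference_method, target_method):
        if m not in _METHOD_REJECT:
            raise KeyError(f"unknown analysis method {m!r}")
    n0 = scenario.n_per_arm
    n_max = n_max_factor * n0
    reps = scenario.n_reps

    sims = [_simulate_arrays(scenario, r, n_max) for r in range(reps)]

    def subset(sim, n):
        z, y, b = sim
        idx = np.concatenate([np.arange(n), n_max + np.arange(n)])
        return z[idx], y[idx], b[idx]

    def rejections(method: str, n: int) -> np.ndarray:
        fn = _METHOD_REJECT[method]
        return np.array(
            [fn(*subset(sim, n), scenario.rule, scenario.alpha_level) for sim in sims],
            dtype=bool,
        )

    rej_target = rejections(target_method, n0)
    p_target = float(rej_target.mean())
    if not (0.2 < p_target < 0.95):
        raise ValueError(
            f"target power {p_target:.3f} outside (0.2, 0.95); choose a scenario "
            "with moderate power for a stable sample-size match"
        )

    rej_ref0 = rejections(reference_method, n0)
    cache: dict[int, float] = {n0: float(rej_ref0.mean())}

    def p_ref(n: int) -> float:
        if n not in cache:
            cache[n] = float(rejections(reference_method, n).mean())
        return cache[n]

    mk = lambda n_star: EssResult(
        gain_percent=100.0 * (n_star / n0 - 1.0),
        n_matched=float(n_star),
        n_base=n0,
        target_power=p_target,
        reference_power_at_base=cache[n0],
        n_reps=reps,
        scenario_seed=scenario.seed,
        config_hash=scenario.config_hash(),
    )

    if np.array_equal(rej_ref0, rej_target):
        return mk(n0)  # same rejections replicate-by-replicate: same power curve

    n_floor = max(4, n0 // n_max_factor)
    if p_ref(n0) < p_target:  # reference needs MORE subjects (the usual case)
        lo, hi = n0, None
        n = 2 * n0
        while n <= n_max:
            if p_ref(n) >= p_target:
                hi = n
                break
            lo, n = n, 2 * n
        if hi is None:
            raise RuntimeError(
                f"reference power does not reach {p_target:.3f} within "
                f"n in [{n0}, {n_max}]; power curve not bracketed"
            )
    else:  # reference at least as powerful: search downward (negative gain)
        lo, hi = None, n0
        n = n0 // 2
        while n >= n_floor:
            if p_ref(n) <= p_target:
                lo = n
                break
            hi, n = n, n // 2
        if lo is None:
            lo = n_floor
            p_ref(lo)

    while hi - lo > 1:
        mid = (lo + hi) // 2
        if p_ref(mid) >= p_target:
            hi = mid
        else:
            lo = mid

    p_lo, p_hi = p_ref(lo), p_ref(hi)
    if p_hi > p_lo:
        n_star = lo + (p_target - p_lo) / (p_hi - p_lo) * (hi - lo)
    else:  # flat (MC ties): take the midpoint
        n_star = 0.5 * (lo + hi)
    n_star = float(min(max(n_star, n_floor), n_max))
    return mk(n_star)


def dichotomisation_cost_analytic(p: float) -> float:
    """Asymptotic sample-size ratio of a threshold proportions test vs a t-test.

    For a normal endpoint under a small location shift, cutting at the
    quantile where a fraction ``p`` responds and comparing proportions needs
    ``p (1 - p) / phi(Phi^-1(p))^2`` times the sample size of the two-sample
    comparison of means.  Minimised at the median cut p = 0.5, where it equals
    pi/2 (about 57% more subjects); it diverges as the cut moves into the
    tails.
    """
    p = float(p)
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be strictly inside (0, 1), got {p}")
    dens = stats.norm.pdf(stats.norm.ppf(p))
    return p * (1.0 - p) / dens**2
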
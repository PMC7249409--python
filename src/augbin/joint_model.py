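"""Joint model for a continuous and a binary trial outcome.

The model underlying the augmented binary analysis of a composite responder
endpoint with one dichotomised continuous component y and one binary
component b, for arm indicator z in {0, 1}:

    y | z      ~  Normal(alpha + theta * z, sigma^2)
    b | y, z   ~  Bernoulli( expit(gamma0 + gamma1 * z + gamma2 * y) )

Six parameters: alpha (control-arm mean), theta (arm effect on the mean),
sigma (residual SD, > 0), gamma0/gamma1 (logistic intercept and arm effect),
gamma2 (dependence of the binary component on the continuous value; fixing
gamma2 = 0 makes the two components independent given arm, and the joint
likelihood separates into a normal and a logistic part).

Missing components enter the likelihood by marginalisation and are assumed
missing at random given arm and the observed components: a missing b
contributes only the normal term; a missing y contributes the Bernoulli
probability integrated over the normal law of y (Gauss-Hermite quadrature).
The responder threshold never enters the likelihood — it only enters
inference — so fits are identical under any responder rule.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, special

from .data import TrialData

__all__ = [
    "JointParams",
    "FittedJointModel",
    "joint_loglik",
    "fit_joint_model",
    "estimate_boxcox",
    "apply_boxcox",
]

PARAM_NAMES = ("alpha", "theta", "sigma", "gamma0", "gamma1", "gamma2")

# Gauss-Hermite rule for marginalising a missing continuous value out of the
# Bernoulli probability; 40 nodes is ample for a logistic integrand.
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(40)
_GH_WEIGHTS = _GH_WEIGHTS / math.sqrt(math.pi)

# |gamma| beyond this on the logit scale is numerically indistinguishable
# from perfect separation of the binary sub-model.
_SEPARATION_LOGIT = 12.0


@dataclass(frozen=True)
class JointParams:
    alpha: float
    theta: float
    sigma: float
    gamma0: float
    gamma1: float
    gamma2: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"parameters must be finite, got {arr}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha, self.theta, self.sigma, self.gamma0, self.gamma1, self.gamma2],
            dtype=float,
        )

    @classmethod
    def from_array(cls, x) -> "JointParams":
        return cls(*(float(v) for v in x))


@dataclass
class FittedJointModel:
    params: JointParams
    vcov: np.ndarray  # 6x6, inverse observed information (symmetrised)
    loglik: float
    n_used: int
    converged: bool
    boxcox_lambda: Optional[float] = None
    message: str = ""
    gamma2_free: bool = True

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))


def _log_expit(eta):
    # log(expit(eta)) computed stably
    return -np.logaddexp(0.0, -eta)


def joint_loglik(params: JointParams, data: TrialData) -> float:
    """Joint log-likelihood of the trial data under ``params``.

    Each subject contributes the normal log-density of y (when observed) plus
    the Bernoulli log-probability of b (when observed), the latter conditional
    on y if y is observed and marginalised over the normal law of y otherwise.
    A subject with both components missing contributes 0.  Invariant to
    subject order.
    """
    if not isinstance(params, JointParams):
        params = JointParams.from_array(np.asarray(params, dtype=float))
    a, t, s, g0, g1, g2 = params.as_array()
    z, y, b = data.z, data.y, data.b
    oy = ~np.isnan(y)
    ob = ~np.isnan(b)

    ll = 0.0
    if oy.any():
        r = y[oy] - a - t * z[oy]
        ll += float(
            np.sum(-0.5 * math.log(2.0 * math.pi) - math.log(s) - 0.5 * (r / s) ** 2)
        )
    both = oy & ob
    if both.any():
        eta = g0 + g1 * z[both] + g2 * y[both]
        ll += float(np.sum(np.where(b[both] == 1.0, _log_expit(eta), _log_expit(-eta))))
    b_only = ob & ~oy
    if b_only.any():
        mu = a + t * z[b_only]
        # P(b=1 | z) = E_y[ expit(g0 + g1 z + g2 y) ], y ~ N(mu, s^2)
        eta = (
            g0
            + g1 * z[b_only, None]
            + g2 * (mu[:, None] + s * math.sqrt(2.0) * _GH_NODES[None, :])
        )
        p1 = np.clip(special.expit(eta) @ _GH_WEIGHTS, 1e-300, 1.0 - 1e-16)
        ll += float(np.sum(np.where(b[b_only] == 1.0, np.log(p1), np.log1p(-p1))))
    return ll


def _check_fit_preconditions(data: TrialData) -> None:
    for arm in (0, 1):
        m = (data.z == arm) & ~np.isnan(data.y)
        if m.sum() < 2:
            raise ValueError(
                f"need at least 2 non-missing continuous values in arm {arm}, "
                f"got {int(m.sum())}"
            )


def _start_values(data: TrialData) -> np.ndarray:
    """Moment-based starting values: per-arm means/SD for the normal part,
    overall logit response fraction for the logistic intercept."""
    z, y, b = data.z, data.y, data.b
    oy = ~np.isnan(y)
    m0 = float(np.mean(y[oy & (z == 0)]))
    m1 = float(np.mean(y[oy & (z == 1)]))
    sd = float(np.std(y[oy] - np.where(z[oy] == 1, m1, m0)))
    sd = max(sd, 1e-6)
    ob = ~np.isnan(b)
    pbar = float(np.mean(b[ob])) if ob.any() else 0.5
    pbar = min(max(pbar, 1e-3), 1.0 - 1e-3)
    g0 = math.log(pbar / (1.0 - pbar))
    return np.array([m0, m1 - m0, sd, g0, 0.0, 0.0])


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    k = len(x)
    h = rel_step * np.maximum(np.abs(x), 0.1)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def fit_joint_model(
    data: TrialData,
    gamma2_free: bool = True,
    boxcox_lambda: Optional[float] = None,
    gtol: float = 1e-8,
) -> FittedJointModel:
    """Maximum-likelihood fit of the joint model.

    Optimises (alpha, theta, log sigma, gamma0, gamma1[, gamma2]) with BFGS
    from moment-based starting values — fitting is deterministic given the
    data and options.  The covariance matrix is the inverse of the
    central-difference observed information in the natural parameters,
    symmetrised before inversion; with ``gamma2_free=False`` the gamma2
    row/column of the 6x6 vcov is zero.

    Complete separation of the binary sub-model (all observed b identical, or
    a diverging gamma estimate) is reported as ``converged=False`` with a
    diagnostic message rather than an exception.  A singular observed
    information raises, suggesting the simpler ``gamma2_free=False`` model.
    """
    _check_fit_preconditions(data)
    ob = ~np.isnan(data.b)
    n_used = int(np.sum(~np.isnan(data.y) | ob))

    x0 = _start_values(data)
    k = 6 if gamma2_free else 5

    separated = ob.any() and (np.all(data.b[ob] == 1.0) or np.all(data.b[ob] == 0.0))
    if separated:
        params = JointParams.from_array(x0)
        return FittedJointModel(
            params=params,
            vcov=np.full((6, 6), np.nan),
            loglik=float("nan"),
            n_used=n_used,
            converged=False,
            boxcox_lambda=boxcox_lambda,
            message=(
                "complete separation: every observed binary component equals "
                f"{int(data.b[ob][0])}; the logistic sub-model is not estimable"
            ),
            gamma2_free=gamma2_free,
        )

    def unpack(x: np.ndarray) -> np.ndarray:
        full = np.empty(6)
        full[0], full[1] = x[0], x[1]
        full[2] = math.exp(x[2])
        full[3], full[4] = x[3], x[4]
        full[5] = x[5] if gamma2_free else 0.0
        return full

    def negll(x: np.ndarray) -> float:
        full = unpack(x)
        if not np.all(np.isfinite(full)) or full[2] <= 0:
            return 1e12
        try:
            return -joint_loglik(JointParams.from_array(full), data)
        except (ValueError, FloatingPointError):
            return 1e12

    x0_opt = x0.copy()[:k]
    x0_opt[2] = math.log(x0[2])
    res = optimize.minimize(negll, x0_opt, method="BFGS", options={"gtol": gtol, "maxiter": 500})

    full = unpack(res.x)
    params = JointParams.from_array(full)
    loglik = -float(res.fun)

    gammas = full[3:]
    if np.any(np.abs(gammas) > _SEPARATION_LOGIT):
        return FittedJointModel(
            params=params,
            vcov=np.full((6, 6), np.nan),
            loglik=loglik,
            n_used=n_used,
            converged=False,
            boxcox_lambda=boxcox_lambda,
            message=(
                "quasi-complete separation: a logistic parameter diverged "
                f"(|gamma| > {_SEPARATION_LOGIT}); the binary sub-model is degenerate"
            ),
            gamma2_free=gamma2_free,
        )

    # Observed information in the NATURAL parameters (alpha..gamma2), so the
    # reported vcov is directly interpretable and delta-method ready.
    free = list(range(6)) if gamma2_free else [0, 1, 2, 3, 4]

    def negll_natural(xn: np.ndarray) -> float:
        full_n = full.copy()
        full_n[free] = xn
        if full_n[2] <= 0:
            return 1e12
        return -joint_loglik(JointParams.from_array(full_n), data)

    H = _numeric_hessian(negll_natural, full[free])
    H = 0.5 * (H + H.T)
    vcov6 = np.zeros((6, 6))
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            "singular observed information; the model is not identified on "
            "these data — consider fixing gamma2 = 0 (gamma2_free=False)"
        ) from exc
    if not np.all(np.isfinite(Hinv)) or np.any(np.diag(Hinv) <= 0):
        raise RuntimeError(
            "observed information is not positive definite at the optimum; "
            "consider the simpler model with gamma2 fixed at 0"
        )
    vcov6[np.ix_(free, free)] = 0.5 * (Hinv + Hinv.T)

    converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-3
    return FittedJointModel(
        params=params,
        vcov=vcov6,
        loglik=loglik,
        n_used=n_used,
        converged=converged,
        boxcox_lambda=boxcox_lambda,
        message=str(res.message),
        gamma2_free=gamma2_free,
    )


def apply_boxcox(y, lam: float):
    """Box-Cox power transform: (y^lam - 1)/lam, log y at lam = 0.

    Continuous in lam at 0; requires strictly positive input.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError(
            "Box-Cox requires strictly positive values; shift the variable first"
        )
    return special.boxcox(y, float(lam))


def estimate_boxcox(
    y,
    arm=None,
    grid: tuple[float, float, float] = (-3.0, 3.0, 0.01),
) -> float:
    """Profile-likelihood Box-Cox exponent over a grid (default [-3, 3], step 0.01).

    For each candidate lambda the data are transformed, residuals are taken
    about per-arm means when ``arm`` is given (profiling out the arm effect so
    a treatment shift is not mistaken for skew) or about the grand mean
    otherwise, and the normal profile log-likelihood with the Box-Cox Jacobian
    term (lambda - 1) * sum(log y) is evaluated.  Returns the maximising
    lambda.
    """
    y = np.asarray(y, dtype=float)
    y = y[~np.isnan(y)]
    if y.size < 3:
        raise ValueError("need at least 3 non-missing values to estimate lambda")
    if np.any(y <= 0):
        raise ValueError(
            "Box-Cox requires strictly positive values; shift the variable first"
        )
    if np.ptp(y) == 0:
        raise ValueError("continuous component is constant; lambda is undefined")
    if arm is not None:
        arm = np.asarray(arm)
        if len(arm) != len(y):
            raise ValueError("arm must align with y")
    lo, hi, step = grid
    lams = np.arange(lo, hi + step / 2, step)
    log_y_sum = float(np.sum(np.log(y)))
    n = y.size
    best_lam, best_ll = lams[0], -np.inf
    for lam in lams:
        t = special.boxcox(y, float(lam))
        if arm is None:
            rss = float(np.sum((t - t.mean()) ** 2))
        else:
            rss = 0.0
            for a in np.unique(arm):
                ta = t[arm == a]
                rss += float(np.sum((ta - ta.mean()) ** 2))
        if rss <= 0:
            continue
        ll = -0.5 * n * math.log(rss / n) + (lam - 1.0) * log_y_sum
        if ll > best_ll:
            best_ll, best_lam = ll, lam
    return float(best_lam)
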
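"""Maximum-likelihood estimation of the triad choice models.

All three variants are fitted by direct maximization of the Bernoulli
likelihood of the darker-test choices, aggregated to per-triad binomial
counts (the likelihood depends on the data only through these counts, so
fitting cost does not grow with the number of participants).

Monotonicity is enforced by construction: free parameters are the
*log-increments* of the curve ordinates (and the log of the baseline
slope), so every candidate g and f is strictly increasing.  Knot
abscissae are fixed — equally spaced over the observed stimulus range for
g, and over [0, max perceived one-sided difference under the current g]
for f (the f grid rides along with g's scale, which removes the
g-scale/f-domain indeterminacy of the joint model from the optimizer's
view).  Optimization is quasi-Newton (L-BFGS-B) with seeded multi-start;
the joint g+f fit is warm-started from the g-only solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize
from scipy.stats import norm

from .models import (
    KnotCurve,
    ScalingModel,
    LIKELIHOOD_EPS,
    aggregate_by_triad,
    responses_to_frame,
    triad_probabilities,
)

__all__ = ["FitConfig", "FitResult", "fit_model", "predict_accuracy"]

#: number of free ordinates per curve (origin excluded), after the study's
#: "origin plus four control points" convention
N_FREE_KNOTS = 4

_F_GRID = np.linspace(0.0, 1.0, N_FREE_KNOTS + 1)  # relative f abscissae
_THETA_BOUND = 30.0  # |log-increment| cap, guards exp overflow


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for :func:`fit_model`."""

    variant: str = "gf"
    n_restarts: int = 5
    seed: int = 0
    tolerance: float = 1e-6
    max_iterations: int = 500

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass(frozen=True)
class FitResult:
    """A fitted model with its training log-likelihood."""

    model: ScalingModel
    train_log_likelihood: float
    converged: bool
    n_responses: int


def _safe_exp(theta: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(theta, -_THETA_BOUND, _THETA_BOUND))


class _Objective:
    """Negative binomial log-likelihood over the aggregated counts."""

    def __init__(self, variant: str, counts, g_knots: np.ndarray):
        self.variant = variant
        self.g_knots = g_knots
        std = counts["standard"].to_numpy(dtype=float)
        self.dark = std - counts["d1"].to_numpy(dtype=float)
        self.mid = std
        self.light = std + counts["d2"].to_numpy(dtype=float)
        self.k = counts["k_dark"].to_numpy(dtype=float)
        self.n = counts["n"].to_numpy(dtype=float)
        self.stim = np.concatenate([self.dark, self.mid, self.light])
        self.n_params = {"baseline": 1, "g": N_FREE_KNOTS, "gf": 2 * N_FREE_KNOTS}[variant]

    def decision(self, theta: np.ndarray) -> np.ndarray:
        if self.variant == "baseline":
            slope = _safe_exp(theta)[0]
            return slope * ((self.mid - self.dark) - (self.light - self.mid))
        gy = np.concatenate([[0.0], np.cumsum(_safe_exp(theta[:N_FREE_KNOTS]))])
        g = PchipInterpolator(self.g_knots, gy)
        psi = g(self.stim)
        m = len(self.mid)
        u_dark = psi[m : 2 * m] - psi[:m]
        u_light = psi[2 * m :] - psi[m : 2 * m]
        if self.variant == "g":
            return u_dark - u_light
        u_max = max(u_dark.max(), u_light.max())
        f = PchipInterpolator(
            u_max * _F_GRID,
            np.concatenate([[0.0], np.cumsum(_safe_exp(theta[N_FREE_KNOTS:]))]),
        )
        return f(u_dark) - f(u_light)

    def __call__(self, theta: np.ndarray) -> float:
        p = np.clip(norm.cdf(self.decision(theta)), LIKELIHOOD_EPS, 1 - LIKELIHOOD_EPS)
        return -float(np.sum(self.k * np.log(p) + (self.n - self.k) * np.log1p(-p)))

    def build_model(self, theta: np.ndarray) -> ScalingModel:
        if self.variant == "baseline":
            return ScalingModel(variant="baseline", slope=float(_safe_exp(theta)[0]))
        gy = np.concatenate([[0.0], np.cumsum(_safe_exp(theta[:N_FREE_KNOTS]))])
        g = KnotCurve(self.g_knots, gy)
        if self.variant == "g":
            return ScalingModel(variant="g", g=g)
        psi = g(self.stim, warn=False)
        m = len(self.mid)
        u = np.concatenate([psi[m : 2 * m] - psi[:m], psi[2 * m :] - psi[m : 2 * m]])
        fy = np.concatenate([[0.0], np.cumsum(_safe_exp(theta[N_FREE_KNOTS:]))])
        f = KnotCurve(float(u.max()) * _F_GRID, fy)
        return ScalingModel(variant="gf", g=g, f=f)


def _baseline_slope_init(obj: _Objective) -> float:
    """Moment start: probit of the per-triad frequencies against d1 - d2."""
    phat = np.clip((obj.k + 0.5) / (obj.n + 1.0), 0.01, 0.99)
    z = norm.ppf(phat)
    dd = (obj.mid - obj.dark) - (obj.light - obj.mid)
    denom = float(np.sum(dd * dd))
    slope = float(np.sum(z * dd)) / denom if denom > 0 else 0.1
    return float(np.clip(slope, 1e-4, 1e4))


def _initial_theta(obj: _Objective, g_theta: np.ndarray | None = None) -> np.ndarray:
    slope0 = _baseline_slope_init(obj)
    if obj.variant == "baseline":
        return np.array([np.log(slope0)])
    if g_theta is None:
        inc = slope0 * (obj.g_knots[-1] - obj.g_knots[0]) / N_FREE_KNOTS
        g_theta = np.full(N_FREE_KNOTS, np.log(max(inc, 1e-8)))
    if obj.variant == "g":
        return g_theta.copy()
    # identity-like f start over the induced difference range
    gy = np.concatenate([[0.0], np.cumsum(_safe_exp(g_theta))])
    g = PchipInterpolator(obj.g_knots, gy)
    psi = g(obj.stim)
    m = len(obj.mid)
    u_max = float(
        np.max(
            np.concatenate(
                [psi[m : 2 * m] - psi[:m], psi[2 * m :] - psi[m : 2 * m]]
            )
        )
    )
    f_theta = np.full(N_FREE_KNOTS, np.log(max(u_max / N_FREE_KNOTS, 1e-8)))
    return np.concatenate([g_theta, f_theta])


def _minimize(obj: _Objective, theta0: np.ndarray, config: FitConfig):
    return minimize(
        obj,
        theta0,
        method="L-BFGS-B",
        options={
            "maxiter": config.max_iterations,
            "ftol": config.tolerance,
            "gtol": 1e-7,
        },
    )


def fit_model(responses, config: FitConfig) -> FitResult:
    """Fit one model variant to triad responses by maximum likelihood.

    Runs ``config.n_restarts`` optimizations (a deterministic start
    derived from the empirical probit slope, then seeded jittered starts)
    and returns the best.  ``converged`` reflects the optimizer status of
    the winning restart; on non-convergence the best iterate is still
    returned.
    """
    frame = responses_to_frame(responses)
    counts = aggregate_by_triad(frame)
    if len(counts) == 1 and counts["k_dark"].iloc[0] in (0, counts["n"].iloc[0]):
        raise ValueError("degenerate data: a single triad with unanimous responses")

    lo = float((counts["standard"] - counts["d1"]).min())
    hi = float((counts["standard"] + counts["d2"]).max())
    if hi <= lo:
        raise ValueError("responses span no stimulus range")
    g_knots = np.linspace(lo, hi, N_FREE_KNOTS + 1)

    obj = _Objective(_normalize_variant(config.variant), counts, g_knots)

    g_theta = None
    if obj.variant == "gf":
        # warm start: one g-only fit seeds the joint optimization
        g_obj = _Objective("g", counts, g_knots)
        res_g = _minimize(g_obj, _initial_theta(g_obj), config)
        g_theta = res_g.x

    theta0 = _initial_theta(obj, g_theta)
    rng = np.random.default_rng(config.seed)
    best = None
    for r in range(config.n_restarts):
        start = theta0 if r == 0 else theta0 + rng.normal(0.0, 0.5, size=obj.n_params)
        res = _minimize(obj, start, config)
        if best is None or res.fun < best.fun:
            best = res
    model = obj.build_model(best.x)
    return FitResult(
        model=model,
        train_log_likelihood=-float(best.fun),
        converged=bool(best.success),
        n_responses=int(counts["n"].sum()),
    )


def _normalize_variant(variant: str) -> str:
    aliases = {
        "baseline": "baseline",
        "g": "g",
        "perceptual": "g",
        "gf": "gf",
        "perceptual+difference": "gf",
        "perceptual_difference": "gf",
    }
    try:
        return aliases[variant]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}") from None


def predict_accuracy(model: ScalingModel, responses) -> float:
    """Fraction of responses matching the model's modal prediction.

    The model predicts the darker test wherever its choice probability
    exceeds one half; exact ties (p = 0.5) score half a point, so a model
    that is indifferent everywhere scores exactly 0.5.
    """
    counts = aggregate_by_triad(responses)
    p = triad_probabilities(model, counts, warn=False)
    k = counts["k_dark"].to_numpy(dtype=float)
    n = counts["n"].to_numpy(dtype=float)
    score = np.where(p > 0.5, k, np.where(p < 0.5, n - k, 0.5 * n))
    return float(score.sum() / n.sum())
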
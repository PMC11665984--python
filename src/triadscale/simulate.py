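"""Synthetic triad responses under the Thurstonian model with presentation noise.

The generative process for one trial of the method of triads:

1. In an uncontrolled (crowdsourced) viewing situation the displayed
   lightness deviates from the intended one.  Because all three patches of
   a trial are rendered on the same screen at the same time, the deviation
   ``delta ~ N(0, sigma_err)`` is shared by the whole triad — drawn once
   per trial (default) or once per participant session.
2. Each outer patch evokes a percept with discriminal dispersion
   ``sigma_disc`` (Thurstone Case V: one dispersion for all stimuli).  The
   comparison of the two perceived differences therefore carries decision
   noise with standard deviation ``sqrt(2) * sigma_disc``.
3. The darker test is chosen iff ``D_dark(delta) - D_light(delta) + eps > 0``
   where D are the model's perceived-difference magnitudes.

Defaults mirror the study being emulated: ``sigma_disc = 5`` L*-equivalent
units and, for the crowdsourced regime, ``sigma_err = 12`` (the worked
noise-budget example; the ratio 2.4 sits under the study's inferred upper
bound of ~3).  In-person simulation uses ``sigma_err = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import TriadDesign, Triad
from .models import KnotCurve, ScalingModel, RESPONSE_COLUMNS

__all__ = [
    "NoiseSpec",
    "SimulatedDataset",
    "simulate_dataset",
    "make_truth_model",
    "marginal_choice_probability",
    "TRUTH_PRESETS",
]

_ERROR_SCOPES = ("per_trial", "per_participant")
_MAX_RESAMPLE_ROUNDS = 200


@dataclass(frozen=True)
class NoiseSpec:
    """Dispersions driving the simulation.

    sigma_disc : discriminal dispersion of a single percept (> 0), in the
        truth model's perceived-strength units.
    sigma_err : SD of the shared presentation error, in L* units (>= 0).
    error_scope : whether the presentation error is redrawn every trial
        (``per_trial``) or held fixed for a participant's whole session
        (``per_participant``).
    """

    sigma_disc: float = 5.0
    sigma_err: float = 0.0
    error_scope: str = "per_trial"

    def __post_init__(self) -> None:
        if self.sigma_disc <= 0:
            raise ValueError(f"sigma_disc must be > 0, got {self.sigma_disc}")
        if self.sigma_err < 0:
            raise ValueError(f"sigma_err must be >= 0, got {self.sigma_err}")
        if self.error_scope not in _ERROR_SCOPES:
            raise ValueError(f"error_scope must be one of {_ERROR_SCOPES}")

    @classmethod
    def in_person(cls, sigma_disc: float = 5.0) -> "NoiseSpec":
        """Controlled-lab regime: no presentation error."""
        return cls(sigma_disc=sigma_disc, sigma_err=0.0)

    @classmethod
    def crowdsourced(cls, sigma_disc: float = 5.0, sigma_err: float = 12.0) -> "NoiseSpec":
        """Uncalibrated-display regime at the study's worked noise budget."""
        return cls(sigma_disc=sigma_disc, sigma_err=sigma_err)

    @property
    def decision_sd(self) -> float:
        """SD of the decision noise, ``sqrt(2) * sigma_disc``."""
        return float(np.sqrt(2.0) * self.sigma_disc)


@dataclass(frozen=True)
class SimulatedDataset:
    """Responses plus the exact generating state (model, noise, seed)."""

    responses: pd.DataFrame
    truth_model: ScalingModel
    noise: NoiseSpec
    seed: int

    @property
    def n_participants(self) -> int:
        return self.responses["participant"].nunique()


def _draw_offsets(rng, noise: NoiseSpec, lo, hi, shape) -> np.ndarray:
    """Presentation offsets within per-column bounds, resampled when outside.

    Resampling makes the realized offsets follow a normal truncated to the
    interval keeping every patch inside L* [0, 100]; the quadrature in
    :func:`marginal_choice_probability` integrates over the same law.
    """
    delta = rng.normal(0.0, noise.sigma_err, size=shape)
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = (delta < lo) | (delta > hi)
        if not bad.any():
            return delta
        delta = np.where(bad, rng.normal(0.0, noise.sigma_err, size=shape), delta)
    raise RuntimeError(
        "could not draw presentation offsets keeping all stimuli in [0, 100]; "
        "sigma_err too large for this design"
    )


def simulate_dataset(
    design: TriadDesign,
    model: ScalingModel,
    noise: NoiseSpec,
    n_participants: int,
    seed: int,
) -> SimulatedDataset:
    """Simulate every participant responding to every triad of the design.

    Deterministic under ``seed``: regenerating from the same (design,
    model, noise, seed) reproduces the responses exactly.
    """
    if len(design) == 0:
        raise ValueError("design must be non-empty")
    if n_participants < 1:
        raise ValueError(f"n_participants must be >= 1, got {n_participants}")
    rng = np.random.default_rng(seed)

    dark = np.array([t.dark for t in design])
    mid = np.array([t.standard for t in design])
    light = np.array([t.light for t in design])
    n_triads = len(design)

    if noise.sigma_err == 0.0:
        delta = np.zeros((n_participants, n_triads))
    elif noise.error_scope == "per_trial":
        lo, hi = -dark[None, :], 100.0 - light[None, :]
        delta = _draw_offsets(rng, noise, lo, hi, (n_participants, n_triads))
    else:  # one offset per participant, valid for every triad of the session
        lo, hi = -dark.min(), 100.0 - light.max()
        delta = _draw_offsets(rng, noise, lo, hi, (n_participants, 1))
        delta = np.broadcast_to(delta, (n_participants, n_triads)).copy()

    dd = model.decision_difference(
        dark[None, :] + delta, mid[None, :] + delta, light[None, :] + delta, warn=False
    )
    eps = rng.normal(0.0, noise.decision_sd, size=(n_participants, n_triads))
    chose_dark = (dd + eps) > 0
    dark_is_larger = np.array([t.d1 > t.d2 for t in design])
    correct = chose_dark == dark_is_larger[None, :]

    participants = np.array([f"p{i:03d}" for i in range(n_participants)])
    frame = pd.DataFrame(
        {
            "participant": np.repeat(participants, n_triads),
            "standard": np.tile(mid, n_participants),
            "d1": np.tile([t.d1 for t in design], n_participants),
            "d2": np.tile([t.d2 for t in design], n_participants),
            "chose_dark": chose_dark.ravel(),
            "correct": correct.ravel(),
        },
        columns=RESPONSE_COLUMNS,
    )
    return SimulatedDataset(responses=frame, truth_model=model, noise=noise, seed=seed)


TRUTH_PRESETS = ("linear", "concave_g", "diminishing_returns")


def make_truth_model(preset: str) -> ScalingModel:
    """Fully specified generating models used throughout testing.

    ``linear``
        Perceived strength is L* itself: baseline model with unit slope
        (the decision variable is ``d1 - d2`` in L* units; pair it with
        ``sigma_disc`` in the same units).
    ``concave_g``
        Compressive perceptual function ``g(x) = 100 * (x/100)**0.7``
        sampled at five equally spaced knots over the full L* range
        [0, 100]; no difference scaling.
    ``diminishing_returns``
        Linear g over [0, 100] plus a strictly concave difference-scaling
        f (``40 * (x/40)**0.6`` at knots 0, 10, 20, 30, 40): successive
        knot increments strictly decrease, the signature of diminishing
        returns.
    """
    if preset == "linear":
        return ScalingModel(variant="baseline", slope=1.0)
    if preset == "concave_g":
        x = np.linspace(0.0, 100.0, 5)
        y = 100.0 * (x / 100.0) ** 0.7
        return ScalingModel(variant="g", g=KnotCurve(x, y))
    if preset == "diminishing_returns":
        gx = np.linspace(0.0, 100.0, 5)
        g = KnotCurve(gx, gx)
        fx = np.linspace(0.0, 40.0, 5)
        f = KnotCurve(fx, 40.0 * (fx / 40.0) ** 0.6)
        return ScalingModel(variant="gf", g=g, f=f)
    raise ValueError(f"unknown preset {preset!r}; expected one of {TRUTH_PRESETS}")


def marginal_choice_probability(
    model: ScalingModel,
    triad: Triad,
    noise: NoiseSpec,
    n_nodes: int = 128,
) -> float:
    """Darker-choice probability marginalized over the presentation error.

    Integrates ``Phi(D(delta) / (sqrt(2) * sigma_disc))`` against the
    truncated-normal law of the shared offset (truncation keeps all three
    patches inside L* [0, 100], matching the simulator's resampling) using
    Gauss-Legendre quadrature.  With ``sigma_err = 0`` this reduces to the
    closed-form probability.
    """
    scale = noise.decision_sd

    def p_given(delta):
        dd = model.decision_difference(
            triad.dark + delta, triad.standard + delta, triad.light + delta, warn=False
        )
        return norm.cdf(np.asarray(dd, dtype=float) / scale)

    if noise.sigma_err == 0.0:
        return float(p_given(0.0))

    a, b = -triad.dark, 100.0 - triad.light
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    delta = 0.5 * (b - a) * nodes + 0.5 * (b + a)
    w = 0.5 * (b - a) * weights * norm.pdf(delta, scale=noise.sigma_err)
    z = norm.cdf(b / noise.sigma_err) - norm.cdf(a / noise.sigma_err)
    return float(np.sum(w * p_given(delta)) / z)
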
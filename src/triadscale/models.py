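"""Choice models for the method of triads under Thurstonian comparative judgment.

Three nested models map a triad to the probability that the observer calls
the *darker* test more different from the standard:

* ``baseline`` — perceived strength is linear in L*: the decision variable
  is ``slope * (d1 - d2)``.
* ``g`` — a monotone perceptual function ``g(x)`` maps L* to perceived
  strength psi; the decision variable is ``(g(mid) - g(dark)) - (g(light) - g(mid))``.
* ``gf`` — additionally a monotone difference-scaling function ``f`` maps a
  difference of perceived strengths to a perceived difference magnitude:
  ``f(g(mid) - g(dark)) - f(g(light) - g(mid))``.  A concave ``f`` expresses
  diminishing returns (a large difference is judged smaller than the sum of
  its parts).

Each decision variable is pushed through the standard normal CDF with a
fixed unit scale (Thurstone Case V identifiability convention: the model's
inverse-normal link has standard deviation 1, absorbing the discriminal
dispersion into the curves).

``g`` and ``f`` are monotone piecewise-cubic (PCHIP / Fritsch-Carlson type)
curves through an origin plus free control points; only ordinates are
estimated, abscissae are fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import norm

from .design import Triad

__all__ = [
    "KnotCurve",
    "ScalingModel",
    "ResponseRecord",
    "ExtrapolationWarning",
    "VARIANTS",
    "eval_curve",
    "choice_probability",
    "log_likelihood",
    "rescale_model",
    "responses_to_frame",
    "frame_to_records",
    "aggregate_by_triad",
    "RESPONSE_COLUMNS",
]

VARIANTS = ("baseline", "g", "gf")
_VARIANT_ALIASES = {
    "baseline": "baseline",
    "g": "g",
    "perceptual": "g",
    "gf": "gf",
    "perceptual+difference": "gf",
    "perceptual_difference": "gf",
}

#: Probabilities are clipped into [eps, 1-eps] inside the likelihood.
LIKELIHOOD_EPS = 1e-9

RESPONSE_COLUMNS = ["participant", "standard", "d1", "d2", "chose_dark", "correct"]


class ExtrapolationWarning(UserWarning):
    """A curve was evaluated outside its knot range (flat extrapolation used)."""


class KnotCurve:
    """Monotone non-decreasing curve through fixed knots.

    The first knot is the curve's origin and must carry ordinate 0 (the
    perceptual scale is anchored there).  Interpolation is shape-preserving
    piecewise cubic (PCHIP), so values between knots never overshoot the
    bracketing ordinates.  Outside the knot range the curve extrapolates
    flat and emits :class:`ExtrapolationWarning`.
    """

    def __init__(
        self,
        knot_x: Sequence[float],
        knot_y: Sequence[float],
        require_origin: bool = True,
    ):
        x = np.asarray(knot_x, dtype=float)
        y = np.asarray(knot_y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape or x.size < 2:
            raise ValueError("knot_x and knot_y must be 1-D, equal length, >= 2 knots")
        if not np.all(np.diff(x) > 0):
            raise ValueError("knot_x must be strictly ascending")
        if np.any(np.diff(y) < 0):
            raise ValueError("knot_y must be non-decreasing")
        if require_origin and y[0] != 0.0:
            raise ValueError(f"origin ordinate must be 0, got {y[0]}")
        self.knot_x = x
        self.knot_y = y
        self._interp = PchipInterpolator(x, y, extrapolate=False)

    @classmethod
    def linear(cls, x0: float, x1: float, slope: float, n_knots: int = 2) -> "KnotCurve":
        """Straight line of given slope anchored at ``(x0, 0)``."""
        x = np.linspace(x0, x1, n_knots)
        return cls(x, slope * (x - x0))

    def __call__(self, x, warn: bool = True):
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        xc = np.clip(x, self.knot_x[0], self.knot_x[-1])
        if warn and np.any(xc != x):
            warnings.warn(
                f"evaluating curve outside knot range "
                f"[{self.knot_x[0]}, {self.knot_x[-1]}]; flat extrapolation used",
                ExtrapolationWarning,
                stacklevel=2,
            )
        out = self._interp(xc)
        return float(out) if scalar else out

    @property
    def span(self) -> float:
        """Total rise of the curve over its knot range."""
        return float(self.knot_y[-1] - self.knot_y[0])

    def increments(self) -> np.ndarray:
        """Successive ordinate differences between knots."""
        return np.diff(self.knot_y)

    def to_dict(self) -> dict:
        return {"knot_x": self.knot_x.tolist(), "knot_y": self.knot_y.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "KnotCurve":
        return cls(d["knot_x"], d["knot_y"], require_origin=False)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, KnotCurve)
            and np.array_equal(self.knot_x, other.knot_x)
            and np.array_equal(self.knot_y, other.knot_y)
        )

    def __repr__(self) -> str:
        pts = ", ".join(f"({x:g}, {y:g})" for x, y in zip(self.knot_x, self.knot_y))
        return f"KnotCurve[{pts}]"


def eval_curve(curve: KnotCurve, x):
    """Evaluate a :class:`KnotCurve` (module-level convenience)."""
    return curve(x)


@dataclass(frozen=True)
class ScalingModel:
    """One of the three nested triad choice models.

    Exactly the fields the variant needs are populated: ``slope`` for
    ``baseline``; ``g`` for ``g``; ``g`` and ``f`` for ``gf``.  ``link_sd``
    is fixed at 1 by convention.
    """

    variant: str
    slope: float | None = None
    g: KnotCurve | None = None
    f: KnotCurve | None = None
    link_sd: float = 1.0

    def __post_init__(self) -> None:
        variant = _VARIANT_ALIASES.get(self.variant)
        if variant is None:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        object.__setattr__(self, "variant", variant)
        if self.link_sd != 1.0:
            raise ValueError("link_sd is fixed at 1 (identifiability convention)")
        if variant == "baseline":
            if self.slope is None or self.slope <= 0:
                raise ValueError("baseline variant requires a positive slope")
            if self.g is not None or self.f is not None:
                raise ValueError("baseline variant must not carry curves")
        else:
            if self.g is None:
                raise ValueError(f"variant {variant!r} requires a perceptual curve g")
            if self.slope is not None:
                raise ValueError("curve variants must not carry a baseline slope")
            if variant == "g" and self.f is not None:
                raise ValueError("variant 'g' must not carry a difference-scaling curve")
            if variant == "gf" and self.f is None:
                raise ValueError("variant 'gf' requires a difference-scaling curve f")

    # -- decision machinery -------------------------------------------------

    def domain(self) -> tuple[float, float] | None:
        """Stimulus range over which g is defined (None for baseline)."""
        if self.g is None:
            return None
        return float(self.g.knot_x[0]), float(self.g.knot_x[-1])

    def decision_difference(self, dark, mid, light, warn: bool = True) -> np.ndarray:
        """Vectorized ``D_dark - D_light`` for stimulus arrays (L* units)."""
        dark = np.asarray(dark, dtype=float)
        mid = np.asarray(mid, dtype=float)
        light = np.asarray(light, dtype=float)
        if self.variant == "baseline":
            return self.slope * ((mid - dark) - (light - mid))
        psi_d = self.g(dark, warn=warn)
        psi_m = self.g(mid, warn=warn)
        psi_l = self.g(light, warn=warn)
        u_dark = psi_m - psi_d
        u_light = psi_l - psi_m
        if self.variant == "gf":
            return self.f(u_dark, warn=warn) - self.f(u_light, warn=warn)
        return u_dark - u_light

    def to_dict(self) -> dict:
        d: dict = {"variant": self.variant, "link_sd": self.link_sd}
        if self.slope is not None:
            d["slope"] = self.slope
        if self.g is not None:
            d["g"] = self.g.to_dict()
        if self.f is not None:
            d["f"] = self.f.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingModel":
        return cls(
            variant=d["variant"],
            slope=d.get("slope"),
            g=KnotCurve.from_dict(d["g"]) if "g" in d else None,
            f=KnotCurve.from_dict(d["f"]) if "f" in d else None,
            link_sd=d.get("link_sd", 1.0),
        )


@dataclass(frozen=True)
class ResponseRecord:
    """One participant judgment on one triad.

    ``chose_dark`` is True when the darker test was called more different;
    ``correct`` means the physically larger L* difference was chosen, which
    is equivalent to ``chose_dark == (d1 > d2)``.
    """

    participant: str
    triad: Triad
    chose_dark: bool
    correct: bool

    def __post_init__(self) -> None:
        expected = self.chose_dark == (self.triad.d1 > self.triad.d2)
        if self.correct != expected:
            raise ValueError(
                f"inconsistent correct flag for triad {self.triad}: "
                f"chose_dark={self.chose_dark} implies correct={expected}"
            )


def responses_to_frame(responses) -> pd.DataFrame:
    """Normalize responses (records or DataFrame) to the tabular schema."""
    if isinstance(responses, pd.DataFrame):
        missing = [c for c in RESPONSE_COLUMNS if c not in responses.columns]
        if missing:
            raise ValueError(f"response table missing columns {missing}")
        return responses
    rows = list(responses)
    return pd.DataFrame(
        {
            "participant": [r.participant for r in rows],
            "standard": [r.triad.standard for r in rows],
            "d1": [r.triad.d1 for r in rows],
            "d2": [r.triad.d2 for r in rows],
            "chose_dark": [r.chose_dark for r in rows],
            "correct": [r.correct for r in rows],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[ResponseRecord]:
    """Materialize a response table as :class:`ResponseRecord` objects."""
    return [
        ResponseRecord(
            participant=str(row.participant),
            triad=Triad(row.standard, row.d1, row.d2),
            chose_dark=bool(row.chose_dark),
            correct=bool(row.correct),
        )
        for row in frame.itertuples(index=False)
    ]


def aggregate_by_triad(responses) -> pd.DataFrame:
    """Collapse responses to per-triad binomial counts.

    Returns one row per unique triad with columns ``standard, d1, d2,
    n, k_dark`` (responses and darker-test choices).  The likelihood only
    depends on these counts, which keeps fitting cost independent of the
    number of participants.
    """
    frame = responses_to_frame(responses)
    if len(frame) == 0:
        raise ValueError("empty response set")
    grouped = (
        frame.groupby(["standard", "d1", "d2"], sort=True)
        .agg(n=("chose_dark", "size"), k_dark=("chose_dark", "sum"))
        .reset_index()
    )
    return grouped


def _check_domain(model: ScalingModel, triad: Triad, offset: float) -> None:
    dom = model.domain()
    if dom is None:
        return
    lo, hi = dom
    for name, value in (
        ("dark", triad.dark + offset),
        ("standard", triad.standard + offset),
        ("light", triad.light + offset),
    ):
        if value < lo or value > hi:
            raise ValueError(
                f"stimulus {name}={value} outside model domain [{lo}, {hi}]"
            )


def choice_probability(
    model: ScalingModel, triad: Triad, presentation_offset: float = 0.0
) -> float:
    """Probability of choosing the darker test, ``Phi(D_dark - D_light)``.

    ``presentation_offset`` shifts all three stimuli by the same amount
    (the crowdsourcing presentation-error mechanism); for curve variants
    all shifted stimuli must lie inside g's knot range.
    """
    _check_domain(model, triad, presentation_offset)
    d = model.decision_difference(
        triad.dark + presentation_offset,
        triad.standard + presentation_offset,
        triad.light + presentation_offset,
    )
    return float(norm.cdf(d / model.link_sd))


def triad_probabilities(model: ScalingModel, table: pd.DataFrame, warn: bool = True) -> np.ndarray:
    """Vectorized darker-choice probabilities for a per-triad table."""
    dark = table["standard"].to_numpy() - table["d1"].to_numpy()
    mid = table["standard"].to_numpy(dtype=float)
    light = table["standard"].to_numpy() + table["d2"].to_numpy()
    d = model.decision_difference(dark, mid, light, warn=warn)
    return norm.cdf(np.asarray(d, dtype=float) / model.link_sd)


def log_likelihood(model: ScalingModel, responses, eps: float = LIKELIHOOD_EPS) -> float:
    """Bernoulli log-likelihood of the observed choices under the model.

    Probabilities are clipped to ``[eps, 1-eps]`` so the result is finite.
    """
    counts = aggregate_by_triad(responses)
    p = np.clip(triad_probabilities(model, counts), eps, 1.0 - eps)
    k = counts["k_dark"].to_numpy(dtype=float)
    n = counts["n"].to_numpy(dtype=float)
    return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def rescale_model(
    model: ScalingModel, stimulus_range: tuple[float, float] | None = None
) -> tuple[ScalingModel, dict]:
    """Presentation form of a curve model with g normalized to span [0, 1].

    Divides g's ordinates by its rise over ``stimulus_range`` (default: its
    full knot range) and compensates f's domain by the same factor, so
    every triad choice probability is unchanged (PCHIP interpolation
    commutes with positive affine maps of the ordinates).  A ``g``-variant
    model gains an explicit linear f carrying the compensation, making the
    result a ``gf`` model.  Returns ``(rescaled_model, report)`` where the
    report records the scale factor and shift.
    """
    if model.variant == "baseline":
        raise ValueError("rescale_model applies to curve variants only")
    g = model.g
    if stimulus_range is None:
        stimulus_range = (float(g.knot_x[0]), float(g.knot_x[-1]))
    lo, hi = stimulus_range
    if not (g.knot_x[0] <= lo < hi <= g.knot_x[-1]):
        raise ValueError(
            f"stimulus_range {stimulus_range} not inside g's knot range "
            f"[{g.knot_x[0]}, {g.knot_x[-1]}]"
        )
    g_lo, g_hi = g(lo), g(hi)
    span = g_hi - g_lo
    if span <= 1e-12:
        raise ValueError("degenerate (flat) perceptual curve cannot be rescaled")
    new_g = KnotCurve(g.knot_x, (g.knot_y - g_lo) / span, require_origin=False)

    if model.variant == "gf":
        old_f = model.f
        new_f = KnotCurve(old_f.knot_x / span, old_f.knot_y, require_origin=False)
    else:
        # implicit identity f: compensation is the line v -> span * v
        u_max = float(g.knot_y[-1] - g.knot_y[0])
        new_f = KnotCurve.linear(0.0, max(u_max, span) / span, span)
    report = {"scale": 1.0 / span, "shift": -float(g_lo) / span, "stimulus_range": [lo, hi]}
    return ScalingModel(variant="gf", g=new_g, f=new_f), report
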
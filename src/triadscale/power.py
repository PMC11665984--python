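"""Sample-size planning for crowdsourced versus in-person perceptual studies.

In an uncalibrated setting the percept of a stimulus is the convolution of
two normal components — the discriminal dispersion ``sigma_disc`` inherent
to perception and a presentation error ``sigma_err`` from uncontrolled
display conditions — giving an effective dispersion

    sigma_cs = sqrt(sigma_disc**2 + sigma_err**2).

Because the extra noise is zero-mean, the crowdsourced sample mean targets
the same perceived strength as the in-person one; equating the standard
errors of the two sample means yields the sample-size relation

    n_cs = n_in * sigma_cs**2 / sigma_disc**2,

its inversion ``sigma_err / sigma_disc = sqrt(n_cs / n_in - 1)`` (an upper
bound on how badly displays vary, inferred from two studies that agreed),
and the effect-size rescaling ``d_cs = d_in * sigma_disc / sigma_cs`` used
to feed a-priori power analyses.  The a-priori planner solves the
two-sample difference-of-means design with the noncentral-t power
function (one-tailed by default — the convention that reproduces the
published worked examples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "NoiseBudget",
    "SampleSizePlan",
    "PowerSpec",
    "CLTReport",
    "combined_sd",
    "crowdsourced_sample_size",
    "noise_ratio_from_sizes",
    "rescaled_effect_size",
    "two_sample_t_power",
    "required_sample_size_ttest",
    "verify_clt_equivalence",
]


@dataclass(frozen=True)
class NoiseBudget:
    """The two dispersions and their combination (enforced on construction)."""

    sigma_disc: float
    sigma_err: float
    sigma_cs: float

    def __post_init__(self) -> None:
        if self.sigma_disc <= 0:
            raise ValueError(f"sigma_disc must be > 0, got {self.sigma_disc}")
        if self.sigma_err < 0:
            raise ValueError(f"sigma_err must be >= 0, got {self.sigma_err}")
        expected = math.hypot(self.sigma_disc, self.sigma_err)
        if not math.isclose(self.sigma_cs, expected, rel_tol=1e-9):
            raise ValueError(
                f"sigma_cs={self.sigma_cs} violates sigma_cs^2 = "
                f"sigma_disc^2 + sigma_err^2 (expected {expected})"
            )

    @classmethod
    def from_components(cls, sigma_disc: float, sigma_err: float) -> "NoiseBudget":
        return cls(sigma_disc, sigma_err, combined_sd(sigma_disc, sigma_err))


@dataclass(frozen=True)
class SampleSizePlan:
    """Matched sample sizes for the two study regimes under one noise budget."""

    n_in: int
    n_cs: int  # ceiling integer
    n_cs_exact: float
    budget: NoiseBudget

    def __post_init__(self) -> None:
        if self.n_in < 1 or self.n_cs < 1:
            raise ValueError("sample sizes must be >= 1")
        if self.n_cs < self.n_in:
            raise ValueError("n_cs must be >= n_in")


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of an a-priori two-sample power analysis."""

    effect_size: float
    alpha: float = 0.05
    power: float = 0.95
    tails: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.alpha < self.power < 1.0:
            raise ValueError(f"power must be in (alpha, 1), got {self.power}")
        if self.effect_size <= 0:
            raise ValueError(f"effect_size must be > 0, got {self.effect_size}")
        if self.tails not in (1, 2):
            raise ValueError(f"tails must be 1 or 2, got {self.tails}")


def combined_sd(sigma_disc: float, sigma_err: float) -> float:
    """Effective crowdsourced dispersion ``sqrt(sigma_disc^2 + sigma_err^2)``."""
    if sigma_disc <= 0:
        raise ValueError(f"sigma_disc must be > 0, got {sigma_disc}")
    if sigma_err < 0:
        raise ValueError(f"sigma_err must be >= 0, got {sigma_err}")
    return math.hypot(sigma_disc, sigma_err)


def crowdsourced_sample_size(
    n_in: int, sigma_disc: float, sigma_err: float
) -> SampleSizePlan:
    """Crowdsourced sample size matching the in-person standard error.

    ``n_cs = n_in * (sigma_disc^2 + sigma_err^2) / sigma_disc^2``, reported
    exactly and rounded up to an integer.  With ``sigma_err = 2*sigma_disc``
    and ``n_in = 12`` this gives 60; with ``sigma_err = 3*sigma_disc``, 120.
    """
    if n_in < 1:
        raise ValueError(f"n_in must be >= 1, got {n_in}")
    budget = NoiseBudget.from_components(sigma_disc, sigma_err)
    exact = n_in * budget.sigma_cs**2 / budget.sigma_disc**2
    return SampleSizePlan(
        n_in=int(n_in),
        n_cs=int(math.ceil(exact - 1e-9)),
        n_cs_exact=float(exact),
        budget=budget,
    )


def noise_ratio_from_sizes(n_in: int, n_cs: int) -> float:
    """Invert the sample-size relation: ``sigma_err/sigma_disc = sqrt(n_cs/n_in - 1)``.

    Given two studies of matched precision this bounds how large the
    presentation error can have been relative to the discriminal
    dispersion (34 in-person vs ~300 crowdsourced gives about 2.8).
    """
    if n_in < 1:
        raise ValueError(f"n_in must be >= 1, got {n_in}")
    if n_cs < n_in:
        raise ValueError(f"n_cs={n_cs} must be >= n_in={n_in}")
    return math.sqrt(n_cs / n_in - 1.0)


def rescaled_effect_size(d_in: float, sigma_disc: float, sigma_err: float) -> float:
    """Standardized effect size after inflating the SD by presentation noise.

    ``d_cs = d_in * sigma_disc / sqrt(sigma_disc^2 + sigma_err^2)``: the
    raw mean difference is unchanged, only the denominator grows.
    """
    if d_in <= 0:
        raise ValueError(f"d_in must be > 0, got {d_in}")
    return d_in * sigma_disc / combined_sd(sigma_disc, sigma_err)


def two_sample_t_power(effect_size: float, n_total: int, alpha: float, tails: int) -> float:
    """Power of the two-sample t-test at equal allocation (noncentral t)."""
    if n_total < 4 or n_total % 2:
        raise ValueError(f"n_total must be an even integer >= 4, got {n_total}")
    n_group = n_total // 2
    df = n_total - 2
    nc = effect_size * math.sqrt(n_group / 2.0)
    if tails == 1:
        t_crit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(t_crit, df, nc))
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(t_crit, df, nc) + stats.nct.cdf(-t_crit, df, nc))


def required_sample_size_ttest(spec: PowerSpec, n_max: int = 10**6) -> int:
    """Smallest even total n reaching the requested power (a-priori planning).

    Equal allocation across two groups; power is evaluated with the
    noncentral-t distribution at each candidate size.  Raises if the
    request is unattainable below ``n_max``.
    """
    n = 4
    while n <= n_max:
        if two_sample_t_power(spec.effect_size, n, spec.alpha, spec.tails) >= spec.power:
            return n
        n += 2
    raise ValueError(
        f"requested power {spec.power} unattainable below n_total={n_max} "
        f"for effect size {spec.effect_size}"
    )


@dataclass(frozen=True)
class CLTReport:
    """Outcome of the equivalence-of-means simulation."""

    sd_ratio: float  # SD(crowdsourced means) / SD(in-person means)
    mean_difference: float  # crowdsourced grand mean - in-person grand mean
    mean_difference_se: float  # standard error of that difference
    n_in: int
    n_cs: int
    n_reps: int


def verify_clt_equivalence(
    sigma_disc: float,
    sigma_err: float,
    n_in: int,
    n_reps: int = 10_000,
    seed: int = 0,
    psi: float = 50.0,
    n_cs: int | None = None,
) -> CLTReport:
    """Simulation check that matched sample sizes equate the two study designs.

    Draws ``n_reps`` in-person mean percepts (``n_in`` draws of SD
    ``sigma_disc`` around ``psi``) and ``n_reps`` crowdsourced mean
    percepts (``n_cs`` draws of SD ``sigma_cs``); when ``n_cs`` follows
    the sample-size relation, the two sampling distributions share their
    mean and, asymptotically, their SD (ratio -> 1).  Pass ``n_cs``
    explicitly to probe a mismatched size.
    """
    if n_reps < 1000:
        raise ValueError(f"n_reps must be >= 1000 for stable SD estimates, got {n_reps}")
    plan = crowdsourced_sample_size(n_in, sigma_disc, sigma_err)
    if n_cs is None:
        n_cs = plan.n_cs
    rng = np.random.default_rng(seed)
    means_in = rng.normal(psi, sigma_disc, size=(n_reps, n_in)).mean(axis=1)
    means_cs = rng.normal(psi, plan.budget.sigma_cs, size=(n_reps, n_cs)).mean(axis=1)
    sd_in = means_in.std(ddof=1)
    sd_cs = means_cs.std(ddof=1)
    diff_se = math.sqrt(sd_in**2 / n_reps + sd_cs**2 / n_reps)
    return CLTReport(
        sd_ratio=float(sd_cs / sd_in),
        mean_difference=float(means_cs.mean() - means_in.mean()),
        mean_difference_se=float(diff_se),
        n_in=int(n_in),
        n_cs=int(n_cs),
        n_reps=int(n_reps),
    )
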
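"""Model validation: participant-level cross-validation, bootstrap bands,
per-triad summaries, and between-study comparison.

Cross-validation is leave-one-participant-out: each participant's
responses are held out once, each model variant is refitted on the rest,
and predictive accuracy on the held-out responses scores the variant.
Bootstrap uncertainty resamples *participants* with replacement (responses
from one participant are dependent, so they travel together); each refit
is rescaled to the presentation convention (g spanning [0, 1]) before
curves are pooled into pointwise quantile bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .fit import FitConfig, fit_model, predict_accuracy, _normalize_variant
from .models import responses_to_frame, rescale_model

__all__ = [
    "CVResult",
    "BootstrapBand",
    "TriadSummary",
    "StudyComparison",
    "loo_cv",
    "bootstrap_bands",
    "per_triad_summary",
    "compare_studies",
]


def _fold_seed(seed: int, index: int) -> int:
    """Stable, collision-free per-fold seed below 2**31."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class CVResult:
    """Per-fold accuracies of leave-one-participant-out cross-validation."""

    folds: pd.DataFrame  # columns: participant, variant, accuracy, converged

    def summary(self) -> pd.DataFrame:
        """Per-variant mean and SD of held-out accuracy."""
        return (
            self.folds.groupby("variant")["accuracy"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )

    def pairwise_differences(self) -> pd.DataFrame:
        """Differences of per-variant mean accuracies for every pair."""
        means = self.folds.groupby("variant")["accuracy"].mean()
        rows = [
            {"variant_a": a, "variant_b": b, "mean_difference": means[a] - means[b]}
            for i, a in enumerate(means.index)
            for b in means.index[i + 1 :]
        ]
        return pd.DataFrame(rows)


def loo_cv(responses, variants: Iterable[str], config: FitConfig) -> CVResult:
    """Leave-one-participant-out cross-validation over model variants.

    Folds are ordered by sorted participant id and seeded from
    ``config.seed``, so the result is deterministic.  A fold whose fit
    does not converge is recorded with ``converged=False`` rather than
    dropped.
    """
    frame = responses_to_frame(responses)
    participants = sorted(frame["participant"].unique())
    if len(participants) < 2:
        raise ValueError("leave-one-out cross-validation needs >= 2 participants")
    variants = list(variants)
    rows = []
    for i, held_out in enumerate(participants):
        train = frame[frame["participant"] != held_out]
        test = frame[frame["participant"] == held_out]
        for variant in variants:
            cfg = replace(config, variant=variant, seed=_fold_seed(config.seed, i))
            result = fit_model(train, cfg)
            rows.append(
                {
                    "participant": held_out,
                    "variant": variant,
                    "accuracy": predict_accuracy(result.model, test),
                    "converged": result.converged,
                }
            )
    return CVResult(folds=pd.DataFrame(rows))


@dataclass(frozen=True)
class BootstrapBand:
    """Pointwise quantile envelope of bootstrap-refitted curves."""

    grid: np.ndarray
    lower: np.ndarray
    point: np.ndarray  # pointwise median
    upper: np.ndarray
    level: float
    n_boot: int
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper):
            raise ValueError("band lower edge exceeds upper edge")

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.grid, "lower": self.lower, "point": self.point, "upper": self.upper}
        )


def _band(grid: np.ndarray, curves: np.ndarray, level: float, n_boot: int, skipped: int) -> BootstrapBand:
    lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    return BootstrapBand(
        grid=grid,
        lower=np.quantile(curves, lo_q, axis=0),
        point=np.quantile(curves, 0.5, axis=0),
        upper=np.quantile(curves, hi_q, axis=0),
        level=level,
        n_boot=n_boot,
        n_skipped=skipped,
    )


def bootstrap_bands(
    responses,
    variant: str,
    n_boot: int,
    level: float = 0.95,
    seed: int = 0,
    config: FitConfig | None = None,
    grid_size: int = 101,
) -> dict[str, BootstrapBand]:
    """Bootstrap envelopes ("middle ``level``" of learned curves) for g and f.

    Participants are resampled with replacement ``n_boot`` times; each
    resample is refitted and rescaled so g spans [0, 1] over the full
    dataset's stimulus range.  g is evaluated on ``grid_size`` equally
    spaced stimulus values; for the ``gf`` variant, f is evaluated on
    [0, 1] in rescaled perceived-strength units (flat-clamped where a
    resample's difference range falls short).  Degenerate resamples that
    cannot be fitted are skipped and counted in ``n_skipped``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must be in [0, 1]")
    frame = responses_to_frame(responses)
    participants = sorted(frame["participant"].unique())
    if len(participants) < 2:
        raise ValueError("bootstrap needs >= 2 participants")
    variant = _normalize_variant(variant)
    if variant == "baseline":
        raise ValueError("bootstrap bands apply to curve variants ('g' or 'gf')")
    config = replace(config or FitConfig(), variant=variant)

    lo = float((frame["standard"] - frame["d1"]).min())
    hi = float((frame["standard"] + frame["d2"]).max())
    g_grid = np.linspace(lo, hi, grid_size)
    f_grid = np.linspace(0.0, 1.0, grid_size)
    by_participant = dict(tuple(frame.groupby("participant")))

    rng = np.random.default_rng(seed)
    g_curves, f_curves, skipped = [], [], 0
    for b in range(n_boot):
        chosen = rng.choice(participants, size=len(participants), replace=True)
        sample = pd.concat([by_participant[p] for p in chosen], ignore_index=True)
        try:
            cfg = replace(config, seed=_fold_seed(seed, b))
            result = fit_model(sample, cfg)
            rescaled, _ = rescale_model(result.model, (lo, hi))
        except (ValueError, RuntimeError):
            skipped += 1
            continue
        g_curves.append(rescaled.g(g_grid, warn=False))
        if variant == "gf":
            f_curves.append(rescaled.f(f_grid, warn=False))
    if not g_curves:
        raise RuntimeError("every bootstrap resample was degenerate")

    bands = {"g": _band(g_grid, np.asarray(g_curves), level, n_boot, skipped)}
    if f_curves:
        bands["f"] = _band(f_grid, np.asarray(f_curves), level, n_boot, skipped)
    return bands


@dataclass(frozen=True)
class TriadSummary:
    """Per-triad response proportions (lighter-choice and correctness)."""

    table: pd.DataFrame  # columns: standard, d1, d2, n, prop_lighter, prop_correct

    def __len__(self) -> int:
        return len(self.table)


def per_triad_summary(responses) -> TriadSummary:
    """Group responses by triad and report choice and accuracy proportions."""
    frame = responses_to_frame(responses)
    if len(frame) == 0:
        raise ValueError("empty response set")
    table = (
        frame.groupby(["standard", "d1", "d2"], sort=True)
        .agg(
            n=("chose_dark", "size"),
            prop_lighter=("chose_dark", lambda s: 1.0 - s.mean()),
            prop_correct=("correct", "mean"),
        )
        .reset_index()
    )
    return TriadSummary(table=table)


class StudyComparison(NamedTuple):
    r: float
    t: float
    df: int


def compare_studies(a: TriadSummary, b: TriadSummary) -> StudyComparison:
    """Pearson correlation of lighter-choice proportions across shared triads.

    Returns ``(r, t, df)`` with ``t = r * sqrt(df / (1 - r^2))`` and
    ``df = n_shared - 2`` — the statistic used to report between-study
    agreement of per-triad response patterns.
    """
    merged = a.table.merge(b.table, on=["standard", "d1", "d2"], suffixes=("_a", "_b"))
    n = len(merged)
    if n < 3:
        raise ValueError(f"studies share only {n} triads; need >= 3")
    x = merged["prop_lighter_a"].to_numpy(dtype=float)
    y = merged["prop_lighter_b"].to_numpy(dtype=float)
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    denom = max(1.0 - r * r, 1e-300)
    t = r * np.sqrt(df / denom)
    return StudyComparison(r=r, t=float(t), df=df)
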
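"""Triad stimulus design: construction, gamut filtering, and blocking.

A *triad* is three achromatic patches shown side by side: a standard of
lightness ``L*`` in the middle, a darker test at ``standard - d1`` and a
lighter test at ``standard + d2`` (CIELAB L*, 0-100).  The observer judges
which outer patch differs more from the middle one (method of triads).
The design enumerates offset pairs on a regular grid, keeping only triads
whose difference of differences ``delta = d1 - d2`` lies in a small set of
signed values so that neither test is trivially the answer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Triad",
    "TriadDesign",
    "Block",
    "build_design",
    "filter_by_standard",
    "make_blocks",
]

# Offsets are small multiples of 2.5 L*; an absolute tolerance well below
# half the finest step keeps float grid checks exact in practice.
_GRID_ATOL = 1e-9


@dataclass(frozen=True, order=True)
class Triad:
    """One trial's stimuli in L* units.

    Parameters
    ----------
    standard : float
        Lightness of the middle (reference) patch.
    d1 : float
        Offset of the darker test below the standard (>= 0).
    d2 : float
        Offset of the lighter test above the standard (>= 0).
    """

    standard: float
    d1: float
    d2: float

    def __post_init__(self) -> None:
        if self.d1 < 0 or self.d2 < 0:
            raise ValueError(f"offsets must be non-negative, got d1={self.d1}, d2={self.d2}")
        if self.standard - self.d1 < 0 or self.standard + self.d2 > 100:
            raise ValueError(
                f"stimuli outside the L* range [0, 100] for triad "
                f"(standard={self.standard}, d1={self.d1}, d2={self.d2})"
            )

    @property
    def dark(self) -> float:
        """L* of the darker test, ``standard - d1``."""
        return self.standard - self.d1

    @property
    def light(self) -> float:
        """L* of the lighter test, ``standard + d2``."""
        return self.standard + self.d2

    @property
    def delta(self) -> float:
        """Difference of differences ``d1 - d2``; its sign marks the correct answer."""
        return self.d1 - self.d2


@dataclass(frozen=True)
class TriadDesign:
    """An ordered, duplicate-free collection of triads plus its provenance."""

    triads: tuple[Triad, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        keys = [(t.standard, t.d1, t.d2) for t in self.triads]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (standard, d1, d2) entries in design")

    def __len__(self) -> int:
        return len(self.triads)

    def __iter__(self):
        return iter(self.triads)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with columns ``standard, d1, d2``."""
        return pd.DataFrame(
            {
                "standard": [t.standard for t in self.triads],
                "d1": [t.d1 for t in self.triads],
                "d2": [t.d2 for t in self.triads],
            }
        )

    @property
    def min_stimulus(self) -> float:
        """Smallest L* value displayed anywhere in the design."""
        if not self.triads:
            raise ValueError("empty design has no stimuli")
        return min(t.dark for t in self.triads)

    @property
    def max_stimulus(self) -> float:
        """Largest L* value displayed anywhere in the design."""
        if not self.triads:
            raise ValueError("empty design has no stimuli")
        return max(t.light for t in self.triads)


@dataclass(frozen=True)
class Block:
    """One experimental block: a subset of triads with per-triad side assignment.

    ``side_dark[i]`` is ``"L"`` or ``"R"``: the screen side on which the
    darker test of ``triads[i]`` is shown.
    """

    index: int
    triads: tuple[Triad, ...]
    side_dark: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.triads) != len(self.side_dark):
            raise ValueError("side_dark length must match the number of triads")
        if any(s not in ("L", "R") for s in self.side_dark):
            raise ValueError("side_dark entries must be 'L' or 'R'")

    def __len__(self) -> int:
        return len(self.triads)


def _check_grid(value: float, step: float, name: str) -> None:
    ratio = value / step
    if abs(ratio - round(ratio)) > _GRID_ATOL:
        raise ValueError(f"{name}={value} is not a multiple of offset_step={step}")


def build_design(
    standards: Iterable[float],
    offset_step: float = 2.5,
    offset_max: float = 30.0,
    allowed_abs_deltas: Iterable[float] = (2.5, 5.0, 10.0),
) -> TriadDesign:
    """Enumerate the full triad design over a grid of offsets.

    For every standard and every offset pair ``(d1, d2)`` with
    ``d1, d2 in {0, offset_step, ..., offset_max}``, a triad is retained
    iff ``|d1 - d2|`` is in ``allowed_abs_deltas``.  The study grid
    (standards {30,40,50,60,70}, step 2.5, max 30, |delta| in {2.5,5,10})
    yields 320 triads, 64 per standard.

    Returns the triads in canonical order, sorted by ``(standard, d1, d2)``.
    """
    standards = sorted(set(float(s) for s in standards))
    if not standards:
        raise ValueError("standards set must be non-empty")
    if offset_step <= 0:
        raise ValueError(f"offset_step must be positive, got {offset_step}")
    _check_grid(offset_max, offset_step, "offset_max")
    deltas = sorted(set(float(d) for d in allowed_abs_deltas))
    for d in deltas:
        if d <= 0:
            raise ValueError(f"allowed |delta| values must be positive, got {d}")
        _check_grid(d, offset_step, "allowed_abs_delta")

    n_steps = int(round(offset_max / offset_step))
    offsets = [i * offset_step for i in range(n_steps + 1)]
    delta_set = set(round(d / offset_step) for d in deltas)

    triads = []
    for s, d1, d2 in itertools.product(standards, offsets, offsets):
        if round(abs(d1 - d2) / offset_step) in delta_set and abs(d1 - d2) > _GRID_ATOL:
            triads.append(Triad(s, d1, d2))
    triads.sort()
    return TriadDesign(
        triads=tuple(triads),
        provenance={
            "standards": standards,
            "offset_step": offset_step,
            "offset_max": offset_max,
            "allowed_abs_deltas": deltas,
        },
    )


def filter_by_standard(design: TriadDesign, min_standard: float) -> TriadDesign:
    """Keep only triads whose standard is at least ``min_standard``.

    Used to drop triads a display cannot render faithfully: with the study
    grid, retaining standards >= 50 means the darkest displayed gray is
    L* = 20.  The empty result is legal.
    """
    kept = tuple(t for t in design.triads if t.standard >= min_standard)
    provenance = dict(design.provenance)
    provenance["min_standard"] = max(min_standard, provenance.get("min_standard", -np.inf))
    return TriadDesign(triads=kept, provenance=provenance)


def make_blocks(design: TriadDesign, n_blocks: int, seed: int) -> list[Block]:
    """Shuffle the design and split it into near-equal blocks.

    Triad order and the side on which the darker test appears are both
    randomized from a single seeded generator, so the same seed reproduces
    the same session layout.  Block sizes differ by at most one (the
    larger blocks come first).
    """
    if n_blocks < 1:
        raise ValueError(f"n_blocks must be >= 1, got {n_blocks}")
    if n_blocks > len(design):
        raise ValueError(f"cannot split {len(design)} triads into {n_blocks} blocks")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(design))
    sides = rng.choice(np.array(["L", "R"]), size=len(design))
    shuffled = [design.triads[i] for i in order]
    blocks = []
    pos = 0
    for b, chunk in enumerate(np.array_split(np.arange(len(design)), n_blocks)):
        size = len(chunk)
        blocks.append(
            Block(
                index=b,
                triads=tuple(shuffled[pos : pos + size]),
                side_dark=tuple(sides[pos : pos + size]),
            )
        )
        pos += size
    return blocks
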
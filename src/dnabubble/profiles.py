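"""TSS-anchored opening profiles and their averages over promoter collections.

Promoter coordinates are TSS-relative with no position 0: the TSS base is
+1 and the base immediately upstream is -1 (the convention of the core
promoter literature, e.g. a TATA window of -33..-23).  A profile value at
relative coordinate r is the bubble probability P_k(n) whose *start*
position n maps to r; no centering is applied.

The average profile over a collection C is the arithmetic mean
avg_k(n) = (1/|C|) * sum_{S in C} P_k(n_S) at each relative coordinate,
where n_S is that coordinate's absolute position in sequence S.  Ragged
collections are allowed: a sequence that does not cover a coordinate is
excluded from that coordinate's mean and the per-coordinate denominator is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .thermo import NucleotideSequence, OpeningProfile, ThermoParams, opening_profile

__all__ = [
    "AnchoredSequence",
    "AverageProfile",
    "coord_span",
    "tss_window_profile",
    "average_profile",
]


@dataclass(frozen=True)
class AnchoredSequence:
    """A promoter sequence plus the 1-based position of its TSS (+1 base)."""

    sequence: NucleotideSequence
    tss_index: int

    def __post_init__(self) -> None:
        if not 1 <= self.tss_index <= self.sequence.n:
            raise ValueError(
                f"tss_index {self.tss_index} outside sequence "
                f"{self.sequence.id!r} of length {self.sequence.n}"
            )

    @property
    def id(self) -> str:
        return self.sequence.id

    def to_relative(self, i: int) -> int:
        """TSS-relative coordinate of absolute position i (no coordinate 0)."""
        t = self.tss_index
        return i - t + 1 if i >= t else i - t

    def to_absolute(self, r: int) -> int:
        """Absolute 1-based position of TSS-relative coordinate r."""
        if r == 0:
            raise ValueError("TSS-relative coordinate 0 does not exist (+1 is the TSS)")
        t = self.tss_index
        return r + t - 1 if r > 0 else r + t


def coord_span(lo: int, hi: int) -> np.ndarray:
    """All TSS-relative coordinates from lo to hi inclusive, skipping 0."""
    if lo > hi:
        raise ValueError(f"empty coordinate range [{lo}, {hi}]")
    coords = np.arange(lo, hi + 1)
    return coords[coords != 0]


def tss_window_profile(
    aseq: AnchoredSequence,
    k: int,
    params: ThermoParams | None = None,
    coord_range: tuple[int, int] | None = None,
    profile: OpeningProfile | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """P_k values at TSS-relative start coordinates.

    Returns ``(coords, values)`` where ``values`` is NaN at coordinates that
    fall outside the valid start range [1, N-k+1] of the sequence (absent,
    never zero-filled).  A precomputed ``profile`` for this sequence may be
    supplied to avoid recomputation.

    Raises
    ------
    ValueError
        If no requested coordinate maps into the sequence.
    """
    if profile is None:
        profile = opening_profile(aseq.sequence, k, params)
    elif profile.k != k:
        raise ValueError(f"profile has k={profile.k}, requested k={k}")
    if coord_range is None:
        coords = np.array([aseq.to_relative(i) for i in range(1, len(profile) + 1)])
        return coords, profile.values.copy()

    coords = coord_span(*coord_range)
    values = np.full(len(coords), np.nan)
    n_max = len(profile)
    hit = False
    for j, r in enumerate(coords):
        i = aseq.to_absolute(int(r))
        if 1 <= i <= n_max:
            values[j] = profile.values[i - 1]
            hit = True
    if not hit:
        raise ValueError(
            f"coordinate range {coord_range} has no overlap with valid start "
            f"positions of sequence {aseq.id!r}"
        )
    return coords, values


@dataclass(frozen=True)
class AverageProfile:
    """Mean P_k per TSS-relative coordinate over a collection.

    ``n_sequences[j]`` is the number of sequences contributing at
    ``coords[j]``; coordinates covered by no sequence have value NaN and
    count 0.
    """

    k: int
    coords: np.ndarray
    values: np.ndarray
    n_sequences: np.ndarray

    def peak_coord(self, lo: int | None = None, hi: int | None = None) -> int:
        """Coordinate of the maximum value, optionally restricted to [lo, hi]."""
        mask = ~np.isnan(self.values)
        if lo is not None:
            mask &= self.coords >= lo
        if hi is not None:
            mask &= self.coords <= hi
        if not mask.any():
            raise ValueError("no finite values in the requested range")
        idx = np.flatnonzero(mask)
        return int(self.coords[idx[np.argmax(self.values[idx])]])


def average_profile(
    collection: Iterable[AnchoredSequence],
    k: int,
    params: ThermoParams | None = None,
    coord_range: tuple[int, int] = (-200, 100),
    profiles: Sequence[OpeningProfile] | None = None,
) -> AverageProfile:
    """Arithmetic mean of P_k(n_S) over the collection at each coordinate.

    ``profiles`` may carry precomputed per-sequence opening profiles
    (same order as the collection).
    """
    collection = list(collection)
    if not collection:
        raise ValueError("empty collection")
    coords = coord_span(*coord_range)
    total = np.zeros(len(coords))
    count = np.zeros(len(coords), dtype=int)
    for idx, aseq in enumerate(collection):
        prof = profiles[idx] if profiles is not None else None
        try:
            _, vals = tss_window_profile(aseq, k, params, coord_range, profile=prof)
        except ValueError:
            continue  # sequence covers none of the requested coordinates
        ok = ~np.isnan(vals)
        total[ok] += vals[ok]
        count[ok] += 1
    values = np.full(len(coords), np.nan)
    covered = count > 0
    values[covered] = total[covered] / count[covered]
    return AverageProfile(k, coords, values, count)
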
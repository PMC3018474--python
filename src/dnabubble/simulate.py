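"""Synthetic promoter collections with planted core-element instances.

Generates promoter-database-like inputs — fixed-length sequences with a
fixed TSS offset, an i.i.d. background of controllable GC content, and
concrete motif instances planted at chosen TSS-relative positions — plus
a ground-truth manifest of every planted site.  The default geometry
(length 1,200 bp with the TSS at position 1,001, i.e. coordinates
-1000..+200) mirrors typical promoter-database extracts.

An optional first-order Markov background (user-supplied transition
matrix) supports sensitivity checks for dinucleotide clustering, which
the i.i.d. default does not model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import IUPAC_CODES
from .profiles import AnchoredSequence
from .thermo import NucleotideSequence

__all__ = [
    "Planting",
    "FixtureSpec",
    "random_sequence",
    "markov_sequence",
    "plant_motif",
    "generate_collection",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Planting:
    """One planned motif insertion: consensus, TSS-relative start, probability."""

    consensus: str
    rel_start: int
    probability: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("planting probability must be in [0, 1]")
        if self.rel_start == 0:
            raise ValueError("TSS-relative coordinate 0 does not exist")
        bad = set(self.consensus) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"unknown IUPAC code(s) {sorted(bad)} in {self.consensus!r}")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic promoter collection."""

    n_sequences: int = 500
    length: int = 1200
    tss_index: int = 1001
    gc_fraction: float = 0.5
    plantings: tuple[Planting, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.length < 1:
            raise ValueError("n_sequences and length must be positive")
        if not 1 <= self.tss_index <= self.length:
            raise ValueError("tss_index outside sequence")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")
        # validate planting spans against the geometry, and mutual overlap
        spans = []
        dummy = AnchoredSequence(
            NucleotideSequence("_geom", "A" * self.length), self.tss_index
        )
        for p in self.plantings:
            start = dummy.to_absolute(p.rel_start)
            end = start + len(p.consensus) - 1
            if start < 1 or end > self.length:
                raise ValueError(
                    f"planting {p.consensus!r} at {p.rel_start} falls outside the sequence"
                )
            spans.append((start, end))
        spans.sort()
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("plantings overlap")


def random_sequence(
    length: int, gc_fraction: float, rng: np.random.Generator, id: str = "random"
) -> NucleotideSequence:
    """i.i.d. sequence with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be strictly between 0 and 1")
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    draws = rng.choice(_BASES, size=length, p=[at, gc, gc, at])
    return NucleotideSequence(id, "".join(draws))


def markov_sequence(
    length: int,
    transition: dict[str, dict[str, float]],
    rng: np.random.Generator,
    id: str = "markov",
    initial: dict[str, float] | None = None,
) -> NucleotideSequence:
    """First-order Markov background from a user-supplied transition table."""
    if length < 1:
        raise ValueError("length must be >= 1")
    order = list("ACGT")
    trans = np.array([[transition[a][b] for b in order] for a in order])
    if not np.allclose(trans.sum(axis=1), 1.0):
        raise ValueError("transition rows must sum to 1")
    init = (
        np.array([initial[b] for b in order])
        if initial is not None
        else np.full(4, 0.25)
    )
    out = np.empty(length, dtype="<U1")
    state = rng.choice(4, p=init / init.sum())
    out[0] = order[state]
    for i in range(1, length):
        state = rng.choice(4, p=trans[state])
        out[i] = order[state]
    return NucleotideSequence(id, "".join(out))


def plant_motif(
    seq: NucleotideSequence,
    consensus: str,
    start: int,
    rng: np.random.Generator,
) -> tuple[NucleotideSequence, str]:
    """Replace the span at 1-based ``start`` with a uniform concrete expansion.

    Each degenerate position is drawn uniformly from its IUPAC options;
    bases outside the span are untouched.  Returns the modified sequence
    and the planted instance.
    """
    length = len(consensus)
    if start < 1 or start + length - 1 > seq.n:
        raise ValueError(
            f"span [{start}, {start + length - 1}] outside sequence of length {seq.n}"
        )
    instance = "".join(rng.choice(list(IUPAC_CODES[c])) for c in consensus)
    bases = seq.bases[: start - 1] + instance + seq.bases[start - 1 + length :]
    return NucleotideSequence(seq.id, bases), instance


def generate_collection(
    spec: FixtureSpec,
) -> tuple[list[AnchoredSequence], pd.DataFrame]:
    """Reproducible collection plus a manifest of every planted site.

    The manifest has columns sequence_id, motif, rel_start, abs_start,
    instance; planted instances are exact matches of their consensus by
    construction, so downstream scanning recalls them all.
    """
    rng = np.random.default_rng(spec.seed)
    collection: list[AnchoredSequence] = []
    rows = []
    for idx in range(spec.n_sequences):
        seq = random_sequence(
            spec.length, spec.gc_fraction, rng, id=f"synthetic_{idx:05d}"
        )
        aseq = AnchoredSequence(seq, spec.tss_index)
        for p in spec.plantings:
            if rng.random() >= p.probability:
                continue
            abs_start = aseq.to_absolute(p.rel_start)
            seq, instance = plant_motif(seq, p.consensus, abs_start, rng)
            rows.append(
                {
                    "sequence_id": seq.id,
                    "motif": p.consensus,
                    "rel_start": p.rel_start,
                    "abs_start": abs_start,
                    "instance": instance,
                }
            )
        collection.append(AnchoredSequence(seq, spec.tss_index))
    manifest = pd.DataFrame(
        rows, columns=["sequence_id", "motif", "rel_start", "abs_start", "instance"]
    )
    return collection, manifest
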
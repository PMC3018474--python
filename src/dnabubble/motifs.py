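"""Core promoter element analysis: IUPAC scanning, site classification,
instability scoring, control-site generation and ECDF comparison.

A motif site is *functional* when its full span lies inside the motif's
TSS-relative functional window, *buffered* (excluded from both samples)
when it is not functional but touches the window widened by a buffer zone
(10 bp by default), and *non-functional* otherwise.  Within each class,
overlapping occurrences are thinned by greedy left-to-right selection.

Each site receives a mean opening-propensity score built from bubble
probabilities P_k: for k below the motif length L the score averages the
k-windows contained in the site; for k above L it averages the k-windows
that contain the site; at k = L it is the single window value.

Score distributions (functional vs non-functional, vs length-matched
random sites from the same promoters, vs shuffled-motif sites) are
compared with the two-sample Kolmogorov-Smirnov test; the sign of the
mean difference summarizes which ECDF lies below (higher scores).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .profiles import AnchoredSequence, AverageProfile, average_profile
from .thermo import NucleotideSequence, OpeningProfile, ThermoParams, opening_profile

__all__ = [
    "IUPAC_CODES",
    "MotifDefinition",
    "DEFAULT_MOTIFS",
    "SiteOccurrence",
    "ScoredSiteSet",
    "ComparisonResult",
    "compile_iupac",
    "expand_iupac",
    "find_sites",
    "classify_sites",
    "select_nonoverlapping",
    "score_site",
    "sample_random_sites",
    "shuffle_motif",
    "ecdf_points",
    "compare_distributions",
    "run_signature_analysis",
]

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class MotifDefinition:
    """An IUPAC consensus plus its TSS-relative functional window [lo, hi]."""

    name: str
    consensus: str
    functional_window: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("empty consensus")
        bad = set(self.consensus) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"motif {self.name!r}: unknown IUPAC code(s) {sorted(bad)}")
        lo, hi = self.functional_window
        if lo > hi:
            raise ValueError(f"motif {self.name!r}: window lo {lo} > hi {hi}")

    @property
    def length(self) -> int:
        return len(self.consensus)


#: The five human core promoter elements with their functional windows.
DEFAULT_MOTIFS: tuple[MotifDefinition, ...] = (
    MotifDefinition("TATA box", "TATAWA", (-33, -23)),
    MotifDefinition("Inr", "YYANWYY", (-5, 6)),
    MotifDefinition("DPE", "RGWYV", (23, 33)),
    MotifDefinition("BRE", "SSRCGCC", (-42, -32)),
    MotifDefinition("GC box", "GGGCGGG", (-170, -5)),
)


@dataclass(frozen=True)
class SiteOccurrence:
    """One motif occurrence on the positive strand of one sequence."""

    sequence_id: str
    start: int  # 1-based absolute
    length: int
    tss_relative_start: int
    label: str | None = None  # functional / buffered / non-functional / random / shuffled

    @property
    def end(self) -> int:
        """1-based inclusive end."""
        return self.start + self.length - 1


@dataclass
class ScoredSiteSet:
    """Sites of one label class with their instability scores at one bubble size."""

    motif_name: str
    k: int
    label: str
    sites: list[SiteOccurrence] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    n_dropped: int = 0  # sites whose scoring windows fell outside the profile

    def __len__(self) -> int:
        return len(self.scores)


def compile_iupac(consensus: str) -> re.Pattern:
    """Regular expression recognizing exactly the IUPAC expansion (positive strand)."""
    parts = []
    for c in consensus:
        if c not in IUPAC_CODES:
            raise ValueError(f"unknown IUPAC code {c!r} in consensus {consensus!r}")
        opts = IUPAC_CODES[c]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def expand_iupac(consensus: str) -> list[str]:
    """All concrete A/C/G/T strings matching the consensus (small motifs only)."""
    strings = [""]
    for c in consensus:
        if c not in IUPAC_CODES:
            raise ValueError(f"unknown IUPAC code {c!r}")
        strings = [s + b for s in strings for b in IUPAC_CODES[c]]
    return strings


def find_sites(aseq: AnchoredSequence, motif: MotifDefinition) -> list[SiteOccurrence]:
    """All (possibly overlapping) match start positions on the positive strand."""
    pat = re.compile(f"(?=({compile_iupac(motif.consensus).pattern}))")
    sites = []
    for m in pat.finditer(aseq.sequence.bases):
        start = m.start() + 1
        sites.append(
            SiteOccurrence(
                sequence_id=aseq.id,
                start=start,
                length=motif.length,
                tss_relative_start=aseq.to_relative(start),
            )
        )
    return sites


def classify_sites(
    sites: Iterable[SiteOccurrence],
    motif: MotifDefinition,
    aseq: AnchoredSequence,
    buffer: int = 10,
) -> list[SiteOccurrence]:
    """Label each site functional / buffered / non-functional.

    Functional: the full motif span lies inside the functional window.
    Buffered: not functional, but some part of the span lies within the
    window widened by ``buffer`` bp on each side (excluded from both
    samples to avoid label contamination at the window edge).
    Non-functional: everything else.

    Window and buffer arithmetic is done on absolute sequence coordinates,
    so the buffer is a plain base-pair margin even when the widened window
    crosses the TSS.
    """
    lo, hi = motif.functional_window
    w_lo, w_hi = aseq.to_absolute(lo), aseq.to_absolute(hi)
    labeled = []
    for s in sites:
        if s.start >= w_lo and s.end <= w_hi:
            lab = "functional"
        elif s.start <= w_hi + buffer and s.end >= w_lo - buffer:
            lab = "buffered"
        else:
            lab = "non-functional"
        labeled.append(replace(s, label=lab))
    return labeled


def select_nonoverlapping(sites: Sequence[SiteOccurrence]) -> list[SiteOccurrence]:
    """Greedy left-to-right thinning: keep a site iff it clears the last kept one."""
    kept: list[SiteOccurrence] = []
    for s in sorted(sites, key=lambda x: (x.sequence_id, x.start)):
        if kept and kept[-1].sequence_id == s.sequence_id and s.start <= kept[-1].end:
            continue
        kept.append(s)
    return kept


def score_site(profile: OpeningProfile, site: SiteOccurrence) -> float | None:
    """Mean opening propensity of the site under the k-vs-length rule.

    With site start s and motif length L: for k < L, mean of P_k(n) over
    n in [s, s+L-k] (windows contained in the site); for k > L, mean over
    n in [s+L-k, s] (windows containing the site); for k = L, P_k(s).
    Returns None when any needed window start falls outside [1, N-k+1]
    (the caller drops and counts such sites).
    """
    k = profile.k
    s, length = site.start, site.length
    if k <= length:
        n_lo, n_hi = s, s + length - k
    else:
        n_lo, n_hi = s + length - k, s
    if n_lo < 1 or n_hi > len(profile):
        return None
    return float(profile.values[n_lo - 1 : n_hi].mean())


def sample_random_sites(
    aseq: AnchoredSequence,
    functional_site: SiteOccurrence,
    count: int = 10,
    rng: np.random.Generator | None = None,
) -> list[SiteOccurrence]:
    """``count`` uniformly drawn equal-length sites from the same promoter.

    Draws are with replacement over all valid start positions; random sites
    may overlap motif occurrences.
    """
    rng = rng if rng is not None else np.random.default_rng()
    length = functional_site.length
    n_starts = aseq.sequence.n - length + 1
    if n_starts < 1:
        raise ValueError(
            f"sequence {aseq.id!r} too short for a site of length {length}"
        )
    starts = rng.integers(1, n_starts + 1, size=count)
    return [
        SiteOccurrence(
            sequence_id=aseq.id,
            start=int(s),
            length=length,
            tss_relative_start=aseq.to_relative(int(s)),
            label="random",
        )
        for s in starts
    ]


def shuffle_motif(
    motif: MotifDefinition, rng: np.random.Generator | None = None, max_tries: int = 1000
) -> str:
    """A random permutation of the consensus characters differing from the original.

    Shuffled motifs are biologically meaningless controls that preserve the
    character multiset (hence degeneracy and composition).  Raises for
    motifs with a single distinct arrangement (e.g. a homopolymer).
    """
    if motif.length < 2:
        raise ValueError("motif too short to shuffle")
    chars = list(motif.consensus)
    if len(set(chars)) == 1:
        raise ValueError(
            f"motif {motif.name!r} ({motif.consensus}) has only one distinct arrangement"
        )
    rng = rng if rng is not None else np.random.default_rng()
    for _ in range(max_tries):
        perm = "".join(rng.permutation(chars))
        if perm != motif.consensus:
            return perm
    raise RuntimeError("failed to draw a distinct shuffle")  # pragma: no cover


def ecdf_points(sample: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Sorted sample values and the ECDF evaluated at them."""
    x = np.sort(np.asarray(sample, dtype=float))
    return x, np.arange(1, len(x) + 1) / len(x)


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample KS comparison of score distributions."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    statistic: float  # KS D = sup |ECDF_a - ECDF_b|
    pvalue: float  # asymptotic, unadjusted
    mean_a: float
    mean_b: float
    ecdf_a: tuple[np.ndarray, np.ndarray]
    ecdf_b: tuple[np.ndarray, np.ndarray]

    @property
    def a_ecdf_below(self) -> bool:
        """True when sample a's ECDF lies below (a scores higher on average)."""
        return self.mean_a > self.mean_b

    def to_dict(self) -> dict:
        return {
            "samples": [self.label_a, self.label_b],
            "n": [self.n_a, self.n_b],
            "ks_statistic": self.statistic,
            "pvalue": self.pvalue,
            "mean_scores": [self.mean_a, self.mean_b],
            "first_ecdf_below": bool(self.a_ecdf_below),
        }


def compare_distributions(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
) -> ComparisonResult:
    """Two-sample Kolmogorov-Smirnov test with ECDF point sets for reporting."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return ComparisonResult(
        label_a=label_a,
        label_b=label_b,
        n_a=len(a),
        n_b=len(b),
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        ecdf_a=ecdf_points(a),
        ecdf_b=ecdf_points(b),
    )


def _score_all(
    sites: Iterable[SiteOccurrence],
    profiles: dict[str, OpeningProfile],
    motif_name: str,
    k: int,
    label: str,
) -> ScoredSiteSet:
    out = ScoredSiteSet(motif_name, k, label)
    for s in sites:
        score = score_site(profiles[s.sequence_id], s)
        if score is None:
            out.n_dropped += 1
            continue
        out.sites.append(s)
        out.scores.append(score)
    return out


def run_signature_analysis(
    collection: Sequence[AnchoredSequence],
    motifs: Sequence[MotifDefinition] = DEFAULT_MOTIFS,
    k: int = 4,
    params: ThermoParams | None = None,
    rng: np.random.Generator | int | None = None,
    buffer: int = 10,
    n_random_per_site: int = 10,
    coord_range: tuple[int, int] = (-200, 100),
    profiles: dict[str, OpeningProfile] | None = None,
) -> dict:
    """Full promoter-element signature analysis on a collection.

    Per motif: (1) average profiles of sequences containing vs lacking a
    functional occurrence; (2) functional vs non-functional score
    comparison; (3) functional vs length-matched random sites (10 per
    functional site by default, drawn from the same promoter); (4)
    functional vs shuffled-motif sites and shuffled vs random.
    Deterministic given ``rng`` (a seed or Generator).

    Returns a nested dict report; comparisons whose samples are empty are
    skipped and flagged under ``"skipped"``.
    """
    params = params or ThermoParams()
    rng = np.random.default_rng(rng)
    collection = list(collection)
    if profiles is None:
        profiles = {
            a.id: opening_profile(a.sequence, k, params) for a in collection
        }

    report: dict = {
        "k": k,
        "n_sequences": len(collection),
        "params_fingerprint": params.fingerprint(),
        "buffer": buffer,
        "motifs": {},
    }
    by_id = {a.id: a for a in collection}

    for motif in motifs:
        sets: dict[str, ScoredSiteSet] = {
            lab: ScoredSiteSet(motif.name, k, lab)
            for lab in ("functional", "non-functional", "buffered")
        }
        functional_by_seq: dict[str, list[SiteOccurrence]] = {}
        containing_ids: set[str] = set()

        for aseq in collection:
            raw = find_sites(aseq, motif)
            labeled = classify_sites(raw, motif, aseq, buffer=buffer)
            for lab, sset in sets.items():
                chosen = select_nonoverlapping([s for s in labeled if s.label == lab])
                scored = _score_all(chosen, profiles, motif.name, k, lab)
                sset.sites.extend(scored.sites)
                sset.scores.extend(scored.scores)
                sset.n_dropped += scored.n_dropped
                if lab == "functional" and scored.sites:
                    functional_by_seq[aseq.id] = scored.sites
                    containing_ids.add(aseq.id)

        # (1) containing vs lacking average profiles
        containing = [a for a in collection if a.id in containing_ids]
        lacking = [a for a in collection if a.id not in containing_ids]
        avg_containing = (
            average_profile(
                containing, k, params, coord_range,
                profiles=[profiles[a.id] for a in containing],
            )
            if containing
            else None
        )
        avg_lacking = (
            average_profile(
                lacking, k, params, coord_range,
                profiles=[profiles[a.id] for a in lacking],
            )
            if lacking
            else None
        )

        # (3) random controls: 10 per functional site, same promoter
        random_set = ScoredSiteSet(motif.name, k, "random")
        for seq_id, fsites in sorted(functional_by_seq.items()):
            aseq = by_id[seq_id]
            for fs in fsites:
                rnd = sample_random_sites(aseq, fs, count=n_random_per_site, rng=rng)
                scored = _score_all(rnd, profiles, motif.name, k, "random")
                random_set.sites.extend(scored.sites)
                random_set.scores.extend(scored.scores)
                random_set.n_dropped += scored.n_dropped

        # (4) shuffled motif sites: all non-overlapping occurrences anywhere
        shuffled_set = ScoredSiteSet(motif.name, k, "shuffled")
        shuffled_consensus = None
        if len(set(motif.consensus)) > 1:
            shuffled_consensus = shuffle_motif(motif, rng=rng)
            shuffled_motif_def = MotifDefinition(
                f"{motif.name} (shuffled)", shuffled_consensus, motif.functional_window
            )
            for aseq in collection:
                occ = select_nonoverlapping(find_sites(aseq, shuffled_motif_def))
                occ = [replace(s, label="shuffled") for s in occ]
                scored = _score_all(occ, profiles, motif.name, k, "shuffled")
                shuffled_set.sites.extend(scored.sites)
                shuffled_set.scores.extend(scored.scores)
                shuffled_set.n_dropped += scored.n_dropped

        comparisons: dict[str, dict] = {}
        skipped: list[str] = []
        pairs = [
            ("functional_vs_nonfunctional", sets["functional"], sets["non-functional"]),
            ("functional_vs_random", sets["functional"], random_set),
            ("functional_vs_shuffled", sets["functional"], shuffled_set),
            ("shuffled_vs_random", shuffled_set, random_set),
        ]
        for name, sa, sb in pairs:
            if len(sa) == 0 or len(sb) == 0:
                skipped.append(name)
                continue
            comparisons[name] = compare_distributions(
                sa.scores, sb.scores, sa.label, sb.label
            ).to_dict()

        report["motifs"][motif.name] = {
            "consensus": motif.consensus,
            "functional_window": list(motif.functional_window),
            "shuffled_consensus": shuffled_consensus,
            "site_counts": {
                "functional": len(sets["functional"]),
                "non-functional": len(sets["non-functional"]),
                "buffered": len(sets["buffered"]),
                "random": len(random_set),
                "shuffled": len(shuffled_set),
                "dropped": sum(s.n_dropped for s in sets.values())
                + random_set.n_dropped
                + shuffled_set.n_dropped,
            },
            "n_containing": len(containing),
            "n_lacking": len(lacking),
            "avg_profile_containing": avg_containing,
            "avg_profile_lacking": avg_lacking,
            "comparisons": comparisons,
            "skipped": skipped,
            "score_sets": {
                "functional": sets["functional"],
                "non-functional": sets["non-functional"],
                "buffered": sets["buffered"],
                "random": random_set,
                "shuffled": shuffled_set,
            },
        }
    return report
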
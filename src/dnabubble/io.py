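"""File formats: FASTA input, TSS anchor tables, per-base profile tracks,
site tables and JSON reports.

Internal coordinates are 1-based closed throughout the package; BED-like
and bedGraph outputs convert to 0-based half-open intervals at write time
(the conversion is owned by the writers only).  Every track and table
carries header comments with the parameter fingerprint, bubble size and
tool version so reruns are auditable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .motifs import SiteOccurrence
from .profiles import AnchoredSequence, AverageProfile
from .thermo import NucleotideSequence, OpeningProfile

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tss_table",
    "write_tss_table",
    "anchor_collection",
    "write_profile_track",
    "read_profile_tsv",
    "write_average_profile",
    "write_sites_table",
    "write_report_json",
]

_AMBIGUOUS_POLICY = ("reject", "skip")


def read_fasta(path: str | Path, ambiguous: str = "reject") -> list[NucleotideSequence]:
    """Read a multi-record FASTA into validated sequences.

    Ids are the first whitespace-delimited header token; bases are
    case-folded to upper.  ``ambiguous="reject"`` (default) errors on any
    non-A/C/G/T character; ``"skip"`` drops offending records.
    """
    if ambiguous not in _AMBIGUOUS_POLICY:
        raise ValueError(f"ambiguous policy must be one of {_AMBIGUOUS_POLICY}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out: list[NucleotideSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            out.append(NucleotideSequence(rec.id, str(rec.seq).upper()))
        except ValueError:
            if ambiguous == "reject":
                raise
    if not out:
        raise ValueError(f"no usable records in {path} after filtering")
    return out


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_tss_table(path: str | Path) -> dict[str, int]:
    """Two-column tab-separated (id, 1-based TSS position) -> mapping."""
    table: dict[str, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected two tab-separated columns")
            table[parts[0]] = int(parts[1])
    if not table:
        raise ValueError(f"empty TSS table {path}")
    return table


def write_tss_table(anchors: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#id\ttss_index\n")
        for sid, tss in anchors.items():
            fh.write(f"{sid}\t{tss}\n")


def anchor_collection(
    seqs: Sequence[NucleotideSequence],
    tss_table: dict[str, int] | None = None,
    tss_offset: int | None = None,
) -> list[AnchoredSequence]:
    """Attach TSS anchors from a per-id table and/or a global offset.

    Per-id entries override the global offset; every sequence must resolve
    to an anchor or a named error is raised.
    """
    out = []
    missing = []
    for seq in seqs:
        if tss_table is not None and seq.id in tss_table:
            out.append(AnchoredSequence(seq, tss_table[seq.id]))
        elif tss_offset is not None:
            out.append(AnchoredSequence(seq, tss_offset))
        else:
            missing.append(seq.id)
    if missing:
        raise ValueError(f"no TSS anchor for sequence id(s): {', '.join(missing[:5])}")
    return out


def _header_lines(profile: OpeningProfile, comment: str = "#") -> list[str]:
    return [
        f"{comment} dnabubble {__version__}",
        f"{comment} sequence={profile.sequence_id} k={profile.k} "
        f"params={profile.params_fingerprint}",
    ]


def write_profile_track(
    profile: OpeningProfile, path: str | Path, format: str = "tsv"
) -> None:
    """Write P_k(n) as tsv (1-based), bedGraph (0-based half-open) or wig.

    Values are rendered with 17 significant digits so a round-trip through
    text is bit-exact.
    """
    path = Path(path)
    with open(path, "w") as fh:
        if format == "tsv":
            for line in _header_lines(profile):
                fh.write(line + "\n")
            fh.write("#n\tP_k\n")
            for n, v in enumerate(profile.values, start=1):
                fh.write(f"{n}\t{v:.17g}\n")
        elif format == "bedgraph":
            for line in _header_lines(profile):
                fh.write(line + "\n")
            fh.write(
                f'track type=bedGraph name="{profile.sequence_id}_k{profile.k}"\n'
            )
            for n, v in enumerate(profile.values, start=1):
                fh.write(f"{profile.sequence_id}\t{n - 1}\t{n}\t{v:.17g}\n")
        elif format == "wig":
            for line in _header_lines(profile):
                fh.write(line + "\n")
            fh.write(f"fixedStep chrom={profile.sequence_id} start=1 step=1\n")
            for v in profile.values:
                fh.write(f"{v:.17g}\n")
        else:
            raise ValueError(f"unknown track format {format!r} (tsv, bedgraph, wig)")


def read_profile_tsv(path: str | Path) -> np.ndarray:
    """Re-parse a tsv track's values (bit-exact round trip)."""
    values = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "fixedStep")):
                continue
            values.append(float(line.split("\t")[1]))
    return np.array(values)


def write_average_profile(avg: AverageProfile, path: str | Path, meta: dict | None = None) -> None:
    """Tab-separated (coordinate, mean, n_sequences) with header comments."""
    with open(path, "w") as fh:
        fh.write(f"# dnabubble {__version__}\n")
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("#coord\tmean_P_k\tn_sequences\n")
        for c, v, n in zip(avg.coords, avg.values, avg.n_sequences):
            rendered = "NA" if np.isnan(v) else f"{v:.17g}"
            fh.write(f"{c}\t{rendered}\t{n}\n")


def write_sites_table(
    sites: Iterable[SiteOccurrence],
    scores: Iterable[float],
    motif_name: str,
    path: str | Path | TextIO,
    meta: dict | None = None,
) -> None:
    """BED-like 6+1 column site table (0-based half-open, plus label)."""
    own = isinstance(path, (str, Path))
    fh = open(path, "w") if own else path
    try:
        fh.write(f"# dnabubble {__version__}\n")
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("#sequence_id\tstart\tend\tmotif\tscore\tstrand\tlabel\n")
        for site, score in zip(sites, scores):
            fh.write(
                f"{site.sequence_id}\t{site.start - 1}\t{site.end}\t"
                f"{motif_name}\t{score:.17g}\t+\t{site.label}\n"
            )
    finally:
        if own:
            fh.close()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer, np.floating)):
        return _jsonable(obj.item())
    if isinstance(obj, float) and np.isnan(obj):
        return None  # absent coordinate
    return obj


def write_report_json(report: dict, path: str | Path) -> None:
    """Machine-readable analysis report (profiles/ECDFs flattened to lists)."""
    slim: dict = {k: v for k, v in report.items() if k != "motifs"}
    slim["version"] = __version__
    slim["motifs"] = {}
    for name, entry in report.get("motifs", {}).items():
        out = {
            k: v
            for k, v in entry.items()
            if k not in ("avg_profile_containing", "avg_profile_lacking", "score_sets")
        }
        for key in ("avg_profile_containing", "avg_profile_lacking"):
            avg = entry.get(key)
            out[key] = (
                None
                if avg is None
                else {
                    "coords": avg.coords,
                    "values": avg.values,
                    "n_sequences": avg.n_sequences,
                }
            )
        slim["motifs"][name] = out
    with open(path, "w") as fh:
        json.dump(_jsonable(slim), fh, indent=2, allow_nan=False, default=str)
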
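"""Motif instance discovery, scoring and filtering.

A motif instance is an anchored full match of a SLiM class pattern at a
given start position. For variable-length patterns all feasible span lengths
(clipped at the protein end) are tried and the longest matching span is
reported, one instance per (class, start); instances at different starts may
overlap freely. Candidate instances are kept when both their mean disorder
and mean relative local conservation exceed strict cutoffs (default 0.5 for
both), which is how low-confidence regex hits in ordered or weakly conserved
regions are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import MotifClass, ProteinRecord, ScoreTrack

__all__ = [
    "MotifInstance",
    "scan_protein",
    "scan_proteome",
    "annotate_instance_scores",
    "classify_region",
    "filter_predicted_instances",
    "instances_from_validated_table",
    "write_instance_table",
    "read_instance_table",
]

DISORDER_CUTOFF = 0.5
RLC_CUTOFF = 0.5


@dataclass(frozen=True)
class MotifInstance:
    """An occurrence of a SLiM class on a protein (1-based inclusive span)."""

    accession: str
    elm_id: str
    start: int
    end: int
    matched_seq: str
    mean_disorder: float | None = None
    mean_rlc: float | None = None
    provenance: str = "predicted"

    @property
    def span(self) -> range:
        """Residue positions covered, as 1-based indices."""
        return range(self.start, self.end + 1)

    def __len__(self) -> int:
        return self.end - self.start + 1


def _feasible_lengths(cls: MotifClass, start0: int, seq_len: int) -> range:
    """Candidate span lengths at 0-based start, longest first."""
    hi = min(cls.max_len, seq_len - start0)
    return range(hi, cls.min_len - 1, -1)


def scan_protein(record: ProteinRecord, cls: MotifClass) -> list[MotifInstance]:
    """Locate all instances of ``cls`` on ``record``.

    At every start position, anchored full matches of every feasible length
    are tested and at most one instance (the longest matching span) is
    emitted; overlapping instances at different starts are all reported.
    Patterns containing ``^``/``$`` anchors are matched against the full
    sequence so the anchors refer to the protein termini.
    """
    seq = record.sequence
    pat = cls.compiled
    # ELM patterns carry anchors only at the pattern ends; they refer to the
    # protein termini, so enforce them on the candidate span's position and
    # match the pattern against the bare substring (where ^/$ always hold).
    n_term = cls.pattern.startswith("^")
    c_term = cls.pattern.endswith("$") and not cls.pattern.endswith(r"\$")
    out: list[MotifInstance] = []
    starts = [0] if n_term else range(len(seq))
    for start0 in starts:
        for length in _feasible_lengths(cls, start0, len(seq)):
            if c_term and start0 + length != len(seq):
                continue
            if pat.fullmatch(seq, start0, start0 + length) is None:
                continue
            out.append(
                MotifInstance(
                    accession=record.accession,
                    elm_id=cls.elm_id,
                    start=start0 + 1,
                    end=start0 + length,
                    matched_seq=seq[start0 : start0 + length],
                )
            )
            break  # longest span at this start found
    return out


def scan_proteome(
    proteome: Mapping[str, ProteinRecord], classes: Iterable[MotifClass]
) -> list[MotifInstance]:
    """Scan every protein with every class; proteome order preserved."""
    out: list[MotifInstance] = []
    for record in proteome.values():
        for cls in classes:
            out.extend(scan_protein(record, cls))
    return out


def annotate_instance_scores(
    inst: MotifInstance, track: ScoreTrack
) -> MotifInstance:
    """Attach the arithmetic means of the per-residue scores over the span."""
    if track is None:
        raise ValueError(f"no score track for {inst.accession}")
    if inst.end > len(track):
        raise ValueError(
            f"{inst.accession}: instance span {inst.start}-{inst.end} "
            f"exceeds track length {len(track)}"
        )
    sl = slice(inst.start - 1, inst.end)
    return replace(
        inst,
        mean_disorder=float(np.mean(track.disorder[sl])),
        mean_rlc=float(np.mean(track.rlc[sl])),
    )


def annotate_all(
    instances: Iterable[MotifInstance], tracks: Mapping[str, ScoreTrack]
) -> list[MotifInstance]:
    return [
        annotate_instance_scores(inst, tracks.get(inst.accession))
        for inst in instances
    ]


def classify_region(position: int, track: ScoreTrack) -> str:
    """'disordered' iff the residue's disorder score is strictly above 0.5."""
    if not 1 <= position <= len(track):
        raise IndexError(
            f"{track.accession}: position {position} outside 1..{len(track)}"
        )
    return "disordered" if track.disorder[position - 1] > DISORDER_CUTOFF else "ordered"


def instance_region(inst: MotifInstance) -> str:
    """Region bin of an instance from its mean disorder (strict > 0.5)."""
    if inst.mean_disorder is None:
        raise ValueError(f"{inst.accession}:{inst.elm_id} not score-annotated")
    return "disordered" if inst.mean_disorder > DISORDER_CUTOFF else "ordered"


def filter_predicted_instances(
    instances: Sequence[MotifInstance],
    disorder_cutoff: float = DISORDER_CUTOFF,
    rlc_cutoff: float = RLC_CUTOFF,
) -> list[MotifInstance]:
    """Keep instances with mean disorder AND mean RLC strictly above cutoff."""
    kept = []
    for inst in instances:
        if inst.mean_disorder is None or inst.mean_rlc is None:
            raise ValueError(
                f"{inst.accession}:{inst.elm_id}@{inst.start} not annotated"
            )
        if inst.mean_disorder > disorder_cutoff and inst.mean_rlc > rlc_cutoff:
            kept.append(inst)
    return kept


def instances_from_validated_table(
    rows: Iterable[tuple[str, str, int, int]],
    proteome: Mapping[str, ProteinRecord],
) -> list[MotifInstance]:
    """Turn (accession, class, start, end) rows into validated instances."""
    out = []
    for acc, elm_id, start, end in rows:
        if acc not in proteome:
            raise ValueError(f"validated instance on unknown protein {acc!r}")
        seq = proteome[acc].sequence
        if end > len(seq):
            raise ValueError(f"{acc}: instance {start}-{end} beyond protein end")
        out.append(
            MotifInstance(
                accession=acc,
                elm_id=elm_id,
                start=start,
                end=end,
                matched_seq=seq[start - 1 : end],
                provenance="validated",
            )
        )
    return out


# ---------------------------------------------------------------------------
# instance table I/O (BED-like but 1-based inclusive; see header line)

_HEADER = (
    "#accession\tstart\tend\telm_id\tmean_disorder\tmean_rlc\tmatched_seq"
    "\tprovenance\t(coordinates are 1-based inclusive)\n"
)


def write_instance_table(
    instances: Iterable[MotifInstance], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER)
        for i in instances:
            md = "" if i.mean_disorder is None else f"{i.mean_disorder:.6g}"
            mr = "" if i.mean_rlc is None else f"{i.mean_rlc:.6g}"
            fh.write(
                f"{i.accession}\t{i.start}\t{i.end}\t{i.elm_id}\t{md}\t{mr}"
                f"\t{i.matched_seq}\t{i.provenance}\n"
            )


def read_instance_table(path: str | Path) -> list[MotifInstance]:
    out: list[MotifInstance] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append(
                MotifInstance(
                    accession=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    elm_id=f[3],
                    mean_disorder=float(f[4]) if f[4] else None,
                    mean_rlc=float(f[5]) if f[5] else None,
                    matched_seq=f[6],
                    provenance=f[7] if len(f) > 7 else "predicted",
                )
            )
    return out
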
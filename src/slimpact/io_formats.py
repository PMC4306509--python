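"""Readers and writers for the pipeline's external file formats.

All tables are tab-delimited UTF-8 text with ``#``-prefixed comment lines.
Residue coordinates are 1-based and inclusive on both ends throughout the
package (the convention of protein residue numbering, NOT 0-based half-open
BED). Motif patterns are normalized once at load time; the original string is
retained for provenance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "FormatError",
    "ProteinRecord",
    "MotifClass",
    "MutationRecord",
    "ScoreTrack",
    "FUNCTIONAL_TYPES",
    "normalize_pattern",
    "pattern_width",
    "read_fasta",
    "write_fasta",
    "read_motif_classes",
    "write_motif_classes",
    "read_validated_instances",
    "read_mutation_table",
    "write_mutation_table",
    "read_score_tracks",
    "write_score_tracks",
]

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_SEQ_ALPHABET = set(AMINO_ACIDS) | {"X"}

#: The six ELM functional types: proteolytic cleavage sites, degrons, docking
#: sites, ligand-binding sites, modification sites and targeting signals.
FUNCTIONAL_TYPES = frozenset({"CLV", "DEG", "DOC", "LIG", "MOD", "TRG"})


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence keyed by its UniProt-style accession."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _SEQ_ALPHABET
        if bad:
            raise FormatError(
                f"{self.accession}: invalid residue letter(s) {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifClass:
    """A SLiM class defined by a regular-expression pattern.

    ``pattern`` is the normalized regex ('x' wildcards as '.', phospho
    markers stripped); ``raw_pattern`` keeps the string as loaded.
    ``min_len``/``max_len`` bound the residue span a full match can cover.
    """

    elm_id: str
    functional_type: str
    pattern: str
    occurrence_probability: float | None = None
    raw_pattern: str = ""
    min_len: int = field(init=False)
    max_len: int = field(init=False)

    def __post_init__(self) -> None:
        if self.functional_type not in FUNCTIONAL_TYPES:
            raise FormatError(
                f"{self.elm_id}: unknown functional type {self.functional_type!r}"
            )
        if self.occurrence_probability is not None and not (
            0.0 < self.occurrence_probability <= 1.0
        ):
            raise FormatError(
                f"{self.elm_id}: occurrence probability "
                f"{self.occurrence_probability} outside (0, 1]"
            )
        try:
            compiled = re.compile(self.pattern)
        except re.error as exc:
            raise FormatError(f"{self.elm_id}: pattern does not compile: {exc}")
        lo, hi = pattern_width(self.pattern)
        if lo < 1:
            lo = 1
        object.__setattr__(self, "min_len", lo)
        object.__setattr__(self, "max_len", max(lo, hi))
        object.__setattr__(self, "_compiled", compiled)
        if not self.raw_pattern:
            object.__setattr__(self, "raw_pattern", self.pattern)

    @property
    def compiled(self) -> re.Pattern:
        return self._compiled  # type: ignore[attr-defined]


@dataclass(frozen=True)
class MutationRecord:
    """A missense substitution at a 1-based residue position."""

    accession: str
    position: int
    wt_aa: str
    mut_aa: str
    dataset: str
    sample_id: str | None = None
    primary_site: str | None = None
    histology: str | None = None

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise FormatError(
                f"{self.accession}:{self.position} silent substitution "
                f"{self.wt_aa}->{self.mut_aa}"
            )
        if self.position < 1:
            raise FormatError(f"{self.accession}: position {self.position} < 1")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of a unique mutation: (accession, position, wt, mut)."""
        return (self.accession, self.position, self.wt_aa, self.mut_aa)

    @property
    def site(self) -> tuple[str, int]:
        return (self.accession, self.position)


@dataclass
class ScoreTrack:
    """Per-residue disorder (in [0, 1]) and relative local conservation."""

    accession: str
    disorder: np.ndarray
    rlc: np.ndarray

    def __post_init__(self) -> None:
        self.disorder = np.asarray(self.disorder, dtype=float)
        self.rlc = np.asarray(self.rlc, dtype=float)
        if self.disorder.shape != self.rlc.shape:
            raise FormatError(f"{self.accession}: disorder/RLC length mismatch")
        if self.disorder.size and (
            self.disorder.min() < 0.0 or self.disorder.max() > 1.0
        ):
            raise FormatError(f"{self.accession}: disorder score outside [0, 1]")

    def __len__(self) -> int:
        return int(self.disorder.size)


# ---------------------------------------------------------------------------
# pattern handling

_PHOSPHO = re.compile(r"p(?=[STY\[])")


def normalize_pattern(raw: str) -> str:
    """Normalize an ELM-style motif pattern to a plain regular expression.

    Lowercase ``x`` wildcard tokens become ``.``; lowercase ``p`` phospho
    markers in front of S/T/Y (or a character class) are stripped; negated
    character classes additionally exclude the unknown residue ``X`` so that
    an unknown residue never satisfies a sequence constraint.
    """
    out: list[str] = []
    in_class = False
    i = 0
    while i < len(raw):
        ch = raw[i]
        if in_class:
            out.append(ch)
            if ch == "]":
                in_class = False
            i += 1
            continue
        if ch == "[":
            if raw[i : i + 2] == "[^":
                out.append("[^X")
                i += 2
            else:
                out.append("[")
                i += 1
            in_class = True
            continue
        if ch == "x":
            out.append(".")
            i += 1
            continue
        if ch == "p" and _PHOSPHO.match(raw, i):
            i += 1  # drop the marker, keep the residue token
            continue
        out.append(ch)
        i += 1
    return "".join(out)


def pattern_width(pattern: str) -> tuple[int, int]:
    """Minimum and maximum number of residues a full match can span."""
    try:
        parser = re._parser  # type: ignore[attr-defined]
    except AttributeError:  # pragma: no cover - older interpreters
        import sre_parse as parser  # type: ignore[no-redef]
    lo, hi = parser.parse(pattern).getwidth()
    return int(lo), int(min(hi, 10_000))


# ---------------------------------------------------------------------------
# FASTA

def _accession_from_header(header: str) -> str:
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 2 and parts[1]:
        return parts[1]
    return token


def read_fasta(path: str | Path) -> dict[str, ProteinRecord]:
    """Load a proteome FASTA keyed by accession.

    Accessions come from the second pipe-delimited field of ``db|ACC|NAME``
    headers, else the first whitespace token. Sequences are uppercased.
    """
    proteome: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = _accession_from_header(rec.description or rec.id)
        if acc in proteome:
            raise FormatError(f"duplicate accession {acc!r} in {path}")
        proteome[acc] = ProteinRecord(acc, str(rec.seq).upper())
    return proteome


def write_fasta(proteome: Mapping[str, ProteinRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.accession, description="")
        for p in proteome.values()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# generic TSV plumbing

def _iter_rows(path: str | Path, n_required: int) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < n_required:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {n_required} columns, "
                    f"got {len(fields)}"
                )
            yield lineno, fields


def _parse_int(text: str, where: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise FormatError(f"{where}: not an integer: {text!r}")


def _parse_float(text: str, where: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"{where}: not a number: {text!r}")


# ---------------------------------------------------------------------------
# motif classes

_MISSING = {"", "-", "–", "NA", "None"}


def read_motif_classes(path: str | Path) -> list[MotifClass]:
    """Load a SLiM class table: elm_id, type, pattern, probability."""
    classes: list[MotifClass] = []
    seen: set[str] = set()
    for lineno, f in _iter_rows(path, 3):
        elm_id, ftype, raw = f[0], f[1], f[2]
        if elm_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate class id {elm_id!r}")
        seen.add(elm_id)
        prob: float | None = None
        if len(f) > 3 and f[3].strip() not in _MISSING:
            prob = _parse_float(f[3], f"{path}:{lineno}")
        classes.append(
            MotifClass(
                elm_id=elm_id,
                functional_type=ftype,
                pattern=normalize_pattern(raw),
                occurrence_probability=prob,
                raw_pattern=raw,
            )
        )
    return classes


def write_motif_classes(classes: Iterable[MotifClass], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#elm_id\ttype\tpattern\tprobability\n")
        for c in classes:
            prob = "-" if c.occurrence_probability is None else repr(
                c.occurrence_probability
            )
            fh.write(f"{c.elm_id}\t{c.functional_type}\t{c.raw_pattern}\t{prob}\n")


# ---------------------------------------------------------------------------
# validated instances (accession, class, start, end)

def read_validated_instances(path: str | Path) -> list[tuple[str, str, int, int]]:
    """Load an experimentally validated instance table.

    Returns raw (accession, elm_id, start, end) tuples; conversion into
    scored :class:`~slimpact.motif_engine.MotifInstance` objects happens in
    the motif engine, where the proteome and tracks are available.
    """
    rows: list[tuple[str, str, int, int]] = []
    for lineno, f in _iter_rows(path, 4):
        start = _parse_int(f[2], f"{path}:{lineno}")
        end = _parse_int(f[3], f"{path}:{lineno}")
        if not (1 <= start <= end):
            raise FormatError(f"{path}:{lineno}: bad span {start}-{end}")
        rows.append((f[0], f[1], start, end))
    return rows


# ---------------------------------------------------------------------------
# mutations

def read_mutation_table(path: str | Path, dataset: str) -> list[MutationRecord]:
    """Load a mutation table (accession, position, wt, mut [+ metadata]).

    Silent rows (wt == mut) are dropped; use
    :func:`read_mutation_table_with_rejects` to inspect them.
    """
    records, _ = read_mutation_table_with_rejects(path, dataset)
    return records


def read_mutation_table_with_rejects(
    path: str | Path, dataset: str
) -> tuple[list[MutationRecord], list[tuple[int, str]]]:
    records: list[MutationRecord] = []
    rejected: list[tuple[int, str]] = []
    for lineno, f in _iter_rows(path, 4):
        acc = f[0]
        pos = _parse_int(f[1], f"{path}:{lineno}")
        wt, mut = f[2].upper(), f[3].upper()
        if len(wt) != 1 or len(mut) != 1:
            raise FormatError(f"{path}:{lineno}: wt/mut must be single letters")
        if wt == mut:
            rejected.append((lineno, f"silent substitution {wt}{pos}{mut}"))
            continue
        records.append(
            MutationRecord(
                accession=acc,
                position=pos,
                wt_aa=wt,
                mut_aa=mut,
                dataset=dataset,
                sample_id=f[4] if len(f) > 4 and f[4] else None,
                primary_site=f[5] if len(f) > 5 and f[5] else None,
                histology=f[6] if len(f) > 6 and f[6] else None,
            )
        )
    return records, rejected


def write_mutation_table(
    mutations: Iterable[MutationRecord], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#accession\tposition\twt\tmut\tsample_id\n")
        for m in mutations:
            fh.write(
                f"{m.accession}\t{m.position}\t{m.wt_aa}\t{m.mut_aa}"
                f"\t{m.sample_id or ''}\n"
            )


# ---------------------------------------------------------------------------
# score tracks

def read_score_tracks(
    path: str | Path, proteome: Mapping[str, ProteinRecord]
) -> dict[str, ScoreTrack]:
    """Load dense per-residue disorder/RLC tracks, validated per protein.

    One row per residue: accession, position, disorder, rlc. Every covered
    protein must be fully covered (track length equals protein length).
    """
    per_acc: dict[str, dict[int, tuple[float, float]]] = {}
    for lineno, f in _iter_rows(path, 4):
        acc = f[0]
        pos = _parse_int(f[1], f"{path}:{lineno}")
        dis = _parse_float(f[2], f"{path}:{lineno}")
        rlc = _parse_float(f[3], f"{path}:{lineno}")
        if not 0.0 <= dis <= 1.0:
            raise FormatError(f"{path}:{lineno}: disorder {dis} outside [0, 1]")
        per_acc.setdefault(acc, {})[pos] = (dis, rlc)
    tracks: dict[str, ScoreTrack] = {}
    for acc, rows in per_acc.items():
        if acc not in proteome:
            raise FormatError(f"{path}: track for unknown accession {acc!r}")
        n = proteome[acc].length
        if sorted(rows) != list(range(1, n + 1)):
            raise FormatError(
                f"{path}: {acc} track covers {len(rows)} residues, "
                f"protein has {n}"
            )
        dis = np.array([rows[i][0] for i in range(1, n + 1)])
        rlc = np.array([rows[i][1] for i in range(1, n + 1)])
        tracks[acc] = ScoreTrack(acc, dis, rlc)
    return tracks


def write_score_tracks(
    tracks: Mapping[str, ScoreTrack], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#accession\tposition\tdisorder\trlc\n")
        for acc in tracks:
            t = tracks[acc]
            for i in range(len(t)):
                fh.write(
                    f"{acc}\t{i + 1}\t{float(t.disorder[i])!r}"
                    f"\t{float(t.rlc[i])!r}\n"
                )
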
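"""Motif-breaking versus motif-conserving classification of mutations.

A mutation overlapping a motif instance is *breaking* when, after the
substitution, the class pattern no longer fully matches any span anchored at
the instance's start (all feasible lengths between the class's minimum and
maximum width are tried, clipped at the protein end); otherwise it is
*conserving*. A substitution at a wild-card position is therefore always
conserving, and a substitution at a fully constrained position to a residue
outside the allowed set is always breaking. Because SLiM instances can
overlap, one mutation can break one instance while conserving another; such
mutations aggregate to BOTH. Phospho-primed positions are matched as their
unmodified residue — modification state is not modeled.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .io_formats import MotifClass, MutationRecord
from .motif_engine import MotifInstance

__all__ = [
    "Verdict",
    "Aggregate",
    "ImpactCall",
    "apply_missense",
    "classify_against_instance",
    "classify_mutation",
    "classify_dataset",
    "classification_summary",
]


class Verdict(str, Enum):
    BREAKING = "breaking"
    CONSERVING = "conserving"


class Aggregate(str, Enum):
    ONLY_BREAKING = "only_breaking"
    ONLY_CONSERVING = "only_conserving"
    BOTH = "both"
    NONE = "none"


@dataclass(frozen=True)
class ImpactCall:
    mutation: MutationRecord
    per_instance: tuple[tuple[MotifInstance, Verdict], ...]

    @property
    def aggregate(self) -> Aggregate:
        verdicts = {v for _, v in self.per_instance}
        if not verdicts:
            return Aggregate.NONE
        if verdicts == {Verdict.BREAKING}:
            return Aggregate.ONLY_BREAKING
        if verdicts == {Verdict.CONSERVING}:
            return Aggregate.ONLY_CONSERVING
        return Aggregate.BOTH


def apply_missense(sequence: str, mutation: MutationRecord) -> str:
    """Apply a single validated substitution to a protein sequence."""
    idx = mutation.position - 1
    if not 0 <= idx < len(sequence):
        raise ValueError(f"position {mutation.position} outside protein")
    if sequence[idx] != mutation.wt_aa:
        raise ValueError(
            f"wild-type mismatch at {mutation.accession}:{mutation.position}: "
            f"sequence has {sequence[idx]}, record says {mutation.wt_aa}"
        )
    return sequence[:idx] + mutation.mut_aa + sequence[idx + 1 :]


def classify_against_instance(
    inst: MotifInstance,
    cls: MotifClass,
    mutation: MutationRecord,
    sequence: str,
) -> Verdict:
    """Verdict of one mutation against one overlapping instance.

    The re-match is anchored at the instance's annotated start; spans of
    every feasible length are tried so variable-length quantifiers keep
    their flexibility.
    """
    if not inst.start <= mutation.position <= inst.end:
        raise ValueError(
            f"mutation at {mutation.position} outside instance span "
            f"{inst.start}-{inst.end}"
        )
    mutated = apply_missense(sequence, mutation)
    start0 = inst.start - 1
    n_term = cls.pattern.startswith("^")
    c_term = cls.pattern.endswith("$") and not cls.pattern.endswith(r"\$")
    if n_term and start0 != 0:
        return Verdict.BREAKING
    hi = min(cls.max_len, len(mutated) - start0)
    for length in range(hi, cls.min_len - 1, -1):
        if c_term and start0 + length != len(mutated):
            continue
        if cls.compiled.fullmatch(mutated, start0, start0 + length):
            return Verdict.CONSERVING
    return Verdict.BREAKING


def classify_mutation(
    mutation: MutationRecord,
    overlapping: Sequence[tuple[MotifInstance, MotifClass]],
    sequence: str,
) -> ImpactCall:
    """Classify one mutation against all instances containing its position."""
    per_instance = tuple(
        (inst, classify_against_instance(inst, cls, mutation, sequence))
        for inst, cls in overlapping
    )
    return ImpactCall(mutation=mutation, per_instance=per_instance)


def classify_dataset(
    mutations: Iterable[MutationRecord],
    instances: Sequence[MotifInstance],
    classes: Sequence[MotifClass],
    proteome: Mapping[str, "object"],
) -> list[ImpactCall]:
    """Classify every unique mutation of a dataset against the instance set.

    Mutations that overlap no instance yield aggregate NONE and are kept so
    the caller can audit coverage; summary tables exclude them.
    """
    by_id = {c.elm_id: c for c in classes}
    by_acc: dict[str, list[MotifInstance]] = {}
    for inst in instances:
        by_acc.setdefault(inst.accession, []).append(inst)
    seen: set[tuple] = set()
    calls: list[ImpactCall] = []
    for m in mutations:
        if m.key in seen:
            continue
        seen.add(m.key)
        overlapping = [
            (inst, by_id[inst.elm_id])
            for inst in by_acc.get(m.accession, [])
            if inst.start <= m.position <= inst.end and inst.elm_id in by_id
        ]
        seq = proteome[m.accession].sequence  # type: ignore[attr-defined]
        calls.append(classify_mutation(m, overlapping, seq))
    return calls


def classification_summary(calls_per_dataset: Mapping[str, Sequence[ImpactCall]]) -> dict:
    """Per-dataset counts and percentages of the three impact categories.

    Only calls overlapping at least one motif (aggregate != NONE) enter the
    table; row sums equal the number of unique classified mutations. Also
    reports the number of distinct mutated SLiM instances per dataset.
    """
    out: dict[str, dict] = {}
    for dataset, calls in calls_per_dataset.items():
        hits = [c for c in calls if c.aggregate is not Aggregate.NONE]
        counts = Counter(c.aggregate for c in hits)
        n = len(hits)
        slims = {
            (i.accession, i.elm_id, i.start, i.end)
            for c in hits
            for i, _ in c.per_instance
        }
        row = {
            "n_mutated_slims": len(slims),
            "n_mutations": n,
            "only_breaking": counts.get(Aggregate.ONLY_BREAKING, 0),
            "only_conserving": counts.get(Aggregate.ONLY_CONSERVING, 0),
            "both": counts.get(Aggregate.BOTH, 0),
        }
        for cat in ("only_breaking", "only_conserving", "both"):
            row[f"pct_{cat}"] = round(100.0 * row[cat] / n, 1) if n else 0.0
        out[dataset] = row
    return out
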
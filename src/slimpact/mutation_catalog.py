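"""Validation, deduplication and cross-dataset comparison of mutation sets.

Two identity conventions coexist and are kept as separate accessors:
a *unique mutation* is a distinct (accession, position, wt, mut) tuple and
is the unit of impact classification; a *mutated site* is a distinct
(accession, position) pair, counted once no matter how many substitutions
hit it, and is the unit of enrichment analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import MutationRecord, ProteinRecord

__all__ = [
    "MutatedSite",
    "RejectedMutation",
    "validate_against_proteome",
    "unique_mutations",
    "collapse_sites",
    "shared_protein_subset",
    "dataset_overlap_stats",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MutatedSite:
    """A unique (protein, residue position) carrying >= 1 missense mutation."""

    accession: str
    position: int


@dataclass(frozen=True)
class RejectedMutation:
    record: MutationRecord
    reason: str  # 'unknown accession' | 'position out of range' | 'wt mismatch'


def validate_against_proteome(
    mutations: Iterable[MutationRecord],
    proteome: Mapping[str, ProteinRecord],
) -> tuple[list[MutationRecord], list[RejectedMutation]]:
    """Check each record against the loaded proteome.

    A record is valid when its accession is known, its position lies within
    the protein and the protein carries the stated wild-type residue there.
    Failures become logged rejections, never silent drops.
    """
    valid: list[MutationRecord] = []
    rejected: list[RejectedMutation] = []
    for m in mutations:
        prot = proteome.get(m.accession)
        if prot is None:
            rejected.append(RejectedMutation(m, "unknown accession"))
        elif not 1 <= m.position <= prot.length:
            rejected.append(RejectedMutation(m, "position out of range"))
        elif prot.sequence[m.position - 1] != m.wt_aa:
            rejected.append(RejectedMutation(m, "wt mismatch"))
        else:
            valid.append(m)
    if rejected:
        logger.warning(
            "rejected %d of %d mutation records during proteome validation",
            len(rejected),
            len(rejected) + len(valid),
        )
    return valid, rejected


def unique_mutations(mutations: Iterable[MutationRecord]) -> list[MutationRecord]:
    """Deduplicate to distinct (accession, position, wt, mut), order kept."""
    seen: set[tuple] = set()
    out: list[MutationRecord] = []
    for m in mutations:
        if m.key not in seen:
            seen.add(m.key)
            out.append(m)
    return out


def collapse_sites(mutations: Iterable[MutationRecord]) -> set[MutatedSite]:
    """Collapse mutations to the set of unique mutated sites."""
    return {MutatedSite(m.accession, m.position) for m in mutations}


def shared_protein_subset(
    dataset_a: Sequence[MutationRecord], dataset_b: Sequence[MutationRecord]
) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Restrict both datasets to proteins mutated in both.

    Non-shared proteins are excluded so that compositional differences
    between the datasets' protein sets cannot bias downstream comparisons.
    """
    prots_a = {m.accession for m in dataset_a}
    prots_b = {m.accession for m in dataset_b}
    shared = prots_a & prots_b
    if not shared:
        logger.warning("compared datasets share no proteins")
    return (
        [m for m in dataset_a if m.accession in shared],
        [m for m in dataset_b if m.accession in shared],
    )


def dataset_overlap_stats(
    dataset_a: Sequence[MutationRecord], dataset_b: Sequence[MutationRecord]
) -> dict:
    """Overlap of dataset A with dataset B at protein and site level.

    Percentages are shared/|A| rounded to one decimal; sites are collapsed
    before counting so multiply-hit sites count once.
    """
    prots_a = {m.accession for m in dataset_a}
    prots_b = {m.accession for m in dataset_b}
    sites_a = collapse_sites(dataset_a)
    sites_b = collapse_sites(dataset_b)
    shared_prots = prots_a & prots_b
    shared_sites = sites_a & sites_b
    return {
        "proteins_a": len(prots_a),
        "sites_a": len(sites_a),
        "shared_proteins": len(shared_prots),
        "shared_sites": len(shared_sites),
        "pct_shared_proteins": round(100.0 * len(shared_prots) / len(prots_a), 1)
        if prots_a
        else 0.0,
        "pct_shared_sites": round(100.0 * len(shared_sites) / len(sites_a), 1)
        if sites_a
        else 0.0,
    }
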
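"""Physicochemical classification of amino acids and transition matrices.

Six categorical property schemes — charge, hydropathy, polarity, volume,
side-chain chemical characteristics, and hydrogen donor/acceptor
availability — each partition the 20 standard amino acids into labelled
subclasses. For a set of motif-overlapping mutations, a per-property N×N
matrix counts wild-type-subclass → mutant-subclass transitions; the
off-diagonal mass fraction is the rate at which mutations *change* the
property. Volume subclasses are ordered (very small < small < medium <
large < very large) so a signed rank difference expresses whether a
substitution increases residue volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .io_formats import AMINO_ACIDS, MutationRecord

__all__ = [
    "PROPERTY_SCHEMES",
    "VOLUME_ORDER",
    "subclass_of",
    "TransitionMatrix",
    "transition_matrix",
    "change_fraction",
    "volume_rank_change",
]

def _expand(groups: Mapping[str, str]) -> dict[str, str]:
    """{'label': 'RHK', ...} -> per-residue lookup, partition-checked."""
    lookup: dict[str, str] = {}
    for label, members in groups.items():
        for aa in members:
            if aa in lookup:
                raise ValueError(f"{aa} assigned to two subclasses")
            lookup[aa] = label
    if set(lookup) != set(AMINO_ACIDS):
        raise ValueError("subclasses do not partition the 20 amino acids")
    return lookup


#: label order is preserved and defines matrix row/column order
PROPERTY_SCHEMES: dict[str, dict[str, str]] = {
    "charge": {
        "positively charged": "RHK",
        "negatively charged": "DE",
        "uncharged": "ANCQGILMFPSTWYV",
    },
    "hydropathy": {
        "hydrophobic": "ACILMFWV",
        "neutral": "GHPSTY",
        "hydrophilic": "RNDQEK",
    },
    "polarity": {
        "polar": "RNDQEHKSTY",
        "non-polar": "ACGILMFPWV",
    },
    "volume": {
        "very small": "AGS",
        "small": "NDCPT",
        "medium": "QEHV",
        "large": "RILKM",
        "very large": "FWY",
    },
    "chemical": {
        "aliphatic": "AGILPV",
        "aromatic": "FWY",
        "sulfur": "CM",
        "hydroxyl": "ST",
        "basic": "RHK",
        "acidic": "DE",
        "amide": "NQ",
    },
    "hydrogen": {
        "donor": "RKW",
        "acceptor": "DE",
        "donor and acceptor": "NQHSTY",
        "neither": "ACGILMFPV",
    },
}

_LOOKUP = {prop: _expand(groups) for prop, groups in PROPERTY_SCHEMES.items()}

VOLUME_ORDER = ["very small", "small", "medium", "large", "very large"]


def subclass_of(aa: str, prop: str) -> str:
    """Subclass label of a standard amino acid under one property scheme."""
    try:
        table = _LOOKUP[prop]
    except KeyError:
        raise KeyError(f"unknown property {prop!r}; one of {sorted(_LOOKUP)}")
    try:
        return table[aa]
    except KeyError:
        raise ValueError(f"non-standard residue {aa!r}")


@dataclass
class TransitionMatrix:
    """Counts of wild-type-subclass (rows) → mutant-subclass (columns)."""

    property_name: str
    labels: list[str]
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.counts is None:
            self.counts = np.zeros((n, n), dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if (self.counts < 0).any():
            raise ValueError("negative transition count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "TransitionMatrix") -> "TransitionMatrix":
        if self.property_name != other.property_name or self.labels != other.labels:
            raise ValueError("cannot add matrices of different schemes")
        return TransitionMatrix(
            self.property_name, list(self.labels), self.counts + other.counts
        )

    def off_diagonal(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))


def transition_matrix(
    mutations: Iterable[MutationRecord], prop: str
) -> TransitionMatrix:
    """Build the wt→mut subclass transition matrix for one property."""
    labels = list(PROPERTY_SCHEMES[prop])
    index = {lab: i for i, lab in enumerate(labels)}
    mat = TransitionMatrix(prop, labels)
    for m in mutations:
        i = index[subclass_of(m.wt_aa, prop)]
        j = index[subclass_of(m.mut_aa, prop)]
        mat.counts[i, j] += 1
    return mat


def change_fraction(matrix: TransitionMatrix) -> float:
    """Fraction of mutations that change the property (off-diagonal mass)."""
    total = matrix.total
    if total == 0:
        raise ValueError("change fraction undefined for an all-zero matrix")
    return matrix.off_diagonal() / total


def volume_rank_change(wt_aa: str, mut_aa: str) -> int:
    """Signed step along the volume ordering; positive = volume increase."""
    return VOLUME_ORDER.index(subclass_of(mut_aa, "volume")) - VOLUME_ORDER.index(
        subclass_of(wt_aa, "volume")
    )
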
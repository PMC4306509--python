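"""SLiM-mediated protein interaction network and mutation burden analysis.

A binary PPI edge (A, B) is *SLiM-mediated* when one partner carries a motif
instance whose class is known to bind a domain family annotated on the other
partner. Matching is identity-based on (motif class, domain id) — the known
domain–motif pair table is the mechanistic dictionary; domain coordinates are
carried along as metadata only. The network is undirected; an edge is unique
per unordered protein pair and records every mediator (instance, partner
domain, direction).

The *interaction burden* of a mutated site is the number of distinct
interaction partners reachable through mediator instances covering the site
(multiple mediators to one partner count once); sites covered by no network
instance have burden zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .enrichment_stats import wilcoxon_rank_sum
from .io_formats import FormatError, ScoreTrack, _iter_rows, _parse_int
from .motif_engine import MotifInstance
from .mutation_catalog import MutatedSite

__all__ = [
    "DomainAnnotation",
    "DomainMotifPair",
    "SlimEdge",
    "load_network_inputs",
    "build_slim_interactome",
    "interactions_per_site",
    "interaction_burden_comparison",
    "write_edge_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DomainAnnotation:
    """A PFAM-like domain occurrence on a protein (1-based inclusive)."""

    accession: str
    domain_id: str
    start: int
    end: int


@dataclass(frozen=True)
class DomainMotifPair:
    """A motif class known to be recognised by a domain family."""

    elm_id: str
    domain_id: str


@dataclass(frozen=True)
class Mediator:
    """One mechanistic explanation of an edge: instance on one side,
    binding domain on the other. ``motif_side`` names the protein that
    carries the instance."""

    instance: MotifInstance
    domain_id: str
    motif_side: str
    domain_side: str


@dataclass(frozen=True)
class SlimEdge:
    acc_a: str
    acc_b: str
    mediators: tuple[Mediator, ...]

    @property
    def pair(self) -> frozenset:
        return frozenset((self.acc_a, self.acc_b))


def load_network_inputs(
    ppi_path: str | Path,
    domains_path: str | Path,
    pairs_path: str | Path,
) -> tuple[list[tuple[str, str]], list[DomainAnnotation], list[DomainMotifPair]]:
    """Load PPI edges, domain annotations and the domain–motif pair table.

    Duplicate undirected edges collapse to one; self-interactions are kept
    but logged.
    """
    edges: list[tuple[str, str]] = []
    seen: set[frozenset] = set()
    n_self = 0
    for lineno, f in _iter_rows(ppi_path, 2):
        a, b = f[0], f[1]
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        if a == b:
            n_self += 1
        edges.append((a, b))
    if n_self:
        logger.info("kept %d self-interaction(s) (flagged)", n_self)

    domains = []
    for lineno, f in _iter_rows(domains_path, 4):
        start = _parse_int(f[2], f"{domains_path}:{lineno}")
        end = _parse_int(f[3], f"{domains_path}:{lineno}")
        if not 1 <= start <= end:
            raise FormatError(f"{domains_path}:{lineno}: bad span {start}-{end}")
        domains.append(DomainAnnotation(f[0], f[1], start, end))

    pairs = []
    pair_seen: set[tuple[str, str]] = set()
    for _, f in _iter_rows(pairs_path, 2):
        key = (f[0], f[1])
        if key not in pair_seen:
            pair_seen.add(key)
            pairs.append(DomainMotifPair(elm_id=f[0], domain_id=f[1]))
    return edges, domains, pairs


def build_slim_interactome(
    ppi: Iterable[tuple[str, str]],
    annotations: Sequence[DomainAnnotation],
    instances: Sequence[MotifInstance],
    pairs: Sequence[DomainMotifPair],
) -> list[SlimEdge]:
    """Explain each PPI edge by motif–domain recognition where possible.

    For each undirected edge (A, B), every (instance on A, paired domain on
    B) and symmetrically (instance on B, paired domain on A) becomes a
    mediator; edges with at least one mediator become SlimEdges.
    """
    paired_domains: dict[str, set[str]] = {}
    for p in pairs:
        paired_domains.setdefault(p.elm_id, set()).add(p.domain_id)
    inst_by_acc: dict[str, list[MotifInstance]] = {}
    for i in instances:
        inst_by_acc.setdefault(i.accession, []).append(i)
    doms_by_acc: dict[str, set[str]] = {}
    for d in annotations:
        doms_by_acc.setdefault(d.accession, set()).add(d.domain_id)

    def mediators_of(motif_prot: str, domain_prot: str) -> list[Mediator]:
        out = []
        partner_doms = doms_by_acc.get(domain_prot, set())
        for inst in inst_by_acc.get(motif_prot, ()):
            for dom in sorted(paired_domains.get(inst.elm_id, set()) & partner_doms):
                out.append(
                    Mediator(
                        instance=inst,
                        domain_id=dom,
                        motif_side=motif_prot,
                        domain_side=domain_prot,
                    )
                )
        return out

    edges_out: list[SlimEdge] = []
    for a, b in ppi:
        meds = mediators_of(a, b)
        if a != b:
            meds += mediators_of(b, a)
        if meds:
            edges_out.append(SlimEdge(acc_a=a, acc_b=b, mediators=tuple(meds)))
    return edges_out


def to_graph(edges: Iterable[SlimEdge]) -> nx.Graph:
    """The SLiM-mediated interactome as an undirected networkx graph."""
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.acc_a, e.acc_b, mediators=e.mediators)
    return g


def interactions_per_site(
    site: MutatedSite,
    edges: Sequence[SlimEdge],
    instances: Sequence[MotifInstance] | None = None,
) -> int:
    """Number of distinct partners mediated by instances covering the site."""
    partners: set[str] = set()
    for e in edges:
        for med in e.mediators:
            inst = med.instance
            if (
                inst.accession == site.accession
                and inst.start <= site.position <= inst.end
            ):
                partners.add(med.domain_side)
    partners.discard(site.accession)  # self-loop mediators add no partner
    return len(partners)


def interaction_burden_comparison(
    disease_sites: Sequence[MutatedSite],
    neutral_sites: Sequence[MutatedSite],
    edges: Sequence[SlimEdge],
    tracks: Mapping[str, ScoreTrack],
) -> dict:
    """Compare per-site interaction burdens between two datasets.

    Both site sets are restricted to disordered residues (disorder > 0.5).
    Burden histograms are scaled to counts per 10 000 sites so datasets of
    different sizes are comparable; the test is a two-sided Wilcoxon
    rank-sum on the raw per-site burdens.
    """

    def disordered(sites: Sequence[MutatedSite]) -> list[MutatedSite]:
        kept = []
        for s in sites:
            track = tracks.get(s.accession)
            if track is not None and track.disorder[s.position - 1] > 0.5:
                kept.append(s)
        return kept

    groups = {
        "disease": disordered(disease_sites),
        "neutral": disordered(neutral_sites),
    }
    for name, sites in groups.items():
        if not sites:
            raise ValueError(f"no disordered {name} sites to compare")

    burdens = {
        name: np.array([interactions_per_site(s, edges) for s in sites])
        for name, sites in groups.items()
    }
    histograms = {}
    for name, values in burdens.items():
        counts = np.bincount(values)
        histograms[name] = {
            int(k): float(10_000.0 * counts[k] / values.size)
            for k in range(counts.size)
            if counts[k]
        }
    return {
        "n_sites": {name: int(v.size) for name, v in burdens.items()},
        "mean_burden": {name: float(v.mean()) for name, v in burdens.items()},
        "histogram_per_10k": histograms,
        "p_value": wilcoxon_rank_sum(burdens["disease"], burdens["neutral"]),
    }


def write_edge_table(edges: Iterable[SlimEdge], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "#acc_a\tacc_b\tmotif_side\telm_id\tstart\tend\tdomain_id"
            "\tdomain_side\n"
        )
        for e in edges:
            for m in e.mediators:
                i = m.instance
                fh.write(
                    f"{e.acc_a}\t{e.acc_b}\t{m.motif_side}\t{i.elm_id}"
                    f"\t{i.start}\t{i.end}\t{m.domain_id}\t{m.domain_side}\n"
                )
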
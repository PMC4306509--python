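"""Seeded synthetic study bundles with known ground truth.

The generator emulates the structure the analysis depends on, nothing more:
proteins are random sequences carrying a two-state order/disorder profile
(disordered tracts with disorder scores above 0.5, ordered elsewhere);
exact-match realizations of real ELM-style motif patterns are planted inside
disordered tracts and given elevated relative local conservation; a neutral
mutation set samples sites uniformly while disease-like sets oversample
motif residues by a configured odds ratio and bias their substitutions
toward pattern-violating residues; and a skew-degree PPI network with domain
annotations is built so that a configured fraction of edges is
motif-mediated by construction. Every draw flows from one
``numpy.random.Generator`` seeded by the mandatory study seed, so a bundle
is reproducible bit-for-bit, and the planted-instance manifest is the ground
truth against which every downstream statistic can be checked.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .impact_classifier import Verdict, classify_against_instance
from .io_formats import (
    AMINO_ACIDS,
    MotifClass,
    MutationRecord,
    ProteinRecord,
    ScoreTrack,
    normalize_pattern,
    write_fasta,
    write_motif_classes,
    write_mutation_table,
    write_score_tracks,
)
from .motif_engine import MotifInstance

__all__ = [
    "DEFAULT_PLANTED_CLASSES",
    "SyntheticStudyConfig",
    "SyntheticStudy",
    "generate_proteome_and_tracks",
    "generate_mutations",
    "generate_network",
    "generate_study",
    "write_study_bundle",
]

#: Real ELM-style classes used for planting, including the phospho-degron
#: bound by the SCF-betaTrCP ubiquitin ligase, the STAT5 SH2-binding motif
#: and the integrin-recognised RGD tripeptide.
DEFAULT_PLANTED_CLASSES: tuple[MotifClass, ...] = (
    MotifClass(
        "DEG_SCF_TRCP1_1", "DEG", normalize_pattern("DSGx{2,3}[ST]"),
        occurrence_probability=0.0003, raw_pattern="DSGx{2,3}[ST]",
    ),
    MotifClass(
        "LIG_SH2_STAT5", "LIG", normalize_pattern("Y[VLTFIC]xx"),
        occurrence_probability=0.005, raw_pattern="Y[VLTFIC]xx",
    ),
    MotifClass(
        "LIG_RGD", "LIG", "RGD",
        occurrence_probability=0.002, raw_pattern="RGD",
    ),
    MotifClass(
        "MOD_PKA_1", "MOD", normalize_pattern("R[RK]x[ST]"),
        occurrence_probability=0.004, raw_pattern="R[RK]x[ST]",
    ),
)


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study conditions for one synthetic bundle.

    ``odds_ratio`` multiplies the sampling odds of within-motif residues for
    the disease-like dataset; ``breaking_bias`` is the probability that a
    within-motif disease substitution is drawn from the residues that
    violate the motif pattern. ``motif_density`` is planted instances per
    disordered residue.
    """

    n_proteins: int = 40
    length_range: tuple[int, int] = (300, 540)
    disordered_fraction: float = 0.45
    mean_tract_length: float = 60.0
    motif_density: float = 0.012
    classes: tuple[MotifClass, ...] = DEFAULT_PLANTED_CLASSES
    odds_ratio: float = 3.0
    breaking_bias: float = 0.8
    n_sites: Mapping[str, int] = field(
        default_factory=lambda: {"disease": 2000, "neutral": 2000}
    )
    n_edges: int = 300
    mediated_fraction: float = 0.5
    degree_skew: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.breaking_bias <= 1.0:
            raise ValueError("breaking_bias must lie in [0, 1]")
        if not 0.0 < self.disordered_fraction < 1.0:
            raise ValueError("disordered_fraction must lie in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class SyntheticStudy:
    config: SyntheticStudyConfig
    proteome: dict[str, ProteinRecord]
    tracks: dict[str, ScoreTrack]
    manifest: list[MotifInstance]
    mutations: dict[str, list[MutationRecord]]
    ppi: list[tuple[str, str]]
    domains: list
    pairs: list


# ---------------------------------------------------------------------------
# pattern realization


def _class_alphabet(items) -> list[str]:
    allowed: set[str] = set()
    negate = False
    for op, arg in items:
        name = str(op)
        if name.endswith("NEGATE"):
            negate = True
        elif name.endswith("LITERAL"):
            allowed.add(chr(arg))
        elif name.endswith("RANGE"):
            lo, hi = arg
            allowed.update(chr(c) for c in range(lo, hi + 1))
    if negate:
        return [a for a in AMINO_ACIDS if a not in allowed]
    return [a for a in AMINO_ACIDS if a in allowed]


def realize_pattern(pattern: str, rng: np.random.Generator) -> str:
    """Draw one amino-acid string that fully matches ``pattern``."""
    from re import _parser as parser  # type: ignore[attr-defined]

    def walk(nodes) -> str:
        out = []
        for op, arg in nodes:
            name = str(op)
            if name.endswith("NOT_LITERAL"):
                choices = [a for a in AMINO_ACIDS if a != chr(arg)]
                out.append(rng.choice(choices))
            elif name.endswith("LITERAL"):
                out.append(chr(arg))
            elif name.endswith("ANY"):
                out.append(rng.choice(list(AMINO_ACIDS)))
            elif name.endswith("IN"):
                choices = _class_alphabet(arg)
                if not choices:
                    raise ValueError(f"unrealizable character class in {pattern}")
                out.append(rng.choice(choices))
            elif "REPEAT" in name:
                lo, hi, item = arg
                hi = min(hi, lo + 10)
                n = int(rng.integers(lo, hi + 1))
                for _ in range(n):
                    out.append(walk(item))
            elif name.endswith("SUBPATTERN"):
                out.append(walk(arg[3]))
            elif name.endswith("BRANCH"):
                branches = arg[1]
                out.append(walk(branches[rng.integers(len(branches))]))
            elif name.endswith("AT"):
                continue  # anchors occupy no residues
            else:
                raise ValueError(f"unsupported regex construct {name} in {pattern}")
        return "".join(out)

    realization = walk(parser.parse(pattern))
    assert re.fullmatch(pattern.lstrip("^").rstrip("$"), realization)
    return realization


# ---------------------------------------------------------------------------
# proteome, tracts, planting


def _tract_mask(
    length: int, cfg: SyntheticStudyConfig, rng: np.random.Generator
) -> np.ndarray:
    """Boolean per-residue mask, True inside disordered tracts."""
    f = cfg.disordered_fraction
    mean_dis = cfg.mean_tract_length
    mean_ord = max(2.0, mean_dis * (1.0 - f) / f)
    mask = np.zeros(length, dtype=bool)
    pos = 0
    state_dis = rng.random() < f
    while pos < length:
        mean = mean_dis if state_dis else mean_ord
        run = 1 + rng.geometric(1.0 / mean)
        mask[pos : pos + run] = state_dis
        pos += run
        state_dis = not state_dis
    return mask


def generate_proteome_and_tracks(
    config: SyntheticStudyConfig, seed: int | None = None
) -> tuple[dict[str, ProteinRecord], dict[str, ScoreTrack], list[MotifInstance]]:
    """Generate proteins, their score tracks and the planted-motif manifest.

    Planted instances are exact pattern realizations written into disordered
    tracts, never overlapping each other; their residues receive elevated
    RLC (> 0.5) while the background RLC stays below 0.5, so the planted set
    is exactly what survives the default disorder/RLC filter.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    max_len = max(c.max_len for c in config.classes)
    if max_len >= config.length_range[0]:
        raise ValueError("motif longer than the shortest allowed protein")
    aa = np.array(list(AMINO_ACIDS))
    proteome: dict[str, ProteinRecord] = {}
    tracks: dict[str, ScoreTrack] = {}
    manifest: list[MotifInstance] = []

    for k in range(config.n_proteins):
        acc = f"SYN{k:04d}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = rng.choice(aa, size=length)
        dis_mask = _tract_mask(length, config, rng)

        occupied = np.zeros(length, dtype=bool)
        planted: list[tuple[str, int, str]] = []  # (elm_id, start0, realization)
        # contiguous disordered tracts
        edges = np.flatnonzero(np.diff(np.r_[0, dis_mask.view(np.int8), 0]))
        for t0, t1 in zip(edges[::2], edges[1::2]):
            tract_len = t1 - t0
            n_plant = rng.binomial(tract_len, config.motif_density)
            for _ in range(n_plant):
                cls = config.classes[rng.integers(len(config.classes))]
                real = realize_pattern(cls.pattern, rng)
                if len(real) > tract_len:
                    continue
                start0 = int(t0 + rng.integers(tract_len - len(real) + 1))
                if occupied[start0 : start0 + len(real)].any():
                    continue
                seq[start0 : start0 + len(real)] = list(real)
                occupied[start0 : start0 + len(real)] = True
                planted.append((cls.elm_id, start0, real))

        sequence = "".join(seq)
        proteome[acc] = ProteinRecord(acc, sequence)
        disorder = np.where(
            dis_mask,
            rng.uniform(0.55, 0.98, size=length),
            rng.uniform(0.02, 0.45, size=length),
        )
        rlc = rng.uniform(-2.0, 0.45, size=length)
        for _, start0, real in planted:
            rlc[start0 : start0 + len(real)] = rng.uniform(0.6, 1.6, size=len(real))
        tracks[acc] = ScoreTrack(acc, disorder, rlc)
        for elm_id, start0, real in planted:
            manifest.append(
                MotifInstance(
                    accession=acc,
                    elm_id=elm_id,
                    start=start0 + 1,
                    end=start0 + len(real),
                    matched_seq=real,
                    mean_disorder=float(
                        disorder[start0 : start0 + len(real)].mean()
                    ),
                    mean_rlc=float(rlc[start0 : start0 + len(real)].mean()),
                    provenance="predicted",
                )
            )
    return proteome, tracks, manifest


# ---------------------------------------------------------------------------
# mutations


def _breaking_alternatives(
    inst: MotifInstance,
    cls: MotifClass,
    sequence: str,
    position: int,
) -> list[str]:
    """Mutant residues at ``position`` that break the instance's pattern."""
    wt = sequence[position - 1]
    out = []
    for mut in AMINO_ACIDS:
        if mut == wt:
            continue
        rec = MutationRecord(inst.accession, position, wt, mut, dataset="probe")
        if classify_against_instance(inst, cls, rec, sequence) is Verdict.BREAKING:
            out.append(mut)
    return out


def generate_mutations(
    config: SyntheticStudyConfig,
    proteome: Mapping[str, ProteinRecord],
    manifest: Sequence[MotifInstance],
    seed: int | None = None,
    tracks: Mapping[str, ScoreTrack] | None = None,
) -> dict[str, list[MutationRecord]]:
    """Sample the neutral and disease-like mutation datasets.

    Neutral sites are uniform over all residues. Disease sites multiply the
    within-motif sampling odds by ``config.odds_ratio``; within planted
    motifs, with probability ``config.breaking_bias`` the substitution is
    drawn from the pattern-violating residues at a constrained position
    (relocating within the instance when the sampled position is an
    unconstrained wild card), otherwise uniformly over the 19 alternatives.
    """
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 1_000_003
    )
    by_class = {c.elm_id: c for c in config.classes}
    accs = list(proteome)
    offsets = {}
    flat_sites: list[tuple[str, int]] = []
    for acc in accs:
        offsets[acc] = len(flat_sites)
        flat_sites.extend((acc, p) for p in range(1, proteome[acc].length + 1))
    n_total = len(flat_sites)

    in_motif = np.zeros(n_total, dtype=bool)
    site_instance: dict[int, MotifInstance] = {}
    for inst in manifest:
        base = offsets[inst.accession]
        for pos in inst.span:
            idx = base + pos - 1
            in_motif[idx] = True
            site_instance[idx] = inst

    datasets: dict[str, list[MutationRecord]] = {}
    for name, n_sites in config.n_sites.items():
        if n_sites > n_total:
            raise ValueError(f"{name}: requested {n_sites} sites, only {n_total}")
        is_disease = name != "neutral"
        weights = np.ones(n_total)
        if is_disease:
            weights[in_motif] = config.odds_ratio
        chosen = rng.choice(
            n_total, size=n_sites, replace=False, p=weights / weights.sum()
        )
        chosen_set = set(int(i) for i in chosen)
        records: list[MutationRecord] = []
        for idx in sorted(chosen_set):
            acc, pos = flat_sites[idx]
            seq = proteome[acc].sequence
            mut: str | None = None
            if is_disease and in_motif[idx] and rng.random() < config.breaking_bias:
                inst = site_instance[idx]
                cls = by_class[inst.elm_id]
                breakers = _breaking_alternatives(inst, cls, seq, pos)
                if not breakers:
                    # wild-card position: relocate to a constrained position
                    # of the same instance, preferring unused sites
                    base = offsets[acc]
                    candidates = [
                        p
                        for p in inst.span
                        if _breaking_alternatives(inst, cls, seq, p)
                    ]
                    unused = [
                        p for p in candidates if (base + p - 1) not in chosen_set
                    ]
                    pool = unused or candidates
                    if pool:
                        new_pos = int(pool[rng.integers(len(pool))])
                        chosen_set.discard(idx)
                        chosen_set.add(base + new_pos - 1)
                        pos = new_pos
                        breakers = _breaking_alternatives(inst, cls, seq, pos)
                if breakers:
                    mut = str(breakers[rng.integers(len(breakers))])
            wt = seq[pos - 1]
            if mut is None:
                alternatives = [a for a in AMINO_ACIDS if a != wt]
                mut = str(alternatives[rng.integers(len(alternatives))])
            records.append(
                MutationRecord(
                    accession=acc, position=pos, wt_aa=wt, mut_aa=mut, dataset=name
                )
            )
        datasets[name] = records
    return datasets


# ---------------------------------------------------------------------------
# network


def generate_network(
    config: SyntheticStudyConfig,
    proteome: Mapping[str, ProteinRecord],
    manifest: Sequence[MotifInstance],
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], list, list]:
    """Build a PPI edge list, domain annotations and the pair table.

    A ``mediated_fraction`` of edges is SLiM-mediated by construction: the
    partner of a planted instance is annotated with the domain paired to the
    instance's class. Partner choice follows a Zipf-like weight so hubs
    emerge.
    """
    from .interactome import DomainAnnotation, DomainMotifPair

    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 2_000_003
    )
    accs = list(proteome)
    ranks = rng.permutation(len(accs))
    weights = 1.0 / (1.0 + ranks.astype(float)) ** config.degree_skew
    weights /= weights.sum()

    pairs = [
        DomainMotifPair(elm_id=c.elm_id, domain_id=f"PF_{c.elm_id}")
        for c in config.classes
    ]

    edge_keys: set[frozenset] = set()
    edges: list[tuple[str, str]] = []
    domains: list[DomainAnnotation] = []
    domain_keys: set[tuple[str, str]] = set()

    n_mediated = int(round(config.mediated_fraction * config.n_edges))
    attempts = 0
    while len(edges) < n_mediated and manifest and attempts < 20 * config.n_edges:
        attempts += 1
        inst = manifest[rng.integers(len(manifest))]
        partner = accs[rng.choice(len(accs), p=weights)]
        if partner == inst.accession:
            continue
        key = frozenset((inst.accession, partner))
        if key in edge_keys:
            continue
        edge_keys.add(key)
        edges.append((inst.accession, partner))
        dom_id = f"PF_{inst.elm_id}"
        if (partner, dom_id) not in domain_keys:
            domain_keys.add((partner, dom_id))
            length = proteome[partner].length
            start = int(rng.integers(1, max(2, length - 40)))
            domains.append(
                DomainAnnotation(partner, dom_id, start, min(length, start + 39))
            )

    while len(edges) < config.n_edges and attempts < 40 * config.n_edges:
        attempts += 1
        a, b = (accs[i] for i in rng.choice(len(accs), size=2, p=weights))
        if a == b:
            continue
        key = frozenset((a, b))
        if key in edge_keys:
            continue
        edge_keys.add(key)
        edges.append((a, b))
    return edges, domains, pairs


# ---------------------------------------------------------------------------
# bundles


def generate_study(config: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate a full in-memory study bundle from one config/seed."""
    proteome, tracks, manifest = generate_proteome_and_tracks(config)
    mutations = generate_mutations(config, proteome, manifest, tracks=tracks)
    ppi, domains, pairs = generate_network(config, proteome, manifest)
    return SyntheticStudy(
        config=config,
        proteome=proteome,
        tracks=tracks,
        manifest=manifest,
        mutations=mutations,
        ppi=ppi,
        domains=domains,
        pairs=pairs,
    )


def write_study_bundle(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Serialize a study to the pipeline's input formats plus manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(study.proteome, out / "proteome.fasta")
    write_motif_classes(study.config.classes, out / "classes.tsv")
    write_score_tracks(study.tracks, out / "tracks.tsv")
    for name, records in study.mutations.items():
        write_mutation_table(records, out / f"mutations_{name}.tsv")
    with open(out / "ppi.tsv", "w", encoding="utf-8") as fh:
        fh.write("#acc_a\tacc_b\n")
        for a, b in study.ppi:
            fh.write(f"{a}\t{b}\n")
    with open(out / "domains.tsv", "w", encoding="utf-8") as fh:
        fh.write("#accession\tdomain_id\tstart\tend\n")
        for d in study.domains:
            fh.write(f"{d.accession}\t{d.domain_id}\t{d.start}\t{d.end}\n")
    with open(out / "pairs.tsv", "w", encoding="utf-8") as fh:
        fh.write("#elm_id\tdomain_id\n")
        for p in study.pairs:
            fh.write(f"{p.elm_id}\t{p.domain_id}\n")
    manifest = [
        {
            "accession": i.accession,
            "elm_id": i.elm_id,
            "start": i.start,
            "end": i.end,
            "matched_seq": i.matched_seq,
            "mean_disorder": i.mean_disorder,
            "mean_rlc": i.mean_rlc,
        }
        for i in study.manifest
    ]
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(
            {"seed": study.config.seed, "instances": manifest}, fh, indent=1
        )
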
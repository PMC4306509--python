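"""End-to-end orchestration: validate → scan/filter → classify → enrich →
properties → network → report.

The pipeline is configured by one declarative mapping (typically a YAML
file): input paths, the disorder/RLC cutoffs (default 0.5/0.5), the RLC bin
edges and the occurrence-probability threshold (default 0.01) used for the
candidate-protein list. Each stage logs record counts in and out, every
p-value in the report sits next to the contingency table it came from, and
the run is deterministic given its inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from . import enrichment_stats as es
from . import impact_classifier as ic
from . import interactome as net
from . import io_formats as io
from . import motif_engine as me
from . import mutation_catalog as mc
from . import property_transitions as pt

__all__ = ["AnalysisReport", "run_full_analysis", "load_config"]

logger = logging.getLogger(__name__)

DEFAULTS = {
    "disorder_cutoff": 0.5,
    "rlc_cutoff": 0.5,
    "probability_threshold": 0.01,
    "neutral_dataset": "neutral",
    "rlc_bins": list(np.arange(-2.5, 2.0 + 1e-9, 0.5)),
}


@dataclass
class AnalysisReport:
    """Structured results of one full run; JSON-serializable."""

    metadata: dict = field(default_factory=dict)
    overlap: dict = field(default_factory=dict)
    classification: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    properties: dict = field(default_factory=dict)
    burden: dict = field(default_factory=dict)
    candidates: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, default=_jsonify)


def _jsonify(obj: Any):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return {**DEFAULTS, **cfg}


def _result_dict(res: es.EnrichmentResult) -> dict:
    return {
        "stratum": res.stratum,
        "table": [list(r) for r in res.table.counts],
        "row_labels": list(res.table.row_labels),
        "col_labels": list(res.table.col_labels),
        "p_value": res.p_value,
        "odds_ratio": res.odds_ratio,
        "testable": res.testable,
    }


def run_full_analysis(
    config: Mapping[str, Any], out_dir: str | Path | None = None
) -> AnalysisReport:
    """Run the whole analysis described by ``config``; optionally write the
    standard output files into ``out_dir``."""
    cfg = {**DEFAULTS, **dict(config)}
    report = AnalysisReport()
    report.metadata = {
        "version": __version__,
        "config": {
            k: v for k, v in cfg.items() if not isinstance(v, (dict, list))
        },
    }

    # --- stage: load and validate -----------------------------------------
    proteome = io.read_fasta(cfg["fasta"])
    classes = io.read_motif_classes(cfg["classes"])
    tracks = io.read_score_tracks(cfg["tracks"], proteome)
    datasets: dict[str, list[io.MutationRecord]] = {}
    rejected_counts: dict[str, int] = {}
    for name, path in cfg["mutations"].items():
        raw = io.read_mutation_table(path, dataset=name)
        valid, rejected = mc.validate_against_proteome(raw, proteome)
        datasets[name] = mc.unique_mutations(valid)
        rejected_counts[name] = len(rejected)
        logger.info(
            "dataset %s: %d records in, %d valid unique, %d rejected",
            name, len(raw), len(datasets[name]), len(rejected),
        )
    report.metadata["rejected_records"] = rejected_counts
    neutral = cfg["neutral_dataset"]
    disease_names = [n for n in datasets if n != neutral]

    # --- stage: overlap summaries ------------------------------------------
    if neutral in datasets:
        report.overlap = {
            name: mc.dataset_overlap_stats(datasets[name], datasets[neutral])
            for name in disease_names
        }

    # --- stage: scan, annotate, filter --------------------------------------
    candidates_raw = me.scan_proteome(proteome, classes)
    annotated = me.annotate_all(candidates_raw, tracks)
    predicted = me.filter_predicted_instances(
        annotated, cfg["disorder_cutoff"], cfg["rlc_cutoff"]
    )
    logger.info(
        "scan: %d candidate instances, %d kept after filtering",
        len(candidates_raw), len(predicted),
    )
    if cfg.get("validated_instances"):
        validated = me.instances_from_validated_table(
            io.read_validated_instances(cfg["validated_instances"]), proteome
        )
        validated = me.annotate_all(validated, tracks)
    else:
        validated = None
    classify_set = validated if validated is not None else predicted

    # --- stage: impact classification ---------------------------------------
    calls = {
        name: ic.classify_dataset(muts, classify_set, classes, proteome)
        for name, muts in datasets.items()
    }
    report.classification = ic.classification_summary(calls)

    # --- stage: enrichment ---------------------------------------------------
    sites = {name: mc.collapse_sites(m) for name, m in datasets.items()}
    enr: dict[str, Any] = {}
    for name in disease_names:
        per_region = es.site_overlap_enrichment(
            sites[name], sites[neutral], classify_set, tracks,
            labels=(name, neutral),
        )
        enr[f"{name}_vs_{neutral}_by_region"] = {
            region: _result_dict(r) for region, r in per_region.items()
        }
        by_rlc = es.rlc_binned_enrichment(
            predicted, sites[name], sites[neutral], tracks,
            bin_edges=cfg["rlc_bins"], labels=(name, neutral),
        )
        enr[f"{name}_vs_{neutral}_by_rlc"] = [_result_dict(r) for r in by_rlc]
    report.enrichment = enr

    # --- stage: property transitions ----------------------------------------
    in_motif = {
        name: [c.mutation for c in cs if c.aggregate is not ic.Aggregate.NONE]
        for name, cs in calls.items()
    }
    matrices = {
        name: {
            prop: pt.transition_matrix(muts, prop)
            for prop in pt.PROPERTY_SCHEMES
        }
        for name, muts in in_motif.items()
    }
    prop_report: dict[str, Any] = {
        name: {
            prop: {
                "labels": m.labels,
                "counts": m.counts.tolist(),
                "change_fraction": (
                    pt.change_fraction(m) if m.total else None
                ),
            }
            for prop, m in per_prop.items()
        }
        for name, per_prop in matrices.items()
    }
    tests = {}
    if neutral in matrices:
        for name in disease_names:
            tests[f"{name}_vs_{neutral}"] = {
                prop: es.property_change_test(
                    matrices[name][prop], matrices[neutral][prop]
                )
                for prop in pt.PROPERTY_SCHEMES
                if matrices[name][prop].total and matrices[neutral][prop].total
            }
    report.properties = {"matrices": prop_report, "change_tests": tests}

    # --- stage: interactome --------------------------------------------------
    if all(k in cfg for k in ("ppi", "domains", "pairs")):
        ppi, domains, pairs = net.load_network_inputs(
            cfg["ppi"], cfg["domains"], cfg["pairs"]
        )
        edges = net.build_slim_interactome(ppi, domains, predicted, pairs)
        logger.info("interactome: %d of %d PPI edges SLiM-mediated",
                    len(edges), len(ppi))
        burden = {}
        for name in disease_names:
            burden[f"{name}_vs_{neutral}"] = net.interaction_burden_comparison(
                sorted(sites[name], key=lambda s: (s.accession, s.position)),
                sorted(sites[neutral], key=lambda s: (s.accession, s.position)),
                edges, tracks,
            )
        report.burden = burden
    else:
        edges = []

    # --- stage: candidate list ----------------------------------------------
    low_prob = {
        c.elm_id
        for c in classes
        if c.occurrence_probability is not None
        and c.occurrence_probability < cfg["probability_threshold"]
    }
    candidate_prots: set[str] = set()
    for name in disease_names:
        for call in calls[name]:
            for inst, verdict in call.per_instance:
                if (
                    verdict is ic.Verdict.BREAKING
                    and inst.provenance == "predicted"
                    and inst.elm_id in low_prob
                ):
                    candidate_prots.add(inst.accession)
    report.candidates = sorted(candidate_prots)

    # --- outputs -------------------------------------------------------------
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        me.write_instance_table(predicted, out / "instances.tsv")
        with open(out / "calls.tsv", "w", encoding="utf-8") as fh:
            fh.write(
                "#dataset\taccession\tposition\twt\tmut\telm_id\tstart\tend"
                "\tverdict\taggregate\n"
            )
            for name, cs in calls.items():
                for c in cs:
                    for inst, verdict in c.per_instance:
                        m = c.mutation
                        fh.write(
                            f"{name}\t{m.accession}\t{m.position}\t{m.wt_aa}"
                            f"\t{m.mut_aa}\t{inst.elm_id}\t{inst.start}"
                            f"\t{inst.end}\t{verdict.value}"
                            f"\t{c.aggregate.value}\n"
                        )
        net.write_edge_table(edges, out / "edges.tsv")
        with open(out / "candidates.txt", "w", encoding="utf-8") as fh:
            fh.writelines(f"{acc}\n" for acc in report.candidates)
        report.to_json(out / "report.json")
    return report
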
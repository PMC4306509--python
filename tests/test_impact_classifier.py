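import re

import pytest

import slimpact as sp
from slimpact.impact_classifier import Aggregate, Verdict


def _mut(acc, pos, wt, mut, dataset="somatic-cancer"):
    return sp.MutationRecord(acc, pos, wt, mut, dataset)


class TestApplyMissense:
    def test_substitution_and_revert(self):
        m = _mut("P", 6, "S", "F")
        out = sp.apply_missense("DSGIHS", m)
        assert out == "DSGIHF"
        assert sp.apply_missense(out, _mut("P", 6, "F", "S")) == "DSGIHS"

    def test_wt_mismatch_is_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            sp.apply_missense("DSGIHS", _mut("P", 6, "T", "F"))


class TestClassifyAgainstInstance:
    def test_degron_constrained_position_breaks(self, degron_protein, degron_class):
        (inst,) = sp.scan_protein(degron_protein, degron_class)
        verdict = sp.classify_against_instance(
            inst, degron_class, _mut(inst.accession, 34, "G", "R"),
            degron_protein.sequence,
        )
        assert verdict is Verdict.BREAKING

    def test_stat5_wildcard_position_conserves(self, stat5_class):
        rec = sp.ProteinRecord("P", "AYVQQW")
        (inst,) = sp.scan_protein(rec, stat5_class)
        verdict = sp.classify_against_instance(
            inst, stat5_class, _mut("P", 4, "Q", "R"), rec.sequence
        )
        assert verdict is Verdict.CONSERVING

    def test_stat5_within_degenerate_class_conserves(self, stat5_class):
        rec = sp.ProteinRecord("P", "AYVQQW")
        verdict = sp.classify_against_instance(
            sp.scan_protein(rec, stat5_class)[0],
            stat5_class,
            _mut("P", 3, "V", "L"),
            rec.sequence,
        )
        assert verdict is Verdict.CONSERVING

    def test_rgd_any_substitution_breaks(self, rgd_class):
        rec = sp.ProteinRecord("P", "ARGDW")
        (inst,) = sp.scan_protein(rec, rgd_class)
        verdict = sp.classify_against_instance(
            inst, rgd_class, _mut("P", 4, "D", "E"), rec.sequence
        )
        assert verdict is Verdict.BREAKING

    def test_mutation_outside_span_is_error(self, rgd_class):
        rec = sp.ProteinRecord("P", "ARGDW")
        (inst,) = sp.scan_protein(rec, rgd_class)
        with pytest.raises(ValueError, match="outside"):
            sp.classify_against_instance(
                inst, rgd_class, _mut("P", 5, "W", "A"), rec.sequence
            )

    def test_variable_length_flexibility_is_honored(self, degron_class):
        # DSGIHS followed by T: breaking S37 still leaves the 7-residue
        # span DSGIH?T matching, so the verdict is conserving
        rec = sp.ProteinRecord("P", "DSGIHST")
        inst = sp.scan_protein(rec, degron_class)[0]
        verdict = sp.classify_against_instance(
            inst, degron_class, _mut("P", 6, "S", "A"), rec.sequence
        )
        assert verdict is Verdict.CONSERVING

    def test_oracle_equivalence_fixed_length_classes(self, rng):
        """For fixed-length classes, conserving iff the pattern re-matches
        the mutated substring of the original span (brute force)."""
        aa = list(sp.AMINO_ACIDS)
        patterns = ["RGD", "Y[VLTFIC]..", "L.[^P]E", "[KR][KR].[ST]"]
        n_checked = 0
        while n_checked < 300:
            seq = "".join(rng.choice(aa, size=20))
            pattern = patterns[rng.integers(len(patterns))]
            cls = sp.MotifClass("T", "LIG", pattern)
            rec = sp.ProteinRecord("P", seq)
            instances = sp.scan_protein(rec, cls)
            if not instances:
                continue
            inst = instances[rng.integers(len(instances))]
            pos = int(rng.integers(inst.start, inst.end + 1))
            wt = seq[pos - 1]
            mut = aa[rng.integers(20)]
            if mut == wt:
                continue
            verdict = sp.classify_against_instance(
                inst, cls, _mut("P", pos, wt, mut), seq
            )
            mutated_span = (
                seq[inst.start - 1 : pos - 1] + mut + seq[pos : inst.end]
            )
            expected = (
                Verdict.CONSERVING
                if re.fullmatch(pattern, mutated_span)
                else Verdict.BREAKING
            )
            assert verdict is expected
            n_checked += 1

    def test_literal_always_breaks_and_wildcard_always_conserves(self, rng):
        aa = list(sp.AMINO_ACIDS)
        for _ in range(100):
            lit = aa[rng.integers(20)]
            cls = sp.MotifClass("T", "LIG", f"{lit}..")
            seq = lit + "".join(rng.choice(aa, size=5))
            rec = sp.ProteinRecord("P", seq)
            inst = sp.scan_protein(rec, cls)[0]
            other = aa[(aa.index(lit) + 1 + int(rng.integers(19))) % 20]
            if other == lit:
                continue
            assert (
                sp.classify_against_instance(
                    inst, cls, _mut("P", 1, lit, other), seq
                )
                is Verdict.BREAKING
            )
            wt2 = seq[1]
            mut2 = aa[rng.integers(20)]
            if mut2 != wt2:
                assert (
                    sp.classify_against_instance(
                        inst, cls, _mut("P", 2, wt2, mut2), seq
                    )
                    is Verdict.CONSERVING
                )


class TestAggregation:
    def test_single_breaking(self, rgd_class):
        rec = sp.ProteinRecord("P", "ARGDW")
        (inst,) = sp.scan_protein(rec, rgd_class)
        call = sp.classify_mutation(
            _mut("P", 4, "D", "E"), [(inst, rgd_class)], rec.sequence
        )
        assert call.aggregate is Aggregate.ONLY_BREAKING

    def test_overlapping_instances_give_both(self, rgd_class):
        # RGD overlaps a pattern that tolerates the substitution
        rec = sp.ProteinRecord("P", "ARGDW")
        tolerant = sp.MotifClass("TOL", "LIG", "G[DE]W")
        rgd_inst = sp.scan_protein(rec, rgd_class)[0]
        tol_inst = sp.scan_protein(rec, tolerant)[0]
        call = sp.classify_mutation(
            _mut("P", 4, "D", "E"),
            [(rgd_inst, rgd_class), (tol_inst, tolerant)],
            rec.sequence,
        )
        assert call.aggregate is Aggregate.BOTH

    def test_no_overlap_gives_none(self):
        call = sp.classify_mutation(_mut("P", 1, "A", "V"), [], "AW")
        assert call.aggregate is Aggregate.NONE


class TestSummary:
    def _call(self, aggregate):
        inst = sp.MotifInstance("P", "T", 1, 3, "RGD")
        verdicts = {
            Aggregate.ONLY_BREAKING: [(inst, Verdict.BREAKING)],
            Aggregate.ONLY_CONSERVING: [(inst, Verdict.CONSERVING)],
            Aggregate.BOTH: [
                (inst, Verdict.BREAKING),
                (sp.MotifInstance("P", "U", 2, 4, "GDW"), Verdict.CONSERVING),
            ],
            Aggregate.NONE: [],
        }[aggregate]
        return sp.ImpactCall(_mut("P", 2, "G", "R"), tuple(verdicts))

    def test_counts_and_percentages(self):
        calls = [self._call(Aggregate.ONLY_BREAKING)] * 2 + [
            self._call(Aggregate.ONLY_CONSERVING)
        ]
        row = sp.classification_summary({"d": calls})["d"]
        assert (row["only_breaking"], row["only_conserving"], row["both"]) == (2, 1, 0)
        assert (row["pct_only_breaking"], row["pct_only_conserving"]) == (66.7, 33.3)

    def test_empty_dataset_zero_row(self):
        row = sp.classification_summary({"d": []})["d"]
        assert row["n_mutations"] == 0 and row["pct_only_breaking"] == 0.0

    def test_none_calls_excluded(self):
        calls = [self._call(Aggregate.NONE), self._call(Aggregate.ONLY_BREAKING)]
        row = sp.classification_summary({"d": calls})["d"]
        assert row["n_mutations"] == 1

    def test_row_sums_conserved_under_split_and_merge(self, small_study):
        cfg = small_study.config
        calls = sp.classify_dataset(
            small_study.mutations["disease"],
            small_study.manifest,
            list(cfg.classes),
            small_study.proteome,
        )
        merged = sp.classification_summary({"all": calls})["all"]
        half = len(calls) // 2
        split = sp.classification_summary(
            {"x": calls[:half], "y": calls[half:]}
        )
        for key in ("n_mutations", "only_breaking", "only_conserving", "both"):
            assert split["x"][key] + split["y"][key] == merged[key]
        assert (
            merged["only_breaking"] + merged["only_conserving"] + merged["both"]
            == merged["n_mutations"]
        )
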
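"""Locate a phospho-degron and classify its recurrent cancer mutations.

Builds a small synthetic protein carrying the hexamer DSGIHS at residues
32-37 (the span the degron occupies in beta-catenin), scans it with the
SCF-betaTrCP degron pattern DSGx{2,3}[ST], and classifies the six
recurrently observed substitutions. Every one hits a constrained pattern
position, so every verdict is motif-breaking: each would abolish
recognition by the ubiquitin ligase and stabilise the protein.
"""

import slimpact as sp

sequence = "MATQADLMELWQQFEQLAEKNPHVVNKVELH" + "DSGIHS" + "AWQQTRNALEHAIQ"
protein = sp.ProteinRecord("CTNB1_SYN", sequence)

degron = sp.MotifClass(
    "DEG_SCF_TRCP1_1", "DEG",
    sp.normalize_pattern("DSGx{2,3}[ST]"),
    occurrence_probability=0.0003, raw_pattern="DSGx{2,3}[ST]",
)

(instance,) = sp.scan_protein(protein, degron)
print(f"degron instance: residues {instance.start}-{instance.end} "
      f"({instance.matched_seq})")

for pos, wt, mut in [(32, "D", "Y"), (33, "S", "F"), (33, "S", "C"),
                     (34, "G", "R"), (37, "S", "F"), (37, "S", "C")]:
    record = sp.MutationRecord(protein.accession, pos, wt, mut, "somatic-cancer")
    verdict = sp.classify_against_instance(instance, degron, record, sequence)
    print(f"  {wt}{pos}{mut}: {verdict.value}")

# A substitution at a wild-card position, by contrast, conserves the motif:
record = sp.MutationRecord(protein.accession, 35, "I", "L", "somatic-cancer")
print(f"  I35L (wild-card position): "
      f"{sp.classify_against_instance(instance, degron, record, sequence).value}")
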
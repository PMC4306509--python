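"""Generate a synthetic study and test within-motif site enrichment.

The generator plants motif instances in disordered tracts and oversamples
them threefold when drawing disease sites. The ordered-region table is
degenerate (planted motifs are never ordered), while the disordered-region
table recovers the planted enrichment: an odds ratio near 3 with a small
exact Fisher p-value.
"""

import slimpact as sp

config = sp.SyntheticStudyConfig(seed=42)
proteome, tracks, manifest = sp.generate_proteome_and_tracks(config)
mutations = sp.generate_mutations(config, proteome, manifest)

print(f"{len(proteome)} proteins, {len(manifest)} planted motif instances")
sites = {name: sp.collapse_sites(muts) for name, muts in mutations.items()}

results = sp.site_overlap_enrichment(
    sites["disease"], sites["neutral"], manifest, tracks,
    labels=("disease", "neutral"),
)
for region, res in results.items():
    table = res.table.to_array()
    if not res.testable:
        print(f"{region}: untestable (within-motif column empty)")
        continue
    print(f"{region}: table {table.tolist()}  "
          f"OR={res.odds_ratio:.2f}  p={res.p_value:.3g}")

# Per-RLC-bin view: only the bins holding the conserved planted motifs
# (mean RLC > 0.5 by construction) can show the disease excess.
for res in sp.rlc_binned_enrichment(
    manifest, sites["disease"], sites["neutral"], tracks,
    labels=("disease", "neutral"),
):
    if res.testable:
        print(f"  {res.stratum}: p={res.p_value:.3g}")
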
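# Methods

## The problem

Short linear motifs (SLiMs) are 3–10 residue peptide modules, found mostly
in intrinsically disordered regions (IDRs), that mediate cleavage,
modification, docking, ligand binding, targeting and degradation by being
recognised by a partner globular domain. Operationally a SLiM class is a
regular expression over the amino-acid alphabet: some positions are fixed
(`D`, `S`, `G` in the SCF-βTrCP degron `DSGx{2,3}[ST]`), some degenerate
(`[ST]`), some free (`x`). A missense mutation inside an instance either
leaves the pattern satisfiable — *motif-conserving* — or makes it
unsatisfiable — *motif-breaking*, abolishing recognition. `slimpact`
implements the full analysis around this idea: motif scanning and
filtering, impact classification, enrichment statistics, physicochemical
transition analysis, and a motif-mediated interactome with a per-site
interaction-burden comparison.

## Scanning and filtering

Scanning tests, at every start position, anchored full matches of every
feasible span length between the class's minimum and maximum width
(derived from the compiled pattern, clipped at the protein end). One
instance per (class, start) is reported — the longest matching span — a
choice that is non-destructive because the impact classifier re-tries all
feasible lengths anyway; instances at different starts may overlap freely.
`^`/`$` anchors refer to the protein termini. Unknown residues (`X`) never
satisfy a constrained position: positive classes and literals exclude `X`
naturally, and negated classes are rewritten `[^...]` → `[^X...]` at load;
only the explicit wildcard `.` accepts `X`.

Candidate instances carry the arithmetic mean of two per-residue score
tracks over their span: a disorder propensity in [0, 1] (IUPred-style;
values above 0.5 indicate likely disorder) and a relative local
conservation (RLC) score (positive = more conserved than the surrounding
sequence; observed range about −2.5 to 2). Predicted instances are kept
when mean disorder > 0.5 AND mean RLC > 0.5. Both cutoffs are strict
inequalities; a residue with disorder exactly 0.5 is classified ordered.

## Impact classification

A mutation overlapping an instance is re-matched with the class pattern
anchored at the instance's annotated start, trying all feasible span
lengths on the mutated sequence; if some span still fully matches, the
verdict is conserving, otherwise breaking. Anchoring at the instance start
(rather than asking whether the motif survives anywhere in the protein)
reflects that the question is about *this* instance's integrity. Because
instances can overlap, one mutation can break one instance and conserve
another; per-mutation aggregates are ONLY_BREAKING, ONLY_CONSERVING, BOTH,
or NONE (no overlap; excluded from summary tables). Classification
operates on unique mutations (accession, position, wt, mut); enrichment
operates on unique mutated sites (accession, position), counted once no
matter how many substitutions hit them. Phospho-primed positions are
matched as their unmodified residue; modification state is not modeled.

## Exact tests

The two-sided Fisher exact test uses the probability-mass criterion: under
the fixed-margin multivariate hypergeometric null, p is the summed
probability of all tables whose probability is at most that of the
observed table times (1 + 1e−7). The relative tolerance guards against
ties lost to floating-point rounding and matches the convention of the
standard statistical environments, which is what makes small printed
p-values (0.003, 0.023, 0.299 on 2×3 category tables) reproducible to the
printed digit. 2×2 tables are computed by direct hypergeometric summation;
general r×c tables by exhaustive enumeration over the free cells (a 2×3
table is a two-dimensional loop, entirely feasible at the count magnitudes
this analysis produces); tables whose enumeration would exceed ~5×10⁶
candidate tables fall back to a seeded Monte-Carlo estimate with an
add-one correction so p never reports exactly zero. A degenerate tested
margin (an empty row or column) returns p = 1 with a warning. The odds
ratio is the sample cross-product ratio, with the Haldane 0.5 correction
applied (and logged) only when a zero cell occurs. No multiple-testing
correction is applied anywhere — each p-value is reported raw, matching
how the underlying analysis presents them — and the pipeline report keeps
every p-value next to the table it came from.

The Wilcoxon rank-sum test is exact by enumeration when the smaller sample
has ≤ 8 observations and no ties occur, and otherwise uses the normal
approximation with midrank tie correction and continuity correction
(`scipy.stats.mannwhitneyu` provides exactly this contract; the test suite
checks it against an independent enumeration/permutation oracle).

## Enrichment constructions

*Region-stratified site enrichment.* Two mutation datasets are first
restricted to proteins mutated in both and containing at least one motif
instance (avoiding composition bias from non-shared proteins). Instances
are binned ordered/disordered by mean disorder; sites by their residue
disorder. Per region, a 2×2 table (dataset × within/outside motif) is
tested, where "within" requires the covering instance to belong to the
same region bin as the site.

*RLC-binned enrichment.* Instances are stratified by mean RLC into bins of
width 0.5 over [−2.5, 2] (configurable; the exact published intervals are
not recorded, so the default is a recorded choice). Sites are restricted
to disordered residues. For bin k the 2×2 compares, per dataset, sites
covered by a bin-k instance against sites covered by no instance at all.
Binning sites by their own residue RLC instead is degenerate whenever
motif residues and background occupy disjoint RLC ranges (as the synthetic
generator's ground truth does by design): every bin would be all-within or
all-outside. The chosen construction keeps one conservation property: the
within-motif column pools across bins to the unbinned within-motif count.

*Property transitions.* The 20 standard amino acids are partitioned under
six categorical schemes — charge (3 subclasses), hydropathy (3), polarity
(2), volume (5, ordered very small → very large), side-chain chemistry
(7), hydrogen donor/acceptor availability (4) — hard-coded as printed in
the underlying classification; no continuous scales are consulted. For a
mutation set, an N×N matrix counts wt-subclass → mut-subclass transitions;
the change fraction is the off-diagonal mass share. Dataset comparisons
are Fisher 2×2 on (dataset × change/no-change), and per-transition tests
compare Si→Sj against Si→(anything else) between datasets.

## Interactome and burden

A PPI edge (A, B) becomes SLiM-mediated when a motif instance on one
partner belongs to a class paired (in the known domain–motif pair table)
with a domain family annotated on the other partner. Matching is
identity-based on (class id, domain id); domain coordinates are metadata.
The network is undirected, one edge per unordered pair, with every
mediator recorded. A mutated site's interaction burden is the number of
*distinct* partner proteins reachable through mediator instances covering
the site — multiple mediators to one partner count once, and self-loop
mediators contribute no partner. Burden distributions are compared between
datasets restricted to disordered sites, as histograms normalized to
counts per 10 000 sites (so the heights of each dataset's histogram sum to
10 000) plus a two-sided rank-sum test on the raw per-site burdens.

## Synthetic study generator

The generator's purpose is a fully offline, seeded test bed whose ground
truth is known exactly, not realism. Design choices and defaults:

- **Proteome**: 40 proteins, lengths uniform on [300, 540] (mean 420),
  uniform residue composition. Small enough that a full study generates in
  ~0.1 s, large enough for ~16 800 residues.
- **Disorder**: a two-state tract model (alternating geometric run
  lengths; disordered mean tract 60 residues, disordered fraction 0.45).
  Disordered residues draw disorder scores from U(0.55, 0.98), ordered
  from U(0.02, 0.45). Since every consumer thresholds at 0.5, realism
  beyond the threshold would be wasted.
- **Planted motifs**: exact-match realizations of real ELM-style patterns
  (the SCF-βTrCP degron `DSGx{2,3}[ST]`, the STAT5 SH2 motif `Y[VLTFIC]xx`,
  the integrin-binding `RGD`, and a basophilic phosphosite motif
  `R[RK]x[ST]`), planted without mutual overlap inside disordered tracts
  at density 0.012 per disordered residue (~65 instances per study).
  Planted residues draw RLC from U(0.6, 1.6); background RLC from
  U(−2.0, 0.45), so the planted set is exactly what survives the default
  disorder/RLC filter.
- **Mutations**: 2 000 sites per dataset. Neutral sites are uniform over
  residues with substitutions uniform over the 19 alternatives. Disease
  sites multiply within-motif sampling odds by the configured odds ratio
  (default 3). Within motifs, with probability `breaking_bias` (default
  0.8) the substitution is drawn from the pattern-violating residues at
  that position; a draw landing on an unconstrained wild-card position is
  relocated to a constrained position of the same instance, which keeps
  the bias-1.0 guarantee (every biased draw classifies breaking) at the
  cost of a slight positional skew toward constrained residues.
- **Network**: 300 undirected edges, half mediated by construction (a
  planted instance's protein is connected to a partner annotated with the
  paired domain), partner choice Zipf-weighted (exponent 1) so hubs
  emerge; the remainder random.

What the generator does *not* emulate — realistic amino-acid composition,
mutational signatures, allele frequencies, correlated disorder predictors,
annotation noise in motif class definitions — bounds what passing tests
show: they demonstrate that the pipeline recovers planted effects of known
size under clean conditions and controls its type-I error, not that real
proteomes would yield any particular effect size.

Determinism: every draw flows from `numpy.random.default_rng(seed)` (with
fixed offsets separating the proteome, mutation and network stages), so a
bundle is bit-identical across runs and platforms for a given seed.

## Measured operating characteristics

Computed by `tests/test_acceptance.py` and `scripts/acceptance.py` at the
default study conditions above: detection of the planted within-motif
odds ratio 3 at α = 0.01 succeeded in 100/100 seeded studies (each with
≥ 500 disordered sites per dataset in the tested table); under the null
(odds ratio 1) rejection at α = 0.05 occurred in ≤ 5/100 studies; with
breaking bias 1.0, 100% of within-motif disease mutations classify as
breaking.

## Numerical and degenerate-input conventions

Coordinates are 1-based inclusive everywhere, including the BED-like
instance table (documented in its header line — explicitly not 0-based
half-open). Rejected mutation records (unknown accession, out-of-range
position, wild-type mismatch, silent substitution) are logged with
reasons, never silently dropped. Overlap percentages are computed values
rounded to one decimal (a source table that prints 81.5% where the quotient
rounds to 81.4% is reported as computed). Empty strata and degenerate
margins are flagged untestable rather than erroring. Multi-isoform
accessions are treated as independent sequences.

## Known limitations

- Occurrence probabilities are consumed from the class table, never
  estimated from amino-acid frequencies.
- Disorder and RLC scores are inputs; the predictors that produce them are
  out of scope, as are domain scanning (annotations are inputs) and
  pathway enrichment itself (the pipeline emits the filtered candidate
  protein list that a pathway tool would consume).
- The anchored re-match does not consider instance boundary shifts beyond
  the quantifier flexibility of the pattern; a mutation that destroys one
  instance while creating a new overlapping one elsewhere is still
  breaking for the annotated instance.
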
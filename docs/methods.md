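# Methods

This note documents the models, rules and numerical choices behind
`metanno`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the design was genuinely open.

## Preprocessing

Input contigs are FASTA records; the id is the first
whitespace-delimited header token, the rest of the line is kept as a
description. Ids must be pairwise distinct — a duplicate rejects the
whole input rather than silently renaming, because every downstream
join (evidence, depth, bins) keys on the id. Cleaning uppercases the
sequence, deletes gap (`-`) and pad (`*`) characters, and replaces
every remaining non-ACGT character with `N`; `U` is treated as
ambiguous because the declared alphabet is DNA. Cleaning is idempotent
and length-preserving up to the deleted characters. Contigs shorter
than `min_contig_len` (default 200 bp; the threshold is user-defined by
design) are removed; "shorter than" is strict everywhere — a sequence
exactly at the threshold is kept. Removed ids are listed in the
preprocessing report rather than discarded silently.

## Structural features

Coordinates are 1-based inclusive throughout (the GFF3 convention);
converters for 0-based half-open external tables must be explicit.

rRNA detection with per-domain-of-life HMMs produces competing hits
over the same locus. Conflict groups are the connected components of
the pairwise interval-overlap graph on each contig (overlap = ≥ 1
shared bp; strand is ignored, since the models are strand-resolved
upstream). Within a group only hits whose E-value equals the group
minimum survive; ties are exact equality of the parsed values, no
tolerance, and tied hits are all kept. Components are computed with a
start-sorted sweep, which is equivalent to BFS on the overlap graph;
the test suite pins this equivalence against an explicit pairwise
brute-force oracle, including planted exact ties. One consequence of
the component rule worth stating: a dropped hit is guaranteed to lose
to a strictly better hit *in its component*, which on transitive chains
need not be a hit it directly overlaps.

Resolved noncoding features (CRISPR, tRNA, rRNA) are masked by
replacing their spans with `N`; masking conserves length and all
positions outside the union of feature intervals. ORF calls are then
filtered at `min_orf_nt` (default 180 nt, the span including the stop
codon, applied to partial and complete ORFs alike), and any ORF lying
entirely inside a masked noncoding feature is discarded as artifactual.

rRNA genes are classified by their best pairwise hit against a
lineage-labelled reference, under the same best-hit key used for
protein taxonomy (below).

## Evidence merging

Pairwise hit tables are the 12-column `outfmt 6` layout; an optional
13th `qlen` column enables query coverage, computed as
100·(qend−qstart+1)/qlen. Domain tables are HMMER3 `--domtblout`:
target = the gene, query = the model, domain i-evalue is the
significance measure, alignment coordinates are on the gene.

The significance cutoff defaults to 1e−5 for both hit kinds (the
upstream tools publish no per-database cutoff; it is exposed per run).
Selection policy: pairwise sources keep their single best hit under the
lexicographic key (E-value, −bitscore, subject id) — the subject-id
tail makes selection invariant to input order; profile sources keep
every significant domain, including repeated domains of the same model
(a repeated 4Fe-4S domain is biology, not duplication).

Union fields follow the source ordering observed in real merged
records: `allec_ids` is protein-db-first then FOAM; `allko_ids` is
FOAM-first then protein-db; both are duplicate-free and order-stable.
GO terms union protein-db-derived and TIGRFAM-derived lists. FOAM model
names follow the `KO:K#####[_EC]*` grammar with comma-separated KO
alternatives; EC segments may carry `-` wildcards. The product name is
the protein-db best-hit description when present, else the first
significant domain description by priority TIGRFAM > Pfam > FOAM >
metabolic > cas; a gene with no functional evidence at all is
`hypothetical protein`. A gene whose only evidence is a genome-db
(taxonomy) hit is still hypothetical: taxonomic placement names no
function. Functional metadata that hit tables cannot carry (protein-db
EC/GO/KO per subject, TIGRFAM roles per model, FOAM KO→ontology
strings) comes from optional side tables and is simply absent
otherwise — merging never fabricates an identifier that appears in no
input.

Motif evidence (signal peptide presence, transmembrane-helix count) is
attached verbatim from ingested tables when the `--sp`/`--tm` toggles
are on; no prediction is performed.

## Taxonomy

Gene classification is the lineage of the single best significant
genome-database hit — deliberately not a lowest-common-ancestor of top
hits, which is noted as a plausible extension. Lineage strings are
rank-prefixed (`d__` … `s__`), must appear in canonical order without
gaps, and may terminate early.

The community profile is a weighted tree: each gene adds its per-sample
weight to every node on its lineage path; a gene with an empty lineage
adds to an explicit `unclassified` child of the root. Node weight
therefore equals the sum of child weights plus the weight assigned
exactly at that node, for every node and sample — the conservation
identity the tests check per node. Serialization orders children by
descending total weight then name, so ring layouts are deterministic;
serialize/deserialize is weight-lossless.

The MAG report computes, per rank, the plurality taxon (ties broken by
the lexicographically smallest name, for determinism) and the
discordant fraction 1 − plurality/classified, excluding genes
unclassified at that rank from the denominator. MAG extraction routes
records by their contig's bin; unbinned contigs go to an `unbinned`
pseudo-MAG and totals are conserved exactly.

## Minimal pathway reconstruction

The objective is parsimony: the minimum-cardinality set of pathways
whose members cover every observed family that belongs to at least one
pathway; families in no pathway are reported as `uncovered_families`,
never silently dropped. The exact solver enumerates candidate
combinations in ascending size and, within a size, in lexicographic id
order — the first cover found is therefore both minimum and the
lexicographically smallest id-set, making ties reproducible. Because
enumeration is exponential, `auto` mode uses it only when at most 20
pathways intersect the observed set (the threshold is a tunable) and
otherwise falls back to the classic greedy heuristic: repeatedly take
the pathway covering the most uncovered families, ties to the smallest
id. Greedy output is never smaller than exact output, which the suite
verifies, along with exact-solution cardinality against an independent
exhaustive subset-enumeration oracle on hundreds of random instances
(≤ 12 pathways, ≤ 30 families).

KEGG-style reconstruction keys on KO ids and MetaCyc-style on EC ids as
two independent runs. In EC mode an observed wildcard EC (`7.1.1.-`)
matches any member it agrees with on all specified fields. Per-pathway
fill = observed members / total members diagnoses how complete each
kept pathway is.

## Abundance

Depth input is the MetaBat `jgi_summarize_bam_contig_depths` dialect
(`contigName contigLen totalAvgDepth` plus per-sample mean/variance
column pairs); variance columns are parsed and discarded. Gene depth is
the contig's per-sample mean depth — no per-base recomputation, because
the input is per-contig. The default per-gene weight for profiles is
depth; `depth_x_len` (depth × gene span) and `count` are switches. A
gene mapping to several KOs contributes its full weight to each
(switchable to fractional splitting); the double-counting choice is
deliberate and documented rather than hidden. Pathway activity sums,
over each kept pathway's observed member families, the weights of the
genes supporting those families — a gene supporting two families of one
pathway counts once per family. Every profile column sums to 1 over its
rows including `unassigned`; a sample with zero total weight reports
zeros and is flagged rather than raising mid-pipeline. Spectral-count
weighting is identical with the gene-by-sample expression table; genes
absent from the table have zero expression. Count- and depth-weighted
profiles coincide when all depths are equal.

## Pipeline and determinism

Stages run in a fixed order and communicate only through files, so a
stage can be skipped whenever its recorded parameter hash (its own
settings chained with its upstream stage's hash) matches and its
outputs exist; changing e.g. `min_orf_nt` re-runs the structural stage
and everything downstream. All writers use fixed orderings and fixed
float formats (`%.4f` for depths/abundances, `%.1e` for E-values), so
identical inputs give byte-identical outputs and a resumed run is
byte-identical to a fresh one; the run log records skip/run decisions
and every threshold in effect, and is deliberately excluded from the
checksum manifest. The HTML index is a single static page linking the
emitted files and embedding the taxonomy/pathway JSON; interactive
tables, sunburst rendering and pathway-map highlighting are out of
scope — their data contracts (the JSON documents) are the supported
surface.

## The synthetic-data generator

The generator exists so the whole engine runs and is tested with no
reference databases, no search binaries and no downloads. One master
seed fans out to independent per-file streams, so every sub-fixture is
reproducible in isolation and byte-identical across runs.

What it plants, and how the pipeline recovers it:

* contigs with non-overlapping CRISPR/tRNA/rRNA/CDS intervals (a
  uniform variant places an exact CDS count per contig for designs
  needing exact gene counts);
* per-gene lineages over a configurable MAG set, with a contamination
  fraction q per MAG realized as round(q·n) off-lineage genes among the
  n genes long enough to survive the ORF filter — so the MAG report
  recovers q exactly whenever q·n is integral;
* genome-db evidence in which the true subject's E-value is drawn
  strictly below every decoy's, so best-hit classification is exact at
  any decoy rate; functional roles (protein-db / TIGRFAM / Pfam / FOAM
  / none) with matching metadata tables;
* rRNA model hits where the true domain model gets the lowest E-value
  over the planted locus;
* a pathway world whose minimum cover is unique by construction: every
  planted pathway owns at least one observed family private to it, so
  any cover must contain the whole planted set; decoy pathways hold
  only unobserved families; uniqueness is additionally verified by
  exhaustive enumeration at generation time for ≤ 12 pathways; one
  observed family belongs to no pathway, exercising the uncovered
  path;
* depths (lognormal across contigs, multiplicative lognormal replicate
  noise, values pre-rounded to the 4 decimals the dialect carries so
  files round-trip losslessly; `totalAvgDepth` is the per-sample sum)
  and spectral counts (Poisson jitter around a per-gene rate) for three
  replicate samples by default — zero noise makes replicates identical,
  which is what the replicate-similarity property checks.

What it does **not** emulate: sequence evolution and alignment (contigs
are i.i.d. random nucleotides; identities and scores are drawn, not
computed), read mapping, assembly or binning error beyond the planted
contamination, database bias, or realistic E-value distributions.
Passing tests therefore demonstrate that the engine's logic — parsing,
resolution, merging, aggregation, set cover, normalization, resume — is
correct under controlled truth, not that annotations of real data are
biologically accurate; that depends on the upstream searches and
databases the engine consumes.

## Problem sizes used in tests

The shared test fixture uses 8 contigs of 3–6 kb (≈ 30–40 genes, 2
MAGs, 3 samples); contamination-recovery designs use 2 MAGs × 100
genes; oracle equivalence uses 300 random set-cover instances and 1000
random rRNA hit sets. These sizes exercise every code path (ties,
decoys, orphan families, unclassified genes) while keeping the full
suite and the acceptance script each within a few seconds on one CPU.

## Known limitations

* Gene taxonomy is single-best-hit; no LCA, no placement.
* Exact set cover is enumeration-based and intended for the ≤ 20
  candidate regime the auto mode enforces; forcing `exact` on much
  larger instances is exponential.
* The EC wildcard rule treats `-` fields as agreeing in both observed
  and member codes; hierarchical EC semantics beyond field agreement
  are not modeled.
* Motif (signal peptide / transmembrane) evidence is ingested, never
  predicted.
* Spectral counts are assumed pre-normalized; no normalization is
  applied.
* Eukaryote-aware gene calling, viral contig handling and
  transcriptomics weighting are out of scope.
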
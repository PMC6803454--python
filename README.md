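# metanno

A metagenome annotation engine for assembled contigs and
metagenome-assembled genomes (MAGs). It covers the annotation steps that
come *after* the external search tools have run: cleaning and validating
contigs, resolving competing rRNA model hits and masking noncoding
features, merging multi-database search evidence into one record per
gene, classifying every gene taxonomically and flagging chimeric MAGs,
reconstructing a parsimony-minimal pathway set, and quantifying taxa,
functions and pathways per sample from sequencing depth or metaproteome
spectral counts.

It is written for people who already have contigs plus search outputs in
standard dialects — BLAST/DIAMOND `outfmt 6` tabular hits, HMMER3
`--domtblout` domain tables, MetaBat `jgi_summarize_bam_contig_depths`
depth files, gene-by-sample spectral-count tables — and want a
deterministic, resumable way to turn them into per-gene, per-MAG and
community-level annotation reports. The search binaries themselves are
out of scope; only their output formats are consumed. A bundled
synthetic-data generator emits every input dialect with planted ground
truth, so the whole engine is testable with no reference databases.

## The methods at the core

**rRNA conflict resolution.** Profile HMMs from all three domains of
life can hit the same genomic region. Overlapping hits (≥ 1 shared bp,
grouped as connected components of the overlap graph per contig) are
resolved by keeping only the hit(s) with the lowest E-value; exact
E-value ties keep all best predictions. Resolved noncoding features
(CRISPR, tRNA, rRNA) are masked with `N`s before protein-coding genes
are considered, and ORFs shorter than 180 nt are excluded by default.

**Evidence merging.** Pairwise sources (a SwissProt-style protein
database, a lineage-labelled genome database) contribute their single
best hit under the key (E-value, −bitscore, subject id); profile sources
(Pfam, TIGRFAM, FOAM, metabolic HMMs, cas genes) contribute every
significant domain, repeats included. Per gene, `allec_ids` is the
ordered duplicate-free union of protein-db and FOAM EC numbers,
`allko_ids` of FOAM and protein-db KO accessions. Genes with no
functional evidence become `hypothetical protein`.

**Taxonomy and contamination.** Each gene takes the GTDB-style lineage
(`d__;p__;c__;o__;f__;g__;s__`) of its best genome-database hit.
Lineages aggregate into a weighted taxon tree (one sunburst ring per
rank; node weight = Σ weights of genes passing through; explicit
`unclassified` children keep every ring a partition). Per MAG and rank,
the report gives the plurality taxon and the discordant fraction
1 − plurality/classified — high values flag chimeric bins.

**Minimal pathways.** Given observed gene families (KOs, or ECs with
`-` wildcards) and pathway→members definitions, the reconstruction
selects a minimum-cardinality pathway set covering every coverable
family (set cover, the MinPath parsimony objective): exact by
size-ascending lexicographic enumeration on small instances, classic
greedy above 20 candidate pathways.

**Abundance.** Genes inherit their contig's per-sample mean depth;
category weight = Σ gene weights; relative abundances sum to 1 per
sample over all rows including `unassigned`. Spectral-count weighting
works the same way with genes absent from the proteome table at zero.

## Worked example

`examples/02_merge_evidence.py` merges one gene's evidence — a perfect
protein-db hit, a FOAM domain named `KO:K00390_1.8.4.8`, two repeated
Pfam `Fer4` domains, and a genome-db hit mapped to a *Cupriavidus*
lineage:

```
product:     NADH-quinone oxidoreductase subunit I
allec_ids:   7.1.1.-; 1.8.4.8
allko_ids:   K00390; K00338
genomedb_oc: d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Betaproteobacteriales;f__Burkholderiaceae;g__Cupriavidus;
pfam domains retained: 2
```

The product comes from the protein-db description; the EC union lists
the protein-db EC before the FOAM EC while the KO union is FOAM-first;
both repeated Pfam segments are retained. The other example scripts each
demonstrate one capability (preprocessing/masking, contamination
detection, minimal pathways, abundance profiles, the full pipeline) and
print a line or two explaining their numbers.

## Command line

```sh
metanno fixtures inputs/ --seed 17      # synthetic input set + truth.json
metanno run inputs/ -o annotated/       # full pipeline, resumable stages
metanno extract-mag annotated/master.tsv inputs/binmap.tsv -o mags/
metanno profile assignments.tsv --depth inputs/depth.txt -o profile.tsv
```

`run` executes preprocess → structural → homology-merge → taxonomy →
pathways → abundance → reports, persisting every stage's outputs.
Restarting with the same parameters skips completed stages; changing a
parameter re-runs that stage and everything downstream. All outputs are
byte-deterministic.

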
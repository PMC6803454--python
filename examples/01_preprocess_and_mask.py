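"""Clean raw contigs, resolve competing rRNA model hits, and mask
noncoding features before gene calling.

Three raw sequences go in: one with ambiguity codes and gaps, one too
short to keep, one clean. Two rRNA models hit the same region of the
kept contig; only the lower-E-value model survives, and its span is
masked with Ns so no protein-coding gene can be called on top of it.
"""
from metanno.seqprep import RawSequenceRecord, preprocess
from metanno.structural import RrnaModelHit, mask_regions, resolve_model_hits

records = [
    RawSequenceRecord("contig_a", "", "ACGT" * 120 + "RYKM-ACGT**" + "ACGT" * 20),
    RawSequenceRecord("contig_b", "", "ACGTACGT"),  # below min length
    RawSequenceRecord("contig_c", "", "ACGT" * 100),
]
result = preprocess(records, min_len=200)
print(f"kept {len(result.contigs)} of {len(records)} contigs "
      f"({result.n_removed} below 200 bp)")
contig = result.contigs[0]
print(f"{contig.id}: {contig.length} bp, Ns after cleaning: "
      f"{contig.sequence.count('N')} (ambiguity codes became N)")

hits = [
    RrnaModelHit("contig_a", "Bacteria", "16S", 50, 450, "+", 1e-40, 210.0),
    RrnaModelHit("contig_a", "Archaea", "16S", 60, 440, "+", 1e-12, 95.0),
]
resolved = resolve_model_hits(hits)
print(f"rRNA models hitting the same region: {len(hits)}; kept after "
      f"lowest-E-value resolution: {len(resolved)} ({resolved[0].domain_model})")

masked = mask_regions(contig, [resolved[0].to_feature()])
print(f"masked contig still {masked.length} bp; masked positions: "
      f"{masked.sequence.count('N') - contig.sequence.count('N')}")
# The masked span equals the resolved rRNA gene length, so downstream ORF
# calls cannot overlap the rRNA gene.
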
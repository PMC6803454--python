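"""Merge multi-database search evidence into one per-gene record.

A gene with a perfect protein-database hit, a FOAM domain carrying a KO
and an EC, two repeated Pfam domains, and a lineage-labelled genome-db
hit. The merged record unions EC/KO ids across sources (protein db first
for EC, FOAM first for KO), takes the product name from the best
protein-db hit, and the taxonomy from the best genome-db hit.
"""
from metanno.homology import (
    DomainHit, EvidenceBundle, PairwiseHit, SprotMeta, merge_evidence,
)
from metanno.structural import OrfCall

gene = OrfCall("demo|1", "contig_1", 1000, 1491, "+")
bundle = EvidenceBundle(
    gene.gene_id,
    sprot=[PairwiseHit(gene.gene_id, "sp|Q1LPV5|NUOI_CUPMC", 100.0, 163, 0, 0,
                       1, 163, 1, 163, 4.1e-65, 300.0, qlen=163)],
    genomedb=[PairwiseHit(gene.gene_id, "GCA_900185755.1|FYAX01000037.1_317",
                          100.0, 163, 0, 0, 1, 163, 1, 163, 1.4e-89, 400.0, qlen=163)],
    domains={
        "FOAM": [DomainHit(gene.gene_id, "HMMsoil748", "KO:K00390_1.8.4.8",
                           "FOAM", 2.5e-13, 41.9, 47.9, 63, 117)],
        "Pfam": [
            DomainHit(gene.gene_id, "PF00037.27", "Fer4", "Pfam",
                      2e-07, 24.1, 53.6, 61, 80, "4Fe-4S binding domain"),
            DomainHit(gene.gene_id, "PF00037.27", "Fer4", "Pfam",
                      5.5e-11, 35.4, 53.6, 97, 118, "4Fe-4S binding domain"),
        ],
    },
)
sprot_meta = {
    "sp|Q1LPV5|NUOI_CUPMC": SprotMeta(
        "NADH-quinone oxidoreductase subunit I", ("7.1.1.-",),
        ("GO:0005886", "GO:0051539"), ("K00338",),
    )
}
refmap = {
    "GCA_900185755.1|FYAX01000037.1_317":
        "d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;"
        "o__Betaproteobacteriales;f__Burkholderiaceae;g__Cupriavidus;"
}
rec = merge_evidence(gene, bundle, sprot_meta, refmap=refmap)
print("product:    ", rec.product)
print("allec_ids:  ", "; ".join(rec.allec_ids))   # protein-db EC first
print("allko_ids:  ", "; ".join(rec.allko_ids))   # FOAM KO first
print("genomedb_oc:", rec.genomedb_oc)
print("pfam domains retained:", len(rec.pfam_target.split("; ")))
# Both repeated Fer4 segments are kept: profile sources contribute every
# significant domain, pairwise sources only their single best hit.
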
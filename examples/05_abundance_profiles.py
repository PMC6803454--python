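"""Depth-weighted relative-abundance profiles.

Parses a MetaBat-dialect depth file, attaches each gene its contig's
per-sample mean depth, and builds a genus-level profile whose columns
sum to 1 per sample. A second profile uses spectral counts instead,
weighting only the genes detected in the proteome.
"""
import tempfile
from pathlib import Path

from metanno.abundance import (
    attach_gene_depth, parse_depth, parse_spectral, profile_to_frame, weighted_profile,
)
from metanno.homology import AnnotationRecord

with tempfile.TemporaryDirectory() as tmp:
    d = Path(tmp)
    (d / "depth.txt").write_text(
        "contigName\tcontigLen\ttotalAvgDepth\ts1\ts1-var\ts2\ts2-var\n"
        "c1\t50000\t120.0000\t82.0316\t3.0\t37.9684\t2.0\n"
        "c2\t20000\t30.0000\t10.0000\t1.0\t20.0000\t1.5\n"
    )
    (d / "plevel.txt").write_text(
        "gene_id\ts1\ts2\nc1|g1\t14.0\t16.0\nc2|g3\t6.0\t4.0\n"
    )
    depth = parse_depth(d / "depth.txt")
    spectral = parse_spectral(d / "plevel.txt")

records = [
    AnnotationRecord(id="c1|g1", contigid="c1", genomedb_oc="g__Cupriavidus"),
    AnnotationRecord(id="c1|g2", contigid="c1", genomedb_oc="g__Cupriavidus"),
    AnnotationRecord(id="c2|g3", contigid="c2", genomedb_oc="g__Bacillus"),
]
attach_gene_depth(records, depth)
print("per-gene depths:", {r.id: r.depth for r in records})

taxa = {r.id: r.genomedb_oc for r in records}
pm = weighted_profile(taxa, {r.id: r.depth for r in records})
print("\ndepth-weighted genus profile (columns sum to 1):")
print(profile_to_frame(pm).to_string(index=False))

sw = {r.id: spectral.gene_weights(r.id) for r in records}
pm_sp = weighted_profile(taxa, sw)
print("\nspectral-count (proteome) profile — c1|g2 was not detected, so it")
print("contributes nothing here even though it has sequencing depth:")
print(profile_to_frame(pm_sp).to_string(index=False))
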
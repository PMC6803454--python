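"""Final report writers: GFF3, feature FASTA, master annotation table,
profile tables, hierarchical JSON and a minimal static HTML index.

All writers are deterministic: identical inputs produce byte-identical
outputs (fixed row ordering, %.4f for depths/abundances, %.1e for
E-values). Determinism is what makes stage resume and diffing meaningful.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from urllib.parse import quote, unquote

import pandas as pd

from .errors import ParseError
from .structural import FeatureInterval
from .homology import AnnotationRecord

# GFF3 reserves ; = & , and % inside attribute values
_GFF3_SAFE = " !\"#$'()*+-./:<>?@[]^_`{|}~"


def _enc(v: str) -> str:
    return quote(str(v), safe=_GFF3_SAFE)


@dataclass
class ReportBundle:
    """Paths of every emitted report file plus a checksum manifest."""

    outdir: Path
    files: dict = field(default_factory=dict)  # label -> Path
    stage_hashes: dict = field(default_factory=dict)

    def add(self, label: str, path: str | Path) -> Path:
        p = Path(path)
        self.files[label] = p
        return p

    def manifest(self) -> dict:
        entries = {}
        for label, p in sorted(self.files.items()):
            digest = hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None
            entries[label] = {"path": p.name, "sha256": digest}
        return {"files": entries, "stage_hashes": dict(sorted(self.stage_hashes.items()))}

    def write_manifest(self, path: str | Path | None = None) -> Path:
        p = Path(path) if path else self.outdir / "manifest.json"
        p.write_text(json.dumps(self.manifest(), indent=1, sort_keys=True) + "\n")
        return p


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(
    path: str | Path,
    features: Sequence[FeatureInterval],
    records: Mapping[str, AnnotationRecord] | None = None,
) -> None:
    """Write features as GFF3 (1-based inclusive, percent-encoded attrs).

    CDS features whose ``ID`` attribute matches an annotation record also
    carry product, allec_ids, allko_ids and genomedb_oc attributes.
    """
    records = records or {}
    lines = ["##gff-version 3"]
    for f in sorted(features, key=lambda x: (x.contig_id, x.start, x.end, x.ftype)):
        attrs = dict(f.attributes)
        fid = attrs.get("ID")
        if fid and fid in records:
            rec = records[fid]
            attrs["product"] = rec.product
            if rec.allec_ids:
                attrs["allec_ids"] = ";".join(rec.allec_ids)
            if rec.allko_ids:
                attrs["allko_ids"] = ";".join(rec.allko_ids)
            if rec.genomedb_oc:
                attrs["genomedb_oc"] = rec.genomedb_oc
        if f.subtype and "subtype" not in attrs:
            attrs["subtype"] = f.subtype
        attr_s = ";".join(f"{_enc(k)}={_enc(v)}" for k, v in attrs.items()) or "."
        lines.append(
            "\t".join(
                [
                    f.contig_id, "metanno", f.ftype,
                    str(f.start), str(f.end), ".", f.strand, ".", attr_s,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[FeatureInterval]:
    """Read a GFF3 file back into feature intervals (test support; inverse
    of :func:`write_gff3` on its own output). Unknown attributes are kept
    verbatim."""
    path = Path(path)
    feats = []
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise ParseError(f"expected 9 GFF3 columns, got {len(f)}", path, line_no)
        try:
            start, end = int(f[3]), int(f[4])
        except ValueError:
            raise ParseError("non-integer coordinate", path, line_no) from None
        attrs = {}
        if f[8] != ".":
            for pair in f[8].split(";"):
                if not pair:
                    continue
                k, _, v = pair.partition("=")
                attrs[unquote(k)] = unquote(v)
        subtype = attrs.get("subtype", "")
        feats.append(FeatureInterval(f[0], start, end, f[6], f[2], subtype, attrs))
    return feats


# ---------------------------------------------------------------------------
# master annotation table

MASTER_COLUMNS = [
    "id", "contigid", "start", "end", "strand", "product",
    "allec_ids", "allko_ids", "allko_ontology", "go_terms",
    "sprot_desc", "sprot_ec", "sprot_go", "sprot_kos", "sprot_target",
    "pfam_id", "pfam_desc", "pfam_target",
    "tigrfam_id", "tigrfam_desc", "tigrfam_go", "tigrfam_mainrole",
    "tigrfam_sub1role", "tigrfam_target",
    "foam_kos", "foam_ecs", "foam_target",
    "metabolic_target", "casgene_target",
    "genomedb_oc", "genomedb_target", "sp", "tm_num",
]

_LIST_FIELDS = {
    "allec_ids", "allko_ids", "go_terms", "sprot_ec", "sprot_go", "sprot_kos",
    "pfam_id", "pfam_desc", "tigrfam_id", "tigrfam_desc", "tigrfam_go",
    "foam_kos", "foam_ecs",
}


def write_master_table(
    path: str | Path,
    records: Sequence[AnnotationRecord],
    samples: Sequence[str] = (),
) -> None:
    """One row per gene, one column per annotation tag; multi-valued fields
    are ';'-joined; per-sample depth columns appended; rows ordered by
    (contig, start, id)."""
    rows = []
    for rec in sorted(records, key=lambda r: (r.contigid, r.start, r.id)):
        row = {}
        for col in MASTER_COLUMNS:
            v = getattr(rec, col)
            row[col] = ";".join(v) if col in _LIST_FIELDS else v
        for s in samples:
            row[f"depth_{s}"] = f"{rec.depth.get(s, 0.0):.4f}"
        rows.append(row)
    cols = MASTER_COLUMNS + [f"depth_{s}" for s in samples]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_master_table(path: str | Path) -> pd.DataFrame:
    """Parse the master table back (lists stay ';'-joined strings)."""
    return pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)


# ---------------------------------------------------------------------------
# feature FASTA

def write_feature_fasta(
    path: str | Path,
    contigs: Mapping[str, str],
    features: Sequence[FeatureInterval],
    id_attr: str = "ID",
) -> None:
    """Extract feature nucleotide sequences (.ffn); '-' strand features are
    reverse-complemented."""
    from Bio.Seq import Seq

    lines = []
    for f in sorted(features, key=lambda x: (x.contig_id, x.start, x.end)):
        seq = contigs[f.contig_id][f.start - 1 : f.end]
        if f.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        fid = f.attributes.get(id_attr) or f"{f.contig_id}:{f.start}-{f.end}"
        lines.append(f">{fid} {f.ftype} {f.contig_id}:{f.start}-{f.end}({f.strand})")
        for i in range(0, len(seq), 60):
            lines.append(seq[i : i + 60])
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# JSON + HTML

def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>annotation summary</title></head>
<body>
<h1>Annotation summary</h1>
<ul>
{links}
</ul>
{json_blocks}
</body>
</html>
"""


def write_html_index(bundle: ReportBundle, embed: Mapping[str, object] | None = None) -> Path:
    """Write a single static index page linking every emitted file and
    embedding the taxonomy/profile JSON documents (no interactive JS).
    Sections for absent optional outputs are simply omitted."""
    links = "\n".join(
        f'<li><a href="{p.name}">{label}</a></li>'
        for label, p in sorted(bundle.files.items())
        if p.exists()
    )
    blocks = []
    for name, obj in sorted((embed or {}).items()):
        blocks.append(
            f"<h2>{name}</h2>\n"
            f'<script type="application/json" id="{name}">\n'
            + json.dumps(obj, indent=1, sort_keys=True)
            + "\n</script>"
        )
    path = bundle.outdir / "index.html"
    path.write_text(_HTML_TEMPLATE.format(links=links, json_blocks="\n".join(blocks)))
    bundle.add("index", path)
    return path
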
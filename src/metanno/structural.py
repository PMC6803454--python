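"""Structural features: CRISPR/tRNA/rRNA/ORF calls, rRNA model-hit
resolution, noncoding-feature masking, and ORF length filtering.

Feature callers for a metagenome may be run with rRNA HMMs from all three
domains of life, so several models can hit the same genomic region. Within
each group of mutually overlapping hits on a contig only the hit(s) with
the lowest E-value survive; exact E-value ties keep all best predictions.
Detected noncoding features are then masked with Ns so that downstream
protein-coding gene calls cannot overlap them, and ORFs shorter than a
nucleotide threshold (default 180 nt) are excluded.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import CoordinateError, MissingSubjectError, OutOfBoundsError, ParseError
from .seqprep import CleanContig

FEATURE_TYPES = frozenset({"CRISPR", "tRNA", "rRNA", "CDS"})
RRNA_DOMAINS = frozenset({"Bacteria", "Archaea", "Eukaryota"})
RRNA_TYPES = frozenset({"5S", "5.8S", "16S", "18S", "23S", "28S"})

#: Default minimum ORF length in nucleotides (stop codon included).
DEFAULT_MIN_ORF_NT = 180


@dataclass
class FeatureInterval:
    """A located feature on a contig, 1-based inclusive coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str  # '+', '-' or '.'
    ftype: str
    subtype: str = ""
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise CoordinateError(
                f"invalid interval [{self.start},{self.end}] on {self.contig_id}"
            )
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "FeatureInterval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class RrnaModelHit:
    """One rRNA HMM hit from one domain-of-life model."""

    contig_id: str
    domain_model: str
    rna_type: str
    start: int
    end: int
    strand: str
    evalue: float
    score: float

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise CoordinateError(
                f"invalid rRNA hit [{self.start},{self.end}] on {self.contig_id}"
            )
        if not (self.evalue > 0 and self.evalue == self.evalue):
            raise ValueError("evalue must be finite and positive")

    def to_feature(self) -> FeatureInterval:
        return FeatureInterval(
            self.contig_id,
            self.start,
            self.end,
            self.strand,
            "rRNA",
            self.rna_type,
            {
                "domain_model": self.domain_model,
                "evalue": repr(self.evalue),
                "score": repr(self.score),
            },
        )


@dataclass
class OrfCall:
    """A predicted protein-coding gene on a contig."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    partial_5: bool = False
    partial_3: bool = False

    @property
    def nt_length(self) -> int:
        return self.end - self.start + 1


def resolve_model_hits(hits: Sequence[RrnaModelHit]) -> list[RrnaModelHit]:
    """Resolve competing rRNA model hits to the same region.

    Overlap groups are connected components of the pairwise interval-overlap
    graph on each contig (>= 1 shared bp; strand is ignored — the models are
    strand-resolved upstream). Within a group, only hits whose E-value
    equals the group minimum are kept; equal E-values keep every best hit.
    Output sorted by (contig_id, start).
    """
    kept: list[RrnaModelHit] = []
    by_contig: dict[str, list[RrnaModelHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    for contig_hits in by_contig.values():
        contig_hits.sort(key=lambda h: (h.start, h.end))
        # sweep: a new group starts when the next hit begins past the
        # rightmost end seen so far (components of the overlap graph)
        group: list[RrnaModelHit] = []
        max_end = -1
        for h in contig_hits:
            if group and h.start > max_end:
                kept.extend(_filter_group(group))
                group = []
                max_end = -1
            group.append(h)
            max_end = max(max_end, h.end)
        if group:
            kept.extend(_filter_group(group))
    kept.sort(key=lambda h: (h.contig_id, h.start, h.end))
    return kept


def _filter_group(group: list[RrnaModelHit]) -> list[RrnaModelHit]:
    best = min(h.evalue for h in group)
    return [h for h in group if h.evalue == best]


def mask_regions(
    contig: CleanContig, features: Sequence[FeatureInterval]
) -> CleanContig:
    """Replace every position covered by a feature with 'N'.

    Length is conserved; positions outside the union of intervals are
    unchanged. Raises :class:`OutOfBoundsError` if a feature exceeds the
    contig bounds.
    """
    seq = list(contig.sequence)
    n = len(seq)
    for f in features:
        if f.contig_id != contig.id:
            continue
        if f.end > n:
            raise OutOfBoundsError(
                f"feature [{f.start},{f.end}] exceeds contig {contig.id} length {n}"
            )
        for i in range(f.start - 1, f.end):
            seq[i] = "N"
    return CleanContig(contig.id, "".join(seq), contig.description)


def filter_orfs(
    orfs: Sequence[OrfCall], min_nt: int = DEFAULT_MIN_ORF_NT
) -> list[OrfCall]:
    """Exclude ORFs shorter than ``min_nt`` nucleotides (strict <)."""
    if min_nt < 0:
        raise ValueError("min_nt must be >= 0")
    return [o for o in orfs if o.nt_length >= min_nt]


# ---------------------------------------------------------------------------
# ingestion of feature-call tables (MinCED/ARAGORN-style TSV, or GFF3)

_TSV_FTYPE_ALIASES = {
    "crispr": "CRISPR",
    "repeat_region": "CRISPR",
    "trna": "tRNA",
    "rrna": "rRNA",
    "cds": "CDS",
}


def ingest_feature_table(path: str | Path, ftype: str | None = None) -> list[FeatureInterval]:
    """Read structural feature calls from a TSV or GFF3 file.

    The TSV dialect is ``contig_id  start  end  strand  subtype`` with
    optional trailing ``key=value`` attribute pairs; 1-based inclusive
    coordinates. Files whose first data line starts with ``##gff-version``
    (or a ``.gff``/``.gff3`` suffix) are read as GFF3. When ``ftype`` is
    given, it overrides/validates the feature kind of every row.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".gff", ".gff3"} or text.startswith("##gff-version"):
        from .reports import read_gff3

        feats = read_gff3(path)
        if ftype is not None:
            feats = [f for f in feats if f.ftype == ftype]
        return feats
    feats = []
    for line_no, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 5:
            raise ParseError(
                f"expected >= 5 tab-separated columns, got {len(fields)}",
                path,
                line_no,
            )
        contig_id, start_s, end_s, strand, subtype = fields[:5]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError("non-integer coordinate", path, line_no) from None
        attrs = {}
        for extra in fields[5:]:
            if "=" in extra:
                k, v = extra.split("=", 1)
                attrs[k] = v
        row_ftype = ftype
        if row_ftype is None:
            key = subtype.split("-")[0].lower()
            row_ftype = _TSV_FTYPE_ALIASES.get(key, _TSV_FTYPE_ALIASES.get(subtype.lower()))
            if row_ftype is None and subtype in RRNA_TYPES:
                row_ftype = "rRNA"
            if row_ftype is None:
                raise ParseError(f"cannot infer feature type from {subtype!r}", path, line_no)
        try:
            feats.append(
                FeatureInterval(contig_id, start, end, strand, row_ftype, subtype, attrs)
            )
        except CoordinateError as exc:
            raise CoordinateError(f"{exc} (line {line_no} of {path})") from None
    return feats


def read_orf_table(path: str | Path) -> list[OrfCall]:
    """Read ORF calls from a TSV: gene_id, contig_id, start, end, strand
    [, partial_5, partial_3]."""
    path = Path(path)
    orfs = []
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 5:
            raise ParseError(f"expected >= 5 columns, got {len(f)}", path, line_no)
        try:
            start, end = int(f[2]), int(f[3])
        except ValueError:
            raise ParseError("non-integer coordinate", path, line_no) from None
        if end < start:
            raise CoordinateError(f"end < start at line {line_no} of {path}")
        p5 = len(f) > 5 and f[5] in ("1", "true", "True")
        p3 = len(f) > 6 and f[6] in ("1", "true", "True")
        orfs.append(OrfCall(f[0], f[1], start, end, f[4], p5, p3))
    return orfs


def read_rrna_model_hits(path: str | Path) -> list[RrnaModelHit]:
    """Read rRNA model hits from a TSV:
    contig_id, domain_model, rna_type, start, end, strand, evalue, score."""
    path = Path(path)
    hits = []
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 8:
            raise ParseError(f"expected 8 columns, got {len(f)}", path, line_no)
        try:
            hits.append(
                RrnaModelHit(f[0], f[1], f[2], int(f[3]), int(f[4]), f[5],
                             float(f[6]), float(f[7]))
            )
        except ValueError as exc:
            raise ParseError(str(exc), path, line_no) from None
    return hits


def classify_rrna(gene: FeatureInterval, hits, refmap: Mapping[str, object]):
    """Classify a detected rRNA gene by its best pairwise hit.

    ``hits`` are :class:`~metanno.homology.PairwiseHit` objects restricted
    to this gene's query id; the winning subject is looked up in ``refmap``
    (subject_id -> lineage). Returns the unclassified (empty) lineage when
    there are no hits.
    """
    from .homology import select_best_hit
    from .taxonomy import Lineage

    best = select_best_hit(hits)
    if best is None:
        return Lineage.empty()
    if best.subject_id not in refmap:
        raise MissingSubjectError(best.subject_id)
    lin = refmap[best.subject_id]
    return lin if isinstance(lin, Lineage) else Lineage.parse(str(lin))
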
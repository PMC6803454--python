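"""Similarity-search parsing and per-gene evidence merging.

Two evidence dialects are ingested: 12/13-column pairwise tabular hits
(the BLAST/DIAMOND ``outfmt 6`` layout, optionally extended with a query
length column) and HMMER3 per-domain tables (``--domtblout``). Evidence
from every source — a SwissProt-style protein database, a lineage-labelled
genome database, and profile-HMM collections (Pfam, TIGRFAM, FOAM,
metabolic HMMs, cas genes) — is merged into one annotation record per
gene. Pairwise sources contribute their single best hit; profile sources
contribute every significant domain. A gene with no evidence at all is a
"hypothetical protein".
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import GrammarError, ParseError
from .structural import OrfCall

#: Default significance cutoff applied to pairwise E-values and to domain
#: i-evalues alike (the underlying searches publish no per-database cutoff).
DEFAULT_MAX_EVALUE = 1e-5

DOMAIN_DBS = ("Pfam", "TIGRFAM", "FOAM", "MetabolicHMM", "CasGene")

HYPOTHETICAL = "hypothetical protein"


@dataclass
class PairwiseHit:
    """One line of 12/13-column tabular pairwise search output."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: Optional[int] = None

    @property
    def qcov(self) -> Optional[float]:
        """Query coverage in %, available only when qlen was supplied."""
        if self.qlen is None or self.qlen == 0:
            return None
        return 100.0 * (self.qend - self.qstart + 1) / self.qlen


@dataclass
class DomainHit:
    """One domain line of a HMMER3 ``--domtblout`` table."""

    query_id: str
    model_id: str
    model_name: str
    db_tag: str
    evalue: float  # i-evalue of the domain
    dom_score: float
    seq_score: float
    ali_from: int
    ali_to: int
    description: str = ""


@dataclass
class SprotMeta:
    """Per-subject functional metadata for the protein reference database."""

    description: str = ""
    ecs: tuple = ()
    gos: tuple = ()
    kos: tuple = ()


@dataclass
class TigrfamMeta:
    """Per-model role metadata for TIGRFAM-style HMMs."""

    description: str = ""
    gos: tuple = ()
    mainrole: str = ""
    sub1role: str = ""


@dataclass
class EvidenceBundle:
    """All search evidence gathered for one gene."""

    gene_id: str
    sprot: list = field(default_factory=list)
    genomedb: list = field(default_factory=list)
    domains: dict = field(default_factory=dict)  # db_tag -> list[DomainHit]
    motifs: dict = field(default_factory=dict)  # e.g. {'sp': 'YES', 'tm_num': 3}

    def is_empty(self) -> bool:
        return not (self.sprot or self.genomedb or any(self.domains.values()))


@dataclass
class AnnotationRecord:
    """The merged per-gene annotation (tag/value schema)."""

    id: str
    contigid: str
    start: int = 0
    end: int = 0
    strand: str = "."
    product: str = HYPOTHETICAL
    allec_ids: list = field(default_factory=list)
    allko_ids: list = field(default_factory=list)
    allko_ontology: str = ""
    go_terms: list = field(default_factory=list)
    sprot_desc: str = ""
    sprot_ec: list = field(default_factory=list)
    sprot_go: list = field(default_factory=list)
    sprot_kos: list = field(default_factory=list)
    sprot_target: str = ""
    pfam_id: list = field(default_factory=list)
    pfam_desc: list = field(default_factory=list)
    pfam_target: str = ""
    tigrfam_id: list = field(default_factory=list)
    tigrfam_desc: list = field(default_factory=list)
    tigrfam_go: list = field(default_factory=list)
    tigrfam_mainrole: str = ""
    tigrfam_sub1role: str = ""
    tigrfam_target: str = ""
    foam_kos: list = field(default_factory=list)
    foam_ecs: list = field(default_factory=list)
    foam_target: str = ""
    metabolic_target: str = ""
    casgene_target: str = ""
    genomedb_oc: str = ""
    genomedb_target: str = ""
    depth: dict = field(default_factory=dict)  # sample -> depth
    sp: str = ""
    tm_num: str = ""


# ---------------------------------------------------------------------------
# parsers

def parse_tabular_hits(path: str | Path) -> list[PairwiseHit]:
    """Parse 12-column tabular pairwise hits; a 13th column is read as qlen."""
    path = Path(path)
    hits = []
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) not in (12, 13):
            raise ParseError(f"expected 12 or 13 columns, got {len(f)}", path, line_no)
        try:
            hits.append(
                PairwiseHit(
                    f[0], f[1], float(f[2]), int(f[3]), int(f[4]), int(f[5]),
                    int(f[6]), int(f[7]), int(f[8]), int(f[9]),
                    float(f[10]), float(f[11]),
                    int(f[12]) if len(f) == 13 else None,
                )
            )
        except ValueError:
            raise ParseError("non-numeric field", path, line_no) from None
    return hits


def parse_domain_table(path: str | Path, db_tag: str) -> list[DomainHit]:
    """Parse a HMMER3 ``--domtblout`` file.

    Column layout (whitespace-separated, per-domain lines): target (the
    gene) in column 1, query model name/accession in columns 4/5, domain
    i-evalue in column 13, domain score in 14, alignment coordinates on the
    target in columns 18-19; the free-text model description is the tail.
    Repeated domains of the same model on one gene are all retained.
    """
    path = Path(path)
    hits = []
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split()
        if len(f) < 22:
            raise ParseError(f"expected >= 22 columns, got {len(f)}", path, line_no)
        model_id = f[4] if f[4] != "-" else f[3]
        try:
            hits.append(
                DomainHit(
                    query_id=f[0],
                    model_id=model_id,
                    model_name=f[3],
                    db_tag=db_tag,
                    evalue=float(f[12]),
                    dom_score=float(f[13]),
                    seq_score=float(f[7]),
                    ali_from=int(f[17]),
                    ali_to=int(f[18]),
                    description=" ".join(f[22:]),
                )
            )
        except ValueError:
            raise ParseError("malformed numeric field", path, line_no) from None
    return hits


def load_sprot_meta(path: str | Path) -> dict[str, SprotMeta]:
    """Load subject metadata: subject_id, description, ECs, GOs, KOs
    (';'-separated lists, empty allowed)."""
    meta = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 5:
            raise ParseError(f"expected 5 columns, got {len(f)}", Path(path), line_no)
        split = lambda s: tuple(x for x in s.split(";") if x)
        meta[f[0]] = SprotMeta(f[1], split(f[2]), split(f[3]), split(f[4]))
    return meta


def load_tigrfam_meta(path: str | Path) -> dict[str, TigrfamMeta]:
    """Load model role metadata: model_id, description, GOs, mainrole, sub1role."""
    meta = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 5:
            raise ParseError(f"expected 5 columns, got {len(f)}", Path(path), line_no)
        gos = tuple(x for x in f[2].split(";") if x)
        meta[f[0]] = TigrfamMeta(f[1], gos, f[3], f[4])
    return meta


# ---------------------------------------------------------------------------
# selection and filtering

def select_best_hit(hits: Sequence[PairwiseHit]) -> Optional[PairwiseHit]:
    """The hit minimizing (evalue, -bitscore, subject_id); None when empty."""
    if not hits:
        return None
    return min(hits, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))


def significance_filter(hits: Iterable, max_evalue: float = DEFAULT_MAX_EVALUE) -> list:
    """Keep hits with evalue <= max_evalue (works for both hit kinds)."""
    if not max_evalue > 0:
        raise ValueError("max_evalue must be > 0")
    return [h for h in hits if h.evalue <= max_evalue]


_FOAM_RE = re.compile(r"^KO:(?P<body>.+)$")


def parse_foam_name(model_name: str) -> tuple[list[str], list[str]]:
    """Split a FOAM model name into its KO and EC accessions.

    Grammar: ``KO:K#####[_EC]*`` where comma-separated segments give
    alternative KOs, and ``_``-joined trailing segments that look like EC
    numbers (possibly '-'-wildcarded) are enzyme codes.
    """
    m = _FOAM_RE.match(model_name.strip())
    if not m:
        raise GrammarError(f"FOAM model name lacks 'KO:' prefix: {model_name!r}")
    kos: list[str] = []
    ecs: list[str] = []
    for alt in m.group("body").split(","):
        alt = alt[3:] if alt.startswith("KO:") else alt
        for seg in alt.split("_"):
            if not seg:
                continue
            if re.fullmatch(r"K\d+", seg):
                if seg not in kos:
                    kos.append(seg)
            elif re.fullmatch(r"[\d-]+(\.[\w-]+){1,3}", seg):
                if seg not in ecs:
                    ecs.append(seg)
            else:
                raise GrammarError(f"unrecognized FOAM name segment {seg!r} in {model_name!r}")
    return kos, ecs


# ---------------------------------------------------------------------------
# target-string formatting (the per-source evidence summary strings)

def _fmt_pairwise_target(db: str, h: PairwiseHit) -> str:
    s = f"db:{db}|{h.subject_id} {h.qstart} {h.qend} evalue:{h.evalue:.1e}"
    if h.qcov is not None:
        s += f" qcov:{h.qcov:.2f}"
    s += f" identity:{h.pct_identity:.2f}"
    return s


def _fmt_domain_target(db: str, h: DomainHit) -> str:
    return (
        f"db:{db}|{h.model_id} {h.ali_from} {h.ali_to} "
        f"evalue:{h.evalue:.1e} score:{h.dom_score:.1f} seqT:{h.seq_score:.1f} "
        f"name:{h.model_name}"
    )


def _ordered_union(*lists: Iterable[str]) -> list[str]:
    out: list[str] = []
    for lst in lists:
        for x in lst:
            if x not in out:
                out.append(x)
    return out


# ---------------------------------------------------------------------------
# the merge

def merge_evidence(
    gene: OrfCall,
    bundle: EvidenceBundle,
    sprot_meta: Mapping[str, SprotMeta] | None = None,
    tigrfam_meta: Mapping[str, TigrfamMeta] | None = None,
    ko_ontology: Mapping[str, str] | None = None,
    refmap: Mapping[str, object] | None = None,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> AnnotationRecord:
    """Combine all search results for one gene into an annotation record.

    Pairwise sources (protein db, genome db) contribute their single best
    significant hit; profile sources contribute every significant domain.
    ``allec_ids`` is the ordered duplicate-free union protein-db-first then
    FOAM; ``allko_ids`` is FOAM-first then protein-db. The product name
    comes from the protein-db best hit description when present, otherwise
    from the first significant domain by priority TIGRFAM > Pfam > FOAM,
    otherwise the gene is a hypothetical protein.
    """
    sprot_meta = sprot_meta or {}
    tigrfam_meta = tigrfam_meta or {}
    rec = AnnotationRecord(
        id=gene.gene_id, contigid=gene.contig_id,
        start=gene.start, end=gene.end, strand=gene.strand,
    )
    if bundle.motifs:
        rec.sp = str(bundle.motifs.get("sp", ""))
        rec.tm_num = str(bundle.motifs.get("tm_num", ""))

    # protein reference database: best significant hit
    sprot_best = select_best_hit(significance_filter(bundle.sprot, max_evalue))
    if sprot_best is not None:
        meta = sprot_meta.get(sprot_best.subject_id, SprotMeta())
        rec.sprot_desc = meta.description
        rec.sprot_ec = list(meta.ecs)
        rec.sprot_go = list(meta.gos)
        rec.sprot_kos = list(meta.kos)
        rec.sprot_target = _fmt_pairwise_target("uniprot_sprot", sprot_best)

    # lineage-labelled genome database: best significant hit
    gdb_best = select_best_hit(significance_filter(bundle.genomedb, max_evalue))
    if gdb_best is not None:
        rec.genomedb_target = _fmt_pairwise_target("genomedb", gdb_best)
        if refmap is not None and gdb_best.subject_id in refmap:
            rec.genomedb_oc = str(refmap[gdb_best.subject_id])

    # profile sources: all significant domains, repeats retained
    def sig_domains(tag: str) -> list[DomainHit]:
        return significance_filter(bundle.domains.get(tag, []), max_evalue)

    pfam = sig_domains("Pfam")
    if pfam:
        rec.pfam_id = _ordered_union(h.model_name for h in pfam)
        rec.pfam_desc = _ordered_union(h.description for h in pfam if h.description)
        rec.pfam_target = "; ".join(_fmt_domain_target("Pfam-A.hmm", h) for h in pfam)

    tigr = sig_domains("TIGRFAM")
    if tigr:
        descs, gos, ids = [], [], []
        mainrole = sub1role = ""
        for h in tigr:
            meta = tigrfam_meta.get(h.model_id, TigrfamMeta(description=h.description))
            name = meta.description or h.description
            if name and name not in descs:
                descs.append(name)
            gos = _ordered_union(gos, meta.gos)
            if not mainrole and meta.mainrole:
                mainrole, sub1role = meta.mainrole, meta.sub1role
            if h.model_name not in ids:
                ids.append(h.model_name)
        rec.tigrfam_id = ids
        rec.tigrfam_desc = descs
        rec.tigrfam_go = gos
        rec.tigrfam_mainrole = mainrole
        rec.tigrfam_sub1role = sub1role
        rec.tigrfam_target = "; ".join(
            _fmt_domain_target("TIGRFAMs.hmm", h) for h in tigr
        )

    foam = sig_domains("FOAM")
    foam_desc = ""
    if foam:
        kos: list[str] = []
        ecs: list[str] = []
        for h in foam:
            k, e = parse_foam_name(h.model_name)
            kos = _ordered_union(kos, k)
            ecs = _ordered_union(ecs, e)
        rec.foam_kos = kos
        rec.foam_ecs = ecs
        rec.foam_target = "; ".join(
            _fmt_domain_target("FOAM-hmm_rel1a.hmm", h) for h in foam
        )
        foam_desc = foam[0].description or foam[0].model_name

    metabolic = sig_domains("MetabolicHMM")
    if metabolic:
        rec.metabolic_target = "; ".join(
            _fmt_domain_target("metabolic.hmm", h) for h in metabolic
        )
    casgene = sig_domains("CasGene")
    if casgene:
        rec.casgene_target = "; ".join(
            _fmt_domain_target("casgenes.hmm", h) for h in casgene
        )

    # union fields: EC is protein-db-first; KO is FOAM-first
    rec.allec_ids = _ordered_union(rec.sprot_ec, rec.foam_ecs)
    rec.allko_ids = _ordered_union(rec.foam_kos, rec.sprot_kos)
    rec.go_terms = _ordered_union(rec.sprot_go, rec.tigrfam_go)
    if ko_ontology is not None:
        for ko in rec.allko_ids:
            if ko in ko_ontology:
                rec.allko_ontology = ko_ontology[ko]
                break

    # product naming: protein db, else TIGRFAM > Pfam > FOAM, else hypothetical
    if rec.sprot_desc:
        rec.product = rec.sprot_desc
    elif rec.tigrfam_desc:
        rec.product = rec.tigrfam_desc[0]
    elif rec.pfam_desc:
        rec.product = rec.pfam_desc[0]
    elif rec.pfam_id:
        rec.product = rec.pfam_id[0]
    elif foam_desc:
        rec.product = foam_desc
    elif metabolic:
        rec.product = metabolic[0].description or metabolic[0].model_name
    elif casgene:
        rec.product = casgene[0].description or casgene[0].model_name
    else:
        rec.product = HYPOTHETICAL
    return rec
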
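"""Deterministic synthetic-data generator with planted ground truth.

Generates every input dialect the annotation engine consumes — contig
FASTA, structural-feature call tables, rRNA model-hit tables, pairwise and
domain-table search evidence, lineage reference maps, pathway definitions,
MetaBat-dialect depth files and spectral-count tables — from a single
master seed, together with a ``truth.json`` describing what was planted:
per-gene lineages, a per-MAG contamination fraction q, a pathway world
with a provably unique minimum cover, and per-sample depths/spectral
counts. Zero-noise settings make every planted parameter exactly
recoverable by the pipeline, which is what the property tests exploit.

The generator emulates the *shape* of real data (dialects, id schemes,
plausible E-value ordering), not sequence evolution: contigs are i.i.d.
random nucleotides and hit scores are drawn, not computed from alignments.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import InfeasibleDensityError
from .seqprep import CleanContig, write_fasta
from .structural import FeatureInterval, OrfCall, RrnaModelHit

_BASES = np.array(list("ACGT"))

# feature length ranges (bp)
_TRNA_LEN = (72, 90)
_RRNA_LEN = (900, 1500)
_CRISPR_LEN = (150, 350)
_CDS_LEN = (180, 900)
_SHORT_CDS_LEN = (90, 179)

_RNA_DOMAINS = ("Bacteria", "Archaea", "Eukaryota")


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Per-file child stream of the master seed."""
    return np.random.default_rng([int(seed), *map(int, stream)])


@dataclass
class FixtureSet:
    """Paths of all generated files plus the planted truth."""

    outdir: Path
    truth: dict
    paths: dict = field(default_factory=dict)

    def path(self, label: str) -> Path:
        return self.paths[label]


# ---------------------------------------------------------------------------
# contigs + structural features

def gen_contigs(
    seed: int,
    n_contigs: int = 6,
    length_range: tuple = (3000, 6000),
    feature_density: float = 1.0,
    short_orf_fraction: float = 0.1,
    outdir: str | Path | None = None,
):
    """Generate random contigs with non-overlapping planted features.

    ``feature_density`` scales how tightly features are packed (0 = none;
    > 5 is rejected as infeasible — inter-feature gaps would vanish).
    Returns (contigs, features, orfs, truth). When ``outdir`` is given,
    writes ``contigs.fna``, ``features.tsv`` (CRISPR+tRNA), ``orfs.tsv``,
    ``rrna_model_hits.tsv`` companion truth and a truth GFF3.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if feature_density > 5:
        raise InfeasibleDensityError(
            f"feature_density {feature_density} leaves no room between features"
        )
    rng = _rng(seed, 1)
    contigs: list[CleanContig] = []
    features: list[FeatureInterval] = []
    orfs: list[OrfCall] = []
    gene_serial = 0
    for ci in range(n_contigs):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        cid = f"ctg{ci + 1:03d}"
        seq = "".join(rng.choice(_BASES, size=length))
        contigs.append(CleanContig(cid, seq))
        if feature_density <= 0:
            continue
        mean_gap = max(10, int(200 / feature_density))
        pos = 1 + int(rng.integers(10, mean_gap))
        while True:
            r = rng.random()
            if r < 0.62:
                ftype = "CDS"
                if rng.random() < short_orf_fraction:
                    flen = int(rng.integers(*_SHORT_CDS_LEN))
                else:
                    flen = int(rng.integers(_CDS_LEN[0] // 3, _CDS_LEN[1] // 3)) * 3
                subtype = ""
            elif r < 0.80:
                ftype, subtype = "tRNA", f"tRNA-{rng.choice(list('AGLVST'))}"
                flen = int(rng.integers(*_TRNA_LEN))
            elif r < 0.90:
                ftype = "rRNA"
                subtype = str(rng.choice(["16S", "23S", "5S"]))
                flen = int(rng.integers(*_RRNA_LEN)) if subtype != "5S" else 120
            else:
                ftype, subtype = "CRISPR", "CRISPR"
                flen = int(rng.integers(*_CRISPR_LEN))
            end = pos + flen - 1
            if end > length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            if ftype == "CRISPR":
                strand = "."
            if ftype == "CDS":
                gene_serial += 1
                gid = f"{cid}|{gene_serial}"
                orfs.append(OrfCall(gid, cid, pos, end, strand))
                features.append(
                    FeatureInterval(cid, pos, end, strand, "CDS", "", {"ID": gid})
                )
            else:
                features.append(FeatureInterval(cid, pos, end, strand, ftype, subtype))
            pos = end + 1 + int(rng.integers(5, mean_gap))
    truth = {
        "seed": int(seed),
        "contigs": {c.id: {"length": c.length} for c in contigs},
        "features": [
            {
                "contig_id": f.contig_id, "start": f.start, "end": f.end,
                "strand": f.strand, "ftype": f.ftype, "subtype": f.subtype,
            }
            for f in features
        ],
        "orfs": [
            {
                "gene_id": o.gene_id, "contig_id": o.contig_id,
                "start": o.start, "end": o.end, "strand": o.strand,
            }
            for o in orfs
        ],
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(contigs, outdir / "contigs.fna")
        _write_feature_tsv(
            outdir / "features.tsv",
            [f for f in features if f.ftype in ("CRISPR", "tRNA")],
        )
        _write_orf_tsv(outdir / "orfs.tsv", orfs)
        from .reports import write_gff3

        write_gff3(outdir / "truth_features.gff3", features)
    return contigs, features, orfs, truth


def _write_feature_tsv(path: Path, features: Sequence[FeatureInterval]) -> None:
    lines = [
        "\t".join([f.contig_id, str(f.start), str(f.end), f.strand, f.subtype or f.ftype])
        for f in features
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _write_orf_tsv(path: Path, orfs: Sequence[OrfCall]) -> None:
    lines = [
        "\t".join([o.gene_id, o.contig_id, str(o.start), str(o.end), o.strand])
        for o in orfs
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# taxonomy planting

def _mag_lineage(i: int) -> str:
    return (
        f"d__Bacteria;p__Phylum{i};c__Class{i};o__Order{i};"
        f"f__Family{i};g__Genus{i};s__Genus{i} species{i}"
    )


def gen_uniform_contigs(
    seed: int,
    n_contigs: int,
    orfs_per_contig: int,
    orf_len: int = 300,
    gap: int = 50,
    outdir: str | Path | None = None,
):
    """Contigs holding exactly ``orfs_per_contig`` CDS features each.

    Used when exact per-MAG gene counts matter (e.g. planting an exactly
    recoverable contamination fraction q). All ORFs exceed the default
    length filter. Returns (contigs, features, orfs, truth) like
    :func:`gen_contigs`.
    """
    rng = _rng(seed, 11)
    contigs, features, orfs = [], [], []
    gene_serial = 0
    length = gap + orfs_per_contig * (orf_len + gap)
    for ci in range(n_contigs):
        cid = f"ctg{ci + 1:03d}"
        contigs.append(CleanContig(cid, "".join(rng.choice(_BASES, size=length))))
        pos = gap + 1
        for _ in range(orfs_per_contig):
            end = pos + orf_len - 1
            gene_serial += 1
            gid = f"{cid}|{gene_serial}"
            strand = "+" if rng.random() < 0.5 else "-"
            orfs.append(OrfCall(gid, cid, pos, end, strand))
            features.append(
                FeatureInterval(cid, pos, end, strand, "CDS", "", {"ID": gid})
            )
            pos = end + 1 + gap
    truth = {
        "seed": int(seed),
        "contigs": {c.id: {"length": c.length} for c in contigs},
        "features": [
            {
                "contig_id": f.contig_id, "start": f.start, "end": f.end,
                "strand": f.strand, "ftype": f.ftype, "subtype": f.subtype,
            }
            for f in features
        ],
        "orfs": [
            {
                "gene_id": o.gene_id, "contig_id": o.contig_id,
                "start": o.start, "end": o.end, "strand": o.strand,
            }
            for o in orfs
        ],
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(contigs, outdir / "contigs.fna")
        _write_feature_tsv(outdir / "features.tsv", [])
        _write_orf_tsv(outdir / "orfs.tsv", orfs)
    return contigs, features, orfs, truth


def plant_taxonomy(
    truth: dict,
    seed: int,
    mag_qs: Sequence[float] = (0.0, 0.25),
    min_orf_nt: int = 180,
) -> dict:
    """Assign contigs to MAGs and genes to lineages with planted
    contamination.

    Contigs are dealt round-robin to ``len(mag_qs)`` MAGs. Only genes long
    enough to survive the default ORF length filter are classified (short
    ORFs stay unclassified, so the planted fraction is measured on exactly
    the genes the pipeline retains). Within each MAG, ``round(q * n)`` of
    its n classifiable genes are assigned the lineage of another MAG; the
    realized fraction round(q*n)/n is stored as ``q_realized`` and equals
    q whenever q*n is integral.
    """
    rng = _rng(seed, 2)
    n_mags = len(mag_qs)
    mags = [f"MAG{i + 1:02d}" for i in range(n_mags)]
    lineages = {mags[i]: _mag_lineage(i + 1) for i in range(n_mags)}
    contig_mag = {}
    for i, cid in enumerate(sorted(truth["contigs"])):
        contig_mag[cid] = mags[i % n_mags]
    orf_nt = {
        o["gene_id"]: o["end"] - o["start"] + 1 for o in truth["orfs"]
    }
    genes: dict[str, dict] = {}
    per_mag: dict[str, list] = {m: [] for m in mags}
    for orf in truth["orfs"]:
        mag = contig_mag[orf["contig_id"]]
        per_mag[mag].append(orf["gene_id"])
    realized = {}
    for mi, mag in enumerate(mags):
        gids = per_mag[mag]
        eligible = [g for g in gids if orf_nt[g] >= min_orf_nt]
        n_off = int(round(mag_qs[mi] * len(eligible)))
        contaminants = set(eligible[:n_off])
        other_mags = [m for m in mags if m != mag] or [mag]
        for gid in gids:
            if gid in contaminants:
                src = other_mags[int(rng.integers(len(other_mags)))]
                genes[gid] = {
                    "mag": mag, "lineage": lineages[src], "contaminant": True,
                }
            elif gid in eligible:
                genes[gid] = {
                    "mag": mag, "lineage": lineages[mag], "contaminant": False,
                }
            else:
                genes[gid] = {"mag": mag, "lineage": "", "contaminant": False}
        realized[mag] = n_off / len(eligible) if eligible else 0.0
    truth = dict(truth)
    truth["mags"] = {
        mag: {
            "lineage": lineages[mag],
            "q": float(mag_qs[i]),
            "q_realized": realized[mag],
            "n_genes": len(per_mag[mag]),
        }
        for i, mag in enumerate(mags)
    }
    truth["contig_mag"] = contig_mag
    truth["genes"] = genes
    return truth


# ---------------------------------------------------------------------------
# evidence

_ROLES = ("sprot_foam", "sprot", "tigrfam", "pfam", "foam", "none")
_ROLE_P = (0.25, 0.2, 0.15, 0.15, 0.1, 0.15)

_DOMTBL_FMT = (
    "{gene} - {tlen} {name} {acc} {mlen} {fE:.1e} {fscore:.1f} 0.1 1 1 "
    "{cE:.1e} {iE:.1e} {dscore:.1f} 0.0 1 {mlen} {afrom} {ato} {afrom} {ato} "
    "0.90 {desc}"
)


def gen_evidence(
    truth: dict,
    seed: int,
    identity_noise: float = 0.0,
    decoy_rate: float = 0.0,
    outdir: str | Path | None = None,
) -> dict:
    """Generate search-evidence files matching the planted truth.

    Every classified gene receives one genome-database best hit to a
    subject carrying its true lineage, with an E-value strictly lower than
    any decoy hit (decoys are added per gene at rate ``decoy_rate`` and
    point at other lineages). Functional roles (protein-db / TIGRFAM /
    Pfam / FOAM / none) are planted per gene; role "none" genes end up as
    hypothetical proteins. ``identity_noise`` lowers percent identities
    without changing hit ranking.
    """
    rng = _rng(seed, 3)
    mags = sorted(truth["mags"])
    lineage_of = {m: truth["mags"][m]["lineage"] for m in mags}
    subj_of = {m: f"GCF_{i + 1:06d}.1|S1_1" for i, m in enumerate(mags)}
    refmap = {subj_of[m]: lineage_of[m] for m in mags}
    # extra decoy subjects per MAG
    decoy_subj = {m: f"GCF_{i + 1:06d}.1|S1_2" for i, m in enumerate(mags)}
    refmap.update({decoy_subj[m]: lineage_of[m] for m in mags})

    orf_len = {
        o["gene_id"]: (o["end"] - o["start"] + 1) // 3 for o in truth["orfs"]
    }
    genes = truth["genes"]
    gene_ids = [o["gene_id"] for o in truth["orfs"]]

    genomedb_lines = []
    sprot_lines = []
    dom_lines: dict[str, list] = {
        "pfam": [], "tigrfam": [], "foam": [], "metabolic": [], "casgene": [],
    }
    sprot_meta_rows = []
    tigrfam_meta_rows = []
    ko_serial = 0
    for gi, gid in enumerate(gene_ids):
        info = genes[gid]
        aa = max(orf_len.get(gid, 60), 30)
        ident = max(40.0, 100.0 - identity_noise * float(rng.random()) * 40.0)
        # --- taxonomy evidence
        if info["lineage"]:
            mag_src = next(m for m in mags if lineage_of[m] == info["lineage"])
            true_e = 10.0 ** -float(rng.uniform(60, 90))
            genomedb_lines.append(_pairwise_line(
                gid, subj_of[mag_src], ident, aa, true_e, 200.0 + aa, aa))
            n_decoys = int(rng.poisson(decoy_rate)) if decoy_rate > 0 else 0
            for _ in range(n_decoys):
                other = mags[int(rng.integers(len(mags)))]
                decoy_e = 10.0 ** -float(rng.uniform(6, 40))
                genomedb_lines.append(_pairwise_line(
                    gid, decoy_subj[other], ident * 0.8, aa, decoy_e, 80.0, aa))
        # --- functional evidence
        role = _ROLES[int(rng.choice(len(_ROLES), p=_ROLE_P))]
        info["role"] = role
        kos: list[str] = []
        ecs: list[str] = []
        if role in ("sprot_foam", "sprot"):
            ko_serial += 1
            sko = f"K{10000 + ko_serial:05d}"
            sec = f"{1 + ko_serial % 6}.{1 + ko_serial % 4}.1.{1 + ko_serial % 9}"
            subj = f"sp|P{10000 + gi:05d}|PROT_{gi}"
            e = 10.0 ** -float(rng.uniform(40, 70))
            sprot_lines.append(_pairwise_line(gid, subj, ident, aa, e, 150.0 + aa, aa))
            sprot_meta_rows.append(
                (subj, f"planted protein {gi}", sec, f"GO:{7000000 + gi}", sko)
            )
            kos.append(sko)
            ecs.append(sec)
            info["product"] = f"planted protein {gi}"
        if role in ("sprot_foam", "foam"):
            ko_serial += 1
            fko = f"K{20000 + ko_serial:05d}"
            fec = f"{1 + ko_serial % 6}.{8 - ko_serial % 4}.4.{1 + ko_serial % 8}"
            name = f"KO:{fko}_{fec}"
            e = 10.0 ** -float(rng.uniform(10, 25))
            dom_lines["foam"].append(_domtbl_line(
                gid, name, f"HMMsoil{700 + gi}", e, 40.0, aa, rng,
                desc="planted FOAM family"))
            kos.insert(0, fko) if role == "sprot_foam" else kos.append(fko)
            ecs.append(fec)
            info.setdefault("product", "planted FOAM family")
        if role == "tigrfam":
            model = f"TIGR{1000 + gi:05d}"
            e = 10.0 ** -float(rng.uniform(20, 50))
            dom_lines["tigrfam"].append(_domtbl_line(
                gid, f"Name{gi}", model, e, 120.0, aa, rng,
                desc=f"planted TIGR role {gi}"))
            tigrfam_meta_rows.append(
                (model, f"planted TIGR role {gi}", f"GO:{8000000 + gi}",
                 "Energy metabolism", "Electron transport")
            )
            info["product"] = f"planted TIGR role {gi}"
        if role == "pfam":
            e = 10.0 ** -float(rng.uniform(6, 15))
            # a repeated domain now and then, both lines retained downstream
            n_dom = 2 if rng.random() < 0.3 else 1
            for _ in range(n_dom):
                dom_lines["pfam"].append(_domtbl_line(
                    gid, f"Fam{gi}", f"PF{10000 + gi:05d}.1", e, 30.0, aa, rng,
                    desc=f"planted Pfam domain {gi}"))
            info["product"] = f"planted Pfam domain {gi}"
        if role == "none":
            info["product"] = "hypothetical protein"
        info["kos"] = kos
        info["ecs"] = ecs

    # rRNA model hits: per planted rRNA feature, one hit per domain of
    # life over the same region; the true domain gets the lowest E-value
    rrna_lines = []
    rrna_truth = []
    for f in truth["features"]:
        if f["ftype"] != "rRNA":
            continue
        true_dom = str(rng.choice(_RNA_DOMAINS, p=[0.6, 0.2, 0.2]))
        base_e = 10.0 ** -float(rng.uniform(30, 60))
        n_models = int(rng.integers(1, 4))
        doms = [true_dom] + [d for d in _RNA_DOMAINS if d != true_dom][: n_models - 1]
        for k, dom in enumerate(doms):
            e = base_e if k == 0 else base_e * 10.0 ** float(rng.uniform(3, 10))
            jitter = int(rng.integers(0, 30))
            rrna_lines.append("\t".join([
                f["contig_id"], dom, f["subtype"],
                str(f["start"] + (jitter if k else 0)),
                str(f["end"] - (jitter if k else 0)),
                f["strand"], f"{e:.3e}", f"{100 + 10 * (len(doms) - k):.1f}",
            ]))
        rrna_truth.append({**f, "true_domain": true_dom, "evalue": base_e})
    truth["rrna_model_truth"] = rrna_truth

    truth["refmap"] = refmap
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "genomedb.tsv").write_text(_join(genomedb_lines))
        (outdir / "sprot.tsv").write_text(_join(sprot_lines))
        for tag, lines in dom_lines.items():
            header = "# generated domain table\n"
            (outdir / f"{tag}.domtblout").write_text(header + _join(lines))
        (outdir / "rrna_model_hits.tsv").write_text(_join(rrna_lines))
        (outdir / "refmap.tsv").write_text(
            _join(f"{s}\t{l}" for s, l in sorted(refmap.items()))
        )
        (outdir / "sprot_meta.tsv").write_text(
            _join("\t".join(r) for r in sprot_meta_rows)
        )
        (outdir / "tigrfam_meta.tsv").write_text(
            _join("\t".join(r) for r in tigrfam_meta_rows)
        )
        (outdir / "binmap.tsv").write_text(
            _join(f"{c}\t{m}" for c, m in sorted(truth["contig_mag"].items()))
        )
    return truth


def _pairwise_line(q, s, ident, alen, e, bits, qlen) -> str:
    mism = max(0, int(alen * (100.0 - ident) / 100.0))
    return "\t".join([
        q, s, f"{ident:.2f}", str(alen), str(mism), "0",
        "1", str(alen), "1", str(alen), f"{e:.3e}", f"{bits:.1f}", str(qlen),
    ])


def _domtbl_line(gene, name, acc, e, score, aa, rng, desc="") -> str:
    afrom = 1 + int(rng.integers(0, max(1, aa // 3)))
    ato = min(aa, afrom + int(rng.integers(15, 60)))
    return _DOMTBL_FMT.format(
        gene=gene, tlen=aa, name=name, acc=acc, mlen=max(20, ato - afrom + 1),
        fE=e, fscore=score + 5.0, cE=e / 2, iE=e, dscore=score,
        afrom=afrom, ato=ato, desc=desc or name,
    )


def _join(lines) -> str:
    lines = list(lines)
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# pathway world

def gen_pathway_world(
    seed: int,
    n_pathways: int = 8,
    n_families: int = 24,
    cover_size: int = 3,
    observed_pool: Sequence[str] | None = None,
    mapping: Sequence[tuple] | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Construct a pathway world with a provably unique minimum cover.

    Each of the ``cover_size`` planted pathways owns at least one observed
    *private* family (a member of no other pathway), so every cover must
    contain the whole planted set, which is therefore the unique minimum.
    Decoy pathways hold only unobserved families. For <= 12 pathways,
    uniqueness is verified by exhaustive subset enumeration at generation
    time.

    ``observed_pool`` optionally supplies the observed family ids (e.g.
    the KO accessions actually planted in the evidence files); otherwise
    synthetic family ids are invented. ``mapping`` optionally supplies the
    true (gene_id, family_id) support pairs to emit; otherwise synthetic
    gene ids are used.
    """
    if n_pathways < 2:
        raise ValueError("n_pathways must be >= 2")
    if not 1 <= cover_size < n_pathways:
        raise ValueError("cover_size must be in [1, n_pathways)")
    rng = _rng(seed, 4)
    if observed_pool is None:
        observed = [f"K{30000 + i:05d}" for i in range(max(n_families // 2, cover_size + 1))]
    else:
        observed = sorted(set(observed_pool))
        if len(observed) <= cover_size:
            raise ValueError("observed_pool smaller than cover_size + 1")
    unobserved = [f"K{40000 + i:05d}" for i in range(max(n_families - len(observed), n_pathways))]
    planted = [f"path{i + 1:03d}" for i in range(cover_size)]
    decoys = [f"path{i + 1:03d}" for i in range(cover_size, n_pathways)]
    members: dict[str, set] = {p: set() for p in planted + decoys}
    # one observed family kept out of every pathway: always uncovered
    orphan = observed[-1]
    assignable = observed[:-1]
    # private observed family per planted pathway, rest shared round-robin
    for i, fam in enumerate(assignable):
        members[planted[i % cover_size]].add(fam)
    # decoys hold only unobserved families (padded with more if needed)
    for i, fam in enumerate(unobserved):
        tgt = (decoys + planted)[i % n_pathways]
        members[tgt].add(fam)
    for d in decoys:
        if not members[d]:
            members[d].add(unobserved[0])

    if mapping is None:
        genes = [f"g{i + 1:04d}" for i in range(2 * len(observed))]
        mapping = []
        for i, fam in enumerate(sorted(observed)):
            n_support = 1 + int(rng.integers(0, 2))
            for k in range(n_support):
                mapping.append((genes[(2 * i + k) % len(genes)], fam))
    mapping = sorted(mapping)

    if n_pathways <= 12:
        assert _unique_min_cover_check(
            set(assignable), members, frozenset(planted)
        ), "generated pathway world lost cover uniqueness"

    world = {
        "defs": {p: sorted(members[p]) for p in sorted(members)},
        "planted_cover": sorted(planted),
        "observed": sorted(observed),
        "orphan_family": orphan,
        "mapping": mapping,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "kegg_pathways.tsv").write_text(_join(
            f"{p}\tPathway {p}\t{','.join(sorted(members[p]))}"
            for p in sorted(members)
        ))
        (outdir / "ko_map.tsv").write_text(_join(
            f"{g}\t{fam}" for g, fam in world["mapping"]
        ))
    return world


def _unique_min_cover_check(
    coverable: set, members: Mapping[str, set], planted: frozenset
) -> bool:
    """Exhaustively confirm planted is the unique minimum cover."""
    from itertools import combinations

    ids = sorted(members)
    best_size = None
    solutions = []
    for k in range(1, len(ids) + 1):
        if best_size is not None and k > best_size:
            break
        for combo in combinations(ids, k):
            u: set = set()
            for p in combo:
                u |= members[p] & coverable
            if u >= coverable:
                best_size = k
                solutions.append(frozenset(combo))
    return solutions == [planted]


# ---------------------------------------------------------------------------
# depth + spectral counts

def gen_depth_and_spectral(
    truth: dict,
    seed: int,
    n_samples: int = 3,
    replicate_noise: float = 0.0,
    expressed_fraction: float = 0.6,
    outdir: str | Path | None = None,
) -> dict:
    """Generate a MetaBat-dialect depth file and a spectral-count table.

    Replicate samples share a per-contig base depth (lognormal across
    contigs) multiplied by per-sample lognormal noise of scale
    ``replicate_noise``; zero noise makes replicates identical. Spectral
    counts are Poisson draws around a per-gene base rate, again shared
    across replicates at zero noise. All values are rounded to the 4
    decimals the file dialect carries, so files round-trip losslessly.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = _rng(seed, 5)
    samples = [f"sample{i + 1}.bam" for i in range(n_samples)]
    depth: dict[str, dict] = {}
    variance: dict[str, dict] = {}
    for cid in sorted(truth["contigs"]):
        base = float(rng.lognormal(mean=3.0, sigma=0.6))
        depth[cid] = {}
        variance[cid] = {}
        for s in samples:
            noise = float(rng.lognormal(0.0, replicate_noise)) if replicate_noise > 0 else 1.0
            depth[cid][s] = round(base * noise, 4)
            variance[cid][s] = round(base * 0.1, 4)
    total = {cid: round(sum(depth[cid].values()), 4) for cid in depth}

    spectral: dict[str, dict] = {}
    gene_ids = [o["gene_id"] for o in truth["orfs"]]
    for gid in gene_ids:
        if rng.random() > expressed_fraction:
            continue
        base_rate = float(rng.uniform(2, 50))
        row = {}
        for s in samples:
            if replicate_noise > 0:
                v = float(rng.poisson(base_rate))
            else:
                v = round(base_rate, 4)
            row[s] = round(v, 4)
        spectral[gid] = row

    truth["samples"] = samples
    truth["depth"] = depth
    truth["spectral"] = spectral
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .abundance import DepthTable, SpectralTable, write_depth, write_spectral

        table = DepthTable(
            contig_len={c: truth["contigs"][c]["length"] for c in depth},
            total_avg_depth=total,
            depths=depth,
            samples=tuple(samples),
        )
        write_depth(table, outdir / "depth.txt", variances=variance)
        write_spectral(
            SpectralTable(spectral, tuple(samples)), outdir / "plevel.txt"
        )
    return truth


# ---------------------------------------------------------------------------
# one-call orchestration

def generate_fixture_set(
    outdir: str | Path,
    seed: int,
    n_contigs: int = 6,
    length_range: tuple = (3000, 6000),
    feature_density: float = 1.0,
    mag_qs: Sequence[float] = (0.0, 0.25),
    identity_noise: float = 0.0,
    decoy_rate: float = 0.5,
    n_samples: int = 3,
    replicate_noise: float = 0.0,
    n_pathways: int = 8,
    cover_size: int = 3,
    orfs_per_contig: int | None = None,
) -> FixtureSet:
    """Generate a complete, self-consistent input directory plus truth.json.

    With ``orfs_per_contig`` set, contigs carry exactly that many CDS
    features (no noncoding features) so per-MAG gene counts are exact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if orfs_per_contig is not None:
        contigs, features, orfs, truth = gen_uniform_contigs(
            seed, n_contigs, orfs_per_contig, outdir=outdir
        )
    else:
        contigs, features, orfs, truth = gen_contigs(
            seed, n_contigs, length_range, feature_density, outdir=outdir
        )
    truth = plant_taxonomy(truth, seed, mag_qs=mag_qs)
    truth = gen_evidence(
        truth, seed, identity_noise=identity_noise, decoy_rate=decoy_rate,
        outdir=outdir,
    )
    ko_pairs = sorted(
        (gid, ko)
        for gid, info in truth["genes"].items()
        for ko in info.get("kos", ())
    )
    world = gen_pathway_world(
        seed, n_pathways=n_pathways, cover_size=cover_size,
        observed_pool=[ko for _, ko in ko_pairs] or None,
        mapping=ko_pairs or None, outdir=outdir,
    )
    truth["pathway_world"] = world
    truth = gen_depth_and_spectral(
        truth, seed, n_samples=n_samples, replicate_noise=replicate_noise,
        outdir=outdir,
    )
    (outdir / "truth.json").write_text(
        json.dumps(truth, indent=1, sort_keys=True) + "\n"
    )
    paths = {
        "contigs": outdir / "contigs.fna",
        "features": outdir / "features.tsv",
        "orfs": outdir / "orfs.tsv",
        "rrna_model_hits": outdir / "rrna_model_hits.tsv",
        "genomedb": outdir / "genomedb.tsv",
        "sprot": outdir / "sprot.tsv",
        "pfam": outdir / "pfam.domtblout",
        "tigrfam": outdir / "tigrfam.domtblout",
        "foam": outdir / "foam.domtblout",
        "metabolic": outdir / "metabolic.domtblout",
        "casgene": outdir / "casgene.domtblout",
        "refmap": outdir / "refmap.tsv",
        "sprot_meta": outdir / "sprot_meta.tsv",
        "tigrfam_meta": outdir / "tigrfam_meta.tsv",
        "binmap": outdir / "binmap.tsv",
        "kegg_pathways": outdir / "kegg_pathways.tsv",
        "ko_map": outdir / "ko_map.tsv",
        "depth": outdir / "depth.txt",
        "spectral": outdir / "plevel.txt",
        "truth": outdir / "truth.json",
    }
    return FixtureSet(outdir, truth, paths)
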
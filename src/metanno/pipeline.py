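"""Resumable end-to-end annotation pipeline.

Stages run in a fixed order — preprocess, structural, homology-merge,
taxonomy, pathways, abundance, reports — and every stage persists its
outputs as files. Each stage records a parameter hash (its own settings
chained with its upstream stage's hash); on a rerun with unchanged
parameters a stage whose outputs all exist is skipped, so restarting with
the same inputs reuses the intermediate files, while changing any
parameter re-executes that stage and everything downstream. All writers
are deterministic, so a resumed run is byte-identical to a fresh one.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import abundance, homology, pathways, reports, seqprep, structural, taxonomy
from .homology import AnnotationRecord
from .taxonomy import Lineage

STAGES = (
    "preprocess", "structural", "homology", "taxonomy",
    "pathways", "abundance", "reports",
)


@dataclass
class RunConfig:
    """All pipeline inputs and thresholds.

    ``input_dir`` must follow the standard layout (the fixture generator
    emits it): contigs.fna, features.tsv, rrna_model_hits.tsv, orfs.tsv,
    genomedb.tsv, sprot.tsv, *.domtblout, refmap.tsv, sprot_meta.tsv,
    tigrfam_meta.tsv, binmap.tsv, kegg_pathways.tsv, depth.txt,
    plevel.txt. Missing optional files disable the matching outputs.
    """

    input_dir: Path
    outdir: Path
    min_contig_len: int = seqprep.DEFAULT_MIN_CONTIG_LEN
    min_orf_nt: int = structural.DEFAULT_MIN_ORF_NT
    max_evalue: float = homology.DEFAULT_MAX_EVALUE
    weighting: str = "depth"  # depth | depth_x_len | count
    pathway_mode: str = "auto"
    sp: bool = False
    tm: bool = False
    force: bool = False
    seed: int = 0

    def __post_init__(self):
        self.input_dir = Path(self.input_dir)
        self.outdir = Path(self.outdir)
        if self.min_contig_len < 0 or self.min_orf_nt < 0:
            raise ValueError("thresholds must be >= 0")

    def in_path(self, name: str) -> Path:
        return self.input_dir / name

    def stage_params(self, stage: str) -> dict:
        common = {"input_dir": str(self.input_dir)}
        per_stage = {
            "preprocess": {"min_contig_len": self.min_contig_len},
            "structural": {"min_orf_nt": self.min_orf_nt},
            "homology": {"max_evalue": self.max_evalue, "sp": self.sp, "tm": self.tm},
            "taxonomy": {},
            "pathways": {"mode": self.pathway_mode},
            "abundance": {"weighting": self.weighting},
            "reports": {},
        }
        return {**common, **per_stage[stage]}


@dataclass
class StageState:
    name: str
    hash: str
    outputs: list

    def fresh(self, outdir: Path, recorded: dict | None) -> bool:
        """A stage is skippable iff outputs exist and the hash matches."""
        if recorded is None or recorded.get("hash") != self.hash:
            return False
        return all((outdir / o).exists() for o in recorded.get("outputs", []))


def _digest(obj) -> str:
    return hashlib.md5(json.dumps(obj, sort_keys=True).encode()).hexdigest()


class Pipeline:
    def __init__(self, config: RunConfig):
        self.cfg = config
        self.outdir = config.outdir
        self.state_path = self.outdir / "state.json"
        self.log_lines: list[str] = []

    # -- state -------------------------------------------------------------
    def _load_state(self) -> dict:
        if self.state_path.exists():
            return json.loads(self.state_path.read_text())
        return {}

    def _save_state(self, state: dict) -> None:
        self.state_path.write_text(json.dumps(state, indent=1, sort_keys=True) + "\n")

    def log(self, msg: str) -> None:
        self.log_lines.append(msg)

    # -- driver ------------------------------------------------------------
    def run(self) -> reports.ReportBundle:
        self.outdir.mkdir(parents=True, exist_ok=True)
        state = self._load_state()
        bundle = reports.ReportBundle(self.outdir)
        upstream_hash = ""
        executed: dict[str, bool] = {}
        for stage in STAGES:
            params = self.cfg.stage_params(stage)
            h = _digest({"stage": stage, "params": params, "upstream": upstream_hash})
            st = StageState(stage, h, [])
            if not self.cfg.force and st.fresh(self.outdir, state.get(stage)):
                self.log(f"stage {stage}: skipped (outputs present, params unchanged)")
                outputs = state[stage]["outputs"]
                executed[stage] = False
            else:
                self.log(f"stage {stage}: running with {params}")
                outputs = getattr(self, f"_stage_{stage}")()
                state[stage] = {"hash": h, "outputs": outputs}
                self._save_state(state)
                executed[stage] = True
            for o in outputs:
                bundle.add(o, self.outdir / o)
            bundle.stage_hashes[stage] = h
            upstream_hash = h
        # the log records skip/run decisions, so it is deliberately outside
        # the checksum manifest (resume must stay byte-identical)
        bundle.write_manifest()
        bundle.add("manifest", self.outdir / "manifest.json")
        (self.outdir / "run.log").write_text("\n".join(self.log_lines) + "\n")
        bundle.add("run.log", self.outdir / "run.log")
        return bundle

    # -- stages ------------------------------------------------------------
    def _stage_preprocess(self) -> list:
        recs = seqprep.read_fasta(self.cfg.in_path("contigs.fna"))
        result = seqprep.preprocess(recs, self.cfg.min_contig_len)
        seqprep.write_fasta(result.contigs, self.outdir / "cleaned.fna")
        seqprep.write_report(result.report, self.outdir / "preprocess_report.tsv")
        self.log(
            f"preprocess: kept {len(result.contigs)} contigs, removed {result.n_removed}"
        )
        return ["cleaned.fna", "preprocess_report.tsv"]

    def _stage_structural(self) -> list:
        contigs = {
            r.id: seqprep.CleanContig(r.id, r.sequence, r.description)
            for r in seqprep.read_fasta(self.outdir / "cleaned.fna")
        }
        feats = []
        fpath = self.cfg.in_path("features.tsv")
        if fpath.exists():
            feats = structural.ingest_feature_table(fpath)
        rrna_feats = []
        rpath = self.cfg.in_path("rrna_model_hits.tsv")
        if rpath.exists():
            hits = structural.read_rrna_model_hits(rpath)
            hits = [h for h in hits if h.contig_id in contigs]
            resolved = structural.resolve_model_hits(hits)
            rrna_feats = [h.to_feature() for h in resolved]
        noncoding = [f for f in feats if f.contig_id in contigs] + rrna_feats
        masked = [
            structural.mask_regions(c, [f for f in noncoding if f.contig_id == cid])
            for cid, c in sorted(contigs.items())
        ]
        seqprep.write_fasta(masked, self.outdir / "masked.fna")
        orfs = structural.read_orf_table(self.cfg.in_path("orfs.tsv"))
        orfs = [o for o in orfs if o.contig_id in contigs]
        orfs = structural.filter_orfs(orfs, self.cfg.min_orf_nt)
        # a CDS entirely inside a masked noncoding feature cannot be real
        masked_by_contig: dict[str, list] = {}
        for f in noncoding:
            masked_by_contig.setdefault(f.contig_id, []).append(f)
        orfs = [
            o for o in orfs
            if not any(
                f.start <= o.start and o.end <= f.end
                for f in masked_by_contig.get(o.contig_id, [])
            )
        ]
        with open(self.outdir / "orfs_retained.tsv", "w") as fh:
            for o in sorted(orfs, key=lambda x: (x.contig_id, x.start)):
                fh.write(f"{o.gene_id}\t{o.contig_id}\t{o.start}\t{o.end}\t{o.strand}\n")
        cds = [
            structural.FeatureInterval(
                o.contig_id, o.start, o.end, o.strand, "CDS", "", {"ID": o.gene_id}
            )
            for o in orfs
        ]
        reports.write_gff3(self.outdir / "structural.gff3", noncoding + cds)
        self.log(
            f"structural: {len(noncoding)} noncoding features, {len(orfs)} ORFs retained"
        )
        return ["masked.fna", "orfs_retained.tsv", "structural.gff3"]

    def _collect_bundles(self, orfs) -> dict:
        cfg = self.cfg
        bundles = {
            o.gene_id: homology.EvidenceBundle(o.gene_id) for o in orfs
        }

        def feed_pairwise(name: str, attr: str):
            p = cfg.in_path(name)
            if not p.exists():
                return
            for h in homology.parse_tabular_hits(p):
                if h.query_id in bundles:
                    getattr(bundles[h.query_id], attr).append(h)

        feed_pairwise("sprot.tsv", "sprot")
        feed_pairwise("genomedb.tsv", "genomedb")
        for fname, tag in (
            ("pfam.domtblout", "Pfam"),
            ("tigrfam.domtblout", "TIGRFAM"),
            ("foam.domtblout", "FOAM"),
            ("metabolic.domtblout", "MetabolicHMM"),
            ("casgene.domtblout", "CasGene"),
        ):
            p = cfg.in_path(fname)
            if not p.exists():
                continue
            for h in homology.parse_domain_table(p, tag):
                if h.query_id in bundles:
                    bundles[h.query_id].domains.setdefault(tag, []).append(h)
        return bundles

    def _stage_homology(self) -> list:
        orfs = structural.read_orf_table(self.outdir / "orfs_retained.tsv")
        bundles = self._collect_bundles(orfs)
        sprot_meta = {}
        p = self.cfg.in_path("sprot_meta.tsv")
        if p.exists():
            sprot_meta = homology.load_sprot_meta(p)
        tigr_meta = {}
        p = self.cfg.in_path("tigrfam_meta.tsv")
        if p.exists():
            tigr_meta = homology.load_tigrfam_meta(p)
        refmap = {}
        p = self.cfg.in_path("refmap.tsv")
        if p.exists():
            refmap = taxonomy.load_refmap(p)
        records = [
            homology.merge_evidence(
                o, bundles[o.gene_id], sprot_meta, tigr_meta,
                refmap=refmap, max_evalue=self.cfg.max_evalue,
            )
            for o in orfs
        ]
        records.sort(key=lambda r: (r.contigid, r.start, r.id))
        payload = [dataclasses.asdict(r) for r in records]
        (self.outdir / "annotations.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True) + "\n"
        )
        n_hyp = sum(1 for r in records if r.product == homology.HYPOTHETICAL)
        self.log(f"homology: merged {len(records)} records, {n_hyp} hypothetical")
        return ["annotations.json"]

    def _load_records(self) -> list[AnnotationRecord]:
        payload = json.loads((self.outdir / "annotations.json").read_text())
        return [AnnotationRecord(**d) for d in payload]

    def _stage_taxonomy(self) -> list:
        records = self._load_records()
        assignments = {
            r.id: Lineage.parse(r.genomedb_oc) if r.genomedb_oc else Lineage.empty()
            for r in records
        }
        tree = taxonomy.build_profile(assignments)
        reports.write_json(taxonomy.serialize_tree(tree), self.outdir / "taxonomy_tree.json")
        taxonomy.profile_table(tree).to_csv(
            self.outdir / "taxonomy_profile.tsv", sep="\t", index=False,
            float_format="%.4f",
        )
        outputs = ["taxonomy_tree.json", "taxonomy_profile.tsv"]
        p = self.cfg.in_path("binmap.tsv")
        if p.exists():
            binmap = taxonomy.load_binmap(p)
            per_mag = taxonomy.extract_mag_annotations(records, binmap)
            mag_assign = {
                mag: {r.id: assignments[r.id] for r in recs}
                for mag, recs in per_mag.items()
            }
            taxonomy.mag_report_table(mag_assign).to_csv(
                self.outdir / "mag_report.tsv", sep="\t", index=False,
                float_format="%.4f",
            )
            outputs.append("mag_report.tsv")
        self.log(f"taxonomy: profiled {len(records)} genes")
        return outputs

    def _stage_pathways(self) -> list:
        records = self._load_records()
        defs_path = self.cfg.in_path("kegg_pathways.tsv")
        outputs = []
        obs_rows = []
        for r in records:
            for ko in r.allko_ids:
                obs_rows.append((r.id, ko))
        (self.outdir / "gene_ko_map.tsv").write_text(
            "".join(f"{g}\t{k}\n" for g, k in sorted(obs_rows))
        )
        outputs.append("gene_ko_map.tsv")
        if defs_path.exists():
            defs = pathways.load_pathway_defs(defs_path)
            fam_obs = pathways.load_family_map(self.outdir / "gene_ko_map.tsv")
            observed = [o.family_id for o in fam_obs]
            recon = pathways.reconstruct_minimal(observed, defs, mode=self.cfg.pathway_mode)
            rep = pathways.pathway_report(recon, defs, observed)
            rep.to_csv(
                self.outdir / "pathway_report.tsv", sep="\t", index=False,
                float_format="%.4f",
            )
            reports.write_json(
                {
                    "kept": sorted(recon.kept),
                    "mode_used": recon.mode_used,
                    "uncovered_families": sorted(recon.uncovered_families),
                    "fill": {k: round(v, 4) for k, v in sorted(recon.fill.items())},
                },
                self.outdir / "pathways.json",
            )
            outputs += ["pathway_report.tsv", "pathways.json"]
            self.log(
                f"pathways: kept {len(recon.kept)} of {len(defs)} "
                f"({recon.mode_used} mode)"
            )
        return outputs

    def _gene_weights(self, records, depth_table) -> dict:
        cfg = self.cfg
        if cfg.weighting == "count" or depth_table is None:
            return {r.id: {"count": 1.0} for r in records}
        weights = {}
        for r in records:
            w = dict(r.depth)
            if cfg.weighting == "depth_x_len":
                span = max(1, r.end - r.start + 1)
                w = {s: v * span for s, v in w.items()}
            weights[r.id] = w
        return weights

    def _stage_abundance(self) -> list:
        records = self._load_records()
        outputs = []
        depth_table = None
        p = self.cfg.in_path("depth.txt")
        if p.exists():
            depth_table = abundance.parse_depth(p)
            abundance.attach_gene_depth(records, depth_table, strict=False)
            payload = [dataclasses.asdict(r) for r in records]
            (self.outdir / "annotations.json").write_text(
                json.dumps(payload, indent=1, sort_keys=True) + "\n"
            )
        weights = self._gene_weights(records, depth_table)
        # taxon profile at genus rank
        taxa = {
            r.id: (
                Lineage.parse(r.genomedb_oc).at_rank("g__") or ""
                if r.genomedb_oc else ""
            )
            for r in records
        }
        pm = abundance.weighted_profile(taxa, weights)
        abundance.profile_to_frame(pm).to_csv(
            self.outdir / "taxon_abundance.tsv", sep="\t", index=False,
            float_format="%.4f",
        )
        outputs.append("taxon_abundance.tsv")
        # function (KO) profile: full weight to each KO of a gene
        kos = {r.id: tuple(r.allko_ids) for r in records}
        pm_ko = abundance.multi_category_profile(kos, weights)
        abundance.profile_to_frame(pm_ko).to_csv(
            self.outdir / "function_abundance.tsv", sep="\t", index=False,
            float_format="%.4f",
        )
        outputs.append("function_abundance.tsv")
        # pathway activity
        pjson = self.outdir / "pathways.json"
        defs_path = self.cfg.in_path("kegg_pathways.tsv")
        if pjson.exists() and defs_path.exists():
            doc = json.loads(pjson.read_text())
            recon = pathways.PathwayReconstruction(
                tuple(doc["kept"]), frozenset(doc["uncovered_families"]),
                dict(doc["fill"]), doc["mode_used"],
            )
            fam_obs = pathways.load_family_map(self.outdir / "gene_ko_map.tsv")
            defs = pathways.load_pathway_defs(defs_path)
            pm_pw = abundance.pathway_activity(recon, fam_obs, weights, defs)
            abundance.profile_to_frame(pm_pw).to_csv(
                self.outdir / "pathway_abundance.tsv", sep="\t", index=False,
                float_format="%.4f",
            )
            outputs.append("pathway_abundance.tsv")
        # proteome profiles from spectral counts
        p = self.cfg.in_path("plevel.txt")
        if p.exists():
            spectral = abundance.parse_spectral(p)
            sw = {r.id: spectral.gene_weights(r.id) for r in records}
            pm_sp = abundance.weighted_profile(taxa, sw)
            abundance.profile_to_frame(pm_sp).to_csv(
                self.outdir / "taxon_proteome.tsv", sep="\t", index=False,
                float_format="%.4f",
            )
            outputs.append("taxon_proteome.tsv")
        self.log(f"abundance: weighting={self.cfg.weighting}")
        return outputs

    def _stage_reports(self) -> list:
        records = self._load_records()
        samples: list[str] = []
        for r in records:
            for s in r.depth:
                if s not in samples:
                    samples.append(s)
        reports.write_master_table(self.outdir / "master.tsv", records, samples)
        feats = reports.read_gff3(self.outdir / "structural.gff3")
        rec_by_id = {r.id: r for r in records}
        reports.write_gff3(self.outdir / "annotated.gff3", feats, rec_by_id)
        contigs = {
            r.id: r.sequence for r in seqprep.read_fasta(self.outdir / "cleaned.fna")
        }
        cds = [f for f in feats if f.ftype == "CDS"]
        reports.write_feature_fasta(self.outdir / "features.ffn", contigs, cds)
        bundle = reports.ReportBundle(self.outdir)
        for name in (
            "master.tsv", "annotated.gff3", "features.ffn",
            "taxonomy_tree.json", "taxonomy_profile.tsv",
        ):
            if (self.outdir / name).exists():
                bundle.add(name, self.outdir / name)
        embed = {}
        tj = self.outdir / "taxonomy_tree.json"
        if tj.exists():
            embed["taxonomy"] = json.loads(tj.read_text())
        pj = self.outdir / "pathways.json"
        if pj.exists():
            embed["pathways"] = json.loads(pj.read_text())
        reports.write_html_index(bundle, embed)
        self.log(f"reports: master table with {len(records)} records")
        return ["master.tsv", "annotated.gff3", "features.ffn", "index.html"]


def run_pipeline(config: RunConfig) -> reports.ReportBundle:
    """Execute all stages in order; see :class:`RunConfig`."""
    return Pipeline(config).run()
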
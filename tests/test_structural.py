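"""rRNA hit resolution, masking, ORF filtering, feature ingestion."""
import numpy as np
import pytest

from metanno.errors import CoordinateError, MissingSubjectError, OutOfBoundsError, ParseError
from metanno.homology import PairwiseHit
from metanno.seqprep import CleanContig
from metanno.structural import (
    FeatureInterval,
    OrfCall,
    RrnaModelHit,
    classify_rrna,
    filter_orfs,
    ingest_feature_table,
    mask_regions,
    resolve_model_hits,
)
from metanno.taxonomy import Lineage


def brute_force_resolve(hits):
    """Independent oracle: explicit pairwise-overlap graph, BFS components,
    keep group-minimum E-values."""
    n = len(hits)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = hits[i], hits[j]
            if a.contig_id == b.contig_id and a.start <= b.end and b.start <= a.end:
                adj[i].add(j)
                adj[j].add(i)
    seen, kept = set(), []
    for i in range(n):
        if i in seen:
            continue
        comp, queue = {i}, [i]
        while queue:
            u = queue.pop()
            for v in adj[u]:
                if v not in comp:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        best = min(hits[k].evalue for k in comp)
        kept.extend(hits[k] for k in comp if hits[k].evalue == best)
    return sorted(kept, key=lambda h: (h.contig_id, h.start, h.end))


def random_hits(rng, n, n_contigs=3, span=2000, tie_prob=0.15):
    hits = []
    evalues = [1e-30, 1e-20, 1e-10, 1e-5]
    for _ in range(n):
        start = int(rng.integers(1, span))
        end = start + int(rng.integers(50, 400))
        if hits and rng.random() < tie_prob:
            e = hits[-1].evalue  # plant exact ties
        else:
            e = float(rng.choice(evalues)) * float(10.0 ** -rng.integers(0, 5))
        hits.append(
            RrnaModelHit(
                f"c{int(rng.integers(1, n_contigs + 1))}",
                str(rng.choice(["Bacteria", "Archaea", "Eukaryota"])),
                str(rng.choice(["16S", "23S", "5S"])),
                start, end, "+", e, float(rng.uniform(50, 200)),
            )
        )
    return hits


class TestResolveModelHits:
    def _hit(self, start, end, e, contig="c1", dom="Bacteria"):
        return RrnaModelHit(contig, dom, "16S", start, end, "+", e, 100.0)

    def test_lowest_evalue_wins(self):
        bac = self._hit(100, 1600, 1e-30, dom="Bacteria")
        arc = self._hit(120, 1580, 1e-10, dom="Archaea")
        assert resolve_model_hits([arc, bac]) == [bac]

    def test_exact_tie_keeps_all(self):
        a = self._hit(100, 1600, 1e-20, dom="Bacteria")
        b = self._hit(150, 1550, 1e-20, dom="Archaea")
        assert resolve_model_hits([b, a]) == [a, b]

    def test_non_overlapping_always_retained(self):
        a = self._hit(1, 100, 1e-3)
        b = self._hit(101, 200, 1e-30)  # adjacent, not overlapping
        assert resolve_model_hits([b, a]) == [a, b]

    def test_transitive_group_resolved_together(self):
        # a-b overlap, b-c overlap, a-c do not: one component
        a = self._hit(1, 100, 1e-10)
        b = self._hit(90, 200, 1e-30)
        c = self._hit(190, 300, 1e-20)
        assert resolve_model_hits([a, b, c]) == [b]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            hits = random_hits(rng, int(rng.integers(1, 50)))
            assert resolve_model_hits(hits) == brute_force_resolve(hits)

    def test_dropped_hits_lose_to_their_overlap_component(self):
        # groups are connected components of the overlap graph, so every
        # dropped hit shares a component with a kept, strictly better hit
        rng = np.random.default_rng(7)
        hits = random_hits(rng, 40)
        kept = resolve_model_hits(hits)
        kept_ids = {id(h) for h in kept}
        assert kept_ids <= {id(h) for h in hits}  # output is a subset
        n = len(hits)
        adj = {
            i: {
                j for j in range(n)
                if j != i
                and hits[i].contig_id == hits[j].contig_id
                and hits[i].start <= hits[j].end
                and hits[j].start <= hits[i].end
            }
            for i in range(n)
        }
        for i, h in enumerate(hits):
            if id(h) in kept_ids:
                continue
            comp, queue = {i}, [i]
            while queue:
                u = queue.pop()
                for v in adj[u]:
                    if v not in comp:
                        comp.add(v)
                        queue.append(v)
            assert any(
                id(hits[k]) in kept_ids and hits[k].evalue < h.evalue
                for k in comp
            )


class TestMaskRegions:
    def test_single_feature(self):
        c = CleanContig("c1", "ACGTACGTAC")
        m = mask_regions(c, [FeatureInterval("c1", 3, 5, "+", "tRNA")])
        assert m.sequence == "ACNNNCGTAC"

    def test_no_features_identity(self):
        c = CleanContig("c1", "ACGT")
        assert mask_regions(c, []).sequence == "ACGT"

    def test_overlapping_features_position_oracle(self):
        c = CleanContig("c1", "A" * 12)
        feats = [
            FeatureInterval("c1", 2, 6, "+", "rRNA"),
            FeatureInterval("c1", 4, 9, "+", "tRNA"),
        ]
        m = mask_regions(c, feats)
        masked = {
            i for f in feats for i in range(f.start, f.end + 1)
        }
        assert m.sequence.count("N") == len(masked) == 8
        for i, ch in enumerate(m.sequence, 1):
            assert (ch == "N") == (i in masked)

    def test_length_and_unmasked_content_conserved(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        c = CleanContig("c1", seq)
        feats = [FeatureInterval("c1", 50, 120, "+", "rRNA")]
        m = mask_regions(c, feats)
        assert m.length == c.length
        for i in list(range(0, 49)) + list(range(120, 300)):
            assert m.sequence[i] == seq[i]

    def test_out_of_bounds(self):
        c = CleanContig("c1", "ACGT")
        with pytest.raises(OutOfBoundsError):
            mask_regions(c, [FeatureInterval("c1", 2, 10, "+", "tRNA")])


class TestFilterOrfs:
    def _orf(self, nt, gid="g1"):
        return OrfCall(gid, "c1", 1, nt, "+")

    def test_default_threshold_boundary(self):
        assert filter_orfs([self._orf(179)]) == []
        kept = filter_orfs([self._orf(180)])
        assert len(kept) == 1

    def test_empty(self):
        assert filter_orfs([]) == []

    def test_mixed_lengths(self):
        orfs = [self._orf(n, f"g{n}") for n in (90, 180, 300)]
        assert [o.gene_id for o in filter_orfs(orfs)] == ["g180", "g300"]


class TestIngestFeatureTable:
    def test_tsv_line(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("c1\t10\t85\t+\ttRNA-Ala\n")
        feats = ingest_feature_table(p)
        f = feats[0]
        assert (f.contig_id, f.start, f.end, f.strand, f.ftype, f.subtype) == (
            "c1", 10, 85, "+", "tRNA", "tRNA-Ala",
        )

    def test_gff3_single_base_feature(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text("##gff-version 3\nc1\tx\tCRISPR\t7\t7\t.\t.\t.\t.\n")
        feats = ingest_feature_table(p)
        assert feats[0].start == feats[0].end == 7

    def test_end_before_start_rejected(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("c1\t85\t10\t+\ttRNA-Ala\n")
        with pytest.raises(CoordinateError):
            ingest_feature_table(p)

    def test_bad_column_count(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("c1\t10\t85\n")
        with pytest.raises(ParseError):
            ingest_feature_table(p)


class TestClassifyRrna:
    def _gene(self):
        return FeatureInterval("c1", 1, 1500, "+", "rRNA", "16S", {"ID": "r1"})

    def _hit(self, subject, e, bits=100.0):
        return PairwiseHit("r1", subject, 99.0, 1400, 10, 0, 1, 1400, 1, 1400, e, bits)

    def test_single_hit(self):
        refmap = {"S1": Lineage.parse("d__Bacteria;p__Firmicutes")}
        lin = classify_rrna(self._gene(), [self._hit("S1", 1e-50)], refmap)
        assert str(lin) == "d__Bacteria;p__Firmicutes"

    def test_no_hits_unclassified(self):
        assert classify_rrna(self._gene(), [], {}).is_empty

    def test_missing_subject(self):
        with pytest.raises(MissingSubjectError):
            classify_rrna(self._gene(), [self._hit("S1", 1e-50)], {})

    def test_best_hit_oracle(self):
        rng = np.random.default_rng(3)
        refmap = {
            f"S{i}": Lineage.parse(f"d__Bacteria;p__P{i}") for i in range(20)
        }
        hits = [
            self._hit(f"S{int(rng.integers(0, 20))}",
                      float(10.0 ** -rng.integers(5, 80)),
                      float(rng.uniform(50, 500)))
            for _ in range(20)
        ]
        best = min(hits, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
        assert classify_rrna(self._gene(), hits, refmap) == refmap[best.subject_id]
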
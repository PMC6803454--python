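"""Lineage parsing, gene classification, weighted trees, MAG reports."""
import numpy as np
import pytest

from metanno.errors import LineageFormatError, MissingSubjectError, NoClassifiedGenesError
from metanno.homology import AnnotationRecord, EvidenceBundle, PairwiseHit
from metanno.taxonomy import (
    Lineage,
    build_profile,
    classify_gene,
    contamination_report,
    deserialize_tree,
    extract_mag_annotations,
    parse_lineage,
    serialize_tree,
)

CUPRIAVIDUS = (
    "d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;"
    "o__Betaproteobacteriales;f__Burkholderiaceae;g__Cupriavidus;"
)


class TestParseLineage:
    def test_six_rank_lineage_trailing_semicolon(self):
        lin = parse_lineage(CUPRIAVIDUS)
        assert len(lin.ranks) == 6
        assert lin.at_rank("g__") == "Cupriavidus"
        assert lin.at_rank("s__") is None

    def test_empty_is_unclassified(self):
        assert parse_lineage("").is_empty

    def test_out_of_order_rejected(self):
        with pytest.raises(LineageFormatError):
            parse_lineage("p__X;d__Y")

    def test_unknown_prefix_rejected(self):
        with pytest.raises(LineageFormatError):
            parse_lineage("k__Bacteria")

    def test_round_trip(self):
        s = "d__Bacteria;p__Firmicutes;c__Bacilli"
        assert str(parse_lineage(s)) == s


def _hit(s, e, bits=100.0):
    return PairwiseHit("g1", s, 90.0, 100, 5, 0, 1, 100, 1, 100, e, bits)


class TestClassifyGene:
    refmap = {f"S{i}": Lineage.parse(f"d__Bacteria;p__P{i}") for i in range(10)}

    def test_best_hit_lineage(self):
        bundle = EvidenceBundle("g1", genomedb=[_hit("S1", 1e-50), _hit("S2", 1e-20)])
        assert classify_gene(bundle, self.refmap) == self.refmap["S1"]

    def test_no_hits_unclassified(self):
        assert classify_gene(EvidenceBundle("g1"), self.refmap).is_empty

    def test_missing_subject(self):
        bundle = EvidenceBundle("g1", genomedb=[_hit("ABSENT", 1e-50)])
        with pytest.raises(MissingSubjectError):
            classify_gene(bundle, self.refmap)

    def test_order_invariance_and_oracle(self):
        rng = np.random.default_rng(4)
        hits = [
            _hit(f"S{int(rng.integers(0, 10))}", float(10.0 ** -rng.integers(6, 60)),
                 float(rng.integers(50, 400)))
            for _ in range(30)
        ]
        best = min(hits, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
        expected = self.refmap[best.subject_id]
        for perm_seed in range(3):
            perm = list(hits)
            np.random.default_rng(perm_seed).shuffle(perm)
            assert classify_gene(EvidenceBundle("g1", genomedb=perm), self.refmap) == expected


class TestBuildProfile:
    def test_same_genus_accumulates(self):
        lin = Lineage.parse("d__B;p__P;c__C;o__O;f__F;g__G")
        tree = build_profile({"g1": lin, "g2": lin})
        node = tree.root
        for name in lin.names():
            node = node.children[name]
        assert node.weight("count") == 2.0
        assert tree.root.weight("count") == 2.0

    def test_two_phyla_proportions(self):
        a = Lineage.parse("d__B;p__X")
        b = Lineage.parse("d__B;p__Y")
        tree = build_profile(
            {"g1": a, "g2": b},
            {"g1": {"s": 10.0}, "g2": {"s": 30.0}},
        )
        d = tree.root.children["B"]
        assert d.children["X"].weight("s") / tree.root.weight("s") == pytest.approx(0.25)
        assert d.children["Y"].weight("s") / tree.root.weight("s") == pytest.approx(0.75)

    def test_unclassified_pseudo_child(self):
        tree = build_profile({"g1": Lineage.empty(), "g2": Lineage.parse("d__B")})
        assert tree.root.children["unclassified"].weight("count") == 1.0
        assert tree.root.weight("count") == 2.0

    def test_conservation_on_random_fixture(self):
        rng = np.random.default_rng(8)
        assignments, weights = {}, {}
        for i in range(500):
            depth = int(rng.integers(0, 7))
            parts = [f"{p}T{int(rng.integers(0, 3))}" for p in "dpcofgs"[:depth]]
            prefixes = ["d__", "p__", "c__", "o__", "f__", "g__", "s__"]
            s = ";".join(pref + name for pref, name in zip(prefixes, parts))
            assignments[f"g{i}"] = Lineage.parse(s)
            weights[f"g{i}"] = {
                "s1": float(rng.uniform(0, 5)), "s2": float(rng.uniform(0, 5))
            }
        tree = build_profile(assignments, weights)
        for node in tree.iter_nodes():
            for s in ("s1", "s2"):
                child_sum = sum(c.weight(s) for c in node.children.values())
                at_node = node.at_node_weight(s)
                assert at_node >= -1e-9
                assert node.weight(s) == pytest.approx(child_sum + at_node)
        total = sum(w["s1"] for w in weights.values())
        assert tree.root.weight("s1") == pytest.approx(total)


class TestSerializeTree:
    def _tree(self):
        rng = np.random.default_rng(1)
        assignments = {
            f"g{i}": Lineage.parse(f"d__B;p__P{int(rng.integers(0, 4))}")
            for i in range(40)
        }
        return build_profile(assignments)

    def test_round_trip_preserves_weights(self):
        tree = self._tree()
        doc = serialize_tree(tree)
        back = deserialize_tree(doc)
        orig = {(n.name, n.rank): n.weights for n in tree.iter_nodes()}
        new = {(n.name, n.rank): n.weights for n in back.iter_nodes()}
        assert orig == new

    def test_child_ordering_descending_weight_then_name(self):
        doc = serialize_tree(self._tree())

        def check(d):
            keys = [(-sum(c["weights"].values()), c["name"]) for c in d["children"]]
            assert keys == sorted(keys)
            for c in d["children"]:
                check(c)

        check(doc)

    def test_single_lineage_depth(self):
        tree = build_profile({"g1": Lineage.parse("d__B;p__P;c__C")})
        doc = serialize_tree(tree)
        depth = 0
        node = doc
        while node["children"]:
            node = node["children"][0]
            depth += 1
        assert depth == 3


class TestContaminationReport:
    def _genes(self, counts):
        genes = {}
        i = 0
        for genus, n in counts.items():
            for _ in range(n):
                genes[f"g{i}"] = Lineage.parse(f"d__B;p__P;c__C;o__O;f__F;g__{genus}")
                i += 1
        return genes

    def test_plurality_and_fraction(self):
        rep = contamination_report(self._genes({"A": 97, "B": 3}), "g__")
        assert rep.plurality_taxon == "A"
        assert rep.discordant_fraction == pytest.approx(0.03)

    def test_pure_mag_zero(self):
        rep = contamination_report(self._genes({"A": 50}), "g__")
        assert rep.discordant_fraction == 0.0

    def test_even_split_lexicographic_tie(self):
        rep = contamination_report(self._genes({"B": 5, "A": 5}), "g__")
        assert rep.plurality_taxon == "A"
        assert rep.discordant_fraction == pytest.approx(0.5)

    def test_unclassified_excluded_from_denominator(self):
        genes = self._genes({"A": 8})
        genes["u1"] = Lineage.parse("d__B")  # no genus
        rep = contamination_report(genes, "g__")
        assert rep.n_classified == 8 and rep.n_unclassified == 1

    def test_no_classified_genes(self):
        with pytest.raises(NoClassifiedGenesError):
            contamination_report({"g1": Lineage.empty()}, "g__")


class TestExtractMagAnnotations:
    def _records(self, contigs):
        return [AnnotationRecord(id=f"g{i}", contigid=c) for i, c in enumerate(contigs)]

    def test_partition_by_contig(self):
        recs = self._records(["c1", "c1", "c2", "c3"])
        out = extract_mag_annotations(recs, {"c1": "M1", "c2": "M1", "c3": "M2"})
        assert len(out["M1"]) == 3 and len(out["M2"]) == 1

    def test_empty_binmap_all_unbinned(self):
        recs = self._records(["c1", "c2"])
        out = extract_mag_annotations(recs, {})
        assert set(out) == {"unbinned"} and len(out["unbinned"]) == 2

    def test_totals_conserved_random(self):
        rng = np.random.default_rng(6)
        contigs = [f"c{int(rng.integers(0, 20))}" for _ in range(200)]
        binmap = {f"c{i}": f"M{i % 4}" for i in range(15)}  # partial
        recs = self._records(contigs)
        out = extract_mag_annotations(recs, binmap)
        assert sum(len(v) for v in out.values()) == len(recs)
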
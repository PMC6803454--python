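"""Hit-table parsing, best-hit selection, FOAM grammar, evidence merging."""
import numpy as np
import pytest

from metanno.errors import GrammarError, ParseError
from metanno.homology import (
    DomainHit,
    EvidenceBundle,
    PairwiseHit,
    SprotMeta,
    TigrfamMeta,
    merge_evidence,
    parse_domain_table,
    parse_foam_name,
    parse_tabular_hits,
    select_best_hit,
    significance_filter,
)
from metanno.structural import OrfCall

TAB12 = "g1\tsubj1\t98.50\t163\t2\t0\t1\t163\t5\t167\t1.4e-89\t512.0"


class TestParseTabularHits:
    def test_twelve_columns(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(TAB12 + "\n")
        (h,) = parse_tabular_hits(p)
        assert (h.query_id, h.subject_id) == ("g1", "subj1")
        assert h.pct_identity == 98.5 and h.evalue == 1.4e-89
        assert h.qcov is None  # no qlen column

    def test_qcov_full_coverage(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(TAB12 + "\t163\n")
        (h,) = parse_tabular_hits(p)
        assert h.qcov == pytest.approx(100.00)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("")
        assert parse_tabular_hits(p) == []

    def test_wrong_column_count(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("a\tb\tc\n")
        with pytest.raises(ParseError) as exc:
            parse_tabular_hits(p)
        assert exc.value.line_no == 1


DOMLINE = (
    "g1 - 163 Fer4 PF00037.27 60 2e-07 30.0 0.1 1 2 "
    "1e-07 2e-07 24.1 0.0 1 60 61 80 61 80 0.90 4Fe-4S binding domain"
)


class TestParseDomainTable:
    def test_comment_only(self, tmp_path):
        p = tmp_path / "d.tbl"
        p.write_text("# comment\n#\n")
        assert parse_domain_table(p, "Pfam") == []

    def test_one_domain_line(self, tmp_path):
        p = tmp_path / "d.tbl"
        p.write_text(DOMLINE + "\n")
        (h,) = parse_domain_table(p, "Pfam")
        assert h.query_id == "g1" and h.model_id == "PF00037.27"
        assert h.model_name == "Fer4"
        assert h.evalue == 2e-07  # i-evalue column
        assert (h.ali_from, h.ali_to) == (61, 80)
        assert h.description == "4Fe-4S binding domain"

    def test_repeated_domains_both_retained(self, tmp_path):
        p = tmp_path / "d.tbl"
        p.write_text(DOMLINE + "\n" + DOMLINE.replace("61 80 61 80", "97 118 97 118") + "\n")
        hits = parse_domain_table(p, "Pfam")
        assert len(hits) == 2
        assert {(h.ali_from, h.ali_to) for h in hits} == {(61, 80), (97, 118)}


def _hit(q="g1", s="s1", e=1e-10, bits=100.0):
    return PairwiseHit(q, s, 90.0, 100, 5, 0, 1, 100, 1, 100, e, bits)


class TestSelectBestHit:
    def test_single(self):
        h = _hit()
        assert select_best_hit([h]) is h

    def test_lower_evalue_wins(self):
        a, b = _hit(s="a", e=1e-50), _hit(s="b", e=1e-20)
        assert select_best_hit([b, a]) is a

    def test_empty(self):
        assert select_best_hit([]) is None

    def test_tie_break_bitscore_then_subject(self):
        a = _hit(s="z", e=1e-20, bits=200.0)
        b = _hit(s="a", e=1e-20, bits=100.0)
        assert select_best_hit([b, a]) is a  # higher bitscore
        c = _hit(s="a", e=1e-20, bits=200.0)
        assert select_best_hit([a, c]) is c  # lexicographic subject

    def test_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(11)
        hits = [
            _hit(s=f"s{int(rng.integers(0, 30))}",
                 e=float(10.0 ** -rng.integers(5, 60)),
                 bits=float(rng.integers(50, 500)))
            for _ in range(100)
        ]
        best = None
        for h in hits:  # plain exhaustive scan
            if best is None:
                best = h
            elif (h.evalue, -h.bitscore, h.subject_id) < (
                best.evalue, -best.bitscore, best.subject_id
            ):
                best = h
        assert select_best_hit(hits) == best


class TestSignificanceFilter:
    def test_cutoff(self):
        hits = [_hit(e=1e-7), _hit(e=1e-3)]
        assert significance_filter(hits, 1e-5) == [hits[0]]

    def test_infinite_cutoff_identity(self):
        hits = [_hit(e=1.0), _hit(e=1e-50)]
        assert significance_filter(hits, float("inf")) == hits

    def test_count_matches_direct_scan(self):
        rng = np.random.default_rng(2)
        hits = [_hit(e=float(10.0 ** -rng.uniform(0, 20))) for _ in range(200)]
        out = significance_filter(hits, 1e-5)
        assert len(out) == sum(1 for h in hits if h.evalue <= 1e-5)


class TestParseFoamName:
    @pytest.mark.parametrize(
        "name,kos,ecs",
        [
            ("KO:K00390_1.8.4.8", ["K00390"], ["1.8.4.8"]),
            ("KO:K01234", ["K01234"], []),
            ("KO:K00001,KO:K00002", ["K00001", "K00002"], []),
            ("KO:K00390_7.1.1.-", ["K00390"], ["7.1.1.-"]),
            ("KO:K11111_1.2.3.4_5.6.7.8", ["K11111"], ["1.2.3.4", "5.6.7.8"]),
        ],
    )
    def test_grammar(self, name, kos, ecs):
        assert parse_foam_name(name) == (kos, ecs)

    def test_missing_prefix_rejected(self):
        with pytest.raises(GrammarError):
            parse_foam_name("K00390_1.8.4.8")

    def test_generated_names_round_trip(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            kos = [f"K{int(rng.integers(1, 99999)):05d}"
                   for _ in range(int(rng.integers(1, 3)))]
            ecs = [
                f"{int(rng.integers(1, 7))}.{int(rng.integers(1, 20))}."
                f"{int(rng.integers(1, 20))}.{'-' if rng.random() < 0.3 else int(rng.integers(1, 40))}"
                for _ in range(int(rng.integers(0, 3)))
            ]
            kos = list(dict.fromkeys(kos))
            ecs = list(dict.fromkeys(ecs))
            name = ",".join(
                ["KO:" + "_".join([kos[0]] + ecs)] + [f"KO:{k}" for k in kos[1:]]
            )
            got_kos, got_ecs = parse_foam_name(name)
            assert got_kos == kos and got_ecs == ecs


def _dom(model_name, db, e=1e-10, model_id=None, desc=""):
    return DomainHit("g1", model_id or model_name, model_name, db, e, 40.0, 45.0, 10, 60, desc)


class TestMergeEvidence:
    gene = OrfCall("g1", "c1", 100, 591, "+")

    def test_empty_bundle_is_hypothetical(self):
        rec = merge_evidence(self.gene, EvidenceBundle("g1"))
        assert rec.product == "hypothetical protein"
        assert rec.allec_ids == [] and rec.allko_ids == [] and rec.go_terms == []

    def test_pfam_only_product_from_domain(self):
        bundle = EvidenceBundle(
            "g1", domains={"Pfam": [_dom("Fer4", "Pfam", desc="4Fe-4S binding domain")]}
        )
        rec = merge_evidence(self.gene, bundle)
        assert rec.product == "4Fe-4S binding domain"
        assert rec.allec_ids == []

    def test_product_priority_tigrfam_over_pfam(self):
        bundle = EvidenceBundle(
            "g1",
            domains={
                "Pfam": [_dom("Fer4", "Pfam", desc="pfam desc")],
                "TIGRFAM": [_dom("NuoI", "TIGRFAM", model_id="TIGR01971", desc="tigr desc")],
            },
        )
        rec = merge_evidence(self.gene, bundle)
        assert rec.product == "tigr desc"

    def test_insignificant_hits_ignored(self):
        bundle = EvidenceBundle("g1", sprot=[_hit(e=1e-3)])
        rec = merge_evidence(self.gene, bundle, max_evalue=1e-5)
        assert rec.product == "hypothetical protein"

    def test_no_fabricated_identifiers(self):
        sprot_meta = {"s1": SprotMeta("desc", ("1.1.1.1",), ("GO:1",), ("K00001",))}
        bundle = EvidenceBundle(
            "g1",
            sprot=[_hit(s="s1", e=1e-40)],
            domains={"FOAM": [_dom("KO:K00002_2.2.2.2", "FOAM")]},
        )
        rec = merge_evidence(self.gene, bundle, sprot_meta)
        inputs = {"1.1.1.1", "2.2.2.2", "K00001", "K00002", "GO:1"}
        for x in rec.allec_ids + rec.allko_ids + rec.go_terms:
            assert x in inputs

    def test_union_order_stable_and_deduplicated(self):
        sprot_meta = {"s1": SprotMeta("d", ("1.1.1.1",), (), ("K00001",))}
        bundle = EvidenceBundle(
            "g1",
            sprot=[_hit(s="s1", e=1e-40)],
            domains={
                "FOAM": [
                    _dom("KO:K00002_1.1.1.1", "FOAM"),
                    _dom("KO:K00002_3.3.3.3", "FOAM", e=1e-12),
                ]
            },
        )
        r1 = merge_evidence(self.gene, bundle, sprot_meta)
        r2 = merge_evidence(self.gene, bundle, sprot_meta)
        assert r1.allec_ids == r2.allec_ids == ["1.1.1.1", "3.3.3.3"]
        assert r1.allko_ids == ["K00002", "K00001"]  # FOAM first for KO

    def test_tigrfam_roles_attached(self):
        tigr_meta = {
            "TIGR01971": TigrfamMeta(
                "NADH-quinone oxidoreductase, chain I",
                ("GO:0050136", "GO:0055114"),
                "Energy metabolism", "Electron transport",
            )
        }
        bundle = EvidenceBundle(
            "g1", domains={"TIGRFAM": [_dom("NuoI", "TIGRFAM", model_id="TIGR01971")]}
        )
        rec = merge_evidence(self.gene, bundle, tigrfam_meta=tigr_meta)
        assert rec.tigrfam_mainrole == "Energy metabolism"
        assert rec.tigrfam_go == ["GO:0050136", "GO:0055114"]
        assert rec.product == "NADH-quinone oxidoreductase, chain I"
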
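"""Per-gene taxonomy and hierarchical community/MAG profiling.

Each protein-coding gene is classified by the lineage of its single best
hit against a lineage-labelled genome database (GTDB-style rank-prefixed
strings, ``d__;p__;c__;o__;f__;g__;s__``). Gene lineages are aggregated
into a weighted taxon tree — one ring per rank in the sunburst view, with
segment areas proportional to relative abundance — and, per MAG, into a
plurality/discordance report that flags chimeric bins or contamination
with genes from other community members.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import (
    LineageFormatError,
    MissingSubjectError,
    NegativeWeightError,
    NoClassifiedGenesError,
)
from .homology import EvidenceBundle, select_best_hit, significance_filter

RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus", "species")
_PREFIX_INDEX = {p: i for i, p in enumerate(RANK_PREFIXES)}

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Lineage:
    """An ordered rank-prefixed taxonomy path; may terminate early."""

    ranks: tuple  # of (prefix, name)

    @classmethod
    def empty(cls) -> "Lineage":
        return cls(())

    @classmethod
    def parse(cls, s: str) -> "Lineage":
        """Parse 'd__Bacteria;p__Proteobacteria;...' (trailing ';' allowed)."""
        segs = [x.strip() for x in s.split(";")]
        while segs and not segs[-1]:
            segs.pop()
        ranks = []
        for i, seg in enumerate(segs):
            prefix, _, name = seg.partition("__")
            prefix += "__"
            if prefix not in _PREFIX_INDEX:
                raise LineageFormatError(f"unknown rank prefix in segment {seg!r}")
            if _PREFIX_INDEX[prefix] != i:
                raise LineageFormatError(
                    f"rank {prefix} out of order at position {i} in {s!r}"
                )
            if not name:
                raise LineageFormatError(f"empty name for rank {prefix} in {s!r}")
            ranks.append((prefix, name))
        return cls(tuple(ranks))

    def at_rank(self, prefix: str) -> str | None:
        idx = _PREFIX_INDEX[prefix]
        if idx < len(self.ranks):
            return self.ranks[idx][1]
        return None

    @property
    def is_empty(self) -> bool:
        return not self.ranks

    def names(self) -> tuple:
        return tuple(name for _, name in self.ranks)

    def __str__(self) -> str:
        return ";".join(p + n for p, n in self.ranks)


def parse_lineage(s: str) -> Lineage:
    """Parse a rank-prefixed lineage string (see :meth:`Lineage.parse`)."""
    return Lineage.parse(s)


def load_refmap(path: str | Path) -> dict[str, Lineage]:
    """Load a subject_id -> lineage TSV reference map."""
    refmap = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        sid, _, lin = line.partition("\t")
        refmap[sid] = Lineage.parse(lin.rstrip("\n"))
    return refmap


def load_binmap(path: str | Path) -> dict[str, str]:
    """Load a contig_id -> mag_id TSV bin-membership map (may be partial)."""
    binmap = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cid, _, mag = line.partition("\t")
        binmap[cid] = mag.strip()
    return binmap


def classify_gene(
    bundle: EvidenceBundle,
    refmap: Mapping[str, Lineage],
    max_evalue: float = 1e-5,
) -> Lineage:
    """Lineage of the best significant genome-database hit for a gene.

    Uses the single best hit (not a lowest-common-ancestor of top hits);
    returns the empty lineage when no hit survives the significance filter.
    """
    best = select_best_hit(significance_filter(bundle.genomedb, max_evalue))
    if best is None:
        return Lineage.empty()
    if best.subject_id not in refmap:
        raise MissingSubjectError(best.subject_id)
    return refmap[best.subject_id]


# ---------------------------------------------------------------------------
# weighted taxon tree

@dataclass
class TaxonNode:
    name: str
    rank: str  # 'root' or one of RANK_NAMES
    weights: dict = field(default_factory=dict)  # sample -> weight
    children: dict = field(default_factory=dict)  # name -> TaxonNode

    def weight(self, sample: str) -> float:
        return self.weights.get(sample, 0.0)

    def at_node_weight(self, sample: str) -> float:
        """Weight assigned exactly at this node (not passed to children)."""
        return self.weight(sample) - sum(c.weight(sample) for c in self.children.values())


@dataclass
class TaxonTree:
    root: TaxonNode
    samples: tuple

    def iter_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children.values())


def build_profile(
    assignments: Mapping[str, Lineage],
    weights: Mapping[str, Mapping[str, float]] | None = None,
) -> TaxonTree:
    """Aggregate per-gene lineages into a weighted taxon tree.

    ``weights`` maps gene_id -> {sample -> weight}; by default every gene
    counts 1 in a single "count" sample. Genes with an empty lineage
    accumulate under an explicit "unclassified" child of the root so that
    ring proportions still partition the whole. Node weight is the sum of
    weights of all genes whose lineage passes through the node.
    """
    if weights is None:
        weights = {g: {"count": 1.0} for g in assignments}
    samples: list[str] = []
    for w in weights.values():
        for s in w:
            if s not in samples:
                samples.append(s)
    root = TaxonNode("root", "root")
    for gene_id, lineage in assignments.items():
        gw = weights.get(gene_id, {})
        for s, v in gw.items():
            if v < 0:
                raise NegativeWeightError(f"negative weight for gene {gene_id}")
            root.weights[s] = root.weights.get(s, 0.0) + v
        if lineage.is_empty:
            path = ((UNCLASSIFIED, UNCLASSIFIED),)
        else:
            path = tuple(
                (RANK_NAMES[_PREFIX_INDEX[p]], n) for p, n in lineage.ranks
            )
        node = root
        for rank, name in path:
            child = node.children.get(name)
            if child is None:
                child = TaxonNode(name, rank)
                node.children[name] = child
            for s, v in gw.items():
                child.weights[s] = child.weights.get(s, 0.0) + v
            node = child
    return TaxonTree(root, tuple(samples))


def serialize_tree(tree: TaxonTree) -> dict:
    """Nested dict (name, rank, weights, children) with deterministic child
    ordering: descending weight over all samples, then name."""

    def total(node: TaxonNode) -> float:
        return sum(node.weights.values())

    def ser(node: TaxonNode) -> dict:
        children = sorted(node.children.values(), key=lambda c: (-total(c), c.name))
        return {
            "name": node.name,
            "rank": node.rank,
            "weights": {s: node.weights.get(s, 0.0) for s in tree.samples},
            "children": [ser(c) for c in children],
        }

    return ser(tree.root)


def deserialize_tree(doc: dict) -> TaxonTree:
    samples: list[str] = list(doc.get("weights", {}).keys())

    def des(d: dict) -> TaxonNode:
        node = TaxonNode(d["name"], d["rank"], dict(d["weights"]))
        for c in d["children"]:
            node.children[c["name"]] = des(c)
        return node

    return TaxonTree(des(doc), tuple(samples))


def profile_table(tree: TaxonTree) -> pd.DataFrame:
    """Flat rank-path table with per-sample weight and proportion of root."""
    rows = []

    def walk(node: TaxonNode, path: tuple):
        if node.rank != "root":
            row = {"path": ";".join(path), "rank": node.rank}
            for s in tree.samples:
                rw = tree.root.weight(s)
                row[f"weight_{s}"] = node.weight(s)
                row[f"proportion_{s}"] = node.weight(s) / rw if rw > 0 else 0.0
            rows.append(row)
        for name in sorted(node.children):
            walk(node.children[name], path + (name,))

    walk(tree.root, ())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MAG-level reporting

@dataclass
class MagRankReport:
    mag_id: str
    rank_prefix: str
    plurality_taxon: str
    discordant_fraction: float
    n_classified: int
    n_unclassified: int


def contamination_report(
    mag_genes: Mapping[str, Lineage], rank: str = "g__", mag_id: str = ""
) -> MagRankReport:
    """Plurality taxon and gene-level discordance of a MAG at one rank.

    Genes without a name at the rank are excluded from the denominator.
    The plurality taxon is the most frequent name (ties broken by the
    lexicographically smallest name); discordant_fraction = 1 − plurality
    count / classified count. A high fraction flags a chimeric MAG.
    """
    counts: dict[str, int] = {}
    n_unclassified = 0
    for lineage in mag_genes.values():
        name = lineage.at_rank(rank) if not lineage.is_empty else None
        if name is None:
            n_unclassified += 1
        else:
            counts[name] = counts.get(name, 0) + 1
    if not counts:
        raise NoClassifiedGenesError(f"MAG {mag_id or '?'} has no genes classified at {rank}")
    plurality = min(counts, key=lambda n: (-counts[n], n))
    n_classified = sum(counts.values())
    discordant = 1.0 - counts[plurality] / n_classified
    return MagRankReport(mag_id, rank, plurality, discordant, n_classified, n_unclassified)


def extract_mag_annotations(
    records: Sequence, binmap: Mapping[str, str]
) -> dict[str, list]:
    """Route annotation records to their contig's MAG; unbinned contigs go
    to the "unbinned" pseudo-MAG. Totals are conserved."""
    out: dict[str, list] = {}
    for rec in records:
        mag = binmap.get(rec.contigid, "unbinned")
        out.setdefault(mag, []).append(rec)
    return out


def mag_report_table(
    mag_assignments: Mapping[str, Mapping[str, Lineage]],
    ranks: Sequence[str] = RANK_PREFIXES,
) -> pd.DataFrame:
    """Per-MAG, per-rank plurality/discordance table (skips ranks with no
    classified genes)."""
    rows = []
    for mag_id in sorted(mag_assignments):
        genes = mag_assignments[mag_id]
        for rank in ranks:
            try:
                r = contamination_report(genes, rank, mag_id)
            except NoClassifiedGenesError:
                continue
            rows.append(
                {
                    "mag_id": r.mag_id,
                    "rank": r.rank_prefix,
                    "plurality_taxon": r.plurality_taxon,
                    "discordant_fraction": r.discordant_fraction,
                    "n_classified": r.n_classified,
                    "n_unclassified": r.n_unclassified,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mag_id", "rank", "plurality_taxon",
            "discordant_fraction", "n_classified", "n_unclassified",
        ],
    )
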
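"""Depth- and spectral-count-weighted abundance profiles.

Sequencing depth comes in as a per-contig table in the MetaBat
``jgi_summarize_bam_contig_depths`` dialect (contigName, contigLen,
totalAvgDepth, then a mean-depth and a variance column per sample); each
gene inherits the mean depth of its contig per sample. Metaproteome
spectral counts come in as a gene-by-sample table of normalized protein
expression levels. Either weighting turns per-gene category assignments
(taxon, function family, pathway) into relative-abundance profiles whose
columns each sum to 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import (
    DuplicateGeneError,
    NegativeWeightError,
    ParseError,
    UnknownContigError,
)

UNASSIGNED = "unassigned"


@dataclass
class DepthTable:
    """Per-contig mean depth per sample (variance columns discarded)."""

    contig_len: dict  # contig -> int
    total_avg_depth: dict  # contig -> float
    depths: dict  # contig -> {sample -> float}
    samples: tuple

    def __contains__(self, contig: str) -> bool:
        return contig in self.depths

    def gene_weights(self, contig: str) -> dict:
        return dict(self.depths[contig])


def parse_depth(path: str | Path) -> DepthTable:
    """Parse a MetaBat-dialect depth file.

    Header: ``contigName  contigLen  totalAvgDepth`` followed by paired
    per-sample columns ``<sample>  <sample>-var``; variance columns are
    parsed and discarded.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["contigName", "contigLen", "totalAvgDepth"]
    if list(df.columns[:3]) != required:
        raise ParseError(
            f"depth file must start with columns {required}, got {list(df.columns[:3])}",
            path,
        )
    sample_cols = [c for c in df.columns[3:] if not c.endswith("-var")]
    if len(df) and sample_cols and (df[sample_cols].to_numpy() < 0).any():
        raise ParseError("negative depth value", path)
    depths = {}
    for _, row in df.iterrows():
        depths[row["contigName"]] = {s: float(row[s]) for s in sample_cols}
    return DepthTable(
        contig_len={r["contigName"]: int(r["contigLen"]) for _, r in df.iterrows()},
        total_avg_depth={r["contigName"]: float(r["totalAvgDepth"]) for _, r in df.iterrows()},
        depths=depths,
        samples=tuple(sample_cols),
    )


def write_depth(table: DepthTable, path: str | Path, variances: Mapping | None = None) -> None:
    """Write a DepthTable back to the MetaBat dialect (zero variances by
    default)."""
    cols = ["contigName", "contigLen", "totalAvgDepth"]
    for s in table.samples:
        cols += [s, f"{s}-var"]
    rows = []
    for contig in table.depths:
        row = {
            "contigName": contig,
            "contigLen": table.contig_len[contig],
            "totalAvgDepth": f"{table.total_avg_depth[contig]:.4f}",
        }
        for s in table.samples:
            row[s] = f"{table.depths[contig][s]:.4f}"
            var = variances[contig][s] if variances else 0.0
            row[f"{s}-var"] = f"{var:.4f}"
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


@dataclass
class SpectralTable:
    """Per-gene normalized protein expression level per sample."""

    values: dict  # gene -> {sample -> float}
    samples: tuple

    def gene_weights(self, gene: str) -> dict:
        """Genes absent from the table have zero expression."""
        if gene in self.values:
            return dict(self.values[gene])
        return {s: 0.0 for s in self.samples}


def parse_spectral(path: str | Path) -> SpectralTable:
    """Parse a spectral-count TSV: first column gene id, one column per
    sample of normalized expression."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.columns.size < 2:
        raise ParseError("spectral table needs a gene column plus >= 1 sample", path)
    gene_col = df.columns[0]
    if df[gene_col].duplicated().any():
        dup = df[gene_col][df[gene_col].duplicated()].iloc[0]
        raise DuplicateGeneError(f"gene {dup!r} listed twice in {path}")
    samples = tuple(df.columns[1:])
    values = {
        str(row[gene_col]): {s: float(row[s]) for s in samples}
        for _, row in df.iterrows()
    }
    return SpectralTable(values, samples)


def write_spectral(table: SpectralTable, path: str | Path) -> None:
    rows = []
    for gene in table.values:
        row = {"gene_id": gene}
        row.update({s: f"{table.values[gene][s]:.4f}" for s in table.samples})
        rows.append(row)
    pd.DataFrame(rows, columns=["gene_id", *table.samples]).to_csv(path, sep="\t", index=False)


def attach_gene_depth(records: Sequence, depth: DepthTable, strict: bool = True) -> list:
    """Give each annotation record its contig's per-sample mean depth.

    In strict mode an unknown contig raises; otherwise the record is
    skipped with zero depths. Records are returned (mutated in place).
    """
    for rec in records:
        if rec.contigid in depth:
            rec.depth = depth.gene_weights(rec.contigid)
        elif strict:
            raise UnknownContigError(
                f"contig {rec.contigid!r} of gene {rec.id!r} absent from depth table"
            )
        else:
            rec.depth = {s: 0.0 for s in depth.samples}
    return list(records)


# ---------------------------------------------------------------------------
# profiles

@dataclass
class ProfileMatrix:
    """Category x sample weights and relative abundances.

    Per sample, proportions over all rows (including the "unassigned" row
    when present) sum to 1; samples whose total weight is zero are listed
    in ``zero_total_samples`` and report all-zero proportions.
    """

    weights: pd.DataFrame
    proportions: pd.DataFrame = field(repr=False)
    zero_total_samples: tuple = ()

    @property
    def samples(self) -> tuple:
        return tuple(self.weights.columns)

    @property
    def categories(self) -> tuple:
        return tuple(self.weights.index)


def _make_profile(weight_rows: dict, samples: Sequence[str]) -> ProfileMatrix:
    idx = sorted(weight_rows)
    w = pd.DataFrame(
        [[weight_rows[c].get(s, 0.0) for s in samples] for c in idx],
        index=idx,
        columns=list(samples),
        dtype=float,
    )
    totals = w.sum(axis=0)
    zero = tuple(s for s in samples if totals[s] == 0.0)
    safe = totals.replace(0.0, 1.0)
    p = w / safe
    return ProfileMatrix(w, p, zero)


def weighted_profile(
    assignments: Mapping[str, str],
    weights: Mapping[str, Mapping[str, float]],
    samples: Sequence[str] | None = None,
) -> ProfileMatrix:
    """Sum per-gene weights into per-category rows and normalize per sample.

    ``assignments`` maps gene_id -> category; genes missing a category (or
    mapped to None/'') accumulate in an explicit "unassigned" row.
    """
    if samples is None:
        seen: list[str] = []
        for w in weights.values():
            for s in w:
                if s not in seen:
                    seen.append(s)
        samples = seen
    rows: dict[str, dict] = {}
    for gene_id, gw in weights.items():
        cat = assignments.get(gene_id) or UNASSIGNED
        acc = rows.setdefault(cat, {})
        for s, v in gw.items():
            if v < 0:
                raise NegativeWeightError(f"negative weight for gene {gene_id}")
            acc[s] = acc.get(s, 0.0) + v
    return _make_profile(rows, samples)


def multi_category_profile(
    assignments: Mapping[str, Sequence[str]],
    weights: Mapping[str, Mapping[str, float]],
    samples: Sequence[str] | None = None,
    split: bool = False,
) -> ProfileMatrix:
    """Profile for genes that may map to several categories (e.g. KOs).

    By default a gene contributes its full weight to every category it maps
    to; with ``split=True`` the weight is divided evenly instead.
    """
    if samples is None:
        seen: list[str] = []
        for w in weights.values():
            for s in w:
                if s not in seen:
                    seen.append(s)
        samples = seen
    rows: dict[str, dict] = {}
    for gene_id, gw in weights.items():
        cats = list(assignments.get(gene_id) or ()) or [UNASSIGNED]
        frac = 1.0 / len(cats) if split else 1.0
        for cat in cats:
            acc = rows.setdefault(cat, {})
            for s, v in gw.items():
                if v < 0:
                    raise NegativeWeightError(f"negative weight for gene {gene_id}")
                acc[s] = acc.get(s, 0.0) + v * frac
    return _make_profile(rows, samples)


def pathway_activity(
    recon,
    family_obs: Sequence,
    weights: Mapping[str, Mapping[str, float]],
    defs: Sequence | None = None,
    family_match: str = "exact",
) -> ProfileMatrix:
    """Per-pathway activity: sum, over each kept pathway's observed member
    families, of the weights of the genes supporting those families.

    A gene supporting two families of the same pathway is counted once per
    family. Pathways with no observed members never appear (reconstruction
    keeps only explanatory pathways).
    """
    from .pathways import ec_matches

    by_family = {o.family_id: o for o in family_obs}
    members_of: dict[str, list] = {}
    if defs is not None:
        defs_by_id = {d.pathway_id: d for d in defs}
    else:
        defs_by_id = {}
    samples: list[str] = []
    for w in weights.values():
        for s in w:
            if s not in samples:
                samples.append(s)
    rows: dict[str, dict] = {}
    for pid in recon.kept:
        acc: dict[str, float] = {}
        if pid in defs_by_id:
            members = defs_by_id[pid].members
            if family_match == "ec_wildcard":
                fams = [
                    f for f in by_family
                    if any(ec_matches(f, m) for m in members)
                ]
            else:
                fams = [f for f in by_family if f in members]
        else:
            fams = list(by_family)
        for fam in fams:
            for gene in by_family[fam].gene_ids:
                for s, v in weights.get(gene, {}).items():
                    acc[s] = acc.get(s, 0.0) + v
        rows[pid] = acc
    return _make_profile(rows, samples)


def profile_to_frame(pm: ProfileMatrix) -> pd.DataFrame:
    """Long-form table: category, then per-sample weight and proportion."""
    rows = []
    for cat in pm.categories:
        row = {"category": cat}
        for s in pm.samples:
            row[f"weight_{s}"] = pm.weights.loc[cat, s]
            row[f"proportion_{s}"] = pm.proportions.loc[cat, s]
        rows.append(row)
    cols = ["category"] + [c for s in pm.samples for c in (f"weight_{s}", f"proportion_{s}")]
    return pd.DataFrame(rows, columns=cols)
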
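"""Parsimony-based minimal pathway reconstruction.

Given the set of gene families observed in a dataset (KO accessions for
KEGG-style pathways, EC numbers for MetaCyc-style pathways) and pathway
definitions (pathway -> member families), the reconstruction selects the
minimum-cardinality set of pathways whose members jointly cover every
coverable observed family — a conservative, parsimony-first estimate of
which pathways are actually present. Exact minimization is used on small
instances; a classic greedy set-cover heuristic takes over on large ones.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ParseError

#: `auto` mode solves exactly when at most this many pathways intersect
#: the observed family set, else it falls back to greedy.
AUTO_EXACT_LIMIT = 20


@dataclass(frozen=True)
class PathwayDef:
    pathway_id: str
    name: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id} has no members")


@dataclass(frozen=True)
class FamilyObservation:
    family_id: str
    gene_ids: frozenset


@dataclass
class PathwayReconstruction:
    kept: tuple  # sorted pathway ids
    uncovered_families: frozenset  # observed families in no pathway
    fill: dict = field(default_factory=dict)  # pathway_id -> fraction of members observed
    mode_used: str = "exact"


def load_pathway_defs(path: str | Path) -> list[PathwayDef]:
    """Load pathway definitions: pathway_id \\t name \\t comma-separated members."""
    defs = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 3:
            raise ParseError(f"expected 3 columns, got {len(f)}", Path(path), line_no)
        members = frozenset(m.strip() for m in f[2].split(",") if m.strip())
        if not members:
            raise ParseError("pathway with no members", Path(path), line_no)
        defs.append(PathwayDef(f[0], f[1], members))
    return defs


def load_family_map(path: str | Path) -> list[FamilyObservation]:
    """Load a gene_id \\t family_id mapping; duplicate pairs collapse.

    Returns observations sorted by family id, each carrying the supporting
    gene ids.
    """
    groups: dict[str, set] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) != 2:
            raise ParseError(f"expected 2 columns, got {len(f)}", Path(path), line_no)
        groups.setdefault(f[1], set()).add(f[0])
    return [
        FamilyObservation(fam, frozenset(groups[fam])) for fam in sorted(groups)
    ]


# ---------------------------------------------------------------------------
# EC wildcard matching

def ec_matches(observed: str, member: str) -> bool:
    """True when an observed EC matches a pathway-member EC.

    A '-' field is a wildcard: the observed EC matches any member it agrees
    with on all its specified fields (e.g. observed ``7.1.1.-`` matches
    member ``7.1.1.2``). Non-EC family ids fall back to exact equality.
    """
    if observed == member:
        return True
    of, mf = observed.split("."), member.split(".")
    if len(of) != len(mf):
        return False
    for o, m in zip(of, mf):
        if o != m and o != "-" and m != "-":
            return False
    return True


def _covered_sets(
    observed: frozenset, defs: Sequence[PathwayDef], family_match: str
) -> dict[str, frozenset]:
    """For each pathway, the subset of observed families it explains."""
    out = {}
    for d in defs:
        if family_match == "ec_wildcard":
            cov = frozenset(
                o for o in observed if any(ec_matches(o, m) for m in d.members)
            )
        else:
            cov = observed & d.members
        if cov:
            out[d.pathway_id] = cov
    return out


def reconstruct_minimal(
    observed: Iterable[str],
    defs: Sequence[PathwayDef],
    mode: str = "auto",
    family_match: str = "exact",
) -> PathwayReconstruction:
    """Select a minimal pathway set explaining the observed families.

    ``exact`` returns a true minimum-cardinality cover of the coverable
    families, breaking ties by the lexicographically smallest id-set;
    ``greedy`` iteratively picks the pathway covering the most uncovered
    families (ties -> smallest id); ``auto`` solves exactly when at most
    ``AUTO_EXACT_LIMIT`` candidate pathways intersect the observed set.
    Families that belong to no pathway are reported as uncovered.
    """
    if not defs:
        raise ValueError("pathway definitions must be non-empty")
    if mode not in ("exact", "greedy", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    observed = frozenset(observed)
    covered = _covered_sets(observed, defs, family_match)
    coverable = frozenset().union(*covered.values()) if covered else frozenset()
    uncovered = observed - coverable

    if mode == "auto":
        mode_used = "exact" if len(covered) <= AUTO_EXACT_LIMIT else "greedy"
    else:
        mode_used = mode

    if not coverable:
        kept: tuple = ()
    elif mode_used == "exact":
        kept = _exact_cover(coverable, covered)
    else:
        kept = _greedy_cover(coverable, covered)

    by_id = {d.pathway_id: d for d in defs}
    fill = {}
    for pid in kept:
        d = by_id[pid]
        if family_match == "ec_wildcard":
            n_obs = sum(1 for m in d.members if any(ec_matches(o, m) for o in observed))
        else:
            n_obs = len(d.members & observed)
        fill[pid] = n_obs / len(d.members)
    return PathwayReconstruction(kept, frozenset(uncovered), fill, mode_used)


def _exact_cover(coverable: frozenset, covered: Mapping[str, frozenset]) -> tuple:
    """Minimum-cardinality cover; ties -> lexicographically smallest id-set.

    Enumerates candidate combinations in ascending size and, within a size,
    in lexicographic id order, so the first cover found is the answer.
    Intended for small candidate counts (auto caps at AUTO_EXACT_LIMIT).
    """
    ids = sorted(covered)
    # prune dominated candidates? keep all: dominated sets can still win lex
    # ties only if equal, and equality keeps the smaller id anyway via order.
    for k in range(1, len(ids) + 1):
        for combo in combinations(ids, k):
            u: set = set()
            for pid in combo:
                u |= covered[pid]
            if u >= coverable:
                return combo
    return tuple(ids)  # unreachable: full set always covers


def _greedy_cover(coverable: frozenset, covered: Mapping[str, frozenset]) -> tuple:
    remaining = set(coverable)
    kept = []
    while remaining:
        best = min(
            covered, key=lambda pid: (-len(covered[pid] & remaining), pid)
        )
        gain = covered[best] & remaining
        if not gain:
            break  # cannot happen while remaining ⊆ coverable
        kept.append(best)
        remaining -= gain
    return tuple(sorted(kept))


def pathway_report(
    recon: PathwayReconstruction,
    defs: Sequence[PathwayDef],
    observed: Iterable[str],
    family_match: str = "exact",
) -> pd.DataFrame:
    """One row per kept pathway: id, name, member/observed counts, fill."""
    observed = frozenset(observed)
    by_id = {d.pathway_id: d for d in defs}
    rows = []
    for pid in sorted(recon.kept):
        d = by_id[pid]
        if family_match == "ec_wildcard":
            obs_members = sorted(
                m for m in d.members if any(ec_matches(o, m) for o in observed)
            )
        else:
            obs_members = sorted(d.members & observed)
        rows.append(
            {
                "pathway_id": pid,
                "name": d.name,
                "n_members": len(d.members),
                "n_observed": len(obs_members),
                "fill": recon.fill.get(pid, len(obs_members) / len(d.members)),
                "observed_members": ",".join(obs_members),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["pathway_id", "name", "n_members", "n_observed", "fill", "observed_members"],
    )
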
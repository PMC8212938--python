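"""Homeolog-group inference, typing, nomenclature, and catalog statistics.

In allohexaploid bread wheat every gene may retain up to three homeologous
copies, one per subgenome (A, B, D).  Copies of one gene are expected to form
a tight clade in the protein tree; this module partitions the tree into such
groups, types each group by its retained-subgenome configuration (A:B:D full
triad down to single-copy orphans), applies the complement-ordered systematic
nomenclature (e.g. TaWRKY75-A), and computes the retention/summary statistics.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .io_formats import ProteinRecord
from .phylo import TreeNode

__all__ = [
    "HomeologGroup",
    "CatalogStats",
    "HOMEOLOG_TYPES",
    "infer_groups",
    "type_groups",
    "assign_names",
    "summary_stats",
    "fold_ratio",
    "round_pct",
]

HOMEOLOG_TYPES = ("A:B:D", "A:B", "A:D", "B:D", "A", "B", "D")
_SUBGENOME_PRIORITY = {"A": 0, "B": 1, "D": 2}


class HomeologError(ValueError):
    """Raised for invalid homeolog-group inputs."""


@dataclass
class HomeologGroup:
    """One gene: 1-3 subgenome copies sharing a chromosome complement."""

    members: list[ProteinRecord]
    complement: int | None
    homeolog_type: str
    serial: int | None = None
    base_name: str | None = None
    member_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        subs = [m.subgenome for m in self.members if m.subgenome]
        if len(subs) != len(set(subs)):
            raise HomeologError(
                f"duplicate subgenome within group {[m.gene_id for m in self.members]}"
            )
        if not 1 <= len(self.members) <= 3:
            raise HomeologError("a homeolog group has 1-3 members")


def _make_group(members: list[ProteinRecord]) -> HomeologGroup:
    subs = sorted(
        {m.subgenome for m in members if m.subgenome},
        key=_SUBGENOME_PRIORITY.get,
    )
    htype = ":".join(subs) if subs else "?"
    return HomeologGroup(
        members=sorted(members, key=lambda m: (_SUBGENOME_PRIORITY.get(m.subgenome, 9), m.gene_id)),
        complement=members[0].complement,
        homeolog_type=htype,
    )


def infer_groups(tree: TreeNode, records: Sequence[ProteinRecord]) -> list[HomeologGroup]:
    """Greedy maximal-clade partition of the tree into homeolog groups.

    A clade qualifies as a group iff all its leaves share one (non-null)
    chromosome complement and no subgenome appears twice (so at most three
    leaves, one per subgenome).  The NJ tree is unrooted (trifurcating root),
    so clades are taken as edge sides: every subtree leaf set *and* its
    complement is a candidate, which keeps groups that happen to span the
    arbitrary root intact.  Maximal qualifying clades are claimed first;
    leaves in no qualifying multi-leaf clade become singletons.  Leaves
    without a complement are routed to singleton groups.
    """
    by_id = {r.record_id: r for r in records}
    all_leaves = frozenset(tree.leaf_names())
    if all_leaves != set(by_id) or len(tree.leaf_names()) != len(by_id):
        raise HomeologError("tree leaves and records do not match one-to-one")

    def qualifies(names: frozenset) -> bool:
        members = [by_id[n] for n in names]
        comps = {m.complement for m in members}
        if len(comps) != 1 or None in comps:
            return False
        subs = [m.subgenome for m in members]
        return None not in subs and len(subs) == len(set(subs))

    # collect both sides of every internal edge
    candidates: set[frozenset] = set()

    def collect(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset().union(*(collect(c) for c in node.children))
        if node is not tree:
            for side in (below, all_leaves - below):
                if 2 <= len(side) <= 3 and qualifies(side):
                    candidates.add(side)
        return below

    collect(tree)
    if 2 <= len(all_leaves) <= 3 and qualifies(all_leaves):
        candidates.add(all_leaves)

    groups: list[HomeologGroup] = []
    taken: set[str] = set()
    for cand in sorted(candidates, key=lambda s: (-len(s), min(s))):
        if cand & taken:
            continue
        groups.append(_make_group([by_id[n] for n in cand]))
        taken |= cand
    for name in sorted(all_leaves - taken):
        groups.append(_make_group([by_id[name]]))
    return groups


def round_pct(part: float, total: float) -> float:
    """Percentage 100 * part / total, rounded half-up to 2 decimals."""
    if total == 0:
        return 0.0
    q = (Decimal(part) * 100 / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


def fold_ratio(n_copies: int, comparator: int) -> float:
    """Copy-count ratio against another species' family size, 2 decimals."""
    q = (Decimal(n_copies) / Decimal(comparator)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass
class CatalogStats:
    """Per-type, per-subgenome, and per-complement counts for the catalog."""

    type_gene_counts: dict[str, int]
    type_copy_counts: dict[str, int]
    type_gene_pct: dict[str, float]
    subgenome_copy_counts: dict[str, int]
    subgenome_copy_pct: dict[str, float]
    complement_gene_counts: dict[int, int]
    total_copies: int
    total_genes: int

    def as_dict(self) -> dict:
        return {
            "type_gene_counts": self.type_gene_counts,
            "type_copy_counts": self.type_copy_counts,
            "type_gene_pct": self.type_gene_pct,
            "subgenome_copy_counts": self.subgenome_copy_counts,
            "subgenome_copy_pct": self.subgenome_copy_pct,
            "complement_gene_counts": {str(k): v for k, v in self.complement_gene_counts.items()},
            "total_copies": self.total_copies,
            "total_genes": self.total_genes,
        }


def summary_stats(groups: Sequence[HomeologGroup]) -> CatalogStats:
    """Full catalog statistics: homeolog-type breakdown, subgenome copy
    shares, and per-complement gene counts."""
    type_genes = Counter()
    type_copies = Counter()
    sub_copies = Counter()
    comp_genes = Counter()
    for g in groups:
        type_genes[g.homeolog_type] += 1
        type_copies[g.homeolog_type] += len(g.members)
        for m in g.members:
            if m.subgenome:
                sub_copies[m.subgenome] += 1
        if g.complement is not None:
            comp_genes[g.complement] += 1
    total_genes = len(groups)
    total_copies = sum(len(g.members) for g in groups)
    types = [t for t in HOMEOLOG_TYPES] + sorted(set(type_genes) - set(HOMEOLOG_TYPES))
    return CatalogStats(
        type_gene_counts={t: type_genes.get(t, 0) for t in types},
        type_copy_counts={t: type_copies.get(t, 0) for t in types},
        type_gene_pct={t: round_pct(type_genes.get(t, 0), total_genes) for t in types},
        subgenome_copy_counts={s: sub_copies.get(s, 0) for s in "ABD"},
        subgenome_copy_pct={s: round_pct(sub_copies.get(s, 0), total_copies) for s in "ABD"},
        complement_gene_counts={c: comp_genes[c] for c in sorted(comp_genes)},
        total_copies=total_copies,
        total_genes=total_genes,
    )


def type_groups(groups: Sequence[HomeologGroup]) -> CatalogStats:
    """Homeolog-type counts and percentage breakdown (Table-1-style)."""
    return summary_stats(groups)


def _ref_member(group: HomeologGroup, subgenome: str) -> ProteinRecord | None:
    for m in group.members:
        if m.subgenome == subgenome:
            return m
    return None


def assign_names(
    groups: Sequence[HomeologGroup], prefix: str = "TaWRKY"
) -> list[HomeologGroup]:
    """Assign serials and systematic names in place; returns groups sorted by serial.

    Serials run 1..G over chromosome complements 1-7.  Within a complement the
    reference subgenome is the one carrying the most family copies (ties
    A > B > D); groups with a copy on it are ordered by that copy's start
    coordinate, remaining groups follow ordered by (highest-priority
    subgenome, start).  Member names are ``prefix + serial + '-' + subgenome``.
    Groups without a complement are numbered last, ordered by gene id.
    """
    placed = [g for g in groups if g.complement is not None]
    unplaced = sorted(
        (g for g in groups if g.complement is None),
        key=lambda g: min(m.gene_id for m in g.members),
    )
    serial = 0
    ordered: list[HomeologGroup] = []
    for comp in sorted({g.complement for g in placed}):
        comp_groups = [g for g in placed if g.complement == comp]
        copies = Counter(m.subgenome for g in comp_groups for m in g.members if m.subgenome)
        ref = min("ABD", key=lambda s: (-copies.get(s, 0), _SUBGENOME_PRIORITY[s]))
        on_ref = [g for g in comp_groups if _ref_member(g, ref) is not None]
        on_ref.sort(key=lambda g: (_ref_member(g, ref).start or 0,
                                   _ref_member(g, ref).gene_id))

        def rest_key(g: HomeologGroup):
            m = min(g.members, key=lambda x: _SUBGENOME_PRIORITY.get(x.subgenome, 9))
            return (_SUBGENOME_PRIORITY.get(m.subgenome, 9), m.start or 0, m.gene_id)

        rest = sorted((g for g in comp_groups if _ref_member(g, ref) is None), key=rest_key)
        ordered.extend(on_ref + rest)
    ordered.extend(unplaced)
    for g in ordered:
        serial += 1
        g.serial = serial
        g.base_name = f"{prefix}{serial}"
        g.member_names = {
            m.record_id: (f"{g.base_name}-{m.subgenome}" if m.subgenome else g.base_name)
            for m in g.members
        }
    return ordered
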
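"""WRKY structural group classification (I, IIa-IIe, III).

Family members fall into three major groups: group I proteins carry two WRKY
domains, group II one domain with a C2H2 zinc finger, and group III one
domain with a C2HC (CCHC) zinc finger.  Group II subgroups IIa-IIe are
resolved by phylogenetic proximity to labelled reference proteins (minimum
patristic distance), a deterministic stand-in for visual clade assignment.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .domain_scan import DomainHit
from .phylo import TreeNode, leaf_distances

__all__ = ["GroupCall", "SUBGROUPS", "call_major_group", "resolve_subgroup"]

SUBGROUPS = ("IIa", "IIb", "IIc", "IId", "IIe")


class ClassifyError(ValueError):
    """Raised for unclassifiable inputs (no domains, missing references)."""


@dataclass
class GroupCall:
    """A structural group assignment with its supporting evidence."""

    group: str  # "I", "IIa".."IIe", "III", or "II" when the subgroup is unresolved
    n_domains: int
    zf_type: str
    nearest_reference: str | None = None
    missing_zinc_finger: bool = False

    @property
    def major_group(self) -> str:
        return "II" if self.group.startswith("II") and self.group != "III" else self.group


def call_major_group(hits: Sequence[DomainHit]) -> GroupCall:
    """Major-group call from domain count and zinc-finger type.

    Two or more WRKY domains -> group I; one domain with a C2HC finger ->
    group III; one domain with a C2H2 finger -> group II (subgroup left
    unresolved).  When hits disagree on finger type, the C-terminal domain's
    type decides.  A single domain with no detectable finger is kept in the
    family as group II with the missing finger flagged.
    """
    if not hits:
        raise ClassifyError("cannot classify a protein with no WRKY domain")
    ordered = sorted(hits, key=lambda h: h.hepta_start)
    zf = ordered[-1].zf_type
    n = len(ordered)
    if n >= 2:
        return GroupCall("I", n, zf)
    if zf == "C2HC":
        return GroupCall("III", 1, zf)
    return GroupCall("II", 1, zf, missing_zinc_finger=(zf == "none"))


def resolve_subgroup(
    copy_id: str,
    tree_with_references: TreeNode,
    reference_labels: Mapping[str, str],
    base_call: GroupCall | None = None,
) -> GroupCall:
    """Resolve a group-II subgroup by nearest labelled reference in the tree.

    The subgroup is the label of the reference leaf at minimum path-length
    distance from the copy; ties are broken by alphabetical subgroup order.
    All subgroups IIa-IIe must be represented among the references.
    """
    present = set(reference_labels.values())
    missing = [s for s in SUBGROUPS if s not in present]
    if missing:
        raise ClassifyError(f"missing reference(s) for subgroup(s): {', '.join(missing)}")
    names, d = leaf_distances(tree_with_references)
    index = {nm: i for i, nm in enumerate(names)}
    if copy_id not in index:
        raise ClassifyError(f"copy {copy_id!r} is not a leaf of the tree")
    row = d[index[copy_id]]
    best = min(
        (
            (row[index[ref]], reference_labels[ref], ref)
            for ref in reference_labels
            if ref in index
        ),
        key=lambda t: (t[0], t[1], t[2]),
        default=None,
    )
    if best is None:
        raise ClassifyError("no reference leaves present in the tree")
    _, subgroup, ref = best
    if base_call is not None:
        return replace(base_call, group=subgroup, nearest_reference=ref)
    return GroupCall(subgroup, 1, "C2H2", nearest_reference=ref)
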
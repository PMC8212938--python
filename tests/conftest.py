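"""Shared fixtures and small construction helpers for the test suite."""
from __future__ import annotations

import pytest

from familymap.io_formats import ProteinRecord
from familymap.homeolog import HomeologGroup


def make_record(
    gene_id: str,
    subgenome: str | None = None,
    complement: int | None = None,
    start: int | None = None,
    isoform: int = 1,
    sequence: str = "M",
) -> ProteinRecord:
    chromosome = f"{complement}{subgenome}" if complement and subgenome else None
    return ProteinRecord(
        record_id=f"{gene_id}.{isoform}",
        gene_id=gene_id,
        isoform_index=isoform,
        sequence=sequence,
        chromosome=chromosome,
        complement=complement,
        subgenome=subgenome,
        start=start,
        end=(start + 99) if start is not None else None,
    )


def make_table1_groups() -> list[HomeologGroup]:
    """A catalog with the wheat family's homeolog-type architecture:
    75 triads, 1 A:B, 12 A:D, 7 B:D, 10 A, 4 B, 15 D over complements 1-7."""
    plan = [("A:B:D", 75), ("A:B", 1), ("A:D", 12), ("B:D", 7),
            ("A", 10), ("B", 4), ("D", 15)]
    groups = []
    i = 0
    for htype, count in plan:
        subs = htype.split(":")
        for _ in range(count):
            i += 1
            comp = (i - 1) % 7 + 1
            members = [
                make_record(f"t{i:03d}{s}", subgenome=s, complement=comp,
                            start=1000 * i)
                for s in subs
            ]
            groups.append(HomeologGroup(members=members, complement=comp,
                                        homeolog_type=htype))
    return groups


@pytest.fixture
def table1_groups():
    return make_table1_groups()
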
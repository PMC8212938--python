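"""WRKY domain and zinc-finger motif detection, and splice-isoform collapsing.

The scanner is a deterministic motif-based detector: it finds occurrences of
the WRKY heptapeptide (WRKYGQK by default, with the common WRKYGKK/WRKYGEK
variants admitted in permissive mode) and attaches the nearest downstream
zinc-finger motif, typed as C2H2 (C-x(4,5)-C-x(22,23)-H-x-H) or C2HC
(C-x(7)-C-x(23)-H-x-C).  It deliberately replaces profile-HMM scoring with
exact motif matching, trading sensitivity on degenerate domains for full
determinism.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import ProteinRecord

__all__ = [
    "DomainHit",
    "DEFAULT_HEPTAPEPTIDES",
    "STRICT_HEPTAPEPTIDES",
    "DEFAULT_MAX_ZF_GAP",
    "find_wrky_domains",
    "scan_proteome",
    "collapse_isoforms",
]

DEFAULT_HEPTAPEPTIDES = frozenset({"WRKYGQK", "WRKYGKK", "WRKYGEK"})
STRICT_HEPTAPEPTIDES = frozenset({"WRKYGQK"})
DEFAULT_MAX_ZF_GAP = 60

_ZF_PATTERNS = (
    ("C2H2", re.compile(r"C.{4,5}C.{22,23}H.H")),
    ("C2HC", re.compile(r"C.{7}C.{23}H.C")),
)


class ScanError(ValueError):
    """Raised for invalid scanner inputs (duplicate isoforms, bad config)."""


@dataclass
class DomainHit:
    """A located WRKY domain.

    ``hepta_start`` and ``zf_span`` are 1-based; ``zf_span`` is inclusive and
    unset when no zinc finger was found within the allowed gap.
    """

    heptapeptide: str
    hepta_start: int
    zf_type: str = "none"
    zf_span: tuple[int, int] | None = None


def _nearest_zinc_finger(seq: str, hepta_end0: int, max_zf_gap: int):
    """Earliest zinc-finger match whose first cysteine lies within
    ``max_zf_gap`` residues downstream of the heptapeptide end.

    If both patterns match, the one whose first cysteine is nearest wins;
    ties go to C2H2 (pattern order).
    """
    best = None  # (first_c_offset, order, type, span)
    for order, (zf_type, pat) in enumerate(_ZF_PATTERNS):
        m = pat.search(seq, hepta_end0)
        if m is None:
            continue
        gap = m.start() - hepta_end0
        if gap > max_zf_gap:
            continue
        cand = (gap, order, zf_type, (m.start() + 1, m.end()))
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        return "none", None
    return best[2], best[3]


def find_wrky_domains(
    seq: str,
    allowed_heptapeptides: Iterable[str] = DEFAULT_HEPTAPEPTIDES,
    max_zf_gap: int = DEFAULT_MAX_ZF_GAP,
) -> list[DomainHit]:
    """All non-overlapping WRKY heptapeptide occurrences with attached
    zinc-finger typing, scanned left to right."""
    allowed = frozenset(allowed_heptapeptides)
    if any(len(h) != 7 for h in allowed):
        raise ScanError("allowed heptapeptides must be 7-mers")
    hits: list[DomainHit] = []
    i = 0
    n = len(seq)
    while i + 7 <= n:
        window = seq[i:i + 7]
        if window in allowed:
            zf_type, zf_span = _nearest_zinc_finger(seq, i + 7, max_zf_gap)
            hits.append(DomainHit(window, i + 1, zf_type, zf_span))
            i += 7
        else:
            i += 1
    return hits


def scan_proteome(
    records: Sequence[ProteinRecord],
    allowed_heptapeptides: Iterable[str] = DEFAULT_HEPTAPEPTIDES,
    max_zf_gap: int = DEFAULT_MAX_ZF_GAP,
) -> list[tuple[ProteinRecord, list[DomainHit]]]:
    """Family candidates: records carrying at least one WRKY domain, in input
    order, each paired with its position-sorted hits."""
    out = []
    for rec in records:
        hits = find_wrky_domains(rec.sequence, allowed_heptapeptides, max_zf_gap)
        if hits:
            out.append((rec, hits))
    return out


def _collapse_sort_key(r: ProteinRecord):
    return (
        r.complement is None,
        r.complement if r.complement is not None else 0,
        r.subgenome or "~",
        r.start if r.start is not None else 0,
        r.gene_id,
    )


def collapse_isoforms(candidates: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Keep exactly one record per gene: the smallest isoform index.

    Output is sorted by (complement, subgenome, start); unplaced records sort
    last.  Idempotent.  Duplicate (gene_id, isoform_index) pairs are an error.
    """
    seen: set[tuple[str, int]] = set()
    best: dict[str, ProteinRecord] = {}
    for rec in candidates:
        key = (rec.gene_id, rec.isoform_index)
        if key in seen:
            raise ScanError(f"duplicate record for {rec.gene_id}.{rec.isoform_index}")
        seen.add(key)
        cur = best.get(rec.gene_id)
        if cur is None or rec.isoform_index < cur.isoform_index:
            best[rec.gene_id] = rec
    return sorted(best.values(), key=_collapse_sort_key)
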
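"""Seeded generator of allohexaploid synthetic proteomes with planted WRKY
family structure.

The generator emulates the input the family-cataloguing pipeline sees on a
real hexaploid wheat proteome: three subgenomes (A/B/D) with homeologous
gene groups in configurable retention types, planted WRKY motif cassettes
(heptapeptide plus a zinc finger of the planned structural group), multiple
splice isoforms for a chosen subset of gene copies, and motif-free background
proteins.  Every pipeline stage is therefore testable against known ground
truth without any download.

Divergence structure
--------------------
Copies of one gene differ by ``within_triad_divergence`` substitutions/site;
distinct genes are organised into "clans" of up to seven genes, one per
chromosome complement, sharing a clan root mutated per gene at
``between_gene_divergence``; different clans have independent root backbones.
Because every pair of genes close enough to be tree-adjacent then sits on
*different* complements, the maximal-clade homeolog grouping rule can never
merge two distinct genes, making planted-structure recovery exact by
construction at the default divergences.

Family backbones and substitutions are drawn from a 17-letter alphabet that
excludes W, C and H, so the planted heptapeptides and zinc-finger C/H
positions are the only motif matches in family sequences; background proteins
use the full 20-letter alphabet with heptapeptide-containing draws rejected.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path


import numpy as np

from .io_formats import ProteinRecord, write_fasta

__all__ = [
    "SimConfig",
    "SimConfigError",
    "GroundTruth",
    "SimResult",
    "RecoveryReport",
    "generate",
    "score_recovery",
    "TABLE1_TYPE_COUNTS",
    "DEFAULT_COMPLEMENT_COUNTS",
    "DEFAULT_GROUP_PLAN",
]

HEPTAPEPTIDE = "WRKYGQK"
FAMILY_ALPHABET = "ADEFGIKLMNPQRSTVY"  # no W/C/H: planted motifs stay unique
FULL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_REJECT_HEPTAS = ("WRKYGQK", "WRKYGKK", "WRKYGEK")

TABLE1_TYPE_COUNTS = {
    "A:B:D": 75, "A:B": 1, "A:D": 12, "B:D": 7, "A": 10, "B": 4, "D": 15,
}
DEFAULT_COMPLEMENT_COUNTS = {1: 24, 2: 19, 3: 19, 4: 19, 5: 19, 6: 5, 7: 19}
DEFAULT_GROUP_PLAN = {
    "I": 52, "III": 94, "IIa": 8, "IIb": 16, "IIc": 60, "IId": 24, "IIe": 40,
}
_GROUP_ORDER = ("I", "III", "IIa", "IIb", "IIc", "IId", "IIe")


class SimConfigError(ValueError):
    """Raised for infeasible or inconsistent simulation plans."""


@dataclass
class SimConfig:
    """Simulation plan; the defaults mirror the catalogued wheat family
    architecture (75 triads, 20 two-copy genes, 29 orphans = 294 copies of
    124 genes; 47 copies with extra splice isoforms totalling 59)."""

    seed: int = 0
    type_counts: dict = field(default_factory=lambda: dict(TABLE1_TYPE_COUNTS))
    per_complement_counts: dict = field(
        default_factory=lambda: dict(DEFAULT_COMPLEMENT_COUNTS)
    )
    group_plan: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_PLAN))
    n_multi_isoform: int = 47
    extra_isoforms_total: int = 59
    n_background: int = 500
    within_triad_divergence: float = 0.08
    between_gene_divergence: float = 0.25
    protein_length_range: tuple = (130, 210)

    @property
    def n_genes(self) -> int:
        return sum(self.type_counts.values())

    @property
    def n_copies(self) -> int:
        return sum(
            (t.count(":") + 1) * c for t, c in self.type_counts.items()
        )

    def validate(self) -> None:
        for t in self.type_counts:
            subs = t.split(":")
            if not subs or any(s not in "ABD" for s in subs) or len(subs) != len(set(subs)):
                raise SimConfigError(f"bad homeolog type {t!r}")
        if any(v < 0 for v in self.type_counts.values()):
            raise SimConfigError("negative type count")
        if set(self.per_complement_counts) - set(range(1, 8)):
            raise SimConfigError("complements must be 1-7")
        if sum(self.per_complement_counts.values()) != self.n_genes:
            raise SimConfigError(
                "per-complement counts must sum to the number of genes"
            )
        if sum(self.group_plan.values()) != self.n_copies:
            raise SimConfigError("group plan must sum to the number of gene copies")
        if self.extra_isoforms_total < self.n_multi_isoform:
            raise SimConfigError(
                "extra_isoforms_total must be >= n_multi_isoform "
                "(each multi-isoform gene needs at least one extra isoform)"
            )
        if self.n_multi_isoform > self.n_copies:
            raise SimConfigError("more multi-isoform genes than gene copies")
        if not 0.0 <= self.within_triad_divergence < self.between_gene_divergence <= 1.0:
            raise SimConfigError(
                "need 0 <= within_triad_divergence < between_gene_divergence <= 1"
            )
        lo, hi = self.protein_length_range
        if lo < 120 or hi < lo:
            raise SimConfigError("protein lengths must satisfy 120 <= min <= max")


@dataclass
class GroundTruth:
    """The planted structure the pipeline is expected to recover."""

    grouping: dict  # gene key -> sorted copy gene_ids
    types: dict  # gene key -> homeolog type
    complements: dict  # gene key -> complement
    copy_labels: dict  # copy gene_id -> planted structural group (I, IIa.., III)
    isoform_map: dict  # copy gene_id -> record ids, isoform order
    n_genes: int
    n_copies: int
    n_family_records: int
    n_background: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimResult:
    records: list  # ProteinRecords in FASTA order (family first, then background)
    coordinates: dict  # gene_id -> (chromosome, start, end)
    truth: GroundTruth

    def write(self, outdir) -> dict:
        """Emit proteome FASTA, coordinate TSV, and ground-truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "proteome.fasta"
        coords = outdir / "coordinates.tsv"
        truth = outdir / "ground_truth.json"
        write_fasta(self.records, fasta)
        with open(coords, "w") as fh:
            fh.write("gene_id\tchromosome\tstart\tend\n")
            for gid, (chrom, start, end) in self.coordinates.items():
                fh.write(f"{gid}\t{chrom}\t{start}\t{end}\n")
        truth.write_text(json.dumps(self.truth.as_dict(), indent=1))
        return {"fasta": fasta, "coordinates": coords, "truth": truth}


# ---------------------------------------------------------------------------
# plan solving
# ---------------------------------------------------------------------------


def _assign_groups(genes: list[dict], plan: dict, rng: np.random.Generator) -> None:
    """Assign a structural group to every gene so per-copy totals hit the plan."""
    pools = {k: [g for g in genes if len(g["subgenomes"]) == k] for k in (3, 2, 1)}
    for k in pools:
        rng.shuffle(pools[k])
    order = [g for g in _GROUP_ORDER if g in plan]
    order += sorted(set(plan) - set(order))
    for grp in order:
        t = plan[grp]
        x = min(len(pools[3]), t // 3)
        while True:
            rem = t - 3 * x
            y = min(len(pools[2]), rem // 2)
            z = rem - 2 * y
            if z <= len(pools[1]):
                break
            if x == 0:
                raise SimConfigError(
                    f"group plan infeasible: cannot allocate {t} copies to {grp}"
                )
            x -= 1
        for _ in range(x):
            pools[3].pop()["group"] = grp
        for _ in range(y):
            pools[2].pop()["group"] = grp
        for _ in range(z):
            pools[1].pop()["group"] = grp
    leftover = sum(len(p) for p in pools.values())
    if leftover:
        raise SimConfigError("group plan does not cover every gene")


def _assign_complements(genes: list[dict], quotas: dict, rng: np.random.Generator) -> None:
    comp_list = [c for c in sorted(quotas) for _ in range(quotas[c])]
    order = rng.permutation(len(genes))
    for slot, gi in enumerate(order):
        genes[gi]["complement"] = comp_list[slot]


def _assign_clans(genes: list[dict], quotas: dict) -> int:
    """Clans of <=7 genes with pairwise-distinct complements, balanced fill."""
    n_genes = len(genes)
    n_clans = max(math.ceil(n_genes / 7), max(quotas.values(), default=1))
    fill = [0] * n_clans
    for comp in sorted(quotas, key=lambda c: (-quotas[c], c)):
        taken: set[int] = set()
        for g in (g for g in genes if g["complement"] == comp):
            clan = min(
                (t for t in range(n_clans) if t not in taken),
                key=lambda t: (fill[t], t),
            )
            taken.add(clan)
            fill[clan] += 1
            g["clan"] = clan
    return n_clans


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------


def _random_string(rng: np.random.Generator, alphabet: str, n: int) -> list[str]:
    return [alphabet[i] for i in rng.integers(0, len(alphabet), size=n)]


def _mutate(
    seq: list[str],
    rate: float,
    rng: np.random.Generator,
    protected: frozenset[int],
) -> list[str]:
    """Substitute ``round(rate * n_mutable)`` distinct non-cassette positions
    with a different residue from the family alphabet.  No indels."""
    out = list(seq)
    mutable = [i for i in range(len(seq)) if i not in protected]
    n_mut = round(rate * len(mutable))
    if n_mut == 0:
        return out
    picks = rng.choice(len(mutable), size=n_mut, replace=False)
    for p in picks:
        pos = mutable[p]
        old = out[pos]
        choices = [c for c in FAMILY_ALPHABET if c != old]
        out[pos] = choices[int(rng.integers(0, len(choices)))]
    return out


def _cassette(zf_type: str, rng: np.random.Generator) -> tuple[str, int]:
    """A motif cassette: heptapeptide, 5-residue linker, zinc finger."""
    x = lambda n: "".join(_random_string(rng, FAMILY_ALPHABET, n))
    if zf_type == "C2H2":
        zf = "C" + x(4) + "C" + x(22) + "H" + x(1) + "H"
    elif zf_type == "C2HC":
        zf = "C" + x(7) + "C" + x(23) + "H" + x(1) + "C"
    else:  # pragma: no cover - internal misuse
        raise SimConfigError(f"unknown zinc-finger type {zf_type!r}")
    cass = HEPTAPEPTIDE + x(5) + zf
    return cass, len(cass)


def _plant_cassettes(
    backbone: list[str],
    group: str,
    cassettes: dict[str, str],
) -> tuple[list[str], frozenset[int]]:
    """Overwrite the backbone with the family-shared motif cassette(s).

    Cassette content is shared across the whole family and positions are
    proportional to protein length (the WRKY domain is strongly conserved in
    both sequence and position), which keeps family members colinear in the
    multiple alignment: group I carries two cassettes in the N- and C-terminal
    halves, other groups one central cassette.
    """
    L = len(backbone)
    seq = list(backbone)
    protected: set[int] = set()

    def place(pos: int, cass: str) -> None:
        seq[pos:pos + len(cass)] = list(cass)
        protected.update(range(pos, pos + len(cass)))

    if group == "I":
        cass = cassettes["C2H2"]
        free = L - 2 * len(cass)
        p1 = free // 4
        p2 = p1 + len(cass) + free // 2
        place(p1, cass)
        place(p2, cass)
    else:
        cass = cassettes["C2HC" if group == "III" else "C2H2"]
        place((L - len(cass)) // 2, cass)
    return seq, frozenset(protected)


def _background_protein(rng: np.random.Generator, lo: int, hi: int) -> str:
    while True:
        seq = "".join(
            _random_string(rng, FULL_ALPHABET, int(rng.integers(lo, hi + 1)))
        )
        if not any(h in seq for h in _REJECT_HEPTAS):
            return seq


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate(config: SimConfig) -> SimResult:
    """Generate a synthetic allohexaploid proteome with planted family structure.

    Fully reproducible for a fixed ``config.seed``: the same config yields
    byte-identical FASTA output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes: list[dict] = []
    for htype in list(TABLE1_TYPE_COUNTS) + sorted(
        set(config.type_counts) - set(TABLE1_TYPE_COUNTS)
    ):
        for _ in range(config.type_counts.get(htype, 0)):
            genes.append({"type": htype, "subgenomes": htype.split(":")})

    _assign_groups(genes, config.group_plan, rng)
    _assign_complements(genes, config.per_complement_counts, rng)
    n_clans = _assign_clans(genes, config.per_complement_counts)

    lo, hi = config.protein_length_range
    clan_len = [int(rng.integers(lo, hi + 1)) for _ in range(n_clans)]
    clan_root = [
        _random_string(rng, FAMILY_ALPHABET, clan_len[t]) for t in range(n_clans)
    ]
    # one conserved cassette per zinc-finger type, shared family-wide
    cassettes = {zf: _cassette(zf, rng)[0] for zf in ("C2H2", "C2HC")}

    family_records: list[ProteinRecord] = []
    coordinates: dict[str, tuple[str, int, int]] = {}
    grouping: dict[str, list[str]] = {}
    types: dict[str, str] = {}
    complements: dict[str, int] = {}
    copy_labels: dict[str, str] = {}
    per_comp_index: dict[int, int] = {}

    # genes within a clan form a mutation chain: each backbone derives from
    # the previous gene's backbone, so every gene's nearest relative is a
    # chain neighbour on a different chromosome complement
    chain_state = list(clan_root)
    for num, gene in enumerate(genes, start=1):
        key = f"g{num:03d}"
        clan = gene["clan"]
        backbone = chain_state[clan]
        chain_state[clan] = _mutate(
            backbone, config.between_gene_divergence, rng, frozenset()
        )
        backbone, protected = _plant_cassettes(backbone, gene["group"], cassettes)
        L = len(backbone)
        comp = gene["complement"]
        idx = per_comp_index.get(comp, 0)
        per_comp_index[comp] = idx + 1
        start = 10_000 * (idx + 1)
        end = start + 3 * L - 1
        copy_ids = []
        for sub in gene["subgenomes"]:
            seq = _mutate(backbone, config.within_triad_divergence, rng, protected)
            gid = f"{key}_c{comp}{sub}"
            rec = ProteinRecord(
                record_id=f"{gid}.1",
                gene_id=gid,
                isoform_index=1,
                sequence="".join(seq),
                chromosome=f"{comp}{sub}",
                complement=comp,
                subgenome=sub,
                start=start,
                end=end,
            )
            family_records.append(rec)
            coordinates[gid] = (rec.chromosome, start, end)
            copy_ids.append(gid)
            copy_labels[gid] = gene["group"]
        grouping[key] = sorted(copy_ids)
        types[key] = gene["type"]
        complements[key] = comp

    # splice isoforms: identical sequence, incremented suffix
    n_copies = len(family_records)
    chosen = rng.choice(n_copies, size=config.n_multi_isoform, replace=False)
    extras = np.ones(config.n_multi_isoform, dtype=int)
    for _ in range(config.extra_isoforms_total - config.n_multi_isoform):
        extras[int(rng.integers(0, config.n_multi_isoform))] += 1
    extra_by_copy = {int(c): int(e) for c, e in zip(chosen, extras)}

    isoform_map: dict[str, list[str]] = {}
    records_with_isoforms: list[ProteinRecord] = []
    for pos, rec in enumerate(family_records):
        records_with_isoforms.append(rec)
        ids = [rec.record_id]
        for k in range(extra_by_copy.get(pos, 0)):
            iso = ProteinRecord(
                record_id=f"{rec.gene_id}.{k + 2}",
                gene_id=rec.gene_id,
                isoform_index=k + 2,
                sequence=rec.sequence,
                chromosome=rec.chromosome,
                complement=rec.complement,
                subgenome=rec.subgenome,
                start=rec.start,
                end=rec.end,
            )
            records_with_isoforms.append(iso)
            ids.append(iso.record_id)
        isoform_map[rec.gene_id] = ids

    background = [
        ProteinRecord(
            record_id=f"bg{i + 1:04d}",
            gene_id=f"bg{i + 1:04d}",
            isoform_index=1,
            sequence=_background_protein(rng, lo, hi),
        )
        for i in range(config.n_background)
    ]

    truth = GroundTruth(
        grouping=grouping,
        types=types,
        complements=complements,
        copy_labels=copy_labels,
        isoform_map=isoform_map,
        n_genes=len(genes),
        n_copies=n_copies,
        n_family_records=len(records_with_isoforms),
        n_background=len(background),
    )
    return SimResult(records_with_isoforms + background, coordinates, truth)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """Exact-match rates of the pipeline output against the planted truth."""

    grouping: float
    homeolog_types: float
    group_labels: float
    isoform_collapse: float

    @property
    def all_perfect(self) -> bool:
        return all(
            r == 1.0
            for r in (self.grouping, self.homeolog_types,
                      self.group_labels, self.isoform_collapse)
        )

    def as_dict(self) -> dict:
        return asdict(self)


def _major(label: str) -> str:
    return "II" if label.startswith("II") and label != "III" else label


def score_recovery(truth: GroundTruth, catalog) -> RecoveryReport:
    """Exact-match recovery rates for grouping, homeolog types, structural
    group labels, and isoform collapse.

    ``catalog`` is a FamilyCatalog (or anything with ``collapsed`` records,
    ``groups``, and per-record ``calls``).  A mismatch between the planted and
    catalogued copy sets is an error.
    """
    truth_copies = {gid for ids in truth.grouping.values() for gid in ids}
    catalog_copies = {r.gene_id for r in catalog.collapsed}
    if not catalog_copies:
        return RecoveryReport(0.0, 0.0, 0.0, 0.0)
    if truth_copies != catalog_copies:
        raise SimConfigError(
            "catalog copies do not match planted copies "
            f"(missing {sorted(truth_copies - catalog_copies)[:3]}..., "
            f"extra {sorted(catalog_copies - truth_copies)[:3]}...)"
        )
    inferred = {
        frozenset(m.gene_id for m in g.members): g for g in catalog.groups
    }
    n_genes = len(truth.grouping)
    group_hits = 0
    type_hits = 0
    for key, ids in truth.grouping.items():
        fs = frozenset(ids)
        if fs in inferred:
            group_hits += 1
            if inferred[fs].homeolog_type == truth.types[key]:
                type_hits += 1
    calls = catalog.calls
    label_hits = sum(
        1
        for r in catalog.collapsed
        if r.record_id in calls
        and _major(calls[r.record_id].group) == _major(truth.copy_labels[r.gene_id])
    )
    iso_hits = sum(1 for r in catalog.collapsed if r.isoform_index == 1)
    n_copies = len(catalog.collapsed)
    return RecoveryReport(
        grouping=group_hits / n_genes if n_genes else 0.0,
        homeolog_types=type_hits / n_genes if n_genes else 0.0,
        group_labels=label_hits / n_copies if n_copies else 0.0,
        isoform_collapse=iso_hits / n_copies if n_copies else 0.0,
    )
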
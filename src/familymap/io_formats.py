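"""File formats and accession parsing.

Readers/writers for protein FASTA, gene-coordinate tables, newick trees, and
the family-catalog report, plus ID parsing for IWGSC-style accessions such as
``TraesCS4A02G123456.1`` (chromosome complement 4, subgenome A, isoform 1).

ID parsing is total: headers that match neither the IWGSC grammar nor the
generator's ``gN_cKS.i`` grammar fall back to ``gene_id[.isoform]`` with the
chromosome fields left unset rather than guessed.  Coordinates are 1-based
inclusive throughout (GFF3 convention).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylo import TreeNode

__all__ = [
    "FormatError",
    "ProteinRecord",
    "parse_accession",
    "parse_chromosome",
    "read_fasta",
    "write_fasta",
    "read_coordinates",
    "apply_coordinates",
    "newick_string",
    "write_newick",
    "read_newick",
    "write_catalog",
    "CATALOG_COLUMNS",
]

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_IWGSC_RE = re.compile(r"^(TraesCS(?:([1-7])([ABD])|U)02G\d{6}(?:LC)?)(?:\.(\d+))?$")
_SYNTH_RE = re.compile(r"^(g\d+_c([1-7])([ABD]))(?:\.(\d+))?$")
_CHROM_RE = re.compile(r"^([1-7])([ABD])$")

CATALOG_COLUMNS = [
    "name", "gene_id", "subgenome", "complement", "homeolog_type",
    "group", "chromosome", "start", "end",
]


class FormatError(ValueError):
    """Raised for malformed input files or accessions."""


@dataclass
class ProteinRecord:
    """One FASTA entry with its parsed locus information.

    ``gene_id`` is the accession without the isoform suffix; ``complement``
    (homeologous chromosome group, 1-7) and ``subgenome`` (A/B/D) are both
    unset for unplaced or unrecognized loci.
    """

    record_id: str
    gene_id: str
    isoform_index: int
    sequence: str
    chromosome: str | None = None
    complement: int | None = None
    subgenome: str | None = None
    start: int | None = None
    end: int | None = None


def parse_accession(record_id: str) -> tuple[str, int, str | None, int | None, str | None]:
    """Parse an accession into (gene_id, isoform_index, chromosome, complement, subgenome)."""
    for pat in (_IWGSC_RE, _SYNTH_RE):
        m = pat.match(record_id)
        if m:
            gene_id, comp, sub, iso = m.group(1), m.group(2), m.group(3), m.group(4)
            chromosome = f"{comp}{sub}" if comp else "U"
            return (
                gene_id,
                int(iso) if iso else 1,
                chromosome,
                int(comp) if comp else None,
                sub,
            )
    base, dot, tail = record_id.rpartition(".")
    if dot and base and tail.isdigit():
        return base, int(tail), None, None, None
    return record_id, 1, None, None, None


def parse_chromosome(label: str | None) -> tuple[int | None, str | None]:
    """Chromosome label such as '4A' -> (complement, subgenome); 'U'/unknown -> (None, None)."""
    if label is None:
        return None, None
    m = _CHROM_RE.match(label)
    if not m:
        return None, None
    return int(m.group(1)), m.group(2)


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA into ProteinRecords, order preserved.

    Sequences are uppercased with a trailing stop symbol ``*`` stripped;
    residues outside the 20 standard amino acids plus X are rejected.
    """
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if not acc:
            raise FormatError(f"{path}: FASTA entry with an empty accession")
        seq = str(rec.seq).upper().rstrip("*")
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"record {acc!r}: invalid residue(s) {''.join(sorted(bad))!r}"
            )
        gene_id, iso, chromosome, complement, subgenome = parse_accession(acc)
        records.append(
            ProteinRecord(acc, gene_id, iso, seq, chromosome, complement, subgenome)
        )
    return records


def write_fasta(records, path, width: int = 70) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.record_id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_coordinates(path) -> dict[str, tuple[str, int, int]]:
    """Read a gene-coordinate TSV (gene_id, chromosome, start, end).

    Returns a mapping gene_id -> (chromosome, start, end) with 1-based
    inclusive coordinates.  Duplicate gene ids and start > end are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    required = {"gene_id", "chromosome", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    out: dict[str, tuple[str, int, int]] = {}
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if start > end:
            raise FormatError(f"{path}: start > end for gene {row.gene_id!r}")
        out[row.gene_id] = (str(row.chromosome), start, end)
    return out


def apply_coordinates(records, coords) -> list[ProteinRecord]:
    """Return records with chromosome/complement/subgenome/start/end overridden
    from a coordinate mapping; records absent from the mapping are unchanged."""
    out = []
    for r in records:
        if r.gene_id in coords:
            chromosome, start, end = coords[r.gene_id]
            complement, subgenome = parse_chromosome(chromosome)
            out.append(
                replace(r, chromosome=chromosome, complement=complement,
                        subgenome=subgenome, start=start, end=end)
            )
        else:
            out.append(r)
    return out


def newick_string(tree: TreeNode) -> str:
    """Serialize a tree: branch lengths at 6 decimals, integer bootstrap
    supports as internal-node labels."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            s = node.label or ""
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.support is not None:
                s += str(int(node.support))
        if node.length is not None:
            s += f":{node.length:.6f}"
        return s

    return fmt(tree) + ";"


def write_newick(tree: TreeNode, path) -> None:
    if tree.is_leaf:
        raise FormatError("refusing to write an empty (single-leaf) tree")
    Path(path).write_text(newick_string(tree) + "\n")


def read_newick(path) -> TreeNode:
    t = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )

    def conv(nd) -> TreeNode:
        if nd.is_leaf():
            return TreeNode(label=nd.taxon.label, length=nd.edge.length)
        node = TreeNode(
            children=[conv(c) for c in nd.child_nodes()], length=nd.edge.length
        )
        if nd.label is not None and str(nd.label).strip().isdigit():
            node.support = int(str(nd.label).strip())
        return node

    return conv(t.seed_node)


def write_catalog(catalog, path) -> None:
    """Write the catalog TSV, one row per gene copy.

    ``catalog`` is anything exposing ``to_frame()`` (a FamilyCatalog) or a
    pandas DataFrame with the catalog columns.
    """
    frame = catalog.to_frame() if hasattr(catalog, "to_frame") else catalog
    frame.to_csv(path, sep="\t", index=False)
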
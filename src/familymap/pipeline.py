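"""End-to-end orchestration: scan -> tree -> group -> name -> classify -> stats.

``run_all`` executes the whole family-cataloguing pipeline on either a
generated synthetic proteome or user-supplied FASTA/coordinate files, and
returns a :class:`FamilyCatalog` aggregating every stage's output together
with a machine-readable run manifest.  Reruns with the same config and seed
produce identical catalogs.
"""
from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import (
    CATALOG_COLUMNS,
    ProteinRecord,
    apply_coordinates,
    read_coordinates,
    read_fasta,
    write_catalog,
    write_newick,
)
from .domain_scan import (
    DEFAULT_HEPTAPEPTIDES,
    DEFAULT_MAX_ZF_GAP,
    STRICT_HEPTAPEPTIDES,
    collapse_isoforms,
    scan_proteome,
)
from .phylo import (
    TreeNode,
    bootstrap_support,
    distance_from_alignment,
    neighbor_joining,
    progressive_msa,
)
from .homeolog import assign_names, infer_groups, summary_stats
from .classify import GroupCall, call_major_group, resolve_subgroup
from .synthetic_data import GroundTruth, SimConfig, generate, score_recovery

__all__ = ["PipelineConfig", "FamilyCatalog", "run_all"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the failing stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run configuration; every field has a logged default."""

    seed: int = 0
    simulate: bool = True
    sim: SimConfig | None = None
    fasta: str | None = None
    coordinates: str | None = None
    strict_heptapeptides: bool = False
    max_zf_gap: int = DEFAULT_MAX_ZF_GAP
    distance_model: str = "p_distance"
    gap_open: float = -10.0
    gap_extend: float = -1.0
    n_bootstrap: int = 0
    prefix: str = "TaWRKY"
    references: str | None = None

    def __post_init__(self) -> None:
        if self.simulate and self.sim is None:
            self.sim = SimConfig(seed=self.seed)

    @property
    def heptapeptides(self) -> frozenset:
        return STRICT_HEPTAPEPTIDES if self.strict_heptapeptides else DEFAULT_HEPTAPEPTIDES

    def as_dict(self) -> dict:
        d = asdict(self)
        if self.sim is not None:
            d["sim"] = asdict(self.sim)
        d["heptapeptides"] = sorted(self.heptapeptides)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("sim", None)
        data.pop("heptapeptides", None)
        cfg = cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__})
        if sim is not None:
            sim = dict(sim)
            sim["protein_length_range"] = tuple(sim.get("protein_length_range",
                                                        (130, 210)))
            sim["per_complement_counts"] = {
                int(k): v for k, v in sim.get("per_complement_counts", {}).items()
            } or None
            if sim["per_complement_counts"] is None:
                sim.pop("per_complement_counts")
            cfg.sim = SimConfig(**sim)
        return cfg


@dataclass
class FamilyCatalog:
    """The full result set of one pipeline run."""

    records: list = field(default_factory=list)
    candidates: list = field(default_factory=list)  # (ProteinRecord, hits)
    collapsed: list = field(default_factory=list)
    tree: TreeNode | None = None
    groups: list = field(default_factory=list)
    calls: dict = field(default_factory=dict)  # record_id -> GroupCall
    stats: object = None
    truth: GroundTruth | None = None
    recovery: object = None
    config: PipelineConfig | None = None
    manifest: dict = field(default_factory=dict)

    @property
    def counts(self) -> dict:
        per_gene = Counter(rec.gene_id for rec, _ in self.candidates)
        n_multi = sum(1 for v in per_gene.values() if v >= 2)
        return {
            "n_input_records": len(self.records),
            "n_candidates": len(self.candidates),
            "n_multi_isoform_candidates": n_multi,
            "n_copies": len(self.collapsed),
            "n_genes": len(self.groups),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.groups, key=lambda g: g.serial or 0):
            for m in g.members:
                call = self.calls.get(m.record_id)
                rows.append(
                    {
                        "name": g.member_names.get(m.record_id),
                        "gene_id": m.gene_id,
                        "subgenome": m.subgenome,
                        "complement": m.complement,
                        "homeolog_type": g.homeolog_type,
                        "group": call.group if call else None,
                        "chromosome": m.chromosome,
                        "start": m.start,
                        "end": m.end,
                    }
                )
        return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.as_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        sim = generate(config.sim)
        return sim.records, sim.coordinates, sim.truth
    if not config.fasta:
        raise FileNotFoundError("no input FASTA configured and simulate is off")
    records = read_fasta(config.fasta)
    coords = read_coordinates(config.coordinates) if config.coordinates else {}
    return records, coords, None


def run_all(config: PipelineConfig | None = None, outdir=None) -> FamilyCatalog:
    """Execute every stage in order and return the finished catalog.

    When ``outdir`` is given, writes catalog.tsv, tree.nwk, stats.json, and
    manifest.json (plus recovery.json on simulated runs).
    """
    config = config or PipelineConfig()
    catalog = FamilyCatalog(config=config)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    records, coords, truth = stage("load", lambda: _load_inputs(config))
    if coords:
        records = stage("coordinates", lambda: apply_coordinates(records, coords))
    catalog.records = records
    catalog.truth = truth

    catalog.candidates = stage(
        "scan",
        lambda: scan_proteome(records, config.heptapeptides, config.max_zf_gap),
    )
    hits_by_record = {rec.record_id: hits for rec, hits in catalog.candidates}
    catalog.collapsed = stage(
        "collapse", lambda: collapse_isoforms([rec for rec, _ in catalog.candidates])
    )

    def build_tree() -> TreeNode:
        seqs = [r.sequence for r in catalog.collapsed]
        names = [r.record_id for r in catalog.collapsed]
        if config.n_bootstrap > 0:
            return bootstrap_support(
                seqs,
                n_reps=config.n_bootstrap,
                seed=config.seed,
                names=names,
                model=config.distance_model,
                gap_open=config.gap_open,
                gap_extend=config.gap_extend,
            )
        aln = progressive_msa(seqs, names=names, gap_open=config.gap_open,
                              gap_extend=config.gap_extend)
        return neighbor_joining(distance_from_alignment(aln, config.distance_model))

    catalog.tree = stage("tree", build_tree)
    catalog.groups = stage(
        "group", lambda: infer_groups(catalog.tree, catalog.collapsed)
    )
    catalog.groups = stage(
        "name", lambda: assign_names(catalog.groups, prefix=config.prefix)
    )
    catalog.calls = stage(
        "classify",
        lambda: {
            r.record_id: call_major_group(hits_by_record[r.record_id])
            for r in catalog.collapsed
        },
    )
    if config.references:
        catalog.calls = stage(
            "subgroups", lambda: _resolve_subgroups(catalog, config)
        )
    catalog.stats = stage("stats", lambda: summary_stats(catalog.groups))
    if truth is not None:
        catalog.recovery = stage(
            "recovery", lambda: score_recovery(truth, catalog)
        )

    catalog.manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.as_dict(),
        "config_hash": _config_hash(config),
        "numpy": np.__version__,
        "counts": catalog.counts,
    }
    if outdir is not None:
        stage("write", lambda: _write_outputs(catalog, outdir))
    return catalog


def _resolve_subgroups(catalog: FamilyCatalog, config: PipelineConfig) -> dict:
    """Resolve group-II subgroups against a labelled reference panel.

    Reference FASTA headers carry the subgroup after a pipe, e.g.
    ``>AtWRKY40|IIa``.
    """
    refs = read_fasta(config.references)
    labels = {}
    for r in refs:
        if "|" not in r.record_id:
            raise ValueError(f"reference {r.record_id!r} lacks a |subgroup label")
        labels[r.record_id] = r.record_id.rsplit("|", 1)[1]
    seqs = [r.sequence for r in catalog.collapsed] + [r.sequence for r in refs]
    names = [r.record_id for r in catalog.collapsed] + [r.record_id for r in refs]
    aln = progressive_msa(seqs, names=names, gap_open=config.gap_open,
                          gap_extend=config.gap_extend)
    tree = neighbor_joining(distance_from_alignment(aln, config.distance_model))
    calls = dict(catalog.calls)
    for rec in catalog.collapsed:
        call = calls[rec.record_id]
        if call.group == "II":
            calls[rec.record_id] = resolve_subgroup(
                rec.record_id, tree, labels, base_call=call
            )
    return calls


def _write_outputs(catalog: FamilyCatalog, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_catalog(catalog, outdir / "catalog.tsv")
    if catalog.tree is not None:
        write_newick(catalog.tree, outdir / "tree.nwk")
    (outdir / "stats.json").write_text(json.dumps(catalog.stats.as_dict(), indent=1))
    (outdir / "manifest.json").write_text(
        json.dumps(catalog.manifest, indent=1, default=str)
    )
    if catalog.recovery is not None:
        (outdir / "recovery.json").write_text(
            json.dumps(catalog.recovery.as_dict(), indent=1)
        )
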
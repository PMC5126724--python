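"""Cohort orchestration: run the full comparative pipeline over a set of
annotated genomes and emit machine-readable reports.

Stages: structure detection → canonical rotation → gene inventory →
reference projection → SNP calling → partitioning → hotspot scoring →
barcode filtering.  Per-taxon stage failures are recorded without aborting
the cohort; reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import barcode_screen as bs
from . import divergence as dv
from . import gene_inventory as gi
from . import genome_io as io
from . import quadripartite as qp

__all__ = ["RunConfig", "CohortReport", "run_pipeline", "load_config"]

log = logging.getLogger("plastomics")


@dataclass
class RunConfig:
    """Configuration for one cohort run."""

    genbank_paths: list[str]
    reference: str  # taxon_id of the reference genome (no silent default)
    outdir: str = "plastomics_out"
    min_ir_len: int = 1000
    max_mismatch_frac: float = 0.005
    min_len: int = 200
    max_len: int = 1500
    min_pct: float = 3.0
    window: int = 100
    step: int = 25


def load_config(path) -> RunConfig:
    """Read a flat ``key = value`` config file (paths comma-separated)."""
    raw: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        raw[key.strip()] = val.strip()
    if "genbank_paths" not in raw or "reference" not in raw:
        raise ValueError("config needs genbank_paths and reference")
    kwargs: dict = {
        "genbank_paths": [p.strip() for p in raw.pop("genbank_paths").split(",")],
        "reference": raw.pop("reference"),
    }
    for key, val in raw.items():
        typ = RunConfig.__dataclass_fields__[key].type
        if typ == "int":
            kwargs[key] = int(val)
        elif typ == "float":
            kwargs[key] = float(val)
        else:
            kwargs[key] = val
    return RunConfig(**kwargs)


@dataclass
class CohortReport:
    """All per-cohort result tables plus paths of the emitted files."""

    structure_table: pd.DataFrame
    inventory_table: pd.DataFrame
    divergence: dv.DivergenceSummary | None
    hotspots: list[bs.HotspotCandidate]
    barcodes: list[bs.HotspotCandidate]
    snps: dv.SnpTable | None
    failures: dict[str, str]
    paths: dict[str, str] = field(default_factory=dict)


def _stage(name: str, taxon: str, failures: dict):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                failures[taxon] = f"{name}: {exc}"
                log.error("stage %-12s %-16s FAILED (%s)", name, taxon, exc)
                return True
            log.info("stage %-12s %-16s %.2fs", name, taxon, dt)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> CohortReport:
    """Execute the full comparative analysis for one cohort.

    Requires the designated reference taxon to be present.  A cohort of one
    genome produces structure and inventory tables only; SNP-dependent
    stages are skipped with a notice.
    """
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, force=False)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failures: dict[str, str] = {}

    records = [io.read_genbank(p) for p in config.genbank_paths]
    by_id = {r.taxon_id: r for r in records}
    if config.reference not in by_id:
        raise ValueError(
            f"reference taxon {config.reference!r} not among inputs "
            f"{sorted(by_id)}"
        )

    canonical: dict[str, io.PlastomeRecord] = {}
    structures: dict[str, qp.QuadripartiteStructure] = {}
    profiles = []
    struct_rows = []
    inventories = []
    for rec in records:
        with _stage("structure", rec.taxon_id, failures):
            st = qp.detect_structure(
                rec, config.min_ir_len, config.max_mismatch_frac
            )
            can = qp.canonical_rotation(rec, st)
            st = st.canonical()
            canonical[rec.taxon_id] = can
            structures[rec.taxon_id] = st
            prof = qp.profile_junctions(can, st)
            profiles.append(prof)
            struct_rows.append(
                {
                    "taxon_id": rec.taxon_id,
                    "genome_bp": rec.length_bp,
                    "gc_percent": io.gc_content(rec),
                    "lsc_bp": st.lsc_len,
                    "ssc_bp": st.ssc_len,
                    "ir_bp": st.ir_len,
                    "ir_ssc_junction_gene": prof.jsa[0],
                    "ir_lsc_junction_gene": prof.jlb[0],
                    "expansion": qp.classify_expansion(prof),
                    "ycf1_ndhf_overlap_bp": prof.ycf1_ndhf_overlap,
                    "trni_cau_copies": _trni_copies_or_na(can),
                }
            )
        with _stage("inventory", rec.taxon_id, failures):
            inventories.append(
                gi.build_inventory(canonical.get(rec.taxon_id, rec))
            )

    structure_table = pd.DataFrame(struct_rows)
    inventory_table = (
        gi.compare_inventories(inventories)
        if len(inventories) >= 2
        else _single_inventory_table(inventories)
    )

    snps = None
    summary = None
    hotspots: list[bs.HotspotCandidate] = []
    barcodes: list[bs.HotspotCandidate] = []
    reference = canonical.get(config.reference)
    queries = [
        canonical[r.taxon_id]
        for r in records
        if r.taxon_id != config.reference and r.taxon_id in canonical
    ]
    if reference is not None and queries:
        projections = []
        for q in queries:
            with _stage("align", q.taxon_id, failures):
                projections.append(dv.align_to_reference(reference, q))
        with _stage("snp", config.reference, failures):
            snps = dv.call_snps(reference, projections)
            partition = bs.partition_regions(
                reference, structures[config.reference]
            )
            summary = dv.summarize_divergence(
                snps, partition, reference.length_bp
            )
            hotspots = bs.score_regions(snps, partition)
            barcodes = bs.filter_candidates(
                hotspots, config.min_len, config.max_len, config.min_pct
            )
            primers = bs.end_anchored_primers(reference, partition, barcodes)
            identity = dv.sliding_identity(
                reference, projections, config.window, config.step
            )
            _emit(outdir, reference, snps, summary, partition, hotspots,
                  barcodes, primers, identity, projections)
    else:
        log.info("cohort of one genome: SNP stages skipped")

    paths = {"outdir": str(outdir)}
    structure_table.to_csv(outdir / "structure.tsv", sep="\t", index=False)
    inventory_table.to_csv(outdir / "inventory.tsv", sep="\t")
    paths["structure"] = str(outdir / "structure.tsv")
    paths["inventory"] = str(outdir / "inventory.tsv")
    return CohortReport(
        structure_table=structure_table,
        inventory_table=inventory_table,
        divergence=summary,
        hotspots=hotspots,
        barcodes=barcodes,
        snps=snps,
        failures=failures,
        paths=paths,
    )


def _trni_copies_or_na(record: io.PlastomeRecord):
    try:
        return gi.count_trni_copies(record).copies
    except ValueError:
        return "NA"


def _single_inventory_table(inventories) -> pd.DataFrame:
    if not inventories:
        return pd.DataFrame()
    inv = inventories[0]
    return pd.DataFrame(
        {
            "taxon_id": [inv.taxon_id],
            "total_unique": [inv.total_unique],
            "protein": [len(inv.protein)],
            "trna": [len(inv.trna)],
            "rrna": [len(inv.rrna)],
        }
    )


def _emit(outdir, reference, snps, summary, partition, hotspots, barcodes,
          primers, identity, projections):
    io.write_snp_vcf(snps, reference, outdir / "snps.vcf")
    snps.to_tsv(outdir / "snps.tsv")
    pd.DataFrame([summary.as_dict()]).to_csv(
        outdir / "divergence.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "label": c.label,
                "class": c.region_class,
                "location": c.location,
                "length_bp": c.length_bp,
                "snp_count": c.snp_count,
                "snp_pct": round(c.snp_pct, 3),
                "rank": c.rank,
            }
            for c in hotspots
        ]
    ).to_csv(outdir / "hotspots.tsv", sep="\t", index=False)
    bs.emit_barcode_table(barcodes, primers, outdir / "barcodes.tsv")
    identity.to_csv(outdir / "identity.tsv", sep="\t", index=False)
    io.write_region_bed(
        [(r.interval, f"{r.label}|{r.region_class}") for r in partition.regions],
        reference.length_bp,
        outdir / "regions.bed",
        chrom=reference.taxon_id,
    )
    aligned = {reference.taxon_id: reference.sequence}
    for p in projections:
        aligned[p.taxon_id] = "".join(p.alleles)
    io.write_fasta(aligned, outdir / "alignment.fasta")
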
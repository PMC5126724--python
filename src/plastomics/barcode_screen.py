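"""Partitioning, divergence-hotspot screening and DNA-barcode metrics.

The reference genome is partitioned exhaustively into coding (exons of all
annotated genes), intron (within-gene gaps not covered by any exon) and
spacer (positions covered by no gene) regions; every position belongs to
exactly one class.  Per-region SNP percentages are scored and candidate
barcode loci are the non-coding regions of 200–1,500 bp whose SNP
percentage strictly exceeds 3%.  Primer metrics (GC%, melting temperature)
follow the conventions of short-oligo barcode tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .genome_io import GenomeInterval, PlastomeRecord, revcomp
from .quadripartite import QuadripartiteStructure

__all__ = [
    "Region",
    "RegionPartition",
    "HotspotCandidate",
    "PrimerPair",
    "partition_regions",
    "score_regions",
    "filter_candidates",
    "gc_percent",
    "melting_temp",
    "end_anchored_primers",
    "emit_barcode_table",
]


@dataclass(frozen=True)
class Region:
    interval: GenomeInterval
    label: str
    region_class: str  # coding | intron | spacer
    location: str  # LSC | IRB | SSC | IRA

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class RegionPartition:
    """Exhaustive, non-overlapping classification of reference positions."""

    reference_id: str
    reference_length: int
    regions: list[Region]

    @property
    def coding_length(self) -> int:
        return self._class_len("coding")

    @property
    def intron_length(self) -> int:
        return self._class_len("intron")

    @property
    def spacer_length(self) -> int:
        return self._class_len("spacer")

    def _class_len(self, cls: str) -> int:
        return sum(r.length for r in self.regions if r.region_class == cls)

    def class_of_positions(self, positions: np.ndarray) -> np.ndarray:
        codes = np.full(self.reference_length, "unassigned", dtype=object)
        for r in self.regions:
            for s, e in r.interval.split_at_origin(self.reference_length):
                codes[s:e] = r.region_class
        return codes[positions]


def _segment_of(midpoint: int, structure: QuadripartiteStructure) -> str:
    st = structure.canonical()
    for name, iv in (("LSC", st.lsc), ("IRB", st.irb), ("SSC", st.ssc), ("IRA", st.ira)):
        if iv.contains(midpoint, structure.genome_length):
            return name
    return "LSC"


def partition_regions(
    record: PlastomeRecord, structure: QuadripartiteStructure
) -> RegionPartition:
    """Partition a canonical, annotated reference into coding / intron /
    spacer regions, each tagged LSC/IRB/SSC/IRA by its midpoint.

    Coding is the union of all annotated exons (pseudo-genes included, so
    the truncated ycf1 copy is not mistaken for a spacer); introns are the
    within-gene gaps left uncovered — a gene nested inside another gene's
    intron splits that intron; spacers are maximal gene-free intervals
    labelled ``geneA/geneB`` after their flanking genes in genome order.
    """
    n = record.length_bp
    coding = np.zeros(n, dtype=bool)
    functional = np.zeros(n, dtype=bool)
    overlap_warned = False
    for f in record.features:
        for s, e in f.exons:
            s, e = s % n, min(e, n)
            # overlaps with a pseudo-gene (ycf1ψ/ndhF at JSB) are expected
            if functional[s:e].any() and not overlap_warned and not f.pseudo:
                warnings.warn(
                    "overlapping genes: overlap assigned to coding once",
                    stacklevel=2,
                )
                overlap_warned = True
            coding[s:e] = True
            if not f.pseudo:
                functional[s:e] = True

    gene_cover = np.zeros(n, dtype=bool)
    for f in record.features:
        s, e = f.span
        if f.wraps_origin:
            gene_cover[s:] = True
            gene_cover[: min(e, n)] = True
        else:
            gene_cover[s:e] = True

    regions: list[Region] = []

    # --- introns: per multi-exon gene, gaps between consecutive exons,
    # minus any nested coding
    for f in record.features:
        exons = f.sorted_exons
        gaps = [
            (exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i + 1][0] > exons[i][1]
        ]
        if f.wraps_origin:
            gaps = [g for g in gaps if not (g[0] <= 0 or g[1] > n)]
        ordinal_needed = len(gaps) > 1
        if f.strand == -1:
            gaps = gaps[::-1]  # intron 1 is 5'-most on the feature strand
        for i, (a, b) in enumerate(gaps):
            label = f"{f.name} intron" + (f" {i + 1}" if ordinal_needed else "")
            free = ~coding[a:b]
            for s, e in _true_intervals(free, offset=a):
                regions.append(
                    Region(
                        GenomeInterval(s, e),
                        label,
                        "intron",
                        _segment_of((s + e) // 2, structure),
                    )
                )

    intron_mask = np.zeros(n, dtype=bool)
    for r in regions:
        intron_mask[r.interval.start : r.interval.end] = True

    # --- coding regions: maximal exon-covered runs, labelled by the genes
    # whose exons start the run
    span_starts = sorted((f.span[0], f.name) for f in record.features)
    for s, e in _true_intervals(coding, offset=0):
        names = [name for st_, name in span_starts if s <= st_ < e]
        label = names[0] if names else _nearest_gene_label(record, s)
        regions.append(
            Region(
                GenomeInterval(s, e),
                label,
                "coding",
                _segment_of((s + e) // 2, structure),
            )
        )

    # --- spacers: positions covered by no gene span
    free = ~(gene_cover | coding | intron_mask)
    ordered = sorted(record.features, key=lambda f: f.span[0])
    for s, e in _true_intervals(free, offset=0):
        left = [f.name for f in ordered if f.span[1] <= s] or [ordered[-1].name]
        right = [f.name for f in ordered if f.span[0] >= e] or [ordered[0].name]
        regions.append(
            Region(
                GenomeInterval(s, e),
                f"{left[-1]}/{right[0]}",
                "spacer",
                _segment_of((s + e) // 2, structure),
            )
        )

    regions.sort(key=lambda r: r.interval.start)
    part = RegionPartition(
        reference_id=record.taxon_id, reference_length=n, regions=regions
    )
    assert (
        part.coding_length + part.intron_length + part.spacer_length == n
    ), "partition must cover every position exactly once"
    return part


def _true_intervals(mask: np.ndarray, offset: int) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s) + offset, int(e) + offset) for s, e in zip(starts, ends)]


def _nearest_gene_label(record: PlastomeRecord, pos: int) -> str:
    best = min(record.features, key=lambda f: abs(f.span[0] - pos))
    return best.name


@dataclass(frozen=True)
class HotspotCandidate:
    """A scored region: SNP count, percentage and within-class rank."""

    label: str
    region_class: str
    location: str
    length_bp: int
    snp_count: int
    snp_pct: float
    rank: int = 0


def score_regions(snps, partition: RegionPartition) -> list[HotspotCandidate]:
    """Score every region's SNP percentage and rank within its class.

    Regions located in IRA are skipped — each is the mirror of an IRB region
    and would double-report the same locus.  Ranks are dense, descending by
    SNP percentage; ties broken by longer region, then label.
    """
    pos = snps.df["pos"].to_numpy()
    n = partition.reference_length
    hit = np.zeros(n, dtype=bool)
    hit[pos] = True
    scored: list[HotspotCandidate] = []
    for r in partition.regions:
        if r.location == "IRA":
            continue
        if r.length == 0:  # pragma: no cover - GenomeInterval forbids this
            warnings.warn(f"zero-length region {r.label} excluded", stacklevel=2)
            continue
        count = int(
            sum(hit[s:e].sum() for s, e in r.interval.split_at_origin(n))
        )
        scored.append(
            HotspotCandidate(
                label=r.label,
                region_class=r.region_class,
                location=r.location,
                length_bp=r.length,
                snp_count=count,
                snp_pct=100.0 * count / r.length,
            )
        )
    # dense descending rank within class
    out: list[HotspotCandidate] = []
    for cls in sorted({c.region_class for c in scored}):
        group = [c for c in scored if c.region_class == cls]
        group.sort(key=lambda c: (-c.snp_pct, -c.length_bp, c.label))
        rank = 0
        last_pct = None
        ranked = []
        for c in group:
            if c.snp_pct != last_pct:
                rank += 1
                last_pct = c.snp_pct
            ranked.append(
                HotspotCandidate(
                    c.label, c.region_class, c.location, c.length_bp,
                    c.snp_count, c.snp_pct, rank,
                )
            )
        out.extend(ranked)
    return out


def filter_candidates(
    candidates: list[HotspotCandidate],
    min_len: int = 200,
    max_len: int = 1500,
    min_pct: float = 3.0,
    classes: tuple[str, ...] = ("intron", "spacer"),
) -> list[HotspotCandidate]:
    """The barcode screen: non-coding regions of ``min_len``–``max_len`` bp
    (inclusive) whose SNP percentage strictly exceeds ``min_pct``, ordered
    by SNP percentage descending (ties: longer region, then label)."""
    kept = [
        c
        for c in candidates
        if c.region_class in classes
        and min_len <= c.length_bp <= max_len
        and c.snp_pct > min_pct
    ]
    kept.sort(key=lambda c: (-c.snp_pct, -c.length_bp, c.label))
    return kept


def gc_percent(seq: str) -> float:
    """GC percentage of a primer sequence, rounded half-up to 1 decimal."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguous bases in {seq!r}")
    gc = seq.count("G") + seq.count("C")
    val = Decimal(100 * gc) / Decimal(len(seq))
    return float(val.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


_TM_METHODS = ("wallace", "gc")


def melting_temp(seq: str, method: str = "wallace") -> float:
    """Melting temperature of a short oligo, 1 decimal.

    ``wallace``: Tm = 2·(A+T) + 4·(G+C) — the standard quick estimate for
    primers under ~14–20 nt.  ``gc``: the GC-fraction formula
    Tm = 64.9 + 41·(GC − 16.4)/N, better for longer oligos.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguous bases in {seq!r}")
    if method not in _TM_METHODS:
        raise ValueError(f"unknown method {method!r}; available: {_TM_METHODS}")
    gc = seq.count("G") + seq.count("C")
    at = len(seq) - gc
    if method == "wallace":
        return round(2.0 * at + 4.0 * gc, 1)
    return round(64.9 + 41.0 * (gc - 16.4) / len(seq), 1)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair for one barcode locus."""

    locus_label: str
    location: str
    forward_seq: str
    reverse_seq: str

    def metrics(self) -> dict:
        out = {}
        for tag, seq in (("f", self.forward_seq), ("r", self.reverse_seq)):
            try:
                out[f"gc_{tag}"] = gc_percent(seq)
                out[f"tm_{tag}"] = melting_temp(seq)
            except ValueError:
                out[f"gc_{tag}"] = None
                out[f"tm_{tag}"] = None
        return out


def end_anchored_primers(
    reference: PlastomeRecord,
    partition: RegionPartition,
    kept: list[HotspotCandidate],
    k: int = 20,
) -> list[PrimerPair]:
    """Trivial primer picker: the first k-mer of the region as forward
    primer, the reverse complement of its last k-mer as reverse primer."""
    by_label = {r.label: r for r in partition.regions if r.location != "IRA"}
    pairs = []
    for c in kept:
        r = by_label[c.label]
        s, e = r.interval.start, min(r.interval.end, reference.length_bp)
        seq = reference.slice(r.interval.start, r.interval.end)
        pairs.append(
            PrimerPair(
                locus_label=c.label,
                location=c.location,
                forward_seq=seq[:k],
                reverse_seq=revcomp(seq[-k:]),
            )
        )
    return pairs


def emit_barcode_table(
    kept: list[HotspotCandidate],
    primers: list[PrimerPair],
    path,
) -> None:
    """Write the barcode-locus table (locus, location, primers, GC%, Tm)."""
    by_label = {p.locus_label: p for p in primers}
    rows = []
    for c in kept:
        p = by_label.get(c.label)
        row = {
            "locus": c.label,
            "location": c.location,
            "class": c.region_class,
            "length_bp": c.length_bp,
            "snp_count": c.snp_count,
            "snp_pct": round(c.snp_pct, 3),
        }
        if p is not None:
            m = p.metrics()
            row.update(
                forward_primer=p.forward_seq,
                reverse_primer=p.reverse_seq,
                gc_f=m["gc_f"] if m["gc_f"] is not None else "NA",
                gc_r=m["gc_r"] if m["gc_r"] is not None else "NA",
                tm_f=m["tm_f"] if m["tm_f"] is not None else "NA",
                tm_r=m["tm_r"] if m["tm_r"] is not None else "NA",
            )
        rows.append(row)
    cols = [
        "locus", "location", "class", "length_bp", "snp_count", "snp_pct",
        "forward_primer", "reverse_primer", "gc_f", "gc_r", "tm_f", "tm_r",
    ]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False)
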
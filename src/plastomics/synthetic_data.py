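"""Synthetic annotated plastomes with planted ground truth.

The generator emulates the salient features of *Paris*/*Daiswa*-group
chloroplast genomes: a circular ~158 kb quadripartite molecule (LSC ~84.5 kb,
SSC ~18.3 kb, IR ~27.5 kb), a catalog of 115 unique gene loci (81
protein-coding entries including both rps12 loci, 30 tRNAs, 4 rRNAs; 12
protein-coding genes and 6 tRNAs intron-containing), optional tandem
duplication/triplication of trnI-CAU between rpl23 and ycf2, an IR/LSC
junction placed inside rps3 or rps19, a ycf1 pseudo-fragment overlapping
ndhF at the IRb/SSC junction, and per-partition point-mutation rates with
injected hotspot regions.

Gene order and approximate lengths follow the canonical angiosperm plastome
arrangement; intergenic spacers are sized to fill each segment evenly,
except a set of deliberately wider spacers (~800 bp) at the classic
variable intergenic loci so that hotspot injection acts on realistically
sized regions.  Sequence composition is uniform random at 37.3% GC.

Taxa are mutated independently from a single ancestor (star phylogeny) with
a Jukes–Cantor-like substitution model: each site flips to a uniformly
chosen different base with its partition's per-site probability.  Inverted
repeats evolve concertedly — substitutions drawn on IRb are mirrored into
IRa — so the simulated IRs remain exact reverse complements, as in real
plastomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import GeneFeature, PlastomeRecord, revcomp

__all__ = [
    "CatalogGene",
    "GeneCatalog",
    "SimulationParams",
    "SimulationTruth",
    "TaxonTruth",
    "default_catalog",
    "simulate_ancestor",
    "mutate_taxa",
    "simulate_cohort",
    "per_taxon_rate",
]


@dataclass(frozen=True)
class CatalogGene:
    """One catalog entry: exon/intron lengths are 5'→3'."""

    name: str
    category: str
    exons: tuple[int, ...]
    introns: tuple[int, ...] = ()
    strand: int = 1
    nested_in: str | None = None  # host gene; placed inside its first intron

    @property
    def span(self) -> int:
        return sum(self.exons) + sum(self.introns)


@dataclass(frozen=True)
class GeneCatalog:
    """Ordered per-segment gene lists plus boundary geometry."""

    lsc: tuple[CatalogGene, ...]
    ir: tuple[CatalogGene, ...]  # IRb order from JLB, excluding boundary genes
    ssc: tuple[CatalogGene, ...]
    ycf1_ir_bp: int  # portion of ycf1 inside IRa (== ycf1 pseudo length)
    ndhf_overlap_bp: int  # ndhF extension into IRb past JSB
    wide_spacers: dict[str, int] = field(default_factory=dict)

    @property
    def entries(self) -> list[CatalogGene]:
        return [*self.lsc, *self.ir, *self.ssc]


def _g(name, cat, exons, introns=(), strand=1, nested_in=None):
    return CatalogGene(name, cat, tuple(exons), tuple(introns), strand, nested_in)


#: The ten classically variable non-coding loci the full catalog emulates
#: (seven intergenic spacers and three introns); these are the natural
#: targets for hotspot injection and barcode screening.
DEFAULT_HOTSPOT_LOCI = (
    "ndhC/trnV-UAC",
    "trnN-GUU/ycf1",
    "rps15/ycf1",
    "rpl33/rps18",
    "ndhA intron",
    "atpF intron",
    "psbZ/trnG-GCC",
    "psaA/ycf3",
    "trnV-UAC intron",
    "ccsA/ndhD",
)

# Classic variable intergenic loci given realistic (wider) spacer widths.
_WIDE = {
    "ndhC/trnV-UAC": 800,
    "psbZ/trnG-GCC": 800,
    "psaA/ycf3": 750,
    "rpl33/rps18": 750,
    "trnN-GUU/ycf1": 800,
    "rps15/ycf1": 850,
    "ccsA/ndhD": 800,
}


def _full_catalog() -> GeneCatalog:
    P, T, R = "protein", "tRNA", "rRNA"
    lsc = (
        _g("trnH-GUG", T, [74]),
        _g("psbA", P, [1062], strand=-1),
        _g("trnK-UUU", T, [37, 35], [2480], strand=-1),
        _g("matK", P, [1530], strand=-1, nested_in="trnK-UUU"),
        _g("rps16", P, [40, 227], [860], strand=-1),
        _g("trnQ-UUG", T, [72], strand=-1),
        _g("psbK", P, [186]),
        _g("psbI", P, [111]),
        _g("trnS-GCU", T, [88], strand=-1),
        _g("trnG-UCC", T, [23, 48], [715]),
        _g("trnR-UCU", T, [72]),
        _g("atpA", P, [1524], strand=-1),
        _g("atpF", P, [410, 145], [700], strand=-1),
        _g("atpH", P, [246], strand=-1),
        _g("atpI", P, [744], strand=-1),
        _g("rps2", P, [711], strand=-1),
        _g("rpoC2", P, [4140], strand=-1),
        _g("rpoC1", P, [432, 1614], [740], strand=-1),
        _g("rpoB", P, [3213], strand=-1),
        _g("trnC-GCA", T, [71]),
        _g("petN", P, [90]),
        _g("psbM", P, [105], strand=-1),
        _g("trnD-GUC", T, [74], strand=-1),
        _g("trnY-GUA", T, [84], strand=-1),
        _g("trnE-UUC", T, [73], strand=-1),
        _g("trnT-GGU", T, [72]),
        _g("psbD", P, [1062]),
        _g("psbC", P, [1386]),
        _g("trnS-UGA", T, [93], strand=-1),
        _g("psbZ", P, [189]),
        _g("trnG-GCC", T, [71]),
        _g("trnfM-CAU", T, [74], strand=-1),
        _g("rps14", P, [303], strand=-1),
        _g("psaB", P, [2205], strand=-1),
        _g("psaA", P, [2253], strand=-1),
        _g("ycf3", P, [124, 230, 153], [720, 740], strand=-1),
        _g("trnS-GGA", T, [87], strand=-1),
        _g("rps4", P, [606], strand=-1),
        _g("trnT-UGU", T, [73], strand=-1),
        _g("trnL-UAA", T, [35, 50], [500]),
        _g("trnF-GAA", T, [73]),
        _g("ndhJ", P, [477], strand=-1),
        _g("ndhK", P, [678], strand=-1),
        _g("ndhC", P, [363], strand=-1),
        _g("trnV-UAC", T, [38, 37], [570], strand=-1),
        _g("trnM-CAU", T, [73]),
        _g("atpB", P, [1497], strand=-1),
        _g("atpE", P, [402], strand=-1),
        _g("rbcL", P, [1428]),
        _g("accD", P, [1464]),
        _g("psaI", P, [111]),
        _g("ycf4", P, [552]),
        _g("cemA", P, [690]),
        _g("petA", P, [963]),
        _g("psbJ", P, [123], strand=-1),
        _g("psbL", P, [117], strand=-1),
        _g("psbF", P, [120], strand=-1),
        _g("psbE", P, [252], strand=-1),
        _g("petL", P, [96]),
        _g("petG", P, [114]),
        _g("trnW-CCA", T, [74], strand=-1),
        _g("trnP-UGG", T, [74], strand=-1),
        _g("psaJ", P, [129]),
        _g("rpl33", P, [201]),
        _g("rps18", P, [306]),
        _g("rpl20", P, [354], strand=-1),
        _g("rps12", P, [114], strand=-1),  # 5' locus
        _g("clpP", P, [71, 291, 228], [800, 620], strand=-1),
        _g("psbB", P, [1527]),
        _g("psbT", P, [108]),
        _g("psbN", P, [132], strand=-1),
        _g("psbH", P, [222]),
        _g("petB", P, [6, 642], [750]),
        _g("petD", P, [8, 475], [720]),
        _g("rpoA", P, [1014], strand=-1),
        _g("rps11", P, [417], strand=-1),
        _g("rpl36", P, [114], strand=-1),
        _g("infA", P, [234], strand=-1),
        _g("rps8", P, [405], strand=-1),
        _g("rpl14", P, [369], strand=-1),
        _g("rpl16", P, [9, 399], [1020], strand=-1),
        _g("rps3", P, [657], strand=-1),
        _g("rpl22", P, [462], strand=-1),
        _g("rps19", P, [279], strand=-1),
    )
    ir = (
        _g("rpl2", P, [391, 434], [660], strand=-1),
        _g("rpl23", P, [282], strand=-1),
        _g("trnI-CAU", T, [74], strand=-1),
        _g("ycf2", P, [6906]),
        _g("ycf15", P, [258]),
        _g("trnL-CAA", T, [81], strand=-1),
        _g("ndhB", P, [777, 756], [680], strand=-1),
        _g("rps7", P, [468], strand=-1),
        _g("rps12", P, [26, 232], [540], strand=-1),  # trans-spliced 3' locus
        _g("trnV-GAC", T, [72]),
        _g("rrn16", R, [1491]),
        _g("trnI-GAU", T, [42, 35], [940]),
        _g("trnA-UGC", T, [38, 35], [800]),
        _g("rrn23", R, [2810]),
        _g("rrn4.5", R, [103]),
        _g("rrn5", R, [121]),
        _g("trnR-ACG", T, [74]),
        _g("trnN-GUU", T, [72], strand=-1),
    )
    ssc = (
        _g("ndhF", P, [2241], strand=-1),
        _g("rpl32", P, [174]),
        _g("trnL-UAG", T, [80]),
        _g("ccsA", P, [963]),
        _g("ndhD", P, [1503], strand=-1),
        _g("psaC", P, [246], strand=-1),
        _g("ndhE", P, [306], strand=-1),
        _g("ndhG", P, [531], strand=-1),
        _g("ndhI", P, [504], strand=-1),
        _g("ndhA", P, [553, 539], [1080], strand=-1),
        _g("ndhH", P, [1182], strand=-1),
        _g("rps15", P, [273], strand=-1),
        _g("ycf1", P, [5400]),
    )
    return GeneCatalog(
        lsc=lsc, ir=ir, ssc=ssc, ycf1_ir_bp=1000, ndhf_overlap_bp=120,
        wide_spacers=dict(_WIDE),
    )


def _scaled_catalog() -> GeneCatalog:
    P, T, R = "protein", "tRNA", "rRNA"
    lsc = (
        _g("psbA", P, [300], strand=-1),
        _g("trnK-UUU", T, [37, 35], [600], strand=-1),
        _g("matK", P, [400], strand=-1, nested_in="trnK-UUU"),
        _g("rps16", P, [40, 160], [300], strand=-1),
        _g("trnQ-UUG", T, [72], strand=-1),
        _g("rbcL", P, [500]),
        _g("rps12", P, [114], strand=-1),
        _g("clpP", P, [60, 120, 100], [200, 180], strand=-1),
        _g("rpl16", P, [9, 150], [250], strand=-1),
        _g("rps3", P, [400], strand=-1),
        _g("rpl22", P, [200], strand=-1),
        _g("rps19", P, [279], strand=-1),
    )
    ir = (
        _g("rpl2", P, [120, 140], [200], strand=-1),
        _g("rpl23", P, [180], strand=-1),
        _g("trnI-CAU", T, [74], strand=-1),
        _g("ycf2", P, [800]),
        _g("ndhB", P, [300, 280], [250], strand=-1),
        _g("rps12", P, [26, 160], [200], strand=-1),
        _g("rrn16", R, [600]),
        _g("trnN-GUU", T, [72], strand=-1),
    )
    ssc = (
        _g("ndhF", P, [600], strand=-1),
        _g("ndhA", P, [200, 180], [300], strand=-1),
        _g("rps15", P, [180], strand=-1),
        _g("ycf1", P, [1200]),
    )
    return GeneCatalog(
        lsc=lsc, ir=ir, ssc=ssc, ycf1_ir_bp=300, ndhf_overlap_bp=60,
        wide_spacers={"rps15/ycf1": 400, "trnN-GUU/ycf1": 350},
    )


def default_catalog(scaled: bool = False) -> GeneCatalog:
    """The built-in gene catalog (full 115-locus, or a ~25-gene scaled
    variant with every category, intron and duplication pattern kept)."""
    return _scaled_catalog() if scaled else _full_catalog()


def per_taxon_rate(cohort_divergence: float, n_taxa: int) -> float:
    """Per-taxon per-site substitution probability whose cohort-level SNP
    proportion (any of ``n_taxa`` differing from the ancestor) equals
    ``cohort_divergence`` under a star phylogeny."""
    return 1.0 - (1.0 - cohort_divergence) ** (1.0 / n_taxa)


@dataclass
class SimulationParams:
    """Study conditions for the simulator.

    Defaults mirror the sequenced cohort: 11 mutated taxa plus the ancestral
    reference, segment lengths at the middle of the observed ranges, 37.3%
    GC, and per-taxon substitution rates chosen so the cohort-level SNP
    proportions equal the observed 1.655% (coding) and 2.033% (non-coding).
    """

    lsc_len: int = 84_500
    ssc_len: int = 18_300
    ir_len: int = 27_500
    gene_catalog: GeneCatalog | None = None
    trni_copies: int = 1
    jla_gene: str = "rps3"
    n_taxa: int = 11
    coding_rate: float = per_taxon_rate(0.01655, 11)
    intron_rate: float = per_taxon_rate(0.02033, 11)
    spacer_rate: float = per_taxon_rate(0.02033, 11)
    indel_rate: float = 0.0
    hotspots: list[tuple[str, float]] = field(default_factory=list)
    gc_fraction: float = 0.373
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lsc_len <= self.ssc_len:
            raise ValueError("lsc_len must exceed ssc_len")
        for r in (self.coding_rate, self.intron_rate, self.spacer_rate):
            if not 0.0 <= r <= 0.2:
                raise ValueError(f"substitution rate {r} outside [0, 0.2]")
        if self.trni_copies not in (1, 2, 3):
            raise ValueError("trni_copies must be 1, 2 or 3")
        if self.jla_gene not in ("rps3", "rps19"):
            raise ValueError("jla_gene must be 'rps3' or 'rps19'")

    @property
    def catalog(self) -> GeneCatalog:
        return self.gene_catalog or default_catalog()

    @property
    def genome_length(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


@dataclass
class TaxonTruth:
    """Planted ground truth for one simulated taxon (ancestor coordinates
    for substitutions; segment lengths after any indels)."""

    taxon_id: str
    substitutions: dict[str, list[int]]  # class -> ancestor positions (incl. IRa mirrors)
    counts: dict[str, int]
    lsc_len: int
    ssc_len: int
    ir_len: int
    n_indels: int = 0


@dataclass
class SimulationTruth:
    """Cohort-level ground truth manifest."""

    lsc_len: int
    ssc_len: int
    ir_len: int
    trni_copies: int
    jla_gene: str
    regions: list[tuple[str, str, int, int]]  # (label, class, start, end)
    taxa: list[TaxonTruth] = field(default_factory=list)

    def region_interval(self, label: str) -> tuple[int, int]:
        for lab, _cls, s, e in self.regions:
            if lab == label:
                return s, e
        raise KeyError(f"no planted region labelled {label!r}")


# ---------------------------------------------------------------------------
# Ancestor construction


def _genomic_exons(gene: CatalogGene, start: int) -> list[tuple[int, int]]:
    """Genomic exon intervals in 5'→3' order for a gene placed at ``start``."""
    pieces: list[tuple[int, int]] = []
    pos = start
    lens: list[int] = []
    for i, ex in enumerate(gene.exons):
        lens.append(ex)
        if i < len(gene.introns):
            lens.append(gene.introns[i])
    # lay out alternating exon/intron from the genomic left edge
    order = lens if gene.strand == 1 else lens[::-1]
    genomic: list[tuple[int, int]] = []
    is_exon = [True, False] * len(gene.exons)
    flags = []
    for i in range(len(lens)):
        flags.append(i % 2 == 0)
    gflags = flags if gene.strand == 1 else flags[::-1]
    for length, is_ex in zip(order, gflags):
        if is_ex:
            genomic.append((pos, pos + length))
        pos += length
    if gene.strand == -1:
        genomic = genomic[::-1]  # 5'→3' order on the minus strand
    return genomic


def _intron_intervals(gene: CatalogGene, start: int) -> list[tuple[int, int]]:
    exons = sorted(_genomic_exons(gene, start))
    return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


class _SegmentPlacer:
    def __init__(self, name: str, start: int, end: int, wide: dict[str, int]):
        self.name = name
        self.start, self.end = start, end
        self.wide = wide
        self.placed: list[tuple[CatalogGene, int]] = []
        self.spacers: list[tuple[str, int, int]] = []

    def fill(
        self,
        genes: list[CatalogGene],
        lead_label: str | None,
        trail_label: str | None,
        min_gap: int = 30,
    ) -> None:
        """Place genes in order with spacers filling the free room evenly,
        honouring fixed widths for labelled wide spacers."""
        spans = [g.span for g in genes]
        n_gaps = len(genes) + 1
        labels = []
        prev = lead_label
        for g in genes:
            labels.append(f"{prev}/{g.name}" if prev else None)
            prev = g.name
        labels.append(f"{prev}/{trail_label}" if trail_label else None)
        budget = (self.end - self.start) - sum(spans)
        fixed = {i: self.wide[lab] for i, lab in enumerate(labels) if lab in self.wide}
        flex = n_gaps - len(fixed)
        free = budget - sum(fixed.values())
        if flex <= 0 or free < flex * min_gap:
            raise ValueError(
                f"genes do not fit segment {self.name}: "
                f"{sum(spans)} bp of genes in {self.end - self.start} bp"
            )
        base, rem = divmod(free, flex)
        pos = self.start
        flex_seen = 0
        for i, g in enumerate(genes):
            gap = fixed.get(i)
            if gap is None:
                gap = base + (1 if flex_seen < rem else 0)
                flex_seen += 1
            if labels[i]:
                self.spacers.append((labels[i], pos, pos + gap))
            pos += gap
            self.placed.append((g, pos))
            pos += g.span
        gap = fixed.get(n_gaps - 1)
        if gap is None:
            gap = base + (1 if flex_seen < rem else 0)
        if labels[-1]:
            self.spacers.append((labels[-1], pos, pos + gap))


def _mirror_interval(s: int, e: int, jsb: int, jsa: int) -> tuple[int, int]:
    return jsa + jsb - e, jsa + jsb - s


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _break_complement(seq: list[str], i: int, j: int) -> None:
    if seq[i] == _COMP[seq[j]]:
        seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[i]]


def simulate_ancestor(
    params: SimulationParams,
) -> tuple[PlastomeRecord, SimulationTruth]:
    """Build the annotated ancestral plastome and its truth manifest.

    Deterministic for a fixed seed.  The genome comes out in canonical
    rotation (LSC at 0) with IRa an exact reverse complement of IRb.
    """
    cat = params.catalog
    lsc_len, ssc_len, ir_len = params.lsc_len, params.ssc_len, params.ir_len
    jlb, jsb = lsc_len, lsc_len + ir_len
    jsa = jsb + ssc_len
    n = jsa + ir_len

    lsc_genes = [g for g in cat.lsc if g.nested_in is None]
    nested = [g for g in cat.lsc if g.nested_in is not None]
    if params.jla_gene == "rps3":
        boundary = next(g for g in lsc_genes if g.name == "rps3")
        ir_head = [g for g in lsc_genes if g.name in ("rpl22", "rps19")]
        lsc_resident = [g for g in lsc_genes if g.name not in ("rps3", "rpl22", "rps19")]
    else:
        boundary = next(g for g in lsc_genes if g.name == "rps19")
        ir_head = []
        lsc_resident = [g for g in lsc_genes if g.name != "rps19"]
    ir_tail = boundary.span // 3  # bp of the boundary gene inside the IR
    lsc_part = boundary.span - ir_tail

    ir_genes: list[CatalogGene] = list(ir_head)
    for g in cat.ir:
        if g.name == "trnI-CAU":
            ir_genes.extend([g] * params.trni_copies)
        else:
            ir_genes.append(g)

    ycf1 = cat.ssc[-1]
    ssc_mid = list(cat.ssc[1:-1])
    ndhf = cat.ssc[0]

    # --- LSC: residents then the boundary gene ending ir_tail past JLB
    pl_lsc = _SegmentPlacer("LSC", 0, jlb - lsc_part, cat.wide_spacers)
    pl_lsc.fill(lsc_resident, lead_label=None, trail_label=boundary.name)
    placed = list(pl_lsc.placed)
    spacers = list(pl_lsc.spacers)
    placed.append((boundary, jlb - lsc_part))

    # --- IRb: from the boundary tail to the ycf1 pseudo-fragment
    pl_ir = _SegmentPlacer(
        "IR", jlb + ir_tail, jsb - cat.ycf1_ir_bp, cat.wide_spacers
    )
    pl_ir.fill(ir_genes, lead_label=boundary.name, trail_label="ycf1")
    placed.extend(pl_ir.placed)
    spacers.extend(pl_ir.spacers)

    # --- SSC: ndhF overlapping back past JSB, then middles, then ycf1
    ndhf_start = jsb - cat.ndhf_overlap_bp
    placed.append((ndhf, ndhf_start))
    ycf1_ssc = ycf1.span - cat.ycf1_ir_bp
    pl_ssc = _SegmentPlacer(
        "SSC", ndhf_start + ndhf.span, jsa - ycf1_ssc, cat.wide_spacers
    )
    pl_ssc.fill(ssc_mid, lead_label=ndhf.name, trail_label=ycf1.name)
    placed.extend(pl_ssc.placed)
    spacers.extend(pl_ssc.spacers)
    placed.append((ycf1, jsa - ycf1_ssc))

    # --- nested genes (inside the host's first intron)
    placed_by_name = {g.name: (g, s) for g, s in placed}
    for g in nested:
        host, hstart = placed_by_name[g.nested_in]
        intron = _intron_intervals(host, hstart)[0]
        off = (intron[1] - intron[0] - g.span) // 2
        if off < 0:
            raise ValueError(
                f"nested gene {g.name} does not fit intron of {g.nested_in}"
            )
        placed.append((g, intron[0] + off))

    features = [
        GeneFeature(
            name=g.name,
            category=g.category,
            strand=g.strand,
            exons=_genomic_exons(g, s),
        )
        for g, s in placed
    ]

    # ycf1 pseudo-fragment at the IRb end (mirror of ycf1's IRa portion)
    features.append(
        GeneFeature(
            name="ycf1",
            category="protein",
            strand=-ycf1.strand,
            exons=[(jsb - cat.ycf1_ir_bp, jsb)],
            pseudo=True,
        )
    )
    # boundary-gene fragment mirrored at the IRa/LSC junction
    features.append(
        GeneFeature(
            name=boundary.name,
            category="protein",
            strand=-boundary.strand,
            exons=[(n - ir_tail, n)],
            pseudo=True,
        )
    )
    # mirror every feature fully inside IRb into IRa
    for g, s in placed:
        lo, hi = s, s + g.span
        if lo >= jlb and hi <= jsb:
            mirrored = [
                _mirror_interval(a, b, jsb, jsa) for a, b in _genomic_exons(g, s)
            ]
            features.append(
                GeneFeature(
                    name=g.name,
                    category=g.category,
                    strand=-g.strand,
                    exons=mirrored,
                )
            )

    rng = np.random.default_rng([params.seed, 0xA5])
    gc = params.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    core = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=jsa, p=probs)
    seq_list = list(core.tobytes().decode("ascii"))
    # ensure the planted IR pair is maximal: the bases flanking the repeats
    # must not be complementary by chance, or detection would rightly report
    # a longer repeat than planted
    _break_complement(seq_list, jsb, jsa - 1)  # first SSC vs last SSC base
    _break_complement(seq_list, jlb - 1, 0)  # last LSC vs first LSC base
    seq = "".join(seq_list)
    seq = seq + revcomp(seq[jlb:jsb])

    record = PlastomeRecord(
        taxon_id="ancestor", sequence=seq, features=features
    )

    regions: list[tuple[str, str, int, int]] = [
        (lab, "spacer", s, e) for lab, s, e in spacers
    ]
    for g, s in placed:
        ivs = _intron_intervals(g, s)
        for i, (a, b) in enumerate(ivs):
            lab = f"{g.name} intron" if len(ivs) == 1 else f"{g.name} intron {i + 1}"
            regions.append((lab, "intron", a, b))
    truth = SimulationTruth(
        lsc_len=lsc_len,
        ssc_len=ssc_len,
        ir_len=ir_len,
        trni_copies=params.trni_copies,
        jla_gene=params.jla_gene,
        regions=regions,
    )
    return record, truth


# ---------------------------------------------------------------------------
# Mutation


_CLASS_NAMES = {0: "coding", 1: "intron", 2: "spacer"}


def class_array(record: PlastomeRecord) -> np.ndarray:
    """Per-position partition class: 0 coding, 1 intron, 2 spacer.

    Coding is the union of all annotated exons (pseudo included); introns
    are within-gene gaps not covered by any exon; the rest is spacer.
    """
    n = record.length_bp
    cls = np.full(n, 2, dtype=np.uint8)
    for f in record.features:
        for s, e in _unwrap_pieces(f, n):
            cls[s:e] = np.minimum(cls[s:e], 1)
    coding = np.zeros(n, dtype=bool)
    for f in record.features:
        for s, e in f.exons:
            coding[s % n : min(e, n)] = True
            if e > n:
                coding[: e - n] = True
    cls[coding] = 0
    # the "intron" marking above covered whole gene spans; restore spacer
    # where a span gap is not inside any gene (cannot happen by construction)
    return cls


def _unwrap_pieces(f: GeneFeature, n: int) -> list[tuple[int, int]]:
    s, e = f.span
    if not f.wraps_origin:
        return [(s, e)]
    # span of a wrapping feature covers [s, n) + [0, e')
    starts = [a for a, _ in f.exons]
    ends = [b for _, b in f.exons]
    return [(max(starts), n), (0, min(ends))]


def mutate_taxa(
    ancestor: PlastomeRecord,
    truth: SimulationTruth,
    params: SimulationParams,
) -> list[tuple[PlastomeRecord, TaxonTruth]]:
    """Mutate ``n_taxa`` descendants of the ancestor independently.

    Substitutions are drawn per site with the partition's rate (hotspot
    regions boosted) over LSC + IRb + SSC and mirrored into IRa; the default
    mode is substitution-only.  With ``indel_rate > 0`` short (1–4 bp)
    indels are additionally placed in single-copy spacers and feature
    coordinates are shifted accordingly.
    """
    n = ancestor.length_bp
    jlb = truth.lsc_len
    jsb = jlb + truth.ir_len
    jsa = jsb + truth.ssc_len
    cls = class_array(ancestor)
    base_rates = np.array(
        [params.coding_rate, params.intron_rate, params.spacer_rate]
    )
    rates = base_rates[cls[:jsa]].copy()
    for label, boost in params.hotspots:
        s, e = truth.region_interval(label)
        if e > jsa:
            raise ValueError(f"hotspot {label!r} lies in IRa")
        rates[s:e] = rates[s:e] * boost
    if rates.max(initial=0.0) > 0.2:
        raise ValueError("hotspot boost drives a substitution rate above 0.2")

    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    anc = np.frombuffer(ancestor.sequence.encode("ascii"), dtype=np.uint8)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    out = []
    for t in range(params.n_taxa):
        rng = np.random.default_rng([params.seed, 1 + t])
        hit = np.flatnonzero(rng.random(jsa) < rates)
        seq = anc.copy()
        # substitute to a uniformly chosen different base
        shift = rng.integers(1, 4, size=hit.size)
        cur_idx = np.searchsorted(bases, seq[hit])
        seq[hit] = bases[(cur_idx + shift) % 4]
        # concerted evolution: mirror IRb substitutions into IRa
        in_irb = hit[(hit >= jlb) & (hit < jsb)]
        mirror = jsa + jsb - 1 - in_irb
        seq[mirror] = comp[seq[in_irb]]

        positions = np.concatenate([hit, mirror])
        pos_cls = cls[positions]
        subs = {
            name: sorted(int(p) for p in positions[pos_cls == code])
            for code, name in _CLASS_NAMES.items()
        }
        counts = {k: len(v) for k, v in subs.items()}

        taxon_id = f"taxon_{t + 1:02d}"
        features = [
            GeneFeature(f.name, f.category, f.strand, list(f.exons), f.pseudo,
                        wraps_origin=f.wraps_origin)
            for f in ancestor.features
        ]
        seq_str = seq.tobytes().decode("ascii")
        seg = dict(lsc=truth.lsc_len, ssc=truth.ssc_len, ir=truth.ir_len)
        n_indels = 0
        if params.indel_rate > 0:
            seq_str, features, seg, n_indels = _apply_indels(
                seq_str, features, cls, jlb, jsb, jsa, seg, params, rng
            )
        rec = PlastomeRecord(taxon_id=taxon_id, sequence=seq_str, features=features)
        tt = TaxonTruth(
            taxon_id=taxon_id,
            substitutions=subs,
            counts=counts,
            lsc_len=seg["lsc"],
            ssc_len=seg["ssc"],
            ir_len=seg["ir"],
            n_indels=n_indels,
        )
        truth.taxa.append(tt)
        out.append((rec, tt))
    return out


def _apply_indels(seq, features, cls, jlb, jsb, jsa, seg, params, rng):
    """Short indels in single-copy spacers; features shifted accordingly."""
    n = len(seq)
    spacer = (cls == 2).copy()
    spacer[jlb:jsb] = False  # keep IRs exact copies
    spacer[jsa:] = False
    # stay clear of spacer edges so edits never touch gene coordinates
    safe = spacer & np.roll(spacer, 6) & np.roll(spacer, -6)
    sites = np.flatnonzero(rng.random(n) < params.indel_rate)
    sites = sites[safe[sites]]
    edits = []  # (pos, delta, replacement)
    for p in sites:
        length = int(rng.integers(1, 5))
        if rng.random() < 0.5:
            edits.append((int(p), -length, ""))
        else:
            ins = "".join(rng.choice(list("ACGT"), size=length))
            edits.append((int(p), length, ins))
    edits.sort(reverse=True)
    s = seq
    for p, delta, ins in edits:
        if delta < 0:
            s = s[:p] + s[p - delta :]
        else:
            s = s[:p] + ins + s[p:]
    for p, delta, _ in edits:
        for f in features:
            f.exons = [
                (a + delta if a >= p else a, b + delta if b > p else b)
                for a, b in f.exons
            ]
        if p < jlb:
            seg["lsc"] += delta
        elif jsb <= p < jsa:
            seg["ssc"] += delta
    return s, features, seg, len(edits)


def simulate_cohort(
    params: SimulationParams,
) -> tuple[PlastomeRecord, list[PlastomeRecord], SimulationTruth]:
    """Ancestor plus mutated taxa in one call."""
    ancestor, truth = simulate_ancestor(params)
    taxa = [rec for rec, _ in mutate_taxa(ancestor, truth, params)]
    return ancestor, taxa, truth
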
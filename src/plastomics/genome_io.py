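"""Input/output and the coordinate model shared by every analysis module.

All internal coordinates are 0-based half-open on the forward strand of the
circular molecule.  Conversions happen only at the file boundary: GenBank and
VCF are 1-based inclusive, BED is 0-based half-open.

A plastome is modelled as a :class:`PlastomeRecord` — an uppercase DNA string
over ``{A,C,G,T,N}`` plus an ordered list of :class:`GeneFeature` annotations.
Features may wrap the circular origin; the ``wraps_origin`` flag marks a
feature whose exon list was split at position 0 so that the split is not
mistaken for an intron.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeInterval",
    "GeneFeature",
    "PlastomeRecord",
    "read_genbank",
    "write_genbank",
    "write_fasta",
    "write_snp_vcf",
    "write_region_bed",
    "normalize_gene_name",
    "gc_content",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Annotation sources disagree on separators and capitalisation for tRNA
#: names; names are compared case-insensitively with ``_`` mapped to ``-``.
_SYNONYMS = {
    "trni-cau": "trnI-CAU",
}


def revcomp(seq: str) -> str:
    """Reverse complement of an ``{A,C,G,T,N}`` string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_gene_name(name: str) -> str:
    """Canonical spelling of a gene symbol (separator- and case-insensitive).

    ``trnI_CAU``, ``TRNI-cau`` and ``trnI-CAU`` all normalise to the same
    symbol; non-tRNA/rRNA symbols keep their conventional mixed case from the
    first component (e.g. ``rps3``, ``ycf1``).
    """
    cleaned = name.strip().replace("_", "-")
    key = cleaned.lower()
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    return cleaned


@dataclass(frozen=True)
class GenomeInterval:
    """0-based half-open interval on a circular genome.

    ``wraps_origin`` marks an interval crossing position 0; its ``end`` is
    then given in unwrapped coordinates (``end > length_bp`` of the genome).
    """

    start: int
    end: int
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int, length_bp: int) -> bool:
        if not self.wraps_origin:
            return self.start <= pos < self.end
        return pos >= self.start or pos < self.end - length_bp

    def split_at_origin(self, length_bp: int) -> list[tuple[int, int]]:
        """Concrete [start, end) pieces in genome coordinates."""
        if not self.wraps_origin:
            return [(self.start, self.end)]
        return [(self.start, length_bp), (0, self.end - length_bp)]


@dataclass
class GeneFeature:
    """One annotated gene (or gene copy) on a plastome.

    ``exons`` are 0-based half-open intervals ordered 5'→3' on the feature's
    strand (i.e. descending start for ``strand == -1``).  ``copy_index``
    distinguishes repeated copies of the same symbol in genome order.
    """

    name: str
    category: str  # "protein" | "tRNA" | "rRNA"
    strand: int
    exons: list[tuple[int, int]]
    pseudo: bool = False
    copy_index: int = 1
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.category not in ("protein", "tRNA", "rRNA"):
            raise ValueError(f"unknown category {self.category!r}")
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")
        if not self.exons:
            raise ValueError(f"{self.name}: empty exon list")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.name}: empty exon ({s}, {e})")

    @property
    def intron_count(self) -> int:
        n = len(self.exons) - 1
        return n - 1 if self.wraps_origin else n

    @property
    def sorted_exons(self) -> list[tuple[int, int]]:
        return sorted(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """(min start, max end) over exons in genome coordinates."""
        starts, ends = zip(*self.exons)
        return min(starts), max(ends)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exon_signature(self) -> tuple[int, ...]:
        """Sorted exon lengths — identical for IR-mirrored or tandem copies."""
        return tuple(sorted(e - s for s, e in self.exons))


@dataclass
class PlastomeRecord:
    """One circular annotated chloroplast genome."""

    taxon_id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    accession: str = ""
    is_circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"unknown residues in sequence: {sorted(bad)}")
        n = self.length_bp
        for f in self.features:
            for s, e in f.exons:
                if s < 0 or e > n:
                    raise ValueError(
                        f"feature {f.name} exon ({s}, {e}) outside [0, {n})"
                    )
        self.features.sort(key=lambda f: f.span[0])
        self._assign_copy_indices()

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def _assign_copy_indices(self) -> None:
        seen: dict[str, int] = {}
        for f in self.features:
            key = normalize_gene_name(f.name)
            seen[key] = seen.get(key, 0) + 1
            f.copy_index = seen[key]

    def features_named(self, name: str) -> list[GeneFeature]:
        key = normalize_gene_name(name)
        return [f for f in self.features if normalize_gene_name(f.name) == key]

    def slice(self, start: int, end: int) -> str:
        """Sequence of [start, end), transparently wrapping the origin."""
        n = self.length_bp
        if end <= n:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[: end - n]


def gc_content(record: PlastomeRecord | str, decimals: int = 1) -> float:
    """GC percentage of a genome (N bases excluded from the denominator)."""
    seq = record if isinstance(record, str) else record.sequence
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("sequence has no unambiguous bases")
    gc = seq.count("G") + seq.count("C")
    return round(100.0 * gc / acgt, decimals)


# ---------------------------------------------------------------------------
# GenBank


_FEATURE_TYPES = {"CDS": "protein", "tRNA": "tRNA", "rRNA": "rRNA"}


def _category_from_name(name: str) -> str:
    low = name.lower()
    if low.startswith("trn"):
        return "tRNA"
    if low.startswith("rrn"):
        return "rRNA"
    return "protein"


def _feature_from_seqfeature(sf: SeqFeature, category: str, length_bp: int) -> GeneFeature:
    quals = sf.qualifiers
    name = (quals.get("gene") or quals.get("locus_tag") or ["unknown"])[0]
    strand = -1 if sf.location.strand == -1 else 1
    parts = sorted(
        ((int(p.start), int(p.end)) for p in sf.location.parts),
        key=lambda t: t[0],
    )
    # A join touching both ends of the molecule is an origin-spanning exon
    # split in two, not an intron.
    wraps = len(parts) >= 2 and parts[0][0] == 0 and parts[-1][1] == length_bp
    if strand == -1:
        parts = parts[::-1]
    return GeneFeature(
        name=normalize_gene_name(name),
        category=category,
        strand=strand,
        exons=parts,
        pseudo="pseudo" in quals or "pseudogene" in quals,
        wraps_origin=wraps,
    )


def read_genbank(path) -> PlastomeRecord:
    """Read a single-record GenBank flat file into a :class:`PlastomeRecord`.

    Joined locations become multi-exon features, complement locations get
    strand -1, ``/pseudo`` qualifiers (or a ``-pseudo``/``-fragment`` name
    suffix) set the pseudo flag.  Duplicate gene names receive ascending
    ``copy_index`` in genome order.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise ValueError(
            f"{path}: expected exactly 1 GenBank record, found {len(records)}"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    features: list[GeneFeature] = []
    typed_names: set[tuple[str, tuple]] = set()
    n = len(seq)
    for sf in rec.features:
        if sf.type not in _FEATURE_TYPES:
            continue
        gf = _feature_from_seqfeature(sf, _FEATURE_TYPES[sf.type], n)
        _check_bounds(gf, n, path)
        features.append(gf)
        typed_names.add((normalize_gene_name(gf.name), gf.span))
    # gene features carry annotations (e.g. /pseudo) that may lack a typed
    # sibling — keep those too.
    for sf in rec.features:
        if sf.type != "gene":
            continue
        name = (sf.qualifiers.get("gene") or ["unknown"])[0]
        gf = _feature_from_seqfeature(sf, _category_from_name(name), n)
        if (normalize_gene_name(gf.name), gf.span) in typed_names:
            continue
        _check_bounds(gf, n, path)
        features.append(gf)
    for gf in features:
        if gf.name.lower().endswith(("-pseudo", "-fragment")):
            gf.name = gf.name.rsplit("-", 1)[0]
            gf.pseudo = True
    topology = rec.annotations.get("topology", "circular")
    return PlastomeRecord(
        taxon_id=rec.id if rec.id and rec.id != "<unknown id>" else rec.name,
        sequence=seq,
        features=features,
        accession=rec.annotations.get("accessions", [""])[0],
        is_circular=topology != "linear",
    )


def _check_bounds(gf: GeneFeature, length_bp: int, path) -> None:
    for s, e in gf.exons:
        if s < 0 or e > length_bp:
            raise ValueError(
                f"{path}: feature {gf.name} coordinates ({s}, {e}) exceed "
                f"sequence length {length_bp}"
            )


def write_genbank(record: PlastomeRecord, path) -> None:
    """Write a :class:`PlastomeRecord` as a GenBank flat file.

    Inverse of :func:`read_genbank`: a read-back reproduces the sequence and
    feature list.
    """
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.accession or record.taxon_id,
        name=record.taxon_id[:16].replace(" ", "_"),
        description=f"{record.taxon_id} chloroplast genome",
    )
    seqrec.annotations["molecule_type"] = "DNA"
    seqrec.annotations["topology"] = "circular" if record.is_circular else "linear"
    if record.accession:
        seqrec.annotations["accessions"] = [record.accession]
    type_of = {"protein": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
    for f in record.features:
        exons = f.exons if f.strand == 1 else f.exons[::-1]
        locs = [SimpleLocation(s, e, strand=f.strand) for s, e in exons]
        if f.strand == -1:
            locs = locs[::-1]  # CompoundLocation parts listed in genome order
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [f.name]}
        ftype = "gene" if f.pseudo else type_of[f.category]
        if f.pseudo:
            quals["pseudo"] = [""]
        seqrec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    with open(path, "w") as fh:
        SeqIO.write(seqrec, fh, "genbank")


def write_fasta(records: dict[str, str] | PlastomeRecord, path, width: int = 70) -> None:
    """Write one or more sequences as FASTA (``{name: seq}`` or a record)."""
    if isinstance(records, PlastomeRecord):
        records = {records.taxon_id: records.sequence}
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF / BED


def write_snp_vcf(snps, reference: PlastomeRecord, path) -> None:
    """Write a SNP table as minimal multi-sample VCF 4.2 (haploid GT).

    Positions are emitted 1-based and strictly increasing; an empty table
    produces a header-only file.
    """
    taxa = list(snps.taxa)
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write(
        f"##contig=<ID={reference.taxon_id},length={reference.length_bp}>\n"
    )
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(taxa)
        + "\n"
    )
    df = snps.df.sort_values("pos")
    for row in df.itertuples(index=False):
        pos = int(row.pos)
        if pos >= reference.length_bp:
            raise ValueError(f"SNP position {pos} beyond reference length")
        ref = reference.sequence[pos]
        alts: list[str] = []
        gts = []
        for t in taxa:
            allele = getattr(row, _safe_col(t))
            if allele in (ref, "N", "-"):
                gts.append("0" if allele == ref else ".")
            else:
                if allele not in alts:
                    alts.append(allele)
                gts.append(str(1 + alts.index(allele)))
        buf.write(
            f"{reference.taxon_id}\t{pos + 1}\t.\t{ref}\t"
            f"{','.join(alts) if alts else '.'}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
            + "\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _safe_col(taxon: str) -> str:
    # pandas itertuples mangles non-identifier column names; SnpTable stores
    # taxon columns already sanitised via this same mapping.
    out = "".join(c if c.isalnum() else "_" for c in taxon)
    return out if out[:1].isalpha() else "t_" + out


def write_region_bed(
    regions: list[tuple[GenomeInterval, str]],
    length_bp: int,
    path,
    chrom: str = "chr",
) -> None:
    """Write labelled intervals as BED4; wrapping intervals split in two
    lines sharing a ``/wrap`` label suffix."""
    with open(path, "w") as fh:
        for iv, label in regions:
            if not label:
                raise ValueError("empty region label")
            pieces = iv.split_at_origin(length_bp)
            suffix = [""] if len(pieces) == 1 else ["/wrapA", "/wrapB"]
            for (s, e), suf in zip(pieces, suffix):
                fh.write(f"{chrom}\t{s}\t{e}\t{label}{suf}\n")
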
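"""Unique-gene inventories, intron counts and trnI-CAU duplication typing.

The counting unit is the *gene locus*: features sharing both a symbol and an
exon-length signature are copies of one locus (inverted-repeat mirrors and
tandem duplicates collapse), while structurally distinct loci under one
symbol count separately.  This reproduces the standard plastome gene-table
convention in which the trans-spliced rps12 contributes two entries (its
independently transcribed 5' and 3' loci) while the duplicated or
triplicated trnI-CAU contributes one.  Pseudo-genes (e.g. the truncated
ycf1 copy at the IRb/SSC junction) are excluded from inventories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .genome_io import GeneFeature, PlastomeRecord, normalize_gene_name

__all__ = [
    "GeneInventory",
    "DuplicationType",
    "build_inventory",
    "count_trni_copies",
    "compare_inventories",
]


@dataclass
class GeneInventory:
    """Unique gene loci of one plastome, by category.

    Category lists hold one entry per locus; a symbol appears twice when a
    genome carries two structurally distinct loci under that name (rps12).
    """

    taxon_id: str
    protein: list[str] = field(default_factory=list)
    trna: list[str] = field(default_factory=list)
    rrna: list[str] = field(default_factory=list)
    intron_bearing_protein: list[str] = field(default_factory=list)
    intron_bearing_trna: list[str] = field(default_factory=list)
    duplicated_genes: dict[str, int] = field(default_factory=dict)

    @property
    def total_unique(self) -> int:
        return len(self.protein) + len(self.trna) + len(self.rrna)

    def copy_count(self, name: str) -> int:
        return self.duplicated_genes.get(normalize_gene_name(name), 1)


@dataclass(frozen=True)
class DuplicationType:
    """Copy-number state of a gene, labelled per the field's typology."""

    gene: str
    copies: int
    label: str


_DUP_LABELS = {
    1: "single-copy (Daiswa type)",
    2: "duplicated",
    3: "triplicated (Paris s.s. type)",
}


def _dup_label(copies: int) -> str:
    return _DUP_LABELS.get(copies, f"other:{copies}")


def build_inventory(record: PlastomeRecord, collapse_ir: bool = True) -> GeneInventory:
    """Build the unique-locus inventory of an annotated plastome.

    With ``collapse_ir`` (the default) multi-copy genes are additionally
    recorded in ``duplicated_genes`` with their feature copy counts.  An
    unannotated record yields an empty inventory with a warning.
    """
    inv = GeneInventory(taxon_id=record.taxon_id)
    functional = [f for f in record.features if not f.pseudo]
    if not functional:
        warnings.warn(
            f"{record.taxon_id}: no functional annotations; empty inventory",
            stacklevel=2,
        )
        return inv
    loci: dict[tuple[str, tuple[int, ...]], list[GeneFeature]] = {}
    for f in functional:
        key = (normalize_gene_name(f.name), f.exon_signature())
        loci.setdefault(key, []).append(f)
    by_cat = {"protein": inv.protein, "tRNA": inv.trna, "rRNA": inv.rrna}
    name_counts: dict[str, int] = {}
    for (name, _sig), copies in sorted(loci.items()):
        by_cat[copies[0].category].append(name)
        name_counts[name] = name_counts.get(name, 0) + len(copies)
        if copies[0].intron_count >= 1:
            target = {
                "protein": inv.intron_bearing_protein,
                "tRNA": inv.intron_bearing_trna,
            }.get(copies[0].category)
            if target is not None and name not in target:
                target.append(name)
    if collapse_ir:
        inv.duplicated_genes = {
            name: cnt for name, cnt in name_counts.items() if cnt >= 2
        }
    for lst in (inv.protein, inv.trna, inv.rrna,
                inv.intron_bearing_protein, inv.intron_bearing_trna):
        lst.sort()
    return inv


def count_trni_copies(record: PlastomeRecord) -> DuplicationType:
    """Count trnI-CAU copies between rpl23 and ycf2 within one IR copy.

    Raises ``ValueError`` naming the missing anchor if rpl23 or ycf2 is not
    annotated.  Copy positions are compared by midpoint along the shorter
    arc between the two anchors.
    """
    n = record.length_bp
    rpl23 = record.features_named("rpl23")
    ycf2 = record.features_named("ycf2")
    for name, feats in (("rpl23", rpl23), ("ycf2", ycf2)):
        if not feats:
            raise ValueError(f"anchor gene {name} absent from {record.taxon_id}")

    def midpoint(f: GeneFeature) -> int:
        s, e = f.span
        return (s + e) // 2

    a = midpoint(rpl23[0])
    # the ycf2 copy nearest this rpl23 copy bounds the same IR copy
    b_feat = min(ycf2, key=lambda f: min((midpoint(f) - a) % n, (a - midpoint(f)) % n))
    b = midpoint(b_feat)
    fwd = (b - a) % n  # arc a -> b
    use_forward = fwd <= n - fwd

    def between(m: int) -> bool:
        if use_forward:
            return 0 < (m - a) % n < fwd
        return 0 < (a - m) % n < (a - b) % n

    copies = sum(
        1
        for f in record.features_named("trnI-CAU")
        if not f.pseudo and between(midpoint(f))
    )
    return DuplicationType(gene="trnI-CAU", copies=copies, label=_dup_label(copies))


def compare_inventories(inventories: list[GeneInventory]) -> pd.DataFrame:
    """Per-gene presence/copy-count matrix across taxa.

    One row per gene symbol, one column per taxon holding the feature copy
    count (0 = absent); the ``flagged`` column marks genes whose copy count
    differs across taxa.
    """
    if len(inventories) < 2:
        raise ValueError("need at least two inventories to compare")
    all_genes = sorted(
        {g for inv in inventories for g in (*inv.protein, *inv.trna, *inv.rrna)}
    )
    data = {}
    for inv in inventories:
        present = set(inv.protein) | set(inv.trna) | set(inv.rrna)
        data[inv.taxon_id] = [
            (inv.duplicated_genes.get(g, 1) if g in present else 0)
            for g in all_genes
        ]
    df = pd.DataFrame(data, index=pd.Index(all_genes, name="gene"))
    df["flagged"] = df.nunique(axis=1) > 1
    return df
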
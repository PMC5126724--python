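"""Region partitioning, hotspot scoring/filtering and primer metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plastomics as pl
from plastomics.barcode_screen import HotspotCandidate, Region, RegionPartition
from plastomics.genome_io import GenomeInterval, revcomp


@pytest.fixture(scope="module")
def scaled_partition(scaled_ancestor):
    _, ancestor, _ = scaled_ancestor
    structure = pl.detect_structure(ancestor).canonical()
    return ancestor, pl.partition_regions(ancestor, structure)


class TestPartition:
    def test_completeness(self, scaled_partition):
        """coding + intron + spacer lengths cover the genome exactly."""
        record, part = scaled_partition
        assert (
            part.coding_length + part.intron_length + part.spacer_length
            == record.length_bp
        )

    def test_spacer_labels_follow_flanking_genes(self, scaled_partition):
        _, part = scaled_partition
        labels = {r.label for r in part.regions if r.region_class == "spacer"}
        assert "psbA/trnK-UUU" in labels
        assert "rps15/ycf1" in labels

    def test_intron_regions_named_and_located(self, scaled_partition):
        """ndhA has one intron, in the SSC."""
        _, part = scaled_partition
        ndha = [r for r in part.regions if r.label == "ndhA intron"]
        assert len(ndha) == 1 and ndha[0].location == "SSC"
        # two-intron genes get ordinals
        clp = sorted(r.label for r in part.regions if r.label.startswith("clpP intron"))
        assert clp == ["clpP intron 1", "clpP intron 2"]

    def test_nested_gene_splits_host_intron(self, scaled_partition):
        """matK sits inside the trnK-UUU intron: the intron region is split
        around the nested exon and no intron position is coding."""
        record, part = scaled_partition
        trnk = [r for r in part.regions if r.label == "trnK-UUU intron"]
        assert len(trnk) == 2
        matk = next(f for f in record.features if f.name == "matK")
        lo, hi = matk.span
        for r in trnk:
            assert r.interval.end <= lo or r.interval.start >= hi

    def test_adjacent_genes_gap_is_one_spacer(self):
        feats = [
            pl.GeneFeature("geneA", "protein", 1, [(100, 400)]),
            pl.GeneFeature("geneB", "protein", 1, [(550, 800)]),
        ]
        rec = pl.PlastomeRecord(taxon_id="t", sequence="A" * 1000, features=feats)
        structure = pl.QuadripartiteStructure(
            lsc=GenomeInterval(0, 500),
            irb=GenomeInterval(500, 600),
            ssc=GenomeInterval(600, 900),
            ira=GenomeInterval(900, 1000),
            genome_length=1000,
        )
        part = pl.partition_regions(rec, structure)
        spacers = [r for r in part.regions if r.region_class == "spacer"]
        gap = next(r for r in spacers if r.label == "geneA/geneB")
        assert gap.length == 150


def _cand(label, cls, length, count, location="LSC"):
    return HotspotCandidate(
        label=label,
        region_class=cls,
        location=location,
        length_bp=length,
        snp_count=count,
        snp_pct=100.0 * count / length,
    )


class TestScoreAndFilter:
    def test_score_arithmetic_and_tie_rule(self, scaled_partition):
        record, part = scaled_partition
        df = pd.DataFrame(
            {
                "pos": [10, 20, 30],
                "ref": ["A"] * 3,
                "q": ["G"] * 3,
                "n_alleles": [2] * 3,
                "region_class": ["unassigned"] * 3,
            }
        )
        snps = pl.SnpTable(reference_id=record.taxon_id, taxa=["q"], df=df)
        cands = pl.score_regions(snps, part)
        total = sum(c.snp_count for c in cands)
        assert total == 3
        for c in cands:
            assert c.snp_pct == pytest.approx(100.0 * c.snp_count / c.length_bp)
        # dense ranks per class start at 1
        for cls in ("coding", "intron", "spacer"):
            ranks = sorted(c.rank for c in cands if c.region_class == cls)
            assert ranks[0] == 1

    def test_ira_regions_not_double_reported(self, scaled_partition):
        _, part = scaled_partition
        df = pd.DataFrame(
            columns=["pos", "ref", "q", "n_alleles", "region_class"]
        ).astype({"pos": int})
        snps = pl.SnpTable(reference_id="x", taxa=["q"], df=df)
        cands = pl.score_regions(snps, part)
        assert all(c.location != "IRA" for c in cands)
        assert any(c.location == "IRB" for c in cands)

    @pytest.mark.parametrize(
        "length, count, kept",
        [
            (300, 10, True),   # 3.33% in range
            (1800, 80, False),  # 4.4% but too long
            (200, 6, False),   # exactly 3.0%: strict threshold rejects
            (200, 7, True),    # 3.5% at the inclusive length bound
            (1500, 50, True),  # inclusive upper length bound
        ],
    )
    def test_filter_boundaries(self, length, count, kept):
        out = pl.filter_candidates([_cand("x", "spacer", length, count)])
        assert bool(out) is kept

    def test_filter_orders_by_pct_desc(self):
        cands = [
            _cand("a", "spacer", 300, 10),
            _cand("b", "intron", 400, 20),
            _cand("c", "coding", 300, 30),  # wrong class
        ]
        out = pl.filter_candidates(cands)
        assert [c.label for c in out] == ["b", "a"]

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["coding", "intron", "spacer"]),
                st.integers(min_value=1, max_value=2500),
                st.integers(min_value=0, max_value=200),
            ),
            max_size=40,
        )
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_filter_equals_naive_scan(self, raw):
        """Filter output equals a naive scan applying the three predicates."""
        cands = [
            _cand(f"r{i}", cls, length, min(count, length))
            for i, (cls, length, count) in enumerate(raw)
        ]
        out = pl.filter_candidates(cands)
        naive = [
            c
            for c in cands
            if c.region_class in ("intron", "spacer")
            and 200 <= c.length_bp <= 1500
            and c.snp_pct > 3.0
        ]
        assert sorted(c.label for c in out) == sorted(c.label for c in naive)
        pcts = [c.snp_pct for c in out]
        assert pcts == sorted(pcts, reverse=True)


class TestPrimerMetrics:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("ACAAAACTTTCTCGCTCGGT", 45.0),   # ndhC/trnV-UAC forward
            ("CATCTGGTATACGCAAAAGCG", 47.6),  # rps15/ycf1 forward
            ("CCGGAACTTCTTCGTAGTGG", 55.0),   # trnN-GUU/ycf1 forward
            ("GGGG", 100.0),
        ],
    )
    def test_gc_percent_published_primers(self, seq, expected):
        assert pl.gc_percent(seq) == expected

    def test_gc_percent_rejects_bad_input(self):
        with pytest.raises(ValueError):
            pl.gc_percent("")
        with pytest.raises(ValueError):
            pl.gc_percent("ACGN")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=40))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_gc_percent_permutation_and_complement_invariant(self, seq):
        shuffled = "".join(sorted(seq))
        assert pl.gc_percent(seq) == pl.gc_percent(shuffled)
        assert pl.gc_percent(seq) == pl.gc_percent(revcomp(seq))

    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("ACAAAACTTTCTCGCTCGGT", 58.0),  # 9 GC, 11 AT: 4*9 + 2*11
            ("AAAA", 8.0),
            ("GGCC", 16.0),
        ],
    )
    def test_wallace_rule(self, seq, expected):
        assert pl.melting_temp(seq) == expected

    def test_alternative_method_and_unknown_method(self):
        assert pl.melting_temp("ACGTACGTACGTACGTACGTACGT", method="gc") > 0
        with pytest.raises(ValueError, match="wallace"):
            pl.melting_temp("ACGT", method="nearest-neighbour")


class TestBarcodeTable:
    def test_empty_kept_list_header_only(self, tmp_path):
        path = tmp_path / "barcodes.tsv"
        pl.emit_barcode_table([], [], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("locus")

    def test_row_with_computed_metrics(self, tmp_path):
        kept = [_cand("geneA/geneB", "spacer", 300, 12)]
        primers = [
            pl.PrimerPair(
                locus_label="geneA/geneB",
                location="LSC",
                forward_seq="ACAAAACTTTCTCGCTCGGT",
                reverse_seq="CCGGAACTTCTTCGTAGTGG",
            )
        ]
        path = tmp_path / "barcodes.tsv"
        pl.emit_barcode_table(kept, primers, path)
        df = pd.read_csv(path, sep="\t")
        row = df.iloc[0]
        assert row.gc_f == 45.0 and row.gc_r == 55.0
        assert row.tm_f == 58.0

    def test_primers_with_n_marked_na(self, tmp_path):
        kept = [_cand("x/y", "spacer", 300, 12)]
        primers = [
            pl.PrimerPair(
                locus_label="x/y", location="LSC",
                forward_seq="ACGTNACGTACGTACGTACG", reverse_seq="ACGTACGTACGTACGTACGT",
            )
        ]
        path = tmp_path / "barcodes.tsv"
        pl.emit_barcode_table(kept, primers, path)
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        assert df.iloc[0].gc_f == "NA"
        assert df.iloc[0].gc_r != "NA"

    def test_end_anchored_primers_come_from_region_ends(self, scaled_partition):
        record, part = scaled_partition
        spacer = next(
            r for r in part.regions
            if r.region_class == "spacer" and r.location == "LSC" and r.length >= 40
        )
        kept = [_cand(spacer.label, "spacer", spacer.length, 10)]
        (pair,) = pl.end_anchored_primers(record, part, kept)
        seq = record.slice(spacer.interval.start, spacer.interval.end)
        assert pair.forward_seq == seq[:20]
        assert pair.reverse_seq == revcomp(seq[-20:])
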
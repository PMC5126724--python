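"""Reference projection, SNP calling and divergence summaries."""

import numpy as np
import pytest

import plastomics as pl
from plastomics import synthetic_data as sd
from conftest import scaled_params

from _oracles import edit_distance


def _rec(taxon, seq):
    return pl.PlastomeRecord(taxon_id=taxon, sequence=seq)


class TestAlignToReference:
    def test_identity(self):
        p = pl.align_to_reference(_rec("r", "ACGTACGT"), _rec("q", "ACGTACGT"))
        assert p.edit_distance == 0
        assert "".join(p.alleles) == "ACGTACGT" and not p.insertions

    def test_single_substitution(self):
        p = pl.align_to_reference(
            _rec("r", "ACGTACGT"), _rec("q", "ACGAACGT"), try_revcomp=False
        )
        assert "".join(p.alleles) == "ACGAACGT"
        assert int(np.flatnonzero(p.alleles != list("ACGTACGT"))[0]) == 3

    def test_deletion_projects_as_gap(self):
        """Deleting the T of ACGTACGT leaves a '-' at position 3 (verified
        against the exhaustive DP: distance 1)."""
        ref, qry = "ACGTACGT", "ACGACGT"
        assert edit_distance(ref, qry) == 1
        p = pl.align_to_reference(_rec("r", ref), _rec("q", qry), try_revcomp=False)
        assert p.edit_distance == 1
        assert "".join(p.alleles) == "ACG-ACGT"

    def test_insertion_recorded_separately(self):
        p = pl.align_to_reference(
            _rec("r", "ACGTACGT"), _rec("q", "ACGTTTACGT"), try_revcomp=False
        )
        assert (p.alleles != "-").all()
        assert sum(len(s) for _, s in p.insertions) == 2

    def test_revcomp_query_recovered(self):
        from plastomics.genome_io import revcomp

        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        p = pl.align_to_reference(_rec("r", seq), _rec("q", revcomp(seq)))
        assert p.edit_distance == 0

    def test_too_divergent_raises(self):
        rng = np.random.default_rng(2)
        a = "".join(rng.choice(list("ACGT"), size=300))
        b = "".join(rng.choice(list("ACGT"), size=300))
        with pytest.raises(ValueError, match="divergent"):
            pl.align_to_reference(_rec("r", a), _rec("q", b))

    @pytest.mark.parametrize("seed", range(8))
    def test_edit_distance_matches_exhaustive_dp(self, seed):
        """On toys <= 200 bp the aligner's score equals the full DP."""
        rng = np.random.default_rng(seed + 10)
        n = int(rng.integers(50, 200))
        ref = "".join(rng.choice(list("ACGT"), size=n))
        qry = list(ref)
        for _ in range(int(rng.integers(1, 8))):
            op = rng.random()
            pos = int(rng.integers(0, len(qry)))
            if op < 0.5:
                qry[pos] = "ACGT"[int(rng.integers(0, 4))]
            elif op < 0.75 and len(qry) > 10:
                del qry[pos]
            else:
                qry.insert(pos, "ACGT"[int(rng.integers(0, 4))])
        qry = "".join(qry)
        p = pl.align_to_reference(_rec("r", ref), _rec("q", qry), try_revcomp=False)
        assert p.edit_distance == edit_distance(ref, qry)

    def test_adjacent_substitutions_stay_substitutions(self):
        """Equal-cost del+ins representations are normalised to mismatch
        columns so substitution-only callers see them."""
        ref = "TTTAATCTGAACCTTT"
        qry = "TTTAACGTGAACCTTT"  # two adjacent substitutions
        p = pl.align_to_reference(_rec("r", ref), _rec("q", qry), try_revcomp=False)
        assert (p.alleles != "-").all() and not p.insertions
        diff = np.flatnonzero(p.alleles != np.array(list(ref)))
        assert list(diff) == [5, 6]


class TestCallSnps:
    def _project(self, ref, queries):
        reference = _rec("ref", ref)
        projs = [
            pl.align_to_reference(reference, _rec(f"q{i}", q), try_revcomp=False)
            for i, q in enumerate(queries)
        ]
        return reference, projs

    def test_no_variation_no_rows(self):
        ref, projs = self._project("ACGTACGTAC", ["ACGTACGTAC"] * 3)
        assert pl.call_snps(ref, projs).total_snps == 0

    def test_single_biallelic_row(self):
        seq = "ACGTACGTACGT"
        var = seq[:10] + "A" + seq[11:]  # ref G -> A at position 10
        ref, projs = self._project(seq, [var, seq, seq])
        snps = pl.call_snps(ref, projs)
        assert snps.total_snps == 1
        row = snps.df.iloc[0]
        assert (row.pos, row.ref, row.n_alleles) == (10, "G", 2)

    def test_multiallelic_position_counts_once(self):
        seq = "ACGTACGTACGT"
        ref, projs = self._project(
            seq, [seq[:6] + "A" + seq[7:], seq[:6] + "T" + seq[7:], seq]
        )
        snps = pl.call_snps(ref, projs)
        assert snps.total_snps == 1
        assert snps.df.iloc[0].n_alleles == 3

    def test_n_and_gap_only_differences_excluded(self):
        seq = "ACGTACGTACGT"
        withN = seq[:4] + "N" + seq[5:]
        deleted = seq[:4] + seq[5:]
        ref, projs = self._project(seq, [withN, deleted])
        assert pl.call_snps(ref, projs).total_snps == 0

    def test_snp_count_symmetric_between_genomes(self):
        """Without indels, swapping reference and query preserves the SNP
        count (coordinates differ, count does not)."""
        rng = np.random.default_rng(5)
        a = "".join(rng.choice(list("ACGT"), size=800))
        b = list(a)
        for pos in rng.choice(800, size=12, replace=False):
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        b = "".join(b)
        ra, rb = _rec("a", a), _rec("b", b)
        n_ab = pl.call_snps(ra, [pl.align_to_reference(ra, rb, try_revcomp=False)]).total_snps
        n_ba = pl.call_snps(rb, [pl.align_to_reference(rb, ra, try_revcomp=False)]).total_snps
        assert n_ab == n_ba == 12


class TestSummaries:
    def _partition(self, coding_len, noncoding_len):
        regions = [
            pl.RegionPartition,
        ]
        from plastomics.barcode_screen import Region, RegionPartition
        from plastomics.genome_io import GenomeInterval

        return RegionPartition(
            reference_id="r",
            reference_length=coding_len + noncoding_len,
            regions=[
                Region(GenomeInterval(0, coding_len), "geneA", "coding", "LSC"),
                Region(
                    GenomeInterval(coding_len, coding_len + noncoding_len),
                    "geneA/geneB", "spacer", "LSC",
                ),
            ],
        )

    def test_percentages_arithmetic(self):
        """10/500 coding and 20/500 non-coding on a 1000 bp reference give
        2.0%, 4.0% and 3.0% overall."""
        import pandas as pd

        part = self._partition(500, 500)
        pos = list(range(10)) + list(range(500, 520))
        df = pd.DataFrame(
            {
                "pos": pos,
                "ref": ["A"] * 30,
                "q": ["G"] * 30,
                "n_alleles": [2] * 30,
                "region_class": ["unassigned"] * 30,
            }
        )
        snps = pl.SnpTable(reference_id="r", taxa=["q"], df=df)
        summ = pl.summarize_divergence(snps, part, 1000)
        assert summ.coding_pct == pytest.approx(2.0)
        assert summ.noncoding_pct == pytest.approx(4.0)
        assert summ.total_pct == pytest.approx(3.0)

    def test_zero_snps(self):
        import pandas as pd

        part = self._partition(500, 500)
        df = pd.DataFrame(
            columns=["pos", "ref", "q", "n_alleles", "region_class"]
        ).astype({"pos": int})
        snps = pl.SnpTable(reference_id="r", taxa=["q"], df=df)
        summ = pl.summarize_divergence(snps, part, 1000)
        assert (summ.total_pct, summ.coding_pct, summ.noncoding_pct) == (0, 0, 0)

    def test_zero_length_partition_reports_undefined(self):
        import pandas as pd
        from plastomics.barcode_screen import Region, RegionPartition
        from plastomics.genome_io import GenomeInterval

        part = RegionPartition(
            reference_id="r",
            reference_length=100,
            regions=[Region(GenomeInterval(0, 100), "g", "coding", "LSC")],
        )
        df = pd.DataFrame(
            columns=["pos", "ref", "q", "n_alleles", "region_class"]
        ).astype({"pos": int})
        snps = pl.SnpTable(reference_id="r", taxa=["q"], df=df)
        summ = pl.summarize_divergence(snps, part, 100)
        assert summ.noncoding_pct is None  # undefined, not zero

    def test_recovery_within_binomial_error_on_scaled_sim(self):
        """Planted per-partition rates are recovered within 3 binomial SE
        on a scaled cohort."""
        params = scaled_params(
            seed=77, n_taxa=6,
            coding_rate=sd.per_taxon_rate(0.0165, 6),
            intron_rate=sd.per_taxon_rate(0.0203, 6),
            spacer_rate=sd.per_taxon_rate(0.0203, 6),
        )
        anc, taxa, truth = sd.simulate_cohort(params)
        st = pl.detect_structure(anc).canonical()
        part = pl.partition_regions(anc, st)
        projs = [pl.align_to_reference(anc, t) for t in taxa]
        summ = pl.summarize_divergence(
            pl.call_snps(anc, projs), part, anc.length_bp
        )
        for observed, planted, length in (
            (summ.coding_pct, 1.65, part.coding_length),
            (summ.noncoding_pct, 2.03, part.intron_length + part.spacer_length),
        ):
            se = 100 * np.sqrt(planted / 100 * (1 - planted / 100) / length)
            assert abs(observed - planted) <= 3 * se


class TestSlidingIdentity:
    def test_identical_genomes_all_windows_one(self):
        ref = _rec("r", "ACGT" * 100)
        p = pl.align_to_reference(ref, _rec("q", "ACGT" * 100))
        tbl = pl.sliding_identity(ref, [p], window=100, step=25)
        assert (tbl["identity"] == 1.0).all()

    def test_one_mismatch_in_window(self):
        seq = "ACGT" * 50
        var = "T" + seq[1:]
        ref = _rec("r", seq)
        p = pl.align_to_reference(ref, _rec("q", var), try_revcomp=False)
        tbl = pl.sliding_identity(ref, [p], window=100, step=100)
        assert tbl.iloc[0].identity == pytest.approx(0.99)

    def test_window_longer_than_genome_collapses(self):
        ref = _rec("r", "ACGTACGTAC")
        p = pl.align_to_reference(ref, _rec("q", "ACGTACGTAC"))
        tbl = pl.sliding_identity(ref, [p], window=10_000, step=1000)
        assert len(tbl) == 1 and tbl.iloc[0].end == 10

    def test_all_gap_window_is_na(self):
        ref = _rec("r", "ACGTACGTACGTACGTACGT")
        p = pl.ProjectedAlignment(
            taxon_id="q",
            alleles=np.array(["-"] * 10 + list("ACGTACGTAC")),
        )
        p._matches = np.array([False] * 10 + [True] * 10)
        tbl = pl.sliding_identity(ref, [p], window=10, step=10)
        assert np.isnan(tbl.iloc[0].identity)
        assert tbl.iloc[1].identity == 1.0

    def test_tsv_output_deterministic(self, tmp_path, scaled_cohort):
        _, anc, taxa, _ = scaled_cohort
        projs = [pl.align_to_reference(anc, t) for t in taxa[:2]]
        snps = pl.call_snps(anc, projs)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        snps.to_tsv(p1)
        pl.call_snps(anc, projs).to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()
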
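"""Window geometry, binning, and per-interval boundary tests."""

import math

import numpy as np
import pandas as pd
import pytest

import methsplice as ms
from methsplice.profiles import ProfileConfig, Window, bin_methylation, extract_window


def make_sites(rows):
    return ms.CpGSites(
        pd.DataFrame(rows, columns=["chrom", "pos", "meth_reads", "unmeth_reads"])
    )


class TestExtractWindow:
    def test_plus_strand_start_anchor_geometry(self):
        w = extract_window("chr1", 1000, 1500, "+", "start", 200, 20)
        assert w.anchor_pos == 1000
        assert w.edges[0] == 800 and w.edges[-1] == 1200
        assert len(w.edges) == 21
        assert np.all(np.diff(w.edges) == 20)
        assert not w.reverse

    def test_minus_strand_start_is_biological(self):
        # for a minus-strand exon [2000, 2500) the biological start is 2500
        w = extract_window("chr1", 2000, 2500, "-", "start", 200, 20)
        assert w.anchor_pos == 2500
        assert w.edges[0] == 2300 and w.edges[-1] == 2700
        assert w.reverse

    def test_anchor_near_chromosome_origin_keeps_truncated_bins(self):
        w = extract_window("chr1", 150, 400, "+", "start", 200, 20)
        sites = make_sites([("chr1", 0, 1, 1)])
        prof = bin_methylation([w], sites)
        # upstream bins [-200,-150) fall before position 0: zero effective length
        assert (prof.effective_len[0, :2] == 0).all()
        assert (prof.effective_len[0, 3:] == 20).all()
        assert prof.effective_len[0, 2] == 10  # bin [-60,-40) clipped to [0,10)

    def test_anchor_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            extract_window("chr1", 900, 990, "+", "end", 200, 20, chrom_size=500)


class TestBinMethylation:
    def test_single_site_lands_in_first_downstream_bin(self):
        # one fully methylated CpG 10 bp downstream of the anchor:
        # absolute = 1.0 / 20 bp in the first within-feature bin only
        sites = make_sites([("chr1", 1010, 4, 0)])
        w = extract_window("chr1", 1000, 1400, "+", "start", 200, 20)
        prof = bin_methylation([w], sites)
        assert prof.absolute[0, 10] == pytest.approx(1 / 20)
        others = np.delete(prof.absolute[0], 10)
        assert np.allclose(others, 0.0)

    def test_cpg_free_window_zero_absolute_undefined_relative(self):
        sites = make_sites([("chr1", 99_999, 1, 1)])
        w = extract_window("chr1", 5000, 5400, "+", "start", 200, 20)
        prof = bin_methylation([w], sites)
        assert np.allclose(prof.absolute[0], 0.0)
        assert np.isnan(prof.relative[0]).all()

    def test_minus_strand_bins_are_reversed(self):
        sites = make_sites([("chr1", 2510, 3, 1)])  # 10 bp upstream of biological start
        w = extract_window("chr1", 2000, 2500, "-", "start", 200, 20)
        prof = bin_methylation([w], sites)
        # genomically just right of the anchor = biologically just upstream: bin 9
        assert prof.sum_mCG[0, 9] == pytest.approx(0.75)

    def test_matches_per_site_assignment_oracle(self, small_bundle):
        sites = small_bundle["sites"]
        frame = sites.frame
        rng = np.random.default_rng(1)
        for _ in range(30):
            start = int(rng.integers(1000, 500_000))
            strand = "+" if rng.random() < 0.5 else "-"
            w = extract_window("chr1", start, start + 500, strand, "start", 200, 20)
            prof = bin_methylation([w], sites)
            ref_counts = np.zeros(20)
            ref_sums = np.zeros(20)
            sub = frame[frame["chrom"] == "chr1"]
            for pos, mcg in zip(sub["pos"], sub["mCG"]):
                for j in range(20):
                    lo, hi = w.edges[j], w.edges[j + 1]
                    if lo <= pos < hi:
                        k = 19 - j if w.reverse else j
                        ref_counts[k] += 1
                        ref_sums[k] += mcg
            assert np.array_equal(prof.n_cpg[0], ref_counts)
            assert np.allclose(prof.sum_mCG[0], ref_sums, atol=1e-9)

    def test_binning_conserves_mass(self, small_bundle):
        sites = small_bundle["sites"]
        rng = np.random.default_rng(2)
        for _ in range(50):
            start = int(rng.integers(1000, 500_000))
            w = extract_window("chr1", start, start + 300, "+", "start", 200, 20)
            prof = bin_methylation([w], sites)
            mass = np.where(
                prof.effective_len[0] > 0,
                prof.absolute[0] * prof.effective_len[0],
                0.0,
            ).sum()
            whole = ms.region_methylation(
                sites, "chr1", int(w.edges[0]), int(w.edges[-1])
            )
            assert mass == pytest.approx(whole.sum_mCG, abs=1e-9)


class TestBoundaryProfileTest:
    def features(self, n, rng, chrom="chr1"):
        starts = np.sort(rng.integers(1000, 500_000, n))
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": starts + 200,
                "strand": np.where(rng.random(n) < 0.5, "+", "-"),
            }
        )

    def test_profile_invariant_to_feature_order(self, small_bundle):
        sites = small_bundle["sites"]
        rng = np.random.default_rng(3)
        fa, fb = self.features(40, rng), self.features(40, rng)
        cfg = ProfileConfig()
        t1 = ms.boundary_profile_test(fa, fb, sites, cfg).table
        t2 = ms.boundary_profile_test(
            fa.sample(frac=1, random_state=0), fb.sample(frac=1, random_state=1), sites, cfg
        ).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_class_bin_untestable_not_significant(self):
        # class B sits at the chromosome edge under the relative metric with
        # no CpGs upstream: its upstream bins have no defined values
        sites = make_sites([("chr1", 1005, 3, 1), ("chr1", 25, 1, 3)])
        fa = pd.DataFrame(
            {"chrom": ["chr1"], "start": [1000], "end": [1200], "strand": ["+"]}
        )
        fb = pd.DataFrame(
            {"chrom": ["chr1"], "start": [20], "end": [220], "strand": ["+"]}
        )
        cfg = ProfileConfig(metric="relative")
        table = ms.boundary_profile_test(fa, fb, sites, cfg).table
        assert not table["testable"].all()
        untestable = table[~table["testable"]]
        assert not untestable["significant"].any()
        assert table["testable"].any()

    def test_pvalues_within_unit_interval_and_bin_count(self, small_bundle):
        sites = small_bundle["sites"]
        rng = np.random.default_rng(4)
        table = ms.boundary_profile_test(
            self.features(60, rng), self.features(60, rng), sites, ProfileConfig()
        ).table
        assert len(table) == 20
        ok = table.loc[table["testable"], "p_value"]
        assert ((ok >= 0) & (ok <= 1)).all()


class TestGenebodyQuintiles:
    def make_inputs(self, n_genes, level_by_rank):
        """Genes of 400 bp at 10 kb spacing; one CpG per gene at a level
        determined by the gene's expression rank."""
        rows, gene_rows, fpkm = [], [], {}
        for i in range(n_genes):
            start = 10_000 * (i + 1)
            gid = f"g{i:03d}"
            gene_rows.append((gid, "chr1", start, start + 400, "+"))
            fpkm[gid] = float(i + 1)
            meth = level_by_rank(i)
            rows.append(("chr1", start + 50, meth, 10 - meth))
        genes = pd.DataFrame(
            gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
        )
        sites = make_sites(rows)
        return genes, pd.Series(fpkm), sites

    def test_equal_size_quintiles(self):
        genes, fpkm, sites = self.make_inputs(10, lambda i: 5)
        out = ms.genebody_quintile_profile(genes, fpkm, sites)
        sizes = out.groupby("quintile")["n_genes"].max()
        assert (sizes == 2).all()

    def test_identical_methylation_gives_identical_curves(self):
        genes, fpkm, sites = self.make_inputs(10, lambda i: 5)
        out = ms.genebody_quintile_profile(genes, fpkm, sites)
        start = out[out["anchor"] == "start"]
        pivot = start.pivot(index="bin", columns="quintile", values="mean_metric")
        assert pivot.nunique(axis=1).max() == 1

    def test_planted_monotone_relationship_orders_quintiles(self):
        genes, fpkm, sites = self.make_inputs(25, lambda i: min(9, i // 3))
        cfg = ProfileConfig(flank_bp=2000, n_bins=40, metric="relative")
        out = ms.genebody_quintile_profile(genes, fpkm, sites, cfg)
        # the bin just downstream of the start anchor holds each gene's CpG
        sub = out[(out["anchor"] == "start") & (out["bin"] == 20)]
        means = sub.set_index("quintile")["mean_metric"].sort_index()
        assert means.is_monotonic_increasing

    def test_too_few_genes_rejected(self):
        genes, fpkm, sites = self.make_inputs(4, lambda i: 5)
        with pytest.raises(ValueError):
            ms.genebody_quintile_profile(genes, fpkm, sites)
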
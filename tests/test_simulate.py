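"""Planted-structure guarantees of the synthetic-data generator."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import methsplice as ms
from methsplice.simulate import SizingError, splicing_rates

# 99% Monte-Carlo sampling interval of the recovered odds ratio under a
# planted odds ratio of 1 at 2000 genes (meth fraction 0.5, spliced
# marginal 0.3, expressed fraction 0.7), precomputed by simulating the
# planting scheme 1000 times.
OR1_INTERVAL = (0.746, 1.336)


def tiny_config(**kw):
    defaults = dict(seed=5, n_genes=40, n_chromosomes=2, chromosome_length=250_000)
    defaults.update(kw)
    return ms.SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"frac_genes_methylated": 1.5},
            {"splicing_odds_ratio": 0.0},
            {"exons_min": 0},
            {"exon_length": (0, 10)},
            {"cpg_spacing": -1},
        ],
    )
    def test_invalid_settings_rejected(self, kw):
        with pytest.raises(ValueError):
            tiny_config(**kw)

    def test_unknown_conservation_category_rejected(self):
        probs = {"sp": {"methylated_spliced": 0.5}}
        with pytest.raises(ValueError, match="missing categories"):
            tiny_config(conservation_probs=probs)

    def test_config_round_trips_through_json(self):
        cfg = tiny_config()
        assert ms.SimulationConfig.from_json(cfg.to_json()) == cfg


class TestAnnotation:
    def test_gene_count_and_seed_determinism(self):
        cfg = tiny_config(n_genes=100, chromosome_length=600_000)
        m1, t1 = ms.generate_annotation(cfg)
        m2, t2 = ms.generate_annotation(cfg)
        assert len(m1) == 100
        assert m1 == m2
        pd.testing.assert_frame_equal(t1.genes, t2.genes)

    def test_genes_do_not_overlap_and_fit_chromosomes(self):
        cfg = tiny_config(n_genes=80, chromosome_length=500_000)
        _, truth = ms.generate_annotation(cfg)
        for _, grp in truth.genes.groupby("chrom"):
            g = grp.sort_values("start")
            assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()
            assert (g["end"] <= cfg.chromosome_length).all()

    def test_exons_stay_within_their_gene(self):
        _, truth = ms.generate_annotation(tiny_config())
        joined = truth.exons.merge(truth.genes, on="gene_id", suffixes=("", "_g"))
        assert (joined["start"] >= joined["start_g"]).all()
        assert (joined["end"] <= joined["end_g"]).all()

    def test_spliced_genes_have_two_distinct_transcripts(self):
        models, truth = ms.generate_annotation(tiny_config(n_genes=60, chromosome_length=400_000))
        spliced = set(truth.genes.loc[truth.genes["spliced"], "gene_id"])
        for m in models:
            if m.gene_id in spliced:
                assert len({t.exons for t in m.transcripts}) >= 2
            else:
                assert len(m.transcripts) == 1

    def test_no_skipping_marks_every_expressed_exon_included(self):
        cfg = tiny_config(frac_exons_skipped=0.0)
        _, truth = ms.generate_annotation(cfg)
        expressed = truth.genes.set_index("gene_id")["expressed"]
        exp_exons = truth.exons[truth.exons["gene_id"].map(expressed)]
        assert exp_exons["included"].all()

    def test_oversized_genome_request_raises(self):
        with pytest.raises(SizingError):
            ms.generate_annotation(
                tiny_config(n_genes=500, n_chromosomes=1, chromosome_length=20_000)
            )

    def test_splicing_rates_match_marginal_and_odds_ratio(self):
        cfg = tiny_config(splicing_odds_ratio=3.0)
        p1, p0 = splicing_rates(cfg)
        odds = (p1 / (1 - p1)) / (p0 / (1 - p0))
        marginal = cfg.frac_genes_methylated * p1 + (1 - cfg.frac_genes_methylated) * p0
        assert odds == pytest.approx(3.0, rel=1e-9)
        assert marginal == pytest.approx(cfg.frac_genes_spliced, rel=1e-9)

    def test_null_odds_ratio_planting_within_sampling_interval(self):
        cfg = ms.SimulationConfig(
            seed=17, n_genes=2000, splicing_odds_ratio=1.0, n_chromosomes=4,
            chromosome_length=4_000_000,
        )
        _, truth = ms.generate_annotation(cfg)
        g = truth.genes[truth.genes["expressed"]]
        a = ((g["methylated"]) & (g["spliced"])).sum()
        b = ((g["methylated"]) & (~g["spliced"])).sum()
        c = ((~g["methylated"]) & (g["spliced"])).sum()
        d = ((~g["methylated"]) & (~g["spliced"])).sum()
        sample_or = (a * d) / (b * c)
        assert OR1_INTERVAL[0] <= sample_or <= OR1_INTERVAL[1]


class TestMethylation:
    def test_degenerate_intergenic_beta_forces_zero(self):
        cfg = tiny_config(meth_level_intergenic=(0.0, 1.0))
        models, truth = ms.generate_annotation(cfg)
        calls, site_truth = ms.generate_methylation(models, truth, cfg)
        inter = site_truth["context"] == "intergenic"
        assert inter.any()
        assert (calls.loc[inter.to_numpy(), "meth_reads"] == 0).all()

    def test_unmethylated_genes_have_level_exactly_zero(self, small_bundle):
        truth = small_bundle["truth"]
        unmeth = set(truth.genes.loc[~truth.genes["methylated"], "gene_id"])
        in_unmeth = truth.sites["gene_id"].isin(unmeth)
        assert (truth.sites.loc[in_unmeth, "true_level"] == 0).all()

    def test_context_means_match_beta_binomial_expectation(self):
        cfg = ms.SimulationConfig(
            seed=23, n_genes=300, n_chromosomes=2, chromosome_length=1_200_000,
            frac_genes_methylated=1.0, cpg_spacing=40.0,
            meth_length_scale=1.0, meth_exon_factor=1.0,
        )
        models, truth = ms.generate_annotation(cfg)
        calls, site_truth = ms.generate_methylation(models, truth, cfg)
        mcg = calls["meth_reads"] / (calls["meth_reads"] + calls["unmeth_reads"])
        expected = {
            "included_exon": 4 / 10,
            "skipped_exon": 1 / 20,
            "intron": 1 / 50,
            "intergenic": 1 / 100,
        }
        for context, mean_level in expected.items():
            sel = (site_truth["context"] == context).to_numpy()
            n = sel.sum()
            assert n > 200
            # mean of meth/(meth+unmeth) given binomial reads equals the
            # beta mean; allow 5 standard errors of the observed spread
            obs = mcg[sel]
            tol = 5 * obs.std() / np.sqrt(n)
            assert obs.mean() == pytest.approx(mean_level, abs=max(tol, 5e-3))

    def test_sites_stay_on_their_chromosome(self, small_bundle):
        calls = small_bundle["calls"]
        cfg = small_bundle["config"]
        assert (calls["pos"] >= 0).all()
        assert (calls["pos"] < cfg.chromosome_length).all()


class TestExpressionGeneration:
    def test_unexpressed_fraction_zero_silences_everything(self):
        cfg = tiny_config(frac_genes_expressed=0.0)
        models, truth = ms.generate_annotation(cfg)
        expr = ms.generate_expression(models, truth, cfg)
        assert (expr["value"] == 0).all()

    def test_included_features_strictly_positive_skipped_exactly_zero(self, small_bundle):
        expr = small_bundle["expression"]
        truth = small_bundle["truth"]
        exons = expr[expr["feature_type"] == "exon"].set_index("feature_id")["value"]
        included = truth.exons.set_index("exon_id")["included"]
        assert (exons[included] > 0).all()
        assert (exons[~included] == 0).all()

    def test_inclusion_classifier_recovers_planted_labels(self, small_bundle):
        expr = small_bundle["expression"]
        truth = small_bundle["truth"]
        exons = expr[expr["feature_type"] == "exon"]
        labels = ms.classify_inclusion(exons)
        planted = truth.exons.set_index("exon_id")["included"]
        assert (labels.to_numpy() == planted[exons["feature_id"]].to_numpy()).all()


class TestConservationGeneration:
    def test_probability_one_conserves_everything(self):
        cfg = tiny_config(
            conservation_probs={"sp": {k: 1.0 for k in
                ("methylated_spliced", "methylated_unspliced",
                 "unmethylated_spliced", "unmethylated_unspliced")}},
            frac_no_hit=0.0,
        )
        _, truth = ms.generate_annotation(cfg)
        table, cons_truth = ms.generate_conservation(truth, cfg)
        assert cons_truth["conserved"].all()
        assert (table["evalue"] < 1e-150).all()
        assert len(table) == cfg.n_genes

    def test_probability_zero_conserves_nothing(self):
        cfg = tiny_config(
            conservation_probs={"sp": {k: 0.0 for k in
                ("methylated_spliced", "methylated_unspliced",
                 "unmethylated_spliced", "unmethylated_unspliced")}},
        )
        _, truth = ms.generate_annotation(cfg)
        table, cons_truth = ms.generate_conservation(truth, cfg)
        assert not cons_truth["conserved"].any()
        assert (table["evalue"] >= 1e-150).all()


class TestBundleDeterminism:
    def test_two_bundles_identical_byte_for_byte(self, tmp_path):
        cfg = tiny_config()
        p1 = ms.simulate_bundle(cfg, tmp_path / "a")
        p2 = ms.simulate_bundle(cfg, tmp_path / "b")
        assert set(p1) == set(p2)
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_label_marginals_match_configured_fractions(self):
        cfg = ms.SimulationConfig(seed=29, n_genes=1500, n_chromosomes=4,
                                  chromosome_length=4_000_000)
        from scipy.stats import binom
        _, truth = ms.generate_annotation(cfg)
        for col, p in (
            ("methylated", cfg.frac_genes_methylated),
            ("spliced", cfg.frac_genes_spliced),
            ("expressed", cfg.frac_genes_expressed),
        ):
            k = int(truth.genes[col].sum())
            lo = binom.ppf(0.005, cfg.n_genes, p)
            hi = binom.ppf(0.995, cfg.n_genes, p)
            assert lo <= k <= hi, (col, k)
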
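"""Generator contracts: determinism, quotas, and generative structure."""

import numpy as np
import pandas as pd
import pytest

from neuroloc.simulate import (
    ConfigurationError,
    SimConfig,
    simulate_bundle,
    simulate_circ,
    simulate_footprints,
    simulate_genes,
    simulate_protein_intensities,
    simulate_rna_counts,
    simulate_silac,
)


def _config(**kw):
    return SimConfig(**{"n_genes": 200, "seed": 3, **kw})


class TestGenes:
    def test_degenerate_mixture_gives_uniform_effect(self):
        cfg = _config(
            n_genes=100, mechanism_fractions={"mrna_localization": 1.0}, lncrna_fraction=0.0
        )
        genes = simulate_genes(cfg)
        assert len(genes) == 100
        assert (genes["mechanism"] == "mrna_localization").all()
        assert (genes["rna_loc_log2fc"] == cfg.loc_effect_log2).all()

    def test_quota_allocation_is_exact(self):
        cfg = _config(
            n_genes=10_000,
            mechanism_fractions={"mrna_localization": 0.1, "unlocalized": 0.9},
        )
        counts = simulate_genes(cfg)["mechanism"].value_counts()
        assert counts["mrna_localization"] == 1000
        assert counts["unlocalized"] == 9000

    def test_determinism_same_seed_identical(self):
        a = simulate_genes(_config())
        b = simulate_genes(_config())
        pd.testing.assert_frame_equal(a, b)

    def test_mechanism_sign_patterns(self):
        genes = simulate_genes(_config(n_genes=2000))
        coding = genes[genes["biotype"] == "coding"]
        patterns = {
            # (rna test, ribo test, prot test)
            "mrna_localization": (lambda x: x > 1, lambda x: x > 1, lambda x: x > 1),
            "intermediate": (lambda x: 0 < x < 1, lambda x: 0 < x < 1, lambda x: x > 1),
            "protein_transport": (lambda x: x < 0, lambda x: x < 0, lambda x: x > 1),
            "local_translation": (lambda x: x < 0, lambda x: x > 1, lambda x: x > 1),
            "combination": (lambda x: x < 0, lambda x: 0 < x < 1, lambda x: x > 1),
            "soma_restricted": (lambda x: x < -1, lambda x: x < -1, lambda x: x < -1),
            "unlocalized": (lambda x: x == 0, lambda x: x == 0, lambda x: x == 0),
        }
        for _, g in coding.iterrows():
            rna_ok, ribo_ok, prot_ok = patterns[g["mechanism"]]
            assert rna_ok(g["rna_loc_log2fc"]), g
            assert ribo_ok(g["ribo_loc_log2fc"]), g
            assert prot_ok(g["prot_loc_log2fc"]), g
        lnc = genes[genes["biotype"] == "lncRNA"]
        assert lnc["mechanism"].isin(
            ["mrna_localization", "soma_restricted", "unlocalized"]
        ).all()
        assert lnc[["ribo_loc_log2fc", "prot_loc_log2fc"]].isna().all().all()
        assert (lnc["cds_length"] == 0).all()
        assert (coding["cds_length"] % 3 == 0).all()
        assert (genes["cds_length"] <= genes["tx_length"]).all()

    @pytest.mark.parametrize(
        "bad",
        [
            {"mechanism_fractions": {"mrna_localization": 0.5}},
            {"mechanism_fractions": {"mrna_localization": -0.1, "unlocalized": 1.1}},
            {"mechanism_fractions": {"teleportation": 1.0}},
            {"n_replicates": 1},
            {"frame0_bias": 0.2},
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            simulate_genes(_config(**bad))


class TestRnaCounts:
    def test_poisson_limit_neurite_mean_scaling(self):
        # one localized + one unlocalized gene, negligible dispersion: the
        # localized gene's neurite/soma ratio, referenced to the
        # unlocalized gene (library scaling cancels), is 2**rna_loc_log2fc
        cfg = _config(
            n_genes=2,
            mechanism_fractions={"mrna_localization": 0.5, "unlocalized": 0.5},
            lncrna_fraction=0.0,
            rna_dispersion=0.0,
            rna_depth=2_000_000,
            n_replicates=50,
        )
        genes = simulate_genes(cfg)
        counts = simulate_rna_counts(genes, cfg)
        soma = counts.filter(like="soma").mean(axis=1)
        neurite = counts.filter(like="neurite").mean(axis=1)
        loc = genes.index[genes["mechanism"] == "mrna_localization"][0]
        unloc = genes.index[genes["mechanism"] == "unlocalized"][0]
        ratio_of_ratios = (neurite[loc] / soma[loc]) / (neurite[unloc] / soma[unloc])
        assert ratio_of_ratios == pytest.approx(2.0 ** cfg.loc_effect_log2, rel=0.05)

    def test_zero_depth_gives_zero_matrix(self):
        cfg = _config(rna_depth=0.0)
        counts = simulate_rna_counts(simulate_genes(cfg), cfg)
        assert (counts.to_numpy() == 0).all()

    def test_unlocalized_genes_have_null_mean_log_ratio(self):
        for seed in range(1, 6):
            cfg = SimConfig(
                n_genes=1000,
                seed=seed,
                mechanism_fractions={"unlocalized": 1.0},
                lncrna_fraction=0.0,
            )
            genes = simulate_genes(cfg)
            counts = simulate_rna_counts(genes, cfg)
            ratio = np.log2(
                (counts.filter(like="neurite").mean(axis=1) + 0.5)
                / (counts.filter(like="soma").mean(axis=1) + 0.5)
            )
            assert abs(ratio.mean()) < 0.05

    def test_library_size_conservation(self):
        cfg = SimConfig(n_genes=1000, seed=2)
        counts = simulate_rna_counts(simulate_genes(cfg), cfg)
        for col, total in counts.sum(axis=0).items():
            assert total == pytest.approx(cfg.rna_depth, rel=0.02), col


class TestFootprints:
    def test_pure_frame0_bias(self):
        cfg = _config(frame0_bias=1.0, footprint_depth=5000)
        fp = simulate_footprints(simulate_genes(cfg), cfg)
        psite = fp["five_prime_offset"] + 12
        assert (psite % 3 == 0).all()

    def test_uniform_bias_gives_uniform_frames(self):
        from scipy.stats import chisquare

        cfg = _config(frame0_bias=1.0 / 3.0, footprint_depth=10_000, n_replicates=2)
        fp = simulate_footprints(simulate_genes(cfg), cfg)
        frames = (fp["five_prime_offset"] + 12) % 3
        assert chisquare(np.bincount(frames, minlength=3)).pvalue > 0.01

    def test_lengths_within_window(self):
        cfg = _config(footprint_depth=3000)
        fp = simulate_footprints(simulate_genes(cfg), cfg)
        assert fp["length"].between(27, 31).all()
        assert (fp["length"] == 31).any()  # the filter-exercising tail exists

    def test_lncrna_only_gives_empty_table_with_warning(self):
        cfg = _config(
            mechanism_fractions={"unlocalized": 1.0}, lncrna_fraction=0.9
        )
        genes = simulate_genes(cfg)
        genes = genes[genes["biotype"] == "lncRNA"]
        with pytest.warns(UserWarning, match="no coding genes"):
            fp = simulate_footprints(genes, cfg)
        assert fp.empty


class TestProtein:
    def test_noise_free_difference_equals_true_effect(self):
        cfg = _config(protein_noise_sd=0.0, missing_midpoint=-np.inf)
        genes = simulate_genes(cfg)
        sim = simulate_protein_intensities(genes, cfg)
        assert not sim.observed.isna().any().any()
        diff = sim.observed.filter(like="neurite").mean(axis=1) - sim.observed.filter(
            like="soma"
        ).mean(axis=1)
        coding = genes[genes["cds_length"] > 0]
        np.testing.assert_allclose(diff.to_numpy(), coding["prot_loc_log2fc"].to_numpy())

    def test_missingness_is_mnar(self):
        cfg = SimConfig(n_genes=1000, seed=5)
        genes = simulate_genes(cfg)
        sim = simulate_protein_intensities(genes, cfg)
        mask = sim.observed.isna().to_numpy()
        truth = sim.complete.to_numpy()
        assert truth[mask].mean() < truth[~mask].mean()
        # binned missingness rate is monotonically non-increasing in intensity
        bins = pd.qcut(truth.ravel(), 8, labels=False)
        rate = pd.Series(mask.ravel()).groupby(bins).mean()
        assert (rate.diff().dropna() <= 1e-12).all()


class TestSilac:
    def test_noise_free_ratio_equals_translation_effect(self):
        cfg = _config(silac_noise_sd=0.0, silac_coverage=1.0)
        genes = simulate_genes(cfg)
        table = simulate_silac(genes, cfg)
        fc = genes.loc[table.index, "ribo_loc_log2fc"]
        np.testing.assert_allclose(np.log2(table["ratio_fw"]), fc)
        np.testing.assert_allclose(np.log2(table["ratio_rev"]), fc)

    def test_zero_coverage_gives_empty_table(self):
        cfg = _config(silac_coverage=0.0)
        assert simulate_silac(simulate_genes(cfg), cfg).empty

    def test_log_mean_is_unbiased(self):
        errs = []
        for seed in range(1, 6):
            cfg = SimConfig(
                n_genes=500, seed=seed, silac_noise_sd=0.2, silac_coverage=1.0
            )
            genes = simulate_genes(cfg)
            table = simulate_silac(genes, cfg)
            avg = 0.5 * (np.log2(table["ratio_fw"]) + np.log2(table["ratio_rev"]))
            errs.append((avg - genes.loc[table.index, "ribo_loc_log2fc"]).mean())
        assert abs(np.mean(errs)) < 0.03


class TestCirc:
    def test_flagged_genes_follow_reversal_pattern(self):
        cfg = SimConfig(n_genes=500, seed=9, circ_fraction=0.1)
        genes = simulate_genes(cfg)
        sim = simulate_circ(genes, cfg)
        flagged = list(sim.neurite_preferential)
        assert len(flagged) == 50
        circ_n = sim.circ_counts.loc[flagged].filter(like="neurite").mean(axis=1)
        lin_n = sim.linear_counts.loc[flagged].filter(like="neurite").mean(axis=1)
        circ_s = sim.circ_counts.loc[flagged].filter(like="soma").mean(axis=1)
        lin_s = sim.linear_counts.loc[flagged].filter(like="soma").mean(axis=1)
        # expected circ:linear is 10:1 in neurites and 1:7 in soma
        assert (circ_n.sum() / lin_n.sum()) == pytest.approx(10.0, rel=0.1)
        assert (circ_s.sum() / lin_s.sum()) == pytest.approx(1 / 7, rel=0.15)

    def test_unflagged_ratio_identical_across_compartments(self):
        cfg = SimConfig(
            n_genes=400,
            seed=9,
            circ_fraction=0.0,
            mechanism_fractions={"unlocalized": 1.0},
            lncrna_fraction=0.0,
        )
        genes = simulate_genes(cfg)
        sim = simulate_circ(genes, cfg)
        r_n = sim.circ_counts.filter(like="neurite").sum().sum() / sim.linear_counts.filter(
            like="neurite"
        ).sum().sum()
        r_s = sim.circ_counts.filter(like="soma").sum().sum() / sim.linear_counts.filter(
            like="soma"
        ).sum().sum()
        assert r_n == pytest.approx(r_s, rel=0.1)
        assert r_n == pytest.approx(cfg.circ_background_ratio, rel=0.1)

    def test_zero_circ_rate_gives_zero_counts(self):
        cfg = _config(circ_fraction=0.0, circ_background_ratio=0.0)
        sim = simulate_circ(simulate_genes(cfg), cfg)
        assert (sim.circ_counts.to_numpy() == 0).all()


class TestBundle:
    def test_bundle_determinism(self):
        a = simulate_bundle(SimConfig(n_genes=150, seed=11))
        b = simulate_bundle(SimConfig(n_genes=150, seed=11))
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.rna_counts, b.rna_counts)
        pd.testing.assert_frame_equal(a.footprints, b.footprints)
        pd.testing.assert_frame_equal(a.protein.observed, b.protein.observed)
        pd.testing.assert_frame_equal(a.silac, b.silac)
        pd.testing.assert_frame_equal(a.circ.circ_counts, b.circ.circ_counts)

    def test_tables_key_only_annotated_genes(self, small_bundle):
        ids = set(small_bundle.genes.index)
        assert set(small_bundle.rna_counts.index) <= ids
        assert set(small_bundle.footprints["gene_id"]) <= ids
        assert set(small_bundle.protein.observed.index) <= ids
        assert set(small_bundle.silac.index) <= ids
        assert set(small_bundle.circ.circ_counts.index) <= ids

    def test_truth_separate_from_annotation(self, small_bundle):
        assert "mechanism" not in small_bundle.annotation.columns
        assert "mechanism" in small_bundle.truth.columns

    def test_roundtrip_write(self, small_bundle, tmp_path):
        from neuroloc.simulate import write_bundle
        from neuroloc import io

        write_bundle(small_bundle, tmp_path)
        ann = io.read_annotation_tsv(tmp_path / "annotation.tsv")
        assert len(ann) == len(small_bundle.genes)
        counts = io.read_matrix_tsv(tmp_path / "rna_counts.tsv")
        pd.testing.assert_frame_equal(counts, small_bundle.rna_counts, check_names=False)
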
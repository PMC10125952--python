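"""Phantom generators: conservation, determinism, planted mixtures."""

import numpy as np
import pandas as pd
import pytest

from phytocyto.synthetic import (
    PLOIDY_CLASSES,
    STAGES,
    PackingError,
    PhantomSpec,
    TraitSimSpec,
    gen_aoeb_field,
    gen_nuclei_field,
    gen_signal_field,
    gen_trait_table,
    sample_intensities,
)


class TestPhantomSpecValidation:
    def test_bad_mixture_sum(self):
        spec = PhantomSpec(ploidy_mixture=(0.5, 0.5, 0.5, 0, 0))
        with pytest.raises(ValueError, match="sum to 1"):
            spec.validate()

    @pytest.mark.parametrize("kwargs", [
        dict(n_cells=-1), dict(noise_sd=-0.5), dict(min_separation=0.0),
        dict(stage_mixture=(1.0, 0.0, 0.0)),
    ])
    def test_invalid_fields(self, kwargs):
        with pytest.raises(ValueError):
            PhantomSpec(**kwargs).validate()

    def test_packing_failure(self):
        spec = PhantomSpec(image_shape=(64, 64), n_cells=50, seed=0)
        with pytest.raises(PackingError):
            gen_nuclei_field(spec)


class TestNucleiField:
    def test_empty_field_is_blank_background(self):
        spec = PhantomSpec(n_cells=0, noise_sd=0.0, image_shape=(128, 128))
        img, truth = gen_nuclei_field(spec)
        assert np.all(img.data == spec.background)
        assert len(truth.objects) == 0

    def test_noise_free_conservation(self, nuclei_field, small_spec):
        """Summed above-background signal equals the planted
        C x scale / 2 for every nucleus (raster-exact)."""
        img, truth = nuclei_field
        raster = img.channel("dapi")
        for row in truth.objects.itertuples():
            region = truth.masks["nucleus"] == row.object_id
            measured = raster[region].sum() - small_spec.background * region.sum()
            assert measured == pytest.approx(row.integrated_au, rel=5e-3)
            assert row.integrated_au == pytest.approx(
                row.dna_content_c / 2 * small_spec.intensity_scale
            )

    def test_one_truth_record_per_object(self, nuclei_field):
        img, truth = nuclei_field
        mask_ids = set(np.unique(truth.masks["nucleus"])) - {0}
        assert mask_ids == set(truth.objects["object_id"])

    def test_seed_determinism_bit_identical(self):
        spec = PhantomSpec(image_shape=(128, 128), n_cells=6, noise_sd=2.0, seed=99)
        img1, t1 = gen_nuclei_field(spec)
        img2, t2 = gen_nuclei_field(spec)
        np.testing.assert_array_equal(img1.data, img2.data)
        pd.testing.assert_frame_equal(t1.objects, t2.objects)
        np.testing.assert_array_equal(t1.masks["nucleus"], t2.masks["nucleus"])

    def test_mixture_counts_reproducible_under_seed(self):
        """Label counts of a 700-nucleus draw are a multinomial draw
        fully determined by the seed."""
        spec = PhantomSpec(
            n_cells=700, ploidy_mixture=(0.0, 0.60, 0.30, 0.10, 0.0), seed=1234
        )
        labels1, _ = sample_intensities(spec)
        labels2, _ = sample_intensities(spec)
        assert (labels1 == labels2).all()
        counts = pd.Series(labels1).value_counts(normalize=True)
        assert counts.get("2C", 0) == pytest.approx(0.60, abs=0.06)
        assert counts.get("S", 0) == pytest.approx(0.30, abs=0.06)

    def test_mean_label_fractions_match_mixture(self):
        """Over 50 seeds at n=700, mean fractions sit within 3 SE of the
        planted mixture."""
        mix = (0.0, 0.60, 0.30, 0.10, 0.0)
        n, n_seeds = 700, 50
        fracs = np.zeros((n_seeds, len(PLOIDY_CLASSES)))
        for s in range(n_seeds):
            labels, _ = sample_intensities(
                PhantomSpec(n_cells=n, ploidy_mixture=mix, seed=s)
            )
            for k, cls in enumerate(PLOIDY_CLASSES):
                fracs[s, k] = np.mean(labels == cls)
        mean = fracs.mean(axis=0)
        se = np.sqrt(np.array(mix) * (1 - np.array(mix)) / (n * n_seeds))
        assert np.all(np.abs(mean - mix) <= 3 * se + 1e-12)


class TestAoebField:
    def test_all_alive_red_at_background(self):
        spec = PhantomSpec(image_shape=(256, 256), n_cells=6, noise_sd=0.0,
                           stage_mixture=(1.0, 0, 0, 0), seed=3)
        img, truth = gen_aoeb_field(spec)
        assert np.all(img.channel("red") == spec.background)
        assert set(truth.objects["stage"]) == {"alive"}

    def test_all_dead_ratio_above_threshold(self):
        spec = PhantomSpec(image_shape=(256, 256), n_cells=6, noise_sd=0.0,
                           stage_mixture=(0, 0, 0, 1.0), seed=4)
        img, truth = gen_aoeb_field(spec)
        assert (truth.objects["rho_nucleus"] >= 1.5).all()

    def test_nucleolus_nested_in_nucleus(self, aoeb_field):
        img, truth = aoeb_field
        nco = truth.masks["nucleolus"] > 0
        nuc = truth.masks["nucleus"] > 0
        assert not np.any(nco & ~nuc)


class TestSignalFields:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown signal kind"):
            gen_signal_field("starch", PhantomSpec(), None)

    def test_callose_planted_wall_means(self):
        img, truth = gen_signal_field(
            "callose", PhantomSpec(noise_sd=0.0, seed=5),
            {"wall_means": [150.0, 330.0]},
        )
        raster = img.channel("aniline_blue")
        for row in truth.objects.itertuples():
            wall = truth.masks["cross_wall"] == row.object_id
            assert raster[wall].mean() - 100.0 == pytest.approx(row.mean_au)

    def test_calcium_nuclear_twice_cytoplasmic(self):
        img, truth = gen_signal_field(
            "calcium", PhantomSpec(n_cells=4, noise_sd=0.0, seed=6),
            {"cyto_mean": 80.0, "nuc_mean": 160.0},
        )
        raster = img.channel("ctc")
        cell1 = truth.masks["cell"] == 1
        nuc1 = truth.masks["nucleus"] == 1
        cyto1 = cell1 & ~nuc1
        ratio = (raster[nuc1].mean() - 100.0) / (raster[cyto1].mean() - 100.0)
        assert ratio == pytest.approx(2.0)

    def test_evans_blue_planted_stained_fraction(self):
        img, truth = gen_signal_field(
            "evans_blue", PhantomSpec(n_cells=40, noise_sd=0.0, seed=7),
            {"stained_fraction": 0.60},
        )
        assert truth.objects["stained"].mean() == pytest.approx(0.60)


class TestTraitTable:
    def test_non_psd_matrix_rejected(self):
        corr = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        spec = TraitSimSpec(traits=("a", "b", "c"), corr=corr)
        with pytest.raises(ValueError, match="positive semidefinite"):
            gen_trait_table(spec)

    def test_identity_correlation_low_sample_r(self):
        """n=1000 with identity corr: every off-diagonal |r| < 0.11
        (Fisher-z bound at that n)."""
        spec = TraitSimSpec(traits=("a", "b", "c", "d"), n_samples=500, seed=13)
        table, _ = gen_trait_table(spec)
        r = table[["a", "b", "c", "d"]].corr().to_numpy()
        off = r[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.11)

    def test_planted_perfect_correlation(self):
        corr = np.array([[1.0, 1.0], [1.0, 1.0]])
        table, _ = gen_trait_table(
            TraitSimSpec(traits=("a", "b"), n_samples=30, corr=corr, seed=2)
        )
        r = np.corrcoef(table["a"], table["b"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_planted_block_mean_r_unbiased(self):
        """Planted r=0.9 at n=50: mean sample r over 200 seeds within
        0.9 +/- 0.02."""
        corr = np.array([[1.0, 0.9], [0.9, 1.0]])
        rs = []
        for s in range(200):
            table, _ = gen_trait_table(
                TraitSimSpec(traits=("a", "b"), n_samples=25, corr=corr, seed=s)
            )
            rs.append(np.corrcoef(table["a"], table["b"])[0, 1])
        assert np.mean(rs) == pytest.approx(0.9, abs=0.02)

    def test_group_effects_shift_kinetin(self):
        spec = TraitSimSpec(traits=("x", "y"), n_samples=200,
                            effects={"x": 2.0}, seed=8)
        table, _ = gen_trait_table(spec)
        dx = table[table.group == "kinetin"]["x"].mean() - \
            table[table.group == "control"]["x"].mean()
        assert dx == pytest.approx(2.0, abs=0.3)
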
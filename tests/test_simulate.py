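import numpy as np
import pytest
from dataclasses import replace

from jembed.datatypes import CountMatrix
from jembed.metrics import kni, kni_chance_level, silhouette_mean
from jembed.preprocess import log_normalize, pca_project
from jembed.simulate import (
    ModalityParams,
    SimConfig,
    make_shuffled_modality,
    scaling_suite,
    simulate_multimodal,
    three_modality_dataset,
    toy_two_view_scenario,
)


class TestSimulateMultimodal:
    def test_seed_determinism(self):
        cfg = SimConfig(n_cells=50, seed=7)
        a = simulate_multimodal(cfg)
        b = simulate_multimodal(cfg)
        np.testing.assert_array_equal(
            a.modalities["RNA"].values, b.modalities["RNA"].values
        )
        np.testing.assert_array_equal(
            a.modalities["ADT"].values, b.modalities["ADT"].values
        )
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_counts_are_nonnegative_integers_with_requested_shape(self):
        cfg = SimConfig(n_cells=40, rna=ModalityParams(n_features=25))
        sim = simulate_multimodal(cfg)
        rna = sim.modalities["RNA"]
        assert rna.values.shape == (40, 25)
        assert np.issubdtype(rna.values.dtype, np.integer)
        assert np.all(rna.values >= 0)

    def test_invalid_group_probs_raise(self):
        with pytest.raises(ValueError, match="simplex"):
            SimConfig(n_groups=3, group_probs=(0.5, 0.2, 0.1))

    def test_unequal_group_abundances_supported(self):
        cfg = SimConfig(
            n_cells=300, n_groups=5, group_probs=(0.4, 0.3, 0.15, 0.1, 0.05), seed=0
        )
        sim = simulate_multimodal(cfg)
        _, counts = np.unique(sim.labels, return_counts=True)
        assert counts.max() > counts.min()  # abundances differ

    def test_no_de_signal_means_chance_level_kni(self):
        """With de_prob = 0 the labels carry no information."""
        vals = []
        for seed in range(10):
            cfg = SimConfig(
                n_cells=200,
                seed=seed,
                rna=ModalityParams(n_features=100, de_prob=0.0),
                adt=ModalityParams(n_features=100, de_prob=0.0),
            )
            sim = simulate_multimodal(cfg)
            view = pca_project(log_normalize(sim.modalities["RNA"]), 2)
            vals.append(kni(view.values, sim.labels, k=10))
            chance = kni_chance_level(sim.labels)
        assert abs(np.mean(vals) - chance) < 0.05

    def test_negative_binomial_moments(self):
        """Without dropout / library-size noise, Var = mu + phi * mu^2."""
        phi = 0.3
        cfg = SimConfig(
            n_cells=10_000,
            n_groups=1,
            group_probs=(1.0,),
            rna=ModalityParams(
                n_features=200, dispersion=phi, dropout_shape=0.0,
                libsize_sigma=0.0, de_prob=0.0, outlier_prob=0.0,
            ),
            seed=3,
        )
        sim = simulate_multimodal(cfg)
        X = sim.modalities["RNA"].values.astype(float)
        mean = X.mean(axis=0)
        var = X.var(axis=0)
        expected = mean + phi * mean**2
        keep = mean > 0.5  # moments of near-empty features are noise
        rel_err = np.abs(var[keep] - expected[keep]) / expected[keep]
        assert np.median(rel_err) < 0.15

    def test_separation_increases_with_effect_size(self):
        sils = []
        for scale in (0.25, 1.0, 4.0):
            vals = []
            for seed in range(5):
                cfg = SimConfig(
                    n_cells=150,
                    seed=seed,
                    rna=ModalityParams(n_features=100, de_logfc_scale=scale),
                )
                sim = simulate_multimodal(cfg)
                view = pca_project(log_normalize(sim.modalities["RNA"]), 10)
                vals.append(silhouette_mean(view.values, sim.labels))
            sils.append(np.mean(vals))
        assert sils[0] < sils[1] < sils[2]


class TestShuffledModality:
    @pytest.fixture()
    def counts(self, rng):
        return CountMatrix(
            values=rng.poisson(5, (50, 8)),
            cell_ids=[f"c{i}" for i in range(50)],
            feature_ids=[f"g{i}" for i in range(8)],
            modality_name="RNA",
        )

    def test_zero_fraction_is_identity(self, counts):
        out = make_shuffled_modality(counts, 0.0, seed=1)
        np.testing.assert_array_equal(out.values, counts.values)

    def test_row_multiset_preserved(self, counts):
        out = make_shuffled_modality(counts, 0.7, seed=1)
        orig = np.sort(counts.values, axis=0)
        new = np.sort(out.values, axis=0)
        np.testing.assert_array_equal(
            np.sort(counts.values.view([("", counts.values.dtype)] * 8), axis=0),
            np.sort(out.values.view([("", out.values.dtype)] * 8), axis=0),
        )
        np.testing.assert_array_equal(orig, new)

    def test_at_most_floor_fraction_rows_change(self, counts):
        frac = 0.4
        out = make_shuffled_modality(counts, frac, seed=2)
        changed = np.any(out.values != counts.values, axis=1).sum()
        assert changed <= int(np.floor(frac * 50))

    def test_invalid_fraction_raises(self, counts):
        with pytest.raises(ValueError):
            make_shuffled_modality(counts, 1.5)


class TestToyScenario:
    def test_four_balanced_groups(self):
        sim = toy_two_view_scenario(80, seed=0)
        _, counts = np.unique(sim.labels, return_counts=True)
        np.testing.assert_array_equal(counts, [20, 20, 20, 20])

    def test_each_modality_confounds_one_pair(self):
        sim = toy_two_view_scenario(200, seed=0)
        A = sim.modalities["modality_A"].values
        B = sim.modalities["modality_B"].values
        lab = sim.labels
        # confounded pair: centroid distance ~ 0; separated pair: ~ 2 * sep
        def centroid_gap(X, g1, g2):
            return np.linalg.norm(
                X[lab == g1].mean(axis=0) - X[lab == g2].mean(axis=0)
            )

        assert centroid_gap(A, "type1", "type2") < 2.0
        assert centroid_gap(A, "type3", "type4") > 10.0
        assert centroid_gap(B, "type3", "type4") < 2.0
        assert centroid_gap(B, "type1", "type2") > 10.0

    def test_unimodal_kni_bounded_by_confounding(self):
        vals = []
        for seed in range(5):
            sim = toy_two_view_scenario(200, seed=seed)
            vals.append(kni(sim.modalities["modality_A"].values, sim.labels, k=10))
        assert np.mean(vals) <= 0.80

    def test_seed_determinism_and_divisibility_check(self):
        a = toy_two_view_scenario(40, seed=5)
        b = toy_two_view_scenario(40, seed=5)
        np.testing.assert_array_equal(
            a.modalities["modality_A"].values, b.modalities["modality_A"].values
        )
        with pytest.raises(ValueError, match="divisible"):
            toy_two_view_scenario(42, seed=0)


class TestScalingSuite:
    def test_two_modality_suite(self):
        sims = scaling_suite([40, 60], n_modalities=2, seed=0)
        assert len(sims) == 2
        assert sims[0].labels.size == 40
        assert sims[1].labels.size == 60
        assert set(sims[0].modalities) == {"RNA", "ADT"}

    def test_four_modality_suite_has_shuffled_copies(self):
        sims = scaling_suite([40], n_modalities=4, seed=0)
        mods = sims[0].modalities
        assert set(mods) == {"RNA", "ADT", "RNA_shuffled", "ADT_shuffled"}
        # shuffled copies share the feature space of their source
        assert mods["RNA_shuffled"].feature_ids == mods["RNA"].feature_ids

    def test_invalid_modality_count_raises(self):
        with pytest.raises(ValueError):
            scaling_suite([40], n_modalities=3, seed=0)


def test_three_modality_dataset_wiring():
    sim = three_modality_dataset(60, shuffle_fraction=0.5, seed=0)
    assert set(sim.modalities) == {"RNA", "ADT", "RNA_shuffled"}
    assert sim.labels.size == 60
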
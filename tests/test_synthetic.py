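import numpy as np
import pandas as pd
import pytest

from karstpatch import geometry, synthetic


class TestConfig:
    def test_defaults_valid(self):
        cfg = synthetic.SynthConfig()
        assert cfg.n_rows == cfg.n_cols == 26
        assert cfg.cell_side == pytest.approx(0.39)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rock_fraction": 1.5},
            {"rock_fraction": -0.1},
            {"n_taxa": 1},
            {"depth_mean": 0.0},
            {"assembly_mode": "bogus"},
            {"clumping": -1.0},
            {"samples_per_patch": 0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            synthetic.SynthConfig(**kwargs)

    def test_json_round_trip(self, tmp_path):
        cfg = synthetic.SynthConfig(seed=9, rock_fraction=0.3)
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        assert synthetic.SynthConfig.from_json(path) == cfg


class TestGenTree:
    def test_smallest_tree(self):
        tree = synthetic.gen_tree(2, 1)
        assert tree.n_tips == 2

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            synthetic.gen_tree(1, 0)

    def test_byte_identical_newick(self):
        assert synthetic.gen_tree(50, 7).to_newick() == synthetic.gen_tree(50, 7).to_newick()

    def test_different_seeds_differ(self):
        assert synthetic.gen_tree(20, 1).to_newick() != synthetic.gen_tree(20, 2).to_newick()

    def test_cophenetic_metric_properties(self):
        dist = synthetic.gen_tree(50, 7).cophenetic()
        np.testing.assert_allclose(dist.values, dist.values.T)
        np.testing.assert_allclose(np.diag(dist.values), 0.0)
        assert (dist.values[~np.eye(50, dtype=bool)] > 0).all()

    def test_positive_branch_lengths(self):
        tree = synthetic.gen_tree(30, 5)
        assert tree.total_branch_length() > 0
        # ultrametric by construction
        depths = [tree.faith_pd([label]) for label in tree.tip_labels]
        assert max(depths) - min(depths) < 1e-6


class TestGenSoilGrid:
    def test_no_rock_single_patch(self):
        cfg = synthetic.SynthConfig(rock_fraction=0.0, seed=1)
        grid = synthetic.gen_soil_grid(cfg)
        assert (grid.depths > 0).all()
        assert geometry.delineate_patches(grid).n_patches == 1

    def test_all_rock_zero_patches(self):
        cfg = synthetic.SynthConfig(rock_fraction=1.0, seed=1)
        grid = synthetic.gen_soil_grid(cfg)
        assert (grid.depths == 0).all()
        assert geometry.delineate_patches(grid).n_patches == 0

    @pytest.mark.parametrize("fraction", [0.2, 0.5, 0.8])
    def test_rock_fraction_within_tolerance(self, fraction):
        cfg = synthetic.SynthConfig(rock_fraction=fraction, seed=4)
        grid = synthetic.gen_soil_grid(cfg)
        assert abs((grid.depths == 0).mean() - fraction) <= 0.05

    def test_clumping_reduces_patch_count(self):
        clumped = synthetic.SynthConfig(rock_fraction=0.5, clumping=2.0, seed=3)
        scattered = synthetic.SynthConfig(rock_fraction=0.5, clumping=0.0, seed=3)
        n_clumped = geometry.delineate_patches(synthetic.gen_soil_grid(clumped)).n_patches
        n_scattered = geometry.delineate_patches(synthetic.gen_soil_grid(scattered)).n_patches
        assert n_clumped < n_scattered

    def test_depth_distribution(self):
        cfg = synthetic.SynthConfig(
            n_rows=100, n_cols=100, rock_fraction=0.0, depth_mean=24.27, depth_cv=0.53, seed=8
        )
        depths = synthetic.gen_soil_grid(cfg).depths
        assert depths.mean() == pytest.approx(24.27, rel=0.05)
        assert depths.std() / depths.mean() == pytest.approx(0.53, rel=0.15)

    def test_determinism(self):
        cfg = synthetic.SynthConfig(seed=12)
        a = synthetic.gen_soil_grid(cfg)
        b = synthetic.gen_soil_grid(cfg)
        np.testing.assert_array_equal(a.depths, b.depths)


@pytest.fixture(scope="module")
def patch_map():
    cfg = synthetic.SynthConfig(seed=3)
    return geometry.delineate_patches(synthetic.gen_soil_grid(cfg))


class TestGenResourceSamples:
    def test_every_patch_sampled(self, patch_map):
        cfg = synthetic.SynthConfig(seed=3)
        table = synthetic.gen_resource_samples(patch_map, cfg, seed=1)
        assert set(table["patch_id"]) == set(patch_map.patch_ids)
        assert (table.groupby("patch_id").size() >= 1).all()

    def test_zero_cv_constant_records(self, patch_map):
        cfg = synthetic.SynthConfig(seed=3, swc_cv=0.0)
        table = synthetic.gen_resource_samples(patch_map, cfg, seed=1)
        assert table["SWC_pct"].nunique() == 1
        assert table["SWC_pct"].iloc[0] == pytest.approx(cfg.swc_mean)

    def test_determinism(self, patch_map):
        cfg = synthetic.SynthConfig(seed=3)
        a = synthetic.gen_resource_samples(patch_map, cfg, seed=2)
        b = synthetic.gen_resource_samples(patch_map, cfg, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_monte_carlo_targets(self, patch_map):
        # 1000+ records: sample mean within 5% of target, CV within 15%
        cfg = synthetic.SynthConfig(seed=3, samples_per_patch=200)
        table = synthetic.gen_resource_samples(patch_map, cfg, seed=5)
        swc = table["SWC_pct"]
        assert len(swc) >= 1000
        assert swc.mean() == pytest.approx(17.17, rel=0.05)
        assert swc.std() / swc.mean() == pytest.approx(0.37, rel=0.15)

    def test_empty_patch_map_rejected(self):
        cfg = synthetic.SynthConfig(rock_fraction=1.0, seed=1)
        empty = geometry.delineate_patches(synthetic.gen_soil_grid(cfg))
        with pytest.raises(ValueError):
            synthetic.gen_resource_samples(empty, cfg, seed=0)


@pytest.fixture(scope="module")
def tree():
    return synthetic.gen_tree(40, 2)


class TestGenCommunities:

    def test_flat_richness_model(self, tree):
        cfg = synthetic.SynthConfig(
            n_taxa=40, richness_intercept=5, richness_slope=0, richness_noise_sd=0.0
        )
        areas = synthetic.gen_patch_areas(30, seed=1)
        comm = synthetic.gen_communities(areas, tree, cfg, seed=4)
        assert ((comm > 0).sum(axis=1) == 5).all()

    def test_positive_integer_abundances(self, tree):
        cfg = synthetic.SynthConfig(n_taxa=40)
        areas = synthetic.gen_patch_areas(10, seed=2)
        comm = synthetic.gen_communities(areas, tree, cfg, seed=4)
        present = comm.to_numpy()[comm.to_numpy() > 0]
        assert np.issubdtype(comm.dtypes.iloc[0], np.integer)
        assert (present >= 1).all()

    def test_columns_are_tip_labels(self, tree):
        cfg = synthetic.SynthConfig(n_taxa=40)
        comm = synthetic.gen_communities({1: 2.0}, tree, cfg, seed=0)
        assert list(comm.columns) == tree.tip_labels

    def test_richness_clipped_and_logged(self, tree, caplog):
        cfg = synthetic.SynthConfig(
            n_taxa=40, richness_intercept=-10, richness_slope=0, richness_noise_sd=0.0
        )
        with caplog.at_level("INFO"):
            comm = synthetic.gen_communities({1: 2.0}, tree, cfg, seed=0)
        assert (comm > 0).sum(axis=1).iloc[0] == 1
        assert "clipped" in caplog.text

    def test_determinism(self, tree):
        cfg = synthetic.SynthConfig(n_taxa=40, assembly_mode="filtered")
        areas = synthetic.gen_patch_areas(10, seed=3)
        a = synthetic.gen_communities(areas, tree, cfg, seed=6)
        b = synthetic.gen_communities(areas, tree, cfg, seed=6)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_patches_rejected(self, tree):
        cfg = synthetic.SynthConfig(n_taxa=40)
        with pytest.raises(ValueError):
            synthetic.gen_communities({}, tree, cfg, seed=0)

    def test_richness_tracks_log_area(self, tree):
        cfg = synthetic.SynthConfig(
            n_taxa=40, richness_intercept=5, richness_slope=8, richness_noise_sd=0.0
        )
        comm = synthetic.gen_communities({1: 0.5, 2: 50.0}, tree, cfg, seed=0)
        r = (comm > 0).sum(axis=1)
        assert r.loc[2] > r.loc[1]


class TestGenPatchAreas:
    def test_count_and_range(self):
        areas = synthetic.gen_patch_areas(100, seed=0)
        assert len(areas) == 100
        assert areas["PA_m2"].between(0.15, 67.19).all()

    def test_determinism(self):
        pd.testing.assert_frame_equal(
            synthetic.gen_patch_areas(50, seed=1), synthetic.gen_patch_areas(50, seed=1)
        )
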
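import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter

from gazecross.gazemaps import GazeMap
from gazecross.statmap import (
    DesignError,
    cluster_bootstrap_correct,
    contrast_map,
    pixelwise_fit,
    significant_area,
)

H, W = 68, 120  # small grid keeps the unit tests fast


def smooth_noise_maps(n_per_group, seed, effect=0.0, disc=None, groups=("A", "B"), sigma=3):
    rng = np.random.default_rng(seed)
    maps, rows = [], []
    for name in groups:
        for p in range(n_per_group):
            m = gaussian_filter(rng.normal(0, 1, (H, W)), sigma)
            m /= m.std()
            if name == groups[-1] and disc is not None:
                m = m + effect * disc
            maps.append(m)
            rows.append({"participant_id": f"{name}{p}", "age_group": name})
    return np.stack(maps), pd.DataFrame(rows)


def centre_disc(r=12, cx=40, cy=30):
    yy, xx = np.mgrid[0:H, 0:W]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


class TestPixelwiseFit:
    def test_identical_maps_give_zero_f(self):
        maps, design = smooth_noise_maps(4, seed=0)
        maps = np.repeat(maps[:1], len(maps), axis=0)
        sm = pixelwise_fit(maps, design, "age_group")
        np.testing.assert_allclose(sm.stat, 0.0)

    def test_peak_statistic_inside_planted_disc(self):
        disc = centre_disc()
        maps, design = smooth_noise_maps(8, seed=1, effect=2.0, disc=disc)
        sm = pixelwise_fit(maps, design, "age_group")
        iy, ix = np.unravel_index(np.argmax(sm.stat), sm.stat.shape)
        assert disc[iy, ix]

    def test_matches_anova_oracle_per_pixel(self):
        # independent check: scipy one-way ANOVA on individual pixels
        maps, design = smooth_noise_maps(6, seed=2, effect=1.0, disc=centre_disc())
        sm = pixelwise_fit(maps, design, "age_group")
        rng = np.random.default_rng(3)
        a = maps[design["age_group"] == "A"]
        b = maps[design["age_group"] == "B"]
        for _ in range(10):
            iy, ix = rng.integers(0, H), rng.integers(0, W)
            f_ref, _ = stats.f_oneway(a[:, iy, ix], b[:, iy, ix])
            assert sm.stat[iy, ix] == pytest.approx(f_ref, rel=1e-8)

    def test_invariant_to_row_order(self):
        maps, design = smooth_noise_maps(5, seed=4, effect=1.0, disc=centre_disc())
        sm1 = pixelwise_fit(maps, design, "age_group")
        perm = np.random.default_rng(0).permutation(len(maps))
        sm2 = pixelwise_fit(maps[perm], design.iloc[perm], "age_group")
        np.testing.assert_allclose(sm1.stat, sm2.stat, rtol=1e-8)

    def test_single_level_factor_rejected(self):
        maps, design = smooth_noise_maps(4, seed=5, groups=("A",))
        with pytest.raises(DesignError):
            pixelwise_fit(maps, design, "age_group")

    def test_trials_average_within_participant(self):
        # two trials per participant: fitting on trial maps equals fitting
        # on participant means
        maps, design = smooth_noise_maps(4, seed=6)
        maps2 = np.concatenate([maps, maps + np.random.default_rng(1).normal(0, 0.1, maps.shape)])
        design2 = pd.concat([design, design], ignore_index=True)
        sm2 = pixelwise_fit(maps2, design2, "age_group")
        mean_maps = (maps2[: len(maps)] + maps2[len(maps) :]) / 2
        sm1 = pixelwise_fit(mean_maps, design, "age_group")
        np.testing.assert_allclose(sm2.stat, sm1.stat, rtol=1e-8)


class TestClusterCorrection:
    def test_corrected_mask_subset_of_suprathreshold(self):
        disc = centre_disc()
        maps, design = smooth_noise_maps(8, seed=7, effect=1.5, disc=disc)
        un = pixelwise_fit(maps, design, "age_group")
        co = cluster_bootstrap_correct(un, maps, design, alpha=0.05, n_boot=100, seed=0)
        supra = co.stat > co.threshold
        assert np.all(supra[co.mask])

    def test_planted_disc_recovered(self):
        disc = centre_disc()
        maps, design = smooth_noise_maps(10, seed=8, effect=2.0, disc=disc)
        un = pixelwise_fit(maps, design, "age_group")
        co = cluster_bootstrap_correct(un, maps, design, alpha=0.05, n_boot=200, seed=1)
        jac = (co.mask & disc).sum() / (co.mask | disc).sum()
        assert jac >= 0.5

    def test_cluster_sizes_sum_to_mask_area(self):
        disc = centre_disc()
        maps, design = smooth_noise_maps(8, seed=9, effect=2.0, disc=disc)
        un = pixelwise_fit(maps, design, "age_group")
        co = cluster_bootstrap_correct(un, maps, design, alpha=0.05, n_boot=100, seed=2)
        assert sum(c.size_px for c in co.clusters if c.significant) == co.mask.sum()

    def test_small_nboot_rejected(self):
        maps, design = smooth_noise_maps(4, seed=10)
        un = pixelwise_fit(maps, design, "age_group")
        with pytest.raises(ValueError):
            cluster_bootstrap_correct(un, maps, design, n_boot=50)

    def test_permissive_alpha_keeps_more_area(self):
        disc = centre_disc()
        maps, design = smooth_noise_maps(8, seed=11, effect=1.5, disc=disc)
        un = pixelwise_fit(maps, design, "age_group")
        strict = cluster_bootstrap_correct(un, maps, design, alpha=0.01, n_boot=100, seed=3)
        lax = cluster_bootstrap_correct(un, maps, design, alpha=0.5, n_boot=100, seed=3)
        assert lax.mask.sum() >= strict.mask.sum()


class TestContrast:
    def test_self_contrast_is_zero(self):
        maps, design = smooth_noise_maps(5, seed=12)
        design2 = design.copy()
        sm = contrast_map(maps, design2, "A", "A", n_boot=100, seed=0)
        np.testing.assert_allclose(sm.stat, 0.0, atol=1e-10)

    def test_antisymmetry(self):
        maps, design = smooth_noise_maps(5, seed=13, effect=1.0, disc=centre_disc())
        ab = contrast_map(maps, design, "A", "B", n_boot=100, seed=0)
        ba = contrast_map(maps, design, "B", "A", n_boot=100, seed=0)
        np.testing.assert_allclose(ab.stat, -ba.stat, atol=1e-10)

    def test_signed_clusters_at_planted_hotspots(self):
        rng = np.random.default_rng(14)
        disc_a = centre_disc(10, 30, 20)
        disc_b = centre_disc(10, 90, 50)
        maps, rows = [], []
        for name, disc in (("A", disc_a), ("B", disc_b)):
            for p in range(8):
                m = gaussian_filter(rng.normal(0, 1, (H, W)), 3)
                m = m / m.std() + 2.5 * disc
                maps.append(m)
                rows.append({"participant_id": f"{name}{p}", "age_group": name})
        sm = contrast_map(np.stack(maps), pd.DataFrame(rows), "A", "B", n_boot=200, seed=1)
        assert sm.mask is not None and sm.mask.any()
        assert sm.stat[sm.mask & disc_a].mean() > 0
        assert sm.stat[sm.mask & disc_b].mean() < 0

    def test_unknown_group_rejected(self):
        maps, design = smooth_noise_maps(4, seed=15)
        with pytest.raises(KeyError):
            contrast_map(maps, design, "A", "Z")


class TestSignificantArea:
    def test_requires_mask(self):
        maps, design = smooth_noise_maps(4, seed=16)
        un = pixelwise_fit(maps, design, "age_group")
        with pytest.raises(ValueError):
            significant_area(un)

    def test_empty_and_full_mask_rescaling(self):
        maps, design = smooth_noise_maps(4, seed=17)
        un = pixelwise_fit(maps, design, "age_group")
        un.downsample = 4
        un.mask = np.zeros((270, 480), bool)
        assert significant_area(un) == 0
        un.mask = np.ones((270, 480), bool)
        assert significant_area(un) == 1920 * 1080

    def test_planted_disc_area_within_factor_two(self):
        # 50x50 px full-resolution disc (radius 25 px) on maps downsampled 4x
        h, w = 270, 480
        yy, xx = np.mgrid[0:h, 0:w]
        disc = (xx - 120) ** 2 + (yy - 80) ** 2 <= (25 / 4) ** 2
        rng = np.random.default_rng(18)
        maps, rows = [], []
        for name in ("A", "B"):
            for p in range(10):
                m = gaussian_filter(rng.normal(0, 1, (h, w)), 2)
                m /= m.std()
                if name == "B":
                    m = m + 3.0 * disc
                maps.append(GazeMap(grid=m, sigma_deg=1.0, downsample=4, z_scored=True))
                rows.append({"participant_id": f"{name}{p}", "age_group": name})
        design = pd.DataFrame(rows)
        un = pixelwise_fit(maps, design, "age_group")
        co = cluster_bootstrap_correct(un, maps, design, alpha=0.05, n_boot=200, seed=5)
        area = significant_area(co)
        true_area = np.pi * 25**2  # ~1963 full-resolution px
        assert true_area / 2 <= area <= true_area * 2
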
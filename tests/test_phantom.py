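"""Phantom generator: ground-truth consistency, defect carving, and the
cohort simulator."""

import numpy as np
import pytest

from fissint.cohort import classify_gold
from fissint.phantom import (
    FISSURE_LABELS,
    PhantomConfigError,
    PhantomSpec,
    carve_defects,
    generate_phantom,
    simulate_cohort,
    simulate_spirometry,
)
from fissint.surfaces import voxel_sheet_area


class TestGeneratePhantom:
    def test_no_defects_means_full_integrity(self, phantom_complete):
        _, _, truth = phantom_complete
        for lb in FISSURE_LABELS:
            assert truth.true_integrity[lb] == pytest.approx(100.0)
            assert np.array_equal(truth.fissure_truth[lb], truth.boundary_truth[lb])
        assert truth.true_elf == pytest.approx(100.0)

    def test_true_integrity_tracks_targets(self, phantom_noise_free):
        spec, _, truth = phantom_noise_free
        for lb, target in zip(FISSURE_LABELS, spec.target_integrity):
            assert truth.true_integrity[lb] == pytest.approx(target, abs=2.0)

    def test_true_integrity_recomputes_from_masks(self, phantom_noise_free):
        spec, _, truth = phantom_noise_free
        for lb in FISSURE_LABELS:
            recomputed = 100.0 * voxel_sheet_area(
                truth.fissure_truth[lb], spec.spacing
            ) / voxel_sheet_area(truth.boundary_truth[lb], spec.spacing)
            assert recomputed == pytest.approx(truth.true_integrity[lb], abs=0.1)

    def test_fissure_subset_of_boundary(self, phantom_noise_free):
        _, _, truth = phantom_noise_free
        for lb in FISSURE_LABELS:
            assert np.all(truth.boundary_truth[lb][truth.fissure_truth[lb]])

    def test_lobe_partition(self, phantom_noise_free):
        _, _, truth = phantom_noise_free
        # five lobes partition the two lungs exactly
        assert set(np.unique(truth.lobe_mask)) == {0, 1, 2, 3, 4, 5}
        assert np.array_equal(truth.lobe_mask > 0, truth.lung_mask > 0)
        left = truth.lung_mask == 1
        assert set(np.unique(truth.lobe_mask[left])) == {1, 2}
        right = truth.lung_mask == 2
        assert set(np.unique(truth.lobe_mask[right])) == {3, 4, 5}

    def test_seeded_determinism_bit_for_bit(self):
        spec = PhantomSpec(target_integrity=(70, 50, 80), seed=7, noise_sd=25.0)
        v1, t1 = generate_phantom(spec)
        v2, t2 = generate_phantom(spec)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(t1.lung_mask, t2.lung_mask)
        for lb in FISSURE_LABELS:
            assert np.array_equal(t1.fissure_truth[lb], t2.fissure_truth[lb])

    def test_fissure_voxels_carry_fissure_intensity(self, phantom_noise_free):
        spec, volume, truth = phantom_noise_free
        for lb in FISSURE_LABELS:
            vals = volume.data[truth.fissure_truth[lb]]
            assert np.all(vals == spec.intensity_fissure)

    def test_grid_too_small_raises(self):
        with pytest.raises(PhantomConfigError):
            generate_phantom(PhantomSpec(grid_shape=(8, 8, 8)))

    def test_invalid_targets_rejected(self):
        with pytest.raises(PhantomConfigError):
            PhantomSpec(target_integrity=(120.0, 50.0, 50.0))
        with pytest.raises(PhantomConfigError):
            PhantomSpec(spacing=(0.7, -0.7, 0.625))


class TestCarveDefects:
    @pytest.fixture()
    def sheet(self):
        m = np.zeros((100, 100, 5), dtype=bool)
        m[:, :, 2] = True  # 10,000-voxel planar sheet
        return m

    def test_target_100_is_identity(self, sheet):
        out = carve_defects(sheet, 100.0, 4, seed=0)
        assert np.array_equal(out, sheet)

    def test_target_0_is_empty(self, sheet):
        out = carve_defects(sheet, 0.0, 4, seed=0)
        assert not out.any()

    def test_retained_fraction_hits_target(self, sheet):
        out = carve_defects(sheet, 60.0, 5, seed=2, spacing=(0.7, 0.7, 0.625))
        frac = out.sum() / sheet.sum()
        assert 0.58 <= frac <= 0.62

    def test_output_always_subset(self, sheet, rng):
        for target in (15.0, 45.0, 85.0):
            out = carve_defects(sheet, target, 3, seed=int(rng.integers(1 << 30)))
            assert np.all(sheet[out])

    def test_interior_default_leaves_margin(self, sheet):
        out = carve_defects(
            sheet, 70.0, 2, seed=3, spacing=(0.7, 0.7, 0.625), allow_marginal=False
        )
        removed = sheet & ~out
        # no removed voxel on the outermost rim of the sheet footprint
        rim = np.zeros_like(sheet)
        rim[0, :, 2] = rim[-1, :, 2] = True
        rim[:, 0, 2] = rim[:, -1, 2] = True
        assert not (removed & rim).any()

    def test_marginal_mode_can_cut_the_rim(self, sheet):
        hit_rim = False
        for seed in range(8):
            out = carve_defects(
                sheet, 50.0, 2, seed=seed, spacing=(0.7, 0.7, 0.625),
                allow_marginal=True,
            )
            removed = sheet & ~out
            if removed[0, :, 2].any() or removed[:, 0, 2].any() \
               or removed[-1, :, 2].any() or removed[:, -1, 2].any():
                hit_rim = True
                break
        assert hit_rim

    def test_needs_positive_defect_count(self, sheet):
        with pytest.raises(ValueError):
            carve_defects(sheet, 50.0, 0, seed=0)


class TestSimulateCohort:
    def test_category_counts_follow_mix(self):
        mix = (0.387, 0.145, 0.246, 0.110, 0.112)
        pairs = simulate_cohort(400, gold_mix=mix, seed=11)
        from collections import Counter

        counts = Counter(sp.intended_gold for _, sp in pairs)
        for cat, p in zip(
            ("non-COPD", "GOLD-I", "GOLD-II", "GOLD-III", "GOLD-IV"), mix
        ):
            # within ~4 multinomial standard deviations
            sd = np.sqrt(400 * p * (1 - p))
            assert abs(counts[cat] - 400 * p) < 4 * sd + 1

    def test_degenerate_mix_all_non_copd(self):
        pairs = simulate_cohort(10, gold_mix=(1, 0, 0, 0, 0), seed=5)
        for _, spiro in pairs:
            assert spiro.intended_gold == "non-COPD"
            assert classify_gold(spiro.fev1_fvc_pct, spiro.fev1_pct_pred) == "non-COPD"

    def test_staging_rule_recovers_intended_category(self):
        pairs = simulate_cohort(200, seed=17)
        for _, spiro in pairs:
            staged = classify_gold(spiro.fev1_fvc_pct, spiro.fev1_pct_pred)
            assert staged == spiro.intended_gold

    def test_zero_sd_integrity_is_exact(self):
        dist = {"ROF": (80.0, 0.0), "RHF": (60.0, 0.0), "LOF": (75.0, 0.0)}
        pairs = simulate_cohort(10, integrity_dist=dist, seed=3)
        for spec, _ in pairs:
            assert spec.target_integrity == (80.0, 60.0, 75.0)

    def test_spirometry_physiology(self):
        pairs = simulate_cohort(100, seed=23)
        for _, s in pairs:
            assert 0 < s.fev1_l <= s.fvc_l
            assert s.fev1_pct_pred > 0

    def test_invalid_mix_rejected(self):
        with pytest.raises(PhantomConfigError):
            simulate_cohort(10, gold_mix=(0.5, 0.5, 0.5, 0, 0), seed=0)
        with pytest.raises(PhantomConfigError):
            simulate_cohort(0, seed=0)

    def test_deterministic_for_fixed_seed(self):
        a = simulate_cohort(20, seed=9)
        b = simulate_cohort(20, seed=9)
        for (sa, pa), (sb, pb) in zip(a, b):
            assert sa.target_integrity == sb.target_integrity
            assert sa.seed == sb.seed
            assert pa.fev1_l == pb.fev1_l


class TestSpirometryBands:
    @pytest.mark.parametrize(
        "category", ["non-COPD", "GOLD-I", "GOLD-II", "GOLD-III", "GOLD-IV"]
    )
    def test_each_band_maps_to_its_category(self, category, rng):
        for _ in range(20):
            s = simulate_spirometry(category, rng)
            assert classify_gold(s.fev1_fvc_pct, s.fev1_pct_pred) == category
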
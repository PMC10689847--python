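"""Feature families: closed forms, brute-force oracles and invariances."""

import numpy as np
import pytest

from ifcprofiler.core_data import CellRecord
from ifcprofiler.features import (
    COLOC_NAMES,
    GLCM_LEVELS,
    INTENSITY_NAMES,
    MORPHOLOGY_NAMES,
    SynapseMask,
    _masked_glcm,
    colocalization_features,
    derive_synapse_mask,
    extract_features,
    fluor_relevant_inventory,
    full_inventory,
    intensity_features,
    morphology_features,
    qc_features,
    synaptic_features,
    texture_features,
)
from .conftest import make_record


def disk_mask(center, radius, size=40):
    yy, xx = np.mgrid[:size, :size]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def record_with_masks(cd3, mhcii, size=40):
    channels = ("BF", "F-actin", "MHCII", "CD3", "P-CD3z")
    image = np.ones((5, size, size), dtype=np.uint16)
    masks = np.zeros((5, size, size), dtype=bool)
    masks[2] = mhcii
    masks[3] = cd3
    return CellRecord(record_id="r", channels=channels, image=image, masks=masks)


class TestSynapseMask:
    def test_disjoint_masks_give_empty_synapse(self):
        rec = record_with_masks(disk_mask((10, 10), 3), disk_mask((30, 30), 3))
        assert derive_synapse_mask(rec).area == 0

    def test_identical_masks_superset_by_dilation(self):
        m = disk_mask((20, 20), 5)
        syn = derive_synapse_mask(record_with_masks(m, m))
        assert np.all(syn.mask[m])

    def test_touching_disks_match_brute_force_dilation_oracle(self):
        cd3 = disk_mask((20, 14), 5)
        mhcii = disk_mask((20, 26), 5)
        syn = derive_synapse_mask(record_with_masks(cd3, mhcii))
        # oracle: dilation by pixel enumeration with a euclidean disk footprint
        offsets = [
            (dy, dx)
            for dy in range(-3, 4)
            for dx in range(-3, 4)
            if dy**2 + dx**2 <= 9
        ]

        def dilate(mask):
            out = np.zeros_like(mask)
            for y, x in np.argwhere(mask):
                for dy, dx in offsets:
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < mask.shape[0] and 0 <= xx < mask.shape[1]:
                        out[yy, xx] = True
            return out

        oracle = dilate(cd3) & dilate(mhcii)
        assert oracle.sum() > 0
        np.testing.assert_array_equal(syn.mask, oracle)

    def test_missing_channel_named_in_error(self):
        rec = make_record(channels=("BF", "MHCII"))
        with pytest.raises(KeyError, match="CD3"):
            derive_synapse_mask(rec)


class TestMorphology:
    def test_square_closed_forms(self):
        mask = np.zeros((32, 32), bool)
        mask[5:15, 5:15] = True
        f = morphology_features(mask)
        assert f["area"] == 100
        assert f["extent"] == 1.0
        assert f["solidity"] == 1.0
        assert f["euler number"] == 1
        assert f["bounding box area"] == 100
        assert f["min feret diameter"] == pytest.approx(10.0)
        assert f["equivalent diameter"] == pytest.approx(np.sqrt(400 / np.pi))

    def test_disk_eccentricity_near_zero_vs_stretched(self):
        d = morphology_features(disk_mask((20, 20), 9))
        stretched = np.zeros((40, 40), bool)
        stretched[18:22, 5:35] = True
        s = morphology_features(stretched)
        assert d["eccentricity"] < 0.2 < s["eccentricity"]

    def test_empty_mask_all_missing(self):
        f = morphology_features(np.zeros((8, 8), bool))
        assert all(np.isnan(v) for v in f.values())
        assert len(f) == 30

    def test_hu_moments_invariant_to_translation_and_rotation(self, rng):
        mask = np.zeros((40, 40), bool)
        mask[8:18, 10:16] = True
        mask[12:14, 16:22] = True
        base = morphology_features(mask)
        shifted = np.roll(np.roll(mask, 7, axis=0), -5, axis=1)
        rotated = np.rot90(mask)
        for other in (morphology_features(shifted), morphology_features(rotated)):
            for i in range(1, 8):
                key = f"hu moment {i}"
                assert other[key] == pytest.approx(base[key], rel=1e-6, abs=1e-12)

    def test_weighted_hu_requires_image(self):
        mask = disk_mask((20, 20), 6)
        f = morphology_features(mask, image=None)
        assert np.isnan(f["weighted hu moment 1"])
        g = morphology_features(mask, image=np.ones((40, 40)))
        assert np.isfinite(g["weighted hu moment 1"])

    def test_shape_descriptors_invariant_to_intensity_scaling(self):
        mask = disk_mask((20, 20), 6)
        img = np.random.default_rng(0).uniform(0, 1000, (40, 40))
        a = morphology_features(mask, img)
        b = morphology_features(mask, img * 37.0)
        for name in MORPHOLOGY_NAMES:
            if "weighted" in name:
                continue  # intensity-weighted moments are scale-normalized too
            assert a[name] == pytest.approx(b[name])


class TestIntensity:
    def test_constant_values(self):
        img = np.full((10, 10), 7.0)
        mask = np.ones((10, 10), bool)
        f = intensity_features(img, mask)
        assert f["min intensity"] == f["max intensity"] == f["mean intensity"] == 7
        assert f["std intensity"] == 0
        assert f["entropy"] == 0
        assert f["skewness"] == 0 and f["kurtosis"] == 0

    def test_decile_linear_interpolation(self):
        img = np.arange(1, 101, dtype=float).reshape(10, 10)
        f = intensity_features(img, np.ones((10, 10), bool))
        assert f["10th percentile"] == pytest.approx(10.9)
        assert f["50th percentile"] == pytest.approx(50.5)

    def test_outside_mask_pixels_irrelevant(self, rng):
        img = rng.uniform(0, 5000, (12, 12))
        mask = np.zeros((12, 12), bool)
        mask[3:9, 3:9] = True
        f1 = intensity_features(img, mask)
        img2 = img.copy()
        img2[~mask] = 60000.0
        f2 = intensity_features(img2, mask)
        for name in INTENSITY_NAMES:
            assert f1[name] == pytest.approx(f2[name])

    def test_empty_mask_missing(self):
        f = intensity_features(np.ones((4, 4)), np.zeros((4, 4), bool))
        assert all(np.isnan(v) for v in f.values())


def brute_force_glcm(image, mask):
    """Pair-enumeration oracle for the masked, quantized, averaged GLCM."""
    img = np.asarray(image, float)
    vals = img[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q = np.clip(
            np.floor((img - lo) / (hi - lo) * GLCM_LEVELS), 0, GLCM_LEVELS - 1
        ).astype(int)
    else:
        q = np.zeros_like(img, int)
    acc = np.zeros((GLCM_LEVELS, GLCM_LEVELS))
    for dr, dc in [(0, 1), (1, 1), (1, 0), (1, -1)]:
        counts = np.zeros((GLCM_LEVELS, GLCM_LEVELS))
        H, W = img.shape
        for r in range(H):
            for c in range(W):
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W and mask[r, c] and mask[rr, cc]:
                    counts[q[r, c], q[rr, cc]] += 1
                    counts[q[rr, cc], q[r, c]] += 1
        if counts.sum():
            acc += counts / counts.sum()
    return acc / acc.sum()


class TestTexture:
    def test_constant_image_degenerate_matrix(self):
        f = texture_features(np.full((8, 8), 3.0), np.ones((8, 8), bool))
        assert f["contrast"] == 0
        assert f["dissimilarity"] == 0
        assert f["homogeneity"] == 1
        assert f["ASM"] == 1
        assert f["energy"] == 1
        assert f["correlation"] == 1

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(5):
            img = rng.integers(0, 500, (9, 9)).astype(float)
            mask = rng.random((9, 9)) > 0.3
            if mask.sum() < 4:
                continue
            P = _masked_glcm(img, mask)
            O = brute_force_glcm(img, mask)
            np.testing.assert_allclose(P, O, atol=1e-12)

    def test_checkerboard_contrast_is_squared_level_gap(self):
        img = np.indices((8, 8)).sum(axis=0) % 2 * 100.0
        mask = np.ones((8, 8), bool)
        f = texture_features(img, mask)
        P = brute_force_glcm(img, mask)
        # two quantized levels 0 and 31: contrast = 31^2 * P(unlike pair)
        unlike = P[0, GLCM_LEVELS - 1] + P[GLCM_LEVELS - 1, 0]
        assert f["contrast"] == pytest.approx((GLCM_LEVELS - 1) ** 2 * unlike)

    def test_energy_is_sqrt_asm(self, rng):
        img = rng.uniform(0, 900, (10, 10))
        f = texture_features(img, np.ones((10, 10), bool))
        assert f["energy"] == pytest.approx(np.sqrt(f["ASM"]))


class TestColocalization:
    def test_two_pixel_set_arithmetic(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = a[0, 1] = True
        b[0, 1] = b[1, 1] = True
        img = np.random.default_rng(1).uniform(1, 10, (4, 4))
        f = colocalization_features(img, a, img, b)
        assert f["dice distance"] == pytest.approx(0.5)
        assert f["jaccard distance"] == pytest.approx(2 / 3)
        assert f["intersection area"] == 1
        assert f["union area"] == 3
        assert f["overlap fraction"] == pytest.approx(0.5)

    def test_identity_case(self, rng):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        img = rng.uniform(1, 100, (8, 8))
        f = colocalization_features(img, mask, img, mask)
        assert f["dice distance"] == 0
        assert f["hausdorff distance"] == 0
        assert f["pearson correlation"] == pytest.approx(1.0)
        assert f["ICQ"] == pytest.approx(0.5)
        assert f["structural similarity"] == pytest.approx(1.0)
        assert f["correlation distance"] == pytest.approx(0.0, abs=1e-12)

    def test_hausdorff_single_points(self):
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[0, 0] = True
        b[3, 4] = True
        f = colocalization_features(np.ones((6, 6)), a, np.ones((6, 6)), b)
        assert f["hausdorff distance"] == pytest.approx(5.0)

    def test_bounds_on_random_inputs(self, rng):
        for _ in range(10):
            a = rng.random((10, 10)) > 0.5
            b = rng.random((10, 10)) > 0.5
            ia = rng.uniform(0, 3000, (10, 10))
            ib = rng.uniform(0, 3000, (10, 10))
            if not (a.any() or b.any()):
                continue
            f = colocalization_features(ia, a, ib, b)
            assert 0 <= f["dice distance"] <= 1
            assert 0 <= f["jaccard distance"] <= 1
            assert -0.5 <= f["ICQ"] <= 0.5
            for m in ("manders M1", "manders M2"):
                if not np.isnan(f[m]):
                    assert 0 <= f[m] <= 1
            for d in ("euclidean distance", "correlation distance",
                      "cosine distance", "hausdorff distance"):
                if not np.isnan(f[d]):
                    assert f[d] >= 0

    def test_both_masks_empty_all_missing(self):
        z = np.zeros((4, 4), bool)
        f = colocalization_features(np.ones((4, 4)), z, np.ones((4, 4)), z)
        assert all(np.isnan(v) for v in f.values())
        assert len(f) == len(COLOC_NAMES)


class TestSynaptic:
    def test_uniform_intensity_enrichment_one(self):
        cell = disk_mask((20, 20), 8)
        syn = SynapseMask(mask=disk_mask((20, 24), 3))
        img = np.where(cell, 5.0, 0.0)
        f = synaptic_features(img, cell, syn)
        assert f["enrichment (mean)"] == pytest.approx(1.0)

    def test_all_signal_inside_synapse_sum_one(self):
        cell = disk_mask((20, 20), 8)
        synm = disk_mask((20, 22), 2) & cell
        img = np.where(synm, 9.0, 0.0)
        f = synaptic_features(img, cell, SynapseMask(mask=synm))
        assert f["enrichment (sum)"] == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        # 5 cell pixels {0, 0, 4, 6, 0}: mean 2; synapse pixels {4, 6}
        cell = np.zeros((4, 4), bool)
        cell[0, :4] = True
        cell[1, 0] = True
        img = np.zeros((4, 4))
        img[0] = [0, 0, 4, 6]
        syn = np.zeros((4, 4), bool)
        syn[0, 2] = syn[0, 3] = True
        f = synaptic_features(img, cell, SynapseMask(mask=syn))
        assert f["enrichment (mean)"] == pytest.approx(2.5)
        assert f["enrichment (max)"] == pytest.approx(3.0)

    def test_empty_synapse_is_zero_not_missing(self):
        cell = disk_mask((20, 20), 5)
        f = synaptic_features(np.ones((40, 40)), cell, SynapseMask(np.zeros((40, 40), bool)))
        assert all(v == 0.0 for v in f.values())

    def test_zero_channel_missing(self):
        cell = disk_mask((20, 20), 5)
        syn = SynapseMask(mask=disk_mask((20, 20), 2))
        f = synaptic_features(np.zeros((40, 40)), cell, syn)
        assert np.isnan(f["enrichment (mean)"])


class TestQC:
    def test_constant_channel_zero_gradient(self):
        rec = make_record()
        rec.image[0] = 500
        f = qc_features(rec)
        assert f["gradient RMS of BF"] == pytest.approx(0.0)

    def test_blur_reduces_gradient_rms(self, rng):
        from scipy.ndimage import gaussian_filter

        sharp = np.where(disk_mask((16, 16), 8, size=32), 3000.0, 0.0)
        blurred = gaussian_filter(sharp, 2.5)
        mask = np.ones((1, 32, 32), bool)
        rec_sharp = CellRecord("s", ("BF",), sharp[None], mask)
        rec_blur = CellRecord("b", ("BF",), blurred[None], mask)
        assert (
            qc_features(rec_sharp)["gradient RMS of BF"]
            > qc_features(rec_blur)["gradient RMS of BF"]
        )

    def test_full_frame_mask_background_missing(self):
        rec = make_record()
        rec.masks[:] = True
        f = qc_features(rec)
        assert np.isnan(f["background mean of BF"])


class TestExtraction:
    def test_fluor_inventory_column_counts(self):
        assert len(fluor_relevant_inventory(("F-actin", "MHCII", "CD3", "P-CD3z"))) == 210
        assert len(fluor_relevant_inventory(("F-actin", "MHCII", "P-CD3z"))) == 132

    def test_row_order_follows_input_and_permutation_equivalence(self):
        recs = [make_record(record_id=f"r{i}", seed=i) for i in range(4)]
        inv = fluor_relevant_inventory()
        t1 = extract_features(recs, inv)
        t2 = extract_features(recs[::-1], inv)
        assert list(t1.df.index) == [f"r{i}" for i in range(4)]
        assert t1.df.loc["r2"].equals(t2.df.loc["r2"])

    def test_parallel_equals_serial(self):
        recs = [make_record(record_id=f"r{i}", seed=i) for i in range(6)]
        inv = fluor_relevant_inventory()
        serial = extract_features(recs, inv, n_jobs=1)
        parallel = extract_features(recs, inv, n_jobs=2)
        assert serial.df.equals(parallel.df)

    def test_failing_record_yields_missing_row_not_abort(self):
        good = make_record(record_id="good")
        bad = make_record(record_id="bad", channels=("BF", "F-actin"))  # no CD3
        inv = fluor_relevant_inventory()
        table = extract_features([good, bad], inv)
        assert table.df.loc["bad"].isna().all()
        assert table.df.loc["good"].notna().any()

    def test_full_inventory_includes_morphology_and_qc(self):
        inv = full_inventory(("BF", "F-actin", "MHCII", "CD3", "P-CD3z"))
        names = inv.names
        assert "eccentricity of BF" in names
        assert "gradient RMS of BF" in names
        assert "mean intensity of CD3" in names

    def test_inventory_json_round_trip(self, tmp_path):
        inv = fluor_relevant_inventory()
        path = inv.to_json(tmp_path / "inv.json")
        from ifcprofiler.features import FeatureInventory

        back = FeatureInventory.from_json(path)
        assert back.names == inv.names
        assert back.content_hash == inv.content_hash
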
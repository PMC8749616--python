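"""Texture features vs independent brute-force oracles and hand cases."""

import numpy as np
import pytest

import thermotex as tt
from oracles import naive_cooccurrence, naive_glcm_features, naive_hs
from conftest import random_masked_plane


def full_mask(shape):
    return np.ones(shape, dtype=bool)


class TestHistogram:
    def test_constant_roi(self):
        plane = np.full((10, 10), 100, dtype=np.uint8)
        mask = np.zeros((10, 10), dtype=bool)
        mask[:5, :] = True
        hist = tt.roi_histogram(plane, mask)
        assert hist.n_pixels == 50
        assert hist.probs[100] == 1.0 and hist.probs.sum() == 1.0

    def test_bimodal_roi(self):
        plane = np.zeros((4, 4), dtype=np.uint8)
        plane[:2] = 255
        hist = tt.roi_histogram(plane, full_mask((4, 4)))
        assert hist.probs[0] == 0.5 and hist.probs[255] == 0.5

    def test_matches_brute_force_tally(self, rng):
        plane, mask = random_masked_plane(rng)
        hist = tt.roi_histogram(plane, mask)
        values = plane[mask]
        for k in range(256):
            assert hist.probs[k] == pytest.approx((values == k).sum() / len(values))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tt.roi_histogram(np.zeros((4, 4), dtype=np.uint8), np.zeros((4, 4), dtype=bool))


class TestHSFeatures:
    def test_degenerate_constant(self):
        plane = np.full((5, 5), 100, dtype=np.uint8)
        feats = tt.hs_features(tt.roi_histogram(plane, full_mask((5, 5))))
        assert feats["Mean"] == 100 and feats["Variance"] == 0
        assert feats["Skewness"] == 0 and feats["Kurtosis"] == 0
        for qq in ("01", "10", "50", "90", "99"):
            assert feats[f"Perc{qq}"] == 100
        assert feats["Domn01"] == 100 and feats["Maxm01"] == 1.0

    def test_half_half_hand_case(self):
        plane = np.zeros((2, 2), dtype=np.uint8)
        plane[0] = 255
        feats = tt.hs_features(tt.roi_histogram(plane, full_mask((2, 2))))
        assert feats["Mean"] == 127.5
        assert feats["Variance"] == 16256.25
        assert feats["Skewness"] == 0
        assert feats["Perc50"] == 0  # cumulative reaches 0.50 already at level 0

    @pytest.mark.parametrize("levels", [4, 256])
    def test_matches_naive_loop(self, rng, levels):
        for _ in range(25):
            plane, mask = random_masked_plane(rng, levels=levels)
            feats = tt.hs_features(tt.roi_histogram(plane, mask, levels))
            expected = naive_hs(plane.tolist(), mask.tolist(), levels)
            for name in tt.HS_FEATURES:
                assert feats[name] == pytest.approx(expected[name], abs=1e-9), name


class TestCoOccurrence:
    def test_two_column_asymmetric(self):
        plane = np.array([[0, 1], [0, 1]], dtype=np.uint8)
        com = tt.build_cooccurrence(plane, full_mask((2, 2)), symmetric=False, levels=2)
        assert com.counts[0, 1] == 2 and com.counts.sum() == 2
        assert com.probs[0, 1] == 1.0

    def test_two_column_symmetric(self):
        plane = np.array([[0, 1], [0, 1]], dtype=np.uint8)
        com = tt.build_cooccurrence(plane, full_mask((2, 2)), symmetric=True, levels=2)
        assert com.probs[0, 1] == 0.5 and com.probs[1, 0] == 0.5
        np.testing.assert_allclose(com.probs, com.probs.T)

    def test_constant_plane(self):
        plane = np.full((3, 3), 7, dtype=np.uint8)
        com = tt.build_cooccurrence(plane, full_mask((3, 3)))
        assert com.probs[7, 7] == 1.0

    def test_pairs_require_both_endpoints_in_roi(self, rng):
        plane, mask = random_masked_plane(rng, levels=4)
        for symmetric in (False, True):
            com = tt.build_cooccurrence(plane, mask, symmetric=symmetric, levels=4)
            expected = naive_cooccurrence(plane.tolist(), mask.tolist(), symmetric=symmetric)
            dense = np.zeros((4, 4))
            for (k, l), v in expected.items():
                dense[k, l] = v
            np.testing.assert_allclose(com.probs, dense, atol=1e-12)

    def test_no_valid_pairs_rejected(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[:, 1] = True  # isolated column: no horizontal pairs
        with pytest.raises(ValueError, match="pairs"):
            tt.build_cooccurrence(np.zeros((3, 3), dtype=np.uint8), mask)


class TestHaralickFeatures:
    def test_single_cell_matrix(self):
        plane = np.full((3, 3), 5, dtype=np.uint8)
        feats = tt.glcm_features(tt.build_cooccurrence(plane, full_mask((3, 3))))
        assert feats["AngScMom"] == 1.0 and feats["InvDefMom"] == 1.0
        for name in ("Contrast", "Entropy", "SumEntrp", "DifEntrp", "SumVarnc"):
            assert feats[name] == 0.0

    def test_two_cell_hand_case(self):
        plane = np.array([[0, 1], [0, 1]], dtype=np.uint8)
        com = tt.build_cooccurrence(plane, full_mask((2, 2)), symmetric=True, levels=2)
        feats = tt.glcm_features(com)
        assert feats["AngScMom"] == pytest.approx(0.5)
        assert feats["Contrast"] == pytest.approx(1.0)
        assert feats["InvDefMom"] == pytest.approx(0.5)
        assert feats["Entropy"] == pytest.approx(np.log(2))
        assert feats["SumAverg"] == pytest.approx(1.0)  # all mass at k + l = 1
        assert feats["SumVarnc"] == pytest.approx(0.0)
        assert feats["SumEntrp"] == pytest.approx(0.0)
        assert feats["DifEntrp"] == pytest.approx(0.0)  # all mass at |k − l| = 1
        assert feats["Correlat"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("levels", [4, 256])
    @pytest.mark.parametrize("symmetric", [False, True])
    def test_matches_naive_loop(self, rng, levels, symmetric):
        for _ in range(13):
            plane, mask = random_masked_plane(rng, levels=levels)
            com = tt.build_cooccurrence(plane, mask, symmetric=symmetric, levels=levels)
            feats = tt.glcm_features(com)
            expected = naive_glcm_features(
                naive_cooccurrence(plane.tolist(), mask.tolist(), symmetric=symmetric)
            )
            for name in tt.GLCM_FEATURES:
                assert feats[name] == pytest.approx(expected[name], abs=1e-9), name

    def test_contrast_identity_direct_double_sum(self, rng):
        """Difference-decomposition Contrast equals Σ p(k,l)(k−l)²."""
        for _ in range(10):
            plane, mask = random_masked_plane(rng, levels=8)
            com = tt.build_cooccurrence(plane, mask, levels=8)
            k = np.arange(8)
            direct = float(np.sum(com.probs * (k[:, None] - k[None, :]) ** 2))
            assert tt.glcm_features(com)["Contrast"] == pytest.approx(direct, abs=1e-12)

    def test_gray_shift_invariance(self, rng):
        """Level-shifted planes: spread features fixed, location features shifted."""
        plane, mask = random_masked_plane(rng, levels=100)
        shifted = plane + 50
        hist_a = tt.hs_features(tt.roi_histogram(plane, mask))
        hist_b = tt.hs_features(tt.roi_histogram(shifted, mask))
        assert hist_b["Mean"] == pytest.approx(hist_a["Mean"] + 50)
        assert hist_b["Perc50"] == hist_a["Perc50"] + 50
        assert hist_b["Variance"] == pytest.approx(hist_a["Variance"], abs=1e-9)
        glcm_a = tt.glcm_features(tt.build_cooccurrence(plane, mask))
        glcm_b = tt.glcm_features(tt.build_cooccurrence(shifted, mask))
        for name in ("Contrast", "Entropy", "AngScMom", "InvDefMom", "DifEntrp"):
            assert glcm_b[name] == pytest.approx(glcm_a[name], abs=1e-9)

    def test_symmetric_functionals_agree_between_glcm_and_glch(self, rng):
        """Features symmetric in (k,l) coincide for the two matrix variants."""
        shared = (
            "Contrast", "InvDefMom", "SumAverg", "SumVarnc",
            "SumEntrp", "DifVarnc", "DifEntrp",
        )
        for _ in range(10):
            plane, mask = random_masked_plane(rng, levels=16)
            glcm = tt.glcm_features(tt.build_cooccurrence(plane, mask, symmetric=True, levels=16))
            glch = tt.glcm_features(tt.build_cooccurrence(plane, mask, symmetric=False, levels=16))
            for name in shared:
                assert glcm[name] == pytest.approx(glch[name], abs=1e-9), name


class TestExtractAll:
    def test_350_records_per_frame(self, small_cohort):
        frames, _ = small_cohort
        table = tt.extract_all(frames[0])
        assert len(table) == 350
        assert table.groupby("approach").size().to_dict() == {
            "HS": 130, "GLCM": 110, "GLCH": 110
        }
        # 35 features per component
        assert (table.groupby("component").size() == 35).all()

    def test_constant_frame_glcm_equals_glch(self):
        frame = tt.ThermalFrame(
            image=np.full((64, 64, 3), 90, dtype=np.uint8),
            mask=np.ones((64, 64), dtype=bool),
            mare_id="X", group="NP", subgroup="-", month=None, session=1,
        )
        table = tt.extract_all(frame)
        piv = table[table.approach.isin(["GLCM", "GLCH"])].pivot_table(
            index=["component", "feature"], columns="approach", values="value"
        )
        np.testing.assert_allclose(piv["GLCM"], piv["GLCH"], atol=1e-12)
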
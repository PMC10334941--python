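"""Synthetic generator: determinism, feature detectability, score coupling."""

import numpy as np
import pytest
from scipy.special import expit

from tripoint.synthetic import (
    SyntheticConfig,
    generate_dataset,
    render_lesion,
    sample_disease,
)


def _half_asymmetry_stat(pixels, nbins=16):
    """Max half-vs-half difference of the lesion's radial extent profile.

    Radial distances of dark (lesion) pixels are measured from the render
    center, binned by angle into a boundary profile r(θ); the statistic is
    the largest relative difference between the two halves of the profile
    over all half-plane splits.
    """
    lum = pixels.mean(axis=2)
    dark = lum < lum.mean() - 0.5 * lum.std()
    ys, xs = np.nonzero(dark)
    if xs.size == 0:
        return 0.0
    cy = cx = pixels.shape[0] / 2.0
    ang = np.arctan2(ys - cy, xs - cx)
    r = np.hypot(ys - cy, xs - cx)
    bins = ((ang + np.pi) / (2 * np.pi) * nbins).astype(int) % nbins
    prof = np.array([r[bins == b].max() if (bins == b).any() else 0.0
                     for b in range(nbins)])
    best = 0.0
    for shift in range(nbins):
        rolled = np.roll(prof, shift)
        h1, h2 = rolled[: nbins // 2].mean(), rolled[nbins // 2 :].mean()
        best = max(best, abs(h1 - h2) / (h1 + h2))
    return best


class TestRenderLesion:
    def test_render_is_deterministic_per_rng_state(self):
        a = render_lesion((1, 0, 1), 64, np.random.default_rng(5))
        b = render_lesion((1, 0, 1), 64, np.random.default_rng(5))
        assert np.array_equal(a.pixels, b.pixels)

    def test_all_features_off_yields_near_symmetric_lesion(self):
        rng = np.random.default_rng(0)
        img = render_lesion((0, 0, 0), 64, rng)
        assert img.pixels.shape == (64, 64, 3)
        assert _half_asymmetry_stat(img.pixels) < 0.5

    def test_asymmetric_renders_separate_from_symmetric(self):
        """100 renders per condition: the half-profile statistic splits them."""
        rng = np.random.default_rng(7)
        sym = [_half_asymmetry_stat(render_lesion((0, 0, 0), 64, rng).pixels)
               for _ in range(100)]
        asym = [_half_asymmetry_stat(render_lesion((1, 1, 1), 64, rng).pixels)
                for _ in range(100)]
        assert np.mean(asym) > np.mean(sym) + 2 * np.std(sym)

    def test_too_small_canvas_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            render_lesion((1, 1, 1), 16, np.random.default_rng(0))

    def test_non_binary_feature_rejected(self):
        with pytest.raises(ValueError):
            render_lesion((2, 0, 0), 64, np.random.default_rng(0))

    def test_cast_free_reference_matches_tinted_geometry(self):
        img, clean, cast = render_lesion(
            (0, 1, 0), 48, np.random.default_rng(3), return_clean=True
        )
        assert np.allclose(img.pixels, np.clip(clean * cast, 0, 1))


class TestSampleDisease:
    def test_probability_matches_logistic_closed_form(self):
        # defaults β0=-2.2, β1=1.5 at score 3: P = 1/(1+e^-2.3) ≈ 0.909
        cfg = SyntheticConfig()
        p_expected = expit(-2.2 + 1.5 * 3)
        assert p_expected == pytest.approx(0.9089, abs=5e-4)
        rng = np.random.default_rng(42)
        draws = [sample_disease(3, cfg, rng) for _ in range(20_000)]
        assert np.mean(draws) == pytest.approx(p_expected, abs=0.01)

    def test_melanoma_fraction_monotone_in_score(self):
        cfg = SyntheticConfig()
        rng = np.random.default_rng(9)
        fracs = []
        for s in range(4):
            draws = [sample_disease(s, cfg, rng) for _ in range(10_000)]
            fracs.append(np.mean(draws))
        # binomial SE at n=10k is ~0.005; successive gaps are >= 0.2
        assert all(b > a + 0.03 for a, b in zip(fracs, fracs[1:]))

    def test_zero_slope_removes_score_dependence(self):
        cfg = SyntheticConfig(score_logit_slope=0.0)
        rng = np.random.default_rng(5)
        fracs = [np.mean([sample_disease(s, cfg, rng) for _ in range(8_000)])
                 for s in range(4)]
        assert np.ptp(fracs) < 0.03

    def test_invalid_score_rejected(self):
        with pytest.raises(ValueError):
            sample_disease(4, SyntheticConfig(), np.random.default_rng(0))


class TestGenerateDataset:
    def test_labeled_class_balance_exact(self):
        cfg = SyntheticConfig(n_labeled=120, n_unlabeled=0, holdout_size=0, seed=3)
        data = generate_dataset(cfg)
        labeled = data.subset(labeled=True)
        assert sum(s.disease for s in labeled) == 60

    def test_eighty_twenty_split(self, tiny_synth):
        labeled = tiny_synth.subset(labeled=True)
        in_split = [s for s in labeled if s.split in ("train", "val")]
        train = [s for s in in_split if s.split == "train"]
        val = [s for s in in_split if s.split == "val"]
        assert len(train) == 48 and len(val) == 12

    def test_holdout_disjoint_and_full_partition(self, tiny_synth):
        ids = [s.image.image_id for s in tiny_synth.samples]
        assert len(set(ids)) == len(ids)
        splits = {s.split for s in tiny_synth.samples}
        assert splits == {"train", "val", "holdout"}
        assert len(tiny_synth.subset("holdout")) == 20

    def test_unlabeled_rows_have_empty_feature_cells(self, tiny_synth):
        m = tiny_synth.manifest()
        unl = m[~m["labeled"]]
        assert len(unl) == 20
        assert unl[["asymmetry", "network", "bluewhite"]].isna().all().all()
        lab = m[m["labeled"]]
        assert lab[["asymmetry", "network", "bluewhite"]].notna().all().all()
        assert m["disease"].notna().all()

    def test_dataset_is_pure_function_of_config(self):
        cfg = SyntheticConfig(n_labeled=30, n_unlabeled=10, holdout_size=10, seed=21)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        for sa, sb in zip(a.samples, b.samples):
            assert np.array_equal(sa.image.pixels, sb.image.pixels)
            assert sa.disease == sb.disease and sa.split == sb.split

    def test_unreachable_balance_warns_and_fills(self):
        cfg = SyntheticConfig(n_labeled=20, n_unlabeled=0, holdout_size=0,
                              class_balance=1.0, score_logit_intercept=-30.0,
                              score_logit_slope=0.0, seed=1)
        with pytest.warns(UserWarning, match="unreachable"):
            data = generate_dataset(cfg)
        assert len(data.subset(labeled=True)) == 20
        assert data.warnings


class TestLearnabilityFloor:
    def test_knn_separates_each_feature(self):
        """10-NN on downsampled pixels detects every checklist feature.

        Guarantees the rendered cues are machine-detectable before any
        network training is blamed for missing them.
        """
        from sklearn.metrics import roc_auc_score
        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(17)
        n = 500
        flags = rng.integers(0, 2, size=(n, 3))
        X = np.empty((n, 8 * 8 * 3))
        for i in range(n):
            img = render_lesion(tuple(flags[i]), 64, rng)
            X[i] = img.pixels[::8, ::8, :].ravel()
        half = n // 2
        for k in range(3):
            knn = KNeighborsClassifier(n_neighbors=10)
            knn.fit(X[:half], flags[:half, k])
            prob = knn.predict_proba(X[half:])[:, 1]
            auc = roc_auc_score(flags[half:, k], prob)
            assert auc > 0.7, f"feature {k} not detectable: AUC={auc:.3f}"
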
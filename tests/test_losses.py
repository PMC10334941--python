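"""Loss-term correctness against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tripoint.losses import (
    ChecklistAnnotation,
    LossWeights,
    checklist_score,
    combined_loss,
    consistency_loss,
    disease_supervised_loss,
    feature_supervised_loss,
    ranking_loss,
    ranking_target,
)

from _oracles import (
    bce_bruteforce,
    consistency_mse_bruteforce,
    ranking_loss_bruteforce,
    softmax_ce_bruteforce,
)


class TestChecklist:
    @pytest.mark.parametrize(
        "flags,score", [((0, 0, 0), 0), ((1, 1, 1), 3), ((1, 0, 1), 2), ((0, 1, 0), 1)]
    )
    def test_score_is_sum_of_flags(self, flags, score):
        assert checklist_score(ChecklistAnnotation(*flags)) == score

    def test_non_binary_flag_rejected(self):
        with pytest.raises(ValueError):
            ChecklistAnnotation(2, 0, 0)

    @pytest.mark.parametrize(
        "si,sj,target", [(3, 1, 1.0), (2, 2, 0.5), (0, 3, 0.0), (1, 0, 1.0)]
    )
    def test_ranking_target(self, si, sj, target):
        assert ranking_target(si, sj) == target

    def test_ranking_target_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ranking_target(4, 1)


class TestRankingLoss:
    def test_equal_scores_equal_logits_give_log2(self):
        # P̄ = 0.5 and o = 0 force the entropy of a fair coin
        assert ranking_loss([1.0, 1.0], [2, 2]) == pytest.approx(math.log(2), abs=1e-12)

    def test_large_correct_margin_vanishes(self):
        # s=(3,0), o=+20: cost is log(1 + e^-20)
        expected = math.log1p(math.exp(-20.0))
        assert ranking_loss([20.0, 0.0], [3, 0]) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(2.06e-9, rel=0.01)

    def test_matches_bruteforce_on_random_batches(self, rng):
        for _ in range(20):
            f = rng.normal(0, 3, size=16)
            s = rng.integers(0, 4, size=16)
            assert ranking_loss(f, s) == pytest.approx(
                ranking_loss_bruteforce(f, s), abs=1e-8
            )

    def test_translation_invariance(self, rng):
        f = rng.normal(0, 2, size=12)
        s = rng.integers(0, 4, size=12)
        assert ranking_loss(f, s) == pytest.approx(ranking_loss(f + 57.3, s), abs=1e-9)

    def test_loss_decreases_with_correct_margin(self):
        losses = [ranking_loss([m, 0.0], [3, 1]) for m in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_pair_order_swap_leaves_loss_unchanged(self, rng):
        f = rng.normal(size=8)
        s = rng.integers(0, 4, size=8)
        perm = rng.permutation(8)
        assert ranking_loss(f, s) == pytest.approx(ranking_loss(f[perm], s[perm]), abs=1e-10)

    def test_singleton_batch_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert ranking_loss([1.0], [2]) == 0.0

    def test_gradient_matches_finite_differences(self, rng):
        f = rng.normal(size=6)
        s = rng.integers(0, 4, size=6)
        _, g = ranking_loss(f, s, return_grad=True)
        eps = 1e-6
        for k in range(6):
            fp, fm = f.copy(), f.copy()
            fp[k] += eps
            fm[k] -= eps
            num = (ranking_loss(fp, s) - ranking_loss(fm, s)) / (2 * eps)
            assert g[k] == pytest.approx(num, abs=1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        shift=st.floats(-50, 50),
        seed=st.integers(0, 10_000),
    )
    def test_depends_only_on_logit_differences(self, shift, seed):
        r = np.random.default_rng(seed)
        f = r.normal(size=5)
        s = r.integers(0, 4, size=5)
        assert ranking_loss(f, s) == pytest.approx(ranking_loss(f + shift, s), abs=1e-8)


class TestSupervisedLosses:
    def test_uniform_logits_give_ln2(self):
        z = np.zeros((5, 2))
        assert disease_supervised_loss(z, np.array([0, 1, 0, 1, 1])) == pytest.approx(
            math.log(2)
        )

    def test_confident_correct_vanishes(self):
        z = np.array([[-30.0, 30.0], [30.0, -30.0]])
        assert disease_supervised_loss(z, np.array([1, 0])) < 1e-12

    def test_ce_matches_per_sample_oracle(self, rng):
        z = rng.normal(0, 2, size=(16, 2))
        y = rng.integers(0, 2, size=16)
        assert disease_supervised_loss(z, y) == pytest.approx(
            softmax_ce_bruteforce(z, y), abs=1e-10
        )

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            disease_supervised_loss(np.zeros((2, 2)), np.array([0, 2]))

    def test_zero_feature_logits_give_ln2(self, rng):
        y = rng.integers(0, 2, size=(7, 3)).astype(float)
        assert feature_supervised_loss(np.zeros((7, 3)), y) == pytest.approx(math.log(2))

    def test_bce_matches_elementwise_oracle(self, rng):
        z = rng.normal(0, 2, size=(16, 3))
        y = rng.integers(0, 2, size=(16, 3)).astype(float)
        assert feature_supervised_loss(z, y) == pytest.approx(
            bce_bruteforce(z, y), abs=1e-8
        )

    def test_asymmetry_emphasis_raises_loss_when_wrong_on_asymmetry(self):
        # confidently wrong on feature 0 only, right on the others
        z = np.array([[4.0, 4.0, -4.0]] * 6)
        y = np.array([[0.0, 1.0, 0.0]] * 6)
        plain = feature_supervised_loss(z, y, (1, 1, 1))
        emph = feature_supervised_loss(z, y, (2, 1, 1))
        assert emph > plain

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            feature_supervised_loss(np.zeros((2, 3)), np.zeros((2, 3)), (-1, 1, 1))


class TestConsistencyLoss:
    def test_identical_outputs_vanish(self, rng):
        zd = rng.normal(size=(6, 2))
        zf = rng.normal(size=(6, 3))
        assert consistency_loss(zd, zf, zd, zf) == 0.0

    def test_disease_term_arithmetic(self):
        # softmaxes (1,0) vs (0.5,0.5): mean over the two disease dims is 0.25
        zd_s = np.array([[50.0, -50.0]])
        zd_t = np.array([[0.0, 0.0]])
        zf = np.zeros((1, 3))
        value = consistency_loss(zd_s, zf, zd_t, zf, heads="disease")
        assert value == pytest.approx(0.25, abs=1e-12)

    def test_matches_elementwise_oracle(self, rng):
        zd_s, zd_t = rng.normal(size=(2, 16, 2))
        zf_s, zf_t = rng.normal(size=(2, 16, 3))
        assert consistency_loss(zd_s, zf_s, zd_t, zf_t) == pytest.approx(
            consistency_mse_bruteforce(zd_s, zf_s, zd_t, zf_t), abs=1e-8
        )

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            consistency_loss(np.zeros((3, 2)), np.zeros((3, 3)),
                             np.zeros((2, 2)), np.zeros((3, 3)))


class TestCombinedLoss:
    def test_single_term_selection(self):
        w = LossWeights(1, 0, 0, 0)
        assert combined_loss(0.42, None, None, None, w) == 0.42

    def test_plain_sum(self):
        w = LossWeights(1, 1, 1, 1)
        assert combined_loss(0.2, 0.3, 0.1, 0.05, w) == pytest.approx(0.65)

    def test_enabled_term_requires_value(self):
        with pytest.raises(ValueError):
            combined_loss(0.2, None, None, None, LossWeights(1, 1, 0, 0))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(0, 0, 0, 0)
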
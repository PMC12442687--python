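"""Prompted readout, virtual task bridges, tuning and classification."""

import numpy as np
import pytest

from pairprompt.encoder import Subgraph, readout
from pairprompt.prompt import (
    PromptState,
    classify,
    compute_bridges,
    prompt_loss,
    prompt_readout,
    prompt_similarity,
    transfer_prompt,
    tune_prompt,
)
from tests.conftest import make_base


def simple_sub_and_reps():
    sub = Subgraph(0, 1, frozenset({0, 1, 2}), frozenset({(0, 1), (0, 2)}))
    reps = np.array([[1.0, 2.0], [3.0, -1.0], [0.5, 0.5]])
    return sub, reps


class TestPromptReadout:
    def test_identity_prompt_equals_plain_sum(self):
        sub, reps = simple_sub_and_reps()
        prompt = PromptState("t", np.ones(2), "sum")
        np.testing.assert_allclose(
            prompt_readout(sub, reps, prompt), readout(sub, reps, "sum")
        )

    def test_zero_prompt_gives_zero(self):
        sub, reps = simple_sub_and_reps()
        prompt = PromptState("t", np.zeros(2), "sum")
        np.testing.assert_allclose(prompt_readout(sub, reps, prompt), 0.0)

    def test_prompt_homogeneity(self):
        sub, reps = simple_sub_and_reps()
        doubled = PromptState("t", 2 * np.ones(2), "sum")
        np.testing.assert_allclose(
            prompt_readout(sub, reps, doubled), 2 * readout(sub, reps, "sum")
        )

    def test_weighted_identity_matches_sum(self):
        sub, reps = simple_sub_and_reps()
        prompt = PromptState("t", np.ones(2), "feature_weighted_sum", np.eye(2))
        np.testing.assert_allclose(
            prompt_readout(sub, reps, prompt), readout(sub, reps, "sum")
        )

    def test_width_mismatch_rejected(self):
        sub, reps = simple_sub_and_reps()
        with pytest.raises(ValueError, match="width"):
            prompt_readout(sub, reps, PromptState("t", np.ones(3), "sum"))


class TestBridges:
    def test_single_positive_equals_its_rep(self):
        base = make_base(np.array([[1.0, 2.0], [0.0, -1.0]]))
        bridges = compute_bridges(
            [(0, 1), (1, 0)], base, PromptState("t", np.ones(2), "sum")
        )
        np.testing.assert_allclose(bridges.b_true, [1.0, 2.0])

    def test_mean_of_two_positives(self):
        base = make_base(np.array([[1.0, 0.0], [0.0, 1.0], [5.0, 5.0]]))
        bridges = compute_bridges(
            [(0, 1), (1, 1), (2, 0)], base, PromptState("t", np.ones(2), "sum")
        )
        np.testing.assert_allclose(bridges.b_true, [0.5, 0.5])

    def test_duplicates_leave_mean_unchanged(self):
        base = make_base(np.array([[1.0, 0.0], [0.0, 1.0], [5.0, 5.0]]))
        prompt = PromptState("t", np.ones(2), "sum")
        once = compute_bridges([(0, 1), (1, 1), (2, 0)], base, prompt)
        twice = compute_bridges(
            [(0, 1), (1, 1), (0, 1), (1, 1), (2, 0)], base, prompt
        )
        np.testing.assert_allclose(once.b_true, twice.b_true)

    def test_empty_class_rejected(self):
        base = make_base(np.eye(2))
        with pytest.raises(ValueError, match="each class"):
            compute_bridges([(0, 1), (1, 1)], base, PromptState("t", np.ones(2), "sum"))


class TestPromptLoss:
    def test_full_ambiguity_gives_n_ln2(self):
        # all examples equidistant from both bridges
        base = make_base(np.array([[1.0, 1.0]] * 6 + [[1.0, 0.0], [0.0, 1.0]]))
        prompt = PromptState("t", np.ones(2), "sum")
        train = [(i, i % 2) for i in range(6)]
        bridges = compute_bridges([(6, 1), (7, 0)], base, prompt)
        loss = prompt_loss(train, bridges, base, prompt, tau=1.0)
        assert loss == pytest.approx(6 * np.log(2), abs=1e-12)

    def test_unit_margin_closed_form(self):
        base = make_base(np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 0.0], [0.0, 2.0]]))
        prompt = PromptState("t", np.ones(2), "sum")
        train = [(0, 1), (1, 0)]
        bridges = compute_bridges(train, base, prompt)
        loss = prompt_loss(train, bridges, base, prompt, tau=1.0)
        assert loss == pytest.approx(2 * np.log(1 + np.exp(-1)), abs=1e-12)

    def test_loss_drops_when_own_similarity_rises(self):
        prompt = PromptState("t", np.ones(2), "sum")
        losses = []
        for a in (0.9, 0.5, 0.2):
            base = make_base(
                np.array([[np.cos(a), np.sin(a)], [1.0, 0.0], [0.0, 1.0]])
            )
            bridges = compute_bridges([(1, 1), (2, 0)], base, prompt)
            losses.append(prompt_loss([(0, 1)], bridges, base, prompt, 1.0))
        assert losses[0] > losses[1] > losses[2]


class TestTunePrompt:
    def test_zero_steps_returns_initial_prompt(self):
        base = make_base(np.array([[1.0, 0.0], [0.0, 1.0]]))
        prompt = tune_prompt([(0, 1), (1, 0)], base, steps=0)
        np.testing.assert_array_equal(prompt.p, np.ones(2))

    def test_separable_reps_reach_full_training_accuracy(self):
        rng = np.random.default_rng(0)
        n = 40
        reps = np.zeros((n, 6))
        labels = np.arange(n) % 2
        # class signal on axis 0, distractor noise on remaining axes
        reps[:, 0] = np.where(labels == 1, 1.0, -1.0)
        reps[:, 1:] = rng.standard_normal((n, 5)) * 2.0
        base = make_base(reps)
        train = list(zip(range(n), labels))
        prompt = tune_prompt(train, base, strategy="sum", steps=200, learning_rate=5e-2)
        bridges = compute_bridges(train, base, prompt)
        pred, _ = classify(list(range(n)), prompt, bridges, base)
        assert (pred == labels).mean() == 1.0

    def test_encoder_untouched_by_tuning(self, small_results):
        digest_before = small_results.params.digest()
        graph = small_results.model.graph
        task = graph.pair_types()[0]
        labeled = graph.labeled_nodes(task)[:20]
        small_results.tune(labeled, steps=30)
        assert small_results.params.digest() == digest_before

    def test_both_classes_required(self):
        base = make_base(np.eye(2))
        with pytest.raises(ValueError):
            tune_prompt([(0, 1), (1, 1)], base)
        with pytest.raises(ValueError):
            tune_prompt([], base)


class TestClassify:
    def test_higher_similarity_wins(self):
        base = make_base(np.array([[1.0, 0.1], [1.0, 0.0], [0.0, 1.0]]))
        prompt = PromptState("t", np.ones(2), "sum")
        bridges = compute_bridges([(1, 1), (2, 0)], base, prompt)
        label, score = classify(0, prompt, bridges, base)
        assert label == 1 and score > 0.5

    def test_exact_tie_is_negative(self):
        base = make_base(np.array([[1.0, 1.0], [1.0, 0.0], [0.0, 1.0]]))
        prompt = PromptState("t", np.ones(2), "sum")
        bridges = compute_bridges([(1, 1), (2, 0)], base, prompt)
        label, score = classify(0, prompt, bridges, base)
        assert label == 0 and score == pytest.approx(0.5)

    def test_scale_invariance_of_labels(self):
        rng = np.random.default_rng(1)
        reps = rng.standard_normal((10, 4))
        scaled = reps.copy()
        scaled[0] *= 37.0
        prompt = PromptState("t", np.ones(4), "sum")
        train = [(1, 1), (2, 1), (3, 0), (4, 0)]
        l1, _ = classify(0, prompt, compute_bridges(train, make_base(reps), prompt),
                         make_base(reps))
        l2, _ = classify(0, prompt, compute_bridges(train, make_base(scaled), prompt),
                         make_base(scaled))
        assert l1 == l2

    def test_agreement_with_softmax_oracle(self):
        rng = np.random.default_rng(7)
        reps = rng.standard_normal((104, 8))
        base = make_base(reps)
        prompt = PromptState("t", rng.standard_normal(8), "sum", tau=0.7)
        train = [(100, 1), (101, 1), (102, 0), (103, 0)]
        bridges = compute_bridges(train, base, prompt)
        labels, scores = classify(list(range(100)), prompt, bridges, base)

        def cos(a, b):
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

        for i in range(100):
            s = reps[i] * prompt.p
            zt = cos(s, bridges.b_true) / 0.7
            zf = cos(s, bridges.b_false) / 0.7
            post = np.exp(zt) / (np.exp(zt) + np.exp(zf))
            expected = int(zt > zf)  # tie -> negative
            assert labels[i] == expected
            assert scores[i] == pytest.approx(post, rel=1e-9)


class TestPromptSimilarity:
    def test_identical_prompts(self):
        p = PromptState("a", np.array([1.0, 2.0]), "sum")
        q = PromptState("b", np.array([1.0, 2.0]), "sum")
        assert prompt_similarity([p, q])[0, 1] == pytest.approx(1.0)

    def test_orthogonal_prompts(self):
        p = PromptState("a", np.array([1.0, 0.0]), "sum")
        q = PromptState("b", np.array([0.0, 1.0]), "sum")
        assert prompt_similarity([p, q])[0, 1] == pytest.approx(0.0)

    def test_valid_similarity_matrix(self):
        rng = np.random.default_rng(0)
        prompts = [PromptState(str(i), rng.standard_normal(5), "sum") for i in range(4)]
        mat = prompt_similarity(prompts)
        np.testing.assert_allclose(mat, mat.T)
        np.testing.assert_allclose(np.diag(mat), 1.0)
        assert np.all(mat >= -1 - 1e-12) and np.all(mat <= 1 + 1e-12)

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            prompt_similarity(
                [PromptState("a", np.ones(2), "sum"), PromptState("b", np.ones(3), "sum")]
            )


class TestTransfer:
    def test_self_transfer_reproduces_own_accuracy(self):
        rng = np.random.default_rng(3)
        reps = rng.standard_normal((50, 4))
        base = make_base(reps)
        train = [(i, i % 2) for i in range(10)]
        eval_set = [(i, i % 2) for i in range(10, 50)]
        prompt = tune_prompt(train, base, steps=50)
        bridges = compute_bridges(train, base, prompt)
        pred, _ = classify([n for n, _ in eval_set], prompt, bridges, base)
        own = float((pred == np.array([y for _, y in eval_set])).mean())
        assert transfer_prompt(prompt, train, eval_set, base) == pytest.approx(own)

    def test_identity_prompt_transfer_is_plain_sum_baseline(self):
        rng = np.random.default_rng(4)
        reps = rng.standard_normal((30, 4))
        base = make_base(reps)
        train = [(i, i % 2) for i in range(8)]
        eval_set = [(i, i % 2) for i in range(8, 30)]
        ones = PromptState("src", np.ones(4), "sum")
        bridges = compute_bridges(train, base, ones)
        pred, _ = classify([n for n, _ in eval_set], ones, bridges, base)
        baseline = float((pred == np.array([y for _, y in eval_set])).mean())
        assert transfer_prompt(ones, train, eval_set, base) == pytest.approx(baseline)
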
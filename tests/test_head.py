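import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazelink.embedding import LookupBackend, l2_normalize
from gazelink.errors import InitializationError, ValidationError
from gazelink.head import (
    CosineSoftmaxHead,
    HeadTrainConfig,
    finetune,
    init_head,
    load_head,
    logits,
    posterior,
    predict_topk,
    save_head,
    softmax_with_temperature,
)
from gazelink.kb_io import TrainingEntry


def make_head(weights, temperature=1.0):
    weights = np.asarray(weights, dtype=float)
    return CosineSoftmaxHead(
        weights=weights,
        concept_order=tuple(f"c{i}" for i in range(weights.shape[0])),
        temperature=temperature,
    )


def nearest_centroid_oracle(weights, codes, query):
    """Independent scan: argmax of direct cosine against every raw row."""
    best, best_code = -2.0, None
    for row, code in zip(weights, codes):
        c = float(np.dot(row, query) / (np.linalg.norm(row) * np.linalg.norm(query)))
        if c > best or (c == best and code < best_code):
            best, best_code = c, code
    return best_code


class TestInitHead:
    def test_mean_of_two(self):
        backend = LookupBackend(["a", "b"], np.array([[1.0, 0.0], [0.0, 1.0]]))
        entries = [TrainingEntry("a", "c"), TrainingEntry("b", "c")]
        head = init_head(entries, backend)
        np.testing.assert_allclose(head.weights, [[0.5, 0.5]])

    def test_single_term_identity(self, rng):
        v = rng.standard_normal((1, 8))
        head = init_head([TrainingEntry("x", "c")], LookupBackend(["x"], v))
        np.testing.assert_array_equal(head.weights, v)

    def test_column_mean_oracle(self, rng):
        # 5 concepts x 3 terms; every row must equal an independently computed
        # column-mean of that concept's block
        surfaces, vectors, entries = [], [], []
        blocks = {}
        for c in range(5):
            block = rng.standard_normal((3, 8))
            blocks[f"c{c}"] = block
            for t in range(3):
                name = f"s{c}_{t}"
                surfaces.append(name)
                vectors.append(block[t])
                entries.append(TrainingEntry(name, f"c{c}"))
        head = init_head(entries, LookupBackend(surfaces, np.vstack(vectors)))
        for i, code in enumerate(head.concept_order):
            np.testing.assert_allclose(head.weights[i], blocks[code].mean(axis=0), atol=1e-12)

    def test_sorted_inventory(self, rng):
        backend = LookupBackend(["a", "b"], rng.standard_normal((2, 8)))
        head = init_head([TrainingEntry("b", "z"), TrainingEntry("a", "a")], backend)
        assert head.concept_order == ("a", "z")

    def test_zero_mean_names_code(self):
        backend = LookupBackend(["a", "b"], np.array([[1.0, 0.0], [-1.0, 0.0]]))
        entries = [TrainingEntry("a", "bad"), TrainingEntry("b", "bad")]
        with pytest.raises(InitializationError, match="bad"):
            init_head(entries, backend)


class TestLogits:
    def test_orthonormal(self):
        head = make_head([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(logits(head, np.array([1.0, 0.0])), [1.0, 0.0], atol=1e-12)

    def test_scale_invariance(self):
        head = make_head([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(logits(head, np.array([2.0, 0.0])), [1.0, 0.0], atol=1e-12)

    def test_hand_computed_cosine(self):
        head = make_head([[1.0, 1.0]])
        assert logits(head, np.array([1.0, 0.0]))[0] == pytest.approx(1 / np.sqrt(2), abs=1e-9)

    def test_zero_mention_rejected(self):
        with pytest.raises(ValidationError):
            logits(make_head([[1.0, 0.0]]), np.zeros(2))

    def test_range(self, rng):
        head = make_head(rng.standard_normal((30, 8)))
        s = logits(head, rng.standard_normal(8))
        assert np.all(s >= -1 - 1e-12) and np.all(s <= 1 + 1e-12)


class TestPosterior:
    def test_worked_softmax_value(self):
        # independent evaluation: p = (e/(e+1), 1/(e+1)) = (0.73106, 0.26894)
        p = softmax_with_temperature(np.array([1.0, 0.0]), 1.0)
        np.testing.assert_allclose(p, [0.7310585786300049, 0.2689414213699951], atol=1e-9)

    def test_temperature_sharpening(self):
        # p2 = 1/(1 + e^20) ~ 2.06e-9
        p = softmax_with_temperature(np.array([1.0, 0.0]), 0.05)
        assert p[0] >= 1 - 1e-8

    def test_single_concept(self):
        head = make_head([[1.0, 1.0]], temperature=7.3)
        np.testing.assert_allclose(posterior(head, np.array([0.2, 0.9])), [1.0])

    def test_non_positive_temperature(self):
        with pytest.raises(ValidationError):
            softmax_with_temperature(np.array([1.0, 0.0]), 0.0)

    @given(seed=st.integers(0, 10_000), n=st.integers(1, 40), tau=st.floats(0.01, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_normalization_and_positivity(self, seed, n, tau):
        rng = np.random.default_rng(seed)
        head = make_head(rng.standard_normal((n, 6)), temperature=tau)
        p = posterior(head, rng.standard_normal(6))
        assert abs(p.sum() - 1.0) < 1e-9
        assert np.all(p > 0) and np.all(p < 1 + 1e-12)

    def test_scale_invariance_of_posterior(self, rng):
        head = make_head(rng.standard_normal((10, 6)), temperature=0.3)
        m = rng.standard_normal(6)
        np.testing.assert_allclose(posterior(head, m), posterior(head, 17.3 * m), atol=1e-12)

    def test_temperature_limit_concentrates(self, rng):
        head_warm = make_head(rng.standard_normal((15, 6)), temperature=1.0)
        head_cold = make_head(head_warm.weights, temperature=1e-3)
        m = rng.standard_normal(6)
        assert posterior(head_cold, m).max() > posterior(head_warm, m).max()
        assert posterior(head_cold, m).max() > 1 - 1e-6


class TestPredictTopk:
    def test_top1_is_argmax_logit(self, rng):
        head = make_head(rng.standard_normal((25, 8)), temperature=0.05)
        m = rng.standard_normal(8)
        top = predict_topk(head, m, 1)
        assert top.items[0][0] == head.concept_order[int(np.argmax(logits(head, m)))]

    def test_full_k_is_permutation(self, rng):
        head = make_head(rng.standard_normal((12, 8)))
        out = predict_topk(head, rng.standard_normal(8), 12)
        assert sorted(out.codes) == sorted(head.concept_order)

    def test_init_time_nearest_centroid_equivalence(self, rng):
        surfaces, vectors, entries = [], [], []
        for c in range(40):
            for t in range(2):
                name = f"s{c}_{t}"
                surfaces.append(name)
                vectors.append(rng.standard_normal(16))
                entries.append(TrainingEntry(name, f"k{c:02d}"))
        head = init_head(entries, LookupBackend(surfaces, np.vstack(vectors)), temperature=0.7)
        for _ in range(50):
            q = rng.standard_normal(16)
            assert predict_topk(head, q, 1).items[0][0] == nearest_centroid_oracle(
                head.weights, head.concept_order, q
            )


class TestFinetune:
    def _clusters(self, rng, n_concepts=3, dim=8, per=30, sd=0.05):
        centers = l2_normalize(rng.standard_normal((n_concepts, dim)), axis=1)
        X, y = [], []
        for i in range(n_concepts):
            X.append(centers[i] + sd * rng.standard_normal((per, dim)))
            y += [f"c{i}"] * per
        head = make_head(centers + 0.3 * rng.standard_normal(centers.shape), temperature=0.05)
        return head, np.vstack(X), y

    def test_zero_learning_rate_is_identity(self, rng):
        head, X, y = self._clusters(rng)
        config = HeadTrainConfig(learning_rate=0.0, epochs=3, batch_size=16, seed=0, patience=0)
        tuned, trace = finetune(head, X, y, config)
        np.testing.assert_array_equal(tuned.weights, head.weights)
        assert max(trace) - min(trace) < 1e-9

    def test_loss_decreases_on_separated_clusters(self, rng):
        head, X, y = self._clusters(rng)
        config = HeadTrainConfig(learning_rate=1e-2, epochs=50, batch_size=16, seed=1, patience=0)
        tuned, trace = finetune(head, X, y, config)
        assert trace[-1] < trace[0]

    def test_bit_identical_under_same_seed(self, rng):
        head, X, y = self._clusters(rng)
        config = HeadTrainConfig(learning_rate=1e-3, epochs=5, batch_size=8, seed=99)
        a, _ = finetune(head, X, y, config)
        b, _ = finetune(head, X, y, config)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_unknown_label_named(self, rng):
        head, X, y = self._clusters(rng)
        y[3] = "mystery"
        with pytest.raises(ValidationError, match="mystery"):
            finetune(head, X, y, HeadTrainConfig())

    def test_input_head_unchanged(self, rng):
        head, X, y = self._clusters(rng)
        before = head.weights.copy()
        finetune(head, X, y, HeadTrainConfig(learning_rate=1e-2, epochs=2))
        np.testing.assert_array_equal(head.weights, before)

    def test_learning_rate_bounds(self):
        with pytest.raises(ValidationError):
            HeadTrainConfig(learning_rate=0.5)


class TestSerialization:
    def test_exact_round_trip(self, tmp_path, rng):
        head = CosineSoftmaxHead(
            weights=rng.standard_normal((6, 9)) * np.e,
            concept_order=tuple(f"code {i}" for i in range(6)),
            temperature=0.0731,
        )
        p = tmp_path / "head.txt"
        save_head(head, p)
        loaded = load_head(p)
        np.testing.assert_array_equal(loaded.weights, head.weights)
        assert loaded.concept_order == head.concept_order
        assert loaded.temperature == head.temperature
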
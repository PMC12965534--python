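"""Transformer classifier: learning sanity, determinism, reports, embeddings."""

import numpy as np
import pytest
from sklearn.exceptions import NotFittedError

from rankshift import StateTransformerClassifier
from rankshift.encoding import RankEncoding
from rankshift.model import ClassificationReport
from rankshift.simulate import CONTROL, DISEASE


def _encodings(token_lists, L=16):
    return [
        RankEncoding(cell_id=f"c{i}", tokens=tuple(t), context_length=L)
        for i, t in enumerate(token_lists)
    ]


def _tiny_model(**kw):
    defaults = dict(vocab_size=14, n_layers=1, n_heads=2, hidden_dim=16,
                    context_length=16, batch_size=32, seed=0)
    defaults.update(kw)
    return StateTransformerClassifier(**defaults)


class TestPretraining:
    def test_loss_decreases_on_learnable_corpus(self, small_setup):
        model = StateTransformerClassifier(
            vocab_size=small_setup.vocabulary.size, context_length=48,
            pretrain_epochs=3, batch_size=32, seed=2,
        )
        model.pretrain(small_setup.enc_train[:300])
        assert model.phase_ == "pretrained"
        assert model.pretrain_loss_history_[-1] < model.pretrain_loss_history_[0]

    def test_identical_encoding_corpus_beats_chance(self):
        """Masked prediction on a corpus of one repeated encoding must beat
        1/vocab_size once converged."""
        tokens = tuple(range(2, 14))
        encs = _encodings([tokens] * 120)
        model = _tiny_model(pretrain_epochs=20, learning_rate=3e-3, dropout=0.0)
        model.pretrain(encs)
        acc = model.masked_prediction_accuracy(encs[:20], seed=1)
        assert acc > 1.0 / 14

    def test_same_seed_same_loss_trajectory(self, small_setup):
        runs = []
        for _ in range(2):
            m = StateTransformerClassifier(
                vocab_size=small_setup.vocabulary.size, context_length=48,
                pretrain_epochs=2, batch_size=32, seed=11,
            )
            m.pretrain(small_setup.enc_train[:150])
            runs.append(m.pretrain_loss_history_)
        assert runs[0] == runs[1]

    def test_needs_at_least_100_encodings(self):
        with pytest.raises(ValueError, match="100"):
            _tiny_model().pretrain(_encodings([(2, 3)] * 99))


class TestFinetuning:
    def test_separable_corpus_reaches_high_heldout_accuracy(self, small_setup):
        acc = small_setup.model.score(small_setup.enc_test,
                                      small_setup.test.condition)
        assert acc >= 0.9

    def test_shuffled_labels_stay_at_chance(self, small_setup):
        rng = np.random.default_rng(5)
        y_shuffled = rng.permutation(small_setup.train.condition)
        model = StateTransformerClassifier(
            vocab_size=small_setup.vocabulary.size, context_length=48,
            epochs=6, batch_size=32, seed=1,
        )
        model.fit(small_setup.enc_train, y_shuffled)
        acc = model.score(small_setup.enc_test, small_setup.test.condition)
        assert 0.4 <= acc <= 0.6

    def test_single_class_training_set_rejected(self):
        encs = _encodings([(2, 3), (4, 5)])
        with pytest.raises(ValueError, match="single class"):
            _tiny_model().fit(encs, [CONTROL, CONTROL])

    def test_finetune_from_random_phase_is_recorded(self, small_setup):
        assert small_setup.model.phase_ == "finetuned"
        assert small_setup.model.started_from_phase_ == "random"

    def test_pretrain_then_finetune_phase_chain(self, small_setup):
        model = StateTransformerClassifier(
            vocab_size=small_setup.vocabulary.size, context_length=48,
            pretrain_epochs=1, epochs=1, batch_size=32, seed=3,
        )
        model.pretrain(small_setup.enc_train[:150])
        model.fit(small_setup.enc_train, small_setup.train.condition)
        assert model.phase_ == "finetuned"
        assert model.started_from_phase_ == "pretrained"
        with pytest.raises(ValueError, match="phase"):
            model.pretrain(small_setup.enc_train[:150])


class TestClassificationReport:
    def test_perfect_predictions(self):
        y = np.array([CONTROL, DISEASE, CONTROL, DISEASE], dtype=object)
        r = ClassificationReport.from_predictions(y, y)
        assert r.accuracy == 1.0 and r.macro_f1 == 1.0
        assert (r.tp, r.fp, r.fn, r.tn) == (2, 0, 0, 2)

    def test_hand_computed_confusion_example(self):
        """TP=2 FP=1 FN=1 TN=2 -> accuracy 4/6, macro-F1 2/3."""
        y_true = [DISEASE, DISEASE, DISEASE, CONTROL, CONTROL, CONTROL]
        y_pred = [DISEASE, DISEASE, CONTROL, DISEASE, CONTROL, CONTROL]
        r = ClassificationReport.from_predictions(
            np.array(y_true, dtype=object), np.array(y_pred, dtype=object)
        )
        assert (r.tp, r.fp, r.fn, r.tn) == (2, 1, 1, 2)
        assert r.accuracy == pytest.approx(4 / 6)
        assert r.macro_f1 == pytest.approx(2 / 3)
        assert r.n_cells == 6

    def test_constant_prediction_on_balanced_set(self):
        y_true = np.array([CONTROL, CONTROL, DISEASE, DISEASE], dtype=object)
        y_pred = np.array([DISEASE] * 4, dtype=object)
        r = ClassificationReport.from_predictions(y_true, y_pred)
        assert r.accuracy == 0.5

    def test_probabilities_sum_to_one(self, small_setup):
        report = small_setup.model.evaluate(
            small_setup.enc_test[:20], small_setup.test.condition[:20]
        )
        total = report.probabilities.p_control + report.probabilities.p_disease
        np.testing.assert_allclose(total, 1.0, atol=1e-6)


class TestEmbeddings:
    def test_identical_encodings_identical_embeddings(self, small_setup):
        enc = small_setup.enc_test[0]
        emb = small_setup.model.embed([enc, enc, enc])
        np.testing.assert_array_equal(emb[0], emb[1])
        np.testing.assert_array_equal(emb[0], emb[2])

    def test_embedding_dimension_is_hidden_dim(self, small_setup):
        emb = small_setup.model.embed(small_setup.enc_test[:3])
        assert emb.shape == (3, small_setup.model.hidden_dim)
        assert np.isfinite(emb).all()

    def test_batched_equals_one_at_a_time(self, small_setup):
        encs = small_setup.enc_test[:10]
        batched = small_setup.model.embed(encs)
        single = np.vstack([small_setup.model.embed([e]) for e in encs])
        np.testing.assert_allclose(batched, single, atol=1e-5)
        p_batched = small_setup.model.predict_proba(encs)
        p_single = np.vstack([small_setup.model.predict_proba([e]) for e in encs])
        np.testing.assert_allclose(p_batched, p_single, atol=1e-5)

    def test_overlong_encoding_rejected(self, small_setup):
        long_enc = RankEncoding(
            cell_id="x", tokens=tuple(range(2, 2 + 60)), context_length=64
        )
        with pytest.raises(ValueError, match="context length"):
            small_setup.model.embed([long_enc])

    def test_embed_requires_trained_model(self):
        with pytest.raises(NotFittedError):
            _tiny_model().embed(_encodings([(2, 3)]))


class TestPersistence:
    def test_save_load_roundtrip(self, small_setup, tmp_path):
        path = tmp_path / "model.npz"
        small_setup.model.save(path)
        loaded = StateTransformerClassifier.load(path)
        assert loaded.phase_ == "finetuned"
        encs = small_setup.enc_test[:8]
        np.testing.assert_array_equal(
            loaded.predict(encs), small_setup.model.predict(encs)
        )
        np.testing.assert_allclose(
            loaded.predict_proba(encs), small_setup.model.predict_proba(encs)
        )
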
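import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from tsfs.teacher import (
    CodeMatrix,
    TeacherNetwork,
    TeacherSpec,
    default_teacher_spec,
    extract_codes,
    standardize_codes,
    train_teacher,
)


@pytest.fixture(scope="module")
def blobs():
    """Linearly separable 10-dim data with two informative dimensions."""
    rng = np.random.default_rng(0)
    X = rng.standard_normal((60, 10))
    y = np.array([0] * 30 + [1] * 30)
    X[y == 1, :2] += 3.0
    return X, y


@pytest.fixture(scope="module")
def trained_blob_teacher(blobs):
    X, y = blobs
    spec = default_teacher_spec(10, epochs=200, learning_rate=0.5, seed=0)
    return train_teacher(X, y, spec)


class TestDefaultSpec:
    def test_aal_scale_funnel(self):
        spec = default_teacher_spec(4005)
        assert len(spec.layer_sizes) == 17
        assert spec.layer_sizes[0] == 4005
        assert spec.layer_sizes[-1] == 2
        assert spec.layer_sizes.count(5) == 1
        funnel = spec.layer_sizes[:-1]
        assert all(a >= b for a, b in zip(funnel[:-1], funnel[1:]))

    def test_small_input_still_17_layers(self):
        spec = default_teacher_spec(10)
        assert len(spec.layer_sizes) == 17
        assert spec.layer_sizes[0] == 10 and spec.layer_sizes[-2:] == (5, 2)

    def test_dropout_decays_to_zero_before_code_layer(self):
        spec = default_teacher_spec(100)
        assert spec.dropout_schedule[0] == pytest.approx(0.3)
        assert spec.dropout_schedule[-1] == 0.0
        assert all(a >= b for a, b in zip(spec.dropout_schedule, spec.dropout_schedule[1:]))

    def test_rejects_input_not_exceeding_code(self):
        with pytest.raises(ValueError):
            default_teacher_spec(5)

    @pytest.mark.parametrize(
        "sizes",
        [
            (10, 8, 5, 3),  # head is not 2 units
            (10, 5, 5, 2),  # code width repeated
            (10, 6, 8, 5, 2),  # widening before the code layer
        ],
    )
    def test_spec_invariants_enforced(self, sizes):
        with pytest.raises(ValueError):
            TeacherSpec(layer_sizes=sizes)


class TestTraining:
    def test_separable_blobs_reach_high_accuracy(self, blobs, trained_blob_teacher):
        X, y = blobs
        # a linear oracle certifies the data is separable
        assert LogisticRegression(max_iter=1000).fit(X, y).score(X, y) >= 0.95
        acc = (trained_blob_teacher.predict(X) == y).mean()
        assert acc >= 0.95

    def test_label_flip_near_symmetry(self, blobs):
        # the 2-unit cross-entropy head treats the classes symmetrically;
        # equality is only exact under mirrored initialisation, so allow a
        # small optimisation-path difference
        X, y = blobs
        spec = default_teacher_spec(10, epochs=200, learning_rate=0.5, seed=0)
        acc = (train_teacher(X, y, spec).predict(X) == y).mean()
        acc_flipped = (train_teacher(X, 1 - y, spec).predict(X) == (1 - y)).mean()
        assert acc_flipped == pytest.approx(acc, abs=0.05)

    def test_loss_history_finite_one_entry_per_epoch(self, trained_blob_teacher):
        h = trained_blob_teacher.loss_history_
        assert len(h) == 200
        assert np.all(np.isfinite(h))

    def test_softmax_rows_sum_to_one(self, blobs, trained_blob_teacher):
        X, _ = blobs
        proba = trained_blob_teacher.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(proba >= 0)

    def test_seeded_training_reproducible(self, blobs):
        X, y = blobs
        spec = default_teacher_spec(10, epochs=30, seed=7)
        a = train_teacher(X, y, spec)
        b = train_teacher(X, y, spec)
        for wa, wb in zip(a.net_.weights, b.net_.weights):
            np.testing.assert_array_equal(wa, wb)
        assert a.loss_history_ == b.loss_history_

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 10))
        with pytest.raises(ValueError):
            TeacherNetwork(epochs=1).fit(X, np.zeros(10))

    def test_non_finite_input_rejected(self, blobs):
        X, y = blobs
        X = X.copy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            TeacherNetwork(epochs=1).fit(X, y)


class TestCodes:
    def test_code_matrix_shape(self, blobs, trained_blob_teacher):
        X, _ = blobs
        codes = extract_codes(trained_blob_teacher, X)
        assert codes.values.shape == (60, 5)
        assert not codes.standardized

    def test_identical_inputs_identical_codes(self, blobs, trained_blob_teacher):
        X, _ = blobs
        stacked = np.vstack([X[:1], X[:1]])
        codes = trained_blob_teacher.transform(stacked)
        np.testing.assert_array_equal(codes[0], codes[1])

    def test_codes_match_manual_forward_pass(self, blobs, trained_blob_teacher):
        X, _ = blobs
        net = trained_blob_teacher.net_
        a = X
        for l in range(trained_blob_teacher.code_layer_index_):
            a = np.tanh(a @ net.weights[l] + net.biases[l])
        np.testing.assert_allclose(trained_blob_teacher.transform(X), a, atol=1e-12)

    def test_untrained_transform_rejected(self):
        with pytest.raises(Exception):
            TeacherNetwork().transform(np.zeros((3, 10)))


class TestStandardize:
    def test_hand_z_score_population_sd(self):
        codes = CodeMatrix(values=np.array([[1.0], [2.0], [3.0]]), standardized=False)
        out = standardize_codes(codes)
        sd = np.sqrt(2.0 / 3.0)  # population convention
        np.testing.assert_allclose(out.values[:, 0], [-1 / sd, 0.0, 1 / sd])
        np.testing.assert_allclose(out.means, [2.0])
        np.testing.assert_allclose(out.sds, [sd])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        once = standardize_codes(rng.standard_normal((50, 4)))
        twice = standardize_codes(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-9)

    def test_moments_after_standardizing(self):
        rng = np.random.default_rng(2)
        out = standardize_codes(rng.standard_normal((30, 5)) * 3 + 1)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(out.values.std(axis=0), 1.0, atol=1e-6)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            standardize_codes(np.ones((1, 5)))

    def test_zero_variance_column_rejected(self):
        vals = np.random.default_rng(3).standard_normal((10, 3))
        vals[:, 2] = 4.2
        with pytest.raises(ValueError, match=r"\[2\]"):
            standardize_codes(vals)
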
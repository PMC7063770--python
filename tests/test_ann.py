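"""Neural-network estimator: forward pass, gradients, training, I/O."""

import json
import math

import numpy as np
import pytest

from egfrkit import (AnnModel, Cohort, NormalizationParams, Sex,
                     SyntheticCohortSpec, TrainConfig, export_model,
                     fit_preprocessing, generate, import_model, predict,
                     predict_batch, train)
from egfrkit.ann import (INPUT_ORDER, AnnError, ModelFileError,
                         TrainingDivergedError, gradients)
from conftest import make_record


def identity_norm() -> NormalizationParams:
    return NormalizationParams(center=(0.0,) * 9, scale=(1.0,) * 9)


def zero_model(b2=0.0, **kw) -> AnnModel:
    return AnnModel(W1=np.zeros((4, 9)), b1=np.zeros(4), W2=np.zeros((1, 4)),
                    b2=b2, leak_alpha=0.1, norm=identity_norm(), **kw)


class TestForwardPass:
    def test_zero_weights_predict_constant_bias(self):
        model = zero_model(b2=42.0)
        for i in range(3):
            assert predict(model, make_record(i)) == 42.0

    def test_single_neuron_worked_example(self):
        """Hand computation: one hidden unit reads the creatinine input.
        z_scr = (1.4 - 1.0)/0.5 = 0.8; hidden pre-activation
        2*0.8 - 1 = 0.6 >= 0 so phi = 0.6; output 3*0.6 + 0.5 = 2.3."""
        scr_idx = INPUT_ORDER.index("scr")
        center = [0.0] * 9
        scale = [1.0] * 9
        center[scr_idx], scale[scr_idx] = 1.0, 0.5
        norm = NormalizationParams(center=tuple(center), scale=tuple(scale))
        W1 = np.zeros((4, 9))
        W1[0, scr_idx] = 2.0
        model = AnnModel(W1=W1, b1=np.array([-1.0, 0, 0, 0]),
                         W2=np.array([[3.0, 0, 0, 0]]), b2=0.5,
                         leak_alpha=0.1, norm=norm)
        got = predict(model, make_record(0, scr=1.4), floor=None)
        assert got == pytest.approx(2.3, abs=1e-12)

    def test_negative_preactivations_scale_by_leak(self):
        """Same network driven to the negative side: phi(-u) = -0.1*u,
        so the output is attenuated by the leak factor."""
        scr_idx = INPUT_ORDER.index("scr")
        W1 = np.zeros((4, 9))
        W1[0, scr_idx] = 1.0
        model = AnnModel(W1=W1, b1=np.zeros(4), W2=np.array([[1.0, 0, 0, 0]]),
                         b2=0.0, leak_alpha=0.1, norm=identity_norm())
        pos = predict(model, make_record(0, scr=2.0), floor=None)
        neg = predict(model, make_record(0, scr=2.0), floor=None)
        # mirror the input through the weight sign instead (scr must be > 0)
        model_neg = AnnModel(W1=-W1, b1=np.zeros(4),
                             W2=np.array([[1.0, 0, 0, 0]]), b2=0.0,
                             leak_alpha=0.1, norm=identity_norm())
        neg = predict(model_neg, make_record(0, scr=2.0), floor=None)
        assert pos == pytest.approx(2.0)
        assert neg == pytest.approx(-0.1 * 2.0)

    def test_forward_matches_independent_arithmetic(self):
        """Oracle: plain nested Python loops, no numpy linear algebra."""
        rng = np.random.default_rng(5)
        W1 = rng.normal(size=(4, 9))
        b1 = rng.normal(size=4)
        W2 = rng.normal(size=(1, 4))
        b2 = float(rng.normal())
        center = tuple(rng.normal(size=9))
        scale = tuple(np.abs(rng.normal(size=9)) + 0.5)
        norm = NormalizationParams(center=center, scale=scale,
                                   target_center=2.0, target_sd=3.0)
        model = AnnModel(W1=W1, b1=b1, W2=W2, b2=b2, leak_alpha=0.1,
                         norm=norm)
        for i in range(20):
            r = make_record(i, np.random.default_rng(100 + i))
            x = [r.age, 1.0 if r.sex is Sex.MALE else 0.0, r.scr, r.scys,
                 r.bmi, r.bun, r.alb, r.ua, r.hgb]
            z = [(x[j] - center[j]) / scale[j] for j in range(9)]
            hidden = []
            for k in range(4):
                u = b1[k]
                for j in range(9):
                    u += W1[k][j] * z[j]
                hidden.append(u if u >= 0 else 0.1 * u)
            out = b2
            for k in range(4):
                out += W2[0][k] * hidden[k]
            expected = out * 3.0 + 2.0
            assert predict(model, r, floor=None) == pytest.approx(
                expected, abs=1e-10)

    def test_missing_variable_is_explicit_error(self):
        with pytest.raises(AnnError, match="hgb"):
            predict(zero_model(), make_record(0, hgb=None))


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Central finite differences (step 1e-6) at 20 random parameter
        points, relative error < 1e-4."""
        rng = np.random.default_rng(11)
        Z = rng.normal(size=(16, 9))
        t = rng.normal(size=16)
        for trial in range(20):
            W1 = rng.normal(size=(4, 9)) * 0.5
            b1 = rng.normal(size=4) * 0.5
            W2 = rng.normal(size=(1, 4)) * 0.5
            b2 = float(rng.normal())
            loss, dW1, db1, dW2, db2 = gradients(Z, t, W1, b1, W2, b2, 0.1)
            h = 1e-6

            def loss_at(W1=W1, b1=b1, W2=W2, b2=b2):
                return gradients(Z, t, W1, b1, W2, b2, 0.1)[0]

            # spot-check one entry of each parameter block
            i, j = rng.integers(4), rng.integers(9)
            E = np.zeros_like(W1); E[i, j] = h
            num = (loss_at(W1=W1 + E) - loss_at(W1=W1 - E)) / (2 * h)
            assert num == pytest.approx(dW1[i, j], rel=1e-4, abs=1e-8)
            e1 = np.zeros_like(b1); e1[i] = h
            num = (loss_at(b1=b1 + e1) - loss_at(b1=b1 - e1)) / (2 * h)
            assert num == pytest.approx(db1[i], rel=1e-4, abs=1e-8)
            E2 = np.zeros_like(W2); E2[0, i] = h
            num = (loss_at(W2=W2 + E2) - loss_at(W2=W2 - E2)) / (2 * h)
            assert num == pytest.approx(dW2[0, i], rel=1e-4, abs=1e-8)
            num = (loss_at(b2=b2 + h) - loss_at(b2=b2 - h)) / (2 * h)
            assert num == pytest.approx(db2, rel=1e-4, abs=1e-8)


class TestPreprocessing:
    def test_extreme_outlier_removed(self):
        records = [make_record(i, np.random.default_rng(i)) for i in range(60)]
        scrs = [r.scr for r in records]
        mu, sd = np.mean(scrs), np.std(scrs)
        records.append(make_record(99, scr=float(mu + 12 * sd)))
        _, cleaned, n_removed = fit_preprocessing(Cohort(records), outlier_z=3.0)
        assert n_removed >= 1
        assert "p099" not in cleaned.subject_ids()

    def test_infinite_threshold_removes_nothing(self, random_cohort):
        _, cleaned, n_removed = fit_preprocessing(random_cohort,
                                                  outlier_z=math.inf)
        assert n_removed == 0 and len(cleaned) == len(random_cohort)

    def test_cleaned_columns_standardized(self, random_cohort):
        norm, cleaned, _ = fit_preprocessing(random_cohort, outlier_z=3.0)
        from egfrkit.ann import _cohort_matrix
        Z = norm.transform(_cohort_matrix(cleaned))
        cont = [i for i, v in enumerate(INPUT_ORDER) if v != "sex"]
        np.testing.assert_allclose(Z[:, cont].mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(Z[:, cont].std(axis=0), 1, atol=1e-10)

    def test_zero_variance_rejected(self):
        records = [make_record(i, age=50.0) for i in range(30)]
        with pytest.raises(AnnError, match="variance"):
            fit_preprocessing(Cohort(records))


class TestTraining:
    def test_same_seed_gives_bit_identical_weights(self):
        dev = generate(SyntheticCohortSpec(n=200, seed=1))
        cfg = TrainConfig(epochs=30)
        m1 = train(dev, cfg, seed=7)
        m2 = train(dev, cfg, seed=7)
        assert np.array_equal(m1.W1, m2.W1) and np.array_equal(m1.W2, m2.W2)
        assert m1.training_log == m2.training_log

    def test_beats_intercept_only_predictor(self):
        dev = generate(SyntheticCohortSpec(n=1000, seed=2))
        val = generate(SyntheticCohortSpec(n=500, seed=3))
        cfg = TrainConfig(target_scale="log", log_inputs=("scr", "scys", "bun"),
                          epochs=300)
        model = train(dev, cfg, seed=0)
        _, pred = predict_batch(model, val)
        m = val.column("mgfr")
        rmse = np.sqrt(np.mean((pred - m) ** 2))
        rmse_const = np.sqrt(np.mean((dev.column("mgfr").mean() - m) ** 2))
        assert rmse < rmse_const
        assert len(model.training_log) > 0
        assert model.training_log[-1] <= model.training_log[0]

    def test_near_linear_map_is_representable(self):
        """With a noiseless log-linear generating law, log target and
        log-scale marker inputs, the trained network's training RMSE on
        the log scale approaches the zero residual floor."""
        dev = generate(SyntheticCohortSpec(n=1000, seed=3, gfr_noise_sd=0.0))
        cfg = TrainConfig(target_scale="log", log_inputs=("scr", "scys", "bun"),
                          epochs=1500, patience=200)
        model = train(dev, cfg, seed=0)
        _, pred = predict_batch(model, dev)
        m = dev.column("mgfr")
        rmse = np.sqrt(np.mean((np.log(pred) - np.log(m)) ** 2))
        assert rmse < 0.08

    def test_divergence_raises_helpful_error(self):
        dev = generate(SyntheticCohortSpec(n=200, seed=4))
        with pytest.raises(TrainingDivergedError, match="learning rate"):
            train(dev, TrainConfig(learning_rate=1e6, epochs=20), seed=0)

    def test_too_small_cohort_rejected(self):
        dev = generate(SyntheticCohortSpec(n=30, seed=5))
        with pytest.raises(AnnError, match="50"):
            train(dev, TrainConfig(epochs=5), seed=0)


class TestModelFile:
    def test_export_import_round_trip_bit_identical(self, tmp_path):
        dev = generate(SyntheticCohortSpec(n=200, seed=6))
        model = train(dev, TrainConfig(epochs=20), seed=1)
        path = tmp_path / "model.json"
        export_model(model, path)
        back = import_model(path)
        probe = generate(SyntheticCohortSpec(n=100, seed=7))
        _, p1 = predict_batch(model, probe)
        _, p2 = predict_batch(back, probe)
        np.testing.assert_array_equal(p1, p2)

    def test_missing_b2_named_in_error(self, tmp_path):
        dev = generate(SyntheticCohortSpec(n=200, seed=6))
        model = train(dev, TrainConfig(epochs=5), seed=1)
        path = tmp_path / "model.json"
        export_model(model, path)
        doc = json.loads(path.read_text())
        del doc["b2"]
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFileError, match="b2"):
            import_model(path)

    def test_flat_file_reproducible_by_independent_script(self, tmp_path):
        """Evaluate the exported file with standalone arithmetic (an
        emulation of a spreadsheet implementation) and compare."""
        dev = generate(SyntheticCohortSpec(n=300, seed=8))
        cfg = TrainConfig(target_scale="log", log_inputs=("scr", "scys", "bun"),
                          epochs=50)
        model = train(dev, cfg, seed=2)
        path = tmp_path / "model.json"
        export_model(model, path)
        doc = json.loads(path.read_text())

        def spreadsheet_eval(row: dict) -> float:
            z = []
            for j, name in enumerate(doc["input_order"]):
                v = row[name]
                if name in doc["norm"]["log_inputs"]:
                    v = math.log(v)
                z.append((v - doc["norm"]["center"][j])
                         / doc["norm"]["scale"][j])
            out = doc["b2"]
            for k in range(len(doc["b1"])):
                u = doc["b1"][k]
                for j in range(len(z)):
                    u += doc["W1"][k][j] * z[j]
                out += doc["W2"][0][k] * (u if u >= 0
                                          else doc["leak_alpha"] * u)
            y = out * doc["norm"]["target_sd"] + doc["norm"]["target_center"]
            if doc["target_scale"] == "log":
                y = math.exp(y)
            return max(y, 1.0)

        probe = generate(SyntheticCohortSpec(n=100, seed=9))
        _, got = predict_batch(model, probe)
        for r, g in zip(probe, got):
            row = {"age": r.age, "sex": 1.0 if r.sex is Sex.MALE else 0.0,
                   "scr": r.scr, "scys": r.scys, "bmi": r.bmi, "bun": r.bun,
                   "alb": r.alb, "ua": r.ua, "hgb": r.hgb}
            assert g == pytest.approx(spreadsheet_eval(row), abs=1e-10)
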
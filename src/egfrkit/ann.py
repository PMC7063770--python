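"""A small neural network for GFR estimation: 9 inputs, one hidden
layer of 4 Leaky-ReLU units, one linear output.

The network is deliberately implemented from first principles — explicit
weight matrices and hand-written backpropagation — because the model has
only 49 parameters and its predictions must be exactly reproducible by
plain arithmetic on an exported flat weight file (e.g. in a
spreadsheet).  Training is plain mini-batch stochastic gradient descent
on mean squared error, fully deterministic given a seed.

Preprocessing follows the usual tabular recipe: the eight continuous
inputs are z-scored with development-set statistics (recomputed after
outlier removal); sex enters as 0/1 unscaled; records with any
continuous variable (including the target) beyond ``outlier_z`` standard
deviations are dropped.  The target can be regressed on the identity
scale or, with ``target_scale="log"``, on ``ln(mGFR)`` (the scale on
which GFR–marker relations are near-linear); either way it is
standardized internally for SGD stability and the transform is undone
at prediction time.  Reported predictions are floored at
1 mL/min/1.73 m^2 to avoid nonphysical non-positive estimates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import Cohort, PatientRecord, Sex

__all__ = [
    "INPUT_ORDER",
    "NormalizationParams",
    "TrainConfig",
    "AnnModel",
    "AnnError",
    "TrainingDivergedError",
    "ModelFileError",
    "fit_preprocessing",
    "train",
    "predict",
    "predict_batch",
    "export_model",
    "import_model",
]

#: the 9 network inputs, in contract order (part of the weight-file format)
INPUT_ORDER = ("age", "sex", "scr", "scys", "bmi", "bun", "alb", "ua", "hgb")

#: continuous inputs (everything but sex) — these are z-scored
CONTINUOUS_INPUTS = tuple(v for v in INPUT_ORDER if v != "sex")

#: floor applied to reported predictions, mL/min/1.73 m^2
PREDICTION_FLOOR = 1.0


class AnnError(Exception):
    pass


class TrainingDivergedError(AnnError):
    pass


class ModelFileError(AnnError):
    pass


@dataclass(frozen=True)
class NormalizationParams:
    """Per-input center/scale plus the target's center/SD.

    ``center``/``scale`` are aligned with :data:`INPUT_ORDER`; the sex
    column uses center 0 and scale 1 (0/1 passed through unscaled).
    Inputs named in ``log_inputs`` are natural-log-transformed before
    centering (useful for the right-skewed markers scr, scys and BUN);
    their center/scale refer to the log scale.
    """
    center: tuple[float, ...]
    scale: tuple[float, ...]
    target_center: float = 0.0
    target_sd: float = 1.0
    log_inputs: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.center) != len(INPUT_ORDER) or \
                len(self.scale) != len(INPUT_ORDER):
            raise AnnError("center/scale must cover all 9 inputs")
        if any(s <= 0 for s in self.scale) or self.target_sd <= 0:
            raise AnnError("all scales must be > 0")
        unknown = set(self.log_inputs) - set(INPUT_ORDER)
        if unknown or "sex" in self.log_inputs:
            raise AnnError(f"invalid log_inputs {self.log_inputs!r}")

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.array(X, dtype=float, copy=True)
        for name in self.log_inputs:
            j = INPUT_ORDER.index(name)
            if np.any(X[:, j] <= 0):
                raise AnnError(f"{name} must be > 0 for log transform")
            X[:, j] = np.log(X[:, j])
        return (X - np.asarray(self.center)) / np.asarray(self.scale)


@dataclass(frozen=True)
class TrainConfig:
    """SGD hyperparameters.  Every knob of the training recipe is here."""
    learning_rate: float = 0.01
    batch_size: int = 32
    epochs: int = 2000
    validation_fraction: float = 0.1
    patience: int = 50
    hidden_units: int = 4
    leak_alpha: float = 0.1
    outlier_z: float = 3.0
    target_scale: str = "identity"  # or "log"
    log_inputs: tuple[str, ...] = ()  # e.g. ("scr", "scys", "bun")

    def __post_init__(self):
        if self.target_scale not in ("identity", "log"):
            raise AnnError(f"unknown target_scale {self.target_scale!r}")


@dataclass(frozen=True)
class AnnModel:
    """Trained network: weights, normalization, and provenance."""
    W1: np.ndarray  # hidden x 9
    b1: np.ndarray  # hidden
    W2: np.ndarray  # 1 x hidden
    b2: float
    leak_alpha: float
    norm: NormalizationParams
    target_scale: str = "identity"
    seed: int | None = None
    training_log: tuple[float, ...] = ()

    def __post_init__(self):
        W1 = np.asarray(self.W1, dtype=float)
        W2 = np.asarray(self.W2, dtype=float)
        if W1.shape[1] != len(INPUT_ORDER) or W2.shape != (1, W1.shape[0]):
            raise AnnError(f"weight shapes {W1.shape}/{W2.shape} do not form "
                           f"a {len(INPUT_ORDER)}->h->1 network")
        object.__setattr__(self, "W1", W1)
        object.__setattr__(self, "b1", np.asarray(self.b1, dtype=float))
        object.__setattr__(self, "W2", W2)


def _leaky(u: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(u >= 0, u, alpha * u)


def _record_inputs(rec: PatientRecord) -> np.ndarray:
    vals = []
    missing = []
    for name in INPUT_ORDER:
        if name == "sex":
            vals.append(1.0 if rec.sex is Sex.MALE else 0.0)
            continue
        v = rec.get(name)
        if v is None:
            missing.append(name)
            vals.append(np.nan)
        else:
            vals.append(float(v))
    if missing:
        raise AnnError(f"subject {rec.subject_id!r} missing variables "
                       f"{missing} required by the network")
    return np.asarray(vals)


def _cohort_matrix(cohort: Cohort) -> np.ndarray:
    return np.vstack([_record_inputs(r) for r in cohort]) if len(cohort) \
        else np.empty((0, len(INPUT_ORDER)))


def fit_preprocessing(dev: Cohort, outlier_z: float = 3.0,
                      target_scale: str = "identity",
                      log_inputs: Sequence[str] = ()
                      ) -> tuple[NormalizationParams, Cohort, int]:
    """Fit normalization on a development cohort and drop outliers.

    A record is an outlier if any continuous input (after any
    ``log_inputs`` transform), or the (possibly log-transformed) target,
    lies more than ``outlier_z`` SDs from the development mean.
    Center/scale are then recomputed on the cleaned cohort and frozen
    for later application to validation data.

    Returns ``(params, cleaned_cohort, n_removed)``.
    """
    if len(dev) == 0:
        raise AnnError("empty development cohort")
    X = _cohort_matrix(dev)
    for name in log_inputs:
        j = INPUT_ORDER.index(name)
        if np.any(X[:, j] <= 0):
            raise AnnError(f"{name} must be > 0 for log transform")
        X[:, j] = np.log(X[:, j])
    m = np.array([np.nan if r.mgfr is None else float(r.mgfr) for r in dev])
    if np.isnan(m).any():
        raise AnnError("preprocessing requires mgfr on every record")
    y = np.log(m) if target_scale == "log" else m

    def stats(M: np.ndarray, t: np.ndarray):
        c = M.mean(axis=0)
        s = M.std(axis=0, ddof=0)
        cont = [i for i, name in enumerate(INPUT_ORDER) if name != "sex"]
        if any(s[i] == 0 for i in cont) or t.std(ddof=0) == 0:
            raise AnnError("zero variance in a continuous variable")
        return c, s, t.mean(), t.std(ddof=0)

    c, s, tc, ts = stats(X, y)
    cont_idx = [i for i, name in enumerate(INPUT_ORDER) if name != "sex"]
    z = np.abs((X[:, cont_idx] - c[cont_idx]) / s[cont_idx])
    zt = np.abs((y - tc) / ts)
    keep = np.ones(len(dev), dtype=bool)
    if np.isfinite(outlier_z):
        keep = (z <= outlier_z).all(axis=1) & (zt <= outlier_z)
    cleaned = dev.with_records([r for r, k in zip(dev, keep) if k])
    n_removed = int((~keep).sum())
    if n_removed:
        X, y = X[keep], y[keep]
        c, s, tc, ts = stats(X, y)
    center = [0.0 if name == "sex" else float(c[i])
              for i, name in enumerate(INPUT_ORDER)]
    scale = [1.0 if name == "sex" else float(s[i])
             for i, name in enumerate(INPUT_ORDER)]
    params = NormalizationParams(center=tuple(center), scale=tuple(scale),
                                 target_center=float(tc), target_sd=float(ts),
                                 log_inputs=tuple(log_inputs))
    return params, cleaned, n_removed


def _forward(Z: np.ndarray, W1, b1, W2, b2, alpha: float):
    A1 = Z @ W1.T + b1
    H = _leaky(A1, alpha)
    out = H @ W2.T + b2
    return A1, H, out[:, 0]


def gradients(Z: np.ndarray, t: np.ndarray, W1, b1, W2, b2, alpha: float):
    """Analytic MSE gradients for one batch (used by SGD and testable
    against finite differences).  Returns (loss, dW1, db1, dW2, db2)."""
    n = Z.shape[0]
    with np.errstate(over="ignore", invalid="ignore"):
        A1, H, out = _forward(Z, W1, b1, W2, b2, alpha)
        err = out - t
        loss = float(err @ err) / n
        dout = (2.0 / n) * err[:, None]        # n x 1
        dW2 = dout.T @ H                        # 1 x h
        db2 = float(dout.sum())
        dH = dout @ W2                          # n x h
        dA1 = dH * np.where(A1 >= 0, 1.0, alpha)
        dW1 = dA1.T @ Z                         # h x 9
        db1 = dA1.sum(axis=0)
    return loss, dW1, db1, dW2, db2


def train(dev: Cohort, config: TrainConfig = TrainConfig(), seed: int = 0,
          norm: NormalizationParams | None = None) -> AnnModel:
    """Train the network on a development cohort by mini-batch SGD.

    Preprocessing (outlier removal + normalization) is fitted here
    unless ``norm`` is supplied.  A ``validation_fraction`` of the
    cleaned development data is held out for early stopping (patience in
    epochs, best weights restored).  Fully deterministic given ``seed``:
    weight initialization, the holdout split and batch shuffling all
    derive from it.
    """
    if norm is None:
        norm, dev, _ = fit_preprocessing(dev, outlier_z=config.outlier_z,
                                         target_scale=config.target_scale,
                                         log_inputs=config.log_inputs)
    n = len(dev)
    if n < 50:
        raise AnnError(f"need at least 50 records to train, got {n}")
    X = _cohort_matrix(dev)
    m = np.array([float(r.mgfr) for r in dev])
    y = np.log(m) if config.target_scale == "log" else m
    Z = norm.transform(X)
    t = (y - norm.target_center) / norm.target_sd

    rng = np.random.default_rng(seed)
    h = config.hidden_units
    # uniform init scaled by fan-in
    W1 = rng.uniform(-1, 1, size=(h, Z.shape[1])) / math.sqrt(Z.shape[1])
    b1 = np.zeros(h)
    W2 = rng.uniform(-1, 1, size=(1, h)) / math.sqrt(h)
    b2 = 0.0

    idx = rng.permutation(n)
    n_val = int(round(n * config.validation_fraction))
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    Ztr, ttr = Z[tr_idx], t[tr_idx]
    Zval, tval = Z[val_idx], t[val_idx]

    best = (math.inf, W1.copy(), b1.copy(), W2.copy(), b2)
    best_epoch = 0
    log: list[float] = []
    lr = config.learning_rate
    for epoch in range(config.epochs):
        order = rng.permutation(len(tr_idx))
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            _, dW1, db1, dW2, db2 = gradients(
                Ztr[batch], ttr[batch], W1, b1, W2, b2, config.leak_alpha)
            W1 -= lr * dW1
            b1 -= lr * db1
            W2 -= lr * dW2
            b2 -= lr * db2
        loss, *_ = gradients(Ztr, ttr, W1, b1, W2, b2, config.leak_alpha)
        log.append(loss)
        if not math.isfinite(loss):
            raise TrainingDivergedError(
                "training loss diverged (NaN/inf); try a smaller learning rate")
        if n_val > 0:
            vloss, *_ = gradients(Zval, tval, W1, b1, W2, b2, config.leak_alpha)
            if vloss < best[0]:
                best = (vloss, W1.copy(), b1.copy(), W2.copy(), b2)
                best_epoch = epoch
            elif epoch - best_epoch >= config.patience:
                break
    if n_val > 0 and math.isfinite(best[0]):
        _, W1, b1, W2, b2 = best
    return AnnModel(W1=W1, b1=b1, W2=W2, b2=b2,
                    leak_alpha=config.leak_alpha, norm=norm,
                    target_scale=config.target_scale, seed=seed,
                    training_log=tuple(log))


def _predict_matrix(model: AnnModel, X: np.ndarray,
                    floor: float | None) -> np.ndarray:
    Z = model.norm.transform(X)
    _, _, out = _forward(Z, model.W1, model.b1, model.W2, model.b2,
                         model.leak_alpha)
    y = out * model.norm.target_sd + model.norm.target_center
    if model.target_scale == "log":
        y = np.exp(y)
    if floor is not None:
        y = np.maximum(y, floor)
    return y


def predict(model: AnnModel, rec: PatientRecord,
            floor: float | None = PREDICTION_FLOOR) -> float:
    """Predict eGFR (mL/min/1.73 m^2) for one record."""
    return float(_predict_matrix(model, _record_inputs(rec)[None, :], floor)[0])


def predict_batch(model: AnnModel, cohort: Cohort,
                  floor: float | None = PREDICTION_FLOOR
                  ) -> tuple[list[str], np.ndarray]:
    """Predict for every record; order preserved."""
    return cohort.subject_ids(), _predict_matrix(model, _cohort_matrix(cohort),
                                                 floor)


# ---- flat weight file -------------------------------------------------

_REQUIRED_KEYS = ("W1", "b1", "W2", "b2", "leak_alpha", "norm",
                  "target_scale", "input_order")
_REQUIRED_NORM_KEYS = ("center", "scale", "target_center", "target_sd")


def export_model(model: AnnModel, path: str | Path) -> None:
    """Write the model as a human-readable JSON flat weight file.

    The file carries everything needed to reproduce predictions with
    plain arithmetic: weights, biases, leak coefficient, normalization
    constants, target transform, and the explicit input variable order.
    """
    doc = {
        "input_order": list(INPUT_ORDER),
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "W2": model.W2.tolist(),
        "b2": float(model.b2),
        "leak_alpha": float(model.leak_alpha),
        "norm": {
            "center": list(model.norm.center),
            "scale": list(model.norm.scale),
            "target_center": float(model.norm.target_center),
            "target_sd": float(model.norm.target_sd),
            "log_inputs": list(model.norm.log_inputs),
        },
        "target_scale": model.target_scale,
        "seed": model.seed,
        "training_log": list(model.training_log),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def import_model(path: str | Path) -> AnnModel:
    """Read a flat weight file; inverse of :func:`export_model`."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFileError(f"malformed model file {path}: {exc}")
    for key in _REQUIRED_KEYS:
        if key not in doc:
            raise ModelFileError(f"model file missing field {key!r}")
    for key in _REQUIRED_NORM_KEYS:
        if key not in doc["norm"]:
            raise ModelFileError(f"model file missing field 'norm.{key}'")
    if list(doc["input_order"]) != list(INPUT_ORDER):
        raise ModelFileError(
            f"unsupported input_order {doc['input_order']!r}")
    norm = NormalizationParams(
        center=tuple(doc["norm"]["center"]), scale=tuple(doc["norm"]["scale"]),
        target_center=float(doc["norm"]["target_center"]),
        target_sd=float(doc["norm"]["target_sd"]),
        log_inputs=tuple(doc["norm"].get("log_inputs", ())))
    return AnnModel(W1=np.asarray(doc["W1"], dtype=float),
                    b1=np.asarray(doc["b1"], dtype=float),
                    W2=np.asarray(doc["W2"], dtype=float),
                    b2=float(doc["b2"]),
                    leak_alpha=float(doc["leak_alpha"]), norm=norm,
                    target_scale=str(doc["target_scale"]),
                    seed=doc.get("seed"),
                    training_log=tuple(doc.get("training_log", ())))
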
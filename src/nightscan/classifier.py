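"""15-class linear SVM classification and binary collapsing.

Each plant-observation belongs to one of 15 treatment classes — every valid
combination of measurement period (baseline/early/late), fertilizer regime
(low/medium/high) and infestation status (baseline plants are never
infested, so 3 + 6 + 6 = 15).  A linear-kernel support vector machine with
one-vs-one decomposition is trained on the 31 binned first-derivative bands
and its 15-class predictions are collapsed to the infestation bit:
mis-assignments of period or fertilizer within the correct infestation
status are not detection errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import synth_scene as _sc

N_CLASSES = 15

# Canonical class ordering: baseline low/med/high = 1-3, early non-infested
# 4-6, early infested 7-9, late non-infested 10-12, late infested 13-15;
# fertilizer cycles low/medium/high within each block.
_BLOCKS = [
    ("baseline", False),
    ("early", False),
    ("early", True),
    ("late", False),
    ("late", True),
]
_CODE_TO_LABEL: dict[int, tuple[str, str, bool]] = {}
for _i, (_period, _inf) in enumerate(_BLOCKS):
    for _j, _fert in enumerate(_sc.FERTILIZERS):
        _CODE_TO_LABEL[3 * _i + _j + 1] = (_period, _fert, _inf)
_LABEL_TO_CODE = {v: k for k, v in _CODE_TO_LABEL.items()}

INFESTED_CODES = frozenset(c for c, (_, _, i) in _CODE_TO_LABEL.items() if i)


def encode_class(period: str, fertilizer: str, infested: bool) -> int:
    """Map a treatment cell to its class code 1-15.

    Raises ``ValueError`` for baseline+infested, which does not exist.
    """
    if period == "baseline" and infested:
        raise ValueError("baseline plants cannot be infested")
    try:
        return _LABEL_TO_CODE[(period, fertilizer, bool(infested))]
    except KeyError:
        raise ValueError(f"invalid treatment cell {(period, fertilizer, infested)}")


def decode_class(code: int) -> tuple[str, str, bool]:
    """Inverse of :func:`encode_class`."""
    try:
        return _CODE_TO_LABEL[int(code)]
    except KeyError:
        raise ValueError(f"class code must be 1-{N_CLASSES}, got {code}")


def collapse(codes) -> np.ndarray:
    """Collapse class codes to the infestation bit (True = infested)."""
    codes = np.atleast_1d(np.asarray(codes, dtype=int))
    if np.any((codes < 1) | (codes > N_CLASSES)):
        raise ValueError("class codes must be in 1..15")
    return np.isin(codes, list(INFESTED_CODES))


def codes_for_frame(frame: pd.DataFrame) -> np.ndarray:
    """Class codes for a labelled profile frame."""
    return np.array(
        [
            encode_class(p, f, i)
            for p, f, i in zip(frame["period"], frame["fertilizer"], frame["infested"])
        ]
    )


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def band_columns(frame: pd.DataFrame) -> list[str]:
    """Feature columns: derivative bands (``d<nm>``) when present, else
    reflectance bands (``b<nm>``) for the raw-reflectance mode."""
    deriv = [c for c in frame.columns if c.startswith("d") and c[1].isdigit()]
    if deriv:
        return deriv
    return [c for c in frame.columns if c.startswith("b") and c[1].isdigit()]


_DESIGN_COVARIATES = ("period", "fertilizer")


def _design_matrix(frame: pd.DataFrame, features: list[str], with_covariates: bool) -> np.ndarray:
    X = frame[features].to_numpy(dtype=float)
    if with_covariates:
        # the 33-variable encoding: spectral bands plus numeric period and
        # fertilizer codes as two extra explanatory variables
        period = frame["period"].map({p: i for i, p in enumerate(_sc.PERIODS)})
        fert = frame["fertilizer"].map({f: i for i, f in enumerate(_sc.FERTILIZERS)})
        X = np.column_stack([X, period.to_numpy(float), fert.to_numpy(float)])
    return X


@dataclass
class TrainedModel:
    """Fitted scaler + one-vs-one linear SVM with its class scheme."""

    pipeline: Pipeline | None
    classes: np.ndarray
    feature_names: list[str]
    crop: str = ""
    seed: int | None = None
    with_design_covariates: bool = False
    # manual one-vs-one state used after JSON round-trip
    _pair_coef: np.ndarray | None = field(default=None, repr=False)
    _pair_intercept: np.ndarray | None = field(default=None, repr=False)
    _scaler_mean: np.ndarray | None = field(default=None, repr=False)
    _scaler_scale: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        return len(self.feature_names) + (2 if self.with_design_covariates else 0)


def train(
    frame: pd.DataFrame,
    codes=None,
    features: list[str] | None = None,
    crop: str = "",
    seed: int | None = None,
    C: float = 1.0,
    with_design_covariates: bool = False,
) -> TrainedModel:
    """Fit the 15-class linear SVM on derivative-band features.

    Features are z-scored on the training set.  ``C`` defaults to 1, the
    conventional default of libsvm front-ends.  Deterministic given the data
    (a linear SVC fit involves no random sampling at these problem sizes).
    """
    if codes is None:
        codes = codes_for_frame(frame)
    codes = np.asarray(codes, dtype=int)
    if len(codes) != len(frame):
        raise ValueError("codes length does not match profile count")
    if len(np.unique(codes)) < 2:
        raise ValueError("training data must contain at least two classes")
    if features is None:
        features = band_columns(frame)
    X = _design_matrix(frame, features, with_design_covariates)
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="linear", C=C, decision_function_shape="ovo")),
        ]
    )
    pipe.fit(X, codes)
    return TrainedModel(
        pipeline=pipe,
        classes=pipe.named_steps["svm"].classes_.copy(),
        feature_names=list(features),
        crop=crop,
        seed=seed,
        with_design_covariates=with_design_covariates,
    )


def predict(model: TrainedModel, frame: pd.DataFrame) -> np.ndarray:
    """Predict class codes for profiles; one code per row."""
    if len(frame) == 0:
        return np.array([], dtype=int)
    missing = [f for f in model.feature_names if f not in frame.columns]
    if missing:
        raise ValueError(f"profiles lack model features: {missing[:3]}...")
    X = _design_matrix(frame, model.feature_names, model.with_design_covariates)
    if X.shape[1] != model.n_features:
        raise ValueError("feature dimension mismatch")
    if model.pipeline is not None:
        return model.pipeline.predict(X).astype(int)
    return _predict_manual(model, X)


def _predict_manual(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """One-vs-one voting from stored pairwise hyperplanes.

    Pair ordering follows libsvm: (0,1), (0,2), ..., (1,2), ...  Ties in the
    vote are broken by the summed signed decision values, deterministically.
    """
    Z = (X - model._scaler_mean) / model._scaler_scale
    dec = Z @ model._pair_coef.T + model._pair_intercept
    k = len(model.classes)
    votes = np.zeros((len(X), k))
    score = np.zeros((len(X), k))
    for idx, (i, j) in enumerate(combinations(range(k), 2)):
        pos = dec[:, idx] > 0
        votes[pos, i] += 1
        votes[~pos, j] += 1
        score[:, i] += dec[:, idx]
        score[:, j] -= dec[:, idx]
    # lexicographic: votes first, decision-value sum as tie-break
    order = votes + 1e-9 * np.tanh(score)
    return model.classes[np.argmax(order, axis=1)].astype(int)


# ---------------------------------------------------------------------------
# Serialization — documented JSON sidecar
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    """Write the model as JSON: scaler moments, pairwise hyperplanes, scheme."""
    if model.pipeline is None:
        raise ValueError("model was already deserialized; refit to save")
    svm: SVC = model.pipeline.named_steps["svm"]
    scaler: StandardScaler = model.pipeline.named_steps["scale"]
    doc = {
        "format": "nightscan-linear-svm-ovo/1",
        "crop": model.crop,
        "seed": model.seed,
        "with_design_covariates": model.with_design_covariates,
        "feature_names": model.feature_names,
        "classes": model.classes.tolist(),
        "scaler_mean": scaler.mean_.tolist(),
        "scaler_scale": scaler.scale_.tolist(),
        "pair_coef": svm.coef_.tolist(),
        "pair_intercept": svm.intercept_.tolist(),
        "class_scheme": {str(c): list(decode_class(c)) for c in model.classes},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> TrainedModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "nightscan-linear-svm-ovo/1":
        raise ValueError("unrecognized model file format")
    return TrainedModel(
        pipeline=None,
        classes=np.asarray(doc["classes"], dtype=int),
        feature_names=list(doc["feature_names"]),
        crop=doc.get("crop", ""),
        seed=doc.get("seed"),
        with_design_covariates=bool(doc.get("with_design_covariates", False)),
        _pair_coef=np.asarray(doc["pair_coef"], dtype=float),
        _pair_intercept=np.asarray(doc["pair_intercept"], dtype=float),
        _scaler_mean=np.asarray(doc["scaler_mean"], dtype=float),
        _scaler_scale=np.asarray(doc["scaler_scale"], dtype=float),
    )
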
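"""Two-stage cascade classification of pain states.

Stage 1 is a binary margin classifier separating baseline (no pain) from
pain; stage 2, trained only on pain windows, separates low from high pain.
An input routed to "no pain" by stage 1 is labeled B without consulting
stage 2.  Each stage's SVM margin is calibrated to a probability by a
Platt-style sigmoid fitted on the training margins, and the two calibrated
probabilities define a continuous sensor score

    score = p(pain) * (1 + p(HP | pain))  in [0, 2],

the expected class code under the cascade's probabilities (B=0, LP=1,
HP=2).  Per-modality cascades restricted to one modality's feature group
produce the sensor scores consumed by decision-level fusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .modalities import MODALITY_ORDER, PAIN_LABELS


@dataclass
class CascadeConfig:
    """Hyperparameters for both cascade stages.

    ``gamma="median"`` selects the RBF bandwidth by the median pairwise
    squared-distance heuristic on standardized training features; class
    weights are inverse-frequency because baseline windows are rare (one
    of ~11 per subject-day).
    """

    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "median"
    class_weight: str | dict | None = "balanced"
    seed: int = 0


@dataclass
class _Stage:
    svm: SVC
    platt: LogisticRegression

    def prob(self, X: np.ndarray) -> np.ndarray:
        margin = self.svm.decision_function(X).reshape(-1, 1)
        return self.platt.predict_proba(margin)[:, 1]


@dataclass
class CascadeModel:
    """A fitted two-stage cascade with its standardizer and namespace."""

    scaler: StandardScaler
    stage1: _Stage                 # B (0) vs pain (1)
    stage2: _Stage                 # LP (0) vs HP (1), pain rows only
    feature_names: tuple[str, ...]
    config: CascadeConfig = field(default_factory=CascadeConfig)


def _median_gamma(X: np.ndarray) -> float:
    # subsample deterministically for large n; heuristic only needs scale
    sub = X[:500]
    d2 = pdist(sub, "sqeuclidean")
    med = np.median(d2[d2 > 0]) if np.any(d2 > 0) else 1.0
    return 1.0 / max(med, 1e-12)


def _fit_stage(X: np.ndarray, y: np.ndarray, cfg: CascadeConfig) -> _Stage:
    gamma = _median_gamma(X) if cfg.gamma == "median" else cfg.gamma
    svm = SVC(
        kernel=cfg.kernel, C=cfg.C,
        gamma=gamma if cfg.kernel == "rbf" else "scale",
        class_weight=cfg.class_weight, random_state=cfg.seed,
    )
    svm.fit(X, y)
    margins = svm.decision_function(X).reshape(-1, 1)
    # moderate regularization keeps the sigmoid from becoming a step
    # function when the training margins are separable
    platt = LogisticRegression(C=1.0, max_iter=1000)
    platt.fit(margins, y)
    return _Stage(svm, platt)


def _as_matrix(
    X: pd.DataFrame | np.ndarray, feature_names: tuple[str, ...] | None = None
) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [c for c in feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"missing features: {missing}")
            return X[list(feature_names)].to_numpy(dtype=float), feature_names
        names = tuple(X.columns)
        return X.to_numpy(dtype=float), names
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    names = feature_names or tuple(f"x{i}" for i in range(arr.shape[1]))
    if len(names) != arr.shape[1]:
        raise ValueError("feature count mismatch")
    return arr, names


def train_cascade(
    X: pd.DataFrame | np.ndarray,
    labels,
    config: CascadeConfig | None = None,
) -> CascadeModel:
    """Fit the two-stage cascade on labeled window features.

    All three classes must be present (stage 2 needs both LP and HP rows).
    The standardizer and both stages are fitted on training rows only;
    deterministic given data and config.
    """
    config = config or CascadeConfig()
    Xm, names = _as_matrix(X)
    y = np.asarray(labels, dtype=object)
    if Xm.shape[0] != y.shape[0]:
        raise ValueError("X and labels disagree in length")
    present = set(np.unique(y))
    missing = set(PAIN_LABELS) - present
    if missing:
        raise ValueError(f"training requires all classes; missing {sorted(missing)}")
    for cls in PAIN_LABELS:
        if (y == cls).sum() < 2:
            raise ValueError(f"need >= 2 rows of class {cls}")
    if not np.all(np.isfinite(Xm)):
        raise ValueError("non-finite feature values")

    scaler = StandardScaler().fit(Xm)
    Z = scaler.transform(Xm)
    y_pain = (y != "B").astype(int)
    stage1 = _fit_stage(Z, y_pain, config)
    pain_rows = y_pain == 1
    y_hp = (y[pain_rows] == "HP").astype(int)
    stage2 = _fit_stage(Z[pain_rows], y_hp, config)
    return CascadeModel(scaler, stage1, stage2, names, config)


def predict_probabilities(
    model: CascadeModel, X: pd.DataFrame | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Calibrated (p_pain, p_hp_given_pain) per row."""
    Xm, _ = _as_matrix(X, model.feature_names)
    Z = model.scaler.transform(Xm)
    return model.stage1.prob(Z), model.stage2.prob(Z)


def label_from_probabilities(p_pain: float, p_hp: float) -> str:
    """Cascade routing: stage 1 decides pain/no-pain, stage 2 LP/HP.

    Decision boundaries at 0.5; exact ties break toward the higher-pain
    branch (never under-call pain at the boundary).
    """
    if p_pain < 0.5:
        return "B"
    return "HP" if p_hp >= 0.5 else "LP"


def score_from_probabilities(p_pain, p_hp) -> np.ndarray | float:
    """Expected-class-code sensor score p(pain) * (1 + p(HP|pain))."""
    return p_pain * (1.0 + p_hp)


def predict_label(model: CascadeModel, X) -> np.ndarray:
    """Predicted pain class per row, via the cascade routing rule."""
    p_pain, p_hp = predict_probabilities(model, X)
    out = np.where(p_pain < 0.5, "B", np.where(p_hp >= 0.5, "HP", "LP"))
    return out.astype(object)


def predict_score(model: CascadeModel, X) -> np.ndarray:
    """Continuous sensor score in [0, 2] per row."""
    p_pain, p_hp = predict_probabilities(model, X)
    return np.asarray(score_from_probabilities(p_pain, p_hp), dtype=float)


MODALITY_PREFIX: dict[str, str] = {m: f"{m}." for m in MODALITY_ORDER}


def modality_columns(columns, modality: str) -> list[str]:
    """Feature columns belonging to one modality's namespace."""
    prefix = MODALITY_PREFIX[modality]
    return [c for c in columns if c.startswith(prefix)]


def train_per_modality(
    features: pd.DataFrame,
    labels,
    config: CascadeConfig | None = None,
    modalities=MODALITY_ORDER,
) -> dict[str, CascadeModel]:
    """One cascade per enabled modality, restricted to its namespace."""
    if len(modalities) == 0:
        raise ValueError("at least one modality must be enabled")
    models: dict[str, CascadeModel] = {}
    for m in modalities:
        cols = modality_columns(features.columns, m)
        if not cols:
            raise ValueError(f"no feature columns for modality {m!r}")
        models[m] = train_cascade(features[cols], labels, config)
    return models
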
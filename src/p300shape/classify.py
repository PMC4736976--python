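"""Linear classification of shape-feature vectors and the validation protocol.

Two classifiers are provided over the shape features: SWLDA (stepwise linear
discriminant analysis — the stepwise regression of the calibration stage
refit as a discriminant with a midpoint threshold) and a linear
maximum-margin classifier (SVM), including the leave-one-out protocol that
trains 2U models on a balanced set and picks one at random.

Validation builds a balanced subset from held-out epochs: D = floor(P'/K)
disjoint groups of K P300 trials and D groups of K non-P300 trials per
electrode are averaged, featurized against the calibrated template, and
classified; accuracy psi = (TP+TN)/total is reported per electrode, ranked
best to worst.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.svm import SVC

from .calibration import CalibrationProfile, stepwise_select
from .epochs import NONP300, P300, EpochSet
from .preprocess import coherent_average
from .shcc import chain_distance, encode_chain, normalize_curve, resample_curve, tortuosity
from .shape_features import area_difference_features, assemble_vector

__all__ = [
    "LinearModel",
    "ConfusionCounts",
    "ValidationReport",
    "swlda_train",
    "margin_train",
    "margin_train_loo",
    "accuracy",
    "validate",
    "n_validation_pairs",
]


@dataclass
class LinearModel:
    """Masked linear decision rule: P300 iff w . v[mask] + b >= 0."""

    feature_mask: np.ndarray
    weights: np.ndarray
    intercept: float

    def __post_init__(self) -> None:
        self.feature_mask = np.asarray(self.feature_mask, dtype=bool)
        self.weights = np.asarray(self.weights, dtype=float)
        if int(self.feature_mask.sum()) != self.weights.size:
            raise ValueError(
                f"mask selects {int(self.feature_mask.sum())} features, "
                f"{self.weights.size} weights given"
            )

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X[:, self.feature_mask] @ self.weights + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_values(X) >= 0, P300, NONP300).astype(object)


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN with P300 as the positive class."""

    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[str], y_pred: Sequence[str]
    ) -> "ConfusionCounts":
        c = cls()
        for t, p in zip(y_true, y_pred, strict=True):
            if t == P300:
                c.TP += p == P300
                c.FN += p != P300
            else:
                c.TN += p == NONP300
                c.FP += p != NONP300
        return c


def accuracy(counts: ConfusionCounts) -> float:
    """psi = (TP + TN) / (TP + FP + FN + TN)."""
    if counts.total <= 0:
        raise ValueError("confusion counts are empty")
    return (counts.TP + counts.TN) / counts.total


def _as_signed(y: Sequence) -> np.ndarray:
    arr = np.asarray(y, dtype=object)
    if set(map(str, arr)) <= {P300, NONP300}:
        return np.where(arr == P300, 1.0, -1.0)
    return np.asarray(y, dtype=float)


def swlda_train(
    X: np.ndarray, y: Sequence, p_enter: float = 0.1, p_remove: float = 0.15
) -> LinearModel:
    """Stepwise-selected least-squares discriminant.

    Labels are coded +1 (P300) / -1 (non-P300); the decision threshold sits
    at the midpoint of the projected class-mean scores.
    """
    ys = _as_signed(y)
    if np.unique(ys).size < 2:
        raise ValueError("training data must contain both classes")
    sw = stepwise_select(np.asarray(X, dtype=float), ys, p_enter, p_remove)
    scores = np.asarray(X, dtype=float)[:, sw.mask] @ sw.weights + sw.intercept
    midpoint = 0.5 * (scores[ys > 0].mean() + scores[ys < 0].mean())
    return LinearModel(sw.mask, sw.weights, sw.intercept - midpoint)


def margin_train(X: np.ndarray, y: Sequence, regularization: float = 1.0) -> LinearModel:
    """Linear maximum-margin (SVM) classifier over all features."""
    ys = _as_signed(y)
    if np.unique(ys).size < 2:
        raise ValueError("training data must contain both classes")
    X = np.asarray(X, dtype=float)
    svc = SVC(kernel="linear", C=regularization)
    svc.fit(X, ys)
    mask = np.ones(X.shape[1], dtype=bool)
    return LinearModel(mask, svc.coef_.ravel(), float(svc.intercept_[0]))


def margin_train_loo(
    X: np.ndarray,
    y: Sequence,
    regularization: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[list[LinearModel], int]:
    """Leave-one-out margin training on a balanced set.

    Fits one model per left-out example (2U models on a 2U-example set) and
    returns them with the index of one model selected uniformly at random
    under *seed*, mirroring a random pick among the cross-validated SVMs.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    ys = _as_signed(y)
    models = []
    for i in range(n):
        keep = np.arange(n) != i
        models.append(margin_train(X[keep], ys[keep], regularization))
    rng = np.random.default_rng(seed)
    return models, int(rng.integers(n))


# ---------------------------------------------------------------------------
# Validation protocol


def n_validation_pairs(n_p300_valid: int, k: int) -> int:
    """Balanced validation groups D = floor(P' / K)."""
    return n_p300_valid // k


def _featurize_groups(
    profile: CalibrationProfile,
    electrode_set: EpochSet,
    electrode: str,
    groups: list[np.ndarray],
) -> np.ndarray:
    ep = profile.per_electrode[electrode]
    S = profile.segments
    t_norm = normalize_curve(resample_curve(ep.template_curve, S))
    rows = []
    for g in groups:
        curve = coherent_average(electrode_set, indices=g)
        chain = encode_chain(curve, S, profile.codec_mode)
        c_norm = normalize_curve(resample_curve(curve, S))
        diffs, dsum = area_difference_features(t_norm, c_norm)
        d = chain_distance(ep.template_chain, chain)
        rows.append(assemble_vector(diffs, dsum, d, tortuosity(chain), chain).to_array())
    return np.array(rows)


def _balanced_groups(
    epochs: EpochSet, k: int, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray], int]:
    """D disjoint K-trial groups per class from a labeled epoch set."""
    p_idx = epochs.label_indices(P300)
    n_idx = epochs.label_indices(NONP300)
    D = n_validation_pairs(p_idx.size, k)
    if D < 1 or n_idx.size < D * k:
        raise ValueError(
            f"validation set too small: {p_idx.size} P300 / {n_idx.size} "
            f"non-P300 trials for K={k}"
        )
    p_perm = rng.permutation(p_idx)
    n_perm = rng.permutation(n_idx)
    groups_p = [p_perm[i * k : (i + 1) * k] for i in range(D)]
    groups_n = [n_perm[i * k : (i + 1) * k] for i in range(D)]
    return groups_p, groups_n, D


@dataclass
class ValidationReport:
    """Per-electrode accuracy and confusion counts, ranked best to worst."""

    psi: dict[str, float]
    counts: dict[str, ConfusionCounts]
    ranking: list[str]
    stimulations: int
    pairs: int

    def to_text(self) -> str:
        lines = [
            "# validation report",
            f"stimulations: {self.stimulations}",
            f"balanced_pairs: {self.pairs}",
            "rank electrode psi TP TN FP FN",
        ]
        for r, name in enumerate(self.ranking, start=1):
            c = self.counts[name]
            lines.append(
                f"{r} {name} {self.psi[name]:.4f} {c.TP} {c.TN} {c.FP} {c.FN}"
            )
        return "\n".join(lines) + "\n"

    def save_text(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text(), encoding="utf-8")


def validate(
    profile: CalibrationProfile,
    validation: EpochSet,
    stimulations: int | None = None,
    seed: int | np.random.SeedSequence = 0,
    models: dict[str, LinearModel] | None = None,
    mode: str = "per_electrode",
    model_trainer: Callable[[np.ndarray, Sequence], LinearModel] | None = None,
    training: EpochSet | None = None,
) -> ValidationReport:
    """Score the calibrated profile on held-out epochs.

    For every selected electrode, D = floor(P'/K) averaged P300 and D
    averaged non-P300 feature vectors are built against the profile's
    template and classified. By default each electrode's stepwise model from
    calibration (weights, intercept, zero threshold on the +1/-1 coding)
    does the classification; alternatively pass *models* per electrode, or a
    *model_trainer* (e.g. :func:`swlda_train` or :func:`margin_train`)
    together with *training* epochs to refit on a balanced training subset.

    ``mode="concat"`` concatenates the per-electrode feature vectors into a
    single vector over all profile electrodes before classification, in
    which case a trainer (or a model under the key ``"__concat__"``) is
    required; the report then carries one entry named ``"all"``.
    """
    if not profile.per_electrode:
        raise ValueError("profile selected no electrodes; nothing to validate")
    k = stimulations or profile.optimum_stimulations
    rng = np.random.default_rng(seed)
    groups_p, groups_n, D = _balanced_groups(validation, k, rng)
    per_X: dict[str, np.ndarray] = {}
    for name in profile.electrodes:
        ec = validation.select_electrode(name)
        Xp = _featurize_groups(profile, ec, name, groups_p)
        Xn = _featurize_groups(profile, ec, name, groups_n)
        per_X[name] = np.vstack([Xp, Xn])
    y_true = np.array([P300] * D + [NONP300] * D, dtype=object)

    def trained(name: str, X_val: np.ndarray) -> LinearModel:
        if models is not None and name in models:
            return models[name]
        if model_trainer is not None:
            if training is None:
                raise ValueError("model_trainer requires training epochs")
            Xt, yt = _training_features(profile, training, k, rng, name)
            return model_trainer(Xt, yt)
        if name == "__concat__":
            raise ValueError("concat mode needs explicit models or a model_trainer")
        ep = profile.per_electrode[name]
        return LinearModel(ep.feature_mask, ep.weights, ep.intercept)

    psi: dict[str, float] = {}
    counts: dict[str, ConfusionCounts] = {}
    if mode == "concat":
        X = np.hstack([per_X[n] for n in profile.electrodes])
        model = trained("__concat__", X)
        cc = ConfusionCounts.from_predictions(y_true, model.predict(X))
        counts["all"] = cc
        psi["all"] = accuracy(cc)
    elif mode == "per_electrode":
        for name in profile.electrodes:
            model = trained(name, per_X[name])
            cc = ConfusionCounts.from_predictions(y_true, model.predict(per_X[name]))
            counts[name] = cc
            psi[name] = accuracy(cc)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ranking = sorted(psi, key=lambda n: (-psi[n], n))
    return ValidationReport(psi, counts, ranking, k, D)


def _training_features(
    profile: CalibrationProfile,
    training: EpochSet,
    k: int,
    rng: np.random.Generator,
    name: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced averaged training features for one electrode (or all, concat)."""
    groups_p, groups_n, _ = _balanced_groups(training, k, rng)

    def one(n: str) -> np.ndarray:
        ec = training.select_electrode(n)
        return np.vstack(
            [
                _featurize_groups(profile, ec, n, groups_p),
                _featurize_groups(profile, ec, n, groups_n),
            ]
        )

    if name == "__concat__":
        X = np.hstack([one(n) for n in profile.electrodes])
    else:
        X = one(name)
    D = len(groups_p)
    y = np.array([P300] * D + [NONP300] * D, dtype=object)
    return X, y
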
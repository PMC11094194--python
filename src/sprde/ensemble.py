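"""AdaBoost ensemble of weighted RBF-kernel SVM weak learners.

Each boosting round fits an SVM on the current sample-weight distribution
(weights enter the SVM objective directly, not via resampling), measures
the weighted 0-1 error

    eps_t = sum of w_i over misclassified samples,

assigns the learner weight a_t = 1/2 * ln((1 - eps_t) / eps_t) and
reweights samples by w_i <- w_i * exp(-a_t * y_i * xi_t(x_i)) / C_t with
C_t normalizing the weights back onto the simplex.  The strong classifier
is H(x) = sign(sum_t a_t * xi_t(x)), with an exact zero vote resolved to
+1 (supine).

A round whose error reaches 0.5 is rejected: such a learner cannot carry
positive weight.  Its kernel width is jittered (+/-20%, seeded) and the
fit retried a few times before boosting stops with the learners accepted
so far.  Training also stops early once the partial ensemble's training
0-1 error hits zero.  eps_t is floored at 1e-10 so a perfect learner
still gets a finite weight.

Models serialize to a plain JSON container (support vectors, dual
coefficients, intercepts, kernel widths, learner weights) so a stored
ensemble predicts identically regardless of library version.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

EPS_FLOOR = 1e-10

#: Tie vote resolves to supine.
TIE_LABEL = 1


class TrainingFailureError(RuntimeError):
    """No weak learner could beat chance on the training distribution."""


@dataclass
class TrainingSet:
    """Feature matrix, +/-1 labels and a simplex weight vector."""

    X: np.ndarray
    y: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int).ravel()
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError(f"X is {self.X.shape}, y has {self.y.size} labels")
        if self.y.size < 2 or len(np.unique(self.y)) < 2:
            raise ValueError("need at least two samples and both classes present")
        if not np.isin(self.y, (-1, 1)).all():
            raise ValueError("labels must be +1 (supine) or -1 (lateral)")
        if self.weights is None:
            self.weights = np.full(self.y.size, 1.0 / self.y.size)
        else:
            self.weights = np.asarray(self.weights, dtype=float).ravel()
            if self.weights.size != self.y.size or (self.weights < 0).any():
                raise ValueError("weights must be non-negative, one per sample")
            if abs(self.weights.sum() - 1.0) > 1e-12:
                raise ValueError("weights must sum to 1")


@dataclass
class BoostConfig:
    """Ensemble hyperparameters.

    ``gamma=None`` means the data-driven default 1 / (n_features * var(X)).
    Rejected rounds retry with the kernel width jittered by +/- ``jitter``
    (relative), drawn from a generator seeded with ``seed``.
    """

    T_iters: int = 50
    C: float = 1.0
    gamma: float | None = None
    max_retries: int = 3
    jitter: float = 0.2
    seed: int = 0


@dataclass
class WeakLearner:
    """One RBF-SVM vote, stored as explicit kernel-expansion arrays."""

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    C: float
    alpha: float = 0.0     # learner weight a_t
    eps: float = 0.0       # weighted training error eps_t

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        sq = (
            (X ** 2).sum(axis=1)[:, None]
            - 2.0 * X @ self.support_vectors.T
            + (self.support_vectors ** 2).sum(axis=1)[None, :]
        )
        K = np.exp(-self.gamma * np.clip(sq, 0.0, None))
        return K @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision(X)
        return np.where(d >= 0, 1, -1)


@dataclass
class EnsembleModel:
    """Ordered weak learners plus the per-round training trace."""

    learners: list[WeakLearner] = field(default_factory=list)
    config: BoostConfig = field(default_factory=BoostConfig)
    trace: list[dict] = field(default_factory=list)

    def decision(self, X: np.ndarray) -> np.ndarray:
        if not self.learners:
            raise ValueError("empty ensemble: train or load a model first")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        score = np.zeros(X.shape[0])
        for learner in self.learners:
            score += learner.alpha * learner.predict(X)
        return score

    def staged_decision(self, X: np.ndarray) -> np.ndarray:
        """Cumulative vote after each round; shape (T, n_samples)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        score = np.zeros(X.shape[0])
        stages = []
        for learner in self.learners:
            score = score + learner.alpha * learner.predict(X)
            stages.append(score.copy())
        return np.asarray(stages)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "format": "sprde-ensemble-v1",
            "config": {
                "T_iters": self.config.T_iters,
                "C": self.config.C,
                "gamma": self.config.gamma,
                "max_retries": self.config.max_retries,
                "jitter": self.config.jitter,
                "seed": self.config.seed,
            },
            "trace": self.trace,
            "learners": [
                {
                    "support_vectors": l.support_vectors.tolist(),
                    "dual_coef": l.dual_coef.tolist(),
                    "intercept": l.intercept,
                    "gamma": l.gamma,
                    "C": l.C,
                    "alpha": l.alpha,
                    "eps": l.eps,
                }
                for l in self.learners
            ],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EnsembleModel":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                        and Path(source).exists()):
            source = Path(source).read_text()
        payload = json.loads(source)
        if payload.get("format") != "sprde-ensemble-v1":
            raise ValueError("not a recognized ensemble container")
        config = BoostConfig(**payload["config"])
        learners = [
            WeakLearner(
                support_vectors=np.asarray(rec["support_vectors"], dtype=float),
                dual_coef=np.asarray(rec["dual_coef"], dtype=float),
                intercept=float(rec["intercept"]),
                gamma=float(rec["gamma"]),
                C=float(rec["C"]),
                alpha=float(rec["alpha"]),
                eps=float(rec["eps"]),
            )
            for rec in payload["learners"]
        ]
        return cls(learners=learners, config=config, trace=payload["trace"])


def learner_weight(eps: float) -> float:
    """Learner weight a = 1/2 * ln((1 - eps) / eps), with eps floored at 1e-10.

    Raises ``ValueError`` for eps >= 0.5: such a learner must be rejected
    by the caller rather than weighted.
    """
    if eps >= 0.5:
        raise ValueError(f"weak learner at or below chance (eps={eps}); reject it")
    eps = max(float(eps), EPS_FLOOR)
    return 0.5 * float(np.log((1.0 - eps) / eps))


def weighted_error(predictions: np.ndarray, training_set: TrainingSet) -> float:
    """Weighted 0-1 error: total weight on misclassified samples."""
    predictions = np.asarray(predictions, dtype=int).ravel()
    mis = predictions != training_set.y
    return float(training_set.weights[mis].sum())


def update_weights(training_set: TrainingSet, predictions: np.ndarray,
                   alpha: float) -> np.ndarray:
    """Reweight samples by exp(-a * y * xi(x)) and renormalize to the simplex."""
    predictions = np.asarray(predictions, dtype=float).ravel()
    w = training_set.weights * np.exp(-alpha * training_set.y * predictions)
    return w / w.sum()


def _fit_weak(X: np.ndarray, y: np.ndarray, weights: np.ndarray,
              C: float, gamma: float) -> WeakLearner:
    svc = SVC(kernel="rbf", C=C, gamma=gamma)
    # scale weights so their mean is 1: keeps the effective C comparable
    svc.fit(X, y, sample_weight=weights * weights.size)
    return WeakLearner(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        gamma=gamma,
        C=C,
    )


def default_gamma(X: np.ndarray) -> float:
    """Kernel width 1 / (n_features * var(X)), the usual RBF scaling."""
    X = np.asarray(X, dtype=float)
    var = X.var()
    if var <= 0:
        raise ValueError("feature matrix has zero variance; cannot scale the kernel")
    return 1.0 / (X.shape[1] * var)


def train(training_set: TrainingSet, config: BoostConfig | None = None) -> EnsembleModel:
    """Boost RBF-SVM weak learners on the SE feature set.

    Runs up to ``config.T_iters`` rounds; rejects rounds with eps >= 0.5
    (retrying with jittered kernel width up to ``max_retries`` times, then
    stopping), and stops early when the ensemble's training error is zero.

    Raises :class:`TrainingFailureError` if no learner is ever accepted.
    """
    config = config or BoostConfig()
    X, y = training_set.X, training_set.y
    base_gamma = config.gamma if config.gamma is not None else default_gamma(X)
    rng = np.random.default_rng(config.seed)
    weights = training_set.weights.copy()
    model = EnsembleModel(config=config)
    running_score = np.zeros(y.size)
    for t in range(config.T_iters):
        current = TrainingSet(X, y, weights)
        accepted = None
        gamma_t = base_gamma
        for attempt in range(config.max_retries + 1):
            learner = _fit_weak(X, y, weights, config.C, gamma_t)
            predictions = learner.predict(X)
            eps = weighted_error(predictions, current)
            if eps < 0.5:
                accepted = (learner, predictions, eps)
                break
            gamma_t = base_gamma * (1.0 + config.jitter * rng.uniform(-1.0, 1.0))
        if accepted is None:
            break
        learner, predictions, eps = accepted
        learner.eps = eps
        learner.alpha = learner_weight(eps)
        weights = update_weights(current, predictions, learner.alpha)
        model.learners.append(learner)
        running_score += learner.alpha * predictions
        ensemble_pred = np.where(running_score >= 0, 1, -1)
        train_err = float((ensemble_pred != y).mean())
        model.trace.append({"round": t + 1, "eps": eps, "alpha": learner.alpha,
                            "train_error": train_err})
        if train_err == 0.0:
            break
    if not model.learners:
        raise TrainingFailureError("no weak learner beat chance on this training set")
    return model


def predict(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Strong-classifier labels: sign of the weighted vote, 0 -> +1 (supine)."""
    score = model.decision(X)
    return np.where(score >= 0, TIE_LABEL, -TIE_LABEL)
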
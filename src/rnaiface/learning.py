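"""Interface classifiers: NB, RF100, SVML, SVMRBF and the SVMRBF+RF100 consensus.

The central object is :class:`InterfaceClassifier`, a scikit-learn style
estimator over the 500-feature window encodings.  The ``"consensus"``
algorithm trains an RBF-kernel SVM and a 100-tree random forest on the same
data and predicts the elementwise arithmetic mean of their interface
probabilities — a cheap ensemble that recovers the accuracy lost when PSSM
profiles are generated against a heavily subsampled reference database.

SVM probabilities come from the standard sigmoid (Platt) calibration as
implemented by the underlying library.  Default hyperparameters: C = 1.0 and
RBF gamma = 1 / n_features (the feature values already live in (0, 1), so no
further scaling is applied).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .encoding import LabeledDataset

ALGORITHMS = ("NB", "RF100", "SVML", "SVMRBF", "CONSENSUS")
MODEL_FORMAT_VERSION = 1

__all__ = [
    "ALGORITHMS",
    "ModelSpec",
    "InterfaceClassifier",
    "train",
    "predict_proba",
    "consensus_predict",
    "classify",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a classifier configuration."""

    algorithm: str = "CONSENSUS"
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm.upper() not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )


class InterfaceClassifier(ClassifierMixin, BaseEstimator):
    """Per-residue interface probability estimator.

    Parameters
    ----------
    algorithm:
        One of ``NB`` (Gaussian naive Bayes), ``RF100`` (random forest),
        ``SVML`` (linear-kernel SVM), ``SVMRBF`` (RBF-kernel SVM) or
        ``CONSENSUS`` (mean of SVMRBF and RF100 probabilities).
    n_trees:
        Forest size for RF100 / the consensus member (default 100).
    C, gamma:
        SVM regularization and RBF width; ``gamma=None`` means
        ``1 / n_features``.
    threshold:
        Probability cutoff used by :meth:`predict`; ties go to the positive
        class (``p >= threshold`` predicts interface).
    random_state:
        Seed controlling forest bootstrap and SVM probability calibration;
        fits are reproducible given the same data and seed.
    """

    def __init__(
        self,
        algorithm: str = "CONSENSUS",
        n_trees: int = 100,
        C: float = 1.0,
        gamma: float | None = None,
        threshold: float = 0.5,
        random_state: int | None = 0,
    ) -> None:
        self.algorithm = algorithm
        self.n_trees = n_trees
        self.C = C
        self.gamma = gamma
        self.threshold = threshold
        self.random_state = random_state

    def _build_member(self, name: str):
        gamma = self.gamma if self.gamma is not None else "auto"  # auto = 1/n_features
        if name == "NB":
            return GaussianNB()
        if name == "RF100":
            return RandomForestClassifier(
                n_estimators=self.n_trees, random_state=self.random_state
            )
        if name in ("SVML", "SVMRBF"):
            svc = SVC(
                kernel="linear" if name == "SVML" else "rbf",
                C=self.C,
                gamma="scale" if name == "SVML" else gamma,
                random_state=self.random_state,
            )
            # sigmoid (Platt) calibration provides the probability outputs
            return CalibratedClassifierCV(svc, method="sigmoid", ensemble=False)
        raise ValueError(f"unknown member {name!r}")

    def fit(self, X, y) -> "InterfaceClassifier":
        X, y = check_X_y(X, y)
        if X.shape[1] == 0:
            raise ValueError("training data has zero feature width")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain both classes")
        algorithm = self.algorithm.upper()
        if algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if algorithm == "CONSENSUS":
            self.members_ = {
                name: self._build_member(name).fit(X, y) for name in ("SVMRBF", "RF100")
            }
        else:
            self.members_ = {algorithm: self._build_member(algorithm).fit(X, y)}
        self.n_features_in_ = X.shape[1]
        return self

    @property
    def feature_width(self) -> int:
        check_is_fitted(self)
        return int(self.n_features_in_)

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature width {X.shape[1]} does not match the fitted width "
                f"{self.n_features_in_}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities, columns ordered as ``classes_``."""
        X = self._check_X(X)
        probs = [m.predict_proba(X) for m in self.members_.values()]
        return np.mean(probs, axis=0)

    def predict_interface_proba(self, X) -> np.ndarray:
        """Probability of the positive (interface) class per row."""
        return self.predict_proba(X)[:, list(self.classes_).index(1)]

    def predict(self, X) -> np.ndarray:
        return classify(self.predict_interface_proba(X), self.threshold)


def train(dataset: LabeledDataset, spec: ModelSpec) -> InterfaceClassifier:
    """Fit an :class:`InterfaceClassifier` described by ``spec`` on a dataset."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    params = dict(spec.hyperparams)
    model = InterfaceClassifier(
        algorithm=spec.algorithm.upper(), random_state=spec.seed, **params
    )
    return model.fit(dataset.vectors, dataset.labels)


def predict_proba(model, vectors) -> np.ndarray:
    """Per-row interface probability in [0, 1].

    Accepts an :class:`InterfaceClassifier` or any fitted probabilistic
    classifier exposing ``predict_proba`` and ``classes_``.
    """
    if isinstance(model, InterfaceClassifier):
        return model.predict_interface_proba(vectors)
    positive_col = list(model.classes_).index(1)
    return model.predict_proba(vectors)[:, positive_col]


def consensus_predict(member_models: dict, vectors) -> np.ndarray:
    """Elementwise mean of the SVMRBF and RF100 member probabilities.

    ``member_models`` must contain exactly the keys ``"SVMRBF"`` and
    ``"RF100"``, each a fitted estimator with matching feature width.
    """
    required = {"SVMRBF", "RF100"}
    if set(member_models) != required:
        missing = required - set(member_models)
        raise ValueError(f"consensus requires members {sorted(required)}; missing {sorted(missing)}")
    probs = [predict_proba(member_models[name], vectors) for name in ("SVMRBF", "RF100")]
    return np.mean(probs, axis=0)


def classify(probabilities, threshold: float = 0.5) -> np.ndarray:
    """Binarize probabilities: label 1 iff probability >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    probabilities = np.asarray(probabilities, dtype=float)
    if ((probabilities < 0) | (probabilities > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return (probabilities >= threshold).astype(int)


def save_model(model: InterfaceClassifier, path: str) -> None:
    check_is_fitted(model)
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "params": model.get_params(),
            "model": model,
        },
        path,
    )


def load_model(path: str) -> InterfaceClassifier:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {payload.get('format_version')!r}"
        )
    return payload["model"]


def clone_spec(model: InterfaceClassifier) -> InterfaceClassifier:
    """Unfitted copy with identical hyperparameters (sklearn ``clone``)."""
    return clone(model)
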
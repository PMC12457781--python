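"""Reference classifiers for the model comparison: SVM, random forest, and
a standalone LSTM (same topology as the main classifier, no autoencoder).

SVM and random forest are classical per-window classifiers and consume a
fixed-length featureization of each window: either the flattened Lw*D
vector or per-channel summary statistics (mean, s.d., min, max). The plain
LSTM consumes the raw normalized windows directly. All models are trained
and evaluated on byte-identical window sets so accuracy differences are
attributable to the model alone.

No hyperparameters are claimed from prior work; defaults are conventional
(RBF-kernel SVM with C=1, 200-tree unrestricted random forest) and fully
configurable through :class:`BaselineSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from . import classifier as _clf
from .classifier import TrainConfig
from .preprocess import WindowSet

__all__ = ["BaselineSpec", "FittedBaseline", "train_baseline", "predict_baseline"]

KINDS = ("svm", "rf", "lstm_plain")
FEATURIZATIONS = ("flatten", "summary_stats")


@dataclass
class BaselineSpec:
    """Which baseline to fit and how windows are featurized for it."""

    kind: str
    featureization: str = "flatten"
    params: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown baseline kind {self.kind!r}; expected one of {KINDS}")
        if self.featureization not in FEATURIZATIONS:
            raise ValueError(
                f"unknown featureization {self.featureization!r}; expected one of {FEATURIZATIONS}"
            )


@dataclass
class FittedBaseline:
    spec: BaselineSpec
    model: object
    Lw: int
    D: int


def _featurize(windows: WindowSet, how: str) -> np.ndarray:
    x = windows.windows.astype(np.float64)
    if how == "flatten":
        return x.reshape(len(windows), -1)
    # summary_stats: per-channel mean/sd/min/max -> 4*D features
    return np.concatenate(
        [x.mean(axis=1), x.std(axis=1), x.min(axis=1), x.max(axis=1)], axis=1
    )


def train_baseline(windows: WindowSet, spec: BaselineSpec) -> FittedBaseline:
    """Fit one baseline classifier on labeled windows.

    ``svm``/``rf`` see the featurized windows; ``lstm_plain`` trains the
    standard 2-layer/50-unit LSTM on the raw normalized windows with no
    autoencoder front end. Random forest and LSTM runs are seeded.
    """
    if len(windows) < 2 or np.unique(windows.labels).size < 2:
        raise ValueError("baseline training needs labeled windows from >= 2 classes")
    if spec.kind == "svm":
        model = SVC(kernel=spec.params.get("kernel", "rbf"), C=spec.params.get("C", 1.0))
        model.fit(_featurize(windows, spec.featureization), windows.labels)
    elif spec.kind == "rf":
        model = RandomForestClassifier(
            n_estimators=spec.params.get("n_estimators", 200),
            max_depth=spec.params.get("max_depth", None),
            random_state=spec.rng_seed,
            n_jobs=1,
        )
        model.fit(_featurize(windows, spec.featureization), windows.labels)
    else:  # lstm_plain
        cfg = TrainConfig(
            epochs=spec.params.get("epochs", 100),
            lr_classifier=spec.params.get("lr", 5e-5),
            batch_size=spec.params.get("batch_size", 64),
            rng_seed=spec.rng_seed,
        )
        params, _ = _clf.train(windows, cfg)
        model = params
    return FittedBaseline(spec=spec, model=model, Lw=windows.Lw, D=windows.D)


def predict_baseline(fitted: FittedBaseline, windows: WindowSet) -> np.ndarray:
    """Deterministic phase labels for new windows from a fitted baseline."""
    if windows.Lw != fitted.Lw or windows.D != fitted.D:
        raise ValueError(
            f"window shape (Lw={windows.Lw}, D={windows.D}) does not match the "
            f"fitted model (Lw={fitted.Lw}, D={fitted.D})"
        )
    if fitted.spec.kind == "lstm_plain":
        return _clf.predict(windows, fitted.model)
    return np.asarray(fitted.model.predict(_featurize(windows, fitted.spec.featureization)), dtype=np.int64)
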
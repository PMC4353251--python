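"""Normalization, fold construction, and the four classifier families.

The training protocol mirrors a fixed-pattern, session-transfer classifier:
z-score normalization is fitted on the learning set only and re-used verbatim
on every test set; folds subsample 90% of the learning session with exact
class balance; the four families are pooled-covariance LDA, soft-margin SVMs
with linear and RBF kernels (hyperparameters tuned by Nelder-Mead simplex on
an inner cross-validation), and a single-hidden-layer sigmoidal network
trained by backpropagation with early stopping at minimum validation RMSE.

Labels are integers: 0 = low workload, 1 = high workload (the positive
class). Decision-boundary ties resolve to low workload.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import minimize
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

LOW, HIGH = 0, 1
KINDS = ("LDA", "SVM-LIN", "SVM-RBF", "ANN")
_EPS_SD = 1e-12


@dataclass
class NormalizationModel:
    """Per-feature mean/sd fitted on a learning set; provenance records which
    session (or other source) supplied that set."""

    mean: np.ndarray
    sd: np.ndarray
    fitted_on: str = "unspecified"
    n_constant_features: int = 0


def zscore_fit(learning: np.ndarray, fitted_on: str = "unspecified") -> NormalizationModel:
    """Fit per-feature z-score statistics on the learning matrix.

    Constant features get sd substituted by 1 (epsilon rule), which maps them
    to all-zero columns after centering.
    """
    x = np.asarray(learning, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("learning matrix must be 2-D with at least 2 rows")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    constant = sd <= _EPS_SD
    sd = np.where(constant, 1.0, sd)
    return NormalizationModel(
        mean=mean, sd=sd, fitted_on=fitted_on, n_constant_features=int(constant.sum())
    )


def zscore_apply(model: NormalizationModel, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[1] != len(model.mean):
        raise ValueError("column count does not match the fitted model")
    return (x - model.mean) / model.sd


@dataclass
class FoldSpec:
    k: int = 10
    learn_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0.0 < self.learn_fraction < 1.0:
            raise ValueError("learn_fraction must lie in (0, 1)")


def make_folds(y: np.ndarray, spec: FoldSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """k class-balanced (learning, nested-test) index pairs.

    Each fold subsamples round(learn_fraction * n_c) indices per class without
    replacement; the nested test set is the complement. Folds differ by the
    seeded random stream, not by a partition.
    """
    y = np.asarray(y)
    n = len(y)
    if n < 20:
        raise ValueError("need at least 20 samples to build folds")
    classes = np.unique(y)
    rng = np.random.default_rng(spec.seed)
    folds = []
    for _ in range(spec.k):
        learn_idx = []
        for c in classes:
            idx_c = np.flatnonzero(y == c)
            n_learn = int(round(spec.learn_fraction * len(idx_c)))
            if n_learn < 1 or n_learn >= len(idx_c):
                raise ValueError("class too small for the requested learn fraction")
            learn_idx.append(rng.choice(idx_c, size=n_learn, replace=False))
        learn = np.sort(np.concatenate(learn_idx))
        test = np.setdiff1d(np.arange(n), learn)
        folds.append((learn, test))
    return folds


# ---------------------------------------------------------------------------
# Classifier configs


@dataclass
class SVMConfig:
    tune: bool = True
    inner_folds: int = 5
    max_tune_iter: int = 50
    cost0: float = 1.0
    gamma0: float | None = None  # RBF kernel coefficient start; None = 1/n_features


@dataclass
class ANNConfig:
    hidden_units: int = 20
    learning_rate: float = 0.01
    max_epochs: int = 500
    batch_size: int = 32
    momentum: float = 0.9
    validation_fraction: float = 0.33


@dataclass
class ClassifierConfig:
    svm: SVMConfig = field(default_factory=SVMConfig)
    ann: ANNConfig = field(default_factory=ANNConfig)


# ---------------------------------------------------------------------------
# ANN: 37-input / one sigmoidal hidden layer / 2 sigmoidal outputs, trained by
# mini-batch backpropagation on squared error with early stopping at minimum
# validation RMSE. Output node 0 codes low workload, node 1 high workload;
# prediction is the larger output, ties to low.


class SigmoidNetwork:
    def __init__(self, n_in: int, config: ANNConfig, seed: int):
        self.config = config
        rng = np.random.default_rng(seed)
        h = config.hidden_units
        self.w1 = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, h))
        self.b1 = np.zeros(h)
        self.w2 = rng.normal(0.0, 1.0 / np.sqrt(h), size=(h, 2))
        self.b2 = np.zeros(2)
        self._rng = rng

    @staticmethod
    def _sigmoid(z: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = self._sigmoid(x @ self.w1 + self.b1)
        o = self._sigmoid(h @ self.w2 + self.b2)
        return h, o

    def fit(self, x: np.ndarray, y: np.ndarray) -> "SigmoidNetwork":
        cfg = self.config
        n = len(x)
        rng = self._rng
        # stratified validation split
        val_idx = []
        for c in (LOW, HIGH):
            idx_c = np.flatnonzero(y == c)
            n_val = max(1, int(round(cfg.validation_fraction * len(idx_c))))
            val_idx.append(rng.choice(idx_c, size=n_val, replace=False))
        val = np.sort(np.concatenate(val_idx))
        train = np.setdiff1d(np.arange(n), val)
        xt, yt = x[train], y[train]
        xv, yv = x[val], y[val]
        tt = np.eye(2)[yt]
        tv = np.eye(2)[yv]

        vel = [np.zeros_like(p) for p in (self.w1, self.b1, self.w2, self.b2)]
        best = None
        best_rmse = np.inf
        lr, mom = cfg.learning_rate, cfg.momentum
        for _ in range(cfg.max_epochs):
            order = rng.permutation(len(xt))
            for start in range(0, len(xt), cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                xb, tb = xt[sel], tt[sel]
                h, o = self.forward(xb)
                delta_o = (o - tb) * o * (1.0 - o)
                delta_h = (delta_o @ self.w2.T) * h * (1.0 - h)
                grads = (
                    xb.T @ delta_h / len(xb),
                    delta_h.mean(axis=0),
                    h.T @ delta_o / len(xb),
                    delta_o.mean(axis=0),
                )
                params = (self.w1, self.b1, self.w2, self.b2)
                for p, g, v in zip(params, grads, vel):
                    v *= mom
                    v -= lr * g
                    p += v
            _, ov = self.forward(xv)
            rmse = float(np.sqrt(np.mean((ov - tv) ** 2)))
            if rmse < best_rmse:
                best_rmse = rmse
                best = tuple(p.copy() for p in (self.w1, self.b1, self.w2, self.b2))
        if best is not None:
            self.w1, self.b1, self.w2, self.b2 = best
        self.validation_rmse = best_rmse
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        _, o = self.forward(x)
        return (o[:, HIGH] > o[:, LOW]).astype(int)

    def input_gradients(self, x: np.ndarray) -> np.ndarray:
        """d(output)/d(input) per sample: (n, n_in, 2)."""
        h, o = self.forward(x)
        do = (o * (1.0 - o))[:, None, :] * self.w2[None, :, :]  # (n, h, 2)
        dh = (h * (1.0 - h))[:, :, None] * do  # (n, h, 2)
        return np.einsum("ih,nho->nio", self.w1, dh)


# ---------------------------------------------------------------------------


@dataclass
class TrainedClassifier:
    """A fitted binary workload classifier of one of the four kinds."""

    kind: str
    model: object
    normalization: NormalizationModel | None = None
    hyperparameters: dict = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "kind": self.kind,
            "hyperparameters": {k: float(v) for k, v in self.hyperparameters.items()},
            "normalization_fitted_on": (
                self.normalization.fitted_on if self.normalization else None
            ),
        }
        if self.kind == "ANN":
            net: SigmoidNetwork = self.model
            doc["weights"] = {
                "w1": net.w1.tolist(),
                "b1": net.b1.tolist(),
                "w2": net.w2.tolist(),
                "b2": net.b2.tolist(),
            }
        return json.dumps(doc)


def _check_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if set(np.unique(y)) != {LOW, HIGH}:
        raise ValueError("labels must be binary {0 low, 1 high} with both present")
    return x, y


def _tune_svm(x, y, kernel: str, cfg: SVMConfig, seed: int) -> dict:
    """Nelder-Mead simplex search on log10 hyperparameters, minimising inner
    cross-validated error."""
    skf = StratifiedKFold(n_splits=cfg.inner_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))

    def objective(logp):
        c = 10.0 ** logp[0]
        gamma = 10.0 ** logp[1] if kernel == "rbf" else "scale"
        errs = []
        for tr, te in splits:
            clf = SVC(kernel=kernel, C=c, gamma=gamma)
            clf.fit(x[tr], y[tr])
            errs.append(1.0 - clf.score(x[te], y[te]))
        return float(np.mean(errs))

    gamma0 = cfg.gamma0 if cfg.gamma0 is not None else 1.0 / x.shape[1]
    x0 = [np.log10(cfg.cost0)] + ([np.log10(gamma0)] if kernel == "rbf" else [])
    res = minimize(
        lambda p: objective(np.concatenate([p, [0.0]]) if kernel == "linear" else p),
        x0,
        method="Nelder-Mead",
        options={"maxiter": cfg.max_tune_iter, "xatol": 0.05, "fatol": 1e-3},
    )
    params = {"C": 10.0 ** res.x[0]}
    if kernel == "rbf":
        params["gamma"] = 10.0 ** res.x[1]
    return params


def train_classifier(
    kind: str,
    x: np.ndarray,
    y: np.ndarray,
    config: ClassifierConfig | None = None,
    seed: int = 0,
    normalization: NormalizationModel | None = None,
) -> TrainedClassifier:
    """Fit one classifier of the given kind on (already normalized) data."""
    if config is None:
        config = ClassifierConfig()
    x, y = _check_xy(x, y)
    if kind == "LDA":
        model = LinearDiscriminantAnalysis(solver="svd").fit(x, y)
        return TrainedClassifier("LDA", model, normalization)
    if kind in ("SVM-LIN", "SVM-RBF"):
        kernel = "linear" if kind == "SVM-LIN" else "rbf"
        if config.svm.tune:
            params = _tune_svm(x, y, kernel, config.svm, seed)
        else:
            params = {"C": config.svm.cost0}
            if kernel == "rbf":
                params["gamma"] = "scale"
        model = SVC(kernel=kernel, **params).fit(x, y)
        hp = {k: v for k, v in params.items() if isinstance(v, float)}
        return TrainedClassifier(kind, model, normalization, hp)
    if kind == "ANN":
        net = SigmoidNetwork(x.shape[1], config.ann, seed).fit(x, y)
        return TrainedClassifier("ANN", net, normalization)
    raise ValueError(f"unknown classifier kind: {kind!r}")


def predict(clf: TrainedClassifier, x: np.ndarray) -> np.ndarray:
    """Binary labels (0 low, 1 high); decision-boundary ties resolve to low."""
    x = np.asarray(x, dtype=float)
    if clf.kind == "ANN":
        if x.shape[1] != clf.model.w1.shape[0]:
            raise ValueError("column count does not match the trained network")
        return clf.model.predict(x)
    n_fit = clf.model.n_features_in_
    if x.shape[1] != n_fit:
        raise ValueError("column count does not match the trained model")
    # strict > 0: a sample exactly on the boundary is assigned low workload
    return (clf.model.decision_function(x) > 0).astype(int)
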
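"""Feature extraction: PCA baseline and the symmetric deep autoencoder.

The autoencoder is a five-layer symmetric network [d, 8J, J, 8J, d]:
symmetric saturating (tanh) hidden layers, a linear output, trained to
reconstruct its standardised
input (the identity map f(x) = x) with the Adam optimiser, minibatches of
64, and reconstruction quality measured as the root-mean-squared error
between X and its reconstruction.  The bottleneck width J is selected by a
grid search over 1 <= J <= 10 under k-fold cross-validation; the J
activations of the bottleneck are the extracted features handed to
clustering.

The network is built on scikit-learn's multilayer perceptron (MSE is the
monotone training surrogate of RMSE), advanced one epoch at a time so
per-epoch validation curves can be recorded.  The hidden activation is
configurable ("tanh" default: with standardised inputs a symmetric
saturating unit avoids the one-sided dead zone rectifiers exhibit at very
narrow bottlenecks; "relu" is available); so is the 1e-3 Adam learning
rate.  Runs are deterministic given the seed in single-threaded
execution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from .errors import ConfigurationError, SleepPIError

# ---------------------------------------------------------------------------
# Reconstruction error
# ---------------------------------------------------------------------------


def rmse(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Root-mean-squared error over all matrix entries."""
    X = np.asarray(X, dtype=float)
    X_hat = np.asarray(X_hat, dtype=float)
    if X.shape != X_hat.shape:
        raise ConfigurationError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    return float(np.sqrt(np.mean((X - X_hat) ** 2)))


# ---------------------------------------------------------------------------
# Autoencoder
# ---------------------------------------------------------------------------


@dataclass
class TrainingConfig:
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    activation: str = "tanh"
    seed: int = 0


@dataclass
class AutoencoderModel:
    """Architecture spec plus (after fit) the trained network."""

    d: int
    J: int
    config: TrainingConfig = field(default_factory=TrainingConfig)
    net: MLPRegressor | None = None
    train_curve: list = field(default_factory=list)

    @property
    def widths(self) -> tuple:
        return (self.d, 8 * self.J, self.J, 8 * self.J, self.d)

    @property
    def hidden_widths(self) -> tuple:
        return (8 * self.J, self.J, 8 * self.J)

    @property
    def is_trained(self) -> bool:
        return self.net is not None and hasattr(self.net, "coefs_")


def build_autoencoder(d: int, J: int, config: TrainingConfig | None = None) -> AutoencoderModel:
    """Untrained symmetric autoencoder with hidden widths (8J, J, 8J)."""
    if J < 1:
        raise ConfigurationError("J (bottleneck width) must be >= 1")
    if d < 1:
        raise ConfigurationError("d (input width) must be >= 1")
    return AutoencoderModel(d=d, J=J, config=config or TrainingConfig())


def _make_net(model: AutoencoderModel) -> MLPRegressor:
    cfg = model.config
    return MLPRegressor(
        hidden_layer_sizes=model.hidden_widths,
        activation=cfg.activation,
        solver="adam",
        batch_size=cfg.batch_size,
        learning_rate_init=cfg.learning_rate,
        max_iter=1,
        shuffle=True,
        random_state=cfg.seed,
        tol=0.0,
        n_iter_no_change=10**9,
    )


def train_autoencoder(
    model: AutoencoderModel,
    X_train: np.ndarray,
    X_val: np.ndarray | None = None,
    record_curves: bool = False,
):
    """Train in place for ``config.epochs`` epochs; returns per-epoch curves.

    Returns ``(train_curve, val_curve)`` — lists of per-epoch RMSE (empty
    unless ``record_curves``; the validation curve needs ``X_val``).
    Divergence (non-finite loss) raises with the epoch index.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.shape[1] != model.d:
        raise ConfigurationError(f"X has width {X_train.shape[1]}, model expects {model.d}")
    net = _make_net(model)
    net.batch_size = int(min(model.config.batch_size, X_train.shape[0]))
    train_curve, val_curve = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for epoch in range(model.config.epochs):
            net.partial_fit(X_train, X_train)
            if not np.isfinite(net.loss_):
                raise SleepPIError(f"autoencoder diverged at epoch {epoch}")
            if record_curves:
                train_curve.append(rmse(X_train, net.predict(X_train)))
                if X_val is not None:
                    val_curve.append(rmse(X_val, net.predict(X_val)))
    model.net = net
    model.train_curve = train_curve
    return train_curve, val_curve


def fit_final_autoencoder(
    X_train: np.ndarray, J: int, config: TrainingConfig | None = None,
    restarts: int = 3,
) -> AutoencoderModel:
    """Refit on the full training partition after grid selection of J.

    Several seeded weight initialisations are trained and the one with the
    lowest final training reconstruction RMSE is kept, guarding against the
    occasional dead-unit collapse of narrow relu bottlenecks.
    """
    X_train = np.asarray(X_train, dtype=float)
    base = config or TrainingConfig()
    best, best_rmse = None, np.inf
    for r in range(max(1, restarts)):
        cfg = replace(base, seed=(base.seed + 7919 * r) % (2**31))
        model = build_autoencoder(X_train.shape[1], J, cfg)
        train_autoencoder(model, X_train)
        score = rmse(X_train, reconstruct(model, X_train))
        if score < best_rmse:
            best, best_rmse = model, score
    return best


def encode(model: AutoencoderModel, X: np.ndarray) -> np.ndarray:
    """Bottleneck activations (n x J): the extracted features."""
    if not model.is_trained:
        raise SleepPIError("autoencoder is not trained")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.d:
        raise ConfigurationError(f"X must be (n, {model.d})")
    if X.shape[0] == 0:
        return np.empty((0, model.J))
    coefs, intercepts = model.net.coefs_, model.net.intercepts_
    act = X
    for layer in range(2):  # input -> 8J -> J
        act = act @ coefs[layer] + intercepts[layer]
        if model.config.activation == "relu":
            act = np.maximum(act, 0.0)
        elif model.config.activation == "tanh":
            act = np.tanh(act)
        elif model.config.activation == "logistic":
            act = 1.0 / (1.0 + np.exp(-act))
        elif model.config.activation != "identity":
            raise ConfigurationError(f"unknown activation '{model.config.activation}'")
    return act


def reconstruct(model: AutoencoderModel, X: np.ndarray) -> np.ndarray:
    if not model.is_trained:
        raise SleepPIError("autoencoder is not trained")
    return model.net.predict(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# Cross-validated grid search over J
# ---------------------------------------------------------------------------


def crossval_grid(
    X_train: np.ndarray,
    J_grid=range(1, 11),
    folds: int = 10,
    epochs: int = 100,
    batch_size: int = 64,
    seed: int = 0,
    record_curves: bool = False,
):
    """k-fold CV of the autoencoder across the bottleneck grid.

    For each J, each fold trains on (folds-1)/folds of the rows and
    evaluates reconstruction RMSE on the held-out fold.  Returns a tidy
    table (J, train/validation RMSE mean and SD across folds) and, when
    ``record_curves``, a dict J -> per-epoch validation-RMSE array of shape
    (epochs, folds).
    """
    X_train = np.asarray(X_train, dtype=float)
    n = X_train.shape[0]
    if n < folds:
        raise ConfigurationError(f"n={n} rows cannot support {folds}-fold CV")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    rows, curves = [], {}
    for J in J_grid:
        tr_scores, va_scores, fold_curves = [], [], []
        for fold_idx, (tr, va) in enumerate(kf.split(X_train)):
            cfg = TrainingConfig(
                epochs=epochs, batch_size=batch_size,
                seed=(seed + 1000 * int(J) + fold_idx) % (2**31),
            )
            model = build_autoencoder(X_train.shape[1], int(J), cfg)
            _, val_curve = train_autoencoder(
                model, X_train[tr], X_train[va], record_curves=record_curves
            )
            tr_scores.append(rmse(X_train[tr], reconstruct(model, X_train[tr])))
            va_scores.append(rmse(X_train[va], reconstruct(model, X_train[va])))
            if record_curves:
                fold_curves.append(val_curve)
        rows.append(
            {
                "J": int(J),
                "train_rmse_mean": float(np.mean(tr_scores)),
                "train_rmse_sd": float(np.std(tr_scores, ddof=1)),
                "val_rmse_mean": float(np.mean(va_scores)),
                "val_rmse_sd": float(np.std(va_scores, ddof=1)),
            }
        )
        if record_curves:
            curves[int(J)] = np.asarray(fold_curves).T  # (epochs, folds)
    return pd.DataFrame(rows), curves


def select_bottleneck(grid: pd.DataFrame) -> int:
    """Smallest J within one fold-SD of the best mean validation RMSE."""
    best = grid.loc[grid["val_rmse_mean"].idxmin()]
    threshold = best["val_rmse_mean"] + best["val_rmse_sd"]
    ok = grid.loc[grid["val_rmse_mean"] <= threshold, "J"]
    return int(ok.min())


# ---------------------------------------------------------------------------
# PCA baseline
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    components: np.ndarray        # (n_components, d) loading vectors
    explained_variance: np.ndarray  # all d eigenvalues, non-increasing
    n_components: int
    mean: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.components.T


def scree_elbow(explained_variance: np.ndarray) -> int:
    """Component count at the scree kink (max second difference).

    The elbow index is where the curve's discrete curvature peaks — the
    first component of the flat tail — and the components before it are
    kept.
    """
    ev = np.asarray(explained_variance, dtype=float)
    if ev.size < 3:
        return max(1, ev.size - 1)
    d2 = ev[:-2] - 2.0 * ev[1:-1] + ev[2:]  # curvature at positions 1..m-2
    return max(int(np.argmax(d2)) + 1, 1)


def fit_pca(X_train: np.ndarray, n_components="auto"):
    """Full PCA; ``auto`` picks the component count by the scree elbow.

    Returns ``(PCAModel, Z_train)`` with the projection onto the retained
    components.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.ndim != 2 or X_train.shape[1] == 0:
        raise ConfigurationError("X_train must be a non-empty 2-D matrix")
    full = PCA(svd_solver="full").fit(X_train)
    ev = full.explained_variance_
    n = scree_elbow(ev) if n_components == "auto" else int(n_components)
    n = int(np.clip(n, 1, X_train.shape[1]))
    model = PCAModel(
        components=full.components_[:n],
        explained_variance=ev,
        n_components=n,
        mean=full.mean_,
    )
    return model, model.transform(X_train)
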
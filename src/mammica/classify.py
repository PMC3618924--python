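"""Mass-vs-normal classifiers over ICA coefficient features.

Two families, matched in interface:

* a single-hidden-layer perceptron (sigmoid units, one sigmoid output)
  trained by batch resilient backpropagation (Rprop) on cross-entropy, with
  validation-based early stopping and random restarts, model-selected over a
  hidden-layer-size grid by validation AUC;
* a soft-margin SVM with RBF kernel K(x, y) = exp(-gamma ||x - y||^2),
  model-selected over the (C, gamma) grid by validation AUC.  The quadratic
  program is solved by scikit-learn's libsvm binding; ROC scores are raw
  decision values, never calibrated probabilities.

Rprop uses only gradient signs with per-weight adaptive steps (the Rprop-
variant, original constants eta+ = 1.2, eta- = 0.5, Delta0 = 0.1,
Delta_max = 50, Delta_min = 1e-6).  Features are standardized per dimension
with training-set statistics before either classifier, since both the RBF
kernel and Rprop are scale-sensitive.  Selection never sees test data: the
selection functions accept only train and validation sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

__all__ = [
    "RpropState",
    "MLPModel",
    "TrainedClassifier",
    "rprop_step",
    "train_mlp",
    "grid_select_mlp",
    "train_svm_grid",
    "score",
    "DEFAULT_HIDDEN_GRID",
    "DEFAULT_GAMMA_GRID",
    "DEFAULT_C_GRID",
]

#: hidden-layer sizes 50..650 in steps of 50
DEFAULT_HIDDEN_GRID: tuple[int, ...] = tuple(range(50, 651, 50))
#: RBF width grid, exponents -5..3 in steps of 0.5 (17 points)
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** (np.arange(-10, 7) / 2.0))
#: penalty grid, exponents -5..10 in steps of 0.5 (31 points)
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0 ** (np.arange(-10, 21) / 2.0))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class RpropState:
    """Per-weight adaptive step sizes and previous gradient signs."""

    step: dict[str, np.ndarray]
    prev_grad: dict[str, np.ndarray]
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.1
    delta_max: float = 50.0
    delta_min: float = 1e-6

    @classmethod
    def init(cls, params: dict[str, np.ndarray], **kw) -> "RpropState":
        state = cls(step={}, prev_grad={}, **kw)
        for k, v in params.items():
            state.step[k] = np.full_like(v, state.delta0)
            state.prev_grad[k] = np.zeros_like(v)
        return state


def rprop_step(
    params: dict[str, np.ndarray], grads: dict[str, np.ndarray], state: RpropState
) -> None:
    """One batch Rprop- update, in place.

    Steps grow by eta+ when the gradient sign persists, shrink by eta- on a
    sign flip (and the flipped gradient is zeroed so the next step is not
    misread as another flip); weights move against the gradient sign by the
    current step.  Steps stay clamped to [delta_min, delta_max].
    """
    for k in params:
        g = grads[k]
        prod = state.prev_grad[k] * g
        grew = prod > 0
        flipped = prod < 0
        state.step[k][grew] = np.minimum(state.step[k][grew] * state.eta_plus, state.delta_max)
        state.step[k][flipped] = np.maximum(
            state.step[k][flipped] * state.eta_minus, state.delta_min
        )
        g_eff = np.where(flipped, 0.0, g)
        params[k] -= np.sign(g_eff) * state.step[k]
        state.prev_grad[k] = g_eff


@dataclass
class MLPModel:
    """Single-hidden-layer perceptron with sigmoid units and one sigmoid output."""

    W1: np.ndarray  # (n_in, n_hidden)
    b1: np.ndarray
    W2: np.ndarray  # (n_hidden, 1)
    b2: np.ndarray
    train_log: dict = field(default_factory=dict)

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[1]

    def score(self, X: np.ndarray) -> np.ndarray:
        """Output-unit activation in (0, 1); higher = more mass-like."""
        H = _sigmoid(np.asarray(X, dtype=float) @ self.W1 + self.b1)
        return _sigmoid(H @ self.W2 + self.b2).ravel()


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def train_mlp(
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    n_hidden: int,
    seed: int = 0,
    max_epochs: int = 2000,
    patience: int = 30,
) -> MLPModel:
    """Batch Rprop training on cross-entropy with early stopping.

    Training stops when validation loss has not improved for ``patience``
    epochs; the returned weights are those of the best-validation epoch,
    never a later one.  Raises on single-class training labels and aborts
    with diagnostics if the loss goes non-finite.
    """
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(seed)
    n_in = X.shape[1]
    limit1 = np.sqrt(6.0 / (n_in + n_hidden))
    limit2 = np.sqrt(6.0 / (n_hidden + 1))
    params = {
        "W1": rng.uniform(-limit1, limit1, size=(n_in, n_hidden)),
        "b1": np.zeros(n_hidden),
        "W2": rng.uniform(-limit2, limit2, size=(n_hidden, 1)),
        "b2": np.zeros(1),
    }
    state = RpropState.init(params)
    best = {k: v.copy() for k, v in params.items()}
    best_val = np.inf
    best_epoch = 0
    history = []
    m = X.shape[0]
    for epoch in range(1, max_epochs + 1):
        H = _sigmoid(X @ params["W1"] + params["b1"])
        p = _sigmoid(H @ params["W2"] + params["b2"]).ravel()
        loss = _bce(p, y)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss at epoch {epoch} (n_hidden={n_hidden}, seed={seed})"
            )
        # gradients of mean cross-entropy wrt sigmoid pre-activations
        delta_out = ((p - y) / m)[:, None]  # (m, 1)
        gW2 = H.T @ delta_out
        gb2 = delta_out.sum(axis=0)
        delta_hid = (delta_out @ params["W2"].T) * H * (1.0 - H)
        gW1 = X.T @ delta_hid
        gb1 = delta_hid.sum(axis=0)
        rprop_step(params, {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}, state)

        Hv = _sigmoid(np.asarray(val_X, dtype=float) @ params["W1"] + params["b1"])
        pv = _sigmoid(Hv @ params["W2"] + params["b2"]).ravel()
        val_loss = _bce(pv, np.asarray(val_y, dtype=float).ravel())
        history.append((loss, val_loss))
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_epoch = epoch
            best = {k: v.copy() for k, v in params.items()}
        elif epoch - best_epoch >= patience:
            break
    model = MLPModel(
        W1=best["W1"], b1=best["b1"], W2=best["W2"], b2=best["b2"],
        train_log={
            "best_epoch": best_epoch,
            "n_epochs_run": len(history),
            "best_val_loss": best_val,
            "seed": seed,
        },
    )
    model._rprop_state = state  # exposed for invariant checks
    return model


@dataclass
class _Scaler:
    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Scaler":
        X = np.asarray(X, dtype=float)
        std = X.std(axis=0)
        return cls(mean=X.mean(axis=0), std=np.where(std > 1e-12, std, 1.0))

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std


@dataclass
class TrainedClassifier:
    """Selected model plus its selection record (validation metric only)."""

    kind: str  # "mlp" | "svm"
    model: object
    scaler: _Scaler | None
    selection: dict = field(default_factory=dict)

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.scaler is not None:
            X = self.scaler(X)
        if self.kind == "mlp":
            return self.model.score(X)
        return self.model.decision_function(X)


def score(clf: TrainedClassifier, features: np.ndarray) -> np.ndarray:
    """Classifier score, higher = more mass-like (MLP sigmoid output or SVM
    signed distance to the separating hyperplane)."""
    return clf.score(features)


def grid_select_mlp(
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    hidden_grid: Sequence[int] = DEFAULT_HIDDEN_GRID,
    restarts: int = 4,
    seed: int = 0,
    max_epochs: int = 2000,
    patience: int = 30,
    metric: Callable | None = None,
    standardize: bool = True,
) -> TrainedClassifier:
    """Train MLPs over the hidden-size grid with random restarts.

    Each grid setting is retrained ``restarts`` times from fresh random
    initial weights; the model with the best validation AUC (or injected
    ``metric``) wins.  Ties break to the smaller hidden size, then the lower
    restart index.
    """
    if not hidden_grid or restarts < 1:
        raise ValueError("hidden grid and restarts must be non-empty")
    scaler = _Scaler.fit(train_X) if standardize else None
    Xt = scaler(train_X) if scaler else np.asarray(train_X, dtype=float)
    Xv = scaler(val_X) if scaler else np.asarray(val_X, dtype=float)
    ss = np.random.SeedSequence([seed, 0x313])
    seeds = ss.generate_state(len(hidden_grid) * restarts) % (2**31)
    best = None
    k = 0
    for n_hidden in hidden_grid:
        for r in range(restarts):
            model = train_mlp(
                Xt, train_y, Xv, val_y, n_hidden,
                seed=int(seeds[k]), max_epochs=max_epochs, patience=patience,
            )
            k += 1
            if metric is not None:
                val_metric = float(metric(model, Xv, val_y))
            else:
                val_metric = float(roc_auc_score(val_y, model.score(Xv)))
            # strict > with ordered iteration implements the tie-break
            if best is None or val_metric > best[0] + 0.0:
                best = (val_metric, n_hidden, r, model)
    val_metric, n_hidden, r, model = best
    return TrainedClassifier(
        kind="mlp",
        model=model,
        scaler=scaler,
        selection={
            "n_hidden": n_hidden,
            "restart": r,
            "val_auc": val_metric,
            "seed": seed,
            "best_epoch": model.train_log["best_epoch"],
        },
    )


def train_svm_grid(
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    tol: float = 1e-4,
    standardize: bool = True,
) -> TrainedClassifier:
    """RBF-SVM grid search selected by validation AUC.

    Ties break to smaller C, then smaller gamma (grids iterated in
    ascending order).  A grid point whose solve fails is recorded and
    skipped; only if every point fails does the search raise.
    """
    y = np.asarray(train_y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    if not len(gamma_grid) or not len(C_grid):
        raise ValueError("empty parameter grid")
    scaler = _Scaler.fit(train_X) if standardize else None
    Xt = scaler(train_X) if scaler else np.asarray(train_X, dtype=float)
    Xv = scaler(val_X) if scaler else np.asarray(val_X, dtype=float)
    best = None
    failures = []
    for C in C_grid:
        for gamma in gamma_grid:
            try:
                model = SVC(kernel="rbf", C=C, gamma=gamma, tol=tol, cache_size=64)
                model.fit(Xt, y)
                val_auc = float(roc_auc_score(val_y, model.decision_function(Xv)))
            except Exception as exc:  # solver failure at one grid point
                failures.append({"C": C, "gamma": gamma, "error": str(exc)})
                continue
            if best is None or val_auc > best[0]:
                best = (val_auc, C, gamma, model)
    if best is None:
        raise RuntimeError(f"SVM training failed at every grid point: {failures[:3]}")
    val_auc, C, gamma, model = best
    return TrainedClassifier(
        kind="svm",
        model=model,
        scaler=scaler,
        selection={"C": float(C), "gamma": float(gamma), "val_auc": val_auc,
                   "n_failed_grid_points": len(failures)},
    )
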
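"""Three-layer feed-forward network, quasi-Newton training, restart ensembles.

The regressor is deliberately small and classical: one hidden layer of tanh
units and a single linear output neuron,

    y(x) = w2 . tanh(W1 x + b1) + b2,

trained full-batch on mean squared error by BFGS with an analytic
backpropagation gradient.  One "epoch" is one quasi-Newton iteration.
Overfitting control is validation-based early stopping with a patience
window and best-snapshot rollback: the model returned is the iterate with
the lowest validation MSE ever observed, not the final one.

Because tiny random initial weights (uniform on [-0.1, 0.1]) leave a seed
dependence in the converged network, predictions are stabilized by
re-training from many random restarts and averaging the member outputs
(default 100 members).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .features import ModelingDataset, Scaler, build_feature_grid
from .gradients import DesignTable

__all__ = [
    "AnnModel",
    "EnsembleModel",
    "TrainResult",
    "init_weights",
    "mse_and_grad",
    "predict_tR",
    "train",
    "train_ensemble",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_EPOCHS = 2000
DEFAULT_PATIENCE = 200
DEFAULT_GTOL = 1e-8
DEFAULT_BASE_SEED = 12345


@dataclass
class AnnModel:
    """Weights of one n_in - n_hidden - 1 network."""

    W1: np.ndarray  # (n_hidden, n_in)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.W1).all() and np.isfinite(self.b1).all()
                and np.isfinite(self.w2).all() and np.isfinite(self.b2)):
            raise ValueError("non-finite network weights")

    @property
    def n_in(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def architecture(self) -> str:
        return f"{self.n_in}-{self.n_hidden}-1"

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Network response for a row vector or a matrix of rows."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != self.n_in:
            raise ValueError(f"expected {self.n_in} inputs, got {X.shape[1]}")
        out = np.tanh(X @ self.W1.T + self.b1) @ self.w2 + self.b2
        return float(out[0]) if single else out

    def pack(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.w2, [self.b2]])

    @classmethod
    def unpack(cls, flat: np.ndarray, n_in: int, n_hidden: int) -> "AnnModel":
        h, d = n_hidden, n_in
        W1 = flat[: h * d].reshape(h, d)
        b1 = flat[h * d: h * d + h]
        w2 = flat[h * d + h: h * d + 2 * h]
        b2 = float(flat[-1])
        return cls(W1=W1.copy(), b1=b1.copy(), w2=w2.copy(), b2=b2)

    def to_dict(self) -> dict:
        return {"W1": self.W1.tolist(), "b1": self.b1.tolist(),
                "w2": self.w2.tolist(), "b2": self.b2}

    @classmethod
    def from_dict(cls, d: dict) -> "AnnModel":
        return cls(W1=np.array(d["W1"], dtype=float), b1=np.array(d["b1"], dtype=float),
                   w2=np.array(d["w2"], dtype=float), b2=float(d["b2"]))


def init_weights(n_in: int, n_hidden: int, seed: int) -> AnnModel:
    """Fresh network with all weights/biases i.i.d. uniform on [-0.1, 0.1]."""
    if n_hidden < 1:
        raise ValueError("need at least one hidden neuron")
    rng = np.random.default_rng(seed)
    return AnnModel(
        W1=rng.uniform(-0.1, 0.1, size=(n_hidden, n_in)),
        b1=rng.uniform(-0.1, 0.1, size=n_hidden),
        w2=rng.uniform(-0.1, 0.1, size=n_hidden),
        b2=float(rng.uniform(-0.1, 0.1)),
    )


def mse_and_grad(
    flat: np.ndarray, X: np.ndarray, y: np.ndarray, n_in: int, n_hidden: int
) -> tuple[float, np.ndarray]:
    """Full-batch MSE and its analytic gradient (backpropagation)."""
    h, d, n = n_hidden, n_in, X.shape[0]
    W1 = flat[: h * d].reshape(h, d)
    b1 = flat[h * d: h * d + h]
    w2 = flat[h * d + h: h * d + 2 * h]
    b2 = flat[-1]
    A = np.tanh(X @ W1.T + b1)          # (n, h)
    r = A @ w2 + b2 - y                 # residuals
    mse = float(r @ r) / n
    dout = (2.0 / n) * r                # dMSE/d(output)
    g_w2 = A.T @ dout
    g_b2 = dout.sum()
    dZ = np.outer(dout, w2) * (1.0 - A * A)   # (n, h)
    g_W1 = dZ.T @ X
    g_b1 = dZ.sum(axis=0)
    return mse, np.concatenate([g_W1.ravel(), g_b1, g_w2, [g_b2]])


@dataclass
class TrainResult:
    """Outcome of one training run: best-validation snapshot + trajectories."""

    model: AnnModel
    epochs_run: int
    best_epoch: int
    train_mse: list[float]
    val_mse: list[float]
    seed: int | None = None


def train(
    model: AnnModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    max_epochs: int = DEFAULT_MAX_EPOCHS,
    patience: int = DEFAULT_PATIENCE,
    gtol: float = DEFAULT_GTOL,
    seed: int | None = None,
) -> TrainResult:
    """BFGS training with validation-based early stopping.

    Validation MSE is recorded at the initial point and after every
    quasi-Newton iteration; training halts when it has not improved for
    ``patience`` consecutive iterations (or at ``max_epochs``), and the
    snapshot with the lowest validation MSE is returned.
    """
    if max_epochs < 1:
        raise ValueError("max_epochs must be >= 1")
    n_in, n_hidden = model.n_in, model.n_hidden

    def objective(flat):
        return mse_and_grad(flat, X_train, y_train, n_in, n_hidden)

    def val_of(flat):
        m = AnnModel.unpack(flat, n_in, n_hidden)
        r = m.forward(X_val) - y_val
        return float(r @ r) / len(y_val)

    x0 = model.pack()
    state = {
        "train_mse": [objective(x0)[0]],
        "val_mse": [val_of(x0)],
        "best_x": x0.copy(),
        "best_epoch": 0,
        "since_best": 0,
        "epochs": 0,
    }
    state["best_val"] = state["val_mse"][0]

    def callback(xk):
        state["epochs"] += 1
        tr = objective(xk)[0]
        if not np.isfinite(tr):
            raise RuntimeError("training loss became non-finite; aborting")
        vl = val_of(xk)
        state["train_mse"].append(tr)
        state["val_mse"].append(vl)
        if vl < state["best_val"]:
            state["best_val"] = vl
            state["best_x"] = np.array(xk, dtype=float, copy=True)
            state["best_epoch"] = state["epochs"]
            state["since_best"] = 0
        else:
            state["since_best"] += 1
            if state["since_best"] >= patience:
                raise StopIteration

    res = minimize(
        objective,
        x0,
        jac=True,
        method="BFGS",
        callback=callback,
        options={"maxiter": max_epochs, "gtol": gtol},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError("training loss became non-finite; aborting")
    return TrainResult(
        model=AnnModel.unpack(state["best_x"], n_in, n_hidden),
        epochs_run=state["epochs"],
        best_epoch=state["best_epoch"],
        train_mse=state["train_mse"],
        val_mse=state["val_mse"],
        seed=seed,
    )


@dataclass
class EnsembleModel:
    """Average of networks re-trained from independent random restarts.

    The prediction is the arithmetic mean of member outputs on the scaled
    log-target scale; the attached scaler converts back to minutes.
    """

    members: list[AnnModel]
    scaler: Scaler | None = None
    tag: str | None = None
    roster: tuple[str, ...] | None = None
    base_seed: int | None = None
    train_results: list[TrainResult] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        archs = {m.architecture for m in self.members}
        if len(archs) != 1:
            raise ValueError(f"members disagree on architecture: {sorted(archs)}")

    @property
    def architecture(self) -> str:
        return self.members[0].architecture

    @property
    def n_in(self) -> int:
        return self.members[0].n_in

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Mean member output (scaled log-target units)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.mean([m.forward(X) for m in self.members], axis=0)

    def predict_minutes(self, X_scaled: np.ndarray) -> np.ndarray:
        if self.scaler is None:
            raise ValueError("ensemble has no scaler attached")
        return self.scaler.invert_y(self.predict(X_scaled))


def train_ensemble(
    data: ModelingDataset,
    n_hidden: int,
    n_restarts: int = 100,
    base_seed: int = DEFAULT_BASE_SEED,
    max_epochs: int = DEFAULT_MAX_EPOCHS,
    patience: int = DEFAULT_PATIENCE,
    keep_train_results: bool = False,
) -> EnsembleModel:
    """Re-train ``n_restarts`` networks (member i seeded base_seed + i) and
    average their outputs.

    Individual members that fail (non-finite loss) are logged and dropped;
    the ensemble is valid only if at least 90% of restarts succeed.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    members, results = [], []
    for i in range(n_restarts):
        seed = base_seed + i
        model0 = init_weights(data.n_in, n_hidden, seed)
        try:
            result = train(
                model0, data.X_train, data.y_train, data.X_val, data.y_val,
                max_epochs=max_epochs, patience=patience, seed=seed,
            )
        except RuntimeError as exc:
            logger.warning("restart %d (seed %d) failed: %s", i, seed, exc)
            continue
        members.append(result.model)
        if keep_train_results:
            results.append(result)
    if len(members) < 0.9 * n_restarts:
        raise RuntimeError(
            f"only {len(members)}/{n_restarts} restarts succeeded; ensemble invalid"
        )
    return EnsembleModel(
        members=members,
        scaler=data.scaler,
        tag=data.tag,
        roster=data.roster,
        base_seed=base_seed,
        train_results=results,
    )


#: Scaled inputs beyond this band trigger an extrapolation flag when predicting.
EXTRAPOLATION_BAND = (-0.5, 1.5)


def predict_tR(
    ensemble: EnsembleModel,
    design: DesignTable,
    roster: tuple[str, ...] | None = None,
    context_tag: str | None = None,
) -> pd.DataFrame:
    """Predicted retention times (minutes) for every (run, solute) pair.

    Returns columns ``run_id, solute_id, tR_min, extrapolated``; rows whose
    scaled descriptors fall far outside the training range (beyond
    [-0.5, 1.5]) are flagged and a warning is emitted.
    """
    if ensemble.scaler is None:
        raise ValueError("ensemble has no scaler attached")
    roster = roster or ensemble.roster
    if roster is None:
        raise ValueError("no roster available for prediction")
    tag = context_tag or ensemble.tag or design.tag
    X_raw, prov = build_feature_grid(design, tuple(roster), context_tag=tag)
    X = ensemble.scaler.transform_X(X_raw)
    if X.shape[1] != ensemble.n_in:
        raise ValueError(
            f"feature width {X.shape[1]} does not match model inputs {ensemble.n_in}"
        )
    lo, hi = EXTRAPOLATION_BAND
    extrapolated = ((X < lo) | (X > hi)).any(axis=1)
    if extrapolated.any():
        flagged = sorted(prov.loc[extrapolated, "run_id"].unique())
        logger.warning("predictions extrapolate beyond the training range on runs %s", flagged)
    out = prov.copy()
    out["tR_min"] = ensemble.scaler.invert_y(ensemble.predict(X))
    out["extrapolated"] = extrapolated
    return out[["run_id", "solute_id", "tR_min", "extrapolated"]]
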
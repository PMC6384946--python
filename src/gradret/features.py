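"""Model inputs and targets: gradient descriptors + one-hot solute codes.

Each training row concatenates the active gradient descriptors of a run
(context dependent, see :data:`gradret.gradients.ACTIVE_DESCRIPTORS`) with a
16-bit one-hot code identifying the solute; the regression target is
``ln t_R``.  Categorical bit-string codes replace molecular descriptors
deliberately: one network then models all solutes at once with no structural
assumptions.  All inputs and the target are range-scaled to [0, 1] on
statistics of the *training* rows only; validation/test rows may legitimately
scale outside [0, 1] (extrapolated gradients are part of the exercise).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gradients import ACTIVE_DESCRIPTORS, DesignTable, compute_descriptors
from .simulator import ROSTER

__all__ = [
    "ModelingDataset",
    "Scaler",
    "SoluteCode",
    "assemble",
    "build_feature_grid",
    "build_features",
    "encode_solute",
    "fit_scaler",
]


@dataclass(frozen=True)
class SoluteCode:
    """One-hot identity code of a solute within a fixed roster."""

    solute_id: str
    index: int  # 1-based roster position n
    bits: np.ndarray

    def __post_init__(self) -> None:
        if int(self.bits.sum()) != 1 or int(self.bits[self.index - 1]) != 1:
            raise ValueError(f"{self.solute_id}: malformed one-hot code")


def encode_solute(solute_id: str, roster: tuple[str, ...] = ROSTER) -> SoluteCode:
    """One-hot encode a solute at its (1-based) roster position."""
    try:
        n = roster.index(solute_id) + 1
    except ValueError:
        raise KeyError(f"solute {solute_id!r} not in roster") from None
    bits = np.zeros(len(roster), dtype=float)
    bits[n - 1] = 1.0
    return SoluteCode(solute_id=solute_id, index=n, bits=bits)


def _descriptor_matrix(design: DesignTable, tag: str) -> dict[str, np.ndarray]:
    return {
        p.run_id: compute_descriptors(p, context_tag=tag).active_values()
        for p in design
    }


def build_features(
    design: DesignTable,
    records: pd.DataFrame,
    roster: tuple[str, ...] = ROSTER,
    context_tag: str | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Unscaled feature matrix, ``ln t_R`` target vector and row provenance.

    Rows follow design order then roster order, restricted to the (run,
    solute) pairs present in ``records``.  Every record must reference a run
    in the design and a solute in the roster.
    """
    tag = design.tag if context_tag is None else context_tag
    desc = _descriptor_matrix(design, tag)
    unknown_runs = sorted(set(records["run_id"]) - set(desc))
    if unknown_runs:
        raise KeyError(f"records reference runs absent from the design: {unknown_runs}")
    unknown_solutes = sorted(set(records["solute_id"]) - set(roster))
    if unknown_solutes:
        raise KeyError(f"records reference solutes absent from the roster: {unknown_solutes}")

    run_order = {p.run_id: i for i, p in enumerate(design)}
    splits = {p.run_id: p.split for p in design}
    recs = records.copy()
    recs["_run_ord"] = recs["run_id"].map(run_order)
    recs["_sol_ord"] = recs["solute_id"].map({s: i for i, s in enumerate(roster)})
    recs = recs.sort_values(["_run_ord", "_sol_ord"], kind="stable")

    rows, prov = [], []
    for run_id, solute_id, t_r in zip(recs["run_id"], recs["solute_id"], recs["tR_min"]):
        if not t_r > 0:
            raise ValueError(f"non-positive retention time for ({run_id}, {solute_id})")
        rows.append(np.concatenate([desc[run_id], encode_solute(solute_id, roster).bits]))
        prov.append({"run_id": run_id, "solute_id": solute_id,
                     "split": splits[run_id], "tR_min": t_r})
    n_desc = len(ACTIVE_DESCRIPTORS[tag])
    X = np.array(rows, dtype=float).reshape(len(rows), n_desc + len(roster))
    y = np.log(recs["tR_min"].to_numpy(dtype=float))
    return X, y, pd.DataFrame(prov)


def build_feature_grid(
    design: DesignTable,
    roster: tuple[str, ...] = ROSTER,
    context_tag: str | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Unscaled features for every (run, solute) pair of a design (no targets)."""
    tag = design.tag if context_tag is None else context_tag
    desc = _descriptor_matrix(design, tag)
    rows, prov = [], []
    for p in design:
        for solute_id in roster:
            rows.append(np.concatenate([desc[p.run_id], encode_solute(solute_id, roster).bits]))
            prov.append({"run_id": p.run_id, "solute_id": solute_id, "split": p.split})
    return np.array(rows, dtype=float), pd.DataFrame(prov)


@dataclass
class Scaler:
    """Range scaling of features and the log target to [0, 1].

    Fitted on training rows only; columns that are constant there are
    dropped (they carry no information) with a warning.  Applying the scaler
    to out-of-range rows yields values outside [0, 1] -- extrapolation is
    passed through untouched.
    """

    x_min: np.ndarray
    x_max: np.ndarray
    keep: np.ndarray
    y_min: float
    y_max: float
    fitted_on: str = "train"

    @property
    def n_out(self) -> int:
        return int(self.keep.sum())

    def transform_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.keep.size:
            raise ValueError(f"expected {self.keep.size} raw columns, got {X.shape[1]}")
        kept = X[:, self.keep]
        return (kept - self.x_min[self.keep]) / (self.x_max[self.keep] - self.x_min[self.keep])

    def transform_y(self, y_ln: np.ndarray) -> np.ndarray:
        return (np.asarray(y_ln, dtype=float) - self.y_min) / (self.y_max - self.y_min)

    def invert_y(self, y_scaled: np.ndarray) -> np.ndarray:
        """Scaled log targets back to retention times in minutes."""
        return np.exp(self.y_min + np.asarray(y_scaled, dtype=float) * (self.y_max - self.y_min))

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min.tolist(),
            "x_max": self.x_max.tolist(),
            "keep": self.keep.astype(int).tolist(),
            "y_min": self.y_min,
            "y_max": self.y_max,
            "fitted_on": self.fitted_on,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(
            x_min=np.array(d["x_min"], dtype=float),
            x_max=np.array(d["x_max"], dtype=float),
            keep=np.array(d["keep"], dtype=bool),
            y_min=float(d["y_min"]),
            y_max=float(d["y_max"]),
            fitted_on=d.get("fitted_on", "train"),
        )


def fit_scaler(X: np.ndarray, y_ln: np.ndarray, on: str = "train") -> Scaler:
    """Fit per-column and target ranges on the given (training) rows."""
    X = np.asarray(X, dtype=float)
    y_ln = np.asarray(y_ln, dtype=float)
    x_min, x_max = X.min(axis=0), X.max(axis=0)
    keep = x_max > x_min
    if not keep.all():
        dropped = np.flatnonzero(~keep).tolist()
        warnings.warn(f"dropping constant feature columns {dropped}", stacklevel=2)
    y_min, y_max = float(y_ln.min()), float(y_ln.max())
    if not y_max > y_min:
        raise ValueError("target range is degenerate; cannot scale")
    return Scaler(x_min=x_min, x_max=x_max, keep=keep, y_min=y_min, y_max=y_max, fitted_on=on)


@dataclass
class ModelingDataset:
    """Scaled train/val/test matrices with per-row provenance.

    ``prov_*`` frames keep (run_id, solute_id, split, tR_min) per row so
    errors can later be reported per solute and per gradient in minutes.
    """

    tag: str
    roster: tuple[str, ...]
    scaler: Scaler
    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    prov_train: pd.DataFrame
    prov_val: pd.DataFrame
    prov_test: pd.DataFrame

    @property
    def n_in(self) -> int:
        return self.X_train.shape[1]

    def counts(self) -> tuple[int, int, int]:
        return len(self.y_train), len(self.y_val), len(self.y_test)

    def observed_minutes(self, split: str) -> np.ndarray:
        return getattr(self, f"prov_{split}")["tR_min"].to_numpy(dtype=float)

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for split in ("train", "val", "test"):
            X = getattr(self, f"X_{split}")
            y = getattr(self, f"y_{split}")
            prov = getattr(self, f"prov_{split}")
            frame = prov.reset_index(drop=True).copy()
            for j in range(X.shape[1]):
                frame[f"x{j}"] = X[:, j]
            frame["y_scaled"] = y
            frame.to_csv(path / f"{split}.csv", index=False)
        sidecar = {"tag": self.tag, "roster": list(self.roster),
                   "scaler": self.scaler.to_dict()}
        (path / "scaler.json").write_text(json.dumps(sidecar, indent=2))


def assemble(
    tag: str,
    design: DesignTable,
    records: pd.DataFrame,
    roster: tuple[str, ...] = ROSTER,
) -> ModelingDataset:
    """Build the scaled train/val/test matrices for one modeling context.

    Splits come from the design's labels; the scaler is fitted on training
    rows only and applied everywhere (no leakage of val/test statistics).
    """
    unlabeled = [p.run_id for p in design if p.split == "unassigned"]
    if unlabeled:
        raise ValueError(f"runs without split labels: {unlabeled}")
    X, y, prov = build_features(design, records, roster, context_tag=tag)
    masks = {s: (prov["split"] == s).to_numpy() for s in ("train", "val", "test")}
    scaler = fit_scaler(X[masks["train"]], y[masks["train"]])
    parts: dict[str, object] = {}
    for split, mask in masks.items():
        parts[f"X_{split}"] = scaler.transform_X(X[mask])
        parts[f"y_{split}"] = scaler.transform_y(y[mask])
        parts[f"prov_{split}"] = prov[mask].reset_index(drop=True)
    return ModelingDataset(tag=tag, roster=tuple(roster), scaler=scaler, **parts)
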
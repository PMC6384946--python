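"""Model statistics and hidden-layer selection.

All statistics are computed on unscaled retention times in minutes.  For the
training split the determination coefficient is the ordinary R-squared; for
validation/test splits the external-validation form Q2_F1 is used: the total
sum of squares is taken about the *training-set* mean, so Q2 measures how
much better than the naive "predict the training mean" baseline the model is
on outside data.  Standard errors (SEC in calibration, SEP in prediction)
use an n - 1 denominator.  Percentage errors are signed,
err% = 100 * (pred - obs) / obs; summary tables aggregate their absolute
values, per-solute/per-gradient profiles keep the sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ann import EnsembleModel, train_ensemble
from .features import ModelingDataset

__all__ = [
    "ErrorProfile",
    "MetricsReport",
    "ScanResult",
    "architecture_scan",
    "compute_metrics",
    "error_profile",
    "table_report",
]


@dataclass(frozen=True)
class MetricsReport:
    """Goodness-of-fit summary of one split, on retention times in minutes.

    ``r2`` holds R-squared for the training split and Q2 (external form)
    otherwise; ``se`` is the corresponding standard error (SEC/SEP) in
    minutes.
    """

    split: str
    r2: float
    se: float
    mean_pct: float
    max_pct: float
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.mean_pct <= self.max_pct):
            raise ValueError("need 0 <= mean_pct <= max_pct")
        if self.se < 0 or self.r2 > 1 + 1e-12:
            raise ValueError("invalid SE or determination coefficient")


def compute_metrics(
    pred_minutes: np.ndarray,
    obs_minutes: np.ndarray,
    split: str,
    train_mean_minutes: float | None = None,
) -> MetricsReport:
    """R2/Q2, SEC/SEP and mean/max absolute percentage error of one split.

    ``train_mean_minutes`` anchors the total sum of squares (Q2_F1
    convention); it defaults to the mean of ``obs_minutes``, which is the
    correct choice for the training split itself.
    """
    pred = np.asarray(pred_minutes, dtype=float)
    obs = np.asarray(obs_minutes, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or len(obs) < 2:
        raise ValueError("need equal-length 1-D vectors with at least 2 points")
    if (obs == 0).any():
        raise ValueError("observed retention times must be non-zero")
    mean0 = float(obs.mean()) if train_mean_minutes is None else float(train_mean_minutes)
    sse = float(((pred - obs) ** 2).sum())
    sst = float(((obs - mean0) ** 2).sum())
    if sst == 0:
        raise ValueError("degenerate observations: zero total sum of squares")
    err_pct = 100.0 * (pred - obs) / obs
    return MetricsReport(
        split=split,
        r2=1.0 - sse / sst,
        se=float(np.sqrt(sse / (len(obs) - 1))),
        mean_pct=float(np.abs(err_pct).mean()),
        max_pct=float(np.abs(err_pct).max()),
        n=len(obs),
    )


def table_report(ensemble: EnsembleModel, data: ModelingDataset) -> pd.DataFrame:
    """Train/val/test metrics table for a fitted ensemble (minutes scale)."""
    train_mean = float(data.observed_minutes("train").mean())
    rows = []
    for split in ("train", "val", "test"):
        X = getattr(data, f"X_{split}")
        obs = data.observed_minutes(split)
        pred = ensemble.predict_minutes(X)
        rep = compute_metrics(
            pred, obs, split,
            train_mean_minutes=None if split == "train" else train_mean,
        )
        rows.append({
            "split": rep.split, "r2_or_q2": rep.r2, "se_min": rep.se,
            "mean_pct": rep.mean_pct, "max_pct": rep.max_pct, "n": rep.n,
        })
    return pd.DataFrame(rows)


@dataclass
class ErrorProfile:
    """Signed percentage errors per (run, solute), with grouped retrieval."""

    table: pd.DataFrame  # columns run_id, solute_id, tR_obs, tR_pred, err_pct

    def by_solute(self) -> pd.Series:
        return self.table.groupby("solute_id", sort=False)["err_pct"].mean()

    def by_gradient(self) -> pd.Series:
        return self.table.groupby("run_id", sort=False)["err_pct"].mean()

    def pivot(self) -> pd.DataFrame:
        """Solutes as rows, gradients as columns (error-chart layout)."""
        return self.table.pivot(index="solute_id", columns="run_id", values="err_pct")


def error_profile(records_pred: pd.DataFrame, records_obs: pd.DataFrame) -> ErrorProfile:
    """Join predictions with observations on (run_id, solute_id) keys.

    Both frames need ``run_id, solute_id, tR_min`` columns; any key present
    on one side only is an error.
    """
    keys = ["run_id", "solute_id"]
    merged = records_obs[keys + ["tR_min"]].rename(columns={"tR_min": "tR_obs"}).merge(
        records_pred[keys + ["tR_min"]].rename(columns={"tR_min": "tR_pred"}),
        on=keys, how="outer", indicator=True,
    )
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        missing = [tuple(r) for r in bad[keys].itertuples(index=False)]
        raise KeyError(f"unmatched (run, solute) keys: {missing}")
    merged = merged.drop(columns="_merge")
    merged["err_pct"] = 100.0 * (merged["tR_pred"] - merged["tR_obs"]) / merged["tR_obs"]
    if not np.isfinite(merged["err_pct"]).all():
        raise ValueError("non-finite percentage errors")
    return ErrorProfile(table=merged)


@dataclass
class ScanResult:
    """Hidden-layer scan log: candidates N-6 ... N+6 and the chosen width."""

    candidates: list[int]
    val_mse: list[float]
    chosen: int

    def __post_init__(self) -> None:
        best = min(self.val_mse)
        winners = [c for c, v in zip(self.candidates, self.val_mse) if v == best]
        if self.chosen != min(winners):
            raise ValueError("chosen architecture is not the validation argmin")


def architecture_scan(
    data: ModelingDataset,
    N: int | None = None,
    base_seed: int = 12345,
    restarts_per_candidate: int = 10,
    max_epochs: int = 2000,
    patience: int = 30,
) -> ScanResult:
    """Scan hidden-layer widths N-6 ... N+6 and pick the validation argmin.

    ``N`` defaults to the input count.  Every candidate is trained as a
    small restart ensemble (default 10 members) with early stopping, and
    scored by the validation MSE of the averaged prediction; ties go to the
    narrower network.  The full scan log is returned.
    """
    if N is None:
        N = data.n_in
    if N < 7:
        raise ValueError("N must be >= 7 so that N - 6 >= 1")
    candidates = list(range(N - 6, N + 7))
    val_mse = []
    for h in candidates:
        ens = train_ensemble(
            data, n_hidden=h, n_restarts=restarts_per_candidate,
            base_seed=base_seed, max_epochs=max_epochs, patience=patience,
        )
        r = ens.predict(data.X_val) - data.y_val
        val_mse.append(float(r @ r) / len(data.y_val))
    best = min(val_mse)
    chosen = min(c for c, v in zip(candidates, val_mse) if v == best)
    return ScanResult(candidates=candidates, val_mse=val_mse, chosen=chosen)
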
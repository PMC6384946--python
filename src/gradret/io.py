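"""CSV / JSON persistence for solute libraries, retention records and models.

Everything is plain text: designs and records travel as headered CSV with a
"." decimal point, fitted ensembles as a single JSON artifact holding the
architecture, every member's weights, the scaler and the seeds, so a model
reloads bit-exactly and stays human-diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .ann import AnnModel, EnsembleModel
from .features import Scaler
from .simulator import IsocraticRetentionParams

__all__ = [
    "load_model",
    "read_records",
    "read_solute_library",
    "save_model",
    "write_records",
    "write_solute_library",
]

_LIBRARY_COLUMNS = [
    "solute_id", "ln_kw_neutral", "S_neutral", "ln_kw_ion", "S_ion",
    "pKa", "charge_type", "pKa_phi_shift",
]


def write_solute_library(solutes: list[IsocraticRetentionParams], path) -> None:
    rows = [{c: getattr(p, c) for c in _LIBRARY_COLUMNS} for p in solutes]
    pd.DataFrame(rows, columns=_LIBRARY_COLUMNS).to_csv(path, index=False)


def read_solute_library(path) -> list[IsocraticRetentionParams]:
    frame = pd.read_csv(path)
    missing = set(_LIBRARY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"solute library {path} lacks columns {sorted(missing)}")
    return [
        IsocraticRetentionParams(
            solute_id=str(r.solute_id),
            ln_kw_neutral=float(r.ln_kw_neutral),
            S_neutral=float(r.S_neutral),
            ln_kw_ion=float(r.ln_kw_ion),
            S_ion=float(r.S_ion),
            pKa=float(r.pKa),
            charge_type=str(r.charge_type),
            pKa_phi_shift=float(r.pKa_phi_shift),
        )
        for r in frame.itertuples(index=False)
    ]


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    needed = {"run_id", "solute_id", "tR_min"}
    missing = needed - set(frame.columns)
    if missing:
        rowinfo = f" (columns found: {list(frame.columns)})"
        raise ValueError(f"records file {path} lacks columns {sorted(missing)}{rowinfo}")
    bad = frame.index[~(frame["tR_min"] > 0)].tolist()
    if bad:
        raise ValueError(f"records file {path}: non-positive tR_min at rows {bad}")
    return frame


def save_model(ensemble: EnsembleModel, path) -> None:
    payload = {
        "format": "gradret-ensemble-v1",
        "architecture": ensemble.architecture,
        "tag": ensemble.tag,
        "roster": list(ensemble.roster) if ensemble.roster else None,
        "base_seed": ensemble.base_seed,
        "scaler": ensemble.scaler.to_dict() if ensemble.scaler else None,
        "members": [m.to_dict() for m in ensemble.members],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> EnsembleModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "gradret-ensemble-v1":
        raise ValueError(f"{path} is not a gradret model artifact")
    return EnsembleModel(
        members=[AnnModel.from_dict(d) for d in payload["members"]],
        scaler=Scaler.from_dict(payload["scaler"]) if payload["scaler"] else None,
        tag=payload.get("tag"),
        roster=tuple(payload["roster"]) if payload.get("roster") else None,
        base_seed=payload.get("base_seed"),
    )
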
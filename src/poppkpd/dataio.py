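"""Dataset and result I/O.

Long-format study datasets are stored as NONMEM-style CSV with a
mandatory header (ID, TIME, AMT, EVID, MDV, DVID, DV, BLQ, DOSE) and
``.`` for missing values.  The generating truth record travels as a
JSON side-car next to the CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import DATASET_COLUMNS, PopulationDataset

__all__ = ["read_dataset", "write_dataset", "truth_sidecar_path"]

MISSING = "."


def truth_sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".truth.json")


def write_dataset(dataset: PopulationDataset, path: str | Path) -> None:
    """Write the dataset CSV (and truth side-car when present)."""
    path = Path(path)
    df = dataset.records.copy()
    out = df.astype(object).where(df.notna(), MISSING)
    out.to_csv(path, index=False, columns=DATASET_COLUMNS)
    if dataset.truth is not None:
        truth_sidecar_path(path).write_text(
            json.dumps(dataset.truth, indent=1, sort_keys=True)
        )


def read_dataset(path: str | Path, validate: bool = True) -> PopulationDataset:
    """Read a dataset CSV; raises ``ValueError`` on malformed input."""
    path = Path(path)
    df = pd.read_csv(path, na_values=[MISSING], keep_default_na=True)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns: {missing}")
    for col, dtype in (("ID", int), ("EVID", int), ("MDV", int), ("DVID", int), ("BLQ", int)):
        df[col] = df[col].astype(dtype)
    for col in ("TIME", "AMT", "DV", "DOSE"):
        df[col] = df[col].astype(float)

    truth = None
    sidecar = truth_sidecar_path(path)
    if sidecar.exists():
        truth = json.loads(sidecar.read_text())

    dataset = PopulationDataset(records=df, truth=truth)
    if validate:
        dataset.validate()
    return dataset
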
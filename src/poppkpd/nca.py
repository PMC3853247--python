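"""Non-compartmental analysis of concentration profiles.

Metrics: Cmax (maximum observed value), Tmax (its time, earliest on
ties) and AUClast (linear trapezoid to the last quantifiable point,
reported in ng*h/mL).  Group summaries report mean +/- sample SD with
percent CV and the median Tmax.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import DVID_PK, PopulationDataset

__all__ = [
    "NCAResult",
    "auc_last_trapezoid",
    "cmax_tmax",
    "nca_by_subject",
    "summarize_group",
]

PG_PER_NG = 1000.0


def _as_profile(profile: Sequence[tuple[float, float]] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(profile, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("profile must be a non-empty sequence of (time, value) pairs")
    t, v = arr[:, 0], arr[:, 1]
    if np.any(np.diff(t) <= 0):
        raise ValueError("profile times must be strictly increasing")
    return t, v


def cmax_tmax(profile: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Maximum observed value and its time; ties resolved to the earliest."""
    t, v = _as_profile(profile)
    i = int(np.argmax(v))  # argmax returns the first maximal index
    return float(v[i]), float(t[i])


def auc_last_trapezoid(profile: Sequence[tuple[float, float]]) -> float:
    """Linear-trapezoid AUC to the last point, converted pg*h/mL -> ng*h/mL."""
    t, v = _as_profile(profile)
    if t.size < 2:
        raise ValueError("AUC needs at least 2 observations")
    return float(np.trapezoid(v, t)) / PG_PER_NG


@dataclass(frozen=True)
class NCAResult:
    """Per-subject metrics and the per-group summary table."""

    subjects: pd.DataFrame  # ID, DOSE, cmax, tmax, auclast
    groups: pd.DataFrame    # DOSE, n, means/SDs/CVs, median tmax


def nca_by_subject(dataset: PopulationDataset, drop_blq: bool = True) -> pd.DataFrame:
    """Compute Cmax/Tmax/AUClast per subject from the PK observations.

    BLQ records are excluded from the metric support by default (M1
    policy); subjects left with fewer than 2 quantifiable points are
    skipped.
    """
    obs = dataset.observations(dvid=DVID_PK, drop_blq=drop_blq)
    rows = []
    for sid, grp in obs.groupby("ID"):
        grp = grp.sort_values("TIME")
        if len(grp) < 2:
            continue
        profile = list(zip(grp["TIME"].values, grp["DV"].values))
        cmax, tmax = cmax_tmax(profile)
        rows.append(
            {"ID": sid, "DOSE": float(grp["DOSE"].iloc[0]), "cmax": cmax,
             "tmax": tmax, "auclast": auc_last_trapezoid(profile)}
        )
    return pd.DataFrame(rows)


def summarize_group(
    subjects: pd.DataFrame, group_col: str = "DOSE"
) -> pd.DataFrame:
    """Group table: mean, sample SD (n-1), percent CV, median Tmax.

    Single-subject groups get SD = CV = 0 and ``degenerate = True``.
    """
    rows = []
    for dose, grp in subjects.groupby(group_col):
        n = len(grp)
        degenerate = n < 2
        row: dict = {"DOSE": dose, "n": n, "degenerate": degenerate}
        for metric in ("cmax", "auclast"):
            vals = grp[metric].values
            mean = float(np.mean(vals))
            sd = 0.0 if degenerate else float(np.std(vals, ddof=1))
            row[f"{metric}_mean"] = mean
            row[f"{metric}_sd"] = sd
            row[f"{metric}_cv"] = 0.0 if mean == 0 else 100.0 * sd / mean
        row["tmax_median"] = float(np.median(grp["tmax"].values))
        rows.append(row)
    return pd.DataFrame(rows).sort_values("DOSE").reset_index(drop=True)


def run_nca(dataset: PopulationDataset, drop_blq: bool = True) -> NCAResult:
    """Full NCA: per-subject metrics plus the group summary table."""
    subjects = nca_by_subject(dataset, drop_blq=drop_blq)
    return NCAResult(subjects=subjects, groups=summarize_group(subjects))
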
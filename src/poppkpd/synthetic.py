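"""Synthetic study generation.

Builds complete simulated trials with the single-ascending-dose design
(4 dose groups x 6 subjects, fixed rich sampling grids), log-normal
between-subject variability and the study's residual-error models, so
every downstream stage (NCA, estimation, evaluation) is testable
without external data.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .model_core import (
    DEFAULT_MIU_TO_UG,
    DoseEvent,
    PDParameters,
    PKParameters,
    pd_trajectory,
    pk_concentration,
)

__all__ = [
    "DATASET_COLUMNS",
    "IndividualParameters",
    "PopulationDataset",
    "RandomEffectsSpec",
    "ResidualErrorSpec",
    "StudyDesign",
    "apply_residual_error",
    "default_pd_error",
    "default_pk_error",
    "default_random_effects",
    "default_study_design",
    "draw_individual_parameters",
    "rng_stream",
    "simulate_study",
]

#: mandatory column order of the long-format dataset
DATASET_COLUMNS = ["ID", "TIME", "AMT", "EVID", "MDV", "DVID", "DV", "BLQ", "DOSE"]

#: DVID codes for the two observation types
DVID_PK = 1
DVID_PD = 2

_PK_TIMES = (0.0, 0.75, 1.5, 3, 6, 8, 10, 12, 18, 24, 30, 36, 48, 60, 72, 96,
             120, 144, 168, 192)
_PD_TIMES = (0.0, 3, 8, 12, 18, 24, 36, 48, 72, 96, 120, 144, 168, 192, 264)


def rng_stream(seed: int, label: str) -> np.random.Generator:
    """Named, reproducible substream fanned out from a single seed."""
    return np.random.default_rng([int(seed) & 0xFFFFFFFF, zlib.crc32(label.encode())])


@dataclass(frozen=True)
class StudyDesign:
    """Trial layout: dose groups, sampling grids, units, detection limits."""

    groups: tuple[tuple[float, int], ...] = ((9.0, 6), (18.0, 6), (27.0, 6), (36.0, 6))
    pk_times: tuple[float, ...] = _PK_TIMES
    pd_times: tuple[float, ...] = _PD_TIMES
    miu_to_ug: float = DEFAULT_MIU_TO_UG
    lloq_pk: float = 12.5  # pg/mL
    lloq_pd: float = 0.7   # nmol/L

    def __post_init__(self) -> None:
        for dose, n in self.groups:
            if dose <= 0:
                raise ValueError(f"group dose must be > 0, got {dose}")
            if n <= 0:
                raise ValueError(f"group size must be > 0, got {n}")
        for name, grid in (("pk_times", self.pk_times), ("pd_times", self.pd_times)):
            arr = np.asarray(grid, float)
            if np.any(arr < 0) or np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be sorted, unique and >= 0")

    @property
    def n_subjects(self) -> int:
        return sum(n for _, n in self.groups)

    def subject_doses(self) -> list[float]:
        """Flat per-subject dose list in subject-id order."""
        out: list[float] = []
        for dose, n in self.groups:
            out.extend([dose] * n)
        return out


def default_study_design() -> StudyDesign:
    """The reference trial design (24 subjects, printed sampling grids)."""
    return StudyDesign()


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Standard deviations of the log-scale random effects (diagonal)."""

    omega: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, sd in self.omega.items():
            if sd < 0 or not np.isfinite(sd):
                raise ValueError(f"omega[{name}] must be finite and >= 0, got {sd}")
        object.__setattr__(self, "omega", dict(self.omega))

    def sd(self, name: str) -> float:
        return float(self.omega.get(name, 0.0))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.omega)


def default_random_effects() -> tuple[RandomEffectsSpec, RandomEffectsSpec]:
    """Reference between-subject variabilities (PK spec, PD spec).

    Values are the reported percent CVs divided by 100, interpreted as
    standard deviations of the log-scale random effects.
    """
    pk = RandomEffectsSpec(
        {"cl_f": 0.261, "v_f": 0.238, "d2": 0.357, "rf": 0.347, "ka": 0.770}
    )
    pd = RandomEffectsSpec(
        {"base": 0.1385, "cb": 0.5731, "gamma": 0.1351, "ecb": 0.2131, "mtt": 0.1336}
    )
    return pk, pd


@dataclass(frozen=True)
class ResidualErrorSpec:
    """Residual (intra-individual) error model.

    ``combined`` observations are drawn as
    ``Y = IPRED + eps * sqrt(sigma_add^2 + (sigma_prop * IPRED)^2)``
    with a single standard-normal ``eps`` — the variance-correct reading
    of a combined additive/proportional error.
    """

    kind: str = "additive"
    sigma_add: float = 0.0
    sigma_prop: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown residual error kind {self.kind!r}")
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValueError("sigmas must be >= 0")
        if self.kind == "additive" and self.sigma_prop:
            raise ValueError("additive model must not set sigma_prop")
        if self.kind == "proportional" and self.sigma_add:
            raise ValueError("proportional model must not set sigma_add")

    def sd(self, ipred: np.ndarray | float) -> np.ndarray | float:
        """Residual standard deviation at the given prediction."""
        if self.kind == "additive":
            return np.broadcast_to(self.sigma_add, np.shape(ipred)).astype(float) \
                if np.ndim(ipred) else self.sigma_add
        if self.kind == "proportional":
            return self.sigma_prop * np.asarray(ipred, float)
        return np.sqrt(self.sigma_add**2 + (self.sigma_prop * np.asarray(ipred, float)) ** 2)

    def variance(self, ipred: np.ndarray | float) -> np.ndarray | float:
        sd = self.sd(ipred)
        return np.asarray(sd, float) ** 2 if np.ndim(sd) else sd**2


def default_pk_error() -> ResidualErrorSpec:
    """Reference PK residual model (combined)."""
    return ResidualErrorSpec(kind="combined", sigma_add=3.92, sigma_prop=0.078)


def default_pd_error() -> ResidualErrorSpec:
    """Reference PD residual model (additive)."""
    return ResidualErrorSpec(kind="additive", sigma_add=1.14)


@dataclass(frozen=True)
class IndividualParameters:
    """Realised parameters of one subject plus the etas that made them."""

    subject_id: int
    pk: PKParameters
    pd: PDParameters
    eta_pk: Mapping[str, float]
    eta_pd: Mapping[str, float]

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "pk": dataclasses.asdict(self.pk),
            "pd": dataclasses.asdict(self.pd),
            "eta_pk": dict(self.eta_pk),
            "eta_pd": dict(self.eta_pd),
        }


@dataclass
class PopulationDataset:
    """Long-format event/observation records for one study."""

    records: pd.DataFrame
    truth: dict | None = None

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"dataset missing mandatory columns: {missing}")
        self.records = self.records[DATASET_COLUMNS].reset_index(drop=True)

    @property
    def subject_ids(self) -> list[int]:
        return sorted(self.records["ID"].unique())

    def observations(self, dvid: int | None = None, drop_blq: bool = False) -> pd.DataFrame:
        obs = self.records[self.records["EVID"] == 0]
        if dvid is not None:
            obs = obs[obs["DVID"] == dvid]
        if drop_blq:
            obs = obs[obs["BLQ"] == 0]
        return obs

    def doses(self) -> pd.DataFrame:
        return self.records[self.records["EVID"] == 1]

    def validate(self) -> None:
        """Raise ``ValueError`` on structural violations."""
        for sid, grp in self.records.groupby("ID"):
            n_dose = int((grp["EVID"] == 1).sum())
            if n_dose != 1:
                raise ValueError(f"subject {sid}: expected 1 dose record, found {n_dose}")
            if grp["TIME"].values[0] != 0 or grp["EVID"].values[0] != 1:
                raise ValueError(f"subject {sid}: first record must be the dose at t=0")
            obs = grp[grp["EVID"] == 0]
            for dvid, sub in obs.groupby("DVID"):
                if np.any(np.diff(sub["TIME"].values) < 0):
                    raise ValueError(f"subject {sid}: unsorted times for DVID {dvid}")


def draw_individual_parameters(
    pk_typical: PKParameters,
    pd_typical: PDParameters,
    pk_iiv: RandomEffectsSpec,
    pd_iiv: RandomEffectsSpec,
    n: int,
    seed: int | np.random.Generator,
) -> list[IndividualParameters]:
    """Draw ``n`` subjects' parameters as ``P = TVP * exp(eta)``.

    Each eta is independent ``Normal(0, omega^2)``; parameters with no
    listed omega get eta = 0.  The same seed reproduces identical draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else rng_stream(seed, "iiv")
    out = []
    for j in range(n):
        eta_pk = {name: rng.normal(0.0, pk_iiv.sd(name)) for name in pk_iiv.names}
        eta_pd = {name: rng.normal(0.0, pd_iiv.sd(name)) for name in pd_iiv.names}
        out.append(
            IndividualParameters(
                subject_id=j + 1,
                pk=pk_typical.with_eta(eta_pk),
                pd=pd_typical.with_eta(eta_pd),
                eta_pk=eta_pk,
                eta_pd=eta_pd,
            )
        )
    return out


def apply_residual_error(
    ipred: np.ndarray | float,
    spec: ResidualErrorSpec,
    rng: np.random.Generator,
) -> np.ndarray | float:
    """Add one residual-error draw per prediction."""
    ipred_arr = np.asarray(ipred, float)
    if np.any(ipred_arr < 0):
        raise ValueError("ipred must be >= 0")
    eps = rng.standard_normal(ipred_arr.shape)
    out = ipred_arr + eps * spec.sd(ipred_arr)
    return out if np.ndim(ipred) else float(out)


def simulate_study(
    design: StudyDesign,
    pk_typical: PKParameters,
    pd_typical: PDParameters,
    pk_iiv: RandomEffectsSpec,
    pd_iiv: RandomEffectsSpec,
    pk_error: ResidualErrorSpec,
    pd_error: ResidualErrorSpec,
    seed: int,
    *,
    include_pd: bool = True,
    flag_blq: bool = True,
) -> PopulationDataset:
    """Simulate one complete study under the given design and model.

    Per subject: one dose record at t=0, PK observations at every PK
    grid point and (optionally) PD observations at every PD grid point.
    Predose PK is simulated as 0 (no endogenous drug).  Values below the
    detection limits are flagged, not dropped.  The generating
    individual parameters are retained in ``dataset.truth``.
    """
    rng_iiv = rng_stream(seed, "iiv")
    rng_res = rng_stream(seed, "residual")
    individuals = draw_individual_parameters(
        pk_typical, pd_typical, pk_iiv, pd_iiv, design.n_subjects, rng_iiv
    )

    doses = design.subject_doses()
    pk_t = np.asarray(design.pk_times, float)
    pd_t = np.asarray(design.pd_times, float)
    rows: list[dict] = []
    for ind, dose_miu in zip(individuals, doses):
        sid = ind.subject_id
        dose = DoseEvent(amount=dose_miu, time=0.0)
        rows.append(
            {"ID": sid, "TIME": 0.0, "AMT": dose_miu, "EVID": 1, "MDV": 1,
             "DVID": 0, "DV": np.nan, "BLQ": 0, "DOSE": dose_miu}
        )
        try:
            cpred = pk_concentration(ind.pk, dose, pk_t, design.miu_to_ug)
            cpred = np.where(pk_t == 0.0, 0.0, cpred)  # predose: no endogenous drug
            y_pk = apply_residual_error(cpred, pk_error, rng_res)
            if include_pd:
                a4 = pd_trajectory(ind.pk, ind.pd, dose, pd_t, miu_to_ug=design.miu_to_ug)
                y_pd = apply_residual_error(a4, pd_error, rng_res)
        except Exception as exc:  # add subject context to integration failures
            raise type(exc)(f"subject {sid}: {exc}") from exc

        for t, y in zip(pk_t, y_pk):
            rows.append(
                {"ID": sid, "TIME": t, "AMT": np.nan, "EVID": 0, "MDV": 0,
                 "DVID": DVID_PK, "DV": y,
                 "BLQ": int(flag_blq and y < design.lloq_pk), "DOSE": dose_miu}
            )
        if include_pd:
            for t, y in zip(pd_t, y_pd):
                rows.append(
                    {"ID": sid, "TIME": t, "AMT": np.nan, "EVID": 0, "MDV": 0,
                     "DVID": DVID_PD, "DV": y,
                     "BLQ": int(flag_blq and y < design.lloq_pd), "DOSE": dose_miu}
                )

    truth = {
        "seed": int(seed),
        "typical_pk": dataclasses.asdict(pk_typical),
        "typical_pd": dataclasses.asdict(pd_typical),
        "omega_pk": dict(pk_iiv.omega),
        "omega_pd": dict(pd_iiv.omega),
        "pk_error": dataclasses.asdict(pk_error),
        "pd_error": dataclasses.asdict(pd_error),
        "miu_to_ug": design.miu_to_ug,
        "individuals": [ind.to_dict() for ind in individuals],
    }
    return PopulationDataset(records=pd.DataFrame(rows), truth=truth)
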
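"""Structural PK-PD model mathematics.

The drug model is a one-compartment disposition with first-order
elimination fed by two parallel absorption routes: a zero-order
(constant-rate) input active on ``[0, d2]`` and a lagged first-order
input starting at ``alag``.  The response model is a turnover
(indirect-response) system with a single transit compartment; drug
stimulates the zero-order production of the response marker through a
sigmoid function whose half-maximal concentration rises over time
following the CDF of an exponential distribution.

Concentrations are in pg/mL, response in nmol/L, times in hours.  Doses
are given in MIU and converted to mass with a configurable factor
(``DEFAULT_MIU_TO_UG`` micrograms per MIU by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DEFAULT_MIU_TO_UG",
    "DoseEvent",
    "IntegrationError",
    "PDParameters",
    "PKParameters",
    "default_pd_parameters",
    "default_pk_parameters",
    "dose_to_pg",
    "ec50_at_time",
    "pd_trajectory",
    "pk_concentration",
    "stimulation_effect",
    "zero_order_fraction",
]

#: micrograms of protein per MIU (typical IFN-alpha specific activity
#: ~2e8 IU/mg).  A documented convention, not a measured quantity; all
#: downstream results are either invariant to it or use it consistently.
DEFAULT_MIU_TO_UG = 5.0


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to produce a trajectory."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be a finite positive number, got {value!r}")


@dataclass(frozen=True)
class PKParameters:
    """Fixed-effect drug-disposition parameters.

    Attributes
    ----------
    cl_f : apparent clearance (L/h)
    v_f : apparent volume of distribution (L)
    d2 : duration of the zero-order input (h)
    ka : first-order absorption rate constant (1/h)
    alag : lag before first-order absorption starts (h)
    rf : unconstrained real; the zero-order dose fraction is
        ``logistic(rf)`` (see :func:`zero_order_fraction`)
    """

    cl_f: float
    v_f: float
    d2: float
    ka: float
    alag: float
    rf: float

    def __post_init__(self) -> None:
        _require_positive(cl_f=self.cl_f, v_f=self.v_f, d2=self.d2, ka=self.ka)
        if not math.isfinite(self.alag) or self.alag < 0:
            raise ValueError(f"alag must be finite and >= 0, got {self.alag!r}")
        if not math.isfinite(self.rf):
            raise ValueError(f"rf must be finite, got {self.rf!r}")

    @property
    def ke(self) -> float:
        """First-order elimination rate constant (1/h)."""
        return self.cl_f / self.v_f

    @property
    def fz(self) -> float:
        """Fraction of the dose absorbed through the zero-order route."""
        return zero_order_fraction(self.rf)

    def with_eta(self, eta: Mapping[str, float]) -> "PKParameters":
        """Return individual parameters ``P = TVP * exp(eta)`` per field."""
        updates = {name: getattr(self, name) * math.exp(e) for name, e in eta.items()}
        return replace(self, **updates)


@dataclass(frozen=True)
class PDParameters:
    """Fixed-effect turnover-response parameters.

    Attributes
    ----------
    base : baseline response-marker concentration (nmol/L)
    kout : first-order loss rate of the marker (1/h)
    emax : maximum stimulation of production (unitless)
    gamma : Hill coefficient (unitless)
    ca : plateau coefficient of the EC50 rise (unitless)
    cb : rate constant of the EC50 rise (1/h)
    ecb : EC50 at time zero (pg/mL)
    mtt : mean transit time of the single transit compartment (h)
    """

    base: float
    kout: float
    emax: float
    gamma: float
    ca: float
    cb: float
    ecb: float
    mtt: float

    def __post_init__(self) -> None:
        _require_positive(
            base=self.base,
            kout=self.kout,
            emax=self.emax,
            gamma=self.gamma,
            ca=self.ca,
            cb=self.cb,
            ecb=self.ecb,
            mtt=self.mtt,
        )

    @property
    def kin(self) -> float:
        """Zero-order production rate fixed by the baseline steady state."""
        return self.kout * self.base

    @property
    def ktr(self) -> float:
        """Transit rate constant, reciprocal of the mean transit time."""
        return 1.0 / self.mtt

    def with_eta(self, eta: Mapping[str, float]) -> "PDParameters":
        """Return individual parameters ``P = TVP * exp(eta)`` per field."""
        updates = {name: getattr(self, name) * math.exp(e) for name, e in eta.items()}
        return replace(self, **updates)


@dataclass(frozen=True)
class DoseEvent:
    """A single subcutaneous dose: ``amount`` in MIU at ``time`` hours.

    ``amount == 0`` is allowed and denotes a drug-free (placebo) run.
    """

    amount: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.amount) or self.amount < 0:
            raise ValueError(f"dose amount must be finite and >= 0, got {self.amount!r}")
        if not math.isfinite(self.time) or self.time < 0:
            raise ValueError(f"dose time must be finite and >= 0, got {self.time!r}")


def default_pk_parameters() -> PKParameters:
    """Reference population PK estimates used as simulation defaults."""
    return PKParameters(cl_f=12.2, v_f=691.0, d2=20.2, ka=0.00653, alag=85.7, rf=0.185)


def default_pd_parameters() -> PDParameters:
    """Reference population PD estimates used as simulation defaults."""
    return PDParameters(
        base=5.85, kout=0.0311, emax=16.1, gamma=1.24, ca=405.0, cb=0.0068,
        ecb=2.17, mtt=14.6,
    )


def zero_order_fraction(rf: float) -> float:
    """Map the unconstrained ``rf`` to the zero-order dose fraction.

    Uses the logistic transform ``1 / (1 + exp(-rf))``, strictly
    increasing with values in (0, 1).
    """
    if not math.isfinite(rf):
        raise ValueError(f"rf must be finite, got {rf!r}")
    # numerically stable logistic
    if rf >= 0:
        return 1.0 / (1.0 + math.exp(-rf))
    z = math.exp(rf)
    return z / (1.0 + z)


def dose_to_pg(amount_miu: float, miu_to_ug: float = DEFAULT_MIU_TO_UG) -> float:
    """Convert a dose in MIU to picograms via the mass-activity factor."""
    if amount_miu < 0:
        raise ValueError("dose amount must be >= 0")
    return amount_miu * miu_to_ug * 1e6


def pk_concentration(
    p: PKParameters,
    dose: DoseEvent,
    t: float | Sequence[float] | np.ndarray,
    miu_to_ug: float = DEFAULT_MIU_TO_UG,
) -> np.ndarray | float:
    """Analytic drug concentration (pg/mL) at times ``t`` (hours post dose).

    The profile is the superposition of the zero-order route (constant
    rate ``fz*D/d2`` on ``[0, d2]``) and the lagged first-order route
    ((1-fz)*D absorbed at rate ``ka`` from ``alag``), both eliminated at
    ``ke = cl_f/v_f``.  The response is continuous and linear in dose.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(~np.isfinite(t_arr)) or np.any(t_arr < 0):
        raise ValueError("times must be finite and >= 0")

    d_pg = dose_to_pg(dose.amount, miu_to_ug)
    ke = p.ke
    fz = p.fz

    tau0 = t_arr - dose.time  # time since dose; dose.time is usually 0
    tau0 = np.where(tau0 < 0, 0.0, tau0)

    # zero-order route: accumulation during input, mono-exponential after
    r0 = fz * d_pg / p.d2
    t_in = np.minimum(tau0, p.d2)
    a_zero = (r0 / ke) * (1.0 - np.exp(-ke * t_in)) * np.exp(
        -ke * np.maximum(tau0 - p.d2, 0.0)
    )

    # first-order route from the lag time
    tau1 = np.maximum(tau0 - p.alag, 0.0)
    if abs(p.ka - ke) <= 1e-10 * max(p.ka, ke):
        kernel = ke * tau1 * np.exp(-ke * tau1)  # analytic ka -> ke limit
    else:
        kernel = (p.ka / (p.ka - ke)) * (np.exp(-ke * tau1) - np.exp(-p.ka * tau1))
    a_first = (1.0 - fz) * d_pg * kernel

    conc = (a_zero + a_first) / (p.v_f * 1e3)  # pg / mL
    return float(conc[0]) if scalar else conc


def ec50_at_time(p: PDParameters, t: float | np.ndarray) -> np.ndarray | float:
    """Time-varying EC50 (pg/mL): ``ecb * (1 + ca * (1 - exp(-cb*t)))``.

    Monotone non-decreasing in ``t``, rising from ``ecb`` at time zero
    toward the plateau ``ecb * (1 + ca)``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(~np.isfinite(t_arr)):
        raise ValueError("time must be finite and >= 0")
    out = p.ecb * (1.0 + p.ca * (1.0 - np.exp(-p.cb * t_arr)))
    return float(out) if np.ndim(t) == 0 else out


def stimulation_effect(
    c: float | np.ndarray, emax: float, ec50: float | np.ndarray, gamma: float
) -> np.ndarray | float:
    """Sigmoid production multiplier ``1 + emax*c^g / (ec50^g + c^g)``.

    Bounded in ``[1, 1 + emax]`` and monotone increasing in ``c``.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0) or np.any(~np.isfinite(c_arr)):
        raise ValueError("concentration must be finite and >= 0")
    ec50_arr = np.asarray(ec50, dtype=float)
    if np.any(ec50_arr <= 0):
        raise ValueError("ec50 must be > 0")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    # (ec50/c)^gamma form avoids overflow for large c
    with np.errstate(divide="ignore"):
        ratio = np.where(c_arr > 0, (ec50_arr / np.where(c_arr > 0, c_arr, 1.0)) ** gamma, np.inf)
    out = 1.0 + emax / (1.0 + ratio)
    return float(out) if (np.ndim(c) == 0 and np.ndim(ec50) == 0) else out


def _pd_rhs_factory(
    pd: PDParameters, conc: Callable[[float], float]
) -> Callable[[float, np.ndarray], list[float]]:
    kin, ktr, kout = pd.kin, pd.ktr, pd.kout

    def rhs(t: float, y: np.ndarray) -> list[float]:
        c = conc(t)
        e = stimulation_effect(c, pd.emax, ec50_at_time(pd, t), pd.gamma)
        a3, a4 = y
        return [kin * e - ktr * a3, ktr * a3 - kout * a4]

    return rhs


def pd_trajectory(
    pk: PKParameters,
    pd: PDParameters,
    dose: DoseEvent,
    times: Sequence[float] | np.ndarray,
    *,
    miu_to_ug: float = DEFAULT_MIU_TO_UG,
    concentration: Callable[[float], float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    return_states: bool = False,
) -> np.ndarray:
    """Response-marker concentrations (nmol/L) at the requested times.

    Integrates the two turnover states from the drug-free steady state
    ``A3(0) = kin/ktr``, ``A4(0) = base`` with the analytic drug
    concentration as forcing function.  Integration is split at the
    kinks of the forcing function (end of zero-order input, absorption
    lag) so the adaptive solver never steps across a derivative jump.

    Parameters
    ----------
    concentration
        Optional override of the forcing function ``C(t)``; used for
        forcing-function tests (e.g. constant concentration).
    return_states
        If true, return the full ``(len(times), 2)`` state array
        ``[A3, A4]`` instead of only ``A4``.
    """
    t_req = np.asarray(times, dtype=float)
    if t_req.ndim != 1 or t_req.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t_req) < 0) or np.any(t_req < 0):
        raise ValueError("times must be sorted and >= 0")

    if concentration is None:
        conc = lambda t: pk_concentration(pk, dose, t, miu_to_ug)  # noqa: E731
        kinks = sorted({pk.d2, pk.alag})
    else:
        conc = concentration
        kinks = []

    rhs = _pd_rhs_factory(pd, conc)
    y0 = np.array([pd.kin / pd.ktr, pd.base])
    t_end = float(t_req[-1])

    # segment boundaries: 0, interior kinks, end
    bounds = [0.0] + [k for k in kinks if 0.0 < k < t_end] + [t_end]
    out = np.empty((t_req.size, 2))
    # requested time 0 is the initial condition
    done = t_req == 0.0
    out[done] = y0
    y = y0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            continue
        mask = (~done) & (t_req > lo) & (t_req <= hi)
        t_eval = t_req[mask]
        sol = solve_ivp(
            rhs,
            (lo, hi),
            y,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE integration failed on [{lo}, {hi}]: {sol.message}"
            )
        if t_eval.size:
            out[mask] = sol.sol(t_eval).T
        y = sol.sol(hi)

    if return_states:
        return out
    return out[:, 1]
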
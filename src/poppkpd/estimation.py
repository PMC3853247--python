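"""Approximate-marginal-likelihood population estimation.

The population objective is minus twice the Laplace-approximated log
marginal likelihood, summed over subjects.  For each subject the
conditional -2 log-likelihood (residual term with interaction plus the
Gaussian random-effect penalty) is minimised over the subject's etas by
a damped Gauss-Newton iteration; the log-determinant term uses the
Gauss-Newton (expected-information) Hessian at the mode, which makes
the approximation exact for linear-Gaussian models and is the classic
first-order-conditional-with-interaction flavour of the Laplace family.

PK and PD are coupled sequentially: the PK model is fitted first, each
subject's empirical Bayes parameters are fixed, and the PD model is
fitted conditional on them (the drug concentration forcing function is
then precomputed per subject, which is what makes the PD fit cheap).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._ode import half_step_times, pd_rk4_batch, stimulation_grid
from .model_core import (
    DEFAULT_MIU_TO_UG,
    DoseEvent,
    PDParameters,
    PKParameters,
    pk_concentration,
)
from .synthetic import (
    DVID_PD,
    DVID_PK,
    PopulationDataset,
    ResidualErrorSpec,
)

__all__ = [
    "FitResult",
    "LRT_THRESHOLD_PER_DF",
    "PD_ETA_NAMES",
    "PK_ETA_NAMES",
    "compare_models",
    "compute_ebes",
    "conditional_m2ll",
    "fit_pd",
    "fit_pk",
    "laplace_ofv",
    "marginal_ofv_pd",
    "marginal_ofv_pk",
]

LOG_2PI = math.log(2.0 * math.pi)

#: chi-square 0.05 critical value per added parameter
LRT_THRESHOLD_PER_DF = 3.84

#: parameters carrying between-subject variability
PK_ETA_NAMES = ("cl_f", "v_f", "d2", "rf", "ka")
PD_ETA_NAMES = ("base", "cb", "gamma", "ecb", "mtt")

_PENALTY_OFV = 1e10  # returned when a candidate parameter vector fails


def conditional_m2ll(
    y: np.ndarray,
    ipred: np.ndarray,
    eta: np.ndarray,
    omega_sd: np.ndarray,
    res_spec: ResidualErrorSpec,
) -> float:
    """Penalised individual -2 log-likelihood.

    ``sum[log(2 pi var) + (y - ipred)^2 / var] + eta' Omega^-1 eta +
    log det(2 pi Omega)`` with the residual variance evaluated at the
    individual prediction (interaction).
    """
    y = np.asarray(y, float)
    ipred = np.asarray(ipred, float)
    eta = np.asarray(eta, float)
    omega_sd = np.asarray(omega_sd, float)
    var = np.asarray(res_spec.variance(ipred), float)
    if np.any(var <= 0):
        raise ValueError("residual variance must be > 0 at every observation")
    out = float(np.sum(np.log(2.0 * np.pi * var) + (y - ipred) ** 2 / var))
    if eta.size:
        if np.any(omega_sd <= 0):
            raise ValueError(
                "singular Omega: every omega with an eta must be > 0 (apply an omega floor)"
            )
        out += float(np.sum(eta**2 / omega_sd**2))
        out += float(np.sum(np.log(2.0 * np.pi * omega_sd**2)))
    return out


def _obs_m2ll(y: np.ndarray, f: np.ndarray, res_spec: ResidualErrorSpec) -> float:
    # inf is a legitimate outcome for wild trial points; the line search
    # rejects it, so overflow is expected rather than exceptional here
    with np.errstate(over="ignore"):
        var = np.asarray(res_spec.variance(f), float)
        return float(np.sum(np.log(2.0 * np.pi * var) + (y - f) ** 2 / var))


def _inner_laplace(
    y: np.ndarray,
    predict: Callable[[np.ndarray], np.ndarray],
    omega_sd: np.ndarray,
    res_spec: ResidualErrorSpec,
    eta0: np.ndarray,
    gtol: float = 1e-6,
    max_iter: int = 50,
    fd_step: float = 1e-4,
) -> tuple[np.ndarray, float]:
    """Mode-find the subject's etas and return the Laplace contribution.

    ``predict`` maps an ``(m, d)`` eta matrix to ``(m, n_obs)``
    predictions.  Returns ``(eta_hat, -2 log marginal contribution)``.
    """
    d = omega_sd.size
    if d == 0:
        f = predict(np.zeros((1, 0)))[0]
        return np.zeros(0), _obs_m2ll(y, f, res_spec)
    if y.size == 0:
        # no information: mode at zero, penalty and determinant cancel exactly
        return np.zeros(d), 0.0

    if np.any(omega_sd <= 0):
        raise ValueError(
            "singular Omega: every omega with an eta must be > 0 (apply an omega floor)"
        )
    inv_om2 = 1.0 / omega_sd**2
    pen_const = float(np.sum(np.log(2.0 * np.pi * omega_sd**2)))

    def full_m2ll(f: np.ndarray, eta: np.ndarray) -> float:
        return _obs_m2ll(y, f, res_spec) + float(np.sum(eta**2 * inv_om2)) + pen_const

    eta = np.asarray(eta0, float).copy()
    lam = 0.0
    sp2 = res_spec.sigma_prop**2 if res_spec.kind in ("proportional", "combined") else 0.0

    # Damped Gauss-Newton.  All exit paths leave the loop right after a
    # Jacobian evaluation at (or within 1e-10 of) the final eta, so the
    # Laplace determinant reuses it without a second evaluation.
    it = 0
    while True:
        mat = np.tile(eta, (2 * d + 1, 1))
        for i in range(d):
            mat[2 * i + 1, i] += fd_step
            mat[2 * i + 2, i] -= fd_step
        preds = predict(mat)
        f0 = preds[0]
        jac = (preds[1::2] - preds[2::2]).T / (2.0 * fd_step)  # (n, d)
        m2 = full_m2ll(f0, eta)
        var = np.asarray(res_spec.variance(f0), float)
        r = y - f0
        grad = jac.T @ (-2.0 * r / var) + 2.0 * inv_om2 * eta
        if sp2:
            dvar = 2.0 * sp2 * f0[:, None] * jac  # (n, d)
            grad = grad + dvar.T @ (1.0 / var - r**2 / var**2)
        if np.max(np.abs(grad)) < gtol or it >= max_iter:
            break

        hess = 2.0 * (jac.T @ (jac / var[:, None]) + np.diag(inv_om2))
        improved = False
        step = np.zeros(d)
        for _try in range(12):
            try:
                step = np.linalg.solve(hess + lam * np.eye(d), -grad)
            except np.linalg.LinAlgError:
                lam = max(lam * 10.0, 1e-6)
                continue
            cand = eta + step
            f_c = predict(cand[None, :])[0]
            m2_c = full_m2ll(f_c, cand)
            if np.isfinite(m2_c) and m2_c <= m2 + 1e-12:
                eta = cand
                lam = lam / 3.0 if lam > 1e-12 else 0.0
                improved = True
                break
            lam = max(lam * 10.0, 1e-4)
        if not improved:
            break
        if np.max(np.abs(step)) < 1e-10:
            eta = eta - step  # keep eta consistent with the cached Jacobian
            break
        it += 1

    m2_hat = m2
    half_hess = jac.T @ (jac / var[:, None]) + np.diag(inv_om2)
    sign, logdet = np.linalg.slogdet(half_hess)
    if sign <= 0:
        raise FloatingPointError("non positive-definite Laplace Hessian")
    return eta, m2_hat + logdet - d * LOG_2PI


def laplace_ofv(
    problems: Sequence[tuple[np.ndarray, Callable[[np.ndarray], np.ndarray]]],
    omega_sd: np.ndarray,
    res_spec: ResidualErrorSpec,
    warm: dict[int, np.ndarray] | None = None,
    gtol: float = 1e-6,
    max_iter: int = 50,
) -> tuple[float, list[np.ndarray]]:
    """Population OFV: sum of per-subject Laplace contributions.

    ``problems`` is a list of ``(y, predict)`` pairs, one per subject.
    ``warm`` optionally maps the subject index to a starting eta.
    ``gtol``/``max_iter`` control the inner mode search; the outer
    optimiser uses a relaxed ``gtol`` for speed (the OFV is stationary
    at the mode, so the induced error is second order) and the final
    reported OFV/EBEs are recomputed at the strict default.
    """
    omega_sd = np.asarray(omega_sd, float)
    total = 0.0
    etas: list[np.ndarray] = []
    for i, (y, predict) in enumerate(problems):
        eta0 = warm.get(i, np.zeros(omega_sd.size)) if warm is not None else np.zeros(omega_sd.size)
        eta, contrib = _inner_laplace(y, predict, omega_sd, res_spec, eta0,
                                      gtol=gtol, max_iter=max_iter)
        if warm is not None:
            warm[i] = eta
        total += contrib
        etas.append(eta)
    return total, etas


# ---------------------------------------------------------------------------
# model adapters
# ---------------------------------------------------------------------------


@dataclass
class _Subject:
    sid: int
    dose_miu: float
    times: np.ndarray
    y: np.ndarray


def _extract_subjects(
    dataset: PopulationDataset, dvid: int, drop_blq: bool = True
) -> list[_Subject]:
    obs = dataset.observations(dvid=dvid, drop_blq=drop_blq)
    doses = dataset.doses().set_index("ID")["AMT"]
    out = []
    for sid in dataset.subject_ids:
        grp = obs[obs["ID"] == sid].sort_values("TIME")
        out.append(
            _Subject(
                sid=int(sid),
                dose_miu=float(doses.loc[sid]),
                times=grp["TIME"].values.astype(float),
                y=grp["DV"].values.astype(float),
            )
        )
    return out


def _pk_conc_batch(
    cl: np.ndarray, v: np.ndarray, d2: np.ndarray, ka: np.ndarray,
    alag: np.ndarray, rf: np.ndarray, dose_pg: float, times: np.ndarray,
) -> np.ndarray:
    """Vectorised analytic concentration for a batch of parameter sets.

    Mirrors :func:`poppkpd.model_core.pk_concentration` (their agreement
    is asserted in the test suite); exists because the inner eta search
    evaluates many perturbed parameter sets per subject.
    """
    ke = (cl / v)[:, None]
    fz = 1.0 / (1.0 + np.exp(-rf))[:, None]
    d2c = d2[:, None]
    t = times[None, :]

    r0 = fz * dose_pg / d2c
    t_in = np.minimum(t, d2c)
    a_zero = (r0 / ke) * (1.0 - np.exp(-ke * t_in)) * np.exp(
        -ke * np.maximum(t - d2c, 0.0)
    )

    kac = ka[:, None]
    tau = np.maximum(t - alag[:, None], 0.0)
    diff = kac - ke
    safe = np.where(np.abs(diff) > 1e-10 * np.maximum(kac, ke), diff, 1.0)
    kernel = np.where(
        np.abs(diff) > 1e-10 * np.maximum(kac, ke),
        (kac / safe) * (np.exp(-ke * tau) - np.exp(-kac * tau)),
        ke * tau * np.exp(-ke * tau),
    )
    a_first = (1.0 - fz) * dose_pg * kernel
    return (a_zero + a_first) / (v[:, None] * 1e3)


def _pk_predict_factory(
    theta: PKParameters, subject: _Subject, miu_to_ug: float
) -> Callable[[np.ndarray], np.ndarray]:
    from .model_core import dose_to_pg

    dose_pg = dose_to_pg(subject.dose_miu, miu_to_ug)
    times = subject.times

    def predict(eta_mat: np.ndarray) -> np.ndarray:
        # eta columns follow PK_ETA_NAMES = (cl_f, v_f, d2, rf, ka)
        e = np.exp(np.clip(eta_mat, -20.0, 20.0))
        return _pk_conc_batch(
            theta.cl_f * e[:, 0],
            theta.v_f * e[:, 1],
            theta.d2 * e[:, 2],
            theta.ka * e[:, 4],
            np.full(eta_mat.shape[0], theta.alag),
            theta.rf * e[:, 3],
            dose_pg,
            times,
        )

    return predict


class _PDForcing:
    """Per-subject precomputed drug-concentration grid for the RK4 path."""

    def __init__(
        self,
        pk_individual: PKParameters,
        dose_miu: float,
        t_end: float,
        dt: float,
        miu_to_ug: float,
    ) -> None:
        self.dt = dt
        self.t_grid, self.n_steps = half_step_times(max(t_end, dt), dt)
        dose = DoseEvent(amount=dose_miu, time=0.0)
        self.c_half = np.asarray(
            pk_concentration(pk_individual, dose, self.t_grid, miu_to_ug), float
        )
        with np.errstate(divide="ignore"):
            self.log_c = np.log(self.c_half)  # -inf where concentration is 0


def _pd_predict_factory(
    theta: PDParameters, subject: _Subject, forcing: _PDForcing
) -> Callable[[np.ndarray], np.ndarray]:
    times = subject.times

    def predict(eta_mat: np.ndarray) -> np.ndarray:
        m = eta_mat.shape[0]
        e = np.exp(np.clip(eta_mat, -20.0, 20.0))
        base = theta.base * e[:, 0]
        cb = theta.cb * e[:, 1]
        gamma = theta.gamma * e[:, 2]
        ecb = theta.ecb * e[:, 3]
        mtt = theta.mtt * e[:, 4]
        kout = np.full(m, theta.kout)
        kin = kout * base
        ktr = 1.0 / mtt
        emax = np.full(m, theta.emax)
        ca = np.full(m, theta.ca)
        effect = stimulation_grid(
            forcing.log_c, forcing.t_grid, emax, gamma, ecb, ca, cb
        )
        return pd_rk4_batch(kin[:, None] * effect, forcing.dt, times, ktr, kout)

    return predict


def _active_eta_problems(problems, omega, names):
    """Drop eta dimensions whose omega is 0 (no variability) by wrapping
    each predict to zero-fill the inactive columns."""
    active = [i for i, n in enumerate(names) if omega.get(n, 0.0) > 0]
    omega_sd = np.array([omega[names[i]] for i in active])
    d_full = len(names)

    def wrap(predict):
        def wrapped(eta_red: np.ndarray) -> np.ndarray:
            full = np.zeros((eta_red.shape[0], d_full))
            full[:, active] = eta_red
            return predict(full)

        return wrapped

    wrapped_problems = [(y, wrap(predict)) for y, predict in problems]
    def expand(etas):
        out = []
        for eta in etas:
            full = np.zeros(d_full)
            full[active] = eta
            out.append(full)
        return out

    return wrapped_problems, omega_sd, expand


def marginal_ofv_pk(
    dataset: PopulationDataset,
    theta: PKParameters,
    omega: Mapping[str, float],
    sigma: ResidualErrorSpec,
    *,
    miu_to_ug: float = DEFAULT_MIU_TO_UG,
    warm: dict[int, np.ndarray] | None = None,
) -> tuple[float, list[np.ndarray]]:
    """Population OFV of the PK model on the dataset's PK observations."""
    subjects = _extract_subjects(dataset, DVID_PK)
    problems = [
        (s.y, _pk_predict_factory(theta, s, miu_to_ug)) for s in subjects
    ]
    problems, omega_sd, expand = _active_eta_problems(problems, omega, PK_ETA_NAMES)
    ofv, etas = laplace_ofv(problems, omega_sd, sigma, warm)
    return ofv, expand(etas)


def marginal_ofv_pd(
    dataset: PopulationDataset,
    ebes: Mapping[int, PKParameters],
    theta: PDParameters,
    omega: Mapping[str, float],
    sigma: ResidualErrorSpec,
    *,
    miu_to_ug: float = DEFAULT_MIU_TO_UG,
    dt: float = 0.5,
    warm: dict[int, np.ndarray] | None = None,
) -> tuple[float, list[np.ndarray]]:
    """Population OFV of the PD model with fixed per-subject PK."""
    subjects = _extract_subjects(dataset, DVID_PD)
    problems = []
    for s in subjects:
        t_end = float(s.times[-1]) if s.times.size else dt
        forcing = _PDForcing(ebes[s.sid], s.dose_miu, t_end, dt, miu_to_ug)
        problems.append((s.y, _pd_predict_factory(theta, s, forcing)))
    problems, omega_sd, expand = _active_eta_problems(problems, omega, PD_ETA_NAMES)
    ofv, etas = laplace_ofv(problems, omega_sd, sigma, warm)
    return ofv, expand(etas)


# ---------------------------------------------------------------------------
# outer optimisation
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a population fit."""

    theta: dict[str, float]
    omega: dict[str, float]
    sigma: dict[str, float]
    ofv: float
    eta_names: tuple[str, ...]
    ebes: dict[int, np.ndarray]
    converged: bool
    n_evals: int
    trace: list[float] = field(default_factory=list)
    se: dict[str, float] | None = None
    meta: dict = field(default_factory=dict)

    def estimates(self) -> dict[str, float]:
        """Flat name -> estimate mapping (theta, om_*, sig_*)."""
        out = dict(self.theta)
        out.update({f"om_{k}": v for k, v in self.omega.items()})
        out.update({f"sig_{k}": v for k, v in self.sigma.items()})
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, value in self.estimates().items():
            rse = None
            if self.se is not None and name in self.se and value != 0:
                rse = 100.0 * self.se[name] / abs(value)
            rows.append({"parameter": name, "estimate": value, "pct_rse": rse})
        return pd.DataFrame(rows)


class _ParamVector:
    """Pack/unpack named parameters with log or identity transforms."""

    def __init__(
        self,
        entries: Sequence[tuple[str, float, str]],
        fix: Mapping[str, float] | None = None,
    ) -> None:
        self.fix = dict(fix or {})
        self.free = [(n, v, t) for n, v, t in entries if n not in self.fix]
        for name, value, transform in self.free:
            if transform == "log" and value <= 0:
                raise ValueError(f"initial value for {name} must be > 0")

    def x0(self) -> np.ndarray:
        return np.array(
            [math.log(v) if t == "log" else v for _, v, t in self.free]
        )

    def unpack(self, x: np.ndarray) -> dict[str, float]:
        out = dict(self.fix)
        for (name, _, transform), xi in zip(self.free, x):
            out[name] = math.exp(xi) if transform == "log" else float(xi)
        return out

    @property
    def free_names(self) -> list[str]:
        return [n for n, _, _ in self.free]


def _run_outer(
    objective: Callable[[np.ndarray], float],
    pv: _ParamVector,
    method: str,
    maxfev: int,
    xtol: float,
) -> tuple[np.ndarray, float, bool, int, list[float]]:
    trace: list[float] = []
    best = {"x": pv.x0(), "f": np.inf}
    n_evals = 0

    def wrapped(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        f = objective(x)
        if f < best["f"]:
            best["f"] = f
            best["x"] = x.copy()
            trace.append(f)
        return f

    options = {"maxfev": maxfev, "xtol": xtol, "ftol": 1e-7}
    res = minimize(wrapped, pv.x0(), method=method, options=options)
    ok = bool(res.success) or np.isfinite(best["f"])
    return best["x"], best["f"], ok, n_evals, trace


def _standard_errors(
    objective: Callable[[np.ndarray], float],
    x_hat: np.ndarray,
    pv: _ParamVector,
    step: float = 1e-3,
) -> dict[str, float]:
    """Delta-method SEs from a central finite-difference OFV Hessian."""
    n = x_hat.size
    hess = np.empty((n, n))
    f0 = objective(x_hat)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = step
            ej = np.zeros(n); ej[j] = step
            fpp = objective(x_hat + ei + ej)
            fpm = objective(x_hat + ei - ej)
            fmp = objective(x_hat - ei + ej)
            fmm = objective(x_hat - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * step**2)
    try:
        cov = 2.0 * np.linalg.inv(hess)  # OFV = -2 log L
    except np.linalg.LinAlgError:
        return {}
    se_x = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    out = {}
    values = pv.unpack(x_hat)
    for (name, _, transform), s in zip(pv.free, se_x):
        out[name] = values[name] * s if transform == "log" else s
    return out


def _safe(objective: Callable[[np.ndarray], float]) -> Callable[[np.ndarray], float]:
    def wrapped(x: np.ndarray) -> float:
        try:
            f = objective(x)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError,
                OverflowError, RuntimeError):
            return _PENALTY_OFV
        return f if np.isfinite(f) else _PENALTY_OFV

    return wrapped


def fit_pk(
    dataset: PopulationDataset,
    init_theta: PKParameters | None = None,
    init_omega: Mapping[str, float] | None = None,
    init_sigma: ResidualErrorSpec | None = None,
    *,
    fix: Mapping[str, float] | None = None,
    miu_to_ug: float = DEFAULT_MIU_TO_UG,
    method: str = "Powell",
    maxfev: int = 4000,
    xtol: float = 1e-4,
    se: bool = False,
    drop_blq: bool = True,
) -> FitResult:
    """Fit the population PK model by approximate marginal likelihood.

    Positive parameters are optimised on the log scale; ``rf`` on the
    identity scale.  ``fix`` holds named parameters (theta, ``om_*`` or
    ``sig_*``) at given values.  ``drop_blq`` applies the M1 policy
    (discard below-limit records) before fitting.
    """
    from .model_core import default_pk_parameters
    from .synthetic import default_pk_error, default_random_effects

    theta0 = init_theta or default_pk_parameters()
    omega0 = dict(init_omega) if init_omega is not None else dict(default_random_effects()[0].omega)
    sigma0 = init_sigma or default_pk_error()

    subjects = _extract_subjects(dataset, DVID_PK, drop_blq=drop_blq)
    if not any(s.y.size for s in subjects):
        raise ValueError("no quantifiable PK observations in dataset")

    entries = [
        ("cl_f", theta0.cl_f, "log"),
        ("v_f", theta0.v_f, "log"),
        ("d2", theta0.d2, "log"),
        ("ka", theta0.ka, "log"),
        ("alag", theta0.alag, "log"),
        ("rf", theta0.rf, "identity"),
    ]
    for name in PK_ETA_NAMES:
        entries.append((f"om_{name}", omega0.get(name, 0.1), "log"))
    entries.append(("sig_add", sigma0.sigma_add or 1e-3, "log"))
    if sigma0.kind == "combined":
        entries.append(("sig_prop", sigma0.sigma_prop or 1e-3, "log"))
    pv = _ParamVector(entries, fix)

    warm: dict[int, np.ndarray] = {}

    def build(values: Mapping[str, float]):
        theta = PKParameters(
            cl_f=values["cl_f"], v_f=values["v_f"], d2=values["d2"],
            ka=values["ka"], alag=values["alag"], rf=values["rf"],
        )
        omega = {n: values[f"om_{n}"] for n in PK_ETA_NAMES}
        if sigma0.kind == "combined":
            res = ResidualErrorSpec("combined", values["sig_add"], values["sig_prop"])
        elif sigma0.kind == "proportional":
            res = ResidualErrorSpec("proportional", 0.0, values["sig_add"])
        else:
            res = ResidualErrorSpec("additive", values["sig_add"], 0.0)
        return theta, omega, res

    def objective(x: np.ndarray) -> float:
        theta, omega, res = build(pv.unpack(x))
        problems = [(s.y, _pk_predict_factory(theta, s, miu_to_ug)) for s in subjects]
        omega_sd = np.array([omega[n] for n in PK_ETA_NAMES])
        ofv, _ = laplace_ofv(problems, omega_sd, res, warm, gtol=3e-4, max_iter=12)
        return ofv

    safe_obj = _safe(objective)
    x_hat, ofv, ok, n_evals, trace = _run_outer(safe_obj, pv, method, maxfev, xtol)

    values = pv.unpack(x_hat)
    theta, omega, res = build(values)
    problems = [(s.y, _pk_predict_factory(theta, s, miu_to_ug)) for s in subjects]
    omega_sd = np.array([omega[n] for n in PK_ETA_NAMES])
    ofv_final, etas = laplace_ofv(problems, omega_sd, res, None)

    sigma_out = {"add": res.sigma_add}
    if res.kind != "additive":
        sigma_out["prop"] = res.sigma_prop

    result = FitResult(
        theta={k: values[k] for k in ("cl_f", "v_f", "d2", "ka", "alag", "rf")},
        omega=omega,
        sigma=sigma_out,
        ofv=float(ofv_final),
        eta_names=PK_ETA_NAMES,
        ebes={s.sid: e for s, e in zip(subjects, etas)},
        converged=bool(ok and np.isfinite(ofv_final) and ofv_final < _PENALTY_OFV),
        n_evals=n_evals,
        trace=trace,
        meta={"stage": "pk", "method": method, "miu_to_ug": miu_to_ug,
              "residual_kind": res.kind},
    )
    if se:
        result.se = _standard_errors(safe_obj, x_hat, pv)
    return result


def compute_ebes(
    fit: FitResult, dataset: PopulationDataset | None = None
) -> dict[int, PKParameters]:
    """Per-subject realised PK parameters ``TVP * exp(eta_hat)``."""
    if fit.meta.get("stage") != "pk":
        raise ValueError("compute_ebes expects a PK fit result")
    typical = PKParameters(**fit.theta)
    return {
        sid: typical.with_eta(dict(zip(fit.eta_names, eta)))
        for sid, eta in fit.ebes.items()
    }


def fit_pd(
    dataset: PopulationDataset,
    ebes: Mapping[int, PKParameters],
    init_theta: PDParameters | None = None,
    init_omega: Mapping[str, float] | None = None,
    init_sigma: ResidualErrorSpec | None = None,
    *,
    fix: Mapping[str, float] | None = None,
    miu_to_ug: float = DEFAULT_MIU_TO_UG,
    dt: float = 0.5,
    method: str = "Powell",
    maxfev: int = 4000,
    xtol: float = 1e-4,
    se: bool = False,
    drop_blq: bool = True,
) -> FitResult:
    """Fit the population PD model with per-subject PK parameters fixed."""
    from .model_core import default_pd_parameters
    from .synthetic import default_pd_error, default_random_effects

    theta0 = init_theta or default_pd_parameters()
    omega0 = dict(init_omega) if init_omega is not None else dict(default_random_effects()[1].omega)
    sigma0 = init_sigma or default_pd_error()
    if sigma0.kind != "additive":
        raise ValueError("PD residual model is additive")

    subjects = _extract_subjects(dataset, DVID_PD, drop_blq=drop_blq)
    if not any(s.y.size for s in subjects):
        raise ValueError("no quantifiable PD observations in dataset")

    forcings = {}
    for s in subjects:
        if s.sid not in ebes:
            raise ValueError(f"no PK empirical Bayes parameters for subject {s.sid}")
        t_end = float(s.times[-1]) if s.times.size else dt
        forcings[s.sid] = _PDForcing(ebes[s.sid], s.dose_miu, t_end, dt, miu_to_ug)

    theta_names = ("base", "kout", "emax", "gamma", "ca", "cb", "ecb", "mtt")
    entries = [(n, getattr(theta0, n), "log") for n in theta_names]
    for name in PD_ETA_NAMES:
        entries.append((f"om_{name}", omega0.get(name, 0.1), "log"))
    entries.append(("sig_add", sigma0.sigma_add or 1e-3, "log"))
    pv = _ParamVector(entries, fix)

    warm: dict[int, np.ndarray] = {}

    def build(values: Mapping[str, float]):
        theta = PDParameters(**{n: values[n] for n in theta_names})
        omega = {n: values[f"om_{n}"] for n in PD_ETA_NAMES}
        res = ResidualErrorSpec("additive", values["sig_add"], 0.0)
        return theta, omega, res

    def objective(x: np.ndarray) -> float:
        theta, omega, res = build(pv.unpack(x))
        problems = [
            (s.y, _pd_predict_factory(theta, s, forcings[s.sid])) for s in subjects
        ]
        omega_sd = np.array([omega[n] for n in PD_ETA_NAMES])
        ofv, _ = laplace_ofv(problems, omega_sd, res, warm, gtol=3e-4, max_iter=12)
        return ofv

    safe_obj = _safe(objective)
    x_hat, ofv, ok, n_evals, trace = _run_outer(safe_obj, pv, method, maxfev, xtol)

    values = pv.unpack(x_hat)
    theta, omega, res = build(values)
    problems = [(s.y, _pd_predict_factory(theta, s, forcings[s.sid])) for s in subjects]
    omega_sd = np.array([omega[n] for n in PD_ETA_NAMES])
    ofv_final, etas = laplace_ofv(problems, omega_sd, res, None)

    result = FitResult(
        theta={n: values[n] for n in theta_names},
        omega=omega,
        sigma={"add": res.sigma_add},
        ofv=float(ofv_final),
        eta_names=PD_ETA_NAMES,
        ebes={s.sid: e for s, e in zip(subjects, etas)},
        converged=bool(ok and np.isfinite(ofv_final) and ofv_final < _PENALTY_OFV),
        n_evals=n_evals,
        trace=trace,
        meta={"stage": "pd", "method": method, "dt": dt, "miu_to_ug": miu_to_ug,
              "residual_kind": "additive"},
    )
    if se:
        result.se = _standard_errors(safe_obj, x_hat, pv)
    return result


def compare_models(ofv_reduced: float, ofv_full: float, df_diff: int = 1) -> bool:
    """Nested-model selection: keep the full model iff the OFV drops by
    more than 3.84 per added parameter (chi-square 0.05 per df,
    strict inequality)."""
    if df_diff < 1:
        raise ValueError("df_diff must be >= 1")
    return (ofv_reduced - ofv_full) > LRT_THRESHOLD_PER_DF * df_diff
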
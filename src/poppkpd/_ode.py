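"""Fixed-step batched RK4 integrator for the turnover system.

The estimation stage needs thousands of response-trajectory evaluations
with slightly perturbed parameters.  The drug effect multiplier E(t)
does not depend on the turnover states, so the whole production forcing
``kin * E(t)`` is precomputed on a half-step grid (vectorised numpy)
and the kernel integrates the remaining *linear* two-state system —
no transcendentals inside the step loop.  The loop is JIT-compiled with
numba when available; the same code runs (slower) as plain numpy
otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["half_step_times", "pd_rk4_batch", "stimulation_grid"]


def _rk4_kernel(p_half, dt, n_steps, ktr, kout):
    b = p_half.shape[0]
    a3 = p_half[:, 0] / ktr  # production at t=0 is kin (drug-free)
    a4 = p_half[:, 0] / kout
    hist = np.empty((b, n_steps + 1))
    hist[:, 0] = a4
    half = 0.5 * dt
    sixth = dt / 6.0
    for k in range(n_steps):
        p0 = p_half[:, 2 * k]
        pm = p_half[:, 2 * k + 1]
        p1 = p_half[:, 2 * k + 2]

        k1_3 = p0 - ktr * a3
        k1_4 = ktr * a3 - kout * a4
        y3 = a3 + half * k1_3
        y4 = a4 + half * k1_4
        k2_3 = pm - ktr * y3
        k2_4 = ktr * y3 - kout * y4
        y3 = a3 + half * k2_3
        y4 = a4 + half * k2_4
        k3_3 = pm - ktr * y3
        k3_4 = ktr * y3 - kout * y4
        y3 = a3 + dt * k3_3
        y4 = a4 + dt * k3_4
        k4_3 = p1 - ktr * y3
        k4_4 = ktr * y3 - kout * y4
        a3 = a3 + sixth * (k1_3 + 2.0 * k2_3 + 2.0 * k3_3 + k4_3)
        a4 = a4 + sixth * (k1_4 + 2.0 * k2_4 + 2.0 * k3_4 + k4_4)
        hist[:, k + 1] = a4
    return hist


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _rk4 = njit(cache=True, fastmath=False)(_rk4_kernel)
except ImportError:  # pragma: no cover
    _rk4 = _rk4_kernel


def half_step_times(t_end: float, dt: float) -> tuple[np.ndarray, int]:
    """Half-step grid covering ``[0, t_end]`` with step ``dt``.

    Returns the grid of ``2*n + 1`` stage times and the step count ``n``.
    """
    n_steps = int(np.ceil(t_end / dt - 1e-9))
    n_steps = max(n_steps, 1)
    return np.arange(2 * n_steps + 1) * (dt / 2.0), n_steps


def stimulation_grid(
    log_c: np.ndarray,
    t_grid: np.ndarray,
    emax: np.ndarray,
    gamma: np.ndarray,
    ecb: np.ndarray,
    ca: np.ndarray,
    cb: np.ndarray,
) -> np.ndarray:
    """Effect multiplier ``E`` on the stage grid for a parameter batch.

    ``log_c`` holds log drug concentrations on the grid (``-inf`` where
    the concentration is zero); parameters are ``(b,)`` arrays.  Uses
    ``E = 1 + emax / (1 + exp(g*(log EC50(t) - log C(t))))`` which is
    overflow-safe at both extremes.
    """
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        log_ec = np.log(ecb)[:, None] + np.log1p(
            ca[:, None] * (-np.expm1(-cb[:, None] * t_grid[None, :]))
        )
        w = gamma[:, None] * (log_ec - log_c[None, :])
        e = 1.0 + emax[:, None] / (1.0 + np.exp(w))
    return np.where(np.isnan(e), 1.0, e)


def pd_rk4_batch(
    production_half: np.ndarray,
    dt: float,
    obs_times: np.ndarray,
    ktr: np.ndarray,
    kout: np.ndarray,
) -> np.ndarray:
    """Integrate the turnover system for a batch of parameter sets.

    Parameters
    ----------
    production_half
        ``(b, 2*n_steps + 1)`` production rates ``kin * E(t)`` on the
        half-step grid (one row per batch member); the initial state is
        the steady state of the first column (drug-free production).
    dt
        Step size (h); ``obs_times`` need not be grid-aligned — the
        recorded trajectory is linearly interpolated at them.
    obs_times
        Requested output times (h), within ``[0, n_steps*dt]``.

    Returns
    -------
    ``(b, len(obs_times))`` array of response values (state ``A4``).
    """
    b, m = production_half.shape
    n_steps = (m - 1) // 2
    hist = _rk4(
        np.ascontiguousarray(production_half, dtype=np.float64),
        float(dt),
        n_steps,
        np.ascontiguousarray(ktr, dtype=np.float64),
        np.ascontiguousarray(kout, dtype=np.float64),
    )
    grid = np.arange(n_steps + 1) * dt
    # vectorised linear interpolation along axis 1 (shared grid)
    idx = np.clip(np.searchsorted(grid, obs_times, side="right") - 1, 0, n_steps - 1)
    frac = (obs_times - grid[idx]) / dt
    return hist[:, idx] * (1.0 - frac) + hist[:, idx + 1] * frac
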
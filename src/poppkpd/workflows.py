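"""End-to-end experiment drivers shared by the CLI, the acceptance
script and the acceptance tests."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import RunConfig
from .estimation import FitResult, compute_ebes, fit_pd, fit_pk
from .synthetic import PopulationDataset, simulate_study

__all__ = ["RecoveryOutcome", "perturbed", "recovery_experiment", "simulate_from_config"]


def simulate_from_config(config: RunConfig, seed: int | None = None) -> PopulationDataset:
    """Simulate one study described by the configuration."""
    return simulate_study(
        config.design(),
        config.pk_parameters(),
        config.pd_parameters(),
        config.pk_iiv(),
        config.pd_iiv(),
        config.pk_error(),
        config.pd_error(),
        seed=config.seed if seed is None else seed,
    )


def perturbed(theta, factor: float = 1.4):
    """Alternately scale fields up/down by ``factor`` (rf shifted, not
    scaled, since it lives on the whole real line)."""
    fields = dataclasses.fields(theta)
    updates = {}
    for i, f in enumerate(fields):
        value = getattr(theta, f.name)
        if f.name == "rf":
            updates[f.name] = value + (0.5 if i % 2 == 0 else -0.5)
        else:
            updates[f.name] = value * (factor if i % 2 == 0 else 1.0 / factor)
    return dataclasses.replace(theta, **updates)


@dataclass
class RecoveryOutcome:
    """One seed's simulate -> fit-PK -> fit-PD round trip."""

    seed: int
    dataset: PopulationDataset
    pk_fit: FitResult
    pd_fit: FitResult

    def estimates(self) -> dict[str, float]:
        out = dict(self.pk_fit.theta)
        out.update(self.pd_fit.theta)
        return out


def recovery_experiment(
    config: RunConfig,
    seeds: Sequence[int],
    *,
    maxfev_pk: int | None = None,
    maxfev_pd: int | None = None,
    start_perturbation: float = 1.0,
    censor_blq: bool = False,
    pd_dt: float = 1.0,
) -> tuple[list[RecoveryOutcome], dict[str, float]]:
    """Simulate/refit at each seed and report median fixed effects.

    Following the standard simulation-reestimation convention, each fit
    is initialised at the generating typical values (set
    ``start_perturbation`` > 1 to displace the starting point by that
    factor, alternating up/down per field).  Note that the mixture
    absorption model has a shallow likelihood valley trading the
    zero-order fraction against clearance and the slow absorption rate
    (the same weak identifiability shows up as very wide bootstrap
    intervals for those parameters); optimisation is deliberately local,
    so distant starting points may settle in a rival basin a few OFV
    units deeper.
    """
    maxfev_pk = maxfev_pk or config.fit_maxfev
    maxfev_pd = maxfev_pd or config.fit_maxfev
    pk_start = config.pk_parameters()
    pd_start = config.pd_parameters()
    if start_perturbation != 1.0:
        pk_start = perturbed(pk_start, start_perturbation)
        pd_start = perturbed(pd_start, start_perturbation)

    outcomes: list[RecoveryOutcome] = []
    for seed in seeds:
        dataset = simulate_from_config(config, seed=seed)
        pk_fit = fit_pk(
            dataset,
            init_theta=pk_start,
            init_omega=config.pk_omega,
            init_sigma=config.pk_error(),
            miu_to_ug=config.miu_to_ug,
            maxfev=maxfev_pk,
            drop_blq=censor_blq,
        )
        ebes = compute_ebes(pk_fit)
        pd_fit = fit_pd(
            dataset,
            ebes,
            init_theta=pd_start,
            init_omega=config.pd_omega,
            init_sigma=config.pd_error(),
            miu_to_ug=config.miu_to_ug,
            maxfev=maxfev_pd,
            dt=pd_dt,
            drop_blq=censor_blq,
        )
        outcomes.append(RecoveryOutcome(seed=seed, dataset=dataset,
                                        pk_fit=pk_fit, pd_fit=pd_fit))

    names = list(outcomes[0].estimates())
    medians = {
        name: float(np.median([o.estimates()[name] for o in outcomes]))
        for name in names
    }
    return outcomes, medians
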
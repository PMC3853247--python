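# poppkpd

Population PK-PD modelling of a sustained-release interferon-α
formulation with a neopterin turnover response.

The structural model is a one-compartment disposition with parallel
zero-order (duration `d2`) and lagged first-order (`ka`, `alag`)
absorption; the response is a turnover (indirect-response) system with
a single transit compartment in which drug stimulates production
through a sigmoid function whose EC50 rises over time (the CDF of an
exponential), capturing the saturable neopterin response. The package
provides:

- `poppkpd.model_core` — analytic drug concentration, effect/EC50
  functions, and the response-trajectory ODE solve.
- `poppkpd.synthetic` — complete synthetic studies at the trial design
  (4 dose groups × 6 subjects; rich PK/PD sampling grids) with
  log-normal between-subject variability and additive/proportional/
  combined residual error; truth records kept for recovery tests.
- `poppkpd.nca` — non-compartmental Cmax/Tmax/AUClast with group
  summaries.
- `poppkpd.estimation` — nonlinear mixed-effects estimation by a
  Laplace (FOCE-with-interaction flavoured) approximate marginal
  likelihood, with sequential PK→PD coupling through per-subject
  empirical Bayes estimates, and the ΔOFV > 3.84 nested-model rule.
- `poppkpd.evaluation` — subject-resampling bootstrap CIs, visual
  predictive checks (12.5/50/87.5 percentile bands, 1000 replicates by
  default), goodness-of-fit tables and recovery reports.
- `poppkpd.cli` — `poppkpd` command with `simulate`, `fit-pk`,
  `fit-pd`, `nca`, `vpc`, `bootstrap` and `pipeline` subcommands.

Datasets are long-format NONMEM-style CSV (`ID, TIME, AMT, EVID, MDV,
DVID, DV, BLQ, DOSE`; missing values as `.`), with the generating truth
as a JSON side-car.

## CLI

```sh
poppkpd simulate --seed 1 --out run/
poppkpd fit-pk --data run/dataset.csv --out run/
poppkpd fit-pd --data run/dataset.csv --pk-fit run/pk_fit.json --out run/
poppkpd nca --data run/dataset.csv --out run/nca.csv
poppkpd vpc --data run/dataset.csv --seed 1 --n-sim 200 --out run/
poppkpd bootstrap --data run/dataset.csv --n-replicates 100 --out run/
poppkpd pipeline --seed 1 --out run/        # end-to-end driver
```

All stages accept `--config config.yaml` (see `poppkpd.config.RunConfig`
for the schema; defaults reproduce the reference study design and
estimates) and write a provenance JSON (seed, config hash, version)
next to their outputs.

## Conventions

- Doses are in MIU and converted to mass with a configurable factor
  (default 5 µg/MIU, `DEFAULT_MIU_TO_UG`); results are invariant to it
  or use it self-consistently.
- ω values are standard deviations of log-scale random effects
  (reported in tables as percent); `Kin = Kout × BASE` and
  `Ktr = 1/MTT` are derived, not estimated.
- OFV includes the 2π constants; only OFV differences are meaningful.
- Below-limit (BLQ) observations are flagged at simulation time and
  discarded before fitting by default (M1 policy; `drop_blq=False` to
  keep them).
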
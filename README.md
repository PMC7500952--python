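# ifngate

Modeling delayed, cell-cycle-gated negative feedback in interferon
signaling.

Cells treated twice with IFN-α respond to the second dose in opposite
ways depending on how long the first exposure lasted: brief pretreatment
*primes* (a larger second response), prolonged pretreatment
*desensitizes*. `ifngate` implements a minimal kinetic model that
explains this through two feedback genes with very different induction
kinetics — IRF9, an ISGF3 component that closes a fast positive loop,
and USP18, a receptor-level inhibitor whose induction is delayed and, at
the single-cell level, gated by the cell cycle. The package is aimed at
systems-biology researchers who want to simulate, refit, or extend the
model, and at analysts quantifying dual-reporter single-cell traces.

The model:

```
dIRF9/dt  = I(t) · (k4 + pf·nf)          pf = k1·IRF9/(k2 + IRF9)
dUSP18/dt = I(t) · Su(t) · (k5 + pf·nf)  nf = k3/(k3 + USP18)
```

with binary input `I(t)`, no decay (production-only), and a stepwise
gate `Su` that enables USP18 production only after continuous exposure
exceeds a delay — a fixed `tau` (≈ 8 h), or a cell-cycle gate: induction
starts immediately only if treatment lands inside an open window of
length `w = 7.3` h at the start of a `T = 21.82` h cycle, otherwise the
cell waits for the next division. With uniform onset phase this gate
yields a delay distribution with an atom `w/T` at zero and survival
`P(delay > d) = (T − w − d)/T`.

What's inside:

- `ifngate.model` — the ODE core, input programs (pretreatment and
  pulse protocols), Euler integration (numba-accelerated) and an
  adaptive reference integrator;
- `ifngate.gating` — the cell-cycle gate: per-cell delays, the analytic
  delay distribution, window fitting (KS distance);
- `ifngate.stochastic` — single-cell SDE cohorts of the pretreatment
  protocol, with CV and correlation summaries;
- `ifngate.fitting` — least-squares fitting at assigned delays, the
  tau scan (1–20 h), Gaussian likelihood, AIC comparison of the full
  model vs loop-ablated variants;
- `ifngate.synthetic` — synthetic dual-reporter imaging cohorts with
  ground truth, and simulated fitting datasets;
- `ifngate.traces` — trace quantification: smoothed derivatives,
  activation/delay calls, % cell-cycle progression, delay-group
  classification, induction amounts;
- `ifngate.cli` / `ifngate.io` — a thin `ifngate` command-line tool,
  YAML config validation, tidy CSV I/O with provenance.

## Worked example

```python
from ifngate import (DEFAULT_PARAMS, GatingPolicy, build_pretreatment_program,
                     integrate)

policy = GatingPolicy.fixed_delay(DEFAULT_PARAMS.tau)   # tau = 8 h
raw = {}
for pre in (0.0, 2.0, 10.0, 24.0):
    program = build_pretreatment_program(pre, 8.0, 10.0)  # pre / break / second
    second_on = pre + 8.0
    traj = integrate(DEFAULT_PARAMS, program, policy,
                     t_end=second_on + 10.0, dt=0.001)
    raw[pre] = traj.irf9[-1] - traj.irf9[int(round(second_on / 0.001))]
for pre in (2.0, 10.0, 24.0):
    print(f"{pre:>4g} h pretreatment: {raw[pre] / raw[0.0]:.3f}")
```

prints

```
   2 h pretreatment: 1.409
  10 h pretreatment: 1.155
  24 h pretreatment: 0.536
```

— the second response relative to a no-pretreatment control: 2-h and
10-h pretreatments prime (IRF9 accumulated while the USP18 gate was
still shut), a 24-h pretreatment desensitizes (16 h of gated USP18
production saturates the negative feedback). The same mechanism makes
repetitive inputs more potent than sustained ones: five 8-h pulses,
each shorter than the 8-h delay, never open the gate and induce ~4.4×
more IRF9 than a 40-h sustained input; under USP18 knockdown the ratio
collapses to 1.0.

The stochastic cohort (400 cells per condition, cell-cycle gate)
reproduces the single-cell picture: USP18 expression after pretreatment
anticorrelates with IRF9 induction by the second input (pooled Pearson
r ≈ −0.5), and cell-to-cell variability in USP18 falls with pretreatment
duration as the gate saturates.

A CLI mirrors the library, e.g.:

```sh
ifngate generate --seed 1 --out runs/cohort       # synthetic dual-reporter cells
ifngate analyze --traces runs/cohort/traces.csv \
    --divisions runs/cohort/divisions.csv --out runs/quant
ifngate cohort --seed 1 --out runs/stochastic     # stochastic pretreatment cohort
```

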
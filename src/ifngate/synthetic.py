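"""Synthetic single-cell dual-reporter cohorts and fitting datasets.

The cohort generator emulates time-lapse imaging of the dual-reporter
line: an IRF9-promoter reporter that activates with a fast, fairly
uniform lognormal latency (target mean 7.9 h, CV 0.556) and a
USP18-promoter reporter whose activation lags by the cell-cycle-gated
waiting time.  Each cell carries its own cycle length (truncated normal
around 21.82 h), a uniform treatment-onset phase within that cycle,
division annotations, and two asynchronously sampled reporter traces
(20-min cadence for the IRF9 channel, 30-min for the USP18 channel)
shaped as a baseline plus saturating exponential ramp with additive
Gaussian noise.  Ground truth is returned alongside so every downstream
quantification can be checked against it.

The fitting-dataset generator simulates the kinetic model itself (a
sustained-input trace plus pretreatment-protocol endpoints) and is the
stand-in for digitized bulk observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import Dataset
from .gating import GatingModel, gated_delay
from .model import (
    FULL_MODEL,
    GatingPolicy,
    InputProgram,
    ModelParameters,
    Variant,
    build_pretreatment_program,
    integrate,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticCell",
    "generate_cohort",
    "cohort_frames",
    "generate_fitting_dataset",
]

IRF9_CHANNEL = "reporter_irf9"
USP18_CHANNEL = "reporter_usp18"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic imaging cohort.

    Cycle lengths ~ Normal(21.82, 2.0) truncated above 4 h; open window
    7.3 h anchored at division; IRF9 activation latency lognormal with
    mean 7.9 h and CV 0.556; USP18 activation = IRF9 activation + gated
    delay + Gaussian jitter (SD 0.5 h), floored at the IRF9 activation.
    Traces run from ``t_start`` (pre-onset baseline) to ``t_end`` around
    the treatment onset at t = 0.
    """

    n_cells: int = 200
    seed: int = 0
    cycle_mean: float = 21.82
    cycle_sd: float = 2.0
    cycle_min: float = 4.0
    window: float = 7.3
    act_mean: float = 7.9
    act_cv: float = 0.556
    usp18_jitter_sd: float = 0.5
    dt_irf9: float = 1.0 / 3.0   # 20-min cadence
    dt_usp18: float = 0.5        # 30-min cadence
    baseline_irf9: float = 100.0
    baseline_usp18: float = 50.0
    amplitude_irf9: float = 1000.0
    amplitude_usp18: float = 800.0
    ramp_tau: float = 8.0
    noise_sd: float = 20.0
    t_start: float = -5.0
    t_end: float = 45.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("cycle_mean", "cycle_sd", "act_mean", "act_cv",
                     "dt_irf9", "dt_usp18", "ramp_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0 or self.usp18_jitter_sd < 0:
            raise ValueError("noise scales must be non-negative")
        if max(self.dt_irf9, self.dt_usp18) >= self.cycle_mean:
            raise ValueError("sampling interval must be below the cycle mean")
        if self.t_start >= 0 or self.t_end <= 0:
            raise ValueError("trace must bracket the treatment onset at t=0")


@dataclass
class SyntheticCell:
    cell_id: int
    cycle_length: float
    onset_phase: float
    division_times: np.ndarray
    act_irf9: float
    act_usp18: float
    gate_delay: float       # delay imposed by the cycle gate (pre-jitter)
    delay: float            # act_usp18 - act_irf9 (>= 0 in truth)
    traces: dict            # channel -> (times, values)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _ramp(t: np.ndarray, act: float, baseline: float, amp: float, tau: float):
    out = np.full(t.shape, baseline, dtype=float)
    late = t >= act
    out[late] = baseline + amp * (1.0 - np.exp(-(t[late] - act) / tau))
    return out


def generate_cohort(config: GeneratorConfig) -> tuple[list, pd.DataFrame]:
    """Generate ``n_cells`` synthetic cells plus a ground-truth table.

    Returns ``(cells, truth)`` where ``truth`` has one row per cell with
    columns cell_id, cycle_length_h, onset_phase_h, act_irf9_h,
    act_usp18_h, gate_delay_h, delay_h.
    """
    rng = np.random.default_rng(config.seed)
    mu, sig = _lognormal_params(config.act_mean, config.act_cv)

    # truncated-normal cycle lengths (> cycle_min), by rejection
    L = rng.normal(config.cycle_mean, config.cycle_sd, size=config.n_cells)
    while np.any(L <= config.cycle_min):
        bad = L <= config.cycle_min
        L[bad] = rng.normal(config.cycle_mean, config.cycle_sd, size=bad.sum())

    cells: list[SyntheticCell] = []
    truth_rows = []
    for cid in range(config.n_cells):
        cycle = float(L[cid])
        t0 = float(rng.uniform(0.0, cycle))
        gm = GatingModel(cycle, min(config.window, cycle))
        gate_delay = gated_delay(t0, gm)
        act_i = float(rng.lognormal(mu, sig))
        jitter = float(rng.normal(0.0, config.usp18_jitter_sd))
        delay = max(0.0, gate_delay + jitter)
        act_u = act_i + delay
        # divisions: previous division at -t0, then every `cycle` hours
        ks = np.arange(0, int(np.floor((config.t_end + t0) / cycle)) + 1)
        divisions = -t0 + ks * cycle
        divisions = divisions[divisions <= config.t_end]

        traces = {}
        for channel, dt, base, amp, act in (
            (IRF9_CHANNEL, config.dt_irf9, config.baseline_irf9,
             config.amplitude_irf9, act_i),
            (USP18_CHANNEL, config.dt_usp18, config.baseline_usp18,
             config.amplitude_usp18, act_u),
        ):
            n = int(np.floor((config.t_end - config.t_start) / dt))
            ts = config.t_start + np.arange(n + 1) * dt
            vals = _ramp(ts, act, base, amp, config.ramp_tau)
            if config.noise_sd > 0:
                vals = vals + rng.normal(0.0, config.noise_sd, size=vals.shape)
            traces[channel] = (ts, vals)

        cells.append(
            SyntheticCell(
                cell_id=cid, cycle_length=cycle, onset_phase=t0,
                division_times=divisions, act_irf9=act_i, act_usp18=act_u,
                gate_delay=gate_delay, delay=delay, traces=traces,
            )
        )
        truth_rows.append(
            {
                "cell_id": cid,
                "cycle_length_h": cycle,
                "onset_phase_h": t0,
                "act_irf9_h": act_i,
                "act_usp18_h": act_u,
                "gate_delay_h": gate_delay,
                "delay_h": delay,
            }
        )
    return cells, pd.DataFrame(truth_rows)


def cohort_frames(cells: list) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy (traces, divisions) tables for a list of synthetic cells.

    Traces: cell_id, time_h, channel, value.  Divisions: cell_id,
    division_time_h.
    """
    trace_rows = []
    div_rows = []
    for cell in cells:
        for channel, (ts, vals) in cell.traces.items():
            trace_rows.append(
                pd.DataFrame(
                    {
                        "cell_id": cell.cell_id,
                        "time_h": ts,
                        "channel": channel,
                        "value": vals,
                    }
                )
            )
        for d in cell.division_times:
            div_rows.append({"cell_id": cell.cell_id, "division_time_h": d})
    traces = pd.concat(trace_rows, ignore_index=True)
    divisions = pd.DataFrame(div_rows)
    return traces, divisions


def generate_fitting_dataset(
    params: ModelParameters,
    tau: float,
    noise_frac: float = 0.0,
    seed: int = 0,
    trace_t_end: float = 48.0,
    trace_dt: float = 1.0 / 3.0,
    pre_durations=(2.0, 10.0, 24.0),
    break_h: float = 8.0,
    second_h: float = 10.0,
    dt: float = 0.001,
    variant: Variant = FULL_MODEL,
) -> Dataset:
    """Simulate the model and package the observations a fit consumes: a
    sustained-input IRF9 trace sampled at the imaging cadence and
    control-normalized pretreatment endpoints.

    ``noise_frac`` scales additive Gaussian noise relative to the signal
    (trace maximum for trace points; control induction for endpoints),
    applied to the raw quantities before normalization.
    """
    rng = np.random.default_rng(seed)
    policy = GatingPolicy.fixed_delay(tau)

    traj = integrate(
        params, InputProgram(((0.0, trace_t_end),)), policy, variant,
        t_end=trace_t_end, dt=dt,
    )
    n = int(np.floor(trace_t_end / trace_dt))
    ts = np.arange(n + 1) * trace_dt
    trace = np.interp(ts, traj.times, traj.irf9)
    if noise_frac > 0:
        trace = trace + rng.normal(0, noise_frac * trace.max(), size=trace.shape)

    raw = {}
    for pre in (0.0, *pre_durations):
        program = build_pretreatment_program(pre, break_h, second_h)
        second_on = pre + break_h
        traj_p = integrate(
            params, program, policy, variant,
            t_end=second_on + second_h, dt=dt,
        )
        i_on = int(round(second_on / dt))
        raw[pre] = traj_p.irf9[-1] - traj_p.irf9[i_on]
    if noise_frac > 0:
        scale = noise_frac * raw[0.0]
        for pre in pre_durations:
            raw[pre] = raw[pre] + rng.normal(0, scale)
    norm = np.array([raw[p] / raw[0.0] for p in pre_durations])

    return Dataset(
        trace_times=ts,
        trace_values=trace,
        endpoint_pre_h=np.asarray(pre_durations, dtype=float),
        endpoint_induction_norm=norm,
        break_h=break_h,
        second_h=second_h,
    )
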
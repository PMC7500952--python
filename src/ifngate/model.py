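"""Deterministic kinetic model of interferon-driven IRF9/USP18 expression.

Two species, production only (no decay on the experimental time scale):

    dIRF9/dt  = I(t) * (k4 + pf * nf)
    dUSP18/dt = I(t) * Su(t) * (k5 + pf * nf)

with positive feedback ``pf = k1*IRF9/(k2+IRF9)`` (IRF9 is an ISGF3
component that amplifies its own induction), negative feedback
``nf = k3/(k3+USP18)`` (USP18 dampens receptor signaling), a binary
interferon input ``I(t)`` and a stepwise gate ``Su(t)`` that switches
USP18 production on only after the continuous exposure of the current ON
episode exceeds a delay.  The delay is either fixed (``tau``) or drawn
from the cell-cycle gate (see :mod:`ifngate.gating`).

Integration is forward Euler (default dt = 0.001 h); an adaptive
high-order reference integrator is provided for verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .gating import GatingModel, gated_delay

__all__ = [
    "ModelParameters",
    "InputProgram",
    "GatingPolicy",
    "Variant",
    "Trajectory",
    "FULL_MODEL",
    "positive_feedback",
    "negative_feedback",
    "input_indicator",
    "continuous_exposure",
    "su_gate",
    "derivatives",
    "integrate",
    "reference_trajectory",
    "build_pretreatment_program",
    "build_pulse_program",
]


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic constants of the feedback model.

    k1: maximal positive-feedback production rate (conc/h)
    k2: IRF9 half-saturation level of the positive feedback (conc)
    k3: USP18 half-inhibition level of the negative feedback (conc)
    k4: basal IFN-driven IRF9 production rate (conc/h)
    k5: basal IFN-driven USP18 production rate (conc/h)
    tau: delay of USP18 induction (h)

    Concentrations are arbitrary fluorescence-like units.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "k5"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k2 <= 0:
            raise ValueError("k2 must be > 0")
        if self.k3 <= 0:
            raise ValueError("k3 must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class InputProgram:
    """Piecewise-constant binary interferon input, given as ordered
    half-open ON intervals ``[on, off)`` in hours.

    Intervals are validated (sorted, disjoint, on < off); adjacent
    intervals with zero gap are merged on construction.
    """

    intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        ivs = [(float(a), float(b)) for a, b in self.intervals]
        for a, b in ivs:
            if a < 0:
                raise ValueError(f"interval start must be >= 0, got {a}")
            if a >= b:
                raise ValueError(f"interval must satisfy on < off, got ({a}, {b})")
        ivs.sort()
        merged: list[tuple[float, float]] = []
        for a, b in ivs:
            if merged and a < merged[-1][1]:
                raise ValueError("intervals overlap")
            if merged and a == merged[-1][1]:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        object.__setattr__(self, "intervals", tuple(merged))

    @property
    def end(self) -> float:
        return self.intervals[-1][1] if self.intervals else 0.0

    @property
    def total_on(self) -> float:
        return sum(b - a for a, b in self.intervals)


@dataclass(frozen=True)
class GatingPolicy:
    """Policy governing the Su gate for USP18 production.

    Modes: ``fixed_delay`` (deterministic delay ``tau``), ``cell_cycle``
    (delay from the phase of the cell at each ON-episode onset),
    ``always_on`` (Su = 1) and ``never_on`` (Su = 0, the USP18-knockdown
    surrogate at the gate level).
    """

    mode: str
    tau: float = 0.0
    cycle_length: float = 21.82
    window: float = 7.3
    onset_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_delay", "cell_cycle", "always_on", "never_on"):
            raise ValueError(f"unknown gating mode {self.mode!r}")
        if self.mode == "fixed_delay" and self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.mode == "cell_cycle":
            if not 0 <= self.window <= self.cycle_length:
                raise ValueError("need 0 <= window <= cycle_length")
            if not 0 <= self.onset_phase < self.cycle_length:
                raise ValueError("need 0 <= onset_phase < cycle_length")

    @classmethod
    def fixed_delay(cls, tau: float) -> "GatingPolicy":
        return cls(mode="fixed_delay", tau=tau)

    @classmethod
    def cell_cycle(
        cls, cycle_length: float, window: float, onset_phase: float
    ) -> "GatingPolicy":
        return cls(
            mode="cell_cycle",
            cycle_length=cycle_length,
            window=window,
            onset_phase=onset_phase,
        )

    @classmethod
    def always_on(cls) -> "GatingPolicy":
        return cls(mode="always_on")

    @classmethod
    def never_on(cls) -> "GatingPolicy":
        return cls(mode="never_on")

    def episode_delay(self, episode_on: float) -> float:
        """Effective Su delay for the ON episode starting at ``episode_on``."""
        if self.mode == "fixed_delay":
            return self.tau
        if self.mode == "always_on":
            return 0.0
        if self.mode == "never_on":
            return np.inf
        # cell_cycle: the cell's phase advances continuously modulo T from
        # a single draw at t=0.
        gm = GatingModel(self.cycle_length, self.window)
        phase = (self.onset_phase + episode_on) % self.cycle_length
        return gated_delay(phase, gm)


@dataclass(frozen=True)
class Variant:
    """Model variant flags.

    ``positive_feedback=False`` replaces pf by the constant k1 (the loop is
    cut; k2 becomes unused).  ``negative_feedback=False`` forces nf = 1
    (k3 unused).  ``usp18_knockdown=True`` holds USP18 at zero, hence
    nf = 1 as well.  ``grouping`` selects the algebraic grouping of the
    rate laws: ``"gated"`` (default) multiplies the whole production term
    by the input; ``"ungated"`` leaves pf*nf outside the input gate and is
    provided only for sensitivity checks (it grows without bound after
    input removal).
    """

    positive_feedback: bool = True
    negative_feedback: bool = True
    usp18_knockdown: bool = False
    grouping: str = "gated"

    def __post_init__(self) -> None:
        if self.grouping not in ("gated", "ungated"):
            raise ValueError(f"unknown grouping {self.grouping!r}")

    @property
    def is_full(self) -> bool:
        return (
            self.positive_feedback
            and self.negative_feedback
            and not self.usp18_knockdown
        )


FULL_MODEL = Variant()


@dataclass
class Trajectory:
    """Time-indexed IRF9 and USP18 levels on a uniform grid."""

    times: np.ndarray
    irf9: np.ndarray
    usp18: np.ndarray
    program: InputProgram

    def value_at(self, t: float, species: str = "irf9") -> float:
        series = getattr(self, species)
        return float(np.interp(t, self.times, series))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.times,
                "irf9": self.irf9,
                "usp18": self.usp18,
                "input": input_indicator(self.program, self.times),
            }
        )


# ---------------------------------------------------------------------------
# elementary pieces


def positive_feedback(irf9, params: ModelParameters):
    """pf = k1 * IRF9 / (k2 + IRF9); saturating in [0, k1)."""
    irf9 = np.asarray(irf9, dtype=float)
    if np.any(irf9 < 0):
        raise ValueError("irf9 must be non-negative")
    out = params.k1 * irf9 / (params.k2 + irf9)
    return float(out) if out.ndim == 0 else out


def negative_feedback(usp18, params: ModelParameters):
    """nf = k3 / (k3 + USP18); in (0, 1]."""
    usp18 = np.asarray(usp18, dtype=float)
    if np.any(usp18 < 0):
        raise ValueError("usp18 must be non-negative")
    out = params.k3 / (params.k3 + usp18)
    return float(out) if out.ndim == 0 else out


def input_indicator(program: InputProgram, t):
    """I(t): 1 iff t lies in some half-open ON interval [on, off)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape)
    for a, b in program.intervals:
        out = np.where((t >= a) & (t < b), 1.0, out)
    if out.ndim == 0:
        return int(out)
    return out


def continuous_exposure(program: InputProgram, t: float) -> float:
    """Duration of uninterrupted exposure at time t: ``t - on`` of the
    containing ON interval, 0 when the input is off.  The exposure clock
    resets at every input OFF."""
    if t < 0:
        raise ValueError("t must be non-negative")
    for a, b in program.intervals:
        if a <= t < b:
            return t - a
    return 0.0


def su_gate(policy: GatingPolicy, program: InputProgram, t: float) -> int:
    """Su(t): 1 once the continuous exposure of the current ON episode
    reaches that episode's effective delay (closed boundary: on at
    exposure == delay)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    for a, b in program.intervals:
        if a <= t < b:
            return int((t - a) >= policy.episode_delay(a))
    return 0


def derivatives(
    irf9: float,
    usp18: float,
    t: float,
    params: ModelParameters,
    program: InputProgram,
    policy: GatingPolicy,
    variant: Variant = FULL_MODEL,
) -> tuple[float, float]:
    """Right-hand side of the model at state (irf9, usp18) and time t."""
    if irf9 < 0 or usp18 < 0:
        raise ValueError("state must be non-negative")
    I = input_indicator(program, t)
    Su = su_gate(policy, program, t)
    pf = params.k1 if not variant.positive_feedback else positive_feedback(irf9, params)
    if variant.usp18_knockdown or not variant.negative_feedback:
        nf = 1.0
    else:
        nf = negative_feedback(usp18, params)
    drive = pf * nf
    if variant.grouping == "gated":
        d_irf9 = I * (params.k4 + drive)
        d_usp18 = I * Su * (params.k5 + drive)
    else:
        d_irf9 = I * params.k4 + drive
        d_usp18 = I * Su * params.k5 + drive
    if variant.usp18_knockdown:
        d_usp18 = 0.0
    return d_irf9, d_usp18


# ---------------------------------------------------------------------------
# integration


def gate_arrays(
    program: InputProgram, policy: GatingPolicy, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized I(t) and Su(t) on a time grid (both piecewise constant)."""
    I = np.zeros(times.shape)
    Su = np.zeros(times.shape)
    for a, b in program.intervals:
        on = (times >= a) & (times < b)
        I[on] = 1.0
        delay = policy.episode_delay(a)
        if np.isfinite(delay):
            Su[on & (times >= a + delay)] = 1.0
    return I, Su


@njit(cache=False)
def _euler_core(
    I, Su, dt, k1, k2, k3, k4, k5,
    use_pf, use_nf, kd, gated,
    s_irf9, s_usp18, noise_irf9, noise_usp18,
    y0_irf9, y0_usp18,
):  # pragma: no cover - exercised through integrate()
    n = I.shape[0]
    irf9 = np.empty(n + 1)
    usp18 = np.empty(n + 1)
    irf9[0] = y0_irf9
    usp18[0] = y0_usp18
    for i in range(n):
        x = irf9[i]
        u = usp18[i]
        pf = k1 * x / (k2 + x) if use_pf else k1
        nf = k3 / (k3 + u) if use_nf else 1.0
        drive = pf * nf
        if gated:
            di = I[i] * (k4 + drive)
            du = I[i] * Su[i] * (k5 + drive)
        else:
            di = I[i] * k4 + drive
            du = I[i] * Su[i] * k5 + drive
        if kd:
            du = 0.0
        xn = x + dt * di
        un = u + dt * du
        if s_irf9 > 0.0:
            xn += s_irf9 * noise_irf9[i]
        if s_usp18 > 0.0:
            un += s_usp18 * noise_usp18[i]
        if xn < 0.0:
            xn = 0.0
        if un < 0.0:
            un = 0.0
        if kd:
            un = 0.0
        irf9[i + 1] = xn
        usp18[i + 1] = un
    return irf9, usp18


_EMPTY = np.zeros(0)


def _simulate(
    params: ModelParameters,
    program: InputProgram,
    policy: GatingPolicy,
    variant: Variant,
    t_end: float,
    dt: float,
    y0: tuple[float, float] = (0.0, 0.0),
    noise_step: tuple[float, float] = (0.0, 0.0),
    noise: tuple[np.ndarray, np.ndarray] | None = None,
) -> Trajectory:
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if dt >= t_end:
        raise ValueError("dt must be smaller than t_end")
    n = int(round(t_end / dt))
    times = np.arange(n + 1) * dt
    I, Su = gate_arrays(program, policy, times[:-1])
    use_nf = variant.negative_feedback and not variant.usp18_knockdown
    ni, nu = (noise if noise is not None else (_EMPTY, _EMPTY))
    irf9, usp18 = _euler_core(
        I, Su, dt,
        params.k1, params.k2, params.k3, params.k4, params.k5,
        variant.positive_feedback, use_nf, variant.usp18_knockdown,
        variant.grouping == "gated",
        noise_step[0], noise_step[1], ni, nu,
        float(y0[0]), float(y0[1]),
    )
    return Trajectory(times=times, irf9=irf9, usp18=usp18, program=program)


def integrate(
    params: ModelParameters,
    program: InputProgram,
    policy: GatingPolicy,
    variant: Variant = FULL_MODEL,
    t_end: float = 48.0,
    dt: float = 0.001,
    y0: tuple[float, float] = (0.0, 0.0),
) -> Trajectory:
    """Forward-Euler trajectory from state ``y0`` (default (0, 0)) on the
    grid ``0..t_end`` with step ``dt``."""
    return _simulate(params, program, policy, variant, t_end, dt, y0=y0)


def _su_breakpoints(program: InputProgram, policy: GatingPolicy) -> list[float]:
    pts = []
    for a, b in program.intervals:
        pts.extend((a, b))
        d = policy.episode_delay(a)
        if np.isfinite(d) and a + d < b:
            pts.append(a + d)
    return pts


def reference_trajectory(
    params: ModelParameters,
    program: InputProgram,
    policy: GatingPolicy,
    variant: Variant = FULL_MODEL,
    t_end: float = 48.0,
    n_points: int = 201,
    rtol: float = 1e-10,
    atol: float = 1e-10,
) -> Trajectory:
    """High-accuracy trajectory from an adaptive Runge–Kutta integrator.

    The input I and gate Su are piecewise constant, so the ODE is solved
    segment by segment between their switch times.  Used to verify the
    Euler integrator; independent of it.
    """
    bps = sorted({0.0, float(t_end), *(p for p in _su_breakpoints(program, policy) if p < t_end)})
    times = np.linspace(0.0, t_end, n_points)
    out_i = np.zeros(n_points)
    out_u = np.zeros(n_points)
    y = np.array([0.0, 0.0])
    for a, b in zip(bps[:-1], bps[1:]):
        mid = 0.5 * (a + b)
        I = input_indicator(program, mid)
        Su = su_gate(policy, program, mid)

        def rhs(t, y, I=I, Su=Su):
            x, u = max(y[0], 0.0), max(y[1], 0.0)
            pf = params.k1 if not variant.positive_feedback else positive_feedback(x, params)
            if variant.usp18_knockdown or not variant.negative_feedback:
                nf = 1.0
            else:
                nf = negative_feedback(u, params)
            drive = pf * nf
            if variant.grouping == "gated":
                di = I * (params.k4 + drive)
                du = I * Su * (params.k5 + drive)
            else:
                di = I * params.k4 + drive
                du = I * Su * params.k5 + drive
            if variant.usp18_knockdown:
                du = 0.0
            return [di, du]

        mask = (times >= a) & (times <= b)
        eval_ts = times[mask]
        sol = solve_ivp(
            rhs, (a, b), y, method="RK45", rtol=rtol, atol=atol,
            dense_output=True,
        )
        if eval_ts.size:
            vals = sol.sol(eval_ts)
            out_i[mask] = vals[0]
            out_u[mask] = vals[1]
        y = sol.y[:, -1]
    return Trajectory(times=times, irf9=out_i, usp18=out_u, program=program)


# ---------------------------------------------------------------------------
# experiment programs


def build_pretreatment_program(
    pre_duration: float, break_duration: float, second_duration: float
) -> InputProgram:
    """Pretreatment protocol: ``pre`` hours of input, a break, then a second
    input.  With ``pre_duration = 0`` the single second interval still
    starts at ``break_duration`` so every condition shares the
    second-input clock."""
    for name, v in (
        ("pre_duration", pre_duration),
        ("break_duration", break_duration),
        ("second_duration", second_duration),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    second_on = pre_duration + break_duration
    intervals = []
    if pre_duration > 0:
        intervals.append((0.0, pre_duration))
    if second_duration > 0:
        intervals.append((second_on, second_on + second_duration))
    return InputProgram(tuple(intervals))


def build_pulse_program(n_pulses: int, on: float, off: float) -> InputProgram:
    """``n_pulses`` pulses of length ``on`` separated by gaps ``off``,
    starting at 0.  Zero-gap pulses merge into one sustained interval."""
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    if on <= 0:
        raise ValueError("on must be > 0")
    if off < 0:
        raise ValueError("off must be non-negative")
    period = on + off
    return InputProgram(tuple((i * period, i * period + on) for i in range(n_pulses)))
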
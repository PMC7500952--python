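"""Cell-cycle gating of USP18 induction.

USP18 transcription can only initiate inside an "open window" at the start
of the cell cycle (G1/early S).  If interferon arrives while a cell is
inside the window, induction starts immediately; otherwise the cell waits
until the window reopens at the next division.  With treatment onset
uniformly distributed over the cycle this produces a mixed delay
distribution: an atom at zero of mass ``w/T`` plus a uniform tail on
``(0, T - w]``.

All times are in hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GatingModel",
    "gated_delay",
    "sample_onset_phases",
    "delay_survival",
    "delay_cdf",
    "mean_delay",
    "fit_window",
    "group_fraction_above",
]


@dataclass(frozen=True)
class GatingModel:
    """Fixed-cycle gate: full cycle length ``cycle_length`` (T) and open
    window ``window`` (w), both in hours.  The window is anchored at the
    cycle start (division) and is half-open ``[0, w)``."""

    cycle_length: float = 21.82
    window: float = 7.3

    def __post_init__(self) -> None:
        if self.cycle_length <= 0:
            raise ValueError(f"cycle_length must be > 0, got {self.cycle_length}")
        if not 0 <= self.window <= self.cycle_length:
            raise ValueError(
                f"window must lie in [0, cycle_length], got {self.window}"
            )


def gated_delay(t0: float, model: GatingModel) -> float:
    """Delay before USP18 induction for a cell at cycle phase ``t0`` (hours
    since last division) at treatment onset.

    Zero inside the open window ``[0, w)``; otherwise the waiting time
    ``T - t0`` until the next division, where the window reopens.
    """
    T, w = model.cycle_length, model.window
    if not 0 <= t0 < T:
        raise ValueError(f"onset phase must lie in [0, T), got {t0}")
    return 0.0 if t0 < w else T - t0


def sample_onset_phases(
    n: int, model: GatingModel, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` treatment-onset phases uniformly on ``[0, T)``.

    ``seed`` may be an integer, an existing ``numpy.random.Generator``, or
    None (fresh entropy).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(0.0, model.cycle_length, size=n)


def delay_survival(d, model: GatingModel):
    """P(delay > d) under uniform onset phase.

    Closed form: ``(T - w - d)/T`` for ``0 <= d < T - w`` and 0 beyond;
    the mass at exactly zero delay is ``w/T``.  Accepts scalars or arrays.
    """
    T, w = model.cycle_length, model.window
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("delay must be non-negative")
    out = np.clip((T - w - d) / T, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def delay_cdf(d, model: GatingModel):
    """P(delay <= d); complements :func:`delay_survival`."""
    T, w = model.cycle_length, model.window
    d = np.asarray(d, dtype=float)
    out = np.where(d < 0, 0.0, np.clip((w + d) / T, 0.0, 1.0))
    return float(out) if out.ndim == 0 else out


def mean_delay(model: GatingModel) -> float:
    """E[delay] = (T - w)^2 / (2T) for uniform onset phase."""
    T, w = model.cycle_length, model.window
    return (T - w) ** 2 / (2.0 * T)


def fit_window(
    delays, cycle_length: float, grid_step: float = 0.01
) -> float:
    """Estimate the open-window length from observed delay times.

    Scans ``w`` on a grid over ``[0, T]`` and returns the value minimising
    the Kolmogorov–Smirnov (sup-norm) distance between the model delay CDF
    and the empirical CDF of ``delays``.  Ties break toward smaller ``w``.
    """
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0:
        raise ValueError("fit_window requires at least one delay sample")
    T = float(cycle_length)
    if np.any(delays < 0) or np.any(delays > T):
        raise ValueError("delays must lie within [0, cycle_length]")
    xs, counts = np.unique(delays, return_counts=True)
    n = delays.size
    cum = np.cumsum(counts)
    ecdf_hi = cum / n                      # F_n(x_j)
    ecdf_lo = (cum - counts) / n           # F_n(x_j^-)
    ws = np.arange(0.0, T + grid_step / 2, grid_step)
    # model CDF (and its left limit) at the sample points per candidate w;
    # both CDFs share an atom at exactly zero, so left limits must use the
    # model's left limit there as well
    F = np.clip((ws[:, None] + xs[None, :]) / T, 0.0, 1.0)
    F_left = np.where(xs[None, :] > 0, F, 0.0)
    ks = np.maximum(
        np.abs(F - ecdf_hi[None, :]).max(axis=1),
        np.abs(F_left - ecdf_lo[None, :]).max(axis=1),
    )
    return float(ws[int(np.argmin(ks))])


def group_fraction_above(delays, threshold: float) -> float:
    """Fraction of delays strictly greater than ``threshold`` (the Group-2
    fraction when ``threshold`` is 10 h)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0:
        raise ValueError("empty delay list")
    return float(np.mean(delays > threshold))
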
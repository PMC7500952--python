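"""Least-squares fitting, delay-time scan, and AIC model comparison.

The delay time tau is not fitted directly: it is assigned on a grid
(1..20 h in the original analysis) and the kinetic constants are refit at
every grid point; the fitting-error curve over tau then locates the
best-supported delay.  Three variants are compared by AIC: the full model,
the model without the positive feedback loop (pf replaced by the constant
k1), and the model without the negative feedback loop (nf = 1).

Observations combine a time trace of the IRF9 reporter under sustained
input with endpoint induction amounts from the pretreatment protocol,
normalized to the no-pretreatment control.  Because the trace and the
endpoints live on very different scales, trace residuals are divided by
the trace's maximum before weighting; the endpoint weight (default 10)
then means a tenfold per-observation weight relative to trace points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

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
    "Dataset",
    "FitResult",
    "TauScanResult",
    "AICResult",
    "sse_objective",
    "residual_vector",
    "fit_parameters",
    "scan_tau",
    "gaussian_loglik",
    "compare_models_aic",
    "free_parameter_names",
]

_ALL_KS = ("k1", "k2", "k3", "k4", "k5")


@dataclass
class Dataset:
    """Observations for fitting.

    ``trace_times``/``trace_values``: IRF9 reporter under sustained input
    (input on from 0 to the last trace time).  ``endpoint_pre_h`` /
    ``endpoint_induction_norm``: control-normalized induction amounts for
    pretreatment durations (the no-pretreatment control, 1.0 by
    definition, need not be included).  ``break_h``/``second_h`` define
    the protocol used for the endpoint predictions.
    """

    trace_times: np.ndarray
    trace_values: np.ndarray
    endpoint_pre_h: np.ndarray
    endpoint_induction_norm: np.ndarray
    trace_weight: float = 1.0
    endpoint_weight: float = 10.0
    break_h: float = 8.0
    second_h: float = 10.0

    def __post_init__(self) -> None:
        self.trace_times = np.asarray(self.trace_times, dtype=float)
        self.trace_values = np.asarray(self.trace_values, dtype=float)
        self.endpoint_pre_h = np.asarray(self.endpoint_pre_h, dtype=float)
        self.endpoint_induction_norm = np.asarray(
            self.endpoint_induction_norm, dtype=float
        )
        if self.trace_times.size + self.endpoint_pre_h.size == 0:
            raise ValueError("dataset needs at least one observation")
        if self.trace_times.size != self.trace_values.size:
            raise ValueError("trace_times and trace_values differ in length")
        if self.endpoint_pre_h.size != self.endpoint_induction_norm.size:
            raise ValueError("endpoint arrays differ in length")
        if self.trace_weight <= 0 or self.endpoint_weight <= 0:
            raise ValueError("weights must be > 0")

    @property
    def n_obs(self) -> int:
        return int(self.trace_times.size + self.endpoint_pre_h.size)

    @property
    def trace_scale(self) -> float:
        if self.trace_times.size == 0:
            return 1.0
        s = float(np.max(np.abs(self.trace_values)))
        return s if s > 0 else 1.0


@dataclass
class FitResult:
    params: ModelParameters
    tau: float
    sse: float
    converged: bool
    free_names: tuple[str, ...]
    n_starts: int = 0

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be non-negative")


@dataclass
class TauScanResult:
    taus: np.ndarray
    fits: list
    best_tau: float

    @property
    def errors(self) -> np.ndarray:
        return np.array([f.sse for f in self.fits])


@dataclass
class AICResult:
    entries: dict  # variant name -> {log_likelihood, n_params, aic, fit}
    best: str


def free_parameter_names(variant: Variant) -> tuple[str, ...]:
    """Kinetic constants that are free under a variant.

    Cutting the positive feedback loop replaces pf by the constant k1, so
    k2 drops out; disabling the negative feedback drops k3; the USP18
    knockdown additionally removes k5 (and k3) since USP18 is held at 0.
    """
    if variant.usp18_knockdown:
        names = ["k1", "k4"] + (["k2"] if variant.positive_feedback else [])
        return tuple(sorted(names, key=_ALL_KS.index))
    names = list(_ALL_KS)
    if not variant.positive_feedback:
        names.remove("k2")
    if not variant.negative_feedback:
        names.remove("k3")
    return tuple(names)


def predict(
    dataset: Dataset,
    params: ModelParameters,
    tau: float,
    variant: Variant = FULL_MODEL,
    dt: float = 0.005,
) -> tuple[np.ndarray, np.ndarray]:
    """Model predictions at the dataset's observation points: the sustained
    trace sampled at ``trace_times`` and the control-normalized endpoint
    inductions."""
    policy = GatingPolicy.fixed_delay(tau)
    trace_pred = np.zeros(0)
    if dataset.trace_times.size:
        t_end = float(dataset.trace_times[-1])
        traj = integrate(
            params, InputProgram(((0.0, t_end),)), policy, variant,
            t_end=t_end, dt=dt,
        )
        trace_pred = np.interp(dataset.trace_times, traj.times, traj.irf9)
    endpoint_pred = np.zeros(0)
    if dataset.endpoint_pre_h.size:
        pres = np.unique(np.concatenate(([0.0], dataset.endpoint_pre_h)))
        raw = {}
        for pre in pres:
            program = build_pretreatment_program(pre, dataset.break_h, dataset.second_h)
            second_on = pre + dataset.break_h
            t_end = second_on + dataset.second_h
            traj = integrate(params, program, policy, variant, t_end=t_end, dt=dt)
            i_on = int(round(second_on / dt))
            raw[pre] = traj.irf9[-1] - traj.irf9[i_on]
        control = raw[0.0]
        if control <= 0:
            raise FloatingPointError(
                "control induction is non-positive; cannot normalize endpoints"
            )
        endpoint_pred = np.array([raw[p] / control for p in dataset.endpoint_pre_h])
    return trace_pred, endpoint_pred


def residual_vector(
    dataset: Dataset,
    params: ModelParameters,
    tau: float,
    variant: Variant = FULL_MODEL,
    dt: float = 0.005,
) -> np.ndarray:
    """Weighted residuals; trace residuals are scale-normalized (divided by
    the trace maximum) so the two observation types are commensurate."""
    trace_pred, endpoint_pred = predict(dataset, params, tau, variant, dt)
    parts = []
    if dataset.trace_times.size:
        parts.append(
            np.sqrt(dataset.trace_weight)
            * (dataset.trace_values - trace_pred)
            / dataset.trace_scale
        )
    if dataset.endpoint_pre_h.size:
        parts.append(
            np.sqrt(dataset.endpoint_weight)
            * (dataset.endpoint_induction_norm - endpoint_pred)
        )
    return np.concatenate(parts)


def sse_objective(
    dataset: Dataset,
    params: ModelParameters,
    tau: float,
    variant: Variant = FULL_MODEL,
    dt: float = 0.005,
) -> float:
    """Weighted sum of squared residuals."""
    r = residual_vector(dataset, params, tau, variant, dt)
    return float(np.dot(r, r))


def _initial_points(
    dataset: Dataset, names: tuple[str, ...], n_starts: int, seed: int
) -> np.ndarray:
    """Seeded log-uniform initial points spanning four decades around
    data-informed scales (rates ~ trace scale per observation span;
    saturation constants ~ trace scale)."""
    rng = np.random.default_rng(seed)
    span = float(dataset.trace_times[-1]) if dataset.trace_times.size else 40.0
    rate_scale = max(dataset.trace_scale / max(span, 1.0), 1e-6)
    conc_scale = max(dataset.trace_scale, 1e-6)
    centers = {
        "k1": rate_scale, "k4": rate_scale, "k5": rate_scale,
        "k2": conc_scale, "k3": conc_scale,
    }
    logc = np.array([np.log10(centers[n]) for n in names])
    return logc[None, :] + rng.uniform(-2.0, 2.0, size=(n_starts, len(names)))


def fit_parameters(
    dataset: Dataset,
    tau: float,
    variant: Variant = FULL_MODEL,
    n_starts: int = 10,
    seed: int = 0,
    dt: float = 0.005,
    free: tuple[str, ...] | None = None,
    base_params: ModelParameters | None = None,
    max_nfev: int = 200,
) -> FitResult:
    """Bounded nonlinear least squares over the variant's free kinetic
    constants, optimized in log10 space with seeded multistart.

    ``free`` overrides the variant's free-parameter set; an empty tuple
    evaluates ``base_params`` without optimizing.
    """
    names = free_parameter_names(variant) if free is None else tuple(free)
    base = base_params or ModelParameters(k1=1.0, k2=1.0, k3=1.0, k4=1.0, k5=1.0)

    def make_params(logx: np.ndarray) -> ModelParameters:
        kw = {n: 10.0 ** v for n, v in zip(names, logx)}
        return base.replace(**kw)

    if not names:
        sse = sse_objective(dataset, base, tau, variant, dt)
        return FitResult(base, tau, sse, True, (), 0)

    def fun(logx):
        try:
            return residual_vector(dataset, make_params(logx), tau, variant, dt)
        except FloatingPointError:
            return np.full(dataset.n_obs, 1e6)

    x0s = _initial_points(dataset, names, n_starts, seed)
    best = None
    failures = []
    for x0 in x0s:
        try:
            res = least_squares(
                fun, x0, method="trf", bounds=(-10.0, 10.0),
                xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=max_nfev,
            )
        except Exception as exc:  # noqa: BLE001 - collected for reporting
            failures.append(exc)
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(
            f"all {n_starts} starts failed for tau={tau}, variant={variant}: "
            f"{failures[-1] if failures else 'no attempts'}"
        )
    sse = float(2.0 * best.cost)  # least_squares cost = 0.5 * sum r^2
    return FitResult(
        make_params(best.x), tau, sse, bool(best.status > 0), names, n_starts
    )


def scan_tau(
    dataset: Dataset,
    taus=tuple(range(1, 21)),
    variant: Variant = FULL_MODEL,
    **fit_kwargs,
) -> TauScanResult:
    """Refit all free constants at each assigned delay time and return the
    error curve; the best tau minimizes the fitting error (ties break
    toward the smallest tau)."""
    taus = np.asarray(list(taus), dtype=float)
    if taus.size == 0:
        raise ValueError("taus must be non-empty")
    fits = [fit_parameters(dataset, float(t), variant, **fit_kwargs) for t in taus]
    errors = np.array([f.sse for f in fits])
    order = np.lexsort((taus, errors))
    best_tau = float(taus[order[0]])
    return TauScanResult(taus=taus, fits=fits, best_tau=best_tau)


def gaussian_loglik(residuals, sigma="mle") -> float:
    """Gaussian log-likelihood of a residual vector.

    With ``sigma="mle"`` the variance is profiled out (sigma^2 = SSE/n),
    giving ``lnL = -(n/2) * (ln(2*pi*SSE/n) + 1)``.
    """
    r = np.asarray(residuals, dtype=float)
    n = r.size
    if n == 0:
        raise ValueError("empty residual vector")
    sse = float(np.dot(r, r))
    if isinstance(sigma, str):
        if sigma != "mle":
            raise ValueError(f"unknown sigma spec {sigma!r}")
        sigma2 = max(sse / n, 1e-300)
        return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return -0.5 * n * np.log(2.0 * np.pi * sigma**2) - sse / (2.0 * sigma**2)


_COMPARED_VARIANTS = {
    "full": Variant(),
    "no_positive_feedback": Variant(positive_feedback=False),
    "no_negative_feedback": Variant(negative_feedback=False),
}


def compare_models_aic(
    dataset: Dataset,
    tau: float,
    n_starts: int = 10,
    seed: int = 0,
    dt: float = 0.005,
    max_nfev: int = 200,
) -> AICResult:
    """Fit the full and both loop-ablated variants at the same assigned
    tau and rank them by AIC = 2k - 2 lnL.

    k counts the fitted kinetic constants plus one for the MLE noise
    variance.  Ties in AIC break toward the smaller k.
    """
    entries = {}
    for name, variant in _COMPARED_VARIANTS.items():
        fit = fit_parameters(
            dataset, tau, variant, n_starts=n_starts, seed=seed, dt=dt,
            max_nfev=max_nfev,
        )
        r = residual_vector(dataset, fit.params, tau, variant, dt)
        lnl = gaussian_loglik(r, sigma="mle")
        k = len(fit.free_names) + 1
        entries[name] = {
            "log_likelihood": float(lnl),
            "n_params": k,
            "aic": float(2 * k - 2 * lnl),
            "fit": fit,
        }
    best = min(entries, key=lambda n: (entries[n]["aic"], entries[n]["n_params"]))
    return AICResult(entries=entries, best=best)
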
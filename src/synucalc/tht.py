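"""Finke–Watzky aggregation kinetics, lag times, and monomer quantification.

ThT fluorescence reports fibril mass over time. The two-step
nucleation/autocatalytic-growth mechanism (nucleation rate constant k1,
elongation rate constant k2) gives the product concentration

    B(t) = A0 - (k1/k2 + A0) / (1 + (k1/(k2*A0)) * exp((k1 + k2*A0) * t))

with B(0) = 0 and B(inf) = A0. Lag times are extracted by the tangent
method: a line fitted to the elongation phase is extended back to the
baseline, and the lag is the intersection time. Remaining monomer after
aggregation is read off a linear SEC calibration curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from synucalc.errors import FitError, InputError, NoTransitionError

_EXP_CLIP = 700.0  # exp argument guard


@dataclass
class ThTCurve:
    """One well's fluorescence time course (times in hours, ascending)."""

    times: np.ndarray
    fluorescence: np.ndarray
    well: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.shape != self.fluorescence.shape:
            raise InputError("times and fluorescence must align")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly ascending")


@dataclass
class FWFit:
    A0: float
    k1: float
    k2: float
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    rss: float
    baseline: float
    message: str = ""


@dataclass
class LagTime:
    lag: float
    slope: float
    intercept: float
    baseline: float


def fw_model(t, A0: float, k1: float, k2: float):
    """Product concentration of the two-step nucleation/growth model."""
    if A0 <= 0 or k1 <= 0 or k2 <= 0:
        raise InputError("A0, k1, k2 must all be positive")
    t = np.asarray(t, dtype=float)
    kappa = k1 + k2 * A0
    r = k1 / (k2 * A0)
    expo = np.exp(np.clip(kappa * t, None, _EXP_CLIP))
    out = A0 - (k1 / k2 + A0) / (1.0 + r * expo)
    return float(out) if out.ndim == 0 else out


def average_curves(curves: list[ThTCurve], condition: str | None = None) -> ThTCurve:
    """Mean fluorescence over replicate wells on a common time grid."""
    if condition is not None:
        curves = [c for c in curves if c.condition == condition]
    if not curves:
        raise InputError("no curves to average")
    t0 = curves[0].times
    for c in curves[1:]:
        if len(c.times) != len(t0) or not np.allclose(c.times, t0):
            raise InputError("curves must share a common time grid to average")
    mean = np.mean([c.fluorescence for c in curves], axis=0)
    return ThTCurve(times=t0, fluorescence=mean, well="mean",
                    condition=condition or curves[0].condition)


def _baseline_window(y: np.ndarray, frac: float = 0.10) -> int:
    """Number of leading pre-transition samples to use for the baseline.

    The first ``frac`` of points, capped at the first crossing of 10% of
    the total amplitude so that fast transitions do not leak into the
    baseline estimate.
    """
    thresh = y.min() + 0.10 * (y.max() - y.min())
    below = np.flatnonzero(y <= thresh)
    # last sub-threshold sample: robust onset for monotone transitions,
    # ~end of trace for flat/noise-only input (no spurious capping)
    crossing = int(below[-1]) + 1 if len(below) else len(y)
    return max(2, min(int(round(frac * len(y))), crossing))


def _baseline(y: np.ndarray, frac: float = 0.10) -> float:
    return float(np.median(y[: _baseline_window(y, frac)]))


def fit_fw(
    curve: ThTCurve,
    a0_fixed: float | None = None,
    baseline_frac: float = 0.10,
) -> FWFit:
    """Bounded least-squares fit of (A0, k1, k2) to a baseline-subtracted trace.

    Deterministic given the data; initialisation is derived from the trace
    (amplitude, half-rise time and local slope). ``a0_fixed`` pins the
    amplitude and fits only the rate constants.
    """
    if len(curve.times) < 10:
        raise InputError("need at least 10 time points")
    y = curve.fluorescence
    k = max(2, len(y) // 10)
    if y[-k:].mean() <= y[:k].mean():
        raise NoTransitionError("curve shows no net increase")
    base0 = _baseline(y, baseline_frac)
    t = curve.times

    amp = float(y.max() - base0)
    if amp <= 0:
        raise NoTransitionError("no positive amplitude above baseline")
    # initial guesses from the half-rise point
    ihalf = int(np.argmax(y - base0 >= amp / 2))
    thalf = t[ihalf] if t[ihalf] > 0 else (t[1] + t[0]) / 2
    span = max(t[-1] - t[0], 1e-9)
    kappa0 = max(4.0 / max(thalf, 0.05 * span), 1e-3)
    r0 = np.exp(-np.clip(kappa0 * thalf, None, _EXP_CLIP))
    k10 = max(kappa0 * r0 / (1 + r0), 1e-12)
    A00 = a0_fixed if a0_fixed is not None else amp
    k20 = max((kappa0 - k10) / A00, 1e-12)

    # the baseline offset is fitted jointly (subtracted within the model)
    if a0_fixed is None:
        def resid(theta):
            return theta[3] + fw_model(t, theta[0], theta[1], theta[2]) - y
        theta0 = np.array([A00, k10, k20, base0])
        lo = np.array([amp * 0.2, 1e-15, 1e-15, -np.inf])
        hi = np.array([amp * 10.0, np.inf, np.inf, np.inf])
        names = ["A0", "k1", "k2", "baseline"]
    else:
        def resid(theta):
            return theta[2] + fw_model(t, a0_fixed, theta[0], theta[1]) - y
        theta0 = np.array([k10, k20, base0])
        lo = np.array([1e-15, 1e-15, -np.inf])
        hi = np.array([np.inf, np.inf, np.inf])
        names = ["k1", "k2", "baseline"]

    res = least_squares(resid, np.clip(theta0, lo, hi), bounds=(lo, hi),
                        method="trf", x_scale="jac")
    if not res.success:
        raise FitError(f"Finke-Watzky fit failed: {res.message}")
    rss = float(2 * res.cost)
    dof = max(len(t) - len(res.x), 1)
    s2 = rss / dof
    cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
    se = {n: float(np.sqrt(max(cov[i, i], 0.0))) for i, n in enumerate(names)}
    ci = {n: (float(res.x[i] - 1.96 * se[n]), float(res.x[i] + 1.96 * se[n]))
          for i, n in enumerate(names)}
    params = dict(zip(names, (float(v) for v in res.x)))
    if a0_fixed is not None:
        params["A0"] = float(a0_fixed)
        se.setdefault("A0", 0.0)
        ci.setdefault("A0", (params["A0"], params["A0"]))
    return FWFit(A0=params["A0"], k1=params["k1"], k2=params["k2"], se=se,
                 ci95=ci, rss=rss, baseline=params["baseline"], message=res.message)


def lag_time_tangent(
    curve: ThTCurve,
    window: tuple[float, float] = (0.2, 0.8),
    baseline_frac: float = 0.10,
    noise_factor: float = 5.0,
) -> LagTime:
    """Lag time by extending the elongation-phase line back to the baseline.

    The baseline is the median of the first ``baseline_frac`` of points; the
    elongation line is a least-squares fit over points whose amplitude lies
    between the ``window`` fractions of (max - baseline), restricted to the
    rising flank. A sharp (step-like) transition with no in-window samples
    falls back to the two samples bracketing the jump. Negative lags are
    clamped to 0 with a warning.
    """
    t, y = curve.times, curve.fluorescence
    k = _baseline_window(y, baseline_frac)
    base = float(np.median(y[:k]))
    noise = float(np.std(y[:k], ddof=1))
    amp = float(y.max() - base)
    if amp <= 0 or (noise > 0 and amp <= noise_factor * noise):
        raise NoTransitionError("no detectable transition above baseline noise")
    lo = base + window[0] * amp
    hi = base + window[1] * amp
    i_top = int(np.argmax(y >= hi))  # first sample at/above the upper level
    mask = (y >= lo) & (y <= hi)
    mask[i_top + 1:] = False  # stay on the rising flank
    if mask.sum() >= 2:
        fit = linregress(t[mask], y[mask])
        slope, intercept = float(fit.slope), float(fit.intercept)
    else:
        # step-like transition: line through the bracketing samples
        i_pre = max(i_top - 1, 0)
        if i_top == i_pre:
            raise NoTransitionError("transition at the first sample")
        slope = float((y[i_top] - y[i_pre]) / (t[i_top] - t[i_pre]))
        intercept = float(y[i_top] - slope * t[i_top])
    if slope <= 0:
        raise FitError("elongation-phase slope is nonpositive")
    lag = (base - intercept) / slope
    if lag < 0:
        warnings.warn("negative lag time clamped to 0")
        lag = 0.0
    return LagTime(lag=float(lag), slope=slope, intercept=intercept, baseline=base)


def fold_change(value_a: float, value_b: float) -> float:
    """Ratio a/b (e.g. rate constant with vs without calcium)."""
    if value_b == 0:
        raise InputError("zero denominator in fold change")
    return value_a / value_b


@dataclass
class MonomerEstimate:
    concentration_uM: float
    extrapolated: bool
    slope: float
    intercept: float


def sec_monomer(
    peak_area: float, calibration: list[tuple[float, float]]
) -> MonomerEstimate:
    """Map an SEC peak area to monomer concentration via a linear calibration.

    ``calibration`` is a list of (area, concentration µM) pairs; an ordinary
    least-squares line is fitted and the query area interpolated. Queries
    outside the calibrated area range are flagged as extrapolated.
    """
    if len(calibration) < 2:
        raise InputError("need at least 2 calibration points")
    areas = np.array([a for a, _ in calibration], dtype=float)
    concs = np.array([c for _, c in calibration], dtype=float)
    if np.ptp(areas) == 0:
        raise InputError("calibration areas must be distinct")
    fit = linregress(areas, concs)
    value = fit.slope * peak_area + fit.intercept
    extrapolated = not (areas.min() <= peak_area <= areas.max())
    return MonomerEstimate(
        concentration_uM=float(value),
        extrapolated=bool(extrapolated),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )
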
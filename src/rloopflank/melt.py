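"""Melting-temperature extraction from UV absorbance refolding curves.

Nicked-dumbbell junction constructs are refolded by slow cooling while A260
is recorded (hyperchromicity: the unfolded state absorbs more).  Because the
constructs are unimolecular, folding is concentration-independent and a
two-state model with linear folded/unfolded baselines is the natural fit:

``A(T) = B_low(T) + (B_high(T) - B_low(T)) * s(T)``,
``s(T) = 1 / (1 + exp(-(T - Tm) / w))``

with ``B_low``/``B_high`` linear in ``T`` and ``w`` the transition width.
``Tm`` is the transition midpoint.  A smoothed-derivative method (extremum of
``dA/dT``) is available as a fallback and cross-check; the width parameter is
reported as-is and not interpreted thermodynamically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .reactivity import ValidationError, aggregate_replicates

MIN_POINTS = 20


class NoTransitionError(ValidationError):
    """Raised when a curve shows no detectable folding transition."""


@dataclass(frozen=True)
class MeltingCurve:
    """A260 versus temperature, strictly monotone temperature grid."""

    temperature_c: tuple[float, ...]
    absorbance: tuple[float, ...]
    ramp: str = "cooling"

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature_c)
        if len(t) < MIN_POINTS:
            raise ValidationError(f"need >= {MIN_POINTS} points, got {len(t)}")
        if len(self.absorbance) != len(t):
            raise ValidationError("temperature and absorbance lengths differ")
        d = np.diff(t)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("temperatures must be strictly monotone")


@dataclass(frozen=True)
class TmResult:
    """Fitted melting temperature with method provenance."""

    tm_c: float
    method: str  # "two_state_fit" or "derivative"
    width_c: float | None = None
    baseline_low: tuple[float, float] | None = None  # (intercept, slope)
    baseline_high: tuple[float, float] | None = None
    replicate_tms: tuple[float, ...] | None = None
    mean: float | None = None
    sd: float | None = None


@dataclass(frozen=True)
class TmDifference:
    """Difference of two melting temperatures with propagated uncertainty."""

    delta_c: float
    uncertainty_c: float | None
    uncertainty_available: bool


def simulate_melting_curve(
    tm: float,
    width: float,
    baseline_low: tuple[float, float] = (0.30, 0.0002),
    baseline_high: tuple[float, float] = (0.40, 0.0004),
    noise_sd: float = 0.0,
    seed: int = 0,
    t_start: float = 95.0,
    t_stop: float = 2.0,
    t_step: float = 0.5,
) -> MeltingCurve:
    """Generate a two-state refolding curve on a cooling ramp.

    Defaults mimic the measurement protocol (95 -> 2 °C in 0.5 °C steps, 187
    points).  Baselines are ``(intercept, slope)`` pairs; Gaussian noise of
    ``noise_sd`` absorbance units is added with the given seed.
    """
    if width <= 0:
        raise ValidationError("transition width must be > 0")
    n = int(round(abs(t_start - t_stop) / t_step)) + 1
    temps = np.linspace(t_start, t_stop, n)
    low = baseline_low[0] + baseline_low[1] * temps
    high = baseline_high[0] + baseline_high[1] * temps
    s = 1.0 / (1.0 + np.exp(-(temps - tm) / width))
    a = low + (high - low) * s
    if noise_sd > 0:
        a = a + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return MeltingCurve(
        temperature_c=tuple(temps),
        absorbance=tuple(a),
        ramp="cooling" if t_start > t_stop else "heating",
    )


def _smoothed_derivative(t: np.ndarray, a: np.ndarray, window: int = 5) -> np.ndarray:
    """dA/dT of a centered-moving-average-smoothed curve."""
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.repeat(a[0], pad), a, np.repeat(a[-1], pad)])
    smooth = np.convolve(padded, kernel, mode="valid")
    return np.gradient(smooth, t)


def fit_tm(curve: MeltingCurve, method: str = "two_state_fit") -> TmResult:
    """Extract Tm from one curve.

    ``two_state_fit`` (default): least-squares fit of the two-state logistic
    with linear baselines; falls back to the derivative method (tagged as
    such) if the optimizer fails.  ``derivative``: temperature of the
    extremal smoothed derivative.  The fit is invariant to affine rescaling
    of the absorbance axis and to reversing the temperature order.  A curve
    with no detectable transition raises :class:`NoTransitionError`.
    """
    t = np.asarray(curve.temperature_c, dtype=float)
    a = np.asarray(curve.absorbance, dtype=float)
    order = np.argsort(t)
    t, a = t[order], a[order]

    # normalize absorbance so tolerances are scale-free
    a_span = float(a.max() - a.min())
    detrend = a - np.polyval(np.polyfit(t, a, 1), t)
    if a_span == 0 or float(np.abs(detrend).max()) <= max(1e-12, 1e-3 * a_span):
        raise NoTransitionError("no transition: curve is baseline only")
    z = (a - a.min()) / a_span

    deriv = _smoothed_derivative(t, z)
    interior = slice(2, len(t) - 2)
    i_star = int(np.argmax(np.abs(deriv[interior]))) + 2
    tm0 = float(t[i_star])
    if method == "derivative":
        return TmResult(tm_c=tm0, method="derivative")
    if method != "two_state_fit":
        raise ValidationError(f"unknown method {method!r}")

    n_edge = max(3, len(t) // 7)
    lo_fit = np.polyfit(t[:n_edge], z[:n_edge], 1)
    hi_fit = np.polyfit(t[-n_edge:], z[-n_edge:], 1)
    w0 = max(0.5, (t[-1] - t[0]) / 30.0)

    def model(params: np.ndarray) -> np.ndarray:
        tm, logw, c_lo, m_lo, c_hi, m_hi = params
        s = 1.0 / (1.0 + np.exp(-(t - tm) / math.exp(logw)))
        low = c_lo + m_lo * t
        high = c_hi + m_hi * t
        return low + (high - low) * s

    def resid(params: np.ndarray) -> np.ndarray:
        return model(params) - z

    x0 = np.array([tm0, math.log(w0), lo_fit[1], lo_fit[0], hi_fit[1], hi_fit[0]])
    try:
        sol = least_squares(resid, x0, method="lm", max_nfev=20000)
        ok = sol.success and t.min() - 5 <= sol.x[0] <= t.max() + 5
    except Exception:
        ok = False
    if not ok:
        return TmResult(tm_c=tm0, method="derivative")

    tm, logw, c_lo, m_lo, c_hi, m_hi = sol.x
    width = math.exp(logw)
    amp_at_tm = abs((c_hi + m_hi * tm) - (c_lo + m_lo * tm))
    resid_sd = float(np.std(sol.fun))
    if amp_at_tm < 3.0 * max(resid_sd, 1e-6):
        raise NoTransitionError("no transition: fitted amplitude within noise")
    # de-normalize baselines back to absorbance units
    scale, offset = a_span, float(a.min())
    return TmResult(
        tm_c=float(tm),
        method="two_state_fit",
        width_c=float(width),
        baseline_low=(float(c_lo * scale + offset), float(m_lo * scale)),
        baseline_high=(float(c_hi * scale + offset), float(m_hi * scale)),
    )


def aggregate_tm(results: Sequence[TmResult]) -> TmResult:
    """Combine replicate fits into mean ± sample SD."""
    if not results:
        raise ValidationError("no replicate results")
    tms = tuple(r.tm_c for r in results)
    agg = aggregate_replicates(tms)
    return TmResult(
        tm_c=float(agg.mean),
        method=results[0].method,
        replicate_tms=tms,
        mean=float(agg.mean),
        sd=None if agg.sd is None else float(agg.sd),
    )


def compare_tm(a: TmResult, b: TmResult) -> TmDifference:
    """``Tm(a) - Tm(b)`` with root-sum-square propagated uncertainty.

    If either input lacks replicate scatter (single replicate, or no
    replicate data), the difference is still reported but the uncertainty is
    flagged unavailable.
    """
    mean_a = a.mean if a.mean is not None else a.tm_c
    mean_b = b.mean if b.mean is not None else b.tm_c
    delta = float(mean_a - mean_b)
    if a.sd is None or b.sd is None:
        return TmDifference(delta_c=delta, uncertainty_c=None, uncertainty_available=False)
    return TmDifference(
        delta_c=delta,
        uncertainty_c=float(math.hypot(a.sd, b.sd)),
        uncertainty_available=True,
    )
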
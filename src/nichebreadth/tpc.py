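"""Zero-inflated Kumaraswamy-shaped thermal performance curves.

A thermal performance curve (TPC) maps temperature to expected performance
(here: relative growth rate, RGR). The curve used throughout this package is
a mode-normalized Kumaraswamy kernel on the interval between the critical
thermal minimum ``L`` and maximum ``U``:

    t      = (x - L) / (U - L)
    g(t)   = a * b * t**(a-1) * (1 - t**a)**(b-1)
    t_star = ((a - 1) / (a*b - 1))**(1/a)
    P(x)   = h * g(t) / g(t_star)   for L < x < U, else 0

With shapes ``a > 1`` and ``b > 1`` the kernel has a unique interior mode at
``t_star``, so ``P`` is unimodal on ``(L, U)``, zero outside, and attains its
maximum value exactly ``h`` at the thermal optimum
``T_opt = L + t_star * (U - L)``.

Thermal breadth (B50) is the span of temperatures over which performance is
at least a fraction (default 50%) of the maximum; the two crossing points are
found by bisection and, to avoid extrapolating beyond the experiment, clipped
to the measurement window (15-50 degC by default).

The observation model carried alongside the curve is a zero-inflated
truncated normal: an exact zero occurs with probability
``inv_logit(zi_intercept + zi_slope * mu)`` (``zi_slope <= 0``, so zeros
concentrate where expected performance is low, i.e. near the thermal limits),
otherwise performance is Normal(mu, noise_sd) truncated to (0, inf).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ParameterError",
    "CurveParams",
    "MeasurementWindow",
    "BreadthBounds",
    "evaluate_curve",
    "thermal_optimum",
    "breadth_bounds",
    "breadth_bounds_arrays",
    "to_unconstrained",
    "from_unconstrained",
    "UNCONSTRAINED_NAMES",
]

#: order of the unconstrained curve-parameter vector used by the simulator
#: and the hierarchical fit: location (degC), log span, log(a-1), log(b-1),
#: log height.
UNCONSTRAINED_NAMES = ("lower", "log_span", "log_am1", "log_bm1", "log_height")

BISECT_TOL_C = 1e-6  # degC tolerance for the B50 root finder


class ParameterError(ValueError):
    """Raised when curve parameters violate their domain constraints."""


@dataclass(frozen=True)
class CurveParams:
    """Parameters of one genotype's zero-inflated TPC.

    Attributes
    ----------
    lower, upper:
        Critical thermal minimum / maximum (degC); performance is exactly
        zero at and beyond them.
    shape_a, shape_b:
        Kumaraswamy shape parameters, both > 1 so the optimum is interior.
    height:
        Expected performance at the optimum (performance units, > 0).
    noise_sd:
        Residual SD of the truncated-normal observation model (> 0).
    zi_intercept, zi_slope:
        Zero-inflation logit intercept and slope (per performance unit,
        <= 0): P(zero) = inv_logit(zi_intercept + zi_slope * mu).
    """

    lower: float
    upper: float
    shape_a: float
    shape_b: float
    height: float
    noise_sd: float = 0.05
    zi_intercept: float = -2.0
    zi_slope: float = -10.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ParameterError(f"need lower < upper, got {self.lower} >= {self.upper}")
        if not self.shape_a > 1.0:
            raise ParameterError(f"shape_a must be > 1, got {self.shape_a}")
        if not self.shape_b > 1.0:
            raise ParameterError(f"shape_b must be > 1, got {self.shape_b}")
        if not self.height > 0.0:
            raise ParameterError(f"height must be > 0, got {self.height}")
        if not self.noise_sd > 0.0:
            raise ParameterError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.zi_slope > 0.0:
            raise ParameterError(f"zi_slope must be <= 0, got {self.zi_slope}")

    def shifted(self, delta_c: float) -> "CurveParams":
        """Return a copy translated by ``delta_c`` degC along the temperature axis."""
        return replace(self, lower=self.lower + delta_c, upper=self.upper + delta_c)


@dataclass(frozen=True)
class MeasurementWindow:
    """Temperature range actually measured in the growth-chamber experiment.

    Breadth bounds falling outside ``[t_min, t_max]`` are clipped to the
    nearest measured temperature rather than extrapolated.
    """

    regime_temps: tuple = (15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0)

    def __post_init__(self) -> None:
        temps = tuple(float(t) for t in self.regime_temps)
        if len(temps) < 2 or any(b <= a for a, b in zip(temps, temps[1:])):
            raise ParameterError("regime_temps must be strictly increasing with >= 2 entries")
        object.__setattr__(self, "regime_temps", temps)

    @property
    def t_min(self) -> float:
        return self.regime_temps[0]

    @property
    def t_max(self) -> float:
        return self.regime_temps[-1]

    @property
    def span(self) -> float:
        return self.t_max - self.t_min

    def center(self) -> float:
        """Grand mean of the regime temperatures (used to center data)."""
        return float(np.mean(self.regime_temps))


@dataclass(frozen=True)
class BreadthBounds:
    """B50 interval of one curve, after clipping to the measurement window."""

    lower: float
    upper: float
    lower_truncated: bool = False
    upper_truncated: bool = False

    @property
    def breadth(self) -> float:
        return self.upper - self.lower

    def __iter__(self):
        return iter((self.lower, self.upper))


def _mode_t(a, b):
    # interior mode of the Kumaraswamy kernel on (0, 1); requires a>1, b>1
    return ((a - 1.0) / (a * b - 1.0)) ** (1.0 / a)


def _kernel(t, a, b):
    return a * b * t ** (a - 1.0) * (1.0 - t**a) ** (b - 1.0)


def evaluate_curve(params: CurveParams, x) -> np.ndarray | float:
    """Expected performance at temperature(s) ``x``.

    Returns 0 outside ``(lower, upper)`` and exactly ``height`` at the
    thermal optimum. Accepts scalars or arrays.
    """
    x_arr = np.asarray(x, dtype=float)
    L, U, a, b = params.lower, params.upper, params.shape_a, params.shape_b
    t = (x_arr - L) / (U - L)
    inside = (t > 0.0) & (t < 1.0)
    t_safe = np.where(inside, t, 0.5)
    peak = _kernel(_mode_t(a, b), a, b)
    vals = np.where(inside, params.height * _kernel(t_safe, a, b) / peak, 0.0)
    if np.ndim(x) == 0:
        return float(vals)
    return vals


def thermal_optimum(params: CurveParams) -> float:
    """Temperature (degC) at which expected performance is maximal."""
    t_star = _mode_t(params.shape_a, params.shape_b)
    return params.lower + t_star * (params.upper - params.lower)


def _bisect_arrays(lo, hi, target, L, U, a, b, tol=BISECT_TOL_C, max_iter=200):
    """Vectorized bisection for kernel(t)/kernel(t*) = target on [lo, hi] (degC).

    The bracket endpoints must straddle the root; unimodality of the kernel
    guarantees this when one endpoint is the optimum and the other a limit.
    """
    lo = np.array(lo, dtype=float, copy=True)
    hi = np.array(hi, dtype=float, copy=True)
    peak = _kernel(_mode_t(a, b), a, b)

    def rel(x):
        t = np.clip((x - L) / (U - L), 1e-300, 1.0 - 1e-16)
        return _kernel(t, a, b) / peak - target

    f_lo = rel(lo)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = rel(mid)
        same = np.sign(f_mid) == np.sign(f_lo)
        lo = np.where(same, mid, lo)
        f_lo = np.where(same, f_mid, f_lo)
        hi = np.where(same, hi, mid)
        if np.max(hi - lo) < tol and np.max(lo - hi) < tol:
            break
    return 0.5 * (lo + hi)


def breadth_bounds_arrays(L, U, a, b, threshold=0.5, window: MeasurementWindow | None = None):
    """B50 bounds for arrays of curve parameters (broadcast element-wise).

    Returns ``(lo, hi, lo_trunc, hi_trunc)`` where the boolean arrays flag
    bounds clipped to the measurement window.
    """
    if not 0.0 < threshold < 1.0:
        raise ParameterError(f"threshold must lie in (0, 1), got {threshold}")
    if window is None:
        window = MeasurementWindow()
    L, U, a, b = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (L, U, a, b))
    )
    t_star = _mode_t(a, b)
    topt = L + t_star * (U - L)
    lo = _bisect_arrays(L, topt, threshold, L, U, a, b)
    hi = _bisect_arrays(topt, U, threshold, L, U, a, b)
    lo_trunc = lo < window.t_min
    hi_trunc = hi > window.t_max
    lo = np.where(lo_trunc, window.t_min, lo)
    hi = np.where(hi_trunc, window.t_max, hi)
    return lo, hi, lo_trunc, hi_trunc


def breadth_bounds(
    params: CurveParams,
    threshold: float = 0.5,
    window: MeasurementWindow | None = None,
) -> BreadthBounds:
    """Temperatures where performance crosses ``threshold * height``.

    The two roots (one on each side of the optimum, unique by unimodality)
    are located by bisection to 1e-6 degC; each bound is then independently
    clipped to the nearest measured temperature if it falls outside the
    measurement window, so the reported breadth never extrapolates beyond
    the experiment. ``T_breadth = upper - lower``.
    """
    lo, hi, lt, ht = breadth_bounds_arrays(
        params.lower, params.upper, params.shape_a, params.shape_b, threshold, window
    )
    return BreadthBounds(float(lo), float(hi), bool(lt), bool(ht))


def to_unconstrained(params: CurveParams) -> np.ndarray:
    """Map curve parameters to the unconstrained vector used for sampling.

    Order: ``lower`` (degC, unbounded), ``log(upper - lower)``,
    ``log(shape_a - 1)``, ``log(shape_b - 1)``, ``log(height)``. Any real
    vector maps back to a valid curve, which is what keeps simulated family
    deviations and MCMC proposals inside the parameter domain.
    """
    return np.array(
        [
            params.lower,
            np.log(params.upper - params.lower),
            np.log(params.shape_a - 1.0),
            np.log(params.shape_b - 1.0),
            np.log(params.height),
        ]
    )


def from_unconstrained(z: Sequence[float], **observation_kwargs) -> CurveParams:
    """Inverse of :func:`to_unconstrained`; extra kwargs set the observation model."""
    z = np.asarray(z, dtype=float)
    if z.shape != (5,):
        raise ParameterError(f"expected 5 unconstrained parameters, got shape {z.shape}")
    return CurveParams(
        lower=float(z[0]),
        upper=float(z[0] + np.exp(z[1])),
        shape_a=float(1.0 + np.exp(z[2])),
        shape_b=float(1.0 + np.exp(z[3])),
        height=float(np.exp(z[4])),
        **observation_kwargs,
    )
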
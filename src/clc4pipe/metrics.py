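"""Headline transport statistics.

* Boltzmann fits to per-cell Q_off-V relations and the activation midpoint
  V0.5;
* the Q_off/current ratio rho at the reference prepulse (an inverse measure of
  transport efficiency: capacitive charge per unit of transport current);
* "transport activity": normalized Q_off divided by rho, a voltage-resolved,
  expression-independent measure of transport efficacy;
* expression-normalized current amplitudes via linear fits of steady-state
  current against per-cell fluorescence (slope factors).

The fitted model is a single Boltzmann. Because the protocol measures the
charge moved between the prepulse and the holding potential, the pipeline fits

    Q(V) = q_max * (sigma(V) - sigma(v_ref)),   sigma(V) = 1/(1+exp(-(V-v_half)/k))

with ``v_ref`` the holding potential; Q is then zero at the holding potential
and slightly negative below it, exactly as measured. Passing ``v_ref=None``
fits the plain 3-parameter Boltzmann ``q_max * sigma(V)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "BoltzmannFit",
    "fit_boltzmann",
    "normalize_qv",
    "Ratio",
    "qoff_current_ratio",
    "transport_activity",
    "SlopeFit",
    "fluorescence_slope",
]


def _sigma(v, v_half, k):
    # expit is overflow-safe for the extreme k values probed by the optimizer
    return expit((v - v_half) / k)


@dataclass(frozen=True)
class BoltzmannFit:
    """Result of a Boltzmann fit to (V, Q) points."""

    q_max: float          # pC
    v_half: float         # mV
    k: float              # mV, > 0
    residual_norm: float  # sqrt(SSE)
    n_points: int
    converged: bool
    v_ref: Optional[float] = None
    message: str = ""

    def predict(self, v):
        v = np.asarray(v, float)
        out = self.q_max * _sigma(v, self.v_half, self.k)
        if self.v_ref is not None:
            out = out - self.q_max * _sigma(self.v_ref, self.v_half, self.k)
        return out


def _initial_guess(v: np.ndarray, q: np.ndarray) -> tuple[float, float, float]:
    """Data-driven start values: q_max from the top of the curve, v_half from
    the half-rise crossing, k from the 10-90% rise span (span = k*ln 81)."""
    q_top = float(np.max(q))
    q_bot = float(min(np.min(q), 0.0))
    q_max0 = max(q_top - q_bot, 1e-12)

    def crossing(level: float) -> float:
        above = q >= level
        if above.all():
            return float(v[0])
        if not above.any():
            return float(v[-1])
        i = int(np.argmax(above))
        if i == 0:
            return float(v[0])
        v0, v1, q0, q1 = v[i - 1], v[i], q[i - 1], q[i]
        if q1 == q0:
            return float(v1)
        return float(v0 + (level - q0) * (v1 - v0) / (q1 - q0))

    v_half0 = crossing(q_bot + 0.5 * q_max0)
    span = crossing(q_bot + 0.9 * q_max0) - crossing(q_bot + 0.1 * q_max0)
    k0 = span / np.log(81.0) if span > 0 else 25.0
    k0 = float(np.clip(k0, 1.0, 200.0))
    return q_max0, v_half0, k0


def fit_boltzmann(
    v: Sequence[float],
    q: Sequence[float],
    v_ref: Optional[float] = None,
) -> BoltzmannFit:
    """Least-squares Boltzmann fit to (prepulse voltage, Q_off) points.

    Parameters
    ----------
    v, q
        Prepulse potentials (mV) and integrated charges (pC).
    v_ref
        If given, fit ``q_max*(sigma(V)-sigma(v_ref))`` (holding-referenced
        model used by the pipeline); if None, fit ``q_max*sigma(V)``.

    Non-convergence returns a flagged result (``converged=False``) with
    diagnostics rather than raising.
    """
    v = np.asarray(v, float)
    q = np.asarray(q, float)
    if v.shape != q.shape or v.ndim != 1:
        raise ValueError("v and q must be 1-D arrays of equal length")
    if len(v) < 5:
        raise ValueError(
            f"need at least 5 points to fit 3 parameters, got {len(v)}"
        )
    order = np.argsort(v)
    v, q = v[order], q[order]

    q_max0, v_half0, k0 = _initial_guess(v, q)
    v_lo, v_hi = float(v[0]) - 50.0, float(v[-1]) + 50.0
    v_half0 = float(np.clip(v_half0, v_lo, v_hi))

    if v_ref is None:
        def model(vv, q_max, v_half, k):
            return q_max * _sigma(vv, v_half, k)
    else:
        def model(vv, q_max, v_half, k):
            return q_max * (_sigma(vv, v_half, k) - _sigma(v_ref, v_half, k))

    bounds = ([1e-12, v_lo, 1e-3], [np.inf, v_hi, 1e3])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model, v, q, p0=[q_max0, v_half0, k0], bounds=bounds,
                maxfev=20000,
            )
        resid = q - model(v, *popt)
        return BoltzmannFit(
            q_max=float(popt[0]), v_half=float(popt[1]), k=float(popt[2]),
            residual_norm=float(np.sqrt(resid @ resid)), n_points=len(v),
            converged=True, v_ref=v_ref,
        )
    except (RuntimeError, ValueError) as exc:
        return BoltzmannFit(
            q_max=np.nan, v_half=np.nan, k=np.nan, residual_norm=np.nan,
            n_points=len(v), converged=False, v_ref=v_ref, message=str(exc),
        )


def normalize_qv(fit: BoltzmannFit, q: Sequence[float]) -> np.ndarray:
    """Divide charges by the fitted q_max.

    Values may slightly exceed 1 under noise; they are deliberately not
    clipped so the normalization stays linear.
    """
    if not np.isfinite(fit.q_max) or fit.q_max <= 0:
        raise ValueError("fit q_max must be positive to normalize")
    return np.asarray(q, float) / fit.q_max


@dataclass(frozen=True)
class Ratio:
    """Q_off/current ratio at the reference prepulse, possibly undefined."""

    value: float        # pC/nA; NaN when undefined
    defined: bool
    v_ref: float
    reason: str = ""


def qoff_current_ratio(
    q_off_ref: float,
    i_ss_ref: float,
    v_ref: float = 135.0,
    i_threshold: float = 0.05,
) -> Ratio:
    """rho = Q_off / I_ss at the reference prepulse (pC/nA).

    Currents below ``i_threshold`` (nA) are treated as below the noise floor
    -- loss-of-function cells -- and flagged undefined rather than producing
    an unstable ratio.
    """
    if not np.isfinite(i_ss_ref) or abs(i_ss_ref) < i_threshold:
        return Ratio(np.nan, False, v_ref,
                     reason=f"|I_ss|={i_ss_ref!r} nA below threshold "
                            f"{i_threshold} nA")
    return Ratio(float(q_off_ref) / float(i_ss_ref), True, v_ref)


def transport_activity(
    norm_q: Sequence[float],
    rho: Ratio | float,
    min_norm_q: float = 0.05,
) -> np.ndarray:
    """Transport activity: normalized Q_off divided by rho, per prepulse.

    Entries where the normalized charge is below ``min_norm_q`` are returned
    as NaN (ratios there are noise-dominated). If rho is undefined the whole
    curve is NaN.
    """
    norm_q = np.asarray(norm_q, float)
    if isinstance(rho, Ratio):
        if not rho.defined:
            return np.full_like(norm_q, np.nan)
        rho_val = rho.value
    else:
        rho_val = float(rho)
    if not np.isfinite(rho_val) or rho_val <= 0:
        raise ValueError("rho must be positive and defined")
    ta = norm_q / rho_val
    ta[norm_q <= min_norm_q] = np.nan
    return ta


@dataclass(frozen=True)
class SlopeFit:
    """OLS line through (fluorescence, current) points."""

    slope: float        # nA per a.u.
    intercept: float    # nA
    stderr: float       # standard error of the slope
    r_value: float
    n: int


def fluorescence_slope(
    fluorescence: Sequence[float],
    i_ss: Sequence[float],
) -> SlopeFit:
    """Expression-normalized current: OLS slope of I_ss against fluorescence.

    A free intercept absorbs background fluorescence; forcing the line through
    the origin would bias the slope.
    """
    f = np.asarray(fluorescence, float)
    i = np.asarray(i_ss, float)
    ok = np.isfinite(f) & np.isfinite(i)
    f, i = f[ok], i[ok]
    if len(f) < 3:
        raise ValueError("need at least 3 cells for a slope factor")
    if np.ptp(f) == 0:
        raise ValueError("fluorescence values are all equal; slope undefined")
    res = stats.linregress(f, i)
    return SlopeFit(slope=float(res.slope), intercept=float(res.intercept),
                    stderr=float(res.stderr), r_value=float(res.rvalue),
                    n=len(f))
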
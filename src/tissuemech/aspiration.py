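"""Viscoelastic parameter estimation from micropipette-aspiration traces.

A spherical tissue explant aspirated into a pipette at constant pressure
``dP`` deforms in two regimes: a fast "passive" phase (the first ~20 s,
dominated by cell elasticity and cortical tension) and a slow viscous phase
in which the aspirated tongue advances at a constant rate ``v_asp``.  When
the pressure is reset to zero, surface tension drives retraction, again with
a fast recoil followed by a slow linear phase at rate ``v_ret``.  The slow
slopes give

- tissue viscosity    ``eta = R_p dP / (3 pi (v_asp + v_ret))``
- critical pressure   ``P_c = dP v_ret / (v_asp + v_ret)``
- surface tension     ``gamma = P_c / (2 (1/R_p - 1/R_0))``  (Laplace law)

where ``R_p`` is the pipette radius and ``R_0`` the explant radius of
curvature.  The deformation reached 20 s after aspiration onset (``L20``)
serves as a model-free indicator of short-term stiffness.

With lengths in micrometres, rates in um/s and pressures in Pa, the factors
of 1e-6 cancel in ``eta`` (Pa s); ``gamma`` is reported in mN/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import AspirationTrace

__all__ = [
    "PhaseWindows",
    "ViscoelasticFit",
    "segment_phases",
    "fit_slopes",
    "estimate_viscosity",
    "estimate_surface_tension",
    "stiffness_indicator",
    "fit_viscoelastic",
]


@dataclass(frozen=True)
class PhaseWindows:
    """Time intervals (s) of the four aspiration/release phases."""

    fast_aspiration: tuple[float, float]
    slow_aspiration: tuple[float, float]
    fast_release: tuple[float, float]
    slow_retraction: tuple[float, float]


@dataclass
class ViscoelasticFit:
    """Fitted rheological parameters of one explant."""

    v_asp: float  # um/s
    v_ret: float  # um/s, magnitude of retraction slope
    eta: float  # Pa s
    p_c: float  # Pa
    gamma: float  # mN/m
    l20: float  # um
    fit_windows: PhaseWindows
    r2_asp: float
    r2_ret: float
    delta_p: float = float("nan")

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if not (0.0 <= self.p_c < self.delta_p or np.isnan(self.delta_p)):
            raise ValueError("need 0 <= p_c < delta_p")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R^2 of an ordinary least-squares line fit.

    R^2 is defined as 1 when the total variance is numerically zero (a flat
    trace is a perfect line).
    """
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 1e-30:
        return float(slope), float(intercept), 1.0
    return float(slope), float(intercept), 1.0 - ss_res / ss_tot


def _trim_suffix(
    t: np.ndarray, y: np.ndarray, r2_min: float, min_window_s: float
) -> tuple[float, float]:
    """Longest suffix ``[t_i, t[-1]]`` whose line fit reaches ``r2_min``.

    Trimming removes leading samples contaminated by residual elastic creep.
    A window whose trend is not resolvable above the noise floor (total
    variance below a few times the residual variance) is accepted as is: R^2
    is meaningless there and the OLS slope is already the best estimate.
    """
    lo = 0
    n = len(t)
    while True:
        tt, yy = t[lo:], y[lo:]
        if tt[-1] - tt[0] < min_window_s or len(tt) < 5:
            raise ValueError(
                "insufficient slow phase: could not reach the requested linearity "
                f"within a window of at least {min_window_s} s"
            )
        slope, intercept, r2 = _ols_line(tt, yy)
        if r2 >= r2_min:
            return float(tt[0]), float(tt[-1])
        ss_res = float(np.sum((yy - (slope * tt + intercept)) ** 2))
        ss_tot = float(np.sum((yy - yy.mean()) ** 2))
        noise_var = ss_res / max(len(tt) - 2, 1)
        if ss_tot <= 4.0 * noise_var * len(tt):
            # no resolvable trend above the noise floor; accept the window
            return float(tt[0]), float(tt[-1])
        lo += max(1, (n - lo) // 20)


def segment_phases(
    trace: AspirationTrace,
    fast_phase_s: float = 20.0,
    settle_s: float = 10.0,
    r2_min: float = 0.95,
    min_window_s: float = 30.0,
) -> PhaseWindows:
    """Split a trace into fast/slow aspiration and release windows.

    The fast phases are the first ``fast_phase_s`` seconds after aspiration
    onset and after pressure release.  Slow windows start ``settle_s`` after
    the fast phase ends (to avoid contaminating the viscous slope with
    residual elastic creep) and are trimmed from the left until their line
    fit reaches ``r2_min``; the retraction window additionally stops where
    the tongue has fully recoiled (L = 0).

    Raises
    ------
    ValueError
        If a slow window shorter than ``min_window_s`` would result.
    """
    t, l = trace.t_s, trace.l_um
    t0, t_rel, t_end = float(t[0]), float(trace.t_release), float(t[-1])
    if t_rel - t0 < fast_phase_s + settle_s + min_window_s:
        raise ValueError("insufficient slow phase: aspiration span too short")

    asp = (t >= t0 + fast_phase_s + settle_s) & (t <= t_rel)
    a_lo, a_hi = _trim_suffix(t[asp], l[asp], r2_min, min_window_s)

    ret_start = t_rel + fast_phase_s + settle_s
    ret = (t >= ret_start) & (t <= t_end)
    # retraction slope fit stops if/when L reaches 0 (fully recoiled)
    zero = ret & (l <= 0.0)
    if np.any(zero):
        ret &= t <= t[zero][0]
    if not np.any(ret) or t[ret][-1] - t[ret][0] < min_window_s:
        raise ValueError("insufficient slow phase: retraction span too short")
    r_lo, r_hi = _trim_suffix(t[ret], l[ret], r2_min, min_window_s)

    return PhaseWindows(
        fast_aspiration=(t0, t0 + fast_phase_s),
        slow_aspiration=(a_lo, a_hi),
        fast_release=(t_rel, t_rel + fast_phase_s),
        slow_retraction=(r_lo, r_hi),
    )


def fit_slopes(trace: AspirationTrace, windows: PhaseWindows) -> tuple[float, float, float, float]:
    """OLS slopes of the two slow phases.

    Returns ``(v_asp, v_ret, r2_asp, r2_ret)`` in um/s; ``v_ret`` is the
    magnitude of the (negative) retraction slope, floored at 0.
    """
    t, l = trace.t_s, trace.l_um
    out: list[float] = []
    r2s: list[float] = []
    for lo, hi in (windows.slow_aspiration, windows.slow_retraction):
        sel = (t >= lo) & (t <= hi)
        slope, _, r2 = _ols_line(t[sel], l[sel])
        if not np.isfinite(slope):
            raise ValueError("non-finite slope in slow-phase fit")
        out.append(slope)
        r2s.append(r2)
    v_asp = out[0]
    v_ret = max(-out[1], 0.0)
    return v_asp, v_ret, r2s[0], r2s[1]


def estimate_viscosity(v_asp: float, v_ret: float, r_p: float, delta_p: float) -> float:
    """``eta = R_p dP / (3 pi (v_asp + v_ret))`` in Pa s.

    ``r_p`` in um, rates in um/s, ``delta_p`` in Pa (the micron factors
    cancel).
    """
    total = v_asp + v_ret
    if total <= 0:
        raise ValueError("v_asp + v_ret must be positive")
    return float(r_p * delta_p / (3.0 * np.pi * total))


def estimate_surface_tension(
    v_asp: float, v_ret: float, delta_p: float, r_p: float, r_0: float
) -> tuple[float, float]:
    """Critical pressure and tissue surface tension from the slow rates.

    ``P_c = dP v_ret / (v_asp + v_ret)`` (Pa) and, by Laplace inversion,
    ``gamma = P_c / (2 (1/R_p - 1/R_0))`` reported in mN/m (radii in um).
    """
    if not r_0 > r_p > 0:
        raise ValueError("need r_0 > r_p > 0")
    total = v_asp + v_ret
    if total <= 0:
        raise ValueError("v_asp + v_ret must be positive")
    p_c = delta_p * v_ret / total
    gamma = p_c / (2.0 * (1.0 / r_p - 1.0 / r_0)) * 1e-3  # Pa um -> mN/m
    return float(p_c), float(gamma)


def stiffness_indicator(
    trace: AspirationTrace, at_s: float = 20.0, subtract_baseline: bool = True
) -> float:
    """Deformation ``L`` at absolute time ``at_s`` (s after aspiration onset).

    Linear interpolation between samples; by default the deformation at the
    first sample is subtracted so the indicator measures the change over the
    initial passive phase.
    """
    t, l = trace.t_s, trace.l_um
    if t[0] > at_s or t[-1] < at_s:
        raise ValueError(f"trace does not cover t = {at_s} s")
    l20 = float(np.interp(at_s, t, l))
    if subtract_baseline:
        l20 -= float(l[0])
    return l20


def fit_viscoelastic(
    trace: AspirationTrace,
    fast_phase_s: float = 20.0,
    settle_s: float = 10.0,
    r2_min: float = 0.95,
    min_window_s: float = 30.0,
) -> ViscoelasticFit:
    """Full pipeline: segment phases, fit slopes, invert for eta, P_c, gamma."""
    windows = segment_phases(trace, fast_phase_s, settle_s, r2_min, min_window_s)
    v_asp, v_ret, r2_asp, r2_ret = fit_slopes(trace, windows)
    eta = estimate_viscosity(v_asp, v_ret, trace.r_p, trace.delta_p)
    p_c, gamma = estimate_surface_tension(v_asp, v_ret, trace.delta_p, trace.r_p, trace.r_0)
    l20 = stiffness_indicator(trace, at_s=fast_phase_s)
    return ViscoelasticFit(
        v_asp=v_asp,
        v_ret=v_ret,
        eta=eta,
        p_c=p_c,
        gamma=gamma,
        l20=l20,
        fit_windows=windows,
        r2_asp=r2_asp,
        r2_ret=r2_ret,
        delta_p=trace.delta_p,
    )
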
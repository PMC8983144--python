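"""Nonlinear least-squares fits: Boltzmann activation, single-exponential
activation kinetics, and Hill concentration-response.

All fits report a ``converged`` flag instead of raising on degenerate
inputs (flat data, optimizer failure, estimates pinned at bounds); callers
exclude non-converged cells from group summaries.  Fits use damped least
squares (Trust Region Reflective) with data-driven starting values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = ["ActivationFit", "TauFit", "HillFit",
           "fit_boltzmann", "fit_activation_tau", "fit_hill",
           "boltzmann_curve", "InsufficientDataError"]

_MAX_NFEV = 500
_XTOL = 1e-10

SLOPE_BOUNDS = (1.0, 40.0)     # mV
TAU_BOUNDS = (5.0, 2000.0)     # ms
HILL_BOUNDS = (0.3, 4.0)


class InsufficientDataError(ValueError):
    """Raised when a fit is requested on too few points."""


def boltzmann_curve(v, i_max, v_half, slope):
    """I(V) = Imax / (1 + exp((V1/2 - V) / k))."""
    return i_max / (1.0 + np.exp((v_half - np.asarray(v, float)) / slope))


@dataclass(frozen=True)
class ActivationFit:
    """Boltzmann fit of the voltage dependence of activation."""

    i_max: float
    v_half: float      # mV
    slope: float       # mV
    residual_norm: float
    converged: bool
    n_points: int


@dataclass(frozen=True)
class TauEntry:
    voltage: float
    tau: float         # ms
    a0: float          # pA
    offset_c: float    # pA
    converged: bool


@dataclass(frozen=True)
class TauFit:
    """Per-voltage single-exponential activation time constants."""

    entries: tuple[TauEntry, ...] = field(default_factory=tuple)

    def tau_at(self, voltage: float) -> float:
        for e in self.entries:
            if np.isclose(e.voltage, voltage):
                return e.tau if e.converged else float("nan")
        raise KeyError(f"no tau entry at {voltage} mV")


@dataclass(frozen=True)
class HillFit:
    ic50: float        # mM
    hill_coeff: float
    residual_norm: float
    converged: bool


# ---------------------------------------------------------------------------


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, dict):
        keys = np.array(sorted(data), float)
        vals = np.array([data[k] for k in sorted(data)], float)
        return keys, vals
    x, y = data
    return np.asarray(x, float), np.asarray(y, float)


def _crossing_voltage(v: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """Linearly interpolated voltage where y first crosses ``level``."""
    order = np.argsort(v)
    v, y = v[order], y[order]
    for i in range(len(v) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - level) * (y1 - level) <= 0 and y0 != y1:
            return float(v[i] + (level - y0) * (v[i + 1] - v[i]) / (y1 - y0))
    return None


def fit_boltzmann(normalized_tails, *, v_half_init: float | None = None,
                  slope_init: float = 8.0,
                  span_voltages: tuple[float, float] | None = None) -> ActivationFit:
    """Fit I(V) = Imax / (1 + exp((V1/2 - V)/k)) to (voltage, tail) data.

    ``normalized_tails`` is a mapping voltage -> tail value or an (x, y)
    pair of sequences.  At least 4 points are required.  The fit is
    invariant to voltage ordering and to uniform scaling of the tails
    (Imax absorbs scale).  Degenerate data (no dynamic range / no
    inflection) or estimates pinned at the sanity bounds yield
    ``converged=False`` rather than an exception.

    When the tails were min-max normalized over the protocol grid (the
    pipeline's per-cell normalization), pass ``span_voltages=(v_lo, v_hi)``:
    the fitted model then becomes the identically normalized Boltzmann,
    Imax * (B(V) - B(v_lo)) / (B(v_hi) - B(v_lo)).  This inverts the
    normalization exactly, so V1/2 and k stay unbiased even when the foot
    of the activation curve lies below the lowest protocol voltage (e.g.
    under retigabine).
    """
    v, y = _as_xy(normalized_tails)
    mask = np.isfinite(v) & np.isfinite(y)
    v, y = v[mask], y[mask]
    if len(v) < 4:
        raise InsufficientDataError("fit_boltzmann needs >= 4 finite points")

    span = float(y.max() - y.min())
    scale = float(np.abs(y).max())
    v_lo, v_hi = float(v.min()) - 20.0, float(v.max()) + 20.0
    n = len(v)

    if scale == 0 or span < 0.05 * scale:
        return ActivationFit(float(y.mean()), float("nan"), float("nan"),
                             0.0, False, n)

    if v_half_init is None:
        v_half_init = _crossing_voltage(v, y, 0.5 * (y.min() + y.max()))
        if v_half_init is None:
            v_half_init = float(np.median(v))
    x0 = np.array([max(y.max(), 1e-12), np.clip(v_half_init, v_lo, v_hi),
                   slope_init])

    if span_voltages is None:
        def resid(p):
            return boltzmann_curve(v, *p) - y
    else:
        v_span_lo, v_span_hi = span_voltages

        def resid(p):
            i_max, v_half, slope = p
            b = 1.0 / (1.0 + np.exp((v_half - v) / slope))
            b_lo = 1.0 / (1.0 + np.exp((v_half - v_span_lo) / slope))
            b_hi = 1.0 / (1.0 + np.exp((v_half - v_span_hi) / slope))
            denom = max(b_hi - b_lo, 1e-12)
            return i_max * (b - b_lo) / denom - y

    sol = least_squares(
        resid, x0,
        bounds=([0.0, v_lo, SLOPE_BOUNDS[0]], [np.inf, v_hi, SLOPE_BOUNDS[1]]),
        xtol=_XTOL, ftol=_XTOL, gtol=_XTOL, max_nfev=_MAX_NFEV)

    i_max, v_half, slope = sol.x
    at_bound = (
        np.isclose(slope, SLOPE_BOUNDS[0]) or np.isclose(slope, SLOPE_BOUNDS[1])
        or np.isclose(v_half, v_lo) or np.isclose(v_half, v_hi))
    converged = bool(sol.success) and not at_bound and slope > 0
    return ActivationFit(float(i_max), float(v_half), float(slope),
                         float(np.linalg.norm(sol.fun)), converged, n)


# ---------------------------------------------------------------------------


def _fit_single_exponential(t: np.ndarray, y: np.ndarray,
                            noise_gate: float = 0.0):
    """Least-squares fit of y = A0 exp(-t/tau) + C.  Returns (a0, tau, c,
    residual_norm, converged)."""
    span = float(y.max() - y.min())
    if span <= max(noise_gate, 1e-12):
        return float("nan"), float("nan"), float(np.mean(y)), 0.0, False

    # activation rises toward a plateau: regress log(C0 - y) on t
    c0 = float(y[-1])
    s = c0 - y
    rising = float(np.median(s[:max(3, len(s) // 10)])) > 0
    if not rising:
        c0 = float(y[-1])
        s = y - c0  # decaying segment
    good = s > 1e-9 * max(1.0, abs(c0))
    if good.sum() >= 3:
        slope_ln, intercept = np.polyfit(t[good], np.log(s[good]), 1)
        tau0 = -1.0 / slope_ln if slope_ln < 0 else 0.3 * (t[-1] - t[0])
        a0_0 = float(np.exp(intercept)) * (-1.0 if rising else 1.0)
    else:
        tau0 = 0.3 * (t[-1] - t[0])
        a0_0 = -span if rising else span
    tau0 = float(np.clip(tau0, *TAU_BOUNDS))

    def resid(p):
        a0, tau, c = p
        return a0 * np.exp(-t / tau) + c - y

    sol = least_squares(
        resid, np.array([a0_0, tau0, c0]),
        bounds=([-np.inf, TAU_BOUNDS[0], -np.inf],
                [np.inf, TAU_BOUNDS[1], np.inf]),
        xtol=_XTOL, ftol=_XTOL, gtol=_XTOL, max_nfev=_MAX_NFEV)
    a0, tau, c = sol.x
    at_bound = np.isclose(tau, TAU_BOUNDS[0]) or np.isclose(tau, TAU_BOUNDS[1])
    converged = bool(sol.success) and not at_bound
    return float(a0), float(tau), float(c), float(np.linalg.norm(sol.fun)), converged


def fit_activation_tau(cell_or_traces, window_ms: tuple[float, float] = (50.0, 1000.0),
                       voltage_range: tuple[float, float] = (-30.0, 40.0)) -> TauFit:
    """Single-exponential fits of activation kinetics per voltage.

    Accepts a ``CellRecording`` (fits each sweep whose step voltage lies
    in ``voltage_range``, over ``window_ms`` after step onset) or a
    mapping voltage -> (t_ms, current) arrays with t measured from step
    onset.  Flat or non-monotone segments yield ``converged=False``.
    """
    from .records import CellRecording

    series: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    if isinstance(cell_or_traces, CellRecording):
        cell = cell_or_traces
        p = cell.protocol
        dt = p.sampling_interval
        # step sample k (1-based, time k*dt after onset) sits at index
        # n_holding + k - 1
        k_lo = int(np.ceil(window_ms[0] / dt))
        k_hi = int(np.floor(min(window_ms[1], p.step_duration) / dt))
        t = np.arange(k_lo, k_hi + 1) * dt
        lo, hi = p.n_holding + k_lo - 1, p.n_holding + k_hi - 1
        for v in p.step_voltages:
            if voltage_range[0] <= v <= voltage_range[1]:
                series[v] = (t, cell.sweeps[v][lo:hi + 1])
    else:
        for v, (t, y) in cell_or_traces.items():
            if voltage_range[0] <= v <= voltage_range[1]:
                t = np.asarray(t, float)
                y = np.asarray(y, float)
                keep = (t >= window_ms[0]) & (t <= window_ms[1])
                series[v] = (t[keep], y[keep])

    entries = []
    for v in sorted(series):
        t, y = series[v]
        if len(t) < 4:
            raise InsufficientDataError(f"too few samples in fit window at {v} mV")
        a0, tau, c, _, converged = _fit_single_exponential(t, y)
        entries.append(TauEntry(float(v), tau, a0, c, converged))
    return TauFit(tuple(entries))


# ---------------------------------------------------------------------------


def fit_hill(block_fractions) -> HillFit:
    """Fit fractional block b(c) = 1 / (1 + (ic50/c)^h) to
    concentration-response data (concentrations in mM).

    Requires at least 3 concentrations; data that never leave the floor or
    ceiling (all block < 0.05 or > 0.95) give ``converged=False``.
    """
    c, b = _as_xy(block_fractions)
    mask = np.isfinite(c) & np.isfinite(b) & (c > 0)
    c, b = c[mask], b[mask]
    if len(c) < 3:
        raise InsufficientDataError("fit_hill needs >= 3 positive concentrations")

    if np.all(b < 0.05) or np.all(b > 0.95):
        return HillFit(float("nan"), float("nan"), 0.0, False)

    log_ic50_0 = float(np.mean(np.log(c)))  # geometric-mean start
    lo, hi = float(np.log(c.min()) - 7.0), float(np.log(c.max()) + 7.0)

    def resid(p):
        log_ic50, h = p
        return 1.0 / (1.0 + np.exp(h * (log_ic50 - np.log(c)))) - b

    sol = least_squares(
        resid, np.array([log_ic50_0, 1.0]),
        bounds=([lo, HILL_BOUNDS[0]], [hi, HILL_BOUNDS[1]]),
        xtol=_XTOL, ftol=_XTOL, gtol=_XTOL, max_nfev=_MAX_NFEV)
    log_ic50, h = sol.x
    at_bound = (np.isclose(h, HILL_BOUNDS[0]) or np.isclose(h, HILL_BOUNDS[1])
                or np.isclose(log_ic50, lo) or np.isclose(log_ic50, hi))
    converged = bool(sol.success) and not at_bound
    return HillFit(float(np.exp(log_ic50)), float(h),
                   float(np.linalg.norm(sol.fun)), converged)
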
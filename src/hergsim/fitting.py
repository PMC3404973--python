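"""Analysis equations for hERG current traces.

Three fitters cover the standard analysis chain for deactivating
potassium currents:

* two-exponential tail fits, I(t) = A0 + A1*exp(-t/tau1) + A2*exp(-t/tau2),
  with tau1 the slow and tau2 the fast component;
* Boltzmann fits of normalized activation and availability curves,
  I/Imax = Imax / (1 + exp(+-(V1/2 - V)/s));
* Nelder-Mead (simplex) estimation of Markov-chain rate constants from
  whole families of current traces.

Exponential amplitudes are solved by linear projection at fixed time
constants (variable projection), which makes the nonlinear search
low-dimensional and robust to poor starting values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lmfit import Parameters, minimize as lm_minimize
from scipy.optimize import minimize as sp_minimize

from .markov import RateConstantSet, TRANSITIONS
from .protocols import CurrentConfig, CurrentTrace, ProtocolFamily, simulate_family

__all__ = [
    "BiexpFit",
    "BoltzmannFit",
    "FitOptions",
    "fit_biexponential",
    "fit_boltzmann",
    "normalize_tail_curve",
    "fit_markov_rates",
]


@dataclass(frozen=True)
class FitOptions:
    """Knobs shared by the fitters; defaults suit 5 kHz tail records."""

    max_iter: int = 2000
    tol: float = 1e-12
    tau_bounds: tuple = (0.1, 1e5)  # ms
    initial: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")
        lo, hi = self.tau_bounds
        if not (0 < lo < hi):
            raise ValueError(f"inconsistent tau bounds {self.tau_bounds}")


@dataclass
class BiexpFit:
    """Result of a two-exponential deactivation fit (times in ms).

    tau1 is the slow component (tau1 >= tau2 enforced by ordering);
    ``degenerate`` marks fits where the two components are not
    distinguishable (effectively mono-exponential input).
    """

    a0: float
    a1: float
    a2: float
    tau1: float
    tau2: float
    residual_norm: float
    converged: bool
    degenerate: bool = False
    message: str = ""

    def model(self, t):
        t = np.asarray(t, dtype=float)
        return (
            self.a0
            + self.a1 * np.exp(-t / self.tau1)
            + self.a2 * np.exp(-t / self.tau2)
        )


@dataclass
class BoltzmannFit:
    """Result of a Boltzmann fit: half voltage v_half (mV), slope s (mV),
    plateau scale imax, and the curve direction."""

    v_half: float
    s: float
    imax: float
    direction: str
    residual_norm: float
    converged: bool
    message: str = ""

    def model(self, v):
        v = np.asarray(v, dtype=float)
        if self.direction == "activation":
            arg = (self.v_half - v) / self.s
        else:
            arg = (v - self.v_half) / self.s
        return self.imax / (1.0 + np.exp(arg))


def _amplitudes_for_taus(t, y, tau1, tau2):
    """Linear least-squares amplitudes (a0, a1, a2) at fixed taus."""
    basis = np.column_stack(
        [np.ones_like(t), np.exp(-t / tau1), np.exp(-t / tau2)]
    )
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    resid = y - basis @ coef
    return coef, float(np.sqrt(np.sum(resid**2)))


def _extract_window(trace, window):
    if isinstance(trace, CurrentTrace):
        t_all, y_all = trace.t, trace.i
    else:
        t_all, y_all = (np.asarray(a, dtype=float) for a in trace)
    if window is None:
        lo, hi = t_all[0], t_all[-1]
    else:
        lo, hi = window
    mask = (t_all >= lo - 1e-9) & (t_all <= hi + 1e-9)
    t = t_all[mask]
    y = y_all[mask]
    if len(t) < 50:
        raise ValueError(f"fit window holds {len(t)} samples; need at least 50")
    return t - t[0], y


def fit_biexponential(
    trace,
    window: tuple | None = None,
    options: FitOptions = FitOptions(),
) -> BiexpFit:
    """Fit I(t) = A0 + A1 exp(-t/tau1) + A2 exp(-t/tau2) to a tail record.

    ``trace`` is a CurrentTrace or an ``(t, i)`` pair; ``window`` is a
    ``(t_start, t_end)`` interval on the trace's time axis (time inside
    the fit is measured from the window start).  Time constants are
    initialized from a log-spaced grid with linearly projected
    amplitudes, then refined by damped least squares.  Components are
    returned with tau1 >= tau2 (slow first).  Non-convergence and
    degeneracy are flagged, never raised.
    """
    t, y = _extract_window(trace, window)
    span = t[-1]

    # 3x3 log-spaced grid over plausible time constants
    taus = np.geomspace(max(span / 300.0, options.tau_bounds[0]), span, 3)
    best = None
    for tau1 in taus:
        for tau2 in taus:
            if tau1 <= tau2:
                continue
            coef, rn = _amplitudes_for_taus(t, y, tau1, tau2)
            if best is None or rn < best[2]:
                best = (tau1, tau2, rn, coef)
    if best is None:  # single grid point survived; fall back
        best = (span, span / 10.0, np.inf, np.zeros(3))
    tau1_0, tau2_0 = best[0], best[1]

    params = Parameters()
    scale = float(np.max(np.abs(y))) or 1.0
    params.add("log_tau1", value=math.log(tau1_0))
    params.add("log_tau2", value=math.log(tau2_0))

    def residual(p):
        tau1 = math.exp(p["log_tau1"].value)
        tau2 = math.exp(p["log_tau2"].value)
        tau1 = min(max(tau1, options.tau_bounds[0]), options.tau_bounds[1])
        tau2 = min(max(tau2, options.tau_bounds[0]), options.tau_bounds[1])
        basis = np.column_stack([np.ones_like(t), np.exp(-t / tau1), np.exp(-t / tau2)])
        coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
        return y - basis @ coef

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = lm_minimize(
            residual,
            params,
            method="leastsq",
            max_nfev=options.max_iter,
            xtol=options.tol,
            ftol=options.tol,
        )
    tau1 = math.exp(out.params["log_tau1"].value)
    tau2 = math.exp(out.params["log_tau2"].value)
    (a0, a1, a2), rn = _amplitudes_for_taus(t, y, tau1, tau2)
    if tau1 < tau2:  # order: slow first
        tau1, tau2 = tau2, tau1
        a1, a2 = a2, a1
    converged = bool(out.success)

    degenerate = False
    msg = ""
    amp_scale = max(abs(a1), abs(a2), abs(a0), scale * 1e-12)
    if tau1 / tau2 < 1.05 or min(abs(a1), abs(a2)) < 1e-4 * amp_scale:
        degenerate = True
        msg = (
            "components not separable: input is effectively mono-exponential "
            f"(tau1={tau1:.4g}, tau2={tau2:.4g}, A1={a1:.4g}, A2={a2:.4g})"
        )
        warnings.warn(msg, stacklevel=2)
    if not converged:
        msg = msg or f"fit did not converge: {out.message}"
    return BiexpFit(
        a0=float(a0),
        a1=float(a1),
        a2=float(a2),
        tau1=float(tau1),
        tau2=float(tau2),
        residual_norm=rn,
        converged=converged,
        degenerate=degenerate,
        message=msg,
    )


def fit_boltzmann(
    points: Sequence,
    direction: str = "activation",
    options: FitOptions = FitOptions(),
) -> BoltzmannFit:
    """Fit a Boltzmann sigmoid to normalized (V, I/Imax) points.

    ``direction="activation"`` fits I = Imax/(1 + exp((V1/2 - V)/s))
    (increasing with depolarization); ``"availability"`` fits the
    mirrored, decreasing form I = Imax/(1 + exp((V - V1/2)/s)).  The
    slope factor s is positive in both conventions.
    """
    if direction not in ("activation", "availability"):
        raise ValueError("direction must be 'activation' or 'availability'")
    pts = np.asarray([(float(v), float(i)) for v, i in points], dtype=float)
    if len(pts) < 5:
        raise ValueError(f"need at least 5 points, got {len(pts)}")
    v = pts[:, 0]
    y = pts[:, 1]
    if v.max() - v.min() < 40.0:
        raise ValueError(
            f"points span {v.max() - v.min():.1f} mV; need at least 40 mV"
        )

    # initialize V1/2 at the half-crossing of the data
    order = np.argsort(v)
    vv, yy = v[order], y[order]
    ymax = float(np.max(np.abs(yy))) or 1.0
    yn = yy / ymax
    half_idx = int(np.argmin(np.abs(yn - 0.5)))
    v_half0 = options.initial.get("v_half", float(vv[half_idx]))
    s0 = options.initial.get("s", 6.0)

    params = Parameters()
    params.add("v_half", value=v_half0)
    params.add("log_s", value=math.log(s0))
    params.add("imax", value=ymax)

    sign = 1.0 if direction == "activation" else -1.0

    def residual(p):
        s = math.exp(p["log_s"].value)
        arg = sign * (p["v_half"].value - v) / s
        return y - p["imax"].value / (1.0 + np.exp(np.clip(arg, -500, 500)))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = lm_minimize(
            residual,
            params,
            method="leastsq",
            max_nfev=options.max_iter,
            xtol=options.tol,
            ftol=options.tol,
        )
    s_fit = math.exp(out.params["log_s"].value)
    fit = BoltzmannFit(
        v_half=float(out.params["v_half"].value),
        s=float(s_fit),
        imax=float(out.params["imax"].value),
        direction=direction,
        residual_norm=float(np.sqrt(np.sum(residual(out.params) ** 2))),
        converged=bool(out.success),
        message="" if out.success else str(out.message),
    )
    # plateau-only data: V1/2 escapes the sampled range or the slope
    # collapses/diverges; flag rather than raise
    if fit.v_half < v.min() - 20 or fit.v_half > v.max() + 20 or not (
        0.1 < fit.s < 200
    ):
        fit.converged = False
        fit.message = (
            "data do not constrain the sigmoid (all points on one plateau?)"
        )
    return fit


def normalize_tail_curve(peaks: Sequence) -> list:
    """Normalize (V, tail peak) pairs by the largest-magnitude peak."""
    pts = [(float(v), float(p)) for v, p in peaks]
    if not pts:
        raise ValueError("no tail peaks given")
    imax = max(abs(p) for _, p in pts)
    if imax == 0:
        raise ValueError("all tail peaks are zero; cannot normalize")
    return [(v, p / imax) for v, p in pts]


# ---------------------------------------------------------------------------
# simplex estimation of Markov rates


def _get_field(params: RateConstantSet, transition: str, fld: str) -> float:
    return getattr(params[transition], fld)


def _pack(params: RateConstantSet, free: Sequence) -> np.ndarray:
    """Parameter vector for the simplex: prefactors in log space (they
    are positive rates); b and v0 linear."""
    x = []
    for transition, fld in free:
        val = _get_field(params, transition, fld)
        x.append(math.log(val) if fld == "a" else val)
    return np.array(x)


def _unpack(x, params: RateConstantSet, free: Sequence) -> RateConstantSet:
    out = params
    for xi, (transition, fld) in zip(x, free):
        val = math.exp(xi) if fld == "a" else float(xi)
        out = out.replace(transition, **{fld: val})
    return out


def fit_markov_rates(
    observed: Sequence[CurrentTrace],
    family: ProtocolFamily,
    free: Sequence,
    init: RateConstantSet,
    options: FitOptions = FitOptions(),
    config: CurrentConfig = CurrentConfig(),
):
    """Estimate Markov rate constants from current traces by simplex search.

    Minimizes the summed squared residual between simulated and
    observed currents over all sweeps of ``family`` with Nelder-Mead,
    starting from ``init``.  ``free`` lists the adjustable fields as
    ``(transition, field)`` pairs, e.g. ``[("k23", "a"), ("k12", "a")]``;
    prefactors are searched in log space so they stay positive.

    Returns ``(best RateConstantSet, final objective, info dict)``;
    ``info["converged"]`` is False when the iteration cap was hit (the
    best-so-far parameters are still returned).
    """
    free = [tuple(f) for f in free]
    for transition, fld in free:
        if transition not in TRANSITIONS or fld not in ("a", "b", "v0"):
            raise ValueError(f"invalid free parameter ({transition}, {fld})")
    if len(observed) != len(family.sweep_voltages):
        raise ValueError(
            f"{len(observed)} traces for {len(family.sweep_voltages)} sweeps"
        )
    targets = [np.asarray(tr.i, dtype=float) for tr in observed]

    def objective(x):
        cand = _unpack(x, init, free)
        try:
            sim = simulate_family(family, cand, config=config, backend="expm")
        except Exception:
            return np.inf
        sse = 0.0
        for tr, tgt in zip(sim, targets):
            if len(tr.i) != len(tgt):
                raise ValueError("observed trace length does not match protocol")
            sse += float(np.sum((tr.i - tgt) ** 2))
        return sse

    if not free:
        return init, objective(np.array([])), {"converged": True, "n_eval": 1}

    x0 = _pack(init, free)
    f0 = objective(x0)
    if not np.isfinite(f0):
        raise ValueError("objective is not finite at the initial parameters")

    res = sp_minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "maxiter": options.max_iter,
            "xatol": 1e-6,
            "fatol": max(options.tol, 1e-12) * max(f0, 1e-30),
            "adaptive": True,
        },
    )
    best = _unpack(res.x, init, free)
    info = {
        "converged": bool(res.success),
        "n_eval": int(res.nfev),
        "message": str(res.message),
        "objective_init": f0,
    }
    return best, float(res.fun), info
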
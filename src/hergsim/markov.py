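"""Five-state Markov model of hERG (Kv11.1) channel gating.

The channel is described as a linear chain of conformational states

    C1 <-> C2 <-> C3 <-> O <-> I        (states 1..5)

with three closed states, one open state and one inactivated state.
Each transition rate follows a single-exponential voltage dependence

    k(V) = a * exp(b * (V + v0))        [1/ms, V in mV]

and a condition (e.g. physiological saline, or saline plus 3 uM
palmitoyl-carnitine) is fully specified by the eight rate laws
k12, k21, k23, k32, k34, k43, k45, k54.

The module provides the generator (master-equation) matrix, closed-form
steady states, occupancy integration under piecewise-constant voltage
commands, and the open-state ohmic current.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "TRANSITIONS",
    "STATE_NAMES",
    "N_STATES",
    "RateLaw",
    "RateConstantSet",
    "OccupancyState",
    "transition_rate",
    "generator",
    "steady_state",
    "integrate_occupancy",
    "markov_current",
]

#: Transition identifiers of the linear chain, in "kij" notation
#: (i -> j between adjacent states; 4 = open, 5 = inactivated).
TRANSITIONS = ("k12", "k21", "k23", "k32", "k34", "k43", "k45", "k54")

STATE_NAMES = ("C1", "C2", "C3", "O", "I")
N_STATES = 5

# (from_state, to_state) per transition id, 0-based
_EDGES = {
    "k12": (0, 1),
    "k21": (1, 0),
    "k23": (1, 2),
    "k32": (2, 1),
    "k34": (2, 3),
    "k43": (3, 2),
    "k45": (3, 4),
    "k54": (4, 3),
}

# forward/backward transition ids along the chain, in order
_FORWARD = ("k12", "k23", "k34", "k45")
_BACKWARD = ("k21", "k32", "k43", "k54")


@dataclass(frozen=True)
class RateLaw:
    """One voltage-dependent transition rate, k(V) = a*exp(b*(V + v0)).

    Parameters
    ----------
    a : float
        Prefactor in 1/ms; must be strictly positive.
    b : float
        Voltage sensitivity in 1/mV; 0 for voltage-independent rates.
    v0 : float
        Voltage offset in mV.
    """

    a: float
    b: float = 0.0
    v0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"rate prefactor must be > 0, got a={self.a}")
        if not (math.isfinite(self.a) and math.isfinite(self.b) and math.isfinite(self.v0)):
            raise ValueError("rate-law parameters must be finite")

    def rate(self, v: float) -> float:
        """Evaluate the rate at membrane potential ``v`` (mV), in 1/ms."""
        return self.a * math.exp(self.b * (v + self.v0))

    def log_rate(self, v: float) -> float:
        """log k(V); overflow-safe form used for steady-state ratios."""
        return math.log(self.a) + self.b * (v + self.v0)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "v0": self.v0}


@dataclass(frozen=True)
class RateConstantSet:
    """The eight rate laws of the five-state chain for one condition.

    ``condition`` is a free label; the shipped parameter sets use
    ``"PSS"`` (physiological saline, control) and ``"C16CAR"``
    (3 uM palmitoyl-carnitine).
    """

    condition: str
    rates: Mapping[str, RateLaw]

    def __post_init__(self) -> None:
        missing = [t for t in TRANSITIONS if t not in self.rates]
        extra = [t for t in self.rates if t not in TRANSITIONS]
        if missing or extra:
            raise ValueError(
                f"rate set must define exactly {TRANSITIONS}; "
                f"missing={missing}, unexpected={extra}"
            )

    def __getitem__(self, transition: str) -> RateLaw:
        try:
            return self.rates[transition]
        except KeyError:
            raise KeyError(
                f"unknown transition {transition!r}; valid ids: {', '.join(TRANSITIONS)}"
            ) from None

    def rate(self, transition: str, v: float) -> float:
        return self[transition].rate(v)

    def replace(self, transition: str, **fields) -> "RateConstantSet":
        """Return a copy with one rate law's fields replaced."""
        law = self[transition]
        new = RateLaw(
            a=fields.get("a", law.a),
            b=fields.get("b", law.b),
            v0=fields.get("v0", law.v0),
        )
        rates = dict(self.rates)
        rates[transition] = new
        return RateConstantSet(condition=self.condition, rates=rates)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "rates": {t: self.rates[t].to_dict() for t in TRANSITIONS},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RateConstantSet":
        if "rates" not in d:
            raise ValueError("parameter dictionary lacks a 'rates' section")
        rates = {}
        for t, law in d["rates"].items():
            if t not in TRANSITIONS:
                raise ValueError(
                    f"unknown transition {t!r}; valid ids: {', '.join(TRANSITIONS)}"
                )
            try:
                rates[t] = RateLaw(
                    a=float(law["a"]),
                    b=float(law.get("b", 0.0)),
                    v0=float(law.get("v0", 0.0)),
                )
            except KeyError as e:
                raise ValueError(f"rate law {t}: missing field {e}") from None
        return cls(condition=str(d.get("condition", "custom")), rates=rates)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RateConstantSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def _from_package_data(cls, name: str) -> "RateConstantSet":
        text = resources.files("hergsim").joinpath("data", name).read_text()
        return cls.from_dict(json.loads(text))

    @classmethod
    def pss(cls) -> "RateConstantSet":
        """Control condition (physiological saline solution)."""
        return cls._from_package_data("pss.json")

    @classmethod
    def c16car(cls) -> "RateConstantSet":
        """3 uM palmitoyl-carnitine condition."""
        return cls._from_package_data("c16car.json")


class OccupancyState:
    """Probabilities of the five channel states (C1, C2, C3, O, I).

    Wraps a length-5 probability vector; validates non-negativity and
    normalization (|sum - 1| <= 1e-8) on construction.
    """

    __slots__ = ("p",)

    def __init__(self, p: Iterable[float]):
        p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
        if p.shape != (N_STATES,):
            raise ValueError(f"occupancy must have {N_STATES} entries, got shape {p.shape}")
        if not np.all(np.isfinite(p)):
            raise ValueError("occupancy contains non-finite entries")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError(f"occupancy probabilities outside [0, 1]: {p}")
        if abs(p.sum() - 1.0) > 1e-8:
            raise ValueError(f"occupancy does not sum to 1 (sum={p.sum()!r})")
        self.p = np.clip(p, 0.0, 1.0)

    @property
    def open_prob(self) -> float:
        """Occupancy of the open state (state 4)."""
        return float(self.p[3])

    def __getitem__(self, i):
        return self.p[i]

    def __iter__(self):
        return iter(self.p)

    def __repr__(self):
        body = ", ".join(f"{n}={x:.6g}" for n, x in zip(STATE_NAMES, self.p))
        return f"OccupancyState({body})"


def transition_rate(transition: str, v: float, params: RateConstantSet) -> float:
    """Rate of one transition at membrane potential ``v`` (mV), in 1/ms."""
    if not math.isfinite(v):
        raise ValueError(f"membrane potential must be finite, got {v}")
    return params[transition].rate(v)


def generator(v: float, params: RateConstantSet) -> np.ndarray:
    """Master-equation generator matrix Q(V) with d/dt p = Q p.

    Column convention: ``Q[j, i]`` is the rate i -> j for adjacent
    states; the diagonal holds minus the total escape rate, so every
    column sums to zero and probability is conserved.  The chain is
    linear, so all entries off the tridiagonal band are exactly zero.
    """
    if not math.isfinite(v):
        raise ValueError(f"membrane potential must be finite, got {v}")
    q = np.zeros((N_STATES, N_STATES))
    for t in TRANSITIONS:
        i, j = _EDGES[t]
        k = params[t].rate(v)
        q[j, i] += k
        q[i, i] -= k
    return q


def steady_state(v: float, params: RateConstantSet) -> OccupancyState:
    """Stationary occupancy of the chain at a fixed voltage.

    A linear (birth-death) chain satisfies detailed balance, so the
    stationary distribution follows from the closed-form ratios
    p_{i+1}/p_i = k_{i,i+1}/k_{i+1,i}.  Computed in log space to stay
    finite at extreme voltages.
    """
    if not math.isfinite(v):
        raise ValueError(f"membrane potential must be finite, got {v}")
    log_w = [0.0]
    for fwd, bwd in zip(_FORWARD, _BACKWARD):
        kf = params[fwd].rate(v)
        kb = params[bwd].rate(v)
        if not (0 < kf < math.inf) or not (0 < kb < math.inf):
            raise ArithmeticError(
                f"degenerate chain at V={v} mV: {fwd}={kf!r}, {bwd}={kb!r} "
                "(rate underflowed or overflowed)"
            )
        log_w.append(log_w[-1] + params[fwd].log_rate(v) - params[bwd].log_rate(v))
    log_w = np.array(log_w)
    w = np.exp(log_w - log_w.max())
    return OccupancyState(w / w.sum())


def _expm_step(q: np.ndarray, dt: float) -> np.ndarray:
    """Single-step propagator expm(Q dt) for a modest step.

    Steps are kept at the output-sampling scale so the Pade
    scaling-and-squaring inside :func:`scipy.linalg.expm` operates at a
    moderate norm; long intervals are covered by repeated application
    of the step matrix, which is stable because the exact propagator of
    a generator matrix is column-stochastic (norm 1).
    """
    from scipy.linalg import expm as _scipy_expm

    return _scipy_expm(q * dt)


def _propagate_segment_expm(q, p0, local_times, dur, dt_out):
    """Analytic propagation within one constant-voltage segment.

    Returns occupancies at ``local_times`` (sorted, within [0, dur])
    and the end-of-segment state.  Occupancies are renormalized after
    every step to pin the conserved total probability at 1.
    """
    out = np.empty((len(local_times), N_STATES))
    p = p0.copy()
    t_cur = 0.0
    e_out = None
    for k, tt in enumerate(local_times):
        step = tt - t_cur
        if step > 0:
            if abs(step - dt_out) < 1e-9:
                if e_out is None:
                    e_out = _expm_step(q, dt_out)
                p = e_out @ p
            else:
                p = _expm_step(q, step) @ p
            p = np.maximum(p, 0.0)
            p /= p.sum()
            t_cur = tt
        out[k] = p
    # advance to the segment end, substepping long gaps at dt_out scale
    remaining = dur - t_cur
    if remaining > 1e-12:
        n_sub = int(remaining // dt_out)
        if n_sub > 0:
            if e_out is None:
                e_out = _expm_step(q, dt_out)
            for _ in range(n_sub):
                p = e_out @ p
                p = np.maximum(p, 0.0)
                p /= p.sum()
        tail = remaining - n_sub * dt_out
        if tail > 1e-12:
            p = _expm_step(q, tail) @ p
            p = np.maximum(p, 0.0)
            p /= p.sum()
    return out, p


def _segments_of(protocol) -> Sequence[tuple]:
    """Accept a VoltageProtocol-like object or raw (duration, voltage) pairs."""
    segs = getattr(protocol, "segments", protocol)
    segs = [(float(d), float(v)) for d, v in segs]
    if not segs:
        raise ValueError("protocol has no segments")
    for i, (d, v) in enumerate(segs):
        if d <= 0:
            raise ValueError(f"segment {i}: duration must be > 0, got {d}")
        if not math.isfinite(v):
            raise ValueError(f"segment {i}: voltage must be finite, got {v}")
    return segs


class SolverError(RuntimeError):
    """Occupancy integration failed; carries the segment index and time."""

    def __init__(self, message: str, segment: int, time_ms: float):
        super().__init__(f"{message} (segment {segment}, t={time_ms:.6g} ms)")
        self.segment = segment
        self.time_ms = time_ms


def integrate_occupancy(
    protocol,
    params: RateConstantSet,
    init: OccupancyState | None = None,
    dt_out: float = 0.2,
    *,
    backend: str = "bdf",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
):
    """Integrate state occupancies under a piecewise-constant voltage command.

    Parameters
    ----------
    protocol
        A :class:`~hergsim.protocols.VoltageProtocol` or a sequence of
        ``(duration_ms, voltage_mV)`` pairs.
    params
        Rate-constant set for the condition being simulated.
    init
        Initial occupancy; defaults to the steady state at the first
        segment's voltage.
    dt_out
        Output sampling interval in ms.
    backend
        ``"bdf"`` — adaptive implicit ODE solve (default tolerances
        rtol 1e-8, atol 1e-10); ``"expm"`` — within-segment analytic
        propagation through the matrix exponential (rates are constant
        at fixed voltage), sub-stepped at the output interval.

    Returns
    -------
    (t, P) : ndarray shape (n,), ndarray shape (n, 5)
        Output time grid (ms, starting at 0) and occupancies per sample.
        The final instant of the protocol is always included.
    """
    segs = _segments_of(protocol)
    if dt_out <= 0:
        raise ValueError("dt_out must be > 0")
    if init is None:
        init = steady_state(segs[0][1], params)
    elif not isinstance(init, OccupancyState):
        init = OccupancyState(init)

    total = sum(d for d, _ in segs)
    n_full = int(math.floor(total / dt_out + 1e-9))
    t_grid = np.arange(n_full + 1) * dt_out
    if t_grid[-1] > total:
        t_grid[-1] = total
    elif t_grid[-1] < total - 1e-9 * max(total, 1.0):
        t_grid = np.append(t_grid, total)

    out = np.empty((len(t_grid), N_STATES))
    p = init.p.copy()
    t0 = 0.0
    idx = 0
    for si, (dur, v) in enumerate(segs):
        t1 = t0 + dur
        # output samples falling in (t0, t1]; the very first sample (t=0)
        # is the initial condition
        if si == 0:
            out[0] = p
            idx = 1
        hi = np.searchsorted(t_grid, t1, side="right")
        times = t_grid[idx:hi]
        local = np.clip(times - t0, 0.0, dur)
        if backend == "expm":
            q = generator(v, params)
            out[idx:hi], p = _propagate_segment_expm(q, p, local, dur, dt_out)
        elif backend == "bdf":
            q = generator(v, params)
            t_eval = np.concatenate([local, [dur]]) if (len(local) == 0 or local[-1] < dur) else local
            sol = solve_ivp(
                lambda t, y: q @ y,
                (0.0, dur),
                p,
                method=method,
                t_eval=np.unique(t_eval),
                rtol=rtol,
                atol=atol,
                jac=lambda t, y: q,
            )
            if not sol.success:
                raise SolverError(f"ODE solver failed: {sol.message}", si, t0)
            lookup = {round(tt, 9): yy for tt, yy in zip(sol.t, sol.y.T)}
            for k, tt in enumerate(local):
                out[idx + k] = lookup[round(tt, 9)]
            p = sol.y[:, -1] if sol.t[-1] == dur else lookup[round(dur, 9)]
            # structure preservation: the exact flow conserves sum(p)=1, but
            # the solver's interior interpolants drift by ~rtol per segment
            # (amplified by the near-singular Newton matrices the printed
            # k32 induces); project back onto the probability simplex and
            # keep the raw drift as a solver-health diagnostic.
            raw_drift = max(
                float(np.max(np.abs(out[idx:hi].sum(axis=1) - 1.0))) if hi > idx else 0.0,
                abs(float(p.sum()) - 1.0),
            )
            if raw_drift > 1e-5:
                raise SolverError(
                    f"ODE solution lost probability mass (drift {raw_drift:.3g})", si, t0
                )
            if hi > idx:
                out[idx:hi] /= out[idx:hi].sum(axis=1, keepdims=True)
            p = p / p.sum()
        else:
            raise ValueError(f"unknown backend {backend!r}; use 'bdf' or 'expm'")
        idx = hi
        t0 = t1

    # conservation guard
    drift = np.abs(out.sum(axis=1) - 1.0)
    bad = np.argmax(drift)
    if drift[bad] > 1e-8:
        raise SolverError(
            f"probability conservation violated (|sum p - 1| = {drift[bad]:.3g})",
            -1,
            t_grid[bad],
        )
    return t_grid, out


def markov_current(
    occ,
    v: float,
    g_kr: float = 0.153,
    e_k: float = -88.0,
    ko_factor: float = math.sqrt(4.0 / 5.4),
):
    """Open-state ohmic current density, I = g_Kr * f_Ko * p_O * (V - E_K).

    ``occ`` may be an OccupancyState, a length-5 vector, an open
    probability scalar, or an array of open probabilities; ``v`` may be
    scalar or array (broadcast).  Units: g_kr in nS/pF, result in pA/pF.

    The default ``ko_factor`` is sqrt(K_o / 5.4 mM) at the 4 mM external
    potassium of the recording saline; pass 1.0 for the ventricular-cell
    convention at K_o = 5.4 mM.
    """
    if g_kr < 0:
        raise ValueError(f"g_kr must be >= 0, got {g_kr}")
    if isinstance(occ, OccupancyState):
        p_open = occ.open_prob
    else:
        arr = np.asarray(occ, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == N_STATES:
            p_open = arr[:, 3]
        elif arr.ndim == 1 and arr.shape == (N_STATES,):
            p_open = arr[3]
        else:
            p_open = arr
    return g_kr * ko_factor * p_open * (np.asarray(v) - e_k)
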
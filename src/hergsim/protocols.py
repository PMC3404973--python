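"""Voltage-clamp protocols and simulated current measurements.

Encodes the step protocols used to characterize hERG currents
(steady-state IV with deactivating tails, repeated single steps,
two-pulse availability), drives the Markov gating model through whole
sweep families, and extracts the quantities reported from such
recordings: end-pulse current, peak tail current, availability peaks.

Conventions: time in ms, voltage in mV, currents as density (pA/pF) by
default.  Cells are held at -70 mV between sweeps and the model state
is carried across sweeps through the inter-sweep holding interval, so
cumulative (rate-dependent) effects are represented rather than assumed
away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .markov import (
    OccupancyState,
    RateConstantSet,
    integrate_occupancy,
    markov_current,
    steady_state,
)

__all__ = [
    "VoltageProtocol",
    "ProtocolFamily",
    "CurrentTrace",
    "CurrentConfig",
    "build_iv_family",
    "build_single_step_family",
    "build_availability_family",
    "simulate_family",
    "simulate_sweep",
    "measure_end_pulse",
    "measure_tail_peak",
]

#: Default output sampling interval, ms (5 kHz acquisition rate).
DEFAULT_DT = 0.2

#: Holding potential between and before sweeps, mV.
HOLDING_MV = -70.0


@dataclass(frozen=True)
class VoltageProtocol:
    """Piecewise-constant voltage command for one sweep.

    ``segments`` is an ordered tuple of ``(duration_ms, voltage_mV)``.
    """

    segments: tuple
    dt: float = DEFAULT_DT
    label: str = ""

    def __post_init__(self):
        segs = tuple((float(d), float(v)) for d, v in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("protocol must have at least one segment")
        for i, (d, v) in enumerate(segs):
            if d <= 0:
                raise ValueError(f"segment {i}: duration must be > 0, got {d}")
            if not math.isfinite(v):
                raise ValueError(f"segment {i}: non-finite voltage")
        if self.dt <= 0:
            raise ValueError(f"sampling interval must be > 0, got {self.dt}")

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)

    @property
    def boundaries(self) -> tuple:
        """Segment start times, plus the final end time."""
        t = [0.0]
        for d, _ in self.segments:
            t.append(t[-1] + d)
        return tuple(t)

    def voltage_at(self, t) -> np.ndarray:
        """Commanded voltage at time(s) t; boundary instants take the
        voltage of the segment that begins there (the command has
        already switched)."""
        t = np.asarray(t, dtype=float)
        b = np.asarray(self.boundaries)
        idx = np.clip(np.searchsorted(b, t, side="right") - 1, 0, len(self.segments) - 1)
        volts = np.array([v for _, v in self.segments])
        return volts[idx]

    def with_voltage(self, index: int, voltage: float) -> "VoltageProtocol":
        segs = list(self.segments)
        segs[index] = (segs[index][0], float(voltage))
        return replace(self, segments=tuple(segs))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "dt_ms": self.dt,
            "segments": [{"duration_ms": d, "voltage_mV": v} for d, v in self.segments],
        }

    @classmethod
    def from_dict(cls, d) -> "VoltageProtocol":
        return cls(
            segments=tuple((s["duration_ms"], s["voltage_mV"]) for s in d["segments"]),
            dt=float(d.get("dt_ms", DEFAULT_DT)),
            label=str(d.get("label", "")),
        )


@dataclass(frozen=True)
class ProtocolFamily:
    """A sweep family: one protocol template with one varying segment."""

    template: VoltageProtocol
    vary_index: int
    sweep_voltages: tuple
    intersweep_ms: float = 18000.0
    label: str = ""

    def __post_init__(self):
        object.__setattr__(
            self, "sweep_voltages", tuple(float(v) for v in self.sweep_voltages)
        )
        if not (0 <= self.vary_index < len(self.template.segments)):
            raise ValueError(
                f"vary_index {self.vary_index} outside the template's "
                f"{len(self.template.segments)} segments"
            )
        if not self.sweep_voltages:
            raise ValueError("sweep_voltages must be non-empty")
        if self.intersweep_ms <= 0:
            raise ValueError("intersweep_ms must be > 0")

    def __len__(self):
        return len(self.sweep_voltages)

    def sweep(self, voltage: float) -> VoltageProtocol:
        return self.template.with_voltage(self.vary_index, voltage)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "template": self.template.to_dict(),
            "vary_index": self.vary_index,
            "sweep_voltages": list(self.sweep_voltages),
            "intersweep_ms": self.intersweep_ms,
        }

    @classmethod
    def from_dict(cls, d) -> "ProtocolFamily":
        return cls(
            template=VoltageProtocol.from_dict(d["template"]),
            vary_index=int(d["vary_index"]),
            sweep_voltages=tuple(d["sweep_voltages"]),
            intersweep_ms=float(d.get("intersweep_ms", 18000.0)),
            label=str(d.get("label", "")),
        )


@dataclass
class CurrentTrace:
    """Uniformly sampled current time series with segment annotations.

    ``segments`` holds ``(start_ms, end_ms, voltage_mV)`` per command
    segment; ``meta`` carries free-form provenance (condition, sweep
    voltage, seed, ...).
    """

    t: np.ndarray
    i: np.ndarray
    unit: str = "pA/pF"
    segments: tuple = ()
    label: str = ""
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.i.shape:
            raise ValueError("time and current must be 1-D arrays of equal length")
        if len(self.t) < 2:
            raise ValueError("trace needs at least two samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-6 * max(dt[0], 1.0):
            raise ValueError("time grid must be uniform")
        if not np.all(np.isfinite(self.i)):
            raise ValueError("current contains non-finite samples")
        for s in self.segments:
            if not (self.t[0] - 1e-9 <= s[0] <= s[1] <= self.t[-1] + 1e-9):
                raise ValueError(f"segment annotation {s} outside trace span")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def segment_slice(self, index: int, skip: int = 0) -> slice:
        """Index slice of samples in segment ``index``.

        The sample exactly at the segment start carries the voltage-step
        discontinuity; ``skip`` drops that many leading samples.
        """
        start, end, _ = self.segments[index]
        lo = int(np.searchsorted(self.t, start - 1e-9))
        hi = int(np.searchsorted(self.t, end + 1e-9))
        return slice(lo + skip, hi)


@dataclass(frozen=True)
class CurrentConfig:
    """Open-channel current parameters for clamp simulations.

    g_kr in nS/pF; e_k is the K+ reversal potential in mV (default:
    Nernst potential for 4 mM external / 130 mM internal K+ at 23 C);
    ko_factor the sqrt(K_o/5.4 mM) conductance scaling; optional
    capacitance converts density to absolute pA.
    """

    g_kr: float = 0.153
    e_k: float = -88.8
    ko_factor: float = math.sqrt(4.0 / 5.4)
    capacitance_pF: float | None = None

    @property
    def unit(self) -> str:
        return "pA" if self.capacitance_pF else "pA/pF"


# ---------------------------------------------------------------------------
# protocol builders

def build_iv_family(dt: float = DEFAULT_DT) -> ProtocolFamily:
    """Steady-state IV family with deactivating tails.

    From a -70 mV hold, 5 s steps to -80..+50 mV in 10 mV increments,
    then a 5 s tail at -55 mV where deactivation is recorded.
    """
    template = VoltageProtocol(
        segments=(
            (200.0, HOLDING_MV),
            (5000.0, -10.0),
            (5000.0, -55.0),
        ),
        dt=dt,
        label="iv",
    )
    return ProtocolFamily(
        template=template,
        vary_index=1,
        sweep_voltages=tuple(float(v) for v in range(-80, 51, 10)),
        intersweep_ms=18000.0,
        label="iv",
    )


def build_single_step_family(dt: float = DEFAULT_DT) -> ProtocolFamily:
    """Repeated 5 s test pulses to -10 mV applied every 18 s from -70 mV,
    with the -55 mV tail segment used for deactivation analysis."""
    template = VoltageProtocol(
        segments=(
            (200.0, HOLDING_MV),
            (5000.0, -10.0),
            (5000.0, -55.0),
        ),
        dt=dt,
        label="single_step",
    )
    return ProtocolFamily(
        template=template,
        vary_index=1,
        sweep_voltages=(-10.0,),
        intersweep_ms=18000.0,
        label="single_step",
    )


def build_availability_family(dt: float = DEFAULT_DT) -> ProtocolFamily:
    """Two-pulse availability protocol.

    1 s conditioning pulse to +40 mV, a 25 ms interpulse to -120..+10 mV
    in 10 mV increments, then a +40 mV test pulse whose peak current
    reports channel availability.
    """
    template = VoltageProtocol(
        segments=(
            (200.0, HOLDING_MV),
            (1000.0, 40.0),
            (25.0, -120.0),
            (500.0, 40.0),
        ),
        dt=dt,
        label="availability",
    )
    return ProtocolFamily(
        template=template,
        vary_index=2,
        sweep_voltages=tuple(float(v) for v in range(-120, 11, 10)),
        intersweep_ms=18000.0,
        label="availability",
    )


# ---------------------------------------------------------------------------
# simulation

def simulate_sweep(
    protocol: VoltageProtocol,
    params: RateConstantSet,
    config: CurrentConfig = CurrentConfig(),
    init: OccupancyState | None = None,
    backend: str = "expm",
):
    """Simulate one sweep; returns (CurrentTrace, final OccupancyState)."""
    n_samples = protocol.total_duration / protocol.dt
    if abs(n_samples - round(n_samples)) > 1e-6:
        raise ValueError(
            f"sampling interval {protocol.dt} ms does not divide the "
            f"protocol duration {protocol.total_duration} ms; the trace "
            "grid would be non-uniform"
        )
    t, occ = integrate_occupancy(
        protocol, params, init=init, dt_out=protocol.dt, backend=backend
    )
    v = protocol.voltage_at(t)
    cur = markov_current(
        occ, v, g_kr=config.g_kr, e_k=config.e_k, ko_factor=config.ko_factor
    )
    if config.capacitance_pF:
        cur = cur * config.capacitance_pF
    bounds = protocol.boundaries
    segs = tuple(
        (bounds[k], bounds[k + 1], protocol.segments[k][1])
        for k in range(len(protocol.segments))
    )
    trace = CurrentTrace(
        t=t,
        i=np.asarray(cur, dtype=float),
        unit=config.unit,
        segments=segs,
        label=protocol.label,
        condition=params.condition,
    )
    return trace, OccupancyState(occ[-1])


def simulate_family(
    family: ProtocolFamily,
    params: RateConstantSet,
    config: CurrentConfig = CurrentConfig(),
    backend: str = "expm",
    carry_state: bool = True,
):
    """Simulate every sweep of a family through the Markov model.

    The initial state is the steady state at the holding potential; in
    between sweeps the model relaxes at the holding potential for the
    family's inter-sweep interval (``carry_state=False`` resets to the
    holding steady state instead).
    """
    hold_v = family.template.segments[0][1]
    state = steady_state(hold_v, params)
    traces = []
    for v in family.sweep_voltages:
        protocol = family.sweep(v)
        try:
            trace, state = simulate_sweep(
                protocol, params, config=config, init=state, backend=backend
            )
        except Exception as e:
            raise RuntimeError(
                f"simulation failed for sweep at {v} mV of family "
                f"{family.label!r}: {e}"
            ) from e
        trace.meta["sweep_mV"] = v
        trace.label = f"{family.label}@{v:+g}mV" if family.label else f"{v:+g}mV"
        traces.append(trace)
        if carry_state:
            # relax at holding potential until the next sweep
            _, occ = integrate_occupancy(
                [(family.intersweep_ms, hold_v)],
                params,
                init=state,
                dt_out=family.intersweep_ms / 10,
                backend=backend,
            )
            state = OccupancyState(occ[-1])
        else:
            state = steady_state(hold_v, params)
    return traces


# ---------------------------------------------------------------------------
# measurements

def measure_end_pulse(trace: CurrentTrace, segment_index: int, window_ms: float = 50.0):
    """Mean current over the final ``window_ms`` of a command segment."""
    start, end, _ = trace.segments[segment_index]
    if window_ms <= 0:
        raise ValueError("window must be > 0")
    if window_ms > end - start + 1e-9:
        raise ValueError(
            f"window {window_ms} ms longer than segment {segment_index} "
            f"({end - start} ms)"
        )
    lo = int(np.searchsorted(trace.t, end - window_ms - 1e-9))
    hi = int(np.searchsorted(trace.t, end + 1e-9))
    if hi <= lo:
        raise ValueError("no samples in end-pulse window")
    return float(np.mean(trace.i[lo:hi]))


def measure_tail_peak(trace: CurrentTrace, segment_index: int, skip: int = 1):
    """Peak (largest-magnitude) current of a tail segment and its time.

    The first ``skip`` samples after the voltage step are excluded to
    avoid the instantaneous-jump artifact at the step itself.  Sign is
    preserved: outward tails report positive peaks.
    """
    sl = trace.segment_slice(segment_index, skip=skip)
    seg_t = trace.t[sl]
    seg_i = trace.i[sl]
    if len(seg_i) == 0:
        raise ValueError(f"segment {segment_index} has no samples after skip={skip}")
    k = int(np.argmax(np.abs(seg_i)))
    return float(seg_i[k]), float(seg_t[k])
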
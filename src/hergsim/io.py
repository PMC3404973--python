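"""Text formats, run configuration and the end-to-end pipeline.

Traces travel as delimited text with ``#``-prefixed header lines
(label, condition, unit, segment annotations, free-form JSON metadata);
parameters and reports are JSON.  Every artifact written by
:func:`pipeline_run` embeds the seed and a hash of the configuration
for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ap_model import PacingSpec, simulate_paced
from .fitting import fit_biexponential, fit_boltzmann, normalize_tail_curve
from .markov import RateConstantSet
from .protocols import (
    CurrentConfig,
    CurrentTrace,
    build_availability_family,
    build_iv_family,
    measure_end_pulse,
    measure_tail_peak,
    simulate_family,
)

__all__ = [
    "RunConfig",
    "read_trace",
    "write_trace",
    "load_rate_params",
    "pipeline_run",
]

log = logging.getLogger("hergsim")


class TraceParseError(ValueError):
    """Malformed trace file; message carries the offending line number."""


def write_trace(path, trace: CurrentTrace) -> None:
    """Write a CurrentTrace as commented delimited text (lossless)."""
    path = Path(path)
    lines = [
        "# hergsim-trace v1",
        f"# label: {trace.label}",
        f"# condition: {trace.condition}",
        f"# unit: {trace.unit}",
        "# segments: " + ";".join(f"{a:.17g}:{b:.17g}:{v:.17g}" for a, b, v in trace.segments),
        "# meta: " + json.dumps(trace.meta, sort_keys=True),
        "time_ms,current",
    ]
    body = "\n".join(f"{t:.17g},{i:.17g}" for t, i in zip(trace.t, trace.i))
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def read_trace(path) -> CurrentTrace:
    """Parse a trace file written by :func:`write_trace`.

    Raises :class:`TraceParseError` with line numbers on malformed
    headers or a non-uniform time grid.
    """
    path = Path(path)
    header: dict = {}
    t_vals: list = []
    i_vals: list = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    header[key.strip()] = val.strip()
                continue
            if line.lower().startswith("time"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise TraceParseError(
                    f"{path}:{lineno}: expected 'time,current', got {line!r}"
                )
            try:
                t_vals.append(float(parts[0]))
                i_vals.append(float(parts[1]))
            except ValueError:
                raise TraceParseError(
                    f"{path}:{lineno}: non-numeric sample {line!r}"
                ) from None
    if len(t_vals) < 2:
        raise TraceParseError(f"{path}: fewer than two samples")
    t = np.asarray(t_vals)
    dt = np.diff(t)
    if np.any(dt <= 0) or np.max(np.abs(dt - dt[0])) > 1e-6 * max(dt[0], 1.0):
        bad = int(np.argmax(np.abs(dt - dt[0]))) + 2
        raise TraceParseError(
            f"{path}: non-uniform or non-increasing time grid near data line {bad}"
        )
    segments = ()
    if header.get("segments"):
        try:
            segments = tuple(
                tuple(float(x) for x in chunk.split(":"))
                for chunk in header["segments"].split(";")
            )
        except ValueError:
            raise TraceParseError(f"{path}: malformed segments header") from None
    meta = {}
    if header.get("meta"):
        try:
            meta = json.loads(header["meta"])
        except json.JSONDecodeError:
            raise TraceParseError(f"{path}: malformed meta header (not JSON)") from None
    return CurrentTrace(
        t=t,
        i=np.asarray(i_vals),
        unit=header.get("unit", "pA/pF"),
        segments=segments,
        label=header.get("label", ""),
        condition=header.get("condition", ""),
        meta=meta,
    )


def load_rate_params(path) -> RateConstantSet:
    """Load a rate-constant JSON file at full printed precision."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parameter file not found: {path}")
    return RateConstantSet.from_json(path)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    ``param_files`` maps condition labels to JSON parameter files; when
    empty the two shipped sets (control saline and 3 uM
    palmitoyl-carnitine) are used.
    """

    param_files: dict = field(default_factory=dict)
    protocols: tuple = ("iv", "availability", "ap")
    out_dir: str | None = None
    seed: int = 0
    dt_ms: float = 0.2
    n_beats: int = 50
    cycle_length_ms: float = 1000.0
    rtol: float = 1e-6
    atol: float = 1e-8
    verbosity: str = "INFO"

    def load_conditions(self):
        if self.param_files:
            out = []
            for label, p in self.param_files.items():
                ps = load_rate_params(p)
                out.append(ps)
            return out
        return [RateConstantSet.pss(), RateConstantSet.c16car()]

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _analyze_condition(params: RateConstantSet, cfg: RunConfig, report: dict):
    entry: dict = {"condition": params.condition}
    config = CurrentConfig()

    t0 = time.time()
    iv = build_iv_family(dt=cfg.dt_ms)
    traces = simulate_family(iv, params)
    entry["iv_end_pulse"] = {
        f"{v:+g}": measure_end_pulse(tr, 1) for v, tr in zip(iv.sweep_voltages, traces)
    }
    peaks = [
        (v, measure_tail_peak(tr, 2)[0]) for v, tr in zip(iv.sweep_voltages, traces)
    ]
    act = fit_boltzmann(normalize_tail_curve(peaks), direction="activation")
    entry["activation"] = {
        "v_half_mV": act.v_half, "s_mV": act.s, "converged": act.converged,
    }
    # deactivation kinetics from the -10 mV sweep's tail
    sweep_idx = iv.sweep_voltages.index(-10.0)
    tr = traces[sweep_idx]
    start, end, _ = tr.segments[2]
    biexp = fit_biexponential(tr, window=(start + 2 * tr.dt, end))
    entry["deactivation"] = {
        "tau1_ms": biexp.tau1, "tau2_ms": biexp.tau2,
        "converged": biexp.converged, "degenerate": biexp.degenerate,
    }
    log.info("%s: clamp IV + fits in %.1f s", params.condition, time.time() - t0)

    if "availability" in cfg.protocols:
        t0 = time.time()
        avail = build_availability_family(dt=cfg.dt_ms)
        atraces = simulate_family(avail, params)
        apeaks = [
            (v, measure_tail_peak(tr, 3)[0])
            for v, tr in zip(avail.sweep_voltages, atraces)
        ]
        afit = fit_boltzmann(normalize_tail_curve(apeaks), direction="availability")
        entry["availability"] = {
            "v_half_mV": afit.v_half, "s_mV": afit.s, "converged": afit.converged,
        }
        log.info("%s: availability in %.1f s", params.condition, time.time() - t0)

    if "ap" in cfg.protocols:
        t0 = time.time()
        rec = simulate_paced(
            params,
            PacingSpec(
                cycle_length_ms=cfg.cycle_length_ms, n_beats=cfg.n_beats, record_beats=2
            ),
            rtol=cfg.rtol,
            atol=cfg.atol,
        )
        entry["ap"] = {
            "apd90_ms": rec.apd90_per_beat[-1],
            "apd50_ms": None,
            "diastolic_mV": float(rec.v.min()),
            "peak_mV": float(rec.v.max()),
            "beats": cfg.n_beats,
        }
        from .ap_model import ap_metrics

        last = rec.beat_starts[-1]
        mask = rec.t >= last
        m = ap_metrics((rec.t[mask], rec.v[mask]))
        entry["ap"]["apd90_ms"] = m.apd90
        entry["ap"]["apd50_ms"] = m.apd50
        log.info("%s: AP (%d beats) in %.1f s", params.condition, cfg.n_beats, time.time() - t0)
    report["conditions"][params.condition] = entry
    return entry


def pipeline_run(config: RunConfig) -> dict:
    """Simulate both conditions end to end and report the comparison.

    Stages: clamp IV family -> end-pulse table, activation Boltzmann,
    tail biexponential; availability family -> availability Boltzmann;
    paced cell -> APD90/APD50.  A stage failure marks the stage failed
    in the report and skips dependent stages for that condition.
    """
    logging.basicConfig(level=config.verbosity)
    report: dict = {
        "tool": "hergsim",
        "seed": config.seed,
        "config_hash": config.digest(),
        "conditions": {},
        "deltas": {},
        "failed": {},
    }
    entries = []
    try:
        conditions = config.load_conditions()
    except (OSError, ValueError) as e:
        report["failed"]["load_params"] = str(e)
        return report
    for params in conditions:
        try:
            entries.append(_analyze_condition(params, config, report))
        except Exception as e:  # stage failure: record, continue
            log.error("condition %s failed: %s", params.condition, e)
            report["failed"][params.condition] = str(e)

    if len(entries) == 2:
        a, b = entries
        d: dict = {"reference": a["condition"], "treated": b["condition"]}
        d["delta_tau1_ms"] = b["deactivation"]["tau1_ms"] - a["deactivation"]["tau1_ms"]
        d["delta_tau2_ms"] = b["deactivation"]["tau2_ms"] - a["deactivation"]["tau2_ms"]
        d["delta_v_half_act_mV"] = (
            a["activation"]["v_half_mV"] - b["activation"]["v_half_mV"]
        )
        if "ap" in a and "ap" in b:
            d["delta_apd90_ms"] = b["ap"]["apd90_ms"] - a["ap"]["apd90_ms"]
        report["deltas"] = d

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
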
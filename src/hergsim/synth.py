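"""Synthetic electrophysiology data with the statistical structure the
analysis assumes.

Three generators cover the pipeline's inputs: noisy biexponential tail
currents, normalized Boltzmann activation/availability datasets, and
multi-cell cohorts whose per-cell parameters are drawn from truncated
normal population distributions (summarized as mean +- SEM, the way
patch-clamp cohorts are reported).

All noise is additive i.i.d. Gaussian and every stochastic output takes
a mandatory seed (numpy Generator, PCG64), so results are reproducible
across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import fit_biexponential, fit_boltzmann
from .protocols import CurrentTrace

__all__ = [
    "CohortSpec",
    "generate_tail_trace",
    "generate_boltzmann_dataset",
    "generate_cohort",
]

#: Default deactivation parameters: control-condition tail time
#: constants (ms) at -55 mV after a 5 s step to -10 mV.
DEFAULT_TAU1 = 1663.0
DEFAULT_TAU2 = 314.4

#: Default trace noise, as a fraction of the initial tail amplitude.
DEFAULT_NOISE_FRAC = 0.02


@dataclass(frozen=True)
class CohortSpec:
    """Population description for a simulated cohort of cells.

    ``means``/``sds`` map parameter names to population mean and SD:
    tails use (tau1, tau2, a0, a1, a2); Boltzmann datasets use
    (v_half, s).  ``noise_sd`` is the per-trace additive noise as a
    fraction of the initial tail amplitude (tails) or on the normalized
    current axis (Boltzmann).  A seed is mandatory.
    """

    n: int
    means: dict
    sds: dict
    noise_sd: float = DEFAULT_NOISE_FRAC
    capacitance_pF: tuple = (10.0, 20.0)
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("cohort needs n >= 1 cells")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        for k, v in self.sds.items():
            if v < 0:
                raise ValueError(f"population SD for {k} must be >= 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic generation")


def generate_tail_trace(
    tau1: float = DEFAULT_TAU1,
    tau2: float = DEFAULT_TAU2,
    a0: float = 0.0,
    a1: float = 100.0,
    a2: float = 100.0,
    duration_ms: float = 8000.0,
    sampling_khz: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    unit: str = "pA",
) -> CurrentTrace:
    """Simulated deactivating tail: A0 + A1 e^(-t/tau1) + A2 e^(-t/tau2)
    plus additive Gaussian noise of the given SD (current units).

    ``duration_ms`` of at least ~3*tau1 is recommended so the slow
    component is resolved.
    """
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("time constants must be > 0")
    if noise_sd < 0:
        raise ValueError(f"noise SD must be >= 0, got {noise_sd}")
    if duration_ms <= 0 or sampling_khz <= 0:
        raise ValueError("duration and sampling rate must be > 0")
    dt = 1.0 / sampling_khz
    n = int(round(duration_ms / dt)) + 1
    t = np.arange(n) * dt
    y = a0 + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=n)
    return CurrentTrace(
        t=t,
        i=y,
        unit=unit,
        segments=((0.0, t[-1], -55.0),),
        label="synthetic_tail",
        meta={
            "tau1": tau1, "tau2": tau2, "a0": a0, "a1": a1, "a2": a2,
            "noise_sd": noise_sd, "seed": seed,
        },
    )


def generate_boltzmann_dataset(
    v_grid,
    v_half: float,
    s: float = 6.0,
    direction: str = "activation",
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Normalized current vs voltage from an exact Boltzmann sigmoid,
    plus Gaussian noise on the normalized axis.

    Returns a list of ``(V_mV, I/Imax)`` pairs.
    """
    v_grid = np.asarray(list(v_grid), dtype=float)
    if v_grid.size == 0:
        raise ValueError("voltage grid is empty")
    if s <= 0:
        raise ValueError("slope factor must be > 0")
    if noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    if direction not in ("activation", "availability"):
        raise ValueError("direction must be 'activation' or 'availability'")
    sign = 1.0 if direction == "activation" else -1.0
    y = 1.0 / (1.0 + np.exp(sign * (v_half - v_grid) / s))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=len(v_grid))
    return list(zip(v_grid.tolist(), y.tolist()))


def generate_cohort(spec: CohortSpec, kind: str = "tails"):
    """Per-cell synthetic datasets plus a mean +- SEM summary table.

    ``kind="tails"`` draws per-cell (tau1, tau2, amplitudes) from
    truncated normals (positivity enforced by redrawing), generates a
    noisy tail per cell, and fits each with the two-exponential fitter;
    ``kind="boltzmann"`` does the same for (v_half, s) with the
    Boltzmann fitter on a 14-point voltage grid.

    Returns ``(cells, summary)``: a list of per-cell dicts (truth,
    dataset, fit) and a pandas DataFrame of fitted values summarized as
    mean, SEM and n.
    """
    if kind not in ("tails", "boltzmann"):
        raise ValueError("kind must be 'tails' or 'boltzmann'")
    want_sem = spec.n >= 2
    if not want_sem:
        raise ValueError("SEM summary requires n >= 2 cells")
    rng = np.random.default_rng(spec.seed)

    def draw(name, default, positive=False):
        mu = spec.means.get(name, default)
        sd = spec.sds.get(name, 0.0)
        if sd == 0:
            return mu
        val = rng.normal(mu, sd)
        while positive and val <= 0:  # truncate to positive support
            val = rng.normal(mu, sd)
        return float(val)

    cells = []
    if kind == "tails":
        fitted_names = ("tau1", "tau2", "a0", "a1", "a2")
        for c in range(spec.n):
            truth = {
                "tau1": draw("tau1", DEFAULT_TAU1, positive=True),
                "tau2": draw("tau2", DEFAULT_TAU2, positive=True),
                "a0": draw("a0", 0.0),
                "a1": draw("a1", 100.0),
                "a2": draw("a2", 100.0),
            }
            amp0 = truth["a0"] + truth["a1"] + truth["a2"]
            trace = generate_tail_trace(
                tau1=truth["tau1"],
                tau2=truth["tau2"],
                a0=truth["a0"],
                a1=truth["a1"],
                a2=truth["a2"],
                noise_sd=spec.noise_sd * abs(amp0),
                seed=int(rng.integers(2**31)),
            )
            fit = fit_biexponential(trace)
            cells.append(
                {
                    "cell": c,
                    "truth": truth,
                    "data": trace,
                    "fit": fit,
                    "fitted": {
                        "tau1": fit.tau1, "tau2": fit.tau2,
                        "a0": fit.a0, "a1": fit.a1, "a2": fit.a2,
                    },
                    "capacitance_pF": float(rng.uniform(*spec.capacitance_pF)),
                }
            )
    else:
        fitted_names = ("v_half", "s")
        v_grid = np.arange(-80.0, 51.0, 10.0)
        direction = spec.means.get("direction", "activation")
        for c in range(spec.n):
            truth = {
                "v_half": draw("v_half", -20.0),
                "s": draw("s", 6.0, positive=True),
            }
            pts = generate_boltzmann_dataset(
                v_grid,
                v_half=truth["v_half"],
                s=truth["s"],
                direction=direction,
                noise_sd=spec.noise_sd,
                seed=int(rng.integers(2**31)),
            )
            fit = fit_boltzmann(pts, direction=direction)
            cells.append(
                {
                    "cell": c,
                    "truth": truth,
                    "data": pts,
                    "fit": fit,
                    "fitted": {"v_half": fit.v_half, "s": fit.s},
                    "capacitance_pF": float(rng.uniform(*spec.capacitance_pF)),
                }
            )

    rows = []
    for name in fitted_names:
        vals = np.array([c["fitted"][name] for c in cells])
        rows.append(
            {
                "parameter": name,
                "mean": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / math.sqrt(spec.n)),
                "n": spec.n,
            }
        )
    summary = pd.DataFrame(rows).set_index("parameter")
    return cells, summary
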
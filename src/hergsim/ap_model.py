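"""Human endocardial ventricular myocyte model with Markov-chain IKr.

The cell is the Ten Tusscher-Panfilov 2006 (TTP06) human ventricular
model in its endocardial parameterization, with one substitution: the
Hodgkin-Huxley xr1*xr2 gating of the rapid delayed rectifier is
replaced by the five-state Markov chain of :mod:`hergsim.markov`,

    I_Kr = g_Kr * sqrt(K_o / 5.4) * p_O * (V - E_K),

so the acylcarnitine-dependent gating kinetics propagate directly into
the action potential.  All other currents (INa, ICaL, Ito, IKs, IK1,
INaCa, INaK, IpCa, IpK, background) and the calcium subsystem follow
the published TTP06 equations; units are mV, ms, mM, pA/pF.

The public surface is ``cell_rhs`` (the full right-hand side),
``simulate_paced`` (paced beats from a documented initial state) and
``apd`` (action-potential duration at a repolarization fraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .markov import N_STATES, RateConstantSet, steady_state

__all__ = [
    "CellState",
    "PacingSpec",
    "APMetrics",
    "APRecording",
    "STATE_NAMES",
    "initial_state",
    "cell_rhs",
    "simulate_paced",
    "apd",
    "ap_metrics",
]

# ---------------------------------------------------------------------------
# constants (TTP06, endocardial cell type)

R_GAS = 8314.472      # mJ/(mol K)
T_KELVIN = 310.0
FARADAY = 96485.3415  # C/mol
RTONF = R_GAS * T_KELVIN / FARADAY

KO = 5.4      # mM
CAO = 2.0
NAO = 140.0

VC = 0.016404     # cytoplasmic volume, um^3 scaled
VSR = 0.001094
VSS = 0.00005468
CAPACITANCE = 0.185

BUFC, KBUFC = 0.2, 0.001
BUFSR, KBUFSR = 10.0, 0.3
BUFSS, KBUFSS = 0.4, 0.00025

VMAXUP, KUP = 0.006375, 0.00025
VREL, VLEAK, VXFER = 0.102, 0.00036, 0.0038
K1_, K2_, K3, K4 = 0.15, 0.045, 0.060, 0.005
EC, MAXSR, MINSR = 1.5, 2.5, 1.0

PKNA = 0.03
GNA = 14.838
GBNA = 0.00029
KMK, KMNA, KNAK = 1.0, 40.0, 2.724
GCAL = 0.00003980
GBCA = 0.000592
KNACA, KMNAI, KMCA, KSAT, NGAMMA = 1000.0, 87.5, 1.38, 0.1, 0.35
GPCA, KPCA = 0.1238, 0.0005
GPK = 0.0146
GK1 = 5.405

# endocardial cell type
GKS = 0.392
GTO = 0.073
#: TTP06 endocardial IKr conductance, nS/pF; the Markov open state uses
#: the same value by default.
GKR_DEFAULT = 0.153

STATE_NAMES = (
    "V", "Nai", "Ki", "Cai", "CaSR", "CaSS",
    "m", "h", "j", "xs", "r", "s", "d", "f", "f2", "fcass", "rr",
    "C1", "C2", "C3", "O", "I",
)
N_CELL = len(STATE_NAMES)
_MARKOV0 = 17  # index of first Markov occupancy


@dataclass
class CellState:
    """Full cell state: membrane potential, TTP06 gates and ion
    concentrations, plus the five Markov occupancies replacing the
    xr1/xr2 IKr gates."""

    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (N_CELL,):
            raise ValueError(f"cell state needs {N_CELL} entries, got {self.y.shape}")

    def __getattr__(self, name):
        try:
            return float(self.y[STATE_NAMES.index(name)])
        except ValueError:
            raise AttributeError(name) from None

    @property
    def markov(self) -> np.ndarray:
        return self.y[_MARKOV0:]

    def validate(self):
        for name in ("Nai", "Ki", "Cai", "CaSR", "CaSS"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"concentration {name}={v!r} must be finite and > 0")
        for name in ("m", "h", "j", "xs", "r", "s", "d", "f", "f2", "fcass", "rr"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 1 + 1e-9):
                raise ValueError(f"gate {name}={v!r} outside [0, 1]")
        p = self.markov
        if np.any(p < -1e-6) or abs(p.sum() - 1) > 1e-6:
            raise ValueError(f"Markov occupancies invalid: {p}")
        if not math.isfinite(self.V):
            raise ValueError(f"membrane potential non-finite: {self.V!r}")

    def to_dict(self) -> dict:
        return {n: float(v) for n, v in zip(STATE_NAMES, self.y)}

    @classmethod
    def from_dict(cls, d) -> "CellState":
        return cls(np.array([float(d[n]) for n in STATE_NAMES]))


@dataclass(frozen=True)
class PacingSpec:
    """Stimulation schedule: ``cycle_length_ms`` between stimuli of
    ``amplitude`` (pA/pF, negative = depolarizing in the TTP06 sign
    convention) lasting ``duration_ms``; ``n_beats`` total with the
    last ``record_beats`` returned at full resolution."""

    cycle_length_ms: float = 1000.0
    amplitude: float = -52.0
    duration_ms: float = 1.0
    n_beats: int = 50
    record_beats: int = 2

    def __post_init__(self):
        if self.cycle_length_ms <= 0 or self.duration_ms <= 0:
            raise ValueError("cycle length and stimulus duration must be > 0")
        if self.duration_ms >= self.cycle_length_ms:
            raise ValueError("stimulus outlasts the cycle")
        if self.n_beats < 1:
            raise ValueError("need at least one beat")
        if not (1 <= self.record_beats <= self.n_beats):
            raise ValueError("record_beats must be in [1, n_beats]")


@dataclass
class APMetrics:
    """Summary of one action potential (durations in ms, potentials mV)."""

    apd90: float
    apd50: float
    resting_mV: float
    peak_mV: float
    max_upstroke_mV_per_ms: float


@dataclass
class APRecording:
    """Paced-simulation output: recorded-beat voltage trace plus
    bookkeeping (per-beat APD90, final state, elicitation flags)."""

    t: np.ndarray                 # ms, relative to first recorded stimulus
    v: np.ndarray                 # mV
    beat_starts: np.ndarray       # stimulus times on the same axis
    apd90_per_beat: list          # all beats, ms (nan if no AP)
    elicited: list                # bool per beat
    final_state: CellState
    condition: str = ""


def initial_state(params: RateConstantSet) -> CellState:
    """Published TTP06 endocardial resting state, with the Markov block
    at its steady state for the initial potential."""
    y = np.zeros(N_CELL)
    vals = {
        "V": -86.2, "Nai": 7.67, "Ki": 138.3, "Cai": 0.00007,
        "CaSR": 1.3, "CaSS": 0.00007,
        "m": 0.0, "h": 0.75, "j": 0.75, "xs": 0.0, "r": 0.0, "s": 1.0,
        "d": 0.0, "f": 1.0, "f2": 1.0, "fcass": 1.0, "rr": 1.0,
    }
    for n, v in vals.items():
        y[STATE_NAMES.index(n)] = v
    y[_MARKOV0:] = steady_state(vals["V"], params).p
    return CellState(y)


def _rate_table(params: RateConstantSet):
    """(a, b, v0) per transition in chain order, for fast evaluation."""
    from .markov import TRANSITIONS

    return tuple((params[t].a, params[t].b, params[t].v0) for t in TRANSITIONS)


def _markov_derivs(v, p, tab):
    """Occupancy derivatives of the linear 5-state chain (sum is 0)."""
    k = [a * math.exp(b * (v + v0)) for a, b, v0 in tab]
    k12, k21, k23, k32, k34, k43, k45, k54 = k
    p1, p2, p3, p4, p5 = p
    f1 = k12 * p1 - k21 * p2
    f2 = k23 * p2 - k32 * p3
    f3 = k34 * p3 - k43 * p4
    f4 = k45 * p4 - k54 * p5
    return (-f1, f1 - f2, f2 - f3, f3 - f4, f4)


def cell_rhs(
    t: float,
    y,
    params: RateConstantSet,
    g_kr: float = GKR_DEFAULT,
    i_stim: float = 0.0,
    _tab=None,
):
    """Time derivative of the full cell state (TTP06 endo + Markov IKr).

    ``i_stim`` is the applied stimulus in pA/pF (negative depolarizes).
    Raises on non-finite state entries, naming the offending variable.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        bad = STATE_NAMES[int(np.argmin(np.isfinite(y)))]
        raise FloatingPointError(f"non-finite state variable {bad!r}")
    tab = _tab if _tab is not None else _rate_table(params)

    (v, nai, ki, cai, casr, cass,
     m, h, j, xs, r, s, d, f, f2g, fcass, rr) = y[:_MARKOV0]
    pmk = y[_MARKOV0:]

    ek = RTONF * math.log(KO / ki)
    ena = RTONF * math.log(NAO / nai)
    eks = RTONF * math.log((KO + PKNA * NAO) / (ki + PKNA * nai))
    eca = 0.5 * RTONF * math.log(CAO / cai)

    # inward rectifier
    ak1 = 0.1 / (1.0 + math.exp(0.06 * (v - ek - 200.0)))
    bk1 = (
        3.0 * math.exp(0.0002 * (v - ek + 100.0))
        + math.exp(0.1 * (v - ek - 10.0))
    ) / (1.0 + math.exp(-0.5 * (v - ek)))
    ik1 = GK1 * ak1 / (ak1 + bk1) * (v - ek)

    # rapid delayed rectifier: Markov open state
    ikr = g_kr * math.sqrt(KO / 5.4) * pmk[3] * (v - ek)

    iks = GKS * xs * xs * (v - eks)
    ito = GTO * r * s * (v - ek)
    ina = GNA * m ** 3 * h * j * (v - ena)
    ibna = GBNA * (v - ena)

    vfort = (v - 15.0) * FARADAY / (R_GAS * T_KELVIN)
    if abs(vfort) < 1e-7:
        # L'Hopital limit of the GHK-like driving term at V = 15 mV
        ical = GCAL * d * f * f2g * fcass * 2.0 * FARADAY * (0.25 * cass - CAO)
    else:
        e2 = math.exp(2.0 * vfort)
        ical = (
            GCAL * d * f * f2g * fcass * 4.0 * (v - 15.0)
            * (FARADAY ** 2 / (R_GAS * T_KELVIN))
            * (0.25 * cass * e2 - CAO) / (e2 - 1.0)
        )

    ibca = GBCA * (v - eca)
    vfrt = v * FARADAY / (R_GAS * T_KELVIN)
    inak = (
        KNAK * (KO / (KO + KMK)) * (nai / (nai + KMNA))
        / (1.0 + 0.1245 * math.exp(-0.1 * vfrt) + 0.0353 * math.exp(-vfrt))
    )
    inaca = (
        KNACA
        * (1.0 / (KMNAI ** 3 + NAO ** 3))
        * (1.0 / (KMCA + CAO))
        * (1.0 / (1.0 + KSAT * math.exp((NGAMMA - 1.0) * vfrt)))
        * (
            math.exp(NGAMMA * vfrt) * nai ** 3 * CAO
            - math.exp((NGAMMA - 1.0) * vfrt) * NAO ** 3 * cai * 2.5
        )
    )
    ipca = GPCA * cai / (KPCA + cai)
    ipk = GPK * (v - ek) / (1.0 + math.exp((25.0 - v) / 5.98))

    itot = (
        ik1 + ito + ikr + iks + ical + inak + ina + ibna + inaca + ibca
        + ipk + ipca + i_stim
    )

    # gate kinetics
    m_inf = 1.0 / (1.0 + math.exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + 0.10 / (
        1.0 + math.exp((v - 50.0) / 200.0)
    )
    tau_m = am * bm

    h_inf = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
    tau_h = 1.0 / (ah + bh)

    j_inf = h_inf
    if v >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        aj = (
            (-2.5428e4 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + math.exp(0.311 * (v + 79.23)))
        )
        bj = 0.02424 * math.exp(-0.01052 * v) / (
            1.0 + math.exp(-0.1378 * (v + 40.14))
        )
    tau_j = 1.0 / (aj + bj)

    xs_inf = 1.0 / (1.0 + math.exp((-5.0 - v) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((v - 35.0) / 15.0))
    tau_xs = axs * bxs + 80.0

    r_inf = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
    tau_r = 9.5 * math.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8
    s_inf = 1.0 / (1.0 + math.exp((v + 28.0) / 5.0))       # endo
    tau_s = 1000.0 * math.exp(-((v + 67.0) ** 2) / 1000.0) + 8.0

    d_inf = 1.0 / (1.0 + math.exp((-8.0 - v) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    cd = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
    tau_d = ad * bd + cd

    f_inf = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
    af = 1102.5 * math.exp(-((v + 27.0) ** 2) / 225.0)
    bf = 200.0 / (1.0 + math.exp((13.0 - v) / 10.0))
    cf = 180.0 / (1.0 + math.exp((v + 30.0) / 10.0)) + 20.0
    tau_f = af + bf + cf

    f2_inf = 0.67 / (1.0 + math.exp((v + 35.0) / 7.0)) + 0.33
    af2 = 600.0 * math.exp(-((v + 25.0) ** 2) / 170.0)
    bf2 = 31.0 / (1.0 + math.exp((25.0 - v) / 10.0))
    cf2 = 16.0 / (1.0 + math.exp((v + 30.0) / 10.0))
    tau_f2 = af2 + bf2 + cf2

    fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0

    # calcium subsystem
    kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC / casr) ** 2)
    k1 = K1_ / kcasr
    k2 = K2_ * kcasr
    drr = K4 * (1.0 - rr) - k2 * cass * rr
    so = k1 * cass * cass * rr / (K3 + k1 * cass * cass)
    irel = VREL * so * (casr - cass)
    ileak = VLEAK * (casr - cai)
    iup = VMAXUP / (1.0 + (KUP / cai) ** 2)
    ixfer = VXFER * (cass - cai)

    csqn_buf = 1.0 / (1.0 + BUFSR * KBUFSR / (casr + KBUFSR) ** 2)
    dcasr = csqn_buf * (iup - irel - ileak)

    inv_vss_f2 = 1.0 / (2.0 * VSS * FARADAY)
    ss_buf = 1.0 / (1.0 + BUFSS * KBUFSS / (cass + KBUFSS) ** 2)
    dcass = ss_buf * (
        -ixfer * (VC / VSS)
        + irel * (VSR / VSS)
        + (-ical * inv_vss_f2 * CAPACITANCE)
    )

    inv_vc_f2 = 1.0 / (2.0 * VC * FARADAY)
    c_buf = 1.0 / (1.0 + BUFC * KBUFC / (cai + KBUFC) ** 2)
    dcai = c_buf * (
        -(ibca + ipca - 2.0 * inaca) * inv_vc_f2 * CAPACITANCE
        - (iup - ileak) * (VSR / VC)
        + ixfer
    )

    inv_vc_f = 1.0 / (VC * FARADAY)
    dnai = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * inv_vc_f * CAPACITANCE
    dki = -(i_stim + ik1 + ito + ikr + iks - 2.0 * inak + ipk) * inv_vc_f * CAPACITANCE

    dmk = _markov_derivs(v, pmk, tab)

    dy = np.empty(N_CELL)
    dy[0] = -itot
    dy[1] = dnai
    dy[2] = dki
    dy[3] = dcai
    dy[4] = dcasr
    dy[5] = dcass
    dy[6] = (m_inf - m) / tau_m
    dy[7] = (h_inf - h) / tau_h
    dy[8] = (j_inf - j) / tau_j
    dy[9] = (xs_inf - xs) / tau_xs
    dy[10] = (r_inf - r) / tau_r
    dy[11] = (s_inf - s) / tau_s
    dy[12] = (d_inf - d) / tau_d
    dy[13] = (f_inf - f) / tau_f
    dy[14] = (f2_inf - f2g) / tau_f2
    dy[15] = (fcass_inf - fcass) / tau_fcass
    dy[16] = drr
    dy[_MARKOV0:] = dmk
    return dy


class DepolarizationFailure(RuntimeError):
    """No action potential was elicited by the stimulus."""


def simulate_paced(
    params: RateConstantSet,
    pacing: PacingSpec = PacingSpec(),
    g_kr: float = GKR_DEFAULT,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    dt_record: float = 0.5,
    init: CellState | None = None,
    require_ap: bool = False,
) -> APRecording:
    """Pace the cell for ``pacing.n_beats`` beats and record the last
    ``pacing.record_beats`` at ``dt_record`` resolution.

    The initial state is the published TTP06 resting state with the
    Markov block equilibrated at the initial potential (or ``init``).
    Integration uses an adaptive implicit (BDF) solver; the Markov
    occupancies are renormalized at beat boundaries to absorb solver
    round-off.  ``require_ap=True`` raises
    :class:`DepolarizationFailure` if any beat fails to produce an
    overshooting action potential; otherwise failures are flagged.
    """
    if g_kr < 0:
        raise ValueError("g_kr must be >= 0")
    state = init if init is not None else initial_state(params)
    state.validate()
    tab = _rate_table(params)
    y = state.y.copy()

    cl = pacing.cycle_length_ms
    record_from = pacing.n_beats - pacing.record_beats

    rec_t = []
    rec_v = []
    beat_starts = []
    apd90s = []
    elicited = []

    def rhs_stim(t, yy):
        return cell_rhs(t, yy, params, g_kr=g_kr, i_stim=pacing.amplitude, _tab=tab)

    def rhs_free(t, yy):
        return cell_rhs(t, yy, params, g_kr=g_kr, i_stim=0.0, _tab=tab)

    for beat in range(pacing.n_beats):
        t_offset = beat * cl
        recording = beat >= record_from
        beat_t = []
        beat_v = []
        for (rhs, t0, t1) in (
            (rhs_stim, 0.0, pacing.duration_ms),
            (rhs_free, pacing.duration_ms, cl),
        ):
            n_eval = max(2, int(round((t1 - t0) / dt_record)) + 1)
            t_eval = np.linspace(t0, t1, n_eval)
            sol = solve_ivp(
                rhs, (t0, t1), y, method="BDF", rtol=rtol, atol=atol,
                t_eval=t_eval, max_step=(1.0 if rhs is rhs_stim else np.inf),
            )
            if not sol.success:
                raise RuntimeError(
                    f"cell integration failed on beat {beat}: {sol.message}"
                )
            y = sol.y[:, -1].copy()
            # half-open segments avoid duplicate samples at boundaries;
            # the very last instant of the run is kept
            keep_end = t1 == cl and beat == pacing.n_beats - 1
            sl = slice(None) if keep_end else slice(None, -1)
            beat_t.extend(sol.t[sl] + t_offset)
            beat_v.extend(sol.y[0, sl])
        # absorb round-off in the conserved Markov block
        pm = np.maximum(y[_MARKOV0:], 0.0)
        y[_MARKOV0:] = pm / pm.sum()

        beat_t = np.asarray(beat_t)
        beat_v = np.asarray(beat_v)
        peak = float(beat_v.max())
        got_ap = peak > 0.0
        elicited.append(got_ap)
        if require_ap and not got_ap:
            raise DepolarizationFailure(
                f"beat {beat}: peak potential {peak:.1f} mV, no AP elicited"
            )
        if got_ap:
            apd90s.append(apd((beat_t - t_offset, beat_v), 0.9))
        else:
            apd90s.append(float("nan"))
        if recording:
            rec_t.extend(beat_t - record_from * cl)
            rec_v.extend(beat_v)
            beat_starts.append(t_offset - record_from * cl)

    final = CellState(y)
    final.validate()
    return APRecording(
        t=np.asarray(rec_t),
        v=np.asarray(rec_v),
        beat_starts=np.asarray(beat_starts),
        apd90_per_beat=apd90s,
        elicited=elicited,
        final_state=final,
        condition=params.condition,
    )


def _as_tv(trace):
    if isinstance(trace, APRecording):
        return trace.t, trace.v
    t, v = trace
    return np.asarray(t, dtype=float), np.asarray(v, dtype=float)


def apd(trace, fraction: float = 0.9) -> float:
    """Action-potential duration at a repolarization fraction.

    Measured from the maximum-upstroke instant to the crossing of
    V_rest + (1 - fraction) * amplitude on the repolarizing limb, with
    linear interpolation between samples.  ``trace`` is an
    :class:`APRecording` or a ``(t, V)`` pair containing one AP.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    t, v = _as_tv(trace)
    dv = np.diff(v) / np.diff(t)
    up = int(np.argmax(dv))
    t_up = t[up + 1]
    v_rest = float(v[: up + 1].min()) if up > 0 else float(v[0])
    peak_idx = up + int(np.argmax(v[up:]))
    amplitude = float(v[peak_idx]) - v_rest
    if amplitude <= 0:
        raise ValueError("no depolarization in trace")
    threshold = v_rest + (1.0 - fraction) * amplitude
    below = np.nonzero((v[peak_idx:] <= threshold))[0]
    if len(below) == 0:
        raise ValueError(
            f"membrane never repolarizes to {fraction:.0%} within the trace"
        )
    k = peak_idx + below[0]
    if k == 0 or v[k] == v[k - 1]:
        t_cross = t[k]
    else:
        frac = (v[k - 1] - threshold) / (v[k - 1] - v[k])
        t_cross = t[k - 1] + frac * (t[k] - t[k - 1])
    return float(t_cross - t_up)


def ap_metrics(trace) -> APMetrics:
    """APD90/APD50, resting and peak potential, max upstroke velocity."""
    t, v = _as_tv(trace)
    dv = np.diff(v) / np.diff(t)
    up = int(np.argmax(dv))
    v_rest = float(v[: up + 1].min()) if up > 0 else float(v[0])
    return APMetrics(
        apd90=apd((t, v), 0.9),
        apd50=apd((t, v), 0.5),
        resting_mV=v_rest,
        peak_mV=float(v.max()),
        max_upstroke_mV_per_ms=float(dv.max()),
    )
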
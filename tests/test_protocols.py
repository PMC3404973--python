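"""Protocol builders, sweep simulation and measurement operators."""

import numpy as np
import pytest

from hergsim.markov import steady_state
from hergsim.protocols import (
    CurrentTrace,
    ProtocolFamily,
    VoltageProtocol,
    build_availability_family,
    build_iv_family,
    build_single_step_family,
    measure_end_pulse,
    measure_tail_peak,
    simulate_family,
)


# ---------------------------------------------------------------------------
# builders

def test_iv_family_structure():
    fam = build_iv_family()
    assert len(fam) == 14                      # -80..+50 in 10 mV steps
    assert fam.sweep_voltages[0] == -80.0
    assert fam.sweep_voltages[-1] == 50.0
    dur, _ = fam.template.segments[fam.vary_index]
    assert dur == 5000.0                       # 5 s test step
    assert fam.template.segments[-1][1] == -55.0   # tail potential
    assert fam.template.segments[0][1] == -70.0    # holding potential


def test_single_step_family_structure():
    fam = build_single_step_family()
    assert fam.sweep_voltages == (-10.0,)
    assert fam.intersweep_ms == 18000.0
    assert fam.template.segments[0][1] == -70.0


def test_availability_family_structure():
    fam = build_availability_family()
    assert len(fam) == 14                      # -120..+10 in 10 mV steps
    cond_dur, cond_v = fam.template.segments[1]
    assert (cond_dur, cond_v) == (1000.0, 40.0)
    inter_dur, _ = fam.template.segments[fam.vary_index]
    assert inter_dur == 25.0
    assert fam.template.segments[3][1] == 40.0     # test pulse


def test_protocol_family_round_trip():
    fam = build_availability_family()
    back = ProtocolFamily.from_dict(fam.to_dict())
    assert back == fam


def test_protocol_validation():
    with pytest.raises(ValueError, match="duration"):
        VoltageProtocol(segments=((0.0, -70.0),))
    with pytest.raises(ValueError, match="at least one"):
        VoltageProtocol(segments=())
    tmpl = VoltageProtocol(segments=((10.0, -70.0),))
    with pytest.raises(ValueError, match="vary_index"):
        ProtocolFamily(template=tmpl, vary_index=3, sweep_voltages=(0.0,))
    with pytest.raises(ValueError, match="non-empty"):
        ProtocolFamily(template=tmpl, vary_index=0, sweep_voltages=())


# ---------------------------------------------------------------------------
# simulation

@pytest.fixture(scope="module")
def small_iv(pss):
    fam = build_iv_family(dt=2.0)
    fam = ProtocolFamily(
        template=fam.template,
        vary_index=fam.vary_index,
        sweep_voltages=fam.sweep_voltages,
        intersweep_ms=fam.intersweep_ms,
        label=fam.label,
    )
    return fam, simulate_family(fam, pss)


def test_family_yields_one_trace_per_sweep(small_iv):
    fam, traces = small_iv
    assert len(traces) == 14
    for v, tr in zip(fam.sweep_voltages, traces):
        assert tr.meta["sweep_mV"] == v
        assert len(tr.segments) == 3


def test_sampling_must_divide_protocol_duration(pss):
    fam = build_availability_family(dt=2.0)  # 1725 ms total, 2 ms grid
    with pytest.raises(RuntimeError, match="does not divide"):
        simulate_family(fam, pss)


def test_simulation_is_deterministic(pss):
    fam = build_single_step_family(dt=2.0)
    a = simulate_family(fam, pss)[0]
    b = simulate_family(fam, pss)[0]
    assert np.array_equal(a.i, b.i)
    assert np.array_equal(a.t, b.t)


def test_end_pulse_tracks_open_probability_order(small_iv, pss):
    # depolarization opens the channel: the -80 mV step carries less
    # end-pulse current than the 0 mV step, as steady states predict
    fam, traces = small_iv
    i_m80 = abs(measure_end_pulse(traces[0], 1))
    i_0 = abs(measure_end_pulse(traces[8], 1))
    assert steady_state(-80.0, pss).open_prob < steady_state(0.0, pss).open_prob
    assert i_m80 < i_0


def test_tail_peak_non_decreasing_with_activation(small_iv):
    _, traces = small_iv
    peaks = [measure_tail_peak(tr, 2)[0] for tr in traces]
    assert all(b >= a * (1 - 1e-9) for a, b in zip(peaks, peaks[1:]))


def test_availability_monotone_over_hyperpolarized_range(pss, c16car):
    # test-pulse current falls with interpulse depolarization once
    # recovery from inactivation is complete; under the acylcarnitine
    # set the fastest deactivation partly closes channels during the
    # 25 ms interpulse at the most negative potentials, so the
    # monotone range starts at -80 mV there (control holds from -120)
    for ps, v_from in ((pss, -120.0), (c16car, -80.0)):
        fam = build_availability_family(dt=2.5)
        traces = simulate_family(fam, ps)
        peaks = {
            v: abs(measure_tail_peak(tr, 3)[0])
            for v, tr in zip(fam.sweep_voltages, traces)
        }
        volts = [v for v in fam.sweep_voltages if v_from <= v <= -40.0]
        norm = max(peaks.values())
        vals = [peaks[v] / norm for v in volts]
        assert all(b <= a + 1e-9 for a, b in zip(vals, vals[1:])), (ps.condition, vals)


# ---------------------------------------------------------------------------
# measurement operators

def _synthetic_trace(t, i, segments):
    return CurrentTrace(t=np.asarray(t), i=np.asarray(i), segments=segments)


def test_end_pulse_constant_segment():
    t = np.arange(0.0, 100.1, 0.5)
    tr = _synthetic_trace(t, np.full_like(t, 7.0), ((0.0, 100.0, -10.0),))
    assert measure_end_pulse(tr, 0, window_ms=50.0) == pytest.approx(7.0)


def test_end_pulse_linear_ramp_closed_form():
    t = np.arange(0.0, 100.0 + 1e-9, 0.5)
    tr = _synthetic_trace(t, 0.1 * t, ((0.0, 100.0, -10.0),))
    got = measure_end_pulse(tr, 0, window_ms=20.0)
    # mean of 0.1*t over samples t = 80.5..100 (window excludes the
    # sample exactly at end-50... measured from searchsorted bounds)
    lo = int(np.searchsorted(t, 100.0 - 20.0 - 1e-9))
    expected = float(np.mean(0.1 * t[lo:]))
    assert got == pytest.approx(expected, rel=1e-12)


def test_end_pulse_window_longer_than_segment_raises():
    t = np.arange(0.0, 10.5, 0.5)
    tr = _synthetic_trace(t, np.zeros_like(t), ((0.0, 10.0, -10.0),))
    with pytest.raises(ValueError, match="longer than segment"):
        measure_end_pulse(tr, 0, window_ms=50.0)


def test_tail_peak_monotone_decay_returns_first_searched_sample():
    t = np.arange(0.0, 50.1, 0.5)
    tr = _synthetic_trace(t, 10.0 * np.exp(-t / 5.0), ((0.0, 50.0, -55.0),))
    peak, tpk = measure_tail_peak(tr, 0, skip=1)
    assert tpk == pytest.approx(0.5)           # first sample after skip
    assert peak == pytest.approx(10.0 * np.exp(-0.5 / 5.0))


def test_tail_peak_hooked_tail_finds_interior_extremum():
    t = np.arange(0.0, 100.1, 0.5)
    i = (1 - np.exp(-t / 3.0)) * np.exp(-t / 30.0)  # rise then decay
    tr = _synthetic_trace(t, i, ((0.0, 100.0, -55.0),))
    peak, tpk = measure_tail_peak(tr, 0)
    k = int(np.argmax(i))
    assert tpk == pytest.approx(t[k])
    assert peak == pytest.approx(i[k])


def test_tail_peak_empty_segment_raises():
    t = np.arange(0.0, 10.5, 0.5)
    tr = _synthetic_trace(t, np.zeros_like(t), ((0.0, 10.0, -55.0),))
    with pytest.raises(ValueError, match="no samples"):
        measure_tail_peak(tr, 0, skip=100)


def test_measurements_invariant_to_time_offset():
    t = np.arange(0.0, 100.1, 0.5)
    i = 5.0 + 3.0 * np.exp(-t / 20.0)
    tr0 = _synthetic_trace(t, i, ((0.0, 100.0, -55.0),))
    off = 1234.5
    tr1 = _synthetic_trace(t + off, i, ((off, 100.0 + off, -55.0),))
    assert measure_end_pulse(tr0, 0) == pytest.approx(measure_end_pulse(tr1, 0))
    p0, tp0 = measure_tail_peak(tr0, 0)
    p1, tp1 = measure_tail_peak(tr1, 0)
    assert p0 == pytest.approx(p1)
    assert tp1 - tp0 == pytest.approx(off)


def test_current_trace_validation():
    with pytest.raises(ValueError, match="uniform"):
        CurrentTrace(t=np.array([0.0, 1.0, 3.0]), i=np.zeros(3))
    with pytest.raises(ValueError, match="increasing"):
        CurrentTrace(t=np.array([0.0, 2.0, 1.0]), i=np.zeros(3))
    with pytest.raises(ValueError, match="non-finite"):
        CurrentTrace(t=np.array([0.0, 1.0, 2.0]), i=np.array([0.0, np.nan, 1.0]))
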
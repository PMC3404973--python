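"""Unit and property tests for the five-state gating chain."""

import json
import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

from hergsim.markov import (
    N_STATES,
    TRANSITIONS,
    OccupancyState,
    RateConstantSet,
    RateLaw,
    generator,
    integrate_occupancy,
    markov_current,
    steady_state,
    transition_rate,
)
from hergsim.markov import _EDGES

from conftest import expm_oracle_final

VOLTAGES = (-120.0, -90.0, -55.0, -10.0, 0.0, 40.0)


# ---------------------------------------------------------------------------
# rate laws

@pytest.mark.parametrize(
    "transition,v,expected",
    [
        ("k12", 0.0, 0.01507341),     # exponential term is 1 at V=0
        ("k23", 37.0, 0.08927204),    # voltage-independent
        ("k45", -18.0, 0.05042237),   # offset (V+18) cancels at -18 mV
    ],
)
def test_published_control_rates(pss, transition, v, expected):
    assert transition_rate(transition, v, pss) == pytest.approx(expected, rel=1e-12)


def test_rate_set_has_exactly_eight_transitions(pss, c16car):
    for ps in (pss, c16car):
        assert set(ps.rates) == set(TRANSITIONS)


def test_unknown_transition_names_valid_ids(pss):
    with pytest.raises(KeyError, match="k12.*k54"):
        transition_rate("k99", 0.0, pss)


def test_rate_law_rejects_nonpositive_prefactor():
    with pytest.raises(ValueError, match="> 0"):
        RateLaw(a=0.0)
    with pytest.raises(ValueError, match="> 0"):
        RateLaw(a=-1.0)


def test_parameter_json_round_trip_preserves_printed_precision(pss, tmp_path):
    path = tmp_path / "pss.json"
    pss.to_json(path)
    back = RateConstantSet.from_json(path)
    for t in TRANSITIONS:
        assert back[t].a == pss[t].a
        assert back[t].b == pss[t].b
        assert back[t].v0 == pss[t].v0
    # the printed constant survives as text
    assert "0.08927204" in json.dumps(back.to_dict())


@settings(deadline=None, max_examples=40, derandomize=True)
@given(v1=st.floats(-120, 60), v2=st.floats(-120, 60))
def test_rate_laws_monotone_in_voltage_with_sign_of_b(v1, v2):
    ps = RateConstantSet.pss()
    lo, hi = min(v1, v2), max(v1, v2)
    for t in TRANSITIONS:
        law = ps[t]
        r_lo, r_hi = law.rate(lo), law.rate(hi)
        if law.b > 0:
            assert r_hi >= r_lo
        elif law.b < 0:
            assert r_hi <= r_lo
        else:
            assert r_hi == r_lo


# ---------------------------------------------------------------------------
# generator matrix

@pytest.mark.parametrize("v", VOLTAGES)
def test_generator_columns_conserve_probability(pss, c16car, v):
    for ps in (pss, c16car):
        q = generator(v, ps)
        # scaled: the huge printed k32 makes an absolute 1e-12 bound
        # unattainable in double precision
        assert np.abs(q.sum(axis=0)).max() <= 1e-12 * max(1.0, np.abs(q).max())


def test_generator_entries_match_rates_and_chain_topology(pss):
    q = generator(0.0, pss)
    assert q[1, 0] == pytest.approx(0.01507341, rel=1e-12)  # C1 -> C2
    # non-adjacent transitions are exactly zero (linear chain)
    for i in range(N_STATES):
        for j in range(N_STATES):
            if abs(i - j) > 1:
                assert q[i, j] == 0.0
    for i in range(N_STATES):
        for j in range(N_STATES):
            if i != j:
                assert q[i, j] >= 0.0


# ---------------------------------------------------------------------------
# steady states

def _exact_null_space(v, ps):
    """Oracle: exact rational null space of the generator, with the
    diagonal built as the exact negative column sum."""
    m = sympy.zeros(N_STATES, N_STATES)
    for t in TRANSITIONS:
        i, j = _EDGES[t]
        k = sympy.Rational(transition_rate(t, v, ps))
        m[j, i] += k
        m[i, i] -= k
    vec = m.nullspace()[0]
    arr = np.array([float(x) for x in vec])
    return arr / arr.sum()


@pytest.mark.parametrize("v", VOLTAGES)
def test_steady_state_matches_null_space_oracle(pss, c16car, v):
    for ps in (pss, c16car):
        ours = steady_state(v, ps).p
        oracle = _exact_null_space(v, ps)
        assert np.max(np.abs(ours - oracle)) < 1e-10
        assert ours.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(ours >= 0)


def test_steady_state_detailed_balance_ratio(pss):
    p = steady_state(-10.0, pss).p
    expected = transition_rate("k12", -10.0, pss) / transition_rate("k21", -10.0, pss)
    assert p[1] / p[0] == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# occupancy integration

def test_constant_voltage_from_steady_state_is_fixed_point(pss):
    init = steady_state(-70.0, pss)
    t, occ = integrate_occupancy([(500.0, -70.0)], pss, init, dt_out=10.0)
    assert np.max(np.abs(occ - init.p)) < 1e-8


@pytest.mark.parametrize("backend", ["bdf", "expm"])
def test_step_integration_matches_expm_oracle(pss, c16car, backend):
    segs = [(200.0, -70.0), (5000.0, -10.0)]
    for ps in (pss, c16car):
        init = steady_state(-70.0, ps)
        t, occ = integrate_occupancy(segs, ps, init, dt_out=10.0, backend=backend)
        ref = expm_oracle_final(segs, ps, init.p)
        rel = np.max(np.abs(occ[-1] - ref)) / np.max(np.abs(ref))
        assert rel < 1e-6


def test_deep_hyperpolarization_closes_the_channel(c16car):
    # from an activated state, a long step to -120 mV empties O
    init = steady_state(0.0, c16car)
    assert init.open_prob > 0.05
    _, occ = integrate_occupancy([(2000.0, -120.0)], c16car, init, dt_out=100.0)
    assert occ[-1][3] < 1e-3
    assert occ[-1][3] == pytest.approx(steady_state(-120.0, c16car).open_prob, abs=1e-4)


def test_conservation_through_random_protocols(pss, c16car):
    rng = np.random.default_rng(42)
    for ps in (pss, c16car):
        for _ in range(5):
            segs = [
                (float(rng.uniform(5, 200)), float(rng.uniform(-100, 50)))
                for _ in range(4)
            ]
            for backend in ("bdf", "expm"):
                _, occ = integrate_occupancy(
                    segs, ps, steady_state(-70.0, ps), dt_out=1.0, backend=backend
                )
                assert np.max(np.abs(occ.sum(axis=1) - 1.0)) < 1e-8
                assert occ.min() >= -1e-12


def test_solver_error_carries_segment_index(pss):
    with pytest.raises(ValueError, match="segment 1"):
        integrate_occupancy([(10.0, -70.0), (-5.0, 0.0)], pss, dt_out=1.0)


# ---------------------------------------------------------------------------
# open-channel current

def test_markov_current_zero_cases():
    occ = OccupancyState([1.0, 0.0, 0.0, 0.0, 0.0])
    assert markov_current(occ, -10.0) == 0.0          # p_O = 0
    occ2 = OccupancyState([0.0, 0.0, 0.0, 1.0, 0.0])
    assert markov_current(occ2, -80.0, e_k=-80.0) == 0.0  # V = E_K


def test_markov_current_arithmetic():
    occ = OccupancyState([0.5, 0.0, 0.0, 0.5, 0.0])
    got = markov_current(occ, -78.0, g_kr=1.0, e_k=-88.0, ko_factor=1.0)
    assert got == pytest.approx(5.0)


def test_markov_current_rejects_negative_conductance():
    occ = OccupancyState([0.2, 0.2, 0.2, 0.2, 0.2])
    with pytest.raises(ValueError, match="g_kr"):
        markov_current(occ, 0.0, g_kr=-1.0)


def test_occupancy_state_validation():
    with pytest.raises(ValueError, match="sum"):
        OccupancyState([0.5, 0.5, 0.5, 0.0, 0.0])
    with pytest.raises(ValueError, match="5 entries"):
        OccupancyState([1.0, 0.0])
    with pytest.raises(ValueError):
        OccupancyState([1.2, -0.2, 0.0, 0.0, 0.0])
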
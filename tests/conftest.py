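"""Shared fixtures: parameter sets and the expensive simulations that
several test modules interrogate (paced action potentials, tail-current
sweeps)."""

import numpy as np
import pytest

from hergsim.ap_model import PacingSpec, simulate_paced
from hergsim.markov import RateConstantSet
from hergsim.protocols import build_single_step_family, simulate_family


@pytest.fixture(scope="session")
def pss():
    return RateConstantSet.pss()


@pytest.fixture(scope="session")
def c16car():
    return RateConstantSet.c16car()


@pytest.fixture(scope="session")
def tail_sweeps(pss, c16car):
    """The repeated -10 mV step protocol with its -55 mV deactivating
    tail, simulated at 5 kHz for both conditions."""
    fam = build_single_step_family()
    return {
        ps.condition: (fam, simulate_family(fam, ps)[0]) for ps in (pss, c16car)
    }


@pytest.fixture(scope="session")
def paced_recordings(pss, c16car):
    """Fifty paced beats at a 1000 ms cycle length per condition; the
    last two beats recorded at full resolution."""
    pacing = PacingSpec(cycle_length_ms=1000.0, n_beats=50, record_beats=2)
    return {ps.condition: simulate_paced(ps, pacing) for ps in (pss, c16car)}


def expm_oracle_final(segments, params, p0):
    """Independent propagation oracle: chained scipy matrix exponentials
    with substeps bounded in norm so the Pade scaling stays accurate."""
    from scipy.linalg import expm

    from hergsim.markov import generator

    p = np.asarray(p0, dtype=float).copy()
    for dur, v in segments:
        q = generator(v, params)
        norm = np.abs(q).max()
        n_sub = max(1, int(np.ceil(dur * norm / 1e6)))
        e = expm(q * (dur / n_sub))
        for _ in range(n_sub):
            p = e @ p
            p = p / p.sum()
    return p
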
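"""First-passage density, choice probability and simulator checks.

The independent oracle throughout is the closed-form absorption probability
of the drifted Wiener process between two boundaries; the density must
integrate to it, and the Euler simulator must reproduce it.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from socialddm import (
    Boundary,
    DDMParams,
    absorption_probability,
    choice_probability,
    fpt_density,
    simulate_trials,
)

# frozen from the closed form (e^{-2vza} - e^{-2va}) / (1 - e^{-2va}) at
# v=-2, a=2, z=0.5 under unit diffusion; quadrature of the density agrees
# to 1e-8
P_LOWER_REFERENCE = 0.98201379


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(a=0.0),
        dict(a=-1.0),
        dict(a=2.0, z=0.0),
        dict(a=2.0, z=1.0),
        dict(a=2.0, t0=-0.1),
        dict(a=2.0, sv=-0.5),
        dict(a=np.inf),
    ],
)
def test_invalid_parameters_rejected(kwargs):
    with pytest.raises(ValueError):
        DDMParams(**kwargs)


def test_density_zero_before_nondecision_time():
    p = DDMParams(a=2.0, z=0.5, t0=0.3, v=-1.0)
    assert fpt_density(0.3, Boundary.LOWER, p) == 0.0
    assert fpt_density(0.12, Boundary.LOWER, p) == 0.0
    with pytest.raises(ValueError):
        fpt_density(0.0, Boundary.LOWER, p)
    with pytest.raises(ValueError):
        fpt_density(-1.0, Boundary.UPPER, p)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    v=st.floats(-3, 3),
    a=st.floats(0.5, 3),
    z=st.floats(0.2, 0.8),
    t=st.floats(0.05, 4.0),
)
def test_reflection_symmetry(v, a, z, t):
    """Upper-boundary passage of (v, z) is lower-boundary passage of (-v, 1-z)."""
    p = DDMParams(a=a, z=z, v=v)
    mirrored = DDMParams(a=a, z=1.0 - z, v=-v)
    assert fpt_density(t, Boundary.UPPER, p) == pytest.approx(
        fpt_density(t, Boundary.LOWER, mirrored), rel=1e-12, abs=1e-300
    )


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    v=st.floats(-2, 2),
    t0=st.floats(0.0, 1.0),
    t_dec=st.floats(0.05, 3.0),
)
def test_time_shift(v, t0, t_dec):
    """Non-decision time only translates the density along the time axis."""
    shifted = DDMParams(a=1.5, z=0.4, t0=t0, v=v)
    base = DDMParams(a=1.5, z=0.4, t0=0.0, v=v)
    assert fpt_density(t0 + t_dec, Boundary.LOWER, shifted) == pytest.approx(
        fpt_density(t_dec, Boundary.LOWER, base), rel=1e-12, abs=1e-300
    )


@pytest.mark.parametrize("v,a,z", [(-2, 2, 0.5), (1, 1, 0.3), (0.5, 3, 0.7), (-1.5, 0.8, 0.4)])
def test_density_integrates_to_absorption_probability(v, a, z):
    p = DDMParams(a=a, z=z, v=v)
    lower, _ = integrate.quad(lambda t: fpt_density(t, Boundary.LOWER, p), 1e-9, 60, limit=400)
    upper, _ = integrate.quad(lambda t: fpt_density(t, Boundary.UPPER, p), 1e-9, 60, limit=400)
    assert lower == pytest.approx(absorption_probability(v, a, z), abs=1e-6)
    assert lower + upper == pytest.approx(1.0, abs=1e-6)


def test_choice_probability_examples():
    assert choice_probability(Boundary.LOWER, DDMParams(a=2.0, z=0.5, v=0.0)) == pytest.approx(0.5)
    assert choice_probability(Boundary.UPPER, DDMParams(a=2.0, z=0.5, v=0.0)) == pytest.approx(0.5)
    p = DDMParams(a=2.0, z=0.5, v=-2.0)
    assert choice_probability(Boundary.LOWER, p) == pytest.approx(P_LOWER_REFERENCE, abs=1e-6)
    strong = DDMParams(a=2.0, z=0.5, v=5.0)
    assert choice_probability(Boundary.LOWER, strong) < 0.01
    assert choice_probability(Boundary.LOWER, p) + choice_probability(Boundary.UPPER, p) == pytest.approx(1.0)


def test_sv_marginal_matches_numerical_integration():
    """sv > 0 density equals the sv=0 density averaged over a Gaussian drift."""
    p = DDMParams(a=2.0, z=0.4, t0=0.2, v=-1.0, sv=0.8)
    for t in (0.25, 0.4, 0.7, 1.2, 2.5):
        brute, _ = integrate.quad(
            lambda u: fpt_density(t, Boundary.LOWER, DDMParams(a=2.0, z=0.4, t0=0.2, v=u))
            * stats.norm.pdf(u, -1.0, 0.8),
            -8,
            6,
            limit=300,
        )
        assert fpt_density(t, Boundary.LOWER, p) == pytest.approx(brute, abs=1e-5)


def test_sv_choice_probability_matches_quadrature():
    p = DDMParams(a=2.0, z=0.4, v=-1.0, sv=0.8)
    brute, _ = integrate.quad(
        lambda u: absorption_probability(u, 2.0, 0.4) * stats.norm.pdf(u, -1.0, 0.8),
        -9,
        7,
        limit=300,
    )
    assert choice_probability(Boundary.LOWER, p) == pytest.approx(brute, abs=1e-7)


def test_simulation_is_deterministic_and_bounded():
    p = DDMParams(a=2.0, z=0.5, t0=0.3, v=-1.0)
    s1 = simulate_trials(p, n=500, seed=9)
    s2 = simulate_trials(p, n=500, seed=9)
    np.testing.assert_array_equal(s1.rt, s2.rt)
    np.testing.assert_array_equal(s1.boundary, s2.boundary)
    assert (s1.rt > p.t0).all()
    assert (s1.rt <= 5.0).all()
    assert (s1.rt[s1.censored] == 5.0).all()


def test_simulation_symmetric_process():
    p = DDMParams(a=1.5, z=0.5, t0=0.2, v=0.0)
    sim = simulate_trials(p, n=10_000, seed=3, dt=2e-4)
    frac = (sim.boundary == Boundary.LOWER.value).mean()
    se = np.sqrt(0.25 / 10_000)
    assert abs(frac - 0.5) < 3 * se + 0.005  # small allowance for censored trials


def test_simulation_matches_closed_form_absorption():
    p = DDMParams(a=2.0, z=0.5, t0=0.3, v=-2.0)
    n = 40_000
    sim = simulate_trials(p, n=n, seed=17)
    frac = (sim.boundary == Boundary.LOWER.value).mean()
    se = np.sqrt(P_LOWER_REFERENCE * (1 - P_LOWER_REFERENCE) / n)
    assert abs(frac - P_LOWER_REFERENCE) < 3 * se + 1e-3


def test_simulation_rejects_bad_window():
    with pytest.raises(ValueError):
        simulate_trials(DDMParams(a=1.0, t0=0.5), n=10, seed=0, max_t=0.4)
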
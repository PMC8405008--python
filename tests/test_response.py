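"""Amplitude-response theory: examples, identities, oracle cross-checks."""

import numpy as np
import pytest

from acdsim.dynamics import DynamicsConfig, oa_derivative, oa_trajectory
from acdsim.model_core import UPRC
from acdsim.response import (
    ResponseInput,
    amplitude_response,
    gamma_surface,
    local_amplitude_response,
    local_term,
    pl_response,
)


def _inputs_from_locals(rho_s, psi_s, weights, voltages, uprcs):
    z = np.sum(np.asarray(weights) * np.asarray(rho_s) * np.exp(1j * np.asarray(psi_s)))
    return ResponseInput(
        rho_sigma=rho_s, psi_sigma=psi_s, rho=abs(z), psi=float(np.angle(z)),
        weights=weights, voltages=voltages, uprcs=uprcs,
    )


def _random_inputs(rng, uprcs=None, S=3, rho_max=0.95):
    rho_s = rng.uniform(0.05, rho_max, S)
    psi_s = rng.uniform(-np.pi, np.pi, S)
    w = rng.uniform(0.2, 1.0, S)
    w /= w.sum()
    v = rng.uniform(0.0, 2.0, S)
    if uprcs is None:
        uprcs = [UPRC.sinusoidal(rng.uniform(-1, 4)) for _ in range(S)]
    return _inputs_from_locals(rho_s, psi_s, w, v, uprcs)


def test_local_amplitude_response_examples():
    # vanishing local amplitude leaves only the global term
    u = UPRC(a0=1.0, a=(0.4,), b=(-0.7,))
    psi = 0.8
    assert local_amplitude_response(0.0, 1.0, psi, u) == pytest.approx(
        0.4 * np.sin(psi) + 0.7 * np.cos(psi)
    )
    # term-by-term evaluation
    u2 = UPRC.sinusoidal(2.0)
    assert local_amplitude_response(0.5, np.pi / 2, 0.0, u2) == pytest.approx(0.25)
    # psi_sigma = psi kills the a0 term for any rho
    for rho in (0.1, 0.5, 0.9):
        with_a0 = local_amplitude_response(rho, 1.1, 1.1, UPRC.sinusoidal(5.0))
        without = local_amplitude_response(rho, 1.1, 1.1, UPRC.sinusoidal(0.0))
        assert with_a0 == pytest.approx(without, abs=1e-12)


def test_amplitude_response_zero_without_stimulation(rng):
    inp = _random_inputs(rng)
    inp.voltages = np.zeros_like(inp.voltages)
    assert amplitude_response(inp) == 0.0


def test_amplitude_response_equals_gamma_combination(rng):
    """Truncated at M=1 the expansion equals (1/2) sum w V Gamma exactly."""
    for _ in range(50):
        inp = _random_inputs(rng)
        direct = amplitude_response(inp, M=1)
        combo = 0.5 * sum(
            w * v * local_amplitude_response(r, p, inp.psi, u)
            for w, v, r, p, u in zip(
                inp.weights, inp.voltages, inp.rho_sigma, inp.psi_sigma, inp.uprcs
            )
        )
        assert direct == pytest.approx(combo, abs=1e-14)


def test_amplitude_response_matches_oa_finite_difference(rng):
    """Single population on the OA manifold: the response equals both the
    stimulation term of the reduced ODE and a central finite difference of
    rho under short OA integration with intensity +/- eps."""
    cfg = DynamicsConfig(omega0=0.0, gamma=2 * np.pi * 0.15, k_diag=8.0, S=1, N_sigma=1)
    uprc = UPRC.sinusoidal(2.0)
    for _ in range(5):
        rho = rng.uniform(0.2, 0.9)
        psi = rng.uniform(-np.pi, np.pi)
        inp = _inputs_from_locals([rho], [psi], [1.0], [1.0], [uprc])
        pred = amplitude_response(inp, M=1)
        r = rho * np.exp(1j * psi)
        stim = oa_derivative(r, cfg, 1.0, uprc) - oa_derivative(r, cfg, 0.0, uprc)
        assert pred == pytest.approx(np.real(np.exp(-1j * psi) * stim), abs=1e-12)
        eps, h = 1e-4, 1e-4
        rp = oa_trajectory(r, cfg, +eps, uprc, (0, h)).r[-1]
        rm = oa_trajectory(r, cfg, -eps, uprc, (0, h)).r[-1]
        fd = (abs(rp) - abs(rm)) / (2 * eps * h)
        assert pred == pytest.approx(fd, abs=5e-4)


def test_pl_response_sign_structure():
    """With Z = a0/2 - sin(theta): d rho_PL/dt ~ cos(psi), negative exactly on
    (pi/2, 3 pi/2), zero at pi/2, and equal to the full response at rho_sigma=0."""
    u = UPRC.sinusoidal(2.0)
    w = np.full(3, 1 / 3)
    v = np.array([0.5, 1.0, 0.2])
    for psi in np.linspace(0.01, 2 * np.pi - 0.01, 37):
        resp = pl_response(psi, v, w, u)
        if np.pi / 2 < psi < 3 * np.pi / 2:
            assert resp < 0
        elif psi < np.pi / 2 or psi > 3 * np.pi / 2:
            assert resp > 0
    assert pl_response(np.pi / 2, v, w, u) == pytest.approx(0.0, abs=1e-12)
    inp = _inputs_from_locals([0.0, 0.0, 0.0], [0.1, 0.2, 0.3], w, v, u)
    assert amplitude_response(inp) == pytest.approx(
        pl_response(inp.psi, v, w, u), abs=1e-14
    )


def test_local_term_vanishing_identities(rng):
    """Uniform intensity + homogeneous a0 => local term is exactly zero;
    a single population likewise."""
    for _ in range(200):
        S = int(rng.integers(2, 6))
        rho_s = rng.uniform(0.0, 1.0, S)
        psi_s = rng.uniform(-np.pi, np.pi, S)
        w = rng.uniform(0.1, 1.0, S)
        w /= w.sum()
        v = np.full(S, rng.uniform(0.1, 3.0))
        inp = _inputs_from_locals(rho_s, psi_s, w, v, UPRC.sinusoidal(2.0))
        assert abs(local_term(inp)) < 1e-10
    single = _inputs_from_locals([0.7], [0.4], [1.0], [1.5], UPRC.sinusoidal(3.0))
    assert local_term(single) == pytest.approx(0.0, abs=1e-14)


def test_local_term_zero_for_population_blind_transfer(rng):
    """If each contact's transfer coefficient is the same for every population,
    no current vector can exercise the local term (homogeneous a0)."""
    for _ in range(200):
        S, L = 3, 3
        d_col = rng.uniform(0.5, 3.0, L)  # d~ constant across populations
        d_tilde = np.tile(d_col, (S, 1))
        currents = rng.uniform(0.0, 2.0, L)
        v = d_tilde @ currents
        rho_s = rng.uniform(0, 1, S)
        psi_s = rng.uniform(-np.pi, np.pi, S)
        w = rng.uniform(0.1, 1, S)
        w /= w.sum()
        inp = _inputs_from_locals(rho_s, psi_s, w, v, UPRC.sinusoidal(2.0))
        assert abs(local_term(inp)) < 1e-10


def test_banding_structure():
    """a0 = 0 at small local amplitude: Gamma is a function of the global
    phase only (horizontal banding); a0 = 4 breaks it."""
    def variance_ratio(a0):
        df = gamma_surface(UPRC.sinusoidal(a0), rho_sigma=0.05, n_grid=61)
        grid = df.pivot(index="psi", columns="psi_sigma", values="gamma").to_numpy()
        var_over_local = grid.var(axis=1).mean()  # fixed psi, vary psi_sigma
        var_over_global = grid.var(axis=0).mean()
        return var_over_local / var_over_global

    assert variance_ratio(0.0) <= 0.01
    assert variance_ratio(4.0) > 0.01


def test_truncation_bound(rng):
    """|full response - PL response| is bounded by the local-term budget."""
    for _ in range(100):
        inp = _random_inputs(rng)
        full = amplitude_response(inp, M=1)
        pl = pl_response(inp.psi, inp.voltages, inp.weights, inp.uprcs)
        bound = 0.5 * sum(
            w * abs(v) * (r * abs(u.a0) + r**2 * (abs(u.a[0]) + abs(u.b[0])))
            for w, v, r, u in zip(inp.weights, inp.voltages, inp.rho_sigma, inp.uprcs)
        )
        assert abs(full - pl) <= bound + 1e-12


def test_response_input_consistency_guard():
    with pytest.raises(ValueError):
        ResponseInput(
            rho_sigma=[0.5, 0.5], psi_sigma=[0.0, 0.0], rho=0.9, psi=0.0,
            weights=[0.5, 0.5], voltages=[0.0, 0.0], uprcs=UPRC.sinusoidal(0.0),
        )
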
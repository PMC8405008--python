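"""Finite-N stochastic Kuramoto integration and the Ott-Antonsen reduction.

The finite system evolves by Euler-Maruyama:

    theta_{sigma n} <- theta_{sigma n}
        + [omega_{sigma n}
           + sum_{sigma'} w_{sigma'} k_{sigma sigma'} rho_{sigma'} sin(psi_{sigma'} - theta_{sigma n})
           + Vhat_sigma * Z_sigma(theta_{sigma n})] dt
        + sigma_noise * sqrt(dt) * xi,     xi ~ N(0, 1) i.i.d. per oscillator.

Natural frequencies are Lorentzian (Cauchy) with centre ``omega0`` and
half-width ``gamma``, which makes the infinite-N system exactly reducible by
the Ott-Antonsen ansatz to a single complex ODE for the order parameter
(:func:`oa_derivative`).  The reduction is used as the analytic oracle for the
finite-N simulator and supplies the closed-form amplitude/phase response
curves that the controllers are built on.

The coupling term uses the mean-field form (local order parameters computed
once per step); this is algebraically identical to the pairwise sine sums, not
an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import UPRC, PopulationPhaseState, SystemState, wrap_phase

__all__ = [
    "DynamicsConfig",
    "NumericalError",
    "sample_natural_frequencies",
    "initial_state",
    "step",
    "oa_derivative",
    "oa_trajectory",
]


class NumericalError(RuntimeError):
    """Integration produced a non-finite phase."""


@dataclass
class DynamicsConfig:
    """Parameters of the multi-population stochastic Kuramoto model.

    Defaults reproduce the tremor-calibrated regime: centre frequency
    ``omega0/2pi = 3.92`` Hz, Lorentzian half-width ``gamma/2pi = 0.15`` Hz,
    intrapopulation coupling 55 1/s, no interpopulation coupling, three
    populations of 600 oscillators, Euler step 2.5 ms.
    """

    omega0: float = 2 * np.pi * 3.92
    gamma: float = 2 * np.pi * 0.15
    k_diag: float = 55.0
    k_offdiag: float = 0.0
    sigma_noise: float = 0.0
    dt: float = 0.0025
    S: int = 3
    N_sigma: int = 600

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.S < 1 or self.N_sigma < 1:
            raise ValueError("S and N_sigma must be at least 1")

    @property
    def k_matrix(self) -> np.ndarray:
        k = np.full((self.S, self.S), float(self.k_offdiag))
        np.fill_diagonal(k, float(self.k_diag))
        return k


def sample_natural_frequencies(
    omega0: float, gamma: float, S: int, N_sigma: int, seed=None
) -> np.ndarray:
    """I.i.d. Lorentzian(omega0, gamma) draws, shape (S, N_sigma)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return omega0 + gamma * rng.standard_cauchy(size=(S, N_sigma))


def initial_state(cfg: DynamicsConfig, seed=None) -> SystemState:
    """Uniform random phases and Lorentzian frequencies; equal weights."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    omega = sample_natural_frequencies(cfg.omega0, cfg.gamma, cfg.S, cfg.N_sigma, rng)
    pops = [
        PopulationPhaseState(
            theta=rng.uniform(0.0, 2 * np.pi, cfg.N_sigma),
            omega=omega[s],
            weight=1.0 / cfg.S,
        )
        for s in range(cfg.S)
    ]
    return SystemState(populations=pops, t=0.0)


def step(state: SystemState, voltages, uprcs, cfg: DynamicsConfig, rng=None) -> SystemState:
    """One Euler-Maruyama step of the multi-population model.

    ``voltages`` holds the stimulation intensity Vhat_sigma at each
    population; ``uprcs`` is one :class:`~acdsim.model_core.UPRC` per
    population (a single UPRC is broadcast).  Noise is drawn only when
    ``cfg.sigma_noise > 0``, in which case ``rng`` is required.
    """
    voltages = np.asarray(voltages, dtype=float)
    S = state.n_populations
    if voltages.shape != (S,):
        raise ValueError("one stimulation intensity per population is required")
    if isinstance(uprcs, UPRC):
        uprcs = [uprcs] * S
    if cfg.sigma_noise > 0 and rng is None:
        raise ValueError("sigma_noise > 0 requires a random generator")

    locals_ = state.local_order_parameters()
    weights = state.weights
    k = cfg.k_matrix if S == cfg.S else _k_matrix(S, cfg.k_diag, cfg.k_offdiag)
    rho = np.array([op.rho for op in locals_])
    psi = np.array([op.psi for op in locals_])

    new_pops = []
    sqdt = np.sqrt(cfg.dt)
    for s, pop in enumerate(state.populations):
        theta = pop.theta
        coupling = np.zeros_like(theta)
        for sp in range(S):
            coupling += weights[sp] * k[s, sp] * rho[sp] * np.sin(psi[sp] - theta)
        drift = pop.omega + coupling + voltages[s] * uprcs[s](theta)
        dtheta = drift * cfg.dt
        if cfg.sigma_noise > 0:
            dtheta = dtheta + cfg.sigma_noise * sqdt * rng.standard_normal(theta.size)
        new_theta = theta + dtheta
        if not np.all(np.isfinite(new_theta)):
            raise NumericalError("non-finite phase after update")
        new_pops.append(
            PopulationPhaseState(wrap_phase(new_theta), pop.omega, pop.weight)
        )
    return SystemState(populations=new_pops, t=state.t + cfg.dt)


def _k_matrix(S, k_diag, k_offdiag):
    k = np.full((S, S), float(k_offdiag))
    np.fill_diagonal(k, float(k_diag))
    return k


def oa_derivative(r: complex, cfg: DynamicsConfig, vhat: float, uprc: UPRC) -> complex:
    """Ott-Antonsen order-parameter derivative for a single population.

    dr/dt = (i omega0 - gamma) r + (k/2) r (1 - |r|^2)
            + (i Vhat / 2) { a0 r + sum_m a_m [(r*)^(m-1) + r^(m+1)]
                                   + i sum_m b_m [(r*)^(m-1) - r^(m+1)] }
    """
    r = complex(r)
    if abs(r) > 1.0 + 1e-9:
        raise ValueError("|r| must not exceed 1")
    drift = (1j * cfg.omega0 - cfg.gamma) * r + 0.5 * cfg.k_diag * r * (1.0 - abs(r) ** 2)
    stim = uprc.a0 * r
    rc = np.conj(r)
    for m, (am, bm) in enumerate(zip(uprc.a, uprc.b), start=1):
        low = rc ** (m - 1)
        high = r ** (m + 1)
        stim += am * (low + high) + 1j * bm * (low - high)
    return drift + 0.5j * vhat * stim


def oa_trajectory(r0: complex, cfg: DynamicsConfig, vhat, uprc: UPRC, t_span, t_eval=None):
    """Integrate the reduced order-parameter ODE.

    ``vhat`` may be a constant or a callable ``t -> float``.  Returns the
    solve_ivp result with complex r reconstructed in ``.r``.
    """
    vfun = vhat if callable(vhat) else (lambda t: vhat)

    def rhs(t, y):
        d = oa_derivative(y[0] + 1j * y[1], cfg, vfun(t), uprc)
        return [d.real, d.imag]

    sol = solve_ivp(
        rhs,
        t_span,
        [np.real(r0), np.imag(r0)],
        t_eval=t_eval,
        rtol=1e-10,
        atol=1e-12,
        method="RK45",
    )
    sol.r = sol.y[0] + 1j * sol.y[1]
    return sol
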
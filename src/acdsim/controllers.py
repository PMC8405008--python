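"""Stimulation strategies: ACD, phase-locked, coordinated reset, none.

All strategies are bang-bang: a contact either delivers a single-step pulse at
``I_max`` or is silent.

* **ACD** (adaptive coordinated desynchronisation): each step, contact ``l``
  is energised exactly when its predicted effect on the global amplitude,
  ``sum_sigma d~_{sigma l} w_sigma Gamma_sigma``, is negative.  This is the
  minimiser of the linear per-step objective over the current box
  ``[0, I_max]^L`` (greedy: optimal per step, not over the horizon).
* **PL** (phase-locked): all contacts are energised when the global-phase-only
  response ``a1 sin(psi) - b1 cos(psi)`` predicts suppression; local state is
  ignored.
* **CR** (coordinated reset): open-loop bursts of high-frequency pulse trains,
  time-shifted across contacts by one oscillation period divided by the number
  of contacts.

ACD and PL are additionally rate-capped per contact by a refractory interval
of ``1/f_max``, rounded to the nearest whole number of integration steps when
the step size is known (pulses can only occur on the step grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import UPRC
from .response import local_amplitude_response, pl_response

__all__ = [
    "StimulationCommand",
    "ControllerConfig",
    "acd_currents",
    "pl_currents",
    "cr_currents",
    "cr_time_shifts",
    "cr_pulses_per_burst",
    "apply_rate_limit",
    "RateLimiter",
]


@dataclass(frozen=True)
class StimulationCommand:
    """Per-contact currents for one integration step."""

    currents: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.currents, dtype=float)
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValueError("currents must be finite and non-negative")
        object.__setattr__(self, "currents", c)

    @property
    def total(self) -> float:
        return float(self.currents.sum())


@dataclass
class ControllerConfig:
    """Strategy selection and its parameters.

    ``f_max`` caps the per-contact pulse rate of the closed-loop strategies;
    the CR parameters set the burst repetition rate (one burst per oscillation
    cycle), the intra-burst pulse-train frequency, the burst width, and the
    mean oscillation frequency used for the inter-contact time shifts.
    """

    strategy: str = "acd"
    f_max: float = 130.0
    state_source: str = "oracle"
    f_burst: float = 3.92
    f_train: float = 130.0
    t_burst: float = 0.1
    omega_bar: float = 2 * np.pi * 3.92

    def __post_init__(self):
        if self.strategy not in {"acd", "pl", "cr", "none"}:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.state_source not in {"oracle", "estimated"}:
            raise ValueError(f"unknown state source {self.state_source!r}")
        if self.f_max <= 0:
            raise ValueError("f_max must be positive")
        if self.strategy == "cr" and self.t_burst * self.f_train < 1:
            raise ValueError("a CR burst must contain at least one pulse")


def acd_currents(gammas, weights, d_tilde, i_max: float) -> StimulationCommand:
    """Greedy per-step optimum: contact on iff its response coefficient is negative.

    ``gammas`` are the per-population local amplitude responses Gamma_sigma,
    ``d_tilde`` the S x L transfer matrix.  The strict inequality makes a zero
    coefficient energy-conservative (no stimulation).
    """
    gammas = np.asarray(gammas, dtype=float)
    weights = np.asarray(weights, dtype=float)
    d_tilde = np.asarray(d_tilde, dtype=float)
    if d_tilde.shape[0] != gammas.size or gammas.size != weights.size:
        raise ValueError("d_tilde must be S x L with one Gamma and weight per population")
    gate = d_tilde.T @ (weights * gammas)
    return StimulationCommand(np.where(gate < 0.0, i_max, 0.0))


def pl_currents(
    psi: float, voltages_per_unit_current, weights, uprcs, i_max: float,
    n_contacts: int = None,
) -> StimulationCommand:
    """All contacts at ``I_max`` when the phase-locked response is negative.

    ``voltages_per_unit_current`` is the intensity each population receives
    when every contact delivers unit current (``d~ @ 1``); since it is
    non-negative, gating reduces to the sign of the global-phase response.
    The phase-only law cannot distinguish contacts, so they all fire together.
    """
    v = np.asarray(voltages_per_unit_current, dtype=float)
    if n_contacts is None:
        n_contacts = v.size
    resp = pl_response(psi, v, weights, uprcs)
    on = resp < 0.0
    return StimulationCommand(np.full(n_contacts, i_max if on else 0.0))


def cr_time_shifts(L: int, omega_bar: float) -> np.ndarray:
    """Per-contact onset delays tau_l = 2 pi (l - 1) / (omega_bar L)."""
    return 2 * np.pi * np.arange(L) / (omega_bar * L)


def cr_pulses_per_burst(cfg: ControllerConfig) -> int:
    return int(np.floor(cfg.t_burst * cfg.f_train))


def cr_currents(
    t: float, L: int, cfg: ControllerConfig, i_max: float, dt: float
) -> StimulationCommand:
    """Coordinated-reset currents for the step covering [t, t + dt).

    Contact ``l`` emits single-step pulses at times
    ``tau_l + j / f_burst + m / f_train`` for ``m = 0 .. pulses_per_burst - 1``
    and bursts ``j = 0, 1, ...``; a contact is on when one of these times
    falls inside the current step.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    tau = cr_time_shifts(L, cfg.omega_bar)
    period = 1.0 / cfg.f_burst
    n_pulses = cr_pulses_per_burst(cfg)
    f_train = cfg.f_train
    eps = 1e-12
    currents = np.zeros(L)
    for l in range(L):
        s = t - tau[l]
        if s < -eps:
            # the contact's very first pulse (at tau_l) may still fall in this step
            if s > -dt + eps:
                currents[l] = i_max
            continue
        u = np.mod(s, period)
        m = np.ceil((u - eps) * f_train)
        hit = (m <= n_pulses - 1) and (m / f_train < u + dt - eps)
        # the next burst's first pulse may fall inside this step
        hit = hit or (period >= u and period < u + dt - eps)
        if hit:
            currents[l] = i_max
    return StimulationCommand(currents)


def refractory_interval(f_max: float, dt: float = None) -> float:
    """Minimum inter-pulse gap: 1/f_max, snapped to the step grid when known."""
    gap = 1.0 / f_max
    if dt is not None:
        gap = max(1, round(gap / dt)) * dt
    return gap


def apply_rate_limit(
    requested: StimulationCommand,
    last_pulse_times: np.ndarray,
    t: float,
    f_max: float,
    dt: float = None,
):
    """Zero any contact's request arriving within the refractory interval.

    Contacts are independent.  Returns the gated command and the updated
    per-contact last-pulse times (a new array; the input is not mutated).
    """
    last = np.asarray(last_pulse_times, dtype=float).copy()
    if np.any(last > t + 1e-12):
        raise ValueError("last pulse times must not lie in the future")
    gap = refractory_interval(f_max, dt)
    req = requested.currents
    fire = (req > 0) & (t - last >= gap - 1e-12)
    last[fire] = t
    return StimulationCommand(np.where(fire, req, 0.0)), last


class RateLimiter:
    """Stateful per-contact refractory gate for step-by-step simulation."""

    def __init__(self, n_contacts: int, f_max: float, dt: float = None):
        self.f_max = f_max
        self.dt = dt
        self.last_pulse_times = np.full(n_contacts, -np.inf)

    def __call__(self, requested: StimulationCommand, t: float) -> StimulationCommand:
        out, self.last_pulse_times = apply_rate_limit(
            requested, self.last_pulse_times, t, self.f_max, self.dt
        )
        return out


def make_controller(cfg: ControllerConfig, d_tilde, i_max: float, dt: float,
                    uprcs, weights, t_start: float = 0.0):
    """Step-by-step controller closure for the reference (non-vectorised) loop.

    Returns ``controller(t, rho_sigma, psi_sigma, psi) -> StimulationCommand``.
    Used as the readable single-trial path; the batch engine in
    :mod:`acdsim.engine` must agree with it step for step.
    """
    d_tilde = np.asarray(d_tilde, dtype=float)
    S, L = d_tilde.shape
    weights = np.asarray(weights, dtype=float)
    if isinstance(uprcs, UPRC):
        uprcs = [uprcs] * S
    limiter = RateLimiter(L, cfg.f_max, dt)
    v_unit = d_tilde.sum(axis=1)
    zeros = StimulationCommand(np.zeros(L))

    def controller(t, rho_sigma, psi_sigma, psi):
        if t < t_start or cfg.strategy == "none":
            return zeros
        if cfg.strategy == "cr":
            return cr_currents(t - t_start, L, cfg, i_max, dt)
        if cfg.strategy == "pl":
            req = pl_currents(psi, v_unit, weights, uprcs, i_max, n_contacts=L)
        else:
            gam = np.array(
                [
                    local_amplitude_response(rho_sigma[s], psi_sigma[s], psi, uprcs[s])
                    for s in range(S)
                ]
            )
            req = acd_currents(gam, weights, d_tilde, i_max)
        return limiter(req, t)

    return controller
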
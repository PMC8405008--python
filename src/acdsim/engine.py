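"""Vectorised trial engine: many stochastic Kuramoto trials integrated in lock-step.

This is the computational core behind the benchmarking harness.  A batch of
trials (each with its own geometry, natural frequencies, initial phases and,
optionally, uPRC draws) is advanced simultaneously with array operations, one
Euler-Maruyama step at a time.  Per-trial randomness is derived from the
master seed and the trial index only, so two runs with the same master seed
and trial count share frequencies, initial phases and noise stream regardless
of strategy: strategy contrasts are paired (common random numbers).

The readable single-trial reference path (``dynamics.step`` plus the
controller closures in :mod:`acdsim.controllers`) defines the semantics; the
engine is required, and tested, to reproduce it step for step.
"""

from __future__ import annotations

import numpy as np

from . import geometry as geo
from .controllers import ControllerConfig, cr_pulses_per_burst, cr_time_shifts

__all__ = ["simulate_trials", "cr_schedule"]

TWO_PI = 2.0 * np.pi


def cr_schedule(n_steps: int, dt: float, L: int, cfg: ControllerConfig) -> np.ndarray:
    """Boolean (n_steps, L) mask of CR pulses, time measured from stimulation onset."""
    n_pulses = cr_pulses_per_burst(cfg)
    period = 1.0 / cfg.f_burst
    tau = cr_time_shifts(L, cfg.omega_bar)
    t = np.arange(n_steps) * dt
    eps = 1e-12
    on = np.zeros((n_steps, L), dtype=bool)
    for l in range(L):
        s = t - tau[l]
        u = np.mod(s, period)
        m = np.ceil((u - eps) * cfg.f_train)
        hit = (m <= n_pulses - 1) & (m / cfg.f_train < u + dt - eps)
        hit |= (period >= u) & (period < u + dt - eps)
        on[:, l] = ((s >= -eps) & hit) | ((s < -eps) & (s > -dt + eps))
    return on


def _trial_rng(master_seed: int, trial_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(trial_index)]))


def _noise_rng(master_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), 0x6E016E]))


def simulate_trials(
    cfg,
    strategy: str,
    *,
    master_seed: int = None,
    n_trials: int = None,
    delta_theta_max: float = None,
    record_rho: bool = False,
    record_currents: bool = False,
    record_signal: bool = False,
    precision: str = "fast",
) -> dict:
    """Run ``n_trials`` trials of one strategy under an :class:`ExperimentConfig`.

    Returns a dict with per-trial summaries: ``rho_bar`` (mean global
    amplitude over the averaging window), ``energy`` (total delivered
    current x time), ``eta`` (realised configuration parameter) and, on
    request, the full ``rho`` traces and per-step ``currents``.

    ``precision='fast'`` (default) evaluates the per-oscillator trigonometry
    in single precision while phases, reductions and the noise stream remain
    double; the resulting per-step phase error (~1e-6 rad) is far below the
    trial-to-trial variability of the stochastic experiments.
    ``precision='exact'`` keeps everything in double precision and reproduces
    the step-by-step reference path (:func:`acdsim.dynamics.step` plus the
    controller closures) to rounding error.
    """
    if precision not in ("fast", "exact"):
        raise ValueError("precision must be 'fast' or 'exact'")
    master_seed = cfg.seed if master_seed is None else master_seed
    n = cfg.n_trials if n_trials is None else n_trials
    dtm = cfg.delta_theta_max if delta_theta_max is None else delta_theta_max
    S, L, N_sigma = cfg.S, cfg.L, cfg.N_sigma
    N = S * N_sigma
    dt = cfg.dt
    n_steps = int(round(cfg.T / dt))
    stim_start = int(round(cfg.t_start / dt))
    avg_start = int(round(cfg.t_avg / dt))
    sigma = cfg.sigma_noise
    a1, b1 = cfg.a1, cfg.b1
    w = np.full(S, 1.0 / S)
    k_w = _k_matrix(S, cfg.k_diag, cfg.k_offdiag) * w[None, :]  # k_{ss'} w_{s'}
    pop_idx = np.repeat(np.arange(S), N_sigma)

    # ---- per-trial setup (geometry, frequencies, initial phases, uPRC draws)
    d_tilde = np.empty((n, S, L))
    i_max = np.empty(n)
    eta = np.empty(n)
    theta = np.empty((n, N))
    omega = np.empty((n, N))
    a0 = np.empty((n, S))
    for i in range(n):
        rng = _trial_rng(master_seed, i)
        geom_seed = int(rng.integers(0, 2**31 - 1))
        if getattr(cfg, "geometry", None) is not None:
            g = cfg.geometry
        else:
            g = geo.generate_system(
                cfg.eta, L=L, S=S, seed=geom_seed,
                tolerance=cfg.eta_tolerance, epsilon_min=cfg.epsilon_min,
                kappa_e=cfg.kappa_e,
            )
        d_tilde[i] = g.d_tilde
        eta[i] = g.eta
        i_max[i] = geo.max_current(dtm, g.d_tilde, dt)
        a0[i] = cfg.a0_mean + cfg.s_a * rng.standard_normal(S) if cfg.s_a > 0 \
            else np.full(S, cfg.a0_mean)
        omega[i] = (cfg.omega0 + cfg.gamma * rng.standard_cauchy(N_sigma * S)).ravel()
        theta[i] = rng.uniform(0.0, TWO_PI, N)
    noise_rng = _noise_rng(master_seed)

    a0_osc = a0[:, pop_idx]  # (n, N)
    half_a0 = 0.5 * a0_osc
    ctrl = ControllerConfig(
        strategy=strategy,
        f_max=cfg.f_max,
        state_source=cfg.state_source,
        f_burst=cfg.f_burst,
        f_train=cfg.f_train,
        t_burst=cfg.t_burst,
        omega_bar=cfg.omega0,
    )
    gap_steps = max(1, round(1.0 / (cfg.f_max * dt)))
    last_pulse_step = np.full((n, L), -(10**9), dtype=np.int64)
    cr_on = cr_schedule(n_steps - stim_start, dt, L, ctrl) if strategy == "cr" else None

    estimated = cfg.state_source == "estimated" and strategy in ("acd", "pl")
    if estimated:
        from .measurement import _OnlineEstimator

        v_buffer = np.empty((n, stim_start, L))
        estimator = None

    energy = np.zeros(n)
    rho_trace = np.empty((n, n_steps)) if record_rho else None
    sig_trace = np.empty((n, n_steps)) if record_signal else None
    rho_accum = np.zeros(n)
    curr_trace = np.empty((n, n_steps, L)) if record_currents else None

    sqdt_sigma = sigma * np.sqrt(dt)
    fast = precision == "fast"
    omega_dt = omega * dt  # constant per-oscillator drift
    if fast:
        a0_half32 = half_a0.astype(np.float32)
        a1_32, b1_32 = np.float32(a1), np.float32(b1)
    wrap_buf = np.empty_like(theta)
    for step_i in range(n_steps):
        t = step_i * dt
        if fast:
            th32 = theta.astype(np.float32)
            cos_t = np.cos(th32)
            sin_t = np.sin(th32)
        else:
            cos_t = np.cos(theta)
            sin_t = np.sin(theta)
        C = cos_t.reshape(n, S, N_sigma).mean(axis=2, dtype=np.float64)
        Sm = sin_t.reshape(n, S, N_sigma).mean(axis=2, dtype=np.float64)
        rho_loc = np.hypot(C, Sm)
        psi_loc = np.arctan2(Sm, C)
        zr = C.mean(axis=1)  # equal weights: sum w_s C_s
        zi = Sm.mean(axis=1)
        rho_g = np.hypot(zr, zi)
        psi_g = np.arctan2(zi, zr)
        if record_rho:
            rho_trace[:, step_i] = rho_g
        if record_signal:
            sig_trace[:, step_i] = zr
        if step_i >= avg_start:
            rho_accum += rho_g

        if estimated:
            f_loc = rho_loc * np.cos(psi_loc)  # (n, S)
            if step_i < stim_start:
                # electrode voltages: mixing is the transposed transfer matrix
                v_buffer[:, step_i] = np.einsum("nsl,ns->nl", d_tilde, f_loc)
            elif step_i == stim_start:
                estimator = _OnlineEstimator.fit_batch(
                    v_buffer, d_tilde, cfg.omega0, dt, master_seed
                )

        # ---- controller
        if step_i < stim_start or strategy == "none":
            currents = None
        elif strategy == "cr":
            currents = cr_on[step_i - stim_start][None, :] * i_max[:, None]
        else:
            if estimated:
                v_now = np.einsum("nsl,ns->nl", d_tilde, rho_loc * np.cos(psi_loc))
                rho_c, psi_c, psi_gc = estimator.update(v_now, zr, t)
            else:
                rho_c, psi_c, psi_gc = rho_loc, psi_loc, psi_g
            if strategy == "pl":
                on = (a1 * np.sin(psi_gc) - b1 * np.cos(psi_gc)) < 0.0
                req = np.where(on[:, None], i_max[:, None], 0.0) * np.ones((1, L))
            else:  # acd
                dpsi = psi_c - psi_gc[:, None]
                gam = (
                    (a1 * np.sin(psi_gc) - b1 * np.cos(psi_gc))[:, None]
                    - rho_c * a0 * np.sin(dpsi)
                    - rho_c**2 * (a1 * np.sin(2 * psi_c - psi_gc[:, None])
                                  - b1 * np.cos(2 * psi_c - psi_gc[:, None]))
                )
                gate = np.einsum("nsl,ns->nl", d_tilde, w[None, :] * gam)
                req = np.where(gate < 0.0, i_max[:, None], 0.0)
            fire = (req > 0) & (step_i - last_pulse_step >= gap_steps)
            last_pulse_step[fire] = step_i
            currents = np.where(fire, req, 0.0)

        # ---- dynamics
        if currents is None:
            vhat = None
            if record_currents:
                curr_trace[:, step_i] = 0.0
        else:
            energy += currents.sum(axis=1) * dt
            vhat = np.einsum("nsl,nl->ns", d_tilde, currents)  # (n, S)
            if record_currents:
                curr_trace[:, step_i] = currents

        # coupling sum_s' w_s' k_{ss'} rho_s' sin(psi_s' - theta), expanded in
        # cos/sin so the per-oscillator work is arithmetic only
        As = (rho_loc * np.sin(psi_loc)) @ k_w.T  # (n, S)
        Ac = (rho_loc * np.cos(psi_loc)) @ k_w.T
        if fast:
            part = As.astype(np.float32)[:, pop_idx] * cos_t
            part -= Ac.astype(np.float32)[:, pop_idx] * sin_t
            if vhat is not None:
                z = a0_half32 + a1_32 * cos_t + b1_32 * sin_t
                part += vhat.astype(np.float32)[:, pop_idx] * z
            theta += omega_dt
            theta += part * np.float32(dt)
        else:
            part = As[:, pop_idx] * cos_t - Ac[:, pop_idx] * sin_t
            if vhat is not None:
                part += vhat[:, pop_idx] * (half_a0 + a1 * cos_t + b1 * sin_t)
            theta = theta + (omega + part) * dt
        if sigma > 0:
            theta += sqdt_sigma * noise_rng.standard_normal((n, N))
        if fast:
            np.floor(theta * (1.0 / TWO_PI), out=wrap_buf)
            theta -= wrap_buf * TWO_PI
        else:
            theta = np.mod(theta, TWO_PI)

    n_avg = n_steps - avg_start
    out = {
        "rho_bar": rho_accum / n_avg,
        "energy": energy,
        "eta": eta,
        "i_max": i_max,
        "n_steps": n_steps,
        "dt": dt,
    }
    if record_rho:
        out["rho"] = rho_trace
        out["t"] = np.arange(n_steps) * dt
    if record_currents:
        out["currents"] = curr_trace
    if record_signal:
        out["signal"] = sig_trace
        out.setdefault("t", np.arange(n_steps) * dt)
    return out


def _k_matrix(S, k_diag, k_offdiag):
    k = np.full((S, S), float(k_offdiag))
    np.fill_diagonal(k, float(k_diag))
    return k
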
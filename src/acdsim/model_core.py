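"""Domain types and order-parameter arithmetic for multi-population phase-oscillator systems.

A system of ``N`` phase oscillators grouped into ``S`` populations is summarised
by the complex Kuramoto order parameter ``r = rho * exp(i*psi)``: ``rho`` is the
degree of phase synchrony (0 = incoherent, 1 = fully locked) and ``psi`` the
collective phase.  For grouped oscillators the global order parameter is a
weighted superposition of per-population (local) order parameters, with weights
``w_sigma = N_sigma / N`` that sum to one.  The observable neural signal is the
real part of ``r``, i.e. ``f = rho * cos(psi)``, which plays the role of the
symptom-related oscillation (tremor, beta-band LFP power) whose amplitude
closed-loop stimulation tries to suppress.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

TWO_PI = 2.0 * np.pi

#: rho below this value leaves the collective phase undefined; psi = 0 is
#: returned by convention and downstream code must not branch on it.
RHO_PHASE_FLOOR = 1e-12

__all__ = [
    "UPRC",
    "OrderParameter",
    "PopulationPhaseState",
    "SystemState",
    "wrap_phase",
    "local_order_parameter",
    "global_order_parameter",
    "global_signal",
]


def wrap_phase(theta):
    """Wrap phases to [0, 2*pi).  Order-parameter arithmetic is wrap-invariant;
    wrapping is numerical hygiene only."""
    return np.mod(theta, TWO_PI)


@dataclass(frozen=True)
class UPRC:
    """Unit phase response curve as a truncated Fourier series.

    ``Z(theta) = a0/2 + sum_m a[m-1] cos(m theta) + sum_m b[m-1] sin(m theta)``.

    ``a0`` is the zeroth harmonic (the vertical shift): a large ``|a0|``
    relative to the other coefficients makes the curve type I (stimulation can
    only advance the phase), a small one type II.  The default is the
    sinusoidal curve ``Z(theta) = a0/2 - sin(theta)`` (``a1 = 0``, ``b1 = -1``)
    used throughout the numerical experiments.
    """

    a0: float = 0.0
    a: tuple = (0.0,)
    b: tuple = (-1.0,)

    def __post_init__(self):
        a = tuple(float(x) for x in self.a)
        b = tuple(float(x) for x in self.b)
        if len(a) != len(b) or len(a) < 1:
            raise ValueError("cosine/sine coefficient sequences must have equal length >= 1")
        coeffs = (self.a0, *a, *b)
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("uPRC coefficients must be finite")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "a0", float(self.a0))

    @property
    def order(self) -> int:
        """Highest retained harmonic M."""
        return len(self.a)

    @classmethod
    def sinusoidal(cls, a0: float) -> "UPRC":
        """The standard test curve ``Z(theta) = a0/2 - sin(theta)``."""
        return cls(a0=a0, a=(0.0,), b=(-1.0,))

    def __call__(self, theta):
        theta = np.asarray(theta, dtype=float)
        z = np.full_like(theta, self.a0 / 2.0)
        for m, (am, bm) in enumerate(zip(self.a, self.b), start=1):
            if am != 0.0:
                z = z + am * np.cos(m * theta)
            if bm != 0.0:
                z = z + bm * np.sin(m * theta)
        return z


@dataclass(frozen=True)
class OrderParameter:
    """Polar order parameter (rho, psi) with rho in [0, 1] and psi in (-pi, pi]."""

    rho: float
    psi: float

    def __post_init__(self):
        if not (np.isfinite(self.rho) and np.isfinite(self.psi)):
            raise ValueError("order parameter must be finite")
        if self.rho < 0.0 or self.rho > 1.0 + 1e-9:
            raise ValueError(f"rho = {self.rho} outside [0, 1]")
        object.__setattr__(self, "rho", float(min(self.rho, 1.0)))
        object.__setattr__(self, "psi", float(self.psi))

    @classmethod
    def from_complex(cls, z: complex) -> "OrderParameter":
        rho = abs(z)
        if rho < RHO_PHASE_FLOOR:
            return cls(rho, 0.0)
        psi = float(np.arctan2(z.imag, z.real))
        if psi <= -np.pi:  # arctan2 may return -pi; contract is (-pi, pi]
            psi = np.pi
        return cls(rho, psi)

    @property
    def complex(self) -> complex:
        return self.rho * np.exp(1j * self.psi)


@dataclass
class PopulationPhaseState:
    """Phases and natural frequencies of one population, plus its weight."""

    theta: np.ndarray
    omega: np.ndarray
    weight: float

    def __post_init__(self):
        self.theta = wrap_phase(np.asarray(self.theta, dtype=float))
        self.omega = np.asarray(self.omega, dtype=float)
        if self.theta.shape != self.omega.shape or self.theta.ndim != 1:
            raise ValueError("theta and omega must be 1-d arrays of equal length")
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("population weight must lie in (0, 1]")

    @property
    def size(self) -> int:
        return self.theta.size

    def order_parameter(self) -> OrderParameter:
        return local_order_parameter(self.theta)


@dataclass
class SystemState:
    """All oscillator phases grouped by population, at time ``t`` (seconds)."""

    populations: list
    t: float = 0.0

    def __post_init__(self):
        if len(self.populations) < 1:
            raise ValueError("at least one population is required")
        wsum = sum(p.weight for p in self.populations)
        if abs(wsum - 1.0) > 1e-12:
            raise ValueError(f"population weights must sum to 1 (got {wsum!r})")

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.populations])

    def pooled_phases(self) -> np.ndarray:
        return np.concatenate([p.theta for p in self.populations])

    def local_order_parameters(self) -> list:
        return [p.order_parameter() for p in self.populations]

    def global_order_parameter(self) -> OrderParameter:
        return global_order_parameter(self.local_order_parameters(), self.weights)


def local_order_parameter(phases: Sequence[float]) -> OrderParameter:
    """Order parameter ``(1/N) sum_n exp(i theta_n)`` of one population."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("cannot compute the order parameter of an empty phase set")
    z = complex(np.exp(1j * phases).mean())
    return OrderParameter.from_complex(z)

def global_order_parameter(
    locals_: Sequence[OrderParameter], weights: Sequence[float]
) -> OrderParameter:
    """Weighted superposition ``sum_sigma w_sigma rho_sigma exp(i psi_sigma)``.

    Equals the order parameter of the pooled phases when the weights are the
    population size fractions.
    """
    weights = np.asarray(weights, dtype=float)
    if len(locals_) != weights.size:
        raise ValueError("one weight per local order parameter is required")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {weights.sum()!r})")
    z = complex(sum(w * op.complex for w, op in zip(weights, locals_)))
    return OrderParameter.from_complex(z)


def global_signal(op: OrderParameter) -> float:
    """Observable neural signal ``f = rho cos(psi)`` (real part of r)."""
    return float(op.rho * np.cos(op.psi))
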
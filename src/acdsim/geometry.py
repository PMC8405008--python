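"""Electrode/population placement and the stimulation transfer model.

The target nucleus is idealised as a sphere of unit radius.  ``L`` electrode
contacts sit, equally spaced, on a line through the sphere's centre (the
collinear contact arrangement of a DBS lead); ``S`` point-like neural
populations are placed inside the sphere.  In a homogeneous isotropic medium
the stimulation intensity (extracellular potential) a population receives from
unit current at a contact falls off with inverse distance, giving the S x L
transfer matrix ``d~_{sigma l} = kappa_e / |p_l - p^_sigma|``.

How focal stimulation can be is summarised by the configuration parameter
``eta``: for each contact, the distance to its nearest population divided by
the mean distance to all populations, averaged over contacts.  Small ``eta``
means each contact predominantly drives one population; ``eta -> 1`` means all
populations are equidistant from every contact and per-contact control carries
no spatial information.

Stimulation intensity is parameterised by the maximum per-step phase
perturbation ``delta_theta_max`` a single oscillator may receive, which fixes
the per-contact current ceiling ``I_max`` given the geometry and time step.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "GeometryConfig",
    "StimulationLimits",
    "collinear_electrodes",
    "transfer_matrix",
    "configuration_parameter",
    "generate_system",
    "max_current",
]

SPHERE_RADIUS = 1.0


class GeometryError(ValueError):
    """Degenerate electrode/population placement."""


def collinear_electrodes(n_contacts: int, half_span: float = 0.5) -> np.ndarray:
    """Equally spaced contacts on the z-axis, centred on the sphere centre.

    The default half-span of 0.5 sphere radii keeps the lead inside the
    nucleus with contacts 0.5 radii apart for the standard 3-contact lead.
    """
    if n_contacts < 1:
        raise ValueError("need at least one contact")
    pos = np.zeros((n_contacts, 3))
    if n_contacts > 1:
        pos[:, 2] = np.linspace(-half_span, half_span, n_contacts)
    return pos


def _distances(electrode_positions, population_positions) -> np.ndarray:
    """Pairwise distances, shape (S, L)."""
    e = np.asarray(electrode_positions, dtype=float)
    p = np.asarray(population_positions, dtype=float)
    return np.linalg.norm(p[:, None, :] - e[None, :, :], axis=2)


def transfer_matrix(
    electrode_positions,
    population_positions,
    kappa_e: float = 1.0,
    epsilon_min: float = 0.05,
) -> np.ndarray:
    """Inverse-distance transfer coefficients ``d~_{sigma l}``, shape (S, L).

    Raises :class:`GeometryError` if any contact-population pair is closer
    than ``epsilon_min``, which would make the point-source 1/r field blow up.
    """
    dists = _distances(electrode_positions, population_positions)
    if dists.min() < epsilon_min:
        raise GeometryError(
            f"contact-population distance {dists.min():.4g} below epsilon_min={epsilon_min}"
        )
    return kappa_e / dists


def configuration_parameter(electrode_positions, population_positions) -> float:
    """eta = mean over contacts of (nearest population distance / mean distance)."""
    dists = _distances(electrode_positions, population_positions)  # (S, L)
    eta_l = dists.min(axis=0) / dists.mean(axis=0)
    return float(eta_l.mean())


@dataclass
class GeometryConfig:
    """A concrete electrode/population system with its cached transfer data."""

    electrode_positions: np.ndarray
    population_positions: np.ndarray
    kappa_e: float = 1.0
    epsilon_min: float = 0.05
    d_tilde: np.ndarray = None
    eta: float = None
    seed: int = None

    def __post_init__(self):
        self.electrode_positions = np.asarray(self.electrode_positions, dtype=float)
        self.population_positions = np.asarray(self.population_positions, dtype=float)
        if self.d_tilde is None:
            self.d_tilde = transfer_matrix(
                self.electrode_positions,
                self.population_positions,
                self.kappa_e,
                self.epsilon_min,
            )
        else:
            self.d_tilde = np.asarray(self.d_tilde, dtype=float)
        if np.any(self.d_tilde <= 0):
            raise GeometryError("transfer coefficients must be strictly positive")
        if self.eta is None:
            self.eta = configuration_parameter(
                self.electrode_positions, self.population_positions
            )
        if not 0.0 < self.eta <= 1.0:
            raise GeometryError(f"eta = {self.eta} outside (0, 1]")

    @property
    def n_contacts(self) -> int:
        return self.electrode_positions.shape[0]

    @property
    def n_populations(self) -> int:
        return self.population_positions.shape[0]

    def to_json(self) -> str:
        payload = {
            "electrode_positions": self.electrode_positions.tolist(),
            "population_positions": self.population_positions.tolist(),
            "kappa_e": self.kappa_e,
            "epsilon_min": self.epsilon_min,
            "eta": self.eta,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeometryConfig":
        payload = json.loads(text)
        return cls(
            electrode_positions=np.array(payload["electrode_positions"]),
            population_positions=np.array(payload["population_positions"]),
            kappa_e=payload.get("kappa_e", 1.0),
            epsilon_min=payload.get("epsilon_min", 0.05),
            seed=payload.get("seed"),
        )


def _uniform_in_sphere(rng, radius=SPHERE_RADIUS):
    while True:
        x = rng.uniform(-radius, radius, size=3)
        if np.dot(x, x) <= radius * radius:
            return x


def _random_unit_vector(rng):
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def generate_system(
    eta_target: float,
    L: int = 3,
    S: int = 3,
    seed: int = 0,
    tolerance: float = 0.02,
    kappa_e: float = 1.0,
    epsilon_min: float = 0.05,
    max_attempts: int = 20000,
) -> GeometryConfig:
    """Random electrode/population system with ``|eta - eta_target| <= tolerance``.

    Contacts are fixed on the lead axis; population positions interpolate
    between focal anchors (each population just off a distinct contact, where
    eta is small) and a randomly oriented ring of common height around the
    lead axis (where every contact sees all populations at nearly equal
    distance, eta -> 1).  A small isotropic jitter keeps high-eta systems from
    being exactly symmetric.  The interpolation coefficient is
    rejection-sampled until eta lands within tolerance; deterministic for a
    fixed seed.
    """
    if not 0.0 < eta_target < 1.0:
        raise ValueError("eta_target must lie strictly between 0 and 1")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    electrodes = collinear_electrodes(L)
    rng = np.random.default_rng(seed)

    anchors = rings = jitter = None
    for attempt in range(max_attempts):
        if attempt % 64 == 0:
            # Fresh scene: anchors just off each contact, a random ring, jitter.
            anchors = np.empty((S, 3))
            for s in range(S):
                home = electrodes[s % L]
                anchors[s] = home + 1.02 * epsilon_min * _random_unit_vector(rng)
            ring_radius = rng.uniform(0.35, 0.8)
            ring_height = rng.uniform(-0.4, 0.4) * np.sqrt(
                max(SPHERE_RADIUS**2 - ring_radius**2, 0.0)
            )
            phase0 = rng.uniform(0.0, 2 * np.pi)
            ang = phase0 + 2 * np.pi * np.arange(S) / S
            rings = np.column_stack(
                [ring_radius * np.cos(ang), ring_radius * np.sin(ang),
                 np.full(S, ring_height)]
            )
            jitter = 0.03 * rng.standard_normal((S, 3))
        lam = rng.uniform(0.0, 1.0)
        pops = (1.0 - lam) * anchors + lam * rings + lam * jitter
        if np.linalg.norm(pops, axis=1).max() > SPHERE_RADIUS:
            continue
        if _distances(electrodes, pops).min() < epsilon_min:
            continue
        eta = configuration_parameter(electrodes, pops)
        if abs(eta - eta_target) <= tolerance:
            return GeometryConfig(
                electrode_positions=electrodes,
                population_positions=pops,
                kappa_e=kappa_e,
                epsilon_min=epsilon_min,
                seed=seed,
            )
    raise GeometryError(
        f"could not reach eta = {eta_target} +/- {tolerance} in {max_attempts} attempts"
    )


def max_current(delta_theta_max: float, d_tilde, dt: float) -> float:
    """Per-contact current ceiling from the per-step phase-perturbation budget.

    With every contact at ``I_max`` the most exposed population receives
    intensity ``I_max * max_sigma sum_l d~_{sigma l}``; over one step, and with
    the uPRC normalised so its oscillatory part has unit amplitude, the largest
    single-oscillator phase kick is then exactly ``delta_theta_max``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if delta_theta_max <= 0:
        raise ValueError("delta_theta_max must be positive")
    d_tilde = np.asarray(d_tilde, dtype=float)
    return float(delta_theta_max / (d_tilde.sum(axis=1).max() * dt))


@dataclass(frozen=True)
class StimulationLimits:
    """Intensity budget: phase-kick ceiling, resulting current ceiling, step."""

    delta_theta_max: float
    i_max: float
    dt: float

    def __post_init__(self):
        if self.delta_theta_max <= 0 or self.i_max <= 0 or self.dt <= 0:
            raise ValueError("all stimulation limits must be positive")

    @classmethod
    def from_geometry(cls, delta_theta_max: float, geom: GeometryConfig, dt: float):
        return cls(delta_theta_max, max_current(delta_theta_max, geom.d_tilde, dt), dt)
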
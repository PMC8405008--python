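"""Forward LFP model and recovery of local state from multi-contact recordings.

Populations are point current sources: the voltage at contact ``l`` is a
linear superposition of population activities,

    V_l(t) = sum_sigma d_{l sigma} rho_sigma(t) cos(psi_sigma(t)),

with inverse-distance mixing coefficients (the transposed stimulation
transfer matrix, up to constants).  Because the mixing matrix is fixed by the
anatomy, independent component analysis applied offline to a stretch of
recordings recovers the population activities up to permutation, sign and
scale; the permutation and sign are resolved by matching the recovered mixing
columns against the geometry (or against reference signals), while the scale
is irreducible and local amplitudes are therefore reported up to a positive
per-source factor, normalised so the envelope peaks at one.

Instantaneous amplitude/phase extraction is provided both offline (analytic
signal via the Hilbert transform) and online (causal complex demodulation at
the oscillation frequency), the latter feeding the closed-loop controller
when it runs from estimated rather than oracle state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import hilbert
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .model_core import OrderParameter, global_signal, wrap_phase

__all__ = [
    "MixingModel",
    "SourceSeparation",
    "LocalStateEstimate",
    "mixing_from_geometry",
    "lfp_forward",
    "separate_sources",
    "extract_phase_amplitude",
    "reconstruct_global",
]


@dataclass
class MixingModel:
    """Activity-to-voltage mixing: ``V = D f`` with D of shape (L, S)."""

    D: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2:
            raise ValueError("D must be a 2-d L x S matrix")
        if not np.all(np.isfinite(self.D)):
            raise ValueError("mixing coefficients must be finite")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def mixing_from_geometry(geom, scale: float = 1.0) -> MixingModel:
    """Recording mixing matrix from a stimulation geometry.

    In the isotropic medium the recording kernel is the same inverse-distance
    law as stimulation, so ``D = scale * d_tilde.T / kappa_e``.
    """
    return MixingModel(scale * geom.d_tilde.T / geom.kappa_e, scale)


def lfp_forward(local_order_parameters, D) -> np.ndarray:
    """Electrode voltages ``V_l = sum_sigma d_{l sigma} rho_sigma cos(psi_sigma)``.

    ``local_order_parameters`` may be a sequence of
    :class:`~acdsim.model_core.OrderParameter` or a plain activity vector
    ``f_sigma``.
    """
    D = D.D if isinstance(D, MixingModel) else np.asarray(D, dtype=float)
    if len(local_order_parameters) != D.shape[1]:
        raise ValueError("mixing matrix must have one column per population")
    if isinstance(local_order_parameters[0], OrderParameter):
        f = np.array([global_signal(op) for op in local_order_parameters])
    else:
        f = np.asarray(local_order_parameters, dtype=float)
    return D @ f


@dataclass
class SourceSeparation:
    """ICA output: sources (S, T), unmixing (S, L), mixing (L, S), matching.

    ``matching[j] = sigma`` maps recovered source ``j`` to population
    ``sigma``; ``quality`` holds the absolute correlation achieved per matched
    pair (empty when no reference was supplied).  After matching, sources and
    matrices are reordered so row ``sigma`` corresponds to population
    ``sigma``, with signs flipped so matched correlations are positive.
    """

    sources: np.ndarray
    unmixing: np.ndarray
    mixing: np.ndarray
    matching: np.ndarray
    quality: np.ndarray


def _abs_corr_matrix(A, B):
    """|corr| between columns-as-signals of A (p, T) and B (q, T)."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    A = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), 1e-300)
    B = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), 1e-300)
    return A @ B.T


def separate_sources(
    v_timeseries: np.ndarray,
    S: int,
    seed: int = 0,
    references: np.ndarray = None,
    reference_mixing: np.ndarray = None,
) -> SourceSeparation:
    """Blind separation of ``S`` population activities from L-contact recordings.

    ``v_timeseries`` has shape (L, T).  Requires the determined or
    overdetermined case ``L >= S``.  Matching against ``references`` (S, T)
    signals, or against the columns of a known ``reference_mixing`` (L, S),
    uses the optimal assignment on absolute correlations; signs are flipped so
    matched correlations are positive.
    """
    V = np.asarray(v_timeseries, dtype=float)
    if V.ndim != 2:
        raise ValueError("v_timeseries must be L x T")
    L, T = V.shape
    if L < S:
        raise ValueError(
            f"underdetermined separation: {L} contacts cannot resolve {S} sources"
        )
    ica = FastICA(
        n_components=S,
        random_state=np.random.RandomState(seed),
        whiten="unit-variance",
        max_iter=1000,
        tol=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        sources = ica.fit_transform(V.T).T  # (S, T)
    unmixing = ica.components_  # (S, L)
    mixing = ica.mixing_  # (L, S)

    corr = None
    if references is not None:
        corr = _abs_corr_matrix(sources, np.asarray(references, dtype=float))
    elif reference_mixing is not None:
        corr = _abs_corr_matrix(
            mixing.T, np.asarray(reference_mixing, dtype=float).T
        )
    if corr is None:
        order = np.arange(S)
        signs = np.ones(S)
        quality = np.array([])
    else:
        rows, cols = linear_sum_assignment(-np.abs(corr))
        order = np.empty(S, dtype=int)
        order[cols] = rows  # source occupying slot sigma
        signs = np.sign(corr[order, np.arange(S)])
        signs[signs == 0] = 1.0
        quality = np.abs(corr[order, np.arange(S)])
    matching = order
    sources = signs[:, None] * sources[order]
    unmixing = signs[:, None] * unmixing[order]
    mixing = mixing[:, order] * signs[None, :]
    return SourceSeparation(sources, unmixing, mixing, matching, quality)


def extract_phase_amplitude(signal, sample_rate: float):
    """Analytic-signal envelope and instantaneous phase of a narrowband signal.

    The phase convention matches ``signal = amplitude * cos(phase)``.  Returns
    ``(amplitude, phase, valid)``; the first and last 5% of samples are
    flagged invalid because the Hilbert transform is unreliable at the
    endpoints.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 4:
        raise ValueError("signal must contain at least 4 samples")
    # Pad each end with a periodic continuation at the dominant period before
    # the transform: the wrap-around discontinuity of the implicit periodic
    # extension then falls outside the returned samples, suppressing the edge
    # ripple that plain use of the Hilbert transform leaves well inside a
    # narrowband signal.
    spec = np.abs(np.fft.rfft(x - x.mean()))
    k_peak = int(np.argmax(spec[1:])) + 1 if spec.size > 1 else 0
    period = int(round(x.size / k_peak)) if k_peak > 0 else 0
    if 4 <= period <= x.size // 2 and spec[k_peak] > 0:
        pad = max(x.size // 10, 2 * period)
        reps = int(np.ceil(pad / period)) + 1
        front = np.tile(x[:period], reps)[reps * period - pad:]
        back = np.tile(x[-period:], reps)[:pad]
        analytic = hilbert(np.concatenate([front, x, back]))[pad:pad + x.size]
    else:
        analytic = hilbert(x)
    amplitude = np.abs(analytic)
    phase = wrap_phase(np.angle(analytic))
    valid = np.zeros(x.size, dtype=bool)
    margin = max(1, int(0.05 * x.size))
    valid[margin:-margin] = True
    return amplitude, phase, valid


def reconstruct_global(f_locals, weights) -> np.ndarray:
    """Weighted global signal ``f = sum_sigma w_sigma f_sigma``.

    Fed oracle local activities this reproduces ``rho cos(psi)`` exactly.
    """
    f = np.asarray(f_locals, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {weights.sum()!r})")
    if f.shape[0] != weights.size:
        raise ValueError("one weight per local signal is required")
    return weights @ f


@dataclass
class LocalStateEstimate:
    """Recovered local state: activities, scaled (rho, psi) per population,
    the reconstructed global state, and the source-population matching."""

    f_locals: np.ndarray
    rho_sigma: np.ndarray
    psi_sigma: np.ndarray
    rho: np.ndarray
    psi: np.ndarray
    matching: np.ndarray
    quality: np.ndarray


# ---------------------------------------------------------------------------
# Online estimation for closed-loop control from measurements
# ---------------------------------------------------------------------------

#: time constant (s) of the single-pole demodulation filter; ~0.6 Hz bandwidth
#: around the oscillation frequency, wide enough for the tremor line and its
#: Lorentzian spread, narrow enough to reject the mirror component at 2*omega0.
DEMOD_TAU = 0.25


class _Demodulator:
    """Causal complex demodulation: multiply by exp(-i omega0 t), low-pass.

    The analytic baseband ``z`` gives envelope ``|z|`` and instantaneous phase
    ``omega0 t + arg z`` without the non-causal Hilbert transform.
    """

    def __init__(self, omega0: float, dt: float, shape, tau: float = DEMOD_TAU):
        self.omega0 = omega0
        self.dt = dt
        self.decay = float(np.exp(-dt / tau))
        self.z = np.zeros(shape, dtype=complex)

    def update(self, x, t: float):
        mix = 2.0 * np.asarray(x) * np.exp(-1j * self.omega0 * t)
        self.z = self.decay * self.z + (1.0 - self.decay) * mix
        return np.abs(self.z), np.angle(self.z) + self.omega0 * t

    def run(self, x_series, t0: float = 0.0):
        """Offline pass over (T, ...) samples; returns final state's envelope trace."""
        env = np.empty(x_series.shape)
        for i in range(x_series.shape[0]):
            env[i], _ = self.update(x_series[i], t0 + i * self.dt)
        return env


class _OnlineEstimator:
    """Per-trial ICA unmixing plus online demodulation, batched across trials.

    Fitted once on the pre-stimulation recording window; thereafter
    :meth:`update` turns the instantaneous contact voltages and the measured
    global (tremor) signal into the state estimate the controller consumes.
    Local amplitudes carry an irreducible positive scale, normalised so each
    source's envelope peaks at one over the fitting window.
    """

    #: seconds of recording discarded before the ICA fit (startup transient)
    FIT_SKIP = 1.0

    def __init__(self, unmixing, scales, demod_loc, demod_glob):
        self.unmixing = unmixing  # (n, S, L)
        self.scales = scales  # (n, S)
        self.demod_loc = demod_loc
        self.demod_glob = demod_glob

    @classmethod
    def fit_batch(cls, v_buffer, d_tilde, omega0, dt, seed):
        n, T0, L = v_buffer.shape
        S = d_tilde.shape[1]
        skip = min(int(cls.FIT_SKIP / dt), T0 // 2)
        unmixing = np.empty((n, S, L))
        for i in range(n):
            sep = separate_sources(
                v_buffer[i, skip:].T, S, seed=(int(seed) + i) % (2**31 - 1),
                reference_mixing=d_tilde[i].T,
            )
            unmixing[i] = sep.unmixing
        # offline demodulation of the window initialises filter state and scale
        demod_loc = _Demodulator(omega0, dt, (n, S))
        f_win = np.einsum("nsl,ntl->nts", unmixing, v_buffer)
        env = demod_loc.run(np.swapaxes(f_win, 0, 1))  # (T0, n, S)
        scales = np.maximum(env[skip:].max(axis=0), 1e-12)
        demod_glob = _Demodulator(omega0, dt, (n,))
        return cls(unmixing, scales, demod_loc, demod_glob)

    def update(self, v_now, f_global, t: float):
        """State estimate at time t from contact voltages and the tremor signal."""
        f_hat = np.einsum("nsl,nl->ns", self.unmixing, v_now)
        env, psi_loc = self.demod_loc.update(f_hat, t)
        rho_loc = np.minimum(env / self.scales, 1.0)
        _, psi_g = self.demod_glob.update(f_global, t)
        return rho_loc, psi_loc, psi_g
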
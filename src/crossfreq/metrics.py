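"""The four modulation-index (MI) estimators.

Each estimator consumes one instantaneous-phase series (radians) and one
amplitude-envelope series of equal length N and returns a non-negative
scalar:

* ``mvl_canolty`` — length of the mean vector (1/N)·Σ a(n)·e^{iφ(n)}.
  Scales linearly with amplitude, so it partly reflects high-frequency
  power rather than coupling; kept because it is widely used.
* ``mvl_ozkurt`` — the same resultant normalized by the envelope power,
  (1/√N)·|Σ a·e^{iφ}| / √(Σ a²); amplitude-scale invariant and bounded by 1.
* ``plv_cohen`` — phase-locking value between the low-frequency phase and
  the phase of the (demeaned) envelope's own analytic signal: if coupling
  is present the envelope oscillates at the phase frequency.
* ``kl_tort`` — Kullback–Leibler divergence of the mean-amplitude-per-
  phase-bin distribution (18 bins by default) from uniform, normalized by
  log(Nbins) so the value lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .exceptions import DegenerateInputError, EmptyBinError

__all__ = [
    "MIEstimate",
    "PhaseAmplitudeDistribution",
    "mvl_canolty",
    "mvl_ozkurt",
    "plv_cohen",
    "phase_amplitude_histogram",
    "kl_tort",
    "METHODS",
    "compute_mi",
    "envelope_phase",
]


@dataclass(frozen=True)
class MIEstimate:
    """One modulation-index value with its provenance."""

    method: str
    value: float
    phase_center: float | None = None
    amp_center: float | None = None
    n_samples: int | None = None

    def as_row(self) -> tuple:
        return (self.method, self.phase_center, self.amp_center,
                self.value, self.n_samples)


@dataclass(frozen=True)
class PhaseAmplitudeDistribution:
    """Normalized mean amplitude per phase bin (sums to 1) plus the uniform
    reference Q = 1/Nbins used by the KL modulation index."""

    P: np.ndarray
    bin_edges: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.P.size

    @property
    def Q(self) -> np.ndarray:
        return np.full(self.n_bins, 1.0 / self.n_bins)


def _check_pair(phase: np.ndarray, amp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    phase = np.asarray(phase, dtype=float).ravel()
    amp = np.asarray(amp, dtype=float).ravel()
    if phase.size != amp.size:
        raise ValueError(
            f"phase ({phase.size}) and amplitude ({amp.size}) series differ in length"
        )
    if phase.size < 2:
        raise ValueError("need at least 2 samples")
    return phase, amp


def mvl_canolty(phase: np.ndarray, amp: np.ndarray) -> float:
    """Mean-vector-length MI: |(1/N)·Σ a(n)·e^{iφ(n)}|.

    Note: scales linearly with the amplitude envelope (the documented
    power confound of this estimator).
    """
    phase, amp = _check_pair(phase, amp)
    return float(np.abs(np.mean(amp * np.exp(1j * phase))))


def mvl_ozkurt(phase: np.ndarray, amp: np.ndarray) -> float:
    """Power-normalized mean-vector-length MI:
    (1/√N)·|Σ a·e^{iφ}| / √(Σ a²). Invariant to amplitude scaling."""
    phase, amp = _check_pair(phase, amp)
    norm = np.sqrt(np.sum(amp ** 2))
    if norm == 0:
        raise DegenerateInputError("all-zero amplitude envelope")
    n = phase.size
    return float(np.abs(np.sum(amp * np.exp(1j * phase))) / (np.sqrt(n) * norm))


def envelope_phase(amp: np.ndarray) -> np.ndarray:
    """Instantaneous phase of an amplitude envelope's own oscillation.

    The envelope is demeaned first — its DC offset otherwise dominates the
    Hilbert phase — then the analytic-signal argument is taken.
    """
    amp = np.asarray(amp, dtype=float)
    centered = amp - np.mean(amp, axis=-1, keepdims=True)
    if np.all(centered == 0):
        raise DegenerateInputError("constant amplitude envelope has no phase")
    return np.angle(hilbert(centered, axis=-1))


def plv_cohen(phase_lo: np.ndarray, amp_hi: np.ndarray) -> float:
    """Phase-locking value between the low-frequency phase and the phase of
    the high-frequency amplitude envelope."""
    phase_lo, amp_hi = _check_pair(phase_lo, amp_hi)
    phi_a = envelope_phase(amp_hi)
    return float(np.abs(np.mean(np.exp(1j * (phase_lo - phi_a)))))


def _bin_indices(phase: np.ndarray, n_bins: int) -> np.ndarray:
    # left-closed, right-open partition of [-pi, pi); exactly pi -> last bin
    width = 2 * np.pi / n_bins
    idx = np.floor((phase + np.pi) / width).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def phase_amplitude_histogram(phase: np.ndarray, amp: np.ndarray,
                              n_bins: int = 18) -> PhaseAmplitudeDistribution:
    """Mean amplitude within each of `n_bins` equal phase bins, normalized
    to sum to 1. An empty bin raises (its mean amplitude is undefined)."""
    phase, amp = _check_pair(phase, amp)
    if n_bins < 2:
        raise ValueError(f"need at least 2 bins, got {n_bins}")
    idx = _bin_indices(phase, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise EmptyBinError(int(empty[0]), n_bins)
    sums = np.bincount(idx, weights=amp, minlength=n_bins)
    means = sums / counts
    total = means.sum()
    if total == 0:
        raise DegenerateInputError("all-zero amplitude envelope")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    return PhaseAmplitudeDistribution(P=means / total, bin_edges=edges)


def kl_tort(phase: np.ndarray, amp: np.ndarray, n_bins: int = 18) -> float:
    """KL modulation index: D(P, uniform) / log(Nbins), in [0, 1].

    Uses natural logs in both numerator and denominator (the ratio is
    base-invariant); P=0 terms contribute 0.
    """
    dist = phase_amplitude_histogram(phase, amp, n_bins)
    P = dist.P
    nz = P > 0
    d = float(np.sum(P[nz] * np.log(P[nz] * dist.n_bins)))
    return d / np.log(dist.n_bins)


METHODS = {
    "mvl_canolty": mvl_canolty,
    "mvl_ozkurt": mvl_ozkurt,
    "plv_cohen": plv_cohen,
    "kl_tort": kl_tort,
}


def compute_mi(method: str, phase: np.ndarray, amp: np.ndarray, **kwargs) -> float:
    """Dispatch to one of the four estimators by name."""
    try:
        fn = METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown MI method {method!r}; choose from {sorted(METHODS)}"
        ) from None
    return fn(phase, amp, **kwargs)
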
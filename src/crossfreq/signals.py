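"""Filter design, analytic-signal extraction, and band power change.

This is the front end feeding every PAC metric: narrow-band phase is taken
with a fixed ±1 Hz band, the high-frequency amplitude envelope with a band
that scales as ±0.4 times its center frequency (wide enough to contain the
modulation sidebands of any alpha-range phase frequency). Both use a
fourth-order Butterworth applied forward and backward (two-pass, zero net
phase shift), followed by the Hilbert transform; a settable stretch at each
trial edge is discarded afterwards so that filter and Hilbert edge
artifacts are removed together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .exceptions import DegenerateInputError, InvalidBandError, TrimError

__all__ = [
    "BandFilterSpec",
    "TrialSeries",
    "AnalyticSeries",
    "design_phase_band",
    "design_amplitude_band",
    "min_amplitude_center",
    "extract_analytic",
    "band_power_change",
]


@dataclass(frozen=True)
class BandFilterSpec:
    """A band-pass definition: center ± half_bw Hz, Butterworth design order
    `order`, applied `passes` times (2 = forward-backward, zero phase)."""

    center: float
    half_bw: float
    order: int = 4
    passes: int = 2

    def __post_init__(self):
        if self.half_bw <= 0:
            raise InvalidBandError(f"half bandwidth must be positive, got {self.half_bw}")
        if self.lo_edge <= 0:
            raise InvalidBandError(
                f"low band edge {self.lo_edge:g} Hz is not positive "
                f"(center {self.center:g} Hz, half bandwidth {self.half_bw:g} Hz)"
            )
        if self.passes not in (1, 2):
            raise InvalidBandError(f"passes must be 1 or 2, got {self.passes}")

    @property
    def lo_edge(self) -> float:
        return self.center - self.half_bw

    @property
    def hi_edge(self) -> float:
        return self.center + self.half_bw

    @property
    def edges(self) -> tuple[float, float]:
        return (self.lo_edge, self.hi_edge)

    def validate_against(self, fs: float) -> None:
        """Raise if the band does not fit inside (0, fs/2)."""
        if self.hi_edge >= fs / 2:
            raise InvalidBandError(
                f"high band edge {self.hi_edge:g} Hz is not below Nyquist "
                f"({fs / 2:g} Hz at fs={fs:g} Hz)"
            )


@dataclass
class TrialSeries:
    """Trial-epoched single-channel time series.

    data: (n_trials, n_samples) array; fs: sampling rate in Hz;
    t0: time of the first sample relative to the event (s);
    condition: label; pad: padding duration included at each end (s).
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0
    condition: str = ""
    pad: float = 0.0

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("trial data must be a trials x samples matrix")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.pad < 0:
            raise ValueError(f"pad must be non-negative, got {self.pad}")
        n_pad = self.pad * self.fs
        if abs(n_pad - round(n_pad)) > 1e-6:
            raise ValueError(
                f"pad ({self.pad} s) must be an integer number of samples at fs={self.fs} Hz"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Event-relative time of each sample (s)."""
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class AnalyticSeries:
    """Per-trial instantaneous phase and amplitude after filtering, Hilbert
    transform, and edge trimming. `degenerate` flags trials whose raw input
    was constant (phase there is meaningless but kept finite)."""

    phase: np.ndarray       # (n_trials, n_samples), radians in [-pi, pi)
    amplitude: np.ndarray   # (n_trials, n_samples), >= 0
    band: BandFilterSpec
    fs: float
    t0: float = 0.0
    degenerate: np.ndarray = field(default=None)  # (n_trials,) bool

    def __post_init__(self):
        if self.degenerate is None:
            self.degenerate = np.zeros(self.phase.shape[0], dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.phase.shape[1]

    @property
    def n_trials(self) -> int:
        return self.phase.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


def design_phase_band(center: float) -> BandFilterSpec:
    """Phase-frequency band: center ± 1 Hz, order-4 two-pass Butterworth.

    The narrow fixed bandwidth keeps the extracted waveform sinusoidal so
    its instantaneous phase is well defined.
    """
    if center < 2:
        raise InvalidBandError(
            f"phase center {center:g} Hz too low: low edge {center - 1:g} Hz "
            "would not be positive"
        )
    return BandFilterSpec(center=float(center), half_bw=1.0)


def design_amplitude_band(center: float, scale: float = 0.4) -> BandFilterSpec:
    """Amplitude-frequency band: center ± scale*center Hz.

    The bandwidth scales with the center frequency so that the modulation
    sidebands (center ± phase frequency) stay inside the band; e.g. a 60 Hz
    center gives half-bandwidth 24 Hz and edges [36, 84] Hz.
    """
    if center <= 0:
        raise InvalidBandError(f"amplitude center must be positive, got {center}")
    if not 0 < scale < 1:
        raise InvalidBandError(f"bandwidth scale must be in (0, 1), got {scale}")
    return BandFilterSpec(center=float(center), half_bw=float(scale) * float(center))


def min_amplitude_center(max_phase: float, scale: float = 0.4,
                         amp_grid_step: float = 2.0) -> float:
    """Smallest grid frequency (a multiple of `amp_grid_step`) whose scaled
    half-bandwidth covers the sidebands of `max_phase`.

    For a 13 Hz maximum phase frequency with the 0.4 scaling on a 2 Hz grid
    this is 34 Hz (0.4*34 = 13.6 >= 13 while 0.4*32 = 12.8 < 13).
    """
    if max_phase <= 0:
        raise ValueError(f"max_phase must be positive, got {max_phase}")
    exact = max_phase / scale
    k = int(np.ceil(exact / amp_grid_step - 1e-12))
    return k * amp_grid_step


def _bandpass_sos(band: BandFilterSpec, fs: float) -> np.ndarray:
    band.validate_against(fs)
    return _sig.butter(band.order, band.edges, btype="bandpass", fs=fs, output="sos")


def bandpass_filter(data: np.ndarray, band: BandFilterSpec, fs: float) -> np.ndarray:
    """Apply the band-pass along the last axis; two passes give zero phase."""
    sos = _bandpass_sos(band, fs)
    if band.passes == 2:
        return _sig.sosfiltfilt(sos, data, axis=-1)
    return _sig.sosfilt(sos, data, axis=-1)


def extract_analytic(trials: TrialSeries, band: BandFilterSpec,
                     trim: float = 0.5) -> AnalyticSeries:
    """Band-pass each trial, take the Hilbert analytic signal, trim edges.

    `trim` seconds are removed from BOTH ends AFTER the transform, so the
    same cut removes filter ringing and Hilbert edge effects. Constant
    trials are flagged degenerate instead of raising, so batch runs survive
    dead channels.
    """
    n_trim = int(round(trim * trials.fs))
    if trials.n_samples <= 2 * n_trim:
        raise TrimError(
            f"trial of {trials.n_samples} samples cannot lose 2 x {n_trim} "
            f"edge samples (trim={trim:g} s at fs={trials.fs:g} Hz)"
        )
    filtered = bandpass_filter(trials.data, band, trials.fs)
    analytic = _sig.hilbert(filtered, axis=-1)
    if n_trim:
        analytic = analytic[:, n_trim:-n_trim]
    phase = np.angle(analytic)
    # np.angle returns (-pi, pi]; fold the single boundary value to -pi
    phase[phase >= np.pi] = -np.pi
    amplitude = np.abs(analytic)
    degenerate = np.ptp(trials.data, axis=-1) == 0
    return AnalyticSeries(
        phase=phase,
        amplitude=amplitude,
        band=band,
        fs=trials.fs,
        t0=trials.t0 + n_trim / trials.fs,
        degenerate=degenerate,
    )


def band_power_change(trials_active: TrialSeries, trials_baseline: TrialSeries,
                      freqs: tuple[float, float] = (1.0, 100.0),
                      window: float = 0.5, step: float = 0.02,
                      smoothing: float = 8.0) -> tuple[np.ndarray, np.ndarray]:
    """Percent spectral power change, active vs. baseline, per frequency.

    Power is estimated in sliding windows (`window` s long, advancing by
    `step` s) with a multitaper (DPSS) estimator whose time-half-bandwidth
    realizes ±`smoothing` Hz of frequency smoothing, then averaged over
    windows and trials. Returns ``(freqs_hz, 100*(active-baseline)/baseline)``
    restricted to the requested frequency range.
    """
    if trials_active.fs != trials_baseline.fs:
        raise ValueError("active and baseline series must share a sampling rate")
    fs = trials_active.fs
    n_win = int(round(window * fs))
    n_step = max(1, int(round(step * fs)))
    for ts, name in ((trials_active, "active"), (trials_baseline, "baseline")):
        if n_win > ts.n_samples:
            raise ValueError(
                f"window of {n_win} samples exceeds {name} trial length {ts.n_samples}"
            )
    nw = smoothing * window  # time-half-bandwidth product
    n_tapers = max(1, int(2 * nw - 1))
    tapers = _sig.windows.dpss(n_win, nw, Kmax=n_tapers)  # (K, n_win)
    n_fft = max(n_win, int(round(fs)))  # >= 1 Hz grid
    freq_axis = np.fft.rfftfreq(n_fft, d=1.0 / fs)

    def _psd(ts: TrialSeries) -> np.ndarray:
        starts = np.arange(0, ts.n_samples - n_win + 1, n_step)
        acc = np.zeros(freq_axis.size)
        for s in starts:
            seg = ts.data[:, s:s + n_win]              # (T, n_win)
            tapered = seg[:, None, :] * tapers[None]   # (T, K, n_win)
            spec = np.fft.rfft(tapered, n=n_fft, axis=-1)
            acc += np.mean(np.abs(spec) ** 2, axis=(0, 1))
        return acc / starts.size

    p_act = _psd(trials_active)
    p_base = _psd(trials_baseline)
    lo, hi = freqs
    sel = (freq_axis >= lo) & (freq_axis <= hi)
    base = p_base[sel]
    if np.any(base == 0):
        raise DegenerateInputError("baseline power is zero at some frequencies")
    change = 100.0 * (p_act[sel] - base) / base
    return freq_axis[sel], change
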
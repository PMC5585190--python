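"""Cluster-based permutation statistics and the sinusoidality diagnostic.

Condition comparison follows the non-parametric cluster approach for
multi-cell grids: a dependent-samples t statistic per comodulogram cell,
clustering of adjacent supra-threshold cells (4-neighbour connectivity,
positive and negative cells clustered separately), the maximum |t| within
each cluster as the cluster statistic, and a null distribution built by
randomly swapping the condition labels within subjects (equivalent to sign
flips of the per-subject differences). A cluster-mass statistic (sum of t
within the cluster) is available behind the `statistic` switch.

The sinusoidality diagnostic measures, per phase frequency, the mean
trough-to-peak (rise) and peak-to-trough (decay) times of each oscillatory
cycle; a rise/decay ratio different from 1 marks sawtooth-like waveforms,
whose phase harmonics can masquerade as phase-amplitude coupling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as _sig
from scipy import stats as _st

from .comodulogram import ComodulogramGrid
from .signals import TrialSeries, design_phase_band, extract_analytic

__all__ = [
    "PairedTResult",
    "ClusterTestResult",
    "SinusoidalityResult",
    "SinusoidalityComparison",
    "paired_t",
    "cluster_permutation_test",
    "rise_decay_ratio",
    "sinusoidality_comparison",
]


@dataclass(frozen=True)
class PairedTResult:
    """Dependent-samples t statistic; `degenerate` marks zero difference
    variance (t undefined or infinite, p undefined)."""

    t: float
    p: float
    df: int
    degenerate: bool = False


def paired_t(a: np.ndarray, b: np.ndarray) -> PairedTResult:
    """Standard paired t with two-tailed p; flags zero-variance pairs."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"paired samples differ in length ({a.size} vs {b.size})")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
        return PairedTResult(t=float(t), p=np.nan, df=n - 1, degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * _st.t.sf(abs(t), df=n - 1)
    return PairedTResult(t=float(t), p=float(p), df=n - 1)


@dataclass
class ClusterTestResult:
    t_map: np.ndarray                      # (n_phase, n_amp)
    clusters: list[np.ndarray]             # each: (k, 2) array of (i, j) cells
    cluster_signs: np.ndarray              # (+1 / -1) per cluster
    cluster_stats: np.ndarray              # max |t| (or |mass|) per cluster
    null_distribution: np.ndarray          # (n_perm,) largest cluster stat
    p_values: np.ndarray                   # per cluster
    sig_mask: np.ndarray                   # bool grid: cells in p < alpha clusters
    t_critical: float
    alpha: float
    cluster_alpha: float
    n_perm: int
    statistic: str
    seed: int | None


_ADJACENCY = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-neighbour


def _stack(grids) -> np.ndarray:
    arrs = [g.mi if isinstance(g, ComodulogramGrid) else np.asarray(g, dtype=float)
            for g in grids]
    out = np.stack(arrs)
    if out.ndim != 3:
        raise ValueError("each grid must be a 2-D phase x amplitude matrix")
    return out


def _t_map(d: np.ndarray) -> np.ndarray:
    """Paired t per cell from per-subject differences (S, P, A); cells with
    zero variance get t = 0 (no evidence either way)."""
    s = d.shape[0]
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d.mean(axis=0) / (sd / np.sqrt(s))
    t[sd == 0] = 0.0
    return t


def _clusters_and_stats(t: np.ndarray, t_crit: float, statistic: str):
    """Signed supra-threshold clusters and their statistics."""
    clusters, signs, stats_ = [], [], []
    for sign, mask in ((1, t > t_crit), (-1, t < -t_crit)):
        labels, n_lab = ndimage.label(mask, structure=_ADJACENCY)
        for lab in range(1, n_lab + 1):
            cells = np.argwhere(labels == lab)
            vals = t[labels == lab]
            stat = np.max(np.abs(vals)) if statistic == "max_t" else np.abs(vals.sum())
            clusters.append(cells)
            signs.append(sign)
            stats_.append(stat)
    return clusters, np.array(signs, dtype=int), np.array(stats_, dtype=float)


def _null_max_stats(d: np.ndarray, t_crit: float, n_perm: int, statistic: str,
                    rng: np.random.Generator) -> np.ndarray:
    """Largest cluster statistic per label permutation.

    Label randomization for a paired design is a per-subject condition
    swap, i.e. a sign flip of that subject's difference grid. Sign patterns
    are drawn in +/- pairs so the null is exactly invariant under exchange
    of the two conditions.
    """
    s = d.shape[0]
    flat = d.reshape(s, -1)
    half = (n_perm + 1) // 2
    signs = rng.choice([-1.0, 1.0], size=(half, s))
    signs = np.vstack([signs, -signs])[:n_perm]
    means = signs @ flat / s                       # (n_perm, cells)
    sumsq = np.sum(flat ** 2, axis=0)              # invariant to sign flips
    var = (sumsq - s * means ** 2) / (s - 1)
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / s)
    t[var == 0] = 0.0
    if statistic == "max_t":
        supra = np.abs(t) > t_crit
        return np.max(np.where(supra, np.abs(t), 0.0), axis=1)
    # cluster mass needs per-permutation labeling
    shape = d.shape[1:]
    out = np.empty(n_perm)
    for k in range(n_perm):
        _, _, stats_ = _clusters_and_stats(t[k].reshape(shape), t_crit, "mass")
        out[k] = stats_.max() if stats_.size else 0.0
    return out


def cluster_permutation_test(grids_a, grids_b, n_perm: int = 1000,
                             cluster_alpha: float = 0.05, alpha: float = 0.05,
                             seed: int | None = None,
                             statistic: str = "max_t") -> ClusterTestResult:
    """Compare per-subject comodulograms between two conditions.

    Parameters: `grids_a`/`grids_b` are sequences (one per subject) of
    ComodulogramGrid or plain matrices with matching shapes;
    `cluster_alpha` sets the two-tailed t quantile used to form clusters;
    `alpha` the cluster-level significance threshold; `statistic` is
    ``"max_t"`` (maximum |t| within the cluster) or ``"mass"`` (|sum of t|).
    The cluster p-value is the proportion of permutations whose largest
    cluster statistic reaches the observed one.
    """
    if statistic not in ("max_t", "mass"):
        raise ValueError(f"statistic must be 'max_t' or 'mass', got {statistic!r}")
    if n_perm < 1:
        raise ValueError("need at least 1 permutation")
    a = _stack(grids_a)
    b = _stack(grids_b)
    if a.shape != b.shape:
        raise ValueError(f"condition grids mismatch: {a.shape} vs {b.shape}")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    d = a - b
    s = d.shape[0]
    t_map = _t_map(d)
    t_crit = float(_st.t.ppf(1 - cluster_alpha / 2, df=s - 1))
    clusters, signs, stats_ = _clusters_and_stats(t_map, t_crit, statistic)
    rng = np.random.default_rng(seed)
    null = _null_max_stats(d, t_crit, n_perm, statistic, rng)
    if stats_.size:
        p_values = np.array([(null >= st).mean() for st in stats_])
    else:
        p_values = np.empty(0)
    sig_mask = np.zeros(t_map.shape, dtype=bool)
    for cells, p in zip(clusters, p_values):
        if p < alpha:
            sig_mask[cells[:, 0], cells[:, 1]] = True
    return ClusterTestResult(
        t_map=t_map, clusters=clusters, cluster_signs=signs,
        cluster_stats=stats_, null_distribution=null, p_values=p_values,
        sig_mask=sig_mask, t_critical=t_crit, alpha=alpha,
        cluster_alpha=cluster_alpha, n_perm=n_perm, statistic=statistic,
        seed=seed,
    )


@dataclass
class SinusoidalityResult:
    """Per phase frequency: mean rise (trough-to-peak) and decay
    (peak-to-trough) times in seconds and their ratio."""

    freqs: np.ndarray
    rise: np.ndarray
    decay: np.ndarray
    ratio: np.ndarray
    t_stats: np.ndarray | None = None  # filled by condition comparison
    p_values: np.ndarray | None = None


def _cycle_times(phase: np.ndarray, broadband: np.ndarray, fs: float):
    """Rise/decay intervals for one trial.

    Cycle landmarks come from the narrow-band phase (peak near phase 0,
    trough near the +/-pi wrap); the actual extrema are then located in the
    low-passed broadband copy within each half-cycle, because extrema of a
    narrow-band signal are sinusoidal by construction.
    """
    unwrapped = np.unwrap(phase)
    # nominal peak indices: upward crossings of 2*pi*k (phase == 0)
    k = np.floor(unwrapped / (2 * np.pi))
    peak_nom = np.flatnonzero(np.diff(k) > 0) + 1
    # nominal trough indices: crossings of pi + 2*pi*k
    m = np.floor((unwrapped - np.pi) / (2 * np.pi))
    trough_nom = np.flatnonzero(np.diff(m) > 0) + 1
    if peak_nom.size < 2 or trough_nom.size < 2:
        return np.empty(0), np.empty(0)
    # refine: trough = argmin of broadband between consecutive nominal peaks,
    # peak = argmax between consecutive nominal troughs
    peaks = np.array([t0 + np.argmax(broadband[t0:t1])
                      for t0, t1 in zip(trough_nom[:-1], trough_nom[1:])])
    troughs = np.array([p0 + np.argmin(broadband[p0:p1])
                        for p0, p1 in zip(peak_nom[:-1], peak_nom[1:])])
    rises, decays = [], []
    for pk in peaks:
        before = troughs[troughs < pk]
        after = troughs[troughs > pk]
        if before.size:
            rises.append((pk - before[-1]) / fs)
        if after.size:
            decays.append((after[0] - pk) / fs)
    return np.asarray(rises), np.asarray(decays)


def rise_decay_ratio(trials: TrialSeries, phase_freqs=None, trim: float = 0.5,
                     broadband_cutoff: float = 40.0) -> SinusoidalityResult:
    """Mean rise and decay times and their ratio per phase frequency.

    A ratio of 1 indicates a symmetric (sinusoidal) waveform; rising-
    sawtooth shapes give ratio > 1, falling sawtooths < 1.
    """
    if phase_freqs is None:
        phase_freqs = np.arange(7.0, 14.0)
    phase_freqs = np.asarray(phase_freqs, dtype=float)
    lowest = phase_freqs.min()
    n_trim = int(round(trim * trials.fs))
    usable = (trials.n_samples - 2 * n_trim) / trials.fs
    if usable < 3.0 / lowest:
        raise ValueError(
            f"trials provide {usable:g} s after trimming; need at least 3 "
            f"cycles ({3 / lowest:g} s) at {lowest:g} Hz"
        )
    sos = _sig.butter(4, broadband_cutoff, btype="lowpass", fs=trials.fs, output="sos")
    smooth = _sig.sosfiltfilt(sos, trials.data, axis=-1)
    smooth = smooth[:, n_trim:trials.n_samples - n_trim] if n_trim else smooth
    rise = np.empty(phase_freqs.size)
    decay = np.empty(phase_freqs.size)
    for i, f in enumerate(phase_freqs):
        ana = extract_analytic(trials, design_phase_band(f), trim=trim)
        all_r, all_d = [], []
        for tr in range(trials.n_trials):
            r, d = _cycle_times(ana.phase[tr], smooth[tr], trials.fs)
            all_r.append(r)
            all_d.append(d)
        rise[i] = np.concatenate(all_r).mean()
        decay[i] = np.concatenate(all_d).mean()
    return SinusoidalityResult(
        freqs=phase_freqs, rise=rise, decay=decay, ratio=rise / decay,
    )


@dataclass
class SinusoidalityComparison:
    """Per phase frequency: per-subject mean rise/decay ratios in each
    condition and a paired t comparing them."""

    freqs: np.ndarray
    ratio_a: np.ndarray        # (n_subjects, n_freqs)
    ratio_b: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray


def sinusoidality_comparison(cond_a: list[TrialSeries], cond_b: list[TrialSeries],
                             phase_freqs=None, trim: float = 0.5) -> SinusoidalityComparison:
    """Paired t per phase frequency on per-subject rise/decay ratios
    between two conditions (e.g. stimulus vs. baseline)."""
    if len(cond_a) != len(cond_b) or len(cond_a) < 2:
        raise ValueError("need matched per-subject trial sets, at least 2 subjects")
    if phase_freqs is None:
        phase_freqs = np.arange(7.0, 14.0)
    phase_freqs = np.asarray(phase_freqs, dtype=float)
    ratios_a = np.stack([rise_decay_ratio(ts, phase_freqs, trim=trim).ratio
                         for ts in cond_a])
    ratios_b = np.stack([rise_decay_ratio(ts, phase_freqs, trim=trim).ratio
                         for ts in cond_b])
    t_stats = np.empty(phase_freqs.size)
    p_values = np.empty(phase_freqs.size)
    for i in range(phase_freqs.size):
        res = paired_t(ratios_a[:, i], ratios_b[:, i])
        t_stats[i] = res.t
        p_values[i] = res.p
    return SinusoidalityComparison(
        freqs=phase_freqs, ratio_a=ratios_a, ratio_b=ratios_b,
        t_stats=t_stats, p_values=p_values,
    )
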
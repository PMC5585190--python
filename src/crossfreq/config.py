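"""Run configuration: one YAML file per run, archived next to the outputs.

The schema is strict — unknown keys raise a named :class:`ConfigError` —
and a config round-trips losslessly through YAML, so any published
artifact is reproducible from its logged config plus seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .comodulogram import GridSpec
from .exceptions import ConfigError
from .simulate import SimulationSpec

__all__ = ["RunConfig", "load_config", "save_config",
           "ACTIVE_WINDOW", "BASELINE_WINDOW"]

# Default event-relative analysis windows: the stimulus window starts
# 300 ms after onset (skipping the evoked transient) and the baseline is
# the 1.2 s ending 300 ms before onset.
ACTIVE_WINDOW = (0.3, 1.5)
BASELINE_WINDOW = (-1.5, -0.3)


@dataclass
class RunConfig:
    """Every tunable of the pipeline in one strict, serializable record."""

    seed: int | None = None
    outdir: str = "."
    verbosity: int = 1
    # grid / bandwidth rules
    phase_centers: list = field(default_factory=lambda: list(np.arange(7.0, 14.0)))
    amp_centers: list = field(default_factory=lambda: list(np.arange(34.0, 101.0, 2.0)))
    method: str = "kl_tort"
    amp_scale: float = 0.4
    phase_half_bw: float = 1.0
    n_bins: int = 18
    trim: float = 0.5
    analysis_window: list | None = None
    # surrogates & statistics
    n_surrogates: int = 200
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    alpha: float = 0.05
    cluster_statistic: str = "max_t"
    # simulator
    fs: float = 1000.0
    trial_len: float = 1.2
    n_trials: int = 64
    fp: float = 10.0
    amp_band: list = field(default_factory=lambda: [50.0, 70.0])
    coupling: float = 1.0
    snr_db: float | None = None
    gamma_rms: float = 0.5

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def to_dict(self) -> dict:
        out = asdict(self)
        for key, val in out.items():
            if isinstance(val, (list, tuple)):
                out[key] = [float(v) if isinstance(v, (int, float, np.floating))
                            else v for v in val]
        return out

    def grid_spec(self) -> GridSpec:
        window = tuple(self.analysis_window) if self.analysis_window else None
        return GridSpec(
            phase_centers=np.asarray(self.phase_centers, dtype=float),
            amp_centers=np.asarray(self.amp_centers, dtype=float),
            method=self.method, amp_scale=self.amp_scale,
            phase_half_bw=self.phase_half_bw, n_bins=self.n_bins,
            trim=self.trim, analysis_window=window,
        )

    def simulation_spec(self) -> SimulationSpec:
        return SimulationSpec(
            fs=self.fs, trial_len=self.trial_len, n_trials=self.n_trials,
            fp=self.fp, amp_band=tuple(self.amp_band), coupling=self.coupling,
            snr_db=self.snr_db, gamma_rms=self.gamma_rms, seed=self.seed,
        )


def load_config(path) -> RunConfig:
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML ({exc})") from None
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
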
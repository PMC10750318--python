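"""Seeded synthetic multichannel EEG with controlled second-order structure.

The generator emulates the geometry of a motor-execution EEG protocol
(16 electrodes, 125 Hz, 4-second trials, 5–50 Hz acquisition band,
124 trials per session with Rest interleaved after every task) and the
qualitative task structure the analysis targets: movement trials are
more variable than Rest on every electrode, and Rest shows elevated
amplitude on electrodes 14 and 15.

The model is deliberately minimal: each channel is zero-mean Gaussian
band-limited noise (the acquisition band) plus, for movement-related
tasks, an additional band-limited oscillatory "burst" component in a
narrower band.  Hjorth parameters are fully determined by second-order
spectral structure, which this model controls directly; no 1/f
background, artifacts or volume conduction are simulated.

Band-limiting uses a zero-phase forward-backward 4th-order Butterworth
filter, matching an acquisition-style bandpass without phase distortion.
Every trial draws from its own random substream derived from
``(seed, subject, task, trial_index)``, so any trial is reproducible
independently of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.signal import butter, sosfiltfilt

from .io import MOVEMENT_PROTOCOL_ORDER, TaskCode, Trial

__all__ = [
    "ElectrodeSpec",
    "SyntheticConfig",
    "default_config",
    "bandlimited_noise",
    "generate_trial",
    "generate_session",
    "default_schedule",
    "save_config",
    "load_config",
]


@dataclass(frozen=True)
class ElectrodeSpec:
    """Generative parameters for one electrode under one task.

    noise_sd : baseline band-limited noise amplitude, µV (> 0); the
        channel's full-band component is rescaled to exactly this sample SD.
    burst_sd : additional movement-related oscillatory amplitude, µV
        (>= 0; 0 for Rest-like tasks).
    burst_low, burst_high : burst band edges in Hz, inside the
        acquisition band.
    """

    noise_sd: float
    burst_sd: float = 0.0
    burst_low: float = 8.0
    burst_high: float = 30.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.burst_sd < 0:
            raise ValueError("burst_sd must be non-negative")
        if not self.burst_low < self.burst_high:
            raise ValueError("burst band must satisfy burst_low < burst_high")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full ground-truth description of a synthetic recording session."""

    seed: int
    sampling_rate: float = 125.0
    trial_duration: float = 4.0
    n_electrodes: int = 16
    band_low: float = 5.0
    band_high: float = 50.0
    task_specs: Mapping[TaskCode, tuple[ElectrodeSpec, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.sampling_rate * self.trial_duration
        if abs(n - round(n)) > 1e-9 or round(n) < 2:
            raise ValueError(
                "sampling_rate x trial_duration must be an integer number of samples >= 2"
            )
        if not (0 < self.band_low < self.band_high < self.sampling_rate / 2):
            raise ValueError("need 0 < band_low < band_high < sampling_rate / 2")
        for task, specs in self.task_specs.items():
            if len(specs) != self.n_electrodes:
                raise ValueError(
                    f"task {task} has {len(specs)} electrode specs, "
                    f"expected {self.n_electrodes}"
                )
            for i, spec in enumerate(specs, start=1):
                if spec.burst_sd > 0 and not (
                    self.band_low <= spec.burst_low < spec.burst_high <= self.band_high
                ):
                    raise ValueError(
                        f"task {task} electrode {i}: burst band "
                        f"[{spec.burst_low}, {spec.burst_high}] outside acquisition "
                        f"band [{self.band_low}, {self.band_high}]"
                    )

    @property
    def n_samples(self) -> int:
        return round(self.sampling_rate * self.trial_duration)

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


# Default amplitudes (µV).  Chosen so that every movement electrode's
# variance (8² + 12² = 208 µV²) exceeds the largest Rest variance
# (14² = 196 µV² on electrodes 14-15), giving the movement > Rest
# activity contrast on all electrodes, while windowed movement features
# stay in realistic EEG ranges (activity of order 10¹–10³ µV²,
# mobility ~1, complexity slightly above 1).
_REST_BASE_SD = 8.0
_REST_ELEVATED_SD = 14.0
_REST_ELEVATED_ELECTRODES = (14, 15)
_MOVEMENT_BURST_SD = 12.0
_MOVEMENT_EMPHASIS_SD = 18.0
_MOVEMENT_BAND = (8.0, 30.0)
_BEO_BURST_SD = 5.0
_BEO_BAND = (8.0, 13.0)  # alpha-like band for the eyes-open baseline

# Per-task electrode pairs with an emphasized burst, giving each movement
# task a distinct spatial signature (1-based electrode numbers).
_MOVEMENT_EMPHASIS: dict[TaskCode, tuple[int, int]] = {
    TaskCode.CLH: (9, 10),
    TaskCode.CRH: (7, 8),
    TaskCode.DLF: (3, 4),
    TaskCode.PLF: (5, 6),
    TaskCode.DRF: (1, 2),
    TaskCode.PRF: (11, 12),
}


def default_config(seed: int = 0, n_electrodes: int = 16) -> SyntheticConfig:
    """The shipped default generator configuration (see module docstring)."""
    specs: dict[TaskCode, tuple[ElectrodeSpec, ...]] = {}

    rest = []
    for e in range(1, n_electrodes + 1):
        sd = _REST_ELEVATED_SD if e in _REST_ELEVATED_ELECTRODES else _REST_BASE_SD
        rest.append(ElectrodeSpec(noise_sd=sd))
    specs[TaskCode.REST] = tuple(rest)

    specs[TaskCode.BEO] = tuple(
        ElectrodeSpec(
            noise_sd=_REST_BASE_SD,
            burst_sd=_BEO_BURST_SD,
            burst_low=_BEO_BAND[0],
            burst_high=_BEO_BAND[1],
        )
        for _ in range(n_electrodes)
    )

    for task, emphasis in _MOVEMENT_EMPHASIS.items():
        specs[task] = tuple(
            ElectrodeSpec(
                noise_sd=_REST_BASE_SD,
                burst_sd=_MOVEMENT_EMPHASIS_SD if e in emphasis else _MOVEMENT_BURST_SD,
                burst_low=_MOVEMENT_BAND[0],
                burst_high=_MOVEMENT_BAND[1],
            )
            for e in range(1, n_electrodes + 1)
        )

    return SyntheticConfig(seed=seed, n_electrodes=n_electrodes, task_specs=specs)


def bandlimited_noise(
    n_samples: int,
    sd: float,
    low: float,
    high: float,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean Gaussian noise band-limited to [low, high] Hz.

    White Gaussian noise is passed through a zero-phase 4th-order
    Butterworth bandpass, re-centred, and rescaled so its sample
    standard deviation equals ``sd`` exactly (to floating precision).
    Requires ``n_samples >= 8`` and ``0 < low < high < fs/2``; ``sd``
    must be positive (a zero-amplitude signal has undefined mobility).
    """
    if n_samples < 8:
        raise ValueError("n_samples must be at least 8")
    if not (0 < low < high < fs / 2):
        raise ValueError("need 0 < low < high < fs/2")
    if sd <= 0:
        raise ValueError("sd must be positive")

    sos = butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    signal = sosfiltfilt(sos, rng.standard_normal(n_samples))
    signal = signal - signal.mean()
    scale = signal.std()
    if scale == 0.0:  # pragma: no cover - essentially impossible for Gaussian input
        raise ValueError("filtered noise degenerated to a constant")
    return signal * (sd / scale)


def _task_ordinal(task: TaskCode) -> int:
    return list(TaskCode).index(TaskCode(task))


def trial_rng(
    seed: int, subject: str, task: TaskCode, trial_index: int
) -> np.random.Generator:
    """Per-trial random substream, stable under generation order.

    The stream key mixes the session seed with a CRC-32 of the subject
    identifier, the task ordinal and the trial index, so each trial is
    reproducible in isolation.
    """
    key = [
        int(seed),
        zlib.crc32(str(subject).encode("utf-8")),
        _task_ordinal(task),
        int(trial_index),
    ]
    return np.random.default_rng(np.random.SeedSequence(key))


def generate_trial(
    config: SyntheticConfig,
    task: TaskCode,
    subject: str = "S01",
    trial_index: int = 0,
    rng: np.random.Generator | None = None,
) -> Trial:
    """Generate one synthetic trial for ``task``.

    Each channel is ``bandlimited_noise(noise_sd)`` over the acquisition
    band plus, when ``burst_sd > 0``, an independent
    ``bandlimited_noise(burst_sd)`` over the electrode's burst band.
    Deterministic given ``(config.seed, subject, task, trial_index)``
    unless an explicit ``rng`` is supplied.
    """
    task = TaskCode(task)
    if task not in config.task_specs:
        raise ValueError(f"task {task} not present in config.task_specs")
    if rng is None:
        rng = trial_rng(config.seed, subject, task, trial_index)

    n = config.n_samples
    channels = []
    for spec in config.task_specs[task]:
        channel = bandlimited_noise(
            n, spec.noise_sd, config.band_low, config.band_high, config.sampling_rate, rng
        )
        if spec.burst_sd > 0:
            channel = channel + bandlimited_noise(
                n, spec.burst_sd, spec.burst_low, spec.burst_high, config.sampling_rate, rng
            )
        channels.append(channel)

    return Trial(
        data=np.vstack(channels),
        sampling_rate=config.sampling_rate,
        task=task,
        subject=str(subject),
        trial_index=trial_index,
    )


def default_schedule(n_trials: int = 124) -> list[TaskCode]:
    """The default session schedule: 62 (task, Rest) pairs.

    Non-Rest tasks cycle through the protocol order (BEO, CLH, CRH, DLF,
    PLF, DRF, PRF) and every task is immediately followed by a Rest
    trial, so even positions (0-based) hold tasks and odd positions hold
    Rest.  ``n_trials`` must be even.
    """
    if n_trials % 2 != 0 or n_trials < 2:
        raise ValueError("n_trials must be an even count >= 2")
    schedule: list[TaskCode] = []
    for pair in range(n_trials // 2):
        schedule.append(MOVEMENT_PROTOCOL_ORDER[pair % len(MOVEMENT_PROTOCOL_ORDER)])
        schedule.append(TaskCode.REST)
    return schedule


def generate_session(
    config: SyntheticConfig,
    subject: str = "S01",
    schedule: Sequence[TaskCode] | None = None,
) -> list[Trial]:
    """Generate a full session of trials (default: the 124-trial schedule).

    The trial index is the position within the session, so any single
    trial can be regenerated independently.
    """
    if schedule is None:
        schedule = default_schedule()
    return [
        generate_trial(config, task, subject=subject, trial_index=i)
        for i, task in enumerate(schedule)
    ]


def save_config(config: SyntheticConfig, path) -> None:
    """Serialize a config as YAML (flat scalars plus a per-task spec map)."""
    payload = {
        "seed": int(config.seed),
        "sampling_rate": float(config.sampling_rate),
        "trial_duration": float(config.trial_duration),
        "n_electrodes": int(config.n_electrodes),
        "band_low": float(config.band_low),
        "band_high": float(config.band_high),
        "task_specs": {
            TaskCode(task).value: [
                {
                    "noise_sd": spec.noise_sd,
                    "burst_sd": spec.burst_sd,
                    "burst_low": spec.burst_low,
                    "burst_high": spec.burst_high,
                }
                for spec in specs
            ]
            for task, specs in config.task_specs.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_config(path) -> SyntheticConfig:
    """Load a config written by :func:`save_config`; the seed is mandatory."""
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict) or "seed" not in payload:
        raise ValueError(f"{path}: config must be a mapping with a mandatory 'seed'")
    task_specs = {
        TaskCode(code): tuple(ElectrodeSpec(**spec) for spec in specs)
        for code, specs in payload.get("task_specs", {}).items()
    }
    return SyntheticConfig(
        seed=int(payload["seed"]),
        sampling_rate=float(payload.get("sampling_rate", 125.0)),
        trial_duration=float(payload.get("trial_duration", 4.0)),
        n_electrodes=int(payload.get("n_electrodes", 16)),
        band_low=float(payload.get("band_low", 5.0)),
        band_high=float(payload.get("band_high", 50.0)),
        task_specs=task_specs,
    )
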
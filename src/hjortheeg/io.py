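"""Per-trial CSV reading/writing and trial metadata.

One trial is a fixed-duration multichannel EEG segment (for the target
dataset geometry: 16 electrodes, 125 Hz, 4 s = 500 samples, microvolts)
stored as a plain CSV with one header row naming the electrodes
``E1..E16`` and one row per sample.  Values are written with Python's
shortest round-trip float representation, so write → read reproduces the
in-memory matrix to the last bit.

Task and subject metadata do not live in the CSV; they travel in a
manifest table (columns ``filename, subject, task``), because real
recordings encode them in dataset-specific filename schemes that a thin
manifest can adapt to.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TaskCode",
    "Trial",
    "FormatError",
    "write_trial_csv",
    "read_trial_csv",
    "load_session",
]


class TaskCode(str, enum.Enum):
    """The eight task labels of the motor-execution protocol."""

    BEO = "BEO"  # baseline, eyes open
    CLH = "CLH"  # closing left hand
    CRH = "CRH"  # closing right hand
    DLF = "DLF"  # dorsal flexion, left foot
    PLF = "PLF"  # plantar flexion, left foot
    DRF = "DRF"  # dorsal flexion, right foot
    PRF = "PRF"  # plantar flexion, right foot
    REST = "Rest"  # inter-task rest

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Table order of the seven non-Rest tasks, used by the default session schedule.
MOVEMENT_PROTOCOL_ORDER = (
    TaskCode.BEO,
    TaskCode.CLH,
    TaskCode.CRH,
    TaskCode.DLF,
    TaskCode.PLF,
    TaskCode.DRF,
    TaskCode.PRF,
)


class FormatError(ValueError):
    """A trial CSV or manifest does not conform to the expected dialect."""


@dataclass
class Trial:
    """One multichannel EEG segment in microvolts with its metadata.

    ``data`` has shape ``(n_electrodes, n_samples)``; row ``i`` is
    electrode ``i + 1`` (electrodes are numbered 1–16 to match common
    dataset prose).
    """

    data: np.ndarray
    sampling_rate: float
    task: TaskCode
    subject: str
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"trial data must be 2-D, got shape {self.data.shape}")
        if self.data.shape[1] < 2:
            raise ValueError("trial must contain at least 2 samples per electrode")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial data contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.task = TaskCode(self.task)

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def electrodes(self) -> range:
        """Electrode numbers, 1-based."""
        return range(1, self.n_electrodes + 1)


def _electrode_header(n_electrodes: int) -> list[str]:
    return [f"E{i}" for i in range(1, n_electrodes + 1)]


def write_trial_csv(trial: Trial, path) -> None:
    """Write one trial as CSV: header ``E1..En``, one row per sample.

    Floats use the shortest round-trip representation, so the file
    reproduces the binary matrix exactly on read-back.
    """
    frame = pd.DataFrame(trial.data.T, columns=_electrode_header(trial.n_electrodes))
    frame.to_csv(path, index=False)


def read_trial_csv(
    path,
    task: TaskCode,
    subject: str,
    sampling_rate: float,
    trial_index: int = 0,
    n_electrodes: int = 16,
) -> Trial:
    """Read a trial CSV written in the package dialect.

    The file must have exactly ``n_electrodes`` columns named
    ``E1..En`` in order; column ``Ek`` maps to electrode ``k``.  A
    wrong column count, an unexpected header, a missing value or a
    non-numeric cell raises :class:`FormatError` naming the offending
    row (1-based data row) and column.
    """
    path = Path(path)
    try:
        # round_trip parsing preserves the binary values bit-exactly
        numeric = pd.read_csv(
            path, header=0, skipinitialspace=True, float_precision="round_trip"
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise FormatError(f"{path}: not parseable as CSV: {exc}") from exc

    expected = _electrode_header(n_electrodes)
    if list(numeric.columns) != expected:
        raise FormatError(
            f"{path}: expected {n_electrodes} columns named "
            f"{expected[0]}..{expected[-1]}, got {len(numeric.columns)} columns "
            f"{list(numeric.columns)}"
        )
    if len(numeric) < 2:
        raise FormatError(f"{path}: trial must contain at least 2 sample rows")

    bad_dtype = [c for c in numeric.columns if numeric[c].dtype == object]
    if bad_dtype or numeric.isna().to_numpy().any():
        # re-read as text to name the first offending cell precisely
        raw = pd.read_csv(path, header=0, dtype=str, skipinitialspace=True)
        coerced = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
        row_idx, col_idx = np.argwhere(coerced.isna().to_numpy())[0]
        column = expected[col_idx]
        cell = raw.iat[row_idx, col_idx]
        what = "missing value" if pd.isna(cell) else f"non-numeric cell {cell!r}"
        raise FormatError(f"{path}: {what} at row {row_idx + 1}, column {column}")

    return Trial(
        data=numeric.to_numpy(dtype=np.float64).T,
        sampling_rate=sampling_rate,
        task=TaskCode(task),
        subject=str(subject),
        trial_index=trial_index,
    )


def load_session(
    directory,
    manifest,
    sampling_rate: float = 125.0,
    n_electrodes: int = 16,
) -> list[Trial]:
    """Load the trials listed in a manifest, in manifest order.

    ``manifest`` is a DataFrame or CSV path with columns
    ``filename, subject, task``; each filename is resolved relative to
    ``directory``.  The row position becomes the trial index.  A missing
    file raises ``FileNotFoundError`` naming it.
    """
    directory = Path(directory)
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, dtype=str)
    required = {"filename", "subject", "task"}
    if not required.issubset(manifest.columns):
        raise FormatError(
            f"manifest must have columns {sorted(required)}, got {list(manifest.columns)}"
        )

    trials: list[Trial] = []
    for position, row in enumerate(manifest.itertuples(index=False)):
        trial_path = directory / row.filename
        if not trial_path.exists():
            raise FileNotFoundError(f"manifest entry not found: {trial_path}")
        trials.append(
            read_trial_csv(
                trial_path,
                task=TaskCode(row.task),
                subject=str(row.subject),
                sampling_rate=sampling_rate,
                trial_index=position,
                n_electrodes=n_electrodes,
            )
        )
    return trials
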
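"""Readers, writers and validators for the trial dataset format.

Each experimental trial is stored as a pair of files:

* a CSV matrix with one row per sample and, in order, the time in seconds,
  27 EEG channels in microvolts, 4 EOG channels in microvolts, and an
  integer task label;
* a JSON sidecar describing the acquisition (sampling rate, channel counts,
  reference/ground placement, the task-label code map, and the hardware
  preprocessing filters).

A recording session is a folder of such pairs named
``subject_SS_cond_CC_run_RR.csv/.json`` plus a free-text ``CONDITIONS.txt``
describing the condition numbering.  Two scenarios exist: *experience*
(flat-ground exoskeleton walking: two 4-minute baselines plus sixteen
mental-task trials) and *slopes* (ramp walking: eight conditions crossed
with ascending/descending runs).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    FormatError,
    LayoutError,
    LayoutWarning,
    MetadataError,
)

#: EEG montage (10-10 system subset) in recorded column order.
EEG_CHANNELS: tuple[str, ...] = (
    "F3", "FZ", "FC1", "FCZ", "C1", "CZ", "CP1", "CPZ", "FC5", "FC3",
    "C5", "C3", "CP5", "CP3", "P3", "PZ", "F4", "FC2", "FC4", "FC6",
    "C2", "C4", "CP2", "CP4", "C6", "CP6", "P4",
)
#: Bipolar EOG channels (vertical up/down, horizontal right/left).
EOG_CHANNELS: tuple[str, ...] = ("VU", "VD", "HR", "HL")

N_EEG = len(EEG_CHANNELS)
N_EOG = len(EOG_CHANNELS)
N_CSV_COLUMNS = 1 + N_EEG + N_EOG + 1

#: Equipment synchronization periods carry label 0 and are excluded from analysis.
SYNC_CODE = 0

# Default task-label code maps.  The flat-ground scenario uses one map; the
# ramp scenario uses different codes for ascending and descending runs.  The
# maps are configurable per dataset because recorded archives may deviate.
EXPERIENCE_TASK_LABELS: dict[int, str] = {0: "sync", 402: "relax", 404: "mi", 406: "count"}
SLOPES_ASCENDING_TASK_LABELS: dict[int, str] = {0: "sync", 402: "relax", 752: "mi", 756: "count"}
SLOPES_DESCENDING_TASK_LABELS: dict[int, str] = {0: "sync", 402: "relax", 754: "mi", 758: "count"}

SCENARIOS = ("experience", "slopes")

_TIME_STEP_TOL = 1e-9  # seconds

_REQUIRED_META_FIELDS = (
    "file_name",
    "acquisition_system",
    "sampling_rate",
    "n_eeg_channels",
    "n_eog_channels",
    "voltage_units",
    "reference",
    "ground",
    "task_labels",
    "preprocessing_filters",
)


@dataclass
class TrialMeta:
    """JSON sidecar contents for one trial.

    ``task_labels`` maps integer label codes to canonical task names
    (``sync``, ``relax``, ``mi``, ``count``).  Unknown extra sidecar fields
    are preserved in ``extra`` for forward compatibility.
    """

    file_name: str
    acquisition_system: str
    sampling_rate: float
    n_eeg_channels: int
    n_eog_channels: int
    voltage_units: str
    reference: str
    ground: str
    task_labels: dict[int, str]
    preprocessing_filters: dict[str, float]
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise MetadataError(f"sampling_rate must be positive, got {self.sampling_rate}")

    @classmethod
    def from_json(cls, path: str | Path) -> "TrialMeta":
        path = Path(path)
        if not path.exists():
            raise MetadataError(f"sidecar not found: {path}")
        payload = json.loads(path.read_text(encoding="utf-8"))
        for name in _REQUIRED_META_FIELDS:
            if name not in payload:
                raise MetadataError(f"{path.name}: missing required field {name!r}")
        known = {k: payload[k] for k in _REQUIRED_META_FIELDS}
        known["task_labels"] = {int(code): str(name) for code, name in known["task_labels"].items()}
        extra = {k: v for k, v in payload.items() if k not in _REQUIRED_META_FIELDS}
        return cls(**known, extra=extra)

    def to_dict(self) -> dict:
        out = {
            "file_name": self.file_name,
            "acquisition_system": self.acquisition_system,
            "sampling_rate": self.sampling_rate,
            "n_eeg_channels": self.n_eeg_channels,
            "n_eog_channels": self.n_eog_channels,
            "voltage_units": self.voltage_units,
            "reference": self.reference,
            "ground": self.ground,
            "task_labels": {str(code): name for code, name in self.task_labels.items()},
            "preprocessing_filters": self.preprocessing_filters,
        }
        out.update(self.extra)
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")


@dataclass
class Recording:
    """One trial: time base, EEG/EOG matrices in microvolts, label stream."""

    time: np.ndarray           # (n,) seconds, uniform
    eeg: np.ndarray            # (n, 27) microvolts
    eog: np.ndarray            # (n, 4) microvolts
    labels: np.ndarray         # (n,) integer task codes
    channel_names: tuple[str, ...] = EEG_CHANNELS + EOG_CHANNELS

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def sampling_rate(self) -> float:
        if self.n_samples < 2:
            raise FormatError("cannot infer a sampling rate from fewer than 2 samples")
        return 1.0 / float(np.mean(np.diff(self.time)))

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def validate(self, meta: TrialMeta | None = None) -> None:
        """Check the structural invariants, raising on violation."""
        n = self.n_samples
        if self.eeg.shape != (n, N_EEG):
            raise FormatError(f"eeg must have shape ({n}, {N_EEG}), got {self.eeg.shape}")
        if self.eog.shape != (n, N_EOG):
            raise FormatError(f"eog must have shape ({n}, {N_EOG}), got {self.eog.shape}")
        if self.labels.shape != (n,):
            raise FormatError(f"labels must have shape ({n},), got {self.labels.shape}")
        diffs = np.diff(self.time)
        if len(diffs) and (np.max(diffs) - np.min(diffs)) > _TIME_STEP_TOL:
            raise FormatError("time column is not uniformly sampled")
        if len(diffs) and np.min(diffs) <= 0:
            raise FormatError("time column is not strictly increasing")
        if meta is not None:
            if meta.n_eeg_channels != N_EEG:
                raise MetadataError(
                    f"sidecar declares {meta.n_eeg_channels} EEG channels, format requires {N_EEG}"
                )
            if meta.n_eog_channels != N_EOG:
                raise MetadataError(
                    f"sidecar declares {meta.n_eog_channels} EOG channels, format requires {N_EOG}"
                )
            if len(diffs) and abs(np.mean(diffs) - 1.0 / meta.sampling_rate) > _TIME_STEP_TOL:
                raise ConsistencyError(
                    f"time step {np.mean(diffs):.9f} s disagrees with sidecar "
                    f"sampling rate {meta.sampling_rate} Hz"
                )
            unknown = set(np.unique(self.labels).tolist()) - set(meta.task_labels)
            if unknown:
                raise MetadataError(
                    f"label code(s) {sorted(unknown)} not declared in sidecar task_labels"
                )


def read_trial(csv_path: str | Path, json_path: str | Path) -> tuple[Recording, TrialMeta]:
    """Parse one trial CSV and its JSON sidecar.

    The label stream and channel order are preserved exactly.  Raises
    :class:`FormatError` for a malformed CSV (naming the offending row),
    :class:`MetadataError` for a deficient sidecar, and
    :class:`ConsistencyError` when the time column contradicts the declared
    sampling rate.
    """
    csv_path, json_path = Path(csv_path), Path(json_path)
    if not csv_path.exists():
        raise FormatError(f"trial CSV not found: {csv_path}")
    meta = TrialMeta.from_json(json_path)

    df = pd.read_csv(csv_path)
    if df.shape[1] != N_CSV_COLUMNS:
        raise FormatError(
            f"{csv_path.name}: expected {N_CSV_COLUMNS} columns "
            f"(time + {N_EEG} EEG + {N_EOG} EOG + label), found {df.shape[1]}"
        )
    for name in df.columns:
        col = df[name]
        if col.dtype == object:
            numeric = pd.to_numeric(col, errors="coerce")
            bad = int(numeric.isna().idxmax())
            raise FormatError(
                f"{csv_path.name}: non-numeric value {col.iloc[bad]!r} "
                f"in column {name!r} at data row {bad}"
            )
        if col.isna().any():
            bad = int(col.isna().idxmax())
            raise FormatError(f"{csv_path.name}: missing value in column {name!r} at data row {bad}")

    values = df.to_numpy()
    labels = values[:, -1]
    if not np.allclose(labels, np.round(labels)):
        bad = int(np.flatnonzero(labels != np.round(labels))[0])
        raise FormatError(f"{csv_path.name}: non-integer label at data row {bad}")
    names = tuple(str(c) for c in df.columns[1:-1])
    recording = Recording(
        time=np.ascontiguousarray(values[:, 0]),
        eeg=np.ascontiguousarray(values[:, 1 : 1 + N_EEG]),
        eog=np.ascontiguousarray(values[:, 1 + N_EEG : 1 + N_EEG + N_EOG]),
        labels=labels.astype(np.int64),
        channel_names=names if len(names) == N_EEG + N_EOG else EEG_CHANNELS + EOG_CHANNELS,
    )
    recording.validate(meta)
    return recording, meta


def write_trial(
    recording: Recording,
    meta: TrialMeta,
    out_dir: str | Path,
    stem: str | None = None,
) -> tuple[Path, Path]:
    """Write one trial as CSV + JSON sidecar; returns the two paths.

    Numeric text uses Python's shortest round-trip float formatting, so a
    subsequent :func:`read_trial` reproduces the matrices bit-exactly.
    """
    recording.validate(meta)
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise LayoutError(f"output directory does not exist: {out_dir}")
    if stem is None:
        stem = Path(meta.file_name).stem
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.json"

    columns = {"time": recording.time}
    for j, name in enumerate(recording.channel_names[:N_EEG]):
        columns[name] = recording.eeg[:, j]
    for j, name in enumerate(recording.channel_names[N_EEG:]):
        columns[name] = recording.eog[:, j]
    columns["label"] = recording.labels
    pd.DataFrame(columns).to_csv(csv_path, index=False)
    meta.to_json(json_path)
    return csv_path, json_path


@dataclass(frozen=True)
class TrialRef:
    """One discovered (condition, run) trial within a session folder."""

    condition: int
    run: int
    csv_path: Path
    json_path: Path


@dataclass
class DatasetLayout:
    """A scanned recording session: scenario, subject and trial file pairs."""

    scenario: str
    subject_id: str
    trials: list[TrialRef]
    session_date: str | None = None
    conditions_text: str | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def select(self, condition: int | None = None) -> list[TrialRef]:
        return [t for t in self.trials if condition is None or t.condition == condition]


_TRIAL_NAME = re.compile(r"^(?:subject[_-]?(\d+)[_-])?cond[_-]?(\d+)[_-]run[_-]?(\d+)\.csv$", re.I)
_DATE_DIR = re.compile(r"^\d{4}[-_.]?\d{2}[-_.]?\d{2}$")


def scan_dataset(root: str | Path, scenario: str) -> DatasetLayout:
    """Discover the trial file pairs of one session folder.

    ``root`` may be the CSV folder itself or a parent containing a date or
    ``CSV`` subfolder; the scan is recursive.  Orphan CSVs (no sidecar) and
    stray files are recorded as layout warnings, never errors.
    """
    root = Path(root)
    if scenario not in SCENARIOS:
        raise LayoutError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if not root.is_dir():
        raise LayoutError(f"dataset root does not exist: {root}")

    trials: list[TrialRef] = []
    notes: list[str] = []
    subject_id = ""
    session_date = None
    conditions_text = None

    for path in sorted(root.rglob("*")):
        if path.is_dir():
            if _DATE_DIR.match(path.name):
                session_date = path.name
            continue
        if path.name.upper() == "CONDITIONS.TXT":
            conditions_text = path.read_text(encoding="utf-8")
            continue
        if path.suffix.lower() == ".json":
            continue  # paired below
        match = _TRIAL_NAME.match(path.name)
        if match is None:
            notes.append(f"ignored unrelated file: {path.name}")
            continue
        subj, cond, run = match.groups()
        if subj:
            subject_id = f"subject_{int(subj):02d}"
        json_path = path.with_suffix(".json")
        if not json_path.exists():
            notes.append(f"orphan CSV without sidecar: {path.name}")
            continue
        trials.append(TrialRef(int(cond), int(run), path, json_path))

    seen: set[tuple[int, int]] = set()
    for t in trials:
        key = (t.condition, t.run)
        if key in seen:
            raise LayoutError(f"duplicate condition/run pair cond_{t.condition:02d}_run_{t.run:02d}")
        seen.add(key)
    trials.sort(key=lambda t: (t.condition, t.run))

    for note in notes:
        warnings.warn(note, LayoutWarning, stacklevel=2)
    return DatasetLayout(
        scenario=scenario,
        subject_id=subject_id or root.name,
        trials=trials,
        session_date=session_date,
        conditions_text=conditions_text,
        warnings=notes,
    )


def slopes_condition_semantics(condition: int, run: int) -> tuple[int, str, str]:
    """Decode a slopes (condition, run) pair to (inclination deg, task, direction).

    Odd conditions are motor-imagery trials and even conditions regressive
    count; the inclination grows one degree per condition pair; run 1 walks
    up the ramp and run 2 down.
    """
    if not 1 <= condition <= 8:
        raise ValueError(f"slopes condition must be in 1..8, got {condition}")
    if run not in (1, 2):
        raise ValueError(f"slopes run must be 1 or 2, got {run}")
    inclination = (condition + 1) // 2
    task = "mi" if condition % 2 == 1 else "count"
    direction = "ascending" if run == 1 else "descending"
    return inclination, task, direction


@dataclass
class ValidationReport:
    """Outcome of a full dataset validation pass."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def summary(self) -> str:
        lines = [f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)"]
        lines += [f"ERROR: {e}" for e in self.errors]
        lines += [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines)


def validate_dataset(root: str | Path, scenario: str) -> ValidationReport:
    """Scan a session folder and check every trial against the format contract."""
    report = ValidationReport()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", LayoutWarning)
            layout = scan_dataset(root, scenario)
    except LayoutError as exc:
        report.errors.append(str(exc))
        return report
    report.warnings.extend(layout.warnings)
    if not layout.trials:
        report.warnings.append("empty dataset: no trial pairs found")
    for ref in layout.trials:
        try:
            read_trial(ref.csv_path, ref.json_path)
        except (FormatError, MetadataError, ConsistencyError) as exc:
            report.errors.append(str(exc))
    return report
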
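"""Turn per-sample label streams into effective analysis windows.

Each trial's label column encodes the task sequence.  Analysis never uses a
task period whole: the first seconds after each task cue are discarded to
skip filter convergence, movement transitions and instruction-evoked
potentials.  The remaining span is an *effective analysis window*, which is
what classifiers train on and what the area-ratio metric scores.

Flat-ground (*experience*) trials follow a fixed timeline — 15 s relax,
24 s motor imagery, 22 s regressive count, 14 s relax — with printed
neglect times of 5/4/2/4 s, leaving 10/20/20/10 s of effective signal.
Ramp (*slopes*) trials have one variable-length active period bracketed by
static rests, with a configurable post-cue neglect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ProtocolError, ProtocolWarning, TaskMappingError
from .io import SYNC_CODE, TrialMeta

#: Experience timeline: (task name, nominal duration s, neglect-at-start s).
EXPERIENCE_SEQUENCE: tuple[tuple[str, float, float], ...] = (
    ("relax", 15.0, 5.0),
    ("mi", 24.0, 4.0),
    ("count", 22.0, 2.0),
    ("relax", 14.0, 4.0),
)

#: Target maps per paradigm.  The motor-imagery paradigm is a two-class
#: problem (relax vs MI) and drops count periods entirely; the attention
#: paradigm scores every task, with MI the only high-attention class.
MI_TARGETS: dict[str, int | None] = {"relax": 0, "mi": 1, "count": None}
ATT_TARGETS: dict[str, int | None] = {"relax": 0, "mi": 1, "count": 0}

PARADIGMS = ("mi", "att")


@dataclass(frozen=True)
class TaskEvent:
    """A maximal run of one constant label: [start, end) in samples."""

    code: int
    name: str
    start: int
    end: int

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnalysisWindow:
    """A labeled effective-analysis period in trial time (seconds)."""

    task: str
    start: float
    end: float
    target: int | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class ProtocolSpec:
    """Scenario timing rules: nominal durations and neglect times.

    ``slopes_neglect_start`` is applied after the staff-marked cue that
    opens the active (ramp) period; rests around it get
    ``slopes_rest_neglect_start``.  End-neglects default to zero because
    the closing cue is itself placed before the ramp ends.
    """

    scenario: str = "experience"
    sequence: tuple[tuple[str, float, float], ...] = EXPERIENCE_SEQUENCE
    slopes_neglect_start: float = 2.0
    slopes_neglect_end: float = 0.0
    slopes_rest_neglect_start: float = 2.0
    slopes_rest_neglect_end: float = 0.0

    def __post_init__(self) -> None:
        for task, nominal, neglect in self.sequence:
            if neglect >= nominal:
                raise ProtocolError(
                    f"neglect {neglect} s must be shorter than the nominal "
                    f"{nominal} s duration of task {task!r}"
                )


def extract_events(labels: np.ndarray, meta: TrialMeta) -> list[TaskEvent]:
    """Segment a per-sample label stream into ordered task events.

    One event per maximal run of a constant label; events tile the trial.
    Sync periods (label 0) become events named ``sync`` that downstream
    windowing excludes.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ProtocolError("cannot extract events from an empty label stream")
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [labels.size]))
    events = []
    for s, e in zip(starts, ends):
        code = int(labels[s])
        name = meta.task_labels.get(code)
        if name is None:
            name = "sync" if code == SYNC_CODE else f"unknown_{code}"
        events.append(TaskEvent(code=code, name=name, start=int(s), end=int(e)))
    return events


def _window_from_event(
    event: TaskEvent,
    neglect_start: float,
    neglect_end: float,
    sampling_rate: float,
) -> AnalysisWindow | None:
    start = event.start / sampling_rate + neglect_start
    end = event.end / sampling_rate - neglect_end
    if end - start <= 0:
        warnings.warn(
            f"{event.name} event of {event.n_samples / sampling_rate:.2f} s leaves no "
            f"effective time after neglect; window dropped",
            ProtocolWarning,
            stacklevel=3,
        )
        return None
    return AnalysisWindow(task=event.name, start=start, end=end)


def experience_windows(
    events: list[TaskEvent],
    spec: ProtocolSpec,
    sampling_rate: float,
) -> list[AnalysisWindow]:
    """Apply the flat-ground neglect rules to an event sequence.

    Expects the relax → MI → count → relax pattern after any sync lead-in.
    A truncated recording (operator stopped early) yields fewer windows and
    a warning rather than an error; a reordered one raises
    :class:`ProtocolError` naming the deviation.
    """
    tasks = [e for e in events if e.name != "sync"]
    expected = [name for name, _, _ in spec.sequence]
    if len(tasks) > len(expected):
        raise ProtocolError(
            f"expected at most {len(expected)} task events {expected}, got {len(tasks)}"
        )
    for i, (event, name) in enumerate(zip(tasks, expected)):
        if event.name != name:
            raise ProtocolError(f"task event {i + 1} is {event.name!r}, expected {name!r}")
    if len(tasks) < len(expected):
        warnings.warn(
            f"trial truncated: {len(tasks)} of {len(expected)} task events present",
            ProtocolWarning,
            stacklevel=2,
        )
    windows = []
    for event, (_, _nominal, neglect) in zip(tasks, spec.sequence):
        w = _window_from_event(event, neglect, 0.0, sampling_rate)
        if w is not None:
            windows.append(w)
    return windows


def slopes_windows(
    events: list[TaskEvent],
    spec: ProtocolSpec,
    sampling_rate: float,
) -> list[AnalysisWindow]:
    """Apply the ramp-scenario neglect rules to an event sequence.

    The trial must contain exactly one active period (MI or count);
    durations are data-driven.  Rest periods become relax windows.
    """
    tasks = [e for e in events if e.name != "sync"]
    active = [e for e in tasks if e.name in ("mi", "count")]
    if not active:
        raise ProtocolError("no active (mi/count) event found in slopes trial")
    if len(active) > 1:
        raise ProtocolError(f"slopes trial must have one active event, found {len(active)}")
    windows = []
    for event in tasks:
        if event.name in ("mi", "count"):
            w = _window_from_event(
                event, spec.slopes_neglect_start, spec.slopes_neglect_end, sampling_rate
            )
        else:
            w = _window_from_event(
                event, spec.slopes_rest_neglect_start, spec.slopes_rest_neglect_end, sampling_rate
            )
        if w is not None:
            windows.append(w)
    return windows


def assign_targets(windows: list[AnalysisWindow], paradigm: str) -> list[AnalysisWindow]:
    """Attach 0/1 targets to windows for one paradigm, dropping excluded tasks.

    MI paradigm: relax → 0, MI → 1, count removed.  Attention paradigm:
    relax → 0, count → 0, MI → 1.
    """
    if paradigm not in PARADIGMS:
        raise TaskMappingError(f"unknown paradigm {paradigm!r}; expected one of {PARADIGMS}")
    mapping = MI_TARGETS if paradigm == "mi" else ATT_TARGETS
    out = []
    for w in windows:
        if w.task not in mapping:
            raise TaskMappingError(f"task {w.task!r} has no target under paradigm {paradigm!r}")
        target = mapping[w.task]
        if target is None:
            continue
        out.append(AnalysisWindow(task=w.task, start=w.start, end=w.end, target=target))
    return out
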
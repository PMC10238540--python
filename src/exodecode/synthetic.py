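"""Protocol-structured synthetic EEG sessions in the exact dataset format.

The generator emulates the statistical contrasts the decoding pipeline
assumes, so every stage is testable without the recorded archive:

* 1/f (pink) background noise per channel, at EEG-like amplitudes;
* band-limited alpha and beta sources over the central sensorimotor
  channels whose amplitude is multiplied by the *ERD factor* during motor
  imagery (event-related desynchronization: a factor below 1 suppresses
  the rhythms during imagery);
* band-limited gamma sources over central/parietal channels whose
  amplitude is multiplied by the *attention factor* during motor imagery
  relative to the distracted count (attended gait raises gamma power);
* blink transients on the EOG channels leaking into frontal EEG with
  decaying gains;
* the hardware preprocessing of the real recordings (0.1 Hz high-pass and
  50 Hz notch), and a 5 s equipment-sync lead-in carrying label 0.

Effects are amplitude modulations of spatially mixed narrowband sources —
not feature-space injections — so CSP has a genuine spatial pattern to
find.  The output is a pure function of the configuration: the same seed
produces byte-identical files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.signal

from .errors import ConfigError
from .io import (
    EEG_CHANNELS,
    EOG_CHANNELS,
    EXPERIENCE_TASK_LABELS,
    N_EEG,
    N_EOG,
    SLOPES_ASCENDING_TASK_LABELS,
    SLOPES_DESCENDING_TASK_LABELS,
    DatasetLayout,
    Recording,
    TrialMeta,
    scan_dataset,
    write_trial,
)

#: Experience mental-task trial timeline: (task, seconds).  A 5 s sync
#: lead-in precedes the 15/24/22/14 s relax/MI/count/relax sequence.
EXPERIENCE_TRIAL_PLAN: tuple[tuple[str, float], ...] = (
    ("sync", 5.0),
    ("relax", 15.0),
    ("mi", 24.0),
    ("count", 22.0),
    ("relax", 14.0),
)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic session.

    ``erd_factor`` multiplies the alpha/beta source amplitude during MI
    samples (0.6 by default: a clear desynchronization); ``gamma_factor``
    multiplies the gamma source amplitude during MI relative to count and
    relax (1.6: attended gait).  A factor of 1.0 means a null effect.
    """

    seed: int = 0
    scenario: str = "experience"
    sampling_rate: float = 200.0
    n_trials: int = 16
    subject: int = 1
    erd_factor: float = 0.6
    gamma_factor: float = 1.6
    noise_amplitude: float = 10.0      # pink-noise rms per channel, microvolts
    alpha_amplitude: float = 6.0       # microvolts rms at topography peak
    beta_amplitude: float = 4.0
    gamma_amplitude: float = 3.0
    eog_noise_amplitude: float = 3.0
    blink_rate: float = 10.0           # blinks per minute
    blink_amplitude: float = 150.0     # microvolts on the vertical EOG pair
    lead_in: float = 5.0               # sync period, seconds
    baseline_duration: float = 240.0
    slopes_rest_duration: float = 10.0
    slopes_active_range: tuple[float, float] = (8.0, 14.0)
    label_codes: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            "experience": {name: code for code, name in EXPERIENCE_TASK_LABELS.items()},
            "ascending": {name: code for code, name in SLOPES_ASCENDING_TASK_LABELS.items()},
            "descending": {name: code for code, name in SLOPES_DESCENDING_TASK_LABELS.items()},
        }
    )

    def __post_init__(self) -> None:
        if self.erd_factor <= 0 or self.gamma_factor <= 0:
            raise ConfigError("effect factors must be positive (1.0 = null effect)")
        if self.scenario not in ("experience", "slopes"):
            raise ConfigError(f"unknown scenario {self.scenario!r}")


# --- channel geometry -----------------------------------------------------

_NAME_RE = re.compile(r"^([A-Z]+?)(Z|\d)$")
_ROW_Y = {"F": 2.0, "FC": 1.0, "C": 0.0, "CP": -1.0, "P": -2.0}


def _channel_position(name: str) -> tuple[float, float]:
    match = _NAME_RE.match(name)
    if match is None:
        raise ConfigError(f"cannot place channel {name!r}")
    row, col = match.groups()
    y = _ROW_Y[row]
    if col == "Z":
        x = 0.0
    else:
        digit = int(col)
        x = ((digit + 1) // 2) * (-1.0 if digit % 2 == 1 else 1.0)
    return x, y


_POSITIONS = np.array([_channel_position(name) for name in EEG_CHANNELS])


def _topography(center: tuple[float, float], sigma: float) -> np.ndarray:
    d2 = np.sum((_POSITIONS - np.asarray(center)) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * sigma**2))


# (band Hz, amplitude attr, center, sigma, modulation) — the source recipe.
_SOURCES = (
    ((8.0, 12.0), "alpha_amplitude", (0.0, 0.0), 1.5, "erd"),
    ((16.0, 26.0), "beta_amplitude", (-1.5, 0.0), 1.5, "erd"),
    ((16.0, 26.0), "beta_amplitude", (1.5, 0.0), 1.5, "erd"),
    ((30.0, 70.0), "gamma_amplitude", (0.0, -0.5), 1.5, "att"),
    ((30.0, 70.0), "gamma_amplitude", (0.0, -2.0), 1.5, "att"),
)

#: Blink leakage gain into EEG rows (frontal strongest, fading backwards).
_BLINK_LEAK = {"F": 0.12, "FC": 0.06, "C": 0.02, "CP": 0.0, "P": 0.0}


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-rms 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0
    shaped = np.fft.irfft(spectrum * scale, n)
    return shaped / np.std(shaped)


def _band_noise(rng: np.random.Generator, n: int, band: tuple[float, float], fs: float) -> np.ndarray:
    sos = scipy.signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    source = scipy.signal.sosfilt(sos, rng.standard_normal(n))
    return source / np.std(source)


def _blink_waveform(fs: float) -> np.ndarray:
    n = int(round(0.3 * fs))
    return np.hanning(n) ** 2


def _hardware_filters(data: np.ndarray, fs: float) -> np.ndarray:
    """Causal 0.1 Hz high-pass + 50 Hz notch, as applied by the amplifier."""
    sos_hp = scipy.signal.butter(2, 0.1, btype="highpass", fs=fs, output="sos")
    out = scipy.signal.sosfilt(sos_hp, data, axis=0)
    b, a = scipy.signal.iirnotch(50.0, 30.0, fs=fs)
    return scipy.signal.lfilter(b, a, out, axis=0)


def _task_code_map(config: SyntheticConfig, direction: str | None) -> dict[str, int]:
    key = config.scenario if config.scenario == "experience" else direction
    try:
        return config.label_codes[key]
    except KeyError:
        raise ConfigError(f"no label code map for {key!r}") from None


def generate_trial(
    config: SyntheticConfig,
    plan: tuple[tuple[str, float], ...],
    rng: np.random.Generator,
    direction: str | None = None,
    file_name: str = "synthetic_trial.csv",
) -> tuple[Recording, TrialMeta]:
    """Synthesize one labeled trial following ``plan`` (task, seconds) pairs."""
    fs = config.sampling_rate
    code_map = _task_code_map(config, direction)

    segments = [(name, int(round(duration * fs))) for name, duration in plan]
    n = sum(count for _, count in segments)
    labels = np.concatenate(
        [np.full(count, code_map[name], dtype=np.int64) for name, count in segments]
    )
    is_mi = np.concatenate(
        [np.full(count, name == "mi") for name, count in segments]
    )

    erd_env = np.where(is_mi, config.erd_factor, 1.0)
    att_env = np.where(is_mi, config.gamma_factor, 1.0)

    eeg = np.zeros((n, N_EEG))
    for band, amp_attr, center, sigma, modulation in _SOURCES:
        source = _band_noise(rng, n, band, fs) * getattr(config, amp_attr)
        env = erd_env if modulation == "erd" else att_env
        eeg += np.outer(source * env, _topography(center, sigma))
    for ch in range(N_EEG):
        eeg[:, ch] += config.noise_amplitude * _pink_noise(rng, n)

    eog = np.zeros((n, N_EOG))
    for ch in range(N_EOG):
        eog[:, ch] += config.eog_noise_amplitude * _pink_noise(rng, n)
    waveform = _blink_waveform(fs)
    n_blinks = rng.poisson(config.blink_rate * n / fs / 60.0)
    blink_train = np.zeros(n)
    for start in np.sort(rng.integers(0, max(n - len(waveform), 1), size=n_blinks)):
        blink_train[start : start + len(waveform)] += waveform[: n - start]
    eog[:, 0] += config.blink_amplitude * blink_train        # VU
    eog[:, 1] += -0.8 * config.blink_amplitude * blink_train  # VD
    eog[:, 2] += 0.05 * config.blink_amplitude * blink_train  # HR
    eog[:, 3] += 0.05 * config.blink_amplitude * blink_train  # HL
    leak = np.array(
        [_BLINK_LEAK[_NAME_RE.match(name).group(1)] for name in EEG_CHANNELS]
    )
    eeg += np.outer(config.blink_amplitude * blink_train, leak)

    eeg = _hardware_filters(eeg, fs)
    eog = _hardware_filters(eog, fs)

    recording = Recording(
        time=np.arange(n) / fs,
        eeg=eeg,
        eog=eog,
        labels=labels,
    )
    meta = TrialMeta(
        file_name=file_name,
        acquisition_system="synthetic (exodecode generator)",
        sampling_rate=fs,
        n_eeg_channels=N_EEG,
        n_eog_channels=N_EOG,
        voltage_units="uV",
        reference="A1",
        ground="A2",
        task_labels={code: name for name, code in code_map.items()},
        preprocessing_filters={"highpass_hz": 0.1, "notch_hz": 50.0},
        extra={"synthetic": True, "scenario": config.scenario},
    )
    return recording, meta


def _experience_trials(config: SyntheticConfig):
    yield 1, 1, (("sync", config.lead_in), ("relax", config.baseline_duration)), None
    yield 2, 1, (("sync", config.lead_in), ("relax", config.baseline_duration)), None
    plan = (("sync", config.lead_in),) + EXPERIENCE_TRIAL_PLAN[1:]
    for run in range(1, config.n_trials + 1):
        yield 3, run, plan, None


def _slopes_trials(config: SyntheticConfig, rng: np.random.Generator):
    low, high = config.slopes_active_range
    for condition in range(1, 9):
        task = "mi" if condition % 2 == 1 else "count"
        for run in (1, 2):
            direction = "ascending" if run == 1 else "descending"
            active = float(rng.uniform(low, high))
            plan = (
                ("sync", config.lead_in),
                ("relax", config.slopes_rest_duration),
                (task, active),
                ("relax", config.slopes_rest_duration),
            )
            yield condition, run, plan, direction


_CONDITIONS_TEXT = {
    "experience": (
        "cond_01_run_01: 4 minutes of EEG register with the subject sitting"
        " without the exoskeleton.\n"
        "cond_02_run_01: 4 minutes of EEG register with the subject standing"
        " wearing the exoskeleton.\n"
        "cond_03_run_01:16: 16 trials of EEG register with the subject standing"
        " and walking wearing the exoskeleton, performing mental tasks\n"
        " (relax / motor imagery / regressive count / relax).\n"
    ),
    "slopes": (
        "Conditions 01-08: ramp inclination grows one degree per condition pair"
        " (cond 01-02 -> 1 degree ... cond 07-08 -> 4 degrees).\n"
        "Odd conditions: motor imagery during the ramp; even conditions:"
        " regressive count.\n"
        "Run 01 ascends the ramp, run 02 descends.\n"
    ),
}


def generate_session(config: SyntheticConfig, out_dir: str | Path) -> DatasetLayout:
    """Write a full synthetic session to ``out_dir`` and return its layout.

    Experience sessions comprise two 4-minute baselines plus ``n_trials``
    mental-task trials; slopes sessions the 8 x 2 condition/run grid.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "CONDITIONS.txt").write_text(_CONDITIONS_TEXT[config.scenario], encoding="utf-8")

    root_seq = np.random.SeedSequence(config.seed)
    plan_rng = np.random.default_rng(root_seq.spawn(1)[0])
    if config.scenario == "experience":
        trial_specs = list(_experience_trials(config))
    else:
        trial_specs = list(_slopes_trials(config, plan_rng))

    children = root_seq.spawn(len(trial_specs) + 1)[1:]
    for (condition, run, plan, direction), child in zip(trial_specs, children):
        stem = f"subject_{config.subject:02d}_cond_{condition:02d}_run_{run:02d}"
        recording, meta = generate_trial(
            config,
            plan,
            np.random.default_rng(child),
            direction=direction,
            file_name=f"{stem}.csv",
        )
        write_trial(recording, meta, out_dir, stem=stem)
    return scan_dataset(out_dir, config.scenario)


def null_config(config: SyntheticConfig | None = None, **overrides) -> SyntheticConfig:
    """A copy of ``config`` with both effect factors set to 1 (no contrast)."""
    base = config or SyntheticConfig()
    return replace(base, erd_factor=1.0, gamma_factor=1.0, **overrides)
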
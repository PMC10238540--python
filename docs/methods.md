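# Methods

## Problem and data model

A subject walks with a fully assisting lower-limb exoskeleton while
performing one of three mental tasks: *relax* (mind blank, device
static), *MI* (kinesthetically focused gait — "motor imagery" here means
high attention to the assisted movement, not classical imagery at rest)
and *regressive count* (cumulative mental subtraction, a high-load
distractor that pulls attention away from gait). EEG is recorded from 27
channels (10-10 montage over fronto-central-parietal cortex) plus 4
bipolar EOG channels at 200 Hz, hardware-filtered with a 0.1 Hz high-pass
and a 50 Hz notch, and stored per trial as a CSV matrix plus a JSON
sidecar. Two decoding paradigms are evaluated:

- **MI paradigm** — relax (0) vs MI (1), from alpha/beta rhythms: motor
  engagement suppresses sensorimotor alpha/beta power (event-related
  desynchronization, ERD).
- **Attention paradigm** — MI (1, attended gait) vs relax and count (0),
  from gamma-band power, which rises with attention to the movement.

## Effective analysis windows

Classifier training and metric evaluation never use a task period whole.
Flat-ground trials follow a fixed timeline (15 s relax, 24 s MI, 22 s
count, 14 s relax after a 5 s equipment-sync lead-in carrying label 0);
the first 5/4/2/4 s of the four periods are discarded (filter
convergence, walking transition, instruction-evoked potentials), leaving
10/20/20/10 s of effective signal — 40 s per trial for the MI paradigm
(count dropped) and 60 s for the attention paradigm. Ramp trials have one
variable-length active period (MI or count, cued by staff after the
exoskeleton is fully on the ramp) bracketed by static rests; a
configurable 2 s post-cue neglect is applied at the start of active and
rest periods and none at their ends, since the closing cue already
precedes the ramp end. Neglects are anchored to labeled event boundaries,
not absolute trial time, so slightly drifting recordings are handled
identically; truncated trials clip windows with a warning instead of
failing, because real recordings end on operator action.

## Feature extraction

Per paradigm, the 27 EEG channels pass through a causal Butterworth
band-pass bank (design order 4 per band): MI bank 8–12 / 12–18 / 18–24 /
24–30 Hz; attention bank 30–36 / 36–42 / 42–48 / 52–58 / 58–64 / 64–70 Hz
(48–52 Hz skipped — the recordings carry a 50 Hz notch, so that band is
uninformative). Band edges are configurable; causal filtering is the
default because the protocol explicitly budgets convergence time for
forward-only filters (zero-phase filtering is available as an option).

The filtered signal is cut into 1.5 s epochs advanced every 0.5 s.
Labeled epochs are tiled from each window's start and must lie entirely
inside their window; a parallel continuous tiling of the whole trial
feeds index rendering. Per band, a two-class CSP is fitted on the labeled
epochs: each epoch's mean-removed channel covariance is trace-normalized,
averaged per class, the composite covariance whitened (eigendecomposition
with a ridge of 1e-8 × trace added only if near-singular), and the
whitened class-1 covariance diagonalized. Columns are sorted by class-1
eigenvalue descending; the first and last m = 4 components are kept. The
per-epoch feature is the variance of each selected component — computed
as w'Cw from the same covariance stack — then z-scored per feature with
the training mean and SD (raw variance, not log-variance, is the default;
both are available, and per-feature z-scoring over training epochs was
chosen over within-epoch normalization). Trace normalization plus
z-scoring makes the features invariant to a global amplitude rescaling of
the data.

## Classification

MI uses a closed-form LDA: weights solve (pooled covariance) w = m1 − m0
with a ridge of 1e-6 × mean diagonal on the pooled covariance, so folds
with fewer rows than features still fit; the bias places the boundary at
the class-mean midpoint, and an exact tie predicts class 0 (relax as the
conservative outcome).

Attention uses a cascade of two LDAs on the gamma features: classifier A
(Count 0 vs MI 1) and classifier B (Relax+Count 0 vs MI 1). Per epoch,
the MI paradigm's output gates which classifier is consulted: A when the
MI decoder said imagery, B otherwise. The gate is the raw per-epoch MI
decision by default (keeping the cascade causal per epoch); a smoothed
gate (MI index ≥ 0.5) is available. Both classifiers share the feature
space, whose CSP is fitted on the attention target grouping
(relax+count vs MI). When no relax rows exist, B is fitted on the same
rows as A and the cascade degenerates to a single classifier.

## Index and metric

Binary epoch decisions are averaged over a centered window of the k = 5
previous and posterior epochs (11 epochs in the interior; truncated at
trial edges, which the protocol never defines otherwise), giving a
continuous [0, 1] index per epoch. With 1.5 s epochs and 0.5 s shift the
window spans about ±3 s of signal around each epoch, so the index lags at
task transitions — which the metric excludes by construction.

Accuracy per trial is `%PI = 100 · Σᵢ (tᵢ/t_T) · Aᵢ` over the effective
windows, with Aᵢ the mean index (target 1) or mean complement (target 0)
over the epochs fully contained in window i, and tᵢ/t_T the duration
weights. Aᵢ uses uniform epoch weighting, equivalent to the area ratio of
the stepwise index at epoch resolution. Windows containing no epoch are
skipped with a warning and excluded from t_T. Because of the index lag, a
perfect classifier does not reach exactly 100 %.

## Cross-validation

Leave-one-out over trials, refitting CSP, standardization and all
classifiers inside each fold (no leakage from the test trial). Flat
ground: 16 folds over the condition-3 trials, 15 training trials each;
the two baseline trials are never used. Ramp: the MI paradigm folds over
the 8 MI trials (7 train / 1 test); the attention paradigm folds over all
16 trials. For attention folds the same fold's MI models supply the gate.
Summaries report the mean and sample SD (n−1) of the fold %PI values per
subject, plus grand averages, in a machine-readable table.

## Synthetic sessions

The generator emulates the study conditions so every stage is testable
without recordings. Signal = spatially mixed narrowband sources + noise:

- per-channel 1/f pink noise, 10 µV rms (spectral shaping of white
  noise);
- an 8–12 Hz source centered on CZ (6 µV) and two 16–26 Hz sources over
  left/right sensorimotor cortex (4 µV), with Gaussian topographies on an
  idealized 10-10 grid; their amplitude is multiplied by the **ERD
  factor** (default 0.6) during MI samples;
- two 30–70 Hz gamma sources over central/parietal cortex (3 µV)
  multiplied by the **attention factor** (default 1.6) during MI samples
  relative to relax and count;
- blink transients (0.3 s raised-cosine, ~150 µV on the vertical EOG
  pair, Poisson 10/min) leaking into EEG with gains decaying from frontal
  (0.12) to central (0.02) rows;
- the hardware chain (0.1 Hz high-pass, 50 Hz notch) applied causally,
  and a 5 s label-0 lead-in.

Effects are amplitude modulations of mixed sources — never feature-space
injections — so CSP has a genuine spatial pattern to recover. A factor of
1.0 is a null effect. Ramp active periods draw their duration uniformly
from 8–14 s; static rests around them are labeled relax (10 s), which is
what gives the ramp scenario relax epochs for the MI paradigm and relax
rows for cascade training. Output is a pure function of the
configuration: one seed sequence drives everything, and identical
configurations produce byte-identical files.

What the generator does **not** emulate: volume-conducted gait artifacts,
EMG contamination, electrode drift, non-stationary rhythms, inter-subject
topography variation, or realistic head geometry. Passing tests therefore
show the pipeline recovers the class structure it is designed for under
controlled contrasts and stays at chance without them — not that any
particular accuracy level transfers to recorded subjects.

## Problem sizes and numerical choices

Tests and the acceptance script use full 16-trial sessions for effect
recovery and chance control, and 8-trial sessions at three ERD levels
(1.0 / 0.7 / 0.4, matched seeds) for the monotonicity property; the
Monte-Carlo band-power checks use 30 generated trials at a 95 %
pass-fraction. Degenerate inputs are handled explicitly: zero-variance
epochs standardize to finite values (zero training SDs are replaced by
1), singular covariances are ridge-regularized, windows shorter than one
epoch yield warnings rather than errors, and empty decision vectors yield
empty traces.

## Known limitations

- The descending-ramp MI/count label codes are configurable because
  recorded archives are ambiguous about one code; defaults are 754 (MI)
  and 758 (count).
- The cascade gate definition (raw vs smoothed MI output) and the
  attention fold set on ramps (all 16 trials vs count-only) are design
  choices exposed in the configuration; raw gate and all-16 folds are the
  defaults.
- The pipeline is pseudo-online (batch per trial); no real-time
  incremental smoothing or closed-loop control is provided.
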
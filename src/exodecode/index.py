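"""Continuous decoder indices from binary epoch decisions.

The per-epoch 0/1 decisions are averaged over a centered window of the
``k`` previous and ``k`` posterior epochs (plus the current one), yielding
a continuous index in [0, 1] at one-epoch resolution.  At the trial edges
the window is truncated rather than padded.  With the default k = 5 and
0.5 s epoch shift the interior window spans 11 epochs, so the index mixes
information from roughly +/-3 s around each epoch — the source of the
natural delay visible at task transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_SMOOTHING_K = 5


@dataclass
class IndexTrace:
    """A continuous [0, 1] index sampled once per shifted epoch."""

    values: np.ndarray
    starts: np.ndarray
    epoch_length: float
    shift: float
    paradigm: str
    k: int

    @property
    def n_epochs(self) -> int:
        return len(self.values)


def smooth_index(
    decisions: np.ndarray,
    k: int = DEFAULT_SMOOTHING_K,
    starts: np.ndarray | None = None,
    epoch_length: float = 1.5,
    shift: float = 0.5,
    paradigm: str = "mi",
) -> IndexTrace:
    """Centered truncated moving average of binary epoch decisions.

    The value at epoch i is the mean of decisions over [i-k, i+k]
    intersected with the trial.  An empty decision vector yields an empty
    trace.
    """
    if k < 0:
        raise ValueError(f"smoothing half-width k must be >= 0, got {k}")
    decisions = np.asarray(decisions, dtype=float)
    n = len(decisions)
    if starts is None:
        starts = shift * np.arange(n)
    starts = np.asarray(starts, dtype=float)
    if len(starts) != n:
        raise ValueError(f"starts has {len(starts)} entries for {n} decisions")

    if n == 0:
        values = np.empty(0)
    else:
        cumulative = np.concatenate(([0.0], np.cumsum(decisions)))
        idx = np.arange(n)
        lo = np.maximum(idx - k, 0)
        hi = np.minimum(idx + k, n - 1)
        values = (cumulative[hi + 1] - cumulative[lo]) / (hi - lo + 1)
    return IndexTrace(
        values=values,
        starts=starts,
        epoch_length=epoch_length,
        shift=shift,
        paradigm=paradigm,
        k=k,
    )
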
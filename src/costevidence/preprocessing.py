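"""Force-trace reduction: maximal-force estimation and epoch detection.

Raw traces are sampled force versus time.  Maximal force is estimated from
a calibration squeeze; effort onsets and offsets in free-allocation trials
are detected off-line from the force level (relative to half the maximal
force) and its temporal derivative (relative to one standard deviation of
the derivative over the trial), after light smoothing.  For the
imposed-duration tasks, effort onset is detected on-line as the first
sample above 20% of maximal force.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ForceTrace",
    "Epoch",
    "estimate_max_force",
    "detect_epochs_offline",
    "detect_onset_online",
    "read_trace",
    "write_trace",
    "epochs_to_frame",
]


@dataclass(frozen=True)
class ForceTrace:
    """Uniformly sampled force time series.

    ``force`` is either raw units or a fraction of maximal force after
    normalisation; ``time`` is a uniform grid in seconds.
    """

    time: np.ndarray
    force: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        if len(self.time) != len(self.force):
            raise ValueError("time and force must have equal length")
        if len(self.time) == 0:
            raise ValueError("empty trace")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def normalized(self, max_force: float) -> "ForceTrace":
        return ForceTrace(self.time, self.force / max_force, self.sampling_rate)


@dataclass(frozen=True)
class Epoch:
    kind: str  # "effort" | "rest"
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("epoch end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


def estimate_max_force(trace: ForceTrace, variant: str = "main") -> float:
    """Maximal force from a calibration squeeze.

    main: mean of the samples in the last half of the squeeze window whose
    value is at least the whole-window median.  simplified: mean of all
    samples (fixed-duration squeeze window).
    """
    force = np.asarray(trace.force, dtype=float)
    if variant == "simplified":
        return float(np.mean(force))
    if variant != "main":
        raise ValueError(f"unknown variant {variant!r}")
    median = np.median(force)
    last_half = force[len(force) // 2 :]
    selected = last_half[last_half >= median]
    if selected.size == 0:
        raise ValueError("no samples in the last half reach the window median")
    return float(np.mean(selected))


def _smooth(force: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return force.astype(float)
    kernel = np.ones(window) / window
    padded = np.pad(force.astype(float), (window // 2, window - 1 - window // 2), mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def detect_epochs_offline(
    trace: ForceTrace,
    max_force: float = 1.0,
    smooth_ms: float = 50.0,
) -> list[Epoch]:
    """Segment a trial into alternating rest/effort epochs.

    Effort onsets satisfy: force derivative above one standard deviation of
    the derivative series (whole trial) while force is below half the
    maximal force; offsets: derivative below minus one standard deviation
    while force is above half max.  The derivative is taken on a lightly
    smoothed trace.  The first rest period runs from the start of the trial
    (incentive presentation) to the first effort onset.
    """
    window = max(1, int(round(smooth_ms / 1000.0 * trace.sampling_rate)))
    force = _smooth(np.asarray(trace.force, dtype=float), window)
    deriv = np.gradient(force, 1.0 / trace.sampling_rate)
    sd = float(np.std(deriv))
    half = 0.5 * max_force
    t = np.asarray(trace.time, dtype=float)
    t_end = t[-1] + 1.0 / trace.sampling_rate

    above = force > half  # ties resolve toward continuing the current epoch
    if not above.any():
        return [Epoch("rest", t[0], t_end)]

    # Contiguous above-half-max runs are the effort cores; extend each edge
    # through the adjoining high-derivative ramp to locate onset/offset.
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [i + 1 for i in edges[~above[edges]]] if len(edges) else []
    stops = [i + 1 for i in edges[above[edges]]] if len(edges) else []
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        stops = stops + [len(force)]

    boundaries: list[tuple[float, float]] = []
    for i0, i1 in zip(starts, stops):
        # Onset: first sample of the rising run (derivative > sd, force still
        # below half max) that leads into this above-half core.
        j = i0
        while j > 0 and deriv[j - 1] > sd and not above[j - 1]:
            j -= 1
        # Offset: first sample of the falling run (derivative < -sd, force
        # still above half max) that ends this core.
        onset = t[j]
        if i1 >= len(force):
            offset = t_end  # trial ends mid-effort, no falling edge observed
        else:
            m = i1 - 1
            while m > j and deriv[m] < -sd and above[m]:
                m -= 1
            offset = t[m + 1]
        boundaries.append((onset, offset))

    # Merge overlapping detections, drop zero-length leftovers.
    merged: list[tuple[float, float]] = []
    for onset, offset in boundaries:
        if merged and onset <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], offset))
        else:
            merged.append((onset, offset))

    epochs: list[Epoch] = []
    cursor = t[0]
    for onset, offset in merged:
        if onset > cursor:
            epochs.append(Epoch("rest", cursor, onset))
        epochs.append(Epoch("effort", max(onset, cursor), offset))
        cursor = offset
    if cursor < t_end:
        epochs.append(Epoch("rest", cursor, t_end))
    return epochs


def detect_onset_online(trace: ForceTrace, max_force: float = 1.0) -> Optional[float]:
    """Time of the first sample above 20% of maximal force, or None."""
    idx = np.flatnonzero(np.asarray(trace.force) > 0.2 * max_force)
    if idx.size == 0:
        return None
    return float(trace.time[idx[0]])


def read_trace(path, sampling_rate: Optional[float] = None) -> ForceTrace:
    """Two-column delimited text: time_s, force_fraction."""
    df = pd.read_csv(path, sep=None, engine="python")
    time = df.iloc[:, 0].to_numpy(dtype=float)
    force = df.iloc[:, 1].to_numpy(dtype=float)
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(np.diff(time)))
    return ForceTrace(time, force, sampling_rate)


def write_trace(trace: ForceTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time, "force_fraction": trace.force}).to_csv(
        path, sep="\t", index=False
    )


def epochs_to_frame(epochs: list[Epoch]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "epoch_index": range(len(epochs)),
            "kind": [e.kind for e in epochs],
            "start_s": [e.start for e in epochs],
            "end_s": [e.end for e in epochs],
            "duration_s": [e.duration for e in epochs],
        }
    )
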
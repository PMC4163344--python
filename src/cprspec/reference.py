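"""Gold-standard annotation of the compression-depth (CD) signal.

In the emulated study design the reference channel is the displacement
measured by a distance sensor inside the manikin (here: the simulator's
ground-truth displacement).  Compressions are identified as local maxima
exceeding a fixed 15 mm threshold, and per-window reference feedback is the
mean inter-peak rate and mean peak depth of the compressions whose maxima
fall inside the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import InsufficientCompressionsError
from .signal_io import DisplacementRecord
from .spectral import FeedbackEstimate, WindowGap

__all__ = [
    "CompressionAnnotation",
    "detect_compressions",
    "reference_feedback",
    "reference_session",
]

DEFAULT_THRESHOLD_MM = 15.0
DEFAULT_REFRACTORY_S = 0.25  # 240 min^-1 ceiling; suppresses double detection


@dataclass(frozen=True)
class CompressionAnnotation:
    """One detected compression: time and depth of its displacement peak."""

    peak_time: float
    peak_depth: float


def detect_compressions(
    cd: DisplacementRecord,
    threshold: float = DEFAULT_THRESHOLD_MM,
    refractory: float = DEFAULT_REFRACTORY_S,
) -> list[CompressionAnnotation]:
    """Peak detector with a fixed depth threshold and refractory period.

    Local maxima of the CD signal above ``threshold`` mm, separated by at
    least ``refractory`` seconds.  ``peak_depth`` is the sample value at
    the maximum (the CD signal is referenced to the resting chest
    position, 0 mm).  An empty list is a valid result.
    """
    if len(cd) == 0:
        return []
    distance = max(1, int(round(refractory * cd.fs)))
    idx, _ = signal.find_peaks(cd.samples, height=threshold, distance=distance)
    times = cd.t0 + idx / cd.fs
    return [CompressionAnnotation(float(t), float(cd.samples[i])) for t, i in zip(times, idx)]


def _window_peaks(
    annotations: Sequence[CompressionAnnotation], window_start: float, tw: float
) -> list[CompressionAnnotation]:
    end = window_start + tw
    return [a for a in annotations if window_start <= a.peak_time < end]


def reference_feedback(
    annotations: Sequence[CompressionAnnotation],
    window_start: float,
    tw: float,
    aggregate: str = "mean",
) -> FeedbackEstimate:
    """Per-window reference rate and depth from detected compressions.

    rate = 60 / aggregate inter-peak interval, depth = aggregate peak
    depth, over the peaks whose maxima fall inside the half-open window
    [window_start, window_start + tw).  ``aggregate`` is ``"mean"``
    (default) or ``"median"``.

    Raises
    ------
    InsufficientCompressionsError
        Fewer than two peaks in the window.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError(f"aggregate must be 'mean' or 'median', got {aggregate!r}")
    peaks = _window_peaks(annotations, window_start, tw)
    if len(peaks) < 2:
        raise InsufficientCompressionsError(
            f"insufficient reference compressions in window at {window_start} s "
            f"({len(peaks)} found, need >= 2)"
        )
    agg = np.mean if aggregate == "mean" else np.median
    intervals = np.diff([p.peak_time for p in peaks])
    return FeedbackEstimate(
        rate=60.0 / float(agg(intervals)),
        depth=float(agg([p.peak_depth for p in peaks])),
        window_start=window_start,
        duration=tw,
        source="reference",
    )


def reference_session(
    annotations: Sequence[CompressionAnnotation],
    duration: float,
    tw: float,
    aggregate: str = "mean",
) -> list[FeedbackEstimate | WindowGap]:
    """Reference feedback on the same nonoverlapping window grid as the method."""
    n_windows = int(np.floor(duration / tw + 1e-9))
    out: list[FeedbackEstimate | WindowGap] = []
    for i in range(n_windows):
        start = i * tw
        try:
            out.append(reference_feedback(annotations, start, tw, aggregate))
        except InsufficientCompressionsError as exc:
            out.append(WindowGap(window_start=start, duration=tw, reason=str(exc)))
    return out
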
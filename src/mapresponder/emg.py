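"""Peri-stimulus EMG processing: MEP extraction, discernibility, aMT, hotspot.

Frames are assumed already amplified and band-pass filtered by the recording
chain (20-1000 Hz, 2 kHz sampling); this module measures peak-to-peak MEP
amplitude in a post-stimulus window, applies frame-rejection rules based on
the pre-stimulus background contraction, and implements the active-motor-
threshold (aMT) and hotspot decision rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .mapping import StimulationEvent

__all__ = [
    "EMGFrame",
    "MEPMeasurement",
    "DiscernibilityRule",
    "extract_mep",
    "is_discernible",
    "amt_search",
    "hotspot",
    "flag_inconsistent_background",
]

DEFAULT_WINDOW_MS: tuple[float, float] = (10.0, 60.0)
PRE_STIM_RMS_MS: float = 50.0


@dataclass
class EMGFrame:
    """One peri-stimulus EMG sweep.

    ``samples`` are in mV; ``stim_onset_index`` marks the TMS pulse within the
    sweep.  Identifier fields are free-form bookkeeping carried through to the
    MEP table.
    """

    samples: np.ndarray
    sampling_rate: float = 2000.0
    stim_onset_index: int = 0
    participant_id: str = ""
    timepoint: str = ""
    trial: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 <= self.stim_onset_index < len(self.samples):
            raise ValueError("stim_onset_index outside frame")


@dataclass
class MEPMeasurement:
    """Peak-to-peak MEP amplitude with rejection bookkeeping."""

    amplitude: float
    pre_stim_rms: float
    rejected: bool = False
    reason: str = ""
    participant_id: str = ""
    timepoint: str = ""
    trial: int = 0


@dataclass(frozen=True)
class DiscernibilityRule:
    """MEP discernibility during active contraction.

    A response counts as discernible when its peak-to-peak amplitude exceeds
    both an absolute floor and a multiple of the pre-stimulus background RMS
    (both strict inequalities).  Defaults: > max(0.1 mV, 2 x pre-stimulus RMS).
    """

    floor_mv: float = 0.1
    rms_multiple: float = 2.0

    def __call__(self, meas: MEPMeasurement) -> bool:
        return is_discernible(meas, self)


def extract_mep(
    frame: EMGFrame, window_ms: tuple[float, float] = DEFAULT_WINDOW_MS
) -> MEPMeasurement:
    """Measure the peak-to-peak amplitude in the post-stimulus response window.

    ``amplitude = max - min`` of the samples in ``window_ms`` (ms after
    stimulus onset); ``pre_stim_rms`` is computed over the 50 ms preceding the
    stimulus (or whatever shorter history the frame holds).  Frames containing
    non-finite samples are returned rejected rather than raising.
    """
    start_ms, end_ms = window_ms
    if end_ms <= start_ms:
        raise ValueError("window end must exceed window start")
    fs = frame.sampling_rate
    i0 = frame.stim_onset_index + int(round(start_ms * fs / 1000.0))
    i1 = frame.stim_onset_index + int(round(end_ms * fs / 1000.0))
    if i0 < 0 or i1 > len(frame.samples) or i0 >= i1:
        raise ValueError("MEP window falls outside the frame")

    n_pre = int(round(PRE_STIM_RMS_MS * fs / 1000.0))
    pre = frame.samples[max(0, frame.stim_onset_index - n_pre) : frame.stim_onset_index]
    window = frame.samples[i0:i1]

    ids = dict(
        participant_id=frame.participant_id, timepoint=frame.timepoint, trial=frame.trial
    )
    if not np.all(np.isfinite(frame.samples)):
        return MEPMeasurement(
            amplitude=np.nan, pre_stim_rms=np.nan,
            rejected=True, reason="non-finite samples", **ids,
        )

    amplitude = float(window.max() - window.min())
    pre_rms = float(np.sqrt(np.mean(pre**2))) if len(pre) else 0.0
    return MEPMeasurement(amplitude=amplitude, pre_stim_rms=pre_rms, **ids)


def is_discernible(
    meas: MEPMeasurement, rule: DiscernibilityRule | None = None
) -> bool:
    """Apply a discernibility rule to a (non-rejected) measurement."""
    if meas.rejected:
        raise ValueError("discernibility undefined for rejected frames")
    rule = rule or DiscernibilityRule()
    return meas.amplitude > max(rule.floor_mv, rule.rms_multiple * meas.pre_stim_rms)


def amt_search(
    response_fn: Callable[[float], Sequence[MEPMeasurement]],
    intensity_grid: Sequence[float],
    rule: DiscernibilityRule | None = None,
    min_discernible: int = 5,
) -> float:
    """Active motor threshold: lowest intensity with >= 5 discernible MEPs of 10.

    ``response_fn`` maps a stimulator intensity (% maximal output) to the
    train of MEP measurements it evokes; the grid is scanned in ascending
    order and the first qualifying intensity returned.

    Raises ``ValueError`` if the grid is not ascending or no intensity
    qualifies.
    """
    grid = list(intensity_grid)
    if not grid:
        raise ValueError("empty intensity grid")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("intensity grid must be strictly ascending")
    rule = rule or DiscernibilityRule()
    for intensity in grid:
        train = response_fn(intensity)
        n_ok = sum(is_discernible(m, rule) for m in train if not m.rejected)
        if n_ok >= min_discernible:
            return float(intensity)
    raise ValueError("active motor threshold not found within intensity range")


def hotspot(events: Iterable[StimulationEvent]) -> tuple[float, float]:
    """Coordinate of the event with the maximal MEP amplitude.

    Ties are broken by first occurrence in trial order.
    """
    best: StimulationEvent | None = None
    for ev in events:
        if best is None or ev.amplitude > best.amplitude:
            best = ev
    if best is None:
        raise ValueError("hotspot undefined for an empty event list")
    return (best.x, best.y)


def flag_inconsistent_background(
    measurements: Sequence[MEPMeasurement], tolerance: float = 0.5
) -> list[MEPMeasurement]:
    """Reject frames whose background contraction drifted from the session norm.

    Frames with pre-stimulus RMS deviating more than ``tolerance`` (fraction)
    from the session median are flagged; mapping excludes flagged frames.
    Already-rejected frames are passed through unchanged.
    """
    valid = [m.pre_stim_rms for m in measurements if not m.rejected]
    if not valid:
        return list(measurements)
    median = float(np.median(valid))
    out = []
    for m in measurements:
        if not m.rejected and median > 0 and abs(m.pre_stim_rms - median) > tolerance * median:
            m = MEPMeasurement(
                amplitude=m.amplitude, pre_stim_rms=m.pre_stim_rms,
                rejected=True, reason="inconsistent background contraction",
                participant_id=m.participant_id, timepoint=m.timepoint, trial=m.trial,
            )
        out.append(m)
    return out
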
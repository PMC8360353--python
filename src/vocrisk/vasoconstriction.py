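"""Vasoconstriction event detection and quantification.

A vasoconstriction episode appears in the normalized, filtered finger-PPG
amplitude (PPGa) as a transient drop below the pre-event baseline, usually
accompanied by a negative R-to-R-interval excursion (heart-rate rise). This
module detects such episodes, extracts the fixed 180-s two-channel segments
around them, and computes the per-event metrics:

- ``T_vasoc``  — event duration (s)
- ``A_vasoc``  — cumulative percent drop of PPGa below baseline (percent * s)
- ``M_vasoc``  — average percent drop, ``A_vasoc / T_vasoc`` (percent); this
  is also the average percent change in PPGa from the pre-event baseline
- ``A_RRI-`` / ``A_RRI+`` — RRI area below / above its baseline (s * s),
  i.e. cumulative heart-rate increase / decrease over the event

Detection thresholds are exposed as configuration: they are tunable
hyper-parameters, not physiological constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocessing import UniformSeries

__all__ = [
    "VasoEvent",
    "DetectorParams",
    "Segment",
    "EventMetrics",
    "SubjectEventSummary",
    "detect_events",
    "extract_segment",
    "extract_segments",
    "event_metrics",
    "subject_event_summary",
]

#: Segment geometry: 30 s pre-onset baseline + 150 s post-onset at 2 Hz.
PRE_ONSET_S = 30.0
POST_ONSET_S = 150.0
SEGMENT_SAMPLES = 360
ONSET_SAMPLE = 60


@dataclass(frozen=True)
class VasoEvent:
    """One detected vasoconstriction episode."""

    onset_time: float
    end_time: float

    def __post_init__(self) -> None:
        if self.end_time <= self.onset_time:
            raise ValueError("end_time must exceed onset_time")

    @property
    def duration(self) -> float:
        return self.end_time - self.onset_time


@dataclass(frozen=True)
class DetectorParams:
    """Tunable thresholds of the event detector.

    d_min : minimum fractional PPGa drop below baseline to trigger onset.
    t_min : minimum time (s) the signal must stay below the trigger level.
    baseline_win : pre-onset window (s) defining the local baseline.
    baseline_cv_max : maximum coefficient of variation of the baseline
        window; a candidate without a sufficiently flat baseline is
        rejected (the stated mechanism by which events are missed).
    onset_frac : fractional drop defining the refined onset position when
        walking back from the trigger crossing.
    recovery_frac : event ends when PPGa recovers to within this fraction
        of baseline.
    max_duration : hard cap (s) on event duration; the vast majority of
        episodes last well under this.
    masked_guard : events closer than this (s) to a masked interval are
        discarded to protect baseline integrity.
    """

    d_min: float = 0.10
    t_min: float = 10.0
    baseline_win: float = PRE_ONSET_S
    baseline_cv_max: float = 0.05
    onset_frac: float = 0.02
    recovery_frac: float = 0.05
    max_duration: float = POST_ONSET_S
    masked_guard: float = 30.0


@dataclass(frozen=True)
class Segment:
    """Fixed 180-s two-channel window around one event.

    360 samples per channel at 2 Hz; the first 60 samples (30 s) strictly
    precede onset and represent the pre-vasoconstriction baseline.
    Flattening both channels yields 720 values.
    """

    ppga: np.ndarray
    rri: np.ndarray
    onset_index: int
    subject_id: str
    event: VasoEvent
    label: int | None = None

    def __post_init__(self) -> None:
        if len(self.ppga) != SEGMENT_SAMPLES or len(self.rri) != SEGMENT_SAMPLES:
            raise ValueError(f"segment channels must have {SEGMENT_SAMPLES} samples")
        if self.onset_index != ONSET_SAMPLE:
            raise ValueError(f"onset must fall at sample {ONSET_SAMPLE}")

    def as_tensor(self) -> np.ndarray:
        """Stacked (2, 360) array: channel 0 = PPGa, channel 1 = RRI."""
        return np.stack([self.ppga, self.rri])

    def flatten(self) -> np.ndarray:
        return self.as_tensor().ravel()


@dataclass(frozen=True)
class EventMetrics:
    """Per-event quantities; ``M_vasoc = A_vasoc / T_vasoc`` by construction."""

    T_vasoc: float
    A_vasoc: float
    M_vasoc: float
    A_RRI_minus: float
    A_RRI_plus: float


@dataclass(frozen=True)
class SubjectEventSummary:
    """Per-subject medians over all detected events; NaN when event-free."""

    n_vasoc: int
    median_M_vasoc: float
    median_A_RRI_minus: float
    median_A_RRI_plus: float


def _rolling_mean_std(x: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean/SD of the w samples strictly preceding each index (NaN-padded)."""
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    n = len(x)
    mean = np.full(n, np.nan)
    std = np.full(n, np.nan)
    idx = np.arange(w, n)
    s1 = c1[idx] - c1[idx - w]
    s2 = c2[idx] - c2[idx - w]
    mean[idx] = s1 / w
    var = np.maximum(s2 / w - (s1 / w) ** 2, 0.0)
    std[idx] = np.sqrt(var)
    return mean, std


def detect_events(
    ppga: UniformSeries, params: DetectorParams | None = None
) -> list[VasoEvent]:
    """Detect vasoconstriction episodes in a normalized, filtered PPGa series.

    Onset is triggered at the first sample where PPGa falls below
    ``(1 - d_min) * baseline`` and stays below for at least ``t_min``
    seconds, where the baseline is the mean of the preceding
    ``baseline_win`` seconds and must be flat (CV <= ``baseline_cv_max``)
    and fully valid. The reported onset is refined by walking back to where
    the drop first exceeded ``onset_frac`` of baseline. The event ends at
    recovery to within ``recovery_frac`` of baseline or after
    ``max_duration`` seconds, whichever comes first. Events are
    non-overlapping, ordered by onset, and never straddle masked intervals.
    """
    p = params or DetectorParams()
    v = ppga.values
    mask = ppga.mask
    rate = ppga.rate
    n = len(v)
    w = int(round(p.baseline_win * rate))
    t_min_n = int(round(p.t_min * rate))
    guard_n = int(round(p.masked_guard * rate))
    if n <= w + t_min_n:
        return []

    base_mean, base_std = _rolling_mean_std(v, w)
    valid_count = np.concatenate([[0], np.cumsum(mask.astype(int))])
    baseline_all_valid = (valid_count[w:] - valid_count[:-w]) == w  # index i -> window before i

    events: list[VasoEvent] = []
    i = w
    while i < n:
        if not mask[i]:
            i += 1
            continue
        base = base_mean[i]
        if not np.isfinite(base) or base <= 0 or not baseline_all_valid[i - w]:
            i += 1
            continue
        trigger = (1.0 - p.d_min) * base
        if v[i] >= trigger:
            i += 1
            continue
        # flat-baseline requirement
        if base_std[i] / base > p.baseline_cv_max:
            i += 1
            continue
        # must stay below trigger for t_min
        j_end = min(i + t_min_n, n)
        below = v[i:j_end] < trigger
        if j_end - i < t_min_n or not below.all():
            i += 1
            continue
        # refine onset: walk back to the first sample exceeding onset_frac drop
        onset_level = (1.0 - p.onset_frac) * base
        k = i
        while k > 0 and v[k - 1] < onset_level and mask[k - 1]:
            k -= 1
        onset_idx = k
        # event end: recovery or max duration
        recovery_level = (1.0 - p.recovery_frac) * base
        max_end = min(onset_idx + int(round(p.max_duration * rate)), n - 1)
        end_idx = max_end
        for j in range(i + t_min_n, max_end + 1):
            if not mask[j] or v[j] >= recovery_level:
                end_idx = j
                break
        if end_idx <= onset_idx:
            i += 1
            continue
        # reject events near masked samples
        lo = max(onset_idx - guard_n, 0)
        hi = min(end_idx + guard_n, n - 1)
        if not mask[lo : hi + 1].all():
            i = end_idx + 1
            continue
        # a full flat baseline must fit between the previous event and this
        # onset; repetitive drops close together are missed by design
        if events and (onset_idx / rate + ppga.start_time) - events[-1].end_time < p.baseline_win:
            i = end_idx + 1
            continue
        t0 = ppga.start_time
        events.append(
            VasoEvent(onset_time=t0 + onset_idx / rate, end_time=t0 + end_idx / rate)
        )
        i = end_idx + 1
    return events


def extract_segment(
    ppga: UniformSeries,
    rri: UniformSeries,
    event: VasoEvent,
    subject_id: str = "",
    label: int | None = None,
) -> Segment | None:
    """Extract the 180-s two-channel segment around one event.

    The window covers [onset - 30 s, onset + 150 s); onset falls at sample
    60. Events without 30 s of valid pre-onset context or 150 s of
    post-onset data are skipped (returns None), mirroring the detector's
    stated miss mechanisms rather than raising.
    """
    rate = ppga.rate
    onset_idx = int(round((event.onset_time - ppga.start_time) * rate))
    lo = onset_idx - ONSET_SAMPLE
    hi = lo + SEGMENT_SAMPLES
    if lo < 0 or hi > len(ppga) or hi > len(rri):
        return None
    if not (ppga.mask[lo:hi].all() and rri.mask[lo:hi].all()):
        return None
    return Segment(
        ppga=ppga.values[lo:hi].copy(),
        rri=rri.values[lo:hi].copy(),
        onset_index=ONSET_SAMPLE,
        subject_id=subject_id,
        event=event,
        label=label,
    )


def extract_segments(
    ppga: UniformSeries,
    rri: UniformSeries,
    events: list[VasoEvent],
    subject_id: str = "",
    label: int | None = None,
) -> list[Segment]:
    """Extract segments for all events, silently dropping infeasible ones."""
    out = []
    for ev in events:
        seg = extract_segment(ppga, rri, ev, subject_id=subject_id, label=label)
        if seg is not None:
            out.append(seg)
    return out


def event_metrics(segment: Segment, rate: float = 2.0) -> EventMetrics:
    """Compute the per-event metrics from a segment.

    The per-channel baseline is the mean of the 30-s pre-onset samples.
    ``A_vasoc`` integrates (trapezoidal rule at 2 Hz) the percent drop of
    PPGa below baseline over [onset, end]; excursions above baseline
    contribute zero. The RRI areas integrate the positive parts of
    (baseline - RRI) and (RRI - baseline) respectively.
    """
    ev = segment.event
    dur = ev.duration
    if dur <= 0:
        raise ValueError("zero-length event")
    dt = 1.0 / rate
    onset = segment.onset_index
    end = onset + int(round(dur * rate))
    end = min(end, len(segment.ppga) - 1)
    if end <= onset:
        raise ValueError("event shorter than one sample")

    base_p = segment.ppga[:onset].mean()
    base_r = segment.rri[:onset].mean()
    if base_p <= 0:
        raise ValueError("non-positive PPGa baseline")

    drop_pct = np.maximum((base_p - segment.ppga[onset : end + 1]) / base_p, 0.0) * 100.0
    a_vasoc = float(np.trapezoid(drop_pct, dx=dt))
    t_vasoc = (end - onset) * dt
    m_vasoc = a_vasoc / t_vasoc

    rr = segment.rri[onset : end + 1]
    a_minus = float(np.trapezoid(np.maximum(base_r - rr, 0.0), dx=dt))
    a_plus = float(np.trapezoid(np.maximum(rr - base_r, 0.0), dx=dt))
    return EventMetrics(
        T_vasoc=t_vasoc,
        A_vasoc=a_vasoc,
        M_vasoc=m_vasoc,
        A_RRI_minus=a_minus,
        A_RRI_plus=a_plus,
    )


def subject_event_summary(metrics: list[EventMetrics]) -> SubjectEventSummary:
    """Medians of the event metrics across a subject's night.

    An event-free night yields ``n_vasoc = 0`` with NaN medians; the
    missing medians are imputed later, inside cross-validation folds.
    """
    if not metrics:
        return SubjectEventSummary(0, math.nan, math.nan, math.nan)
    return SubjectEventSummary(
        n_vasoc=len(metrics),
        median_M_vasoc=float(np.median([m.M_vasoc for m in metrics])),
        median_A_RRI_minus=float(np.median([m.A_RRI_minus for m in metrics])),
        median_A_RRI_plus=float(np.median([m.A_RRI_plus for m in metrics])),
    )
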
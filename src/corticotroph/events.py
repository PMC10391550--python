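"""Event detection and phenotyping of current-clamp voltage traces.

A recording is segmented into *events* by a threshold/re-arm rule: an event
opens when the membrane potential rises 20 mV above baseline and closes when
it falls back below baseline + 5 mV, after which detection re-arms.  Events
shorter than (or exactly) 100 ms are single spikes; events longer than 100 ms
that carry at least two spikelets are pseudo-plateau bursts; long events with
fewer spikelets fall into an explicit "other" class.

Cells are phenotyped from the afterhyperpolarization (AHP) of their spikes:
averaging the AHP depth of the first ten consecutive single spikes, cells
with mean AHP > 25 mV are A-type, < 20 mV are B-type, and the 20–25 mV band
is labelled ambiguous.  Twelve per-cell excitability metrics (capacitance,
membrane potential, event/spike/burst frequency and duration, burst factor,
active-time fraction, event amplitude, days in culture) summarise each
recording for downstream feature analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "Trace",
    "Event",
    "EventTable",
    "SpikeShape",
    "ABClass",
    "CellSummary",
    "estimate_baseline",
    "detect_events",
    "count_spikelets",
    "classify_event",
    "spike_shape",
    "classify_cell_ab",
    "classify_cell",
    "first_consecutive_spike_run",
    "membrane_potential",
    "burst_factor",
    "summarize_cell",
]

# Detection constants (mV / ms): threshold and re-arm offsets from baseline,
# the spike/burst duration boundary, and the spikelet definition.
DELTA_THRESHOLD_MV = 20.0
DELTA_REARM_MV = 5.0
SPIKE_BURST_BOUNDARY_MS = 100.0
MIN_SPIKELETS_PER_BURST = 2
SPIKELET_PROMINENCE_MV = 5.0
SPIKELET_SEPARATION_MS = 2.0
AHP_WINDOW_MS = 200.0
A_TYPE_AHP_MV = 25.0
B_TYPE_AHP_MV = 20.0
N_SPIKES_FOR_CLASSIFICATION = 10


@dataclass
class Trace:
    """Uniformly sampled membrane-potential record (mV vs s)."""

    v_mv: np.ndarray
    fs_hz: float
    t0_s: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.v_mv = np.asarray(self.v_mv, dtype=float)
        if self.v_mv.ndim != 1 or self.v_mv.size < 2:
            raise ValueError("trace must be a 1-D array with >= 2 samples")
        if not np.all(np.isfinite(self.v_mv)):
            raise ValueError("trace contains non-finite samples")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def t_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.v_mv.size) / self.fs_hz

    @property
    def duration_s(self) -> float:
        return self.v_mv.size / self.fs_hz

    @classmethod
    def from_arrays(cls, t_s: np.ndarray, v_mv: np.ndarray,
                    metadata: dict | None = None,
                    max_jitter_s: float = 1e-9) -> "Trace":
        """Build from explicit time stamps, enforcing a uniform grid."""
        t_s = np.asarray(t_s, dtype=float)
        dt = np.diff(t_s)
        if dt.size == 0 or dt.min() <= 0:
            raise ValueError("time stamps must be strictly increasing")
        if np.abs(dt - dt[0]).max() > max_jitter_s:
            bad = int(np.argmax(np.abs(dt - dt[0]))) + 1
            raise ValueError(f"non-uniform time grid at row {bad}")
        return cls(v_mv=np.asarray(v_mv, dtype=float), fs_hz=1.0 / dt[0],
                   t0_s=float(t_s[0]), metadata=metadata or {})


@dataclass
class Event:
    start_s: float
    end_s: float
    peak_v_mv: float
    amplitude_mv: float
    n_spikelets: int
    klass: str = "other"

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("event end must follow its start")

    @property
    def duration_ms(self) -> float:
        return (self.end_s - self.start_s) * 1000.0


@dataclass
class EventTable:
    events: list[Event]
    recording_duration_s: float
    baseline_mv: float

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.events, self.events[1:]):
            if nxt.start_s < prev.end_s:
                raise ValueError("events overlap or are out of order")

    def __len__(self) -> int:
        return len(self.events)

    def of_class(self, klass: str) -> list[Event]:
        return [e for e in self.events if e.klass == klass]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"start_s": e.start_s, "end_s": e.end_s,
              "duration_ms": e.duration_ms, "peak_v_mv": e.peak_v_mv,
              "amplitude_mv": e.amplitude_mv, "n_spikelets": e.n_spikelets,
              "class": e.klass} for e in self.events],
            columns=["start_s", "end_s", "duration_ms", "peak_v_mv",
                     "amplitude_mv", "n_spikelets", "class"])


@dataclass(frozen=True)
class SpikeShape:
    width_ms: float
    time_to_peak_ms: float
    ahp_amplitude_mv: float  # nan when the post-spike window is truncated
    peak_amplitude_mv: float


@dataclass(frozen=True)
class ABClass:
    label: str  # {"A", "B", "ambiguous", "none"}
    mean_ahp_mv: float
    n_spikes_used: int


# Median and standard deviation of a standard normal truncated below its
# 0.6 quantile; their ratio debiases the quiet-subset median under Gaussian
# recording noise.
_TRUNC_BIAS_RATIO = 0.5244 / 0.6496


def estimate_baseline(trace: Trace) -> float:
    """Robust resting potential from the quiet bulk of the amplitude
    distribution.

    Samples below the 60th percentile exclude event-dominated stretches
    (events push the potential upward); the median of that quiet subset is
    then corrected for the downward bias truncation induces under Gaussian
    noise (the correction vanishes on noise-free traces).
    """
    v = trace.v_mv
    p60 = np.percentile(v, 60)
    below = v[v < p60]
    if below.size == 0:  # constant trace
        return float(np.median(v))
    return float(np.median(below) + _TRUNC_BIAS_RATIO * below.std())


def _interp_crossing(t0: float, v0: float, t1: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t1
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def detect_events(
    trace: Trace,
    delta_threshold_mv: float = DELTA_THRESHOLD_MV,
    delta_rearm_mv: float = DELTA_REARM_MV,
    baseline_mv: float | None = None,
) -> EventTable:
    """Segment a trace into threshold/re-arm events and classify each.

    An event opens at the first upward crossing of baseline + threshold while
    the detector is armed, and closes at the next downward crossing of
    baseline + re-arm, at which point the detector re-arms.  Crossing times
    are linearly interpolated between samples.  An event still open at the
    end of the record is closed at the final sample.
    """
    if not delta_threshold_mv > delta_rearm_mv > 0:
        raise ValueError("need delta_threshold > delta_rearm > 0")
    v = trace.v_mv
    if v.size < 2:
        raise ValueError("trace too short to detect events")
    baseline = estimate_baseline(trace) if baseline_mv is None else baseline_mv
    thr = baseline + delta_threshold_mv
    rearm = baseline + delta_rearm_mv
    t = trace.t_s
    fs = trace.fs_hz

    above_thr = v >= thr
    below_rearm = v < rearm
    up_idx = np.flatnonzero(above_thr[1:] & ~above_thr[:-1]) + 1
    down_idx = np.flatnonzero(below_rearm[1:] & ~below_rearm[:-1]) + 1

    events: list[Event] = []
    pos = 0  # events may not start before this sample
    di = 0
    for ui in up_idx:
        if ui < pos:
            continue
        while di < down_idx.size and down_idx[di] <= ui:
            di += 1
        if di < down_idx.size:
            ci = int(down_idx[di])
            end_s = _interp_crossing(t[ci - 1], v[ci - 1], t[ci], v[ci], rearm)
            last = ci
        else:  # event truncated by end of record
            ci = v.size - 1
            end_s = float(t[-1])
            last = ci + 1
        start_s = _interp_crossing(t[ui - 1], v[ui - 1], t[ui], v[ui], thr)
        seg = v[ui:last]
        peak = float(seg.max()) if seg.size else float(v[ui])
        n_spk = count_spikelets(trace, int(ui), int(last), baseline,
                                delta_threshold_mv=delta_threshold_mv)
        ev = Event(start_s=start_s, end_s=end_s, peak_v_mv=peak,
                   amplitude_mv=peak - baseline, n_spikelets=n_spk)
        ev.klass = classify_event(ev)
        events.append(ev)
        pos = last
    return EventTable(events=events, recording_duration_s=trace.duration_s,
                      baseline_mv=baseline)


def count_spikelets(
    trace: Trace,
    start_idx: int,
    end_idx: int,
    baseline_mv: float,
    delta_threshold_mv: float = DELTA_THRESHOLD_MV,
    prominence_mv: float = SPIKELET_PROMINENCE_MV,
    separation_ms: float = SPIKELET_SEPARATION_MS,
) -> int:
    """Count spikelets in ``[start_idx, end_idx)`` of the trace.

    A spikelet is a local maximum exceeding baseline + threshold with
    prominence >= 5 mV, separated from its neighbours by >= 2 ms.  Any
    detected event crossed threshold at least once, so the count is never
    below one (plateau ripples of small prominence are ignored).
    """
    seg = trace.v_mv[start_idx:end_idx]
    if seg.size < 3:
        return 1
    distance = max(1, int(round(separation_ms * 1e-3 * trace.fs_hz)))
    peaks, _ = find_peaks(seg, height=baseline_mv + delta_threshold_mv,
                          prominence=prominence_mv, distance=distance)
    return max(1, int(peaks.size))


def classify_event(event: Event) -> str:
    """Spike if <= 100 ms; burst if > 100 ms with >= 2 spikelets; else other."""
    # epsilon keeps float noise from flipping the class at the boundary
    if event.duration_ms <= SPIKE_BURST_BOUNDARY_MS + 1e-9:
        return "spike"
    if event.n_spikelets >= MIN_SPIKELETS_PER_BURST:
        return "burst"
    return "other"


def _idx(trace: Trace, t: float) -> int:
    return int(round((t - trace.t0_s) * trace.fs_hz))


def spike_shape(trace: Trace, event: Event, baseline_mv: float) -> SpikeShape:
    """Shape metrics of a single spike.

    Width is measured at half of (peak - baseline); time-to-peak runs from
    the threshold crossing (event start) to the peak sample; AHP amplitude is
    baseline minus the minimum within 200 ms after the event's close, floored
    at zero, and flagged nan when the window runs past the end of the record.
    """
    v = trace.v_mv
    t = trace.t_s
    i0 = max(0, _idx(trace, event.start_s))
    i1 = min(v.size, _idx(trace, event.end_s) + 1)
    seg = v[i0:i1]
    if seg.size == 0:
        raise ValueError("event lies outside the trace")
    pk = int(np.argmax(seg))
    peak_v = float(seg[pk])
    half = baseline_mv + 0.5 * (peak_v - baseline_mv)

    # The half level can sit below the detection threshold, so walk outward
    # from the peak past the event bounds until the trace drops below it.
    left = i0 + pk
    while left > 0 and v[left - 1] >= half:
        left -= 1
    right = i0 + pk
    while right + 1 < v.size and v[right + 1] >= half:
        right += 1
    t_left = t[left]
    if left > 0:
        t_left = _interp_crossing(t[left - 1], v[left - 1],
                                  t[left], v[left], half)
    t_right = t[right]
    if right + 1 < v.size:
        t_right = _interp_crossing(t[right], v[right],
                                   t[right + 1], v[right + 1], half)
    width_ms = (t_right - t_left) * 1000.0

    time_to_peak_ms = (t[i0 + pk] - event.start_s) * 1000.0

    j0 = min(v.size, _idx(trace, event.end_s))
    j1 = _idx(trace, event.end_s + AHP_WINDOW_MS * 1e-3)
    if j1 > v.size:
        ahp = math.nan  # window truncated by end of record
    else:
        ahp = max(0.0, baseline_mv - float(v[j0:j1].min()))
    return SpikeShape(width_ms=width_ms,
                      time_to_peak_ms=max(0.0, time_to_peak_ms),
                      ahp_amplitude_mv=ahp,
                      peak_amplitude_mv=peak_v - baseline_mv)


def first_consecutive_spike_run(
    table: EventTable, n: int = N_SPIKES_FOR_CLASSIFICATION,
) -> list[Event]:
    """First run of ``n`` consecutive spike-class events, else empty list."""
    run: list[Event] = []
    for ev in table.events:
        if ev.klass == "spike":
            run.append(ev)
            if len(run) == n:
                return run
        else:
            run = []
    return []


def classify_cell_ab(
    shapes: Sequence[SpikeShape],
    a_threshold_mv: float = A_TYPE_AHP_MV,
    b_threshold_mv: float = B_TYPE_AHP_MV,
    n_required: int = N_SPIKES_FOR_CLASSIFICATION,
) -> ABClass:
    """A/B phenotype from the mean AHP of the first ``n_required`` spikes."""
    usable = [s for s in shapes if not math.isnan(s.ahp_amplitude_mv)]
    if len(usable) < n_required:
        mean = (float(np.mean([s.ahp_amplitude_mv for s in usable]))
                if usable else math.nan)
        return ABClass("none", mean, len(usable))
    used = usable[:n_required]
    mean = float(np.mean([s.ahp_amplitude_mv for s in used]))
    if mean > a_threshold_mv:
        label = "A"
    elif mean < b_threshold_mv:
        label = "B"
    else:
        label = "ambiguous"
    return ABClass(label, mean, len(used))


def classify_cell(trace: Trace, table: EventTable, **kwargs) -> ABClass:
    """Convenience: find the first 10-spike run and classify the cell."""
    run = first_consecutive_spike_run(
        table, kwargs.pop("n_required", N_SPIKES_FOR_CLASSIFICATION))
    shapes = [spike_shape(trace, ev, table.baseline_mv) for ev in run]
    return classify_cell_ab(shapes, n_required=len(run) or 1, **kwargs) \
        if len(run) >= N_SPIKES_FOR_CLASSIFICATION else \
        classify_cell_ab(shapes, **kwargs)


def membrane_potential(trace: Trace, window_ms: float = 50.0) -> float:
    """Membrane potential as the mean of three 50 ms window medians.

    Windows sit at the beginning, middle and end of the record; medians
    within each window reject any spike that happens to fall there.
    """
    v = trace.v_mv
    n = v.size
    if n < 3:
        raise ValueError("trace too short")
    w = max(1, int(round(window_ms * 1e-3 * trace.fs_hz)))
    w = min(w, n)
    mid0 = max(0, min(n - w, (n - w) // 2))
    pts = [float(np.median(v[0:w])),
           float(np.median(v[mid0:mid0 + w])),
           float(np.median(v[n - w:n]))]
    return float(np.mean(pts))


def burst_factor(table: EventTable) -> float:
    """Proportion of events that are bursts; nan for an empty table."""
    if len(table) == 0:
        return math.nan
    n_burst = len(table.of_class("burst"))
    return n_burst / len(table)


@dataclass
class CellSummary:
    """The 12 per-cell excitability parameters plus identifying metadata."""

    cell_id: str
    sex: str
    condition: str
    capacitance_pf: float
    membrane_potential_mv: float
    event_freq_hz: float
    spike_freq_hz: float
    burst_freq_hz: float
    event_duration_ms: float
    spike_duration_ms: float
    burst_duration_ms: float
    burst_factor: float
    active_time_frac: float
    event_amplitude_mv: float
    days_in_culture: float

    METRICS = ("capacitance_pf", "membrane_potential_mv", "event_freq_hz",
               "spike_freq_hz", "burst_freq_hz", "event_duration_ms",
               "spike_duration_ms", "burst_duration_ms", "burst_factor",
               "active_time_frac", "event_amplitude_mv", "days_in_culture")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("cell_id", "sex", "condition") + self.METRICS}


def summarize_cell(
    trace: Trace,
    table: EventTable,
    metadata: dict | None = None,
    analysis_duration_s: float | None = None,
) -> CellSummary:
    """Compute the 12 per-cell parameters from a detected event table.

    Frequencies are counts over the analysis duration; durations are
    class-wise means (nan when a class is absent); active time is the summed
    event duration divided by the analysis duration.
    """
    meta = dict(trace.metadata)
    if metadata:
        meta.update(metadata)
    dur = analysis_duration_s if analysis_duration_s is not None \
        else table.recording_duration_s
    if dur > trace.duration_s + 1e-9:
        raise ValueError("analysis window longer than the trace")

    evs = table.events
    spikes = table.of_class("spike")
    bursts = table.of_class("burst")

    def _mean_dur(lst: list[Event]) -> float:
        return float(np.mean([e.duration_ms for e in lst])) if lst else math.nan

    def _num(key: str) -> float:
        val = meta.get(key)
        return float(val) if val is not None else math.nan

    return CellSummary(
        cell_id=str(meta.get("cell_id") or ""),
        sex=str(meta.get("sex") or ""),
        condition=str(meta.get("condition") or ""),
        capacitance_pf=_num("capacitance_pf"),
        membrane_potential_mv=membrane_potential(trace),
        event_freq_hz=len(evs) / dur,
        spike_freq_hz=len(spikes) / dur,
        burst_freq_hz=len(bursts) / dur,
        event_duration_ms=_mean_dur(evs),
        spike_duration_ms=_mean_dur(spikes),
        burst_duration_ms=_mean_dur(bursts),
        burst_factor=burst_factor(table),
        active_time_frac=sum(e.duration_ms for e in evs) / 1000.0 / dur,
        event_amplitude_mv=(float(np.mean([e.amplitude_mv for e in evs]))
                            if evs else math.nan),
        days_in_culture=_num("days_in_culture"),
    )
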
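"""Synthetic current-clamp traces with ground-truth event labels.

Real corticotroph recordings are low-frequency (~0.5 Hz) trains of single
action potentials riding on a resting potential near −51 mV, sampled at
10 kHz with 2 kHz low-pass filtering.  Spikes come in two shapes: A-type
(sharp upstroke, deep afterhyperpolarization > 25 mV) and B-type (slower
time-to-peak, shallow AHP < 20 mV).  Secretagogue-stimulated cells either
speed up their spiking or transition to pseudo-plateau bursts — depolarized
events longer than 100 ms carrying two or more small spikelets.

This module generates traces with exactly that structure from parametric
piecewise-exponential templates placed by a renewal process, plus filtered
Gaussian noise, and records the ground truth (event boundaries, classes,
spikelet counts, cell phenotype) so detection and classification can be
validated without any recorded data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.signal import butter, sosfilt

from .events import Trace

__all__ = [
    "TraceSpec",
    "TruthEvent",
    "LabeledTrace",
    "GroupSpec",
    "CohortSpec",
    "spike_template",
    "burst_template",
    "make_trace",
    "make_cohort",
    "reference_cohort_spec",
    "CONDITION_RATES",
    "SPIKE_SHAPE_DEFAULTS",
]

# Detection geometry the generator guarantees (mirrors the events module).
_THR_MV = 20.0
_REARM_MV = 5.0

# Template shape defaults, relative to baseline (mV, ms).  A-type: sharp
# upstroke and AHP depth 30 mV (> the 25 mV A threshold); B-type: slower
# time-to-peak, wider, AHP depth 12 mV (< the 20 mV B threshold).  The
# ambiguous 20-25 mV AHP band is avoided by construction unless
# ``allow_ambiguous_ahp`` is set on the spec.
SPIKE_SHAPE_DEFAULTS = {
    "A": dict(peak_mv=32.0, ahp_mv=30.0, time_to_peak_ms=3.0,
              fall_ms=10.0, recover_ms=60.0),
    "B": dict(peak_mv=30.0, ahp_mv=12.0, time_to_peak_ms=9.0,
              fall_ms=15.0, recover_ms=50.0),
}

# Burst template geometry: depolarized plateau with spikelet bumps on top.
_BURST_PLATEAU_MV = 22.0
_BURST_SPIKELET_MV = 8.0   # bump height above plateau (prominence >= 5 mV)
_BURST_EDGE_MS = 3.0
_BURST_AHP_MV = 8.0

# Mean event rates (Hz) and burst fractions emulating the reported cohort
# conditions: basal rates 0.53 (male) / 0.70 (female); CRH-evoked bursting
# with burst factors 0.73 (male), 0.48 (female B-type), 0.64 (B-type with
# added BK conductance); CRH-evoked spiking as a rate increase without
# bursting.
CONDITION_RATES = {
    ("basal", "male"): dict(event_rate_hz=0.53, burst_fraction=0.0),
    ("basal", "female"): dict(event_rate_hz=0.70, burst_fraction=0.0),
    ("crh_spiking", "male"): dict(event_rate_hz=2.0, burst_fraction=0.0),
    ("crh_spiking", "female"): dict(event_rate_hz=2.0, burst_fraction=0.0),
    ("crh_bursting", "male"): dict(event_rate_hz=1.0, burst_fraction=0.73,
                                   burst_duration_ms=500.0, min_bursts=1),
    ("crh_bursting", "female"): dict(event_rate_hz=1.0, burst_fraction=0.48,
                                     burst_duration_ms=400.0, min_bursts=1),
    ("crh_bk", "male"): dict(event_rate_hz=1.0, burst_fraction=0.64,
                             burst_duration_ms=550.0, min_bursts=1),
    ("crh_bk", "female"): dict(event_rate_hz=1.0, burst_fraction=0.64,
                               burst_duration_ms=550.0, min_bursts=1),
}

# Capacitance distributions (pF) by sex, as reported for the two cohorts.
CAPACITANCE_PF = {"male": (4.41, 1.7), "female": (4.91, 2.1)}


@dataclass(frozen=True)
class TraceSpec:
    """Parameters of one synthetic recording."""

    duration_s: float = 62.0
    fs_hz: float = 10_000.0
    baseline_mv: float = -51.4
    noise_sd_mv: float = 0.8
    lowpass_hz: float = 2000.0
    event_rate_hz: float = 0.53
    spike_kind: str = "B"
    burst_fraction: float = 0.0
    burst_duration_ms: float = 200.0
    spikelets_per_burst: int = 3
    min_bursts: int = 0
    burst_free_head: int = 0  # first N events forced to spikes (clean epoch)
    amplitude_jitter_frac: float = 0.03
    allow_ambiguous_ahp: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.fs_hz <= 2 * self.lowpass_hz:
            raise ValueError("sampling rate must exceed twice the low-pass corner")
        if not 0.0 <= self.burst_fraction <= 1.0:
            raise ValueError("burst_fraction must lie in [0, 1]")
        if self.event_rate_hz < 0:
            raise ValueError("event rate must be non-negative")
        if self.spike_kind not in SPIKE_SHAPE_DEFAULTS:
            raise ValueError(f"spike_kind must be one of "
                             f"{sorted(SPIKE_SHAPE_DEFAULTS)}, got {self.spike_kind!r}")
        if self.spikelets_per_burst < 2:
            raise ValueError("bursts need at least 2 spikelets")
        if self.burst_duration_ms <= 100.0 and self.burst_fraction > 0:
            raise ValueError("burst duration must exceed 100 ms")


class TruthEvent(NamedTuple):
    start_s: float
    end_s: float
    klass: str
    n_spikelets: int


@dataclass
class LabeledTrace:
    trace: Trace
    truth_events: list[TruthEvent]
    truth_cell_class: str  # {"A", "B", "none"}

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.truth_events, self.truth_events[1:]):
            if nxt.start_s < prev.end_s:
                raise ValueError("truth events overlap or are out of order")


def spike_template(kind: str, fs_hz: float = 10_000.0, *,
                   peak_mv: float | None = None, ahp_mv: float | None = None,
                   time_to_peak_ms: float | None = None,
                   fall_ms: float | None = None,
                   recover_ms: float | None = None) -> np.ndarray:
    """Single-spike waveform (mV relative to baseline) for an A or B cell.

    Piecewise exponential: a rise reaching ``peak_mv`` at ``time_to_peak_ms``,
    an exponential fall to the AHP minimum ``-ahp_mv``, and an exponential
    recovery ending within 1 mV of baseline.
    """
    if kind not in SPIKE_SHAPE_DEFAULTS:
        raise ValueError(f"unknown spike kind {kind!r}")
    p = dict(SPIKE_SHAPE_DEFAULTS[kind])
    for name, val in dict(peak_mv=peak_mv, ahp_mv=ahp_mv,
                          time_to_peak_ms=time_to_peak_ms, fall_ms=fall_ms,
                          recover_ms=recover_ms).items():
        if val is not None:
            p[name] = val
    dt_ms = 1000.0 / fs_hz
    t_rise = np.arange(0.0, p["time_to_peak_ms"], dt_ms)
    tau_r = p["time_to_peak_ms"] / 3.0
    rise = p["peak_mv"] * (1 - np.exp(-t_rise / tau_r)) / (1 - math.exp(-p["time_to_peak_ms"] / tau_r))
    t_fall = np.arange(0.0, p["fall_ms"], dt_ms)
    tau_f = p["fall_ms"] / 5.0
    fall = -p["ahp_mv"] + (p["peak_mv"] + p["ahp_mv"]) * np.exp(-t_fall / tau_f)
    v_min = fall[-1] if t_fall.size else -p["ahp_mv"]
    t_rec = np.arange(0.0, p["recover_ms"], dt_ms)
    tau_rec = p["recover_ms"] / 4.0
    rec = v_min * np.exp(-t_rec / tau_rec)
    return np.concatenate([rise, fall, rec])


def burst_template(duration_ms: float, n_spikelets: int,
                   fs_hz: float = 10_000.0) -> np.ndarray:
    """Pseudo-plateau burst waveform (mV relative to baseline).

    A plateau 22 mV above baseline lasting ``duration_ms`` carries
    ``n_spikelets`` Gaussian bumps whose peaks exceed the detection threshold
    with >= 5 mV prominence; the plateau decays through a small AHP back to
    baseline.
    """
    if duration_ms <= 100.0:
        raise ValueError("a burst plateau must exceed 100 ms")
    if n_spikelets < 2:
        raise ValueError("a burst carries at least 2 spikelets")
    dt_ms = 1000.0 / fs_hz
    t_edge = np.arange(0.0, _BURST_EDGE_MS, dt_ms)
    rise = _BURST_PLATEAU_MV * (t_edge / _BURST_EDGE_MS)
    t_plat = np.arange(0.0, duration_ms, dt_ms)
    plat = np.full(t_plat.size, _BURST_PLATEAU_MV)
    centers = np.linspace(0.15, 0.85, n_spikelets) * duration_ms
    sigma_ms = min(4.0, duration_ms / (6.0 * n_spikelets))
    for c in centers:
        plat += _BURST_SPIKELET_MV * np.exp(-0.5 * ((t_plat - c) / sigma_ms) ** 2)
    t_fall = np.arange(0.0, 8.0, dt_ms)
    tau_f = 8.0 / 5.0
    fall = -_BURST_AHP_MV + (_BURST_PLATEAU_MV + _BURST_AHP_MV) * np.exp(-t_fall / tau_f)
    t_rec = np.arange(0.0, 40.0, dt_ms)
    rec = fall[-1] * np.exp(-t_rec / (40.0 / 4.0))
    return np.concatenate([rise, plat, fall, rec])


def _truth_bounds(template: np.ndarray, fs_hz: float) -> tuple[float, float]:
    """Threshold/re-arm crossing times (s, relative to template start).

    The generator guarantees every event template crosses baseline+20 mV on
    the way up and baseline+5 mV on the way down, so the boundaries the
    detector should report are a geometric property of the clean waveform.
    """
    above = template >= _THR_MV
    i_up = int(np.argmax(above))
    if not above.any():
        raise RuntimeError("template never crosses the detection threshold")
    t_up = i_up / fs_hz
    if i_up > 0:
        v0, v1 = template[i_up - 1], template[i_up]
        t_up = (i_up - 1 + (_THR_MV - v0) / (v1 - v0)) / fs_hz
    below = template < _REARM_MV
    below[:i_up] = False
    i_dn = int(np.argmax(below))
    v0, v1 = template[i_dn - 1], template[i_dn]
    t_dn = (i_dn - 1 + (_REARM_MV - v0) / (v1 - v0)) / fs_hz
    return t_up, t_dn


def _lowpass(noise: np.ndarray, fs_hz: float, lowpass_hz: float) -> np.ndarray:
    sos = butter(4, lowpass_hz, btype="low", fs=fs_hz, output="sos")
    return sosfilt(sos, noise)


def make_trace(spec: TraceSpec, metadata: dict | None = None) -> LabeledTrace:
    """Generate one labelled trace.

    Events are placed by a renewal process whose inter-event gap is a hard
    refractory period (the template length) plus an exponential draw chosen
    so the mean gap equals 1/rate.  Each event is a burst with probability
    ``burst_fraction``, otherwise a single spike of ``spike_kind``.  White
    Gaussian noise of sd ``noise_sd_mv`` is low-pass filtered at
    ``lowpass_hz`` and added after event placement.  Identical (spec, seed)
    gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs_hz
    n = int(round(spec.duration_s * fs))
    v = np.zeros(n)

    base_spike = spike_template(spec.spike_kind, fs)
    base_burst = (burst_template(spec.burst_duration_ms,
                                 spec.spikelets_per_burst, fs)
                  if spec.burst_fraction > 0 or spec.min_bursts > 0 else None)
    refr_samples = max(base_spike.size,
                       base_burst.size if base_burst is not None else 0)
    refractory_s = refr_samples / fs + 0.01

    truth: list[TruthEvent] = []
    if spec.event_rate_hz > 0:
        mean_gap = 1.0 / spec.event_rate_hz
        if mean_gap <= refractory_s:
            raise ValueError(
                f"event rate {spec.event_rate_hz} Hz is too high for the "
                f"{refractory_s * 1e3:.0f} ms refractory period of the "
                f"templates; the renewal process cannot achieve it")
        # Pre-draw classes so min_bursts can be enforced deterministically.
        n_max = int(spec.duration_s * spec.event_rate_hz * 3) + 20
        is_burst = rng.random(n_max) < spec.burst_fraction
        gaps = refractory_s + rng.exponential(mean_gap - refractory_s, n_max)
        t_next = rng.exponential(mean_gap)
        placed = 0
        starts: list[float] = []
        classes: list[bool] = []
        while t_next * fs + refr_samples < n and placed < n_max:
            starts.append(t_next)
            classes.append(bool(is_burst[placed]))
            t_next += gaps[placed]
            placed += 1
        head = min(spec.burst_free_head, len(classes))
        for i in range(head):
            classes[i] = False
        if sum(classes) < spec.min_bursts:
            need = spec.min_bursts - sum(classes)
            for i in range(head, len(classes)):
                if need == 0:
                    break
                if not classes[i]:
                    classes[i] = True
                    need -= 1
            for i in range(len(classes) - 1, -1, -1):  # short record fallback
                if need == 0:
                    break
                if not classes[i]:
                    classes[i] = True
                    need -= 1
        for t_start, burst in zip(starts, classes):
            i0 = int(round(t_start * fs))
            templ = base_burst if burst else base_spike
            jit = 1.0 + spec.amplitude_jitter_frac * rng.standard_normal()
            templ = templ * max(0.5, jit)
            seg = templ[: n - i0]
            v[i0:i0 + seg.size] += seg
            t_up, t_dn = _truth_bounds(templ, fs)
            truth.append(TruthEvent(
                start_s=t_start + t_up, end_s=t_start + t_dn,
                klass="burst" if burst else "spike",
                n_spikelets=spec.spikelets_per_burst if burst else 1))

    if spec.noise_sd_mv > 0:
        v += _lowpass(rng.standard_normal(n) * spec.noise_sd_mv,
                      fs, spec.lowpass_hz)
    v += spec.baseline_mv

    meta = {"fs_hz": fs, "seed": spec.seed}
    if metadata:
        meta.update(metadata)
    cell_class = spec.spike_kind if any(e.klass == "spike" for e in truth) \
        else "none"
    return LabeledTrace(trace=Trace(v_mv=v, fs_hz=fs, metadata=meta),
                        truth_events=truth, truth_cell_class=cell_class)


@dataclass(frozen=True)
class GroupSpec:
    """One sex-by-condition group of a synthetic cohort."""

    sex: str
    n_a: int
    n_b: int
    n_none: int = 0
    n_spont_bursting: int = 0  # subset of the B cells (A cells never burst)
    condition: str = "basal"
    duration_s: float = 62.0

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b, self.n_none, self.n_spont_bursting) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_spont_bursting > self.n_b:
            raise ValueError("bursting cells are a subset of the B cells")

    @property
    def n_cells(self) -> int:
        return self.n_a + self.n_b + self.n_none


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    seed: int = 0
    noise_sd_mv: float = 0.8


def reference_cohort_spec(seed: int = 0, condition: str = "basal") -> CohortSpec:
    """The default two-sex cohort: 29 male cells (3 A / 25 B / 1 neither,
    13 spontaneously bursting) and 30 female cells (12 A / 17 B / 1 neither,
    6 spontaneously bursting)."""
    return CohortSpec(groups=(
        GroupSpec(sex="male", n_a=3, n_b=25, n_none=1,
                  n_spont_bursting=13, condition=condition),
        GroupSpec(sex="female", n_a=12, n_b=17, n_none=1,
                  n_spont_bursting=6, condition=condition),
    ), seed=seed)


def make_cohort(spec: CohortSpec) -> list[LabeledTrace]:
    """Generate one labelled trace per cell with per-cell metadata.

    Truth class counts match the spec exactly.  Capacitance is drawn from the
    sex-specific normal (4.41 +/- 1.7 pF male, 4.91 +/- 2.1 pF female,
    clipped at 0.5 pF); days in culture are uniform on 1-4.  Spontaneously
    bursting B cells receive a small burst fraction with at least one burst
    guaranteed; all other cells emit single spikes only.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[LabeledTrace] = []
    cell_idx = 0
    for grp in spec.groups:
        cap_mean, cap_sd = CAPACITANCE_PF.get(grp.sex, (4.5, 1.8))
        roles = (["A"] * grp.n_a
                 + ["B_burst"] * grp.n_spont_bursting
                 + ["B"] * (grp.n_b - grp.n_spont_bursting)
                 + ["none"] * grp.n_none)
        for role in roles:
            cell_idx += 1
            seed_i = int(rng.integers(0, 2 ** 31 - 1))
            cond = dict(CONDITION_RATES.get((grp.condition, grp.sex),
                                            CONDITION_RATES[("basal", "male")]))
            kind = "A" if role == "A" else "B"
            kwargs = dict(duration_s=grp.duration_s,
                          noise_sd_mv=spec.noise_sd_mv,
                          spike_kind=kind, seed=seed_i, **cond)
            if role == "none":
                kwargs.update(event_rate_hz=0.0, burst_fraction=0.0,
                              min_bursts=0)
            elif role == "B_burst" and grp.condition == "basal":
                # A clean head of single spikes precedes any spontaneous
                # burst, so the basal A/B phenotype (10 consecutive spikes)
                # is always measurable in a >= 60 s record.
                kwargs.update(burst_fraction=0.10, min_bursts=1,
                              burst_duration_ms=180.0, burst_free_head=10)
            elif role == "A":
                # A-type cells do not burst, whatever the condition.
                kwargs.update(burst_fraction=0.0, min_bursts=0)
                if grp.condition in ("crh_bursting", "crh_bk"):
                    kwargs.update(event_rate_hz=2.0)
            meta = {
                "cell_id": f"{grp.sex}_{grp.condition}_{cell_idx:03d}",
                "sex": grp.sex,
                "condition": grp.condition,
                "capacitance_pf": float(max(0.5, rng.normal(cap_mean, cap_sd))),
                "days_in_culture": int(rng.integers(1, 5)),
                "spont_bursting": role == "B_burst",
            }
            out.append(make_trace(TraceSpec(**kwargs), metadata=meta))
    return out
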
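"""Spike detection, activity-state segmentation, trimodal period.

The activity labels follow the firing modes of the spontaneously active
Purkinje cell: *tonic* simple spiking, *burst* firing driven by dendritic
Ca spikes, *quiescent* hyperpolarised silence, and *depolarization_block*
(silence at a depolarised potential, furrowed by deflections conducted from
a still-spiking dendrite). Default rules (all configurable):

* spike: upward crossing of -20 mV (soma) with a 1 ms lockout; dendritic Ca
  spikes use a -30 mV threshold;
* silent interval (> 1 s without somatic spikes): quiescent if its mean V is
  below -50 mV, depolarization block otherwise;
* burst: >= 2 somatic spikes at inter-spike intervals < 30 ms inside a
  window containing a dendritic spike (when a dendritic channel is present);
* tonic: any remaining spiking stretch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import Trace

__all__ = [
    "SpikeTrain",
    "ActivitySegment",
    "ClassifierConfig",
    "detect_spikes",
    "classify_activity",
    "trimodal_period",
    "segments_to_frame",
]

TONIC = "tonic"
BURST = "burst"
QUIESCENT = "quiescent"
DEPOL_BLOCK = "depolarization_block"


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) for one compartment."""

    times_ms: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_ms, dtype=float)
        object.__setattr__(self, "times_ms", t)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self):
        return self.times_ms.size

    def rate_hz(self, duration_ms: float) -> float:
        return 1000.0 * len(self) / duration_ms if duration_ms > 0 else 0.0


@dataclass(frozen=True)
class ActivitySegment:
    start_ms: float
    end_ms: float
    label: str

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class ClassifierConfig:
    spike_threshold_mV: float = -20.0
    dend_spike_threshold_mV: float = -30.0
    lockout_ms: float = 1.0
    silent_gap_ms: float = 1000.0
    silent_split_mV: float = -50.0
    burst_isi_ms: float = 30.0
    burst_window_ms: float = 60.0   # half-width around a dendritic spike


def detect_spikes(
    v_mV: np.ndarray,
    dt_ms: float,
    threshold_mV: float = -20.0,
    lockout_ms: float = 1.0,
) -> SpikeTrain:
    """One event per upward threshold crossing, with a refractory lockout."""
    v = np.asarray(v_mV, dtype=float)
    if v.size < 2:
        return SpikeTrain(np.empty(0))
    crossings = np.flatnonzero((v[:-1] < threshold_mV) & (v[1:] >= threshold_mV)) + 1
    if crossings.size == 0:
        return SpikeTrain(np.empty(0))
    lockout = lockout_ms / dt_ms
    kept = [crossings[0]]
    for idx in crossings[1:]:
        if idx - kept[-1] >= lockout:
            kept.append(idx)
    return SpikeTrain(np.asarray(kept, dtype=float) * dt_ms)


def classify_activity(
    trace: Trace,
    spikes: SpikeTrain | None = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> list[ActivitySegment]:
    """Label the whole trace as ordered, non-overlapping activity segments."""
    v = trace.v_soma
    dt = trace.dt_ms
    total_ms = (len(v) - 1) * dt
    if spikes is None:
        spikes = detect_spikes(v, dt, config.spike_threshold_mV, config.lockout_ms)
    dend_spikes = None
    if "v_dend" in trace:
        dend_spikes = detect_spikes(
            trace.v_dend, dt, config.dend_spike_threshold_mV, config.lockout_ms
        )

    st = spikes.times_ms
    if st.size == 0:
        label = _silent_label(v, config)
        return [ActivitySegment(0.0, total_ms, label)]

    segments: list[ActivitySegment] = []

    # silent stretches: before the first spike, between spikes, after the last
    bounds = np.concatenate(([0.0], st, [total_ms]))
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1]
        is_edge = i == 0 or i == len(bounds) - 2
        gap_needed = config.silent_gap_ms
        if b - a >= gap_needed or (is_edge and b - a >= gap_needed):
            i0, i1 = int(a / dt), max(int(a / dt) + 1, int(b / dt))
            label = _silent_label(v[i0:i1], config)
            segments.append(ActivitySegment(a, b, label))

    # spiking stretches are the complement of the silent segments
    silent = sorted((s.start_ms, s.end_ms) for s in segments)
    spiking_regions = []
    cursor = 0.0
    for a, b in silent:
        if a > cursor:
            spiking_regions.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < total_ms:
        spiking_regions.append((cursor, total_ms))

    for a, b in spiking_regions:
        segments.extend(
            _split_spiking_region(a, b, st, dend_spikes, config)
        )

    segments.sort(key=lambda s: s.start_ms)
    return _coalesce(segments)


def _silent_label(v: np.ndarray, config: ClassifierConfig) -> str:
    if v.size == 0:
        return QUIESCENT
    return QUIESCENT if float(np.mean(v)) < config.silent_split_mV else DEPOL_BLOCK


def _split_spiking_region(a, b, spike_times, dend_spikes, config):
    in_region = spike_times[(spike_times >= a) & (spike_times <= b)]
    if in_region.size == 0:
        return [ActivitySegment(a, b, TONIC)]
    burst_mask = np.zeros(in_region.size, dtype=bool)
    if dend_spikes is not None and len(dend_spikes):
        ds = dend_spikes.times_ms
        # somatic spikes near a dendritic spike and in an ISI<threshold cluster
        isi_prev = np.diff(in_region, prepend=np.inf)
        isi_next = np.diff(in_region, append=np.inf)
        clustered = (isi_prev < config.burst_isi_ms) | (isi_next < config.burst_isi_ms)
        for i, t in enumerate(in_region):
            if not clustered[i]:
                continue
            j = np.searchsorted(ds, t)
            near = False
            if j < ds.size and abs(ds[j] - t) <= config.burst_window_ms:
                near = True
            if j > 0 and abs(ds[j - 1] - t) <= config.burst_window_ms:
                near = True
            burst_mask[i] = near
    segments = []
    seg_start = a
    cur_label = BURST if burst_mask[0] else TONIC
    for i in range(1, in_region.size):
        label = BURST if burst_mask[i] else TONIC
        if label != cur_label:
            boundary = 0.5 * (in_region[i - 1] + in_region[i])
            segments.append(ActivitySegment(seg_start, boundary, cur_label))
            seg_start = boundary
            cur_label = label
    segments.append(ActivitySegment(seg_start, b, cur_label))
    return segments


def _coalesce(segments):
    out = []
    for seg in segments:
        if out and out[-1].label == seg.label and abs(out[-1].end_ms - seg.start_ms) < 1e-9:
            out[-1] = ActivitySegment(out[-1].start_ms, seg.end_ms, seg.label)
        else:
            out.append(seg)
    return out


def trimodal_period(segments: list[ActivitySegment]) -> float | None:
    """Mean interval (s) between successive tonic onsets that begin a
    complete tonic -> ... -> quiescent cycle; None when no complete cycle."""
    onsets = []
    prev_label = None
    for seg in segments:
        if seg.label == TONIC and prev_label in (QUIESCENT, None):
            onsets.append(seg.start_ms)
        if seg.label in (TONIC, QUIESCENT, DEPOL_BLOCK):
            prev_label = seg.label
    # drop a leading onset at trace start only if it doesn't follow quiescence
    if len(onsets) >= 2:
        periods = np.diff(onsets)
        return float(np.mean(periods)) / 1000.0
    return None


def summarize_modes(
    segments: list[ActivitySegment], min_duration_ms: float = 500.0
) -> list[str]:
    """Collapse a segment list into a coarse mode sequence.

    Short segments are dropped; runs of tonic/burst count as "firing".
    A region where firing and quiescence alternate (at least two quiescent
    episodes flanked by firing) is reported as a single "bimodal" phase;
    otherwise firing regions are reported by their dominant label.
    """
    coarse = []
    for seg in segments:
        if seg.duration_ms < min_duration_ms:
            continue
        label = "firing" if seg.label in (TONIC, BURST) else seg.label
        if coarse and coarse[-1][0] == label:
            prev, dur = coarse[-1]
            coarse[-1] = (prev, dur + seg.duration_ms)
        else:
            coarse.append((label, seg.duration_ms))
    # detect alternation runs: firing Q firing Q ... (>= 2 quiescent episodes
    # strictly inside a firing context)
    out: list[str] = []
    i = 0
    while i < len(coarse):
        label = coarse[i][0]
        if label == "firing":
            j = i
            n_quiet = 0
            while j + 2 < len(coarse) and coarse[j + 1][0] == QUIESCENT \
                    and coarse[j + 2][0] == "firing":
                n_quiet += 1
                j += 2
            if n_quiet >= 2:
                # the trailing firing run is the sustained (tonic) phase
                out.append("bimodal")
                i = j
                continue
            out.append("tonic")
        else:
            out.append(label)
        i += 1
    # merge repeats produced by the collapse
    dedup = []
    for label in out:
        if not dedup or dedup[-1] != label:
            dedup.append(label)
    return dedup


def quiescent_durations(segments: list[ActivitySegment]) -> np.ndarray:
    """Durations (ms) of the quiescent episodes, in temporal order."""
    return np.array(
        [s.duration_ms for s in segments if s.label == QUIESCENT]
    )


def segments_to_frame(segments):
    import pandas as pd

    return pd.DataFrame(
        {
            "start_ms": [s.start_ms for s in segments],
            "end_ms": [s.end_ms for s in segments],
            "label": [s.label for s in segments],
        }
    )
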
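"""Synthetic fixtures: small branched trees and voltage traces with known
activity structure.

These generators define controlled inputs with hand-computable expectations:
trees whose collapse follows directly from the per-branch radii/lengths, and
traces assembled from spike templates whose ground-truth labels are emitted
alongside. Both are seeded and fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphology import Branch, MorphTree, Soma
from .trace import Trace
from .trace_analysis import ActivitySegment, BURST, DEPOL_BLOCK, QUIESCENT, TONIC

__all__ = ["gen_synthetic_tree", "SegmentPlan", "gen_synthetic_trace"]


def gen_synthetic_tree(
    n_branches: int,
    radius_range=(0.5, 3.0),
    length_range=(20.0, 200.0),
    seed: int = 0,
    radii=None,
    lengths=None,
) -> MorphTree:
    """Random (seeded) chain-topology dendritic tree.

    Explicit ``radii``/``lengths`` sequences override the random draw, giving
    fixtures whose equivalent cylinder is hand-computable.
    """
    if n_branches < 1:
        raise ValueError("need at least one branch")
    rng = np.random.default_rng(seed)
    if radii is None:
        radii = rng.uniform(*radius_range, size=n_branches)
    if lengths is None:
        lengths = rng.uniform(*length_range, size=n_branches)
    radii = np.asarray(radii, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if radii.size != n_branches or lengths.size != n_branches:
        raise ValueError("radii/lengths must match n_branches")
    branches = [
        Branch(id=i + 2, parent_id=i + 1, radius_um=float(radii[i]),
               length_um=float(lengths[i]))
        for i in range(n_branches)
    ]
    return MorphTree(branches=branches, soma=Soma())


# ---------------------------------------------------------------------------
# Trace synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentPlan:
    """One planned activity block."""

    label: str
    duration_s: float
    rate_hz: float = 40.0          # tonic spike rate
    burst_rate_hz: float = 2.0     # dendritic-spike (burst) rate
    spikes_per_burst: int = 4


_BASELINES = {TONIC: -55.0, BURST: -55.0, QUIESCENT: -70.0, DEPOL_BLOCK: -40.0}


def _spike_template(dt_ms: float, peak_mV: float, base_mV: float, width_ms=1.6):
    n = max(3, int(round(width_ms / dt_ms)))
    rise = n // 3
    tpl = np.empty(n)
    tpl[:rise] = np.linspace(base_mV, peak_mV, rise, endpoint=False)
    tpl[rise:] = np.linspace(peak_mV, base_mV, n - rise)
    return tpl


def gen_synthetic_trace(
    plan, seed: int = 0, dt_ms: float = 0.1, noise_mV: float = 0.3
):
    """Assemble a soma+dendrite trace from an activity plan.

    Returns ``(trace, truth)`` where ``truth`` is the list of ground-truth
    ActivitySegments matching the plan. Tonic blocks place regular somatic
    spikes; burst blocks place dendritic Ca spikes, each topped by a fast
    somatic spike cluster; quiescent and depolarization-block plateaus sit at
    -70 and -40 mV (the latter rippled by conducted dendritic deflections).
    """
    plan = [p if isinstance(p, SegmentPlan) else SegmentPlan(*p) for p in plan]
    rng = np.random.default_rng(seed)
    n_total = int(round(sum(p.duration_s for p in plan) * 1000.0 / dt_ms)) + 1
    v_s = np.full(n_total, -70.0)
    v_d = np.full(n_total, -70.0)
    truth: list[ActivitySegment] = []

    soma_spike = _spike_template(dt_ms, 15.0, -55.0)
    dend_spike = _spike_template(dt_ms, -5.0, -60.0, width_ms=8.0)

    cursor = 0
    t_cursor = 0.0
    for p in plan:
        n = int(round(p.duration_s * 1000.0 / dt_ms))
        sl = slice(cursor, cursor + n)
        base = _BASELINES[p.label]
        v_s[sl] = base
        v_d[sl] = -60.0 if p.label == BURST else -65.0
        if p.label == TONIC:
            period = int(round(1000.0 / p.rate_hz / dt_ms))
            for start in range(period // 2, n - len(soma_spike), period):
                v_s[cursor + start:cursor + start + len(soma_spike)] = soma_spike
        elif p.label == BURST:
            period = int(round(1000.0 / p.burst_rate_hz / dt_ms))
            isi = int(round(8.0 / dt_ms))
            for start in range(period // 2, n - len(dend_spike), period):
                v_d[cursor + start:cursor + start + len(dend_spike)] = dend_spike
                for k in range(p.spikes_per_burst):
                    s0 = cursor + start + k * isi
                    if s0 + len(soma_spike) < cursor + n:
                        v_s[s0:s0 + len(soma_spike)] = soma_spike
        elif p.label == DEPOL_BLOCK:
            tt = np.arange(n) * dt_ms
            v_s[sl] += 2.0 * np.sin(2.0 * np.pi * tt / 500.0)  # small furrows
            period = int(round(1000.0 / p.burst_rate_hz / dt_ms))
            for start in range(period // 2, n - len(dend_spike), period):
                v_d[cursor + start:cursor + start + len(dend_spike)] = dend_spike
        truth.append(
            ActivitySegment(t_cursor, t_cursor + p.duration_s * 1000.0, p.label)
        )
        cursor += n
        t_cursor += p.duration_s * 1000.0

    v_s += rng.normal(0.0, noise_mV, size=n_total)
    v_d += rng.normal(0.0, noise_mV, size=n_total)
    trace = Trace(
        dt_ms=dt_ms,
        channels={"v_soma": v_s, "v_dend": v_d},
        meta={"synthetic": True, "seed": seed},
    )
    return trace, truth
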
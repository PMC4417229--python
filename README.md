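# purkinje2c

A two-compartment biophysical model of the cerebellar Purkinje neuron, with
the dendritic-tree reduction algorithm that produces it, the full ionic
mechanism roster, in-silico pharmacology/knockout protocols, and trace
analysis.

## The problem

Cerebellar Purkinje cells in slice fire spontaneously in a repeating
*trimodal* motif — tonic simple spiking, dendritically driven bursting, and
quiescence — with a repeat period of tens of seconds. Morphologically
detailed compartmental models reproduce this but are far too expensive for
network studies. This package implements a reduced surrogate: a somatic
cylinder (22 × 22 µm) coupled to a single dendritic equivalent cylinder
(529.29 × 3.22 µm), carrying the detailed model's mechanisms at rescaled
densities. It is intended for computational neuroscientists who need a
Purkinje cell cheap enough for network embedding, or a sandbox for the
pump-centric hypotheses the model encodes (e.g. alcohol action via Na⁺/K⁺
pump inhibition).

## The model

**Reduction.** A dendritic arbour of branches with radii *rᵢ* and lengths
*lᵢ* is collapsed to one cylinder conserving axial resistance:

    R = √(Σᵢ rᵢ²),    l = Σᵢ lᵢ rᵢ / Σᵢ rᵢ,    V = π R² l

The cylinder is then re-lengthed at constant volume, R′ = √(V/(π l′)), to
restore soma–dendrite electrotonic separation, and membrane densities are
rescaled by the dendritic correction factor *C_d* = (arbour area)/(cylinder
lateral area) = 42 310/6 874 ≈ 6.16, applied to every dendritic g_max, to
C_m and to the Ca²⁺ shell depth. The soma never enters the collapse.

**Membrane.** Per compartment, C_m dV/dt = −Σ I_ionic + I_axial, with
I_axial = (V_other − V)/(R_axial·A) and R_axial built from the two
half-cylinder core resistances (Ra = 35.4 Ω·cm). The soma carries a 13-state
Markov resurgent Na⁺ channel (closed chain C1–C5, open O, open-blocked OB,
inactivated I1–I6), three voltage-gated K⁺ currents, BK and SK, a GHK-form
P-type Ca²⁺ current, HCN and leak. The dendrite carries T-, E- and P-type
Ca²⁺ currents (fixed E_Ca = +135 mV), A-, D-, M-type, delayed-rectifier,
Kv1.2, BK and K2 K⁺ currents, HCN and leak. Both compartments have an
electrogenic Na⁺/K⁺ pump pair (3 Na⁺ out : 2 K⁺ in) and a Na⁺/Ca²⁺
exchanger (3 Na⁺ in : 1 Ca²⁺ out, net depolarising).

**Slow dynamics.** Submembrane Ca²⁺ shells gate BK/SK/K2; intracellular Na⁺
integrates the (5-s-lagged) net Na⁺ current and gates the somatic pump
around its affinity constant K_Na = 40 mM; extracellular K⁺ accumulates in a
70-nm dendritic shell (clamped to 2–3.03 mM) and moves the dendritic E_K.
These loops generate the slow firing-mode alternation without any stimulus.

## Worked example

```python
from purkinje2c import SimConfig, simulate
from purkinje2c.trace_analysis import classify_activity, trimodal_period

trace = simulate(SimConfig(duration_ms=120000.0, stride=40))
window = trace.window(30000.0, trace.duration_ms)
period = trimodal_period(classify_activity(window))
print(f"repeat period: {period:.1f} s")
```

prints

    repeat period: 23.5 s

the interval between successive tonic-phase onsets of the spontaneous motif
(the published detailed model repeats at roughly 20 s). The narrative
scripts in `examples/` each print what they compute: `02_spontaneous_firing`
shows the segment sequence (e.g. `T20.3s Q6.6s T19.8s …`) and the [Na]ᵢ
excursion (≈25–39 mM) pacing the cycle; `03_pump_affinity_switch` shows that
lowering K_Na from 40 to 12 mM silences the cell (96 → 0 spikes/30 s);
`04_alcohol_block` runs the progressive pump-block protocol into
depolarisation block with the dendrite still firing; `05_bk_knockout_erg`
shows the BK-knockout dual plateau (soma −27 mV, dendrite +34 mV).

A thin CLI wraps the same library calls:

```bash
purkinje2c reduce --swc tree.swc --length 529.29
purkinje2c simulate --duration 60 --out run/
purkinje2c protocol alcohol --duration 120 --out run/
purkinje2c analyze --trace run/trace.csv --report report/
```

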
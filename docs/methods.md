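# Methods

## Units and conventions

Internal units are mV, ms, mS/cm², µA/cm², mM, µm; membrane currents are
positive outward. Pump and exchanger densities are quoted in mA/cm² (the
convention of their source descriptions) and converted at load. Somatic gate
time constants are published in seconds and converted to ms; dendritic
rate constants are in ms⁻¹ as published. Temperature is 36 °C; most
dendritic kinetics carry a Q10 factor 3^((T−37)/10), Kv1.2 uses
3^((T−22)/10), and the M-type factor 2.3^((T−36)/10) is unity.

Steady states published in the form 1/exp(−(V−V½)/k) are implemented as
Boltzmann sigmoids 1/(1+exp(−(V−V½)/k)); the literal form exceeds one above
V½ and cannot be an occupancy. `mechanisms.gate_inf_tau(..., literal=True)`
evaluates the uncorrected form for audit.

## Integration scheme

Fixed-step integration at dt = 25 µs throughout, ordered within a step as:
(1) gate and Markov updates at the old voltage; (2) current evaluation with
the fresh gates at the old voltage; (3) voltage update; (4) ion-pool updates
and catch clamps; (5) reversal-potential refresh.

* H–H gates relax exponentially, x ← x + (1−e^(−dt/τ))(x∞−x), with
  coefficients frozen over the step — exact for frozen coefficients and
  unconditionally stable. Mechanisms whose source prescribes explicit
  relaxation factors with extra divisors (E-type Ca /4 and /10, D-type /10
  and ×1.6, delayed rectifier, BK m, K2 m) are expressed through the
  equivalent effective time constant, reproducing those factors exactly.
* The 13-state resurgent-Na scheme is advanced by backward Euler (one 13×13
  Gaussian elimination per step; the matrix is strictly column-diagonally
  dominant, so no pivoting is needed). Its transition rates reach ~10³ ms⁻¹
  at depolarised potentials (dt·rate ≫ 1), which rules out explicit
  stepping at this dt; the implicit step conserves total occupancy exactly
  (the generator's columns sum to zero) and preserves non-negativity. A
  final renormalisation pins Σoccupancy = 1 to 10⁻¹⁰.
* Voltages use a linearised-implicit (backward-Euler-style) update: ohmic
  currents contribute frozen conductance/reversal pairs, the non-ohmic
  terms (GHK Ca flux, pumps, exchangers) enter as frozen sources, and the
  two membrane equations plus the axial coupling are solved as one 2×2
  linear system. This is unconditionally stable at the tens of mS/cm²
  reached during spikes. Halving dt leaves early spike times (aligned on
  firing onset) within 0.8 ms.
* Ion pools use explicit Euler with hard catch clamps: somatic shell
  Ca ≥ 100 nM, [Na]ᵢ ≥ 10 mM, E_Na ≥ +70 mV, 2 ≤ [K]ₒ ≤ 3.03 mM. The
  clamps hold at every step; note the published initial somatic Ca (50 nM)
  itself lies below the floor, so the floor engages at the first step.

Degenerate inputs: the somatic pump's (V+80) factor is guarded to
±0.01 mV around its zero; the GHK flux and the delayed-rectifier α use
series branches at their removable singularities (V = 0 and V = −55 mV); a
non-finite voltage aborts the run with the failure time.

## Parameters

Defaults are the published density table: soma (mS/cm²) — resurgent Na 15.6,
fast/mid/slow K 41.6/20.8/41.6, BK 72.86, SK 1.0, P-type Ca 0.52 (GHK,
P = 5×10⁻⁵ cm/s), HCN 1.04, leak 0.1; dendrite — the detailed model's
densities times C_d = 6.16 (e.g. A-type 32 → 197.12). Pumps: somatic
saturating pump 1 mA/cm² gated by [Na]ᵢ around K_Na = 40 mM (slope 1 mM)
with voltage factor (V+75)/(V+80); dendritic saturating pump 0.001 mA/cm²,
half-active at [K]ₒ = 2.245 mM; counterbalance pairs g_ex/g_pump =
0.511/0.5 mA/cm² (soma; the 0.011 mismatch admits a slow Na influx) and
0.0021/0.0021 (dendrite, exact cancellation). Na lag τ = 5 s (a 200 000
-sample FIFO at dt = 25 µs); K accumulation factor Q = 0.0119 in a 70-nm
shell. The longitudinal Na diffusion term is omitted (its stated effect is
negligible); no synaptic input is modelled.

Two published figures required interpretation beyond face value; each was
resolved once and fixed as a default:

* **SK density 1.0 mS/cm².** The published table's SK row is ambiguous at
  the decade level; at 10 mS/cm² the SK current, standing at ~7% activation
  on the 100-nM Ca floor, is a 0.7 mS/cm² K leak that makes somatic firing
  impossible under any conditions. 1.0 mS/cm² leaves SK a spike-triggered
  AHP current, which is both the physiological picture and the only reading
  consistent with spontaneous firing.
* **Dendritic E_K closure, K_i = 45 mM.** [K]ₒ must move the dendritic E_K
  (that is its only coupling to excitability), but the intracellular K that
  closes the Nernst relation is not published. K_i = 45 mM maps the [K]ₒ
  catch range 2–3.03 mM to E_K = −82.9…−71.9 mV, placing the dendritic
  Ca-spike threshold inside the operating range so that K⁺ accumulation
  during firing recruits the dendrite and quiescence releases it. (An
  anchor at the −77 mV initialisation value leaves the dendrite firing
  continuously; anchors beyond ≈ −85 mV silence it permanently.)

## Protocols

* **Pump block ("alcohol"):** the somatic saturating pump declines as
  d(0) − 0.014·t (mA·cm⁻²·s⁻¹) from t = 0; the dendritic saturating pump
  and both counterbalance pump densities decline as d(0) − 0.005·(t−50 s)
  after onset; all densities floor at zero, the exchangers are untouched.
  Run on the K_Na = 12 mM background (quiescent start).
* **K_Na switch:** replaces the somatic pump affinity constant (40 → 12 mM
  switches the model from the spontaneous motif into quiescence).
* **BK knockout:** zeroes BK in both compartments.
* **ERG insertion:** adds the ERG K⁺ current (activation V½ = −5 mV, slope
  5; fast inactivation) to the dendrite at 0.5·C_d = 3.08 mS/cm².

## Synthetic data

`synth.gen_synthetic_tree` builds seeded chain-topology trees with known
per-branch radii/lengths, so the equivalent-cylinder result is
hand-computable; it writes standard 7-column SWC. `synth.gen_synthetic_trace`
assembles soma/dendrite voltage traces from spike templates and plateaus
with emitted ground-truth labels (tonic trains, dendritic-Ca-spike-topped
burst clusters, hyperpolarised quiescence, rippled depolarised block) plus
seeded Gaussian noise. These fixtures exercise the reduction arithmetic and
the classifier rules; they do not emulate channel noise, electrode artefacts
or the spike-shape diversity of real recordings, so passing them validates
the algorithms' logic, not their robustness to experimental data.

## Trace analysis

Spikes are upward threshold crossings (−20 mV soma, −30 mV dendritic Ca
spikes) with a 1-ms lockout. Silent intervals (> 1 s without somatic spikes)
are quiescent below a −50 mV mean and depolarisation block above it; somatic
spikes in ISI < 30 ms clusters within ±60 ms of a dendritic spike are
burst; remaining spiking is tonic. All thresholds are configurable
(`ClassifierConfig`). The motif period is the mean interval between
successive tonic onsets that follow quiescence; measurements discard a 30-s
settle window because [Na]ᵢ starts at its 10-mM floor and the first one to
two cycles are longer than the limit cycle.

## Known limitations

* The reconstructed operating point is **dendrite-led**: during the active
  phase, high-threshold dendritic Ca spikes accompany somatic firing
  throughout rather than appearing only in a late burst mode. The repeat
  period of the active/quiescent alternation is 23–24 s. A pure somatic
  tonic mode with a silent dendrite requires a dendritic stability margin
  of a few µA/cm² that the published kinetics do not pin down.
* Consequently the pump-block cascade resolves as quiescent → firing →
  depolarisation block; a bimodal (tonic/quiescent alternation) phase with
  successively shorter quiescent periods does not separate out.
* The ERG insertion does not rescue the BK-knockout block here: at the
  knockout plateau (+20…+34 mV) the printed ERG inactivation leaves ~0.5%
  of the inserted conductance (≈0.02 mS/cm²) against several mS/cm² of
  P-type Ca conductance. These three behaviours are asserted as written in
  `tests/test_acceptance.py` and deliberately left failing.
* Only the two-compartment model is simulated; the reduction tooling
  accepts arbitrary SWC morphologies but no multi-compartment simulation is
  provided. Voltages are single-valued per compartment.
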
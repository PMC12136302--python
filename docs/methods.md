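# Methods

## Model and assumptions

The simulator is a Wilson–Cowan–Amari-type neural field in one spatial
dimension, extended with a humoral variable: extracellular potassium obeys
a reaction–diffusion equation and feeds back on both populations.  The key
assumptions:

* **1D symmetric propagation.**  CSD is assumed to propagate horizontally
  and symmetrically within a cortical layer, so the patch is a segment
  Q = [−Lx, Lx] and every analysis uses only the rightward front.
* **Potassium-gated firing regimes.**  The firing-rate transfer function
  has three potassium regimes — normal (cap ½), hyperactive (cap 1, for
  k1\* ≤ k ≤ k2\*) and depolarization block (rate 0 above k2\*).  The
  discontinuities in k are kept as written: the threshold effect *is* the
  mechanism of the block, so no smoothing is applied.  Both boundary points
  belong to the middle branch.
* **Potassium drive and production.**  Elevated potassium depolarizes both
  populations through a sigmoid g_v that depends on k only (its v argument
  is kept for signature symmetry).  Population firing releases potassium
  through g_k(s) = a·cosh(b(s − c·s\*)); production is strictly positive
  (floor a), so total potassium can only grow — the model has no clearance
  mechanism.  Consequently every configuration eventually ignites globally;
  the reference horizon is chosen so the background stays well below the
  drive threshold over the full run (≥ 0.35 concentration units of margin
  in every shipped condition).
* **Wave mechanism.**  The puff blocks a central core; the hyperactive
  annulus at the core's edge fires near its potassium-boosted ceiling and
  releases potassium, which diffuses outward and recruits the next nodes.
  Inhibition throttles the annulus firing level, which is why reducing the
  inhibitory synaptic weights (the gabazine conditions) speeds the wave,
  and why the interneurons' own potassium contribution (c2) matters only
  once their synaptic inhibition is reduced.

## Discretization and integration

* **Nonlocal term.**  Rectangle-rule quadrature of the kernel integral on
  the truncated axis (dense N×N matrix, precomputed once; no periodic
  wrap).  Kernel mass lost at the boundaries is accepted; all measurements
  stay in the interior.
* **Diffusion.**  Central second difference with sealed (no-flux) ends in
  flux form — the one-sided boundary difference makes the discrete mass sum
  telescope to zero exactly, so potassium conservation under pure diffusion
  is testable to rounding.
* **Integrator.**  Fixed-step classical RK4.  Adaptive error estimators are
  unreliable across the transfer function's k-discontinuities; instead the
  step is validated by convergence tests (halving dt changes the measured
  control speed by < 1%; doubling N changes it by ≈ 4.5%).  The integrator
  refuses dt above 0.9× the explicit diffusion bound τh²/(2δ) and raises a
  divergence error naming the first non-finite time.
* **Guards.**  Sigmoid exponents are clipped at |x| = 500 (value change
  < 1e−217); the cosh argument at 700, past which the divergence check
  takes over.

## Reference configuration and calibration

Only a handful of constants are fixed by the source experiments
(c_ee = c_ie = 1, c_ei = c_ii = 15, c1 = c2 = 15, τ = 0.15 in the control
condition).  Everything else is frozen in the shipped reference config
(`csdwave.config`), tuned once against exactly two anchors:

1. **Control speed.**  The control run's model-unit speed (0.275 grid
   units per time unit) is mapped to 2.2 mm/min by the unit calibration
   (mm_per_grid_unit = 2.2/(60·0.275) ≈ 0.1333, seconds_per_time_unit = 1).
2. **Bifurcation point.**  The model is exactly invariant under a global
   rescale of the potassium dimension (k-valued parameters ×λ, drive
   sharpnesses ÷λ), which moves the quiescent↔propagating transition of
   kv\* without changing any speed.  λ = 0.709 places the transition at
   1.5.

All other reported numbers (gabazine 3.33 mm/min, gabazine+light
4.73 mm/min, the c2 ≈ 56 recovering 5 mm/min) are measured outcomes of the
frozen config, not tuning targets.

Key frozen parameters (model units):

| parameter | value | role |
|---|---|---|
| β_e = β_i | 10 | firing sigmoid sharpness |
| h_e, h_i | 0.3, 0.38 | half-response voltages; the small E/I offset weakens interneuron recruitment at the front and thereby sets the strength of the c2 lever |
| k1\*, k2\* | 0.709, 1.418 | potassium regime thresholds (both populations) |
| β_ve = β_vi | 7.052 | drive sharpness (soft enough that the front tracks the drive quasi-statically — a numerical-convergence requirement) |
| kv\* | 0.851 | drive threshold, control value (below the 1.5 transition) |
| a, b, c | 3.545e−5, 12, 0 | production floor, sharpness, reference shift |
| v\*, s\* | 1.0, σ(β(v\*−h)) | reference voltage / rate (recomputed, never cached) |
| δ | 0.2 | potassium diffusion constant |
| grid | Lx = 20, N = 201 (h_x = 0.2) | propagation axis |
| stimulus | amp 3.545, width 1, duration 0.5, centered | potassium puff |
| integration | dt = 0.005, t_final = 24, snapshot every 1.0 | horizon keeps background drift subcritical |
| threshold | 0.5 | wavefront detection level, midway between the resting (≈0) and depolarized-plateau (≈1) excitatory potential |
| reach fraction | 0.15 | minimum half-axis coverage for the "propagating" label |
| probe offset | +25 nodes | bifurcation-diagram probe |

## Condition presets

gabazine (c_ei = c_ii = 11) and gabazine+light (10.5 with c2 = 49) use the
reported experimental mapping.  The isoguvacine and light magnitudes are not pinned down by the experimental reports; iso
raises c_ei = c_ii to 20, and light uses c_ei = c_ii = 17 with c2 = 25 —
the point on the measured compensation contour where the two opposing
effects (more synaptic inhibition, more interneuronal potassium) cancel
and the speed equals control, which is the reported qualitative outcome of
the light condition.  Both presets are overridable per run.

## Speed estimators

The headline estimator uses only the final front position and the full
horizon, so it folds the initiation latency into the average.  A
least-squares front-tracking slope over the second half of the run is
reported alongside.  On the reference run the two disagree (~0.275 vs
~0.10 model units): the simulated wave decelerates after the stimulated
ignition rather than settling into a constant-velocity regime, and the
final-front estimator is dominated by the fast early phase.  All
cross-condition comparisons and all headline numbers use the final-front
estimator consistently, so condition ratios compare like with like.

## What the simulations do and do not emulate

The simulation reproduces: focal ignition by a potassium puff, a
propagating depolarization-block front with a potassium plateau behind it,
control-speed calibration at 2.2 mm/min, the speed-up under disinhibition
and its potentiation by interneuron activation, the null effect of the
light condition, a monotone moderate speed increase with c2, and a sharp
quiescent↔propagating transition in kv\*.

It does not emulate: LFP/DC-shift waveforms or intrinsic optical signals,
2D front geometry, potassium clearance (glial buffering; hence unbounded
potassium growth), or the *saturation plateau* of speed for inhibitory
weights above control — in this implementation the speed keeps declining
(decelerating, all conditions still propagating) as c_ei = c_ii grows from
15 to 25, by ≈27% in total, rather than flattening within 5%.  With the
single shared cosh production channel, the exponential fuel differential
needed for the gabazine speed-up and a flat response above control weights
are structurally in tension; the corresponding acceptance check is left
failing by design rather than weakening the claim.  Passing tests on this
synthetic system therefore validate the mechanism and the relative
pharmacological effects, not quantitative agreement with slice physiology
outside the calibrated anchors.

## Degenerate inputs and tie-breaks

Wavefront detection returns the *largest* suprathreshold index at or right
of the center node (odd N keeps a node exactly at x = 0); absence of a
front raises a measurement error, while sweeps record such failures as
missing points instead of aborting.  A bifurcation scan with more than one
label change attaches a multistability warning and reports the midpoint of
the *last* change.  Node extrema discard a configurable initial fraction
of the horizon before taking max/min.  Config validation is strict:
unknown keys, non-positive scales, inverted thresholds (k2\* ≤ k1\*),
v\* ≤ h and resting potassium at or above k1\* are all rejected with the
offending field named.
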
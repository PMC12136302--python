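# csdwave

A potassium-coupled neural field simulator of **cortical spreading
depolarization (CSD)** — the slow wave of massive neuronal depolarization
and transient silencing implicated in migraine aura.  The package simulates
CSD ignition by a focal potassium puff, its propagation along a 1D cortical
axis, the dependence of propagation speed on GABAergic synaptic weights and
on the potassium released by interneuron spiking (mimicking gabazine,
isoguvacine and optogenetic activation of GABAergic neurons), and the
bifurcation between quiescent and wave-supporting regimes.

## Model

Average membrane potentials of excitatory (`v_e`) and inhibitory (`v_i`)
populations on the axis Q = [-Lx, Lx] are coupled to a reaction–diffusion
equation for extracellular potassium `k`:

    τ ∂v_e/∂t = -v_e + c_ee S_e - c_ei S_i + g_v(v_e, k; β_ve, k_v*)
    τ ∂v_i/∂t = -v_i + c_ie S_e - c_ii S_i + g_v(v_i, k; β_vi, k_v*)
    τ ∂k/∂t   = δ ∂²k/∂x² + c1 g_k(s_e, s_e*) + c2 g_k(s_i, s_i*) + I(x, t)

with nonlocal interactions `S_α(x) = ∫_Q w(x−y) s_α(v_α(y), k(y)) dy`,
Gaussian connectivity kernel `w(d) = ½ e^{−d²}`, and three nonlinearities:

* `s_α(v, k)` — a firing-rate sigmoid whose ceiling depends on potassium:
  cap ½ for `k < k1*` (normal activity), cap 1 for `k1* ≤ k ≤ k2*`
  (hyperactivity), and exactly 0 for `k > k2*` (depolarization block — the
  CSD core);
* `g_v(k) = σ(β_v (k − k_v*))` — depolarizing drive of extracellular
  potassium on both populations;
* `g_k(s, s*) = a cosh(b (s − c s*))` — potassium release by population
  firing, the fuel of the traveling wave.

A focal puff `I` raises `k` at the center past the block threshold; the
hyperactive ring around the blocked core releases potassium, diffusion
carries it outward, and a depolarization-block front travels toward the
boundaries.  The front position is read off the excitatory potential at a
fixed threshold and the speed is `ν = h_x (n_th − N//2) / t_F` from the
final front index, converted to mm/min by the shipped unit calibration.

## Worked example

```bash
$ csdwave condition control --out out/ctrl
2.2000
$ csdwave condition gbz --out out/gbz          # gabazine: c_ei = c_ii = 11
3.3333
$ csdwave condition gbz_light --out out/gl     # + light: c_ei = c_ii = 10.5, c2 = 49
4.7333
```

Each number is the CSD propagation speed in mm/min under the frozen
reference configuration (201 nodes).  Blocking GABA-A receptors (gabazine,
modeled as reduced inhibitory synaptic weights) speeds the wave ~1.5-fold;
adding optogenetic activation of the (disinhibited) GABAergic population
(modeled as a larger interneuronal potassium contribution `c2`) speeds it
further — interneuron spiking feeds the wave with potassium once its
synaptic inhibition is disarmed.  The same workflow in Python:

```python
from csdwave import RunConfig, apply_condition, measure_speed
cfg = RunConfig.reference()
m = measure_speed(apply_condition(cfg, "gbz"))
print(m.speed_mm_per_min)       # 3.3333...
```

Other entry points: `csdwave simulate` (trajectory + space–time heatmaps),
`csdwave sweep --parameter coupling.c2 --values 15,25,35,49` (speed vs
parameter curves), `csdwave bifurcate --kv-values 1.4,1.45,...` (regime
diagram over the potassium-drive threshold `k_v*`).

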
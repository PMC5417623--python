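# phasic — noise-enhanced coding in phasic neuron models

Phasic (Class III) neurons — common in the auditory brainstem and spinal
cord — spike at stimulus onsets and to fast inputs, but a slow depolarizing
input of *any* amplitude fails to drive them: a subthreshold negative
feedback cancels it first.  Yet in the presence of moderate broadband
noise these neurons phase-lock well to slow signals.  `phasic` is a
toolkit for studying this noise-enhanced code at two levels:

1. **A planar stochastic neuron model** — an augmented FitzHugh–Nagumo
   system with a vertical recovery nullcline and (optionally) a
   voltage-dependent recovery rate ε(v),

       τ_v dv/dt = v(0.1 − v)(v − 1) − w + A sin(2πφt) + √(2D) ξ(t),
           dw/dt = ε(v) v,

   with Euler–Maruyama ensemble simulation, spike detection on the
   recovery variable, firing rates ν, phase densities p(ψ), vector
   strength r, the coding measure q = νr, spike-triggered averages,
   spectra, and deterministic phase-plane analysis (separatrix and
   threshold-distance traces).

2. **A reduced two-barrier renewal model** — escapes over a left barrier
   (ΔU_L, the hyperpolarizing excursion that primes the cell) reset the
   clock of a damped-oscillatory right barrier ΔU_R(t) (the spike
   threshold), with Arrhenius hazards H(ΔU, D) = 5 e^(−3 ΔU^1.5 / D).
   The interspike-interval density solves the renewal equation
   f = J_R + J_L ∗ f, computed in the Fourier domain; a fixed-point
   phase map yields the stationary phase density, vector strength and q
   for slow sinusoidal drive.  An exact thinning Monte Carlo simulator of
   the same point process serves as an independent cross-check.

The central result the package reproduces: the phasic (two-barrier)
mechanism yields higher firing rates and strictly better slow-signal
encoding (q) than the classical constant-threshold stochastic-resonance
model over a broad range of noise intensities.

See `docs/methods.md` for the model assumptions, numerics and known
limitations.

## Worked example

```python
import numpy as np
from phasic import (BarrierModelSpec, FNParams, auto_grid, firing_rate,
                    simulate_barrier_process, simulate_spike_trains,
                    theory_metrics)
from phasic.barrier_mc import nu_with_se, vector_strength_with_se

# reduced model, moderate noise, weak slow sinusoid
spec = BarrierModelSpec(D=1.0, variant="phasic", A=0.1, phi=0.1)
nu, r, q = theory_metrics(spec, auto_grid(spec))
print(f"theory:      nu = {nu:.4f}, r = {r:.4f}, q = {q:.4f}")

# exact Monte Carlo of the same process (theory's phase convention)
rec = simulate_barrier_process(spec, t_end=5e4, seed=0,
                               sinusoid_clock="per_reset")
print(f"monte carlo: nu = {nu_with_se(rec)[0]:.4f}, "
      f"r = {vector_strength_with_se(rec)[0]:.4f} "
      f"({rec.spike_times.size} spikes)")

# planar neuron ensemble: 20 cells x 10 s at D = 0.03
params = FNParams(D=0.03, eps_mode="voltage_dependent",
                  duration=10_000.0, n_cells=20, seed=0)
print(f"FN ensemble: nu = {firing_rate(simulate_spike_trains(params)):.4f}"
      " spikes/ms")
```

prints

```
theory:      nu = 0.2146, r = 0.1642, q = 0.0352
monte carlo: nu = 0.2155, r = 0.1631 (10773 spikes)
FN ensemble: nu = 0.0301 spikes/ms
```

The theory and the thinning Monte Carlo agree on the firing rate to well
within sampling error, and the vector strength r ≈ 0.16 quantifies how
strongly spikes lock to a sinusoid whose period (10 time units) is much
longer than any intrinsic timescale of the barriers.  The planar-model
ensemble rate (spikes per ms of biological time) is the quantity scanned
against noise intensity in the noise-enhancement analyses.

A command-line interface wraps the experiment families:

```sh
phasic theory-scan --out-dir results/scan          # (D, nu, r, q) per variant
phasic fn-scan --config my_config.toml             # FN noise scan
phasic mc-validate --seed 7 --out-dir results/mc   # theory vs Monte Carlo
phasic phase-plane --out-dir results/pp            # separatrix + dU(t)
```

Every run writes its resolved configuration and seed beside its CSV
outputs; identical (config, seed) runs are byte-identical.

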
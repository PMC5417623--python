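# Methods

## The two levels of description

`phasic` implements a two-level account of how background noise lets a
phasic (Class III) neuron encode slow signals it would otherwise ignore.

**Level 1 — planar neuron model.** The membrane model is an augmented
FitzHugh–Nagumo system,

    tau_v dv/dt = v (0.1 - v)(v - 1) - w + I(t) + sqrt(2 D) xi(t),
        dw/dt = eps(v) v,

with unit-intensity Gaussian white noise `xi`, a sinusoidal drive
`I(t) = A sin(2 pi phi t)`, and a *vertical* w-nullcline (v = 0), so rest
is stable for every constant input — the defining phasic property.  Two
recovery-timescale variants are provided:

* the ε-model: `eps(v) = eps_const = 0.03 /ms`;
* the ε(v)-model: a logistic blend from `eps_hi = 0.1 /ms` when
  hyperpolarized to `eps_lo = 0.03 /ms` when depolarized (midpoint
  `v_half = 0.15`, width `v_slope = 0.03`).  Fast subthreshold feedback
  plus slow spike repolarization produces rotational subthreshold flow
  reminiscent of mixed-mode oscillations, and a firing rate far more
  sensitive to the noise intensity D.

A spike is an upward crossing of the recovery variable through `w_c`
(0.14 for the ε(v)-model, 0.15 for the ε-model), located by linear
interpolation; a sample exactly at threshold counts only if the previous
sample is strictly below, so successive spikes are always separated by a
subthreshold sample.

**Level 2 — two-barrier hazard model.** The reduced description keeps only
large excursions of a particle in a well: exits over a right barrier
(height `dU_R`, a spike) compete with exits over a left barrier
(`dU_L = 0.9`, the hyperpolarizing excursion that recruits the fast
feedback).  Exit rates follow the Arrhenius-type hazard
`H(dU, D) = 5 exp(-3 dU^1.5 / D)`.  A left crossing restarts the clock of
the damped-oscillatory right-barrier height

    dU_R(t) = 1.5 - 1.4 sin(0.8 pi (t + 0.15)) exp(-0.8 (t + 0.25)),

whose transient dip (minimum ≈ 0.676 at t ≈ 0.352, from a bounded
minimization seeded by a dense scan) transiently lowers the spike
threshold — the reduced image of the distance-to-separatrix dip of the
planar model.  Variants: `phasic` (both barriers), `right_moving` (moving
right barrier, no left barrier), `classic` (constant barrier; the standard
stochastic-resonance reference).  A slow, weak sinusoid
(`phi << 1`, `A << v_R`; defaults `A = 0.1`, `phi = 0.1`) modulates both
barrier heights quasi-statically.

## Renewal solver

With kernels `J_R = H_R exp(-int (H_L + H_R))` and
`J_L = H_L exp(-int (H_L + H_R))` (cumulative hazards by trapezoidal
quadrature), the interspike-interval density of the phasic variant solves
the renewal convolution equation `f = J_R + J_L * f`, solved in the
Fourier domain as `f_hat = J_R_hat / (1 - J_L_hat)` on the grid conjugate
to the time grid.  Numerical choices:

* **Jump splitting.**  The kernels jump at t = 0, which plain DFTs turn
  into O(dt) errors and Gibbs ringing.  Each kernel is split as
  `J_X = H_X(0) e^{-lambda t} + R_X` with `lambda` the initial total
  hazard, so `R_X(0) = 0` and its plain FFT is Poisson-summation
  consistent; the exponential part is transformed analytically.  The
  inverse transform splits off `f(0+) e^{-mu t}` with
  `mu = max(H_R(0), 20/t_max)` the constant-barrier decay rate.  When the
  right barrier is constant every remainder vanishes identically and the
  solver reproduces `H_R e^{-H_R t}` to ~1e-8 relative error; the test
  suite also cross-checks the general solve against direct trapezoidal
  summation of the convolution series (a strict lower bound, term by
  term) and against thinning Monte Carlo.
* **Grid adaptation.**  `t_max` is set where a conservative lower bound on
  the integrated total hazard reaches 20 (survivor mass ~ e^-20).  For the
  phasic variant the solved density decays at roughly the *spike* rate,
  which with many left resets per spike is far slower than the kernels;
  `t_max` is therefore extended to 25 estimated mean ISIs, using a rate
  estimate from a provisional kernel grid.  Because a circular-convolution
  wrap conserves mass (normalization checks cannot see it), the solver
  additionally requires the solved density's tail to have decayed below
  1e-4 of its peak.  `dt` resolves the barrier oscillation (>= 64 points
  per cycle) and the sinusoid (>= 128 points per period); `n_t` is a power
  of two in [2^14, 2^21], and grid construction fails loudly when a noise
  level would need more.
* **Negativity.**  Residual FFT ringing below zero is clipped and its mass
  reported; negativity beyond 1e-5 of the density's peak is an error
  (observed ringing with the default grids is ~5e-7 of peak).

Firing rate is `nu = 1 / int t f(t) dt` (trapezoid).  Densities are
normalized to a 1e-3 tolerance or the computation errors out.

## Phase machinery for an exogenous sinusoid

The convolution theorem requires kernels stationary in time-since-reset,
so within the solver the sinusoid phase is referenced to the most recent
barrier reset with a starting offset `psi0` — the quasi-static renewal
bookkeeping.  From the conditional densities `f(t | psi0)` on a 64-point
phase grid, the spike-to-spike phase map

    g(psi | psi0) ∝ sum_k f(k T + psi - psi0 | psi0),   T = 1/phi,

is column-normalized to integrate to one (the normalization is enforced
rather than derived from a prefactor, since it is the property the map
must satisfy), with the wrap sum truncated only once the residual ISI mass
is below 1e-8.  The stationary phase density `p(psi)` is the fixed point
of `p -> int g(psi|psi0) p(psi0) dpsi0`, found by power iteration from the
uniform density to an L1 residual of 1e-12 (densities renormalized each
iterate).  Vector strength is the resultant
`r = |(int p cos, int p sin)|`, the exogenous ISI density is the mixture
`f(t) = int f(t|psi) p(psi) dpsi`, and `q = nu r`.

## Thinning Monte Carlo

The point process is simulated exactly by rejection from a homogeneous
Poisson process at rate `2 gamma` (each hazard is bounded by `gamma`).
Three sinusoid clocks are provided: `absolute` (physical wall-clock
signal, the default), `per_reset` (the renewal theory's reset-referenced
phase, with the starting offset advanced by the ISI at each spike — the
exact law of the semi-analytic model, used to validate its numerics), and
`endogenous` (offset re-imposed after every spike, making ISIs i.i.d.
draws from `f(t | psi0)`, used for distributional KS tests).  Differences
between `absolute` and `per_reset` runs measure the quasi-static
approximation itself.  Standard errors for MC rates and vector strengths
use batch means over contiguous windows (50 batches), the latter
propagated through `r = |(C, S)|` by the delta method.

## Ensemble simulation and statistics

Euler–Maruyama with `dt = 0.01 ms`; the noise increment on v has variance
`2 D dt / tau_v^2`.  Ensembles use independent per-cell streams spawned
deterministically from the master seed, so runs are reproducible
bit-for-bit and independent of cell order.  Deterministic phase-plane work
uses fixed-step RK4 (`dt = 0.01 ms`; halving the step changes trajectories
by < 1e-8).  The separatrix is located per w by bisection on the initial
v (tolerance 1e-4), classifying each candidate by whether a 400 ms
deterministic path spikes; the default w grid spans [-0.05, 0.12] because
outside it no spiking/non-spiking bracket exists (above w ≈ 0.123, the
cubic's maximum, no initial v can spike; below w ≈ -0.055 every initial v
does).  The spike-triggered average stores per-step unit noise deviates
scaled by `1/sqrt(dt)` as the white-noise estimate; spectra use Welch
averaging (Hann taper, 50% overlap); presentation smoothing is three
passes of a centered moving average with edge renormalization.

## Parameters that matter

| symbol | meaning | default | unit |
|---|---|---|---|
| `tau_v` | membrane time constant | 1 | ms |
| `D` | noise intensity | — | (model units) |
| `A`, `phi` | signal amplitude, frequency | 0.1, 0.1 (reduced model) | —, 1/time |
| `w_c` | spike threshold on w | 0.14 / 0.15 | — |
| `dt` | EM step | 0.01 | ms |
| `gamma`, `beta`, `p_exp` | hazard shape | 5, 3, 1.5 | — |
| `dU_L`, `v_R` | barrier heights | 0.9, 1.5 | — |

`tau_v` never enters the reduced model; in the planar model it is a free
scale whose value is not pinned by the equations themselves.  The package
keeps `tau_v = 1 ms` and treats the reference firing-rate pair
(ν = 0.0045/ms at D = 0.03 for the ε(v)-model and at D = 0.069 for the
ε-model) as calibration checks computed by the acceptance tests: under the
default parameterization the measured rates are ≈ 0.030/ms and
≈ 0.024/ms, so those two checks document a calibration discrepancy (no
choice of `tau_v`, nor any single rescaling of D, reproduces the reference
pair; the qualitative structure — rate monotone in D, the ε(v)-model's
greater noise sensitivity, the STA sign structure — is unaffected).

## What the simulations do and do not show

All data are generated internally by the two simulators; there is no
external data.  The planar model is a caricature of phasic excitability:
it has no conductances, no absolute refractory period, and white rather
than synaptically filtered noise, so passing tests demonstrate properties
of the model class, not of any recorded neuron.  The reduced model assumes
slow (`phi << 1`), weak (`A << v_R`) signals; the solver inherits the
quasi-static and per-reset phase approximations, whose size can be
measured by comparing absolute-clock and per-reset Monte Carlo runs (the
`mc-validate` driver exposes both).  For slow signals with amplitude above `w_c` the
w-threshold spike definition itself breaks down (the recovery variable
tracks the signal through threshold without a spike excursion), and at
`phi = 0.005` the deterministic ε(v)-model genuinely fires for A >= 0.2:
the "no deterministic response to slow signals" property holds jointly for
small A and slow phi, not uniformly in A.

## Problem sizes

Default test and reproduction runs use: 2,000 s of total ensemble time
(20 cells) per FN rate estimate; >= 10^4 Monte Carlo spikes per
theory-validation point; 64-point phase grids and 2^14–2^19 time points
per renewal solve.  These sizes give Monte Carlo standard errors well
below the effects being tested.
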
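"""Two-barrier hazard/renewal theory of phasic spiking.

The reduced model replaces the planar neuron by a point in a potential well
that exits over one of two energy barriers under noise of intensity D.
Crossing the right barrier (height dU_R) is a spike; crossing the left
barrier (height dU_L) stands for the hyperpolarizing excursion that recruits
the fast negative feedback and is modelled by restarting the clock of a
damped-oscillatory right-barrier height

    dU_R(t) = v_R - mb_amp * sin(mb_freq (t + mb_shift1))
              * exp(-mb_decay (t + mb_shift2)),

so a recent leftward excursion transiently lowers the spike threshold.
Exit rates follow an Arrhenius-type hazard H(dU, D) = gamma
exp(-beta dU**p_exp / D).  Three variants are compared:

* ``phasic`` - both barriers; left crossings (and spikes) reset the dU_R
  clock.  Interspike intervals solve the renewal convolution equation
  f = J_R + J_L * f, solved here in the Fourier domain.
* ``right_moving`` - moving right barrier reset only by spikes, no left
  barrier (f = J_R directly).
* ``classic`` - constant right barrier v_R, no left barrier: the standard
  stochastic-resonance reference model.

A slow sinusoid A sin(2 pi phi (t + psi0)) modulates the barrier heights
quasi-statically.  The phase density p(psi) at spikes is the fixed point of
the map built from the conditional ISI densities f(t | psi0), from which the
vector strength r and q = nu * r follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from . import _kernels as _k

__all__ = [
    "BarrierModelSpec", "GridSpec", "ISIDensity", "PhaseDensity",
    "hazard", "moving_barrier", "exit_kernels", "isi_density_endogenous",
    "firing_rate_from_density", "isi_family", "phase_kernel",
    "phase_density_fixed_point", "isi_density_exogenous", "theory_metrics",
]

_VARIANT_CODES = {"classic": _k.VARIANT_CLASSIC,
                  "right_moving": _k.VARIANT_RIGHT_MOVING,
                  "phasic": _k.VARIANT_PHASIC}


@dataclass(frozen=True)
class BarrierModelSpec:
    """Variant plus every constant of the hazard/barrier theory."""

    D: float
    variant: Literal["phasic", "right_moving", "classic"] = "phasic"
    gamma: float = 5.0
    beta: float = 3.0
    p_exp: float = 1.5
    dU_L: float = 0.9
    v_R: float = 1.5
    mb_amp: float = 1.4
    mb_freq: float = 0.8 * np.pi
    mb_shift1: float = 0.15
    mb_decay: float = 0.8
    mb_shift2: float = 0.25
    A: float = 0.0
    phi: float = 0.0

    def __post_init__(self):
        if self.variant not in _VARIANT_CODES:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.A < 0:
            raise ValueError("A must be non-negative")
        if self.A > 0 and self.phi <= 0:
            raise ValueError("phi must be positive when A > 0")

    @property
    def variant_code(self) -> int:
        return _VARIANT_CODES[self.variant]

    @property
    def period(self) -> float:
        if self.phi <= 0:
            raise ValueError("no signal period without a sinusoid")
        return 1.0 / self.phi

    def with_(self, **kw) -> "BarrierModelSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class GridSpec:
    """Numerical grids for the renewal solver.

    ``t_max`` and ``n_t`` define the uniform time grid for kernels and
    densities; the Fourier grid is its conjugate (n_omega = n_t,
    omega_max = pi / dt).  ``n_psi`` grids the starting phase and ``k_max``
    truncates the wrap sum of the phase kernel.
    """

    t_max: float
    n_t: int
    n_psi: int = 64
    k_max: int | None = None
    tol_norm: float = 1e-3

    def __post_init__(self):
        if self.t_max <= 0 or self.n_t < 2:
            raise ValueError("t_max must be positive, n_t >= 2")

    @property
    def dt(self) -> float:
        return self.t_max / self.n_t

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_t) * self.dt

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * np.fft.fftfreq(self.n_t, d=self.dt)

    @property
    def n_omega(self) -> int:
        return self.n_t

    @property
    def omega_max(self) -> float:
        return np.pi / self.dt


def auto_grid(spec: BarrierModelSpec, n_psi: int = 64,
              cumhaz_target: float = 20.0, min_n_t: int = 2 ** 14,
              max_n_t: int = 2 ** 21) -> GridSpec:
    """Choose grids per noise level.

    ``t_max`` is set where the integrated total hazard reaches
    ``cumhaz_target`` (survivor mass ~ exp(-target)), so the exit kernels
    have decayed; dt must resolve the barrier oscillation and, with a
    signal, the sinusoid period.
    """
    # lower bound on the total hazard after the barrier transient: the
    # moving barrier settles at v_R, the sinusoid raises it by at most A;
    # the transient itself gets a fixed time allowance
    h_floor = hazard(spec.v_R + spec.A, spec.D, spec)
    if spec.variant == "phasic":
        h_floor += hazard(spec.dU_L + spec.A, spec.D, spec)
    t_max = cumhaz_target / h_floor + 8.0 / spec.mb_decay
    if spec.variant == "phasic":
        # the solved ISI density decays at roughly the spike rate, which for
        # rare spiking (many left resets per spike) is much slower than the
        # exit kernels; estimate it from a provisional kernel grid and
        # extend t_max so the density itself has decayed
        prov = GridSpec(t_max=t_max, n_t=min_n_t, n_psi=n_psi)
        J_L, J_R = exit_kernels(spec.with_(A=0.0, phi=0.0), prov)
        q_R = float(np.trapezoid(J_R, dx=prov.dt))
        m_epoch = float(np.trapezoid(prov.t * (J_L + J_R), dx=prov.dt))
        nu_est = q_R / m_epoch
        t_max = max(t_max, 1.25 * cumhaz_target / nu_est)
    dt_targets = [t_max / min_n_t]
    if spec.variant != "classic":
        dt_targets.append((2.0 * np.pi / spec.mb_freq) / 64.0)
    if spec.A > 0:
        dt_targets.append(spec.period / 128.0)
    dt = min(dt_targets)
    n_t = int(2 ** np.ceil(np.log2(t_max / dt)))
    if n_t > max_n_t:
        raise RuntimeError(
            f"noise level D = {spec.D:g} needs t_max = {t_max:.3g} at "
            f"dt <= {dt:.3g} (n_t = {n_t:.3g} > cap {max_n_t:g}); the exit "
            "rate is too slow for the default grid caps")
    n_t = int(max(n_t, min_n_t))
    return GridSpec(t_max=float(t_max), n_t=n_t, n_psi=n_psi)


def hazard(dU, D: float, spec: BarrierModelSpec):
    """Arrhenius-type escape rate gamma * exp(-beta dU**p_exp / D).

    Monotone decreasing in the barrier height dU, increasing in D, bounded
    by gamma.  Negative heights mean the sinusoid has collapsed a barrier
    (A too large) and are an error.
    """
    dU = np.asarray(dU, dtype=float)
    if np.any(dU < 0):
        raise ValueError("barrier height is negative (collapsed barrier: "
                         "signal amplitude too large)")
    out = spec.gamma * np.exp(-spec.beta * dU ** spec.p_exp / D)
    return float(out) if out.ndim == 0 else out


def moving_barrier(t, spec: BarrierModelSpec):
    """Right-barrier height dU_R(t), t since the last clock reset.

    Damped oscillation around the asymptote v_R; the ``classic`` variant
    has the constant height v_R.
    """
    t = np.asarray(t, dtype=float)
    if spec.variant == "classic":
        out = np.full_like(t, spec.v_R)
    else:
        out = spec.v_R - spec.mb_amp * np.sin(
            spec.mb_freq * (t + spec.mb_shift1)) \
            * np.exp(-spec.mb_decay * (t + spec.mb_shift2))
    return float(out) if out.ndim == 0 else out


@dataclass
class ISIDensity:
    """Gridded interspike-interval density f(t)."""

    t: np.ndarray
    f: np.ndarray
    norm_defect: float          # |1 - integral of f|
    clipped_mass: float = 0.0   # negative FFT ringing removed

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def mean(self) -> float:
        return float(np.trapezoid(self.t * self.f, self.t))


@dataclass
class PhaseDensity:
    """Stationary density of the sinusoid phase at spikes on [0, T)."""

    psi: np.ndarray
    p: np.ndarray
    residual: float             # L1 residual ||p - Lp||
    n_iter: int

    @property
    def dpsi(self) -> float:
        return float(self.psi[1] - self.psi[0])


def _hazards_on_grid(spec: BarrierModelSpec, grid: GridSpec, psi0: float):
    t = grid.t
    s = spec.A * np.sin(2.0 * np.pi * spec.phi * (t + psi0)) \
        if spec.A > 0 else 0.0
    H_R = hazard(moving_barrier(t, spec) - s, spec.D, spec)
    if spec.variant == "phasic":
        H_L = hazard(spec.dU_L - s, spec.D, spec)
        if np.isscalar(H_L):
            H_L = np.full_like(t, H_L)
    else:
        H_L = np.zeros_like(t)
    return H_L, H_R


def exit_kernels(spec: BarrierModelSpec, grid: GridSpec, psi0: float = 0.0):
    """Sub-densities of first exit through each barrier.

    J_X(t) = H_X(t) exp(-int_0^t (H_L + H_R)); the ``right_moving`` and
    ``classic`` variants have no left barrier, so J_L is identically zero.
    """
    H_L, H_R = _hazards_on_grid(spec, grid, psi0)
    dt = grid.dt
    total = H_L + H_R
    # cumulative trapezoid of the total hazard
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (total[1:] + total[:-1]))))
    S = np.exp(-cum * dt)
    return H_L * S, H_R * S


def _solve_renewal_fft(J_L: np.ndarray, J_R: np.ndarray, grid: GridSpec,
                       ill_cond_tol: float = 1e-8):
    """Fourier-domain solution of f = J_R + J_L * f.

    The jump discontinuities of the kernels at t = 0 are handled by
    splitting off exponentials with analytically known transforms:
    J_X = H_X(0) e^{-lambda t} + R_X with lambda the initial total hazard
    (R_X(0) = 0, so its plain FFT is Poisson-summation consistent), and the
    solved density is inverted as f = c e^{-mu t} + remainder with
    c = f(0+) = H_R(0) and mu matching the constant-barrier decay, which
    makes the constant-hazard reduction exact to machine precision.
    """
    dt = grid.dt
    omega = grid.omega
    aL = J_L[0]
    aR = J_R[0]
    lam = aL + aR
    expo = np.exp(-lam * grid.t)
    denom_exp = lam + 1j * omega
    J_L_hat = aL / denom_exp + np.fft.fft(J_L - aL * expo) * dt
    J_R_hat = aR / denom_exp + np.fft.fft(J_R - aR * expo) * dt
    one_minus = 1.0 - J_L_hat
    if np.abs(one_minus).min() < ill_cond_tol:
        raise RuntimeError("1 - J_L_hat vanishes on the Fourier grid: "
                           "enlarge the time domain")
    f_hat = J_R_hat / one_minus
    c = aR
    mu = max(aR, 20.0 / grid.t_max)
    f = c * np.exp(-mu * grid.t) + \
        np.real(np.fft.ifft(f_hat - c / (mu + 1j * omega))) / dt
    return f


def _as_density(f: np.ndarray, grid: GridSpec,
                neg_tol: float = 1e-5) -> ISIDensity:
    fmax = float(f.max())
    if fmax <= 0:
        raise RuntimeError("density is non-positive everywhere")
    fmin = float(f.min())
    if fmin < -neg_tol * fmax:
        raise RuntimeError(
            f"density negativity {fmin:.3g} exceeds the ringing floor "
            f"{-neg_tol * fmax:.3g}; enlarge the grid")
    neg = f < 0
    clipped = float(-f[neg].sum() * grid.dt) if np.any(neg) else 0.0
    f = np.where(neg, 0.0, f)
    norm = float(np.trapezoid(f, dx=grid.dt))
    return ISIDensity(t=grid.t, f=f, norm_defect=abs(1.0 - norm),
                      clipped_mass=clipped)


def isi_density_endogenous(spec: BarrierModelSpec, grid: GridSpec,
                           psi0: float = 0.0) -> ISIDensity:
    """ISI density for a signal that restarts at phase psi0 after a spike.

    For the phasic variant the renewal convolution is solved in the Fourier
    domain; for the variants without a left barrier f = J_R directly.
    """
    J_L, J_R = exit_kernels(spec, grid, psi0)
    if spec.variant == "phasic":
        f = _solve_renewal_fft(J_L, J_R, grid)
        # a circular-convolution wrap conserves mass, so normalization alone
        # cannot detect a too-short domain; the density must have decayed
        tail = float(np.max(f[-max(grid.n_t // 200, 2):]))
        if tail > 1e-4 * float(f.max()):
            raise RuntimeError(
                f"ISI density tail {tail:.3g} has not decayed by t_max = "
                f"{grid.t_max:.4g}: enlarge t_max")
    else:
        f = J_R
    d = _as_density(f, grid)
    if d.norm_defect > grid.tol_norm:
        raise RuntimeError(
            f"ISI density normalization defect {d.norm_defect:.3g} exceeds "
            f"{grid.tol_norm}: enlarge t_max or n_t")
    return d


def firing_rate_from_density(f: ISIDensity, tol_norm: float = 1e-3) -> float:
    """nu = 1 / mean ISI by trapezoidal quadrature of t f(t)."""
    if f.norm_defect > tol_norm:
        raise ValueError(
            f"density normalization defect {f.norm_defect:.3g} too large")
    return 1.0 / f.mean()


def isi_family(spec: BarrierModelSpec, grid: GridSpec) -> np.ndarray:
    """f(t | psi0) for every starting phase on the psi grid.

    Returns an (n_psi, n_t) array; rows are densities.  With A = 0 all rows
    are identical and only one solve is performed.
    """
    psi_grid = _psi_grid(spec, grid)
    fam = np.empty((grid.n_psi, grid.n_t))
    if spec.A == 0:
        f = isi_density_endogenous(spec, grid, 0.0)
        fam[:] = f.f
        return fam
    for j, psi0 in enumerate(psi_grid):
        fam[j] = isi_density_endogenous(spec, grid, float(psi0)).f
    return fam


def _psi_grid(spec: BarrierModelSpec, grid: GridSpec) -> np.ndarray:
    return np.arange(grid.n_psi) * (spec.period / grid.n_psi)


def phase_kernel(spec: BarrierModelSpec, grid: GridSpec,
                 fam: np.ndarray | None = None,
                 k_max: int | None = None,
                 wrap_tol: float = 1e-8) -> np.ndarray:
    """Conditional phase density g(psi | psi0) on the psi x psi0 grid.

    g(psi | psi0) is proportional to sum_k f(k T + psi - psi0 | psi0); each
    psi0 column is renormalized to integrate to one (the printed 1/(2 pi
    phi) prefactor is dimensionally inconsistent with that stated property,
    so normalization is enforced instead).  Truncation mass beyond
    k_max * T must be below ``wrap_tol``.
    """
    if fam is None:
        fam = isi_family(spec, grid)
    T = spec.period
    psi = _psi_grid(spec, grid)
    if k_max is None:
        k_max = int(np.ceil(grid.t_max / T)) + 1
    # mass of f beyond k_max T, per column
    tail_start = k_max * T
    for j in range(grid.n_psi):
        tail = float(np.trapezoid(
            np.where(grid.t >= tail_start, fam[j], 0.0), dx=grid.dt))
        if tail > wrap_tol:
            raise RuntimeError(
                f"ISI mass {tail:.3g} beyond k_max*T = {tail_start:.3g}; "
                "enlarge k_max")
    dpsi = psi[1] - psi[0] if grid.n_psi > 1 else T
    g = np.empty((grid.n_psi, grid.n_psi))   # [psi, psi0]
    ks = np.arange(k_max + 1)
    for j in range(grid.n_psi):
        # arguments kT + psi_i - psi0_j for all i, k
        args = ks[None, :] * T + (psi[:, None] - psi[j])
        vals = np.interp(args, grid.t, fam[j], left=0.0, right=0.0)
        vals[args < 0] = 0.0
        g[:, j] = vals.sum(axis=1)
        col = g[:, j].sum() * dpsi
        if col <= 0:
            raise RuntimeError("empty phase-kernel column")
        g[:, j] /= col
    return g


def phase_density_fixed_point(g: np.ndarray, spec: BarrierModelSpec,
                              grid: GridSpec, tol: float = 1e-12,
                              max_iter: int = 2000) -> PhaseDensity:
    """Stationary phase density p = Lp by power iteration from uniform."""
    psi = _psi_grid(spec, grid)
    dpsi = psi[1] - psi[0] if grid.n_psi > 1 else spec.period
    p = np.full(grid.n_psi, 1.0 / spec.period)
    for it in range(1, max_iter + 1):
        p_new = g @ p * dpsi
        p_new /= p_new.sum() * dpsi
        resid = float(np.sum(np.abs(p_new - p)) * dpsi)
        p = p_new
        if resid < tol:
            return PhaseDensity(psi=psi, p=p, residual=resid, n_iter=it)
    raise RuntimeError(
        f"phase-density iteration did not converge: residual {resid:.3g}")


def isi_density_exogenous(fam: np.ndarray, p: PhaseDensity,
                          grid: GridSpec) -> ISIDensity:
    """Mixture f(t) = int f(t | psi) p(psi) dpsi over the stationary phases."""
    if fam.shape != (p.psi.size, grid.n_t):
        raise ValueError("family and phase density grids do not match")
    f = (p.p[:, None] * fam).sum(axis=0) * p.dpsi
    return _as_density(f, grid)


def theory_metrics(spec: BarrierModelSpec, grid: GridSpec | None = None
                   ) -> tuple[float, float, float]:
    """Full pipeline (nu, r, q) for an exogenous sinusoid.

    kernels -> f(t | psi0) family -> phase kernel -> stationary p(psi) ->
    vector strength r, firing rate nu from the exogenous ISI density,
    q = nu r.
    """
    if spec.A > 0 and spec.phi <= 0:
        raise ValueError("phi must be positive when A > 0")
    if grid is None:
        grid = auto_grid(spec)
    if spec.A == 0 or spec.phi <= 0:
        f = isi_density_endogenous(spec, grid, 0.0)
        nu = firing_rate_from_density(f, grid.tol_norm)
        return nu, 0.0, 0.0
    fam = isi_family(spec, grid)
    g = phase_kernel(spec, grid, fam=fam, k_max=grid.k_max)
    p = phase_density_fixed_point(g, spec, grid)
    f = isi_density_exogenous(fam, p, grid)
    nu = firing_rate_from_density(f, grid.tol_norm)
    ang = 2.0 * np.pi * spec.phi * p.psi
    c = float(np.sum(p.p * np.cos(ang)) * p.dpsi)
    s = float(np.sum(p.p * np.sin(ang)) * p.dpsi)
    r = min(float(np.hypot(c, s)), 1.0)
    return nu, r, nu * r
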
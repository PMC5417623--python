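"""Exact stochastic simulation of the two-barrier point process.

Thinning (rejection from a homogeneous Poisson process at rate 2*gamma,
which bounds the total instantaneous hazard because each barrier's hazard
is bounded by gamma) generates competing left/right crossing events exactly.
Right crossings are spikes; both event types reset the moving-barrier clock
according to the variant's rules.  Used as the independent oracle for the
semi-analytic renewal theory and to generate spike trains for the
spike-train statistics.

Two conventions for the sinusoid clock are provided: ``absolute`` (the
physical signal runs in wall-clock time) and ``per_reset`` (the signal
phase is referenced to the most recent barrier reset, which is exactly the
quasi-static bookkeeping of the renewal theory; differences between the two
quantify that approximation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as _k
from .barrier_theory import BarrierModelSpec
from .fn_simulator import SpikeTrain

__all__ = ["EventRecord", "simulate_barrier_process"]


@dataclass
class EventRecord:
    """Spike and left-crossing times of one thinning run."""

    spike_times: np.ndarray
    left_times: np.ndarray
    t_end: float
    spec: BarrierModelSpec
    seed: int
    sinusoid_clock: str

    def __post_init__(self):
        for arr in (self.spike_times, self.left_times):
            if arr.size and not np.all(np.diff(arr) > 0):
                raise ValueError("event times must be strictly increasing")
        merged = np.sort(np.concatenate([self.spike_times, self.left_times]))
        if merged.size and np.any(np.diff(merged) <= 0):
            raise ValueError("coincident events in the merged record")

    @property
    def nu(self) -> float:
        return self.spike_times.size / self.t_end

    def to_spike_train(self) -> SpikeTrain:
        return SpikeTrain(times=self.spike_times, duration=self.t_end)


class BarrierCollapse(RuntimeError):
    pass


_CLOCKS = {"absolute": _k.CLOCK_ABSOLUTE,
           "per_reset": _k.CLOCK_PER_RESET,
           "endogenous": _k.CLOCK_ENDOGENOUS}


def simulate_barrier_process(spec: BarrierModelSpec, t_end: float,
                             seed: int = 0,
                             sinusoid_clock: str = "absolute",
                             psi0: float = 0.0) -> EventRecord:
    """Thinning simulation up to ``t_end``; reproducible by ``seed``.

    ``psi0`` is the initial sinusoid offset for the reset-referenced clocks;
    with ``endogenous`` it is re-imposed after every spike, so the ISIs are
    independent draws from the conditional density f(t | psi0).
    """
    if sinusoid_clock not in _CLOCKS:
        raise ValueError(f"unknown sinusoid clock {sinusoid_clock!r}")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    clock = _CLOCKS[sinusoid_clock]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    state = np.zeros(4)          # t, tau, psi0, t_last_spike
    state[2] = psi0
    spikes: list[np.ndarray] = []
    lefts: list[np.ndarray] = []
    # segment the run so event buffers stay bounded regardless of t_end
    cap = 1 << 18
    seg_len = max(cap / (4.0 * spec.gamma), 1.0)
    spike_buf = np.empty(cap)
    left_buf = np.empty(cap)
    while state[0] < t_end:
        seg_end = min(state[0] + seg_len, t_end)
        n_sp, n_lf, status = _k.thinning_segment(
            rng, state, seg_end, spec.gamma, spec.beta, spec.p_exp, spec.D,
            spec.A, spec.phi, spec.dU_L, spec.v_R, spec.mb_amp, spec.mb_freq,
            spec.mb_shift1, spec.mb_decay, spec.mb_shift2,
            spec.variant_code, clock, spike_buf, left_buf)
        if status == 1:
            raise BarrierCollapse(
                f"barrier height went negative at t = {state[0]:.4g} "
                "(signal amplitude too large)")
        if n_sp:
            spikes.append(spike_buf[:n_sp].copy())
        if n_lf:
            lefts.append(left_buf[:n_lf].copy())
        # status 2 (buffer full) simply continues from the updated state
    return EventRecord(
        spike_times=np.concatenate(spikes) if spikes else np.empty(0),
        left_times=np.concatenate(lefts) if lefts else np.empty(0),
        t_end=t_end, spec=spec, seed=seed, sinusoid_clock=sinusoid_clock)


def nu_with_se(rec: EventRecord, n_batches: int = 50
               ) -> tuple[float, float]:
    """Firing rate and its standard error by batch means over time windows."""
    edges = np.linspace(0.0, rec.t_end, n_batches + 1)
    counts = np.histogram(rec.spike_times, bins=edges)[0]
    rates = counts / np.diff(edges)
    se = float(rates.std(ddof=1) / np.sqrt(n_batches))
    return rec.nu, se


def vector_strength_with_se(rec: EventRecord, n_batches: int = 50
                            ) -> tuple[float, float]:
    """Vector strength of the spike phases with a batch-means delta-method SE.

    Spike phases are t mod T (identical bookkeeping in both sinusoid-clock
    conventions).  The covariance of the resultant components is estimated
    from contiguous batches, then propagated through r = |(C, S)|.
    """
    spec = rec.spec
    if spec.phi <= 0:
        raise ValueError("no sinusoid: vector strength undefined")
    ang = 2.0 * np.pi * spec.phi * rec.spike_times
    n = ang.size
    if n < 10 * n_batches:
        n_batches = max(n // 10, 2)
    cos, sin = np.cos(ang), np.sin(ang)
    C, S = cos.mean(), sin.mean()
    r = float(np.hypot(C, S))
    batches = np.array_split(np.arange(n), n_batches)
    bc = np.array([cos[b].mean() for b in batches])
    bs = np.array([sin[b].mean() for b in batches])
    cov = np.cov(np.vstack([bc, bs])) / n_batches
    grad = np.array([C, S]) / max(r, 1e-300)
    se = float(np.sqrt(grad @ cov @ grad))
    return r, se
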
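"""Stochastic FitzHugh-Nagumo model of phasic (Class III) excitability.

The membrane equation is

    tau_v dv/dt = v(0.1 - v)(v - 1) - w + I(t) + sqrt(2 D) xi(t)
    dw/dt       = eps(v) * v

with I(t) = A sin(2 pi phi t) and xi unit white noise.  The w-nullcline is
vertical, so rest (v, w) = (0, 0) is stable for any constant input: spikes
require fast transients or noise.  Two variants of the recovery timescale
are supported: a constant rate ``eps`` and a voltage-dependent sigmoid
``eps(v)`` that is fast (0.1/ms) when hyperpolarized and slow (0.03/ms) when
depolarized, which is what makes the model phasic.

Spikes are defined as upward crossings of the recovery variable w through a
threshold w_c, located by linear interpolation between samples.  Time is in
milliseconds throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from . import _kernels as _k

__all__ = [
    "FNParams",
    "Trajectory",
    "SpikeTrain",
    "epsilon_of_v",
    "simulate_fn",
    "simulate_spike_trains",
    "detect_spikes",
    "integrate_deterministic",
]

#: default spike-detection threshold per epsilon mode
DEFAULT_W_C = {"voltage_dependent": 0.14, "constant": 0.15}

# memory guard for full-path recording (floats)
_MAX_RECORDED_VALUES = 600_000_000


@dataclass(frozen=True)
class FNParams:
    """All constants of the model plus integration/ensemble settings."""

    D: float = 0.0
    eps_mode: Literal["constant", "voltage_dependent"] = "voltage_dependent"
    tau_v: float = 1.0
    eps_const: float = 0.03
    eps_lo: float = 0.03
    eps_hi: float = 0.1
    v_half: float = 0.15
    v_slope: float = 0.03
    A: float = 0.0
    phi: float = 0.0
    w_c: float | None = None
    dt: float = 0.01
    duration: float = 1000.0
    n_cells: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.eps_mode not in ("constant", "voltage_dependent"):
            raise ValueError(f"unknown eps_mode {self.eps_mode!r}")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.D < 0 or self.A < 0 or self.phi < 0:
            raise ValueError("D, A and phi must be non-negative")
        if self.tau_v <= 0:
            raise ValueError("tau_v must be positive")
        if not self.eps_lo < self.eps_hi:
            raise ValueError("eps_lo must be below eps_hi")
        if self.w_c is None:
            object.__setattr__(self, "w_c", DEFAULT_W_C[self.eps_mode])
        if not 0.0 < self.w_c < 1.0:
            raise ValueError("w_c must lie in (0, 1)")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def eps_mode_code(self) -> int:
        return (_k.EPS_VOLTAGE if self.eps_mode == "voltage_dependent"
                else _k.EPS_CONST)

    def with_(self, **kw) -> "FNParams":
        return replace(self, **kw)


@dataclass
class Trajectory:
    """Sampled paths of an ensemble on a shared uniform time grid."""

    t: np.ndarray                    # (n_t,)
    v: np.ndarray                    # (n_cells, n_t)
    w: np.ndarray                    # (n_cells, n_t)
    params: FNParams
    noise_path: np.ndarray | None = None   # (n_cells, n_t - 1), xi estimate

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1])


@dataclass
class SpikeTrain:
    """Ordered spike times of one cell over an observation window."""

    times: np.ndarray
    duration: float
    cell_id: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size:
            if not np.all(np.diff(self.times) > 0):
                raise ValueError("spike times must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")

    def __len__(self) -> int:
        return self.times.size


def epsilon_of_v(v, params: FNParams):
    """Recovery rate eps(v) of the voltage-dependent variant.

    eps(v) = (eps_hi + eps_lo * e^{(v - v_half)/v_slope})
             / (1 + e^{(v - v_half)/v_slope})

    decreasing from ``eps_hi`` (hyperpolarized) to ``eps_lo`` (depolarized),
    evaluated in an overflow-safe form.
    """
    if params.eps_mode != "voltage_dependent":
        raise ValueError("epsilon_of_v requires voltage_dependent mode; "
                         "the constant variant has eps = eps_const")
    v = np.asarray(v, dtype=float)
    x = (v - params.v_half) / params.v_slope
    out = np.empty_like(x)
    pos = x > 0
    e = np.exp(-x[pos])
    out[pos] = (params.eps_lo + params.eps_hi * e) / (1.0 + e)
    e = np.exp(x[~pos])
    out[~pos] = (params.eps_hi + params.eps_lo * e) / (1.0 + e)
    return out if out.ndim else float(out)


def _cell_rngs(params: FNParams) -> list[np.random.Generator]:
    """Independent per-cell streams derived from the master seed."""
    ss = np.random.SeedSequence(params.seed)
    return [np.random.default_rng(c) for c in ss.spawn(params.n_cells)]


def _spike_buffer(params: FNParams) -> np.ndarray:
    # w must fall below w_c between spikes, which takes >> 1 ms; one spike
    # per ms is a generous hard cap
    return np.empty(int(params.duration) + 16, dtype=float)


class SimulationDiverged(RuntimeError):
    """Non-finite state encountered mid-run."""

    def __init__(self, step: int, cell: int):
        self.step = step
        self.cell = cell
        super().__init__(f"non-finite state at step {step}, cell {cell}")


def simulate_fn(params: FNParams, record_noise: bool = False) -> Trajectory:
    """Euler-Maruyama ensemble integration with full path recording.

    The noise increment applied to v at each step has mean 0 and variance
    2*D*dt/tau_v**2; when ``record_noise`` the unit deviates are stored
    divided by sqrt(dt) as an estimate of xi(t) (used by the spike-triggered
    average).  Identical (params, seed) give bit-identical output.  For long
    runs where the recorded paths would not fit in memory use
    :func:`simulate_spike_trains`.
    """
    n_steps = params.n_steps
    n_vals = (3 if record_noise else 2) * params.n_cells * (n_steps + 1)
    if n_vals > _MAX_RECORDED_VALUES:
        raise MemoryError(
            f"recording {n_vals:.2g} values exceeds the guard; "
            "use simulate_spike_trains for long runs")
    t = np.arange(n_steps + 1) * params.dt
    v = np.empty((params.n_cells, n_steps + 1))
    w = np.empty_like(v)
    xi = (np.empty((params.n_cells, n_steps)) if record_noise
          else np.empty((params.n_cells, 0)))
    spike_buf = _spike_buffer(params)
    for i, rng in enumerate(_cell_rngs(params)):
        _, status = _k.em_cell(
            rng, 0.0, 0.0, n_steps, params.dt, params.tau_v, params.D,
            params.A, params.phi, params.eps_mode_code, params.eps_const,
            params.eps_lo, params.eps_hi, params.v_half, params.v_slope,
            params.w_c, spike_buf, 1, v[i], w[i],
            xi[i] if record_noise else xi[0])
        if status >= 0:
            raise SimulationDiverged(status, i)
    return Trajectory(t=t, v=v, w=w, params=params,
                      noise_path=xi if record_noise else None)


def simulate_spike_trains(params: FNParams) -> list[SpikeTrain]:
    """Streaming ensemble run returning only the spike trains.

    Memory use is O(spike count); suitable for the multi-thousand-second
    ensembles needed to estimate low firing rates.
    """
    n_steps = params.n_steps
    trains = []
    for i, rng in enumerate(_cell_rngs(params)):
        buf = _spike_buffer(params)
        empty = np.empty(0)
        n_spk, status = _k.em_cell(
            rng, 0.0, 0.0, n_steps, params.dt, params.tau_v, params.D,
            params.A, params.phi, params.eps_mode_code, params.eps_const,
            params.eps_lo, params.eps_hi, params.v_half, params.v_slope,
            params.w_c, buf, 0, empty, empty, empty)
        if status >= 0:
            raise SimulationDiverged(status, i)
        if n_spk > buf.size:
            raise RuntimeError(
                f"cell {i}: {n_spk} spikes overflow the buffer "
                f"({buf.size}); spike rate above 1/ms is unphysical here")
        trains.append(SpikeTrain(times=buf[:n_spk].copy(),
                                 duration=params.duration, cell_id=i))
    return trains


def detect_spikes(traj: Trajectory, w_c: float | None = None
                  ) -> list[SpikeTrain]:
    """Upward crossings of w through w_c, linearly interpolated.

    A sample exactly at w_c counts as a crossing only when the previous
    sample is strictly below, so consecutive spikes are always separated by
    at least one sub-threshold sample.
    """
    if w_c is None:
        w_c = traj.params.w_c
    w = traj.w
    dt = traj.dt
    crossing = (w[:, :-1] < w_c) & (w[:, 1:] >= w_c)
    trains = []
    duration = float(traj.t[-1])
    for i in range(w.shape[0]):
        idx = np.nonzero(crossing[i])[0]
        w0 = w[i, idx]
        w1 = w[i, idx + 1]
        times = traj.t[idx] + dt * (w_c - w0) / (w1 - w0)
        times = times[times < duration]
        trains.append(SpikeTrain(times=times, duration=duration, cell_id=i))
    return trains


def integrate_deterministic(params: FNParams,
                            ic: tuple[float, float] | Sequence,
                            t_end: float,
                            dt: float = 0.01) -> Trajectory:
    """Fixed-step RK4 path of the deterministic (D = 0) system.

    ``ic`` is a single (v0, w0) pair or a pair of arrays for a batch of
    initial conditions.  The sinusoidal drive A sin(2 pi phi t) from
    ``params`` is included; params.D is ignored.
    """
    v0 = np.atleast_1d(np.asarray(ic[0], dtype=float))
    w0 = np.atleast_1d(np.asarray(ic[1], dtype=float))
    if v0.shape != w0.shape:
        raise ValueError("v0 and w0 must have matching shapes")
    n_steps = int(round(t_end / dt))
    counts = np.zeros(v0.size, dtype=np.int64)
    v = np.empty((v0.size, n_steps + 1))
    w = np.empty_like(v)
    status = _k.rk4_batch(
        v0, w0, n_steps, dt, params.tau_v, params.A, params.phi,
        params.eps_mode_code, params.eps_const, params.eps_lo, params.eps_hi,
        params.v_half, params.v_slope, params.w_c, counts, 1, v, w)
    if status >= 0:
        raise SimulationDiverged(status, -1)
    t = np.arange(n_steps + 1) * dt
    return Trajectory(t=t, v=v, w=w, params=params)


def count_spikes_deterministic(params: FNParams, v0, w0, t_end: float,
                               dt: float = 0.01) -> np.ndarray:
    """Spike counts of deterministic paths from a batch of ICs (no storage)."""
    v0 = np.atleast_1d(np.asarray(v0, dtype=float))
    w0 = np.broadcast_to(np.asarray(w0, dtype=float), v0.shape).copy()
    n_steps = int(round(t_end / dt))
    counts = np.zeros(v0.size, dtype=np.int64)
    empty = np.empty((1, 1))
    status = _k.rk4_batch(
        v0, w0, n_steps, dt, params.tau_v, params.A, params.phi,
        params.eps_mode_code, params.eps_const, params.eps_lo, params.eps_hi,
        params.v_half, params.v_slope, params.w_c, counts, 0, empty, empty)
    if status >= 0:
        raise SimulationDiverged(status, -1)
    return counts
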
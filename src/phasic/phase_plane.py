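"""Deterministic phase-plane analysis of the phasic FN variants.

The separatrix is the curve v*(w) dividing initial conditions that relax
straight back to rest from those that make a spike excursion first.  It is
located per w by bisection on the initial v, classifying each candidate by
integrating the deterministic system and asking whether the recovery
variable crosses w_c from below.  The horizontal distance

    dU(t) = v*(w(t)) - v(t)

of a trajectory to the separatrix is the effective threshold distance that
motivates the moving right barrier of the reduced hazard model: after a
hyperpolarizing excursion the distance transiently dips below its resting
value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fn_simulator import (FNParams, Trajectory, count_spikes_deterministic,
                           integrate_deterministic)

__all__ = ["Separatrix", "DistanceTrace", "compute_separatrix",
           "threshold_distance_trace"]


@dataclass
class Separatrix:
    w: np.ndarray          # grid of w values
    v_star: np.ndarray     # separatrix abscissa v*(w); NaN where undefined
    tol: float             # bisection convergence tolerance on v
    params: FNParams
    horizon: float         # classification integration horizon (ms)

    def __call__(self, w) -> np.ndarray:
        """Interpolated v*(w); error outside the grid."""
        w = np.asarray(w, dtype=float)
        if np.any(w < self.w[0]) or np.any(w > self.w[-1]):
            raise ValueError("w outside the separatrix grid")
        return np.interp(w, self.w, self.v_star)


@dataclass
class DistanceTrace:
    t: np.ndarray
    dU: np.ndarray


def _spiking(params: FNParams, v0: np.ndarray, w0: np.ndarray,
             horizon: float, dt: float) -> np.ndarray:
    return count_spikes_deterministic(params, v0, w0, horizon, dt) > 0


def compute_separatrix(params: FNParams,
                       w_range: tuple[float, float] = (-0.05, 0.12),
                       n_w: int = 37,
                       tol: float = 1e-4,
                       horizon: float = 400.0,
                       dt: float = 0.01,
                       v_bracket: tuple[float, float] = (0.0, 1.2),
                       allow_undefined: bool = False) -> Separatrix:
    """Bisection separatrix on a uniform w grid.

    The classifier integrates deterministically (D = 0, A = 0 enforced) for
    ``horizon`` ms.  If the initial bracket classifies identically it is
    widened once to (-1, 2); if that still fails the row has no separatrix
    (above w ~ 0.123, the maximum of the cubic, no initial v spikes) and is
    an error unless ``allow_undefined`` marks it NaN.
    """
    params = params.with_(D=0.0, A=0.0)
    w_grid = np.linspace(w_range[0], w_range[1], n_w)
    lo = np.full(n_w, v_bracket[0])
    hi = np.full(n_w, v_bracket[1])
    spk_lo = _spiking(params, lo, w_grid, horizon, dt)
    spk_hi = _spiking(params, hi, w_grid, horizon, dt)
    bad = spk_lo | ~spk_hi
    if np.any(bad):
        lo[bad] = -1.0
        hi[bad] = 2.0
        spk_lo[bad] = _spiking(params, lo[bad], w_grid[bad], horizon, dt)
        spk_hi[bad] = _spiking(params, hi[bad], w_grid[bad], horizon, dt)
    undefined = spk_lo | ~spk_hi
    if np.any(undefined) and not allow_undefined:
        raise RuntimeError(
            f"no spiking/non-spiking bracket at w = "
            f"{w_grid[undefined].round(4).tolist()}; no separatrix there")
    n_iter = int(np.ceil(np.log2((hi - lo).max() / tol)))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        spk = _spiking(params, mid, w_grid, horizon, dt)
        hi = np.where(spk, mid, hi)
        lo = np.where(spk, lo, mid)
    v_star = 0.5 * (lo + hi)
    v_star[undefined] = np.nan
    return Separatrix(w=w_grid, v_star=v_star, tol=tol, params=params,
                      horizon=horizon)


def threshold_distance_trace(params: FNParams,
                             ic: tuple[float, float],
                             separatrix: Separatrix,
                             t_end: float = 150.0,
                             dt: float = 0.01) -> DistanceTrace:
    """dU(t) = v*(w(t)) - v(t) along the deterministic path from ``ic``.

    Signals (with the exit time) if the trajectory's w leaves the
    separatrix grid.
    """
    traj: Trajectory = integrate_deterministic(
        params.with_(D=0.0, A=0.0), ic, t_end, dt=dt)
    w = traj.w[0]
    outside = (w < separatrix.w[0]) | (w > separatrix.w[-1])
    if np.any(outside):
        t_exit = traj.t[np.argmax(outside)]
        raise ValueError(
            f"trajectory leaves the separatrix w-grid at t = {t_exit:.3f} ms"
            f" (w = {w[np.argmax(outside)]:.4f})")
    dU = separatrix(w) - traj.v[0]
    return DistanceTrace(t=traj.t, dU=dU)
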
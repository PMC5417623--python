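"""Spike-train and trajectory statistics.

Firing rate, phase density and vector strength of periodically driven spike
trains, the q-value (rate-weighted vector strength), the spike-triggered
average of the injected noise, Welch power spectra of the membrane variable,
and the pseudo-Gaussian smoother used for presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .fn_simulator import SpikeTrain, Trajectory

__all__ = [
    "PhaseHistogram",
    "STAResult",
    "SpectrumEstimate",
    "firing_rate",
    "empirical_phase_density",
    "vector_strength",
    "vector_strength_spikes",
    "q_value",
    "spike_triggered_average",
    "power_spectrum_v",
    "smooth_signal",
]


@dataclass
class PhaseHistogram:
    """Histogram of spike phases on [0, T), T = 1/phi.

    ``mass`` sums to one; ``density`` = mass / bin width integrates to one.
    """

    bin_edges: np.ndarray
    mass: np.ndarray
    phi: float
    n_spikes: int

    @property
    def period(self) -> float:
        return 1.0 / self.phi

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def density(self) -> np.ndarray:
        return self.mass / np.diff(self.bin_edges)


@dataclass
class STAResult:
    """Mean noise waveform around spikes; lag < 0 precedes the spike."""

    lags: np.ndarray
    sta: np.ndarray
    n_spikes: int

    def peak_normalized(self) -> np.ndarray:
        m = np.max(np.abs(self.sta))
        return self.sta / m if m > 0 else self.sta.copy()


@dataclass
class SpectrumEstimate:
    freqs: np.ndarray
    power: np.ndarray
    nperseg: int
    n_segments: int


def firing_rate(trains: list[SpikeTrain]) -> float:
    """Total spike count divided by total observed time (per ms)."""
    total_time = sum(tr.duration for tr in trains)
    if total_time <= 0:
        raise ValueError("total observation time must be positive")
    return sum(len(tr) for tr in trains) / total_time


def _all_phases(trains: list[SpikeTrain], phi: float) -> np.ndarray:
    if phi <= 0:
        raise ValueError("phi must be positive")
    period = 1.0 / phi
    times = np.concatenate([tr.times for tr in trains]) if trains else \
        np.empty(0)
    return np.mod(times, period)


def empirical_phase_density(trains: list[SpikeTrain], phi: float,
                            n_bins: int = 50) -> PhaseHistogram:
    """Histogram of signal phases at spike times, normalized to a density."""
    phases = _all_phases(trains, phi)
    if phases.size == 0:
        raise ValueError("no spikes: phase density undefined")
    period = 1.0 / phi
    mass, edges = np.histogram(phases, bins=n_bins, range=(0.0, period))
    return PhaseHistogram(bin_edges=edges, mass=mass / phases.size,
                          phi=phi, n_spikes=phases.size)


def vector_strength(p, phi: float | None = None, psi=None,
                    tol_norm: float = 1e-3) -> float:
    """Resultant length r in [0, 1] of a normalized phase density.

    r = |(int p cos(2 pi phi psi), int p sin(2 pi phi psi))|

    ``p`` is a :class:`PhaseHistogram` or a density array on a uniform grid
    ``psi`` covering one period.  Unnormalized input is rejected.
    """
    if isinstance(p, PhaseHistogram):
        phi = p.phi
        psi = p.centers
        weights = p.mass
        total = weights.sum()
    else:
        p = np.asarray(p, dtype=float)
        psi = np.asarray(psi, dtype=float)
        if phi is None:
            raise ValueError("phi required for gridded densities")
        dpsi = psi[1] - psi[0]
        weights = p * dpsi
        total = weights.sum()
    if abs(total - 1.0) > tol_norm:
        raise ValueError(f"density integrates to {total:.6g}, not 1")
    ang = 2.0 * np.pi * phi * psi
    c = float(np.sum(weights * np.cos(ang)))
    s = float(np.sum(weights * np.sin(ang)))
    return min(float(np.hypot(c, s)), 1.0)


def vector_strength_spikes(trains: list[SpikeTrain], phi: float) -> float:
    """Vector strength from raw spike phases (no binning bias)."""
    phases = _all_phases(trains, phi)
    if phases.size == 0:
        raise ValueError("no spikes: vector strength undefined")
    ang = 2.0 * np.pi * phi * phases
    return min(float(np.hypot(np.mean(np.cos(ang)), np.mean(np.sin(ang)))),
               1.0)


def q_value(nu: float, r: float) -> float:
    """Encoding quality q = nu * r (vector strength weighted by rate)."""
    if nu < 0 or not 0.0 <= r <= 1.0:
        raise ValueError("require nu >= 0 and r in [0, 1]")
    return nu * r


def spike_triggered_average(traj: Trajectory, trains: list[SpikeTrain],
                            window: tuple[float, float] = (100.0, 20.0)
                            ) -> STAResult:
    """Mean injected-noise waveform aligned on spikes.

    ``window`` = (pre_ms, post_ms).  Only spikes with a full window of noise
    history qualify.  The noise path must have been recorded
    (``simulate_fn(..., record_noise=True)``).
    """
    if traj.noise_path is None:
        raise ValueError("trajectory has no recorded noise path")
    pre, post = window
    dt = traj.dt
    n_pre = int(round(pre / dt))
    n_post = int(round(post / dt))
    n_max = traj.noise_path.shape[1]
    acc = np.zeros(n_pre + n_post + 1)
    count = 0
    for tr in trains:
        xi = traj.noise_path[tr.cell_id]
        idx = np.round(tr.times / dt).astype(int)
        idx = idx[(idx - n_pre >= 0) & (idx + n_post < n_max)]
        for j in idx:
            acc += xi[j - n_pre: j + n_post + 1]
        count += idx.size
    if count == 0:
        raise ValueError("no spikes with a full window of history")
    lags = (np.arange(-n_pre, n_post + 1)) * dt
    return STAResult(lags=lags, sta=acc / count, n_spikes=count)


def power_spectrum_v(traj: Trajectory, nperseg: int = 4096,
                     cell: int | None = None) -> SpectrumEstimate:
    """Averaged-periodogram (Welch) estimate of the spectrum of v(t).

    Segments overlap by 50% under a Hann taper; with ``cell=None`` the
    estimate is additionally averaged across the ensemble.
    """
    v = traj.v if cell is None else traj.v[cell: cell + 1]
    if v.shape[1] < nperseg:
        raise ValueError("record shorter than one segment")
    fs = 1.0 / traj.dt
    freqs, power = _signal.welch(v, fs=fs, nperseg=nperseg,
                                 noverlap=nperseg // 2, window="hann",
                                 detrend="constant", axis=1)
    n_segments = v.shape[0] * (1 + (v.shape[1] - nperseg) // (nperseg // 2))
    return SpectrumEstimate(freqs=freqs, power=power.mean(axis=0),
                            nperseg=nperseg, n_segments=n_segments)


def smooth_signal(x: np.ndarray, width: int) -> np.ndarray:
    """Pseudo-Gaussian smoother: three passes of a centered moving average.

    Length-preserving; edges are renormalized by the local kernel mass so
    constant inputs pass through unchanged.
    """
    x = np.asarray(x, dtype=float)
    width = int(width)
    if width < 1:
        raise ValueError("width must be >= 1 sample")
    if width > x.size:
        raise ValueError("width exceeds record length")
    if width % 2 == 0:
        width += 1
    kernel = np.ones(width)
    out = x
    for _ in range(3):
        norm = np.convolve(np.ones_like(out), kernel, mode="same")
        out = np.convolve(out, kernel, mode="same") / norm
    return out
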
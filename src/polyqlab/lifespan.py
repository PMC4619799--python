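"""Residence-time and escape-probability statistics from RMSD time series.

A conformer's residence time t_R is the last sampled time at which the
trajectory's superposed CA RMSD to its starting structure is at or below
a threshold (default 2 A); a conformer that never leaves by the end of
the run is censored at the run length.  The escape probability P_e(t) is
the fraction of conformers (censored ones included in the denominator)
that have left their initial conformation before time t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from polyqlab.structure import Ensemble, superpose_rmsd_coords

DEFAULT_RMSD_THRESHOLD = 2.0  # angstrom


@dataclass
class RmsdSeries:
    """RMSD-to-first-frame trace of one trajectory (times in ns)."""

    times: np.ndarray
    rmsd: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.rmsd = np.asarray(self.rmsd, float)
        if len(self.times) != len(self.rmsd):
            raise ValueError("times and rmsd must be parallel")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be increasing")
        if abs(self.rmsd[0]) > 1e-9 or self.times[0] != 0.0:
            raise ValueError("series must start at (t=0, rmsd=0)")

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("t_ns,rmsd_angstrom\n")
            for t, r in zip(self.times, self.rmsd):
                fh.write(f"{t:.6f},{r:.4f}\n")


@dataclass
class EscapeCurve:
    """Step-function escape probability on the union of event times."""

    times: np.ndarray
    P_e: np.ndarray
    residence_times: np.ndarray
    censored: np.ndarray

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("t_ns,P_e\n")
            for t, p in zip(self.times, self.P_e):
                fh.write(f"{t:.6f},{p:.6f}\n")


def rmsd_series(trajectory: Ensemble, times=None) -> RmsdSeries:
    """Superposed CA RMSD of every frame to frame 0.

    ``times`` (ns) overrides frame timestamps; without either, frame
    indices are used as times.
    """
    if len(trajectory) < 2:
        raise ValueError("a trajectory needs at least 2 frames")
    ref = trajectory[0].ca_coords()
    vals = [superpose_rmsd_coords(ref, frame.ca_coords())
            for frame in trajectory]
    if times is None:
        stamps = [c.timestamp for c in trajectory]
        times = (np.array(stamps, float) if all(t is not None for t in stamps)
                 else np.arange(len(trajectory), dtype=float))
        times = times - times[0]
    vals[0] = 0.0
    return RmsdSeries(np.asarray(times, float), np.array(vals))


def rmsd_series_from_frames(frames: np.ndarray, times: np.ndarray) -> RmsdSeries:
    """RMSD series directly from an (n_frames, n, 3) coordinate array."""
    frames = np.asarray(frames, float)
    ref = frames[0]
    vals = np.array([superpose_rmsd_coords(ref, f) for f in frames])
    vals[0] = 0.0
    t = np.asarray(times, float) - times[0]
    return RmsdSeries(t, vals)


def residence_time(series: RmsdSeries,
                   threshold: float = DEFAULT_RMSD_THRESHOLD):
    """(t_R, censored): last sampled time at or below the threshold.

    Censored means the trajectory is still within the threshold at its
    final frame (it never left within the simulated window).
    """
    below = series.rmsd <= threshold
    censored = bool(below[-1])
    idx = np.nonzero(below)[0]
    t_r = float(series.times[idx[-1]]) if len(idx) else 0.0
    return t_r, censored


def escape_probability(residence_times) -> EscapeCurve:
    """Escape-probability step function from (t_R, censored) pairs.

    P_e(t) is the fraction of all conformers whose (non-censored)
    residence time is < t; censored conformers never escape within the
    window but still count in the denominator.
    """
    pairs = list(residence_times)
    if not pairs:
        raise ValueError("need at least one conformer")
    t_r = np.array([t for t, _ in pairs], float)
    cens = np.array([c for _, c in pairs], bool)
    events = np.sort(np.unique(t_r[~cens])) if (~cens).any() else np.array([])
    grid = np.concatenate([[0.0], events, [max(t_r.max(), 0.0) * 1.0 + 1e-12]])
    grid = np.unique(grid)
    n = len(pairs)
    pe = np.array([np.sum(~cens & (t_r < t)) / n for t in grid])
    return EscapeCurve(grid, pe, t_r, cens)
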
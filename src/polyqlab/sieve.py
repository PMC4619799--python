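"""Three-sieve selection of independent conformers from a trajectory.

A time-ordered ensemble is reduced to temporally and structurally
independent conformers in three stages: (1) keep frames whose
secondary-structure content exceeds a threshold (default 30%, strict);
(2) group surviving frames into time clusters, cutting whenever the gap
between successive structured frames exceeds 50 ps, and represent each
cluster by its highest-SS member; (3) keep representatives whose
superposed CA RMSD to every already-accepted conformer exceeds 2 A
(greedy leader clustering in temporal order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from polyqlab.structure import Conformer, Ensemble, superpose_rmsd

DEFAULT_SS_THRESHOLD = 30.0   # percent
DEFAULT_GAP_PS = 50.0
DEFAULT_RMSD_A = 2.0


@dataclass
class TimeCluster:
    """A contiguous burst of structured frames."""

    members: list[int]            # frame indices into the filtered list
    start_ps: float
    end_ps: float
    representative: int           # frame index with maximum SS (earliest wins)


@dataclass
class SieveResult:
    """Counts and selections of the full three-sieve pass."""

    n_input_frames: int
    n_structured_frames: int
    time_clusters: list[TimeCluster]
    independent_ids: list[str]
    independent_indices: list[int]
    parameters: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.time_clusters)

    @property
    def n_independent(self) -> int:
        return len(self.independent_ids)

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def ss_sieve(ensemble: Ensemble, ss_values, threshold: float = DEFAULT_SS_THRESHOLD):
    """Indices of frames with SS strictly above the threshold, in order."""
    ss_values = np.asarray(ss_values, float)
    if len(ss_values) != len(ensemble):
        raise ValueError(
            f"{len(ss_values)} SS values for {len(ensemble)} frames"
        )
    return [i for i, s in enumerate(ss_values) if s > threshold]


def time_cluster(frames, timestamps, ss_values,
                 gap_threshold: float = DEFAULT_GAP_PS) -> list[TimeCluster]:
    """Split structured frames into clusters at time gaps > ``gap_threshold``.

    ``frames`` are frame indices; ``timestamps`` and ``ss_values`` are
    parallel to them.  The representative is the member with maximum SS
    (earliest member wins ties).
    """
    frames = list(frames)
    timestamps = np.asarray(timestamps, float)
    ss_values = np.asarray(ss_values, float)
    if not (len(frames) == len(timestamps) == len(ss_values)):
        raise ValueError("frames, timestamps and SS values must be parallel")
    if len(frames) == 0:
        return []
    if np.any(np.diff(timestamps) <= 0):
        raise ValueError("timestamps must be increasing")
    clusters = []
    start = 0
    for k in range(1, len(frames) + 1):
        if k == len(frames) or timestamps[k] - timestamps[k - 1] > gap_threshold:
            members = frames[start:k]
            ss_block = ss_values[start:k]
            rep = members[int(np.argmax(ss_block))]  # argmax takes earliest tie
            clusters.append(TimeCluster(
                members=members,
                start_ps=float(timestamps[start]),
                end_ps=float(timestamps[k - 1]),
                representative=rep,
            ))
            start = k
    return clusters


def structural_independence(representatives: list[Conformer],
                            rmsd_threshold: float = DEFAULT_RMSD_A) -> list[int]:
    """Greedy leader clustering: indices of structurally independent members.

    A representative is kept iff its superposed CA RMSD to every already
    kept conformer exceeds the threshold; the first is always kept.
    """
    if len(representatives) == 0:
        raise ValueError("need at least one representative")
    n = len(representatives[0])
    for c in representatives:
        if len(c) != n:
            raise ValueError("representatives differ in chain length")
    kept: list[int] = []
    for idx, cand in enumerate(representatives):
        if all(superpose_rmsd(cand, representatives[k]) > rmsd_threshold
               for k in kept):
            kept.append(idx)
    return kept


def run_sieve(ensemble: Ensemble, ss_values,
              ss_threshold: float = DEFAULT_SS_THRESHOLD,
              gap_threshold: float = DEFAULT_GAP_PS,
              rmsd_threshold: float = DEFAULT_RMSD_A) -> SieveResult:
    """Full three-sieve pass over a time-ordered ensemble."""
    if not ensemble.is_time_ordered:
        raise ValueError("sieve requires a time-ordered ensemble")
    ss_values = np.asarray(ss_values, float)
    structured = ss_sieve(ensemble, ss_values, ss_threshold)
    times = [ensemble[i].timestamp for i in structured]
    clusters = time_cluster(structured, times, ss_values[structured],
                            gap_threshold)
    reps = [ensemble[c.representative] for c in clusters]
    if reps:
        kept_local = structural_independence(reps, rmsd_threshold)
        kept = [clusters[k].representative for k in kept_local]
    else:
        kept = []
    return SieveResult(
        n_input_frames=len(ensemble),
        n_structured_frames=len(structured),
        time_clusters=clusters,
        independent_ids=[ensemble[i].id for i in kept],
        independent_indices=kept,
        parameters={
            "ss_threshold_pct": ss_threshold,
            "ss_comparison": "strict",
            "gap_ps": gap_threshold,
            "rmsd_A": rmsd_threshold,
        },
    )


def independence_kinetics(times, counts):
    """Least-squares slope of cumulative independent-structure count vs time.

    Returns (slope, slope standard error, intercept); short trajectories
    accumulate independent conformers linearly, so the slope is the
    generation rate of new structures per unit time.
    """
    times = np.asarray(times, float)
    counts = np.asarray(counts, float)
    if len(times) != len(counts) or len(times) < 3:
        raise ValueError("need at least 3 (time, count) points")
    res = stats.linregress(times, counts)
    return float(res.slope), float(res.stderr), float(res.intercept)
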
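"""Knot detection, classification and localization in open CA chains.

Open chains are simplified by KMT triangle elimination, closed
stochastically through a bounding sphere, and classified per closure by
the Alexander-polynomial determinants |Delta(-1)| and |Delta(-2)| read off
a generic planar projection; the voted majority over closures is the
chain's knot type.  The invariant pair separates the knot types relevant
for short homopolymer ensembles: 0_1, 3_1, 4_1, 5_1 and 5_2 (anything
else reports as "other").
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from polyqlab.structure import Conformer

KNOT_TYPES = ("0_1", "3_1", "4_1", "5_1", "5_2", "other")
DEFAULT_CLOSURES = 64


@dataclass
class KnotReport:
    """Knot type with core boundaries (1-based, inclusive) and vote share."""

    knot_type: str
    k_minus: int | None = None
    k_plus: int | None = None
    closure_votes: float = 0.0

    @property
    def delta_k(self) -> int | None:
        if self.k_minus is None or self.k_plus is None:
            return None
        return self.k_plus - self.k_minus + 1


def _as_coords(trace) -> np.ndarray:
    if isinstance(trace, Conformer):
        return trace.ca_coords()
    return np.asarray(trace, float)


# ---------------------------------------------------------------------------
# KMT reduction
# ---------------------------------------------------------------------------

def _segment_hits_triangle(a, b, c, P, Q) -> np.ndarray:
    """Vectorized test whether segments P->Q cross triangle (a, b, c)."""
    eps = 1e-12

    def vol(p, q, r, s):
        return np.einsum("...i,...i->...", np.cross(q - p, r - p), s - p)

    vP = vol(a, b, c, P)
    vQ = vol(a, b, c, Q)
    straddle = vP * vQ < -eps
    v1 = vol(P, Q, a, b)
    v2 = vol(P, Q, b, c)
    v3 = vol(P, Q, c, a)
    same = ((v1 >= -eps) & (v2 >= -eps) & (v3 >= -eps)) | (
        (v1 <= eps) & (v2 <= eps) & (v3 <= eps))
    # coplanar or touching cases are treated as hits (conservative: keep vertex)
    degenerate = (np.abs(vP) <= eps) | (np.abs(vQ) <= eps)
    return (straddle & same) | (degenerate & same)


def kmt_reduce(trace) -> np.ndarray:
    """KMT chain simplification preserving the knot type of an open chain.

    Vertex i is deleted when the triangle (i-1, i, i+1) is crossed by no
    other chain segment; endpoints are never removed.  Iterates to a fixed
    point; idempotent.
    """
    pts = _as_coords(trace).copy()
    if len(pts) < 3:
        return pts
    changed = True
    while changed and len(pts) > 2:
        changed = False
        i = 1
        while i < len(pts) - 1 and len(pts) > 2:
            a, b, c = pts[i - 1], pts[i], pts[i + 1]
            # degenerate (colinear) triangle: retracting the spike crosses
            # no chain material, so the vertex is always removable
            if np.linalg.norm(np.cross(b - a, c - a)) < 1e-9:
                pts = np.delete(pts, i, axis=0)
                changed = True
                continue
            P = pts[:-1]
            Q = pts[1:]
            mask = np.ones(len(P), bool)
            lo = max(0, i - 2)
            hi = min(len(P), i + 2)
            mask[lo:hi] = False
            if not np.any(_segment_hits_triangle(a, b, c, P[mask], Q[mask])):
                pts = np.delete(pts, i, axis=0)
                changed = True
            else:
                i += 1
    return pts


# ---------------------------------------------------------------------------
# closures
# ---------------------------------------------------------------------------

def close_chain(trace, n_closures: int, seed: int) -> list[np.ndarray]:
    """Stochastic closures of an open chain through a bounding sphere.

    Both termini are extended radially away from the chain centroid to a
    sphere of radius 10x the trace gyration radius (at least 2x the
    farthest vertex), then joined through a random point on that sphere.
    """
    pts = _as_coords(trace)
    centroid = pts.mean(axis=0)
    rg = float(np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean()))
    rmax = float(np.linalg.norm(pts - centroid, axis=1).max())
    R = max(10.0 * rg, 2.0 * rmax, 1.0)

    def radial(p):
        d = p - centroid
        norm = np.linalg.norm(d)
        if norm < 1e-9:
            d = np.array([1.0, 0.0, 0.0])
            norm = 1.0
        return centroid + d / norm * R

    rng = np.random.default_rng(seed)
    closures = []
    for _ in range(n_closures):
        s = rng.normal(size=3)
        s = centroid + s / np.linalg.norm(s) * R
        loop = np.vstack([pts, radial(pts[-1]), s, radial(pts[0])])
        closures.append(loop)
    return closures


# ---------------------------------------------------------------------------
# Alexander invariants from a planar projection
# ---------------------------------------------------------------------------

def _project(loop: np.ndarray, rot: np.ndarray) -> np.ndarray:
    return loop @ rot.T


def _crossings(xy: np.ndarray, z: np.ndarray):
    """All transversal crossings of the closed 2D polyline.

    Returns a list of (pos_under, pos_over, sign) with positions measured
    as edge_index + parameter, or None if the projection is non-generic.
    """
    n = len(xy)
    P = xy
    Q = np.vstack([xy[1:], xy[:1]])
    zP = z
    zQ = np.concatenate([z[1:], z[:1]])
    events = []
    eps = 1e-9
    for i in range(n):
        d1 = Q[i] - P[i]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            d2 = Q[j] - P[j]
            denom = d1[0] * d2[1] - d1[1] * d2[0]
            if abs(denom) < 1e-12:
                continue
            r = P[j] - P[i]
            t = (r[0] * d2[1] - r[1] * d2[0]) / denom
            u = (r[0] * d1[1] - r[1] * d1[0]) / denom
            if t <= eps or t >= 1 - eps:
                if -eps < t < 1 + eps and -eps < u < 1 + eps:
                    if (abs(t) < eps or abs(t - 1) < eps) and (
                            -eps < u < 1 + eps):
                        pass
                continue
            if u <= eps or u >= 1 - eps:
                continue
            if min(t, u) < 1e-7 or max(t, u) > 1 - 1e-7:
                return None  # too close to a vertex: retry projection
            zi = zP[i] + t * (zQ[i] - zP[i])
            zj = zP[j] + u * (zQ[j] - zP[j])
            if abs(zi - zj) < 1e-9:
                return None
            # crossing handedness from (over direction) x (under direction)
            if zi < zj:  # segment i under, j over
                sign = 1 if -denom > 0 else -1
                events.append((i + t, j + u, sign))
            else:
                sign = 1 if denom > 0 else -1
                events.append((j + u, i + t, sign))
    return events


def _alexander_dets(crossings) -> tuple[int, int]:
    """(|Delta(-1)|, odd part of |Delta(-2)|) from the crossing list."""
    c = len(crossings)
    if c < 3:
        return 1, 1
    under_pos = sorted(x[0] for x in crossings)

    def arc_of(pos: float) -> int:
        k = np.searchsorted(under_pos, pos)
        return int(k % c)

    rows = []
    for pos_u, pos_o, sign in crossings:
        k = arc_of(pos_u)  # incoming arc index (ends at this underpass)
        j = arc_of(pos_o)
        rows.append((k, (k + 1) % c, j, sign))

    def det_at(t: Fraction) -> Fraction:
        m = [[Fraction(0)] * c for _ in range(c)]
        for k, k1, j, sign in rows:
            if j == k or j == k1:
                m[k][k] += -1
                m[k][k1] += 1
            elif sign > 0:
                m[k][k] += 1
                m[k][k1] += -t
                m[k][j] += t - 1
            else:
                m[k][k] += -t
                m[k][k1] += 1
                m[k][j] += t - 1
        size = c - 1
        a = [row[:size] for row in m[:size]]
        # fraction-free Gaussian elimination
        det = Fraction(1)
        for col in range(size):
            piv = None
            for r in range(col, size):
                if a[r][col] != 0:
                    piv = r
                    break
            if piv is None:
                return Fraction(0)
            if piv != col:
                a[col], a[piv] = a[piv], a[col]
                det = -det
            det *= a[col][col]
            inv = a[col][col]
            for r in range(col + 1, size):
                f = a[r][col] / inv
                if f == 0:
                    continue
                for cc in range(col, size):
                    a[r][cc] -= f * a[col][cc]
        return det

    d1 = abs(det_at(Fraction(-1)))
    d2 = abs(det_at(Fraction(-2)))
    d1 = int(d1)
    num = abs(d2.numerator)
    den = d2.denominator
    # strip the t^m unit: remove all factors of two from numerator/denominator
    while num and num % 2 == 0:
        num //= 2
    while den % 2 == 0:
        den //= 2
    d2_odd = num if den == 1 else 0
    return d1, d2_odd


def alexander_invariants(closed, seed: int = 0) -> tuple[int, int]:
    """Invariant pair for a closed polyline.

    Returns (|Delta(-1)|, odd part of |Delta(-2)|); the odd part removes
    the 2^m unit ambiguity of the determinant at t = -2.  The projection
    direction is re-drawn until generic.
    """
    loop = np.asarray(closed, float)
    rng = np.random.default_rng(seed)
    for attempt in range(40):
        # random rotation; project on xy, keep z for depth
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, zq = q
        rot = np.array([
            [1 - 2 * (y * y + zq * zq), 2 * (x * y - zq * w), 2 * (x * zq + y * w)],
            [2 * (x * y + zq * w), 1 - 2 * (x * x + zq * zq), 2 * (y * zq - x * w)],
            [2 * (x * zq - y * w), 2 * (y * zq + x * w), 1 - 2 * (x * x + y * y)],
        ])
        proj = _project(loop, rot)
        events = _crossings(proj[:, :2], proj[:, 2])
        if events is None:
            continue
        return _alexander_dets(events)
    raise RuntimeError("no generic projection found after 40 attempts")


def _invariants_to_type(d1: int, d2: int) -> str:
    if d1 == 1 and d2 == 1:
        return "0_1"
    if d1 == 3:
        return "3_1"
    if d1 == 5 and d2 == 11:
        return "4_1"
    if d1 == 5 and d2 == 31:
        return "5_1"
    if d1 == 7:
        return "5_2"
    return "other"


def classify_knot(trace, n_closures: int = DEFAULT_CLOSURES,
                  seed: int = 0) -> tuple[str, float]:
    """Voted knot type of an open chain.

    KMT-reduces the chain, generates stochastic closures, computes the
    invariant pair per closure and returns the majority type with its vote
    fraction; exact ties report "other".
    """
    pts = kmt_reduce(trace)
    if len(pts) <= 3:
        return "0_1", 1.0
    votes: dict[str, int] = {}
    for ci, loop in enumerate(close_chain(pts, n_closures, seed)):
        reduced_loop = loop
        try:
            d1, d2 = alexander_invariants(reduced_loop, seed=seed * 7919 + ci)
            ktype = _invariants_to_type(d1, d2)
        except RuntimeError:
            ktype = "other"
        votes[ktype] = votes.get(ktype, 0) + 1
    best = max(votes.values())
    winners = [k for k, v in votes.items() if v == best]
    if len(winners) > 1:
        return "other", best / n_closures
    return winners[0], best / n_closures


def knot_core(trace, n_closures: int = DEFAULT_CLOSURES,
              seed: int = 0) -> tuple[int, int, int]:
    """Knot core boundaries by bidirectional trimming.

    Residues are removed one at a time from the N terminus while the
    remaining subchain still classifies to the full-chain knot type, then
    likewise from the C terminus.  Returns (k_minus, k_plus, delta_k) with
    1-based inclusive boundaries.
    """
    pts = _as_coords(trace)
    full_type, _ = classify_knot(pts, n_closures, seed)
    if full_type == "0_1":
        raise ValueError("knot core undefined for an unknotted chain")
    n = len(pts)
    start = 0
    while start < n - 4:
        t, _ = classify_knot(pts[start + 1:], n_closures, seed)
        if t != full_type:
            break
        start += 1
    end = n - 1
    while end > start + 3:
        t, _ = classify_knot(pts[start:end], n_closures, seed)
        if t != full_type:
            break
        end -= 1
    k_minus = start + 1
    k_plus = end + 1
    return k_minus, k_plus, k_plus - k_minus + 1


def knot_report(trace, n_closures: int = DEFAULT_CLOSURES,
                seed: int = 0) -> KnotReport:
    """Full knot report (type, votes, core boundaries) for one chain."""
    ktype, votes = classify_knot(trace, n_closures, seed)
    if ktype in ("0_1", "other"):
        return KnotReport(ktype, closure_votes=votes)
    k_minus, k_plus, _ = knot_core(trace, n_closures, seed)
    return KnotReport(ktype, k_minus, k_plus, votes)


def untying_under_stretch(model, params, n_seeds: int,
                          n_closures: int = 32, seed: int = 0):
    """Fraction of pulling runs whose final conformation is unknotted.

    The verdict uses the final frame only.  Returns (fraction, binomial
    standard error, per-seed final knot types).
    """
    from polyqlab.go_model import pull_constant_speed

    initial_type, _ = classify_knot(model.native_coords, n_closures, seed)
    if initial_type == "0_1":
        raise ValueError("initial conformation is not knotted")
    finals = []
    for s in range(n_seeds):
        run_params = params.with_seed(params.seed + 1000 * s + 1)
        curve, traj = pull_constant_speed(model, run_params)
        ktype, _ = classify_knot(traj[-1], n_closures, seed)
        finals.append(ktype)
    untied = sum(1 for k in finals if k == "0_1")
    frac = untied / n_seeds
    se = float(np.sqrt(max(frac * (1 - frac), 1e-12) / n_seeds))
    return frac, se, finals
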
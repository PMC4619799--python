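"""Synthetic conformer and trajectory generators.

These generators stand in for biased-sampling trajectories when exercising
the analysis chain: ideal secondary-structure motifs, self-avoiding coils,
chains with planted knots of known type and core location, and time-ordered
ensembles with planted cluster structure for the independence sieve.  Every
generator is a pure function of its arguments (bitwise reproducible per
seed).  Synthetic conformers carry backbone heavy atoms only; no side
chains are synthesized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from polyqlab import _geometry as geom
from polyqlab.structure import Conformer, Ensemble, Residue

DEFAULT_BOND = 3.8  # CA-CA spacing in angstrom

# ideal dihedrals (phi, psi) in degrees
HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -139.0, 135.0
EXTENDED_PHI, EXTENDED_PSI = -180.0, 180.0
# two-residue turn joining the hairpin strands (type II')
TURN_DIHEDRALS = ((60.0, -120.0), (-80.0, 0.0))


@dataclass
class GeneratorSpec:
    """Declarative description of one synthetic conformer."""

    kind: str
    n_residues: int
    knot_type: str = "0_1"
    tail_lengths: tuple[int, int] = (5, 5)
    seed: int = 0
    bond_length: float = DEFAULT_BOND

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("n_residues must be >= 4")


def _conformer_from_backbone(backbone: dict[str, np.ndarray], id: str) -> Conformer:
    n = len(backbone["CA"])
    residues = [
        Residue("GLN", {name: backbone[name][i] for name in ("N", "CA", "C", "O")})
        for i in range(n)
    ]
    return Conformer(id, "Q" * n, residues)


def _ca_only_conformer(coords: np.ndarray, id: str) -> Conformer:
    residues = [Residue("GLN", {"CA": c}) for c in np.asarray(coords, float)]
    return Conformer(id, "Q" * len(residues), residues)


def make_ideal(kind: str, n: int) -> Conformer:
    """Ideal-geometry motif with a full N/CA/C/O backbone.

    ``helix`` uses canonical alpha dihedrals (phi=-57, psi=-47); ``hairpin``
    is two antiparallel strands joined by a tight two-residue turn;
    ``extended`` is a near-colinear all-trans chain.
    """
    if kind in ("helix", "hairpin") and n < 6:
        raise ValueError(f"{kind} needs at least 6 residues")
    if n < 2:
        raise ValueError("n must be >= 2")
    if kind == "helix":
        phi = np.full(n, HELIX_PHI)
        psi = np.full(n, HELIX_PSI)
    elif kind == "extended":
        phi = np.full(n, EXTENDED_PHI)
        psi = np.full(n, EXTENDED_PSI)
    elif kind == "hairpin":
        n_turn = 2
        n_first = (n - n_turn) // 2
        phi = np.full(n, STRAND_PHI)
        psi = np.full(n, STRAND_PSI)
        for k, (tphi, tpsi) in enumerate(TURN_DIHEDRALS):
            phi[n_first + k] = tphi
            psi[n_first + k] = tpsi
    else:
        raise ValueError(f"unknown motif kind {kind!r}")
    backbone = geom.backbone_from_dihedrals(phi, psi)
    return _conformer_from_backbone(backbone, f"{kind}_{n}")


def make_self_avoiding_coil(n: int, seed: int,
                            bond_length: float = DEFAULT_BOND,
                            min_distance: float = 4.0,
                            max_restarts: int = 500) -> Conformer:
    """Self-avoiding random walk with fixed CA-CA bond length.

    No two non-bonded CA atoms come closer than ``min_distance``.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        coords = np.zeros((n, 3))
        ok = True
        for i in range(1, n):
            placed = False
            for _ in range(120):
                v = rng.normal(size=3)
                v *= bond_length / np.linalg.norm(v)
                cand = coords[i - 1] + v
                if i >= 2:
                    d = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                    if d.min() < min_distance:
                        continue
                coords[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return _ca_only_conformer(coords, f"coil_{n}_s{seed}")
    raise RuntimeError(f"self-avoiding walk failed after {max_restarts} restarts")


# ---------------------------------------------------------------------------
# planted knots
# ---------------------------------------------------------------------------

def _parametric_curve(knot_type: str, n_samples: int = 4000) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n_samples, endpoint=False)
    if knot_type == "3_1":
        x = np.sin(t) + 2 * np.sin(2 * t)
        y = np.cos(t) - 2 * np.cos(2 * t)
        z = -np.sin(3 * t)
    elif knot_type == "4_1":
        x = (2 + np.cos(2 * t)) * np.cos(3 * t)
        y = (2 + np.cos(2 * t)) * np.sin(3 * t)
        z = np.sin(4 * t)
    elif knot_type == "5_1":
        x = (2 + np.cos(5 * t)) * np.cos(2 * t)
        y = (2 + np.cos(5 * t)) * np.sin(2 * t)
        z = np.sin(5 * t)
    elif knot_type == "5_2":
        return _braid_closure_curve([1, 1, 1, 2, -1, 2], n_strands=3)
    else:
        raise ValueError(f"no parametric curve for {knot_type!r}")
    return np.column_stack([x, y, z])


def _braid_closure_curve(word: list[int], n_strands: int) -> np.ndarray:
    """Closed polyline realizing the closure of a braid word.

    Generator ``i`` (1-based, sign = crossing handedness) swaps the strands
    in slots i-1 and i; closure arcs run behind the braid at distinct
    depths so they introduce no extra crossings.
    """
    spacing = 4.0
    h = 1.0
    paths: dict[int, list[np.ndarray]] = {s: [] for s in range(n_strands)}
    slot_of = list(range(n_strands))  # strand occupying each slot
    y = 0.0
    for s in range(n_strands):
        paths[s].append(np.array([s * spacing, y, 0.0]))
    for letter in word:
        i = abs(letter) - 1
        y += 2.0
        a, b = slot_of[i], slot_of[i + 1]
        za = h if letter > 0 else -h
        mid_y = y - 1.0
        mid_x = (i + 0.5) * spacing
        paths[a].append(np.array([mid_x, mid_y, za]))
        paths[b].append(np.array([mid_x, mid_y, -za]))
        paths[a].append(np.array([(i + 1) * spacing, y, 0.0]))
        paths[b].append(np.array([i * spacing, y, 0.0]))
        for j in range(n_strands):
            if j != i and j != i + 1:
                paths[slot_of[j]].append(np.array([j * spacing, y, 0.0]))
        slot_of[i], slot_of[i + 1] = b, a
    y_end = y + 2.0
    for j in range(n_strands):
        paths[slot_of[j]].append(np.array([j * spacing, y_end, 0.0]))
    # follow the closure: top of slot j connects behind to bottom of slot j
    curve: list[np.ndarray] = []
    strand = 0
    visited = 0
    while True:
        curve.extend(paths[strand])
        end_slot = slot_of.index(strand)
        depth = 3.0 + 1.5 * end_slot
        x = end_slot * spacing
        curve.append(np.array([x, y_end + 2.0, -depth]))
        curve.append(np.array([x, -2.0, -depth]))
        visited += 1
        next_strand = end_slot  # strand that started in this slot
        if next_strand == 0:
            break
        strand = next_strand
        if visited > n_strands:  # pragma: no cover - malformed word
            raise RuntimeError("braid closure is not a single component")
    if visited != n_strands:
        raise RuntimeError("braid closure is not a knot (multiple components)")
    return np.array(curve)


def _densify(points: np.ndarray, step: float = 0.05, closed: bool = False) -> np.ndarray:
    pts = np.asarray(points, float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = np.linalg.norm(b - a)
        k = max(1, int(np.ceil(seg / step)))
        for m in range(1, k + 1):
            out.append(a + (b - a) * m / k)
    return np.array(out)


def _open_knot_core(knot_type: str, n_core: int, bond_length: float) -> np.ndarray:
    """Open polyline with ``n_core`` vertices at fixed spacing tracing the knot."""
    if knot_type == "0_1":
        # open three-quarter circle: trivially unknotted
        t = np.linspace(0.0, 1.5 * np.pi, 400)
        base = np.column_stack([np.cos(t), np.sin(t), 0.02 * t])
    else:
        closed = _parametric_curve(knot_type)
        dense = _densify(closed, step=np.ptp(closed) / 2000.0, closed=True)[:-1]
        # cut where the curve is farthest from its centroid so that radial
        # tails leave through empty space instead of piercing the knot
        radii = np.linalg.norm(dense - dense.mean(axis=0), axis=1)
        dense = np.roll(dense, -int(np.argmax(radii)), axis=0)
        gap = max(2, len(dense) // 50)
        base = dense[gap:]
    dense = _densify(base, step=float(np.ptp(base)) / 4000.0)
    # bisect the scale factor until chord resampling yields n_core vertices
    lo, hi = 1e-2, 1e4
    for _ in range(80):
        scale = np.sqrt(lo * hi)
        pts = geom.chord_resample(dense * scale, bond_length)
        if len(pts) < n_core:
            lo = scale
        elif len(pts) > n_core:
            hi = scale
        else:
            return pts
    raise RuntimeError(f"could not fit {n_core} residues on a {knot_type} curve")


def make_knotted_chain(n: int, knot_type: str, tail_lengths: tuple[int, int] = (5, 5),
                       seed: int = 0, bond_length: float = DEFAULT_BOND) -> Conformer:
    """CA chain tracing a planted knot with straight flanking tails.

    The backbone resamples the standard parametric curve of the requested
    knot at fixed CA spacing.  The planted core span (0-based, inclusive)
    is recorded on the returned conformer as ``planted_core``.
    """
    if knot_type not in ("0_1", "3_1", "4_1", "5_1", "5_2"):
        raise ValueError(f"unsupported knot type {knot_type!r}")
    t_n, t_c = tail_lengths
    n_core = n - t_n - t_c
    if n_core < 16:
        raise ValueError("chain too short to host the knot core")
    core = _open_knot_core(knot_type, n_core, bond_length)
    centroid = core.mean(axis=0)

    def tail(end_point: np.ndarray, length: int) -> np.ndarray:
        if length == 0:
            return np.empty((0, 3))
        d = end_point - centroid
        d /= np.linalg.norm(d)
        return end_point + bond_length * d * np.arange(1, length + 1)[:, None]

    head = tail(core[0], t_n)[::-1]
    back = tail(core[-1], t_c)
    coords = np.vstack([head, core, back])
    conf = _ca_only_conformer(coords, f"{knot_type}_n{n}_s{seed}")
    conf.planted_span = (t_n, n - t_c - 1)
    if knot_type != "0_1":
        conf.planted_core = crossing_span(coords, seed=seed)
    return conf


def crossing_span(coords: np.ndarray, n_projections: int = 30,
                  seed: int = 0) -> tuple[int, int]:
    """Median span of vertices taking part in diagram crossings.

    A purely geometric ground truth for where a planted knot lives: for
    each of ``n_projections`` random planar projections, find the first
    and last vertex involved in any polyline self-crossing; return the
    median span (0-based, inclusive).  End arcs beyond all crossings are
    isotopically removable, so this marks the essential core.
    """
    pts = np.asarray(coords, float)
    n = len(pts)
    rng = np.random.default_rng(seed)
    firsts, lasts = [], []
    for _ in range(n_projections):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ])
        xy = (pts @ rot.T)[:, :2]
        first, last = None, None
        for i in range(n - 1):
            d1 = xy[i + 1] - xy[i]
            for j in range(i + 2, n - 1):
                d2 = xy[j + 1] - xy[j]
                den = d1[0] * d2[1] - d1[1] * d2[0]
                if abs(den) < 1e-12:
                    continue
                r = xy[j] - xy[i]
                t = (r[0] * d2[1] - r[1] * d2[0]) / den
                u = (r[0] * d1[1] - r[1] * d1[0]) / den
                if 0 < t < 1 and 0 < u < 1:
                    if first is None or i < first:
                        first = i
                    if j + 1 > (last if last is not None else -1):
                        last = j + 1
        if first is not None:
            firsts.append(first)
            lasts.append(last)
    if not firsts:
        raise ValueError("no crossings in any projection (unknotted?)")
    return int(np.median(firsts)), int(np.median(lasts))


def backbone_from_ca(trace: Conformer) -> Conformer:
    """Rebuild N/CA/C/O backbone atoms around a CA-only trace.

    Peptide planes use ideal trans geometry; CA positions are unchanged.
    """
    ca = trace.ca_coords()
    n = len(ca)
    if n < 3:
        raise ValueError("need at least 3 residues")
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    if d.min() < 2.5 or d.max() > 4.5:
        raise ValueError(
            f"CA spacing outside [2.5, 4.5] angstrom (range {d.min():.2f}"
            f"-{d.max():.2f})"
        )
    # rigid trans-peptide quad CA(i)-C(i)-N(i+1)-CA(i+1) in local 2D frame
    origin = np.zeros(3)
    c_loc = np.array([geom.BOND_CA_C, 0.0, 0.0])
    n_loc = geom.place_atom(np.array([0.0, 1.0, 0.0]), origin, c_loc,
                            geom.BOND_C_N, geom.ANGLE_CA_C_N, 0.0)
    ca2_loc = geom.place_atom(origin, c_loc, n_loc,
                              geom.BOND_C_N * 0 + geom.BOND_N_CA,
                              geom.ANGLE_C_N_CA, 180.0)
    L0 = np.linalg.norm(ca2_loc)
    e1 = ca2_loc / L0
    c_par, n_par = np.dot(c_loc, e1), np.dot(n_loc, e1)
    e2 = c_loc - np.dot(c_loc, e1) * e1
    e2 /= np.linalg.norm(e2)
    c_perp, n_perp = np.dot(c_loc, e2), np.dot(n_loc, e2)

    C = np.zeros((n, 3))
    N = np.zeros((n, 3))
    O = np.zeros((n, 3))
    for i in range(n - 1):
        u = ca[i + 1] - ca[i]
        L = np.linalg.norm(u)
        u = u / L
        if i + 2 < n:
            ref = ca[i + 2] - ca[i + 1]
        else:
            ref = ca[i] - ca[i - 1]
        w = np.cross(u, ref)
        if np.linalg.norm(w) < 1e-8:
            w = np.cross(u, np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(w) < 1e-8:
                w = np.cross(u, np.array([0.0, 1.0, 0.0]))
        w /= np.linalg.norm(w)
        v = np.cross(w, u)
        scale = L / L0
        C[i] = ca[i] + (c_par * scale) * u + c_perp * v
        N[i + 1] = ca[i] + (n_par * scale) * u + n_perp * v
    # first N and last C from ideal internal coordinates
    N[0] = geom.place_atom(ca[1], C[0], ca[0], geom.BOND_N_CA,
                           geom.ANGLE_N_CA_C, 180.0)
    C[n - 1] = geom.place_atom(C[n - 2], N[n - 1], ca[n - 1], geom.BOND_CA_C,
                               geom.ANGLE_N_CA_C, 180.0)
    for i in range(n - 1):
        O[i] = geom.carbonyl_oxygen(ca[i], C[i], N[i + 1])
    u = C[-1] - ca[-1]
    u /= np.linalg.norm(u)
    O[-1] = C[-1] + geom.BOND_C_O * u
    backbone = {"N": N, "CA": ca, "C": C, "O": O}
    out = _conformer_from_backbone(backbone, trace.id)
    out.timestamp = trace.timestamp
    if hasattr(trace, "planted_core"):
        out.planted_core = trace.planted_core
    return out


def perturb(conformer: Conformer, amplitude: float, seed: int) -> Conformer:
    """Add zero-mean isotropic Gaussian noise (std ``amplitude`` per coordinate)."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    residues = []
    for res in conformer.residues:
        atoms = {
            name: coord + rng.normal(scale=amplitude, size=3) if amplitude > 0
            else coord.copy()
            for name, coord in res.atoms.items()
        }
        residues.append(Residue(res.name, atoms))
    out = Conformer(conformer.id, conformer.sequence, residues,
                    conformer.timestamp)
    return out


@dataclass
class SieveFixture:
    """Time-ordered ensemble with planted cluster structure."""

    ensemble: Ensemble
    ss_values: np.ndarray  # percent per frame
    n_clusters: int
    frame_cluster: np.ndarray = field(default=None)  # planted cluster id per frame


def make_sieve_fixture(n_frames: int, cluster_plan, seed: int,
                       n_residues: int = 20) -> SieveFixture:
    """Trajectory whose timestamps and SS values realize a planted plan.

    ``cluster_plan`` is a list of ``(start_ps, end_ps, ss_percent)`` with
    disjoint, increasing intervals; ``n_frames`` frames are distributed over
    the intervals proportionally to their durations (at least one each).
    Frames within one interval are small perturbations of a per-interval
    base coil, so structural independence also recovers the plan.
    """
    plan = sorted(cluster_plan)
    for (s1, e1, _), (s2, _, _) in zip(plan, plan[1:]):
        if e1 >= s2:
            raise ValueError("cluster plan intervals overlap")
    for s, e, _ in plan:
        if e < s:
            raise ValueError("interval end before start")
    durations = np.array([e - s for s, e, _ in plan], float)
    weights = durations + 1e-9
    alloc = np.maximum(1, np.round(n_frames * weights / weights.sum()).astype(int))
    rng = np.random.default_rng(seed)
    conformers, ss_values, cluster_ids = [], [], []
    for ci, ((start, end, ss), k) in enumerate(zip(plan, alloc)):
        base = make_self_avoiding_coil(n_residues, seed=seed * 1000 + ci)
        times = np.linspace(start, end, k)
        for fi, t in enumerate(times):
            frame = perturb(base, 0.2, seed=seed * 100000 + ci * 1000 + fi)
            frame.timestamp = float(t)
            frame.id = f"frame_c{ci}_{fi}"
            conformers.append(frame)
            ss_values.append(ss + rng.uniform(-0.5, 0.5))
            cluster_ids.append(ci)
    ens = Ensemble(conformers, is_time_ordered=True)
    return SieveFixture(ens, np.array(ss_values), len(plan),
                        np.array(cluster_ids))
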
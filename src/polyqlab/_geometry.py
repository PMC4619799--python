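"""Internal-coordinate geometry helpers (NeRF atom placement, peptide geometry)."""

from __future__ import annotations

import numpy as np

# ideal backbone internal coordinates (angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA_TRANS = 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d given the three preceding atoms and internal coordinates.

    ``|d - c| = bond``, ``angle(b, c, d) = angle_deg`` and
    ``dihedral(a, b, c, d) = dihedral_deg``.
    """
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:  # colinear frame: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, bc)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def carbonyl_oxygen(ca: np.ndarray, c: np.ndarray, n_next: np.ndarray) -> np.ndarray:
    """Carbonyl O in the peptide plane, opposite the CA/N bisector at C."""
    u = ca - c
    v = n_next - c
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    d = -(u + v)
    d /= np.linalg.norm(d)
    return c + BOND_C_O * d


def backbone_from_dihedrals(phi: np.ndarray, psi: np.ndarray,
                            omega: float = OMEGA_TRANS) -> dict[str, np.ndarray]:
    """Build N/CA/C/O backbone coordinates for a chain from phi/psi arrays.

    ``phi[0]`` and ``psi[-1]`` are undefined for a real chain but still
    consumed to seed/terminate the build.  Returns arrays of shape (n, 3).
    """
    n_res = len(phi)
    if len(psi) != n_res:
        raise ValueError("phi/psi length mismatch")
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    # seed the first residue
    N[0] = np.array([0.0, 0.0, 0.0])
    CA[0] = np.array([BOND_N_CA, 0.0, 0.0])
    C[0] = place_atom(np.array([0.0, 1.0, 0.0]), N[0], CA[0],
                      BOND_CA_C, ANGLE_N_CA_C, psi[0] + 120.0)
    for i in range(1, n_res):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                          BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                           BOND_N_CA, ANGLE_C_N_CA, omega)
        C[i] = place_atom(C[i - 1], N[i], CA[i],
                          BOND_CA_C, ANGLE_N_CA_C, phi[i])
    O = np.zeros((n_res, 3))
    for i in range(n_res - 1):
        O[i] = carbonyl_oxygen(CA[i], C[i], N[i + 1])
    # last O: trans to N along the CA->C direction, in the N-CA-C plane
    u = C[-1] - CA[-1]
    u /= np.linalg.norm(u)
    w = N[-1] - CA[-1]
    w -= np.dot(w, u) * u
    w /= np.linalg.norm(w)
    O[-1] = C[-1] + BOND_C_O * (u * np.cos(np.deg2rad(59.2))
                                - w * np.sin(np.deg2rad(59.2)))
    return {"N": N, "CA": CA, "C": C, "O": O}


def chord_resample(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a dense polyline so consecutive output points are exactly
    ``spacing`` apart (last partial step dropped)."""
    points = np.asarray(points, float)
    out = [points[0]]
    j = 0
    while True:
        last = out[-1]
        # advance to the first vertex beyond `spacing` from `last`
        while j < len(points) - 1 and np.linalg.norm(points[j + 1] - last) < spacing:
            j += 1
        if j >= len(points) - 1:
            break
        a, b = points[j], points[j + 1]
        # solve |a + t (b - a) - last| = spacing for t in (0, 1]
        d = b - a
        f = a - last
        aa = np.dot(d, d)
        bb = 2.0 * np.dot(f, d)
        cc = np.dot(f, f) - spacing ** 2
        disc = bb * bb - 4 * aa * cc
        if disc < 0:
            j += 1
            continue
        t = (-bb + np.sqrt(disc)) / (2 * aa)
        if not (0.0 <= t <= 1.0):
            j += 1
            continue
        out.append(a + t * d)
    return np.array(out)


def resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at fixed arc-length spacing (endpoints kept)."""
    points = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n_out = max(2, int(round(total / spacing)) + 1)
    targets = np.linspace(0.0, total, n_out)
    out = np.empty((n_out, 3))
    for k, t in enumerate(targets):
        j = min(np.searchsorted(arc, t, side="right") - 1, len(seg) - 1)
        frac = (t - arc[j]) / seg[j] if seg[j] > 0 else 0.0
        out[k] = points[j] + frac * (points[j + 1] - points[j])
    return out
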
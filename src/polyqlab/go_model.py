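"""Structure-based coarse-grained CA model with Langevin dynamics and pulling.

The model is built from a reference conformer and its contact map: harmonic
bonds at native lengths, 12-6 Lennard-Jones wells of depth eps with minima
at the native CA-CA distances for every native contact, a harmonic
chirality term on each backbone quadruplet, and purely repulsive
excluded-volume interactions for non-contact non-bonded pairs.  Energies
are in eps, lengths in angstrom, time in the intrinsic unit tau; at the
calibration eps = 110 pN A, a force of 1 eps/A equals 110 pN.

Constant-speed stretching tethers one terminus to a fixed harmonic anchor
and the other to an anchor moving along the initial end-to-end axis; the
recorded spring force vs anchor displacement, boxcar-averaged over 1 A,
is the force-extension curve from which peaks, F_max and the unfolding
scenario are read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.signal import find_peaks

from polyqlab.structure import Conformer
from polyqlab.descriptors import ContactMap

EPS_PN_ANGSTROM = 110.0  # force-unit calibration: 1 eps/A = 110 pN


def force_to_pN(f_eps_per_A, eps_pN_A: float = EPS_PN_ANGSTROM):
    """Convert a force from eps/A to pN (reporting layer)."""
    return np.asarray(f_eps_per_A, float) * eps_pN_A


@dataclass
class GoModelParams:
    """Simulation parameters in reduced units (eps, angstrom, tau)."""

    epsilon: float = 1.0          # energy unit
    temperature: float = 0.3      # eps/k_B
    v_pull: float = 5e-3          # A/tau
    timestep: float = 0.005       # tau
    damping: float = 2.0          # 1/tau
    bond_k: float = 100.0         # eps/A^2
    chirality_k: float = 1.0      # eps
    repulsive_sigma: float = 4.0  # A
    spring_k: float = 0.12        # eps/A^2
    noise_level: float = 0.1      # eps/A, force-peak detection threshold
    break_factor: float = 1.5     # contact rupture criterion
    seed: int = 0
    eps_pN_A: float = EPS_PN_ANGSTROM

    def __post_init__(self) -> None:
        for name in ("epsilon", "timestep", "bond_k", "spring_k",
                     "repulsive_sigma", "break_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("temperature", "damping", "v_pull", "noise_level",
                     "chirality_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_seed(self, seed: int) -> "GoModelParams":
        return replace(self, seed=int(seed))


@dataclass
class GoModel:
    """Native geometry plus the interaction lists derived from it."""

    native_coords: np.ndarray            # (n, 3) CA positions
    bond_lengths: np.ndarray             # (n-1,)
    contact_i: np.ndarray                # (m,) int
    contact_j: np.ndarray
    contact_r0: np.ndarray               # native CA-CA distances
    rep_i: np.ndarray                    # repulsive (non-contact) pairs
    rep_j: np.ndarray
    rep_sigma: np.ndarray
    native_chirality: np.ndarray         # (n-3,)
    chir_norm: np.ndarray                # d0^3 per quadruplet

    @property
    def n_residues(self) -> int:
        return len(self.native_coords)

    @property
    def n_contacts(self) -> int:
        return len(self.contact_i)

    @property
    def contour_length(self) -> float:
        return float(self.bond_lengths.sum())


@dataclass
class ForceCurve:
    """Force-extension record with detected peaks."""

    displacement: np.ndarray     # A, increasing
    force: np.ndarray            # eps/A
    peaks: list[tuple[float, float]] = field(default_factory=list)
    F_max: float = 0.0
    n_p: int = 0
    contour_length: float = 0.0

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("d_angstrom,F_eps_per_angstrom\n")
            for d, f in zip(self.displacement, self.force):
                fh.write(f"{d:.3f},{f:.6f}\n")


@dataclass
class ScenarioEvent:
    """Last rupture of one native contact during a pull (1-based report)."""

    i: int
    j: int
    sep: int
    d_break: float | None        # anchor displacement in A; None if unbroken

    @property
    def broken(self) -> bool:
        return self.d_break is not None


def _chirality(coords: np.ndarray, norm: np.ndarray) -> np.ndarray:
    v = np.diff(coords, axis=0)
    c = np.einsum("ij,ij->i", np.cross(v[:-2], v[1:-1]), v[2:])
    return c / norm


def build_go_model(conformer: Conformer, cmap: ContactMap,
                   params: GoModelParams | None = None) -> GoModel:
    """Assemble the coarse-grained model from a conformer and its contacts."""
    params = params or GoModelParams()
    coords = conformer.ca_coords()
    n = len(coords)
    if cmap.n_residues != n:
        raise ValueError("contact map does not match the conformer length")
    bonds = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    ci = np.array([i for i, _ in cmap.contacts], dtype=np.int64)
    cj = np.array([j for _, j in cmap.contacts], dtype=np.int64)
    r0 = cmap.native_ca_distance.astype(float)
    contact_set = set(cmap.contacts)
    rep_i, rep_j, rep_s = [], [], []
    d_nat = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    for i in range(n):
        for j in range(i + 2, n):
            if (i, j) in contact_set:
                continue
            # sigma never exceeds the native separation, so the native state
            # carries exactly -eps per contact and nothing else
            rep_i.append(i)
            rep_j.append(j)
            rep_s.append(min(params.repulsive_sigma, d_nat[i, j]))
    norm = np.array([bonds[k] * bonds[k + 1] * bonds[k + 2]
                     for k in range(n - 3)])
    chir = _chirality(coords, norm)
    return GoModel(
        native_coords=coords,
        bond_lengths=bonds,
        contact_i=ci, contact_j=cj, contact_r0=r0,
        rep_i=np.array(rep_i, dtype=np.int64),
        rep_j=np.array(rep_j, dtype=np.int64),
        rep_sigma=np.array(rep_s, float),
        native_chirality=chir,
        chir_norm=norm,
    )


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=False)
def _add_forces(pos, b0, ci, cj, r0, ri, rj, sig, cnat, cnorm,
                eps, bond_k, chir_k, forces):
    n = pos.shape[0]
    energy = 0.0
    # bonds
    for k in range(n - 1):
        dx = pos[k + 1, 0] - pos[k, 0]
        dy = pos[k + 1, 1] - pos[k, 1]
        dz = pos[k + 1, 2] - pos[k, 2]
        r = (dx * dx + dy * dy + dz * dz) ** 0.5
        dr = r - b0[k]
        energy += 0.5 * bond_k * dr * dr
        f = -bond_k * dr / r
        forces[k + 1, 0] += f * dx
        forces[k + 1, 1] += f * dy
        forces[k + 1, 2] += f * dz
        forces[k, 0] -= f * dx
        forces[k, 1] -= f * dy
        forces[k, 2] -= f * dz
    # native contacts: 12-6 with minimum -eps at r0
    for k in range(ci.shape[0]):
        i = ci[k]
        j = cj[k]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = r2 ** 0.5
        s6 = (r0[k] * r0[k] / r2) ** 3
        s12 = s6 * s6
        energy += eps * (s12 - 2.0 * s6)
        dv = -12.0 * eps * (s12 - s6) / r  # dV/dr
        f = -dv / r
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz
    # excluded volume: shifted 12-6, zero beyond sigma
    for k in range(ri.shape[0]):
        i = ri[k]
        j = rj[k]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        s = sig[k]
        if r2 < s * s:
            r = r2 ** 0.5
            s6 = (s * s / r2) ** 3
            s12 = s6 * s6
            energy += eps * (s12 - 2.0 * s6) + eps
            dv = -12.0 * eps * (s12 - s6) / r
            f = -dv / r
            forces[j, 0] += f * dx
            forces[j, 1] += f * dy
            forces[j, 2] += f * dz
            forces[i, 0] -= f * dx
            forces[i, 1] -= f * dy
            forces[i, 2] -= f * dz
    # chirality: V = k/2 (C - C_nat)^2, C = det(v1, v2, v3) / d0^3
    for q in range(n - 3):
        v1x = pos[q + 1, 0] - pos[q, 0]
        v1y = pos[q + 1, 1] - pos[q, 1]
        v1z = pos[q + 1, 2] - pos[q, 2]
        v2x = pos[q + 2, 0] - pos[q + 1, 0]
        v2y = pos[q + 2, 1] - pos[q + 1, 1]
        v2z = pos[q + 2, 2] - pos[q + 1, 2]
        v3x = pos[q + 3, 0] - pos[q + 2, 0]
        v3y = pos[q + 3, 1] - pos[q + 2, 1]
        v3z = pos[q + 3, 2] - pos[q + 2, 2]
        c12x = v1y * v2z - v1z * v2y
        c12y = v1z * v2x - v1x * v2z
        c12z = v1x * v2y - v1y * v2x
        det = c12x * v3x + c12y * v3y + c12z * v3z
        c = det / cnorm[q]
        dc = c - cnat[q]
        energy += 0.5 * chir_k * dc * dc
        pref = chir_k * dc / cnorm[q]
        # d(det)/dv1 = v2 x v3 ; /dv2 = v3 x v1 ; /dv3 = v1 x v2
        c23x = v2y * v3z - v2z * v3y
        c23y = v2z * v3x - v2x * v3z
        c23z = v2x * v3y - v2y * v3x
        c31x = v3y * v1z - v3z * v1y
        c31y = v3z * v1x - v3x * v1z
        c31z = v3x * v1y - v3y * v1x
        # atom gradients: v1 = p1 - p0, v2 = p2 - p1, v3 = p3 - p2
        forces[q, 0] += pref * c23x
        forces[q, 1] += pref * c23y
        forces[q, 2] += pref * c23z
        forces[q + 1, 0] += pref * (-c23x + c31x)
        forces[q + 1, 1] += pref * (-c23y + c31y)
        forces[q + 1, 2] += pref * (-c23z + c31z)
        forces[q + 2, 0] += pref * (-c31x + c12x)
        forces[q + 2, 1] += pref * (-c31y + c12y)
        forces[q + 2, 2] += pref * (-c31z + c12z)
        forces[q + 3, 0] += pref * (-c12x)
        forces[q + 3, 1] += pref * (-c12y)
        forces[q + 3, 2] += pref * (-c12z)
    return energy


@njit(cache=False)
def _run_langevin(pos, vel, b0, ci, cj, r0, ri, rj, sig, cnat, cnorm,
                  eps, bond_k, chir_k, temperature, gamma, dt,
                  n_steps, record_every, seed):
    np.random.seed(seed)
    n = pos.shape[0]
    n_rec = n_steps // record_every
    frames = np.empty((n_rec, n, 3))
    e_kin = np.empty(n_rec)
    e_pot = np.empty(n_rec)
    # BAOAB splitting: velocity Verlet plus an exact Ornstein-Uhlenbeck kick
    c1 = np.exp(-gamma * dt)
    c2 = (temperature * (1.0 - c1 * c1)) ** 0.5
    forces = np.zeros((n, 3))
    _add_forces(pos, b0, ci, cj, r0, ri, rj, sig, cnat, cnorm,
                eps, bond_k, chir_k, forces)
    rec = 0
    epot = 0.0
    for step in range(n_steps):
        for a in range(n):
            for d in range(3):
                vel[a, d] += 0.5 * dt * forces[a, d]
                pos[a, d] += 0.5 * dt * vel[a, d]
        if gamma > 0.0:
            g = np.random.standard_normal(n * 3)
            for a in range(n):
                for d in range(3):
                    vel[a, d] = c1 * vel[a, d] + c2 * g[3 * a + d]
        for a in range(n):
            for d in range(3):
                pos[a, d] += 0.5 * dt * vel[a, d]
        forces[:] = 0.0
        epot = _add_forces(pos, b0, ci, cj, r0, ri, rj, sig, cnat, cnorm,
                           eps, bond_k, chir_k, forces)
        for a in range(n):
            for d in range(3):
                vel[a, d] += 0.5 * dt * forces[a, d]
        if (step + 1) % record_every == 0:
            ok = True
            ek = 0.0
            for a in range(n):
                for d in range(3):
                    if not np.isfinite(pos[a, d]):
                        ok = False
                    ek += 0.5 * vel[a, d] * vel[a, d]
            if not ok:
                return frames[:rec], e_kin[:rec], e_pot[:rec], step + 1
            frames[rec] = pos
            e_kin[rec] = ek
            e_pot[rec] = epot
            rec += 1
    return frames[:rec], e_kin[:rec], e_pot[:rec], -1


@njit(cache=False)
def _run_pull(pos, vel, b0, ci, cj, r0, ri, rj, sig, cnat, cnorm,
              eps, bond_k, chir_k, temperature, gamma, dt,
              v_pull, spring_k, axis, d_max, ext_stop,
              sample_every, snap_every, seed):
    np.random.seed(seed)
    n = pos.shape[0]
    anchor0 = pos[0].copy()
    anchor1 = pos[n - 1].copy()
    max_steps = int(d_max / (v_pull * dt)) + 1
    n_samp = max_steps // sample_every + 2
    n_snap = max_steps // snap_every + 2
    samp_d = np.empty(n_samp)
    samp_f = np.empty(n_samp)
    snaps = np.empty((n_snap, n, 3))
    snap_d = np.empty(n_snap)
    c1 = np.exp(-gamma * dt)
    c2 = (temperature * (1.0 - c1 * c1)) ** 0.5
    forces = np.zeros((n, 3))
    tx = ty = tz = 0.0

    ns = 0
    nf = 0
    status = -1
    for step in range(max_steps):
        disp = v_pull * dt * step
        for a in range(n):
            for d in range(3):
                vel[a, d] += 0.5 * dt * forces[a, d]
                pos[a, d] += 0.5 * dt * vel[a, d]
        if gamma > 0.0:
            g = np.random.standard_normal(n * 3)
            for a in range(n):
                for d in range(3):
                    vel[a, d] = c1 * vel[a, d] + c2 * g[3 * a + d]
        for a in range(n):
            for d in range(3):
                pos[a, d] += 0.5 * dt * vel[a, d]
        forces[:] = 0.0
        _add_forces(pos, b0, ci, cj, r0, ri, rj, sig, cnat, cnorm,
                    eps, bond_k, chir_k, forces)
        # anchors: fixed at the first terminus, moving at the last
        forces[0, 0] += spring_k * (anchor0[0] - pos[0, 0])
        forces[0, 1] += spring_k * (anchor0[1] - pos[0, 1])
        forces[0, 2] += spring_k * (anchor0[2] - pos[0, 2])
        tx = anchor1[0] + axis[0] * disp - pos[n - 1, 0]
        ty = anchor1[1] + axis[1] * disp - pos[n - 1, 1]
        tz = anchor1[2] + axis[2] * disp - pos[n - 1, 2]
        forces[n - 1, 0] += spring_k * tx
        forces[n - 1, 1] += spring_k * ty
        forces[n - 1, 2] += spring_k * tz
        for a in range(n):
            for d in range(3):
                vel[a, d] += 0.5 * dt * forces[a, d]
        if step % sample_every == 0:
            # spring force projected on the pulling axis
            fproj = spring_k * (tx * axis[0] + ty * axis[1] + tz * axis[2])
            samp_d[nf] = disp
            samp_f[nf] = fproj
            nf += 1
            if not np.isfinite(pos[0, 0]):
                status = step
                break
        if step % snap_every == 0:
            snaps[ns] = pos
            snap_d[ns] = disp
            ns += 1
            ex = pos[n - 1, 0] - pos[0, 0]
            ey = pos[n - 1, 1] - pos[0, 1]
            ez = pos[n - 1, 2] - pos[0, 2]
            if (ex * ex + ey * ey + ez * ez) ** 0.5 >= ext_stop:
                break
    return samp_d[:nf], samp_f[:nf], snaps[:ns], snap_d[:ns], status


# ---------------------------------------------------------------------------
# user-facing operations
# ---------------------------------------------------------------------------

def _model_args(model: GoModel, params: GoModelParams):
    return (model.bond_lengths, model.contact_i, model.contact_j,
            model.contact_r0, model.rep_i, model.rep_j, model.rep_sigma,
            model.native_chirality, model.chir_norm,
            params.epsilon, params.bond_k, params.chirality_k)


def potential_energy(model: GoModel, coords: np.ndarray,
                     params: GoModelParams | None = None) -> float:
    """Total potential energy (eps) of the model at given coordinates."""
    params = params or GoModelParams()
    forces = np.zeros_like(coords)
    return float(_add_forces(np.asarray(coords, float),
                             *_model_args(model, params), forces))


def forces_at(model: GoModel, coords: np.ndarray,
              params: GoModelParams | None = None) -> np.ndarray:
    """Conservative forces (eps/A) at given coordinates."""
    params = params or GoModelParams()
    forces = np.zeros_like(coords)
    _add_forces(np.asarray(coords, float), *_model_args(model, params), forces)
    return forces


@dataclass
class LangevinResult:
    """Recorded trajectory of a free-dynamics run (times in tau)."""

    frames: np.ndarray        # (n_frames, n, 3)
    times: np.ndarray         # tau
    kinetic: np.ndarray       # eps per frame (total kinetic energy)
    potential: np.ndarray     # eps per frame


def run_langevin(model: GoModel, params: GoModelParams, n_steps: int,
                 record_every: int = 100,
                 initial_coords: np.ndarray | None = None,
                 initial_velocities: np.ndarray | None = None) -> LangevinResult:
    """Langevin dynamics at params.temperature; deterministic per seed.

    With damping and temperature both zero this reduces to a symplectic
    integrator, which the energy-conservation tests rely on.
    """
    pos = np.array(initial_coords if initial_coords is not None
                   else model.native_coords, float)
    vel = (np.array(initial_velocities, float)
           if initial_velocities is not None else np.zeros_like(pos))
    frames, ekin, epot, bad_step = _run_langevin(
        pos, vel, *_model_args(model, params),
        params.temperature, params.damping, params.timestep,
        n_steps, record_every, params.seed % (2 ** 31),
    )
    if bad_step >= 0:
        raise FloatingPointError(
            f"Langevin integration diverged at step {bad_step}"
        )
    times = params.timestep * record_every * np.arange(1, len(frames) + 1)
    return LangevinResult(frames, times, ekin, epot)


def pull_constant_speed(model: GoModel, params: GoModelParams,
                        sample_every: int = 20,
                        snap_spacing_A: float = 0.5,
                        max_stretch: float = 1.1):
    """Stretch the model at constant speed; returns (ForceCurve, trajectory).

    The trajectory is the (n_snapshots, n, 3) coordinate array with its
    anchor displacements stored in ``trajectory.displacements`` via the
    returned PullTrajectory wrapper.
    """
    contour = model.contour_length
    ends = model.native_coords[-1] - model.native_coords[0]
    ee0 = float(np.linalg.norm(ends))
    axis = ends / ee0
    snap_every = max(1, int(snap_spacing_A / (params.v_pull * params.timestep)))
    # anchor-travel budget: missing extension plus compliance of the two
    # tether springs at the largest force of interest (~3 eps/A), plus slack
    d_max = (max_stretch * contour - ee0) + 2 * 3.0 / params.spring_k + 5.0
    ext_stop = 0.95 * contour
    pos = model.native_coords.copy()
    vel = np.zeros_like(pos)
    d, f, snaps, snap_d, status = _run_pull(
        pos, vel, *_model_args(model, params),
        params.temperature, params.damping, params.timestep,
        params.v_pull, params.spring_k, axis, d_max, ext_stop,
        sample_every, snap_every, params.seed % (2 ** 31),
    )
    if status >= 0:
        raise FloatingPointError(f"pulling run diverged at step {status}")
    curve = ForceCurve(displacement=d, force=f, contour_length=contour)
    curve = detect_force_peaks(curve, params.noise_level)
    traj = PullTrajectory(snaps, snap_d)
    return curve, traj


@dataclass
class PullTrajectory:
    """Decimated coordinate snapshots of one pulling run."""

    frames: np.ndarray          # (n_frames, n, 3)
    displacements: np.ndarray   # anchor displacement (A) per frame

    def __getitem__(self, k):
        return self.frames[k]

    def __len__(self):
        return len(self.frames)

    def to_ensemble(self, template: Conformer, stride: int = 1):
        """CA-only Ensemble of every ``stride``-th snapshot (for PDB export)."""
        from polyqlab.structure import Ensemble

        members = [
            template.with_ca_coords(f, id=f"d{d:.0f}A")
            for f, d in zip(self.frames[::stride],
                            self.displacements[::stride])
        ]
        return Ensemble(members)


def boxcar_average(d: np.ndarray, f: np.ndarray, width: float = 1.0):
    """Average a sampled curve into fixed-width displacement bins."""
    if len(d) == 0:
        raise ValueError("empty force curve")
    edges = np.arange(d.min(), d.max() + width, width)
    idx = np.digitize(d, edges) - 1
    centers, means = [], []
    for b in range(idx.max() + 1):
        m = idx == b
        if np.any(m):
            centers.append(edges[b] + width / 2)
            means.append(f[m].mean())
    return np.array(centers), np.array(means)


def detect_force_peaks(curve: ForceCurve | tuple, noise_level: float = 0.1,
                       smooth_width: float = 1.0) -> ForceCurve:
    """Locate articulated force peaks above the thermal noise level.

    The raw samples are boxcar-averaged over ``smooth_width`` angstrom of
    displacement; local maxima with height and prominence above
    ``noise_level`` count as peaks, excluding the terminal monotone rise
    where the backbone itself stretches.  F_max is the largest peak height
    (zero if no peak exists) and n_p the peak count.
    """
    if isinstance(curve, ForceCurve):
        d_raw, f_raw = curve.displacement, curve.force
        contour = curve.contour_length
    else:
        d_raw, f_raw = np.asarray(curve[0], float), np.asarray(curve[1], float)
        contour = float(d_raw[-1]) if len(d_raw) else 0.0
    if len(d_raw) == 0:
        raise ValueError("empty force curve")
    if np.any(np.diff(d_raw) < 0):
        raise ValueError("displacement samples must be increasing")
    d, f = boxcar_average(d_raw, f_raw, smooth_width)
    # strip the terminal monotone rise (tolerating small dips)
    end = len(f)
    while end > 1 and f[end - 2] <= f[end - 1] + 0.02:
        end -= 1
    body_f = f[:end] if end > 1 else f
    idx, props = find_peaks(body_f, height=noise_level,
                            prominence=noise_level)
    peaks = [(float(d[k]), float(f[k])) for k in idx]
    f_max = max((h for _, h in peaks), default=0.0)
    return ForceCurve(d, f, peaks, float(f_max), len(peaks), contour)


def unfolding_scenario(trajectory: PullTrajectory, cmap: ContactMap,
                       break_factor: float = 1.5) -> list[ScenarioEvent]:
    """Displacement of the last rupture of every native contact.

    A contact is ruptured when its CA-CA distance exceeds ``break_factor``
    times the native distance; the event records the displacement of the
    last upward crossing.  Contacts that never break are flagged unbroken.
    """
    frames = trajectory.frames
    disp = trajectory.displacements
    events = []
    for (i, j), r0 in zip(cmap.contacts, cmap.native_ca_distance):
        dist = np.linalg.norm(frames[:, j] - frames[:, i], axis=1)
        above = dist > break_factor * r0
        if not above.any():
            events.append(ScenarioEvent(i + 1, j + 1, j - i, None))
            continue
        crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
        last = crossings[-1] if len(crossings) else np.nonzero(above)[0][0]
        events.append(ScenarioEvent(i + 1, j + 1, j - i, float(disp[last])))
    return events
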
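"""Per-conformer structural descriptors.

Implements the descriptor set used to characterize conformer ensembles:
overlap-criterion contact maps built from enlarged van der Waals spheres,
radius of gyration, the gyration-tensor shape parameter w (positive for
elongated, negative for flattened, near zero for globular shapes),
secondary-structure content from a Kabsch-Sander hydrogen-bond assigner,
mean coordination number ⟨z⟩, relative contact order, and the finite-size
Maxwell rigidity threshold on ⟨z⟩.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from polyqlab.structure import Conformer

# Heavy-atom van der Waals radii (angstrom) in the Tsai-Taylor-Chothia
# style used by structure-based contact maps, keyed by bonding class.
DEFAULT_RADII = {
    "C_sp3": 1.88,      # tetrahedral carbon (CA, aliphatic side chain)
    "C_sp2": 1.76,      # trigonal/aromatic carbon
    "C_carbonyl": 1.61, # backbone carbonyl carbon
    "N": 1.64,
    "O": 1.42,
    "S": 1.77,
}
DEFAULT_ENLARGEMENT = 1.24


@dataclass
class RadiiTable:
    """Van der Waals radii per heavy-atom class plus the sphere enlargement."""

    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    enlargement_factor: float = DEFAULT_ENLARGEMENT

    def __post_init__(self) -> None:
        for name, r in self.radii.items():
            if not 1.0 <= r <= 2.5:
                raise ValueError(f"radius of {name} outside [1.0, 2.5]: {r}")
        if self.enlargement_factor < 1:
            raise ValueError("enlargement_factor must be >= 1")

    def radius_of(self, atom_name: str) -> float:
        first = atom_name[0]
        if first == "N":
            return self.radii["N"]
        if first == "O":
            return self.radii["O"]
        if first == "S":
            return self.radii["S"]
        if first == "C":
            if atom_name == "C":
                return self.radii["C_carbonyl"]
            return self.radii["C_sp3"]
        raise KeyError(f"no radius for atom {atom_name!r}")


@dataclass
class ContactMap:
    """Native residue-residue contacts with reference CA distances."""

    n_residues: int
    contacts: list[tuple[int, int]]          # i < j, 0-based
    native_ca_distance: np.ndarray           # angstrom, parallel to contacts
    min_separation: int = 3
    mode: str = "backbone"                   # backbone-only or heavy-atom input

    def __post_init__(self) -> None:
        self.native_ca_distance = np.asarray(self.native_ca_distance, float)
        for (i, j) in self.contacts:
            if not (0 <= i < j < self.n_residues):
                raise ValueError(f"bad contact ({i}, {j})")
            if j - i < self.min_separation:
                raise ValueError(f"contact ({i}, {j}) below min separation")
        if np.any(~np.isfinite(self.native_ca_distance)) or np.any(
                self.native_ca_distance <= 0):
            raise ValueError("native distances must be positive and finite")

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def sequence_separations(self) -> np.ndarray:
        return np.array([j - i for i, j in self.contacts], dtype=int)

    def to_text(self, path) -> None:
        """Write as 3-column text (i, j, native_distance), 1-based."""
        with open(path, "w") as fh:
            for (i, j), d in zip(self.contacts, self.native_ca_distance):
                fh.write(f"{i + 1} {j + 1} {d:.4f}\n")


def build_contact_map(conformer: Conformer, radii: RadiiTable | None = None,
                      min_separation: int = 3) -> ContactMap:
    """Overlap-criterion contact map.

    Residues i and j (j - i >= ``min_separation``) are in contact iff at
    least one pair of heavy atoms, one from each residue, has centre
    distance below the sum of their enlarged van der Waals radii.
    """
    radii = radii or RadiiTable()
    res_idx, xyz, names = conformer.heavy_atoms()
    r = np.array([radii.radius_of(n) for n in names]) * radii.enlargement_factor
    d = cdist(xyz, xyz)
    cutoff = r[:, None] + r[None, :]
    sep = np.abs(res_idx[:, None] - res_idx[None, :])
    overlap = (d < cutoff) & (sep >= min_separation)
    pairs = set()
    ii, jj = np.nonzero(overlap)
    for a, b in zip(ii, jj):
        ri, rj = int(res_idx[a]), int(res_idx[b])
        if ri < rj:
            pairs.add((ri, rj))
    contacts = sorted(pairs)
    ca = conformer.ca_coords()
    native = np.array([np.linalg.norm(ca[i] - ca[j]) for i, j in contacts])
    mode = "backbone" if all(
        set(res.atoms) <= {"N", "CA", "C", "O"} for res in conformer.residues
    ) else "heavy"
    return ContactMap(len(conformer), contacts, native, min_separation, mode)


def radius_of_gyration(conformer_or_coords) -> float:
    """Root-mean-square CA distance from the CA centroid (angstrom)."""
    coords = (conformer_or_coords.ca_coords()
              if isinstance(conformer_or_coords, Conformer)
              else np.asarray(conformer_or_coords, float))
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c ** 2).sum(axis=1).mean()))


def gyration_eigenvalues(coords: np.ndarray) -> np.ndarray:
    """Eigenvalues of the gyration tensor, descending."""
    c = coords - coords.mean(axis=0)
    tensor = c.T @ c / len(c)
    vals = np.linalg.eigvalsh(tensor)[::-1]
    return vals


def shape_parameter_w(conformer_or_coords) -> float:
    """Normalized prolateness of the gyration tensor.

    With eigenvalues l1 >= l2 >= l3 and mean lb,
    ``w = prod(li - lb) / lb**3``: ~0 for globules, positive (up to 2 for a
    thin rod) for elongated shapes, negative (down to -0.25 for a thin
    disk) for flattened ones.
    """
    coords = (conformer_or_coords.ca_coords()
              if isinstance(conformer_or_coords, Conformer)
              else np.asarray(conformer_or_coords, float))
    vals = gyration_eigenvalues(coords)
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("degenerate gyration tensor (all points coincident)")
    return float(np.prod(vals - mean) / mean ** 3)


def mean_coordination(cmap: ContactMap) -> float:
    """Mean coordination number ⟨z⟩: peptide-bond neighbours plus contacts."""
    n = cmap.n_residues
    z = np.full(n, 2.0)
    z[0] = z[-1] = 1.0
    for i, j in cmap.contacts:
        z[i] += 1
        z[j] += 1
    return float(z.mean())


def contact_order(cmap: ContactMap) -> float:
    """Relative contact order: mean sequence separation of contacts over L."""
    if cmap.n_contacts == 0:
        raise ValueError("contact order undefined for a map with no contacts")
    return float(cmap.sequence_separations.sum()
                 / (cmap.n_residues * cmap.n_contacts))


def stiff_limit(n_residues: int) -> float:
    """Finite-size Maxwell rigidity threshold on ⟨z⟩.

    Constraint counting N z / 2 >= 3 N - 6 gives z >= 6 - 12/N, which tends
    to the classic bulk value 6 for large N.
    """
    if n_residues < 3:
        raise ValueError("threshold needs at least 3 residues")
    return 6.0 - 12.0 / n_residues


# ---------------------------------------------------------------------------
# Kabsch-Sander secondary structure (DSSP-lite)
# ---------------------------------------------------------------------------

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_KS_PREFACTOR = 0.084 * 332.0


@dataclass
class SecondaryStructure:
    """Per-residue codes plus rounded content percentages."""

    codes: str            # one of H, E, B, T, '-' per residue
    ss_alpha: float       # % residues in alpha-helix (H)
    ss_beta: float        # % in strands/bridges (E + B)
    ss_turn: float        # % in hydrogen-bonded turns (T)

    @property
    def ss_total(self) -> float:
        return round(self.ss_alpha + self.ss_beta + self.ss_turn, 1)


def _amide_hydrogens(N: np.ndarray, C: np.ndarray, O: np.ndarray) -> np.ndarray:
    """Place amide H 1.0 A from N, anti to the preceding carbonyl."""
    n = len(N)
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        d = C[i - 1] - O[i - 1]
        d /= np.linalg.norm(d)
        H[i] = N[i] + d
    return H


def _hbond_matrix(N, C, O, H) -> np.ndarray:
    """hb[d, a] true iff NH of residue d donates to C=O of residue a."""
    n = len(N)
    d_on = cdist(N, O)
    d_cn = cdist(N, C)
    with np.errstate(invalid="ignore"):
        d_oh = cdist(H, O)
        d_ch = cdist(H, C)
        energy = _KS_PREFACTOR * (1.0 / d_on + 1.0 / d_ch
                                  - 1.0 / d_oh - 1.0 / d_cn)
    hb = energy < HBOND_ENERGY_CUTOFF
    hb &= ~np.isnan(energy)
    idx = np.arange(n)
    near = np.abs(idx[:, None] - idx[None, :]) < 2
    hb[near] = False
    return hb


def assign_secondary_structure(conformer: Conformer) -> SecondaryStructure:
    """Kabsch-Sander style assignment from backbone N/CA/C/O atoms.

    Hydrogen bonds use the classic electrostatic criterion
    ``E = 0.084 * 332 * (1/d_ON + 1/d_CH - 1/d_OH - 1/d_CN) < -0.5``
    kcal/mol with the amide H placed by the package.  Codes: H (alpha helix
    from two consecutive 4-turns), E/B (extended/isolated bridge), T
    (3-, 4- or 5-turn).  Only H counts toward the alpha percentage.
    """
    for i, res in enumerate(conformer.residues):
        missing = [a for a in ("N", "CA", "C", "O") if a not in res.atoms]
        if missing:
            raise ValueError(
                f"residue {i + 1} lacks backbone atoms {missing} "
                "(run backbone_from_ca first)"
            )
    N = conformer.atom_coords("N")
    C = conformer.atom_coords("C")
    O = conformer.atom_coords("O")
    H = _amide_hydrogens(N, C, O)
    hb = _hbond_matrix(N, C, O, H)
    n = len(N)

    def HB(donor: int, acceptor: int) -> bool:
        if not (0 <= donor < n and 0 <= acceptor < n):
            return False
        return bool(hb[donor, acceptor])

    turn = {3: np.zeros(n, bool), 4: np.zeros(n, bool), 5: np.zeros(n, bool)}
    for k in (3, 4, 5):
        for i in range(n - k):
            if HB(i + k, i):
                turn[k][i] = True

    helix = np.zeros(n, bool)
    for i in range(1, n - 4):
        if turn[4][i - 1] and turn[4][i]:
            helix[i:i + 4] = True

    bridges: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 3, n):
            anti = (HB(j, i) and HB(i, j)) or (
                HB(j + 1, i - 1) and HB(i + 1, j - 1))
            para = (HB(j, i - 1) and HB(i + 1, j)) or (
                HB(i, j - 1) and HB(j + 1, i))
            if anti or para:
                bridges.append((i, j))
    bridge_res = set()
    ladder_res = set()
    bset = set(bridges)
    for (i, j) in bridges:
        bridge_res.update((i, j))
        for (di, dj) in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            if (i + di, j + dj) in bset or (j + dj, i + di) in bset:
                ladder_res.update((i, j))

    codes = ["-"] * n
    for i in range(n):
        if helix[i]:
            codes[i] = "H"
    for i in sorted(bridge_res):
        if codes[i] == "-":
            codes[i] = "E" if i in ladder_res else "B"
    for k in (3, 4, 5):
        for i in range(n):
            if turn[k][i]:
                for m in range(i + 1, min(i + k, n)):
                    if codes[m] == "-":
                        codes[m] = "T"

    counts = {c: codes.count(c) for c in "HEBT"}
    alpha = round(100.0 * counts["H"] / n, 1)
    beta = round(100.0 * (counts["E"] + counts["B"]) / n, 1)
    turn_pct = round(100.0 * counts["T"] / n, 1)
    return SecondaryStructure("".join(codes), alpha, beta, turn_pct)


# ---------------------------------------------------------------------------
# descriptor bundle
# ---------------------------------------------------------------------------

@dataclass
class DescriptorSet:
    """All per-conformer descriptors in one record."""

    n_residues: int
    R_g: float
    w: float
    ss_alpha: float
    ss_beta: float
    ss_turn: float
    ss_total: float
    z_mean: float
    CO: float | None
    n_contacts: int
    contact_mode: str

    @property
    def volatile(self) -> bool:
        return is_volatile(self)


def is_volatile(descriptors: DescriptorSet) -> bool:
    """True iff ⟨z⟩ is strictly below the finite-size Maxwell threshold."""
    return descriptors.z_mean < stiff_limit(descriptors.n_residues)


def compute_descriptors(conformer: Conformer,
                        cmap: ContactMap | None = None,
                        radii: RadiiTable | None = None,
                        min_separation: int = 3) -> DescriptorSet:
    """Compute the full descriptor set for one conformer.

    CA-only traces get an ideal-geometry backbone rebuilt before the
    secondary-structure assignment; the contact map is then computed in
    backbone-only mode (recorded in ``contact_mode``).
    """
    from polyqlab.synthetic import backbone_from_ca

    has_backbone = all(
        all(a in res.atoms for a in ("N", "CA", "C", "O"))
        for res in conformer.residues
    )
    full = conformer if has_backbone else backbone_from_ca(conformer)
    if cmap is None:
        cmap = build_contact_map(full, radii, min_separation)
    ss = assign_secondary_structure(full)
    co = contact_order(cmap) if cmap.n_contacts else None
    return DescriptorSet(
        n_residues=len(conformer),
        R_g=radius_of_gyration(conformer),
        w=shape_parameter_w(conformer),
        ss_alpha=ss.ss_alpha,
        ss_beta=ss.ss_beta,
        ss_turn=ss.ss_turn,
        ss_total=ss.ss_total,
        z_mean=mean_coordination(cmap),
        CO=co,
        n_contacts=cmap.n_contacts,
        contact_mode=cmap.mode,
    )
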
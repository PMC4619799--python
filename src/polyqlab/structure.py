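"""Conformer/ensemble data model, PDB and XYZ I/O, and optimal-superposition RMSD.

Coordinates are stored and reported in angstroms.  Residue indices are
0-based in memory and 1-based in every file written (PDB convention).
Only the first chain of a PDB file is read; alternate locations take
conformer ``A``; hydrogens are ignored on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.sequence import ProteinSequence
from biotite.structure.io.pdb import PDBFile


class PDBParseError(ValueError):
    """Raised when a structure file violates the chain contract."""


# heavy backbone atoms every conformer built by this package carries
BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Residue:
    """One residue: name plus named heavy atoms with coordinates in angstrom."""

    name: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atoms = {k: np.asarray(v, dtype=float) for k, v in self.atoms.items()}

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]


@dataclass
class Conformer:
    """A single-chain conformer.

    Parameters
    ----------
    id : str
        Free-text label.
    sequence : str
        One-letter residue codes, one per residue.
    residues : list of Residue
        Ordered residues; every residue must carry a CA atom.
    timestamp : float, optional
        Frame time in ps for trajectory frames.
    """

    id: str
    sequence: str
    residues: list[Residue]
    timestamp: float | None = None

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError("a conformer needs at least 2 residues")
        if len(self.sequence) != len(self.residues):
            raise ValueError(
                f"sequence length {len(self.sequence)} != residue count "
                f"{len(self.residues)}"
            )
        for i, res in enumerate(self.residues):
            if "CA" not in res.atoms:
                raise PDBParseError(f"residue {i + 1} lacks a CA atom")
            if not np.all(np.isfinite(res.atoms["CA"])):
                raise ValueError(f"residue {i + 1} has non-finite CA coordinates")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """CA coordinates as an (N, 3) array."""
        return np.array([r.atoms["CA"] for r in self.residues])

    def atom_coords(self, atom_set: str = "CA") -> np.ndarray:
        """Coordinates of the named atom for every residue, shape (N, 3)."""
        try:
            return np.array([r.atoms[atom_set] for r in self.residues])
        except KeyError:
            raise ValueError(f"atom {atom_set!r} missing from some residue")

    def heavy_atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """All heavy atoms as (residue_index array, (M, 3) coordinate array)."""
        idx, xyz, names = [], [], []
        for i, res in enumerate(self.residues):
            for name, coord in res.atoms.items():
                idx.append(i)
                xyz.append(coord)
                names.append(name)
        return np.asarray(idx), np.asarray(xyz), names

    def with_ca_coords(self, coords: np.ndarray, id: str | None = None,
                       timestamp: float | None = None) -> "Conformer":
        """Copy of this conformer keeping only CA atoms at new coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self), 3):
            raise ValueError("coordinate shape mismatch")
        residues = [
            Residue(r.name, {"CA": coords[i]}) for i, r in enumerate(self.residues)
        ]
        return Conformer(id or self.id, self.sequence, residues, timestamp)


@dataclass
class Ensemble:
    """An ordered collection of conformers, optionally a time series (ps)."""

    conformers: list[Conformer]
    is_time_ordered: bool = False
    time_unit: str = "ps"

    def __post_init__(self) -> None:
        if self.is_time_ordered:
            times = [c.timestamp for c in self.conformers]
            if any(t is None for t in times):
                raise ValueError("time-ordered ensemble needs timestamps")
            if not all(b > a for a, b in zip(times, times[1:])):
                raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def __getitem__(self, i):
        return self.conformers[i]


def _three_to_one(name: str) -> str:
    try:
        return ProteinSequence.convert_letter_3to1(name.capitalize())
    except Exception:
        return "X"


def _one_to_three(letter: str) -> str:
    try:
        return ProteinSequence.convert_letter_1to3(letter).upper()
    except Exception:
        return "UNK"


def read_pdb(path) -> Ensemble:
    """Read a (multi-model) PDB file into an Ensemble.

    One Conformer per MODEL record (one if the file has no MODEL records).
    Only the first chain is kept; altloc 'A' wins; hydrogens are dropped.
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise PDBParseError(f"{path}: no ATOM records")
    try:
        stack = pdb.get_structure(altloc="first")
        if isinstance(stack, struc.AtomArray):  # pragma: no cover
            stack = struc.stack([stack])
        arrays = [stack[m] for m in range(stack.stack_depth())]
    except Exception:
        # models with unequal atom counts: read them one by one
        arrays = [pdb.get_structure(model=m + 1, altloc="first")
                  for m in range(n_models)]
    conformers = []
    for m, arr in enumerate(arrays):
        arr = arr[arr.chain_id == arr.chain_id[0]]
        arr = arr[arr.element != "H"]
        arr = arr[~np.isin(arr.atom_name, ["OXT"])]
        residues = []
        seq = []
        for res_id in np.unique(arr.res_id):
            sub = arr[arr.res_id == res_id]
            atoms = {
                name: sub.coord[k] for k, name in enumerate(sub.atom_name)
            }
            if "CA" not in atoms:
                raise PDBParseError(
                    f"{path}: residue {int(res_id)} lacks a CA atom"
                )
            residues.append(Residue(str(sub.res_name[0]), atoms))
            seq.append(_three_to_one(str(sub.res_name[0])))
        if not residues:
            raise PDBParseError(f"{path}: model {m + 1} has no residues")
        conformers.append(
            Conformer(id=f"model_{m + 1}", sequence="".join(seq), residues=residues)
        )
    return Ensemble(conformers)


def _to_atom_array(conformer: Conformer) -> struc.AtomArray:
    n_atoms = sum(len(r.atoms) for r in conformer.residues)
    arr = struc.AtomArray(n_atoms)
    k = 0
    for i, res in enumerate(conformer.residues):
        res_name = (
            res.name if len(res.name) == 3 else _one_to_three(conformer.sequence[i])
        )
        # write backbone atoms first, in conventional order
        names = [a for a in BACKBONE_ATOMS if a in res.atoms]
        names += [a for a in res.atoms if a not in BACKBONE_ATOMS]
        for name in names:
            arr.coord[k] = res.atoms[name]
            arr.atom_name[k] = name
            arr.res_name[k] = res_name
            arr.res_id[k] = i + 1
            arr.chain_id[k] = "A"
            arr.element[k] = name[0]
            arr.hetero[k] = False
            k += 1
    return arr


def write_pdb(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a multi-model PDB file (1-based residue ids)."""
    if len(ensemble) == 0:
        raise ValueError("cannot write an empty ensemble")
    arrays = [_to_atom_array(c) for c in ensemble]
    pdb = PDBFile()
    if len({a.array_length() for a in arrays}) == 1:
        pdb.set_structure(struc.stack(arrays))
    else:  # heterogeneous models: emit MODEL blocks one by one
        lines = []
        for m, arr in enumerate(arrays, start=1):
            single = PDBFile()
            single.set_structure(arr)
            lines.append(f"MODEL     {m:>4}")
            lines.extend(l for l in single.lines if l.startswith(("ATOM", "HETATM")))
            lines.append("ENDMDL")
        pdb.lines = lines
    pdb.write(str(path))


def read_xyz(path) -> Ensemble:
    """Read an XYZ trace file (CA-only frames) into an Ensemble.

    Format per frame: atom count line, comment line, then
    ``element x y z`` lines; frames concatenated.
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    conformers = []
    i = 0
    frame = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if not line:
            i += 1
            continue
        n = int(line)
        coords = []
        for j in range(n):
            parts = tokens[i + 2 + j].split()
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frame += 1
        residues = [Residue("GLN", {"CA": c}) for c in coords]
        conformers.append(Conformer(f"frame_{frame}", "Q" * n, residues))
        i += 2 + n
    if not conformers:
        raise PDBParseError(f"{path}: empty XYZ file")
    return Ensemble(conformers)


def write_xyz(ensemble: Ensemble, path) -> None:
    """Write CA traces of an ensemble in XYZ format."""
    if len(ensemble) == 0:
        raise ValueError("cannot write an empty ensemble")
    with open(path, "w") as fh:
        for c in ensemble:
            fh.write(f"{len(c)}\n{c.id}\n")
            for xyz in c.ca_coords():
                fh.write(f"CA {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centered ``p`` onto centered ``q``.

    Reflections are disallowed: the determinant is forced positive.
    """
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def superpose_rmsd(a: Conformer, b: Conformer, atom_set: str = "CA") -> float:
    """Minimal RMSD between two equal-length conformers over rigid motions.

    Uses the closed-form (SVD) optimal rotation after centroid removal;
    symmetric in its arguments.
    """
    if len(a) != len(b):
        raise ValueError(f"chain length mismatch: {len(a)} vs {len(b)}")
    p = a.atom_coords(atom_set)
    q = b.atom_coords(atom_set)
    return superpose_rmsd_coords(p, q)


def superpose_rmsd_coords(p: np.ndarray, q: np.ndarray) -> float:
    """Kabsch RMSD between two (N, 3) coordinate arrays."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError("coordinate shape mismatch")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    rot = kabsch_rotation(pc, qc)
    diff = pc @ rot.T - qc
    return float(np.sqrt((diff ** 2).sum() / len(p)))
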
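"""Solvent accessibility of exit vectors in docked poses.

A DEL compound is attached to its DNA tag through an exit vector — an
ordered pair of ligand atoms whose direction (terminal minus base, unit
normalized) points where the linker and tag must leave the molecule.
Docking engines ignore the tag, so a pose may bury the exit vector
inside the pocket and be physically unavailable for the tagged compound.

The accessibility score B is a repulsive potential between the exit
vector and the protein:

    B = sum_j  A * max(cos theta_j, 0) / r_j**n

over protein atoms j within a cutoff of the terminal ligand atom, where
r_j is the distance from the terminal atom to protein atom j and
theta_j is the angle between the exit-vector direction and the line
from the terminal atom to atom j.  A (default 1e9) and n (default 6)
control the steepness.  Atoms behind the exit vector (cos theta <= 0)
contribute nothing: the tag does not traverse that half-space.  B = 0
means the exit vector is fully accessible and the pose is feasible for
the DNA-tagged compound; higher B means more burial.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.PDB import PDBParser, PDBIO, StructureBuilder

__all__ = [
    "ProteinAtoms",
    "ExitVector",
    "PoseGeometry",
    "AccessibilityResult",
    "accessibility_score",
    "best_exit_vector",
    "feasible_ratio",
    "read_pdb_atoms",
    "write_pdb_atoms",
    "read_exit_vectors_csv",
    "write_exit_vectors_csv",
]

#: B values below this are treated as exactly zero for the feasibility flag.
FEASIBLE_EPS = 1e-9


@dataclass
class ProteinAtoms:
    """Protein coordinates (Å) with element symbols."""

    coords: np.ndarray
    elements: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or not len(self.coords):
            raise ValueError("coords must be a non-empty (N, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if not self.elements:
            self.elements = ["C"] * len(self.coords)

    def heavy_only(self) -> "ProteinAtoms":
        keep = [i for i, e in enumerate(self.elements) if e.upper() != "H"]
        return ProteinAtoms(self.coords[keep], [self.elements[i] for i in keep])


@dataclass(frozen=True)
class ExitVector:
    """Ordered ligand atom pair: base (attachment) and terminal (outward)."""

    base_atom: int
    terminal_atom: int

    def __post_init__(self) -> None:
        if self.base_atom == self.terminal_atom:
            raise ValueError("base and terminal atoms must differ")


@dataclass
class PoseGeometry:
    """One docked ligand pose: coordinates plus candidate exit vectors."""

    coords: np.ndarray
    exit_vectors: list[ExitVector]
    pose_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("ligand coords must be (N, 3)")
        n = len(self.coords)
        for ev in self.exit_vectors:
            if not (0 <= ev.base_atom < n and 0 <= ev.terminal_atom < n):
                raise ValueError(
                    f"exit vector atoms {ev} outside ligand range 0..{n - 1}"
                )


@dataclass(frozen=True)
class AccessibilityResult:
    pose_id: str
    b_score: float
    feasible: bool
    exit_vector_index: int


def accessibility_score(
    pose: PoseGeometry,
    protein: ProteinAtoms,
    ev: ExitVector,
    A: float = 1e9,
    n: float = 6.0,
    cutoff: float = 10.0,
) -> float:
    """Repulsive accessibility potential B of one exit vector (see module doc).

    Only protein atoms within ``cutoff`` Å of the terminal atom are
    summed; with the n = 6 decay, remoter atoms are negligible.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    base = pose.coords[ev.base_atom]
    terminal = pose.coords[ev.terminal_atom]
    direction = terminal - base
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("degenerate exit vector: base and terminal coincide")
    direction = direction / norm

    rel = protein.coords - terminal
    r = np.linalg.norm(rel, axis=1)
    if np.any(r == 0):
        raise ValueError("protein atom coincident with the terminal ligand atom")
    within = r <= cutoff
    if not np.any(within):
        return 0.0
    r = r[within]
    cos_theta = (rel[within] @ direction) / r
    weight = np.maximum(cos_theta, 0.0)
    return float(np.sum(A * weight / r**n))


def best_exit_vector(
    pose: PoseGeometry,
    protein: ProteinAtoms,
    A: float = 1e9,
    n: float = 6.0,
    cutoff: float = 10.0,
) -> AccessibilityResult:
    """Score every candidate exit vector and keep the most accessible one.

    Ties go to the lowest exit-vector index.
    """
    if not pose.exit_vectors:
        raise ValueError(f"pose {pose.pose_id!r} has no exit vectors")
    scores = [
        accessibility_score(pose, protein, ev, A=A, n=n, cutoff=cutoff)
        for ev in pose.exit_vectors
    ]
    best = int(np.argmin(scores))  # argmin takes the first minimum
    b = scores[best]
    return AccessibilityResult(
        pose_id=pose.pose_id,
        b_score=b,
        feasible=b < FEASIBLE_EPS,
        exit_vector_index=best,
    )


def feasible_ratio(results: Sequence[AccessibilityResult]) -> float:
    """Percentage of poses with B = 0 (feasible for the tagged compound)."""
    if not results:
        raise ValueError("no accessibility results")
    return 100.0 * sum(r.feasible for r in results) / len(results)


# ---------------------------------------------------------------------------
# File interfaces

def read_pdb_atoms(path, heavy_only: bool = False) -> ProteinAtoms:
    """All atom coordinates of a PDB file, in file order."""
    structure = PDBParser(QUIET=True).get_structure("protein", path)
    coords, elements = [], []
    for atom in structure.get_atoms():
        coords.append(atom.coord)
        elements.append(atom.element or "C")
    atoms = ProteinAtoms(np.asarray(coords, dtype=float), elements)
    return atoms.heavy_only() if heavy_only else atoms


def write_pdb_atoms(atoms: ProteinAtoms, path) -> None:
    """Write pseudo-atoms as a single-chain PDB (one residue per atom)."""
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("synthetic")
    builder.init_model(0)
    builder.init_chain("A")
    builder.init_seg("    ")
    for i, (xyz, element) in enumerate(zip(atoms.coords, atoms.elements)):
        builder.init_residue("DUM", " ", i + 1, " ")
        name = element.upper()
        builder.init_atom(
            name,
            np.asarray(xyz, dtype=float),
            0.0,
            1.0,
            " ",
            name.rjust(3) + " ",
            element=element.upper(),
        )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def read_poses_sdf(path, exit_vectors: dict[str, list[ExitVector]] | None = None) -> list[PoseGeometry]:
    """Load ligand poses from an SDF file (one record per pose).

    Exit vectors come either from the ``EXIT_VECTORS`` SDF property
    (semicolon-separated ``base,terminal`` pairs, 1-based atom-block
    order) or from a sidecar mapping keyed by pose id (the molecule
    title, or ``pose_<k>`` when untitled).  The sidecar wins when both
    are present.
    """
    from rdkit import Chem

    poses: list[PoseGeometry] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for k, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unreadable SDF record #{k} in {path}")
        pose_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"pose_{k}"
        coords = mol.GetConformer().GetPositions()
        evs: list[ExitVector] = []
        if exit_vectors is not None and pose_id in exit_vectors:
            evs = exit_vectors[pose_id]
        elif mol.HasProp("EXIT_VECTORS"):
            for pair in mol.GetProp("EXIT_VECTORS").split(";"):
                base_s, term_s = pair.split(",")
                evs.append(ExitVector(int(base_s) - 1, int(term_s) - 1))
        if not evs:
            raise ValueError(f"pose {pose_id!r}: no exit vectors given")
        poses.append(PoseGeometry(coords=coords, exit_vectors=evs, pose_id=pose_id))
    return poses


def write_poses_sdf(poses: Sequence[PoseGeometry], path) -> None:
    """Write poses as carbon-skeleton SDF records with EXIT_VECTORS tags."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    try:
        for pose in poses:
            rw = Chem.RWMol()
            for _ in range(len(pose.coords)):
                rw.AddAtom(Chem.Atom(6))
            for i in range(len(pose.coords) - 1):
                rw.AddBond(i, i + 1, Chem.BondType.SINGLE)
            mol = rw.GetMol()
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, (x, y, z) in enumerate(pose.coords):
                conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
            mol.AddConformer(conf)
            Chem.SanitizeMol(mol)
            mol.SetProp("_Name", pose.pose_id)
            mol.SetProp(
                "EXIT_VECTORS",
                ";".join(
                    f"{ev.base_atom + 1},{ev.terminal_atom + 1}"
                    for ev in pose.exit_vectors
                ),
            )
            writer.write(mol)
    finally:
        writer.close()


def read_exit_vectors_csv(path) -> dict[str, list[ExitVector]]:
    """Sidecar table: pose_id, base_atom, terminal_atom (1-based atom order)."""
    out: dict[str, list[ExitVector]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["pose_id"], []).append(
                ExitVector(
                    base_atom=int(row["base_atom"]) - 1,
                    terminal_atom=int(row["terminal_atom"]) - 1,
                )
            )
    return out


def write_exit_vectors_csv(evs: dict[str, list[ExitVector]], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pose_id", "base_atom", "terminal_atom"])
        for pose_id, vectors in evs.items():
            for ev in vectors:
                w.writerow([pose_id, ev.base_atom + 1, ev.terminal_atom + 1])
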
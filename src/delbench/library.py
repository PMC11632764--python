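"""Combinatorial DEL chemical spaces: definition, enumeration, identifiers.

A DNA-encoded library (DEL) is a combinatorial space built from
position-wise lists of building blocks.  Each building block is a SMILES
fragment carrying one or more single-atom attachment markers (``[*:n]``
wildcards with an atom-map number).  Assembly pairs equal map numbers
across the chosen fragments and fuses each pair into a single bond, which
covers both linear chains (``C[*:1]`` + ``[*:1]N[*:2]`` + ``[*:2]O``) and
scaffold topologies (one central block carrying all markers).

Compound identifiers are zero-padded per-position indices joined by
hyphens (``003-087-112``): human-readable, sortable, and a bijection of
the index tuple.
"""

from __future__ import annotations

import csv
import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "BuildingBlock",
    "LibraryDefinition",
    "CompoundRecord",
    "LibraryError",
    "AssemblyError",
    "library_size",
    "enumerate_library",
    "assemble_smiles",
    "find_duplicate_compounds",
    "unique_compound_count",
    "match_hits_by_composition",
    "compound_id_from_indices",
    "indices_from_compound_id",
    "read_blocks_csv",
    "write_blocks_csv",
    "write_compounds_csv",
    "read_compounds_csv",
]


class LibraryError(ValueError):
    """An ill-formed library definition or out-of-range index."""


class AssemblyError(ValueError):
    """A fragment set that cannot be assembled into one molecule."""


@dataclass(frozen=True)
class BuildingBlock:
    """One fragment occupying one combinatorial position.

    Parameters
    ----------
    position : int
        0-based position index within the library.
    index : int
        0-based index within the position.
    fragment : str
        SMILES with attachment markers written as ``[*:n]`` wildcards.
    label : str
        Free-text annotation (e.g. vendor name).
    """

    position: int
    index: int
    fragment: str
    label: str = ""

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.fragment)
        if m is None:
            raise AssemblyError(
                f"building block position={self.position} index={self.index}: "
                f"fragment {self.fragment!r} does not parse"
            )
        return m

    def attachment_map_numbers(self) -> list[int]:
        """Map numbers of the wildcard attachment atoms, sorted."""
        return sorted(
            a.GetAtomMapNum()
            for a in self.mol().GetAtoms()
            if a.GetAtomicNum() == 0 and a.GetAtomMapNum() > 0
        )


@dataclass
class LibraryDefinition:
    """Position-wise building-block lists defining a combinatorial DEL.

    ``assembly_rule`` is declarative; the default ``"by_map_number"`` pairs
    equal attachment map numbers across the per-position fragments.
    """

    blocks: list[list[BuildingBlock]]
    assembly_rule: str = "by_map_number"
    name: str = ""
    _id_widths: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.blocks or any(len(p) == 0 for p in self.blocks):
            raise LibraryError("every position must have at least one building block")
        for pos, plist in enumerate(self.blocks):
            for i, bb in enumerate(plist):
                if bb.position != pos or bb.index != i:
                    raise LibraryError(
                        f"block at position {pos} slot {i} carries inconsistent "
                        f"indices (position={bb.position}, index={bb.index})"
                    )
        self._id_widths = [max(3, len(str(c - 1))) for c in self.positions]

    @property
    def positions(self) -> list[int]:
        """Per-position cardinalities."""
        return [len(p) for p in self.blocks]

    @classmethod
    def from_cardinalities(cls, cards: Sequence[int], name: str = "") -> "LibraryDefinition":
        """Index-only definition (count-only mode); fragments are empty."""
        if not cards or any(c < 1 for c in cards):
            raise LibraryError(f"cardinalities must all be >= 1, got {list(cards)}")
        blocks = [
            [BuildingBlock(p, i, "") for i in range(c)] for p, c in enumerate(cards)
        ]
        return cls(blocks=blocks, name=name)


@dataclass(frozen=True)
class CompoundRecord:
    """One enumerated library member."""

    compound_id: str
    bb_indices: tuple[int, ...]
    smiles: str | None = None


def library_size(defn: LibraryDefinition) -> int:
    """Number of compounds, as the product of position cardinalities.

    Pure arithmetic; never enumerates.
    """
    size = 1
    for c in defn.positions:
        size *= c
    return size


def compound_id_from_indices(defn: LibraryDefinition, indices: Sequence[int]) -> str:
    if len(indices) != len(defn.positions):
        raise LibraryError(
            f"expected {len(defn.positions)} indices, got {len(indices)}"
        )
    for pos, (i, c) in enumerate(zip(indices, defn.positions)):
        if not 0 <= i < c:
            raise LibraryError(
                f"index {i} out of range at position {pos} (cardinality {c})"
            )
    return "-".join(
        str(i).zfill(w) for i, w in zip(indices, defn._id_widths)
    )


def indices_from_compound_id(defn: LibraryDefinition, compound_id: str) -> tuple[int, ...]:
    parts = compound_id.split("-")
    if len(parts) != len(defn.positions):
        raise LibraryError(
            f"compound id {compound_id!r} has {len(parts)} fields, "
            f"library has {len(defn.positions)} positions"
        )
    return tuple(int(p) for p in parts)


def _combined_fragments(mols: Sequence[Chem.Mol]) -> Chem.RWMol:
    combo = mols[0]
    for m in mols[1:]:
        combo = Chem.CombineMols(combo, m)
    return Chem.RWMol(combo)


def assemble_smiles(fragments: Sequence[str]) -> str:
    """Fuse attachment markers pairwise into single bonds; canonical SMILES.

    Each atom-map number must appear on exactly two wildcard atoms across
    the fragment set; the wildcards are removed and their neighbours bonded.
    """
    mols = []
    for frag in fragments:
        m = Chem.MolFromSmiles(frag)
        if m is None:
            raise AssemblyError(f"fragment {frag!r} does not parse")
        mols.append(m)
    rw = _combined_fragments(mols)

    by_map: dict[int, list[int]] = {}
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() > 0:
            by_map.setdefault(atom.GetAtomMapNum(), []).append(atom.GetIdx())
    if not by_map:
        raise AssemblyError(f"no attachment markers found in {list(fragments)!r}")
    bad = {m: len(idx) for m, idx in by_map.items() if len(idx) != 2}
    if bad:
        raise AssemblyError(
            f"attachment map numbers must occur exactly twice across fragments; "
            f"violations (map -> count): {bad} in {list(fragments)!r}"
        )

    to_remove: list[int] = []
    for map_num, (a_idx, b_idx) in sorted(by_map.items()):
        a, b = rw.GetAtomWithIdx(a_idx), rw.GetAtomWithIdx(b_idx)
        a_nbrs, b_nbrs = list(a.GetNeighbors()), list(b.GetNeighbors())
        if len(a_nbrs) != 1 or len(b_nbrs) != 1:
            raise AssemblyError(
                f"attachment marker [*:{map_num}] must have exactly one neighbour"
            )
        rw.AddBond(a_nbrs[0].GetIdx(), b_nbrs[0].GetIdx(), Chem.BondType.SINGLE)
        to_remove.extend([a_idx, b_idx])
    for idx in sorted(to_remove, reverse=True):
        rw.RemoveAtom(idx)

    product = rw.GetMol()
    Chem.SanitizeMol(product)
    return Chem.MolToSmiles(product)


def enumerate_library(
    defn: LibraryDefinition, with_smiles: bool = True
) -> Iterator[CompoundRecord]:
    """Yield every library member in lexicographic order of bb_indices.

    With ``with_smiles=False`` (count-only mode) SMILES assembly is
    skipped, so arbitrarily large spaces stream in pure arithmetic.
    """
    if with_smiles:
        frags = [[bb.fragment for bb in plist] for plist in defn.blocks]
    for indices in itertools.product(*(range(c) for c in defn.positions)):
        cid = compound_id_from_indices(defn, indices)
        smiles = None
        if with_smiles:
            smiles = assemble_smiles([frags[p][i] for p, i in enumerate(indices)])
        yield CompoundRecord(compound_id=cid, bb_indices=indices, smiles=smiles)


def find_duplicate_compounds(
    records: Iterable[CompoundRecord],
) -> list[list[tuple[int, ...]]]:
    """Groups (size >= 2) of bb_indices whose assembled SMILES coincide.

    Downstream analyses keep duplicates as separate entries; this reports
    them so the unique-compound count can be stated alongside the
    enumerated total.  Records with missing/unparsable SMILES are excluded
    and logged.
    """
    by_smiles: dict[str, list[tuple[int, ...]]] = {}
    for rec in records:
        if rec.smiles is None:
            raise LibraryError("find_duplicate_compounds requires SMILES on records")
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            logger.warning("unparsable SMILES for %s; excluded", rec.compound_id)
            continue
        by_smiles.setdefault(Chem.MolToSmiles(mol), []).append(rec.bb_indices)
    return [grp for grp in by_smiles.values() if len(grp) >= 2]


def unique_compound_count(records: Iterable[CompoundRecord]) -> int:
    """Number of distinct canonical SMILES among the records."""
    seen: set[str] = set()
    for rec in records:
        if rec.smiles is None:
            raise LibraryError("unique_compound_count requires SMILES on records")
        seen.add(Chem.CanonSmiles(rec.smiles))
    return len(seen)


def match_hits_by_composition(
    defn: LibraryDefinition, hit_bb_tuples: Iterable[Sequence[int]]
) -> list[str]:
    """Reconstruct deterministic compound ids from building-block tuples.

    This mirrors hit identification when the source data report only the
    constituent building blocks of each hit, not a compound identifier.
    """
    return [compound_id_from_indices(defn, t) for t in hit_bb_tuples]


# ---------------------------------------------------------------------------
# CSV interfaces

_BLOCK_FIELDS = ["position", "index", "smiles", "label"]


def write_blocks_csv(defn: LibraryDefinition, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_BLOCK_FIELDS)
        for plist in defn.blocks:
            for bb in plist:
                w.writerow([bb.position, bb.index, bb.fragment, bb.label])


def read_blocks_csv(path, name: str = "") -> LibraryDefinition:
    rows: list[BuildingBlock] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append(
                BuildingBlock(
                    position=int(row["position"]),
                    index=int(row["index"]),
                    fragment=row["smiles"],
                    label=row.get("label", "") or "",
                )
            )
    if not rows:
        raise LibraryError(f"no building blocks in {path}")
    n_pos = max(bb.position for bb in rows) + 1
    blocks: list[list[BuildingBlock]] = [[] for _ in range(n_pos)]
    for bb in sorted(rows, key=lambda b: (b.position, b.index)):
        blocks[bb.position].append(bb)
    return LibraryDefinition(blocks=blocks, name=name)


def write_compounds_csv(records: Iterable[CompoundRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "bb_indices", "smiles"])
        for rec in records:
            w.writerow(
                [
                    rec.compound_id,
                    "-".join(str(i) for i in rec.bb_indices),
                    rec.smiles or "",
                ]
            )


def read_compounds_csv(path) -> list[CompoundRecord]:
    out: list[CompoundRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                CompoundRecord(
                    compound_id=row["compound_id"],
                    bb_indices=tuple(int(x) for x in row["bb_indices"].split("-")),
                    smiles=row["smiles"] or None,
                )
            )
    return out
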
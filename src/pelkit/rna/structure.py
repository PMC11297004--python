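"""RNA 3-D structures from multi-model PDB files.

Each MODEL in a PDB file becomes one :class:`RnaStructure` (an NMR ensemble
yields one structure per proposed configuration).  Residues are renumbered
1-based along the chain; only standard ribonucleotides (A, C, G, U, plus
common aliases) are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from ..exceptions import EmptyStructureError, PdbParseError

__all__ = ["NucleotideRecord", "RnaStructure", "read_pdb_models"]

_RNA_ALIASES = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "RA": "A", "RC": "C", "RG": "G", "RU": "U",
    "A5": "A", "C5": "C", "G5": "G", "U5": "U",
    "A3": "A", "C3": "C", "G3": "G", "U3": "U",
}

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}

# ring atoms used for base planes and centres
RING_ATOMS = {
    "A": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "G": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "C": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "U": ["N1", "C2", "N3", "C4", "C5", "C6"],
}

SUGAR_RING = ["C1'", "C2'", "C3'", "C4'", "O4'"]


@dataclass
class NucleotideRecord:
    """One residue: 1-based index, base identity, atom name → coordinates (Å)."""

    index: int
    base: str
    atoms: dict = field(default_factory=dict)
    author_id: int | None = None

    def coord(self, name: str):
        return self.atoms.get(name)

    def has_atoms(self, names) -> bool:
        return all(n in self.atoms for n in names)

    @property
    def is_purine(self) -> bool:
        return self.base in PURINES

    def ring_coords(self) -> np.ndarray | None:
        names = RING_ATOMS[self.base]
        if not self.has_atoms(names):
            return None
        return np.array([self.atoms[n] for n in names])


@dataclass
class RnaStructure:
    """One model of an RNA chain."""

    residues: list
    model_id: int = 0
    chain_id: str = "A"

    @property
    def sequence(self) -> str:
        return "".join(r.base for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, index: int) -> NucleotideRecord:
        """Residue by its 1-based index (indices need not be contiguous)."""
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"no residue with index {index}")

    def residue_or_none(self, index: int) -> NucleotideRecord | None:
        try:
            return self.residue(index)
        except KeyError:
            return None

    def transformed(self, rotation=None, translation=None) -> "RnaStructure":
        """Copy with every atom rotated then translated (invariance checks)."""
        rot = np.eye(3) if rotation is None else np.asarray(rotation, float)
        tr = np.zeros(3) if translation is None else np.asarray(translation, float)
        new_res = []
        for r in self.residues:
            atoms = {n: rot @ np.asarray(c, float) + tr for n, c in r.atoms.items()}
            new_res.append(
                NucleotideRecord(r.index, r.base, atoms, r.author_id)
            )
        return RnaStructure(new_res, self.model_id, self.chain_id)


def _prevalidate(path: Path) -> None:
    """Check ATOM/HETATM coordinate fields parse, reporting the line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PdbParseError(
                    f"truncated ATOM record at line {lineno}", line_number=lineno
                )
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise PdbParseError(
                    f"malformed coordinates in ATOM record at line {lineno}",
                    line_number=lineno,
                ) from None


def read_pdb_models(path) -> list[RnaStructure]:
    """Parse a (multi-model) PDB file into one :class:`RnaStructure` per model.

    The first chain containing RNA residues is used in each model; the first
    alternate location of a disordered atom is kept.  Raises
    :class:`EmptyStructureError` if no model contains RNA residues and
    :class:`PdbParseError` (with line number) on malformed ATOM records.
    """
    path = Path(path)
    _prevalidate(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))

    models = []
    for model in structure:
        for chain in model:
            residues = []
            idx = 0
            for res in chain:
                base = _RNA_ALIASES.get(res.get_resname().strip())
                if base is None:
                    continue
                idx += 1
                atoms = {}
                for atom in res.get_atoms():
                    # Bio.PDB presents the highest-occupancy / first altloc
                    # for disordered atoms
                    atoms[atom.get_name()] = np.array(atom.get_coord(), dtype=float)
                residues.append(
                    NucleotideRecord(
                        index=idx,
                        base=base,
                        atoms=atoms,
                        author_id=res.get_id()[1],
                    )
                )
            if residues:
                models.append(
                    RnaStructure(
                        residues=residues,
                        model_id=model.get_id(),
                        chain_id=chain.get_id(),
                    )
                )
                break  # first RNA-bearing chain per model
    if not models:
        raise EmptyStructureError(f"{path}: no RNA residues found")
    return models
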
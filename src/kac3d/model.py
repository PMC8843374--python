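"""Hierarchical structure model: atoms, residues, chains, entries.

Residues carry *author* numbering (the numbers printed in the coordinate
file), because acetylation sites in the literature are cited that way
(K136 of Adk, K56 of KatE, ...). Insertion codes are honored; the pair
(author_number, insertion_code) is unique within a chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

#: 3-letter -> 1-letter amino-acid codes, plus common modified residues
#: mapped to their parent amino acid (sequence view only; the Residue
#: keeps its original name).
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # modified residues -> parent
    "MSE": "M", "SEC": "C", "PYL": "K", "CSO": "C", "PTR": "Y",
    "SEP": "S", "TPO": "T", "MLY": "K", "ALY": "K", "KCX": "K",
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

NUCLEOTIDE_NAMES = {
    "A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU", "I", "DI",
    "PSU", "1MA", "5MC", "7MG", "H2U", "OMG", "OMC", "5MU", "2MG", "M2G",
    "4SU", "YG",
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False
    residue: Optional["Residue"] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be 3 finite numbers")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    author_number: int
    name: str
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)
    chain: Optional["Chain"] = field(default=None, repr=False, compare=False)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def is_nucleotide(self) -> bool:
        return self.name in NUCLEOTIDE_NAMES

    @property
    def is_polymer(self) -> bool:
        """Amino-acid residue (waters and het groups are not polymer)."""
        return self.name in THREE_TO_ONE

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    @property
    def label(self) -> str:
        return f"{self.name}{self.author_number}{self.insertion_code}"

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.atom("CA")

    def heavy_coords(self) -> np.ndarray:
        """Coordinates of non-hydrogen atoms, shape (n, 3)."""
        pts = [a.coords for a in self.atoms if a.element != "H"]
        return np.array(pts) if pts else np.empty((0, 3))

    def add_atom(self, atom: Atom) -> None:
        atom.residue = self
        self.atoms.append(atom)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    #: declared (SEQRES / entity) sequence; empty string when absent
    seqres_sequence: str = ""

    def add_residue(self, res: Residue) -> None:
        res.chain = self
        self.residues.append(res)

    @property
    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer]

    @property
    def atom_sequence(self) -> str:
        """1-letter sequence of resolved polymer residues, in file order."""
        return "".join(r.one_letter for r in self.polymer_residues)

    @property
    def numbering_map(self) -> list[tuple[int, str]]:
        """``numbering_map[i]`` is ``(author_number, insertion_code)`` of the
        residue at ``atom_sequence[i]``; a bijection onto resolved residues."""
        return [(r.author_number, r.insertion_code) for r in self.polymer_residues]

    def residue_by_number(self, author_number: int, insertion_code: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.author_number == author_number and r.insertion_code == insertion_code:
                return r
        return None

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates of polymer residues that have one, shape (n, 3)."""
        return np.array([r.ca.coords for r in self.polymer_residues if r.ca is not None])

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)


@dataclass
class StructureModel:
    entry_id: str
    chains: list[Chain] = field(default_factory=list)
    resolution: Optional[float] = None

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.entry_id}: duplicate chain ids {ids}")
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError(f"{self.entry_id}: resolution must be positive")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"{self.entry_id}: no chain {chain_id!r}")

    @property
    def polymer_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.polymer_residues]

    @property
    def het_groups(self) -> list[Residue]:
        """Non-water, non-polymer residues (ligands, cofactors, ions)."""
        return [
            r
            for c in self.chains
            for r in c.residues
            if not r.is_polymer and not r.is_water and not r.is_nucleotide
        ]

    @property
    def waters(self) -> list[Residue]:
        return [r for c in self.chains for r in c.residues if r.is_water]

    def all_atoms(self) -> list[Atom]:
        return [a for c in self.chains for r in c.residues for a in r.atoms]
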
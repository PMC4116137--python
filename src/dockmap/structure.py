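"""Hierarchical structure model and PDB I/O.

A :class:`Structure` is an ordered chain -> residue -> atom hierarchy with
author numbering (insertion codes preserved).  PDB reading and writing are
delegated to :mod:`gemmi`; this module only adapts gemmi's hierarchy to the
lightweight containers the analysis layer works on, applies the altloc
policy (keep the highest-occupancy conformer) and filters heteroatoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Residues whose side chain is predominantly apolar.  CYS and GLY are kept
#: on the hydrophobic side, following the sign of the Kyte-Doolittle scale.
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "GLY", "CYS"}
)
#: The remaining ten standard residues (polar / charged side chains).
HYDROPHILIC_RESIDUES = frozenset(
    {"SER", "THR", "ASN", "GLN", "TYR", "HIS", "LYS", "ARG", "ASP", "GLU"}
)
STANDARD_RESIDUES = HYDROPHOBIC_RESIDUES | HYDROPHILIC_RESIDUES

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_ATOMIC_MASS = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971,
}

#: Key identifying a residue within a structure: (chain_id, seq_num, icode).
ResidueKey = tuple[str, int, str]


def classify_residue(res_name: str, fallback: str = "hydrophilic") -> str:
    """Polarity class of a residue: ``"hydrophobic"`` or ``"hydrophilic"``.

    The twenty standard residues are split 10/10; non-standard names fall
    back to *fallback* with a logged warning.
    """
    name = res_name.upper()
    if name in HYDROPHOBIC_RESIDUES:
        return "hydrophobic"
    if name in HYDROPHILIC_RESIDUES:
        return "hydrophilic"
    logger.warning("non-standard residue %r classified as %s", res_name, fallback)
    return fallback


@dataclass
class Atom:
    """A single atom: PDB name, element symbol and Cartesian coordinate (A)."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {self.name}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    @property
    def mass(self) -> float:
        return _ATOMIC_MASS.get(self.element.upper(), 12.011)


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def polarity_class(self) -> str:
        return classify_residue(self.res_name)

    @property
    def label(self) -> str:
        """Compact residue label, e.g. ``Arg31L`` or ``Asp52aH``."""
        return f"{self.res_name.capitalize()}{self.seq_num}{self.icode.strip()}{self.chain_id}"

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


class Structure:
    """An ordered collection of chains of residues.

    Residue keys ``(chain_id, seq_num, icode)`` are unique; chains keep their
    file order.  All coordinate math downstream reads through
    :meth:`atom_table`.
    """

    def __init__(self, residues: list[Residue], model_id: int = 1, title: str = ""):
        if not residues:
            raise ValueError("a Structure needs at least one residue")
        self.model_id = model_id
        self.title = title
        self.chains: dict[str, list[Residue]] = {}
        seen: set[ResidueKey] = set()
        for res in residues:
            if res.key in seen:
                raise ValueError(f"duplicate residue key {res.key}")
            seen.add(res.key)
            self.chains.setdefault(res.chain_id, []).append(res)

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self, chains: set[str] | None = None) -> list[Residue]:
        ids = self.chain_ids if chains is None else [c for c in self.chain_ids if c in chains]
        return [r for c in ids for r in self.chains[c]]

    def __len__(self) -> int:
        return sum(len(rs) for rs in self.chains.values())

    def n_atoms(self, heavy_only: bool = False) -> int:
        return sum(
            1 for r in self.residues() for a in r.atoms if a.is_heavy or not heavy_only
        )

    def atom_table(
        self, chains: set[str] | None = None, heavy_only: bool = True
    ) -> tuple[np.ndarray, list[Residue], np.ndarray]:
        """Flat coordinate view: (coords [n,3], residue list, residue index per atom)."""
        coords, res_idx, residues = [], [], self.residues(chains)
        for i, res in enumerate(residues):
            for atom in res.atoms:
                if heavy_only and not atom.is_heavy:
                    continue
                coords.append(atom.coord)
                res_idx.append(i)
        if not coords:
            return np.empty((0, 3)), residues, np.empty(0, dtype=int)
        return np.array(coords), residues, np.array(res_idx, dtype=int)

    def coords(self, chains: set[str] | None = None, heavy_only: bool = True) -> np.ndarray:
        return self.atom_table(chains, heavy_only)[0]

    def copy(self) -> "Structure":
        residues = [
            Residue(
                r.chain_id, r.seq_num, r.icode, r.res_name,
                [Atom(a.name, a.element, a.coord.copy(), a.occupancy, a.altloc) for a in r.atoms],
            )
            for r in self.residues()
        ]
        return Structure(residues, model_id=self.model_id, title=self.title)

    def transform(self, rotation: np.ndarray, translation: np.ndarray,
                  chains: set[str] | None = None) -> "Structure":
        """Return a copy with ``x -> R x + t`` applied to *chains* (default all)."""
        out = self.copy()
        targets = out.chain_ids if chains is None else chains
        for res in out.residues(set(targets)):
            for atom in res.atoms:
                atom.coord = rotation @ atom.coord + translation
        return out


@dataclass(frozen=True)
class Partition:
    """Role split of a complex into receptor (Ab1) and ligand (Ab2) chain groups."""

    receptor_chains: frozenset[str]
    ligand_chains: frozenset[str]

    def __post_init__(self) -> None:
        rec = frozenset(self.receptor_chains)
        lig = frozenset(self.ligand_chains)
        object.__setattr__(self, "receptor_chains", rec)
        object.__setattr__(self, "ligand_chains", lig)
        if not rec or not lig:
            raise ValueError("both partition sides must be non-empty")
        if rec & lig:
            raise ValueError(f"partition sides overlap: {sorted(rec & lig)}")

    def validate(self, s: Structure) -> None:
        present = set(s.chain_ids)
        missing = (self.receptor_chains | self.ligand_chains) - present
        if missing:
            raise ValueError(f"partition chains absent from structure: {sorted(missing)}")

    def swapped(self) -> "Partition":
        return Partition(self.ligand_chains, self.receptor_chains)


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def _from_gemmi_model(model: gemmi.Model, include_het: bool, title: str) -> Structure:
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES:
                continue
            if res.het_flag == "H" and not include_het:
                continue
            # altloc policy: per atom name keep max occupancy, ties -> first altloc
            by_name: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = by_name.get(atom.name)
                if prev is None or (atom.occ, -ord(atom.altloc or "~")) > (
                    prev.occ, -ord(prev.altloc or "~")
                ):
                    by_name[atom.name] = atom
            atoms = [
                Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]),
                     occupancy=a.occ, altloc=(a.altloc or "").strip())
                for a in by_name.values()
            ]
            if atoms:
                residues.append(Residue(chain.name, res.seqid.num,
                                        res.seqid.icode.strip(), res.name, atoms))
    if not residues:
        raise ValueError("no ATOM records found")
    return Structure(residues, model_id=getattr(model, "num", 1), title=title)


def read_pdb(path: str, model_index: int = 1, include_het: bool = False) -> Structure:
    """Read one MODEL of a PDB file into a :class:`Structure`.

    *model_index* is 1-based.  For altloc duplicates the highest-occupancy
    conformer is kept (ties broken towards the lexicographically first
    altloc).  Waters are always dropped; other HETATM records only with
    ``include_het=True``.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no ATOM records")
    if not 1 <= model_index <= len(st):
        raise ValueError(f"{path}: model {model_index} absent ({len(st)} model(s))")
    return _from_gemmi_model(st[model_index - 1], include_het, st.name or "")


def read_pdb_models(path: str, include_het: bool = False) -> list[Structure]:
    """Read every MODEL of a (possibly multi-model) PDB file."""
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no ATOM records")
    return [_from_gemmi_model(m, include_het, st.name or "") for m in st]


def _to_gemmi(structures: list[Structure]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structures[0].title or "dockmap"
    for i, s in enumerate(structures, start=1):
        model = gemmi.Model(i)
        for chain_id in s.chain_ids:
            chain = gemmi.Chain(chain_id)
            for res in s.chains[chain_id]:
                gres = gemmi.Residue()
                gres.name = res.res_name
                gres.seqid = gemmi.SeqId(res.seq_num, res.icode or " ")
                gres.het_flag = "A"
                for atom in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*atom.coord)
                    ga.occ = atom.occupancy
                    ga.altloc = atom.altloc[:1] if atom.altloc else "\0"
                    gres.add_atom(ga)
                chain.add_residue(gres)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(s: Structure, path: str) -> None:
    """Write a Structure to a PDB file (fixed-format, 3-decimal coordinates)."""
    _to_gemmi([s]).write_pdb(str(path))


def write_pdb_models(structures: list[Structure], path: str) -> None:
    """Write several structures as consecutive MODEL records (trajectory PDB)."""
    if not structures:
        raise ValueError("nothing to write")
    _to_gemmi(structures).write_pdb(str(path))


def select(s: Structure, chains: set[str], atom_class: str = "all") -> Structure:
    """Sub-structure restricted to *chains* and an atom class.

    ``atom_class`` is one of ``all``, ``heavy``, ``backbone`` (N, CA, C, O)
    or ``calpha``.
    """
    unknown = set(chains) - set(s.chain_ids)
    if unknown:
        raise ValueError(f"unknown chain id(s): {sorted(unknown)}")

    def keep(a: Atom) -> bool:
        if atom_class == "all":
            return True
        if atom_class == "heavy":
            return a.is_heavy
        if atom_class == "backbone":
            return a.name in BACKBONE_ATOMS
        if atom_class == "calpha":
            return a.name == "CA"
        raise ValueError(f"unknown atom class {atom_class!r}")

    residues = []
    for res in s.residues(set(chains)):
        atoms = [Atom(a.name, a.element, a.coord.copy(), a.occupancy, a.altloc)
                 for a in res.atoms if keep(a)]
        if atoms:
            residues.append(Residue(res.chain_id, res.seq_num, res.icode, res.res_name, atoms))
    if not residues:
        raise ValueError("selection is empty")
    return Structure(residues, model_id=s.model_id, title=s.title)
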
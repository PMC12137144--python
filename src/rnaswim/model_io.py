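"""Atomic-model I/O, RNA chemistry annotation, and geometric queries.

Models are stored as parallel arrays of heavy atoms (hydrogens are
dropped on read; all downstream geometry considers heavy atoms only).
A residue is identified by ``(chain, seqid)``. Alternate locations are
resolved to the highest-occupancy conformer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "StructureModel",
    "ChemistryFlags",
    "read_model",
    "write_model",
    "write_model_with_solvent",
    "annotate_chemistry",
    "residues_near",
    "b_from_q",
]

#: residue names treated as solvent/ions rather than polymer
SOLVENT_NAMES = frozenset({"HOH", "WAT", "MG", "NA", "K", "CL", "ZN", "MN"})

RNA_RESIDUES = frozenset({"A", "C", "G", "U"})

# Standard neutral-pH RNA protonation: ring/exocyclic nitrogens bearing a
# hydrogen (hydrogen-bond donors) versus bare ring nitrogens (acceptors).
# Glycosidic nitrogens (purine N9, pyrimidine N1) are substituted by the
# sugar and are neither donors nor acceptors.
PROTONATED_N = frozenset({
    ("G", "N1"), ("G", "N2"), ("U", "N3"), ("A", "N6"), ("C", "N4"),
})
ACCEPTOR_N = frozenset({
    ("A", "N1"), ("A", "N3"), ("A", "N7"),
    ("G", "N3"), ("G", "N7"),
    ("C", "N3"),
})


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    residue_name: str
    chain: str
    residue_seq: int
    position: np.ndarray
    b_iso: float = 0.0
    occupancy: float = 1.0

    @property
    def residue_id(self) -> tuple[str, int]:
        return (self.chain, self.residue_seq)


@dataclass(frozen=True)
class ChemistryFlags:
    is_nonpolar: bool
    is_electronegative: bool
    is_protonated_nitrogen: bool

    @property
    def category(self) -> str:
        if self.is_nonpolar:
            return "nonpolar"
        if self.is_electronegative:
            return "electronegative"
        if self.is_protonated_nitrogen:
            return "protonated_n"
        return "other"


class StructureModel:
    """Heavy-atom model with residue bookkeeping and fast spatial queries."""

    def __init__(self, atoms: list[Atom]):
        if not atoms:
            raise ValueError("model contains no atoms")
        self.atoms = list(atoms)
        self.coords = np.array([a.position for a in self.atoms], dtype=float)
        self.names = np.array([a.name for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])
        self.residue_names = np.array([a.residue_name for a in self.atoms])
        self.chains = np.array([a.chain for a in self.atoms])
        self.residue_seqs = np.array([a.residue_seq for a in self.atoms])
        self._tree: cKDTree | None = None
        self._residue_index: dict[tuple[str, int], np.ndarray] = {}
        for i, a in enumerate(self.atoms):
            self._residue_index.setdefault(a.residue_id, []).append(i)
        self._residue_index = {
            k: np.asarray(v, dtype=int) for k, v in self._residue_index.items()
        }

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.coords)
        return self._tree

    @property
    def residue_ids(self) -> list[tuple[str, int]]:
        return list(self._residue_index)

    def residue_atom_indices(self, residue_id: tuple[str, int]) -> np.ndarray:
        return self._residue_index[residue_id]

    def is_polymer_atom(self) -> np.ndarray:
        return ~np.isin(self.residue_names, sorted(SOLVENT_NAMES))

    def polymer(self) -> "StructureModel":
        """Sub-model containing only non-solvent, non-ion residues."""
        keep = self.is_polymer_atom()
        return StructureModel([a for a, k in zip(self.atoms, keep) if k])

    def select(self, mask) -> "StructureModel":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return StructureModel([self.atoms[i] for i in idx])

    def binder_class(self) -> np.ndarray:
        """Atom names with OP1/OP2 collapsed to the common OP class."""
        return np.where(np.isin(self.names, ["OP1", "OP2"]), "OP", self.names)


def _element_from_name(name: str, residue_name: str) -> str:
    if residue_name == "MG" or name == "MG":
        return "Mg"
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_model(path) -> StructureModel:
    """Read a PDB or mmCIF model, keeping heavy atoms only.

    Altloc duplicates are resolved to the highest-occupancy conformer.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    atoms: dict[tuple, Atom] = {}
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                if at.element.is_hydrogen:
                    continue
                key = (chain.name, res.seqid.num, res.name, at.name)
                element = at.element.name if at.element.name != "X" else \
                    _element_from_name(at.name, res.name)
                candidate = Atom(
                    name=at.name,
                    element=element,
                    residue_name=res.name.strip(),
                    chain=chain.name,
                    residue_seq=res.seqid.num,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    b_iso=at.b_iso,
                    occupancy=at.occ,
                )
                if key not in atoms or candidate.occupancy > atoms[key].occupancy:
                    atoms[key] = candidate
    if not atoms:
        raise ValueError(f"no heavy atoms found in {path!r}")
    return StructureModel(list(atoms.values()))


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    # gemmi containers copy on add, so each level is fully built before
    # being attached to its parent
    grouped: dict[str, list[list[Atom]]] = {}
    for a in model.atoms:
        residues = grouped.setdefault(a.chain, [])
        key = (a.chain, a.residue_seq, a.residue_name)
        if not residues or residues[-1][0] != key:
            residues.append([key, []])
        residues[-1][1].append(a)

    st = gemmi.Structure()
    st.name = "rnaswim"
    gm = gemmi.Model("1")
    for chain_name, residues in grouped.items():
        ch = gemmi.Chain(chain_name)
        for (_, seq, resname), atom_list in residues:
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(seq, " ")
            res.het_flag = "H" if resname in SOLVENT_NAMES else "A"
            for a in atom_list:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.position)
                ga.b_iso = float(a.b_iso)
                ga.occ = float(a.occupancy)
                res.add_atom(ga)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_model(model: StructureModel, path) -> None:
    """Write PDB or mmCIF depending on file suffix (.pdb / .cif, .mmcif)."""
    st = _to_gemmi(model)
    suffix = Path(path).suffix.lower()
    if suffix == ".pdb":
        st.write_pdb(str(path))
    elif suffix in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unsupported model format {suffix!r}")


def b_from_q(q: float) -> float:
    """Isotropic displacement factor assigned from resolvability: B = 150(1 - Q)."""
    if not -1.0 <= q <= 1.0:
        raise ValueError(f"Q score {q} outside [-1, 1]")
    return 150.0 * (1.0 - q)


def write_model_with_solvent(model: StructureModel, placements, path,
                             start_seq: int = 1) -> None:
    """Write the model plus SWIM placements as HOH O / MG records.

    Each solvent atom carries B = 150(1 - Q) computed from its full-map
    Q score.
    """
    solvent_atoms = []
    seq = start_seq
    for p in placements:
        q_full = p.q.q_full if hasattr(p, "q") else p.q_full
        if p.kind == "water":
            resname, name, element, chain = "HOH", "O", "O", "W"
        elif p.kind == "magnesium":
            resname, name, element, chain = "MG", "MG", "Mg", "I"
        else:
            raise ValueError(f"unknown solvent kind {p.kind!r}")
        solvent_atoms.append(Atom(
            name=name, element=element, residue_name=resname,
            chain=chain, residue_seq=seq,
            position=np.asarray(p.position, dtype=float),
            b_iso=b_from_q(q_full), occupancy=1.0,
        ))
        seq += 1
    write_model(StructureModel(model.atoms + solvent_atoms), path)


def annotate_chemistry(model: StructureModel) -> list[ChemistryFlags]:
    """Assign SWIM chemistry flags to every heavy atom.

    Carbon and phosphorus are non-polar; all oxygens and acceptor
    (non-protonated) nitrogens are electronegative; donor nitrogens are
    flagged protonated. Atoms of unknown residues fall to "other" with a
    warning, never silently electronegative.
    """
    flags = []
    warned: set[str] = set()
    for a in model.atoms:
        el = a.element.upper()
        rn = a.residue_name
        if el in ("C", "P"):
            flags.append(ChemistryFlags(True, False, False))
        elif rn in RNA_RESIDUES:
            if el == "O":
                flags.append(ChemistryFlags(False, True, False))
            elif el == "N":
                if (rn, a.name) in PROTONATED_N:
                    flags.append(ChemistryFlags(False, False, True))
                elif (rn, a.name) in ACCEPTOR_N:
                    flags.append(ChemistryFlags(False, True, False))
                else:  # glycosidic N9 / pyrimidine N1
                    flags.append(ChemistryFlags(False, False, False))
            else:
                flags.append(ChemistryFlags(False, False, False))
        elif rn in SOLVENT_NAMES:
            flags.append(ChemistryFlags(False, False, False))
        else:
            if rn not in warned:
                warnings.warn(
                    f"unknown residue {rn!r}: atoms flagged 'other'",
                    stacklevel=2,
                )
                warned.add(rn)
            flags.append(ChemistryFlags(False, False, False))
    return flags


def residues_near(model: StructureModel, position, radius: float) -> set:
    """Residue ids having at least one heavy atom within radius of position."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if np.isinf(radius):
        return set(model.residue_ids)
    idx = model.tree.query_ball_point(np.asarray(position, dtype=float), radius)
    return {self_atom.residue_id for self_atom in (model.atoms[i] for i in idx)}
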
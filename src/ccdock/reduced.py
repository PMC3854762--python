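"""Coarse-grain (reduced) protein representation.

Each amino acid becomes one backbone pseudo-atom at the C-alpha position
plus, except for Gly, one or two side-chain pseudo-atoms:

* Ala, Ser, Thr, Val, Leu, Ile, Asn, Asp, Cys carry a single side-chain
  bead at the geometric centre of the side-chain heavy atoms;
* all other residues carry a first bead midway between C-beta and C-gamma
  and a second bead at the geometric centre of the remaining side-chain
  heavy atoms.

Point charges (Asp/Glu -1, Lys/Arg +1, His configurable) sit on the
outermost side-chain bead of the charged residue types.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .config import Config, DEFAULTS

log = logging.getLogger(__name__)

ResidueId = tuple[str, int, str]  # (chain, author sequence number, insertion code)

#: residue types represented by a single side-chain bead
ONE_BEAD = {"ALA", "SER", "THR", "VAL", "LEU", "ILE", "ASN", "ASP", "CYS"}
TWO_BEAD = {"ARG", "LYS", "HIS", "GLU", "GLN", "MET", "PHE", "TYR", "TRP", "PRO"}
STANDARD = ONE_BEAD | TWO_BEAD | {"GLY"}

#: net charges of the charged side chains, in elementary-charge units
CHARGES = {"ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class PseudoAtom:
    residue_id: ResidueId
    role: str  # 'backbone' | 'sidechain1' | 'sidechain2'
    position: np.ndarray
    lj_type: str
    charge: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for {self.residue_id}")


@dataclass
class ReducedProtein:
    """Rigid coarse-grain body: an ordered set of pseudo-atoms.

    Multimeric inputs are merged into a single rigid body; chain identity
    is retained inside each residue id.
    """

    protein_id: str
    pseudo_atoms: list[PseudoAtom]
    residue_names: dict[ResidueId, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._coords = np.array([a.position for a in self.pseudo_atoms], dtype=float)
        self._charges = np.array([a.charge for a in self.pseudo_atoms], dtype=float)
        self._lj_types = [a.lj_type for a in self.pseudo_atoms]
        self._index: dict[ResidueId, list[int]] = {}
        for i, a in enumerate(self.pseudo_atoms):
            self._index.setdefault(a.residue_id, []).append(i)

    # -- array views ---------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        return self._coords

    @property
    def charges(self) -> np.ndarray:
        return self._charges

    @property
    def lj_types(self) -> list[str]:
        return self._lj_types

    @property
    def residue_index(self) -> dict[ResidueId, list[int]]:
        return self._index

    @property
    def residue_ids(self) -> list[ResidueId]:
        return list(self._index)

    @property
    def chains(self) -> set[str]:
        return {rid[0] for rid in self._index}

    @property
    def n_residues(self) -> int:
        return len(self._index)

    def center(self) -> np.ndarray:
        """Centre of mass with unit bead masses."""
        return self._coords.mean(axis=0)

    def atom_residue_ids(self) -> list[ResidueId]:
        return [a.residue_id for a in self.pseudo_atoms]

    def residue_point(self, rid: ResidueId) -> np.ndarray:
        """A residue collapsed to a point: the mean of its bead positions."""
        return self._coords[self._index[rid]].mean(axis=0)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> np.ndarray:
        """Coordinates after rotating about the centre of mass, then translating."""
        xyz = self._coords
        if rotation is not None:
            c = self.center()
            xyz = (xyz - c) @ np.asarray(rotation).T + c
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return xyz


@dataclass
class InterfaceSpec:
    """A set of interface residues of one protein (experimental or predicted)."""

    protein_id: str
    residues: frozenset[ResidueId]
    provenance: str = "experimental"  # 'experimental' | 'predicted'

    def __post_init__(self) -> None:
        self.residues = frozenset(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def expected_bead_count(residue_names: Iterable[str]) -> int:
    """Bead bookkeeping: 1 for Gly, 2 for one-bead types, 3 otherwise."""
    n = 0
    for name in residue_names:
        n += 1 if name == "GLY" else 2 if name in ONE_BEAD else 3
    return n


def _sidechain_heavy(residue) -> dict[str, np.ndarray]:
    """Highest-occupancy heavy side-chain atoms of a Bio.PDB residue."""
    best: dict[str, tuple[float, np.ndarray]] = {}
    for atom in residue.get_unpacked_list():
        name = atom.get_name()
        if name in BACKBONE_ATOMS or atom.element == "H" or name.startswith("H"):
            continue
        occ = atom.get_occupancy() or 1.0
        if name not in best or occ > best[name][0]:
            best[name] = (occ, np.asarray(atom.get_coord(), dtype=float))
    return {name: xyz for name, (_, xyz) in best.items()}


def reduce_residue(resname: str, rid: ResidueId, ca: np.ndarray,
                   sidechain: dict[str, np.ndarray],
                   his_charge: float = 0.0) -> list[PseudoAtom]:
    """Apply the bead placement rules to one residue."""
    beads = [PseudoAtom(rid, "backbone", ca, "BB")]
    if resname == "GLY":
        return beads
    charge = CHARGES.get(resname, 0.0)
    if resname == "HIS":
        charge = his_charge
    if resname in ONE_BEAD:
        if sidechain:
            center = np.mean(list(sidechain.values()), axis=0)
            beads.append(PseudoAtom(rid, "sidechain1", center, f"{resname}1", charge))
        return beads
    # two-bead residue
    cb, cg = sidechain.get("CB"), sidechain.get("CG")
    if cg is None:  # aromatic/branched gamma naming
        for alt in ("CG1", "OG", "OG1", "SG", "CG2"):
            if alt in sidechain:
                cg = sidechain[alt]
                break
    if cb is not None and cg is not None:
        beads.append(PseudoAtom(rid, "sidechain1", 0.5 * (cb + cg), f"{resname}1"))
    rest = [xyz for name, xyz in sidechain.items()
            if name not in ("CB", "CG") and xyz is not cg]
    if rest:
        beads.append(PseudoAtom(rid, "sidechain2", np.mean(rest, axis=0),
                                f"{resname}2", charge))
    elif len(beads) == 2:
        # degenerate side chain (e.g. truncated): charge falls on bead 1
        beads[1] = PseudoAtom(rid, "sidechain1", beads[1].position,
                              beads[1].lj_type, charge)
    return beads


def build_reduced(structure, protein_id: str | None = None,
                  config: Config = DEFAULTS) -> ReducedProtein:
    """Build the reduced model from an atomic structure.

    Parameters
    ----------
    structure : Bio.PDB entity or path to a PDB file
        Single-model structure; all chains are merged into one rigid body.
    protein_id : str, optional
        Defaults to the structure id / file stem.
    """
    from Bio.PDB import PDBParser

    if isinstance(structure, (str, Path)):
        path = Path(structure)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
        if protein_id is None:
            protein_id = path.stem
    if protein_id is None:
        protein_id = getattr(structure, "id", "protein")

    model = next(structure.get_models()) if hasattr(structure, "get_models") else structure
    beads: list[PseudoAtom] = []
    names: dict[ResidueId, str] = {}
    for chain in model:
        for residue in chain:
            het, seq, icode = residue.get_id()
            if het.strip():
                continue  # waters / ligands
            resname = residue.get_resname()
            if resname not in STANDARD:
                if config.unknown_residue == "skip":
                    log.warning("skipping unknown residue %s %s%d", resname,
                                chain.id, seq)
                    continue
                raise ValueError(f"unknown residue type {resname} at {chain.id}{seq}")
            if "CA" not in residue:
                log.warning("missing CA, rejecting residue %s %s%d", resname,
                            chain.id, seq)
                continue
            rid: ResidueId = (chain.id, seq, icode.strip() or "")
            ca = np.asarray(residue["CA"].get_coord(), dtype=float)
            beads.extend(reduce_residue(resname, rid, ca, _sidechain_heavy(residue),
                                        his_charge=config.his_charge))
            names[rid] = resname
    if not beads:
        raise ValueError(f"no standard residues found in {protein_id}")
    return ReducedProtein(protein_id, beads, names)


def format_residue_id(rid: ResidueId) -> str:
    chain, seq, icode = rid
    return f"{chain}:{seq}{icode}"


def parse_residue_id(text: str) -> ResidueId:
    chain, rest = text.split(":", 1)
    icode = ""
    while rest and rest[-1].isalpha():
        icode = rest[-1] + icode
        rest = rest[:-1]
    return (chain, int(rest), icode)


def write_reduced_pdb(protein: ReducedProtein, path: str | Path) -> None:
    """Write pseudo-atoms as HETATM records plus a tabular sidecar.

    The sidecar ``<path>.beads.tsv`` lists residue id, role, LJ type and
    charge for every bead, which the PDB format cannot carry.
    """
    path = Path(path)
    role_name = {"backbone": "CA", "sidechain1": "S1", "sidechain2": "S2"}
    with open(path, "w") as fh:
        for i, a in enumerate(protein.pseudo_atoms, start=1):
            chain, seq, icode = a.residue_id
            resname = protein.residue_names.get(a.residue_id, "UNK")
            x, y, z = a.position
            fh.write(
                f"HETATM{i:5d} {role_name[a.role]:<4s}{resname:>3s} "
                f"{chain[:1]}{seq:4d}{(icode or ' '):1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
            )
        fh.write("END\n")
    with open(path.with_suffix(path.suffix + ".beads.tsv"), "w") as fh:
        fh.write("residue_id\trole\tlj_type\tcharge\n")
        for a in protein.pseudo_atoms:
            fh.write(f"{format_residue_id(a.residue_id)}\t{a.role}\t"
                     f"{a.lj_type}\t{a.charge:g}\n")
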
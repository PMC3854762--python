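from __future__ import annotations

import numpy as np
import pytest

from ccdock.docking import DecoySet, DockedConformation, StartConfiguration
from ccdock.energy import EnergyParams
from ccdock.reduced import PseudoAtom, ReducedProtein
from ccdock.synth import ToySpec, make_toy_protein


def build_structure(residues):
    """Minimal Bio.PDB structure from [(resname, {atom: xyz}), ...]."""
    from Bio.PDB.StructureBuilder import StructureBuilder

    sb = StructureBuilder()
    sb.init_structure("test")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    serial = 1
    for i, (resname, atoms) in enumerate(residues):
        sb.init_residue(resname, " ", i + 1, " ")
        for name, xyz in atoms.items():
            element = name[0] if name[0] in "CNOS" else "C"
            sb.init_atom(name, np.asarray(xyz, dtype=float), 0.0, 1.0, " ",
                         f" {name:<3s}"[:4], serial, element)
            serial += 1
    return sb.get_structure()


def bead_protein(pid, positions, lj_type="BB", charges=None):
    """One single-bead residue per position."""
    beads = []
    for i, p in enumerate(positions):
        q = 0.0 if charges is None else charges[i]
        beads.append(PseudoAtom(("A", i + 1, ""), "backbone", p, lj_type, q))
    return ReducedProtein(pid, beads)


def make_decoys(rec_id, lig_id, specs):
    """Decoy set from [(energy, iface_rec, iface_lig), ...] tuples."""
    start = StartConfiguration(0.0, 0.0, np.array([0.0, 0.0, 0.0, 1.0]))
    confs = [DockedConformation(start, start.orientation, np.zeros(3),
                                float(e), frozenset(ir), frozenset(il),
                                conf_id=k)
             for k, (e, ir, il) in enumerate(specs)]
    return DecoySet(rec_id, lig_id, confs)


def rid(i, chain="A"):
    return (chain, i, "")


@pytest.fixture(scope="session")
def toy_pair():
    _, rec = make_toy_protein(ToySpec(n_residues=8, patch=(2, 6), seed=11,
                                      protein_id="rec"))
    _, lig = make_toy_protein(ToySpec(n_residues=8, patch=(2, 6), seed=12,
                                      protein_id="lig"))
    return rec, lig


@pytest.fixture(scope="session")
def default_params():
    return EnergyParams.synthetic_default()
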
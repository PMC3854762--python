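"""Tabular input/output for decoys, matrices and residue scores.

All tables are tab-separated text with a schema-version header line
(``# ccdock-schema <name>/<version>``) followed by a column header.
Decoy rows carry the (theta, phi)-indexed start, the final pose
(quaternion + centre) and the semicolon-joined interface residue lists,
which is enough to regenerate the PDB structure of any conformation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .docking import DecoySet, DockedConformation, StartConfiguration
from .reduced import (ReducedProtein, ResidueId, format_residue_id,
                      parse_residue_id, write_reduced_pdb)

SCHEMA = {"decoys": 1, "matrix": 1, "scores": 1, "signatures": 1}


def _header(name: str) -> str:
    return f"# ccdock-schema {name}/{SCHEMA[name]}\n"


def _join_residues(residues) -> str:
    return ";".join(format_residue_id(r) for r in sorted(residues)) or "-"


def _split_residues(text: str) -> frozenset[ResidueId]:
    if not text or text == "-":
        return frozenset()
    return frozenset(parse_residue_id(t) for t in text.split(";"))


def write_decoys(decoys: DecoySet, path: str | Path) -> None:
    cols = ("receptor_id\tligand_id\tconf_id\ttheta\tphi\tqx\tqy\tqz\tqw\t"
            "cx\tcy\tcz\tseparation\tenergy\tconverged\t"
            "interface_receptor\tinterface_ligand\n")
    with open(path, "w") as fh:
        fh.write(_header("decoys"))
        fh.write(cols)
        for c in decoys.conformations:
            q = c.rotation
            x, y, z = c.center
            sep = c.start.separation if c.start.separation is not None else np.nan
            fh.write(f"{decoys.receptor_id}\t{decoys.ligand_id}\t{c.conf_id}\t"
                     f"{c.start.theta:.8g}\t{c.start.phi:.8g}\t"
                     f"{q[0]:.8g}\t{q[1]:.8g}\t{q[2]:.8g}\t{q[3]:.8g}\t"
                     f"{x:.8g}\t{y:.8g}\t{z:.8g}\t{sep:.8g}\t"
                     f"{c.energy:.8g}\t{int(c.converged)}\t"
                     f"{_join_residues(c.interface_receptor)}\t"
                     f"{_join_residues(c.interface_ligand)}\n")


def read_decoys(path: str | Path) -> DecoySet:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"interface_receptor": str, "interface_ligand": str})
    confs = []
    for row in df.itertuples(index=False):
        start = StartConfiguration(row.theta, row.phi,
                                   np.array([row.qx, row.qy, row.qz, row.qw]),
                                   separation=row.separation)
        confs.append(DockedConformation(
            start, np.array([row.qx, row.qy, row.qz, row.qw]),
            np.array([row.cx, row.cy, row.cz]), float(row.energy),
            _split_residues(row.interface_receptor),
            _split_residues(row.interface_ligand),
            converged=bool(row.converged), conf_id=int(row.conf_id)))
    rid = df["receptor_id"].iloc[0] if len(df) else "receptor"
    lid = df["ligand_id"].iloc[0] if len(df) else "ligand"
    return DecoySet(rid, lid, confs, {"source": str(path)})


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header("matrix"))
        matrix.to_csv(fh, sep="\t", float_format="%.6g", na_rep="NA")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0,
                       na_values=["NA"])


def write_scores(table: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header("scores"))
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       keep_default_na=False,
                       na_values=[""], dtype={"chain": str, "icode": str})


def write_signatures(signatures, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header("signatures"))
        fh.write("query\tcandidate\tmean_ir\tsd_ir\tmean_auc\tlabel\n")
        for s in signatures:
            fh.write(f"{s.query}\t{s.candidate}\t{s.mean_ir:.6g}\t"
                     f"{s.sd_ir:.6g}\t{s.mean_auc:.6g}\t{s.label}\n")


def reconstruct_pose(receptor: ReducedProtein, ligand: ReducedProtein,
                     conformation: DockedConformation,
                     path: str | Path) -> None:
    """Write the complex of one decoy row as a pseudo-atom PDB file.

    The receptor keeps its stored coordinates; the ligand is posed from
    the conformation's rotation and centre.
    """
    posed = ReducedProtein(
        ligand.protein_id,
        [type(a)(a.residue_id, a.role,
                 pos, a.lj_type, a.charge)
         for a, pos in zip(ligand.pseudo_atoms,
                           conformation.ligand_coords(ligand))],
        ligand.residue_names)
    path = Path(path)
    write_reduced_pdb(receptor, path.with_suffix(".receptor.pdb"))
    write_reduced_pdb(posed, path.with_suffix(".ligand.pdb"))
    with open(path, "w") as fh:
        for part in (path.with_suffix(".receptor.pdb"),
                     path.with_suffix(".ligand.pdb")):
            fh.write(part.read_text())
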
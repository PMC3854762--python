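"""Partner identification scores built on docking decoys.

For one docked conformation, the fraction of interface residues (FIR) is
the fraction of its docked-interface residues that belong to a reference
interface, computed on the receptor side (FIR_R), the ligand side
(FIR_L), and combined (arithmetic mean by default).  The interaction
index (II) of an ordered pair is the FIR of the conformation minimising
FIR x energy over the decoy set: with negative energies the product
rewards jointly low energy and high interface agreement.  II matrices
are symmetrised (sII) and normalised (NII) over the rows and columns
featuring either partner, yielding values in [0, 1] comparable across
pairs; the pair attaining its scope maximum scores 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .config import Config, DEFAULTS
from .docking import DecoySet, DockedConformation
from .reduced import InterfaceSpec

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FIRRecord:
    fir_receptor: float
    fir_ligand: float
    fir_overall: float


_FIR_COMBINERS: dict[str, Callable[[float, float], float]] = {
    "mean": lambda r, l: 0.5 * (r + l),
    "min": min,
    "max": max,
}

_SII_COMBINERS: dict[str, Callable[[float, float], float]] = {
    "mean": lambda a, b: 0.5 * (a + b),
    "max": max,
    "min": min,
}


def _side_fir(docked: frozenset, reference: frozenset) -> float:
    if not docked:
        return 0.0
    return len(docked & reference) / len(docked)


def conformation_fir(conf: DockedConformation,
                     ref_receptor: InterfaceSpec,
                     ref_ligand: InterfaceSpec,
                     combiner: str | None = None,
                     config: Config = DEFAULTS) -> FIRRecord:
    """FIR of one conformation against reference interfaces."""
    comb = _FIR_COMBINERS[config.fir_combiner if combiner is None else combiner]
    r = _side_fir(conf.interface_receptor, ref_receptor.residues)
    l = _side_fir(conf.interface_ligand, ref_ligand.residues)
    return FIRRecord(r, l, comb(r, l))


def interaction_index(decoys: DecoySet,
                      ref_receptor: InterfaceSpec | None,
                      ref_ligand: InterfaceSpec | None,
                      fir_of: Callable[[DockedConformation], float] | None = None,
                      config: Config = DEFAULTS) -> float:
    """II of an ordered pair: the FIR of the conformation minimising FIR x E.

    ``fir_of`` overrides the per-conformation FIR (used for predicted
    interfaces); by default the experimental references are used.  Ties on
    the product resolve to the lowest energy, then the lowest
    conformation id.  Returns NaN when either reference is empty (the
    masked, no-prediction case).
    """
    if len(decoys) == 0:
        raise ValueError("empty decoy set")
    if fir_of is None:
        if ref_receptor is None or ref_ligand is None \
                or not ref_receptor.residues or not ref_ligand.residues:
            return float("nan")
        fir_of = lambda c: conformation_fir(c, ref_receptor, ref_ligand,
                                            config=config).fir_overall
    best_key = None
    best_fir = 0.0
    for c in decoys.conformations:
        f = fir_of(c)
        key = (f * c.energy, c.energy, c.conf_id)
        if best_key is None or key < best_key:
            best_key = key
            best_fir = f
    return float(best_fir)


def build_ii_matrix(decoy_sets: Mapping[tuple[str, str], DecoySet],
                    references: Mapping[str, InterfaceSpec] | None = None,
                    fir_factory: Callable[[str, str], Callable] | None = None,
                    config: Config = DEFAULTS) -> pd.DataFrame:
    """Assemble the ordered-pair II matrix (receptor rows, ligand columns).

    Either ``references`` (experimental mode) or ``fir_factory`` giving a
    per-pair FIR function (predicted mode) must be supplied.  Pairs with
    no decoy set or an empty reference are NaN (masked).
    """
    proteins = sorted({p for pair in decoy_sets for p in pair})
    mat = pd.DataFrame(np.nan, index=proteins, columns=proteins)
    for (rid, lid), ds in decoy_sets.items():
        if fir_factory is not None:
            mat.loc[rid, lid] = interaction_index(ds, None, None,
                                                  fir_of=fir_factory(rid, lid),
                                                  config=config)
        else:
            mat.loc[rid, lid] = interaction_index(
                ds, references.get(rid), references.get(lid), config=config)
    return mat


def symmetrize(ii: pd.DataFrame, combiner: str | None = None,
               config: Config = DEFAULTS) -> pd.DataFrame:
    """sII: combine II[i, j] and II[j, i] (mean by default); NaN propagates."""
    if ii.shape[0] != ii.shape[1] or not ii.index.equals(ii.columns):
        raise ValueError("II matrix must be square with matching labels")
    comb = _SII_COMBINERS[config.sii_combiner if combiner is None else combiner]
    v = ii.to_numpy(dtype=float)
    out = np.empty_like(v)
    n = len(v)
    for i in range(n):
        for j in range(n):
            out[i, j] = comb(v[i, j], v[j, i])
    return pd.DataFrame(out, index=ii.index, columns=ii.columns)


def normalize(sii: pd.DataFrame, config: Config = DEFAULTS) -> pd.DataFrame:
    """NII: divide sII[i, j] by the maximum over the rows and columns
    indexed by i and j (their union); an all-zero scope yields 0, masked
    entries never contribute to a maximum."""
    v = sii.to_numpy(dtype=float)
    n = len(v)
    out = np.full_like(v, np.nan)
    for i in range(n):
        for j in range(n):
            if np.isnan(v[i, j]):
                continue
            scope = np.concatenate([v[i, :], v[j, :], v[:, i], v[:, j]])
            m = np.nanmax(scope) if np.any(np.isfinite(scope)) else 0.0
            out[i, j] = 0.0 if m <= 0.0 else v[i, j] / m
    return pd.DataFrame(out, index=sii.index, columns=sii.columns)


def nii_from_decoys(decoy_sets, references=None, fir_factory=None,
                    config: Config = DEFAULTS) -> pd.DataFrame:
    """Convenience: II -> sII -> NII."""
    ii = build_ii_matrix(decoy_sets, references, fir_factory, config)
    return normalize(symmetrize(ii, config=config), config=config)


def predicted_partner(nii: pd.DataFrame, protein_id: str) -> str:
    """The protein with the highest NII against the query (ties resolve
    to the lexicographically smallest id, logged)."""
    if protein_id not in nii.index:
        raise KeyError(protein_id)
    row = nii.loc[protein_id].drop(labels=[protein_id], errors="ignore")
    if row.isna().all():
        raise ValueError(f"all entries masked for {protein_id}")
    top = row.max()
    winners = sorted(row.index[row == top])
    if len(winners) > 1:
        log.info("tie for predicted partner of %s: %s", protein_id, winners)
    return winners[0]
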
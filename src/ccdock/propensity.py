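"""Per-residue interaction propensities from cross-docking decoys.

Decoy energies of each pair are Boltzmann-normalised against the pair's
best energy, w(c) = exp(-(E(c) - E_min) / (R T)) at T = 300 K, and
conformations with w above a retention threshold (0.1 by default, i.e.
within R T ln 10 of the best energy) are kept.  The interaction
propensity ip(i) of a surface residue is the fraction of retained
conformations, pooled over all docked partners, whose interface contains
the residue.  Centred at the surface mean and scaled so that the maximum
is 1, it becomes the normalised interaction propensity (NIP): positive
for residues favoured at potential binding sites, negative for
disfavoured ones.  NIP combines with an evolutionary-conservation score
(the per-residue frequency of occurrence in predicted conserved patches,
the "JET" score) into a convex combination a*NIP + b*JET used to score
docked interfaces when no experimental interface is known.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import Config, DEFAULTS
from .docking import DecoySet, DockedConformation
from .reduced import InterfaceSpec, ResidueId
from .scoring import FIRRecord

log = logging.getLogger(__name__)


@dataclass
class BoltzmannWeights:
    """Per-conformation Boltzmann-normalised energies of one decoy set."""

    weights: np.ndarray
    e_min: float
    temperature: float
    gas_constant: float

    def retained_mask(self, min_weight: float) -> np.ndarray:
        if not 0.0 < min_weight <= 1.0:
            raise ValueError("min_weight must be in (0, 1]")
        return self.weights >= min_weight


def boltzmann_weights(decoys: DecoySet, temperature: float | None = None,
                      config: Config = DEFAULTS) -> BoltzmannWeights:
    """w(c) = exp(-(E(c) - E_min)/(R T)); the best conformation gets 1."""
    if len(decoys) == 0:
        raise ValueError("empty decoy set")
    T = config.temperature if temperature is None else temperature
    if T <= 0:
        raise ValueError("temperature must be positive")
    e = decoys.energies
    e_min = float(e.min())
    w = np.exp(-(e - e_min) / (config.gas_constant * T))
    return BoltzmannWeights(w, e_min, T, config.gas_constant)


def retain(decoys: DecoySet, min_weight: float | None = None,
           temperature: float | None = None,
           config: Config = DEFAULTS) -> list[DockedConformation]:
    """Conformations whose Boltzmann-normalised energy clears the
    retention threshold; always includes the best-energy conformation."""
    mw = config.boltzmann_min_weight if min_weight is None else min_weight
    bw = boltzmann_weights(decoys, temperature, config)
    mask = bw.retained_mask(mw)
    return [c for c, keep in zip(decoys.conformations, mask) if keep]


def interaction_propensity(protein_id: str,
                           decoy_sets: Iterable[DecoySet],
                           surface: frozenset[ResidueId],
                           min_weight: float | None = None,
                           config: Config = DEFAULTS) -> dict[ResidueId, float]:
    """ip per surface residue of ``protein_id``, pooled over all partners.

    Each decoy set must have ``protein_id`` as receptor or ligand; the
    residue counts use the matching interface side.
    """
    counts = {rid: 0 for rid in surface}
    total = 0
    for ds in decoy_sets:
        if ds.receptor_id == protein_id:
            side = "interface_receptor"
        elif ds.ligand_id == protein_id:
            side = "interface_ligand"
        else:
            raise ValueError(f"{protein_id} not in pair "
                             f"({ds.receptor_id}, {ds.ligand_id})")
        for c in retain(ds, min_weight, config=config):
            total += 1
            for rid in getattr(c, side):
                if rid in counts:
                    counts[rid] += 1
    if total == 0:
        raise ValueError("no retained conformations")
    return {rid: n / total for rid, n in counts.items()}


def normalize_nip(ip: Mapping[ResidueId, float],
                  surface: frozenset[ResidueId]) -> dict[ResidueId, float]:
    """NIP(i) = (ip(i) - mean) / (max - mean) over surface residues.

    The top residue maps to 1, mean-level residues to 0, below-mean to
    negative values.  A constant profile (max = mean) is degenerate and
    maps everything to 0 with a warning.
    """
    if not surface:
        raise ValueError("empty surface set")
    vals = np.array([ip[rid] for rid in surface])
    mean, vmax = vals.mean(), vals.max()
    if vmax - mean <= 1e-12:
        log.warning("constant interaction propensity: NIP set to 0")
        return {rid: 0.0 for rid in surface}
    return {rid: (ip[rid] - mean) / (vmax - mean) for rid in surface}


def nip_interface(nip: Mapping[ResidueId, float], protein_id: str,
                  cutoff: float | None = None,
                  config: Config = DEFAULTS) -> InterfaceSpec:
    """Predicted binding interface: residues with NIP >= cutoff (0 by
    default).  May be empty; downstream scoring masks such proteins."""
    c = config.nip_cutoff if cutoff is None else cutoff
    return InterfaceSpec(protein_id,
                         frozenset(rid for rid, v in nip.items() if v >= c),
                         provenance="predicted")


def jet_frequency(run_patches: Sequence[Iterable[ResidueId]],
                  surface: frozenset[ResidueId]) -> dict[ResidueId, float]:
    """Occurrence frequency of each surface residue over repeated
    conserved-patch predictions (10 runs in the standard protocol)."""
    if not run_patches:
        raise ValueError("need at least one run")
    n = len(run_patches)
    counts = {rid: 0 for rid in surface}
    for patch in run_patches:
        for rid in patch:
            if rid in counts:
                counts[rid] += 1
    return {rid: c / n for rid, c in counts.items()}


def combine(nip: Mapping[ResidueId, float], jet: Mapping[ResidueId, float],
            a: float | None = None, b: float | None = None,
            config: Config = DEFAULTS) -> dict[ResidueId, float]:
    """Combined residue score a*NIP + b*JET with a + b = 1, a, b >= 0."""
    a = config.combine_a if a is None else a
    b = config.combine_b if b is None else b
    if a < 0 or b < 0 or abs(a + b - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    return {rid: a * nip[rid] + b * jet.get(rid, 0.0) for rid in nip}


def fir_predicted(conf: DockedConformation,
                  scores_receptor: Mapping[ResidueId, float],
                  scores_ligand: Mapping[ResidueId, float],
                  tau: float | None = None,
                  config: Config = DEFAULTS) -> FIRRecord:
    """Score a docked interface from combined residue scores.

    Per side, the fraction of docked-interface residues whose combined
    score is >= tau; it substitutes the experimental-interface FIR in the
    interaction-index pipeline.
    """
    t = config.combined_score_min if tau is None else tau

    def side(docked: frozenset, scores: Mapping[ResidueId, float]) -> float:
        if not docked:
            return 0.0
        return sum(1 for rid in docked if scores.get(rid, -np.inf) >= t) / len(docked)

    r = side(conf.interface_receptor, scores_receptor)
    l = side(conf.interface_ligand, scores_ligand)
    from .scoring import _FIR_COMBINERS
    comb = _FIR_COMBINERS[config.fir_combiner]
    return FIRRecord(r, l, comb(r, l))


def residue_score_table(protein_id: str,
                        surface: frozenset[ResidueId],
                        ip: Mapping[ResidueId, float],
                        nip: Mapping[ResidueId, float],
                        jet: Mapping[ResidueId, float],
                        combined: Mapping[ResidueId, float]) -> pd.DataFrame:
    """Tidy per-residue score table (one row per surface residue)."""
    rows = [{"protein_id": protein_id, "chain": rid[0], "resnum": rid[1],
             "icode": rid[2], "ip": ip.get(rid, np.nan),
             "nip": nip.get(rid, np.nan), "jet": jet.get(rid, np.nan),
             "combined": combined.get(rid, np.nan)}
            for rid in sorted(surface)]
    return pd.DataFrame(rows)
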
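"""Coarse-grain interaction energy.

The pairwise energy of pseudo-atoms i (receptor) and j (ligand) at
distance r is a soft 8-6 Lennard-Jones term plus a Coulomb term with a
distance-dependent dielectric eps(r) = eps0 * r:

    E_ij = A_ij / r^8  -  B_ij / r^6  +  k_e * q_i * q_j / (eps0 * r^2)

in kcal/mol with r in Angstrom and charges in elementary-charge units.
A_ij and B_ij derive from a per-type equilibrium distance r* and well
depth e via A = 3 e r*^8, B = 4 e r*^6 (so that E(r*) = -e and
dE/dr(r*) = 0).  Only receptor-ligand (inter-molecular) terms count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .config import Config, DEFAULTS
from .reduced import ReducedProtein


def lj_ab(r_star: float, depth: float) -> tuple[float, float]:
    """8-6 coefficients with minimum at ``r_star`` and depth ``depth``."""
    return 3.0 * depth * r_star ** 8, 4.0 * depth * r_star ** 6


def lj_minimum_distance(a: float, b: float) -> float:
    """Distance of the 8-6 minimum: r* = sqrt(4A / 3B)."""
    if a <= 0 or b <= 0:
        raise ValueError("A and B must be positive to define a minimum")
    return np.sqrt(4.0 * a / (3.0 * b))


@dataclass
class EnergyParams:
    """Symmetric LJ parameter table plus the electrostatic model.

    ``lj_table`` maps an unordered type pair to (A, B).  Pairs absent from
    the table fall back to Lorentz-Berthelot-style combination of the
    per-type ``r_star``/``depth`` entries.
    """

    r_star: dict[str, float] = field(default_factory=dict)
    depth: dict[str, float] = field(default_factory=dict)
    lj_table: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    eps0: float = DEFAULTS.dielectric_eps0
    coulomb_constant: float = DEFAULTS.coulomb_constant
    default_r_star: float = 5.0
    default_depth: float = 0.1

    def pair_ab(self, t1: str, t2: str) -> tuple[float, float]:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        if key in self.lj_table:
            return self.lj_table[key]
        r1 = self.r_star.get(t1, self.default_r_star)
        r2 = self.r_star.get(t2, self.default_r_star)
        e1 = self.depth.get(t1, self.default_depth)
        e2 = self.depth.get(t2, self.default_depth)
        ab = lj_ab(0.5 * (r1 + r2), np.sqrt(e1 * e2))
        self.lj_table[key] = ab
        return ab

    def set_pair(self, t1: str, t2: str, r_star: float, depth: float) -> None:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        self.lj_table[key] = lj_ab(r_star, depth)

    def radius_of(self, lj_type: str) -> float:
        """Bead radius: half the equilibrium distance of the identical pair."""
        a, b = self.pair_ab(lj_type, lj_type)
        return 0.5 * lj_minimum_distance(a, b)

    def tables_for(self, types_r: Iterable[str], types_l: Iterable[str]
                   ) -> tuple[np.ndarray, np.ndarray]:
        """(A, B) matrices over a receptor-type x ligand-type product."""
        types_r, types_l = list(types_r), list(types_l)
        A = np.empty((len(types_r), len(types_l)))
        B = np.empty_like(A)
        cache: dict[tuple[str, str], tuple[float, float]] = {}
        for i, t1 in enumerate(types_r):
            for j, t2 in enumerate(types_l):
                key = (t1, t2) if t1 <= t2 else (t2, t1)
                if key not in cache:
                    cache[key] = self.pair_ab(t1, t2)
                A[i, j], B[i, j] = cache[key]
        return A, B

    @classmethod
    def synthetic_default(cls, eps0: float | None = None) -> "EnergyParams":
        """Single bead class with r* = 5.0 A and well depth 0.1 kcal/mol."""
        p = cls()
        if eps0 is not None:
            p.eps0 = eps0
        return p

    @classmethod
    def from_file(cls, path: str | Path) -> "EnergyParams":
        """Read a parameter file: ``type r_star depth`` lines and optional
        ``pair type1 type2 r_star depth`` override lines."""
        p = cls()
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                tok = line.split()
                if tok[0] == "pair":
                    p.set_pair(tok[1], tok[2], float(tok[3]), float(tok[4]))
                elif tok[0] == "eps0":
                    p.eps0 = float(tok[1])
                else:
                    p.r_star[tok[0]] = float(tok[1])
                    p.depth[tok[0]] = float(tok[2])
        return p


class PairPotential:
    """Precomputed tables for one receptor/ligand type assignment."""

    def __init__(self, receptor: ReducedProtein, ligand: ReducedProtein,
                 params: EnergyParams):
        self.params = params
        self.A, self.B = params.tables_for(receptor.lj_types, ligand.lj_types)
        self.QQ = (params.coulomb_constant / params.eps0
                   * np.outer(receptor.charges, ligand.charges))

    def energy(self, rec_xyz: np.ndarray, lig_xyz: np.ndarray) -> float:
        d = rec_xyz[:, None, :] - lig_xyz[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", d, d)
        if np.any(r2 == 0.0):
            raise ValueError("overlapping beads (zero distance)")
        inv2 = 1.0 / r2
        inv6 = inv2 * inv2 * inv2
        return float(np.sum(self.A * inv6 * inv2 - self.B * inv6 + self.QQ * inv2))

    def energy_gradient(self, rec_xyz: np.ndarray, lig_xyz: np.ndarray
                        ) -> tuple[float, np.ndarray]:
        """Energy and its gradient with respect to ligand bead positions."""
        d = rec_xyz[:, None, :] - lig_xyz[None, :, :]   # x_i - x_j
        r2 = np.einsum("ijk,ijk->ij", d, d)
        if np.any(r2 == 0.0):
            raise ValueError("overlapping beads (zero distance)")
        inv2 = 1.0 / r2
        inv6 = inv2 * inv2 * inv2
        e = float(np.sum(self.A * inv6 * inv2 - self.B * inv6 + self.QQ * inv2))
        # dE/d(r^2) summed into a per-pair factor
        dEdr2 = -4.0 * self.A * inv6 * inv2 * inv2 + 3.0 * self.B * inv6 * inv2 \
            - self.QQ * inv2 * inv2
        # d(r^2)/d(x_j) = -2 (x_i - x_j)
        grad = -2.0 * np.einsum("ij,ijk->jk", dEdr2, d)
        return e, grad


def pair_energy(receptor: ReducedProtein, ligand: ReducedProtein,
                params: EnergyParams,
                rec_xyz: np.ndarray | None = None,
                lig_xyz: np.ndarray | None = None) -> float:
    """Inter-molecular interaction energy (kcal/mol) of a posed pair."""
    pot = PairPotential(receptor, ligand, params)
    return pot.energy(receptor.coords if rec_xyz is None else np.asarray(rec_xyz),
                      ligand.coords if lig_xyz is None else np.asarray(lig_xyz))
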
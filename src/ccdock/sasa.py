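"""Solvent-accessible surface area by deterministic Shrake-Rupley sampling.

Each atom (or pseudo-atom) is expanded by the probe radius and covered
with a fixed spiral point set; a point is accessible when it lies outside
every neighbouring expanded sphere.  The point set is deterministic, so
areas are exactly reproducible for a fixed structure, probe and
resolution, and invariant under rigid motion up to the stated tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .config import Config, DEFAULTS
from .reduced import ReducedProtein, ResidueId

#: default radius (A) of a coarse-grain bead: half the single-class
#: equilibrium distance of the synthetic LJ parameter set.
DEFAULT_BEAD_RADIUS = 2.5

#: heavy-atom van der Waals radii (A) for atomic-structure accessibility
ATOM_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

#: reference accessible areas (A^2) of residue X in an extended Gly-X-Gly
#: tripeptide (theoretical maxima of Tien et al. 2013)
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@lru_cache(maxsize=8)
def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa_spheres(centers: np.ndarray, radii: np.ndarray,
                 probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Accessible area (A^2) of each sphere in a set.

    Parameters
    ----------
    centers : (N, 3) array
    radii : (N,) array of intrinsic radii; the probe radius is added.
    """
    centers = np.asarray(centers, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if centers.ndim != 2 or len(centers) == 0:
        raise ValueError("need a non-empty (N, 3) coordinate array")
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    ext = radii + probe
    pts = sphere_points(n_points)
    tree = cKDTree(centers)
    rmax = ext.max()
    areas = np.empty(len(centers))
    for i in range(len(centers)):
        surf = centers[i] + ext[i] * pts
        neighbours = [j for j in tree.query_ball_point(centers[i], ext[i] + rmax)
                      if j != i
                      and np.dot(centers[j] - centers[i], centers[j] - centers[i])
                      < (ext[i] + ext[j]) ** 2]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", surf - centers[j], surf - centers[j])
            accessible &= d2 > ext[j] ** 2
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.mean()
    return areas


@dataclass
class AccessibilityProfile:
    """Per-residue absolute and relative solvent accessibility."""

    protein_id: str
    residue_ids: list[ResidueId]
    area: np.ndarray           # absolute accessible area, A^2
    relative: np.ndarray       # fraction of the reference area, in [0, 1]
    probe_radius: float

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        self.relative = np.clip(np.asarray(self.relative, dtype=float), 0.0, 1.0)

    def as_dict(self) -> dict[ResidueId, float]:
        return dict(zip(self.residue_ids, self.relative))

    def area_dict(self) -> dict[ResidueId, float]:
        return dict(zip(self.residue_ids, self.area))


def bead_radii(protein: ReducedProtein,
               radius_of: Mapping[str, float] | Callable[[str], float] | None = None
               ) -> np.ndarray:
    """Radius per pseudo-atom, from a mapping/callable over LJ types."""
    if radius_of is None:
        return np.full(len(protein.pseudo_atoms), DEFAULT_BEAD_RADIUS)
    if callable(radius_of):
        return np.array([radius_of(t) for t in protein.lj_types])
    return np.array([radius_of.get(t, DEFAULT_BEAD_RADIUS) for t in protein.lj_types])


def accessibility(protein: ReducedProtein,
                  probe: float | None = None,
                  coords: np.ndarray | None = None,
                  radius_of=None,
                  config: Config = DEFAULTS) -> AccessibilityProfile:
    """Residue accessibility of a reduced model.

    The relative accessibility of a residue is its accessible area divided
    by the area its beads would expose in isolation, the coarse-grain
    analogue of the extended-tripeptide reference.
    """
    probe = config.probe_radius if probe is None else probe
    xyz = protein.coords if coords is None else np.asarray(coords, dtype=float)
    radii = bead_radii(protein, radius_of)
    areas = sasa_spheres(xyz, radii, probe, config.sasa_points)
    iso = 4.0 * np.pi * (radii + probe) ** 2
    rids = protein.residue_ids
    res_area = np.empty(len(rids))
    res_rel = np.empty(len(rids))
    for k, rid in enumerate(rids):
        idx = protein.residue_index[rid]
        res_area[k] = areas[idx].sum()
        res_rel[k] = areas[idx].sum() / iso[idx].sum()
    return AccessibilityProfile(protein.protein_id, rids, res_area, res_rel, probe)


def atomic_accessibility(structure, probe: float = 1.4,
                         n_points: int = 960) -> AccessibilityProfile:
    """Residue accessibility of an atomic structure (heavy atoms only).

    Relative accessibility uses extended-tripeptide reference areas.
    """
    model = next(structure.get_models()) if hasattr(structure, "get_models") else structure
    centers, radii, owner, resnames, rids = [], [], [], {}, []
    for chain in model:
        for residue in chain:
            het, seq, icode = residue.get_id()
            if het.strip():
                continue
            rid = (chain.id, seq, icode.strip() or "")
            rids.append(rid)
            resnames[rid] = residue.get_resname()
            for atom in residue.get_unpacked_list():
                elem = atom.element
                if elem == "H":
                    continue
                centers.append(atom.get_coord())
                radii.append(ATOM_RADII.get(elem, 1.7))
                owner.append(rid)
    if not centers:
        raise ValueError("structure has no heavy atoms")
    areas = sasa_spheres(np.asarray(centers), np.asarray(radii), probe, n_points)
    res_area = {rid: 0.0 for rid in rids}
    for a, rid in zip(areas, owner):
        res_area[rid] += a
    area = np.array([res_area[rid] for rid in rids])
    ref = np.array([MAX_ASA.get(resnames[rid], 200.0) for rid in rids])
    pid = getattr(structure, "id", "protein")
    return AccessibilityProfile(pid, rids, area, area / ref, probe)


def surface_residues(profile: AccessibilityProfile,
                     threshold: float | None = None,
                     config: Config = DEFAULTS) -> frozenset[ResidueId]:
    """Residues with relative accessibility >= threshold."""
    t = config.surface_rel_acc_min if threshold is None else threshold
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return frozenset(rid for rid, rel in zip(profile.residue_ids, profile.relative)
                     if rel >= t)


def interface_residues(components: Sequence[tuple[ReducedProtein, np.ndarray | None]],
                       delta_threshold: float | None = None,
                       probe: float | None = None,
                       radius_of=None,
                       config: Config = DEFAULTS) -> dict[str, frozenset[ResidueId]]:
    """Interface residues of each component of a complex.

    A residue belongs to the interface when its accessible area in the
    assembled complex drops by at least ``delta_threshold`` (A^2) relative
    to the isolated component at the same pose.

    Parameters
    ----------
    components : sequence of (ReducedProtein, coords or None)
        Posed rigid bodies; ``None`` uses the stored coordinates.
    """
    delta = config.interface_dsasa_min if delta_threshold is None else delta_threshold
    probe = config.probe_radius if probe is None else probe
    ids = [p.protein_id for p, _ in components]
    if len(set(ids)) != len(ids):
        raise ValueError("components must have distinct protein ids")
    posed = [(p, p.coords if xyz is None else np.asarray(xyz, dtype=float))
             for p, xyz in components]
    all_xyz = np.vstack([xyz for _, xyz in posed])
    all_radii = np.concatenate([bead_radii(p, radius_of) for p, _ in posed])
    bound = sasa_spheres(all_xyz, all_radii, probe, config.sasa_points)
    out: dict[str, frozenset[ResidueId]] = {}
    offset = 0
    for p, xyz in posed:
        n = len(p.pseudo_atoms)
        free = sasa_spheres(xyz, bead_radii(p, radius_of), probe, config.sasa_points)
        drop_atom = free - bound[offset:offset + n]
        iface = []
        for rid, idx in p.residue_index.items():
            if drop_atom[idx].sum() >= delta:
                iface.append(rid)
        out[p.protein_id] = frozenset(iface)
        offset += n
    return out


def contact_interface(receptor: ReducedProtein, rec_xyz: np.ndarray,
                      ligand: ReducedProtein, lig_xyz: np.ndarray,
                      cutoff: float) -> tuple[frozenset[ResidueId], frozenset[ResidueId]]:
    """Fast distance-based interface: residues with any cross bead pair
    closer than ``cutoff`` (A)."""
    d2 = np.sum((rec_xyz[:, None, :] - lig_xyz[None, :, :]) ** 2, axis=-1)
    close = d2 < cutoff * cutoff
    rec_hits = close.any(axis=1)
    lig_hits = close.any(axis=0)
    rec_res = frozenset(rid for rid, idx in receptor.residue_index.items()
                        if rec_hits[idx].any())
    lig_res = frozenset(rid for rid, idx in ligand.residue_index.items()
                        if lig_hits[idx].any())
    return rec_res, lig_res
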
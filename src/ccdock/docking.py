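"""Systematic rigid-body docking over the receptor surface.

The receptor stays fixed.  Start axes are laid on the sphere of
directions from the receptor centre of mass with a Korobov lattice, at a
surface density of one position per 10 A^2 by default; each axis carries
a batch of seeded random ligand orientations.  The ligand is slid in
along the axis until no bead pair is closer than the clearance (6 A by
default) and its six rigid-body degrees of freedom are then energy
minimised with an analytic-gradient quasi-Newton scheme, under a harmonic
restraint keeping the ligand centre of mass near the start axis.  The
reported energy of a conformation excludes the restraint term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation

from .config import Config, DEFAULTS
from .energy import EnergyParams, PairPotential
from .reduced import InterfaceSpec, ReducedProtein, ResidueId
from .sasa import accessibility, contact_interface, interface_residues

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- rotations

def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


def rotation_jacobian(omega: np.ndarray) -> np.ndarray:
    """d(R(omega))/d(omega_i) for the rotation-vector parametrisation.

    Returns a (3, 3, 3) array J with J[i] = dR/d(omega_i) (exact closed
    form; reduces to the skew generators at omega = 0).
    """
    omega = np.asarray(omega, dtype=float)
    n2 = float(omega @ omega)
    J = np.empty((3, 3, 3))
    if n2 < 1e-18:
        for i in range(3):
            e = np.zeros(3)
            e[i] = 1.0
            J[i] = _skew(e)
        return J
    R = Rotation.from_rotvec(omega).as_matrix()
    I = np.eye(3)
    for i in range(3):
        e = np.zeros(3)
        e[i] = 1.0
        v = np.cross(omega, (I - R) @ e)
        J[i] = (omega[i] * _skew(omega) + _skew(v)) @ R / n2
    return J


def axis_from_angles(theta: float, phi: float) -> np.ndarray:
    """Unit vector from the two Euler angles of a start direction."""
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def axis_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``u`` to an orthonormal frame."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(u, e1)


def korobov_angles(n: int, generator: int) -> np.ndarray:
    """(theta, phi) pairs of an n-point Korobov lattice, mapped equal-area
    onto the sphere (theta via arccos of a uniform variate)."""
    k = np.arange(n, dtype=float)
    u = (k + 0.5) / n
    v = np.mod(generator * k, n) / n
    return np.column_stack([np.arccos(1.0 - 2.0 * u), 2.0 * np.pi * v])


# ---------------------------------------------------------------- data types

@dataclass
class StartConfiguration:
    theta: float
    phi: float
    orientation: np.ndarray  # unit quaternion, scalar-last (x, y, z, w)
    separation: float | None = None
    start_id: int = 0

    def __post_init__(self) -> None:
        q = np.asarray(self.orientation, dtype=float)
        self.orientation = q / np.linalg.norm(q)
        if not (0.0 <= self.theta <= np.pi):
            raise ValueError("theta out of [0, pi]")
        self.phi = float(np.mod(self.phi, 2.0 * np.pi))

    @property
    def axis(self) -> np.ndarray:
        return axis_from_angles(self.theta, self.phi)


@dataclass
class DockedConformation:
    start: StartConfiguration
    rotation: np.ndarray        # final ligand rotation, quaternion (x, y, z, w)
    center: np.ndarray          # final ligand centre of mass
    energy: float               # interaction energy, restraint excluded
    interface_receptor: frozenset[ResidueId] = frozenset()
    interface_ligand: frozenset[ResidueId] = frozenset()
    converged: bool = True
    conf_id: int = 0

    def ligand_coords(self, ligand: ReducedProtein) -> np.ndarray:
        R = Rotation.from_quat(self.rotation).as_matrix()
        c = ligand.center()
        return (ligand.coords - c) @ R.T + self.center


@dataclass
class DecoySet:
    receptor_id: str
    ligand_id: str
    conformations: list[DockedConformation]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.conformations)

    @property
    def energies(self) -> np.ndarray:
        return np.array([c.energy for c in self.conformations])

    def best(self) -> DockedConformation:
        return min(self.conformations, key=lambda c: (c.energy, c.conf_id))


# ---------------------------------------------------------------- operations

def generate_starts(receptor: ReducedProtein,
                    density: float | None = None,
                    n_orientations: int | None = None,
                    generator: int | None = None,
                    seed: int = 0,
                    radius_of=None,
                    n_directions: int | None = None,
                    config: Config = DEFAULTS) -> list[StartConfiguration]:
    """Start configurations covering the receptor surface.

    The number of axis directions is round(surface area x density) unless
    given explicitly; each direction carries ``n_orientations`` ligand
    orientations drawn deterministically from ``seed``.
    """
    density = config.start_density if density is None else density
    n_orient = config.n_orientations if n_orientations is None else n_orientations
    gen = config.korobov_generator if generator is None else generator
    if density <= 0 or n_orient < 1:
        raise ValueError("density must be > 0 and n_orientations >= 1")
    if n_directions is None:
        prof = accessibility(receptor, radius_of=radius_of, config=config)
        n_directions = max(1, int(round(prof.area.sum() * density)))
    angles = korobov_angles(n_directions, gen)
    rng = np.random.default_rng(seed)
    quats = Rotation.random(n_orient, random_state=rng).as_quat()
    if quats.ndim == 1:
        quats = quats[None, :]
    starts = []
    sid = 0
    for theta, phi in angles:
        for q in quats:
            starts.append(StartConfiguration(theta, phi, q, start_id=sid))
            sid += 1
    return starts


def initial_placement(receptor: ReducedProtein, ligand: ReducedProtein,
                      start: StartConfiguration,
                      clearance: float | None = None,
                      config: Config = DEFAULTS) -> tuple[np.ndarray, float]:
    """Slide the ligand in along the start axis.

    Returns the posed ligand coordinates and the centre separation: the
    smallest distance along the axis at which no receptor-ligand bead
    pair is closer than ``clearance`` (exact, from the per-pair quadratic
    constraint).
    """
    c = config.clearance if clearance is None else clearance
    if c <= 0:
        raise ValueError("clearance must be positive")
    u = start.axis
    R = Rotation.from_quat(start.orientation).as_matrix()
    b = (ligand.coords - ligand.center()) @ R.T            # ligand beads about centre
    a = receptor.coords - receptor.center()                # receptor beads about centre
    # pair constraint: |w + s u| >= c with w = b_j - a_i
    w = b[None, :, :] - a[:, None, :]
    wu = w @ u
    disc = wu * wu - np.einsum("ijk,ijk->ij", w, w) + c * c
    viol = disc > 0.0
    s = 0.0
    if np.any(viol):
        s = float(np.max(-wu[viol] + np.sqrt(disc[viol])))
    s = max(s, 0.0)
    xyz = b + receptor.center() + s * u
    return xyz, s


class _PoseProblem:
    """Rigid-body pose energy over (rotation vector, axial, lateral) dofs."""

    def __init__(self, receptor: ReducedProtein, ligand: ReducedProtein,
                 start: StartConfiguration, separation: float,
                 params: EnergyParams, config: Config):
        self.pot = PairPotential(receptor, ligand, params)
        self.rec_xyz = receptor.coords
        self.u = start.axis
        self.e1, self.e2 = axis_frame(self.u)
        self.R0 = Rotation.from_quat(start.orientation).as_matrix()
        self.v = (ligand.coords - ligand.center()) @ self.R0.T
        self.p0 = receptor.center() + separation * self.u
        self.k = config.restraint_k

    def pose(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        omega, t = z[:3], z[3:]
        R = Rotation.from_rotvec(omega).as_matrix()
        p = self.p0 + t[0] * self.u + t[1] * self.e1 + t[2] * self.e2
        return self.v @ R.T + p, R, p

    def __call__(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        xyz, R, p = self.pose(z)
        e, g = self.pot.energy_gradient(self.rec_xyz, xyz)
        G = g.sum(axis=0)
        grad = np.empty(6)
        J = rotation_jacobian(z[:3])
        M = self.v.T @ g                     # (3, 3): sum_j v_j g_j^T
        for i in range(3):
            grad[i] = float(np.sum(J[i] * M.T))
        grad[3] = G @ self.u
        grad[4] = G @ self.e1 + self.k * z[4]
        grad[5] = G @ self.e2 + self.k * z[5]
        e_total = e + 0.5 * self.k * (z[4] ** 2 + z[5] ** 2)
        return e_total, grad

    def interaction_energy(self, z: np.ndarray) -> float:
        xyz, _, _ = self.pose(z)
        return self.pot.energy(self.rec_xyz, xyz)


def _docked_interfaces(receptor: ReducedProtein, ligand: ReducedProtein,
                       lig_xyz: np.ndarray, params: EnergyParams,
                       config: Config) -> tuple[frozenset, frozenset]:
    if config.interface_mode == "contact":
        return contact_interface(receptor, receptor.coords, ligand, lig_xyz,
                                 config.contact_cutoff)
    both = interface_residues([(receptor, None), (ligand, lig_xyz)],
                              radius_of=params.radius_of, config=config)
    return both[receptor.protein_id], both[ligand.protein_id]


def minimize_pose(receptor: ReducedProtein, ligand: ReducedProtein,
                  start: StartConfiguration, params: EnergyParams,
                  config: Config = DEFAULTS,
                  compute_interfaces: bool = True) -> DockedConformation:
    """Locally minimise the interaction energy of one start configuration."""
    xyz0, sep = initial_placement(receptor, ligand, start, config=config)
    start.separation = sep
    prob = _PoseProblem(receptor, ligand, start, sep, params, config)
    res = _scipy_minimize(prob, np.zeros(6), jac=True, method="L-BFGS-B",
                          options={"maxiter": config.minimizer_maxiter,
                                   "gtol": config.minimizer_gtol})
    z = res.x
    e = prob.interaction_energy(z)
    if not np.isfinite(e):
        raise FloatingPointError("non-finite energy after minimisation")
    lig_xyz, R, p = prob.pose(z)
    quat = Rotation.from_matrix(R @ prob.R0).as_quat()
    iface_r: frozenset = frozenset()
    iface_l: frozenset = frozenset()
    if compute_interfaces:
        iface_r, iface_l = _docked_interfaces(receptor, ligand, lig_xyz,
                                              params, config)
    return DockedConformation(start, quat, p, e, iface_r, iface_l,
                              converged=bool(res.success), conf_id=start.start_id)


def tube_filter(receptor: ReducedProtein, predicted_site: InterfaceSpec | None,
                start: StartConfiguration, radius: float | None = None,
                config: Config = DEFAULTS) -> bool:
    """Keep a start axis only if it passes near the predicted binding site.

    A site residue (collapsed to the mean of its coordinates) supports the
    start when it lies within ``radius`` of the receptor-centre-to-ligand
    axis and on the ligand side of the receptor centre.  An empty site
    retains nothing (the degenerate no-prediction case), with a warning.
    """
    r = config.tube_radius if radius is None else radius
    if predicted_site is None or len(predicted_site.residues) == 0:
        log.warning("empty predicted site for %s: dropping all starts",
                    receptor.protein_id)
        return False
    u = start.axis
    c = receptor.center()
    for rid in predicted_site.residues:
        if rid not in receptor.residue_index:
            continue
        d = receptor.residue_point(rid) - c
        along = d @ u
        if along <= 0.0:
            continue
        perp2 = d @ d - along * along
        if perp2 <= r * r:
            return True
    return False


def dock_pair(receptor: ReducedProtein, ligand: ReducedProtein,
              params: EnergyParams, config: Config = DEFAULTS,
              seed: int = 0,
              starts: Sequence[StartConfiguration] | None = None,
              density: float | None = None,
              n_orientations: int | None = None,
              n_directions: int | None = None,
              predicted_site: InterfaceSpec | None = None,
              restrict: bool = False,
              tube_radius: float | None = None,
              best_per_cell: bool = False,
              keep_best: int | None = None) -> DecoySet:
    """Systematic docking of one ordered receptor-ligand pair.

    Set ``restrict=True`` to drop start axes that do not pass near
    ``predicted_site`` (tube restriction).  ``best_per_cell`` keeps only
    the best-energy conformation per (theta, phi) direction;
    ``keep_best`` truncates the set to the N lowest energies.
    """
    if starts is None:
        starts = generate_starts(receptor, density=density,
                                 n_orientations=n_orientations,
                                 n_directions=n_directions, seed=seed,
                                 radius_of=params.radius_of, config=config)
    n_total = len(starts)
    if restrict:
        starts = [s for s in starts
                  if tube_filter(receptor, predicted_site, s, tube_radius, config)]
    confs: list[DockedConformation] = []
    n_failed = 0
    for s in starts:
        try:
            confs.append(minimize_pose(receptor, ligand, s, params, config))
        except (FloatingPointError, ValueError) as exc:
            n_failed += 1
            log.warning("start %d failed: %s", s.start_id, exc)
    if not confs:
        raise RuntimeError(
            f"all {len(starts)} starts failed for "
            f"{receptor.protein_id}->{ligand.protein_id}")
    if best_per_cell:
        by_cell: dict[tuple[float, float], DockedConformation] = {}
        for c in confs:
            key = (c.start.theta, c.start.phi)
            if key not in by_cell or (c.energy, c.conf_id) < \
                    (by_cell[key].energy, by_cell[key].conf_id):
                by_cell[key] = c
        confs = sorted(by_cell.values(), key=lambda c: c.conf_id)
    if keep_best is not None and len(confs) > keep_best:
        confs = sorted(confs, key=lambda c: (c.energy, c.conf_id))[:keep_best]
        confs = sorted(confs, key=lambda c: c.conf_id)
    meta = {"seed": seed, "n_starts": n_total, "n_retained_starts": len(starts),
            "n_failed": n_failed, "restricted": bool(restrict),
            "interface_mode": config.interface_mode}
    return DecoySet(receptor.protein_id, ligand.protein_id, confs, meta)


def energy_map(decoys: DecoySet, n_theta: int = 12, n_phi: int = 24) -> np.ndarray:
    """2-D (theta, phi) map of the per-cell minimum energy.

    Theta bins are equal-area (uniform in cos theta); empty cells are NaN.
    """
    if len(decoys) == 0:
        raise ValueError("empty decoy set")
    grid = np.full((n_theta, n_phi), np.nan)
    for c in decoys.conformations:
        it = min(int((1.0 - np.cos(c.start.theta)) / 2.0 * n_theta), n_theta - 1)
        ip = min(int(c.start.phi / (2.0 * np.pi) * n_phi), n_phi - 1)
        if np.isnan(grid[it, ip]) or c.energy < grid[it, ip]:
            grid[it, ip] = c.energy
    return grid
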
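"""Deterministic synthetic inputs for desk-scale cross-docking studies.

Three generators, all pure functions of their seed:

* toy proteins -- self-avoiding bead-chain structures with a planted
  surface patch acting as the "true" interface;
* decoy collections -- cross-docking decoy sets for every ordered pair
  of a synthetic protein set, where native pairs are planted with lower
  mean energies and interfaces hitting the planted patches with a given
  signal probability, while non-native pairs draw background energies
  and uniform-random interfaces;
* synthetic conservation scores -- repeated-run interface patches
  enriched at the planted interfaces, mimicking the output format of an
  evolutionary conservation tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .benchmark import Benchmark
from .config import Config, DEFAULTS
from .docking import DecoySet, DockedConformation, StartConfiguration
from .energy import EnergyParams
from .evaluation import GoldStandard
from .reduced import InterfaceSpec, PseudoAtom, ReducedProtein, ResidueId


@dataclass
class ToySpec:
    """An arc-shaped bead-chain protein with a contiguous planted patch.

    The backbone bends along a circular arc whose convex side faces +x;
    the patch sits at the apex, so a partner docked onto it contacts only
    the central residues and docked interfaces stay localised.
    """

    n_residues: int = 12
    patch: tuple[int, int] = (4, 8)     # half-open residue-index range (0-based)
    spacing: float = 4.0                # A between consecutive backbone beads
    side_length: float = 2.0            # backbone-to-side-bead distance, A
    arc_radius: float = 15.0            # curvature radius of the backbone, A
    seed: int = 0
    protein_id: str = "toy"

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")
        lo, hi = self.patch
        if not (0 <= lo < hi <= self.n_residues):
            raise ValueError("patch out of sequence bounds")

    @property
    def patch_residues(self) -> frozenset[ResidueId]:
        return frozenset(("A", i + 1, "") for i in range(*self.patch))


def make_toy_protein(spec: ToySpec) -> tuple[object, ReducedProtein]:
    """Build the atomic structure and reduced model of a toy protein.

    One Ala-like residue per backbone position along the arc.  Patch
    side beads point along the outward surface normal (the +x face at
    the apex); other side beads point away from it with seeded jitter.
    All residues are surface-exposed.
    """
    from Bio.PDB.StructureBuilder import StructureBuilder

    rng = np.random.default_rng(spec.seed)
    sb = StructureBuilder()
    sb.init_structure(spec.protein_id)
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    lo, hi = spec.patch
    serial = 1
    dphi = spec.spacing / spec.arc_radius
    mid = 0.5 * (spec.n_residues - 1)
    for i in range(spec.n_residues):
        sb.init_residue("ALA", " ", i + 1, " ")
        phi = (i - mid) * dphi
        # apex at the origin, arc curving away from +x
        ca = spec.arc_radius * np.array([np.cos(phi) - 1.0, 0.0, np.sin(phi)])
        outward = np.array([np.cos(phi), 0.0, np.sin(phi)])
        if lo <= i < hi:
            direction = outward
        else:
            ang = rng.uniform(0.5 * np.pi, 1.5 * np.pi)  # away from outward
            lateral = np.array([0.0, 1.0, 0.0])
            direction = np.cos(ang) * outward + np.sin(ang) * lateral
        cb = ca + spec.side_length * direction
        sb.init_atom("CA", ca, 0.0, 1.0, " ", " CA ", serial, "C")
        serial += 1
        sb.init_atom("CB", cb, 0.0, 1.0, " ", " CB ", serial, "C")
        serial += 1
    structure = sb.get_structure()

    from .reduced import build_reduced

    reduced = build_reduced(structure, protein_id=spec.protein_id)
    # self-avoidance check on backbone beads
    bb = np.array([a.position for a in reduced.pseudo_atoms
                   if a.role == "backbone"])
    d = np.linalg.norm(bb[:, None] - bb[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < 0.5 * spec.spacing:
        raise RuntimeError("toy chain self-intersects")
    return structure, reduced


def plant_patch_types(protein: ReducedProtein,
                      patch: frozenset[ResidueId],
                      type_name: str) -> ReducedProtein:
    """Relabel the side-chain beads of patch residues with a dedicated LJ
    type so a parameter table can make two patches complementary."""
    beads = []
    for a in protein.pseudo_atoms:
        if a.residue_id in patch and a.role != "backbone":
            beads.append(PseudoAtom(a.residue_id, a.role, a.position,
                                    type_name, a.charge))
        else:
            beads.append(a)
    return ReducedProtein(protein.protein_id, beads, protein.residue_names)


def complementary_params(patch_pairs: Sequence[tuple[str, str]],
                         r_star: float = 5.0,
                         base_depth: float = 0.01,
                         patch_depth: float = 2.0,
                         eps0: float | None = None) -> EnergyParams:
    """Synthetic LJ table where each listed patch-type pair attracts
    strongly and everything else interacts weakly (single bead class,
    r* = 5 A)."""
    params = EnergyParams(default_r_star=r_star, default_depth=base_depth)
    if eps0 is not None:
        params.eps0 = eps0
    for t1, t2 in patch_pairs:
        params.set_pair(t1, t2, r_star, patch_depth)
        # identical-type pairs keep the weak default so radii stay uniform
        params.set_pair(t1, t1, r_star, base_depth)
        params.set_pair(t2, t2, r_star, base_depth)
    return params


# ----------------------------------------------------------- decoy plants

@dataclass
class SyntheticDecoyConfig:
    """Conditions of a planted decoy collection.

    Native pairs draw conformation energies from N(mu_native, sigma) with
    interfaces covering the planted patches with probability
    ``p_signal``; all other conformations draw N(mu_background, sigma)
    energies and uniform-random surface interfaces.  Optional promiscuous
    and inert proteins receive native-like energies against everyone or
    background-only interactions, enabling three-population tests.
    """

    n_complexes: int = 4
    n_residues: int = 30
    patch_size: int = 6
    n_conformations: int = 2000
    mu_native: float = -20.0
    mu_background: float = -10.0
    sigma: float = 2.0
    p_signal: float = 0.9
    #: probability that a background conformation's interface sits on the
    #: planted patch of each side: how strongly arbitrary-partner decoys
    #: concentrate on the sticky site
    p_site: float = 0.0
    promiscuous: str | None = None      # protein id with native-like energies vs all
    inert: str | None = None            # protein id with weak energies vs all
    mu_inert: float = -5.0
    seed: int = 0


@dataclass
class DecoyCollection:
    benchmark: Benchmark
    decoy_sets: dict[tuple[str, str], DecoySet]
    surfaces: dict[str, frozenset[ResidueId]]
    patches: dict[str, InterfaceSpec]
    gold: GoldStandard
    config: SyntheticDecoyConfig


_DUMMY_START = StartConfiguration(0.0, 0.0, np.array([0.0, 0.0, 0.0, 1.0]))


def _random_interface(rng: np.random.Generator,
                      residues: list[ResidueId], size: int) -> frozenset[ResidueId]:
    idx = rng.choice(len(residues), size=min(size, len(residues)), replace=False)
    return frozenset(residues[i] for i in idx)


def make_decoy_collection(cfg: SyntheticDecoyConfig) -> DecoyCollection:
    """Planted cross-docking decoy collection over all ordered pairs."""
    from .benchmark import synthetic_benchmark

    bench = synthetic_benchmark(cfg.n_complexes)
    proteins = bench.proteins
    partner = {}
    for r, l in bench.pairs:
        partner[r], partner[l] = l, r

    residues = [("A", i + 1, "") for i in range(cfg.n_residues)]
    surfaces = {p: frozenset(residues) for p in proteins}
    rng0 = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    patches = {}
    for p in proteins:
        start = int(rng0.integers(0, cfg.n_residues - cfg.patch_size + 1))
        patches[p] = InterfaceSpec(
            p, frozenset(residues[start:start + cfg.patch_size]))

    decoy_sets: dict[tuple[str, str], DecoySet] = {}
    for k, (rec, lig) in enumerate(((r, l) for r in proteins for l in proteins
                                    if r != l)):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1, k]))
        native = partner[rec] == lig
        if cfg.promiscuous in (rec, lig):
            native = True
        mu = cfg.mu_native if native else cfg.mu_background
        if cfg.inert in (rec, lig):
            native, mu = False, cfg.mu_inert
        confs = []
        for c in range(cfg.n_conformations):
            planted = native and rng.random() < cfg.p_signal
            if planted:
                e = rng.normal(mu, cfg.sigma)
                ir = patches[rec].residues
                il = patches[lig].residues
            else:
                e = rng.normal(cfg.mu_background if native else mu, cfg.sigma)
                ir = patches[rec].residues if rng.random() < cfg.p_site \
                    else _random_interface(rng, residues, cfg.patch_size)
                il = patches[lig].residues if rng.random() < cfg.p_site \
                    else _random_interface(rng, residues, cfg.patch_size)
            confs.append(DockedConformation(_DUMMY_START, _DUMMY_START.orientation,
                                            np.zeros(3), float(e), ir, il,
                                            conf_id=c))
        decoy_sets[(rec, lig)] = DecoySet(rec, lig, confs,
                                          {"synthetic": True, "native": native})
    return DecoyCollection(bench, decoy_sets, surfaces, patches,
                           bench.gold_standard(), cfg)


def make_planted_nii(n_complexes: int, noise: float = 0.05, seed: int = 0,
                     mu_native: float = 0.9, mu_background: float = 0.3,
                     promiscuous: str | None = None,
                     inert: str | None = None,
                     inert_vs: str | None = None):
    """A planted symmetric NII-like matrix over a synthetic benchmark.

    Native pairs score near ``mu_native``, background pairs near
    ``mu_background`` (Gaussian noise, clipped to [0, 1]).  An optional
    promiscuous protein scores native-like against everyone.  An optional
    inert protein is planted to never compete with a designated query
    (``inert_vs``, the first receptor by default): their mutual score sits
    far below the inert protein's other interactions, so the pair ranks
    last in both of its rows.  Returns (matrix, benchmark).
    """
    import pandas as pd

    from .benchmark import synthetic_benchmark

    bench = synthetic_benchmark(n_complexes)
    proteins = bench.proteins
    native = {frozenset(p) for p in bench.pairs}
    if inert is not None and inert_vs is None:
        inert_vs = bench.pairs[0][0]
    rng = np.random.default_rng(seed)
    n = len(proteins)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = proteins[i], proteins[j]
            mu = mu_native if frozenset((a, b)) in native else mu_background
            if promiscuous in (a, b):
                mu = mu_native
            v = float(np.clip(rng.normal(mu, noise), 0.0, 1.0))
            if inert is not None and {a, b} == {inert, inert_vs}:
                v = 0.01
            m[i, j] = m[j, i] = v
    return pd.DataFrame(m, index=proteins, columns=proteins), bench


def make_synthetic_jet(interfaces: Mapping[str, InterfaceSpec],
                       surfaces: Mapping[str, frozenset[ResidueId]],
                       enrichment: float = 0.9,
                       n_runs: int = 10,
                       seed: int = 0) -> dict[str, list[frozenset[ResidueId]]]:
    """Per-run conserved-patch predictions enriched at the interfaces.

    Each run's patch contains every interface residue with probability
    ``enrichment`` and each non-interface surface residue with
    probability (1 - enrichment) scaled so the expected patch size stays
    near the interface size.
    """
    if not 0.0 <= enrichment <= 1.0:
        raise ValueError("enrichment must be in [0, 1]")
    out: dict[str, list[frozenset[ResidueId]]] = {}
    for j, pid in enumerate(sorted(interfaces)):
        iface = interfaces[pid].residues
        background = sorted(surfaces[pid] - iface)
        p_bg = (1.0 - enrichment) * len(iface) / max(len(background), 1)
        rng = np.random.default_rng(np.random.SeedSequence([seed, j]))
        runs = []
        for _ in range(n_runs):
            patch = {rid for rid in sorted(iface) if rng.random() < enrichment}
            patch |= {rid for rid in background if rng.random() < p_bg}
            runs.append(frozenset(patch))
        out[pid] = runs
    return out
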
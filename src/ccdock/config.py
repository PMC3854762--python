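"""Layered configuration for the cross-docking pipeline.

Every tunable constant of the method lives here with its unit and default,
so that a run can be reproduced from the effective configuration alone.
Values can be overridden from a YAML file and/or keyword arguments; the
effective configuration is echoed into output headers by the I/O layer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class Config:
    """Pipeline-wide settings.

    Attributes
    ----------
    surface_rel_acc_min : float
        Minimum relative solvent accessibility (fraction of the reference
        accessible area) for a residue to count as a surface residue.
    interface_dsasa_min : float
        Minimum decrease in accessible surface area (A^2) upon complex
        formation for a residue to count as an interface residue.
    probe_radius : float
        Solvent probe radius in Angstrom used for all accessibility
        calculations.
    sasa_points : int
        Number of deterministic sphere sample points per atom in the
        Shrake-Rupley accessibility calculation.
    dielectric_eps0 : float
        Slope of the distance-dependent dielectric eps(r) = eps0 * r
        (dimensionless per Angstrom).
    coulomb_constant : float
        Electrostatic conversion constant in kcal*A/(mol*e^2).
    clearance : float
        Minimum initial receptor-ligand bead separation (A) when placing
        the ligand on a start axis.
    start_density : float
        Docking start-axis density over the receptor surface, in
        positions per A^2 of accessible surface.
    n_orientations : int
        Number of ligand orientations generated per start axis.
    korobov_generator : int
        Generator of the Korobov lattice used to lay start axes uniformly
        over the sphere of directions.
    restraint_k : float
        Harmonic force constant (kcal/(mol*A^2)) keeping the ligand centre
        of mass near its start axis during minimisation.
    minimizer_maxiter : int
        Iteration cap for each rigid-body energy minimisation.
    minimizer_gtol : float
        Gradient-norm convergence tolerance of the minimiser.
    contact_cutoff : float
        Bead-bead distance (A) below which two residues are considered in
        contact when the fast distance-based interface mode is active.
    interface_mode : str
        'contact' (distance cutoff) or 'dsasa' (accessibility change) for
        interfaces of docked conformations.
    keep_best : int | None
        If set, a decoy set is truncated to this many best-energy
        conformations.
    tube_radius : float
        Radius (A) of the axial tube used to restrict docking starts to
        the neighbourhood of predicted binding-site residues.
    temperature : float
        Temperature (K) of the Boltzmann weighting of decoy energies.
    gas_constant : float
        Gas constant in kcal/(mol*K), matching the energy units.
    boltzmann_min_weight : float
        Retention threshold on Boltzmann-normalised energies; 0.1 keeps
        conformations within R*T*ln(10) (~1.4 kcal/mol at 300 K) of the
        best one.
    nip_cutoff : float
        Normalised interaction propensity above which a residue is
        predicted to belong to the binding interface.
    combine_a, combine_b : float
        Convex weights of the docking (NIP) and evolutionary (JET) terms
        in the combined residue score; they must sum to 1.
    combine_a_ab, combine_b_ab : float
        Weight profile for antibody/antigen proteins, where the
        conservation signal is weaker and the JET weight is lowered.
    combined_score_min : float
        Threshold tau on the combined residue score: a docked-interface
        residue counts as predicted-interface if its score is >= tau.
    fir_combiner : str
        How the receptor- and ligand-side fractions of interface residues
        are merged into one value ('mean').
    sii_combiner : str
        Symmetrisation of the interaction-index matrix ('mean', 'max' or
        'min' of the two ordered directions).
    nii_threshold_experimental, nii_threshold_predicted : float
        Operating points used when reporting confusion-matrix metrics for
        experimental-interface and predicted-interface runs.
    env_n_sets : int
        Number of random environments sampled per target complex.
    env_n_complexes : int
        Complexes per environment, target complex included.
    ir_top : float
        Interaction-rank threshold used when counting competing partners.
    label_t_low, label_t_high_margin, label_s_stable : float
        Three-population labelling: a partner is a strong competitor when
        its mean rank is <= label_t_low with spread <= label_s_stable, and
        never-competing when its mean rank is within label_t_high_margin
        of the bottom with the same spread bound.
    his_charge : float
        Charge assigned to His side chains (0 by default; +1 for a fully
        protonated model).
    unknown_residue : str
        'skip' or 'fail' when an unknown residue type is met while
        reducing a structure.
    """

    # surface / interface definition
    surface_rel_acc_min: float = 0.05
    interface_dsasa_min: float = 1.0
    probe_radius: float = 1.4
    sasa_points: int = 960

    # energy model
    dielectric_eps0: float = 15.0
    coulomb_constant: float = 332.0636
    his_charge: float = 0.0

    # docking
    clearance: float = 6.0
    start_density: float = 0.1
    n_orientations: int = 210
    korobov_generator: int = 89
    restraint_k: float = 1.0
    minimizer_maxiter: int = 500
    minimizer_gtol: float = 1e-4
    contact_cutoff: float = 7.0
    interface_mode: str = "contact"
    keep_best: int | None = 2000
    tube_radius: float = 2.9

    # partner scoring
    fir_combiner: str = "mean"
    sii_combiner: str = "mean"
    nii_threshold_experimental: float = 0.5
    nii_threshold_predicted: float = 0.25

    # residue propensities
    temperature: float = 300.0
    gas_constant: float = 1.987204e-3
    boltzmann_min_weight: float = 0.1
    nip_cutoff: float = 0.0
    combine_a: float = 0.4
    combine_b: float = 0.6
    combine_a_ab: float = 0.6
    combine_b_ab: float = 0.4
    combined_score_min: float = 0.5

    # environment sampling
    env_n_sets: int = 100
    env_n_complexes: int = 20
    ir_top: float = 10.0
    label_t_low: float = 10.0
    label_t_high_margin: float = 10.0
    label_s_stable: float = 5.0

    # structure handling
    unknown_residue: str = "fail"

    def replace(self, **kwargs: Any) -> "Config":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides: Any) -> "Config":
        """Build a configuration from an optional YAML file plus overrides."""
        values: dict[str, Any] = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
            unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
            if unknown:
                raise KeyError(f"unknown config keys: {sorted(unknown)}")
            values.update(data)
        values.update(overrides)
        return cls(**values)


DEFAULTS = Config()
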
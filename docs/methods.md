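# Methods

This note documents the model, the numerical choices and the synthetic
study conditions implemented in `ccdock`, in the order of the pipeline.

## Reduced protein model

Residues are reduced to 1–3 pseudo-atoms: a backbone bead at Cα; a single
side-chain bead at the geometric centre of the side-chain heavy atoms for
Ala, Ser, Thr, Val, Leu, Ile, Asn, Asp, Cys; for all other non-Gly types a
first bead midway between Cβ and Cγ and a second at the centroid of the
remaining side-chain heavy atoms. Gly carries the backbone bead only.
Multimeric inputs merge into one rigid body; residue identity is
(chain, author residue number, insertion code); the highest-occupancy
altloc is kept; hydrogens, waters and non-standard residues are ignored
(unknown residue types fail by default, or skip with a warning under
`unknown_residue: skip`). Charges follow the standard coarse-grain
convention — Asp/Glu −1, Lys/Arg +1, His configurable (default 0) — and
sit on the outermost side-chain bead of the residue (the second bead
where one exists, otherwise the single side-chain bead: Asp carries its
charge on its only side-chain bead).

## Solvent accessibility, surface and interfaces

Accessibility is a deterministic Shrake–Rupley calculation: each sphere
(atom radius + probe, probe 1.4 Å) is sampled with a fixed golden-spiral
point set (960 points); a point is accessible when outside every
neighbouring expanded sphere. Translation invariance is exact; rotation
invariance holds to the sampling resolution (≲ 2 % relative at 960
points — the point set is fixed in the laboratory frame), which is the
package's stated tolerance for rotation tests.

Relative accessibility divides a residue's area by its reference area:
extended-tripeptide theoretical maxima for atomic structures, and the
isolated-bead area sum for reduced models. Surface residues have relative
accessibility ≥ `surface_rel_acc_min` (default 0.05). Interface residues
lose ≥ `interface_dsasa_min` (default 1.0 Å²) of accessible area upon
complexation. Coarse-grain bead radii come from the energy parameter
table (half the equilibrium distance of the identical-type pair), keeping
one source of geometric truth.

Docked-conformation interfaces have two modes: the ΔSASA rule above, and
a fast contact mode (any cross-pair bead distance < `contact_cutoff`,
default 7 Å) used by default in systematic runs and flagged in decoy-set
metadata.

## Energy model

Pseudo-atom pairs interact via a soft 8-6 Lennard-Jones plus screened
Coulomb term, E = A/r⁸ − B/r⁶ + k·qᵢqⱼ/(ε₀ r²), with k = 332.0636
kcal·Å/(mol·e²) and ε(r) = ε₀·r, ε₀ = 15. A and B derive from a per-type
equilibrium distance r\* and well depth e (A = 3e·r\*⁸, B = 4e·r\*⁶, so
the minimum sits at r\* with depth e). Parameters are read from an
external file (`type r* depth` lines plus `pair` overrides); the shipped
synthetic default is a single bead class with r\* = 5.0 Å and
e = 0.1 kcal/mol. Only inter-molecular terms are summed; coincident beads
raise an error.

## Systematic docking

Start axes: n = round(receptor accessible area × density) directions
(default density 0.1 Å⁻²) laid with a Korobov lattice (generator 89,
configurable) mapped equal-area onto the sphere (θ = arccos of a uniform
variate, φ uniform), so axis density is uniform over directions. Each
axis carries `n_orientations` ligand rotations (production default 210)
drawn from the run seed — the seed governs orientation sampling only;
everything else is deterministic.

Initial placement solves the per-pair quadratic constraint exactly for
the smallest axial separation at which no bead pair is closer than the
clearance (6 Å). Minimisation runs L-BFGS-B over six rigid-body degrees
of freedom (rotation vector, axial offset, two lateral offsets) with
analytic gradients — including the exact rotation-vector Jacobian — a
harmonic lateral restraint (1.0 kcal/(mol·Å²)), at most 500 iterations
and gradient tolerance 1e-4. Reported conformation energies exclude the
restraint term. Failed starts (non-finite energies) are logged and
skipped; a pair whose starts all fail raises.

Decoy sets can keep the best conformation per (θ, φ) direction and/or be
truncated to the N best energies (release convention ≈ 2000). 2-D energy
maps bin (θ, φ) equal-area and store per-cell minima.

**Tube restriction.** A start axis is retained when at least one
predicted-site residue point (mean of its coordinates) lies within
`tube_radius` (default 2.9 Å) of the axis *and* on the ligand side of the
receptor centre (positive scalar product). An empty prediction retains
nothing, with a warning — the degenerate no-prediction case propagates as
a masked pair. Because minimisations are independent per start,
restricting before docking and filtering an unrestricted run's
conformations by their start axis are identical at the same seed; the
pipeline uses the latter to avoid re-docking. At toy scale the tube
radius must be commensurate with the toy geometry (examples use 6 Å on
~10-residue chains); the 2.9 Å default matches production-scale protein
dimensions.

## Partner scoring

FIR of a conformation: per side, |docked ∩ reference| / |docked| (0 for
an empty docked side); the two sides combine by arithmetic mean
(`fir_combiner`). The interaction index II of an ordered pair is the FIR
of the conformation minimising FIR × E (ties: lower energy, then lower
conformation id) — with negative energies this rewards jointly low energy
and high interface agreement. sII averages II[i,j] and II[j,i]
(`sii_combiner`, pluggable); NII divides sII[i,j] by the maximum over the
four rows/columns featuring i or j (all-zero scope → 0). Pairs with an
empty reference interface are masked (NaN), excluded from maxima and from
evaluation. The predicted partner maximises NII against the query; ties
resolve lexicographically and are logged.

Evaluation defaults to unordered pairs scored by max(NII[i,j], NII[j,i]);
ordered-instance evaluation is available (`ordered=True`). AUC uses the
rank statistic with ties counted half; threshold metrics report MCC = 0
when a denominator factor vanishes. Default operating points: NII ≥ 0.5
for experimental-interface runs, ≥ 0.25 for predicted.

## Residue propensities and score fusion

Boltzmann weights w = exp(−(E − E_min)/RT) with T = 300 K and
R = 1.987·10⁻³ kcal/(mol·K); conformations with w ≥ 0.1 are retained
(an energy window of RT·ln 10 ≈ 1.4 kcal/mol above each pair's best).
ip(i) is the fraction of retained conformations, pooled over all
partners, whose interface contains residue i; NIP centres ip at the
surface mean and scales the maximum to 1 (constant profiles map to 0
with a warning). The NIP interface keeps residues with NIP ≥ 0
(`nip_cutoff`). JET-style scores are consumed, not computed: per-run
conserved-patch residue lists (10 runs standard) are merged into
occurrence frequencies. The combined score is a·NIP + b·JET with
a + b = 1 (defaults 0.4/0.6; an antibody/antigen profile lowers the
conservation weight to 0.6/0.4 since faster interface evolution blurs
the signal). Predicted-interface FIR counts docked-interface residues
with combined score ≥ τ (default 0.5) and feeds the II machinery exactly
as experimental FIR does.

## Environment competition

The interaction rank of (P1, P2) is computed per NII row: the rank of
NII[P1, P2] among row P1 restricted to the environment, likewise for row
P2, keeping the better; ties share the best position. The maximum
attainable rank is therefore the environment size n (ranking is per row,
even though 2(n−1)+1 distinct pairs feature P1 or P2). Environments
default to 100 sets of 20 complexes (40 proteins), each the target
complex plus 19 complexes sampled without replacement from per-environment
sub-seeds (run-order independent). Per pair we record mean IR, population
standard deviation, and per-environment AUC. Labels: strong competitor if
mean IR ≤ 10 with sd ≤ 5; never-competing if mean IR ≥ n − 10 with
sd ≤ 5; intermediate otherwise (all thresholds configurable).
Rank-recovery tables count proteins whose native partner ranks within the
top round(f·N) per fraction f, flooring the top-set size at 1 so the 1 %
row of small sets is well defined.

## Synthetic study conditions

The generators are pure functions of their seeds.

*Toy proteins* are arc-shaped bead chains (spacing 4 Å, arc radius 15 Å,
side beads 2 Å out) with a contiguous planted patch at the apex whose
side beads point along the outward normal; other side beads point away
with seeded jitter. The arc localises docked contacts to the apex region
so interface measures are meaningful on small chains. For docking
studies, patch beads of each complex get a dedicated LJ type and the
parameter table makes the two patch types of a complex attract strongly
(well depth 2.0 vs 0.01 kcal/mol background) — one engineered
complementary patch per native pair.

*Decoy collections* plant native pairs with energies N(−20, σ) against a
N(−10, σ) background (σ default 2 kcal/mol) and interfaces covering the
planted patches with probability `p_signal` (default 0.9); non-native
conformations draw uniform random interfaces, except that with
probability `p_site` (default 0) a background interface sits on the
side's planted patch — the dial for how strongly arbitrary partners
concentrate on sticky sites. Optional plants: a promiscuous protein with
native-like energies against everyone, and an inert protein with weak
energies. Planted NII matrices (for environment studies) score native
pairs near 0.9, background near 0.3 with Gaussian noise; a promiscuous
protein scores native-like everywhere, and an inert protein is planted to
never compete with a designated query (their mutual score sits below all
of the inert protein's other interactions — a uniformly weak protein
would receive noise-uniform ranks within its own row, which is not the
never-competing phenotype).

What the synthetics do **not** emulate: real protein shapes and
electrostatics, correlated energy–interface noise, conformational change
on binding, and realistic conservation patterns. Passing tests therefore
demonstrate the correctness and calibration of the scoring machinery on
controlled signal, not predictive performance on real structures.

## Problem sizes

Desk-scale defaults keep every study on one CPU in minutes: docking
studies use 3 complexes of 10-residue toys with 16 directions × 2
orientations per pair (~30 s for 30 ordered pairs including both scoring
modes and the restriction comparison); planted-decoy studies use 4
complexes × 400 conformations per ordered pair; environment studies use
30 complexes with 50 sampled environments. Production-scale settings
(density 0.1 Å⁻², 210 orientations, ~2000 retained decoys, 100
environments) remain the configuration defaults.

## Known limitations

- The SASA point set is laboratory-fixed, so rotation equivariance is
  approximate (see above); areas are otherwise exactly reproducible.
- The contact-mode interface is a speed approximation to the ΔSASA
  definition; the two can disagree at the margins of an interface.
- Rigid-body docking only: no side-chain or backbone flexibility, no
  all-atom refinement.
- NII normalisation makes scores relative to the protein set analysed;
  absolute NII values are not comparable across different sets.
- The minimiser is local; coverage comes from the multi-start protocol,
  not from any global-optimisation guarantee.
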
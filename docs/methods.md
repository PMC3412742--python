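# Methods

This note records the models the package implements, the parameter choices
that matter, what the synthetic generators do and do not emulate, and the
numerical decisions a maintainer would want written down.

## Coordinate and unit conventions

Coordinates are nanometres everywhere inside the package; PDB files are
converted on read/write (Å ↔ nm). Energies are kJ/mol. SASA is reported in
Å² because the apolar surface-tension coefficient γ is conventionally
quoted per Å². ENM force constants are quoted in kcal mol⁻¹ Å⁻² (the unit
the field uses for these models) and converted by ×418.4 to
kJ mol⁻¹ nm⁻² when the Hessian is assembled, so eigenvalues carry
kJ mol⁻¹ nm⁻²; every shape-level ENM output (fluctuation profiles,
overlaps, correlations) is invariant to this choice. Residue ranges are
author-numbered and inclusive on both ends.

## Structure handling

`read_pdb` (backed by Biopython's parser) keeps one residue per
(chain, author number), resolves alternate locations to the
highest-occupancy copy, excludes waters and — unless asked — other
heteroatoms, and flags residues lacking a Cα. Hydrogens are retained when
present because hydrogen-bond geometry needs them; every other operation
accepts heavy-atom-only structures.

Disulfides are detected geometrically: all CYS SG–SG pairs within 0.25 nm,
assigned closest-first so each cysteine joins at most one bridge. The
0.25 nm default covers the canonical ~0.205 nm S–S bond with margin while
excluding nonbonded sulfur contacts; it replaces a call to an external
assignment program, whose only consumed output would be the same pair
list. Secondary structure is likewise ingested as a plain
(chain, resnum, label) table with labels H/E/C — any assigner can produce
it — and unlisted residues default to coil.

## The extended anisotropic network model

Node placement: one backbone node per residue at the Cα; one side-chain
node at the unit-mass centre of the side-chain heavy atoms, except ASP,
ASN, ARG, LYS, GLN, GLU, which use their terminal interaction atom (Cγ,
Cγ, Cζ, Nζ, Cδ, Cδ) — these side chains interact through their charged or
amide tip, not their geometric middle. Glycine has no side-chain node. A
missing terminal atom falls back to the centre of mass with a warning.

Spring rules, first match wins:

1. intra-residue Cα–side-chain tether, k = 10 kcal mol⁻¹ Å⁻²;
2. disulfide side-chain–side-chain bridge, k = 10;
3. sequential (i, i+1) Cα pairs whose residues share one contiguous helix
   or strand element, k = 6;
4. distance shells at 3 / 2 / 1 kcal mol⁻¹ Å⁻² for separations ≤ 0.4 nm,
   (0.4, 0.8] nm, (0.8, 1.2] nm; no spring beyond 1.2 nm.

Decisions worth recording: the precedence order (tether ≥ bridge >
secondary structure > shell) is a design choice — the rules overlap and
some order must be fixed; bonded rules 1–2 apply regardless of the 1.2 nm
nonbonded cutoff; the shell rule applies to all node kinds
(backbone–backbone, backbone–side-chain, side-chain–side-chain) without
restriction; and the secondary-structure stiffening is read conservatively
as sequential-pair stiffening, with an `ss_all_pairs_in_element` switch
for the broader all-intra-element reading, since either is defensible.
A secondary-structure "element" is a maximal run of consecutively numbered
same-chain residues sharing the same H or E label.

The Hessian uses the standard ANM form: off-diagonal 3×3 super-element
−(k/d²)·r_ij r_ijᵀ per spring, diagonal super-elements closing each row to
zero, which makes uniform translations exact null vectors (to float
summation order) and rotations null to numerical tolerance. Dense
`scipy.linalg.eigh` diagonalization is used; the systems this package
targets (10²–10³ nodes) do not need sparse iterative solvers. Modes with
|λ| ≤ 10⁻⁸·λ_max are classified rigid; more than six rigid modes raises an
error naming the disconnected components. Eigenvector sign is fixed by
making the largest-magnitude component positive; overlaps take absolute
values, so the sign convention affects only exported mode files. There is
no mass weighting — this is the pure ANM, where only the contact topology
matters.

Analyses: MSF_i = Σ_m |v_i^m|²/λ_m over selected non-rigid modes (the
diagonal 3×3 trace of the Hessian pseudo-inverse), B = (8π²/3)·MSF, both
up to a global scale because no k_BT prefactor is applied — profiles, not
absolute values, are the comparable quantity. Mode overlap between two
models restricts each eigenvector to the mapped common nodes, renormalizes
the sub-vectors and takes |dot|; modes are compared pairwise without
reordering. The n-mode correlation map normalizes the pseudo-inverse
block traces to unit diagonal (25 modes by default — enough to capture
the collective regime while staying clearly below the full spectrum).
Dominant-motion arrows scale the unit mode so the two elongated structures
differ by a target RMSD (default 0.2 nm = 2 Å, the conventional display
amplitude): for a unit mode, RMSD(+s, −s) = 2s/√N, so s = target·√N/2.

## Trajectory metrics

RMSD: each frame is Kabsch-fitted (scipy `Rotation.align_vectors`; RMSD
recomputed from the fitted coordinates rather than the solver's residual,
which carries ~10⁻⁸ quaternion noise) to the reference over the effective
Cα selection, selection minus exclusions. Excluding a floppy tail (e.g. a
receptor's membrane-proximal domain) keeps the fit from being dragged by
it. RMSF and DCCM superpose all frames on the ensemble mean — align to the
first frame, average, re-align to that average once, which converges for
the small-fluctuation regimes these metrics describe — then take
per-residue fluctuations and normalized displacement covariances.

Hydrogen bonds: donors are N/O atoms with ≥ 1 hydrogen within 0.12 nm
(covalent attachment inferred geometrically — united-atom structures carry
only polar hydrogens); acceptors are all N/O; same-residue pairs are
ignored. A bond requires donor–acceptor distance ≤ 0.35 nm and a D–H…A
geometry within 60° of linearity (angle ≥ 120°). The 60° figure is read as
maximum deviation from linear, the convention of the common visual
analysis tools; because the bare phrase "angle cutoff of 60°" is genuinely
ambiguous, `HBondCriteria.angle_is_deviation_from_linear` switches to the
raw-angle reading.

SASA is Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points — total areas shift < 0.5 % on doubling), probe
0.14 nm, Bondi-type van der Waals radii (C 0.170, N 0.155, O 0.152,
S 0.180, P 0.180, H 0.120 nm), hydrogens excluded by default. Buried area
of residue i is SASA_i(its partner alone) − SASA_i(complex), non-negative
up to quadrature noise, averaged over frames; the partner partition must
cover the complex's chains exactly once. Group distances use unweighted
geometric centres by default with optional rough mass weighting.

## MM/PBSA bookkeeping

The ledger implements ΔG_binding = ΔG_complex − Σ coeff·ΔG_partner with
G = H_int + H_vdW + H_elect + G_polar + G_apolar and the entropy term
identically zero — deliberately neglected, on the usual argument that the
receptor-immobilization entropy is comparable across the steps being
compared and cancels in their differences; every ledger records
"entropy: neglected" in its metadata. Component identities
(ΔG_solv = ΔG_polar + ΔG_apolar; the grand total equals the component sum)
are enforced at construction, exactly.

Gas phase: Coulomb f·Σ q_iq_j/r_ij with f = 138.935458 kJ mol⁻¹ nm e⁻²
and vacuum dielectric by default (the reduced solute dielectric belongs to
the PB stage, not the gas-phase sum; a config override exists);
Lennard-Jones full 12-6 sums with geometric combination (the
Gromos-family convention) or Lorentz–Berthelot. No cutoffs, no
periodicity, no exclusions by default — the primary use is cross-partner
interaction energies, where intramolecular exclusions never enter.
H_int is computed only when harmonic bond/angle and periodic dihedral
parameters are supplied; a SETA ledger without them omits the row and
flags itself incomplete rather than inventing force-field terms.

Solvation: G_polar is an imported per-snapshot column — solving the
Poisson–Boltzmann equation is outside this package's scope — tagged with
the solver settings (`PolarInputSpec`: dielectrics 2 / 78.54, 225³ grid,
0.5 Å spacing, van der Waals boundary, no counterions) as provenance.
G_apolar = γ·SASA + b with γ = 0.0227 kJ mol⁻¹ Å⁻², b = 3.85112 kJ mol⁻¹.
In a binding difference the intercept contributes −b (one complex minus
two partners).

SITA evaluates everything on the complex trajectory: ΔH_int ≡ 0 because
identical coordinates make bonded terms cancel, and by bilinearity the
Coulomb/LJ differences equal explicit cross-partner pair sums, which is
what is computed. SETA averages each species' per-snapshot components
independently, then differences the means with the reaction's
stoichiometric coefficients (the unbound receptor enters as ½ of a
receptor dimer, scaled before differencing) and combines SEMs in
quadrature. SEM is plain σ/√n (ddof = 1) with no autocorrelation
correction — snapshot correlation would require time information the
ledger does not assume; derived rows in SITA are aggregated from
per-snapshot sums so their SEMs honour within-snapshot correlations.
Ledgers print at 0.1 kJ/mol (the precision such tables are published at)
while machine output keeps full precision; published totals that disagree
with their own column sums by a trailing 0.1 are treated as rounding
artifacts, and this package reports the full-precision sums.

## Synthetic data: what it does and does not emulate

`make_toy_structure` builds idealized Cα traces — helical geometry
(radius 0.23 nm, rise 0.15 nm, 100°/residue, giving the canonical 0.38 nm
Cα–Cα step) for H runs, a wider extended spiral for E/C, tiny seeded
jitter on coil so no trace is exactly degenerate (exactly planar or
collinear geometries would add spurious zero modes) — with N/CA/C/O plus a
CB pseudo side chain per residue and SG pairs placed 0.203 nm apart for
requested disulfides. Multi-chain layouts place translated copies far
enough apart not to interact.

`sample_enm_ensemble` draws frames from the exact Gaussian the network
defines: displacement = Σ_m z_m·√(T/λ_m)·v_m with z standard normal, so
rigid-mode projections are identically zero, mode variances are T/λ_m by
construction, and the DCCM/RMSF stages have a closed-form ground truth.
Atoms inherit their residue's node displacement (backbone atoms the
backbone node, side-chain atoms the side-chain node), making the Cα
statistics of the trajectory exactly the backbone-node model. The
temperature parameter is a pure variance scale; all downstream comparisons
are shape-based. The default scale is chosen small (fluctuations ≪
structure size) so superposition removes almost nothing.

What this does **not** emulate: anharmonicity, barrier crossings, solvent
friction, force-field realism, or time correlation (frames are i.i.d.).
Passing the recovery tests therefore shows the measurement chain is
faithful to a known harmonic ensemble — not that the ENM describes any
real protein's dynamics.

`make_planted_interface` spaces donor/acceptor pairs 2 nm apart so planted
bonds and decoys cannot interact; decoys violate exactly one criterion
(0.40 nm distance, or a 90° kink at the hydrogen). `make_energy_table`
draws i.i.d. Gaussian columns around known means, making ledger
aggregation a parameter-recovery exercise with analytic SEMs.

## Problem sizes and determinism

The test and acceptance workloads use toy systems of 8–30 residues and
ensembles of up to 5000 frames — large enough that sampled correlation
matrices pin down the generating model (matrix correlations > 0.95,
χ²-calibrated mode variances at α = 0.01) while a full run of suite plus
acceptance script completes in well under a minute. Every stochastic stage
takes an explicit integer seed; identical seeds give bit-identical
fixtures, ensembles, tables and CLI outputs.

## Known limitations

* No mmCIF, no binary trajectory formats, no PBC unwrapping; inputs are
  assumed whole molecules in plain-text formats.
* No structure repair, protonation, or missing-atom modelling.
* No Poisson–Boltzmann or Generalized-Born solver; G_polar is an input.
* No entropy estimation (normal-mode or quasi-harmonic), no per-residue
  free-energy decomposition, no alanine scanning.
* The ENM has no Gaussian-network variant, no all-atom normal modes, no
  mass weighting.
* SEMs assume uncorrelated snapshots; correlated MD frames will understate
  uncertainties unless the caller thins them.
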
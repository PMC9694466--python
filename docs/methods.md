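# Methods

This note records the models implemented by `switchscope`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter when reproducing or
extending the results.

## The synthetic system

All trajectory-dependent stages are validated against a coarse-grained
generator rather than against archived MD data.  The toy system is a
72-residue protein of one bead per residue (the bead serves as both the
Cα and the residue's only heavy atom) laid out on a compact idealized
helix (rise 1.2 Å, radius 1.9 Å, 120°/residue).  The helix parameters
are chosen so that i/i±2 (4.07 Å) and i/i±3 (3.6 Å) bead distances fall
inside the 4.5 Å network contact cutoff: with sequence-adjacent pairs
excluded, the backbone alone forms a connected contact network, as a
folded protein's does.

Two loop regions — LoopI (residues 30–42) and LoopII (57–63), the
defaults following the reaction-coordinate definitions used for the PMF
stage — interconvert between a *closed* and an *open* reference
conformation.  The hidden conformational state evolves as a
**discrete-time Markov chain** (default transition matrix
`[[0.95, 0.05], [0.2, 0.8]]`, stationary distribution 0.8/0.2
closed/open, satisfying detailed balance); each frame is the current
state's reference coordinates plus isotropic Gaussian noise (default
σ = 0.15 Å per coordinate).  Markov hidden-state dynamics, rather than
Langevin dynamics, were chosen deliberately: the generator's transition
matrix is then *exact* ground truth for Markov-model recovery, with no
discretization error to argue about.  In the open state each loop is
rigidly displaced by 8 Å, the two loops in opposite directions so the
net center-of-mass shift between states is small and the displacement is
not absorbed by global superposition — this keeps loop-bead RMSF near
its full ~3 Å while non-loop beads stay below 1 Å, giving a clean
separation around the 2 Å flexibility gate.

A 12-atom ligand (aromatic hexagon, H-bond donor with explicit
hydrogen, acceptor, formal cation and anion, covalent "warhead" carbon)
sits in a pocket built against LoopII.  Seven pocket residues are
hand-placed so that one interaction of each geometric type fires *by
construction*: three against static residues (100 % designed frequency)
and four against LoopII residues (frequency = closed-state occupancy).
Planted distances sit ≥2σ of the thermal noise away from every rule
threshold, so noise cannot flip an interaction.  The manifest records the
planted (residue, type) table, per-state contact table, and pocket
membership; contact pairs whose noise-free distance falls within 3σ of
the 4.5 Å cutoff are omitted from the manifest because their contact
status is genuinely ambiguous — the generator only vouches for decisive
designs.  A 5-atom nucleotide analogue (zigzag chain — an exactly
collinear chain would be a zero-stiffness mechanism in the entropy
model) and one Mg²⁺ ion bind near the nucleotide site and anchor the
network's NUC and ION nodes.

What the toy does **not** emulate: force-field-driven dynamics (no
thermostats, no solvent, no realistic energy surface), side-chain
packing, realistic protein geometry, or diffusive barrier crossing
(state switches are instantaneous).  Passing tests therefore demonstrate
that each analysis stage recovers *known inputs* under its own
assumptions — they do not demonstrate force-field accuracy or
convergence behavior on real MD data.

## Geometry

Superposition is Kabsch's SVD solution with the reflection corrected to
a proper rotation; collinear point sets are rejected since the rotation
is then degenerate.  It is cross-checked against an independent
quaternion (Horn) implementation to 1e-8 Å.  RMSF uses the mean
structure after one re-superposition pass (iterating to full convergence
changes values far below the 2 Å gate).  The flexibility gate is a
strict inequality (RMSF > 2 Å).  The switch-state classifier is a set of
disjoint, half-open rectangular zones in the (loop I, loop II) RMSD
plane; the zone geometry is configuration because no published
coordinate-space definition of the conformational types exists.

## Energetics

The ledger is the standard single-trajectory MM/GBSA decomposition.
Conventions: Coulomb constant 332.0637 (kcal Å / mol e²), interior
dielectric 1, exterior 78.5, GB prefactor 166.03 with Still's
f_GB = √(r² + R_iR_j exp(−r²/4R_iR_j)) including self terms, probe
radius 1.4 Å, surface tension 0.0072 kcal/(mol Å²), temperature 310 K,
no distance cutoffs.  Nonbonded cross terms exclude 1-2 and 1-3 bonded
pairs — their energy belongs to the covalent term, which is the harmonic
strain of bonds crossing the receptor/ligand partition (zero for a
noncovalent split).  SASA uses a deterministic golden-spiral
Shrake–Rupley lattice (default 960 points per atom; 480 in the pipeline
for speed), validated against Monte-Carlo surface sampling to 0.5 %.

Vibrational entropy comes from mass-weighted normal modes.  The surrogate
potential is an elastic network (springs between all atom pairs within
12 Å, k = 1 kcal/mol/Å²) built at the scored frame, which is therefore
its own minimum — the general code path still supports minimization and
a numerical Hessian for arbitrary energy models, and the elastic network
carries an analytic Hessian.  The 12 Å cutoff was set after verifying
(900 spectra across seeds, states and species) that every sub-system has
exactly six near-zero modes; at 10 Å an isolated pocket bead in
receptor-only open frames becomes a zero-stiffness mechanism.  At most
six near-zero modes are removed; more, or any strongly negative
eigenvalue, raises "not a minimum".  −TΔS for binding is
−T(S_complex − S_receptor − S_ligand), averaged over a small number of
evenly spaced frames (default 3 in the pipeline; the published protocol
used 50 of 5000 — the same ratio class, scaled to the toy).

The toy potential is not calibrated to make binding favorable — planted
polar contacts sit inside the LJ minimum, so ΔE_bind is near zero while
−TΔS is positive.  The ledger identities, not the sign of the toy's
binding energy, are the tested contract.

`ΔG_exp = RT ln(IC50·10⁻⁹)` with R = 1.9872×10⁻³ kcal/(mol K), T = 310 K.
The correlation statistic is the *squared* Pearson coefficient:
recomputing from the published per-system values gives 0.706/0.953,
matching the printed 0.70/0.95 only as r², not as r.

## Markov models and flux pathways

Featurization takes the superposed 3D bead coordinates of the flexible
(RMSF > 2 Å) residues, fitting on the non-flexible beads so the metric is
internal motion.  Microstates come from seeded k-means++ (deterministic
per seed); the pipeline default is k = 100 at desk scale with the
published-scale k = 5000 available by configuration.  Estimation uses
sliding-window counts at the lag, symmetrized (C ← (C+Cᵀ)/2) for
reversibility — a deterministic approximation to maximum-likelihood
reversible estimation that is exact when the underlying chain satisfies
detailed balance, as the generator's does — then row-normalization on
the largest strongly connected set, stationary distribution from the
leading left eigenvector, and implied timescales −lag/ln λ.

Metastates use a PCCA-style inner-simplex construction on the top right
eigenvectors: the most mutually distant states in spectral coordinates
become vertices, every state gets barycentric memberships (clipped and
renormalized), crisp assignment is the argmax.  The metastate count is
user-set (default 2, matching the generator's ground truth; the original
study reports 10–14 per system from an unstated criterion).

TPT: forward committor from the standard linear system, backward
committor via the time-reversed chain, gross flux
f_ij = π_i q⁻_i T_ij q⁺_j, net flux f⁺ = max(0, f − fᵀ).  Pathways are
peeled off by iterative bottleneck decomposition; the widest-path value
is found Dijkstra-style and the representative path is the
lexicographically smallest one on the subgraph of edges carrying at
least that flux (net reactive flux is acyclic, so ascending
depth-first search terminates quickly).  Decomposition stops when the
residual drops below 1e-8 of the total flux.  Dominant states are the
shortest pathway prefix whose cumulative flux fraction strictly exceeds
60 %.  Representatives are the 10 frames nearest each metastate's
π-weighted center in feature space; the metastate's loop-RMSD label is
the mean over those frames, the start state is the lowest-RMSD
metastate and the end state the most populated one.

## 2D PMF

F = −k_BT ln(count/max count) on a default 50×50 grid spanning the data
range padded 5 % (the pipeline uses 40×40), bins half-open [lo, hi) with
the right-most bin closed.  Normalizing by the maximum count rather than
the total anchors the minimum at exactly 0; the two normalizations
differ by a constant, so free-energy *differences* are identical (this
is a tested invariant).  Empty bins are masked, and displayed at
max(occupied F) + 1 kcal/mol rather than ∞.  Basins are local minima
over 8-neighborhoods within 1 kcal/mol of the global minimum
(threshold chosen to separate the 1–3 wells the toy surfaces produce);
tied plateau minima that touch are merged into one basin, and the global
minimum is always retained.

## Interaction fingerprints

Typing is ligand-centric (HBDonor = the ligand donates, Cationic = the
ligand carries the positive charge), matching the convention of the
standard fingerprinting tools.  Default thresholds: hydrophobic C/S–C/S
≤ 4.5 Å; H-bond donor–acceptor ≤ 3.5 Å with D–H⋯A ≥ 130° when an
explicit hydrogen is present (distance-only otherwise); π-stacking
centroid ≤ 5.5 Å with plane tilt ≤ 30°, or edge-to-face at 60–90° tilt
within 6.5 Å; ionic ≤ 4.5 Å between opposite formal charges; cation–π
≤ 4.5 Å to the ring centroid.  These are community-standard values; all
are configuration, and the validation geometries are planted far from
every boundary so the tests do not hinge on threshold taste.  The seven
types implemented are the quoted ones plus those appearing in the
published frequency tables; the rule set is extensible.  Reports keep
rows whose frequency strictly exceeds 30 % in at least one system; raw
frequencies are retained.

## Dynamic network

Nodes: one per protein residue (positioned at its bead), one per ligand
heavy atom, one per ion, and one for the nucleotide at its C1′-equivalent
atom.  An edge requires the minimum heavy-atom distance ≤ 4.5 Å in at
least 75 % of frames, excluding sequence-adjacent residues (|i−j| ≤ 1),
the established convention that stops trivial backbone paths from
dominating.  Weights are w = −log|C_ij| capped at 13.8 (|C| < 10⁻⁶),
with C_ij the scalar-product correlation of node displacement vectors
after superposition on the protein beads.  Communities come from
weighted Girvan–Newman (edge betweenness with the distance weights),
keeping the partition of maximum weighted modularity; ties are broken by
networkx's stable orderings, so results are deterministic.  Suboptimal
paths are enumerated exhaustively by depth-first search bounded by the
exact remaining Dijkstra distance to the sink, which guarantees no path
within tolerance is missed (verified against all-simple-paths
enumeration).  Source and sink are explicit arguments; the pipeline
default pairs a pocket residue with the nucleotide node.

## Pipeline, seeds, determinism

Every stage constant is a named `StudyConfig` key with its protocol
default (310 K; 2 Å RMSF gate; 6 Å pocket; 30 % report rule; 4.5 Å/75 %
edges; 60 % flux rule; 1.4 Å probe; 0.0072 surface tension).  One
integer seed drives everything through `numpy` `SeedSequence` spawning
(generator chain, generator noise, per-system sub-seeds, k-means), so a
rerun with the same config and seed is identical; the run manifest
records the config digest and seed.  A failed system yields a partial
bundle with per-system status rather than aborting the study.

Desk-scale problem sizes used by the default pipeline and the
acceptance script — 800–2000-frame studies, 50 000 frames for
transition-matrix recovery, 5000 frames for fingerprint recovery, 10⁵
samples for the Gaussian PMF check, 200 random chains and 1000 random
point sets for the oracle suites — were chosen as the smallest sizes at
which the statistical tolerances (±0.02 on transition probabilities,
±3 percentage points on frequencies, 0.15 kcal/mol RMS on the PMF) are
comfortably resolved.

## Known limitations

- The reversible estimator is count-symmetrization, not the
  maximum-likelihood reversible iteration; unbiased only when the
  underlying chain is reversible (true for the generator, approximately
  true for well-sampled MD).
- The per-residue nonpolar column attributes protein-side SASA burial
  only; the ligand's own burial is not redistributed onto residues.
  The pairwise columns (elec, vdW, GB polar) close exactly against the
  whole-system cross terms.
- Girvan–Newman is O(E²·N) and intended for the ≤100-node networks this
  package produces, not for all-atom graphs.
- The elastic-network entropy is a topological surrogate: it ranks
  flexibility changes consistently but its absolute −TΔS values carry no
  force-field meaning.
- The coarse-grained H-bond rule degrades to distance-only when a donor
  has no explicit hydrogen.
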
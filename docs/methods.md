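# Methods

This note documents the models, conventions and design choices behind
`oligorder`, in the spirit of a simulation-analysis package's methods
appendix. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Orientational order

The degree of beta-sheet order of a few-chain peptide system is
quantified by the nematic order parameter. Each peptide chain of length
L contributes L − 2 molecular vectors, the normalized displacements from
Cα(i) to Cα(i+2); for three heptapeptides that is N = 3 × 5 = 15
vectors. (A per-chain count of L is sometimes quoted for this system,
but an i→i+2 rule on a 7-residue chain can only yield 5 vectors; the
vector rule is isolated in `molecular_vectors` as the single point of
change if a different convention is wanted.) The order matrix

    Q = (1/N) Σ_k (3/2 û_k û_k^T − 1/2 I)

is symmetric and traceless; P2 is its largest eigenvalue (clipped to
[0, 1] against roundoff) and the director is the corresponding
eigenvector, sign-fixed so its first nonzero component is positive.
Eigenvalue degeneracy (e.g. perfect planar order) is broken by the
deterministic eigenvector ordering of the symmetric eigensolver. P2 is
invariant under rigid motion of the frame and under flipping any subset
of vectors; both are property-tested at 1e−9.

Frames are **ordered** when P2 strictly exceeds the crossover
P2\* = 0.665 — a tie classifies as disordered, since order is defined by
"greater than". The order:disorder ratio r divides ordered by
disordered event counts; when nothing is disordered, r is flagged
infinite rather than raising. Both counts are always reported so the
reciprocal convention is recoverable.

P2 frequency histograms default to bin width 0.05, which resolves the
characteristic two-mode structure (disordered mass near 0.2, sheet mass
near 0.8) without over-binning short synthetic runs.

Segments are decomposed into overlapping windows
[start + k·step, start + k·step + window − 1]; residues 14–24 with a
7-residue window and step 2 give the three heptapeptide windows
starting at 14, 16 and 18. A warning is emitted when the final window
stops short of the segment end.

## Nonbonded energetics

Inter-chain energies use a 12-6 Lennard-Jones term in Rmin convention
with Lorentz–Berthelot combining plus a Coulomb term with
C = 332.0716 kcal·Å/(mol·e²), summed over atom pairs within a 7.5 Å
cutoff. Truncation is a hard cutoff by default; a shifted variant
(energies scaled by (1 − (r/rc)²)²) is available as a config option.
Hard truncation was chosen because the analysis consumes energy
*distributions*, not forces, so the discontinuity at the cutoff is
immaterial; the option exists for users who prefer a smooth tail. Only
inter-chain terms are ever evaluated, so no bonded exclusions are
needed. Pairs closer than 0.1 Å are rejected as nonphysical input
rather than silently contributing r⁻¹² noise.

The per-peptide interaction energy E_p is the sum of pair energies of
peptide p with every other peptide, ligand terms excluded by
construction — additivity (E_p equals the row sum of the symmetric pair
matrix) is exact, not approximate. In an ordered trimer the central
peptide interacts with both neighbours, so its energy is twice an edge
peptide's; this two-mode structure is what the energy histograms are
designed to resolve (default bin width 5 kcal/mol, zero aligned on a
bin edge so out-of-contact frames are countable either way).

Ligand–residue van der Waals profiles average the LJ-only
ligand–residue energy over frames, excluding frames in which the ligand
touches *no* residue at all: a ligand in contact half the time with
energy e reports a mean of e, not e/2. The count of frames used is
always reported, and a never-in-contact profile is flagged undefined
(NaN) rather than zero.

Synthetic ensembles carry no force-field parameters, so a minimal
Cα-level bead set is provided (`apply_toy_params`): one site per
residue with a generic bead well (ε = 0.30 kcal/mol, Rmin/2 = 2.6 Å)
and small residue-type charges (±0.1 e on Lys/Arg/Asp/Glu, +0.05 on
His). It is deliberately generic — distribution *shapes* (edge vs
center modes, contact vs no-contact), not absolute magnitudes, are the
analysis target, and files with real per-atom parameters (via the
topology sidecar) override it.

## Hydrogen bonds

A donor N–H donates to an acceptor O when the H···O distance is
**smaller than** 2.5 Å and the N–H···O angle is **larger than** 130°;
both inequalities are strict, so exact ties are non-bonds. Acceptors
default to oxygen only (the criterion is stated on H–O distances);
other acceptor elements are a configuration extension. Donor hydrogens
are attached to the nitrogen of their own residue by name (H→N, H1→N1,
HE1→NE1) or proximity; a nitrogen without any hydrogen is skipped with
a warning. Donor and acceptor within one residue are never paired —
standard practice that also suppresses trivially short intramolecular
contacts in idealized geometries.

Ligand polar groups carry field-style labels: NH1 (anilinic N–H,
donor), CO1/CO2 (quinone carbonyls, acceptors), CO3 (the carboxylate
oxygen pair — one symmetry class, OR-collapsed into a single row), NE1
(indole N–H, donor). Occupancy rows exist at group resolution
("NH1-CO": the group bonded to *any* backbone carbonyl) or residue
resolution ("NH1-Phe20", collapsed over the identical chains of the
trimer); residue rows OR together consistently with the group row.
Backbone–backbone bond counts (intra- vs inter-peptide) are always
computed alongside.

The primary pair statistic is the plain co-occurrence frequency
c_ij = (1/T) Σ_t h_i(t) h_j(t), whose diagonal is the marginal
occupancy and which satisfies 0 ≤ c_ij ≤ min(c_ii, c_jj). Because the
natural alternative normalization is a correlation coefficient, the
Pearson phi of the two binary series is emitted in parallel (NaN for
constant series); consumers can use either reading.

## Binding modes

Mode frames are those in which every required labeled hydrogen bond is
formed simultaneously. The RMSD atom set is the ligand's heavy atoms
plus peptide heavy atoms within 4.5 Å of any ligand atom in the first
selected frame (per-frame union available as an option; the radius is
configurable — no canonical value exists for "close"), minus atoms in
declared symmetry classes (defaults on the shipped templates: the
ligand carboxylate oxygen pair; Phe ring CD1/CD2 and CE1/CE2 and
Asp/Glu carboxylates when present) so that chemically indistinguishable
flips cannot split clusters.

Clustering is a deterministic leader (first-fit) algorithm: frames are
visited in trajectory order, each joins the first cluster whose leader
is within 1.5 Å after optimal superposition, else founds a new cluster.
This is a documented stand-in for unpublished clustering tools used in
earlier studies of this system: it is order-deterministic, standard in
trajectory analysis, and guarantees every member is within the cutoff
of its leader while distinct leaders are farther than the cutoff apart.
Clusters are re-ranked by size; the representative is the medoid
(minimum mean RMSD to co-members, ties broken by lowest frame index).

Superposition is the Kabsch SVD construction with the determinant
correction for proper rotations; collinear or < 3-atom sets are
rejected. It is cross-checked in the tests against an independent
quaternion (Horn) eigenvalue oracle at 1e−9.

## NMR tools

Chemical-shift deviations compare matched (residue, nucleus) keys of
two assignment tables sharing one spectrometer field; |Δδ| is reported
in ppm and in Hz (ppm × MHz). Deviations are absolute — titration
analyses of this kind discuss magnitudes — and unmatched keys are
listed as unresolved rather than dropped silently. NOE restraints are
classified by sequence separation: 0 intra, 1 sequential, 2 and 3
medium range, and ≥ 4 long range (the standard NMR convention; the
categories below long range are enumerated only up to i+3, which forces
this boundary). A proton assignment table for the amyloid-beta 12–28
fragment in its ligand-bound state is packaged as a TSV fixture for
parser tests; free-peptide reference shifts are not available, so
titration tests plant known Hz deltas on top of it rather than claiming
recomputed deviations.

## Synthetic ensembles

The generators emulate the study conditions of implicit-solvent
aggregation runs — three monodisperse heptapeptide replicas (defaults:
the amyloid-beta windows 14–20 HQKLVFF, 16–22 KLVFFAE, 18–24 VFFAEDV,
derived from the canonical sequence and overridable) in a cubic box at
5 mg/ml, with or without one ligand molecule:

- **Sheet trimer.** An idealized in-register extended-strand template:
  3.8 Å consecutive Cα spacing (zig-zag pleat 0.7 Å), strands stacked
  4.8 Å apart along the hydrogen-bond direction, backbone N, C, O and
  amide H placed so amide donors and carbonyl acceptors of adjacent
  strands meet in near-linear N–H···O bonds satisfying the 2.5 Å/130°
  criteria, with alternate strands staggered by half a residue so
  facing carbonyl oxygens stay apart. The constants are
  textbook-flavoured, not fitted: their only job is to make the
  noise-free sheet exactly ordered (all molecular vectors parallel,
  P2 = 1) and hydrogen-bonded. Isotropic Gaussian noise of chosen sigma
  degrades order monotonically in expectation.
- **Disordered trimer.** Self-avoiding freely-jointed Cα walks (3.8 Å
  steps, backfolding under 45° rejected, 3.5 Å self-clearance) decorated
  with backbone atoms in local frames, placed at random positions and
  orientations in the box with at least 4 Å between chains (bounded
  rejection; failure raises). Disorder is operationalized purely as
  geometry — these are not unfolded thermodynamic states, but the
  analysis consumes only coordinates.
- **Mixture.** Exactly round(f·n) sheet frames and the remainder coils,
  shuffled deterministically; ground-truth labels are returned beside
  the trajectory and no analysis stage reads them.
- **Planted ligand poses.** Rigid transforms of the template ligand
  chosen multinomially by weight plus Gaussian jitter; planted poses
  must be separated by more than twice the clustering cutoff so cluster
  recovery is well-posed, and labels are returned.
- **Correlated H-bond series.** I.i.d. draws from the bivariate
  Bernoulli with cells (p_ij, p_i − p_ij, p_j − p_ij, 1 − p_i − p_j +
  p_ij); the Fréchet bounds are validated.
- **Box side from concentration.** side = (n·M / (N_A·c))^(1/3) with
  Da→g and ml→Å³ bookkeeping; chain mass is the sum of average residue
  masses plus one water. For 3 × HQKLVFF at 5 mg/ml this gives ≈ 97 Å;
  published setups for the same system quote 98 Å, a ~1 Å discrepancy
  attributable to an unstated mass convention (termini protonation,
  united-atom masses), which is why the mass table is a parameter.

Every generator is a pure function of its spec including the seed:
reruns are byte-identical. The ligand template is a *synthetic* rigid
stand-in for a naphthoquinone-tryptophan hybrid — fused hexagons, a
short linker, and named polar atoms (N1/H1, O1, O2, OX1/OX2, NE1/HE1) —
not the compound's real conformation; all analyses require only a rigid
body with labeled polar groups.

What passing tests on these ensembles shows — and what it does not:
they validate the *estimators* (P2 classification, ratio, occupancy,
correlation, cluster frequencies) against known ground truth, and the
*implementations* against independent oracles. They do not reproduce
the physics of microsecond force-field trajectories: headline numbers
from such runs (histogram peak positions, −80/−40 kcal/mol energy
modes, specific binding-mode percentages, absolute H-bond counts) are
properties of the sampled ensemble and are covered here only as
qualitative structure (bimodality, center ≈ 2 × edge, order loss with
noise).

## Pipeline and reproducibility

`run_pipeline` wires generate → order/energy/hbonds → modes under one
config with a single global seed; per-stage seeds are derived by stable
SHA-256 hashing (one knob, independent streams, all below 2³¹). Outputs
are CSV/JSON plus a manifest (config hash, package version, per-stage
row counts); identical configs give byte-identical outputs. Every stage
logs input frame counts, parameters and output summaries at INFO.

File formats: multi-model PDB (chains A/B/C for peptides, L for the
ligand, occupancy/B-factor 1.00/0.00, CRYST1 for the cubic box) and XYZ
(lossless full-precision floats). Since neither format carries charges,
LJ parameters, polar-group labels or symmetry classes, those travel in
a YAML topology sidecar, which for XYZ also lists the atoms in file
order. PDB coordinates are fixed-width %.3f, so round trips are exact
to 1e−3 Å; XYZ round trips are bit-exact. Termini conventions are
never guessed: the sidecar's `atom_params` selectors let users declare
termini charges explicitly.

Problem sizes used by the default test suite and the acceptance script
(1e5 isotropic draws, 500 disordered seeds, 1000-frame mixtures,
500-frame pose trajectories, T = 1e5 binary series) were chosen so
statistical assertions sit at 3 standard errors with comfortable
margin while the whole suite runs in well under a minute on one core.

## Known limitations

- No molecular dynamics, force-field sampling, implicit-solvent model
  or integrator: generators produce geometry, not thermodynamics.
- Hydrogen-bond detection assumes explicit or reconstructible amide
  hydrogens; the reconstruction (external bisector of C(prev)–N–Cα,
  1.0 Å) is idealized planar-amide geometry and skips chain-initial
  residues.
- Binding-site atom selection on the first selected frame can differ
  from a per-frame definition when the ligand migrates; the per-frame
  union option exists but changes the atom set and hence RMSD values.
- The correlation statistic's normalization is deliberately dual
  (co-occurrence frequency and phi); neither is claimed canonical.
- Binary trajectory formats (DCD/XTC), PDBx/mmCIF and NMR-STAR are out
  of scope.
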
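# oligorder

Trajectory analysis for the early, ordered aggregation of short amyloid
peptides — and for how a small molecule disrupts it.

Small fragments of the amyloid-beta peptide (e.g. the central region
around Phe19/Phe20) assemble into ordered beta-sheet oligomers. Whether
a candidate aggregation inhibitor breaks that order is usually judged
from multi-microsecond simulations of a few peptide replicas with and
without the ligand. `oligorder` implements the complete analysis layer
of that experiment as a tested, reusable library:

- **Nematic order parameter (P2).** For every frame, unit "molecular
  vectors" are built joining the Cα of residue *i* to the Cα of residue
  *i*+2 in each peptide chain (a chain of length *L* gives *L* − 2
  vectors). The order matrix

  Q = (1/N) Σₖ ( 3/2 ûₖ ûₖᵀ − 1/2 **I** )

  is traceless and symmetric; P2 is its largest eigenvalue and the
  corresponding eigenvector is the director. P2 = 1 when all vectors are
  parallel or antiparallel (an in-register sheet), and ≈ 0 for an
  isotropic, disordered arrangement. Frames are classified ordered when
  P2 > P2\* (default crossover 0.665), and summarized by the
  order:disorder event ratio *r* = n(P2 > P2\*) / n(P2 < P2\*).
- **Inter-peptide energetics.** Truncated (7.5 Å) Lennard-Jones +
  Coulomb energy of each peptide with all other peptides, ligand terms
  always excluded; per-residue ligand van der Waals profiles that skip
  frames with no ligand contact at all.
- **Hydrogen bonds.** Geometric detection (H···O < 2.5 Å and N–H···O
  angle > 130°, strict), occupancy matrices for the ligand's labeled
  polar groups (NH1, CO1, CO2, CO3, NE1) with OR-collapsing of
  symmetry-equivalent atoms such as the two carboxylate oxygens, pair
  co-occurrence frequencies c₍ᵢⱼ₎ = (1/T) Σₜ hᵢ(t) hⱼ(t) and
  simultaneous-set probabilities.
- **Binding modes.** Frames forming a required set of hydrogen bonds
  simultaneously are clustered on binding-site heavy-atom RMSD
  (Kabsch superposition, deterministic leader algorithm, 1.5 Å cutoff),
  reporting cluster frequencies and medoid representatives.
- **NMR desk tools.** Amide chemical-shift deviation mapping between
  titration points (ppm ↔ Hz via the spectrometer frequency) and NOE
  restraint classification by sequence separation.
- **Synthetic ensembles.** Ground-truth generators — ideal
  parallel/antiparallel sheet trimers, self-avoiding disordered coils in
  a concentration-derived box, ordered/disordered mixtures, planted
  ligand poses and correlated binary H-bond series — so every stage is
  testable without any trajectory download.

## Worked example

```python
from oligorder import (SheetSpec, MixtureSpec, build_mixture_trajectory,
                       order_profile, order_disorder_ratio)

spec = MixtureSpec(n_frames=500, ordered_fraction=0.7,
                   sheet=SheetSpec(positional_noise_sigma=0.3, seed=42),
                   disordered_seed=7, box_side=98.0)
traj, truth = build_mixture_trajectory(spec)

prof = order_profile(traj)           # per-frame P2, director, label
rep = order_disorder_ratio(prof)
print(f"ordered: {rep.n_ordered}  disordered: {rep.n_disordered}  r = {rep.r:.3f}")
print(f"mean P2 (ordered frames):    {prof.p2[prof.labels].mean():.3f}")
print(f"mean P2 (disordered frames): {prof.p2[~prof.labels].mean():.3f}")
print(f"agreement with ground truth: {(prof.labels == truth).mean():.3f}")
```

prints

```
ordered: 350  disordered: 150  r = 2.333
mean P2 (ordered frames):    0.989
mean P2 (disordered frames): 0.235
agreement with ground truth: 1.000
```

i.e. the 70/30 planted mixture is recovered exactly: sheet frames sit
near P2 ≈ 0.99, coil frames near 0.24, and the 0.665 crossover separates
them without error at this noise level.

The same pipeline is available from the shell:

```sh
oligorder generate mixture --n-frames 500 --ordered-fraction 0.7 --seed 42 --out mix.pdb
oligorder order --input mix.pdb --threshold 0.665 --out order.csv
oligorder run --config run.yaml        # full generate -> order/energy/hbonds -> modes run
```

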
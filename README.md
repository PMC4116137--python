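# dockmap

Contact-map consensus analysis of protein–protein docking decoys, with
quantitative interface profiling, binding-mode comparison and
molecular-dynamics convergence metrics.

## The problem

Rigid-body docking of two proteins — in the motivating use case, an
idiotype antibody (Ab1) and the anti-idiotype antibody (Ab2) raised
against its binding site — produces hundreds to thousands of candidate
poses ("decoys") with no reliable single-pose energy score.  A robust way
to pick a representative model is *consensus of interface contacts*: a
residue pair (i on the receptor, j on the ligand) is a contact when any
pair of heavy atoms is closer than 5 Å, and a contact's **conservation
rate** is the fraction of decoys in the ensemble that contain it.  A
decoy's consensus score (the CONSRANK statistic) is the mean conservation
rate of its own contacts,

    S(m) = (1 / |C_m|) · Σ_{c ∈ C_m} f(c),      f(c) = n_c / N,

where `C_m` is decoy *m*'s contact set, `n_c` the number of decoys
containing contact *c*, and `N` the ensemble size.  Decoys whose
interface matches the most frequently observed contacts rank highest;
when a substantial fraction of decoys cluster near the true pose, the
top-ranked decoy is near-native.

Around that core the package implements the full post-docking analysis a
structural immunologist would run on the selected model:

* **contact maps** — binary (5 Å heavy-atom) and distance-range
  (7/10/13/16 Å) intermolecular residue–residue maps, map overlap
  (Jaccard), map rendering;
* **interface profile** — Shrake–Rupley solvent-accessible surface areas,
  interface area `(ASA_rec + ASA_lig − ASA_complex)/2`, interface residue
  lists (ΔASA > 1 Å²), geometric hydrogen bonds (donor–acceptor heavy
  atoms ≤ 3.5 Å) and salt bridges (opposite charged-group atoms ≤ 4 Å),
  polar fraction of the buried surface, per-residue % buried ASA;
* **superposition** — Kabsch fitting, ligand RMSD (fit one side, measure
  the other), whole-complex RMSD, and the fraction of atoms superposable
  below a target RMSD under iterative 2 % trimming;
* **trajectory metrics** — fitted RMSD series, radius of gyration,
  Cα-covariance PCA, RMSIP between the eigenvector sets of two trajectory
  halves, and the cosine content of principal-component projections
  (Hess's convergence diagnostic);
* **synthetic generators** — a deterministic toy complex with planted
  interface chemistry, rigid-body decoy ensembles with a controllable
  near-native fraction, and fluctuation/drift trajectories, so every
  stage is testable without external data.

## Worked example

```sh
python examples/02_consensus_ranking.py
```

```
top 5 decoys by consensus score (mean contact-conservation rate):
  near_014   score=0.3033  (6 contacts)
  near_009   score=0.2971  (7 contacts)
  near_010   score=0.2971  (7 contacts)
  near_003   score=0.2900  (8 contacts)
  far_031    score=0.2850  (4 contacts)

6 contacts conserved in at least 25% of the 50 decoys;
...
ligand-RMSD of the top-ranked decoy to the native pose: 1.95 A
(below 5 A = near-native: consensus ranking recovered the planted cluster)
```

Fifty decoys are generated around the toy complex, 30 % of them
near-native; the consensus score concentrates on the contacts the
near-native cluster shares, so a near-native decoy tops the table and its
ligand RMSD to the native pose confirms it.  The other example scripts
cover contact maps (`01`), the Table-style interface report (`03`),
superposition metrics (`04`) and trajectory convergence (`05`).

The same operations are available from the shell:

```sh
dockmap synth complex --seed 7 -o toy.pdb
dockmap synth decoys --native toy.pdb --n 50 --near-frac 0.3 --seed 7 -o decoys/
dockmap rank --decoys decoys/*.pdb --receptor A --ligand B
dockmap interface --pdb toy.pdb --receptor A --ligand B
```

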
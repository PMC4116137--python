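# Methods

This note documents the models, conventions and numerical choices behind
dockmap, in the order of the analysis pipeline.  Everything stated here
is either a definition or is exercised by the test suite /
`scripts/acceptance.py`; no empirical claim is made that the code does
not itself compute.

## Structures and conventions

Structures are a chain → residue → atom hierarchy read from PDB files
through gemmi.  Author residue numbering and insertion codes are kept
verbatim (antibody Chothia-style labels such as `Asp52a_H` only survive
if insertion codes do), waters are always dropped, other heteroatoms are
dropped by default, and for altloc duplicates the highest-occupancy
conformer is kept (ties → first altloc alphabetically).  Hydrogens, when
present, stay in the model but are excluded from all contact and surface
math, which keeps hydrogen-free crystallographic inputs and modelled
structures comparable.

The receptor/ligand split of a complex is an explicit `Partition` of
chain identifiers (for an idiotype–anti-idiotype pair: Ab1 chains vs Ab2
chains).  All interface quantities are strictly inter-partition.

Residue polarity: the twenty standard residues are split 10/10 into
hydrophobic {ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO, GLY, CYS} and
hydrophilic {SER, THR, ASN, GLN, TYR, HIS, LYS, ARG, ASP, GLU}.  GLY and
CYS sit on the hydrophobic side, following the sign of the
Kyte–Doolittle scale; the assignment is configurable in
`classify_residue` (non-standard residues fall back to hydrophilic with
a warning).

## Contact maps

Two residues across the partition are in contact when the minimum over
their heavy-atom pairs of the Euclidean distance is below the cutoff;
5 Å is the default because every downstream count is tied to it (an 8 Å
visual convention exists in web servers but is deliberately not the
default).  A k-d tree restricts which atom pairs are examined; the
recorded minima are exact, and the suite asserts identity with a
brute-force all-pairs scan.  Contacts are classed phil-phil, phob-phob
or mixed from the two residues' polarity; the three classes partition
the contact set.  The distance-range map assigns each residue pair the
smallest of the thresholds 7/10/13/16 Å that its closest atom pair
beats, so every 5 Å contact falls in the 7 Å bin.

## Consensus scoring and ranking

For an ensemble of N decoy maps (same complex, same cutoff), each
contact observed anywhere gets rate k/N, with k the number of decoys
containing it.  A decoy's score is the mean rate over its own contacts —
normalising by the decoy's contact count so large interfaces are not
trivially favoured; an un-normalised sum is available behind a flag.
The consensus includes the decoy being scored (appropriate for the large
cluster-centroid ensembles the method is used on); a leave-one-out mode
subtracts the self-contribution exactly and is recommended only for
small ensembles.  Ranking is deterministic: score descending, ties
broken by model label ascending.  An empty contact map scores 0 with a
warning.  Sub-ensemble and pooled-ensemble rankings are just calls on
different map lists.

## Interface profile

SASA is Shrake–Rupley sphere sampling on heavy atoms: each atom's
accessible area is `4π(r+1.4)²` times the unoccluded fraction of a
960-point Fibonacci (golden-spiral) lattice on its probe-expanded
sphere.  The lattice is deterministic — no RNG — so results are exactly
reproducible, and doubling the point count moves the toy interface area
by well under 1 %.  Van der Waals radii: C 1.70, N 1.55, O 1.52,
S 1.80 Å, 1.80 Å fallback.  The suite cross-checks totals against
biotite's independent Shrake–Rupley with matched radii.

* Interface area = `(ASA_receptor-alone + ASA_ligand-alone −
  ASA_complex)/2`, components extracted with coordinates unchanged.  By
  construction the summed per-residue buried ASA over both sides equals
  twice this area.
* Interface residues: ASA drop > 1 Å² upon complexation.  A ΔASA
  criterion (not a contact criterion) is used because burial reaches
  residues beyond the 5 Å shell.
* Hydrogen bonds: inter-partition donor–acceptor heavy-atom pairs at
  ≤ 3.5 Å, using per-residue donor/acceptor dictionaries (backbone N
  donates except proline, backbone O/OXT accepts; side chains per
  residue chemistry; Ser/Thr/Tyr hydroxyls and His ring nitrogens act in
  either role, each atom pair reported once).  No angular term: typical
  inputs lack hydrogens, and reproducibility is preferred over chemical
  strictness.  The cutoff is a flag.
* Salt bridges: pairs of oppositely charged group atoms (Lys NZ;
  Arg NE/NH1/NH2; His ND1/NE2 — His is treated as positively charged,
  protonation states are not computed — vs Asp OD1/OD2, Glu OE1/OE2,
  C-terminal OXT) at ≤ 4.0 Å, one bridge per residue pair (closest atom
  pair kept).  Every salt bridge within 3.5 Å is by construction also
  counted among the hydrogen bonds.
* % polar buried surface: the share of the summed per-atom ΔASA carried
  by nitrogen and oxygen atoms.  This area-based definition is the
  operational one; a residue-count-based "% polar at the interface" is a
  different statistic and is not implemented.
* Per-residue % buried = `100·(ASA_component − ASA_complex)/ASA_component`;
  residues with under 1 Å² accessible surface in the isolated component
  are reported as undefined rather than 100 %.

## Superposition and binding-mode comparison

Kabsch fitting via SVD of the cross-covariance, reflection corrected by
flipping the smallest singular vector, so the rotation is always proper;
degenerate (collinear) inputs are rejected.  Atom correspondence between
two poses of the same complex is by identical (chain, residue number,
insertion code, atom name); cross-complex comparison requires an
explicit correspondence — sequence alignment is out of scope.  Ligand
RMSD fits one partition side (backbone N/CA/C/O by default) and measures
the other without refitting; both fit directions are available since
published tables use either convention.  The matched-fraction statistic
fits, drops the worst 2 % of pairs by post-fit deviation, and refits
until the RMSD over the retained pairs reaches the target or fewer than
three pairs remain; it is a simple deterministic stand-in for
structure-alignment-server coverage statistics and is not equivalent to
LGA.

## Trajectory metrics

Trajectories are ordered frames over a fixed atom selection (multi-model
PDB or a plain-text xyz-per-frame format; binary MD formats are not
parsed — conversion is the user's job, the analysis math is the point
here).  Per-frame RMSD Kabsch-fits each frame to the reference first.
Radius of gyration is mass-weighted by default (unweighted and nm output
available).  PCA fits frames to the first frame, averages, refits once
to the mean (the standard single-iteration essential-dynamics practice),
then eigendecomposes the 3n-dimensional coordinate covariance via SVD of
the centred frame matrix with the n_frames−1 divisor; at most
min(n_frames−1, 3n) modes exist.  RMSIP over the first k=10 modes is
`sqrt((1/k)ΣΣ(v_i·w_j)²)`.  Cosine content of a projection p is
`(2/T)(Σ_t p(t)cos(iπt/T))²/Σ_t p(t)²` with t = 0…T−1 and mean-centred
p; i is the 1-based mode index.  Split-half convergence runs PCA on each
trajectory half independently, reports their RMSIP, and the cosine
contents of the full trajectory's leading projections.  Note the
expectation of the cosine content of an i.i.d. (white-noise) series is
≈ 1/T, the baseline against which "low" is judged; values near 1 flag
diffusion-like, unconverged sampling.

## Synthetic generators

The generators exist to give every analysis stage inputs whose ground
truth is known, and their defaults are the conditions under which the
package's claims are tested.

**Toy complex.**  Two chains of 12 residues, each a two-strand slab: a
facing strand whose side chains point at the partner and an
outward-facing backing strand 5 Å behind it.  Residues come from
ideal-geometry templates (GLY, ALA, VAL, LEU, SER, ASN, ASP, GLU, LYS,
ARG, TYR; backbone + side-chain heavy atoms, no Ramachandran realism —
distance-based analytics only).  Facing columns sit 4.2 Å apart along
the strand with an alternating 1.6 Å z-stagger (bulky neighbouring side
chains would otherwise clash); per column, the partner backbone height
is solved so designated tip atoms meet at their target distance,
planting Lys–Asp and Arg–Glu salt bridges (2.9–3.0 Å), Ser–Tyr and
Tyr–Asn hydrogen bonds, and a Leu–Leu hydrophobic contact (4.0 Å) — so
the complex is guaranteed to show ≥ 1 salt bridge, ≥ 2 H-bonds and both
contact polarity classes at 5 Å; the builder asserts the planted
distances after construction.  A seeded 0.03 Å jitter makes different
seeds give distinct complexes; the same seed is bit-reproducible.  The
backing strands give the bodies bulk: with bare single strands, random
touching poses re-find the native contact register far too easily.

**Decoy ensembles.**  Near-native decoys perturb the ligand rigidly by a
Gaussian translation (σ 1.5 Å) and a rotation of Gaussian angle (σ 5°)
about a random axis through its centroid, resampling (≤ 100 draws) until
the backbone ligand-RMSD is below the 5 Å near-native criterion — an
unconstrained draw violates the label ~1 % of the time.  Far decoys get
a uniform random orientation and are placed along a random direction
through a random receptor surface atom, sliding until the minimum
inter-side heavy-atom distance lies in [3, 5] Å (touching,
non-clashing; the 1-Lipschitz dependence of the minimum distance on the
slide offset makes the search a few jumps).  A far pose is accepted only
if it forms a touching patch of at least 3 residue contacts at 5 Å:
real docking decoys always bury a multi-residue patch, and a
single-grazing-contact "decoy" sitting on the ensemble's most conserved
contact would outscore any genuine near-native decoy's mean rate by
construction — an artefact of mean-rate scoring on degenerate
interfaces, not a property of docking ensembles.  The approach-anchor
randomisation matters for the same reason: approaching through the
centroid concentrates all far contacts on the tallest central side
chains and manufactures a spurious far consensus.  Decoy titles encode
the ground truth (`near_###`/`far_###`).  Under the default study
conditions (50 decoys, near fraction 0.3) the consensus ranking places a
near-native decoy first in ≈ 98–99 of 100 seeded replicates, which the
acceptance suite requires to be ≥ 95.

**Trajectories.**  `frame_t = ref + N(0, σ²) + A·cos(πt/T)·v` over a
selection (Cα by default), with v a fixed unit 3n-vector (seeded random
for "auto").  σ is the harmonic fluctuation scale (default 0.3 Å, a
typical equilibrated Cα RMSF magnitude), A the drift amplitude; dominant
drift produces a first principal component whose projection is a
half-period cosine — the textbook unconverged-sampling signature — and
A = 0 gives a stationary trajectory whose split halves share no
preferred mode beyond noise.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: side-chain flexibility and repacking, backbone
conformational change on binding, solvent, crystallographic artefacts,
and docking-energy-shaped (funnel-correlated) decoy distributions.  The
synthetic results validate the *statistics and the machinery*, not
docking accuracy on real complexes; the crystal-structure anchor tests
(PDB 1DVF, user-supplied at `data/1dvf.pdb`) are the real-data check of
the interface descriptors.

## Numerical notes and limitations

* SASA discretisation: 960 lattice points give isolated-sphere areas
  within 0.1 % of closed form; per-atom areas on dense clusters are
  accurate to a few %.  Counts derived from thresholds (interface
  residues, > 50 % buried) can shift by ±1–2 residues with the point
  count; the anchor tolerances absorb this.
* H-bond/salt-bridge counts are geometric and hydrogen-free by design;
  against experimentally curated counts they are approximations with a
  tolerance of a few bonds.
* Problem sizes in tests and the acceptance script (24-residue toy
  complexes, ensembles of 40–100 decoys, 100-replicate recovery runs,
  trajectories of 30–200 frames) were chosen so the whole validation
  cycle completes in about a minute while every statistic is measured,
  not asserted.
* The contact/consensus machinery scales to real Fv–Fv complexes
  (hundreds of residues, thousands of atoms) through the k-d-tree paths;
  the SASA implementation is O(atoms × neighbours × points) and takes a
  few seconds on an Fv–Fv complex.
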
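"""Stability and convergence metrics of a trajectory.

Generates two synthetic C-alpha trajectories around the toy complex —
one stationary (harmonic fluctuation only) and one with a slow cosine
drift along a collective mode — and contrasts the convergence
diagnostics: RMSIP between the two halves' essential subspaces, and the
cosine content of the leading principal-component projections.
"""

import numpy as np

import dockmap as dm

ref = dm.make_toy_complex(seed=0)

for label, spec in [
    ("stationary", dm.TrajectorySpec(200, noise_sigma=0.3, seed=5)),
    ("drifting", dm.TrajectorySpec(200, noise_sigma=0.3, drift_amplitude=3.0, seed=5)),
]:
    t = dm.generate_trajectory(ref, spec)
    rmsd = dm.traj_rmsd(t, t.frames[0])
    rgyr = dm.radius_of_gyration(t, mass_weighted=True)
    rmsip_halves, cosines = dm.split_half_convergence(t, k=10)
    print(f"{label} trajectory ({t.n_frames} frames, {t.n_atoms} CA atoms):")
    print(f"  RMSD to frame 0:      {rmsd.mean():.2f} +/- {rmsd.std():.2f} A")
    print(f"  radius of gyration:   {rgyr.mean():.2f} A "
          f"({rgyr.mean() / 10:.3f} nm)")
    print(f"  RMSIP of halves (10): {rmsip_halves:.3f}")
    print(f"  cosine content PC1:   {cosines[0]:.3f}\n")

print("A drifting trajectory shows cosine content near 1 on its first PC —")
print("the signature of unconverged, diffusion-like sampling — while its")
print("half-vs-half RMSIP is inflated by the shared drift mode.  Converged")
print("sampling pairs a high RMSIP with low cosine content.")
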
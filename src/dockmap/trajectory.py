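"""Stability and convergence metrics for coordinate trajectories.

Implements the standard essential-dynamics toolbox: least-squares-fitted
RMSD time series, radius of gyration, principal component analysis of the
Cartesian covariance, root mean square inner product (RMSIP) between
eigenvector sets, and the cosine content of principal-component
projections.  RMSIP near 1 between independently analysed trajectory
halves, together with low cosine content of the leading projections,
indicates converged sampling; cosine content near 1 is the signature of
random-walk-like drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Structure, read_pdb_models, select
from .superpose import kabsch


@dataclass
class Trajectory:
    """Ordered frames over a fixed atom selection: (n_frames, n_atoms, 3) in A."""

    frames: np.ndarray
    atom_keys: list | None = None
    masses: np.ndarray | None = None
    dt_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def __getitem__(self, idx) -> "Trajectory":
        frames = self.frames[idx]
        if frames.ndim == 2:
            frames = frames[None]
        return Trajectory(frames, self.atom_keys, self.masses, self.dt_label)


@dataclass
class ModeSet:
    """Orthonormal 3n-dimensional eigenvectors with descending eigenvalues (A^2)."""

    eigenvectors: np.ndarray  # (3n, n_modes), column-major modes
    eigenvalues: np.ndarray  # (n_modes,)
    mean_structure: np.ndarray  # (n_atoms, 3)

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]


# ---------------------------------------------------------------------------
# I/O

def trajectory_from_pdb(path: str, atom_class: str = "calpha",
                        chains: set[str] | None = None) -> Trajectory:
    """Load a multi-model PDB as a trajectory over a fixed atom selection."""
    models = read_pdb_models(path)
    structures = []
    for m in models:
        sel_chains = set(chains) if chains else set(m.chain_ids)
        structures.append(select(m, sel_chains, atom_class))
    keys = [(r.key, a.name) for r in structures[0].residues() for a in r.atoms]
    masses = np.array([a.mass for r in structures[0].residues() for a in r.atoms])
    frames = []
    for s in structures:
        k = [(r.key, a.name) for r in s.residues() for a in r.atoms]
        if k != keys:
            raise ValueError("models differ in atom content; cannot form a trajectory")
        frames.append(s.coords(heavy_only=False))
    return Trajectory(np.array(frames), keys, masses)


def trajectory_from_structure(ref: Structure, frames: np.ndarray,
                              atom_class: str = "all") -> Trajectory:
    sel = select(ref, set(ref.chain_ids), atom_class)
    keys = [(r.key, a.name) for r in sel.residues() for a in r.atoms]
    masses = np.array([a.mass for r in sel.residues() for a in r.atoms])
    return Trajectory(frames, keys, masses)


def read_xyz_frames(path: str) -> Trajectory:
    """Read the plain-text frames format: first line n_atoms, then one
    whitespace-separated ``x y z`` row per atom, frames concatenated."""
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise ValueError(f"{path}: empty trajectory file")
    n_atoms = int(tokens[0])
    values = np.array(tokens[1:], dtype=float)
    if values.size % (3 * n_atoms):
        raise ValueError(f"{path}: truncated frame data")
    return Trajectory(values.reshape(-1, n_atoms, 3))


def write_xyz_frames(t: Trajectory, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{t.n_atoms}\n")
        for frame in t.frames:
            for x, y, z in frame:
                fh.write(f"{x:.4f} {y:.4f} {z:.4f}\n")


# ---------------------------------------------------------------------------
# metrics

def _fit_frames(frames: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Kabsch-fit every frame onto *ref*; returns the fitted copies."""
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        out[i] = kabsch(ref, frame).apply(frame)
    return out


def traj_rmsd(t: Trajectory, ref: np.ndarray | Structure) -> np.ndarray:
    """Per-frame RMSD (A) to *ref* after least-squares fitting each frame."""
    if isinstance(ref, Structure):
        ref = ref.coords(heavy_only=False)
    ref = np.asarray(ref, dtype=float)
    if ref.shape != (t.n_atoms, 3):
        raise ValueError(f"reference shape {ref.shape} != (n_atoms, 3)")
    fitted = _fit_frames(t.frames, ref)
    return np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=2), axis=1))


def radius_of_gyration(t: Trajectory, mass_weighted: bool = True,
                       unit: str = "angstrom") -> np.ndarray:
    """Per-frame radius of gyration, sqrt(sum m |r - r_com|^2 / sum m).

    ``unit`` is ``"angstrom"`` or ``"nm"``.  Unweighted uses unit masses.
    """
    if t.n_atoms == 0:
        raise ValueError("trajectory has no atoms")
    if mass_weighted:
        if t.masses is None:
            raise ValueError("mass-weighted Rgyr requires atom masses")
        m = np.asarray(t.masses, dtype=float)
    else:
        m = np.ones(t.n_atoms)
    w = m / m.sum()
    com = np.einsum("i,fij->fj", w, t.frames)
    d2 = np.sum((t.frames - com[:, None, :]) ** 2, axis=2)
    rg = np.sqrt(d2 @ w)
    if unit == "nm":
        return rg / 10.0
    if unit != "angstrom":
        raise ValueError(f"unknown unit {unit!r}")
    return rg


def pca_modes(t: Trajectory) -> ModeSet:
    """Essential-dynamics PCA of the Cartesian covariance.

    Frames are rigid-body fitted to the first frame, averaged, then refit
    once to that mean (single refit iteration, the common essential-
    dynamics practice).  Eigenpairs come from the SVD of the centered
    (n_frames x 3n) coordinate matrix; eigenvalues use the n_frames - 1
    divisor.  At most min(n_frames - 1, 3n) modes are returned.
    """
    if t.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    fitted = _fit_frames(t.frames, t.frames[0])
    mean = fitted.mean(axis=0)
    fitted = _fit_frames(fitted, mean)
    mean = fitted.mean(axis=0)
    x = (fitted - mean).reshape(t.n_frames, -1)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    eigenvalues = s**2 / (t.n_frames - 1)
    n_keep = min(t.n_frames - 1, x.shape[1])
    return ModeSet(vt[:n_keep].T.copy(), eigenvalues[:n_keep], mean)


def rmsip(a: ModeSet, b: ModeSet, k: int = 10) -> float:
    """Root mean square inner product of the first *k* modes of two sets.

    ``sqrt((1/k) sum_i sum_j (v_i . w_j)^2)``; 1 for identical subspaces,
    0 for orthogonal ones.
    """
    if a.eigenvectors.shape[0] != b.eigenvectors.shape[0]:
        raise ValueError("mode sets live in different dimensions")
    if k < 1 or k > a.n_modes or k > b.n_modes:
        raise ValueError(f"k={k} exceeds available modes ({a.n_modes}, {b.n_modes})")
    overlap = a.eigenvectors[:, :k].T @ b.eigenvectors[:, :k]
    return float(np.sqrt(np.sum(overlap**2) / k))


def cosine_content(projection: np.ndarray, mode_index: int = 1) -> float:
    """Cosine content of a principal-component projection time series.

    ``c_i = (2/T) (sum_t p(t) cos(i pi t / T))^2 / sum_t p(t)^2`` with
    ``t = 0..T-1`` and mean-centered ``p``.  Near 1 means the projection is
    indistinguishable from the *i*-th cosine mode of a random diffusion.
    """
    p = np.asarray(projection, dtype=float)
    if p.ndim != 1 or p.size < 4:
        raise ValueError("projection must be a 1-D series of length >= 4")
    if mode_index < 1:
        raise ValueError("mode_index is 1-based")
    p = p - p.mean()
    denom = float(np.sum(p**2))
    if denom <= 0:
        raise ValueError("zero-variance projection")
    T = p.size
    t = np.arange(T)
    num = float(np.sum(p * np.cos(mode_index * np.pi * t / T))) ** 2
    return (2.0 / T) * num / denom


def project(t: Trajectory, modes: ModeSet, k: int = 10) -> np.ndarray:
    """Projections of the fitted, mean-centered frames on the first k modes.

    Returns an (n_frames, k) array.
    """
    if k > modes.n_modes:
        raise ValueError(f"k={k} exceeds available modes ({modes.n_modes})")
    fitted = _fit_frames(t.frames, modes.mean_structure)
    x = (fitted - modes.mean_structure).reshape(t.n_frames, -1)
    return x @ modes.eigenvectors[:, :k]


def split_half_convergence(t: Trajectory, k: int = 10) -> tuple[float, np.ndarray]:
    """Convergence diagnostics: halves' RMSIP and full-trajectory cosine contents.

    The trajectory is split in half; PCA is run independently on each half
    and the RMSIP of their first *k* eigenvectors is reported, together
    with the cosine content of the first *k* projections of the full
    trajectory on its own modes.
    """
    if t.n_frames < 4:
        raise ValueError("need at least 4 frames to split")
    half = t.n_frames // 2
    first, second = pca_modes(t[:half]), pca_modes(t[half:])
    full = pca_modes(t)
    k_eff = min(k, first.n_modes, second.n_modes, full.n_modes)
    value = rmsip(first, second, k_eff)
    proj = project(t, full, k_eff)
    cosines = np.array(
        [cosine_content(proj[:, i], i + 1) for i in range(k_eff)]
    )
    return value, cosines
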
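"""Rigid-body superposition and RMSD-based binding-mode comparison.

Least-squares fitting uses the Kabsch algorithm (SVD of the cross
covariance, reflection corrected), the standard for comparing docking
poses.  Ligand RMSD fits one side of a complex and measures the other
without refitting — the usual measure of how far two binding modes
diverge; the matched-fraction routine iteratively trims the worst-fitting
atom pairs until the remainder superposes below a target RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Partition, Structure, select

AtomPairKey = tuple


@dataclass
class SuperposeResult:
    rotation: np.ndarray  # 3x3, proper (det +1)
    translation: np.ndarray  # 3-vector, A
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class AtomCorrespondence:
    """Explicit one-to-one pairing of atom keys between two structures."""

    pairs: list[tuple[AtomPairKey, AtomPairKey]]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("empty correspondence")
        a_keys = [p[0] for p in self.pairs]
        b_keys = [p[1] for p in self.pairs]
        if len(set(a_keys)) != len(a_keys) or len(set(b_keys)) != len(b_keys):
            raise ValueError("correspondence is not one-to-one")


def _as_matrix(coords) -> np.ndarray:
    c = np.asarray(coords, dtype=float)
    if c.ndim != 2 or c.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array")
    return c


def kabsch(coords_a, coords_b) -> SuperposeResult:
    """Optimal proper-rotation + translation fit of *coords_b* onto *coords_a*.

    Returns the transform minimizing the RMSD of ``R b + t`` to ``a``.
    A reflection in the SVD solution is corrected by flipping the sign of
    the smallest singular vector, so the rotation always has det +1.
    """
    a, b = _as_matrix(coords_a), _as_matrix(coords_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("at least 3 atom pairs are required")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    s = np.linalg.svd(b0.T @ a0, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1e-12):
        raise ValueError("degenerate (collinear) configuration")
    u, _, vt = np.linalg.svd(b0.T @ a0)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = ca - rotation @ cb
    fitted = b @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - a) ** 2, axis=1))))
    return SuperposeResult(rotation, translation, rmsd, len(a))


def _matched_coords(c1: Structure, c2: Structure, chains: set[str],
                    atom_class: str) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of atoms shared by key between two complexes, same order."""
    s1 = select(c1, chains, atom_class)
    s2 = select(c2, chains, atom_class)

    def keyed(s: Structure) -> dict:
        return {(r.key, a.name): a.coord for r in s.residues() for a in r.atoms}

    k1, k2 = keyed(s1), keyed(s2)
    common = [k for k in k1 if k in k2]
    missing = [k for k in k1 if k not in k2] + [k for k in k2 if k not in k1]
    if not common:
        raise ValueError("no matching atoms between the two structures")
    if missing:
        raise ValueError(
            f"residue/atom content mismatch; {len(missing)} unmatched keys, "
            f"e.g. {missing[:5]}"
        )
    return (np.array([k1[k] for k in common]), np.array([k2[k] for k in common]))


def ligand_rmsd(
    c1: Structure, c2: Structure, p: Partition,
    fit_side: str = "ligand", atom_class: str = "backbone",
) -> float:
    """RMSD of one binding partner after best-fitting the other.

    The *fit_side* atoms define the superposition; the RMSD is then
    measured over the opposite side's atoms without refitting.  Atoms are
    paired by identical (chain, residue number, insertion code, atom name).
    """
    if fit_side not in ("receptor", "ligand"):
        raise ValueError("fit_side must be 'receptor' or 'ligand'")
    fit_chains = set(p.ligand_chains if fit_side == "ligand" else p.receptor_chains)
    measure_chains = set(p.receptor_chains if fit_side == "ligand" else p.ligand_chains)
    fa, fb = _matched_coords(c1, c2, fit_chains, atom_class)
    fit = kabsch(fa, fb)
    ma, mb = _matched_coords(c1, c2, measure_chains, atom_class)
    moved = fit.apply(mb)
    return float(np.sqrt(np.mean(np.sum((moved - ma) ** 2, axis=1))))


def complex_rmsd(c1: Structure, c2: Structure, atom_class: str = "heavy") -> float:
    """RMSD over all matched atoms after a single global best fit."""
    a, b = _matched_coords(c1, c2, set(c1.chain_ids) & set(c2.chain_ids), atom_class)
    return kabsch(a, b).rmsd


def matched_fraction(
    c1: Structure, c2: Structure, corr: AtomCorrespondence, rmsd_max: float = 5.0,
) -> tuple[float, SuperposeResult]:
    """Fraction of corresponding atoms superposable below *rmsd_max*.

    Iterative trimming: fit on the current pair set, drop the worst 2% of
    pairs by post-fit deviation, refit — until the RMSD over the retained
    pairs is at or below the threshold or fewer than 3 pairs remain.
    Deterministic stand-in for the structure-alignment-server statistic;
    not equivalent to LGA.
    """

    def lookup(s: Structure) -> dict:
        return {(r.key, a.name): a.coord for r in s.residues() for a in r.atoms}

    l1, l2 = lookup(c1), lookup(c2)
    try:
        a = np.array([l1[ka] for ka, _ in corr.pairs])
        b = np.array([l2[kb] for _, kb in corr.pairs])
    except KeyError as err:
        raise ValueError(f"correspondence key absent from structure: {err}") from err

    n_total = len(a)
    keep = np.arange(n_total)
    while True:
        fit = kabsch(a[keep], b[keep])
        if fit.rmsd <= rmsd_max:
            return len(keep) / n_total, fit
        if len(keep) <= 3:
            return len(keep) / n_total, fit  # flagged by fit.rmsd > rmsd_max
        dev = np.sum((fit.apply(b[keep]) - a[keep]) ** 2, axis=1)
        n_drop = max(1, int(np.ceil(0.02 * len(keep))))
        keep = keep[np.argsort(dev)[: len(keep) - n_drop]]
        keep.sort()
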
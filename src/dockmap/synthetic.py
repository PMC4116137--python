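"""Synthetic complexes, decoy ensembles and trajectories.

These generators produce inputs with the statistical structure the
analysis stages assume, so the whole pipeline can be exercised and
validated without external data:

* a deterministic two-chain toy complex with planted salt bridges,
  hydrogen bonds, and both hydrophilic-hydrophilic and
  hydrophobic-hydrophobic contacts at the 5 A criterion;
* rigid-body decoy ensembles around that native pose with a controllable
  near-native fraction — near decoys are small Gaussian perturbations of
  the native ligand placement, far decoys are re-oriented and re-placed at
  touching (non-clashing) random positions, giving non-empty but mutually
  inconsistent contact maps, the regime consensus ranking exploits;
* harmonic-fluctuation trajectories around a reference with an optional
  slow half-period cosine drift along one collective mode.

Every generator is a pure function of its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure import Atom, Partition, Residue, Structure, select
from .trajectory import Trajectory

# Ideal-geometry residue templates in a local frame: backbone in the
# xz-ish plane, side chain extending along +y.  Bond geometry is
# idealized; no Ramachandran realism — sufficient for distance-based
# analytics.
_BACKBONE = [
    ("N", "N", (-1.20, 0.43, 0.00)),
    ("CA", "C", (0.00, 0.00, 0.00)),
    ("C", "C", (1.25, 0.43, 0.00)),
    ("O", "O", (1.37, 1.65, 0.05)),
]
_SIDECHAINS: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [("CB", "C", (0.00, 1.53, 0.00))],
    "VAL": [("CB", "C", (0.00, 1.53, 0.00)), ("CG1", "C", (1.20, 2.30, 0.10)),
            ("CG2", "C", (-1.10, 2.35, -0.10))],
    "LEU": [("CB", "C", (0.00, 1.53, 0.00)), ("CG", "C", (0.10, 2.95, 0.10)),
            ("CD1", "C", (1.25, 3.65, 0.00)), ("CD2", "C", (-1.05, 3.70, 0.20))],
    "SER": [("CB", "C", (0.00, 1.53, 0.00)), ("OG", "O", (0.15, 2.92, 0.05))],
    "ASN": [("CB", "C", (0.00, 1.53, 0.00)), ("CG", "C", (0.10, 2.90, 0.00)),
            ("OD1", "O", (1.17, 3.55, 0.05)), ("ND2", "N", (-0.98, 3.60, 0.15))],
    "ASP": [("CB", "C", (0.00, 1.53, 0.00)), ("CG", "C", (0.10, 2.90, 0.00)),
            ("OD1", "O", (1.17, 3.55, 0.05)), ("OD2", "O", (-0.98, 3.60, 0.15))],
    "GLU": [("CB", "C", (0.00, 1.53, 0.00)), ("CG", "C", (0.10, 2.90, 0.00)),
            ("CD", "C", (0.05, 4.30, 0.05)), ("OE1", "O", (1.12, 4.95, 0.10)),
            ("OE2", "O", (-1.00, 5.00, 0.15))],
    "LYS": [("CB", "C", (0.00, 1.53, 0.00)), ("CG", "C", (0.10, 2.90, 0.00)),
            ("CD", "C", (0.00, 4.35, 0.10)), ("CE", "C", (0.10, 5.75, 0.05)),
            ("NZ", "N", (0.05, 7.05, 0.10))],
    "ARG": [("CB", "C", (0.00, 1.53, 0.00)), ("CG", "C", (0.10, 2.90, 0.00)),
            ("CD", "C", (0.00, 4.35, 0.10)), ("NE", "N", (0.10, 5.70, 0.05)),
            ("CZ", "C", (0.05, 7.00, 0.10)), ("NH1", "N", (1.15, 7.70, 0.05)),
            ("NH2", "N", (-1.05, 7.65, 0.20))],
    "TYR": [("CB", "C", (0.00, 1.53, 0.00)), ("CG", "C", (0.10, 2.90, 0.00)),
            ("CD1", "C", (1.25, 3.60, 0.05)), ("CD2", "C", (-1.05, 3.65, 0.10)),
            ("CE1", "C", (1.25, 5.00, 0.05)), ("CE2", "C", (-1.05, 5.05, 0.10)),
            ("CZ", "C", (0.10, 5.75, 0.08)), ("OH", "O", (0.12, 7.10, 0.10))],
}

# Facing-column design: (chain A residue, chain B residue, A tip atom,
# B tip atom, target tip-tip distance in A; None = kept apart).  The first
# three columns plant a salt bridge (Lys-Asp), a hydrophobic contact
# (Leu-Leu) and a second hydrogen bond (Ser-Tyr), so every guarantee holds
# from n_res_per_chain >= 3.
_COLUMNS = [
    ("LYS", "ASP", "NZ", "OD1", 2.9),   # salt bridge + H-bond, phil-phil
    ("LEU", "LEU", "CD1", "CD1", 4.0),  # phob-phob contact
    ("SER", "TYR", "OG", "OH", 2.9),    # H-bond, phil-phil
    ("ARG", "GLU", "NH1", "OE1", 3.0),  # salt bridge + H-bond
    ("GLY", "GLY", None, None, None),
    ("TYR", "ASN", "OH", "OD1", 3.0),   # H-bond
    ("ALA", "VAL", None, None, None),
    ("ASP", "ARG", "OD1", "NH1", 2.9),  # salt bridge, reversed orientation
    ("VAL", "LEU", "CG1", "CD1", 4.2),  # phob-phob contact
    ("ASN", "SER", "ND2", "OG", 3.0),   # H-bond
    ("GLU", "LYS", "OE1", "NZ", 3.0),   # salt bridge
    ("GLY", "ALA", None, None, None),
]
_CA_SPACING = 4.2  # A between consecutive residue columns along x
_ZIGZAG_Z = 1.6  # A alternating z-stagger keeping bulky neighbour columns apart
NEAR_NATIVE_RMSD = 5.0  # A, standard ligand-RMSD bound for a near-native pose
_FAR_PLANE_GAP = 9.0  # tip-tip clearance for non-interacting columns
_BACK_STRAND_OFFSET = 5.0  # A between the facing strand and its backing strand


@dataclass(frozen=True)
class DecoyEnsembleSpec:
    """Parameters of a rigid-body decoy ensemble around a native pose."""

    n_decoys: int
    near_native_fraction: float
    near_sigma_t: float = 1.5  # A, translation spread of near-native decoys
    near_sigma_r: float = 5.0  # degrees, rotation spread of near-native decoys
    far_min_clearance: float = 3.0  # A, minimum inter-side gap of far decoys
    far_min_contacts: int = 3  # minimum touching-patch size (residue contacts at 5 A)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_decoys < 2:
            raise ValueError("n_decoys must be >= 2")
        if not 0.0 <= self.near_native_fraction <= 1.0:
            raise ValueError("near_native_fraction must be in [0, 1]")


@dataclass(frozen=True)
class TrajectorySpec:
    """Parameters of a harmonic-fluctuation + cosine-drift trajectory."""

    n_frames: int
    noise_sigma: float = 0.3  # A, isotropic per-atom fluctuation
    drift_amplitude: float = 0.0  # A, amplitude of the slow cosine mode
    drift_mode: np.ndarray | str = "auto"  # unit 3n-vector, or seeded random
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 4:
            raise ValueError("n_frames must be >= 4")
        if self.noise_sigma < 0 or self.drift_amplitude < 0:
            raise ValueError("sigmas must be non-negative")


def _template_atoms(res_name: str) -> list[tuple[str, str, np.ndarray]]:
    return [(n, e, np.array(xyz)) for n, e, xyz in _BACKBONE + _SIDECHAINS[res_name]]


def toy_partition() -> Partition:
    """The receptor/ligand split of the toy complex (chain A vs chain B)."""
    return Partition(frozenset("A"), frozenset("B"))


def make_toy_complex(seed: int = 0, n_res_per_chain: int = 12) -> Structure:
    """Deterministic two-chain complex with planted interface chemistry.

    Chain A and chain B are facing extended strands backed by a second,
    outward-facing strand each (a small two-strand slab per chain).  Per
    facing-column the chain-B backbone height is solved so designated
    side-chain tip atoms sit at their target distance, planting at least
    one salt bridge, two hydrogen bonds, and both polar-polar and
    apolar-apolar contacts within 5 A.  A small seeded jitter (sigma
    0.03 A) makes distinct seeds give distinct, still-valid complexes;
    the same seed is bit-reproducible.
    """
    if n_res_per_chain < 3:
        raise ValueError("n_res_per_chain must be >= 3")
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []
    planted: list[tuple[int, str, str, float]] = []

    # Each chain is a two-strand slab: the front strand carries the planted
    # interface (side chains toward the partner), the back strand faces
    # away, giving the bodies bulk so random touching poses land on many
    # distinct surface patches instead of re-finding the native register.
    n_front = max(3, (n_res_per_chain + 1) // 2)
    n_back = n_res_per_chain - n_front

    placements = []  # (column index, A res name, B res name, facing plane y)
    for i in range(n_front):
        a_name, b_name, a_tip, b_tip, target = _COLUMNS[i % len(_COLUMNS)]
        a_tmpl = dict((n, np.array(x)) for n, _, x in _BACKBONE + _SIDECHAINS[a_name])
        b_tmpl = dict((n, np.array(x)) for n, _, x in _BACKBONE + _SIDECHAINS[b_name])
        if target is None:
            ya = max(v[1] for v in a_tmpl.values())
            yb = max(v[1] for v in b_tmpl.values())
            plane = ya + yb + _FAR_PLANE_GAP
        else:
            ta, tb = a_tmpl[a_tip], b_tmpl[b_tip]
            dx, dz = ta[0] - tb[0], ta[2] - tb[2]
            dy = np.sqrt(target**2 - dx**2 - dz**2)
            plane = ta[1] + tb[1] + dy
            planted.append((i, a_tip, b_tip, target))
        placements.append((i, a_name, b_name, plane))

    def build(chain_id: str, res_name: str, seq_num: int, x0: float,
              y_ca: float, flip: bool) -> Residue:
        sign = -1.0 if flip else 1.0
        z0 = _ZIGZAG_Z if (seq_num - 1) % 2 else 0.0  # stagger adjacent columns
        atoms = [
            Atom(n, e, np.array([x0 + v[0], y_ca + sign * v[1], z0 + v[2]])
                 + rng.normal(0, 0.03, 3))
            for n, e, v in _template_atoms(res_name)
        ]
        return Residue(chain_id, seq_num, "", res_name, atoms)

    mean_plane = float(np.mean([pl for _, _, _, pl in placements]))
    for i, a_name, b_name, plane in placements:
        x0 = i * _CA_SPACING
        residues.append(build("A", a_name, i + 1, x0, 0.0, flip=False))
    for i in range(n_back):
        a_name = _COLUMNS[(i + 6) % len(_COLUMNS)][0]
        residues.append(build("A", a_name, n_front + i + 1, i * _CA_SPACING,
                              -_BACK_STRAND_OFFSET, flip=True))
    for i, a_name, b_name, plane in placements:
        x0 = i * _CA_SPACING
        res = build("B", b_name, i + 1, x0, plane, flip=True)
        residues.append(res)
    for i in range(n_back):
        b_name = _COLUMNS[(i + 6) % len(_COLUMNS)][1]
        residues.append(build("B", b_name, n_front + i + 1, i * _CA_SPACING,
                              mean_plane + _BACK_STRAND_OFFSET, flip=False))

    s = Structure(residues, title=f"toy complex seed={seed}")
    # geometric verification of the planted interactions at construction time
    for i, a_tip, b_tip, target in planted:
        ra = s.chains["A"][i].get_atom(a_tip)
        rb = s.chains["B"][i].get_atom(b_tip)
        d = float(np.linalg.norm(ra.coord - rb.coord))
        assert abs(d - target) < 0.5, f"planted distance off: col {i} {d:.2f} vs {target}"
    return s


def _min_interside_distance(rec: np.ndarray, lig: np.ndarray) -> float:
    d, _ = cKDTree(rec).query(lig, k=1)
    return float(d.min())


def generate_decoys(
    native: Structure, p: Partition, spec: DecoyEnsembleSpec
) -> list[Structure]:
    """Rigid-body decoy ensemble around a native pose.

    Near-native decoys perturb the ligand by a Gaussian translation
    (sigma ``near_sigma_t``) and a small rotation (sigma ``near_sigma_r``
    degrees about a random axis through the ligand centroid).  Far decoys
    give the ligand a uniform random orientation and re-place it along a
    random direction from the receptor so the minimum inter-side
    heavy-atom distance lands in ``[far_min_clearance, far_min_clearance
    + 2]`` — touching but non-clashing.  Decoy titles encode the ground
    truth (``near_###`` / ``far_###``).
    """
    p.validate(native)
    rng = np.random.default_rng(spec.seed)
    rec_coords, _, rec_residx = native.atom_table(p.receptor_chains, heavy_only=True)
    lig_coords, _, lig_residx = native.atom_table(p.ligand_chains, heavy_only=True)
    lig_centroid = lig_coords.mean(axis=0)
    rec_centroid = rec_coords.mean(axis=0)
    rec_tree = cKDTree(rec_coords)

    n_near = int(round(spec.n_decoys * spec.near_native_fraction))
    decoys: list[Structure] = []

    for i in range(spec.n_decoys):
        if i < n_near:
            # resample until the pose is genuinely near-native (backbone
            # ligand-RMSD below the standard 5 A near-native criterion);
            # an unconstrained Gaussian draw exceeds it ~1% of the time
            lig_bb = select(native, set(p.ligand_chains), "backbone").coords(
                heavy_only=False)
            for _ in range(100):
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                angle = np.deg2rad(rng.normal(0.0, spec.near_sigma_r))
                rot = Rotation.from_rotvec(angle * axis).as_matrix()
                t = rng.normal(0.0, spec.near_sigma_t, size=3)
                translation = lig_centroid - rot @ lig_centroid + t
                moved = lig_bb @ rot.T + translation
                if np.sqrt(np.mean(np.sum((moved - lig_bb) ** 2, axis=1))) < NEAR_NATIVE_RMSD:
                    break
            label = f"near_{i:03d}"
            decoy = native.transform(rot, translation, set(p.ligand_chains))
        else:
            lo, hi = spec.far_min_clearance, spec.far_min_clearance + 2.0
            r_rec = np.linalg.norm(rec_coords - rec_centroid, axis=1).max()
            placement = None
            for _ in range(1000):
                rot = Rotation.random(rng=rng).as_matrix()
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                # approach through a random surface anchor, not the centroid,
                # so far binding modes scatter over the whole receptor
                anchor = rec_coords[rng.integers(len(rec_coords))]
                lig_local = (lig_coords - lig_centroid) @ rot.T
                r_lig = np.linalg.norm(lig_local, axis=1).max()
                s_val = r_lig + spec.far_min_clearance
                target = (lo + hi) / 2.0
                for _ in range(60):
                    placed = lig_local + anchor + s_val * direction
                    d, _ = rec_tree.query(placed, k=1)
                    dmin = float(d.min())
                    if lo <= dmin <= hi:
                        break
                    # min distance is 1-Lipschitz in s: jumping by the
                    # residual never overshoots past the target clearance
                    s_val -= dmin - target
                else:
                    continue
                # accept only if a real touching patch forms: docking decoys
                # always bury a multi-residue interface, never a single
                # grazing atom contact
                pairs = set()
                for ai, js in enumerate(rec_tree.query_ball_point(placed, 5.0)):
                    for j in js:
                        pairs.add((int(rec_residx[j]), int(lig_residx[ai])))
                if len(pairs) >= spec.far_min_contacts:
                    placement = (rot, anchor + s_val * direction)
                    break
            if placement is None:
                raise RuntimeError(f"far decoy {i}: placement failed after 1000 tries")
            rot, new_centroid = placement
            translation = new_centroid - rot @ lig_centroid
            label = f"far_{i:03d}"
            decoy = native.transform(rot, translation, set(p.ligand_chains))
        decoy.title = label
        decoys.append(decoy)
    return decoys


def generate_trajectory(
    ref: Structure, spec: TrajectorySpec, atom_class: str = "calpha"
) -> Trajectory:
    """Harmonic fluctuation around *ref* plus an optional slow cosine drift.

    ``frame_t = ref + N(0, sigma^2) + drift_amplitude * cos(pi t / T) * mode``
    with the drift mode a fixed unit 3n-vector (seeded random for
    ``"auto"``).  Dominant drift produces a first principal component whose
    projection is a half-period cosine — the textbook unconverged-sampling
    signature.
    """
    rng = np.random.default_rng(spec.seed)
    sel = select(ref, set(ref.chain_ids), atom_class)
    atom_keys = [(r.key, a.name) for r in sel.residues() for a in r.atoms]
    masses = np.array([a.mass for r in sel.residues() for a in r.atoms])
    ref_coords = sel.coords(heavy_only=False)
    n_atoms = len(ref_coords)
    if n_atoms < 3:
        raise ValueError("reference selection has fewer than 3 atoms")
    if isinstance(spec.drift_mode, str):
        if spec.drift_mode != "auto":
            raise ValueError("drift_mode must be 'auto' or a unit 3n-vector")
        mode = rng.normal(size=3 * n_atoms)
        mode /= np.linalg.norm(mode)
    else:
        mode = np.asarray(spec.drift_mode, dtype=float)
        if mode.shape != (3 * n_atoms,):
            raise ValueError(f"drift_mode must have shape ({3 * n_atoms},)")
        mode = mode / np.linalg.norm(mode)
    mode3 = mode.reshape(n_atoms, 3)

    T = spec.n_frames
    frames = np.empty((T, n_atoms, 3))
    for t in range(T):
        noise = rng.normal(0.0, spec.noise_sigma, size=(n_atoms, 3))
        frames[t] = ref_coords + noise + spec.drift_amplitude * np.cos(np.pi * t / T) * mode3
    return Trajectory(frames, atom_keys, masses)
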
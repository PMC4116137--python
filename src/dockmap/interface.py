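"""Quantitative interface profiling of a two-component complex.

Descriptors computed here mirror what interface-analysis servers report
for a docked or crystallographic complex: the buried (interface) area from
solvent-accessible surface differences, interface residue lists, geometric
hydrogen bonds and salt bridges, the polar fraction of the buried surface,
and per-residue buried-ASA percentages.

SASA uses Shrake-Rupley sphere sampling with a deterministic Fibonacci
point construction, so results are exactly reproducible for a fixed point
count.  Heavy atoms only: crystallographic inputs generally lack hydrogens
and every descriptor is defined on heavy-atom geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .contacts import contact_map
from .structure import Partition, ResidueKey, Structure, select

#: van der Waals radii (A) used for SASA; unknown elements fall back to 1.80.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
FALLBACK_RADIUS = 1.80

AtomKey = tuple[ResidueKey, str]

# Heavy-atom hydrogen-bond chemistry.  Backbone N donates (except proline),
# backbone O / OXT accept; side-chain entries follow standard residue
# chemistry.  Atoms like Ser OG, Thr OG1, Tyr OH and His ring nitrogens act
# in either role.
SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"}, "TRP": {"NE1"},
}
SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}
# Charged groups for salt bridges; His counted positive (both ring N),
# protonation states are not computed.
POSITIVE_ATOMS = {"LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"}}
NEGATIVE_ATOMS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}


def _is_donor(res_name: str, atom_name: str) -> bool:
    if atom_name == "N" and res_name != "PRO":
        return True
    return atom_name in SIDECHAIN_DONORS.get(res_name, ())


def _is_acceptor(res_name: str, atom_name: str) -> bool:
    if atom_name in ("O", "OXT"):
        return True
    return atom_name in SIDECHAIN_ACCEPTORS.get(res_name, ())


def _charge(res_name: str, atom_name: str) -> int:
    if atom_name in POSITIVE_ATOMS.get(res_name, ()):
        return 1
    if atom_name in NEGATIVE_ATOMS.get(res_name, ()) or atom_name == "OXT":
        return -1
    return 0


@dataclass
class SasaResult:
    per_atom: dict[AtomKey, float]
    per_residue: dict[ResidueKey, float]
    total: float
    probe_radius: float
    n_points: int


@dataclass(frozen=True)
class HBond:
    donor_atom: AtomKey
    acceptor_atom: AtomKey
    distance: float
    is_salt_bridge: bool = False


@dataclass
class InterfaceReport:
    """The one-row interface summary: areas, counts and the buried-ASA table."""

    interface_area: float
    interface_residues: dict[str, list[ResidueKey]]
    n_hbonds: int
    n_salt_bridges: int
    n_contacts_total: int
    n_phil_phil: int
    n_phob_phob: int
    pct_polar_buried: float
    buried_table: dict[ResidueKey, float | None]
    hbonds: list[HBond] = field(default_factory=list)

    def to_dict(self) -> dict:
        def keystr(k: ResidueKey) -> str:
            return f"{k[0]}/{k[1]}{k[2]}"

        return {
            "interface_area": round(self.interface_area, 1),
            "n_interface_residues": {
                side: len(keys) for side, keys in self.interface_residues.items()
            },
            "interface_residues": {
                side: [keystr(k) for k in keys]
                for side, keys in self.interface_residues.items()
            },
            "n_hbonds": self.n_hbonds,
            "n_salt_bridges": self.n_salt_bridges,
            "n_contacts_total": self.n_contacts_total,
            "n_phil_phil": self.n_phil_phil,
            "n_phob_phob": self.n_phob_phob,
            "pct_polar_buried": round(self.pct_polar_buried, 1),
            "buried_pct": {
                keystr(k): (None if v is None else round(v, 2))
                for k, v in sorted(self.buried_table.items())
            },
        }


def fibonacci_sphere(n: int) -> np.ndarray:
    """*n* quasi-uniform unit-sphere points from the golden-spiral lattice."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(s: Structure, probe: float = 1.4, n_points: int = 960) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area on heavy atoms.

    Each atom's accessible area is ``4 pi (r + probe)^2`` times the fraction
    of its sampling sphere not occluded by any neighbour's probe-expanded
    sphere.  Deterministic: the sphere points come from a fixed Fibonacci
    lattice, no RNG involved.
    """
    if n_points < 60:
        raise ValueError("n_points must be >= 60 for a usable discretization")
    keys: list[AtomKey] = []
    coords, radii = [], []
    for res in s.residues():
        for atom in res.atoms:
            if not atom.is_heavy:
                continue
            keys.append((res.key, atom.name))
            coords.append(atom.coord)
            radii.append(VDW_RADII.get(atom.element.upper(), FALLBACK_RADIUS))
    if not coords:
        raise ValueError("no heavy atoms present")
    coords = np.array(coords)
    radii = np.array(radii) + probe
    sphere = fibonacci_sphere(n_points)

    tree = cKDTree(coords)
    reach = 2.0 * radii.max()
    neighbor_lists = tree.query_ball_point(coords, r=reach)

    per_atom: dict[AtomKey, float] = {}
    per_residue: dict[ResidueKey, float] = {}
    for i in range(len(coords)):
        nbrs = [j for j in neighbor_lists[i]
                if j != i and np.dot(coords[j] - coords[i], coords[j] - coords[i])
                < (radii[i] + radii[j]) ** 2]
        pts = coords[i] + radii[i] * sphere
        exposed = np.ones(n_points, dtype=bool)
        for j in nbrs:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > radii[j] ** 2
        area = 4.0 * np.pi * radii[i] ** 2 * exposed.sum() / n_points
        per_atom[keys[i]] = area
        res_key = keys[i][0]
        per_residue[res_key] = per_residue.get(res_key, 0.0) + area
    return SasaResult(per_atom, per_residue, sum(per_atom.values()), probe, n_points)


def _burial(
    s: Structure, p: Partition, probe: float = 1.4, n_points: int = 960
) -> tuple[SasaResult, SasaResult, SasaResult, dict[AtomKey, float]]:
    """SASA of complex and of each isolated side, plus per-atom buried area.

    Components are extracted with coordinates unchanged; buried area per
    atom is its isolated-side ASA minus its in-complex ASA.
    """
    p.validate(s)
    full = sasa(s, probe, n_points)
    rec = sasa(select(s, set(p.receptor_chains), "heavy"), probe, n_points)
    lig = sasa(select(s, set(p.ligand_chains), "heavy"), probe, n_points)
    delta: dict[AtomKey, float] = {}
    for side in (rec, lig):
        for key, a_alone in side.per_atom.items():
            delta[key] = a_alone - full.per_atom[key]
    return full, rec, lig, delta


def interface_area(
    s: Structure, p: Partition, probe: float = 1.4, n_points: int = 960
) -> float:
    """Buried surface area, as half the total ASA lost upon complexation (A^2)."""
    full, rec, lig, _ = _burial(s, p, probe, n_points)
    return (rec.total + lig.total - full.total) / 2.0


def interface_residues(
    s: Structure, p: Partition, min_delta: float = 1.0,
    probe: float = 1.4, n_points: int = 960,
) -> dict[str, list[ResidueKey]]:
    """Residues whose ASA drops by more than *min_delta* upon complexation."""
    full, rec, lig, _ = _burial(s, p, probe, n_points)
    out: dict[str, list[ResidueKey]] = {}
    for side, result in (("receptor", rec), ("ligand", lig)):
        out[side] = [
            key for key, alone in result.per_residue.items()
            if alone - full.per_residue[key] > min_delta
        ]
    return out


def _inter_side_atom_pairs(s: Structure, p: Partition, d_max: float):
    """Yield (rec residue, rec atom, lig residue, lig atom, distance) within d_max."""
    rc, r_res, r_idx = s.atom_table(p.receptor_chains, heavy_only=True)
    lc, l_res, l_idx = s.atom_table(p.ligand_chains, heavy_only=True)
    r_atoms = [a for res in r_res for a in res.heavy_atoms()]
    l_atoms = [a for res in l_res for a in res.heavy_atoms()]
    hits = cKDTree(rc).query_ball_tree(cKDTree(lc), r=d_max)
    for i, js in enumerate(hits):
        for j in js:
            d = float(np.linalg.norm(rc[i] - lc[j]))
            if d <= d_max:
                yield r_res[r_idx[i]], r_atoms[i], l_res[l_idx[j]], l_atoms[j], d


def hydrogen_bonds(s: Structure, p: Partition, d_max: float = 3.5) -> list[HBond]:
    """Geometric inter-partition hydrogen bonds on heavy atoms.

    A donor and an acceptor heavy atom within *d_max* across the interface
    count as one bond; no angular term, since inputs typically lack
    hydrogens.  An atom pair is reported once even when both atoms could
    take either role.
    """
    p.validate(s)
    bonds: dict[tuple[AtomKey, AtomKey], HBond] = {}
    for rres, ratom, lres, latom, d in _inter_side_atom_pairs(s, p, d_max):
        rk: AtomKey = (rres.key, ratom.name)
        lk: AtomKey = (lres.key, latom.name)
        if _is_donor(rres.res_name, ratom.name) and _is_acceptor(lres.res_name, latom.name):
            donor, acceptor = rk, lk
        elif _is_donor(lres.res_name, latom.name) and _is_acceptor(rres.res_name, ratom.name):
            donor, acceptor = lk, rk
        else:
            continue
        pair = (rk, lk)
        if pair in bonds and bonds[pair].distance <= d:
            continue
        is_sb = (
            _charge(rres.res_name, ratom.name) * _charge(lres.res_name, latom.name) < 0
        )
        bonds[pair] = HBond(donor, acceptor, d, is_sb)
    return sorted(bonds.values(), key=lambda b: (b.donor_atom, b.acceptor_atom))


def salt_bridges(s: Structure, p: Partition, d_max: float = 4.0) -> list[HBond]:
    """Inter-partition salt bridges: oppositely charged group atoms within *d_max*.

    One bridge per residue pair; the closest qualifying atom pair is kept.
    """
    p.validate(s)
    best: dict[tuple[ResidueKey, ResidueKey], HBond] = {}
    for rres, ratom, lres, latom, d in _inter_side_atom_pairs(s, p, d_max):
        qr = _charge(rres.res_name, ratom.name)
        ql = _charge(lres.res_name, latom.name)
        if qr * ql >= 0:
            continue
        donor = (rres.key, ratom.name) if qr > 0 else (lres.key, latom.name)
        acceptor = (lres.key, latom.name) if qr > 0 else (rres.key, ratom.name)
        key = (rres.key, lres.key)
        if key not in best or d < best[key].distance:
            best[key] = HBond(donor, acceptor, d, True)
    return sorted(best.values(), key=lambda b: (b.donor_atom, b.acceptor_atom))


def buried_fractions(
    s: Structure, p: Partition, probe: float = 1.4, n_points: int = 960,
) -> dict[ResidueKey, float | None]:
    """Per-residue percent ASA buried upon complexation.

    Residues with less than 1 A^2 accessible surface already in the
    isolated component are reported as ``None`` (undefined), not as 100%.
    """
    full, rec, lig, _ = _burial(s, p, probe, n_points)
    out: dict[ResidueKey, float | None] = {}
    for side in (rec, lig):
        for key, alone in side.per_residue.items():
            if alone < 1.0:
                out[key] = None
            else:
                out[key] = 100.0 * (alone - full.per_residue[key]) / alone
    return out


def polar_buried_pct(
    s: Structure, p: Partition, probe: float = 1.4, n_points: int = 960,
) -> float:
    """Percent of the buried surface contributed by polar (N and O) atoms."""
    elements = {
        (res.key, a.name): a.element.upper()
        for res in s.residues() for a in res.atoms if a.is_heavy
    }
    _, _, _, delta = _burial(s, p, probe, n_points)
    total = sum(delta.values())
    if total <= 0:
        raise ValueError("no buried surface; polar fraction undefined")
    polar = sum(v for k, v in delta.items() if elements[k] in ("N", "O"))
    return 100.0 * polar / total


def interface_report(
    s: Structure, p: Partition, cutoff: float = 5.0,
    probe: float = 1.4, n_points: int = 960,
    hbond_max: float = 3.5, saltbridge_max: float = 4.0, min_delta: float = 1.0,
) -> InterfaceReport:
    """Aggregate every interface descriptor into one record."""
    p.validate(s)
    cm = contact_map(s, p, cutoff)
    by_class = cm.count_by_class()
    full, rec, lig, delta = _burial(s, p, probe, n_points)
    area = (rec.total + lig.total - full.total) / 2.0

    residues: dict[str, list[ResidueKey]] = {}
    buried: dict[ResidueKey, float | None] = {}
    for side, result in (("receptor", rec), ("ligand", lig)):
        residues[side] = [
            key for key, alone in result.per_residue.items()
            if alone - full.per_residue[key] > min_delta
        ]
        for key, alone in result.per_residue.items():
            buried[key] = (
                None if alone < 1.0
                else 100.0 * (alone - full.per_residue[key]) / alone
            )

    total_buried = sum(delta.values())
    if total_buried > 0:
        elements = {
            (r.key, a.name): a.element.upper()
            for r in s.residues() for a in r.atoms if a.is_heavy
        }
        polar = sum(v for k, v in delta.items() if elements[k] in ("N", "O"))
        pct_polar = 100.0 * polar / total_buried
    else:
        pct_polar = 0.0

    hbonds = hydrogen_bonds(s, p, hbond_max)
    bridges = salt_bridges(s, p, saltbridge_max)
    return InterfaceReport(
        interface_area=area,
        interface_residues=residues,
        n_hbonds=len(hbonds),
        n_salt_bridges=len(bridges),
        n_contacts_total=len(cm),
        n_phil_phil=by_class["phil-phil"],
        n_phob_phob=by_class["phob-phob"],
        pct_polar_buried=pct_polar,
        buried_table=buried,
        hbonds=hbonds,
    )
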
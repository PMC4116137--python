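"""Intermolecular residue-residue contact maps.

Two residues on opposite sides of a :class:`~dockmap.structure.Partition`
are in contact when any pair of their heavy atoms is closer than the cutoff
(5 A by default, the criterion all interface counts are tied to).  The
distance-range variant records, per residue pair, the smallest of a series
of any-atom distance thresholds (7/10/13/16 A by default) it satisfies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import Partition, Residue, ResidueKey, Structure

#: Distance-range thresholds (A) used for range maps.
DEFAULT_RANGE_BINS = (7.0, 10.0, 13.0, 16.0)

PairKey = tuple[ResidueKey, ResidueKey]


@dataclass(frozen=True)
class Contact:
    receptor_residue: ResidueKey
    ligand_residue: ResidueKey
    receptor_name: str
    ligand_name: str
    min_dist: float
    contact_class: str  # phil-phil | phob-phob | mixed

    @property
    def pair(self) -> PairKey:
        return (self.receptor_residue, self.ligand_residue)


def _pair_class(res_a: Residue, res_b: Residue) -> str:
    pa, pb = res_a.polarity_class, res_b.polarity_class
    if pa == pb == "hydrophilic":
        return "phil-phil"
    if pa == pb == "hydrophobic":
        return "phob-phob"
    return "mixed"


@dataclass
class ContactMap:
    contacts: dict[PairKey, Contact]
    cutoff: float
    partition: Partition
    model_label: str = ""

    def __len__(self) -> int:
        return len(self.contacts)

    @property
    def pairs(self) -> set[PairKey]:
        return set(self.contacts)

    def count_by_class(self) -> dict[str, int]:
        out = {"phil-phil": 0, "phob-phob": 0, "mixed": 0}
        for c in self.contacts.values():
            out[c.contact_class] += 1
        return out

    def residues_per_side(self) -> tuple[set[ResidueKey], set[ResidueKey]]:
        rec = {c.receptor_residue for c in self.contacts.values()}
        lig = {c.ligand_residue for c in self.contacts.values()}
        return rec, lig

    def to_rows(self) -> list[dict]:
        """One row per contact, sorted by (receptor key, ligand key)."""
        rows = []
        for c in sorted(self.contacts.values(), key=lambda c: c.pair):
            rc, rn, ri = c.receptor_residue
            lc, ln, li = c.ligand_residue
            rows.append({
                "receptor_chain": rc, "receptor_res": f"{rn}{ri}",
                "receptor_resname": c.receptor_name,
                "ligand_chain": lc, "ligand_res": f"{ln}{li}",
                "ligand_resname": c.ligand_name,
                "min_dist": round(c.min_dist, 2), "class": c.contact_class,
            })
        return rows


@dataclass
class RangeMap:
    """Residue pair -> smallest distance threshold it falls under."""

    entries: dict[PairKey, float]
    bins: tuple[float, ...]
    partition: Partition


def min_residue_distances(
    s: Structure, p: Partition, max_dist: float
) -> dict[tuple[int, int], float]:
    """Minimum heavy-atom distance per inter-partition residue pair.

    Only pairs with at least one atom pair closer than *max_dist* are
    returned, as indices into the per-side residue lists.  A k-d tree
    restricts the atom pairs examined; the recorded minima are exact.
    """
    rc, r_res, r_idx = s.atom_table(p.receptor_chains, heavy_only=True)
    lc, l_res, l_idx = s.atom_table(p.ligand_chains, heavy_only=True)
    if len(rc) == 0 or len(lc) == 0:
        raise ValueError("a partition side has no heavy atoms")
    pairs = cKDTree(rc).query_ball_tree(cKDTree(lc), r=max_dist)
    out: dict[tuple[int, int], float] = {}
    for i, js in enumerate(pairs):
        if not js:
            continue
        d = np.sqrt(np.sum((lc[js] - rc[i]) ** 2, axis=1))
        ri = r_idx[i]
        for j, dij in zip(js, d):
            key = (ri, l_idx[j])
            if dij < out.get(key, np.inf):
                out[key] = float(dij)
    return out


def contact_map(
    s: Structure, p: Partition, cutoff: float = 5.0, model_label: str = ""
) -> ContactMap:
    """Binary intermolecular contact map at an atom-pair distance *cutoff*."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    p.validate(s)
    r_res = s.residues(p.receptor_chains)
    l_res = s.residues(p.ligand_chains)
    contacts: dict[PairKey, Contact] = {}
    for (i, j), d in min_residue_distances(s, p, cutoff).items():
        if d >= cutoff:
            continue
        ra, lb = r_res[i], l_res[j]
        c = Contact(ra.key, lb.key, ra.res_name, lb.res_name, d, _pair_class(ra, lb))
        contacts[c.pair] = c
    return ContactMap(contacts, cutoff, p, model_label)


def range_map(
    s: Structure, p: Partition, bins: tuple[float, ...] = DEFAULT_RANGE_BINS
) -> RangeMap:
    """Distance-range map: per pair, the smallest bin its any-atom distance beats."""
    bins = tuple(float(b) for b in bins)
    if list(bins) != sorted(bins) or len(set(bins)) != len(bins):
        raise ValueError("bins must be strictly ascending")
    p.validate(s)
    r_res = s.residues(p.receptor_chains)
    l_res = s.residues(p.ligand_chains)
    entries: dict[PairKey, float] = {}
    for (i, j), d in min_residue_distances(s, p, bins[-1]).items():
        smallest = next((b for b in bins if d < b), None)
        if smallest is not None:
            entries[(r_res[i].key, l_res[j].key)] = smallest
    return RangeMap(entries, bins, p)


def map_overlap(a: ContactMap, b: ContactMap) -> tuple[float, float]:
    """(Jaccard index, fraction of *a*'s contacts shared) for two maps."""
    pa, pb = a.pairs, b.pairs
    if not pa and not pb:
        warnings.warn("both contact maps are empty; overlap defined as 1.0")
        return 1.0, 1.0
    inter = len(pa & pb)
    jaccard = inter / len(pa | pb)
    frac_a = inter / len(pa) if pa else 0.0
    return jaccard, frac_a


def render_map(
    cm: ContactMap, path: str, consensus: dict[PairKey, float] | None = None
) -> None:
    """Render a contact (or consensus-weighted) map to a raster image.

    Axes are ordered by (chain, seq_num, icode); dot intensity is uniform
    for a plain map or proportional to the conservation rate when a
    *consensus* rate dict is given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rec_keys = sorted({c.receptor_residue for c in cm.contacts.values()})
    lig_keys = sorted({c.ligand_residue for c in cm.contacts.values()})
    ri = {k: n for n, k in enumerate(rec_keys)}
    li = {k: n for n, k in enumerate(lig_keys)}
    fig, ax = plt.subplots(figsize=(6, 6))
    xs, ys, cs = [], [], []
    for c in cm.contacts.values():
        xs.append(ri[c.receptor_residue])
        ys.append(li[c.ligand_residue])
        cs.append(consensus.get(c.pair, 0.0) if consensus else 1.0)
    ax.scatter(xs, ys, c=cs, cmap="Greys", vmin=0.0, vmax=1.0, s=25,
               edgecolors="k", linewidths=0.3)
    ax.set_xlabel("receptor residue index")
    ax.set_ylabel("ligand residue index")
    ax.set_title(cm.model_label or "contact map")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
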
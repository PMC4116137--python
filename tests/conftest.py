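import numpy as np
import pytest

import dockmap as dm


@pytest.fixture(scope="session")
def toy() -> dm.Structure:
    """The default planted two-chain toy complex."""
    return dm.make_toy_complex(seed=0)


@pytest.fixture(scope="session")
def part() -> dm.Partition:
    return dm.toy_partition()


@pytest.fixture(scope="session")
def toy_maps(toy, part):
    """Contact maps of a small mixed decoy ensemble of the toy complex."""
    decoys = dm.generate_decoys(toy, part, dm.DecoyEnsembleSpec(12, 0.5, seed=11))
    return [dm.contact_map(d, part, model_label=d.title) for d in decoys]


def make_residue(chain, num, name, atoms, icode=""):
    """Hand-build a residue from (atom_name, element, xyz) triples."""
    return dm.Residue(
        chain, num, icode, name,
        [dm.Atom(n, e, np.asarray(xyz, dtype=float)) for n, e, xyz in atoms],
    )



def brute_force_contact_pairs(s, p, cutoff):
    """Independent all-pairs O(n^2) contact scan (no spatial indexing)."""
    pairs = {}
    for res_r in s.residues(p.receptor_chains):
        for res_l in s.residues(p.ligand_chains):
            dmin = np.inf
            for a in res_r.atoms:
                if not a.is_heavy:
                    continue
                for b in res_l.atoms:
                    if not b.is_heavy:
                        continue
                    d = float(np.linalg.norm(a.coord - b.coord))
                    dmin = min(dmin, d)
            if dmin < cutoff:
                pairs[(res_r.key, res_l.key)] = dmin
    return pairs
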
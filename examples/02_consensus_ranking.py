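"""Consensus ranking of a docking-decoy ensemble.

Generates 50 rigid-body decoys of the toy complex (30% near-native, the
rest scattered touching poses), computes the per-contact conservation
rates across the ensemble, and ranks every decoy by the mean conservation
of its own contacts.  A near-native decoy should top the table: the
consensus concentrates on the contacts the near-native cluster shares.
"""

import warnings

import dockmap as dm

native = dm.make_toy_complex(seed=0)
part = dm.toy_partition()

spec = dm.DecoyEnsembleSpec(n_decoys=50, near_native_fraction=0.3, seed=42)
decoys = dm.generate_decoys(native, part, spec)
maps = [dm.contact_map(d, part, model_label=d.title) for d in decoys]

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # scattered decoys may have empty maps
    table = dm.rank_models(maps)
    cons = dm.consensus(maps)

print("top 5 decoys by consensus score (mean contact-conservation rate):")
for label, score, n_contacts in table.rows[:5]:
    print(f"  {label:10s} score={score:.4f}  ({n_contacts} contacts)")

kept = dm.conserved_contacts(cons, threshold=0.25)
print(f"\n{len(kept)} contacts conserved in at least 25% of the {cons.n_models} decoys;")
print("the most conserved:")
for (rk, lk), rate in kept[:3]:
    print(f"  {rk[0]}{rk[1]} -- {lk[0]}{lk[1]}  rate={rate:.2f}")

top = next(d for d in decoys if d.title == table.top)
lrmsd = dm.ligand_rmsd(native, top, part, fit_side="receptor")
print(f"\nligand-RMSD of the top-ranked decoy to the native pose: {lrmsd:.2f} A")
print("(below 5 A = near-native: consensus ranking recovered the planted cluster)")
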
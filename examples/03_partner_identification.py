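"""Identify interaction partners from a planted decoy collection.

Builds cross-docking decoy sets for every ordered pair of a synthetic
benchmark (native pairs planted with lower energies and interfaces on
the designated patches), scores them into an NII matrix, and evaluates
partner prediction.
"""

from ccdock.evaluation import roc_auc
from ccdock.scoring import nii_from_decoys, predicted_partner
from ccdock.synth import SyntheticDecoyConfig, make_decoy_collection

coll = make_decoy_collection(SyntheticDecoyConfig(
    n_complexes=4, n_conformations=400, p_signal=0.9, sigma=2.0, seed=0))
nii = nii_from_decoys(coll.decoy_sets, references=coll.patches)

print(f"{coll.benchmark.n_proteins} proteins, "
      f"{len(coll.decoy_sets)} ordered pairs docked")
print(f"partner-prediction AUC: {roc_auc(nii, coll.gold):.3f}")

partner = {}
for r, l in coll.benchmark.pairs:
    partner[r], partner[l] = l, r
hits = sum(predicted_partner(nii, p) == partner[p]
           for p in coll.benchmark.proteins)
print(f"predicted partner correct for {hits}/{coll.benchmark.n_proteins} "
      "proteins")
# AUC near 1 and full recovery: the planted interaction signal dominates
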
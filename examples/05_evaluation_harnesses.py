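"""The three study harnesses: task ablation, class exclusion, and
identity-stratified evaluation, plus ligand-embedding clustering.

Ablation retrains a base model with one task group's labels hidden to
measure multitask transfer; class exclusion holds out one pseudo-EC class
entirely to measure generalization to unseen chemistry classes;
identity-stratified evaluation bins test records by their maximum sequence
identity to the training set.  All three run at reduced size here.
"""

import numpy as np

from plikit import (
    ModelConfig, StrategyConfig, SyntheticConfig, cluster_ligands,
    default_vocabularies, generate,
)
from plikit.evaluation import (
    ablation_harness, class_exclusion_harness, identity_stratified_eval,
    ligand_embeddings, predict_records,
)
from plikit.finetune import prepare_records, train
from plikit.model import JointTransformer, TASKS

pv, lv = default_vocabularies()
dataset = generate(SyntheticConfig(n_records=300, master_seed=4))
mcfg = ModelConfig.preset("tiny", protein_vocab_size=len(pv),
                          ligand_vocab_size=len(lv), seed=0)
scfg = StrategyConfig(epochs_phase1=6, seed=0)

print("task-ablation grid (test RMSD; site precision):")
grid = ablation_harness(dataset, ["none", "binding"], mcfg, scfg, pv, lv)
for setting, row in grid.items():
    shown = {k: (round(v, 2) if v is not None else None) for k, v in row.items()
             if k in ("kcat_rmsd", "Ki_rmsd", "site_precision")}
    print(f"  excluded={setting:8s} {shown}")

print("\nleave-one-class-out (class 2 held out of training):")
rep = class_exclusion_harness(dataset, 2, mcfg, scfg, pv, lv)
kcat = rep["metrics"]["kcat"]
print(f"  n_test={rep['n_test']}  held-out-class kcat RMSD={kcat['rmsd']:.2f}")

print("\nidentity-stratified evaluation:")
model = JointTransformer(mcfg)
result = train(model, dataset.subset("train"), dataset.subset("val"), scfg, pv, lv)
test_records = dataset.subset("test")
prep = prepare_records(test_records, pv, lv)
mu, _, _ = predict_records(result.models, prep)
truths = np.stack([p.y for p in prep])
avail = np.stack([p.avail for p in prep])
idents = np.array([r.max_train_identity for r in test_records])
strata = identity_stratified_eval(mu, truths, avail, idents)
for bin_name, entry in strata.items():
    rmsd = entry["tasks"]["kcat"]["rmsd"]
    print(f"  identity {bin_name:5s} n={entry['n_records']:3d} "
          f"kcat RMSD={rmsd:.2f}")

ligands = sorted({r.smiles for r in test_records})
emb = ligand_embeddings(model, ligands, lv)
labels = cluster_ligands(emb, k=5)
print(f"\nligand clustering: {len(ligands)} unique ligands -> "
      f"{len(set(labels))} connected components")
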
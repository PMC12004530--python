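"""Finetune the tiny joint transformer with the base regime and predict.

Base regime: the protein and ligand encoders stay frozen; only the joint
transformer layer and the task heads train, with the equal-weight multitask
Gaussian-NLL + site-BCE loss and validation-steady-state stopping.  Each
prediction is a per-task Normal(mu, sigma) on log10 scale, so sigma is a
direct uncertainty estimate.
"""

import numpy as np

from plikit import (
    JointTransformer, ModelConfig, StrategyConfig, SyntheticConfig, TASKS,
    default_vocabularies, generate, train,
)
from plikit.finetune import prepare_records
from plikit.evaluation import evaluate_split

pv, lv = default_vocabularies()
dataset = generate(SyntheticConfig(n_records=600, master_seed=1,
                                   annotate_identity=False))

model = JointTransformer(ModelConfig.preset(
    "tiny", protein_vocab_size=len(pv), ligand_vocab_size=len(lv), seed=0))
strategy = StrategyConfig(strategy="base", epochs_phase1=20, seed=0)
result = train(model, dataset.subset("train"), dataset.subset("val"),
               strategy, pv, lv)
history = result.histories[0]
print(f"stopped after epoch {history.stop_epoch} ({history.stop_reason}); "
      f"validation loss {history.val_loss[0]:.3f} -> {history.val_loss[-1]:.3f}")

test = prepare_records(dataset.subset("test"), pv, lv)
pred, sites = model.predict_record(test[0].joint)
print("\nfirst test record, per-task prediction (log10 units):")
for t, task in enumerate(TASKS):
    print(f"  {task:5s} mu={pred.mu[t]:+.2f}  sigma={pred.sigma[t]:.2f}"
          + (f"   truth={test[0].y[t]:+.2f}" if test[0].avail[t] else ""))
print("most site-like residue:", int(np.argmax(sites)) + 1,
      f"(p={sites.max():.2f})")

report = evaluate_split(result.models, test)
print("\nheld-out metrics (R^2 / RMSD / P_1mag%):")
for task in TASKS:
    m = report[task]
    if m["n"]:
        print(f"  {task:5s} {m['r2']:.2f} / {m['rmsd']:.2f} / {m['p1mag']:.0f}%  (n={m['n']})")
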
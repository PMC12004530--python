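# Methods

This note documents the modeling, the synthetic benchmark, the numerical
choices, and the limits of what the bundled experiments can show.

## Model

**Inputs.** One protein and one or more ligands.  Protein tokenization is
one token per residue over the 20 canonical amino acids plus X; letters
outside the alphabet map to UNK and are counted rather than rejected,
because ambiguity codes (B, Z, J, U, O) are common in real sequence data.
Ligand tokenization is strict: an unrecognized SMILES/SELFIES symbol raises,
because silently UNK-ing chemistry would corrupt the molecule.  SMILES are
scanned greedily left to right with two-character halogens and whole bracket
atoms as single tokens; SELFIES are split at bracket boundaries.  Both
vocabularies carry the same six specials (PAD=0, BOS, EOS, MASK, UNK, SEP);
PAD id 0 and right-side padding are fixed conventions.

**Joint layout.** `BOS protein EOS` then `SEP ligand` per ligand,
protein-first, with a per-position modality mask.  The mask — not the token
values — decides which positions the pooling and site heads see, and a
learned 3-row segment embedding (protein / ligand / special) is added before
the joint layer so it receives an explicit modality signal.  Nothing in the
two-tower design forces this layout; it was chosen because it is the
simplest order-preserving one and makes span bookkeeping testable.

**Encoders.** Pre-norm transformer blocks (self-attention + GELU FFN) per
modality, with learned absolute positional embeddings that restart at each
segment, followed by a final LayerNorm.  The joint stage is self-attention
over the concatenated sequence; the text this design derives from is
ambiguous between that and an explicit cross-attention block, and plain
self-attention over the concatenation was chosen as the simpler reading.
With `joint_layers: 0` the model degenerates, by contract, to the
concatenated encoder outputs.  Attention masks exclude PAD keys, so PAD
content can never influence a valid position (asserted bit-exactly in
tests).

**Heads.**
* Regression: arithmetic mean over non-PAD, non-special positions (so the
  pooled statistic is independent of padding), then per task an affine map
  to (μ, raw_s) with σ = softplus(raw_s) + 1e-4.  The floor keeps the
  Gaussian NLL finite for degenerate fits; any constant offset in the NLL
  changes no optimum.
* Sites: per-token affine + logistic restricted to protein residue
  positions; ligand and special tokens are excluded.
* Masked-LM: separate affine heads per modality over that modality's own
  vocabulary.

**Presets.** `tiny` (E=32, 2+2+1 layers, 4 heads, FFN 64; ~54k parameters)
is the test surface and default; `reference` (E=480, 12+12+1, 20 heads) mirrors
the 480-dimensional scale of the 35M-parameter encoder family the
architecture follows, without chasing its exact parameterization.  The
engine is float32; tests switch it to float64 for finite-difference checks.

## Objectives and training

The multitask loss is the unweighted mean of per-task mean losses over
tasks with at least one label in the batch: six Gaussian NLL terms plus
the site binary cross-entropy (computed in logit space).  Missing labels
drop out of both numerator and divisor, keeping the loss scale stable under
sparse labeling.  Masked-LM pretraining uses BERT-style 80/10/10 corruption
at rate 0.15 on non-special positions, each modality masked and scored in
its own vocabulary.  Class imbalance in site labels is not reweighted; a
config toggle exists but defaults to off, and the low site precision of
undertrained runs reflects that choice.

Optimization is Adam (phase 1 lr 5e-3, phase 2 lr 1e-3, batch 32); these
are this package's defaults, not values claimed from elsewhere.  Stopping:
the best validation loss must improve by more than τ·max(1, |best|)
(τ=1e-3, patience 5) or training stops with reason `steady_state`; the
`max(1, ·)` guard keeps the relative rule well-defined when the NLL crosses
zero.  Frozen parameters are actual graph constants during a phase — they
receive no gradient and are bit-identical afterwards.

**LoRA.** Adapters W + s·A·B with A ~ N(0, r^(-1/2)), B = 0 (so injection
is a bit-exact no-op), s = α/r with α = 2r, attached to every attention and
FFN matrix in the protein, ligand, and joint blocks; during phase 2 only
adapters and heads train.  `merge_lora` materializes the sum for
deployment; the CLI stores merged checkpoints so any checkpoint loads into
a plain model.

**Ensemble.** M members (default 3), each a base-regime training on a
bootstrap resample (n draws with replacement, member-specific derived
seeds) with re-randomized joint layer + heads; the frozen encoders are
shared.  Aggregation uses the exact moments of the equal-weight Gaussian
mixture — the law of total variance — so the ensemble SD dominates the mean
member variance whenever members disagree.  The alternative that averages
member variances and ignores the μ-spread is available as
`variant="mean_variance"` for comparison.  Site votes: majority at
threshold 0.5; even member counts break ties toward negative with a
warning.

## Synthetic benchmark

The generator emulates the statistical structure of enzyme-kinetics
datasets while staying fully controlled:

* **Proteins**: uniform random sequences, length 30–50, with one of C=3
  class motifs (length 10, 10% per-position mutation) inserted at a random
  position.  The class motif is the pseudo-EC class: class exclusion
  removes a planted sequence pattern, giving the leave-one-class-out
  harness a real generalization gap to measure.
* **Ligands**: a tiny guaranteed-valid SMILES grammar — chains of 4–12
  C/N/O atoms with optional branches and one optional ring — plus a
  mechanical SELFIES-style bracket rendering of the same parse
  (`[C] [Branch1] [EndBranch1] [Ring1]` …).  This is deliberately not real
  chemistry; the goal is tokenizer and trainability coverage, not molecular
  realism.
* **Targets**: y_t = a_t·f_p + b_t·f_l + ρ·z + ε_t on log₁₀ scale, where
  f_p is the motif-window residue composition, f_l the ligand atom counts,
  z a per-record latent shared across tasks (scaled by ρ, default 0.4), and
  ε_t ~ N(0, σ²) with σ = 0.25.  Coefficients are drawn once per master
  seed and rescaled on a fixed calibration sample so each task's planted
  signal variance equals `signal_var` (default 2.0).  The oracle ceiling —
  OLS of y_t on (f_p, f_l), the best any sequence-based model can do since
  z and ε are invisible in the input — is then analytically
  signal_var / (signal_var + ρ² + σ²) ≈ 0.90 under the defaults.
* **Labels**: per-task availability (kcat/Km 0.9, Kd/IC50/EC50 0.5,
  Ki 0.3 — Ki deliberately sparse so multitask transfer has something to
  help), site labels = the motif window (positive rate ≈ motif_len·E[1/L]
  ≈ 0.25, available for 80% of records), splits 70/15/15, and per-record
  maximum identity to the training proteins.

Identity is 100·(1 − d/max(len)) with d the Needleman–Wunsch edit distance
(unit mismatch/gap), so identical sequences score 100 and `AAAA` vs `AAAT`
scores 75.  Because backgrounds are uniform random, most synthetic test
records fall below 40% identity; the stratified bins are exercised, but the
gradient across bins is weaker than in natural data.

What passing on this generator does **not** show: performance on real
enzymes.  The planted signal is linear in low-dimensional features, the
class structure is a single motif, and ligand "chemistry" is a toy grammar;
results demonstrate that the machinery (tokenization → attention → heads →
losses → strategies → metrics) is correct and recovers plantable structure,
not that the tiny model rivals large pretrained encoders on natural data.

## Problem sizes used by the bundled experiments

The committed experiments run at sizes chosen to keep the full suite
comfortably reproducible on a single CPU: the core recovery run uses
n=2000 records with the tiny preset and a 50-epoch cap (reference result:
held-out R² 0.766 / 0.625 for kcat/Km, stopping at epoch 26); the
multitask-transfer comparison uses n=600, ρ=0.8, Ki availability 0.2, 15
epochs, 5 seeds; Monte-Carlo checks use 10⁶ draws per member set.  The
harness examples run at n≈300 for illustration.

## Numerical and design notes

* Determinism: every stochastic component draws from a named
  `SeedSequence` stream fanned out from one master seed (data / init /
  bagging / corruption / train), so datasets, corruptions, trainings,
  checkpoints, and reports are bit-reproducible given seeds.
* Ligand clustering builds the union-symmetrized kNN graph under cosine
  similarity (edge when either endpoint ranks the other in its top k, ties
  by index) and takes connected components; strict mutual-kNN fragments
  tight clusters once a node's k slots saturate.
* PR-AUC is the step-wise (average-precision) estimator, not the
  interpolated envelope; ROC-AUC uses midranks for ties.  R² is undefined
  for constant truths and reported as missing with a warning.
* Residue indices are 1-based in all files, 0-based in memory; conversion
  happens only at the I/O boundary.  In the dataset TSV an empty cell means
  "label unavailable"; `-` means "site-labeled, no positives".
* Even-M ensembles are allowed but warn: vote ties break toward the
  negative class.

## Known limitations

* The NumPy engine is single-threaded beyond BLAS and has no GPU path;
  the `reference`-scale preset constructs and runs but is not practical to
  train here.
* The base regime trains on frozen *randomly initialized* encoders unless
  a masked-LM pretraining checkpoint is supplied first; with the planted
  linear signal this is sufficient, but it understates what pretrained
  encoders contribute on natural data.
* Site classification under the default (unweighted) loss converges to
  low-recall operating points on short trainings, mirroring the known
  behavior of unweighted BCE under class imbalance.
* Multi-ligand inputs are supported by the tokenizer, model, and masks,
  but the bundled generator emits one ligand per record, so that path is
  exercised only by unit tests.
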
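"""Finetuning regimes: base, full, LoRA, and bagged ensemble.

* base: only the joint transformer layer(s) and the task heads train; the
  protein and ligand encoders stay frozen.
* full: phase 1 trains joint + heads, phase 2 unfreezes everything.
* lora: phase 1 trains joint + heads; phase 2 freezes all base weights and
  attaches rank-r adapters (W + scale*A*B, A Gaussian, B zero, so injection
  is a bit-exact no-op) to every attention and feed-forward matrix in the
  protein, ligand, and joint blocks; adapters and heads train.
* ensemble: M independent base-regime trainings on bootstrap resamples of
  the training set, each with a re-randomized joint layer + heads.

Convergence is the steady state of the validation loss: stop when the best
validation loss has not improved by more than a relative tolerance for
``patience`` consecutive epochs, or at the epoch cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .model import (
    Batch, JointTransformer, Linear, ModelConfig, N_TASKS, collate,
)
from .objectives import (
    ObjectiveError, corrupt_for_mlm, gaussian_nll, masked_lm_loss,
    multitask_loss, site_loss_from_logits,
)
from .tokenization import (
    MOD_PROTEIN, SMILES, Vocabulary, assemble_joint, tokenize_ligand,
    tokenize_protein,
)

HEAD_PREFIXES = ("heads.regression", "heads.site")


class StrategyError(ValueError):
    pass


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class StrategyConfig:
    strategy: str = "base"            # base | full | lora | ensemble
    rank: int | None = None           # lora only (2 and 6 are the reference settings)
    members: int = 3                  # ensemble only
    bagging_seed: int = 0
    lr_phase1: float = 5e-3
    lr_phase2: float = 1e-3
    epochs_phase1: int = 50
    epochs_phase2: int = 25
    patience: int = 5
    tol: float = 1e-3                 # relative steady-state tolerance
    batch_size: int = 32
    seed: int = 0
    lora_scale: float = 2.0           # alpha/r with alpha = 2r
    representation: str = SMILES

    def __post_init__(self):
        if self.strategy not in ("base", "full", "lora", "ensemble"):
            raise StrategyError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "lora" and (self.rank is None or self.rank < 1):
            raise StrategyError("lora strategy requires rank >= 1")
        if self.strategy != "lora" and self.rank is not None:
            raise StrategyError("rank is only meaningful for the lora strategy")
        if self.strategy == "ensemble" and self.members < 2:
            raise StrategyError("ensemble requires at least 2 members")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    stop_reason: str = ""
    phase_starts: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"train_loss": self.train_loss, "val_loss": self.val_loss,
                "stop_epoch": self.stop_epoch, "stop_reason": self.stop_reason,
                "phase_starts": self.phase_starts}


# ---------------------------------------------------------------------------
# LoRA


def inject_lora(model: JointTransformer, rank: int, target_selector=None,
                scale: float = 2.0, seed: int = 0) -> JointTransformer:
    """Attach rank-``rank`` adapters; forward outputs are unchanged (B = 0)."""
    linears = model.block_linears()
    if target_selector is not None:
        linears = {k: v for k, v in linears.items() if target_selector(k)}
    if not linears:
        raise StrategyError("no target matrices selected for adaptation")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    for name, lin in linears.items():
        if rank >= min(lin.d_in, lin.d_out):
            raise StrategyError(
                f"rank {rank} >= min dimension {min(lin.d_in, lin.d_out)} of {name}")
        if lin.lora_A is not None:
            raise StrategyError(f"{name} already has an adapter")
        lin.lora_A = Tensor(rng.normal(0.0, rank ** -0.5, size=(lin.d_in, rank)),
                            requires_grad=True)
        lin.lora_B = Tensor(np.zeros((rank, lin.d_out)), requires_grad=True)
        lin.lora_scale = float(scale)
    return model


def merge_lora(model: JointTransformer) -> JointTransformer:
    """Materialize W <- W + scale*A*B and drop the adapters."""
    merged = 0
    for lin in model.block_linears().values():
        if lin.lora_A is None:
            continue
        lin.W.data = lin.W.data + lin.lora_scale * (lin.lora_A.data @ lin.lora_B.data)
        lin.lora_A = lin.lora_B = None
        lin.lora_scale = 1.0
        merged += 1
    if merged == 0:
        raise StrategyError("no adapters present (already merged?)")
    return model


def trainable_parameter_report(model: JointTransformer,
                               strategy: StrategyConfig) -> dict:
    """Frozen vs trainable totals for the strategy's final phase."""
    params = model.parameters()
    trainable_names = _trainable_names(params, strategy.strategy, final_phase=True)
    n_train = sum(int(np.prod(params[k].shape)) for k in trainable_names)
    n_total = sum(int(np.prod(p.shape)) for p in params.values())
    by_component: dict[str, int] = {}
    for k in trainable_names:
        comp = k.split(".")[0]
        by_component[comp] = by_component.get(comp, 0) + int(np.prod(params[k].shape))
    return {"trainable": n_train, "frozen": n_total - n_train,
            "total": n_total, "by_component": by_component}


def _trainable_names(params: dict[str, Tensor], strategy: str,
                     final_phase: bool) -> list[str]:
    def is_head(k: str) -> bool:
        return any(k.startswith(p) for p in HEAD_PREFIXES)

    def is_joint(k: str) -> bool:
        return k.startswith("joint.") and ".lora_" not in k

    if strategy in ("base", "ensemble") or not final_phase:
        return [k for k in params if (is_joint(k) or is_head(k)) and ".lora_" not in k]
    if strategy == "full":
        return [k for k in params if ".lora_" not in k]
    if strategy == "lora":
        return [k for k in params if ".lora_" in k or is_head(k)]
    raise StrategyError(strategy)


# ---------------------------------------------------------------------------
# bagging


def bootstrap_resample(n: int, member_index: int, seed: int) -> np.ndarray:
    """n draws with replacement, deterministic given (seed, member_index)."""
    if n < 1:
        raise StrategyError("cannot resample an empty dataset")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(member_index,)))
    return rng.integers(0, n, size=n)


# ---------------------------------------------------------------------------
# data preparation


@dataclass
class PreparedRecord:
    joint: object                # JointSequence
    y: np.ndarray                # (6,)
    avail: np.ndarray            # (6,) bool
    site_labels: np.ndarray | None
    site_avail: bool
    record_id: str


def prepare_records(records, protein_vocab: Vocabulary, ligand_vocab: Vocabulary,
                    representation: str = SMILES,
                    max_length: int | None = None) -> list[PreparedRecord]:
    """Tokenize and assemble once; reused across epochs."""
    out = []
    for r in records:
        prot = tokenize_protein(r.protein, protein_vocab)
        lig_string = r.smiles if representation == SMILES else r.selfies
        lig = tokenize_ligand(lig_string, representation, ligand_vocab)
        joint = assemble_joint(prot, [lig], protein_vocab, ligand_vocab, max_length)
        out.append(PreparedRecord(
            joint=joint, y=np.asarray(r.y, dtype=float),
            avail=np.asarray(r.avail, dtype=bool),
            site_labels=None if r.site_labels is None else np.asarray(r.site_labels),
            site_avail=bool(r.site_avail), record_id=r.record_id))
    return out


# ---------------------------------------------------------------------------
# losses over a batch


def batch_loss(model: JointTransformer, prepared: list[PreparedRecord],
               rng: np.random.Generator | None = None) -> Tensor:
    """Equal-weight multitask loss (six Gaussian tasks + site task)."""
    batch = collate([p.joint for p in prepared])
    emb = model.encode(batch, rng)
    mu, sigma = model.regress(emb, batch)
    y = np.stack([p.y for p in prepared])
    avail = np.stack([p.avail for p in prepared])
    components: dict[str, tuple] = {}
    for t in range(N_TASKS):
        rows = np.nonzero(avail[:, t])[0]
        if rows.size == 0:
            components[f"task{t}"] = (None, 0)
            continue
        nll = gaussian_nll(mu[rows, t], sigma[rows, t], Tensor(y[rows, t]))
        components[f"task{t}"] = (nll.mean(), rows.size)
    rows_idx, cols_idx, labels = [], [], []
    for i, p in enumerate(prepared):
        if not p.site_avail or p.site_labels is None:
            continue
        pos = batch.residue_positions(i)
        rows_idx.extend([i] * pos.size)
        cols_idx.extend(pos.tolist())
        labels.extend(p.site_labels.tolist())
    if labels:
        logits = model.site_logits(emb)
        flat = logits[np.array(rows_idx), np.array(cols_idx)]
        t = np.asarray(labels, dtype=float)
        per = flat.softplus() - flat * Tensor(t)
        components["site"] = (per.mean(), len(labels))
    else:
        components["site"] = (None, 0)
    return multitask_loss(components)


def dataset_loss(model: JointTransformer, prepared: list[PreparedRecord],
                 batch_size: int = 64) -> float:
    """Mean multitask loss over fixed batches (validation path)."""
    losses, weights = [], []
    with ad.no_grad():
        for lo in range(0, len(prepared), batch_size):
            chunk = prepared[lo:lo + batch_size]
            try:
                losses.append(float(batch_loss(model, chunk).data))
                weights.append(len(chunk))
            except ObjectiveError:
                continue
    if not losses:
        raise StrategyError("validation set has no labels at all")
    return float(np.average(losses, weights=weights))


# ---------------------------------------------------------------------------
# the training loop


class _SteadyState:
    """Validation steady-state stopper with relative tolerance."""

    def __init__(self, patience: int, tol: float):
        self.patience = patience
        self.tol = tol
        self.best = math.inf
        self.since = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's validation loss; True means stop now."""
        if math.isinf(self.best):
            threshold = math.inf
        else:
            threshold = self.best - self.tol * max(1.0, abs(self.best))
        if loss < threshold:
            self.best = loss
            self.since = 0
        else:
            self.since += 1
        return self.since >= self.patience


def steady_state_stop(val_losses: list[float], patience: int, tol: float
                      ) -> tuple[int, str]:
    """Epoch (1-based) at which training stops, and the reason."""
    stopper = _SteadyState(patience, tol)
    for epoch, loss in enumerate(val_losses, start=1):
        if stopper.update(loss):
            return epoch, "steady_state"
    return len(val_losses), "epoch_cap"


def _run_phase(model: JointTransformer, train_prep, val_prep,
               trainable: dict[str, Tensor], lr: float, epoch_cap: int,
               cfg: StrategyConfig, rng: np.random.Generator,
               history: TrainingHistory) -> None:
    if not train_prep or not val_prep:
        raise StrategyError("empty train or validation split")
    opt = Adam(trainable, lr=lr)
    stopper = _SteadyState(cfg.patience, cfg.tol)
    history.phase_starts.append(len(history.val_loss) + 1)
    all_params = model.parameters()
    # frozen parameters become graph constants: they receive zero gradient
    # and backward skips their subgraphs entirely
    for name, p in all_params.items():
        p.requires_grad = name in trainable
    try:
        _phase_epochs(model, train_prep, val_prep, opt, stopper, epoch_cap,
                      cfg, rng, history)
    finally:
        for p in all_params.values():
            p.requires_grad = True


def _phase_epochs(model, train_prep, val_prep, opt, stopper, epoch_cap,
                  cfg, rng, history) -> None:
    all_params = model.parameters()
    for epoch in range(epoch_cap):
        order = rng.permutation(len(train_prep))
        epoch_losses = []
        for lo in range(0, len(order), cfg.batch_size):
            chunk = [train_prep[i] for i in order[lo:lo + cfg.batch_size]]
            try:
                loss = batch_loss(model, chunk)
            except ObjectiveError:
                continue
            value = float(loss.data)
            if not math.isfinite(value):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch + 1}, batch {lo // cfg.batch_size}")
            for p in all_params.values():
                p.grad = None
            loss.backward()
            opt.step()
            epoch_losses.append(value)
        val = dataset_loss(model, val_prep, batch_size=max(64, cfg.batch_size))
        history.train_loss.append(float(np.mean(epoch_losses)) if epoch_losses else math.nan)
        history.val_loss.append(val)
        history.stop_epoch = len(history.val_loss)
        if stopper.update(val):
            history.stop_reason = "steady_state"
            return
    history.stop_reason = "epoch_cap"


@dataclass
class TrainResult:
    models: list[JointTransformer]
    histories: list[TrainingHistory]

    @property
    def model(self) -> JointTransformer:
        return self.models[0]


def _clone_with_seed(source: JointTransformer, seed: int) -> JointTransformer:
    """Fresh trainable parts (joint + heads), frozen encoders copied over."""
    cfg = ModelConfig.from_dict({**source.cfg.to_dict(), "seed": seed})
    member = JointTransformer(cfg)
    src = source.parameters()
    for k, p in member.parameters().items():
        if k.startswith(("protein.", "ligand.")):
            p.data = src[k].data.copy()
    return member


def train(model: JointTransformer, train_records, val_records,
          strategy: StrategyConfig, protein_vocab: Vocabulary,
          ligand_vocab: Vocabulary) -> TrainResult:
    """Run the configured finetuning strategy.

    base/full/lora train ``model`` in place and return it; ensemble leaves
    ``model`` untouched (it provides the frozen encoders) and returns the M
    trained members.
    """
    if not train_records or not val_records:
        raise StrategyError("empty train or validation split")
    max_len = model.cfg.max_joint_len
    train_prep = prepare_records(train_records, protein_vocab, ligand_vocab,
                                 strategy.representation, max_len)
    val_prep = prepare_records(val_records, protein_vocab, ligand_vocab,
                               strategy.representation, max_len)

    if strategy.strategy == "ensemble":
        models, histories = [], []
        for m in range(strategy.members):
            seed_seq = np.random.SeedSequence(strategy.seed, spawn_key=(100 + m,))
            member_seed = int(seed_seq.generate_state(1)[0] % (2 ** 31))
            member = _clone_with_seed(model, member_seed)
            idx = bootstrap_resample(len(train_prep), m, strategy.bagging_seed)
            subset = [train_prep[i] for i in idx]
            hist = TrainingHistory()
            rng = np.random.default_rng(np.random.SeedSequence(strategy.seed, spawn_key=(200 + m,)))
            params = member.parameters()
            names = _trainable_names(params, "base", final_phase=True)
            _run_phase(member, subset, val_prep, {k: params[k] for k in names},
                       strategy.lr_phase1, strategy.epochs_phase1, strategy, rng, hist)
            models.append(member)
            histories.append(hist)
        return TrainResult(models, histories)

    history = TrainingHistory()
    rng = np.random.default_rng(np.random.SeedSequence(strategy.seed, spawn_key=(50,)))
    params = model.parameters()
    phase1 = _trainable_names(params, strategy.strategy, final_phase=False)
    _run_phase(model, train_prep, val_prep, {k: params[k] for k in phase1},
               strategy.lr_phase1, strategy.epochs_phase1, strategy, rng, history)

    if strategy.strategy in ("full", "lora") and strategy.epochs_phase2 > 0:
        if strategy.strategy == "lora":
            inject_lora(model, strategy.rank, scale=strategy.lora_scale,
                        seed=strategy.seed)
        params = model.parameters()
        phase2 = _trainable_names(params, strategy.strategy, final_phase=True)
        _run_phase(model, train_prep, val_prep, {k: params[k] for k in phase2},
                   strategy.lr_phase2, strategy.epochs_phase2, strategy, rng, history)
    return TrainResult([model], [history])


# ---------------------------------------------------------------------------
# masked-LM pretraining


def pretrain(model: JointTransformer, records, protein_vocab: Vocabulary,
             ligand_vocab: Vocabulary, epochs: int = 2, mask_rate: float = 0.15,
             lr: float = 1e-3, batch_size: int = 32, seed: int = 0,
             representation: str = SMILES) -> TrainingHistory:
    """Masked-token pretraining over both modalities; all weights train."""
    prep = prepare_records(records, protein_vocab, ligand_vocab, representation,
                           model.cfg.max_joint_len)
    params = model.parameters()
    opt = Adam(params, lr=lr)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(60,)))
    history = TrainingHistory()
    for _ in range(epochs):
        order = rng.permutation(len(prep))
        losses = []
        for lo in range(0, len(order), batch_size):
            chunk = [prep[i] for i in order[lo:lo + batch_size]]
            results = [corrupt_for_mlm(p.joint, mask_rate, rng) for p in chunk]
            if not any(r.positions for r in results):
                continue
            batch = collate([r.corrupted for r in results])
            emb = model.encode(batch)
            logp_p, logp_l = model.predict_masked(emb, batch)
            loss, _ = masked_lm_loss(logp_p, logp_l, batch, results)
            value = float(loss.data)
            if not math.isfinite(value):
                raise TrainingDiverged("non-finite masked-LM loss")
            for p in params.values():
                p.grad = None
            loss.backward()
            opt.step()
            losses.append(value)
        history.train_loss.append(float(np.mean(losses)))
        history.stop_epoch = len(history.train_loss)
    history.stop_reason = "epoch_cap"
    return history
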
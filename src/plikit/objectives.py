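"""Training objectives: Gaussian NLL, site BCE, masked-LM corruption, and the
equal-weight multitask combination with missing-label masking.

The regression loss is the heteroscedastic Gaussian negative log-likelihood

    nll(mu, sigma, y) = 1/2 * ln(2 pi sigma^2) + (y - mu)^2 / (2 sigma^2),

averaged over the labels actually present in a batch.  Every task (the six
regression targets plus the site task, plus the masked-LM loss during
pretraining) enters the total with equal weight; tasks with no available
label in a batch contribute nothing and do not change the divisor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .tokenization import JointSequence, MOD_SPECIAL

LOG_2PI = math.log(2.0 * math.pi)


class ObjectiveError(ValueError):
    pass


def gaussian_nll(mu, sigma, y):
    """Pointwise Gaussian NLL; works on Tensors (training) or floats/arrays.

    The batch value used in training is the mean over available labels only.
    """
    if isinstance(mu, Tensor) or isinstance(sigma, Tensor) or isinstance(y, Tensor):
        mu = mu if isinstance(mu, Tensor) else Tensor(mu)
        sigma = sigma if isinstance(sigma, Tensor) else Tensor(sigma)
        y = y if isinstance(y, Tensor) else Tensor(y)
        if np.any(sigma.data <= 0):
            raise ObjectiveError("sigma must be positive (softplus floor upstream)")
        var = sigma * sigma
        return 0.5 * (var.log() + LOG_2PI) + ((y - mu) ** 2.0) / (2.0 * var)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(sigma <= 0):
        raise ObjectiveError("sigma must be positive (softplus floor upstream)")
    return 0.5 * (np.log(sigma ** 2) + LOG_2PI) + (y - mu) ** 2 / (2.0 * sigma ** 2)


def site_loss(probabilities, labels) -> float:
    """Mean binary cross-entropy over labeled residues (NumPy, analysis path).

    Training uses the logit-space variant below for numerical stability.
    """
    p = np.asarray(probabilities, dtype=float)
    t = np.asarray(labels, dtype=float)
    if p.shape != t.shape:
        raise ObjectiveError(f"length mismatch: {p.shape} probabilities vs {t.shape} labels")
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(np.mean(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))))


def site_loss_from_logits(logits: Tensor, labels: np.ndarray, mask: np.ndarray) -> Tensor:
    """Masked mean BCE computed from logits: softplus(z) - t*z, stable for any z.

    ``mask`` selects labeled residue positions; must select at least one.
    """
    w = mask.astype(float)
    total = w.sum()
    if total == 0:
        raise ObjectiveError("site loss requested with no labeled residues")
    t = Tensor(labels.astype(float))
    per = logits.softplus() - logits * t
    return (per * Tensor(w)).sum() * (1.0 / total)


@dataclass
class CorruptionResult:
    corrupted: JointSequence
    positions: list[int]          # joint-axis indices that were selected
    targets: list[int]            # original merged ids at those positions


def corrupt_for_mlm(joint: JointSequence, mask_rate: float,
                    rng: np.random.Generator) -> CorruptionResult:
    """BERT-style corruption: each non-special position is selected i.i.d.
    with probability ``mask_rate``; of the selected, 80% become MASK, 10% a
    random same-modality token, 10% stay unchanged.  Targets are the original
    ids.  Deterministic given the generator state.
    """
    if not (0.0 < mask_rate < 1.0):
        raise ObjectiveError("mask_rate must lie strictly between 0 and 1")
    Vp = joint.protein_vocab_size
    # special-token rows of each vocabulary occupy ids 0..5 by construction
    ids = list(joint.ids)
    positions: list[int] = []
    targets: list[int] = []
    mask_id_protein = 3            # MASK id within either vocabulary
    mask_id_ligand = Vp + 3
    for pos, (tok, mod) in enumerate(zip(joint.ids, joint.modality_mask)):
        if mod == MOD_SPECIAL:
            continue
        if rng.random() >= mask_rate:
            continue
        positions.append(pos)
        targets.append(tok)
        action = rng.random()
        if action < 0.8:
            ids[pos] = mask_id_protein if tok < Vp else mask_id_ligand
        elif action < 0.9:
            if tok < Vp:
                ids[pos] = int(rng.integers(6, Vp))
            else:
                ids[pos] = int(Vp + rng.integers(6, joint.ligand_vocab_size))
        # else: leave unchanged
    corrupted = JointSequence(ids=ids, modality_mask=list(joint.modality_mask),
                              protein_span=joint.protein_span,
                              ligand_spans=list(joint.ligand_spans),
                              protein_vocab_size=Vp,
                              ligand_vocab_size=joint.ligand_vocab_size)
    return CorruptionResult(corrupted, positions, targets)


@dataclass
class LossReport:
    """Per-component losses with the example counts actually used."""

    components: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    total: float = float("nan")

    def add(self, name: str, value: float, count: int) -> None:
        if count > 0:
            self.components[name] = float(value)
            self.counts[name] = int(count)


def multitask_loss(components):
    """Equal-weight mean over components that have at least one label.

    Accepts either a dict name->(value, count) or name->Tensor/float for the
    training path; entries with count 0 are dropped before averaging.
    """
    live = []
    for name, entry in components.items():
        if isinstance(entry, tuple):
            value, count = entry
            if count < 1:
                continue
            live.append(value)
        elif entry is not None:
            live.append(entry)
    if not live:
        raise ObjectiveError("multitask loss needs at least one component with labels")
    total = live[0]
    for v in live[1:]:
        total = total + v
    return total * (1.0 / len(live))


def masked_lm_loss(prot_log_probs: Tensor, lig_log_probs: Tensor,
                   batch, corruption_results: list[CorruptionResult]) -> tuple[Tensor, int]:
    """Mean cross-entropy of the true token at selected positions.

    Positions in each CorruptionResult are joint-sequence indices; the batch
    pads the protein and ligand segments separately, so ligand positions are
    shifted by (padded protein length - true protein segment length).
    """
    rows_p, cols_p, tgt_p = [], [], []
    rows_l, cols_l, tgt_l = [], [], []
    Tp = batch.prot_len
    for i, res in enumerate(corruption_results):
        js = batch.sequences[i]
        prot_seg_len = js.protein_span[1] + 1
        for pos, tok in zip(res.positions, res.targets):
            if tok < js.protein_vocab_size:
                rows_p.append(i)
                cols_p.append(pos)
                tgt_p.append(tok)
            else:
                rows_l.append(i)
                cols_l.append(pos - prot_seg_len + Tp)
                tgt_l.append(tok - js.protein_vocab_size)
    n = len(tgt_p) + len(tgt_l)
    if n == 0:
        raise ObjectiveError("no masked positions in batch")
    parts = []
    if tgt_p:
        parts.append(-prot_log_probs[np.array(rows_p), np.array(cols_p), np.array(tgt_p)].sum())
    if tgt_l:
        parts.append(-lig_log_probs[np.array(rows_l), np.array(cols_l), np.array(tgt_l)].sum())
    total = parts[0]
    for p in parts[1:]:
        total = total + p
    return total * (1.0 / n), n
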
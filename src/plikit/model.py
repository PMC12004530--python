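"""Scale-configurable joint protein-ligand transformer with multitask heads.

The network mirrors the two-tower-plus-joint design used for sequence-based
interaction prediction: a protein encoder and a ligand encoder (pre-norm
transformer stacks with modality-specific token and learned positional
embeddings) run independently over their segments; their per-token outputs
are concatenated along the sequence axis, a learned modality (segment)
embedding is added, and one or more joint transformer layers self-attend
across both modalities.  Four heads read the joint representation:

* six-task Gaussian regression (kcat, Km, Ki, Kd, IC50, EC50 on log10
  scale): mean-pool over non-PAD, non-special positions, one affine map per
  task to (mu, raw_s) with sigma = softplus(raw_s) + 1e-4;
* per-residue functional-site classification: per-token affine + logistic,
  applied only to protein residue positions (ligand tokens excluded);
* masked-token prediction for each modality over its own vocabulary.

Everything runs on the bundled NumPy autodiff engine; the "tiny" preset is
the test surface, the "reference" preset mirrors the 480-dimensional
embedding scale of the encoder family the design derives from.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .tokenization import (
    JointSequence, MOD_LIGAND, MOD_PROTEIN, MOD_SPECIAL,
)

TASKS = ("kcat", "Km", "Ki", "Kd", "IC50", "EC50")
N_TASKS = len(TASKS)
SIGMA_FLOOR = 1e-4

# modality code for padded positions in a batch
MOD_PAD = -1


class ConfigError(ValueError):
    pass


@dataclass
class ModelConfig:
    embed_dim: int = 32
    n_heads: int = 4
    protein_layers: int = 2
    ligand_layers: int = 2
    joint_layers: int = 1
    ffn_dim: int = 64
    dropout: float = 0.0
    max_protein_len: int = 128
    max_ligand_len: int = 64
    protein_vocab_size: int = 27
    ligand_vocab_size: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ConfigError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}")
        for name in ("embed_dim", "n_heads", "ffn_dim", "max_protein_len", "max_ligand_len"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    @property
    def max_joint_len(self) -> int:
        return self.max_protein_len + self.max_ligand_len

    @classmethod
    def preset(cls, name: str, **overrides) -> "ModelConfig":
        """Named presets: "tiny" (test surface) and "reference" (480-dim scale)."""
        if name == "tiny":
            base = dict(embed_dim=32, n_heads=4, protein_layers=2, ligand_layers=2,
                        joint_layers=1, ffn_dim=64)
        elif name == "reference":
            base = dict(embed_dim=480, n_heads=20, protein_layers=12, ligand_layers=12,
                        joint_layers=1, ffn_dim=1920)
        else:
            raise ConfigError(f"unknown preset {name!r}; use 'tiny' or 'reference'")
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# layers


class Linear:
    """Affine map with optional low-rank (LoRA) adapter.

    Weight layout: ``y = x @ W + b`` with W of shape (d_in, d_out).  When an
    adapter (A: d_in x r, B: r x d_out, scale) is attached, the effective
    weight is W + scale * A @ B; W stays frozen by convention of the training
    strategies, the adapter carries the update.
    """

    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.d_in, self.d_out = d_in, d_out
        self.W = Tensor(rng.normal(0.0, d_in ** -0.5, size=(d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)
        self.lora_A: Tensor | None = None
        self.lora_B: Tensor | None = None
        self.lora_scale: float = 1.0

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W + self.b
        if self.lora_A is not None:
            y = y + ((x @ self.lora_A) @ self.lora_B) * self.lora_scale
        return y

    def named_params(self, prefix: str) -> dict[str, Tensor]:
        out = {f"{prefix}.W": self.W, f"{prefix}.b": self.b}
        if self.lora_A is not None:
            out[f"{prefix}.lora_A"] = self.lora_A
            out[f"{prefix}.lora_B"] = self.lora_B
        return out


class LayerNorm:
    def __init__(self, dim: int):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = 1e-5

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layernorm(x, self.gamma, self.beta, self.eps)

    def named_params(self, prefix: str) -> dict[str, Tensor]:
        return {f"{prefix}.gamma": self.gamma, f"{prefix}.beta": self.beta}


class MultiHeadAttention:
    def __init__(self, rng: np.random.Generator, dim: int, n_heads: int):
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.wq = Linear(rng, dim, dim)
        self.wk = Linear(rng, dim, dim)
        self.wv = Linear(rng, dim, dim)
        self.wo = Linear(rng, dim, dim)

    def __call__(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        """x: (B, T, E); key_mask: (B, T) bool, True where attendable."""
        B, T, E = x.shape
        H, dh = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, H, dh).transpose(0, 2, 1, 3)  # (B,H,T,dh)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (dh ** -0.5)  # (B,H,T,T)
        bias = np.where(key_mask[:, None, None, :], 0.0, -1e9)
        attn = (scores + Tensor(bias)).softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, E)
        return self.wo(out)

    def named_params(self, prefix: str) -> dict[str, Tensor]:
        out = {}
        for name in ("wq", "wk", "wv", "wo"):
            out.update(getattr(self, name).named_params(f"{prefix}.{name}"))
        return out


class TransformerBlock:
    """Pre-norm block: x + attn(LN(x)), then x + ffn(LN(x))."""

    def __init__(self, rng: np.random.Generator, dim: int, n_heads: int, ffn_dim: int,
                 dropout: float = 0.0):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(rng, dim, n_heads)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(rng, dim, ffn_dim)
        self.ff2 = Linear(rng, ffn_dim, dim)
        self.dropout = dropout

    def __call__(self, x: Tensor, key_mask: np.ndarray,
                 rng: np.random.Generator | None = None) -> Tensor:
        h = self.attn(self.ln1(x), key_mask)
        h = _maybe_dropout(h, self.dropout, rng)
        x = x + h
        h = self.ff2(self.ff1(self.ln2(x)).gelu())
        h = _maybe_dropout(h, self.dropout, rng)
        return x + h

    def named_params(self, prefix: str) -> dict[str, Tensor]:
        out = {}
        out.update(self.ln1.named_params(f"{prefix}.ln1"))
        out.update(self.attn.named_params(f"{prefix}.attn"))
        out.update(self.ln2.named_params(f"{prefix}.ln2"))
        out.update(self.ff1.named_params(f"{prefix}.ff1"))
        out.update(self.ff2.named_params(f"{prefix}.ff2"))
        return out

    def linears(self) -> dict[str, Linear]:
        """The adapter-eligible weight matrices of this block."""
        return {"attn.wq": self.attn.wq, "attn.wk": self.attn.wk,
                "attn.wv": self.attn.wv, "attn.wo": self.attn.wo,
                "ff1": self.ff1, "ff2": self.ff2}


def _maybe_dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    if p <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(keep)


class Encoder:
    """Modality-specific stack: token + learned positional embedding, blocks, final LN."""

    def __init__(self, rng: np.random.Generator, vocab_size: int, max_len: int,
                 n_layers: int, cfg: ModelConfig):
        E = cfg.embed_dim
        self.tok_emb = Tensor(rng.normal(0.0, 0.02, size=(vocab_size, E)), requires_grad=True)
        self.pos_emb = Tensor(rng.normal(0.0, 0.02, size=(max_len, E)), requires_grad=True)
        self.blocks = [TransformerBlock(rng, E, cfg.n_heads, cfg.ffn_dim, cfg.dropout)
                       for _ in range(n_layers)]
        self.final_ln = LayerNorm(E)

    def __call__(self, ids: np.ndarray, key_mask: np.ndarray,
                 rng: np.random.Generator | None = None) -> Tensor:
        T = ids.shape[1]
        x = ad.embedding(self.tok_emb, ids) + self.pos_emb[:T]
        for blk in self.blocks:
            x = blk(x, key_mask, rng)
        return self.final_ln(x)

    def named_params(self, prefix: str) -> dict[str, Tensor]:
        out = {f"{prefix}.tok_emb": self.tok_emb, f"{prefix}.pos_emb": self.pos_emb}
        for i, blk in enumerate(self.blocks):
            out.update(blk.named_params(f"{prefix}.blocks.{i}"))
        out.update(self.final_ln.named_params(f"{prefix}.final_ln"))
        return out


# ---------------------------------------------------------------------------
# batching


@dataclass
class Batch:
    """Padded arrays for a list of joint sequences.

    The protein segment (BOS..EOS) and ligand segment (SEP ligand [SEP
    ligand]*) are padded separately; the joint sequence is their
    concatenation, so per-record PAD runs sit at the end of each segment.
    ``modality``: MOD_PAD at padding, else the JointSequence modality code.
    """

    prot_ids: np.ndarray      # (B, Tp) protein-vocabulary ids
    lig_ids: np.ndarray       # (B, Tl) ligand-vocabulary ids
    prot_valid: np.ndarray    # (B, Tp) bool
    lig_valid: np.ndarray     # (B, Tl) bool
    modality: np.ndarray      # (B, Tp+Tl) int
    sequences: list[JointSequence]

    @property
    def joint_valid(self) -> np.ndarray:
        return np.concatenate([self.prot_valid, self.lig_valid], axis=1)

    @property
    def n_records(self) -> int:
        return self.prot_ids.shape[0]

    @property
    def prot_len(self) -> int:
        return self.prot_ids.shape[1]

    def residue_positions(self, record: int) -> np.ndarray:
        """Joint-axis indices of protein residue positions for one record."""
        return np.nonzero(self.modality[record] == MOD_PROTEIN)[0]


def collate(sequences: list[JointSequence], protein_pad_id: int = 0,
            ligand_pad_id: int = 0) -> Batch:
    segs = [js.segments() for js in sequences]
    Tp = max(len(p) for p, _ in segs)
    Tl = max(len(l) for _, l in segs)
    B = len(sequences)
    prot_ids = np.full((B, Tp), protein_pad_id, dtype=np.intp)
    lig_ids = np.full((B, Tl), ligand_pad_id, dtype=np.intp)
    prot_valid = np.zeros((B, Tp), dtype=bool)
    lig_valid = np.zeros((B, Tl), dtype=bool)
    modality = np.full((B, Tp + Tl), MOD_PAD, dtype=np.int8)
    for i, (js, (p, l)) in enumerate(zip(sequences, segs)):
        prot_ids[i, :len(p)] = p
        prot_valid[i, :len(p)] = True
        lig_ids[i, :len(l)] = l
        lig_valid[i, :len(l)] = True
        modality[i, :len(p)] = js.modality_mask[:len(p)]
        modality[i, Tp:Tp + len(l)] = js.modality_mask[len(p):]
    return Batch(prot_ids, lig_ids, prot_valid, lig_valid, modality, list(sequences))


# ---------------------------------------------------------------------------
# the model


@dataclass
class GaussianPrediction:
    """Per-task (mu, sigma) on log10 scale; arrays of shape (N_TASKS,)."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != (N_TASKS,) or self.sigma.shape != (N_TASKS,):
            raise ValueError(f"expected {N_TASKS}-task prediction arrays")
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.sigma))):
            raise ValueError("non-finite prediction")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")


class JointTransformer:
    """The full network; construction is deterministic given config.seed."""

    def __init__(self, cfg: ModelConfig):
        if cfg.ligand_vocab_size < 7:
            raise ConfigError("ligand_vocab_size not set (build vocabularies first)")
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
        E = cfg.embed_dim
        self.protein_encoder = Encoder(rng, cfg.protein_vocab_size, cfg.max_protein_len + 2,
                                       cfg.protein_layers, cfg)
        self.ligand_encoder = Encoder(rng, cfg.ligand_vocab_size, cfg.max_ligand_len + 2,
                                      cfg.ligand_layers, cfg)
        self.segment_emb = Tensor(rng.normal(0.0, 0.02, size=(3, E)), requires_grad=True)
        self.joint_blocks = [TransformerBlock(rng, E, cfg.n_heads, cfg.ffn_dim, cfg.dropout)
                             for _ in range(cfg.joint_layers)]
        self.joint_ln = LayerNorm(E)
        self.reg_head = Linear(rng, E, 2 * N_TASKS)
        self.site_head = Linear(rng, E, 1)
        self.mlm_protein_head = Linear(rng, E, cfg.protein_vocab_size)
        self.mlm_ligand_head = Linear(rng, E, cfg.ligand_vocab_size)

    # -- parameter bookkeeping ----------------------------------------------

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        out.update(self.protein_encoder.named_params("protein"))
        out.update(self.ligand_encoder.named_params("ligand"))
        out["joint.segment_emb"] = self.segment_emb
        for i, blk in enumerate(self.joint_blocks):
            out.update(blk.named_params(f"joint.blocks.{i}"))
        out.update(self.joint_ln.named_params("joint.final_ln"))
        out.update(self.reg_head.named_params("heads.regression"))
        out.update(self.site_head.named_params("heads.site"))
        out.update(self.mlm_protein_head.named_params("heads.mlm_protein"))
        out.update(self.mlm_ligand_head.named_params("heads.mlm_ligand"))
        return out

    def block_linears(self) -> dict[str, Linear]:
        """All adapter-eligible attention/FFN matrices, keyed by dotted path."""
        out: dict[str, Linear] = {}
        for tower, blocks in (("protein", self.protein_encoder.blocks),
                              ("ligand", self.ligand_encoder.blocks),
                              ("joint", self.joint_blocks)):
            for i, blk in enumerate(blocks):
                for name, lin in blk.linears().items():
                    out[f"{tower}.blocks.{i}.{name}"] = lin
        return out

    def n_parameters(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.parameters().values())

    # -- forward -------------------------------------------------------------

    def encode(self, batch: Batch, rng: np.random.Generator | None = None) -> Tensor:
        """Per-token joint embeddings, shape (B, Tp+Tl, E).

        With zero joint layers the output is exactly the concatenated
        per-modality encoder outputs (no segment embedding, no extra norm).
        """
        if batch.prot_ids.shape[1] > self.cfg.max_protein_len + 2:
            raise ConfigError(
                f"protein segment length {batch.prot_ids.shape[1]} exceeds "
                f"max_protein_len+2={self.cfg.max_protein_len + 2}")
        if batch.lig_ids.shape[1] > self.cfg.max_ligand_len + 2:
            raise ConfigError(
                f"ligand segment length {batch.lig_ids.shape[1]} exceeds "
                f"max_ligand_len+2={self.cfg.max_ligand_len + 2}")
        hp = self.protein_encoder(batch.prot_ids, batch.prot_valid, rng)
        hl = self.ligand_encoder(batch.lig_ids, batch.lig_valid, rng)
        x = ad.concat([hp, hl], axis=1)
        if not self.joint_blocks:
            return x
        seg_ids = np.clip(batch.modality, 0, 2).astype(np.intp)  # PAD rows share special row
        x = x + ad.embedding(self.segment_emb, seg_ids)
        key_mask = batch.joint_valid
        for blk in self.joint_blocks:
            x = blk(x, key_mask, rng)
        return self.joint_ln(x)

    def regress(self, embeddings: Tensor, batch: Batch) -> tuple[Tensor, Tensor]:
        """Pooled Gaussian heads.  Returns (mu, sigma), each (B, N_TASKS).

        Pooling is the arithmetic mean over non-PAD, non-special positions
        (protein residues and ligand tokens), so padding length cannot move
        the pooled statistic.
        """
        pool_mask = (batch.modality == MOD_PROTEIN) | (batch.modality == MOD_LIGAND)
        w = pool_mask.astype(float)
        w = w / w.sum(axis=1, keepdims=True)
        pooled = (embeddings * Tensor(w[:, :, None])).sum(axis=1)  # (B, E)
        out = self.reg_head(pooled)
        mu = out[:, :N_TASKS]
        sigma = out[:, N_TASKS:].softplus() + SIGMA_FLOOR
        return mu, sigma

    def site_logits(self, embeddings: Tensor) -> Tensor:
        """Per-position site logits, shape (B, T); caller masks to residues."""
        return self.site_head(embeddings).reshape(embeddings.shape[0], embeddings.shape[1])

    def classify_sites(self, embeddings: Tensor, batch: Batch) -> list[np.ndarray]:
        """Per-record functional-site probabilities over protein residues only."""
        probs = self.site_logits(embeddings).sigmoid()
        out = []
        for i in range(batch.n_records):
            pos = batch.residue_positions(i)
            out.append(probs.data[i, pos].copy())
        return out

    def predict_masked(self, embeddings: Tensor, batch: Batch
                       ) -> tuple[Tensor, Tensor]:
        """Per-position log-distributions over each modality's own vocabulary.

        Returns (protein_log_probs (B,T,Vp), ligand_log_probs (B,T,Vl));
        rows are meaningful only at positions of the matching modality.
        """
        return (self.mlm_protein_head(embeddings).log_softmax(axis=-1),
                self.mlm_ligand_head(embeddings).log_softmax(axis=-1))

    # -- convenience single-record API ---------------------------------------

    def predict_record(self, joint: JointSequence) -> tuple[GaussianPrediction, np.ndarray]:
        """(GaussianPrediction, site probabilities) for one joint sequence."""
        with ad.no_grad():
            batch = collate([joint])
            emb = self.encode(batch)
            mu, sigma = self.regress(emb, batch)
            sites = self.classify_sites(emb, batch)[0]
        return GaussianPrediction(mu.data[0], sigma.data[0]), sites

    # -- state ----------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ConfigError(f"state mismatch: missing={sorted(missing)[:3]} extra={sorted(extra)[:3]}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ConfigError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()


# -- spec-level functional wrappers (single sequence) ------------------------

def encode(joint: JointSequence, model: JointTransformer) -> np.ndarray:
    """Joint embeddings for a single sequence, shape (len(joint), E)."""
    with ad.no_grad():
        batch = collate([joint])
        return model.encode(batch).data[0]


def regress(joint: JointSequence, model: JointTransformer) -> GaussianPrediction:
    pred, _ = model.predict_record(joint)
    return pred


def classify_sites(joint: JointSequence, model: JointTransformer) -> np.ndarray:
    _, sites = model.predict_record(joint)
    return sites
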
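"""Vocabularies and tokenizers for protein sequences and SMILES/SELFIES ligands.

Proteins are tokenized one residue per token over the 20 canonical amino
acids plus X; letters outside that alphabet map to UNK (counted, not fatal).
SMILES strings are scanned greedily left to right: two-character halogens
(Cl, Br) and whole bracket atoms ``[...]`` become single tokens, everything
else is one character.  SELFIES strings are a closed set of bracketed
symbols.  A joint protein-ligand input is laid out as

    BOS  protein...  EOS  SEP  ligand...  [SEP ligand...]*

with a per-position modality mask distinguishing protein, ligand, and
special positions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

PROTEIN = "protein"
SMILES = "smiles"
SELFIES = "selfies"
MODALITIES = (PROTEIN, SMILES, SELFIES)

PAD, BOS, EOS, MASK, UNK, SEP = SPECIALS = (
    "<pad>", "<bos>", "<eos>", "<mask>", "<unk>", "<sep>",
)

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY") + ("X",)

# Organic-subset atoms (upper and aromatic lowercase), two-character
# halogens, bond/ring/branch/charge punctuation.
SMILES_ALPHABET = (
    tuple("BCNOPSFI") + tuple("bcnops")
    + ("Cl", "Br")
    + tuple("-=#:/\\") + tuple("()") + tuple("123456789") + ("+", ".", "%")
)

# Default closed symbol set for SELFIES-style bracket tokens: the symbols the
# bundled synthetic ligand grammar emits plus a few common organic symbols.
SELFIES_ALPHABET = (
    "[C]", "[N]", "[O]", "[F]", "[S]", "[P]",
    "[=C]", "[=N]", "[=O]", "[#C]", "[#N]",
    "[Branch1]", "[EndBranch1]", "[Branch2]", "[EndBranch2]",
    "[Ring1]", "[Ring2]",
)

# Modality codes used in JointSequence.modality_mask
MOD_SPECIAL = 0
MOD_PROTEIN = 1
MOD_LIGAND = 2


class TokenizationError(ValueError):
    """Raised on malformed or out-of-alphabet input."""


@dataclass(frozen=True)
class Vocabulary:
    """An ordered token table with the six special tokens at the front.

    Invariants: ids are contiguous from 0, PAD has id 0, each special token
    appears exactly once, and ``id_of[tokens[i]] == i``.
    """

    modality: str
    tokens: tuple[str, ...]
    id_of: dict[str, int] = field(compare=False)

    def __len__(self) -> int:
        return len(self.tokens)

    def id(self, token: str) -> int:
        return self.id_of[token]

    def token(self, idx: int) -> str:
        return self.tokens[idx]

    def __contains__(self, token: str) -> bool:
        return token in self.id_of

    @property
    def pad_id(self) -> int:
        return self.id_of[PAD]

    @property
    def bos_id(self) -> int:
        return self.id_of[BOS]

    @property
    def eos_id(self) -> int:
        return self.id_of[EOS]

    @property
    def mask_id(self) -> int:
        return self.id_of[MASK]

    @property
    def unk_id(self) -> int:
        return self.id_of[UNK]

    @property
    def sep_id(self) -> int:
        return self.id_of[SEP]

    def non_special_ids(self) -> list[int]:
        return [i for i, t in enumerate(self.tokens) if t not in SPECIALS]

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {"modality": self.modality, "tokens": list(self.tokens), "specials": list(SPECIALS)},
            indent=0,
        )

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        obj = json.loads(text)
        tokens = tuple(obj["tokens"])
        return cls(modality=obj["modality"], tokens=tokens,
                   id_of={t: i for i, t in enumerate(tokens)})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        return cls.from_json(Path(path).read_text())

    def content_hash(self) -> str:
        """Stable hash used to pin checkpoints to the vocabulary they assume."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def build_vocabulary(modality: str, extra_tokens: tuple[str, ...] = ()) -> Vocabulary:
    """Build the vocabulary for one modality.

    Base alphabets: protein = 20 canonical amino acids + X; smiles = the
    organic-subset scanner alphabet; selfies = the documented default bracket
    symbol set.  ``extra_tokens`` append fresh ids (e.g. bracket atoms like
    ``[nH]`` for SMILES); duplicating an existing token is an error.
    """
    if modality not in MODALITIES:
        raise TokenizationError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    base = {PROTEIN: AMINO_ACIDS, SMILES: SMILES_ALPHABET, SELFIES: SELFIES_ALPHABET}[modality]
    tokens = list(SPECIALS) + list(base)
    seen = set(tokens)
    for tok in extra_tokens:
        if tok in seen:
            raise TokenizationError(f"duplicate token {tok!r} already present in the {modality} vocabulary")
        tokens.append(tok)
        seen.add(tok)
    tokens = tuple(tokens)
    return Vocabulary(modality=modality, tokens=tokens,
                      id_of={t: i for i, t in enumerate(tokens)})


@dataclass
class TokenSequence:
    """Tokenized single-modality string: parallel ids and surface tokens."""

    modality: str
    ids: list[int]
    surface: list[str]
    n_unknown: int = 0

    def __len__(self) -> int:
        return len(self.ids)

    def detokenize(self) -> str:
        return "".join(self.surface)


def tokenize_protein(sequence: str, vocab: Vocabulary | None = None) -> TokenSequence:
    """One token per residue; out-of-alphabet letters map to UNK (counted)."""
    if vocab is None:
        vocab = build_vocabulary(PROTEIN)
    if not sequence:
        raise TokenizationError("empty protein sequence")
    if sequence != sequence.upper():
        raise TokenizationError(
            "protein sequence contains lowercase letters; normalize to uppercase first")
    ids, surface, n_unknown = [], [], 0
    for ch in sequence:
        if ch in vocab.id_of and ch not in SPECIALS:
            ids.append(vocab.id(ch))
            surface.append(ch)
        else:
            ids.append(vocab.unk_id)
            surface.append(ch)
            n_unknown += 1
    return TokenSequence(PROTEIN, ids, surface, n_unknown)


def _scan_smiles(string: str) -> list[str]:
    out: list[str] = []
    i = 0
    n = len(string)
    while i < n:
        ch = string[i]
        if ch == "[":
            j = string.find("]", i)
            if j < 0:
                raise TokenizationError(f"unbalanced bracket opened at position {i}")
            out.append(string[i:j + 1])
            i = j + 1
        elif ch == "]":
            raise TokenizationError(f"unbalanced closing bracket at position {i}")
        elif string[i:i + 2] in ("Cl", "Br"):
            out.append(string[i:i + 2])
            i += 2
        else:
            out.append(ch)
            i += 1
    return out


def _scan_selfies(string: str) -> list[str]:
    out: list[str] = []
    i = 0
    n = len(string)
    while i < n:
        if string[i] != "[":
            raise TokenizationError(f"expected '[' at position {i} of SELFIES string")
        j = string.find("]", i)
        if j < 0:
            raise TokenizationError(f"unbalanced bracket opened at position {i}")
        out.append(string[i:j + 1])
        i = j + 1
    return out


def tokenize_ligand(string: str, representation: str,
                    vocab: Vocabulary | None = None) -> TokenSequence:
    """Tokenize a SMILES or SELFIES ligand string.

    Unknown symbols are rejected rather than UNK-mapped: malformed chemistry
    should not pass silently.
    """
    if representation not in (SMILES, SELFIES):
        raise TokenizationError(f"representation must be smiles or selfies, got {representation!r}")
    if not string:
        raise TokenizationError("empty ligand string")
    if vocab is None:
        vocab = build_vocabulary(representation)
    surface = _scan_smiles(string) if representation == SMILES else _scan_selfies(string)
    ids = []
    for pos, tok in enumerate(surface):
        if tok not in vocab.id_of or tok in SPECIALS:
            raise TokenizationError(
                f"unknown {representation} symbol {tok!r} (token index {pos}); "
                "add it to the vocabulary via extra_tokens")
        ids.append(vocab.id(tok))
    return TokenSequence(representation, ids, surface)


@dataclass
class JointSequence:
    """Concatenated protein+ligand token ids over a merged id space.

    Layout: ``BOS protein EOS`` then, per ligand, ``SEP ligand``.  Protein ids
    keep their protein-vocabulary values; ligand and SEP ids are offset by the
    protein vocabulary size.  ``modality_mask`` holds MOD_SPECIAL /
    MOD_PROTEIN / MOD_LIGAND per position.
    """

    ids: list[int]
    modality_mask: list[int]
    protein_span: tuple[int, int]
    ligand_spans: list[tuple[int, int]]
    protein_vocab_size: int
    ligand_vocab_size: int

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def ligand_span(self) -> tuple[int, int]:
        """Hull of all ligand spans (equals the single span for one ligand)."""
        return (self.ligand_spans[0][0], self.ligand_spans[-1][1])

    @property
    def n_protein_residues(self) -> int:
        a, b = self.protein_span
        return b - a

    def segments(self) -> tuple[list[int], list[int]]:
        """Split merged ids back into (protein-local, ligand-local) id lists.

        The protein segment is ``BOS..EOS``; the ligand segment is everything
        after, with the vocabulary offset removed.
        """
        cut = self.protein_span[1] + 1  # position after EOS
        prot = self.ids[:cut]
        lig = [i - self.protein_vocab_size for i in self.ids[cut:]]
        return prot, lig


def assemble_joint(protein_tokens: TokenSequence,
                   ligand_token_lists: list[TokenSequence],
                   protein_vocab: Vocabulary,
                   ligand_vocab: Vocabulary,
                   max_length: int | None = None) -> JointSequence:
    """Assemble one protein and >=1 ligands into the joint layout."""
    if protein_tokens.modality != PROTEIN:
        raise TokenizationError("first argument must be a protein TokenSequence")
    if not ligand_token_lists:
        raise TokenizationError("at least one ligand token sequence is required")
    offset = len(protein_vocab)
    ids = [protein_vocab.bos_id] + list(protein_tokens.ids) + [protein_vocab.eos_id]
    mask = [MOD_SPECIAL] + [MOD_PROTEIN] * len(protein_tokens) + [MOD_SPECIAL]
    protein_span = (1, 1 + len(protein_tokens))
    ligand_spans: list[tuple[int, int]] = []
    for lig in ligand_token_lists:
        if lig.modality not in (SMILES, SELFIES):
            raise TokenizationError("ligand token sequences must be smiles or selfies")
        ids.append(offset + ligand_vocab.sep_id)
        mask.append(MOD_SPECIAL)
        start = len(ids)
        ids.extend(offset + i for i in lig.ids)
        mask.extend([MOD_LIGAND] * len(lig))
        ligand_spans.append((start, len(ids)))
    if max_length is not None and len(ids) > max_length:
        raise TokenizationError(
            f"joint sequence length {len(ids)} exceeds maximum {max_length} "
            f"(protein {len(protein_tokens)}, ligands {[len(l) for l in ligand_token_lists]})")
    return JointSequence(ids=ids, modality_mask=mask, protein_span=protein_span,
                         ligand_spans=ligand_spans,
                         protein_vocab_size=len(protein_vocab),
                         ligand_vocab_size=len(ligand_vocab))


# -- file plumbing -----------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA; returns (description, sequence) pairs."""
    return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_ligand_list(path: str | Path) -> list[str]:
    """One SMILES or SELFIES string per line; blank lines skipped."""
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
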
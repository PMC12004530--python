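"""File formats and run plumbing: dataset TSV, checkpoints, seed fan-out.

Dataset TSV schema (tab-separated, one header row):

    record_id  protein_seq  ligand_smiles  ligand_selfies  class_label  split
    kcat  Km  Ki  Kd  IC50  EC50  site_labels  max_train_identity

Empty numeric cells mean "label unavailable".  ``site_labels`` holds the
1-based indices of positive residues separated by semicolons; "-" means the
record is labeled but has no positive residue; an empty cell means site
labels are unavailable.  Residue indices are 1-based in all external files
and 0-based internally; conversion happens only here.

Checkpoints are a ``.npz`` weight archive plus a ``.json`` sidecar holding
the model config, vocabulary hashes, strategy, training history, and seed;
loading refuses a checkpoint whose vocabulary hashes do not match.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ConfigError, JointTransformer, ModelConfig, TASKS
from .synthetic import SyntheticConfig, SyntheticDataset, SyntheticRecord
from .tokenization import (
    PROTEIN, SELFIES, SMILES, Vocabulary, build_vocabulary,
)

COLUMNS = ["record_id", "protein_seq", "ligand_smiles", "ligand_selfies",
           "class_label", "split", *TASKS, "site_labels", "max_train_identity"]


class DatasetFormatError(ValueError):
    pass


def default_vocabularies(representation: str = SMILES) -> tuple[Vocabulary, Vocabulary]:
    """The canonical protein vocabulary and the ligand vocabulary for
    ``representation``; these are what the CLI and examples use throughout."""
    return build_vocabulary(PROTEIN), build_vocabulary(representation)


# ---------------------------------------------------------------------------
# dataset TSV


def _format_sites(record: SyntheticRecord) -> str:
    if not record.site_avail or record.site_labels is None:
        return ""
    positives = np.nonzero(np.asarray(record.site_labels))[0] + 1  # 1-based
    return ";".join(str(i) for i in positives) if positives.size else "-"


def write_dataset(dataset: SyntheticDataset | list[SyntheticRecord],
                  path: str | Path) -> None:
    records = dataset.records if isinstance(dataset, SyntheticDataset) else dataset
    rows = []
    for r in records:
        row = {"record_id": r.record_id, "protein_seq": r.protein,
               "ligand_smiles": r.smiles, "ligand_selfies": r.selfies,
               "class_label": r.class_label, "split": r.split,
               "site_labels": _format_sites(r),
               "max_train_identity": f"{r.max_train_identity:.4f}"}
        for t, task in enumerate(TASKS):
            row[task] = f"{r.y[t]:.6f}" if r.avail[t] else ""
        rows.append(row)
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, sep="\t", index=False)


def write_sidecar(dataset: SyntheticDataset, path: str | Path) -> None:
    """Config + hidden features, for oracle fits on a written dataset."""
    hidden = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
              for k, v in dataset.hidden.items()}
    Path(path).write_text(json.dumps(
        {"config": dataset.config.to_dict(), "hidden": hidden}, indent=0))


def read_dataset(path: str | Path) -> list[SyntheticRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing columns: {missing}")
    records: list[SyntheticRecord] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        protein = row["protein_seq"]
        if not protein:
            raise DatasetFormatError(f"line {line}: empty protein sequence")
        y = np.zeros(len(TASKS))
        avail = np.zeros(len(TASKS), dtype=bool)
        for t, task in enumerate(TASKS):
            cell = row[task].strip()
            if cell:
                try:
                    y[t] = float(cell)
                except ValueError as e:
                    raise DatasetFormatError(f"line {line}: bad {task} value {cell!r}") from e
                avail[t] = True
        site_cell = row["site_labels"].strip()
        site = np.zeros(len(protein), dtype=int)
        site_avail = bool(site_cell)
        if site_cell and site_cell != "-":
            for tok in site_cell.split(";"):
                try:
                    pos = int(tok)
                except ValueError as e:
                    raise DatasetFormatError(f"line {line}: bad site index {tok!r}") from e
                if not 1 <= pos <= len(protein):
                    raise DatasetFormatError(
                        f"line {line}: site index {pos} out of range 1..{len(protein)}")
                site[pos - 1] = 1
        ident_cell = row["max_train_identity"].strip()
        records.append(SyntheticRecord(
            record_id=row["record_id"], protein=protein,
            smiles=row["ligand_smiles"], selfies=row["ligand_selfies"],
            y=y, avail=avail, site_labels=site, site_avail=site_avail,
            class_label=int(row["class_label"]), split=row["split"],
            max_train_identity=float(ident_cell) if ident_cell else float("nan")))
    return records


def read_sidecar(path: str | Path) -> SyntheticDataset:
    obj = json.loads(Path(path).read_text())
    cfg_d = obj["config"]
    cfg = SyntheticConfig(**{**cfg_d,
                             "protein_len_range": tuple(cfg_d["protein_len_range"]),
                             "chain_len_range": tuple(cfg_d["chain_len_range"]),
                             "fractions": tuple(cfg_d["fractions"])})
    hidden = {k: (np.array(v) if isinstance(v, list) and k != "motifs" else v)
              for k, v in obj["hidden"].items()}
    return SyntheticDataset(records=[], config=cfg, hidden=hidden)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: JointTransformer, path_prefix: str | Path,
                    protein_vocab: Vocabulary, ligand_vocab: Vocabulary,
                    strategy: dict | None = None, history: dict | None = None,
                    seed: int | None = None) -> None:
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savez(f"{prefix}.npz", **model.state_dict())
    meta = {"config": model.cfg.to_dict(),
            "vocab_hashes": {"protein": protein_vocab.content_hash(),
                             "ligand": ligand_vocab.content_hash()},
            "ligand_modality": ligand_vocab.modality,
            "strategy": strategy, "history": history, "seed": seed}
    Path(f"{prefix}.json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path_prefix: str | Path, protein_vocab: Vocabulary,
                    ligand_vocab: Vocabulary) -> JointTransformer:
    prefix = Path(path_prefix)
    meta = json.loads(Path(f"{prefix}.json").read_text())
    for name, vocab in (("protein", protein_vocab), ("ligand", ligand_vocab)):
        expected = meta["vocab_hashes"][name]
        got = vocab.content_hash()
        if expected != got:
            raise ConfigError(
                f"{name} vocabulary hash mismatch: checkpoint expects {expected}, got {got}")
    cfg = ModelConfig.from_dict(meta["config"])
    model = JointTransformer(cfg)
    with np.load(f"{prefix}.npz") as archive:
        model.load_state_dict({k: archive[k] for k in archive.files})
    return model


# ---------------------------------------------------------------------------
# seed fan-out


SEED_STREAMS = ("data", "init", "bagging", "corruption", "train")


def derive_seed(master_seed: int, stream: str) -> int:
    """One master seed fans out to named sub-seeds so each stochastic
    component is independently reproducible."""
    if stream not in SEED_STREAMS:
        raise ValueError(f"unknown seed stream {stream!r}; use one of {SEED_STREAMS}")
    ss = np.random.SeedSequence(master_seed, spawn_key=(SEED_STREAMS.index(stream),))
    return int(ss.generate_state(1)[0] % (2 ** 31))
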
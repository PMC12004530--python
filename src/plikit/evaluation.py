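"""Metrics and study harnesses.

Regression tasks report R^2, RMSD, and P_1mag (the percentage of predictions
within one order of magnitude, i.e. one log10 unit, of the truth); the site
task reports ROC-AUC, PR-AUC, and precision/recall at threshold 0.5.  The
harnesses reproduce the study designs used to probe multitask transfer
(task-group ablation), class-level generalization (leave-one-class-out), and
out-of-distribution robustness (sequence-identity-stratified evaluation),
plus mutual-kNN cosine clustering of ligand encoder embeddings.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import average_precision_score, r2_score, roc_auc_score

from . import autodiff as ad
from .ensemble import aggregate_regression, aggregate_votes
from .finetune import StrategyConfig, prepare_records, train
from .model import JointTransformer, ModelConfig, N_TASKS, TASKS, collate
from .tokenization import SMILES, Vocabulary, tokenize_ligand

IDENTITY_BINS = (40.0, 60.0, 80.0, 99.0)

TASK_GROUPS = {
    "kinetics": ("kcat", "Km"),
    "binding": ("Ki", "Kd", "IC50", "EC50"),
    "site": (),
}


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# metrics


def regression_metrics(predictions: np.ndarray, truths: np.ndarray) -> dict:
    """R^2, RMSD, P_1mag for one task on aligned log10-scale arrays."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise EvaluationError("predictions and truths must be aligned 1-D arrays")
    if p.size == 0:
        return {"r2": None, "rmsd": None, "p1mag": None, "n": 0}
    rmsd = float(np.sqrt(np.mean((p - t) ** 2)))
    p1mag = float(100.0 * np.mean(np.abs(p - t) <= 1.0))
    if np.all(t == t[0]):
        warnings.warn("constant truths: R^2 undefined, reported as None")
        r2 = None
    else:
        r2 = float(r2_score(t, p))
    return {"r2": r2, "rmsd": rmsd, "p1mag": p1mag, "n": int(p.size)}


def classification_metrics(probabilities: np.ndarray, labels: np.ndarray,
                           threshold: float = 0.5) -> dict:
    """ROC-AUC (midrank ties), PR-AUC (step-wise), precision/recall at 0.5."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise EvaluationError("probabilities and labels must be aligned")
    if not np.any(y == 1):
        raise EvaluationError("no positive labels present")
    if not np.any(y == 0):
        raise EvaluationError("no negative labels present")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {
        "roc_auc": float(roc_auc_score(y, p)),
        "pr_auc": float(average_precision_score(y, p)),
        "precision": float(precision),
        "recall": float(recall),
        "n": int(y.size),
        "prevalence": float(np.mean(y)),
    }


# ---------------------------------------------------------------------------
# prediction plumbing


def predict_records(models: list[JointTransformer], prepared,
                    batch_size: int = 64) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Predict (mu, sd, site probabilities) for prepared records.

    With one model, sd is the predictive sigma; with several, members are
    aggregated by mixture moments and majority voting.
    """
    per_model = []
    for model in models:
        mus, sigmas, sites = [], [], []
        with ad.no_grad():
            for lo in range(0, len(prepared), batch_size):
                chunk = [p.joint for p in prepared[lo:lo + batch_size]]
                batch = collate(chunk)
                emb = model.encode(batch)
                mu, sigma = model.regress(emb, batch)
                mus.append(mu.data.copy())
                sigmas.append(sigma.data.copy())
                sites.extend(model.classify_sites(emb, batch))
        per_model.append((np.concatenate(mus), np.concatenate(sigmas), sites))
    if len(models) == 1:
        mu, sigma, sites = per_model[0]
        return mu, sigma, sites
    n = per_model[0][0].shape[0]
    mu_out = np.zeros((n, N_TASKS))
    sd_out = np.zeros((n, N_TASKS))
    site_out: list[np.ndarray] = []
    from .model import GaussianPrediction
    for i in range(n):
        members = [GaussianPrediction(pm[0][i], pm[1][i]) for pm in per_model]
        agg = aggregate_regression(members)
        mu_out[i] = agg.mu
        sd_out[i] = agg.sd
        site_out.append(aggregate_votes([pm[2][i] for pm in per_model]).fractions)
    return mu_out, sd_out, site_out


def evaluate_split(models: list[JointTransformer], prepared) -> dict:
    """MetricsReport over a prepared record list: per task + site metrics."""
    mu, _, sites = predict_records(models, prepared)
    report: dict = {}
    for t, task in enumerate(TASKS):
        mask = np.array([p.avail[t] for p in prepared])
        if mask.sum() == 0:
            report[task] = {"r2": None, "rmsd": None, "p1mag": None, "n": 0}
            continue
        truths = np.array([p.y[t] for p in prepared])[mask]
        report[task] = regression_metrics(mu[mask, t], truths)
    probs, labels = [], []
    for p, s in zip(prepared, sites):
        if p.site_avail and p.site_labels is not None:
            probs.append(np.asarray(s, dtype=float))
            labels.append(p.site_labels)
    if probs:
        flat_p = np.concatenate(probs)
        flat_y = np.concatenate(labels)
        try:
            report["site"] = classification_metrics(flat_p, flat_y)
        except EvaluationError:
            report["site"] = None
    return report


# ---------------------------------------------------------------------------
# harnesses


def _mask_task_group(records, group: str):
    """Copies of records with the group's labels marked unavailable."""
    if group not in TASK_GROUPS:
        raise EvaluationError(f"unknown task group {group!r}; choose from {sorted(TASK_GROUPS)}")
    import copy
    masked = []
    for r in records:
        r2 = copy.copy(r)
        r2.avail = np.asarray(r.avail, dtype=bool).copy()
        if group == "site":
            r2.site_avail = False
        else:
            for task in TASK_GROUPS[group]:
                r2.avail[TASKS.index(task)] = False
        masked.append(r2)
    return masked


def ablation_harness(dataset, task_groups_to_exclude: list[str],
                     model_cfg: ModelConfig, strategy: StrategyConfig,
                     protein_vocab: Vocabulary, ligand_vocab: Vocabulary) -> dict:
    """Task-group ablation: retrain a base-strategy model per exclusion
    setting and report RMSD (regression) / precision (site) on the test split.

    ``task_groups_to_exclude`` entries are group names or "none"; excluding
    every group at once is rejected.
    """
    if set(task_groups_to_exclude) >= set(TASK_GROUPS):
        raise EvaluationError("cannot exclude all task groups")
    report: dict = {}
    for setting in task_groups_to_exclude:
        train_recs = dataset.subset("train")
        val_recs = dataset.subset("val")
        if setting != "none":
            train_recs = _mask_task_group(train_recs, setting)
            val_recs = _mask_task_group(val_recs, setting)
        model = JointTransformer(model_cfg)
        result = train(model, train_recs, val_recs, strategy, protein_vocab, ligand_vocab)
        test_prep = prepare_records(dataset.subset("test"), protein_vocab, ligand_vocab,
                                    strategy.representation, model_cfg.max_joint_len)
        full = evaluate_split(result.models, test_prep)
        row: dict = {}
        excluded_tasks = set(TASK_GROUPS.get(setting, ()))
        for task in TASKS:
            if setting != "none" and task in excluded_tasks:
                continue
            row[f"{task}_rmsd"] = None if full[task]["n"] == 0 else full[task]["rmsd"]
        if setting != "site" and full.get("site"):
            row["site_precision"] = full["site"]["precision"]
        report[setting] = row
    return report


def class_exclusion_harness(dataset, class_label: int, model_cfg: ModelConfig,
                            strategy: StrategyConfig, protein_vocab: Vocabulary,
                            ligand_vocab: Vocabulary, min_test_records: int = 1) -> dict:
    """Leave-one-class-out: train without the class, evaluate only on it."""
    if class_label not in dataset.classes():
        raise EvaluationError(f"class {class_label} absent from dataset")
    train_recs = [r for r in dataset.subset("train") if r.class_label != class_label]
    val_recs = [r for r in dataset.subset("val") if r.class_label != class_label]
    test_recs = [r for r in dataset.subset("test") if r.class_label == class_label]
    if len(test_recs) < min_test_records:
        raise EvaluationError(
            f"class {class_label} has {len(test_recs)} test records (< {min_test_records})")
    model = JointTransformer(model_cfg)
    result = train(model, train_recs, val_recs, strategy, protein_vocab, ligand_vocab)
    test_prep = prepare_records(test_recs, protein_vocab, ligand_vocab,
                                strategy.representation, model_cfg.max_joint_len)
    return {"excluded_class": class_label,
            "n_test": len(test_recs),
            "metrics": evaluate_split(result.models, test_prep)}


def identity_stratified_eval(predictions: np.ndarray, truths: np.ndarray,
                             avail: np.ndarray, identities: np.ndarray) -> dict:
    """Cumulative identity bins (<=40, <=60, <=80, <=99 percent) per task.

    ``predictions``/``truths``: (n, N_TASKS); ``avail``: (n, N_TASKS) bool;
    ``identities``: (n,) max identity to any training protein.
    """
    identities = np.asarray(identities, dtype=float)
    if np.any(np.isnan(identities)):
        raise EvaluationError("missing identity annotation")
    report: dict = {}
    for bin_edge in IDENTITY_BINS:
        in_bin = identities <= bin_edge
        per_task = {}
        for t, task in enumerate(TASKS):
            mask = in_bin & avail[:, t]
            per_task[task] = regression_metrics(predictions[mask, t], truths[mask, t])
        report[f"<={bin_edge:.0f}"] = {"n_records": int(in_bin.sum()), "tasks": per_task}
    return report


# ---------------------------------------------------------------------------
# ligand embedding clustering


def ligand_embeddings(model: JointTransformer, ligand_strings: list[str],
                      ligand_vocab: Vocabulary, representation: str = SMILES
                      ) -> np.ndarray:
    """Mean-pooled ligand-encoder outputs (ligand tokens only), (n, E)."""
    out = np.zeros((len(ligand_strings), model.cfg.embed_dim))
    with ad.no_grad():
        for i, s in enumerate(ligand_strings):
            ts = tokenize_ligand(s, representation, ligand_vocab)
            ids = np.array([[ligand_vocab.sep_id] + ts.ids])
            valid = np.ones_like(ids, dtype=bool)
            h = model.ligand_encoder(ids, valid).data[0]
            out[i] = h[1:].mean(axis=0)     # exclude the SEP position
    return out


def cluster_ligands(embeddings: np.ndarray, k: int = 5) -> np.ndarray:
    """Symmetrized k-nearest-neighbor graph under cosine similarity; clusters
    are its connected components (singletons allowed).  An edge exists when
    either endpoint lists the other among its k most cosine-similar ligands
    (ties broken by index, so the assignment is deterministic)."""
    X = np.asarray(embeddings, dtype=float)
    if X.shape[0] < k + 1:
        raise EvaluationError(f"need at least k+1={k + 1} ligands, got {X.shape[0]}")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise EvaluationError("zero-norm embedding")
    Xn = X / norms[:, None]
    sim = Xn @ Xn.T
    np.fill_diagonal(sim, -np.inf)
    n = X.shape[0]
    knn = np.argsort(-sim, axis=1, kind="stable")[:, :k]
    is_neighbor = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    is_neighbor[rows, knn.ravel()] = True
    graph = csr_matrix(is_neighbor | is_neighbor.T)
    _, labels = connected_components(graph, directed=False)
    return labels


# ---------------------------------------------------------------------------
# report writers


def write_report(report: dict, path_prefix: str | Path) -> None:
    """JSON plus a flat TSV rendering of a nested metrics report."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    Path(f"{prefix}.json").write_text(json.dumps(report, indent=2, default=_json_default))
    rows = []

    def walk(node, keys):
        if isinstance(node, dict):
            for k, v in node.items():
                walk(v, keys + [str(k)])
        else:
            rows.append({"key": ".".join(keys), "value": node})

    walk(report, [])
    pd.DataFrame(rows).to_csv(f"{prefix}.tsv", sep="\t", index=False)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def long_format_table(prepared, predictions: np.ndarray,
                      strata: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Violin-plot-ready long format: one row per (record, task) with truth,
    prediction, and any per-record stratum columns (identity bin, cluster...)."""
    rows = []
    for i, p in enumerate(prepared):
        for t, task in enumerate(TASKS):
            if not p.avail[t]:
                continue
            row = {"record_id": p.record_id, "task": task,
                   "truth": float(p.y[t]), "prediction": float(predictions[i, t])}
            if strata:
                for name, values in strata.items():
                    row[name] = values[i]
            rows.append(row)
    return pd.DataFrame(rows)
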
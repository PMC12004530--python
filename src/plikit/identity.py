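"""Pairwise sequence identity for train/test stratification.

Convention: identity between two sequences is computed from the best global
(Needleman-Wunsch) alignment under unit mismatch and unit gap penalties, i.e.
from the Levenshtein distance d:

    identity(a, b) = 100 * (1 - d / max(len(a), len(b)))

The distance comes from edlib's NW mode.  Identical sequences score 100;
"AAAA" vs "AAAT" scores 75.
"""

from __future__ import annotations

import edlib
import numpy as np

__all__ = ["percent_identity", "max_identity_to_train"]


def percent_identity(a: str, b: str) -> float:
    if not a or not b:
        raise ValueError("cannot compute identity of an empty sequence")
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 100.0 * (1.0 - d / max(len(a), len(b)))


def max_identity_to_train(sequence: str, train_sequences: list[str]) -> float:
    """Maximum percent identity of ``sequence`` to any training protein."""
    if not train_sequences:
        raise ValueError("empty training set")
    return float(max(percent_identity(sequence, t) for t in train_sequences))


def annotate_max_identity(sequences: list[str], train_sequences: list[str]) -> np.ndarray:
    return np.array([max_identity_to_train(s, train_sequences) for s in sequences])
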
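"""MEM-weighted read classification over a document-array profile index.

Each read is matched against the pangenome; the maximal exact matches (MEMs)
of length at least ``min_len`` (default 15) vote for documents, each vote
weighted by the MEM's length.  In ``full_listing`` mode a MEM's weight goes
to *every* document containing it (read off its profile); in the
``one_doc_baseline`` mode it goes only to the single document reported by a
sampled document array, mimicking classifiers that keep one document number
per BWT run boundary.  The read is assigned to the document with the largest
total weight; a tie (including the no-surviving-MEM case) is reported as
unclassified rather than broken arbitrarily.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .query_engine import MEM, find_mems, list_documents
from .suffix_structures import DocumentError

UNCLASSIFIED = "unclassified"

MODES = ("full_listing", "one_doc_baseline")

DEFAULT_MIN_MEM_LENGTH = 15


@dataclass
class ReadClassification:
    """Per-read result: document weights and the argmax assignment.

    ``assigned`` is a 1-based document index, or ``None`` for unclassified
    (no MEM survived the length filter, or the top weight was tied).
    """

    read_id: str
    weights: np.ndarray
    assigned: int | None
    mode: str


def classify_read(
    mems: list[MEM],
    d: int,
    mode: str = "full_listing",
    min_len: int = DEFAULT_MIN_MEM_LENGTH,
) -> ReadClassification:
    """Weight documents by MEM length and assign the read to the argmax."""
    if d < 1:
        raise DocumentError("need at least one document")
    if mode not in MODES:
        raise DocumentError(f"unknown mode {mode!r}; expected one of {MODES}")
    weights = np.zeros(d, dtype=np.int64)
    read_id = mems[0].read_id if mems else ""
    for mem in mems:
        if mem.length < min_len:
            continue
        if mode == "full_listing":
            for j in list_documents(mem.profile, mem.length):
                weights[j - 1] += mem.length
        else:
            weights[mem.one_doc - 1] += mem.length
    assigned: int | None = None
    if weights.any():
        best = int(weights.max())
        top = np.flatnonzero(weights == best)
        if len(top) == 1:
            assigned = int(top[0]) + 1
    return ReadClassification(
        read_id=read_id, weights=weights, assigned=assigned, mode=mode
    )


@dataclass
class ClassificationSummary:
    """Batch result: per-read assignments and aggregate accuracy metrics."""

    results: list[ReadClassification]
    confusion: pd.DataFrame        # rows: true label, cols: assigned label
    per_class_recall: dict[str, float]
    accuracy: float
    error_rate: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "error_rate": self.error_rate,
            "per_class_recall": self.per_class_recall,
            "confusion": {
                t: {a: int(v) for a, v in row.items()}
                for t, row in self.confusion.to_dict(orient="index").items()
            },
        }


def classify_batch(
    reads,
    structures,
    index,
    mode: str = "full_listing",
    min_len: int = DEFAULT_MIN_MEM_LENGTH,
) -> ClassificationSummary:
    """Classify labelled reads and tabulate a confusion matrix.

    ``reads`` yields ``(read_id, sequence, true_label)`` triples (or objects
    with those attributes); true labels must be index labels.  A read shorter
    than ``min_len`` or with no surviving MEM counts as unclassified, which
    is an error for accuracy purposes.
    """
    labels = list(structures.text.labels)
    label_set = set(labels)
    results: list[ReadClassification] = []
    pairs: list[tuple[str, str]] = []  # (true, assigned) label pairs
    for read in reads:
        if isinstance(read, tuple):
            read_id, seq, true_label = read
        else:
            read_id, seq, true_label = read.read_id, read.sequence, read.true_class
        if true_label not in label_set:
            raise DocumentError(f"read {read_id!r} has unknown label {true_label!r}")
        mems = find_mems(structures, index, seq, read_id=read_id, min_len=min_len)
        res = classify_read(mems, d=len(labels), mode=mode, min_len=min_len)
        res.read_id = read_id
        results.append(res)
        assigned = UNCLASSIFIED if res.assigned is None else labels[res.assigned - 1]
        pairs.append((true_label, assigned))
    cols = labels + [UNCLASSIFIED]
    confusion = pd.DataFrame(0, index=labels, columns=cols, dtype=np.int64)
    for true_label, assigned in pairs:
        confusion.loc[true_label, assigned] += 1
    totals = confusion.sum(axis=1)
    recall = {
        lab: (float(confusion.loc[lab, lab] / totals[lab]) if totals[lab] else 0.0)
        for lab in labels
    }
    n_reads = int(totals.sum())
    n_correct = int(sum(confusion.loc[lab, lab] for lab in labels))
    accuracy = n_correct / n_reads if n_reads else 0.0
    return ClassificationSummary(
        results=results,
        confusion=confusion,
        per_class_recall=recall,
        accuracy=accuracy,
        error_rate=1.0 - accuracy,
    )
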
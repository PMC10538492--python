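"""Building, serializing and loading a queryable pangenome index.

:class:`PangenomeIndex` bundles the document collection, the suffix
structures over the concatenation, and the run-boundary profile samples into
one handle exposing the common workflows (listing queries, MEM extraction,
read classification).

Serialization uses a versioned JSON container holding the documents, labels,
runs, SA samples, profile samples and the width cap.  The suffix structures
themselves are rebuilt deterministically from the documents on load, so a
save/load round trip is bit-identical.  FASTA input follows the
one-document-per-record convention, optionally regrouped into classes via a
two-column TSV (record-name prefix -> class label).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .classifier import ClassificationSummary, classify_batch
from .doc_profiles import (
    ProfileIndex,
    profiles_naive,
    profiles_streaming,
    profiles_two_pass,
    sample_profiles,
    truncate,
)
from .query_engine import MEM, find_mems, list_documents, query_with_profiles
from .suffix_structures import (
    DocumentCollection,
    DocumentError,
    SuffixStructures,
    find_runs,
)

FORMAT_NAME = "daprofile-index"
FORMAT_VERSION = 1

BUILD_METHODS = ("streaming", "two_pass", "naive")


def content_hash(collection: DocumentCollection) -> str:
    """Seed-free hash of the indexed content (documents + labels)."""
    h = hashlib.sha256()
    for label, doc in zip(collection.labels, collection.docs):
        h.update(label.encode())
        h.update(b"\x00")
        h.update(doc.encode())
        h.update(b"\x00")
    return h.hexdigest()


def build_profile_index(
    structures: SuffixStructures,
    method: str = "streaming",
    cap: int | None = None,
    selfcheck: bool = False,
) -> ProfileIndex:
    """Construct the run-boundary profile samples by the chosen method.

    ``streaming`` is the single-scan construction; ``two_pass`` and ``naive``
    build the full matrix first and sample it (``two_pass`` is the fast
    vectorised route for larger inputs).  With ``selfcheck=True`` the result
    is verified entry-for-entry against the definitional construction.
    """
    if method not in BUILD_METHODS:
        raise DocumentError(f"unknown build method {method!r}")
    runs = find_runs(structures.bwt)
    if method == "streaming":
        index = profiles_streaming(structures, runs, selfcheck=selfcheck)
    elif method == "two_pass":
        index = sample_profiles(profiles_two_pass(structures), runs, structures)
    else:
        index = sample_profiles(profiles_naive(structures), runs, structures)
    if selfcheck:
        ref = sample_profiles(profiles_naive(structures), runs, structures)
        if not (
            np.array_equal(ref.prof_start, index.prof_start)
            and np.array_equal(ref.prof_end, index.prof_end)
        ):
            raise AssertionError("profile construction failed the self-check")
    if cap is not None:
        index = truncate(index, cap)
    return index


@dataclass
class PangenomeIndex:
    """A document collection plus everything needed to query it."""

    collection: DocumentCollection
    structures: SuffixStructures
    profiles: ProfileIndex

    @classmethod
    def build(
        cls,
        collection: DocumentCollection,
        method: str = "streaming",
        cap: int | None = None,
        selfcheck: bool = False,
    ) -> "PangenomeIndex":
        structures = SuffixStructures.from_collection(collection)
        profiles = build_profile_index(
            structures, method=method, cap=cap, selfcheck=selfcheck
        )
        return cls(collection=collection, structures=structures, profiles=profiles)

    # -- queries ---------------------------------------------------------

    @property
    def labels(self) -> tuple[str, ...]:
        return self.collection.labels

    def list_pattern(self, pattern: str) -> set[str]:
        """Labels of the documents containing ``pattern`` (empty set if absent)."""
        state = query_with_profiles(self.structures, self.profiles, pattern)
        if state is None:
            return set()
        docs = list_documents(state.profile, state.matched_length)
        return {self.labels[j - 1] for j in docs}

    def find_mems(self, read: str, read_id: str = "read", min_len: int = 1) -> list[MEM]:
        return find_mems(self.structures, self.profiles, read, read_id, min_len)

    def classify(self, reads, mode: str = "full_listing", min_len: int = 15
                 ) -> ClassificationSummary:
        return classify_batch(reads, self.structures, self.profiles,
                              mode=mode, min_len=min_len)

    # -- persistence -----------------------------------------------------

    def to_payload(self) -> dict:
        p = self.profiles
        return {
            "format": FORMAT_NAME,
            "version": FORMAT_VERSION,
            "alphabet": self.collection.alphabet,
            "labels": list(self.labels),
            "docs": list(self.collection.docs),
            "content_hash": content_hash(self.collection),
            "width_cap": p.width_cap,
            "n": p.n,
            "d": p.d,
            "runs": {
                "starts": p.runs.starts.tolist(),
                "ends": p.runs.ends.tolist(),
                "chars": p.runs.chars,
            },
            "sa_start": p.sa_start.tolist(),
            "sa_end": p.sa_end.tolist(),
            "prof_start": p.prof_start.tolist(),
            "prof_end": p.prof_end.tolist(),
        }

    def save(self, path: str | Path) -> None:
        payload = self.to_payload()
        Path(path).write_text(
            json.dumps(payload, sort_keys=True, separators=(",", ":")) + "\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "PangenomeIndex":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != FORMAT_NAME:
            raise DocumentError(f"{path}: not a {FORMAT_NAME} file")
        if payload.get("version") != FORMAT_VERSION:
            raise DocumentError(
                f"{path}: index version {payload.get('version')!r} not "
                f"supported (expected {FORMAT_VERSION})"
            )
        collection = DocumentCollection(
            tuple(payload["docs"]),
            tuple(payload["labels"]),
            alphabet=payload["alphabet"],
        )
        if content_hash(collection) != payload["content_hash"]:
            raise DocumentError(f"{path}: content hash mismatch")
        structures = SuffixStructures.from_collection(collection)
        runs = find_runs(structures.bwt)
        if (
            runs.starts.tolist() != payload["runs"]["starts"]
            or runs.chars != payload["runs"]["chars"]
        ):
            raise DocumentError(f"{path}: stored runs disagree with the documents")
        profiles = ProfileIndex(
            runs=runs,
            sa_start=np.asarray(payload["sa_start"], dtype=np.int64),
            sa_end=np.asarray(payload["sa_end"], dtype=np.int64),
            prof_start=np.asarray(payload["prof_start"], dtype=np.int64),
            prof_end=np.asarray(payload["prof_end"], dtype=np.int64),
            d=int(payload["d"]),
            n=int(payload["n"]),
            width_cap=payload["width_cap"],
        )
        return cls(collection=collection, structures=structures, profiles=profiles)


def read_fasta_collection(
    paths: list[str | Path],
    groups_tsv: str | Path | None = None,
    alphabet: str = "ACGTN",
) -> DocumentCollection:
    """Read documents from FASTA files.

    Without a grouping table every record becomes one document labelled by
    its record id (a single-record file falls back to the file stem if ids
    collide).  With ``groups_tsv`` (two tab-separated columns: record-name
    prefix, class label) records are assigned to the first matching prefix
    and all records of a class are joined — with a single ``N`` — into one
    document, so one class is one document.
    """
    records: list[tuple[str, str]] = []
    for path in paths:
        path = Path(path)
        parsed = list(SeqIO.parse(str(path), "fasta"))
        if not parsed:
            raise DocumentError(f"{path}: no FASTA records")
        for rec in parsed:
            seq = str(rec.seq).upper()
            records.append((rec.id, seq))
    if groups_tsv is None:
        labels = [rid for rid, _ in records]
        if len(set(labels)) != len(labels):
            raise DocumentError("duplicate record ids; use a grouping table")
        return DocumentCollection(
            tuple(seq for _, seq in records), tuple(labels), alphabet=alphabet
        )
    prefixes: list[tuple[str, str]] = []
    for line in Path(groups_tsv).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        try:
            prefix, label = line.split("\t")
        except ValueError:
            raise DocumentError(f"bad grouping line: {line!r}") from None
        prefixes.append((prefix, label))
    grouped: dict[str, list[str]] = {}
    order: list[str] = []
    for rid, seq in records:
        for prefix, label in prefixes:
            if rid.startswith(prefix):
                if label not in grouped:
                    grouped[label] = []
                    order.append(label)
                grouped[label].append(seq)
                break
        else:
            raise DocumentError(f"record {rid!r} matches no grouping prefix")
    docs = tuple("N".join(grouped[label]) for label in order)
    return DocumentCollection(docs, tuple(order), alphabet=alphabet)


def read_fastq_reads(path: str | Path) -> list[tuple[str, str, str | None]]:
    """Read ``(read_id, sequence, true_class_or_None)`` triples from FASTQ.

    The true class is taken from a ``class=...`` token in the description,
    when present (as written by the simulator).
    """
    out: list[tuple[str, str, str | None]] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        true_class = None
        for token in rec.description.split():
            if token.startswith("class="):
                true_class = token[len("class="):]
        out.append((rec.id, str(rec.seq).upper(), true_class))
    return out
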
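"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own machinery: suffixes are
compared as python strings in which each document's separator is a distinct
control character (so separators sort below the alphabet and by position),
occurrences come from substring scans, and profiles from explicit pairwise
lcp loops.
"""

from __future__ import annotations

import random

import numpy as np
import pytest

from daprofile import DocumentCollection, PangenomeIndex


def sentinel_text(docs: tuple[str, ...]) -> str:
    """Concatenation with distinct low-codepoint separators (oracle view)."""
    return "".join(doc + chr(1 + j) for j, doc in enumerate(docs))


def brute_suffix_order(docs: tuple[str, ...]) -> list[int]:
    """0-based text positions in lexicographic suffix order."""
    text = sentinel_text(docs)
    return sorted(range(len(text)), key=lambda p: text[p:])


def brute_lcp_pair(text: str, a: int, b: int) -> int:
    h = 0
    n = len(text)
    while a + h < n and b + h < n and text[a + h] == text[b + h]:
        h += 1
    return h


def brute_occurrences(docs: tuple[str, ...], pattern: str) -> list[int]:
    """Sorted 1-based positions of the pattern in the concatenation."""
    text = sentinel_text(docs)
    out = []
    start = 0
    while True:
        k = text.find(pattern, start)
        if k < 0:
            return out
        out.append(k + 1)
        start = k + 1


def brute_membership(docs: tuple[str, ...], pattern: str) -> set[int]:
    """1-based documents containing the pattern."""
    return {j + 1 for j, doc in enumerate(docs) if pattern in doc}


def brute_profile_matrix(docs: tuple[str, ...]) -> np.ndarray:
    """Profile matrix from explicit pairwise lcp loops over the oracle text."""
    text = sentinel_text(docs)
    order = brute_suffix_order(docs)
    doc_of = np.zeros(len(text), dtype=int)
    pos = 0
    for j, doc in enumerate(docs):
        doc_of[pos : pos + len(doc) + 1] = j
        pos += len(doc) + 1
    n, d = len(text), len(docs)
    out = np.zeros((n, d), dtype=np.int64)
    for i in range(n):
        for k in range(n):
            h = brute_lcp_pair(text, order[i], order[k])
            j = doc_of[order[k]]
            if h > out[i, j]:
                out[i, j] = h
    return out


def brute_matching_statistics(docs: tuple[str, ...], read: str) -> list[int]:
    text = sentinel_text(docs)
    out = []
    for p in range(len(read)):
        L = 0
        while p + L < len(read) and read[p : p + L + 1] in text:
            L += 1
        out.append(L)
    return out


def brute_mems(docs: tuple[str, ...], read: str, min_len: int) -> list[tuple[int, int]]:
    """(1-based offset, length) of maximal exact matches, length >= min_len."""
    ms = brute_matching_statistics(docs, read)
    out = []
    for p in range(len(read)):
        if ms[p] >= min_len and (p == 0 or ms[p - 1] <= ms[p]):
            out.append((p + 1, ms[p]))
    return out


def random_docs(
    rng: random.Random,
    d_range: tuple[int, int] = (2, 6),
    total_max: int = 190,
    sigmas: tuple[int, ...] = (2, 4),
) -> tuple[tuple[str, ...], str]:
    """A random collection (docs, alphabet) with n <= total_max + d."""
    d = rng.randint(*d_range)
    alphabet = "ACGT"[: rng.choice(sigmas)]
    budget = rng.randint(max(d, 12), total_max)
    lengths = []
    remaining = budget
    for k in range(d):
        left = d - k - 1
        hi = max(1, remaining - left)
        length = 1 if left >= remaining else rng.randint(1, hi)
        lengths.append(length)
        remaining -= length
    docs = tuple(
        "".join(rng.choice(alphabet) for _ in range(length)) for length in lengths
    )
    return docs, alphabet


def make_collection(docs: tuple[str, ...], alphabet: str = "ACGTN") -> DocumentCollection:
    return DocumentCollection(
        docs, tuple(f"doc{j + 1}" for j in range(len(docs))), alphabet=alphabet
    )


@pytest.fixture(scope="session")
def small_index() -> PangenomeIndex:
    """A fixed three-document index reused by read-level tests."""
    rng = random.Random(20240917)
    docs = tuple(
        "".join(rng.choice("ACGT") for _ in range(150)) for _ in range(3)
    )
    return PangenomeIndex.build(make_collection(docs), method="streaming")
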
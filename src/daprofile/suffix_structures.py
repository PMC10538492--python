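"""Classical suffix structures over a concatenated document collection.

A *document collection* is an ordered set of ``d`` strings (documents) over a
DNA-like alphabet.  One document is one classification unit (a strain, or a
group of related genomes joined into a single string).  The documents are
concatenated with one separator appended to each; all separators compare
lexicographically smaller than every alphabet symbol, and separators at
distinct positions compare by position (earlier < later).  This makes every
suffix of the concatenation distinct, so the suffix array is well defined, and
it prevents a longest-common-prefix from extending across a document boundary.

All public coordinates are 1-based: suffix-array *values* are 1-based text
positions, document indices run ``1..d``, and BWT intervals ``(s, e)`` are
1-based inclusive.  Arrays are stored as numpy vectors where python index
``i`` holds the entry of rank ``i + 1``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

SEPARATOR = "#"
DNA_ALPHABET = "ACGTN"


class DocumentError(ValueError):
    """Raised for invalid collections or inconsistent structure inputs."""


@dataclass(frozen=True)
class DocumentCollection:
    """An ordered collection of ``d`` labelled documents.

    Parameters
    ----------
    docs : tuple of str
        The document strings.  Every document must be nonempty and contain
        only characters from ``alphabet`` (the separator is reserved).
    labels : tuple of str
        Human-readable class names, one per document, unique.
    alphabet : str
        Ordered alphabet; defaults to ``ACGTN`` with ``N`` treated as an
        ordinary symbol.
    """

    docs: tuple[str, ...]
    labels: tuple[str, ...]
    alphabet: str = DNA_ALPHABET

    def __post_init__(self) -> None:
        if len(self.docs) < 1:
            raise DocumentError("collection must contain at least one document")
        if len(self.labels) != len(self.docs):
            raise DocumentError("need exactly one label per document")
        if len(set(self.labels)) != len(self.labels):
            raise DocumentError("document labels must be unique")
        if SEPARATOR in self.alphabet:
            raise DocumentError("alphabet may not contain the separator")
        allowed = set(self.alphabet)
        for lab, doc in zip(self.labels, self.docs):
            if not doc:
                raise DocumentError(f"document {lab!r} is empty")
            extra = set(doc) - allowed
            if extra:
                raise DocumentError(
                    f"document {lab!r} contains characters outside the "
                    f"alphabet: {sorted(extra)!r}"
                )

    @property
    def d(self) -> int:
        return len(self.docs)


@dataclass(frozen=True)
class ConcatenatedText:
    """The documents joined with one separator each, plus the boundary map.

    ``text`` shows every separator as ``#``; internally each separator is a
    distinct symbol (the ``j``-th separator sorts as the ``j``-th smallest
    character overall), encoded in ``enc``.
    """

    text: str
    enc: np.ndarray          # int32 codes; separator of doc j -> j, char -> d + rank + 1
    doc_start: np.ndarray    # 1-based start position of each document
    d: int
    alphabet: str
    labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.text)

    def doc_of(self, p: int) -> int:
        """Document index (1-based) containing text position ``p`` (1-based).

        The separator appended to document ``j`` belongs to document ``j``,
        so ``doc_of`` is a total, non-decreasing step function.
        """
        if not 1 <= p <= self.n:
            raise IndexError(f"position {p} outside 1..{self.n}")
        return int(np.searchsorted(self.doc_start, p, side="right"))

    def char_code(self, c: str) -> int | None:
        """Encoded value of an alphabet character, or None if out of alphabet."""
        k = self.alphabet.find(c)
        if k < 0:
            return None
        return self.d + 1 + k

    def suffix_length(self, p: int) -> int:
        """Length of the suffix starting at 1-based position ``p``."""
        return self.n - p + 1


def concatenate(collection: DocumentCollection) -> ConcatenatedText:
    """Join the documents, appending one separator per document.

    The separators are assigned strictly increasing codes ``1..d`` smaller
    than every alphabet code, so every suffix of the result is distinct.
    """
    d = collection.d
    parts: list[str] = []
    codes: list[np.ndarray] = []
    doc_start = np.empty(d, dtype=np.int64)
    char_code = {c: d + 1 + k for k, c in enumerate(collection.alphabet)}
    pos = 1
    for j, doc in enumerate(collection.docs, start=1):
        doc_start[j - 1] = pos
        parts.append(doc)
        parts.append(SEPARATOR)
        enc = np.fromiter((char_code[c] for c in doc), dtype=np.int32, count=len(doc))
        codes.append(enc)
        codes.append(np.array([j], dtype=np.int32))
        pos += len(doc) + 1
    return ConcatenatedText(
        text="".join(parts),
        enc=np.concatenate(codes),
        doc_start=doc_start,
        d=d,
        alphabet=collection.alphabet,
        labels=collection.labels,
    )


def build_suffix_array(text: ConcatenatedText) -> np.ndarray:
    """Suffix array (1-based values) by prefix doubling on the encoded text.

    All suffixes are distinct thanks to the positional separator codes, so the
    doubling loop terminates with a full permutation of ``1..n``.
    """
    t = text.enc
    n = len(t)
    if n == 0:
        raise DocumentError("empty text")
    rank = np.unique(t, return_inverse=True)[1].astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    tmp = np.empty(n, dtype=np.int64)
    k = 1
    while rank[sa[-1]] != n - 1:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        sa = np.lexsort((second, rank))
        tmp[sa[0]] = 0
        changed = (rank[sa[1:]] != rank[sa[:-1]]) | (second[sa[1:]] != second[sa[:-1]])
        tmp[sa[1:]] = np.cumsum(changed)
        rank = tmp.copy()
        k *= 2
    return (sa + 1).astype(np.int64)


def build_lcp(text: ConcatenatedText, sa: np.ndarray) -> np.ndarray:
    """LCP array by Kasai's algorithm on the encoded text; ``LCP[1] = 0``."""
    t = text.enc
    n = len(t)
    sa0 = sa - 1
    rank = np.empty(n, dtype=np.int64)
    rank[sa0] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa0[r - 1]
            while i + h < n and j + h < n and t[i + h] == t[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


def build_bwt_lf_da(
    text: ConcatenatedText, sa: np.ndarray
) -> tuple[str, np.ndarray, np.ndarray, np.ndarray]:
    """BWT (separators shown as ``#``), LF mapping, document array, and ISA.

    ``LF[i] = ISA[(SA[i] - 2 mod n) + 1]`` with 1-based values; ``DA[i]`` is
    the document of the suffix at ``SA[i]``.
    """
    n = text.n
    sa0 = sa - 1
    isa0 = np.empty(n, dtype=np.int64)
    isa0[sa0] = np.arange(n)
    prev0 = (sa0 - 1) % n
    bwt = "".join(text.text[p] for p in prev0)
    lf = isa0[prev0] + 1
    da = np.searchsorted(text.doc_start, sa, side="right").astype(np.int64)
    isa = isa0 + 1
    return bwt, lf, da, isa


def lf_from_counts(text: ConcatenatedText, sa: np.ndarray) -> np.ndarray:
    """LF recomputed from first-column counts plus ranks on the encoded BWT.

    Used as an independent cross-check of the ISA-formula LF: for each BWT
    position, LF is the first-column block start of its (distinct-separator)
    symbol plus the symbol's rank so far.
    """
    n = text.n
    sa0 = sa - 1
    enc_bwt = text.enc[(sa0 - 1) % n]
    order = np.argsort(enc_bwt, kind="stable")
    lf = np.empty(n, dtype=np.int64)
    lf[order] = np.arange(1, n + 1)
    return lf


@dataclass(frozen=True)
class BWTRuns:
    """Maximal equal-letter runs of the BWT (all separators count as ``#``)."""

    starts: np.ndarray   # 1-based, increasing
    ends: np.ndarray     # 1-based, inclusive
    chars: str           # run character, one per run

    @property
    def r(self) -> int:
        return len(self.starts)

    def run_of(self, pos: int) -> int:
        """0-based index of the run covering 1-based BWT position ``pos``."""
        return int(np.searchsorted(self.starts, pos, side="right")) - 1


def find_runs(bwt: str) -> BWTRuns:
    """Split the BWT into its maximal equal-letter runs."""
    if not bwt:
        raise DocumentError("empty BWT")
    arr = np.frombuffer(bwt.encode("latin-1"), dtype=np.uint8)
    breaks = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], breaks)) + 1
    ends = np.concatenate((breaks, [len(bwt)]))
    chars = "".join(bwt[s - 1] for s in starts)
    return BWTRuns(starts=starts.astype(np.int64), ends=ends.astype(np.int64), chars=chars)


@dataclass
class SuffixStructures:
    """SA, ISA, LCP, BWT, LF and DA over the concatenation, plus query tables.

    ``occ`` holds, per alphabet character, the sorted 1-based BWT positions of
    that character (rank by binary search); ``cbase`` is the first-column
    offset of each character (separators occupy positions ``1..d``).
    """

    text: ConcatenatedText
    sa: np.ndarray
    isa: np.ndarray
    lcp: np.ndarray
    bwt: str
    lf: np.ndarray
    da: np.ndarray
    occ: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    cbase: dict[str, int] = field(default_factory=dict, repr=False)

    @classmethod
    def from_collection(cls, collection: DocumentCollection) -> "SuffixStructures":
        return cls.from_text(concatenate(collection))

    @classmethod
    def from_text(cls, text: ConcatenatedText) -> "SuffixStructures":
        sa = build_suffix_array(text)
        lcp = build_lcp(text, sa)
        bwt, lf, da, isa = build_bwt_lf_da(text, sa)
        st = cls(text=text, sa=sa, isa=isa, lcp=lcp, bwt=bwt, lf=lf, da=da)
        st._build_query_tables()
        return st

    def _build_query_tables(self) -> None:
        arr = np.frombuffer(self.bwt.encode("latin-1"), dtype=np.uint8)
        base = self.text.d  # separators fill the first d rows of the F column
        for c in self.text.alphabet:
            self.occ[c] = np.flatnonzero(arr == ord(c)) + 1
            self.cbase[c] = base
            base += len(self.occ[c])

    @property
    def n(self) -> int:
        return self.text.n

    def suffix_length_at_rank(self, i: int) -> int:
        """Length of the suffix of rank ``i`` (1-based)."""
        return self.text.suffix_length(int(self.sa[i - 1]))


def backward_step(
    structures: SuffixStructures,
    interval: tuple[int, int] | None,
    c: str,
) -> tuple[int, int] | None:
    """One backward-search step: the SA interval of ``c ·`` (current pattern).

    ``interval=None`` means the full range ``[1, n]`` (empty pattern so far).
    Returns ``None`` when the extended pattern does not occur, including for
    characters outside the alphabet.
    """
    pos = structures.occ.get(c)
    if pos is None or len(pos) == 0:
        return None
    if interval is None:
        s, e = 1, structures.n
    else:
        s, e = interval
        if not 1 <= s <= e <= structures.n:
            raise DocumentError(f"invalid interval {interval!r}")
    base = structures.cbase[c]
    lo = bisect.bisect_right(pos, s - 1)
    hi = bisect.bisect_right(pos, e)
    if lo >= hi:
        return None
    return (base + lo + 1, base + hi)


def pattern_interval(
    structures: SuffixStructures, pattern: str
) -> tuple[int, int] | None:
    """SA interval of a whole pattern via iterated backward steps."""
    if not pattern:
        raise DocumentError("empty pattern")
    interval: tuple[int, int] | None = None
    for c in reversed(pattern):
        interval = backward_step(structures, interval, c)
        if interval is None:
            return None
    return interval
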
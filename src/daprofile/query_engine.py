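"""Queries over the profile index: listing, backward search, MEM extraction.

The central routine is :func:`query_with_profiles`, which runs a right-to-left
backward search for a pattern while maintaining a profile ``P'`` with the
invariant that, after matching the last ``q`` characters, ``P'[j] >= q``
exactly for the documents ``j`` containing the matched suffix.  Each step is
one of two cases:

* the current BWT interval contains a run boundary of the next character —
  adopt the profile sample stored at that boundary (it is the profile of the
  extended match's neighbourhood, valid by the exact-increment lemma);
* the interval lies entirely inside a run of that character — every
  occurrence is preceded by the same character, so all profile entries
  advance by one.

Thresholding the final profile at the pattern length lists the documents in
``O(d)``, independent of the occurrence count — unlike the locate baseline,
which touches every occurrence.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .doc_profiles import ProfileIndex
from .suffix_structures import (
    DocumentError,
    SuffixStructures,
    backward_step,
    pattern_interval,
)


@dataclass
class QueryState:
    """Backward-search state: interval, maintained profile, matched length."""

    interval: tuple[int, int]
    profile: np.ndarray
    matched_length: int


@dataclass(frozen=True)
class MEM:
    """A maximal exact match between a read and the indexed text.

    ``read_offset`` is 1-based; the match cannot be extended by one character
    on either side in the read.  ``one_doc`` is the single document reported
    by the sampled-document-array baseline for this match.
    """

    read_id: str
    read_offset: int
    length: int
    interval: tuple[int, int]
    profile: np.ndarray
    one_doc: int

    def documents(self) -> set[int]:
        return list_documents(self.profile, self.length)


class _Boundaries:
    """Per-character sorted run-boundary positions of a ProfileIndex."""

    def __init__(self, index: ProfileIndex) -> None:
        runs = index.runs
        self.starts: dict[str, list[int]] = {}
        self.ends: dict[str, list[int]] = {}
        for k, c in enumerate(runs.chars):
            self.starts.setdefault(c, []).append(int(runs.starts[k]))
            self.ends.setdefault(c, []).append(int(runs.ends[k]))

    def first_in(self, c: str, s: int, e: int) -> tuple[int, bool] | None:
        """Lowest boundary position of a ``c``-run in ``[s, e]``, with a flag
        telling whether it is a run start (run starts win position ties)."""
        best: tuple[int, bool] | None = None
        for positions, is_start in ((self.starts.get(c), True), (self.ends.get(c), False)):
            if not positions:
                continue
            k = bisect.bisect_left(positions, s)
            if k < len(positions) and positions[k] <= e:
                p = positions[k]
                if best is None or p < best[0] or (p == best[0] and is_start):
                    best = (p, is_start)
        return best


# One-slot cache; holds the index itself so its id cannot be recycled.
_BOUNDARY_CACHE: list = []


def _boundaries(index: ProfileIndex) -> _Boundaries:
    if _BOUNDARY_CACHE and _BOUNDARY_CACHE[0] is index:
        return _BOUNDARY_CACHE[1]
    b = _Boundaries(index)
    _BOUNDARY_CACHE[:] = [index, b]
    return b


def query_with_profiles(
    structures: SuffixStructures,
    index: ProfileIndex,
    pattern: str,
    counter: dict | None = None,
) -> QueryState | None:
    """Backward search with profile maintenance.

    Returns the final :class:`QueryState`, or ``None`` when the pattern does
    not occur in any document (including patterns with characters outside the
    alphabet).  Rejects the empty pattern, which occurs everywhere.
    """
    if not pattern:
        raise DocumentError("empty pattern has no defined listing")
    bounds = _boundaries(index)
    interval: tuple[int, int] | None = None
    profile: np.ndarray | None = None
    matched = 0
    for c in reversed(pattern):
        if interval is None:
            s, e = 1, structures.n
        else:
            s, e = interval
        b = bounds.first_in(c, s, e)
        nxt = backward_step(structures, interval, c)
        if nxt is None:
            return None
        if b is not None:
            pos, is_start = b
            k = index.runs.run_of(pos)
            profile = (
                index.prof_start[k] if is_start else index.prof_end[k]
            ).astype(np.int64, copy=True)
        else:
            # Interval strictly inside a run of c: every occurrence is
            # preceded by c, all entries advance by one.
            if profile is None or structures.bwt[s - 1] != c:
                return None
            profile += 1
        matched += 1
        interval = nxt
        if counter is not None:
            counter["steps"] = counter.get("steps", 0) + 1
    assert interval is not None and profile is not None
    return QueryState(interval=interval, profile=profile, matched_length=matched)


def list_documents(
    profile: np.ndarray, length: int, counter: dict | None = None
) -> set[int]:
    """Documents whose profile entry reaches the match length (1-based ids)."""
    if length < 1:
        raise DocumentError("match length must be at least 1")
    profile = np.asarray(profile)
    if counter is not None:
        counter["doc_comparisons"] = counter.get("doc_comparisons", 0) + len(profile)
    return {int(j) + 1 for j in np.flatnonzero(profile >= length)}


def list_documents_via_locate(
    structures: SuffixStructures, pattern: str, counter: dict | None = None
) -> set[int]:
    """Baseline listing: locate every occurrence and map it to its document.

    Work grows with the occurrence count ``occ`` (counted in ``counter``),
    unlike the profile path which performs ``d`` comparisons after the search.
    """
    interval = pattern_interval(structures, pattern)
    if interval is None:
        return set()
    s, e = interval
    positions = structures.sa[s - 1 : e]
    if counter is not None:
        counter["occ_ops"] = counter.get("occ_ops", 0) + len(positions)
    docs = np.searchsorted(structures.text.doc_start, positions, side="right")
    return {int(j) for j in np.unique(docs)}


def sampled_da_lookup(
    structures: SuffixStructures,
    index: ProfileIndex,
    interval: tuple[int, int],
) -> int:
    """One containing document for a match, from boundary samples only.

    This emulates a sampled document array (one document number per BWT run
    boundary): return the document at the first run start inside the
    interval, else at a run end inside it.  When the interval lies strictly
    inside a run no boundary is available; the document of the interval's
    first suffix — the toehold value a run-length index carries through such
    steps — is returned instead.  The result always contains the match, since
    every position in the interval is an occurrence.
    """
    s, e = interval
    if not 1 <= s <= e <= structures.n:
        raise DocumentError(f"invalid interval {interval!r}")
    runs = index.runs
    k = runs.run_of(s)
    # first run start in [s, e]
    if runs.starts[k] >= s:
        return int(structures.da[runs.starts[k] - 1])
    if k + 1 < runs.r and runs.starts[k + 1] <= e:
        return int(structures.da[runs.starts[k + 1] - 1])
    # first run end in [s, e] (can only be e itself)
    if runs.ends[k] <= e:
        return int(structures.da[runs.ends[k] - 1])
    return int(structures.text.doc_of(int(structures.sa[s - 1])))


class _SuffixAutomaton:
    """Suffix automaton of a string; answers streaming longest-match queries."""

    __slots__ = ("nexts", "link", "length")

    def __init__(self, s: str) -> None:
        self.nexts: list[dict[str, int]] = [{}]
        self.link: list[int] = [-1]
        self.length: list[int] = [0]
        last = 0
        for ch in s:
            last = self._extend(last, ch)

    def _extend(self, last: int, ch: str) -> int:
        nexts, link, length = self.nexts, self.link, self.length
        cur = len(nexts)
        nexts.append({})
        link.append(-1)
        length.append(length[last] + 1)
        p = last
        while p != -1 and ch not in nexts[p]:
            nexts[p][ch] = cur
            p = link[p]
        if p == -1:
            link[cur] = 0
        else:
            q = nexts[p][ch]
            if length[p] + 1 == length[q]:
                link[cur] = q
            else:
                clone = len(nexts)
                nexts.append(dict(nexts[q]))
                link.append(link[q])
                length.append(length[p] + 1)
                while p != -1 and nexts[p].get(ch) == q:
                    nexts[p][ch] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        return cur

    def longest_suffix_matches(self, query: str) -> list[int]:
        """For each prefix of ``query``, the longest suffix occurring in the
        indexed string (the streaming matching-statistics scan)."""
        nexts, link, length = self.nexts, self.link, self.length
        v, ell = 0, 0
        out = []
        for ch in query:
            if ch in nexts[v]:
                v = nexts[v][ch]
                ell += 1
            else:
                while v != -1 and ch not in nexts[v]:
                    v = link[v]
                if v == -1:
                    v, ell = 0, 0
                else:
                    ell = length[v] + 1
                    v = nexts[v][ch]
            out.append(ell)
        return out


_SAM_CACHE: list = []


def _reverse_automaton(structures: SuffixStructures) -> _SuffixAutomaton:
    if _SAM_CACHE and _SAM_CACHE[0] is structures:
        return _SAM_CACHE[1]
    sam = _SuffixAutomaton(structures.text.text[::-1])
    _SAM_CACHE[:] = [structures, sam]
    return sam


def matching_statistics(structures: SuffixStructures, read: str) -> np.ndarray:
    """Per-position longest-match lengths against the indexed text.

    Entry ``p`` (0-based) is the length of the longest prefix of
    ``read[p..]`` occurring anywhere in the text.  Computed by streaming the
    reversed read through a suffix automaton of the reversed text: the
    longest suffix of a reversed-read prefix equals the longest forward match
    starting at the mirrored position.
    """
    if not read:
        raise DocumentError("empty read")
    sam = _reverse_automaton(structures)
    rev = sam.longest_suffix_matches(read[::-1])
    return np.asarray(rev[::-1], dtype=np.int64)


def find_mems(
    structures: SuffixStructures,
    index: ProfileIndex,
    read: str,
    read_id: str = "read",
    min_len: int = 1,
) -> list[MEM]:
    """All maximal exact matches of length >= ``min_len``, with profiles.

    A match starting at position ``p`` with length ``MS[p]`` is right-maximal
    by definition of the matching statistics and left-maximal iff ``p`` is
    the read start or it is not a suffix of the previous position's match
    (``MS[p-1] <= MS[p]``).
    """
    if min_len < 1:
        raise DocumentError("min_len must be at least 1")
    ms = matching_statistics(structures, read)
    mems: list[MEM] = []
    for p0 in range(len(read)):
        L = int(ms[p0])
        if L < min_len:
            continue
        if p0 > 0 and int(ms[p0 - 1]) > L:
            continue
        state = query_with_profiles(structures, index, read[p0 : p0 + L])
        assert state is not None, "matching statistics promised an occurrence"
        mems.append(
            MEM(
                read_id=read_id,
                read_offset=p0 + 1,
                length=L,
                interval=state.interval,
                profile=state.profile,
                one_doc=sampled_da_lookup(structures, index, state.interval),
            )
        )
    return mems
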
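"""Document-array profiles: construction, run-boundary sampling, truncation.

The *document array profile* at BWT rank ``i`` is the ``d``-vector whose
``j``-th entry is the longest common prefix between the suffix of rank ``i``
and any suffix starting inside document ``j``::

    P[i][j] = max{ lcp(T[SA[i]..n], T[SA[k]..n]) : DA[k] = j }

(the maximum includes ``k = i``, so the own-document entry equals the suffix
length).  Thresholding a profile at a match length yields the document
listing.  Storing profiles only at BWT run boundaries — at run ``[s, e]`` we
keep the profiles of ranks ``LF(s)`` and ``LF(e)`` — gives a structure of
``2r`` profiles (``O(rd)`` integers) that suffices to answer listing queries,
by the same toehold reasoning the r-index uses for suffix-array samples.

Three constructions are provided:

``profiles_naive``
    Entry-by-entry evaluation of the definition; the ground-truth oracle.
``profiles_two_pass``
    Per document, the best-matching suffix is the nearest preceding or
    following SA neighbour from that document, so two sweeps maintaining
    running LCP minima produce the full matrix in ``O(nd)``.
``profiles_streaming``
    A single left-to-right scan over (BWT, SA, LCP, DA) that emits only the
    ``2r`` boundary samples, using a predecessor table and a queue of pending
    profiles for the successor halves.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace

import numpy as np

from .suffix_structures import (
    SEPARATOR,
    BWTRuns,
    DocumentError,
    SuffixStructures,
    find_runs,
)


@dataclass(frozen=True)
class ProfileIndex:
    """Run-length BWT runs plus profiles and SA values sampled at boundaries.

    For run ``k`` with boundaries ``(s, e)``, ``prof_start[k]`` is the profile
    of rank ``LF(s)`` and ``prof_end[k]`` that of rank ``LF(e)`` (for a run of
    length one the two coincide).  ``width_cap`` records a truncation cap, if
    any: every stored value is then ``min(value, width_cap)``.
    """

    runs: BWTRuns
    sa_start: np.ndarray      # SA[s] per run
    sa_end: np.ndarray        # SA[e] per run
    prof_start: np.ndarray    # (r, d) int64
    prof_end: np.ndarray      # (r, d) int64
    d: int
    n: int
    width_cap: int | None = None

    @property
    def r(self) -> int:
        return self.runs.r

    def profile_at_boundary(self, pos: int, prefer_start: bool = True) -> np.ndarray:
        """Stored profile sample for a boundary position of some run."""
        k = self.runs.run_of(pos)
        if prefer_start and self.runs.starts[k] == pos:
            return self.prof_start[k]
        if self.runs.ends[k] == pos:
            return self.prof_end[k]
        if self.runs.starts[k] == pos:
            return self.prof_start[k]
        raise DocumentError(f"position {pos} is not a run boundary")


def profiles_naive(structures: SuffixStructures) -> np.ndarray:
    """Full ``n × d`` profile matrix straight from the definition (O(n^2))."""
    text = structures.text
    t = text.enc
    n, d = text.n, text.d
    sa0 = structures.sa - 1
    da0 = structures.da - 1
    out = np.zeros((n, d), dtype=np.int64)
    for i in range(n):
        a = sa0[i]
        row = out[i]
        for k in range(n):
            b = sa0[k]
            j = da0[k]
            h = 0
            while a + h < n and b + h < n and t[a + h] == t[b + h]:
                h += 1
            if h > row[j]:
                row[j] = h
    return out


def profiles_two_pass(structures: SuffixStructures) -> np.ndarray:
    """Full profile matrix from two sweeps of running LCP minima.

    The best same-document neighbour of a suffix in SA order is either the
    nearest preceding or the nearest following suffix of that document, and
    the lcp to it is the minimum of the LCP array over the gap.  The own
    document entry is the suffix length (self match).
    """
    n, d = structures.n, structures.text.d
    lcp = structures.lcp
    da0 = structures.da - 1
    slen = structures.n - structures.sa + 1
    pred = np.zeros(d, dtype=np.int64)
    out = np.empty((n, d), dtype=np.int64)
    for i in range(n):
        if i > 0:
            np.minimum(pred, lcp[i], out=pred)
        out[i] = pred
        pred[da0[i]] = slen[i]
    succ = np.zeros(d, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        if i < n - 1:
            np.minimum(succ, lcp[i + 1], out=succ)
        np.maximum(out[i], succ, out=out[i])
        succ[da0[i]] = slen[i]
    out[np.arange(n), da0] = slen
    return out


def sample_profiles(
    full: np.ndarray, runs: BWTRuns, structures: SuffixStructures
) -> ProfileIndex:
    """Reference sampler: pick ``P[LF(s)]`` and ``P[LF(e)]`` for every run."""
    lf = structures.lf
    s0 = runs.starts - 1
    e0 = runs.ends - 1
    return ProfileIndex(
        runs=runs,
        sa_start=structures.sa[s0].copy(),
        sa_end=structures.sa[e0].copy(),
        prof_start=full[lf[s0] - 1].copy(),
        prof_end=full[lf[e0] - 1].copy(),
        d=full.shape[1],
        n=structures.n,
        width_cap=None,
    )


def profiles_streaming(
    structures: SuffixStructures,
    runs: BWTRuns | None = None,
    selfcheck: bool = False,
) -> ProfileIndex:
    """Single-scan construction of the run-boundary profile samples.

    Scans (BWT, SA, LCP, DA) once from rank 1 to ``n``.  For each rank ``i``
    the profile being assembled is the one of rank ``LF(i)``, i.e. of the
    suffix ``BWT[i] · T[SA[i]..n]``:

    * the *predecessor* halves come from a table ``Pred[doc][char]`` holding
      (plus one, for the prepended character) the lcp between the current
      suffix and the nearest preceding suffix of each document that is
      preceded by each character;
    * the *successor* halves are filled in later: each rank enters a FIFO
      queue as a tuple ``(pos, ch, doc, lcp)`` alongside its pending profile,
      and subsequent ranks preceded by the same character fold their lcp into
      the pending profiles.  A counter table ``LQC[doc][char]`` tells when
      every document has contributed, i.e. when a pending profile is final.

    Separator-preceded ranks are final immediately: distinct separators never
    share a first character, so their cross-document entries are zero.

    With ``selfcheck=True`` the LQC bookkeeping is re-counted from the queue
    at every step (slow; used by instrumented tests and ``--selfcheck``).
    """
    text = structures.text
    n, d = structures.n, text.d
    if runs is None:
        runs = find_runs(structures.bwt)
    bwt = structures.bwt
    lcp = structures.lcp
    lf = structures.lf
    sa = structures.sa
    da = structures.da
    if not (len(lcp) == len(lf) == len(sa) == len(da) == len(bwt) == n):
        raise DocumentError("structure arrays have inconsistent lengths")
    if runs.starts[0] != 1 or runs.ends[-1] != n:
        raise DocumentError("runs do not cover the BWT")

    # Boundary bookkeeping: pos -> (run index, is_start, is_end).
    r = runs.r
    prof_start = np.zeros((r, d), dtype=np.int64)
    prof_end = np.zeros((r, d), dtype=np.int64)
    boundary: dict[int, list[tuple[int, bool]]] = {}
    for k in range(r):
        boundary.setdefault(int(runs.starts[k]), []).append((k, True))
        boundary.setdefault(int(runs.ends[k]), []).append((k, False))

    def emit(pos: int, profile: np.ndarray) -> None:
        for k, is_start in boundary.get(pos, ()):
            if is_start:
                prof_start[k] = profile
            else:
                prof_end[k] = profile

    # pred_plus[j][c] = 1 + lcp(current suffix, nearest preceding suffix of
    # document j preceded by char c); 0 while no such suffix has been seen.
    sigma = len(text.alphabet)
    char_idx = {c: k for k, c in enumerate(text.alphabet)}
    pred_plus = np.zeros((d, sigma), dtype=np.int64)
    lqc = np.zeros((d, sigma), dtype=np.int64)
    queue: deque[list] = deque()  # entries [pos, ch_idx, doc0, lcp, profile]

    for i0 in range(n):
        i = i0 + 1
        ell_i = int(lcp[i0])
        if i0 > 0:
            np.minimum(pred_plus, ell_i + 1, out=pred_plus)
        ch = bwt[i0]
        doc0 = int(da[lf[i0] - 1]) - 1          # DA[LF(i)], 0-based
        slen_lf = n - int(sa[lf[i0] - 1]) + 1   # |T[SA[LF(i)]..n]|
        slen_i = n - int(sa[i0]) + 1

        if ch == SEPARATOR:
            # Distinct separators never share a first character, so the
            # profile is final at insertion (cross entries zero).  The tuple
            # still enters the queue — its LCP value is needed to chain the
            # lcp minima across it — flagged complete with char index -1.
            c = -1
            profile = np.zeros(d, dtype=np.int64)
        else:
            c = char_idx[ch]
            profile = pred_plus[:, c].copy()
        profile[doc0] = slen_lf
        queue.append([i, c, doc0, ell_i, profile])
        if c >= 0:
            lqc[doc0, c] += 1
            pred_plus[doc0, c] = slen_i + 1

            # Fold this rank's lcp into the pending successor halves; going
            # newest-to-oldest keeps ell = lcp(current suffix, suffix at pos).
            ell = slen_i
            for t in reversed(queue):
                if t[0] != i and t[1] == c and t[2] != doc0:
                    if ell + 1 > t[4][doc0]:
                        t[4][doc0] = ell + 1
                ell = min(ell, t[3])

        if selfcheck:
            counted = np.zeros_like(lqc)
            for t in queue:
                if t[1] >= 0:
                    counted[t[2], t[1]] += 1
            if not np.array_equal(counted, lqc):
                raise AssertionError("LQC counters out of sync with the queue")

        # Pop finalized profiles from the front: a pending profile is done
        # once every document has contributed a suffix preceded by its char.
        while queue:
            t = queue[0]
            if t[1] >= 0 and not np.all(lqc[:, t[1]] > 0):
                break
            queue.popleft()
            if t[1] >= 0:
                lqc[t[2], t[1]] -= 1
            emit(t[0], t[4])

    # End-of-scan flush: documents that never provided a same-character
    # suffix leave the successor bound at its predecessor-side value.
    while queue:
        t = queue.popleft()
        emit(t[0], t[4])

    s0 = runs.starts - 1
    e0 = runs.ends - 1
    return ProfileIndex(
        runs=runs,
        sa_start=sa[s0].copy(),
        sa_end=sa[e0].copy(),
        prof_start=prof_start,
        prof_end=prof_end,
        d=d,
        n=n,
        width_cap=None,
    )


def truncate(index: ProfileIndex, cap: int = 255) -> ProfileIndex:
    """Cap every stored profile value at ``cap`` (the 8-bit variant).

    Listing queries for match lengths up to ``cap`` are unaffected: a capped
    value compares identically against any threshold ``<= cap``.
    """
    if cap < 1:
        raise DocumentError("width cap must be a positive integer")
    return replace(
        index,
        prof_start=np.minimum(index.prof_start, cap),
        prof_end=np.minimum(index.prof_end, cap),
        width_cap=cap,
    )


def min_run_substring_length(lcp: np.ndarray, s: int, e: int) -> int:
    """Length of the smallest substring whose occurrences all lie in ``SA[s..e]``.

    For a BWT run ``[s, e]`` this is ``max(LCP[s], LCP[e+1]) + 1`` with the
    convention ``LCP[n+1] = 0``.  All indices are 1-based.
    """
    n = len(lcp)
    if not 1 <= s <= e <= n:
        raise DocumentError(f"invalid run ({s}, {e}) for n={n}")
    left = int(lcp[s - 1])
    right = int(lcp[e]) if e < n else 0
    return max(left, right) + 1


def check_lf_step_lemmas(
    profile: np.ndarray, profile_lf: np.ndarray, ell: int
) -> None:
    """Assert the two LF-step profile relations for one (rank, LF(rank)) pair.

    * Upper bound: every entry grows by at most one under an LF step.
    * Exact increment: entries at least ``ell`` (the minimal run substring
      length) grow by exactly one.

    Raises ``AssertionError`` if either relation fails.
    """
    profile = np.asarray(profile)
    profile_lf = np.asarray(profile_lf)
    if not np.all(profile_lf <= profile + 1):
        raise AssertionError("LF-step upper bound violated")
    big = profile >= ell
    if not np.all(profile_lf[big] == profile[big] + 1):
        raise AssertionError("LF-step exact increment violated")
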
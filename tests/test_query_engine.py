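"""Listing queries, MEM extraction and the locate / one-doc baselines."""

import random

import numpy as np
import pytest

from daprofile import (
    DocumentError,
    PangenomeIndex,
    find_mems,
    list_documents,
    list_documents_via_locate,
    matching_statistics,
    query_with_profiles,
    sampled_da_lookup,
    truncate,
)

from conftest import (
    brute_matching_statistics,
    brute_membership,
    brute_mems,
    brute_occurrences,
    make_collection,
    random_docs,
)


def _index(docs, alphabet="ACGTN", **kw):
    return PangenomeIndex.build(make_collection(docs, alphabet), **kw)


# -- Lemma-1 listing from a profile -------------------------------------


@pytest.mark.parametrize(
    "length, expected",
    [(1, {1, 2, 3}), (2, {2, 3}), (3, {3})],
)
def test_listing_thresholds_printed_profile(length, expected):
    assert list_documents(np.array([1, 2, 4]), length) == expected


def test_listing_rejects_nonpositive_length():
    with pytest.raises(DocumentError):
        list_documents(np.array([1, 2, 4]), 0)


# -- backward search with profile maintenance ---------------------------


def test_whole_unique_document_lists_only_itself():
    docs = ("GATTACAGT", "CCCGGGTTA", "TTTTAAACG")
    idx = _index(docs)
    for j, doc in enumerate(docs, start=1):
        state = query_with_profiles(idx.structures, idx.profiles, doc)
        assert state is not None
        assert list_documents(state.profile, state.matched_length) == {j}


def test_absent_and_invalid_patterns():
    idx = _index(("AACCAA",), alphabet="AC")
    assert query_with_profiles(idx.structures, idx.profiles, "CCC") is None
    assert query_with_profiles(idx.structures, idx.profiles, "AXA") is None
    with pytest.raises(DocumentError):
        query_with_profiles(idx.structures, idx.profiles, "")


def test_final_profile_thresholds_to_brute_membership():
    rng = random.Random(11)
    for _ in range(8):
        docs, alphabet = random_docs(rng, total_max=70)
        idx = _index(docs, alphabet)
        text = "".join(docs)
        patterns = {
            text[p : p + L]
            for L in range(1, 9)
            for p in range(0, len(text) - L + 1, 3)
        }
        patterns.add("G" * 9)
        for pattern in patterns:
            truth = brute_membership(docs, pattern)
            state = query_with_profiles(idx.structures, idx.profiles, pattern)
            got = (
                set()
                if state is None
                else list_documents(state.profile, state.matched_length)
            )
            assert got == truth
            # invariant: entries reach the matched length exactly for the
            # documents containing the pattern
            if state is not None:
                assert state.matched_length == len(pattern)


# -- locate baseline -----------------------------------------------------


def test_locate_baseline_agrees_and_counts_occurrences():
    rng = random.Random(12)
    docs, alphabet = random_docs(rng, total_max=90)
    idx = _index(docs, alphabet)
    text = "".join(docs)
    for L in (2, 4, 6):
        for p in range(0, len(text) - L, 5):
            pattern = text[p : p + L]
            counter: dict = {}
            via_locate = list_documents_via_locate(
                idx.structures, pattern, counter=counter
            )
            assert via_locate == brute_membership(docs, pattern)
            assert counter.get("occ_ops", 0) == len(brute_occurrences(docs, pattern))
            ndoc = len(via_locate)
            assert ndoc <= min(len(docs), counter.get("occ_ops", 0))


def test_pattern_once_per_document_occ_vs_ndoc():
    shared = "GATTACAGG"
    docs = (shared + "TTT", "CCC" + shared, "AA" + shared + "AA")
    idx = _index(docs)
    counter: dict = {}
    via_locate = list_documents_via_locate(idx.structures, shared, counter=counter)
    assert via_locate == {1, 2, 3}
    assert counter["occ_ops"] == 3  # occ enumerations for ndoc = d = 3


def test_profile_path_work_is_d_not_occ():
    # A pattern with many occurrences: the locate baseline touches each one,
    # the profile path does d comparisons after the search.
    docs = ("GAT" * 30, "GAT" * 20 + "C")
    idx = _index(docs)
    pattern = "GAT"
    loc_counter: dict = {}
    list_documents_via_locate(idx.structures, pattern, counter=loc_counter)
    prof_counter: dict = {}
    state = query_with_profiles(idx.structures, idx.profiles, pattern, prof_counter)
    list_documents(state.profile, state.matched_length, counter=prof_counter)
    assert loc_counter["occ_ops"] >= 49
    assert prof_counter["doc_comparisons"] == 2
    assert prof_counter["steps"] == len(pattern)


# -- sampled document array baseline ------------------------------------


def test_one_doc_lookup_unique_match_and_containment():
    rng = random.Random(13)
    docs = ("GATTACA", "GATTAGA", "CATTACA")
    idx = _index(docs)
    state = query_with_profiles(idx.structures, idx.profiles, "TTAG")
    assert sampled_da_lookup(idx.structures, idx.profiles, state.interval) == 2
    for _ in range(200):
        docs, alphabet = random_docs(rng, total_max=80)
        idx2 = _index(docs, alphabet)
        text = "".join(docs)
        p = rng.randrange(len(text))
        pattern = text[p : p + rng.randint(1, 6)]
        state = query_with_profiles(idx2.structures, idx2.profiles, pattern)
        if state is None:
            continue
        doc = sampled_da_lookup(idx2.structures, idx2.profiles, state.interval)
        assert doc in list_documents(state.profile, state.matched_length)


def test_one_doc_lookup_boundary_rule_is_deterministic():
    docs = ("GATTACAGATTACA", "GATTACATTACA")
    idx = _index(docs)
    runs = idx.profiles.runs
    text = "".join(docs)
    state = None
    for L in (2, 3, 4, 5):
        for p in range(len(text) - L):
            pattern = text[p : p + L]
            cand = query_with_profiles(idx.structures, idx.profiles, pattern)
            if cand is None:
                continue
            s, e = cand.interval
            if runs.run_of(e) > runs.run_of(s) and runs.starts[runs.run_of(s) + 1] <= e:
                state = cand
                break
        if state is not None:
            break
    assert state is not None, "no multi-run interval in this instance"
    s, e = state.interval
    first = sampled_da_lookup(idx.structures, idx.profiles, state.interval)
    assert first == sampled_da_lookup(idx.structures, idx.profiles, state.interval)
    # the rule picks the first run start inside the interval
    k = runs.run_of(s)
    start = runs.starts[k] if runs.starts[k] >= s else runs.starts[k + 1]
    assert first == int(idx.structures.da[int(start) - 1])


# -- matching statistics and MEMs ---------------------------------------


def test_matching_statistics_prefix_and_absent_characters():
    docs = ("GATTACAGTC",)
    idx = _index(docs, alphabet="ACGT")
    ms = matching_statistics(idx.structures, docs[0][2:8])
    assert ms[0] == 6  # the read starts with a length-6 text substring
    ms = matching_statistics(idx.structures, "NNNN")
    assert ms.tolist() == [0, 0, 0, 0]


def test_matching_statistics_equals_brute_force():
    rng = random.Random(14)
    for _ in range(10):
        docs, alphabet = random_docs(rng, total_max=80)
        idx = _index(docs, alphabet)
        read = "".join(rng.choice("ACGT") for _ in range(40))
        assert matching_statistics(idx.structures, read).tolist() == \
            brute_matching_statistics(docs, read)


def test_read_identical_to_document_gives_one_covering_mem():
    docs = ("GATTACAGTCCGATAACGT", "TTGGCCAATTGGCA")
    idx = _index(docs)
    mems = find_mems(idx.structures, idx.profiles, docs[0], min_len=1)
    assert len(mems) == 1
    assert (mems[0].read_offset, mems[0].length) == (1, len(docs[0]))
    assert mems[0].documents() == {1}


def test_single_mismatch_splits_the_match():
    rng = random.Random(15)
    doc = "".join(rng.choice("ACGT") for _ in range(40))
    idx = _index((doc,))
    read = doc[:15] + ("A" if doc[15] != "A" else "C") + doc[16:30]
    mems = find_mems(idx.structures, idx.profiles, read, min_len=10)
    assert [(m.read_offset, m.length) for m in mems] == [(1, 15), (17, 14)]


def test_mems_equal_brute_force_on_mutated_reads():
    rng = random.Random(16)
    for _ in range(10):
        docs, alphabet = random_docs(rng, d_range=(2, 4), total_max=120)
        idx = _index(docs, alphabet)
        base = "".join(docs)[:60]
        read = "".join(
            c if rng.random() > 0.08 else rng.choice("ACGT") for c in base
        )
        for min_len in (1, 4):
            mems = find_mems(idx.structures, idx.profiles, read, min_len=min_len)
            assert [(m.read_offset, m.length) for m in mems] == \
                brute_mems(docs, read, min_len)
            for m in mems:
                assert m.documents() == brute_membership(
                    docs, read[m.read_offset - 1 : m.read_offset - 1 + m.length]
                )


# -- truncation at query time -------------------------------------------


def test_truncated_index_lists_identically_below_cap():
    rng = random.Random(17)
    docs, alphabet = random_docs(rng, total_max=100)
    idx = _index(docs, alphabet)
    capped = truncate(idx.profiles, 6)
    text = "".join(docs)
    for L in range(1, 7):
        for p in range(0, len(text) - L, 2):
            pattern = text[p : p + L]
            a = query_with_profiles(idx.structures, idx.profiles, pattern)
            b = query_with_profiles(idx.structures, capped, pattern)
            la = set() if a is None else list_documents(a.profile, a.matched_length)
            lb = set() if b is None else list_documents(b.profile, b.matched_length)
            assert la == lb
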
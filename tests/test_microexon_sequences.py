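"""Length filter, conservation, layout classification, RT-PCR quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mescreen.microexon_sequences import (
    MicroexonRecord,
    classify_upstream_layout,
    cluster_inclusion_profiles,
    ddct,
    identity_ratio,
    linkage_to_newick,
    microexon_length_filter,
    percent_identity,
    rtpcr_inclusion,
)


# ---------------------------------------------------------------------------
# definition filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("nt_len,expected", [(3, True), (30, True), (31, False),
                                             (2, False), (12, True)])
def test_length_filter_boundaries(nt_len, expected):
    assert microexon_length_filter("A" * nt_len) is expected


def test_length_filter_empty_sequence_error():
    with pytest.raises(ValueError, match="empty"):
        microexon_length_filter("")


def test_frame_preserving_record_consistency():
    with pytest.raises(ValueError, match="3 x aa"):
        MicroexonRecord("g", "ATGC", "M", "M", 0.5, "A" * 50)


# ---------------------------------------------------------------------------
# percent identity with an exhaustive alignment oracle
# ---------------------------------------------------------------------------

def oracle_alignments_bruteforce(a, b, match=1.0, mismatch=0.0, gap=-1.0):
    """All global alignments by explicit recursion on (i, j)."""
    results = []

    def rec(i, j, score, matches, columns):
        if i == len(a) and j == len(b):
            results.append((score, matches, columns))
            return
        if i < len(a) and j < len(b):
            hit = a[i] == b[j]
            rec(i + 1, j + 1, score + (match if hit else mismatch),
                matches + hit, columns + 1)
        if i < len(a):
            rec(i + 1, j, score + gap, matches, columns + 1)
        if j < len(b):
            rec(i, j + 1, score + gap, matches, columns + 1)

    rec(0, 0, 0.0, 0, 0)
    best = max(s for s, _, _ in results)
    identities = {
        100.0 * m / c for s, m, c in results if abs(s - best) < 1e-9 and c > 0
    }
    return best, identities


def test_identical_peptides_are_100_percent():
    assert percent_identity("MKLVANGR", "MKLVANGR") == 100.0


def test_single_substitution_in_five():
    assert percent_identity("MKLVA", "MKLIA") == pytest.approx(80.0)


def test_symmetry():
    assert percent_identity("MKLV", "MKV") == pytest.approx(percent_identity("MKV", "MKLV"))


def test_invalid_residue_rejected():
    with pytest.raises(ValueError, match="invalid residue"):
        percent_identity("MKX1", "MK")


@pytest.mark.parametrize("seed", range(8))
def test_alignment_agrees_with_exhaustive_oracle(seed):
    """On peptides up to 6 aa the aligner's identity comes from a genuinely
    optimal alignment (score equal to the enumerated optimum, identity in the
    co-optimal set)."""
    rng = np.random.default_rng(seed)
    alphabet = list("ACDG")
    a = "".join(rng.choice(alphabet, size=rng.integers(1, 7)))
    b = "".join(rng.choice(alphabet, size=rng.integers(1, 7)))
    best, identities = oracle_alignments_bruteforce(a, b)
    got = percent_identity(a, b)
    assert any(got == pytest.approx(i) for i in identities), (a, b, got, identities)


def test_identity_bounds_and_exactness():
    rng = np.random.default_rng(42)
    for _ in range(20):
        a = "".join(rng.choice(list("ACDEFGHIK"), size=rng.integers(1, 9)))
        b = "".join(rng.choice(list("ACDEFGHIK"), size=rng.integers(1, 9)))
        pid = percent_identity(a, b)
        assert 0.0 <= pid <= 100.0
        if a == b:
            assert pid == 100.0


def test_identity_ratio_closed_forms():
    assert identity_ratio(100.0, 50.0) == pytest.approx(2.0)
    assert identity_ratio(70.0, 70.0) == pytest.approx(1.0)
    assert identity_ratio(80.0, 40.0) * identity_ratio(40.0, 80.0) == pytest.approx(1.0)
    assert np.isnan(identity_ratio(50.0, 0.0))


# ---------------------------------------------------------------------------
# upstream layout classification
# ---------------------------------------------------------------------------

def test_canonical_layout_by_inspection():
    # UGC repeats plus a UC-repeat polypyrimidine tract directly upstream
    seq = "G" * 50 + "UGCUGCUGC" + "UCUCUCUCUCUC"
    assert classify_upstream_layout(seq) == "canonical"


def test_all_purine_sequence_noncanonical():
    assert classify_upstream_layout("AG" * 60) == "noncanonical"


def test_ugc_without_tract_partial():
    # UGC repeats embedded in purines: no pyrimidine tract anywhere
    seq = "AG" * 40 + "UGCUGC" + "A" * 10
    assert classify_upstream_layout(seq) == "partial"


def test_tract_without_ugc_partial():
    seq = "AG" * 40 + "UUUCUUCUUC" + "A" * 2
    assert classify_upstream_layout(seq) == "partial"


def test_dna_input_transcribed():
    seq = "G" * 50 + "TGCTGCTGC" + "TCTCTCTCTCTC"
    assert classify_upstream_layout(seq) == "canonical"


def test_invalid_nucleotides_rejected():
    with pytest.raises(ValueError, match="invalid nucleotide"):
        classify_upstream_layout("ACGX")


def test_classifier_ignores_content_outside_window():
    proximal = "UGCUGCUGC" + "UCUCUCUCUCUC"
    far = "UC" * 200  # pyrimidine-rich but beyond the scan window
    assert classify_upstream_layout("A" * 79 + proximal) == \
        classify_upstream_layout(far + "A" * 79 + proximal)


def test_appending_ugc_repeats_never_demotes_canonical():
    seq = "A" * 40 + "UCUCUCUCUCUCUCUC" + "UGCUGC"
    assert classify_upstream_layout(seq) == "canonical"
    for extra in (1, 2, 3):
        assert classify_upstream_layout(seq + "UGC" * extra) == "canonical"


def test_short_sequence_window_shrinks():
    assert classify_upstream_layout("UGCUGCUCUCUCUCUCUC") == "canonical"


# ---------------------------------------------------------------------------
# RT-PCR inclusion and ddCt
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("inc,skip,expected", [(100, 0, 1.0), (0, 50, 0.0),
                                               (30, 10, 0.75), (10, 30, 0.25)])
def test_inclusion_fraction_closed_forms(inc, skip, expected):
    assert rtpcr_inclusion(inc, skip) == pytest.approx(expected)


def test_inclusion_degenerate_and_invalid():
    assert np.isnan(rtpcr_inclusion(0.0, 0.0))
    with pytest.raises(ValueError):
        rtpcr_inclusion(-1.0, 5.0)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    inc=st.floats(0.0, 1e3), skip=st.floats(1e-3, 1e3), bump=st.floats(1e-3, 1e3)
)
def test_inclusion_monotone_in_included_band(inc, skip, bump):
    assert rtpcr_inclusion(inc + bump, skip) > rtpcr_inclusion(inc, skip)


def test_ddct_control_group_centered_at_one():
    ct_t = np.array([20.0, 21.0, 22.0, 18.0])
    ct_r = np.array([15.0, 16.0, 17.0, 15.0])
    ctrl = np.array([True, True, True, False])
    rel = ddct(ct_t, ct_r, ctrl)
    # all control samples share dCt = 5 -> each is exactly 1
    np.testing.assert_allclose(rel[:3], 1.0)
    assert rel[3] == pytest.approx(2.0 ** (-(3.0 - 5.0)))  # ddCt = -2 -> 4.0


def test_ddct_one_cycle_halving():
    rel = ddct([11.0, 10.0], [5.0, 5.0], [False, True])
    assert rel[1] == pytest.approx(1.0)
    assert rel[0] == pytest.approx(0.5)  # ddCt = +1


def test_ddct_empty_control_rejected():
    with pytest.raises(ValueError, match="control"):
        ddct([1.0], [1.0], [False])


# ---------------------------------------------------------------------------
# clustering with a naive agglomeration oracle
# ---------------------------------------------------------------------------

def naive_average_linkage(points):
    """O(n^3) agglomeration: merge the closest pair of clusters under average
    linkage (mean pairwise Euclidean distance); lexicographic tie-break."""
    clusters = {i: [i] for i in range(len(points))}
    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if i >= j:
                    continue
                d = np.mean(
                    [
                        np.linalg.norm(points[p] - points[q])
                        for p in clusters[i]
                        for q in clusters[j]
                    ]
                )
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return heights


def _profile_frame(points, labels=None):
    labels = labels or [f"me{i}" for i in range(len(points))]
    return pd.DataFrame(points, index=labels)


def test_identical_profiles_merge_at_zero():
    df = _profile_frame([[0.1, 0.5, 0.9], [0.1, 0.5, 0.9], [0.9, 0.1, 0.0]])
    _, lm = cluster_inclusion_profiles(df)
    assert lm[0, 2] == 0.0
    assert set(lm[0, :2].astype(int)) == {0, 1}


def test_close_pair_merges_first():
    df = _profile_frame([[0.0, 0.0], [0.01, 0.0], [5.0, 5.0]])
    _, lm = cluster_inclusion_profiles(df)
    assert set(lm[0, :2].astype(int)) == {0, 1}


@pytest.mark.parametrize("seed,n", [(0, 4), (1, 5), (2, 6)])
def test_linkage_heights_match_naive_agglomeration(seed, n):
    rng = np.random.default_rng(seed)
    points = rng.uniform(size=(n, 5))
    df = _profile_frame(points)
    _, lm = cluster_inclusion_profiles(df)
    np.testing.assert_allclose(sorted(lm[:, 2]), sorted(naive_average_linkage(points)),
                               atol=1e-9)


def test_clustering_row_order_invariance():
    rng = np.random.default_rng(3)
    points = rng.uniform(size=(6, 4))
    df = _profile_frame(points)
    order1, _ = cluster_inclusion_profiles(df)
    perm = [3, 0, 5, 1, 4, 2]
    order2, _ = cluster_inclusion_profiles(df.iloc[perm])
    # same partition structure: leaf orders agree up to the documented
    # tie-breaking, i.e. as sets of adjacent merges the trees are identical;
    # with distinct distances the leaf sequence itself matches up to reversal
    assert set(order1) == set(order2)


def test_missing_values_rejected():
    df = _profile_frame([[0.1, np.nan], [0.2, 0.3]])
    with pytest.raises(ValueError, match="missing"):
        cluster_inclusion_profiles(df)


def test_minimum_two_profiles():
    with pytest.raises(ValueError, match="at least 2"):
        cluster_inclusion_profiles(_profile_frame([[0.1, 0.2]]))


def test_newick_export_parses_and_preserves_leaves():
    rng = np.random.default_rng(4)
    df = _profile_frame(rng.uniform(size=(5, 3)))
    _, lm = cluster_inclusion_profiles(df)
    nwk = linkage_to_newick(lm, list(df.index))
    assert nwk.endswith(";")
    import io as _io
    from Bio import Phylo
    tree = Phylo.read(_io.StringIO(nwk), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == sorted(df.index)
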
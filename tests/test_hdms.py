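"""Empirical background p-values, HDMS calling/merging and the cross-mark
overlap and correlation matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from diffem import (
    DynamicsTrack,
    GenomeBins,
    NoSignalError,
    call_hdms,
    empirical_pvalues,
    hdms_overlap_matrix,
    mark_correlation_matrix,
    rank_regions,
)
from diffem.hdms import HDMSRegion


def make_dynamics(scores, n_chroms=1, mask=None, larger=True, ceiling=None,
                  n_cells=4, mark="m", method="diffem"):
    scores = np.asarray(scores, dtype=float)
    N = len(scores)
    per = N // n_chroms
    bins = GenomeBins(
        tuple(f"chr{i+1}" for i in range(n_chroms)),
        tuple([per] * (n_chroms - 1) + [N - per * (n_chroms - 1)]),
        bin_size=200,
    )
    return DynamicsTrack(
        mark=mark, method=method, bins=bins, scores=scores,
        retained_mask=np.ones(N, bool) if mask is None else np.asarray(mask, bool),
        n_cell_types=n_cells, larger_is_dynamic=larger, score_ceiling=ceiling,
    )


def bed_region(chrom, start, end, rid="r"):
    nb = max((end - start) // 200, 1)
    return HDMSRegion(region_id=rid, chrom=chrom, start=start, end=end,
                      start_bin=0, end_bin=nb, peak_bin=0, score=1.0,
                      rank_score=1.0, score_sum=1.0, score_mean=1.0, pvalue=0.01)


class TestEmpiricalPvalues:
    def test_unique_max_among_21(self):
        scores = [1.0] * 20 + [2.0]
        p = empirical_pvalues(make_dynamics(scores))
        assert p[-1] == pytest.approx(1 / 21)
        assert p[-1] < 0.05

    def test_unique_max_among_20_hits_boundary(self):
        scores = [1.0] * 19 + [2.0]
        p = empirical_pvalues(make_dynamics(scores))
        assert p[-1] == pytest.approx(0.05)
        assert not (p[-1] < 0.05)

    def test_degenerate_equal_background(self):
        p = empirical_pvalues(make_dynamics([3.0, 3.0, 3.0]))
        assert np.all(p == 1.0)

    def test_zero_score_bins_get_p_one(self):
        p = empirical_pvalues(make_dynamics([0.0, 1.0, 2.0]))
        assert p[0] == 1.0

    def test_unretained_bins_excluded_and_p_one(self):
        p = empirical_pvalues(make_dynamics([5.0, 1.0, 2.0], mask=[False, True, True]))
        assert p[0] == 1.0
        assert p[2] == pytest.approx(0.5)  # background is only the retained bins

    def test_all_zero_raises_no_signal(self):
        with pytest.raises(NoSignalError):
            empirical_pvalues(make_dynamics([0.0, 0.0]))

    def test_smaller_is_dynamic_flipped(self):
        # entropy-style: score 0 (one-hot) is most dynamic, ceiling = log2 M
        tr = make_dynamics([2.0, 1.0, 0.0, 2.0], larger=False, ceiling=2.0)
        p = empirical_pvalues(tr)
        assert np.argmin(p) == 2
        assert p[0] == 1.0 and p[3] == 1.0  # at-ceiling bins are not dynamic

    @given(scores=st.lists(st.integers(0, 8), min_size=1, max_size=60).filter(lambda s: any(s)))
    @settings(max_examples=80, deadline=None)
    def test_monotone_and_matches_sort_oracle(self, scores):
        tr = make_dynamics(np.array(scores, float))
        p = empirical_pvalues(tr)
        s = np.array(scores, float)
        # oracle: direct counting over the nonzero background
        bg = s[s > 0]
        expected = np.array([(bg >= v).sum() / bg.size if v > 0 else 1.0 for v in s])
        np.testing.assert_allclose(p, expected)
        # monotone non-increasing in score
        order = np.argsort(s)
        assert np.all(np.diff(p[order]) <= 1e-12)


def oracle_components(sig_indices, chrom_of):
    """Union-find over adjacency of significant bins (same chrom, gap 0)."""
    parent = {i: i for i in sig_indices}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in sig_indices:
        if i + 1 in parent and chrom_of(i) == chrom_of(i + 1):
            parent[find(i + 1)] = find(i)
    comps = {}
    for i in sig_indices:
        comps.setdefault(find(i), []).append(i)
    return sorted(sorted(c) for c in comps.values())


class TestCallHdms:
    def test_adjacent_bins_merge_gap_splits(self):
        scores = np.ones(100)
        scores[[10, 11, 12, 14]] = 50.0
        regions = call_hdms(make_dynamics(scores))
        assert [(r.start_bin, r.end_bin) for r in regions] == [(10, 13), (14, 15)]
        assert regions[0].n_bins == 3
        assert regions[0].end - regions[0].start == 3 * 200

    def test_chromosome_boundary_splits_run(self):
        scores = np.ones(100)
        scores[[49, 50]] = 50.0  # last bin of chr1, first of chr2
        regions = call_hdms(make_dynamics(scores, n_chroms=2))
        assert len(regions) == 2
        assert [r.chrom for r in regions] == ["chr1", "chr2"]

    def test_no_significant_bins_empty(self):
        regions = call_hdms(make_dynamics([1.0, 1.0, 2.0, 1.0]))
        assert regions == []

    def test_peak_and_region_score(self):
        scores = np.ones(40)
        scores[20], scores[21], scores[22] = 30.0, 50.0, 40.0
        (r,) = call_hdms(make_dynamics(scores))
        assert r.peak_bin == 21
        assert r.score == 50.0
        assert r.pvalue == pytest.approx(1 / 40)

    def test_merge_gap_allows_tolerance(self):
        scores = np.ones(100)
        scores[[10, 12]] = 50.0
        assert len(call_hdms(make_dynamics(scores))) == 2
        assert len(call_hdms(make_dynamics(scores), merge_gap=1)) == 1

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_merging_matches_union_find_oracle(self, data):
        N = data.draw(st.integers(4, 60))
        n_chroms = data.draw(st.integers(1, 3))
        raw = data.draw(st.lists(st.integers(0, 5), min_size=N, max_size=N))
        scores = np.where(np.array(raw) >= 4, 100.0, np.maximum(raw, 1)).astype(float)
        tr = make_dynamics(scores, n_chroms=min(n_chroms, N))
        p = empirical_pvalues(tr)
        regions = call_hdms(tr, pvalues=p)
        sig = [int(i) for i in np.flatnonzero(p < 0.05)]
        expected = oracle_components(sig, lambda i: int(tr.bins.chrom_of(i)))
        got = [list(range(r.start_bin, r.end_bin)) for r in regions]
        assert sorted(got) == expected

    def test_ranking_key(self):
        rs = [
            bed_region("chr1", 0, 200, "a"),
            bed_region("chr1", 1000, 1600, "b"),
            bed_region("chr2", 0, 200, "c"),
        ]
        rs[0].rank_score, rs[1].rank_score, rs[2].rank_score = 5.0, 9.0, 9.0
        rs[1].end_bin, rs[2].end_bin = 3, 1
        ranked = rank_regions(rs)
        assert [r.region_id for r in ranked] == ["b", "c", "a"]
        assert [r.region_id for r in rank_regions(rs, top_k=1)] == ["b"]


class TestOverlapMatrix:
    def test_identical_call_sets_all_one(self):
        a = [bed_region("chr1", 0, 1000, "a1"), bed_region("chr2", 0, 400, "a2")]
        m = hdms_overlap_matrix({"x": a, "y": list(a)})
        assert (m.to_numpy() == 1.0).all()

    def test_disjoint_call_sets_zero_off_diagonal(self):
        a = [bed_region("chr1", 0, 400, "a1")]
        b = [bed_region("chr1", 1000, 1400, "b1")]
        m = hdms_overlap_matrix({"x": a, "y": b})
        assert m.loc["x", "y"] == 0.0 and m.loc["y", "x"] == 0.0
        assert m.loc["x", "x"] == 1.0

    def test_asymmetric_proportions(self):
        a = [bed_region("chr1", 0, 1000, "a1")]
        b = [bed_region("chr1", 800, 1200, "b1"), bed_region("chr1", 5000, 5400, "b2")]
        m = hdms_overlap_matrix({"A": a, "B": b})
        assert m.loc["A", "B"] == 1.0
        assert m.loc["B", "A"] == 0.5

    def test_empty_set_counts_as_zero(self):
        m = hdms_overlap_matrix({"A": [], "B": [bed_region("chr1", 0, 200)]})
        assert m.loc["A", "A"] == 0.0 and m.loc["A", "B"] == 0.0

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_naive_all_pairs_oracle(self, data):
        def rand_set(tag):
            n = data.draw(st.integers(0, 6))
            out = []
            for i in range(n):
                s = data.draw(st.integers(0, 40)) * 200
                L = data.draw(st.integers(1, 5)) * 200
                chrom = data.draw(st.sampled_from(["chr1", "chr2"]))
                out.append(bed_region(chrom, s, s + L, f"{tag}{i}"))
            return out

        A, B = rand_set("a"), rand_set("b")
        m = hdms_overlap_matrix({"A": A, "B": B})

        def naive(xs, ys):
            if not xs:
                return 0.0
            hit = sum(
                any(x.chrom == y.chrom and x.start < y.end and x.end > y.start for y in ys)
                for x in xs
            )
            return hit / len(xs)

        assert m.loc["A", "B"] == pytest.approx(naive(A, B))
        assert m.loc["B", "A"] == pytest.approx(naive(B, A))


class TestCorrelationMatrix:
    def test_self_correlation_one(self):
        t = make_dynamics([0.0, 2.0, 4.0, 1.0])
        m = mark_correlation_matrix({"a": t, "b": t})
        assert m.loc["a", "b"] == pytest.approx(1.0)

    def test_orientation_flip_gives_minus_one(self):
        a = make_dynamics([0.0, 2.0, 4.0])
        b = make_dynamics([0.0, 2.0, 4.0], larger=False, ceiling=4.0)
        m = mark_correlation_matrix({"a": a, "b": b})
        assert m.loc["a", "b"] == pytest.approx(-1.0)

    def test_linear_tracks_correlate_perfectly(self):
        a = make_dynamics([0.0, 2.0, 4.0])
        b = make_dynamics([1.0, 2.0, 3.0])
        m = mark_correlation_matrix({"a": a, "b": b})
        assert m.loc["a", "b"] == pytest.approx(1.0)
        assert m.equals(m.T)

    def test_constant_track_undefined(self):
        a = make_dynamics([1.0, 1.0, 1.0])
        b = make_dynamics([1.0, 2.0, 3.0])
        m = mark_correlation_matrix({"a": a, "b": b})
        assert np.isnan(m.loc["a", "b"])

    def test_joint_mask_restricts_bins(self):
        # over the joint mask the two tracks agree exactly
        a = make_dynamics([1.0, 2.0, 3.0, 9.0], mask=[True, True, True, False])
        b = make_dynamics([1.0, 2.0, 3.0, 0.0], mask=[True, True, True, True])
        m = mark_correlation_matrix({"a": a, "b": b})
        assert m.loc["a", "b"] == pytest.approx(1.0)
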
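import numpy as np
import pytest

import svmix
from svmix.invcall import InversionCandidate
from svmix.io_align import DepthIndex

from helpers import orient_pair, singleton

MODEL = svmix.InsertModel(mu=200, sigma=20, x=4)  # slack 2*x*sigma = 160


def _cluster(ff_specs, rr_specs, chrom="c1"):
    """Build an InversionCandidate from (left_start, right_start) specs."""
    return InversionCandidate(
        chrom=chrom,
        ff_pairs=[orient_pair("FF", l, r, chrom) for l, r in ff_specs],
        rr_pairs=[orient_pair("RR", l, r, chrom) for l, r in rr_specs],
    )


class TestClusterInversions:
    def test_three_overlapping_ff_pairs_form_a_cluster(self):
        pairs = [orient_pair("FF", 1000 + 10 * i, 6000 - 10 * i)
                 for i in range(3)]
        got = svmix.cluster_inversions(pairs, min_cluster=3)
        assert len(got) == 1
        assert len(got[0].ff_pairs) == 3 and not got[0].rr_pairs

    def test_mixed_orientations_count_together(self):
        pairs = sorted(
            [orient_pair("FF", 1000, 6000), orient_pair("FF", 1010, 5990),
             orient_pair("RR", 1200, 6100)],
            key=lambda p: p.left_start)
        got = svmix.cluster_inversions(pairs, min_cluster=3)
        assert len(got) == 1
        assert got[0].n_pairs == 3

    def test_two_pairs_below_threshold(self):
        pairs = [orient_pair("FF", 1000, 6000),
                 orient_pair("FF", 1010, 5990)]
        assert svmix.cluster_inversions(pairs, min_cluster=3) == []

    def test_disjoint_spans_split_clusters(self):
        pairs = [orient_pair("FF", 1000 + i, 2000 + i) for i in range(3)] \
            + [orient_pair("FF", 50_000 + i, 51_000 + i) for i in range(3)]
        got = svmix.cluster_inversions(pairs, min_cluster=3)
        assert len(got) == 2


class TestGeometryFilter:
    def test_non_increasing_distances_pass(self):
        # FF distances 5000, 4800, 4500 in left-start order
        c = _cluster([(1000, 5964), (1010, 5774), (1020, 5484)], [])
        assert svmix.inversion_geometry_filter(c, MODEL)

    def test_increasing_distances_reject(self):
        # 4500 then 5000: a later pair with a larger mapped distance
        c = _cluster([(1000, 5464), (1010, 5974), (1020, 5984)], [])
        assert not svmix.inversion_geometry_filter(c, MODEL)

    def test_small_increase_within_insert_noise_allowed(self):
        c = _cluster([(1000, 5964), (1010, 6004), (1020, 5904)], [])
        assert svmix.inversion_geometry_filter(c, MODEL)

    def test_ff_left_mates_must_precede_rr_left_mates(self):
        c = _cluster([(1000, 5000), (1100, 4950)], [(900, 5400)])
        assert not svmix.inversion_geometry_filter(c, MODEL)
        ok = _cluster([(1000, 5000), (1100, 4950)], [(1200, 5400)])
        assert svmix.inversion_geometry_filter(ok, MODEL)

    def test_left_start_spread_bounded_by_first_pair_distance(self):
        # spread 600 exceeds the first pair's distance of ~536
        c = _cluster([(1000, 1500), (1300, 1450), (1600, 1400)], [])
        assert not svmix.inversion_geometry_filter(c, MODEL)

    def test_mean_insert_spread_mode(self):
        # spread 250 < first distance (5036) but > mu = 200
        c = _cluster([(1000, 6000), (1250, 5900)], [])
        assert svmix.inversion_geometry_filter(c, MODEL)
        assert not svmix.inversion_geometry_filter(
            c, MODEL, spread_limit="mean_insert")


class TestSingletonWindows:
    def test_ff_window_layout(self):
        pair = orient_pair("FF", 1000, 5000)
        w = svmix.singleton_windows(pair, alpha=300)
        assert [(x.start, x.end, x.strand_rule) for x in w] == [
            (700, 1000, "plus_only"),
            (1000, 1300, "both"),
            (4700, 5000, "plus_only"),
            (5000, 5450, "both"),
        ]

    def test_rr_strand_rules_mirrored(self):
        w = svmix.singleton_windows(orient_pair("RR", 1000, 5000), alpha=300)
        assert [x.strand_rule for x in w] == \
            ["minus_only", "both", "minus_only", "both"]

    def test_alpha_zero_gives_empty_windows(self):
        w = svmix.singleton_windows(orient_pair("FF", 1000, 5000), alpha=0)
        assert all(x.end == x.start for x in w)

    def test_clipping_at_chromosome_start(self):
        w = svmix.singleton_windows(orient_pair("FF", 100, 5000), alpha=300)
        assert (w[0].start, w[0].end) == (0, 100)


def brute_force_f2(cluster, singletons, alpha, chrom_length):
    """Per-base exhaustive singleton-depth count over all windows."""
    best = 0
    for pair in cluster.ff_pairs + cluster.rr_pairs:
        for w in svmix.singleton_windows(pair, alpha, chrom_length):
            for b in range(w.start, w.end):
                depth = 0
                for s in singletons:
                    if s.left_start <= b < s.left_end:
                        if w.strand_rule == "both" \
                                or (w.strand_rule == "plus_only"
                                    and s.singleton_strand == "+") \
                                or (w.strand_rule == "minus_only"
                                    and s.singleton_strand == "-"):
                            depth += 1
                best = max(best, depth)
    return best


class TestInversionFeatures:
    def _index(self, singletons, length=20_000):
        idx = DepthIndex({"c1": length})
        for s in singletons:
            idx.add_singletons("c1", [s.left_start], [s.left_end],
                               [s.singleton_strand])
        return idx

    def test_f1_is_max_of_orientation_counts(self):
        c = _cluster([(1000 + i, 6000) for i in range(10)],
                     [(1500 + i, 6500) for i in range(6)])
        f1, f2 = svmix.inversion_features(c, self._index([]), alpha=300)
        assert (f1, f2) == (10, 0)

    def test_f1_robust_to_one_sided_support(self):
        c = _cluster([(1000 + i, 6000) for i in range(4)], [])
        f1, _ = svmix.inversion_features(c, self._index([]), alpha=300)
        assert f1 == 4

    def test_f2_counts_stacked_plus_singletons_in_first_window(self):
        c = _cluster([(1000, 5000)], [])
        stack = [singleton(960, "+"), singleton(950, "+"),
                 singleton(970, "+")]  # all cover base 980 inside W1
        _, f2 = svmix.inversion_features(c, self._index(stack), alpha=300)
        assert f2 == 3

    def test_minus_singletons_invisible_to_plus_only_window(self):
        c = _cluster([(1000, 5000)], [])
        stack = [singleton(960, "-"), singleton(950, "-")]
        _, f2 = svmix.inversion_features(c, self._index(stack), alpha=300)
        assert f2 == 0

    def test_brute_force_equivalence_on_random_clusters(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_ff = int(rng.integers(0, 5))
            n_rr = int(rng.integers(0 if n_ff else 1, 5))
            c = _cluster(
                [(int(rng.integers(500, 2000)), int(rng.integers(4000, 6000)))
                 for _ in range(n_ff)],
                [(int(rng.integers(500, 2000)), int(rng.integers(4000, 6000)))
                 for _ in range(n_rr)])
            singles = [singleton(int(rng.integers(0, 7000)),
                                 str(rng.choice(["+", "-"])))
                       for _ in range(int(rng.integers(0, 15)))]
            f1, f2 = svmix.inversion_features(c, self._index(singles, 8000),
                                              alpha=120)
            assert f1 == max(n_ff, n_rr)
            assert f2 == brute_force_f2(c, singles, 120, 8000)

    def test_features_invariant_under_pair_reordering(self):
        ff = [(1000, 5000), (1100, 4900), (1050, 4950)]
        singles = [singleton(900, "+"), singleton(905, "+")]
        idx = self._index(singles)
        a = svmix.inversion_features(_cluster(ff, []), idx, alpha=300)
        b = svmix.inversion_features(_cluster(ff[::-1], []), idx, alpha=300)
        assert a == b
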
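"""SE calling: filtering, stitching, density, the rank-curve cutoff.

Each non-trivial stage is checked against an independent brute-force
oracle: union-find transitive closure for stitching, per-base distance
scans for TSS exclusion, and an exhaustive unit-slope tangent-line scan
for the inflection cutoff.
"""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sepipe import (
    GenomicInterval,
    Peak,
    SECallerConfig,
    SignalTrack,
    TSSIndex,
    call_superenhancers,
    compare_se_sets,
    compute_density,
    exclude_tss_proximal,
    filter_peaks,
    find_inflection_cutoff,
    overlaps,
    recovery,
    stitch,
)
from sepipe.se_caller import EmptyLandscapeError
from sepipe.synthetic_data import SimulationConfig, simulate_landscape


def peak(start, end, pvalue=1e-12, chrom="chr1", tags=None):
    return Peak(GenomicInterval(chrom, start, end), pvalue, tags=tags)


# ---------------------------------------------------------------------------
# oracles


def stitch_oracle(peaks, d):
    """Union-find over all pairs with gap <= d (transitive closure)."""
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = peaks[i].interval, peaks[j].interval
            if a.chrom != b.chrom:
                continue
            gap = max(0, max(a.start, b.start) - min(a.end, b.end))
            if gap <= d:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(peaks[i])
    regions = []
    for members in groups.values():
        chrom = members[0].interval.chrom
        start = min(p.interval.start for p in members)
        end = max(p.interval.end for p in members)
        regions.append((chrom, start, end, len(members)))
    return sorted(regions)


def tangency_oracle(densities, tol=1e-12):
    """Exhaustive scan: for each point, test whether the slope-1 line
    through it stays at or below the whole rescaled curve; among touching
    points return the largest index. A curve whose tangent intercept is
    within two rank steps of the diagonal has no elbow (cutoff at top)."""
    d = np.asarray(densities, dtype=float)
    n = d.size
    x = [i / (n - 1) for i in range(n)]
    y = [(v - d[0]) / (d[-1] - d[0]) for v in d]
    best = None
    for i in range(n):
        b = y[i] - x[i]
        if all(y[j] >= x[j] + b - tol for j in range(n)):
            best = i
    if y[best] - x[best] >= -2.0 / (n - 1):
        return n - 1
    return best


# ---------------------------------------------------------------------------
# filtering


class TestFilterPeaks:
    def test_threshold_is_inclusive(self):
        peaks = [peak(0, 10, 1e-10), peak(20, 30, 1e-9), peak(40, 50, 1e-8)]
        kept = filter_peaks(peaks, 1e-9)
        assert kept == peaks[:2]

    def test_threshold_one_is_identity(self):
        peaks = [peak(0, 10, 0.5), peak(20, 30, 1e-3)]
        assert filter_peaks(peaks, 1.0) == peaks

    def test_empty_input(self):
        assert filter_peaks([], 1e-9) == []


class TestTSSExclusion:
    def base_distance(self, p, tss):
        """Brute-force minimum distance from any peak base to the TSS."""
        return min(abs(b - tss) for b in range(p.interval.start, p.interval.end))

    def test_boundary_removed_at_window(self):
        p = peak(3000, 3100)
        assert self.base_distance(p, 1000) == 2000
        assert exclude_tss_proximal([p], [("chr1", 1000)], 2000) == []

    def test_boundary_retained_past_window(self):
        p = peak(3002, 3100)
        assert self.base_distance(p, 1000) == 2002 > 2000
        assert exclude_tss_proximal([p], [("chr1", 1000)], 2000) == [p]

    def test_empty_tss_list_is_identity(self):
        peaks = [peak(0, 10), peak(5000, 5100)]
        assert exclude_tss_proximal(peaks, [], 2000) == peaks

    @given(
        st.lists(
            st.tuples(st.integers(0, 20_000), st.integers(1, 500)),
            min_size=1,
            max_size=15,
        ),
        st.lists(st.integers(0, 20_000), max_size=5),
        st.integers(0, 3000),
    )
    def test_matches_base_distance_oracle(self, raw_peaks, tss_pos, window):
        peaks = [peak(s, s + l) for s, l in raw_peaks]
        tss = [("chr1", t) for t in tss_pos]
        kept = exclude_tss_proximal(peaks, tss, window)
        for p in peaks:
            removed = tss_pos and min(
                self.base_distance(p, t) for t in tss_pos
            ) <= window
            assert (p not in kept) == bool(removed)


# ---------------------------------------------------------------------------
# stitching


class TestStitch:
    def test_stitches_within_distance(self):
        regions = stitch([peak(100, 200), peak(10_000, 10_100)], 12_500)
        assert len(regions) == 1
        assert regions[0].region == GenomicInterval("chr1", 100, 10_100)
        assert len(regions[0].constituents) == 2

    def test_boundary_gap_merges(self):
        regions = stitch([peak(0, 100), peak(100 + 12_500, 100 + 12_600)], 12_500)
        assert len(regions) == 1
        regions = stitch([peak(0, 100), peak(100 + 12_501, 100 + 12_600)], 12_500)
        assert len(regions) == 2

    def test_distant_singletons_stay_single(self):
        peaks = [peak(i * 50_000, i * 50_000 + 100) for i in range(10)]
        regions = stitch(peaks, 12_500)
        assert len(regions) == 10
        for p, r in zip(peaks, regions):
            assert r.region == p.interval

    def _random_peaks(self, rng, n):
        out = []
        for _ in range(n):
            chrom = f"chr{rng.integers(1, 3)}"
            s = int(rng.integers(0, 200_000))
            out.append(peak(s, s + int(rng.integers(50, 2000)), chrom=chrom))
        return out

    def test_matches_union_find_oracle_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            peaks = self._random_peaks(rng, int(rng.integers(1, 40)))
            d = int(rng.integers(0, 30_000))
            got = sorted(
                (r.region.chrom, r.region.start, r.region.end, len(r.constituents))
                for r in stitch(peaks, d)
            )
            assert got == stitch_oracle(peaks, d)

    def test_idempotent_and_conserves_constituents(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            peaks = self._random_peaks(rng, 30)
            first = stitch(peaks, 12_500)
            assert sum(len(r.constituents) for r in first) == len(peaks)
            refake = [
                Peak(r.region, 1e-12) for r in first
            ]  # re-stitch the merged regions
            second = stitch(refake, 12_500)
            # regions that were separate stay separate
            assert len(second) == len(first) or all(
                a.region == b.region for a, b in zip(first, second)
            )
            for a, b in zip(first, stitch([p for r in first for p in r.constituents], 12_500)):
                assert a.region == b.region

    def test_monotone_in_distance(self):
        rng = np.random.default_rng(3)
        peaks = self._random_peaks(rng, 40)
        small = stitch(peaks, 2_000)
        large = stitch(peaks, 20_000)
        # every small region is contained in exactly one large region
        for s in small:
            containers = [
                l
                for l in large
                if l.region.chrom == s.region.chrom
                and l.region.start <= s.region.start
                and s.region.end <= l.region.end
            ]
            assert len(containers) == 1


# ---------------------------------------------------------------------------
# density


class TestDensity:
    def track(self, positions, library):
        return SignalTrack.from_tags({"chr1": np.array(positions)}, library_size=library)

    def test_subtraction(self):
        region = GenomicInterval("chr1", 0, 100)
        t = self.track(list(range(10)), 1_000_000)
        c = self.track(list(range(4)), 1_000_000)
        assert compute_density(region, t, c) == pytest.approx(6.0)

    def test_clipping_at_zero(self):
        region = GenomicInterval("chr1", 0, 100)
        t = self.track(list(range(2)), 1_000_000)
        c = self.track(list(range(10)), 1_000_000)
        assert compute_density(region, t, c) == 0.0

    def test_no_control(self):
        region = GenomicInterval("chr1", 0, 100)
        t = self.track(list(range(10)), 2_000_000)
        assert compute_density(region, t) == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# inflection cutoff


class TestInflectionCutoff:
    def test_linear_ramp_has_zero_ses(self):
        d = np.linspace(0.0, 10.0, 100)
        rank, cutoff = find_inflection_cutoff(d)
        assert rank == 99
        assert cutoff == pytest.approx(10.0)
        assert np.sum(d > cutoff) == 0

    def test_single_outlier_is_the_only_se(self):
        d = np.concatenate([np.ones(999), [1000.0]])
        rank, cutoff = find_inflection_cutoff(d)
        assert cutoff == pytest.approx(1.0)
        assert np.sum(d > cutoff) == 1

    def test_quadratic_tangency_at_half(self):
        # y = x^2 on rescaled axes: dy/dx = 1 at x = 0.5
        n = 1001
        x = np.linspace(0.0, 1.0, n)
        rank, _ = find_inflection_cutoff(x**2)
        assert rank == 500

    def test_degenerate_all_equal_warns_and_gives_zero_ses(self):
        d = np.full(50, 3.0)
        with pytest.warns(UserWarning):
            rank, cutoff = find_inflection_cutoff(d)
        assert np.sum(d > cutoff) == 0

    def test_short_or_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            find_inflection_cutoff([1.0])
        with pytest.raises(ValueError):
            find_inflection_cutoff([3.0, 1.0, 2.0])

    def test_matches_tangent_line_oracle_on_random_curves(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            n = int(rng.integers(2, 400))
            d = np.sort(rng.lognormal(1.0, rng.uniform(0.2, 2.0), n))
            if d[-1] == d[0]:
                continue
            rank, _ = find_inflection_cutoff(d)
            assert rank == tangency_oracle(d)

    def test_scale_invariance_of_labels(self):
        rng = np.random.default_rng(5)
        d = np.sort(rng.lognormal(2.0, 1.0, 500))
        r1, c1 = find_inflection_cutoff(d)
        r2, c2 = find_inflection_cutoff(d * 37.5)
        assert r1 == r2
        assert np.array_equal(d > c1, d * 37.5 > c2)


# ---------------------------------------------------------------------------
# full pipeline


class TestCallSuperenhancers:
    def test_planted_recovery_is_exact(self, called_landscape):
        land, rankings = called_landscape
        for cond, ranking in rankings.items():
            truth = {
                (l.chrom, l.start, l.end)
                for l in land.manifest.se_loci()
                if cond in l.members
            }
            called = {(r.chrom, r.start, r.end) for r in ranking.se_regions()}
            assert called == truth

    def test_se_fraction_small_on_heavy_tailed_input(self, called_landscape):
        land, rankings = called_landscape
        for ranking in rankings.values():
            assert ranking.n_se / len(ranking.enhancers) < 0.10

    def test_ses_are_contiguous_suffix(self, called_landscape):
        _, rankings = called_landscape
        for ranking in rankings.values():
            labels = ranking.labels
            first_se = labels.index("SE")
            assert all(l == "SE" for l in labels[first_se:])
            dens = [e.density for e in ranking.enhancers]
            assert dens == sorted(dens)

    def test_all_tss_proximal_peaks_is_an_error(self):
        peaks = [peak(1000, 1100), peak(1500, 1600)]
        t = SignalTrack.from_tags({"chr1": np.array([1050])})
        with pytest.raises(EmptyLandscapeError, match="TSS exclusion"):
            call_superenhancers(peaks, [("chr1", 1000)], t)

    def test_deterministic_rank_curve(self, called_landscape):
        land, rankings = called_landscape
        cond = land.conditions[0]
        tss = TSSIndex(land.coding_tss())
        again = call_superenhancers(
            land.peaks[cond], tss, land.signals[cond], land.control
        )
        a = rankings[cond].rank_curve().to_csv(sep="\t", float_format="%.6f")
        b = again.rank_curve().to_csv(sep="\t", float_format="%.6f")
        assert a == b

    def test_regions_bed_mode_skips_stitching(self, called_landscape):
        land, rankings = called_landscape
        cond = land.conditions[0]
        regions = [e.region for e in rankings[cond].enhancers]
        reranked = call_superenhancers(
            [], [], land.signals[cond], land.control, regions=regions
        )
        assert len(reranked.enhancers) == len(regions)
        assert reranked.n_se == rankings[cond].n_se


class TestCompareSESets:
    def iv(self, s, e):
        return GenomicInterval("chr1", s, e)

    def test_identical_sets_fully_shared(self):
        ses = [self.iv(0, 1000), self.iv(5000, 7000)]
        cmp = compare_se_sets({"A": ses, "B": list(ses)})
        assert cmp.shared_all_fraction == 1.0

    def test_disjoint_sets_share_nothing(self):
        cmp = compare_se_sets(
            {"A": [self.iv(0, 1000)], "B": [self.iv(5000, 6000)]}
        )
        assert cmp.shared_all_fraction == 0.0
        assert cmp.shared_two_plus_fraction == 0.0

    def test_one_bp_overlap_counts_with_brute_force_venn(self):
        a = [self.iv(0, 10_000)]
        b = [self.iv(9_999, 20_000)]
        cmp = compare_se_sets({"A": a, "B": b, "C": []})
        # brute-force pairwise overlap enumeration
        assert overlaps(a[0], b[0])
        assert cmp.venn_counts == {("A", "B"): 1}
        assert cmp.shared_all_fraction == 0.0

    def test_recovery_counts(self):
        ref = [self.iv(0, 1000), self.iv(5000, 6000), self.iv(9000, 9500)]
        query = [self.iv(900, 1100), self.iv(9400, 9600)]
        assert recovery(ref, query) == (2, 3)
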
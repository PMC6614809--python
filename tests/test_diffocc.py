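"""Effect-size statistics: Cohen's d, common peaks, scope comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from occudiff.diffocc import (
    UndefinedEffectSizeError,
    cohens_d,
    compare_samples,
    effect_label,
    match_common_peaks,
    region_enrichment,
    stratify_by_overlap,
)
from occudiff.interval_io import CoverageTrack
from occudiff.peaks import Peak, PeakSet
from occudiff.scenarios import simulate_tracks_and_peaks
from occudiff.synthetic_data import OccupancyModel, place_point_sites

finite_vec = st.lists(
    st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
    min_size=2, max_size=30,
)


def peakset(*intervals, chrom="chr1"):
    peaks = [
        Peak(chrom, s, e, (s + e) // 2, 1.0, 2.0) for s, e in sorted(intervals)
    ]
    return PeakSet(peaks)


def uniform_track(value, n_bins=100, bin_size=100, chrom="chr1", library=1):
    return CoverageTrack(
        bin_size=bin_size,
        counts={chrom: np.full(n_bins, float(value))},
        chrom_sizes={chrom: n_bins * bin_size},
        library_size=library,
        norm="per_million",
    )


class TestCohensD:
    def test_identical_constant_vectors(self):
        es = cohens_d([5, 5, 5, 5], [5, 5, 5, 5])
        assert es.d == 0.0 and es.label == "negligible"

    def test_textbook_example(self):
        es = cohens_d([1, 2, 3, 4], [3, 4, 5, 6])
        assert es.d == pytest.approx(-1.549, abs=5e-4)
        assert es.sd_pooled == pytest.approx(math.sqrt(5 / 3), rel=1e-12)
        assert es.label == "large"

    @pytest.mark.parametrize(
        "d,label",
        [(1.56, "large"), (0.49, "small"), (0.62, "medium"), (0.05, "negligible"),
         (-1.02, "large"), (0.2, "small"), (0.8, "large"), (0.5, "medium")],
    )
    def test_conventional_labels(self, d, label):
        assert effect_label(d) == label

    def test_zero_spread_unequal_means_is_undefined(self):
        with pytest.raises(UndefinedEffectSizeError):
            cohens_d([1, 1, 1], [2, 2, 2])

    def test_needs_two_observations(self):
        with pytest.raises(ValueError, match="at least 2"):
            cohens_d([1], [2, 3])

    @given(finite_vec, finite_vec)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antisymmetry(self, x, y):
        try:
            dxy = cohens_d(x, y).d
        except UndefinedEffectSizeError:
            return
        assert cohens_d(y, x).d == -dxy

    @given(finite_vec, finite_vec, st.floats(1e-3, 1e3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_invariance(self, x, y, a):
        x, y = np.asarray(x), np.asarray(y)
        try:
            d1 = cohens_d(x, y).d
        except UndefinedEffectSizeError:
            return
        d2 = cohens_d(a * x, a * y).d
        assert d2 == pytest.approx(d1, rel=1e-9, abs=1e-9)

    def test_matches_independent_implementation(self):
        """Cross-check against pingouin's pooled-SD Cohen's d."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        for _ in range(200):
            nx, ny = rng.integers(2, 50, size=2)
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), nx)
            y = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), ny)
            ours = cohens_d(x, y).d
            theirs = pingouin.compute_effsize(x, y, eftype="cohen")
            assert ours == pytest.approx(theirs, abs=1e-10)


class TestCommonPeaks:
    def test_identical_sets_pair_per_peak(self):
        ps = peakset((100, 300), (1000, 1200))
        pairs = match_common_peaks(ps, ps)
        assert [(p.start, p.end) for p in pairs] == [(100, 300), (1000, 1200)]

    def test_disjoint_sets_give_nothing(self):
        a = peakset((100, 300))
        b = peakset((5000, 5200))
        assert match_common_peaks(a, b) == []

    def test_chained_union_component(self):
        """A=[100,300), B=[250,400)+[380,500) chains into one [100,500) region
        (the B intervals overlap each other, so they are passed as a raw list)."""
        a = peakset((100, 300))
        b = [Peak("chr1", 250, 400, 300, 1.0, 2.0),
             Peak("chr1", 380, 500, 400, 1.0, 2.0)]
        pairs = match_common_peaks(a, b, min_overlap=1)
        assert [(p.start, p.end) for p in pairs] == [(100, 500)]

    def test_min_overlap_breaks_weak_chains(self):
        a = peakset((100, 300))
        b = peakset((295, 400))  # 5 bp overlap
        assert match_common_peaks(a, b, min_overlap=1)
        assert match_common_peaks(a, b, min_overlap=10) == []

    def test_brute_force_union_oracle(self):
        """Union components agree with a per-base brute-force painting."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            a_iv = sorted(
                {(int(s), int(s) + int(l)) for s, l in
                 zip(rng.integers(0, 5000, 8), rng.integers(10, 300, 8))}
            )
            b_iv = sorted(
                {(int(s), int(s) + int(l)) for s, l in
                 zip(rng.integers(0, 5000, 8), rng.integers(10, 300, 8))}
            )
            a_iv = _drop_overlaps(a_iv)
            b_iv = _drop_overlaps(b_iv)
            pairs = match_common_peaks(peakset(*a_iv), peakset(*b_iv))
            # brute force: paint bases, find components, keep those with both
            paint = np.zeros(6000, dtype=int)
            for s, e in a_iv:
                paint[s:e] |= 1
            for s, e in b_iv:
                paint[s:e] |= 2
            expected = []
            covered = paint > 0
            i = 0
            while i < len(covered):
                if covered[i]:
                    j = i
                    while j < len(covered) and covered[j]:
                        j += 1
                    if (paint[i:j] & 1).any() and (paint[i:j] & 2).any():
                        expected.append((i, j))
                    i = j
                else:
                    i += 1
            assert [(p.start, p.end) for p in pairs] == expected


def _drop_overlaps(ivs):
    out = []
    for s, e in ivs:
        if not out or s >= out[-1][1]:
            out.append((s, e))
    return out


class TestRegionEnrichment:
    def test_uniform_track_returns_value(self):
        track = uniform_track(7.0)
        vals = region_enrichment(track, [("chr1", 0, 1000), ("chr1", 4321, 6789)])
        assert vals.tolist() == [7.0, 7.0]

    def test_half_covered_region_averages(self):
        track = uniform_track(0.0)
        track.counts["chr1"][:5] = 2.0  # first 500 bp at 2v
        vals = region_enrichment(track, [("chr1", 0, 1000)])
        assert vals[0] == pytest.approx(1.0)

    def test_empty_region_list(self):
        assert len(region_enrichment(uniform_track(1.0), [])) == 0

    @pytest.mark.parametrize(
        "region", [("chr1", 500, 500), ("chr1", 9000, 11_000), ("chrX", 0, 100)]
    )
    def test_bad_regions_rejected(self, region):
        with pytest.raises(ValueError):
            region_enrichment(uniform_track(1.0), [region])

    def test_requires_per_million(self):
        track = uniform_track(1.0)
        track.norm = "raw"
        with pytest.raises(ValueError, match="per-million"):
            region_enrichment(track, [("chr1", 0, 100)])


class TestCompareSamples:
    def _tracks_and_peaks(self, seed, multiplier=1.0):
        from occudiff.scenarios import two_chrom_genome

        genome = two_chrom_genome(chrom_len=400_000, n_chroms=1)
        mean_w = genome.total_length * 0.25 / 0.75 / 60
        sites = place_point_sites(genome, 60, 300, mean_w, 0.35, seed=9)
        model = OccupancyModel("f", sites, 1.0, drug_multiplier=multiplier)
        ref = simulate_tracks_and_peaks(genome, model, False, seed, n_fragments=60_000)
        drug = simulate_tracks_and_peaks(genome, model, True, seed + 1, n_fragments=60_000)
        return ref, drug

    def test_identical_tracks_give_zero_d(self):
        (enr, ps, _), _ = self._tracks_and_peaks(seed=10)
        res = compare_samples(enr, enr, ps, ps)
        assert res.genome.d == 0.0
        assert res.peaks.d == 0.0
        assert len(res.pairs) == len(ps)

    def test_drug_signal_concentrates_in_peaks(self):
        """A 2x site multiplier is clearer at Peaks scope than genome-wide."""
        (enr_ref, ps_ref, _), (enr_drug, ps_drug, _) = self._tracks_and_peaks(
            seed=20, multiplier=2.0
        )
        res = compare_samples(enr_drug, enr_ref, ps_drug, ps_ref)
        assert res.peaks is not None
        assert abs(res.peaks.d) > abs(res.genome.d) > 0

    def test_no_common_peaks_flagged(self):
        track = uniform_track(1.0, n_bins=200)
        a = peakset((100, 300))
        b = peakset((15_000, 15_200))
        res = compare_samples(track, track, a, b)
        assert res.peaks is None and res.pairs == []
        assert res.genome is not None


class TestStratify:
    def test_full_mask_binds_everything(self):
        pairs = match_common_peaks(peakset((100, 300)), peakset((100, 300)))
        mask = peakset((0, 10_000))
        bound, unbound = stratify_by_overlap(pairs, mask)
        assert len(bound) == 1 and unbound == []

    def test_empty_mask_binds_nothing(self):
        pairs = match_common_peaks(peakset((100, 300)), peakset((100, 300)))
        bound, unbound = stratify_by_overlap(pairs, PeakSet([]))
        assert bound == [] and len(unbound) == 1

    def test_partition_is_exhaustive_and_exclusive(self):
        pairs = match_common_peaks(
            peakset((100, 300), (1000, 1300), (5000, 5400)),
            peakset((200, 350), (1100, 1250), (5100, 5300)),
        )
        mask = peakset((1200, 1600))
        bound, unbound = stratify_by_overlap(pairs, mask)
        assert len(bound) + len(unbound) == len(pairs)
        assert not (set(p.region for p in bound) & set(p.region for p in unbound))
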
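"""Repeat-family quantification with multimappers, and category fractions."""

import numpy as np
import pytest
from scipy import stats

from occudiff.peaks import Peak, PeakSet
from occudiff.repeats import category_fractions, compare_family_conditions, family_signal
from occudiff.synthetic_data import (
    Condition,
    GeneModel,
    OccupancyModel,
    RepeatFamily,
    Site,
    simulate_library,
)

COND = Condition("factor", "WT", False)
COND_DRUG = Condition("factor", "WT", True)


def family_site_model(genome, weight=1e6, drug_multiplier=1.0, **kw):
    """A single site in the middle of the family's first copy, negligible background."""
    fam = genome.repeat_families[0]
    chrom, cs, ce = fam.copies[0]
    site = Site(chrom, (cs + ce) // 2, 100, weight)
    return OccupancyModel("factor", (site,), 1e-6, drug_multiplier=drug_multiplier, **kw)


class TestFamilySignal:
    def test_empty_library_zero_signal(self, spread_repeat_genome):
        fam = spread_repeat_genome.repeat_families[0]
        sig = family_signal([], fam, spread_repeat_genome)
        assert sig.unfiltered_total == 0 and sig.filtered_total == 0
        assert sig.unfiltered_enrichment.sum() == 0

    def test_scattered_family_totals_and_binomial_copy_counts(self, spread_repeat_genome):
        fam = spread_repeat_genome.repeat_families[0]
        model = family_site_model(spread_repeat_genome)
        frags, _ = simulate_library(spread_repeat_genome, model, COND, 1000, seed=1)
        sig = family_signal(frags, fam, spread_repeat_genome)
        assert sig.unfiltered_total == 1000
        assert sig.filtered_total == 0  # every fragment is a MAPQ-0 multimapper
        lo = stats.binom.ppf(0.005, 1000, 0.1)
        hi = stats.binom.ppf(0.995, 1000, 0.1)
        assert ((sig.unfiltered_counts >= lo) & (sig.unfiltered_counts <= hi)).all()

    def test_totals_invariant_across_assignment_seeds(self, spread_repeat_genome):
        fam = spread_repeat_genome.repeat_families[0]
        model = family_site_model(spread_repeat_genome)
        totals = set()
        copy_layouts = set()
        for aseed in range(10):
            frags, _ = simulate_library(
                spread_repeat_genome, model, COND, 1000, seed=2,
                assignment_seed=aseed,
            )
            sig = family_signal(frags, fam, spread_repeat_genome)
            totals.add(sig.unfiltered_total)
            copy_layouts.add(tuple(sig.unfiltered_counts.tolist()))
        assert totals == {1000}
        assert len(copy_layouts) > 1  # per-copy placement does move

    def test_filtered_bounded_by_unfiltered_per_copy(self, spread_repeat_genome):
        fam = spread_repeat_genome.repeat_families[0]
        model = family_site_model(spread_repeat_genome, weight=100.0)
        model = OccupancyModel("factor", model.sites, 1.0)  # real background too
        frags, _ = simulate_library(spread_repeat_genome, model, COND, 20_000, seed=3)
        sig = family_signal(frags, fam, spread_repeat_genome)
        assert (sig.filtered_enrichment <= sig.unfiltered_enrichment + 1e-12).all()
        assert (sig.filtered_counts <= sig.unfiltered_counts).all()


class TestCompareFamilyConditions:
    def _signals(self, genome, multiplier, seed=4, n=20_000):
        fam = genome.repeat_families[0]
        # one site per copy: the whole family is occupied
        sites = tuple(
            Site(chrom, (s + e) // 2, 100, 500.0) for chrom, s, e in fam.copies
        )
        model = OccupancyModel("factor", sites, 1.0, drug_multiplier=multiplier)
        fr_ref, _ = simulate_library(genome, model, COND, n, seed=seed)
        fr_drug, _ = simulate_library(genome, model, COND_DRUG, n, seed=seed + 1)
        return (
            family_signal(fr_drug, fam, genome),
            family_signal(fr_ref, fam, genome),
        )

    def test_identical_signals_give_zero(self, spread_repeat_genome):
        fam = spread_repeat_genome.repeat_families[0]
        model = family_site_model(spread_repeat_genome)
        frags, _ = simulate_library(spread_repeat_genome, model, COND, 1000, seed=5)
        sig = family_signal(frags, fam, spread_repeat_genome)
        assert compare_family_conditions(sig, sig).d == 0.0

    def test_doubling_gives_large_effect(self, spread_repeat_genome):
        sig_drug, sig_ref = self._signals(spread_repeat_genome, multiplier=2.0)
        es = compare_family_conditions(sig_drug, sig_ref)
        assert es.d >= 0.8

    def test_antisymmetry(self, spread_repeat_genome):
        sig_drug, sig_ref = self._signals(spread_repeat_genome, multiplier=2.0)
        assert compare_family_conditions(sig_ref, sig_drug).d == pytest.approx(
            -compare_family_conditions(sig_drug, sig_ref).d
        )

    def test_genotype_dependent_sign_flip(self, spread_repeat_genome):
        """Drug halves the family signal in one genotype (active removal by
        the protector) and doubles it in the deletion: d flips sign."""
        d_wt = compare_family_conditions(
            *self._signals(spread_repeat_genome, multiplier=0.5, seed=6)
        ).d
        d_del = compare_family_conditions(
            *self._signals(spread_repeat_genome, multiplier=2.0, seed=6)
        ).d
        assert d_wt < 0 < d_del

    def test_single_copy_family_rejected(self):
        fam = RepeatFamily("solo", "rDNA", (("chr1", 100, 200),))
        from occudiff.synthetic_data import GenomeSpec

        genome = GenomeSpec((("chr1", 10_000),), (fam,))
        sig = family_signal([], fam, genome)
        with pytest.raises(ValueError, match="2 copies"):
            compare_family_conditions(sig, sig)


class TestCategoryFractions:
    def _genes(self):
        return [
            GeneModel("t1", "chr1", 1000, 1100, "+", "tRNA", 5.0),
            GeneModel("t2", "chr1", 3000, 3100, "+", "tRNA", 5.0),
            GeneModel("m1", "chr1", 6000, 8000, "+", "mRNA", 1.0),
        ]

    def test_all_peaks_in_trna(self):
        peaks = PeakSet([
            Peak("chr1", 1000, 1100, 1050, 1.0, 2.0),
            Peak("chr1", 3000, 3100, 3050, 1.0, 2.0),
        ])
        fr = category_fractions(peaks, self._genes())
        assert fr["tRNA"] == 1.0 and fr["mRNA"] == 0.0 and fr["unannotated"] == 0.0

    def test_no_overlap_is_all_unannotated(self):
        peaks = PeakSet([Peak("chr1", 9000, 9200, 9100, 1.0, 2.0)])
        fr = category_fractions(peaks, self._genes())
        assert fr["unannotated"] == 1.0
        assert fr["tRNA"] == 0.0 and fr["mRNA"] == 0.0

    def test_empty_peakset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            category_fractions(PeakSet([]), self._genes())

    def test_multi_class_peak_counted_in_both(self):
        genes = self._genes() + [GeneModel("m2", "chr1", 950, 1500, "-", "mRNA", 1.0)]
        # overlapping annotation entries on purpose (peak spans tRNA and mRNA)
        peaks = PeakSet([Peak("chr1", 990, 1200, 1050, 1.0, 2.0)])
        fr = category_fractions(peaks, genes)
        assert fr["tRNA"] == 1.0 and fr["mRNA"] == 1.0
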
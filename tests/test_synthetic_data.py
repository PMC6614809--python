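"""Generator contracts: determinism, conservation, mixture behaviour."""

import numpy as np
import pytest
from scipy import stats

from occudiff.synthetic_data import (
    Condition,
    FragmentLengthModel,
    GenomeSpec,
    OccupancyModel,
    RepeatFamily,
    Site,
    build_toy_genome,
    simulate_input_library,
    simulate_library,
    write_annotation,
)

from conftest import footprint_count, single_site_model

COND = Condition("factor", "WT", False)
COND_DRUG = Condition("factor", "WT", True)


class TestToyGenome:
    def test_construction_contract(self, toy_genome_genes):
        genome, genes = toy_genome_genes
        assert genome.chromosomes == (("chr1", 200_000),)
        assert [f.n_copies for f in genome.repeat_families] == [10]
        assert sum(1 for g in genes if g.gene_class == "mRNA") == 50
        assert sum(1 for g in genes if g.gene_class == "tRNA") == 10
        # genes are sorted and non-overlapping, strands assigned, expression >= 0
        for a, b in zip(genes, genes[1:]):
            assert (a.chrom, a.start) <= (b.chrom, b.start)
            if a.chrom == b.chrom:
                assert b.start >= a.end
        assert all(g.strand in "+-" and g.expression >= 0 for g in genes)

    def test_deterministic_annotation(self, tmp_path):
        paths = []
        for i in range(2):
            _, genes = build_toy_genome(1, 200_000, 50, [10], seed=1)
            p = tmp_path / f"ann{i}.tsv"
            write_annotation(genes, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_seed_changes_coordinates(self):
        _, genes1 = build_toy_genome(1, 200_000, 50, [10], seed=1)
        _, genes2 = build_toy_genome(1, 200_000, 50, [10], seed=2)
        assert [(g.start, g.end) for g in genes1] != [(g.start, g.end) for g in genes2]

    def test_overflow_raises(self):
        with pytest.raises(RuntimeError):
            build_toy_genome(1, 10_000, 500, [10], seed=1)


class TestGenomeSpecValidation:
    def test_rejects_overlapping_repeat_copies(self):
        fam = RepeatFamily("f", "tRNA", (("chr1", 100, 200), ("chr1", 150, 250)))
        with pytest.raises(ValueError, match="overlap"):
            GenomeSpec((("chr1", 1000),), (fam,))

    def test_rejects_duplicate_chromosomes(self):
        with pytest.raises(ValueError, match="unique"):
            GenomeSpec((("chr1", 1000), ("chr1", 2000)))

    def test_rejects_bad_repeat_class(self):
        with pytest.raises(ValueError, match="repeat class"):
            RepeatFamily("f", "LINE", (("chr1", 0, 10),))


class TestSimulateLibrary:
    def test_empty_library(self, flat_genome):
        model = OccupancyModel("factor", (), 1.0)
        frags, truth = simulate_library(flat_genome, model, COND, 0, seed=1)
        assert frags == []
        assert truth.params["n_fragments"] == 0

    @pytest.mark.parametrize("n", [1, 777, 5000])
    def test_fragment_count_conserved(self, flat_genome, n):
        model = single_site_model("chr1", 50_000, 1000.0)
        frags, _ = simulate_library(flat_genome, model, COND, n, seed=3)
        assert len(frags) == n

    def test_lengths_within_shearing_range(self, flat_genome):
        """Sampled lengths stay in the 250-500 bp shearing window (fragments
        hitting a chromosome end are truncated and excluded here)."""
        model = OccupancyModel("factor", (), 1.0)
        frags, _ = simulate_library(flat_genome, model, COND, 5000, seed=4)
        interior = [f for f in frags if f.start > 0 and f.end < 100_000]
        assert len(interior) > 4900
        lengths = np.array([f.length for f in interior])
        assert lengths.min() >= 250 and lengths.max() <= 500
        se = np.sqrt(np.var(np.arange(250, 501).astype(float)) / len(lengths))
        assert abs(lengths.mean() - 375.0) < 3 * se

    def test_background_uniform_chi_square(self, flat_genome):
        model = OccupancyModel("factor", (), 1.0)
        frags, _ = simulate_library(flat_genome, model, COND, 10_000, seed=5)
        centers = np.array([(f.start + f.end) // 2 for f in frags])
        counts, _ = np.histogram(centers, bins=20, range=(0, 100_000))
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_determinism_and_seed_sensitivity(self, flat_genome):
        model = single_site_model("chr1", 50_000, 500.0)
        a1, _ = simulate_library(flat_genome, model, COND, 2000, seed=6)
        a2, _ = simulate_library(flat_genome, model, COND, 2000, seed=6)
        b, _ = simulate_library(flat_genome, model, COND, 2000, seed=7)
        assert a1 == a2
        assert a1 != b

    def test_fragments_truncated_at_chromosome_ends(self, flat_genome):
        model = single_site_model("chr1", 10, 1e9, width=20, background_rate=1e-9)
        frags, _ = simulate_library(flat_genome, model, COND, 500, seed=8)
        assert all(f.start >= 0 and f.end <= 100_000 and f.start < f.end for f in frags)

    def test_site_outside_genome_rejected(self, flat_genome):
        model = single_site_model("chr1", 200_000, 1.0)
        with pytest.raises(ValueError, match="outside"):
            simulate_library(flat_genome, model, COND, 10, seed=1)

    def test_dose_response_monotone(self, flat_genome):
        """Expected footprint count rises with effective site weight
        (3 weight levels x 10 seeds, Wilcoxon signed-rank on the trend)."""
        counts = {w: [] for w in (500.0, 1000.0, 2000.0)}
        for w in counts:
            model = single_site_model("chr1", 50_000, w)
            for seed in range(10):
                frags, _ = simulate_library(flat_genome, model, COND, 5000, seed=seed)
                counts[w].append(footprint_count(frags, "chr1", 49_700, 50_300))
        lo, mid, hi = (np.array(counts[w]) for w in (500.0, 1000.0, 2000.0))
        assert stats.wilcoxon(mid - lo, alternative="greater").pvalue < 0.05
        assert stats.wilcoxon(hi - mid, alternative="greater").pvalue < 0.05

    def test_protected_sites_unaffected_by_drug(self, flat_genome):
        """A protected site (multiplier override = 1) keeps its expected
        footprint count under drug, within 3 SE."""
        model = single_site_model(
            "chr1", 50_000, 2000.0,
            drug_multiplier=3.0, protection_map=frozenset({0}),
            protected_multiplier=1.0,
        )
        per_cond = []
        for cond in (COND, COND_DRUG):
            vals = [
                footprint_count(
                    simulate_library(flat_genome, model, cond, 20_000, seed=s)[0],
                    "chr1", 49_700, 50_300,
                )
                for s in range(5)
            ]
            per_cond.append(np.mean(vals))
        se = np.sqrt(per_cond[0] / 5)
        assert abs(per_cond[1] - per_cond[0]) < 3 * se

    def test_identical_landscape_when_multipliers_one(self, flat_genome):
        model = single_site_model("chr1", 50_000, 1000.0, drug_multiplier=1.0)
        a, ta = simulate_library(flat_genome, model, COND, 3000, seed=9)
        b, tb = simulate_library(flat_genome, model, COND_DRUG, 3000, seed=9)
        assert [(f.chrom, f.start, f.end) for f in a] == [
            (f.chrom, f.start, f.end) for f in b
        ]
        assert ta.expected_counts().tolist() == tb.expected_counts().tolist()


class TestInputLibrary:
    def test_empty_and_seed_sensitivity(self, flat_genome):
        assert simulate_input_library(flat_genome, COND, 0, seed=1) == []
        a = simulate_input_library(flat_genome, COND, 1000, seed=1)
        b = simulate_input_library(flat_genome, COND, 1000, seed=2)
        assert {(f.start, f.end) for f in a} != {(f.start, f.end) for f in b}

    def test_uncorrelated_with_binding_sites(self, flat_genome):
        """Input fragment counts around sites carry no signal: their
        correlation with site weights is statistically indistinguishable
        from zero."""
        rng = np.random.default_rng(10)
        positions = np.arange(5_000, 95_000, 3_000)
        weights = rng.uniform(10, 1000, size=len(positions))
        frags = simulate_input_library(flat_genome, COND, 10_000, seed=11)
        counts = [footprint_count(frags, "chr1", p - 300, p + 300) for p in positions]
        r, p = stats.pearsonr(counts, weights)
        assert p > 0.01


class TestMultimappers:
    def test_flagging_and_uniform_reassignment(self, spread_repeat_genome):
        fam = spread_repeat_genome.repeat_families[0]
        chrom, cs, ce = fam.copies[0]
        model = single_site_model(chrom, (cs + ce) // 2, 1e6, width=100,
                                  background_rate=1e-6)
        frags, _ = simulate_library(spread_repeat_genome, model, COND, 2000, seed=12)
        multi = [f for f in frags if f.multiplicity > 1]
        assert len(multi) == 2000
        assert all(f.mapq == 0 and f.multiplicity == 10 for f in multi)
        # every reassigned fragment overlaps some copy of the family
        for f in multi:
            assert any(f.start < e and f.end > s for _, s, e in fam.copies)

    def test_assignment_subseed_changes_copies_not_totals(self, spread_repeat_genome):
        fam = spread_repeat_genome.repeat_families[0]
        chrom, cs, ce = fam.copies[0]
        model = single_site_model(chrom, (cs + ce) // 2, 1e6, width=100,
                                  background_rate=1e-6)
        per_copy = []
        for aseed in (1, 2):
            frags, _ = simulate_library(
                spread_repeat_genome, model, COND, 1000, seed=13,
                assignment_seed=aseed,
            )
            counts = [
                sum(1 for f in frags if f.start < e and f.end > s)
                for _, s, e in fam.copies
            ]
            per_copy.append(counts)
            assert sum(counts) == 1000
        assert per_copy[0] != per_copy[1]
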
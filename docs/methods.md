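# Methods

## The model

The package analyses *fragment-level* ChIP-seq data: each sequenced molecule
is an aligned interval (0-based, half-open) carrying a MAPQ and an alignment
multiplicity. Everything upstream of that — base calling, trimming, short-read
alignment — is outside the contract; everything downstream (coverage, peaks,
effect sizes, profiles, repeat quantification) is implemented here.

The simulator's occupancy model is a two-component mixture for fragment
centers:

* a uniform background with relative mass `background_rate × genome_length`
  (non-specific pull-down);
* point sources: each site *i* contributes mass *w<sub>i</sub>* spread as a
  top-hat of width *w* around the site position (fragment-scale resolution;
  no finer site-shape model is warranted at 250–500 bp fragments).

Fragment lengths are uniform on [250, 500] bp, the shearing window of the
emulated protocol; fragments running past a chromosome end are truncated.
Exactly `n_fragments` records are emitted per library (counts are multinomial
over the mixture), and replicate libraries are pooled by concatenation before
analysis, mirroring a design in which four ChIP replicates are pooled into
two sequencing replicates.

Drug exposure multiplies every site weight by `drug_multiplier`, except sites
in the protection map, which use `protected_multiplier` instead. A multiplier
of 1 for both leaves the ±drug landscapes identical, which is the null the
tests lean on. A `protected_multiplier` below 1 encodes a protector that
actively removes the factor at its own sites.

**Normalization caveat.** Because each library has a fixed size, mixture
shares renormalize: if unprotected sites double their mass, every other
component's *share* shrinks by the total-mass ratio M. Per-million
normalization therefore cannot see a uniform global gain (genome-scope d ≈ 0
by construction) and protected sites appear to *lose* a little signal under
drug. The default scenarios keep the drug-responsive site mass a small
fraction of the library, so this systematic shift stays well inside the
sampling noise of the protected stratum; it is the same spike-in-free
limitation real ChIP-seq has.

**Multimappers.** Fragments overlapping a repeat-family copy are flagged
(MAPQ 0, multiplicity = copy count) and re-assigned uniformly at random among
the family's copies, emulating an aligner's arbitrary placement of a read
that maps equally well to identical copies. Re-assignment consumes a
dedicated sub-stream (`assignment_seed`), so *family totals* are invariant to
that seed while per-copy placement is not — the property the repeat analyses
rely on. A fragment is attributed to the copy it overlaps most (ties to the
leftmost). Sequence-level effects (base errors, partial homology,
mappability gradients) are not modelled: repeat identity is declared by the
annotation, and copies within a family are identical by construction.

## Coverage and peak calling

`compute_coverage` produces two track flavours: base-pair-overlap mass per
bin (used, per-million normalized, for enrichment values) and integer
midpoint counts per bin (used for peak calling, where a Poisson model is
exact). Filtered mode keeps records with MAPQ ≥ 1, i.e. it excludes exactly
the multimapping reads; unfiltered mode counts every record once at its
assigned location. Both are normalized by the same library size so filtered ≤
unfiltered holds bin-wise.

The caller slides a 300-bp window (stride = bin, default 50 bp) and tests the
observed count against λ = max(genome-wide rate, rates in 1-kb and 10-kb
windows centered on the test window, scaled to window length). With a control
track the local rates come from the control (scaled to the IP depth); with no
control, only local windows ≥ 5 kb are estimated from the IP itself (smaller
ones would mask a peak with its own signal), and an explicit numeric
background rate is trusted as-is. P-values are Poisson upper tails,
corrected by Benjamini–Hochberg across all windows; windows with q ≤ 0.05
and fold ≥ 2 are kept and merged when closer than 200 bp. The summit is the
maximum of 3-bin-smoothed coverage within the peak, ties broken leftmost.
A zero-depth IP yields an empty peak set; an all-zero control falls back to
the IP genome-wide mean with a warning. Defaults (window 300 bp ≈ fragment
scale, q 0.05, fold 2, merge 200 bp) were fixed at design time and validated
by the recovery/specificity scenarios: ≥95% recovery of 10-fold sites and
≤1 false peak per 10 Mb on flat libraries.

## Effect sizes

Cohen's d uses the pooled sample SD with n−1 variances; the sign convention
is mean(A) − mean(B). Zero pooled SD with equal means is d = 0; with unequal
means it is signalled with a dedicated exception rather than ±inf, so callers
cannot silently propagate an unbounded effect. Labels follow the 0.2 / 0.5 /
0.8 convention.

"Common peaks" between two samples are the connected components of the union
of both peak sets, chained wherever consecutive intervals overlap the growing
component by ≥ `min_overlap` (default 1 bp; this is the closest executable
definition of an intersect-based common-region workflow). Each component is
scored by its mean per-bin per-million enrichment in each sample, and d is
computed across components. Genome scope pairs per-bin values over all bins
with signal in either sample; which aggregation a published genome-wide
comparison used is generally underdetermined, and per-bin is this package's
definition. Stratification splits common regions by ≥1 bp overlap with a mask
peak set (e.g. the protector's peaks); the partition is exhaustive and
exclusive.

## Metagene profiles

For each gene the window −500…+1500 bp around the TSS (annotated start on +,
end on −; no UTR model) is cut into 50-bp strand-oriented bins; the per-bin
statistic is the fraction of genes with ≥1 overlapping peak. The 95% band is
a percentile bootstrap over genes (default 300–500 resamples), implemented
with multinomial weights for vectorization; its empirical coverage on
Bernoulli indicators is 95% ± ~1% at the scales used. `genome_expected`
normalization divides by the chance that a random bin-sized window overlaps
any peak, approximating genome length by the peak span extent; the default
`raw_fraction` mode reports the plain fraction, bounded by the band in
[0, 1].

## Repeats and association

Repeat families are quantified per copy (copies are the natural replicates of
a family; per-family totals are also reported) under both counting modes, and
conditions compared by d over per-copy unfiltered enrichment — undefined and
signalled for single-copy families. Peak category fractions allow multi-class
overlap, so fractions can sum to >1; peaks touching no annotation count as
"unannotated".

Peaks are assigned to the gene containing their summit, else the gene with
the largest body overlap, else the nearest gene within 1 kb (strand-aware
upstream/downstream; equidistant ties go to the lower-coordinate gene; a
peak exactly abutting a gene shares no base with it, so non-overlap distances
are floored at 1 bp to keep distance 0 synonymous with "within gene").
Expression quantiles are equal-count bins (sizes differ by ≤1 gene; ties
broken by gene id), and the within-gene counts across bins sum exactly to the
number of within-gene links.

## Default study conditions

The pipeline's default configuration is the package's rendition of the
emulated experiment, chosen once: a 2 × 1 Mb genome; three tRNA families of
10, 8 and 6 copies; 400 factor-1 sites holding 25% of the library mass
(log-normal weights, CV 0.35), half of them inside gene bodies sampled
proportionally to log-normal expression; drug multiplier 1.35 in the wild
type and 2.0 in the deletion, with the 30% protector-bound sites (plus all
repeat-copy sites) overridden to 0.7 in the wild type — a protector that
actively strips the trapped enzyme; factor 2 with multiplier 1.0 (its total
binding is drug-independent) but a drug-dependent relocation of 20% of its
sites onto tRNA copies, against a ~4% baseline confined to the smallest
family. Libraries are 2 × 150,000 fragments per condition. Validation
scenarios use 2 × 10⁵-fragment libraries and 500–650 sites on ~3 Mb, sizes at
which a null Peaks-scope d has a standard error of ~0.06 and the scenario
outcomes are stable across seeds.

Because relocated repeat fragments scatter uniformly over a family, a family
is effectively all-or-nothing at peak level: occupying *m* of *k* copies
gives every copy *m/k* of a site's signal. The relocation scenarios therefore
fill whole families, which is also why the baseline tRNA presence is confined
to the smallest family.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the comparative design — paired
conditions, replicate pooling, point-source binding, fragment-scale
resolution, protected sites, identical repeat copies — with uniform
background and no PCR duplicates, GC or chromatin-accessibility bias,
fragment-length/site interactions, or partial repeat homology. Passing tests
therefore demonstrate that the statistics recover programmed truths under the
stated noise model, not that any particular biological dataset would yield
the same numbers; printed effect sizes from the real experiment this design
emulates are reproducible only from the deposited sequencing data, which this
package deliberately does not require.

## Numerical choices

All coordinates 0-based half-open; BH via `scipy.stats.false_discovery_control`;
Poisson tails via `scipy.stats.poisson.sf` with q floored at 1e-300 before
−log10; lognormal weight parameterisation by mean and CV
(σ² = ln(1+CV²)); every stage seeded from a single run seed through
`numpy.random.SeedSequence` children (kept below 2³¹); determinism is tested
byte-for-byte on serialized outputs and manifest checksums.
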
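# occudiff

Comparative ChIP-seq occupancy analysis for the question: *when a drug traps a
chromatin enzyme on DNA, where does its binding increase, and which loci are
protected?* The motivating system is a type II topoisomerase (Top2-like
"factor 1") poisoned by an intercalating drug, and a Snf2-family remodeller
(Uls1-like "factor 2") that strips the trapped enzyme from its own binding
sites — including heavily duplicated tRNA genes that standard unique-read
analyses cannot see.

The package is organised as an analysis project: every computation lives in
the library under `src/occudiff/`, the numbered scripts under `analysis/`
drive the narrative, and `scripts/acceptance.py` recomputes the headline
numbers from scratch.

## What it computes

Given fragment-level alignments (BED6 with MAPQ and a `read/k` multiplicity
convention) or libraries simulated from a programmable ground truth:

* **Peak calling** — sliding 300-bp windows against a Poisson background
  whose rate λ is the maximum of the genome-wide rate and local estimates in
  1 kb / 10 kb windows; windows with Benjamini–Hochberg *q* ≤ 0.05 and fold
  ≥ 2 are merged into peaks (narrowPeak output).
* **Effect-size comparison** — for two samples, *common peaks* are the union
  components containing a peak from each; per-region per-million enrichment
  is compared with Cohen's

  *d* = (x̄₁ − x̄₂) / s_p,  s_p² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2),

  with |d| ≥ 0.2 / 0.5 / 0.8 read as small / medium / large; genome-wide
  (per-bin) and common-peak scopes are both reported, and common regions can
  be stratified by overlap with another factor's peaks.
* **TSS metagene profiles** — per-bin probability that a gene carries a peak,
  strand-oriented around the TSS, with a percentile-bootstrap 95% band.
* **Repeat families with multimappers** — per-copy signal under *filtered*
  (unique reads) and *unfiltered* (all reads, once each) counting; Cohen's d
  over per-copy enrichment between conditions; fraction of peaks per
  annotation class.
* **Peak–gene association** — summit-based assignment and within-gene peak
  counts across gene-expression quantiles.
* **Simulation** — toy genomes with multi-copy tRNA families; fragment
  libraries (uniform 250–500 bp lengths) drawn from a background + point-site
  mixture with a drug multiplier, protected sites, and uniform re-assignment
  of repeat-overlapping fragments among family copies.

## Worked example

Run the full simulated experiment (six conditions: factor 1 in WT and
protector-deletion genotypes ± drug, factor 2 in WT ± drug; two pooled
replicates of 150,000 fragments each on a 2-Mb two-chromosome genome):

```sh
python analysis/01_simulate.py
python analysis/02_call_peaks.py
python analysis/03_effect_sizes.py
```

`03_effect_sizes.py` prints:

```
f1_wt_drug_vs_untreated: Peaks d = +0.245 (small, 360 common regions); Genome d = -0.001
f1_del_drug_vs_untreated: Peaks d = +1.131 (large, 365 common regions); Genome d = +0.001
f1_del_vs_wt_drug: Peaks d = +0.812 (large, 360 common regions); Genome d = +0.001
f2_drug_vs_untreated: Peaks d = +0.307 (small, 96 common regions); Genome d = +0.001
protector-bound regions (n=91): d = -0.752 (medium)
protector-unbound regions (n=269): d = +0.615 (medium)
```

Reading: the drug increases factor-1 occupancy at common peaks modestly in
the wild type (d = +0.25) and strongly when the protector is deleted
(d = +1.13); under drug the deletion strain carries more factor 1 than the
wild type (d = +0.81). Stratifying the wild-type drug response shows the
increase is confined to protector-*unbound* regions, while protector-bound
regions actually lose signal — the protector removes the trapped enzyme.
Genome-scope d is ≈ 0 because per-million normalization cancels any uniform
gain; only the redistribution into peaks is observable.

`analysis/05_repeats.py` then shows the repeat story (visible only with
unfiltered reads): the protector's tRNA-family signal rises sharply under
drug (d ≈ +4), the trapped enzyme's tRNA signal *falls* in the wild type
(d ≈ −1.0) but rises in the deletion (d ≈ +1.1), and the fraction of
protector peaks at tRNA genes jumps from ~5% to ~20%.

The same machinery works on real data through the CLI:

```sh
occudiff callpeaks --fragments ip.bed --chrom-sizes genome.sizes --out ip.narrowPeak
occudiff compare --fragments-a a.bed --fragments-b b.bed \
    --peaks-a a.narrowPeak --peaks-b b.narrowPeak \
    --chrom-sizes genome.sizes --out comparison.tsv
occudiff all --config run.yaml --outdir out/
```

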
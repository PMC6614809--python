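"""Compare occupancy between conditions with Cohen's d.

The four headline contrasts (factor 1 WT +/- drug; deletion +/- drug; WT vs
deletion under drug; factor 2 +/- drug) at Genome and common-Peaks scope,
plus the stratification of the WT drug response into protector-bound and
unbound regions.  The expected pattern: a modest drug effect in the wild
type, a much larger one in the deletion, and no effect at protector-bound
regions.
"""

from common import CONFIG, RESULTS, ensure_dirs, library_bed, peaks_file

from occudiff.diffocc import (
    cohens_d,
    compare_samples,
    stratify_by_overlap,
    write_comparison_table,
)
from occudiff.interval_io import compute_coverage, read_chrom_sizes, read_fragment_bed
from occudiff.peaks import read_narrowpeak

CONTRASTS = {
    "f1_wt_drug_vs_untreated": ("f1_wt_drug", "f1_wt_untreated"),
    "f1_del_drug_vs_untreated": ("f1_del_drug", "f1_del_untreated"),
    "f1_del_vs_wt_drug": ("f1_del_drug", "f1_wt_drug"),
    "f2_drug_vs_untreated": ("f2_wt_drug", "f2_wt_untreated"),
}


def main() -> None:
    ensure_dirs()
    cfg = CONFIG
    sizes = read_chrom_sizes(RESULTS / "chrom.sizes")
    tracks = {}

    def track(name):
        if name not in tracks:
            frags = read_fragment_bed(library_bed(name), sizes)
            tracks[name] = compute_coverage(
                frags, sizes, cfg.enrich_bin, "filtered", cfg.mapq_min
            ).per_million()
        return tracks[name]

    rows = {}
    results = {}
    for cname, (a, b) in CONTRASTS.items():
        res = compare_samples(track(a), track(b), read_narrowpeak(peaks_file(a)),
                              read_narrowpeak(peaks_file(b)), cfg.min_overlap)
        results[cname] = res
        rows[f"{cname}/Genome"] = res.genome
        rows[f"{cname}/Peaks"] = res.peaks
        d = res.peaks.d if res.peaks else float("nan")
        print(f"{cname}: Peaks d = {d:+.3f} ({res.peaks.label if res.peaks else '-'}, "
              f"{len(res.pairs)} common regions); Genome d = {res.genome.d:+.3f}")

    mask = read_narrowpeak(peaks_file("f2_wt_drug"))
    bound, unbound = stratify_by_overlap(
        results["f1_wt_drug_vs_untreated"].pairs, mask, cfg.min_overlap
    )
    for label, subset in (("bound", bound), ("unbound", unbound)):
        es = (cohens_d([p.value_a for p in subset], [p.value_b for p in subset])
              if len(subset) >= 2 else None)
        rows[f"f1_wt_drug_vs_untreated/{label}"] = es
        if es:
            print(f"protector-{label} regions (n={len(subset)}): d = {es.d:+.3f} "
                  f"({es.label})")
    write_comparison_table(rows, RESULTS / "effect_sizes.tsv")
    print(f"\ntable -> {RESULTS / 'effect_sizes.tsv'}")


if __name__ == "__main__":
    main()
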
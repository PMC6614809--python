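"""Call enrichment peaks for every simulated condition.

Reads the fragment libraries from 01, builds raw midpoint-count tracks
(standard filtered counting; additionally unfiltered counting for the
protector factor so repeat loci are visible), and calls peaks against the
local Poisson background.  Writes narrowPeak files and a peak-count table —
the drug's first visible signature is the change in peak numbers.
"""

from common import CONFIG, CONDITIONS, RESULTS, ensure_dirs, library_bed, peaks_file

from occudiff.interval_io import compute_coverage, read_chrom_sizes, read_fragment_bed
from occudiff.peaks import call_peaks, write_narrowpeak


def main() -> None:
    ensure_dirs()
    cfg = CONFIG
    sizes = read_chrom_sizes(RESULTS / "chrom.sizes")
    rows = []
    for name in CONDITIONS:
        frags = read_fragment_bed(library_bed(name), sizes)
        modes = ["filtered"] + (["unfiltered"] if name.startswith("f2") else [])
        counts = {}
        for mode in modes:
            track = compute_coverage(frags, sizes, cfg.call_bin, mode,
                                     cfg.mapq_min, stat="midpoint")
            ps = call_peaks(track, None, cfg.window, cfg.local_windows,
                            cfg.q_max, cfg.merge_dist, cfg.min_fold)
            write_narrowpeak(ps, peaks_file(name, mode))
            counts[mode] = len(ps)
        rows.append((name, counts))
        print(f"{name}: " + ", ".join(f"{m}={c} peaks" for m, c in counts.items()))
    with open(RESULTS / "peak_counts.tsv", "w") as fh:
        fh.write("condition\tmode\tn_peaks\n")
        for name, counts in rows:
            for mode, c in counts.items():
                fh.write(f"{name}\t{mode}\t{c}\n")
    drug = dict(rows)["f1_wt_drug"]["filtered"]
    ref = dict(rows)["f1_wt_untreated"]["filtered"]
    print(f"\nfactor-1 peak count WT untreated -> drug: {ref} -> {drug}")


if __name__ == "__main__":
    main()
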
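"""Repeat-family signal with multimapping reads, and peak-category fractions.

Standard ChIP-seq analyses discard reads that map to multiple genomic
locations, which makes multi-copy loci (duplicated tRNA genes, rDNA,
telomeres, Ty elements) invisible.  These operations quantify factor signal
over a repeat family under both counting modes — *filtered* (unique reads
only, MAPQ >= threshold) and *unfiltered* (every read counted once at its
assigned copy) — and compare conditions with Cohen's d over per-copy values,
the copies being the natural replicates of a repeat family.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .diffocc import EffectSize, cohens_d
from .interval_io import FragmentRecord, fragments_to_arrays
from .peaks import PeakSet
from .synthetic_data import Condition, GeneModel, GenomeSpec, RepeatFamily

__all__ = [
    "FamilySignal",
    "family_signal",
    "compare_family_conditions",
    "category_fractions",
    "write_family_report",
    "write_category_fractions",
]


@dataclass
class FamilySignal:
    family_id: str
    repeat_class: str
    n_copies: int
    unfiltered_enrichment: np.ndarray  # per-copy per-million mean coverage
    filtered_enrichment: np.ndarray
    unfiltered_counts: np.ndarray      # per-copy overlapping-fragment counts (int)
    filtered_counts: np.ndarray
    condition: Condition | None = None

    @property
    def unfiltered_total(self) -> int:
        return int(self.unfiltered_counts.sum())

    @property
    def filtered_total(self) -> int:
        return int(self.filtered_counts.sum())


def _copy_overlap_stats(
    starts: np.ndarray, ends: np.ndarray, copy: tuple[str, int, int]
) -> tuple[int, float]:
    """(#fragments overlapping the copy, total overlapping base pairs)."""
    _, cs, ce = copy
    ov = np.minimum(ends, ce) - np.maximum(starts, cs)
    hit = ov > 0
    return int(hit.sum()), float(ov[hit].sum())


def family_signal(
    frags: Sequence[FragmentRecord],
    family: RepeatFamily,
    genome: GenomeSpec,
    mapq_min: int = 1,
    condition: Condition | None = None,
) -> FamilySignal:
    """Per-copy enrichment of a repeat family under both counting modes.

    Enrichment is mean per-base coverage over the copy, per million library
    fragments.  Both modes are normalized by the same total library size so
    that filtered <= unfiltered holds per copy by construction (the filtered
    mode can only remove fragments).  An empty library gives zero signal.
    """
    sizes = genome.chrom_sizes
    for chrom, start, end in family.copies:
        if chrom not in sizes or start < 0 or end > sizes[chrom]:
            raise ValueError(f"family copy {chrom}:{start}-{end} outside genome")
    n = family.n_copies
    unf_counts = np.zeros(n, dtype=np.int64)
    fil_counts = np.zeros(n, dtype=np.int64)
    unf_enr = np.zeros(n, dtype=float)
    fil_enr = np.zeros(n, dtype=float)
    library_size = len(frags)
    if library_size:
        arrays = fragments_to_arrays(frags)
        scale = 1e6 / library_size
        for ci, copy in enumerate(family.copies):
            chrom, cs, ce = copy
            if chrom not in arrays:
                continue
            starts, ends, mapqs = arrays[chrom]
            cnt, mass = _copy_overlap_stats(starts, ends, copy)
            unf_counts[ci] = cnt
            unf_enr[ci] = mass / (ce - cs) * scale
            keep = mapqs >= mapq_min
            cnt_f, mass_f = _copy_overlap_stats(starts[keep], ends[keep], copy)
            fil_counts[ci] = cnt_f
            fil_enr[ci] = mass_f / (ce - cs) * scale
    return FamilySignal(
        family_id=family.family_id,
        repeat_class=family.repeat_class,
        n_copies=n,
        unfiltered_enrichment=unf_enr,
        filtered_enrichment=fil_enr,
        unfiltered_counts=unf_counts,
        filtered_counts=fil_counts,
        condition=condition,
    )


def compare_family_conditions(sig_a: FamilySignal, sig_b: FamilySignal) -> EffectSize:
    """Cohen's d over per-copy unfiltered enrichment between two conditions."""
    if sig_a.family_id != sig_b.family_id or sig_a.n_copies != sig_b.n_copies:
        raise ValueError("family signals must come from the same family")
    if sig_a.n_copies < 2:
        raise ValueError(
            f"family {sig_a.family_id!r} has < 2 copies: per-copy effect size undefined"
        )
    return cohens_d(sig_a.unfiltered_enrichment, sig_b.unfiltered_enrichment)


def category_fractions(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    min_overlap: int = 1,
) -> dict[str, float]:
    """Fraction of peaks overlapping each annotated gene class.

    A peak may overlap several classes, so fractions can sum to more than 1;
    peaks overlapping no annotated feature contribute to ``"unannotated"``.
    An empty peak set is an error (the fraction is undefined).
    """
    if len(peaks) == 0:
        raise ValueError("category_fractions is undefined for an empty peak set")
    by_chrom: dict[str, dict[str, list[tuple[int, int]]]] = {}
    classes: set[str] = set()
    for g in genes:
        classes.add(g.gene_class)
        by_chrom.setdefault(g.chrom, {}).setdefault(g.gene_class, []).append(
            (g.start, g.end)
        )
    arrays = {
        chrom: {
            k: (np.array([s for s, _ in iv]), np.array([e for _, e in iv]))
            for k, iv in kls.items()
        }
        for chrom, kls in by_chrom.items()
    }
    hits = {k: 0 for k in classes}
    unannotated = 0
    for p in peaks:
        any_hit = False
        chrom_classes = arrays.get(p.chrom, {})
        for k, (starts, ends) in chrom_classes.items():
            ov = np.minimum(ends, p.end) - np.maximum(starts, p.start)
            if (ov >= min_overlap).any():
                hits[k] += 1
                any_hit = True
        if not any_hit:
            unannotated += 1
    total = len(peaks)
    out = {k: hits[k] / total for k in sorted(hits)}
    out["unannotated"] = unannotated / total
    return out


def write_family_report(signals: Sequence[FamilySignal], path: str | Path) -> None:
    """Per-copy tab-separated family report (both counting modes)."""
    with open(path, "w") as fh:
        fh.write(
            "family_id\tclass\tcopy\tunfiltered_count\tfiltered_count\t"
            "unfiltered_enrichment\tfiltered_enrichment\n"
        )
        for sig in signals:
            for ci in range(sig.n_copies):
                fh.write(
                    f"{sig.family_id}\t{sig.repeat_class}\t{ci + 1}\t"
                    f"{sig.unfiltered_counts[ci]}\t{sig.filtered_counts[ci]}\t"
                    f"{sig.unfiltered_enrichment[ci]:.6g}\t"
                    f"{sig.filtered_enrichment[ci]:.6g}\n"
                )
            fh.write(
                f"{sig.family_id}\t{sig.repeat_class}\ttotal\t"
                f"{sig.unfiltered_total}\t{sig.filtered_total}\t"
                f"{sig.unfiltered_enrichment.sum():.6g}\t"
                f"{sig.filtered_enrichment.sum():.6g}\n"
            )


def write_category_fractions(fractions: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in fractions.items():
            fh.write(f"{k}\t{v:.6g}\n")
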
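"""Differential occupancy by effect size.

The comparative analysis at the heart of the package: identify *common peaks*
between two samples (regions called as enriched in both), quantify per-region
enrichment in each, and summarize the difference with Cohen's d — the
standardized difference of two means in units of pooled standard deviation,
with |d| >= 0.2 / 0.5 / 0.8 conventionally read as small / medium / large.
Effect sizes rather than p-values are the right summary here because the
number of paired observations (genomic bins, peak regions) is large enough to
make almost any difference "significant".

Two scopes are computed: *Genome* (paired per-bin enrichment over all bins
with signal in either sample — the genome-wide aggregate) and *Peaks* (paired
per-region enrichment over common peak regions, where binding differences
concentrate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .interval_io import CoverageTrack
from .peaks import PeakSet

__all__ = [
    "PeakPair",
    "EffectSize",
    "EnrichmentSummary",
    "ComparisonResult",
    "UndefinedEffectSizeError",
    "cohens_d",
    "effect_label",
    "match_common_peaks",
    "region_enrichment",
    "compare_samples",
    "stratify_by_overlap",
    "write_comparison_table",
]


class UndefinedEffectSizeError(ValueError):
    """Raised when the pooled SD is zero but the means differ (infinite effect)."""


@dataclass(frozen=True)
class PeakPair:
    """A common-peak region with its enrichment in the two samples."""

    chrom: str
    start: int
    end: int
    value_a: float = math.nan
    value_b: float = math.nan

    @property
    def region(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class EffectSize:
    d: float
    mean_a: float
    mean_b: float
    sd_pooled: float
    n_a: int
    n_b: int
    label: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"d={self.d:+.3f} ({self.label}; n={self.n_a},{self.n_b})"


@dataclass
class EnrichmentSummary:
    """Per-unit enrichment vector for one sample at one scope."""

    scope: str  # "Genome" | "Peaks"
    values: np.ndarray
    sample: str = ""


@dataclass
class ComparisonResult:
    genome: EffectSize
    peaks: EffectSize | None  # None when the samples share no common peaks
    pairs: list[PeakPair]


def effect_label(d: float) -> str:
    """Conventional qualitative label for |d|: >=0.8 large, >=0.5 medium, >=0.2 small."""
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.2:
        return "small"
    return "negligible"


def cohens_d(x, y) -> EffectSize:
    """Cohen's d with the pooled sample standard deviation.

    d = (mean_x - mean_y) / s_p,  s_p^2 = ((n_x-1)s_x^2 + (n_y-1)s_y^2) / (n_x+n_y-2)

    Positive d means mean_x > mean_y.  Both inputs need n >= 2.  When the
    pooled SD is zero, equal means give d = 0 (label "negligible"); unequal
    means raise :class:`UndefinedEffectSizeError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x, n_y = len(x), len(y)
    if n_x < 2 or n_y < 2:
        raise ValueError("cohens_d needs at least 2 observations per group")
    mean_x, mean_y = float(np.mean(x)), float(np.mean(y))
    var_x = float(np.var(x, ddof=1))
    var_y = float(np.var(y, ddof=1))
    sp = math.sqrt(((n_x - 1) * var_x + (n_y - 1) * var_y) / (n_x + n_y - 2))
    if sp == 0.0:
        if mean_x == mean_y:
            return EffectSize(0.0, mean_x, mean_y, 0.0, n_x, n_y, "negligible")
        raise UndefinedEffectSizeError(
            "pooled SD is zero but means differ: effect size is unbounded"
        )
    d = (mean_x - mean_y) / sp
    return EffectSize(d, mean_x, mean_y, sp, n_x, n_y, effect_label(d))


def match_common_peaks(a, b, min_overlap: int = 1) -> list[PeakPair]:
    """Merge the two peak sets into union components containing peaks from both.

    Intervals are chained into a component while each next interval overlaps
    the growing union by at least ``min_overlap`` bases; components holding at
    least one peak from each sample become :class:`PeakPair` regions (their
    enrichment values are filled in by :func:`compare_samples`).

    Accepts :class:`~occudiff.peaks.PeakSet` objects or plain iterables of
    peaks (the latter may contain mutually overlapping intervals).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    tagged: dict[str, list[tuple[int, int, int]]] = {}
    for src, ps in ((0, a), (1, b)):
        for p in ps:
            tagged.setdefault(p.chrom, []).append((p.start, p.end, src))
    pairs: list[PeakPair] = []
    for chrom in sorted(tagged):
        ivs = sorted(tagged[chrom])
        i = 0
        while i < len(ivs):
            s, e, src = ivs[i]
            sources = {src}
            j = i + 1
            while j < len(ivs) and ivs[j][0] <= e - min_overlap:
                e = max(e, ivs[j][1])
                sources.add(ivs[j][2])
                j += 1
            if sources == {0, 1}:
                pairs.append(PeakPair(chrom, s, e))
            i = j
    return pairs


def region_enrichment(track: CoverageTrack, regions) -> np.ndarray:
    """Mean per-bin normalized coverage over each region.

    Partially overlapped bins are weighted by their base-pair overlap, so the
    value is the per-base mean of the binned track over the region.  Requires
    a per-million track; rejects empty or out-of-genome regions.
    """
    if track.norm != "per_million":
        raise ValueError("region_enrichment requires a per-million normalized track")
    out = np.empty(len(regions), dtype=float)
    bs = track.bin_size
    for i, region in enumerate(regions):
        chrom, start, end = (
            (region.chrom, region.start, region.end)
            if hasattr(region, "chrom")
            else region
        )
        if chrom not in track.counts:
            raise ValueError(f"region on unknown chromosome {chrom!r}")
        if start >= end:
            raise ValueError(f"zero-length region {chrom}:{start}-{end}")
        if start < 0 or end > track.chrom_sizes[chrom]:
            raise ValueError(f"region {chrom}:{start}-{end} outside genome")
        counts = track.counts[chrom]
        b0, b1 = start // bs, -(-end // bs)
        edges = np.arange(b0, b1 + 1) * bs
        weights = np.minimum(edges[1:], end) - np.maximum(edges[:-1], start)
        out[i] = float(np.dot(counts[b0:b1], weights) / (end - start))
    return out


def compare_samples(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    min_overlap: int = 1,
) -> ComparisonResult:
    """Effect-size comparison of two samples at Genome and Peaks scope.

    Genome scope pairs per-bin per-million enrichment across all bins with
    nonzero coverage in either sample; Peaks scope pairs per-region enrichment
    over the samples' common peaks.  With no common peaks the Peaks entry is
    ``None`` and Genome scope is still computed.
    """
    ta, tb = track_a.per_million(), track_b.per_million()
    if ta.bin_size != tb.bin_size or set(ta.chrom_sizes) != set(tb.chrom_sizes):
        raise ValueError("tracks must share genome and bin size")
    xs, ys = [], []
    for chrom in ta.counts:
        va, vb = ta.counts[chrom], tb.counts[chrom]
        mask = (va > 0) | (vb > 0)
        xs.append(va[mask])
        ys.append(vb[mask])
    genome_d = cohens_d(np.concatenate(xs), np.concatenate(ys))

    pairs = match_common_peaks(peaks_a, peaks_b, min_overlap=min_overlap)
    if not pairs:
        return ComparisonResult(genome=genome_d, peaks=None, pairs=[])
    vals_a = region_enrichment(ta, pairs)
    vals_b = region_enrichment(tb, pairs)
    filled = [
        PeakPair(p.chrom, p.start, p.end, float(a), float(b))
        for p, a, b in zip(pairs, vals_a, vals_b)
    ]
    peaks_d = cohens_d(vals_a, vals_b) if len(pairs) >= 2 else None
    return ComparisonResult(genome=genome_d, peaks=peaks_d, pairs=filled)


def stratify_by_overlap(
    pairs: list[PeakPair], mask: PeakSet, min_overlap: int = 1
) -> tuple[list[PeakPair], list[PeakPair]]:
    """Split common-peak regions into (bound, unbound) by overlap with a mask.

    A region is *bound* iff it overlaps at least one mask peak by at least
    ``min_overlap`` bases.  The partition is exhaustive and exclusive; an
    empty mask leaves everything unbound.
    """
    by_chrom = mask.by_chrom()
    bound: list[PeakPair] = []
    unbound: list[PeakPair] = []
    for p in pairs:
        hit = False
        if p.chrom in by_chrom:
            starts, ends = by_chrom[p.chrom]
            overlap = np.minimum(ends, p.end) - np.maximum(starts, p.start)
            hit = bool((overlap >= min_overlap).any())
        (bound if hit else unbound).append(p)
    return bound, unbound


def write_comparison_table(rows: dict[str, EffectSize | None], path: str | Path) -> None:
    """Tab-separated effect-size table: scope, n, means, pooled SD, d, label."""
    with open(path, "w") as fh:
        fh.write("scope\tn_a\tn_b\tmean_a\tmean_b\tsd_pooled\td\tlabel\n")
        for scope, es in rows.items():
            if es is None:
                fh.write(f"{scope}\t0\t0\tnan\tnan\tnan\tnan\tempty\n")
            else:
                fh.write(
                    f"{scope}\t{es.n_a}\t{es.n_b}\t{es.mean_a:.6g}\t{es.mean_b:.6g}\t"
                    f"{es.sd_pooled:.6g}\t{es.d:.6g}\t{es.label}\n"
                )
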
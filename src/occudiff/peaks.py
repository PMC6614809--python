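"""Enrichment peak calling against a local Poisson background.

A stand-in for a conventional ChIP-seq peak caller, small enough to test
exhaustively: fragment counts in a sliding window are compared with a Poisson
null whose rate is the *maximum* of the genome-wide background rate and rates
estimated in larger windows centered on the same point (mirroring the local
lambda idea that protects against locally elevated background).  Windows
passing a Benjamini-Hochberg q-value cutoff and a minimum fold enrichment are
merged into peaks.

The IP (and control) track must be a *raw midpoint-count* track
(``CoverageTrack(stat="midpoint", norm="raw")``): counts are integers, so the
Poisson upper tail is exact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .interval_io import CoverageTrack
from .synthetic_data import Condition

__all__ = ["Peak", "PeakSet", "call_peaks", "write_narrowpeak", "read_narrowpeak"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    score: float  # -log10(q)
    fold_enrichment: float
    neglog10_p: float = 0.0

    def __post_init__(self) -> None:
        if not self.start <= self.summit < self.end:
            raise ValueError(f"summit {self.summit} outside peak {self.start}-{self.end}")
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if self.fold_enrichment <= 0:
            raise ValueError("fold_enrichment must be > 0")


@dataclass
class PeakSet:
    """Sorted, non-overlapping called peaks plus the sample they came from."""

    peaks: list[Peak]
    condition: Condition | None = None
    _by_chrom: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        keyed = [(p.chrom, p.start, p.end) for p in self.peaks]
        if keyed != sorted(keyed):
            raise ValueError("peaks must be sorted by (chrom, start)")
        for a, b in zip(self.peaks, self.peaks[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError("peaks must not overlap")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Cached per-chromosome (starts, ends) arrays for interval queries."""
        if not self._by_chrom:
            grouped: dict[str, list[tuple[int, int]]] = {}
            for p in self.peaks:
                grouped.setdefault(p.chrom, []).append((p.start, p.end))
            self._by_chrom = {
                c: (np.array([s for s, _ in iv]), np.array([e for _, e in iv]))
                for c, iv in grouped.items()
            }
        return self._by_chrom


def _sliding_sums(counts: np.ndarray, w: int) -> np.ndarray:
    """Sum of ``counts`` over every length-``w`` window (stride 1)."""
    cs = np.concatenate(([0.0], np.cumsum(counts)))
    return cs[w:] - cs[:-w]


def _centered_local_rate(counts: np.ndarray, w_bins: int, local_bins: int) -> np.ndarray:
    """Per-window background sum over a ``local_bins`` window centered on it,
    rescaled to the ``w_bins`` test-window length."""
    n = len(counts) - w_bins + 1
    cs = np.concatenate(([0.0], np.cumsum(counts)))
    centers = np.arange(n) + w_bins / 2.0
    lo = np.clip(np.round(centers - local_bins / 2.0).astype(int), 0, len(counts))
    hi = np.clip(lo + local_bins, 0, len(counts))
    lo = np.minimum(lo, hi - 1).clip(0)
    span = np.maximum(hi - lo, 1)
    return (cs[hi] - cs[lo]) * (w_bins / span)


def call_peaks(
    ip: CoverageTrack,
    control: CoverageTrack | float | None = None,
    window: int = 300,
    local_windows: tuple[int, ...] = (1000, 10_000),
    q_max: float = 0.05,
    merge_dist: int = 200,
    min_fold: float = 2.0,
    self_local_min: int = 5000,
) -> PeakSet:
    """Call enrichment peaks on a raw midpoint-count track.

    Parameters
    ----------
    control
        A matched control track (scaled to the IP depth), a float giving the
        expected background fragments *per base*, or ``None`` — in which case
        the IP's own genome-wide mean is the lambda floor and only local
        windows of at least ``self_local_min`` bases are estimated from the
        IP itself (smaller ones would mask the peak with its own signal).
    q_max, min_fold
        Windows are kept when BH q <= q_max and observed/lambda >= min_fold.
    merge_dist
        Kept windows closer than this (bp) are merged into one peak.

    Returns an empty :class:`PeakSet` for a zero-depth IP track.
    """
    if ip.norm != "raw":
        raise ValueError("peak calling requires a raw count track")
    if ip.stat != "midpoint":
        raise ValueError("peak calling requires a midpoint-count track (stat='midpoint')")
    bin_size = ip.bin_size
    if window < bin_size:
        raise ValueError("window must be >= the track bin size")
    w_bins = max(1, window // bin_size)

    ip_total = ip.total_mass()
    if ip_total == 0:
        return PeakSet([], condition=None)
    total_bins = ip.n_bins()
    ip_rate_per_bin = ip_total / total_bins

    ctrl_counts: dict[str, np.ndarray] | None = None
    ctrl_scale = 1.0
    if isinstance(control, CoverageTrack):
        if control.bin_size != bin_size or set(control.chrom_sizes) != set(ip.chrom_sizes):
            raise ValueError("IP and control tracks must share genome and bin size")
        ctrl_total = control.total_mass()
        if ctrl_total == 0:
            warnings.warn(
                "control track has zero depth; falling back to the IP genome-wide "
                "mean as the lambda floor",
                stacklevel=2,
            )
        else:
            ctrl_counts = control.counts
            ctrl_scale = ip_total / ctrl_total

    lam_global = (
        float(control) * window if isinstance(control, (int, float)) and control is not None
        else ip_rate_per_bin * w_bins
    )

    chroms: list[str] = []
    win_start_bin: list[np.ndarray] = []
    obs_all: list[np.ndarray] = []
    lam_all: list[np.ndarray] = []
    for chrom, counts in ip.counts.items():
        if len(counts) < w_bins:
            continue
        obs = _sliding_sums(counts, w_bins)
        lam = np.full(len(obs), lam_global)
        if ctrl_counts is not None:
            base = ctrl_counts[chrom]
            for lw in local_windows:
                lb = max(w_bins, lw // bin_size)
                lam = np.maximum(lam, _centered_local_rate(base, w_bins, lb) * ctrl_scale)
        elif not isinstance(control, (int, float)):
            # no control at all: estimate large local windows from the IP itself
            # (an explicit float rate is trusted as-is, no self-local estimate)
            for lw in local_windows:
                if lw < self_local_min:
                    continue
                lb = max(w_bins, lw // bin_size)
                lam = np.maximum(lam, _centered_local_rate(counts, w_bins, lb))
        chroms.append(chrom)
        win_start_bin.append(np.arange(len(obs)))
        obs_all.append(obs)
        lam_all.append(lam)

    if not obs_all:
        return PeakSet([], condition=None)
    obs_cat = np.concatenate(obs_all)
    lam_cat = np.concatenate(lam_all)
    pvals = stats.poisson.sf(obs_cat - 1, lam_cat)
    qvals = stats.false_discovery_control(pvals, method="bh")
    fold = obs_cat / np.maximum(lam_cat, 1e-300)
    keep = (qvals <= q_max) & (fold >= min_fold) & (obs_cat > 0)

    peaks: list[Peak] = []
    offset = 0
    peak_no = 0
    for chrom, idx, obs in zip(chroms, win_start_bin, obs_all):
        n = len(obs)
        sel = keep[offset: offset + n]
        q_chrom = qvals[offset: offset + n]
        p_chrom = pvals[offset: offset + n]
        f_chrom = fold[offset: offset + n]
        offset += n
        if not sel.any():
            continue
        kept = np.flatnonzero(sel)
        counts = ip.counts[chrom]
        chrom_len = ip.chrom_sizes[chrom]
        # 3-bin moving average for summit finding; ties -> leftmost
        if len(counts) >= 3:
            smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
        else:
            smooth = counts.astype(float)
        # merge kept windows into peaks
        starts = kept * bin_size
        ends = np.minimum(starts + window, chrom_len)
        merged: list[tuple[int, int, list[int]]] = []
        for wi, (s, e) in zip(kept, zip(starts, ends)):
            if merged and s - merged[-1][1] <= merge_dist:
                prev = merged[-1]
                merged[-1] = (prev[0], max(prev[1], int(e)), prev[2] + [int(wi)])
            else:
                merged.append((int(s), int(e), [int(wi)]))
        for s, e, members in merged:
            b0, b1 = s // bin_size, -(-e // bin_size)
            local = smooth[b0:b1]
            summit_bin = b0 + int(np.argmax(local))
            summit = min(summit_bin * bin_size + bin_size // 2, e - 1)
            summit = max(summit, s)
            q_min = float(np.min(q_chrom[members]))
            p_min = float(np.min(p_chrom[members]))
            peak_no += 1
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=s,
                    end=e,
                    summit=summit,
                    score=float(-np.log10(max(q_min, 1e-300))),
                    fold_enrichment=float(np.max(f_chrom[members])),
                    neglog10_p=float(-np.log10(max(p_min, 1e-300))),
                )
            )
    log.info(
        "call_peaks: %d windows tested, %d kept, %d peaks (q_max=%g, min_fold=%g)",
        len(obs_cat), int(keep.sum()), len(peaks), q_max, min_fold,
    )
    return PeakSet(sorted(peaks, key=lambda p: (p.chrom, p.start)), condition=None)


def write_narrowpeak(peak_set: PeakSet, path) -> None:
    """Write peaks as narrowPeak (BED6+4)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peak_set, start=1):
            score = int(min(1000, round(10 * p.score)))
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{score}\t.\t"
                f"{p.fold_enrichment:.4f}\t{p.neglog10_p:.4f}\t{p.score:.4f}\t"
                f"{p.summit - p.start}\n"
            )


def read_narrowpeak(path) -> PeakSet:
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ValueError(f"{path}: line {lineno}: expected 10 narrowPeak columns")
            chrom, start_s, end_s, _name, _score, _strand, fold_s, p_s, q_s, off_s = fields
            start, end = int(start_s), int(end_s)
            peaks.append(
                Peak(chrom, start, end, start + int(off_s), float(q_s),
                     float(fold_s), float(p_s))
            )
    return PeakSet(sorted(peaks, key=lambda p: (p.chrom, p.start)))
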
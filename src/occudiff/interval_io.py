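"""Fragment-interval formats and binned genome coverage.

The package's unit of sequencing data is the *fragment*: one immunoprecipitated,
sheared DNA molecule represented as a genomic interval (0-based, half-open,
BED convention).  Alignment multiplicity is carried on the record so that the
"filtered" (unique reads only) versus "unfiltered" (all reads, each counted
once at its assigned location) distinction of repeat-locus analyses can be made
at coverage time rather than at parse time.

Formats handled here:

* fragment BED6 — ``chrom start end read_id mapq strand`` with the alignment
  multiplicity appended to the read id as ``read_id/k`` for multimappers;
* ``chrom.sizes`` — two-column chromosome length table;
* bedGraph — for exporting any :class:`CoverageTrack`;
* a GFF3-like 9-column annotation table (see :func:`read_annotation`).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "FragmentRecord",
    "CoverageTrack",
    "read_fragment_bed",
    "write_fragment_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "write_bedgraph",
    "compute_coverage",
    "fragments_to_arrays",
]


@dataclass(slots=True)
class FragmentRecord:
    """One sequenced ChIP fragment as an aligned genomic interval.

    ``multiplicity`` is the number of genomic locations the fragment maps to
    equally well; multimappers (multiplicity > 1) carry MAPQ 0 by convention
    and are assigned to exactly one location (``start``/``end``) by the
    upstream aligner or simulator.
    """

    chrom: str
    start: int
    end: int
    read_id: str
    mapq: int
    strand: str = "."
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"fragment {self.read_id!r}: start ({self.start}) must be < end ({self.end})"
            )
        if not 0 <= self.mapq <= 60:
            raise ValueError(f"fragment {self.read_id!r}: MAPQ {self.mapq} outside [0, 60]")
        if self.multiplicity < 1:
            raise ValueError(f"fragment {self.read_id!r}: multiplicity must be >= 1")
        if self.multiplicity > 1 and self.mapq != 0:
            raise ValueError(
                f"fragment {self.read_id!r}: multimapping fragments must have MAPQ 0"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"fragment {self.read_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _chrom_sizes_of(genome) -> dict[str, int]:
    """Accept a GenomeSpec-like object or a plain ``{chrom: length}`` mapping."""
    if hasattr(genome, "chromosomes"):
        return {name: length for name, length in genome.chromosomes}
    return dict(genome)


def fragments_to_arrays(
    frags: Sequence[FragmentRecord],
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Group fragments by chromosome into (starts, ends, mapqs) integer arrays."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for f in frags:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end, f.mapq))
    out = {}
    for chrom, rows in by_chrom.items():
        arr = np.asarray(rows, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return out


# ---------------------------------------------------------------------------
# BED6 fragment dialect
# ---------------------------------------------------------------------------

def write_fragment_bed(frags: Iterable[FragmentRecord], path: str | Path) -> None:
    """Write fragments in the BED6 dialect (score column = MAPQ).

    Multimappers get ``read_id/k`` names, where k is the copy count.
    """
    with open(path, "w") as fh:
        for f in frags:
            name = f.read_id if f.multiplicity == 1 else f"{f.read_id}/{f.multiplicity}"
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t{f.mapq}\t{f.strand}\n")


def read_fragment_bed(
    path: str | Path, chrom_sizes: Mapping[str, int] | None = None
) -> list[FragmentRecord]:
    """Parse the fragment BED6 dialect, validating every record.

    Malformed lines are reported with their 1-based line number.  When
    ``chrom_sizes`` is given, records on unknown chromosomes or extending past
    a chromosome end are rejected.
    """
    records: list[FragmentRecord] = []
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                errors.append(f"line {lineno}: expected 6 tab-separated fields, got {len(fields)}")
                continue
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            try:
                start, end, mapq = int(start_s), int(end_s), int(score_s)
            except ValueError:
                errors.append(f"line {lineno}: non-integer coordinate or score")
                continue
            multiplicity = 1
            read_id = name
            if "/" in name:
                stem, _, suffix = name.rpartition("/")
                if suffix.isdigit():
                    read_id, multiplicity = stem, int(suffix)
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    errors.append(f"line {lineno}: unknown chromosome {chrom!r}")
                    continue
                if end > chrom_sizes[chrom]:
                    errors.append(
                        f"line {lineno}: interval end {end} beyond chromosome "
                        f"{chrom!r} length {chrom_sizes[chrom]}"
                    )
                    continue
            try:
                records.append(
                    FragmentRecord(chrom, start, end, read_id, mapq, strand, multiplicity)
                )
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        shown = "\n".join(errors[:20])
        raise ValueError(f"{path}: {len(errors)} malformed fragment line(s):\n{shown}")
    return records


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                chrom, length_s = line.split("\t")
                sizes[chrom] = int(length_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Per-chromosome binned fragment coverage.

    ``stat`` records how fragments were aggregated: ``"overlap"`` adds each
    fragment's base-pair overlap to every bin it intersects (so at bin size 1
    the track's total mass equals the total covered base pairs); ``"midpoint"``
    adds one count to the bin containing the fragment midpoint (integer counts,
    suited to Poisson peak statistics).
    """

    bin_size: int
    counts: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]
    library_size: int
    norm: str = "raw"  # "raw" | "per_million"
    stat: str = "overlap"  # "overlap" | "midpoint"

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.norm not in ("raw", "per_million"):
            raise ValueError(f"unknown normalization {self.norm!r}")

    def total_mass(self) -> float:
        return float(sum(arr.sum() for arr in self.counts.values()))

    def n_bins(self) -> int:
        return sum(len(arr) for arr in self.counts.values())

    def genome_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def per_million(self) -> "CoverageTrack":
        """Library-size normalized copy: raw counts x 1e6 / library_size."""
        if self.norm == "per_million":
            return self
        if self.library_size == 0:
            scaled = {c: a.astype(float) for c, a in self.counts.items()}
        else:
            factor = 1e6 / self.library_size
            scaled = {c: a * factor for c, a in self.counts.items()}
        return dataclasses.replace(self, counts=scaled, norm="per_million")


def compute_coverage(
    frags: Sequence[FragmentRecord],
    genome,
    bin_size: int = 50,
    mode: str = "unfiltered",
    mapq_min: int = 1,
    stat: str = "overlap",
) -> CoverageTrack:
    """Bin fragment coverage over the genome.

    Parameters
    ----------
    mode
        ``"filtered"`` counts only records with ``mapq >= mapq_min`` (the
        standard unique-reads analysis); ``"unfiltered"`` counts every record
        exactly once at its assigned location, multimappers included.
    stat
        See :class:`CoverageTrack`.

    An empty fragment list yields an all-zero track with library size 0.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if mode not in ("filtered", "unfiltered"):
        raise ValueError(f"unknown coverage mode {mode!r}")
    if stat not in ("overlap", "midpoint"):
        raise ValueError(f"unknown coverage stat {stat!r}")
    sizes = _chrom_sizes_of(genome)
    counts: dict[str, np.ndarray] = {}
    arrays = fragments_to_arrays(frags)
    library_size = 0
    for chrom, length in sizes.items():
        n_bins = -(-length // bin_size)
        if chrom not in arrays:
            counts[chrom] = np.zeros(n_bins, dtype=float)
            continue
        starts, ends, mapqs = arrays[chrom]
        if ends.max(initial=0) > length:
            raise ValueError(f"fragment beyond end of chromosome {chrom!r}")
        if mode == "filtered":
            keep = mapqs >= mapq_min
            starts, ends = starts[keep], ends[keep]
        library_size += len(starts)
        if stat == "midpoint":
            mids = (starts + ends) // 2
            binned = np.bincount(mids // bin_size, minlength=n_bins).astype(float)
        else:
            # per-base coverage via a difference array, then aggregate into bins
            diff = np.zeros(length + 1, dtype=np.int64)
            np.add.at(diff, starts, 1)
            np.add.at(diff, ends, -1)
            per_base = np.cumsum(diff[:-1])
            edges = np.arange(0, length, bin_size)
            binned = np.add.reduceat(per_base, edges).astype(float)
        counts[chrom] = binned
    unknown = set(arrays) - set(sizes)
    if unknown:
        raise ValueError(f"fragments on unknown chromosome(s): {sorted(unknown)}")
    return CoverageTrack(
        bin_size=bin_size,
        counts=counts,
        chrom_sizes=sizes,
        library_size=library_size,
        norm="raw",
        stat=stat,
    )


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Export a track as bedGraph, merging runs of equal-valued adjacent bins."""
    with open(path, "w") as fh:
        for chrom, arr in track.counts.items():
            length = track.chrom_sizes[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            run_starts = np.concatenate(([0], change))
            run_ends = np.concatenate((change, [len(arr)]))
            for i0, i1 in zip(run_starts, run_ends):
                value = arr[i0]
                if value == 0:
                    continue
                gstart = int(i0) * track.bin_size
                gend = min(int(i1) * track.bin_size, length)
                fh.write(f"{chrom}\t{gstart}\t{gend}\t{value:g}\n")
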
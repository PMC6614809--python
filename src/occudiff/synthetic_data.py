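"""Toy genomes, ground-truth occupancy models, and simulated ChIP libraries.

This module generates everything the downstream analyses need without any
external data: a small annotated genome with multi-copy repeat families
(duplicated tRNA genes, rDNA, telomeres, Ty elements), a point-source
occupancy landscape for a chromatin factor, and fragment libraries emulating
a ChIP protocol in which chromatin is sheared to 250-500 bp fragments.

The occupancy model encodes the comparative design this package analyses:
a genome-wide drug-dependent multiplier on binding-site weights (a poison
that traps the factor on chromatin) and a protection map of sites whose
multiplier is overridden (sites bound by a protector that prevents, or even
reverses, drug-dependent accumulation).  Fragments overlapping a repeat
family's copies are flagged as multimapping (MAPQ 0, multiplicity = copy
count) and re-assigned uniformly at random among the copies — the simulated
counterpart of an aligner placing a multi-mapping read arbitrarily.

All coordinates are 0-based half-open.  Every operation is deterministic for
a fixed seed.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .interval_io import FragmentRecord

__all__ = [
    "RepeatFamily",
    "GenomeSpec",
    "GeneModel",
    "Site",
    "OccupancyModel",
    "Condition",
    "FragmentLengthModel",
    "TruthTable",
    "build_toy_genome",
    "simulate_library",
    "simulate_input_library",
    "place_point_sites",
    "sites_from_genes",
    "relocate_sites_to_repeats",
    "read_annotation",
    "write_annotation",
]

REPEAT_CLASSES = ("tRNA", "rDNA", "telomere", "Ty")
GENE_CLASSES = ("mRNA", "tRNA", "rDNA", "Ty", "telomere")


@dataclass(frozen=True)
class RepeatFamily:
    """A family of identical genomic repeat copies (e.g. a duplicated tRNA gene)."""

    family_id: str
    repeat_class: str
    copies: tuple[tuple[str, int, int], ...]  # (chrom, start, end), sorted

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")
        if len(self.copies) < 1:
            raise ValueError(f"family {self.family_id!r} must have >= 1 copy")
        if list(self.copies) != sorted(self.copies):
            raise ValueError(f"family {self.family_id!r}: copies must be sorted")
        for chrom, start, end in self.copies:
            if start >= end:
                raise ValueError(f"family {self.family_id!r}: empty copy interval")

    @property
    def n_copies(self) -> int:
        return len(self.copies)


@dataclass(frozen=True)
class GenomeSpec:
    chromosomes: tuple[tuple[str, int], ...]
    repeat_families: tuple[RepeatFamily, ...] = ()

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be > 0")
        sizes = dict(self.chromosomes)
        all_copies: list[tuple[str, int, int]] = []
        for fam in self.repeat_families:
            for chrom, start, end in fam.copies:
                if chrom not in sizes:
                    raise ValueError(f"repeat copy on unknown chromosome {chrom!r}")
                if start < 0 or end > sizes[chrom]:
                    raise ValueError(f"repeat copy {chrom}:{start}-{end} outside chromosome")
                all_copies.append((chrom, start, end))
        all_copies.sort()
        for (c1, s1, e1), (c2, s2, e2) in zip(all_copies, all_copies[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError("repeat-family copies must not overlap")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_class: str
    expression: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id!r}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"gene {self.gene_id!r}: unknown class {self.gene_class!r}")
        if self.expression < 0:
            raise ValueError(f"gene {self.gene_id!r}: expression must be >= 0")

    @property
    def tss(self) -> int:
        """Transcription start site (base coordinate; gene end-1 on the - strand)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class Site:
    """A point-source binding site: fragments center within pos +/- width/2."""

    chrom: str
    pos: int
    width: int
    weight: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("site weight must be > 0")
        if self.width < 1:
            raise ValueError("site width must be >= 1")


@dataclass(frozen=True)
class OccupancyModel:
    """Ground-truth binding landscape for one factor.

    ``background_rate`` is a relative rate (mass per base) for the
    non-specific uniform background; site weights are on the same relative
    scale (mass per site).  Under drug, each site's weight is multiplied by
    ``drug_multiplier``, except sites listed in ``protection_map`` which use
    ``protected_multiplier`` instead.  With both multipliers equal to 1 the
    +/- drug landscapes are identical.
    """

    factor: str
    sites: tuple[Site, ...]
    background_rate: float
    drug_multiplier: float = 1.0
    protection_map: frozenset[int] = field(default_factory=frozenset)
    protected_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")
        if self.drug_multiplier <= 0 or self.protected_multiplier <= 0:
            raise ValueError("multipliers must be > 0")
        bad = [i for i in self.protection_map if not 0 <= i < len(self.sites)]
        if bad:
            raise ValueError(f"protection_map indices out of range: {bad}")

    def effective_weights(self, drug: bool) -> np.ndarray:
        w = np.array([s.weight for s in self.sites], dtype=float)
        if drug and len(w):
            mult = np.full(len(w), self.drug_multiplier)
            if self.protection_map:
                mult[list(self.protection_map)] = self.protected_multiplier
            w = w * mult
        return w


@dataclass(frozen=True)
class Condition:
    factor: str
    genotype: str  # "WT" or a deletion label such as "uls1d"
    drug: bool
    dose_label: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    @property
    def label(self) -> str:
        drug = "drug" if self.drug else "untreated"
        return f"{self.factor}_{self.genotype}_{drug}_rep{self.replicate}"


@dataclass(frozen=True)
class FragmentLengthModel:
    """Uniform fragment length on [min_len, max_len] (sheared chromatin)."""

    min_len: int = 250
    max_len: int = 500

    def __post_init__(self) -> None:
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("need 1 <= min_len <= max_len")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.integers(self.min_len, self.max_len + 1, size=n)


@dataclass
class TruthTable:
    """Simulator ground truth: parameters plus per-site expected fragment shares."""

    params: dict
    site_table: list[dict]

    def expected_counts(self) -> np.ndarray:
        return np.array([row["expected_count"] for row in self.site_table], dtype=float)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, value in self.params.items():
                fh.write(f"# {key}\t{value}\n")
            cols = ["site", "chrom", "pos", "width", "weight", "eff_multiplier",
                    "share", "expected_count"]
            fh.write("\t".join(cols) + "\n")
            for row in self.site_table:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")


# ---------------------------------------------------------------------------
# Toy genome construction
# ---------------------------------------------------------------------------

_TRNA_COPY_LEN = 100
_MAX_PLACEMENT_TRIES = 200


def _place_interval(
    rng: np.random.Generator,
    sizes: list[tuple[str, int]],
    cum: np.ndarray,
    occupied: dict[str, list[tuple[int, int]]],
    length: int,
) -> tuple[str, int] | None:
    """Try to place one interval of ``length`` without overlapping ``occupied``."""
    total = int(cum[-1])
    for _ in range(_MAX_PLACEMENT_TRIES):
        u = int(rng.integers(0, total))
        ci = int(np.searchsorted(cum, u, side="right"))
        chrom, chrom_len = sizes[ci]
        start = u - (int(cum[ci - 1]) if ci else 0)
        if start + length > chrom_len:
            continue
        end = start + length
        clash = False
        for s, e in occupied[chrom]:
            if start < e and s < end:
                clash = True
                break
        if not clash:
            occupied[chrom].append((start, end))
            return chrom, start
    return None


def build_toy_genome(
    n_chroms: int,
    chrom_len: int,
    n_genes: int,
    trna_family_sizes: Sequence[int],
    seed: int,
    expression_mu: float = 3.0,
    expression_sigma: float = 1.0,
) -> tuple[GenomeSpec, list[GeneModel]]:
    """Build a toy genome with non-overlapping genes and multi-copy tRNA families.

    Gene lengths are log-normal (clipped to 300-4000 bp, roughly yeast-like);
    expression levels are log-normal in arbitrary units, with tRNA genes drawn
    from a higher-mean distribution (they are among the most heavily
    transcribed genes).  Deterministic for a fixed seed.

    Raises ``RuntimeError`` if the requested features cannot be placed without
    overlap after bounded retries.
    """
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    if chrom_len < 10_000:
        raise ValueError("chrom_len must be >= 10 kb")
    rng = np.random.default_rng(seed)
    sizes = [(f"chr{i + 1}", chrom_len) for i in range(n_chroms)]
    cum = np.cumsum([length for _, length in sizes])
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name, _ in sizes}

    families: list[RepeatFamily] = []
    trna_genes: list[GeneModel] = []
    for fi, n_copies in enumerate(trna_family_sizes):
        copies: list[tuple[str, int, int]] = []
        for _ in range(n_copies):
            placed = _place_interval(rng, sizes, cum, occupied, _TRNA_COPY_LEN)
            if placed is None:
                raise RuntimeError("could not place tRNA family copies without overlap")
            chrom, start = placed
            copies.append((chrom, start, start + _TRNA_COPY_LEN))
        copies.sort()
        fam_id = f"tF{fi + 1}"
        families.append(RepeatFamily(fam_id, "tRNA", tuple(copies)))
        expr = float(rng.lognormal(expression_mu + 2.0, 0.5))
        for ci, (chrom, start, end) in enumerate(copies):
            strand = "+" if rng.random() < 0.5 else "-"
            trna_genes.append(
                GeneModel(f"{fam_id}_c{ci + 1}", chrom, start, end, strand, "tRNA", expr)
            )

    mrna: list[GeneModel] = []
    lengths = np.clip(rng.lognormal(7.0, 0.45, size=n_genes), 300, 4000).astype(int)
    for gi in range(n_genes):
        placed = _place_interval(rng, sizes, cum, occupied, int(lengths[gi]))
        if placed is None:
            raise RuntimeError("could not place genes without overlap; genome too dense")
        chrom, start = placed
        strand = "+" if rng.random() < 0.5 else "-"
        expr = float(rng.lognormal(expression_mu, expression_sigma))
        mrna.append(
            GeneModel(f"g{gi + 1:04d}", chrom, start, start + int(lengths[gi]),
                      strand, "mRNA", expr)
        )

    genes = sorted(mrna + trna_genes, key=lambda g: (g.chrom, g.start))
    genome = GenomeSpec(tuple(sizes), tuple(families))
    return genome, genes


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

def _global_to_chrom(genome: GenomeSpec, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map global base offsets to (chrom index, position) pairs."""
    lengths = np.array([length for _, length in genome.chromosomes], dtype=np.int64)
    cum = np.cumsum(lengths)
    ci = np.searchsorted(cum, u, side="right")
    offsets = np.concatenate(([0], cum[:-1]))
    return ci, u - offsets[ci]


def _repeat_copy_arrays(genome: GenomeSpec):
    """Per-chromosome sorted arrays of repeat copies: (starts, ends, fam_idx, copy_idx)."""
    per_chrom: dict[str, list[tuple[int, int, int, int]]] = {}
    for fi, fam in enumerate(genome.repeat_families):
        for ci, (chrom, start, end) in enumerate(fam.copies):
            per_chrom.setdefault(chrom, []).append((start, end, fi, ci))
    out = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        arr = np.asarray(rows, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])
    return out


def simulate_library(
    genome: GenomeSpec,
    model: OccupancyModel,
    cond: Condition,
    n_fragments: int,
    flen: FragmentLengthModel = FragmentLengthModel(),
    seed: int = 0,
    assignment_seed: int | None = None,
) -> tuple[list[FragmentRecord], TruthTable]:
    """Draw a ChIP fragment library from the occupancy mixture.

    Fragment centers come from a mixture of a uniform genomic background
    (mass ``background_rate * genome_length``) and top-hat kernels at each
    site (center = site position + uniform jitter of +/- width/2), with site
    weights scaled by the condition's effective multiplier.  Exactly
    ``n_fragments`` records are emitted; fragments extending past a
    chromosome end are truncated.

    Fragments overlapping any repeat-family copy are flagged multimapping
    (multiplicity = family copy count, MAPQ 0) and re-assigned uniformly at
    random among the family's copies.  The re-assignment uses its own
    sub-stream (``assignment_seed``, derived from ``seed`` when not given),
    so family totals are invariant to the assignment seed while per-copy
    placement is not.
    """
    if n_fragments < 0:
        raise ValueError("n_fragments must be >= 0")
    sizes = genome.chrom_sizes
    chrom_names = [name for name, _ in genome.chromosomes]
    chrom_lengths = np.array([length for _, length in genome.chromosomes], dtype=np.int64)
    name_to_idx = {name: i for i, name in enumerate(chrom_names)}
    for s in model.sites:
        if s.chrom not in sizes:
            raise ValueError(f"site on unknown chromosome {s.chrom!r}")
        if not 0 <= s.pos < sizes[s.chrom]:
            raise ValueError(f"site position {s.chrom}:{s.pos} outside chromosome")

    rng = np.random.default_rng(seed)
    weights = model.effective_weights(cond.drug)
    bg_mass = model.background_rate * genome.total_length
    masses = np.concatenate(([bg_mass], weights))
    shares = masses / masses.sum()
    counts = rng.multinomial(n_fragments, shares) if n_fragments else np.zeros(
        len(masses), dtype=np.int64
    )

    # fragment centers, background first then per-site blocks
    chrom_idx_parts: list[np.ndarray] = []
    center_parts: list[np.ndarray] = []
    n_bg = int(counts[0])
    if n_bg:
        u = rng.integers(0, genome.total_length, size=n_bg)
        ci, pos = _global_to_chrom(genome, u)
        chrom_idx_parts.append(ci)
        center_parts.append(pos)
    for si, site in enumerate(model.sites):
        c = int(counts[si + 1])
        if not c:
            continue
        half = site.width // 2
        jitter = rng.integers(-half, half + 1, size=c)
        centers = np.clip(site.pos + jitter, 0, sizes[site.chrom] - 1)
        chrom_idx_parts.append(np.full(c, name_to_idx[site.chrom], dtype=np.int64))
        center_parts.append(centers)

    if chrom_idx_parts:
        chrom_idx = np.concatenate(chrom_idx_parts)
        centers = np.concatenate(center_parts)
    else:
        chrom_idx = np.zeros(0, dtype=np.int64)
        centers = np.zeros(0, dtype=np.int64)
    lengths = flen.sample(rng, len(centers))
    strands = np.where(rng.random(len(centers)) < 0.5, "+", "-")
    L = chrom_lengths[chrom_idx] if len(centers) else np.zeros(0, dtype=np.int64)
    starts = np.maximum(centers - lengths // 2, 0)
    ends = np.minimum(centers + (lengths - lengths // 2), L)

    mapq = np.full(len(centers), 60, dtype=np.int64)
    multiplicity = np.ones(len(centers), dtype=np.int64)

    # multimapper flagging and re-assignment (dedicated sub-stream)
    sub_seed = assignment_seed if assignment_seed is not None else seed
    rng_assign = np.random.default_rng([int(sub_seed), 7919])
    copy_arrays = _repeat_copy_arrays(genome)
    fam_copies = [np.asarray(f.copies, dtype=object) for f in genome.repeat_families]
    for chrom, (rc_start, rc_end, rc_fam, rc_copy) in copy_arrays.items():
        cidx = name_to_idx[chrom]
        on_chrom = np.flatnonzero(chrom_idx == cidx)
        if not len(on_chrom):
            continue
        fs, fe = starts[on_chrom], ends[on_chrom]
        # copies are sorted and disjoint; a fragment can overlap at most a few
        j = np.searchsorted(rc_end, fs, side="right")
        best = np.full(len(on_chrom), -1, dtype=np.int64)
        best_ov = np.zeros(len(on_chrom), dtype=np.int64)
        for step in (0, 1):
            cand = j + step
            ok = cand < len(rc_start)
            ov = np.zeros(len(on_chrom), dtype=np.int64)
            ov[ok] = np.minimum(fe[ok], rc_end[cand[ok]]) - np.maximum(fs[ok], rc_start[cand[ok]])
            take = ov > best_ov  # strict: ties keep the leftmost copy
            best[take] = cand[take]
            best_ov[take] = ov[take]
        hit = best_ov > 0
        if not hit.any():
            continue
        frag_rows = on_chrom[hit]
        src = best[hit]
        for row, s_idx in zip(frag_rows, src):
            fi = int(rc_fam[s_idx])
            fam = genome.repeat_families[fi]
            k = fam.n_copies
            if k == 1:
                continue
            target = int(rng_assign.integers(0, k))
            t_chrom, t_start, t_end = fam.copies[target]
            offset = int(starts[row]) - int(rc_start[s_idx])
            flen_i = int(ends[row]) - int(starts[row])
            new_start = max(0, t_start + offset)
            new_end = min(sizes[t_chrom], new_start + flen_i)
            new_start = max(0, min(new_start, new_end - 1))
            starts[row], ends[row] = new_start, new_end
            chrom_idx[row] = name_to_idx[t_chrom]
            mapq[row] = 0
            multiplicity[row] = k

    records = [
        FragmentRecord(
            chrom_names[int(chrom_idx[i])],
            int(starts[i]),
            int(ends[i]),
            f"frag{i:07d}",
            int(mapq[i]),
            str(strands[i]),
            int(multiplicity[i]),
        )
        for i in range(len(centers))
    ]

    site_table = [
        {
            "site": si,
            "chrom": s.chrom,
            "pos": s.pos,
            "width": s.width,
            "weight": s.weight,
            "eff_multiplier": float(weights[si] / s.weight) if s.weight else 1.0,
            "share": float(shares[si + 1]),
            "expected_count": float(n_fragments * shares[si + 1]),
        }
        for si, s in enumerate(model.sites)
    ]
    truth = TruthTable(
        params={
            "factor": model.factor,
            "genotype": cond.genotype,
            "drug": cond.drug,
            "dose_label": cond.dose_label,
            "replicate": cond.replicate,
            "n_fragments": n_fragments,
            "background_rate": model.background_rate,
            "background_share": float(shares[0]),
            "drug_multiplier": model.drug_multiplier,
            "protected_multiplier": model.protected_multiplier,
            "n_protected": len(model.protection_map),
            "seed": seed,
            "assignment_seed": sub_seed,
            "fragment_len_min": flen.min_len,
            "fragment_len_max": flen.max_len,
        },
        site_table=site_table,
    )
    return records, truth


def simulate_input_library(
    genome: GenomeSpec,
    cond: Condition,
    n_fragments: int,
    flen: FragmentLengthModel = FragmentLengthModel(),
    seed: int = 0,
) -> list[FragmentRecord]:
    """No-enrichment control: background-only library (uniform over the genome)."""
    model = OccupancyModel(factor=f"{cond.factor}_input", sites=(), background_rate=1.0)
    frags, _ = simulate_library(genome, model, cond, n_fragments, flen, seed)
    return frags


# ---------------------------------------------------------------------------
# Model-building helpers
# ---------------------------------------------------------------------------

def place_point_sites(
    genome: GenomeSpec,
    n_sites: int,
    width: int,
    mean_weight: float,
    weight_cv: float,
    seed: int,
    min_separation: int = 1500,
    avoid_repeats: bool = True,
) -> tuple[Site, ...]:
    """Scatter point sites with a minimum pairwise separation.

    Weights are log-normal with the requested mean and coefficient of
    variation.  By default positions avoid repeat-family copies so that
    site fragments stay uniquely mappable.
    """
    rng = np.random.default_rng(seed)
    sizes = [(name, length) for name, length in genome.chromosomes]
    cum = np.cumsum([length for _, length in sizes])
    placed: dict[str, list[int]] = {name: [] for name, _ in sizes}
    repeat_iv: dict[str, list[tuple[int, int]]] = {name: [] for name, _ in sizes}
    if avoid_repeats:
        pad = width // 2 + 600  # keep site fragments clear of repeat copies
        for fam in genome.repeat_families:
            for chrom, start, end in fam.copies:
                repeat_iv[chrom].append((start - pad, end + pad))
    positions: list[tuple[str, int]] = []
    margin = width // 2 + 300
    tries = 0
    max_tries = 400 * max(n_sites, 1)
    while len(positions) < n_sites:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place sites with the requested separation")
        u = int(rng.integers(0, genome.total_length))
        ci = int(np.searchsorted(cum, u, side="right"))
        chrom, chrom_len = sizes[ci]
        pos = u - (int(cum[ci - 1]) if ci else 0)
        if pos < margin or pos > chrom_len - margin:
            continue
        if any(abs(pos - p) < min_separation for p in placed[chrom]):
            continue
        if any(s <= pos < e for s, e in repeat_iv[chrom]):
            continue
        placed[chrom].append(pos)
        positions.append((chrom, pos))
    if weight_cv > 0:
        sigma2 = np.log1p(weight_cv**2)
        mu = np.log(mean_weight) - sigma2 / 2
        weights = rng.lognormal(mu, np.sqrt(sigma2), size=n_sites)
    else:
        weights = np.full(n_sites, mean_weight)
    return tuple(
        Site(chrom, pos, width, float(w)) for (chrom, pos), w in zip(positions, weights)
    )


def sites_from_genes(
    genes: Sequence[GeneModel],
    width: int = 300,
    weight_scale: float = 1.0,
    weight_by_expression: bool = True,
) -> tuple[Site, ...]:
    """One site per gene at the gene-body midpoint, optionally weighted by expression."""
    sites = []
    for g in genes:
        w = weight_scale * (g.expression if weight_by_expression else 1.0)
        if w > 0:
            sites.append(Site(g.chrom, (g.start + g.end) // 2, width, float(w)))
    return tuple(sites)


def relocate_sites_to_repeats(
    model: OccupancyModel,
    genome: GenomeSpec,
    family_ids: Sequence[str],
    n_sites: int,
    seed: int = 0,
) -> OccupancyModel:
    """Move the last ``n_sites`` sites of the model into repeat-family copies.

    Relocated sites are centered on copies of the named families, one site
    per copy in order (families must provide at least ``n_sites`` copies).
    This emulates a drug-dependent redistribution of a factor onto a repeat
    class while leaving total site mass unchanged.
    """
    targets: list[tuple[str, int, int]] = []
    fam_by_id = {f.family_id: f for f in genome.repeat_families}
    for fam_id in family_ids:
        targets.extend(fam_by_id[fam_id].copies)
    if len(targets) < n_sites:
        raise ValueError("not enough repeat copies to host the relocated sites")
    if n_sites > len(model.sites):
        raise ValueError("cannot relocate more sites than the model has")
    sites = list(model.sites)
    for k in range(n_sites):
        old = sites[len(sites) - n_sites + k]
        chrom, start, end = targets[k]
        mid = (start + end) // 2
        sites[len(sites) - n_sites + k] = Site(chrom, mid, min(old.width, end - start), old.weight)
    return OccupancyModel(
        factor=model.factor,
        sites=tuple(sites),
        background_rate=model.background_rate,
        drug_multiplier=model.drug_multiplier,
        protection_map=model.protection_map,
        protected_multiplier=model.protected_multiplier,
    )


# ---------------------------------------------------------------------------
# Annotation IO (GFF3-like tab format)
# ---------------------------------------------------------------------------

def write_annotation(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write genes as a GFF3-like table.

    Columns: chrom, source, class, start (1-based), end, expression, strand,
    ".", gene_id.  Internally the package is 0-based half-open; the on-disk
    convention matches GFF.
    """
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\toccudiff\t{g.gene_class}\t{g.start + 1}\t{g.end}\t"
                f"{g.expression:.6g}\t{g.strand}\t.\t{g.gene_id}\n"
            )


def read_annotation(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 columns")
            chrom, _src, klass, start_s, end_s, expr_s, strand, _dot, gene_id = fields
            genes.append(
                GeneModel(gene_id, chrom, int(start_s) - 1, int(end_s), strand,
                          klass, float(expr_s))
            )
    return genes
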
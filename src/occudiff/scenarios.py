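"""Canonical simulated study conditions for validation and benchmarking.

Each function here wires the synthetic generator, coverage, peak calling and
effect-size machinery into one named experimental scenario — a null pair of
identical libraries, a drug dose-response, protected versus unprotected
sites, programmed-site recovery, a repeat-family relocation — and returns
the measured quantities.  The parameter defaults ARE the study conditions:
2 x 10^5 fragments per library, several hundred point sites on a few
megabases of genome, 250-500 bp fragments.  Tests and the reproduction
script both run these scenarios rather than re-wiring their own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffocc import cohens_d, compare_samples, stratify_by_overlap
from .interval_io import compute_coverage
from .peaks import Peak, PeakSet, call_peaks
from .repeats import category_fractions
from .synthetic_data import (
    Condition,
    GenomeSpec,
    OccupancyModel,
    Site,
    build_toy_genome,
    place_point_sites,
    relocate_sites_to_repeats,
    simulate_library,
)

__all__ = [
    "two_chrom_genome",
    "simulate_tracks_and_peaks",
    "paired_comparison",
    "multiplier_response",
    "ProtectionOutcome",
    "protection_stratification",
    "RecoveryOutcome",
    "site_recovery",
    "flat_false_peaks",
    "trna_category_shift",
    "lognormal_weights",
]

CALL_BIN = 50
ENRICH_BIN = 300
N_FRAGMENTS = 200_000


def two_chrom_genome(chrom_len: int = 1_500_000, n_chroms: int = 2) -> GenomeSpec:
    return GenomeSpec(tuple((f"chr{i + 1}", chrom_len) for i in range(n_chroms)))


def lognormal_weights(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.full(n, mean)
    s2 = np.log1p(cv**2)
    return rng.lognormal(np.log(mean) - s2 / 2, np.sqrt(s2), n)


def simulate_tracks_and_peaks(
    genome: GenomeSpec,
    model: OccupancyModel,
    drug: bool,
    seed: int,
    n_fragments: int = N_FRAGMENTS,
    mode: str = "filtered",
):
    """One library -> (per-million enrichment track, called peaks, fragments)."""
    cond = Condition(model.factor, "WT", drug)
    frags, _ = simulate_library(genome, model, cond, n_fragments, seed=seed)
    count = compute_coverage(frags, genome, CALL_BIN, mode, stat="midpoint")
    enrich = compute_coverage(frags, genome, ENRICH_BIN, mode).per_million()
    return enrich, call_peaks(count), frags


def _standard_model(
    genome: GenomeSpec,
    n_sites: int = 600,
    site_mass_fraction: float = 0.25,
    weight_cv: float = 0.35,
    drug_multiplier: float = 1.0,
    seed: int = 11,
) -> OccupancyModel:
    mean_w = genome.total_length * site_mass_fraction / (1 - site_mass_fraction) / n_sites
    sites = place_point_sites(genome, n_sites, 300, mean_w, weight_cv, seed=seed)
    return OccupancyModel("factor", sites, 1.0, drug_multiplier=drug_multiplier)


def paired_comparison(
    seed: int,
    drug_multiplier: float = 1.0,
    n_sites: int = 600,
    n_fragments: int = N_FRAGMENTS,
    site_seed: int = 11,
):
    """Simulate a +/- drug library pair from one landscape and compare them.

    With ``drug_multiplier=1`` this is the null: two libraries from an
    identical occupancy model differing only in sampling noise.  Returns the
    full :class:`~occudiff.diffocc.ComparisonResult` (drug is sample A).
    """
    genome = two_chrom_genome()
    model = _standard_model(genome, n_sites=n_sites,
                            drug_multiplier=drug_multiplier, seed=site_seed)
    enr_ref, ps_ref, _ = simulate_tracks_and_peaks(
        genome, model, drug=False, seed=seed, n_fragments=n_fragments)
    enr_drug, ps_drug, _ = simulate_tracks_and_peaks(
        genome, model, drug=True, seed=seed + 1000, n_fragments=n_fragments)
    return compare_samples(enr_drug, enr_ref, ps_drug, ps_ref)


def multiplier_response(
    seed: int, multipliers: tuple[float, ...] = (1.0, 1.5, 2.0)
) -> dict[float, float]:
    """Peaks-scope Cohen's d for a series of drug multipliers (protection off)."""
    out: dict[float, float] = {}
    for mult in multipliers:
        res = paired_comparison(seed, drug_multiplier=mult)
        out[mult] = res.peaks.d if res.peaks is not None else float("nan")
    return out


@dataclass
class ProtectionOutcome:
    d_bound: float
    d_unbound: float
    n_bound: int
    n_unbound: int


def protection_stratification(
    seed: int,
    n_protected: int = 500,
    n_unprotected: int = 150,
    protected_mass: float = 0.20,
    unprotected_mass: float = 0.02,
    drug_multiplier: float = 2.0,
    protected_multiplier: float = 1.0,
    n_fragments: int = N_FRAGMENTS,
) -> ProtectionOutcome:
    """Drug response at protector-bound versus unbound sites.

    Protected sites keep their weight under drug (``protected_multiplier``);
    the rest are multiplied.  Common drug/untreated peak regions are
    stratified by a mask built from the protected-site footprints (the
    protector's own binding map), and Cohen's d is computed per stratum.
    Protected sites carry a wider weight distribution (CV 0.5 vs 0.2) and
    most of the site mass, as befits the dominant factor-bound compartment.
    """
    genome = two_chrom_genome()
    rng = np.random.default_rng(seed + 17)
    n_total = n_protected + n_unprotected
    positions = place_point_sites(genome, n_total, 300, 1.0, 0.0, seed=5)
    bg_mass = 1.0 - protected_mass - unprotected_mass
    wp = lognormal_weights(
        rng, n_protected, genome.total_length * protected_mass / bg_mass / n_protected, 0.5)
    wu = lognormal_weights(
        rng, n_unprotected,
        genome.total_length * unprotected_mass / bg_mass / n_unprotected, 0.2)
    sites = tuple(
        Site(s.chrom, s.pos, 300, float(w))
        for s, w in zip(positions, np.concatenate([wp, wu]))
    )
    model = OccupancyModel(
        "factor", sites, 1.0, drug_multiplier=drug_multiplier,
        protection_map=frozenset(range(n_protected)),
        protected_multiplier=protected_multiplier,
    )
    mask = PeakSet(sorted(
        (Peak(s.chrom, max(0, s.pos - 150), s.pos + 150, s.pos, 0.0, 1.0)
         for s in sites[:n_protected]),
        key=lambda p: (p.chrom, p.start),
    ))
    enr_ref, ps_ref, _ = simulate_tracks_and_peaks(
        genome, model, drug=False, seed=seed, n_fragments=n_fragments)
    enr_drug, ps_drug, _ = simulate_tracks_and_peaks(
        genome, model, drug=True, seed=seed + 1000, n_fragments=n_fragments)
    res = compare_samples(enr_drug, enr_ref, ps_drug, ps_ref)
    bound, unbound = stratify_by_overlap(res.pairs, mask)
    d_bound = cohens_d([p.value_a for p in bound], [p.value_b for p in bound]).d
    d_unbound = cohens_d([p.value_a for p in unbound], [p.value_b for p in unbound]).d
    return ProtectionOutcome(d_bound, d_unbound, len(bound), len(unbound))


@dataclass
class RecoveryOutcome:
    n_sites: int
    n_recovered: int
    n_peaks: int
    n_false: int


def site_recovery(
    seed: int,
    n_sites: int = 50,
    chrom_len: int = 1_000_000,
    fold: float = 10.0,
    n_fragments: int = 60_000,
) -> RecoveryOutcome:
    """Recovery of programmed constant-fold sites at default calling settings.

    Site weights are set so a 300 bp window at a site holds ``fold`` times the
    background window count.  A site counts as recovered when any called peak
    overlaps its fragment-level footprint (site half-width + maximum fragment
    length on each side); a called peak outside every footprint is false.
    """
    genome = GenomeSpec((("chr1", chrom_len),))
    positions = place_point_sites(genome, n_sites, 300, 1.0, 0.0, seed=7)
    w = (fold - 1) * 300.0  # background_rate is 1 mass/base
    sites = tuple(Site(s.chrom, s.pos, 300, w) for s in positions)
    model = OccupancyModel("factor", sites, 1.0)
    _, ps, _ = simulate_tracks_and_peaks(
        genome, model, drug=False, seed=seed, n_fragments=n_fragments)
    pad = 150 + 500
    footprints = [(s.pos - pad, s.pos + pad) for s in sites]
    recovered = sum(
        1 for fs, fe in footprints
        if any(p.start < fe and p.end > fs for p in ps)
    )
    false = sum(
        1 for p in ps
        if not any(p.start < fe and p.end > fs for fs, fe in footprints)
    )
    return RecoveryOutcome(n_sites, recovered, len(ps), false)


def flat_false_peaks(
    seeds, chrom_len: int = 500_000, n_fragments: int = 25_000
) -> tuple[int, float]:
    """Total peaks called on signal-free uniform libraries.

    Returns (total peak count, megabases scanned) across the seeds; the
    false-peak rate is the ratio.
    """
    genome = GenomeSpec((("chr1", chrom_len),))
    model = OccupancyModel("factor", (), 1.0)
    total = 0
    for seed in seeds:
        _, ps, _ = simulate_tracks_and_peaks(
            genome, model, drug=False, seed=seed, n_fragments=n_fragments)
        total += len(ps)
    return total, chrom_len * len(seeds) / 1e6


def trna_category_shift(
    seed: int,
    n_sites: int = 100,
    relocate_untreated: int = 4,
    relocate_drug: int = 24,
    n_fragments: int = 150_000,
):
    """Fraction of peaks at tRNA genes before and after a drug-driven relocation.

    A factor with ``n_sites`` equal-weight sites has a few sites inside tRNA
    copies at baseline; under drug a further block of sites relocates onto
    tRNA-family copies (filling whole families, so that the uniform
    multimapper scatter reproduces one peak per copy).  Peaks are called on
    unfiltered coverage — with filtered reads the repeat loci are invisible.

    Returns (fraction untreated, fraction drug, genes, genome).
    """
    genome, genes = build_toy_genome(1, 2_000_000, 150, [4, 10, 10], seed=21)
    fam_ids = [f.family_id for f in genome.repeat_families]
    mean_w = genome.total_length * 0.3 / 0.7 / n_sites
    sites = place_point_sites(genome, n_sites, 300, mean_w, 0.0, seed=22)
    base = OccupancyModel("factor2", sites, 1.0)
    m_untreated = relocate_sites_to_repeats(base, genome, fam_ids[:1], relocate_untreated)
    m_drug = relocate_sites_to_repeats(base, genome, fam_ids, relocate_drug)
    fractions = []
    for drug, model in ((False, m_untreated), (True, m_drug)):
        _, ps, _ = simulate_tracks_and_peaks(
            genome, model, drug=drug, seed=seed + (1000 if drug else 0),
            n_fragments=n_fragments, mode="unfiltered")
        fractions.append(category_fractions(ps, genes).get("tRNA", 0.0))
    return fractions[0], fractions[1], genes, genome
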
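"""End-to-end orchestration: simulate -> coverage -> peaks -> comparisons.

A single :class:`RunConfig` drives the whole comparative experiment the
package emulates: a chromatin factor ("factor 1", Top2-like) assayed in a
wild-type and a protector-deletion genotype with and without a trapping drug,
and the protector itself ("factor 2", Uls1-like) assayed in the wild type
with and without drug.  Replicate libraries are pooled by concatenation
before analysis.  Every stage is seeded from the single run seed, so reruns
with the same config produce byte-identical outputs (checksummed in the run
manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import association, diffocc, metagene, repeats
from .interval_io import CoverageTrack, compute_coverage, write_fragment_bed
from .peaks import PeakSet, call_peaks, write_narrowpeak
from .synthetic_data import (
    Condition,
    FragmentLengthModel,
    GenomeSpec,
    OccupancyModel,
    Site,
    build_toy_genome,
    place_point_sites,
    relocate_sites_to_repeats,
    simulate_library,
    write_annotation,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_config", "demo_config"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated parameters for a full simulated comparative ChIP-seq run."""

    schema_version: int = 1
    seed: int = 1

    # genome
    n_chroms: int = 2
    chrom_len: int = 1_000_000
    n_genes: int = 400
    trna_family_sizes: tuple[int, ...] = (10, 8, 6)

    # libraries
    n_fragments: int = 150_000
    n_replicates: int = 2
    fragment_len_min: int = 250
    fragment_len_max: int = 500

    # factor 1 (drug-trapped factor, e.g. a type II topoisomerase)
    factor1: str = "factor1"
    f1_n_sites: int = 400
    f1_site_width: int = 300
    f1_site_mass_fraction: float = 0.25
    f1_weight_cv: float = 0.35
    # fraction of factor-1 sites placed inside gene bodies, sampled with
    # probability proportional to expression (the factor tracks transcription)
    f1_expression_linked_fraction: float = 0.5
    # give factor 1 a site at every tRNA-family copy; these sites are
    # protector-bound in the WT (drug response suppressed/reversed there)
    f1_bind_repeats: bool = True
    f1_drug_multiplier_wt: float = 1.35
    f1_drug_multiplier_del: float = 2.0
    f1_protected_multiplier: float = 0.7
    protect_fraction: float = 0.3

    # factor 2 (the protector / remodeller); site count defaults to the
    # number of protected factor-1 sites (co-binding)
    factor2: str = "factor2"
    f2_n_sites: int | None = None
    f2_site_width: int = 300
    f2_site_mass_fraction: float = 0.15
    f2_drug_multiplier: float = 1.0
    f2_relocate_fraction: float = 0.2  # fraction of sites moved to tRNA copies under drug
    f2_baseline_trna_fraction: float = 0.03  # small tRNA presence without drug

    # analysis
    call_bin: int = 50
    enrich_bin: int = 300
    window: int = 300
    local_windows: tuple[int, ...] = (1000, 10_000)
    q_max: float = 0.05
    merge_dist: int = 200
    min_fold: float = 2.0
    min_overlap: int = 1
    mapq_min: int = 1
    metagene_upstream: int = 500
    metagene_downstream: int = 1500
    metagene_bin: int = 50
    n_boot: int = 300
    assoc_max_dist: int = 1000
    n_expression_bins: int = 4

    outdir: str = "occudiff_out"
    write_fragments: bool = False

    def __post_init__(self) -> None:
        if self.schema_version != 1:
            raise ValueError(f"unsupported config schema version {self.schema_version}")
        positive = [
            "n_chroms", "chrom_len", "n_genes", "n_fragments", "n_replicates",
            "f1_n_sites", "f1_site_width", "f2_site_width", "call_bin",
            "enrich_bin", "window", "merge_dist", "n_boot",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be > 0")
        for name in ("f1_site_mass_fraction", "f2_site_mass_fraction",
                     "protect_fraction", "f2_relocate_fraction",
                     "f1_expression_linked_fraction"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"config field {name!r} must be in [0, 1)")
        if not 0 < self.q_max <= 1:
            raise ValueError("q_max must be in (0, 1]")
        if self.fragment_len_min > self.fragment_len_max:
            raise ValueError("fragment_len_min must be <= fragment_len_max")


def demo_config(outdir: str = "occudiff_demo", seed: int = 1) -> RunConfig:
    """A small single-chromosome configuration that runs in well under a minute."""
    return RunConfig(
        seed=seed,
        n_chroms=1,
        chrom_len=200_000,
        n_genes=60,
        trna_family_sizes=(6,),
        n_fragments=50_000,
        f1_n_sites=40,
        n_boot=200,
        outdir=outdir,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys are errors)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("trna_family_sizes", "local_windows"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


@dataclass
class RunReport:
    outdir: Path
    manifest: dict
    effect_sizes: dict
    peak_counts: dict
    category_fractions: dict
    effect_ns: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)


def _child_seed(root: int, *key: int) -> int:
    ss = np.random.SeedSequence([root, *key])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _pooled_library(genome, model, cond_base: Condition, cfg: RunConfig, cond_idx: int):
    """Concatenate per-replicate libraries, mirroring replicate pooling."""
    flen = FragmentLengthModel(cfg.fragment_len_min, cfg.fragment_len_max)
    frags = []
    for rep in range(1, cfg.n_replicates + 1):
        cond = dataclasses.replace(cond_base, replicate=rep)
        part, _ = simulate_library(
            genome, model, cond, cfg.n_fragments, flen,
            seed=_child_seed(cfg.seed, cond_idx, rep),
        )
        frags.extend(part)
    return frags


def _tracks(frags, genome, cfg: RunConfig):
    """(midpoint-count track for calling, per-million overlap track for enrichment),
    both in filtered (unique-reads) mode, plus the unfiltered pair."""
    count_f = compute_coverage(frags, genome, cfg.call_bin, "filtered",
                               cfg.mapq_min, stat="midpoint")
    enrich_f = compute_coverage(frags, genome, cfg.enrich_bin, "filtered",
                                cfg.mapq_min, stat="overlap").per_million()
    count_u = compute_coverage(frags, genome, cfg.call_bin, "unfiltered",
                               stat="midpoint")
    enrich_u = compute_coverage(frags, genome, cfg.enrich_bin, "unfiltered",
                                stat="overlap").per_million()
    return count_f, enrich_f, count_u, enrich_u


def build_models(cfg: RunConfig, genome: GenomeSpec, genes=None):
    """Ground-truth occupancy models for both factors and all genotypes.

    A fraction of factor-1 sites sits inside gene bodies (genes sampled with
    probability proportional to expression, mirroring a transcription-tracking
    factor); the rest are scattered.  Factor 2 binds at a subset of factor
    1's sites (the protection map): in the wild type those factor-1 sites use
    the protected multiplier under drug; in the deletion genotype the
    protection map is empty.  Under drug, factor 2 additionally relocates a
    fraction of its sites onto tRNA-family copies.
    """
    bg_total = float(genome.total_length)  # background_rate = 1 mass/base

    def mean_weight(mass_fraction: float, n_sites: int) -> float:
        return bg_total * mass_fraction / (1 - mass_fraction) / n_sites

    n_linked = 0
    linked_sites: list[Site] = []
    mrna = [g for g in (genes or []) if g.gene_class == "mRNA"]
    f1_mean_w = mean_weight(cfg.f1_site_mass_fraction, cfg.f1_n_sites)
    if mrna and cfg.f1_expression_linked_fraction > 0:
        rng = np.random.default_rng(_child_seed(cfg.seed, 100))
        n_linked = min(
            int(round(cfg.f1_expression_linked_fraction * cfg.f1_n_sites)),
            len(mrna),
        )
        expr = np.array([g.expression for g in mrna])
        chosen = rng.choice(len(mrna), size=n_linked, replace=False,
                            p=expr / expr.sum())
        s2 = np.log1p(cfg.f1_weight_cv**2)
        weights = rng.lognormal(np.log(f1_mean_w) - s2 / 2, np.sqrt(s2), n_linked)
        linked_sites = [
            Site(mrna[i].chrom, (mrna[i].start + mrna[i].end) // 2,
                 cfg.f1_site_width, float(w))
            for i, w in zip(chosen, weights)
        ]
    f1_sites = tuple(linked_sites) + place_point_sites(
        genome, cfg.f1_n_sites - n_linked, cfg.f1_site_width,
        f1_mean_w, cfg.f1_weight_cv, seed=_child_seed(cfg.seed, 101),
    )
    repeat_sites: list[Site] = []
    if cfg.f1_bind_repeats:
        for fam in genome.repeat_families:
            if fam.repeat_class != "tRNA":
                continue
            for chrom, s, e in fam.copies:
                repeat_sites.append(
                    Site(chrom, (s + e) // 2, min(cfg.f1_site_width, e - s),
                         f1_mean_w)
                )
    n_prot = int(round(cfg.protect_fraction * cfg.f1_n_sites))
    f1_sites = f1_sites + tuple(repeat_sites)
    # WT protection: the designated co-bound block plus every repeat site
    protected = frozenset(range(n_prot)) | frozenset(
        range(len(f1_sites) - len(repeat_sites), len(f1_sites))
    )

    f1_wt = OccupancyModel(
        factor=cfg.factor1, sites=f1_sites, background_rate=1.0,
        drug_multiplier=cfg.f1_drug_multiplier_wt,
        protection_map=protected, protected_multiplier=cfg.f1_protected_multiplier,
    )
    f1_del = OccupancyModel(
        factor=cfg.factor1, sites=f1_sites, background_rate=1.0,
        drug_multiplier=cfg.f1_drug_multiplier_del,
    )

    # factor 2 sits on a leading block of factor-1 sites (co-binding),
    # covering at least the protected ones
    f2_n = cfg.f2_n_sites if cfg.f2_n_sites is not None else max(n_prot, 2)
    f2_n = min(max(f2_n, 2), len(f1_sites))
    f2_weight = mean_weight(cfg.f2_site_mass_fraction, f2_n)
    f2_sites = tuple(
        Site(s.chrom, s.pos, cfg.f2_site_width, f2_weight) for s in f1_sites[:f2_n]
    )
    f2_base = OccupancyModel(
        factor=cfg.factor2, sites=f2_sites, background_rate=1.0,
        drug_multiplier=cfg.f2_drug_multiplier,
    )
    n_reloc = int(round(cfg.f2_relocate_fraction * f2_n))
    n_base = int(round(cfg.f2_baseline_trna_fraction * f2_n))
    fam_ids = [f.family_id for f in genome.repeat_families]
    n_copies = sum(f.n_copies for f in genome.repeat_families)
    f2_drug = f2_base
    if n_reloc and fam_ids and n_copies >= n_reloc:
        f2_drug = relocate_sites_to_repeats(f2_base, genome, fam_ids, n_reloc)
    if n_base and fam_ids:
        # a small baseline tRNA presence, confined to the smallest family:
        # the uniform multimapper scatter lights up whole families, so the
        # smallest one keeps the untreated fraction small
        smallest = min(genome.repeat_families, key=lambda f: f.n_copies)
        f2_base = relocate_sites_to_repeats(
            f2_base, genome, [smallest.family_id],
            min(n_base, smallest.n_copies),
        )
    return f1_wt, f1_del, f2_base, f2_drug, protected


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full simulated experiment and write all reports under ``outdir``.

    Emits, per condition, called peaks (narrowPeak); plus the comparison
    table with the four headline contrasts (factor 1 WT +/- drug, deletion
    +/- drug, WT vs deletion under drug, factor 2 +/- drug), the bound /
    unbound stratification against factor-2 peaks, TSS metagene profiles,
    repeat-family reports, peak category fractions, the expression-quantile
    association table, and a manifest with a parameter hash and per-file
    checksums.  Deterministic given the config.
    """
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def register(name: str, path: Path) -> Path:
        files[name] = path
        return path

    try:
        log.info("stage=genome seed=%d n_chroms=%d chrom_len=%d", cfg.seed,
                 cfg.n_chroms, cfg.chrom_len)
        genome, genes = build_toy_genome(
            cfg.n_chroms, cfg.chrom_len, cfg.n_genes, cfg.trna_family_sizes,
            seed=_child_seed(cfg.seed, 1),
        )
        write_annotation(genes, register("annotation", outdir / "annotation.tsv"))
        f1_wt, f1_del, f2_base, f2_drug, protected = build_models(cfg, genome, genes)

        plan = [
            ("f1_wt_untreated", f1_wt, Condition(cfg.factor1, "WT", False)),
            ("f1_wt_drug", f1_wt, Condition(cfg.factor1, "WT", True, "250 uM")),
            ("f1_del_untreated", f1_del, Condition(cfg.factor1, "del", False)),
            ("f1_del_drug", f1_del, Condition(cfg.factor1, "del", True, "250 uM")),
            ("f2_wt_untreated", f2_base, Condition(cfg.factor2, "WT", False)),
            ("f2_wt_drug", f2_drug, Condition(cfg.factor2, "WT", True, "100 uM")),
        ]
        libraries: dict[str, list] = {}
        tracks: dict[str, tuple] = {}
        peak_sets: dict[str, PeakSet] = {}
        peak_sets_unf: dict[str, PeakSet] = {}
        for idx, (name, model, cond) in enumerate(plan):
            frags = _pooled_library(genome, model, cond, cfg, idx)
            libraries[name] = frags
            if cfg.write_fragments:
                write_fragment_bed(frags, register(f"frags_{name}",
                                                   outdir / f"{name}.bed"))
            count_f, enrich_f, count_u, enrich_u = _tracks(frags, genome, cfg)
            tracks[name] = (count_f, enrich_f, count_u, enrich_u)
            ps = call_peaks(count_f, None, cfg.window, cfg.local_windows,
                            cfg.q_max, cfg.merge_dist, cfg.min_fold)
            ps.condition = cond
            peak_sets[name] = ps
            ps_u = call_peaks(count_u, None, cfg.window, cfg.local_windows,
                              cfg.q_max, cfg.merge_dist, cfg.min_fold)
            ps_u.condition = cond
            peak_sets_unf[name] = ps_u
            write_narrowpeak(ps, register(f"peaks_{name}",
                                          outdir / f"peaks_{name}.narrowPeak"))
            log.info("stage=library name=%s n_frags=%d n_peaks=%d", name,
                     len(frags), len(ps))

        contrasts = {
            "f1_wt_drug_vs_untreated": ("f1_wt_drug", "f1_wt_untreated"),
            "f1_del_drug_vs_untreated": ("f1_del_drug", "f1_del_untreated"),
            "f1_del_vs_wt_drug": ("f1_del_drug", "f1_wt_drug"),
            "f2_drug_vs_untreated": ("f2_wt_drug", "f2_wt_untreated"),
        }
        effect_rows: dict[str, diffocc.EffectSize | None] = {}
        comparisons: dict[str, diffocc.ComparisonResult] = {}
        for cname, (a, b) in contrasts.items():
            res = diffocc.compare_samples(
                tracks[a][1], tracks[b][1], peak_sets[a], peak_sets[b],
                min_overlap=cfg.min_overlap,
            )
            comparisons[cname] = res
            effect_rows[f"{cname}/Genome"] = res.genome
            effect_rows[f"{cname}/Peaks"] = res.peaks

        # stratify the WT drug response by factor-2 binding
        wt_res = comparisons["f1_wt_drug_vs_untreated"]
        mask = peak_sets["f2_wt_drug"]
        bound, unbound = diffocc.stratify_by_overlap(wt_res.pairs, mask,
                                                     cfg.min_overlap)
        for label, subset in (("bound", bound), ("unbound", unbound)):
            if len(subset) >= 2:
                es = diffocc.cohens_d(
                    [p.value_a for p in subset], [p.value_b for p in subset]
                )
            else:
                es = None
            effect_rows[f"f1_wt_drug_vs_untreated/{label}"] = es
        diffocc.write_comparison_table(
            effect_rows, register("comparison", outdir / "comparison.tsv")
        )

        mrna = [g for g in genes if g.gene_class == "mRNA"]
        for name in ("f1_wt_untreated", "f1_wt_drug", "f1_del_drug",
                     "f2_wt_untreated", "f2_wt_drug"):
            prof = metagene.tss_profile(
                peak_sets[name], mrna, cfg.metagene_upstream,
                cfg.metagene_downstream, cfg.metagene_bin, cfg.n_boot,
                seed=_child_seed(cfg.seed, 900 + len(name)),
            )
            metagene.write_profile(
                prof, register(f"profile_{name}", outdir / f"profile_{name}.tsv")
            )

        signals = []
        trna_effects: dict[str, float] = {}
        for name in ("f2_wt_untreated", "f2_wt_drug", "f1_wt_untreated", "f1_wt_drug"):
            for fam in genome.repeat_families:
                signals.append(
                    repeats.family_signal(libraries[name], fam, genome,
                                          cfg.mapq_min,
                                          condition=peak_sets[name].condition)
                )
        repeats.write_family_report(
            signals, register("families", outdir / "family_report.tsv")
        )
        for fam in genome.repeat_families:
            if fam.n_copies < 2:
                continue
            for factor, (na, nb) in (
                ("f2", ("f2_wt_drug", "f2_wt_untreated")),
                ("f1", ("f1_wt_drug", "f1_wt_untreated")),
                ("f1_del", ("f1_del_drug", "f1_del_untreated")),
            ):
                sa = repeats.family_signal(libraries[na], fam, genome, cfg.mapq_min)
                sb = repeats.family_signal(libraries[nb], fam, genome, cfg.mapq_min)
                trna_effects[f"{factor}_{fam.family_id}_drug_vs_untreated"] = (
                    repeats.compare_family_conditions(sa, sb).d
                )

        cat_fracs: dict[str, dict[str, float]] = {}
        for name in ("f2_wt_untreated", "f2_wt_drug"):
            if len(peak_sets_unf[name]):
                cat_fracs[name] = repeats.category_fractions(
                    peak_sets_unf[name], genes, cfg.min_overlap
                )
                repeats.write_category_fractions(
                    cat_fracs[name],
                    register(f"categories_{name}", outdir / f"categories_{name}.tsv"),
                )

        links = association.assign_peaks_to_genes(
            peak_sets["f1_wt_untreated"], genes, cfg.assoc_max_dist
        )
        qtable = association.expression_quantile_table(links, genes,
                                                      cfg.n_expression_bins)
        association.write_quantile_table(
            qtable, register("expression_quantiles", outdir / "expression_quantiles.tsv")
        )

        effect_sizes = {
            name: (None if es is None else es.d) for name, es in effect_rows.items()
        }
        effect_ns = {
            name: (0 if es is None else es.n_a) for name, es in effect_rows.items()
        }
        effect_sizes.update(trna_effects)
        peak_counts = {name: len(ps) for name, ps in peak_sets.items()}

        config_json = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=list)
        manifest = {
            "schema_version": cfg.schema_version,
            "config": json.loads(config_json),
            "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
            "outputs": {},
        }
        summary = {
            "effect_sizes": effect_sizes,
            "peak_counts": peak_counts,
            "category_fractions": cat_fracs,
            "n_protected_sites": len(protected),
        }
        spath = register("summary", outdir / "summary.json")
        spath.write_text(json.dumps(summary, indent=2, sort_keys=True))
        for name, path in sorted(files.items()):
            manifest["outputs"][name] = {
                "path": path.name, "sha256": _sha256(path)
            }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        return RunReport(
            outdir=outdir,
            manifest=manifest,
            effect_sizes=effect_sizes,
            effect_ns=effect_ns,
            peak_counts=peak_counts,
            category_fractions=cat_fracs,
            files={k: str(v) for k, v in files.items()},
        )
    except Exception:
        # flag partial outputs so a half-written run is never mistaken for a result
        (outdir / "FAILED").write_text("run failed; outputs may be partial\n")
        raise
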
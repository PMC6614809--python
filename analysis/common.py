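"""Shared configuration and paths for the numbered analysis scripts.

The scripts form one narrative: simulate the comparative design (01), call
peaks (02), compare occupancy by effect size (03), profile peaks around TSSs
(04), quantify repeat families with multimapping reads (05), and associate
peaks with gene expression (06).  Libraries and coverage tracks are bulky and
go under scratch/; every table a reader would look at goes under results/.
"""

from pathlib import Path

from occudiff.pipeline import RunConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

CONFIG = RunConfig(seed=11, outdir=str(SCRATCH / "pipeline"))

CONDITIONS = [
    "f1_wt_untreated", "f1_wt_drug",
    "f1_del_untreated", "f1_del_drug",
    "f2_wt_untreated", "f2_wt_drug",
]


def library_bed(name: str) -> Path:
    return SCRATCH / "libraries" / f"{name}.bed"


def peaks_file(name: str, mode: str = "filtered") -> Path:
    suffix = "" if mode == "filtered" else ".unfiltered"
    return RESULTS / f"peaks_{name}{suffix}.narrowPeak"


def ensure_dirs() -> None:
    (SCRATCH / "libraries").mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
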
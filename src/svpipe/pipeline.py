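"""End-to-end orchestration of the six pipeline stages.

Stage 1 maps all raw reads with a fast long-read aligner. Stage 2 extracts
per-read features from that output and classifies informative reads.
Stage 3 re-aligns the selected subset (classifier positives plus reads the
fast aligner split) with the slower, SV-sensitive aligner. Stage 4
harmonizes and merges the two alignment streams and converts to sorted
BAM. Stage 5 runs two SV callers on the merged alignments. Stage 6 recounts
unique supporting reads, filters on minimum support, and unifies redundant
calls across the callers.

Stages 1, 3, 5 and the BAM conversion wrap external binaries; each adapter
degrades to a :class:`CapabilityError` naming the missing tool. When a
stage's product is supplied up front (``fast_sam`` / ``accurate_sam`` /
``vcf_a`` / ``vcf_b``), the external call is skipped entirely — the
"bespoke-only" mode used for fully self-contained runs on synthetic data.
"""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import alignment, classifier, svmerge, unify
from .errors import CapabilityError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of coverage / min_support is set."""

    workdir: str
    reads_fastq: str | None = None
    reference_fasta: str | None = None
    model_path: str | None = None
    coverage: float | None = None
    min_support: int | None = None
    merge_window: int = svmerge.DEFAULT_MERGE_WINDOW
    classifier_threshold: float | None = None
    rnames_key: str = "RNAMES"
    seed: int = 0
    threads: int = 1
    force: bool = False
    # precomputed stage products (bespoke-only mode)
    fast_sam: str | None = None
    accurate_sam: str | None = None
    vcf_a: str | None = None
    vcf_b: str | None = None
    # external binaries; None means "resolve from PATH"
    binaries: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.coverage is None) == (self.min_support is None):
            raise ValueError("set exactly one of coverage / min_support")
        Path(self.workdir).mkdir(parents=True, exist_ok=True)

    def binary(self, name: str) -> str:
        configured = self.binaries.get(name) or name
        resolved = shutil.which(configured)
        if resolved is None:
            raise CapabilityError(
                f"external tool {configured!r} not found; install it or supply the "
                f"corresponding stage product to run in bespoke-only mode"
            )
        return resolved


@dataclass
class PipelineResult:
    final_vcf: str
    report: dict
    report_path: str


def _run(cmd: list[str], out_path: str | None = None) -> None:
    log.info("running: %s", " ".join(cmd))
    if out_path is not None:
        with open(out_path, "w") as fh:
            proc = subprocess.run(cmd, stdout=fh, stderr=subprocess.PIPE, text=True)
    else:
        proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise CapabilityError(
            f"command {cmd[0]} failed (exit {proc.returncode}): {proc.stderr[-2000:]}"
        )


# --- external-tool adapters (pinned default argument templates) -------------


def run_fast_aligner(cfg: PipelineConfig, out_sam: str) -> str:
    """Minimap2-style mapping with MD tags and SAM output."""
    binary = cfg.binary("minimap2")
    _run(
        [binary, "-a", "--MD", "-x", "map-pb", "-t", str(cfg.threads),
         cfg.reference_fasta, cfg.reads_fastq],
        out_path=out_sam,
    )
    return out_sam


def run_accurate_aligner(cfg: PipelineConfig, fastq: str, out_sam: str) -> str:
    """NGMLR-style SV-sensitive mapping of the selected read subset."""
    binary = cfg.binary("ngmlr")
    _run(
        [binary, "-x", "pacbio", "-t", str(cfg.threads),
         "-r", cfg.reference_fasta, "-q", fastq, "-o", out_sam]
    )
    return out_sam


def sam_to_sorted_bam(cfg: PipelineConfig, sam: str, out_bam: str) -> str:
    binary = cfg.binary("samtools")
    _run([binary, "sort", "-@", str(cfg.threads), "-o", out_bam, sam])
    _run([binary, "index", out_bam])
    return out_bam


def run_caller_a(cfg: PipelineConfig, bam: str, out_vcf: str) -> str:
    """Sniffles-style caller, asked to emit supporting read names."""
    binary = cfg.binary("sniffles")
    _run([binary, "--input", bam, "--vcf", out_vcf, "--output-rnames",
          "-t", str(cfg.threads)])
    return out_vcf


def run_caller_b(cfg: PipelineConfig, bam: str, out_vcf: str) -> str:
    """SVIM-style caller; read names are on by default in its output."""
    binary = cfg.binary("svim")
    outdir = str(Path(out_vcf).parent / "svim")
    _run([binary, "alignment", outdir, bam, cfg.reference_fasta])
    produced = Path(outdir) / "variants.vcf"
    shutil.copy(produced, out_vcf)
    return out_vcf


# --- orchestration ----------------------------------------------------------


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run stages 1-6, reusing stage products already present in workdir.

    Returns the final merged VCF path and a per-stage report (counts and
    wall-clock seconds). Reruns with the same inputs and seed produce an
    identical final VCF.
    """
    wd = Path(cfg.workdir)
    report: dict[str, dict] = {}

    def fresh(path: Path) -> bool:
        return cfg.force or not path.exists()

    def tick(stage: str, t0: float, **counts) -> None:
        report[stage] = {"seconds": round(time.perf_counter() - t0, 3), **counts}

    # stage 1: fast alignment
    t0 = time.perf_counter()
    fast_sam = cfg.fast_sam or str(wd / "01_fast.sam")
    if cfg.fast_sam is None and fresh(Path(fast_sam)):
        run_fast_aligner(cfg, fast_sam)
    tick("1_fast_alignment", t0, sam=fast_sam)

    # stage 2: features + classification
    t0 = time.perf_counter()
    names, X, split = alignment.features_from_sam(fast_sam)
    alignment.write_feature_table(str(wd / "02_features.tsv"), names, X)
    if cfg.model_path is None:
        raise CapabilityError("a trained classifier model is required (model_path)")
    model = classifier.load_model(cfg.model_path)
    if cfg.classifier_threshold is not None:
        model.threshold = cfg.classifier_threshold
    pred = classifier.classify(model, X)
    labels = {name: int(p) for name, p in zip(names, pred)}
    split_names = {name for name, s in split.items() if s}
    tick(
        "2_find_informative",
        t0,
        reads_seen=len(names),
        classifier_positive=int(pred.sum()),
        split_by_fast_aligner=len(split_names),
    )

    # stage 3: subset + accurate alignment
    t0 = time.perf_counter()
    selection = unify.select_for_realignment(labels, split_names)
    n_extracted = None
    selected_fq = None
    if cfg.reads_fastq is not None:
        selected_fq = str(wd / "03_selected.fastq")
        if fresh(Path(selected_fq)):
            n_extracted = unify.extract_reads_by_name(
                cfg.reads_fastq, selection.names, selected_fq
            )
    accurate_sam = cfg.accurate_sam or str(wd / "03_accurate.sam")
    if cfg.accurate_sam is None and fresh(Path(accurate_sam)):
        if selected_fq is None:
            raise CapabilityError(
                "accurate alignment needs reads_fastq (or supply accurate_sam)"
            )
        run_accurate_aligner(cfg, selected_fq, accurate_sam)
    tick(
        "3_accurate_alignment",
        t0,
        reads_selected=len(selection),
        reads_extracted=n_extracted,
        sam=accurate_sam,
    )

    # stage 4: harmonize + merge (+ BAM when samtools is available)
    t0 = time.perf_counter()
    merged_sam = str(wd / "04_merged.sam")
    n_a, n_b = unify.merge_alignments(fast_sam, accurate_sam, merged_sam)
    merged_bam = None
    if shutil.which(cfg.binaries.get("samtools") or "samtools"):
        merged_bam = sam_to_sorted_bam(cfg, merged_sam, str(wd / "04_merged.bam"))
    tick("4_unify", t0, records_fast=n_a, records_accurate=n_b, bam=merged_bam)

    # stage 5: SV calling
    t0 = time.perf_counter()
    vcf_a = cfg.vcf_a or str(wd / "05_callerA.vcf")
    vcf_b = cfg.vcf_b or str(wd / "05_callerB.vcf")
    if cfg.vcf_a is None and fresh(Path(vcf_a)):
        run_caller_a(cfg, merged_bam or merged_sam, vcf_a)
    if cfg.vcf_b is None and fresh(Path(vcf_b)):
        run_caller_b(cfg, merged_bam or merged_sam, vcf_b)
    calls_a = svmerge.parse_sv_vcf(vcf_a, "callerA", rnames_key=cfg.rnames_key)
    calls_b = svmerge.parse_sv_vcf(vcf_b, "callerB", rnames_key=cfg.rnames_key)
    tick("5_sv_calling", t0, calls_a=len(calls_a), calls_b=len(calls_b))

    # stage 6: unique-support filter + cross-caller merge
    t0 = time.perf_counter()
    min_support = (
        cfg.min_support
        if cfg.min_support is not None
        else svmerge.min_support_threshold(cfg.coverage)
    )
    kept_a = svmerge.filter_min_support(calls_a, min_support)
    kept_b = svmerge.filter_min_support(calls_b, min_support)
    merged = svmerge.merge_calls(kept_a, kept_b, window=cfg.merge_window)
    final_vcf = str(wd / "06_final.vcf")
    svmerge.write_sv_vcf(merged, final_vcf)
    tick(
        "6_filter_redundant",
        t0,
        min_support=min_support,
        kept_a=len(kept_a),
        kept_b=len(kept_b),
        final_calls=len(merged),
    )

    report_path = str(wd / "report.tsv")
    _write_report(report, report_path)
    with open(wd / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return PipelineResult(final_vcf=final_vcf, report=report, report_path=report_path)


def _write_report(report: dict[str, dict], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("stage\tkey\tvalue\n")
        for stage, entries in report.items():
            for key, value in entries.items():
                fh.write(f"{stage}\t{key}\t{value}\n")
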
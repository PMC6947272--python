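"""End-to-end pipeline orchestration and truth-based evaluation.

One run = a barcoded multi-sample flowcell: demultiplex → amplicon
assignment and alignment → error/depth accounting → pileups →
tumor-vs-negative-control calling and filtering → hotspot annotation →
ITD calling → phasing of samples with two PASS variants on one amplicon.
A negative control (healthy donor on the same panel) is mandatory: the
filter chain is anchored on it.  With two NCs a variant must pass
filtering against each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from . import io as nio
from .align import (
    DepthProfile,
    ErrorStats,
    ReadAlignment,
    align_to_panel,
    demultiplex,
    depth_profile,
    error_stats,
)
from .itd import ItdCall, call_itd
from .panel import Panel
from .phase import (
    PhaseCall,
    PhasePartition,
    PhasingError,
    classify_reads,
    phase_call,
    spanning_reads,
)
from .simulate import TruthRecord, VariantSpec
from .variants import (
    FilterConfig,
    HotspotCatalog,
    VariantCall,
    annotate_hotspots,
    call_candidates,
    default_hotspot_catalog,
    filter_somatic,
    pileup,
)

logger = logging.getLogger("nanoamp")

MAX_SAMPLES_PER_RUN = 12  # native barcoding supports 12 barcodes per run


class ConfigurationError(ValueError):
    pass


class RunError(RuntimeError):
    pass


@dataclass(frozen=True)
class SampleSheetEntry:
    sample_id: str
    barcode: str
    role: str  # "tumor" | "negative_control"

    def __post_init__(self) -> None:
        if self.role not in ("tumor", "negative_control"):
            raise ConfigurationError(
                f"sample {self.sample_id}: role must be tumor or negative_control"
            )


@dataclass
class RunConfig:
    panel: Panel
    samples: list[SampleSheetEntry]
    filters: FilterConfig = field(default_factory=FilterConfig)
    hotspots: HotspotCatalog = field(default_factory=default_hotspot_catalog)
    depth_floor: int = 50
    barcode_max_edits: int = 3
    itd_amplicons: Optional[list[str]] = None  # None = scan every amplicon
    itd_min_support: int = 3
    phase_flank_w: int = 5
    seed: int = 0
    output_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        if len(self.samples) > MAX_SAMPLES_PER_RUN:
            raise ConfigurationError(
                f"at most {MAX_SAMPLES_PER_RUN} samples per run, got {len(self.samples)}"
            )
        roles = [s.role for s in self.samples]
        if "negative_control" not in roles:
            raise ConfigurationError(
                "a run requires at least one negative_control sample"
            )
        barcodes = [s.barcode for s in self.samples]
        if len(set(barcodes)) != len(barcodes):
            raise ConfigurationError("sample barcodes must be unique")

    @property
    def tumors(self) -> list[SampleSheetEntry]:
        return [s for s in self.samples if s.role == "tumor"]

    @property
    def negative_controls(self) -> list[SampleSheetEntry]:
        return [s for s in self.samples if s.role == "negative_control"]


@dataclass
class PhaseReport:
    sample_id: str
    amplicon: str
    locus_a: int
    locus_b: int
    partition: PhasePartition
    call: Optional[PhaseCall]
    note: str = ""


@dataclass
class PipelineResult:
    config: RunConfig
    read_counts: dict[str, int]
    alignments: dict[str, dict[str, list[ReadAlignment]]]  # sample → amplicon → alns
    error_stats: list[ErrorStats]
    depths: dict[str, list[DepthProfile]]  # sample → profiles
    calls: dict[str, list[VariantCall]]  # tumor sample → final calls
    itds: dict[str, list[ItdCall]]
    phases: list[PhaseReport]

    def write_outputs(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        panel = self.config.panel
        for sample_id, calls in self.calls.items():
            nio.write_vcf(
                out / f"{sample_id}.vcf", calls, panel,
                sample_id=sample_id, itd_calls=self.itds.get(sample_id, ()),
            )
        (out / "error_stats.tsv").write_text(nio.error_stats_table(self.error_stats))
        depth_lines = []
        for sample_id, profiles in self.depths.items():
            table = nio.depth_table(profiles)
            for line in table.splitlines()[1:]:
                depth_lines.append(f"{sample_id}\t{line}")
        (out / "depth.tsv").write_text(
            "sample\tamplicon\tmin\tmedian\tmax\tmean\tn_low_positions\tfloor\n"
            + "\n".join(depth_lines) + ("\n" if depth_lines else "")
        )
        phase_lines = [
            "sample\tamplicon\tlocus_a\tlocus_b\ta_only\tb_only\tboth\tneither"
            "\tboth_fraction\tconfiguration\tnote"
        ]
        for pr in self.phases:
            part = pr.partition
            cfg = pr.call.configuration if pr.call else "NA"
            phase_lines.append(
                f"{pr.sample_id}\t{pr.amplicon}\t{pr.locus_a}\t{pr.locus_b}"
                f"\t{len(part.a_only)}\t{len(part.b_only)}\t{len(part.both)}"
                f"\t{len(part.neither)}\t{part.both_fraction:.4f}\t{cfg}\t{pr.note}"
            )
        (out / "phase.tsv").write_text("\n".join(phase_lines) + "\n")
        itd_lines = ["sample\tamplicon\tposition\tlength\tn_support\tvaf\tis_tandem"]
        for sample_id, itds in self.itds.items():
            for c in itds:
                itd_lines.append(
                    f"{sample_id}\t{c.amplicon}\t{c.position}\t{c.length}"
                    f"\t{c.n_support}\t{c.vaf:.4f}\t{c.is_tandem}"
                )
        (out / "itd.tsv").write_text("\n".join(itd_lines) + "\n")


def run_pipeline(config: RunConfig, reads: Iterable[tuple[str, str]]) -> PipelineResult:
    """Run the full analysis on a set of barcoded reads.

    Deterministic given identical config and reads.  Raises
    :class:`RunError` when demultiplexing assigns nothing (wrong barcodes or
    empty input).
    """
    reads = list(reads)
    logger.info("run start: %d reads, %d samples", len(reads), len(config.samples))
    barcodes = {s.sample_id: s.barcode for s in config.samples}
    assigned, unassigned = demultiplex(
        reads, barcodes, max_edits=config.barcode_max_edits
    )
    n_assigned = sum(len(v) for v in assigned.values())
    logger.info("demultiplex: %d assigned, %d unassigned", n_assigned, len(unassigned))
    if reads and n_assigned == 0:
        raise RunError("demultiplexing assigned no reads to any sample")

    read_counts = {"total": len(reads), "unassigned": len(unassigned)}
    alignments: dict[str, dict[str, list[ReadAlignment]]] = {}
    for entry in config.samples:
        per_amp, un = align_to_panel(assigned.get(entry.sample_id, []), config.panel)
        alignments[entry.sample_id] = per_amp
        read_counts[entry.sample_id] = sum(len(v) for v in per_amp.values())
        logger.info(
            "sample %s: %d aligned, %d unassignable",
            entry.sample_id, read_counts[entry.sample_id], len(un),
        )

    # pooled per-amplicon error statistics across samples
    stats: list[ErrorStats] = []
    for amp in config.panel:
        pooled = [
            a for per_amp in alignments.values() for a in per_amp.get(amp.name, [])
        ]
        if pooled:
            stats.append(error_stats(pooled, amp.name))

    depths: dict[str, list[DepthProfile]] = {}
    for entry in config.samples:
        depths[entry.sample_id] = [
            depth_profile(
                alignments[entry.sample_id].get(amp.name, []), amp,
                floor=config.depth_floor,
            )
            for amp in config.panel
        ]

    # negative-control pileups per amplicon
    nc_pileups: dict[str, list] = {amp.name: [] for amp in config.panel}
    for nc in config.negative_controls:
        for amp in config.panel:
            cols = pileup(
                alignments[nc.sample_id].get(amp.name, []),
                amp.reference_seq, amp.name,
            )
            nc_pileups[amp.name].append(cols)

    calls: dict[str, list[VariantCall]] = {}
    itds: dict[str, list[ItdCall]] = {}
    phases: list[PhaseReport] = []
    itd_amp_names = config.itd_amplicons or [a.name for a in config.panel]

    for tumor in config.tumors:
        sample_calls: list[VariantCall] = []
        for amp in config.panel:
            alns = alignments[tumor.sample_id].get(amp.name, [])
            if not alns:
                continue
            cols = pileup(alns, amp.reference_seq, amp.name)
            candidates = call_candidates(cols, amp.reference_seq, config.filters)
            final = filter_somatic(candidates, nc_pileups[amp.name], config.filters)
            sample_calls.extend(final)
        annotate_hotspots(sample_calls, config.hotspots, config.panel)
        calls[tumor.sample_id] = sample_calls

        sample_itds: list[ItdCall] = []
        for amp_name in itd_amp_names:
            amp = config.panel[amp_name]
            alns = alignments[tumor.sample_id].get(amp_name, [])
            if not alns:
                continue
            sample_itds.extend(
                call_itd(
                    alns, amp.reference_seq, total_depth=len(alns),
                    min_support=config.itd_min_support, amplicon=amp_name,
                )
            )
        itds[tumor.sample_id] = sample_itds

        # phase any amplicon with ≥ 2 PASS small-variant calls
        by_amp: dict[str, list[VariantCall]] = {}
        for c in sample_calls:
            if c.status == "PASS":
                by_amp.setdefault(c.amplicon, []).append(c)
        for amp_name, amp_calls in by_amp.items():
            if len(amp_calls) < 2:
                continue
            amp = config.panel[amp_name]
            ordered = sorted(amp_calls, key=lambda c: -c.tumor_vaf)[:2]
            va, vb = sorted(ordered, key=lambda c: c.position)
            if va.position == vb.position:
                continue
            alns = alignments[tumor.sample_id].get(amp_name, [])
            spanning = spanning_reads(
                alns, va.position, vb.position, flank_w=config.phase_flank_w
            )
            if not spanning:
                continue
            part = classify_reads(spanning, alns, va, vb)
            try:
                pc = phase_call(part)
                note = ""
            except PhasingError as exc:
                pc = None
                note = str(exc)
            phases.append(
                PhaseReport(
                    sample_id=tumor.sample_id,
                    amplicon=amp_name,
                    locus_a=va.position,
                    locus_b=vb.position,
                    partition=part,
                    call=pc,
                    note=note,
                )
            )

    result = PipelineResult(
        config=config,
        read_counts=read_counts,
        alignments=alignments,
        error_stats=stats,
        depths=depths,
        calls=calls,
        itds=itds,
        phases=phases,
    )
    if config.output_dir is not None:
        result.write_outputs(config.output_dir)
    return result


@dataclass
class VariantOutcome:
    sample_id: str
    description: str
    status: str  # TP | FP | FN
    note: str = ""


@dataclass
class EvaluationReport:
    outcomes: list[VariantOutcome]
    precision: float
    recall: float

    @property
    def n_tp(self) -> int:
        return sum(1 for o in self.outcomes if o.status == "TP")

    @property
    def n_fp(self) -> int:
        return sum(1 for o in self.outcomes if o.status == "FP")

    @property
    def n_fn(self) -> int:
        return sum(1 for o in self.outcomes if o.status == "FN")


def _truth_variants_per_sample(
    truth: Sequence[TruthRecord],
) -> dict[str, set[VariantSpec]]:
    out: dict[str, set[VariantSpec]] = {}
    for rec in truth:
        out.setdefault(rec.sample_id, set()).update(rec.variants)
    return out


def _matches(call: VariantCall, spec: VariantSpec, pos_tol: int = 2) -> bool:
    if call.amplicon != spec.amplicon or call.kind != spec.kind:
        return False
    if abs(call.position - spec.position) > pos_tol:
        return False
    if spec.kind == "SNV":
        return call.alt_allele == spec.alt_allele
    if spec.kind == "INS":
        return call.alt_allele == spec.alt_allele
    if spec.kind == "DEL":
        return len(call.ref_allele) == len(spec.ref_allele)
    return False


def _itd_matches(call: ItdCall, spec: VariantSpec, len_tol: int = 2) -> bool:
    return (
        spec.kind == "ITD"
        and call.amplicon == spec.amplicon
        and call.is_tandem
        and abs(call.length - spec.itd_length) <= len_tol
    )


def evaluate(result: PipelineResult, truth: Sequence[TruthRecord]) -> EvaluationReport:
    """Score pipeline outputs against the simulator's truth table.

    Small variants match by locus (± 2 bp after left-normalization), kind
    and allele; ITDs by tandem-verified length ± 2 bp.  A missed variant at
    a locus flagged below the depth floor is annotated ``low_depth`` — depth
    failure, not filter failure.
    """
    truth_by_sample = _truth_variants_per_sample(truth)
    outcomes: list[VariantOutcome] = []
    n_tp = n_fp = n_fn = 0
    for tumor in result.config.tumors:
        sample_id = tumor.sample_id
        expected = truth_by_sample.get(sample_id, set())
        pass_calls = [c for c in result.calls.get(sample_id, []) if c.status == "PASS"]
        itd_calls = result.itds.get(sample_id, [])
        matched_calls: set[int] = set()
        matched_itds: set[int] = set()
        for spec in sorted(expected, key=lambda v: (v.amplicon, v.position)):
            desc = f"{spec.amplicon}:{spec.position} {spec.kind}"
            if spec.kind == "ITD":
                hit = next(
                    (i for i, c in enumerate(itd_calls)
                     if i not in matched_itds and _itd_matches(c, spec)),
                    None,
                )
                if hit is not None:
                    matched_itds.add(hit)
                    n_tp += 1
                    outcomes.append(VariantOutcome(sample_id, desc, "TP"))
                else:
                    n_fn += 1
                    outcomes.append(VariantOutcome(sample_id, desc, "FN"))
                continue
            hit = next(
                (i for i, c in enumerate(pass_calls)
                 if i not in matched_calls and _matches(c, spec)),
                None,
            )
            if hit is not None:
                matched_calls.add(hit)
                n_tp += 1
                outcomes.append(VariantOutcome(sample_id, desc, "TP"))
            else:
                note = ""
                for profile in result.depths.get(sample_id, []):
                    if profile.amplicon == spec.amplicon:
                        d = profile.depth
                        if 0 < spec.position <= d.size and d[spec.position - 1] < profile.floor:
                            note = "low_depth"
                n_fn += 1
                outcomes.append(VariantOutcome(sample_id, desc, "FN", note))
        for i, c in enumerate(pass_calls):
            if i not in matched_calls:
                n_fp += 1
                outcomes.append(
                    VariantOutcome(
                        sample_id, f"{c.amplicon}:{c.position} {c.kind}", "FP"
                    )
                )
    precision = n_tp / (n_tp + n_fp) if (n_tp + n_fp) else 1.0
    recall = n_tp / (n_tp + n_fn) if (n_tp + n_fn) else 1.0
    return EvaluationReport(outcomes=outcomes, precision=precision, recall=recall)
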
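"""File output: VCF 4.2, minimal SAM, BED and tab-separated reports.

VCF bodies are deterministic (no timestamps) so identical runs produce
byte-identical files.  Small variants are written VCF-style with an anchor
base; ITDs as symbolic ``<DUP:TANDEM>`` records with SVLEN.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

from .align import DepthProfile, ErrorStats, ReadAlignment
from .itd import ItdCall
from .panel import Panel
from .variants import VariantCall

VCF_FILTER_DEFS = [
    ("nc_shared", "Allele present in the negative control above the error cut-off"),
    ("low_delta", "Tumor minus NC VAF difference at or below the minimum"),
    ("high_p", "Fisher exact p-value above the maximum"),
    ("low_depth", "Depth below the minimum at the locus"),
]


def vcf_text(
    calls: Sequence[VariantCall],
    panel: Panel,
    sample_id: str = "SAMPLE",
    itd_calls: Sequence[ItdCall] = (),
) -> str:
    """Render final calls as a VCF 4.2 document with amplicon contigs."""
    lines = ["##fileformat=VCFv4.2", "##source=nanoamp"]
    for amp in panel:
        lines.append(f"##contig=<ID={amp.name},length={amp.length}>")
    lines += [
        '##INFO=<ID=TVAF,Number=1,Type=Float,Description="Tumor variant allele frequency">',
        '##INFO=<ID=NVAF,Number=1,Type=Float,Description="Negative control variant allele frequency">',
        '##INFO=<ID=FP,Number=1,Type=Float,Description="Fisher exact p-value (tumor vs NC)">',
        '##INFO=<ID=HOTSPOT,Number=1,Type=String,Description="AML hotspot label">',
        '##INFO=<ID=GENOMIC,Number=1,Type=String,Description="Genomic coordinate (liftover)">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of structural variant">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">',
        '##ALT=<ID=DUP:TANDEM,Description="Tandem duplication">',
    ]
    for name, desc in VCF_FILTER_DEFS:
        lines.append(f'##FILTER=<ID={name},Description="{desc}">')
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    rows = []
    for c in calls:
        amp = panel[c.amplicon]
        ref_seq = amp.reference_seq or ""
        if c.kind == "SNV":
            pos, ref_a, alt_a = c.position, c.ref_allele, c.alt_allele
        elif c.kind == "INS":
            # anchor base at the attachment position
            pos = c.position
            anchor = ref_seq[pos - 1] if ref_seq else "N"
            ref_a, alt_a = anchor, anchor + c.alt_allele
        else:  # DEL, position = first deleted base
            pos = max(c.position - 1, 1)
            anchor = ref_seq[pos - 1] if ref_seq else "N"
            ref_a, alt_a = anchor + c.ref_allele, anchor
        info = [f"TVAF={c.tumor_vaf:.4f}"]
        if c.nc_vaf is not None:
            info.append(f"NVAF={c.nc_vaf:.4f}")
        if c.fisher_p is not None:
            info.append(f"FP={c.fisher_p:.3e}")
        if c.hotspot:
            info.append(f"HOTSPOT={c.hotspot.replace(' ', '_')}")
        if c.chrom and c.genomic_pos:
            info.append(f"GENOMIC={c.chrom}:{c.genomic_pos}")
        filt = ";".join(sorted(c.filters)) if c.filters else "PASS"
        rows.append((c.amplicon, pos, ref_a, alt_a, filt, ";".join(info)))
    for it in itd_calls:
        amp = panel[it.amplicon]
        ref_seq = amp.reference_seq or ""
        anchor = ref_seq[it.position - 1] if ref_seq else "N"
        info = [
            f"TVAF={it.vaf:.4f}",
            f"SVLEN={it.length}",
            f"SUPPORT={it.n_support}",
        ]
        rows.append((it.amplicon, it.position, anchor, "<DUP:TANDEM>", "PASS", ";".join(info)))

    order = {a.name: i for i, a in enumerate(panel)}
    rows.sort(key=lambda r: (order.get(r[0], 99), r[1]))
    for amp_name, pos, ref_a, alt_a, filt, info in rows:
        lines.append(f"{amp_name}\t{pos}\t.\t{ref_a}\t{alt_a}\t.\t{filt}\t{info}")
    return "\n".join(lines) + "\n"


def write_vcf(path, calls, panel, sample_id="SAMPLE", itd_calls=()) -> None:
    with open(path, "w") as fh:
        fh.write(vcf_text(calls, panel, sample_id, itd_calls))


def sam_text(alignments: Mapping[str, Sequence[ReadAlignment]], panel: Panel) -> str:
    """Minimal SAM (header + M/I/D CIGAR records); sequences omitted."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for amp in panel:
        lines.append(f"@SQ\tSN:{amp.name}\tLN:{amp.length}")
    lines.append("@PG\tID:nanoamp\tPN:nanoamp")
    for amp_name in (a.name for a in panel):
        for aln in alignments.get(amp_name, ()):
            lines.append(
                f"{aln.read_id}\t0\t{amp_name}\t{aln.ref_start}\t60\t{aln.cigar()}"
                f"\t*\t0\t0\t*\t*\tAS:i:{aln.score}"
            )
    return "\n".join(lines) + "\n"


def write_sam(path, alignments, panel) -> None:
    with open(path, "w") as fh:
        fh.write(sam_text(alignments, panel))


def bed_text(panel: Panel) -> str:
    """Amplicon intervals as BED (0-based half-open genomic coordinates)."""
    lines = []
    for amp in panel:
        lines.append(
            f"{amp.interval.chrom}\t{amp.interval.start - 1}\t{amp.interval.end}"
            f"\t{amp.name}\t0\t+"
        )
    return "\n".join(lines) + "\n"


def error_stats_table(stats: Iterable[ErrorStats]) -> str:
    lines = ["amplicon\tn_reads\tidentical_pct\tins_pct\tdel_pct\tsub_pct"]
    for s in stats:
        lines.append(
            f"{s.amplicon}\t{s.n_reads}\t{s.identical_pct}\t{s.ins_pct}"
            f"\t{s.del_pct}\t{s.sub_pct}"
        )
    return "\n".join(lines) + "\n"


def depth_table(profiles: Iterable[DepthProfile]) -> str:
    lines = ["amplicon\tmin\tmedian\tmax\tmean\tn_low_positions\tfloor"]
    for p in profiles:
        s = p.summary()
        lines.append(
            f"{p.amplicon}\t{s['min']:.0f}\t{s['median']:.0f}\t{s['max']:.0f}"
            f"\t{s['mean']:.1f}\t{len(p.low_positions)}\t{p.floor}"
        )
    return "\n".join(lines) + "\n"
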
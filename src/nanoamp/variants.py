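"""Pileup-based somatic variant calling against a negative control.

The caller follows the filtering strategy of the assay this package models:
candidate alleles need a minimum VAF of 10% (SNV) or 15% (INDEL) and 50×
depth; a candidate whose VAF in the negative control (NC, a healthy donor
sequenced on the same panel) stays at or below the 7% panel-wide error
ceiling passes directly, while a candidate also present in the NC above
that ceiling must show a tumor−NC VAF difference above 10% *and* a one-sided
Fisher exact p ≤ 0.01 on the allele counts.  Recurrent homopolymer artifacts
appear at similar VAF in tumor and NC and are removed by this comparison.
No multiple-testing correction is applied (fixed p cut-off by design).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

from .align import ReadAlignment
from .panel import Amplicon, Panel


class VariantCallingError(ValueError):
    pass


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the somatic filter chain."""

    min_vaf_snv: float = 0.10
    min_vaf_indel: float = 0.15
    nc_error_cutoff: float = 0.07
    min_vaf_delta: float = 0.10
    max_p: float = 0.01
    min_depth: int = 50

    def __post_init__(self) -> None:
        for name in ("min_vaf_snv", "min_vaf_indel", "nc_error_cutoff",
                     "min_vaf_delta", "max_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise VariantCallingError(f"{name} must be in (0,1), got {v}")
        if self.min_depth < 1:
            raise VariantCallingError("min_depth must be ≥ 1")


@dataclass
class PileupColumn:
    """Allele counts at one reference position.

    Keys of ``allele_counts``: a plain base for match/substitution alleles,
    ``ins<SEQ>`` for an insertion attached to this (preceding) position, and
    ``del<L>`` for a deletion of L bases starting at this position.  A read
    carrying an insertion supports the insertion allele instead of its
    anchor base, so allele counts never exceed depth.
    """

    amplicon: str
    position: int
    depth: int = 0
    allele_counts: dict[str, int] = field(default_factory=dict)

    def vaf(self, allele: str) -> float:
        if self.depth == 0:
            return 0.0
        return self.allele_counts.get(allele, 0) / self.depth


@dataclass
class VariantCall:
    """A candidate or final somatic call in amplicon coordinates."""

    amplicon: str
    position: int
    ref_allele: str
    alt_allele: str
    kind: str  # SNV | INS | DEL
    tumor_vaf: float
    tumor_alt: int = 0
    tumor_depth: int = 0
    nc_vaf: Optional[float] = None
    nc_alt: int = 0
    nc_depth: int = 0
    fisher_p: Optional[float] = None
    filters: set[str] = field(default_factory=set)
    hotspot: Optional[str] = None
    chrom: Optional[str] = None
    genomic_pos: Optional[int] = None

    @property
    def status(self) -> str:
        return "PASS" if not self.filters else "FAIL"

    @property
    def allele_key(self) -> str:
        if self.kind == "SNV":
            return self.alt_allele
        if self.kind == "INS":
            return f"ins{self.alt_allele}"
        return f"del{len(self.ref_allele)}"


def pileup(
    alignments: Sequence[ReadAlignment], amplicon_ref: str, amplicon: str = ""
) -> list[PileupColumn]:
    """Per-position allele counts over one amplicon.

    Insertions are attached to the preceding reference position (alignments
    are already left-normalized); deletions are keyed by length at their
    first deleted position, with depth maintained across the deleted span.
    """
    n = len(amplicon_ref)
    name = amplicon or (alignments[0].amplicon if alignments else "")
    columns = [PileupColumn(amplicon=name, position=p + 1) for p in range(n)]

    for aln in alignments:
        pos = aln.ref_start  # 1-based next reference position to consume
        start = pos
        last_key_pos: Optional[int] = None
        last_key: Optional[str] = None
        for op, length, seq in aln.ops:
            if op == "match":
                for t in range(length):
                    base = amplicon_ref[pos - 1 + t]
                    col = columns[pos - 1 + t]
                    col.allele_counts[base] = col.allele_counts.get(base, 0) + 1
                last_key_pos, last_key = pos + length - 1, amplicon_ref[pos + length - 2]
                pos += length
            elif op == "mismatch":
                for t in range(length):
                    col = columns[pos - 1 + t]
                    base = seq[t]
                    col.allele_counts[base] = col.allele_counts.get(base, 0) + 1
                last_key_pos, last_key = pos + length - 1, seq[-1]
                pos += length
            elif op == "del":
                key = f"del{length}"
                col = columns[pos - 1]
                col.allele_counts[key] = col.allele_counts.get(key, 0) + 1
                last_key_pos, last_key = None, None
                pos += length
            else:  # ins
                key = f"ins{seq}"
                anchor = pos - 1  # preceding reference position
                if anchor >= 1:
                    col = columns[anchor - 1]
                    # the carrying read supports the insertion allele instead
                    # of its anchor base
                    if last_key_pos == anchor and last_key is not None:
                        cnt = col.allele_counts.get(last_key, 0)
                        if cnt > 0:
                            col.allele_counts[last_key] = cnt - 1
                    col.allele_counts[key] = col.allele_counts.get(key, 0) + 1
                last_key_pos, last_key = None, None
        end = pos - 1
        for p in range(start, min(end, n) + 1):
            columns[p - 1].depth += 1
    return columns


def _merge_insertion_alleles(allele_counts: Mapping[str, int]) -> dict[str, int]:
    """Absorb error-corrupted copies of an insertion allele into its majority form.

    Nanopore noise corrupts a real inserted sequence in a fraction of the
    carrying reads, scattering the support over near-identical keys and
    deflating the measured VAF.  Keys within a small edit distance of a more
    frequent insertion key (≤ 1 plus one per 8 bases of the representative)
    are pooled under it; unrelated singleton noise inserts stay separate.
    """
    import edlib

    ins_items = sorted(
        ((k, v) for k, v in allele_counts.items() if k.startswith("ins")),
        key=lambda kv: (-kv[1], kv[0]),
    )
    if len(ins_items) <= 1:
        return dict(allele_counts)
    out = {k: v for k, v in allele_counts.items() if not k.startswith("ins")}
    reps: list[tuple[str, int]] = []
    for key, count in ins_items:
        seq = key[3:]
        merged = False
        for i, (rep_key, rep_count) in enumerate(reps):
            rep_seq = rep_key[3:]
            tol = 1 + len(rep_seq) // 8
            d = edlib.align(seq, rep_seq, task="distance", k=tol)["editDistance"]
            if 0 <= d <= tol:
                reps[i] = (rep_key, rep_count + count)
                merged = True
                break
        if not merged:
            reps.append((key, count))
    out.update(dict(reps))
    return out


def call_candidates(
    columns: Sequence[PileupColumn],
    amplicon_ref: str,
    cfg: FilterConfig = FilterConfig(),
) -> list[VariantCall]:
    """Tumor-side candidate alleles above the class VAF threshold.

    Loci passing the VAF threshold but sitting below ``min_depth`` are
    emitted with a ``low_depth`` filter rather than silently dropped, so a
    depth failure shows up in reports.
    """
    calls: list[VariantCall] = []
    for col in columns:
        if col.depth == 0:
            continue
        ref_base = amplicon_ref[col.position - 1]
        counts = _merge_insertion_alleles(col.allele_counts)
        for allele, count in sorted(counts.items()):
            if allele == ref_base:
                continue
            vaf = count / col.depth
            if allele.startswith("ins"):
                kind, ref_a, alt_a = "INS", ref_base, allele[3:]
                threshold = cfg.min_vaf_indel
            elif allele.startswith("del"):
                length = int(allele[3:])
                kind = "DEL"
                ref_a = amplicon_ref[col.position - 1 : col.position - 1 + length]
                alt_a = ""
                threshold = cfg.min_vaf_indel
            else:
                kind, ref_a, alt_a = "SNV", ref_base, allele
                threshold = cfg.min_vaf_snv
            if vaf < threshold:
                continue
            call = VariantCall(
                amplicon=col.amplicon,
                position=col.position,
                ref_allele=ref_a,
                alt_allele=alt_a,
                kind=kind,
                tumor_vaf=vaf,
                tumor_alt=count,
                tumor_depth=col.depth,
            )
            if col.depth < cfg.min_depth:
                call.filters.add("low_depth")
            calls.append(call)
    return calls


def fisher_test(
    tumor_alt: int,
    tumor_depth: int,
    nc_alt: int,
    nc_depth: int,
    alternative: str = "greater",
) -> float:
    """One-sided Fisher exact test for tumor allele enrichment over the NC.

    Returns the hypergeometric tail probability of observing at least
    ``tumor_alt`` alt reads in the tumor given the table margins
    (alternative: tumor VAF > NC VAF).  Pass ``alternative="two-sided"``
    for the symmetric test.
    """
    if tumor_depth <= 0 or nc_depth <= 0:
        raise VariantCallingError("fisher_test requires positive depths")
    if tumor_alt > tumor_depth or nc_alt > nc_depth:
        raise VariantCallingError("alt count exceeds depth")
    table = [
        [tumor_alt, tumor_depth - tumor_alt],
        [nc_alt, nc_depth - nc_alt],
    ]
    return float(stats.fisher_exact(table, alternative=alternative).pvalue)


def filter_somatic(
    tumor_candidates: Sequence[VariantCall],
    nc_pileups: Sequence[Sequence[PileupColumn]] | Sequence[PileupColumn],
    cfg: FilterConfig = FilterConfig(),
) -> list[VariantCall]:
    """Apply the NC-anchored somatic filter chain to tumor candidates.

    ``nc_pileups`` is one pileup (list of columns) or several (one per NC);
    with several, a candidate must pass filtering against each (filters are
    unioned).  A candidate locus missing from an NC pileup is an error: the
    NC must be sequenced on the same panel.
    """
    if nc_pileups and isinstance(nc_pileups[0], PileupColumn):
        nc_sets = [nc_pileups]  # type: ignore[list-item]
    else:
        nc_sets = list(nc_pileups)  # type: ignore[arg-type]
    if not nc_sets or any(not s for s in nc_sets):
        raise VariantCallingError(
            "somatic filtering requires a non-empty negative-control pileup"
        )
    indexed = [
        {col.position: col for col in nc_set} for nc_set in nc_sets
    ]

    out: list[VariantCall] = []
    for cand in tumor_candidates:
        call = replace(cand, filters=set(cand.filters))
        worst_nc_vaf = 0.0
        for nc_index in indexed:
            col = nc_index.get(cand.position)
            if col is None or col.depth == 0:
                raise VariantCallingError(
                    f"candidate locus {cand.amplicon}:{cand.position} absent from "
                    "the negative-control pileup"
                )
            nc_count = col.allele_counts.get(cand.allele_key, 0)
            nc_vaf = nc_count / col.depth
            if nc_vaf > worst_nc_vaf:
                worst_nc_vaf = nc_vaf
                call.nc_alt = nc_count
                call.nc_depth = col.depth
            elif call.nc_depth == 0:
                call.nc_alt = nc_count
                call.nc_depth = col.depth
            if nc_vaf <= cfg.nc_error_cutoff:
                continue  # clean in this NC
            delta = cand.tumor_vaf - nc_vaf
            p = fisher_test(cand.tumor_alt, cand.tumor_depth, nc_count, col.depth)
            if call.fisher_p is None or p > call.fisher_p:
                call.fisher_p = p
            failures: set[str] = set()
            if delta <= cfg.min_vaf_delta:
                failures.add("low_delta")
            if p > cfg.max_p:
                failures.add("high_p")
            if failures:
                call.filters |= {"nc_shared"} | failures
        call.nc_vaf = worst_nc_vaf
        out.append(call)
    return out


# ---------------------------------------------------------------------------
# Hotspot catalog and cohort summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HotspotRule:
    """Insertion-class hotspot: frameshift insertions of a given length
    inside a genomic window (the NPM1 exon-11 pattern)."""

    gene: str
    label: str
    chrom: str
    window_start: int
    window_end: int
    ins_length: int


@dataclass
class HotspotCatalog:
    """Exact-locus SNV hotspots plus insertion-window rules."""

    snv_loci: dict[tuple[str, int], str] = field(default_factory=dict)
    rules: list[HotspotRule] = field(default_factory=list)


def default_hotspot_catalog() -> HotspotCatalog:
    """The AML hotspot catalog: NPM1 p.W288fs, FLT3 p.D835, IDH1 p.R132,
    IDH2 p.R140 and p.R172 (GRCh37 loci)."""
    return HotspotCatalog(
        snv_loci={
            ("chr13", 28592642): "FLT3 p.D835",
            ("chr2", 209113113): "IDH1 p.R132",
            ("chr15", 90631934): "IDH2 p.R140",
            ("chr15", 90631838): "IDH2 p.R172",
        },
        rules=[
            HotspotRule(
                gene="NPM1",
                label="NPM1 p.W288fs",
                chrom="chr5",
                window_start=170837530,
                window_end=170837560,
                ins_length=4,
            )
        ],
    )


def annotate_hotspots(
    calls: Iterable[VariantCall],
    catalog: Optional[HotspotCatalog] = None,
    panel: Optional[Panel] = None,
) -> list[VariantCall]:
    """Attach amino-acid hotspot labels to calls (in place; returns the list).

    Calls need genomic coordinates; when absent they are derived from the
    panel amplicon intervals.
    """
    catalog = catalog or default_hotspot_catalog()
    out = []
    for call in calls:
        chrom, gpos = call.chrom, call.genomic_pos
        if (chrom is None or gpos is None) and panel is not None and call.amplicon:
            amp = panel[call.amplicon]
            chrom = amp.interval.chrom
            gpos = amp.to_genomic(call.position)
            call.chrom, call.genomic_pos = chrom, gpos
        if chrom is None or gpos is None:
            out.append(call)
            continue
        if call.kind == "SNV":
            label = catalog.snv_loci.get((chrom, gpos))
            if label:
                call.hotspot = label
        elif call.kind == "INS":
            for rule in catalog.rules:
                if (
                    chrom == rule.chrom
                    and rule.window_start <= gpos <= rule.window_end
                    and len(call.alt_allele) == rule.ins_length
                    and rule.ins_length % 3 != 0  # frameshift
                ):
                    call.hotspot = rule.label
                    break
        out.append(call)
    return out


def cohort_hotspot_summary(
    per_case_calls: Mapping[str, Sequence[VariantCall]]
) -> dict[str, int]:
    """Cases positive per hotspot category, plus the total hotspot count."""
    categories = [
        "NPM1 p.W288fs", "FLT3 p.D835", "IDH1 p.R132", "IDH2 p.R140", "IDH2 p.R172",
    ]
    counts = {c: 0 for c in categories}
    for case, calls in per_case_calls.items():
        labels = {c.hotspot for c in calls if c.hotspot}
        for label in labels:
            if label in counts:
                counts[label] += 1
    counts["total"] = sum(counts[c] for c in categories)
    return counts


def cohort_final_calls(cohort_df) -> dict[str, list[VariantCall]]:
    """Convert the validated-cohort table into per-case final call records.

    Only rows adjudicated positive are kept.  Genotype strings encode the
    allele change: ``-/SEQ`` is an insertion, ``XY../X`` a deletion, equal
    single bases an SNV, anything else an indel-like replacement.
    """
    out: dict[str, list[VariantCall]] = {}
    for row in cohort_df.itertuples(index=False):
        out.setdefault(row.case, [])
        if row.final_status != "positive":
            continue
        ref_g, alt_g = str(row.genotype).split("/")
        if ref_g == "-":
            kind, ref_a, alt_a = "INS", "", alt_g
        elif len(ref_g) == 1 and len(alt_g) == 1:
            kind, ref_a, alt_a = "SNV", ref_g, alt_g
        elif len(ref_g) > len(alt_g) and ref_g.startswith(alt_g):
            kind, ref_a, alt_a = "DEL", ref_g[len(alt_g):], ""
        else:
            kind, ref_a, alt_a = "INS", ref_g, alt_g
        vaf_str = row.minion_vaf if row.minion == "YES" else row.s5_vaf
        vaf = float(vaf_str) / 100.0 if vaf_str else 0.0
        out[row.case].append(
            VariantCall(
                amplicon="",
                position=0,
                ref_allele=ref_a,
                alt_allele=alt_a,
                kind=kind,
                tumor_vaf=vaf,
                chrom=row.chrom,
                genomic_pos=int(row.pos),
            )
        )
    return out
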
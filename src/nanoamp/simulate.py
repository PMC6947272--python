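"""Nanopore-like amplicon read simulation with a machine-readable truth table.

The simulator emulates the dominant features of nanopore amplicon data that
the downstream pipeline has to cope with:

* per-amplicon insertion / deletion / substitution rates, expressed as events
  per 100 alignment columns (the same convention the error-stats estimator
  reports), with multi-base indel events of geometric length;
* elevated deletion rates inside homopolymer runs — the classic nanopore
  failure mode that produces recurrent, high-VAF artifacts;
* sample barcodes ligated at the read 5' end;
* spiked variants (SNVs, small insertions/deletions, internal tandem
  duplications) at chosen allele fractions, with phase groups so that
  co-segregating (cis) and mutually exclusive (trans) configurations can be
  simulated for read-backed phasing.

Every read carries exactly one truth record, so calls can be scored against
ground truth.  Given identical inputs and seed the output is byte-identical.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .panel import Amplicon, GenomicInterval, Panel, PanelError, PrimerPair

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"
_BASE_INDEX = np.zeros(256, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[_b] = _i

# Mean event lengths for the geometric indel-length model.  An insertion
# event has length 1 + Geom(p=0.5) - 1 extra bases (mean 2.0); a deletion
# event 1 + Geom(p=0.7) - 1 (mean ~1.43).  Initiation probabilities are
# scaled by these so the expected per-column rates equal the profile rates.
_INS_EXTRA_P = 0.5
_DEL_EXTRA_P = 0.7
_MEAN_INS_LEN = 1.0 + (1.0 - _INS_EXTRA_P) / _INS_EXTRA_P
_MEAN_DEL_LEN = 1.0 + (1.0 - _DEL_EXTRA_P) / _DEL_EXTRA_P

# Internal seed for the synthetic reference sequences of the built-in panel.
# Fixed so that amplicon coordinates are stable across sessions; unrelated to
# user-facing simulation seeds.
_REFERENCE_SEED = 715


class SimulationError(ValueError):
    """Raised for invalid simulation inputs."""


@dataclass(frozen=True)
class ErrorProfile:
    """Per-amplicon error rates, in events per 100 alignment columns.

    ``homopolymer_del_boost`` is the extra deletion weight per additional base
    of the homopolymer run containing a position; the per-position weights are
    renormalised so the aggregate deletion rate stays at ``del_rate``.
    """

    ins_rate: float
    del_rate: float
    sub_rate: float
    homopolymer_del_boost: float = 0.5

    def __post_init__(self) -> None:
        for label, rate in (("ins", self.ins_rate), ("del", self.del_rate),
                            ("sub", self.sub_rate)):
            if not 0 <= rate < 50:
                raise SimulationError(f"{label}_rate must be in [0, 50), got {rate}")
        if self.ins_rate + self.del_rate + self.sub_rate >= 100:
            raise SimulationError("total error rate must be < 100 per 100 columns")
        if self.homopolymer_del_boost < 0:
            raise SimulationError("homopolymer_del_boost must be non-negative")

    @property
    def identity_rate(self) -> float:
        return 100.0 - self.ins_rate - self.del_rate - self.sub_rate


@dataclass(frozen=True)
class VariantSpec:
    """A variant to spike into simulated reads.

    Position is a 1-based offset within the amplicon.  Conventions:

    * SNV: ``ref_allele``/``alt_allele`` are single differing bases at
      ``position``.
    * INS: ``alt_allele`` is the inserted sequence, placed immediately after
      ``position`` (the anchor base).
    * DEL: ``ref_allele`` is the deleted sequence starting at ``position``.
    * ITD: ``itd_length`` bases ending at ``position`` are duplicated, the
      copy inserted immediately after ``position``.

    ``phase_group`` labels co-segregating variants: variants sharing a group
    always ride the same haplotype; distinct groups are mutually exclusive
    alleles (trans).
    """

    kind: str
    amplicon: str
    position: int
    ref_allele: str = ""
    alt_allele: str = ""
    itd_length: int = 0
    vaf: float = 0.0
    phase_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("SNV", "INS", "DEL", "ITD"):
            raise SimulationError(f"unknown variant kind {self.kind!r}")
        if not 0 <= self.vaf <= 1:
            raise SimulationError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.position < 1:
            raise SimulationError("position must be a 1-based offset ≥ 1")
        if self.kind == "SNV":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1 \
                    or self.ref_allele == self.alt_allele:
                raise SimulationError("SNV needs single differing ref/alt bases")
        if self.kind == "INS" and not self.alt_allele:
            raise SimulationError("INS needs a non-empty inserted sequence")
        if self.kind == "DEL" and not self.ref_allele:
            raise SimulationError("DEL needs a non-empty deleted sequence")
        if self.kind == "ITD" and self.itd_length < 1:
            raise SimulationError("ITD needs itd_length ≥ 1")

    @property
    def group_key(self) -> str:
        if self.phase_group is not None:
            return f"group:{self.phase_group}"
        return f"solo:{self.amplicon}:{self.kind}:{self.position}:{self.alt_allele}:{self.itd_length}"


@dataclass(frozen=True)
class SimSample:
    """One barcoded sample in a simulated run."""

    sample_id: str
    barcode: str
    variants: tuple[VariantSpec, ...] = ()
    depth_per_amplicon: int = 100

    def __post_init__(self) -> None:
        if self.depth_per_amplicon < 1:
            raise SimulationError("depth_per_amplicon must be ≥ 1")


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    sample_id: str
    amplicon: str
    variants: tuple[VariantSpec, ...]


@dataclass
class SimResult:
    """Simulated reads plus their truth table."""

    reads: list[tuple[str, str]]  # (read_id, sequence)
    truth: list[TruthRecord]

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.fastq_text())

    def fastq_text(self) -> str:
        buf = io.StringIO()
        for read_id, seq in self.reads:
            buf.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
        return buf.getvalue()

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tsample_id\tamplicon\tvariants\n")
            for rec in self.truth:
                desc = ";".join(
                    f"{v.kind}@{v.position}"
                    + (f":{v.alt_allele}" if v.kind in ("SNV", "INS") else "")
                    + (f":len{len(v.ref_allele)}" if v.kind == "DEL" else "")
                    + (f":len{v.itd_length}" if v.kind == "ITD" else "")
                    for v in rec.variants
                )
                fh.write(f"{rec.read_id}\t{rec.sample_id}\t{rec.amplicon}\t{desc}\n")


def apply_variants(reference: str, variants: Sequence[VariantSpec]) -> str:
    """Apply variants to an amplicon reference, producing a haplotype."""
    seq = reference
    for v in sorted(variants, key=lambda v: v.position, reverse=True):
        pos = v.position
        if pos > len(seq):
            raise SimulationError(
                f"variant position {pos} outside amplicon of length {len(reference)}"
            )
        if v.kind == "SNV":
            if reference[pos - 1] != v.ref_allele:
                raise SimulationError(
                    f"SNV ref allele {v.ref_allele} does not match reference base "
                    f"{reference[pos - 1]} at position {pos}"
                )
            seq = seq[: pos - 1] + v.alt_allele + seq[pos:]
        elif v.kind == "INS":
            seq = seq[:pos] + v.alt_allele + seq[pos:]
        elif v.kind == "DEL":
            if reference[pos - 1 : pos - 1 + len(v.ref_allele)] != v.ref_allele:
                raise SimulationError(
                    f"DEL ref allele mismatch at position {pos}"
                )
            seq = seq[: pos - 1] + seq[pos - 1 + len(v.ref_allele):]
        elif v.kind == "ITD":
            if v.itd_length > pos:
                raise SimulationError("ITD length exceeds available upstream sequence")
            segment = seq[pos - v.itd_length : pos]
            seq = seq[:pos] + segment + seq[pos:]
    return seq


def homopolymer_del_weights(seq: str, boost_per_base: float, cap: float = 5.0) -> np.ndarray:
    """Per-position deletion weight: min(1 + boost·(run_len − 1), cap)."""
    n = len(seq)
    weights = np.ones(n)
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = j - i
        weights[i:j] = min(1.0 + boost_per_base * (run - 1), cap)
        i = j
    return weights


def corrupt_read(seq: str, profile: ErrorProfile, rng: np.random.Generator) -> str:
    """Corrupt a haplotype with the profile's per-column error process.

    The process walks the sequence position by position.  Before each
    position an insertion event may fire; the position itself is then either
    the start of a deletion event, a substitution, or a match.  Initiation
    probabilities are derived from the per-100-column rates so that the
    expected composition of alignment columns matches the profile.
    """
    ri = profile.ins_rate / 100.0
    rd = profile.del_rate / 100.0
    rs = profile.sub_rate / 100.0
    n = len(seq)
    if n == 0:
        return ""
    if ri == rd == rs == 0:
        return seq

    weights = homopolymer_del_weights(seq, profile.homopolymer_del_boost)
    weights /= weights.mean()

    # Per-opportunity initiation probabilities (see docs/methods.md):
    # non-insertion column fractions among all non-ins columns.
    denom = max(1.0 - ri, 1e-9)
    f_d = min(rd / denom, 0.95)
    f_s = min(rs / denom, 0.95)
    # q_d solves q_d·E_Ld/(q_d·E_Ld + 1 − q_d) = f_d  (uniform-weight case)
    q_d_base = f_d / (_MEAN_DEL_LEN * (1.0 - f_d) + f_d)
    consumed_per_opp = q_d_base * _MEAN_DEL_LEN + (1.0 - q_d_base)
    q_s = f_s * consumed_per_opp
    q_i = ri * consumed_per_opp / (max(1.0 - ri, 1e-9) * _MEAN_INS_LEN)

    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(int(n * (1.0 + ri * 4 + 0.05)) + 64, dtype=np.uint8)
    # Pre-draw uniforms in bulk for speed; top up if exhausted.
    draws = rng.random(2 * n + 64)
    di = 0

    def u() -> float:
        nonlocal di, draws
        if di >= len(draws):
            draws = rng.random(n + 64)
            di = 0
        val = draws[di]
        di += 1
        return val

    oi = 0
    i = 0
    while i < n:
        # insertion before position i
        if u() < q_i:
            extra = rng.geometric(_INS_EXTRA_P) - 1
            length = 1 + extra
            ins = _BASES[rng.integers(0, 4, size=length)]
            if oi + length >= len(out):
                out = np.concatenate([out, np.empty(n, dtype=np.uint8)])
            out[oi : oi + length] = ins
            oi += length
        r = u()
        q_d_here = q_d_base * weights[i]
        if r < q_d_here:
            extra = rng.geometric(_DEL_EXTRA_P) - 1
            i += 1 + extra  # skip deleted bases
            continue
        if r < q_d_here + q_s:
            bidx = int(_BASE_INDEX[arr[i]])
            choice = int(rng.integers(0, 3))
            if choice >= bidx:
                choice += 1  # skip the reference base among ACGT
            alt = _BASES[choice]
            if oi >= len(out):
                out = np.concatenate([out, np.empty(n, dtype=np.uint8)])
            out[oi] = alt
            oi += 1
            i += 1
            continue
        if oi >= len(out):
            out = np.concatenate([out, np.empty(n, dtype=np.uint8)])
        out[oi] = arr[i]
        oi += 1
        i += 1
    return out[:oi].tobytes().decode()


_CALIBRATION_SEED = 90021
_calibration_cache: dict[tuple, ErrorProfile] = {}


def calibrate_profile(
    profile: ErrorProfile,
    reference: str,
    rounds: int = 2,
    pilot_reads: int = 120,
) -> ErrorProfile:
    """Adjust raw generator rates so aligner-measured rates match the profile.

    Error-profile rates are defined in measurement space: events per 100
    columns of the *optimal* alignment, which is how per-amplicon error rates
    are estimated from real runs.  Optimal realignment of a corrupted read
    absorbs a fraction of the generated events (an inserted base can extend a
    matching context, errors collide), so raw generation at the nominal rates
    under-shoots on re-measurement by several relative percent.  A short
    pilot simulation (fixed internal seed, deterministic) iteratively
    inflates the raw rates until the re-measured rates agree with the
    nominal ones; results are cached per (profile, reference).
    """
    from .align import align_read, error_stats  # deferred: avoid import cycle

    if profile.ins_rate == profile.del_rate == profile.sub_rate == 0:
        return profile
    key = (
        profile.ins_rate, profile.del_rate, profile.sub_rate,
        profile.homopolymer_del_boost, len(reference), hash(reference),
    )
    if key in _calibration_cache:
        return _calibration_cache[key]

    nominal = np.array([profile.ins_rate, profile.del_rate, profile.sub_rate])
    raw = nominal.copy()
    for _ in range(rounds):
        p = ErrorProfile(float(raw[0]), float(raw[1]), float(raw[2]),
                         homopolymer_del_boost=profile.homopolymer_del_boost)
        rng = np.random.default_rng(_CALIBRATION_SEED)
        alns = [align_read(corrupt_read(reference, p, rng), reference)
                for _ in range(pilot_reads)]
        st = error_stats(alns, "calibration")
        measured = np.array([st.ins_pct, st.del_pct, st.sub_pct])
        ratio = np.where(nominal > 0, nominal / np.maximum(measured, 1e-3), 1.0)
        raw = np.clip(raw * np.clip(ratio, 0.5, 2.0), 0.0, 45.0)
    calibrated = ErrorProfile(float(raw[0]), float(raw[1]), float(raw[2]),
                              homopolymer_del_boost=profile.homopolymer_del_boost)
    _calibration_cache[key] = calibrated
    return calibrated


def generate_barcodes(
    n: int, length: int = 24, seed: int = 7, min_edit_distance: int = 8
) -> list[str]:
    """Random barcodes with pairwise edit distance ≥ ``min_edit_distance``."""
    import edlib

    rng = np.random.default_rng(seed)
    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < n:
        attempts += 1
        if attempts > 10000:
            raise SimulationError("could not generate sufficiently distinct barcodes")
        cand = "".join(_BASE_STR[i] for i in rng.integers(0, 4, size=length))
        if all(
            edlib.align(cand, b, task="distance")["editDistance"] >= min_edit_distance
            for b in barcodes
        ):
            barcodes.append(cand)
    return barcodes


def _choose_haplotype(
    variants: Sequence[VariantSpec], rng: np.random.Generator
) -> tuple[VariantSpec, ...]:
    """Draw the set of variants carried by one read.

    Variants are grouped by phase group; groups are treated as mutually
    exclusive alleles drawn from one multinomial (so trans pairs never
    co-occur pre-noise), and all members of the chosen group co-segregate.
    """
    if not variants:
        return ()
    groups: dict[str, list[VariantSpec]] = {}
    for v in variants:
        groups.setdefault(v.group_key, []).append(v)
    keys = sorted(groups)
    vafs = np.array([max(v.vaf for v in groups[k]) for k in keys])
    total = vafs.sum()
    if total > 1.0 + 1e-9:
        raise SimulationError(
            f"summed haplotype fractions exceed 1 ({total:.3f}); "
            "mutually exclusive variant groups must have total VAF ≤ 1"
        )
    r = rng.random()
    acc = 0.0
    for k, p in zip(keys, vafs):
        acc += p
        if r < acc:
            return tuple(groups[k])
    return ()


def simulate_reads(
    panel: Panel,
    samples: Sequence[SimSample],
    profiles: Optional[Mapping[str, ErrorProfile]] = None,
    seed: int = 0,
    amplicons: Optional[Sequence[str]] = None,
    calibrate: bool = True,
) -> SimResult:
    """Simulate barcoded amplicon reads for a multi-sample run.

    For every sample and amplicon, ``depth_per_amplicon`` reads are drawn:
    a haplotype is chosen from the sample's variant groups, the variants are
    applied, the sequence is corrupted with the amplicon's error profile, and
    the sample barcode is prepended.  Deterministic given the seed.
    """
    if profiles is None:
        profiles = {}
    barcodes = [s.barcode for s in samples if s.barcode]
    if len(set(barcodes)) != len(barcodes):
        raise SimulationError("sample barcodes must be unique within a run")
    amp_names = list(amplicons) if amplicons is not None else panel.names
    for name in amp_names:
        panel[name]  # raises KeyError if absent
    for s in samples:
        for v in s.variants:
            amp = panel[v.amplicon]
            if v.position > len(amp.reference_seq or ""):
                raise SimulationError(
                    f"variant at position {v.position} outside amplicon {v.amplicon}"
                )

    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    truth: list[TruthRecord] = []
    for sample in samples:
        for amp_name in amp_names:
            amp = panel[amp_name]
            if amp.reference_seq is None:
                raise SimulationError(f"amplicon {amp_name} has no reference sequence")
            profile = profiles.get(amp_name) or amp.error_profile
            if profile is None:
                profile = ErrorProfile(0.0, 0.0, 0.0)
            if calibrate:
                profile = calibrate_profile(profile, amp.reference_seq)
            amp_variants = [v for v in sample.variants if v.amplicon == amp_name]
            # cache haplotype strings per carried-variant combination
            hap_cache: dict[tuple[VariantSpec, ...], str] = {}
            for idx in range(sample.depth_per_amplicon):
                carried = _choose_haplotype(amp_variants, rng)
                if carried not in hap_cache:
                    hap_cache[carried] = apply_variants(amp.reference_seq, carried)
                noisy = corrupt_read(hap_cache[carried], profile, rng)
                read_id = f"{sample.sample_id}.{amp_name}.{idx:06d}"
                reads.append((read_id, sample.barcode + noisy))
                truth.append(TruthRecord(read_id, sample.sample_id, amp_name, carried))
    return SimResult(reads=reads, truth=truth)


def read_truth(path, panel: Panel) -> list[TruthRecord]:
    """Read a truth table written by :meth:`SimResult.write_truth`.

    Reference alleles are reconstructed from the panel references (the
    table stores the compact ``KIND@pos[:detail]`` encoding).
    """
    records: list[TruthRecord] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            read_id, sample_id, amp_name, desc = line.rstrip("\n").split("\t")
            ref = panel[amp_name].reference_seq or ""
            variants: list[VariantSpec] = []
            for token in filter(None, desc.split(";")):
                kind, rest = token.split("@", 1)
                if ":" in rest:
                    pos_s, detail = rest.split(":", 1)
                else:
                    pos_s, detail = rest, ""
                pos = int(pos_s)
                if kind == "SNV":
                    variants.append(VariantSpec(
                        kind="SNV", amplicon=amp_name, position=pos,
                        ref_allele=ref[pos - 1], alt_allele=detail))
                elif kind == "INS":
                    variants.append(VariantSpec(
                        kind="INS", amplicon=amp_name, position=pos,
                        alt_allele=detail))
                elif kind == "DEL":
                    length = int(detail[3:])
                    variants.append(VariantSpec(
                        kind="DEL", amplicon=amp_name, position=pos,
                        ref_allele=ref[pos - 1 : pos - 1 + length]))
                else:
                    variants.append(VariantSpec(
                        kind="ITD", amplicon=amp_name, position=pos,
                        itd_length=int(detail[3:])))
            records.append(TruthRecord(read_id, sample_id, amp_name, tuple(variants)))
    return records


# ---------------------------------------------------------------------------
# Built-in fixtures: the 10-amplicon AML panel and the validated cohort table.
# ---------------------------------------------------------------------------

def _random_reference(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASE_STR[i] for i in rng.integers(0, 4, size=length))


def builtin_panel() -> tuple[Panel, dict[str, ErrorProfile]]:
    """The built-in 10-amplicon AML panel with measured error profiles.

    Intervals, primers, pool memberships and per-amplicon error rates are the
    assay's published values; the attached reference sequences are synthetic
    (random with a fixed internal seed, correct lengths), not genome sequence,
    so panel coordinates are display-only.
    """
    text = resources.files("nanoamp.data").joinpath("aml_panel.tsv").read_text()
    df = pd.read_csv(io.StringIO(text), sep="\t")
    rng = np.random.default_rng(_REFERENCE_SEED)
    amplicons: list[Amplicon] = []
    profiles: dict[str, ErrorProfile] = {}
    for row in df.itertuples(index=False):
        interval = GenomicInterval(row.chrom, int(row.start), int(row.end))
        profile = ErrorProfile(
            ins_rate=float(row.ins_pct),
            del_rate=float(row.del_pct),
            sub_rate=float(row.sub_pct),
        )
        amp = Amplicon(
            name=row.name,
            gene=row.gene,
            interval=interval,
            primers=PrimerPair(row.fwd_primer, row.rev_primer),
            pool_id=int(row.pool),
            reference_seq=_random_reference(interval.end - interval.start, rng),
            error_profile=profile,
        )
        amplicons.append(amp)
        profiles[amp.name] = profile
    return Panel(amplicons=amplicons, genome_build="GRCh37"), profiles


def builtin_panel_table() -> pd.DataFrame:
    """The built-in panel spec as a DataFrame (one row per amplicon)."""
    text = resources.files("nanoamp.data").joinpath("aml_panel.tsv").read_text()
    return pd.read_csv(io.StringIO(text), sep="\t")


def validation_cohort() -> pd.DataFrame:
    """Per-case validated variant table for the 22-patient AML cohort.

    One row per reported variant with per-platform detection flags and VAFs
    (nanopore and semiconductor sequencing, plus Sanger for discordant calls)
    and a ``final_status`` adjudication: Sanger decides where evaluated,
    otherwise concordant detection on both platforms counts as positive.
    """
    text = resources.files("nanoamp.data").joinpath("aml_cohort_variants.tsv").read_text()
    df = pd.read_csv(io.StringIO(text), sep="\t", keep_default_na=False,
                     dtype={"minion_vaf": str, "s5_vaf": str})

    def adjudicate(row) -> str:
        if row.sanger == "YES":
            return "positive"
        if row.sanger == "NO":
            return "negative"
        # not evaluated: platforms concordant by construction
        return "positive" if (row.minion == "YES" and row.s5 == "YES") else "negative"

    df["final_status"] = [adjudicate(r) for r in df.itertuples(index=False)]
    return df
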
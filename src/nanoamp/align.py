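"""Demultiplexing, amplicon assignment, pairwise alignment and error accounting.

Reads are assigned to samples by barcode prefix edit distance, to amplicons
by edit-distance screening against the panel references, and then aligned
with a glocal affine-gap dynamic program: read overhangs (barcode remnants,
ragged ends) cost a mild linear penalty, while unaligned reference ends are
charged as deletion gaps and stripped from the reported alignment.  Error
statistics follow the per-100-alignment-columns
convention: the denominator counts every column (match + mismatch + ins +
del), under which the identity/ins/del/sub percentages of an amplicon sum
to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np

from . import _aligndp
from .panel import Amplicon, Panel

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

DEFAULT_SCORES = {"match": 2, "mismatch": -3, "gap_open": -4, "gap_extend": -1,
                  "read_overhang": -1}


class AlignmentError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadAlignment:
    """A read-vs-amplicon alignment as an explicit edit script.

    ``ops`` is an ordered list of ``(op, length, seq)`` with op in
    {"match", "mismatch", "ins", "del"}; ``seq`` carries the read bases for
    insertion and mismatch runs and is empty otherwise.
    ``ref_start``/``read_start`` are 1-based offsets of the first aligned base.
    """

    read_id: str
    amplicon: str
    ops: list[tuple[str, int, str]]
    ref_start: int
    read_start: int
    score: int

    @property
    def ref_span(self) -> int:
        return sum(l for op, l, _ in self.ops if op in ("match", "mismatch", "del"))

    @property
    def read_span(self) -> int:
        return sum(l for op, l, _ in self.ops if op in ("match", "mismatch", "ins"))

    @property
    def ref_end(self) -> int:
        """1-based inclusive end position on the reference."""
        return self.ref_start + self.ref_span - 1

    def column_count(self) -> int:
        return sum(l for _, l, _ in self.ops)

    def cigar(self) -> str:
        out = []
        for op, length, _ in self.ops:
            code = {"match": "M", "mismatch": "M", "ins": "I", "del": "D"}[op]
            if out and out[-1][1] == code:
                out[-1] = (out[-1][0] + length, code)
            else:
                out.append((length, code))
        return "".join(f"{l}{c}" for l, c in out)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _left_normalize(columns: list[tuple[int, int, int]], ref: str, read: str) -> None:
    """Shift indel runs left while the flanking context permits (in place).

    ``columns`` holds (opcode, ref_idx, read_idx) with 0-based indices valid
    for the consuming sequence(s).  Left-aligned indels give stable variant
    coordinates (VCF-style normalization).
    """
    OP_M, OP_X, OP_I, OP_D = 0, 1, 2, 3
    changed = True
    while changed:
        changed = False
        k = 0
        ncols = len(columns)
        while k < ncols:
            op = columns[k][0]
            if op not in (OP_I, OP_D):
                k += 1
                continue
            # find the run
            end = k
            while end + 1 < ncols and columns[end + 1][0] == op:
                end += 1
            # try shifting the run left while preceded by a match column
            while k > 0 and columns[k - 1][0] == OP_M:
                prev = columns[k - 1]
                if op == OP_D:
                    # deleting ref[a..b]; shift if ref[b] == ref[a-1]
                    a = columns[k][1]
                    b = columns[end][1]
                    if ref[b] != ref[a - 1]:
                        break
                    # rotate: deletion becomes a-1..b-1, match moves to ref[b]
                    new_cols = [(OP_D, a - 1 + t, -1) for t in range(b - a + 1)]
                    match_col = (OP_M, b, prev[2])
                    columns[k - 1 : end + 1] = new_cols + [match_col]
                else:
                    a = columns[k][2]
                    b = columns[end][2]
                    if read[b] != read[a - 1]:
                        break
                    new_cols = [(OP_I, -1, a - 1 + t) for t in range(b - a + 1)]
                    match_col = (OP_M, prev[1], b)
                    columns[k - 1 : end + 1] = new_cols + [match_col]
                k -= 1
                end -= 1
                changed = True
            k = end + 1


def align_read(
    read_seq: str,
    amplicon_ref: str,
    scores: Optional[Mapping[str, int]] = None,
    read_id: str = "",
    amplicon: str = "",
) -> ReadAlignment:
    """Optimal ends-free affine-gap alignment of a read to an amplicon reference.

    Tie-breaking is deterministic (match > mismatch > del > ins at equal
    score) and indel runs are left-normalized after traceback so variant
    coordinates are stable.
    """
    if not read_seq or not amplicon_ref:
        raise AlignmentError("both sequences must be non-empty")
    sc = dict(DEFAULT_SCORES)
    if scores:
        sc.update(scores)
    ref_arr = _encode(amplicon_ref)
    read_arr = _encode(read_seq)
    score, i0, j0, i1, j1, op_arr = _aligndp.align_full(
        ref_arr, read_arr, sc["match"], sc["mismatch"], sc["gap_open"],
        sc["gap_extend"], sc["read_overhang"]
    )

    # expand to column triples for normalization
    OP_M, OP_X, OP_I, OP_D = 0, 1, 2, 3
    columns: list[tuple[int, int, int]] = []
    ri, qi = int(i0), int(j0)
    ref_u = amplicon_ref.upper()
    read_u = read_seq.upper()
    for code in op_arr:
        c = int(code)
        if c in (OP_M, OP_X):
            columns.append((OP_M if ref_u[ri] == read_u[qi] else OP_X, ri, qi))
            ri += 1
            qi += 1
        elif c == OP_I:
            columns.append((OP_I, -1, qi))
            qi += 1
        else:
            columns.append((OP_D, ri, -1))
            ri += 1

    # Terminal deletion runs (unmatched reference ends, paid for in the
    # score) are stripped for reporting: the read simply does not cover
    # those reference positions.
    while columns and columns[0][0] == OP_D:
        columns.pop(0)
    while columns and columns[-1][0] == OP_D:
        columns.pop()

    _left_normalize(columns, ref_u, read_u)

    # re-encode as run-length ops, reclassifying match/mismatch post-shift
    ops: list[tuple[str, int, str]] = []
    names = {OP_M: "match", OP_X: "mismatch", OP_I: "ins", OP_D: "del"}
    k = 0
    while k < len(columns):
        op = columns[k][0]
        end = k
        while end + 1 < len(columns) and columns[end + 1][0] == op:
            end += 1
        length = end - k + 1
        if op == OP_I:
            inserted = "".join(read_u[columns[t][2]] for t in range(k, end + 1))
            ops.append(("ins", length, inserted))
        elif op == OP_X:
            observed = "".join(read_u[columns[t][2]] for t in range(k, end + 1))
            ops.append(("mismatch", length, observed))
        else:
            ops.append((names[op], length, ""))
        k = end + 1

    # recompute starts after normalization (first consuming column)
    ref_start = next((c[1] for c in columns if c[1] >= 0), int(i0)) + 1
    read_start = next((c[2] for c in columns if c[2] >= 0), int(j0)) + 1
    return ReadAlignment(
        read_id=read_id,
        amplicon=amplicon,
        ops=ops,
        ref_start=ref_start,
        read_start=read_start,
        score=int(score),
    )


def demultiplex(
    reads: Iterable[tuple[str, str]],
    barcodes: Mapping[str, str],
    max_edits: int = 3,
    trim: bool = True,
) -> tuple[dict[str, list[tuple[str, str]]], list[tuple[str, str]]]:
    """Assign reads to samples by 5' barcode prefix edit distance.

    A read is assigned to the unique barcode whose prefix edit distance is
    minimal and ≤ ``max_edits``; ties and no-hits land in the unassigned bin.
    Both orientations are tried; reverse-orientation reads are normalized to
    forward orientation.  With ``trim`` the matched barcode prefix is removed.
    """
    items = list(barcodes.items())
    if len({b for _, b in items}) != len(items):
        raise AlignmentError("duplicate barcodes in configuration")
    for sample, bc in items:
        if not bc:
            raise AlignmentError(f"sample {sample} has an empty barcode")

    assigned: dict[str, list[tuple[str, str]]] = {s: [] for s, _ in items}
    unassigned: list[tuple[str, str]] = []
    window = max(len(b) for _, b in items) + max_edits + 4

    for read_id, seq in reads:
        best: list[tuple[int, str, str, int]] = []  # (dist, sample, oriented_seq, end)
        for oriented in (seq, reverse_complement(seq)):
            prefix = oriented[:window]
            for sample, bc in items:
                res = edlib.align(bc, prefix, mode="SHW", task="locations")
                d = res["editDistance"]
                if d < 0 or d > max_edits:
                    continue
                end = res["locations"][0][1] + 1 if res["locations"] else len(bc)
                best.append((d, sample, oriented, end))
        if not best:
            unassigned.append((read_id, seq))
            continue
        best.sort(key=lambda t: t[0])
        if len(best) > 1 and best[0][0] == best[1][0] and best[0][1] != best[1][1]:
            unassigned.append((read_id, seq))
            continue
        d, sample, oriented, end = best[0]
        assigned[sample].append((read_id, oriented[end:] if trim else oriented))
    return assigned, unassigned


def assign_amplicon(
    read_seq: str,
    panel: Panel,
    min_score_frac: float = 0.5,
    scores: Optional[Mapping[str, int]] = None,
) -> Optional[str]:
    """Assign a read to the best-matching panel amplicon, or None.

    Candidates are ranked by edit distance of each amplicon reference against
    the read (infix mode); the winner must then reach ``min_score_frac`` of
    its perfect-match affine score.  Ties go to panel order.
    """
    name = _screen_amplicon(read_seq, panel)
    if name is None:
        return None
    sc = dict(DEFAULT_SCORES)
    if scores:
        sc.update(scores)
    aln = align_read(read_seq, panel[name].reference_seq, sc)
    perfect = sc["match"] * len(panel[name].reference_seq)
    if aln.score < min_score_frac * perfect:
        return None
    return name


def _screen_amplicon(read_seq: str, panel: Panel) -> Optional[str]:
    best_name = None
    best_d = None
    for amp in panel:
        ref = amp.reference_seq
        if ref is None:
            continue
        d = edlib.align(ref, read_seq, mode="HW", task="distance")["editDistance"]
        if best_d is None or d < best_d:
            best_d = d
            best_name = amp.name
    return best_name


def align_to_panel(
    reads: Iterable[tuple[str, str]],
    panel: Panel,
    min_score_frac: float = 0.5,
    scores: Optional[Mapping[str, int]] = None,
) -> tuple[dict[str, list[ReadAlignment]], list[str]]:
    """Assign and align every read; returns per-amplicon alignments + unassigned ids."""
    sc = dict(DEFAULT_SCORES)
    if scores:
        sc.update(scores)
    out: dict[str, list[ReadAlignment]] = {a.name: [] for a in panel}
    unassigned: list[str] = []
    for read_id, seq in reads:
        name = _screen_amplicon(seq, panel)
        if name is None:
            unassigned.append(read_id)
            continue
        ref = panel[name].reference_seq
        aln = align_read(seq, ref, sc, read_id=read_id, amplicon=name)
        if aln.score < min_score_frac * sc["match"] * len(ref):
            unassigned.append(read_id)
            continue
        out[name].append(aln)
    return out, unassigned


@dataclass(frozen=True)
class ErrorStats:
    """Pooled per-amplicon error percentages per 100 alignment columns."""

    amplicon: str
    identical_pct: float
    ins_pct: float
    del_pct: float
    sub_pct: float
    n_reads: int

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.identical_pct, self.ins_pct, self.del_pct, self.sub_pct)


def _largest_remainder_percent(counts: Sequence[int], decimals: int = 1) -> list[float]:
    """Percentages rounded to ``decimals`` that sum to exactly 100."""
    total = sum(counts)
    if total == 0:
        raise AlignmentError("no alignment columns")
    scale = 10 ** decimals
    raw = [c / total * 100 * scale for c in counts]
    floors = [int(x) for x in raw]
    shortfall = 100 * scale - sum(floors)
    remainders = sorted(
        range(len(raw)), key=lambda i: (raw[i] - floors[i], -i), reverse=True
    )
    for i in remainders[:shortfall]:
        floors[i] += 1
    return [f / scale for f in floors]


def error_stats(alignments: Sequence[ReadAlignment], amplicon: str = "") -> ErrorStats:
    """Pooled error statistics over a set of alignments on one amplicon."""
    if not alignments:
        raise AlignmentError("error_stats requires at least one alignment")
    counts = {"match": 0, "mismatch": 0, "ins": 0, "del": 0}
    for aln in alignments:
        for op, length, _ in aln.ops:
            counts[op] += length
    pct = _largest_remainder_percent(
        [counts["match"], counts["ins"], counts["del"], counts["mismatch"]]
    )
    name = amplicon or alignments[0].amplicon
    return ErrorStats(
        amplicon=name,
        identical_pct=pct[0],
        ins_pct=pct[1],
        del_pct=pct[2],
        sub_pct=pct[3],
        n_reads=len(alignments),
    )


@dataclass
class DepthProfile:
    """Per-position depth over an amplicon with a low-depth floor flag."""

    amplicon: str
    depth: np.ndarray
    floor: int = 50

    @property
    def low_positions(self) -> np.ndarray:
        """1-based positions whose depth is below the floor."""
        return np.flatnonzero(self.depth < self.floor) + 1

    @property
    def any_low(self) -> bool:
        return bool((self.depth < self.floor).any())

    def summary(self) -> dict[str, float]:
        d = self.depth
        return {
            "min": float(d.min()) if d.size else 0.0,
            "median": float(np.median(d)) if d.size else 0.0,
            "max": float(d.max()) if d.size else 0.0,
            "mean": float(d.mean()) if d.size else 0.0,
        }


def depth_profile(
    alignments: Sequence[ReadAlignment], amplicon: Amplicon, floor: int = 50
) -> DepthProfile:
    """Depth at each reference position = reads whose aligned span covers it."""
    n = amplicon.length
    depth = np.zeros(n, dtype=np.int64)
    for aln in alignments:
        if aln.amplicon and aln.amplicon != amplicon.name:
            raise AlignmentError(
                f"alignment on {aln.amplicon} passed to depth_profile({amplicon.name})"
            )
        start = aln.ref_start - 1
        end = min(start + aln.ref_span, n)
        depth[start:end] += 1
    return DepthProfile(amplicon=amplicon.name, depth=depth, floor=floor)
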
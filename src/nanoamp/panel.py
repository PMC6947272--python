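"""Amplicon panel model: target intervals, primers, pooling and depth balance.

An amplicon panel is an ordered set of PCR targets, each with a genomic
interval, a primer pair, an optional multiplex pool id and an attached
reference sequence.  Amplicons amplified in one multiplex pool must have
similar lengths so that a single extension time suits all of them; the
panel model enforces a configurable maximum within-pool length spread and
can recompute a minimal pooling from scratch.
"""

from __future__ import annotations

import itertools
import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from Bio import SeqIO

_DNA = set("ACGT")


class PanelError(ValueError):
    """Raised for malformed panel specs or inconsistent amplicon data."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based genomic interval ``chrom:start-end``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise PanelError("interval chromosome must be non-empty")
        if self.end <= self.start:
            raise PanelError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    def __str__(self) -> str:  # pragma: no cover - display helper
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse PCR primers, plain ACGT by default."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq:
                raise PanelError(f"{label} primer is empty")
            if not set(seq.upper()) <= _DNA:
                raise PanelError(
                    f"{label} primer contains non-ACGT characters: {seq!r}"
                )


@dataclass(frozen=True)
class Amplicon:
    """One PCR target with its interval, primers and reference sequence.

    The panel length convention is ``end - start`` (see :func:`amplicon_length`);
    ``reference_seq``, when attached, must have exactly that length.
    """

    name: str
    gene: str
    interval: GenomicInterval
    primers: PrimerPair
    pool_id: Optional[int] = None
    reference_seq: Optional[str] = None
    error_profile: Optional[object] = None  # simulate.ErrorProfile, kept loose

    def __post_init__(self) -> None:
        if self.reference_seq is not None:
            expected = amplicon_length(self)
            if len(self.reference_seq) != expected:
                raise PanelError(
                    f"amplicon {self.name}: reference length {len(self.reference_seq)} "
                    f"does not match declared length {expected}"
                )

    @property
    def length(self) -> int:
        return amplicon_length(self)

    def to_genomic(self, position: int) -> int:
        """Map a 1-based offset within the amplicon to a genomic coordinate."""
        return self.interval.start + position - 1

    def from_genomic(self, genomic_pos: int) -> int:
        """Map a genomic coordinate to a 1-based offset within the amplicon."""
        return genomic_pos - self.interval.start + 1


@dataclass
class Panel:
    """An ordered amplicon collection tied to one genome build."""

    amplicons: list[Amplicon] = field(default_factory=list)
    genome_build: str = "GRCh37"
    max_amplicons: int = 96

    def __post_init__(self) -> None:
        if not 1 <= len(self.amplicons) <= self.max_amplicons:
            raise PanelError(
                f"panel must contain between 1 and {self.max_amplicons} amplicons, "
                f"got {len(self.amplicons)}"
            )
        names = [a.name for a in self.amplicons]
        if len(set(names)) != len(names):
            raise PanelError("amplicon names must be unique within a panel")

    def __iter__(self):
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def __getitem__(self, name: str) -> Amplicon:
        for a in self.amplicons:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.amplicons]

    @property
    def total_target_size(self) -> int:
        return sum(amplicon_length(a) for a in self.amplicons)


def amplicon_length(a: Amplicon) -> int:
    """Amplicon length in bp under the panel convention ``end - start``.

    Panel documentation in this assay reports lengths as the plain coordinate
    difference (half-open style), not the inclusive ``end - start + 1``; every
    declared amplicon length in the built-in panel matches this convention, so
    it is adopted package-wide.  Pileup and variant positions remain ordinary
    1-based coordinates.
    """
    return a.interval.end - a.interval.start


PANEL_SPEC_COLUMNS = [
    "name", "gene", "chrom", "start", "end", "fwd_primer", "rev_primer", "pool",
]


def load_panel(panel_spec_path, references_path, genome_build: str = "GRCh37") -> Panel:
    """Load a panel from a tab-separated spec plus a FASTA of reference sequences.

    The spec is tab-separated with a header line
    ``name gene chrom start end fwd_primer rev_primer pool``; the FASTA must
    contain one record per spec row, keyed by amplicon name.  ``pool`` may be
    empty (unassigned).
    """
    refs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(references_path), "fasta")}

    amplicons: list[Amplicon] = []
    with open(panel_spec_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(PANEL_SPEC_COLUMNS)] != PANEL_SPEC_COLUMNS:
            raise PanelError(
                f"panel spec header must start with {PANEL_SPEC_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise PanelError(f"panel spec row {lineno}: expected ≥7 fields")
            row = dict(zip(PANEL_SPEC_COLUMNS, fields))
            try:
                interval = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
            except (KeyError, ValueError) as exc:
                raise PanelError(f"panel spec row {lineno}: malformed interval ({exc})")
            name = row["name"]
            if name not in refs:
                raise PanelError(
                    f"amplicon {name!r} (row {lineno}) has no matching FASTA record"
                )
            pool_raw = row.get("pool", "")
            pool_id = int(pool_raw) if pool_raw not in ("", None) else None
            amplicons.append(
                Amplicon(
                    name=name,
                    gene=row["gene"],
                    interval=interval,
                    primers=PrimerPair(row["fwd_primer"], row["rev_primer"]),
                    pool_id=pool_id,
                    reference_seq=refs[name],
                )
            )
    if not amplicons:
        raise PanelError("no amplicons in panel spec")
    return Panel(amplicons=amplicons, genome_build=genome_build)


def partition_pools(
    amplicons: Iterable[Amplicon],
    max_len_diff: int = 400,
    incompatible_pairs: Optional[set[tuple[str, str]]] = None,
) -> dict[str, int]:
    """Assign amplicons to multiplex pools under a length-spread constraint.

    Within each pool the longest and shortest amplicon may differ by at most
    ``max_len_diff`` bp.  Without incompatibilities a sorted greedy sweep is
    used, which yields the minimum possible number of pools for the length
    constraint (points on a line, fixed-width grouping).  With an
    ``incompatible_pairs`` set (unordered name pairs that must not share a
    pool) a greedy first-fit is used instead, with no minimality guarantee.
    """
    if max_len_diff <= 0:
        raise PanelError("max_len_diff must be positive")
    amps = sorted(amplicons, key=lambda a: (amplicon_length(a), a.name))
    incompat: set[frozenset[str]] = {
        frozenset(p) for p in (incompatible_pairs or set())
    }

    assignment: dict[str, int] = {}
    if not incompat:
        pool = 0
        pool_min: Optional[int] = None
        for a in amps:
            length = amplicon_length(a)
            if pool_min is None or length - pool_min > max_len_diff:
                pool += 1
                pool_min = length
            assignment[a.name] = pool
        return assignment

    pools: list[list[Amplicon]] = []
    for a in amps:
        length = amplicon_length(a)
        placed = False
        for pid, members in enumerate(pools):
            lengths = [amplicon_length(m) for m in members]
            if max(lengths + [length]) - min(lengths + [length]) > max_len_diff:
                continue
            if any(frozenset((a.name, m.name)) in incompat for m in members):
                continue
            members.append(a)
            assignment[a.name] = pid + 1
            placed = True
            break
        if not placed:
            pools.append([a])
            assignment[a.name] = len(pools)
    return assignment


def with_pool_assignment(panel: Panel, assignment: Mapping[str, int]) -> Panel:
    """Return a copy of the panel with pool ids replaced by ``assignment``."""
    amps = [replace(a, pool_id=assignment.get(a.name, a.pool_id)) for a in panel]
    return Panel(amplicons=amps, genome_build=panel.genome_build,
                 max_amplicons=panel.max_amplicons)


def balance_recommendation(observed_depths: Mapping[str, float]) -> dict[str, float]:
    """Recommend per-amplicon primer concentration multipliers.

    The multiplier is ``median_depth / depth`` snapped to the nearest power of
    two (…, 0.25, 0.5, 1, 2, 4, …), mirroring how under-represented amplicons
    get their primer concentration doubled or quadrupled and over-represented
    ones halved.  Amplicons within a factor √2 of the median are left at 1×.
    """
    if not observed_depths:
        return {}
    for name, depth in observed_depths.items():
        if depth <= 0:
            raise PanelError(f"amplicon {name} has non-positive depth; amplicon failed")
    med = statistics.median(observed_depths.values())
    out: dict[str, float] = {}
    for name, depth in observed_depths.items():
        ratio = med / depth
        if 2 ** -0.5 <= ratio <= 2 ** 0.5:
            out[name] = 1.0
            continue
        # snap log2(ratio) to the nearest integer exponent
        import math
        exponent = round(math.log2(ratio))
        out[name] = float(2.0 ** exponent)
    return out


def brute_force_min_pools(lengths: list[int], max_len_diff: int) -> int:
    """Minimum pool count by exhaustive partition search (reference oracle).

    Exponential; intended for n ≤ 10.  Used to validate the greedy sweep.
    """
    n = len(lengths)
    if n == 0:
        return 0

    best = n

    def feasible(group: tuple[int, ...]) -> bool:
        vals = [lengths[i] for i in group]
        return max(vals) - min(vals) <= max_len_diff

    def recurse(remaining: tuple[int, ...], count: int) -> None:
        nonlocal best
        if count >= best:
            return
        if not remaining:
            best = min(best, count)
            return
        first, rest = remaining[0], remaining[1:]
        # enumerate subsets of rest joining `first`
        for r in range(len(rest), -1, -1):
            for combo in itertools.combinations(rest, r):
                group = (first,) + combo
                if feasible(group):
                    left = tuple(i for i in rest if i not in combo)
                    recurse(left, count + 1)

    recurse(tuple(range(n)), 0)
    return best
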
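"""Ascertainment of young, lineage-specific element insertions.

Takes RepeatMasker ``.out`` annotations plus assemblies, applies the
full-length and young-element filters, extracts candidate loci with 600 bp
flanks, calls per-comparison-genome shared/unique status by anchoring the
flanks with exact k-mer seeds and measuring the orthologous gap size, assigns
each element to a subfamily consensus, and proportionally selects candidates
per subfamily.

Coordinates are 1-based inclusive in the ``.out`` dialect and converted to
0-based half-open internally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from .simulate import AluConsensus, revcomp

FLANK_LENGTH = 600
DEFAULT_GAP_TOLERANCE = 15
DEFAULT_ANCHOR_K = 25
MAX_TSD_SCAN = 30

FULL_LENGTH_MIN_BP = 267       # minimum element length
FULL_LENGTH_MAX_OFFSET = 4     # max bp missing from the 5' consensus start
YOUNG_MAX_DIVERGENCE = 2.0     # percent divergence ceiling for "young"


class RepeatMaskerParseError(ValueError):
    pass


@dataclass
class RepeatAnnotation:
    """One RepeatMasker ``.out`` alignment record (1-based inclusive coords)."""

    query_name: str
    begin: int
    end: int
    strand: str  # '+' or 'C'
    repeat_name: str
    percent_divergence: float
    repeat_begin: int  # 1-based start of the match in the consensus
    sw_score: int = 1000
    percent_deleted: float = 0.0
    percent_inserted: float = 0.0
    repeat_class: str = "SINE/Alu"
    query_left: int = 0
    repeat_end: int = 0
    repeat_left: int = 0
    rm_id: int = 0

    def __post_init__(self):
        if self.begin > self.end:
            raise ValueError(f"begin {self.begin} > end {self.end}")
        if not 0 <= self.percent_divergence <= 100:
            raise ValueError("percent divergence outside [0,100]")
        if self.repeat_begin < 1:
            raise ValueError("repeat_begin must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.begin + 1

    @property
    def interval(self) -> tuple[int, int]:
        """0-based half-open query interval."""
        return self.begin - 1, self.end


@dataclass
class CandidateLocus:
    """An element with flanks and per-comparison-genome orthology status."""

    locus_id: str
    scaffold: str
    start: int  # 0-based half-open
    end: int
    element_sequence: str
    left_flank: str
    right_flank: str
    subfamily: str = ""
    divergence: float = 0.0
    orientation: str = "+"
    truncated_flanks: bool = False
    status: dict[str, str] = field(default_factory=dict)

    @property
    def coordinates(self) -> str:
        """``scaffold:begin-end`` in 1-based inclusive convention."""
        return f"{self.scaffold}:{self.start + 1}-{self.end}"


# ---------------------------------------------------------------------------
# RepeatMasker .out IO
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^\s*(SW|score|$)")


def parse_repeatmasker_out(path: str | Path) -> list[RepeatAnnotation]:
    """Parse a RepeatMasker ``.out`` table.

    Handles the standard 14/15-column dialect, including the right-to-left
    repeat-coordinate convention of C-strand (reverse) hits, where columns
    12-14 are ``(left) end begin`` instead of ``begin end (left)``.
    """
    out: list[RepeatAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _HEADER_RE.match(line):
                continue
            fields = line.split()
            if len(fields) < 14:
                raise RepeatMaskerParseError(
                    f"{path}:{lineno}: expected >=14 fields, got {len(fields)}"
                )
            try:
                strand = fields[8]
                if strand == "+":
                    rep_begin, rep_end, rep_left = fields[11], fields[12], fields[13]
                elif strand in ("C", "-"):
                    rep_left, rep_end, rep_begin = fields[11], fields[12], fields[13]
                    strand = "C"
                else:
                    raise ValueError(f"bad strand {strand!r}")
                rec = RepeatAnnotation(
                    sw_score=int(fields[0]),
                    percent_divergence=float(fields[1]),
                    percent_deleted=float(fields[2]),
                    percent_inserted=float(fields[3]),
                    query_name=fields[4],
                    begin=int(fields[5]),
                    end=int(fields[6]),
                    query_left=int(fields[7].strip("()")),
                    strand=strand,
                    repeat_name=fields[9],
                    repeat_class=fields[10],
                    repeat_begin=int(rep_begin.strip("()")),
                    repeat_end=int(rep_end),
                    repeat_left=int(rep_left.strip("()")),
                    rm_id=int(fields[14]) if len(fields) > 14 else 0,
                )
            except (ValueError, IndexError) as exc:
                raise RepeatMaskerParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(rec)
    return out


def write_repeatmasker_out(
    annotations: Iterable[RepeatAnnotation], path: str | Path
) -> None:
    header = (
        "   SW  perc perc perc  query      position in query           matching"
        "       repeat              position in  repeat\n"
        "score  div. del. ins.  sequence    begin     end    (left)    repeat"
        "         class/family         begin  end (left)   ID\n\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, a in enumerate(annotations, start=1):
            if a.strand == "+":
                rep_cols = f"{a.repeat_begin} {a.repeat_end} ({a.repeat_left})"
            else:
                rep_cols = f"({a.repeat_left}) {a.repeat_end} {a.repeat_begin}"
            fh.write(
                f"{a.sw_score} {a.percent_divergence:.1f} {a.percent_deleted:.1f} "
                f"{a.percent_inserted:.1f} {a.query_name} {a.begin} {a.end} "
                f"({a.query_left}) {a.strand} {a.repeat_name} {a.repeat_class} "
                f"{rep_cols} {a.rm_id or i}\n"
            )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_full_length(
    annotations: Sequence[RepeatAnnotation],
    min_length: int = FULL_LENGTH_MIN_BP,
    max_start_offset: int = FULL_LENGTH_MAX_OFFSET,
) -> list[RepeatAnnotation]:
    """Keep elements >= ``min_length`` bp starting within ``max_start_offset``
    bp of the consensus 5' start (repeat_begin <= max_start_offset + 1)."""
    return [
        a
        for a in annotations
        if a.length >= min_length and a.repeat_begin <= max_start_offset + 1
    ]


def filter_young(
    annotations: Sequence[RepeatAnnotation],
    max_divergence: float = YOUNG_MAX_DIVERGENCE,
) -> list[RepeatAnnotation]:
    """Keep elements with consensus divergence <= ``max_divergence`` percent."""
    if max_divergence < 0:
        raise ValueError("max_divergence must be >= 0")
    return [a for a in annotations if a.percent_divergence <= max_divergence]


# ---------------------------------------------------------------------------
# candidate extraction
# ---------------------------------------------------------------------------

def extract_candidates(
    annotations: Sequence[RepeatAnnotation],
    assembly: Mapping[str, str],
    flank: int = FLANK_LENGTH,
    locus_prefix: str = "locus",
) -> list[CandidateLocus]:
    """Cut element + ``flank`` bp of flanking sequence out of the assembly."""
    out = []
    for i, a in enumerate(annotations, start=1):
        seq = assembly[a.query_name]
        start, end = a.interval
        left = seq[max(0, start - flank) : start]
        right = seq[end : end + flank]
        out.append(
            CandidateLocus(
                locus_id=f"{locus_prefix}_{i:04d}",
                scaffold=a.query_name,
                start=start,
                end=end,
                element_sequence=seq[start:end],
                left_flank=left,
                right_flank=right,
                orientation="+" if a.strand == "+" else "-",
                truncated_flanks=len(left) < flank or len(right) < flank,
            )
        )
    return out


# ---------------------------------------------------------------------------
# orthologous gap-size calls
# ---------------------------------------------------------------------------

class KmerIndex:
    """Exact k-mer locator over one or more target sequences.

    Lookup is substring scanning (C-speed ``str.find``) rather than a
    prebuilt hash, so construction is free and memory stays flat even for
    megabase targets; only uniqueness and the first position matter.
    """

    def __init__(self, sequences: Mapping[str, str] | str, k: int = DEFAULT_ANCHOR_K):
        if isinstance(sequences, str):
            sequences = {"target": sequences}
        self.k = k
        self.sequences = dict(sequences)

    def unique_hit(self, kmer: str) -> tuple[str, int] | None:
        hit: tuple[str, int] | None = None
        for name, seq in self.sequences.items():
            start = 0
            while True:
                i = seq.find(kmer, start)
                if i < 0:
                    break
                if hit is not None:
                    return None  # multi-mapping
                hit = (name, i)
                start = i + 1
        return hit


def detect_tsd(left_flank: str, right_flank: str, max_len: int = MAX_TSD_SCAN) -> int:
    """Longest t with left_flank[-t:] == right_flank[:t] (the TSD copies)."""
    best = 0
    limit = min(max_len, len(left_flank), len(right_flank))
    for t in range(1, limit + 1):
        if left_flank[-t:] == right_flank[:t]:
            best = t
    return best


def call_orthologous_state(
    locus: CandidateLocus,
    target: "KmerIndex | Mapping[str, str] | str",
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
    k: int = DEFAULT_ANCHOR_K,
    max_tries: int = 40,
    stride: int = 7,
) -> str:
    """Call ``unique`` / ``shared`` / ``unresolved`` against a target genome.

    Both flanks are anchored in the target by exact k-mer seeds (stepping
    away from the element junction until a uniquely-mapping seed is found).
    Let g be the anchored target gap corrected for the single TSD copy
    present at an empty site.  The element is absent from the target
    (``unique`` to the source lineage) when ``|g| <= gap_tolerance`` and
    present (``shared``) when ``|g - (element_span + TSD)| <= gap_tolerance``.
    Anything else, including anchoring failure, is ``unresolved``.
    """
    if not locus.left_flank or not locus.right_flank:
        raise ValueError("flanks must be non-empty")
    if not isinstance(target, KmerIndex):
        target = KmerIndex(target, k=k)
    k = target.k

    def anchor_left() -> tuple[int, int] | None:
        # k-mer ending `off` bp before the element start
        for i in range(max_tries):
            off = i * stride
            hi = len(locus.left_flank) - off
            if hi - k < 0:
                return None
            hit = target.unique_hit(locus.left_flank[hi - k : hi])
            if hit is not None:
                return hit[1] + k, off  # target end position, junction offset
        return None

    def anchor_right() -> tuple[int, int] | None:
        for i in range(max_tries):
            off = i * stride
            if off + k > len(locus.right_flank):
                return None
            hit = target.unique_hit(locus.right_flank[off : off + k])
            if hit is not None:
                return hit[1], off  # target start position, junction offset
        return None

    left = anchor_left()
    right = anchor_right()
    if left is None or right is None:
        return "unresolved"
    (left_end, left_off), (right_start, right_off) = left, right
    tsd = detect_tsd(locus.left_flank, locus.right_flank)
    # junction positions in the target: anchor end + offset / anchor start - offset
    gap = (right_start - right_off) - (left_end + left_off) + tsd
    filled = len(locus.element_sequence) + tsd
    if abs(gap) <= gap_tolerance:
        return "unique"
    if abs(gap - filled) <= gap_tolerance:
        return "shared"
    return "unresolved"


# ---------------------------------------------------------------------------
# subfamily assignment
# ---------------------------------------------------------------------------

_TAIL_RE = re.compile(r"A{4,}$")
_HEAD_RE = re.compile(r"^T{4,}")


def _strip_tail(seq: str) -> str:
    return _HEAD_RE.sub("", _TAIL_RE.sub("", seq))


def assign_subfamily(
    element_sequence: str, consensus_set: Sequence[AluConsensus]
) -> tuple[str, float]:
    """Best-matching subfamily and percent divergence against its consensus.

    Tries both orientations, ignores the poly-A tail, and breaks ties by
    lexicographically smallest subfamily name.
    """
    if not element_sequence:
        raise ValueError("empty element sequence")
    if not consensus_set:
        raise ValueError("empty consensus set")
    stripped = _strip_tail(element_sequence)
    best: tuple[float, str] | None = None
    for cons in consensus_set:
        dists = []
        for query in (stripped, revcomp(stripped)):
            res = edlib.align(query, cons.sequence, mode="NW", task="distance")
            dists.append(res["editDistance"])
        div = 100.0 * min(dists) / len(cons.sequence)
        key = (div, cons.subfamily_name)
        if best is None or key < best:
            best = key
    return best[1], best[0]


# ---------------------------------------------------------------------------
# proportional candidate selection
# ---------------------------------------------------------------------------

def select_candidates(
    loci_by_subfamily: Mapping[str, Sequence[CandidateLocus]],
    target_total: int,
    all_if_below: int = 5,
    seed: int = 0,
) -> list[CandidateLocus]:
    """Proportional selection by subfamily size, largest-remainder rounding.

    Subfamilies with fewer than ``all_if_below`` members contribute all their
    members; the remaining quota is allocated to the other subfamilies in
    proportion to size and sampled without replacement.
    """
    rng = np.random.default_rng(seed)
    small = {k: v for k, v in loci_by_subfamily.items() if len(v) < all_if_below}
    large = {k: v for k, v in loci_by_subfamily.items() if len(v) >= all_if_below}
    picked: list[CandidateLocus] = []
    for name in sorted(small):
        picked.extend(small[name])
    quota = target_total - len(picked)
    if quota < 0:
        raise ValueError(
            f"target_total {target_total} below the {len(picked)} members of "
            f"subfamilies with < {all_if_below} elements"
        )
    if quota > sum(len(v) for v in large.values()):
        raise ValueError(
            f"quota {quota} exceeds the {sum(len(v) for v in large.values())} "
            "available loci in large subfamilies"
        )
    if large and quota > 0:
        names = sorted(large)
        sizes = np.array([len(large[n]) for n in names], dtype=float)
        exact = quota * sizes / sizes.sum()
        alloc = np.floor(exact).astype(int)
        # largest-remainder top-up, then clip to subfamily size and spill over
        remainders = exact - alloc
        order = np.argsort(-remainders, kind="stable")
        for idx in order:
            if alloc.sum() >= quota:
                break
            alloc[idx] += 1
        while True:
            over = alloc - sizes.astype(int)
            excess = int(over[over > 0].sum())
            if excess == 0:
                break
            alloc = np.minimum(alloc, sizes.astype(int))
            room = sizes.astype(int) - alloc
            for idx in np.argsort(-room, kind="stable"):
                take = min(excess, room[idx])
                alloc[idx] += take
                excess -= take
                if excess == 0:
                    break
        for name, n_pick in zip(names, alloc):
            members = list(large[name])
            idx = rng.choice(len(members), size=int(n_pick), replace=False)
            picked.extend(members[i] for i in sorted(idx))
    return picked
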
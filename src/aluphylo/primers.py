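"""Locus-specific primer pair design and validation.

Constraints follow a conventional Primer3 manual-design block: melting
temperature window 57-62 degC, pairwise Tm difference <= 2, minimum GC 40%,
maximum homopolymer ("poly-X") run 3.  Tm is nearest-neighbor thermodynamics
(Biopython Tm_NN) at 50 mM monovalent salt and 200 nM oligo.  Specificity is
the strictest possible in-silico test: the primer must occur exactly once in
the assembly over both strands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional

from Bio.SeqUtils import MeltingTemp

from .ascertain import CandidateLocus, detect_tsd
from .simulate import revcomp

_VALID = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class PrimerConstraints:
    tm_min: float = 57.0
    tm_max: float = 62.0
    max_tm_diff: float = 2.0
    min_gc: float = 40.0
    max_poly_x: int = 3
    min_length: int = 18
    max_length: int = 27
    #: nearest-neighbor Tm conditions
    salt_mM: float = 50.0
    oligo_nM: float = 200.0


@dataclass(frozen=True)
class AmpliconLimits:
    min_size: int = 80
    max_size: int = 2000
    empty_optimum: int = 250


@dataclass
class PrimerPair:
    forward_seq: str
    reverse_seq: str
    forward_start: int  # 0-based offset of forward 5' end in the left flank
    reverse_start: int  # 0-based offset of reverse 5' end in the right flank
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    predicted_filled_size: int
    predicted_empty_size: int


def melting_temperature(seq: str, constraints: PrimerConstraints = PrimerConstraints()) -> float:
    return float(
        MeltingTemp.Tm_NN(
            seq,
            Na=constraints.salt_mM,
            dnac1=constraints.oligo_nM,
            dnac2=0,
        )
    )


def gc_content(seq: str) -> float:
    return 100.0 * sum(seq.count(b) for b in "GC") / len(seq)


def max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def check_primer_constraints(
    sequence: str, constraints: PrimerConstraints = PrimerConstraints()
) -> tuple[bool, list[str]]:
    """Evaluate every rule; return (pass, list of violated-rule reasons)."""
    if not _VALID.match(sequence or ""):
        raise ValueError(
            "primer contains ambiguity codes or invalid characters; design "
            "space is restricted to unambiguous A/C/G/T"
        )
    reasons = []
    if not constraints.min_length <= len(sequence) <= constraints.max_length:
        reasons.append(
            f"length {len(sequence)} outside "
            f"[{constraints.min_length},{constraints.max_length}]"
        )
    tm = melting_temperature(sequence, constraints)
    if not constraints.tm_min <= tm <= constraints.tm_max:
        reasons.append(f"Tm {tm:.1f} outside [{constraints.tm_min},{constraints.tm_max}]")
    gc = gc_content(sequence)
    if gc < constraints.min_gc:
        reasons.append(f"GC {gc:.1f}% below floor {constraints.min_gc}%")
    run = max_homopolymer(sequence)
    if run > constraints.max_poly_x:
        reasons.append(f"poly-X run {run} exceeds {constraints.max_poly_x}")
    return (not reasons), reasons


def count_exact_matches(primer: str, assembly: Mapping[str, str] | str) -> int:
    """Exact occurrences of the primer on both strands (overlaps counted).

    A palindromic primer occurring once is counted on both strands (2).
    """
    if isinstance(assembly, str):
        assembly = {"seq": assembly}

    def count(seq: str, pattern: str) -> int:
        n = start = 0
        while True:
            i = seq.find(pattern, start)
            if i < 0:
                return n
            n += 1
            start = i + 1

    total = 0
    rc = revcomp(primer)
    for seq in assembly.values():
        total += count(seq, primer) + count(seq, rc)
    return total


def predict_amplicon_sizes(
    pair: PrimerPair, allele_sequence: str, max_size: int = 2000
) -> Optional[int]:
    """Amplicon size on one allele: forward 5' end to reverse 5' end inclusive.

    Returns None (no amplicon; models PCR failure) when either primer does
    not anchor exactly once in convergent orientation within ``max_size``.
    """
    fwd = pair.forward_seq
    rev_rc = revcomp(pair.reverse_seq)
    f = allele_sequence.find(fwd)
    if f < 0 or allele_sequence.find(fwd, f + 1) >= 0:
        return None
    r = allele_sequence.find(rev_rc)
    if r < 0 or allele_sequence.find(rev_rc, r + 1) >= 0:
        return None
    size = (r + len(rev_rc)) - f
    if size < len(fwd) + len(rev_rc) - 1 or size > max_size:
        return None
    return size


def locus_allele_sequences(locus: CandidateLocus) -> tuple[str, str]:
    """(filled, empty) allele sequences reconstructed from a candidate locus.

    The empty allele collapses the two TSD copies to the single pre-integration
    copy, detected as the longest left-suffix/right-prefix overlap.
    """
    filled = locus.left_flank + locus.element_sequence + locus.right_flank
    tsd = detect_tsd(locus.left_flank, locus.right_flank)
    empty = locus.left_flank + locus.right_flank[tsd:]
    return filled, empty


def design_primer_pair(
    locus: CandidateLocus,
    constraints: PrimerConstraints = PrimerConstraints(),
    amplicon_limits: AmpliconLimits = AmpliconLimits(),
    search_span: int = 300,
    max_pairs: int = 20,
) -> list[PrimerPair]:
    """Enumerate and rank feasible primer pairs flanking the element.

    Forward primers are windows of the left flank, reverse primers are
    reverse-complemented windows of the right flank, both within
    ``search_span`` bp of the element junctions.  Pairs must pass all single
    primer constraints, |Tm difference| <= max_tm_diff, and the amplicon
    limits on the empty allele; ranking is by |Tm difference| then closeness
    of the empty amplicon to ``empty_optimum``.

    Returns an empty list when no pair is feasible; inspect
    :func:`design_diagnostics` for per-rule failure counts.
    """
    filled, empty = locus_allele_sequences(locus)

    tm_mid = (constraints.tm_min + constraints.tm_max) / 2
    max_candidates = 80  # per side, nearest the Tm window centre

    def candidates(flank: str, is_forward: bool) -> list[tuple[str, int, float]]:
        out = []
        lo = max(0, len(flank) - search_span) if is_forward else 0
        hi = len(flank) if is_forward else min(len(flank), search_span)
        for start in range(lo, hi):
            for L in range(constraints.min_length, constraints.max_length + 1):
                if start + L > len(flank):
                    break
                window = flank[start : start + L]
                seq = window if is_forward else revcomp(window)
                # cheap screens before the nearest-neighbor Tm computation
                if not _VALID.match(seq):
                    continue
                if gc_content(seq) < constraints.min_gc:
                    continue
                if max_homopolymer(seq) > constraints.max_poly_x:
                    continue
                tm = melting_temperature(seq, constraints)
                if constraints.tm_min <= tm <= constraints.tm_max:
                    out.append((seq, start, tm))
        out.sort(key=lambda item: abs(item[2] - tm_mid))
        return out[:max_candidates]

    forwards = candidates(locus.left_flank, True)
    reverses = candidates(locus.right_flank, False)
    pairs: list[tuple[tuple, PrimerPair]] = []
    for fseq, fstart, ftm in forwards:
        for rseq, rstart, rtm in reverses:
            if abs(ftm - rtm) > constraints.max_tm_diff:
                continue
            pair = PrimerPair(
                forward_seq=fseq,
                reverse_seq=rseq,
                forward_start=fstart,
                reverse_start=rstart,
                tm_forward=ftm,
                tm_reverse=rtm,
                gc_forward=gc_content(fseq),
                gc_reverse=gc_content(rseq),
                predicted_filled_size=0,
                predicted_empty_size=0,
            )
            e = predict_amplicon_sizes(pair, empty, amplicon_limits.max_size)
            f = predict_amplicon_sizes(pair, filled, amplicon_limits.max_size)
            if e is None or f is None or e < amplicon_limits.min_size:
                continue
            if f <= e:
                continue
            pair.predicted_empty_size = e
            pair.predicted_filled_size = f
            rank = (abs(ftm - rtm), abs(e - amplicon_limits.empty_optimum))
            pairs.append((rank, pair))
    pairs.sort(key=lambda x: x[0])
    return [p for _, p in pairs[:max_pairs]]


def design_diagnostics(
    locus: CandidateLocus,
    constraints: PrimerConstraints = PrimerConstraints(),
    search_span: int = 300,
) -> dict[str, int]:
    """Per-rule failure counts over all candidate windows (design triage)."""
    counts: dict[str, int] = {}
    for flank, is_forward in ((locus.left_flank, True), (locus.right_flank, False)):
        lo = max(0, len(flank) - search_span) if is_forward else 0
        hi = len(flank) if is_forward else min(len(flank), search_span)
        for start in range(lo, hi):
            for L in range(constraints.min_length, constraints.max_length + 1):
                if start + L > len(flank):
                    break
                window = flank[start : start + L]
                seq = window if is_forward else revcomp(window)
                _, reasons = check_primer_constraints(seq, constraints)
                for reason in reasons:
                    key = reason.split()[0]
                    counts[key] = counts.get(key, 0) + 1
    return counts
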
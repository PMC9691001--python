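"""In-silico PCR genotyping, locus classification and near-parallel detection.

Genotypes follow the presence/absence band-size convention: (1,1) homozygous
insertion-present, (0,0) homozygous absent, (1,0) heterozygous, missing when
no amplicon is produced.  A fragment matching neither expected size flags a
candidate near-parallel insertion or artifact, which is resolved by aligning
the amplicon sequence against the empty reference (the sequence-comparison
counterpart of confirmatory Sanger sequencing) and re-coding carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import edlib
from Bio import Align

from .ascertain import assign_subfamily
from .primers import PrimerPair, predict_amplicon_sizes
from .simulate import AluConsensus, revcomp

MISSING = None  # genotype sentinel


@dataclass
class Fragment:
    size: int
    sequence: str


@dataclass
class GenotypeCall:
    individual: str
    locus_id: str
    genotype: Optional[tuple[int, int]]  # (1,1)/(1,0)/(0,0) or None=missing
    fragments: list[Fragment] = field(default_factory=list)
    off_size: bool = False  # an amplicon matched neither expected size

    @property
    def has_insertion(self) -> Optional[bool]:
        if self.genotype is None:
            return None
        return 1 in self.genotype


@dataclass
class LocusClassification:
    locus_id: str
    category: str  # fixed_present | fixed_absent | restricted_hp |
    #               restricted_poly | shared_pair | shared_triple | other_ILS
    species: tuple[str, ...] = ()


@dataclass
class AmpliconFinding:
    """Outcome of sequence comparison on an unexpected amplicon."""

    locus_id: str
    kind: str  # 'near_parallel' | 'artifact' | 'unresolved'
    carriers: tuple[str, ...] = ()
    offset_bp: int = 0  # signed; negative = 5' of the target insertion
    orientation: str = ""  # 'same' | 'opposite' relative to the target
    element_class: str = ""  # subfamily name, or 'non_repeat'
    insert_length: int = 0


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

def insilico_pcr(
    pair: PrimerPair,
    haplotypes: Sequence[str],
    max_product: int = 2000,
) -> list[Optional[Fragment]]:
    """Amplify each haplotype; None where no product forms (missing data)."""
    out: list[Optional[Fragment]] = []
    rev_rc = revcomp(pair.reverse_seq)
    for hap in haplotypes:
        size = predict_amplicon_sizes(pair, hap, max_size=max_product)
        if size is None:
            out.append(None)
            continue
        start = hap.find(pair.forward_seq)
        out.append(Fragment(size, hap[start : start + size]))
    return out


def call_genotype(
    fragments: Sequence[Optional[Fragment]],
    expected_filled: int,
    expected_empty: int,
    size_tolerance: int = 20,
    individual: str = "",
    locus_id: str = "",
) -> GenotypeCall:
    """Diploid genotype from observed fragment sizes.

    Sizes within ``size_tolerance`` of the expected filled/empty products are
    assigned to the corresponding allele; both kinds -> (1,0), only filled ->
    (1,1), only empty -> (0,0).  No fragments -> missing; fragments matching
    neither size -> missing with the off-size flag raised.
    """
    if abs(expected_filled - expected_empty) <= 2 * size_tolerance:
        raise ValueError(
            "expected filled/empty sizes are not separable at this tolerance"
        )
    seen = [f for f in fragments if f is not None]
    filled = any(abs(f.size - expected_filled) <= size_tolerance for f in seen)
    empty = any(abs(f.size - expected_empty) <= size_tolerance for f in seen)
    off = any(
        abs(f.size - expected_filled) > size_tolerance
        and abs(f.size - expected_empty) > size_tolerance
        for f in seen
    )
    if filled and empty:
        genotype: Optional[tuple[int, int]] = (1, 0)
    elif filled:
        genotype = (1, 1)
    elif empty:
        genotype = (0, 0)
    else:
        genotype = MISSING
    return GenotypeCall(individual, locus_id, genotype, list(seen), off_size=off)


# ---------------------------------------------------------------------------
# locus classification
# ---------------------------------------------------------------------------

def classify_locus(
    genotypes_by_species: Mapping[str, Sequence[GenotypeCall]],
    reference_species: str,
    locus_id: str = "",
    auxiliary_species: Sequence[str] = (),
) -> LocusClassification:
    """Assign the locus to one polymorphism category.

    Precedence: fixed_present, fixed_absent, restricted to the reference
    species (homozygous-present vs polymorphic), shared by exactly two
    species, shared by three, else other_ILS.  Species listed in
    ``auxiliary_species`` (e.g. single-specimen taxa) are reported but never
    anchor a category on their own; species with only missing genotypes are
    ignored.
    """
    summaries: dict[str, dict[str, bool]] = {}
    for species, calls in genotypes_by_species.items():
        gts = [c.genotype for c in calls if c.genotype is not None]
        if not gts:
            continue
        summaries[species] = {
            "present": any(1 in g for g in gts),
            "all_present": all(1 in g for g in gts),
            "all_hp": all(g == (1, 1) for g in gts),
            "all_absent": all(g == (0, 0) for g in gts),
        }
    if not summaries:
        raise ValueError(f"locus {locus_id or '?'}: all genotypes missing")
    core = {s: v for s, v in summaries.items() if s not in auxiliary_species}
    if not core:
        core = summaries
    carriers = tuple(sorted(s for s, v in core.items() if v["present"]))
    if all(v["all_hp"] for v in core.values()):
        return LocusClassification(locus_id, "fixed_present", tuple(sorted(core)))
    if all(v["all_absent"] for v in core.values()):
        return LocusClassification(locus_id, "fixed_absent", tuple(sorted(core)))
    if carriers == (reference_species,):
        ref = core.get(reference_species, {})
        cat = "restricted_hp" if ref.get("all_hp") else "restricted_poly"
        return LocusClassification(locus_id, cat, carriers)
    # sharing categories require the element in every individual of each
    # carrier species; segregating presence across several species is the
    # erratic pattern attributed to incomplete lineage sorting
    uniform = all(core[s]["all_present"] for s in carriers)
    if uniform and len(carriers) == 2 and len(core) > 2:
        return LocusClassification(locus_id, "shared_pair", carriers)
    if uniform and len(carriers) == 3 and len(core) > 3:
        return LocusClassification(locus_id, "shared_triple", carriers)
    return LocusClassification(locus_id, "other_ILS", carriers)


def classification_counts(
    classifications: Sequence[LocusClassification],
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for c in classifications:
        counts[c.category] = counts.get(c.category, 0) + 1
    return counts


def partition_summary(counts: Mapping[str, int]) -> dict[str, int]:
    """Three-way partition: fixed present / fixed absent / polymorphic."""
    fixed_present = counts.get("fixed_present", 0)
    fixed_absent = counts.get("fixed_absent", 0)
    polymorphic = sum(
        v
        for k, v in counts.items()
        if k not in ("fixed_present", "fixed_absent")
    )
    return {
        "fixed_present": fixed_present,
        "fixed_absent": fixed_absent,
        "polymorphic": polymorphic,
        "total": fixed_present + fixed_absent + polymorphic,
    }


# ---------------------------------------------------------------------------
# near-parallel detection
# ---------------------------------------------------------------------------

def _insertion_aligner() -> Align.PairwiseAligner:
    """Global aligner with affine gaps, so an inserted element stays one
    contiguous gap instead of fragmenting into spurious micro-matches."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -0.2
    return aligner


def detect_near_parallel(
    amplicon: str,
    empty_reference: str,
    target_position: int,
    consensus_set: Sequence[AluConsensus],
    locus_id: str = "",
    target_orientation: str = "+",
    min_insert: int = 30,
    max_element_divergence: float = 25.0,
    max_edit_fraction: float = 0.35,
) -> Optional[AmpliconFinding]:
    """Explain an off-size amplicon by alignment against the empty reference.

    ``target_position`` is the pre-integration site offset of the *target*
    insertion within ``empty_reference``.  An inserted segment classified to
    a subfamily consensus yields a near-parallel finding with signed offset
    (negative = 5' of the target) and relative orientation; a non-repeat
    segment is an artifact/structural finding; no inserted segment means the
    amplicon is the plain empty allele (returns None); an unalignable
    amplicon returns an 'unresolved' finding.
    """
    aln = _insertion_aligner().align(empty_reference, amplicon)[0]
    t_blocks, q_blocks = aln.aligned
    inserts: list[tuple[int, int, int]] = []  # (target pos, query start, len)
    mismatches = deleted = stray = 0
    prev_t = prev_q = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        q_gap = qs - prev_q
        if q_gap >= min_insert:
            inserts.append((ts, prev_q, q_gap))
        elif q_gap > 0:
            stray += q_gap
        deleted += ts - prev_t
        mismatches += sum(
            a != b
            for a, b in zip(empty_reference[ts:te], amplicon[qs:qe])
        )
        prev_t, prev_q = te, qe
    tail_gap = len(amplicon) - prev_q
    if tail_gap >= min_insert:
        inserts.append((len(empty_reference), prev_q, tail_gap))
    elif tail_gap > 0:
        stray += tail_gap
    deleted += len(empty_reference) - prev_t
    residual = mismatches + deleted + stray  # edit cost besides insertions
    if residual > max_edit_fraction * len(empty_reference):
        return AmpliconFinding(locus_id, "unresolved")
    if not inserts:
        return None
    # largest inserted segment explains the size shift
    tpos, qstart, length = max(inserts, key=lambda x: x[2])
    segment = amplicon[qstart : qstart + length]
    subfamily, divergence = assign_subfamily(segment, consensus_set)
    offset = tpos - target_position
    if divergence <= max_element_divergence:
        fwd = edlib.align(
            segment, consensus_set_lookup(consensus_set, subfamily).sequence,
            mode="HW", task="distance",
        )["editDistance"]
        rev = edlib.align(
            revcomp(segment),
            consensus_set_lookup(consensus_set, subfamily).sequence,
            mode="HW", task="distance",
        )["editDistance"]
        insert_orientation = "+" if fwd <= rev else "-"
        relative = "same" if insert_orientation == target_orientation else "opposite"
        return AmpliconFinding(
            locus_id,
            "near_parallel",
            offset_bp=offset,
            orientation=relative,
            element_class=subfamily,
            insert_length=length,
        )
    return AmpliconFinding(
        locus_id,
        "artifact",
        offset_bp=offset,
        element_class="non_repeat",
        insert_length=length,
    )


def consensus_set_lookup(
    consensus_set: Sequence[AluConsensus], name: str
) -> AluConsensus:
    for cons in consensus_set:
        if cons.subfamily_name == name:
            return cons
    raise KeyError(name)


# ---------------------------------------------------------------------------
# post-sequencing genotype adjustment
# ---------------------------------------------------------------------------

@dataclass
class AdjustmentRecord:
    locus_id: str
    individual: str
    old: Optional[tuple[int, int]]
    new: Optional[tuple[int, int]]
    reason: str


def adjust_genotypes(
    calls: Mapping[tuple[str, str], GenotypeCall],
    findings: Sequence[AmpliconFinding],
) -> tuple[dict[tuple[str, str], GenotypeCall], list[AdjustmentRecord]]:
    """Re-code carriers of near-parallel/artifact fragments as target-absent.

    ``calls`` maps (locus_id, individual) to calls.  Near-parallel and
    artifact findings imply the carrier lacks the *target* insertion at the
    amplifying allele, so carriers are set to (0,0); unresolved findings
    yield missing.  Returns the adjusted table plus an audit log with one
    record per changed cell.  The operation is idempotent.
    """
    target: dict[tuple[str, str], tuple[Optional[tuple[int, int]], str]] = {}
    for finding in findings:
        if finding.kind == "unresolved":
            new, why = MISSING, "unresolved amplicon"
        else:
            new, why = (0, 0), f"{finding.kind} ({finding.element_class})"
        for indiv in finding.carriers:
            key = (finding.locus_id, indiv)
            if key not in calls:
                raise KeyError(f"finding references unknown cell {key}")
            if key in target and target[key][0] != new:
                raise ValueError(
                    f"conflicting findings for {key}: "
                    f"{target[key][0]} vs {new}"
                )
            target[key] = (new, why)
    adjusted = dict(calls)
    log: list[AdjustmentRecord] = []
    for key, (new, why) in sorted(target.items()):
        call = adjusted[key]
        if call.genotype == new:
            continue
        log.append(AdjustmentRecord(key[0], key[1], call.genotype, new, why))
        adjusted[key] = GenotypeCall(
            individual=call.individual,
            locus_id=call.locus_id,
            genotype=new,
            fragments=call.fragments,
            off_size=call.off_size,
        )
    return adjusted, log
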
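"""Synthetic Alu insertion panels with known truth.

Simulates a rooted species tree, per-branch germline SINE insertion events
(with target site duplications, A-tails, subfamily diagnostic substitutions
and neutral divergence), and diploid individuals drawn under Hardy-Weinberg
from per-tip allele frequencies.  Incomplete lineage sorting (ILS) is
modelled phenomenologically: an ILS locus receives a presence pattern drawn
to conflict with the species topology.  "Near-parallel" loci place an
independent second element within amplicon range of an existing target.

Everything downstream (ascertainment, primer design, genotyping, phylogeny)
is tested against the truth tables this module emits.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .tree import Clade, parse_newick

BASES = np.array(list("ACGT"))
COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Default five-tip panel: four ingroup owl-monkey-like taxa (A. vociferans
#: basal, nancymaae+azarae sisters) plus one outgroup, time in arbitrary units.
DEFAULT_TREE = (
    "((((nancymaae:1.0,azarae:1.0):1.0,trivirgatus:2.0):1.0,"
    "vociferans:3.0):4.0,outgroup:7.0):0.0;"
)
#: Individuals per taxon, mirroring a multi-specimen PCR panel.
DEFAULT_POPULATIONS = {
    "nancymaae": 9,
    "trivirgatus": 4,
    "vociferans": 6,
    "azarae": 3,
    "outgroup": 1,
}

MIN_CONSENSUS_LENGTH = 267


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class PlacementError(ValueError):
    """Raised when insertion events cannot be placed without collision."""


@dataclass
class SpeciesTree:
    """Rooted binary species tree with per-tip diploid sample counts."""

    root: Clade
    populations: dict[str, int]

    def __post_init__(self):
        taxa = self.root.leaf_names()
        if len(set(taxa)) != len(taxa):
            raise ValueError("tip labels must be unique")
        for node in self.root.postorder():
            if not node.is_leaf and len(node.children) != 2:
                raise ValueError("species tree must be binary")
            if node is not self.root and node.length <= 0:
                raise ValueError("branch lengths must be > 0")
        missing = set(taxa) - set(self.populations)
        if missing:
            raise ValueError(f"populations missing for taxa: {sorted(missing)}")

    @property
    def taxa(self) -> list[str]:
        return self.root.leaf_names()

    @classmethod
    def default(cls) -> "SpeciesTree":
        return cls(parse_newick(DEFAULT_TREE), dict(DEFAULT_POPULATIONS))

    def branches(self) -> list[tuple[Clade, frozenset]]:
        """(child node, descendant tip set) for every edge below the root."""
        out = []
        for _, child in self.root.edges():
            out.append((child, frozenset(child.leaf_names())))
        return out

    def clades(self) -> set[frozenset]:
        """All tip sets compatible with the topology (incl. tips and full set)."""
        out = {frozenset([t]) for t in self.taxa}
        out.add(frozenset(self.taxa))
        for node in self.root.postorder():
            if not node.is_leaf:
                out.add(frozenset(node.leaf_names()))
        return out

    def individuals(self) -> list[tuple[str, str]]:
        """(individual id, taxon) pairs, deterministic ordering."""
        out = []
        for taxon in self.taxa:
            for i in range(self.populations.get(taxon, 0)):
                out.append((f"{taxon}_{i + 1}", taxon))
        return out


@dataclass
class AluConsensus:
    """Subfamily consensus: dimeric body, A-rich linker, 3' A-tail."""

    subfamily_name: str
    sequence: str
    diagnostic_positions: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.sequence) < MIN_CONSENSUS_LENGTH:
            raise ValueError(
                f"consensus length {len(self.sequence)} < {MIN_CONSENSUS_LENGTH} "
                "(would violate the full-length filter)"
            )
        seen = set()
        for pos, base in self.diagnostic_positions:
            if not 0 <= pos < len(self.sequence) or pos in seen:
                raise ValueError("diagnostic positions must be unique and in range")
            seen.add(pos)


@dataclass
class InsertionEvent:
    """One germline insertion on a species-tree branch."""

    locus_id: str
    branch: frozenset  # descendant tip set of the carrying branch
    backbone_position: int  # 0-based offset on the ancestral backbone
    subfamily: AluConsensus
    element_length: int
    tsd_length: int
    orientation: str  # '+' or '-'
    tip_frequencies: dict[str, float]
    ils_flag: bool = False
    near_parallel_of: Optional[tuple[str, int]] = None  # (locus_id, offset bp)
    divergence: float = 0.0  # realized neutral divergence of the copy
    tail_length: int = 0

    @property
    def cassette_length(self) -> int:
        """Element + A-tail: the span a repeat annotation would mask."""
        return self.element_length + self.tail_length

    @property
    def insertion_length(self) -> int:
        """Length added to a filled haplotype: cassette + one extra TSD copy."""
        return self.cassette_length + self.tsd_length


@dataclass
class SimulatedPanel:
    """Realized assemblies, individual haplotypes and the truth tables."""

    tree: SpeciesTree
    events: list[InsertionEvent]
    assemblies: dict[str, str]  # taxon -> assembly sequence
    haplotypes: dict[str, tuple[str, str]]  # individual -> two haplotypes
    individual_taxon: dict[str, str]
    truth_genotypes: dict[tuple[str, str], tuple[int, int]]  # (locus, indiv)
    element_intervals: dict[tuple[str, str], tuple[int, int]]  # (locus, seq name)
    insert_sequences: dict[str, str]  # locus -> realized cassette (with TSD excl.)

    def truth_rows(self) -> list[dict]:
        rows = []
        for (locus, indiv), (a1, a2) in sorted(self.truth_genotypes.items()):
            rows.append(
                {"locus_id": locus, "individual": indiv, "allele1": a1, "allele2": a2}
            )
        return rows


# ---------------------------------------------------------------------------
# consensus construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.55) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def build_consensus_set(
    n_subfamilies: int,
    n_diagnostic: int,
    base_length: int = 300,
    seed: int = 0,
) -> list[AluConsensus]:
    """Derive subfamily consensuses from one root sequence.

    Each subfamily carries ``n_diagnostic`` private diagnostic substitutions,
    so any two subfamilies differ at >= 2*n_diagnostic sites (>= n_diagnostic
    from each side).  The root mimics an Alu: two ~linker-separated monomers
    with a middle A-rich region and no terminal tail (tails are appended per
    insertion, with variable length).
    """
    if n_subfamilies < 1:
        raise ValueError("n_subfamilies must be >= 1")
    if base_length < MIN_CONSENSUS_LENGTH:
        raise ValueError(
            f"base_length {base_length} < {MIN_CONSENSUS_LENGTH}: such elements "
            "would fail the full-length filter"
        )
    rng = np.random.default_rng(seed)
    half = (base_length - 8) // 2
    root = (
        _random_seq(rng, half)
        + "AAAAAAAA"  # A-rich linker between the two monomers
        + _random_seq(rng, base_length - half - 8)
    )
    # candidate diagnostic sites: outside the linker, unique across subfamilies
    linker = set(range(half, half + 8))
    candidates = [i for i in range(base_length) if i not in linker]
    rng.shuffle(candidates)
    needed = n_subfamilies * n_diagnostic
    if needed > len(candidates):
        raise ValueError("too many diagnostic positions for sequence length")
    out = []
    cursor = 0
    for i in range(n_subfamilies):
        sites = sorted(candidates[cursor : cursor + n_diagnostic])
        cursor += n_diagnostic
        seq = list(root)
        diags = []
        for pos in sites:
            alt = rng.choice([b for b in "ACGT" if b != seq[pos]])
            seq[pos] = alt
            diags.append((pos, alt))
        out.append(AluConsensus(f"AluSim{i + 1}", "".join(seq), diags))
    return out


# ---------------------------------------------------------------------------
# insertion events
# ---------------------------------------------------------------------------

def _draw_ils_pattern(
    tree: SpeciesTree, rng: np.random.Generator
) -> dict[str, float]:
    """Presence pattern whose carrier set is NOT a clade of the tree."""
    taxa = tree.taxa
    clades = tree.clades()
    for _ in range(1000):
        k = rng.integers(2, len(taxa))
        carriers = frozenset(rng.choice(taxa, size=k, replace=False))
        if carriers in clades:
            continue
        freqs = {t: 0.0 for t in taxa}
        for t in carriers:
            freqs[t] = float(rng.choice([0.5, 1.0]))
        return freqs
    raise RuntimeError("could not draw an ILS pattern (tree too small?)")


def simulate_insertion_events(
    tree: SpeciesTree,
    rate: float,
    ils_prob: float = 0.0,
    near_parallel_rate: float = 0.0,
    consensus_set: Sequence[AluConsensus] | None = None,
    seed: int = 0,
    tsd_range: tuple[int, int] = (5, 20),
    near_parallel_offset_range: tuple[int, int] = (50, 260),
) -> list[InsertionEvent]:
    """Poisson-distributed insertion events along the branches of ``tree``.

    ``rate`` is insertions per unit branch length; the expected event count
    is rate * total branch length.  Backbone positions are assigned later by
    :func:`realize_panel`.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    for p, name in ((ils_prob, "ils_prob"), (near_parallel_rate, "near_parallel_rate")):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0,1]")
    if not tree.taxa:
        raise ValueError("empty species tree")
    if consensus_set is None:
        consensus_set = build_consensus_set(3, 4, seed=seed)
    rng = np.random.default_rng(seed)
    branches = tree.branches()
    lengths = np.array([b.length for b, _ in branches])
    total = lengths.sum()
    n_events = int(rng.poisson(rate * total))
    events: list[InsertionEvent] = []
    for i in range(n_events):
        locus_id = f"locus_{i + 1:04d}"
        subfam = consensus_set[rng.integers(len(consensus_set))]
        tsd = int(rng.integers(tsd_range[0], tsd_range[1] + 1))
        orientation = "+" if rng.random() < 0.5 else "-"
        is_ils = rng.random() < ils_prob and len(tree.taxa) >= 4
        if is_ils:
            freqs = _draw_ils_pattern(tree, rng)
            branch_idx = int(rng.choice(len(branches), p=lengths / total))
            branch = branches[branch_idx][1]
        else:
            branch_idx = int(rng.choice(len(branches), p=lengths / total))
            branch = branches[branch_idx][1]
            freqs = {t: (1.0 if t in branch else 0.0) for t in tree.taxa}
        near_parallel = None
        if (
            near_parallel_rate > 0
            and events
            and rng.random() < near_parallel_rate
        ):
            # companion element near an earlier target, carried by a tip that
            # lacks the target insertion (the confounding case from PCR)
            target = events[int(rng.integers(len(events)))]
            non_carriers = [
                t for t in tree.taxa if target.tip_frequencies.get(t, 0) == 0
            ]
            if non_carriers:
                carrier = str(rng.choice(non_carriers))
                freqs = {t: (1.0 if t == carrier else 0.0) for t in tree.taxa}
                branch = frozenset([carrier])
                offset = int(
                    rng.integers(
                        near_parallel_offset_range[0],
                        near_parallel_offset_range[1] + 1,
                    )
                )
                near_parallel = (target.locus_id, -offset)  # 5' of the target
                is_ils = False
        events.append(
            InsertionEvent(
                locus_id=locus_id,
                branch=branch,
                backbone_position=-1,
                subfamily=subfam,
                element_length=len(subfam.sequence),
                tsd_length=tsd,
                orientation=orientation,
                tip_frequencies=freqs,
                ils_flag=is_ils,
                near_parallel_of=near_parallel,
            )
        )
    return events


# ---------------------------------------------------------------------------
# panel realization
# ---------------------------------------------------------------------------

def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        old = arr[i].decode()
        arr[i] = rng.choice([b for b in "ACGT" if b != old]).encode()
    return arr.tobytes().decode(), len(hits)


def _event_age(tree: SpeciesTree, event: InsertionEvent) -> float:
    """Time from the branch midpoint of the event down to the tips."""
    def tip_depth(node: Clade) -> float:
        if node.is_leaf:
            return 0.0
        return max(c.length + tip_depth(c) for c in node.children)

    for _, child in tree.root.edges():
        if frozenset(child.leaf_names()) == event.branch:
            return tip_depth(child) + child.length / 2.0
    # ILS patterns may not map to a single branch; use mean tip depth
    return tree.root.total_branch_length() / max(len(tree.taxa), 1)


def realize_panel(
    tree: SpeciesTree,
    events: list[InsertionEvent],
    backbone_length: int = 200_000,
    substitution_rate: float = 0.002,
    seed: int = 0,
    tail_range: tuple[int, int] = (8, 30),
    min_spacing: int = 2500,
    flank_divergence: float = 0.005,
) -> SimulatedPanel:
    """Place events on a backbone and realize assemblies and haplotypes.

    Each filled site is 5'TSD + element(+- substitutions) + A-tail + 3'TSD,
    where the TSD duplicates the ``tsd_length`` target-site bases.  Neutral
    element divergence is substitution_rate x (event age); the mutated copy
    is shared by all carriers (common ancestry).  ``flank_divergence`` is the
    per-site substitution probability applied independently to each taxon's
    backbone copy (flanking sequence drift between taxa).

    Per-taxon assemblies carry an event iff its tip frequency >= 0.5.
    Individuals are diploid Hardy-Weinberg draws from tip frequencies.
    """
    rng = np.random.default_rng(seed)
    backbone = _random_seq(rng, backbone_length, gc=0.42)

    # --- positions: primaries spaced >= min_spacing, companions by offset
    primaries = [e for e in events if e.near_parallel_of is None]
    companions = [e for e in events if e.near_parallel_of is not None]
    n = len(primaries)
    span_needed = (n + 1) * min_spacing
    if span_needed > backbone_length:
        raise PlacementError(
            f"backbone_length {backbone_length} cannot host {n} events at "
            f"spacing {min_spacing} (need >= {span_needed})"
        )
    slack = backbone_length - span_needed
    offsets = (
        np.sort(rng.integers(0, slack + 1, size=n)) if n else np.zeros(0, dtype=int)
    )
    positions = {}
    for i, event in enumerate(primaries):
        positions[event.locus_id] = int(min_spacing * (i + 1) + offsets[i])
    for event in companions:
        target_id, offset = event.near_parallel_of
        if target_id not in positions:
            raise PlacementError(f"near-parallel target {target_id} not placed")
        positions[event.locus_id] = positions[target_id] + offset
    for event in events:
        p = positions[event.locus_id]
        if p < 700 or p > backbone_length - 700:
            raise PlacementError(f"{event.locus_id} too close to backbone edge")
        event.backbone_position = p
    spans = sorted(
        (positions[e.locus_id], positions[e.locus_id] + e.tsd_length, e.locus_id)
        for e in events
    )
    for (s1, e1, id1), (s2, e2, id2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise PlacementError(f"colliding loci: {id1}, {id2}")

    # --- realized insert cassettes (shared by all carriers)
    insert_sequences: dict[str, str] = {}
    for event in events:
        age = _event_age(tree, event)
        body = event.subfamily.sequence
        rate = substitution_rate * age
        mutated, hits = _mutate(body, rate, rng)
        event.divergence = hits / len(body)
        event.tail_length = int(rng.integers(tail_range[0], tail_range[1] + 1))
        cassette = mutated + "A" * event.tail_length
        if event.orientation == "-":
            cassette = revcomp(cassette)
        insert_sequences[event.locus_id] = cassette

    # --- per-taxon backbones (flank drift) and carrier sets
    taxa = tree.taxa
    taxon_backbones = {
        t: _mutate(backbone, flank_divergence, rng)[0] for t in taxa
    }

    ordered = sorted(events, key=lambda e: positions[e.locus_id])

    def build_sequence(
        taxon: str, carried: set[str]
    ) -> tuple[str, dict[str, tuple[int, int]]]:
        base = taxon_backbones[taxon]
        parts: list[str] = []
        intervals: dict[str, tuple[int, int]] = {}
        cursor = 0
        length_so_far = 0
        for event in ordered:
            p = positions[event.locus_id]
            if event.locus_id not in carried:
                continue
            parts.append(base[cursor:p])
            length_so_far += p - cursor
            tsd = base[p : p + event.tsd_length]
            cassette = insert_sequences[event.locus_id]
            parts.append(tsd)
            length_so_far += len(tsd)
            intervals[event.locus_id] = (
                length_so_far,
                length_so_far + len(cassette),
            )
            parts.append(cassette)
            length_so_far += len(cassette)
            cursor = p  # 3' TSD copy is the original site: base[p:p+tsd] stays
        parts.append(base[cursor:])
        return "".join(parts), intervals

    assemblies: dict[str, str] = {}
    element_intervals: dict[tuple[str, str], tuple[int, int]] = {}
    for taxon in taxa:
        carried = {
            e.locus_id
            for e in events
            if e.tip_frequencies.get(taxon, 0.0) >= 0.5
        }
        seq, intervals = build_sequence(taxon, carried)
        assemblies[taxon] = seq
        for locus, iv in intervals.items():
            element_intervals[(locus, taxon)] = iv

    haplotypes: dict[str, tuple[str, str]] = {}
    individual_taxon: dict[str, str] = {}
    truth: dict[tuple[str, str], tuple[int, int]] = {}
    for indiv, taxon in tree.individuals():
        individual_taxon[indiv] = taxon
        allele_sets: list[set[str]] = []
        alleles_by_locus: dict[str, list[int]] = {e.locus_id: [] for e in events}
        for _hap in range(2):
            carried = set()
            for event in events:
                p_freq = event.tip_frequencies.get(taxon, 0.0)
                has = bool(rng.random() < p_freq)
                if has:
                    carried.add(event.locus_id)
                alleles_by_locus[event.locus_id].append(int(has))
            allele_sets.append(carried)
        haps = []
        for h, carried in enumerate(allele_sets):
            seq, intervals = build_sequence(taxon, carried)
            haps.append(seq)
            for locus, iv in intervals.items():
                element_intervals[(locus, f"{indiv}/h{h + 1}")] = iv
        haplotypes[indiv] = (haps[0], haps[1])
        for event in events:
            a = alleles_by_locus[event.locus_id]
            truth[(event.locus_id, indiv)] = (a[0], a[1])

    return SimulatedPanel(
        tree=tree,
        events=events,
        assemblies=assemblies,
        haplotypes=haplotypes,
        individual_taxon=individual_taxon,
        truth_genotypes=truth,
        element_intervals=element_intervals,
        insert_sequences=insert_sequences,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_csv(panel: SimulatedPanel, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["locus_id", "individual", "allele1", "allele2"]
        )
        writer.writeheader()
        writer.writerows(panel.truth_rows())


def write_repeatmasker_out(
    panel: SimulatedPanel, taxon: str, path: str | Path
) -> None:
    """RepeatMasker-style ``.out`` truth annotation for one taxon assembly."""
    from .ascertain import RepeatAnnotation, write_repeatmasker_out as _write

    annotations = []
    for event in panel.events:
        key = (event.locus_id, taxon)
        if key not in panel.element_intervals:
            continue
        start0, end0 = panel.element_intervals[key]
        annotations.append(
            RepeatAnnotation(
                query_name=taxon,
                begin=start0 + 1,
                end=end0,
                strand="+" if event.orientation == "+" else "C",
                repeat_name=event.subfamily.subfamily_name,
                percent_divergence=round(100 * event.divergence, 1),
                repeat_begin=1,
                query_left=len(panel.assemblies[taxon]) - end0,
                repeat_end=event.element_length,
                repeat_left=0,
            )
        )
    _write(annotations, path)
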
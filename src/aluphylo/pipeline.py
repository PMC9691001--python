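"""End-to-end orchestration: simulate -> ascertain -> design -> genotype ->
classify -> phylogeny.

Each stage reads and writes plain-text artifacts (FASTA, CSV, NEXUS, newick)
under an output directory, so stages can also be run independently from the
command line.  All randomness flows from a single seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import ascertain, dollo, genotype, primers, simulate
from .tree import parse_newick

log = logging.getLogger("aluphylo")


@dataclass
class RunConfig:
    """Parameters for a full pipeline run."""

    seed: int = 1
    # simulation
    tree_newick: str = simulate.DEFAULT_TREE
    populations: dict = field(
        default_factory=lambda: dict(simulate.DEFAULT_POPULATIONS)
    )
    reference_taxon: str = "nancymaae"
    outgroup_taxa: list = field(default_factory=lambda: ["outgroup"])
    n_subfamilies: int = 3
    n_diagnostic: int = 4
    consensus_length: int = 300
    insertion_rate: float = 10.0  # insertions per unit branch length
    ils_prob: float = 0.05
    near_parallel_rate: float = 0.01
    backbone_length: int = 900_000
    substitution_rate: float = 0.002
    flank_divergence: float = 0.005
    # ascertainment
    max_divergence: float = 2.0
    gap_tolerance: int = 15
    anchor_k: int = 25
    target_candidates: Optional[int] = None  # None = keep all
    # genotyping
    size_tolerance: int = 20
    # phylogeny
    bootstrap_replicates: int = 100
    search_restarts: int = 10

    def __post_init__(self):
        for name in ("gap_tolerance", "size_tolerance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s: done in %.2fs", stage, dt)
            else:
                log.error("stage %s: FAILED after %.2fs: %s", stage, dt, exc)
            return False

    return _Timer()


@dataclass
class PipelineResult:
    panel: simulate.SimulatedPanel
    candidates: list
    primer_pairs: dict
    calls: dict
    adjusted_calls: dict
    findings: list
    classifications: list
    category_counts: dict
    partition: dict
    matrix: dollo.CharacterMatrix
    best_tree: dollo.ScoredTree
    report: dict


def run_pipeline(config: RunConfig, out_dir: str | Path) -> PipelineResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {
        name: int(s)
        for name, s in zip(
            ("consensus", "events", "panel", "select", "search", "bootstrap"),
            rng.integers(0, 2**31 - 1, size=6),
        )
    }

    # ---- simulate ---------------------------------------------------------
    with _timed("simulate"):
        tree = simulate.SpeciesTree(
            parse_newick(config.tree_newick), dict(config.populations)
        )
        consensus = simulate.build_consensus_set(
            config.n_subfamilies,
            config.n_diagnostic,
            config.consensus_length,
            seed=seeds["consensus"],
        )
        events = simulate.simulate_insertion_events(
            tree,
            rate=config.insertion_rate,
            ils_prob=config.ils_prob,
            near_parallel_rate=config.near_parallel_rate,
            consensus_set=consensus,
            seed=seeds["events"],
        )
        panel = simulate.realize_panel(
            tree,
            events,
            backbone_length=config.backbone_length,
            substitution_rate=config.substitution_rate,
            flank_divergence=config.flank_divergence,
            seed=seeds["panel"],
        )
        simulate.write_fasta(panel.assemblies, out / "assemblies.fasta")
        simulate.write_truth_csv(panel, out / "truth_genotypes.csv")
        simulate.write_repeatmasker_out(
            panel, config.reference_taxon, out / "reference.out"
        )

    # ---- ascertain --------------------------------------------------------
    with _timed("ascertain"):
        annotations = ascertain.parse_repeatmasker_out(out / "reference.out")
        full_length = ascertain.filter_full_length(annotations)
        young = ascertain.filter_young(full_length, config.max_divergence)
        candidates = ascertain.extract_candidates(
            young, {config.reference_taxon: panel.assemblies[config.reference_taxon]}
        )
        # re-key candidates to the simulator's locus ids (match by interval)
        interval_to_locus = {
            iv: locus
            for (locus, name), iv in panel.element_intervals.items()
            if name == config.reference_taxon
        }
        for c in candidates:
            c.locus_id = interval_to_locus.get((c.start, c.end), c.locus_id)
        comparison_taxa = [
            t for t in tree.taxa if t != config.reference_taxon
        ]
        indexes = {
            t: ascertain.KmerIndex(panel.assemblies[t], k=config.anchor_k)
            for t in comparison_taxa
        }
        for locus in candidates:
            for taxon in comparison_taxa:
                locus.status[taxon] = ascertain.call_orthologous_state(
                    locus, indexes[taxon], gap_tolerance=config.gap_tolerance
                )
            locus.subfamily, locus.divergence = ascertain.assign_subfamily(
                locus.element_sequence, consensus
            )
        # lineage-specific = absent from every outgroup assembly
        lineage_specific = [
            c
            for c in candidates
            if all(c.status[t] == "unique" for t in config.outgroup_taxa)
        ]
        if config.target_candidates:
            by_subfamily: dict[str, list] = {}
            for c in lineage_specific:
                by_subfamily.setdefault(c.subfamily, []).append(c)
            selected = ascertain.select_candidates(
                by_subfamily, config.target_candidates, seed=seeds["select"]
            )
        else:
            selected = lineage_specific
        pd.DataFrame(
            {
                "locus_id": [c.locus_id for c in selected],
                "query_sequence": [c.coordinates for c in selected],
                "subfamily": [c.subfamily for c in selected],
                "divergence": [c.divergence for c in selected],
                **{
                    f"status_{t}": [c.status[t] for c in selected]
                    for t in comparison_taxa
                },
            }
        ).to_csv(out / "candidates.csv", index=False)

    # ---- primer design ----------------------------------------------------
    with _timed("design-primers"):
        primer_pairs: dict[str, primers.PrimerPair] = {}
        rows = []
        for locus in selected:
            found = primers.design_primer_pair(locus)
            if not found:
                continue
            pair = found[0]
            primer_pairs[locus.locus_id] = pair
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "forward": pair.forward_seq,
                    "reverse": pair.reverse_seq,
                    "tm_f": round(pair.tm_forward, 1),
                    "tm_r": round(pair.tm_reverse, 1),
                    "filled_bp": pair.predicted_filled_size,
                    "empty_bp": pair.predicted_empty_size,
                }
            )
        pd.DataFrame(rows).to_csv(out / "primers.csv", index=False)

    # ---- genotype ---------------------------------------------------------
    with _timed("genotype"):
        locus_by_id = {c.locus_id: c for c in selected}
        calls: dict[tuple[str, str], genotype.GenotypeCall] = {}
        for locus_id, pair in primer_pairs.items():
            for indiv, haps in panel.haplotypes.items():
                frags = genotype.insilico_pcr(pair, haps)
                calls[(locus_id, indiv)] = genotype.call_genotype(
                    frags,
                    pair.predicted_filled_size,
                    pair.predicted_empty_size,
                    size_tolerance=config.size_tolerance,
                    individual=indiv,
                    locus_id=locus_id,
                )

    # ---- near-parallel resolution -----------------------------------------
    with _timed("sequence-review"):
        findings: list[genotype.AmpliconFinding] = []
        for locus_id, pair in primer_pairs.items():
            locus = locus_by_id[locus_id]
            filled_seq, empty_seq = primers.locus_allele_sequences(locus)
            f = empty_seq.find(pair.forward_seq)
            r = empty_seq.find(simulate.revcomp(pair.reverse_seq))
            if f < 0 or r < 0:
                continue
            empty_amplicon = empty_seq[f : r + len(pair.reverse_seq)]
            target_pos = len(locus.left_flank) - f
            grouped: dict[tuple, tuple[genotype.AmpliconFinding, set[str]]] = {}
            for indiv in panel.haplotypes:
                call = calls[(locus_id, indiv)]
                if not call.off_size:
                    continue
                for frag in call.fragments:
                    if (
                        abs(frag.size - pair.predicted_filled_size)
                        <= config.size_tolerance
                        or abs(frag.size - pair.predicted_empty_size)
                        <= config.size_tolerance
                    ):
                        continue
                    finding = genotype.detect_near_parallel(
                        frag.sequence,
                        empty_amplicon,
                        target_pos,
                        consensus,
                        locus_id=locus_id,
                        target_orientation=locus.orientation,
                    )
                    if finding is None:
                        continue
                    key = (finding.kind, finding.element_class, finding.offset_bp)
                    grouped.setdefault(key, (finding, set()))[1].add(indiv)
            for finding, carriers in grouped.values():
                finding.carriers = tuple(sorted(carriers))
                findings.append(finding)
        adjusted, audit = genotype.adjust_genotypes(calls, findings)
        with open(out / "adjustments.log", "w") as fh:
            for rec in audit:
                fh.write(
                    f"{rec.locus_id}\t{rec.individual}\t{rec.old}->{rec.new}\t"
                    f"{rec.reason}\n"
                )
        gt_rows = []
        for (locus_id, indiv), call in sorted(adjusted.items()):
            g = call.genotype
            gt_rows.append(
                {
                    "locus_id": locus_id,
                    "individual": indiv,
                    "genotype": "?" if g is None else f"{g[0]},{g[1]}",
                }
            )
        pd.DataFrame(gt_rows).to_csv(out / "genotypes.csv", index=False)

    # ---- classify ---------------------------------------------------------
    with _timed("classify"):
        ingroup_species = [
            t for t in tree.taxa if t not in config.outgroup_taxa
        ]
        classifications = []
        for locus_id in primer_pairs:
            by_species = {
                sp: [
                    adjusted[(locus_id, ind)]
                    for ind, t in panel.individual_taxon.items()
                    if t == sp
                ]
                for sp in ingroup_species
            }
            try:
                classifications.append(
                    genotype.classify_locus(
                        by_species, config.reference_taxon, locus_id=locus_id
                    )
                )
            except ValueError:
                continue  # all-missing locus: no classification
        counts = genotype.classification_counts(classifications)
        partition = genotype.partition_summary(counts)
        pd.DataFrame(
            [
                {
                    "locus_id": c.locus_id,
                    "category": c.category,
                    "species": "+".join(c.species),
                }
                for c in classifications
            ]
        ).to_csv(out / "classifications.csv", index=False)

    # ---- phylogeny --------------------------------------------------------
    with _timed("phylo"):
        genotype_table = {
            key: call.genotype
            for key, call in adjusted.items()
        }
        matrix = dollo.encode_character_matrix(
            genotype_table, outgroup_taxa=config.outgroup_taxa
        )
        dollo.write_nexus(matrix, out / "matrix.nex")
        best = dollo.search_most_parsimonious(
            matrix,
            config.outgroup_taxa,
            mode="heuristic",
            seed=seeds["search"],
            n_restarts=config.search_restarts,
        )
        if config.bootstrap_replicates > 0:
            support, freq = dollo.bootstrap_support(
                matrix,
                config.outgroup_taxa,
                replicates=config.bootstrap_replicates,
                seed=seeds["bootstrap"],
                reference_tree=best.topology,
            )
            best.bootstrap_support = support
            consensus_tree = dollo.majority_rule_consensus(freq, matrix.taxa)
            (out / "consensus.nwk").write_text(
                consensus_tree.newick(lengths=False) + "\n"
            )
        (out / "best_tree.nwk").write_text(best.newick(with_support=True) + "\n")

    # ---- report -----------------------------------------------------------
    report = {
        "seed": config.seed,
        "n_events": len(events),
        "n_annotations": len(annotations),
        "n_full_length": len(full_length),
        "n_young": len(young),
        "n_lineage_specific": len(lineage_specific),
        "n_selected": len(selected),
        "n_with_primers": len(primer_pairs),
        "category_counts": dict(sorted(counts.items())),
        "partition": partition,
        "n_taxa": matrix.n_taxa,
        "n_characters": matrix.n_characters,
        "tree_length": best.tree_length,
        "ci": None if best.ci != best.ci else round(best.ci, 3),
        "hi": None if best.hi != best.hi else round(best.hi, 3),
        "ri": None if best.ri != best.ri else round(best.ri, 3),
        "n_adjustments": len(audit),
        "n_findings": len(findings),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return PipelineResult(
        panel=panel,
        candidates=candidates,
        primer_pairs=primer_pairs,
        calls=calls,
        adjusted_calls=adjusted,
        findings=findings,
        classifications=classifications,
        category_counts=counts,
        partition=partition,
        matrix=matrix,
        best_tree=best,
        report=report,
    )
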
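"""In-silico PCR, genotype calls, locus categories, near-parallel findings."""

import numpy as np
import pytest

from aluphylo.genotype import (
    AmpliconFinding,
    Fragment,
    GenotypeCall,
    adjust_genotypes,
    call_genotype,
    classification_counts,
    classify_locus,
    detect_near_parallel,
    insilico_pcr,
    partition_summary,
)
from aluphylo.primers import PrimerPair
from aluphylo.simulate import build_consensus_set, revcomp


def make_pair(fwd, rev):
    return PrimerPair(fwd, rev, 0, 0, 59.0, 59.0, 50.0, 50.0, 0, 0)


@pytest.fixture(scope="module")
def pcr_setup():
    rng = np.random.default_rng(31)
    fwd = "".join(rng.choice(list("ACGT"), size=20))
    rev = "".join(rng.choice(list("ACGT"), size=20))
    spacer = "".join(rng.choice(list("ACGT"), size=205))
    insertion = "".join(rng.choice(list("ACGT"), size=322))
    empty = "CCA" + fwd + spacer + revcomp(rev) + "TGG"
    filled = "CCA" + fwd + spacer[:100] + insertion + spacer[100:] + revcomp(rev) + "TGG"
    return make_pair(fwd, rev), empty, filled


class TestInsilicoPCR:
    def test_homozygous_filled_two_identical_fragments(self, pcr_setup):
        pair, empty, filled = pcr_setup
        frags = insilico_pcr(pair, [filled, filled])
        assert [f.size for f in frags] == [567, 567]

    def test_heterozygote_two_distinct_sizes(self, pcr_setup):
        pair, empty, filled = pcr_setup
        frags = insilico_pcr(pair, [filled, empty])
        assert sorted(f.size for f in frags) == [245, 567]

    def test_primer_site_mutation_gives_null_allele(self, pcr_setup):
        pair, empty, filled = pcr_setup
        broken = empty.replace(pair.forward_seq, pair.forward_seq[:-1] + "N")
        frags = insilico_pcr(pair, [filled, broken])
        assert frags[0] is not None and frags[1] is None


class TestGenotypeCalls:
    @pytest.mark.parametrize(
        "sizes,expected,off",
        [
            ([567], (1, 1), False),
            ([567, 245], (1, 0), False),
            ([245], (0, 0), False),
            ([430], None, True),
            ([], None, False),
            ([560, 250], (1, 0), False),  # within 20 bp tolerance
        ],
    )
    def test_fragment_size_to_genotype(self, sizes, expected, off):
        frags = [Fragment(s, "") for s in sizes]
        call = call_genotype(frags, 567, 245, size_tolerance=20)
        assert call.genotype == expected
        assert call.off_size is off

    def test_inseparable_expected_sizes_rejected(self):
        with pytest.raises(ValueError, match="separable"):
            call_genotype([], 260, 245, size_tolerance=20)


def calls(species, genotypes):
    return [
        GenotypeCall(f"{species}_{i}", "L", g) for i, g in enumerate(genotypes)
    ]


PANEL = ("nancymaae", "trivirgatus", "vociferans", "azarae")


def build_species_calls(pattern):
    """pattern: species -> list of genotype tuples/None."""
    return {sp: calls(sp, gts) for sp, gts in pattern.items()}


class TestClassification:
    def test_fixed_present(self):
        by_sp = build_species_calls({sp: [(1, 1), (1, 1)] for sp in PANEL})
        assert classify_locus(by_sp, "nancymaae").category == "fixed_present"

    def test_fixed_absent(self):
        by_sp = build_species_calls({sp: [(0, 0), (0, 0)] for sp in PANEL})
        assert classify_locus(by_sp, "nancymaae").category == "fixed_absent"

    def test_reference_restricted_homozygous_present(self):
        pattern = {sp: [(0, 0), (0, 0)] for sp in PANEL}
        pattern["nancymaae"] = [(1, 1), (1, 1), (1, 1)]
        c = classify_locus(build_species_calls(pattern), "nancymaae")
        assert c.category == "restricted_hp"
        assert c.species == ("nancymaae",)

    def test_reference_restricted_polymorphic(self):
        pattern = {sp: [(0, 0), (0, 0)] for sp in PANEL}
        pattern["nancymaae"] = [(1, 1), (1, 0), (0, 0)]
        c = classify_locus(build_species_calls(pattern), "nancymaae")
        assert c.category == "restricted_poly"

    def test_red_necked_pair_sharing(self):
        pattern = {sp: [(0, 0), (0, 0)] for sp in PANEL}
        pattern["nancymaae"] = [(1, 1), (1, 1)]
        pattern["azarae"] = [(1, 1), (1, 0)]
        c = classify_locus(build_species_calls(pattern), "nancymaae")
        assert c.category == "shared_pair"
        assert c.species == ("azarae", "nancymaae")

    def test_three_species_sharing_excluding_basal(self):
        pattern = {sp: [(1, 1), (1, 1)] for sp in PANEL}
        pattern["vociferans"] = [(0, 0), (0, 0)]
        c = classify_locus(build_species_calls(pattern), "nancymaae")
        assert c.category == "shared_triple"
        assert "vociferans" not in c.species

    def test_erratic_pattern_is_ils(self):
        pattern = {
            "nancymaae": [(1, 0), (0, 0)],
            "trivirgatus": [(1, 1)],
            "vociferans": [(1, 0), (0, 0)],
            "azarae": [(0, 0)],
        }
        c = classify_locus(build_species_calls(pattern), "nancymaae")
        assert c.category == "other_ILS"

    def test_missing_species_ignored(self):
        pattern = {sp: [(1, 1)] for sp in PANEL}
        pattern["azarae"] = [None, None]
        c = classify_locus(build_species_calls(pattern), "nancymaae")
        assert c.category == "fixed_present"
        assert "azarae" not in c.species

    def test_all_missing_rejected(self):
        by_sp = build_species_calls({sp: [None] for sp in PANEL})
        with pytest.raises(ValueError, match="missing"):
            classify_locus(by_sp, "nancymaae")

    def test_single_sample_taxon_never_anchors_alone(self):
        # presence only in the auxiliary single-sample taxon: not "restricted"
        pattern = {sp: [(0, 0), (0, 0)] for sp in PANEL}
        pattern["griseimembra"] = [(1, 1)]
        c = classify_locus(
            build_species_calls(pattern),
            "nancymaae",
            auxiliary_species=("griseimembra",),
        )
        assert c.category == "fixed_absent"

    def test_partition_sums_to_total(self):
        rng = np.random.default_rng(17)
        classifications = []
        for i in range(60):
            pattern = {
                sp: [tuple(rng.integers(0, 2, size=2)) for _ in range(3)]
                for sp in PANEL
            }
            pattern = {
                sp: [(max(g), min(g)) for g in gts] for sp, gts in pattern.items()
            }
            classifications.append(
                classify_locus(build_species_calls(pattern), "nancymaae", f"L{i}")
            )
        summary = partition_summary(classification_counts(classifications))
        assert summary["total"] == 60
        assert (
            summary["fixed_present"]
            + summary["fixed_absent"]
            + summary["polymorphic"]
            == 60
        )


@pytest.fixture(scope="module")
def np_setup():
    rng = np.random.default_rng(41)
    consensus = build_consensus_set(3, 4, 300, seed=41)
    empty_ref = "".join(rng.choice(list("ACGT"), size=500))
    target_pos = 300  # target insertion point within the empty reference
    return consensus, empty_ref, target_pos, rng


class TestNearParallelDetection:
    def test_plain_empty_amplicon_no_finding(self, np_setup):
        consensus, empty_ref, target_pos, _ = np_setup
        assert (
            detect_near_parallel(empty_ref, empty_ref, target_pos, consensus)
            is None
        )

    def test_upstream_opposite_orientation_element(self, np_setup):
        consensus, empty_ref, target_pos, _ = np_setup
        # independent element 90 bp 5' of the target, opposite orientation
        insert_at = target_pos - 90
        element = revcomp(consensus[1].sequence + "A" * 14)
        amplicon = empty_ref[:insert_at] + element + empty_ref[insert_at:]
        finding = detect_near_parallel(
            amplicon, empty_ref, target_pos, consensus, target_orientation="+"
        )
        assert finding.kind == "near_parallel"
        assert finding.element_class == consensus[1].subfamily_name
        assert finding.orientation == "opposite"
        assert abs(finding.offset_bp - (-90)) <= 5

    def test_nonrepeat_insertion_is_artifact(self, np_setup):
        consensus, empty_ref, target_pos, rng = np_setup
        extra = "".join(rng.choice(list("ACGT"), size=224))
        amplicon = empty_ref[:150] + extra + empty_ref[150:]
        finding = detect_near_parallel(amplicon, empty_ref, target_pos, consensus)
        assert finding.kind == "artifact"
        assert finding.element_class == "non_repeat"
        assert abs(finding.insert_length - 224) <= 5

    def test_unalignable_amplicon_unresolved(self, np_setup):
        consensus, empty_ref, target_pos, rng = np_setup
        garbage = "".join(rng.choice(list("ACGT"), size=len(empty_ref)))
        finding = detect_near_parallel(garbage, empty_ref, target_pos, consensus)
        assert finding.kind == "unresolved"


class TestAdjustment:
    def base_calls(self):
        return {
            ("L1", "azarae_1"): GenotypeCall("azarae_1", "L1", (1, 1)),
            ("L1", "azarae_2"): GenotypeCall("azarae_2", "L1", (0, 0)),
            ("L2", "azarae_1"): GenotypeCall("azarae_1", "L2", (1, 0)),
        }

    def test_near_parallel_carrier_recoded_absent(self):
        finding = AmpliconFinding(
            "L1", "near_parallel", carriers=("azarae_1",), offset_bp=-90
        )
        adjusted, log = adjust_genotypes(self.base_calls(), [finding])
        assert adjusted[("L1", "azarae_1")].genotype == (0, 0)
        assert len(log) == 1
        assert log[0].old == (1, 1) and log[0].new == (0, 0)

    def test_no_findings_identity(self):
        calls = self.base_calls()
        adjusted, log = adjust_genotypes(calls, [])
        assert adjusted == calls
        assert log == []

    def test_audit_log_counts_changes_only(self):
        findings = [
            AmpliconFinding("L1", "near_parallel", carriers=("azarae_1", "azarae_2")),
        ]
        adjusted, log = adjust_genotypes(self.base_calls(), findings)
        # azarae_2 was already (0,0): only one actual change
        assert len(log) == 1

    def test_idempotent(self):
        findings = [AmpliconFinding("L1", "near_parallel", carriers=("azarae_1",))]
        once, log1 = adjust_genotypes(self.base_calls(), findings)
        twice, log2 = adjust_genotypes(once, findings)
        assert {k: v.genotype for k, v in once.items()} == {
            k: v.genotype for k, v in twice.items()
        }
        assert log2 == []

    def test_conflicting_findings_rejected(self):
        findings = [
            AmpliconFinding("L1", "near_parallel", carriers=("azarae_1",)),
            AmpliconFinding("L1", "unresolved", carriers=("azarae_1",)),
        ]
        with pytest.raises(ValueError, match="conflict"):
            adjust_genotypes(self.base_calls(), findings)

    def test_unknown_cell_rejected(self):
        findings = [AmpliconFinding("L9", "artifact", carriers=("azarae_1",))]
        with pytest.raises(KeyError):
            adjust_genotypes(self.base_calls(), findings)
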
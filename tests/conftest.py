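import pytest

from aluphylo.ascertain import CandidateLocus
from aluphylo.simulate import (
    SpeciesTree,
    build_consensus_set,
    realize_panel,
    simulate_insertion_events,
)


@pytest.fixture(scope="session")
def species_tree():
    return SpeciesTree.default()


@pytest.fixture(scope="session")
def consensus_set():
    return build_consensus_set(3, 4, 300, seed=7)


@pytest.fixture(scope="session")
def clean_panel(species_tree, consensus_set):
    """Panel without ILS, near-parallels or flanking divergence."""
    events = simulate_insertion_events(
        species_tree,
        rate=4.0,
        ils_prob=0.0,
        near_parallel_rate=0.0,
        consensus_set=consensus_set,
        seed=11,
    )
    return realize_panel(
        species_tree,
        events,
        backbone_length=350_000,
        substitution_rate=0.002,
        flank_divergence=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noisy_panel(species_tree, consensus_set):
    """Panel with default noise levels: ILS, near-parallels, flank drift."""
    events = simulate_insertion_events(
        species_tree,
        rate=5.0,
        ils_prob=0.05,
        near_parallel_rate=0.01,
        consensus_set=consensus_set,
        seed=23,
    )
    return realize_panel(
        species_tree,
        events,
        backbone_length=400_000,
        substitution_rate=0.002,
        flank_divergence=0.005,
        seed=23,
    )


def locus_from_panel(panel, event, taxon, flank=600):
    """Build a CandidateLocus from simulator truth for one carried event."""
    start, end = panel.element_intervals[(event.locus_id, taxon)]
    seq = panel.assemblies[taxon]
    return CandidateLocus(
        locus_id=event.locus_id,
        scaffold=taxon,
        start=start,
        end=end,
        element_sequence=seq[start:end],
        left_flank=seq[start - flank : start],
        right_flank=seq[end : end + flank],
        orientation=event.orientation,
    )


def bruteforce_dollo(tree, column):
    """Independent oracle: minimum changes over all ancestral assignments
    with root state 0 and at most one 0->1 transition.

    ``column`` maps taxon -> {0, 1, -1} (-1 = missing, free to resolve).
    Enumerates every 0/1 assignment to internal nodes and missing leaves.
    """
    import itertools

    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    free_leaves = [n for n in nodes if n.is_leaf and column[n.name] == -1]
    best = None
    for assign in itertools.product(
        [0, 1], repeat=len(internal) + len(free_leaves)
    ):
        state = {}
        for node, s in zip(internal, assign[: len(internal)]):
            state[id(node)] = s
        for leaf, s in zip(free_leaves, assign[len(internal) :]):
            state[id(leaf)] = s
        for n in nodes:
            if n.is_leaf and column[n.name] != -1:
                state[id(n)] = column[n.name]
        root = nodes[-1]
        # ancestral state is absence; a root in state 1 is itself the gain
        gains = 1 if state[id(root)] == 1 else 0
        losses = 0
        for parent, child in tree.edges():
            a, b = state[id(parent)], state[id(child)]
            if (a, b) == (0, 1):
                gains += 1
            elif (a, b) == (1, 0):
                losses += 1
        if gains > 1:
            continue
        cost = gains + losses
        if best is None or cost < best:
            best = cost
    return best
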
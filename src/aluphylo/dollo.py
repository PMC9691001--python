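"""Dollo parsimony on presence/absence characters.

Insertion presence/absence is scored under rooted Dollo parsimony
("Dollo.up"): absence is the ancestral state, each character may be gained
exactly once (at the most recent common ancestor of its carriers) and lost
any number of times.  The module provides character-matrix encoding, the
per-character step count, exhaustive and heuristic most-parsimonious-tree
search, nonparametric bootstrap supports, and the tree-fit statistics
CI = sum(m_i)/sum(s_i), HI = 1 - CI, RI = (sum(g_i)-sum(s_i))/(sum(g_i)-sum(m_i)),
where m_i = 1 for a variable character, s_i is the realized Dollo length and
g_i is the Dollo length on the fully unresolved star tree.

Missing states '?' are resolved to minimize steps.  NEXUS output carries a
PAUP-compatible ``ctype Dollo.up`` statement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .tree import Clade

MISSING_STATE = -1
_BIG = np.int32(10**6)


class UndefinedIndicesError(ValueError):
    """Raised when CI/HI/RI are undefined (no variable characters)."""


# ---------------------------------------------------------------------------
# character matrix
# ---------------------------------------------------------------------------

@dataclass
class CharacterMatrix:
    """taxa x loci presence/absence matrix; states 0, 1 and -1 (missing)."""

    taxa: list[str]
    loci: list[str]
    states: np.ndarray  # int8, shape (n_taxa, n_loci)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.taxa), len(self.loci)):
            raise ValueError("states shape does not match taxa x loci")
        if not np.isin(self.states, [-1, 0, 1]).all():
            raise ValueError("states must be 0, 1 or -1 (missing)")
        all_missing = (self.states == MISSING_STATE).all(axis=0)
        if all_missing.any():
            bad = [self.loci[i] for i in np.nonzero(all_missing)[0]]
            raise ValueError(f"columns with no observed state: {bad}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.loci)

    def column(self, locus: str) -> dict[str, int]:
        j = self.loci.index(locus)
        return {t: int(self.states[i, j]) for i, t in enumerate(self.taxa)}

    def variable_mask(self) -> np.ndarray:
        """Characters with both a 0 and a 1 observed."""
        has0 = (self.states == 0).any(axis=0)
        has1 = (self.states == 1).any(axis=0)
        return has0 & has1

    def subset_columns(self, index: Sequence[int]) -> "CharacterMatrix":
        index = list(index)
        return CharacterMatrix(
            list(self.taxa),
            [self.loci[j] for j in index],
            self.states[:, index],
        )


def encode_character_matrix(
    genotypes: Mapping[tuple[str, str], Optional[tuple[int, int]]],
    outgroup_taxa: Sequence[str] = (),
) -> CharacterMatrix:
    """Encode diploid genotypes to single presence/absence states.

    (1,1) and (1,0) -> 1; (0,0) -> 0; missing -> '?'.  Outgroup taxa absent
    from the table are appended with state 0 at every locus (ascertained in
    the ingroup reference; absence is the ancestral state).
    """
    loci = sorted({locus for locus, _ in genotypes})
    individuals = sorted({indiv for _, indiv in genotypes})
    taxa = individuals + [t for t in outgroup_taxa if t not in individuals]
    states = np.full((len(taxa), len(loci)), MISSING_STATE, dtype=np.int8)
    col = {locus: j for j, locus in enumerate(loci)}
    row = {taxon: i for i, taxon in enumerate(taxa)}
    for (locus, indiv), gt in genotypes.items():
        if gt is None:
            state = MISSING_STATE
        elif tuple(gt) in ((1, 1), (1, 0), (0, 1)):
            state = 1
        elif tuple(gt) == (0, 0):
            state = 0
        else:
            raise ValueError(f"unknown genotype code {gt!r} at {(locus, indiv)}")
        states[row[indiv], col[locus]] = state
    for taxon in outgroup_taxa:
        if taxon not in individuals:
            states[row[taxon], :] = 0
    return CharacterMatrix(taxa, loci, states)


# ---------------------------------------------------------------------------
# Dollo step counting
# ---------------------------------------------------------------------------

def _postorder_arrays(tree: Clade, taxa: Sequence[str]):
    """Flatten the tree: per-node children indices, leaves map to taxon rows."""
    nodes = list(tree.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    children = [[index[id(c)] for c in n.children] for n in nodes]
    leaf_row = [
        taxa.index(n.name) if n.is_leaf else -1 for n in nodes
    ]
    return children, leaf_row


def dollo_lengths(tree: Clade, matrix: CharacterMatrix) -> np.ndarray:
    """Dollo step count for every character on ``tree`` (vectorized).

    For each character the single gain is placed at the MRCA of the definite
    1-state taxa ('?' resolved to minimize steps); losses are the minimum
    number of 1->0 transitions below it.  All-0 (or all-missing-and-0)
    characters cost 0 steps.
    """
    children, leaf_row = _postorder_arrays(tree, matrix.taxa)
    n_nodes = len(children)
    n_chars = matrix.n_characters
    states = matrix.states
    loss = np.zeros((n_nodes, n_chars), dtype=np.int32)
    pure0 = np.zeros((n_nodes, n_chars), dtype=bool)
    count1 = np.zeros((n_nodes, n_chars), dtype=np.int32)
    for v in range(n_nodes):
        kids = children[v]
        if not kids:
            obs = states[leaf_row[v]]
            loss[v] = (obs == 0).astype(np.int32)  # loss on the leaf edge
            pure0[v] = obs != 1
            count1[v] = (obs == 1).astype(np.int32)
        else:
            sum_loss = loss[kids].sum(axis=0)
            pure = pure0[kids].all(axis=0)
            loss[v] = np.where(pure, np.minimum(1, sum_loss), sum_loss)
            pure0[v] = pure
            count1[v] = count1[kids].sum(axis=0)
    total1 = count1[-1]  # root is last in postorder
    # gain node = deepest node covering all 1s; loss[] is non-decreasing
    # above it, so min over covering nodes equals loss at the MRCA
    covering = count1 == total1[None, :]
    candidate = np.where(covering, loss, _BIG)
    steps = 1 + candidate.min(axis=0)
    steps[total1 == 0] = 0
    return steps.astype(np.int64)


def dollo_steps(tree: Clade, column: Mapping[str, int]) -> int:
    """Dollo steps for a single character given as taxon -> {0,1,-1}."""
    taxa = sorted(column)
    states = np.array([[column[t]] for t in taxa], dtype=np.int8).T
    matrix = CharacterMatrix(taxa, ["c"], states.T)
    return int(dollo_lengths(tree, matrix)[0])


def star_tree(taxa: Sequence[str]) -> Clade:
    return Clade(children=[Clade(t, 1.0) for t in taxa])


# ---------------------------------------------------------------------------
# tree search
# ---------------------------------------------------------------------------

@dataclass
class ScoredTree:
    topology: Clade
    tree_length: int
    min_steps: int = 0
    max_steps: int = 0
    ci: float = float("nan")
    hi: float = float("nan")
    ri: float = float("nan")
    ci_informative_only: float = float("nan")
    bootstrap_support: dict[frozenset, float] = field(default_factory=dict)
    alternatives: list[Clade] = field(default_factory=list)  # co-optimal trees

    def newick(self, with_support: bool = False) -> str:
        labels = None
        if with_support and self.bootstrap_support:
            labels = {k: round(v) for k, v in self.bootstrap_support.items()}
        return self.topology.newick(labels=labels)


def score_tree(tree: Clade, matrix: CharacterMatrix) -> int:
    return int(dollo_lengths(tree, matrix).sum())


def _root_with_outgroup(ingroup: Clade, outgroups: Sequence[str]) -> Clade:
    og = (
        Clade(outgroups[0], 1.0)
        if len(outgroups) == 1
        else Clade(children=[Clade(t, 1.0) for t in outgroups])
    )
    return Clade(children=[og, ingroup])


def enumerate_topologies(
    taxa: Sequence[str], outgroups: Sequence[str]
) -> list[Clade]:
    """All distinct tree shapes, rooted on the outgroup edge.

    Equivalent to enumerating unrooted topologies over
    {outgroup} + ingroup taxa: (2n-5)!! shapes for n tips.
    """
    ingroup = [t for t in taxa if t not in outgroups]
    if len(ingroup) < 2:
        raise ValueError("need >= 2 ingroup taxa")
    if len(ingroup) > 8:
        raise ValueError(
            f"exhaustive search over {len(ingroup)} ingroup taxa is too large; "
            "use the heuristic search"
        )

    def insert_everywhere(tree: Clade, leaf_name: str) -> list[Clade]:
        out = []
        n_edges = sum(1 for _ in tree.edges())
        for e in range(n_edges):
            t = tree.copy()
            edges = list(t.edges())
            parent, child = edges[e]
            new = Clade(children=[child, Clade(leaf_name, 1.0)], length=1.0)
            parent.children[parent.children.index(child)] = new
            out.append(t)
        return out

    base = Clade(children=[Clade(ingroup[0], 1.0), Clade(ingroup[1], 1.0)])
    shapes = [base]
    for name in ingroup[2:]:
        next_shapes = []
        for shape in shapes:
            # edges within the ingroup subtree, plus attachment at its root
            next_shapes.extend(insert_everywhere(shape, name))
            t = shape.copy()
            next_shapes.append(
                Clade(children=[t, Clade(name, 1.0)])
            )
        shapes = next_shapes
    return [_root_with_outgroup(s, outgroups) for s in shapes]


def _nni_neighbors(tree: Clade) -> list[Clade]:
    """Nearest-neighbor interchanges around internal edges (rooted form)."""
    out = []
    nodes = list(tree.postorder())
    for i, node in enumerate(nodes):
        if node.is_leaf or node is tree:
            continue
        if len(node.children) != 2:
            continue
        parent = next(
            (p for p in nodes if node in p.children), None
        )
        # parent == root would swap a subtree with the outgroup attachment
        if parent is None or parent is tree:
            continue
        siblings = [c for c in parent.children if c is not node]
        if not siblings:
            continue
        sib = siblings[0]
        for swap_idx in range(2):
            t = tree.copy()
            t_nodes = list(t.postorder())
            t_node = t_nodes[i]
            t_parent = next(p for p in t_nodes if t_node in p.children)
            t_sib = [c for c in t_parent.children if c is not t_node][0]
            moved = t_node.children[swap_idx]
            t_node.children[swap_idx] = t_sib
            t_parent.children[t_parent.children.index(t_sib)] = moved
            out.append(t)
    return out


def _spr_neighbors(tree: Clade, limit: Optional[int] = None) -> list[Clade]:
    """Subtree-pruning-regrafting moves within the ingroup subtree."""
    out = []
    root_children = tree.children
    if len(root_children) != 2:
        return out
    for prune_idx in range(len(list(tree.edges()))):
        edges = list(tree.edges())
        parent, subtree = edges[prune_idx]
        if parent is tree:  # never prune the outgroup/ingroup split
            continue
        pruned_names = set(subtree.leaf_names())
        t = tree.copy()
        t_edges = list(t.edges())
        t_parent, t_sub = t_edges[prune_idx]
        t_parent.children.remove(t_sub)
        # suppress the degree-2 node left behind
        if len(t_parent.children) == 1:
            only = t_parent.children[0]
            t_parent.name, t_parent.length = only.name, t_parent.length + only.length
            t_parent.children = only.children
        regraft_edges = [
            (p, c)
            for p, c in t.edges()
            if p is not t and not pruned_names & set(c.leaf_names())
        ]
        for p, c in regraft_edges:
            t2 = t.copy()
            t2_edges = list(t2.edges())
            match = None
            for (tp, tc), (op, oc) in zip(t2.edges(), t.edges()):
                if oc is c and op is p:
                    match = (tp, tc)
                    break
            if match is None:
                continue
            tp, tc = match
            new = Clade(children=[tc, t_sub.copy()], length=1.0)
            tp.children[tp.children.index(tc)] = new
            out.append(t2)
            if limit and len(out) >= limit:
                return out
    return out


def _stepwise_addition(
    matrix: CharacterMatrix,
    outgroups: Sequence[str],
    rng: np.random.Generator,
) -> Clade:
    ingroup = [t for t in matrix.taxa if t not in outgroups]
    order = [str(t) for t in rng.permutation(ingroup)]
    tree = _root_with_outgroup(
        Clade(children=[Clade(order[0], 1.0), Clade(order[1], 1.0)]),
        outgroups,
    )
    for name in order[2:]:
        best, best_score = None, None
        edges = list(tree.edges())
        for e, (parent, child) in enumerate(edges):
            if parent is tree and set(child.leaf_names()) == set(outgroups):
                continue
            t = tree.copy()
            t_edges = list(t.edges())
            tp, tc = t_edges[e]
            new = Clade(children=[tc, Clade(name, 1.0)], length=1.0)
            tp.children[tp.children.index(tc)] = new
            s = score_tree(t, matrix)
            if best_score is None or s < best_score:
                best, best_score = t, s
        tree = best
    return tree


def search_most_parsimonious(
    matrix: CharacterMatrix,
    outgroups: Sequence[str],
    mode: str = "heuristic",
    seed: int = 0,
    n_restarts: int = 10,
    use_spr: bool = True,
    compute_indices: bool = True,
) -> ScoredTree:
    """Find minimum Dollo-length tree(s), rooted on the outgroup edge.

    ``exhaustive`` enumerates all topologies (<= 9 distinct taxa) and records
    every co-optimal tree in ``alternatives``; ``heuristic`` runs random-order
    stepwise addition followed by NNI (and optionally SPR) hill climbing with
    ``n_restarts`` restarts.
    """
    if matrix.n_taxa < 4:
        raise ValueError("need >= 4 taxa")
    rng = np.random.default_rng(seed)
    if mode == "exhaustive":
        trees = enumerate_topologies(matrix.taxa, outgroups)
        scores = [score_tree(t, matrix) for t in trees]
        best_score = min(scores)
        best_trees = [t for t, s in zip(trees, scores) if s == best_score]
        result = ScoredTree(best_trees[0], best_score)
        result.alternatives = best_trees
    elif mode == "heuristic":
        best_tree, best_score = None, None
        for _ in range(max(1, n_restarts)):
            tree = _stepwise_addition(matrix, outgroups, rng)
            score = score_tree(tree, matrix)
            improved = True
            while improved:
                improved = False
                neighborhoods = [_nni_neighbors(tree)]
                if use_spr:
                    neighborhoods.append(_spr_neighbors(tree))
                for neighborhood in neighborhoods:
                    for cand in neighborhood:
                        s = score_tree(cand, matrix)
                        if s < score:
                            tree, score = cand, s
                            improved = True
                            break
                    if improved:
                        break
            if best_score is None or score < best_score:
                best_tree, best_score = tree, score
        result = ScoredTree(best_tree, best_score)
        result.alternatives = [best_tree]
    else:
        raise ValueError(f"unknown search mode {mode!r}")
    if compute_indices:
        try:
            stats = tree_indices(result.topology, matrix)
            result.min_steps = stats["min_steps"]
            result.max_steps = stats["max_steps"]
            result.ci = stats["ci"]
            result.hi = stats["hi"]
            result.ri = stats["ri"]
            result.ci_informative_only = stats["ci_informative_only"]
        except UndefinedIndicesError:
            pass
    return result


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    matrix: CharacterMatrix,
    outgroups: Sequence[str],
    replicates: int = 100,
    seed: int = 0,
    reference_tree: Optional[Clade] = None,
    n_restarts: int = 2,
    use_spr: bool = False,
) -> tuple[dict[frozenset, float], list[tuple[frozenset, float]]]:
    """Nonparametric bootstrap over characters.

    Resamples columns with replacement, re-runs the heuristic search and
    reports, for every internal clade of the reference (best) tree, the
    percentage of replicate best trees containing that clade.  Also returns
    the full clade frequency table (input to a majority-rule consensus).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    if reference_tree is None:
        reference_tree = search_most_parsimonious(
            matrix, outgroups, seed=seed, compute_indices=False
        ).topology
    counts: dict[frozenset, int] = {}
    n = matrix.n_characters
    for _ in range(replicates):
        idx = rng.integers(0, n, size=n)
        rep = matrix.subset_columns(idx)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        best = search_most_parsimonious(
            rep,
            outgroups,
            seed=rep_seed,
            n_restarts=n_restarts,
            use_spr=use_spr,
            compute_indices=False,
        )
        for clade in set(best.topology.clades()):
            counts[clade] = counts.get(clade, 0) + 1
    freq_table = sorted(
        ((clade, 100.0 * c / replicates) for clade, c in counts.items()),
        key=lambda x: -x[1],
    )
    support = {
        clade: 100.0 * counts.get(clade, 0) / replicates
        for clade in reference_tree.clades()
    }
    return support, freq_table


def majority_rule_consensus(
    freq_table: Sequence[tuple[frozenset, float]], taxa: Sequence[str]
) -> Clade:
    """Greedy majority-rule consensus from a clade frequency table."""
    keep = [
        (clade, f)
        for clade, f in sorted(freq_table, key=lambda x: -x[1])
        if f > 50.0
    ]
    accepted: list[frozenset] = []
    for clade, _ in keep:
        if all(
            clade <= other or other <= clade or not clade & other
            for other in accepted
        ):
            accepted.append(clade)
    # build the tree top-down
    root = Clade(children=[Clade(t, 1.0) for t in taxa])
    for clade in sorted(accepted, key=len, reverse=True):
        if len(clade) in (1, len(taxa)):
            continue
        host = root
        while True:
            nxt = next(
                (
                    c
                    for c in host.children
                    if not c.is_leaf and clade <= frozenset(c.leaf_names())
                ),
                None,
            )
            if nxt is None:
                break
            host = nxt
        members = [
            c for c in host.children if frozenset(c.leaf_names()) <= clade
        ]
        if len(members) < 2:
            continue
        for m in members:
            host.children.remove(m)
        host.children.append(Clade(children=members, length=1.0))
    return root


# ---------------------------------------------------------------------------
# indices
# ---------------------------------------------------------------------------

def tree_indices(tree: Clade, matrix: CharacterMatrix) -> dict:
    """Tree length and CI/HI/RI under Dollo parsimony.

    Constant characters are excluded throughout; parsimony-uninformative
    characters (g_i == m_i) are excluded from the RI sums (and from the
    alternative CI reported as ``ci_informative_only``).
    """
    variable = matrix.variable_mask()
    s_all = dollo_lengths(tree, matrix)
    if not variable.any():
        raise UndefinedIndicesError(
            "all characters constant: CI/HI/RI undefined"
        )
    star = star_tree(matrix.taxa)
    g_all = dollo_lengths(star, matrix)
    s = s_all[variable]
    g = g_all[variable]
    m = np.ones_like(s)
    ci = float(m.sum() / s.sum())
    informative = g > m
    if informative.any():
        denom = g[informative].sum() - m[informative].sum()
        ri = float((g[informative].sum() - s[informative].sum()) / denom)
        ci_inf = float(m[informative].sum() / s[informative].sum())
    else:
        ri = float("nan")
        ci_inf = float("nan")
    return {
        "tree_length": int(s_all.sum()),
        "variable_length": int(s.sum()),
        "min_steps": int(m.sum()),
        "max_steps": int(g.sum()),
        "ci": ci,
        "hi": 1.0 - ci,
        "ri": ri,
        "ci_informative_only": ci_inf,
        "n_variable": int(variable.sum()),
        "n_informative": int(informative.sum()),
        "n_constant": int((~variable).sum()),
    }


# ---------------------------------------------------------------------------
# NEXUS / CSV IO
# ---------------------------------------------------------------------------

def write_nexus(matrix: CharacterMatrix, path: str | Path) -> None:
    symbols = {0: "0", 1: "1", MISSING_STATE: "?"}
    width = max(len(t) for t in matrix.taxa) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(
            f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};\n"
        )
        fh.write(
            '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;\n'
        )
        fh.write("    MATRIX\n")
        for i, taxon in enumerate(matrix.taxa):
            row = "".join(symbols[int(x)] for x in matrix.states[i])
            fh.write(f"    {taxon:<{width}}{row}\n")
        fh.write("    ;\nEND;\n\n")
        fh.write("BEGIN ASSUMPTIONS;\n")
        fh.write("    OPTIONS DEFTYPE=DOLLO.UP;\n")
        fh.write("END;\n\n")
        fh.write("BEGIN PAUP;\n    ctype Dollo.up: all;\nEND;\n")


def read_nexus(path: str | Path) -> CharacterMatrix:
    import dendropy

    data = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    taxa = [t.label.replace(" ", "_") for t in data.taxon_namespace]
    loci: list[str] = []
    rows = []
    for taxon in data.taxon_namespace:
        seq = data[taxon]
        rows.append(
            [
                MISSING_STATE
                if str(c) in ("?", "-")
                else int(str(c))
                for c in seq
            ]
        )
    n_char = len(rows[0])
    loci = [f"char_{j + 1}" for j in range(n_char)]
    return CharacterMatrix(taxa, loci, np.array(rows, dtype=np.int8))


def read_matrix_csv(path: str | Path) -> CharacterMatrix:
    """CSV with taxa as rows (first column), loci as remaining columns."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    states = df.fillna(MISSING_STATE).to_numpy(dtype=np.int8)
    return CharacterMatrix(list(df.index), list(df.columns), states)
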
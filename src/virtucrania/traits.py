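"""Discrete (non-metric) cranial traits: scoring, distances and trees.

Covers the phylogenetic side of the pipeline: consensus scoring of
multi-individual samples, derived-trait ("Neanderthal condition") counts,
pairwise character distances, neighbour-joining, Fitch parsimony and
exhaustive maximum-parsimony search with strict consensus, plus minimal
NEXUS and Newick I/O. All algorithms are exact and deterministic; the MP
search enumerates every unrooted binary topology (practical for <= 10
taxa, as in small hominin comparative samples).
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CharacterMatrix",
    "PhyloTree",
    "majority_state",
    "combine_pair",
    "count_derived",
    "character_distance",
    "neighbor_joining",
    "fitch_score",
    "exhaustive_mp",
    "strict_consensus",
    "read_nexus",
    "write_nexus",
]

MISSING = "?"


@dataclass
class CharacterMatrix:
    """Taxa x discrete characters, symbols from {0..9, ?}."""

    taxa: list[str]
    characters: list[str]
    states: list[list[str]]  # rows follow taxa order
    derived_state_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.states) != len(self.taxa):
            raise ValueError("one state row per taxon required")
        for t, row in zip(self.taxa, self.states):
            if len(row) != len(self.characters):
                raise ValueError(f"row for {t!r} has wrong length")
            for s in row:
                if s != MISSING and s not in "0123456789":
                    raise ValueError(f"invalid state symbol {s!r} for {t!r}")

    def row(self, taxon: str) -> list[str]:
        return self.states[self.taxa.index(taxon)]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)


class PhyloTree:
    """Unrooted phylogenetic tree with optional branch lengths.

    Leaves are taxon-name strings; internal nodes are integers. Stored as
    an adjacency map with per-edge lengths.
    """

    def __init__(self) -> None:
        self.adj: dict[object, dict[object, float | None]] = {}

    # -- construction ----------------------------------------------------

    def add_edge(self, a, b, length: float | None = None) -> None:
        self.adj.setdefault(a, {})[b] = length
        self.adj.setdefault(b, {})[a] = length

    def remove_edge(self, a, b) -> None:
        del self.adj[a][b]
        del self.adj[b][a]
        for n in (a, b):
            if not self.adj[n]:
                del self.adj[n]

    def set_length(self, a, b, length: float) -> None:
        self.adj[a][b] = length
        self.adj[b][a] = length

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        for a, nbrs in self.adj.items():
            t.adj[a] = dict(nbrs)
        return t

    # -- queries ---------------------------------------------------------

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n in self.adj if isinstance(n, str))

    @property
    def edges(self) -> list[tuple]:
        seen = set()
        out = []
        for a, nbrs in self.adj.items():
            for b, ln in nbrs.items():
                e = tuple(sorted((repr(a), repr(b))))
                if e not in seen:
                    seen.add(e)
                    out.append((a, b, ln))
        return out

    def degree(self, node) -> int:
        return len(self.adj[node])

    def edge_length(self, a, b) -> float | None:
        return self.adj[a][b]

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the canonical side.

        The canonical side is the one *not* containing the
        lexicographically first leaf, so splits compare across trees.
        """
        leaves = self.leaves
        if not leaves:
            return set()
        anchor = leaves[0]
        out: set[frozenset] = set()
        for a, b, _ in self.edges:
            side = self._leafset_beyond(a, b)
            if anchor in side:
                side = frozenset(leaves) - side
            if 1 < len(side) < len(leaves) - 1:
                out.add(frozenset(side))
        return out

    def _leafset_beyond(self, a, b) -> frozenset:
        """Leaves on b's side of edge (a, b)."""
        stack, seen, found = [b], {a, b}, []
        while stack:
            n = stack.pop()
            if isinstance(n, str):
                found.append(n)
            for m in self.adj[n]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return frozenset(found)

    def is_binary(self) -> bool:
        return all(
            self.degree(n) == 3 for n in self.adj if not isinstance(n, str)
        ) and all(self.degree(n) == 1 for n in self.leaves)

    # -- Newick ----------------------------------------------------------

    def to_newick(self, include_lengths: bool = True) -> str:
        leaves = self.leaves
        if not leaves:
            return ";"
        if len(self.adj) == 1:
            return f"{leaves[0]};"
        anchor = leaves[0]
        root = next(iter(self.adj[anchor]))

        def rec(node, parent) -> str:
            children = [n for n in self.adj[node] if n is not parent]
            if not children and isinstance(node, str):
                return node
            parts = []
            for c in children:
                s = rec(c, node)
                ln = self.adj[node][c]
                if include_lengths and ln is not None:
                    s += f":{ln:.9g}"
                parts.append(s)
            label = node if isinstance(node, str) else ""
            return f"({','.join(parts)}){label}"

        inner = rec(root, None)
        return inner + ";"


# ---------------------------------------------------------------------------
# scoring


def majority_state(rows: list[list[str]]) -> list[str]:
    """Per-character most frequent non-missing state over individuals.

    Ties and all-missing characters yield '?'. Used to collapse a
    multi-individual sample (e.g. 17 individuals) into one taxon row.
    """
    if not rows:
        raise ValueError("majority_state needs at least one row")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("rows must have equal length")
    out = []
    for j in range(length):
        counts: dict[str, int] = {}
        for r in rows:
            if r[j] != MISSING:
                counts[r[j]] = counts.get(r[j], 0) + 1
        if not counts:
            out.append(MISSING)
            continue
        best = max(counts.values())
        winners = [s for s, c in counts.items() if c == best]
        out.append(winners[0] if len(winners) == 1 else MISSING)
    return out


def combine_pair(row_a: list[str], row_b: list[str]) -> list[str]:
    """Combine two individuals into one taxon row.

    Agreement keeps the state; a single missing value defers to the other
    individual; disagreement is conservatively coded missing.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    out = []
    for a, b in zip(row_a, row_b):
        if a == b:
            out.append(a)
        elif a == MISSING:
            out.append(b)
        elif b == MISSING:
            out.append(a)
        else:
            out.append(MISSING)
    return out


def count_derived(row: list[str], derived_state_map: dict[str, str], characters: list[str]) -> tuple[int, int]:
    """Count characters in the derived condition: returns (k, n_characters).

    The denominator is the full character count (missing/uncertain scores
    still count toward n), matching the field convention of reporting
    e.g. 15/20 derived traits.
    """
    if len(row) != len(characters):
        raise ValueError("row length must equal character count")
    k = sum(
        1
        for s, c in zip(row, characters)
        if s != MISSING and s == derived_state_map.get(c)
    )
    return k, len(characters)


def character_distance(matrix: CharacterMatrix) -> np.ndarray:
    """Pairwise proportion of mismatching characters (mean character difference).

    Characters missing in either taxon are excluded pairwise; a pair with
    no comparable characters gets distance 0 with a warning.
    """
    n = matrix.n_taxa
    if n < 2:
        raise ValueError("need at least 2 taxa")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = matrix.states[i], matrix.states[j]
            comparable = [(a, b) for a, b in zip(ri, rj) if MISSING not in (a, b)]
            if not comparable:
                warnings.warn(
                    f"no comparable characters between {matrix.taxa[i]!r} and "
                    f"{matrix.taxa[j]!r}; distance set to 0",
                    stacklevel=2,
                )
                d = 0.0
            else:
                d = sum(a != b for a, b in comparable) / len(comparable)
            D[i, j] = D[j, i] = d
    return D


# ---------------------------------------------------------------------------
# neighbour joining


def neighbor_joining(distances: np.ndarray, taxa: list[str]) -> PhyloTree:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of cluster labels. Negative branch lengths are clamped to zero
    with the deficit moved to the sister branch.
    """
    D = np.asarray(distances, dtype=float)
    n = len(taxa)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")

    tree = PhyloTree()
    nodes: list[object] = list(taxa)
    labels: dict[object, str] = {t: t for t in taxa}
    dist: dict[tuple, float] = {}
    for i in range(n):
        for j in range(n):
            dist[(nodes[i], nodes[j])] = D[i, j]
    next_internal = 0

    active = list(nodes)
    while len(active) > 2:
        m = len(active)
        r = {a: sum(dist[(a, b)] for b in active if b is not a) for a in active}
        best = None
        best_q = np.inf
        for a, b in itertools.combinations(active, 2):
            q = (m - 2) * dist[(a, b)] - r[a] - r[b]
            key = tuple(sorted((labels[a], labels[b])))
            if q < best_q - 1e-12 or (
                abs(q - best_q) <= 1e-12 and best is not None and key < best[2]
            ):
                best_q = q
                best = (a, b, key)
        a, b, _ = best
        u = next_internal
        next_internal += 1
        la = 0.5 * dist[(a, b)] + (r[a] - r[b]) / (2 * (m - 2))
        lb = dist[(a, b)] - la
        # clamp negatives, moving the deficit to the sister branch
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        tree.add_edge(u, a, la)
        tree.add_edge(u, b, lb)
        labels[u] = min(labels[a], labels[b])
        for c in active:
            if c is a or c is b:
                continue
            duc = 0.5 * (dist[(a, c)] + dist[(b, c)] - dist[(a, b)])
            dist[(u, c)] = dist[(c, u)] = duc
        active = [c for c in active if c is not a and c is not b] + [u]

    a, b = active
    tree.add_edge(a, b, max(dist[(a, b)], 0.0))
    return tree


# ---------------------------------------------------------------------------
# parsimony


def _rooted_order(tree: PhyloTree) -> tuple[object, list[tuple]]:
    """Pick an internal root (or a leaf's neighbour) and return a postorder
    list of (node, parent)."""
    internals = [n for n in tree.adj if not isinstance(n, str)]
    root = internals[0] if internals else next(iter(tree.adj))
    order = []
    stack = [(root, None)]
    visited = {root}
    seq = []
    while stack:
        node, parent = stack.pop()
        seq.append((node, parent))
        for nbr in tree.adj[node]:
            if nbr is not parent and nbr not in visited:
                visited.add(nbr)
                stack.append((nbr, node))
    return root, list(reversed(seq))


def fitch_score(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    """Parsimony length of the tree: summed Fitch counts over characters.

    '?' is treated as full ambiguity (the set of all states observed for
    that character); characters with no observed state contribute 0.
    """
    if set(tree.leaves) != set(matrix.taxa):
        raise ValueError("tree leaves must match matrix taxa exactly")
    _, postorder = _rooted_order(tree)
    total = 0
    for j in range(matrix.n_characters):
        observed = {
            matrix.states[i][j]
            for i in range(matrix.n_taxa)
            if matrix.states[i][j] != MISSING
        }
        if not observed:
            continue
        full = frozenset(observed)
        sets: dict[object, frozenset] = {}
        changes = 0
        for node, parent in postorder:
            if isinstance(node, str):
                s = matrix.states[matrix.taxa.index(node)][j]
                sets[node] = full if s == MISSING else frozenset((s,))
            else:
                children = [n for n in tree.adj[node] if n is not parent]
                acc = None
                for c in children:
                    cs = sets[c]
                    if acc is None:
                        acc = cs
                        continue
                    inter = acc & cs
                    if inter:
                        acc = inter
                    else:
                        acc = acc | cs
                        changes += 1
                sets[node] = acc
        total += changes
    return total


def _all_topologies(taxa: list[str]):
    """Yield every unrooted binary topology by stepwise addition."""
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    base = PhyloTree()
    base.add_edge(-1, taxa[0])
    base.add_edge(-1, taxa[1])
    base.add_edge(-1, taxa[2])

    def expand(tree: PhyloTree, k: int):
        if k == len(taxa):
            yield tree
            return
        new_leaf = taxa[k]
        new_internal = -(k - 1)  # unique negative id per addition level
        for a, b, ln in tree.edges:
            t = tree.copy()
            t.remove_edge(a, b)
            t.add_edge(a, new_internal)
            t.add_edge(b, new_internal)
            t.add_edge(new_leaf, new_internal)
            yield from expand(t, k + 1)

    yield from expand(base, 3)


def exhaustive_mp(
    matrix: CharacterMatrix, max_taxa: int = 10
) -> tuple[list[PhyloTree], PhyloTree]:
    """Exhaustive maximum-parsimony search and strict consensus.

    Enumerates all 3*5*...*(2n-5) unrooted binary topologies, scores each
    with Fitch parsimony and returns every minimum-length tree plus their
    strict consensus (all edges not shared by every MP tree collapsed).
    """
    n = matrix.n_taxa
    if n > max_taxa:
        raise ValueError(
            f"{n} taxa exceeds the exhaustive-search limit of {max_taxa}; "
            "heuristic tree search is out of scope"
        )
    taxa = list(matrix.taxa)
    best_score = None
    best_trees: list[PhyloTree] = []
    for topo in _all_topologies(taxa):
        s = fitch_score(topo, matrix)
        if best_score is None or s < best_score:
            best_score = s
            best_trees = [topo.copy()]
        elif s == best_score:
            best_trees.append(topo.copy())
    return best_trees, strict_consensus(best_trees)


def strict_consensus(trees: list[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the splits present in every input tree."""
    if not trees:
        raise ValueError("no trees given")
    leaves = trees[0].leaves
    for t in trees[1:]:
        if t.leaves != leaves:
            raise ValueError("trees must share a leaf set")
    shared = set.intersection(*(t.splits() for t in trees))
    return tree_from_splits(leaves, shared)


def tree_from_splits(leaves: list[str], splits: set[frozenset]) -> PhyloTree:
    """Build the (possibly multifurcating) unrooted tree realising a set of
    pairwise-compatible splits (each given as the side excluding the first
    leaf)."""
    anchor = leaves[0]
    rest = [l for l in leaves if l != anchor]
    clades = sorted(splits, key=len)  # small first: nested build-up

    counter = itertools.count(1)
    tree = PhyloTree()
    root = 0

    def build(members: list[str], available: list[frozenset]):
        """Return list of (child_node_builder) attachments for members."""
        node = next(counter)
        maximal = []
        covered: set[str] = set()
        for cl in sorted(available, key=len, reverse=True):
            if cl <= set(members) and not any(cl <= m for m in maximal):
                maximal.append(cl)
        for cl in maximal:
            sub_avail = [c for c in available if c < cl]
            child = build(sorted(cl), sub_avail)
            tree.add_edge(node, child)
            covered |= set(cl)
        for leaf in members:
            if leaf not in covered:
                tree.add_edge(node, leaf)
        return node

    top = build(rest, list(clades))
    tree.add_edge(top, anchor)
    return tree


# ---------------------------------------------------------------------------
# NEXUS I/O (minimal DATA-block dialect, MISSING='?')


def write_nexus(matrix: CharacterMatrix, path) -> None:
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        "    FORMAT DATATYPE=STANDARD MISSING=? SYMBOLS=\"0123456789\";",
        "    MATRIX",
    ]
    width = max(len(t) for t in matrix.taxa) + 2
    for t, row in zip(matrix.taxa, matrix.states):
        safe = t.replace(" ", "_")
        lines.append(f"        {safe:<{width}}{''.join(row)}")
    lines += ["    ;", "END;", ""]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))


def read_nexus(path) -> CharacterMatrix:
    text = open(path, encoding="utf-8").read()
    m = re.search(r"DIMENSIONS\s+NTAX\s*=\s*(\d+)\s+NCHAR\s*=\s*(\d+)", text, re.I)
    if not m:
        raise ValueError("NEXUS file lacks a DIMENSIONS line")
    ntax, nchar = int(m.group(1)), int(m.group(2))
    mm = re.search(r"MATRIX(.*?);", text, re.S | re.I)
    if not mm:
        raise ValueError("NEXUS file lacks a MATRIX block")
    taxa, states = [], []
    for line in mm.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"cannot parse matrix line: {line!r}")
        taxa.append(parts[0])
        states.append(list(parts[1]))
    if len(taxa) != ntax or any(len(r) != nchar for r in states):
        raise ValueError("matrix dimensions disagree with DIMENSIONS line")
    characters = [f"char_{i + 1}" for i in range(nchar)]
    return CharacterMatrix(taxa=taxa, characters=characters, states=states)
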
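"""Parsimony scoring, heuristic tree search, and branch-support indices.

Tree length for unordered (non-additive) characters is computed by the
Fitch/Hartigan downpass generalised to polytomies: at each internal node
the preferred state-set is the set of states receiving the maximum number
of "votes" from child state-sets, and each child short of that maximum
costs one step.  Ordered (additive) characters are scored by Sankoff
dynamic programming with linear step costs.  Missing cells carry the full
observed state universe of their character and can never add steps on
their own; polymorphic cells carry their state-set.

Heuristic search follows the classic parsimony recipe: seeded
random-addition-sequence stepwise addition followed by tree bisection and
reconnection (TBR) hill climbing, retaining every distinct topology at
the best length found.  Bremer decay indices use reverse-constraint
searches (shortest tree *lacking* the clade).

Public tree objects are :class:`dendropy.Tree`; a compact adjacency
representation is used internally during search.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

from .io_formats import CharacterMatrix, normalize_label

__all__ = [
    "SearchConfig",
    "TreeStats",
    "fitch_length",
    "char_min_steps",
    "char_max_steps",
    "ensemble_indices",
    "heuristic_search",
    "exhaustive_search",
    "strict_consensus",
    "prune_taxon",
    "decay_index",
    "tree_key",
    "trees_to_nexus",
]

_PENALTY = 10 ** 9  # added to the length of trees violating a reverse constraint


@dataclass
class SearchConfig:
    """Settings for heuristic parsimony search.

    ``n_replicates`` random addition sequences are run; replicate ``r``
    uses seed ``seed + r`` so runs are reproducible and parallelisable.
    ``max_trees_held`` bounds the equal-length tree pool (None =
    unlimited).  The outgroup is used only to orient output trees.
    """

    n_replicates: int = 10
    seed: int = 0
    outgroup: str | None = None
    max_trees_held: int | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class TreeStats:
    """Tree length and PAUP-style ensemble homoplasy indices."""

    length: int
    ci: float
    ri: float | None
    rc: float | None


# ---------------------------------------------------------------------------
# Character preprocessing
# ---------------------------------------------------------------------------

class _CharData:
    """Matrix recoded for fast scoring: bitmask arrays for unordered
    characters, per-state cost stacks for ordered ones."""

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        self.taxa = matrix.taxa
        self.index = {normalize_label(t): i for i, t in enumerate(matrix.taxa)}
        self.k = max(matrix.n_states, 1)
        if self.k > 16:
            raise ValueError("more than 16 character states not supported")

        flags = matrix.ordered_flags
        self.unordered_cols = [j for j in range(matrix.n_characters) if not flags[j]]
        self.ordered_cols = [j for j in range(matrix.n_characters) if flags[j]]

        n, k = matrix.n_taxa, self.k
        # per-character observed-state universe (missing cells adopt it)
        universe = [0] * matrix.n_characters
        for row in matrix.cells:
            for j, cell in enumerate(row):
                for s in cell:
                    universe[j] |= 1 << s
        universe = [u if u else 1 for u in universe]  # all-missing: inert state 0

        m_u = len(self.unordered_cols)
        self.leaf_masks = np.zeros((n, m_u), dtype=np.uint16)
        for i, row in enumerate(matrix.cells):
            for jj, j in enumerate(self.unordered_cols):
                cell = row[j]
                mask = 0
                for s in cell:
                    mask |= 1 << s
                self.leaf_masks[i, jj] = mask if mask else universe[j]

        m_o = len(self.ordered_cols)
        if m_o:
            big = np.float32(1e7)
            self.leaf_costs = np.full((n, k, m_o), big, dtype=np.float32)
            for i, row in enumerate(matrix.cells):
                for jj, j in enumerate(self.ordered_cols):
                    cell = row[j] or {s for s in range(k) if universe[j] >> s & 1}
                    for s in cell:
                        self.leaf_costs[i, :, jj][s] = 0.0
            self.step_cost = np.abs(
                np.arange(k)[:, None] - np.arange(k)[None, :]
            ).astype(np.float32)
        else:
            self.leaf_costs = None
            self.step_cost = None


def _postorder(adj: dict[int, list[int]], n_leaves: int) -> list[tuple[int, list[int]]]:
    """(node, children) pairs in postorder, rooted at an arbitrary internal
    node (or a leaf for degenerate 1–2 taxon trees)."""
    root = next((v for v in adj if v >= n_leaves), None)
    if root is None:
        root = next(iter(adj))
    out: list[tuple[int, list[int]]] = []
    stack = [(root, -1, False)]
    while stack:
        node, parent, expanded = stack.pop()
        children = [w for w in adj[node] if w != parent]
        if expanded or not children:
            if children:
                out.append((node, children))
        else:
            stack.append((node, parent, True))
            for w in children:
                stack.append((w, node, False))
    return out


def _score_adj(adj: dict[int, list[int]], data: _CharData) -> int:
    """Parsimony length of an adjacency-coded tree (leaves = matrix indices)."""
    n = len(data.taxa)
    order = _postorder(adj, n)
    total = 0

    if data.unordered_cols:
        k = data.k
        masks: dict[int, np.ndarray] = {}
        m = data.leaf_masks.shape[1]
        steps = 0
        for node, children in order:
            rows = [masks[c] if c >= n or c in masks else data.leaf_masks[c]
                    for c in children]
            if len(rows) == 2:
                # classic Fitch rule (= Hartigan for two children)
                a, b = rows
                inter = a & b
                empty = inter == 0
                steps += int(empty.sum())
                masks[node] = np.where(empty, a | b, inter)
                continue
            cm = np.stack(rows)
            votes = np.stack([((cm >> s) & 1).sum(axis=0) for s in range(k)])
            mx = votes.max(axis=0)
            steps += int((cm.shape[0] - mx).sum())
            pref = np.zeros(m, dtype=np.uint16)
            for s in range(k):
                pref |= (votes[s] == mx).astype(np.uint16) << s
            masks[node] = pref
        total += steps

    if data.ordered_cols:
        costs: dict[int, np.ndarray] = {}
        M = data.step_cost  # (k, k)
        last = None
        for node, children in order:
            acc = None
            for c in children:
                child = costs[c] if (c >= n or c in costs) else data.leaf_costs[c]
                # min over child state t of M[s, t] + child[t]
                contrib = (M[:, :, None] + child[None, :, :]).min(axis=1)
                acc = contrib if acc is None else acc + contrib
            costs[node] = acc
            last = node
        total += int(np.round(costs[last].min(axis=0).sum()))

    return total


# ---------------------------------------------------------------------------
# Public scoring operations
# ---------------------------------------------------------------------------

def _tree_to_adj(tree: dendropy.Tree, data: _CharData) -> dict[int, list[int]]:
    n = len(data.taxa)
    adj: dict[int, list[int]] = {}
    next_id = n
    ids: dict[object, int] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            label = normalize_label(node.taxon.label)
            if label not in data.index:
                raise KeyError(f"tree tip {label!r} not present in matrix")
            ids[node] = data.index[label]
        else:
            ids[node] = next_id
            next_id += 1
        adj.setdefault(ids[node], [])
        if node.parent_node is not None:
            adj[ids[node]].append(ids[node.parent_node])
            adj[ids[node.parent_node]].append(ids[node])
    return adj


def fitch_length(tree: dendropy.Tree, matrix: CharacterMatrix) -> int:
    """Parsimony tree length (steps) of ``tree`` on ``matrix``.

    The score is invariant under re-rooting; polytomies are scored
    exactly (Hartigan generalisation for unordered characters, Sankoff
    for ordered ones).
    """
    data = _CharData(matrix)
    return _score_adj(_tree_to_adj(tree, data), data)


def _min_cover_size(cells: list[frozenset[int]], k: int) -> int:
    """Smallest number of states hitting every non-missing cell."""
    cells = [c for c in cells if c]
    if not cells:
        return 0
    states = sorted(set().union(*cells))
    for size in range(1, len(states) + 1):
        for combo in itertools.combinations(states, size):
            cs = set(combo)
            if all(cell & cs for cell in cells):
                return size
    return len(states)


def char_min_steps(matrix: CharacterMatrix, character: int) -> int:
    """Minimum conceivable steps for one character on any tree."""
    cells = [row[character] for row in matrix.cells]
    scored = [c for c in cells if c]
    if not scored:
        return 0
    if matrix.ordered_flags[character]:
        # smallest integer interval hitting every cell, minus nothing: range
        states = sorted(set().union(*scored))
        best = states[-1] - states[0]
        for lo in states:
            for hi in states:
                if hi < lo:
                    continue
                if all(any(lo <= s <= hi for s in c) for c in scored):
                    best = min(best, hi - lo)
        return best
    return _min_cover_size(cells, matrix.n_states) - 1


def char_max_steps(matrix: CharacterMatrix, character: int) -> int:
    """Steps for one character on the star tree (the conceivable maximum).

    For unordered characters this equals (scored tips) − (frequency of the
    most common state), with polymorphic tips assigned to minimise steps.
    """
    cells = [row[character] for row in matrix.cells]
    scored = [c for c in cells if c]
    if not scored:
        return 0
    states = sorted(set().union(*scored))
    if matrix.ordered_flags[character]:
        return min(sum(min(abs(s - t) for t in c) for c in scored) for s in states)
    best_freq = max(sum(1 for c in scored if s in c) for s in states)
    return len(scored) - best_freq


def ensemble_indices(tree: dendropy.Tree, matrix: CharacterMatrix) -> TreeStats:
    """PAUP-style ensemble CI, RI and RC over all included characters.

    CI = Σmin/L, RI = (Σmax − L)/(Σmax − Σmin), RC = CI·RI.  When the
    matrix has no parsimony-informative variation (Σmax = Σmin) the RI is
    undefined and reported as None.
    """
    length = fitch_length(tree, matrix)
    smin = sum(char_min_steps(matrix, j) for j in range(matrix.n_characters))
    smax = sum(char_max_steps(matrix, j) for j in range(matrix.n_characters))
    ci = smin / length if length else 1.0
    if smax == smin:
        ri = rc = None
    else:
        ri = (smax - length) / (smax - smin)
        rc = ci * ri
    return TreeStats(length=length, ci=ci, ri=ri, rc=rc)


# ---------------------------------------------------------------------------
# Adjacency-tree utilities for search
# ---------------------------------------------------------------------------

def _three_leaf(leaves: Sequence[int], n: int) -> dict[int, list[int]]:
    a, b, c = leaves
    hub = 2 * n  # internal ids live above 2n−1 and are reused freely
    return {a: [hub], b: [hub], c: [hub], hub: [a, b, c]}


def _copy(adj: dict[int, list[int]]) -> dict[int, list[int]]:
    return {v: list(ws) for v, ws in adj.items()}


def _edges(adj: dict[int, list[int]]) -> list[tuple[int, int]]:
    return [(v, w) for v, ws in adj.items() for w in ws if v < w]


def _insert_leaf(adj: dict[int, list[int]], leaf: int, edge: tuple[int, int],
                 new_id: int) -> None:
    x, y = edge
    adj[x].remove(y)
    adj[y].remove(x)
    adj[x].append(new_id)
    adj[y].append(new_id)
    adj[new_id] = [x, y, leaf]
    adj[leaf] = [new_id]


def _component(adj: dict[int, list[int]], start: int,
               blocked: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if w == blocked and v == start:
                continue
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def _bipartitions(adj: dict[int, list[int]], n: int) -> frozenset[int]:
    """Canonical set of non-trivial splits as leaf bitmasks."""
    full = (1 << n) - 1
    # leaf mask below each node when rooted at the highest-id internal node
    order = _postorder(adj, n)
    below: dict[int, int] = {}
    splits = set()
    for node, children in order:
        mask = 0
        for c in children:
            cm = below.get(c, 1 << c if c < n else 0)
            mask |= cm
        below[node] = mask
        for c in children:
            cm = below.get(c) if c >= n else 1 << c
            side = cm
            if bin(side).count("1") >= 2 and bin(full ^ side).count("1") >= 2:
                splits.add(min(side, full ^ side))
    return frozenset(splits)


def _tbr_neighbors(adj: dict[int, list[int]], n: int) -> Iterator[dict[int, list[int]]]:
    """All trees reachable by one tree-bisection-reconnection move."""
    for (u, v) in _edges(adj):
        base = _copy(adj)
        base[u].remove(v)
        base[v].remove(u)
        free_ids = []

        def _prep_side(w: int, tree: dict[int, list[int]]):
            """Suppress the degree-2 stump; return attachment options."""
            if len(tree[w]) == 0:  # w is a detached leaf
                return ("node", w)
            if len(tree[w]) == 2:
                x, y = tree[w]
                tree[x].remove(w)
                tree[y].remove(w)
                tree[x].append(y)
                tree[y].append(x)
                del tree[w]
                free_ids.append(w)
                return ("edges", None)
            # degree-2 root of a 2-leaf side cannot occur in a binary tree
            return ("edges", None)

        kind_u = _prep_side(u, base)
        kind_v = _prep_side(v, base)
        side_u = _component_of(base, u, kind_u, adj, v)
        side_v = _component_of(base, v, kind_v, adj, u)

        att_u = ([("node", u)] if kind_u[0] == "node" else
                 [("edge", e) for e in _edges_within(base, side_u)])
        att_v = ([("node", v)] if kind_v[0] == "node" else
                 [("edge", e) for e in _edges_within(base, side_v)])

        for au in att_u:
            for av in att_v:
                t = _copy(base)
                ids = list(free_ids)
                pa = _attach_point(t, au, ids)
                pb = _attach_point(t, av, ids)
                t[pa].append(pb)
                t[pb].append(pa)
                yield t


def _component_of(base, w, kind, orig, other):
    if kind[0] == "node":
        return {w}
    # w was suppressed: its side is the component containing one of its
    # original neighbours other than the removed edge partner
    for nb in orig[w]:
        if nb != other and nb in base:
            return _component(base, nb, -1)
    return set()


def _edges_within(adj: dict[int, list[int]], nodes: set[int]) -> list[tuple[int, int]]:
    return [(v, w) for v, ws in adj.items() if v in nodes
            for w in ws if v < w and w in nodes]


def _attach_point(tree: dict[int, list[int]], att, ids: list[int]) -> int:
    kind, payload = att
    if kind == "node":
        return payload
    x, y = payload
    w = ids.pop()
    tree[x].remove(y)
    tree[y].remove(x)
    tree[x].append(w)
    tree[y].append(w)
    tree[w] = [x, y]
    return w


# ---------------------------------------------------------------------------
# Heuristic and exhaustive search
# ---------------------------------------------------------------------------

def _clade_mask(clade: Iterable[str], index: dict[str, int]) -> int:
    mask = 0
    for name in clade:
        key = normalize_label(name)
        if key not in index:
            raise KeyError(f"clade member {key!r} not in matrix")
        mask |= 1 << index[key]
    return mask


def _contains_split(adj, n: int, mask: int) -> bool:
    full = (1 << n) - 1
    canon = min(mask, full ^ mask)
    return canon in _bipartitions(adj, n)


def _penalized(adj, data: _CharData, n: int, forbid: int | None) -> int:
    s = _score_adj(adj, data)
    if forbid is not None and _contains_split(adj, n, forbid):
        s += _PENALTY
    return s


def _search_impl(matrix: CharacterMatrix, config: SearchConfig,
                 forbid: int | None = None):
    """Random-addition + TBR search.  Returns (pool dict, best score)
    where scores are penalised if a forbidden split is configured."""
    data = _CharData(matrix)
    n = matrix.n_taxa
    if n < 4:
        adj = _three_leaf(list(range(n)), n) if n == 3 else None
        if adj is None:
            raise ValueError("need at least 3 taxa to build a tree")
        return {_bipartitions(adj, n): adj}, _penalized(adj, data, n, forbid)

    cap = config.max_trees_held
    global_best = math.inf
    global_pool: dict[frozenset[int], dict[int, list[int]]] = {}

    for r in range(config.n_replicates):
        rng = np.random.default_rng(config.seed + r)
        order = [int(x) for x in rng.permutation(n)]
        adj = _three_leaf(order[:3], n)
        next_internal = 2 * n + 1
        for leaf in order[3:]:
            best_edges, best_s = [], math.inf
            for e in _edges(adj):
                trial = _copy(adj)
                _insert_leaf(trial, leaf, e, next_internal)
                s = _score_adj(trial, data)
                if s < best_s:
                    best_s, best_edges = s, [e]
                elif s == best_s:
                    best_edges.append(e)
            choice = best_edges[int(rng.integers(len(best_edges)))]
            _insert_leaf(adj, leaf, choice, next_internal)
            next_internal += 1

        # TBR hill climb with plateau collection
        best = _penalized(adj, data, n, forbid)
        pool = {_bipartitions(adj, n): adj}
        queue = list(pool)
        while queue:
            key0 = queue.pop()
            current = pool.get(key0)
            if current is None:
                continue
            restart = False
            for nb in _tbr_neighbors(current, n):
                s = _penalized(nb, data, n, forbid)
                if s < best:
                    best = s
                    pool = {_bipartitions(nb, n): nb}
                    queue = list(pool)
                    restart = True
                    break
                if s == best:
                    kk = _bipartitions(nb, n)
                    if kk not in pool and (cap is None or len(pool) < cap):
                        pool[kk] = nb
                        queue.append(kk)
            if restart:
                continue

        if best < global_best:
            global_best = best
            global_pool = dict(pool)
        elif best == global_best:
            for kk, t in pool.items():
                if kk not in global_pool and (cap is None or len(global_pool) < cap):
                    global_pool[kk] = t

    return global_pool, global_best


def _adj_to_dendropy(adj: dict[int, list[int]], taxa: Sequence[str],
                     namespace: dendropy.TaxonNamespace,
                     outgroup: str | None) -> dendropy.Tree:
    n = len(taxa)
    if outgroup is not None:
        og = normalize_label(outgroup)
        root_leaf = taxa.index(og) if og in list(taxa) else 0
    else:
        root_leaf = min(v for v in adj if v < n)

    def sub(node: int, parent: int) -> str:
        if node < n:
            label = taxa[node].replace(" ", "_")
            return f"'{label}'" if "(" in label else label
        parts = [sub(w, node) for w in adj[node] if w != parent]
        return "(" + ",".join(parts) + ")"

    hub = adj[root_leaf][0]
    rest = sub(hub, root_leaf)
    leaf_lab = taxa[root_leaf].replace(" ", "_")
    newick = f"({leaf_lab},{rest});"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             taxon_namespace=namespace,
                             preserve_underscores=False)
    for t in tree.taxon_namespace:
        t.label = normalize_label(t.label)
    return tree


def heuristic_search(matrix: CharacterMatrix,
                     config: SearchConfig) -> list[dendropy.Tree]:
    """All distinct shortest trees found by seeded random-addition + TBR.

    Tree identity is the set of non-trivial bipartitions (unrooted).  The
    same seed always returns the same tree set.
    """
    pool, _best = _search_impl(matrix, config)
    ns = dendropy.TaxonNamespace()
    return [
        _adj_to_dendropy(adj, matrix.taxa, ns, config.outgroup)
        for adj in pool.values()
    ]


def _all_topologies(n: int) -> Iterator[dict[int, list[int]]]:
    """Every unrooted binary topology on leaves 0..n−1 (incremental leaf
    insertion; (2n−5)!! trees)."""
    base = _three_leaf([0, 1, 2], n)

    def grow(adj: dict[int, list[int]], leaf: int, next_id: int):
        if leaf == n:
            yield adj
            return
        for e in _edges(adj):
            trial = _copy(adj)
            _insert_leaf(trial, leaf, e, next_id)
            yield from grow(trial, leaf + 1, next_id + 1)

    yield from grow(base, 3, 2 * n + 1)


def exhaustive_search(matrix: CharacterMatrix) -> tuple[list[dendropy.Tree], int]:
    """Optimal trees by brute-force enumeration of all unrooted binary
    topologies.  Only feasible for roughly n <= 9 taxa."""
    data = _CharData(matrix)
    n = matrix.n_taxa
    best = math.inf
    pool: dict[frozenset[int], dict[int, list[int]]] = {}
    for adj in _all_topologies(n):
        s = _score_adj(adj, data)
        if s < best:
            best = s
            pool = {_bipartitions(adj, n): adj}
        elif s == best:
            pool.setdefault(_bipartitions(adj, n), adj)
    ns = dendropy.TaxonNamespace()
    trees = [_adj_to_dendropy(adj, matrix.taxa, ns, None) for adj in pool.values()]
    return trees, int(best)


# ---------------------------------------------------------------------------
# Consensus, pruning, identity
# ---------------------------------------------------------------------------

def _label_splits(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    labels = frozenset(normalize_label(t.label) for t in
                       (lf.taxon for lf in tree.leaf_node_iter()))
    ref = min(labels)
    splits = set()
    for node in tree.preorder_internal_node_iter():
        side = frozenset(normalize_label(lf.taxon.label)
                         for lf in node.leaf_iter())
        if ref in side:
            side = labels - side
        if 2 <= len(side) <= len(labels) - 2:
            splits.add(side)
    return frozenset(splits)


def tree_key(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    """Unrooted topology identity: the set of non-trivial bipartitions,
    expressed over taxon labels so it is namespace-independent."""
    return _label_splits(tree)


def strict_consensus(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Tree containing exactly the bipartitions shared by every input."""
    if not trees:
        raise ValueError("cannot take the consensus of an empty tree set")
    common = None
    for t in trees:
        s = _label_splits(t)
        common = s if common is None else (common & s)
    labels = sorted(normalize_label(lf.taxon.label)
                    for lf in trees[0].leaf_node_iter())
    return _tree_from_splits(labels, common)


def _tree_from_splits(labels: list[str],
                      splits: frozenset[frozenset[str]]) -> dendropy.Tree:
    full = frozenset(labels)
    ordered = sorted(splits, key=len)
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    # nest splits by containment, largest first so parents exist first
    node_of: dict[frozenset[str], dendropy.Node] = {full: root}
    for side in sorted(ordered, key=len, reverse=True):
        candidates = [s for s in node_of if side < s]
        parent = node_of[min(candidates, key=len)]
        child = parent.new_child()
        node_of[side] = child
    for label in labels:
        containing = [s for s in node_of if label in s]
        parent = node_of[min(containing, key=len)]
        leaf = parent.new_child()
        leaf.taxon = ns.get_taxon(label)
    tree.is_rooted = False
    return tree


def prune_taxon(trees: Sequence[dendropy.Tree],
                taxon: str) -> list[dendropy.Tree]:
    """Remove one taxon from every tree, suppressing degree-2 nodes and
    merging now-identical topologies."""
    target = normalize_label(taxon)
    out: list[dendropy.Tree] = []
    seen = set()
    for t in trees:
        labels = [normalize_label(lf.taxon.label) for lf in t.leaf_node_iter()]
        if target not in labels:
            raise KeyError(f"taxon {target!r} not present in tree")
        clone = t.clone(depth=1)
        keep = [lf.taxon for lf in clone.leaf_node_iter()
                if normalize_label(lf.taxon.label) != target]
        clone.retain_taxa(keep)
        key = _label_splits(clone)
        if key not in seen:
            seen.add(key)
            out.append(clone)
    return out


# ---------------------------------------------------------------------------
# Bremer decay
# ---------------------------------------------------------------------------

def decay_index(matrix: CharacterMatrix, clade: Iterable[str],
                config: SearchConfig) -> float:
    """Bremer support: extra steps needed before a tree lacking ``clade``
    appears, found by reverse-constraint search.  Returns ``math.inf`` for
    an unbreakable (trivial) bipartition."""
    data_index = {normalize_label(t): i for i, t in enumerate(matrix.taxa)}
    mask = _clade_mask(clade, data_index)
    n = matrix.n_taxa
    size = bin(mask).count("1")
    if size < 2 or size > n - 2:
        return math.inf
    _, best = _search_impl(matrix, config)
    _, constrained = _search_impl(matrix, config, forbid=mask)
    if constrained >= _PENALTY:
        return math.inf
    return int(constrained - best)


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------

def trees_to_nexus(trees: Sequence[dendropy.Tree]) -> str:
    """Serialise trees as a NEXUS TREES block."""
    tl = dendropy.TreeList()
    for i, t in enumerate(trees):
        tl.append(dendropy.Tree.get(data=t.as_string(schema="newick"),
                                    schema="newick",
                                    taxon_namespace=tl.taxon_namespace))
    return tl.as_string(schema="nexus")
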
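"""Stratigraphic time-calibration of cladograms.

A cladogram plus first/last appearance ages becomes a :class:`TimeTree`:
every node carries an absolute age in Ma (larger = older) and every
branch a duration in Myr.  Tip ages default to the first appearance
datum, node ages start from the oldest-descendant rule, and zero-length
branches are then smoothed either by sharing duration equally with the
closest ancestral positive branch ("equal") or by enforcing a minimum
branch length ("mbl", pushing ancestral nodes older).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy

from .io_formats import TaxonRecord, normalize_label

__all__ = ["TimeTree", "calibrate", "lineage_intervals"]


@dataclass
class TimeTree:
    """A rooted tree with absolute node ages (Ma) and tip ranges.

    Ages are stored on each dendropy node as ``node.age``.  ``tip_ranges``
    maps taxon label to (FAD, LAD).
    """

    tree: dendropy.Tree
    tip_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def root_age(self) -> float:
        return self.tree.seed_node.age

    def node_ages(self) -> dict[str, float]:
        """Ages of all nodes keyed by tip label or internal node id."""
        out = {}
        for i, node in enumerate(self.tree.preorder_node_iter()):
            key = (normalize_label(node.taxon.label)
                   if node.is_leaf() else f"node_{i}")
            out[key] = node.age
        return out

    def tip_age(self, label: str) -> float:
        label = normalize_label(label)
        for leaf in self.tree.leaf_node_iter():
            if normalize_label(leaf.taxon.label) == label:
                return leaf.age
        raise KeyError(f"tip {label!r} not in tree")

    def branch_durations(self) -> list[float]:
        return [node.parent_node.age - node.age
                for node in self.tree.preorder_node_iter()
                if node.parent_node is not None]

    def tip_labels(self) -> list[str]:
        return [normalize_label(lf.taxon.label)
                for lf in self.tree.leaf_node_iter()]

    def validate(self, min_duration: float = 0.0) -> None:
        """Check the age invariants: parents at least as old as children,
        branch durations >= min_duration, tips no older than their FAD."""
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                d = node.parent_node.age - node.age
                if d < min_duration - 1e-9:
                    raise ValueError(
                        f"branch duration {d:.6g} below {min_duration}"
                    )
            if node.is_leaf():
                label = normalize_label(node.taxon.label)
                fad, lad = self.tip_ranges[label]
                if node.age > fad + 1e-9:
                    raise ValueError(f"tip {label!r} older than its FAD")

    def mrca_age(self, a: str, b: str) -> float:
        a, b = normalize_label(a), normalize_label(b)
        below: dict[dendropy.Node, set[str]] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                below[node] = {normalize_label(node.taxon.label)}
            else:
                below[node] = set().union(*(below[c]
                                            for c in node.child_nodes()))
            if a in below[node] and b in below[node]:
                return node.age
        raise KeyError(f"tips {a!r}/{b!r} not both in tree")


def calibrate(tree: dendropy.Tree, records: Sequence[TaxonRecord],
              method: str = "mbl", min_duration: float = 1.0,
              root_extension: float = 1.0,
              tip_age: str = "fad") -> TimeTree:
    """Assign absolute ages to a cladogram from stratigraphic tip ranges.

    ``tip_age`` selects the age given to each tip ("fad" or "midpoint" of
    its range).  Initial node ages follow the oldest-descendant rule;
    zero branches are then smoothed per ``method`` and the root is pulled
    back to at least (oldest tip + ``root_extension``).
    """
    if method not in ("equal", "mbl"):
        raise ValueError(f"unknown calibration method {method!r}")
    ranges = {r.name: (r.fad, r.lad) for r in records}

    work = tree.clone(depth=1)
    tip_ranges: dict[str, tuple[float, float]] = {}
    for leaf in work.leaf_node_iter():
        label = normalize_label(leaf.taxon.label)
        if label not in ranges:
            raise KeyError(f"tip {label!r} has no stratigraphic range")
        fad, lad = ranges[label]
        leaf.age = fad if tip_age == "fad" else 0.5 * (fad + lad)
        tip_ranges[label] = (fad, lad)

    # oldest-descendant rule, with the mbl push folded into the same pass
    for node in work.postorder_node_iter():
        if node.is_leaf():
            continue
        kids = node.child_nodes()
        if method == "mbl":
            node.age = max(c.age + min_duration for c in kids) \
                if min_duration > 0 else max(c.age for c in kids)
            # never invent a node younger than the oldest-descendant rule
            node.age = max(node.age, max(c.age for c in kids))
        else:
            node.age = max(c.age for c in kids)

    oldest_tip = max(lf.age for lf in work.leaf_node_iter())
    root = work.seed_node
    root.age = max(root.age, oldest_tip + root_extension)

    if method == "equal":
        _equal_smooth(work)

    result = TimeTree(tree=work, tip_ranges=tip_ranges)
    for node in work.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age - node.age
    return result


def _equal_smooth(tree: dendropy.Tree) -> None:
    """Resolve zero-duration branches by spacing each zero chain evenly
    under the closest ancestral positive branch."""
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None or parent.age - node.age > 1e-12:
            continue
        # walk up to the first ancestor whose incoming branch is positive
        chain = [node, parent]
        top = parent
        while top.parent_node is not None and \
                top.parent_node.age - top.age <= 1e-12:
            top = top.parent_node
            chain.append(top)
        if top.parent_node is not None:
            top = top.parent_node
            chain.append(top)
        chain.reverse()  # oldest first
        span = chain[0].age - chain[-1].age
        if span <= 0:
            raise ValueError(
                "cannot smooth zero branches: no positive ancestral span "
                "(increase root_extension)"
            )
        k = len(chain) - 1
        for i, nd in enumerate(chain[1:-1], start=1):
            nd.age = chain[0].age - span * i / k


def lineage_intervals(timetree: TimeTree) -> list[tuple[str, float, float]]:
    """Per-branch temporal spans (start older, end younger), in Ma.

    Internal branches span parent age to child age.  Terminal branches
    extend through the tip's observed range to its LAD, so each tip's
    interval covers both its ghost segment and its observed duration.
    Returns (label, start, end) tuples; internal branches are labelled
    by the tips they subtend.
    """
    out: list[tuple[str, float, float]] = []
    for node in timetree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        start = node.parent_node.age
        if node.is_leaf():
            label = normalize_label(node.taxon.label)
            end = timetree.tip_ranges[label][1]
        else:
            tips = sorted(normalize_label(lf.taxon.label)
                          for lf in node.leaf_iter())
            label = "|".join(tips)
            end = node.age
        out.append((label, start, end))
    return out
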
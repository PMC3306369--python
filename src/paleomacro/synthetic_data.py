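"""Synthetic inputs with the statistical structure the analyses assume.

The generator emulates an earliest-Jurassic marine-reptile study system:
a birth process over a ~30 Myr window produces a tree whose tips carry
stratigraphic ranges; discrete characters evolve along it under a
symmetric k-state Markov (Mk) process, giving the matrix hierarchical
signal plus homoplasy; continuous traits (trunk length, mm) are drawn
from the exact multivariate normal that each evolutionary model defines,
with within-taxon measurement noise.  Defaults mirror the study
conditions: 32 taxa, 207 characters with states 0–2 and ~40% missing
cells, Lower Jurassic time bins, a 55 mm measurement sd, and trend
parameters of 16.1 mm/Myr drift with 20 mm²/Myr step variance.

Each component draws from its own seeded substream so the stages can be
regenerated independently and deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .chronogram import TimeTree
from .io_formats import CharacterMatrix, TaxonRecord, TimeBin
from .trait_models import TraitData, phylo_vcv

__all__ = ["SimConfig", "simulate_tree_with_ranges", "simulate_matrix",
           "simulate_traits", "default_bins"]


def default_bins() -> list[TimeBin]:
    """Three narrow Lower Jurassic sampling intervals."""
    return [
        TimeBin("earliest Hettangian", 201.4, 199.3),
        TimeBin("Sinemurian", 199.3, 190.8),
        TimeBin("lower Toarcian", 183.0, 180.0),
    ]


@dataclass
class SimConfig:
    """Study-system parameters for the generator.

    Rates are per Myr; ages in Ma (larger = older).  ``char_rate`` is the
    total rate of leaving a character state; ``range_mean`` the mean
    observed stratigraphic range of a tip.
    """

    seed: int = 0
    n_taxa: int = 32
    n_characters: int = 207
    n_states: int = 3
    missing_fraction: float = 0.4
    birth_rate: float = 0.4
    termination_rate: float = 0.12
    age_oldest: float = 205.0
    age_youngest: float = 175.0
    range_mean: float = 2.0
    char_rate: float = 0.01
    trait_model: str = "trend"
    root_state: float = 1000.0
    step_variance: float = 20.0
    step_mean: float = 16.1
    trait_variance: float = 150000.0
    measurement_sd: float = 55.0
    bins: list[TimeBin] = field(default_factory=default_bins)

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing_fraction must lie in [0, 1]")
        for attr in ("birth_rate", "termination_rate", "char_rate"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


class _SimNode:
    __slots__ = ("age_start", "age_end", "children", "name")

    def __init__(self, age_start: float):
        self.age_start = age_start
        self.age_end: float | None = None
        self.children: list["_SimNode"] = []
        self.name: str | None = None


def simulate_tree_with_ranges(config: SimConfig
                              ) -> tuple[TimeTree, list[TaxonRecord]]:
    """Birth-process tree over the configured age window.

    Lineages split at rate ``birth_rate`` and terminate (are last
    sampled) at rate ``termination_rate``; a tip's FAD sits at its branch
    end, its LAD an exponential range-length younger, truncated at the
    window.  Splitting stops once ``n_taxa`` lineages exist, so the tip
    count is exact; the simulation restarts (fresh substream) if the
    clade dies too soon.
    """
    if config.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    for attempt in range(1000):
        rng = config.rng(1000 + attempt)
        root = _SimNode(config.age_oldest)
        active = [root]
        done: list[_SimNode] = []
        while active and len(active) + len(done) < config.n_taxa:
            # advance the oldest active lineage
            active.sort(key=lambda nd: -nd.age_start)
            nd = active.pop(0)
            dt_split = rng.exponential(1.0 / config.birth_rate)
            dt_term = rng.exponential(1.0 / config.termination_rate)
            t_split = nd.age_start - dt_split
            t_term = nd.age_start - dt_term
            if t_split > t_term and t_split > config.age_youngest:
                nd.age_end = t_split
                for _ in range(2):
                    child = _SimNode(t_split)
                    nd.children.append(child)
                    active.append(child)
            else:
                nd.age_end = max(t_term, config.age_youngest)
                done.append(nd)
        if len(active) + len(done) != config.n_taxa:
            continue
        for nd in active:  # splitting frozen; run each to its end
            dt_term = rng.exponential(1.0 / config.termination_rate)
            nd.age_end = max(nd.age_start - dt_term, config.age_youngest)
            done.append(nd)
        break
    else:
        raise RuntimeError("birth process failed to reach the target "
                           "taxon count; raise birth_rate")

    records: list[TaxonRecord] = []
    for i, nd in enumerate(sorted(done, key=lambda x: -x.age_end)):
        nd.name = f"t{i + 1:02d}"
        fad = nd.age_end
        lad = max(fad - rng.exponential(config.range_mean),
                  config.age_youngest)
        bin_label = next((b.label for b in config.bins
                          if b.younger_bound < fad <= b.older_bound), None)
        records.append(TaxonRecord(name=nd.name, fad=fad, lad=lad,
                                   bin_label=bin_label))

    tree = dendropy.Tree()

    def build(sim: _SimNode, node: dendropy.Node) -> None:
        node.age = sim.age_end
        if sim.children:
            for ch in sim.children:
                build(ch, node.new_child())
        else:
            node.taxon = tree.taxon_namespace.new_taxon(sim.name)

    build(root, tree.seed_node)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age - node.age
    timetree = TimeTree(tree=tree,
                        tip_ranges={r.name: (r.fad, r.lad) for r in records})
    return timetree, records


def simulate_matrix(timetree: TimeTree, config: SimConfig,
                    block_mask: Mapping[str, tuple[int, int]] | None = None
                    ) -> CharacterMatrix:
    """Evolve discrete characters along the tree under a symmetric
    k-state Markov process, then mask cells missing.

    ``block_mask`` blanks a contiguous character range per taxon,
    emulating whole anatomical regions (e.g. the postcranium) that a
    fossil simply does not preserve.
    """
    rng = config.rng(2)
    k = config.n_states
    m = config.n_characters
    labels = []
    states: dict[str, np.ndarray] = {}

    def p_same(t: float) -> float:
        if k == 1:
            return 1.0
        return 1.0 / k + (k - 1.0) / k * math.exp(-k * config.char_rate * t
                                                  / (k - 1.0))

    node_states: dict[object, np.ndarray] = {}
    for node in timetree.tree.preorder_node_iter():
        if node.parent_node is None:
            node_states[node] = rng.integers(0, k, size=m)
            continue
        parent = node_states[node.parent_node]
        t = node.parent_node.age - node.age
        stay = rng.random(m) < p_same(t)
        new = parent.copy()
        n_flip = int((~stay).sum())
        if n_flip and k > 1:
            shifts = rng.integers(1, k, size=n_flip)
            new[~stay] = (parent[~stay] + shifts) % k
        node_states[node] = new
        if node.is_leaf():
            label = node.taxon.label
            labels.append(label)
            states[label] = new

    cells = []
    for label in labels:
        row_states = states[label]
        missing = rng.random(m) < config.missing_fraction
        if block_mask and label in block_mask:
            lo, hi = block_mask[label]
            missing[lo:hi] = True
        row = [frozenset() if missing[j] else frozenset({int(row_states[j])})
               for j in range(m)]
        cells.append(row)
    return CharacterMatrix(labels, cells)


def simulate_traits(timetree: TimeTree, config: SimConfig) -> TraitData:
    """Draw tip traits from the exact multivariate normal each model
    defines (same covariance construction the fitters use), plus
    measurement noise."""
    rng = config.rng(3)
    labels, C = phylo_vcv(timetree)
    n = len(labels)
    depths = np.diag(C)
    sd = config.measurement_sd

    if config.trait_model == "stasis":
        mean = np.full(n, config.root_state)
        cov = config.trait_variance * np.eye(n)
    elif config.trait_model == "bm":
        mean = np.full(n, config.root_state)
        cov = config.step_variance * C
    elif config.trait_model == "trend":
        mean = config.root_state + config.step_mean * depths
        cov = config.step_variance * C
    else:
        raise ValueError(f"unknown trait model {config.trait_model!r}")

    cov = cov + sd ** 2 * np.eye(n)
    if np.allclose(cov, 0.0):
        values = mean.copy()
    else:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
        values = mean + L @ rng.standard_normal(n)
    return TraitData(dict(zip(labels, values)), measurement_sd=sd)
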
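"""Character-based disparity from a cladistic matrix.

Dissimilarity between two taxa is the proportion of comparable cells
(scored in both) whose state-sets are disjoint — a shared state in a
polymorphic cell counts as agreement.  The dissimilarity matrix is
embedded by principal coordinates analysis with the Cailliez additive
correction, which finds the smallest constant that, added to every
off-diagonal dissimilarity, makes the configuration Euclidean (no
negative eigenvalues).  Per-interval disparity is summarised by mean
pairwise dissimilarity and by the sum of variances of scores across all
retained ordination axes, with percentile confidence intervals obtained
by rarefaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .io_formats import CharacterMatrix, TimeBin, normalize_label

__all__ = [
    "DissimilarityMatrix",
    "Ordination",
    "BinDisparity",
    "pairwise_dissimilarity",
    "drop_undefined_taxa",
    "pcoa",
    "axis_percentages",
    "mean_pairwise_dissimilarity",
    "sum_of_variances",
    "rarefaction_ci",
    "disparity_by_bin",
]

log = logging.getLogger(__name__)

_EIG_TOL = 1e-10


@dataclass
class DissimilarityMatrix:
    """Symmetric taxon × taxon proportion-of-difference matrix.

    ``d[i, j]`` is NaN where no character is scored in both taxa
    (``n_comparable[i, j] == 0``).
    """

    taxa: list[str]
    d: np.ndarray
    n_comparable: np.ndarray

    def index(self, taxon: str) -> int:
        if taxon in self.taxa:
            return self.taxa.index(taxon)
        want = normalize_label(taxon)
        for i, t in enumerate(self.taxa):
            if normalize_label(t) == want:
                return i
        raise KeyError(f"taxon {taxon!r} not in matrix")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.taxa)
        for i in range(n):
            for j in range(i + 1, n):
                if self.n_comparable[i, j] == 0:
                    out.append((self.taxa[i], self.taxa[j]))
        return out

    def subset(self, taxa: Sequence[str]) -> "DissimilarityMatrix":
        idx = [self.index(t) for t in taxa]
        return DissimilarityMatrix(
            [self.taxa[i] for i in idx],
            self.d[np.ix_(idx, idx)].copy(),
            self.n_comparable[np.ix_(idx, idx)].copy(),
        )


@dataclass
class Ordination:
    """Principal-coordinate scores, eigenvalues, and the Cailliez constant."""

    taxa: list[str]
    scores: np.ndarray          # (n_taxa, n_axes)
    eigenvalues: np.ndarray     # descending, all > tolerance
    cailliez_constant: float

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]

    @property
    def percent_per_axis(self) -> np.ndarray:
        return 100.0 * self.eigenvalues / self.eigenvalues.sum()

    def rows(self, taxa: Sequence[str]) -> np.ndarray:
        idx = []
        for t in taxa:
            if t in self.taxa:
                idx.append(self.taxa.index(t))
            else:
                want = normalize_label(t)
                idx.append(next(i for i, lab in enumerate(self.taxa)
                                if normalize_label(lab) == want))
        return self.scores[idx]


def pairwise_dissimilarity(matrix: CharacterMatrix,
                           taxa: Sequence[str] | None = None
                           ) -> DissimilarityMatrix:
    """Proportion of comparable characters differing, for every pair."""
    labels = (list(matrix.taxa) if taxa is None
              else [normalize_label(t) for t in taxa])
    rows = [matrix.row(t) for t in labels]
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            n_comp = 0
            n_diff = 0
            for a, b in zip(rows[i], rows[j]):
                if a and b:
                    n_comp += 1
                    if not (a & b):
                        n_diff += 1
            comp[i, j] = comp[j, i] = n_comp
            d[i, j] = d[j, i] = (n_diff / n_comp) if n_comp else np.nan
    return DissimilarityMatrix(labels, d, comp)


def drop_undefined_taxa(dissim: DissimilarityMatrix) -> DissimilarityMatrix:
    """Remove taxa until no pair is undefined, greedily deleting the
    taxon participating in the most undefined pairs.  Mirrors the
    treatment of taxa with wholly non-overlapping scored anatomy (e.g.
    a skull-only taxon versus postcranium-only taxa)."""
    taxa = list(dissim.taxa)
    d = dissim.d.copy()
    comp = dissim.n_comparable.copy()
    removed = []
    while True:
        undef = (comp == 0) & ~np.eye(len(taxa), dtype=bool)
        per_taxon = undef.sum(axis=0)
        if per_taxon.max(initial=0) == 0:
            break
        worst = int(per_taxon.argmax())
        removed.append(taxa[worst])
        keep = [i for i in range(len(taxa)) if i != worst]
        taxa = [taxa[i] for i in keep]
        d = d[np.ix_(keep, keep)]
        comp = comp[np.ix_(keep, keep)]
    if removed:
        log.info("dropped taxa with undefined dissimilarities: %s",
                 ", ".join(removed))
    out = DissimilarityMatrix(taxa, d, comp)
    out.removed = removed
    return out


def _gower_center(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest additive constant making ``d`` Euclidean (largest real
    eigenvalue of the standard 2n × 2n companion problem)."""
    n = d.shape[0]
    delta1 = _gower_center(-0.5 * d ** 2)
    delta2 = _gower_center(-0.5 * d)
    top = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    bottom = np.hstack([-np.eye(n), -4.0 * delta2])
    eigvals = scipy.linalg.eigvals(np.vstack([top, bottom]))
    c = max(ev.real for ev in eigvals)
    return max(c, 0.0)


def pcoa(dissim: DissimilarityMatrix, correction: str = "cailliez",
         tol: float = _EIG_TOL) -> Ordination:
    """Principal coordinates analysis of a dissimilarity matrix.

    Gower double-centering of −½d², eigendecomposition, scores scaled by
    √eigenvalue.  With ``correction="cailliez"`` the Cailliez constant is
    added to all off-diagonal dissimilarities first, so every retained
    eigenvalue is non-negative.  Axes with eigenvalue ≤ ``tol`` are
    dropped.
    """
    d = dissim.d
    if np.isnan(d).any():
        raise ValueError("dissimilarity matrix has undefined pairs; "
                         "apply drop_undefined_taxa first")
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if correction not in ("cailliez", "none"):
        raise ValueError(f"unknown correction {correction!r}")

    c = 0.0
    if correction == "cailliez":
        b0 = _gower_center(-0.5 * d ** 2)
        if np.linalg.eigvalsh(b0).min() < -tol:
            c = _cailliez_constant(d)
    dc = d + c * (1 - np.eye(d.shape[0]))
    b = _gower_center(-0.5 * dc ** 2)
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > tol
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    scores = eigvec * np.sqrt(eigval)
    return Ordination(list(dissim.taxa), scores, eigval, c)


def axis_percentages(ordination: Ordination, k: int) -> float:
    """Cumulative percent of total (corrected) dissimilarity captured by
    the first ``k`` axes."""
    if k == 0:
        return 0.0
    if k > ordination.n_axes:
        raise ValueError(f"only {ordination.n_axes} axes retained")
    ev = ordination.eigenvalues
    return float(100.0 * ev[:k].sum() / ev.sum())


def mean_pairwise_dissimilarity(dissim: DissimilarityMatrix,
                                taxa: Sequence[str] | None = None
                                ) -> float | None:
    """Arithmetic mean of d over unordered pairs within a taxon subset.

    Returns None for a singleton subset (no pairs)."""
    labels = list(taxa) if taxa is not None else list(dissim.taxa)
    if len(labels) < 2:
        return None
    sub = dissim.subset(labels)
    iu = np.triu_indices(len(labels), k=1)
    vals = sub.d[iu]
    if np.isnan(vals).any():
        raise ValueError("subset contains undefined pairs")
    return float(vals.mean())


def sum_of_variances(ordination: Ordination,
                     taxa: Sequence[str] | None = None) -> float | None:
    """Sum over axes of the sample variance (n−1 denominator) of scores."""
    labels = list(taxa) if taxa is not None else list(ordination.taxa)
    if len(labels) < 2:
        return None
    sub = ordination.rows(labels)
    return float(sub.var(axis=0, ddof=1).sum())


def rarefaction_ci(metric: str, data, pool: Sequence[str], sample_size: int,
                   n_resamples: int = 1000, seed: int = 0
                   ) -> tuple[float, float, float]:
    """95% percentile interval of a disparity metric under rarefaction.

    ``data`` is a DissimilarityMatrix for ``metric="mpd"`` or an
    Ordination for ``metric="sov"``.  Taxa are resampled without
    replacement at ``sample_size``; returns (lower, upper, point) where
    the point estimate uses the whole pool.
    """
    if sample_size < 2:
        raise ValueError("sample_size must be >= 2")
    pool = list(pool)
    if sample_size > len(pool):
        raise ValueError("sample_size exceeds pool size")
    if metric == "mpd":
        fn = lambda taxa: mean_pairwise_dissimilarity(data, taxa)
    elif metric == "sov":
        fn = lambda taxa: sum_of_variances(data, taxa)
    else:
        raise ValueError(f"unknown metric {metric!r}")

    rng = np.random.default_rng(seed)
    values = np.empty(n_resamples)
    pool_arr = np.array(pool, dtype=object)
    for i in range(n_resamples):
        pick = rng.choice(pool_arr, size=sample_size, replace=False)
        values[i] = fn(list(pick))
    lower, upper = np.percentile(values, [2.5, 97.5])
    return float(lower), float(upper), float(fn(pool))


@dataclass(frozen=True)
class BinDisparity:
    """Disparity summary for one time bin."""

    bin_label: str
    n_taxa: int
    mpd: float | None
    mpd_ci: tuple[float, float] | None
    sov: float | None
    sov_ci: tuple[float, float] | None


def disparity_by_bin(dissim: DissimilarityMatrix, ordination: Ordination,
                     assignments: dict[str, str], bins: Sequence[TimeBin],
                     rarefy_to: int | None = None, n_resamples: int = 1000,
                     seed: int = 0) -> list[BinDisparity]:
    """Per-bin disparity with rarefaction CIs.

    ``assignments`` maps taxon label to bin label; taxa absent from the
    dissimilarity matrix (e.g. dropped for undefined pairs) are ignored.
    ``rarefy_to`` defaults to the smallest bin's taxon count, equalising
    sampling intensity across bins.
    """
    members: dict[str, list[str]] = {b.label: [] for b in bins}
    present = set(dissim.taxa)
    for taxon, bin_label in assignments.items():
        t = normalize_label(taxon)
        if bin_label in members and t in present:
            members[bin_label].append(t)

    sizes = [len(v) for v in members.values() if len(v) >= 2]
    if rarefy_to is None:
        rarefy_to = min(sizes) if sizes else 2

    out = []
    for i, b in enumerate(bins):
        taxa = members[b.label]
        if len(taxa) < 2:
            out.append(BinDisparity(b.label, len(taxa), None, None, None, None))
            continue
        size = min(rarefy_to, len(taxa))
        mpd_lo, mpd_hi, mpd = rarefaction_ci(
            "mpd", dissim, taxa, size, n_resamples, seed + 2 * i)
        sov_lo, sov_hi, sov = rarefaction_ci(
            "sov", ordination, taxa, size, n_resamples, seed + 2 * i + 1)
        out.append(BinDisparity(b.label, len(taxa), mpd, (mpd_lo, mpd_hi),
                                sov, (sov_lo, sov_hi)))
    return out
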
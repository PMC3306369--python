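"""Maximum-likelihood models of continuous-trait evolution on a time tree.

Three models are compared by AICc, mirroring the standard fossil
body-size toolkit:

* **stasis** — white noise: tips i.i.d. normal around a single optimum,
  ignoring phylogeny (2 parameters: trait mean, trait variance);
* **bm** — Brownian motion: multivariate normal with covariance
  proportional to shared root-to-ancestor path lengths (2 parameters:
  root state, step variance per Myr);
* **trend** — Brownian motion with a directional drift, the expected tip
  value increasing linearly with root-to-tip duration (3 parameters);
  identifiable only on non-ultrametric trees, which fossil tip ages
  provide.

Within-taxon measurement error enters as an additive variance on the
covariance diagonal (the Hunt–Carrano construction).  Root state and
trend are profiled out by generalised least squares; the step variance
is optimised numerically on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize

from .chronogram import TimeTree
from .io_formats import normalize_label

__all__ = [
    "TraitData",
    "ModelFit",
    "phylo_vcv",
    "fit_stasis",
    "fit_bm",
    "fit_trend",
    "aicc",
    "akaike_weights",
    "fit_all",
]

_LOG_VAR_BOUNDS = (-25.0, 25.0)  # search window for log step/trait variance


@dataclass
class TraitData:
    """Tip trait values (mm, or log-mm) with measurement error.

    ``measurement_sd`` is one global standard deviation applied to every
    tip, or a per-tip mapping (used e.g. after a log transform, where a
    single absolute sd cannot be right for all body sizes).
    """

    values: dict[str, float]
    measurement_sd: float | Mapping[str, float] = 0.0

    def __post_init__(self) -> None:
        self.values = {normalize_label(k): float(v)
                       for k, v in self.values.items()}
        for v in self.values.values():
            if not math.isfinite(v):
                raise ValueError("trait values must be finite")
        if isinstance(self.measurement_sd, Mapping):
            self.measurement_sd = {normalize_label(k): float(v)
                                   for k, v in self.measurement_sd.items()}
            bad = [v for v in self.measurement_sd.values() if v < 0]
        else:
            self.measurement_sd = float(self.measurement_sd)
            bad = [self.measurement_sd] if self.measurement_sd < 0 else []
        if bad:
            raise ValueError("measurement_sd must be non-negative")

    def taxa(self) -> list[str]:
        return list(self.values)

    def sd_vector(self, taxa: Sequence[str]) -> np.ndarray:
        if isinstance(self.measurement_sd, Mapping):
            return np.array([self.measurement_sd.get(t, 0.0) for t in taxa])
        return np.full(len(taxa), self.measurement_sd)

    def ln_transformed(self) -> "TraitData":
        """Delta-method log transform: sd_log ≈ sd/value per tip."""
        sds = self.sd_vector(self.taxa())
        new_sd = {t: sd / self.values[t] for t, sd in zip(self.taxa(), sds)}
        return TraitData({t: math.log(v) for t, v in self.values.items()},
                         new_sd)


@dataclass
class ModelFit:
    """A fitted evolutionary model with its information-criterion scores."""

    model: str
    k: int
    estimates: dict[str, float]
    lnl: float
    aicc: float | None = None
    akaike_weight: float | None = None
    degenerate: bool = False


def phylo_vcv(timetree: TimeTree, tips: Sequence[str] | None = None
              ) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance structure: shared path length (Myr)
    from the root to each pair's most recent common ancestor."""
    labels = [normalize_label(t) for t in
              (tips or timetree.tip_labels())]
    idx = {t: i for i, t in enumerate(labels)}
    tree_tips = set(timetree.tip_labels())
    for t in labels:
        if t not in tree_tips:
            raise KeyError(f"tip {t!r} not in tree")
    n = len(labels)
    root_age = timetree.root_age
    C = np.zeros((n, n))
    below: dict[object, list[str]] = {}
    for node in timetree.tree.postorder_node_iter():
        if node.is_leaf():
            label = normalize_label(node.taxon.label)
            below[node] = [label] if label in idx else []
            if label in idx:
                C[idx[label], idx[label]] = root_age - node.age
        else:
            kids = [below[c] for c in node.child_nodes()]
            depth = root_age - node.age
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for ta in kids[a]:
                        for tb in kids[b]:
                            C[idx[ta], idx[tb]] = depth
                            C[idx[tb], idx[ta]] = depth
            below[node] = [t for sub in kids for t in sub]
    return labels, C


def _mvn_lnl(resid: np.ndarray, V: np.ndarray) -> float:
    n = len(resid)
    try:
        cf = scipy.linalg.cho_factor(V, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(f"singular covariance matrix: {exc}") from exc
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    quad = float(resid @ scipy.linalg.cho_solve(cf, resid))
    return -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)


def _gls(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> np.ndarray:
    cf = scipy.linalg.cho_factor(V, lower=True)
    Vi_X = scipy.linalg.cho_solve(cf, X)
    Vi_y = scipy.linalg.cho_solve(cf, y)
    return np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)


def fit_stasis(data: TraitData) -> ModelFit:
    """White-noise model: tips i.i.d. normal(mean, variance + sd²)."""
    taxa = data.taxa()
    if len(taxa) < 3:
        raise ValueError("stasis fit needs at least 3 tips")
    y = np.array([data.values[t] for t in taxa])
    sds = data.sd_vector(taxa)
    mean = float(y.mean())
    resid = y - mean

    if np.allclose(sds, sds[0]):
        total = float((resid ** 2).mean())
        var = max(total - sds[0] ** 2, 0.0)
        obs_var = var + sds[0] ** 2
        if obs_var == 0.0:
            return ModelFit("stasis", 2, {"trait_mean": mean,
                                          "trait_variance": 0.0},
                            math.inf, degenerate=True)
        lnl = _mvn_lnl(resid, obs_var * np.eye(len(y)))
    else:
        def neg(logv: float) -> float:
            V = np.diag(math.exp(logv) + sds ** 2)
            m = _gls(y, np.ones((len(y), 1)), V)[0]
            return -_mvn_lnl(y - m, V)

        res = scipy.optimize.minimize_scalar(
            neg, bounds=_LOG_VAR_BOUNDS, method="bounded",
            options={"xatol": 1e-10})
        var = math.exp(res.x)
        V = np.diag(var + sds ** 2)
        mean = float(_gls(y, np.ones((len(y), 1)), V)[0])
        lnl = -res.fun
    return ModelFit("stasis", 2,
                    {"trait_mean": mean, "trait_variance": var}, lnl)


def _check_nonultrametric(depths: np.ndarray) -> None:
    if np.ptp(depths) < 1e-8 * max(depths.max(), 1.0):
        raise ValueError(
            "trend model is unidentifiable on an ultrametric tree "
            "(all root-to-tip durations equal)"
        )


def _fit_gls_model(timetree: TimeTree, data: TraitData,
                   with_trend: bool) -> ModelFit:
    taxa = [t for t in data.taxa()]
    labels, C = phylo_vcv(timetree, taxa)
    y = np.array([data.values[t] for t in labels])
    sds = data.sd_vector(labels)
    depths = np.diag(C).copy()
    if with_trend:
        _check_nonultrametric(depths)
        X = np.column_stack([np.ones(len(y)), depths])
    else:
        X = np.ones((len(y), 1))

    def neg(log_sigma2: float) -> float:
        V = math.exp(log_sigma2) * C + np.diag(sds ** 2)
        try:
            beta = _gls(y, X, V)
            return -_mvn_lnl(y - X @ beta, V)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12

    res = scipy.optimize.minimize_scalar(
        neg, bounds=_LOG_VAR_BOUNDS, method="bounded",
        options={"xatol": 1e-10})
    sigma2 = math.exp(res.x)
    V = sigma2 * C + np.diag(sds ** 2)
    try:
        beta = _gls(y, X, V)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular covariance: tips with identical ages and positions "
            "(duplicate-age cherry) make the model inestimable"
        ) from exc
    lnl = _mvn_lnl(y - X @ beta, V)

    if with_trend:
        est = {"root_state": float(beta[0]), "step_variance": sigma2,
               "step_mean": float(beta[1])}
        return ModelFit("trend", 3, est, lnl)
    est = {"root_state": float(beta[0]), "step_variance": sigma2}
    return ModelFit("bm", 2, est, lnl)


def fit_bm(timetree: TimeTree, data: TraitData) -> ModelFit:
    """Brownian motion: mean = root state, covariance σ²C + sd²I."""
    return _fit_gls_model(timetree, data, with_trend=False)


def fit_trend(timetree: TimeTree, data: TraitData) -> ModelFit:
    """Brownian motion with drift: E[tip] = root + μ · root-to-tip Myr."""
    return _fit_gls_model(timetree, data, with_trend=True)


def aicc(fit: ModelFit, n: int) -> float:
    """Small-sample Akaike information criterion."""
    k = fit.k
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} with k={k}")
    return -2.0 * fit.lnl + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(fits: Sequence[ModelFit]) -> list[float]:
    """Normalised relative likelihoods from AICc differences."""
    a = np.array([f.aicc for f in fits], dtype=float)
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    w /= w.sum()
    for f, wi in zip(fits, w):
        f.akaike_weight = float(wi)
    return [float(x) for x in w]


def fit_all(timetree: TimeTree, data: TraitData,
            transform: str = "none") -> list[ModelFit]:
    """Fit stasis, BM and BM+trend and attach AICc and Akaike weights.

    ``transform="ln"`` fits on the natural-log scale, transporting the
    measurement sd by the delta method.  Taxa in ``data`` missing from
    the tree are dropped before fitting.
    """
    if transform not in ("none", "ln"):
        raise ValueError(f"unknown transform {transform!r}")
    tree_tips = set(timetree.tip_labels())
    usable = {t: v for t, v in data.values.items() if t in tree_tips}
    if len(usable) < 4:
        raise ValueError("need at least 4 usable tips")
    sd = data.measurement_sd
    if isinstance(sd, Mapping):
        sd = {t: sd.get(t, 0.0) for t in usable}
    trimmed = TraitData(usable, sd)
    if transform == "ln":
        trimmed = trimmed.ln_transformed()

    fits = [fit_stasis(trimmed), fit_bm(timetree, trimmed),
            fit_trend(timetree, trimmed)]
    n = len(usable)
    for f in fits:
        f.aicc = aicc(f, n)
    akaike_weights(fits)
    return fits
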
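"""Feature selection and feature extraction for the fusion schemes.

Selection methods:

* **IGA** — information-gain attribute ranking: each (discretized) feature
  scores H(C) - H(C|A) bits; attributes are ranked in descending order and
  positive-gain attributes are kept.
* **CFS** — correlation-based feature subset selection: best-first forward
  search on the merit  k r_cf / sqrt(k + k(k-1) r_ff), where r_cf / r_ff are
  mean feature-class / feature-feature symmetric uncertainties.
* **intersection** of the two subsets (falling back to the first when empty).
* **binary PSO** — a particle swarm over selection masks minimizing the
  wrapper fitness  f = 0.8 * error + 0.2 * (selected / total), with the error
  averaged over a k-NN and a Gaussian naive-Bayes classifier on a seeded
  inner holdout.

Extraction is kernel PCA with linear, 3rd-degree polynomial or Gaussian
kernels: features are standardized, the Gram matrix double-centered, and
projections obtained from its leading eigenvectors scaled by inverse root
eigenvalues.

Continuous features are discretized by equal-frequency binning (10 bins) for
the entropy-based selectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import cdist, pdist
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "PSOConfig",
    "KpcaConfig",
    "discretize_equal_frequency",
    "info_gain_scores",
    "cfs_select",
    "combine_selections",
    "pso_fitness",
    "pso_select",
    "KernelPCA",
    "kpca_fit_transform",
]


@dataclass
class PSOConfig:
    """Binary-PSO settings; the fitness weights (0.8 error / 0.2 size) are the
    study's, the swarm mechanics defaults are this package's."""

    swarm_size: int = 30
    iterations: int = 50
    inertia: float = 0.72
    c1: float = 1.49
    c2: float = 1.49
    error_weight: float = 0.8
    size_weight: float = 0.2
    knn_k: int = 5
    inner_train_fraction: float = 0.7
    inner_subsample: int | None = None
    seed: int = 0

    def __post_init__(self):
        if abs(self.error_weight + self.size_weight - 1.0) > 1e-12:
            raise ValueError("error_weight + size_weight must equal 1")


@dataclass
class KpcaConfig:
    kernel: str = "gaussian"  # linear | polynomial_degree_3 | gaussian
    n_components: int = 300
    gaussian_sigma: float | None = None  # None -> median pairwise distance

    def __post_init__(self):
        if self.kernel not in ("linear", "polynomial_degree_3", "gaussian"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


# --------------------------------------------------------------- entropies

def discretize_equal_frequency(x: np.ndarray, bins: int = 10) -> np.ndarray:
    """Equal-frequency discretization into at most ``bins`` codes."""
    x = np.asarray(x, dtype=float)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.digitize(x, edges)


def _entropy_codes(codes: np.ndarray, n_codes: int | None = None) -> float:
    if n_codes is None:
        codes = np.unique(codes, return_inverse=True)[1]
        n_codes = int(codes.max()) + 1
    counts = np.bincount(codes, minlength=n_codes)
    p = counts[counts > 0] / codes.size
    return float(-np.sum(p * np.log2(p)))


def _mutual_information(a: np.ndarray, b: np.ndarray,
                        na: int | None = None, nb: int | None = None) -> float:
    """I(A;B) in bits from two integer code arrays.

    When ``na``/``nb`` are given, the codes are assumed to already lie in
    [0, na) / [0, nb), which skips the re-indexing pass.
    """
    if na is None:
        a = np.unique(a, return_inverse=True)[1]
        na = int(a.max()) + 1
    if nb is None:
        b = np.unique(b, return_inverse=True)[1]
        nb = int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb) / a.size
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    outer = np.outer(pa, pb)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def _as_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.columns)
    arr = np.asarray(features, dtype=float)
    return arr, [f"f{i}" for i in range(arr.shape[1])]


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are constant; need both classes")
    if len(np.unique(y)) > 2:
        raise ValueError("only binary labels are supported")
    return y


def info_gain_scores(features, labels, bins: int = 10) -> pd.Series:
    """Information-gain score per feature, ranked in descending order."""
    x, names = _as_matrix(features)
    y = _check_binary(labels)
    _, yc = np.unique(y, return_inverse=True)
    scores = {}
    for j, name in enumerate(names):
        codes = discretize_equal_frequency(x[:, j], bins)
        scores[name] = _mutual_information(codes, yc)
    s = pd.Series(scores)
    return s.sort_values(ascending=False, kind="stable")


def iga_select(features, labels, bins: int = 10) -> list[str]:
    """Features with strictly positive information gain, in ranked order."""
    scores = info_gain_scores(features, labels, bins)
    return list(scores.index[scores > 0])


# --------------------------------------------------------------------- CFS

def _symmetric_uncertainty(a: np.ndarray, b: np.ndarray,
                           na: int | None = None, nb: int | None = None,
                           ha: float | None = None, hb: float | None = None) -> float:
    ha = _entropy_codes(a, na) if ha is None else ha
    hb = _entropy_codes(b, nb) if hb is None else hb
    if ha + hb <= 0:
        return 0.0
    return 2.0 * _mutual_information(a, b, na, nb) / (ha + hb)


def _cfs_merit(subset, r_cf, su_ff) -> float:
    """Merit k * rbar_cf / sqrt(k + k(k-1) rbar_ff) = sum r_cf / sqrt(k + 2 sum r_ff)."""
    k = len(subset)
    sum_cf = float(np.sum([r_cf[j] for j in subset]))
    sum_ff = float(np.sum([su_ff(i, j) for idx, i in enumerate(subset)
                           for j in subset[idx + 1 :]]))
    denom = np.sqrt(k + 2.0 * sum_ff)
    return sum_cf / denom if denom > 0 else 0.0


def cfs_select(features, labels, bins: int = 10, stale_limit: int = 5) -> list[str]:
    """Correlation-based feature subset selection with best-first forward search.

    The search expands the best unexpanded subset by one feature at a time
    and stops after ``stale_limit`` consecutive expansions without improving
    the best merit.  Symmetric-uncertainty correlations are computed on
    equal-frequency discretized data and cached lazily.
    """
    x, names = _as_matrix(features)
    if x.shape[1] < 1:
        raise ValueError("need at least one feature")
    y = _check_binary(labels)
    _, yc = np.unique(y, return_inverse=True)
    codes = [discretize_equal_frequency(x[:, j], bins) for j in range(x.shape[1])]
    n_codes = [int(c.max()) + 1 for c in codes]
    ents = [_entropy_codes(c, n) for c, n in zip(codes, n_codes)]
    ny = int(yc.max()) + 1
    hy = _entropy_codes(yc, ny)
    r_cf = np.array([
        _symmetric_uncertainty(c, yc, n, ny, h, hy)
        for c, n, h in zip(codes, n_codes, ents)
    ])
    ff_cache: dict[tuple[int, int], float] = {}

    def su_ff(i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        if key not in ff_cache:
            ki, kj = key
            ff_cache[key] = _symmetric_uncertainty(
                codes[ki], codes[kj], n_codes[ki], n_codes[kj], ents[ki], ents[kj])
        return ff_cache[key]

    n_feat = x.shape[1]
    if n_feat == 1:
        return [names[0]] if r_cf[0] > 0 else []
    # best-first forward search; nodes carry (merit, subset, sum r_cf, sum pairwise r_ff)
    # so expanding by feature j only needs the k new pair correlations SU(j, member)
    start = int(np.argmax(r_cf))
    best_subset = (start,)
    best_merit = float(r_cf[start])
    frontier = [(best_merit, best_subset, float(r_cf[start]), 0.0)]
    visited = {best_subset}
    stale = 0
    while frontier and stale < stale_limit:
        frontier.sort(key=lambda t: t[0])
        merit, subset, sum_cf, sum_ff = frontier.pop()
        improved = False
        for j in range(n_feat):
            if j in subset:
                continue
            cand = tuple(sorted(subset + (j,)))
            if cand in visited:
                continue
            visited.add(cand)
            cf = sum_cf + float(r_cf[j])
            ff = sum_ff + sum(su_ff(i, j) for i in subset)
            k = len(cand)
            denom = np.sqrt(k + 2.0 * ff)
            m = cf / denom if denom > 0 else 0.0
            frontier.append((m, cand, cf, ff))
            if m > best_merit + 1e-12:
                best_merit, best_subset = m, cand
                improved = True
        stale = 0 if improved else stale + 1
    return [names[j] for j in best_subset]


def combine_selections(subset_a: list[str], subset_b: list[str]) -> list[str]:
    """Intersection of two feature subsets (order of ``subset_a`` preserved).

    An empty intersection falls back to ``subset_a`` with a warning, so a
    downstream classifier always has features to work with.
    """
    inter = [f for f in subset_a if f in set(subset_b)]
    if not inter:
        warnings.warn("feature-subset intersection is empty; falling back to the first subset")
        return list(subset_a)
    return inter


# --------------------------------------------------------------------- PSO

def _inner_split(n: int, y: np.ndarray, config: PSOConfig):
    """Seeded stratified holdout used for every fitness evaluation."""
    rng = np.random.default_rng(config.seed)
    idx = np.arange(n)
    if config.inner_subsample is not None and n > config.inner_subsample:
        keep = []
        for cls in np.unique(y):
            cls_idx = idx[y == cls]
            take = max(2, int(round(config.inner_subsample * len(cls_idx) / n)))
            keep.append(rng.choice(cls_idx, size=min(take, len(cls_idx)), replace=False))
        idx = np.concatenate(keep)
    train, val = [], []
    for cls in np.unique(y):
        cls_idx = rng.permutation(idx[y[idx] == cls])
        cut = max(1, int(round(config.inner_train_fraction * len(cls_idx))))
        cut = min(cut, len(cls_idx) - 1)
        train.append(cls_idx[:cut])
        val.append(cls_idx[cut:])
    return np.concatenate(train), np.concatenate(val)


def _inner_error(x_tr, y_tr, x_va, y_va, knn_k: int) -> float:
    """Mean of the k-NN and Gaussian-Bayes error rates (features pre-standardized)."""
    mu, sd = x_tr.mean(axis=0), x_tr.std(axis=0)
    sd[sd == 0] = 1.0
    x_tr = (x_tr - mu) / sd
    x_va = (x_va - mu) / sd
    knn = KNeighborsClassifier(n_neighbors=min(knn_k, len(y_tr)))
    knn.fit(x_tr, y_tr)
    err_knn = 1.0 - float(np.mean(knn.predict(x_va) == y_va))
    gnb = GaussianNB()
    gnb.fit(x_tr, y_tr)
    err_gnb = 1.0 - float(np.mean(gnb.predict(x_va) == y_va))
    return 0.5 * (err_knn + err_gnb)


def pso_fitness(subset_mask, features, labels, config: PSOConfig | None = None,
                _split=None) -> float:
    """Wrapper fitness  0.8 * error + 0.2 * selected/total  for a selection mask.

    The all-zero mask is assigned fitness 1.0 (worst) by contract.
    """
    config = config or PSOConfig()
    mask = np.asarray(subset_mask, dtype=bool)
    if not mask.any():
        return 1.0
    x, _ = _as_matrix(features)
    y = _check_binary(labels)
    _, yc = np.unique(y, return_inverse=True)
    tr, va = _split if _split is not None else _inner_split(len(yc), yc, config)
    error = _inner_error(x[np.ix_(tr, np.flatnonzero(mask))], yc[tr],
                         x[np.ix_(va, np.flatnonzero(mask))], yc[va], config.knn_k)
    return config.error_weight * error + config.size_weight * (mask.sum() / mask.size)


def pso_select(features, labels, config: PSOConfig | None = None) -> list[str]:
    """Binary particle swarm optimization of the selection mask.

    Velocities follow the canonical inertia + cognitive + social update and
    are squashed through a sigmoid; bits are re-sampled stochastically from
    the squashed velocity.  The all-ones mask is seeded into the initial
    swarm, so the returned global best can never be worse than selecting
    everything.  Fully reproducible from ``config.seed``.
    """
    config = config or PSOConfig()
    x, names = _as_matrix(features)
    if x.shape[1] < 2:
        raise ValueError("need at least two features")
    y = _check_binary(labels)
    _, yc = np.unique(y, return_inverse=True)
    rng = np.random.default_rng(config.seed)
    split = _inner_split(len(yc), yc, config)
    d = x.shape[1]
    s = config.swarm_size
    pos = rng.random((s, d)) < 0.5
    pos[0] = True  # the all-ones candidate
    vel = rng.uniform(-1, 1, size=(s, d))
    fit = np.array([pso_fitness(pos[i], x, yc, config, _split=split) for i in range(s)])
    pbest, pbest_fit = pos.copy(), fit.copy()
    g = int(np.argmin(fit))
    gbest, gbest_fit = pos[g].copy(), float(fit[g])
    for _ in range(config.iterations):
        r1 = rng.random((s, d))
        r2 = rng.random((s, d))
        vel = (config.inertia * vel
               + config.c1 * r1 * (pbest.astype(float) - pos)
               + config.c2 * r2 * (gbest.astype(float) - pos))
        np.clip(vel, -4.0, 4.0, out=vel)
        prob = 1.0 / (1.0 + np.exp(-vel))
        pos = rng.random((s, d)) < prob
        fit = np.array([pso_fitness(pos[i], x, yc, config, _split=split) for i in range(s)])
        better = fit < pbest_fit
        pbest[better] = pos[better]
        pbest_fit[better] = fit[better]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
    return [names[j] for j in np.flatnonzero(gbest)]


# -------------------------------------------------------------------- KPCA

class KernelPCA:
    """Kernel principal component analysis with train/test separation.

    Features are standardized with statistics of the fitted data; the kernel
    matrix is double-centered; eigenvectors of the centered Gram matrix are
    scaled by inverse root eigenvalues so that projections have unit
    per-component scaling.  Components are ordered by descending eigenvalue.
    The Gaussian bandwidth defaults to the median pairwise distance of the
    fitted (standardized) data.
    """

    def __init__(self, config: KpcaConfig):
        self.config = config
        self._fit_x = None

    def _kernel(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        kind = self.config.kernel
        if kind == "linear":
            return a @ b.T
        if kind == "polynomial_degree_3":
            gamma = 1.0 / a.shape[1]
            return (gamma * (a @ b.T) + 1.0) ** 3
        sq = cdist(a, b, "sqeuclidean")
        return np.exp(-sq / (2.0 * self.sigma_ ** 2))

    def fit(self, features) -> "KernelPCA":
        x, _ = _as_matrix(features)
        n = x.shape[0]
        if self.config.n_components > n:
            raise ValueError("n_components cannot exceed the number of fitted samples")
        self.mean_ = x.mean(axis=0)
        self.std_ = x.std(axis=0)
        self.std_[self.std_ == 0] = 1.0
        xs = (x - self.mean_) / self.std_
        self._fit_x = xs
        if self.config.kernel == "gaussian":
            if self.config.gaussian_sigma is not None:
                self.sigma_ = float(self.config.gaussian_sigma)
            else:
                sub = xs if n <= 1000 else xs[
                    np.random.default_rng(0).choice(n, 1000, replace=False)]
                med = float(np.median(pdist(sub)))
                self.sigma_ = med if med > 0 else 1.0
        k = self._kernel(xs, xs)
        ones = np.full((n, n), 1.0 / n)
        kc = k - ones @ k - k @ ones + ones @ k @ ones
        want = self.config.n_components
        vals, vecs = eigh(kc, subset_by_index=(n - want, n - 1))
        vals, vecs = vals[::-1], vecs[:, ::-1]
        tol = max(1e-10, 1e-10 * abs(vals[0])) if vals.size else 1e-10
        positive = vals > tol
        if positive.sum() < want:
            warnings.warn(
                f"only {int(positive.sum())} positive-eigenvalue components available; "
                f"truncating from {want}"
            )
        vals, vecs = vals[positive], vecs[:, positive]
        self.eigenvalues_ = vals
        self.alphas_ = vecs / np.sqrt(vals)  # dual coefficients
        self._k_fit_rowmeans = k.mean(axis=1)
        self._k_fit_mean = k.mean()
        self.n_components_ = int(vals.size)
        return self

    def transform(self, features) -> np.ndarray:
        x, _ = _as_matrix(features)
        xs = (x - self.mean_) / self.std_
        k = self._kernel(xs, self._fit_x)
        kc = (k - k.mean(axis=1, keepdims=True)
              - self._k_fit_rowmeans[None, :] + self._k_fit_mean)
        return kc @ self.alphas_

    def fit_transform(self, features) -> np.ndarray:
        self.fit(features)
        # for the fitted rows the projection reduces to vecs * sqrt(eigenvalues)
        return self.alphas_ * self.eigenvalues_


def kpca_fit_transform(features, config: KpcaConfig) -> np.ndarray:
    """Fit KPCA on ``features`` and return the training-row component scores."""
    return KernelPCA(config).fit_transform(features)
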
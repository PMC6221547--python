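"""Non-parametric EM mixture model with weighted kernel density components.

The model treats each subject's feature vector as drawn from one of L latent
clusters.  Conditional on cluster k, the M coordinates are independent and
each coordinate j follows a nonparametric density f_jk estimated by a
weighted kernel density estimate (standard normal kernel) over the training
sample, with weights equal to the posterior membership probabilities of
cluster k.  Fitting iterates:

  E-step   P(k | x_i)  ∝  λ_k · Π_j f_jk(x_ij)     (log-domain)
  M-step   λ_k = mean_i P(k | x_i)
  KDE step f_jk = weighted KDE of column j with cluster-k posterior weights

from a seed-controlled k-means initial partition, until the maximum absolute
change in the posterior matrix falls below ``tol``.  Bandwidths follow
Silverman's rule of thumb, computed once per feature on the pooled scaled
complete-case column and held constant across iterations and clusters.
The log-likelihood is monitored but not asserted monotone: this EM variant
has no guaranteed ascent property.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .preprocess import ReferenceStats

_SQRT2PI = np.sqrt(2.0 * np.pi)
#: density floor applied before logs so a single far-out point cannot
#: propagate -inf through the posterior product
DENSITY_FLOOR = 1e-300


class NpemError(RuntimeError):
    pass


@dataclass
class NpemConfig:
    """Fitting configuration.

    n_clusters : number of mixture components L (>= 1).
    seed : drives the k-means initialisation; same seed, same fit.
    max_iter : EM iteration cap.
    tol : convergence threshold on the max absolute change in posteriors.
    """

    n_clusters: int
    seed: int = 1
    max_iter: int = 500
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


class WeightedKde:
    """Weighted kernel density estimate with a standard normal kernel.

    evaluate(x) = Σ_i w_i φ((x − p_i)/h) / h, with Σ w_i = 1, h > 0.
    ``support_min``/``support_max`` record the observed training range of the
    feature; the classifier clips query points to this range.
    """

    __slots__ = ("points", "weights", "bandwidth", "support_min", "support_max")

    def __init__(self, points, weights, bandwidth, support_min=None,
                 support_max=None):
        self.points = np.asarray(points, dtype=float)
        w = np.asarray(weights, dtype=float)
        if w.shape != self.points.shape:
            raise ValueError("points and weights must have the same shape")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        self.weights = w
        self.bandwidth = float(bandwidth)
        self.support_min = float(self.points.min() if support_min is None
                                 else support_min)
        self.support_max = float(self.points.max() if support_max is None
                                 else support_max)

    def evaluate(self, x):
        """Density at scalar or array ``x``."""
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.points) / self.bandwidth
        phi = np.exp(-0.5 * z * z) / (_SQRT2PI * self.bandwidth)
        return phi @ self.weights

    def __call__(self, x):
        return self.evaluate(x)


def bandwidth_default(column) -> float:
    """Silverman rule-of-thumb bandwidth: 0.9 · min(sd, IQR/1.34) · n^(−1/5).

    Computed once on the pooled scaled complete-case column.  When the IQR
    collapses to zero (e.g. a very unbalanced binary feature) the sd alone is
    used; the result is floored at 1e-6.  A constant column is an error —
    such features must be dropped upstream.
    """
    col = np.asarray(column, dtype=float)
    col = col[~np.isnan(col)]
    n = col.size
    if n < 2 or np.unique(col).size < 2:
        raise NpemError("bandwidth undefined for a constant column")
    sd = col.std(ddof=1)
    q75, q25 = np.percentile(col, [75, 25])
    spread = min(sd, (q75 - q25) / 1.34)
    if spread == 0:
        spread = sd
    return max(0.9 * spread * n ** (-0.2), 1e-6)


def init_kmeans(data: np.ndarray, n_clusters: int, seed: int) -> np.ndarray:
    """Seed-controlled k-means hard partition used as the EM initial state.

    Returns labels in 0..L-1 with every cluster non-empty; retries with fresh
    seeded draws if a cluster comes back empty (k-means can, rarely, on
    degenerate data), then raises.
    """
    data = np.asarray(data, dtype=float)
    if np.isnan(data).any():
        raise ValueError("k-means initialisation requires complete cases")
    if data.shape[0] < n_clusters:
        raise ValueError("need at least as many subjects as clusters")
    rng = np.random.default_rng(seed)
    for _ in range(5):
        state = int(rng.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=state)
        labels = km.fit_predict(data)
        if np.unique(labels).size == n_clusters:
            return labels
    raise NpemError("k-means produced an empty cluster repeatedly")


def estimate_kdes(data: np.ndarray, posterior: np.ndarray,
                  bandwidths: np.ndarray) -> list[list[WeightedKde]]:
    """Weighted KDE f_jk for every (feature j, cluster k).

    Cluster k's weights are the k-th posterior column normalised to sum 1.
    A cluster with zero total posterior mass is degenerate and an error.
    """
    post = np.asarray(posterior, dtype=float)
    mass = post.sum(axis=0)
    if np.any(mass <= 0):
        raise NpemError("cluster with zero posterior mass")
    W = post / mass
    n_feat = data.shape[1]
    dens: list[list[WeightedKde]] = []
    for j in range(n_feat):
        col = data[:, j]
        dens.append([WeightedKde(col, W[:, k], bandwidths[j])
                     for k in range(post.shape[1])])
    return dens


@dataclass
class NpemModel:
    """A fitted npEM mixture: mixing proportions + per-(feature, cluster) KDEs."""

    n_clusters: int
    lambdas: np.ndarray
    densities: list[list[WeightedKde]]  # [feature j][cluster k]
    feature_names: list[str]
    reference_stats: ReferenceStats | None
    final_loglik: float
    n_iter: int
    converged: bool
    seed: int
    bandwidths: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        if np.any(lam < 0) or abs(lam.sum() - 1.0) > 1e-9:
            raise ValueError("lambdas must be non-negative and sum to 1")
        if len(self.densities) != len(self.feature_names):
            raise ValueError("one density list per feature required")
        for row in self.densities:
            if len(row) != self.n_clusters:
                raise ValueError("one density per cluster required")
        self.lambdas = lam

    # -- log density machinery ------------------------------------------

    def _log_cluster_densities(self, data: np.ndarray) -> np.ndarray:
        """N x L matrix of log λ_k + Σ_j log f_jk(x_ij) for complete rows."""
        n, L = data.shape[0], self.n_clusters
        logd = np.tile(np.log(np.maximum(self.lambdas, DENSITY_FLOOR)), (n, 1))
        for j in range(data.shape[1]):
            x = data[:, j]
            fj = np.column_stack(
                [self.densities[j][k].evaluate(x) for k in range(L)])
            logd += np.log(np.maximum(fj, DENSITY_FLOOR))
        return logd

    def posterior(self, data: np.ndarray) -> np.ndarray:
        """E-step: posterior membership probabilities for complete-case rows."""
        data = _check_data(data, len(self.feature_names))
        logd = self._log_cluster_densities(data)
        post = np.exp(logd - logsumexp(logd, axis=1, keepdims=True))
        return post

    def loglik(self, data: np.ndarray) -> float:
        """Mixture log-likelihood Σ_i log Σ_k λ_k Π_j f_jk(x_ij)."""
        data = _check_data(data, len(self.feature_names))
        return float(logsumexp(self._log_cluster_densities(data), axis=1).sum())

    def hard_labels(self, data: np.ndarray) -> np.ndarray:
        """Argmax-posterior cluster labels, 1-based."""
        return self.posterior(data).argmax(axis=1) + 1

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "lambdas": self.lambdas.tolist(),
            "feature_names": list(self.feature_names),
            "bandwidths": None if self.bandwidths is None
                          else np.asarray(self.bandwidths).tolist(),
            "densities": [
                [{
                    "points": kde.points.tolist(),
                    "weights": kde.weights.tolist(),
                    "bandwidth": kde.bandwidth,
                    "support_min": kde.support_min,
                    "support_max": kde.support_max,
                } for kde in row]
                for row in self.densities
            ],
            "reference_stats": None if self.reference_stats is None
                               else self.reference_stats.to_dict(),
            "final_loglik": self.final_loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NpemModel":
        dens = [
            [WeightedKde(e["points"], e["weights"], e["bandwidth"],
                         e["support_min"], e["support_max"]) for e in row]
            for row in d["densities"]
        ]
        stats = (None if d.get("reference_stats") is None
                 else ReferenceStats.from_dict(d["reference_stats"]))
        bw = d.get("bandwidths")
        return cls(
            n_clusters=d["n_clusters"],
            lambdas=np.asarray(d["lambdas"], dtype=float),
            densities=dens,
            feature_names=list(d["feature_names"]),
            reference_stats=stats,
            final_loglik=d["final_loglik"],
            n_iter=d["n_iter"],
            converged=d["converged"],
            seed=d["seed"],
            bandwidths=None if bw is None else np.asarray(bw, dtype=float),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "NpemModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _check_data(data, n_features: int) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != n_features:
        raise ValueError(
            f"data has {arr.shape[1] if arr.ndim == 2 else '?'} columns, "
            f"model has {n_features} features")
    if np.isnan(arr).any():
        raise ValueError("complete-case data required (use the classifier "
                         "for rows with missing features)")
    return arr


def e_step(data, model: NpemModel) -> np.ndarray:
    """Posterior membership probabilities (functional form of the E-step)."""
    return model.posterior(data)


def m_step(posterior: np.ndarray) -> np.ndarray:
    """Mixing proportions: column means of the posterior matrix."""
    post = np.asarray(posterior, dtype=float)
    if np.any(post < 0) or not np.allclose(post.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("posterior rows must be probabilities summing to 1")
    return post.mean(axis=0)


def fit(data, config: NpemConfig,
        feature_names: list[str] | None = None,
        reference_stats: ReferenceStats | None = None) -> NpemModel:
    """Fit the npEM mixture on scaled complete-case data.

    ``data`` may be a DataFrame (feature names and order taken from its
    columns) or a 2-D array with ``feature_names``.  Deterministic given
    (data, config): the k-means initialisation and every subsequent step are
    seed-controlled or closed-form.
    """
    if isinstance(data, pd.DataFrame):
        feature_names = list(data.columns)
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(X.shape[1])]
    if np.isnan(X).any():
        raise ValueError("fit requires complete-case data")
    n, m = X.shape
    L = config.n_clusters

    bandwidths = np.array([bandwidth_default(X[:, j]) for j in range(m)])

    labels = init_kmeans(X, L, config.seed)
    post = np.zeros((n, L))
    post[np.arange(n), labels] = 1.0

    # kernel matrices K_j[i, t] = φ((x_ij − x_tj)/h_j)/h_j are fixed across
    # iterations (constant bandwidths, fixed training points): precompute.
    kernels = []
    for j in range(m):
        z = (X[:, j][:, None] - X[:, j][None, :]) / bandwidths[j]
        kernels.append(np.exp(-0.5 * z * z) / (_SQRT2PI * bandwidths[j]))

    lambdas = m_step(post)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        mass = post.sum(axis=0)
        if np.any(mass <= 0):
            raise NpemError(f"cluster lost all posterior mass at iter {it}")
        W = post / mass                       # n x L, columns sum to 1
        logd = np.tile(np.log(np.maximum(lambdas, DENSITY_FLOOR)), (n, 1))
        for j in range(m):
            fj = kernels[j] @ W               # n x L densities for feature j
            logd += np.log(np.maximum(fj, DENSITY_FLOOR))
        new_post = np.exp(logd - logsumexp(logd, axis=1, keepdims=True))
        delta = np.abs(new_post - post).max()
        post = new_post
        lambdas = m_step(post)
        if delta < config.tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"npEM did not converge in {config.max_iter} iterations "
                      f"(last posterior change {delta:.2e})", RuntimeWarning)

    densities = estimate_kdes(X, post, bandwidths)
    model = NpemModel(
        n_clusters=L, lambdas=lambdas, densities=densities,
        feature_names=feature_names, reference_stats=reference_stats,
        final_loglik=0.0, n_iter=it, converged=converged, seed=config.seed,
        bandwidths=bandwidths,
    )
    model.final_loglik = model.loglik(X)
    return model
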
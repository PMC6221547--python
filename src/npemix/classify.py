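"""Posterior classification of subjects with arbitrary missing features.

A fitted mixture assigns a new subject the posterior

    P(k=K | x_i) = λ_K Π_j f_jK(x_ij) / Σ_k λ_k Π_j f_jk(x_ij)

with two conventions that make the product tolerant of incomplete rows:
missing features contribute density 1 (they drop out of the product, which
is exactly equivalent to deleting those features from the model), and query
values outside the training support of a feature take the density at the
nearest support bound (clipping), so the posterior is constant in each tail.
A subject is assigned to its argmax cluster only when the maximum posterior
strictly exceeds the threshold (default 0.90); otherwise it remains
unclassified.  Cross-cohort use restricts the model to the features the
external cohort shares, via an explicit feature mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .npem import DENSITY_FLOOR, NpemModel, WeightedKde
from scipy.special import logsumexp

#: sentinel label for subjects whose maximum posterior does not clear the threshold
UNCLASSIFIED = "unclassified"


@dataclass
class ClusterAssignment:
    subject_id: object
    label: object  # int cluster index (1-based) or UNCLASSIFIED
    posterior: np.ndarray
    max_posterior: float
    threshold_used: float
    n_features_used: int


@dataclass
class FeatureMapping:
    """Injective map from model feature names to external column names."""

    matched: dict[str, str]
    unmatched: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ext = list(self.matched.values())
        if len(set(ext)) != len(ext):
            raise ValueError("feature mapping must be injective")

    @classmethod
    def identity(cls, names) -> "FeatureMapping":
        return cls({n: n for n in names})

    @classmethod
    def by_shared_names(cls, model: NpemModel, columns) -> "FeatureMapping":
        cols = set(columns)
        matched = {n: n for n in model.feature_names if n in cols}
        unmatched = [n for n in model.feature_names if n not in cols]
        return cls(matched, unmatched)


def density_clipped(kde: WeightedKde, x) -> float:
    """Classifier density convention: missing → 1; out-of-range → clipped."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return 1.0
    xq = min(max(float(x), kde.support_min), kde.support_max)
    return float(kde.evaluate(xq))


def _log_posterior_rows(model: NpemModel, X: np.ndarray) -> np.ndarray:
    """N x L unnormalised log posteriors with missing/clipping conventions."""
    n, L = X.shape[0], model.n_clusters
    logd = np.tile(np.log(np.maximum(model.lambdas, DENSITY_FLOOR)), (n, 1))
    for j, _name in enumerate(model.feature_names):
        col = X[:, j]
        obs = ~np.isnan(col)
        if not obs.any():
            continue
        kdes = model.densities[j]
        # feature-level training support (all clusters share the pooled
        # column range in fitted models; hand-built models may not)
        lo = min(k.support_min for k in kdes)
        hi = max(k.support_max for k in kdes)
        xq = np.clip(col[obs], lo, hi)
        fj = np.column_stack([kdes[k].evaluate(xq) for k in range(L)])
        logd[obs] += np.log(np.maximum(fj, DENSITY_FLOOR))
    return logd


def posterior_row(model: NpemModel, row) -> np.ndarray:
    """Posterior membership probabilities for one (possibly incomplete) row.

    ``row`` must already be scaled with the model's stored reference stats.
    With every feature missing the posterior is the prior λ.
    """
    arr = np.asarray(row, dtype=float).reshape(1, -1)
    if arr.shape[1] != len(model.feature_names):
        raise ValueError("row length does not match model features")
    logd = _log_posterior_rows(model, arr)
    return np.exp(logd - logsumexp(logd, axis=1, keepdims=True))[0]


def classify(model: NpemModel, table: pd.DataFrame,
             threshold: float = 0.90) -> list[ClusterAssignment]:
    """Assign each subject to its argmax cluster iff max posterior > threshold.

    The threshold is strict; a subject at exactly the threshold stays
    unclassified.  ``table`` rows must be scaled with the model's reference
    stats and its columns must match the model's features.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    if list(table.columns) != list(model.feature_names):
        raise ValueError("table columns do not match model features")
    X = table.to_numpy(dtype=float)
    logd = _log_posterior_rows(model, X)
    post = np.exp(logd - logsumexp(logd, axis=1, keepdims=True))
    out = []
    n_used = (~np.isnan(X)).sum(axis=1)
    for i, sid in enumerate(table.index):
        p = post[i]
        k = int(p.argmax())
        mx = float(p[k])
        label = (k + 1) if mx > threshold else UNCLASSIFIED
        out.append(ClusterAssignment(
            subject_id=sid, label=label, posterior=p, max_posterior=mx,
            threshold_used=threshold, n_features_used=int(n_used[i]),
        ))
    return out


def restrict_model(model: NpemModel, mapping: FeatureMapping) -> NpemModel:
    """Subset a model to the features an external cohort shares.

    Densities and reference stats are restricted; λ and everything else is
    unchanged.  Classifying through the restricted model is identical to
    classifying through the full model with the unmatched features missing.
    """
    keep = [n for n in model.feature_names if n in mapping.matched]
    if not keep:
        raise ValueError("feature mapping matches no model features")
    idx = [model.feature_names.index(n) for n in keep]
    stats = (None if model.reference_stats is None
             else model.reference_stats.subset(keep))
    return NpemModel(
        n_clusters=model.n_clusters,
        lambdas=model.lambdas.copy(),
        densities=[model.densities[j] for j in idx],
        feature_names=keep,
        reference_stats=stats,
        final_loglik=model.final_loglik,
        n_iter=model.n_iter,
        converged=model.converged,
        seed=model.seed,
        bandwidths=None if model.bandwidths is None
                   else np.asarray(model.bandwidths)[idx],
    )


def concordance(assign_a: list[ClusterAssignment],
                assign_b: list[ClusterAssignment]) -> float:
    """Fraction of subjects classified in both runs that received the same label."""
    a = {x.subject_id: x.label for x in assign_a}
    b = {x.subject_id: x.label for x in assign_b}
    common = set(a) & set(b)
    if not common:
        raise ValueError("assignments share no subjects")
    both = [s for s in common
            if a[s] != UNCLASSIFIED and b[s] != UNCLASSIFIED]
    if not both:
        raise ValueError("no subject classified in both runs")
    return sum(a[s] == b[s] for s in both) / len(both)


def assignments_to_frame(assignments: list[ClusterAssignment]) -> pd.DataFrame:
    L = len(assignments[0].posterior)
    rows = []
    for a in assignments:
        row = {"subject_id": a.subject_id, "label": a.label,
               "max_posterior": a.max_posterior,
               "n_features_used": a.n_features_used}
        for k in range(L):
            row[f"p_cluster{k + 1}"] = a.posterior[k]
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def read_feature_mapping(path) -> FeatureMapping:
    """Read a mapping CSV with columns model_feature, external_feature."""
    df = pd.read_csv(path)
    matched, unmatched = {}, []
    for _, r in df.iterrows():
        ext = r["external_feature"]
        if pd.isna(ext) or ext == "":
            unmatched.append(r["model_feature"])
        else:
            matched[r["model_feature"]] = ext
    return FeatureMapping(matched, unmatched)
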
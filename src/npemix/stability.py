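"""Cluster stability (leave-one-out Jaccard) and internal validity (silhouette).

Stability is probed by refitting the mixture on the complete-case data with
one individual (or one feature) left out, for each entity in turn and for a
set of initialisation seeds.  Each refit partition is aligned to the
reference partition by an optimal one-to-one matching that maximises total
Jaccard similarity over the L x L cluster-overlap matrix, and the per-cluster
Jaccard indices against the reference clusters are averaged over refits and
seeds.  Internal validity uses Rousseeuw silhouette widths
s(i) = (b(i) − a(i)) / max(a(i), b(i)) on Euclidean distances in the scaled
feature space; members of singleton clusters get width 0 by convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import silhouette_samples

from .npem import NpemConfig, fit


@dataclass
class StabilityReport:
    per_cluster_jaccard: np.ndarray  # mean Jaccard per reference cluster
    seeds: list[int]
    n_refits: int
    n_nonconverged: int
    mode: str  # "loo_individual" | "loo_feature"
    detail: pd.DataFrame | None = None  # long format: seed, left_out, cluster, jaccard


@dataclass
class SilhouetteReport:
    per_subject: pd.Series
    per_cluster_mean: pd.Series
    overall_mean: float


def jaccard(a, b) -> float:
    """|A ∩ B| / |A ∪ B|; two empty sets count as identical (1)."""
    A, B = set(a), set(b)
    union = A | B
    if not union:
        return 1.0
    return len(A & B) / len(union)


def _clusters_of(labels: pd.Series) -> dict[int, set]:
    return {k: set(labels.index[labels == k]) for k in np.unique(labels)}


def align_labels(partition: pd.Series, reference: pd.Series):
    """Match partition clusters to reference clusters, maximising total Jaccard.

    Both arguments are label Series indexed by subject id (overlapping sets).
    Returns ``(mapping, unmatched)`` where ``mapping`` maps a partition label
    to the reference label it was assigned to; with unequal cluster counts the
    optimal rectangular assignment is used and leftovers are reported.
    """
    pc, rc = _clusters_of(partition), _clusters_of(reference)
    p_labels, r_labels = list(pc), list(rc)
    sim = np.array([[jaccard(pc[p], rc[r]) for r in r_labels]
                    for p in p_labels])
    rows, cols = linear_sum_assignment(-sim)
    mapping = {p_labels[i]: r_labels[j] for i, j in zip(rows, cols)}
    unmatched = [p for p in p_labels if p not in mapping]
    return mapping, unmatched


def _per_cluster_jaccard(refit_labels: pd.Series,
                         reference: pd.Series) -> dict[int, float]:
    """Align refit clusters to the reference and report Jaccard per reference
    cluster, over the subjects the two partitions share."""
    common = refit_labels.index.intersection(reference.index)
    refit_c = refit_labels.loc[common]
    ref_c = reference.loc[common]
    mapping, _ = align_labels(refit_c, ref_c)
    pc, rc = _clusters_of(refit_c), _clusters_of(ref_c)
    out = {}
    for r in rc:
        matched = [p for p, rr in mapping.items() if rr == r]
        out[r] = jaccard(pc[matched[0]], rc[r]) if matched else 0.0
    return out


def _loo_report(data: pd.DataFrame, config: NpemConfig, seeds,
                axis: str, stride: int) -> StabilityReport:
    reference = pd.Series(fit(data, config).hard_labels(data.to_numpy()),
                          index=data.index)
    ref_labels = sorted(np.unique(reference))
    entities = (list(data.index) if axis == "loo_individual"
                else list(data.columns))
    if axis == "loo_feature" and len(entities) < 2:
        raise ValueError("cannot leave out the only feature")
    if axis == "loo_individual" and data.shape[0] <= config.n_clusters:
        raise ValueError("too few subjects to leave one out per cluster")
    entities = entities[::stride]
    rows = []
    n_bad = 0
    for seed in seeds:
        cfg = replace(config, seed=int(seed))
        for left_out in entities:
            if axis == "loo_individual":
                sub = data.drop(index=left_out)
            else:
                sub = data.drop(columns=left_out)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                model = fit(sub, cfg)
            if not model.converged:
                n_bad += 1
            labels = pd.Series(model.hard_labels(sub.to_numpy()),
                               index=sub.index)
            jc = _per_cluster_jaccard(labels, reference)
            for r in ref_labels:
                rows.append((int(seed), left_out, int(r), jc.get(r, 0.0),
                             model.converged))
    detail = pd.DataFrame(
        rows, columns=["seed", "left_out", "cluster", "jaccard", "converged"])
    per_cluster = (detail.groupby("cluster")["jaccard"].mean()
                   .reindex(ref_labels).to_numpy())
    return StabilityReport(
        per_cluster_jaccard=per_cluster, seeds=[int(s) for s in seeds],
        n_refits=len(seeds) * len(entities), n_nonconverged=n_bad,
        mode=axis, detail=detail,
    )


def loo_individual(data: pd.DataFrame, config: NpemConfig,
                   seeds=range(1, 11), stride: int = 1) -> StabilityReport:
    """Leave-one-individual-out stability over the given seeds.

    ``stride`` subsamples the left-out individuals (every stride-th subject)
    to keep large runs tractable; stride=1 is the full procedure.
    """
    return _loo_report(data, config, list(seeds), "loo_individual", stride)


def loo_feature(data: pd.DataFrame, config: NpemConfig,
                seeds=range(1, 11), stride: int = 1) -> StabilityReport:
    """Leave-one-feature-out stability over the given seeds."""
    return _loo_report(data, config, list(seeds), "loo_feature", stride)


def silhouette(data: pd.DataFrame, labels) -> SilhouetteReport:
    """Rousseeuw silhouette widths on Euclidean distance in scaled space."""
    labels = pd.Series(np.asarray(labels), index=data.index)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    widths = silhouette_samples(data.to_numpy(dtype=float), labels.to_numpy())
    # singleton-cluster members take width 0 by convention
    singleton = {k for k, c in zip(uniq, counts) if c == 1}
    if singleton:
        widths = np.where(labels.isin(singleton), 0.0, widths)
    per_subject = pd.Series(widths, index=data.index, name="silhouette")
    per_cluster = per_subject.groupby(labels).mean()
    return SilhouetteReport(per_subject, per_cluster,
                            float(per_subject.mean()))
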
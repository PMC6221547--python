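"""Choice of the number of mixture components by BIC.

BIC = −2·log p̂ + ν·ln(N) with ν = L·M + (L−1): L·M effective density
parameters (one nonparametric density per feature per cluster, counted once
each) plus L−1 free mixing proportions.  The sweep refits the mixture for
each candidate L with the same seed and takes the minimiser; ties go to the
smaller L for parsimony.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

from .npem import NpemConfig, NpemModel, fit


@dataclass
class BicRecord:
    L: int
    nu: int
    loglik: float
    bic: float
    converged: bool


def n_parameters(L: int, M: int) -> int:
    """Effective parameter count ν = L·M + (L−1)."""
    return L * M + (L - 1)


def bic(loglik: float, L: int, M: int, N: int) -> float:
    """−2·loglik + ν·ln(N).  Natural log, the standard BIC convention."""
    if min(L, M, N) < 1:
        raise ValueError("L, M, N must all be >= 1")
    return -2.0 * loglik + n_parameters(L, M) * math.log(N)


def sweep_L(data, L_min: int, L_max: int, config: NpemConfig,
            keep_models: bool = False):
    """Fit L = L_min..L_max (same seed each) and select the BIC minimiser.

    Returns ``(records, selected_L)`` or ``(records, selected_L, models)``
    when ``keep_models``.  Non-converged fits are recorded with their flag,
    not dropped.  Ties break toward smaller L.
    """
    N = data.shape[0]
    M = data.shape[1]
    if not (1 <= L_min <= L_max <= N):
        raise ValueError("require 1 <= L_min <= L_max <= N")
    records: list[BicRecord] = []
    models: dict[int, NpemModel] = {}
    for L in range(L_min, L_max + 1):
        model = fit(data, replace(config, n_clusters=L))
        records.append(BicRecord(
            L=L, nu=n_parameters(L, M), loglik=model.final_loglik,
            bic=bic(model.final_loglik, L, M, N), converged=model.converged,
        ))
        if keep_models:
            models[L] = model
    best = min(records, key=lambda r: (r.bic, r.L))
    if keep_models:
        return records, best.L, models
    return records, best.L


def records_to_frame(records: list[BicRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.L, r.nu, r.loglik, r.bic, r.converged) for r in records],
        columns=["L", "nu", "loglik", "bic", "converged"],
    )
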
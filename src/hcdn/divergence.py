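"""Bootstrap difference test of per-group CCA refits ("hits").

For each bootstrap iteration the two family-history groups are resampled
with replacement at their own sizes and one CCA is fit per group.  Both
solutions are aligned to a full-sample reference (mode rank order by
canonical correlation, joint sign flips against the reference vectors), and
the elementwise difference of canonical-vector entries (with-history minus
without) is recorded per mode and region.  A region is a *hit* for a mode
when the 10/90% percentile interval of its difference distribution excludes
zero — an 80% interval, so the nominal null exclusion rate is 20%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hcdn.cca import CCAModel, fit_cca

__all__ = [
    "DifferenceDistribution",
    "align_to_reference",
    "bootstrap_group_difference",
    "detect_hits",
]

logger = logging.getLogger(__name__)


@dataclass
class DifferenceDistribution:
    """Bootstrap difference estimates per canonical-vector entry.

    ``dn`` has shape (B, p, k) and ``hc`` (B, q, k): difference of the
    with-history group's canonical-vector entry minus the without-history
    group's, per bootstrap iteration.
    """

    dn: np.ndarray
    hc: np.ndarray
    dn_regions: list[str]
    hc_regions: list[str]

    @property
    def B(self) -> int:
        return self.dn.shape[0]


def align_to_reference(
    model: CCAModel, reference: CCAModel, match_by_correlation: bool = False
) -> CCAModel:
    """Match a refitted model's modes to a reference solution.

    Modes are ordered by descending within-model canonical correlation (the
    fit already guarantees this; re-sorted defensively), then each
    ``(v_l, u_l)`` pair is jointly sign-flipped when ``corr(v_l, v_ref,l)``
    is negative.  With ``match_by_correlation=True``, modes are instead
    paired greedily with the reference vector of maximal ``|corr|`` —
    protection against mode swapping when canonical correlations nearly tie.
    """
    if model.V.shape != reference.V.shape or model.U.shape != reference.U.shape:
        raise ValueError("model and reference dimensions differ")

    order = np.argsort(-model.rhos, kind="stable")
    V = model.V[:, order].copy()
    U = model.U[:, order].copy()
    rhos = model.rhos[order].copy()

    if match_by_correlation:
        corr = np.corrcoef(V, reference.V, rowvar=False)[: model.k, model.k:]
        perm = np.full(model.k, -1)
        taken: set[int] = set()
        # greedy assignment on |corr|, strongest pairs first
        for i, j in zip(*np.unravel_index(np.argsort(-np.abs(corr), axis=None), corr.shape)):
            if perm[j] < 0 and i not in taken:
                perm[j] = i
                taken.add(i)
        V, U, rhos = V[:, perm], U[:, perm], rhos[perm]

    for j in range(model.k):
        c = np.dot(V[:, j] - V[:, j].mean(), reference.V[:, j] - reference.V[:, j].mean())
        if c < 0:
            V[:, j] *= -1
            U[:, j] *= -1

    return CCAModel(
        V=V,
        U=U,
        rhos=rhos,
        k=model.k,
        x_columns=model.x_columns,
        y_columns=model.y_columns,
        x_mean=model.x_mean,
        x_sd=model.x_sd,
        y_mean=model.y_mean,
        y_sd=model.y_sd,
    )


def bootstrap_group_difference(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    history: np.ndarray,
    reference: CCAModel,
    B: int = 100,
    seed: int = 0,
    match_by_correlation: bool = False,
) -> DifferenceDistribution:
    """Bootstrap distribution of per-entry canonical-vector differences.

    ``2 * B`` CCA fits in total: per iteration, each family-history group is
    resampled with replacement at its own size and refit separately.  A
    resample in which some region has zero variance is redrawn (logged).
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    history = np.asarray(history).astype(bool)
    idx_with = np.flatnonzero(history)
    idx_without = np.flatnonzero(~history)
    if len(idx_with) == 0 or len(idx_without) == 0:
        raise ValueError("both family-history groups must be non-empty")

    rng = np.random.default_rng(seed)
    k = reference.k
    dn = np.empty((B, X.shape[1], k))
    hc = np.empty((B, Y.shape[1], k))

    Xv, Yv = X.reset_index(drop=True), Y.reset_index(drop=True)
    for b in range(B):
        models = []
        for idx in (idx_with, idx_without):
            for _attempt in range(100):
                take = rng.choice(idx, size=len(idx), replace=True)
                Xb, Yb = Xv.iloc[take], Yv.iloc[take]
                if (Xb.std(ddof=0) == 0).any() or (Yb.std(ddof=0) == 0).any():
                    logger.info("zero-variance resample redrawn (iteration %d)", b)
                    continue
                m = fit_cca(Xb, Yb, k=k)
                break
            else:  # pragma: no cover - pathological fixture
                raise RuntimeError("could not draw a non-degenerate resample")
            models.append(align_to_reference(m, reference, match_by_correlation))
        m_with, m_without = models
        dn[b] = m_with.V - m_without.V
        hc[b] = m_with.U - m_without.U

    return DifferenceDistribution(
        dn=dn, hc=hc, dn_regions=list(X.columns), hc_regions=list(Y.columns)
    )


def detect_hits(
    dist: DifferenceDistribution,
    lower_pct: float = 10.0,
    upper_pct: float = 90.0,
) -> pd.DataFrame:
    """Flag entries whose bootstrap percentile interval excludes zero.

    Returns a table with one row per (mode, atlas, region): the
    ``[lower_pct, upper_pct]`` percentile bounds (linear interpolation) and
    a boolean ``hit`` flag true iff 0 lies outside the interval.
    """
    if dist.B == 0:
        raise ValueError("empty difference distribution")
    if dist.B < 10:
        logger.warning("B=%d is small for 10/90%% percentiles", dist.B)

    rows = []
    for atlas, arr, regions in (
        ("DN", dist.dn, dist.dn_regions),
        ("HC", dist.hc, dist.hc_regions),
    ):
        lo = np.percentile(arr, lower_pct, axis=0)
        hi = np.percentile(arr, upper_pct, axis=0)
        k = arr.shape[2]
        for j in range(k):
            for r, region in enumerate(regions):
                l, h = lo[r, j], hi[r, j]
                rows.append(
                    {
                        "mode": j + 1,
                        "atlas": atlas,
                        "region": region,
                        "lo": l,
                        "hi": h,
                        "hit": bool(l > 0 or h < 0),
                    }
                )
    return pd.DataFrame(rows)
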
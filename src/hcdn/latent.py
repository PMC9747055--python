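"""Latent axes of brain-behaviour association via SVD of a correlation matrix.

``M`` (risk factors x canonical variates, 63 x 50 at reference dimensions)
holds the Pearson correlations between every risk factor and every HC/DN
variate.  Its columns are z-scored, then ``M = U S V^T``; the top three
left singular vectors scaled by their singular values (``U S``) project the
risk factors onto the principal axes, and squared singular values give the
explained-variance fractions.  Robustness is assessed by bootstrap:
split-half (resample all subjects, split into two halves of floor(n/2)) or
sex-stratified (resample each sex at its own size), comparing component
weights between the two solutions after sign alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hcdn.cca import VariatePair

__all__ = [
    "LatentAxes",
    "correlation_matrix",
    "latent_axes",
    "reliability_bootstrap",
    "split_half_sizes",
]


def split_half_sizes(n: int) -> tuple[int, int]:
    """Sizes of the two equal split-half subsets: floor(n/2) each.

    A cohort of 37,291 splits into two subsets of 18,645 (one resampled
    subject is left out when n is odd).
    """
    return n // 2, n // 2

logger = logging.getLogger(__name__)


@dataclass
class LatentAxes:
    """Top-component projections, weights and explained-variance fractions."""

    projections: pd.DataFrame  # risk factors x n_components (rows of M on U*S)
    weights: pd.DataFrame  # variate features x n_components (right singular vectors)
    explained_variance: np.ndarray  # fractions for the retained components
    all_singular_values: np.ndarray


def correlation_matrix(
    variates: VariatePair, risk_factors: pd.DataFrame
) -> pd.DataFrame:
    """Pearson matrix M: risk factors (rows) by stacked HC/DN variates (cols)."""
    L = pd.concat(
        [variates.L_X.add_prefix("DN_"), variates.L_Y.add_prefix("HC_")], axis=1
    )
    R = risk_factors.to_numpy(dtype=float)
    V = L.to_numpy(dtype=float)
    n = len(R)
    Rs = (R - R.mean(axis=0)) / R.std(axis=0, ddof=0)
    Vs = (V - V.mean(axis=0)) / V.std(axis=0, ddof=0)
    M = Rs.T @ Vs / n
    return pd.DataFrame(M, index=list(risk_factors.columns), columns=list(L.columns))


def _zscore_matrix(M: np.ndarray, how: str) -> np.ndarray:
    if how == "columns":
        sd = M.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ValueError("zero-variance column in correlation matrix")
        return (M - M.mean(axis=0)) / sd
    if how == "pooled":
        sd = M.std(ddof=0)
        if sd == 0:
            raise ValueError("correlation matrix is constant")
        return (M - M.mean()) / sd
    raise ValueError(f"unknown z-scoring scheme {how!r}")


def latent_axes(
    M: pd.DataFrame, n_components: int = 3, zscore: str = "columns"
) -> LatentAxes:
    """SVD of the z-scored correlation matrix, retaining the top components.

    Per component, the sign is fixed so the largest-|entry| of the weight
    vector (right singular vector) is positive; projection columns flip
    jointly.  Explained-variance fractions are squared singular values over
    their total (summing to 1 across all components).
    """
    if min(M.shape) < n_components:
        raise ValueError(f"need at least {n_components} rows and columns")
    Z = _zscore_matrix(M.to_numpy(dtype=float), zscore)
    Uf, s, Vt = np.linalg.svd(Z, full_matrices=False)
    for j in range(n_components):
        if Vt[j, np.argmax(np.abs(Vt[j]))] < 0:
            Vt[j] *= -1
            Uf[:, j] *= -1
    frac = s**2 / np.sum(s**2)
    comp_names = [f"component_{j + 1}" for j in range(n_components)]
    return LatentAxes(
        projections=pd.DataFrame(
            Uf[:, :n_components] * s[:n_components], index=M.index, columns=comp_names
        ),
        weights=pd.DataFrame(Vt[:n_components].T, index=M.columns, columns=comp_names),
        explained_variance=frac[:n_components],
        all_singular_values=s,
    )


def reliability_bootstrap(
    variates: VariatePair,
    risk_factors: pd.DataFrame,
    scheme: str = "split_half",
    sex: np.ndarray | None = None,
    B: int = 1000,
    seed: int = 0,
    n_components: int = 3,
    zscore: str = "columns",
) -> pd.DataFrame:
    """Bootstrap agreement of latent-component weights between paired subsets.

    ``split_half``: per iteration, draw n subjects with replacement, split
    into two halves of floor(n/2), compute M and the component solution per
    half.  ``by_sex``: resample males and females separately at their own
    sizes.  Agreement per component is the Pearson r between the two weight
    vectors after sign alignment (flip when negative).  Returns the (B x
    n_components) agreement table; summary percentiles via ``describe`` or
    ``np.percentile`` downstream.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    n = len(risk_factors)
    if scheme == "by_sex":
        if sex is None:
            raise ValueError("by_sex scheme requires the sex vector")
        sex = np.asarray(sex)
        groups = [np.flatnonzero(sex == s) for s in ("male", "female")]
    elif scheme == "split_half":
        groups = None
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    rng = np.random.default_rng(seed)
    rows = np.empty((B, n_components))
    for b in range(B):
        if groups is None:
            draw = rng.choice(n, size=n, replace=True)
            half, _ = split_half_sizes(n)
            subsets = (draw[:half], draw[half: 2 * half])
        else:
            subsets = tuple(rng.choice(g, size=len(g), replace=True) for g in groups)
        axes = []
        for idx in subsets:
            if len(idx) < 3:
                raise ValueError("subset too small for correlation")
            vp = VariatePair(
                L_X=variates.L_X.iloc[idx].reset_index(drop=True),
                L_Y=variates.L_Y.iloc[idx].reset_index(drop=True),
            )
            M = correlation_matrix(vp, risk_factors.iloc[idx].reset_index(drop=True))
            axes.append(latent_axes(M, n_components=n_components, zscore=zscore))
        for j in range(n_components):
            w1 = axes[0].weights.iloc[:, j].to_numpy()
            w2 = axes[1].weights.iloc[:, j].to_numpy()
            r = float(np.corrcoef(w1, w2)[0, 1])
            # components are sign-indeterminate: flip one when anti-aligned
            rows[b, j] = abs(r)
    return pd.DataFrame(
        rows, columns=[f"component_{j + 1}" for j in range(n_components)]
    )
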
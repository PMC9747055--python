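"""Canonical correlation analysis of two regional volume sets.

Classical CCA: given standardized matrices ``X`` (n x p, default-network
parcels) and ``Y`` (n x q, hippocampal subfields), find weight matrices
``V`` and ``U`` maximizing ``corr(X v_l, Y u_l)`` per mode, with variates
within each set mutually uncorrelated.  Solved by singular value
decomposition of the whitened cross-covariance
``Sxx^{-1/2} Sxy Syy^{-1/2}``; the singular values are the canonical
correlations, naturally rank-ordered.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CCAModel", "VariatePair", "fit_cca", "transform_to_variates"]

logger = logging.getLogger(__name__)


@dataclass
class CCAModel:
    """Fitted canonical vectors, correlations and training standardization.

    ``V`` (p x k) and ``U`` (q x k) are normalized so each training variate
    has unit variance; ``rhos`` is non-increasing.  The training column
    means/SDs are stored so the model can be applied out of sample.
    """

    V: np.ndarray
    U: np.ndarray
    rhos: np.ndarray
    k: int
    x_columns: list[str]
    y_columns: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray

    def save(self, path: str | Path) -> None:
        """Serialize to a single JSON file (matrices as nested lists)."""
        payload = {
            "k": self.k,
            "V": self.V.tolist(),
            "U": self.U.tolist(),
            "rhos": self.rhos.tolist(),
            "x_columns": self.x_columns,
            "y_columns": self.y_columns,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean.tolist(),
            "y_sd": self.y_sd.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "CCAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            V=np.asarray(d["V"], dtype=float),
            U=np.asarray(d["U"], dtype=float),
            rhos=np.asarray(d["rhos"], dtype=float),
            k=int(d["k"]),
            x_columns=list(d["x_columns"]),
            y_columns=list(d["y_columns"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_sd=np.asarray(d["x_sd"], dtype=float),
            y_mean=np.asarray(d["y_mean"], dtype=float),
            y_sd=np.asarray(d["y_sd"], dtype=float),
        )


@dataclass
class VariatePair:
    """Subject-level mode expressions: ``L_X = X V`` and ``L_Y = Y U``."""

    L_X: pd.DataFrame
    L_Y: pd.DataFrame

    @property
    def k(self) -> int:
        return self.L_X.shape[1]


def _inv_sqrt_psd(S: np.ndarray, label: str) -> np.ndarray:
    """Inverse symmetric square root, ridge-stabilized when near-singular."""
    w, Q = np.linalg.eigh(S)
    if w.min() < 1e-10 * w.max():
        eps = 1e-8 * np.trace(S) / S.shape[0]
        logger.warning(
            "near-singular within-set covariance (%s); ridge eps=%.3e applied", label, eps
        )
        w = w + eps
    return (Q / np.sqrt(w)) @ Q.T


def apply_sign_convention(V: np.ndarray, U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Jointly flip (v_l, u_l) so v_l's largest-|entry| is positive."""
    V = V.copy()
    U = U.copy()
    for j in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] *= -1
            U[:, j] *= -1
    return V, U


def fit_cca(X: pd.DataFrame, Y: pd.DataFrame, k: int = 25) -> CCAModel:
    """Fit classical CCA retaining the leading ``k`` modes.

    Inputs are expected deconfounded; columns are (re-)standardized
    internally using the population-SD convention, and those statistics are
    stored on the model for out-of-sample use.  A deterministic sign
    convention (largest-|entry| of each DN canonical vector positive) makes
    refits reproducible.
    """
    n, p = X.shape
    q = Y.shape[1]
    if k > min(p, q):
        raise ValueError(f"k={k} exceeds min(p, q)={min(p, q)}")
    if n <= p + q:
        logger.warning("n=%d <= p+q=%d: CCA estimates will be unstable", n, p + q)

    Xv = X.to_numpy(dtype=float)
    Yv = Y.to_numpy(dtype=float)
    x_mean, x_sd = Xv.mean(axis=0), Xv.std(axis=0, ddof=0)
    y_mean, y_sd = Yv.mean(axis=0), Yv.std(axis=0, ddof=0)
    if np.any(x_sd == 0) or np.any(y_sd == 0):
        bad = list(X.columns[x_sd == 0]) + list(Y.columns[y_sd == 0])
        raise ValueError(f"zero-variance regions: {bad}")
    Xs = (Xv - x_mean) / x_sd
    Ys = (Yv - y_mean) / y_sd

    Sxx = Xs.T @ Xs / n
    Syy = Ys.T @ Ys / n
    Sxy = Xs.T @ Ys / n
    Wx = _inv_sqrt_psd(Sxx, "X")
    Wy = _inv_sqrt_psd(Syy, "Y")

    Uw, svals, Vwt = np.linalg.svd(Wx @ Sxy @ Wy)
    V = Wx @ Uw[:, :k]
    U = Wy @ Vwt[:k].T
    rhos = np.clip(svals[:k], 0.0, 1.0)

    # normalize variates to unit variance on training data
    V /= np.sqrt(np.sum((Xs @ V) ** 2, axis=0) / n)
    U /= np.sqrt(np.sum((Ys @ U) ** 2, axis=0) / n)
    V, U = apply_sign_convention(V, U)

    return CCAModel(
        V=V,
        U=U,
        rhos=rhos,
        k=k,
        x_columns=list(X.columns),
        y_columns=list(Y.columns),
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
    )


def transform_to_variates(
    model: CCAModel, X: pd.DataFrame, Y: pd.DataFrame
) -> VariatePair:
    """Project volumes onto the model's canonical vectors.

    Applies the model's stored training standardization, then
    ``L_X = X V`` / ``L_Y = Y U``.  Columns must match the training atlas
    order by name.
    """
    for cols, have, side in ((model.x_columns, list(X.columns), "X"),
                             (model.y_columns, list(Y.columns), "Y")):
        if cols != have:
            missing = [c for c in cols if c not in have]
            extra = [c for c in have if c not in cols]
            raise ValueError(
                f"{side} columns do not match training atlas; "
                f"missing={missing}, extra={extra}"
            )
    Xs = (X.to_numpy(dtype=float) - model.x_mean) / model.x_sd
    Ys = (Y.to_numpy(dtype=float) - model.y_mean) / model.y_sd
    mode_names = [f"mode_{j + 1:02d}" for j in range(model.k)]
    return VariatePair(
        L_X=pd.DataFrame(Xs @ model.V, index=X.index, columns=mode_names),
        L_Y=pd.DataFrame(Ys @ model.U, index=Y.index, columns=mode_names),
    )
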
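"""Out-of-sample projection of a reference CCA model onto an external cohort.

External volumes (deconfounded with the external cohort's own confound
model) are standardized using the external cohort's column means/SDs by
default and multiplied by the reference canonical vectors.  Phenotype
correlations with the projected variates are screened by permutation:
phenotype rows are shuffled B times and a coefficient is retained when its
|r| beats the permuted |r| in at least 95% of iterations (add-one p <= 0.05).
Repeated visits are treated as independent rows.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from hcdn.cca import CCAModel, VariatePair

__all__ = ["project_external", "permutation_corr_scan"]

logger = logging.getLogger(__name__)


def project_external(
    reference: CCAModel,
    X_ext: pd.DataFrame,
    Y_ext: pd.DataFrame,
    use_reference_stats: bool = False,
) -> VariatePair:
    """Express reference modes in an unseen cohort's volumes.

    With ``use_reference_stats=True`` the training cohort's column
    means/SDs are applied instead of the external cohort's own.
    """
    if list(X_ext.columns) != reference.x_columns or list(Y_ext.columns) != reference.y_columns:
        raise ValueError("external volume columns do not match the reference atlas")
    Xv = X_ext.to_numpy(dtype=float)
    Yv = Y_ext.to_numpy(dtype=float)
    if use_reference_stats:
        Xs = (Xv - reference.x_mean) / reference.x_sd
        Ys = (Yv - reference.y_mean) / reference.y_sd
    else:
        x_sd = Xv.std(axis=0, ddof=0)
        y_sd = Yv.std(axis=0, ddof=0)
        if np.any(x_sd == 0) or np.any(y_sd == 0):
            raise ValueError("zero-variance region in external cohort")
        Xs = (Xv - Xv.mean(axis=0)) / x_sd
        Ys = (Yv - Yv.mean(axis=0)) / y_sd
    mode_names = [f"mode_{j + 1:02d}" for j in range(reference.k)]
    return VariatePair(
        L_X=pd.DataFrame(Xs @ reference.V, index=X_ext.index, columns=mode_names),
        L_Y=pd.DataFrame(Ys @ reference.U, index=Y_ext.index, columns=mode_names),
    )


def permutation_corr_scan(
    variates: VariatePair,
    phenotypes: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation-screened Pearson correlations of variates with phenotypes.

    Returns a long table with one row per (side, mode, phenotype): observed
    r, add-one permutation p, a ``retained`` flag, and the masked r (NaN
    when not retained).  Constant phenotype columns are skipped with a log
    message; missing values are not supported here (complete table expected).
    """
    L = pd.concat(
        [variates.L_X.add_prefix("DN_"), variates.L_Y.add_prefix("HC_")], axis=1
    )
    keep = phenotypes.columns[phenotypes.std(ddof=0) > 0]
    dropped = set(phenotypes.columns) - set(keep)
    for c in dropped:
        logger.info("phenotype %s skipped: constant column", c)
    P = phenotypes[keep].to_numpy(dtype=float)
    if P.shape[0] < 3:
        raise ValueError("need at least 3 rows for correlation")
    V = L.to_numpy(dtype=float)
    n = len(V)

    Vs = (V - V.mean(axis=0)) / V.std(axis=0, ddof=0)
    Ps = (P - P.mean(axis=0)) / P.std(axis=0, ddof=0)
    r_obs = Vs.T @ Ps / n  # (n_variates, n_phenotypes)

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(r_obs)
    for _ in range(B):
        perm = rng.permutation(n)
        r_perm = Vs.T @ Ps[perm] / n
        exceed += np.abs(r_perm) >= np.abs(r_obs)
    pvals = (1.0 + exceed) / (1.0 + B)
    retained = pvals <= alpha

    side = [c.split("_", 1)[0] for c in L.columns]
    mode = [int(c.rsplit("_", 1)[1]) for c in L.columns]
    rows = []
    for i, col in enumerate(L.columns):
        for j, ph in enumerate(keep):
            rows.append(
                {
                    "side": side[i],
                    "mode": mode[i],
                    "variate": col,
                    "phenotype": ph,
                    "r": r_obs[i, j],
                    "p_perm": pvals[i, j],
                    "retained": bool(retained[i, j]),
                    "masked_r": r_obs[i, j] if retained[i, j] else np.nan,
                }
            )
    return pd.DataFrame(rows)
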
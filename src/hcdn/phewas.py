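"""APOE e2-vs-e4 dosage, stacking regression, and the phenome-wide scan.

The bivariate dosage scale scores each genotype as
(#e2 alleles) - (#e4 alleles): e2/2 -> +2, e2/3 -> +1, e3/3 and e2/4 -> 0,
e3/4 -> -1, e4/4 -> -2.  Per sex and mode, dosage is regressed on the pair
of HC/DN variate expressions (a two-slope "stacking" base model); subjects
in the extreme tails (bottom/top 5%) of the predicted dosage are selected
and, among them, each curated phenotype is Pearson-correlated with the
predicted dosage.  Significance is adjusted per signature by Bonferroni
(alpha / m) and Benjamini-Hochberg FDR at 5%.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from hcdn.cca import VariatePair

__all__ = [
    "DOSAGE_SCALE",
    "dosage_score",
    "stacked_dosage_prediction",
    "select_tails",
    "phenome_scan",
    "multiple_testing_adjust",
    "sex_difference_table",
]

logger = logging.getLogger(__name__)

#: Genotype -> (#e2) - (#e4) allele-count score.
DOSAGE_SCALE = {
    "e2/2": 2,
    "e2/3": 1,
    "e3/3": 0,
    "e2/4": 0,
    "e3/4": -1,
    "e4/4": -2,
}


def dosage_score(genotype: str) -> int:
    """Bivariate allele-counting score of one diploid APOE genotype."""
    try:
        return DOSAGE_SCALE[genotype]
    except KeyError:
        raise ValueError(
            f"unknown APOE genotype {genotype!r}; expected one of {sorted(DOSAGE_SCALE)}"
        ) from None


def stacked_dosage_prediction(
    variates: VariatePair,
    dosage: np.ndarray,
    sex: np.ndarray,
    mode: int,
) -> pd.Series:
    """Per-sex OLS of dosage on one mode's (DN, HC) variate pair.

    Fits ``dosage ~ 1 + L_X[:, mode] + L_Y[:, mode]`` separately in males
    and females and returns the fitted values (indexed like the variates).
    ``mode`` is zero-based.
    """
    dosage = np.asarray(dosage, dtype=float)
    sex = np.asarray(sex)
    lx = variates.L_X.iloc[:, mode].to_numpy()
    ly = variates.L_Y.iloc[:, mode].to_numpy()
    if len(dosage) != len(lx) or len(sex) != len(lx):
        raise ValueError("dosage, sex and variates must have aligned rows")

    predicted = np.full(len(dosage), np.nan)
    for s in np.unique(sex):
        m = sex == s
        if np.ptp(dosage[m]) == 0:
            raise ValueError(f"dosage is constant within sex {s!r}")
        D = np.column_stack([np.ones(m.sum()), lx[m], ly[m]])
        beta, *_ = np.linalg.lstsq(D, dosage[m], rcond=None)
        predicted[m] = D @ beta
    return pd.Series(predicted, index=variates.L_X.index, name=f"predicted_dosage_m{mode + 1}")


def select_tails(
    predicted: np.ndarray | pd.Series,
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
) -> np.ndarray:
    """Mask of subjects in the extreme tails of the predicted dosage.

    True for values at or below the ``lower_pct`` percentile or at or above
    the ``upper_pct`` percentile (linear-interpolation quantiles); with the
    defaults roughly 10% of subjects are selected.  Degenerate bounds
    (0/100) select only the exact extremes.
    """
    x = np.asarray(predicted, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("predicted dosage is constant; tails are undefined")
    if len(x) < 40:
        logger.warning("only %d subjects: percentile tails are degenerate", len(x))
    lo = np.percentile(x, lower_pct)
    hi = np.percentile(x, upper_pct)
    return (x <= lo) | (x >= hi)


def _pearson_with_p(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson r and two-sided p of ``x`` against columns of ``Y``."""
    n = len(x)
    xs = (x - x.mean()) / x.std(ddof=0)
    Ys = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=0)
    r = xs @ Ys / n
    r = np.clip(r, -1.0, 1.0)
    # two-sided p via the exact beta distribution of r under the null
    ab = 0.5 * (n - 2)
    p = 2 * stats.beta.sf(np.abs(r), ab, ab, loc=-1, scale=2)
    return r, np.minimum(p, 1.0)


def phenome_scan(
    predicted: pd.Series | np.ndarray,
    phenotypes: pd.DataFrame,
    categories: pd.Series | None = None,
    alpha: float = 0.05,
    q: float = 0.05,
) -> pd.DataFrame:
    """Correlate predicted dosage with every phenotype among selected subjects.

    ``predicted`` and ``phenotypes`` are already restricted to the
    tail-selected subjects.  Missing phenotype values are handled by
    pairwise-complete deletion; columns with fewer than 3 complete pairs or
    zero variance among them are skipped with a logged reason.  Returns one
    row per tested phenotype sorted by p, with Bonferroni and FDR flags
    computed over the tested set.
    """
    x = np.asarray(predicted, dtype=float)
    if len(x) != len(phenotypes):
        raise ValueError("predicted and phenotypes must have aligned rows")

    names, rs, ps = [], [], []
    Y = phenotypes.to_numpy(dtype=float)
    full = ~np.isnan(Y).any(axis=0)
    if full.any():
        cols = np.flatnonzero(full)
        ok = Y[:, cols].std(axis=0, ddof=0) > 0
        for c in cols[~ok]:
            logger.info("phenotype %s skipped: zero variance", phenotypes.columns[c])
        use = cols[ok]
        r, p = _pearson_with_p(x, Y[:, use])
        names += [phenotypes.columns[c] for c in use]
        rs += list(r)
        ps += list(p)
    for c in np.flatnonzero(~full):
        col = Y[:, c]
        m = ~np.isnan(col)
        name = phenotypes.columns[c]
        if m.sum() < 3:
            logger.info("phenotype %s skipped: <3 complete pairs", name)
            continue
        if col[m].std(ddof=0) == 0 or x[m].std(ddof=0) == 0:
            logger.info("phenotype %s skipped: zero variance on complete pairs", name)
            continue
        r, p = stats.pearsonr(x[m], col[m])
        names.append(name)
        rs.append(r)
        ps.append(p)

    result = pd.DataFrame({"phenotype": names, "r": rs, "p": ps})
    bonf, fdr, thresh = multiple_testing_adjust(result["p"].to_numpy(), alpha=alpha, q=q)
    result["bonferroni"] = bonf
    result["fdr"] = fdr
    result["bonferroni_threshold"] = thresh
    if categories is not None:
        result.insert(1, "category", result["phenotype"].map(categories))
    return result.sort_values("p", kind="stable").reset_index(drop=True)


def multiple_testing_adjust(
    pvalues: np.ndarray, alpha: float = 0.05, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray, float]:
    """Bonferroni mask, Benjamini-Hochberg FDR mask, Bonferroni threshold.

    The Bonferroni threshold is ``alpha / m`` over the tested phenotypes
    (0.05 / 977 = 5.11e-5 at the full inventory); FDR is the BH step-up
    procedure at level ``q``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    threshold = alpha / p.size
    bonferroni = p < threshold
    fdr = multipletests(p, alpha=q, method="fdr_bh")[0]
    return bonferroni, fdr | bonferroni, threshold


def sex_difference_table(
    male_scan: pd.DataFrame, female_scan: pd.DataFrame
) -> pd.DataFrame:
    """Post-hoc male-vs-female comparison of one mode's two scans.

    Joins on phenotype and reports both sexes' r and p plus the absolute
    -log10(p) gap — the tabular counterpart of a mirrored Miami display.
    No new statistics are computed.
    """
    m = male_scan.set_index("phenotype")[["r", "p"]].add_suffix("_male")
    f = female_scan.set_index("phenotype")[["r", "p"]].add_suffix("_female")
    both = m.join(f, how="inner")
    with np.errstate(divide="ignore"):
        both["abs_delta_log10p"] = np.abs(
            -np.log10(both["p_male"]) - (-np.log10(both["p_female"]))
        )
    return both.sort_values("abs_delta_log10p", ascending=False).reset_index()
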
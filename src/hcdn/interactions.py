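"""Brain-by-genotype interaction regressions with permutation masking.

Each outcome (a risk factor, or the binary family-history label) is
regressed, per sex, on one canonical variate, the six APOE genotype
indicators (no global intercept — each genotype coefficient is that group's
adjusted baseline), six genotype-by-variate interaction terms, and age:
14 parameters in total.  Coefficient robustness is assessed against
empirical null distributions built by refitting on outcome-shuffled data;
a coefficient is retained when its add-one two-tailed permutation p-value
is at most 0.05 (i.e., it beats its null in at least 95% of iterations).

Note on identifiability: because the genotype indicators partition the
subjects, the six interaction columns sum exactly to the variate column —
the 14-column design is structurally rank 13.  Linear models are therefore
fit by minimum-norm least squares and logistic models by IRLS with
pseudo-inverse steps; genotype main effects, the age effect and every
per-genotype total slope (variate + interaction coefficient) are uniquely
identified, while the variate/interaction split is resolved by the
minimum-norm convention.  Rank deficiency *beyond* the structural one
(e.g., a genotype absent from a sex subset) is an error naming the
offending columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning
import warnings

from hcdn.synth import GENOTYPES

__all__ = [
    "InteractionDesign",
    "build_interaction_design",
    "fit_interaction_model",
    "permutation_mask",
    "permutation_sweep_plan",
]

logger = logging.getLogger(__name__)


@dataclass
class InteractionDesign:
    """14-column design: variate, 6 genotype indicators, 6 interactions, age."""

    matrix: pd.DataFrame

    @property
    def n_parameters(self) -> int:
        return self.matrix.shape[1]


def build_interaction_design(
    variate: np.ndarray, genotype: np.ndarray, age: np.ndarray
) -> InteractionDesign:
    """Assemble the 14-parameter design for one canonical variate.

    All six genotype indicators are included with no global intercept (they
    partition the subjects, so their span contains the constant); the six
    interaction columns are indicator times variate.
    """
    variate = np.asarray(variate, dtype=float)
    genotype = np.asarray(genotype)
    age = np.asarray(age, dtype=float)
    if not (len(variate) == len(genotype) == len(age)):
        raise ValueError("variate, genotype and age must have equal length")
    unknown = set(genotype) - set(GENOTYPES)
    if unknown:
        raise ValueError(f"unknown genotypes: {sorted(unknown)}")

    cols: dict[str, np.ndarray] = {"variate": variate}
    for g in GENOTYPES:
        cols[f"g[{g}]"] = (genotype == g).astype(float)
    for g in GENOTYPES:
        cols[f"g[{g}]:variate"] = cols[f"g[{g}]"] * variate
    cols["age"] = age
    return InteractionDesign(pd.DataFrame(cols))


def fit_interaction_model(
    outcome: np.ndarray,
    design: InteractionDesign,
    family: str = "linear",
) -> pd.Series:
    """OLS or ML-logistic coefficients of the 14-parameter model.

    Logistic fits report log-odds coefficients; odds ratios are
    ``np.exp(coefficients)``.  Perfect separation is flagged with a warning
    rather than an error.  Rank deficiency is an error naming the collinear
    columns (e.g., a genotype absent from the subset).
    """
    y = np.asarray(outcome, dtype=float)
    D = design.matrix.to_numpy(dtype=float)
    if len(y) != len(D):
        raise ValueError("outcome and design must have aligned rows")

    # the interaction columns sum to the variate column by construction, so
    # full rank is 13 of 14; anything lower indicates genuine collinearity
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1] - 1:
        zero_cols = [
            c for c, s in zip(design.matrix.columns, D.std(axis=0)) if s == 0
        ]
        raise ValueError(
            f"rank-deficient design beyond the structural deficiency "
            f"(rank {rank} < {D.shape[1] - 1}); "
            f"constant/absent columns: {zero_cols or 'none (non-trivial collinearity)'}"
        )

    if family == "linear":
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    elif family == "logistic":
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("logistic family requires a binary 0/1 outcome")
        with warnings.catch_warnings(), np.errstate(over="ignore"):
            warnings.simplefilter("error", PerfectSeparationWarning)
            try:
                # IRLS with pseudo-inverse steps tolerates the structural
                # rank deficiency and is deterministic
                beta = sm.GLM(y, D, family=sm.families.Binomial()).fit(maxiter=200).params
            except (PerfectSeparationError, PerfectSeparationWarning):
                logger.warning("perfect separation detected; coefficients unreliable")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    beta = sm.GLM(y, D, family=sm.families.Binomial()).fit(maxiter=50).params
    else:
        raise ValueError(f"unknown family {family!r}")
    return pd.Series(beta, index=design.matrix.columns, name="coefficient")


def _linear_perm_coefs(D: np.ndarray, Yperm: np.ndarray) -> np.ndarray:
    # pinv trick: B outcome shuffles solved as one matrix product,
    # algebraically identical to B separate OLS refits
    return np.linalg.pinv(D) @ Yperm


def permutation_mask(
    outcome: np.ndarray,
    design: InteractionDesign,
    family: str = "linear",
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation-null robustness test of every coefficient.

    The outcome is shuffled across subjects ``B`` times (design rows fixed)
    and the model refit; per coefficient, the add-one two-tailed p-value is
    ``(1 + #{|b_perm| >= |b_obs|}) / (1 + B)`` and the coefficient is
    flagged (retained) when p <= ``alpha``.  The returned table reports the
    observed coefficient, p, the flag, and the masked value (NaN when not
    flagged).
    """
    if B < 100:
        raise ValueError("B must be at least 100 for stable tail estimates")
    y = np.asarray(outcome, dtype=float)
    rng = np.random.default_rng(seed)
    obs = fit_interaction_model(y, design, family).to_numpy()

    D = design.matrix.to_numpy(dtype=float)
    if family == "linear":
        Yperm = np.empty((len(y), B))
        for b in range(B):
            Yperm[:, b] = rng.permutation(y)
        perm = _linear_perm_coefs(D, Yperm)  # (14, B)
    else:
        perm = np.empty((D.shape[1], B))
        b = 0
        attempts = 0
        while b < B:
            attempts += 1
            if attempts > 2 * B:
                raise RuntimeError("too many failed permutation refits")
            try:
                perm[:, b] = fit_interaction_model(rng.permutation(y), design, family).to_numpy()
            except Exception as exc:  # refit failure: redraw
                logger.info("permutation refit failed (%s); redrawn", exc)
                continue
            b += 1

    exceed = (np.abs(perm) >= np.abs(obs)[:, None]).sum(axis=1)
    pvals = (1.0 + exceed) / (1.0 + B)
    flagged = pvals <= alpha
    out = pd.DataFrame(
        {
            "coefficient": obs,
            "p_perm": pvals,
            "flagged": flagged,
            "masked": np.where(flagged, obs, np.nan),
        },
        index=design.matrix.columns,
    )
    if family == "logistic":
        out["odds_ratio"] = np.exp(out["coefficient"])
    return out


def permutation_sweep_plan(n_outcomes: int, B: int = 1000) -> dict:
    """Bookkeeping for a full permutation sweep across outcomes.

    A sweep over 61 risk factors at B = 1,000 plans 61,000 shuffled refits
    per model.
    """
    return {
        "n_outcomes": int(n_outcomes),
        "iterations_per_outcome": int(B),
        "total_iterations": int(n_outcomes) * int(B),
    }
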
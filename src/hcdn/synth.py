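"""Synthetic cohort generator with planted low-rank brain co-variation.

The generator emulates the statistical structure the downstream analyses
assume: two regional grey-matter volume sets (default-network parcels and
hippocampal subfields) sharing a planted low-rank cross-covariance with
known canonical correlations, a six-genotype APOE distribution with
population frequencies, family-history labels drawn from per-genotype and
per-sex odds ratios, linear confound contamination with known coefficients,
and phenotype / risk-factor tables linearly linked to the latent scores
(optionally in one sex only).

Every planted quantity has a closed-form oracle so that estimation error of
the downstream pipeline can be measured exactly
(:func:`oracle_canonical_correlations`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GENOTYPES",
    "SEXES",
    "PHENOTYPE_CATEGORIES",
    "SynthConfig",
    "PlantedStructure",
    "PhenotypeEffect",
    "generate_cohort",
    "make_planted_structure",
    "generate_brain_volumes",
    "generate_phenotype_tables",
    "oracle_canonical_correlations",
    "cohort_summary",
    "assign_categories",
]

#: The six diploid APOE genotypes formed by the e2/e3/e4 alleles.
GENOTYPES = ("e2/2", "e2/3", "e3/3", "e2/4", "e3/4", "e4/4")

SEXES = ("male", "female")

#: Phenotype category labels (11 broad domains, cycled over columns).
PHENOTYPE_CATEGORIES = (
    "cognitive",
    "physical_health",
    "mental_health",
    "lifestyle",
    "sociodemographic",
    "blood_assay",
    "physical_measure",
    "early_life",
    "medical_history",
    "environment",
    "employment",
)

# Population genotype frequencies in a largely European-ancestry imaging
# cohort: e3/3 59.3%, e3/4 23.1%, e2/3 12.4%, e2/4 2.4%, e4/4 2.2%, e2/2 0.6%.
_DEFAULT_FREQS = {
    "e3/3": 0.593,
    "e3/4": 0.231,
    "e2/3": 0.124,
    "e2/4": 0.024,
    "e4/4": 0.022,
    "e2/2": 0.006,
}

# Per-genotype, per-sex odds ratios for a positive family history of
# Alzheimer's disease and related dementia, relative to baseline prevalence.
# e4 homozygotes raise the odds (+56% males, +86% females); e2 is protective,
# most clearly in females (e2/2 halves the odds).
_DEFAULT_FH_ODDS = {
    ("e2/2", "male"): 1.00,
    ("e2/3", "male"): 0.70,
    ("e3/3", "male"): 0.70,
    ("e2/4", "male"): 1.20,
    ("e3/4", "male"): 1.20,
    ("e4/4", "male"): 1.56,
    ("e2/2", "female"): 0.50,
    ("e2/3", "female"): 0.75,
    ("e3/3", "female"): 0.83,
    ("e2/4", "female"): 1.24,
    ("e3/4", "female"): 1.35,
    ("e4/4", "female"): 1.86,
}

_CONTAMINATED_CONFOUNDS = ("bmi", "head_size", "motion_task", "motion_rest")


@dataclass(frozen=True)
class PhenotypeEffect:
    """Linear link from one latent mode to a phenotype column.

    ``sex`` restricts the effect to one sex (``None`` = both); the other
    sex receives pure noise for that column.
    """

    mode: int
    slope: float
    sex: str | None = None


@dataclass(frozen=True)
class SynthConfig:
    """Stated world of the synthetic cohort.

    Defaults mirror the reference population: n genotyped imaging
    participants with 91 default-network parcels and 38 hippocampal
    subfields, three leading planted canonical correlations
    (0.51, 0.42, 0.39), Table-1 genotype frequencies, 25.5% baseline
    family-history prevalence, 977 phenotypes and 63 risk factors.
    """

    n_subjects: int = 2000
    p_dn: int = 91
    q_hc: int = 38
    k_planted: int = 3
    planted_rhos: tuple[float, ...] = (0.51, 0.42, 0.39)
    genotype_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FREQS)
    )
    family_history_odds: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_FH_ODDS)
    )
    baseline_prevalence: float = 0.255
    female_fraction: float = 0.53
    age_mean: float = 54.8
    age_sd: float = 7.5
    age_range: tuple[float, float] = (40.0, 70.0)
    # Regions whose loadings are perturbed by +hit_delta in the
    # family-history group, per mode and atlas: {mode: {"hc": [...], "dn": [...]}}
    hit_regions: Mapping[int, Mapping[str, Sequence[int]]] = field(
        default_factory=dict
    )
    hit_delta: float = 0.3
    # Mean shift of a latent mode per unit of e2-vs-e4 dosage, optionally
    # sex-restricted: {mode: (slope, sex_or_None)}
    dosage_effects: Mapping[int, tuple[float, str | None]] = field(
        default_factory=dict
    )
    phenotype_effects: Mapping[str, PhenotypeEffect] = field(default_factory=dict)
    n_phenotypes: int = 977
    n_risk_factors: int = 63
    risk_block_strength: float = 0.3
    noise_sd: float = 1.0
    confound_coef_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.k_planted > min(self.p_dn, self.q_hc):
            raise ValueError("k_planted must not exceed min(p_dn, q_hc)")
        if len(self.planted_rhos) != self.k_planted:
            raise ValueError("planted_rhos length must equal k_planted")
        rhos = np.asarray(self.planted_rhos, dtype=float)
        if np.any(rhos <= 0) or np.any(rhos > 1):
            raise ValueError("planted_rhos must lie in (0, 1]")
        if np.any(np.diff(rhos) >= 0):
            raise ValueError("planted_rhos must be strictly decreasing")
        if self.noise_sd > 0 and np.any(rhos >= 1):
            raise ValueError("planted_rhos must be < 1 unless noise_sd is 0")
        if set(self.genotype_freqs) != set(GENOTYPES):
            raise ValueError(f"genotype_freqs must have keys {GENOTYPES}")
        total = float(sum(self.genotype_freqs.values()))
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"genotype frequencies sum to {total}, not 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


@dataclass
class PlantedStructure:
    """Ground-truth loadings and latent scores behind a synthetic cohort.

    ``A`` (p_dn x k) and ``B`` (q_hc x k) carry orthonormal columns;
    ``latent_scores`` (n x k) are i.i.d. standard normal up to configured
    dosage-linked mean shifts.  ``delta_A``/``delta_B`` hold the sparse
    loading perturbation applied to family-history subjects, and
    ``confound_coefs_*`` the known linear contamination coefficients that
    deconfounding must remove.
    """

    A: np.ndarray
    B: np.ndarray
    latent_scores: np.ndarray
    delta_A: np.ndarray
    delta_B: np.ndarray
    mode_scales: np.ndarray
    confound_coefs_dn: pd.DataFrame
    confound_coefs_hc: pd.DataFrame


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(config: SynthConfig) -> pd.DataFrame:
    """Draw per-subject demographics, genotype, confounds and family history.

    Family-history labels are drawn *after* genotype and sex so the
    configured odds ratios hold exactly in the design:
    ``logit P(FH=1 | g, s) = logit(baseline_prevalence) + log OR[g, s]``.
    """
    n = config.n_subjects
    rng = _rng_children(config.seed, 3)[0]

    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    freqs = np.array([config.genotype_freqs[g] for g in GENOTYPES])
    genotype = rng.choice(GENOTYPES, size=n, p=freqs / freqs.sum())

    base_logit = np.log(config.baseline_prevalence / (1 - config.baseline_prevalence))
    log_or = np.array(
        [np.log(config.family_history_odds[(g, s)]) for g, s in zip(genotype, sex)]
    )
    p_fh = 1.0 / (1.0 + np.exp(-(base_logit + log_or)))
    family_history = (rng.random(n) < p_fh).astype(int)

    cohort = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:06d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "genotype": genotype,
            "family_history": family_history,
            "bmi": rng.normal(27.0, 4.0, n),
            "head_size": rng.normal(1500.0, 100.0, n),
            "motion_task": rng.gamma(4.0, 0.025, n),
            "motion_rest": rng.gamma(4.0, 0.025, n),
            "pos_x": rng.normal(0.0, 1.0, n),
            "pos_y": rng.normal(0.0, 1.0, n),
            "pos_z": rng.normal(0.0, 1.0, n),
            "table_pos": rng.normal(0.0, 1.0, n),
            "site": rng.choice(["site1", "site2", "site3"], size=n, p=[0.5, 0.3, 0.2]),
        }
    )
    return cohort


def _dosage_vector(cohort: pd.DataFrame) -> np.ndarray:
    # local copy of the allele-summing scale to keep synth self-contained
    from hcdn.phewas import dosage_score

    return np.array([dosage_score(g) for g in cohort["genotype"]], dtype=float)


def make_planted_structure(
    cohort: pd.DataFrame, config: SynthConfig
) -> PlantedStructure:
    """Draw orthonormal loadings, latent scores and contamination coefficients.

    Per-mode signal scales ``s_l`` are solved analytically from the planted
    canonical correlations: with symmetric scales and isotropic noise
    ``sigma``, ``rho_l = s_l^2 / (s_l^2 + sigma^2)``, hence
    ``s_l^2 = sigma^2 * rho_l / (1 - rho_l)`` (``sigma = 0`` plants
    ``rho = 1`` with unit signal scale).
    """
    n, k = config.n_subjects, config.k_planted
    rng = _rng_children(config.seed, 3)[1]

    A = np.linalg.qr(rng.standard_normal((config.p_dn, k)))[0]
    B = np.linalg.qr(rng.standard_normal((config.q_hc, k)))[0]

    Z = rng.standard_normal((n, k))
    dosage = _dosage_vector(cohort)
    for mode, (slope, sex) in config.dosage_effects.items():
        if not 0 <= mode < k:
            raise ValueError(f"dosage effect references unknown mode {mode}")
        mask = np.ones(n, bool) if sex is None else (cohort["sex"] == sex).to_numpy()
        Z[mask, mode] += slope * dosage[mask]

    rhos = np.asarray(config.planted_rhos, dtype=float)
    if config.noise_sd == 0:
        scales = np.ones(k)
    else:
        scales = config.noise_sd * np.sqrt(rhos / (1.0 - rhos))

    delta_A = np.zeros_like(A)
    delta_B = np.zeros_like(B)
    for mode, atlases in config.hit_regions.items():
        if not 0 <= mode < k:
            raise ValueError(f"hit region references unknown mode {mode}")
        for idx in atlases.get("dn", ()):  # type: ignore[union-attr]
            delta_A[idx, mode] += config.hit_delta
        for idx in atlases.get("hc", ()):  # type: ignore[union-attr]
            delta_B[idx, mode] += config.hit_delta

    c = len(_CONTAMINATED_CONFOUNDS)
    coef_dn = pd.DataFrame(
        config.confound_coef_scale * rng.standard_normal((c, config.p_dn)),
        index=list(_CONTAMINATED_CONFOUNDS),
        columns=dn_region_names(config.p_dn),
    )
    coef_hc = pd.DataFrame(
        config.confound_coef_scale * rng.standard_normal((c, config.q_hc)),
        index=list(_CONTAMINATED_CONFOUNDS),
        columns=hc_region_names(config.q_hc),
    )
    return PlantedStructure(
        A=A,
        B=B,
        latent_scores=Z,
        delta_A=delta_A,
        delta_B=delta_B,
        mode_scales=scales,
        confound_coefs_dn=coef_dn,
        confound_coefs_hc=coef_hc,
    )


def dn_region_names(p: int) -> list[str]:
    return [f"dn_{i + 1:03d}" for i in range(p)]


def hc_region_names(q: int) -> list[str]:
    return [f"hc_{i + 1:03d}" for i in range(q)]


def generate_brain_volumes(
    cohort: pd.DataFrame,
    structure: PlantedStructure,
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region-level volume matrices with planted cross-covariance.

    ``X = Z diag(s) A' + E`` (and likewise for Y), where family-history
    subjects use the perturbed loadings ``A + delta_A`` / ``B + delta_B``.
    Standardized contaminated confounds enter linearly with the known
    coefficients stored in the structure, so that residualization can be
    verified against ground truth.
    """
    if structure.A.shape != (config.p_dn, config.k_planted):
        raise ValueError("structure/config dimension mismatch for DN loadings")
    if structure.B.shape != (config.q_hc, config.k_planted):
        raise ValueError("structure/config dimension mismatch for HC loadings")
    n = config.n_subjects
    if len(cohort) != n or structure.latent_scores.shape[0] != n:
        raise ValueError("cohort / structure / config subject counts disagree")

    rng = _rng_children(config.seed, 3)[2]
    Zs = structure.latent_scores * structure.mode_scales

    fh = cohort["family_history"].to_numpy().astype(bool)
    X = Zs @ structure.A.T
    Y = Zs @ structure.B.T
    if structure.delta_A.any() or structure.delta_B.any():
        X[fh] = Zs[fh] @ (structure.A + structure.delta_A).T
        Y[fh] = Zs[fh] @ (structure.B + structure.delta_B).T
    X = X + config.noise_sd * rng.standard_normal(X.shape)
    Y = Y + config.noise_sd * rng.standard_normal(Y.shape)

    conf = cohort[list(_CONTAMINATED_CONFOUNDS)].to_numpy(dtype=float)
    conf = (conf - conf.mean(axis=0)) / conf.std(axis=0)
    X = X + conf @ structure.confound_coefs_dn.to_numpy()
    Y = Y + conf @ structure.confound_coefs_hc.to_numpy()

    X_df = pd.DataFrame(X, columns=dn_region_names(config.p_dn))
    Y_df = pd.DataFrame(Y, columns=hc_region_names(config.q_hc))
    return X_df, Y_df


def generate_phenotype_tables(
    cohort: pd.DataFrame,
    structure: PlantedStructure,
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Curated-phenotype and risk-factor tables linked to latent scores.

    Configured phenotype columns follow ``slope * latent + N(0,1)``,
    optionally in one sex only; the rest are pure noise.  The risk-factor
    table carries three correlated blocks (social, cardiovascular,
    personality); each block shares a common factor — a planted latent mode
    where one exists, a fresh factor otherwise — with loading
    ``risk_block_strength``.
    """
    n, k = config.n_subjects, config.k_planted
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    Z = structure.latent_scores

    names = [f"pheno_{i + 1:04d}" for i in range(config.n_phenotypes)]
    pheno = rng.standard_normal((n, config.n_phenotypes))
    name_to_col = {nm: j for j, nm in enumerate(names)}
    for name, eff in config.phenotype_effects.items():
        if not 0 <= eff.mode < k:
            raise ValueError(f"phenotype effect references unknown mode {eff.mode}")
        j = name_to_col.get(name)
        if j is None:
            raise ValueError(f"unknown phenotype column {name!r}")
        mask = (
            np.ones(n, bool) if eff.sex is None else (cohort["sex"] == eff.sex).to_numpy()
        )
        pheno[mask, j] += eff.slope * Z[mask, eff.mode]
    pheno_df = pd.DataFrame(pheno, columns=names)

    blocks = ("social", "cardio", "personality")
    sizes = np.full(len(blocks), config.n_risk_factors // len(blocks))
    sizes[: config.n_risk_factors % len(blocks)] += 1
    w = float(config.risk_block_strength)
    risk_cols: dict[str, np.ndarray] = {}
    for b, (block, size) in enumerate(zip(blocks, sizes)):
        factor = Z[:, b] if b < k else rng.standard_normal(n)
        for i in range(size):
            risk_cols[f"{block}_{i + 1:02d}"] = (
                w * factor + np.sqrt(1.0 - w**2) * rng.standard_normal(n)
            )
    risk_df = pd.DataFrame(risk_cols)
    return pheno_df, risk_df


def oracle_canonical_correlations(
    structure: PlantedStructure, config: SynthConfig
) -> np.ndarray:
    """Population canonical correlations from the analytic joint covariance.

    Builds the exact covariance blocks of the generative model
    (``Sxx = A diag(s^2) A' + sigma^2 I`` etc.), whitens the cross block with
    eigendecomposition-based inverse square roots (pseudo-inverse on the
    signal subspace when ``sigma = 0``) and returns the top ``k_planted``
    singular values — an independent brute-force route that never calls the
    sample CCA solver.
    """
    s2 = structure.mode_scales**2
    sig2 = config.noise_sd**2
    Sxx = structure.A @ np.diag(s2) @ structure.A.T + sig2 * np.eye(config.p_dn)
    Syy = structure.B @ np.diag(s2) @ structure.B.T + sig2 * np.eye(config.q_hc)
    Sxy = structure.A @ np.diag(s2) @ structure.B.T

    def inv_sqrt(S: np.ndarray) -> np.ndarray:
        w, Q = np.linalg.eigh(S)
        tol = w.max() * 1e-12
        inv = np.where(w > tol, 1.0 / np.sqrt(np.maximum(w, tol)), 0.0)
        return (Q * inv) @ Q.T

    K = inv_sqrt(Sxx) @ Sxy @ inv_sqrt(Syy)
    svals = np.linalg.svd(K, compute_uv=False)
    rhos = np.clip(svals[: config.k_planted], 0.0, 1.0)
    return rhos


def cohort_summary(cohort: pd.DataFrame) -> dict:
    """Headline cohort descriptives: n, genotype %, family-history %."""
    n = len(cohort)
    geno_pct = {
        g: round(100.0 * (cohort["genotype"] == g).sum() / n, 1) for g in GENOTYPES
    }
    n_fh = int(cohort["family_history"].sum())
    return {
        "n_subjects": n,
        "genotype_percent": geno_pct,
        "n_family_history": n_fh,
        "family_history_percent": round(100.0 * n_fh / n, 1),
        "percent_female": round(100.0 * (cohort["sex"] == "female").sum() / n, 1),
    }


def assign_categories(columns: Sequence[str]) -> pd.Series:
    """Cycle the 11 phenotype-category labels over a column list."""
    cats = [PHENOTYPE_CATEGORIES[i % len(PHENOTYPE_CATEGORIES)] for i in range(len(columns))]
    return pd.Series(cats, index=list(columns), name="category")
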
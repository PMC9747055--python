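"""Generator determinism, planted distributions and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from hcdn import synth
from hcdn.cca import fit_cca


def test_seed_determinism_bit_identical(demo_config):
    cfg = synth.SynthConfig(n_subjects=10, seed=123)
    a = synth.generate_cohort(cfg)
    b = synth.generate_cohort(cfg)
    pd.testing.assert_frame_equal(a, b)
    sa = synth.make_planted_structure(a, cfg)
    sb = synth.make_planted_structure(b, cfg)
    Xa, Ya = synth.generate_brain_volumes(a, sa, cfg)
    Xb, Yb = synth.generate_brain_volumes(b, sb, cfg)
    pd.testing.assert_frame_equal(Xa, Xb)
    pd.testing.assert_frame_equal(Ya, Yb)


def test_config_validation():
    with pytest.raises(ValueError):
        synth.SynthConfig(n_subjects=0)
    with pytest.raises(ValueError):
        synth.SynthConfig(planted_rhos=(0.4, 0.5, 0.3))  # not decreasing
    with pytest.raises(ValueError):
        synth.SynthConfig(
            genotype_freqs={g: (0.5 if g == "e3/3" else 0.2) for g in synth.GENOTYPES}
        )
    with pytest.raises(ValueError):
        synth.SynthConfig(k_planted=40, planted_rhos=tuple(np.linspace(0.9, 0.1, 40)),
                          q_hc=38)


def test_genotype_frequencies_converge():
    """Empirical e3/3 frequency within 3 binomial SDs at the study scale."""
    cfg = synth.SynthConfig(n_subjects=37291, seed=11)
    cohort = synth.generate_cohort(cfg)
    p = 0.593
    phat = (cohort["genotype"] == "e3/3").mean()
    sd = np.sqrt(p * (1 - p) / len(cohort))
    assert abs(phat - p) < 3 * sd


def test_family_history_odds_recovered_by_logistic_refit():
    """Planted female e4/4 odds ratio recovered within +-0.1 by refit."""
    cfg = synth.SynthConfig(n_subjects=200_000, seed=5, baseline_prevalence=0.20)
    cohort = synth.generate_cohort(cfg)
    sub = cohort[cohort["sex"] == "female"]
    y = sub["family_history"].to_numpy(dtype=float)
    # e4/4 indicator against the e3/3 reference group only
    keep = sub["genotype"].isin(["e4/4", "e3/3"])
    D = np.column_stack(
        [np.ones(keep.sum()), (sub.loc[keep, "genotype"] == "e4/4").to_numpy(float)]
    )
    fit = sm.Logit(y[keep.to_numpy()], D).fit(disp=0)
    or_hat = np.exp(fit.params[1])
    planted = cfg.family_history_odds[("e4/4", "female")] / cfg.family_history_odds[
        ("e3/3", "female")
    ]
    assert abs(or_hat - planted) < 0.1


def test_oracle_noiseless_rank1_is_one():
    cfg = synth.SynthConfig(
        n_subjects=500, k_planted=1, planted_rhos=(0.7,), noise_sd=0.0, seed=3
    )
    cohort = synth.generate_cohort(cfg)
    st = synth.make_planted_structure(cohort, cfg)
    rhos = synth.oracle_canonical_correlations(st, cfg)
    assert rhos == pytest.approx([1.0], abs=1e-10)


def test_oracle_equal_signal_noise_gives_half():
    """One latent with signal variance = noise variance on both sides: rho = 1/2.

    Hand computation: per region the covariance is a^2 s^2 + sigma^2 on the
    diagonal and the cross block is s^2 a b'; whitening reduces to the
    scalar fraction s^2 / (s^2 + sigma^2) = 0.5 when s = sigma.
    """
    cfg = synth.SynthConfig(
        n_subjects=100, k_planted=1, planted_rhos=(0.5,), noise_sd=1.0, seed=3
    )
    cohort = synth.generate_cohort(cfg)
    st = synth.make_planted_structure(cohort, cfg)
    assert st.mode_scales[0] == pytest.approx(1.0)  # s^2 = rho/(1-rho) = 1
    rhos = synth.oracle_canonical_correlations(st, cfg)
    assert rhos[0] == pytest.approx(0.5, abs=1e-12)


def test_oracle_matches_sample_cca_at_large_n():
    cfg = synth.SynthConfig(n_subjects=100_000, seed=21, confound_coef_scale=0.0)
    cohort = synth.generate_cohort(cfg)
    st = synth.make_planted_structure(cohort, cfg)
    X, Y = synth.generate_brain_volumes(cohort, st, cfg)
    oracle = synth.oracle_canonical_correlations(st, cfg)
    model = fit_cca(X, Y, k=3)
    # Fisher-z agreement within 3/sqrt(n)
    z = lambda r: np.arctanh(r)
    assert np.all(np.abs(z(model.rhos) - z(oracle)) < 3 / np.sqrt(cfg.n_subjects) + 0.01)


def test_phenotype_tables_shapes_and_effects(demo_world):
    cfg = demo_world["config"]
    pheno, risk = demo_world["phenotypes"], demo_world["risk"]
    assert pheno.shape == (cfg.n_subjects, cfg.n_phenotypes)
    assert risk.shape == (cfg.n_subjects, 63)
    assert {c.split("_")[0] for c in risk.columns} == {"social", "cardio", "personality"}


def test_phenotype_full_inventory_width():
    """Requesting the full curated inventory yields exactly 977 columns."""
    cfg = synth.SynthConfig(n_subjects=50, n_phenotypes=977, seed=1)
    cohort = synth.generate_cohort(cfg)
    st = synth.make_planted_structure(cohort, cfg)
    pheno, _ = synth.generate_phenotype_tables(cohort, st, cfg)
    assert pheno.shape[1] == 977


def test_sex_specific_phenotype_effect_only_in_target_sex():
    cfg = synth.SynthConfig(
        n_subjects=4000,
        seed=2,
        n_phenotypes=5,
        phenotype_effects={"pheno_0003": synth.PhenotypeEffect(mode=0, slope=2.0, sex="male")},
    )
    cohort = synth.generate_cohort(cfg)
    st = synth.make_planted_structure(cohort, cfg)
    pheno, _ = synth.generate_phenotype_tables(cohort, st, cfg)
    male = (cohort["sex"] == "male").to_numpy()
    r_m = np.corrcoef(pheno.loc[male, "pheno_0003"], st.latent_scores[male, 0])[0, 1]
    r_f = np.corrcoef(pheno.loc[~male, "pheno_0003"], st.latent_scores[~male, 0])[0, 1]
    assert r_m > 0.7
    assert abs(r_f) < 0.1


def test_orthonormal_loadings_and_latent_moments(demo_world):
    st = demo_world["structure"]
    np.testing.assert_allclose(st.A.T @ st.A, np.eye(st.A.shape[1]), atol=1e-10)
    np.testing.assert_allclose(st.B.T @ st.B, np.eye(st.B.shape[1]), atol=1e-10)
    Z = st.latent_scores
    assert np.all(np.abs(Z.mean(axis=0)) < 5 / np.sqrt(len(Z)))


def test_cohort_summary_reports_percentages(demo_world):
    summary = synth.cohort_summary(demo_world["cohort"])
    assert summary["n_subjects"] == demo_world["config"].n_subjects
    assert abs(sum(summary["genotype_percent"].values()) - 100.0) < 0.5
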
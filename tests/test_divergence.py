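"""Mode alignment, bootstrap difference distributions and hit detection."""

import numpy as np
import pandas as pd
import pytest

from hcdn import divergence, synth
from hcdn.cca import fit_cca
from hcdn.divergence import DifferenceDistribution
from conftest import make_small_volumes


@pytest.fixture(scope="module")
def small_model():
    X, Y = make_small_volumes(n=300, p=4, q=3, seed=2)
    return fit_cca(X, Y, k=3)


def _copy_model(m):
    import copy

    return copy.deepcopy(m)


def test_align_identity(small_model):
    out = divergence.align_to_reference(small_model, small_model)
    np.testing.assert_allclose(out.V, small_model.V, atol=1e-12)
    np.testing.assert_allclose(out.U, small_model.U, atol=1e-12)


def test_align_repairs_global_sign_flips(small_model):
    flipped = _copy_model(small_model)
    flipped.V = -flipped.V
    flipped.U = -flipped.U
    out = divergence.align_to_reference(flipped, small_model)
    np.testing.assert_allclose(out.V, small_model.V, atol=1e-12)
    np.testing.assert_allclose(out.U, small_model.U, atol=1e-12)


def test_align_restores_swapped_mode_order(small_model):
    swapped = _copy_model(small_model)
    perm = [1, 0, 2]
    swapped.V = swapped.V[:, perm]
    swapped.U = swapped.U[:, perm]
    swapped.rhos = swapped.rhos[perm]
    out = divergence.align_to_reference(swapped, small_model)
    np.testing.assert_allclose(out.rhos, small_model.rhos, atol=1e-12)
    np.testing.assert_allclose(out.V, small_model.V, atol=1e-12)


def test_align_dimension_mismatch(small_model):
    other = fit_cca(*make_small_volumes(n=100, p=5, q=3, seed=1), k=2)
    with pytest.raises(ValueError):
        divergence.align_to_reference(other, small_model)


def test_bootstrap_seed_determinism(small_model):
    X, Y = make_small_volumes(n=300, p=4, q=3, seed=2)
    history = np.arange(300) % 2
    d1 = divergence.bootstrap_group_difference(X, Y, history, small_model, B=3, seed=42)
    d2 = divergence.bootstrap_group_difference(X, Y, history, small_model, B=3, seed=42)
    np.testing.assert_array_equal(d1.dn, d2.dn)
    np.testing.assert_array_equal(d1.hc, d2.hc)


def test_null_differences_centered_at_zero():
    """Identical generative process in both groups: exchangeable labels.

    Individual entries carry the split's sampling noise, but across entries
    the standardized bootstrap centers average out to zero."""
    X, Y = make_small_volumes(n=600, p=4, q=3, seed=8)
    ref = fit_cca(X, Y, k=3)
    rng = np.random.default_rng(0)
    grand = []
    for rep in range(8):
        history = rng.permutation(np.arange(600) % 2)
        dist = divergence.bootstrap_group_difference(
            X, Y, history, ref, B=30, seed=rep
        )
        means = np.concatenate(
            [dist.dn.mean(axis=0).ravel(), dist.hc.mean(axis=0).ravel()]
        )
        spread = np.concatenate(
            [dist.dn.std(axis=0).ravel(), dist.hc.std(axis=0).ravel()]
        )
        grand.append(means / spread)
    grand = np.array(grand)
    # any one split carries shared sampling noise; across random splits the
    # standardized centers average out
    assert abs(grand.mean()) < 0.4
    assert np.all(np.abs(grand) < 5.0)


def test_detect_hits_degenerate_and_symmetric_cases():
    B = 20
    dn = np.zeros((B, 2, 1))
    dn[:, 0, 0] = 0.3  # constant positive difference
    dn[:, 1, 0] = np.linspace(-1, 1, B)  # symmetric spanning zero
    hc = np.zeros((B, 1, 1))
    dist = DifferenceDistribution(
        dn=dn, hc=hc, dn_regions=["dn_001", "dn_002"], hc_regions=["hc_001"]
    )
    hits = divergence.detect_hits(dist)
    table = hits.set_index(["atlas", "region"])
    assert bool(table.loc[("DN", "dn_001"), "hit"]) is True
    assert table.loc[("DN", "dn_001"), "lo"] == pytest.approx(0.3)
    assert bool(table.loc[("DN", "dn_002"), "hit"]) is False
    # zero-difference region: interval [0, 0] contains 0
    assert bool(table.loc[("HC", "hc_001"), "hit"]) is False


def test_detect_hits_empty_distribution_errors():
    dist = DifferenceDistribution(
        dn=np.empty((0, 1, 1)), hc=np.empty((0, 1, 1)),
        dn_regions=["dn_001"], hc_regions=["hc_001"],
    )
    with pytest.raises(ValueError):
        divergence.detect_hits(dist)


def test_hit_table_invariant_under_reference_negation(small_model):
    X, Y = make_small_volumes(n=300, p=4, q=3, seed=2)
    history = np.arange(300) % 2
    ref_neg = _copy_model(small_model)
    ref_neg.V = -ref_neg.V
    ref_neg.U = -ref_neg.U
    h1 = divergence.detect_hits(
        divergence.bootstrap_group_difference(X, Y, history, small_model, B=20, seed=3)
    )
    h2 = divergence.detect_hits(
        divergence.bootstrap_group_difference(X, Y, history, ref_neg, B=20, seed=3)
    )
    pd.testing.assert_series_equal(h1["hit"], h2["hit"])


def test_planted_hits_shift_difference_distribution():
    """Loadings perturbed on 5 HC regions of mode 1 shift those entries."""
    hit_idx = [0, 5, 10, 20, 30]
    cfg = synth.SynthConfig(
        n_subjects=5000,
        seed=33,
        confound_coef_scale=0.0,
        hit_regions={0: {"hc": hit_idx}},
        hit_delta=0.8,
    )
    cohort = synth.generate_cohort(cfg)
    st = synth.make_planted_structure(cohort, cfg)
    X, Y = synth.generate_brain_volumes(cohort, st, cfg)
    ref = fit_cca(X, Y, k=3)
    dist = divergence.bootstrap_group_difference(
        X, Y, cohort["family_history"].to_numpy(), ref, B=60, seed=4
    )
    hits = divergence.detect_hits(dist)
    planted_regions = [f"hc_{i + 1:03d}" for i in hit_idx]
    hc1 = hits[(hits["atlas"] == "HC") & (hits["mode"] == 1)].set_index("region")
    sensitivity = hc1.loc[planted_regions, "hit"].mean()
    background = hits[
        ~(hits["region"].isin(planted_regions) & (hits["atlas"] == "HC") & (hits["mode"] == 1))
    ]["hit"].mean()
    assert sensitivity >= 0.8
    assert background < 0.4


def test_null_exclusion_rate_calibrated_in_asymptotic_regime():
    """With a small atlas (group n >> regions) the 10/90% interval excludes
    zero for ~20% of null entries, averaged over independent cohorts."""
    rates = []
    for s in range(8):
        cfg = synth.SynthConfig(
            n_subjects=5000, seed=300 + s, p_dn=8, q_hc=6, k_planted=1,
            planted_rhos=(0.5,), confound_coef_scale=0.0,
        )
        cohort = synth.generate_cohort(cfg)
        st = synth.make_planted_structure(cohort, cfg)
        X, Y = synth.generate_brain_volumes(cohort, st, cfg)
        ref = fit_cca(X, Y, k=1)
        dist = divergence.bootstrap_group_difference(
            X, Y, cohort["family_history"].to_numpy(), ref, B=60, seed=s
        )
        rates.append(divergence.detect_hits(dist)["hit"].mean())
    # 8 worlds x 14 entries; hit indicators within a world are correlated,
    # so allow a generous Monte Carlo band around the nominal 0.20
    assert 0.10 < np.mean(rates) < 0.30
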
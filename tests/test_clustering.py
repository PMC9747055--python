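"""Masked Spearman correlation, Ward linkage (with brute-force oracle) and
cross-model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy

from hcdn import clustering, synth
from hcdn.deconfound import standardize_columns


def _frames(n=120, n_var=4, n_risk=5, seed=0):
    rng = np.random.default_rng(seed)
    variates = pd.DataFrame(
        rng.standard_normal((n, n_var)), columns=[f"v{j}" for j in range(n_var)]
    )
    risk = pd.DataFrame(
        rng.standard_normal((n, n_risk)), columns=[f"r{j}" for j in range(n_risk)]
    )
    return variates, risk


def test_all_ones_indicator_reduces_to_plain_spearman():
    variates, risk = _frames()
    out = clustering.genotype_masked_spearman(variates, np.ones(len(variates)), risk)
    expected, _ = stats.spearmanr(risk, variates)
    expected = expected[: risk.shape[1], risk.shape[1]:]
    np.testing.assert_allclose(out.to_numpy(), expected, atol=1e-10)


def test_monotone_transform_of_masked_variate_gives_unit_coefficient():
    variates, risk = _frames()
    ind = (np.arange(len(variates)) % 2).astype(float)
    masked = variates["v0"].to_numpy() * ind
    risk = risk.copy()
    risk["r0"] = np.exp(masked)  # strictly monotone transform
    out = clustering.genotype_masked_spearman(variates, ind, risk)
    assert out.loc["r0", "v0"] == pytest.approx(1.0, abs=1e-12)


def test_cross_matrix_has_3150_coefficients():
    rng = np.random.default_rng(3)
    variates = pd.DataFrame(rng.standard_normal((80, 50)))
    variates.columns = [f"v{j}" for j in range(50)]
    risk = pd.DataFrame(rng.standard_normal((80, 63)), columns=[f"r{j}" for j in range(63)])
    ind = rng.integers(0, 2, 80).astype(float)
    out = clustering.genotype_masked_spearman(variates, ind, risk)
    assert out.shape == (63, 50)
    assert out.size == 3150


def test_all_zero_indicator_errors():
    variates, risk = _frames()
    with pytest.raises(ValueError):
        clustering.genotype_masked_spearman(variates, np.zeros(len(variates)), risk)


def test_carriers_only_flag_subsets():
    variates, risk = _frames(n=200)
    ind = (np.arange(200) < 100).astype(float)
    sub = clustering.genotype_masked_spearman(variates, ind, risk, carriers_only=True)
    expected, _ = stats.spearmanr(risk.iloc[:100], variates.iloc[:100])
    expected = expected[: risk.shape[1], risk.shape[1]:]
    np.testing.assert_allclose(sub.to_numpy(), expected, atol=1e-10)


def test_coincident_rows_merge_first_at_zero_distance():
    m = pd.DataFrame([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0]], index=["a", "b", "c"])
    tree = clustering.ward_cluster(m)
    assert {int(tree[0, 0]), int(tree[0, 1])} == {1, 2}
    assert tree[0, 2] == pytest.approx(0.0, abs=1e-12)


def _ward_oracle(X):
    """Greedy Ward merges computed directly from cluster members: at each
    step merge the pair with minimal increase in within-cluster sum of
    squares, Delta = |A||B|/(|A|+|B|) * ||mean_A - mean_B||^2."""
    clusters = {i: [i] for i in range(len(X))}
    merges = []
    next_id = len(X)
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                ma = X[clusters[a]].mean(axis=0)
                mb = X[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                delta = na * nb / (na + nb) * np.sum((ma - mb) ** 2)
                if best is None or delta < best[0]:
                    best = (delta, a, b)
        delta, a, b = best
        merges.append((a, b, np.sqrt(2 * delta), len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def test_ward_matches_brute_force_oracle_on_random_instances():
    rng = np.random.default_rng(11)
    for _ in range(50):
        X = rng.standard_normal((4, 2))
        tree = clustering.ward_cluster(pd.DataFrame(X))
        oracle = _ward_oracle(X)
        for step, (a, b, dist, size) in enumerate(oracle):
            assert {int(tree[step, 0]), int(tree[step, 1])} == {a, b}
            assert tree[step, 2] == pytest.approx(dist, abs=1e-10)
            assert int(tree[step, 3]) == size


def test_ward_heights_monotone(demo_world):
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.standard_normal((30, 8)))
    tree = clustering.ward_cluster(X)
    assert np.all(np.diff(tree[:, 2]) >= -1e-12)


def test_planted_three_block_structure_recovered():
    """Low-noise risk blocks linked to distinct latent modes cluster into
    their blocks at the 3-level cut."""
    cfg = synth.SynthConfig(
        n_subjects=3000, seed=17, risk_block_strength=0.9, confound_coef_scale=0.0
    )
    cohort = synth.generate_cohort(cfg)
    st = synth.make_planted_structure(cohort, cfg)
    _, risk = synth.generate_phenotype_tables(cohort, st, cfg)
    variates = pd.DataFrame(st.latent_scores, columns=["m1", "m2", "m3"])
    cross = clustering.genotype_masked_spearman(
        standardize_columns(variates), np.ones(len(cohort)), standardize_columns(risk)
    )
    tree = clustering.ward_cluster(cross)
    truth = pd.Series([c.split("_")[0] for c in risk.columns])
    from sklearn.metrics import adjusted_rand_score

    # three blocks emerge after two divisions from the root
    labels3 = clustering.cut_tree_levels(tree, levels=2)
    assert adjusted_rand_score(truth, labels3) == pytest.approx(1.0)
    # at the deeper 3-level cut every cluster stays within one true block
    labels4 = clustering.cut_tree_levels(tree, levels=3)
    for lab in np.unique(labels4):
        assert truth[labels4 == lab].nunique() == 1


def test_cut_levels_returns_at_most_four_clusters():
    rng = np.random.default_rng(9)
    tree = clustering.ward_cluster(pd.DataFrame(rng.standard_normal((20, 3))))
    labels = clustering.cut_tree_levels(tree, levels=3)
    assert 2 <= len(np.unique(labels)) <= 4


def test_compare_cluster_models_identity_and_scale():
    rng = np.random.default_rng(13)
    tree = clustering.ward_cluster(pd.DataFrame(rng.standard_normal((10, 4))))
    assert clustering.compare_cluster_models(tree, tree) == pytest.approx(1.0)
    doubled = tree.copy()
    doubled[:, 2] *= 2
    assert clustering.compare_cluster_models(tree, doubled) == pytest.approx(1.0)
    short = clustering.ward_cluster(pd.DataFrame(rng.standard_normal((5, 4))))
    with pytest.raises(ValueError):
        clustering.compare_cluster_models(tree, short)


def test_independent_matrices_comparison_below_identity():
    """Merge-height sequences are monotone by construction, so even
    independent trees correlate strongly; the comparison is informative
    only near the top of the scale, with identical trees pinned at 1."""
    rng = np.random.default_rng(21)
    rs = []
    for _ in range(30):
        a = clustering.ward_cluster(pd.DataFrame(rng.standard_normal((12, 5))))
        b = clustering.ward_cluster(pd.DataFrame(rng.standard_normal((12, 5))))
        rs.append(clustering.compare_cluster_models(a, b))
    assert np.mean(rs) < 0.995
    assert np.std(rs) > 1e-3
    assert max(rs) < 1.0


def test_spearman_equals_pearson_on_ranks():
    variates, risk = _frames(n=150, seed=8)
    ind = np.ones(150)
    ours = clustering.genotype_masked_spearman(variates, ind, risk)
    ranked_v = variates.rank()
    ranked_r = risk.rank()
    for rc in risk.columns:
        for vc in variates.columns:
            r = stats.pearsonr(ranked_r[rc], ranked_v[vc])[0]
            assert ours.loc[rc, vc] == pytest.approx(r, abs=1e-10)


def test_newick_export_round_trips_leaf_count():
    rng = np.random.default_rng(4)
    names = [f"risk_{i}" for i in range(6)]
    tree = clustering.ward_cluster(pd.DataFrame(rng.standard_normal((6, 3)), index=names))
    nwk = clustering.linkage_to_newick(tree, names)
    assert nwk.endswith(";")
    for nm in names:
        assert nm in nwk
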
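import itertools

import numpy as np
import pytest
from scipy import stats as sps

from rootshape.correspondence import PointDistributionModel, icosphere_sampling
from rootshape.shape_stats import (
    compare_groups,
    fdr_bh,
    hotelling_t2,
    hotelling_t2_map,
    permutation_test,
    significance_maps,
)


def _brute_force_t2(a, b):
    """Independent oracle: explicit matrix arithmetic, no shared code path."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    d = a.mean(0) - b.mean(0)
    Sa = sum(np.outer(x - a.mean(0), x - a.mean(0)) for x in a)
    Sb = sum(np.outer(x - b.mean(0), x - b.mean(0)) for x in b)
    S = (Sa + Sb) / (na + nb - 2)
    return float(na * nb / (na + nb) * d @ np.linalg.inv(S) @ d)


def test_hotelling_matches_brute_force_toy():
    # 4 subjects, 2 points, coordinates chosen by hand
    groupA = np.array(
        [
            [[1.0, 2.0, 0.5], [0.1, -0.3, 1.2]],
            [[1.2, 1.8, 0.7], [0.2, -0.1, 1.0]],
            [[0.9, 2.2, 0.4], [-0.1, -0.4, 1.3]],
        ]
    )
    groupB = np.array(
        [
            [[2.0, 1.0, 0.0], [0.5, 0.3, 0.8]],
            [[2.1, 0.8, 0.2], [0.6, 0.2, 0.9]],
            [[1.8, 1.2, -0.1], [0.4, 0.5, 0.7]],
        ]
    )
    for k in range(2):
        expected = _brute_force_t2(groupA[:, k], groupB[:, k])
        assert hotelling_t2(groupA, groupB, point_index=k) == pytest.approx(
            expected, abs=1e-10
        )
        assert hotelling_t2_map(groupA, groupB)[k] == pytest.approx(expected, abs=1e-10)


def test_identical_groups_give_zero(rng):
    X = rng.normal(size=(5, 7, 3))
    t2 = hotelling_t2_map(X, X.copy())
    np.testing.assert_allclose(t2, 0.0, atol=1e-9)


def test_group_size_validation(rng):
    X = rng.normal(size=(5, 4, 3))
    with pytest.raises(ValueError, match="at least 2"):
        hotelling_t2(X[:1], X[1:])


def test_null_t2_follows_f_distribution(rng):
    # 2000 independent replicates vectorized as 2000 'points'
    nA = nB = 10
    XA = rng.normal(size=(nA, 2000, 3))
    XB = rng.normal(size=(nB, 2000, 3))
    t2 = hotelling_t2_map(XA, XB)
    n = nA + nB
    f = t2 * (n - 3 - 1) / (3 * (n - 2))
    _, p = sps.kstest(f, sps.f(3, n - 4).cdf)
    assert p > 0.01


def test_exhaustive_permutation_small_groups(rng):
    XA = rng.normal(size=(3, 5, 3))
    XB = rng.normal(size=(3, 5, 3)) + 0.5
    p, t2_obs, exact = permutation_test(XA, XB, n_perm=999, seed=0)
    assert exact
    # C(6,3) = 20 relabelings; p-values are multiples of 1/20
    np.testing.assert_allclose(np.round(p * 20), p * 20, atol=1e-12)
    assert p.min() >= 1 / 20 - 1e-12

    # independent enumeration oracle at one point
    X = np.concatenate([XA, XB])[:, 2, :]
    obs = _brute_force_t2(X[:3], X[3:])
    count = 0
    for combo in itertools.combinations(range(6), 3):
        rest = [i for i in range(6) if i not in combo]
        if _brute_force_t2(X[list(combo)], X[rest]) >= obs - 1e-9 * (1.0 + abs(obs)):
            count += 1
    assert p[2] == pytest.approx(count / 20, abs=1e-12)


def test_monte_carlo_matches_exhaustive(rng):
    XA = rng.normal(size=(8, 4, 3))
    XB = rng.normal(size=(8, 4, 3)) + 0.4
    p_ex, _, exact = permutation_test(XA, XB, n_perm=13000, seed=0)
    assert exact  # C(16,8) = 12870 <= 13000
    p_mc, _, exact_mc = permutation_test(XA, XB, n_perm=10000, seed=1)
    assert not exact_mc
    assert np.abs(p_mc - p_ex).max() < 2 / np.sqrt(10000) + 0.05


def test_permutation_determinism(rng):
    XA = rng.normal(size=(8, 6, 3))
    XB = rng.normal(size=(8, 6, 3))
    p1, _, _ = permutation_test(XA, XB, n_perm=200, seed=42)
    p2, _, _ = permutation_test(XA, XB, n_perm=200, seed=42)
    p3, _, _ = permutation_test(XA, XB, n_perm=200, seed=43)
    np.testing.assert_array_equal(p1, p2)
    assert np.any(p1 != p3)


def test_permutation_count_floor(rng):
    X = rng.normal(size=(10, 3, 3))
    with pytest.raises(ValueError, match="99"):
        permutation_test(X[:5], X[5:], n_perm=10)


def test_bh_hand_computation():
    p_adj, reject = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
    # hand BH: sorted p * m / rank = .04, .04, .04, .04 -> all rejected
    np.testing.assert_allclose(p_adj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)
    assert reject.all()


def test_bh_degenerate_cases():
    p_adj, reject = fdr_bh(np.ones(10))
    assert not reject.any()
    np.testing.assert_array_equal(p_adj, 1.0)
    p_adj, reject = fdr_bh(np.array([0.03]))
    assert p_adj[0] == pytest.approx(0.03)
    assert reject[0]
    with pytest.raises(ValueError):
        fdr_bh(np.array([1.5]))


def test_adjusted_p_dominates_raw(rng):
    p = rng.uniform(size=200)
    p_adj, _ = fdr_bh(p)
    assert np.all(p_adj >= p - 1e-12)


def test_significance_maps_channels(template_pdm, rng):
    XA = np.stack([template_pdm.points + rng.normal(0, 0.05, (1002, 3)) for _ in range(4)])
    XB = np.stack([template_pdm.points + rng.normal(0, 0.05, (1002, 3)) for _ in range(4)])
    res = compare_groups(XA, XB, n_perm=99, seed=5)
    maps = significance_maps(res, template_pdm)
    for kind in ("raw", "fdr"):
        mesh = maps[kind]
        assert set(mesh.point_data) >= {"t2", "p_raw", "p_fdr", "sig_mask", "rgb"}
        assert set(np.unique(mesh.point_data["sig_mask"])) <= {0, 1}
    if not res.mask.any():
        # no significant points: uniform neutral color, channels still present
        assert len(np.unique(maps["fdr"].point_data["rgb"], axis=0)) == 1
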
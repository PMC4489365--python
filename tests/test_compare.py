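"""Z-scores, change classification, and difference maps."""

import itertools

import numpy as np
import pytest

from qsfr import classify_changes, delta_cc, flexibility_vs_mobility, zscore
from qsfr.compare import hbond_count_difference
from qsfr.constraint_network import HBondPropensityTable


def _uniform(n):
    return np.full(n, 1.0 / n)


def test_zscore_direct_evaluation():
    """x̄_mut = 1, x̄_wt = 0, sigma = 1 on both sides, n = 10 -> Z = 1/sqrt(0.2)."""
    rng = np.random.default_rng(0)
    base = rng.normal(size=10)
    base = (base - base.mean()) / base.std()  # mean 0, sd 1 exactly
    wt = base[:, None]
    mut = (base + 1.0)[:, None]
    prof = zscore(mut, wt, _uniform(10), _uniform(10), n=10)
    assert prof.z[0] == pytest.approx(1.0 / np.sqrt(0.2), rel=1e-12)


def test_zscore_antisymmetric_and_zero_for_equal_means():
    rng = np.random.default_rng(1)
    a = rng.normal(size=(10, 5))
    b = rng.normal(size=(10, 5))
    w = _uniform(10)
    z_ab = zscore(a, b, w, w).z
    z_ba = zscore(b, a, w, w).z
    np.testing.assert_allclose(z_ab, -z_ba)
    same = zscore(a, a, w, w)
    np.testing.assert_allclose(same.z, 0.0)


def test_zscore_scale_equivariance():
    rng = np.random.default_rng(2)
    a = rng.normal(size=(10, 4))
    b = rng.normal(size=(10, 4))
    w = _uniform(10)
    z1 = zscore(a, b, w, w).z
    z2 = zscore(3.7 * a + 2.0, 3.7 * b + 2.0, w, w).z
    np.testing.assert_allclose(z1, z2, rtol=1e-9)


def test_zscore_saturation_flagged():
    a = np.ones((4, 2))
    b = np.zeros((4, 2))
    b[:, 1] = 1.0  # equal means, zero sd
    prof = zscore(a, b, _uniform(4), _uniform(4), n=4)
    assert np.isinf(prof.z[0]) and prof.saturated[0]
    assert prof.z[1] == 0.0 and not prof.saturated[1]


def test_classification_thresholds_and_partition():
    z = np.array([0.0, 2.33, 2.5, 3.5, -2.5, -4.0, -2.33])
    classes, counts = classify_changes(z)
    assert classes.tolist() == [
        "none", "none", "moderate_flexibility", "large_flexibility",
        "moderate_rigidity", "large_rigidity", "none",
    ]
    assert sum(counts["all"].values()) == z.size  # classes partition the profile


def test_classification_region_masks():
    z = np.array([3.0, 0.0, -4.0, 0.0])
    mask = np.array([True, True, False, False])
    _, counts = classify_changes(z, region_masks={"cdr": mask})
    assert counts["cdr"]["moderate_flexibility"] == 1
    assert counts["cdr"]["large_rigidity"] == 0
    assert counts["all"]["large_rigidity"] == 1


def test_hbond_count_difference_rules():
    a = HBondPropensityTable(pair={}, residue={1: 1.0, 2: 0.5}, n_frames=10)
    b = HBondPropensityTable(pair={}, residue={1: 2.0, 2: 0.5, 3: 1.0}, n_frames=10)
    diff, summary = hbond_count_difference(a, b)
    assert diff[1] == 1.0 and diff[2] == 0.0 and diff[3] == 1.0
    assert summary["gained_ge_1"] == 2 and summary["lost_ge_1"] == 0
    rev, rev_summary = hbond_count_difference(b, a)
    np.testing.assert_allclose(rev.to_numpy(), -diff.to_numpy())
    assert rev_summary["lost_ge_2"] == summary["gained_ge_2"]


def test_delta_cc_matches_scalar_path():
    rng = np.random.default_rng(3)
    reps_a = [rng.normal(size=(3, 3)) for _ in range(5)]
    reps_b = [rng.normal(size=(3, 3)) for _ in range(5)]
    reps_a = [(m + m.T) / 2 for m in reps_a]
    reps_b = [(m + m.T) / 2 for m in reps_b]
    w = _uniform(5)
    dz = delta_cc(reps_a, reps_b, w, w, n=5)
    np.testing.assert_allclose(dz, dz.T, atol=1e-12)
    # one pixel cross-checked against the scalar Z-score
    va = np.array([[m[0, 2]] for m in reps_a])
    vb = np.array([[m[0, 2]] for m in reps_b])
    assert dz[0, 2] == pytest.approx(zscore(vb, va, w, w, n=5).z[0])
    same = delta_cc(reps_a, reps_a, w, w, n=5)
    np.testing.assert_allclose(same, 0.0)


def test_mobility_pairing_degenerate_and_perfect_cases():
    z = np.array([1.0, 2.0, 3.0, 4.0])
    table, rho, p = flexibility_vs_mobility(z, np.zeros(4), np.zeros(4))
    assert np.isnan(rho) and np.isnan(p)
    anti = np.array([4.0, 3.0, 2.0, 1.0])
    _, rho, _ = flexibility_vs_mobility(z, np.zeros(4), anti, n_permutations=200)
    assert rho == pytest.approx(-1.0)


def test_mobility_permutation_p_matches_exhaustive_oracle():
    rng = np.random.default_rng(4)
    z = rng.normal(size=6)
    d = rng.normal(size=6)
    _, rho, p = flexibility_vs_mobility(z, np.zeros(6), d, n_permutations=10_000, seed=1)

    from scipy.stats import rankdata

    def spearman(x, y):
        rx, ry = rankdata(x), rankdata(y)
        rx -= rx.mean(); ry -= ry.mean()
        return rx @ ry / np.sqrt((rx @ rx) * (ry @ ry))

    exact = np.mean([
        abs(spearman(z, np.array(perm))) >= abs(rho) - 1e-12
        for perm in itertools.permutations(d)
    ])
    # binomial error of the sampled estimate around the exact enumeration
    se = np.sqrt(exact * (1 - exact) / 10_000)
    assert p == pytest.approx(exact, abs=4 * se + 2e-4)
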
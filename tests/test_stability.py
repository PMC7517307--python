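"""Noise injection, the Kuncheva index and the stability protocol."""

import numpy as np
import pytest

from ffsrrd import (
    SyntheticSpec,
    generate_synthetic,
    inject_noise,
    kuncheva_index,
    kuncheva_stability,
    stability_experiment,
    stability_profile,
    table1_fixture,
)
from conftest import random_dataset


class TestInjectNoise:
    def test_exact_cell_count_per_feature(self):
        rng = np.random.default_rng(0)
        ds = random_dataset(rng, m=100, n=3)
        noisy = inject_noise(ds, fraction=0.10, seed=1)
        changed = (noisy.X != ds.X).sum(axis=0)
        np.testing.assert_array_equal(changed, [10, 10, 10])

    def test_constant_feature_untouched(self):
        from ffsrrd import Dataset

        X = np.column_stack([np.full(20, 2.0), np.arange(20.0)])
        y = np.tile([0, 1], 10)
        ds = Dataset(X, y, ("const", "ramp"), ("continuous", "continuous"))
        noisy = inject_noise(ds, fraction=0.5, seed=2)
        np.testing.assert_array_equal(noisy.X[:, 0], ds.X[:, 0])
        assert (noisy.X[:, 1] != ds.X[:, 1]).any()

    def test_nominal_feature_untouched(self):
        from ffsrrd import Dataset

        X = np.column_stack([np.tile([0.0, 1.0, 2.0], 5), np.arange(15.0)])
        y = np.tile([0, 1, 0], 5)
        ds = Dataset(X, y, ("cat", "num"), ("nominal", "continuous"))
        noisy = inject_noise(ds, fraction=0.5, seed=3)
        np.testing.assert_array_equal(noisy.X[:, 0], ds.X[:, 0])

    def test_deterministic_per_seed_and_original_untouched(self):
        rng = np.random.default_rng(5)
        ds = random_dataset(rng, m=50, n=2)
        before = ds.X.copy()
        a = inject_noise(ds, 0.1, seed=7)
        b = inject_noise(ds, 0.1, seed=7)
        c = inject_noise(ds, 0.1, seed=8)
        np.testing.assert_array_equal(a.X, b.X)
        assert (a.X != c.X).any()
        np.testing.assert_array_equal(ds.X, before)

    def test_scaled_mode_perturbs_every_cell(self):
        rng = np.random.default_rng(6)
        ds = random_dataset(rng, m=30, n=2)
        noisy = inject_noise(ds, 0.1, seed=9, mode="scaled")
        assert (noisy.X != ds.X).all()
        # perturbation magnitude is a tenth of the feature SD on average
        sd = ds.X.std(axis=0, ddof=1)
        assert np.abs(noisy.X - ds.X).mean() < 0.5 * sd.mean()

    def test_invalid_fraction_rejected(self):
        rng = np.random.default_rng(7)
        ds = random_dataset(rng, m=10, n=2)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                inject_noise(ds, bad, seed=0)


class TestKunchevaIndex:
    def test_identical_subsets_score_one(self):
        assert kuncheva_index({1, 2, 3}, {1, 2, 3}, 10) == pytest.approx(1.0)

    def test_disjoint_subsets_closed_form(self):
        # w=0: index = -r/(n-r) = -9/21 for n=10, r=3
        assert kuncheva_index({0, 1, 2}, {3, 4, 5}, 10) == pytest.approx(-9 / 21)

    def test_symmetry_and_upper_bound(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(5, 20))
            r = int(rng.integers(1, n))
            a = set(rng.choice(n, r, replace=False).tolist())
            b = set(rng.choice(n, r, replace=False).tolist())
            k = kuncheva_index(a, b, n)
            assert k == kuncheva_index(b, a, n)
            assert k <= 1.0 + 1e-12

    def test_random_subsets_are_chance_corrected(self):
        """Mean index over 10,000 random pairs is ~0 (the defining property)."""
        rng = np.random.default_rng(12)
        n, r = 12, 5
        vals = [
            kuncheva_index(
                set(rng.choice(n, r, replace=False).tolist()),
                set(rng.choice(n, r, replace=False).tolist()),
                n,
            )
            for _ in range(10_000)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            kuncheva_index(set(), set(), 5)
        with pytest.raises(ValueError):
            kuncheva_index({0, 1, 2}, {0, 1, 2}, 3)
        with pytest.raises(ValueError):
            kuncheva_index({0, 1}, {0}, 5)


class TestKunchevaStability:
    def test_identical_sequences_score_one(self):
        assert kuncheva_stability([{0, 1}] * 5, 6) == pytest.approx(1.0)

    def test_two_sequences_equal_single_index(self):
        a, b = {0, 1, 2}, {1, 2, 3}
        assert kuncheva_stability([a, b], 8) == pytest.approx(kuncheva_index(a, b, 8))

    def test_three_sequences_average_pairwise(self):
        subs = [{0, 1}, {1, 2}, {0, 2}]
        pair = [
            kuncheva_index(subs[i], subs[j], 5)
            for i in range(2)
            for j in range(i + 1, 3)
        ]
        assert kuncheva_stability(subs, 5) == pytest.approx(np.mean(pair))

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            kuncheva_stability([{0, 1}], 5)


class TestStabilityExperiment:
    def test_fixed_selector_is_perfectly_stable(self):
        rng = np.random.default_rng(20)
        ds = random_dataset(rng, m=40, n=6)
        report = stability_experiment(
            ds, selector=lambda d: list(range(d.n)), p=10, fraction=0.1, seed=0
        )
        assert report.stability == pytest.approx(1.0)
        np.testing.assert_allclose(report.pairwise, 1.0)
        np.testing.assert_allclose(np.diag(report.pairwise), 1.0)

    def test_zero_noise_gives_stability_one_for_deterministic_selector(self):
        from ffsrrd import ffs_rrd

        rng = np.random.default_rng(21)
        ds = random_dataset(rng, m=30, n=5)
        report = stability_experiment(
            ds, selector=lambda d: ffs_rrd(d).combined.order, p=4, fraction=0.0,
            seed=0,
        )
        assert report.stability == pytest.approx(1.0)

    def test_random_selector_near_zero(self):
        """Null distribution: |mean stability| < 0.1 over 50 master seeds."""
        rng_outer = np.random.default_rng(22)
        n, r, p = 10, 5, 10
        ds = random_dataset(rng_outer, m=20, n=n)
        vals = []
        for master in range(50):
            state = {"rng": np.random.default_rng(master)}

            def rand_selector(d, _state=state):
                return _state["rng"].permutation(d.n)[:r].tolist()

            vals.append(
                stability_experiment(
                    ds, selector=rand_selector, p=p, fraction=0.1, r=r,
                    seed=master,
                ).stability
            )
        assert abs(np.mean(vals)) < 0.1

    def test_ffs_rrd_beats_random_null_on_synthetic_data(self):
        from ffsrrd import ffs_rrd

        ds, _ = generate_synthetic(SyntheticSpec(m=100, seed=0))
        real = stability_experiment(
            ds, selector=lambda d: ffs_rrd(d).combined.order, p=6, fraction=0.1,
            seed=0,
        )
        rng = np.random.default_rng(99)
        null = stability_experiment(
            ds,
            selector=lambda d: rng.permutation(d.n)[: real.n // 2].tolist(),
            p=6,
            fraction=0.1,
            seed=0,
        )
        assert real.stability > null.stability

    def test_reproducible_per_master_seed(self):
        ds, _ = generate_synthetic(SyntheticSpec(m=60, seed=1))
        from ffsrrd import ffs_rrd

        sel = lambda d: ffs_rrd(d).combined.order
        a = stability_experiment(ds, selector=sel, p=4, seed=5)
        b = stability_experiment(ds, selector=sel, p=4, seed=5)
        assert a.sequences == b.sequences
        assert a.stability == b.stability


def test_stability_profile_averages_first_half_thresholds():
    rng = np.random.default_rng(30)
    ds = random_dataset(rng, m=30, n=6)
    sel = lambda d: list(range(d.n))
    # a fixed selector is perfectly stable at every threshold, so the average is 1
    assert stability_profile(ds, selector=sel, p=3, seed=0) == pytest.approx(1.0)
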
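"""VAF, scree selection, cross-validation, and source alignment."""

import numpy as np
import pytest

from anechoid import VafCurve, align_sources, cross_validate, scree_select, vaf, vaf_sweep
from anechoid.simulate import ScenarioConfig, SourceSpec, make_mixture_dataset
from tests.conftest import small_mixture

FAST = {"n_restarts": 5, "seed": 21}


def one_source_dataset(seed=0, noise=0.0, n_trials=5):
    cfg = ScenarioConfig(
        source_specs=[SourceSpec("discrete", {"center": 0.5, "width": 0.08})],
        weight_pattern=np.array([[1.0], [0.6], [1.4]]),
        delay_mean=np.array([[0.0], [0.1], [-0.05]]),
        delay_sd=np.full((3, 1), 0.01),
        n_trials=n_trials, n_samples=128, sample_rate=120.0,
        noise_sigma=noise, seed=seed,
    )
    return make_mixture_dataset(cfg)


class TestVaf:
    def test_perfect_reconstruction_is_100(self, rng):
        x = rng.normal(size=(4, 30))
        assert vaf(x, x) == pytest.approx(100.0)

    def test_row_means_reconstruction_is_0(self, rng):
        x = rng.normal(size=(4, 30))
        xbar = np.repeat(x.mean(axis=1, keepdims=True), 30, axis=1)
        assert vaf(x, xbar) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_two_by_three(self):
        x = np.array([[1.0, 2.0, 3.0], [2.0, 0.0, 4.0]])
        x_rec = np.array([[1.0, 2.0, 2.0], [2.0, 1.0, 3.0]])
        # ||X - Xrec||^2 = 0+0+1 + 0+1+1 = 3; row means (2, 2):
        # ||X - Xbar||^2 = 1+0+1 + 0+4+4 = 10  ->  100 * (1 - 3/10) = 70
        assert vaf(x, x_rec) == pytest.approx(70.0)

    def test_monotone_in_reconstruction_error(self, rng):
        x = rng.normal(size=(3, 40))
        noise = rng.normal(size=x.shape)
        vals = [vaf(x, x + a * noise) for a in (0.0, 0.1, 0.3)]
        assert vals[0] > vals[1] > vals[2]

    def test_constant_rows_rejected(self):
        with pytest.raises(ValueError):
            vaf(np.ones((2, 5)), np.ones((2, 5)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vaf(np.ones((2, 5)), np.ones((2, 6)))


class TestVafSweep:
    def test_single_source_data_saturates_at_one(self):
        ts, _ = one_source_dataset(seed=1)
        curve = vaf_sweep(ts, range(1, 3), FAST)
        assert curve.vaf[0] >= 99.9

    def test_default_range_is_one_to_five(self):
        import inspect

        sig = inspect.signature(vaf_sweep)
        assert list(sig.parameters["n_range"].default) == [1, 2, 3, 4, 5]

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            VafCurve([1, 1, 2], [10.0, 20.0, 30.0])
        with pytest.raises(ValueError):
            VafCurve([1, 2], [10.0])


class TestScreeSelect:
    def test_elbow_at_two(self):
        curve = VafCurve([1, 2, 3, 4, 5], [60.0, 96.0, 96.3, 96.5, 96.6])
        assert scree_select(curve) == 2

    def test_strictly_linear_curve_has_no_elbow(self):
        curve = VafCurve([1, 2, 3, 4, 5], [20.0, 40.0, 60.0, 80.0, 100.0])
        assert scree_select(curve) is None

    def test_flat_curve_selects_one(self):
        curve = VafCurve([1, 2, 3], [99.9, 99.91, 99.92])
        assert scree_select(curve) == 1

    def test_scale_invariant_between_percent_and_fraction_units(self):
        pct = VafCurve([1, 2, 3, 4, 5], [60.0, 96.0, 96.3, 96.5, 96.6])
        frac = VafCurve([1, 2, 3, 4, 5], [v / 100 for v in pct.vaf])
        assert scree_select(pct) == scree_select(frac) == 2

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            scree_select(VafCurve([1, 2], [50.0, 90.0]))


class TestCrossValidate:
    def test_split_fraction_default(self):
        import inspect

        assert inspect.signature(cross_validate).parameters["train_fraction"].default == 0.8

    def test_noiseless_test_vaf_high_at_true_order(self):
        ts, _ = small_mixture(seed=13, noise=0.0, n_trials=6)
        res = cross_validate(ts, n_range=[2], fit_config=FAST, seed=0)
        assert res.test_curve.vaf[0] >= 99.0

    def test_split_is_by_trial(self):
        ts, _ = small_mixture(seed=13, noise=0.02, n_trials=6)
        res = cross_validate(ts, n_range=[1], fit_config={"n_restarts": 2, "seed": 0}, seed=3)
        assert set(res.train_trials).isdisjoint(res.test_trials)
        assert len(res.train_trials) == 5  # 0.8 of 6, capped to leave a test trial
        assert len(res.test_trials) == 1

    def test_test_trials_never_influence_sources(self):
        ts, _ = small_mixture(seed=14, noise=0.02, n_trials=6)
        cfg = {"n_restarts": 3, "seed": 5}
        res = cross_validate(ts, n_range=[2], fit_config=cfg, seed=1)
        # corrupt the held-out trials; trained sources must be unchanged
        corrupted = ts.data.copy()
        rows = np.flatnonzero(np.isin(np.asarray(ts.trial_ids), res.test_trials))
        corrupted[rows] = np.random.default_rng(0).normal(size=(len(rows), ts.n_samples))
        from anechoid.io import TrajectorySet

        ts2 = TrajectorySet(corrupted, ts.sample_rate, ts.channel_labels, trial_ids=ts.trial_ids)
        res2 = cross_validate(ts2, n_range=[2], fit_config=cfg, seed=1)
        assert np.allclose(res.models[0].source_coeffs(), res2.models[0].source_coeffs())

    def test_missing_trial_ids_rejected(self):
        ts, _ = small_mixture(seed=13, noise=0.0, n_trials=6)
        ts.trial_ids = None
        with pytest.raises(ValueError):
            cross_validate(ts)

    def test_bad_train_fraction_rejected(self):
        ts, _ = small_mixture(seed=13, noise=0.0, n_trials=6)
        with pytest.raises(ValueError):
            cross_validate(ts, train_fraction=1.2)


class TestAlignSources:
    def test_identical_sets_align_trivially(self, rng):
        s = rng.normal(size=(3, 100))
        al = align_sources(s, s.copy())
        assert np.array_equal(al.permutation, [0, 1, 2])
        assert np.all(al.shifts == 0)
        assert np.allclose(al.correlations, 1.0)

    def test_known_circular_shift_recovered(self, rng):
        s = np.vstack([np.sin(2 * np.pi * np.arange(200) / 200),
                       np.exp(-0.5 * ((np.arange(200) - 70) / 12.0) ** 2)])
        shifted = np.roll(s, 40, axis=1)
        al = align_sources(s, shifted)
        assert np.all(al.shifts == 40)
        assert np.allclose(al.correlations, 1.0, atol=1e-9)

    def test_matches_exhaustive_permutation_and_shift_oracle(self, rng):
        a = rng.normal(size=(3, 64))
        b = rng.normal(size=(3, 64))
        al = align_sources(a, b)
        # oracle: brute force over all permutations and integer shifts
        import itertools

        def best_abs_corr(x, y):
            xz, yz = x - x.mean(), y - y.mean()
            denom = np.sqrt((xz**2).sum() * (yz**2).sum())
            return max(abs(np.dot(xz, np.roll(yz, s)) / denom) for s in range(64))

        table = [[best_abs_corr(a[i], b[j]) for j in range(3)] for i in range(3)]
        best_perm, best_score = None, -1
        for perm in itertools.permutations(range(3)):
            score = sum(table[i][perm[i]] for i in range(3))
            if score > best_score:
                best_perm, best_score = perm, score
        assert tuple(al.permutation) == best_perm
        assert sum(np.abs(al.correlations)) == pytest.approx(best_score, abs=1e-9)

    def test_sign_flipped_source_reported_negative(self, rng):
        s = rng.normal(size=(1, 80))
        al = align_sources(s, -s)
        assert al.correlations[0] == pytest.approx(-1.0)

    def test_unequal_counts_rejected(self, rng):
        with pytest.raises(ValueError):
            align_sources(rng.normal(size=(2, 50)), rng.normal(size=(3, 50)))
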
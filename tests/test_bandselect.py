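"""PLS-DA, the retention schedule, CARS selection and VIP scoring."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spectramt as sm
from spectramt.bandselect import rmsecv

FAST_CARS = sm.CarsConfig(R=40, lv_mccv_runs=30, max_lv=4, seed=0)


def planted_data(rng, n=180, p=60, informative=8, amplitude=1.0):
    """Three balanced classes; class signal only on `informative` bands."""
    y = np.repeat([0, 1, 2], n // 3)
    X = rng.normal(size=(n, p))
    bands = rng.choice(p, size=informative, replace=False)
    patterns = rng.normal(size=(3, informative))
    X[:, bands] += amplitude * patterns[y]
    return X, np.array([f"c{v}" for v in y]), np.sort(bands)


class TestOneHot:
    def test_indicator(self):
        Y = sm.one_hot(["b", "a", "b"], ["a", "b", "c"])
        np.testing.assert_array_equal(Y, [[0, 1, 0], [1, 0, 0], [0, 1, 0]])
        np.testing.assert_array_equal(Y.sum(axis=1), 1)

    def test_column_sums_are_class_counts(self):
        Y = sm.one_hot(list("aabbbc"), list("abc"))
        np.testing.assert_array_equal(Y.sum(axis=0), [2, 3, 1])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="'d'"):
            sm.one_hot(["a", "d"], ["a", "b"])


class TestPlsda:
    def test_full_rank_recovery_on_noiseless_linear_data(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 12))
        w = rng.normal(size=12)
        y = X @ w
        model = sm.fit_plsda(X, y, n_latent=12)
        rmse = np.sqrt(((model.predict(X)[:, 0] - y) ** 2).mean())
        assert rmse < 1e-8

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 8))
        Y = sm.one_hot(rng.integers(0, 3, 30), range(3))
        a = sm.fit_plsda(X, Y, 4)
        perm = rng.permutation(30)
        b = sm.fit_plsda(X[perm], Y[perm], 4)
        np.testing.assert_allclose(a.coefficients(), b.coefficients(), atol=1e-10)

    def test_informative_column_dominates_single_component(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 10))
        y = X[:, 4] + 0.01 * rng.normal(size=60)
        model = sm.fit_plsda(X, y, 1)
        coefs = np.abs(model.coefficients()[:, 0])
        assert np.argmax(coefs) == 4

    def test_matches_sklearn_nipals(self):
        # independent cross-check of the NIPALS route
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 15))
        Y = sm.one_hot(rng.integers(0, 3, 50), range(3))
        mine = sm.fit_plsda(X, Y, 5, tol=1e-12)
        ref = PLSRegression(n_components=5, scale=False,
                            tol=1e-12, max_iter=5000).fit(X, Y)
        np.testing.assert_allclose(mine.coefficients(5), ref.coef_.T, atol=1e-5)
        np.testing.assert_allclose(mine.predict(X), ref.predict(X), atol=1e-5)

    def test_degenerate_component_terminates_early(self):
        X = np.outer(np.arange(10.0), np.ones(4))  # rank 1 + centring
        y = np.arange(10.0)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            model = sm.fit_plsda(X, y, 3)
        assert model.n_latent < 3


class TestChooseNLatent:
    def test_recovers_known_rank(self):
        hits = 0
        cfg = dataclasses.replace(FAST_CARS, lv_mccv_runs=40, max_lv=5)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            T = rng.normal(size=(80, 2))
            P = rng.normal(size=(2, 20))
            X = T @ P
            y = T @ rng.normal(size=2)
            lv = sm.choose_n_latent(X, y[:, None], cfg, rng)
            hits += lv == 2
        assert hits >= 9

    def test_single_candidate(self):
        rng = np.random.default_rng(0)
        cfg = dataclasses.replace(FAST_CARS, max_lv=1)
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=(30, 1))
        assert sm.choose_n_latent(X, y, cfg, rng) == 1

    def test_seeded_determinism(self):
        X = np.random.default_rng(5).normal(size=(40, 8))
        y = np.random.default_rng(6).normal(size=(40, 1))
        a = sm.choose_n_latent(X, y, FAST_CARS, np.random.default_rng(9))
        b = sm.choose_n_latent(X, y, FAST_CARS, np.random.default_rng(9))
        assert a == b


class TestEdfSchedule:
    def test_default_boundaries(self):
        sched = sm.edf_counts(273, 100)
        assert sched[1] == 273
        assert sched[100] == 2

    @given(st.integers(5, 500), st.integers(2, 150), st.integers(2, 4))
    def test_boundaries_and_monotonicity(self, n_total, R, floor):
        if n_total <= floor:
            return
        sched = sm.edf_counts(n_total, R, floor)
        assert sched[1] == n_total
        assert sched[R] == floor
        assert np.all(np.diff(sched.counts) <= 0)

    def test_midpoint_against_boundary_equation_oracle(self):
        # solve N(r) = N_total * a * e^(-k r) with N(1)=10, N(3)=2 directly
        n_total, R, floor = 10, 3, 2
        k = np.log(n_total / floor) / (R - 1)
        a = np.exp(k)
        expected_mid = round(n_total * a * np.exp(-k * 2))
        sched = sm.edf_counts(n_total, R, floor)
        assert sched[2] == expected_mid

    def test_power_form_exposed(self):
        sched = sm.edf_counts(100, 10, schedule="power", alpha=2.0)
        assert sched.counts[-1] == 100  # the printed power form grows with r

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sm.edf_counts(2, 10)
        with pytest.raises(ValueError):
            sm.edf_counts(100, 1)


class TestCars:
    def test_retained_counts_respect_schedule(self):
        rng = np.random.default_rng(0)
        X, labels, _ = planted_data(rng, n=60, p=30, informative=4)
        res = sm.cars_run(X, labels, dataclasses.replace(FAST_CARS, n_latent=3))
        for r, retained in enumerate(res.retained_sets, start=1):
            assert len(retained) <= res.schedule[r]

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        X, labels, _ = planted_data(rng, n=60, p=30, informative=4)
        cfg = dataclasses.replace(FAST_CARS, n_latent=3, seed=5)
        a = sm.cars_run(X, labels, cfg)
        b = sm.cars_run(X, labels, cfg)
        np.testing.assert_array_equal(a.selected, b.selected)
        np.testing.assert_allclose(a.rmsecv, b.rmsecv)

    def test_band_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        X, labels, _ = planted_data(rng, n=60, p=20, informative=4)
        cfg = dataclasses.replace(FAST_CARS, R=15, n_latent=3)
        base = sm.cars_run(X, labels, cfg)
        perm = np.random.default_rng(3).permutation(20)
        permuted = sm.cars_run(X[:, perm], labels, cfg)
        np.testing.assert_array_equal(np.sort(perm[permuted.selected]),
                                      np.sort(base.selected))

    def test_selected_set_beats_full_set_rmsecv(self):
        rng = np.random.default_rng(4)
        X, labels, _ = planted_data(rng)
        cfg = dataclasses.replace(FAST_CARS, n_latent=3)
        res = sm.cars_run(X, labels, cfg)
        Y = sm.one_hot(labels, sorted(set(labels)))
        folds = np.random.default_rng(0).permutation(len(X)) % 5
        full = rmsecv(X, Y, 3, folds)
        sel = rmsecv(X[:, res.selected], Y, 3, folds)
        assert sel <= full


class TestTwoStage:
    @pytest.fixture(scope="class")
    def staged_tables(self):
        """Three stages with one shared + one stage-specific informative band."""
        rng = np.random.default_rng(7)
        grid = sm.WavelengthGrid(np.linspace(1000, 2500, 24))
        import pandas as pd

        tables = {}
        planted = {}
        specific = {0: 5, 1: 11, 2: 17}
        for stage, day in enumerate((1, 20, 40)):
            n = 90
            y = np.repeat([0, 1, 2], n // 3)
            X = rng.normal(size=(n, 24))
            X[:, 2] += 1.5 * np.array([0.0, 1.0, -1.0])[y]       # shared band
            X[:, specific[stage]] += 1.5 * np.array([1.0, -1.0, 0.0])[y]
            labels = pd.DataFrame({
                "scan_id": [f"d{day}_{i}" for i in range(n)],
                "egg_id": [f"d{day}_e{i}" for i in range(n)],
                "variety": [f"c{v}" for v in y],
                "day": day,
            })
            tables[day] = sm.SpectraTable(labels, X, grid)
            planted[day] = {2, specific[stage]}
        return tables, planted

    def test_union_contains_final(self, staged_tables):
        tables, _ = staged_tables
        cfg = dataclasses.replace(FAST_CARS, R=25, n_latent=2)
        res = sm.two_stage_select(tables, cfg)
        assert set(res.final) <= set(res.union)

    def test_final_set_touches_every_stage(self, staged_tables):
        tables, planted = staged_tables
        cfg = dataclasses.replace(FAST_CARS, R=25, n_latent=2)
        res = sm.two_stage_select(tables, cfg)
        for day, bands in planted.items():
            assert set(res.final) & bands, f"no informative band of day {day} kept"

    def test_requires_two_stages(self, staged_tables):
        tables, _ = staged_tables
        with pytest.raises(ValueError, match=">= 2"):
            sm.two_stage_select({1: tables[1]}, FAST_CARS)


class TestVip:
    def test_sum_of_squares_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            X = rng.normal(size=(40, 12))
            Y = sm.one_hot(rng.integers(0, 3, 40), range(3))
            model = sm.fit_plsda(X, Y, 4)
            v = sm.vip(model).scores
            assert v.min() >= 0
            assert (v ** 2).sum() == pytest.approx(12, abs=1e-8)

    def test_single_informative_band_attains_max(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(90, 10))
        y = np.repeat([0.0, 1.0, 2.0], 30)
        X[:, 6] += 3.0 * y
        model = sm.fit_plsda(X, sm.one_hot(y, [0.0, 1.0, 2.0]), 2)
        assert np.argmax(sm.vip(model).scores) == 6

    def test_uniform_weights_give_unit_vip(self):
        model = sm.PlsdaModel(
            x_mean=np.zeros(4), y_mean=np.zeros(1),
            W=np.full((4, 1), 0.5), P=np.full((4, 1), 0.5),
            Q=np.ones((1, 1)), tss=np.ones(1), ssy=np.ones(1))
        np.testing.assert_allclose(sm.vip(model).scores, 1.0)
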
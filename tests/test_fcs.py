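"""FCS engine: elementary draw oracles, chain behaviour, block contract."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau, norm

from paindelta.fcs import (ImputationSpec, fit_fcs, impute_binary_logistic,
                           impute_categorical_discriminant, impute_continuous,
                           per_block_impute)
from paindelta.imputables import ColumnMeta, ImputableFrame


def make_frame(columns, kinds, block=None):
    """ImputableFrame from {name: values}; kinds maps name -> (kind, role)."""
    data = pd.DataFrame(columns)
    meta = {}
    for name, (kind, role) in kinds.items():
        levels = None
        if kind in ("binary", "nominal", "ordinal"):
            levels = tuple(sorted(pd.Series(columns[name]).dropna().unique()))
            if kind == "binary":
                levels = (0, 1)
            data[name] = data[name].astype("Int64")
        meta[name] = ColumnMeta(name, kind, role, levels=levels,
                                bounds=(0, 10) if kind == "continuous" else None)
    if block is not None:
        data["blk"] = block
        meta["blk"] = ColumnMeta("blk", "nominal", "block")
    return ImputableFrame(data=data, meta=meta)


class TestDiscriminantDraw:
    def test_perfect_association_six_rows(self):
        """Spec worked example: a perfectly separating predictor reproduces
        the association in >= 95% of draws."""
        y_obs = np.array([0.0, 0, 0, 1, 1, 1])
        X_obs = y_obs[:, None].astype(float)
        X_mis = np.tile([0.0, 1.0], 200)[:, None]
        rng = np.random.default_rng(12)
        matches = 0
        for _ in range(20):
            drawn = impute_categorical_discriminant(y_obs, X_obs, X_mis, rng)
            matches += (drawn == X_mis[:, 0]).sum()
        assert matches / (20 * 400) >= 0.95

    def test_separated_classes_near_bayes(self):
        """Means +-3, unit variance: misassignment <= Bayes rate + 5 pts."""
        rng = np.random.default_rng(5)
        n = 500
        y_obs = np.repeat([0.0, 1.0], n)
        X_obs = np.concatenate([rng.normal(-3, 1, n),
                                rng.normal(3, 1, n)])[:, None]
        true_mis = rng.integers(0, 2, size=2000).astype(float)
        X_mis = rng.normal(np.where(true_mis == 1, 3.0, -3.0), 1.0)[:, None]
        drawn = impute_categorical_discriminant(y_obs, X_obs, X_mis, rng)
        bayes_rate = norm.cdf(-3.0)
        assert np.mean(drawn != true_mis) <= bayes_rate + 0.05

    def test_uninformative_predictor_equal_priors(self):
        rng = np.random.default_rng(9)
        y_obs = np.repeat([0.0, 1.0], 200)
        X_obs = rng.normal(size=(400, 1))
        X_mis = rng.normal(size=(4000, 1))
        drawn = impute_categorical_discriminant(y_obs, X_obs, X_mis, rng)
        # binomial + Dirichlet-draw noise: 3 sigma is ~0.09
        assert abs(drawn.mean() - 0.5) < 0.1

    def test_single_class_constant_fill(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="single observed class"):
            drawn = impute_categorical_discriminant(
                np.array([2.0, 2, 2]), np.zeros((3, 1)), np.zeros((5, 1)), rng)
        assert (drawn == 2.0).all()

    def test_multiclass_levels_preserved(self):
        rng = np.random.default_rng(1)
        y_obs = np.repeat([0.0, 1, 2, 3, 4], 40)
        X_obs = y_obs[:, None] + rng.normal(0, 0.3, size=(200, 1))
        X_mis = np.repeat([0.0, 1, 2, 3, 4], 20)[:, None]
        drawn = impute_categorical_discriminant(y_obs, X_obs, X_mis, rng)
        assert set(np.unique(drawn)) <= {0.0, 1, 2, 3, 4}
        # strongly informative predictor: most draws land on the truth
        assert np.mean(drawn == X_mis[:, 0]) > 0.8


class TestLogisticDraw:
    def test_uninformative_predictor(self):
        rng = np.random.default_rng(4)
        y_obs = np.repeat([0.0, 1.0], 300)
        X_obs = rng.normal(size=(600, 1))
        X_mis = rng.normal(size=(4000, 1))
        drawn = impute_binary_logistic(y_obs, X_obs, X_mis, rng)
        assert abs(drawn.mean() - 0.5) < 0.1

    def test_calibrated_under_covariate_shift(self):
        """The training and missing rows have very different prevalences of a
        binary predictor; the drawn prevalence must track the truth."""
        rng = np.random.default_rng(8)
        n = 20_000
        beta = -1.2
        x_tr = (rng.random(n) < 0.08).astype(float)
        y_tr = (rng.random(n) < 1 / (1 + np.exp(-(0.6 + beta * x_tr)))).astype(float)
        x_mis = (rng.random(n) < 0.62).astype(float)
        truth = float(np.mean(1 / (1 + np.exp(-(0.6 + beta * x_mis)))))
        draws = [impute_binary_logistic(y_tr, x_tr[:, None], x_mis[:, None],
                                        rng).mean() for _ in range(5)]
        assert abs(np.mean(draws) - truth) < 0.02

    def test_single_class_constant_fill(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="single observed class"):
            drawn = impute_binary_logistic(
                np.ones(4), np.zeros((4, 1)), np.zeros((3, 1)), rng)
        assert (drawn == 1.0).all()


class TestContinuousDraw:
    def test_pmm_values_from_observed_support(self):
        rng = np.random.default_rng(2)
        y_obs = rng.choice([0.0, 2, 5, 7, 10], size=300)
        X_obs = rng.normal(size=(300, 2))
        X_mis = rng.normal(size=(500, 2))
        drawn = impute_continuous(y_obs, X_obs, X_mis, rng, method="pmm")
        assert set(np.unique(drawn)) <= set(np.unique(y_obs))

    def test_linear_truth_conditional_mean(self):
        """y = 2x + noise: imputed-cell mean matches the model-implied mean."""
        rng = np.random.default_rng(6)
        n = 2000
        x = rng.normal(size=n)
        y = 2.0 * x + rng.normal(0, 1, size=n)
        miss = rng.random(n) < 0.3
        drawn = impute_continuous(y[~miss], x[~miss][:, None],
                                  x[miss][:, None], rng, method="pmm")
        implied = 2.0 * x[miss].mean()
        se = 1.0 / np.sqrt(miss.sum())
        assert abs(drawn.mean() - implied) < 3 * se + 0.1

    def test_bayes_linear_respects_bounds(self):
        rng = np.random.default_rng(3)
        y_obs = rng.uniform(0, 10, size=200)
        X_obs = rng.normal(size=(200, 1))
        X_mis = rng.normal(size=(500, 1)) * 10
        drawn = impute_continuous(y_obs, X_obs, X_mis, rng,
                                  method="bayes_linear", bounds=(0, 10))
        assert drawn.min() >= 0.0 and drawn.max() <= 10.0

    def test_constant_outcome_constant_fill(self):
        rng = np.random.default_rng(0)
        drawn = impute_continuous(np.full(10, 4.0), np.zeros((10, 1)),
                                  np.zeros((3, 1)), rng)
        assert (drawn == 4.0).all()

    def test_too_few_observed_rows(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="insufficient"):
            impute_continuous(np.array([1.0, 2.0]), np.ones((2, 3)) *
                              np.arange(3), np.ones((1, 3)), rng)

    def test_unknown_method(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="unknown continuous method"):
            impute_continuous(np.arange(10.0), np.zeros((10, 1)),
                              np.zeros((2, 1)), rng, method="nope")


def _mcar_binary_frame(n=5000, p=0.3, miss_rate=0.5, seed=13):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < p).astype(float)
    x = rng.normal(size=n)
    miss = rng.random(n) < miss_rate
    y_col = pd.array(np.where(miss, np.nan, y), dtype="Int64")
    return make_frame(
        {"y": y_col, "x": x},
        {"y": ("binary", "imputable"), "x": ("continuous", "predictor")},
    ), miss


class TestFitFCS:
    def test_zero_missing_returns_copies(self):
        frame = make_frame({"y": [0, 1, 1, 0], "x": [0.1, 0.2, 0.3, 0.4]},
                           {"y": ("binary", "imputable"),
                            "x": ("continuous", "predictor")})
        res = fit_fcs(frame, ImputationSpec(m=3, iterations=2, seed=1))
        assert len(res.frames) == 3
        for f in res.frames:
            pd.testing.assert_frame_equal(f, frame.data)

    def test_observed_cells_immutable(self):
        frame, miss = _mcar_binary_frame(n=800)
        res = fit_fcs(frame, ImputationSpec(m=4, iterations=3, seed=7))
        observed = frame.data.loc[~miss, "y"]
        for f in res.frames:
            pd.testing.assert_series_equal(f.loc[~miss, "y"], observed)
            assert f["y"].notna().all()

    def test_mcar_marginal_recovery(self):
        frame, miss = _mcar_binary_frame()
        res = fit_fcs(frame, ImputationSpec(m=20, iterations=2, seed=3))
        p_obs = float(frame.data.loc[~miss, "y"].mean())
        imputed_means = [float(f.loc[miss, "y"].mean()) for f in res.frames]
        n_obs, n_mis = int((~miss).sum()), int(miss.sum())
        se = np.sqrt(p_obs * (1 - p_obs) * (1 / n_obs + 1 / n_mis))
        assert abs(np.mean(imputed_means) - p_obs) < 3 * se

    def test_determinism(self):
        frame, _ = _mcar_binary_frame(n=600)
        spec = ImputationSpec(m=3, iterations=2, seed=11)
        a = fit_fcs(frame, spec)
        b = fit_fcs(frame, spec)
        for fa, fb in zip(a.frames, b.frames):
            pd.testing.assert_frame_equal(fa, fb)
        assert a.seeds == b.seeds

    def test_traces_shape_and_seed_bounds(self):
        frame, _ = _mcar_binary_frame(n=600)
        res = fit_fcs(frame, ImputationSpec(m=3, iterations=4, seed=11))
        assert res.traces["y"].shape == (3, 4)
        assert all(0 <= s < 2**31 for s in res.seeds)

    def test_chain_stationarity(self):
        """Single-variable MCAR chain reaches its stationary draw at once:
        the per-cycle trace must not trend."""
        frame, _ = _mcar_binary_frame(n=2000)
        res = fit_fcs(frame, ImputationSpec(m=4, iterations=12, seed=19))
        taus = []
        for chain in res.traces["y"]:
            tau, _ = kendalltau(np.arange(len(chain)), chain)
            taus.append(tau)
        assert abs(np.mean(taus)) < 0.5

    def test_all_missing_column_rejected(self):
        frame = make_frame({"y": pd.array([np.nan] * 4, dtype="Int64"),
                            "x": [0.1, 0.2, 0.3, 0.4]},
                           {"y": ("binary", "imputable"),
                            "x": ("continuous", "predictor")})
        with pytest.raises(ValueError, match="no observed values"):
            fit_fcs(frame, ImputationSpec(m=2, iterations=1, seed=0))

    def test_sequential_default_predictors_respected(self):
        """With an explicit predictor map, a variable may not predict itself."""
        with pytest.raises(ValueError, match="predict itself"):
            ImputationSpec(m=2, iterations=1, seed=0,
                           predictors={"y": ["y", "x"]}).validate()

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ImputationSpec(m=1, iterations=1, seed=0).validate()
        with pytest.raises(ValueError):
            ImputationSpec(m=2, iterations=0, seed=0).validate()


class TestPerBlock:
    def _blocked_frame(self, order):
        rng = np.random.default_rng(23)
        n = 400
        block = np.repeat([0, 1], n // 2)
        x = rng.normal(size=n)
        y = (rng.random(n) < 0.4).astype(float)
        miss = rng.random(n) < 0.3
        y_col = pd.array(np.where(miss, np.nan, y), dtype="Int64")
        frame = make_frame({"id": np.arange(n), "y": y_col, "x": x},
                           {"id": ("continuous", "id"),
                            "y": ("binary", "imputable"),
                            "x": ("continuous", "predictor")},
                           block=block)
        return ImputableFrame(data=frame.data.iloc[order].reset_index(drop=True),
                              meta=frame.meta)

    def test_block_order_invariance(self):
        """Concatenating blocks in a different order leaves each resident's
        imputed values unchanged (per-block seeds hash the block label)."""
        n = 400
        forward = np.arange(n)
        swapped = np.concatenate([np.arange(n // 2, n), np.arange(n // 2)])
        spec = ImputationSpec(m=3, iterations=2, seed=5)
        res_a = per_block_impute(self._blocked_frame(forward), spec)
        res_b = per_block_impute(self._blocked_frame(swapped), spec)
        for fa, fb in zip(res_a.frames, res_b.frames):
            fa = fa.sort_values("id").reset_index(drop=True)
            fb = fb.sort_values("id").reset_index(drop=True)
            pd.testing.assert_frame_equal(fa, fb)

    def test_single_block_equals_fit_fcs(self):
        frame = self._blocked_frame(np.arange(400))
        frame.data["blk"] = 0
        spec = ImputationSpec(m=2, iterations=2, seed=5)
        res_block = per_block_impute(frame, spec)
        res_plain = fit_fcs(frame, spec)
        for fa, fb in zip(res_block.frames, res_plain.frames):
            pd.testing.assert_frame_equal(fa, fb)

    def test_block_with_no_observed_rows_rejected(self):
        frame = self._blocked_frame(np.arange(400))
        in_block1 = frame.data["blk"] == 1
        frame.data.loc[in_block1, "y"] = pd.NA
        with pytest.raises(ValueError, match="block"):
            per_block_impute(frame, ImputationSpec(m=2, iterations=1, seed=5))

    def test_block_seeds_recorded(self):
        res = per_block_impute(self._blocked_frame(np.arange(400)),
                               ImputationSpec(m=2, iterations=1, seed=5))
        assert set(res.block_seeds) == {0, 1}
        assert all(0 <= s < 2**31 for s in res.block_seeds.values())
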
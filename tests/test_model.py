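"""Weight-score model: fitting, gauge, prediction, splits, sensitivity."""

import numpy as np
import pandas as pd
import pytest

from recombkin.design import AttVariant, enumerate_library, parse_mutations
from recombkin.model import (
    OneHotVariantEncoder,
    PredictionErrors,
    UnidentifiedWeightError,
    WeightMatrix,
    WeightScoreRegressor,
    classify_weights,
    fit_weights,
    predict_kflip,
    prediction_errors,
    sensitivity_curve,
    simulate_frequency_profile,
    train_val_split,
)
from recombkin.rates import RateTable


def _weight_matrix(design, assignments=None):
    """WeightMatrix with given {(position, base): W}; W=1 elsewhere."""
    lw = np.zeros((design.n_positions, 4))
    wm = WeightMatrix(design=design, log10=lw)
    if assignments:
        cols = design.base_columns()
        for (pos, base), w in assignments.items():
            i = design.position_index(pos)
            lw[i, cols[i].index(base)] = np.log10(w)
    return WeightMatrix(design=design, log10=lw)


def _rates_from_weights(design, weights, variants=None, noise_sd=0.0, seed=0):
    """RateTable generated exactly (or noisily) from a weight matrix."""
    if variants is None:
        variants = [v.bases for v in enumerate_library(design)]
    rng = np.random.default_rng(seed)
    logk = np.array([weights.variant_log10(v) for v in variants])
    if noise_sd:
        logk = logk + rng.normal(0, noise_sd, size=len(variants))
    wt = "".join(design.wt_bases)
    logk[[i for i, v in enumerate(variants) if v == wt]] = 0.0
    df = pd.DataFrame(
        {"k_flip": 10.0**logk, "log10_k_flip": logk},
        index=pd.Index(variants, name="variant"),
    )
    return RateTable(df=df, wt=wt)


class TestEncoder:
    def test_reduced_width_and_names(self, toy3_design):
        enc = OneHotVariantEncoder(design=toy3_design).fit(None)
        X = enc.transform(["AGT"])  # WT
        assert X.shape == (1, 9)
        assert (X == 0).all()  # WT has no non-WT indicator set
        assert list(enc.get_feature_names_out()[:3]) == ["A1C", "A1G", "A1T"]

    def test_full_encoding_row_sums(self, toy3_design):
        enc = OneHotVariantEncoder(design=toy3_design, drop_wt=False).fit(None)
        X = enc.transform(["AGT", "CGA"])
        assert X.shape == (2, 12)
        assert (X.reshape(2, 3, 4).sum(axis=2) == 1).all()

    def test_sklearn_clone_compatible(self, toy3_design):
        from sklearn.base import clone

        est = WeightScoreRegressor(design=toy3_design, alpha=0.5)
        est2 = clone(est)
        assert est2.get_params()["alpha"] == 0.5


class TestFitWeights:
    def test_wt_only_training_set(self, toy3_design):
        rates = _rates_from_weights(
            toy3_design, _weight_matrix(toy3_design), variants=["AGT"]
        )
        fit = fit_weights(rates, toy3_design)
        assert predict_kflip(fit.weights, "AGT") == 1.0
        # nothing but the gauge is identified
        assert np.isnan(fit.weights.log10[:, 1:]).all()

    def test_exact_recovery_on_noiseless_full_library(self, toy3_design):
        truth = _weight_matrix(
            toy3_design,
            {(1, "C"): 2.0, (1, "G"): 0.05, (3, "A"): 0.4, (5, "G"): 3.0},
        )
        rates = _rates_from_weights(toy3_design, truth)
        fit = fit_weights(rates, toy3_design)
        assert np.allclose(fit.weights.log10, truth.log10, atol=1e-8)
        assert fit.rmse < 1e-10

    def test_matches_normal_equations_oracle(self, toy_design):
        """OLS coefficients equal the explicitly solved normal equations."""
        variants = ["CG", "AG", "CT", "AT", "GG", "CA"]
        logk = np.array([0.0, -0.3, 0.5, 0.21, -1.2, 0.8])
        df = pd.DataFrame(
            {"k_flip": 10.0**logk, "log10_k_flip": logk},
            index=pd.Index(variants, name="variant"),
        )
        rates = RateTable(df=df, wt="CG")
        fit = fit_weights(rates, toy_design)

        enc = OneHotVariantEncoder(design=toy_design).fit(None)
        A = enc.transform(variants)
        obs = A.any(axis=0)
        Ao = A[:, obs]
        oracle = np.linalg.solve(Ao.T @ Ao, Ao.T @ logk)
        assert np.allclose(fit.estimator.coef_[obs], oracle, atol=1e-8)

    def test_count_weighted_option(self, toy_design):
        variants = ["CG", "AG", "AG", "CT"]
        logk = np.array([0.0, -0.5, -0.5, 0.2])
        df = pd.DataFrame(
            {"k_flip": 10.0**logk, "log10_k_flip": logk},
            index=pd.Index(["CG", "AG", "CT", "TT"], name="variant"),
        )
        rates = RateTable(df=df.iloc[:3], wt="CG")
        counts = pd.Series({"CG": 100, "AG": 10, "CT": 1})
        fit = fit_weights(rates, toy_design, count_weighted=True, counts=counts)
        assert np.isfinite(fit.rmse)

    def test_underdetermined_fit_warns(self, toy3_design):
        variants = ["AGT", "CCA"]  # 2 sequences, up to 9 free parameters
        logk = np.array([0.0, -1.0])
        df = pd.DataFrame(
            {"k_flip": 10.0**logk, "log10_k_flip": logk},
            index=pd.Index(variants, name="variant"),
        )
        rates = RateTable(df=df, wt="AGT")
        with pytest.warns(UserWarning, match="under-determined"):
            fit = fit_weights(rates, toy3_design)
        assert fit.estimator.rank_deficient_


class TestPredict:
    def test_wt_is_exactly_one(self, toy3_design):
        wm = _weight_matrix(toy3_design, {(3, "A"): 0.7})
        assert predict_kflip(wm, "AGT") == 1.0

    def test_single_mutation_factor(self, toy3_design):
        wm = _weight_matrix(toy3_design, {(3, "A"): 0.5})
        assert predict_kflip(wm, "AAT") == pytest.approx(0.5, rel=1e-12)

    def test_triple_mutant_product(self, toy3_design):
        wm = _weight_matrix(
            toy3_design, {(1, "C"): 2.0, (3, "T"): 1.5, (5, "A"): 1.2}
        )
        assert predict_kflip(wm, "CTA") == pytest.approx(3.6, rel=1e-12)

    def test_log_product_identity(self, toy3_design):
        wm = _weight_matrix(
            toy3_design, {(1, "G"): 0.3, (3, "C"): 2.5, (5, "G"): 0.02}
        )
        for v in ["GCT", "GGG", "ACG"]:
            total = sum(
                wm.log10_weight(pos, b)
                for pos, b in zip(toy3_design.variable_positions, v)
            )
            assert wm.variant_log10(v) == pytest.approx(total, abs=1e-12)

    def test_unidentified_weight_raises(self, toy3_design):
        lw = np.zeros((3, 4))
        lw[0, 1] = np.nan
        wm = WeightMatrix(design=toy3_design, log10=lw)
        bad = "CGT"  # carries the unidentified base at position 1
        with pytest.raises(UnidentifiedWeightError):
            predict_kflip(wm, bad)

    def test_monotone_in_weight(self, toy3_design):
        lo = _weight_matrix(toy3_design, {(3, "A"): 0.5})
        hi = _weight_matrix(toy3_design, {(3, "A"): 0.9})
        carriers = [v.bases for v in enumerate_library(toy3_design) if v.bases[1] == "A"]
        others = [v.bases for v in enumerate_library(toy3_design) if v.bases[1] != "A"]
        for v in carriers:
            assert predict_kflip(hi, v) > predict_kflip(lo, v)
        for v in others:
            assert predict_kflip(hi, v) == predict_kflip(lo, v)


class TestTrainValSplit:
    def _rates(self, toy3_design, n=64):
        wm = _weight_matrix(toy3_design, {(1, "C"): 0.5})
        return _rates_from_weights(toy3_design, wm)

    def test_paper_split_sizes(self, toy3_design):
        rates = self._rates(toy3_design)
        train, val = train_val_split(rates, n_total=50, train_fraction=0.7, seed=1)
        assert (len(train), len(val)) == (35, 15)

    def test_200_at_70_percent_is_140(self, toy3_design):
        # bookkeeping check on the rounding rule itself
        assert int(np.floor(0.7 * 200 + 0.5)) == 140

    def test_tiny_split(self, toy3_design):
        rates = self._rates(toy3_design)
        train, val = train_val_split(rates, n_total=2, train_fraction=0.5, seed=3)
        assert (len(train), len(val)) == (1, 1)

    def test_deterministic_and_disjoint(self, toy3_design):
        rates = self._rates(toy3_design)
        a = train_val_split(rates, 20, seed=9)
        b = train_val_split(rates, 20, seed=9)
        assert list(a[0].df.index) == list(b[0].df.index)
        assert list(a[1].df.index) == list(b[1].df.index)
        assert not set(a[0].df.index) & set(a[1].df.index)

    def test_wt_forced_into_training(self, toy3_design):
        rates = self._rates(toy3_design)
        for seed in range(5):
            train, val = train_val_split(rates, 10, seed=seed)
            assert "AGT" in train.df.index
            assert "AGT" not in val.df.index

    def test_oversized_request_rejected(self, toy3_design):
        with pytest.raises(ValueError):
            train_val_split(self._rates(toy3_design), 1000, seed=0)


class TestPredictionErrors:
    def test_exact_rates_give_zero_error(self, toy3_design):
        wm = _weight_matrix(toy3_design, {(1, "T"): 0.2, (5, "C"): 1.8})
        rates = _rates_from_weights(toy3_design, wm)
        res = prediction_errors(wm, rates)
        assert res.mae == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_gives_mae_delta(self, toy3_design):
        wm = _weight_matrix(toy3_design, {(1, "T"): 0.2})
        rates = _rates_from_weights(toy3_design, wm)
        delta = 0.25
        shifted = RateTable(
            df=pd.DataFrame(
                {
                    "k_flip": rates.df["k_flip"] * 10.0**-delta,
                    "log10_k_flip": rates.df["log10_k_flip"] - delta,
                },
                index=rates.df.index,
            ).drop("AGT"),
            wt="AGT",
        )
        res = prediction_errors(wm, shifted)
        assert res.mae == pytest.approx(delta, abs=1e-12)

    def test_drop_unidentified(self, toy3_design):
        lw = np.zeros((3, 4))
        lw[0, 1] = np.nan
        wm = WeightMatrix(design=toy3_design, log10=lw)
        rates = _rates_from_weights(toy3_design, _weight_matrix(toy3_design))
        res = prediction_errors(wm, rates, on_unidentified="drop")
        assert res.n_unidentified == 16  # 4^2 variants carry base C at position 1
        assert res.n == 48


class TestClassifyWeights:
    def test_thresholds(self, toy3_design):
        wm = _weight_matrix(
            toy3_design,
            {(1, "C"): 2.0, (1, "G"): 0.05, (3, "A"): 0.5, (3, "C"): 0.1},
        )
        cats = classify_weights(wm)
        assert cats[(1, "A")] == "wt-like"  # gauge entry
        assert cats[(1, "C")] == "enhancing"
        assert cats[(1, "G")] == "disrupting"
        assert cats[(3, "A")] == "moderate-loss"
        assert cats[(3, "C")] == "disrupting"  # boundary goes to disrupting

    def test_unidentified_category(self, toy3_design):
        lw = np.zeros((3, 4))
        lw[2, 3] = np.nan
        wm = WeightMatrix(design=toy3_design, log10=lw)
        cats = classify_weights(wm)
        assert "unidentified" in cats.values()

    def test_frame_round_trip(self, toy3_design, tmp_path):
        wm = _weight_matrix(toy3_design, {(1, "C"): 2.0, (5, "G"): 0.01})
        p = tmp_path / "w.tsv"
        wm.to_tsv(p)
        wm2 = WeightMatrix.from_tsv(p, toy3_design)
        assert np.allclose(wm.log10, wm2.log10, equal_nan=True)


@pytest.fixture(scope="module")
def noisy_rates(toy3_design):
    truth = _weight_matrix(
        toy3_design,
        {(1, "C"): 2.0, (1, "T"): 0.1, (3, "A"): 0.3, (5, "G"): 1.5, (5, "C"): 0.05},
    )
    return _rates_from_weights(toy3_design, truth, noise_sd=0.05, seed=7)


class TestSensitivityCurve:

    def test_degenerate_sweep_matches_direct_fit(self, toy3_design, noisy_rates):
        curve = sensitivity_curve(
            noisy_rates, toy3_design, sizes=[len(noisy_rates)], replicates=1, seed=0
        )
        assert curve.summary.shape[0] == 1
        # a single full-size replicate is just one direct split-and-fit
        assert 0 < curve.summary["val_mae"].iloc[0] < 1

    def test_overfitting_regime(self, toy3_design, noisy_rates):
        curve = sensitivity_curve(
            noisy_rates, toy3_design, sizes=[10, 60], replicates=6, seed=3
        )
        s = curve.summary.set_index("size")
        assert s.at[10, "val_mae"] > s.at[60, "val_mae"]
        assert s.at[10, "n_underdetermined"] == 6  # 10 < 9 params + gauge anchor

    def test_weight_dispersion_shrinks(self, toy3_design, noisy_rates):
        curve = sensitivity_curve(
            noisy_rates, toy3_design, sizes=[10, 60], replicates=6, seed=3
        )
        sd = curve.weight_sd.mean(axis=0, skipna=True)
        assert sd[10] > sd[60]


class TestFrequencyProfile:
    def test_flat_when_rates_equal(self):
        prof = simulate_frequency_profile(np.ones(8))
        assert np.allclose(prof, 1 / 8)

    def test_linear_regime_two_variant_shares(self):
        prof = simulate_frequency_profile(
            np.array([2.0, 1.0]), rate_scale=1e-6, reaction_time=1.0
        )
        assert prof[0] == pytest.approx(2 / 3, abs=1e-5)
        assert prof[1] == pytest.approx(1 / 3, abs=1e-5)

    def test_sorted_descending(self):
        rng = np.random.default_rng(0)
        prof = simulate_frequency_profile(rng.uniform(0.01, 4.0, size=50))
        assert (np.diff(prof) <= 0).all()
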
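import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hylocomp.kinship import CoefficientEstimate, KinshipLMMFit, VarianceComponents
from hylocomp.model_selection import (
    AveragedCoefficient,
    ModelRecord,
    ModelSet,
    aicc,
    enumerate_candidate_models,
    fit_all_subsets,
    model_average,
    rank_and_weigh,
    single_predictor_screen,
)
from hylocomp.simulate import simulate_regression_table


def _stub_fit(coeffs: dict[str, tuple[float, float]]) -> KinshipLMMFit:
    cs = [CoefficientEstimate(n, b, s, b / s, 1.0) for n, (b, s) in coeffs.items()]
    return KinshipLMMFit(
        response="y", predictors=[n for n in coeffs if n != "(Intercept)"],
        coefficients=cs,
        variance=VarianceComponents(0.1, 0.1, 0.1, 50.0, 50.0),
        lnL=0.0, n_obs=39, n_params=len(cs) + 3, converged=True,
    )


def _record(subset, aicc_value, coeffs=None):
    fit = _stub_fit(coeffs or {"(Intercept)": (0.0, 1.0),
                               **{p: (1.0, 0.5) for p in subset}})
    return ModelRecord(predictor_subset=tuple(subset), fit=fit,
                       k=len(subset) + 4, lnL=0.0, AICc=aicc_value)


class TestEnumeration:
    def test_five_predictors_gives_31_models(self):
        subsets = enumerate_candidate_models(list("abcde"))
        assert len(subsets) == 31

    def test_single_predictor_gives_one_model(self):
        assert enumerate_candidate_models(["a"]) == [("a",)]

    def test_four_predictors_match_powerset_oracle(self):
        from itertools import chain, combinations

        preds = ["a", "b", "c", "d"]
        got = set(enumerate_candidate_models(preds))
        want = {
            s for s in chain.from_iterable(
                combinations(preds, r) for r in range(1, 5)
            )
        }
        assert got == want and len(got) == 15

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            enumerate_candidate_models([])

    def test_order_is_deterministic(self):
        assert enumerate_candidate_models(["b", "a"]) == [
            ("b",), ("a",), ("b", "a")
        ]


class TestAicc:
    def test_hand_arithmetic(self):
        assert aicc(0.0, 1, 3) == pytest.approx(6.0)  # AIC=2 plus 4/1

    def test_limits_to_aic_for_large_n(self):
        assert aicc(-10.0, 4, 10**6) == pytest.approx(-2 * -10.0 + 8, abs=1e-4)
        assert aicc(-10.0, 1, 10**9) == pytest.approx(-2 * -10.0 + 2, abs=1e-6)

    def test_undefined_below_minimum_n(self):
        with pytest.raises(ValueError):
            aicc(0.0, 5, 6)

    @given(
        lnl=st.floats(-500, 500),
        k=st.integers(1, 10),
        n=st.integers(12, 10_000),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_independent_arithmetic(self, lnl, k, n):
        want = -2 * lnl + 2 * k + (2 * k * (k + 1)) / (n - k - 1)
        assert aicc(lnl, k, n) == pytest.approx(want)


class TestRankAndWeigh:
    def test_single_model(self):
        mset = rank_and_weigh([_record(["a"], 10.0)])
        assert mset.records[0].delta_AICc == 0.0
        assert mset.records[0].akaike_weight == pytest.approx(1.0)

    def test_equal_aicc_splits_weight(self):
        mset = rank_and_weigh([_record(["a"], 5.0), _record(["b"], 5.0)])
        for r in mset.records:
            assert r.akaike_weight == pytest.approx(0.5)

    def test_weights_match_softmax_oracle(self, rng):
        aiccs = rng.uniform(100, 130, size=10)
        mset = rank_and_weigh([_record([f"p{i}"], a) for i, a in enumerate(aiccs)])
        got = {r.predictor_subset: r.akaike_weight for r in mset.records}
        z = np.exp(-(np.sort(aiccs) - aiccs.min()) / 2)
        z /= z.sum()
        ordered = [got[k] for k in sorted(got, key=lambda k: got[k], reverse=True)]
        np.testing.assert_allclose(sorted(ordered, reverse=True), z, rtol=1e-9)
        assert sum(got.values()) == pytest.approx(1.0, abs=1e-9)

    def test_weights_invariant_to_constant_shift(self):
        a = rank_and_weigh([_record(["a"], 3.0), _record(["b"], 6.0)])
        b = rank_and_weigh([_record(["a"], 103.0), _record(["b"], 106.0)])
        for ra, rb in zip(a.records, b.records):
            assert ra.akaike_weight == pytest.approx(rb.akaike_weight)

    def test_confidence_set_threshold_monotone(self):
        records = [_record([f"p{i}"], 100.0 + 2 * i) for i in range(8)]
        sizes = [
            len(rank_and_weigh([_record(r.predictor_subset, r.AICc) for r in records],
                               delta_threshold=th).confidence_set)
            for th in (1, 4, 7, 20)
        ]
        assert sizes == sorted(sizes)
        assert rank_and_weigh(records, delta_threshold=7.0).cumulative_weight <= 1.0


class TestModelAverage:
    def test_single_model_set_returns_its_values(self):
        rec = _record(["a"], 10.0, {"(Intercept)": (0.3, 0.2), "a": (1.5, 0.4)})
        mset = rank_and_weigh([rec])
        avg = {a.name: a for a in model_average(mset)}
        assert avg["a"].averaged_beta == pytest.approx(1.5)
        assert avg["a"].unconditional_se == pytest.approx(0.4)
        assert avg["a"].relative_importance == pytest.approx(1.0)

    def test_hand_arithmetic_example(self):
        """Two models with weights .75/.25, betas 1 and 2, se 0.1 each:
        beta_bar = 1.25 and the unconditional SE is sqrt(0.1975)."""
        # delta of 2*ln(3) makes the renormalised weights exactly .75/.25
        d = 2.0 * np.log(3.0)
        r1 = _record(["a"], 100.0, {"(Intercept)": (0.0, 1.0), "a": (1.0, 0.1)})
        r2 = _record(["a", "b"], 100.0 + d,
                     {"(Intercept)": (0.0, 1.0), "a": (2.0, 0.1), "b": (0.0, 1.0)})
        mset = rank_and_weigh([r1, r2])
        avg = {a.name: a for a in model_average(mset)}
        assert avg["a"].averaged_beta == pytest.approx(1.25, abs=1e-9)
        want_se = np.sqrt(0.75 * (0.01 + 0.0625) + 0.25 * (0.01 + 0.5625))
        assert want_se == pytest.approx(0.4444, abs=5e-5)
        assert avg["a"].unconditional_se == pytest.approx(want_se, abs=1e-6)

    def test_parameter_in_every_model_has_ri_one(self):
        recs = [
            _record(["a"], 100.0),
            _record(["a", "b"], 101.0),
            _record(["a", "c"], 102.0),
        ]
        avg = {a.name: a for a in model_average(rank_and_weigh(recs))}
        assert avg["a"].relative_importance == pytest.approx(1.0)
        assert 0 < avg["b"].relative_importance < 1

    def test_averaged_beta_is_convex_combination(self, rng):
        betas = rng.uniform(-2, 2, size=4)
        recs = [
            _record(["a"], 100 + i, {"(Intercept)": (0.0, 1.0), "a": (b, 0.3)})
            for i, b in enumerate(betas)
        ]
        avg = {a.name: a for a in model_average(rank_and_weigh(recs))}
        assert betas.min() - 1e-12 <= avg["a"].averaged_beta <= betas.max() + 1e-12

    def test_empty_confidence_set_rejected(self):
        mset = rank_and_weigh([_record(["a"], 1.0)])
        mset.confidence_set = []
        with pytest.raises(ValueError, match="confidence set"):
            model_average(mset)


@pytest.fixture(scope="module")
def dataset():
    return simulate_regression_table(
        19, 39, {"(Intercept)": 0.5, "x1": 1.0},
        sigma2_phylo=0.2, sigma2_species=0.1, sigma2_resid=0.2,
        seed=5, n_predictors=4,
    )


class TestScreenAndSubsets:
    def test_eleven_plus_two_candidates_fit_thirteen_models(self, dataset):
        table, kin, _ = dataset
        table = table.copy()
        rng = np.random.default_rng(1)
        preds = [f"q{i}" for i in range(9)]
        for p in preds:
            table[p] = rng.standard_normal(len(table))
        table["co1"] = rng.standard_normal(len(table))
        table["co2"] = rng.standard_normal(len(table))
        cands = ["x1", "x2"] + preds  # 11 predictors
        _, report = single_predictor_screen(
            table, "y", cands, ["co1", "co2"], kin, n_restarts=1
        )
        assert len(report) == 13
        assert list(report.candidate) == cands + ["co1", "co2"]

    def test_strong_effect_detected(self, dataset):
        table, kin, _ = dataset
        sig, report = single_predictor_screen(table, "y", ["x1", "x2"], [], kin)
        assert "x1" in sig

    def test_response_cannot_be_candidate(self, dataset):
        table, kin, _ = dataset
        with pytest.raises(ValueError, match="own predictor"):
            single_predictor_screen(table, "y", ["y"], [], kin)

    def test_failed_candidate_recorded_not_raised(self, dataset):
        table, kin, _ = dataset
        table = table.copy()
        table["broken"] = np.nan
        _, report = single_predictor_screen(table, "y", ["x1", "broken"], [], kin)
        row = report[report.candidate == "broken"].iloc[0]
        assert row.error != "" and not row.significant

    def test_type_one_rate_near_alpha(self):
        """Null candidates pass the screen at roughly the nominal rate.

        Wald z tests with ML variance components at n = 39 run slightly
        anticonservative, so the acceptance band is [0.01, 0.12] around the
        nominal 0.05.
        """
        hits = trials = 0
        for seed in range(60):
            table, kin, _ = simulate_regression_table(
                19, 39, {"(Intercept)": 0.0},
                sigma2_phylo=0.2, sigma2_species=0.1, sigma2_resid=0.2,
                seed=1000 + seed, n_predictors=3,
            )
            sig, rep = single_predictor_screen(
                table, "y", ["x1", "x2", "x3"], [], kin, n_restarts=1
            )
            hits += len(sig)
            trials += 3
        assert 0.01 <= hits / trials <= 0.12

    def test_all_subsets_ranked_and_consistent(self, dataset):
        table, kin, _ = dataset
        mset = fit_all_subsets(table, "y", ["x1", "x2", "x3"], kin, n_restarts=1)
        assert len(mset.records) == 7
        aiccs = [r.AICc for r in mset.records]
        assert aiccs == sorted(aiccs)
        assert sum(r.akaike_weight for r in mset.records) == pytest.approx(1.0)
        assert all(r.delta_AICc < 7 for r in mset.confidence_set)
        best = mset.records[0]
        assert "x1" in best.predictor_subset
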
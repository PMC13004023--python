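"""Covariate formulas, transforms, VIF, AICc machinery, model averaging."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichedyn.core import ContractError
from nichedyn.drivers import (
    DRIVER_NAMES,
    aicc,
    akaike_weights,
    confidence_set_and_average,
    enumerate_subsets,
    introduction_effort,
    nested_filter,
    observations_per_variable,
    power_transform,
    prepare_design,
    residence_time,
    shrink_to_open_interval,
    specialization_index,
    standardize,
    vif_screen,
)
from nichedyn.glmm import FittedModel


class TestCovariateFormulas:
    @pytest.mark.parametrize("L,P,expected", [(1, 1, 1.0), (9, 1, 3.0), (8, 2, 4.0)])
    def test_introduction_effort(self, L, P, expected):
        assert introduction_effort(L, P) == pytest.approx(expected)

    def test_introduction_effort_rejects_nonpositive(self):
        with pytest.raises(ContractError):
            introduction_effort(0, 3)

    @pytest.mark.parametrize(
        "foods,habitats,expected",
        [(10, 10, 0.0), (1, 1, np.log(100)), (20, 10, np.log(0.5))],
    )
    def test_specialization_index(self, foods, habitats, expected):
        assert specialization_index(foods, habitats) == pytest.approx(expected)

    @pytest.mark.parametrize("year,expected", [(1921, 100), (2021, 0), (1821, 200)])
    def test_residence_time(self, year, expected):
        assert residence_time(year) == expected

    def test_residence_time_rejects_future_year(self):
        with pytest.raises(ContractError):
            residence_time(2022)


class TestTransforms:
    def test_yeo_johnson_lambda_one_is_identity(self, rng):
        x = rng.normal(size=40)
        out, lam = power_transform(x, "yeo-johnson", lam=1.0)
        assert np.allclose(out, x)

    def test_yeo_johnson_lambda_zero_is_log1p_for_positives(self):
        out, _ = power_transform(np.array([np.e - 1.0]), "yeo-johnson", lam=0.0)
        assert out[0] == pytest.approx(1.0)

    def test_lambda_estimate_matches_grid_search(self, rng):
        x = np.exp(rng.normal(size=400))  # log-normal: lambda-hat near 0
        for kind, llf in (("box-cox", stats.boxcox_llf),
                          ("yeo-johnson", stats.yeojohnson_llf)):
            _, lam = power_transform(x, kind)
            grid = np.linspace(-5, 5, 1001)
            lam_grid = grid[np.argmax([llf(l, x) for l in grid])]
            assert lam == pytest.approx(lam_grid, abs=0.05)

    def test_box_cox_rejects_nonpositive_naming_rows(self):
        with pytest.raises(ContractError, match="rows"):
            power_transform(np.array([1.0, -2.0, 3.0]), "box-cox")

    def test_log_variants(self):
        with pytest.raises(ContractError):
            power_transform(np.array([0.0, 1.0]), "log")
        out, _ = power_transform(np.array([0.0, np.e - 1]), "log", plus_one=True)
        assert np.allclose(out, [0.0, 1.0])

    def test_shrink_only_at_boundaries(self):
        inner = np.array([0.2, 0.8])
        assert np.array_equal(shrink_to_open_interval(inner), inner)
        with_boundary = shrink_to_open_interval(np.array([0.0, 0.5, 1.0]))
        assert np.all((with_boundary > 0) & (with_boundary < 1))

    def test_standardize(self):
        assert np.allclose(standardize(np.array([1.0, 2.0, 3.0])), [-1, 0, 1])
        z = standardize(np.arange(17.0) ** 2)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_binary_covariates_pass_through_design_untouched(self, driver_table):
        design = prepare_design(driver_table, "expansion")
        assert set(np.unique(design["alien_insularity"])) <= {0.0, 1.0}
        for col in design.columns:
            if col == "alien_insularity":
                continue
            assert design[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert design[col].std(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestVIF:
    def test_orthogonal_columns_keep_unit_vif(self):
        n = 64
        base = np.arange(n)
        X = pd.DataFrame({
            "a": np.where(base % 2 == 0, 1.0, -1.0),
            "b": np.where((base // 2) % 2 == 0, 1.0, -1.0),
            "c": np.where((base // 4) % 2 == 0, 1.0, -1.0),
        })
        kept, table = vif_screen(X, threshold=3.0)
        assert kept == ["a", "b", "c"]
        assert np.allclose(table.vif, 1.0)

    def test_duplicated_column_flagged_unbounded_and_dropped(self, rng):
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=50)})
        kept, table = vif_screen(X, threshold=3.0)
        assert len(kept) == 2 and "c" in kept
        assert np.isinf(table[table.iteration == 0].vif.max())

    def test_vif_matches_per_column_regressions(self, rng):
        z = rng.normal(size=(200, 2))
        X = pd.DataFrame({
            "a": z[:, 0],
            "b": 0.6 * z[:, 0] + 0.8 * z[:, 1],
            "c": rng.normal(size=200),
        })
        _, table = vif_screen(X, threshold=100.0)
        first = table[table.iteration == 0].set_index("variable").vif
        for j, name in enumerate(X.columns):
            yj = X[name].to_numpy()
            others = np.column_stack(
                [np.ones(200)] + [X[c] for c in X.columns if c != name]
            )
            beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
            r2 = 1 - ((yj - others @ beta) ** 2).sum() / ((yj - yj.mean()) ** 2).sum()
            assert first[name] == pytest.approx(1 / (1 - r2), rel=1e-9)


class TestInformationCriteria:
    def test_closed_form_value(self):
        assert aicc(-10.0, 3, 30) == pytest.approx(26.0 + 24.0 / 26.0)

    def test_aicc_tends_to_aic(self):
        aic = -2 * (-10.0) + 2 * 3
        assert aicc(-10.0, 3, 10**9) == pytest.approx(aic, abs=1e-6)

    def test_matches_formula_on_random_tuples(self, rng):
        for _ in range(20):
            ll = rng.normal(scale=50)
            k = int(rng.integers(1, 10))
            n = int(rng.integers(k + 2, 500))
            assert aicc(ll, k, n) == pytest.approx(
                -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            )

    def test_small_sample_guard(self):
        with pytest.raises(ContractError):
            aicc(-10.0, 5, 6)

    def test_akaike_weights_for_delta_two(self):
        w = akaike_weights(np.array([100.0, 102.0]))
        assert w == pytest.approx([0.7311, 0.2689], abs=1e-4)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_observations_per_variable_ratio(self):
        ratio, ok = observations_per_variable(337, 11)
        assert round(ratio, 2) == 30.64 and ok
        ratio, ok = observations_per_variable(50, 11)
        assert not ok


class TestSubsets:
    def test_eleven_variables_give_2048_candidates(self):
        assert len(enumerate_subsets(DRIVER_NAMES)) == 2048

    def test_single_variable(self):
        assert sorted(enumerate_subsets(["a"])) == [(), ("a",)]

    def test_matches_powerset(self):
        vars3 = ["a", "b", "c"]
        got = set(enumerate_subsets(vars3))
        want = set()
        for r in range(4):
            want |= set(itertools.combinations(vars3, r))
        assert got == want

    def test_combinatorial_guard(self):
        with pytest.raises(ContractError):
            enumerate_subsets([f"v{i}" for i in range(21)])


class TestNestedFilter:
    def test_worse_nested_superset_dropped(self):
        kept = nested_filter([(("a",), 100.0), (("a", "b"), 101.0)])
        assert kept == [(("a",), 100.0)]

    def test_better_superset_kept(self):
        kept = nested_filter([(("a", "b"), 99.0), (("a",), 100.0)])
        assert {v for v, _ in kept} == {("a", "b"), ("a",)}

    def test_matches_pairwise_scan(self, rng):
        vars_ = ["a", "b", "c"]
        for _ in range(10):
            cands = [(s, float(rng.normal())) for s in enumerate_subsets(vars_)]
            kept = {v for v, _ in nested_filter(cands)}
            expected = set()
            for v, a in cands:
                sv = frozenset(v)
                dominated = any(
                    frozenset(v2) < sv and a2 <= a for v2, a2 in cands
                )
                if not dominated:
                    expected.add(v)
            assert kept == expected


def _toy_model(names, coefs, ses, loglik, n=100):
    return FittedModel(
        family="binomial", fixed_names=list(names),
        coef=np.asarray(coefs, float), se=np.asarray(ses, float),
        random_sds={}, phi=None, loglik=loglik, k=len(names), n=n,
        converged=True, singular=False,
    )


class TestModelAveraging:
    def test_single_model_returns_its_estimates(self):
        m = _toy_model(["intercept", "a"], [0.5, 2.0], [0.1, 0.2], -50.0)
        fitted = {("a",): m}
        _, avg = confidence_set_and_average(fitted, 4.0, ["a"])
        t = avg.table.set_index("variable")
        assert t.loc["a", "estimate"] == pytest.approx(2.0)
        assert t.loc["a", "se"] == pytest.approx(0.2)
        assert t.loc["a", "importance"] == pytest.approx(1.0)

    def test_zero_substitution_arithmetic(self):
        # two non-nested single-variable models with weights 3:1; the 'a'
        # coefficient 2.0 is present only in the first
        ll_best = -50.0
        delta = 2 * np.log(3.0)  # weight ratio exp(-delta/2) = 1/3
        m1 = _toy_model(["intercept", "a"], [0.0, 2.0], [0.1, 0.0], ll_best)
        m2 = _toy_model(["intercept", "b"], [0.0, 1.0], [0.1, 0.0],
                        ll_best - delta / 2)
        cs, avg = confidence_set_and_average(
            {("a",): m1, ("b",): m2}, 10.0, ["a", "b"]
        )
        t = avg.table.set_index("variable")
        assert t.loc["a", "estimate"] == pytest.approx(0.75 * 2.0)
        assert t.loc["a", "importance"] == pytest.approx(0.75)
        # unconditional SE with zero substitution:
        # 0.75*sqrt(0+(2-1.5)^2) + 0.25*sqrt(0+(0-1.5)^2)
        assert t.loc["a", "se"] == pytest.approx(0.75 * 0.5 + 0.25 * 1.5)
        assert cs.confidence.weight.sum() == pytest.approx(1.0, abs=1e-12)

    def test_full_average_bounded_by_largest_coefficient(self, rng):
        fitted = {}
        for i, subset in enumerate(enumerate_subsets(["a", "b"])):
            coefs = [rng.normal()] + [rng.normal() for _ in subset]
            ses = [abs(rng.normal())] * (1 + len(subset))
            fitted[subset] = _toy_model(
                ["intercept"] + list(subset), coefs, ses,
                float(-50 - rng.uniform(0, 3)),
            )
        _, avg = confidence_set_and_average(fitted, 10.0, ["a", "b"])
        for var in ("a", "b"):
            maxabs = max(
                abs(m.coef_table().get(var, (0.0, 0.0))[0])
                for m in fitted.values()
            )
            est = avg.table.set_index("variable").loc[var, "estimate"]
            assert abs(est) <= maxabs + 1e-12

    def test_ci_contains_estimate(self):
        m = _toy_model(["intercept", "a"], [0.0, -1.0], [0.1, 0.3], -10.0)
        _, avg = confidence_set_and_average({("a",): m}, 4.0, ["a"])
        t = avg.table.set_index("variable")
        assert t.loc["a", "ci_low"] <= t.loc["a", "estimate"] <= t.loc["a", "ci_high"]

    def test_nonconverged_candidates_excluded(self):
        good = _toy_model(["intercept"], [0.0], [0.1], -50.0)
        bad = _toy_model(["intercept", "a"], [0.0, 9.0], [0.1, 9.0], -10.0)
        bad.converged = False
        cs, _ = confidence_set_and_average({(): good, ("a",): bad}, 4.0, ["a"])
        assert cs.n_candidates == 1
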
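"""Suitability ensembles, transfer metrics, and transferability models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nichedyn.core import ContractError
from nichedyn.sdm import (
    UntransferableError,
    arcsine_sqrt,
    auc,
    clamp_mask,
    continuous_boyce_index,
    evaluate_transfer,
    fit_native_ensemble,
    fit_transferability_models,
    max_tss,
    native_size_class,
    predict_suitability,
    sample_pseudo_absences_tiered,
    sensitivity_specificity,
)


def all_pairs_auc(p, a):
    wins = sum((pi > ai) + 0.5 * (pi == ai) for pi in p for ai in a)
    return wins / (len(p) * len(a))


def exhaustive_max_tss(p, a):
    p, a = np.asarray(p), np.asarray(a)
    best = -np.inf
    grid = np.unique(np.concatenate([p, a, [0.0, 1.0], np.linspace(0, 1, 97)]))
    for t in grid:
        tss = np.mean(p >= t) + np.mean(a < t) - 1.0
        best = max(best, tss)
    return best


class TestAUC:
    def test_separable(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_identical_sets_score_half(self):
        s = [0.3, 0.5, 0.7]
        assert auc(s, s) == pytest.approx(0.5)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 100_000))
    def test_matches_all_pairs_statistic(self, seed):
        rng = np.random.default_rng(seed)
        p = np.round(rng.uniform(size=rng.integers(1, 30)), 2)  # forces ties
        a = np.round(rng.uniform(size=rng.integers(1, 30)), 2)
        assert auc(p, a) == pytest.approx(all_pairs_auc(p, a), abs=1e-12)


class TestMaxTSS:
    def test_separable_reaches_one(self):
        tss, _ = max_tss([0.9, 0.8], [0.1, 0.2])
        assert tss == pytest.approx(1.0)

    def test_worked_example(self):
        tss, thr = max_tss([0.9, 0.8, 0.4], [0.6, 0.3, 0.2])
        assert tss == pytest.approx(2.0 / 3.0)
        assert thr == pytest.approx(0.4)  # smallest maximizing threshold

    def test_identical_sets_score_zero(self):
        s = [0.2, 0.5, 0.8]
        tss, _ = max_tss(s, s)
        assert tss == pytest.approx(0.0)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 100_000))
    def test_matches_exhaustive_threshold_scan(self, seed):
        rng = np.random.default_rng(seed)
        p = np.round(rng.uniform(size=rng.integers(2, 25)), 2)
        a = np.round(rng.uniform(size=rng.integers(2, 25)), 2)
        tss, thr = max_tss(p, a)
        assert tss == pytest.approx(exhaustive_max_tss(p, a), abs=1e-12)
        # reported sensitivity/specificity are consistent at that threshold
        sens, spec = sensitivity_specificity(p, a, thr)
        assert sens / 100 + spec / 100 - 1 == pytest.approx(tss, abs=1e-12)


class TestSensitivitySpecificity:
    def test_zero_threshold_catches_all_presences(self):
        sens, _ = sensitivity_specificity([0.1, 0.9], [0.5], 0.0)
        assert sens == 100.0

    def test_above_max_threshold_rejects_all(self):
        _, spec = sensitivity_specificity([0.4], [0.2, 0.9], 1.0 + 1e-9)
        assert spec == 100.0

    def test_counts_at_threshold(self):
        sens, spec = sensitivity_specificity([0.2, 0.5, 0.8], [0.1, 0.5], 0.5)
        assert sens == pytest.approx(200 / 3)
        assert spec == pytest.approx(50.0)


class TestBoyceIndex:
    def test_monotone_concentration_gives_one(self):
        bg = np.linspace(0, 1, 2000)
        u = (np.arange(3000) + 0.5) / 3000
        pres = np.log1p(u * (np.exp(5.0) - 1)) / 5.0  # density rising in s
        assert continuous_boyce_index(pres, bg) > 0.999

    def test_reversed_concentration_gives_minus_one(self):
        bg = np.linspace(0, 1, 2000)
        u = (np.arange(3000) + 0.5) / 3000
        pres = 1.0 - np.log1p(u * (np.exp(5.0) - 1)) / 5.0
        assert continuous_boyce_index(pres, bg) < -0.999

    def test_availability_sampling_is_centred_on_zero(self):
        # individual replicates are noisy (the 101 windows overlap heavily),
        # so the null behaviour is judged on the Monte-Carlo mean
        rng = np.random.default_rng(42)
        bg = np.linspace(0, 1, 4000)
        vals = [
            continuous_boyce_index(rng.choice(bg, 1000, replace=False), bg)
            for _ in range(40)
        ]
        assert abs(np.mean(vals)) < 0.15

    def test_too_few_presences_rejected(self):
        with pytest.raises(ContractError):
            continuous_boyce_index([0.5] * 4, np.linspace(0, 1, 50))


def test_arcsine_sqrt_quarter_is_pi_over_six():
    assert arcsine_sqrt(0.25) == pytest.approx(np.pi / 6)
    with pytest.raises(ContractError):
        arcsine_sqrt(np.array([1.5]))


class TestTieredPseudoAbsences:
    def test_tier1_one_to_one(self, rng):
        pool = rng.normal(size=(5000, 2))
        absences, tier = sample_pseudo_absences_tiered(100, pool, 6000,
                                                       pool, seed=1)
        assert tier == 1 and len(absences) == 100

    def test_tier2_five_percent_target(self, rng):
        pool = rng.normal(size=(60, 2))
        absences, tier = sample_pseudo_absences_tiered(100, pool, 1000,
                                                       rng.normal(size=(9000, 2)),
                                                       seed=1)
        assert tier == 2 and len(absences) == 50  # 5% of 1000

    def test_tier3_fallback_when_background_occupied(self, rng):
        allpool = rng.normal(size=(500, 2))
        absences, tier = sample_pseudo_absences_tiered(
            100, np.empty((0, 2)), 10, allpool, seed=1
        )
        assert tier == 3 and len(absences) == 100

    def test_all_tiers_infeasible(self):
        with pytest.raises(ContractError):
            sample_pseudo_absences_tiered(10, np.empty((0, 2)), 0,
                                          np.empty((0, 2)), seed=0)


def _separable_data(rng, n=100):
    pres = rng.normal([0, 0, 0, 0], 0.3, size=(n, 4))
    bg = rng.normal([5, 5, 5, 5], 0.3, size=(n * 10, 4))
    return pres, bg


class TestEnsemble:
    def test_separable_niche_retains_all_replicates(self, rng):
        pres, bg = _separable_data(rng)
        ens = fit_native_ensemble(pres, bg, seed=1)
        assert ens.retained.all()
        assert np.all(ens.replicate_auc == 1.0)
        suit_p = predict_suitability(ens, pres)
        suit_b = predict_suitability(ens, bg[:100])
        assert suit_p.mean() > 0.9 > 0.1 > suit_b.mean()

    def test_randomized_labels_mostly_rejected(self, rng):
        cloud = rng.normal(size=(400, 4))
        try:
            ens = fit_native_ensemble(cloud[:100], cloud[100:], seed=2)
        except UntransferableError:
            return
        assert ens.replicate_auc.mean() < 0.65
        assert ens.retained.mean() <= 0.4

    def test_presence_minimum_enforced(self, rng):
        pres, bg = _separable_data(rng, n=19)
        with pytest.raises(ContractError, match="20"):
            fit_native_ensemble(pres, bg, seed=0)


class TestClampMask:
    def test_training_region_unmasked(self, rng):
        pres, bg = _separable_data(rng)
        ens = fit_native_ensemble(pres, bg, seed=3)
        assert clamp_mask(ens, pres).all()

    def test_shifted_axis_masked_and_fraction_matches_direct_check(self, rng):
        pres, bg = _separable_data(rng)
        ens = fit_native_ensemble(pres, bg, seed=3)
        proj = rng.normal([2.5, 2.5, 2.5, 2.5], 3.0, size=(400, 4))
        got = clamp_mask(ens, proj)
        from nichedyn.ordination import project_scores

        s = project_scores(ens.ordination, proj)
        direct = np.all((s >= ens.train_min) & (s <= ens.train_max), axis=1)
        assert np.array_equal(got, direct)
        assert 0 < got.mean() < 1


class TestTransferabilityModels:
    def _table(self, rng, beta_e=0.0, n=200):
        realm = rng.integers(0, 8, size=n)
        size_class = native_size_class(np.exp(rng.normal(12, 2, size=n)))
        E = rng.beta(1, 6, size=n)
        U = rng.beta(3, 2, size=n)
        noise = rng.normal(0, 0.08, size=n)
        a = np.clip(0.8 + beta_e * E + noise, 0.02, 0.98)
        return pd.DataFrame({
            "auc": a,
            "max_tss": np.clip(2 * a - 1, -0.98, 0.98),
            "cbi": np.clip(2 * a - 1 + rng.normal(0, 0.1, n), -0.98, 0.98),
            "sensitivity": np.clip(100 * a + rng.normal(0, 5, n), 0, 100),
            "specificity": np.clip(100 * (1 - E) * 0.7 + rng.normal(0, 10, n), 0, 100),
            "expansion": E,
            "unfilling": U,
            "realm": realm,
            "size_class": size_class,
        })

    def test_built_in_negative_expansion_effect_recovered(self):
        rng = np.random.default_rng(10)
        table = self._table(rng, beta_e=-0.6)
        res = fit_transferability_models(table)
        row = res[(res.metric == "auc") & (res.term == "expansion")].iloc[0]
        assert row.estimate < 0 and row.ci_high < 0

    def test_null_effects_covered_by_intervals(self):
        rng = np.random.default_rng(11)
        table = self._table(rng, beta_e=0.0)
        res = fit_transferability_models(table)
        gaussian = res[(res.metric == "auc")]
        for _, row in gaussian.iterrows():
            assert row.ci_low <= 0 <= row.ci_high

    def test_size_class_quintiles_are_balanced(self, rng):
        s = np.exp(rng.normal(10, 3, size=1000))
        cls = native_size_class(s)
        counts = np.bincount(cls, minlength=5)
        assert len(counts) == 5 and counts.min() > 150

    def test_minimum_rows_enforced(self, rng):
        with pytest.raises(ContractError):
            fit_transferability_models(self._table(rng, n=20))


class TestEvaluateTransfer:
    def test_conserved_scenario_transfers_well(self, small_scenario):
        sc = small_scenario
        ng, ag = sc.native_grid, sc.alien_grid
        nmask = np.zeros(ng.n_cells, bool)
        nmask[ng.rows_for(sc.native_range.sorted_cells())] = True
        amask = np.zeros(ag.n_cells, bool)
        amask[ag.rows_for(sc.alien_range.sorted_cells())] = True
        ens = fit_native_ensemble(
            ng.climate[nmask], ng.climate[~nmask],
            np.vstack([ng.climate, ag.climate]), seed=7,
        )
        ev = evaluate_transfer(
            ens, ag.climate[amask], ag.climate[~amask],
            np.vstack([ng.climate[~nmask], ag.climate[~amask]]), seed=7,
        )
        assert ev.auc > 0.9
        assert ev.cbi > 0.5
        assert ev.tier == 1
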
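"""Native-range suitability models and their transfer to the alien region.

A species' native realized niche is modelled with boosted classification
trees (200 shallow trees — a deliberately low-complexity learner that favors
transferability) on the leading axes of a pooled-background climate PCA.
Five pseudo-absence sets are drawn 1:1 within the native background, each
split three times 70/30 into calibration/evaluation; replicates with holdout
AUC > 0.7 enter the averaged suitability ensemble.  Projections to the alien
region are clamped to the training climate range, and transfer skill is
scored against realm-level alien presences with five metrics: AUC, maximized
TSS, Sensitivity, Specificity (at the max-TSS threshold), and the Continuous
Boyce Index.  Mixed models then relate each metric to niche expansion and
unfilling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedShuffleSplit

from .core import ContractError
from .glmm import fit_mixed_model, singularity_check
from .ordination import Ordination, fit_scaled_pca, project_scores

logger = logging.getLogger("nichedyn")

__all__ = [
    "SDMEnsemble",
    "TransferEvaluation",
    "UntransferableError",
    "fit_native_ensemble",
    "predict_suitability",
    "clamp_mask",
    "sample_pseudo_absences_tiered",
    "auc",
    "max_tss",
    "sensitivity_specificity",
    "continuous_boyce_index",
    "arcsine_sqrt",
    "evaluate_transfer",
    "fit_transferability_models",
]


class UntransferableError(RuntimeError):
    """No ensemble replicate reached the calibration-AUC retention cutoff."""


@dataclass
class SDMEnsemble:
    species_id: str
    ordination: Ordination
    models: list                    # retained GradientBoostingClassifier fits
    replicate_auc: np.ndarray       # calibration AUC of every replicate
    retained: np.ndarray            # bool per replicate
    train_min: np.ndarray           # per-axis min of training scores
    train_max: np.ndarray
    auc_cutoff: float


@dataclass
class TransferEvaluation:
    species_id: str
    realm_id: str
    auc: float
    max_tss: float
    sensitivity: float   # percent
    specificity: float   # percent
    cbi: float
    tier: int
    n_presences: int
    n_absences: int


def fit_native_ensemble(
    presences: np.ndarray,
    background: np.ndarray,
    pooled_background: np.ndarray | None = None,
    species_id: str = "species",
    n_axes: int = 4,
    n_pa_sets: int = 5,
    n_replicates: int = 3,
    n_trees: int = 200,
    calibration_fraction: float = 0.7,
    auc_cutoff: float = 0.7,
    seed: int = 0,
) -> SDMEnsemble:
    """Fit the native-range boosted-tree suitability ensemble.

    ``presences``/``background`` are climate matrices; ``background`` is the
    pseudo-absence candidate pool (native background cells without
    presences).  The climate ordination is calibrated on
    ``pooled_background`` (both regions) when given, so projections share
    axes; ``n_axes`` is capped at the number of climate variables.

    Hyperparameters beyond the tree count (depth 2, learning rate 0.1, bag
    fraction 0.5) are the package's shallow-boosting defaults.
    """
    P = np.atleast_2d(np.asarray(presences, dtype=float))
    B = np.atleast_2d(np.asarray(background, dtype=float))
    if len(P) < 20:
        raise ContractError(
            f"suitability models require at least 20 native presences, got {len(P)}"
        )
    pool = pooled_background if pooled_background is not None else np.vstack([P, B])
    k = P.shape[1]
    n_axes = min(n_axes, k)
    ordination = fit_scaled_pca(pool, n_axes=n_axes)
    if ordination.variance_fractions.sum() <= 0.9:
        logger.warning(
            "SDM ordination captures only %.1f%% of climate variance",
            100 * ordination.variance_fractions.sum(),
        )
    sp = project_scores(ordination, P)
    sb = project_scores(ordination, B)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 626]))
    n_p = len(sp)
    models, aucs, retained = [], [], []
    train_rows = [sp]
    for i_set in range(n_pa_sets):
        n_a = min(n_p, len(sb))  # 1:1 pseudo-absences within the background
        idx = rng.choice(len(sb), size=n_a, replace=False)
        sa = sb[idx]
        train_rows.append(sa)
        X = np.vstack([sp, sa])
        y = np.concatenate([np.ones(n_p), np.zeros(n_a)])
        splitter = StratifiedShuffleSplit(
            n_splits=n_replicates,
            train_size=calibration_fraction,
            random_state=int(rng.integers(2**31)),
        )
        for cal_idx, ev_idx in splitter.split(X, y):
            model = GradientBoostingClassifier(
                n_estimators=n_trees,
                max_depth=2,
                learning_rate=0.1,
                subsample=0.5,
                random_state=int(rng.integers(2**31)),
            )
            model.fit(X[cal_idx], y[cal_idx])
            scores = model.predict_proba(X[ev_idx])[:, 1]
            a = auc(scores[y[ev_idx] == 1], scores[y[ev_idx] == 0])
            models.append(model)
            aucs.append(a)
            retained.append(a > auc_cutoff)
    aucs = np.array(aucs)
    retained = np.array(retained, dtype=bool)
    train = np.vstack(train_rows)
    kept = [m for m, r in zip(models, retained) if r]
    if not kept:
        raise UntransferableError(
            f"{species_id}: no replicate exceeded calibration AUC {auc_cutoff}"
        )
    return SDMEnsemble(
        species_id=species_id,
        ordination=ordination,
        models=kept,
        replicate_auc=aucs,
        retained=retained,
        train_min=train.min(axis=0),
        train_max=train.max(axis=0),
        auc_cutoff=auc_cutoff,
    )


def predict_suitability(ensemble: SDMEnsemble, climate: np.ndarray) -> np.ndarray:
    """Averaged suitability of the retained replicates, in [0, 1]."""
    s = project_scores(ensemble.ordination, np.atleast_2d(climate))
    preds = [m.predict_proba(s)[:, 1] for m in ensemble.models]
    return np.mean(preds, axis=0)


def clamp_mask(ensemble: SDMEnsemble, climate: np.ndarray) -> np.ndarray:
    """True for projection cells inside the training climate range.

    Cells whose ordination scores fall outside the per-axis [min, max] of
    the training scores would force the trees to extrapolate; they are
    excluded from evaluation sets.
    """
    s = project_scores(ensemble.ordination, np.atleast_2d(climate))
    return np.all((s >= ensemble.train_min) & (s <= ensemble.train_max), axis=1)


def sample_pseudo_absences_tiered(
    n_presences: int,
    alien_unoccupied: np.ndarray,
    alien_background_total: int,
    all_region_unoccupied: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Tiered pseudo-absence sampling for transfer evaluation.

    Tier 1: 1:1 from unoccupied alien-background cells.  Tier 2 (too few
    unoccupied cells): target 5% of all alien-background cells.  Tier 3 (5%
    target also unavailable): 1:1 from unoccupied cells across all regions.
    Returns (row indices into the chosen pool stacked as rows, tier).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 808]))
    alien_unoccupied = np.atleast_2d(alien_unoccupied)
    all_region_unoccupied = np.atleast_2d(all_region_unoccupied)
    n_alien_un = len(alien_unoccupied) if alien_unoccupied.size else 0
    if n_alien_un >= n_presences:
        idx = rng.choice(n_alien_un, size=n_presences, replace=False)
        return alien_unoccupied[idx], 1
    target = int(round(0.05 * alien_background_total))
    if 1 <= target <= n_alien_un:
        idx = rng.choice(n_alien_un, size=target, replace=False)
        return alien_unoccupied[idx], 2
    n_all = len(all_region_unoccupied) if all_region_unoccupied.size else 0
    if n_all == 0:
        raise ContractError("no unoccupied cells available in any tier")
    take = min(n_presences, n_all)
    idx = rng.choice(n_all, size=take, replace=False)
    return all_region_unoccupied[idx], 3


# ---------------------------------------------------------------------------
# Evaluation metrics


def auc(presence_scores: np.ndarray, absence_scores: np.ndarray) -> float:
    """Rank-based AUC: P(random presence outscores random absence), ties 1/2."""
    p = np.asarray(presence_scores, dtype=float).ravel()
    a = np.asarray(absence_scores, dtype=float).ravel()
    if len(p) == 0 or len(a) == 0:
        raise ContractError("both score sets must be nonempty")
    ranks = stats.rankdata(np.concatenate([p, a]))
    u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2.0
    return float(u / (len(p) * len(a)))


def max_tss(
    presence_scores: np.ndarray, absence_scores: np.ndarray
) -> tuple[float, float]:
    """Maximized True Skill Statistic and its threshold.

    ``TSS(t) = Sensitivity(t) + Specificity(t) - 1`` with presence predicted
    when score >= t, maximized over the sorted unique scores plus {0, 1};
    ties resolve to the smallest maximizing threshold.
    """
    p = np.sort(np.asarray(presence_scores, dtype=float).ravel())
    a = np.sort(np.asarray(absence_scores, dtype=float).ravel())
    if len(p) == 0 or len(a) == 0:
        raise ContractError("both score sets must be nonempty")
    thresholds = np.unique(np.concatenate([p, a, [0.0, 1.0]]))
    sens = 1.0 - np.searchsorted(p, thresholds, side="left") / len(p)
    spec = np.searchsorted(a, thresholds, side="left") / len(a)
    tss = sens + spec - 1.0
    # smallest threshold achieving the maximum (tolerance absorbs the
    # floating-point jitter between algebraically tied values)
    best = int(np.flatnonzero(tss >= tss.max() - 1e-12)[0])
    return float(tss[best]), float(thresholds[best])


def sensitivity_specificity(
    presence_scores: np.ndarray, absence_scores: np.ndarray, threshold: float
) -> tuple[float, float]:
    """(% presences >= threshold, % absences < threshold)."""
    p = np.asarray(presence_scores, dtype=float).ravel()
    a = np.asarray(absence_scores, dtype=float).ravel()
    return (
        float(100.0 * np.mean(p >= threshold)),
        float(100.0 * np.mean(a < threshold)),
    )


def continuous_boyce_index(
    presence_scores: np.ndarray,
    background_scores: np.ndarray,
    n_windows: int = 101,
    window_fraction: float = 0.1,
) -> float:
    """Continuous Boyce Index: presence-only calibration of suitability.

    The suitability range is covered by ``n_windows`` moving windows of
    width ``window_fraction`` of the range; for each window, F = (fraction
    of presences inside) / (fraction of background inside), windows with no
    background skipped.  CBI is the Spearman rank correlation between F and
    the window midpoint: +1 when presences concentrate increasingly in
    high-suitability classes, 0 when presences follow availability.
    Returns NaN when fewer than 2 valid windows remain.
    """
    p = np.asarray(presence_scores, dtype=float).ravel()
    b = np.asarray(background_scores, dtype=float).ravel()
    if len(p) < 5:
        raise ContractError("need at least 5 presences for the Boyce index")
    if len(b) == 0:
        raise ContractError("background must be nonempty")
    lo = min(p.min(), b.min())
    hi = max(p.max(), b.max())
    if hi <= lo:
        return np.nan
    width = (hi - lo) * window_fraction
    starts = np.linspace(lo, hi - width, n_windows)
    mids, F = [], []
    for s in starts:
        e = s + width
        # closed right edge on the last window so the top scores count
        inside_p = (p >= s) & ((p < e) | (e >= hi))
        inside_b = (b >= s) & ((b < e) | (e >= hi))
        eb = inside_b.mean()
        if eb == 0:
            continue
        F.append(inside_p.mean() / eb)
        mids.append(s + width / 2)
    if len(F) < 2:
        return np.nan
    rho = stats.spearmanr(mids, F).statistic
    return float(rho)


def arcsine_sqrt(x: np.ndarray) -> np.ndarray:
    """Variance-stabilizing arcsine-square-root transform for proportions."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ContractError("arcsine-sqrt requires values in [0, 1]")
    return np.arcsin(np.sqrt(x))


# ---------------------------------------------------------------------------
# Transfer evaluation and its drivers


def evaluate_transfer(
    ensemble: SDMEnsemble,
    alien_presences: np.ndarray,
    alien_background: np.ndarray,
    all_region_background: np.ndarray,
    realm_id: str = "realm",
    seed: int = 0,
) -> TransferEvaluation:
    """Score the native ensemble against realm-level alien presences.

    ``alien_background`` must exclude the presence cells (it is the
    pseudo-absence pool).  Cells outside the training climate range are
    clamped away from every evaluation set; the Boyce index uses the
    clamped alien background as its availability sample.
    """
    P = np.atleast_2d(np.asarray(alien_presences, dtype=float))
    B = np.atleast_2d(np.asarray(alien_background, dtype=float))
    if len(P) < 5:
        raise ContractError("need at least 5 alien presences")
    n_bg_total = len(B)
    keep_p = clamp_mask(ensemble, P)
    keep_b = clamp_mask(ensemble, B)
    P = P[keep_p]
    B = B[keep_b]
    if len(P) < 5:
        raise ContractError("fewer than 5 alien presences inside the training range")
    ALL = np.atleast_2d(np.asarray(all_region_background, dtype=float))
    ALL = ALL[clamp_mask(ensemble, ALL)]

    absences, tier = sample_pseudo_absences_tiered(
        len(P), B, n_bg_total, ALL, seed=seed
    )
    sp = predict_suitability(ensemble, P)
    sa = predict_suitability(ensemble, absences)
    sb = predict_suitability(ensemble, B)

    a = auc(sp, sa)
    tss, thr = max_tss(sp, sa)
    sens, spec = sensitivity_specificity(sp, sa, thr)
    cbi = continuous_boyce_index(sp, sb)
    return TransferEvaluation(
        species_id=ensemble.species_id, realm_id=realm_id,
        auc=a, max_tss=tss, sensitivity=sens, specificity=spec, cbi=cbi,
        tier=tier, n_presences=len(sp), n_absences=len(sa),
    )


def native_size_class(native_sizes: np.ndarray, n_classes: int = 5) -> np.ndarray:
    """Percentile-based native-range-size classes (0 = very small ... 4 =
    very large), used as a random effect controlling for data availability."""
    s = np.asarray(native_sizes, dtype=float)
    qs = np.quantile(s, np.linspace(0, 1, n_classes + 1)[1:-1])
    return np.searchsorted(qs, s, side="right")


def fit_transferability_models(table: pd.DataFrame) -> pd.DataFrame:
    """Model each transfer metric against niche expansion and unfilling.

    ``table`` needs columns ``auc, max_tss, cbi, sensitivity, specificity``
    (the last two in percent), ``expansion``, ``unfilling``, and grouping
    columns ``realm`` and ``size_class``.  AUC, TSS and CBI are mapped to
    [0, 1] (``(x+1)/2`` for the two correlations), arcsine-sqrt transformed
    and fitted with Gaussian mixed models; Sensitivity and Specificity are
    binarized at their first quartile and fitted with binomial mixed models.
    A singular random structure falls back along the documented plan (the
    Sensitivity model typically ends with no random effects).  Returns one
    row per metric x fixed effect with estimate, SE, CI and p-value.
    """
    if len(table) < 30:
        raise ContractError("need at least 30 joined evaluations")
    factors_all = {
        "realm": pd.Categorical(table["realm"]).codes.astype(np.intp),
        "size_class": pd.Categorical(table["size_class"]).codes.astype(np.intp),
    }
    X = np.column_stack([
        np.ones(len(table)),
        table["expansion"].to_numpy(dtype=float),
        table["unfilling"].to_numpy(dtype=float),
    ])
    names = ["intercept", "expansion", "unfilling"]
    rows = []
    for metric in ("auc", "max_tss", "cbi", "sensitivity", "specificity"):
        vals = table[metric].to_numpy(dtype=float)
        if metric in ("auc", "max_tss", "cbi"):
            y = vals if metric == "auc" else (vals + 1.0) / 2.0
            y = arcsine_sqrt(np.clip(y, 0.0, 1.0))
            family = "gaussian"
        else:
            q1 = np.quantile(vals, 0.25)
            y = (vals >= q1).astype(float)
            family = "binomial"
        factors = dict(factors_all)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_mixed_model(X, y, family, fixed_names=names, factors=factors)
            singular, plan = singularity_check(model)
            while singular:
                fallback = plan[0] if plan else []
                factors = {f: factors_all[f] for f in fallback if f in factors_all}
                logger.info("%s model singular; refitting with %s",
                            metric, sorted(factors) or "no random effects")
                model = fit_mixed_model(X, y, family, fixed_names=names,
                                        factors=factors)
                if not factors:
                    break
                singular, plan = singularity_check(model)
        for j, name in enumerate(names):
            if name == "intercept":
                continue
            est, se = float(model.coef[j]), float(model.se[j])
            z = est / se if se > 0 else np.nan
            rows.append({
                "metric": metric,
                "family": family,
                "term": name,
                "estimate": est,
                "se": se,
                "ci_low": est - 1.96 * se,
                "ci_high": est + 1.96 * se,
                "p_value": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                "random_terms": ",".join(sorted(model.random_sds)) or "none",
            })
    return pd.DataFrame(rows)
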
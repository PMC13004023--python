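"""Drivers of niche change: covariate construction and multimodel inference.

Eleven species-by-realm covariates (species attributes, invasion history,
environmental context) are screened for collinearity (VIF), transformed
toward symmetry (Yeo-Johnson / Box-Cox / log), standardized, and related to
two responses: a binary expansion outcome (binomial-logit mixed model, the
binarization threshold coming from 1-D 2-means clustering of the continuous
expansion values) and a square-root-transformed unfilling proportion
(beta-logit mixed model).  Inference is information-theoretic: all additive
fixed-effect subsets of the global model are ranked by AICc, more complex
nested variants of better simpler models are discarded, the confidence set
is the non-nested models within DeltaAICc < 4 of the best, and estimates are
full-averaged over that set with Akaike weights (coefficients of absent
variables counted as zero).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import ContractError
from .glmm import FittedModel, fit_mixed_model, singularity_check

logger = logging.getLogger("nichedyn")

__all__ = [
    "DRIVER_NAMES",
    "introduction_effort",
    "specialization_index",
    "residence_time",
    "power_transform",
    "shrink_to_open_interval",
    "standardize",
    "vif_screen",
    "aicc",
    "akaike_weights",
    "enumerate_subsets",
    "nested_filter",
    "confidence_set_and_average",
    "CandidateSet",
    "AveragedEstimates",
    "observations_per_variable",
    "DEFAULT_TRANSFORMS",
    "prepare_design",
    "all_subsets_inference",
]

#: the 11 niche-change drivers, in table order
DRIVER_NAMES = [
    "native_range_size",
    "native_range_loss",
    "dispersal",
    "fast_growth",
    "specialization",
    "introduction_effort",
    "residence_time",
    "alien_insularity",
    "human_disturbance",
    "native_richness",
    "community_similarity",
]

#: default per-response transform map: which covariate gets which transform
#: before standardization (binary covariates are passed through untouched)
DEFAULT_TRANSFORMS: dict[str, dict[str, str]] = {
    "unfilling": {
        "native_range_loss": "yeo-johnson",
        "introduction_effort": "yeo-johnson",
        "dispersal": "log",
        "native_range_size": "log",
        "native_richness": "log",
        "residence_time": "log",
        "human_disturbance": "log",
    },
    "expansion": {
        "human_disturbance": "yeo-johnson",
        "introduction_effort": "yeo-johnson",
        "native_range_loss": "yeo-johnson",
        "native_richness": "yeo-johnson",
        "native_range_size": "box-cox",
        "dispersal": "log",
        "residence_time": "log",
    },
}


# ---------------------------------------------------------------------------
# Covariate formulas


def introduction_effort(locations: int, pathways: int) -> float:
    """Propagule-pressure proxy: sqrt(locations x pathways).

    The product rewards species introduced at many locations through many
    pathways; the square root attenuates extremes.
    """
    if locations < 1 or pathways < 1:
        raise ContractError("locations and pathways must be >= 1")
    return float(np.sqrt(locations * pathways))


def specialization_index(foods: int, habitats: int) -> float:
    """``ln(100 / (foods x habitats))``: negative = generalist,
    positive = specialist."""
    if foods < 1 or habitats < 1:
        raise ContractError("foods and habitats must be >= 1")
    return float(np.log(100.0 / (foods * habitats)))


def residence_time(first_year: int, reference_year: int = 2021) -> int:
    """Years since first recorded introduction (reference year 2021)."""
    if first_year > reference_year:
        raise ContractError("first introduction year lies after the reference year")
    return int(reference_year - first_year)


# ---------------------------------------------------------------------------
# Transforms and screening


def _yeo_johnson(x: np.ndarray, lam: float) -> np.ndarray:
    return stats.yeojohnson(x, lmbda=lam)


def _box_cox(x: np.ndarray, lam: float) -> np.ndarray:
    return stats.boxcox(x, lmbda=lam)


def power_transform(
    values: np.ndarray,
    kind: str,
    lam: float | None = None,
    plus_one: bool = False,
) -> tuple[np.ndarray, float | None]:
    """Yeo-Johnson, Box-Cox, or log transform.

    For the power families, an absent ``lam`` is chosen by profile maximum
    likelihood (normality objective) over lambda in [-5, 5].  ``log``
    requires strictly positive values unless ``plus_one`` selects the
    ``log(x + 1)`` variant for zero-inflated counts.
    """
    x = np.asarray(values, dtype=float).ravel()
    if np.isnan(x).any():
        raise ContractError("values contain NaN")
    if kind == "log":
        if plus_one:
            if np.any(x < 0):
                bad = np.flatnonzero(x < 0)[:5]
                raise ContractError(f"log1p requires x >= 0 (rows {bad.tolist()})")
            return np.log1p(x), None
        if np.any(x <= 0):
            bad = np.flatnonzero(x <= 0)[:5]
            raise ContractError(f"log requires x > 0 (rows {bad.tolist()})")
        return np.log(x), None
    if kind == "box-cox":
        if np.any(x <= 0):
            bad = np.flatnonzero(x <= 0)[:5]
            raise ContractError(f"box-cox requires x > 0 (rows {bad.tolist()})")
        fn = _box_cox
    elif kind == "yeo-johnson":
        fn = _yeo_johnson
    else:
        raise ContractError(f"unknown transform kind {kind!r}")
    if lam is None:
        llf = (stats.boxcox_llf if kind == "box-cox"
               else stats.yeojohnson_llf)
        res = optimize.minimize_scalar(
            lambda l: -llf(l, x), bounds=(-5.0, 5.0), method="bounded",
            options={"xatol": 1e-6},
        )
        lam = float(res.x)
    return fn(x, lam), float(lam)


def shrink_to_open_interval(y: np.ndarray) -> np.ndarray:
    """Shrink a [0, 1] response into (0, 1) by ``(y (n-1) + 0.5) / n``.

    Applied only when exact 0 or 1 occur, so typical responses pass through
    unchanged; the beta likelihood is undefined at the boundary.
    """
    y = np.asarray(y, dtype=float).ravel()
    if np.any(y < 0) or np.any(y > 1):
        raise ContractError("response must lie in [0, 1]")
    if np.any(y == 0.0) or np.any(y == 1.0):
        n = len(y)
        y = (y * (n - 1) + 0.5) / n
    return y


def standardize(values: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to sample SD 1."""
    x = np.asarray(values, dtype=float).ravel()
    sd = x.std(ddof=1)
    if sd == 0:
        raise ContractError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def vif_screen(
    design: pd.DataFrame, threshold: float = 3.0
) -> tuple[list[str], pd.DataFrame]:
    """Iterative variance-inflation-factor screen.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing column j (with intercept) on
    the others; the max-VIF column is dropped while any VIF >= threshold.
    Perfectly collinear columns show unbounded VIF and go first.  Returns the
    retained column names and a per-iteration VIF table.
    """
    cols = list(design.columns)
    n = len(design)
    if n <= len(cols) + 1:
        raise ContractError("need more rows than columns + 1")
    records = []
    it = 0
    while True:
        X = design[cols].to_numpy(dtype=float)
        vifs = {}
        for j, name in enumerate(cols):
            yj = X[:, j]
            others = np.column_stack(
                [np.ones(n)] + [X[:, i] for i in range(len(cols)) if i != j]
            )
            beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
            resid = yj - others @ beta
            tss = float(np.sum((yj - yj.mean()) ** 2))
            if tss == 0:
                vifs[name] = np.inf
                continue
            r2 = 1.0 - float(np.sum(resid ** 2)) / tss
            vifs[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        for name, v in vifs.items():
            records.append({"iteration": it, "variable": name, "vif": v})
        worst = max(vifs, key=lambda nm: vifs[nm])
        if vifs[worst] >= threshold and len(cols) > 1:
            logger.info("VIF screen drops %s (VIF=%.3g)", worst, vifs[worst])
            cols.remove(worst)
            it += 1
        else:
            break
    return cols, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Information-theoretic machinery


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: ``-2 logLik + 2k + 2k(k+1)/(n-k-1)``."""
    if n - k - 1 <= 0:
        raise ContractError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: np.ndarray) -> np.ndarray:
    """``w_i = exp(-Delta_i / 2)`` normalized to sum 1."""
    a = np.asarray(aicc_values, dtype=float)
    d = a - a.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


def enumerate_subsets(
    variables: list[str], force: bool = False
) -> list[tuple[str, ...]]:
    """All 2^p additive fixed-effect subsets, including the intercept-only
    model; no interactions.  Refuses p > 20 unless forced."""
    p = len(variables)
    if p < 1:
        raise ContractError("need at least one variable")
    if p > 20 and not force:
        raise ContractError(f"2^{p} candidate models; pass force=True to proceed")
    out: list[tuple[str, ...]] = []
    for r in range(p + 1):
        out.extend(itertools.combinations(variables, r))
    return out


def nested_filter(
    candidates: list[tuple[tuple[str, ...], float]]
) -> list[tuple[tuple[str, ...], float]]:
    """Drop models that are more complex nested variants of better (or
    equally good) simpler models.

    A model M is removed when some model M' has a fixed-effect set strictly
    contained in M's and ``AICc(M') <= AICc(M)``.
    """
    sets = [frozenset(v) for v, _ in candidates]
    keep = []
    for i, (vars_i, a_i) in enumerate(candidates):
        nested_worse = any(
            sets[j] < sets[i] and candidates[j][1] <= a_i
            for j in range(len(candidates))
        )
        if not nested_worse:
            keep.append((vars_i, a_i))
    return keep


@dataclass
class CandidateSet:
    """Ranked all-subsets candidates with the non-nested confidence set."""

    table: pd.DataFrame        # variables, k, loglik, aicc, delta, weight, flags
    confidence: pd.DataFrame   # the non-nested Delta < cutoff subset, weights sum 1
    models: dict[tuple[str, ...], FittedModel]
    n_candidates: int
    n_nonnested: int
    n_confidence: int


@dataclass
class AveragedEstimates:
    """Full-model-averaged estimates over the confidence set."""

    table: pd.DataFrame  # variable, estimate, se, ci_low, ci_high, importance


def confidence_set_and_average(
    fitted: dict[tuple[str, ...], FittedModel],
    delta_cutoff: float = 4.0,
    variables: list[str] | None = None,
) -> tuple[CandidateSet, AveragedEstimates]:
    """Rank candidates by AICc, filter nested variants, cut at DeltaAICc,
    and full-average coefficients with Akaike weights.

    Full averaging substitutes zero for a coefficient (and its SE) in models
    that exclude the variable, shrinking weakly supported effects toward
    zero.  Unconditional SEs follow
    ``SE_j = sum_i w_i sqrt(SE_ij^2 + (b_ij - bbar_j)^2)``; intervals are
    normal-quantile (estimate +/- 1.96 SE); importance is the summed weight
    of confidence-set models containing the variable.
    """
    ok = {v: m for v, m in fitted.items() if m.converged}
    dropped = len(fitted) - len(ok)
    if dropped:
        logger.info("excluded %d non-convergent candidate(s) from ranking", dropped)
    if not ok:
        raise ContractError("no converged candidate models")
    rows = []
    for vars_, m in ok.items():
        rows.append({
            "variables": vars_,
            "k": m.k,
            "loglik": m.loglik,
            "aicc": aicc(m.loglik, m.k, m.n),
        })
    table = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    table["delta"] = table["aicc"] - table["aicc"].iloc[0]

    ranked = list(zip(table["variables"], table["aicc"]))
    nonnested = nested_filter(ranked)
    nn_set = {v for v, _ in nonnested}
    table["nonnested"] = [v in nn_set for v in table["variables"]]

    best_nn = min(a for _, a in nonnested)
    conf = [(v, a) for v, a in nonnested if a - best_nn < delta_cutoff]
    conf_vars = [v for v, _ in conf]
    conf_aicc = np.array([a for _, a in conf])
    w = akaike_weights(conf_aicc)
    confidence = pd.DataFrame({
        "variables": conf_vars,
        "aicc": conf_aicc,
        "delta": conf_aicc - conf_aicc.min(),
        "weight": w,
    })
    table["in_confidence_set"] = [v in set(conf_vars) for v in table["variables"]]

    if variables is None:
        variables = sorted({x for v in fitted for x in v})
    names = ["intercept"] + list(variables)
    est = np.zeros(len(names))
    se_u = np.zeros(len(names))
    importance = np.zeros(len(names))
    B = np.zeros((len(conf_vars), len(names)))
    S = np.zeros_like(B)
    for i, v in enumerate(conf_vars):
        m = ok[v]
        ct = m.coef_table()
        for j, name in enumerate(names):
            if name in ct:
                B[i, j], S[i, j] = ct[name]
                if name != "intercept":
                    importance[j] += w[i]
    importance[0] = 1.0
    est = w @ B
    se_u = np.array([
        float(np.sum(w * np.sqrt(S[:, j] ** 2 + (B[:, j] - est[j]) ** 2)))
        for j in range(len(names))
    ])
    avg = pd.DataFrame({
        "variable": names,
        "estimate": est,
        "se": se_u,
        "ci_low": est - 1.96 * se_u,
        "ci_high": est + 1.96 * se_u,
        "importance": importance,
    })
    cs = CandidateSet(
        table=table, confidence=confidence, models=ok,
        n_candidates=len(ok), n_nonnested=len(nonnested),
        n_confidence=len(conf),
    )
    return cs, AveragedEstimates(table=avg)


def observations_per_variable(n: int, p: int, minimum: float = 10.0) -> tuple[float, bool]:
    """Rule-of-thumb guard: observations per fixed-effect variable.

    Returns the ratio and whether it meets the minimum (warn below 10).
    """
    ratio = n / p
    ok = ratio >= minimum
    if not ok:
        logger.warning("only %.2f observations per variable (< %g)", ratio, minimum)
    return ratio, ok


# ---------------------------------------------------------------------------
# End-to-end driver inference


def prepare_design(
    table: pd.DataFrame,
    response: str,
    transforms: dict[str, str] | None = None,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Transform and standardize the covariates for one response.

    Binary covariates pass through untouched; every other covariate is
    transformed per the response's transform map (lambda by profile ML) and
    standardized to mean 0 / SD 1.
    """
    if variables is None:
        variables = [v for v in DRIVER_NAMES if v in table.columns]
    if transforms is None:
        transforms = DEFAULT_TRANSFORMS.get(response, {})
    out = {}
    for v in variables:
        x = table[v].to_numpy(dtype=float)
        if set(np.unique(x)) <= {0.0, 1.0}:
            out[v] = x  # binary: untouched
            continue
        kind = transforms.get(v)
        if kind is not None:
            x, _ = power_transform(x, kind)
        out[v] = standardize(x)
    return pd.DataFrame(out, index=table.index)


def _design_matrix(design: pd.DataFrame, subset: tuple[str, ...]) -> np.ndarray:
    n = len(design)
    if subset:
        return np.column_stack([np.ones(n)] + [design[v].to_numpy() for v in subset])
    return np.ones((n, 1))


def all_subsets_inference(
    design: pd.DataFrame,
    y: np.ndarray,
    family: str,
    factors: dict[str, np.ndarray] | None = None,
    delta_cutoff: float = 4.0,
    outer: str = "screen",
    force: bool = False,
) -> tuple[CandidateSet, AveragedEstimates, FittedModel]:
    """Fit every additive subset of the global model and full-average.

    The global model is fitted first with a tight variance-parameter
    optimization; if its random structure is singular, the documented
    fallback plan is applied before dredging.  Submodels keep the global
    random structure, warm-start their variance parameters at the global
    estimates (held fixed there under the default ``outer="screen"``
    profile), and every member of the resulting confidence set is refitted
    with a full variance-parameter optimization before ranking is finalized
    and estimates are averaged.
    """
    variables = list(design.columns)
    subsets = enumerate_subsets(variables, force=force)
    observations_per_variable(len(design), len(variables))

    factors = dict(factors or {})
    global_X = _design_matrix(design, tuple(variables))
    names = ["intercept"] + variables
    gm = fit_mixed_model(global_X, y, family, fixed_names=names,
                         factors=factors, outer="full")
    is_sing, plan = singularity_check(gm)
    if is_sing:
        for fallback in plan:
            fb = {f: factors[f] for f in fallback if f in factors}
            if set(fb) == set(factors):
                continue
            logger.info("singular global model; refitting with random terms %s",
                        sorted(fb) or "none")
            gm2 = fit_mixed_model(global_X, y, family, fixed_names=names,
                                  factors=fb, outer="full")
            if not gm2.singular or not fb:
                gm, factors = gm2, fb
                break
            gm, factors = gm2, fb

    theta0 = (np.log(np.maximum(list(gm.random_sds.values()), 1e-3))
              if gm.random_sds else None)
    gcoef = dict(zip(gm.fixed_names, gm.coef))
    fitted: dict[tuple[str, ...], FittedModel] = {}
    for subset in subsets:
        X = _design_matrix(design, subset)
        start = np.array([gcoef["intercept"]] + [gcoef[v] for v in subset])
        m = fit_mixed_model(
            X, y, family,
            fixed_names=["intercept"] + list(subset),
            factors=factors, outer=outer, theta_start=theta0,
            coef_start=start, phi_start=gm.phi or 5.0,
        )
        fitted[subset] = m
    cs, _ = confidence_set_and_average(fitted, delta_cutoff, variables)
    if factors and outer != "full":
        # refine: refit the confidence-set members with a tight outer
        # optimization before the weights and averages are finalized
        for subset in cs.confidence["variables"]:
            X = _design_matrix(design, subset)
            fitted[subset] = fit_mixed_model(
                X, y, family,
                fixed_names=["intercept"] + list(subset),
                factors=factors, outer="full", theta_start=theta0,
            )
    cs, avg = confidence_set_and_average(fitted, delta_cutoff, variables)
    return cs, avg, gm
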
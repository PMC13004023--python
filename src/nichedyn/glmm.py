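"""Mixed models for niche-change responses.

Binomial-logit and beta-logit regressions with independent random intercepts
are fitted by maximum likelihood with the random effects integrated out by a
Laplace approximation.  For a model with fixed effects ``beta`` and stacked
random intercepts ``u`` (one block per grouping factor, ``u_f ~ N(0,
sigma_f^2 I)``), the joint penalized log-likelihood

    pl(beta, u) = sum_i log f(y_i | eta_i) - 1/2 sum_f |u_f|^2 / sigma_f^2,
    eta = X beta + Z u,

is maximized by penalized Fisher scoring for given variance parameters, and
the marginal log-likelihood is approximated at the joint mode by

    l(theta) ~= pl(beta^, u^) - sum_f g_f log sigma_f - 1/2 log det H_uu,

with ``H_uu = Z'WZ + diag(1/sigma^2)`` the negative Hessian in ``u``.  The
variance parameters (log SDs) are optimized in an outer Nelder-Mead loop; the
beta-family precision ``phi`` is profiled at the joint mode by Newton steps
interleaved with the scoring iterations.  As every ``sigma_f -> 0`` the
approximation collapses exactly to the fixed-effects-only likelihood, which
is also how singular fits are detected.

Gaussian responses (used for the SDM-transferability regressions) go through
``statsmodels`` MixedLM (ML) behind the same result container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .core import ContractError

__all__ = [
    "FittedModel",
    "fit_mixed_model",
    "singularity_check",
    "SINGULARITY_TOL",
]

SINGULARITY_TOL = 1e-4  # link-scale SD below which a random term is singular


def _trigamma(x: np.ndarray) -> np.ndarray:
    """psi'(x), vectorized recurrence + asymptotic series.

    scipy's ``polygamma(1, .)`` goes through the Hurwitz zeta function and
    dominates the beta-family fit time; this direct evaluation is accurate
    to ~1e-12 and an order of magnitude faster.
    """
    x = np.asarray(x, dtype=float).copy()
    res = np.zeros_like(x)
    # push the argument above 6 with psi'(x) = psi'(x+1) + 1/x^2
    for _ in range(6):
        small = x < 6.0
        if not small.any():
            break
        res[small] += 1.0 / (x[small] * x[small])
        x[small] += 1.0
    z = 1.0 / (x * x)
    # asymptotic: 1/x + 1/(2x^2) + 1/(6x^3) - 1/(30x^5) + 1/(42x^7) - 1/(30x^9)
    series = (1.0 + 0.5 / x
              + z * (1.0 / 6.0 + z * (-1.0 / 30.0 + z * (1.0 / 42.0 - z / 30.0)))) / x
    return res + series


@dataclass
class FittedModel:
    """A fitted (mixed) regression model."""

    family: str                       # "binomial" | "beta" | "gaussian"
    fixed_names: list[str]
    coef: np.ndarray                  # (p,) fixed-effect estimates
    se: np.ndarray                    # (p,) standard errors
    random_sds: dict[str, float]      # grouping factor -> intercept SD
    phi: float | None                 # beta precision (None otherwise)
    loglik: float
    k: int                            # parameters counted for AICc
    n: int
    converged: bool
    singular: bool
    random_effects: dict[str, np.ndarray] = field(default_factory=dict)

    def coef_table(self) -> dict[str, tuple[float, float]]:
        return {
            name: (float(b), float(s))
            for name, b, s in zip(self.fixed_names, self.coef, self.se)
        }


# ---------------------------------------------------------------------------
# Families


class _Binomial:
    name = "binomial"
    has_phi = False

    @staticmethod
    def check(y: np.ndarray) -> None:
        if not np.isin(y, (0.0, 1.0)).all():
            raise ContractError("binomial response must be 0/1")

    @staticmethod
    def loglik(y, eta, phi=None):
        # y*eta - log(1 + e^eta), numerically stable
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    @staticmethod
    def score_weight(y, eta, phi=None):
        mu = special.expit(eta)
        return y - mu, np.maximum(mu * (1.0 - mu), 1e-10)


class _Beta:
    """Beta regression, mean-precision (mu, phi) with logit mean link."""

    name = "beta"
    has_phi = True

    @staticmethod
    def check(y: np.ndarray) -> None:
        if np.any(y <= 0.0) or np.any(y >= 1.0):
            raise ContractError("beta response must lie strictly in (0, 1)")

    @staticmethod
    def loglik(y, eta, phi):
        mu = special.expit(eta)
        a, b = mu * phi, (1.0 - mu) * phi
        return float(
            np.sum(
                special.gammaln(phi)
                - special.gammaln(a)
                - special.gammaln(b)
                + (a - 1.0) * np.log(y)
                + (b - 1.0) * np.log1p(-y)
            )
        )

    @staticmethod
    def score_weight(y, eta, phi):
        mu = special.expit(eta)
        dmu = mu * (1.0 - mu)
        ystar = np.log(y) - np.log1p(-y)
        mustar = special.digamma(mu * phi) - special.digamma((1.0 - mu) * phi)
        score = phi * (ystar - mustar) * dmu
        w = phi * phi * (
            _trigamma(mu * phi) + _trigamma((1.0 - mu) * phi)
        ) * dmu * dmu
        return score, np.maximum(w, 1e-10)

    @staticmethod
    def phi_step(y, eta, phi):
        """One Fisher-scoring step for phi on the log scale."""
        mu = special.expit(eta)
        a, b = mu * phi, (1.0 - mu) * phi
        g = np.sum(
            special.digamma(phi)
            - mu * special.digamma(a)
            - (1.0 - mu) * special.digamma(b)
            + mu * np.log(y)
            + (1.0 - mu) * np.log1p(-y)
        )
        info = np.sum(
            mu * mu * _trigamma(a)
            + (1.0 - mu) ** 2 * _trigamma(b)
            - _trigamma(np.full_like(a, phi))
        )
        if info <= 0:
            info = 1e-8
        step = g / (phi * info)  # d loglik / d log phi = phi*g; E[-H] = phi^2*info
        return float(np.clip(step, -1.5, 1.5))


_FAMILIES = {"binomial": _Binomial, "beta": _Beta}


# ---------------------------------------------------------------------------
# Penalized Fisher scoring for (beta, u) at fixed variance parameters


def _pirls(A, y, fam, p, penalty, v0, phi0, tol=1e-9, max_iter=60):
    """Maximize the penalized joint log-likelihood over (beta, u) [and phi].

    ``A`` is the combined design [X, Z]; ``penalty`` the diagonal of the
    quadratic penalty (0 for fixed effects, 1/sigma_f^2 for each random
    intercept).  Returns (v, phi, H, pl, converged).
    """
    v = v0.copy()
    phi = phi0
    eta = A @ v

    def pl(eta_, v_, phi_):
        return fam.loglik(y, eta_, phi_) - 0.5 * float(np.sum(penalty * v_ * v_))

    obj = pl(eta, v, phi)
    H = None
    converged = False
    for _ in range(max_iter):
        score, w = fam.score_weight(y, eta, phi)
        g = A.T @ score - penalty * v
        WA = A * w[:, None]
        H = A.T @ WA
        H[np.diag_indices_from(H)] += penalty
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            H[np.diag_indices_from(H)] += 1e-8
            delta = np.linalg.solve(H, g)
        # step-halving line search on the penalized objective
        step = 1.0
        for _ls in range(12):
            v_new = v + step * delta
            eta_new = A @ v_new
            obj_new = pl(eta_new, v_new, phi)
            if np.isfinite(obj_new) and obj_new >= obj - 1e-12:
                break
            step *= 0.5
        moved = float(np.max(np.abs(step * delta)))
        v, eta = v_new, eta_new
        if fam.has_phi:
            dlog = fam.phi_step(y, eta, phi)
            phi = float(phi * np.exp(dlog))
            phi = float(np.clip(phi, 1e-3, 1e6))
            moved = max(moved, abs(dlog))
        obj_prev, obj = obj, pl(eta, v, phi)
        if moved < 1e-8 or abs(obj - obj_prev) < tol * (1.0 + abs(obj)):
            converged = True
            break
    # final-state Hessian for the Laplace determinant and fixed-effect SEs
    score, w = fam.score_weight(y, eta, phi)
    WA = A * w[:, None]
    H = A.T @ WA
    H[np.diag_indices_from(H)] += penalty
    return v, phi, H, obj, converged


def _laplace_loglik(pl_val, H, penalty, p, group_sizes, log_sigmas):
    """Laplace marginal log-likelihood at the joint mode."""
    q = H.shape[0] - p
    if q == 0:
        return pl_val
    Huu = H[p:, p:]
    sign, logdet = np.linalg.slogdet(Huu)
    if sign <= 0:
        return -np.inf
    const = -float(np.sum(group_sizes * log_sigmas))
    return pl_val + const - 0.5 * logdet


def fit_mixed_model(
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    fixed_names: list[str] | None = None,
    factors: dict[str, np.ndarray] | None = None,
    outer: str = "full",
    theta_start: np.ndarray | None = None,
    coef_start: np.ndarray | None = None,
    phi_start: float = 5.0,
) -> FittedModel:
    """Fit a (mixed) regression by Laplace-approximated maximum likelihood.

    Parameters
    ----------
    X : (n, p) design matrix including the intercept column.
    y : (n,) response; 0/1 for ``binomial``, open-interval (0,1) for ``beta``.
    family : "binomial" or "beta".
    factors : mapping from grouping-factor name to an (n,) integer code
        array (0..g-1); each factor contributes an independent random
        intercept per level.  ``None`` or empty fits a plain GLM.
    outer : "full" for a tight outer optimization of the variance
        parameters, "fast" for a warm-started coarse search, or "screen"
        to hold them at ``theta_start`` entirely (used inside all-subsets
        screens, where the variance parameters move little between
        fixed-effect subsets; confidence-set members are refitted fully
        before any averaging).
    theta_start : starting log-SDs for the outer search.
    coef_start : warm start for the fixed effects.

    The parameter count ``k`` includes every estimated parameter: fixed
    effects, one variance per grouping factor, and the beta precision.
    """
    if family == "gaussian":
        return _fit_gaussian_lmm(X, y, fixed_names, factors)
    try:
        fam = _FAMILIES[family]
    except KeyError:
        raise ContractError(f"unknown family {family!r}") from None
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    fam.check(y)
    n, p = X.shape
    if fixed_names is None:
        fixed_names = [f"x{j}" for j in range(p)]
    factors = factors or {}
    names = list(factors)
    codes = [np.asarray(factors[f], dtype=np.intp) for f in names]
    sizes = np.array([c.max() + 1 if len(c) else 0 for c in codes], dtype=int)
    q = int(sizes.sum())

    # combined design [X | Z_1 | Z_2 | ...]
    A = np.empty((n, p + q), dtype=float)
    A[:, :p] = X
    offs = []
    off = p
    for c, g in zip(codes, sizes):
        block = np.zeros((n, g))
        block[np.arange(n), c] = 1.0
        A[:, off:off + g] = block
        offs.append((off, off + g))
        off += g

    v0 = np.zeros(p + q)
    if coef_start is not None:
        v0[:p] = coef_start
    phi0 = phi_start if fam.has_phi else None

    state = {"v": v0, "phi": phi0 if phi0 is not None else 0.0}

    def objective(log_sigmas: np.ndarray) -> float:
        log_sigmas = np.clip(log_sigmas, -12.0, 4.0)
        penalty = np.zeros(p + q)
        for (a, b), ls in zip(offs, log_sigmas):
            penalty[a:b] = np.exp(-2.0 * ls)
        v, phi, H, pl_val, _ = _pirls(
            A, y, fam, p, penalty, state["v"],
            state["phi"] if fam.has_phi else None,
        )
        state["v"], state["phi"] = v, (phi if fam.has_phi else 0.0)
        ll = _laplace_loglik(pl_val, H, penalty, p, sizes, log_sigmas)
        return -ll

    if q == 0:
        theta_hat = np.empty(0)
    elif outer == "screen":
        # hold the variance parameters at the warm start (typically the
        # global model's estimates, which move little across fixed-effect
        # subsets); precision and (beta, u) are still fully optimized
        theta_hat = (np.full(len(names), np.log(0.3))
                     if theta_start is None else np.asarray(theta_start, float))
    else:
        theta0 = (np.full(len(names), np.log(0.3))
                  if theta_start is None else np.asarray(theta_start, float))
        if outer == "fast":
            opts = {"xatol": 0.08, "fatol": 0.02, "maxfev": 12 * len(names) + 8,
                    "initial_simplex": _simplex(theta0, 0.4)}
        else:
            opts = {"xatol": 1e-3, "fatol": 1e-7, "maxfev": 400,
                    "initial_simplex": _simplex(theta0, 0.7)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(objective, theta0, method="Nelder-Mead",
                                    options=opts)
        theta_hat = np.clip(res.x, -12.0, 4.0)

    # final tight refit at the selected variance parameters
    penalty = np.zeros(p + q)
    for (a, b), ls in zip(offs, theta_hat):
        penalty[a:b] = np.exp(-2.0 * ls)
    v, phi, H, pl_val, conv = _pirls(
        A, y, fam, p, penalty, state["v"],
        state["phi"] if fam.has_phi else None, tol=1e-11, max_iter=100,
    )
    ll = _laplace_loglik(pl_val, H, penalty, p, sizes, theta_hat)

    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        conv = False

    sds = {f: float(np.exp(t)) for f, t in zip(names, theta_hat)}
    singular = any(s < SINGULARITY_TOL for s in sds.values())
    k = p + len(names) + (1 if fam.has_phi else 0)
    reff = {f: v[a:b].copy() for f, (a, b) in zip(names, offs)}
    return FittedModel(
        family=family,
        fixed_names=list(fixed_names),
        coef=v[:p].copy(),
        se=se,
        random_sds=sds,
        phi=float(phi) if fam.has_phi else None,
        loglik=float(ll),
        k=k,
        n=n,
        converged=bool(conv and np.isfinite(ll)),
        singular=bool(singular),
        random_effects=reff,
    )


def _simplex(x0: np.ndarray, step: float) -> np.ndarray:
    d = len(x0)
    s = np.tile(x0, (d + 1, 1))
    for i in range(d):
        s[i + 1, i] += step
    return s


# ---------------------------------------------------------------------------
# Gaussian LMM via statsmodels (ML)


def _fit_gaussian_lmm(X, y, fixed_names, factors):
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if fixed_names is None:
        fixed_names = [f"x{j}" for j in range(p)]
    factors = factors or {}
    if not factors:
        ols = sm.OLS(y, X).fit()
        k = p + 1  # + residual variance
        return FittedModel(
            family="gaussian", fixed_names=list(fixed_names),
            coef=np.asarray(ols.params), se=np.asarray(ols.bse),
            random_sds={}, phi=None, loglik=float(ols.llf), k=k, n=n,
            converged=True, singular=False,
        )
    # one grand group; each factor becomes an iid variance component
    df = pd.DataFrame(X, columns=[f"__x{j}" for j in range(p)])
    df["__y"] = y
    vcs = {}
    for name, codes in factors.items():
        df[f"__f_{name}"] = pd.Categorical(np.asarray(codes))
        vcs[name] = f"0 + C(__f_{name})"
    df["__grand"] = 1
    fixed = " + ".join([f"__x{j}" for j in range(p)]) or "1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            f"__y ~ 0 + {fixed}", groups="__grand", vc_formula=vcs, data=df
        )
        fit = model.fit(reml=False)
        if not fit.converged:
            fit = model.fit(reml=False, method="powell")
    sds = {
        name: float(np.sqrt(max(fit.vcomp[i], 0.0)))
        for i, name in enumerate(model.exog_vc.names)
    }
    singular = any(s < SINGULARITY_TOL for s in sds.values())
    k = p + len(sds) + 1
    return FittedModel(
        family="gaussian", fixed_names=list(fixed_names),
        coef=np.asarray(fit.fe_params), se=np.asarray(fit.bse_fe),
        random_sds=sds, phi=None, loglik=float(fit.llf), k=k, n=n,
        converged=bool(fit.converged), singular=bool(singular),
    )


# ---------------------------------------------------------------------------
# Singularity handling


def singularity_check(
    model: FittedModel, tolerance: float = SINGULARITY_TOL
) -> tuple[bool, list[list[str]]]:
    """Flag singular random structure and propose simpler refits.

    A fit is singular when any random-intercept SD collapses below
    ``tolerance`` on the link scale, indicating an over-parameterized random
    structure.  The returned plan lists fallback random structures to try in
    order: drop the singular terms; then a single ``species`` intercept (to
    retain control of pseudo-replication); then none.
    """
    singular = any(sd < tolerance for sd in model.random_sds.values())
    if not singular:
        return False, []
    keep = [f for f, sd in model.random_sds.items() if sd >= tolerance]
    plan: list[list[str]] = []
    if keep:
        plan.append(keep)
    if "species" not in model.random_sds:
        plan.append(["species"])
    plan.append([])
    return True, plan
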
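"""Phylogenetic generalized least squares with ML Pagel's λ.

The model is y = Xβ + ε, ε ~ N(0, σ²·V(λ)), where V(λ) is the Brownian
phylogenetic covariance matrix with its off-diagonal scaled by λ ∈ [0,1].
β and σ² are profiled analytically (GLS estimate and ML residual rate);
λ is found by bounded scalar maximisation of the profile log-likelihood

    lnL(λ) = −n/2·ln(2πσ̂²(λ)) − ½·ln|V(λ)| − n/2.

All solves go through the Cholesky factor of V (whitening); no explicit
matrix inverse is formed.  Model selection uses the small-sample-corrected
AIC (AICc) and Akaike weights; inference uses t-based confidence intervals
with the n/(n−p) unbiased variance adjustment for standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .phylo import PhyloTree, apply_lambda

__all__ = [
    "PGLSFit",
    "ModelComparison",
    "FitError",
    "gls_fit",
    "fit_lambda_ml",
    "aicc",
    "compare_models",
    "confidence_intervals",
    "multi_tree_pgls",
    "effect_size",
    "MultiTreeResult",
]


class FitError(ValueError):
    """Ill-posed regression input (rank deficiency, non-PD covariance, ...)."""


@dataclass
class PGLSFit:
    """One fitted (P)GLS model."""

    coef_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray          # unbiased-scaled covariance of beta
    ci_low: np.ndarray
    ci_high: np.ndarray
    lambda_hat: float
    sigma2_hat: float             # ML (n-denominator) residual rate
    lnl: float
    k: int                        # parameters counted in AICc (p + σ² [+ λ])
    n: int
    aicc: float
    rss_whitened: float           # residual SS in the V(λ̂)-whitened space
    r: float | None = None        # effect size vs the null model, if computed

    @property
    def p(self) -> int:
        return len(self.beta)

    @property
    def df_resid(self) -> int:
        return self.n - self.p

    def significant(self) -> np.ndarray:
        """Per-coefficient flag: 95% CI excludes zero."""
        return (self.ci_low > 0) | (self.ci_high < 0)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef_names,
                "estimate": self.beta,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "significant": self.significant(),
            }
        )


def aicc(lnl: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction.

    AICc = −2·lnL + 2k + 2k(k+1)/(n − k − 1); requires n > k + 1.
    """
    if n - k - 1 <= 0:
        raise FitError(f"AICc undefined: need n > k + 1, got n={n}, k={k}")
    return -2.0 * lnl + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    n, p = X.shape
    if n < p:
        raise FitError(f"more coefficients ({p}) than observations ({n})")
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise FitError(f"design matrix rank-deficient; collinear columns: {', '.join(bad)}")


def gls_fit(
    y: np.ndarray,
    X: np.ndarray,
    V: np.ndarray,
    coef_names: Sequence[str] | None = None,
    lambda_value: float = 1.0,
    count_lambda: bool = False,
    ci_level: float = 0.95,
) -> PGLSFit:
    """GLS fit at a fixed covariance matrix V.

    Whitens y and X by the Cholesky factor of V and solves the resulting OLS
    problem by QR; σ² is the ML profile estimate RSS/n and the log-likelihood
    is the profiled multivariate-normal likelihood.  Standard errors carry the
    n/(n−p) adjustment.  ``count_lambda`` adds one AICc parameter for λ when
    the caller estimated it.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.shape[0] != n or V.shape != (n, n):
        raise FitError(f"shape mismatch: y {y.shape}, X {X.shape}, V {V.shape}")
    names = list(coef_names) if coef_names is not None else [f"b{i}" for i in range(p)]
    _check_rank(X, names)
    if n == p:
        raise FitError(
            f"degenerate saturated model: n = p = {n}, residuals are exactly zero"
        )
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as e:
        raise FitError(f"covariance matrix not positive definite: {e}") from e
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    beta, _, _, _ = linalg.lstsq(Xw, yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2_ml <= 0:
        raise FitError("degenerate fit: zero whitened residual sum of squares")
    lnl = -0.5 * n * np.log(2.0 * np.pi * sigma2_ml) - 0.5 * logdetV - 0.5 * n
    XtX_inv = linalg.inv(Xw.T @ Xw)
    sigma2_unbiased = rss / (n - p) if n > p else np.nan
    cov_beta = sigma2_unbiased * XtX_inv
    se = np.sqrt(np.diag(cov_beta))
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df=n - p) if n > p else np.nan
    ci_low = beta - tcrit * se
    ci_high = beta + tcrit * se
    k = p + 1 + (1 if count_lambda else 0)
    # the AICc correction is undefined at tiny n; the fit itself is still valid
    aicc_val = aicc(float(lnl), k, n) if n - k - 1 > 0 else float("nan")
    return PGLSFit(
        coef_names=names,
        beta=beta,
        se=se,
        cov_beta=cov_beta,
        ci_low=ci_low,
        ci_high=ci_high,
        lambda_hat=float(lambda_value),
        sigma2_hat=sigma2_ml,
        lnl=float(lnl),
        k=k,
        n=n,
        aicc=aicc_val,
        rss_whitened=rss,
    )


def _profile_lnl(lam: float, y: np.ndarray, X: np.ndarray, V0: np.ndarray) -> float:
    Vl = apply_lambda(V0, lam)
    L = linalg.cholesky(Vl, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    beta, _, _, _ = linalg.lstsq(Xw, yw)
    resid = yw - Xw @ beta
    n = len(y)
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        return np.inf
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * logdet - 0.5 * n


def fit_lambda_ml(
    y: np.ndarray,
    X: np.ndarray,
    tree: PhyloTree | np.ndarray,
    taxa: Sequence[str] | None = None,
    coef_names: Sequence[str] | None = None,
    ci_level: float = 0.95,
    xatol: float = 1e-6,
) -> PGLSFit:
    """PGLS with Pagel's λ estimated by maximum likelihood on [0, 1].

    ``tree`` may be a :class:`PhyloTree` (``taxa`` gives the row order of y/X)
    or a precomputed Brownian VCV matrix.  The profile likelihood over λ is
    maximised by bounded Brent search with explicit endpoint checks at λ = 0
    and λ = 1.  AICc counts λ as an estimated parameter.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if isinstance(tree, PhyloTree):
        if taxa is None:
            raise FitError("taxa order required when fitting from a tree")
        _, V0 = tree.vcv(order=taxa)
    else:
        V0 = np.asarray(tree, dtype=float)
    res = optimize.minimize_scalar(
        lambda lam: -_profile_lnl(lam, y, X, V0),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": xatol},
    )
    if not res.success:
        raise FitError(f"λ optimisation failed to converge: {res.message}")
    candidates = [(float(res.x), -float(res.fun))]
    for lam in (0.0, 1.0):
        candidates.append((lam, _profile_lnl(lam, y, X, V0)))
    lam_hat, _ = max(candidates, key=lambda t: t[1])
    return gls_fit(
        y,
        X,
        apply_lambda(V0, lam_hat),
        coef_names=coef_names,
        lambda_value=lam_hat,
        count_lambda=True,
        ci_level=ci_level,
    )


def confidence_intervals(
    fit: PGLSFit, level: float = 0.95
) -> pd.DataFrame:
    """t-based CIs at an arbitrary level, with CI-excludes-zero significance."""
    if fit.df_resid <= 0:
        raise FitError("no residual degrees of freedom for confidence intervals")
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=fit.df_resid)
    low = fit.beta - tcrit * fit.se
    high = fit.beta + tcrit * fit.se
    return pd.DataFrame(
        {
            "coef": fit.coef_names,
            "estimate": fit.beta,
            "ci_low": low,
            "ci_high": high,
            "significant": (low > 0) | (high < 0),
        }
    )


def effect_size(fit: PGLSFit, null_fit: PGLSFit) -> float:
    """Effect size r = sqrt(1 − RSS(model)/RSS(null)), whitened residuals.

    Each model's residual sum of squares is taken in its own V(λ̂)-whitened
    space; r² is the share of (whitened) variance the predictors explain over
    the intercept-only model.
    """
    if null_fit.rss_whitened <= 0:
        raise FitError("null model has zero residual sum of squares")
    ratio = fit.rss_whitened / null_fit.rss_whitened
    return float(np.sqrt(np.clip(1.0 - ratio, 0.0, 1.0)))


@dataclass
class ModelComparison:
    """Ranked model set with ΔAICc, Akaike weights and evidence ratios."""

    table: pd.DataFrame  # columns: model, aicc, delta_aicc, weight, lambda, r, k

    def evidence_ratio(self, a: str, b: str) -> float:
        """How many times more likely model ``a`` is than model ``b``."""
        w = self.table.set_index("model")["weight"]
        return float(w[a] / w[b])

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["model"])


def compare_models(fits: dict[str, PGLSFit] | Sequence[tuple[str, PGLSFit]]) -> ModelComparison:
    """Rank models by AICc; weights w_i ∝ exp(−ΔAICc_i/2), summing to one.

    All fits must share the same response (same n).  Ties in ΔAICc rank by
    fewer parameters, then model name, for deterministic output.
    """
    items = list(fits.items()) if isinstance(fits, dict) else list(fits)
    if not items:
        raise FitError("no models to compare")
    ns = {f.n for _, f in items}
    if len(ns) != 1:
        raise FitError(f"models fitted on different sample sizes: {sorted(ns)}")
    rows = []
    for name, f in items:
        rows.append(
            {
                "model": name,
                "aicc": f.aicc,
                "lambda": f.lambda_hat,
                "r": f.r,
                "k": f.k,
            }
        )
    df = pd.DataFrame(rows)
    df["delta_aicc"] = df["aicc"] - df["aicc"].min()
    rel = np.exp(-0.5 * df["delta_aicc"])
    df["weight"] = rel / rel.sum()
    df = df.sort_values(
        ["delta_aicc", "k", "model"], kind="mergesort", ignore_index=True
    )
    df = df[["model", "aicc", "delta_aicc", "weight", "lambda", "r", "k"]]
    return ModelComparison(table=df)


def iteration_seed(master_seed: int, iteration: int) -> int:
    """Per-iteration RNG seed derived from the master seed and a counter."""
    return int(np.random.SeedSequence([master_seed, iteration]).generate_state(1)[0] % (2**31))


@dataclass
class MultiTreeResult:
    """PGLS aggregated over random polytomy resolutions of one tree."""

    per_iteration: pd.DataFrame  # iteration, seed, lnl, aicc, lambda, rss, coefs...
    mean_fit: PGLSFit            # coefficient-wise mean across iterations
    median_fit: PGLSFit
    n_failed: int = 0
    failures: list[str] = field(default_factory=list)


def _aggregate_fits(fits: list[PGLSFit], how: str) -> PGLSFit:
    agg = np.mean if how == "mean" else np.median
    f0 = fits[0]
    stack = lambda attr: np.array([getattr(f, attr) for f in fits])
    return PGLSFit(
        coef_names=f0.coef_names,
        beta=agg(stack("beta"), axis=0),
        se=agg(stack("se"), axis=0),
        cov_beta=agg(np.array([f.cov_beta for f in fits]), axis=0),
        ci_low=agg(stack("ci_low"), axis=0),
        ci_high=agg(stack("ci_high"), axis=0),
        lambda_hat=float(agg(stack("lambda_hat"))),
        sigma2_hat=float(agg(stack("sigma2_hat"))),
        lnl=float(agg(stack("lnl"))),
        k=f0.k,
        n=f0.n,
        aicc=float(agg(stack("aicc"))),
        rss_whitened=float(agg(stack("rss_whitened"))),
        r=None if f0.r is None else float(agg(np.array([f.r for f in fits]))),
    )


def multi_tree_pgls(
    y: np.ndarray,
    X: np.ndarray,
    tree: PhyloTree,
    taxa: Sequence[str],
    n_iter: int = 1000,
    seed: int = 0,
    coef_names: Sequence[str] | None = None,
    max_failure_rate: float = 0.01,
) -> MultiTreeResult:
    """λ-ML PGLS repeated over random polytomy resolutions.

    Each iteration resolves the tree's polytomies with a seed derived from
    ``seed`` and the iteration counter, then fits λ-ML PGLS.  Returns the
    per-iteration table plus across-iteration mean and median fits.  A binary
    input tree makes every iteration identical, so it is fitted once and the
    row replicated.  Individual iteration failures are recorded and excluded;
    more than ``max_failure_rate`` of them is a hard error.
    """
    if n_iter < 1:
        raise FitError("n_iter must be ≥ 1")
    binary = tree.is_binary
    fits: list[PGLSFit] = []
    rows: list[dict] = []
    failures: list[str] = []
    n_eff = 1 if binary else n_iter
    for it in range(n_eff):
        it_seed = iteration_seed(seed, it)
        try:
            resolved = tree if binary else tree.resolve_polytomies(it_seed)
            fit = fit_lambda_ml(y, X, resolved, taxa=taxa, coef_names=coef_names)
        except FitError as e:
            failures.append(f"iteration {it} (seed {it_seed}): {e}")
            continue
        fits.append(fit)
        row = {"iteration": it, "seed": it_seed, "lnl": fit.lnl, "aicc": fit.aicc,
               "lambda": fit.lambda_hat, "sigma2": fit.sigma2_hat,
               "rss_whitened": fit.rss_whitened}
        for nm, b, lo, hi in zip(fit.coef_names, fit.beta, fit.ci_low, fit.ci_high):
            row[f"beta_{nm}"] = b
            row[f"ci_low_{nm}"] = lo
            row[f"ci_high_{nm}"] = hi
        rows.append(row)
    if not fits or len(failures) > max_failure_rate * n_eff:
        raise FitError(
            f"{len(failures)}/{n_eff} iterations failed: " + "; ".join(failures[:5])
        )
    if binary and n_iter > 1:
        base = rows[0]
        rows = []
        for it in range(n_iter):
            r = dict(base)
            r["iteration"] = it
            r["seed"] = iteration_seed(seed, it)
            rows.append(r)
        fits = fits * n_iter
    return MultiTreeResult(
        per_iteration=pd.DataFrame(rows),
        mean_fit=_aggregate_fits(fits, "mean"),
        median_fit=_aggregate_fits(fits, "median"),
        n_failed=len(failures),
        failures=failures,
    )
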
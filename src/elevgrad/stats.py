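"""Inferential stage: collinearity screening, spatial GLS, LRT, ANODEV, smooths.

The band-level regressions treat the 49 elevational bands as observations
whose residuals may be spatially autocorrelated along the elevation axis.
The GLS here profiles a single correlation range parameter rho by maximum
likelihood: given rho, residual covariance is sigma^2 * C(rho) with

    gaussian     C_ij = exp(-(d_ij / rho)^2)
    exponential  C_ij = exp(-d_ij / rho)
    spherical    C_ij = 1 - 1.5 d/rho + 0.5 (d/rho)^3   (0 beyond rho)

where d_ij is the absolute elevation distance between bands; beta and
sigma^2 have closed forms given rho, and rho is found by a bounded 1-D
search.  Structures are compared by AIC; nested fixed-effect terms are
tested by ML likelihood-ratio chi-square tests.

Count regressions use Poisson GLMs with a quasi-likelihood overdispersion
correction: sequential analysis of deviance with F statistics
(delta deviance / delta df) / phi, phi estimated as Pearson chi-square over
residual df of the full model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats as sps
from scipy.linalg import cho_factor, cho_solve

from .domain_io import ValidationError

CORRELATION_STRUCTURES = ("none", "gaussian", "exponential", "spherical")

_LOG2PI = np.log(2.0 * np.pi)


def correlation_matrix(structure: str, dist: np.ndarray, rho: float) -> np.ndarray:
    """Spatial correlation matrix for a distance matrix and range parameter rho."""
    if structure == "none":
        return np.eye(dist.shape[0])
    if rho <= 0:
        raise ValidationError("rho must be positive")
    r = dist / rho
    if structure == "gaussian":
        return np.exp(-(r ** 2))
    if structure == "exponential":
        return np.exp(-r)
    if structure == "spherical":
        c = 1.0 - 1.5 * r + 0.5 * r ** 3
        return np.where(dist < rho, c, 0.0)
    raise ValidationError(f"unknown correlation structure {structure!r}")


@dataclass
class GLSFit:
    """A fitted spatial GLS model (ML)."""

    params: pd.Series
    sigma2: float
    rho: float | None
    loglik: float
    aic: float
    k: int  # free parameters counted in AIC (betas + sigma2 [+ rho])
    n_obs: int
    structure: str
    residuals: np.ndarray
    fitted: np.ndarray
    at_boundary: bool = False
    # retained so reduced models can be refitted for LRTs
    _y: np.ndarray = field(default=None, repr=False)
    _design: pd.DataFrame = field(default=None, repr=False)
    _coords: np.ndarray = field(default=None, repr=False)

    @property
    def term_names(self) -> list[str]:
        return [t for t in self.params.index if t != "(Intercept)"]


def _design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    X = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
    names = ["(Intercept)"] + list(design.columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("singular design matrix")
    return X, names


def _profile_loglik(y, X, C):
    """Closed-form beta, sigma2 and ML log-likelihood given a correlation matrix."""
    n = len(y)
    try:
        cf = cho_factor(C, lower=True)
    except np.linalg.LinAlgError as e:
        raise ValidationError(f"correlation matrix not positive definite: {e}") from None
    Ci_X = cho_solve(cf, X)
    Ci_y = cho_solve(cf, y)
    XtCiX = X.T @ Ci_X
    beta = np.linalg.solve(XtCiX, X.T @ Ci_y)
    r = y - X @ beta
    sigma2 = float(r @ cho_solve(cf, r)) / n
    if not np.isfinite(sigma2):
        raise ValidationError("non-finite residual variance")
    sigma2 = max(sigma2, 1e-30)  # exact-fit designs: keep the likelihood finite
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ll = -0.5 * (n * (_LOG2PI + np.log(sigma2) + 1.0) + logdet)
    return beta, sigma2, float(ll)


def fit_gls(
    y,
    design: pd.DataFrame,
    coords,
    structure: str = "gaussian",
    rho: float | None = None,
    rho_bounds: tuple[float, float] | None = None,
) -> GLSFit:
    """Fit a spatial GLS by profile maximum likelihood.

    Parameters
    ----------
    y : response vector (already transformed upstream; zero-richness bands
        are excluded before any log transform).
    design : predictor table (an intercept is added internally).
    coords : 1-D band coordinates (elevation in meters) used for distances.
    structure : one of 'none', 'gaussian', 'exponential', 'spherical'.
    rho : fix the correlation range instead of optimizing it (profiling is
        skipped; rho is still counted as a free parameter only when it was
        optimized).
    """
    if structure not in CORRELATION_STRUCTURES:
        raise ValidationError(f"unknown correlation structure {structure!r}")
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite response values")
    X, names = _design_matrix(design)
    n, p = X.shape
    if n <= p + 1:
        raise ValidationError(f"too few observations (n={n}) for {p} coefficients")
    dist = np.abs(coords[:, None] - coords[None, :])

    at_boundary = False
    if structure == "none":
        C = np.eye(n)
        beta, sigma2, ll = _profile_loglik(y, X, C)
        rho_hat = None
        k = p + 1
    elif rho is not None:
        C = correlation_matrix(structure, dist, rho)
        np.fill_diagonal(C, 1.0)
        beta, sigma2, ll = _profile_loglik(y, X, C)
        rho_hat = float(rho)
        k = p + 1
    else:
        dpos = dist[dist > 0]
        if dpos.size == 0:
            raise ValidationError("all coordinates identical; cannot fit spatial structure")
        dmin, dmax = float(dpos.min()), float(dist.max())
        lo, hi = rho_bounds if rho_bounds else (dmin / 20.0, 5.0 * dmax)

        # no jitter: a near-singular correlation matrix must make the profile
        # likelihood fail rather than act as a spurious nugget
        def negll(log_rho: float) -> float:
            C = correlation_matrix(structure, dist, float(np.exp(log_rho)))
            try:
                return -_profile_loglik(y, X, C)[2]
            except (ValidationError, np.linalg.LinAlgError):
                return np.inf

        grid = np.linspace(np.log(lo), np.log(hi), 40)
        vals = np.array([negll(g) for g in grid])
        if not np.any(np.isfinite(vals)):
            raise ValidationError("likelihood non-finite over the entire rho grid")
        i = int(np.nanargmin(vals))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(negll, bounds=(a, b), method="bounded",
                                       options={"xatol": 1e-6})
        log_rho = float(res.x) if res.fun <= vals[i] else float(grid[i])
        rho_hat = float(np.exp(log_rho))
        if i == 0 or i == len(grid) - 1:
            at_boundary = True
            warnings.warn(
                f"rho optimizer at {structure} search boundary (rho={rho_hat:.3g})",
                stacklevel=2,
            )
        C = correlation_matrix(structure, dist, rho_hat)
        beta, sigma2, ll = _profile_loglik(y, X, C)
        k = p + 2
    fitted = X @ beta
    aic = -2.0 * ll + 2.0 * k
    return GLSFit(
        params=pd.Series(beta, index=names),
        sigma2=sigma2,
        rho=rho_hat,
        loglik=ll,
        aic=aic,
        k=k,
        n_obs=n,
        structure=structure,
        residuals=y - fitted,
        fitted=fitted,
        at_boundary=at_boundary,
        _y=y,
        _design=design,
        _coords=coords,
    )


def compare_correlation_structures(
    y,
    design: pd.DataFrame,
    coords,
    structures: tuple[str, ...] = CORRELATION_STRUCTURES,
) -> pd.DataFrame:
    """Fit one GLS per correlation structure and rank by AIC (winner first)."""
    rows = []
    fits: dict[str, GLSFit] = {}
    for s in structures:
        try:
            f = fit_gls(y, design, coords, structure=s)
            fits[s] = f
            rows.append({"structure": s, "aic": f.aic, "loglik": f.loglik,
                         "rho": f.rho, "k": f.k, "error": ""})
        except (ValidationError, np.linalg.LinAlgError) as e:
            rows.append({"structure": s, "aic": np.nan, "loglik": np.nan,
                         "rho": np.nan, "k": np.nan, "error": str(e)})
    out = pd.DataFrame(rows).sort_values("aic", na_position="last").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].min()
    out["best"] = out["delta_aic"] == 0
    out.attrs["fits"] = fits
    return out


@dataclass(frozen=True)
class TermTest:
    """One nested-model test record (LRT chi-square or ANODEV F)."""

    term: str
    df: int
    statistic: float
    p_value: float
    aic_reduced: float | None = None
    delta_aic: float | None = None


def lrt_term_tests(full_fit: GLSFit, drop_terms: list[str] | None = None) -> list[TermTest]:
    """Single-term deletion likelihood-ratio tests against the full ML fit.

    Each term is dropped in turn, the reduced model is refitted (rho
    re-optimized) and 2 * (logLik_full - logLik_reduced) is referred to a
    chi-square with df equal to the parameter-count difference.
    """
    if drop_terms is None:
        drop_terms = full_fit.term_names
    if not drop_terms:
        raise ValidationError("no terms to drop; full model vs itself is not a valid LRT")
    out = []
    for term in drop_terms:
        if term not in full_fit._design.columns:
            raise ValidationError(f"term {term!r} not in the full model design")
        reduced_design = full_fit._design.drop(columns=[term])
        red = fit_gls(
            full_fit._y, reduced_design, full_fit._coords,
            structure=full_fit.structure,
        )
        df = full_fit.k - red.k
        stat = 2.0 * (full_fit.loglik - red.loglik)
        if stat < 0:
            if stat < -1e-6:
                warnings.warn(f"negative LRT statistic for {term!r}: {stat:.3g}",
                              stacklevel=2)
            stat = 0.0
        out.append(
            TermTest(
                term=term,
                df=df,
                statistic=float(stat),
                p_value=float(sps.chi2.sf(stat, df)),
                aic_reduced=red.aic,
                delta_aic=red.aic - full_fit.aic,
            )
        )
    return out


def vif(design: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factors, VIF_k = 1 / (1 - R^2_k).

    R^2_k is from regressing predictor k on all the others (with intercept).
    Values above 10 are flagged as severe multicollinearity; perfect
    collinearity yields an infinite VIF with the offending predictor named.
    """
    if design.shape[1] < 2:
        raise ValidationError("VIF needs at least 2 predictors")
    if design.shape[0] <= design.shape[1]:
        raise ValidationError("VIF needs more observations than predictors")
    X = design.to_numpy(dtype=float)
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValidationError("constant column among tested predictors")
    rows = []
    for k, name in enumerate(design.columns):
        others = np.column_stack([np.ones(len(X)), np.delete(X, k, axis=1)])
        yk = X[:, k]
        beta, *_ = np.linalg.lstsq(others, yk, rcond=None)
        resid = yk - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yk - yk.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        v = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"variable": name, "vif": v, "severe": bool(v > 10)})
    return pd.DataFrame(rows)


def glm_poisson_anodev(
    y,
    design: pd.DataFrame,
    ordered_terms: list[str] | None = None,
) -> pd.DataFrame:
    """Sequential analysis of deviance for an overdispersed Poisson GLM.

    Terms are added in the stated order; each row reports the deviance drop
    and a quasi-likelihood F test, F = (delta deviance / delta df) / phi,
    with phi the Pearson dispersion of the full model.  Term order is the
    analysis choice (area and the null model are entered first to control
    for geometry before testing the ecological terms).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValidationError("counts must be non-negative")
    if ordered_terms is None:
        ordered_terms = list(design.columns)
    for t in ordered_terms:
        if t not in design.columns:
            raise ValidationError(f"term {t!r} not in design")
    n = len(y)
    if np.all(y == 0):
        # a saturated-at-zero response carries no deviance for any model
        rows = [{"term": "Null", "df": np.nan, "deviance": np.nan,
                 "resid_df": n - 1, "resid_deviance": 0.0,
                 "f_value": np.nan, "p_value": np.nan}]
        df_resid = n - 1
        for t in ordered_terms:
            df_resid -= 1
            rows.append({"term": t, "df": 1, "deviance": 0.0, "resid_df": df_resid,
                         "resid_deviance": 0.0, "f_value": np.nan, "p_value": np.nan})
        out = pd.DataFrame(rows)
        out.attrs["dispersion"] = np.nan
        out.attrs["full_fit"] = None
        return out

    def fit(cols: list[str]):
        X = np.column_stack([np.ones(n)] + [design[c].to_numpy(dtype=float) for c in cols])
        model = sm.GLM(y, X, family=sm.families.Poisson())
        res = model.fit(maxiter=200, tol=1e-10)
        if not res.converged:
            raise ValidationError(f"Poisson GLM failed to converge for terms {cols}")
        return res

    fits = [fit(ordered_terms[:i]) for i in range(len(ordered_terms) + 1)]
    full = fits[-1]
    phi = float(full.pearson_chi2 / full.df_resid) if full.df_resid > 0 else 1.0
    df_resid_full = int(full.df_resid)
    rows = [
        {
            "term": "Null",
            "df": np.nan,
            "deviance": np.nan,
            "resid_df": int(fits[0].df_resid),
            "resid_deviance": float(fits[0].deviance),
            "f_value": np.nan,
            "p_value": np.nan,
        }
    ]
    for i, term in enumerate(ordered_terms):
        d_df = int(fits[i].df_resid - fits[i + 1].df_resid)
        d_dev = float(fits[i].deviance - fits[i + 1].deviance)
        if d_df > 0 and phi > 0 and df_resid_full > 0:
            f_val = (d_dev / d_df) / phi
            p = float(sps.f.sf(f_val, d_df, df_resid_full))
        else:
            f_val, p = np.nan, np.nan
        rows.append(
            {
                "term": term,
                "df": d_df,
                "deviance": d_dev,
                "resid_df": int(fits[i + 1].df_resid),
                "resid_deviance": float(fits[i + 1].deviance),
                "f_value": f_val,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["dispersion"] = phi
    out.attrs["full_fit"] = full
    return out


@dataclass(frozen=True)
class PolynomialFit:
    """Least-squares polynomial fit on an orthogonalized basis."""

    coefficients: tuple[float, ...]  # orthonormal-basis coefficients, degree 1..d
    intercept: float
    r_squared: float
    p_value: float
    fitted: np.ndarray


def residual_elevation_fit(
    y_counts,
    partial_design: pd.DataFrame,
    elevations,
    degree: int = 3,
) -> PolynomialFit:
    """Cubic-polynomial trend of residual richness against elevation.

    A Poisson GLM of the counts on the partial design (typically band area
    and the null-model expectation) is fitted first; its deviance residuals
    are then regressed on an orthogonalized degree-3 polynomial of elevation,
    isolating the elevational pattern left after geometry is removed.
    """
    y_counts = np.asarray(y_counts, dtype=float)
    elev = np.asarray(elevations, dtype=float)
    if len(y_counts) < 5:
        raise ValidationError("need at least 5 observations")
    if np.ptp(elev) == 0:
        raise ValidationError("elevation vector is constant (degenerate basis)")
    Xp = np.column_stack([np.ones(len(y_counts)), partial_design.to_numpy(dtype=float)])
    glm = sm.GLM(y_counts, Xp, family=sm.families.Poisson()).fit(maxiter=200)
    resid = np.asarray(glm.resid_deviance, dtype=float)

    z = (elev - elev.mean()) / elev.std()
    V = np.vander(z, degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    basis = Q[:, 1:] * np.sqrt(len(z))  # orthonormalized, unit-variance columns
    X = sm.add_constant(basis)
    ols = sm.OLS(resid, X).fit()
    return PolynomialFit(
        coefficients=tuple(float(c) for c in ols.params[1:]),
        intercept=float(ols.params[0]),
        r_squared=float(ols.rsquared),
        p_value=float(ols.f_pvalue),
        fitted=np.asarray(ols.fittedvalues),
    )


def natural_spline_basis(x: np.ndarray, df: int, knots: np.ndarray | None = None) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (no intercept column).

    Knots sit at df+1 quantiles of x (including the extremes); the basis is
    linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    if df < 2:
        raise ValidationError("spline df must be >= 2")
    if knots is None:
        knots = np.quantile(x, np.linspace(0, 1, df + 1))
    knots = np.unique(np.asarray(knots, dtype=float))
    K = len(knots)
    if K < df + 1:
        raise ValidationError("duplicated x values leave too few distinct knots")

    def d(k: int) -> np.ndarray:
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - knots[K - 1], 0, None) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [x]
    dK2 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK2)
    return np.column_stack(cols)


@dataclass(frozen=True)
class SmoothFit:
    """A fixed-df natural cubic spline smooth."""

    fitted: np.ndarray
    se: np.ndarray
    df: int
    statistic: float  # F (gaussian) or scaled chi-square (poisson) for the smooth term
    p_value: float
    r_squared: float | None


def spline_smooth(x, y, df: int = 3, family: str = "gaussian") -> SmoothFit:
    """Fit y on a natural cubic spline of x with fixed df, for visualization fits.

    Gaussian responses are fitted by least squares with an F test of the
    smooth term; Poisson responses by IRLS with a quasi-likelihood chi-square
    (deviance-drop) test against the intercept-only model.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y differ in length")
    if len(x) <= df + 1:
        raise ValidationError(f"need n > df + 1 (n={len(x)}, df={df})")
    basis = natural_spline_basis(x, df)
    X = sm.add_constant(basis)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("duplicated x values reduce the basis below full rank")
    if family == "gaussian":
        fit = sm.OLS(y, X).fit()
        stat = float(fit.fvalue)
        p = float(fit.f_pvalue)
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov_params(), X))
        return SmoothFit(np.asarray(fit.fittedvalues), se, df, stat, p,
                         float(fit.rsquared))
    if family == "poisson":
        full = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=200)
        null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Poisson()).fit()
        phi = float(full.pearson_chi2 / full.df_resid) if full.df_resid > 0 else 1.0
        stat = float((null.deviance - full.deviance) / max(phi, 1e-12))
        p = float(sps.chi2.sf(stat, df))
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, full.cov_params(), X))
        se = se * np.asarray(full.mu)  # delta method to the response scale
        return SmoothFit(np.asarray(full.mu), se, df, stat, p, None)
    raise ValidationError(f"unknown family {family!r}")
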
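"""Power-law scaling model of regional volume against intracranial volume.

The model is

    VOI = alpha * ICV**beta + eps,      eps ~ N(0, sigma^2),

with additive homoscedastic noise: the scatter of a regional volume is taken
to be constant across head sizes, which is what volumetric data typically
show.  ``beta`` is the allometric scaling exponent (beta = 1 means the
region is strictly proportional to head size; beta < 1, sublinear growth).
Estimation is by nonlinear least squares; standard errors come from the
Gauss-Newton linearization, sigma2_hat * (J'J)^-1 with J the Jacobian of the
mean function at the optimum and sigma2_hat = SSE / (n - 2).

:class:`PowerLawRegressor` is the scikit-learn estimator; the module-level
functions (`fit_power_law`, `wald_ci`, `flag_nonproportional`,
`fit_all_regions`) are thin wrappers over it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import (
    IdentifiabilityError,
    InsufficientDataError,
    NumericError,
)
from .io import VolumeTable

logger = logging.getLogger(__name__)

__all__ = [
    "PowerLawFit",
    "PowerLawRegressor",
    "FitCollection",
    "profile_alpha",
    "fit_power_law",
    "wald_ci",
    "flag_nonproportional",
    "fit_all_regions",
]


@dataclass(frozen=True)
class PowerLawFit:
    """Result of one power-law fit on a single region.

    ``alpha`` is the scale constant (cc per cc**beta), ``beta`` the
    dimensionless scaling exponent; ``sigma2`` estimates the additive noise
    variance (cc^2) with ``df = n - 2`` residual degrees of freedom.
    """

    region: str | None
    n: int
    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    sigma2: float
    df: int
    sse: float
    ci_level: float
    ci_beta: tuple[float, float]
    converged: bool
    n_iter: int = 0
    message: str = ""


@dataclass
class FitCollection:
    """Batch fit output: one :class:`PowerLawFit` per region that could be
    fitted, plus a record of per-region failures."""

    fits: list[PowerLawFit] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)

    def __iter__(self) -> Iterator[PowerLawFit]:
        return iter(self.fits)

    def __len__(self) -> int:
        return len(self.fits)

    def __getitem__(self, region: str) -> PowerLawFit:
        for f in self.fits:
            if f.region == region:
                return f
        raise KeyError(region)


def profile_alpha(beta: float, icv: np.ndarray, voi: np.ndarray) -> float:
    """Least-squares scale constant for a fixed exponent.

    For fixed beta the model is linear in alpha, so the minimizer of
    sum (voi - alpha * icv**beta)^2 is closed-form:
    alpha = sum(voi * icv**beta) / sum(icv**(2*beta)).
    """
    icv = np.asarray(icv, dtype=float)
    voi = np.asarray(voi, dtype=float)
    if icv.shape != voi.shape or icv.size < 1:
        raise ValueError("icv and voi must be same-length, nonempty")
    with np.errstate(over="raise", invalid="raise"):
        try:
            p = icv**beta
            denom = float(np.sum(p * p))
            num = float(np.sum(voi * p))
        except FloatingPointError as exc:
            raise NumericError(f"icv**beta overflow at beta={beta}") from exc
    if not np.isfinite(denom) or denom == 0.0:
        raise NumericError(f"degenerate denominator at beta={beta}")
    return num / denom


def wald_ci(
    estimate: float, se: float, level: float = 0.95, df: int = np.inf
) -> tuple[float, float]:
    """t-based Wald interval: estimate +/- t_{df,(1+level)/2} * se."""
    if se < 0:
        raise ValueError("se must be nonnegative")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    q = stats.t.ppf((1 + level) / 2, df) if np.isfinite(df) else stats.norm.ppf((1 + level) / 2)
    half = q * se
    return (estimate - half, estimate + half)


def flag_nonproportional(fit: PowerLawFit) -> bool:
    """True when the exponent's confidence interval excludes 1.

    Uses the closed-interval convention: an endpoint exactly at 1 counts as
    containing 1 (not flagged).  Raises on unconverged fits, whose interval
    is not trustworthy.
    """
    if not fit.converged:
        raise ValueError(f"fit for region {fit.region!r} did not converge; flag undefined")
    lo, hi = fit.ci_beta
    return not (lo <= 1.0 <= hi)


def _grid_profile_search(
    z: np.ndarray, y: np.ndarray, lo: float = 0.0, hi: float = 3.0, step: float = 1e-3
) -> tuple[float, float]:
    """Fallback search: profile alpha on a beta grid, return best (alpha, beta).

    ``z`` is expected pre-scaled to geometric mean 1 so powers stay tame.
    """
    betas = np.arange(lo, hi + step / 2, step)
    logz = np.log(z)
    best = (np.inf, np.nan, np.nan)
    # chunked to bound memory at large n
    for start in range(0, betas.size, 256):
        bs = betas[start : start + 256]
        P = np.exp(np.outer(logz, bs))  # n x chunk
        denom = np.einsum("ij,ij->j", P, P)
        num = y @ P
        alphas = num / denom
        sse = np.sum(y * y) - alphas * num  # ||y||^2 - alpha * <y, p> at LS alpha
        j = int(np.argmin(sse))
        if sse[j] < best[0]:
            best = (float(sse[j]), float(alphas[j]), float(bs[j]))
    return best[1], best[2]


class PowerLawRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares estimator of VOI = alpha * ICV**beta + eps.

    Parameters
    ----------
    ci_level : float, default 0.95
        Nominal level of the Wald interval reported by :meth:`confint`.
    init : tuple (alpha0, beta0) or None
        Optional starting point on the original ICV scale.  By default the
        start comes from ordinary least squares on log(VOI) ~ log(ICV),
        which is the closely related multiplicative-noise model and lands
        near the optimum.
    max_iter : int, default 200
        Iteration cap for the Levenberg-Marquardt solver.
    tol : float, default 1e-10
        Relative SSE-change tolerance for convergence.
    grad_tol : float, default 1e-8
        Gradient sup-norm tolerance used to declare convergence.
    grid_fallback : bool, default True
        On solver failure, fall back to a grid search over beta in [0, 3]
        (step 1e-3) with alpha profiled in closed form, then re-polish.

    Attributes
    ----------
    alpha_, beta_ : float
        Estimates on the original cc scale.
    se_alpha_, se_beta_ : float
        Linearization standard errors.
    sigma2_ : float
        Residual variance estimate, SSE / (n - 2).
    sse_, df_, n_, converged_, n_iter_ : fit metadata.

    Notes
    -----
    ICV is internally divided by its sample geometric mean before fitting so
    that icv**beta stays O(1); alpha and its SE are transformed back.  beta
    and se_beta are invariant to that rescaling.
    """

    def __init__(
        self,
        ci_level: float = 0.95,
        init: tuple[float, float] | None = None,
        max_iter: int = 200,
        tol: float = 1e-10,
        grad_tol: float = 1e-8,
        grid_fallback: bool = True,
    ):
        self.ci_level = ci_level
        self.init = init
        self.max_iter = max_iter
        self.tol = tol
        self.grad_tol = grad_tol
        self.grid_fallback = grid_fallback

    # -- internals -------------------------------------------------------
    @staticmethod
    def _validate_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
        X = check_array(X, ensure_2d=False, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single ICV column")
            X = X[:, 0]
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        ok = np.isfinite(X) & np.isfinite(y)
        X, y = X[ok], y[ok]
        if X.size < 3:
            raise InsufficientDataError(
                f"need >= 3 paired observations, got {X.size}"
            )
        if np.any(X <= 0) or np.any(y <= 0):
            raise ValueError("ICV and VOI must be strictly positive")
        if np.ptp(X) == 0:
            raise IdentifiabilityError("ICV is constant; exponent not identifiable")
        return X, y

    def fit(self, X, y) -> "PowerLawRegressor":
        x, yv = self._validate_xy(X, y)
        n = x.size
        g = float(np.exp(np.mean(np.log(x))))  # geometric mean
        z = x / g
        logz = np.log(z)

        if self.init is not None:
            a0_orig, b0 = self.init
            a0 = a0_orig * g**b0  # to scaled coordinates
        else:
            # log-log OLS start
            b0, loga0 = np.polyfit(logz, np.log(yv), 1)
            a0 = float(np.exp(loga0))

        def resid(p):
            a, b = p
            return yv - a * np.exp(b * logz)

        def jac(p):
            a, b = p
            zb = np.exp(b * logz)
            return np.column_stack([-zb, -a * zb * logz])

        res = optimize.least_squares(
            resid,
            x0=np.array([a0, b0], dtype=float),
            jac=jac,
            method="lm",
            ftol=self.tol,
            xtol=1e-14,
            gtol=self.grad_tol * 1e-4,
            max_nfev=self.max_iter * 10,
        )
        def _ok(r) -> bool:
            # scipy status > 0 means ftol (relative SSE change < tol), xtol
            # or gtol was met; status 0 is the iteration cap.  Accept also a
            # tiny absolute gradient, which covers exact-interpolation fits.
            grad = r.jac.T @ r.fun
            return bool(r.status > 0) or float(np.max(np.abs(grad))) <= self.grad_tol

        a_hat, b_hat = res.x
        sse = 2.0 * res.cost
        converged = _ok(res)

        if not converged and self.grid_fallback:
            a_g, b_g = _grid_profile_search(z, yv)
            res2 = optimize.least_squares(
                resid,
                x0=np.array([a_g, b_g]),
                jac=jac,
                method="lm",
                ftol=self.tol,
                xtol=1e-14,
                gtol=self.grad_tol * 1e-4,
                max_nfev=self.max_iter * 10,
            )
            if 2.0 * res2.cost <= sse:
                res, a_hat, b_hat = res2, *res2.x
                sse = 2.0 * res2.cost
            converged = _ok(res)
            if not converged:
                logger.warning("power-law fit did not converge: %s", res.message)

        df = n - 2
        sigma2 = sse / df
        J = -jac(res.x)  # Jacobian of the mean function
        JtJ = J.T @ J
        try:
            cov_scaled = sigma2 * np.linalg.inv(JtJ)
        except np.linalg.LinAlgError as exc:
            raise IdentifiabilityError("singular J'J at the optimum") from exc

        # back-transform alpha to the original ICV scale: alpha = a_hat * g**(-b)
        lng = np.log(g)
        alpha = a_hat * g ** (-b_hat)
        grad_alpha = np.array([g ** (-b_hat), -a_hat * lng * g ** (-b_hat)])
        var_alpha = float(grad_alpha @ cov_scaled @ grad_alpha)
        se_alpha = float(np.sqrt(max(var_alpha, 0.0)))
        se_beta = float(np.sqrt(max(cov_scaled[1, 1], 0.0)))

        self.alpha_ = float(alpha)
        self.beta_ = float(b_hat)
        self.se_alpha_ = se_alpha
        self.se_beta_ = se_beta
        self.sigma2_ = float(sigma2)
        self.sse_ = float(sse)
        self.df_ = int(df)
        self.n_ = int(n)
        self.converged_ = converged
        self.n_iter_ = int(res.nfev)
        self.message_ = str(res.message)
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "beta_")
        X = check_array(X, ensure_2d=False, dtype=float)
        x = X[:, 0] if X.ndim == 2 else X
        return self.alpha_ * x**self.beta_

    def confint(self, level: float | None = None) -> tuple[float, float]:
        """Wald confidence interval for the scaling exponent."""
        check_is_fitted(self, "beta_")
        return wald_ci(self.beta_, self.se_beta_, level or self.ci_level, self.df_)

    def to_fit(self, region: str | None = None) -> PowerLawFit:
        check_is_fitted(self, "beta_")
        return PowerLawFit(
            region=region,
            n=self.n_,
            alpha=self.alpha_,
            beta=self.beta_,
            se_alpha=self.se_alpha_,
            se_beta=self.se_beta_,
            sigma2=self.sigma2_,
            df=self.df_,
            sse=self.sse_,
            ci_level=self.ci_level,
            ci_beta=self.confint(),
            converged=self.converged_,
            n_iter=self.n_iter_,
            message=self.message_,
        )


def fit_power_law(
    icv: Sequence[float],
    voi: Sequence[float],
    *,
    region: str | None = None,
    ci_level: float = 0.95,
    init: tuple[float, float] | None = None,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> PowerLawFit:
    """Fit VOI = alpha * ICV**beta + eps on one region; see
    :class:`PowerLawRegressor` for the algorithm."""
    est = PowerLawRegressor(ci_level=ci_level, init=init, max_iter=max_iter, tol=tol)
    est.fit(np.asarray(icv, dtype=float), np.asarray(voi, dtype=float))
    return est.to_fit(region)


def fit_all_regions(
    table: VolumeTable,
    *,
    ci_level: float = 0.95,
    group: str | None = None,
    **options,
) -> FitCollection:
    """Fit every region of a table independently.

    Each region uses its own non-missing (icv, voi) pairs; failures
    (constant ICV, too few subjects) are recorded per region and do not
    abort the batch.  No multiplicity adjustment is applied across regions.
    ``group`` restricts fitting to subjects with that ``group`` label (e.g.
    estimate exponents on a control group only).
    """
    if group is not None:
        if "group" not in table.data.columns:
            raise ValueError("table has no 'group' column")
        table = table.subset(table.data["group"] == group)
    out = FitCollection()
    for region in table.region_names:
        try:
            icv, voi = table.pairs(region)
            out.fits.append(
                fit_power_law(icv, voi, region=region, ci_level=ci_level, **options)
            )
        except Exception as exc:  # noqa: BLE001 - error isolation is the contract
            logger.warning("region %s failed: %s", region, exc)
            out.failures[region] = f"{type(exc).__name__}: {exc}"
    return out
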
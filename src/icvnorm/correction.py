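"""ICV-correction methods for regional volumes.

Implements the power-proportion correction VOI / ICV**b with the exponent b
estimated from the data, and the comparison methods it is benchmarked
against:

* ``proportion`` - the classical ratio VOI / ICV (assumes strict
  proportionality, b = 1);
* ``ancova_residual`` - residuals of OLS VOI ~ 1 + ICV (assumes linearity);
* ``ancova_quadratic`` - residuals of OLS VOI ~ 1 + ICV + ICV^2;
* ``loglog_residual`` - slope b_log of OLS log(VOI) ~ 1 + log(ICV),
  returned in ratio form VOI / ICV**b_log so it lives on the same scale as
  the power-proportion output (this is the multiplicative-noise analogue of
  the power-law model).

Residual methods are recentred at mean(VOI) by default so every method
returns numbers on an interpretable volume-like scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import IdentifiabilityError, InsufficientDataError
from .io import VolumeTable
from .powerlaw import FitCollection, PowerLawFit, fit_all_regions

METHODS = (
    "power_proportion",
    "proportion",
    "ancova_residual",
    "ancova_quadratic",
    "loglog_residual",
)

__all__ = [
    "METHODS",
    "CorrectedTable",
    "ICVCorrector",
    "apply_power_proportion",
    "apply_proportion",
    "apply_ancova_residual",
    "apply_ancova_quadratic",
    "apply_loglog_residual",
    "correct_table",
]


def _as_pos_arrays(voi, icv, min_n=1) -> tuple[np.ndarray, np.ndarray]:
    voi = np.asarray(voi, dtype=float).ravel()
    icv = np.asarray(icv, dtype=float).ravel()
    if voi.shape != icv.shape:
        raise ValueError("voi and icv lengths differ")
    if voi.size < min_n:
        raise InsufficientDataError(f"need >= {min_n} observations, got {voi.size}")
    if np.any(icv <= 0) or not np.all(np.isfinite(icv)):
        raise ValueError("icv must be strictly positive and finite")
    return voi, icv


def apply_power_proportion(voi, icv, b: float) -> np.ndarray:
    """Power-proportion correction: elementwise voi / icv**b.

    With b = 1 this is exactly the proportion method; with b = 0 the raw
    volumes come back unchanged.
    """
    voi, icv = _as_pos_arrays(voi, icv)
    if not np.isfinite(b):
        raise ValueError("exponent b must be finite")
    return voi / icv**b


def apply_proportion(voi, icv) -> np.ndarray:
    """Classical ratio correction voi / icv."""
    voi, icv = _as_pos_arrays(voi, icv)
    return voi / icv


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residuals and coefficients of OLS y ~ X (X includes the intercept)."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise IdentifiabilityError("design matrix is rank deficient")
    return y - X @ coef, coef


def apply_ancova_residual(voi, icv, recentre: bool = True) -> np.ndarray:
    """ANCOVA / residual correction: residuals of OLS voi ~ 1 + icv.

    With ``recentre`` (default) the mean of voi is added back so corrected
    values remain on the cc scale.
    """
    voi, icv = _as_pos_arrays(voi, icv, min_n=3)
    if np.ptp(icv) == 0:
        raise IdentifiabilityError("icv is constant")
    X = np.column_stack([np.ones_like(icv), icv])
    resid, _ = _ols_residuals(voi, X)
    return resid + voi.mean() if recentre else resid


def apply_ancova_quadratic(
    voi, icv, recentre: bool = True, return_diagnostics: bool = False
):
    """Quadratic ANCOVA correction: residuals of OLS voi ~ 1 + icv + icv^2.

    ICV is centred before squaring for conditioning.  With
    ``return_diagnostics`` a dict is also returned holding the quadratic
    coefficient, its two-sided p-value, and whether it is significant at
    0.05 -- the check for genuine curvature beyond a straight line.
    """
    voi, icv = _as_pos_arrays(voi, icv, min_n=4)
    if np.unique(icv).size < 3:
        raise IdentifiabilityError("need >= 3 distinct icv values for a quadratic")
    c = icv - icv.mean()
    X = np.column_stack([np.ones_like(c), c, c * c])
    resid, coef = _ols_residuals(voi, X)
    out = resid + voi.mean() if recentre else resid
    if not return_diagnostics:
        return out
    n, p = X.shape
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se_q = float(np.sqrt(cov[2, 2]))
    tval = coef[2] / se_q if se_q > 0 else 0.0
    pval = float(2 * stats.t.sf(abs(tval), n - p))
    diag = {
        "quadratic_coef": float(coef[2]),
        "quadratic_se": se_q,
        "p_value": pval,
        "significant_05": pval < 0.05,
    }
    return out, diag


def apply_loglog_residual(voi, icv, return_params: bool = False):
    """Log-log regression correction in ratio form.

    Fits OLS log(voi) ~ 1 + log(icv) and returns voi / icv**b_log, the
    back-transformed analogue of the power-proportion correction under
    multiplicative (log-normal) noise.
    """
    voi, icv = _as_pos_arrays(voi, icv, min_n=3)
    if np.any(voi <= 0):
        raise ValueError("voi must be strictly positive for the log transform")
    if np.ptp(icv) == 0:
        raise IdentifiabilityError("icv is constant")
    b_log, loga = np.polyfit(np.log(icv), np.log(voi), 1)
    corrected = voi / icv**b_log
    if return_params:
        return corrected, {"b_log": float(b_log), "log_alpha": float(loga)}
    return corrected


@dataclass
class CorrectedTable:
    """Long-format corrected volumes with the provenance to reproduce them.

    ``data`` columns: subject_id, region, method, corrected_value.
    ``parameters`` maps region -> the fitted quantities the correction used
    (the exponent b and its source, or regression coefficients).
    """

    data: pd.DataFrame
    method: str
    parameters: dict[str, dict] = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        df = self.data.copy()
        df["parameters"] = df["region"].map(
            lambda r: json.dumps(self.parameters.get(r, {}), sort_keys=True)
        )
        df.to_csv(path, index=False)


class ICVCorrector(TransformerMixin, BaseEstimator):
    """Head-size correction of regional volumes as a sklearn transformer.

    The input matrix X has ICV in column 0 and one regional volume per
    remaining column.  ``fit`` learns the per-region correction parameters
    (the power-law exponent, or OLS coefficients, depending on ``method``);
    ``transform`` returns the corrected regional columns (ICV column
    dropped), so the corrector can sit inside a sklearn pipeline upstream of
    any group-comparison model.

    Parameters
    ----------
    method : str
        One of ``power_proportion``, ``proportion``, ``ancova_residual``,
        ``ancova_quadratic``, ``loglog_residual``.
    exponent : float, array-like, or None
        Externally supplied exponent(s) for ``power_proportion`` (scalar
        shared by all regions, or one per region) -- e.g. estimated on a
        reference control group.  None (default) fits the exponent on the
        data passed to ``fit``.
    recentre : bool, default True
        Residual methods add back mean(voi) so outputs stay on the cc scale.
    ci_level : float, default 0.95
        Level for the exponent intervals stored in ``params_``.
    """

    def __init__(
        self,
        method: str = "power_proportion",
        exponent: float | Sequence[float] | None = None,
        recentre: bool = True,
        ci_level: float = 0.95,
    ):
        self.method = method
        self.exponent = exponent
        self.recentre = recentre
        self.ci_level = ci_level

    def _split(self, X) -> tuple[np.ndarray, np.ndarray]:
        X = check_array(X, ensure_min_features=2, dtype=float, ensure_all_finite=False)
        return X[:, 0], X[:, 1:]

    def fit(self, X, y=None) -> "ICVCorrector":
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        icv, V = self._split(X)
        n_regions = V.shape[1]
        exps = self.exponent
        if exps is not None and np.ndim(exps) == 0:
            exps = [float(exps)] * n_regions

        self.params_: list[dict] = []
        for j in range(n_regions):
            ok = np.isfinite(V[:, j])
            voi, x = V[ok, j], icv[ok]
            p: dict = {"method": self.method}
            if self.method == "power_proportion":
                if exps is not None:
                    p.update(b=float(exps[j]), b_source="supplied")
                else:
                    from .powerlaw import fit_power_law

                    f = fit_power_law(x, voi, ci_level=self.ci_level)
                    p.update(
                        b=f.beta, b_source="fitted", se_b=f.se_beta,
                        ci_b=list(f.ci_beta), alpha=f.alpha, converged=f.converged,
                    )
            elif self.method == "proportion":
                p.update(b=1.0, b_source="fixed")
            elif self.method == "ancova_residual":
                X1 = np.column_stack([np.ones_like(x), x])
                _, coef = _ols_residuals(voi, X1)
                p.update(intercept=float(coef[0]), slope=float(coef[1]),
                         mean_voi=float(voi.mean()))
            elif self.method == "ancova_quadratic":
                _, diag = apply_ancova_quadratic(voi, x, return_diagnostics=True)
                c0 = float(x.mean())
                xc = x - c0
                Xq = np.column_stack([np.ones_like(xc), xc, xc * xc])
                _, coef = _ols_residuals(voi, Xq)
                p.update(coef=[float(v) for v in coef], icv_centre=c0,
                         mean_voi=float(voi.mean()), **diag)
            elif self.method == "loglog_residual":
                _, lp = apply_loglog_residual(voi, x, return_params=True)
                p.update(**lp)
            self.params_.append(p)
        self.n_features_in_ = n_regions + 1
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        icv, V = self._split(X)
        out = np.full_like(V, np.nan)
        for j, p in enumerate(self.params_):
            ok = np.isfinite(V[:, j])
            voi, x = V[ok, j], icv[ok]
            if self.method in ("power_proportion", "proportion"):
                vals = voi / x ** p["b"]
            elif self.method == "ancova_residual":
                fittedv = p["intercept"] + p["slope"] * x
                vals = voi - fittedv + (p["mean_voi"] if self.recentre else 0.0)
            elif self.method == "ancova_quadratic":
                xc = x - p["icv_centre"]
                c = p["coef"]
                fittedv = c[0] + c[1] * xc + c[2] * xc * xc
                vals = voi - fittedv + (p["mean_voi"] if self.recentre else 0.0)
            else:  # loglog_residual
                vals = voi / x ** p["b_log"]
            out[ok, j] = vals
        return out


def correct_table(
    table: VolumeTable,
    method: str = "power_proportion",
    *,
    fits: FitCollection | dict[str, PowerLawFit] | None = None,
    exponent: float | None = None,
    recentre: bool = True,
    group: str | None = None,
) -> CorrectedTable:
    """Correct every region of a table by one method.

    For ``power_proportion`` the exponent per region comes from, in order of
    precedence: an explicit scalar ``exponent``; pre-computed ``fits`` (for
    example fitted on a reference group); otherwise a fresh fit on this
    table (optionally restricted to ``group``).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    records = []
    parameters: dict[str, dict] = {}
    if method == "power_proportion" and fits is None and exponent is None:
        fits = fit_all_regions(table, group=group)
    for region in table.region_names:
        sub = table.data[["icv", region]].dropna()
        icv = sub["icv"].to_numpy(float)
        voi = sub[region].to_numpy(float)
        if method == "power_proportion":
            if exponent is not None:
                b, src = float(exponent), "supplied"
            else:
                try:
                    f = fits[region] if isinstance(fits, FitCollection) else fits[region]
                except KeyError:
                    continue  # region had no usable fit
                b, src = f.beta, "fitted"
            vals = apply_power_proportion(voi, icv, b)
            parameters[region] = {"b": b, "b_source": src}
        elif method == "proportion":
            vals = apply_proportion(voi, icv)
            parameters[region] = {"b": 1.0, "b_source": "fixed"}
        elif method == "ancova_residual":
            vals = apply_ancova_residual(voi, icv, recentre=recentre)
            X1 = np.column_stack([np.ones_like(icv), icv])
            _, coef = _ols_residuals(voi, X1)
            parameters[region] = {
                "intercept": float(coef[0]), "slope": float(coef[1]),
                "mean_voi": float(voi.mean()), "recentre": recentre,
            }
        elif method == "ancova_quadratic":
            vals, diag = apply_ancova_quadratic(
                voi, icv, recentre=recentre, return_diagnostics=True
            )
            parameters[region] = {"recentre": recentre, **diag}
        else:
            vals, lp = apply_loglog_residual(voi, icv, return_params=True)
            parameters[region] = lp
        records.extend(
            {
                "subject_id": sid,
                "region": region,
                "method": method,
                "corrected_value": v,
            }
            for sid, v in zip(sub.index, vals)
        )
    return CorrectedTable(pd.DataFrame(records), method=method, parameters=parameters)
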
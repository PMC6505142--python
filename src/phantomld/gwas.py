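"""OLS fit of the marker-interaction model and the Wald test of the
interaction coefficient.

The empirical model is ``y = intercept + x1 b1 + x2 b2 + (x1*x2) b12
[+ covariates] + e``, fit by ordinary least squares with classical standard
errors.  The interaction regressor is the elementwise product of the
*centered* marker columns and is not re-centered — the intercept absorbs its
mean, which is exactly how the analytic moment matrix accounts for it.  The
two-sided Wald test of H0: b12 = 0 uses the t reference with n - p residual
degrees of freedom; at GWAS-scale n this is indistinguishable from the
normal reference, so the test stays calibrated even for the non-Gaussian
(three-component mixture) errors that imperfect LD induces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .phenotypes import PhenotypeVector

__all__ = [
    "FitResult",
    "TestResult",
    "CollinearityError",
    "fit_interaction_model",
    "wald_interaction_test",
]


class CollinearityError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


@dataclass
class FitResult:
    """OLS estimates of the interaction model."""

    estimates: np.ndarray
    standard_errors: np.ndarray
    term_names: tuple[str, ...]
    residual_variance: float
    n: int
    p: int

    @property
    def df_resid(self) -> int:
        return self.n - self.p

    def __getitem__(self, term: str) -> float:
        return float(self.estimates[self.term_names.index(term)])

    def se(self, term: str) -> float:
        return float(self.standard_errors[self.term_names.index(term)])


@dataclass
class TestResult:
    """Two-sided Wald test of the interaction coefficient."""

    statistic: float
    p_value: float
    df: int
    reject: bool
    alpha: float
    estimate: float
    standard_error: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "statistic": self.statistic,
                "p_value": self.p_value,
                "df": self.df,
                "alpha": self.alpha,
                "reject": self.reject,
                "estimate": self.estimate,
                "standard_error": self.standard_error,
            },
            indent=1,
        )


def fit_interaction_model(
    y: PhenotypeVector | np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: Sequence[str] = (),
    robust: bool = False,
) -> FitResult:
    """OLS fit of ``y ~ 1 + x1 + x2 + x1:x2 [+ covariates]``.

    ``x1`` and ``x2`` must be centered marker columns.  Classical standard
    errors (``sigma^2 (X'X)^{-1}``) by default; ``robust=True`` switches to
    HC0 heteroskedasticity-robust errors.

    Raises
    ------
    CollinearityError
        If the design matrix is rank deficient (e.g. duplicated markers).
    """
    yv = np.asarray(y.values if isinstance(y, PhenotypeVector) else y, dtype=float).ravel()
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if not (yv.size == x1.size == x2.size):
        raise ValueError("y, x1, x2 must have equal lengths")

    names = ["const", "x1", "x2", "x1:x2"]
    columns = [np.ones_like(yv), x1, x2, x1 * x2]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != yv.size:
            C = C.T
        if C.shape[0] != yv.size:
            raise ValueError("covariates must have one row per individual")
        cov_names = list(covariate_names) or [f"cov{k + 1}" for k in range(C.shape[1])]
        names += cov_names
        columns += [C[:, k] for k in range(C.shape[1])]
    X = np.column_stack(columns)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than parameters")

    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # locate the offending columns via pairwise correlations of the
        # non-constant regressors (covers the common duplicated-marker case)
        Xc = X[:, 1:] - X[:, 1:].mean(axis=0)
        sd = Xc.std(axis=0)
        bad: list[str] = [names[1 + k] for k in np.nonzero(sd == 0)[0]]
        ok = sd > 0
        if ok.sum() >= 2:
            corr = np.corrcoef(Xc[:, ok], rowvar=False)
            idx = np.nonzero(ok)[0]
            for a in range(len(idx)):
                for b_ in range(a + 1, len(idx)):
                    if abs(corr[a, b_]) > 1 - 1e-10:
                        bad += [names[1 + idx[a]], names[1 + idx[b_]]]
        detail = f" (collinear terms: {sorted(set(bad))})" if bad else ""
        raise CollinearityError(f"design matrix has rank {rank} < {p}{detail}")

    res = sm.OLS(yv, X).fit(cov_type="HC0" if robust else "nonrobust")
    return FitResult(
        estimates=np.asarray(res.params, dtype=float),
        standard_errors=np.asarray(res.bse, dtype=float),
        term_names=tuple(names),
        residual_variance=float(res.mse_resid),
        n=n,
        p=p,
    )


def wald_interaction_test(fit: FitResult, alpha: float = 0.05) -> TestResult:
    """Two-sided t test of H0: b12 = 0 at significance level ``alpha``."""
    from scipy import stats

    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    est = fit["x1:x2"]
    se = fit.se("x1:x2")
    if se <= 0 or not np.isfinite(se):
        raise ValueError("degenerate fit: interaction standard error is zero")
    t = est / se
    df = fit.df_resid
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(
        statistic=float(t),
        p_value=float(p),
        df=int(df),
        reject=bool(p < alpha),
        alpha=float(alpha),
        estimate=est,
        standard_error=se,
    )
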
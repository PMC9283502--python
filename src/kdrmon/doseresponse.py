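"""Three-parameter log-logistic dose-mortality fitting (binomial MLE).

The mortality law is

    p(x) = d / (1 + exp(-b * (ln x - ln e)))

with slope ``b`` (positive when mortality increases with dose), upper limit
``d`` in (0, 1] and LC50 ``e`` (the dose at which p = d/2).  The lower limit
is fixed at 0.  Counts of dead out of exposed at each positive concentration
are treated as binomial, and the parameters are estimated by maximum
likelihood; dose-0 control rows are excluded from the likelihood and only
validated (a warning flag is raised above 10% control mortality).

Inference is Wald/delta-method on the observed information: the LC50 is
optimised on the log scale and its standard error transformed back, the 95%
interval is e_hat +/- 1.96 * SE(e_hat) truncated at zero, and lack of fit is
the Pearson chi-square over positive-dose groups with groups - 3 degrees of
freedom (groups - 2 when the upper limit is pinned at 1).

Resistance ratios (RR, test LC50 / susceptible-reference LC50) and synergist
ratios (SR, LC50 alone / LC50 with synergist) are ratios of point estimates,
flagged significant when the two 95% intervals do not overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .errors import ConvergenceError, InferenceError, NonIdentifiableError, ValidationError

_LL_TOL = 1e-8
_SLOPE_STARTS = (0.5, 1.0, 2.0, 4.0)
_D_STARTS = (0.9, 1.0)


@dataclass(frozen=True)
class BioassayRecord:
    """One dose group of a bioassay: exposed and dead counts at one dose."""

    population: str
    treatment: str
    dose: float  # ug/ml; 0 allowed for control rows
    n_exposed: int
    n_dead: int

    def __post_init__(self):
        if not 0 <= self.n_dead <= self.n_exposed:
            raise ValidationError(
                f"{self.population}: n_dead {self.n_dead} outside [0, {self.n_exposed}]"
            )
        if self.dose < 0:
            raise ValidationError(f"{self.population}: negative dose {self.dose}")


@dataclass
class DoseResponseFit:
    """A fitted LL.3 curve with covariance and lack-of-fit diagnostics."""

    b: float
    d: float
    e: float
    covariance: np.ndarray  # on the (b, ln e, d) scale; 2x2 when d fixed
    slope_se: float
    chi2: float
    df: int
    lc50_se: float
    lc50_ci: tuple[float, float]
    d_fixed: bool = False
    control_mortality: float | None = None
    control_warning: bool = False
    loglik: float = float("nan")

    def predict(self, dose) -> np.ndarray:
        """Predicted mortality probability at each dose."""
        x = np.asarray(dose, dtype=float)
        return ll3(x, self.b, self.d, self.e)


def ll3(x, b, d, e):
    """LL.3 mortality law; p(e) = d/2 exactly."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        t = np.log(x) - np.log(e)
    return d * expit(b * t)


def _neg_loglik(theta, logx, y, n, d_fixed):
    if d_fixed:
        b, loge = theta
        d = 1.0
    else:
        b, loge, d = theta
    p = d * expit(b * (logx - loge))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -np.sum(y * np.log(p) + (n - y) * np.log1p(-p))


def _pool(records: Sequence[BioassayRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray, float | None]:
    """Pool replicate counts per positive concentration; return control mortality."""
    df = pd.DataFrame(
        {"dose": [r.dose for r in records],
         "n": [r.n_exposed for r in records],
         "y": [r.n_dead for r in records]}
    )
    grouped = df.groupby("dose", sort=True).sum().reset_index()
    ctrl = grouped[grouped["dose"] == 0]
    control_mortality = None
    if len(ctrl):
        control_mortality = float(ctrl["y"].sum() / ctrl["n"].sum())
    pos = grouped[grouped["dose"] > 0]
    return (
        pos["dose"].to_numpy(float),
        pos["n"].to_numpy(float),
        pos["y"].to_numpy(float),
        control_mortality,
    )


def _hessian(fun, theta, eps=1e-5):
    """Central finite-difference Hessian."""
    k = len(theta)
    H = np.empty((k, k))
    h = eps * np.maximum(1.0, np.abs(theta))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            f = (
                fun(theta + ei + ej) - fun(theta + ei - ej)
                - fun(theta - ei + ej) + fun(theta - ei - ej)
            ) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = f
    return H


def fit_ll3(records: Sequence[BioassayRecord]) -> DoseResponseFit:
    """Fit the three-parameter log-logistic law by binomial ML.

    Uses a fixed multi-start schedule (slope in {0.5, 1, 2, 4}, upper limit
    in {0.9, 1.0}, LC50 across the observed dose range) with L-BFGS-B and a
    1e-8 log-likelihood tolerance.  If the upper-limit estimate is pushed to
    1, the model is refit with d fixed at 1 and the lack-of-fit degrees of
    freedom reduced accordingly (flagged via ``d_fixed``).
    """
    doses, n, y, control_mortality = _pool(records)
    if len(doses) < 3:
        raise ValidationError(f"need >=3 distinct positive concentrations, got {len(doses)}")
    total_rate = y.sum() / n.sum()
    if total_rate == 0.0 or total_rate == 1.0:
        raise NonIdentifiableError("all-alive or all-dead across doses")
    rates = y / n
    if rates.min() == rates.max():
        raise NonIdentifiableError("mortality identical at every dose; LC50 not identifiable")
    control_warning = control_mortality is not None and control_mortality > 0.10
    if control_warning:
        warnings.warn(
            f"control mortality {control_mortality:.1%} exceeds 10%", stacklevel=2
        )

    logx = np.log(doses)
    loge_starts = np.quantile(logx, [0.25, 0.5, 0.75])
    bounds3 = [(1e-3, 50.0), (logx.min() - 5, logx.max() + 5), (1e-6, 1.0)]

    best = None
    for b0 in _SLOPE_STARTS:
        for d0 in _D_STARTS:
            for le0 in loge_starts:
                res = optimize.minimize(
                    _neg_loglik, x0=[b0, le0, d0],
                    args=(logx, y, n, False),
                    method="L-BFGS-B", bounds=bounds3,
                    options={"ftol": _LL_TOL, "maxiter": 500},
                )
                if best is None or res.fun < best.fun - 1e-12:
                    best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("LL.3 optimisation failed on every start")

    d_fixed = best.x[2] >= 1.0 - 1e-6
    if d_fixed:
        bounds2 = bounds3[:2]
        best2 = None
        for b0 in _SLOPE_STARTS:
            for le0 in loge_starts:
                res = optimize.minimize(
                    _neg_loglik, x0=[b0, le0],
                    args=(logx, y, n, True),
                    method="L-BFGS-B", bounds=bounds2,
                    options={"ftol": _LL_TOL, "maxiter": 500},
                )
                if best2 is None or res.fun < best2.fun - 1e-12:
                    best2 = res
        best = best2
        theta = best.x
        b_hat, loge_hat, d_hat = theta[0], theta[1], 1.0
        nll = lambda t: _neg_loglik(t, logx, y, n, True)  # noqa: E731
    else:
        theta = best.x
        b_hat, loge_hat, d_hat = theta
        nll = lambda t: _neg_loglik(t, logx, y, n, False)  # noqa: E731

    H = _hessian(nll, theta)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise InferenceError("singular observed information") from exc
    diag = np.diag(cov)
    if not np.all(np.isfinite(diag)) or np.any(diag < 0):
        # boundary solutions can produce a non-PD Hessian; report NaN SEs
        cov = np.full_like(cov, np.nan)
        diag = np.diag(cov)

    e_hat = float(np.exp(loge_hat))
    slope_se = float(np.sqrt(diag[0])) if np.isfinite(diag[0]) else float("nan")
    # delta method: SE(e) = e * SE(ln e)
    lc50_se = float(e_hat * np.sqrt(diag[1])) if np.isfinite(diag[1]) else float("nan")

    groups = len(doses)
    df = groups - (2 if d_fixed else 3)
    p_hat = ll3(doses, b_hat, d_hat, e_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (y - n * p_hat) ** 2 / (n * p_hat * (1 - p_hat))
    chi2 = float(np.sum(terms[np.isfinite(terms)]))

    fit = DoseResponseFit(
        b=float(b_hat), d=float(d_hat), e=e_hat,
        covariance=cov, slope_se=slope_se, chi2=chi2, df=df,
        lc50_se=lc50_se, lc50_ci=(float("nan"), float("nan")),
        d_fixed=d_fixed, control_mortality=control_mortality,
        control_warning=control_warning, loglik=-float(best.fun),
    )
    fit.lc50_ci = lc50_interval(fit)
    return fit


def lc50_interval(fit: DoseResponseFit, level: float = 0.95) -> tuple[float, float]:
    """Delta-method Wald interval for the LC50, truncated at zero."""
    if not np.isfinite(fit.lc50_se):
        raise InferenceError("LC50 standard error unavailable (singular covariance)")
    z = float(stats.norm.ppf(1 - (1 - level) / 2))
    lo = max(0.0, fit.e - z * fit.lc50_se)
    hi = fit.e + z * fit.lc50_se
    return (lo, hi)


def lack_of_fit(fit: DoseResponseFit, records: Sequence[BioassayRecord]) -> tuple[float, int]:
    """Pearson chi-square of the fitted curve against the pooled dose groups."""
    doses, n, y, _ = _pool(records)
    p_hat = fit.predict(doses)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (y - n * p_hat) ** 2 / (n * p_hat * (1 - p_hat))
    chi2 = float(np.sum(terms[np.isfinite(terms)]))
    df = len(doses) - (2 if fit.d_fixed else 3)
    return chi2, df


@dataclass(frozen=True)
class RatioResult:
    """An LC50 ratio (RR or SR) with the CI-overlap significance rule."""

    kind: str  # "RR" or "SR"
    ratio: float
    significant: bool
    numerator_ci: tuple[float, float]
    denominator_ci: tuple[float, float]


def ratio(fit_num: DoseResponseFit, fit_den: DoseResponseFit, kind: str = "RR") -> RatioResult:
    """LC50 ratio of two fits; significant when the 95% CIs do not overlap."""
    if kind not in ("RR", "SR"):
        raise ValidationError(f"kind must be 'RR' or 'SR', got {kind!r}")
    r = fit_num.e / fit_den.e
    (alo, ahi), (blo, bhi) = fit_num.lc50_ci, fit_den.lc50_ci
    significant = ahi < blo or bhi < alo
    return RatioResult(kind, float(r), bool(significant), (alo, ahi), (blo, bhi))
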
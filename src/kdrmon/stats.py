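"""Genotype-phenotype association and resistance-allele-frequency statistics.

Covers the monitoring arithmetic applied to genotype count tables:

* resistant allele frequency, RAF = 100 * (2*hom_mut + het) / (2n);
* an exact two-sided Fisher test for 2 x k contingency tables, by full
  enumeration of the conditional (multivariate hypergeometric) distribution
  with the probability-ordering definition of "as or more extreme";
* allele-count odds ratios pre vs post application, with Wald CIs and a
  Haldane-Anscombe 0.5 correction (always flagged) on zero cells;
* a binomial logit GLM P(resistant allele) ~ time * location fit on
  allele-level data, whose saturated interaction structure reproduces the
  per-location raw-count odds ratios exactly; and
* the equal-weight marginal pooling contrast over locations (the
  estimated-marginal-means convention): the pooled odds ratio is the
  exponentiated equal-weight average of per-location post-minus-pre logit
  differences, i.e. the geometric mean of per-location odds ratios, with its
  CI taken from the averaged contrast's variance.

Each individual's two alleles are treated as independent Bernoulli
observations (no Hardy-Weinberg adjustment), matching the GLM convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb, exp, log, sqrt

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DegenerateTableError, EmptySampleError, ValidationError
from .loci import NINE_CLASSES

# ---------------------------------------------------------------------------
# count tables


@dataclass
class GenotypeCountTable:
    """Genotype counts for one (location, year, group) stratum.

    ``counts`` maps nine-class genotype strings to counts (the
    association-experiment shape); ``margins`` maps a locus aa position to
    (hom_wt, het, hom_mut) counts (the allele-trend shape).  Either may be
    supplied; margins are derived from the
    nine-class counts when absent.
    """

    location: str
    year: int
    group: str  # moribund / survivor / pre / post
    n: int
    counts: dict[str, int] | None = None
    margins: dict[int, tuple[int, int, int]] | None = None
    insecticide: str | None = None

    def __post_init__(self):
        if self.counts is None and self.margins is None:
            raise ValidationError("a count table needs nine-class counts or locus margins")
        if self.counts is not None:
            unknown = set(self.counts) - set(NINE_CLASSES)
            if unknown:
                raise ValidationError(f"unknown genotype classes: {sorted(unknown)}")
            total = sum(self.counts.values())
            if total != self.n:
                raise ValidationError(
                    f"{self.location} {self.year} {self.group}: "
                    f"genotype counts sum to {total}, n = {self.n}"
                )
        if self.margins is not None:
            for pos, (a, b, c) in self.margins.items():
                if a + b + c != self.n:
                    raise ValidationError(
                        f"{self.location} {self.year} {self.group}: locus {pos} "
                        f"margin sums to {a + b + c}, n = {self.n}"
                    )

    def locus_margin(self, aa_position: int) -> tuple[int, int, int]:
        """(hom_wt, het, hom_mut) counts at one locus."""
        if self.margins is not None and aa_position in self.margins:
            return self.margins[aa_position]
        if self.counts is None:
            raise ValidationError(f"no margin available for locus {aa_position}")
        if aa_position == 1014:
            keys = [("L/L", 0), ("L/F", 1), ("F/F", 2)]
            out = [0, 0, 0]
            for cls, cnt in self.counts.items():
                g = cls.split(":")[0]
                out[dict(keys)[g]] += cnt
        elif aa_position == 918:
            keys = {"M/M": 0, "M/I": 1, "I/I": 2}
            out = [0, 0, 0]
            for cls, cnt in self.counts.items():
                out[keys[cls.split(":")[1]]] += cnt
        else:
            raise ValidationError(f"cannot marginalise nine-class counts to locus {aa_position}")
        return tuple(out)

    def nine_class_vector(self) -> list[int]:
        if self.counts is None:
            raise ValidationError("table has no nine-class counts")
        return [self.counts.get(cls, 0) for cls in NINE_CLASSES]

    def allele_count(self, aa_position: int) -> "AlleleCount":
        hom_wt, het, hom_mut = self.locus_margin(aa_position)
        n_res = 2 * hom_mut + het
        return AlleleCount(aa_position=aa_position, n_res=n_res, n_sus=2 * self.n - n_res)


@dataclass(frozen=True)
class AlleleCount:
    """Resistant/susceptible allele counts at one locus (2 per individual)."""

    aa_position: int
    n_res: int
    n_sus: int


def raf(table: GenotypeCountTable, aa_position: int) -> float:
    """Resistant allele frequency, as a percentage in [0, 100]."""
    if table.n == 0:
        raise EmptySampleError(f"{table.location} {table.year} {table.group}: n = 0")
    hom_wt, het, hom_mut = table.locus_margin(aa_position)
    return 100.0 * (2 * hom_mut + het) / (2 * table.n)


# ---------------------------------------------------------------------------
# exact association test


def _support_weights(r1: int, cols: tuple[int, ...]):
    """Integer weights prop. to P(table | margins) over all row-1 fillings.

    Enumerates every (x_1, ..., x_k) with 0 <= x_j <= c_j and sum = r1 by
    depth-first recursion with feasibility pruning; the weight of a filling
    is prod_j C(c_j, x_j), and P = weight / C(n, r1).
    """
    k = len(cols)
    suffix = [0] * (k + 1)
    for j in range(k - 1, -1, -1):
        suffix[j] = suffix[j + 1] + cols[j]
    fillings: list[tuple[tuple[int, ...], int]] = []

    def recurse(j: int, remaining: int, prefix: tuple[int, ...], weight: int):
        if j == k:
            if remaining == 0:
                fillings.append((prefix, weight))
            return
        lo = max(0, remaining - suffix[j + 1])
        hi = min(cols[j], remaining)
        for x in range(lo, hi + 1):
            recurse(j + 1, remaining - x, prefix + (x,), weight * comb(cols[j], x))

    recurse(0, r1, (), 1)
    return fillings


def fisher_exact_2xk(
    table, mc_budget: int = 10_000_000, mc_draws: int = 1_000_000, mc_seed: int = 20220714
) -> float:
    """Exact two-sided Fisher p-value for a 2 x k contingency table.

    Conditions on both margins, enumerates the full conditional distribution
    and sums the probabilities of all tables no more probable than the
    observed one (ties included).  Zero-margin columns are dropped first; a
    table with an all-zero row is degenerate and raises.  When the pruned
    enumeration bound exceeds ``mc_budget`` fillings the p-value falls back
    to Monte Carlo over ``mc_draws`` multivariate-hypergeometric draws with
    the fixed, logged seed ``mc_seed``.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValidationError(f"expected a 2 x k table, got shape {t.shape}")
    if (t < 0).any():
        raise ValidationError("negative counts")
    t = t[:, t.sum(axis=0) > 0]
    if t.shape[1] == 0 or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("a margin of the table is zero")
    if t.shape[1] == 1:
        return 1.0
    r1 = int(t[0].sum())
    cols = tuple(int(c) for c in t.sum(axis=0))
    obs = tuple(int(x) for x in t[0])

    bound = 1
    for c in cols:
        bound *= c + 1
    if bound > mc_budget:
        return _fisher_monte_carlo(t, mc_draws, mc_seed)

    fillings = _support_weights(r1, cols)
    w_obs = next(w for x, w in fillings if x == obs)
    total = sum(w for _, w in fillings)
    num = sum(w for _, w in fillings if w <= w_obs)
    return num / total


def _fisher_monte_carlo(t: np.ndarray, draws: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    r1 = int(t[0].sum())
    cols = t.sum(axis=0)
    # log-probability of the observed table under the conditional law
    logw_obs = sum(_log_comb(c, x) for c, x in zip(cols, t[0]))
    samples = rng.multivariate_hypergeometric(cols, r1, size=draws)
    logw = np.zeros(draws)
    for j, c in enumerate(cols):
        logw += _log_comb_vec(c, samples[:, j])
    hits = int(np.sum(logw <= logw_obs + 1e-9))
    return (hits + 1) / (draws + 1)


def _log_comb(n, k):
    from math import lgamma

    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def _log_comb_vec(n, k):
    from scipy.special import gammaln

    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact(
    group_a: GenotypeCountTable, group_b: GenotypeCountTable
) -> float:
    """Exact association p between two phenotype groups' nine-class counts."""
    table = np.array([group_a.nine_class_vector(), group_b.nine_class_vector()])
    return fisher_exact_2xk(table)


# ---------------------------------------------------------------------------
# odds ratios


@dataclass(frozen=True)
class OddsRatioResult:
    """An odds ratio with Wald CI on the log scale."""

    estimate: float
    ci: tuple[float, float]
    log_se: float
    p: float
    pooling: str  # "single-location" or "equal-weight-over-locations"
    corrected: bool = False  # Haldane-Anscombe 0.5 applied


def allele_or(pre: AlleleCount, post: AlleleCount) -> OddsRatioResult:
    """Post-vs-pre odds ratio of resistant allele counts with Wald CI.

    Zero cells trigger a separation warning and the Haldane-Anscombe 0.5
    correction, flagged in the result.
    """
    cells = [post.n_res, post.n_sus, pre.n_res, pre.n_sus]
    corrected = any(c == 0 for c in cells)
    if corrected:
        warnings.warn(
            "zero allele count: applying Haldane-Anscombe 0.5 correction",
            stacklevel=2,
        )
        cells = [c + 0.5 for c in cells]
    a, b, c, d = cells
    log_or = log((a / b) / (c / d))
    se = sqrt(sum(1.0 / x for x in cells))
    z = log_or / se
    p = 2 * sps.norm.sf(abs(z))
    return OddsRatioResult(
        estimate=exp(log_or),
        ci=(exp(log_or - 1.96 * se), exp(log_or + 1.96 * se)),
        log_se=se,
        p=float(p),
        pooling="single-location",
        corrected=corrected,
    )


# ---------------------------------------------------------------------------
# binomial logit GLM over (time, location) with equal-weight pooling


@dataclass
class AlleleGlmFit:
    """A fitted logit model on allele-level data across locations and times."""

    params: pd.Series
    cov: pd.DataFrame
    locations: tuple[str, ...]
    converged: bool
    separation: bool

    def _contrast(self, location: str) -> np.ndarray:
        names = list(self.params.index)
        c = np.zeros(len(names))
        c[names.index("time_post")] = 1.0
        inter = f"time_post:loc_{location}"
        if inter in names:
            c[names.index(inter)] = 1.0
        return c

    def location_log_or(self, location: str) -> float:
        """Post-minus-pre logit difference for one location (= ln raw OR)."""
        return float(self._contrast(location) @ self.params.values)

    def location_or(self, location: str) -> float:
        return exp(self.location_log_or(location))


def fit_allele_glm(
    strata: list[tuple[str, AlleleCount, AlleleCount]]
) -> AlleleGlmFit:
    """Fit logit P(resistant) ~ time * location on allele-count data.

    ``strata`` is a list of (location, pre, post) allele counts.  The design
    is saturated in the 2 x L cells, so the converged coefficients reproduce
    each location's raw-count log odds ratio exactly.  Complete separation
    (a zero cell somewhere) is flagged; the affected cells receive the
    Haldane-Anscombe correction so the IRLS stays finite.
    """
    rows = []
    separation = False
    for location, pre, post in strata:
        for time, ac in (("pre", pre), ("post", post)):
            res, sus = float(ac.n_res), float(ac.n_sus)
            if res == 0 or sus == 0:
                separation = True
                res, sus = res + 0.5, sus + 0.5
            rows.append({"location": location, "time": time, "res": res, "sus": sus})
    data = pd.DataFrame(rows)
    locations = tuple(sorted(data["location"].unique()))
    if len(rows) < 2:
        raise ValidationError("need at least one location with pre and post samples")

    # hand-built treatment-coded design (reference = first location, time=pre)
    X_cols = ["intercept", "time_post"]
    X_cols += [f"loc_{l}" for l in locations[1:]]
    X_cols += [f"time_post:loc_{l}" for l in locations[1:]]
    X = pd.DataFrame(0.0, index=data.index, columns=X_cols)
    X["intercept"] = 1.0
    X.loc[data["time"] == "post", "time_post"] = 1.0
    for l in locations[1:]:
        in_loc = data["location"] == l
        X.loc[in_loc, f"loc_{l}"] = 1.0
        X.loc[in_loc & (data["time"] == "post"), f"time_post:loc_{l}"] = 1.0

    endog = data[["res", "sus"]].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # saturated designs trip df-resid warnings
        model = sm.GLM(endog, X.to_numpy(), family=sm.families.Binomial())
        fit = model.fit(maxiter=200, tol=1e-10)
    if not fit.converged:
        raise ValidationError("IRLS failed to converge")
    params = pd.Series(fit.params, index=X_cols)
    cov = pd.DataFrame(fit.cov_params(), index=X_cols, columns=X_cols)
    return AlleleGlmFit(
        params=params, cov=cov, locations=locations,
        converged=bool(fit.converged), separation=separation,
    )


def pooled_or(fit: AlleleGlmFit) -> OddsRatioResult:
    """Equal-weight marginal pooled odds ratio over locations.

    Averages the per-location (post - pre) logit contrasts with equal
    weights and exponentiates; equals the geometric mean of the per-location
    allele-count odds ratios.  The CI comes from the averaged contrast's
    variance under the fitted covariance.  With one location this equals
    :func:`allele_or` exactly.
    """
    C = np.mean([fit._contrast(l) for l in fit.locations], axis=0)
    est = float(C @ fit.params.values)
    var = float(C @ fit.cov.values @ C)
    se = sqrt(var)
    z = est / se
    p = 2 * sps.norm.sf(abs(z))
    return OddsRatioResult(
        estimate=exp(est),
        ci=(exp(est - 1.96 * se), exp(est + 1.96 * se)),
        log_se=se,
        p=float(p),
        pooling=(
            "single-location" if len(fit.locations) == 1
            else "equal-weight-over-locations"
        ),
        corrected=fit.separation,
    )


def model_raf(fit: AlleleGlmFit, time: str) -> tuple[float, tuple[float, float]]:
    """Equal-weight marginal RAF (%) at one time point, with 95% CI.

    The inverse-logit of the equal-weight average over locations of the
    linear predictor — the model-based companion to the raw RAF column.
    """
    names = list(fit.params.index)
    vecs = []
    for l in fit.locations:
        c = np.zeros(len(names))
        c[names.index("intercept")] = 1.0
        if f"loc_{l}" in names:
            c[names.index(f"loc_{l}")] = 1.0
        if time == "post":
            c[names.index("time_post")] = 1.0
            if f"time_post:loc_{l}" in names:
                c[names.index(f"time_post:loc_{l}")] = 1.0
        vecs.append(c)
    C = np.mean(vecs, axis=0)
    est = float(C @ fit.params.values)
    se = sqrt(float(C @ fit.cov.values @ C))
    inv = lambda t: 100.0 / (1.0 + exp(-t))  # noqa: E731
    return inv(est), (inv(est - 1.96 * se), inv(est + 1.96 * se))


# ---------------------------------------------------------------------------
# genotype-shift report


def genotype_shift(
    before: GenotypeCountTable, after: GenotypeCountTable
) -> pd.DataFrame:
    """Per-class percentages and percentage-point changes between two groups.

    Percentages are rounded to one decimal (report convention); the change
    column is after% - before%.
    """
    rows = []
    for cls in NINE_CLASSES:
        b = (before.counts or {}).get(cls, 0)
        a = (after.counts or {}).get(cls, 0)
        pb = round(100.0 * b / before.n, 1) if before.n else float("nan")
        pa = round(100.0 * a / after.n, 1) if after.n else float("nan")
        rows.append(
            {"genotype": cls, "before_n": b, "after_n": a,
             "before_pct": pb, "after_pct": pa,
             "change": round(pa - pb, 1) if before.n and after.n else float("nan")}
        )
    return pd.DataFrame(rows)
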
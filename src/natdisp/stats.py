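"""Statistical layer for natal-dispersal analyses.

Covers the distribution-free median CI (sign-test inversion), Rayleigh
tests of circular uniformity on dispersal bearings, Holm-adjusted Pearson
correlations, the two mixed-model sets with backward elimination of
non-significant interactions and quadratic terms, the density-by-year
trend model, the kernel-density mode of breeding densities, and the
natal density at which the fitted model predicts zero density difference.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lmm import LMMFit, fit_lmm

# ---------------------------------------------------------------------------
# Median confidence interval by sign-test inversion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MedianCI:
    median: float
    lower: float
    upper: float
    achieved_conf: float


def median_ci_sign(values, conf: float = 0.95) -> MedianCI:
    """Median with a distribution-free CI from inverting the sign test.

    The bounds are the order statistics x_(k+1) and x_(n-k) with k the
    largest integer whose Binomial(n, 1/2) lower tail is <= (1-conf)/2.
    The achieved confidence 1 - 2 P(X <= k) is reported; for small n no
    interval at the nominal level exists and the whole data range is
    returned with a warning.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("need at least one observation")
    alpha2 = (1.0 - conf) / 2.0
    cdf = sps.binom.cdf(np.arange(n + 1), n, 0.5)
    ks = np.nonzero(cdf <= alpha2)[0]
    if ks.size == 0:
        k = 0
        achieved = 1.0 - 2.0 * float(cdf[0])
        warnings.warn(
            f"n={n} too small for a {conf:.0%} sign-test CI; returning the "
            f"whole range (achieved confidence {achieved:.3f})")
    else:
        k = int(ks[-1])
        achieved = 1.0 - 2.0 * float(cdf[k])
    return MedianCI(float(np.median(x)), float(x[k]), float(x[n - 1 - k]), achieved)


# ---------------------------------------------------------------------------
# Circular statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircularTestResult:
    n: int
    mean_angle: float  # compass degrees in [0, 360)
    r: float  # mean resultant length
    p: float


def rayleigh_test(bearings) -> CircularTestResult:
    """Rayleigh test of uniformity for compass bearings (degrees).

    r is the mean resultant length; the p-value uses the standard series
    approximation of the Rayleigh statistic Z = n r^2.
    """
    theta = np.radians(np.asarray(bearings, dtype=float))
    n = theta.size
    if n < 3:
        raise ValueError("Rayleigh test needs at least 3 bearings")
    C = float(np.sum(np.cos(theta)))
    S = float(np.sum(np.sin(theta)))
    r = math.hypot(C, S) / n
    mean_angle = math.degrees(math.atan2(S, C)) % 360.0
    Z = n * r * r
    p = math.exp(-Z) * (
        1.0 + (2.0 * Z - Z * Z) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z ** 2 + 76.0 * Z ** 3 - 9.0 * Z ** 4) / (288.0 * n * n)
    )
    return CircularTestResult(n, mean_angle, r, float(min(max(p, 0.0), 1.0)))


# ---------------------------------------------------------------------------
# Pearson correlations with Holm adjustment
# ---------------------------------------------------------------------------

def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment of a family of p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def pearson_holm(pairs: Mapping[str, Tuple[Sequence, Sequence]]) -> pd.DataFrame:
    """Pearson correlations for a labelled family of (x, y) vector pairs.

    Returns r, the raw two-sided p and the Holm-adjusted p per label. A
    zero-variance vector yields an undefined (NaN) correlation, which is
    excluded from the adjustment family.
    """
    rows = []
    for label, (x, y) in pairs.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size or x.size < 3:
            raise ValueError(f"{label}: vectors must have equal length >= 3")
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"label": label, "n": x.size, "r": np.nan, "p_raw": np.nan})
            continue
        r, p = sps.pearsonr(x, y)
        rows.append({"label": label, "n": x.size, "r": float(r), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    mask = out["p_raw"].notna()
    if mask.any():
        out.loc[mask, "p_adj"] = holm_adjust(out.loc[mask, "p_raw"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Kernel-density mode
# ---------------------------------------------------------------------------

def kde_mode(values, gridsize: int = 512) -> float:
    """Mode of a distribution from a Gaussian KDE (rule-of-thumb bandwidth).

    The argmax is taken over a regular grid spanning the data range
    padded by three bandwidths.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("kde_mode needs at least 5 observations")
    if np.ptp(x) == 0:
        return float(x[0])
    kde = sps.gaussian_kde(x)
    h = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, gridsize)
    return float(grid[int(np.argmax(kde(grid)))])


# ---------------------------------------------------------------------------
# Scaled-log predictors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scaling:
    """Mean/SD pair used to z-score a (log-transformed) predictor."""

    mean: float
    sd: float

    def apply(self, values):
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def invert(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


def scaled_log(values) -> Tuple[np.ndarray, Scaling]:
    """Natural log followed by z-scoring; returns the scaled values and
    the scaling constants needed for back-transformation."""
    lv = np.log(np.asarray(values, dtype=float))
    sc = Scaling(float(lv.mean()), float(lv.std(ddof=1)))
    return sc.apply(lv), sc


# ---------------------------------------------------------------------------
# Mixed models with backward elimination
# ---------------------------------------------------------------------------

@dataclass
class CoefficientTable:
    """Fixed-effect table of a reduced mixed model plus fit metadata."""

    table: pd.DataFrame  # term, estimate, SE, df, t, p
    response: str
    reduction_path: list  # (dropped term, p at drop) in drop order
    re_var: Dict[str, float]
    sigma2: float
    singular: bool
    fit: LMMFit = field(repr=False, default=None)
    aliased: list = field(default_factory=list)  # columns dropped as collinear

    def estimate(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "estimate"])

    def __contains__(self, term: str) -> bool:
        return term in set(self.table["term"])


def _build_design(data: pd.DataFrame, main_effects: Sequence[str],
                  quadratic: Sequence[str], interactions: bool,
                  references: Optional[Mapping[str, str]]) -> Tuple[pd.DataFrame, dict]:
    """Expand model terms into design columns.

    Categorical mains become treatment dummies against the stated
    reference level; quadratics are squares of the (already scaled)
    numeric columns; interactions are products of every pair of
    main-effect columns.
    """
    references = references or {}
    cols: Dict[str, np.ndarray] = {"(Intercept)": np.ones(len(data))}
    main_cols: Dict[str, list] = {}
    for name in main_effects:
        s = data[name]
        if pd.api.types.is_numeric_dtype(s):
            cols[name] = s.to_numpy(dtype=float)
            main_cols[name] = [name]
        else:
            levels = list(pd.unique(s.astype(str)))
            ref = str(references.get(name, sorted(levels)[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {name}")
            main_cols[name] = []
            for lev in sorted(l for l in levels if l != ref):
                cname = f"{name}[{lev}]"
                cols[cname] = (s.astype(str) == lev).to_numpy(dtype=float)
                main_cols[name].append(cname)
    term_kind = {c: "main" for c in cols if c != "(Intercept)"}
    for name in quadratic:
        cname = f"{name}^2"
        cols[cname] = data[name].to_numpy(dtype=float) ** 2
        term_kind[cname] = "quadratic"
    if interactions:
        for a, b in itertools.combinations(main_effects, 2):
            for ca in main_cols[a]:
                for cb in main_cols[b]:
                    cname = f"{ca}:{cb}"
                    cols[cname] = cols[ca] * cols[cb]
                    term_kind[cname] = "interaction"
    return pd.DataFrame(cols, index=data.index), term_kind


def fit_lmm_reduced(data: pd.DataFrame, response: str,
                    main_effects: Sequence[str],
                    quadratic: Sequence[str] = (),
                    random: Sequence[str] = ("natal_territory", "natal_year"),
                    references: Optional[Mapping[str, str]] = None,
                    interactions: bool = True,
                    alpha: float = 0.05) -> CoefficientTable:
    """Fit a mixed model and reduce it by backward elimination.

    The initial model holds all main effects, the requested quadratic
    terms and all two-way interactions between main effects; crossed
    random intercepts for the factors in ``random``. Interactions, then
    quadratic terms, are dropped one at a time (largest p first, ties by
    term name) while p >= alpha; main effects are always retained. The
    drop order and p-values are recorded as the reduction path.
    """
    design, term_kind = _build_design(data, main_effects, quadratic,
                                      interactions, references)
    # drop aliased (collinear) columns, earlier terms taking priority:
    # intercept, mains, quadratics, then interactions
    kept, aliased = [], []
    for col in design.columns:
        trial = design[kept + [col]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(col)
        else:
            aliased.append(col)
    if aliased:
        warnings.warn(f"dropping aliased model terms: {aliased}")
    design = design[kept]
    re = {name: data[name].to_numpy() for name in random}
    path = []
    current = list(design.columns)

    def _refit(cols):
        return fit_lmm(data[response].to_numpy(dtype=float), design[cols], re)

    fit = _refit(current)
    for kind in ("interaction", "quadratic"):
        while True:
            droppable = [c for c in current if term_kind.get(c) == kind]
            if not droppable:
                break
            pvals = fit.pvalues[droppable]
            worst = sorted(pvals.index[pvals == pvals.max()])[0]
            if pvals[worst] < alpha:
                break
            path.append((worst, float(pvals[worst])))
            current.remove(worst)
            fit = _refit(current)

    table = pd.DataFrame({
        "term": current,
        "estimate": fit.params.to_numpy(),
        "SE": fit.bse.to_numpy(),
        "df": fit.df.to_numpy(),
        "t": fit.tvalues.to_numpy(),
        "p": fit.pvalues.to_numpy(),
    })
    return CoefficientTable(table=table, response=response,
                            reduction_path=path, re_var=fit.re_var,
                            sigma2=fit.sigma2, singular=fit.singular, fit=fit,
                            aliased=aliased)


# ---------------------------------------------------------------------------
# Density trend over years
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendResult:
    slope: float  # change in log density per year
    se: float
    df: float
    p: float
    fit: LMMFit = field(repr=False, default=None)


def density_trend(density_table: pd.DataFrame) -> TrendResult:
    """Yearly trend in log local density with a territory random intercept.

    Response log(density); year enters as a continuous covariate
    (centred internally for conditioning; the slope is unchanged).
    """
    tab = density_table
    years = tab["year"].to_numpy(dtype=float)
    if len(np.unique(years)) < 2:
        raise ValueError("density trend needs at least two years")
    X = pd.DataFrame({"(Intercept)": np.ones(len(tab)),
                      "year": years - years.mean()})
    y = np.log(tab["density"].to_numpy(dtype=float))
    terr = tab["territory_id"].to_numpy()
    if len(np.unique(terr)) < 2:
        warnings.warn("single territory: trend reduces to simple regression")
        fit = fit_lmm(y, X, {})
    else:
        fit = fit_lmm(y, X, {"territory_id": terr})
    return TrendResult(float(fit.params["year"]), float(fit.bse["year"]),
                       float(fit.df["year"]), float(fit.pvalues["year"]), fit)


# ---------------------------------------------------------------------------
# Zero-crossing of the density-difference model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZeroCrossing:
    density: float  # km^-2, back-transformed
    scaled_log_density: float
    in_range: bool


def zero_crossing_density(model: CoefficientTable, scaling: Scaling,
                          term: str = "log_natal_density",
                          observed_log_range: Optional[Tuple[float, float]] = None,
                          ) -> ZeroCrossing:
    """Natal density at which the fitted model predicts zero density difference.

    Evaluated at reference factor levels and mean (i.e. zero, after
    z-scoring) values of the other scaled covariates, so the prediction
    reduces to intercept + b1*z (+ b2*z^2 when the quadratic survived the
    reduction). The scaled-log root is back-transformed to km^-2 with the
    stored scaling constants. With no sign change (all slopes zero) the
    crossing is undefined and a ValueError is raised; a crossing outside
    the observed log-density range is flagged ``in_range=False``.
    """
    t = model.table.set_index("term")
    b0 = float(t.loc["(Intercept)", "estimate"])
    b1 = float(t.loc[term, "estimate"]) if term in t.index else 0.0
    b2 = float(t.loc[f"{term}^2", "estimate"]) if f"{term}^2" in t.index else 0.0
    if b1 == 0.0 and b2 == 0.0:
        raise ValueError("prediction is flat in natal density: no zero crossing")
    if b2 == 0.0:
        z = -b0 / b1
    else:
        disc = b1 * b1 - 4.0 * b2 * b0
        if disc < 0:
            raise ValueError("no real zero crossing")
        roots = ((-b1 - math.sqrt(disc)) / (2 * b2), (-b1 + math.sqrt(disc)) / (2 * b2))
        z = min(roots, key=abs)  # root nearest the covariate mean
    logd = float(scaling.invert(z))
    in_range = True
    if observed_log_range is not None:
        in_range = observed_log_range[0] <= logd <= observed_log_range[1]
    return ZeroCrossing(float(math.exp(logd)), float(z), in_range)
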
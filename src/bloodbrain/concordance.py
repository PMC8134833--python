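"""Correlation analyses: blood-brain concordance, score-trait relationships,
inter-region matrices, Pearson/Spearman sensitivity comparison and a
Monte-Carlo power calculator for the two-sided Pearson test.

All correlations use pairwise-complete deletion, report two-sided p-values
from the t-distribution with df = n - 2, and Fisher-z 95% confidence
intervals. Spearman is Pearson on average-ranked data with the same
t-approximation (an exact permutation p is available for very small n).
P-values are unadjusted; the report carries the number of tests instead.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from bloodbrain.io import BLOOD, BRAIN_REGIONS, SampleSheet

logger = logging.getLogger(__name__)

METHODS = ("pearson", "spearman")

#: n above which exact Spearman permutation p-values are refused (cost 8! = 40320).
_EXACT_N_MAX = 8


@dataclass
class CorrelationResult:
    """One correlation: coefficient, pairwise-complete n, test and CI.

    ``defined`` is False when n < 3 or either vector has zero variance; the
    numeric fields are then NaN rather than propagating silently.
    """

    var_x: str
    var_y: str
    method: str
    r: float
    n: int
    t_stat: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    defined: bool = True
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "var_x": self.var_x,
            "var_y": self.var_y,
            "method": self.method,
            "r": self.r,
            "n": self.n,
            "p": self.p,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "defined": self.defined,
        }


def pvalue_from_r(r: float, n: int) -> float:
    """Two-sided p for a correlation coefficient via t = r*sqrt(n-2)/sqrt(1-r^2),
    df = n - 2. Usable directly on printed (r, n) pairs."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return 2.0 * stats.t.sf(abs(t), n - 2)


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval tanh(atanh(r) +/- z/sqrt(n-3)).

    Degenerate for n <= 3 (returns the full [-1, 1] range)."""
    if n <= 3 or abs(r) >= 1.0:
        return (-1.0, 1.0) if abs(r) < 1.0 or n <= 3 else (r, r)
    z = stats.norm.ppf(0.5 + level / 2.0)
    zr = math.atanh(r)
    half = z / math.sqrt(n - 3)
    return (math.tanh(zr - half), math.tanh(zr + half))


def _undefined(var_x: str, var_y: str, method: str, n: int, note: str) -> CorrelationResult:
    nan = float("nan")
    return CorrelationResult(var_x, var_y, method, nan, n, nan, max(n - 2, 0), nan, nan, nan, defined=False, note=note)


def correlate(
    x,
    y,
    method: str = "pearson",
    var_x: str = "x",
    var_y: str = "y",
    exact: bool = False,
) -> CorrelationResult:
    """Correlate two vectors after pairwise-complete deletion.

    Pearson: product-moment coefficient. Spearman: Pearson on average
    ranks; with ``exact=True`` and n <= 8 the p-value is computed by full
    permutation enumeration instead of the t-approximation.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(keep.sum())
    if n < 3:
        return _undefined(var_x, var_y, method, n, "n < 3 after pairwise-complete deletion")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return _undefined(var_x, var_y, method, n, "zero variance")

    if method == "spearman":
        xr, yr = stats.rankdata(x), stats.rankdata(y)
    else:
        xr, yr = x, y
    r = float(np.corrcoef(xr, yr)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) >= 1.0:
        t_stat, p = math.inf if r > 0 else -math.inf, 0.0
    else:
        t_stat = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
        p = 2.0 * stats.t.sf(abs(t_stat), df)
    if method == "spearman" and exact:
        if n > _EXACT_N_MAX:
            logger.warning("exact spearman p requested at n=%d > %d: using t-approximation", n, _EXACT_N_MAX)
        else:
            p = _exact_spearman_p(xr, yr)
    lo, hi = fisher_ci(r, n)
    return CorrelationResult(var_x, var_y, method, r, n, t_stat, df, p, lo, hi)


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray) -> float:
    """Two-sided permutation p for the rank correlation at tiny n."""
    obs = abs(np.corrcoef(xr, yr)[0, 1])
    count = total = 0
    for perm in itertools.permutations(yr):
        total += 1
        if abs(np.corrcoef(xr, np.asarray(perm))[0, 1]) >= obs - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# Cohort-level assemblies


def measure_by_tissue(values: pd.DataFrame, sheet: SampleSheet, value_col: str = "value") -> pd.DataFrame:
    """Pivot a per-sample measure into an individuals x tissues frame.

    ``values`` needs columns ``sample_id`` and ``value_col``; tissue and
    individual come from the sample sheet. Missing samples produce NaN.
    """
    meta = sheet.frame[["sample_id", "individual_id", "tissue"]]
    merged = values.merge(meta, on="sample_id", how="inner")
    return merged.pivot(index="individual_id", columns="tissue", values=value_col)


def blood_brain_matrix(
    pivot: pd.DataFrame,
    measure: str,
    method: str = "pearson",
    regions: tuple[str, ...] = BRAIN_REGIONS,
) -> list[CorrelationResult]:
    """Correlate the blood column of a tissue pivot against each brain
    region, pairwise-complete (a region missing for one individual simply
    yields n - 1)."""
    if BLOOD not in pivot.columns:
        raise ValueError("pivot has no blood column")
    results = []
    for region in regions:
        if region not in pivot.columns:
            continue
        res = correlate(pivot[BLOOD], pivot[region], method=method,
                        var_x=f"{measure}:{BLOOD}", var_y=f"{measure}:{region}")
        results.append(res)
    return results


#: Which phenotype columns each measure is correlated against.
DEFAULT_TRAIT_PAIRS: dict[str, tuple[str, ...]] = {
    "smoking": ("pack_years", "smoking_status"),
    "cg05575921": ("pack_years", "smoking_status"),
    "HDL": ("hdl",),
    "alcohol": ("alcohol_units_week",),
    "BMI": ("bmi",),
}


def score_trait_correlations(
    pivot: pd.DataFrame,
    phenotypes: pd.DataFrame,
    measure: str,
    traits: tuple[str, ...] | None = None,
    method: str = "pearson",
) -> list[CorrelationResult]:
    """Correlate one measure (per tissue) against its mapped phenotype(s).

    ``pivot`` is individuals x tissues for the measure; ``phenotypes`` is
    indexed (or indexable) by individual_id. Individuals with a missing
    phenotype drop out pairwise, which is how the published pack-years
    analyses arrive at a smaller n than the cohort size.
    """
    if traits is None:
        traits = DEFAULT_TRAIT_PAIRS.get(measure)
        if traits is None:
            raise ValueError(f"no default trait mapping for measure {measure!r}")
    pheno = phenotypes.set_index("individual_id") if "individual_id" in phenotypes.columns else phenotypes
    results = []
    for trait_col in traits:
        trait_vals = pheno[trait_col].astype(float).reindex(pivot.index)
        for tissue in pivot.columns:
            res = correlate(pivot[tissue], trait_vals, method=method,
                            var_x=f"{measure}:{tissue}", var_y=trait_col)
            results.append(res)
    return results


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of correlations over tissue/region axes."""

    labels: list[str]
    r: pd.DataFrame
    results: dict[tuple[str, str], CorrelationResult]
    method: str

    def result(self, a: str, b: str) -> CorrelationResult:
        return self.results[(a, b)] if (a, b) in self.results else self.results[(b, a)]


def interregion_matrix(
    pivot: pd.DataFrame,
    method: str = "spearman",
    include_blood: bool = False,
) -> CorrelationMatrix:
    """Pairwise correlations of one measure across brain regions (and
    optionally blood). Diagonal is exactly 1; the matrix is symmetric."""
    labels = [c for c in pivot.columns if c in BRAIN_REGIONS]
    if include_blood and BLOOD in pivot.columns:
        labels = [BLOOD] + labels
    if len(labels) < 2:
        raise ValueError("need at least 2 regions")
    rmat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    results: dict[tuple[str, str], CorrelationResult] = {}
    for a, b in itertools.combinations(labels, 2):
        res = correlate(pivot[a], pivot[b], method=method, var_x=a, var_y=b)
        results[(a, b)] = res
        rmat.loc[a, b] = rmat.loc[b, a] = res.r
    return CorrelationMatrix(labels=labels, r=rmat, results=results, method=method)


def sensitivity_compare(
    pearson: list[CorrelationResult],
    spearman: list[CorrelationResult],
) -> pd.DataFrame:
    """Pair Pearson and Spearman runs of the same associations.

    Rows are matched on (var_x, var_y); columns give both coefficients, the
    rank of |r| under each method (1 = strongest), and ``top_agree`` — True
    on every row when both methods rank the same association strongest.
    """
    pmap = {(r.var_x, r.var_y): r for r in pearson}
    smap = {(r.var_x, r.var_y): r for r in spearman}
    keys = [k for k in pmap if k in smap]
    if not keys:
        raise ValueError("no shared associations between the two result sets")
    rows = []
    for k in keys:
        rows.append({"var_x": k[0], "var_y": k[1],
                     "r_pearson": pmap[k].r, "p_pearson": pmap[k].p,
                     "r_spearman": smap[k].r, "p_spearman": smap[k].p})
    df = pd.DataFrame(rows)
    df["rank_pearson"] = df["r_pearson"].abs().rank(ascending=False, method="min").astype(int)
    df["rank_spearman"] = df["r_spearman"].abs().rank(ascending=False, method="min").astype(int)
    top_p = df.loc[df["rank_pearson"].idxmin(), ["var_x", "var_y"]].tolist()
    top_s = df.loc[df["rank_spearman"].idxmin(), ["var_x", "var_y"]].tolist()
    df["top_agree"] = top_p == top_s
    return df


def results_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tidy report frame; annotates the number of tests performed (no
    multiple-testing adjustment is applied)."""
    df = pd.DataFrame([r.as_dict() for r in results])
    df["n_tests"] = len(results)
    return df


# ---------------------------------------------------------------------------
# Power


def correlation_power(
    n: int,
    rho: float,
    alpha: float = 0.05,
    n_sims: int = 2000,
    seed: int | None = None,
) -> dict[str, float]:
    """Monte-Carlo power of the two-sided Pearson test, with a Fisher-z
    closed-form cross-check.

    Returns ``power_mc`` (fraction of simulated datasets with p < alpha),
    its binomial standard error ``se_mc``, and ``power_fisher`` from the
    normal approximation of atanh(r).
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must be in (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    hits = 0
    for _ in range(n_sims):
        xy = rng.standard_normal((n, 2)) @ chol.T
        res = correlate(xy[:, 0], xy[:, 1], method="pearson")
        if res.defined and res.p < alpha:
            hits += 1
    power_mc = hits / n_sims
    se_mc = math.sqrt(max(power_mc * (1 - power_mc), 1e-12) / n_sims)

    z_alpha = stats.norm.ppf(1 - alpha / 2.0)
    mu = math.atanh(rho) * math.sqrt(n - 3)
    power_fisher = stats.norm.sf(z_alpha - mu) + stats.norm.cdf(-z_alpha - mu)
    return {"power_mc": power_mc, "se_mc": se_mc, "power_fisher": float(power_fisher)}
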
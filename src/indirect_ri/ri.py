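"""Nonparametric reference intervals, distribution summaries and bias ratios.

A reference interval (RI) is the central 95% of a reference population: the
2.5th and 97.5th sample percentiles, estimated by the CLSI-style rank method
``r = p·(n+1)`` with linear interpolation between order statistics.  Each
limit carries a 90% confidence interval from the distribution-free binomial
(order-statistic) method, with a seeded bootstrap fallback when the required
ranks fall outside 1..n.

An indirect RI is compared to a direct ("gold standard") RI through the bias
ratio: (indirect limit − direct limit) / sd_b, where the between-individual
SD is sd_b = (direct UL − direct LL)/3.92, i.e. the direct RI width mapped
back to a normal SD.  |ratio| ≤ 0.25 is allowable, ≤ 0.375 minimal, above
that unacceptable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Dataset, Stratum

logger = logging.getLogger(__name__)

#: decimals used in report tables, per analyte
REPORT_DECIMALS = {"creatinine": 1, "urea": 2, "uric_acid": 0}
RATIO_DECIMALS = 2

BIAS_ALLOWABLE = 0.25
BIAS_MINIMAL = 0.375


@dataclass(frozen=True)
class ReferenceInterval:
    n: int
    ll: float
    ul: float
    ll_ci90: tuple[float, float]
    ul_ci90: tuple[float, float]
    method: str = "nonparametric"

    def __post_init__(self) -> None:
        if self.ll > self.ul:
            raise ValueError("lower limit exceeds upper limit")

    @property
    def width(self) -> float:
        return self.ul - self.ll


@dataclass(frozen=True)
class DistributionSummary:
    n: int
    median: float
    mean: float
    sd: float
    skewness: float
    kurtosis: float   # excess


@dataclass(frozen=True)
class BiasAssessment:
    sd_b: float
    ratio_ll: float
    ratio_ul: float
    class_ll: str
    class_ul: str


def _rank_limit(sorted_x: np.ndarray, p: float) -> float:
    """Percentile by rank r = p(n+1), linearly interpolated, clamped to 1..n."""
    n = sorted_x.size
    r = p * (n + 1)
    if r <= 1:
        return float(sorted_x[0])
    if r >= n:
        return float(sorted_x[-1])
    lo = int(np.floor(r))
    frac = r - lo
    return float(sorted_x[lo - 1] + frac * (sorted_x[lo] - sorted_x[lo - 1]))


def _rank_ci(n: int, p: float, conf: float) -> Optional[tuple[int, int]]:
    """Narrowest symmetric-in-rank order-statistic pair (l, u), 1-based, with
    P(X_(l) <= xi_p <= X_(u)) >= conf; None if no in-range pair reaches conf."""
    r = p * (n + 1)
    l = max(1, int(np.floor(r)))
    u = min(n, max(l + 1, int(np.ceil(r))))

    def coverage(lo: int, hi: int) -> float:
        return stats.binom.cdf(hi - 1, n, p) - stats.binom.cdf(lo - 1, n, p)

    while coverage(l, u) < conf:
        grow_left = l > 1
        grow_right = u < n
        if not (grow_left or grow_right):
            return None
        if grow_left and (not grow_right or (r - l) <= (u - r)):
            l -= 1
        else:
            u += 1
    return l, u


def estimate_ri(values: np.ndarray, p_lo: float = 0.025, p_hi: float = 0.975,
                conf: float = 0.90, n_boot: int = 2000, seed: int = 0,
                ) -> ReferenceInterval:
    """Nonparametric RI with rank-based 90% CIs per limit.

    n < 20 is a hard error; n < 120 gets a validity warning (the rank CI for
    the 2.5th/97.5th percentile needs roughly 120 observations).
    """
    x = np.sort(np.asarray(values, float))
    n = x.size
    if n < 20:
        raise ValueError("reference interval needs at least 20 values")
    if n < 120:
        warnings.warn("n < 120: nonparametric 90% CIs may be unreliable")
    ll = _rank_limit(x, p_lo)
    ul = _rank_limit(x, p_hi)

    cis = []
    rng = np.random.default_rng(seed)
    for p, point in ((p_lo, ll), (p_hi, ul)):
        pair = _rank_ci(n, p, conf)
        if pair is not None:
            l, u = pair
            cis.append((float(x[l - 1]), float(x[u - 1])))
        else:  # bootstrap percentile fallback
            boot = np.empty(n_boot)
            for b in range(n_boot):
                boot[b] = _rank_limit(np.sort(rng.choice(x, size=n)), p)
            alpha = (1 - conf) / 2
            cis.append(tuple(np.percentile(boot, [100 * alpha, 100 * (1 - alpha)])))
    return ReferenceInterval(n=n, ll=ll, ul=ul, ll_ci90=cis[0], ul_ci90=cis[1])


def summarize(values: np.ndarray) -> DistributionSummary:
    """n, median, mean, SD (n−1), bias-corrected skewness, excess kurtosis."""
    x = np.asarray(values, float)
    if x.size < 4:
        raise ValueError("summary needs at least 4 values")
    return DistributionSummary(
        n=int(x.size),
        median=float(np.median(x)),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        skewness=float(stats.skew(x, bias=False)),
        kurtosis=float(stats.kurtosis(x, bias=False, fisher=True)),
    )


def _bias_class(r: float) -> str:
    a = abs(r)
    if a <= BIAS_ALLOWABLE:
        return "allowable"
    if a <= BIAS_MINIMAL:
        return "minimal"
    return "unacceptable"


def bias_ratio(direct: ReferenceInterval, indirect: ReferenceInterval) -> BiasAssessment:
    """Signed per-limit bias of an indirect RI against the direct RI."""
    if not direct.ul > direct.ll:
        raise ValueError("zero-width direct reference interval")
    sd_b = direct.width / 3.92
    r_ll = (indirect.ll - direct.ll) / sd_b
    r_ul = (indirect.ul - direct.ul) / sd_b
    return BiasAssessment(sd_b=sd_b, ratio_ll=r_ll, ratio_ul=r_ul,
                          class_ll=_bias_class(r_ll), class_ul=_bias_class(r_ul))


# ---------------------------------------------------------------------------
# stratified comparison report

def _density_curve(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return stats.gaussian_kde(values)(grid)


def compare_report(direct_ds: Dataset, gmm_ds: Dataset, som_ds: Dataset,
                   scheme: Sequence[Stratum], seed: int = 0,
                   density_points: int = 256) -> dict:
    """Per-stratum summaries, RIs, bias ratios and density-curve coordinates.

    For every stratum in the scheme, each of the three populations (direct,
    GMM-partitioned, SOM-partitioned) contributes one summary row and one RI;
    each indirect method contributes one bias assessment against the direct
    RI.  Populations missing a stratum (n < 20) produce rows of missing
    markers with a warning.

    Returns a dict of DataFrames: ``summaries``, ``intervals``, ``bias``,
    ``density``.
    """
    methods: Mapping[str, Dataset] = {
        "direct": direct_ds, "gmm": gmm_ds, "som": som_ds}
    sum_rows, ri_rows, bias_rows, dens_rows = [], [], [], []
    for s in scheme:
        per_method: dict[str, Optional[ReferenceInterval]] = {}
        all_vals = {}
        for name, ds in methods.items():
            v = ds.values_for(s)
            all_vals[name] = v
            if v.size < 20:
                warnings.warn(f"stratum {s.label!r}: {name} population too small")
                per_method[name] = None
                sum_rows.append({"stratum": s.label, "method": name, "n": int(v.size),
                                 "median": np.nan, "mean": np.nan, "sd": np.nan,
                                 "skewness": np.nan, "kurtosis": np.nan})
                ri_rows.append({"stratum": s.label, "method": name, "n": int(v.size),
                                "ll": np.nan, "ul": np.nan,
                                "ll_ci_lo": np.nan, "ll_ci_hi": np.nan,
                                "ul_ci_lo": np.nan, "ul_ci_hi": np.nan})
                continue
            d = summarize(v)
            ri = estimate_ri(v, seed=seed)
            per_method[name] = ri
            sum_rows.append({"stratum": s.label, "method": name, "n": d.n,
                             "median": d.median, "mean": d.mean, "sd": d.sd,
                             "skewness": d.skewness, "kurtosis": d.kurtosis})
            ri_rows.append({"stratum": s.label, "method": name, "n": ri.n,
                            "ll": ri.ll, "ul": ri.ul,
                            "ll_ci_lo": ri.ll_ci90[0], "ll_ci_hi": ri.ll_ci90[1],
                            "ul_ci_lo": ri.ul_ci90[0], "ul_ci_hi": ri.ul_ci90[1]})
        direct_ri = per_method.get("direct")
        for name in ("gmm", "som"):
            ri = per_method.get(name)
            if direct_ri is None or ri is None:
                bias_rows.append({"stratum": s.label, "method": name,
                                  "sd_b": np.nan, "ratio_ll": np.nan,
                                  "ratio_ul": np.nan, "class_ll": "missing",
                                  "class_ul": "missing"})
                continue
            b = bias_ratio(direct_ri, ri)
            bias_rows.append({"stratum": s.label, "method": name, "sd_b": b.sd_b,
                              "ratio_ll": b.ratio_ll, "ratio_ul": b.ratio_ul,
                              "class_ll": b.class_ll, "class_ul": b.class_ul})
        nonempty = [v for v in all_vals.values() if v.size]
        pooled = np.concatenate(nonempty) if nonempty else np.empty(0)
        if pooled.size >= 20:
            grid = np.linspace(pooled.min(), pooled.max(), density_points)
            for name, v in all_vals.items():
                if v.size >= 20:
                    dens = _density_curve(v, grid)
                    dens_rows.extend(
                        {"stratum": s.label, "method": name, "x": float(gx),
                         "density": float(dy)}
                        for gx, dy in zip(grid, dens))
    return {
        "summaries": pd.DataFrame(sum_rows),
        "intervals": pd.DataFrame(ri_rows),
        "bias": pd.DataFrame(bias_rows),
        "density": pd.DataFrame(dens_rows),
    }


def round_report(df: pd.DataFrame, scheme: Sequence[Stratum]) -> pd.DataFrame:
    """Apply the per-analyte display rounding (creatinine 1 dp, urea 2 dp;
    ratios 2 dp) to a report table."""
    analyte_of = {s.label: s.analyte for s in scheme}
    out = df.copy()
    num_cols = [c for c in out.columns
                if c not in ("stratum", "method", "n", "class_ll", "class_ul")]
    for i, row in out.iterrows():
        analyte = analyte_of.get(row["stratum"])
        dec = REPORT_DECIMALS.get(analyte, 2)
        for c in num_cols:
            if c.startswith("ratio") or c == "sd_b":
                out.loc[i, c] = np.round(row[c], RATIO_DECIMALS)
            elif pd.notna(row[c]):
                out.loc[i, c] = np.round(row[c], dec)
    return out
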
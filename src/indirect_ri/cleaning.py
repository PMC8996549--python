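"""Data-cleaning chain for LIS-style record tables.

The chain mirrors common practice for indirect reference-interval studies:

1. drop physiologically implausible ("extreme") values against configurable
   bounds (missing values never reach this stage: the reader drops them);
2. deduplicate repeat visits to the *earliest* record per subject and analyte
   (repeat testing is taken as a pathology signal, so the first visit is the
   least selected one);
3. restrict to the study age range (default 1 to <17 years, half-open);
4. within each age/sex stratum: screen for skewness, Box-Cox transform toward
   normality when the screen fails (λ by maximum likelihood), then flag
   outliers with Tukey fences Q1 − 1.5·IQR / Q3 + 1.5·IQR on the (possibly
   transformed) scale;
5. optionally apply the *radical* strategy: a subject flagged in any of
   creatinine, urea or uric acid is removed from all three.

A greedy regression-tree helper reproduces the age/sex partitioning step used
to define strata in the first place (integer-year candidate cuts, optional
per-leaf sex split); the published strata ship as the default scheme, so the
pipeline itself never depends on tree behavior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Dataset, Stratum, assign_strata, validate_scheme

logger = logging.getLogger(__name__)

#: physiologic plausibility bounds (unit-matched to DEFAULT_UNITS); values
#: outside are treated as data errors, not biology
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "creatinine": (1.0, 2000.0),
    "urea": (0.1, 100.0),
    "uric_acid": (10.0, 3000.0),
}

#: |skewness| above which Box-Cox is applied before Tukey fencing
DEFAULT_SKEW_THRESHOLD = 0.5

RENAL_ANALYTES = ("creatinine", "urea", "uric_acid")


# ---------------------------------------------------------------------------
# basic record-level steps

def filter_plausible(ds: Dataset,
                     bounds: Mapping[str, tuple[float, float]] = DEFAULT_BOUNDS,
                     ) -> tuple[Dataset, int]:
    """Drop records outside the per-analyte plausibility bounds.

    Analytes without configured bounds pass through.  Returns the filtered
    dataset and the number of dropped records.
    """
    df = ds.df
    keep = pd.Series(True, index=df.index)
    for analyte, (lo, hi) in bounds.items():
        mask = df["analyte"] == analyte
        keep &= ~mask | ((df["value"] >= lo) & (df["value"] <= hi))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("plausibility filter dropped %d record(s)", dropped)
    return ds.subset(keep), dropped


def deduplicate_earliest(ds: Dataset) -> Dataset:
    """Keep exactly one record per (subject, analyte): the earliest date.

    Ties on date are broken by the lowest value, then input order.  Idempotent.
    """
    df = ds.df.copy()
    df["_order"] = np.arange(len(df))
    df = df.sort_values(["subject_id", "analyte", "date", "value", "_order"],
                        kind="mergesort")
    df = df.groupby(["subject_id", "analyte"], sort=False).head(1)
    df = df.sort_values("_order").drop(columns="_order")
    return ds.replace(df)


def filter_age(ds: Dataset, lo: float = 1.0, hi: float = 17.0) -> Dataset:
    """Keep records with ``lo <= age < hi`` (decimal years, half-open)."""
    if lo >= hi:
        raise ValueError("age filter requires lo < hi")
    df = ds.df
    return ds.subset((df["age"] >= lo) & (df["age"] < hi))


# ---------------------------------------------------------------------------
# Box-Cox + Tukey

@dataclass(frozen=True)
class BoxCoxFit:
    """Maximum-likelihood Box-Cox power transform y = (x^λ − 1)/λ (log at λ=0)."""

    lam: float
    loglik: float
    shift: float = 0.0

    def transform(self, values: np.ndarray) -> np.ndarray:
        x = np.asarray(values, dtype=float) + self.shift
        if np.any(x <= 0):
            raise ValueError("Box-Cox input must be positive after shift")
        return stats.boxcox(x, lmbda=self.lam)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        """Inverse transform; maps y below the transform's range limit to the
        infimum of the raw domain (−shift)."""
        y = np.asarray(y, dtype=float)
        if self.lam == 0:
            return np.exp(y) - self.shift
        arg = self.lam * y + 1.0
        # outside the transform's range (arg <= 0) the inverse is the domain
        # infimum: 0 on the shifted scale
        out = np.where(arg > 0, np.power(np.maximum(arg, 1e-300), 1.0 / self.lam), 0.0)
        return out - self.shift


def fit_box_cox(values: np.ndarray, shift: float = 0.0) -> BoxCoxFit:
    """Estimate λ by maximizing the normal profile log-likelihood.

    Requires all shifted values strictly positive and n >= 10.  The reported
    λ is within 1e-4 of the profile-likelihood optimum.
    """
    x = np.asarray(values, dtype=float) + shift
    if x.size < 10:
        raise ValueError("Box-Cox fit needs at least 10 values")
    if np.any(x <= 0):
        raise ValueError(
            "non-positive values: supply a positive shift to fit_box_cox")
    lam = float(stats.boxcox_normmax(x, method="mle"))
    return BoxCoxFit(lam=lam, loglik=float(stats.boxcox_llf(lam, x)), shift=shift)


@dataclass(frozen=True)
class TukeyFences:
    """Quartiles and 1.5·IQR fences, on the working (possibly transformed)
    scale plus the corresponding raw-scale fences."""

    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float
    lower_raw: float
    upper_raw: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.q1 <= self.q3 <= self.upper):
            raise ValueError("inconsistent fences")


def tukey_outlier_mask(values: np.ndarray, fit: Optional[BoxCoxFit] = None,
                       ) -> tuple[np.ndarray, TukeyFences]:
    """Boolean mask of values strictly outside the Tukey fences.

    Quartiles use linear interpolation (type-7).  When a Box-Cox fit is given
    the fences are computed on the transformed scale and mapped back for the
    raw-scale report; monotonicity of the transform makes the two flag sets
    identical.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("Tukey fences need at least 4 values (quartiles)")
    y = fit.transform(x) if fit is not None else x
    q1, q3 = np.percentile(y, [25, 75])
    iqr = q3 - q1
    lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    if fit is not None:
        lower_raw = float(fit.inverse(np.array([lower]))[0])
        upper_raw = float(fit.inverse(np.array([upper]))[0])
    else:
        lower_raw, upper_raw = float(lower), float(upper)
    mask = (y < lower) | (y > upper)
    fences = TukeyFences(q1=float(q1), q3=float(q3), iqr=float(iqr),
                         lower=float(lower), upper=float(upper),
                         lower_raw=lower_raw, upper_raw=upper_raw)
    return mask, fences


def flag_outliers(ds: Dataset, scheme: Sequence[Stratum],
                  skew_threshold: float = DEFAULT_SKEW_THRESHOLD,
                  ) -> tuple[pd.Series, dict]:
    """Per-stratum Box-Cox (when |skewness| > threshold) + Tukey flags.

    Returns a boolean Series aligned with ``ds.df`` (True = outlier) and a
    per-stratum info dict with λ (or None) and the fences.  Records outside
    every stratum are left unflagged.
    """
    df = ds.df
    labels = assign_strata(df, scheme)
    flags = pd.Series(False, index=df.index)
    info: dict[str, dict] = {}
    for s in scheme:
        idx = df.index[labels == s.label]
        vals = df.loc[idx, "value"].to_numpy(float)
        if vals.size < 4:
            info[s.label] = {"n": int(vals.size), "lambda": None, "fences": None,
                             "note": "too few records; no fencing"}
            continue
        skew = float(stats.skew(vals, bias=False)) if vals.size >= 10 else 0.0
        fit = None
        if abs(skew) > skew_threshold and np.all(vals > 0) and vals.size >= 10:
            fit = fit_box_cox(vals)
        mask, fences = tukey_outlier_mask(vals, fit)
        flags.loc[idx] = mask
        info[s.label] = {
            "n": int(vals.size),
            "skewness": skew,
            "lambda": None if fit is None else fit.lam,
            "fences": fences,
            "n_outliers": int(mask.sum()),
        }
    return flags, info


def radical_exclusion(ds: Dataset, scheme: Sequence[Stratum],
                      analytes: Sequence[str] = RENAL_ANALYTES,
                      skew_threshold: float = DEFAULT_SKEW_THRESHOLD,
                      ) -> tuple[Dataset, dict]:
    """Remove a subject from *all* analytes if flagged in *any* of them.

    Subjects missing one of the analytes are judged only on the evidence
    present; the count of partially observed subjects is logged and reported.
    """
    validate_scheme(scheme)
    df = ds.df
    flags, info = flag_outliers(ds, scheme, skew_threshold=skew_threshold)
    flagged_subjects = set(df.loc[flags, "subject_id"])
    per_subject = df.loc[df["analyte"].isin(analytes)].groupby("subject_id")["analyte"].nunique()
    partial = int((per_subject < len(analytes)).sum())
    if partial:
        logger.info("radical exclusion: %d subject(s) partially observed", partial)
    keep = ~df["subject_id"].isin(flagged_subjects)
    report = {
        "n_flagged_subjects": len(flagged_subjects),
        "n_partially_observed": partial,
        "per_stratum": info,
    }
    return ds.subset(keep), report


# ---------------------------------------------------------------------------
# full chain

def clean_dataset(ds: Dataset, scheme: Sequence[Stratum],
                  bounds: Mapping[str, tuple[float, float]] = DEFAULT_BOUNDS,
                  age_range: tuple[float, float] = (1.0, 17.0),
                  radical: bool = False,
                  skew_threshold: float = DEFAULT_SKEW_THRESHOLD,
                  ) -> tuple[Dataset, dict]:
    """Run the full cleaning chain and return (cleaned dataset, report).

    The report records the count surviving each step.  The chain never
    increases the record count at any step.
    """
    report: dict = {"input": len(ds)}
    ds, dropped = filter_plausible(ds, bounds)
    report["post_plausibility"] = len(ds)
    ds = deduplicate_earliest(ds)
    report["post_dedup"] = len(ds)
    ds = filter_age(ds, *age_range)
    report["post_age_filter"] = len(ds)
    if radical:
        ds, rep = radical_exclusion(ds, scheme, skew_threshold=skew_threshold)
        report["outlier_strategy"] = "radical"
        report["radical"] = rep
    else:
        flags, info = flag_outliers(ds, scheme, skew_threshold=skew_threshold)
        ds = ds.subset(~flags)
        report["outlier_strategy"] = "per-analyte"
        report["per_stratum"] = info
    report["post_outlier"] = len(ds)
    return ds, report


# ---------------------------------------------------------------------------
# age/sex partition tree

@dataclass
class AgePartitionTree:
    """Greedy regression-tree age partition with optional per-leaf sex split."""

    cut_points: list[float]
    sex_split_per_leaf: list[bool] = field(default_factory=list)
    trace: list[dict] = field(default_factory=list)

    @property
    def leaves(self) -> list[tuple[float, float]]:
        edges = [self._lo] + list(self.cut_points) + [self._hi]
        return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]

    _lo: float = 1.0
    _hi: float = 17.0


def _sse(v: np.ndarray) -> float:
    return float(((v - v.mean()) ** 2).sum()) if v.size else 0.0


def fit_age_partition_tree(ds: Dataset, analyte: str,
                           max_leaves: int = 4,
                           min_leaf_frac: float = 0.05,
                           min_rel_gain: float = 0.01,
                           sex_split_rel_gain: float = 0.01,
                           age_range: tuple[float, float] = (1.0, 17.0),
                           ) -> AgePartitionTree:
    """Greedy binary splits on age, candidate cuts at integer years.

    Each split maximizes the within-leaf variance (SSE) reduction; splitting
    stops at ``max_leaves`` or when the best relative gain falls below
    ``min_rel_gain`` of the current total SSE.  A sex split is then tested in
    each terminal age leaf and flagged when it reduces the leaf's pooled SSE
    by at least ``sex_split_rel_gain`` (relative).
    """
    if max_leaves < 2:
        raise ValueError("max_leaves must be at least 2")
    df = ds.df
    sub = df.loc[df["analyte"] == analyte]
    ages = sub["age"].to_numpy(float)
    vals = sub["value"].to_numpy(float)
    sexes = sub["sex"].to_numpy()
    if vals.size < 100:
        raise ValueError("age partition tree needs at least 100 records")
    lo, hi = age_range
    min_leaf = max(1, int(np.ceil(min_leaf_frac * vals.size)))

    leaves: list[tuple[float, float]] = [(lo, hi)]
    trace: list[dict] = []
    while len(leaves) < max_leaves:
        total_sse = sum(_sse(vals[(ages >= a) & (ages < b)]) for a, b in leaves)
        best = None  # (gain, leaf_index, cut)
        for li, (a, b) in enumerate(leaves):
            in_leaf = (ages >= a) & (ages < b)
            v, g = vals[in_leaf], ages[in_leaf]
            for cut in range(int(np.ceil(a)) + 1 if a == int(a) else int(np.ceil(a)),
                             int(np.ceil(b))):
                if not a < cut < b:
                    continue
                left, right = v[g < cut], v[g >= cut]
                if left.size < min_leaf or right.size < min_leaf:
                    continue
                gain = _sse(v) - _sse(left) - _sse(right)
                if best is None or gain > best[0]:
                    best = (gain, li, float(cut))
        if best is None or total_sse <= 0 or best[0] < min_rel_gain * total_sse:
            break
        gain, li, cut = best
        a, b = leaves.pop(li)
        leaves[li:li] = [(a, cut), (cut, b)]
        trace.append({"cut": cut, "sse_reduction": gain,
                      "relative_gain": gain / total_sse})
    leaves.sort()
    cuts = [b for (_, b) in leaves[:-1]]

    sex_flags: list[bool] = []
    for a, b in leaves:
        in_leaf = (ages >= a) & (ages < b)
        v, s = vals[in_leaf], sexes[in_leaf]
        sse0 = _sse(v)
        split = _sse(v[s == "male"]) + _sse(v[s == "female"])
        sex_flags.append(bool(sse0 > 0 and (sse0 - split) >= sex_split_rel_gain * sse0))

    tree = AgePartitionTree(cut_points=cuts, sex_split_per_leaf=sex_flags, trace=trace)
    tree._lo, tree._hi = lo, hi
    return tree
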
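"""Synthetic direct-reference and LIS-style populations with ground truth.

The generator emulates the statistical structure the pipeline assumes:

* a *direct* (recruited healthy) sample: per age/sex stratum, correlated
  (creatinine, urea, uric acid) triples drawn from the healthy component
  only, ages uniform within the stratum;
* an *LIS* (mixed outpatient) sample: a three-component mixture per subject —
  pathological-low, healthy, pathological-high — at configurable weights,
  with repeat visits (the earliest record is the least pathology-selected
  one) and a configurable rate of implausible values to exercise cleaning.

Healthy marginals may be right-skewed: draws are made on a Box-Cox scale and
mapped back through the inverse transform with power ``lam``; the transformed
scale location/spread are chosen by the delta method so the raw-scale mean
and SD stay close to the nominal (mean, sd) while the stated skew direction
appears.  This keeps the cleaning module's Box-Cox estimator testable against
a known λ.  Healthy triples are coupled through a Gaussian copula with the
stratum's correlation matrix; pathological components are independent across
analytes given the component label.

Ground truth records every subject's component label and the closed-form
healthy 2.5/97.5 percentiles per stratum and analyte.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import COLUMNS, DEFAULT_UNITS, Dataset

ANALYTES = ("creatinine", "urea", "uric_acid")
COMPONENTS = ("low", "healthy", "high")


@dataclass(frozen=True)
class HealthySpec:
    """Healthy-component marginal: nominal raw-scale mean/SD and Box-Cox
    power lam (lam = 1 means exactly normal; lam < 1 means right-skew)."""
    mean: float
    sd: float
    lam: float = 1.0

    def transformed_params(self) -> tuple[float, float]:
        """(location, scale) on the Box-Cox(lam) scale via the delta method."""
        mu_t = stats.boxcox(np.array([self.mean]), lmbda=self.lam)[0]
        sd_t = self.sd * self.mean ** (self.lam - 1.0)
        return float(mu_t), float(sd_t)

    def quantile(self, p: float) -> float:
        """Closed-form healthy quantile (monotone transform of a normal)."""
        mu_t, sd_t = self.transformed_params()
        y = mu_t + stats.norm.ppf(p) * sd_t
        if self.lam == 0:
            return float(np.exp(y))
        return float(np.power(self.lam * y + 1.0, 1.0 / self.lam))


@dataclass(frozen=True)
class PathologySpec:
    """A pathological component: plain normal, truncated positive."""
    mean: float
    sd: float


@dataclass
class StratumSpec:
    """Generating model for one age/sex band, all three analytes."""

    label: str
    age_lo: float
    age_hi: float
    sex: str                                    # 'any' | 'male' | 'female'
    healthy: dict[str, HealthySpec]
    low: dict[str, PathologySpec]
    high: dict[str, PathologySpec]
    weights: tuple[float, float, float] = (0.2, 0.6, 0.2)   # (low, healthy, high)
    corr: np.ndarray = field(default_factory=lambda: np.eye(3))
    repeat_visit_rate: float = 0.3

    def validate(self) -> None:
        w = np.asarray(self.weights, float)
        if w.min() < 0 or abs(w.sum() - 1) > 1e-9:
            raise ValueError("component weights must be non-negative and sum to 1")
        C = np.asarray(self.corr, float)
        if C.shape != (len(ANALYTES),) * 2 or not np.allclose(C, C.T):
            raise ValueError("correlation must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(C), 1):
            raise ValueError("correlation diagonal must be 1")
        if np.linalg.eigvalsh(C).min() <= 0:
            raise ValueError("correlation must be positive definite")
        for a in ANALYTES:
            if not self.low[a].mean < self.healthy[a].mean < self.high[a].mean:
                raise ValueError(f"component means must be ordered for {a}")
        if not self.age_lo < self.age_hi:
            raise ValueError("age_lo must be < age_hi")


@dataclass
class GroundTruth:
    """Per-subject component labels and closed-form healthy quantiles."""
    labels: pd.Series                                  # subject_id -> component
    healthy_quantiles: dict[tuple[str, str], tuple[float, float]]
    seed: int


def _quantiles(spec_list: Sequence[StratumSpec],
               p=(0.025, 0.975)) -> dict[tuple[str, str], tuple[float, float]]:
    return {
        (s.label, a): (s.healthy[a].quantile(p[0]), s.healthy[a].quantile(p[1]))
        for s in spec_list for a in ANALYTES
    }


def _draw_healthy(spec: StratumSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """n×3 correlated healthy triples via a Gaussian copula."""
    L = np.linalg.cholesky(np.asarray(spec.corr, float))
    z = rng.standard_normal((n, len(ANALYTES))) @ L.T
    out = np.empty_like(z)
    for j, a in enumerate(ANALYTES):
        h = spec.healthy[a]
        mu_t, sd_t = h.transformed_params()
        y = mu_t + sd_t * z[:, j]
        if h.lam == 0:
            out[:, j] = np.exp(y)
        else:
            out[:, j] = np.power(np.maximum(h.lam * y + 1.0, 1e-9), 1.0 / h.lam)
    return out


def _draw_pathological(ps: PathologySpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Normal draws truncated at > 0 by resampling."""
    x = rng.normal(ps.mean, ps.sd, n)
    for _ in range(100):
        bad = x <= 0
        if not bad.any():
            break
        x[bad] = rng.normal(ps.mean, ps.sd, bad.sum())
    return np.maximum(x, 1e-6)


def _ages_sexes(spec: StratumSpec, n: int, rng: np.random.Generator):
    ages = rng.uniform(spec.age_lo, spec.age_hi, n)
    if spec.sex == "any":
        sexes = np.where(rng.random(n) < 0.5, "male", "female")
    else:
        sexes = np.full(n, spec.sex)
    return ages, sexes


def _dates(n: int, rng: np.random.Generator, year: int) -> list[datetime.date]:
    start = datetime.date(year, 1, 1).toordinal()
    return [datetime.date.fromordinal(start + int(d))
            for d in rng.integers(0, 365, n)]


def _rows(subject_ids, dates, ages, sexes, triples, source) -> pd.DataFrame:
    recs = []
    for i, sid in enumerate(subject_ids):
        for j, a in enumerate(ANALYTES):
            recs.append((sid, dates[i], float(ages[i]), sexes[i], a,
                         float(triples[i, j]), DEFAULT_UNITS[a], source))
    return pd.DataFrame(recs, columns=COLUMNS)


def generate_direct(spec_list: Sequence[StratumSpec], n_per_stratum: int,
                    seed: int, year: int = 2017,
                    platform: str = "roche") -> tuple[Dataset, GroundTruth]:
    """Healthy-only direct reference sample, deterministic under seed.

    The spec's healthy parameters live on the LIS analyzer scale (Beckman;
    that is where direct and indirect populations are compared).  A direct
    study measures on its own platform, so with ``platform='roche'`` (the
    default) the emitted creatinine/urea values are mapped through the
    *inverse* of the published Roche→Beckman transference; running the
    pipeline's transference step then recovers the spec distribution exactly.
    Use ``platform='beckman'`` to emit spec-scale values directly.
    """
    if n_per_stratum < 100:
        raise ValueError("need at least 100 subjects per stratum")
    if platform not in ("roche", "beckman"):
        raise ValueError("platform must be 'roche' or 'beckman'")
    if platform == "roche":
        from .transference import invert, roche_to_beckman
        back = {a: invert(roche_to_beckman(a)) for a in ("creatinine", "urea")}
    rng = np.random.default_rng(seed)
    frames, labels = [], {}
    for si, spec in enumerate(spec_list):
        spec.validate()
        n = n_per_stratum
        sids = [f"D{si}{i:06d}" for i in range(n)]
        ages, sexes = _ages_sexes(spec, n, rng)
        triples = _draw_healthy(spec, n, rng)
        if platform == "roche":
            for j, a in enumerate(ANALYTES):
                if a in back:
                    triples[:, j] = back[a].apply(triples[:, j])
        frames.append(_rows(sids, _dates(n, rng, year), ages, sexes, triples,
                            "direct"))
        labels.update({sid: "healthy" for sid in sids})
    ds = Dataset(pd.concat(frames, ignore_index=True),
                 provenance=f"synthetic direct sample, seed={seed}")
    truth = GroundTruth(labels=pd.Series(labels), seed=seed,
                        healthy_quantiles=_quantiles(spec_list))
    return ds, truth


def generate_lis(spec_list: Sequence[StratumSpec], n_per_stratum: int,
                 seed: int, year: int = 2017,
                 implausible_rate: float = 0.005,
                 within_subject_cv: float = 0.3,
                 ) -> tuple[Dataset, GroundTruth]:
    """Mixed outpatient sample with repeat visits and implausible values.

    Subjects are labelled low/healthy/high at the stratum weights; the label
    applies to the whole renal triple (pathology shifts all three analytes).
    A ``repeat_visit_rate`` fraction of subjects get a second, later record
    per analyte, redrawn around the first with noise
    ``within_subject_cv × healthy SD``.  An ``implausible_rate`` fraction of
    records get a far-out-of-bounds value to exercise the plausibility
    filter.
    """
    if n_per_stratum < 100:
        raise ValueError("need at least 100 subjects per stratum")
    rng = np.random.default_rng(seed)
    frames, labels = [], {}
    for si, spec in enumerate(spec_list):
        spec.validate()
        n = n_per_stratum
        sids = np.array([f"L{si}{i:06d}" for i in range(n)])
        ages, sexes = _ages_sexes(spec, n, rng)
        comp = rng.choice(len(COMPONENTS), size=n, p=np.asarray(spec.weights))
        triples = _draw_healthy(spec, n, rng)
        for ci, cname in ((0, "low"), (2, "high")):
            idx = np.flatnonzero(comp == ci)
            comps = spec.low if cname == "low" else spec.high
            for j, a in enumerate(ANALYTES):
                triples[idx, j] = _draw_pathological(comps[a], idx.size, rng)
        dates = _dates(n, rng, year)
        frames.append(_rows(sids, dates, ages, sexes, triples, "lis"))
        labels.update(dict(zip(sids, (COMPONENTS[c] for c in comp))))

        # repeat visits: later date, value redrawn around the first
        rep = np.flatnonzero(rng.random(n) < spec.repeat_visit_rate)
        if rep.size:
            noise_sd = np.array([spec.healthy[a].sd for a in ANALYTES])
            vals2 = triples[rep] + rng.standard_normal((rep.size, 3)) * \
                (within_subject_cv * noise_sd)
            vals2 = np.maximum(vals2, 1e-6)
            dates2 = [datetime.date.fromordinal(
                dates[i].toordinal() + int(rng.integers(7, 180))) for i in rep]
            frames.append(_rows(sids[rep], dates2, ages[rep], sexes[rep],
                                vals2, "lis"))
    df = pd.concat(frames, ignore_index=True)

    if implausible_rate > 0:
        bad = rng.random(len(df)) < implausible_rate
        far_out = {"creatinine": 9999.0, "urea": 999.0, "uric_acid": 99999.0}
        df.loc[bad, "value"] = df.loc[bad, "analyte"].map(far_out)
    ds = Dataset(df, provenance=f"synthetic LIS sample, seed={seed}")
    truth = GroundTruth(labels=pd.Series(labels), seed=seed,
                        healthy_quantiles=_quantiles(spec_list))
    return ds, truth


# ---------------------------------------------------------------------------
# shipped default study spec

def default_study_spec() -> list[StratumSpec]:
    """Default generating model emulating published pediatric renal-panel
    reference distributions.

    Healthy creatinine/urea components use the published transferred direct-
    sample means/SDs per stratum (creatinine 28.9/5.6, 40.6/5.6, 60.8/12.7
    boys, 52.2/8.3 girls μmol/L; urea 4.33/0.99 mmol/L), with mild right-skew
    (Box-Cox lam < 1) where the published skewness is positive — strongest
    for adolescent boys' creatinine and urea.  Pathological components sit at
    healthy mean + 6·SD (high) and max(mean − 6·SD, 0.25·mean) (low, SD
    halved so draws stay positive); mixing weights are 20/60/20.  Uric acid
    healthy parameters are invented defaults (no published values): ~250
    μmol/L with an age trend, SD 55-70.
    """
    corr = np.array([[1.0, 0.4, 0.4],
                     [0.4, 1.0, 0.3],
                     [0.4, 0.3, 1.0]])
    urea = HealthySpec(4.33, 0.99, lam=0.4)
    bands = [
        ("1 to <6 years", 1, 6, "any", HealthySpec(28.9, 5.6, lam=0.9),
         HealthySpec(200.0, 55.0)),
        ("6 to <12 years", 6, 12, "any", HealthySpec(40.6, 5.6, lam=0.7),
         HealthySpec(240.0, 60.0)),
        ("12 to <17 years boys", 12, 17, "male", HealthySpec(60.8, 12.7, lam=0.5),
         HealthySpec(310.0, 70.0)),
        ("12 to <17 years girls", 12, 17, "female", HealthySpec(52.2, 8.3, lam=0.9),
         HealthySpec(270.0, 60.0)),
    ]

    def _components(h: HealthySpec) -> tuple[PathologySpec, PathologySpec]:
        low_mean = max(h.mean - 6 * h.sd, 0.25 * h.mean)
        return (PathologySpec(low_mean, 0.5 * h.sd),
                PathologySpec(h.mean + 6 * h.sd, h.sd))

    out = []
    for label, lo, hi, sex, creat, uric in bands:
        healthy = {"creatinine": creat, "urea": urea, "uric_acid": uric}
        low, high = {}, {}
        for a, h in healthy.items():
            low[a], high[a] = _components(h)
        out.append(StratumSpec(
            label=label, age_lo=lo, age_hi=hi, sex=sex, healthy=healthy,
            low=low, high=high, weights=(0.2, 0.6, 0.2), corr=corr,
            repeat_visit_rate=0.3,
        ))
    return out
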
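"""Three-component univariate Gaussian mixture partitioning.

A mixed outpatient (LIS) population for a single analyte is modelled as three
normal components representing low-pathological, healthy and high-pathological
levels.  The EM fit is deliberately initialized from the *transferred direct
reference sample*: component means start at the direct sample's quartiles
(Q1, median, Q3) and all three SDs at the direct sample's SD, anchoring the
middle component at the healthy range before any iteration.  After
convergence the component with the middle fitted mean is taken as the
"potential healthy" cluster (EM may reorder components, so the middle is
identified at the end, not by its starting position).

Fitting runs independently within each published age/sex stratum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class GMMInit:
    """Starting parameters derived from a direct reference sample."""

    means0: np.ndarray    # (Q1, median, Q3)
    sds0: np.ndarray      # (SD, SD, SD)
    weights0: np.ndarray  # mixing proportions, default equal thirds

    def __post_init__(self) -> None:
        m = np.asarray(self.means0, float)
        if not (m.shape == (3,) and np.all(np.diff(m) > 0)):
            raise ValueError("initial means must be 3 strictly increasing values")
        if not np.all(np.asarray(self.sds0, float) > 0):
            raise ValueError("initial SDs must be positive")


def make_init(direct_values: np.ndarray,
              weights0: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
              ) -> GMMInit:
    """Quartile/SD initialization from a (transferred) direct sample.

    Quartiles use linear interpolation; SD uses the n−1 denominator.
    """
    x = np.asarray(direct_values, float)
    if x.size < 20:
        raise ValueError("direct sample too small for initialization (n >= 20)")
    q = np.percentile(x, [25, 50, 75])
    sd = float(np.std(x, ddof=1))
    if sd == 0 or not np.all(np.diff(q) > 0):
        raise ValueError("degenerate direct sample: zero spread")
    return GMMInit(means0=q, sds0=np.full(3, sd),
                   weights0=np.asarray(weights0, float))


@dataclass
class MixtureFit:
    """Fitted 3-component univariate Gaussian mixture."""

    weights: np.ndarray       # π_k, sum to 1
    means: np.ndarray         # μ_k
    sds: np.ndarray           # σ_k
    resp: np.ndarray          # n×3 posterior responsibilities
    loglik_trace: np.ndarray  # per-iteration observed-data log-likelihood
    n_iter: int
    converged: bool


def _log_density(x: np.ndarray, weights, means, sds) -> np.ndarray:
    """n×3 matrix of log(π_k) + log N(x | μ_k, σ_k)."""
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return np.log(weights)[None, :] - np.log(sds)[None, :] - _LOG_SQRT_2PI - 0.5 * z * z


def em_fit(values: np.ndarray, init: GMMInit, tol: float = 1e-8,
           max_iter: int = 500, sd_floor_frac: float = 1e-3) -> MixtureFit:
    """EM for the 3-component univariate normal mixture.

    Alternates posterior responsibilities (E) and weighted moment updates (M)
    until the relative log-likelihood change drops below ``tol`` or
    ``max_iter`` iterations.  Component SDs are clamped to
    ``sd_floor_frac × sample SD`` to prevent collapse (with a warning).
    """
    x = np.asarray(values, float)
    if x.size < 50:
        raise ValueError("EM fit needs at least 50 values")
    sd_floor = sd_floor_frac * float(np.std(x, ddof=1))
    w = np.asarray(init.weights0, float).copy()
    w /= w.sum()
    mu = np.asarray(init.means0, float).copy()
    sd = np.asarray(init.sds0, float).copy()

    trace = []
    converged = False
    resp = np.full((x.size, 3), 1 / 3)
    for it in range(1, max_iter + 1):
        logdens = _log_density(x, w, mu, sd)
        norm = logsumexp(logdens, axis=1)
        ll = float(norm.sum())
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite mixture likelihood")
        resp = np.exp(logdens - norm[:, None])
        trace.append(ll)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(ll - prev) < tol * abs(prev):
                converged = True
                break
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / x.size
        mu = resp.T @ x / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(var)
        low = sd < sd_floor
        if low.any():
            warnings.warn("mixture component SD clamped to floor (collapse guard)")
            sd[low] = sd_floor
    return MixtureFit(weights=w, means=mu, sds=sd, resp=resp,
                      loglik_trace=np.asarray(trace), n_iter=len(trace),
                      converged=converged)


def assign_clusters(fit: MixtureFit) -> np.ndarray:
    """Hard labels: argmax posterior responsibility, ties to the lower-mean
    component."""
    resp = fit.resp
    order = np.argsort(fit.means, kind="stable")
    # scan components from lowest mean to highest; first max wins
    reordered = resp[:, order]
    labels_in_order = np.argmax(reordered, axis=1)
    return order[labels_in_order]


def middle_component(fit: MixtureFit) -> int:
    """Index of the component with the middle fitted mean.

    If two means coincide the middle is ill-defined: warn and fall back to
    the largest-weight component among the tied ones.
    """
    order = np.argsort(fit.means, kind="stable")
    mid = int(order[1])
    if len(np.unique(np.round(fit.means, 12))) < 3:
        warnings.warn("tied component means; middle chosen by largest weight")
        tied = np.flatnonzero(np.isclose(fit.means, fit.means[mid]))
        mid = int(tied[np.argmax(fit.weights[tied])])
    return mid


def select_healthy(values: np.ndarray, fit: MixtureFit,
                   labels: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Values assigned to the middle-mean ("potential healthy") component.

    Returns (selected values, boolean selection mask).
    """
    x = np.asarray(values, float)
    if labels is None:
        labels = assign_clusters(fit)
    mask = labels == middle_component(fit)
    return x[mask], mask


def partition_stratum(lis_values: np.ndarray, direct_values: np.ndarray,
                      tol: float = 1e-8, max_iter: int = 500,
                      ) -> tuple[MixtureFit, np.ndarray, np.ndarray]:
    """One-stratum pipeline: init from the direct sample, fit on the LIS
    values, select the healthy cluster.

    Returns (fit, hard labels, healthy mask).
    """
    init = make_init(direct_values)
    fit = em_fit(lis_values, init, tol=tol, max_iter=max_iter)
    labels = assign_clusters(fit)
    _, mask = select_healthy(lis_values, fit, labels)
    logger.info("GMM stratum: n=%d, healthy fraction %.3f",
                len(lis_values), mask.mean())
    return fit, labels, mask
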
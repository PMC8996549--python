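"""Between-analyzer transference.

Systematic differences between biochemistry platforms are corrected by affine
conversion ``y = slope * x + intercept`` with slope > 0.  Published chains are
often expressed through a common source platform; composing the published
Abbott-based formulas for creatinine and urea yields the Roche-to-Beckman
maps used to put a direct (Roche-measured) reference sample on the scale of
LIS values measured on a Beckman analyzer:

* creatinine:  Abbott ×0.965 − 0.447 → Roche;  Abbott ×0.903 − 1.192 → Beckman,
  hence Roche → Beckman is (x + 0.447) × (0.903/0.965) − 1.192
  (slope 0.936 at 3 dp);
* urea:  Abbott ×0.941 + 0.143 → Roche;  Abbott ×0.961 + 0.110 → Beckman,
  hence Roche → Beckman is (x − 0.143) × (0.961/0.941) + 0.110
  (slope 1.021 at 3 dp).

Coefficients are carried at full precision internally; 3-dp values are for
display only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .data_model import Dataset


@dataclass(frozen=True)
class TransferenceMap:
    """Affine analyte conversion between two analyzer platforms."""

    analyte: str
    source: str
    target: str
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("transference slope must be positive (monotone conversion)")

    def apply(self, x):
        """slope·x + intercept, vectorized over array inputs."""
        arr = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("transference input must be finite")
        out = self.slope * arr + self.intercept
        return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def apply_map(m: TransferenceMap, x):
    """Functional form of :meth:`TransferenceMap.apply`."""
    return m.apply(x)


def compose_via_common_source(a_to_b: TransferenceMap,
                              a_to_c: TransferenceMap) -> TransferenceMap:
    """B→C map from two maps sharing source platform A.

    Equivalent to inverting A→B then applying A→C:
    ``slope = slope_ac / slope_ab``;
    ``intercept = intercept_ac − slope · intercept_ab``.
    """
    if a_to_b.analyte != a_to_c.analyte:
        raise ValueError("cannot compose maps for different analytes")
    if a_to_b.source != a_to_c.source:
        raise ValueError("maps must share the same source platform")
    if a_to_b.slope == 0:
        raise ValueError("zero slope cannot be inverted")
    slope = a_to_c.slope / a_to_b.slope
    intercept = a_to_c.intercept - slope * a_to_b.intercept
    return TransferenceMap(
        analyte=a_to_b.analyte, source=a_to_b.target, target=a_to_c.target,
        slope=slope, intercept=intercept,
    )


def invert(m: TransferenceMap) -> TransferenceMap:
    """Inverse affine map (target → source)."""
    return TransferenceMap(
        analyte=m.analyte, source=m.target, target=m.source,
        slope=1.0 / m.slope, intercept=-m.intercept / m.slope,
    )


# -- published default maps ------------------------------------------------

ABBOTT_TO_ROCHE_CREATININE = TransferenceMap(
    "creatinine", "Abbott ARCHITECT c8000", "Roche Cobas", 0.965, -0.447)
ABBOTT_TO_BECKMAN_CREATININE = TransferenceMap(
    "creatinine", "Abbott ARCHITECT c8000", "Beckman Coulter AU", 0.903, -1.192)
ABBOTT_TO_ROCHE_UREA = TransferenceMap(
    "urea", "Abbott ARCHITECT c8000", "Roche Cobas", 0.941, 0.143)
ABBOTT_TO_BECKMAN_UREA = TransferenceMap(
    "urea", "Abbott ARCHITECT c8000", "Beckman Coulter AU", 0.961, 0.110)

DEFAULT_MAPS = [
    ABBOTT_TO_ROCHE_CREATININE, ABBOTT_TO_BECKMAN_CREATININE,
    ABBOTT_TO_ROCHE_UREA, ABBOTT_TO_BECKMAN_UREA,
]


def roche_to_beckman(analyte: str) -> TransferenceMap:
    """Composed Roche→Beckman map for creatinine or urea."""
    if analyte == "creatinine":
        return compose_via_common_source(ABBOTT_TO_ROCHE_CREATININE,
                                         ABBOTT_TO_BECKMAN_CREATININE)
    if analyte == "urea":
        return compose_via_common_source(ABBOTT_TO_ROCHE_UREA,
                                         ABBOTT_TO_BECKMAN_UREA)
    raise KeyError(f"no published Roche→Beckman map for analyte {analyte!r}")


def transfer_dataset(ds: Dataset, maps: Sequence[TransferenceMap]) -> Dataset:
    """Apply each map to the matching analyte's records; analytes without a
    map pass through unchanged."""
    df = ds.df.copy()
    for m in maps:
        mask = df["analyte"] == m.analyte
        if mask.any():
            df.loc[mask, "value"] = m.apply(df.loc[mask, "value"].to_numpy(float))
    return ds.replace(df)
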
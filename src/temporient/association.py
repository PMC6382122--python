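"""Association analysis between TP profiles and user attributes.

Pearson product-moment correlations with Fisher R-to-Z significance
(two-sided normal test on atanh(r) with standard error 1/sqrt(n-3)),
Bonferroni-corrected over all (dimension x attribute) pairs computed in one
report; simple OLS fits; and loess-smoothed standardized-frequency curves of
a TP dimension over an attribute (typically age).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import SENTIMENT_CLASSES, TEMPORAL_CLASSES, profiles_to_frame

logger = logging.getLogger(__name__)

ALPHA = 0.001

UNI_DIMENSIONS = tuple(f"uni_{t}" for t in TEMPORAL_CLASSES)
BI_DIMENSIONS = tuple(f"bi_{t}_{s}" for t in TEMPORAL_CLASSES
                      for s in SENTIMENT_CLASSES)
ALL_DIMENSIONS = UNI_DIMENSIONS + BI_DIMENSIONS


@dataclass
class AssociationResult:
    tp_dimension: str
    attribute: str
    n: int
    r: float
    z: float
    p_raw: float
    p_bonferroni: float
    significant: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"r={self.r} outside [-1, 1]")
        if self.n < 3:
            raise ValueError("n must be at least 3")


@dataclass
class SmoothedCurve:
    attribute: np.ndarray   # sorted ascending
    standardized: np.ndarray
    smoothed: np.ndarray
    span: float


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation; constant input is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input")
    return float(stats.pearsonr(x, y).statistic)


def fisher_r_to_z_test(r: float, n: int, n_tests: int = 1
                       ) -> tuple[float, float, float]:
    """Fisher transform significance test.

    Returns ``(z, p_raw, p_bonferroni)`` where z = atanh(r), the two-sided
    p comes from the normal distribution with SE 1/sqrt(n-3), and the
    Bonferroni p is min(1, p_raw * n_tests).  |r| = 1 is degenerate and
    reports p = 0.
    """
    if n < 4:
        raise ValueError("Fisher R-to-Z needs n >= 4")
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    if abs(r) >= 1.0:
        if abs(r) > 1.0:
            raise ValueError(f"r={r} outside [-1, 1]")
        return math.copysign(math.inf, r), 0.0, 0.0
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    p_raw = float(2.0 * stats.norm.sf(abs(z) / se))
    return z, p_raw, min(1.0, p_raw * n_tests)


def fit_linear_regression(x, y) -> tuple[float, float, float]:
    """OLS fit y = slope * x + intercept; returns (slope, intercept, r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("constant x: regression undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def standardized_frequency_curve(profiles, attributes: pd.DataFrame,
                                 attribute: str, dimension: str,
                                 span: float = 0.75) -> SmoothedCurve:
    """Loess-smoothed z-scored TP dimension over an attribute.

    The dimension is standardized (mean 0, SD 1) across the users with
    defined values, ordered by the attribute and smoothed by local
    regression with fraction ``span``.
    """
    merged = _join(profiles, attributes)
    if dimension not in merged.columns or attribute not in merged.columns:
        raise KeyError(f"unknown column {dimension!r} or {attribute!r}")
    sub = merged[[attribute, dimension]].dropna()
    if len(sub) < 10:
        raise ValueError(f"need >= 10 users with defined values, "
                         f"got {len(sub)}")
    vals = sub[dimension].to_numpy(dtype=float)
    attr = sub[attribute].to_numpy(dtype=float)
    sd = vals.std(ddof=0)
    if sd == 0:
        raise ValueError(f"dimension {dimension!r} is constant: "
                         f"zero standard deviation")
    zvals = (vals - vals.mean()) / sd
    order = np.argsort(attr, kind="stable")
    attr, zvals = attr[order], zvals[order]
    smoothed = lowess(zvals, attr, frac=span, return_sorted=False)
    return SmoothedCurve(attribute=attr, standardized=zvals,
                         smoothed=smoothed, span=span)


def _join(profiles, attributes: pd.DataFrame) -> pd.DataFrame:
    pframe = profiles_to_frame(profiles)
    if "user_id" not in attributes.columns:
        raise ValueError("attribute table needs a 'user_id' column")
    merged = pframe.merge(attributes, on="user_id", how="inner")
    if merged.empty:
        raise ValueError("empty join between profiles and attributes")
    return merged


def correlation_report(profiles, attributes: pd.DataFrame,
                       dimensions=ALL_DIMENSIONS,
                       alpha: float = ALPHA) -> list[AssociationResult]:
    """One Pearson/Fisher result per (TP dimension x attribute) pair.

    Undefined bidimensional entries are dropped pairwise before each
    computation; the Bonferroni family is every pair computed in this run.
    Pairs with fewer than 4 usable observations or a constant vector are
    skipped with a warning (and do not count toward the family).
    """
    merged = _join(profiles, attributes)
    attr_cols = [c for c in attributes.columns
                 if c != "user_id"
                 and pd.api.types.is_numeric_dtype(merged[c])]
    if not attr_cols:
        raise ValueError("no numeric attribute columns to correlate")
    pairs = []
    for dim in dimensions:
        for attr in attr_cols:
            sub = merged[[dim, attr]].dropna()
            if len(sub) < 4:
                warnings.warn(f"{dim} x {attr}: fewer than 4 pairs, skipped",
                              stacklevel=2)
                continue
            x = sub[dim].to_numpy(dtype=float)
            y = sub[attr].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(f"{dim} x {attr}: constant vector, skipped",
                              stacklevel=2)
                continue
            pairs.append((dim, attr, x, y))
    n_tests = len(pairs)
    results = []
    for dim, attr, x, y in pairs:
        r = pearson_r(x, y)
        degenerate = abs(r) >= 1.0
        z, p_raw, p_bonf = fisher_r_to_z_test(r, len(x), n_tests)
        results.append(AssociationResult(
            tp_dimension=dim, attribute=attr, n=len(x), r=r, z=z,
            p_raw=p_raw, p_bonferroni=p_bonf,
            significant=bool(p_bonf < alpha), degenerate=degenerate))
    logger.info("correlation report: %d tests (%d dimensions x %d "
                "attributes offered)", n_tests, len(dimensions),
                len(attr_cols))
    return results
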
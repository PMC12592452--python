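"""Instrument-level quantification and amino-acid concentration contrasts.

Covers the arithmetic from chromatographic peak areas to normalized
amino-acid nitrogen content (ngN amino-acid N per µg particulate N), the
per-stratum outlier screen, and the background vs plume/discharge group
contrasts by one-way ANOVA, per particle size fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationStandard",
    "AnovaResult",
    "quantify_by_response_factor",
    "total_aa_per_pn",
    "flag_outliers",
    "compare_groups_anova",
]


@dataclass(frozen=True)
class CalibrationStandard:
    """A reference material's response factor.

    ``response_factor`` is peak area per reference size: volt-seconds per
    µg PN for bulk nitrogen, volt-seconds per nmol AA for amino acids.
    """

    kind: str  # bulk_N | amino_acid
    response_factor: float
    reference_id: str = ""

    def __post_init__(self):
        if self.kind not in ("bulk_N", "amino_acid"):
            raise ValueError(f"unknown standard kind {self.kind!r}")
        if not self.response_factor > 0:
            raise ValueError("response_factor must be positive")


def quantify_by_response_factor(peak_area: float,
                                standard: CalibrationStandard) -> float:
    """Amount (µg PN or nmol AA) from a peak area via the response factor."""
    if peak_area < 0:
        raise ValueError("peak_area must be non-negative")
    return peak_area / standard.response_factor


def total_aa_per_pn(aa_amounts: Iterable[float], bulk_pn: float,
                    subsample_fraction_csia: float = 0.5,
                    subsample_fraction_bulk: float = 0.5) -> float:
    """Summed amino-acid nitrogen normalized to bulk particulate nitrogen.

    Both the CSIA and bulk determinations are made on known filter
    subsamples; dividing each by its subsample fraction recovers
    whole-filter amounts before taking the ratio (ngN AA per µg PN).  Equal
    subsample fractions therefore cancel.
    """
    aa = np.asarray(list(aa_amounts), dtype=float)
    if aa.size == 0:
        raise ValueError("need at least one amino-acid amount")
    for name, f in (("subsample_fraction_csia", subsample_fraction_csia),
                    ("subsample_fraction_bulk", subsample_fraction_bulk)):
        if not 0 < f <= 1:
            raise ValueError(f"{name} must be in (0, 1]")
    if not bulk_pn > 0:
        raise ValueError("bulk_pn must be positive")
    whole_filter_aa = aa.sum() / subsample_fraction_csia
    whole_filter_pn = bulk_pn / subsample_fraction_bulk
    return whole_filter_aa / whole_filter_pn


def flag_outliers(records: pd.DataFrame, rule: str = "tukey",
                  value_col: str = "normalized_conc",
                  strata: Sequence[str] = ("sample_type", "size_fraction"),
                  k: float = 1.5) -> pd.DataFrame:
    """Flag concentration outliers within sample_type x size_fraction strata.

    Default rule is Tukey's fences (``k`` x IQR beyond the quartiles).
    Flagged records are retained with ``outlier=True`` so downstream steps
    can exclude them without losing the audit trail.  Strata with fewer
    than 4 records are skipped with a warning (quartiles are not
    meaningful there).  ``rule='none'`` flags nothing.
    """
    if rule not in ("tukey", "none"):
        raise ValueError(f"unknown outlier rule {rule!r}")
    out = records.copy()
    out["outlier"] = False
    if rule == "none":
        return out
    for key, sub in records.groupby(list(strata), observed=True):
        if len(sub) < 4:
            warnings.warn(f"stratum {key}: only {len(sub)} records; "
                          "outlier rule skipped")
            continue
        v = sub[value_col]
        q1, q3 = v.quantile([0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        out.loc[sub.index[(v < lo) | (v > hi)], "outlier"] = True
    return out


@dataclass(frozen=True)
class AnovaResult:
    fraction: str
    F: float
    df_between: int
    df_within: int
    p: float
    group_sizes: tuple


def compare_groups_anova(records: pd.DataFrame, fraction: str,
                         pool_plume_discharge: bool = True,
                         log_transform: bool = False,
                         value_col: str = "normalized_conc") -> AnovaResult:
    """One-way fixed-effects ANOVA of AA concentration for one size fraction.

    Background is contrasted against plume and discharge samples; the latter
    two are pooled by default (they are the same particle source seen at
    different distances from the release).  Records flagged as outliers are
    excluded.  ``log_transform`` applies log to the concentrations first
    (they are right-skewed); the default follows the untransformed scale.
    """
    sub = records[records["size_fraction"] == fraction]
    if "outlier" in sub.columns:
        sub = sub[~sub["outlier"]]
    if pool_plume_discharge:
        labels = sub["sample_type"].replace(
            {"plume": "plume/discharge", "discharge": "plume/discharge"})
    else:
        labels = sub["sample_type"]
    groups = []
    for name, g in sub.groupby(labels.to_numpy()):
        vals = g[value_col].dropna().to_numpy()
        if log_transform:
            vals = np.log(vals)
        groups.append((name, vals))
    bad = [name for name, v in groups if len(v) < 2]
    if len(groups) < 2 or bad:
        raise ValueError(
            f"fraction {fraction!r}: need >= 2 groups with >= 2 records each"
            + (f"; degenerate group(s): {bad}" if bad else ""))
    arrays = [v for _, v in groups]
    allvals = np.concatenate(arrays)
    if np.ptp(allvals) == 0:
        f_stat, p = 0.0, 1.0  # constant input: no variance anywhere
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p = stats.f_oneway(*arrays)
        if not np.isfinite(f_stat):
            f_stat, p = 0.0, 1.0
    n = sum(len(a) for a in arrays)
    return AnovaResult(fraction, float(f_stat), len(arrays) - 1, n - len(arrays),
                       float(p), tuple(len(a) for a in arrays))
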
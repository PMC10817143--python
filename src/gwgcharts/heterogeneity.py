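"""Standardized Site Differences (SSD) across multi-country cohorts.

Within each pre-pregnancy-BMI-category x gestational-age-bin cell, each
site's mean is standardized against the pooled distribution of all
individual observations in the cell:

    SSD_site = (site mean - pooled mean) / pooled SD

with the pooled SD the sample SD (n-1 denominator) of the individual
values.  |SSD| <= 0.5 is taken as homogeneity (the data may be pooled);
0.2 / 0.5 / 0.8 SD are the conventional small / acceptable / large effect
magnitudes.  A sensitivity variant drops sites contributing fewer than
``min_n`` records to a cell before recomputing the pooled statistics,
separating genuine between-site differences from small-sample noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GABinScheme",
    "SSDCell",
    "DEFAULT_GA_BINS",
    "assign_ga_bin",
    "compute_ssd",
    "sensitivity_filter",
    "cohen_magnitude",
    "ssd_table",
]


@dataclass(frozen=True)
class GABinScheme:
    """Ordered inclusive integer-week bins, disjoint and exhaustive on [0, 42]."""

    bins: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        expected = 0
        for lo, hi in self.bins:
            if lo != expected or hi < lo:
                raise ValueError("bins must be disjoint, ordered, exhaustive on [0, 42]")
            expected = hi + 1
        if expected != 43:
            raise ValueError("bins must cover weeks 0..42")

    def label(self, lo: int, hi: int) -> str:
        return f"{lo}-{hi}"

    @property
    def labels(self) -> list[str]:
        return [self.label(lo, hi) for lo, hi in self.bins]


DEFAULT_GA_BINS = GABinScheme(((0, 7), (8, 14), (15, 21), (22, 28),
                               (29, 35), (36, 42)))


def assign_ga_bin(ga_weeks: int, scheme: GABinScheme = DEFAULT_GA_BINS) -> str:
    """The unique bin label whose inclusive range contains ``ga_weeks``."""
    if not (0 <= ga_weeks <= 42):
        raise ValueError(f"gestational age {ga_weeks} outside [0, 42]")
    for lo, hi in scheme.bins:
        if lo <= ga_weeks <= hi:
            return scheme.label(lo, hi)
    raise AssertionError("exhaustive bins cannot miss")  # pragma: no cover


@dataclass
class SSDCell:
    """One site's standardized difference within one stratum cell."""

    site: str
    bmi_category: str
    bin_label: str
    n_site: int
    site_mean: float
    pooled_mean: float
    pooled_sd: float
    ssd: float
    verdict: str                      # "homogeneous" | "heterogeneous"
    included_in_sensitivity: bool = True


def cohen_magnitude(ssd: float) -> str:
    """Effect-size band: |SSD| < 0.2 small; < 0.8 acceptable; else large."""
    if not np.isfinite(ssd):
        raise ValueError("SSD must be finite")
    a = abs(ssd)
    if a < 0.2:
        return "small"
    if a < 0.8:
        return "acceptable"
    return "large"


def compute_ssd(values_by_site: dict[str, np.ndarray],
                bmi_category: str = "", bin_label: str = "") -> list[SSDCell]:
    """SSD of every site against the pooled cell distribution.

    ``values_by_site`` maps site label to that site's individual values in
    the cell.  Pooled mean and sample SD are computed over all individual
    values.  With zero pooled SD: all-equal values give SSD 0; differing
    site means are an error (standardization undefined).
    """
    if not values_by_site:
        raise ValueError("at least one site required")
    arrays = {s: np.asarray(v, dtype=float) for s, v in values_by_site.items()}
    if any(a.size == 0 for a in arrays.values()):
        raise ValueError("every site must contribute at least one value")
    pooled = np.concatenate(list(arrays.values()))
    if pooled.size < 2:
        raise ValueError("pooled cell needs n >= 2")
    pooled_mean = float(pooled.mean())
    pooled_sd = float(pooled.std(ddof=1))

    cells = []
    for site, vals in arrays.items():
        site_mean = float(vals.mean())
        if pooled_sd > 0:
            ssd = (site_mean - pooled_mean) / pooled_sd
        elif np.allclose(pooled, pooled[0]):
            ssd = 0.0
        else:  # pragma: no cover - unreachable: sd 0 implies all equal
            raise ValueError("pooled SD is zero but site means differ")
        verdict = "homogeneous" if abs(ssd) <= 0.5 else "heterogeneous"
        cells.append(SSDCell(site=site, bmi_category=bmi_category,
                             bin_label=bin_label, n_site=int(vals.size),
                             site_mean=site_mean, pooled_mean=pooled_mean,
                             pooled_sd=pooled_sd, ssd=float(ssd),
                             verdict=verdict))
    return cells


def sensitivity_filter(values_by_site: dict[str, np.ndarray], min_n: int = 10,
                       bmi_category: str = "", bin_label: str = "",
                       ) -> list[SSDCell]:
    """Recompute a cell's SSDs after dropping sites with n_site < min_n.

    Dropped sites are reported with ``included_in_sensitivity=False`` and no
    SSD (NaN).  If every site is dropped the cell is empty (no error).
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    arrays = {s: np.asarray(v, dtype=float) for s, v in values_by_site.items()}
    kept = {s: v for s, v in arrays.items() if v.size >= min_n}
    dropped = [
        SSDCell(site=s, bmi_category=bmi_category, bin_label=bin_label,
                n_site=int(v.size), site_mean=float(v.mean()),
                pooled_mean=np.nan, pooled_sd=np.nan, ssd=np.nan,
                verdict="excluded", included_in_sensitivity=False)
        for s, v in arrays.items() if v.size < min_n]
    cells: list[SSDCell] = []
    if kept:
        cells = compute_ssd(kept, bmi_category=bmi_category, bin_label=bin_label)
    return cells + dropped


def _cells_to_frame(cells: list[SSDCell]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in cells])


def ssd_table(df: pd.DataFrame, value_col: str, site_col: str = "site",
              category_col: str = "bmi_category", bin_col: str = "ga_bin",
              min_n: int | None = None) -> pd.DataFrame:
    """Tidy SSD table over every category x bin cell of a long dataset.

    With ``min_n`` set, applies the small-site sensitivity filter inside
    each cell.  Cells with pooled n < 2 are skipped.
    """
    records: list[SSDCell] = []
    for (cat, bin_label), cell in df.groupby([category_col, bin_col],
                                             observed=True, sort=True):
        by_site = {
            str(site): grp[value_col].dropna().to_numpy()
            for site, grp in cell.groupby(site_col, sort=True)}
        by_site = {s: v for s, v in by_site.items() if v.size > 0}
        if not by_site or sum(v.size for v in by_site.values()) < 2:
            continue
        if min_n is None:
            records.extend(compute_ssd(by_site, str(cat), str(bin_label)))
        else:
            records.extend(sensitivity_filter(by_site, min_n, str(cat),
                                              str(bin_label)))
    out = _cells_to_frame(records) if records else pd.DataFrame(
        columns=["site", "bmi_category", "bin_label", "n_site", "site_mean",
                 "pooled_mean", "pooled_sd", "ssd", "verdict",
                 "included_in_sensitivity"])
    if len(out):
        out["magnitude"] = [
            cohen_magnitude(s) if np.isfinite(s) else ""
            for s in out["ssd"]]
    return out
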
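"""LMS growth references: z-scores and WHO-style BMI-for-age classification.

The LMS method summarises the age-conditional distribution of an
anthropometric measurement by three curves: a Box-Cox power ``L``, a median
``M`` and a coefficient of variation ``S``.  A measurement ``y`` at age ``a``
maps to a z-score

    z = ((y / M)^L - 1) / (L * S)          (L != 0)
    z = ln(y / M) / S                      (L -> 0 limit)

with ``L``, ``M`` and ``S`` interpolated linearly between tabulated ages.
The reference table is a user-supplied delimited file laid out like the
WHO 2007 adolescent references (columns ``age, L, M, S``); ages outside the
tabulated range are an error, never an extrapolation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LMSReferenceTable",
    "BMICategory",
    "lms_zscore",
    "lms_value",
    "classify_bmi_category",
    "is_stunted",
    "read_reference_table",
]

#: switch point below which the L -> 0 logarithmic limit is used
_L_EPS = 1e-7


class BMICategory(str, enum.Enum):
    """Pre-pregnancy BMI-for-age category on the WHO z-score bands."""

    UNDERWEIGHT = "underweight"   # z < -2
    NORMAL = "normal"             # -2 <= z <= +1
    OVERWEIGHT = "overweight"     # +1 < z <= +2
    OBESITY = "obesity"           # z > +2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class LMSReferenceTable:
    """Age-indexed L/M/S triplets defining a growth reference.

    Parameters
    ----------
    indicator :
        Label of the indicator, e.g. ``"height-for-age"`` or ``"bmi-for-age"``.
    age, L, M, S :
        Equal-length arrays; ages strictly increasing, M > 0, S > 0.
    age_unit :
        ``"years"`` or ``"months"``; purely descriptive, callers must pass
        ages in the same unit as the table.
    sex :
        Optional sex label; tables are single-sex files (female is the
        documented default for this pipeline).
    """

    indicator: str
    age: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray
    age_unit: str = "years"
    sex: str | None = "female"
    _interp: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("age", "L", "M", "S"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.age.size
        if n < 1 or any(getattr(self, k).size != n for k in ("L", "M", "S")):
            raise ValueError("age, L, M, S must be equal-length and non-empty")
        if n > 1 and not np.all(np.diff(self.age) > 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(self.M <= 0) or np.any(self.S <= 0):
            raise ValueError("M and S must be strictly positive")

    @property
    def age_range(self) -> tuple[float, float]:
        return float(self.age[0]), float(self.age[-1])

    def lms_at(self, age) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Linearly interpolated (L, M, S) at ``age``; error outside range."""
        a = np.asarray(age, dtype=float)
        lo, hi = self.age_range
        if np.any(a < lo) or np.any(a > hi):
            raise ValueError(f"age outside reference range [{lo}, {hi}]")
        return (
            np.interp(a, self.age, self.L),
            np.interp(a, self.age, self.M),
            np.interp(a, self.age, self.S),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.age, "L": self.L, "M": self.M, "S": self.S})

    def write(self, path) -> None:
        """Write as delimited text; unit and indicator go in a header comment."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# indicator={self.indicator} age_unit={self.age_unit}"
                     f" sex={self.sex or 'unspecified'}\n")
            self.to_frame().to_csv(fh, index=False)


def _zscore_from_lms(value, L, M, S):
    value = np.asarray(value, dtype=float)
    L = np.asarray(L, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = value / M
        z = np.where(
            np.abs(L) > _L_EPS,
            (np.power(ratio, L) - 1.0) / (L * S),
            np.log(ratio) / S,
        )
    return z


def lms_zscore(value, age, table: LMSReferenceTable):
    """z-score of ``value`` at ``age`` against an LMS reference.

    ``value`` must be positive and ``age`` inside the table's range; both may
    be scalars or arrays (broadcast together).  Strictly increasing in
    ``value`` for fixed age.
    """
    value = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(value)) or np.any(value <= 0):
        raise ValueError("measurement values must be positive and finite")
    L, M, S = table.lms_at(age)
    z = _zscore_from_lms(value, L, M, S)
    return float(z) if np.isscalar(age) and z.ndim == 0 else z


def lms_value(z, age, table: LMSReferenceTable):
    """Inverse of :func:`lms_zscore`: the measurement at z-score ``z``."""
    z = np.asarray(z, dtype=float)
    L, M, S = table.lms_at(age)
    L = np.asarray(L, dtype=float)
    safe_L = np.where(np.abs(L) > _L_EPS, L, 1.0)
    with np.errstate(invalid="ignore"):
        val = np.where(
            np.abs(L) > _L_EPS,
            M * np.power(1.0 + L * S * z, 1.0 / safe_L),
            M * np.exp(S * z),
        )
    return float(val) if val.ndim == 0 else val


def classify_bmi_category(z) -> BMICategory | np.ndarray:
    """WHO BMI-for-age band for a z-score.

    underweight  z < -2;  normal  -2 <= z <= +1;
    overweight   +1 < z <= +2;  obesity  z > +2.
    Both -2 and +1 belong to the normal band; +2 to overweight.
    """
    zs = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(zs)):
        raise ValueError("BMI z-score must be finite")
    cats = np.select(
        [zs < -2.0, zs <= 1.0, zs <= 2.0],
        [BMICategory.UNDERWEIGHT, BMICategory.NORMAL, BMICategory.OVERWEIGHT],
        default=BMICategory.OBESITY,
    )
    return cats.item() if zs.ndim == 0 else cats


def is_stunted(haz) -> bool | np.ndarray:
    """Stunting flag: height-for-age z strictly below -2 (boundary not stunted)."""
    hz = np.asarray(haz, dtype=float)
    if np.any(~np.isfinite(hz)):
        raise ValueError("height-for-age z-score must be finite")
    out = hz < -2.0
    return bool(out) if hz.ndim == 0 else out


def read_reference_table(path, indicator: str | None = None) -> LMSReferenceTable:
    """Read a delimited LMS table (columns ``age, L, M, S``).

    A leading ``#`` comment line may declare ``indicator=... age_unit=...
    sex=...`` keys; explicit arguments win over the header.
    """
    meta = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first.lstrip("#").split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    missing = {"age", "L", "M", "S"} - set(df.columns)
    if missing:
        raise ValueError(f"reference table lacks columns: {sorted(missing)}")
    return LMSReferenceTable(
        indicator=indicator or meta.get("indicator", "unknown"),
        age=df["age"].to_numpy(),
        L=df["L"].to_numpy(),
        M=df["M"].to_numpy(),
        S=df["S"].to_numpy(),
        age_unit=meta.get("age_unit", "years"),
        sex=meta.get("sex", "female"),
    )
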
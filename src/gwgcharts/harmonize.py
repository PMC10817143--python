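"""Harmonization of longitudinal pregnancy-weight records.

Derives conception date, maternal age at conception, cumulative gestational
weight gain (GWG) and WHO-style anthropometric classifications; flags
biologically implausible weight trajectories with an automated robust-line
rule; and applies the eligibility filters in a fixed, documented order,
producing a flowchart-style :class:`ExclusionLedger` so exclusion counts are
comparable across runs.

Eligibility (all must hold): completed age 10-19 years at conception; at
least one visit in each of the second (weeks 14-27) and third (weeks 28-42)
trimesters; term birth (37-42 weeks); birth weight 2,500-4,000 g; free of
hypertension, preeclampsia, diabetes/gestational diabetes, tuberculosis and
cardiovascular disease; not stunted (height-for-age z >= -2); maximal
cumulative GWG below 30 kg (excluded at exactly 30.0); and no missing value
among the analysis variables.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reference import (LMSReferenceTable, classify_bmi_category, is_stunted,
                        lms_zscore)

__all__ = [
    "CleaningConfig",
    "ExclusionLedger",
    "TrajectoryOutlierFlagger",
    "conception_date",
    "maternal_age",
    "cumulative_gwg",
    "derive_subject_fields",
    "derive_visit_fields",
    "flag_implausible_trajectory",
    "apply_eligibility",
]

#: fixed ledger order; counts are only comparable across runs because the
#: filters are always applied in this sequence
LEDGER_ORDER = (
    "age",
    "visit_coverage",
    "term_birth",
    "birth_weight",
    "diseases",
    "stunting",
    "gwg_ge_30",
    "implausible_trajectory",
    "completeness",
)

DISEASE_FLAGS = ("flag_hypertension", "flag_preeclampsia", "flag_diabetes",
                 "flag_tuberculosis", "flag_cardiovascular")


@dataclass
class CleaningConfig:
    """Thresholds of the cleaning stage (defaults are the documented rules)."""

    age_bounds: tuple[int, int] = (10, 19)          # completed years, inclusive
    second_trimester: tuple[int, int] = (14, 27)    # weeks, inclusive
    third_trimester: tuple[int, int] = (28, 42)
    term_bounds: tuple[int, int] = (37, 42)         # GA at birth, weeks
    birth_weight_bounds: tuple[float, float] = (2500.0, 4000.0)  # grams
    gwg_cap: float = 30.0                           # exclude at >= cap
    residual_threshold_kg: float = 4.0              # trajectory QC
    rate_bounds: tuple[float, float] = (-1.0, 3.0)  # kg/week


@dataclass
class ExclusionLedger:
    """Fig-1-style accounting: one row per criterion, fixed order."""

    subjects_in: int
    visits_in: int
    rows: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, criterion: str, subjects_removed: int, visits_removed: int) -> None:
        self.rows.append((criterion, int(subjects_removed), int(visits_removed)))

    @property
    def subjects_out(self) -> int:
        return self.subjects_in - sum(r[1] for r in self.rows)

    @property
    def visits_out(self) -> int:
        return self.visits_in - sum(r[2] for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=["criterion", "subjects_removed",
                                              "visits_removed"])
        df["subjects_remaining"] = self.subjects_in - df["subjects_removed"].cumsum()
        df["visits_remaining"] = self.visits_in - df["visits_removed"].cumsum()
        return df

    def to_text(self) -> str:
        lines = [f"Initial: {self.subjects_in} subjects, {self.visits_in} visits"]
        for crit, ns, nv in self.rows:
            lines.append(f"  - {crit}: removed {ns} subjects, {nv} visits")
        lines.append(f"Final: {self.subjects_out} subjects, {self.visits_out} visits")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# date arithmetic
# ---------------------------------------------------------------------------

def conception_date(lmp: dt.date | None = None,
                    edd: dt.date | None = None,
                    ga_weeks: float | None = None,
                    at_date: dt.date | None = None) -> dt.date:
    """Conception date from exactly one anchor (pregnancy-wheel rules).

    From the last menstrual period: conception = LMP + 14 days.  From the
    estimated due date: conception = EDD - 266 days.  From a known
    gestational age at a known date: conception = date - (GA*7 - 14) days
    (gestational age is counted from the LMP, two weeks before conception).
    """
    anchors = sum(x is not None for x in (lmp, edd, ga_weeks))
    if anchors != 1:
        raise ValueError("supply exactly one of lmp, edd or ga_weeks")
    if lmp is not None:
        return lmp + dt.timedelta(days=14)
    if edd is not None:
        return edd - dt.timedelta(days=266)
    if at_date is None:
        raise ValueError("ga_weeks requires at_date")
    return at_date - dt.timedelta(days=round(ga_weeks * 7 - 14))


def maternal_age(dob: dt.date, conception: dt.date) -> int:
    """Completed years between date of birth and conception date."""
    if conception <= dob:
        raise ValueError("conception date must be after date of birth")
    years = conception.year - dob.year
    if (conception.month, conception.day) < (dob.month, dob.day):
        years -= 1
    return years


def cumulative_gwg(visit_weight: float, prepregnancy_weight: float) -> float:
    """Cumulative GWG: visit weight minus pre-pregnancy weight (may be < 0)."""
    if visit_weight is None or prepregnancy_weight is None or \
            not np.isfinite(visit_weight) or not np.isfinite(prepregnancy_weight):
        raise ValueError("both weights must be present and finite")
    if visit_weight <= 0 or prepregnancy_weight <= 0:
        raise ValueError("weights must be positive")
    return visit_weight - prepregnancy_weight


# ---------------------------------------------------------------------------
# derived fields
# ---------------------------------------------------------------------------

def _exact_years(dob: dt.date, when: dt.date) -> float:
    return (when - dob).days / 365.25


def derive_subject_fields(subjects: pd.DataFrame,
                          height_reference: LMSReferenceTable,
                          bmi_reference: LMSReferenceTable) -> pd.DataFrame:
    """Add conception date, maternal age, HAZ, BMI z and category columns.

    Expects ``date_of_birth`` and ``lmp_date`` as ISO date strings, height in
    cm and pre-pregnancy BMI in kg/m2.  Subjects whose exact age falls
    outside the reference range get NaN z-scores (handled as incomplete by
    the eligibility filter).
    """
    out = subjects.copy()
    dob = pd.to_datetime(out["date_of_birth"]).dt.date
    lmp = pd.to_datetime(out["lmp_date"]).dt.date
    conc = [conception_date(lmp=d) for d in lmp]
    out["conception_date"] = [c.isoformat() for c in conc]
    out["maternal_age_y"] = [maternal_age(b, c) for b, c in zip(dob, conc)]
    exact = np.array([_exact_years(b, c) for b, c in zip(dob, conc)])
    out["exact_age_y"] = exact

    lo_h, hi_h = height_reference.age_range
    lo_b, hi_b = bmi_reference.age_range

    def _z(val, age, ref, lo, hi):
        if not np.isfinite(val) or val <= 0 or not (lo <= age <= hi):
            return np.nan
        return lms_zscore(val, age, ref)

    out["haz"] = [
        _z(h, a, height_reference, lo_h, hi_h)
        for h, a in zip(out["height_cm"], exact)]
    out["bmi_z"] = [
        _z(b, a, bmi_reference, lo_b, hi_b)
        for b, a in zip(out["prepreg_bmi"], exact)]
    out["stunted"] = [bool(is_stunted(z)) if np.isfinite(z) else False
                      for z in out["haz"]]
    out["bmi_category"] = [
        str(classify_bmi_category(z)) if np.isfinite(z) else ""
        for z in out["bmi_z"]]
    return out


def derive_visit_fields(visits: pd.DataFrame,
                        subjects: pd.DataFrame) -> pd.DataFrame:
    """Add cumulative GWG (visit weight minus pre-pregnancy weight)."""
    out = visits.copy()
    prepreg = subjects.set_index("subject_id")["prepreg_weight_kg"]
    out["gwg_kg"] = out["weight_kg"].to_numpy() - \
        prepreg.reindex(out["subject_id"]).to_numpy()
    return out


# ---------------------------------------------------------------------------
# trajectory quality control
# ---------------------------------------------------------------------------

def flag_implausible_trajectory(ga_weeks, weights,
                                threshold_kg: float = 4.0,
                                rate_bounds: tuple[float, float] = (-1.0, 3.0),
                                ) -> np.ndarray:
    """Flag biologically implausible visits of one subject.

    Iterative robust rule: fit a repeated-median (Siegel) straight line to
    weight versus gestational age; take the visit with the largest absolute
    residual and flag it if that residual exceeds ``threshold_kg`` or if
    either inter-visit weight-change rate adjacent to it falls outside
    ``rate_bounds`` (kg/week); refit on the unflagged visits and repeat until
    nothing is flagged or fewer than three visits remain.  Duplicate
    gestational ages with discordant weights are all flagged up front.
    Fewer than three distinct-age visits: nothing is flagged.

    Returns a boolean array (True = implausible), aligned with the input.
    """
    ga = np.asarray(ga_weeks, dtype=float)
    wt = np.asarray(weights, dtype=float)
    n = ga.size
    flags = np.zeros(n, dtype=bool)

    # discordant duplicates: same gestational age, different weights
    order = np.argsort(ga, kind="stable")
    for g in np.unique(ga):
        idx = np.where(ga == g)[0]
        if idx.size > 1 and np.unique(wt[idx]).size > 1:
            flags[idx] = True

    # concordant duplicates: fit on the first of each (ga, weight) pair only
    seen: set[tuple[float, float]] = set()
    fit_mask = ~flags
    for i in order:
        key = (ga[i], wt[i])
        if not flags[i]:
            if key in seen:
                fit_mask[i] = False
            seen.add(key)

    lo_rate, hi_rate = rate_bounds
    while True:
        active = np.where(fit_mask & ~flags)[0]
        if active.size < 3 or np.unique(ga[active]).size < 3:
            break
        slope, intercept = stats.siegelslopes(wt[active], ga[active])
        resid = wt[active] - (intercept + slope * ga[active])
        k = int(np.argmax(np.abs(resid)))
        cand = active[k]
        big_resid = abs(resid[k]) > threshold_kg

        srt = active[np.argsort(ga[active], kind="stable")]
        pos = int(np.where(srt == cand)[0][0])
        bad_rate = False
        for nb in (pos - 1, pos + 1):
            if 0 <= nb < srt.size:
                other = srt[nb]
                dga = ga[cand] - ga[other]
                if dga != 0:
                    rate = (wt[cand] - wt[other]) / dga
                    if not (lo_rate <= rate <= hi_rate):
                        bad_rate = True
        if big_resid or (bad_rate and abs(resid[k]) > 1e-12):
            flags[cand] = True
        else:
            break
    return flags


class TrajectoryOutlierFlagger:
    """Transformer flagging implausible weight records, subject by subject.

    scikit-learn style: ``transform`` returns the visit table with a
    ``qc_flag`` column (``"ok"`` / ``"implausible"``); the flagger is
    stateless, ``fit`` only validates parameters.
    """

    def __init__(self, threshold_kg: float = 4.0,
                 rate_bounds: tuple[float, float] = (-1.0, 3.0)):
        self.threshold_kg = threshold_kg
        self.rate_bounds = rate_bounds

    def get_params(self, deep: bool = True) -> dict:
        return {"threshold_kg": self.threshold_kg, "rate_bounds": self.rate_bounds}

    def set_params(self, **params) -> "TrajectoryOutlierFlagger":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "TrajectoryOutlierFlagger":
        if self.threshold_kg <= 0:
            raise ValueError("threshold_kg must be positive")
        lo, hi = self.rate_bounds
        if lo >= hi:
            raise ValueError("rate_bounds must be an increasing pair")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        flagged = np.zeros(len(out), dtype=bool)
        for _, idx in out.groupby("subject_id", sort=False).groups.items():
            sub = out.loc[idx]
            f = flag_implausible_trajectory(
                sub["ga_weeks"].to_numpy(), sub["weight_kg"].to_numpy(),
                threshold_kg=self.threshold_kg, rate_bounds=self.rate_bounds)
            flagged[out.index.get_indexer(idx)] = f
        out["qc_flag"] = np.where(flagged, "implausible", "ok")
        return out

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

_REQUIRED_SUBJECT_FIELDS = ("maternal_age_y", "prepreg_weight_kg", "height_cm",
                            "prepreg_bmi", "haz", "birth_weight_g",
                            "birth_length_cm")


def apply_eligibility(subjects: pd.DataFrame, visits: pd.DataFrame,
                      config: CleaningConfig | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionLedger]:
    """Filter subjects/visits by the eligibility rules, in the fixed order.

    Inputs must already carry the derived columns from
    :func:`derive_subject_fields` / :func:`derive_visit_fields`.  Removing a
    subject removes all their visits; the trajectory step removes single
    visits, plus any subject who thereby loses second/third-trimester
    coverage.  Ineligibility is ledger accounting, never an error; the
    filter is idempotent.
    """
    cfg = config or CleaningConfig()
    subj = subjects.copy()
    vis = visits.copy()
    ledger = ExclusionLedger(subjects_in=len(subj), visits_in=len(vis))

    def _drop_subjects(bad_ids, criterion):
        bad_ids = set(bad_ids)
        ns = subj["subject_id"].isin(bad_ids).sum()
        nv = vis["subject_id"].isin(bad_ids).sum()
        ledger.add(criterion, ns, nv)
        return (subj[~subj["subject_id"].isin(bad_ids)],
                vis[~vis["subject_id"].isin(bad_ids)])

    # 1. age at conception
    lo, hi = cfg.age_bounds
    bad = subj.loc[~subj["maternal_age_y"].between(lo, hi) |
                   subj["maternal_age_y"].isna(), "subject_id"]
    subj, vis = _drop_subjects(bad, "age")

    # 2. visit coverage: >=1 visit in each of trimesters 2 and 3
    cov = vis.assign(
        t2=vis["ga_weeks"].between(*cfg.second_trimester),
        t3=vis["ga_weeks"].between(*cfg.third_trimester),
    ).groupby("subject_id")[["t2", "t3"]].any()
    covered = cov.index[cov["t2"] & cov["t3"]]
    bad = subj.loc[~subj["subject_id"].isin(covered), "subject_id"]
    subj, vis = _drop_subjects(bad, "visit_coverage")

    # 3. term birth
    lo, hi = cfg.term_bounds
    bad = subj.loc[~subj["ga_birth_weeks"].between(lo, hi) |
                   subj["ga_birth_weeks"].isna(), "subject_id"]
    subj, vis = _drop_subjects(bad, "term_birth")

    # 4. birth weight
    lo, hi = cfg.birth_weight_bounds
    bad = subj.loc[~subj["birth_weight_g"].between(lo, hi) |
                   subj["birth_weight_g"].isna(), "subject_id"]
    subj, vis = _drop_subjects(bad, "birth_weight")

    # 5. diseases
    present = [c for c in DISEASE_FLAGS if c in subj.columns]
    diseased = subj[present].fillna(False).astype(bool).any(axis=1) \
        if present else pd.Series(False, index=subj.index)
    subj, vis = _drop_subjects(subj.loc[diseased, "subject_id"], "diseases")

    # 6. stunting (HAZ < -2, strict)
    bad = subj.loc[subj["haz"].notna() & (subj["haz"] < -2.0), "subject_id"]
    subj, vis = _drop_subjects(bad, "stunting")

    # 7. maximal cumulative GWG >= cap (inclusive at the cap)
    max_gwg = vis.groupby("subject_id")["gwg_kg"].max()
    bad = max_gwg.index[max_gwg >= cfg.gwg_cap]
    subj, vis = _drop_subjects(bad, "gwg_ge_30")

    # 8. implausible-trajectory visit removal (visits, not subjects; but a
    #    subject who loses trimester coverage here is removed here too)
    flagger = TrajectoryOutlierFlagger(threshold_kg=cfg.residual_threshold_kg,
                                       rate_bounds=cfg.rate_bounds)
    flagged = flagger.fit_transform(vis)
    keep_vis = flagged["qc_flag"].eq("ok").to_numpy()
    n_removed_vis = int((~keep_vis).sum())
    vis = vis[keep_vis]
    cov = vis.assign(
        t2=vis["ga_weeks"].between(*cfg.second_trimester),
        t3=vis["ga_weeks"].between(*cfg.third_trimester),
    ).groupby("subject_id")[["t2", "t3"]].any()
    covered = set(cov.index[cov["t2"] & cov["t3"]])
    bad = set(subj["subject_id"]) - covered
    ns = len(bad)
    nv_extra = int(vis["subject_id"].isin(bad).sum())
    subj = subj[~subj["subject_id"].isin(bad)]
    vis = vis[~vis["subject_id"].isin(bad)]
    ledger.add("implausible_trajectory", ns, n_removed_vis + nv_extra)

    # 9. completeness of the analysis variables
    incomplete = subj[list(_REQUIRED_SUBJECT_FIELDS)].isna().any(axis=1)
    bad_vis = vis["gwg_kg"].isna() | vis["ga_weeks"].isna()
    bad_ids = set(subj.loc[incomplete, "subject_id"]) | \
        set(vis.loc[bad_vis, "subject_id"])
    subj, vis = _drop_subjects(bad_ids, "completeness")

    return subj.reset_index(drop=True), vis.reset_index(drop=True), ledger
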
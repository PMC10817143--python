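"""Synthetic multi-country adolescent pregnancy cohorts.

Emulates the structure of a harmonized nine-country antenatal dataset:
site-level shifts in height and gestational weight gain (GWG), a
four-category pre-pregnancy BMI mix dominated by normal weight, individual
GWG trajectories that are near-flat in the first trimester and rise through
pregnancy, missing first-trimester weights driven by late entry into
prenatal care (missing not at random: the latent care-entry week, not any
observed variable, decides the deletion), and occasional implausible weight
records injected as isolated jumps.

Every downstream stage of the pipeline is testable against the
:class:`SyntheticTruth` ground truth this module returns alongside the data.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .reference import LMSReferenceTable, lms_value

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_reference_table",
    "default_height_reference",
    "default_bmi_reference",
]

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obesity")

# Default first-visit (care-entry) week distribution over weeks 2-20.
# Mass after week 13 is 0.10: the fraction of subjects entering care too late
# to have any first-trimester weight.
_EARLY_SHAPE = {2: 1, 3: 2, 4: 3, 5: 5, 6: 7, 7: 9, 8: 10, 9: 10, 10: 9,
                11: 8, 12: 7, 13: 6}
_LATE_SHAPE = {14: 3.0, 15: 2.5, 16: 2.0, 17: 1.5, 18: 1.0, 19: 0.7, 20: 0.3}


def _default_first_visit_pmf() -> dict[int, float]:
    early_tot = sum(_EARLY_SHAPE.values())
    late_tot = sum(_LATE_SHAPE.values())
    pmf = {w: 0.90 * v / early_tot for w, v in _EARLY_SHAPE.items()}
    pmf.update({w: 0.10 * v / late_tot for w, v in _LATE_SHAPE.items()})
    return pmf


def _default_trajectory_params() -> dict[str, dict[str, float]]:
    """Piecewise-quadratic mean GWG curves (kg vs completed week).

    m(t) = early_rate * t                                   for t <= 13
    m(t) = m(13) + mid_rate * u + accel * u**2,  u = t - 13  for t > 13

    Totals at week 40 descend with BMI category (heavier categories gain
    less), with most gain in the third trimester.
    """
    params = {}
    totals = {"underweight": 15.0, "normal": 11.0, "overweight": 9.0,
              "obesity": 7.0}
    for cat, total in totals.items():
        early_rate, mid_rate = 0.05, 0.15
        accel = (total - early_rate * 13 - mid_rate * 27) / 27.0 ** 2
        params[cat] = {"early_rate": early_rate, "mid_rate": mid_rate,
                       "accel": accel}
    return params


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    The defaults emulate a nine-site Latin-American adolescent cohort:
    BMI-category mix heavily dominated by normal weight, ~10% of subjects
    entering prenatal care after week 13 (hence no first-trimester weight),
    roughly four-weekly visits, and a small rate of implausible records.
    """

    n_sites: int = 9
    subjects_per_site: int = 240
    site_height_shift_sd: float = 1.5          # cm
    site_gwg_shift_sd: float = 0.5             # kg at term
    bmi_category_probs: tuple[float, float, float, float] = (
        0.015, 0.718, 0.214, 0.053)            # underweight/normal/overweight/obesity
    trajectory_params: dict[str, dict[str, float]] = field(
        default_factory=_default_trajectory_params)
    residual_sd: float = 0.8                   # kg, visit-level noise
    subject_effect_sd: float = 0.15            # multiplicative trajectory factor SD
    first_visit_week_distribution: dict[int, float] = field(
        default_factory=_default_first_visit_pmf)
    visit_spacing_weeks: float = 4.0           # mean inter-visit gap
    outlier_rate: float = 0.02                 # per interior visit
    outlier_magnitude: float = 10.0            # kg, additive jump
    disease_rate: float = 0.02                 # any of the five exclusion flags
    preterm_rate: float = 0.04                 # GA at birth < 37 weeks
    overage_rate: float = 0.015                # conception age 20 (ineligible)
    missing_birth_length_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.subjects_per_site < 1:
            raise ValueError("counts must be >= 1")
        probs = np.asarray(self.bmi_category_probs, dtype=float)
        if probs.size != 4 or np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("bmi_category_probs must be 4 probabilities")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("bmi_category_probs must sum to 1 within 1e-9")
        pmf = self.first_visit_week_distribution
        if not pmf or any(w < 2 or w > 20 for w in pmf):
            raise ValueError("first-visit weeks must lie in [2, 20]")
        total = sum(pmf.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("first-visit distribution must sum to 1")
        for cat in BMI_CATEGORIES:
            if cat not in self.trajectory_params:
                raise ValueError(f"trajectory_params missing category {cat!r}")
            curve = mean_gwg_curve(np.arange(43), self.trajectory_params[cat])
            # pre-pregnancy weights are drawn above 30 kg; a curve dipping
            # below -30 kg would produce negative visit weights
            if np.min(curve) <= -30.0:
                raise ValueError(
                    f"trajectory curve for {cat!r} produces negative weights")

    # -- serialisation ---------------------------------------------------
    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["bmi_category_probs"] = list(self.bmi_category_probs)
        data["first_visit_week_distribution"] = {
            int(k): float(v) for k, v in self.first_visit_week_distribution.items()}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"cohort": data}, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        data = data.get("cohort", data)
        if "bmi_category_probs" in data:
            data["bmi_category_probs"] = tuple(data["bmi_category_probs"])
        if "first_visit_week_distribution" in data:
            data["first_visit_week_distribution"] = {
                int(k): float(v)
                for k, v in data["first_visit_week_distribution"].items()}
        return cls(**data)


@dataclass
class SyntheticTruth:
    """Ground truth for parameter-recovery tests.

    Attributes
    ----------
    subject_truth :
        Per subject: intended BMI category, latent care-entry week,
        multiplicative trajectory factor, site GWG shift received.
    site_shifts :
        Per site: height shift (cm) and GWG shift at term (kg).
    outlier_visit_ids :
        ``visit_id`` values whose weight was replaced by an implausible one.
    deleted_visits :
        First-trimester rows (gestational age 5-13) removed by the late-entry
        MNAR mechanism, with their pre-deletion weights.
    """

    subject_truth: pd.DataFrame
    site_shifts: pd.DataFrame
    outlier_visit_ids: list[int]
    deleted_visits: pd.DataFrame


def mean_gwg_curve(weeks, params: dict[str, float]) -> np.ndarray:
    """Evaluate a piecewise-quadratic mean GWG curve at completed weeks."""
    t = np.asarray(weeks, dtype=float)
    early = params["early_rate"] * np.minimum(t, 13.0)
    u = np.maximum(t - 13.0, 0.0)
    return early + params["mid_rate"] * u + params["accel"] * u ** 2


def generate_reference_table(age_grid, L_curve, M_curve, S_curve,
                             indicator: str = "synthetic",
                             age_unit: str = "years") -> LMSReferenceTable:
    """Build an LMS reference table on a grid; M and S must be positive."""
    M = np.asarray(M_curve, dtype=float)
    S = np.asarray(S_curve, dtype=float)
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("M and S curves must be strictly positive")
    return LMSReferenceTable(indicator=indicator, age=np.asarray(age_grid, float),
                             L=np.asarray(L_curve, float), M=M, S=S,
                             age_unit=age_unit)


def default_height_reference() -> LMSReferenceTable:
    """Synthetic female height-for-age reference, ages 10-20 years.

    A smooth stand-in laid out like the WHO 2007 tables (not the WHO
    values); medians plateau around 163 cm by late adolescence.
    """
    ages = np.arange(10, 22, dtype=float)
    M = np.array([138.6, 145.0, 151.2, 156.4, 159.8, 161.7,
                  162.5, 162.9, 163.1, 163.2, 163.2, 163.2])
    S = np.linspace(0.045, 0.037, ages.size)
    L = np.ones_like(ages)
    return generate_reference_table(ages, L, M, S, indicator="height-for-age")


def default_bmi_reference() -> LMSReferenceTable:
    """Synthetic female BMI-for-age reference, ages 10-20 years (WHO layout)."""
    ages = np.arange(10, 22, dtype=float)
    M = np.array([16.9, 17.7, 18.6, 19.4, 20.2, 20.9,
                  21.5, 22.0, 22.4, 22.7, 22.9, 23.0])
    S = np.full(ages.size, 0.12)
    L = np.linspace(-1.2, -1.0, ages.size)
    return generate_reference_table(ages, L, M, S, indicator="bmi-for-age")


# conception-age distribution (completed years); mass at 20 is controlled by
# overage_rate and exercises the age-eligibility filter downstream
_AGE_PMF = {13: 0.05, 14: 0.12, 15: 0.15, 16: 0.15, 17: 0.15, 18: 0.20, 19: 0.18}

_TRUNC_BANDS = {
    "underweight": (-3.5, -2.0 - 1e-9),
    "normal": (-2.0, 1.0),
    "overweight": (1.0 + 1e-9, 2.0),
    "obesity": (2.0 + 1e-9, 3.5),
}


def _truncated_normal(rng: np.random.Generator, lo: float, hi: float,
                      size: int) -> np.ndarray:
    from scipy import stats
    u = rng.uniform(stats.norm.cdf(lo), stats.norm.cdf(hi), size=size)
    return stats.norm.ppf(u)


def _shift_years(date: dt.date, years: int) -> dt.date:
    try:
        return date.replace(year=date.year - years)
    except ValueError:                      # Feb 29 -> Feb 28
        return date.replace(year=date.year - years, day=28)


def generate_cohort(
    config: CohortConfig,
    height_reference: LMSReferenceTable | None = None,
    bmi_reference: LMSReferenceTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (subject table, visit table, truth) for one cohort.

    Deterministic under ``config.seed``: identical configs give identical
    tables.  Every subject has at least one visit in weeks 14-27 and one in
    weeks 28-42; a config-controlled fraction (the late-entry mass of
    ``first_visit_week_distribution``) has all week-5-13 visits deleted.
    """
    rng = np.random.default_rng(config.seed)
    h_ref = height_reference or default_height_reference()
    b_ref = bmi_reference or default_bmi_reference()

    n = config.n_sites * config.subjects_per_site
    sites = [f"site_{i + 1:02d}" for i in range(config.n_sites)]

    site_height = rng.normal(0.0, config.site_height_shift_sd, config.n_sites)
    site_gwg = rng.normal(0.0, config.site_gwg_shift_sd, config.n_sites)
    site_shifts = pd.DataFrame({"site": sites, "height_shift_cm": site_height,
                                "gwg_shift_kg": site_gwg})

    # ---- subject-level draws ------------------------------------------
    site_idx = np.repeat(np.arange(config.n_sites), config.subjects_per_site)
    subject_ids = np.array([f"S{i + 1:05d}" for i in range(n)])

    age_weeks = list(_AGE_PMF.items())
    ages_y = np.array([a for a, _ in age_weeks])
    age_p = np.array([p for _, p in age_weeks], dtype=float)
    age_p = age_p * (1.0 - config.overage_rate) / age_p.sum()
    ages_y = np.append(ages_y, 20)
    age_p = np.append(age_p, config.overage_rate)
    age_years = rng.choice(ages_y, size=n, p=age_p)
    extra_days = rng.integers(5, 360, size=n)

    conception = np.array(
        [dt.date(2018, 1, 1) + dt.timedelta(days=int(d))
         for d in rng.integers(0, 365 * 3, size=n)])
    dob = np.array([
        _shift_years(c, int(a)) - dt.timedelta(days=int(e))
        for c, a, e in zip(conception, age_years, extra_days)])
    exact_age = np.array([(c - b).days / 365.25 for c, b in zip(conception, dob)])

    categories = rng.choice(BMI_CATEGORIES, size=n,
                            p=np.asarray(config.bmi_category_probs, float))

    haz = rng.normal(-0.3, 1.0, size=n)
    height = np.array(
        [lms_value(z, a, h_ref) for z, a in zip(haz, exact_age)])
    height = np.round(height + site_height[site_idx], 1)

    bmi_z = np.empty(n)
    for cat, (lo, hi) in _TRUNC_BANDS.items():
        mask = categories == cat
        bmi_z[mask] = _truncated_normal(rng, lo, hi, int(mask.sum()))
    bmi = np.array([lms_value(z, a, b_ref) for z, a in zip(bmi_z, exact_age)])
    prepreg_weight = np.round(bmi * (height / 100.0) ** 2, 1)
    prepreg_weight = np.maximum(prepreg_weight, 30.0)
    prepreg_bmi = np.round(prepreg_weight / (height / 100.0) ** 2, 2)

    disease = rng.random(n) < config.disease_rate
    which_flag = rng.integers(0, 5, size=n)
    flags = np.zeros((n, 5), dtype=bool)
    flags[disease, which_flag[disease]] = True

    preterm = rng.random(n) < config.preterm_rate
    ga_birth = np.where(
        preterm,
        rng.integers(34, 37, size=n),
        rng.choice([37, 38, 39, 40, 41], size=n, p=[0.15, 0.25, 0.3, 0.2, 0.1]))
    birth_weight = np.round(rng.normal(3200.0, 350.0, size=n), 0)
    birth_length = np.round(rng.normal(49.0, 2.0, size=n), 1)
    birth_length[rng.random(n) < config.missing_birth_length_rate] = np.nan

    weight_source = rng.choice(["measured", "medical-record", "self-reported"],
                               size=n, p=[0.3, 0.5, 0.2])

    subjects = pd.DataFrame({
        "subject_id": subject_ids,
        "site": np.array(sites)[site_idx],
        "date_of_birth": [d.isoformat() for d in dob],
        "lmp_date": [(c - dt.timedelta(days=14)).isoformat() for c in conception],
        "prepreg_weight_kg": prepreg_weight,
        "prepreg_weight_source": weight_source,
        "height_cm": height,
        "prepreg_bmi": prepreg_bmi,
        "flag_hypertension": flags[:, 0],
        "flag_preeclampsia": flags[:, 1],
        "flag_diabetes": flags[:, 2],
        "flag_tuberculosis": flags[:, 3],
        "flag_cardiovascular": flags[:, 4],
        "ga_birth_weeks": ga_birth.astype(int),
        "birth_weight_g": birth_weight,
        "birth_length_cm": birth_length,
    })

    # ---- visit schedules and MNAR deletion ----------------------------
    entry_weeks = rng.choice(
        list(config.first_visit_week_distribution),
        size=n, p=list(config.first_visit_week_distribution.values()))
    traj_factor = np.maximum(rng.normal(1.0, config.subject_effect_sd, n), 0.4)

    rows, deleted_rows = [], []
    outlier_ids: list[int] = []
    visit_id = 0
    for i in range(n):
        params = config.trajectory_params[categories[i]]
        last_week = int(min(ga_birth[i], 40))
        entry = int(entry_weeks[i])
        base = []
        w = int(rng.integers(5, 10))
        while w <= last_week:
            base.append(w)
            w += max(1, int(round(rng.normal(config.visit_spacing_weeks, 1.0))))
        # guarantee second- and third-trimester coverage
        if not any(14 <= x <= 27 for x in base):
            base.append(int(rng.integers(16, 25)))
        if not any(28 <= x <= 42 for x in base):
            base.append(min(last_week, int(rng.integers(30, 37))))
        base = set(base)

        # MNAR late-entry deletion: scheduled first-trimester visits before
        # the latent care-entry week never happened; a subject entering at
        # week <= 13 has their first visit at the entry week itself, so only
        # entry after week 13 leaves the window empty
        if entry > 13:
            deleted_weeks = {x for x in base if 5 <= x <= 13}
        else:
            deleted_weeks = {x for x in base if 5 <= x <= 13 and x < entry}
            kept_window = {x for x in base - deleted_weeks if 5 <= x <= 13}
            if entry >= 5 and not kept_window:
                base.add(entry)
        weeks = sorted(base)

        curve = mean_gwg_curve(np.asarray(weeks, float), params)
        gwg = (curve * traj_factor[i]
               + site_gwg[site_idx[i]] * np.asarray(weeks, float) / 40.0
               + rng.normal(0.0, config.residual_sd, len(weeks)))
        weights = np.round(prepreg_weight[i] + gwg, 1)

        # implausible-record injection at interior visits
        jump = rng.random(len(weeks)) < config.outlier_rate
        sign = rng.choice([-1.0, 1.0], size=len(weeks))
        for k, (wk, wt) in enumerate(zip(weeks, weights)):
            is_outlier = bool(jump[k]) and 0 < k < len(weeks) - 1
            if is_outlier:
                wt = round(wt + sign[k] * config.outlier_magnitude, 1)
            row = (visit_id, subject_ids[i], int(wk), float(wt))
            if wk in deleted_weeks:
                deleted_rows.append(row)
            else:
                rows.append(row)
                if is_outlier:
                    outlier_ids.append(visit_id)
            visit_id += 1

    visits = pd.DataFrame(rows, columns=["visit_id", "subject_id",
                                         "ga_weeks", "weight_kg"])
    deleted = pd.DataFrame(deleted_rows, columns=["visit_id", "subject_id",
                                                  "ga_weeks", "weight_kg"])

    subject_truth = pd.DataFrame({
        "subject_id": subject_ids,
        "bmi_category": categories,
        "entry_week": entry_weeks.astype(int),
        "trajectory_factor": traj_factor,
        "site_gwg_shift_kg": site_gwg[site_idx],
    })
    truth = SyntheticTruth(subject_truth=subject_truth, site_shifts=site_shifts,
                           outlier_visit_ids=outlier_ids, deleted_visits=deleted)
    return subjects, visits, truth
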
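"""First-trimester weight imputation under MNAR, with Rubin's-rules pooling.

Subjects with no weight measurement in gestational weeks 5-13 (late entry
into prenatal care: missingness driven by an unobserved quantity, hence
missing not at random) get an imputed weight at a single random week drawn
uniformly from the window.  Imputation is univariate normal-linear-model
with bootstrap ("norm.boot"): each of the m imputations bootstrap-resamples
the complete cases, takes the least-squares coefficients and residual SD
from the resample, and simulates the missing weight with Gaussian noise —
so parameter uncertainty is propagated without an explicit posterior.  A
predictive-mean-matching imputer with the same interface is available as a
comparator.  Estimates over the m completed datasets are combined with
Rubin's rules (Qbar, within-variance Ubar, between-variance B, total
T = Ubar + (1 + 1/m) B).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ImputationSpec",
    "PooledEstimate",
    "NormBootImputer",
    "PMMImputer",
    "find_missing_first_trimester",
    "assign_random_week",
    "rubin_pool",
    "impute_pipeline",
]


@dataclass
class ImputationSpec:
    """Configuration of the first-trimester imputation stage.

    ``iterations`` is accepted for interface fidelity with chained-equations
    software but is a no-op here: with a single incomplete variable there is
    nothing to cycle over.  ``categories`` toggles which pre-pregnancy BMI
    categories are imputed (default: the sparse ones).
    """

    window: tuple[int, int] = (5, 13)
    m: int = 5
    iterations: int = 50
    predictors: tuple[str, ...] = ("assigned_week", "n_visits")
    categories: tuple[str, ...] = ("underweight", "overweight")
    method: str = "norm_boot"            # or "pmm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        lo, hi = self.window
        if not (0 <= lo <= hi <= 13):
            raise ValueError("window must lie within the first trimester")
        if not self.predictors:
            raise ValueError("predictor set must be non-empty")


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m point estimates and variances."""

    Qbar: float
    Ubar: float
    B: float
    T: float
    df: float
    m: int

    def confint(self, level: float = 0.95) -> tuple[float, float]:
        from scipy import stats
        if self.T == 0:
            return (self.Qbar, self.Qbar)
        q = stats.t.ppf(0.5 + level / 2,
                        self.df if np.isfinite(self.df) else 1e12)
        half = q * np.sqrt(self.T)
        return (self.Qbar - half, self.Qbar + half)


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Pool m completed-data estimates by Rubin's rules.

    Qbar = mean(Q); Ubar = mean(U); B = sample variance of Q;
    T = Ubar + (1 + 1/m) B; df = (m-1) (1 + Ubar / ((1 + 1/m) B))^2,
    infinite when B = 0.
    """
    Q = np.asarray(estimates, dtype=float)
    U = np.asarray(variances, dtype=float)
    m = Q.size
    if m < 2 or U.size != m:
        raise ValueError("need m >= 2 estimates with matching variances")
    if np.any(U < 0):
        raise ValueError("variances must be non-negative")
    Qbar = float(Q.mean())
    Ubar = float(U.mean())
    B = float(Q.var(ddof=1))
    T = Ubar + (1.0 + 1.0 / m) * B
    if B > 0:
        df = (m - 1) * (1.0 + Ubar / ((1.0 + 1.0 / m) * B)) ** 2
    else:
        df = np.inf
    return PooledEstimate(Qbar=Qbar, Ubar=Ubar, B=B, T=float(T), df=float(df), m=m)


def find_missing_first_trimester(visits: pd.DataFrame,
                                 window: tuple[int, int] = (5, 13),
                                 subject_ids=None) -> set[str]:
    """Subjects with zero visits at gestational age inside ``window``.

    ``subject_ids`` optionally supplies the full roster (subjects with no
    visits at all would otherwise be invisible).
    """
    lo, hi = window
    if len(visits):
        has = set(visits.loc[visits["ga_weeks"].between(lo, hi), "subject_id"])
        roster = set(subject_ids) if subject_ids is not None \
            else set(visits["subject_id"])
    else:
        has = set()
        roster = set(subject_ids) if subject_ids is not None else set()
    return roster - has


def assign_random_week(subject_ids, window: tuple[int, int] = (5, 13),
                       seed: int | np.random.Generator = 0) -> dict[str, int]:
    """Independent uniform integer week in ``window`` per subject.

    The assignment is made once per subject and shared by all m imputations.
    Subjects are processed in sorted order so the map is seed-reproducible
    regardless of input ordering.
    """
    lo, hi = window
    if hi < lo:
        raise ValueError("empty window")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    ids = sorted(subject_ids)
    weeks = rng.integers(lo, hi + 1, size=len(ids))
    return {s: int(w) for s, w in zip(ids, weeks)}


class NormBootImputer:
    """Univariate normal-linear-model imputer with bootstrap ("norm.boot").

    scikit-learn style: ``fit(X, y)`` stores the complete cases, and
    ``sample(X_missing, m)`` returns an (m, n_missing) array of imputations.
    Each imputation draws a bootstrap sample of the complete cases, takes
    the least-squares coefficients and the residual SD (denominator n - p)
    from it, and returns X beta* plus i.i.d. Gaussian noise.  Rank-deficient
    bootstrap samples are redrawn (up to ``max_redraws``).
    """

    def __init__(self, random_state: int | None = 0, max_redraws: int = 100):
        self.random_state = random_state
        self.max_redraws = max_redraws

    def get_params(self, deep: bool = True) -> dict:
        return {"random_state": self.random_state,
                "max_redraws": self.max_redraws}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _design(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return np.column_stack([np.ones(len(X)), X])

    def fit(self, X, y) -> "NormBootImputer":
        D = self._design(X)
        y = np.asarray(y, dtype=float)
        if len(y) != len(D):
            raise ValueError("X and y lengths differ")
        if len(y) <= D.shape[1]:
            raise ValueError("need more complete cases than parameters")
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            raise ValueError("design matrix is rank deficient")
        self.X_, self.y_ = D, y
        self.n_features_in_ = D.shape[1] - 1
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "X_"):
            raise ValueError("imputer is not fitted")

    def _one_draw(self, rng: np.random.Generator) -> tuple[np.ndarray, float]:
        n, p = self.X_.shape
        for _ in range(self.max_redraws):
            idx = rng.integers(0, n, size=n)
            Xb, yb = self.X_[idx], self.y_[idx]
            if np.linalg.matrix_rank(Xb) == p:
                beta, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
                resid = yb - Xb @ beta
                dof = max(n - p, 1)
                sigma = float(np.sqrt(resid @ resid / dof))
                return beta, sigma
        raise ValueError("persistent rank deficiency in bootstrap samples")

    def sample(self, X_missing, m: int = 5,
               rng: np.random.Generator | None = None) -> np.ndarray:
        """m independent imputations for the missing cases, shape (m, n_mis)."""
        self._check_fitted()
        rng = rng or np.random.default_rng(self.random_state)
        D = self._design(X_missing)
        if D.shape[1] != self.X_.shape[1]:
            raise ValueError("X_missing has wrong number of predictors")
        out = np.empty((m, len(D)))
        for k in range(m):
            beta, sigma = self._one_draw(rng)
            out[k] = D @ beta + rng.normal(0.0, sigma, size=len(D))
        return out


class PMMImputer(NormBootImputer):
    """Predictive-mean-matching comparator with the norm.boot interface.

    Coefficients are perturbed by the same bootstrap device; each missing
    case receives the observed outcome of a donor drawn uniformly from the
    ``k`` complete cases whose (unperturbed) predicted means are closest to
    the case's perturbed predicted mean.
    """

    def __init__(self, random_state: int | None = 0, max_redraws: int = 100,
                 k: int = 5):
        super().__init__(random_state=random_state, max_redraws=max_redraws)
        self.k = k

    def get_params(self, deep: bool = True) -> dict:
        return {**super().get_params(deep), "k": self.k}

    def sample(self, X_missing, m: int = 5,
               rng: np.random.Generator | None = None) -> np.ndarray:
        self._check_fitted()
        rng = rng or np.random.default_rng(self.random_state)
        D = self._design(X_missing)
        beta_hat, *_ = np.linalg.lstsq(self.X_, self.y_, rcond=None)
        pred_obs = self.X_ @ beta_hat
        out = np.empty((m, len(D)))
        k = min(self.k, len(self.y_))
        for j in range(m):
            beta, _ = self._one_draw(rng)
            pred_mis = D @ beta
            for i, pm in enumerate(pred_mis):
                order = np.argsort(np.abs(pred_obs - pm), kind="stable")[:k]
                out[j, i] = self.y_[order[rng.integers(0, k)]]
        return out


def _first_window_visit(visits: pd.DataFrame, window) -> pd.DataFrame:
    lo, hi = window
    ft = visits[visits["ga_weeks"].between(lo, hi)]
    ft = ft.sort_values(["subject_id", "ga_weeks"], kind="stable")
    return ft.groupby("subject_id", as_index=False).first()


#: predictor names resolvable by impute_pipeline; "assigned_week" is the
#: observed (complete cases) or randomly assigned (missing cases) week
PREDICTOR_SOURCES = ("assigned_week", "n_visits", "height_cm",
                     "prepreg_weight_kg", "prepreg_bmi")


def _predictor_matrix(names, week, ids, subjects: pd.DataFrame,
                      n_visits: pd.Series) -> np.ndarray:
    cols = []
    lut = subjects.set_index("subject_id")
    for name in names:
        if name == "assigned_week":
            cols.append(np.asarray(week, dtype=float))
        elif name == "n_visits":
            cols.append(n_visits.reindex(ids).fillna(0).to_numpy(float))
        elif name in lut.columns:
            cols.append(lut[name].reindex(ids).to_numpy(float))
        else:
            raise ValueError(f"unknown predictor {name!r}; "
                             f"known: {PREDICTOR_SOURCES}")
    return np.column_stack(cols)


def impute_pipeline(subjects: pd.DataFrame, visits: pd.DataFrame,
                    spec: ImputationSpec | None = None,
                    ) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Impute first-trimester weight; return m completed tables + diagnostics.

    Subjects must carry ``bmi_category``; only categories toggled in the
    spec are imputed, each with its own model (predictors: assigned/observed
    first-trimester week and the subject's number of antenatal visits).
    Observed rows are returned untouched and identical across the m copies;
    imputed rows are appended with ``imputed=True`` and the imputation index.
    """
    spec = spec or ImputationSpec()
    rng = np.random.default_rng(spec.seed)

    n_visits = visits.groupby("subject_id").size().rename("n_visits")
    cat = subjects.set_index("subject_id")["bmi_category"]

    missing_all = find_missing_first_trimester(
        visits, spec.window, subject_ids=subjects["subject_id"])

    diag_rows = []
    to_impute: dict[str, dict] = {}     # category -> model inputs
    for category in sorted(cat.dropna().unique()):
        ids = set(cat.index[cat == category])
        n_missing = len(ids & missing_all)
        frac = n_missing / len(ids) if ids else 0.0
        toggled = category in spec.categories
        diag_rows.append({"bmi_category": category, "n_subjects": len(ids),
                          "n_missing_first_trimester": n_missing,
                          "missing_fraction": frac, "imputed": toggled})
        if not toggled or n_missing == 0:
            continue

        obs_ids = ids - missing_all
        first = _first_window_visit(visits[visits["subject_id"].isin(obs_ids)],
                                    spec.window)
        if first.empty:
            raise ValueError(
                f"category {category!r} toggled on but has no complete cases")
        X_obs = _predictor_matrix(spec.predictors,
                                  first["ga_weeks"].to_numpy(float),
                                  first["subject_id"], subjects, n_visits)
        y_obs = first["weight_kg"].to_numpy(float)

        mis_ids = sorted(ids & missing_all)
        assigned = assign_random_week(mis_ids, spec.window, seed=rng)
        X_mis = _predictor_matrix(spec.predictors,
                                  [assigned[s] for s in mis_ids],
                                  mis_ids, subjects, n_visits)

        imputer = (PMMImputer if spec.method == "pmm" else NormBootImputer)()
        imputer.fit(X_obs, y_obs)
        draws = imputer.sample(X_mis, m=spec.m, rng=rng)
        to_impute[category] = {"ids": mis_ids, "assigned": assigned,
                               "draws": draws}

    completed = []
    for k in range(spec.m):
        base = visits.copy()
        base["imputed"] = False
        base["imputation"] = k + 1
        new_rows = []
        for category, blob in to_impute.items():
            for i, sid in enumerate(blob["ids"]):
                new_rows.append({
                    "visit_id": -1, "subject_id": sid,
                    "ga_weeks": blob["assigned"][sid],
                    "weight_kg": float(blob["draws"][k, i]),
                    "imputed": True, "imputation": k + 1})
        if new_rows:
            add = pd.DataFrame(new_rows)
            if "gwg_kg" in base.columns and "prepreg_weight_kg" in subjects.columns:
                prepreg = subjects.set_index("subject_id")["prepreg_weight_kg"]
                add["gwg_kg"] = add["weight_kg"].to_numpy() - \
                    prepreg.reindex(add["subject_id"]).to_numpy()
            for col in base.columns:
                if col not in add.columns:
                    add[col] = np.nan
            base = pd.concat([base, add[base.columns]], ignore_index=True)
        completed.append(base)

    diagnostics = pd.DataFrame(diag_rows)
    return completed, diagnostics
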
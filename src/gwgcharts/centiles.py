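"""Gestational-weight-gain centile curves via the BCCG (LMS) distribution.

The Box-Cox Cole-Green distribution underlies the LMS growth-chart method:
a response y > 0 at covariate t follows BCCG(mu(t), sigma(t), nu(t)) when

    z = ((y / mu)^nu - 1) / (nu sigma)        (nu != 0; log limit at nu = 0)

is standard normal, so mu is (approximately) the median, sigma the
coefficient of variation and nu the Box-Cox skewness power.  Density
f(y) = phi(z) y^(nu-1) / (mu^nu sigma); the truncation correction for y > 0
is ignored, as in standard growth-chart practice (its mass is negligible at
realistic sigma).

Parameter curves are linear in a basis of t (constant, linear, polynomial
or cubic B-spline), fitted by blockwise backfitting: the deviance
(-2 log-likelihood, optionally with a second-difference ridge penalty on
spline coefficients) is minimised over each curve's coefficients in turn
until the relative deviance change falls below tolerance.  Deviance is
non-increasing across cycles by construction.

Cumulative GWG can be negative early in pregnancy, while BCCG needs
positive support; fitting therefore applies a fixed documented shift
(default +10 kg) and removes it again when centiles are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline

__all__ = [
    "BCCGCentileModel",
    "QuantileDiagnostics",
    "bccg_logpdf",
    "bccg_cdf",
    "bccg_quantile",
    "fit_bccg",
    "evaluate_centiles",
    "quantile_diagnostics",
    "compare_models",
    "pool_centile_models",
]

_NU_EPS = 1e-4

#: default chart centiles
CENTILES_DEFAULT = (0.03, 0.10, 0.25, 0.50, 0.75, 0.90, 0.97)


# ---------------------------------------------------------------------------
# distribution primitives
# ---------------------------------------------------------------------------

def _bccg_z(y, mu, sigma, nu):
    y, mu, sigma, nu = np.broadcast_arrays(
        *[np.asarray(a, dtype=float) for a in (y, mu, sigma, nu)])
    ratio = y / mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            np.abs(nu) > _NU_EPS,
            (np.power(ratio, nu) - 1.0) / (np.where(np.abs(nu) > _NU_EPS, nu, 1.0) * sigma),
            np.log(ratio) / sigma,
        )
    return z


def bccg_logpdf(y, mu, sigma, nu):
    """Untruncated BCCG log-density at y > 0."""
    y = np.asarray(y, dtype=float)
    z = _bccg_z(y, mu, sigma, nu)
    return ((np.asarray(nu, float) - 1.0) * np.log(y)
            - np.asarray(nu, float) * np.log(mu)
            - np.log(sigma) - 0.5 * z ** 2 - 0.5 * np.log(2.0 * np.pi))


def bccg_cdf(y, mu, sigma, nu):
    """P(Y <= y) = Phi(z)."""
    return stats.norm.cdf(_bccg_z(y, mu, sigma, nu))


def bccg_quantile(p, mu, sigma, nu):
    """Centile p in (0,1): mu (1 + nu sigma z_p)^(1/nu), log limit at nu = 0.

    Returns NaN where the Box-Cox argument is non-positive (only reachable
    for extreme p at large sigma |nu|).
    """
    p, mu, sigma, nu = np.broadcast_arrays(
        *[np.asarray(a, dtype=float) for a in (p, mu, sigma, nu)])
    zp = stats.norm.ppf(p)
    safe_nu = np.where(np.abs(nu) > _NU_EPS, nu, 1.0)
    arg = 1.0 + nu * sigma * zp
    with np.errstate(invalid="ignore"):
        q = np.where(
            np.abs(nu) > _NU_EPS,
            mu * np.where(arg > 0, np.power(np.where(arg > 0, arg, 1.0),
                                            1.0 / safe_nu), np.nan),
            mu * np.exp(sigma * zp),
        )
    return q


def bccg_rvs(mu, sigma, nu, size, rng: np.random.Generator):
    """Random draws by quantile inversion (for simulation tests)."""
    u = rng.uniform(1e-12, 1 - 1e-12, size=size)
    return bccg_quantile(u, mu, sigma, nu)


# ---------------------------------------------------------------------------
# bases
# ---------------------------------------------------------------------------

def _make_basis(kind: str, df: int, t_min: float, t_max: float) -> dict:
    if kind == "constant" or df == 1:
        return {"kind": "constant", "df": 1, "t_min": t_min, "t_max": t_max}
    if kind == "linear" or (kind == "bspline" and df == 2):
        return {"kind": "linear", "df": 2, "t_min": t_min, "t_max": t_max}
    if kind == "poly" or (kind == "bspline" and df == 3):
        return {"kind": "poly", "df": df, "t_min": t_min, "t_max": t_max}
    if kind == "bspline":
        if df < 4:
            raise ValueError("bspline basis needs df >= 4")
        inner = np.linspace(0.0, 1.0, df - 2)[1:-1]
        knots = np.concatenate([[0.0] * 4, inner, [1.0] * 4])
        return {"kind": "bspline", "df": df, "t_min": t_min, "t_max": t_max,
                "knots": knots}
    raise ValueError(f"unknown basis kind {kind!r}")


def _design(t, basis: dict) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    span = basis["t_max"] - basis["t_min"]
    ts = np.clip((t - basis["t_min"]) / (span if span > 0 else 1.0), 0.0, 1.0)
    kind = basis["kind"]
    if kind == "constant":
        return np.ones((ts.size, 1))
    if kind == "linear":
        return np.column_stack([np.ones_like(ts), ts])
    if kind == "poly":
        return np.vander(ts, basis["df"], increasing=True)
    B = BSpline.design_matrix(ts, basis["knots"], 3)
    return np.asarray(B.todense())


def _difference_penalty(df: int) -> np.ndarray:
    if df < 3:
        return np.zeros((df, df))
    D = np.diff(np.eye(df), n=2, axis=0)
    return D.T @ D


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

@dataclass
class QuantileDiagnostics:
    """Adequacy diagnostics of a fitted centile model.

    ``residuals`` are normalized quantile residuals (exactly z under the
    fitted distribution, standard normal if the model is correct);
    ``coverage`` maps each requested centile to the fraction of
    observations lying below its fitted curve; normality is a Shapiro-Wilk
    statistic on the residuals and homoscedasticity the Pearson correlation
    of |residuals| with t (both with p-values).
    """

    residuals: np.ndarray
    coverage: dict[float, float]
    shapiro_stat: float
    shapiro_p: float
    homoscedasticity_corr: float
    homoscedasticity_p: float


class BCCGCentileModel:
    """BCCG/LMS centile estimator over gestational age (scikit-learn style).

    Parameters
    ----------
    mu_basis, sigma_basis, nu_basis :
        Basis kind per parameter curve: "constant", "linear", "poly" or
        "bspline" (cubic).
    mu_df, sigma_df, nu_df :
        Degrees of freedom (number of basis coefficients) per curve.
    shift :
        Fixed support shift in kg added to the response before fitting and
        removed from evaluated centiles; GWG may be negative, BCCG may not.
    penalty :
        Ridge weight on squared second differences of spline coefficients
        (0 = unpenalized maximum likelihood).
    tol, max_cycles :
        Backfitting stops when the relative deviance change is below
        ``tol`` or after ``max_cycles`` cycles (then ``converged_`` is
        False and the best iterate is kept).

    Fitted attributes (trailing underscore): ``mu_coef_``, ``sigma_coef_``,
    ``nu_coef_``, ``deviance_``, ``aic_``, ``edf_``, ``converged_``,
    ``n_cycles_``.
    """

    def __init__(self, mu_basis: str = "bspline", mu_df: int = 4,
                 sigma_basis: str = "linear", sigma_df: int = 2,
                 nu_basis: str = "constant", nu_df: int = 1,
                 shift: float = 10.0, penalty: float = 0.0,
                 fix_nu: float | None = None,
                 tol: float = 1e-6, max_cycles: int = 200):
        self.mu_basis = mu_basis
        self.mu_df = mu_df
        self.sigma_basis = sigma_basis
        self.sigma_df = sigma_df
        self.nu_basis = nu_basis
        self.nu_df = nu_df
        self.shift = shift
        self.penalty = penalty
        self.fix_nu = fix_nu
        self.tol = tol
        self.max_cycles = max_cycles

    # -- sklearn plumbing -----------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "mu_basis", "mu_df", "sigma_basis", "sigma_df", "nu_basis",
            "nu_df", "shift", "penalty", "fix_nu", "tol", "max_cycles")}

    def set_params(self, **params) -> "BCCGCentileModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals -------------------------------------------------------
    def _linpreds(self, Bm, Bs, Bn, a, b, c):
        mu = np.exp(np.clip(Bm @ a, -20.0, 20.0))
        sigma = np.exp(np.clip(Bs @ b, -12.0, 6.0))
        nu = np.clip(Bn @ c, -8.0, 8.0)
        return mu, sigma, nu

    def _deviance(self, y, Bm, Bs, Bn, a, b, c) -> float:
        mu, sigma, nu = self._linpreds(Bm, Bs, Bn, a, b, c)
        dev = -2.0 * float(np.sum(bccg_logpdf(y, mu, sigma, nu)))
        if self.penalty > 0:
            for coef, P in ((a, self._Pm), (b, self._Ps), (c, self._Pn)):
                dev += self.penalty * float(coef @ P @ coef)
        return dev

    @staticmethod
    def _running_stats(t, y, frac: float = 0.25):
        order = np.argsort(t, kind="stable")
        w = max(5, int(frac * t.size))
        means = np.empty(t.size)
        cvs = np.empty(t.size)
        ts, ys = t[order], y[order]
        for i in range(t.size):
            lo = max(0, i - w // 2)
            hi = min(t.size, lo + w)
            seg = ys[lo:hi]
            m = seg.mean()
            means[order[i]] = m
            cvs[order[i]] = max(seg.std(ddof=0) / max(m, 1e-6), 1e-3)
        return means, cvs

    def fit(self, t, y) -> "BCCGCentileModel":
        """Fit parameter curves to (gestational age, GWG) observations.

        ``y`` is the raw response (e.g. cumulative GWG in kg); the support
        shift is applied internally and every post-shift value must be
        positive.
        """
        t = np.asarray(t, dtype=float).ravel()
        y0 = np.asarray(y, dtype=float).ravel()
        if t.size != y0.size:
            raise ValueError("t and y lengths differ")
        if t.size < 50:
            raise ValueError("need at least 50 observations")
        ys = y0 + self.shift
        if np.any(ys <= 0):
            raise ValueError(
                "response not positive after support shift; increase `shift`")

        t_min, t_max = float(t.min()), float(t.max())
        self.basis_mu_ = _make_basis(self.mu_basis, self.mu_df, t_min, t_max)
        self.basis_sigma_ = _make_basis(self.sigma_basis, self.sigma_df,
                                        t_min, t_max)
        self.basis_nu_ = _make_basis(self.nu_basis, self.nu_df, t_min, t_max)
        Bm, Bs, Bn = (_design(t, b) for b in
                      (self.basis_mu_, self.basis_sigma_, self.basis_nu_))
        self._Pm = _difference_penalty(Bm.shape[1])
        self._Ps = _difference_penalty(Bs.shape[1])
        self._Pn = _difference_penalty(Bn.shape[1])

        # initialisation: nu = 1, mu = running mean, sigma = running CV
        run_mean, run_cv = self._running_stats(t, ys)
        a, *_ = np.linalg.lstsq(Bm, np.log(run_mean), rcond=None)
        b, *_ = np.linalg.lstsq(Bs, np.log(run_cv), rcond=None)
        target_nu = 1.0 if self.fix_nu is None else float(self.fix_nu)
        c, *_ = np.linalg.lstsq(Bn, np.full(t.size, target_nu), rcond=None)

        dev = self._deviance(ys, Bm, Bs, Bn, a, b, c)
        self.deviance_path_ = [dev]
        blocks = ["mu", "sigma"] + ([] if self.fix_nu is not None else ["nu"])
        converged = False
        cycle = 0
        for cycle in range(1, self.max_cycles + 1):
            for block in blocks:
                a, b, c, dev = self._update_block(block, ys, Bm, Bs, Bn,
                                                  a, b, c, dev)
            self.deviance_path_.append(dev)
            prev = self.deviance_path_[-2]
            rel = abs(prev - dev) / max(abs(prev), 1.0)
            if rel < self.tol:
                converged = True
                break

        self.mu_coef_, self.sigma_coef_, self.nu_coef_ = a, b, c
        self.deviance_ = dev
        self.converged_ = converged
        self.n_cycles_ = cycle
        self.edf_ = float(Bm.shape[1] + Bs.shape[1]
                          + (0 if self.fix_nu is not None else Bn.shape[1]))
        self.aic_ = self.deviance_ + 2.0 * self.edf_
        self.n_obs_ = int(t.size)
        self.train_checksum_ = float(np.sum(t) + np.sum(y0))
        self.t_range_ = (t_min, t_max)
        return self

    def _update_block(self, block, ys, Bm, Bs, Bn, a, b, c, dev):
        def obj(x):
            aa, bb, cc = a, b, c
            if block == "mu":
                aa = x
            elif block == "sigma":
                bb = x
            else:
                cc = x
            return self._deviance(ys, Bm, Bs, Bn, aa, bb, cc)

        x0 = {"mu": a, "sigma": b, "nu": c}[block]
        res = optimize.minimize(obj, x0, method="BFGS",
                                options={"maxiter": 50, "gtol": 1e-8})
        if np.isfinite(res.fun) and res.fun < dev:
            if block == "mu":
                a = res.x
            elif block == "sigma":
                b = res.x
            else:
                c = res.x
            dev = float(res.fun)
        return a, b, c, dev

    def _check_fitted(self) -> None:
        if not hasattr(self, "mu_coef_"):
            raise ValueError("model is not fitted")

    # -- prediction ------------------------------------------------------
    def parameters(self, t) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mu, sigma, nu) curves at ``t`` on the shifted response scale."""
        self._check_fitted()
        Bm = _design(t, self.basis_mu_)
        Bs = _design(t, self.basis_sigma_)
        Bn = _design(t, self.basis_nu_)
        return self._linpreds(Bm, Bs, Bn, self.mu_coef_, self.sigma_coef_,
                              self.nu_coef_)

    def predict(self, t) -> np.ndarray:
        """Median curve on the original response scale (= centile 0.5)."""
        mu, _, _ = self.parameters(t)
        return mu - self.shift

    def centile(self, t, p) -> np.ndarray:
        """Centile curve(s) p in (0,1) at ``t``, original response scale."""
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("centiles must lie strictly inside (0, 1)")
        mu, sigma, nu = self.parameters(t)
        return bccg_quantile(p, mu, sigma, nu) - self.shift

    def residual_z(self, t, y) -> np.ndarray:
        """Normalized quantile residuals of observations under the fit."""
        mu, sigma, nu = self.parameters(t)
        return _bccg_z(np.asarray(y, float) + self.shift, mu, sigma, nu)

    def gaic(self, k: float = 2.0) -> float:
        """Generalized Akaike criterion: deviance + k * edf (k=2 is AIC)."""
        self._check_fitted()
        return self.deviance_ + k * self.edf_


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_bccg(t, y, mu_df: int = 4, sigma_df: int = 2, nu_df: int = 1,
             shift: float = 10.0, select_df: bool = False,
             k: float = 3.0, **kwargs) -> BCCGCentileModel:
    """Fit a BCCG centile model; optionally select mu_df by GAIC(k).

    With ``select_df`` the model is refitted over a small mu_df grid
    (3, 4, 5, 6) and the GAIC(k)-best fit returned.
    """
    def _one(df):
        basis = "bspline" if df >= 4 else ("poly" if df == 3 else "linear")
        return BCCGCentileModel(mu_basis=basis, mu_df=df, sigma_df=sigma_df,
                                nu_df=nu_df, shift=shift, **kwargs).fit(t, y)

    if not select_df:
        return _one(mu_df)
    fits = [_one(df) for df in (3, 4, 5, 6)]
    fits.sort(key=lambda m: (m.gaic(k), m.edf_))
    return fits[0]


def evaluate_centiles(model: BCCGCentileModel, t_grid,
                      centiles=(0.03, 0.10, 0.25, 0.50, 0.75, 0.90, 0.97),
                      ) -> pd.DataFrame:
    """Centile-by-week table on the original response scale."""
    t_grid = np.asarray(t_grid, dtype=float)
    out = {"ga_weeks": t_grid}
    for p in centiles:
        out[f"P{100 * p:g}"] = model.centile(t_grid, p)
    return pd.DataFrame(out)


def quantile_diagnostics(model: BCCGCentileModel, t, y,
                         centiles=(0.03, 0.10, 0.50, 0.90, 0.97),
                         ) -> QuantileDiagnostics:
    """Coverage, normality and homoscedasticity checks on training data."""
    model._check_fitted()
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    r = model.residual_z(t, y)
    coverage = {}
    for p in centiles:
        yp = model.centile(t, p)
        coverage[float(p)] = float(np.mean(y < yp))
    sub = r if r.size <= 4999 else np.random.default_rng(0).choice(
        r, 4999, replace=False)
    sh_stat, sh_p = stats.shapiro(sub)
    hc, hp = stats.pearsonr(np.abs(r), t)
    return QuantileDiagnostics(residuals=r, coverage=coverage,
                               shapiro_stat=float(sh_stat),
                               shapiro_p=float(sh_p),
                               homoscedasticity_corr=float(hc),
                               homoscedasticity_p=float(hp))


def compare_models(models: list[BCCGCentileModel], k: float = 2.0,
                   ) -> pd.DataFrame:
    """Rank fitted models by GAIC(k); ties broken by fewer edf.

    All models must be fitted on identical data (checked via a stored
    training checksum).
    """
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    for m in models:
        m._check_fitted()
    sums = {(m.n_obs_, round(m.train_checksum_, 6)) for m in models}
    if len(sums) > 1:
        raise ValueError("models were fitted on different data")
    rows = [{"model": i, "deviance": m.deviance_, "edf": m.edf_,
             "aic": m.aic_, "gaic": m.gaic(k)}
            for i, m in enumerate(models)]
    df = pd.DataFrame(rows).sort_values(["gaic", "edf", "model"],
                                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def pool_centile_models(models: list[BCCGCentileModel], t_grid,
                        centiles=(0.03, 0.10, 0.25, 0.50, 0.75, 0.90, 0.97),
                        ) -> pd.DataFrame:
    """Rubin-style pooling of centile fits across m completed datasets.

    Parameter curves are averaged pointwise over the m fitted models and
    centiles evaluated from the averaged (mu, sigma, nu); the shared
    support shift is removed.
    """
    if not models:
        raise ValueError("no models to pool")
    shifts = {m.shift for m in models}
    if len(shifts) > 1:
        raise ValueError("models disagree on the support shift")
    t_grid = np.asarray(t_grid, dtype=float)
    params = np.array([m.parameters(t_grid) for m in models])  # (m, 3, nt)
    mu, sigma, nu = params.mean(axis=0)
    out = {"ga_weeks": t_grid}
    for p in centiles:
        out[f"P{100 * p:g}"] = bccg_quantile(p, mu, sigma, nu) - models[0].shift
    return pd.DataFrame(out)
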
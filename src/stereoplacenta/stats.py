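"""Study statistics: two-factor GLM, repeated measures, litter-nested LMM.

The study design is a 2x2 factorial (hypoxia x MitoQ) with dams as the
experimental unit for placenta-level outcomes and fetuses nested in dams
for fetus-level outcomes.  Three fitting routines cover it:

* :func:`glm_two_factor` — ordinary least squares on one row per dam (or
  per selected placenta), with Type-III F tests under sum-to-zero coding.
* :func:`glm_repeated` — gestational time courses: group x day fixed
  effects with a dam random intercept (equivalent to repeated-measures
  ANOVA under compound symmetry), with per-day group contrasts.
* :func:`lmm_litter` — fetus-level outcomes: hypoxia x MitoQ fixed effects
  with a dam-level random intercept, REML variance components by a 1-D
  profile over the variance ratio, and Satterthwaite denominator degrees
  of freedom.

The REML engine is written here in full (profile likelihood, Woodbury
block inverses, finite-difference Satterthwaite) so it can be validated
against an independent reference implementation rather than being one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar

__all__ = ["EffectTest", "ModelFit", "glm_two_factor", "glm_repeated",
           "lmm_litter", "ALPHA"]

#: Significance threshold for all comparisons.
ALPHA: float = 0.05


@dataclass
class EffectTest:
    name: str
    estimate: float
    se: float
    F: float
    df_num: int
    df_den: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass
class ModelFit:
    """Fixed effects, tests and variance components of one model fit."""

    method: str
    outcome: str
    coefficients: dict[str, float]
    se: dict[str, float]
    effects: dict[str, EffectTest]
    sigma2_resid: float
    sigma2_group: float | None
    df_resid: float
    n_obs: int
    converged: bool = True
    boundary: bool = False
    extra: dict = field(default_factory=dict)

    def significant(self, effect: str) -> bool:
        return self.effects[effect].significant

    def summary(self) -> pd.DataFrame:
        rows = [{"effect": e.name, "estimate": e.estimate, "se": e.se,
                 "F": e.F, "df_num": e.df_num, "df_den": e.df_den,
                 "p": e.p, "significant": e.significant}
                for e in self.effects.values()]
        return pd.DataFrame(rows)


def _two_factor_design(df: pd.DataFrame) -> tuple[np.ndarray, list[str],
                                                  dict[str, list[int]]]:
    """Sum-to-zero design for outcome ~ hypoxia * mitoq.

    Factors are coded -1/+1 so the drop-one-term F tests are Type III.
    Returns (X, column names, effect -> column indices).
    """
    hyp = 2.0 * df["hypoxia"].to_numpy(dtype=float) - 1.0
    mq = 2.0 * df["mitoq"].to_numpy(dtype=float) - 1.0
    X = np.column_stack([np.ones(len(df)), hyp, mq, hyp * mq])
    names = ["intercept", "hypoxia", "mitoq", "hypoxia:mitoq"]
    effects = {"hypoxia": [1], "mitoq": [2], "hypoxia:mitoq": [3]}
    cells = df.groupby(["hypoxia", "mitoq"]).size()
    if len(cells) < 4:
        warnings.warn("empty cell in the 2x2 design: interaction dropped",
                      stacklevel=3)
        X = X[:, :3]
        names = names[:3]
        effects = {"hypoxia": [1], "mitoq": [2]}
    return X, names, effects


def _check_groups(df: pd.DataFrame) -> None:
    if "group" in df.columns and df["group"].nunique() < 2:
        raise ValueError("need at least 2 groups to compare")
    for col in ("hypoxia", "mitoq"):
        if col not in df.columns:
            raise ValueError(f"table lacks required factor column {col!r}")


def glm_two_factor(table: pd.DataFrame, outcome: str) -> ModelFit:
    """Two-factor general linear model for dam/placenta-level outcomes.

    Ordinary least squares of ``outcome ~ hypoxia + mitoq +
    hypoxia:mitoq`` with Type-III F tests (sum-to-zero contrasts, each
    term tested by removal given all others).
    """
    _check_groups(table)
    df = table.dropna(subset=[outcome])
    y = df[outcome].to_numpy(dtype=float)
    X, names, effect_cols = _two_factor_design(df)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"too few observations ({n}) for {p} parameters")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = n - rank
    mse = rss / df_resid
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * mse, 0.0, None))

    effects: dict[str, EffectTest] = {}
    for name, cols in effect_cols.items():
        keep = [j for j in range(p) if j not in cols]
        b_r, _, _, _ = np.linalg.lstsq(X[:, keep], y, rcond=None)
        rss_r = float(np.sum((y - X[:, keep] @ b_r) ** 2))
        q = len(cols)
        F = max(0.0, (rss_r - rss) / q) / mse if mse > 0 else np.inf
        pval = float(sps.f.sf(F, q, df_resid)) if np.isfinite(F) else 0.0
        j = cols[0]
        effects[name] = EffectTest(name=name, estimate=float(beta[j]),
                                   se=float(se[j]), F=float(F), df_num=q,
                                   df_den=float(df_resid), p=pval)

    fitted_means = {g: float((X @ beta)[df["group"].to_numpy() == g].mean())
                    for g in df["group"].unique()} if "group" in df else {}
    return ModelFit(method="glm_two_factor", outcome=outcome,
                    coefficients=dict(zip(names, beta.tolist())),
                    se=dict(zip(names, se.tolist())), effects=effects,
                    sigma2_resid=mse, sigma2_group=None,
                    df_resid=float(df_resid), n_obs=n,
                    extra={"fitted_group_means": fitted_means})


# ---------------------------------------------------------------------------
# random-intercept REML engine

class _RandomInterceptREML:
    """REML for y = X b + Z u + e with one random intercept per group.

    V = s2_resid * (I + lambda * Z Z'), lambda = s2_group / s2_resid.  The
    group-block structure makes V0^{-1} = I - lambda/(1 + lambda m) J per
    block, so everything reduces to per-group sums; the REML criterion is
    profiled down to the scalar lambda.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        codes, self.m = np.unique(groups, return_counts=True)
        idx = {c: i for i, c in enumerate(codes)}
        gi = np.array([idx[g] for g in groups])
        G = len(codes)
        self.sx = np.zeros((G, self.p))
        np.add.at(self.sx, gi, X)
        self.sy = np.zeros(G)
        np.add.at(self.sy, gi, y)
        self.xtx = X.T @ X
        self.xty = X.T @ y
        self.yty = float(y @ y)

    def _parts(self, lam: float):
        w = lam / (1.0 + lam * self.m)
        xtvx = self.xtx - (self.sx * w[:, None]).T @ self.sx
        xtvy = self.xty - self.sx.T @ (w * self.sy)
        ytvy = self.yty - float(w @ self.sy ** 2)
        beta = np.linalg.solve(xtvx, xtvy)
        rss = max(ytvy - float(beta @ xtvy), 1e-300)
        return xtvx, beta, rss

    def _criterion(self, lam: float) -> float:
        """-2 * profiled REML log-likelihood, up to an additive constant."""
        xtvx, _, rss = self._parts(lam)
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return np.inf
        logdet_v = float(np.sum(np.log1p(lam * self.m)))
        return (self.n - self.p) * np.log(rss) + logdet_v + logdet_x

    def loglik(self, s2r: float, s2g: float) -> float:
        """Full REML log-likelihood at variance components (s2r, s2g)."""
        lam = s2g / s2r
        xtvx, _, rss = self._parts(lam)
        _, logdet_x = np.linalg.slogdet(xtvx)
        logdet_v = self.n * np.log(s2r) + float(np.sum(np.log1p(lam * self.m)))
        return -0.5 * (logdet_v + (logdet_x - self.p * np.log(s2r))
                       + rss / s2r + (self.n - self.p) * np.log(2 * np.pi))

    def fit(self, lam_max: float = 1e4):
        res = minimize_scalar(self._criterion, bounds=(0.0, lam_max),
                              method="bounded",
                              options={"xatol": 1e-10, "maxiter": 500})
        lam = float(res.x)
        if self._criterion(0.0) <= res.fun:
            lam = 0.0
        xtvx, beta, rss = self._parts(lam)
        s2r = rss / (self.n - self.p)
        s2g = lam * s2r
        cov_beta = s2r * np.linalg.inv(xtvx)
        return {"lam": lam, "beta": beta, "cov_beta": cov_beta,
                "sigma2_resid": s2r, "sigma2_group": s2g,
                "converged": bool(res.success),
                "boundary": lam < 1e-7}

    # Satterthwaite machinery -------------------------------------------------

    def _var_of_contrast(self, c: np.ndarray, s2r: float, s2g: float) -> float:
        lam = max(s2g, 0.0) / s2r
        xtvx, _, _ = self._parts(lam)
        return float(s2r * c @ np.linalg.solve(xtvx, c))

    def satterthwaite_df(self, c: np.ndarray, s2r: float, s2g: float) -> float:
        """Approximate denominator df for the contrast c'beta.

        df = 2 f^2 / (g' A g) with f the contrast variance, g its gradient
        in (s2r, s2g) and A the inverse observed REML information, all by
        central finite differences.  At the lambda = 0 boundary the model
        is ordinary least squares and df = n - p.
        """
        if s2g < 1e-7 * s2r:
            return float(self.n - self.p)
        theta = np.array([s2r, s2g])
        h = 1e-5 * theta

        def f(t):
            return self._var_of_contrast(c, t[0], t[1])

        grad = np.zeros(2)
        for j in range(2):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h[j]
            tm[j] -= h[j]
            grad[j] = (f(tp) - f(tm)) / (2 * h[j])

        hh = 1e-4 * theta
        H = np.zeros((2, 2))
        ll = self.loglik
        for j in range(2):
            for k in range(j, 2):
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[j] += hh[j]; tpp[k] += hh[k]
                tpm[j] += hh[j]; tpm[k] -= hh[k]
                tmp[j] -= hh[j]; tmp[k] += hh[k]
                tmm[j] -= hh[j]; tmm[k] -= hh[k]
                H[j, k] = H[k, j] = -(ll(*tpp) - ll(*tpm) - ll(*tmp)
                                      + ll(*tmm)) / (4 * hh[j] * hh[k])
        try:
            A = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return float(self.n - self.p)
        denom = float(grad @ A @ grad)
        if denom <= 0:
            return float(self.n - self.p)
        df = 2.0 * f(theta) ** 2 / denom
        return float(np.clip(df, 1.0, self.n - self.p))


def _fit_random_intercept(df: pd.DataFrame, outcome: str, X: np.ndarray,
                          names: list[str],
                          effect_cols: dict[str, list[int]],
                          group_col: str, method: str) -> ModelFit:
    y = df[outcome].to_numpy(dtype=float)
    eng = _RandomInterceptREML(y, X, df[group_col].to_numpy())
    res = eng.fit()
    beta, cov = res["beta"], res["cov_beta"]
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    s2r, s2g = res["sigma2_resid"], res["sigma2_group"]

    effects: dict[str, EffectTest] = {}
    for name, cols in effect_cols.items():
        q = len(cols)
        dfs = []
        for j in cols:
            c = np.zeros(eng.p)
            c[j] = 1.0
            dfs.append(eng.satterthwaite_df(c, s2r, s2g))
        df_den = float(np.mean(dfs))
        sub_cov = cov[np.ix_(cols, cols)]
        b = beta[cols]
        F = float(b @ np.linalg.solve(sub_cov, b) / q)
        pval = float(sps.f.sf(F, q, df_den))
        j = cols[0]
        effects[name] = EffectTest(name=name, estimate=float(beta[j]),
                                   se=float(se[j]), F=F, df_num=q,
                                   df_den=df_den, p=pval)
    return ModelFit(method=method, outcome=outcome,
                    coefficients=dict(zip(names, beta.tolist())),
                    se=dict(zip(names, se.tolist())), effects=effects,
                    sigma2_resid=s2r, sigma2_group=s2g,
                    df_resid=float(eng.n - eng.p), n_obs=eng.n,
                    converged=res["converged"], boundary=res["boundary"],
                    extra={"lambda": res["lam"], "engine": eng,
                           "cov_beta": cov})


def lmm_litter(table: pd.DataFrame, outcome: str) -> ModelFit:
    """Litter-nested linear mixed model for fetus-level outcomes.

    outcome ~ hypoxia * mitoq with a dam-level random intercept, nesting
    offspring within a maternal identifier to account for the shared
    maternal environment.  Variance components are REML via a 1-D profile
    over the between/within variance ratio; fixed-effect tests use
    Satterthwaite denominator df.  A litter variance estimated at the
    boundary (0) is reported via ``boundary=True`` and the fit then
    coincides with ordinary least squares.
    """
    _check_groups(table)
    if "dam_id" not in table.columns:
        raise ValueError("fetus-level table needs a dam_id column")
    df = table.dropna(subset=[outcome])
    per_group = df.groupby("group")["dam_id"].nunique()
    if (per_group < 2).any():
        raise ValueError(
            f"need >= 2 litters per group, got {per_group.to_dict()}")
    X, names, effect_cols = _two_factor_design(df)
    return _fit_random_intercept(df, outcome, X, names, effect_cols,
                                 "dam_id", "lmm_litter")


def _effect_code(values: np.ndarray, levels: list) -> np.ndarray:
    """Sum-to-zero (deviation) coding: one column per non-reference level."""
    cols = []
    ref = levels[0]
    for lev in levels[1:]:
        col = np.where(values == lev, 1.0, np.where(values == ref, -1.0, 0.0))
        cols.append(col)
    return np.column_stack(cols) if cols else np.empty((len(values), 0))


def glm_repeated(table: pd.DataFrame, outcome: str) -> ModelFit:
    """Group x day model for gestational time courses.

    The dam is the repeated-measures blocking unit, fitted as a random
    intercept (equivalent to the classical repeated-measures analysis under
    compound symmetry).  Dams observed on a single day are retained with a
    note; they inform fixed effects only.  Per-day group contrasts (joint
    test of group-mean equality on each day) are reported in
    ``extra["per_day"]``.
    """
    for col in ("day", "dam_id"):
        if col not in table.columns:
            raise ValueError(f"repeated-measures table needs a {col!r} column")
    df = table.dropna(subset=[outcome])
    days_per_dam = df.groupby("dam_id")["day"].nunique()
    single = days_per_dam[days_per_dam < 2].index.tolist()
    if single:
        warnings.warn(f"{len(single)} dam(s) observed on a single day; they "
                      "contribute to fixed effects only", stacklevel=2)
    groups = sorted(df["group"].unique())
    days = sorted(df["day"].unique())
    if len(days) < 2:
        raise ValueError("need observations on >= 2 days")
    g_cols = _effect_code(df["group"].to_numpy(), groups)
    d_cols = _effect_code(df["day"].to_numpy(), days)
    inter = np.column_stack([g_cols[:, i] * d_cols[:, j]
                             for i in range(g_cols.shape[1])
                             for j in range(d_cols.shape[1])]) \
        if g_cols.size and d_cols.size else np.empty((len(df), 0))
    X = np.column_stack([np.ones(len(df)), g_cols, d_cols, inter])
    names = (["intercept"]
             + [f"group[{g}]" for g in groups[1:]]
             + [f"day[{d}]" for d in days[1:]]
             + [f"group[{g}]:day[{d}]" for g in groups[1:] for d in days[1:]])
    ng, nd = g_cols.shape[1], d_cols.shape[1]
    effect_cols = {
        "group": list(range(1, 1 + ng)),
        "day": list(range(1 + ng, 1 + ng + nd)),
        "group:day": list(range(1 + ng + nd, 1 + ng + nd + ng * nd)),
    }
    fit = _fit_random_intercept(df, outcome, X, names, effect_cols,
                                "dam_id", "glm_repeated")

    # per-day group contrasts: joint equality of the group cell means
    eng = fit.extra["engine"]
    beta = np.array(list(fit.coefficients.values()))
    cov = fit.extra["cov_beta"]
    s2r, s2g = fit.sigma2_resid, fit.sigma2_group or 0.0
    per_day = {}
    for d in days:
        rows = []
        for g in groups[1:]:
            c = np.zeros(len(beta))

            def cell(gr, dy, vec):
                gv = _effect_code(np.array([gr]), groups)[0]
                dv = _effect_code(np.array([dy]), days)[0]
                vec[0] += 1.0
                vec[1:1 + ng] += gv
                vec[1 + ng:1 + ng + nd] += dv
                iv = np.array([gv[i] * dv[j] for i in range(ng)
                               for j in range(nd)])
                vec[1 + ng + nd:] += iv

            cell(g, d, c)
            c2 = np.zeros(len(beta))
            cell(groups[0], d, c2)
            rows.append(c - c2)
        C = np.array(rows)
        delta = C @ beta
        vc = C @ cov @ C.T
        F = float(delta @ np.linalg.solve(vc, delta) / len(rows))
        dfs = [eng.satterthwaite_df(r, s2r, max(s2g, 0.0)) for r in C]
        df_den = float(np.mean(dfs))
        per_day[d] = {"F": F, "df_num": len(rows), "df_den": df_den,
                      "p": float(sps.f.sf(F, len(rows), df_den))}
    fit.extra["per_day"] = per_day
    fit.extra["single_day_dams"] = single
    del fit.extra["engine"]
    return fit
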
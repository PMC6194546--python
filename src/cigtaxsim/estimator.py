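"""Fixed-effects panel estimation of the cigarette demand equation.

The demand model is

    ln C_it = b1_i + b2 ln P_it + b3 ln GNI_it + b4 FCTC_it + e_it

with country fixed effects b1_i.  Real price is treated as endogenous and
instrumented by its own lag and the lagged consumer price index, giving a
within (fixed-effects) two-stage least-squares estimator; inference is
cluster-robust by country with a CR1 small-sample factor.  A Swamy-Arora
random-effects GLS estimator and the classical Hausman test decide between
fixed and random effects, and a cluster-robust first-stage Wald F (the
Kleibergen-Paap rk Wald F when there is a single endogenous regressor)
gauges instrument relevance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: GNI-per-capita thresholds (US$, 2015 Atlas method) separating the six
#: income groups; a country at exactly a threshold goes to the higher group.
INCOME_THRESHOLDS = (1000.0, 2000.0, 3000.0, 4000.0, 6000.0)

SLOPE_NAMES = ("ln_price", "ln_gni", "fctc")


class RankError(np.linalg.LinAlgError):
    """Raised when a design or instrument matrix is rank deficient."""


@dataclass(frozen=True)
class IncomeCluster:
    group_id: int
    gni_lower: float
    gni_upper: float  # inf for the top group
    members: tuple[str, ...]


@dataclass
class HausmanResult:
    statistic: float
    df: int
    p_value: float
    indefinite: bool = False  # V_FE - V_RE was not positive definite


@dataclass
class ElasticityFit:
    """One income group's demand-equation fit and diagnostics."""

    group_id: int
    beta_price: float
    beta_gni: float
    beta_fctc: float
    intercepts: dict[str, float]
    vcov: np.ndarray
    se: np.ndarray
    r_squared: float
    hausman_stat: float
    hausman_df: int
    hausman_p: float
    hausman_indefinite: bool
    weak_id_F: float
    n_obs: int
    n_countries: int
    iv: bool = True
    countries: tuple[str, ...] = field(default_factory=tuple)

    @property
    def slopes(self) -> np.ndarray:
        return np.array([self.beta_price, self.beta_gni, self.beta_fctc])

    def to_dict(self) -> dict:
        return {
            "group_id": self.group_id,
            "beta_price": self.beta_price,
            "beta_gni": self.beta_gni,
            "beta_fctc": self.beta_fctc,
            "se": list(map(float, self.se)),
            "vcov": self.vcov.tolist(),
            "intercepts": self.intercepts,
            "r_squared": self.r_squared,
            "hausman_stat": self.hausman_stat,
            "hausman_df": self.hausman_df,
            "hausman_p": self.hausman_p,
            "hausman_indefinite": self.hausman_indefinite,
            "weak_id_F": self.weak_id_F,
            "n_obs": self.n_obs,
            "n_countries": self.n_countries,
            "iv": self.iv,
            "countries": list(self.countries),
        }


# ---------------------------------------------------------------------------
# income clustering


def assign_income_clusters(gni_2015_by_country: dict[str, float]) -> list[IncomeCluster]:
    """Partition countries into the six fixed GNI-per-capita groups.

    Bounds: group 1 below US$1000, then US$1000/2000/3000/4000 bands, group 6
    at or above US$6000.  Every country must have a GNI value.
    """
    for country, gni in gni_2015_by_country.items():
        if gni is None or not np.isfinite(gni):
            raise ValueError(f"missing 2015 GNI for country {country!r}")
    edges = (0.0, *INCOME_THRESHOLDS, np.inf)
    clusters = []
    for gid in range(1, 7):
        lo, hi = edges[gid - 1], edges[gid]
        members = tuple(sorted(c for c, g in gni_2015_by_country.items() if lo <= g < hi))
        clusters.append(IncomeCluster(gid, lo, hi, members))
    return clusters


# ---------------------------------------------------------------------------
# within transform


def within_transform(df: pd.DataFrame, variables: list[str],
                     group: str = "country") -> pd.DataFrame:
    """Subtract country means from each variable (the within transform).

    Countries contributing a single observation carry no within information
    and are dropped with a warning.
    """
    counts = df.groupby(group)[group].transform("size")
    if (counts < 2).any():
        dropped = sorted(df.loc[counts < 2, group].unique())
        logger.warning("within_transform: dropping single-observation countries %s", dropped)
        df = df[counts >= 2]
    out = df.copy()
    out[variables] = df[variables] - df.groupby(group)[variables].transform("mean")
    return out


# ---------------------------------------------------------------------------
# internal linear-algebra helpers


def _check_rank(M: np.ndarray, names: list[str], what: str) -> None:
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise RankError(f"{what} is rank deficient; columns: {names}")


def _cluster_meat(X: np.ndarray, resid: np.ndarray, groups: np.ndarray) -> np.ndarray:
    k = X.shape[1]
    meat = np.zeros((k, k))
    Xe = X * resid[:, None]
    for g in np.unique(groups):
        s = Xe[groups == g].sum(axis=0)
        meat += np.outer(s, s)
    return meat


def _cr1_factor(G: int, N: int, k: int) -> float:
    return (G / (G - 1)) * ((N - 1) / (N - k))


def _prepare(panel: pd.DataFrame, require_lags: bool) -> pd.DataFrame:
    """Log-transform, build lagged instruments, trim rows without a valid lag."""
    df = panel.sort_values(["country", "year"]).reset_index(drop=True).copy()
    for col in ("consumption", "price", "gni", "cpi"):
        if (df[col] <= 0).any():
            bad = df.loc[df[col] <= 0, "country"].iloc[0]
            raise ValueError(f"non-positive {col} (country {bad!r}) is not log-transformable")
    df["ln_c"] = np.log(df["consumption"])
    df["ln_price"] = np.log(df["price"])
    df["ln_gni"] = np.log(df["gni"])
    df["ln_cpi"] = np.log(df["cpi"])
    df["fctc"] = df["fctc"].astype(float)
    if require_lags:
        g = df.groupby("country")
        consecutive = g["year"].diff() == 1
        df["ln_price_lag"] = g["ln_price"].shift(1).where(consecutive)
        df["ln_cpi_lag"] = g["ln_cpi"].shift(1).where(consecutive)
        before = df["country"].nunique()
        df = df.dropna(subset=["ln_price_lag", "ln_cpi_lag"])
        counts = df.groupby("country")["year"].transform("size")
        df = df[counts >= 2]
        lost = before - df["country"].nunique()
        if lost:
            logger.warning("lag construction dropped %d country(ies) with too few observations", lost)
    return df


def _within(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    return (df[cols] - df.groupby("country")[cols].transform("mean")).to_numpy()


# ---------------------------------------------------------------------------
# fixed-effects estimators


DEFAULT_INSTRUMENTS = ("ln_price_lag", "ln_cpi_lag")


def fit_fe_2sls(panel: pd.DataFrame, iv: bool = True,
                instruments: tuple[str, ...] = DEFAULT_INSTRUMENTS,
                compute_diagnostics: bool = True) -> ElasticityFit:
    """Estimate the demand equation by within 2SLS (or within OLS).

    ln C is regressed on ln P, ln GNI and FCTC after demeaning by country;
    when ``iv`` is true, ln P is instrumented by the one-year lags of ln P
    and ln CPI, and the first observation of every country is dropped.  The
    covariance of the slopes is cluster-robust by country with the CR1
    factor G/(G-1) x (N-1)/(N-k), where k counts the slope parameters only
    (absorbed intercepts excluded, so with every observation its own cluster
    the estimator reduces to the HC1 sandwich).

    When ``compute_diagnostics`` is true the fit also carries the classical
    Hausman FE-vs-RE test (on the non-IV estimators, same sample) and the
    cluster-robust first-stage Wald F of the excluded instruments.
    """
    need_lags = iv and any(name.endswith("_lag") for name in instruments)
    df = _prepare(panel, require_lags=need_lags)
    groups_lab = df["country"].to_numpy()
    G = df["country"].nunique()
    if G < 2:
        raise ValueError("cluster-robust estimation requires at least 2 countries")
    N = len(df)

    y = _within(df, ["ln_c"]).ravel()
    X = _within(df, list(SLOPE_NAMES))
    _check_rank(X, list(SLOPE_NAMES), "within design matrix")

    if iv:
        z_names = [*instruments, "ln_gni", "fctc"]
        Z = _within(df, z_names)
        _check_rank(Z, z_names, "instrument matrix")
        # projection of X on Z
        Xhat = Z @ np.linalg.lstsq(Z, X, rcond=None)[0]
    else:
        Xhat = X

    XtX = Xhat.T @ Xhat
    beta = np.linalg.solve(XtX, Xhat.T @ y)
    resid = y - X @ beta

    k = len(SLOPE_NAMES)  # slopes only; absorbed intercepts not counted
    bread = np.linalg.inv(XtX)
    meat = _cluster_meat(Xhat, resid, groups_lab)
    vcov = _cr1_factor(G, N, k) * bread @ meat @ bread
    se = np.sqrt(np.diag(vcov))

    sst = float(y @ y)
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0

    means = df.groupby("country")[["ln_c", *SLOPE_NAMES]].mean()
    intercepts = {c: float(row["ln_c"] - row[list(SLOPE_NAMES)].to_numpy() @ beta)
                  for c, row in means.iterrows()}

    hm = HausmanResult(np.nan, len(SLOPE_NAMES), np.nan)
    wf = np.nan
    if compute_diagnostics:
        fe = _fe_ols_conventional(df)
        re = fit_re_gls_frame(df)
        hm = hausman_test(fe["beta"], fe["vcov"], re["beta"][:3], re["vcov"][:3, :3])
        if iv:
            wf = _first_stage_F(df, instruments)

    return ElasticityFit(
        group_id=0,
        beta_price=float(beta[0]), beta_gni=float(beta[1]), beta_fctc=float(beta[2]),
        intercepts=intercepts, vcov=vcov, se=se, r_squared=r2,
        hausman_stat=hm.statistic, hausman_df=hm.df, hausman_p=hm.p_value,
        hausman_indefinite=hm.indefinite, weak_id_F=wf,
        n_obs=N, n_countries=G, iv=iv,
        countries=tuple(sorted(df["country"].unique())),
    )


def _fe_ols_conventional(df: pd.DataFrame) -> dict:
    """Within OLS with the conventional (iid) covariance, for the Hausman test."""
    y = _within(df, ["ln_c"]).ravel()
    X = _within(df, list(SLOPE_NAMES))
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    N, G = len(df), df["country"].nunique()
    dof = N - G - X.shape[1]
    s2 = float(resid @ resid) / dof
    return {"beta": beta, "vcov": s2 * np.linalg.inv(XtX), "s2_e": s2}


# ---------------------------------------------------------------------------
# random effects (Swamy-Arora)


def fit_re_gls(panel: pd.DataFrame) -> dict:
    """Random-effects GLS of the demand equation (Swamy-Arora components).

    Returns ``{"beta": (b2, b3, b4, intercept), "vcov": 4x4, "theta": ...}``.
    The quasi-demeaning weight theta_i = 1 - sqrt(s2_e / (T_i s2_u + s2_e))
    shrinks to 0 when the between variance vanishes (pooled OLS) and to 1 when
    it dominates (the within estimator).
    """
    df = _prepare(panel, require_lags=False)
    return fit_re_gls_frame(df)


def fit_re_gls_frame(df: pd.DataFrame) -> dict:
    cols = list(SLOPE_NAMES)
    y = df["ln_c"].to_numpy()
    X = df[cols].to_numpy()
    N = len(df)
    G = df["country"].nunique()
    k = X.shape[1]

    fe = _fe_ols_conventional(df)
    s2_e = fe["s2_e"]

    # between regression on country means (with intercept)
    gm = df.groupby("country")[["ln_c", *cols]].mean()
    Xb = np.column_stack([np.ones(G), gm[cols].to_numpy()])
    yb = gm["ln_c"].to_numpy()
    bb, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
    rb = yb - Xb @ bb
    dof_b = G - (k + 1)
    T_bar = N / G
    s2_b = float(rb @ rb) / dof_b if dof_b > 0 else 0.0
    s2_u = s2_b - s2_e / T_bar
    if s2_u < 0:
        logger.warning("Swamy-Arora between variance negative (%.3g); truncating at 0", s2_u)
        s2_u = 0.0

    T_i = df.groupby("country")["country"].transform("size").to_numpy()
    theta = 1.0 - np.sqrt(s2_e / (T_i * s2_u + s2_e))

    Xf = np.column_stack([X, np.ones(N)])
    mean_map = df.groupby("country")[["ln_c", *cols]].transform("mean")
    Xm = np.column_stack([mean_map[cols].to_numpy(), np.ones(N)])
    ym = mean_map["ln_c"].to_numpy()
    Xs = Xf - theta[:, None] * Xm
    ys = y - theta * ym

    XtX = Xs.T @ Xs
    beta = np.linalg.solve(XtX, Xs.T @ ys)
    resid = ys - Xs @ beta
    s2 = float(resid @ resid) / (N - (k + 1))
    vcov = s2 * np.linalg.inv(XtX)
    return {"beta": beta, "vcov": vcov, "theta": theta,
            "s2_e": s2_e, "s2_u": s2_u}


# ---------------------------------------------------------------------------
# Hausman test


def hausman_test(b_fe: np.ndarray, v_fe: np.ndarray,
                 b_re: np.ndarray, v_re: np.ndarray) -> HausmanResult:
    """Classical Hausman specification test of FE vs RE.

    H = (b_FE - b_RE)' (V_FE - V_RE)^{-1} (b_FE - b_RE), chi-square with one
    degree of freedom per compared slope.  A non-positive-definite covariance
    difference (common in finite samples) falls back to the Moore-Penrose
    pseudo-inverse and is flagged, never hidden.
    """
    d = np.asarray(b_fe) - np.asarray(b_re)
    V = np.asarray(v_fe) - np.asarray(v_re)
    df = d.size
    indefinite = False
    try:
        np.linalg.cholesky(V)
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        indefinite = True
        Vinv = np.linalg.pinv(V)
    stat = float(d @ Vinv @ d)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    return HausmanResult(stat, df, p, indefinite)


# ---------------------------------------------------------------------------
# weak identification


def weak_id_F(panel: pd.DataFrame,
              instruments: tuple[str, ...] = DEFAULT_INSTRUMENTS) -> float:
    """Cluster-robust first-stage Wald F of the excluded instruments.

    The first stage regresses within-transformed ln P on the within-transformed
    excluded instruments (lagged ln P and lagged ln CPI by default) and the
    exogenous regressors; the statistic is the cluster-robust Wald test of the
    excluded instruments divided by their number.  With one endogenous
    regressor this equals the Kleibergen-Paap rk Wald F.  Perfect relevance
    (zero first-stage residuals) is reported capped at 1e6.
    """
    need_lags = any(name.endswith("_lag") for name in instruments)
    df = _prepare(panel, require_lags=need_lags)
    return _first_stage_F(df, instruments)


F_CAP = 1e6


def _first_stage_F(df: pd.DataFrame,
                   instruments: tuple[str, ...] = DEFAULT_INSTRUMENTS) -> float:
    names = [*instruments, "ln_gni", "fctc"]
    Z = _within(df, names)
    _check_rank(Z, names, "first-stage design")
    y = _within(df, ["ln_price"]).ravel()
    ZtZ = Z.T @ Z
    b = np.linalg.solve(ZtZ, Z.T @ y)
    resid = y - Z @ b
    G = df["country"].nunique()
    N = len(df)
    k = Z.shape[1]
    bread = np.linalg.inv(ZtZ)
    meat = _cluster_meat(Z, resid, df["country"].to_numpy())
    V = _cr1_factor(G, N, k) * bread @ meat @ bread
    q = len(instruments)  # excluded instruments
    Vq = V[:q, :q]
    bq = b[:q]
    try:
        W = float(bq @ np.linalg.solve(Vq, bq))
    except np.linalg.LinAlgError:
        return F_CAP
    if not np.isfinite(W) or W / q > F_CAP:
        return F_CAP
    return W / q


# ---------------------------------------------------------------------------
# per-income-group driver


def estimate_by_group(panel: pd.DataFrame, clusters: list[IncomeCluster] | None = None,
                      iv: bool = True) -> list[ElasticityFit]:
    """Fit the demand equation separately in each income group.

    When ``clusters`` is omitted, countries are grouped by their final-year
    GNI per capita using the fixed thresholds.  Groups with fewer than two
    countries cannot support clustered inference and are skipped with a
    warning.
    """
    if clusters is None:
        last = panel.sort_values("year").groupby("country").tail(1)
        clusters = assign_income_clusters(dict(zip(last["country"], last["gni"])))
    fits = []
    for cl in clusters:
        sub = panel[panel["country"].isin(cl.members)]
        if sub["country"].nunique() < 2:
            logger.warning("income group %d has <2 countries; skipped", cl.group_id)
            continue
        fit = fit_fe_2sls(sub, iv=iv)
        fit.group_id = cl.group_id
        fits.append(fit)
    return fits
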
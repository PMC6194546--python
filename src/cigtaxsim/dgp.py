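"""Synthetic country-year panel generator for the log-log cigarette demand model.

The generator realizes

    ln C_it = b1_i + b2 ln P_it + b3 ln GNI_it + b4 FCTC_it + e_it

exactly, with known ground-truth coefficients, so that estimator code can be
validated by parameter recovery.  Structure of the covariates:

* log real price is a country-level base plus a stationary AR(1) deviation,
* GNI per capita grows geometrically with a country-specific drift,
* CPI follows a smooth country-specific inflation path (base year = 100); it
  enters the demand equation nowhere and exists only to serve as the lagged
  instrument,
* FCTC ratification is staggered: one adoption year per country, absorbing
  from then on,
* the error is an equicorrelated country component plus idiosyncratic noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

PANEL_COLUMNS = ["country", "year", "consumption", "price", "gni", "fctc", "cpi"]
POLICY_COLUMNS = [
    "country", "specific_share", "advalorem_share", "prevalence", "pop15plus",
    "share_15_29", "share_30_39", "share_40_49", "share_50_59", "share_60plus",
]

#: age-band labels used throughout the package (youngest to oldest)
AGE_BANDS = ("15_29", "30_39", "40_49", "50_59", "60plus")


@dataclass(frozen=True)
class PanelDGPParams:
    """Ground-truth parameters of the demand-panel data generating process.

    Defaults correspond to the study conditions the estimator is validated
    under: 22 countries observed 1999-2015, a Group-6-sized price elasticity,
    strongly autocorrelated real prices (so the lagged price is a relevant
    instrument) and mildly clustered errors.
    """

    n_countries: int = 22
    first_year: int = 1999
    last_year: int = 2015
    beta_price: float = -1.304
    beta_gni: float = 0.769
    beta_fctc: float = -0.103
    alpha_mean: float = 1.0
    alpha_sd: float = 0.5
    #: correlation between country intercepts and the country's mean log price;
    #: nonzero values violate the random-effects assumption (used to study the
    #: power of the Hausman test).
    alpha_price_corr: float = 0.0
    price_rho: float = 0.9
    price_shock_sd: float = 0.08
    error_sd: float = 0.05
    error_cluster_rho: float = 0.3
    fctc_window: tuple[int, int] = (2003, 2010)
    seed: int = 0

    def validate(self) -> None:
        if self.n_countries < 2:
            raise ValueError("n_countries must be >= 2")
        if self.last_year - self.first_year + 1 < 3:
            raise ValueError("years must span at least 3 calendar years")
        for field in ("alpha_sd", "price_shock_sd", "error_sd"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be >= 0")
        if not abs(self.price_rho) < 1:
            raise ValueError("price_rho must satisfy |price_rho| < 1")
        if not 0 <= self.error_cluster_rho < 1:
            raise ValueError("error_cluster_rho must be in [0, 1)")
        if not -1 <= self.alpha_price_corr <= 1:
            raise ValueError("alpha_price_corr must be in [-1, 1]")
        lo, hi = self.fctc_window
        if lo > hi:
            raise ValueError("fctc_window must be an increasing year range")

    def replace(self, **kwargs) -> "PanelDGPParams":
        return dataclasses.replace(self, **kwargs)


def generate_panel(params: PanelDGPParams) -> pd.DataFrame:
    """Draw one balanced country-year panel from the demand model.

    Returns a DataFrame with columns ``country, year, consumption, price,
    gni, fctc, cpi`` (one row per country-year, levels not logs).  The same
    ``params.seed`` always yields the identical panel.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, years = params.n_countries, np.arange(params.first_year, params.last_year + 1)
    T = years.size

    # log real price: country base + stationary AR(1) deviation
    base = rng.normal(np.log(1.2), 0.5, size=n)
    rho, ssd = params.price_rho, params.price_shock_sd
    x = np.empty((n, T))
    stat_sd = ssd / np.sqrt(1 - rho**2) if ssd > 0 else 0.0
    x[:, 0] = rng.normal(0.0, 1.0, size=n) * stat_sd
    for t in range(1, T):
        x[:, t] = rho * x[:, t - 1] + rng.normal(0.0, 1.0, size=n) * ssd
    ln_price = base[:, None] + x

    # GNI: geometric growth with country-specific level and drift
    ln_gni0 = rng.uniform(np.log(500.0), np.log(12000.0), size=n)
    drift = rng.uniform(0.0, 0.05, size=n)
    ln_gni = ln_gni0[:, None] + drift[:, None] * np.arange(T) \
        + rng.normal(0.0, 0.02, size=(n, T))

    # CPI: smooth inflation path, base year = 100
    infl = rng.uniform(0.02, 0.08, size=n)[:, None] + rng.normal(0.0, 0.004, size=(n, T))
    infl = np.maximum(infl, 0.0)
    cpi = 100.0 * np.cumprod(np.concatenate([np.ones((n, 1)), 1 + infl[:, 1:]], axis=1), axis=1)

    # staggered FCTC ratification
    lo, hi = params.fctc_window
    adoption = rng.integers(lo, hi + 1, size=n)
    fctc = (years[None, :] >= adoption[:, None]).astype(float)

    # country intercepts, optionally correlated with mean log price
    z = rng.normal(size=n)
    if params.alpha_price_corr != 0.0:
        mp = ln_price.mean(axis=1)
        sd = mp.std()
        zp = (mp - mp.mean()) / sd if sd > 0 else np.zeros(n)
        c = params.alpha_price_corr
        z = c * zp + np.sqrt(1 - c**2) * z
    alpha = params.alpha_mean + params.alpha_sd * z

    # equicorrelated-within-country error
    rc = params.error_cluster_rho
    u = rng.normal(size=n)[:, None]
    e = rng.normal(size=(n, T))
    eps = params.error_sd * (np.sqrt(rc) * u + np.sqrt(1 - rc) * e)

    ln_c = (alpha[:, None] + params.beta_price * ln_price
            + params.beta_gni * ln_gni + params.beta_fctc * fctc + eps)

    countries = [f"C{i + 1:02d}" for i in range(n)]
    return pd.DataFrame({
        "country": np.repeat(countries, T),
        "year": np.tile(years, n),
        "consumption": np.exp(ln_c).ravel(),
        "price": np.exp(ln_price).ravel(),
        "gni": np.exp(ln_gni).ravel(),
        "fctc": fctc.ravel().astype(int),
        "cpi": cpi.ravel(),
    })


def generate_policy_table(n_countries: int, seed: int) -> pd.DataFrame:
    """Draw a country policy table (tax shares, prevalence, demography).

    Tax shares are drawn so the total excise share stays within the 0-0.67
    range observed across the region; age shares are a Dirichlet draw tilted
    toward younger bands, matching the demography of low- and middle-income
    countries.
    """
    if n_countries < 1:
        raise ValueError("n_countries must be >= 1")
    rng = np.random.default_rng(seed)
    total = rng.uniform(0.0, 0.67, size=n_countries)
    split = rng.uniform(size=n_countries)  # fraction of the total that is specific
    prevalence = rng.uniform(0.10, 0.38, size=n_countries)
    pop = 10 ** rng.uniform(5.0, 9.0, size=n_countries)
    shares = rng.dirichlet([5.0, 4.0, 3.0, 2.0, 2.0], size=n_countries)
    shares /= shares.sum(axis=1, keepdims=True)
    return pd.DataFrame({
        "country": [f"C{i + 1:02d}" for i in range(n_countries)],
        "specific_share": total * split,
        "advalorem_share": total * (1 - split),
        "prevalence": prevalence,
        "pop15plus": pop,
        "share_15_29": shares[:, 0],
        "share_30_39": shares[:, 1],
        "share_40_49": shares[:, 2],
        "share_50_59": shares[:, 3],
        "share_60plus": shares[:, 4],
    })
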
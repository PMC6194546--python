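"""Bundled reference tables for the 22-country Asia-Pacific study.

Three hand-transcribed tables ship with the package:

* ``table1_policy.csv`` — excise structure (specific / ad valorem shares of
  the retail price), 2006/2015 consumption and real prices, and adult smoking
  prevalence per country;
* ``table2_elasticities.csv`` — the six income groups' demand-equation
  estimates (price/income/FCTC coefficients, standard errors, diagnostics)
  and group membership;
* ``table3_expected.csv`` — the published simulation outcomes (percent price
  increments, consumption and revenue changes, smoker and averted-death
  counts) used as the snapshot surface for the simulator.

``policy_inputs_synthetic.csv`` is a constructed simulator input table: the
tax shares and prevalence come from the policy table, while population aged
15+ and the age-band shares — which the source tables do not print — are
backed out of the published smoker/death counts (population from the mean
smoker reduction, age shares calibrated so the mortality adjustment factor
matches the implied death/smoker ratio).  It is synthetic in that sense and
labelled accordingly.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .simulator import CountryPolicyInputs, PriceScenario


def _read(name: str) -> pd.DataFrame:
    with resources.files("cigtaxsim.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_table1() -> pd.DataFrame:
    """Excise structure, consumption/price levels and prevalence (percent units)."""
    return _read("table1_policy.csv")


def load_table2() -> pd.DataFrame:
    """Per-income-group demand-equation estimates and diagnostics."""
    return _read("table2_elasticities.csv")


def load_table3() -> pd.DataFrame:
    """Published simulation outcomes (percent columns suffixed ``_pct``)."""
    return _read("table3_expected.csv")


def load_policy_inputs() -> pd.DataFrame:
    """Simulator inputs (fractions): tax shares, prevalence, implied demography."""
    return _read("policy_inputs_synthetic.csv")


def country_group_map() -> dict[str, int]:
    t2 = load_table2()
    out: dict[str, int] = {}
    for _, row in t2.iterrows():
        for c in str(row["members"]).split(";"):
            out[c] = int(row["group_id"])
    return out


def elasticity_by_country() -> dict[str, float]:
    """Map each country to its income group's price elasticity."""
    t2 = load_table2().set_index("group_id")
    return {c: float(t2.loc[g, "beta_price"]) for c, g in country_group_map().items()}


def policy_inputs_objects() -> list[CountryPolicyInputs]:
    rows = []
    for _, r in load_policy_inputs().iterrows():
        def _opt(v):
            return None if pd.isna(v) else float(v)
        rows.append(CountryPolicyInputs(
            country=r["country"],
            specific_share=_opt(r["specific_share"]),
            advalorem_share=_opt(r["advalorem_share"]),
            prevalence=float(r["prevalence"]),
            pop15plus=float(r["pop15plus"]),
            age_shares=tuple(float(r[f"share_{b}"]) for b in
                             ("15_29", "30_39", "40_49", "50_59", "60plus")),
        ))
    return rows


def reference_scenarios(kinds: tuple[str, ...] = ("mean", "max")) -> list[PriceScenario]:
    """Price scenarios from the published mean/max annual increments (fractions)."""
    t3 = load_table3()
    scenarios = []
    for _, r in t3.iterrows():
        for kind in kinds:
            scenarios.append(PriceScenario(
                country=r["country"], kind=kind,
                dP=float(r[f"dp_{kind}_pct"]) / 100.0,
            ))
    return scenarios
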
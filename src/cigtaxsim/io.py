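"""CSV/JSON/YAML readers and writers plus the end-to-end pipeline.

File conventions: all shares, prevalences and price/consumption changes are
fractions (never percent) in machine-readable files; the report layer alone
multiplies by 100.  Missing values are empty cells, surfaced as undefined
(None), never as 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .dgp import PANEL_COLUMNS, POLICY_COLUMNS, PanelDGPParams, generate_panel
from .estimator import ElasticityFit, estimate_by_group
from .simulator import (CountryPolicyInputs, MortalityParams, PriceScenario,
                        SimulationOutcome, aggregate_region, historical_increments,
                        simulate_country)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# panel CSV


def load_panel(path: str | Path) -> pd.DataFrame:
    """Read and validate a demand-panel CSV (header ``country,year,...``)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["country", "year"])
    if dup.any():
        i = int(np.flatnonzero(dup)[0])
        pair = (df.loc[i, "country"], int(df.loc[i, "year"]))
        raise ValueError(f"{path}: duplicate (country, year) {pair} at line {i + 2}")
    for col in ("consumption", "price", "gni", "cpi"):
        bad = ~(pd.to_numeric(df[col], errors="coerce") > 0)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: line {i + 2}: {col}={df.loc[i, col]!r} must be a positive number")
    if not df["fctc"].isin([0, 1]).all():
        i = int(np.flatnonzero(~df["fctc"].isin([0, 1]))[0])
        raise ValueError(f"{path}: line {i + 2}: fctc must be 0 or 1")
    return df[PANEL_COLUMNS]


def write_panel(df: pd.DataFrame, path: str | Path) -> None:
    df[PANEL_COLUMNS].to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# policy CSV


def load_policy_csv(path: str | Path) -> list[CountryPolicyInputs]:
    """Read a policy table (fractions); empty tax-share cells mean unknown."""
    df = pd.read_csv(path)
    missing = [c for c in POLICY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for i, r in df.iterrows():
        try:
            out.append(CountryPolicyInputs(
                country=r["country"],
                specific_share=None if pd.isna(r["specific_share"]) else float(r["specific_share"]),
                advalorem_share=None if pd.isna(r["advalorem_share"]) else float(r["advalorem_share"]),
                prevalence=float(r["prevalence"]),
                pop15plus=float(r["pop15plus"]),
                age_shares=tuple(float(r[f"share_{b}"]) for b in
                                 ("15_29", "30_39", "40_49", "50_59", "60plus")),
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return out


def write_policy_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[POLICY_COLUMNS].to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# elasticities


def write_fits_json(fits: list[ElasticityFit], path: str | Path) -> None:
    Path(path).write_text(json.dumps([f.to_dict() for f in fits], indent=1))


def load_elasticities(source: str | Path) -> dict[str, float]:
    """Country -> price elasticity, from a fit JSON or ``builtin-table2``."""
    if str(source) == "builtin-table2":
        return datasets.elasticity_by_country()
    records = json.loads(Path(source).read_text())
    out: dict[str, float] = {}
    for rec in records:
        for c in rec.get("countries", []):
            out[c] = float(rec["beta_price"])
    return out


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Configuration of one ``synth -> estimate -> simulate -> report`` run."""

    outdir: str = "out"
    panel: str | None = None          # path | "synth" | None
    policy: str = "builtin"           # path | "builtin"
    elasticities: str = "builtin-table2"  # path | "builtin-table2" | "estimate"
    increments: str = "builtin-table3"    # "panel" | "builtin-table3"
    scenarios: tuple[str, ...] = ("mean", "max")
    aggregation: str = "unweighted"
    positive_only_increments: bool = False
    iv: bool = True
    seed: int = 0
    synth_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.scenarios = tuple(cfg.scenarios)
        return cfg


# ---------------------------------------------------------------------------
# pipeline


def _percent(x: float | None) -> str:
    return "-" if x is None else f"{100 * x:.2f}"


def outcomes_to_frame(outcomes: list[SimulationOutcome]) -> pd.DataFrame:
    return pd.DataFrame([{
        "country": o.country, "kind": o.kind, "dP": o.dP, "dC": o.dC,
        "dRevenue": np.nan if o.dRevenue is None else o.dRevenue,
        "smoker_reduction": o.smoker_reduction,
        "sads_averted": o.sads_averted, "maf": o.maf,
    } for o in outcomes])


def render_report(outcomes: list[SimulationOutcome], aggregates: dict) -> str:
    """Markdown table shaped like the published simulation summary."""
    by_country: dict[str, dict[str, SimulationOutcome]] = {}
    for o in outcomes:
        by_country.setdefault(o.country, {})[o.kind] = o
    lines = [
        "| Country | dP max (%) | dP mean (%) | dC max (%) | dC mean (%) "
        "| dRev max (%) | dRev mean (%) | Smokers averted (mean) | SADs averted (mean) |",
        "|---|---|---|---|---|---|---|---|---|",
    ]
    for c, kinds in by_country.items():
        mx, mn = kinds.get("max"), kinds.get("mean")
        lines.append(
            f"| {c} | {_percent(mx.dP if mx else None)} | {_percent(mn.dP if mn else None)} "
            f"| {_percent(mx.dC if mx else None)} | {_percent(mn.dC if mn else None)} "
            f"| {_percent(mx.dRevenue if mx else None)} | {_percent(mn.dRevenue if mn else None)} "
            f"| {mn.smoker_reduction:,.0f} | {mn.sads_averted:,.0f} |"
            if mn else f"| {c} | - | - | - | - | - | - | - | - |")
    lines.append("")
    for kind, agg in aggregates.items():
        lines.append(
            f"Region ({kind}): mean dP {_percent(agg['mean_dP'])}%, "
            f"dC {_percent(agg['dC'])}%, dRevenue {_percent(agg['dRevenue'])}%, "
            f"smokers {agg['total_smoker_reduction']:,.0f}, "
            f"SADs {agg['total_sads_averted']:,.0f}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the configured stages; returns the paths of all written artifacts.

    Every exclusion (country without elasticity, policy inputs or usable
    price series) is logged; nothing is dropped silently.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # --- panel stage
    panel = None
    if config.panel == "synth":
        params = PanelDGPParams(seed=config.seed, **config.synth_params)
        panel = generate_panel(params)
        artifacts["panel"] = out / "panel.csv"
        write_panel(panel, artifacts["panel"])
    elif config.panel:
        panel = load_panel(config.panel)

    # --- estimation stage
    if config.elasticities == "estimate":
        if panel is None:
            raise ValueError("estimate stage requires a panel (path or 'synth')")
        fits = estimate_by_group(panel, iv=config.iv)
        artifacts["fit"] = out / "fit.json"
        write_fits_json(fits, artifacts["fit"])
        elasticities = load_elasticities(artifacts["fit"])
    else:
        elasticities = load_elasticities(config.elasticities)

    # --- policy inputs
    if config.policy == "builtin":
        policies = datasets.policy_inputs_objects()
    else:
        policies = load_policy_csv(config.policy)
    policy_map = {p.country: p for p in policies}

    # --- price scenarios
    scenarios: list[PriceScenario] = []
    if config.increments == "builtin-table3":
        scenarios = datasets.reference_scenarios(tuple(config.scenarios))
    elif config.increments == "panel":
        if panel is None:
            raise ValueError("panel increments require a panel")
        for c, sub in panel.groupby("country"):
            series = dict(zip(sub["year"], sub["price"]))
            mean_dp, max_dp = historical_increments(
                series, positive_only=config.positive_only_increments)
            for kind, dp in (("mean", mean_dp), ("max", max_dp)):
                if kind in config.scenarios:
                    scenarios.append(PriceScenario(c, kind, dp))
    else:
        raise ValueError(f"unknown increments source {config.increments!r}")

    # --- simulation stage
    outcomes: list[SimulationOutcome] = []
    for sc in scenarios:
        if sc.country not in elasticities:
            logger.warning("no elasticity for %s; excluded from simulation", sc.country)
            continue
        if sc.country not in policy_map:
            logger.warning("no policy inputs for %s; excluded from simulation", sc.country)
            continue
        o = simulate_country(policy_map[sc.country], elasticities[sc.country], sc)
        if o.dRevenue is None:
            logger.info("%s (%s): revenue change undefined (no excise)", sc.country, sc.kind)
        outcomes.append(o)
    if not outcomes:
        raise ValueError("simulation produced no outcomes")

    artifacts["simulation"] = out / "simulation.csv"
    outcomes_to_frame(outcomes).to_csv(artifacts["simulation"], index=False,
                                       float_format="%.17g")

    aggregates = {
        kind: aggregate_region([o for o in outcomes if o.kind == kind],
                               weighting=config.aggregation)
        for kind in config.scenarios
        if any(o.kind == kind for o in outcomes)
    }
    artifacts["report"] = out / "report.md"
    artifacts["report"].write_text(render_report(outcomes, aggregates))
    artifacts["aggregates"] = out / "aggregates.json"
    artifacts["aggregates"].write_text(json.dumps(aggregates, indent=1))
    return artifacts
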
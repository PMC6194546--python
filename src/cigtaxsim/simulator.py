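"""Deterministic tax-policy simulator.

Converts a fractional real-price increase dP into

* a consumption change dC = elasticity x dP (linear response),
* an excise-revenue change ((tau + dP) / tau) x (1 + dC) - 1, where tau is
  the total excise share of the retail price and the whole price increment
  is assumed to accrue to (specific) excise,
* a reduction in smoker numbers, prevalence x population(15+) x |dC|,
  attributing the whole consumption response to quitting,
* averted smoking-attributable deaths, the smoker reduction scaled by a
  mortality adjustment factor that combines the quitters' age distribution
  with age-specific risk-avoidance fractions and the baseline probability
  that a continuing smoker dies of smoking.

Countries with no excise (tau = 0 or unknown) have an undefined revenue
change, reported as None rather than 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dgp import AGE_BANDS

#: fraction of quitters in each age band (15-29, 30-39, 40-49, 50-59, 60+)
#: assumed to escape the mortality consequences of their former habit
DEFAULT_AVOIDANCE_WEIGHTS = (0.95, 0.75, 0.70, 0.50, 0.10)

#: baseline probability that a continuing smoker eventually dies of smoking
DEFAULT_SMOKER_DEATH_RISK = 0.5


@dataclass(frozen=True)
class CountryPolicyInputs:
    """Per-country tax structure, prevalence and demography."""

    country: str
    specific_share: float | None  # fraction of retail price; None = unknown
    advalorem_share: float | None
    prevalence: float
    pop15plus: float
    age_shares: tuple[float, float, float, float, float]

    def __post_init__(self):
        for name in ("specific_share", "advalorem_share"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        tau = self.total_excise_share
        if tau is not None and tau > 1:
            raise ValueError(f"total excise share {tau} exceeds 1")
        if not 0 <= self.prevalence <= 1:
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if self.pop15plus < 0:
            raise ValueError("pop15plus must be >= 0")
        if abs(sum(self.age_shares) - 1) > 1e-9:
            raise ValueError(f"age_shares must sum to 1, got {sum(self.age_shares)}")

    @property
    def total_excise_share(self) -> float | None:
        """tau: specific + ad valorem excise as a fraction of retail price."""
        if self.specific_share is None or self.advalorem_share is None:
            return None
        return self.specific_share + self.advalorem_share


@dataclass(frozen=True)
class MortalityParams:
    avoidance_weights: tuple[float, ...] = DEFAULT_AVOIDANCE_WEIGHTS
    smoker_death_risk: float = DEFAULT_SMOKER_DEATH_RISK

    def __post_init__(self):
        if len(self.avoidance_weights) != len(AGE_BANDS):
            raise ValueError(f"need {len(AGE_BANDS)} avoidance weights")
        if any(not 0 <= w <= 1 for w in self.avoidance_weights):
            raise ValueError("avoidance weights must be in [0, 1]")
        if not 0 <= self.smoker_death_risk <= 1:
            raise ValueError("smoker_death_risk must be in [0, 1]")


@dataclass(frozen=True)
class PriceScenario:
    country: str
    kind: str  # "mean" | "max"
    dP: float  # fractional real-price increase

    def __post_init__(self):
        if self.kind not in ("mean", "max"):
            raise ValueError(f"kind must be 'mean' or 'max', got {self.kind!r}")
        if self.dP <= -1:
            raise ValueError("dP must exceed -1 (price cannot go non-positive)")


@dataclass(frozen=True)
class SimulationOutcome:
    country: str
    kind: str
    dP: float
    dC: float
    dRevenue: float | None  # None when baseline excise is zero/unknown
    smoker_reduction: float
    sads_averted: float
    maf: float


# ---------------------------------------------------------------------------


def historical_increments(price_series: dict[int, float],
                          positive_only: bool = False) -> tuple[float, float]:
    """Mean and max year-over-year fractional price change of a series.

    Changes are computed across consecutive calendar years only; gaps simply
    contribute no change.  ``positive_only`` restricts the mean to increases
    (the max is unaffected unless every change is negative).
    """
    years = sorted(price_series)
    if len(years) < 2:
        raise ValueError("need at least two years of prices")
    changes = []
    for a, b in zip(years, years[1:]):
        if b - a == 1:
            p0, p1 = price_series[a], price_series[b]
            if p0 <= 0 or p1 <= 0:
                raise ValueError("prices must be positive")
            changes.append(p1 / p0 - 1)
    if not changes:
        raise ValueError("no consecutive-year price pairs in series")
    max_dp = max(changes)
    pool = [c for c in changes if c > 0] if positive_only else changes
    if not pool:
        pool = changes
    return float(np.mean(pool)), float(max_dp)


def simulate_consumption_change(elasticity: float, dP: float) -> float:
    """dC = elasticity x dP (linear response to the fractional price change)."""
    if dP <= -1:
        raise ValueError("dP must exceed -1")
    return elasticity * dP


def simulate_revenue_change(policy: CountryPolicyInputs, dP: float,
                            dC: float) -> float | None:
    """Fractional excise-revenue change, or None when there is no excise.

    The entire price increment is treated as new specific excise: per-pack
    excise rises from tau x price to (tau + dP) x price, while volume scales
    by (1 + dC), giving ((tau + dP) / tau) x (1 + dC) - 1.
    """
    tau = policy.total_excise_share
    if tau is None or tau == 0:
        return None
    if tau < 0 or tau > 1:
        raise ValueError(f"total excise share must be in [0, 1], got {tau}")
    return (tau + dP) / tau * (1 + dC) - 1


def simulate_smoker_reduction(policy: CountryPolicyInputs, dC: float) -> float:
    """Persons who quit: prevalence x population(15+) x |dC|.

    The whole consumption response is attributed to the prevalence margin
    (quitting) rather than to reduced intensity among continuing smokers.
    """
    if dC > 0:
        raise ValueError("smoker reduction is defined for non-positive dC")
    if not np.isfinite(policy.prevalence) or not np.isfinite(policy.pop15plus):
        raise ValueError(f"missing prevalence or population for {policy.country}")
    return policy.prevalence * policy.pop15plus * abs(dC)


def mortality_adjustment_factor(policy: CountryPolicyInputs,
                                mp: MortalityParams = MortalityParams()) -> float:
    """MAF = death risk x sum over age bands of share x avoidance weight."""
    return mp.smoker_death_risk * float(
        np.dot(policy.age_shares, mp.avoidance_weights))


def averted_sads(smoker_reduction: float, maf: float) -> float:
    """Averted smoking-attributable deaths = quitters x MAF."""
    if smoker_reduction < 0:
        raise ValueError("smoker_reduction must be >= 0")
    if not 0 <= maf <= 1:
        raise ValueError("maf must be in [0, 1]")
    return smoker_reduction * maf


def simulate_country(policy: CountryPolicyInputs, elasticity: float,
                     scenario: PriceScenario,
                     mp: MortalityParams = MortalityParams()) -> SimulationOutcome:
    """Run the full chain price -> consumption -> revenue/smokers/deaths."""
    dC = simulate_consumption_change(elasticity, scenario.dP)
    dRev = simulate_revenue_change(policy, scenario.dP, dC)
    smokers = simulate_smoker_reduction(policy, min(dC, 0.0))
    maf = mortality_adjustment_factor(policy, mp)
    return SimulationOutcome(
        country=policy.country, kind=scenario.kind, dP=scenario.dP, dC=dC,
        dRevenue=dRev, smoker_reduction=smokers,
        sads_averted=averted_sads(smokers, maf), maf=maf,
    )


def aggregate_region(outcomes: list[SimulationOutcome],
                     weighting: str = "unweighted",
                     weights: dict[str, float] | None = None) -> dict:
    """Regional summary of one scenario kind's outcomes.

    The regional price increment is the unweighted arithmetic mean of the
    country increments; smoker reductions and averted deaths are summed.
    Consumption and revenue percentage aggregation is configurable:
    ``unweighted`` (arithmetic mean) or ``weighted`` with caller-supplied
    per-country weights (e.g. baseline consumption or revenue).
    """
    if not outcomes:
        raise ValueError("aggregate_region requires at least one outcome")
    kinds = {o.kind for o in outcomes}
    if len(kinds) > 1:
        raise ValueError(f"mixed scenario kinds {kinds}; aggregate one kind at a time")

    def _avg(values, countries):
        if weighting == "unweighted":
            return float(np.mean(values))
        if weights is None:
            raise ValueError("weighted aggregation requires weights")
        w = np.array([weights[c] for c in countries], dtype=float)
        return float(np.average(values, weights=w))

    rev = [(o.country, o.dRevenue) for o in outcomes if o.dRevenue is not None]
    return {
        "kind": kinds.pop(),
        "n_countries": len(outcomes),
        "mean_dP": float(np.mean([o.dP for o in outcomes])),
        "dC": _avg([o.dC for o in outcomes], [o.country for o in outcomes]),
        "dRevenue": _avg([r for _, r in rev], [c for c, _ in rev]) if rev else None,
        "total_smoker_reduction": float(sum(o.smoker_reduction for o in outcomes)),
        "total_sads_averted": float(sum(o.sads_averted for o in outcomes)),
    }
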
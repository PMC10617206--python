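"""Configuration-driven end-to-end runs and table-style reports.

Two entry points mirror the published analysis:

* :func:`run_current_burden` — for each exposure period and its lagged
  cost year (2008-2009 consumption -> 2018 costs; 2017-2018 -> 2030),
  computes per-exposure and joint attributable fractions against the
  theoretical-minimum-risk counterfactual, with Monte Carlo uncertainty
  intervals and attributable costs.
* :func:`run_scenarios` — projects costs to 2040 and evaluates the four
  counterfactual consumption scenarios applied to the latest exposure
  period, reporting potential savings.

Inputs (records, RR table, cost series, schemes) come from CSV/JSON paths
in the :class:`RunConfig`, or are generated by the synthetic module when a
path is omitted.  Runs are deterministic given a seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from . import cost_projection as cp
from . import exposure as ex
from . import synthetic_data as sd
from .attribution import joint_pif, truncate_pif
from .exceptions import ConfigurationError
from .relative_risk import EXPOSURES, DoseResponseRR, load_rr_table
from .uncertainty import (
    PIFStratum,
    SimulationConfig,
    joint_draws,
    run_monte_carlo,
)

logger = logging.getLogger("meatcost")

__all__ = [
    "RunConfig",
    "SimulationSettings",
    "PipelineInputs",
    "load_pipeline_inputs",
    "run_current_burden",
    "run_scenarios",
    "format_burden_table",
    "format_scenario_table",
]

COMBINED = "combined"
BOTH = "both"


class SimulationSettings(BaseModel):
    """Monte Carlo block of a run configuration."""

    n_iterations: int = Field(default=10_000, ge=1)
    percentiles: tuple[float, float, float] = (2.5, 50.0, 97.5)
    prevalence_draw_mode: str = "binomial"


class PeriodInput(BaseModel):
    """Record source for one exposure period: CSV paths per sex, or the
    synthetic generator (optionally with an overridden record count)."""

    records_csv: dict[str, str] | None = None
    n_records: int | None = Field(default=None, ge=1)


class RunConfig(BaseModel):
    """Full configuration for an end-to-end run.

    Any omitted path falls back to the packaged synthetic defaults.  The
    lag mapping pairs each exposure period with the cost year it
    influences; each pairing must respect the assumed minimum 10-year
    exposure-to-outcome lag.
    """

    rr_table_csv: str | None = None
    schemes_json: str | None = None
    cost_series_csv: str | None = None
    periods: dict[str, PeriodInput] = Field(
        default_factory=lambda: {p: PeriodInput() for p in sd.PERIODS}
    )
    lag_mapping: dict[str, int] = Field(
        default_factory=lambda: {"2008-2009": 2018, "2017-2018": 2030}
    )
    scenario_period: str = "2017-2018"
    scenario_year: int = 2040
    scenarios: list[int] = Field(default_factory=lambda: [1, 2, 3, 4])
    simulation: SimulationSettings = Field(default_factory=SimulationSettings)
    ppp_current: float = Field(default=cp.PPP_CURRENT, gt=0)
    ppp_future: float = Field(default=cp.PPP_FUTURE, gt=0)

    @field_validator("scenarios")
    @classmethod
    def _known_scenarios(cls, v):
        bad = [s for s in v if s not in ex.SCENARIO_IDS]
        if bad:
            raise ValueError(f"unknown scenario ids: {bad}")
        return v

    @model_validator(mode="after")
    def _lag_at_least_ten_years(self):
        for period, cost_year in self.lag_mapping.items():
            start = int(period.split("-")[0])
            if cost_year < start + 10:
                raise ValueError(
                    f"cost year {cost_year} is under 10 years after exposure "
                    f"period {period}"
                )
            if period not in self.periods:
                raise ValueError(f"lag mapping references unknown period {period!r}")
        return self

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def content_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:12]


@dataclass
class PipelineInputs:
    """Resolved inputs for one run: records per (period, sex), RR per
    (exposure, sex), schemes, and fitted cost trends per sex."""

    records: dict[tuple[str, str], pd.DataFrame]
    rr: dict[tuple[str, str], DoseResponseRR]
    schemes: dict[str, ex.ExposureCategoryScheme]
    cost_series: pd.DataFrame  # year, sex, cost_brl
    trends: dict[str, cp.CostTrend]


def _child_seed(root: np.random.SeedSequence, *labels: str) -> np.random.Generator:
    """Independent, label-addressed deterministic stream."""
    digest = hashlib.sha256("/".join(labels).encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([root.entropy, key]))


def load_pipeline_inputs(config: RunConfig, seed: int | None) -> PipelineInputs:
    """Load or synthesize every input the run needs."""
    root = np.random.SeedSequence(0 if seed is None else seed)

    if config.rr_table_csv:
        table = load_rr_table(config.rr_table_csv)
    else:
        table = sd.generate_rr_table()
    rr = {(d.exposure, d.sex): d for d in table}

    schemes = (
        ex.load_schemes(config.schemes_json)
        if config.schemes_json
        else dict(ex.DEFAULT_SCHEMES)
    )

    records: dict[tuple[str, str], pd.DataFrame] = {}
    for period in sorted(config.periods):
        spec = config.periods[period]
        for sex in sd.SEXES:
            if spec.records_csv:
                try:
                    path = spec.records_csv[sex]
                except KeyError:
                    raise ConfigurationError(
                        f"period {period}: no records CSV for sex {sex!r}"
                    ) from None
                df = pd.read_csv(path)
            else:
                params = sd.default_survey_params(period, sex, spec.n_records)
                df = sd.generate_survey(
                    params, _child_seed(root, "survey", period, sex)
                )
            records[(period, sex)] = ex.validate_records(df)

    if config.cost_series_csv:
        series = cp.load_cost_series(config.cost_series_csv)
    else:
        frames = [
            sd.generate_cost_series(
                sd.default_cost_params(sex), _child_seed(root, "costs", sex)
            )
            for sex in sd.SEXES
        ]
        series = pd.concat(frames, ignore_index=True)

    trends = {
        sex: cp.fit_trend(series[series["sex"] == sex])
        for sex in sd.SEXES
        if (series["sex"] == sex).any()
    }
    missing = [s for s in sd.SEXES if s not in trends]
    if missing:
        raise ConfigurationError(f"cost series missing sex strata: {missing}")
    return PipelineInputs(
        records=records, rr=rr, schemes=schemes, cost_series=series, trends=trends
    )


def _cost_for_year(
    inputs: PipelineInputs, config: RunConfig, sex: str, year: int
) -> tuple[float, tuple[float, float] | None]:
    """Cost in PPP dollars for one sex and year: the observed registry
    value when the year is in the series (current PPP factor, no CI),
    otherwise the trend projection (future PPP factor, mean-response CI).
    """
    obs = inputs.cost_series[
        (inputs.cost_series["sex"] == sex) & (inputs.cost_series["year"] == year)
    ]
    if len(obs):
        return cp.ppp_convert(float(obs["cost_brl"].iloc[0]), config.ppp_current), None
    proj = cp.project(inputs.trends[sex], year)
    f = config.ppp_future
    return (
        cp.ppp_convert(proj.cost, f),
        (cp.ppp_convert(proj.ci[0], f), cp.ppp_convert(proj.ci[1], f)),
    )


def _reference_level(pv: ex.PrevalenceVector, scheme: ex.ExposureCategoryScheme) -> float:
    """Reference exposure value: 0 g/day for a zero-consumption reference
    band, otherwise the empirical median within the reference band."""
    if scheme.zero_band:
        return 0.0
    m = float(pv.medians[scheme.reference_index])
    return 0.0 if np.isnan(m) else m


def _paf_stratum(
    inputs: PipelineInputs, period: str, sex: str, exposure: str
) -> PIFStratum:
    scheme = inputs.schemes[exposure]
    pv = ex.categorize(inputs.records[(period, sex)], scheme, sex=sex, period=period)
    cf = np.zeros(pv.n_categories)
    cf[scheme.reference_index] = 1.0
    try:
        dose = inputs.rr[(exposure, sex)]
    except KeyError:
        raise ConfigurationError(
            f"RR table lacks a row for exposure={exposure!r}, sex={sex!r}"
        ) from None
    return PIFStratum(
        exposure=exposure,
        sex=sex,
        baseline=pv,
        counterfactual=cf,
        dose_rr=dose,
        ref=_reference_level(pv, scheme),
    )


def _sim_config(config: RunConfig, seed: int | None, label: str) -> SimulationConfig:
    digest = hashlib.sha256(label.encode()).digest()
    mixed = ((0 if seed is None else seed) ^ int.from_bytes(digest[:4], "big")) % (
        2**31
    )
    s = config.simulation
    return SimulationConfig(
        n_iterations=s.n_iterations,
        seed=mixed,
        percentiles=s.percentiles,
        prevalence_draw_mode=s.prevalence_draw_mode,
    )


def _percentiles(draws: np.ndarray, percentiles) -> tuple[float, float, float]:
    lo, mid, hi = np.percentile(draws, list(percentiles))
    return float(lo), float(mid), float(hi)


def run_current_burden(
    config: RunConfig, seed: int | None = None
) -> pd.DataFrame:
    """Attributable current/future burden per exposure period.

    Returns one row per (period, exposure incl. combined, sex incl.
    both) with the cost, PIF (theoretical-minimum counterfactual, i.e.
    PAF), uncertainty interval, and attributable cost.
    """
    inputs = load_pipeline_inputs(config, seed)
    logger.info(
        "current-burden run: seed=%s iterations=%d config=%s",
        seed,
        config.simulation.n_iterations,
        config.content_hash(),
    )
    rows = []
    for period in sorted(config.lag_mapping):
        cost_year = config.lag_mapping[period]
        costs = {sex: _cost_for_year(inputs, config, sex, cost_year) for sex in sd.SEXES}

        strata = [
            _paf_stratum(inputs, period, sex, exposure)
            for exposure in EXPOSURES
            for sex in sd.SEXES
        ]
        sim = _sim_config(config, seed, f"burden/{period}")
        dm = run_monte_carlo(strata, sim)
        joint = joint_draws(
            dm,
            {
                f"{COMBINED}/{sex}": [f"{e}/{sex}" for e in EXPOSURES]
                for sex in sd.SEXES
            },
        )
        point = {s.key: truncate_pif(s.point_pif()) for s in strata}
        for sex in sd.SEXES:
            point[f"{COMBINED}/{sex}"] = joint_pif(
                [point[f"{e}/{sex}"] for e in EXPOSURES]
            )
        draws_of = {k: dm.column(k) for k in dm.keys}
        draws_of.update({k: joint.column(k) for k in joint.keys})

        for exposure in (*EXPOSURES, COMBINED):
            att_draws_by_sex = {}
            for sex in sd.SEXES:
                cost, cost_ci = costs[sex]
                key = f"{exposure}/{sex}"
                pif_point = point[key]
                pif_lo, pif_mid, pif_hi = _percentiles(
                    draws_of[key], config.simulation.percentiles
                )
                att_draws_by_sex[sex] = draws_of[key] * cost
                rows.append(
                    {
                        "period": period,
                        "cost_year": cost_year,
                        "exposure": exposure,
                        "sex": sex,
                        "cost_usd": cost,
                        "cost_ci_lower": cost_ci[0] if cost_ci else np.nan,
                        "cost_ci_upper": cost_ci[1] if cost_ci else np.nan,
                        "pif": pif_point,
                        "pif_lower": pif_lo,
                        "pif_median": pif_mid,
                        "pif_upper": pif_hi,
                        "attributable_usd": pif_point * cost,
                        "attributable_lower": pif_lo * cost,
                        "attributable_upper": pif_hi * cost,
                    }
                )
            # both-sex row: attributable costs add; PIF is cost-weighted
            total_cost = sum(costs[s][0] for s in sd.SEXES)
            att_point = sum(point[f"{exposure}/{s}"] * costs[s][0] for s in sd.SEXES)
            att_draws = sum(att_draws_by_sex.values())
            att_lo, att_mid, att_hi = _percentiles(
                att_draws, config.simulation.percentiles
            )
            cis = [costs[s][1] for s in sd.SEXES]
            both_ci = (
                (sum(c[0] for c in cis), sum(c[1] for c in cis))
                if all(c is not None for c in cis)
                else None
            )
            rows.append(
                {
                    "period": period,
                    "cost_year": cost_year,
                    "exposure": exposure,
                    "sex": BOTH,
                    "cost_usd": total_cost,
                    "cost_ci_lower": both_ci[0] if both_ci else np.nan,
                    "cost_ci_upper": both_ci[1] if both_ci else np.nan,
                    "pif": att_point / total_cost,
                    "pif_lower": att_lo / total_cost,
                    "pif_median": att_mid / total_cost,
                    "pif_upper": att_hi / total_cost,
                    "attributable_usd": att_point,
                    "attributable_lower": att_lo,
                    "attributable_upper": att_hi,
                }
            )
    return pd.DataFrame(rows)


def run_scenarios(config: RunConfig, seed: int | None = None) -> pd.DataFrame:
    """Projected costs at the scenario year and potential savings under
    each counterfactual consumption scenario.

    Returns projected-cost rows (scenario = 0) plus one row per
    (scenario, exposure, sex incl. both) with the scenario PIF and the
    savings (truncated at zero) with uncertainty intervals.  An empty
    scenario list yields the projected costs only.
    """
    inputs = load_pipeline_inputs(config, seed)
    logger.info(
        "scenario run: seed=%s iterations=%d config=%s",
        seed,
        config.simulation.n_iterations,
        config.content_hash(),
    )
    period = config.scenario_period
    year = config.scenario_year
    costs = {sex: _cost_for_year(inputs, config, sex, year) for sex in sd.SEXES}

    rows = []
    for sex in (*sd.SEXES, BOTH):
        if sex == BOTH:
            cost = sum(costs[s][0] for s in sd.SEXES)
            ci = (
                sum(costs[s][1][0] for s in sd.SEXES),
                sum(costs[s][1][1] for s in sd.SEXES),
            )
        else:
            cost, ci = costs[sex]
        rows.append(
            {
                "scenario": 0,
                "exposure": "all",
                "sex": sex,
                "projected_cost_usd": cost,
                "cost_ci_lower": ci[0] if ci else np.nan,
                "cost_ci_upper": ci[1] if ci else np.nan,
                "pif": np.nan,
                "pif_lower": np.nan,
                "pif_upper": np.nan,
                "savings_usd": np.nan,
                "savings_lower": np.nan,
                "savings_upper": np.nan,
            }
        )

    for scenario in config.scenarios:
        strata = []
        for sex in sd.SEXES:
            pairs = ex.scenario_prevalences(
                inputs.records[(period, sex)],
                scenario,
                inputs.schemes,
                sex=sex,
                period=period,
            )
            for exposure in EXPOSURES:
                p, p_cf = pairs[exposure]
                strata.append(
                    PIFStratum(
                        exposure=exposure,
                        sex=sex,
                        baseline=p,
                        counterfactual=p_cf.p,
                        dose_rr=inputs.rr[(exposure, sex)],
                        ref=_reference_level(p, inputs.schemes[exposure]),
                    )
                )
        sim = _sim_config(config, seed, f"scenario/{scenario}")
        dm = run_monte_carlo(strata, sim)
        point = {s.key: truncate_pif(s.point_pif()) for s in strata}

        for exposure in EXPOSURES:
            att_draws_by_sex = {}
            for sex in sd.SEXES:
                cost, _ = costs[sex]
                key = f"{exposure}/{sex}"
                pif_lo, pif_mid, pif_hi = _percentiles(
                    dm.column(key), config.simulation.percentiles
                )
                att_draws_by_sex[sex] = dm.column(key) * cost
                rows.append(
                    {
                        "scenario": scenario,
                        "exposure": exposure,
                        "sex": sex,
                        "projected_cost_usd": cost,
                        "cost_ci_lower": np.nan,
                        "cost_ci_upper": np.nan,
                        "pif": point[key],
                        "pif_lower": pif_lo,
                        "pif_upper": pif_hi,
                        "savings_usd": point[key] * cost,
                        "savings_lower": pif_lo * cost,
                        "savings_upper": pif_hi * cost,
                    }
                )
            total_cost = sum(costs[s][0] for s in sd.SEXES)
            att_point = sum(
                point[f"{exposure}/{s}"] * costs[s][0] for s in sd.SEXES
            )
            att_draws = sum(att_draws_by_sex.values())
            att_lo, _, att_hi = _percentiles(att_draws, config.simulation.percentiles)
            rows.append(
                {
                    "scenario": scenario,
                    "exposure": exposure,
                    "sex": BOTH,
                    "projected_cost_usd": total_cost,
                    "cost_ci_lower": np.nan,
                    "cost_ci_upper": np.nan,
                    "pif": att_point / total_cost,
                    "pif_lower": att_lo / total_cost,
                    "pif_upper": att_hi / total_cost,
                    "savings_usd": att_point,
                    "savings_lower": att_lo,
                    "savings_upper": att_hi,
                }
            )
    return pd.DataFrame(rows)


def _usd(x: float) -> str:
    return f"{x:,.0f}"


def _pct(x: float) -> str:
    return f"{100 * x:.1f}"


def format_burden_table(df: pd.DataFrame) -> str:
    """Human-readable current/future burden table (percent to 1 decimal,
    costs to whole dollars)."""
    lines = []
    for period, sub in df.groupby("period", sort=True):
        cost_year = int(sub["cost_year"].iloc[0])
        lines.append(f"Exposure period {period} -> costs in {cost_year}")
        lines.append(
            f"{'exposure':<16}{'sex':<8}{'cost (US$)':>18}{'PIF %':>22}"
            f"{'attributable (US$)':>40}"
        )
        for _, r in sub.iterrows():
            pif_s = f"{_pct(r['pif'])} ({_pct(r['pif_lower'])} to {_pct(r['pif_upper'])})"
            att_s = (
                f"{_usd(r['attributable_usd'])} "
                f"({_usd(r['attributable_lower'])} to {_usd(r['attributable_upper'])})"
            )
            lines.append(
                f"{r['exposure']:<16}{r['sex']:<8}{_usd(r['cost_usd']):>18}"
                f"{pif_s:>22}{att_s:>40}"
            )
        lines.append("")
    return "\n".join(lines)


def format_scenario_table(df: pd.DataFrame) -> str:
    """Human-readable scenario-savings table."""
    lines = []
    proj = df[df["scenario"] == 0]
    lines.append("Projected costs (US$)")
    for _, r in proj.iterrows():
        ci = ""
        if np.isfinite(r["cost_ci_lower"]):
            ci = f" ({_usd(r['cost_ci_lower'])} to {_usd(r['cost_ci_upper'])})"
        lines.append(f"  {r['sex']:<8}{_usd(r['projected_cost_usd'])}{ci}")
    for scenario, sub in df[df["scenario"] > 0].groupby("scenario", sort=True):
        lines.append(f"Scenario {scenario}: potential savings (US$)")
        for _, r in sub.iterrows():
            lines.append(
                f"  {r['exposure']:<16}{r['sex']:<8}{_usd(r['savings_usd'])} "
                f"({_usd(r['savings_lower'])} to {_usd(r['savings_upper'])})"
            )
    lines.append("")
    return "\n".join(lines)
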
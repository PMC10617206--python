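"""Synthetic survey records, RR tables and cost series for the pipeline.

The dietary surveys, cost registries and supplementary RR tables behind
the published analysis are not shipped here; this module generates
statistically similar stand-ins so every pipeline stage is testable:

* **Consumption records** — usual intake in g/day per synthetic person.
  Red meat is lognormal (everyone consumes some in expectation); processed
  meat is zero-inflated lognormal (an explicit point mass at 0 g/day,
  matching the exactly-zero reference category).  Parameters are
  calibrated so the categorical tail marginals reproduce the published
  survey prevalences: two tails (P >= 70 and P >= 280 g/day) identify both
  lognormal parameters for red meat; for processed meat the zero mass plus
  the single printed tail (P >= 150 g/day) identify the zero-inflation and
  the meanlog at a fixed sdlog.
* **Cost series** — annual BRL costs following a linear trend plus
  Gaussian noise, with default slopes/intercepts anchored so the fitted
  2030 projection lands near the published US$ 450M both-sex total.
* **RR table** — dose-response RRs per 100 g/day (red) and 50 g/day
  (processed).  The packaged point estimates are synthetic placeholders
  (the published per-category RRs live in unpublished supplementary
  material); replace the CSV to run with other estimates.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CalibrationError, InvalidParameterError
from .relative_risk import (
    PROCESSED_MEAT,
    RED_MEAT,
    DoseResponseRR,
    load_rr_table,
)

__all__ = [
    "LognormalIntake",
    "SurveyGeneratorParams",
    "CostGeneratorParams",
    "calibrate_intake",
    "generate_survey",
    "generate_cost_series",
    "generate_rr_table",
    "null_rr_table",
    "default_survey_params",
    "default_cost_params",
    "load_calibration_targets",
    "PERIODS",
    "SEXES",
]

PERIODS = ("2008-2009", "2017-2018")
SEXES = ("male", "female")

_DATA = resources.files("meatcost.data")


@dataclass(frozen=True)
class LognormalIntake:
    """Zero-inflated lognormal usual-intake distribution (g/day).

    With probability ``zero_prob`` a person consumes exactly 0 g/day;
    otherwise intake is LogNormal(meanlog, sdlog).
    """

    meanlog: float
    sdlog: float
    zero_prob: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sdlog > 0):
            raise InvalidParameterError(f"sdlog must be > 0, got {self.sdlog}")
        if not (0.0 <= self.zero_prob <= 1.0):
            raise InvalidParameterError(
                f"zero_prob must be in [0, 1], got {self.zero_prob}"
            )

    def tail_prob(self, threshold: float) -> float:
        """P(intake >= threshold) for threshold > 0."""
        z = (np.log(threshold) - self.meanlog) / self.sdlog
        return float((1.0 - self.zero_prob) * stats.norm.sf(z))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        zero_mask = rng.random(n) < self.zero_prob
        values = rng.lognormal(self.meanlog, self.sdlog, n)
        values[zero_mask] = 0.0
        return values


def calibrate_intake(
    tail_targets: dict[float, float],
    zero_prob: float = 0.0,
    sdlog_default: float = 0.8,
) -> LognormalIntake:
    """Solve lognormal parameters from overall tail probabilities.

    ``tail_targets`` maps thresholds (g/day) to target P(intake >=
    threshold) over the whole population, zeros included.  Two targets
    identify (meanlog, sdlog) exactly; one target identifies meanlog at
    ``sdlog_default``.

    Raises
    ------
    CalibrationError
        Infeasible targets: tails not strictly decreasing in the
        threshold, a tail at least as large as the positive mass, or more
        than two targets.
    """
    if not (0.0 <= zero_prob <= 1.0):
        raise InvalidParameterError(f"zero_prob must be in [0, 1], got {zero_prob}")
    if zero_prob == 1.0:
        if any(t > 0 for t in tail_targets.values()):
            raise CalibrationError("zero_prob = 1 is incompatible with positive tails")
        return LognormalIntake(meanlog=0.0, sdlog=sdlog_default, zero_prob=1.0)
    items = sorted(tail_targets.items())
    positive = 1.0 - zero_prob
    for thr, q in items:
        if thr <= 0:
            raise InvalidParameterError(f"threshold must be positive, got {thr}")
        if not (0.0 < q < positive):
            raise CalibrationError(
                f"target P(>= {thr}) = {q} incompatible with positive mass {positive}"
            )
    if len(items) == 1:
        thr, q = items[0]
        z = stats.norm.isf(q / positive)
        return LognormalIntake(
            meanlog=float(np.log(thr) - sdlog_default * z),
            sdlog=sdlog_default,
            zero_prob=zero_prob,
        )
    if len(items) == 2:
        (t1, q1), (t2, q2) = items
        if q2 >= q1:
            raise CalibrationError(
                f"tail targets must decrease with the threshold: "
                f"P(>= {t1}) = {q1} vs P(>= {t2}) = {q2}"
            )
        z1 = stats.norm.isf(q1 / positive)
        z2 = stats.norm.isf(q2 / positive)
        sdlog = float((np.log(t2) - np.log(t1)) / (z2 - z1))
        meanlog = float(np.log(t1) - sdlog * z1)
        return LognormalIntake(meanlog=meanlog, sdlog=sdlog, zero_prob=zero_prob)
    raise CalibrationError(
        f"at most two tail targets are identifiable, got {len(items)}"
    )


@dataclass(frozen=True)
class SurveyGeneratorParams:
    """Parameters for one sex/period block of synthetic survey records."""

    sex: str
    period: str
    n_records: int
    red: LognormalIntake
    processed: LognormalIntake
    weight_cv: float = 0.0  # coefficient of variation of survey weights

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise InvalidParameterError("n_records must be >= 1")
        if self.weight_cv < 0:
            raise InvalidParameterError("weight_cv must be >= 0")


def generate_survey(
    params: SurveyGeneratorParams,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Synthetic consumption records for one sex/period.

    Columns: person_id, sex, red_g_day, processed_g_day, weight.
    Survey weights are 1 unless ``weight_cv > 0``, in which case they are
    gamma-distributed with mean 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.n_records
    red = params.red.sample(rng, n)
    processed = params.processed.sample(rng, n)
    if params.weight_cv > 0:
        shape = 1.0 / params.weight_cv**2
        weights = rng.gamma(shape, 1.0 / shape, n)
    else:
        weights = np.ones(n)
    return pd.DataFrame(
        {
            "person_id": [f"{params.period}-{params.sex}-{i:06d}" for i in range(n)],
            "sex": params.sex,
            "red_g_day": red,
            "processed_g_day": processed,
            "weight": weights,
        }
    )


@dataclass(frozen=True)
class CostGeneratorParams:
    """Linear-trend-plus-noise generator for an annual BRL cost series."""

    sex: str
    intercept_brl: float  # mean cost at base_year
    slope_brl_per_year: float
    noise_sd_brl: float = 0.0
    year_start: int = 2008
    year_end: int = 2019
    base_year: int = 2008

    def __post_init__(self) -> None:
        if self.noise_sd_brl < 0:
            raise InvalidParameterError("noise_sd_brl must be >= 0")
        if self.year_end < self.year_start:
            raise InvalidParameterError("year_end must be >= year_start")


def generate_cost_series(
    params: CostGeneratorParams,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Annual cost series: intercept + slope * (year - base) + noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    years = np.arange(params.year_start, params.year_end + 1)
    trend = params.intercept_brl + params.slope_brl_per_year * (years - params.base_year)
    noise = rng.normal(0.0, params.noise_sd_brl, years.size) if params.noise_sd_brl else 0.0
    cost = np.clip(trend + noise, 0.0, None)
    return pd.DataFrame({"year": years, "sex": params.sex, "cost_brl": cost})


def load_calibration_targets() -> dict:
    """Published categorical marginals used to calibrate the survey
    generator, keyed by period then sex."""
    with (_DATA / "survey_calibration.json").open() as fh:
        return json.load(fh)


def default_survey_params(
    period: str,
    sex: str,
    n_records: int | None = None,
    weight_cv: float = 0.0,
) -> SurveyGeneratorParams:
    """Survey generator parameters calibrated to the packaged marginals."""
    targets = load_calibration_targets()
    try:
        block = targets[period][sex]
    except KeyError:
        raise InvalidParameterError(
            f"no calibration targets for period={period!r}, sex={sex!r}"
        ) from None
    red = calibrate_intake(
        {float(k): float(v) for k, v in block["red"]["tail_targets"].items()}
    )
    proc_block = block["processed"]
    processed = calibrate_intake(
        {float(k): float(v) for k, v in proc_block["tail_targets"].items()},
        zero_prob=1.0 - float(proc_block["positive_prob"]),
        sdlog_default=float(proc_block.get("sdlog", 0.8)),
    )
    return SurveyGeneratorParams(
        sex=sex,
        period=period,
        n_records=int(n_records or block["n_records"]),
        red=red,
        processed=processed,
        weight_cv=weight_cv,
    )


def default_cost_params(sex: str) -> CostGeneratorParams:
    """Cost generator parameters for one sex from the packaged fixture."""
    with (_DATA / "cost_params.json").open() as fh:
        raw = json.load(fh)
    try:
        d = raw[sex]
    except KeyError:
        raise InvalidParameterError(f"no cost parameters for sex={sex!r}") from None
    return CostGeneratorParams(
        sex=sex,
        intercept_brl=float(d["intercept_brl"]),
        slope_brl_per_year=float(d["slope_brl_per_year"]),
        noise_sd_brl=float(d["noise_sd_brl"]),
        year_start=int(d.get("year_start", 2008)),
        year_end=int(d.get("year_end", 2019)),
        base_year=int(d.get("base_year", 2008)),
    )


def generate_rr_table() -> list[DoseResponseRR]:
    """Packaged synthetic-placeholder dose-response RR table."""
    with resources.as_file(_DATA / "rr_table.csv") as path:
        return load_rr_table(path)


def null_rr_table() -> list[DoseResponseRR]:
    """Null-effect RR table (all RRs 1 with degenerate CIs) for
    end-to-end zero-attribution checks."""
    return [
        DoseResponseRR(
            exposure=exposure,
            sex=sex,
            rr=1.0,
            ci_lower=1.0,
            ci_upper=1.0,
            increment=100.0 if exposure == RED_MEAT else 50.0,
        )
        for exposure in (RED_MEAT, PROCESSED_MEAT)
        for sex in SEXES
    ]
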
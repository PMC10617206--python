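"""Dose-response relative risks and their conversion to category risks.

Meta-analytic relative risks for colorectal cancer are reported per fixed
increment of intake (per 100 g/day for red meat, per 50 g/day for processed
meat).  The comparative risk assessment needs a relative risk per exposure
*category*, so the increment-scale RR is first converted to a per-gram RR

    RR_1 = exp(log(RR_x) / x)

and then raised to the distance between the category median ``M_c`` and the
reference exposure level ``ref``:

    RR_c = RR_1 ** (M_c - ref)

Uncertainty in the meta-analytic RR is propagated by sampling on the log
scale: ``log RR`` is treated as normal with standard deviation derived from
the reported 95% confidence interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = [
    "RED_MEAT",
    "PROCESSED_MEAT",
    "DoseResponseRR",
    "CategoryRR",
    "LogRRSampler",
    "rr_per_unit",
    "rr_for_category",
    "category_rrs",
    "log_rr_sampler",
    "load_rr_table",
    "rr_table_to_frame",
]

RED_MEAT = "red_meat"
PROCESSED_MEAT = "processed_meat"
EXPOSURES = (RED_MEAT, PROCESSED_MEAT)

#: 97.5th standard-normal quantile used to translate a 95% CI into a log-sd.
_Z95 = 1.96


@dataclass(frozen=True)
class DoseResponseRR:
    """Meta-analytic relative risk per fixed intake increment.

    Parameters
    ----------
    exposure:
        ``"red_meat"`` or ``"processed_meat"``.
    sex:
        ``"male"`` or ``"female"``.
    rr:
        Relative risk per ``increment`` g/day of intake.
    ci_lower, ci_upper:
        Bounds of the reported 95% confidence interval for ``rr``.
    increment:
        Size of the intake increment in g/day (100 for red meat, 50 for
        processed meat in the colorectal-cancer meta-analyses).
    """

    exposure: str
    sex: str
    rr: float
    ci_lower: float
    ci_upper: float
    increment: float

    def __post_init__(self) -> None:
        if not (self.rr > 0 and math.isfinite(self.rr)):
            raise InvalidParameterError(f"rr must be positive, got {self.rr}")
        if not (self.increment > 0):
            raise InvalidParameterError(
                f"increment must be positive g/day, got {self.increment}"
            )
        if self.ci_upper < self.ci_lower:
            raise InvalidParameterError(
                f"ci_upper {self.ci_upper} < ci_lower {self.ci_lower}"
            )
        if not (0 < self.ci_lower <= self.rr <= self.ci_upper):
            raise InvalidParameterError(
                f"CI ({self.ci_lower}, {self.ci_upper}) must bracket rr={self.rr}"
            )

    @property
    def log_sd(self) -> float:
        """Standard deviation of log(RR) implied by the 95% CI."""
        return (math.log(self.ci_upper) - math.log(self.ci_lower)) / (2 * _Z95)

    def per_unit(self) -> float:
        """RR per 1 g/day of intake."""
        return rr_per_unit(self.rr, self.increment)


@dataclass(frozen=True)
class CategoryRR:
    """Relative risk attached to one exposure category."""

    category_id: int
    rr: float

    def __post_init__(self) -> None:
        if not (self.rr > 0):
            raise InvalidParameterError(f"category RR must be positive, got {self.rr}")


def rr_per_unit(rr_x: float, x: float) -> float:
    """Convert an RR per ``x`` g/day increment into an RR per 1 g/day.

    Uses ``exp(log(rr_x) / x)``, the standard log-linear rescaling of a
    dose-response relative risk.

    Raises
    ------
    InvalidParameterError
        If ``rr_x`` or ``x`` is not strictly positive.
    """
    if not (rr_x > 0):
        raise InvalidParameterError(f"rr_x must be positive, got {rr_x}")
    if not (x > 0):
        raise InvalidParameterError(f"increment x must be positive, got {x}")
    return math.exp(math.log(rr_x) / x)


def rr_for_category(
    rr_1: float,
    median_c: float,
    ref: float,
    *,
    clamp_sub_reference: bool = True,
) -> float:
    """Relative risk for a category with median intake ``median_c``.

    ``rr_1 ** (median_c - ref)`` where ``ref`` is the reference exposure
    level (the theoretical-minimum-risk level).  Category medians below the
    reference are clamped to RR = 1 by default rather than extrapolating a
    protective effect the meta-analysis does not model; a warning is
    emitted when clamping occurs.
    """
    if not (rr_1 > 0):
        raise InvalidParameterError(f"rr_1 must be positive, got {rr_1}")
    if median_c < 0 or ref < 0:
        raise InvalidParameterError("median_c and ref must be non-negative g/day")
    exponent = median_c - ref
    if exponent < 0 and clamp_sub_reference:
        warnings.warn(
            f"category median {median_c} g/day below reference {ref} g/day; "
            "clamping RR to 1",
            stacklevel=2,
        )
        return 1.0
    return rr_1**exponent


def category_rrs(
    dose_rr: DoseResponseRR,
    medians: np.ndarray,
    ref: float,
) -> np.ndarray:
    """Vector of category RRs from one dose-response RR.

    ``medians`` may contain NaN for empty categories; those entries get
    RR = 1 (they carry zero prevalence mass downstream).  Sub-reference
    medians are clamped to RR = 1 without a warning (the reference band's
    own median is the reference value, so this is the expected case for
    the reference category itself).
    """
    rr_1 = dose_rr.per_unit()
    m = np.asarray(medians, dtype=float)
    exponents = np.where(np.isnan(m), 0.0, np.clip(m - ref, 0.0, None))
    return rr_1**exponents


@dataclass(frozen=True)
class LogRRSampler:
    """Lognormal sampler for a dose-response RR.

    Draws ``exp(Normal(mu, sigma))`` where ``mu = log(rr)`` and ``sigma``
    comes from the reported 95% CI.  The sample median converges to the
    point estimate ``rr``.  ``sigma == 0`` yields a degenerate sampler.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidParameterError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        if self.sigma == 0.0:
            if size is None:
                return np.float64(self.median)
            return np.full(size, self.median)
        return np.exp(rng.normal(self.mu, self.sigma, size=size))


def log_rr_sampler(dose_rr: DoseResponseRR) -> LogRRSampler:
    """Build the lognormal sampler for a :class:`DoseResponseRR`."""
    return LogRRSampler(mu=math.log(dose_rr.rr), sigma=dose_rr.log_sd)


_RR_COLUMNS = ["exposure", "sex", "rr", "ci_lower", "ci_upper", "increment_g_per_day"]


def load_rr_table(path) -> list[DoseResponseRR]:
    """Read a dose-response RR table from CSV.

    Expected columns: ``exposure, sex, rr, ci_lower, ci_upper,
    increment_g_per_day``.
    """
    df = pd.read_csv(path)
    missing = [c for c in _RR_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"RR table missing columns: {missing}")
    return [
        DoseResponseRR(
            exposure=row.exposure,
            sex=row.sex,
            rr=float(row.rr),
            ci_lower=float(row.ci_lower),
            ci_upper=float(row.ci_upper),
            increment=float(row.increment_g_per_day),
        )
        for row in df.itertuples()
    ]


def rr_table_to_frame(table: list[DoseResponseRR]) -> pd.DataFrame:
    """Serialize a list of dose-response RRs back to the CSV schema."""
    return pd.DataFrame(
        [
            {
                "exposure": d.exposure,
                "sex": d.sex,
                "rr": d.rr,
                "ci_lower": d.ci_lower,
                "ci_upper": d.ci_upper,
                "increment_g_per_day": d.increment,
            }
            for d in table
        ]
    )
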
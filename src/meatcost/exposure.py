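"""Consumption records, category schemes, prevalence and counterfactuals.

Individual-level meat consumption (g/day, one usual-intake value per
person) is categorized into ordered bands.  Red meat uses bands
``<70, [70,140), [140,210), [210,280), >=280`` g/day with ``<70`` as the
reference (theoretical-minimum-risk) band; processed meat uses
``{0}, (0,50), [50,100), [100,150), >=150`` with exactly-zero consumption
as the reference.

Counterfactual scenarios are applied at the record level and then
re-categorized:

* Scenario 1 subtracts one weekly serving (120 g/week red, 50 g/week
  processed), i.e. ``reduction/7`` g/day per person floored at zero.
* Scenarios 2-4 cap consumption at a band boundary (red 140/210/280,
  processed 50/100/150 g/day); everyone at or above the cap is moved to
  the median of the highest band strictly below the cap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    EmptyInputError,
    InvalidParameterError,
)
from .relative_risk import PROCESSED_MEAT, RED_MEAT

__all__ = [
    "ExposureCategoryScheme",
    "PrevalenceVector",
    "RED_MEAT_SCHEME",
    "PROCESSED_MEAT_SCHEME",
    "DEFAULT_SCHEMES",
    "SCENARIO_IDS",
    "RECORD_COLUMNS",
    "value_column",
    "categorize",
    "apply_serving_reduction",
    "apply_cap",
    "scenario_prevalences",
    "weighted_median",
    "load_schemes",
    "validate_records",
]

#: CSV schema for individual-level consumption records.
RECORD_COLUMNS = ["person_id", "sex", "red_g_day", "processed_g_day", "weight"]

_VALUE_COLUMNS = {RED_MEAT: "red_g_day", PROCESSED_MEAT: "processed_g_day"}

SCENARIO_IDS = (1, 2, 3, 4)

#: g/day caps per scenario id for the cap scenarios (2-4).
SCENARIO_CAPS = {
    2: {RED_MEAT: 140.0, PROCESSED_MEAT: 50.0},
    3: {RED_MEAT: 210.0, PROCESSED_MEAT: 100.0},
    4: {RED_MEAT: 280.0, PROCESSED_MEAT: 150.0},
}

#: Scenario 1 weekly serving reductions in g/week.
SCENARIO1_REDUCTIONS = {RED_MEAT: 120.0, PROCESSED_MEAT: 50.0}


def value_column(exposure: str) -> str:
    """Record column carrying the g/day values for an exposure."""
    try:
        return _VALUE_COLUMNS[exposure]
    except KeyError:
        raise InvalidParameterError(f"unknown exposure {exposure!r}") from None


@dataclass(frozen=True)
class ExposureCategoryScheme:
    """Ordered consumption bands for one exposure.

    Parameters
    ----------
    exposure:
        Which exposure the bands apply to.
    boundaries:
        Strictly increasing interior cut-points in g/day.  With
        ``zero_band=False`` the bands are
        ``[0, b0), [b0, b1), ..., [b_last, inf)``; with ``zero_band=True``
        an extra first band holds exactly-zero consumption and the bands
        are ``{0}, (0, b0), [b0, b1), ..., [b_last, inf)``.
    zero_band:
        Whether the reference band is exactly-zero consumption (processed
        meat) rather than the lowest interval (red meat).
    medians:
        Optional fixed per-band medians M_c in g/day; when omitted,
        :func:`categorize` estimates them from the records.
    reference_index:
        Index of the reference (theoretical-minimum-risk) band; always the
        lowest band here.
    """

    exposure: str
    boundaries: tuple[float, ...]
    zero_band: bool = False
    medians: tuple[float, ...] | None = None
    reference_index: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.size == 0:
            raise InvalidParameterError("scheme needs at least one boundary")
        if np.any(b <= 0) or np.any(np.diff(b) <= 0):
            raise InvalidParameterError(
                f"boundaries must be positive and strictly increasing, got {self.boundaries}"
            )
        if self.reference_index != 0:
            raise InvalidParameterError("reference band must be the lowest band")
        if self.medians is not None:
            if len(self.medians) != self.n_categories:
                raise InvalidParameterError(
                    f"expected {self.n_categories} medians, got {len(self.medians)}"
                )
            lo, hi = self._band_edges()
            for i, m in enumerate(self.medians):
                if not (lo[i] <= m <= hi[i]):
                    raise InvalidParameterError(
                        f"median {m} outside band {i} [{lo[i]}, {hi[i]})"
                    )

    @property
    def n_categories(self) -> int:
        return len(self.boundaries) + (2 if self.zero_band else 1)

    def _band_edges(self) -> tuple[np.ndarray, np.ndarray]:
        b = list(self.boundaries)
        if self.zero_band:
            lo = [0.0, 0.0] + b[:-1]
            hi = [0.0] + b + [np.inf]
        else:
            lo = [0.0] + b[:-1]
            hi = b + [np.inf]
        return np.asarray(lo), np.asarray(hi)

    @property
    def labels(self) -> list[str]:
        b = [f"{v:g}" for v in self.boundaries]
        if self.zero_band:
            bands = ["0", f"(0,{b[0]})"]
            bands += [f"[{b[i]},{b[i + 1]})" for i in range(len(b) - 1)]
        else:
            bands = [f"<{b[0]}"]
            bands += [f"[{b[i]},{b[i + 1]})" for i in range(len(b) - 1)]
        bands.append(f">={b[-1]}")
        return bands

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Category index for each g/day value."""
        v = np.asarray(values, dtype=float)
        if v.size and (not np.all(np.isfinite(v)) or np.any(v < 0)):
            raise InvalidParameterError(
                "consumption values must be finite and non-negative"
            )
        idx = np.searchsorted(np.asarray(self.boundaries), v, side="right")
        if self.zero_band:
            idx = np.where(v == 0.0, 0, idx + 1)
        return idx


RED_MEAT_SCHEME = ExposureCategoryScheme(
    exposure=RED_MEAT, boundaries=(70.0, 140.0, 210.0, 280.0), zero_band=False
)
PROCESSED_MEAT_SCHEME = ExposureCategoryScheme(
    exposure=PROCESSED_MEAT, boundaries=(50.0, 100.0, 150.0), zero_band=True
)
DEFAULT_SCHEMES = {RED_MEAT: RED_MEAT_SCHEME, PROCESSED_MEAT: PROCESSED_MEAT_SCHEME}


def load_schemes(path) -> dict[str, ExposureCategoryScheme]:
    """Load category schemes from a JSON file.

    The JSON maps exposure name to an object with keys ``boundaries``,
    optional ``zero_band``, optional ``medians``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    schemes = {}
    for exposure, d in raw.items():
        schemes[exposure] = ExposureCategoryScheme(
            exposure=exposure,
            boundaries=tuple(float(x) for x in d["boundaries"]),
            zero_band=bool(d.get("zero_band", False)),
            medians=tuple(float(x) for x in d["medians"]) if d.get("medians") else None,
        )
    return schemes


@dataclass(frozen=True)
class PrevalenceVector:
    """Per-category population proportions for one exposure stratum.

    ``p`` sums to one; ``n_effective`` is the effective sample size
    (Kish's (sum w)^2 / sum w^2) used for binomial uncertainty draws;
    ``medians`` are the empirical within-band medians M_c (NaN for empty
    bands).
    """

    exposure: str
    sex: str
    period: str
    p: np.ndarray
    n_effective: float | None = None
    medians: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if np.any(p < 0):
            raise InvalidParameterError("prevalence proportions must be >= 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise InvalidParameterError(
                f"prevalence proportions must sum to 1, got {p.sum()!r}"
            )
        if self.medians is not None:
            m = np.asarray(self.medians, dtype=float)
            if m.shape != p.shape:
                raise AlignmentError("medians and p must have the same length")
            object.__setattr__(self, "medians", m)

    @property
    def n_categories(self) -> int:
        return self.p.size

    def check_aligned(self, other: "PrevalenceVector | np.ndarray") -> np.ndarray:
        q = other.p if isinstance(other, PrevalenceVector) else np.asarray(other, float)
        if q.shape != self.p.shape:
            raise AlignmentError(
                f"category mismatch: {self.p.shape} vs {q.shape}"
            )
        return q


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weight-based median: smallest value whose cumulative weight reaches
    half the total."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        return float("nan")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check the record schema and value domains; returns the frame."""
    missing = [c for c in ("red_g_day", "processed_g_day") if c not in records.columns]
    if missing:
        raise InvalidParameterError(f"records missing columns: {missing}")
    for col in ("red_g_day", "processed_g_day"):
        v = records[col].to_numpy(dtype=float)
        if v.size and (not np.all(np.isfinite(v)) or np.any(v < 0)):
            raise InvalidParameterError(f"{col} must be finite and non-negative")
    if "weight" in records.columns and np.any(records["weight"].to_numpy(float) <= 0):
        raise InvalidParameterError("survey weights must be positive")
    return records


def _weights(records: pd.DataFrame) -> np.ndarray:
    if "weight" in records.columns:
        return records["weight"].to_numpy(dtype=float)
    return np.ones(len(records))


def categorize(
    records: pd.DataFrame,
    scheme: ExposureCategoryScheme,
    *,
    sex: str = "all",
    period: str = "",
) -> PrevalenceVector:
    """Weighted per-band prevalence (and empirical medians) of a record set.

    Raises
    ------
    EmptyInputError
        If ``records`` is empty.
    """
    if len(records) == 0:
        raise EmptyInputError("cannot categorize an empty record set")
    validate_records(records)
    values = records[value_column(scheme.exposure)].to_numpy(dtype=float)
    w = _weights(records)
    idx = scheme.assign(values)
    k = scheme.n_categories
    p = np.zeros(k)
    np.add.at(p, idx, w)
    p = p / p.sum()
    medians = np.full(k, np.nan)
    for c in range(k):
        mask = idx == c
        if mask.any():
            medians[c] = weighted_median(values[mask], w[mask])
        elif scheme.medians is not None:
            medians[c] = scheme.medians[c]
    n_eff = float(w.sum() ** 2 / np.sum(w**2))
    return PrevalenceVector(
        exposure=scheme.exposure,
        sex=sex,
        period=period,
        p=p,
        n_effective=n_eff,
        medians=medians,
    )


def apply_serving_reduction(
    records: pd.DataFrame,
    red_reduction_g_week: float = 0.0,
    processed_reduction_g_week: float = 0.0,
) -> pd.DataFrame:
    """Reduce every record's intake by a weekly amount, spread over 7 days.

    Daily consumption drops by ``reduction / 7`` g/day, floored at zero.
    Returns a new frame; the input is not modified.
    """
    if red_reduction_g_week < 0 or processed_reduction_g_week < 0:
        raise InvalidParameterError("serving reductions must be non-negative")
    out = records.copy()
    out["red_g_day"] = np.clip(
        out["red_g_day"].to_numpy(float) - red_reduction_g_week / 7.0, 0.0, None
    )
    out["processed_g_day"] = np.clip(
        out["processed_g_day"].to_numpy(float) - processed_reduction_g_week / 7.0,
        0.0,
        None,
    )
    return out


def apply_cap(
    records: pd.DataFrame,
    exposure: str,
    cap: float,
    scheme: ExposureCategoryScheme,
) -> pd.DataFrame:
    """Cap one exposure at a scheme boundary.

    Every record with consumption >= ``cap`` is reassigned to the median
    of the highest band strictly below the cap (the empirical weighted
    median of the records already in that band, falling back to the
    scheme's fixed median, then to the band midpoint when the band is
    empty).  Records below the cap are unchanged.
    """
    if cap not in scheme.boundaries:
        raise InvalidParameterError(
            f"cap {cap} is not one of the scheme boundaries {scheme.boundaries}"
        )
    col = value_column(exposure)
    values = records[col].to_numpy(dtype=float)
    w = _weights(records)
    idx = scheme.assign(values)
    # Highest band strictly below the cap: the band whose upper edge is cap.
    target_band = scheme.assign(np.array([cap]))[0] - 1
    in_target = idx == target_band
    if in_target.any():
        target_value = weighted_median(values[in_target], w[in_target])
    elif scheme.medians is not None:
        target_value = float(scheme.medians[target_band])
    else:
        lo, hi = scheme._band_edges()
        upper = hi[target_band] if np.isfinite(hi[target_band]) else cap
        target_value = 0.5 * (lo[target_band] + upper)
    out = records.copy()
    out[col] = np.where(values >= cap, target_value, values)
    return out


def _counterfactual_records(
    records: pd.DataFrame,
    scenario_id: int,
    schemes: dict[str, ExposureCategoryScheme],
) -> pd.DataFrame:
    if scenario_id == 1:
        return apply_serving_reduction(
            records,
            red_reduction_g_week=SCENARIO1_REDUCTIONS[RED_MEAT],
            processed_reduction_g_week=SCENARIO1_REDUCTIONS[PROCESSED_MEAT],
        )
    caps = SCENARIO_CAPS[scenario_id]
    out = records
    for exposure, cap in caps.items():
        out = apply_cap(out, exposure, cap, schemes[exposure])
    return out


def scenario_prevalences(
    baseline_records: pd.DataFrame,
    scenario_id: int,
    schemes: dict[str, ExposureCategoryScheme] | None = None,
    *,
    sex: str = "all",
    period: str = "",
) -> dict[str, tuple[PrevalenceVector, PrevalenceVector]]:
    """Baseline and counterfactual prevalence vectors for one scenario.

    Applies the scenario transform at the record level, re-categorizes,
    and returns ``{exposure: (P, P')}`` on the same scheme.  The
    counterfactual vector reuses the baseline band medians so both share
    one set of category RRs.
    """
    if scenario_id not in SCENARIO_IDS:
        raise InvalidParameterError(
            f"unknown scenario id {scenario_id}; expected one of {SCENARIO_IDS}"
        )
    if len(baseline_records) == 0:
        raise EmptyInputError("cannot build scenario prevalences from no records")
    schemes = dict(DEFAULT_SCHEMES if schemes is None else schemes)
    cf_records = _counterfactual_records(baseline_records, scenario_id, schemes)
    out: dict[str, tuple[PrevalenceVector, PrevalenceVector]] = {}
    for exposure, scheme in schemes.items():
        p = categorize(baseline_records, scheme, sex=sex, period=period)
        p_cf = categorize(cf_records, scheme, sex=sex, period=period)
        p_cf = replace(p_cf, medians=p.medians)
        out[exposure] = (p, p_cf)
    return out
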
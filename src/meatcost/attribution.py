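"""Potential impact fractions, joint fractions and attributable costs.

The potential impact fraction (PIF) contrasts an observed categorical
exposure distribution ``P`` with a counterfactual distribution ``P'``
under shared category relative risks ``RR``:

    PIF = (sum_i P_i RR_i - sum_i P'_i RR_i) / sum_i P_i RR_i

The population attributable fraction (PAF) is the PIF whose counterfactual
puts everyone at the theoretical-minimum-risk level (the reference
category).  Fractions for several exposures combine multiplicatively under
a no-interaction assumption:

    joint PIF = 1 - prod_i (1 - PIF_i)

Attributable cost is PIF times the total disease cost.  Negative fractions
(possible when a counterfactual raises exposure, or in Monte Carlo draws)
are truncated to zero wherever burden or savings are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import (
    AggregationError,
    AlignmentError,
    InvalidParameterError,
)
from .exposure import PrevalenceVector

__all__ = [
    "AttributionResult",
    "pif",
    "paf",
    "joint_pif",
    "truncate_pif",
    "attributable_cost",
    "combine_sexes",
    "savings",
]

_SUM_TOL = 1e-6


def _as_probs(p) -> np.ndarray:
    arr = p.p if isinstance(p, PrevalenceVector) else np.asarray(p, dtype=float)
    if np.any(arr < 0):
        raise InvalidParameterError("prevalence proportions must be >= 0")
    if abs(arr.sum() - 1.0) > _SUM_TOL:
        raise InvalidParameterError(
            f"prevalence proportions must sum to 1, got {arr.sum()!r}"
        )
    return arr


def _as_rrs(rr, k: int) -> np.ndarray:
    seq = rr if isinstance(rr, np.ndarray) else list(rr)
    if len(seq) and hasattr(seq[0], "rr"):
        seq = [c.rr for c in seq]
    arr = np.asarray(seq, dtype=float)
    if arr.shape != (k,):
        raise AlignmentError(f"expected {k} category RRs, got shape {arr.shape}")
    if np.any(arr <= 0):
        raise InvalidParameterError("category RRs must be positive")
    return arr


def pif(p, p_prime, rr) -> float:
    """Potential impact fraction for one exposure.

    Parameters may be :class:`~meatcost.exposure.PrevalenceVector` or raw
    proportion arrays; ``rr`` is a per-category RR array (or CategoryRR
    list) aligned on the same bands.  The result can be negative when the
    counterfactual increases exposure; callers decide whether to truncate.
    """
    p_arr = _as_probs(p)
    q_arr = _as_probs(p_prime)
    if q_arr.shape != p_arr.shape:
        raise AlignmentError(
            f"baseline and counterfactual category counts differ: "
            f"{p_arr.shape} vs {q_arr.shape}"
        )
    r = _as_rrs(rr, p_arr.size)
    s_obs = float(p_arr @ r)
    s_cf = float(q_arr @ r)
    return (s_obs - s_cf) / s_obs


def paf(p, rr, reference_index: int = 0) -> float:
    """Population attributable fraction: PIF against the all-in-reference
    counterfactual."""
    p_arr = _as_probs(p)
    if isinstance(p, PrevalenceVector):
        reference_index = 0  # reference band is always the lowest band
    p_ref = np.zeros_like(p_arr)
    p_ref[reference_index] = 1.0
    return pif(p_arr, p_ref, rr)


def joint_pif(pifs: Iterable[float]) -> float:
    """Combine per-exposure fractions assuming no interaction:
    ``1 - prod(1 - PIF_i)``."""
    values = np.asarray(list(pifs), dtype=float)
    if values.size == 0:
        return 0.0
    if np.any(values > 1):
        raise InvalidParameterError("a PIF cannot exceed 1")
    return float(1.0 - np.prod(1.0 - values))


def truncate_pif(value: float) -> float:
    """Round negative fractions up to zero (no protective attribution)."""
    return max(0.0, value)


def attributable_cost(
    pif_value: float, cost: float, *, pif_percent_decimals: int | None = None
) -> float:
    """Attributable cost = PIF x total cost.

    ``pif_percent_decimals`` optionally rounds the fraction, expressed in
    percent, to that many decimals before multiplying — the convention
    used when reproducing published tables whose costs were derived from
    percentages printed to one decimal.
    """
    if cost < 0:
        raise InvalidParameterError(f"cost must be non-negative, got {cost}")
    if pif_value > 1:
        raise InvalidParameterError("a PIF cannot exceed 1")
    if pif_percent_decimals is not None:
        pif_value = round(100.0 * pif_value, pif_percent_decimals) / 100.0
    return pif_value * cost


@dataclass(frozen=True)
class AttributionResult:
    """PIF and attributable cost for one exposure/sex stratum.

    ``pif_ui`` and ``attributable_ui`` are (2.5th, 97.5th) percentile
    uncertainty intervals when a Monte Carlo run produced them.
    """

    exposure: str
    sex: str
    cost: float
    pif: float
    attributable_cost: float
    pif_ui: tuple[float, float] | None = None
    attributable_ui: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.pif > 1:
            raise InvalidParameterError("a PIF cannot exceed 1")
        if self.cost < 0 or self.attributable_cost < 0:
            raise InvalidParameterError("costs must be non-negative")


def combine_sexes(
    results: Mapping[str, AttributionResult],
    sexes: Sequence[str] = ("male", "female"),
) -> AttributionResult:
    """Aggregate sex-specific attribution into a both-sex result.

    Attributable cost adds across sexes; the combined PIF is
    cost-weighted (summed attributable cost over summed cost).
    Uncertainty intervals, when present for every sex, add across sexes
    on the cost scale and are re-expressed as fractions of the summed
    cost — a conservative convention; per-draw both-sex intervals come
    from the Monte Carlo layer instead.
    """
    missing = [s for s in sexes if s not in results]
    if missing:
        raise AggregationError(f"missing sex strata: {missing}")
    parts = [results[s] for s in sexes]
    exposures = {r.exposure for r in parts}
    if len(exposures) != 1:
        raise AggregationError(f"cannot combine across exposures: {exposures}")
    total_cost = sum(r.cost for r in parts)
    total_attr = sum(r.attributable_cost for r in parts)
    if any(r.attributable_ui is None for r in parts):
        attr_ui = None
        pif_ui = None
    else:
        attr_ui = (
            sum(r.attributable_ui[0] for r in parts),
            sum(r.attributable_ui[1] for r in parts),
        )
        pif_ui = (attr_ui[0] / total_cost, attr_ui[1] / total_cost)
    return AttributionResult(
        exposure=exposures.pop(),
        sex="both",
        cost=total_cost,
        pif=total_attr / total_cost if total_cost > 0 else 0.0,
        attributable_cost=total_attr,
        pif_ui=pif_ui,
        attributable_ui=attr_ui,
    )


def savings(p_baseline, p_scenario, rr, projected_cost: float) -> float:
    """Cost saved under a counterfactual scenario: truncated PIF times the
    projected cost."""
    if projected_cost < 0:
        raise InvalidParameterError(
            f"projected cost must be non-negative, got {projected_cost}"
        )
    return truncate_pif(pif(p_baseline, p_scenario, rr)) * projected_cost
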
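"""Monte Carlo propagation of prevalence and RR uncertainty into PIF.

Each iteration draws (a) the baseline prevalence vector, category by
category from a binomial distribution with the stratum's effective sample
size, renormalized to sum to one, and (b) the log of the dose-response RR
from a normal distribution whose spread comes from the reported 95% CI.
Category RRs are recomputed from the single RR draw (one draw per exposure
per iteration, so the dose-response stays coherent across bands), the PIF
is re-evaluated against the fixed counterfactual vector, and negative
draws are truncated to zero.  Summaries report the 2.5th / 50th / 97.5th
percentiles (linear interpolation between order statistics).

A Dirichlet alternative to the per-category binomial draw is available via
``prevalence_draw_mode="dirichlet"``; it respects the sum-to-one constraint
by construction instead of renormalizing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


from .exceptions import (
    ConfigurationError,
    EmptyInputError,
    InvalidParameterError,
)
from .exposure import PrevalenceVector
from .relative_risk import DoseResponseRR, log_rr_sampler

__all__ = [
    "SimulationConfig",
    "PIFStratum",
    "DrawMatrix",
    "draw_prevalence",
    "run_monte_carlo",
    "joint_draws",
    "summarize",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo settings.

    ``n_iterations`` defaults to 10,000 draws; ``percentiles`` are the
    reported summary quantiles (central estimate is the middle one).
    """

    n_iterations: int = 10_000
    seed: int | None = None
    percentiles: tuple[float, float, float] = (2.5, 50.0, 97.5)
    prevalence_draw_mode: str = "binomial"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise InvalidParameterError("n_iterations must be >= 1")
        if list(self.percentiles) != sorted(self.percentiles):
            raise InvalidParameterError("percentiles must be ordered")
        if self.prevalence_draw_mode not in ("binomial", "dirichlet"):
            raise InvalidParameterError(
                f"unknown prevalence_draw_mode {self.prevalence_draw_mode!r}"
            )


@dataclass(frozen=True)
class PIFStratum:
    """One exposure/sex stratum of the Monte Carlo input.

    ``baseline`` carries the observed prevalence (with effective sample
    size and band medians); ``counterfactual`` is the fixed P' vector;
    ``ref`` is the reference exposure level in g/day used to turn the RR
    draw into category RRs.
    """

    exposure: str
    sex: str
    baseline: PrevalenceVector
    counterfactual: np.ndarray
    dose_rr: DoseResponseRR
    ref: float

    def __post_init__(self) -> None:
        cf = np.asarray(self.counterfactual, dtype=float)
        object.__setattr__(self, "counterfactual", cf)
        self.baseline.check_aligned(cf)
        if self.baseline.medians is None:
            raise ConfigurationError(
                f"stratum {self.key}: baseline prevalence lacks band medians"
            )

    @property
    def key(self) -> str:
        return f"{self.exposure}/{self.sex}"

    def category_rr_matrix(self, rr_x_draws: np.ndarray) -> np.ndarray:
        """(n_draws, k) category RRs from per-increment RR draws."""
        m = np.asarray(self.baseline.medians, dtype=float)
        exponents = np.where(np.isnan(m), 0.0, np.clip(m - self.ref, 0.0, None))
        rr_1 = np.exp(np.log(rr_x_draws) / self.dose_rr.increment)
        return rr_1[:, None] ** exponents[None, :]

    def point_pif(self) -> float:
        """Deterministic PIF at the central RR and observed prevalence."""
        rrc = self.category_rr_matrix(np.array([self.dose_rr.rr]))[0]
        s_obs = float(self.baseline.p @ rrc)
        s_cf = float(self.counterfactual @ rrc)
        return (s_obs - s_cf) / s_obs


@dataclass(frozen=True)
class DrawMatrix:
    """Per-iteration truncated PIF draws, one column per stratum."""

    draws: np.ndarray  # (n_iterations, n_strata)
    keys: tuple[str, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.draws, dtype=float)
        object.__setattr__(self, "draws", d)
        if d.ndim != 2 or d.shape[1] != len(self.keys):
            raise InvalidParameterError("draws must be (n_iterations, n_strata)")
        if d.size and (d.min() < 0 or d.max() > 1):
            raise InvalidParameterError("truncated PIF draws must lie in [0, 1]")

    @property
    def n_iterations(self) -> int:
        return self.draws.shape[0]

    def column(self, key: str) -> np.ndarray:
        return self.draws[:, self.keys.index(key)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=list(self.keys))


def draw_prevalence(
    p: PrevalenceVector,
    rng: np.random.Generator,
    mode: str = "binomial",
    size: int | None = None,
) -> np.ndarray:
    """Sample prevalence vectors around ``p``.

    ``binomial`` draws each category count as Binomial(n_effective, p_i)
    and renormalizes; ``dirichlet`` draws from Dirichlet(n_effective * p).
    ``n_effective = inf`` (or boundary proportions 0/1) gives degenerate
    draws at ``p`` itself.  Returns shape (k,) or (size, k).
    """
    if p.n_effective is None:
        raise ConfigurationError(
            "prevalence vector has no effective sample size for binomial draws"
        )
    n_draws = 1 if size is None else size
    if math.isinf(p.n_effective):
        out = np.tile(p.p, (n_draws, 1))
        return out[0] if size is None else out

    n = int(round(p.n_effective))
    if mode == "binomial":
        counts = rng.binomial(n, p.p, size=(n_draws, p.p.size)).astype(float)
        totals = counts.sum(axis=1)
        # all-zero rows (possible at tiny n) fall back to the point estimate
        degenerate = totals == 0
        if degenerate.any():
            counts[degenerate] = p.p * n
            totals = counts.sum(axis=1)
        out = counts / totals[:, None]
    elif mode == "dirichlet":
        alpha = np.clip(p.p * n, 1e-12, None)
        out = rng.dirichlet(alpha, size=n_draws)
    else:
        raise InvalidParameterError(f"unknown prevalence draw mode {mode!r}")
    return out[0] if size is None else out


def run_monte_carlo(
    strata: list[PIFStratum],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> DrawMatrix:
    """Run the PIF Monte Carlo over all strata.

    Strata are processed in list order with a single generator, so a
    fixed seed reproduces the draw matrix bit for bit.  Negative PIF
    draws are truncated to zero.
    """
    if not strata:
        raise EmptyInputError("no strata to simulate")
    keys = [s.key for s in strata]
    if len(set(keys)) != len(keys):
        raise ConfigurationError(f"duplicate stratum keys: {keys}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_iter = config.n_iterations
    draws = np.empty((n_iter, len(strata)))
    for j, stratum in enumerate(strata):
        p_draws = draw_prevalence(
            stratum.baseline, rng, mode=config.prevalence_draw_mode, size=n_iter
        )
        rr_x = log_rr_sampler(stratum.dose_rr).sample(rng, size=n_iter)
        rr_c = stratum.category_rr_matrix(rr_x)
        s_obs = np.einsum("ik,ik->i", p_draws, rr_c)
        s_cf = rr_c @ stratum.counterfactual
        draws[:, j] = np.clip((s_obs - s_cf) / s_obs, 0.0, 1.0)
    return DrawMatrix(draws=draws, keys=tuple(keys))


def joint_draws(matrix: DrawMatrix, groups: dict[str, list[str]]) -> DrawMatrix:
    """Combine stratum draws within each group by the joint-PIF formula,
    iteration by iteration."""
    cols = []
    for name, members in groups.items():
        sub = np.column_stack([matrix.column(k) for k in members])
        cols.append(1.0 - np.prod(1.0 - sub, axis=1))
    return DrawMatrix(draws=np.column_stack(cols), keys=tuple(groups))


def summarize(matrix: DrawMatrix, config: SimulationConfig) -> pd.DataFrame:
    """Percentile summary per stratum.

    Returns a frame indexed by stratum key with one column per requested
    percentile (``p2.5``, ``p50``, ``p97.5`` by default), computed with
    linear interpolation between order statistics.
    """
    if matrix.draws.size == 0:
        raise EmptyInputError("cannot summarize an empty draw matrix")
    q = np.percentile(matrix.draws, list(config.percentiles), axis=0)
    return pd.DataFrame(
        q.T,
        index=list(matrix.keys),
        columns=[f"p{p:g}" for p in config.percentiles],
    )
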
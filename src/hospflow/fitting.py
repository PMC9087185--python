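"""Least-squares estimation of the model parameters from visit series.

The data are monthly visit volumes for the three hospital tiers,
reported January through November of each year (national statistics
include no December reports).  The fit minimises the pooled sum of
squared residuals over all tiers and months with a bounded
trust-region least-squares solver, optionally from multiple jittered
starting points.  The initial state of the trajectory is fixed to the
first observation triple rather than estimated.

Identifiability
---------------
The trajectory of the system depends on the twelve parameters only
through nine combinations: per tier the quadratic coefficient ``r/m``
and the net linear rate (``r_f - alpha - eta - c_f``,
``r_s - beta - c_s``, ``r_t - c_t``), plus the three transfer rates
``alpha``, ``beta``, ``eta`` which are pinned down by the cross-tier
coupling.  Within each tier, trading growth rate against churn rate
(and rescaling the capacity to keep ``r/m`` fixed) leaves the
trajectory exactly unchanged, so ``r``, ``c`` and ``m`` are not
separately identifiable from visit series alone.  Consequently a fit
can reproduce the data perfectly while disagreeing with the generating
values of ``r``, ``c`` and ``m`` individually; the combinations
returned by :func:`identifiable_combinations` are what the data
determine.  See the methods note for discussion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .params import PARAM_NAMES, ModelParams, VisitState
from .simulate import integrate

__all__ = [
    "ObservedSeries",
    "FitResult",
    "predict",
    "fit",
    "r_squared",
    "identifiable_combinations",
    "DEFAULT_SEED",
    "SchemaError",
]

#: Default seed for the multi-start jitter.
DEFAULT_SEED = 20220426

TIERS = ("FLH", "SLH", "TLH")


class SchemaError(ValueError):
    """An observed-series table violates the expected schema."""


@dataclass(frozen=True)
class ObservedSeries:
    """Monthly three-tier visit observations.

    ``times`` are months since the first observation (continuous
    model time; December is skipped in the data but time still
    advances through it), ``counts`` is ``(n, 3)`` in tier order
    (FLH, SLH, TLH), and ``years``/``months`` carry calendar labels.
    """

    times: np.ndarray
    counts: np.ndarray
    years: np.ndarray
    months: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        years = np.asarray(self.years, dtype=int)
        months = np.asarray(self.months, dtype=int)
        for name, arr in (("times", times), ("counts", counts),
                          ("years", years), ("months", months)):
            object.__setattr__(self, name, arr)
        if counts.shape != (times.size, 3):
            raise SchemaError(
                f"counts must have shape ({times.size}, 3), got {counts.shape}"
            )
        if np.any(np.diff(times) <= 0):
            raise SchemaError("observation times must be strictly increasing")
        if np.any(counts < 0):
            raise SchemaError("visit counts must be non-negative")

    @property
    def n_obs(self) -> int:
        """Total observation count (time points x 3 tiers)."""
        return int(self.counts.size)

    def initial_state(self) -> VisitState:
        return VisitState.from_array(self.counts[0])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservedSeries":
        """Build from a long-format table (year, month, tier, visits_10k)."""
        required = {"year", "month", "tier", "visits_10k"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"missing column(s): {sorted(missing)}")
        bad_tiers = set(df["tier"].unique()) - set(TIERS)
        if bad_tiers:
            raise SchemaError(
                f"unknown tier label(s) {sorted(bad_tiers)}; expected {TIERS}"
            )
        if df["month"].min() < 1 or df["month"].max() > 12:
            raise SchemaError("month must be in 1..12")
        if (df["visits_10k"] < 0).any():
            raise SchemaError("visits_10k must be non-negative")
        wide = df.pivot_table(
            index=["year", "month"], columns="tier", values="visits_10k"
        )
        if wide.isna().any().any():
            raise SchemaError("every (year, month) must report all three tiers")
        wide = wide.sort_index()
        years = wide.index.get_level_values("year").to_numpy()
        months = wide.index.get_level_values("month").to_numpy()
        t = 12.0 * (years - years[0]) + (months - months[0])
        counts = wide[list(TIERS)].to_numpy()
        return cls(times=t, counts=counts, years=years, months=months)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.times)):
            for j, tier in enumerate(TIERS):
                rows.append(
                    {
                        "year": int(self.years[i]),
                        "month": int(self.months[i]),
                        "tier": tier,
                        "visits_10k": float(self.counts[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservedSeries":
        # round_trip parsing so write-then-read is bit-exact
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares fit."""

    params: ModelParams
    sse: float
    r_squared: float
    r_squared_per_tier: tuple[float, float, float]
    n_obs: int
    converged: bool
    initial_state: VisitState
    n_starts: int
    start_costs: tuple[float, ...]  # best cost reached from each start
    guess_sse: float  # objective at the supplied initial guess


def predict(
    params: ModelParams, initial: VisitState, times: np.ndarray
) -> np.ndarray:
    """Model visit volumes at the observation times, ``(n, 3)``.

    Integration is continuous through any gaps in ``times`` (e.g. the
    missing December of each observation year).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 1:
        return initial.to_array()[None, :].copy()
    return integrate(params, initial, times).states


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pooled coefficient of determination ``1 - SSE/SST``.

    The total sum of squares is taken about the grand mean over all
    tier-time observations, matching the single pooled objective used
    by the fit.  Raises on constant data (SST = 0), where the
    statistic is undefined.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have matching shapes")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("R^2 undefined: observations are constant (SST = 0)")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


def identifiable_combinations(params: ModelParams) -> dict[str, float]:
    """The nine parameter combinations the trajectory determines.

    Per tier: the quadratic (crowding) coefficient ``r/m`` and the net
    linear rate; plus the three transfer rates.  Two parameter vectors
    with equal combinations generate identical trajectories from any
    initial state.
    """
    p = params
    return {
        "crowding_f": p.r_f / p.m_f,
        "crowding_s": p.r_s / p.m_s,
        "crowding_t": p.r_t / p.m_t,
        "net_rate_f": p.r_f - p.alpha - p.eta - p.c_f,
        "net_rate_s": p.r_s - p.beta - p.c_s,
        "net_rate_t": p.r_t - p.c_t,
        "alpha": p.alpha,
        "beta": p.beta,
        "eta": p.eta,
    }


def _default_bounds() -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for name in PARAM_NAMES:
        if name.startswith("m_"):
            lo.append(1e-6)
            hi.append(1e7)
        elif name in ("alpha", "beta", "eta"):
            lo.append(0.0)
            hi.append(5.0)
        else:
            lo.append(1e-8)
            hi.append(5.0)
    return np.array(lo), np.array(hi)


def fit(
    observed: ObservedSeries,
    init_guess: ModelParams,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 8,
    seed: int = DEFAULT_SEED,
    tier_weighting: bool = False,
    jitter_sd: float = 0.15,
) -> FitResult:
    """Estimate the twelve parameters by pooled least squares.

    Parameters
    ----------
    observed
        The visit series; at least 24 time points are required as an
        identifiability guard.
    init_guess
        Starting parameter vector; must lie within the bounds.
    bounds
        Optional per-parameter ``(low, high)`` intervals overriding
        the broad positivity defaults.
    n_starts
        Number of optimiser starts.  The first start is the guess
        itself; subsequent starts jitter the guess multiplicatively
        (log-normal, sd ``jitter_sd``) to escape local minima.  The
        best final objective wins.
    seed
        Seed for the jitter; the fit is deterministic given data,
        guess and seed.
    tier_weighting
        When true, residuals of each tier are scaled by the inverse
        standard deviation of that tier's observations, compensating
        the roughly ten-fold scale differences between tiers.  Off by
        default: the reference analysis pooled unweighted residuals.
    """
    if len(observed.times) < 24:
        raise ValueError(
            f"need >= 24 observation times to fit 12 parameters, "
            f"got {len(observed.times)}"
        )
    lo, hi = _default_bounds()
    if bounds:
        unknown = set(bounds) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter name(s) in bounds: {sorted(unknown)}")
        for name, (lo_v, hi_v) in bounds.items():
            i = PARAM_NAMES.index(name)
            lo[i], hi[i] = lo_v, hi_v
    guess = init_guess.to_array()
    if np.any(guess < lo) or np.any(guess > hi):
        raise ValueError("init_guess must lie within the bounds")

    initial = observed.initial_state()
    obs = observed.counts
    if tier_weighting:
        sd = obs.std(axis=0)
        sd[sd == 0] = 1.0
        w = 1.0 / sd
    else:
        w = np.ones(3)

    def residuals(vec: np.ndarray) -> np.ndarray:
        p = ModelParams.from_array(vec)
        pred = predict(p, initial, observed.times)
        return ((pred - obs) * w).ravel()

    def cost(vec: np.ndarray) -> float:
        r = residuals(vec)
        return float(r @ r)

    guess_sse = cost(guess)
    rng = np.random.default_rng(seed)
    starts = [guess]
    for _ in range(max(n_starts, 1) - 1):
        jitter = np.exp(rng.normal(0.0, jitter_sd, size=guess.size))
        starts.append(np.clip(guess * jitter, lo, hi))

    best = None
    start_costs: list[float] = []
    for start in starts:
        sol = least_squares(
            residuals,
            start,
            bounds=(lo, hi),
            method="trf",
            x_scale=np.maximum(np.abs(guess), 1e-12),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        start_costs.append(2.0 * float(sol.cost))
        if best is None or sol.cost < best.cost:
            best = sol

    est = ModelParams.from_array(best.x)
    pred = predict(est, initial, observed.times)
    sse = float(np.sum((pred - obs) ** 2))
    try:
        r2 = r_squared(obs, pred)
    except ValueError:
        import warnings

        warnings.warn("degenerate (constant) series: R^2 undefined, reported as nan")
        r2 = float("nan")
    per_tier = []
    for j in range(3):
        try:
            per_tier.append(r_squared(obs[:, j], pred[:, j]))
        except ValueError:
            per_tier.append(float("nan"))
    return FitResult(
        params=est,
        sse=sse,
        r_squared=r2,
        r_squared_per_tier=tuple(per_tier),
        n_obs=observed.n_obs,
        converged=bool(best.success),
        initial_state=initial,
        n_starts=len(starts),
        start_costs=tuple(start_costs),
        guess_sse=guess_sse,
    )
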
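"""Demographically stochastic projection of the female population.

Each annual step draws integer survivors and recruits:

    n1..n3(t) ~ Binomial(n_{i-1}(t-1), S_i)
    n4+(t)   ~ Binomial(n3(t-1), S_sa) + Binomial(n4+(t-1), P_a)
    n0(t)    ~ Poisson(n4+(t) x F)

Recruitment uses the *current-year* adult count — the adult classes are
updated first within a year, then hatchlings are drawn from the updated 4+
count.  Replicates run on independent substreams spawned from one master
seed, so a run is reproducible and insensitive to replicate order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PopulationState",
    "YearRates",
    "TrajectorySummary",
    "stable_initialization",
    "step",
    "project",
    "deterministic_projection",
    "rates_table",
    "rates_from_table",
]

N_CLASSES = 5


class ProjectionError(ValueError):
    pass


@dataclass(frozen=True)
class PopulationState:
    """Integer counts (n0, n1, n2, n3, n4plus) at a calendar year."""

    counts: tuple[int, ...]
    year: int

    def __post_init__(self) -> None:
        c = tuple(int(x) for x in self.counts)
        if len(c) != N_CLASSES or any(x < 0 for x in c):
            raise ProjectionError(f"counts must be 5 nonnegative integers, got {self.counts}")
        object.__setattr__(self, "counts", c)

    @property
    def adults(self) -> int:
        return self.counts[4]

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class YearRates:
    """Per-year transition rates: survivals (S1, S2, S3 into classes 1-3,
    S_sa into 4+, P_a within 4+) and fertility F."""

    S1: float
    S2: float
    S3: float
    S_sa: float
    P_a: float
    F: float

    def __post_init__(self) -> None:
        for name in ("S1", "S2", "S3", "S_sa", "P_a"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ProjectionError(f"{name} must be in [0, 1], got {v}")
        if self.F < 0:
            raise ProjectionError(f"F must be >= 0, got {self.F}")

    @property
    def survival_vector(self) -> np.ndarray:
        return np.array([self.S1, self.S2, self.S3, self.S_sa, self.P_a])


@dataclass
class TrajectorySummary:
    """Per-year replicate summaries of the adult (4+) female count."""

    years: list[int]
    adult_mean: np.ndarray
    adult_q025: np.ndarray
    adult_q975: np.ndarray
    replicates: int
    seed: int
    metadata: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "mean": self.adult_mean,
                "q025": self.adult_q025,
                "q975": self.adult_q975,
            }
        )


def stable_initialization(total: int, stable_age: np.ndarray, year: int = 0) -> PopulationState:
    """Split ``total`` individuals among classes by largest-remainder rounding
    of the stable age distribution, preserving the total exactly."""
    if total < 0:
        raise ProjectionError("total must be >= 0")
    w = np.asarray(stable_age, dtype=float)
    if w.shape != (N_CLASSES,) or np.any(w < 0):
        raise ProjectionError("stable_age must be a length-5 nonnegative vector")
    s = w.sum()
    if s <= 0:
        raise ProjectionError("stable_age must have positive mass")
    w = w / s
    raw = total * w
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    # distribute the remainder to the largest fractional parts; ties go to
    # the earlier class for determinism
    frac = raw - base
    order = np.lexsort((np.arange(N_CLASSES), -frac))
    base[order[:short]] += 1
    return PopulationState(tuple(base), year)


def step(state: PopulationState, rates: YearRates, rng: np.random.Generator) -> PopulationState:
    """One stochastic annual transition (see module docstring for the draws)."""
    n0, n1, n2, n3, n4 = state.counts
    m1 = rng.binomial(n0, rates.S1)
    m2 = rng.binomial(n1, rates.S2)
    m3 = rng.binomial(n2, rates.S3)
    m4 = rng.binomial(n3, rates.S_sa) + rng.binomial(n4, rates.P_a)
    m0 = rng.poisson(m4 * rates.F)
    return PopulationState((m0, m1, m2, m3, m4), state.year + 1)


def _validate_rates(yearly_rates: dict[int, YearRates], years_needed: list[int]) -> None:
    missing = [y for y in years_needed if y not in yearly_rates]
    if missing:
        raise ProjectionError(f"yearly rates missing for years {missing}")


def project(
    initial: PopulationState,
    yearly_rates: dict[int, YearRates],
    n_years: int,
    n_reps: int = 10_000,
    seed: int = 0,
    return_replicates: bool = False,
):
    """Replicate stochastic projection with per-year adult summaries.

    ``yearly_rates[y]`` supplies the rates governing the transition from
    year ``y`` to ``y + 1``.  Returns a :class:`TrajectorySummary` with the
    per-year mean and 2.5/97.5% quantiles of the adult (4+) count over
    replicates; with ``return_replicates=True`` also the full
    (n_reps, n_years + 1, 5) count array.
    """
    if n_reps < 1:
        raise ProjectionError("n_reps must be >= 1")
    transition_years = [initial.year + t for t in range(n_years)]
    _validate_rates(yearly_rates, transition_years)
    rates_seq = [yearly_rates[y] for y in transition_years]

    streams = np.random.SeedSequence(seed).spawn(n_reps)
    counts = np.empty((n_reps, n_years + 1, N_CLASSES), dtype=np.int64)
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        st = initial
        counts[r, 0] = st.counts
        for t, rates in enumerate(rates_seq):
            st = step(st, rates, rng)
            counts[r, t + 1] = st.counts
    adults = counts[:, :, 4]
    years = [initial.year + t for t in range(n_years + 1)]
    summary = TrajectorySummary(
        years=years,
        adult_mean=adults.mean(axis=0),
        adult_q025=np.quantile(adults, 0.025, axis=0),
        adult_q975=np.quantile(adults, 0.975, axis=0),
        replicates=n_reps,
        seed=seed,
        metadata={"initial": list(initial.counts)},
    )
    if return_replicates:
        return summary, counts
    return summary


def deterministic_projection(
    initial: PopulationState, yearly_rates: dict[int, YearRates], n_years: int
) -> np.ndarray:
    """Mean-field (expected-value) trajectory matching the stochastic update
    order: adults first, then recruitment from the updated adult count.
    Returns a (n_years + 1, 5) real array."""
    transition_years = [initial.year + t for t in range(n_years)]
    _validate_rates(yearly_rates, transition_years)
    out = np.zeros((n_years + 1, N_CLASSES))
    out[0] = initial.counts
    for t, y in enumerate(transition_years):
        r = yearly_rates[y]
        prev = out[t]
        nxt = np.zeros(N_CLASSES)
        nxt[1] = prev[0] * r.S1
        nxt[2] = prev[1] * r.S2
        nxt[3] = prev[2] * r.S3
        nxt[4] = prev[3] * r.S_sa + prev[4] * r.P_a
        nxt[0] = nxt[4] * r.F
        out[t + 1] = nxt
    return out


def rates_table(yearly_rates: dict[int, YearRates]) -> pd.DataFrame:
    """Flatten a yearly-rates mapping to the CSV layout
    ``year,S1,S2,S3,S_sa,P_a,F``."""
    rows = [
        {"year": y, "S1": r.S1, "S2": r.S2, "S3": r.S3, "S_sa": r.S_sa, "P_a": r.P_a, "F": r.F}
        for y, r in sorted(yearly_rates.items())
    ]
    return pd.DataFrame(rows)


def rates_from_table(df: pd.DataFrame) -> dict[int, YearRates]:
    return {
        int(row.year): YearRates(row.S1, row.S2, row.S3, row.S_sa, row.P_a, row.F)
        for row in df.itertuples()
    }
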
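"""Neutral mainland-to-island colonization model with an Allee extension.

A mainland community holds M species whose abundances (propagule
counts) are drawn from a log-normal distribution.  At each discrete
time step t, with probability P(t) a single propagule is translocated
to an island; the propagule's species is drawn with probability
proportional to mainland abundance (every propagule has the same chance
of travelling), and the mainland is an infinite source — sampling is
with replacement and mainland abundances never change.  With
probability 1 - P(t) nothing happens.

In the basic model one arriving propagule establishes its species.  The
Allee extension requires more than ``a`` propagules of the same species
to arrive within a trailing window of T steps before the species counts
as established (raising ``a`` is equivalent to shortening T, so T is
fixed — conventionally at 1,000 steps — and ``a`` varied).

Different temporal shapes of P(t) — constant, linear, exponential, or
proportional to a driver series such as import values or cumulative
botanic-garden foundations — are compared on an equal footing by
standardizing each schedule so the expected number of arriving
propagules over the whole run (the propagule budget, sum of P(t)) is
identical.

The basic model admits a closed-form expected richness, used as an
independent oracle in tests:  E[S(t)] = sum_i (1 - prod_{s<=t} (1 -
P(s) * p_i)) with p_i the relative abundance of species i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records_pipeline import RateSeries

__all__ = [
    "MainlandCommunity",
    "Schedule",
    "SimConfig",
    "SimResult",
    "build_mainland",
    "make_schedule",
    "simulate",
    "expected_richness_oracle",
]

SCHEDULE_SHAPES = ("constant", "linear", "exponential", "proportional")


@dataclass
class MainlandCommunity:
    """Source community: integer propagule count per species."""

    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=np.int64)
        if len(self.abundances) < 1 or np.any(self.abundances < 1):
            raise ValueError("abundances must be >= 1 for at least one species")

    @property
    def m_species(self) -> int:
        return len(self.abundances)

    @property
    def total_propagules(self) -> int:
        return int(self.abundances.sum())

    @property
    def relative_abundance(self) -> np.ndarray:
        return self.abundances / self.abundances.sum()


@dataclass
class Schedule:
    """Per-step introduction probability P(t), standardized to a budget."""

    p: np.ndarray
    shape: str
    budget: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("P(t) must lie in [0, 1]")
        if abs(self.p.sum() - self.budget) > 1e-9:
            raise ValueError("schedule not standardized to its budget")

    @property
    def n_steps(self) -> int:
        return len(self.p)


@dataclass
class SimConfig:
    """Replication and establishment settings for a simulation run."""

    seed: int = 0
    n_replicates: int = 1
    allee_threshold: int = 0  # a = 0 recovers the basic model
    window: int = 1000  # T, in simulation steps

    def __post_init__(self) -> None:
        if self.allee_threshold < 0:
            raise ValueError("allee_threshold must be >= 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SimResult:
    """Colonization trajectories over replicates."""

    establishment_steps: list[dict[int, int]]  # per replicate: species -> step
    richness: np.ndarray  # (n_replicates, n_steps) cumulative species counts
    config: SimConfig
    m_species: int

    @property
    def mean_richness(self) -> np.ndarray:
        return self.richness.mean(axis=0)

    def first_record_rate(self, bin_width: int, *, label: str = "") -> RateSeries:
        """Mean number of new establishments per bin of simulation steps."""
        n_steps = self.richness.shape[1]
        n_bins = int(np.ceil(n_steps / bin_width))
        counts = np.zeros(n_bins)
        for est in self.establishment_steps:
            if est:
                steps = np.fromiter(est.values(), dtype=np.int64)
                counts += np.bincount(steps // bin_width, minlength=n_bins)
        counts /= len(self.establishment_steps)
        return RateSeries(
            bin_start_years=bin_width * np.arange(n_bins),
            bin_width=bin_width,
            counts=counts,
            label=label,
            last_bin_partial=(n_bins * bin_width > n_steps),
        )


def build_mainland(
    m_species: int,
    meanlog: float = 2.0,
    sdlog: float = 1.0,
    seed: int = 0,
) -> MainlandCommunity:
    """Draw a log-normal mainland community.

    Per-species propagule counts are the ceiling of log-normal draws
    (location ``meanlog``, scale ``sdlog`` on the log scale), so every
    species has at least one propagule.
    """
    if m_species < 1:
        raise ValueError("m_species must be >= 1")
    if sdlog < 0:
        raise ValueError("sdlog must be >= 0")
    rng = np.random.default_rng(seed)
    draws = rng.lognormal(mean=meanlog, sigma=sdlog, size=m_species)
    return MainlandCommunity(np.ceil(draws).astype(np.int64))


def make_schedule(
    shape: str,
    n_steps: int,
    budget: float,
    *,
    growth_rate: float | None = None,
    driver: np.ndarray | None = None,
) -> Schedule:
    """Build an introduction-probability schedule with a fixed budget.

    ``budget`` is the expected total number of arriving propagules,
    sum of P(t); it cannot exceed ``n_steps``.  Shapes:

    - ``constant``: P identical at every step;
    - ``linear``: P proportional to t (1..n);
    - ``exponential``: P proportional to exp(growth_rate * t)
      (default growth_rate 5/n_steps, about a 150-fold rise);
    - ``proportional``: P follows ``driver`` (e.g. annual import values
      or cumulative botanic-garden foundations), linearly interpolated
      onto the simulation steps.

    After scaling to the budget, any P(t) > 1 is clipped and the
    remaining mass redistributed over unclipped steps until the budget
    is met within 1e-9.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if budget > n_steps:
        raise ValueError(
            f"budget {budget} exceeds n_steps {n_steps}: P(t) <= 1 unattainable"
        )
    if budget <= 0:
        raise ValueError("budget must be positive")
    t = np.arange(1, n_steps + 1, dtype=float)
    if shape == "constant":
        raw = np.ones(n_steps)
    elif shape == "linear":
        raw = t
    elif shape == "exponential":
        r = 5.0 / n_steps if growth_rate is None else growth_rate
        raw = np.exp(r * (t - 1))
    elif shape == "proportional":
        if driver is None:
            raise ValueError("proportional shape needs a driver series")
        driver = np.asarray(driver, dtype=float)
        if np.any(driver < 0) or driver.sum() <= 0:
            raise ValueError("driver must be non-negative with positive mass")
        raw = np.interp(
            np.linspace(0.0, 1.0, n_steps),
            np.linspace(0.0, 1.0, len(driver)),
            driver,
        )
    else:
        raise ValueError(f"unknown schedule shape '{shape}'")

    p = raw * (budget / raw.sum())
    # iterative clip-and-rescale: clipped steps stay at 1, the shortfall
    # is spread proportionally over the rest
    for _ in range(10_000):
        over = p > 1.0
        if not np.any(over):
            break
        p = np.minimum(p, 1.0)
        free = ~over
        shortfall = budget - p[over].sum()
        if shortfall <= 0 or not np.any(free):
            break
        p[free] *= shortfall / p[free].sum()
    if abs(p.sum() - budget) > 1e-9:
        raise RuntimeError("schedule standardization did not converge")
    return Schedule(p=p, shape=shape, budget=float(budget))


def _establishments(
    arrival_steps: np.ndarray,
    species: np.ndarray,
    allee_threshold: int,
    window: int,
) -> dict[int, int]:
    """Establishment step per species from an arrival log.

    With threshold a = 0 a species establishes on its first arrival.
    With a > 0 it establishes at the first step where more than ``a``
    of its propagules arrived within the trailing window of ``window``
    steps (the current step inclusive).
    """
    established: dict[int, int] = {}
    if allee_threshold == 0:
        sp, first_idx = np.unique(species, return_index=True)
        for s, i in zip(sp, first_idx):
            established[int(s)] = int(arrival_steps[i])
        return established
    a = allee_threshold
    order = np.argsort(species, kind="stable")
    sp_sorted = species[order]
    step_sorted = arrival_steps[order]
    bounds = np.flatnonzero(np.diff(sp_sorted)) + 1
    for lo, hi in zip(
        np.concatenate(([0], bounds)), np.concatenate((bounds, [len(sp_sorted)]))
    ):
        times = step_sorted[lo:hi]  # ascending: arrivals are in step order
        if len(times) <= a:
            continue
        # need a+1 arrivals within `window` consecutive steps
        ok = np.flatnonzero(times[a:] - times[: len(times) - a] <= window - 1)
        if len(ok):
            established[int(sp_sorted[lo])] = int(times[a + ok[0]])
    return established


def simulate(
    community: MainlandCommunity,
    schedule: Schedule,
    config: SimConfig,
) -> SimResult:
    """Run the colonization model.

    Per step, a Bernoulli(P(t)) draw decides whether one propagule
    arrives; its species is sampled by relative mainland abundance.
    The random draws do not depend on the Allee threshold, so a run
    with a = 0 is bitwise identical to the basic model under the same
    seed.
    """
    n_steps = schedule.n_steps
    p_species = community.relative_abundance
    cdf = np.cumsum(p_species)
    cdf[-1] = 1.0
    children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    richness = np.zeros((config.n_replicates, n_steps), dtype=np.int32)
    establishment: list[dict[int, int]] = []
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        arrive = rng.random(n_steps) < schedule.p
        steps = np.flatnonzero(arrive)
        species = np.searchsorted(cdf, rng.random(len(steps)), side="right")
        est = _establishments(
            steps, species, config.allee_threshold, config.window
        )
        establishment.append(est)
        if est:
            est_steps = np.fromiter(est.values(), dtype=np.int64)
            new_per_step = np.bincount(est_steps, minlength=n_steps)
            richness[rep] = np.cumsum(new_per_step)
    return SimResult(
        establishment_steps=establishment,
        richness=richness,
        config=config,
        m_species=community.m_species,
    )


def expected_richness_oracle(
    community: MainlandCommunity,
    schedule: Schedule,
    *,
    allee_threshold: int = 0,
) -> np.ndarray:
    """Exact expected island richness per step for the basic model.

    E[S(t)] = sum_i (1 - prod_{s<=t} (1 - P(s) * p_i)).  Only valid
    without an Allee effect (a = 0); no closed form exists otherwise.
    """
    if allee_threshold != 0:
        raise ValueError("no closed form with an Allee threshold > 0")
    p_species = community.relative_abundance  # (M,)
    log_miss = np.log1p(-np.outer(p_species, schedule.p))  # (M, n_steps)
    cum = np.cumsum(log_miss, axis=1)
    return (1.0 - np.exp(cum)).sum(axis=0)
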
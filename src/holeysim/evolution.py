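"""Forward-time evolution on holey fitness landscapes.

Two regimes are implemented:

* **Blind-ant random walk** (weak mutation, ``2 N^2 U << 1``): the
  population is a single viable genotype; each time step one uniformly
  random mutational neighbor is proposed and the population moves there if
  and only if the neighbor is viable.

* **Wright-Fisher life cycle** (selection -> recombination -> mutation):
  each generation two sets of ``N`` parents are drawn with replacement,
  fitness-proportionally, from the viable members of the population; paired
  parents recombine under one of three regimes (none / limited ``r`` /
  free); each offspring then mutates at per-site rate ``mu = U / L``.

Populations of constant size ``N`` are evolved to an approximate
mutation-recombination-selection-drift equilibrium for robustness and
diversity, cloned, and the two copies allowed to diverge allopatrically
under independent random-number streams while incompatibilities and
summary statistics are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genotypes import Genotype, alphabet_symbols
from .landscapes import Landscape
from . import measurements as _meas

__all__ = [
    "Regime",
    "EvolutionParams",
    "Population",
    "PopulationExtinct",
    "BlindAntState",
    "blind_ant_walk",
    "select_parents",
    "recombine",
    "recombine_many",
    "mutate",
    "mutate_many",
    "wf_generation",
    "EquilibriumCriterion",
    "evolve_to_equilibrium",
    "DivergenceRecord",
    "diverge_pair",
]


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


class PopulationExtinct(RuntimeError):
    """Raised when no member of the population has positive fitness."""

    def __init__(self, generation: int):
        super().__init__(f"population extinct at generation {generation}")
        self.generation = generation


@dataclass(frozen=True)
class Regime:
    """Recombination regime: ``none``, ``limited`` (probability r), or ``free``."""

    kind: str
    r: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("none", "limited", "free"):
            raise ValueError(f"unknown recombination regime {self.kind!r}")
        if self.kind == "limited":
            if self.r is None or not 0.0 < self.r <= 1.0:
                raise ValueError("limited recombination requires r in (0, 1]")
        elif self.r is not None:
            raise ValueError(f"regime {self.kind!r} takes no r parameter")

    @classmethod
    def parse(cls, spec) -> "Regime":
        """Accept 'none', 'free', a float r, or 'limited:<r>'."""
        if isinstance(spec, Regime):
            return spec
        if isinstance(spec, (int, float)):
            return cls("limited", float(spec))
        if spec in ("none", "free"):
            return cls(spec)
        if isinstance(spec, str) and spec.startswith("limited"):
            _, _, r = spec.partition(":")
            return cls("limited", float(r))
        raise ValueError(f"cannot parse recombination regime {spec!r}")

    def label(self) -> str:
        return self.kind if self.r is None else f"limited:{self.r:g}"


@dataclass
class EvolutionParams:
    """Parameters of the Wright-Fisher life cycle.

    ``U`` is the genome-wide mutation rate per generation; the per-site
    rate is ``mu = U / L``.  ``2 N^2 U >= 1`` marks departure from the weak
    mutation regime, where multiple mutations segregate simultaneously and
    selection for robustness and recombination become effective.
    """

    N: int
    U: float
    regime: Regime = field(default_factory=lambda: Regime("free"))
    max_generations: int = 10_000

    def __post_init__(self):
        self.regime = Regime.parse(self.regime)
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if self.U <= 0:
            raise ValueError("genomic mutation rate U must be positive")

    def mu(self, L: int) -> float:
        mu = self.U / L
        if not 0.0 < mu < 1.0:
            raise ValueError(f"per-site mutation rate mu={mu:g} outside (0, 1)")
        return mu

    @property
    def weak_mutation(self) -> bool:
        return 2.0 * self.N**2 * self.U < 1.0


class Population:
    """Generation-stamped multiset of ``N`` genotypes.

    Stored as an ``(N, L)`` uint8 code matrix.  When ``track_origins`` is
    enabled, the generation at which each (site, derived allele) pair first
    appears is recorded in ``origin_log``.
    """

    def __init__(
        self,
        codes: np.ndarray,
        alphabet: str,
        generation: int = 0,
        track_origins: bool = False,
    ):
        self.codes = np.asarray(codes, dtype=np.uint8)
        if self.codes.ndim != 2:
            raise ValueError("population codes must be an (N, L) matrix")
        self.alphabet = alphabet
        self.generation = generation
        self.origin_log: dict[tuple[int, int], int] | None = None
        self._seen: np.ndarray | None = None
        if track_origins:
            self.origin_log = {}
            n = len(alphabet_symbols(alphabet))
            self._seen = np.zeros((self.L, n), dtype=bool)
            self._record_origins()

    @classmethod
    def from_ancestor(
        cls, ancestor: Genotype, N: int, track_origins: bool = False
    ) -> "Population":
        """Clone a single ancestor ``N`` times (generation 0)."""
        return cls(
            np.tile(ancestor.codes, (N, 1)),
            ancestor.alphabet,
            generation=0,
            track_origins=track_origins,
        )

    @property
    def N(self) -> int:
        return self.codes.shape[0]

    @property
    def L(self) -> int:
        return self.codes.shape[1]

    @property
    def members(self) -> list[Genotype]:
        return [Genotype(row.copy(), self.alphabet) for row in self.codes]

    def _record_origins(self) -> None:
        assert self._seen is not None and self.origin_log is not None
        n = self._seen.shape[1]
        for a in range(n):
            present = (self.codes == a).any(axis=0)
            new = present & ~self._seen[:, a]
            for site in np.nonzero(new)[0]:
                self.origin_log[(int(site), a)] = self.generation
            self._seen[:, a] |= present

    def copy(self) -> "Population":
        clone = Population(self.codes.copy(), self.alphabet, self.generation)
        if self.origin_log is not None:
            clone.origin_log = dict(self.origin_log)
            clone._seen = self._seen.copy() if self._seen is not None else None
        return clone


# -- Blind ant --------------------------------------------------------------


@dataclass
class BlindAntState:
    current: Genotype
    steps: int
    trajectory: Optional[list[Genotype]] = None


def blind_ant_walk(
    start: Genotype,
    land: Landscape,
    steps: int,
    rng: np.random.Generator,
    record_trajectory: bool = False,
) -> BlindAntState:
    """Weak-mutation random walk on the neutral network.

    Per step one uniform random mutational neighbor is proposed; the walk
    moves there iff the neighbor is viable, otherwise it stays put.
    """
    land._check(start)
    if not land.is_viable(start):
        raise ValueError("blind ant walk requires a viable starting genotype")
    n = len(alphabet_symbols(start.alphabet))
    codes = start.codes.copy()
    trajectory = [Genotype(codes.copy(), start.alphabet)] if record_trajectory else None
    for _ in range(steps):
        site = int(rng.integers(0, len(codes)))
        offset = int(rng.integers(1, n))
        proposal = codes.copy()
        proposal[site] = (proposal[site] + offset) % n
        if land.viable_many(proposal[None, :])[0]:
            codes = proposal
        if trajectory is not None:
            trajectory.append(Genotype(codes.copy(), start.alphabet))
    return BlindAntState(Genotype(codes, start.alphabet), steps, trajectory)


# -- Wright-Fisher primitives ----------------------------------------------


def select_parents(
    pop: Population, land: Landscape, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent fitness-proportional parent index samples of size N.

    Members with zero fitness are never drawn; on a landscape where every
    viable genotype has fitness 1 this reduces to uniform sampling among
    viable members.  Raises :class:`PopulationExtinct` when total fitness
    is zero.
    """
    w = land.fitness_many(pop.codes)
    cdf = np.cumsum(w)
    total = cdf[-1]
    if total == 0.0:
        raise PopulationExtinct(pop.generation)
    # inverse-CDF sampling (much faster than Generator.choice with weights)
    s1 = np.searchsorted(cdf, rng.random(pop.N) * total, side="right")
    s2 = np.searchsorted(cdf, rng.random(pop.N) * total, side="right")
    return s1, s2


def recombine_many(
    p1: np.ndarray, p2: np.ndarray, regime: Regime, rng: np.random.Generator
) -> np.ndarray:
    """Recombine paired parent rows ``p1[i] x p2[i]`` into offspring rows.

    free
        Every offspring is recombinant; crossovers occur independently with
        probability 0.5 at each of the L - 1 inter-site boundaries (an
        expected ``0.5 * (L - 1)`` crossover events).
    limited (r)
        With probability ``r`` a single crossover at one uniformly random
        boundary; otherwise the offspring is a copy of a random parent.
    none
        The offspring is a copy of a random parent.
    """
    if p1.shape != p2.shape:
        raise ValueError("parent matrices must have identical shape")
    M, L = p1.shape
    if regime.kind == "none":
        pick = rng.integers(0, 2, M)
        return np.where(pick[:, None] == 0, p1, p2)
    if regime.kind == "free":
        # column 0 is the starting parent, the rest are fair crossover
        # bits; the running parity picks each site's source parent
        source = rng.integers(0, 2, (M, L), dtype=np.uint8)
        np.bitwise_xor.accumulate(source, axis=1, out=source)
        return np.where(source == 0, p1, p2)
    # limited
    assert regime.r is not None
    recomb = rng.random(M) < regime.r
    pick = rng.integers(0, 2, M)
    out = np.where(pick[:, None] == 0, p1, p2)
    idx = np.nonzero(recomb)[0]
    if idx.size:
        pos = rng.integers(1, L, idx.size)  # crossover boundary in 1..L-1
        sites = np.arange(L)
        after = sites[None, :] >= pos[:, None]
        lead = np.where(pick[idx, None] == 0, p1[idx], p2[idx])
        trail = np.where(pick[idx, None] == 0, p2[idx], p1[idx])
        out[idx] = np.where(after, trail, lead)
    return out


def recombine(
    parent1: Genotype, parent2: Genotype, regime, rng: np.random.Generator
) -> Genotype:
    """Single-pair wrapper around :func:`recombine_many`."""
    if len(parent1) != len(parent2):
        raise ValueError("parents must have equal length")
    regime = Regime.parse(regime)
    child = recombine_many(
        parent1.codes[None, :], parent2.codes[None, :], regime, rng
    )[0]
    return Genotype(child, parent1.alphabet)


def mutate_many(
    codes: np.ndarray, mu: float, n_symbols: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-site binomial mutation; all point mutations equally likely."""
    mask = rng.random(codes.shape) < mu
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return codes
    out = codes.copy()
    offsets = rng.integers(1, n_symbols, rows.size, dtype=np.uint8)
    out[rows, cols] = (out[rows, cols] + offsets) % n_symbols
    return out


def mutate(g: Genotype, mu: float, rng: np.random.Generator) -> Genotype:
    """Mutate each site independently with probability ``mu``.

    A mutated binary site flips; a mutated RNA site becomes one of the
    three other nucleotides with equal probability.
    """
    if not 0.0 <= mu < 1.0:
        raise ValueError("per-site mutation rate must lie in [0, 1)")
    n = len(alphabet_symbols(g.alphabet))
    return Genotype(mutate_many(g.codes[None, :], mu, n, rng)[0], g.alphabet)


@dataclass
class WFStreams:
    """Named independent random streams for one evolving population."""

    selection: np.random.Generator
    recombination: np.random.Generator
    mutation: np.random.Generator

    @classmethod
    def from_seed(cls, seed) -> "WFStreams":
        # children are derived from the seed's *value*, not via the stateful
        # spawn() protocol, so equal seeds always yield equal streams
        base = _seedseq(seed)
        sel, rec, mut = (
            np.random.SeedSequence(
                entropy=base.entropy, spawn_key=base.spawn_key + (k,)
            )
            for k in range(3)
        )
        return cls(
            np.random.default_rng(sel),
            np.random.default_rng(rec),
            np.random.default_rng(mut),
        )


def wf_generation(
    pop: Population,
    land: Landscape,
    params: EvolutionParams,
    rng: np.random.Generator | WFStreams,
) -> Population:
    """One selection-recombination-mutation generation; returns the offspring."""
    if isinstance(rng, np.random.Generator):
        streams = WFStreams(rng, rng, rng)
    else:
        streams = rng
    s1, s2 = select_parents(pop, land, streams.selection)
    children = recombine_many(
        pop.codes[s1], pop.codes[s2], params.regime, streams.recombination
    )
    n = len(alphabet_symbols(pop.alphabet))
    children = mutate_many(children, params.mu(pop.L), n, streams.mutation)
    out = Population(children, pop.alphabet, pop.generation + 1)
    if pop.origin_log is not None:
        out.origin_log = pop.origin_log
        out._seen = pop._seen
        out._record_origins()
    return out


# -- Equilibration ----------------------------------------------------------


@dataclass
class EquilibriumCriterion:
    """Sliding-window slope test for approximate equilibrium.

    Equilibrium is declared once the absolute OLS slope per generation of
    both mean robustness ``nu`` and diversity ``pi``, over the measurement
    points of the last two windows, falls below ``slope_tol``, subject to a
    hard minimum burn-in.  Selection for robustness is second-order and
    equilibrates slowly in large populations, so the defaults scale with N:
    window ``max(200, 2N)`` generations and burn-in ``40 N`` generations.
    (Long-trajectory diagnostics at N = 500 show a robustness relaxation
    time of roughly 8 N generations; the burn-in allows ~5 relaxation
    times, a residual drift the windowed slope test cannot resolve from
    measurement noise.)
    """

    window: Optional[int] = None  # default max(200, 2N)
    slope_tol: float = 1e-5
    min_generations: Optional[int] = None  # default 40 N
    measure_every: Optional[int] = None
    sample_size: int = 100

    def effective_window(self, N: int) -> int:
        return self.window if self.window is not None else max(200, 2 * N)

    def burn_in(self, N: int) -> int:
        return self.min_generations if self.min_generations is not None else 40 * N


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.ptp(x) == 0:
        return np.inf
    return float(np.polyfit(x, y, 1)[0])


def evolve_to_equilibrium(
    ancestor: Genotype,
    land: Landscape,
    params: EvolutionParams,
    criterion: EquilibriumCriterion | None = None,
    seed=None,
    track_origins: bool = False,
) -> tuple[Population, dict]:
    """Clone the ancestor N times and evolve to approximate equilibrium.

    Returns the final population and a diagnostics dict with the ``nu`` and
    ``pi`` trajectories (sampled every ``measure_every`` generations), the
    stopping generation, and a ``converged`` flag.  Non-convergence at
    ``params.max_generations`` sets ``converged=False`` but is not an
    error.
    """
    if not land.is_viable(ancestor):
        raise ValueError("ancestor must be viable")
    crit = criterion or EquilibriumCriterion()
    ss = _seedseq(seed)
    ev_seed, meas_seed = ss.spawn(2)
    streams = WFStreams.from_seed(ev_seed)
    meas_rng = np.random.default_rng(meas_seed)

    pop = Population.from_ancestor(ancestor, params.N, track_origins=track_origins)
    cadence = crit.measure_every or max(1, params.N // 10)
    burn_in = crit.burn_in(params.N)
    window = crit.effective_window(params.N)
    gens, nus, pis = [], [], []

    def measure(p: Population) -> None:
        gens.append(p.generation)
        nus.append(
            _meas.population_robustness(p, land, crit.sample_size, meas_rng)
        )
        pis.append(_meas.sequence_diversity(p))

    measure(pop)
    converged = False
    while pop.generation < params.max_generations:
        pop = wf_generation(pop, land, params, streams)
        if pop.generation % cadence == 0:
            measure(pop)
            if pop.generation >= max(burn_in, 2 * window):
                g = np.asarray(gens, dtype=float)
                recent = g >= pop.generation - 2 * window
                if recent.sum() >= 4:
                    s_nu = _slope(g[recent], np.asarray(nus)[recent])
                    s_pi = _slope(g[recent], np.asarray(pis)[recent])
                    if abs(s_nu) < crit.slope_tol and abs(s_pi) < crit.slope_tol:
                        converged = True
                        break
    diagnostics = {
        "generations": np.asarray(gens),
        "nu": np.asarray(nus),
        "pi": np.asarray(pis),
        "converged": converged,
        "stopped_at": pop.generation,
    }
    return pop, diagnostics


# -- Allopatric divergence --------------------------------------------------


@dataclass
class DivergenceRecord:
    """Time series of divergence measurements for one population pair.

    ``table`` has one row per measurement event with columns: generation,
    D, II_12, II_21, II_within_1, II_within_2, nu_1, nu_2, pi_1, pi_2 and
    (optionally) RI.  When snapshots are retained, ``snapshots[pop]`` holds
    the full code matrix of every generation, for backcrossing.
    """

    table: pd.DataFrame
    extinct: bool = False
    reached_target: bool = False
    snapshots: Optional[dict[int, list[np.ndarray]]] = None
    origin_logs: Optional[dict[int, dict[tuple[int, int], int]]] = None
    final_populations: Optional[tuple[Population, Population]] = None


def diverge_pair(
    eq_pop: Population,
    land: Landscape,
    params: EvolutionParams,
    target_D: float,
    cadence: Optional[int] = None,
    snapshots: bool = False,
    seed=None,
    pop_seeds=None,
    measure_RI: bool = False,
    max_pairs: int = 100,
) -> DivergenceRecord:
    """Clone an equilibrated population and let the two copies diverge.

    The copies evolve under identical parameters but independent random
    streams (``pop_seeds`` may be supplied explicitly, e.g. to verify that
    identical streams produce zero divergence).  Every ``cadence``
    generations Jost's D, directional between-population II, within-
    population II, robustness, diversity and optionally RI are recorded;
    the run stops once ``D >= target_D`` or at ``params.max_generations``.
    """
    ss = _seedseq(seed)
    if pop_seeds is None:
        s1, s2, sm = ss.spawn(3)
    else:
        s1, s2 = pop_seeds
        (sm,) = ss.spawn(1)
    streams = (WFStreams.from_seed(s1), WFStreams.from_seed(s2))
    meas_rng = np.random.default_rng(sm)
    cadence = cadence or max(1, params.N // 10)

    pops = [eq_pop.copy(), eq_pop.copy()]
    for p in pops:
        p.generation = 0
        if snapshots and p.origin_log is None:
            # origin tracking is required to interpret snapshots
            n = len(alphabet_symbols(p.alphabet))
            p.origin_log = {}
            p._seen = np.zeros((p.L, n), dtype=bool)
            p._record_origins()
    snaps: Optional[dict[int, list[np.ndarray]]] = (
        {0: [pops[0].codes.copy()], 1: [pops[1].codes.copy()]} if snapshots else None
    )

    rows = []
    extinct = False
    reached = False

    def measure() -> float:
        D = _meas.jost_D(pops[0], pops[1])
        ii_12, ii_21 = _meas.sample_between_II(
            pops[0], pops[1], land, max_pairs, meas_rng
        )
        row = {
            "generation": pops[0].generation,
            "D": D,
            "II_12": ii_12.mean_II,
            "II_21": ii_21.mean_II,
            "II_within_1": _meas.sample_within_II(
                pops[0], land, max_pairs, meas_rng
            ).mean_II,
            "II_within_2": _meas.sample_within_II(
                pops[1], land, max_pairs, meas_rng
            ).mean_II,
            "nu_1": _meas.population_robustness(pops[0], land, 100, meas_rng),
            "nu_2": _meas.population_robustness(pops[1], land, 100, meas_rng),
            "pi_1": _meas.sequence_diversity(pops[0]),
            "pi_2": _meas.sequence_diversity(pops[1]),
        }
        if measure_RI:
            row["RI"] = _meas.measure_RI(
                pops[0], pops[1], land, params.regime, meas_rng
            )
        rows.append(row)
        return D

    D = measure()
    if D >= target_D:
        reached = True
    while not reached and not extinct and pops[0].generation < params.max_generations:
        try:
            for i in (0, 1):
                pops[i] = wf_generation(pops[i], land, params, streams[i])
                if snaps is not None:
                    snaps[i].append(pops[i].codes.copy())
        except PopulationExtinct:
            extinct = True
            break
        if pops[0].generation % cadence == 0:
            D = measure()
            if D >= target_D:
                reached = True
    return DivergenceRecord(
        table=pd.DataFrame(rows),
        extinct=extinct,
        reached_target=reached,
        snapshots=snaps,
        origin_logs=(
            {0: dict(pops[0].origin_log or {}), 1: dict(pops[1].origin_log or {})}
            if snapshots
            else None
        ),
        final_populations=(pops[0], pops[1]),
    )
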
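"""Experiment orchestration, curve fitting and replicate aggregation.

The central design: populations are evolved to equilibrium at a grid of
population sizes and recombination regimes, cloned into identical pairs,
allowed to diverge allopatrically under the same parameters
(mutation-order speciation), and the accumulation of incompatible
introgressions (II) with genetic distance D is summarized by the linear
fit ``II = a + b D`` per replicate.  The slope per locus, ``b/L``, is the
empirical rate of II accumulation and is compared with the robustness
expectation ``1 - nu_tilde``.  A nonlinear variant
``II = a + b (L D - 1)^c`` probes for "snowballing" (c >= 2) versus linear
(c = 1) accumulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .evolution import (
    DivergenceRecord,
    EquilibriumCriterion,
    EvolutionParams,
    PopulationExtinct,
    Regime,
    blind_ant_walk,
    diverge_pair,
    evolve_to_equilibrium,
)
from .genotypes import Genotype, random_genotype
from .landscapes import (
    Landscape,
    RNALandscape,
    RussianRouletteLandscape,
    genotype_robustness,
)
from .measurements import count_II

__all__ = [
    "ExperimentConfig",
    "FitResult",
    "Aggregate",
    "BackcrossResult",
    "random_viable_genotype",
    "run_divergence_experiment",
    "weak_mutation_divergence",
    "fit_linear_II",
    "fit_nonlinear_II",
    "divergence_rate",
    "fit_power_law",
    "backcross_experiment",
    "aggregate_replicates",
]


# -- Config -----------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Full specification of a divergence experiment grid.

    ``U_policy`` is either ``"fixed_U"`` (every cell uses ``U``) or
    ``"fixed_NU"`` (``U = NU / N`` per cell, holding the mutational supply
    constant).  Replicate seeds are derived deterministically from
    ``master_seed`` and the (cell, replicate) coordinates, so cells can be
    run independently and in any order.
    """

    model: str = "russian_roulette"  # or "rna"
    L: int = 30
    p: float = 0.5  # russian roulette viability probability
    sigma: float = 0.025  # rna selection strength
    alpha: int = 12  # rna viability threshold
    N_values: Sequence[int] = (100,)
    regimes: Sequence = ("free",)
    U: float = 0.1
    U_policy: str = "fixed_U"
    NU: float = 10.0
    replicates: int = 10
    target_D: float = 0.1
    cadence: Optional[int] = None
    snapshots: bool = False
    measure_RI: bool = False
    master_seed: int = 0
    max_generations: int = 10_000
    equilibrium: EquilibriumCriterion = field(default_factory=EquilibriumCriterion)

    def __post_init__(self):
        if self.model not in ("russian_roulette", "rna"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.U_policy not in ("fixed_U", "fixed_NU"):
            raise ValueError(f"unknown U policy {self.U_policy!r}")
        self.regimes = [Regime.parse(r) for r in self.regimes]

    def cell_U(self, N: int) -> float:
        return self.NU / N if self.U_policy == "fixed_NU" else self.U

    def cells(self) -> list[tuple[int, Regime]]:
        return [(N, r) for N in self.N_values for r in self.regimes]

    def replicate_seed(self, cell_index: int, replicate: int) -> np.random.SeedSequence:
        return np.random.SeedSequence([self.master_seed, cell_index, replicate])


def random_viable_genotype(
    land: Landscape, L: int, alphabet: str, rng: np.random.Generator, cap: int = 10_000
) -> Genotype:
    """Rejection-sample a uniform random viable genotype."""
    for _ in range(cap):
        g = random_genotype(L, alphabet, rng)
        if land.is_viable(g):
            return g
    raise RuntimeError(f"no viable genotype found in {cap} draws")


def _make_replicate(
    config: ExperimentConfig, seed_seq: np.random.SeedSequence, folder=None
) -> tuple[Landscape, Genotype]:
    """Fresh landscape + viable ancestor for one replicate."""
    land_seed, anc_seed = seed_seq.spawn(2)
    rng = np.random.default_rng(anc_seed)
    if config.model == "russian_roulette":
        land = RussianRouletteLandscape(
            config.L, config.p, int(land_seed.generate_state(1)[0] >> 1)
        )
        ancestor = random_viable_genotype(land, config.L, "binary", rng)
        return land, ancestor
    from .fixtures import make_rna_ancestor

    ancestor, reference = make_rna_ancestor(
        L=config.L, alpha=config.alpha, rng=rng, folder=folder
    )
    land = RNALandscape(reference, config.sigma, config.alpha, folder=folder)
    return land, ancestor


def run_divergence_experiment(config: ExperimentConfig, folder=None) -> pd.DataFrame:
    """Equilibrate, clone and diverge every (cell, replicate); tidy output.

    Returns one row per (cell, replicate, measurement event) with D, the
    directional between-population II, within-population II, robustness,
    diversity, and flags.  Extinct replicates are flagged (``extinct``
    column) so downstream aggregation can exclude them.
    """
    frames = []
    for cell_index, (N, regime) in enumerate(config.cells()):
        cell_id = f"N{N}_{regime.label()}"
        for rep in range(config.replicates):
            seed_seq = config.replicate_seed(cell_index, rep)
            land_anc_seed, eq_seed, div_seed = seed_seq.spawn(3)
            land, ancestor = _make_replicate(config, land_anc_seed, folder=folder)
            params = EvolutionParams(
                N=N,
                U=config.cell_U(N),
                regime=regime,
                max_generations=config.max_generations,
            )
            try:
                eq_pop, diag = evolve_to_equilibrium(
                    ancestor, land, params, config.equilibrium, seed=eq_seed
                )
            except PopulationExtinct as exc:
                warnings.warn(
                    f"cell {cell_id} replicate {rep} extinct during "
                    f"equilibration ({exc}); excluded"
                )
                continue
            record = diverge_pair(
                eq_pop,
                land,
                params,
                target_D=config.target_D,
                cadence=config.cadence,
                snapshots=config.snapshots,
                seed=div_seed,
                measure_RI=config.measure_RI,
            )
            tbl = record.table.copy()
            tbl.insert(0, "cell", cell_id)
            tbl.insert(1, "N", N)
            tbl.insert(2, "regime", regime.label())
            tbl.insert(3, "replicate", rep)
            tbl["extinct"] = record.extinct
            tbl["equilibrated"] = diag["converged"]
            frames.append(tbl)
    out = pd.concat(frames, ignore_index=True)
    n_extinct = out.loc[out["extinct"], ["cell", "replicate"]].drop_duplicates().shape[0]
    if n_extinct:
        warnings.warn(f"{n_extinct} replicate(s) went extinct and are flagged")
    return out


# -- Weak mutation ----------------------------------------------------------


def weak_mutation_divergence(
    land: Landscape,
    ancestor: Genotype,
    rng: np.random.Generator,
    k_max: int = 15,
    k_keep: int = 12,
    max_steps: int = 100_000,
) -> pd.DataFrame:
    """Blind-ant divergence of two populations from a common ancestor.

    Both monomorphic populations start at the ancestor and perform
    independent blind-ant steps; after each time step the divergence k, the
    mean directional II and the mean robustness of the two genotypes are
    recorded.  Divergence proceeds until ``k_max`` differences, but rows
    with ``k > k_keep`` are discarded; k can decrease as well as increase.
    Returns columns: step, k, D (= k/L), II, nu.
    """
    walkers = [ancestor, ancestor]
    rows = []
    L = len(ancestor)
    for step in range(1, max_steps + 1):
        walkers = [
            blind_ant_walk(w, land, steps=1, rng=rng).current for w in walkers
        ]
        k = int((walkers[0].codes != walkers[1].codes).sum())
        if k > k_max:
            break
        if k <= k_keep:
            ii = 0.5 * (
                count_II(walkers[0], walkers[1], land)
                + count_II(walkers[1], walkers[0], land)
            )
            nu = 0.5 * (
                genotype_robustness(walkers[0], land)
                + genotype_robustness(walkers[1], land)
            )
            rows.append({"step": step, "k": k, "D": k / L, "II": ii, "nu": nu})
    return pd.DataFrame(rows)


# -- Fitting ----------------------------------------------------------------


@dataclass
class FitResult:
    """Coefficients and diagnostics of a fitted II-accumulation model."""

    coefficients: dict[str, float]
    r_squared: float
    n_points: int
    converged: bool = True
    per_replicate: Optional[pd.DataFrame] = None


def fit_linear_II(D: np.ndarray, II: np.ndarray) -> FitResult:
    """OLS fit of ``II = a + b D`` to points with D > 0.

    Measurements at the start of divergence (D = 0) are excluded: the
    linear theory predicts II from the k - 1 untested alleles, and the
    D = 0 point carries no information about the accumulation rate.
    """
    D = np.asarray(D, dtype=float)
    II = np.asarray(II, dtype=float)
    mask = D > 0
    if mask.sum() < 2:
        raise ValueError("linear II fit requires at least 2 points with D > 0")
    x, y = D[mask], II[mask]
    if np.ptp(x) == 0:
        # vertical stack of points: slope undefined, fall back to mean level
        raise ValueError("linear II fit requires at least 2 distinct D values")
    res = linregress(x, y)
    return FitResult(
        coefficients={"a": float(res.intercept), "b": float(res.slope)},
        r_squared=float(res.rvalue**2),
        n_points=int(mask.sum()),
    )


def fit_nonlinear_II(
    D: np.ndarray, II: np.ndarray, L: int, c_bounds: tuple[float, float] = (0.5, 4.0)
) -> FitResult:
    """Least-squares fit of ``II = a + b (L D - 1)^c`` to points with LD > 1.

    The exponent c discriminates linear accumulation (c = 1) from
    snowballing (c >= 2).  Initialized at c = 1 with the linear-fit slope.
    """
    D = np.asarray(D, dtype=float)
    II = np.asarray(II, dtype=float)
    mask = L * D > 1
    if mask.sum() < 4:
        raise ValueError("nonlinear II fit requires at least 4 points with L*D > 1")
    x = L * D[mask] - 1.0
    y = II[mask]
    b0 = max(float(np.polyfit(x, y, 1)[0]), 1e-6)

    def model(x, a, b, c):
        return a + b * np.power(x, c)

    try:
        popt, _ = curve_fit(
            model,
            x,
            y,
            p0=(0.0, b0, 1.0),
            bounds=([-np.inf, 0.0, c_bounds[0]], [np.inf, np.inf, c_bounds[1]]),
            maxfev=10_000,
        )
        converged = True
    except RuntimeError:
        popt, converged = (np.nan, np.nan, np.nan), False
    if converged:
        resid = y - model(x, *popt)
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else np.nan
    else:
        r2 = np.nan
    return FitResult(
        coefficients={"a": float(popt[0]), "b": float(popt[1]), "c": float(popt[2])},
        r_squared=float(r2),
        n_points=int(mask.sum()),
        converged=converged,
    )


def divergence_rate(
    generations: np.ndarray,
    D: np.ndarray,
    target_D: Optional[float] = None,
    plateau_fraction: float = 0.8,
) -> float:
    """Rate of increase of D per generation over the pre-plateau range.

    When ``target_D`` is given, only measurement events with
    ``D < plateau_fraction * target_D`` enter the slope, avoiding the
    curvature near the stopping threshold.  Returns NaN for series with
    fewer than 2 usable points.
    """
    g = np.asarray(generations, dtype=float)
    d = np.asarray(D, dtype=float)
    if target_D is not None:
        mask = d < plateau_fraction * target_D
        # always keep the first point so short series remain fittable
        mask[0] = True
        g, d = g[mask], d[mask]
    if len(g) < 2 or np.ptp(g) == 0:
        return np.nan
    return float(np.polyfit(g, d, 1)[0])


def fit_power_law(N_values: np.ndarray, rates: np.ndarray) -> FitResult:
    """Log-log OLS of mean divergence rate against N; returns the exponent."""
    N_values = np.asarray(N_values, dtype=float)
    rates = np.asarray(rates, dtype=float)
    ok = (rates > 0) & np.isfinite(rates)
    if ok.sum() < 2:
        raise ValueError("power-law fit requires at least 2 positive rates")
    res = linregress(np.log(N_values[ok]), np.log(rates[ok]))
    return FitResult(
        coefficients={
            "exponent": float(res.slope),
            "prefactor": float(np.exp(res.intercept)),
        },
        r_squared=float(res.rvalue**2),
        n_points=int(ok.sum()),
    )


# -- Replicate aggregation --------------------------------------------------


@dataclass
class Aggregate:
    mean: float
    ci95: float  # half-width; NaN when undefined
    n: int


def aggregate_replicates(values: Sequence[float]) -> Aggregate:
    """Mean and normal-approximation 95% CI over replicate-level estimates.

    The CI is ``1.96 * SEM`` computed from per-replicate values, never from
    pooled points.
    """
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    if v.size == 0:
        return Aggregate(np.nan, np.nan, 0)
    if v.size == 1:
        return Aggregate(float(v[0]), np.nan, 1)
    sem = v.std(ddof=1) / np.sqrt(v.size)
    return Aggregate(float(v.mean()), float(1.96 * sem), int(v.size))


# -- Backcrossing -----------------------------------------------------------


@dataclass
class BackcrossResult:
    """Outcome of backcrossing one focal derived allele into its origin cohort."""

    site: int
    allele: int
    origin_generation: int
    qualification_generation: int
    klass: str  # "II-causing" or "control"
    proportion_viable: float
    nu_at_origin: float
    nu_at_qualification: float


def _allele_frequency(snap: np.ndarray, site: int, allele: int) -> float:
    return float((snap[:, site] == allele).mean())


def _causes_II(
    allele_site: int,
    allele: int,
    sister_snap: np.ndarray,
    land: Landscape,
    rng: np.random.Generator,
    max_pairs: int = 100,
) -> bool:
    """Is the allele lethal in >= 1 sampled viable sister background?"""
    viable = np.nonzero(land.viable_many(sister_snap))[0]
    if viable.size == 0:
        return False
    m = min(max_pairs, viable.size)
    idx = rng.choice(viable, size=m, replace=False)
    recipients = sister_snap[idx]
    differs = recipients[:, allele_site] != allele
    if not differs.any():
        return False
    variants = recipients[differs].copy()
    variants[:, allele_site] = allele
    return bool((~land.viable_many(variants)).any())


def _population_nu(
    snap: np.ndarray, alphabet: str, land: Landscape, rng: np.random.Generator
) -> float:
    from .landscapes import robustness_many

    viable = np.nonzero(land.viable_many(snap))[0]
    if viable.size == 0:
        return np.nan
    idx = rng.choice(viable, size=min(100, viable.size), replace=False)
    return float(robustness_many(snap[idx], alphabet, land).mean())


def backcross_experiment(
    record: DivergenceRecord,
    land: Landscape,
    alphabet: str,
    seed=None,
    frequency_threshold: float = 0.5,
    cadence: int = 1,
    max_pairs: int = 100,
) -> tuple[Optional[BackcrossResult], Optional[BackcrossResult]]:
    """Backcross the first II-causing and first control mutation.

    Scans the derived alleles of both diverging populations in order of
    origin (ties broken by site then allele).  The *focal* mutation is the
    earliest to (a) reach frequency >= 0.5 in its population and (b) be
    lethal when introgressed into at least one sampled viable member of
    the sister population at a measurement event at or after
    qualification.  The *control* is the earliest to reach >= 0.5 without
    ever causing an II at any checked event.  Each is substituted into
    every individual of its origin-generation snapshot and the proportion
    of viable constructs reported, together with the population robustness
    at origin and at qualification.

    Returns ``(focal, control)``; either may be None when no mutation
    qualifies.
    """
    if record.snapshots is None or record.origin_logs is None:
        raise ValueError("backcross requires a divergence record with snapshots")
    rng = np.random.default_rng(seed)
    focal: Optional[BackcrossResult] = None
    control: Optional[BackcrossResult] = None

    candidates = []
    for pop_id in (0, 1):
        for (site, allele), gen in record.origin_logs[pop_id].items():
            if gen > 0:  # ancestral alleles (generation 0) are not mutations
                candidates.append((gen, site, allele, pop_id))
    candidates.sort()

    n_gens = len(record.snapshots[0])
    for gen, site, allele, pop_id in candidates:
        if focal is not None and control is not None:
            break
        snaps = record.snapshots[pop_id]
        sister = record.snapshots[1 - pop_id]
        qual_gen = None
        for g in range(gen, n_gens):
            if _allele_frequency(snaps[g], site, allele) >= frequency_threshold:
                qual_gen = g
                break
        if qual_gen is None:
            continue
        check_gens = [qual_gen] + [
            g for g in range(qual_gen + 1, n_gens) if g % cadence == 0
        ]
        causes = any(
            _causes_II(site, allele, sister[g], land, rng, max_pairs)
            for g in check_gens
        )
        klass = "II-causing" if causes else "control"
        if (klass == "II-causing" and focal is not None) or (
            klass == "control" and control is not None
        ):
            continue
        origin_snap = snaps[gen]
        constructs = origin_snap.copy()
        constructs[:, site] = allele
        result = BackcrossResult(
            site=site,
            allele=allele,
            origin_generation=gen,
            qualification_generation=qual_gen,
            klass=klass,
            proportion_viable=float(land.viable_many(constructs).mean()),
            nu_at_origin=_population_nu(origin_snap, alphabet, land, rng),
            nu_at_qualification=_population_nu(snaps[qual_gen], alphabet, land, rng),
        )
        if klass == "II-causing":
            focal = result
        else:
            control = result
    return focal, control
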
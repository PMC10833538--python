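"""Statistics on populations: incompatibilities, differentiation, DFE.

An *incompatible introgression* (II) is a single divergent allele that is
lethal when substituted alone from a donor genotype into a recipient
genotype's background; each II implies at least one Dobzhansky-Muller
incompatibility.  IIs are counted between populations (in both directions;
the count is not symmetric) and within populations (segregating IIs).

Differentiation between the diverging populations is measured by Jost's D
computed per locus from within- and pooled-population expected
heterozygosity and averaged over loci; within-population diversity ``pi``
is the mean per-locus heterozygosity.  Postzygotic reproductive isolation
is one minus the mean fitness of recombinant hybrids, and the distribution
of fitness effects (DFE) classifies random single mutations by
``s = w'/w - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np

from .genotypes import Genotype, alphabet_symbols
from .landscapes import Landscape, robustness_many

if TYPE_CHECKING:  # pragma: no cover
    from .evolution import Population, Regime

__all__ = [
    "IISample",
    "DFESummary",
    "count_II",
    "sample_between_II",
    "sample_within_II",
    "jost_D",
    "sequence_diversity",
    "population_robustness",
    "measure_RI",
    "measure_DFE",
]

_NEUTRAL_TOL = 1e-12  # |s| below this counts as neutral (float guard)


@dataclass
class IISample:
    """Mean II over sampled genotype pairs in one direction."""

    direction: tuple[int, int]
    pair_count: int
    mean_II: float
    per_pair: list[int]


def _count_II_rows(
    donor: np.ndarray, recipient: np.ndarray, land: Landscape
) -> int:
    diff = np.nonzero(donor != recipient)[0]
    if diff.size == 0:
        return 0
    variants = np.repeat(recipient[None, :], diff.size, axis=0)
    variants[np.arange(diff.size), diff] = donor[diff]
    return int((~land.viable_many(variants)).sum())


def count_II(donor: Genotype, recipient: Genotype, land: Landscape) -> int:
    """Number of donor alleles that are lethal in the recipient background.

    Each allele at a site where donor and recipient differ is introgressed
    into the recipient one at a time; the count of inviable constructs is
    returned (between 0 and the pairwise divergence k).
    """
    land._check(donor)
    land._check(recipient)
    if not land.is_viable(donor) or not land.is_viable(recipient):
        raise ValueError("II counting requires viable donor and recipient")
    return _count_II_rows(donor.codes, recipient.codes, land)


def _viable_indices(pop: "Population", land: Landscape) -> np.ndarray:
    return np.nonzero(land.viable_many(pop.codes))[0]


def _paired_II(
    donors: np.ndarray, recipients: np.ndarray, land: Landscape
) -> list[int]:
    """II count per (donor, recipient) pair; one batched viability query."""
    blocks = []
    sizes = []
    for d, r in zip(donors, recipients):
        diff = np.nonzero(d != r)[0]
        sizes.append(diff.size)
        if diff.size:
            variants = np.repeat(r[None, :], diff.size, axis=0)
            variants[np.arange(diff.size), diff] = d[diff]
            blocks.append(variants)
    if not blocks:
        return [0] * len(sizes)
    inviable = ~land.viable_many(np.concatenate(blocks, axis=0))
    counts, pos = [], 0
    for k in sizes:
        counts.append(int(inviable[pos : pos + k].sum()))
        pos += k
    return counts


def sample_between_II(
    pop1: "Population",
    pop2: "Population",
    land: Landscape,
    max_pairs: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> tuple[IISample, IISample]:
    """Directional mean II over random cross-population pairs.

    ``min(max_pairs, N)`` individuals are sampled without replacement from
    the viable members of each population and paired; II is counted in both
    directions on the same pairs.
    """
    rng = rng or np.random.default_rng()
    v1 = _viable_indices(pop1, land)
    v2 = _viable_indices(pop2, land)
    m = min(max_pairs, v1.size, v2.size)
    idx1 = rng.choice(v1, size=m, replace=False)
    idx2 = rng.choice(v2, size=m, replace=False)
    d1, d2 = pop1.codes[idx1], pop2.codes[idx2]
    c12 = _paired_II(d1, d2, land)
    c21 = _paired_II(d2, d1, land)
    return (
        IISample((1, 2), m, float(np.mean(c12)) if m else 0.0, c12),
        IISample((2, 1), m, float(np.mean(c21)) if m else 0.0, c21),
    )


def sample_within_II(
    pop: "Population",
    land: Landscape,
    max_pairs: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> IISample:
    """Mean segregating II over random pairs from the same population.

    2 * min(max_pairs, N // 2) viable individuals are sampled without
    replacement and paired; II is counted from the first to the second
    member of each pair.
    """
    rng = rng or np.random.default_rng()
    v = _viable_indices(pop, land)
    m = min(max_pairs, v.size // 2)
    if m == 0:
        return IISample((0, 0), 0, 0.0, [])
    idx = rng.choice(v, size=2 * m, replace=False)
    counts = _paired_II(pop.codes[idx[:m]], pop.codes[idx[m:]], land)
    return IISample((0, 0), m, float(np.mean(counts)), counts)


def _allele_freqs(codes: np.ndarray, n_symbols: int) -> np.ndarray:
    """(L, n_symbols) allele-frequency matrix of a code matrix."""
    return np.stack(
        [(codes == a).mean(axis=0) for a in range(n_symbols)], axis=1
    )


def jost_D(pop1: "Population", pop2: "Population") -> float:
    """Jost's D differentiation between two populations, averaged over loci.

    Per locus, with n = 2 demes, ``D = ((H_T - H_S) / (1 - H_S)) * n/(n-1)``
    where H_S is the mean within-deme expected heterozygosity and H_T the
    heterozygosity of the pooled allele frequencies.  A locus fixed for
    different alleles gives D = 1; monomorphic or undifferentiated loci
    give 0; loci with H_S -> 1 use the finite limit ``n/(n-1) *
    (1 - H_S / H_T)``.
    """
    if pop1.L != pop2.L or pop1.alphabet != pop2.alphabet:
        raise ValueError("populations must share L and alphabet")
    n_sym = len(alphabet_symbols(pop1.alphabet))
    f1 = _allele_freqs(pop1.codes, n_sym)
    f2 = _allele_freqs(pop2.codes, n_sym)
    h1 = 1.0 - (f1**2).sum(axis=1)
    h2 = 1.0 - (f2**2).sum(axis=1)
    hs = 0.5 * (h1 + h2)
    fm = 0.5 * (f1 + f2)
    ht = 1.0 - (fm**2).sum(axis=1)
    D = np.zeros(pop1.L)
    eps = 1e-12
    varying = ht > eps
    regular = varying & (1.0 - hs > eps)
    D[regular] = 2.0 * (ht[regular] - hs[regular]) / (1.0 - hs[regular])
    saturated = varying & ~regular
    D[saturated] = 2.0 * (1.0 - hs[saturated] / ht[saturated])
    return float(np.clip(D, 0.0, 1.0).mean())


def sequence_diversity(pop: "Population") -> float:
    """Within-population heterozygosity ``pi``, averaged over loci."""
    n_sym = len(alphabet_symbols(pop.alphabet))
    f = _allele_freqs(pop.codes, n_sym)
    return float((1.0 - (f**2).sum(axis=1)).mean())


def population_robustness(
    pop: "Population",
    land: Landscape,
    sample_size: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Mean robustness ``nu`` of up to ``sample_size`` viable members.

    Individuals are sampled at random without replacement (all of them
    when N < sample_size); ``nu`` is defined only for viable genotypes, so
    sampling is restricted to members with w > 0.
    """
    rng = rng or np.random.default_rng()
    v = _viable_indices(pop, land)
    if v.size == 0:
        raise ValueError("no viable members to measure robustness on")
    m = min(sample_size, v.size)
    idx = rng.choice(v, size=m, replace=False)
    return float(robustness_many(pop.codes[idx], pop.alphabet, land).mean())


def measure_RI(
    pop1: "Population",
    pop2: "Population",
    land: Landscape,
    regime,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Postzygotic reproductive isolation ``RI = 1 - mean hybrid fitness``.

    The i-th members of the two populations are recombined under the
    experiment's regime and the resulting hybrids scored.  Under the
    ``none`` regime a hybrid would be a clone of one parent and RI would be
    trivially 0, so free recombination is substituted (RI measures
    recombinant offspring by definition).
    """
    from .evolution import Regime, recombine_many  # local: avoids import cycle

    rng = rng or np.random.default_rng()
    if pop1.L != pop2.L or pop1.alphabet != pop2.alphabet:
        raise ValueError("populations must share L and alphabet")
    regime = Regime.parse(regime)
    if regime.kind == "none":
        regime = Regime("free")
    m = min(pop1.N, pop2.N)
    hybrids = recombine_many(pop1.codes[:m], pop2.codes[:m], regime, rng)
    w = land.fitness_many(hybrids)
    return float(np.clip(1.0 - w.mean(), 0.0, 1.0))


@dataclass
class DFESummary:
    """Aggregate distribution of fitness effects of random single mutations.

    ``lethal`` (s = -1) is a subset of ``deleterious`` (s < 0);
    deleterious + neutral + beneficial fractions sum to 1.
    """

    n_mutations: int
    fraction_lethal: float
    fraction_deleterious: float
    fraction_neutral: float
    fraction_beneficial: float
    mean_s_all: float
    mean_s_nonlethal: float
    s_values: Optional[np.ndarray] = None


def measure_DFE(
    pop: "Population",
    land: Landscape,
    mutations_per_individual: int = 100,
    rng: Optional[np.random.Generator] = None,
    keep_s: bool = False,
) -> DFESummary:
    """DFE of random single point mutations applied to every viable member.

    Each viable individual receives ``mutations_per_individual``
    independent single-site mutations (uniform site, uniform alternative
    allele); effects are ``s = w'/w - 1`` with lethal s = -1, neutral
    s = 0 (within a 1e-12 guard) and beneficial s > 0.
    """
    rng = rng or np.random.default_rng()
    n_sym = len(alphabet_symbols(pop.alphabet))
    w = land.fitness_many(pop.codes)
    viable = np.nonzero(w > 0)[0]
    if viable.size == 0:
        raise ValueError("no viable members to mutate")
    s_all = []
    k = mutations_per_individual
    for i in viable:
        row = pop.codes[i]
        sites = rng.integers(0, pop.L, k)
        offsets = rng.integers(1, n_sym, k, dtype=np.uint8)
        variants = np.repeat(row[None, :], k, axis=0)
        variants[np.arange(k), sites] = (variants[np.arange(k), sites] + offsets) % n_sym
        wprime = land.fitness_many(variants)
        s_all.append(wprime / w[i] - 1.0)
    s = np.concatenate(s_all)
    lethal = s == -1.0
    neutral = np.abs(s) < _NEUTRAL_TOL
    beneficial = s > _NEUTRAL_TOL
    deleterious = s < -_NEUTRAL_TOL
    nonlethal = s[~lethal]
    return DFESummary(
        n_mutations=s.size,
        fraction_lethal=float(lethal.mean()),
        fraction_deleterious=float(deleterious.mean()),
        fraction_neutral=float(neutral.mean()),
        fraction_beneficial=float(beneficial.mean()),
        mean_s_all=float(s.mean()),
        mean_s_nonlethal=float(nonlethal.mean()) if nonlethal.size else np.nan,
        s_values=s if keep_s else None,
    )
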
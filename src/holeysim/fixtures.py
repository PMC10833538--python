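"""Synthetic fixtures: toy landscapes, scripted scenarios, a fake folder.

Everything the test suite and worked examples need is generated here, with
no external data and no thermodynamic folding engine required:

* a five-locus holey landscape reproducing the classic worked example of
  two allopatric populations whose divergent alleles are incompatible in
  each other's background;
* four-locus scripted divergence histories illustrating which introgressed
  genotypes have or have not been tested by natural selection;
* seeded random explicit landscapes over fully enumerable genotype spaces;
* :class:`FakeFolder`, a deterministic stand-in for the RNA folding engine
  drawing structures from a fixed pool with controllable base-pair counts,
  so the structure-matching fitness function is testable exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .folding import base_pair_count, base_pair_distance
from .genotypes import Genotype, random_genotype
from .landscapes import ExplicitLandscape

__all__ = [
    "FixtureSpec",
    "FakeFolder",
    "ScenarioHistory",
    "make_five_locus_example",
    "make_scenario_histories",
    "make_random_explicit_landscape",
    "make_rna_ancestor",
    "viable_network_connected",
]


# -- Connectivity -----------------------------------------------------------


def viable_network_connected(land: ExplicitLandscape) -> bool:
    """True when the viable genotypes form one mutationally connected network."""
    from .genotypes import alphabet_symbols, iter_all_genotypes, neighbor_codes

    viable = [
        g for g in iter_all_genotypes(land.L, land.alphabet) if land.is_viable(g)
    ]
    if not viable:
        return False
    keys = {g.codes.tobytes() for g in viable}
    seen = {viable[0].codes.tobytes()}
    frontier = [viable[0]]
    while frontier:
        g = frontier.pop()
        for row in neighbor_codes(g.codes, land.alphabet):
            k = row.tobytes()
            if k in keys and k not in seen:
                seen.add(k)
                frontier.append(Genotype(row, land.alphabet))
    return len(seen) == len(keys)


# -- Five-locus worked example ----------------------------------------------

# Locus convention: sites A..E left to right; 0 = ancestral (lowercase),
# 1 = derived (uppercase).  Population 1 fixed ABcde = 11000, population 2
# fixed abCDE = 00111 after the substitution histories below.
_POP1 = "11000"  # ABcde
_POP2 = "00111"  # abCDE
_SUBSTITUTION_PATH = ["00000", "10000", "11000", "00100", "00110", "00111"]
_II_GENOTYPES = ["10111", "00011"]  # AbCDE, abcDE: the two lethal introgressions
_VIABLE_INTROGRESSIONS = ["01111", "00101", "00110"]  # aBCDE, abCdE, abCDe
_N_INVIABLE = 7  # 7 of the 32 genotypes are inviable (22%)


def make_five_locus_example() -> tuple[ExplicitLandscape, tuple[Genotype, Genotype]]:
    """Five-locus landscape with two incompatible introgressions.

    Two populations diverge from the all-ancestral genotype: population 1
    substitutes derived alleles at the first two loci (ABcde), population 2
    at the last three (abCDE).  Introgressing population 1's divergent
    alleles into population 2 one at a time yields exactly two inviable
    genotypes (alleles A and c are deleterious in population 2's
    background), while the full substitution path -- including the
    transitional abCDe genotype -- is viable.  The landscape has 7 inviable
    genotypes out of 32; the facts above pin 11 of the verdicts and the
    remainder are filled deterministically, keeping the viable network
    connected.

    Returns the landscape and the monomorphic genotype pair
    (population 1 = ABcde, population 2 = abCDE).
    """
    pinned_viable = set(_SUBSTITUTION_PATH) | set(_VIABLE_INTROGRESSIONS) | {
        _POP1,
        _POP2,
    }
    pinned_inviable = set(_II_GENOTYPES)
    free = [
        f"{i:05b}"
        for i in range(32)
        if f"{i:05b}" not in pinned_viable and f"{i:05b}" not in pinned_inviable
    ]
    needed = _N_INVIABLE - len(pinned_inviable)
    rng = np.random.default_rng(5)  # fixed: the fill is arbitrary but frozen
    order = list(rng.permutation(free))
    for extra in _choose_connected(order, pinned_inviable, needed):
        inviable = pinned_inviable | set(extra)
        land = ExplicitLandscape(5, "binary", inviable=sorted(inviable))
        if viable_network_connected(land):
            return land, (Genotype(_POP1, "binary"), Genotype(_POP2, "binary"))
    raise RuntimeError("could not construct a connected worked-example landscape")


def _choose_connected(order, pinned, needed):
    # try the frozen shuffle first, then rotations, until connectivity holds
    for shift in range(len(order)):
        rotated = order[shift:] + order[:shift]
        yield rotated[:needed]


# -- Scripted tested/untested scenarios -------------------------------------


@dataclass
class ScenarioHistory:
    """A scripted pair of substitution histories at four diallelic loci.

    ``untested`` are the introgressed genotypes (single donor alleles in
    the recipient background) never visited by either lineage -- the k - 1
    combinations natural selection has not screened; ``tested`` is the one
    introgressed genotype that lies on a lineage's own substitution path.
    """

    kind: str
    donor_history: list[str]
    recipient_history: list[str]
    untested: set[str]
    tested: set[str]

    @property
    def donor(self) -> str:
        return self.donor_history[-1]

    @property
    def recipient(self) -> str:
        return self.recipient_history[-1]

    @property
    def k(self) -> int:
        return sum(a != b for a, b in zip(self.donor, self.recipient))


def make_scenario_histories(kind: str) -> ScenarioHistory:
    """Scripted divergence histories at L = 4 loci (scenario A or B).

    Scenario A: the donor fixes all four derived alleles (1111) while the
    recipient retains the ancestral genotype (0000).  Of the four
    single-allele introgressions, three (0100, 0010, 0001) are untested
    and one (1000) was visited by the donor's own history.

    Scenario B: each lineage fixes two derived alleles (recipient 1010,
    donor 0101).  Again three introgressed genotypes are untested and one
    (1000) was visited by the recipient's history.
    """
    if kind == "A":
        return ScenarioHistory(
            kind="A",
            donor_history=["0000", "1000", "1100", "1110", "1111"],
            recipient_history=["0000"],
            untested={"0100", "0010", "0001"},
            tested={"1000"},
        )
    if kind == "B":
        return ScenarioHistory(
            kind="B",
            donor_history=["0000", "0100", "0101"],
            recipient_history=["0000", "1000", "1010"],
            untested={"0010", "1110", "1011"},
            tested={"1000"},
        )
    raise ValueError("scenario kind must be 'A' or 'B'")


# -- Random explicit landscapes ---------------------------------------------


@dataclass
class FixtureSpec:
    """Specification of a seeded random explicit landscape."""

    L: int
    alphabet: str = "binary"
    viable_fraction: float = 0.7
    seed: int = 0
    require_connected: bool = False


def make_random_explicit_landscape(spec: FixtureSpec) -> ExplicitLandscape:
    """Enumerate all genotypes and assign seeded Bernoulli viability.

    Guards against genotype spaces larger than 2^20.  When connectivity is
    requested the seed is advanced until the viable network is connected
    (verified by graph search).
    """
    from .genotypes import alphabet_symbols, iter_all_genotypes

    n = len(alphabet_symbols(spec.alphabet))
    total = n**spec.L
    if total > 2**20:
        raise ValueError(f"genotype space of {total} is too large to enumerate")
    seed = spec.seed
    for _ in range(100):
        rng = np.random.default_rng(seed)
        verdicts = rng.random(total) < spec.viable_fraction
        inviable = [
            g.sequence
            for g, ok in zip(iter_all_genotypes(spec.L, spec.alphabet), verdicts)
            if not ok
        ]
        land = ExplicitLandscape(spec.L, spec.alphabet, inviable=inviable)
        land.viable_fraction = 1.0 - len(inviable) / total  # type: ignore[attr-defined]
        if not spec.require_connected or viable_network_connected(land):
            return land
        seed += 1
    raise RuntimeError("no connected landscape found in 100 seeds")


# -- Fake folding oracle ----------------------------------------------------


def _hairpin(L: int, stem: int, offset: int) -> str:
    """Dot-bracket hairpin with ``stem`` pairs and a 3-nt loop at ``offset``."""
    body = "(" * stem + "." * 3 + ")" * stem
    if offset + len(body) > L:
        raise ValueError("hairpin does not fit")
    return "." * offset + body + "." * (L - offset - len(body))


class FakeFolder:
    """Deterministic stand-in structure provider for tests.

    Maps each sequence, via a keyed hash, to a structure drawn from a
    small fixed pool of hairpins.  A fraction ``low_beta_fraction`` of
    sequences receive structures with few base pairs (below any sensible
    viability threshold), the rest receive structures near a designated
    reference; this makes the expected robustness of a landscape built on
    the stub directly configurable.  Conforms to the StructureProvider
    contract: deterministic, cache-transparent.
    """

    def __init__(
        self,
        L: int = 100,
        seed: int = 0,
        low_beta_fraction: float = 0.3,
        good_stems: tuple[int, ...] = (16, 17, 18, 19, 20),
        bad_stems: tuple[int, ...] = (2, 3, 4),
    ):
        self.L = L
        self.seed = seed
        self.low_beta_fraction = float(low_beta_fraction)
        self.good_pool = [_hairpin(L, s, 0) for s in good_stems]
        self.bad_pool = [_hairpin(L, s, L - 2 * s - 3 - 1) for s in bad_stems]
        # precomputed pool statistics (beta per structure, delta between members)
        self.pool_beta = {
            s: base_pair_count(s) for s in self.good_pool + self.bad_pool
        }
        self.reference = self.good_pool[-1]
        self.pool_delta = {
            s: base_pair_distance(s, self.reference)
            for s in self.good_pool + self.bad_pool
        }
        self._cache: dict[str, str] = {}

    def _digest(self, sequence: str, salt: bytes) -> int:
        h = hashlib.blake2b(
            sequence.encode(), key=self.seed.to_bytes(8, "little"), salt=salt
        )
        return int.from_bytes(h.digest()[:8], "little")

    def fold(self, sequence: str) -> str:
        cached = self._cache.get(sequence)
        if cached is not None:
            return cached
        if len(sequence) != self.L:
            raise ValueError(f"FakeFolder is configured for length {self.L}")
        u = self._digest(sequence, b"class") / 2.0**64
        pool = self.bad_pool if u < self.low_beta_fraction else self.good_pool
        structure = pool[self._digest(sequence, b"index") % len(pool)]
        self._cache[sequence] = structure
        return structure


# -- RNA ancestor -----------------------------------------------------------


def make_rna_ancestor(
    L: int = 100,
    alpha: int = 12,
    rng: Optional[np.random.Generator] = None,
    folder=None,
    cap: int = 10_000,
) -> tuple[Genotype, str]:
    """Random viable RNA ancestor and its MFE structure as the reference.

    Random sequences are rejection-sampled until one folds into a structure
    with more than ``alpha`` base pairs; that structure becomes the
    reference, so the ancestor has structural distance 0 and fitness
    exactly 1.
    """
    rng = rng or np.random.default_rng()
    if folder is None:
        from .folding import ViennaFolder

        folder = ViennaFolder()
    for _ in range(cap):
        g = random_genotype(L, "rna", rng)
        structure = folder.fold(g.sequence)
        if base_pair_count(structure) > alpha:
            return g, structure
    raise RuntimeError(f"no viable ancestor found in {cap} draws")
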
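"""Holey fitness landscapes and genotype-level robustness.

Three backends share one interface:

* :class:`RussianRouletteLandscape` -- every genotype independently viable
  with probability ``p`` (a random holey landscape / neutral network).
* :class:`RNALandscape` -- fitness from the match between a sequence's MFE
  secondary structure and a reference structure.
* :class:`ExplicitLandscape` -- a fully enumerated viability/fitness table,
  used for worked examples and exact tests.

On a holey landscape every viable genotype has the same *viability*, but
the proportion ``nu`` of its mutational neighbors that are viable -- its
mutational robustness -- varies, and drives the expected number of
incompatible introgressions between diverging populations:
``II(k) = (1 - nu_tilde) * (k - 1)`` where
``nu_tilde = (nu * L - 1) / (L - 1)`` discounts the one neighbor known to
be viable (the other population's previous backgrounds).
"""

from __future__ import annotations

import warnings
from abc import ABC, abstractmethod
from typing import Iterable

import numpy as np

from .folding import StructureProvider, base_pair_count, base_pair_distance
from .genotypes import (
    Genotype,
    alphabet_symbols,
    decode,
    encode,
    neighbor_codes,
)

__all__ = [
    "Landscape",
    "RussianRouletteLandscape",
    "RNALandscape",
    "ExplicitLandscape",
    "rr_is_viable",
    "rna_fitness",
    "percolation_threshold",
    "genotype_robustness",
    "nu_tilde",
    "expected_II",
]


def percolation_threshold(L: int) -> float:
    """Critical viability probability ``p_c ~= 1/L`` for diallelic genomes.

    Below ``p_c`` the neutral network of a random holey landscape breaks
    into many small disconnected subnetworks; above it one giant component
    contains most viable genotypes.
    """
    if L < 2:
        raise ValueError("percolation threshold requires L >= 2")
    return 1.0 / L


def nu_tilde(nu: float, L: int) -> float:
    """Robustness discounting the one neighbor known a priori to be viable.

    ``nu_tilde = (nu * L - 1) / (L - 1)``, clipped to [0, 1].  Sampled
    ``nu`` can fall below ``1/L`` in finite samples; the value is clipped
    (with a warning) rather than rejected because the linear theory treats
    it as a curve parameter, not a validator.
    """
    if nu < 1.0 / L:
        warnings.warn(
            f"nu={nu:g} below 1/L={1.0 / L:g}; nu_tilde clipped to 0",
            stacklevel=2,
        )
    return float(np.clip((nu * L - 1.0) / (L - 1.0), 0.0, 1.0))


def expected_II(k: int, nu: float, L: int) -> float:
    """Expected incompatible introgressions at divergence ``k`` (linear theory).

    ``II(k) = (1 - nu_tilde) * (k - 1)``: of the ``k`` divergent alleles,
    ``k - 1`` have not been tested by selection in the recipient background,
    and each is incompatible with probability ``1 - nu_tilde``.
    """
    if k < 1:
        raise ValueError("expected_II is defined for k >= 1")
    return (1.0 - nu_tilde(nu, L)) * (k - 1)


class Landscape(ABC):
    """Viability/fitness oracle over fixed-length genotypes."""

    alphabet: str
    L: int

    @abstractmethod
    def fitness_many(self, codes: np.ndarray) -> np.ndarray:
        """Fitness of each row of an ``(M, L)`` uint8 code matrix."""

    def fitness(self, g: Genotype) -> float:
        self._check(g)
        return float(self.fitness_many(g.codes[None, :])[0])

    def viable_many(self, codes: np.ndarray) -> np.ndarray:
        return self.fitness_many(codes) > 0.0

    def is_viable(self, g: Genotype) -> bool:
        return self.fitness(g) > 0.0

    def _check(self, g: Genotype) -> None:
        if g.alphabet != self.alphabet:
            raise ValueError(
                f"genotype alphabet {g.alphabet!r} does not match "
                f"landscape alphabet {self.alphabet!r}"
            )
        if len(g) != self.L:
            raise ValueError(f"genotype length {len(g)} != landscape L {self.L}")


# -- Russian roulette -------------------------------------------------------

_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)
_GOLDEN = np.uint64(0x9E3779B97F4A7C15)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer; avalanches every input bit into every output bit."""
    x = (x ^ (x >> np.uint64(30))) * _M1
    x = (x ^ (x >> np.uint64(27))) * _M2
    return x ^ (x >> np.uint64(31))


class RussianRouletteLandscape(Landscape):
    """Random holey landscape: each genotype viable with probability ``p``.

    The verdict for a genotype is a pure function of ``(landscape_seed,
    genotype)``: the genotype's bits are packed into a 64-bit key and passed
    through a seeded SplitMix64 avalanche, and the genotype is viable when
    the resulting uniform deviate falls below ``p``.  This is O(1) memory
    (no table of 2^L verdicts), bit-reproducible across processes, and
    statistically independent across genotypes and across seeds.
    """

    alphabet = "binary"

    def __init__(self, L: int, p: float, landscape_seed: int):
        if not 0.0 < p < 1.0:
            raise ValueError("viability probability p must lie in (0, 1)")
        if not 2 <= L <= 64:
            raise ValueError("Russian roulette landscape supports 2 <= L <= 64")
        if p <= percolation_threshold(L):
            warnings.warn(
                f"p={p:g} is at or below the percolation threshold "
                f"1/L={1.0 / L:g}; the neutral network is fragmented",
                stacklevel=2,
            )
        self.L = int(L)
        self.p = float(p)
        self.landscape_seed = int(landscape_seed)
        self._seed_mix = _splitmix64(
            np.array([np.uint64(self.landscape_seed & 0xFFFFFFFFFFFFFFFF)])
        )[0]
        # p as a 64-bit threshold; double precision gives ~1e-16 relative error
        self._threshold = np.uint64(min(int(p * 2.0**64), 2**64 - 1))
        self._shifts = np.arange(self.L, dtype=np.uint64)

    def _keys(self, codes: np.ndarray) -> np.ndarray:
        bits = codes.astype(np.uint64) << self._shifts
        return bits.sum(axis=1, dtype=np.uint64)

    def viable_many(self, codes: np.ndarray) -> np.ndarray:
        if codes.shape[1] != self.L:
            raise ValueError("code matrix width does not match landscape L")
        h = _splitmix64((self._keys(codes) + _GOLDEN) ^ self._seed_mix)
        return h < self._threshold

    def fitness_many(self, codes: np.ndarray) -> np.ndarray:
        return self.viable_many(codes).astype(float)


def rr_is_viable(g: Genotype, land: RussianRouletteLandscape) -> bool:
    """Deterministic viability verdict of the Russian roulette landscape."""
    land._check(g)
    return bool(land.viable_many(g.codes[None, :])[0])


# -- RNA folding ------------------------------------------------------------


class RNALandscape(Landscape):
    """Fitness from RNA secondary structure.

    A sequence with MFE structure at base-pair distance ``delta`` from the
    reference structure, and ``beta`` base pairs of its own, has fitness::

        w = 1 - sigma * delta    if beta > alpha >= delta
        w = 0                    otherwise

    ``sigma`` is the selection strength per unit of structural distance and
    ``alpha`` is the viability threshold: structures too far from the
    reference (delta > alpha) or with too few pairs (beta <= alpha) are
    holes in the landscape.
    """

    alphabet = "rna"

    def __init__(
        self,
        reference_structure: str,
        sigma: float = 0.025,
        alpha: int = 12,
        folder: StructureProvider | None = None,
    ):
        if folder is None:
            from .folding import ViennaFolder

            folder = ViennaFolder()
        self.reference_structure = reference_structure
        self.L = len(reference_structure)
        self.sigma = float(sigma)
        self.alpha = int(alpha)
        self.folder = folder
        self._fitness_cache: dict[str, float] = {}

    def fitness_of_sequence(self, sequence: str) -> float:
        w = self._fitness_cache.get(sequence)
        if w is not None:
            return w
        structure = self.folder.fold(sequence)
        beta = base_pair_count(structure)
        delta = base_pair_distance(structure, self.reference_structure)
        if beta > self.alpha >= delta:
            w = 1.0 - self.sigma * delta
        else:
            w = 0.0
        self._fitness_cache[sequence] = w
        return w

    def fitness_many(self, codes: np.ndarray) -> np.ndarray:
        if codes.shape[1] != self.L:
            raise ValueError("code matrix width does not match landscape L")
        return np.array(
            [self.fitness_of_sequence(decode(row, "rna")) for row in codes]
        )


def rna_fitness(g: Genotype, land: RNALandscape) -> float:
    """Fitness of an RNA genotype under the structure-matching landscape."""
    land._check(g)
    return land.fitness_of_sequence(g.sequence)


# -- Explicit table (fixture backend) ---------------------------------------


class ExplicitLandscape(Landscape):
    """Enumerated viability/fitness table over a small genotype space.

    Constructed either from a set of inviable genotypes (all others viable
    with fitness 1) or from a full genotype -> fitness table.  Membership
    queries are exact.
    """

    def __init__(
        self,
        L: int,
        alphabet: str,
        inviable: Iterable[Genotype | str] | None = None,
        fitness_table: dict[str, float] | None = None,
    ):
        self.L = int(L)
        self.alphabet = alphabet
        if (inviable is None) == (fitness_table is None):
            raise ValueError("provide exactly one of inviable or fitness_table")
        if inviable is not None:
            self._table: dict[bytes, float] | None = None
            self._inviable = {
                self._key(g) for g in inviable
            }
        else:
            assert fitness_table is not None
            self._inviable = set()
            self._table = {
                encode(seq, alphabet).tobytes(): float(w)
                for seq, w in fitness_table.items()
            }

    def _key(self, g: Genotype | str) -> bytes:
        if isinstance(g, Genotype):
            return g.codes.tobytes()
        return encode(g, self.alphabet).tobytes()

    def fitness_of_key(self, key: bytes) -> float:
        if self._table is not None:
            try:
                return self._table[key]
            except KeyError:
                raise KeyError("genotype not present in explicit fitness table")
        return 0.0 if key in self._inviable else 1.0

    def fitness_many(self, codes: np.ndarray) -> np.ndarray:
        if codes.shape[1] != self.L:
            raise ValueError("code matrix width does not match landscape L")
        return np.array([self.fitness_of_key(row.tobytes()) for row in codes])

    # Plain-text serialization: two header lines (L, alphabet), then one
    # genotype per line with its fitness, tab-separated.
    def to_text(self) -> str:
        from .genotypes import iter_all_genotypes

        lines = [f"#L\t{self.L}", f"#alphabet\t{self.alphabet}"]
        for g in iter_all_genotypes(self.L, self.alphabet):
            w = self.fitness_of_key(g.codes.tobytes())
            lines.append(f"{g.sequence}\t{w:g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ExplicitLandscape":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if len(lines) < 2 or not lines[0].startswith("#L") or not lines[1].startswith(
            "#alphabet"
        ):
            raise ValueError("malformed explicit landscape header")
        L = int(lines[0].split("\t")[1])
        alphabet = lines[1].split("\t")[1].strip()
        table = {}
        for ln in lines[2:]:
            seq, w = ln.split("\t")
            table[seq] = float(w)
        land = cls(L, alphabet, fitness_table=table)
        n = len(alphabet_symbols(alphabet))
        if len(table) != n**L:
            warnings.warn(
                f"explicit landscape table has {len(table)} rows; full "
                f"enumeration would have {n ** L}",
                stacklevel=2,
            )
        return land

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "ExplicitLandscape":
        with open(path) as fh:
            return cls.from_text(fh.read())


# -- Robustness -------------------------------------------------------------


def genotype_robustness(g: Genotype, land: Landscape) -> float:
    """Proportion ``nu`` of single-mutation neighbors that are viable.

    Defined only for viable genotypes ("not inviable" is the criterion, so
    under the RNA model any neighbor with w > 0 counts as viable).
    """
    land._check(g)
    if not land.is_viable(g):
        raise ValueError("robustness nu is undefined for an inviable genotype")
    nbrs = neighbor_codes(g.codes, g.alphabet)
    return float(land.viable_many(nbrs).mean())


def robustness_many(codes: np.ndarray, alphabet: str, land: Landscape) -> np.ndarray:
    """Vectorized ``nu`` for each row of a viable code matrix."""
    M, L = codes.shape
    n = len(alphabet_symbols(alphabet))
    if n == 2:  # binary fast path: flip one site per neighbor row
        nbrs = np.repeat(codes, L, axis=0)
        sites = np.tile(np.arange(L), M)
        nbrs[np.arange(M * L), sites] ^= 1
        return land.viable_many(nbrs).reshape(M, L).mean(axis=1)
    all_nbrs = np.concatenate(
        [neighbor_codes(row, alphabet) for row in codes], axis=0
    )
    viable = land.viable_many(all_nbrs).reshape(M, L * (n - 1))
    return viable.mean(axis=1)
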
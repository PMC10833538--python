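"""RNA secondary-structure providers.

The fitness of an RNA genotype depends on its minimum free-energy (MFE)
secondary structure.  Structure prediction is abstracted behind the
:class:`StructureProvider` contract so that measurement and evolution code
can run against either the real thermodynamic folding engine (ViennaRNA,
default parameters) or a deterministic stub (see
:mod:`holeysim.fixtures`).

Providers memoize sequence -> structure: populations near equilibrium
revisit the same genotypes heavily and folding is by far the most expensive
operation in the RNA model.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable


@runtime_checkable
class StructureProvider(Protocol):
    """Maps an RNA sequence to its MFE dot-bracket structure.

    Implementations must be deterministic: the same sequence always yields
    the same structure, whether or not the call is served from cache.
    """

    def fold(self, sequence: str) -> str:  # pragma: no cover - protocol
        ...


def parse_pairs(structure: str) -> frozenset[tuple[int, int]]:
    """Base-pair set of a dot-bracket structure as (i, j) index pairs, i < j."""
    stack: list[int] = []
    pairs = set()
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced structure: {structure!r}")
            pairs.add((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"invalid dot-bracket symbol {c!r}")
    if stack:
        raise ValueError(f"unbalanced structure: {structure!r}")
    return frozenset(pairs)


def base_pair_count(structure: str) -> int:
    """Number of base pairs (beta) in a dot-bracket structure."""
    return structure.count("(")


def base_pair_distance(s1: str, s2: str) -> int:
    """Base-pair distance: size of the symmetric difference of pair sets.

    This is the standard structure distance of the RNA folding ecosystem; it
    equals the number of pairs that would have to be opened plus the number
    that would have to be formed to turn one structure into the other.
    """
    if len(s1) != len(s2):
        raise ValueError("structures must have equal length")
    return len(parse_pairs(s1) ^ parse_pairs(s2))


class ViennaFolder:
    """MFE folding via the ViennaRNA python bindings, with memoization.

    Uses default thermodynamic parameters.  The cache is unbounded; its size
    is the number of distinct sequences seen, which stays modest in
    equilibrated populations.
    """

    def __init__(self):
        try:
            import RNA  # ViennaRNA python bindings
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "the ViennaRNA python bindings are required for the "
                "thermodynamic folding backend"
            ) from exc
        self._RNA = RNA
        self._cache: dict[str, str] = {}

    def fold(self, sequence: str) -> str:
        cached = self._cache.get(sequence)
        if cached is not None:
            return cached
        try:
            structure, _mfe = self._RNA.fold(sequence)
        except Exception as exc:  # pragma: no cover - engine failure
            raise RuntimeError(f"folding failed for sequence {sequence!r}") from exc
        self._cache[sequence] = structure
        return structure

    @property
    def cache_size(self) -> int:
        return len(self._cache)
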
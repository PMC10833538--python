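"""Fixed-length haploid genotypes over small alphabets.

Genotypes are value objects: two genotypes with the same sequence compare
equal and hash equal, which the landscape backends rely on for caching and
for deterministic viability verdicts.  Internally sequences are stored as
``uint8`` code arrays (index into the alphabet); population-level code in
:mod:`holeysim.evolution` operates on stacked ``(N, L)`` code matrices and
only materializes :class:`Genotype` objects at API boundaries.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np

BINARY = "01"
RNA_ALPHABET = "ACGU"

_ALPHABETS = {"binary": BINARY, "rna": RNA_ALPHABET}


def alphabet_symbols(alphabet: str) -> str:
    """Return the symbol string for a named alphabet (``binary`` or ``rna``)."""
    try:
        return _ALPHABETS[alphabet]
    except KeyError:
        raise ValueError(f"unknown alphabet {alphabet!r}; expected 'binary' or 'rna'")


def encode(sequence: str, alphabet: str) -> np.ndarray:
    """Encode a sequence string into a uint8 code array."""
    symbols = alphabet_symbols(alphabet)
    lookup = {c: i for i, c in enumerate(symbols)}
    try:
        return np.array([lookup[c] for c in sequence], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"symbol {exc.args[0]!r} not in alphabet {alphabet!r}")


def decode(codes: np.ndarray, alphabet: str) -> str:
    """Decode a uint8 code array back into a sequence string."""
    symbols = alphabet_symbols(alphabet)
    return "".join(symbols[c] for c in codes)


class Genotype:
    """An immutable fixed-length sequence over a declared alphabet.

    Parameters
    ----------
    sequence:
        Either a string over the alphabet's symbols or a uint8 code array.
    alphabet:
        ``"binary"`` ({0, 1}) or ``"rna"`` ({A, C, G, U}).
    """

    __slots__ = ("_codes", "alphabet")

    def __init__(self, sequence: str | Sequence[int] | np.ndarray, alphabet: str):
        symbols = alphabet_symbols(alphabet)
        if isinstance(sequence, str):
            codes = encode(sequence, alphabet)
        else:
            codes = np.asarray(sequence, dtype=np.uint8)
            if codes.ndim != 1:
                raise ValueError("genotype codes must be one-dimensional")
            if codes.size and codes.max() >= len(symbols):
                raise ValueError(f"code out of range for alphabet {alphabet!r}")
        codes.setflags(write=False)
        self._codes = codes
        self.alphabet = alphabet

    @property
    def codes(self) -> np.ndarray:
        """Read-only uint8 code array."""
        return self._codes

    @property
    def sequence(self) -> str:
        return decode(self._codes, self.alphabet)

    @property
    def L(self) -> int:
        return self._codes.size

    def __len__(self) -> int:
        return self._codes.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        return self.alphabet == other.alphabet and np.array_equal(
            self._codes, other._codes
        )

    def __hash__(self) -> int:
        return hash((self.alphabet, self._codes.tobytes()))

    def __repr__(self) -> str:
        return f"Genotype({self.sequence!r}, {self.alphabet!r})"

    def with_allele(self, site: int, code: int) -> "Genotype":
        """Return a copy carrying ``code`` at ``site`` (an introgression)."""
        codes = self._codes.copy()
        codes[site] = code
        return Genotype(codes, self.alphabet)


def random_genotype(L: int, alphabet: str, rng: np.random.Generator) -> Genotype:
    """Draw a uniform random genotype of length ``L``."""
    n = len(alphabet_symbols(alphabet))
    return Genotype(rng.integers(0, n, L, dtype=np.uint8), alphabet)


def mutational_neighbors(g: Genotype) -> list[Genotype]:
    """All genotypes reachable from ``g`` by a mutation at a single site.

    Returns ``L * (|alphabet| - 1)`` distinct genotypes; ``g`` itself is
    excluded.
    """
    return [
        Genotype(row, g.alphabet) for row in neighbor_codes(g.codes, g.alphabet)
    ]


def neighbor_codes(codes: np.ndarray, alphabet: str) -> np.ndarray:
    """Code matrix of all single-site variants of ``codes``.

    Shape ``(L * (n_symbols - 1), L)``, ordered by site then by allele code.
    """
    n = len(alphabet_symbols(alphabet))
    L = codes.size
    out = np.repeat(codes[None, :], L * (n - 1), axis=0)
    row = 0
    for site in range(L):
        for code in range(n):
            if code == codes[site]:
                continue
            out[row, site] = code
            row += 1
    return out


def iter_all_genotypes(L: int, alphabet: str) -> Iterator[Genotype]:
    """Enumerate all ``|alphabet|^L`` genotypes in lexicographic code order."""
    n = len(alphabet_symbols(alphabet))
    codes = np.zeros(L, dtype=np.uint8)
    while True:
        yield Genotype(codes.copy(), alphabet)
        for i in range(L - 1, -1, -1):
            if codes[i] < n - 1:
                codes[i] += 1
                break
            codes[i] = 0
        else:
            return
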
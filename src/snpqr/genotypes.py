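"""Diploid genotype calls at a single marker.

A genotype is an unordered pair of allele symbols, or missing.  The symbol
alphabet is the four nucleotides plus ``D``/``I`` for deletion/insertion
alleles as reported by direct-to-consumer (DTC) array exports.  The pair is
stored in the order it was observed (a DTC file's ``GA`` stays ``GA``) so
that downstream concordance checking can distinguish a byte-identical match
from a permuted one, but equality and hashing are order-insensitive.
"""

from __future__ import annotations

from typing import Optional, Tuple

#: Allele symbols a genotype may carry.
ALLELE_ALPHABET = frozenset("ACGTDI")

#: Symbol used for a missing allele in serialized payloads and DTC files.
MISSING_CHAR = "-"


class Genotype:
    """An unordered diploid allele pair, or the missing call.

    Parameters
    ----------
    alleles
        A pair of allele symbols from :data:`ALLELE_ALPHABET`, or ``None``
        for a missing call.
    """

    __slots__ = ("_alleles",)

    def __init__(self, alleles: Optional[Tuple[str, str]] = None):
        if alleles is not None:
            a, b = alleles
            for symbol in (a, b):
                if symbol not in ALLELE_ALPHABET:
                    raise ValueError(f"invalid allele symbol {symbol!r}")
            self._alleles = (a, b)
        else:
            self._alleles = None

    # -- constructors -------------------------------------------------
    @classmethod
    def missing(cls) -> "Genotype":
        return cls(None)

    @classmethod
    def from_token(cls, token: str) -> "Genotype":
        """Parse a two-character payload token (``"GA"``, ``"--"``)."""
        if len(token) != 2:
            raise ValueError(f"genotype token must have 2 characters, got {token!r}")
        if token == MISSING_CHAR * 2:
            return cls(None)
        if MISSING_CHAR in token:
            raise ValueError(f"half-missing genotype token {token!r}")
        return cls((token[0], token[1]))

    # -- views ---------------------------------------------------------
    @property
    def is_missing(self) -> bool:
        return self._alleles is None

    @property
    def alleles(self) -> Optional[Tuple[str, str]]:
        """The allele pair in observed order, or ``None`` if missing."""
        return self._alleles

    @property
    def pair(self) -> Optional[Tuple[str, str]]:
        """The allele pair in sorted (canonical) order, or ``None``."""
        if self._alleles is None:
            return None
        return tuple(sorted(self._alleles))  # type: ignore[return-value]

    @property
    def token(self) -> str:
        """Two-character token in observed order (``"--"`` if missing)."""
        if self._alleles is None:
            return MISSING_CHAR * 2
        return "".join(self._alleles)

    @property
    def canonical_token(self) -> str:
        """Two-character token with alleles in lexicographic order."""
        if self._alleles is None:
            return MISSING_CHAR * 2
        return "".join(sorted(self._alleles))

    def is_het(self) -> bool:
        if self._alleles is None:
            raise ValueError("heterozygosity undefined for a missing genotype")
        return self._alleles[0] != self._alleles[1]

    def count(self, allele: str) -> int:
        """Number of copies of ``allele`` carried (0 for missing calls)."""
        if self._alleles is None:
            return 0
        return self._alleles.count(allele)

    # -- equality: order-insensitive ----------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        return self.pair == other.pair

    def __hash__(self) -> int:
        return hash(self.pair)

    def __repr__(self) -> str:
        return f"Genotype({self.token!r})"


MISSING = Genotype.missing()
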
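"""Five-scenario genotype matching and fingerprint concordance reports.

Two genotype calls at the same marker match under five scenarios: a perfect
(byte-identical) match, a permuted match (``AG`` vs ``GA``), and three
strand-flip scenarios in which one call equals the Watson-Crick complement
of the other, up to allele order (``AG`` vs ``TC``, ``AC`` vs ``TG``, and
their permutations).  Everything else is a mismatch; pairs with a missing
call are reported separately.  Because fingerprint markers are never A/T or
C/G, a genotype and its complement cannot both legitimately occur on the
same strand, so the strand scenarios are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Optional

from .genotypes import Genotype
from .genotype_io import Fingerprint
from .panel import Panel

__all__ = [
    "MatchClass",
    "ConcordanceReport",
    "complement_genotype",
    "classify_pair",
    "compare_fingerprints",
    "compare_qr_images",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "D": "D", "I": "I"}

#: Default fraction of compared markers that must match for a concordant verdict.
DEFAULT_THRESHOLD = 0.95
#: Minimum non-missing overlap below which no verdict is attempted.
DEFAULT_MIN_OVERLAP = 20


class MatchClass(str, Enum):
    PERFECT = "perfect"
    PERMUTED = "permuted"
    STRAND = "strand"
    STRAND_PERMUTED = "strand_permuted"
    MISMATCH = "mismatch"
    MISSING = "missing"

    @property
    def is_match(self) -> bool:
        return self in (
            MatchClass.PERFECT,
            MatchClass.PERMUTED,
            MatchClass.STRAND,
            MatchClass.STRAND_PERMUTED,
        )


def complement_genotype(g: Genotype) -> Genotype:
    """Watson-Crick complement of each allele; D/I and missing pass through."""
    if g.is_missing:
        return g
    a, b = g.alleles
    return Genotype((_COMPLEMENT[a], _COMPLEMENT[b]))


def classify_pair(g1: Genotype, g2: Genotype) -> MatchClass:
    """Classify a marker genotype pair into one of the match scenarios.

    Precedence: missing, perfect, permuted, strand, strand-permuted,
    mismatch.  Indel (D/I) alleles have no strand complement, so only the
    perfect/permuted scenarios can match them.
    """
    if g1.is_missing or g2.is_missing:
        return MatchClass.MISSING
    if g1.token == g2.token:
        return MatchClass.PERFECT
    if g1.pair == g2.pair:
        return MatchClass.PERMUTED
    if any(a in ("D", "I") for a in g1.alleles + g2.alleles):
        return MatchClass.MISMATCH
    comp = complement_genotype(g2)
    if g1.token == comp.token:
        return MatchClass.STRAND
    if g1.pair == comp.pair:
        return MatchClass.STRAND_PERMUTED
    return MatchClass.MISMATCH


@dataclass
class ConcordanceReport:
    """Aggregated per-marker match classes for a pair of fingerprints."""

    n_markers: int
    n_missing: int
    n_compared: int
    counts: Dict[MatchClass, int] = field(default_factory=dict)
    concordance_rate: float = 0.0
    verdict: str = "inconclusive"
    threshold: float = DEFAULT_THRESHOLD
    min_overlap: int = DEFAULT_MIN_OVERLAP

    @property
    def n_matches(self) -> int:
        return sum(n for cls, n in self.counts.items() if cls.is_match)

    def to_dict(self) -> Dict[str, object]:
        return {
            "n_markers": self.n_markers,
            "n_missing": self.n_missing,
            "n_compared": self.n_compared,
            "perfect": self.counts.get(MatchClass.PERFECT, 0),
            "permuted": self.counts.get(MatchClass.PERMUTED, 0),
            "strand": self.counts.get(MatchClass.STRAND, 0),
            "strand_permuted": self.counts.get(MatchClass.STRAND_PERMUTED, 0),
            "mismatch": self.counts.get(MatchClass.MISMATCH, 0),
            "concordance_rate": self.concordance_rate,
            "verdict": self.verdict,
            "threshold": self.threshold,
        }

    def __str__(self) -> str:
        d = self.to_dict()
        lines = [
            f"markers          : {d['n_markers']}",
            f"missing (either) : {d['n_missing']}",
            f"compared overlap : {d['n_compared']}",
            f"  perfect match  : {d['perfect']}",
            f"  permuted match : {d['permuted']}",
            f"  strand match   : {d['strand']} (+ {d['strand_permuted']} permuted)",
            f"  mismatch       : {d['mismatch']}",
            f"concordance rate : {d['concordance_rate']:.4f}",
            f"verdict          : {d['verdict']} (threshold {d['threshold']})",
        ]
        return "\n".join(lines)


def compare_fingerprints(
    f1: Fingerprint,
    f2: Fingerprint,
    threshold: float = DEFAULT_THRESHOLD,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> ConcordanceReport:
    """Compare two fingerprints marker by marker and aggregate the classes.

    The concordance rate is matches / compared (missing pairs excluded).
    The verdict is ``concordant`` when the rate reaches ``threshold``,
    ``inconclusive`` when fewer than ``min_overlap`` markers could be
    compared, else ``discordant``.
    """
    if len(f1) != len(f2):
        raise ValueError(f"fingerprint lengths differ: {len(f1)} vs {len(f2)}")
    counts: Dict[MatchClass, int] = {cls: 0 for cls in MatchClass}
    for g1, g2 in zip(f1, f2):
        counts[classify_pair(g1, g2)] += 1
    n_missing = counts.pop(MatchClass.MISSING)
    n_compared = len(f1) - n_missing
    n_matches = sum(n for cls, n in counts.items() if cls.is_match)
    rate = n_matches / n_compared if n_compared else 0.0
    if n_compared < min_overlap:
        verdict = "inconclusive"
    elif rate >= threshold:
        verdict = "concordant"
    else:
        verdict = "discordant"
    return ConcordanceReport(
        n_markers=len(f1),
        n_missing=n_missing,
        n_compared=n_compared,
        counts=counts,
        concordance_rate=rate,
        verdict=verdict,
        threshold=threshold,
        min_overlap=min_overlap,
    )


def compare_qr_images(
    img1,
    img2,
    panel: Panel,
    threshold: float = DEFAULT_THRESHOLD,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> ConcordanceReport:
    """Decode two QR images and compare the underlying fingerprints."""
    from .codec import decode_qr, deserialize

    f1 = deserialize(decode_qr(img1), panel)
    f2 = deserialize(decode_qr(img2), panel)
    return compare_fingerprints(f1, f2, threshold=threshold, min_overlap=min_overlap)
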
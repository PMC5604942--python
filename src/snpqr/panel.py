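"""The identity SNP panel: bundled QRC-80 data and structural validation.

The bundled panel carries 74 fingerprint SNPs — bi-allelic autosomal markers
shared across eight common genotyping arrays, with MAF > 0.25 in each of the
five continental 1000GP populations, strand-unambiguous alleles (never A/T
or C/G) and at least one 10 Mb gap between neighbours — plus four ABO
blood-group SNVs and two chr1/Y-paralogous sex markers used for
single-dataset sanity checks.  Panel data ships as a plain tab-separated
resource so it is auditable and replaceable without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

__all__ = [
    "PanelSNP",
    "Panel",
    "PanelValidationReport",
    "PanelIntegrityError",
    "load_bundled_panel",
    "validate_panel",
    "BUNDLED_PANEL_NAME",
]

BUNDLED_PANEL_NAME = "QRC-80"
_BUNDLED_RESOURCE = "panel_qrc80.tsv"

#: Strand-ambiguous allele pairs: complement-closed, so a flip is undetectable.
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})

#: Symbolic indel alleles map to the D/I tokens used by DTC exports.
_SYMBOLIC_TOKEN = {"del": "D", "ins": "I"}

_VALID_CATEGORIES = ("fingerprint", "abo", "sex")


class PanelIntegrityError(RuntimeError):
    """The bundled panel resource is corrupted or violates its invariants."""


@dataclass(frozen=True)
class PanelSNP:
    """One marker of the identity panel.

    ``ref``/``alt`` are allele symbols in {A,C,G,T} or the symbolic ``del``/
    ``ins`` for indel markers (the ABO exon-6 deletion).  ``raf`` is the
    reference-allele frequency; for fingerprint markers it is the 1000GP
    overall frequency used both for validation and for Hardy-Weinberg
    simulation.
    """

    index: int
    chrom: str
    pos: int
    rsid: str
    ref: str
    alt: str
    raf: float
    category: str = "fingerprint"

    def __post_init__(self):
        if self.category not in _VALID_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.ref == self.alt:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")
        if not 0.0 <= self.raf <= 1.0:
            raise ValueError(f"{self.rsid}: RAF {self.raf} outside [0, 1]")
        if self.category == "fingerprint":
            if not 0.0 < self.raf < 1.0:
                raise ValueError(f"{self.rsid}: fingerprint RAF must be in (0, 1)")
            if self.is_ambiguous:
                raise ValueError(
                    f"{self.rsid}: strand-ambiguous allele pair "
                    f"{self.ref}/{self.alt} not allowed in fingerprint"
                )
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be 1-based")

    @property
    def ref_token(self) -> str:
        """Single-character genotype symbol for the reference allele."""
        return _SYMBOLIC_TOKEN.get(self.ref, self.ref)

    @property
    def alt_token(self) -> str:
        return _SYMBOLIC_TOKEN.get(self.alt, self.alt)

    @property
    def is_ambiguous(self) -> bool:
        """True for A/T and C/G pairs, whose strand cannot be resolved."""
        return {self.ref, self.alt} in _AMBIGUOUS_PAIRS

    @property
    def maf(self) -> float:
        """Overall minor allele frequency, min(raf, 1 - raf)."""
        return min(self.raf, 1.0 - self.raf)

    @property
    def locus(self) -> str:
        return f"{self.chrom}:{self.pos}"


def _chrom_sort_key(chrom: str) -> Tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (100, chrom)


@dataclass
class Panel:
    """An ordered identity panel: fingerprint markers first, then auxiliaries."""

    snps: List[PanelSNP]
    name: str = "unnamed"
    build: str = "b37"
    _by_rsid: Dict[str, PanelSNP] = field(init=False, repr=False)
    _by_locus: Dict[str, PanelSNP] = field(init=False, repr=False)

    def __post_init__(self):
        indices = [s.index for s in self.snps]
        if indices != list(range(1, len(self.snps) + 1)):
            raise ValueError("panel indices must be unique and contiguous from 1")
        fps = self.fingerprint_snps
        keys = [(_chrom_sort_key(s.chrom), s.pos) for s in fps]
        if keys != sorted(keys):
            raise ValueError("fingerprint SNPs must be sorted by (chrom, pos)")
        loci = [s.locus for s in fps]
        if len(set(loci)) != len(loci):
            raise ValueError("duplicate chrom:pos among fingerprint SNPs")
        self._by_rsid = {s.rsid: s for s in self.snps}
        self._by_locus = {s.locus: s for s in self.snps}

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    @property
    def fingerprint_snps(self) -> List[PanelSNP]:
        return [s for s in self.snps if s.category == "fingerprint"]

    @property
    def abo_snps(self) -> List[PanelSNP]:
        return [s for s in self.snps if s.category == "abo"]

    @property
    def sex_snps(self) -> List[PanelSNP]:
        return [s for s in self.snps if s.category == "sex"]

    def get(self, rsid: str) -> Optional[PanelSNP]:
        return self._by_rsid.get(rsid)

    def get_locus(self, locus: str) -> Optional[PanelSNP]:
        return self._by_locus.get(locus)


@dataclass
class PanelValidationReport:
    """Structural health check of a panel against MAF and spacing thresholds."""

    n_fingerprint: int
    n_abo: int
    n_sex: int
    autosomes_covered: set
    min_adjacent_gap_bp: Optional[int]  # None when < 2 SNPs share a chromosome
    min_overall_maf: float
    violations: List[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        lines = [
            f"fingerprint SNPs : {self.n_fingerprint}",
            f"ABO markers      : {self.n_abo}",
            f"sex markers      : {self.n_sex}",
            f"autosomes covered: {len(self.autosomes_covered)}",
            f"min adjacent gap : "
            + ("n/a" if self.min_adjacent_gap_bp is None else f"{self.min_adjacent_gap_bp:,} bp"),
            f"min overall MAF  : {self.min_overall_maf:.3f}",
        ]
        if self.violations:
            lines.append("violations:")
            lines.extend(f"  - {v}" for v in self.violations)
        else:
            lines.append("violations: none")
        return "\n".join(lines)


def _parse_panel_rows(lines: Sequence[str], name: str) -> Panel:
    snps: List[PanelSNP] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 8:
            raise PanelIntegrityError(
                f"panel line {lineno}: expected 8 tab-separated fields, got {len(parts)}"
            )
        try:
            snp = PanelSNP(
                index=int(parts[0]),
                chrom=parts[1],
                pos=int(parts[2]),
                rsid=parts[3],
                ref=parts[4],
                alt=parts[5],
                raf=float(parts[6]),
                category=parts[7],
            )
        except (ValueError, TypeError) as exc:
            raise PanelIntegrityError(f"panel line {lineno}: {exc}") from exc
        snps.append(snp)
    try:
        return Panel(snps=snps, name=name)
    except ValueError as exc:
        raise PanelIntegrityError(str(exc)) from exc


def load_panel_file(path, name: Optional[str] = None) -> Panel:
    """Load a panel from a tab-separated file (see the bundled resource format)."""
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.readlines()
    return _parse_panel_rows(lines, name or str(path))


def load_bundled_panel() -> Panel:
    """Load the bundled 80-marker QRC panel (74 fingerprint + 4 ABO + 2 sex)."""
    text = resources.files("snpqr.data").joinpath(_BUNDLED_RESOURCE).read_text("utf-8")
    panel = _parse_panel_rows(text.splitlines(), BUNDLED_PANEL_NAME)
    if len(panel) != 80 or len(panel.fingerprint_snps) != 74:
        raise PanelIntegrityError(
            f"bundled panel corrupted: {len(panel)} markers, "
            f"{len(panel.fingerprint_snps)} fingerprint (expected 80/74)"
        )
    return panel


def validate_panel(
    panel: Panel,
    min_maf: float = 0.3,
    min_gap_bp: int = 10_000_000,
) -> PanelValidationReport:
    """Check a panel's fingerprint markers against MAF and spacing thresholds.

    The spacing constraint applies to adjacent fingerprint markers on the
    same chromosome; auxiliary (ABO/sex) markers are informational additions
    and are exempt from both thresholds.
    """
    if not panel.snps:
        raise ValueError("cannot validate an empty panel")
    fps = panel.fingerprint_snps
    violations: List[str] = []

    autosomes = {s.chrom for s in fps}
    min_maf_seen = min((s.maf for s in fps), default=math.nan)

    min_gap: Optional[int] = None
    by_chrom: Dict[str, List[PanelSNP]] = {}
    for s in fps:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, snps in by_chrom.items():
        snps = sorted(snps, key=lambda s: s.pos)
        for left, right in zip(snps, snps[1:]):
            gap = right.pos - left.pos
            if min_gap is None or gap < min_gap:
                min_gap = gap
            if gap < min_gap_bp:
                violations.append(
                    f"spacing: {left.rsid} and {right.rsid} on chr{chrom} are "
                    f"{gap:,} bp apart (< {min_gap_bp:,})"
                )
    for s in fps:
        if s.maf < min_maf:
            violations.append(f"maf: {s.rsid} overall MAF {s.maf:.3f} < {min_maf}")

    return PanelValidationReport(
        n_fingerprint=len(fps),
        n_abo=len(panel.abo_snps),
        n_sex=len(panel.sex_snps),
        autosomes_covered=autosomes,
        min_adjacent_gap_bp=min_gap,
        min_overall_maf=min_maf_seen,
        violations=violations,
    )


def write_panel_file(panel: Panel, path) -> None:
    """Write a panel in the bundled tab-separated format."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# panel: {panel.name} (build {panel.build})\n")
        fh.write("# index\tchrom\tpos\trsid\tref\talt\traf\tcategory\n")
        for s in panel:
            fh.write(
                f"{s.index}\t{s.chrom}\t{s.pos}\t{s.rsid}\t{s.ref}\t{s.alt}\t"
                f"{s.raf:g}\t{s.category}\n"
            )
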
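"""Deriving custom identity-SNP panels and array cross-tabulation.

The selection cascade mirrors the one used to build the bundled panel: a
candidate list (CHR:POS keys) is matched against an allele-frequency
reference carrying per-subpopulation frequencies for the five continental
1000GP groups (AFR, EUR, AMR, EAS, SAS) plus an overall frequency; markers
must reach the MAF cutoff in every subpopulation, strand-ambiguous (A/T,
C/G) and user-excluded (e.g. pathogenic) variants are dropped, and one
marker per genomic region is kept — greedily by highest overall MAF, under
a pairwise same-chromosome distance constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .panel import Panel, PanelSNP, _chrom_sort_key

__all__ = [
    "AFRecord",
    "ArrayManifest",
    "DerivationConfig",
    "DerivationLog",
    "SchemaError",
    "load_af_reference",
    "filter_candidates",
    "prune_by_region",
    "derive_panel",
    "cross_tabulate",
    "load_manifest",
    "load_candidates",
]

SUBPOPULATIONS = ("AFR", "EUR", "AMR", "EAS", "SAS")

_AF_COLUMNS = ["CHROM", "POS", "RSID", "REF", "ALT"] + [
    f"AF_{p}" for p in SUBPOPULATIONS
] + ["AF_ALL"]

_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


class SchemaError(ValueError):
    """An input file does not match its declared column schema."""


@dataclass(frozen=True)
class AFRecord:
    """A candidate variant with per-subpopulation and overall allele frequencies."""

    chrom: str
    pos: int
    rsid: str
    ref: str
    alt: str
    af_by_pop: Dict[str, float]
    af_overall: float

    def __post_init__(self):
        missing = set(SUBPOPULATIONS) - set(self.af_by_pop)
        if missing:
            raise ValueError(f"{self.locus}: missing subpopulation AFs {sorted(missing)}")
        for pop, af in self.af_by_pop.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"{self.locus}: {pop} AF {af} outside [0, 1]")
        if not 0.0 <= self.af_overall <= 1.0:
            raise ValueError(f"{self.locus}: overall AF {self.af_overall} outside [0, 1]")

    @property
    def locus(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @property
    def maf_overall(self) -> float:
        return min(self.af_overall, 1.0 - self.af_overall)

    def maf(self, pop: str) -> float:
        af = self.af_by_pop[pop]
        return min(af, 1.0 - af)

    @property
    def is_ambiguous(self) -> bool:
        return {self.ref, self.alt} in _AMBIGUOUS


@dataclass
class ArrayManifest:
    """A named set of variant keys (chrom:pos:ref:alt or rsid) on one array."""

    name: str
    keys: Set[str]

    def __len__(self) -> int:
        return len(self.keys)


@dataclass
class DerivationConfig:
    """Tunable thresholds of the selection cascade.

    ``maf_cutoff`` (default 0.25) applies to every one of the five
    subpopulations; ``region_size_bp`` (default 10 Mb) is the minimum
    same-chromosome distance between selected markers.
    """

    maf_cutoff: float = 0.25
    region_size_bp: int = 10_000_000
    exclusions: Set[str] = field(default_factory=set)
    drop_ambiguous: bool = True

    def __post_init__(self):
        if not 0.0 <= self.maf_cutoff < 0.5:
            raise ValueError(f"maf_cutoff {self.maf_cutoff} outside [0, 0.5)")
        if self.region_size_bp < 0:
            raise ValueError("region_size_bp must be >= 0")


@dataclass
class DerivationLog:
    """Counts in/out at each stage of the cascade."""

    n_candidates: int = 0
    n_not_in_reference: int = 0
    n_failed_maf: int = 0
    n_ambiguous: int = 0
    n_excluded: int = 0
    n_after_filter: int = 0
    n_after_prune: int = 0
    boundary_maf: List[str] = field(default_factory=list)

    def __str__(self) -> str:
        lines = [
            f"candidates            : {self.n_candidates}",
            f"  not in AF reference : {self.n_not_in_reference}",
            f"  failed MAF cutoff   : {self.n_failed_maf}",
            f"  strand-ambiguous    : {self.n_ambiguous}",
            f"  excluded            : {self.n_excluded}",
            f"after frequency filter: {self.n_after_filter}",
            f"after region pruning  : {self.n_after_prune}",
        ]
        if self.boundary_maf:
            lines.append(
                "note: MAF exactly at cutoff (kept): " + ", ".join(self.boundary_maf)
            )
        return "\n".join(lines)


def load_af_reference(path) -> List[AFRecord]:
    """Load a tab-separated allele-frequency reference.

    Required header columns: CHROM, POS, RSID, REF, ALT, AF_AFR, AF_EUR,
    AF_AMR, AF_EAS, AF_SAS, AF_ALL.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"CHROM": str, "RSID": str}, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, expected header {_AF_COLUMNS}") from exc
    missing = [c for c in _AF_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    records: List[AFRecord] = []
    for i, row in df.iterrows():
        try:
            records.append(
                AFRecord(
                    chrom=str(row["CHROM"]),
                    pos=int(row["POS"]),
                    rsid="" if pd.isna(row["RSID"]) else str(row["RSID"]),
                    ref=str(row["REF"]),
                    alt=str(row["ALT"]),
                    af_by_pop={p: float(row[f"AF_{p}"]) for p in SUBPOPULATIONS},
                    af_overall=float(row["AF_ALL"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def load_candidates(path) -> List[str]:
    """Read a candidate list, one CHR:POS key per line ('#' comments)."""
    keys = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                keys.append(line)
    return keys


def load_manifest(path, name: Optional[str] = None) -> ArrayManifest:
    """Read an array manifest, one variant key per line."""
    with open(path, "rt", encoding="utf-8") as fh:
        keys = {line.strip() for line in fh if line.strip() and not line.startswith("#")}
    return ArrayManifest(name=name or str(path), keys=keys)


def filter_candidates(
    candidates: Sequence[str],
    af: Iterable[AFRecord],
    cfg: DerivationConfig,
    log: Optional[DerivationLog] = None,
) -> List[AFRecord]:
    """Frequency/ambiguity/exclusion filtering of a CHR:POS candidate list.

    Retains records whose MAF reaches the cutoff in all five
    subpopulations; candidates absent from the reference are dropped and
    counted.  The cutoff comparison is inclusive (``>=``); exact-boundary
    hits are flagged in the log.
    """
    if log is None:
        log = DerivationLog()
    by_locus = {rec.locus: rec for rec in af}
    log.n_candidates = len(candidates)
    kept: List[AFRecord] = []
    seen: Set[str] = set()
    for key in candidates:
        rec = by_locus.get(key.strip())
        if rec is None:
            log.n_not_in_reference += 1
            continue
        if rec.locus in seen:  # duplicate candidate keys collapse to one
            continue
        seen.add(rec.locus)
        if rec.rsid in cfg.exclusions or rec.locus in cfg.exclusions:
            log.n_excluded += 1
            continue
        if cfg.drop_ambiguous and rec.is_ambiguous:
            log.n_ambiguous += 1
            continue
        mafs = [rec.maf(p) for p in SUBPOPULATIONS]
        if min(mafs) < cfg.maf_cutoff:
            log.n_failed_maf += 1
            continue
        if min(mafs) == cfg.maf_cutoff:
            log.boundary_maf.append(rec.locus)
        kept.append(rec)
    log.n_after_filter = len(kept)
    return kept


def prune_by_region(records: Sequence[AFRecord], region_size_bp: int) -> List[AFRecord]:
    """Keep one marker per region: greedy by overall MAF under pairwise spacing.

    Records are visited by overall MAF descending (ties broken by (chrom,
    pos) ascending for determinism); a record is accepted iff it lies at
    least ``region_size_bp`` from every already-accepted record on the same
    chromosome.  The output is sorted by (chrom, pos) and guarantees all
    pairwise same-chromosome distances >= ``region_size_bp``.
    """
    ranked = sorted(
        records,
        key=lambda r: (-r.maf_overall, _chrom_sort_key(r.chrom), r.pos),
    )
    accepted: List[AFRecord] = []
    by_chrom: Dict[str, List[int]] = {}
    for rec in ranked:
        positions = by_chrom.setdefault(rec.chrom, [])
        if all(abs(rec.pos - p) >= region_size_bp for p in positions):
            accepted.append(rec)
            positions.append(rec.pos)
    return sorted(accepted, key=lambda r: (_chrom_sort_key(r.chrom), r.pos))


def derive_panel(
    candidates: Sequence[str],
    af: Iterable[AFRecord],
    cfg: Optional[DerivationConfig] = None,
    name: str = "derived",
) -> Tuple[Panel, DerivationLog]:
    """Run the full cascade and wrap the survivors as a fingerprint panel."""
    if cfg is None:
        cfg = DerivationConfig()
    log = DerivationLog()
    filtered = filter_candidates(candidates, af, cfg, log)
    pruned = prune_by_region(filtered, cfg.region_size_bp)
    log.n_after_prune = len(pruned)
    snps = [
        PanelSNP(
            index=i + 1,
            chrom=rec.chrom,
            pos=rec.pos,
            rsid=rec.rsid or rec.locus,
            ref=rec.ref,
            alt=rec.alt,
            raf=rec.af_overall,
            category="fingerprint",
        )
        for i, rec in enumerate(pruned)
    ]
    return Panel(snps=snps, name=name), log


def cross_tabulate(manifests: Sequence[ArrayManifest]) -> pd.DataFrame:
    """Pairwise and cumulative intersection counts across array manifests.

    The diagonal holds manifest sizes; the upper triangle [i, j] (i < j)
    holds |M_i ∩ M_j|; the lower triangle [i, j] (i > j) holds the running
    intersection |M_0 ∩ ... ∩ M_i| of the first i+1 manifests in the given
    order, so the last row repeats the count of keys shared by all arrays.
    """
    if not manifests:
        raise ValueError("cross_tabulate requires at least one manifest")
    names = [m.name for m in manifests]
    n = len(manifests)
    table = pd.DataFrame(0, index=names, columns=names, dtype=int)
    running = set(manifests[0].keys)
    for i, mi in enumerate(manifests):
        table.iloc[i, i] = len(mi)
        for j in range(i + 1, n):
            table.iloc[i, j] = len(mi.keys & manifests[j].keys)
        if i > 0:
            running &= mi.keys
            for j in range(i):
                table.iloc[i, j] = len(running)
    return table
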
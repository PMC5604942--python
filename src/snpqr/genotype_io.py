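"""Reading raw genotype datasets and extracting panel fingerprints.

Two input dialects are supported: the tab-separated direct-to-consumer (DTC)
raw-data export popularised by 23andMe (``rsid  chromosome  position
genotype``, ``#`` comments) and VCF 4.x.  Marker lookup when extracting a
fingerprint is rsid-first with a chrom:pos fallback, since DTC files key on
rsid while VCFs sometimes lack rsids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .genotypes import ALLELE_ALPHABET, Genotype
from .panel import Panel

__all__ = [
    "GenotypeRecord",
    "GenotypeTable",
    "Fingerprint",
    "GenotypeParseError",
    "read_dtc_genotypes",
    "read_vcf_genotypes",
    "extract_fingerprint",
]

#: DTC genotype strings that denote a missing call.
_MISSING_STRINGS = {"--", "-", "00", "", "not determined"}


class GenotypeParseError(ValueError):
    """A raw genotype file could not be parsed."""


def _normalize_chrom(chrom: str) -> str:
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


@dataclass(frozen=True)
class GenotypeRecord:
    """One observed genotype at one genomic position."""

    rsid: str
    chrom: str
    pos: int
    genotype: Genotype

    @property
    def locus(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass
class GenotypeTable:
    """A sample's genotype records, indexed by rsid and by chrom:pos."""

    records: List[GenotypeRecord] = field(default_factory=list)
    sample_label: str = ""
    _by_rsid: Dict[str, GenotypeRecord] = field(init=False, repr=False)
    _by_locus: Dict[str, GenotypeRecord] = field(init=False, repr=False)

    def __post_init__(self):
        self._by_rsid = {}
        self._by_locus = {}
        for rec in self.records:
            if rec.locus in self._by_locus:
                raise GenotypeParseError(f"duplicate record at {rec.locus}")
            self._by_locus[rec.locus] = rec
            if rec.rsid:
                self._by_rsid[rec.rsid] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, rsid: str) -> Optional[GenotypeRecord]:
        return self._by_rsid.get(rsid)

    def get_locus(self, locus: str) -> Optional[GenotypeRecord]:
        return self._by_locus.get(locus)


@dataclass
class Fingerprint:
    """The ordered genotype vector over an identity panel for one sample."""

    panel_name: str
    genotypes: List[Genotype]
    sample_label: str = ""

    def __post_init__(self):
        if not self.genotypes:
            raise ValueError("fingerprint cannot be empty")

    def __len__(self) -> int:
        return len(self.genotypes)

    def __iter__(self):
        return iter(self.genotypes)

    def __getitem__(self, i: int) -> Genotype:
        return self.genotypes[i]

    @property
    def n_missing(self) -> int:
        return sum(1 for g in self.genotypes if g.is_missing)

    @property
    def n_called(self) -> int:
        return len(self.genotypes) - self.n_missing


def _parse_dtc_genotype(text: str, lineno: int) -> Genotype:
    text = text.strip()
    if text.lower() in _MISSING_STRINGS:
        return Genotype.missing()
    if len(text) == 1:
        # Hemizygous single-letter call (X/Y/MT lines): promote to a
        # homozygous pair — the fingerprint format has no one-letter state.
        text = text * 2
    if len(text) != 2 or any(ch not in ALLELE_ALPHABET for ch in text):
        raise GenotypeParseError(f"line {lineno}: unparseable genotype {text!r}")
    return Genotype((text[0], text[1]))


def read_dtc_genotypes(path, sample_label: str = "") -> GenotypeTable:
    """Read a DTC raw-data export (tab-separated rsid/chrom/pos/genotype).

    Lines starting with ``#`` are comments.  Genotype strings ``--``, ``-``,
    ``00`` and empty map to the missing call; single-letter hemizygous calls
    are promoted to homozygous pairs.
    """
    records: List[GenotypeRecord] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise GenotypeParseError(
                    f"line {lineno}: expected >= 4 tab-separated fields, got {len(parts)}"
                )
            rsid, chrom, pos_s = parts[0].strip(), parts[1].strip(), parts[2].strip()
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise GenotypeParseError(f"line {lineno}: bad position {pos_s!r}") from exc
            if pos < 1:
                raise GenotypeParseError(f"line {lineno}: position must be >= 1")
            genotype = _parse_dtc_genotype(parts[3], lineno)
            records.append(
                GenotypeRecord(rsid=rsid, chrom=_normalize_chrom(chrom), pos=pos, genotype=genotype)
            )
    return GenotypeTable(records=records, sample_label=sample_label or str(path))


def read_vcf_genotypes(path, sample: Optional[str] = None) -> GenotypeTable:
    """Read one sample's genotypes from a VCF 4.x file (plain or bgzipped).

    GT indices are resolved to allele symbols via REF/ALT; ``./.`` and
    half-calls map to missing.  ``sample`` defaults to the first sample.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise GenotypeParseError(f"{path}: VCF contains no sample columns")
    if sample is None:
        sample = samples[0]
    if sample not in samples:
        raise GenotypeParseError(
            f"{path}: sample {sample!r} not found; available: {', '.join(samples)}"
        )
    idx = samples.index(sample)

    records: List[GenotypeRecord] = []
    for variant in vcf:
        gt = variant.genotypes[idx]
        a1, a2 = gt[0], gt[1]
        if a1 < 0 or a2 < 0:
            genotype = Genotype.missing()
        else:
            sequences = [variant.REF] + list(variant.ALT)
            if all(len(s) == 1 and s in ALLELE_ALPHABET for s in sequences):
                symbols = sequences
            else:
                # Indel site: map to the D/I tokens DTC arrays use, the
                # shortest allele sequence being the deletion.
                minlen = min(len(s) for s in sequences)
                symbols = ["D" if len(s) == minlen else "I" for s in sequences]
            genotype = Genotype((symbols[a1], symbols[a2]))
        records.append(
            GenotypeRecord(
                rsid=variant.ID or "",
                chrom=_normalize_chrom(variant.CHROM),
                pos=variant.POS,
                genotype=genotype,
            )
        )
    return GenotypeTable(records=records, sample_label=sample)


def extract_fingerprint(table: GenotypeTable, panel: Panel) -> Fingerprint:
    """Pull the panel genotypes out of a raw genotype table, in panel order.

    Lookup is by rsid first, then by chrom:pos.  Markers absent from the
    table yield missing calls.  When a record found by rsid carries a
    contradictory position, a warning is emitted and the rsid match wins.
    """
    genotypes: List[Genotype] = []
    for snp in panel:
        rec = table.get(snp.rsid)
        if rec is not None:
            if rec.chrom != snp.chrom or rec.pos != snp.pos:
                warnings.warn(
                    f"{snp.rsid}: record at {rec.locus} contradicts panel locus "
                    f"{snp.locus}; using the rsid match",
                    stacklevel=2,
                )
            genotypes.append(rec.genotype)
            continue
        rec = table.get_locus(snp.locus)
        genotypes.append(rec.genotype if rec is not None else Genotype.missing())
    return Fingerprint(
        panel_name=panel.name, genotypes=genotypes, sample_label=table.sample_label
    )
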
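"""Hardy-Weinberg cohort simulation and DTC-format fixture generation.

Fingerprint genotypes are drawn marker-independently under Hardy-Weinberg
equilibrium at each marker's bundled reference-allele frequency (the
panel's >= 10 Mb spacing was designed to remove linkage disequilibrium, so
independence across markers is the model the panel itself assumes).  ABO
markers are drawn the same way from their documented allele frequencies;
the two chr1/Y sex markers are drawn conditionally on a simulated sex
label (females homozygous for the chr1 allele, males heterozygous).

The module also provides the closed-form genotype-collision probability
used to quantify fingerprint uniqueness: two random individuals share the
genotype at a marker with probability p^4 + 4 p^2 q^2 + q^4, so the
expected number of duplicate fingerprint pairs in a cohort of n is
C(n, 2) * prod over markers of that probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .genotypes import Genotype
from .genotype_io import Fingerprint, GenotypeRecord, GenotypeTable
from .panel import Panel, PanelSNP

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "simulate_fingerprint_matrix",
    "count_duplicate_fingerprints",
    "expected_duplicate_pairs",
    "match_probability",
    "expected_cross_concordance",
    "mutate_fingerprint",
    "write_dtc_file",
]


@dataclass
class SimulationConfig:
    """Cohort size, seed, and per-genotype missingness / error rates."""

    n_individuals: int
    seed: int = 0
    missing_rate: float = 0.0
    error_rate: float = 0.0

    def __post_init__(self):
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be >= 0")
        for rate_name in ("missing_rate", "error_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{rate_name} must be in [0, 1)")


def match_probability(raf: float) -> float:
    """P(two HWE individuals share the genotype class) at one marker."""
    p, q = raf, 1.0 - raf
    return p**4 + 4 * p**2 * q**2 + q**4


def expected_cross_concordance(panel: Panel) -> float:
    """Expected per-marker match rate between two unrelated individuals."""
    fps = panel.fingerprint_snps
    return float(np.mean([match_probability(s.raf) for s in fps]))


def expected_duplicate_pairs(panel: Panel, n: int) -> float:
    """Expected duplicate fingerprint pairs among n HWE individuals."""
    log_collision = sum(math.log(match_probability(s.raf)) for s in panel.fingerprint_snps)
    return math.exp(math.log(n * (n - 1) / 2.0) + log_collision) if n > 1 else 0.0


def simulate_fingerprint_matrix(panel: Panel, n: int, seed: int = 0) -> np.ndarray:
    """Reference-allele dosage matrix (n x n_fingerprint) under HWE.

    Dosage 0/1/2 identifies the genotype class at a bi-allelic marker, which
    is all that uniqueness and concordance calculations need; the cohort
    generator expands dosages to allele pairs.
    """
    rng = np.random.default_rng(seed)
    rafs = np.array([s.raf for s in panel.fingerprint_snps])
    return rng.binomial(2, rafs, size=(n, len(rafs))).astype(np.int8)


def count_duplicate_fingerprints(panel: Panel, n: int, seed: int = 0) -> int:
    """Number of individuals sharing a full fingerprint with another (HWE cohort)."""
    matrix = simulate_fingerprint_matrix(panel, n, seed)
    if n < 2:
        return 0
    _, counts = np.unique(matrix, axis=0, return_counts=True)
    return int(counts[counts > 1].sum())


def _dosage_to_genotype(snp: PanelSNP, dosage: int) -> Genotype:
    alleles = [snp.ref_token] * dosage + [snp.alt_token] * (2 - dosage)
    return Genotype((alleles[0], alleles[1]))


def simulate_cohort(panel: Panel, cfg: SimulationConfig) -> List[GenotypeTable]:
    """Simulate a cohort of DTC-style genotype tables over the full panel.

    Deterministic given ``cfg.seed``.  Sample labels are ``sim_0001`` ...;
    sex labels are drawn 50/50 and drive the sex markers.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    fp_snps = panel.fingerprint_snps
    abo_snps = panel.abo_snps
    sex_snps = panel.sex_snps

    fp_dosage = rng.binomial(2, [s.raf for s in fp_snps], size=(n, len(fp_snps)))
    abo_dosage = (
        rng.binomial(2, [s.raf for s in abo_snps], size=(n, len(abo_snps)))
        if abo_snps
        else np.zeros((n, 0), dtype=int)
    )
    is_male = rng.random(n) < 0.5

    tables: List[GenotypeTable] = []
    for i in range(n):
        records: List[GenotypeRecord] = []
        genotypes: List[Tuple[PanelSNP, Genotype]] = []
        for j, snp in enumerate(fp_snps):
            genotypes.append((snp, _dosage_to_genotype(snp, int(fp_dosage[i, j]))))
        for j, snp in enumerate(abo_snps):
            genotypes.append((snp, _dosage_to_genotype(snp, int(abo_dosage[i, j]))))
        for snp in sex_snps:
            dosage = 1 if is_male[i] else 2  # het when a Y paralog is present
            genotypes.append((snp, _dosage_to_genotype(snp, dosage)))
        for snp, genotype in genotypes:
            if cfg.error_rate and rng.random() < cfg.error_rate:
                genotype = _dosage_to_genotype(
                    snp, int((genotype.count(snp.ref_token) + rng.integers(1, 3)) % 3)
                )
            if cfg.missing_rate and rng.random() < cfg.missing_rate:
                genotype = Genotype.missing()
            records.append(
                GenotypeRecord(rsid=snp.rsid, chrom=snp.chrom, pos=snp.pos, genotype=genotype)
            )
        tables.append(GenotypeTable(records=records, sample_label=f"sim_{i + 1:04d}"))
    return tables


def mutate_fingerprint(
    fp: Fingerprint,
    n_errors: int,
    seed: int = 0,
    panel: Optional[Panel] = None,
) -> Fingerprint:
    """Replace ``n_errors`` random non-missing genotypes with different ones.

    Replacements are drawn from the marker's ref/alt genotype classes and
    always differ from the original.  Deterministic given ``seed``.
    """
    if panel is None:
        from .panel import load_bundled_panel

        panel = load_bundled_panel()
    if len(fp) != len(panel):
        raise ValueError("fingerprint length does not match panel")
    callable_idx = [i for i, g in enumerate(fp) if not g.is_missing]
    if n_errors > len(callable_idx):
        raise ValueError(
            f"n_errors={n_errors} exceeds {len(callable_idx)} non-missing markers"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(callable_idx), size=n_errors, replace=False)
    genotypes = list(fp.genotypes)
    for k in chosen:
        i = callable_idx[int(k)]
        snp = panel.snps[i]
        old_dosage = genotypes[i].count(snp.ref_token)
        new_dosage = int((old_dosage + rng.integers(1, 3)) % 3)
        genotypes[i] = _dosage_to_genotype(snp, new_dosage)
    return Fingerprint(
        panel_name=fp.panel_name, genotypes=genotypes, sample_label=fp.sample_label
    )


def write_dtc_file(table: GenotypeTable, path) -> None:
    """Write a genotype table in the DTC raw-data dialect (round-trip exact)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# synthetic DTC raw genotype export\n")
        fh.write("# rsid\tchromosome\tposition\tgenotype\n")
        for rec in table:
            fh.write(f"{rec.rsid}\t{rec.chrom}\t{rec.pos}\t{rec.genotype.token}\n")
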
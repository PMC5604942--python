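"""ABO blood group and sex inference from the auxiliary panel markers.

The four ABO markers tag the haplotype classes of the ABO gene: the exon-6
single-base deletion rs8176719 creates the frameshifted O1 allele (a
haplotype carrying the deletion is O regardless of other variants);
rs41302905-T tags the rarer O2 allele; rs8176746-T tags B; rs56392308's
deletion tags the A2 subtype (reported as a note only — it does not change
the major group).  Genotypes are unphased, so when two or more markers are
heterozygous the diplotype is resolved parsimoniously (variant alleles
placed on distinct haplotypes, the configuration overwhelmingly more
frequent in populations) and the alternatives are listed in the notes.

The two sex markers map to paralogous regions on chromosomes 1 and Y:
genotyping reads both paralogs together, so an apparent heterozygote
carries a Y-chromosome base and indicates a male; homozygosity at both
markers indicates a female.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Set, Tuple

from .genotypes import Genotype
from .genotype_io import Fingerprint
from .panel import Panel, load_bundled_panel

__all__ = ["BloodTypeCall", "SexCall", "infer_abo", "infer_sex"]

O1_RSID = "rs8176719"   # deletion allele (D) -> O1
O2_RSID = "rs41302905"  # alt allele -> O2
B_RSID = "rs8176746"    # alt allele -> B
A2_RSID = "rs56392308"  # alt (deletion) allele -> A2
ABO_RSIDS = (O1_RSID, O2_RSID, B_RSID, A2_RSID)
SEX_RSIDS = ("rs12743401", "rs12734338")


@dataclass
class BloodTypeCall:
    group: str  # one of A, B, AB, O, ambiguous, unknown
    subtype_notes: str = ""
    supporting_genotypes: Dict[str, Genotype] = field(default_factory=dict)


@dataclass
class SexCall:
    sex: str  # one of male, female, ambiguous, unknown
    per_marker: Dict[str, Genotype] = field(default_factory=dict)


def _marker_genotypes(fp: Fingerprint, panel: Panel, rsids) -> Dict[str, Genotype]:
    out = {}
    for rsid in rsids:
        snp = panel.get(rsid)
        if snp is None:
            raise ValueError(f"panel {panel.name!r} lacks auxiliary marker {rsid}")
        out[rsid] = fp[snp.index - 1]
    return out


def _variant_dosage(g: Genotype, variant_token: str) -> Optional[int]:
    """Copies of the variant-tagging allele, or None if the call is missing."""
    if g.is_missing:
        return None
    return g.count(variant_token)


def _diplotype_group(h1_tags: Set[str], h2_tags: Set[str]) -> str:
    def hap_allele(tags: Set[str]) -> str:
        if "O1" in tags or "O2" in tags:
            return "O"
        if "B" in tags:
            return "B"
        return "A"

    alleles = sorted((hap_allele(h1_tags), hap_allele(h2_tags)))
    if alleles == ["O", "O"]:
        return "O"
    if alleles == ["A", "B"]:
        return "AB"
    if "B" in alleles:
        return "B"
    if "A" in alleles:
        return "A"
    return "O"


def _assignments(dosages: Dict[str, int]):
    """All phase assignments of per-marker variant dosages to two haplotypes.

    Yields (h1_tags, h2_tags, n_cis) where n_cis counts single-copy tags
    stacked on an already-tagged haplotype (0 = fully trans/parsimonious).
    """
    het_tags = [t for t, d in dosages.items() if d == 1]
    hom_tags = {t for t, d in dosages.items() if d == 2}
    for choice in product((0, 1), repeat=len(het_tags)):
        h: Tuple[Set[str], Set[str]] = (set(hom_tags), set(hom_tags))
        for tag, side in zip(het_tags, choice):
            h[side].add(tag)
        # count tags sharing a haplotype with another tag (cis stacking)
        n_cis = sum(max(0, len(side) - 1) for side in h)
        yield h[0], h[1], n_cis


def infer_abo(fp: Fingerprint, panel: Optional[Panel] = None) -> BloodTypeCall:
    """Infer the ABO group from the four auxiliary markers of a fingerprint.

    Missing markers widen the set of diplotypes consistent with the data;
    the call degrades to ``ambiguous`` when more than one major group
    remains possible and to ``unknown`` when all four markers are missing.
    """
    if panel is None:
        panel = load_bundled_panel()
    genotypes = _marker_genotypes(fp, panel, ABO_RSIDS)
    if all(g.is_missing for g in genotypes.values()):
        return BloodTypeCall(group="unknown", supporting_genotypes=genotypes)

    tag_tokens = {
        "O1": (O1_RSID, "D"),
        "O2": (O2_RSID, panel.get(O2_RSID).alt_token),
        "B": (B_RSID, panel.get(B_RSID).alt_token),
    }
    dosages = {
        tag: _variant_dosage(genotypes[rsid], token)
        for tag, (rsid, token) in tag_tokens.items()
    }

    # Enumerate dosages for missing markers and phases for het markers.
    possible_groups: Set[str] = set()
    scored: List[Tuple[int, str]] = []  # (cis-stacking count, group), no-missing case
    missing_tags = [t for t, d in dosages.items() if d is None]
    for fill in product((0, 1, 2), repeat=len(missing_tags)):
        filled = dict(dosages)
        filled.update(dict(zip(missing_tags, fill)))
        for h1, h2, n_cis in _assignments(filled):
            group = _diplotype_group(h1, h2)
            possible_groups.add(group)
            if not missing_tags:
                scored.append((n_cis, group))
    parsimonious_groups: Set[str] = set()
    if scored:
        min_cis = min(n for n, _ in scored)
        parsimonious_groups = {g for n, g in scored if n == min_cis}

    notes: List[str] = []
    a2 = _variant_dosage(genotypes[A2_RSID], panel.get(A2_RSID).alt_token)
    if a2:
        notes.append(f"A2-tagging allele present ({a2} copies)")
    elif a2 is None:
        notes.append("A2 marker missing")

    if len(possible_groups) == 1:
        group = possible_groups.pop()
    elif not missing_tags and len(parsimonious_groups) == 1:
        group = parsimonious_groups.pop()
        others = sorted(possible_groups - {group})
        notes.append(
            "unphased heterozygotes resolved in trans; "
            f"cis configurations would allow: {', '.join(others)}"
        )
    else:
        group = "ambiguous"
        notes.append(f"consistent groups: {', '.join(sorted(possible_groups))}")

    return BloodTypeCall(
        group=group,
        subtype_notes="; ".join(notes),
        supporting_genotypes=genotypes,
    )


def infer_sex(fp: Fingerprint, panel: Optional[Panel] = None) -> SexCall:
    """Infer sex from the two chr1/Y paralogous markers.

    Heterozygosity at a marker is evidence of a Y chromosome (male);
    homozygosity at all non-missing markers indicates female.  Conflicting
    non-missing markers yield ``ambiguous``; two missing markers yield
    ``unknown``.
    """
    if panel is None:
        panel = load_bundled_panel()
    genotypes = _marker_genotypes(fp, panel, SEX_RSIDS)
    states = [g.is_het() for g in genotypes.values() if not g.is_missing]
    if not states:
        return SexCall(sex="unknown", per_marker=genotypes)
    if all(states):
        sex = "male"
    elif not any(states):
        sex = "female"
    else:
        sex = "ambiguous"
    return SexCall(sex=sex, per_marker=genotypes)
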
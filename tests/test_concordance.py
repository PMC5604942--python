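"""Five-scenario match classification and fingerprint comparison."""

import itertools

import pytest

from snpqr.codec import serialize
from snpqr.concordance import (
    MatchClass,
    classify_pair,
    compare_fingerprints,
    complement_genotype,
)
from snpqr.genotypes import Genotype
from snpqr.genotype_io import Fingerprint, extract_fingerprint
from snpqr.simulate import expected_cross_concordance

_COMP = str.maketrans("ACGT", "TGCA")
_TOKENS = ["".join(p) for p in itertools.product("ACGTDI", repeat=2)] + ["--"]


def oracle_classify(t1: str, t2: str) -> str:
    """Independent enumeration over permutations and strand complementation."""
    if "-" in t1 or "-" in t2:
        return "missing"
    if t1 == t2:
        return "perfect"
    if t1 in (t2, t2[::-1]):
        return "permuted"
    if set(t1 + t2) & set("DI"):
        return "mismatch"
    comp = t2.translate(_COMP)
    if t1 == comp:
        return "strand"
    if t1 == comp[::-1]:
        return "strand_permuted"
    return "mismatch"


class TestComplement:
    @pytest.mark.parametrize(
        "token, expected", [("AG", "TC"), ("AC", "TG"), ("GG", "CC"), ("DI", "DI")]
    )
    def test_watson_crick(self, token, expected):
        got = complement_genotype(Genotype.from_token(token))
        assert got.token == expected

    def test_missing_passes_through(self):
        assert complement_genotype(Genotype.missing()).is_missing


class TestClassifyPair:
    @pytest.mark.parametrize(
        "t1, t2, expected",
        [
            ("AG", "AG", MatchClass.PERFECT),
            ("AG", "GA", MatchClass.PERMUTED),
            ("AG", "TC", MatchClass.STRAND),
            ("AG", "CT", MatchClass.STRAND_PERMUTED),
            ("AC", "TG", MatchClass.STRAND),
            ("AA", "AG", MatchClass.MISMATCH),
            ("--", "AG", MatchClass.MISSING),
            ("DD", "DD", MatchClass.PERFECT),
            ("DI", "ID", MatchClass.PERMUTED),
            ("AA", "TT", MatchClass.STRAND),
        ],
    )
    def test_worked_scenarios(self, t1, t2, expected):
        got = classify_pair(Genotype.from_token(t1), Genotype.from_token(t2))
        assert got is expected

    def test_exhaustive_oracle_equivalence(self):
        """All token pairs agree with the brute-force enumeration oracle."""
        for t1 in _TOKENS:
            for t2 in _TOKENS:
                got = classify_pair(Genotype.from_token(t1), Genotype.from_token(t2))
                assert got.value == oracle_classify(t1, t2), (t1, t2)

    def test_symmetric_match_outcome(self):
        for t1 in _TOKENS:
            for t2 in _TOKENS:
                a = classify_pair(Genotype.from_token(t1), Genotype.from_token(t2))
                b = classify_pair(Genotype.from_token(t2), Genotype.from_token(t1))
                assert a.is_match == b.is_match and (
                    a is MatchClass.MISSING
                ) == (b is MatchClass.MISSING)

    def test_self_comparison_is_perfect(self):
        for t in _TOKENS:
            if t == "--":
                continue
            g = Genotype.from_token(t)
            assert classify_pair(g, g) is MatchClass.PERFECT

    def test_complement_invariance_for_unambiguous_genotypes(self):
        """Complementing one side flips strand<->plain but preserves matching."""
        for t1 in _TOKENS:
            for t2 in _TOKENS:
                if "-" in t1 + t2 or set(t1 + t2) & set("DI"):
                    continue
                if len({*t1}) == 2 and {*t1} in ({"A", "T"}, {"C", "G"}):
                    continue  # strand-ambiguous genotypes excluded by panel design
                if len({*t2}) == 2 and {*t2} in ({"A", "T"}, {"C", "G"}):
                    continue
                g1, g2 = Genotype.from_token(t1), Genotype.from_token(t2)
                assert (
                    classify_pair(g1, complement_genotype(g2)).is_match
                    == classify_pair(g1, g2).is_match
                )

    def test_panel_markers_complement_disjoint(self, panel):
        """A fingerprint genotype and its complement never share alleles."""
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for snp in panel.fingerprint_snps:
            alleles = {snp.ref, snp.alt}
            assert alleles.isdisjoint({comp[a] for a in alleles})


class TestCompareFingerprints:
    def test_reflexive_concordance(self, panel, two_individuals):
        fp = extract_fingerprint(two_individuals[0], panel)
        report = compare_fingerprints(fp, fp)
        assert report.concordance_rate == 1.0
        assert report.verdict == "concordant"
        assert report.n_compared + report.n_missing == report.n_markers

    def test_all_strand_flips_still_concordant(self, panel, two_individuals):
        fp = extract_fingerprint(two_individuals[0], panel)
        flipped = Fingerprint(
            panel_name=fp.panel_name,
            genotypes=[complement_genotype(g) for g in fp],
        )
        report = compare_fingerprints(fp, flipped)
        assert report.concordance_rate == 1.0

    def test_unrelated_pair_discordant(self, panel, two_individuals):
        f1 = extract_fingerprint(two_individuals[0], panel)
        f2 = extract_fingerprint(two_individuals[1], panel)
        report = compare_fingerprints(f1, f2)
        assert report.verdict == "discordant"
        assert report.concordance_rate < 0.95

    def test_expected_match_rate_band(self, panel):
        """Per-marker collision probability from the panel RAFs is ~0.37-0.41."""
        assert 0.37 <= expected_cross_concordance(panel) <= 0.41

    def test_low_overlap_is_inconclusive(self, panel):
        n = len(panel)
        sparse = Fingerprint(
            panel_name=panel.name,
            genotypes=[Genotype(("A", "A"))] * 5 + [Genotype.missing()] * (n - 5),
        )
        report = compare_fingerprints(sparse, sparse)
        assert report.verdict == "inconclusive"

    def test_length_mismatch_rejected(self, panel):
        f1 = Fingerprint(panel_name="x", genotypes=[Genotype(("A", "A"))] * 3)
        f2 = Fingerprint(panel_name="x", genotypes=[Genotype(("A", "A"))] * 4)
        with pytest.raises(ValueError, match="lengths"):
            compare_fingerprints(f1, f2)

    def test_counts_partition_compared_markers(self, panel, two_individuals):
        f1 = extract_fingerprint(two_individuals[0], panel)
        f2 = extract_fingerprint(two_individuals[1], panel)
        report = compare_fingerprints(f1, f2)
        assert sum(report.counts.values()) == report.n_compared


class TestCompareQRImages:
    def test_same_sample_via_images(self, panel, two_individuals, tmp_path):
        from snpqr.codec import encode_qr
        from snpqr.concordance import compare_qr_images

        fp = extract_fingerprint(two_individuals[0], panel)
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        encode_qr(serialize(fp), p1)
        encode_qr(serialize(fp), p2)
        report = compare_qr_images(p1, p2, panel)
        assert report.concordance_rate == 1.0 and report.verdict == "concordant"

    def test_undecodable_image_propagates(self, panel, tmp_path):
        from PIL import Image

        from snpqr.concordance import compare_qr_images
        from snpqr.qr import QRDecodeError

        bad = tmp_path / "bad.png"
        Image.new("L", (50, 50), 255).save(bad)
        with pytest.raises(QRDecodeError):
            compare_qr_images(bad, bad, panel)
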
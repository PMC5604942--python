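"""Custom panel derivation cascade and array cross-tabulation."""

import random

import pytest

from snpqr.derivation import (
    AFRecord,
    ArrayManifest,
    DerivationConfig,
    SchemaError,
    cross_tabulate,
    derive_panel,
    filter_candidates,
    load_af_reference,
    prune_by_region,
)
from snpqr.panel import validate_panel

AF_HEADER = "CHROM\tPOS\tRSID\tREF\tALT\tAF_AFR\tAF_EUR\tAF_AMR\tAF_EAS\tAF_SAS\tAF_ALL\n"


def make_record(chrom="1", pos=1000, rsid="rs1", ref="C", alt="T",
                afs=(0.4, 0.4, 0.4, 0.4, 0.4), overall=0.4):
    return AFRecord(
        chrom=chrom, pos=pos, rsid=rsid, ref=ref, alt=alt,
        af_by_pop=dict(zip(("AFR", "EUR", "AMR", "EAS", "SAS"), afs)),
        af_overall=overall,
    )


def random_records(rng, n, chroms=("1", "2"), span=60_000_000):
    records, used = [], set()
    for i in range(n):
        pos = rng.randrange(1, span)
        chrom = rng.choice(chroms)
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        afs = [round(rng.uniform(0.05, 0.5), 3) for _ in range(5)]
        # overall AF is a mixture of the subpopulation AFs, as in a real
        # reference; this is what makes the derived panel self-consistent
        overall = round(sum(afs) / 5, 3)
        records.append(
            make_record(chrom=chrom, pos=pos, rsid=f"rs{i}", afs=afs, overall=overall)
        )
    return records


class TestLoadAFReference:
    def test_toy_reference(self, tmp_path):
        path = tmp_path / "af.tsv"
        path.write_text(
            AF_HEADER
            + "1\t100\trs1\tC\tT\t0.3\t0.4\t0.5\t0.3\t0.4\t0.4\n"
            + "2\t200\trs2\tA\tG\t0.5\t0.5\t0.5\t0.5\t0.5\t0.5\n"
        )
        records = load_af_reference(path)
        assert len(records) == 2
        assert records[0].maf("AFR") == pytest.approx(0.3)

    def test_bad_frequency_names_row(self, tmp_path):
        path = tmp_path / "af.tsv"
        path.write_text(AF_HEADER + "1\t100\trs1\tC\tT\t1.2\t0.4\t0.5\t0.3\t0.4\t0.4\n")
        with pytest.raises(SchemaError, match="row 2"):
            load_af_reference(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "af.tsv"
        path.write_text("CHROM\tPOS\tRSID\tREF\tALT\tAF_AFR\tAF_ALL\n")
        with pytest.raises(SchemaError, match="AF_EUR"):
            load_af_reference(path)

    def test_empty_body_yields_empty_collection(self, tmp_path):
        path = tmp_path / "af.tsv"
        path.write_text(AF_HEADER)
        assert load_af_reference(path) == []


class TestFilterCandidates:
    def test_maf_cutoff_applies_to_every_subpopulation(self):
        rec = make_record(afs=(0.4, 0.8, 0.4, 0.4, 0.4))  # EUR MAF 0.2
        cfg = DerivationConfig(maf_cutoff=0.25)
        assert filter_candidates(["1:1000"], [rec], cfg) == []

    def test_ambiguous_pair_dropped(self):
        rec = make_record(ref="A", alt="T")
        cfg = DerivationConfig()
        assert filter_candidates(["1:1000"], [rec], cfg) == []
        keep_cfg = DerivationConfig(drop_ambiguous=False)
        assert filter_candidates(["1:1000"], [rec], keep_cfg) == [rec]

    def test_qualifying_record_retained(self):
        rec = make_record(afs=(0.3, 0.3, 0.3, 0.3, 0.3))
        assert filter_candidates(["1:1000"], [rec], DerivationConfig()) == [rec]

    def test_exclusion_list_and_absent_candidates(self):
        rec = make_record()
        cfg = DerivationConfig(exclusions={"rs1"})
        assert filter_candidates(["1:1000", "9:9"], [rec], cfg) == []

    def test_idempotent(self):
        rng = random.Random(0)
        records = random_records(rng, 40)
        cfg = DerivationConfig()
        candidates = [r.locus for r in records]
        once = filter_candidates(candidates, records, cfg)
        twice = filter_candidates([r.locus for r in once], once, cfg)
        assert once == twice
        assert set(r.locus for r in once) <= set(candidates)


def oracle_prune(records, region_size):
    """Naive restatement of the greedy rule: repeatedly take the best record."""
    def sort_key(r):
        try:
            chrom = (int(r.chrom), "")
        except ValueError:
            chrom = (100, r.chrom)
        return (-min(r.af_overall, 1 - r.af_overall), chrom, r.pos)

    remaining = sorted(records, key=sort_key)
    chosen = []
    for rec in remaining:
        if all(
            rec.chrom != c.chrom or abs(rec.pos - c.pos) >= region_size
            for c in chosen
        ):
            chosen.append(rec)
    return sorted(chosen, key=lambda r: (sort_key(r)[1], r.pos))


class TestPruneByRegion:
    def test_highest_maf_wins_within_region(self):
        lo = make_record(pos=1_000_000, rsid="lo", overall=0.30)
        hi = make_record(pos=6_000_000, rsid="hi", overall=0.40)
        kept = prune_by_region([lo, hi], 10_000_000)
        assert [r.rsid for r in kept] == ["hi"]

    def test_different_chromosomes_independent(self):
        a = make_record(chrom="1", pos=100, rsid="a")
        b = make_record(chrom="2", pos=200, rsid="b")
        assert len(prune_by_region([a, b], 10_000_000)) == 2

    def test_zero_region_returns_input_sorted(self):
        rng = random.Random(1)
        records = random_records(rng, 25)
        kept = prune_by_region(records, 0)
        assert sorted(r.locus for r in kept) == sorted(r.locus for r in records)

    def test_pairwise_spacing_guarantee(self):
        rng = random.Random(2)
        for _ in range(20):
            records = random_records(rng, 30)
            kept = prune_by_region(records, 10_000_000)
            for i, a in enumerate(kept):
                for b in kept[i + 1:]:
                    if a.chrom == b.chrom:
                        assert abs(a.pos - b.pos) >= 10_000_000

    def test_agrees_with_naive_greedy_oracle(self):
        rng = random.Random(3)
        for _ in range(50):
            records = random_records(rng, rng.randint(0, 12), span=30_000_000)
            got = prune_by_region(records, 10_000_000)
            expected = oracle_prune(records, 10_000_000)
            assert [r.locus for r in got] == [r.locus for r in expected]


class TestDerivePanel:
    def test_constructed_fixture_known_answer(self):
        # One qualifying SNP per 10MB region on two chromosomes.
        records = [
            make_record(chrom="1", pos=5_000_000, rsid="keep1", overall=0.45),
            make_record(chrom="1", pos=6_000_000, rsid="shadowed", overall=0.30),
            make_record(chrom="1", pos=25_000_000, rsid="keep2", overall=0.40),
            make_record(chrom="2", pos=5_000_000, rsid="keep3", overall=0.35),
            make_record(chrom="2", pos=6_000_000, rsid="lowmaf",
                        afs=(0.1, 0.4, 0.4, 0.4, 0.4), overall=0.49),
        ]
        panel, log = derive_panel([r.locus for r in records], records)
        assert [s.rsid for s in panel] == ["keep1", "keep2", "keep3"]
        assert log.n_failed_maf == 1 and log.n_after_prune == 3

    def test_empty_candidates(self):
        panel, log = derive_panel([], [])
        assert len(panel) == 0 and log.n_candidates == 0

    def test_all_fail_maf(self):
        records = [make_record(pos=p, afs=(0.1,) * 5) for p in (100, 200)]
        panel, log = derive_panel([r.locus for r in records], records)
        assert len(panel) == 0
        assert log.n_failed_maf == 2

    def test_output_satisfies_own_thresholds(self):
        rng = random.Random(4)
        for trial in range(10):
            records = random_records(rng, 40)
            cfg = DerivationConfig(maf_cutoff=0.25, region_size_bp=10_000_000)
            panel, _ = derive_panel([r.locus for r in records], records, cfg)
            if len(panel):
                report = validate_panel(panel, min_maf=cfg.maf_cutoff,
                                        min_gap_bp=cfg.region_size_bp)
                assert report.passed, report.violations


class TestCrossTabulate:
    def test_disjoint_manifests(self):
        t = cross_tabulate([
            ArrayManifest("a", {"x", "y"}),
            ArrayManifest("b", {"z"}),
        ])
        assert t.loc["a", "b"] == 0 and t.loc["b", "a"] == 0
        assert t.loc["a", "a"] == 2 and t.loc["b", "b"] == 1

    def test_identical_manifests_all_cells_equal(self):
        keys = {f"k{i}" for i in range(5)}
        t = cross_tabulate([ArrayManifest(n, set(keys)) for n in "abc"])
        assert (t.values == 5).all()

    def test_agrees_with_set_operations_oracle(self):
        rng = random.Random(5)
        universe = [f"v{i}" for i in range(40)]
        manifests = [
            ArrayManifest(f"m{j}", {k for k in universe if rng.random() < 0.5})
            for j in range(4)
        ]
        t = cross_tabulate(manifests)
        sets = [m.keys for m in manifests]
        for i in range(4):
            assert t.iloc[i, i] == len(sets[i])
            for j in range(i + 1, 4):
                assert t.iloc[i, j] == len(sets[i] & sets[j])
        running = sets[0]
        for i in range(1, 4):
            running = running & sets[i]
            for j in range(i):
                assert t.iloc[i, j] == len(running)

    def test_cumulative_cells_monotone_down_columns(self):
        rng = random.Random(6)
        universe = [f"v{i}" for i in range(30)]
        manifests = [
            ArrayManifest(f"m{j}", {k for k in universe if rng.random() < 0.7})
            for j in range(5)
        ]
        t = cross_tabulate(manifests)
        for j in range(4):
            col = [t.iloc[i, j] for i in range(j + 1, 5)]
            assert col == sorted(col, reverse=True)

    def test_requires_at_least_one_manifest(self):
        with pytest.raises(ValueError):
            cross_tabulate([])
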
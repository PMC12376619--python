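"""Catalog construction: consensus, merging, sharing, annotation, TE tagging."""

import itertools

import numpy as np
import pytest

from svpopgen.catalog import (
    MergePolicy,
    annotate_regions,
    classify_sharing,
    consensus_filter,
    control_absent,
    cumulative_growth,
    major_threshold,
    merge_samples,
    reciprocal_overlap,
    tag_te,
)
from svpopgen.io import HET, HOM_ALT, HOM_REF, MISSING, IntervalSet, SVCatalog
from tests.conftest import make_manifest, make_matrix, make_record


def cat(*recs):
    return SVCatalog(list(recs))


class TestConsensusFilter:
    def test_nearby_same_type_retained(self):
        a = cat(make_record("a", "chr1", 1000, 2000, "DEL"))
        b = cat(make_record("b", "chr1", 1100, 2100, "DEL"))
        out = consensus_filter({"A": a, "B": b})
        assert len(out) == 1
        assert out.records[0].id == "a"  # first caller in priority wins
        assert out.records[0].info["SUPP"] == "2"

    def test_single_caller_call_dropped(self):
        a = cat(make_record("a", "chr1", 1000, 2000, "DEL"))
        b = cat()
        out = consensus_filter({"A": a, "B": b})
        assert len(out) == 0

    def test_type_mismatch_both_dropped(self):
        a = cat(make_record("a", "chr1", 1000, 1000, "INS", svlen=200))
        b = cat(make_record("b", "chr1", 1000, 2000, "DEL"))
        out = consensus_filter({"A": a, "B": b})
        assert len(out) == 0

    def test_single_callset_is_error(self):
        with pytest.raises(ValueError, match="min_caller_support"):
            consensus_filter({"A": cat(make_record())})

    def test_policy_oracle_on_enumerated_pairs(self):
        """Pairwise keep/drop decisions match direct evaluation of the rule."""
        offsets = [0, 100, 500, 501, 2000]
        types = ["DEL", "INS"]
        for off, t1, t2 in itertools.product(offsets, types, types):
            a = cat(make_record("a", "chr1", 10_000, 10_000 if t1 == "INS" else 11_000, t1))
            b = cat(
                make_record(
                    "b", "chr1", 10_000 + off,
                    (10_000 + off) if t2 == "INS" else (11_000 + off), t2,
                )
            )
            out = consensus_filter({"A": a, "B": b})
            expect_kept = (t1 == t2) and off <= 500
            assert (len(out) == 1) == expect_kept, (off, t1, t2)


def _brute_force_clusters(records, max_dist):
    """All-pairs transitive closure of the linkage rule (independent oracle)."""
    n = len(records)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            ri, rj = records[i], records[j]
            adj[i][j] = (
                ri.chrom == rj.chrom
                and ri.svtype == rj.svtype
                and abs(ri.start - rj.start) <= max_dist
                and abs(ri.end - rj.end) <= max_dist
            )
    # transitive closure by BFS
    clusters = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(j for j in range(n) if adj[k][j] and j not in comp)
        seen |= comp
        clusters.append(frozenset(comp))
    return set(clusters)


class TestMergeSamples:
    def test_identical_calls_collapse(self):
        a = cat(make_record("a", "chr1", 1000, 2000, "DEL"))
        b = cat(make_record("b", "chr1", 1000, 2000, "DEL"))
        merged, presence = merge_samples({"s1": a, "s2": b})
        assert len(merged) == 1
        assert presence.presence().sum() == 2

    def test_chained_links_form_one_cluster(self):
        """Starts 1000/1400/1800: consecutive gaps <= 500 chain under single linkage."""
        sets = {
            f"s{i}": cat(make_record(f"r{i}", "chr1", st, st + 1000, "DEL"))
            for i, st in enumerate([1000, 1400, 1800])
        }
        merged, _ = merge_samples(sets)
        assert len(merged) == 1

    def test_type_segregation_at_same_locus(self):
        a = cat(make_record("a", "chr1", 1000, 2000, "DEL"))
        b = cat(make_record("b", "chr1", 1000, 2000, "INV"))
        merged, _ = merge_samples({"s1": a, "s2": b})
        assert len(merged) == 2

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(42)
        sets = {}
        all_records = []
        for s in range(8):
            recs = []
            for k in range(rng.integers(3, 10)):
                start = int(rng.integers(1, 60_000))
                recs.append(
                    make_record(
                        f"s{s}r{k}", "chr1", start, start + 999,
                        rng.choice(["DEL", "DUP"]),
                    )
                )
            sets[f"s{s}"] = cat(*recs)
            all_records.extend(recs)
        merged, presence = merge_samples(sets)
        oracle = _brute_force_clusters(all_records, 500)
        assert len(merged) == len(oracle)
        # carriers per cluster must match the oracle's per-cluster sample sets
        oracle_carrier_sets = sorted(
            sorted({all_records[i].id.split("r")[0] for i in comp}) for comp in oracle
        )
        got = sorted(
            sorted(
                s for j, s in enumerate(presence.sample_ids)
                if presence.gt[i, j] != HOM_REF
            )
            for i in range(len(merged))
        )
        assert got == oracle_carrier_sets

    def test_cluster_membership_order_invariant(self):
        rng = np.random.default_rng(7)
        sets = {}
        for s in range(6):
            recs = []
            for k in range(5):
                start = int(rng.integers(1, 30_000))
                recs.append(make_record(f"s{s}r{k}", "chr1", start, start + 500, "DEL"))
            sets[f"s{s}"] = cat(*recs)
        m1, p1 = merge_samples(sets, order=list(sets))
        m2, p2 = merge_samples(sets, order=list(reversed(list(sets))))
        assert len(m1) == len(m2)
        carriers1 = sorted(
            tuple(sorted(s for j, s in enumerate(p1.sample_ids) if p1.gt[i, j]))
            for i in range(len(m1))
        )
        carriers2 = sorted(
            tuple(sorted(s for j, s in enumerate(p2.sample_ids) if p2.gt[i, j]))
            for i in range(len(m2))
        )
        assert carriers1 == carriers2


class TestGrowthCurve:
    def test_flat_when_identical(self):
        rec = make_record("a", "chr1", 1000, 2000, "DEL")
        sets = {s: cat(rec) for s in ["s1", "s2", "s3"]}
        merged, presence = merge_samples(sets)
        assert cumulative_growth(presence) == [1, 1, 1]

    def test_strictly_increasing_when_disjoint(self):
        sets = {
            f"s{i}": cat(make_record(f"r{i}", "chr1", 10_000 * (i + 1), 10_000 * (i + 1) + 999, "DEL"))
            for i in range(3)
        }
        merged, presence = merge_samples(sets)
        assert cumulative_growth(presence) == [1, 2, 3]

    def test_equals_set_union_oracle(self):
        rng = np.random.default_rng(3)
        sets = {}
        for s in range(20):
            recs = []
            for k in range(rng.integers(1, 12)):
                start = int(rng.integers(1, 40)) * 5000  # lattice: exact matches only
                recs.append(make_record(f"s{s}r{k}", "chr1", start, start + 999, "DEL"))
            sets[f"s{s}"] = cat(*recs)
        merged, presence = merge_samples(sets, policy=MergePolicy(max_breakpoint_dist=0))
        order = list(sets)
        got = cumulative_growth(presence, order)
        union = set()
        expected = []
        for s in order:
            union |= {(r.chrom, r.start, r.end, r.svtype) for r in sets[s]}
            expected.append(len(union))
        assert got == expected

    def test_unknown_sample_errors(self):
        m = make_matrix({"a": [HET, HOM_REF]})
        with pytest.raises(ValueError):
            cumulative_growth(m, ["s1", "nope"])


class TestSharingClasses:
    def test_major_threshold_for_84_samples_is_42(self):
        assert major_threshold(84) == 42

    def test_classes(self):
        n = 4
        m = make_matrix(
            {
                "all": [HET] * n,
                "one": [HOM_ALT] + [HOM_REF] * (n - 1),
                "half": [HET, HET, HOM_REF, HOM_REF],
                "none": [HOM_REF] * n,
            }
        )
        series, counts = classify_sharing(m)
        assert series["all"] == "shared"  # precedence: shared, not major
        assert series["one"] == "singleton"
        assert series["half"] == "major"  # 2 >= ceil(4/2)
        assert series["none"] is None
        assert counts == {"shared": 1, "major": 1, "minor": 0, "singleton": 1}

    def test_partition_property(self):
        rng = np.random.default_rng(11)
        gt = rng.choice([HOM_REF, HET, HOM_ALT, MISSING], size=(200, 9)).astype(np.int8)
        m = make_matrix({f"sv{i}": gt[i].tolist() for i in range(200)})
        series, counts = classify_sharing(m)
        n_with_carrier = int(m.presence().any(axis=1).sum())
        assert sum(counts.values()) == n_with_carrier

    def test_zero_cohort_errors(self):
        m = make_matrix({"a": [HET]})
        with pytest.raises(ValueError):
            classify_sharing(m, n_samples=0)


class TestControlAbsent:
    manifest = make_manifest(
        [("t1", "P1", "target"), ("t2", "P1", "target"),
         ("c1", "L1", "control"), ("c2", "L2", "control")]
    )

    def test_included_when_all_controls_ref(self):
        m = make_matrix({"a": [HET, HOM_REF, HOM_REF, HOM_REF]},
                        ["t1", "t2", "c1", "c2"])
        ids, _ = control_absent(m, self.manifest)
        assert ids == ["a"]

    def test_excluded_when_any_control_carries(self):
        m = make_matrix({"a": [HET, HOM_REF, HET, HOM_REF]},
                        ["t1", "t2", "c1", "c2"])
        ids, _ = control_absent(m, self.manifest)
        assert ids == []

    def test_missing_control_ignored(self):
        m = make_matrix({"a": [HET, HOM_REF, MISSING, HOM_REF]},
                        ["t1", "t2", "c1", "c2"])
        ids, _ = control_absent(m, self.manifest)
        assert ids == ["a"]

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        gt = rng.choice([HOM_REF, HET, HOM_ALT, MISSING], size=(200, 4),
                        p=[0.6, 0.2, 0.1, 0.1]).astype(np.int8)
        m = make_matrix({f"sv{i}": gt[i].tolist() for i in range(200)},
                        ["t1", "t2", "c1", "c2"])
        ids, _ = control_absent(m, self.manifest)
        expected = []
        for i in range(200):
            controls = gt[i, 2:]
            carriers = np.isin(gt[i], (HET, HOM_ALT))
            if all(g in (HOM_REF, MISSING) for g in controls) and carriers.any():
                expected.append(f"sv{i}")
        assert ids == expected
        # disjointness with control carriers, by construction
        for sv in ids:
            assert not np.isin(m.sv_row(sv)[2:], (HET, HOM_ALT)).any()

    def test_no_controls_errors(self):
        m = make_matrix({"a": [HET]}, ["t1"])
        manifest = make_manifest([("t1", "P1", "target")])
        with pytest.raises(ValueError, match="control"):
            control_absent(m, manifest)


class TestRegionAnnotation:
    genes = IntervalSet([("chr1", 10_000, 30_000, "g1")])
    exons = IntervalSet([("chr1", 10_000, 10_500, "g1"), ("chr1", 29_000, 29_300, "g1")])

    def _label(self, rec):
        return annotate_regions(SVCatalog([rec]), self.genes, self.exons).iloc[0]

    def test_exon_overlap(self):
        assert self._label(make_record("a", "chr1", 10_400, 10_600, "DEL")) == "exonic"

    def test_ins_in_intron(self):
        assert self._label(make_record("a", "chr1", 20_000, 20_000, "INS")) == "intronic"

    def test_precedence_exonic_over_intronic(self):
        # spans the exon boundary into the intron: exonic wins
        assert self._label(make_record("a", "chr1", 10_300, 12_000, "DEL")) == "exonic"

    def test_flank_and_intergenic(self):
        assert self._label(make_record("a", "chr1", 31_000, 31_200, "DEL")) == "upstream_downstream"
        assert self._label(make_record("a", "chr1", 500_000, 500_200, "DEL")) == "intergenic"

    def test_empty_gene_set_all_intergenic(self):
        rec = make_record("a", "chr1", 10_400, 10_600, "DEL")
        lab = annotate_regions(SVCatalog([rec]), IntervalSet(), IntervalSet())
        assert lab.iloc[0] == "intergenic"


class TestTeTagging:
    def test_reciprocal_overlap_arithmetic(self):
        # DEL [1000,2000] vs repeat [1050,1950]: 901/1001 vs 901/901 -> min 0.90
        assert reciprocal_overlap(1000, 2000, 1050, 1950) == pytest.approx(901 / 1001)

    def test_tagged_above_threshold(self):
        catalog = SVCatalog([make_record("a", "chr1", 1000, 2000, "DEL")])
        repeats = IntervalSet([("chr1", 1050, 1950, "LINE")])
        assert tag_te(catalog, repeats)["a"] == "LINE"

    def test_untagged_when_repeat_side_fails(self):
        catalog = SVCatalog([make_record("a", "chr1", 1000, 2000, "DEL")])
        repeats = IntervalSet([("chr1", 1500, 4000, "LINE")])
        assert tag_te(catalog, repeats)["a"] is None

    def test_no_overlap_untagged(self):
        catalog = SVCatalog([make_record("a", "chr1", 1000, 2000, "DEL")])
        repeats = IntervalSet([("chr1", 9000, 9900, "LINE")])
        assert tag_te(catalog, repeats)["a"] is None

    def test_ins_from_sidecar(self):
        catalog = SVCatalog([make_record("a", "chr1", 5000, 5000, "INS", svlen=300)])
        assert tag_te(catalog, IntervalSet(), ins_labels={"a": "SINE"})["a"] == "SINE"

    def test_bad_threshold(self):
        catalog = SVCatalog([make_record("a", "chr1", 1000, 2000, "DEL")])
        with pytest.raises(ValueError):
            tag_te(catalog, IntervalSet(), min_reciprocal=0.0)

    def test_agrees_with_brute_force_on_random_intervals(self):
        rng = np.random.default_rng(17)
        recs, rep_rows = [], []
        for i in range(500):
            s = int(rng.integers(1, 500_000))
            recs.append(make_record(f"sv{i}", "chr1", s, s + int(rng.integers(50, 5000)), "DEL"))
        for j in range(500):
            s = int(rng.integers(1, 500_000))
            rep_rows.append(("chr1", s, s + int(rng.integers(50, 5000)), "LINE"))
        catalog = SVCatalog(recs)
        repeats = IntervalSet(rep_rows)
        got = tag_te(catalog, repeats)
        for rec in catalog:
            expect = any(
                reciprocal_overlap(rec.start, rec.end, rs, re) >= 0.8
                for _, rs, re, _ in rep_rows
            )
            assert (got[rec.id] is not None) == expect, rec.id
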
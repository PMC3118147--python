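"""Perfect-match mapping, normalization, partition assignment, ratios."""
import numpy as np
import pandas as pd
import pytest

from phasemir.quant import (
    LEAK,
    SmallRNALibrary,
    assign_partition,
    length_class_ratio,
    map_reads,
    normalize,
    quantify,
    ratio_mut_wt,
)
from phasemir.sequences import RnaSequence
from phasemir.simulate import (
    HairpinSpec,
    LibrarySpec,
    gen_hairpin,
    gen_library,
    gen_shared_paralog,
)


@pytest.fixture(scope="module")
def planted():
    return gen_hairpin(HairpinSpec(seed=41))


class TestMapReads:
    def test_single_placement(self, planted):
        seq = planted.hairpin.seq
        read = seq.residues[30:51]
        (pl,) = map_reads([read], [seq])
        assert pl.interval == (30, 51) and pl.multiplicity == 1 and not pl.shared

    def test_shared_read_across_paralogs(self, planted):
        seq = planted.hairpin.seq
        paralog = gen_shared_paralog(planted, seed=1)
        m0, m1 = planted.scheme.intervals["miR"]
        read = seq.residues[m0:m1]
        placements = map_reads([read], [seq, paralog])
        assert len(placements) == 2 and all(p.shared for p in placements)

    def test_matches_naive_substring_oracle(self):
        rng = np.random.default_rng(2)
        precursors = [
            RnaSequence(f"p{i}", "".join("ACGU"[j] for j in rng.integers(0, 4, 60)))
            for i in range(3)
        ]
        reads = [p.residues[k:k + 8] for p in precursors for k in (0, 25, 50)]
        placements = map_reads(reads, precursors)
        expected = set()
        for r in set(reads):
            for p in precursors:
                for s in range(len(p.residues) - len(r) + 1):
                    if p.residues[s:s + len(r)] == r:
                        expected.add((r, p.id, s))
        assert {(pl.read, pl.precursor_id, pl.interval[0]) for pl in placements} == expected

    def test_within_precursor_repeat_splits_weight(self):
        p = RnaSequence("p", "ACGUACGUAC" + "GGGG" + "ACGUACGUAC")
        placements = map_reads(["ACGUACGUAC"], [p])
        assert len(placements) == 2
        assert all(pl.within_weight == 0.5 for pl in placements)
        assert all(pl.multiplicity == 1 for pl in placements)


class TestNormalize:
    def test_mean_total_scaling(self):
        libs = [
            SmallRNALibrary.from_pairs("a", [("ACGUACGUACGUACGUACGUA", 10)], total_reads=100),
            SmallRNALibrary.from_pairs("b", [("ACGUACGUACGUACGUACGUA", 10)], total_reads=300),
        ]
        f = normalize(libs)
        assert f["a"] == pytest.approx(2.0)
        assert f["b"] == pytest.approx(2 / 3)

    def test_single_library_factor_one(self):
        lib = SmallRNALibrary.from_pairs("a", [("ACGUACGUACGUACGUACGUA", 5)])
        assert normalize([lib]) == {"a": 1.0}

    def test_pre_normalized_untouched(self):
        libs = [
            SmallRNALibrary.from_pairs("a", [("ACGUACGUACGUACGUACGUA", 10)],
                                       total_reads=100, pre_normalized=True),
            SmallRNALibrary.from_pairs("b", [("ACGUACGUACGUACGUACGUA", 10)], total_reads=300),
        ]
        assert normalize(libs)["a"] == 1.0

    def test_mean_preserved(self):
        rng = np.random.default_rng(0)
        libs = [
            SmallRNALibrary.from_pairs(f"s{i}", [("ACGUACGUACGUACGUACGUA", 1)],
                                       total_reads=float(rng.integers(50, 500)))
            for i in range(5)
        ]
        f = normalize(libs)
        scaled = [f[l.sample_id] * l.total_reads for l in libs]
        raw = [l.total_reads for l in libs]
        assert np.mean(scaled) == pytest.approx(np.mean(raw))


class TestAssignPartition:
    def test_overlap_boundaries_21nt(self, planted):
        scheme = planted.scheme
        ps, pe = scheme.intervals["miR"]
        # full containment
        assert assign_partition((ps, ps + 21), scheme) == "miR"
        # 17/21 = 80.95% is assigned; 16/21 = 76.2% is leak
        assert assign_partition((ps - 4, ps + 17), scheme) == "miR"
        assert assign_partition((ps - 5, ps + 16), scheme) == LEAK

    def test_exact_eighty_percent_of_20nt(self, planted):
        scheme = planted.scheme
        ps, pe = scheme.intervals["miR"]
        assert assign_partition((ps - 4, ps + 16), scheme) == "miR"

    def test_no_double_assignment_possible(self, planted):
        # overlap_fraction > 0.5 makes the winner unique: sweep every
        # placement and confirm the threshold partition is the argmax
        scheme = planted.scheme
        L = 21
        seq_len = scheme.length
        for s in range(seq_len - L + 1):
            winners = [
                n for n in scheme.order
                if (min(s + L, scheme.intervals[n][1]) - max(s, scheme.intervals[n][0])) / L >= 0.8
            ]
            assert len(winners) <= 1


class TestQuantify:
    def test_recovers_planted_proportions(self, planted):
        lib, truth = gen_library(planted, LibrarySpec(depth=50_000, seed=7))
        expr = quantify([lib], [planted.hairpin.seq], {planted.hairpin.seq.id: planted.scheme})
        got = expr.groupby("partition")["unique"].sum()
        for name, expected in truth.items():
            assert got.get(name, 0.0) == pytest.approx(expected)

    def test_conservation_identity(self, planted):
        lib, _ = gen_library(planted, LibrarySpec(depth=20_000, seed=8))
        expr = quantify([lib], [planted.hairpin.seq], {planted.hairpin.seq.id: planted.scheme})
        mapped = sum(c for _, c in lib.records)  # all reads map by construction
        assert expr["unique"].sum() == pytest.approx(mapped, abs=1e-9)

    def test_scale_invariance(self, planted):
        # scaling every raw count and total by a constant leaves the scale
        # factors unchanged and the normalized values exactly homogeneous
        lib, _ = gen_library(planted, LibrarySpec(depth=5_000, seed=9))
        other = SmallRNALibrary.from_pairs(
            "other", lib.records, total_reads=lib.total_reads * 3
        )
        def scaled_by(l, c):
            return SmallRNALibrary.from_pairs(
                l.sample_id, [(r, cnt * c) for r, cnt in l.records],
                total_reads=l.total_reads * c,
            )
        assert normalize([lib, other]) == normalize(
            [scaled_by(lib, 7), scaled_by(other, 7)]
        )
        schemes = {planted.hairpin.seq.id: planted.scheme}
        a = quantify([lib, other], [planted.hairpin.seq], schemes)
        b = quantify([scaled_by(lib, 7), scaled_by(other, 7)],
                     [planted.hairpin.seq], schemes)
        assert np.allclose(b[["unique", "max_possible"]], 7 * a[["unique", "max_possible"]])

    def test_shared_read_in_max_possible_only(self, planted):
        seq = planted.hairpin.seq
        paralog = gen_shared_paralog(planted, seed=2)
        m0, _ = planted.scheme.intervals["miR"]
        shared_read = seq.residues[m0:m0 + 21]
        lib = SmallRNALibrary.from_pairs("s", [(shared_read, 10)])
        expr = quantify([lib], [seq, paralog], {seq.id: planted.scheme})
        row = expr[(expr.precursor == seq.id) & (expr.partition == "miR")].iloc[0]
        assert row["unique"] == 0.0 and row["max_possible"] == pytest.approx(10.0)

    def test_empty_library_all_zero(self, planted):
        lib = SmallRNALibrary.from_pairs("s", [("G" * 25, 1)])  # unmappable
        expr = quantify([lib], [planted.hairpin.seq], {planted.hairpin.seq.id: planted.scheme})
        assert (expr[["unique", "max_possible"]].to_numpy() == 0).all()


class TestPoolGroup:
    def test_shared_reads_counted_once_per_group(self, planted):
        from phasemir.quant import pool_group

        seq = planted.hairpin.seq
        paralog = gen_shared_paralog(planted, seed=3)
        m0, m1 = planted.scheme.intervals["miR"]
        shared_read = seq.residues[m0:m1]
        lib = SmallRNALibrary.from_pairs("s", [(shared_read, 12)])
        # the paralog has no partition scheme: pool over the one schemed member
        pooled = pool_group([lib], "group159", [seq.id],
                            [seq, paralog], {seq.id: planted.scheme})
        mir_total = pooled[pooled.partition == "miR"]["abundance"].sum()
        assert mir_total == pytest.approx(12.0)


def _expr(sample, precursor, values):
    rows = [
        {"sample": sample, "precursor": precursor, "partition": p,
         "unique": v, "max_possible": v}
        for p, v in values.items()
    ]
    return pd.DataFrame.from_records(rows)


class TestRatioConventions:
    def test_plain_ratio(self):
        r = ratio_mut_wt(_expr("m", "p", {"miR": 200.0}), _expr("w", "p", {"miR": 20.0}))
        assert r.iloc[0].ratio == pytest.approx(10.0) and r.iloc[0].flag == ""

    def test_both_below_floor_absent(self):
        r = ratio_mut_wt(_expr("m", "p", {"ACR3": 0.2}), _expr("w", "p", {"ACR3": 0.1}))
        assert r.iloc[0].ratio == 1.0 and r.iloc[0].flag == "absent"

    def test_denominator_floored(self):
        r = ratio_mut_wt(_expr("m", "p", {"ACR3": 50.0}), _expr("w", "p", {"ACR3": 0.1}))
        assert r.iloc[0].ratio == pytest.approx(50.0) and r.iloc[0].flag == "floored"

    def test_replicates_averaged_before_ratio(self):
        mut = pd.concat([_expr("m1", "p", {"miR": 10.0}), _expr("m2", "p", {"miR": 30.0})])
        wt = pd.concat([_expr("w1", "p", {"miR": 5.0}), _expr("w2", "p", {"miR": 15.0})])
        r = ratio_mut_wt(mut, wt)
        assert r.iloc[0].ratio == pytest.approx(2.0)


class TestLengthClassRatio:
    def test_uniform_doubling(self):
        read = "ACGUACGUACGUACGUACGUA"  # 21 nt
        mut = SmallRNALibrary.from_pairs("m", [(read, 40)], total_reads=100)
        wt = SmallRNALibrary.from_pairs("w", [(read, 20)], total_reads=100)
        out = length_class_ratio([mut], [wt], [(20, 21), (24, 24)])
        b2021 = out[out["bin"] == "20-21"].iloc[0]
        assert b2021.ratio == pytest.approx(2.0)
        b24 = out[out["bin"] == "24-24"].iloc[0]
        assert b24.ratio == 1.0 and b24.flag == "absent"

    def test_planted_depletion(self):
        rng = np.random.default_rng(4)
        reads24 = ["".join("ACGU"[i] for i in rng.integers(0, 4, 24)) for _ in range(30)]
        reads21 = ["".join("ACGU"[i] for i in rng.integers(0, 4, 21)) for _ in range(30)]
        wt = SmallRNALibrary.from_pairs("w", [(r, 100) for r in reads24 + reads21],
                                        total_reads=6000)
        mut = SmallRNALibrary.from_pairs(
            "m", [(r, 10) for r in reads24] + [(r, 100) for r in reads21],
            total_reads=3300,
        )
        out = length_class_ratio([mut], [wt], [(20, 21), (24, 24)])
        # normalization rescales both to the mean total first
        f_m, f_w = (6000 + 3300) / 2 / 3300, (6000 + 3300) / 2 / 6000
        b24 = out[out["bin"] == "24-24"].iloc[0]
        assert b24.ratio == pytest.approx((300 * f_m) / (3000 * f_w))

    def test_overlapping_bins_rejected(self):
        lib = SmallRNALibrary.from_pairs("a", [("ACGUACGUACGUACGUACGUA", 1)])
        with pytest.raises(ValueError):
            length_class_ratio([lib], [lib], [(20, 22), (22, 24)])
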
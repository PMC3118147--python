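"""Hairpin geometry, homolog window search, and the miRcheck rules."""
import numpy as np
import pytest

import oracles
from phasemir.hairpin import Arm, arm_of, locate_star
from phasemir.scan import (
    MatureQuery,
    Status,
    assign_name,
    call_status,
    evaluate_mircheck,
    extract_flanks,
    find_matches,
    levenshtein,
    merge_windows,
    shared_nucleotides,
    _windows_for_strand,
)
from phasemir.sequences import RnaSequence, reverse_complement
from phasemir.simulate import HairpinSpec, gen_hairpin


@pytest.fixture
def clean():
    return gen_hairpin(HairpinSpec(seed=11))


class TestArmOf:
    def test_five_three_and_spanning(self, clean):
        h = clean.hairpin
        lo, hi = h.loop_span
        assert arm_of(h, (0, lo)) is Arm.FIVE_PRIME
        assert arm_of(h, (hi, len(h.seq))) is Arm.THREE_PRIME
        assert arm_of(h, (lo - 2, lo + 2)) is Arm.SPANS_LOOP


class TestLocateStar:
    def test_perfect_duplex_is_shifted_reverse_window(self, clean):
        # planted duplex: miR fully paired, so the star is the 21-nt partner
        # window under the symmetric 2-nt 3'-overhang offset
        star = locate_star(clean.hairpin, clean.mir)
        assert star[1] - star[0] == 21
        partner = clean.hairpin.struct.partner
        partners = [partner[i] for i in range(*clean.mir)]
        assert star == (min(partners) + 2, max(partners) + 1 + 2)

    def test_star_side_bulge_widens_star(self):
        planted = gen_hairpin(HairpinSpec(seed=4, star_bulges=((10, 2),)))
        star = locate_star(planted.hairpin, planted.mir)
        assert star[1] - star[0] == 23

    def test_mir_overlapping_loop_rejected(self, clean):
        lo, hi = clean.hairpin.loop_span
        with pytest.raises(ValueError):
            locate_star(clean.hairpin, (lo - 3, lo + 3))

    def test_unpaired_mir_rejected(self, clean):
        # sp5 tail is unpaired by construction
        L = len(clean.hairpin.seq)
        with pytest.raises(ValueError, match="unpaired"):
            locate_star(clean.hairpin, (L - 4, L))


class TestFindMatches:
    def test_exact_substring(self):
        rng = np.random.default_rng(0)
        query = MatureQuery("q", "AAGGCUGGAAUCCGAUCGAUG")
        t = "".join("ACGU"[i] for i in rng.integers(0, 4, 80))
        target = RnaSequence("t", t[:30] + query.residues + t[30:])
        hits = [h for h in find_matches(target, query, 0) if h.strand == "+"]
        assert [(h.start, h.end, h.distance) for h in hits] == [(30, 51, 0)]

    def test_single_substitution(self):
        query = MatureQuery("q", "AAAACCCCGGGGAAACCCGG")
        window = "AAAACCACGGGGAAACCCGG"
        target = RnaSequence("t", "GUGUGUGU" + window + "GUGUGUGU")
        hits = [h for h in find_matches(target, query, 2) if h.strand == "+"]
        assert any(h.distance == 1 for h in hits)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(3)
        query = MatureQuery("q", "".join("ACGU"[i] for i in rng.integers(0, 4, 21)))
        t = "".join("ACGU"[i] for i in rng.integers(0, 4, 120))
        target = RnaSequence("t", t)
        rc = RnaSequence("t_rc", reverse_complement(t))
        fwd = {(h.start, h.end, h.distance, h.strand) for h in find_matches(target, query, 2)}
        rev = {
            (len(t) - h.end, len(t) - h.start, h.distance, {"+": "-", "-": "+"}[h.strand])
            for h in find_matches(rc, query, 2)
        }
        assert fwd == rev

    def test_windows_match_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(15):
            t = "".join("ACGU"[i] for i in rng.integers(0, 4, 90))
            q = "".join("ACGU"[i] for i in rng.integers(0, 4, 12))
            # plant an approximate copy to guarantee hits
            t = t[:40] + q[:5] + "A" + q[6:] + t[40:]
            got = sorted(_windows_for_strand(t, q, 3))
            expected = sorted(oracles.all_windows(t, q, 3))
            assert got == expected
            assert merge_windows(got) == merge_windows(expected)

    def test_empty_target(self):
        q = MatureQuery("q", "ACGUACGUACGUACGUACGU")
        assert find_matches(RnaSequence("t", "A", allow_n=True), q, 1) == []


class TestExtractFlanks:
    def test_interior_hit(self):
        t = RnaSequence("t", "A" * 1000)
        sub, off = extract_flanks(t, (400, 421), 350)
        assert (len(sub), off) == (721, 350)

    def test_left_truncation(self):
        t = RnaSequence("t", "A" * 1000)
        sub, off = extract_flanks(t, (10, 31), 350)
        assert (len(sub), off) == (381, 10)

    def test_whole_target(self):
        t = RnaSequence("t", "A" * 50)
        sub, off = extract_flanks(t, (0, 50), 350)
        assert (len(sub), off) == (50, 0)


def _oracle_decisions(h, mir):
    counts = oracles.mircheck_counts(h.struct.partner, h.loop_span, len(h.seq), mir)
    return oracles.mircheck_decisions(counts)


class TestMircheck:
    def test_clean_hairpin_passes_all(self, clean):
        rep = evaluate_mircheck(clean.hairpin, clean.mir)
        assert rep.overall and all(r.passed for r in rep.rules.values())

    @pytest.mark.parametrize(
        "spec_kwargs,failing",
        [
            (dict(sym_loops=((5, 3), (10, 3), (15, 1))), {2}),         # 7 unpaired
            (dict(sym_loops=((3, 1), (7, 1), (11, 1), (15, 1))), {3}),  # 4 bulges
            (dict(star_bulges=((10, 4),)), {4}),                        # star 4 longer
            (dict(mir_bulges=((5, 2), (12, 2)), star_bulges=((17, 4),)), {5}),
            (dict(sym_loops=((8, 4),)), {6}),                           # 4-run
            (dict(short_d=True, loop=6), {7}),                          # D = 4
        ],
    )
    def test_single_rule_violations(self, spec_kwargs, failing):
        planted = gen_hairpin(HairpinSpec(seed=23, **spec_kwargs))
        rep = evaluate_mircheck(planted.hairpin, planted.mir)
        assert {k for k, r in rep.rules.items() if not r.passed} == failing
        assert not rep.overall

    def test_agrees_with_bruteforce_checker(self):
        rng = np.random.default_rng(5)
        specs = [
            {},
            dict(sym_loops=((4, 2), (9, 3), (14, 2))),
            dict(mir_bulges=((6, 4),)),
            dict(star_bulges=((3, 2), (15, 3))),
            dict(short_d=True, loop=6),
            dict(short_d=True, loop=12),
        ]
        for _ in range(40):
            kw = specs[int(rng.integers(len(specs)))]
            planted = gen_hairpin(HairpinSpec(seed=int(rng.integers(1 << 30)), **kw))
            rep = evaluate_mircheck(planted.hairpin, planted.mir)
            expected = _oracle_decisions(planted.hairpin, planted.mir)
            got = {k: r.passed for k, r in rep.rules.items()}
            assert got == expected
            assert rep.overall == all(expected.values())

    def test_rule7_boundary_inclusive(self):
        ok = gen_hairpin(HairpinSpec(seed=9, short_d=True, loop=7))   # D = 5
        bad = gen_hairpin(HairpinSpec(seed=9, short_d=True, loop=6))  # D = 4
        assert evaluate_mircheck(ok.hairpin, ok.mir).rules[7].passed
        assert not evaluate_mircheck(bad.hairpin, bad.mir).rules[7].passed


class TestCallStatus:
    @pytest.fixture
    def passing_report(self, clean):
        return evaluate_mircheck(clean.hairpin, clean.mir)

    @pytest.mark.parametrize(
        "d,expected",
        [(0, Status.HOMOLOG), (3, Status.HOMOLOG), (4, Status.CANDIDATE), (5, Status.REJECTED)],
    )
    def test_edit_distance_thresholds(self, d, expected, passing_report):
        assert call_status(d, passing_report) is expected

    def test_rule_failure_rejects_even_perfect_match(self):
        planted = gen_hairpin(HairpinSpec(seed=2, short_d=True, loop=6))
        rep = evaluate_mircheck(planted.hairpin, planted.mir)
        assert call_status(2, rep) is Status.REJECTED

    def test_monotone_in_distance(self, passing_report):
        order = {Status.HOMOLOG: 0, Status.CANDIDATE: 1, Status.REJECTED: 2}
        ranks = [order[call_status(d, passing_report)] for d in range(8)]
        assert ranks == sorted(ranks)


class TestAssignName:
    def test_closest_reference_wins(self):
        refs = [MatureQuery("x", "AAAACCCCGGGGAAAACCCC"),
                MatureQuery("y", "GGGGAAAACCCCGGGGAAAA")]
        assert assign_name("AAAACCCCGGGGAAAACCCC", refs) == "x"
        assert assign_name("AAAACCACGGGGAAAACCCC", refs) == "x"

    def test_matches_exhaustive_distance_oracle(self):
        rng = np.random.default_rng(13)
        refs = [
            MatureQuery(f"r{i}", "".join("ACGU"[j] for j in rng.integers(0, 4, 21)))
            for i in range(10)
        ]
        for _ in range(50):
            probe = "".join("ACGU"[j] for j in rng.integers(0, 4, 21))
            got = assign_name(probe, refs)
            best = min(refs, key=lambda r: (oracles.lev(probe, r.residues), r.id))
            assert got == best.id


class TestSequenceSimilarity:
    def test_levenshtein_matches_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a = "".join("ACGUN"[i] for i in rng.integers(0, 5, int(rng.integers(0, 12))))
            b = "".join("ACGUN"[i] for i in rng.integers(0, 5, int(rng.integers(1, 12))))
            assert levenshtein(a, b) == oracles.lev(a, b)

    def test_shared_nucleotides_identity(self):
        assert shared_nucleotides("ACGU", "ACGU") == 4
        assert shared_nucleotides("AAAA", "CCCC") == 0
        # offset by one: best ungapped register
        assert shared_nucleotides("GACGU", "ACGUU") == 4
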
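"""Gap filtering, consensus columns, and covariation pair detection."""
import math

import numpy as np
import pytest

import oracles
from phasemir.consensus import (
    ConsensusParams,
    StructuralAlignment,
    column_consensus,
    consensus_dotbracket,
    consensus_result,
    detect_pairs,
    filter_columns,
    pair_support,
    write_stockholm,
)
from phasemir.phylo.models import SubstitutionModel
from phasemir.phylo.trees import random_unrooted_topology
from phasemir.simulate import EvolSpec, evolve, paired_doublet_freqs


def _aln(rows):
    return StructuralAlignment(tuple(f"r{i}" for i in range(len(rows))), tuple(rows))


class TestFilterColumns:
    def test_gap_fraction_boundary(self):
        # 10 rows: 8 gaps (80%) removed, 7 gaps (70%) kept
        rows = []
        for i in range(10):
            c0 = "-" if i < 8 else "A"
            c1 = "-" if i < 7 else "C"
            rows.append(c0 + c1 + "G")
        filtered, kept = filter_columns(_aln(rows))
        assert kept == (1, 2)

    def test_exactly_75_percent_kept(self):
        rows = ["-A" if i < 3 else "AA" for i in range(4)]  # col 0: 75% gaps
        _, kept = filter_columns(_aln(rows))
        assert kept == (0, 1)

    def test_all_removed_errors(self):
        rows = ["-", "-", "-", "A"]  # single column, 75% gaps -> kept; force removal
        with pytest.raises(ValueError):
            filter_columns(_aln(["-", "-", "-", "-", "A"]))  # 80% gaps

    def test_row_permutation_commutes(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACGU-"), 30)) for _ in range(8)]
        perm = list(rng.permutation(8))
        a = filter_columns(_aln(rows))[1]
        b = filter_columns(_aln([rows[i] for i in perm]))[1]
        assert a == b


class TestColumnConsensus:
    def test_pure_column(self):
        cons, ic = column_consensus("UUUUUUUUUU")
        assert cons == "U" and ic == pytest.approx(2.0)

    def test_uniform_column(self):
        cons, ic = column_consensus("ACGUACGU")
        assert cons is None and ic == pytest.approx(0.0)

    def test_seventy_thirty_column(self):
        cons, ic = column_consensus("AAAAAAAGGG")
        assert cons is None  # 0.7 < 0.8
        h = -(0.7 * math.log2(0.7) + 0.3 * math.log2(0.3))
        assert ic == pytest.approx(2 - h, abs=1e-9)

    def test_gaps_scale_information(self):
        _, ic_full = column_consensus("AAAA")
        _, ic_half = column_consensus("AA--")
        assert ic_half == pytest.approx(ic_full / 2)

    def test_ic_two_iff_pure_and_gapless(self):
        assert column_consensus("AAA-")[1] < 2.0
        assert column_consensus("AAAA")[1] == pytest.approx(2.0)


class TestPairSupport:
    def test_all_gc(self):
        sup, ntypes = pair_support(_aln(["G...C"] * 6), 0, 4)
        assert sup == 1.0 and ntypes == 1

    def test_mixed_pair_types(self):
        sup, ntypes = pair_support(_aln(["G...C"] * 5 + ["A...U"] * 5), 0, 4)
        assert sup == 1.0 and ntypes == 2

    def test_gap_rows_excluded_from_denominator(self):
        rows = ["G...C"] * 6 + ["-...C"] * 2
        sup, _ = pair_support(_aln(rows), 0, 4)
        assert sup == 1.0

    def test_too_gappy_pair_ineligible(self):
        rows = ["G...C"] * 2 + ["-...C"] * 6
        sup, _ = pair_support(_aln(rows), 0, 4)
        assert sup == 0.0


class TestDetectPairs:
    def test_single_consensus_pair(self):
        calls = detect_pairs(_aln(["G....C"] * 10))
        assert [(c.i, c.j, c.klass) for c in calls] == [(0, 5, "consensus")]

    def test_covarying_pair(self):
        calls = detect_pairs(_aln(["G....C"] * 5 + ["A....U"] * 5))
        assert [(c.i, c.j, c.klass) for c in calls] == [(0, 5, "covarying")]

    def test_selected_set_never_crosses(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            rows = ["".join(rng.choice(list("ACGU"), 40)) for _ in range(8)]
            calls = detect_pairs(_aln(rows))
            for a in range(len(calls)):
                for b in range(a + 1, len(calls)):
                    i, j = calls[a].i, calls[a].j
                    k, l = calls[b].i, calls[b].j
                    assert not (i < k < j < l or k < i < l < j)

    def test_dp_equals_exhaustive_on_small_alignments(self):
        rng = np.random.default_rng(11)
        params = ConsensusParams()
        for _ in range(12):
            rows = ["".join(rng.choice(list("ACGU-"), 14)) for _ in range(6)]
            aln = _aln(rows)
            calls = detect_pairs(aln, params)
            got = sum(c.support for c in calls)
            cand = {}
            for i in range(14):
                for j in range(i + params.min_loop + 1, 14):
                    sup, _ = pair_support(aln, i, j)
                    if sup >= params.min_pair_support - 1e-12:
                        cand[(i, j)] = sup
            best = oracles.best_noncrossing_support(cand, 14, params.min_loop)
            assert got == pytest.approx(best, abs=1e-9)

    def test_planted_structure_recovery(self):
        rng = np.random.default_rng(21)
        tree = random_unrooted_topology(
            [f"t{i}" for i in range(30)], rng, lambda: float(rng.exponential(0.1))
        )
        pairs = tuple((i, 149 - i) for i in range(40))
        model = SubstitutionModel(doublet_freqs=paired_doublet_freqs())
        rows = evolve(EvolSpec(tree, model, 150, pairs, seed=8))
        aln = _aln([rows[k] for k in sorted(rows)])
        got = {(c.i, c.j) for c in detect_pairs(aln)}
        assert len(got & set(pairs)) / len(pairs) >= 0.9


class TestStockholmRoundTrip:
    def test_write_and_reread(self, tmp_path):
        rows = ["GAAAC-", "GACAC-", "GAUACA"]
        aln = _aln(rows)
        result = consensus_result(aln)
        out = tmp_path / "cons.sto"
        write_stockholm(aln, result, out)
        back = StructuralAlignment.from_file(out, "stockholm")
        assert back.n_rows == 3
        text = out.read_text()
        assert "#=GC SS_cons" in text
        assert consensus_dotbracket(result) in text
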
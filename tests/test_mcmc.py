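"""MCMC sampling, majority-rule consensus, duplicate-taxon handling."""
import dendropy
import numpy as np
import pytest

from phasemir.phylo.likelihood import SitePartition
from phasemir.phylo.mcmc import (
    McmcConfig,
    TreeSample,
    dedup_reinsert,
    majority_consensus,
    mcmc,
    reinsert_duplicates,
)
from phasemir.phylo.models import SubstitutionModel
from phasemir.phylo.trees import Tree, nni, random_unrooted_topology
from phasemir.simulate import EvolSpec, evolve, paired_doublet_freqs


class TestMajorityConsensus:
    def test_identical_samples_return_that_tree(self):
        rng = np.random.default_rng(0)
        tree = random_unrooted_topology(list("abcdef"), rng)
        samples = [TreeSample(tree.splits(), tree.newick(), 0.0, 1.0)] * 10
        cons = majority_consensus(samples, list("abcdef"))
        assert cons.splits() == tree.splits()
        supports = [n.support for n in cons.postorder() if n.support is not None]
        assert all(s == pytest.approx(1.0) for s in supports)

    def test_sixty_forty_contested_split(self):
        rng = np.random.default_rng(1)
        t1 = random_unrooted_topology(list("abcdef"), rng)
        t2 = t1.copy()
        assert nni(t2, rng) is not None
        samples = [TreeSample(t1.splits(), "", 0.0, 1.0)] * 6 + [
            TreeSample(t2.splits(), "", 0.0, 1.0)
        ] * 4
        cons = majority_consensus(samples, list("abcdef"))
        assert cons.splits() <= t1.splits()
        contested = t1.splits() - t2.splits()
        for node in cons.postorder():
            if node.support is not None and node.support < 0.99:
                assert node.support == pytest.approx(0.6)

    def test_split_frequencies_match_bruteforce_counting(self):
        rng = np.random.default_rng(3)
        trees = [random_unrooted_topology(list("abcdef"), rng) for _ in range(30)]
        samples = [TreeSample(t.splits(), "", 0.0, 1.0) for t in trees]
        cons = majority_consensus(samples, list("abcdef"))
        counts = {}
        for t in trees:
            for s in t.splits():
                counts[s] = counts.get(s, 0) + 1
        expected = {s for s, c in counts.items() if c / 30 > 0.5}
        assert cons.splits() == expected

    def test_agrees_with_dendropy_consensus(self):
        rng = np.random.default_rng(7)
        base = random_unrooted_topology(list("abcdefg"), rng)
        trees = []
        for _ in range(40):
            t = base.copy()
            if rng.random() < 0.4:
                nni(t, rng)
            trees.append(t)
        samples = [TreeSample(t.splits(), t.newick(), 0.0, 1.0) for t in trees]
        cons = majority_consensus(samples, list("abcdefg"))

        tns = dendropy.TaxonNamespace()
        dtrees = dendropy.TreeList(
            [dendropy.Tree.get(data=t.newick(), schema="newick", taxon_namespace=tns)
             for t in trees], taxon_namespace=tns)
        dcons = dtrees.consensus(min_freq=0.5)
        got = Tree._from_dendropy(dcons).splits()
        assert cons.splits() == got


class TestDedupReinsert:
    def test_no_duplicates_identity(self):
        rows = {"a": "ACGU", "b": "ACGA", "c": "ACGC"}
        reduced, mapping = dedup_reinsert(rows)
        assert reduced == rows and mapping == {}

    def test_three_identical_rows_collapse_and_reinsert(self):
        rows = {"a": "ACGU", "b": "ACGU", "c": "ACGU", "d": "AAAA", "e": "CCCC"}
        reduced, mapping = dedup_reinsert(rows)
        assert set(reduced) == {"a", "d", "e"}
        assert mapping == {"a": ["a", "b", "c"]}
        rng = np.random.default_rng(0)
        tree = random_unrooted_topology(sorted(reduced), rng)
        expanded = reinsert_duplicates(tree, mapping)
        assert sorted(expanded.leaf_names()) == ["a", "b", "c", "d", "e"]
        holder = [n for n in expanded.postorder()
                  if {c.name for c in n.children} == {"a", "b", "c"}]
        assert len(holder) == 1
        assert holder[0].support == 100.0
        assert all(c.length == pytest.approx(0.001) for c in holder[0].children)

    def test_round_trip_preserves_taxa(self):
        rng = np.random.default_rng(5)
        rows = {f"t{i}": "ACGU" if i % 3 == 0 else f"ACG{'ACGU'[i % 4]}" for i in range(9)}
        reduced, mapping = dedup_reinsert(rows)
        tree = random_unrooted_topology(sorted(reduced), rng)
        expanded = reinsert_duplicates(tree, mapping)
        assert sorted(expanded.leaf_names()) == sorted(rows)


class TestMcmcSampling:
    def test_prior_only_topologies_near_uniform(self):
        # 4 taxa: 3 unrooted topologies; prior-only sampling should visit
        # them in roughly equal proportion
        model = SubstitutionModel()
        res = mcmc(None, None, model,
                   McmcConfig(n_generations=30000, sample_interval=10, n_runs=1,
                              burn_in=0.1, seed=5),
                   taxa=list("abcd"))
        counts = {}
        for s in res.runs[0]:
            counts[s.splits] = counts.get(s.splits, 0) + 1
        freqs = np.array(sorted(counts.values())) / sum(counts.values())
        assert len(counts) == 3
        assert freqs.min() > 0.2 and freqs.max() < 0.5

    def test_small_recovery_and_convergence_report(self):
        rng = np.random.default_rng(12)
        true_tree = random_unrooted_topology(
            list("abcdef"), rng, lambda: float(rng.uniform(0.08, 0.3))
        )
        pairs = tuple((i, 199 - i) for i in range(60))
        model = SubstitutionModel(doublet_freqs=paired_doublet_freqs(0.9),
                                  gamma_shape=0.8)
        rows = evolve(EvolSpec(true_tree, model, 600, pairs, seed=2))
        part = SitePartition.from_structure(600, pairs)
        res = mcmc(rows, part, model,
                   McmcConfig(n_generations=8000, n_runs=2, seed=3))
        cons = majority_consensus(res.pooled(), list("abcdef"))
        assert cons.splits() == true_tree.splits()
        assert np.isfinite(res.asdsf) and res.asdsf < 0.15
        assert set(res.acceptance) == {"nni", "branch", "alpha", "freq"}

    def test_deterministic_given_seed(self):
        model = SubstitutionModel()
        rng = np.random.default_rng(4)
        tree = random_unrooted_topology(list("abcde"), rng)
        pairs = ((0, 9), (1, 8))
        rows = evolve(EvolSpec(tree, model, 10, pairs, seed=6))
        part = SitePartition.from_structure(10, pairs)
        cfg = McmcConfig(n_generations=500, sample_interval=50, seed=42)
        a = mcmc(rows, part, model, cfg)
        b = mcmc(rows, part, model, cfg)
        assert [s.newick for r in a.runs for s in r] == [s.newick for r in b.runs for s in r]
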
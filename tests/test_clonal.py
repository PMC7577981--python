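import numpy as np
import pytest

import clonalevo as ce
from clonalevo.clonal import DEFAULT_PATHWAY_MAP
from clonalevo.phylogeny import AttachmentPosterior
from clonalevo.tree import MutationTree


def _attachment(tree, counts, n_draws=50, jitter=0.0, seed=0):
    """Build an attachment posterior with given point counts."""
    counts = np.asarray(counts, dtype=float)
    rng = np.random.default_rng(seed)
    draws = np.maximum(counts + rng.normal(0, jitter, size=(n_draws, len(counts))), 0)
    n = counts.sum()
    probs = np.tile(counts / n, (int(n), 1))
    return AttachmentPosterior(
        probs=probs,
        counts_draws=draws,
        point=draws.mean(axis=0),
        ci_low=np.percentile(draws, 2.5, axis=0),
        ci_high=np.percentile(draws, 97.5, axis=0),
        cell_ids=tuple(f"c{i}" for i in range(int(n))),
        node_labels=("root",) + tuple(tree.labels),
        tree=tree,
        uninformative_cells=np.zeros(int(n), dtype=bool),
    )


class TestComposeClones:
    def test_all_wildtype_gives_empty_composition(self):
        tree = MutationTree((0,), labels=("A",))
        comp = ce.compose_clones(_attachment(tree, [100, 0]))
        assert comp.subclones == []
        assert comp.wt_cell_count == 100

    def test_linear_tree_fractions(self):
        tree = MutationTree((0, 1), labels=("A", "B"))
        comp = ce.compose_clones(_attachment(tree, [0, 60, 40]))
        assert comp.n_subclones == 2
        by_muts = {s.mutations: s.fraction for s in comp.subclones}
        assert by_muts[("A",)] == pytest.approx(0.6)
        assert by_muts[("A", "B")] == pytest.approx(0.4)

    def test_cell_conservation(self, small_sample):
        cfg = ce.McmcConfig(chain_length=3000, n_chains=1, seed=1, model_id=2)
        post = ce.mcmc_infer(small_sample["observed"],
                             ce.ErrorModel(fpr=0.01, fnr=0.06), cfg)
        att = ce.attach_cells(post, small_sample["observed"], seed=2)
        comp = ce.compose_clones(att)
        total = comp.wt_cell_count + sum(s.cell_count for s in comp.subclones)
        assert total == pytest.approx(small_sample["observed"].n_cells)

    def test_fractions_sum_to_one_and_threshold_flagging(self):
        tree = MutationTree((0, 0, 0), labels=("A", "B", "C"))
        comp = ce.compose_clones(_attachment(tree, [10, 990, 7, 3]),
                                 threshold=0.01)
        assert sum(s.fraction for s in comp.subclones) == pytest.approx(1.0)
        flags = {s.mutations[0]: s.below_threshold for s in comp.subclones}
        assert not flags["A"] and flags["C"]  # 3/1000 < 1%

    def test_twelve_clone_composition_recovered(self):
        # a convergent 12-clone structure, all clones above 1%
        parent = (0, 1, 1, 2, 2, 3, 3, 4, 5, 6, 7, 2)
        tree = MutationTree(parent)
        counts = [0] + [100] * 12
        comp = ce.compose_clones(_attachment(tree, counts), threshold=0.01)
        assert comp.n_subclones == 12
        assert not any(s.below_threshold for s in comp.subclones)


class TestShannonIndex:
    def test_single_clone_exact_zero(self):
        assert ce.shannon_index(np.array([1.0])) == 0.0

    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_equal_clones_exact_log2k(self, k):
        assert ce.shannon_index(np.full(k, 1 / k)) == pytest.approx(np.log2(k))

    def test_hand_computed_example(self):
        assert ce.shannon_index(np.array([0.5, 0.25, 0.25])) == pytest.approx(1.5)

    def test_matches_reference_implementation(self):
        # the diversity routine the field uses (scikit-bio) as oracle
        from skbio.diversity.alpha import shannon

        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(1, 500, size=rng.integers(2, 10))
            ours = ce.shannon_index(counts / counts.sum())
            theirs = float(shannon(counts, base=2))
            assert ours == pytest.approx(theirs, abs=1e-9)

    def test_empty_composition_errors(self):
        with pytest.raises(ValueError):
            ce.shannon_index(np.array([]))


class TestClassifyEvolution:
    def test_pure_path_is_linear(self):
        call = ce.classify_evolution(MutationTree((0, 1, 2)))
        assert call.pattern == "linear" and not call.convergent

    def test_terminal_fork_counts_as_linear(self):
        # trunk then a fork whose children are both leaves
        call = ce.classify_evolution(MutationTree((0, 1, 1)))
        assert call.pattern == "linear"

    def test_terminal_fork_strict_mode_is_branching(self):
        call = ce.classify_evolution(MutationTree((0, 1, 1)), strict_linear=True)
        assert call.pattern == "branching"

    def test_non_terminal_fork_is_branching(self):
        # root -> A, A -> {B, C}, B -> D
        call = ce.classify_evolution(MutationTree((0, 1, 1, 2)))
        assert call.pattern == "branching"

    def test_convergent_parallel_gene_hits(self):
        labels = ("NPM1 p.L287fs", "IDH1 p.R132H", "IDH2 p.R140Q",
                  "KRAS p.G12A", "NRAS p.G12A")
        tree = MutationTree((0, 1, 1, 2, 3), labels=labels)
        call = ce.classify_evolution(tree, pathway_map=DEFAULT_PATHWAY_MAP)
        assert call.pattern == "branching"
        assert call.convergent
        assert "DNA methylation" in call.convergent_units  # IDH1 vs IDH2
        assert "RTK/RAS/MAPK" in call.convergent_units  # KRAS vs NRAS

    def test_same_gene_convergence_without_map(self):
        labels = ("NPM1", "IDH1 p.R132C", "IDH1 p.R132H", "KRAS p.G12D")
        tree = MutationTree((0, 1, 1, 2), labels=labels)
        call = ce.classify_evolution(tree)
        assert call.pattern == "branching"
        assert call.convergent and call.convergent_units == ("IDH1",)

    def test_terminal_fork_same_gene_stays_linear_hence_not_convergent(self):
        # a bare terminal fork is linear by convention, and convergence is
        # only called on branching trees
        tree = MutationTree((0, 1, 1), labels=("NPM1", "IDH1 a", "IDH1 b"))
        call = ce.classify_evolution(tree)
        assert call.pattern == "linear" and not call.convergent

    def test_serial_same_gene_hits_not_convergent(self):
        # two hits in one gene on the same lineage: not parallel
        tree = MutationTree((0, 1, 2, 1), labels=("A", "TP53 a", "TP53 b", "B"))
        call = ce.classify_evolution(tree)
        assert call.pattern == "branching"
        assert not call.convergent

    def test_dead_clones_change_classification(self):
        # branching topology, but one branch has no surviving cells
        tree = MutationTree((0, 1, 1, 2), labels=("A", "B", "C", "D"))
        att = _attachment(tree, [0, 10, 50, 0, 40])
        comp = ce.compose_clones(att)
        call = ce.classify_evolution(tree, comp)
        # event C has no cells at or below its node, so it is pruned and the
        # surviving A -> B -> D path is linear
        assert call.pattern == "linear"

    def test_invariance_to_fraction_rescaling(self):
        tree = MutationTree((0, 1, 1, 2))
        a = _attachment(tree, [0, 400, 300, 200, 100])
        b = _attachment(tree, [0, 40, 30, 20, 10])
        assert (
            ce.classify_evolution(tree, ce.compose_clones(a)).pattern
            == ce.classify_evolution(tree, ce.compose_clones(b)).pattern
        )


class TestPrevalenceMatrix:
    def test_timepoints_by_clones_layout(self):
        tree = MutationTree((0, 1))
        comps = {
            "t0": ce.compose_clones(_attachment(tree, [10, 80, 10])),
            "t1": ce.compose_clones(_attachment(tree, [10, 30, 60])),
        }
        mat = ce.prevalence_matrix(comps)
        assert list(mat.index) == ["t0", "t1"]
        assert list(mat.columns) == ["clone1", "clone2"]
        assert mat.loc["t1", "clone2"] == pytest.approx(60 / 90)


def test_branching_yields_higher_diversity_than_linear_under_selection():
    """With cumulative driver fitness, a chain is dominated by its deepest
    clone while branching trees spread mass over parallel deep branches."""
    rng = np.random.default_rng(99)
    h_linear, h_branching = [], []
    chain = MutationTree(tuple(range(8)))  # 0,1,2,...: pure path
    for rep in range(120):
        fr = ce.simulate_clone_fractions(
            chain, wt_fraction=0.05, selection_strength=2.0,
            seed=int(rng.integers(1e9)),
        )[0]
        h_linear.append(ce.shannon_index(fr[1:]))
        while True:
            t = ce.simulate_tree(8, seed=int(rng.integers(1e9)))
            if ce.classify_evolution(t).pattern == "branching":
                break
        fr = ce.simulate_clone_fractions(
            t, wt_fraction=0.05, selection_strength=2.0,
            seed=int(rng.integers(1e9)),
        )[0]
        h_branching.append(ce.shannon_index(fr[1:]))
    assert np.mean(h_branching) > np.mean(h_linear)
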
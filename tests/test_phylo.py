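"""GTR+I+G likelihood, exhaustive ML search and bootstrap."""

import itertools

import numpy as np
import pytest
import scipy.linalg

from plastokit.codonalign import Supermatrix
from plastokit.phylo import (
    FitResult,
    GTRIGModel,
    TreeNode,
    bipartitions,
    bootstrap,
    compress_patterns,
    enumerate_topologies,
    fit,
    log_likelihood,
    ml_search,
    parse_newick,
    write_result,
)


def _matrix(taxa, rows):
    return Supermatrix(list(taxa), list(rows), [("all", 0, len(rows[0]))])


def _random_matrix(taxa, length, seed):
    rng = np.random.default_rng(seed)
    rows = ["".join(rng.choice(list("ACGT"), length)) for _ in taxa]
    return _matrix(taxa, rows)


def _brute_force_lnl(tree, model, taxa, rows):
    """Independent oracle: explicit summation over all internal-node state
    assignments, per site, per rate category, with the invariant class."""
    pi = model.base_freqs
    rates = model.category_rates()
    code = {c: i for i, c in enumerate("ACGT")}
    internals = [n for n in tree.walk() if not n.is_leaf]
    parents = {
        id(c): n for n in tree.walk() for c in n.children
    }
    total = 0.0
    for site in range(len(rows[0])):
        obs = {t: code[rows[i][site]] for i, t in enumerate(taxa)}
        lik_var = 0.0
        for r in rates:
            P = {
                id(n): scipy.linalg.expm(model.rate_matrix() * r * n.length)
                for n in tree.walk()
                if n is not tree
            }
            s = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                st = dict(zip((id(n) for n in internals), assign))
                prob = pi[st[id(tree)]]
                for n in tree.walk():
                    if n is tree:
                        continue
                    ps = st[id(parents[id(n)])]
                    cs = obs[n.name] if n.is_leaf else st[id(n)]
                    prob *= P[id(n)][ps, cs]
                s += prob
            lik_var += s / len(rates)
        const = len(set(obs.values())) == 1
        lik = model.p_inv * (pi[next(iter(obs.values()))] if const else 0.0)
        lik += (1 - model.p_inv) * lik_var
        total += np.log(lik)
    return total


class TestPatterns:
    def test_identical_columns_collapse(self):
        pat = compress_patterns(_matrix(["a", "b"], ["AAAA", "CCCC"]))
        assert pat.masks.shape[1] == 1 and pat.counts.tolist() == [4.0]

    def test_counts_sum_to_length(self):
        mat = _random_matrix(["a", "b", "c"], 200, 0)
        assert compress_patterns(mat).length == 200

    def test_empty_alignment_is_error(self):
        with pytest.raises(ValueError):
            compress_patterns(_matrix(["a"], [""]))

    def test_pattern_likelihood_equals_per_site_sum(self):
        mat = _random_matrix(["a", "b", "c", "d"], 50, 1)
        tree = enumerate_topologies(list(mat.taxa))[0]
        model = GTRIGModel(alpha=0.6, p_inv=0.1)
        whole = log_likelihood(tree, model, compress_patterns(mat))
        per_site = sum(
            log_likelihood(
                tree,
                model,
                compress_patterns(
                    _matrix(mat.taxa, [r[i] for r in mat.rows])
                ),
            )
            for i in range(50)
        )
        assert whole == pytest.approx(per_site, abs=1e-8)


class TestLikelihood:
    def test_two_taxa_zero_branch_limit(self):
        tree = TreeNode(children=[
            TreeNode(name="a", length=1e-9), TreeNode(name="b", length=1e-9)
        ])
        model = GTRIGModel(n_cat=1)
        lnl = log_likelihood(tree, model, compress_patterns(_matrix("ab", ["A", "A"])))
        assert lnl == pytest.approx(np.log(0.25), abs=1e-6)

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0])
    def test_jukes_cantor_closed_form(self, t):
        tree = TreeNode(children=[
            TreeNode(name="a", length=t), TreeNode(name="b", length=0.0)
        ])
        model = GTRIGModel(n_cat=1)
        same = log_likelihood(tree, model, compress_patterns(_matrix("ab", ["A", "A"])))
        diff = log_likelihood(tree, model, compress_patterns(_matrix("ab", ["A", "C"])))
        p_same = 0.25 * (0.25 + 0.75 * np.exp(-4 * t / 3))
        p_diff = 0.25 * (0.25 - 0.25 * np.exp(-4 * t / 3))
        assert same == pytest.approx(np.log(p_same), abs=1e-10)
        assert diff == pytest.approx(np.log(p_diff), abs=1e-10)

    @pytest.mark.parametrize("n_taxa,seed", [(4, 0), (4, 1), (5, 2), (5, 3)])
    def test_pruning_equals_brute_force(self, n_taxa, seed):
        rng = np.random.default_rng(seed)
        taxa = list("abcde"[:n_taxa])
        mat = _random_matrix(taxa, 10, seed)
        model = GTRIGModel(
            np.array([1.5, 3.0, 0.8, 1.2, 2.5, 1.0]),
            np.array([0.3, 0.2, 0.25, 0.25]),
            alpha=0.7,
            p_inv=0.15,
        )
        topo = enumerate_topologies(taxa)[int(rng.integers(3))]
        for n in topo.walk():
            n.length = float(rng.uniform(0.05, 0.5))
        lnl = log_likelihood(topo, model, compress_patterns(mat))
        oracle = _brute_force_lnl(topo, model, taxa, mat.rows)
        assert abs(lnl - oracle) < 1e-8

    def test_invariant_under_rerooting(self):
        # same unrooted tree rooted at either internal node
        mat = _random_matrix(list("abcd"), 40, 4)
        model = GTRIGModel(alpha=0.9, p_inv=0.05)
        e = 0.2
        t1 = TreeNode(children=[
            TreeNode(children=[TreeNode(name="a", length=0.1),
                               TreeNode(name="b", length=0.15)], length=e),
            TreeNode(name="c", length=0.12),
            TreeNode(name="d", length=0.3),
        ])
        t2 = TreeNode(children=[
            TreeNode(children=[TreeNode(name="c", length=0.12),
                               TreeNode(name="d", length=0.3)], length=e),
            TreeNode(name="a", length=0.1),
            TreeNode(name="b", length=0.15),
        ])
        pat = compress_patterns(mat)
        assert log_likelihood(t1, model, pat) == pytest.approx(
            log_likelihood(t2, model, pat), abs=1e-9
        )


class TestTopologies:
    def test_counts(self):
        assert len(enumerate_topologies(list("abcd"))) == 3
        assert len(enumerate_topologies(list("abcde"))) == 15

    def test_all_distinct(self):
        tops = enumerate_topologies(list("abcde"))
        seen = {frozenset(bipartitions(t)) for t in tops}
        assert len(seen) == 15


class TestFit:
    def test_refit_is_idempotent(self, genome_family):
        genomes, _, _ = genome_family
        taxa = sorted(genomes)
        mat = _matrix(taxa, [genomes[t].sequence.residues for t in taxa])
        pat = compress_patterns(mat)
        first = fit(enumerate_topologies(taxa)[0], pat)
        second = fit(first.tree, pat, model=first.model)
        assert abs(second.lnL - first.lnL) < 1e-6

    def test_two_taxon_distance_matches_1d_oracle(self):
        rng = np.random.default_rng(5)
        model = GTRIGModel(
            np.array([1.2, 2.5, 0.7, 1.1, 3.0, 1.0]),
            np.array([0.28, 0.22, 0.26, 0.24]),
            n_cat=1,
        )
        # simulate a two-taxon alignment at known distance
        P = scipy.linalg.expm(model.rate_matrix() * 0.15)
        pi = model.base_freqs
        anc = rng.choice(4, size=5000, p=pi)
        der = np.array([rng.choice(4, p=P[a]) for a in anc])
        rows = ["".join("ACGT"[i] for i in anc), "".join("ACGT"[i] for i in der)]
        mat = _matrix(["a", "b"], rows)
        pat = compress_patterns(mat)
        tree = TreeNode(children=[TreeNode(name="a", length=0.1),
                                  TreeNode(name="b", length=1e-9)])
        res = fit(tree, pat, model=model, optimize_model=False)
        fitted = sum(n.length for n in tree.children)

        from scipy.optimize import minimize_scalar

        def neg(t):
            tr = TreeNode(children=[TreeNode(name="a", length=t),
                                    TreeNode(name="b", length=1e-9)])
            return -log_likelihood(tr, model, pat)

        oracle = minimize_scalar(neg, bounds=(1e-6, 2.0), method="bounded").x
        assert fitted == pytest.approx(oracle, abs=1e-3)


class TestSearchAndBootstrap:
    def test_four_taxa_evaluates_three_topologies(self, monkeypatch):
        mat = _random_matrix(list("abcd"), 60, 6)
        calls = []
        import plastokit.phylo as P

        orig = P.fit

        def counting_fit(*a, **k):
            calls.append(1)
            return orig(*a, **k)

        monkeypatch.setattr(P, "fit", counting_fit)
        P.ml_search(mat)
        assert len(calls) == 3

    def test_long_internal_branch_topology_recovered(self):
        from plastokit.seqio import AnnotatedGenome, NucleotideSequence
        from plastokit.synth import _random_seq, evolve_genomes

        rng = np.random.default_rng(7)
        anc = AnnotatedGenome(
            NucleotideSequence("anc", _random_seq(rng, 8000, 0.45)), []
        )
        genomes, _ = evolve_genomes(
            anc, "((a:0.02,b:0.02):0.1,c:0.02,d:0.02);",
            frame_safe=False, seed=7,
        )
        taxa = sorted(genomes)
        mat = _matrix(taxa, [genomes[t].sequence.residues for t in taxa])
        best = ml_search(mat)
        assert frozenset({"c", "d"}) in bipartitions(best.tree)

    def test_too_many_taxa_rejected(self):
        mat = _random_matrix([f"t{i}" for i in range(9)], 10, 8)
        with pytest.raises(ValueError, match="exhaustive"):
            ml_search(mat)

    def test_bootstrap_supports_bounded_and_strong_signal(self):
        from plastokit.seqio import AnnotatedGenome, NucleotideSequence
        from plastokit.synth import _random_seq, evolve_genomes

        rng = np.random.default_rng(9)
        anc = AnnotatedGenome(
            NucleotideSequence("anc", _random_seq(rng, 50_000, 0.45)), []
        )
        genomes, _ = evolve_genomes(
            anc, "((a:0.01,b:0.01):0.1,c:0.01,d:0.01);",
            frame_safe=False, seed=9,
        )
        taxa = sorted(genomes)
        mat = _matrix(taxa, [genomes[t].sequence.residues for t in taxa])
        best = ml_search(mat)
        supports = bootstrap(
            mat, best=best, n_replicates=100, seed=9, optimize_model=False
        )
        assert all(0 <= v <= 100 for v in supports.values())
        internal = frozenset({"c", "d"})
        assert supports[internal] >= 95.0

    def test_bootstrap_reproducible_given_seed(self):
        mat = _random_matrix(list("abcd"), 300, 10)
        best = ml_search(mat)
        s1 = bootstrap(mat, best=best, n_replicates=10, seed=3, optimize_model=False)
        s2 = bootstrap(mat, best=best, n_replicates=10, seed=3, optimize_model=False)
        assert s1 == s2


class TestOutput:
    def test_newick_round_trip_preserves_topology(self, tmp_path):
        mat = _random_matrix(list("abcd"), 100, 11)
        best = ml_search(mat)
        best.supports = {bp: 87.0 for bp in bipartitions(best.tree)}
        write_result(
            best,
            newick_path=tmp_path / "t.nwk",
            nexus_path=tmp_path / "t.nex",
            params_path=tmp_path / "p.tsv",
        )
        text = (tmp_path / "t.nwk").read_text().strip()
        back = parse_newick(text)
        assert bipartitions(back) == bipartitions(best.tree)
        assert "87" in text
        nexus = (tmp_path / "t.nex").read_text()
        assert nexus.startswith("#NEXUS") and "TREE best_ml" in nexus
        params = (tmp_path / "p.tsv").read_text()
        assert "lnL" in params and "alpha" in params

    def test_nexus_tree_reparses_to_same_topology(self, tmp_path):
        mat = _random_matrix(list("abcd"), 80, 12)
        best = ml_search(mat)
        write_result(best, nexus_path=tmp_path / "t.nex")
        import dendropy

        tree = dendropy.Tree.get(path=str(tmp_path / "t.nex"), schema="nexus")
        newick = tree.as_string(schema="newick").strip().lstrip("[&U] ")
        back = parse_newick(newick)
        assert bipartitions(back) == bipartitions(best.tree)
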
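"""GRM, pedigree kinship, eGRM, phylogenetic vcv, eigendecomposition."""

import numpy as np
import pytest

from structcorr import (
    CovarianceMatrix,
    EffectSizeModel,
    GenotypeMatrix,
    Pedigree,
    build_felsenstein_tree,
    egrm_from_genetrees,
    eigendecompose,
    grm,
    parse_newick,
    pedigree_kinship,
    phylo_vcv,
    shared_path_matrix,
    simulate_pure_birth,
)


def random_genotypes(rng, n=20, L=50):
    p = rng.uniform(0.1, 0.9, size=L)
    return GenotypeMatrix(
        rng.binomial(2, p, size=(n, L)).astype(np.int8), [f"i{k}" for k in range(n)]
    )


class TestGRM:
    def test_hand_example_two_individuals(self):
        g = GenotypeMatrix(np.array([[0, 2], [2, 0]]), ["i1", "i2"])
        np.testing.assert_allclose(grm(g).values, [[2, -2], [-2, 2]])

    def test_alpha_zero_is_centered_crossproduct(self, rng):
        g = random_genotypes(rng)
        Gc = g.dosages - g.dosages.mean(axis=0)
        np.testing.assert_allclose(
            grm(g, alpha=0.0, normalize_by_L=False).values, Gc @ Gc.T, atol=1e-10
        )

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_rows_sum_to_zero(self, rng, alpha):
        K = grm(random_genotypes(rng), alpha=alpha)
        assert np.abs(K.values.sum(axis=1)).max() <= 1e-8 * np.trace(K.values)

    def test_monomorphic_loci_dropped(self):
        g = GenotypeMatrix(np.array([[0, 0, 2], [2, 0, 0]]), ["a", "b"])
        assert g.monomorphic.tolist() == [False, True, False]
        np.testing.assert_allclose(grm(g).values, grm(
            GenotypeMatrix(np.array([[0, 2], [2, 0]]), ["a", "b"])
        ).values)

    def test_all_monomorphic_is_error(self):
        g = GenotypeMatrix(np.array([[2, 0], [2, 0]]), ["a", "b"])
        with pytest.raises(ValueError, match="monomorphic"):
            grm(g)

    def test_hardy_weinberg_unrelated_limits(self):
        """Canonical GRM of unrelated individuals: diag -> 1, off-diag -> 0
        (sample centering makes the off-diagonal mean exactly -mean(diag)/(n-1),
        which vanishes only as n grows)."""
        rng = np.random.default_rng(11)
        n = 150
        g = random_genotypes(rng, n=n, L=5_000)
        K = grm(g).values
        off = K[np.triu_indices(n, k=1)]
        assert abs(np.diag(K).mean() - 1.0) < 0.05
        assert abs(off.mean()) < 0.02
        assert off.mean() == pytest.approx(-np.diag(K).mean() / (n - 1), rel=1e-6)


class TestEffectSizeModel:
    def test_alpha_zero_frequency_independent(self):
        esm = EffectSizeModel(scale=0.3, alpha=0.0)
        np.testing.assert_allclose(esm.variance([0.1, 0.5, 0.9]), 0.3)

    def test_mutation_selection_form(self):
        esm = EffectSizeModel.from_mutation_selection(mu=1e-4, V_s=2.0)
        p = 0.3
        assert esm.variance(p) == pytest.approx(2 * 1e-4 / (2.0 * 2 * p * (1 - p)))

    def test_boundary_frequency_rejected(self):
        with pytest.raises(ValueError):
            EffectSizeModel().variance([0.0, 0.5])


class TestPedigreeKinship:
    def test_founders_are_identity(self):
        K = pedigree_kinship(Pedigree([("a", None, None), ("b", None, None)]))
        np.testing.assert_allclose(K.values, np.eye(2))

    def test_full_sibs_and_inbred_offspring(self):
        ped = Pedigree(
            [
                ("f", None, None),
                ("m", None, None),
                ("s1", "f", "m"),
                ("s2", "f", "m"),
                ("o", "s1", "s2"),
            ]
        )
        K = pedigree_kinship(ped)
        i = {l: k for k, l in enumerate(K.labels)}
        assert K.values[i["s1"], i["s2"]] == pytest.approx(0.5)
        assert K.values[i["o"], i["o"]] == pytest.approx(1.25)  # F = 0.25

    def test_full_sib_gene_dropping_oracle(self):
        """2*theta for full sibs ~ mean allele sharing over simulated meioses."""
        rng = np.random.default_rng(12)
        n = 100_000
        # founder alleles labelled 0..3; each sib inherits one from each parent
        s1 = np.stack([rng.integers(0, 2, n), 2 + rng.integers(0, 2, n)])
        s2 = np.stack([rng.integers(0, 2, n), 2 + rng.integers(0, 2, n)])
        # kinship: P(random allele of s1 IBD to random allele of s2)
        pick1 = s1[rng.integers(0, 2, n), np.arange(n)]
        pick2 = s2[rng.integers(0, 2, n), np.arange(n)]
        theta = (pick1 == pick2).mean()
        assert 2 * theta == pytest.approx(0.5, abs=3 * 2 * np.sqrt(0.25 * 0.75 / n))

    def test_cyclic_pedigree_rejected(self):
        with pytest.raises(ValueError, match="cyclic"):
            Pedigree([("a", "b", None), ("b", "a", None)])

    def test_unknown_parent_rejected(self):
        with pytest.raises(ValueError, match="no record"):
            Pedigree([("a", "ghost", None)])


class TestEGRM:
    def test_single_tree_collapses_to_vcv_over_total_length(self, three_tip_tree):
        e = egrm_from_genetrees([three_tip_tree])
        S = shared_path_matrix(three_tip_tree)
        np.testing.assert_allclose(e.values, S.values / three_tip_tree.total_length)

    def test_identical_trees_match_single(self, three_tip_tree):
        single = egrm_from_genetrees([three_tip_tree]).values
        for convention in ("ratio-of-means", "mean-of-ratios"):
            multi = egrm_from_genetrees([three_tip_tree] * 5, convention).values
            np.testing.assert_allclose(multi, single)

    def test_conventions_differ_on_heterogeneous_trees(self):
        t1 = parse_newick("((A:1,B:1):1,C:2);")
        t2 = parse_newick("((A:3,B:3):1,C:4);")
        rom = egrm_from_genetrees([t1, t2], "ratio-of-means").values
        mor = egrm_from_genetrees([t1, t2], "mean-of-ratios").values
        assert not np.allclose(rom, mor)

    def test_mismatched_tip_sets_listed(self):
        t1 = parse_newick("(A:1,B:1);")
        t2 = parse_newick("(A:1,C:1);")
        with pytest.raises(ValueError, match="'B', 'C'"):
            egrm_from_genetrees([t1, t2])

    def test_mutation_dropping_oracle_small(self):
        """Cov(A_i, A_j) over mutational replicates ~ u E(beta^2) sum_k S_k.

        Poisson mutations at rate u per branch unit, iid N(0,1) effects: the
        expected cross-product of genetic values equals the mutation rate
        times expected squared effect times total shared branch length.
        """
        rng = np.random.default_rng(13)
        trees = [simulate_pure_birth(5, 1.0, rng) for _ in range(40)]
        labels = trees[0].tip_labels
        trees = [t for t in trees if t.tip_labels == labels]
        e = egrm_from_genetrees(trees, "ratio-of-means")
        u = 2.0
        mean_T = np.mean([t.total_length for t in trees])
        expected = u * 1.0 * len(trees) * mean_T * e.values  # = u * sum_k S_k
        reps = 4000
        prods = np.zeros_like(e.values)
        A = np.zeros((reps, 5))
        for r in range(reps):
            a = np.zeros(5)
            for t in trees:
                a += _drop_mutations(t, u, labels, rng)
            A[r] = a
        emp = (A[:, :, None] * A[:, None, :]).mean(axis=0)
        se = (A[:, :, None] * A[:, None, :]).std(axis=0) / np.sqrt(reps)
        assert np.all(np.abs(emp - expected) <= 4 * se + 1e-12)


def _drop_mutations(tree, u, labels, rng):
    """One mutational realization of genetic values on one tree."""
    pos = {lab: i for i, lab in enumerate(labels)}
    a = np.zeros(len(labels))
    # stem mutations hit everyone
    for _ in range(rng.poisson(u * tree.root_length)):
        a += rng.normal()
    for node in range(1, tree.n_nodes):
        k = rng.poisson(u * tree.length[node])
        if not k:
            continue
        stack, tips = [node], []
        while stack:
            v = stack.pop()
            if tree.is_tip(v):
                tips.append(pos[tree.labels[v]])
            else:
                stack.extend(tree.children[v])
        for _ in range(k):
            a[tips] += rng.normal()
    return a


class TestPhyloVcv:
    def test_rate_scaling(self, three_tip_tree):
        S = shared_path_matrix(three_tip_tree)
        np.testing.assert_allclose(phylo_vcv(three_tip_tree, 1.0).values, S.values)
        np.testing.assert_allclose(
            phylo_vcv(three_tip_tree, 2.5).values, 2.5 * S.values
        )

    def test_cherry(self):
        t = parse_newick("(A:1,B:1);")
        np.testing.assert_allclose(phylo_vcv(t, 2.0).values, 2.0 * np.eye(2))

    def test_nonpositive_rate_rejected(self, three_tip_tree):
        with pytest.raises(ValueError):
            phylo_vcv(three_tip_tree, 0.0)


class TestEigendecomposition:
    def test_identity_orthonormal(self):
        sigma = CovarianceMatrix(np.eye(4), list("abcd"))
        lam, V = eigendecompose(sigma)
        np.testing.assert_allclose(lam, 1.0)
        np.testing.assert_allclose(V.T @ V, np.eye(4), atol=1e-12)

    def test_reconstruction(self, rng):
        A = rng.normal(size=(15, 15))
        M = A @ A.T
        sigma = CovarianceMatrix((M + M.T) / 2, [f"s{i}" for i in range(15)])
        lam, V = eigendecompose(sigma)
        np.testing.assert_allclose(V @ np.diag(lam) @ V.T, sigma.values, atol=1e-8)
        assert np.all(np.diff(lam) <= 1e-12)

    def test_sign_convention_deterministic(self, rng):
        A = rng.normal(size=(8, 8))
        M = (A @ A.T + (A @ A.T).T) / 2
        sigma = CovarianceMatrix(M, [f"s{i}" for i in range(8)])
        _, V = eigendecompose(sigma)
        for j in range(8):
            k = np.argmax(np.abs(V[:, j]))
            assert V[k, j] > 0

    def test_nonsymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            CovarianceMatrix(np.array([[1.0, 0.2], [0.1, 1.0]]), ["a", "b"])

    def test_indefinite_rejected(self):
        with pytest.raises(ValueError, match="PSD"):
            CovarianceMatrix(np.diag([1.0, -0.5]), ["a", "b"]).eigenvalues


class TestCrossModelStructure:
    def test_genotype_pc1_matches_phylo_eigenvector(self):
        """Deep two-population divergence: the top eigenvector of the
        genotype GRM and of the Felsenstein-tree vcv both recover
        population membership (same covariates up to scaling)."""
        from structcorr import Demography, simulate_coalescent_genotypes

        dem = Demography.two_populations(40_000, 10_000, 15)
        geno = simulate_coalescent_genotypes(
            dem, 200, 1e-4, np.random.default_rng(14)
        )
        K = grm(geno)
        membership = np.array(
            [1.0 if p == "pop1" else 0.0 for p in geno.populations]
        )
        r_geno = np.corrcoef(K.eigenvectors[:, 0], membership)[0, 1]
        assert abs(r_geno) >= 0.95
        tree = build_felsenstein_tree(15, 0.5, 3.0)
        S = shared_path_matrix(tree)
        c1 = np.array([l.startswith("c1_") for l in S.labels], dtype=float)
        assert abs(np.corrcoef(S.eigenvectors[:, 0], c1)[0, 1]) >= 0.95

    def test_panmictic_egrm_offdiagonals_tighten(self):
        """Exchangeable coalescent tips: eGRM off-diagonals approach a
        common constant as gene trees accumulate."""
        from structcorr import Demography, simulate_coalescent_genotypes

        dem = Demography.single_population(1000, 4)
        _, trees = simulate_coalescent_genotypes(
            dem, 400, 0.0, np.random.default_rng(15), return_trees=True
        )
        def off_spread(ts):
            e = egrm_from_genetrees(ts).values
            off = e[np.triu_indices(e.shape[0], k=1)]
            return np.std(off)

        assert off_spread(trees[:400]) < off_spread(trees[:20])
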
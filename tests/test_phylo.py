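import numpy as np
import pytest

from hylocomp.phylo import (
    KinshipMatrix,
    NewickFormatError,
    PhyloTree,
    TreeValidationError,
    lambda_transform,
    population_kinship,
    read_newick,
    vcv_from_tree,
    write_newick,
)
from hylocomp.simulate import simulate_tree


class TestNewickIO:
    def test_parse_three_tip_tree(self, three_tip_tree):
        assert three_tip_tree.n_tips == 3
        assert sorted(three_tip_tree.tip_labels) == ["A", "B", "C"]
        assert three_tip_tree.depths().max() == pytest.approx(2.0)

    def test_missing_semicolon_is_format_error(self):
        with pytest.raises(NewickFormatError, match="terminate"):
            PhyloTree.from_newick_string("((A:1,B:1):1,C:2)")

    def test_garbage_is_format_error(self):
        with pytest.raises(NewickFormatError):
            PhyloTree.from_newick_string("((A:1,B:1:1,C;")

    def test_missing_branch_lengths_rejected(self):
        with pytest.raises(NewickFormatError, match="branch length"):
            PhyloTree.from_newick_string("((A,B),C);")

    def test_single_tip_rejected(self):
        with pytest.raises(TreeValidationError, match="tips"):
            PhyloTree.from_newick_string("(A:1,B:1);")

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(TreeValidationError, match="unique"):
            PhyloTree.from_newick_string("((A:1,A:1):1,C:2);")

    def test_zero_length_branch_warns(self):
        with pytest.warns(UserWarning, match="zero-length"):
            PhyloTree.from_newick_string("((A:0,B:1):1,C:2);")

    def test_write_emits_parseable_newick(self, three_tip_tree, tmp_path):
        path = tmp_path / "t.nwk"
        write_newick(three_tip_tree, path)
        text = path.read_text().strip()
        assert text.endswith(";")
        again = read_newick(path)
        assert sorted(again.tip_labels) == ["A", "B", "C"]

    @pytest.mark.parametrize("seed", range(50))
    def test_write_read_round_trip_preserves_tree(self, seed, tmp_path):
        tree = simulate_tree(np.random.default_rng(seed).integers(4, 40), seed)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        c1 = vcv_from_tree(tree)
        c2 = vcv_from_tree(back)
        idx = [c2.tip_order.index(lbl) for lbl in c1.tip_order]
        # identical topology + lengths <=> identical covariance structure
        np.testing.assert_allclose(c1.C, c2.C[np.ix_(idx, idx)], rtol=0, atol=0)

    def test_hundred_tip_round_trip(self, tmp_path):
        tree = simulate_tree(100, seed=7)
        path = tmp_path / "big.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert back.n_tips == 100
        np.testing.assert_array_equal(
            np.sort(vcv_from_tree(back).C.ravel()),
            np.sort(vcv_from_tree(tree).C.ravel()),
        )


def _brute_force_vcv(tree):
    """Path-enumeration oracle: sum shared branches on explicit root->tip paths."""
    def path_to_root(i):
        out = []
        while tree.parent[i] >= 0:
            out.append(i)
            i = tree.parent[i]
        return set(out)

    tips = tree.tips
    n = len(tips)
    C = np.zeros((n, n))
    for a in range(n):
        pa = path_to_root(tips[a])
        for b in range(n):
            shared = pa & path_to_root(tips[b])
            C[a, b] = sum(tree.length[i] for i in shared)
    return C


class TestVcv:
    def test_three_tip_example(self, three_tip_tree):
        cov = vcv_from_tree(three_tip_tree)
        want = {"A": {"A": 2, "B": 1, "C": 0}, "B": {"B": 2, "C": 0}, "C": {"C": 2}}
        for i, a in enumerate(cov.tip_order):
            for j, b in enumerate(cov.tip_order):
                key = (a, b) if a <= b else (b, a)
                assert cov.C[i, j] == want[key[0]][key[1]]
        assert cov.is_ultrametric
        assert cov.depth == 2.0

    def test_star_tree_gives_diagonal(self):
        star = PhyloTree.from_newick_string("(A:1,B:1,C:1,D:1);")
        cov = vcv_from_tree(star)
        np.testing.assert_allclose(cov.C, np.eye(4))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_path_enumeration_oracle(self, seed):
        tree = simulate_tree(20, seed)
        cov = vcv_from_tree(tree)
        np.testing.assert_allclose(cov.C, _brute_force_vcv(tree), atol=1e-12)

    def test_psd_and_symmetric(self, yule20_cov):
        C = yule20_cov.C
        np.testing.assert_allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() >= -1e-8

    def test_tip_permutation_equivariance(self, yule20):
        """Relabelled newick input permutes C's rows/cols, nothing else."""
        cov = vcv_from_tree(yule20)
        back = PhyloTree.from_newick_string(yule20.to_newick())
        cov2 = vcv_from_tree(back)
        idx = [cov2.tip_order.index(lbl) for lbl in cov.tip_order]
        np.testing.assert_allclose(cov.C, cov2.C[np.ix_(idx, idx)])


class TestLambdaTransform:
    def test_identity_at_one(self, yule20_cov):
        np.testing.assert_array_equal(lambda_transform(yule20_cov, 1.0).C, yule20_cov.C)

    def test_diagonal_at_zero(self, yule20_cov):
        out = lambda_transform(yule20_cov, 0.0).C
        np.testing.assert_allclose(out, np.diag(np.diag(yule20_cov.C)))

    def test_half_scales_offdiagonals(self, three_tip_tree):
        cov = vcv_from_tree(three_tip_tree)
        out = lambda_transform(cov, 0.5).C
        i, j = cov.tip_order.index("A"), cov.tip_order.index("B")
        assert out[i, j] == 0.5
        assert out[i, i] == 2.0

    @pytest.mark.parametrize("lam", np.linspace(0, 1, 11))
    def test_remains_psd_on_ultrametric_trees(self, yule20_cov, lam):
        out = lambda_transform(yule20_cov, lam).C
        assert np.linalg.eigvalsh(out).min() >= -1e-8

    @pytest.mark.parametrize("lam", [-0.1, 1.1, 5.0])
    def test_out_of_range_rejected(self, yule20_cov, lam):
        with pytest.raises(ValueError):
            lambda_transform(yule20_cov, lam)


class TestPopulationKinship:
    def test_same_species_pair_is_one(self, three_tip_tree):
        cov = vcv_from_tree(three_tip_tree)
        kin = population_kinship(cov, {"p1": "A", "p2": "A"})
        np.testing.assert_allclose(kin.A, np.ones((2, 2)))

    def test_cross_species_normalisation(self, three_tip_tree):
        cov = vcv_from_tree(three_tip_tree)  # C_AB = 1, C_AA = C_BB = 2
        kin = population_kinship(cov, {"p1": "A", "p2": "B"})
        assert kin.A[0, 1] == pytest.approx(0.5)

    def test_unknown_species_listed(self, three_tip_tree):
        cov = vcv_from_tree(three_tip_tree)
        with pytest.raises(KeyError, match="Zeta"):
            population_kinship(cov, {"p1": "A", "p2": "Zeta"})

    def test_matches_per_pair_oracle(self, rng):
        tree = simulate_tree(19, seed=5)
        cov = vcv_from_tree(tree)
        species = list(cov.tip_order)
        pops = {f"p{i}": species[rng.integers(19)] for i in range(39)}
        for i, sp in enumerate(species):  # ensure every species present
            pops[f"q{i}"] = sp
        kin = population_kinship(cov, pops)
        names = kin.population_order
        for a in range(0, len(names), 7):
            for b in range(0, len(names), 5):
                sa, sb = pops[names[a]], pops[names[b]]
                ia, ib = cov.index_of(sa), cov.index_of(sb)
                want = cov.C[ia, ib] / np.sqrt(cov.C[ia, ia] * cov.C[ib, ib])
                if a == b:
                    want = 1.0
                assert kin.A[a, b] == pytest.approx(want, abs=1e-12)

    def test_one_population_per_species_equals_correlation_form(self, yule20_cov):
        pops = {f"p_{lbl}": lbl for lbl in yule20_cov.tip_order}
        kin = population_kinship(yule20_cov, pops)
        d = np.sqrt(np.diag(yule20_cov.C))
        np.testing.assert_allclose(kin.A, yule20_cov.C / np.outer(d, d), atol=1e-12)

    def test_result_is_kinship_matrix(self, yule20_cov):
        kin = population_kinship(yule20_cov, {"p": yule20_cov.tip_order[0],
                                              "q": yule20_cov.tip_order[1],
                                              "r": yule20_cov.tip_order[2]})
        assert isinstance(kin, KinshipMatrix)
        np.testing.assert_allclose(np.diag(kin.A), 1.0)
        assert np.linalg.eigvalsh(kin.A).min() >= -1e-8
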
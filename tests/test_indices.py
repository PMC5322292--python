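import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netdiv.data import AssociationMatrix, CountTable, DataValidationError
from netdiv.indices import (
    INDEX_CODES,
    bray_curtis,
    distance_matrix,
    index_spec,
    jaccard_chao,
    jaccard_classical,
    jaccard_weighted,
    morisita_horn,
    pina_unweighted,
    pina_weighted,
    similarity_matrix,
    tina_unweighted,
    tina_weighted,
    unifrac_unweighted,
    unifrac_weighted,
)
from netdiv.networks import phylo_association

from conftest import canonical_assoc


def _assoc(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"t{i}" for i in range(values.shape[0])]
    return AssociationMatrix(ids, values)


NEUTRAL3 = _assoc([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1]])
ONES3 = _assoc(np.ones((3, 3)))


class TestCountBasedIndices:
    @pytest.mark.parametrize("fn", [jaccard_classical, jaccard_weighted,
                                    jaccard_chao, bray_curtis, morisita_horn])
    def test_identical_samples_give_one(self, fn):
        a = np.array([4, 1, 0, 7])
        assert fn(a, a) == pytest.approx(1.0)

    @pytest.mark.parametrize("fn", [jaccard_classical, jaccard_weighted,
                                    jaccard_chao, bray_curtis, morisita_horn])
    def test_disjoint_samples_give_zero(self, fn):
        a = np.array([4, 1, 0, 0])
        b = np.array([0, 0, 3, 7])
        assert fn(a, b) == pytest.approx(0.0)

    def test_jci_hand_count(self):
        # A observes {t1,t2,t3}, B observes {t2,t3,t4}: 2 shared / 4 union
        a = np.array([2, 1, 5, 0])
        b = np.array([0, 3, 1, 2])
        assert jaccard_classical(a, b) == pytest.approx(0.5)

    def test_jcw_direct_formula(self):
        a = np.array([8, 2, 0])
        b = np.array([0, 5, 5])
        # shared = {t2}: (2/10 + 5/10) / 2 = 0.35
        assert jaccard_weighted(a, b) == pytest.approx(0.35)

    def test_jcc_matches_independent_formula9_oracle(self):
        a = np.array([5, 3, 0, 2, 0, 1])
        b = np.array([2, 1, 0, 0, 3, 0])

        def chao_u_oracle(x, y):
            shared = [i for i in range(len(x)) if x[i] > 0 and y[i] > 0]
            n, m = x.sum(), y.sum()
            obs = sum(x[i] for i in shared) / n
            f1 = sum(1 for i in shared if y[i] == 1)
            f2 = sum(1 for i in shared if y[i] == 2)
            corr = ((m - 1) / m) * (f1 / (2 * (f2 if f2 > 0 else 1))) \
                * sum(x[i] for i in shared if y[i] == 1) / n
            return min(obs + corr, 1.0)

        u, v = chao_u_oracle(a, b), chao_u_oracle(b, a)
        expect = u * v / (u + v - u * v)
        assert jaccard_chao(a, b) == pytest.approx(expect, abs=1e-12)
        assert jaccard_chao(a, b) == pytest.approx(37 / 81)

    def test_bc_direct_formula(self):
        assert bray_curtis(np.array([2, 2, 0]), np.array([0, 2, 2])) \
            == pytest.approx(0.5)

    def test_mh_direct_formula(self):
        assert morisita_horn(np.array([1, 1, 0]), np.array([0, 1, 1])) \
            == pytest.approx(0.5)


class TestUniFrac:
    def test_identical_incidence_gives_one(self, worked_tree):
        taxa = ["A", "B", "C", "D"]
        a = np.array([3, 1, 0, 0])
        b = np.array([1, 5, 0, 0])
        assert unifrac_unweighted(a, b, worked_tree, taxa) == pytest.approx(1.0)

    def test_opposite_subtrees_share_nothing(self, worked_tree):
        taxa = ["A", "B", "C", "D"]
        a = np.array([3, 0, 0, 0])
        b = np.array([0, 0, 2, 0])
        assert unifrac_unweighted(a, b, worked_tree, taxa) == pytest.approx(0.0)

    def test_edge_set_oracle(self, worked_tree):
        # A observes {A,B}, B observes {A,C}: shared edges {A, AB-stem} = 2,
        # union {A, B, AB-stem, C, CD-stem} = 5
        taxa = ["A", "B", "C", "D"]
        a = np.array([1, 1, 0, 0])
        b = np.array([1, 0, 1, 0])
        assert unifrac_unweighted(a, b, worked_tree, taxa) == pytest.approx(2 / 5)

    def test_weighted_identical_gives_one(self, worked_tree):
        taxa = ["A", "B", "C", "D"]
        a = np.array([3, 1, 2, 0])
        assert unifrac_weighted(a, a, worked_tree, taxa) == pytest.approx(1.0)

    def test_weighted_two_leaf_extremes(self, tmp_path):
        from netdiv.data import read_tree

        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B:2);")
        tree = read_tree(p)
        a = np.array([4, 0])
        b = np.array([0, 9])
        assert unifrac_weighted(a, b, tree, ["A", "B"]) == pytest.approx(0.0)

    def test_weighted_per_branch_oracle(self, worked_tree):
        taxa = ["A", "B", "C", "D"]
        a = np.array([4, 4, 2, 0])
        b = np.array([0, 2, 2, 6])
        pa, pb = a / a.sum(), b / b.sum()
        # branches: A,B,C,D tips (len 1) + AB and CD stems (len 1)
        stem = {"A": [0], "B": [1], "C": [2], "D": [3],
                "AB": [0, 1], "CD": [2, 3]}
        num = sum(abs(pa[ix].sum() - pb[ix].sum()) for ix in stem.values())
        phi = np.array([2.0, 2.0, 2.0, 2.0])
        den = (phi * (pa + pb)).sum()
        expect = 1 - num / den
        assert unifrac_weighted(a, b, worked_tree, taxa) \
            == pytest.approx(expect, abs=1e-12)

    def test_skbio_cross_check(self, worked_tree):
        from skbio.diversity.beta import unweighted_unifrac, weighted_unifrac

        taxa = ["A", "B", "C", "D"]
        rng = np.random.default_rng(5)
        a = rng.integers(0, 10, 4)
        b = rng.integers(0, 10, 4)
        a[0] += 1
        b[3] += 1
        du = 1 - unifrac_unweighted(a, b, worked_tree, taxa)
        ref = unweighted_unifrac(a, b, taxa=taxa, tree=worked_tree.tree)
        assert du == pytest.approx(ref, abs=1e-10)
        dw = 1 - unifrac_weighted(a, b, worked_tree, taxa)
        refw = weighted_unifrac(a, b, taxa=taxa, tree=worked_tree.tree,
                                normalized=True)
        assert dw == pytest.approx(refw, abs=1e-10)

    def test_missing_taxon_error(self, worked_tree):
        with pytest.raises(DataValidationError, match="missing"):
            unifrac_unweighted(np.array([1, 1]), np.array([1, 0]),
                               worked_tree, ["A", "X"])


class TestTina:
    def test_disjoint_neutral_gives_half(self):
        a = np.array([1, 0, 0])
        b = np.array([0, 2, 3])
        assert tina_unweighted(a, b, NEUTRAL3) == pytest.approx(0.5)

    def test_disjoint_fully_associated_gives_one(self):
        a = np.array([1, 0, 0])
        b = np.array([0, 2, 3])
        assert tina_unweighted(a, b, ONES3) == pytest.approx(1.0)

    def test_disjoint_avoidance_gives_zero(self):
        c = _assoc([[1, 0, 0], [0, 1, 1], [0, 1, 1]])
        a = np.array([1, 0, 0])
        b = np.array([0, 2, 3])
        assert tina_unweighted(a, b, c) == pytest.approx(0.0)
        assert tina_weighted(a, b, c) == pytest.approx(0.0)

    def test_tu_hand_summation(self):
        c = _assoc([[1, 0.6, 0.2], [0.6, 1, 0.8], [0.2, 0.8, 1]])
        a = np.array([3, 1, 0])   # observes {t0, t1}
        b = np.array([0, 2, 5])   # observes {t1, t2}
        # cross entries: C(0,1), C(0,2), C(1,1), C(1,2)
        expect = (0.6 + 0.2 + 1.0 + 0.8) / 4
        assert tina_unweighted(a, b, c) == pytest.approx(expect, abs=1e-12)

    def test_tw_self_similarity_is_one(self):
        c = canonical_assoc(6, seed=9)
        a = np.array([5, 0, 3, 2, 0, 7])
        assert tina_weighted(a, a, c) == pytest.approx(1.0, abs=1e-12)

    def test_tw_bilinear_form_oracle(self):
        c = _assoc([[1, 0.6, 0.2], [0.6, 1, 0.8], [0.2, 0.8, 1]])
        a = np.array([2, 1, 1])
        b = np.array([1, 0, 3])
        pa, pb = a / a.sum(), b / b.sum()
        cm = c.values
        num = sum(pa[i] * pb[j] * cm[i, j] for i in range(3) for j in range(3))
        saa = sum(pa[i] * pa[j] * cm[i, j] for i in range(3) for j in range(3))
        sbb = sum(pb[i] * pb[j] * cm[i, j] for i in range(3) for j in range(3))
        expect = num / np.sqrt(saa * sbb)
        assert tina_weighted(a, b, c) == pytest.approx(expect, abs=1e-12)

    def test_tu_neutral_independent_of_community_size(self):
        for na, nb in [(2, 5), (1, 7), (4, 4)]:
            n = na + nb
            c = _assoc((np.full((n, n), 0.5) + 0.5 * np.eye(n)))
            a = np.array([1] * na + [0] * nb)
            b = np.array([0] * na + [2] * nb)
            assert tina_unweighted(a, b, c) == pytest.approx(0.5)

    def test_pina_mirrors_tina(self, worked_tree):
        phi = phylo_association(worked_tree)
        a = np.array([1, 2, 0, 0])
        b = np.array([0, 0, 3, 1])
        assert pina_unweighted(a, b, phi) == pytest.approx(
            tina_unweighted(a, b, phi))
        assert pina_weighted(a, a, phi) == pytest.approx(1.0, abs=1e-12)

    def test_pina_composed_oracle(self, worked_tree):
        # two-step oracle: hand cophenetic distances -> transform -> average
        d = np.array([[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
                     dtype=float)
        sim = 1 - d / 4
        np.fill_diagonal(sim, 1.0)
        r = np.corrcoef(sim)
        expect_phi = (1 + r) / 2
        phi = phylo_association(worked_tree)
        order = [phi.taxa_ids.index(n) for n in ["A", "B", "C", "D"]]
        assert np.allclose(phi.values[np.ix_(order, order)], expect_phi, atol=1e-10)
        a = np.array([1, 0, 0, 0])
        b = np.array([0, 0, 1, 1])
        vals = phi.values[np.ix_(order, order)]
        assert pina_unweighted(a, b, phi_ordered(vals)) == pytest.approx(
            vals[0, [2, 3]].mean(), abs=1e-12)


def phi_ordered(vals):
    return AssociationMatrix(["A", "B", "C", "D"], vals, "phylogeny")


class TestDistanceMatrix:
    def test_all_indices_match_per_pair_scalar_calls(self, worked_tree):
        rng = np.random.default_rng(21)
        counts = rng.integers(0, 12, size=(4, 10))
        counts[:, counts.sum(axis=0) == 0] += 1
        table = CountTable(["A", "B", "C", "D"],
                           [f"s{j}" for j in range(10)], counts)
        assoc = canonical_assoc(4, seed=2)
        assoc.taxa_ids = ["A", "B", "C", "D"]
        phi = phylo_association(worked_tree)
        scalar = {
            "JCI": jaccard_classical, "JCW": jaccard_weighted,
            "JCC": jaccard_chao, "BC": bray_curtis, "MH": morisita_horn,
            "UFU": lambda a, b: unifrac_unweighted(a, b, worked_tree, table.taxa_ids),
            "UFW": lambda a, b: unifrac_weighted(a, b, worked_tree, table.taxa_ids),
            "TU": lambda a, b: tina_unweighted(a, b, assoc),
            "TW": lambda a, b: tina_weighted(a, b, assoc),
            "PU": lambda a, b: pina_unweighted(a, b, phi),
            "PW": lambda a, b: pina_weighted(a, b, phi),
        }
        for code in INDEX_CODES:
            d = distance_matrix(
                table, code, tree=worked_tree,
                assoc=assoc if code in ("TU", "TW") else
                (phi if code in ("PU", "PW") else None))
            for i in range(10):
                for j in range(i + 1, 10):
                    s = scalar[code](counts[:, i], counts[:, j])
                    assert d.values[i, j] == pytest.approx(
                        max(0.0, 1 - s), abs=1e-12), code

    def test_diagonal_zero_and_symmetric(self, random_table):
        d = distance_matrix(random_table, "BC")
        assert np.allclose(np.diag(d.values), 0.0)
        assert np.allclose(d.values, d.values.T)

    def test_disjoint_samples_jci_distance_one(self):
        table = CountTable(["a", "b", "c"], ["s1", "s2", "s3"], np.eye(3, dtype=int))
        d = distance_matrix(table, "JCI")
        off = d.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_incidence_invariance(self, worked_tree):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 5, size=(4, 6))
        counts[:, counts.sum(axis=0) == 0] += 1
        t1 = CountTable(["A", "B", "C", "D"], [f"s{j}" for j in range(6)], counts)
        t2 = CountTable(["A", "B", "C", "D"], [f"s{j}" for j in range(6)],
                        counts * 7)  # presence/absence preserved
        assoc = canonical_assoc(4, seed=3)
        assoc.taxa_ids = ["A", "B", "C", "D"]
        phi = phylo_association(worked_tree)
        for code in ("JCI", "UFU", "TU", "PU"):
            d1 = distance_matrix(t1, code, tree=worked_tree,
                                 assoc=assoc if code == "TU" else
                                 (phi if code == "PU" else None))
            d2 = distance_matrix(t2, code, tree=worked_tree,
                                 assoc=assoc if code == "TU" else
                                 (phi if code == "PU" else None))
            assert np.allclose(d1.values, d2.values, atol=1e-12), code

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 9, size=(5, 6)) + 1
        ids = [f"t{i}" for i in range(5)]
        table = CountTable(ids, [f"s{j}" for j in range(6)], counts)
        assoc = canonical_assoc(5, seed=4)
        perm = [3, 1, 4, 0, 2]
        table_p = CountTable([ids[i] for i in perm],
                             table.sample_ids, counts[perm, :])
        assoc_p = AssociationMatrix([ids[i] for i in perm],
                                    assoc.values[np.ix_(perm, perm)])
        for code in ("JCI", "BC", "MH", "TU", "TW"):
            d1 = distance_matrix(table, code, assoc=assoc)
            d2 = distance_matrix(table_p, code, assoc=assoc_p)
            assert np.allclose(d1.values, d2.values, atol=1e-12), code

    def test_missing_auxiliary_errors(self, random_table):
        with pytest.raises(DataValidationError, match="tree"):
            distance_matrix(random_table, "UFU")
        with pytest.raises(DataValidationError, match="association"):
            distance_matrix(random_table, "TW")


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_similarity_symmetry_and_range(seed):
    """All 11 indices are symmetric in their arguments and live on [0, 1]."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 10, size=(5, 2))
    counts[:, counts.sum(axis=0) == 0] += 1
    a, b = counts[:, 0], counts[:, 1]
    c = canonical_assoc(5, seed=seed)
    for fn in (jaccard_classical, jaccard_weighted, jaccard_chao,
               bray_curtis, morisita_horn):
        s1, s2 = fn(a, b), fn(b, a)
        assert s1 == pytest.approx(s2, abs=1e-12)
        assert -1e-12 <= s1 <= 1 + 1e-12
    for fn in (tina_unweighted, tina_weighted):
        s1, s2 = fn(a, b, c), fn(b, a, c)
        assert s1 == pytest.approx(s2, abs=1e-12)
        assert -1e-12 <= s1 <= 1 + 1e-9
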
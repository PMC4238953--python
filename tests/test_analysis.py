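"""Downstream analysis: JSD, divergence matrices, component matching and
subnetwork categories."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon

from biomenet.analysis import (
    MetabosystemProfile,
    core_subnetworks,
    discriminatory_subnetworks,
    divergence_matrix,
    jsd,
    match_components,
    membership_score,
    principal_reactions,
    principal_subnetworks,
    subnetwork_graph,
)


def _profile(mat, tag="run"):
    mat = np.asarray(mat, dtype=float)
    return MetabosystemProfile(mat, [f"R{i}" for i in range(mat.shape[1])], tag=tag)


class TestJSD:
    def test_identity_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jsd(p, p) == 0.0

    def test_disjoint_supports_give_one_in_base2(self):
        assert jsd([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        # independent evaluation of the two KL terms against m = (0.7, 0.3)
        p, q = np.array([0.5, 0.5]), np.array([0.9, 0.1])
        m = 0.5 * (p + q)
        expected = 0.5 * np.sum(p * np.log2(p / m)) + 0.5 * np.sum(q * np.log2(q / m))
        assert jsd(p, q) == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_squared_distance(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(6))
        q = rng.dirichlet(np.ones(6))
        assert jsd(p, q) == pytest.approx(jensenshannon(p, q, base=2) ** 2, rel=1e-9)

    def test_rejects_non_simplex_and_length_mismatch(self):
        with pytest.raises(ValueError):
            jsd([0.5, 0.6], [0.5, 0.5])
        with pytest.raises(ValueError):
            jsd([1.0], [0.5, 0.5])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_bounded_symmetric_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(5))
        q = rng.dirichlet(np.ones(5))
        d = jsd(p, q)
        assert 0.0 <= d <= 1.0 + 1e-12
        assert d == pytest.approx(jsd(q, p), rel=1e-12)


class TestDivergenceMatrix:
    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(2)
        prof = _profile(rng.dirichlet(np.ones(5), size=3))
        dm = divergence_matrix([prof]).to_numpy()
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0.0)

    def test_duplicated_profile_gives_zero_offdiagonal_block(self):
        rng = np.random.default_rng(3)
        mat = rng.dirichlet(np.ones(5), size=2)
        dm = divergence_matrix([_profile(mat, "a"), _profile(mat, "b")]).to_numpy()
        assert np.allclose(dm[0, 2], 0.0) and np.allclose(dm[1, 3], 0.0)

    def test_entries_match_pairwise_jsd(self):
        rng = np.random.default_rng(4)
        m1 = rng.dirichlet(np.ones(6), size=2)
        m2 = rng.dirichlet(np.ones(6), size=2)
        dm = divergence_matrix([_profile(m1, "a"), _profile(m2, "b")])
        assert dm.shape == (4, 4)
        rows = np.vstack([m1, m2])
        for i in range(4):
            for j in range(4):
                assert dm.iloc[i, j] == pytest.approx(jsd(rows[i], rows[j]), abs=1e-12)

    def test_catalog_mismatch_rejected(self):
        p1 = _profile(np.eye(2))
        p2 = MetabosystemProfile(np.eye(2), ["X0", "X1"], tag="other")
        with pytest.raises(ValueError):
            divergence_matrix([p1, p2])


class TestMatchComponents:
    def test_identity(self):
        rng = np.random.default_rng(5)
        ref = rng.dirichlet(np.ones(6), size=3)
        assert match_components(ref, ref).tolist() == [0, 1, 2]

    def test_row_swap_recovered(self):
        rng = np.random.default_rng(6)
        ref = rng.dirichlet(np.ones(6), size=3)
        swapped = ref[[2, 0, 1]]
        perm = match_components(ref, swapped)
        np.testing.assert_array_equal(swapped[perm], ref)

    @pytest.mark.parametrize("metric", ["jsd", "l1"])
    def test_equals_exhaustive_search_k4(self, metric):
        rng = np.random.default_rng(7)
        ref = rng.dirichlet(np.ones(8), size=4)
        other = rng.dirichlet(np.ones(8), size=4)
        perm = match_components(ref, other, metric=metric)

        def cost(p):
            if metric == "jsd":
                return sum(jsd(ref[i], other[p[i]]) for i in range(4))
            return sum(np.abs(ref[i] - other[p[i]]).sum() for i in range(4))

        best = min(itertools.permutations(range(4)), key=cost)
        assert cost(tuple(perm)) == pytest.approx(cost(best), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_components(np.eye(3), np.eye(4))


class TestSubnetworkCategories:
    def test_principal_on_worked_mixture(self):
        # membership 20% subnetwork 3, 10% subnetwork 6, 70% subnetwork 9
        # over L=10: only the 0.7 entry clears the strict > 2/L = 0.2 threshold
        row = np.zeros(10)
        row[3], row[6], row[9] = 0.2, 0.1, 0.7
        phi = row[None, :]
        per_k, union = principal_subnetworks(phi)
        assert per_k[0] == [9] and union == [9]

    def test_uniform_row_has_no_principal(self):
        per_k, union = principal_subnetworks(np.full((1, 10), 0.1))
        assert per_k[0] == [] and union == []

    def test_indicator_row(self):
        phi = np.zeros((1, 5))
        phi[0, 2] = 1.0
        per_k, _ = principal_subnetworks(phi)
        assert per_k[0] == [2]

    def test_membership_score_worked_example(self):
        phi = np.array([[0.7], [0.2], [0.05]])
        assert membership_score(phi, 0, 0) == pytest.approx(math.log(3.5))

    def test_membership_score_symmetric_in_other_maximum(self):
        phi1 = np.array([[0.6], [0.3], [0.05]])
        phi2 = np.array([[0.6], [0.05], [0.3]])
        assert membership_score(phi1, 0, 0) == membership_score(phi2, 0, 0)

    def test_membership_score_equal_gives_zero_and_k1_rejected(self):
        assert membership_score(np.array([[0.25], [0.25]]), 0, 0) == 0.0
        with pytest.raises(ValueError):
            membership_score(np.array([[1.0]]), 0, 0)

    def test_discriminatory_worked_example(self):
        # subnetwork 0 has memberships (0.7, 0.2, 0.05) across K=3; the
        # remaining mass of each row is spread over the other 9 subnetworks
        phi = np.zeros((3, 10))
        phi[:, 0] = [0.7, 0.2, 0.05]
        phi[:, 1:] = (1.0 - phi[:, 0])[:, None] / 9
        flags = discriminatory_subnetworks(phi)
        assert flags[0, 0]  # ln(0.7/0.2) = ln 3.5 >= ln 2, enriched in k=0
        assert not flags[2, 0]  # depleted metabosystem is not flagged

    def test_flat_column_not_discriminatory(self):
        # principal (0.25 > 2/10) in every metabosystem but score 0
        phi = np.zeros((3, 10))
        phi[:, 0] = 0.25
        phi[:, 1:] = 0.75 / 9
        flags = discriminatory_subnetworks(phi)
        assert not flags[:, 0].any()

    def test_infinite_threshold_flags_nothing(self):
        phi = np.array([[0.9, 0.1], [0.1, 0.9]])
        assert not discriminatory_subnetworks(phi, np.inf).any()

    def test_core_abundant_everywhere_nondiscriminatory(self):
        # L=10; subnetwork 0 has weight 0.3 in every metabosystem
        phi = np.full((3, 10), 0.7 / 9)
        phi[:, 0] = 0.3
        assert core_subnetworks(phi) == [0]

    def test_discriminatory_subnetwork_not_core(self):
        # abundant in every metabosystem but > 2-fold enriched in k=0
        phi = np.zeros((3, 10))
        phi[:, 0] = [0.5, 0.24, 0.22]
        phi[:, 1:] = (1.0 - phi[:, 0])[:, None] / 9
        assert discriminatory_subnetworks(phi)[0, 0]
        assert 0 not in core_subnetworks(phi)

    def test_rare_subnetwork_not_core(self):
        phi = np.full((3, 10), 0.1)
        phi[:, 0] = 0.01
        phi /= phi.sum(axis=1, keepdims=True)
        assert 0 not in core_subnetworks(phi)

    def test_core_and_discriminatory_disjoint(self):
        rng = np.random.default_rng(8)
        phi = rng.dirichlet(np.full(12, 0.3), size=4)
        disc = discriminatory_subnetworks(phi)
        for l in core_subnetworks(phi):
            assert not disc[:, l].any()


class TestPrincipalReactions:
    def test_indicator_row(self):
        row = np.zeros((1, 100))
        row[0, 42] = 1.0
        [(idx, probs, cum)] = principal_reactions(row, 100)
        assert idx.tolist() == [42] and cum == 1.0

    def test_uniform_row_below_threshold(self):
        [(idx, _, _)] = principal_reactions(np.full((1, 100), 0.01), 100)
        assert len(idx) == 0  # 0.01 < 2/100

    def test_toy_row_threshold_and_order(self):
        row = np.zeros((1, 100))
        row[0, :4] = [0.5, 0.3, 0.15, 0.05]
        [(idx, probs, cum)] = principal_reactions(row, 100)
        assert idx.tolist() == [0, 1, 2, 3]  # all >= 0.02, sorted descending
        assert probs.tolist() == [0.5, 0.3, 0.15, 0.05]
        assert cum == pytest.approx(1.0)

    def test_inclusive_boundary(self):
        row = np.zeros((1, 100))
        row[0, 0] = 0.98
        row[0, 1] = 0.02  # exactly 2/R: retained (filter removes only < 2/R)
        [(idx, _, _)] = principal_reactions(row, 100)
        assert idx.tolist() == [0, 1]


def test_subnetwork_graph_bipartite_structure(catalog_file):
    from biomenet.core import read_catalog

    cat = read_catalog(catalog_file)
    g = subnetwork_graph(cat, [0, 1], currency_compounds={"C3"})
    kinds = {n: d["kind"] for n, d in g.nodes(data=True)}
    assert kinds["R1"] == "reaction" and kinds["C1"] == "compound"
    assert g.edges["R1", "C3"]["currency"] is True
    assert g.edges["C1", "R1"]["currency"] is False
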
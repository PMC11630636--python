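"""Lumping (occupancy/flux preservation) and spectral coarse-graining."""

import numpy as np
import pytest

from permkin import (LagTransitionMatrix, LumpingMap, ProbabilityVector,
                     StateLabelSet, base_flux_matrix, crisp_partition,
                     current_from_transition, eigen_spectrum,
                     fuzzy_macrostates, lump_states, stationary_distribution,
                     transition_from_rates, validate_rate_matrix,
                     MembershipMatrix)

from conftest import TOY_PINF


@pytest.fixture
def toy_tfp(toy):
    T = transition_from_rates(toy.Q, 0.1)
    F = base_flux_matrix(toy.labels, 0.1)
    P = stationary_distribution(T)
    return T, F, P


def random_chain(rng, n):
    V = rng.dirichlet(np.ones(n) * 0.7, size=n) + 1e-4
    V /= V.sum(axis=1, keepdims=True)
    return LagTransitionMatrix(V, StateLabelSet([f"s{i}" for i in range(n)]),
                               1.0)


class TestLumpStates:
    def test_identity_map_leaves_model_unchanged(self, toy, toy_tfp):
        T, F, P = toy_tfp
        lmap = LumpingMap({l: l for l in toy.labels})
        red = lump_states(T, F, P, lmap)
        assert np.max(np.abs(red.T_red.values - T.values)) < 1e-12
        assert np.max(np.abs(red.F_red.values - F.values)) < 1e-12
        assert np.max(np.abs(red.Pinf_red.values - P.values)) < 1e-15

    def test_fig3b_macrostate_mass_and_current(self, toy, toy_tfp, fig3b_map):
        T, F, P = toy_tfp
        red = lump_states(T, F, P, fig3b_map)
        assert len(red.T_red.labels) == 4
        mass = red.Pinf_red.values[red.T_red.labels.index["X"]]
        assert mass == pytest.approx(TOY_PINF[3:].sum(), abs=1e-10)
        assert abs(mass - 0.52) < 0.01
        I = current_from_transition(red.T_red, red.F_red, red.Pinf_red)
        assert abs(I.value_pA - 2.09) < 0.01

    def test_one_pass_equals_sequential_pairwise(self, toy, toy_tfp):
        T, F, P = toy_tfp
        one = lump_states(T, F, P, LumpingMap({
            "WOKKOK": "WOKKOK", "KOKKOK": "KOKKOK", "KOKKOO": "KOKKOO",
            "KOKOOK": "X", "KOOKOK": "X", "WKOKOK": "X"}))
        # pairwise: first merge KOKOOK+KOOKOK into Y, then Y+WKOKOK into X
        step1 = lump_states(T, F, P, LumpingMap({
            "WOKKOK": "WOKKOK", "KOKKOK": "KOKKOK", "KOKKOO": "KOKKOO",
            "KOKOOK": "Y", "KOOKOK": "Y", "WKOKOK": "WKOKOK"}))
        step2 = lump_states(step1.T_red, step1.F_red, step1.Pinf_red,
                            LumpingMap({
                                "WOKKOK": "WOKKOK", "KOKKOK": "KOKKOK",
                                "KOKKOO": "KOKKOO", "Y": "X", "WKOKOK": "X"}))
        assert np.max(np.abs(one.T_red.values - step2.T_red.values)) < 1e-12
        assert np.max(np.abs(one.F_red.values - step2.F_red.values)) < 1e-12

    def test_lumping_preserves_stationarity(self, toy, toy_tfp, fig3b_map):
        T, F, P = toy_tfp
        red = lump_states(T, F, P, fig3b_map)
        recomputed = stationary_distribution(red.T_red)
        assert np.max(np.abs(recomputed.values - red.Pinf_red.values)) < 1e-8

    def test_repeated_lumping_equals_composed_partition(self, toy, toy_tfp):
        T, F, P = toy_tfp
        m1 = LumpingMap({"WOKKOK": "A", "KOKKOK": "A", "KOKKOO": "B",
                         "KOKOOK": "B", "KOOKOK": "C", "WKOKOK": "C"})
        m2 = LumpingMap({"A": "AB", "B": "AB", "C": "C"})
        red1 = lump_states(T, F, P, m1)
        red2 = lump_states(red1.T_red, red1.F_red, red1.Pinf_red, m2)
        direct = lump_states(T, F, P, m1.compose(m2))
        assert np.max(np.abs(red2.T_red.values - direct.T_red.values)) < 1e-12
        assert np.max(np.abs(red2.F_red.values - direct.F_red.values)) < 1e-12

    def test_current_preserved_for_random_partitions(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            n = int(rng.integers(4, 9))
            T = random_chain(rng, n)
            F_vals = rng.normal(0, 0.3, size=(n, n))
            F_vals = (F_vals - F_vals.T) / 2
            np.fill_diagonal(F_vals, 0.0)
            from permkin import FluxMatrix
            F = FluxMatrix(F_vals, T.labels, 1.0, kind="base")
            P = stationary_distribution(T)
            groups = rng.integers(0, 3, size=n)
            lmap = LumpingMap({T.labels[i]: f"g{groups[i]}" for i in range(n)})
            red = lump_states(T, F, P, lmap)
            I0 = current_from_transition(T, F, P).value_pA
            I1 = current_from_transition(red.T_red, red.F_red,
                                         red.Pinf_red).value_pA
            assert abs(I0 - I1) < 1e-9

    def test_partial_map_rejected(self, toy, toy_tfp):
        T, F, P = toy_tfp
        with pytest.raises(ValueError, match="cover"):
            lump_states(T, F, P, LumpingMap({"WOKKOK": "A"}))


def block_chain(p_cross=1e-4):
    """Two weakly coupled 2-state blocks."""
    V = np.array([[0.9, 0.1, 0, 0],
                  [0.1, 0.9, 0, 0],
                  [0, 0, 0.9, 0.1],
                  [0, 0, 0.1, 0.9]], dtype=float)
    V[1, 2] = p_cross
    V[2, 1] = p_cross
    V /= V.sum(axis=1, keepdims=True)
    return LagTransitionMatrix(V, StateLabelSet("abcd"), 1.0)


def three_well_chain():
    """Nine microstates in three wells, intra-well rates 100x inter-well."""
    n = 9
    Q = np.zeros((n, n))
    wells = [(0, 1, 2), (3, 4, 5), (6, 7, 8)]
    for w in wells:
        for i in w:
            for j in w:
                if i != j:
                    Q[i, j] = 1.0
    Q[2, 3] = Q[3, 2] = 0.01     # gateways between wells
    Q[5, 6] = Q[6, 5] = 0.01
    Q[8, 0] = 0.012              # weak directed link closing a cycle
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Qm = validate_rate_matrix(Q, [f"m{i}" for i in range(n)])
    return transition_from_rates(Qm, 0.5), wells


class TestEigenSpectrum:
    def test_weakly_coupled_blocks_suggest_two(self):
        rep = eigen_spectrum(block_chain())
        assert rep.suggested_n_macro == 2

    def test_leading_modulus_is_one(self, toy):
        rep = eigen_spectrum(transition_from_rates(toy.Q, 1.0))
        assert rep.moduli[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(rep.moduli) <= 1e-12)

    def test_identity_has_no_meaningful_gap(self):
        T = LagTransitionMatrix(np.eye(5), StateLabelSet("abcde"), 1.0)
        rep = eigen_spectrum(T)
        assert rep.suggested_n_macro is None


class TestFuzzyMacrostates:
    def test_exact_blocks_give_indicator_memberships(self):
        T = block_chain(p_cross=0.0)
        M = fuzzy_macrostates(T, 2)
        # 0/1 memberships aligned with the blocks, up to column order
        V = np.round(M.values, 9)
        assert set(map(tuple, V)) == {(1.0, 0.0), (0.0, 1.0)}
        assert tuple(V[0]) == tuple(V[1])
        assert tuple(V[2]) == tuple(V[3])
        assert tuple(V[0]) != tuple(V[2])

    def test_metastable_wells_dominate_memberships(self):
        T, wells = three_well_chain()
        M = fuzzy_macrostates(T, 3)
        top = np.argmax(M.values, axis=1)
        assert M.values.max(axis=1).min() > 0.95
        for w in wells:
            assert len({top[i] for i in w}) == 1
        assert len({top[w[0]] for w in wells}) == 3

    def test_rows_sum_to_one(self, toy):
        T = transition_from_rates(toy.Q, 1.0)
        M = fuzzy_macrostates(T, 3)
        assert np.max(np.abs(M.values.sum(axis=1) - 1.0)) < 1e-9

    def test_out_of_range_macro_count_rejected(self, toy):
        T = transition_from_rates(toy.Q, 1.0)
        with pytest.raises(ValueError, match="n_macro"):
            fuzzy_macrostates(T, 1)
        with pytest.raises(ValueError, match="n_macro"):
            fuzzy_macrostates(T, 6)


class TestCrispPartition:
    def test_indicator_membership_roundtrip(self):
        T = block_chain(p_cross=0.0)
        M = fuzzy_macrostates(T, 2)
        lmap = crisp_partition(M)
        assert lmap["a"] == lmap["b"]
        assert lmap["c"] == lmap["d"]
        assert lmap["a"] != lmap["c"]

    def test_tie_goes_to_lower_index_with_warning(self):
        M = MembershipMatrix(np.array([[0.5, 0.5], [0.2, 0.8]]),
                             StateLabelSet("ab"), StateLabelSet(["M0", "M1"]))
        with pytest.warns(UserWarning, match="tied"):
            lmap = crisp_partition(M)
        assert lmap["a"] == "M0"

    def test_empty_macrostate_dropped_with_warning(self):
        M = MembershipMatrix(np.array([[0.9, 0.1], [0.8, 0.2]]),
                             StateLabelSet("ab"), StateLabelSet(["M0", "M1"]))
        with pytest.warns(UserWarning, match="dropped"):
            lmap = crisp_partition(M)
        assert set(lmap.macro_labels) == {"M0"}

    def test_three_well_partition_matches_construction(self):
        T, wells = three_well_chain()
        lmap = crisp_partition(fuzzy_macrostates(T, 3))
        for w in wells:
            assert len({lmap[f"m{i}"] for i in w}) == 1
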
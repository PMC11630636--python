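"""Charge-flux construction: elementary moves, minimal pathways, composites."""

import itertools

import networkx as nx
import numpy as np
import pytest

from permkin import (LagTransitionMatrix, StateLabelSet, base_flux_matrix,
                     composite_flux_empirical, composite_flux_markov,
                     current_from_transition, elementary_moves,
                     ion_configuration, minimal_path_flux,
                     stationary_distribution, transition_from_rates)

from conftest import TOY_F7


def oracle_flux(a, b):
    """Independent shortest-path oracle built on networkx.

    Nodes are ion configurations; edges carry the signed interval count of a
    single ion move (enumerated here from first principles, not via the
    implementation).  Returns the set of net fluxes over all shortest paths,
    in units of 1/(n+1).
    """
    n = len(a)
    G = nx.DiGraph()

    def neighbors(c):
        for k in range(n):          # in-file hops
            if c[k] and k + 1 < n and not c[k + 1]:
                d = list(c); d[k] = 0; d[k + 1] = 1
                yield tuple(d), +1
            if c[k] and k - 1 >= 0 and not c[k - 1]:
                d = list(c); d[k] = 0; d[k - 1] = 1
                yield tuple(d), -1
        d = list(c); d[0] = 1 - d[0]
        yield tuple(d), (+1 if d[0] else -1)        # inner reservoir exchange
        d = list(c); d[-1] = 1 - d[-1]
        yield tuple(d), (-1 if d[-1] else +1)       # outer reservoir exchange

    for c in itertools.product([0, 1], repeat=n):
        for d, w in neighbors(c):
            G.add_edge(c, d, w=w)
    a = tuple(int(x) for x in a)
    b = tuple(int(x) for x in b)
    if a == b:
        return {0}
    fluxes = set()
    for path in nx.all_shortest_paths(G, a, b):
        fluxes.add(sum(G[u][v]["w"] for u, v in zip(path, path[1:])))
    return fluxes


class TestElementaryMoves:
    def test_occupied_filter_moves(self):
        cfg = ion_configuration("KOKKOK")   # ions at S5, S3, S2, S0
        moves = {t: round(f * 7) for t, f in elementary_moves(cfg)}
        ions = lambda s: tuple(c == "K" for c in s)
        # hand enumeration: hops into the two empty sites (S4, S1), plus the
        # two reservoir exchanges at the occupied chain ends; the S2 ion
        # cannot hop outward into the occupied S3 position
        assert moves == {
            ions("OKKKOK"): +1,   # S5 ion hops outward into S4
            ions("OOKKOK"): -1,   # S5 ion exits to the intracellular bulk
            ions("KKOKOK"): -1,   # S3 ion hops inward into S4
            ions("KOKOKK"): +1,   # S2 ion hops outward into S1
            ions("KOKKKO"): -1,   # S0 ion hops inward into S1
            ions("KOKKOO"): +1,   # S0 ion exits to the extracellular bulk
        }

    def test_empty_filter_has_two_entries(self):
        moves = elementary_moves((False,) * 6)
        assert len(moves) == 2
        assert sorted(f for _, f in moves) == [pytest.approx(-1 / 7),
                                               pytest.approx(+1 / 7)]

    def test_full_filter_has_two_exits(self):
        moves = elementary_moves((True,) * 6)
        assert len(moves) == 2
        assert sorted(f for _, f in moves) == [pytest.approx(-1 / 7),
                                               pytest.approx(+1 / 7)]


class TestMinimalPathFlux:
    def test_single_hop_worked_example(self):
        res = minimal_path_flux(ion_configuration("KOKKOO"),
                                ion_configuration("KOKOKO"))
        assert res.flux == pytest.approx(1 / 7)
        assert res.n_moves == 1
        assert not res.ambiguous

    def test_six_move_reverse_route_sums_to_minus_six_sevenths(self):
        # the long way round for the same endpoints: the S5 ion exits inward,
        # the S3 ion walks down to S5, the S2 ion to S3, and an outside ion
        # enters down to S1 -- six elementary moves, net -6/7
        route = ["KOKKOO", "OOKKOO", "OKOKOO", "KOOKOO", "KOKOOO",
                 "KOKOOK", "KOKOKO"]
        total = 0.0
        n_moves = 0
        for s, t in zip(route, route[1:]):
            moves = dict(elementary_moves(ion_configuration(s)))
            total += moves[ion_configuration(t)]
            n_moves += 1
        assert n_moves == 6
        assert round(total * 7) == -6
        assert total == pytest.approx(-6 / 7)

    def test_identity_configuration(self):
        res = minimal_path_flux(ion_configuration("KOKKOO"),
                                ion_configuration("KOKKOO"))
        assert res.flux == 0.0 and res.n_moves == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_networkx_shortest_path_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = tuple(bool(x) for x in rng.integers(0, 2, size=6))
        b = tuple(bool(x) for x in rng.integers(0, 2, size=6))
        res = minimal_path_flux(a, b)
        fluxes = oracle_flux(a, b)
        assert round(res.flux * 7) in fluxes
        assert res.ambiguous == (len(fluxes) > 1)
        if len(fluxes) > 1:
            assert abs(round(res.flux * 7)) == min(abs(f) for f in fluxes)


class TestBaseFluxMatrix:
    def test_six_state_cycle_fluxes(self, toy):
        F = base_flux_matrix(toy.labels, 1.0)
        assert np.allclose(F.values, TOY_F7 / 7, atol=1e-12)
        cycle = ["WOKKOK", "KOKKOK", "KOKKOO", "KOKOOK", "KOOKOK",
                 "WKOKOK", "WOKKOK"]
        idx = [toy.labels.index[s] for s in cycle]
        total = sum(F.values[i, j] for i, j in zip(idx, idx[1:]))
        assert total == pytest.approx(1.0)      # one full permeation per cycle

    def test_water_only_differences_carry_no_flux(self):
        F = base_flux_matrix(["KOKKOK", "KOKKWK", "KOKWOB"], 1.0)
        assert abs(F.values[0, 1]) < 1e-15      # same ion configuration
        assert abs(F.values[0, 2]) > 0          # genuinely different ions

    def test_exact_antisymmetry(self, toy):
        F = base_flux_matrix(toy.labels, 1.0)
        assert np.max(np.abs(F.values + F.values.T)) == 0.0


class TestCompositeFlux:
    def test_n_equals_one_returns_base(self, toy):
        T = transition_from_rates(toy.Q, 1.0)
        F = base_flux_matrix(toy.labels, 1.0)
        Fc = composite_flux_markov(T, F, 1)
        assert np.array_equal(Fc.values, F.values)
        assert Fc.kind == "composite_markov"

    def test_two_step_matches_pathway_enumeration(self, toy):
        # brute force: average F_im + F_mj over all two-step pathways i->m->j
        # weighted by their probability
        T = transition_from_rates(toy.Q, 1.0)
        F = base_flux_matrix(toy.labels, 1.0)
        Fc = composite_flux_markov(T, F, 2)
        n = 6
        expected = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                num = den = 0.0
                for m in range(n):
                    w = T.values[i, m] * T.values[m, j]
                    num += w * (F.values[i, m] + F.values[m, j])
                    den += w
                expected[i, j] = num / den if den > 0 else 0.0
        assert np.max(np.abs(Fc.values - expected)) < 1e-14

    def test_markov_composite_current_is_lagtime_invariant(self, toy):
        T = transition_from_rates(toy.Q, 1.0)
        F = base_flux_matrix(toy.labels, 1.0)
        P = stationary_distribution(T)
        ref = current_from_transition(T, F, P).value_pA
        for n in (2, 5, 13, 30):
            Tn = LagTransitionMatrix(np.linalg.matrix_power(T.values, n),
                                     toy.labels, float(n))
            I = current_from_transition(Tn, composite_flux_markov(T, F, n),
                                        P).value_pA
            assert abs(I - ref) < 1e-9

    def test_empirical_equals_markov_for_exact_powers(self, toy):
        T = transition_from_rates(toy.Q, 1.0)
        F = base_flux_matrix(toy.labels, 1.0)
        stars = [
            LagTransitionMatrix(np.linalg.matrix_power(T.values, n),
                                toy.labels, float(n))
            for n in range(1, 8)
        ]
        Fe = composite_flux_empirical(stars, F)
        Fm = composite_flux_markov(T, F, 7)
        assert np.max(np.abs(Fe.values - Fm.values)) < 1e-12
        assert Fe.kind == "composite_empirical"

    def test_missing_intermediate_lagtime_rejected(self, toy):
        T = transition_from_rates(toy.Q, 1.0)
        F = base_flux_matrix(toy.labels, 1.0)
        stars = [T, transition_from_rates(toy.Q, 3.0)]
        with pytest.raises(ValueError, match=r"\[2\]"):
            composite_flux_empirical(stars, F)

    def test_composite_reduces_to_base_in_short_lagtime_limit(self, toy):
        # on pairs with a direct rate the single hop dominates as dt -> 0;
        # pairs only reachable through intermediate states keep a genuine
        # multi-step average (with vanishing probability), so they are not
        # expected to match the minimal-path value
        T = transition_from_rates(toy.Q, 1e-4)
        F = base_flux_matrix(toy.labels, 1e-4)
        Fc = composite_flux_markov(T, F, 3)
        direct = (toy.Q.values > 0) & ~np.eye(6, dtype=bool)
        assert np.max(np.abs(Fc.values - F.values)[direct]) < 1e-3
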
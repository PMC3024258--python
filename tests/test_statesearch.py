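"""Candidate generation, ground-state search, and threshold enumeration.

The certification strategy: on fixtures small enough for exhaustive
enumeration, the production search must reproduce the brute-force oracle's
state set, partition function and ensemble averages exactly (no threshold),
and within the exp(-theta/RT) neglected-weight bound when thresholded.
"""

import numpy as np
import pytest

from sibz.energetics import encode
from sibz.fixtures import make_fixture, poly_t_with_insert
from sibz.mechanics import PhysicalConstants, TopologyContext
from sibz.oracle import brute_force_ensemble, count_states
from sibz.statesearch import SearchParams, StateSearch, generate_candidates

TWIN = make_fixture("twin_islands60")
TWIN_CODES = encode(TWIN.sequence)


def twin_search(sigma, theta=None, max_runs=2, max_run_len=30, min_run_len=8):
    params = SearchParams(theta=theta, min_run_len=min_run_len,
                          max_run_len=max_run_len, max_runs=max_runs)
    cand = generate_candidates(TWIN_CODES, True, params)
    return StateSearch(TopologyContext(60, sigma), cand, params)


class TestCandidates:
    def test_combinatorial_count_on_circle(self):
        """A circular N has N starts for every admissible even length."""
        params = SearchParams(min_run_len=8, max_run_len=250)
        cand = generate_candidates(encode("T" * 200), True, params)
        n_lengths = len(range(8, 199, 2))  # capped at N-2 = 198
        assert len(cand) == 200 * n_lengths

    def test_relaxed_count_small_linear(self):
        params = SearchParams(min_run_len=2, max_run_len=20)
        cand = generate_candidates(encode("ACGTACGTACGTACGTACGT"), False, params)
        expect = sum(20 - length + 1 for length in range(2, 21, 2))
        assert len(cand) == expect

    def test_poly_t_minimum_candidate_energy(self):
        """All 8-bp windows of poly-T cost 4 x 3.9 = 15.6 kcal/mol."""
        cand = generate_candidates(encode("T" * 200), True)
        eight = cand.energies[cand.lengths == 8]
        assert np.allclose(eight, 15.6)
        assert cand.energies.min() == pytest.approx(15.6)

    def test_lone_insert_hosts_all_cheap_candidates(self):
        """With a single (CG)16 island, every minimum-energy window (pure
        in-phase CG at 0.35/bp) lies inside the insert, and the full 32-bp
        window is the cheapest of its length."""
        fx = poly_t_with_insert(968, "CG" * 16, 300)
        cand = generate_candidates(encode(fx.sequence), True)
        cheap = cand.energies <= cand.lengths * 0.35 + 1e-9
        assert cheap.any()
        assert (cand.starts[cheap] >= 300).all()
        assert (cand.starts[cheap] + cand.lengths[cheap] <= 332).all()
        len32 = cand.lengths == 32
        i = int(np.argmin(np.where(len32, cand.energies, np.inf)))
        assert int(cand.starts[i]) == 300
        assert cand.energies[i] == pytest.approx(11.2)


class TestMinimumState:
    def test_relaxed_molecule_stays_untransformed(self):
        """At sigma = 0 transition plus nucleation always costs energy."""
        eng = twin_search(0.0, theta=12.0)
        state = eng.find_minimum_state()
        assert state.r == 0
        assert state.free_energy == pytest.approx(0.0)

    def test_modest_stress_cannot_pay_nucleation(self):
        """A 200-bp poly-T circle at sigma=-0.03: the cheapest run costs
        15.6 + 10 kcal/mol, far above the available quadratic relief."""
        cand = generate_candidates(encode("T" * 200), True)
        eng = StateSearch(TopologyContext(200, -0.03), cand)
        assert eng.find_minimum_state().r == 0

    def test_ground_state_covers_dominant_insert(self):
        """A strongly stressed lone (CG)16 insert flips exactly (the domain
        is large enough that full transition does not overshoot alpha_r)."""
        fx = poly_t_with_insert(2968, "CG" * 16, 300)
        cand = generate_candidates(encode(fx.sequence), True)
        eng = StateSearch(TopologyContext(3000, -0.06), cand)
        state = eng.find_minimum_state()
        assert state.r == 1
        assert (state.runs[0].start, state.runs[0].length) == (300, 32)

    def test_matches_oracle_ground_state(self):
        for sigma in (-0.15, -0.1, -0.05):
            eng = twin_search(sigma)
            orc = brute_force_ensemble(TWIN.sequence, sigma, True, 8, 30, 2)
            assert eng.find_minimum_state().free_energy == pytest.approx(
                orc.g_min, abs=1e-9
            )


class TestEnumeration:
    def test_exact_enumeration_equals_oracle(self):
        """Without a threshold the state multiset matches the oracle."""
        eng = twin_search(-0.15)
        ours = sorted(
            (tuple((r.start, r.length) for r in s.runs), round(s.free_energy, 9))
            for s in eng.enumerate_states(max_states=200_000)
        )
        orc = brute_force_ensemble(TWIN.sequence, -0.15, True, 8, 30, 2)
        theirs = sorted(
            (tuple(sorted(runs)), round(g, 9)) for runs, g in orc.states
        )
        assert ours == theirs

    def test_three_run_states_match_oracle(self):
        eng = twin_search(-0.15, max_runs=3, max_run_len=12)
        res = eng.accumulate()
        orc = brute_force_ensemble(TWIN.sequence, -0.15, True, 8, 12, 3)
        assert res.states_enumerated == orc.states_count
        assert res.g_min == pytest.approx(orc.g_min, abs=1e-9)
        np.testing.assert_allclose(res.coverage(), orc.p, atol=1e-12)
        assert res.avg_n_z == pytest.approx(orc.avg_n_z, abs=1e-12)
        assert res.avg_runs == pytest.approx(orc.avg_runs, abs=1e-12)

    def test_thresholded_subset_and_bound(self):
        """Every enumerated state satisfies G <= G_min + theta; each theta's
        set nests inside larger thetas'; thresholded ensemble quantities sit
        within the exp(-theta/RT) neglected-weight bound of the exact ones."""
        rt = PhysicalConstants().rt
        orc = brute_force_ensemble(TWIN.sequence, -0.15, True, 8, 30, 2)
        seen = {}
        for theta in (9.0, 12.0, 40.0):
            eng = twin_search(-0.15, theta=theta)
            states = list(eng.enumerate_states(max_states=200_000))
            assert all(
                s.free_energy <= eng.find_minimum_state().free_energy + theta + 1e-9
                for s in states
            )
            seen[theta] = {
                tuple((r.start, r.length) for r in s.runs) for s in states
            }
            res = eng.accumulate()
            assert res.states_enumerated == len(states)
            bound = np.exp(-theta / rt)
            assert np.abs(res.coverage() - orc.p).max() <= bound + 1e-15
        assert seen[9.0] <= seen[12.0] <= seen[40.0]

    def test_theta_must_be_positive(self):
        with pytest.raises(ValueError):
            SearchParams(theta=-1.0)
        with pytest.raises(ValueError):
            SearchParams(theta=0.0)

    def test_determinism(self):
        a = twin_search(-0.12, theta=40.0).accumulate()
        b = twin_search(-0.12, theta=40.0).accumulate()
        assert a.z_rel == b.z_rel
        assert a.states_enumerated == b.states_enumerated
        np.testing.assert_array_equal(a.t_weight, b.t_weight)

    def test_runs_respect_geometry(self):
        """Enumerated runs never overlap, never merge across a 0-bp gap."""
        for state in twin_search(-0.15, theta=40.0).enumerate_states():
            runs = sorted(state.runs, key=lambda r: r.start)
            for a, b in zip(runs, runs[1:]):
                assert b.start >= a.end + 1
            if runs and state.runs[-1].end > 60:
                assert state.runs[-1].end - 60 <= runs[0].start - 1


class TestRelaxedCounts:
    @pytest.mark.parametrize("n", range(4, 16))
    @pytest.mark.parametrize("circular", [True, False])
    def test_count_mode_equals_tiling_theory(self, n, circular):
        """With min length 2 and unlimited runs, admissible placements
        (plus the two all-Z phasings of an even circle) reproduce the
        recursion counts."""
        params = SearchParams(theta=None, min_run_len=2, max_run_len=n,
                              max_runs=n // 3 + 2)
        cand = generate_candidates(encode("T" * n), circular, params)
        eng = StateSearch(TopologyContext(n, -0.05), cand, params)
        sc = count_states(n, "circular" if circular else "linear")
        want = sc.circular_count if circular else sc.linear_count
        assert eng.count_all_states() == want


class TestRunCountSufficiency:
    def test_raising_max_runs_changes_little(self):
        """On a two-island fixture the default run cap is saturated: adding
        a fifth allowed run changes ensemble averages by < 1e-3."""
        fx = poly_t_with_insert(968, "CG" * 16, 300)
        cand4 = generate_candidates(encode(fx.sequence), True,
                                    SearchParams(max_runs=4))
        cand5 = generate_candidates(encode(fx.sequence), True,
                                    SearchParams(max_runs=5))
        ctx = TopologyContext(1000, -0.06)
        r4 = StateSearch(ctx, cand4, SearchParams(max_runs=4)).accumulate()
        r5 = StateSearch(ctx, cand5, SearchParams(max_runs=5)).accumulate()
        assert abs(r4.avg_n_z - r5.avg_n_z) < 1e-3
        assert abs(r4.avg_runs - r5.avg_runs) < 1e-3
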
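"""Equilibrium profiles, region probabilities, sweeps, onset, aggregation."""

import numpy as np
import pytest

from sibz.ensemble import (
    aggregate_profiles,
    boltzmann_profile,
    call_z_regions,
    onset_sigma,
    profile_sequence,
    region_probability,
    sigma_sweep,
)
from sibz.fixtures import make_fixture, poly_t_with_insert, random_sequence, tss_cohort
from sibz.io import make_context
from sibz.mechanics import PhysicalConstants
from sibz.oracle import brute_force_ensemble
from sibz.statesearch import SearchParams, generate_candidates

TWIN = make_fixture("twin_islands60")
TWIN_PARAMS = SearchParams(theta=None, min_run_len=8, max_run_len=30, max_runs=2)

LONE = poly_t_with_insert(2968, "CG" * 16, 300)  # 3-kb circle, one strong site
LONE_CTX = make_context(LONE.sequence, circular=True)
# candidate energies are sigma-independent; share them across tests
LONE_CAND = generate_candidates(LONE_CTX.codes, True)


def twin_profile(sigma, params=TWIN_PARAMS):
    ctx = make_context(TWIN.sequence, circular=True)
    return profile_sequence(ctx, sigma, params)


class TestBoltzmannProfile:
    def test_matches_exact_oracle(self):
        """Pipeline probabilities equal the brute-force Boltzmann computation
        to full precision on the 60-bp twin-island circle."""
        prof, _ = twin_profile(-0.15)
        orc = brute_force_ensemble(TWIN.sequence, -0.15, True, 8, 30, 2)
        np.testing.assert_allclose(prof.p, orc.p, rtol=1e-10, atol=1e-30)
        assert prof.avg_runs == pytest.approx(orc.avg_runs, rel=1e-10)

    def test_relaxed_molecule_has_flat_zero_profile(self):
        prof, _ = twin_profile(0.0)
        assert prof.p.max() < 1e-6
        assert prof.avg_n_z < 1e-4

    def test_probability_bounds_and_nz_identity(self):
        """0 <= p <= 1 everywhere and sum(p) = <n_Z> on every fixture."""
        for sigma in (-0.05, -0.1, -0.15):
            prof, _ = twin_profile(sigma)
            assert prof.p.min() >= 0.0
            assert prof.p.max() <= 1.0
            assert prof.p.sum() == pytest.approx(prof.avg_n_z, rel=1e-12)
        prof, _ = profile_sequence(LONE_CTX, -0.06, candidates=LONE_CAND)
        assert prof.p.min() >= 0.0 and prof.p.max() <= 1.0
        assert prof.p.sum() == pytest.approx(prof.avg_n_z, rel=1e-12)

    def test_twin_islands_share_probability_by_symmetry(self):
        """Two identical, equidistant islands are exactly degenerate."""
        prof, _ = twin_profile(-0.15)
        (a1, b1), (a2, b2) = TWIN.regions["island1"], TWIN.regions["island2"]
        np.testing.assert_allclose(prof.p[a1:b1], prof.p[a2:b2], rtol=1e-9)

    def test_strong_lone_insert_flips(self):
        """The insert interior is decisively Z; its outermost base pairs
        share weight with near-degenerate partial runs."""
        prof, res = profile_sequence(LONE_CTX, -0.06, candidates=LONE_CAND)
        a, b = LONE.regions["insert"]
        assert prof.p[a + 6:b - 6].min() > 0.9
        assert prof.p[a:b].mean() > 0.9
        assert prof.p[:a - 20].max() < 0.05

    def test_reverse_complement_profile_symmetry(self):
        """The profile of the reverse complement is the reversed profile
        (randomized 500-bp circle with an embedded Z-susceptible patch)."""
        seq = random_sequence(500, seed=11, gc_patch="CG" * 10, patch_at=120)
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        p_fwd, _ = profile_sequence(make_context(seq, True), -0.12)
        p_rev, _ = profile_sequence(make_context(rc, True), -0.12)
        np.testing.assert_allclose(p_fwd.p, p_rev.p[::-1], atol=1e-9)

    def test_threshold_stability(self):
        """theta = 10 vs 12 changes p(x) by less than 1e-4."""
        p10, _ = profile_sequence(LONE_CTX, -0.06, SearchParams(theta=10.0), candidates=LONE_CAND)
        p12, _ = profile_sequence(LONE_CTX, -0.06, SearchParams(theta=12.0), candidates=LONE_CAND)
        assert np.abs(p10.p - p12.p).max() < 1e-4

    def test_higher_temperature_smooths_profile(self):
        """Doubling T halves beta: occupancy spreads away from the ground
        state, so the dominant site's peak probability drops."""
        hot = PhysicalConstants(temperature=620.0)
        cold, _ = profile_sequence(LONE_CTX, -0.055, candidates=LONE_CAND)
        warm, _ = profile_sequence(LONE_CTX, -0.055, constants=hot, candidates=LONE_CAND)
        a, b = LONE.regions["insert"]
        assert warm.p[a:b].max() < cold.p[a:b].max()


class TestRegionProbability:
    def test_modes_ordering(self):
        """all_z <= min p over the region <= mean_p (set inclusion)."""
        _, res = twin_profile(-0.15)
        for region in (TWIN.regions["island1"], (38, 50)):
            az = region_probability(res, region, "all_z")
            mp = region_probability(res, region, "mean_p")
            pmin = res.coverage()[slice(*region)].min()
            assert az <= pmin + 1e-12
            assert pmin <= mp + 1e-12

    def test_background_region_is_cold(self):
        _, res = profile_sequence(LONE_CTX, -0.06, candidates=LONE_CAND)
        assert region_probability(res, (600, 900), "mean_p") < 1e-6
        assert region_probability(res, (600, 900), "all_z") < 1e-9

    def test_all_z_matches_oracle_definition(self):
        """all_z equals the summed weight of oracle states covering the
        region entirely."""
        _, res = twin_profile(-0.15)
        orc = brute_force_ensemble(TWIN.sequence, -0.15, True, 8, 30, 2)
        a, b = TWIN.regions["island1"]
        want = sum(
            np.exp(-(g - orc.g_min) / PhysicalConstants().rt)
            for runs, g in orc.states
            if any(s <= a and s + ln >= b for s, ln in runs)
        ) / orc.z
        assert region_probability(res, (a, b), "all_z") == pytest.approx(want, rel=1e-9)

    def test_bad_regions_rejected(self):
        _, res = twin_profile(-0.1)
        with pytest.raises(ValueError):
            region_probability(res, (10, 10))
        with pytest.raises(ValueError):
            region_probability(res, (50, 70))
        with pytest.raises(ValueError):
            region_probability(res, (0, 8), mode="median")


class TestSigmaSweep:
    def test_avg_nz_monotone_in_stress(self):
        grid = np.arange(-0.07, -0.019, 0.01)
        sweep = sigma_sweep(LONE_CTX, grid)
        nz = sweep.avg_n_z  # grid ascends toward 0: <n_Z> must not increase
        assert all(b <= a + 1e-9 for a, b in zip(nz, nz[1:]))

    def test_poly_t_stays_inert_at_physiological_stress(self):
        """A pure poly-T circle acquires essentially no Z-form down to
        sigma = -0.07 (TT units at 3.9 kcal/mol never repay nucleation)."""
        ctx = make_context("T" * 1000, circular=True)
        sweep = sigma_sweep(ctx, np.arange(-0.07, 0.001, 0.014))
        assert sweep.avg_n_z.max() < 0.05
        assert max(p.p.max() for p in sweep.profiles) < 1e-3

    def test_grid_refinement_is_consistent(self):
        """Per-sigma results are independent of the rest of the grid."""
        coarse = sigma_sweep(LONE_CTX, [-0.06, -0.04])
        fine = sigma_sweep(LONE_CTX, [-0.06, -0.05, -0.04])
        assert coarse.avg_n_z[0] == fine.avg_n_z[0]
        assert coarse.avg_n_z[-1] == fine.avg_n_z[-1]

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            sigma_sweep(LONE_CTX, [-0.06, -0.02, -0.04])

    def test_region_curves_present_in_both_modes(self):
        sweep = sigma_sweep(LONE_CTX, [-0.07, -0.05, -0.03],
                            regions={"insert": LONE.regions["insert"]})
        c = sweep.region_curves["insert"]
        assert set(c) == {"mean_p", "all_z"}
        assert (c["all_z"] <= c["mean_p"] + 1e-12).all()


class TestOnset:
    def test_lone_insert_onset_is_bracketed(self):
        """A (CG)16 insert in a 3-kb poly-T circle flips around sigma -0.037
        (two-state estimate); the bisection lands nearby at 3 decimals."""
        o = onset_sigma(LONE_CTX, LONE.regions["insert"], level=0.8,
                        sigma_range=(-0.07, 0.0))
        assert o.found
        assert -0.06 < o.sigma_c < -0.025
        assert o.sigma_c == round(o.sigma_c_raw, 3)

    def test_deeper_level_needs_more_stress(self):
        o50 = onset_sigma(LONE_CTX, LONE.regions["insert"], level=0.5,
                          sigma_range=(-0.07, 0.0))
        o80 = onset_sigma(LONE_CTX, LONE.regions["insert"], level=0.8,
                          sigma_range=(-0.07, 0.0))
        assert o80.sigma_c_raw <= o50.sigma_c_raw + 1e-12

    def test_doubled_nucleation_shifts_onset_deeper(self):
        hard = PhysicalConstants(junction_nucleation=10.0)
        o_std = onset_sigma(LONE_CTX, LONE.regions["insert"],
                            sigma_range=(-0.07, 0.0))
        o_hard = onset_sigma(LONE_CTX, LONE.regions["insert"], constants=hard,
                             sigma_range=(-0.07, 0.0))
        assert o_hard.sigma_c_raw < o_std.sigma_c_raw

    def test_no_onset_reported_explicitly(self):
        ctx = make_context("T" * 400, circular=True)
        o = onset_sigma(ctx, (100, 140), sigma_range=(-0.08, 0.0))
        assert not o.found
        assert o.sigma_c is None


class TestAggregate:
    def test_identical_profiles_average_to_themselves(self):
        p = np.linspace(0, 1, 50)
        res = aggregate_profiles([p, p, p], anchor=25)
        np.testing.assert_allclose(res.mean_p, p)

    def test_half_and_half_mean(self):
        a = np.zeros(40)
        b = np.zeros(40)
        b[10:20] = 1.0
        res = aggregate_profiles([a, b], anchor=0)
        np.testing.assert_allclose(res.mean_p[10:20], 0.5)
        assert res.calls[0] == []
        assert res.calls[1] == [(10, 20)]

    def test_ragged_profiles_rejected(self):
        with pytest.raises(ValueError):
            aggregate_profiles([np.zeros(10), np.zeros(12)], anchor=0)

    def test_call_z_regions_segments(self):
        p = np.array([0.0, 0.9, 0.95, 0.1, 0.85, 0.85, 0.0])
        assert call_z_regions(p, 0.8) == [(1, 3), (4, 6)]

    def test_synthetic_cohort_upstream_counts(self):
        """Half of a 20-sequence cohort carries a (CG)12 insert upstream of
        the anchor; at sigma = -0.07 exactly those 10 are called."""
        cohort, anchor = tss_cohort(n_sequences=20, length=2000, anchor=1000,
                                    insert="CG" * 12, offset=-100, seed=3)
        # two distinct sequences in the cohort; candidate caching makes the
        # repeats cheap
        profiles = []
        for fx in cohort:
            ctx = make_context(fx.sequence, circular=False)
            prof, _ = profile_sequence(ctx, -0.07)
            profiles.append(prof)
        res = aggregate_profiles(profiles, anchor, level=0.8,
                                 windows=[(-1000, -1), (1, 500)])
        assert res.window_counts[(-1000, -1)] == 10
        assert res.window_counts[(1, 500)] == 0
        carriers = sum(1 for calls in res.calls if calls)
        assert carriers == 10


class TestCompetitionRegimes:
    def test_insert_probabilities_cross_with_stress(self):
        """Two inserts in a 5-kb poly-T circle: the short cheap insert
        flips first; deeper stress favours the long junction-bearing insert,
        which reverts the short one before both transform together."""
        fx = make_fixture("competition5000")
        ctx = make_context(fx.sequence, circular=True)
        grid = np.array([-0.07, -0.0525, -0.0375, -0.03])
        sweep = sigma_sweep(ctx, grid, regions=fx.regions)
        m1 = sweep.region_curves["insert1"]["mean_p"]
        m2 = sweep.region_curves["insert2"]["mean_p"]
        # grid ascends toward zero: deep, reversion, insert-1-only, neither
        assert m1[3] < 0.2 and m2[3] < 0.2
        assert m1[2] > 0.5 and m2[2] < 0.5
        assert m1[1] < 0.5 and m2[1] > 0.5  # insert 2 displaced insert 1
        assert m1[0] > 0.5 and m2[0] > 0.5
        # the flip-entirely observable shows the reversion starkly
        z1 = sweep.region_curves["insert1"]["all_z"]
        assert z1[1] < 0.12 < z1[2]


def test_boltzmann_profile_report_mask():
    """Linear sequences are analyzed on the augmented circle but reported in
    user coordinates; the 50-T joint never appears."""
    fx = poly_t_with_insert(368, "CG" * 12, 100)
    ctx = make_context(fx.sequence, circular=False)
    assert ctx.n_domain == ctx.report_len + 50
    prof, res = profile_sequence(ctx, -0.08)
    assert len(prof.p) == ctx.report_len
    full = boltzmann_profile(res, -0.08)
    assert len(full.p) == ctx.n_domain
    assert full.p[ctx.report_len:].max() < 1e-6
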
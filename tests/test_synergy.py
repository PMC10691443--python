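"""Hill fitting, reference surfaces, and the screen's replicate/missing rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spherosynergy import simulate as sim
from spherosynergy import synergy as sy

DOSES = np.array([0.0, 0.0617, 0.1852, 0.5556, 1.6667, 5.0])


def matrix(values, reps=1, **ids):
    return sy.DoseMatrix(
        doses1=DOSES, doses2=DOSES, values=np.asarray(values, float),
        pair="A+B", cell_line="L1", day=18, replicate=reps, **ids,
    )


def full_grid(level=50.0):
    return np.full((6, 6), float(level))


# ---------------------------------------------------------------------------
# Replicate merging and missing-data rules
# ---------------------------------------------------------------------------

class TestReplicateRules:
    def test_mean_where_both_present(self):
        m = sy.merge_replicates(matrix(full_grid(80)), matrix(full_grid(90), reps=2))
        assert np.allclose(m.values, 85.0)

    def test_single_value_used_instead_of_mean(self):
        v1 = full_grid(80)
        v1[3, 4] = np.nan
        m = sy.merge_replicates(matrix(v1), matrix(full_grid(90), reps=2))
        assert m.values[3, 4] == 80.0 + 10.0  # only replicate 2 contributes
        assert m.values[0, 0] == 85.0

    def test_both_missing_stays_missing(self):
        v1, v2 = full_grid(), full_grid()
        v1[2, 2] = v2[2, 2] = np.nan
        m = sy.merge_replicates(matrix(v1), matrix(v2, reps=2))
        assert np.isnan(m.values[2, 2])

    def test_dose_mismatch_rejected(self):
        other = sy.DoseMatrix(
            doses1=DOSES, doses2=DOSES * 2.0, values=full_grid(),
            pair="A+B", cell_line="L1", day=18,
        )
        with pytest.raises(ValueError):
            sy.merge_replicates(matrix(full_grid()), other)


class TestMissingRules:
    def test_monotherapy_gap_excludes_matrix(self):
        broken = full_grid()
        broken[3, 0] = np.nan  # monotherapy well
        ok = full_grid()
        usable = sy.apply_missing_rules(matrix(broken), matrix(ok, reps=2))
        assert len(usable) == 1
        assert usable[0].replicate == 2

    def test_interior_gap_imputed_to_100(self):
        v = full_grid(60)
        v[2, 3] = np.nan
        usable = sy.apply_missing_rules(matrix(v))
        assert len(usable) == 1
        assert usable[0].values[2, 3] == 100.0
        assert usable[0].values[2, 2] == 60.0

    def test_complete_pair_passes_through_unchanged(self):
        usable = sy.apply_missing_rules(matrix(full_grid()), matrix(full_grid(), reps=2))
        assert len(usable) == 2
        assert all(not np.isnan(u.values).any() for u in usable)

    def test_both_broken_yields_empty(self):
        v = full_grid()
        v[0, 5] = np.nan
        usable = sy.apply_missing_rules(matrix(v.copy()), matrix(v.copy(), reps=2))
        assert usable == []


# ---------------------------------------------------------------------------
# Hill fitting
# ---------------------------------------------------------------------------

class TestHillFit:
    def test_recovers_noiseless_parameters(self):
        true = sy.HillParams(e0=100, emax=10, ec50=0.5, slope=1.5)
        fit = sy.fit_monotherapy(DOSES, sy.hill_viability(DOSES, true))
        for got, want in [(fit.e0, 100), (fit.emax, 10), (fit.ec50, 0.5), (fit.slope, 1.5)]:
            assert abs(got - want) / want < 1e-3
        assert not fit.flat and not fit.poor_fit

    def test_midpoint_identity(self):
        p = sy.HillParams(e0=100, emax=20, ec50=0.7, slope=2.3)
        assert sy.hill_viability(0.7, p) == pytest.approx((100 + 20) / 2)

    def test_inactive_drug_flat_fit(self):
        fit = sy.fit_monotherapy(DOSES, np.full(6, 100.0))
        assert fit.flat
        assert fit.e0 == fit.emax == pytest.approx(100.0)

    def test_rising_response_flagged_not_fatal(self):
        v = np.array([100.0, 98.0, 101.0, 110.0, 121.0, 133.0])
        fit = sy.fit_monotherapy(DOSES, v)
        assert fit.poor_fit

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            sy.fit_monotherapy([0, 1, 2], [100, 50, 10])


# ---------------------------------------------------------------------------
# Reference surfaces
# ---------------------------------------------------------------------------

HILL_A = sy.HillParams(e0=100, emax=5, ec50=0.4, slope=1.8)
HILL_B = sy.HillParams(e0=100, emax=15, ec50=1.1, slope=0.9)


class TestBlissHsa:
    def test_product_rule_and_margins(self):
        ref = sy.bliss_reference(HILL_A, HILL_B, DOSES, DOSES)
        vA = sy.hill_viability(DOSES, HILL_A)
        vB = sy.hill_viability(DOSES, HILL_B)
        np.testing.assert_allclose(ref[:, 0], vA)
        np.testing.assert_allclose(ref[0, :], vB)
        for i in range(6):  # brute-force cellwise oracle
            for j in range(6):
                assert ref[i, j] == pytest.approx(vA[i] * vB[j] / 100.0)

    def test_hsa_min_rule_and_symmetry(self):
        ref = sy.hsa_reference(HILL_A, HILL_B, DOSES, DOSES)
        vA = sy.hill_viability(DOSES, HILL_A)
        vB = sy.hill_viability(DOSES, HILL_B)
        for i in range(6):
            for j in range(6):
                assert ref[i, j] == min(vA[i], vB[j])
        same = sy.hsa_reference(HILL_A, HILL_A, DOSES, DOSES)
        np.testing.assert_allclose(same, same.T)

    @given(
        ecA=st.floats(0.05, 5), ecB=st.floats(0.05, 5),
        sA=st.floats(0.5, 4), sB=st.floats(0.5, 4),
        emA=st.floats(0, 60), emB=st.floats(0, 60),
    )
    def test_hsa_dominates_bliss_on_viability_scale(self, ecA, ecB, sA, sB, emA, emB):
        hA = sy.HillParams(100, emA, ecA, sA)
        hB = sy.HillParams(100, emB, ecB, sB)
        bliss = sy.bliss_reference(hA, hB, DOSES, DOSES)
        hsa = sy.hsa_reference(hA, hB, DOSES, DOSES)
        assert np.all(hsa >= bliss - 1e-9)


class TestLoewe:
    def test_sham_combination_is_additive(self):
        # canonical correctness oracle: a drug combined with itself must
        # reproduce its own dose-response at the summed dose
        h = sy.HillParams(e0=100, emax=0, ec50=0.8, slope=1.3)
        ref = sy.loewe_reference(h, h, DOSES, DOSES)
        for i, d1 in enumerate(DOSES):
            for j, d2 in enumerate(DOSES):
                expected = sy.hill_viability(d1 + d2, h)
                assert ref[i, j] == pytest.approx(expected, abs=1e-6)

    def test_unit_slope_closed_form(self, rng):
        # with slope 1, e0=100, emax=0 the implicit equation solves to
        # V = 100 / (1 + d1/ec50A + d2/ec50B)
        worst = 0.0
        for _ in range(100):
            ecA, ecB = rng.uniform(0.05, 5, 2)
            hA = sy.HillParams(100, 0, ecA, 1.0)
            hB = sy.HillParams(100, 0, ecB, 1.0)
            d1 = np.sort(np.concatenate([[0.0], rng.uniform(0.01, 10, 5)]))
            d2 = np.sort(np.concatenate([[0.0], rng.uniform(0.01, 10, 5)]))
            ref = sy.loewe_reference(hA, hB, d1, d2)
            closed = 100.0 / (1.0 + d1[:, None] / ecA + d2[None, :] / ecB)
            worst = max(worst, float(np.abs(ref - closed).max()))
        assert worst < 1e-6

    def test_zero_dose_cell_is_untreated_plane(self):
        ref = sy.loewe_reference(HILL_A, HILL_B, DOSES, DOSES)
        assert ref[0, 0] == pytest.approx(100.0)
        np.testing.assert_allclose(ref[:, 0], sy.hill_viability(DOSES, HILL_A))
        np.testing.assert_allclose(ref[0, :], sy.hill_viability(DOSES, HILL_B))

    def test_inactive_partner_reduces_to_single_drug_curve(self):
        flat = sy.HillParams(e0=100, emax=100, ec50=1.0, slope=1.0, flat=True)
        ref = sy.loewe_reference(HILL_A, flat, DOSES, DOSES)
        np.testing.assert_allclose(ref, np.tile(
            sy.hill_viability(DOSES, HILL_A)[:, None], (1, 6)))


# ---------------------------------------------------------------------------
# Synergy maps and the full chain
# ---------------------------------------------------------------------------

class TestSynergyMap:
    def test_zero_delta_for_matching_surfaces(self):
        obs = matrix(sy.bliss_reference(HILL_A, HILL_B, DOSES, DOSES))
        res = sy.synergy_map(obs, obs.values.copy(), "BLISS")
        assert res.score == 0.0
        assert np.allclose(res.delta, 0.0)

    def test_single_cell_excess_arithmetic(self):
        ref = full_grid(50)
        observed = full_grid(50)
        observed[3, 3] = 30.0
        res = sy.synergy_map(matrix(observed), ref, "BLISS")
        assert res.delta[3, 3] == pytest.approx(20.0)
        assert res.score == pytest.approx(20.0 / 25.0)
        assert res.n_wells_used == 25

    def test_no_combination_wells_is_an_error(self):
        v = full_grid()
        v[1:, 1:] = np.nan
        with pytest.raises(ValueError):
            sy.synergy_map(matrix(v), full_grid(), "HSA")


class TestComputeAll:
    def simulated_pair(self, alpha, noise_sd=0.0, seed=0):
        from spherosynergy.study_design import desk_design

        design = desk_design(1, 1, 2)
        resp = sim.default_response_params(design, alpha)
        traj = sim.simulate_trajectories(design, responses=resp,
                                         noise_sd=noise_sd, seed=seed)
        t18 = traj[traj.day == 18]
        return sy.matrices_from_viability(t18, value_column="measured_viability_pct")

    def test_three_methods_per_complete_sample(self):
        results = sy.compute_all(self.simulated_pair(0.0))
        assert len(results) == 3
        assert {r.method for r in results} == {"LOEWE", "BLISS", "HSA"}

    def test_results_deterministic(self):
        a = sy.compute_all(self.simulated_pair(0.5))
        b = sy.compute_all(self.simulated_pair(0.5))
        assert [(r.method, r.score) for r in a] == [(r.method, r.score) for r in b]

    def test_sample_with_all_replicates_broken_is_absent(self):
        mats = self.simulated_pair(0.0)
        for m in mats[0]:
            m.values[0, 3] = np.nan  # monotherapy gap in both replicates
        assert sy.compute_all(mats) == []

    def test_sign_recovery_over_seeds(self):
        # additive truth stays within the noise band, synergistic truth
        # shows a clearly positive Bliss score
        scores = {0.0: [], 1.0: []}
        for seed in range(20):
            for alpha in scores:
                res = sy.compute_all(self.simulated_pair(alpha, noise_sd=5.0, seed=seed),
                                     methods=("BLISS",))
                scores[alpha].append(res[0].score)
        null = np.array(scores[0.0])
        syn = np.array(scores[1.0])
        sem = null.std(ddof=1) / np.sqrt(len(null))
        assert abs(null.mean()) < 2 * sem
        assert syn.mean() > 0
        assert (syn > 0).mean() >= 0.9


def test_bliss_score_at_least_hsa_score_for_same_observation():
    observed = matrix(sy.bliss_reference(HILL_A, HILL_B, DOSES, DOSES) * 0.8)
    bliss = sy.synergy_map(
        observed, sy.bliss_reference(HILL_A, HILL_B, DOSES, DOSES), "BLISS").score
    hsa = sy.synergy_map(
        observed, sy.hsa_reference(HILL_A, HILL_B, DOSES, DOSES), "HSA").score
    assert hsa >= bliss
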
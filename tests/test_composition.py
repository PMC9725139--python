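import numpy as np
import pytest

from tcsgain import SystemParams
from tcsgain.autoregulation import NegativeFeedbackParams, max_lg_F
from tcsgain.composition import (
    composed_production,
    dose_response,
    integrate_dynamics,
    lg3_at,
    lg3_profile,
    phase_diagram,
    steady_states,
)
from tcsgain.core_params import ConfigurationError

from .conftest import loglog_derivative


class TestLg3Profile:
    def test_reduces_to_autoregulation_gain(self):
        # no decoys, no phosphorylation bottleneck: LG_3 = LG_F
        p = SystemParams(f=5, h=2, D_star=0.0, Ct_star=0.0, Cp_star=1e6, R_b_star=1.0)
        grid = np.geomspace(0.01, 10.0, 60)
        prof = lg3_profile(p, grid)
        assert prof.LG_A == pytest.approx(np.ones_like(grid), abs=1e-9)
        assert prof.LG_B == pytest.approx(np.ones_like(grid), abs=1e-12)
        assert prof.LG_3 == pytest.approx(prof.LG_F, rel=1e-9)

    def test_product_identity_and_ordering(self, bistable_params):
        grid = np.geomspace(0.1, 100, 80)
        prof = lg3_profile(bistable_params, grid)
        assert prof.LG_3 == pytest.approx(prof.LG_A * prof.LG_B * prof.LG_F, abs=1e-10)
        assert np.all(prof.R_f_star <= prof.R_P_star + 1e-12)
        assert np.all(prof.R_P_star <= prof.R_T_grid + 1e-12)

    def test_max_bounded_by_autoregulation_maximum_without_decoys(self):
        p = SystemParams(f=5, h=2, D_star=0.0, Ct_star=0.0, Cp_star=1e6)
        prof = lg3_profile(p, np.geomspace(1e-3, 1e3, 200))
        bound, _ = max_lg_F(5.0, 2.0)
        assert bound == pytest.approx(2 * (np.sqrt(5) - 1) / (np.sqrt(5) + 1))
        assert prof.max_LG_3 <= bound + 1e-9

    def test_matches_composite_finite_difference(self, bistable_params):
        fba = composed_production(bistable_params)
        for rt in np.geomspace(0.5, 50, 20):
            numeric = loglog_derivative(fba, rt)
            assert lg3_at(rt, bistable_params) == pytest.approx(numeric, abs=1e-5)

    def test_bad_grid_rejected(self, default_params):
        with pytest.raises(Exception):
            lg3_profile(default_params, [3.0, 2.0, 1.0])


class TestSteadyStates:
    def test_no_feedback_single_state_at_basal(self):
        p = SystemParams(f=1.0, R_b_star=2.0, Cp_star=5.0)
        states = steady_states(p)
        assert len(states) == 1
        assert states[0].R_T_star == pytest.approx(2.0, rel=1e-8)
        assert states[0].stability == "stable"

    def test_bistable_reference_set(self, bistable_params):
        states = steady_states(bistable_params)
        assert len(states) == 3
        labels = [s.stability for s in states]
        assert labels == ["stable", "unstable", "stable"]

    def test_weak_decoy_affinity_is_monostable(self, monostable_params):
        for cp in (0.5, 5.0, 50.0, 500.0):
            states = steady_states(monostable_params, Cp_star_override=cp)
            assert len(states) == 1

    def test_counts_match_dense_scan_oracle(self, bistable_params):
        # 10^4-point sign-change scan, independent of the solver path
        fba = composed_production(bistable_params)
        grid = np.geomspace(
            0.9 * bistable_params.R_b_star,
            1.1 * bistable_params.f * bistable_params.R_b_star,
            10_000,
        )
        g = np.array([fba(x) - x for x in grid])
        crossings = int(np.sum(np.sign(g[:-1]) != np.sign(g[1:])))
        assert crossings == len(steady_states(bistable_params))

    def test_fixed_point_residual(self, bistable_params):
        fba = composed_production(bistable_params)
        for s in steady_states(bistable_params):
            assert abs(fba(s.R_T_star) - s.R_T_star) < 1e-8 * max(1.0, s.R_T_star)

    def test_unstable_implies_high_gain(self, bistable_params):
        for s in steady_states(bistable_params):
            if s.stability == "unstable":
                assert s.LG_3_at_point > 1.0
            elif s.stability == "stable":
                assert s.LG_3_at_point < 1.0

    def test_stability_labels_match_dynamics(self, bistable_params, rng):
        # perturbed time-integration oracle on random cases
        states = steady_states(bistable_params)
        for s in states:
            for _ in range(2):
                bump = 1.0 + rng.uniform(0.01, 0.03) * rng.choice([-1, 1])
                traj = integrate_dynamics(bistable_params, s.R_T_star * bump, t_end=400.0)
                final = traj[-1, 1]
                if s.stability == "stable":
                    assert final == pytest.approx(s.R_T_star, rel=1e-4)
                else:
                    assert abs(final - s.R_T_star) > 0.05 * s.R_T_star


class TestDoseResponse:
    def test_monostable_sweep(self, monostable_params):
        cps = np.geomspace(0.5, 200, 25)
        bif = dose_response(monostable_params, cps)
        assert bif.bistable_interval is None
        occ = bif.occupancy["upper_branch"]
        assert np.all(np.diff(occ[~np.isnan(occ)]) >= -1e-9)

    def test_bistable_sweep_with_hysteresis(self, bistable_params):
        cps = np.geomspace(1.0, 300, 30)
        bif = dose_response(bistable_params, cps)
        assert bif.bistable_interval is not None
        lo, hi = bif.bistable_interval
        assert lo < hi
        inside = (bif.Cp_grid >= lo) & (bif.Cp_grid <= hi)
        counts = np.array([len(s) for s in bif.states])
        assert np.all(counts[inside] == 3)
        assert np.all((counts == 1) | (counts == 3))
        # hysteresis: branch occupancies differ inside the interval
        gap = (
            bif.occupancy["upper_branch"][inside]
            - bif.occupancy["lower_branch"][inside]
        )
        assert np.all(gap > 1e-3)
        # at least the lower fold lies inside the sweep; the upper one may
        # sit beyond the grid when bistability persists at high capacity
        assert len(bif.saddle_node_points) >= 1

    def test_transcriptional_cnf_never_enlarges_bistable_interval(self, bistable_params):
        cps = np.geomspace(1.0, 300, 25)
        base = dose_response(bistable_params, cps)
        nf = NegativeFeedbackParams(f_N=0.3, K_N_star=1.0)
        coupled = dose_response(bistable_params, cps, nf=nf)

        def width(bif):
            if bif.bistable_interval is None:
                return 0.0
            return bif.bistable_interval[1] - bif.bistable_interval[0]

        assert width(coupled) <= width(base) + 1e-9

    def test_capacity_inhibition_cnf_reduces_response(self, bistable_params):
        nf = NegativeFeedbackParams(mode="capacity-inhibition", K_I_star=1.0, h_I=2.0)
        base = steady_states(bistable_params)
        coupled = steady_states(bistable_params, nf=nf)
        assert max(s.R_T_star for s in coupled) <= max(s.R_T_star for s in base) + 1e-9

    def test_bad_grid(self, default_params):
        with pytest.raises(ConfigurationError):
            dose_response(default_params, [2.0, 1.0])


class TestPhaseDiagram:
    def test_low_fold_change_all_monostable_without_decoys(self, default_params):
        p = default_params.replace(D_star=0.0)
        pd_ = phase_diagram(
            p,
            ("f", np.geomspace(1.01, 8.9, 8)),
            ("Cp_star", np.geomspace(0.1, 100, 8)),
            include_phospho=False,
        )
        assert np.all(pd_.values < 1.0)

    def test_weaker_decoy_affinity_shrinks_bistable_region(self, default_params):
        axes = (("f", np.geomspace(2, 60, 10)), ("D_star", np.geomspace(0.1, 20, 10)))
        strong = phase_diagram(
            default_params.replace(K_star=0.5), *axes, include_phospho=False
        )
        weak = phase_diagram(
            default_params.replace(K_star=2.0), *axes, include_phospho=False
        )
        assert np.sum(weak.values > 1) < np.sum(strong.values > 1)
        # pointwise the weak-affinity value never exceeds... region containment:
        assert np.all((weak.values > 1) <= (strong.values > 1))

    def test_interior_max_agrees_with_fine_local_remaximization(self, bistable_params):
        rt_scan = np.geomspace(0.1, 100, 100)
        prof = lg3_profile(bistable_params, rt_scan)
        fine = np.geomspace(
            prof.argmax_R_T_star / 1.5, prof.argmax_R_T_star * 1.5, 10_000
        )
        fine_max = max(lg3_at(float(rt), bistable_params) for rt in fine)
        assert prof.max_LG_3 == pytest.approx(fine_max, abs=1e-3)

    def test_pointwise_mode_with_ratio_annotation(self, bistable_params):
        pd_ = phase_diagram(
            bistable_params,
            ("R_T_star", np.geomspace(0.5, 50, 6)),
            ("D_star", np.geomspace(0.5, 8, 5)),
            mode="pointwise",
        )
        assert pd_.tf_tfbs_ratio is not None
        assert pd_.tf_tfbs_ratio.shape == pd_.values.shape
        i, j = 2, 3
        assert pd_.tf_tfbs_ratio[i, j] == pytest.approx(
            pd_.axis1_grid[j] / pd_.axis2_grid[i]
        )

    def test_contour_points_lie_on_level_one(self, default_params):
        p = default_params.replace(K_star=0.5, Ct_star=3.0)
        pd_ = phase_diagram(
            p,
            ("f", np.geomspace(2, 60, 12)),
            ("Cp_star", np.geomspace(0.5, 200, 12)),
        )
        assert pd_.values.max() > 1 and pd_.values.min() < 1
        assert len(pd_.contour_at_1) >= 1

    def test_bistability_implies_gain_above_one(self, bistable_params):
        # necessary-condition semantics
        prof = lg3_profile(bistable_params, np.geomspace(0.1, 100, 150))
        assert len(steady_states(bistable_params)) == 3
        assert prof.max_LG_3 > 1.0

    def test_more_decoys_promote_bistability(self, default_params):
        # direction check standing in for the wet-lab observation
        p = default_params.replace(f=5.0, K_star=0.5, R_b_star=2.5, Cp_star=50.0)
        assert len(steady_states(p.replace(D_star=0.0))) == 1
        assert len(steady_states(p.replace(D_star=4.0))) == 3
        # and a low capacity removes bistability again
        assert len(steady_states(p.replace(D_star=4.0, Cp_star=1.0))) == 1

    def test_config_errors(self, default_params):
        with pytest.raises(ConfigurationError):
            phase_diagram(default_params, ("f", [1.0]), ("Cp_star", [1.0, 2.0]))
        with pytest.raises(ConfigurationError):
            phase_diagram(
                default_params, ("nope", [1.0, 2.0]), ("Cp_star", [1.0, 2.0])
            )
        with pytest.raises(ConfigurationError):
            phase_diagram(
                default_params, ("f", [1.0, 2.0]), ("Cp_star", [1.0, 2.0]),
                mode="pointwise",
            )
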
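"""Prodrug/effector transport: kinetics, conservation, and exposure fields."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import hapsim as hs
from hapsim.transport import activation_rate, intracellular_prodrug
from hapsim.units import mol_s_cm3_to_uM_h, uM_h_to_mol_s_cm3


class TestActivationRate:
    def test_anoxic_maximum(self):
        assert activation_rate(0.0, 0.126, 0.01) == pytest.approx(0.01)

    def test_half_maximum_at_KO2(self):
        assert activation_rate(0.126, 0.126, 0.01) == pytest.approx(0.005)

    def test_direct_evaluation(self):
        # 0.01 × 0.126 / (0.126 + 1.26)
        assert activation_rate(1.26, 0.126, 0.01) == pytest.approx(
            9.0909e-4, rel=1e-4)

    @given(st.floats(0, 100), st.floats(0.2, 200))
    def test_monotone_decreasing_in_O2(self, o2, do2):
        assert activation_rate(o2 + do2, 0.126, 0.01) < \
            activation_rate(o2, 0.126, 0.01)


class TestIntracellularProdrug:
    def test_no_metabolism_equilibrates(self):
        assert intracellular_prodrug(50.0, 0.1, 0.0) == pytest.approx(50.0)

    def test_symmetric_rates_halve(self):
        assert intracellular_prodrug(50.0, 0.1, 0.1) == pytest.approx(25.0)

    def test_fast_transfer_limit(self):
        assert intracellular_prodrug(50.0, 1e6, 0.01) == pytest.approx(
            50.0, rel=1e-6)


class TestUnitAudit:
    @given(st.floats(1e-6, 1e4))
    def test_auc_conversion_round_trip(self, auc):
        assert mol_s_cm3_to_uM_h(uM_h_to_mol_s_cm3(auc)) == pytest.approx(
            auc, rel=1e-14)


class TestProdrugSolve:
    def test_no_metabolism_gives_uniform_inflow(self, krogh):
        net, dom = krogh
        o2 = hs.solve_oxygen(net, dom, hs.OxygenParameters(M0=2.5e-4,
                                                           Km_O2=1e-3))
        sol = hs.solve_prodrug(net, dom, o2,
                               hs.ProdrugParameters(kmetP_max=0.0))
        assert sol.AUCeP.active_values() == pytest.approx(50.0, rel=1e-8)
        assert sol.segment_amounts["prodrug_pmol"].abs().max() < 1e-6

    def test_linearity_in_inflow_auc(self, small_tumor_o2):
        net, dom = small_tumor_o2.network, small_tumor_o2.domain
        pp = hs.ProdrugParameters()
        sol1 = hs.solve_prodrug(net, dom, small_tumor_o2, pp)
        # doubled plasma AUC on the same geometry
        from dataclasses import replace
        net2 = hs.VesselNetwork(
            net.nodes, net.segments,
            [replace(b, auc_prodrug_uM_h=2 * b.auc_prodrug_uM_h)
             for b in net.inflow_boundaries],
            net.region_volume_mm3)
        sol2 = hs.solve_prodrug(net2, dom, small_tumor_o2, pp)
        act = dom.active_mask
        assert np.allclose(sol2.AUCeP.values[act], 2 * sol1.AUCeP.values[act],
                           rtol=1e-9)
        assert np.allclose(sol2.segment_amounts["prodrug_pmol"],
                           2 * sol1.segment_amounts["prodrug_pmol"], rtol=1e-9)

    def test_conservation_extracted_equals_metabolized(
            self, small_tumor_o2, base_prodrug_effector):
        pp, _, psol, _ = base_prodrug_effector
        # independent audit recomputed from the returned fields
        dom = psol.domain
        act = dom.active_mask
        kmet = psol.kmetP_per_s
        auci = psol.AUCiP.values[act]
        vol_cm3 = (dom.h * 1e-4) ** 3
        metabolized_pmol = float(
            np.sum(pp.phi_i * kmet * uM_h_to_mol_s_cm3(auci)) * vol_cm3) * 1e12
        extracted_pmol = -psol.segment_amounts["prodrug_pmol"].sum()
        assert extracted_pmol == pytest.approx(metabolized_pmol, rel=0.005)
        assert psol.prodrug_balance_error < 0.005

    def test_prodrug_is_pure_sink(self, base_prodrug_effector):
        _, _, psol, _ = base_prodrug_effector
        assert (psol.segment_amounts["prodrug_pmol"] <= 1e-12).all()

    def test_penetration_loss_smaller_for_low_KO2(self, small_tumor_o2):
        """Raising activation hurts hypoxic exposure less when KO2 is low."""
        net, dom = small_tumor_o2.network, small_tumor_o2.domain
        d = hs.distance_to_nearest_vessel(net, dom)
        act = dom.active_mask
        far = np.nanargmax(np.where(act, d.values, -1.0).ravel())
        far_idx = np.unravel_index(far, dom.shape)
        ratios = {}
        for ko2 in (0.126, 1.26):
            vals = []
            for km in (0.01, 1.0):
                sol = hs.solve_prodrug(net, dom, small_tumor_o2,
                                       hs.ProdrugParameters(kmetP_max=km,
                                                            KO2=ko2))
                vals.append(sol.AUCiP.values[far_idx])
            assert vals[1] < vals[0]  # more activation → less penetration
            ratios[ko2] = vals[1] / vals[0]
        assert ratios[0.126] > ratios[1.26]


class TestEffectorSolve:
    def test_no_bystander_closed_form(self, small_tumor_o2,
                                      base_prodrug_effector):
        _, _, psol, _ = base_prodrug_effector
        net, dom = small_tumor_o2.network, small_tumor_o2.domain
        esol = hs.solve_effector(net, dom, small_tumor_o2, psol,
                                 hs.EffectorParameters(ktE=0.0, kmetE=0.01))
        act = dom.active_mask
        expect = psol.kmetP_per_s / 0.01 * psol.AUCiP.values[act]
        assert np.allclose(esol.AUCiE.values[act], expect, rtol=1e-12)
        assert np.all(esol.AUCeE.values[act] == 0.0)
        assert esol.segment_amounts["effector_pmol"].abs().max() == 0.0

    def test_impermeable_vessels_balance_production_degradation(
            self, small_tumor_o2, base_prodrug_effector):
        _, _, psol, _ = base_prodrug_effector
        net, dom = small_tumor_o2.network, small_tumor_o2.domain
        esol = hs.solve_effector(net, dom, small_tumor_o2, psol,
                                 hs.EffectorParameters(vessel_permeable=False))
        assert esol.segment_amounts["effector_pmol"].abs().sum() == 0.0
        assert esol.effector_produced_pmol == pytest.approx(
            esol.effector_degraded_pmol, rel=0.005)

    def test_permeable_vessels_balance_includes_washout(
            self, base_prodrug_effector):
        _, _, _, esol = base_prodrug_effector
        washout = esol.segment_amounts["effector_pmol"].sum()
        assert esol.effector_produced_pmol == pytest.approx(
            esol.effector_degraded_pmol + washout, rel=0.005)
        assert esol.effector_balance_error < 0.005

    def test_washout_non_negative_without_effector_inflow(
            self, base_prodrug_effector):
        _, _, _, esol = base_prodrug_effector
        assert hs.net_transvascular_per_volume(esol, "effector") >= 0.0

    def test_net_transvascular_requires_solved_species(
            self, base_prodrug_effector):
        _, _, psol, _ = base_prodrug_effector
        with pytest.raises(ValueError, match="effector"):
            hs.net_transvascular_per_volume(psol, "effector")


class TestWashoutSensitivity:
    def test_ordering_of_parameter_sensitivities(self, small_tumor_o2,
                                                 base_prodrug_effector):
        """Washout responds most to production/stability, least to diffusivity."""
        net, dom = small_tumor_o2.network, small_tumor_o2.domain
        pp, ep, psol, esol = base_prodrug_effector
        base = hs.net_transvascular_per_volume(esol, "effector")

        def washout(pp_v, ep_v, cached_psol=None):
            ps = cached_psol or hs.solve_prodrug(net, dom, small_tumor_o2, pp_v)
            es = hs.solve_effector(net, dom, small_tumor_o2, ps, ep_v)
            return hs.net_transvascular_per_volume(es, "effector")

        w_kmetP = washout(hs.ProdrugParameters(kmetP_max=0.1), ep)
        w_kmetE = washout(pp, hs.EffectorParameters(kmetE=0.1), psol)
        w_ktE = washout(pp, hs.EffectorParameters(ktE=0.1), psol)
        base_de = washout(pp, hs.EffectorParameters(ktE=0.1, D_E=1e-6), psol)
        w_de = washout(pp, hs.EffectorParameters(ktE=0.1, D_E=1e-5), psol)
        assert w_kmetP > base            # more activation → more washout
        assert w_kmetE < base            # less stable effector → less washout
        rel_kmetP = w_kmetP / base
        assert abs(np.log(w_ktE / base)) < abs(np.log(rel_kmetP))
        assert abs(np.log(w_de / base_de)) < abs(np.log(rel_kmetP))
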
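"""Unit and property tests of the electrolyte-sensitive cell model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atrisim.ionic import (
    CURRENT_NAMES, CellParameters, DomainError, ElectrolyteOverrideMask,
    ElectrolyteSet, NumericalError, REFERENCE_ELECTROLYTES,
    apply_fibrosis_remodelling, derivatives, nernst_potential,
    potassium_scaling, rest_state,
)


class TestNernst:
    @pytest.mark.parametrize("valence,out,inn,expect", [
        (1, 5.4, 139.0, -86.77),     # potassium at CRN defaults
        (2, 1.8, 1e-4, 130.91),      # calcium
    ])
    def test_closed_form(self, valence, out, inn, expect):
        assert nernst_potential(valence, out, inn, 310.0) == pytest.approx(expect, abs=0.05)

    def test_equal_concentrations_zero(self):
        assert nernst_potential(1, 7.0, 7.0, 310.0) == 0.0

    @pytest.mark.parametrize("out,inn", [(0.0, 1.0), (1.0, -2.0)])
    def test_nonpositive_concentration_rejected(self, out, inn):
        with pytest.raises(DomainError):
            nernst_potential(1, out, inn)

    def test_zero_valence_rejected(self):
        with pytest.raises(DomainError):
            nernst_potential(0, 1.0, 1.0)


class TestPotassiumScaling:
    def test_identity_at_anchor(self):
        assert potassium_scaling(5.4, 5.4, 0.5) == 1.0

    def test_reference_value(self):
        assert potassium_scaling(4.5, 5.4, 0.5) == pytest.approx(0.91287, abs=1e-4)

    @settings(deadline=None, max_examples=50)
    @given(ko1=st.floats(2.0, 10.0), ko2=st.floats(2.0, 10.0))
    def test_monotone_in_ko(self, ko1, ko2):
        if ko1 < ko2:
            assert potassium_scaling(ko1) < potassium_scaling(ko2)


class TestElectrolyteSet:
    def test_reference_values(self):
        assert (REFERENCE_ELECTROLYTES.Ko, REFERENCE_ELECTROLYTES.Nao,
                REFERENCE_ELECTROLYTES.Cao) == (4.5, 140.0, 1.8)

    @pytest.mark.parametrize("kw", [
        dict(Ko=1.0, Nao=140, Cao=1.8),    # below accepted range
        dict(Ko=4.5, Nao=250, Cao=1.8),    # above accepted range
        dict(Ko=4.5, Nao=140, Cao=-1.0),   # non-positive
    ])
    def test_out_of_range_rejected(self, kw):
        with pytest.raises(DomainError):
            ElectrolyteSet(**kw)


class TestDerivatives:
    def test_zero_conductances_zero_dvdt(self):
        p = CellParameters(g_na=0, g_k1=0, g_to=0, g_kur=0, g_kr=0, g_ks=0,
                           g_cal=0, g_bca=0, g_bna=0, i_nak_max=0,
                           i_naca_max=0, i_cap_max=0)
        dy, cur = derivatives(rest_state(), p, REFERENCE_ELECTROLYTES)
        assert dy[0] == 0.0
        assert cur.total == 0.0

    def test_charge_bookkeeping(self, healthy_params):
        """dV/dt (without stimulus) equals minus the sum of the currents."""
        y = rest_state()
        y[0] = -30.0  # mid-AP voltage exercises every current
        dy, cur = derivatives(y, healthy_params, REFERENCE_ELECTROLYTES)
        total = sum(cur)
        assert abs(dy[0] + total) <= 1e-10 * max(1.0, abs(total))

    def test_mask_restricts_nao_to_inaca(self, healthy_params):
        """Changing perturbed Nao with an INaCa-only mask alters only the
        INaCa entry of the current set."""
        mask = ElectrolyteOverrideMask.only_perturbed("INaCa")
        ref = REFERENCE_ELECTROLYTES
        y = rest_state()
        y[0] = -40.0
        _, c1 = derivatives(y, healthy_params, ElectrolyteSet(4.5, 110.0, 1.8),
                            ref, mask)
        _, c2 = derivatives(y, healthy_params, ElectrolyteSet(4.5, 170.0, 1.8),
                            ref, mask)
        for name in CURRENT_NAMES:
            if name == "INaCa":
                assert getattr(c1, name) != getattr(c2, name)
            else:
                assert getattr(c1, name) == getattr(c2, name)

    def test_mask_neutrality(self, healthy_params):
        """All-perturbed mask with perturbed == reference is bitwise
        identical to the unmasked model."""
        y = rest_state()
        e = REFERENCE_ELECTROLYTES
        dy0, c0 = derivatives(y, healthy_params, e)
        dy1, c1 = derivatives(y, healthy_params, e, e, ElectrolyteOverrideMask())
        assert np.array_equal(dy0, dy1)
        assert c0 == c1

    def test_rest_attractor_near_equilibrium(self, healthy_params):
        """After a long unstimulated integration the rate of change of V is
        negligible (the rest state is an attractor)."""
        from atrisim.protocols0d import PacingSpec, record_ap
        pacing = PacingSpec(cl_ms=10_000.0, n_beats=1, stim_amp=0.0001)
        tr = record_ap(rest_state(), healthy_params, REFERENCE_ELECTROLYTES,
                       pacing, n_beats=2, out_dt=10.0)
        dy, _ = derivatives(tr.states[-1], healthy_params, REFERENCE_ELECTROLYTES)
        assert abs(dy[0]) < 0.01


class TestSerialisation:
    def test_parameter_json_round_trip(self, healthy_params):
        from atrisim.ionic import PARAMETER_UNITS
        back = CellParameters.from_json(healthy_params.to_json())
        assert back == healthy_params
        import dataclasses
        assert set(PARAMETER_UNITS) == set(
            f.name for f in dataclasses.fields(CellParameters))

    def test_nonfinite_state_raises_numerical_error(self, healthy_params):
        y = rest_state()
        y[18] = -1.0  # negative intracellular Ca -> NaN reversal potential
        with pytest.raises(NumericalError):
            derivatives(y, healthy_params, REFERENCE_ELECTROLYTES)


class TestFibrosisRemodelling:
    def test_conductance_reductions(self, healthy_params, fibrotic_params):
        assert fibrotic_params.g_na == pytest.approx(4.68)        # GNa -40 %
        assert fibrotic_params.g_k1 == pytest.approx(0.045)       # GK1 -50 %
        assert fibrotic_params.g_cal == pytest.approx(0.061875)   # GCaL -50 %
        assert fibrotic_params.g_kr == healthy_params.g_kr        # untouched
        assert fibrotic_params.fibrotic

    def test_double_application_rejected(self, fibrotic_params):
        with pytest.raises(DomainError):
            apply_fibrosis_remodelling(fibrotic_params)

    def test_fibrotic_rmp_depolarised(self, baseline_lc, fibrotic_params):
        """Paired limit-cycle runs: fibrotic RMP is less negative."""
        from atrisim.protocols0d import limit_cycle_ap
        bm_h, _, _ = baseline_lc
        bm_f, _, _ = limit_cycle_ap(fibrotic_params, REFERENCE_ELECTROLYTES,
                                    n_prepace=100)
        assert bm_f.rmp > bm_h.rmp


class TestStateInvariants:
    def test_gates_and_concentrations_stay_physical(self, baseline_lc):
        _, trace, _ = baseline_lc
        gates = trace.states[:, 1:16]
        assert np.all(gates >= 0.0) and np.all(gates <= 1.0 + 1e-12)
        assert np.all(trace.states[:, 16:] > 0.0)
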
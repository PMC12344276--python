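"""Unit tests of the single-individual DEB core."""

import dataclasses
import math

import numpy as np
import pytest

from chirosim import deb
from chirosim.deb import (DEFAULT_PARAMS, DEBParams, Stage, DeathCause,
                          advance_stage, deb_step, dump_params,
                          eggs_from_buffer, init_embryo, load_params,
                          potential_ingestion, scaled_reserve_density,
                          starvation_check)


def daily_assimilation(state, params, f):
    """Assimilated energy for one day at functional response f."""
    return (state.z * params.pAm_median * state.sM * state.V ** (2 / 3)) * f


# --------------------------------------------------------------------------
# Embryo initialisation
# --------------------------------------------------------------------------


class TestInitEmbryo:
    def test_birth_state(self, deb_params):
        st = init_embryo(deb_params, z=1.0)
        assert st.stage is Stage.LARVA
        assert st.EH == deb_params.EHb
        assert st.sM == 1.0
        assert st.Lb == pytest.approx(st.V ** (1 / 3))
        e = scaled_reserve_density(st.E, st.V, st.z, st.sM, deb_params)
        assert e == pytest.approx(1.0, rel=1e-9)

    def test_scatter_multiplier_scales_reserve_not_e(self, deb_params):
        lo = init_embryo(deb_params, z=1.0)
        hi = init_embryo(deb_params, z=1.5)
        for st in (lo, hi):
            e = scaled_reserve_density(st.E, st.V, st.z, st.sM, deb_params)
            assert e == pytest.approx(1.0, rel=1e-9)
        # [Em] scales with z, so at equal e the reserve is larger
        assert hi.E > lo.E

    def test_birth_length_matches_fine_step_oracle(self, deb_params):
        """Independent explicit integration at dt = 1e-3 d agrees < 0.5 %."""
        p = deb_params
        Em = p.pAm_median / p.v_dot
        V, EH, dt = 1.0e-9, 0.0, 1.0e-3
        denom = p.EG_vol + p.kappa * Em
        while EH < p.EHb:
            pC = Em * (p.EG_vol * p.v_dot * V ** (2 / 3)
                       + p.pM_vol * V) / denom
            V += max(0.0, p.kappa * pC - p.pM_vol * V) * dt / p.EG_vol
            EH += ((1 - p.kappa) * pC - p.kJ * EH) * dt
        st = init_embryo(p, z=1.0)
        assert st.Lb == pytest.approx(V ** (1 / 3), rel=5e-3)

    def test_inconsistent_parameters_raise(self, deb_params):
        bad = dataclasses.replace(deb_params, EHb=1.0e9, EHp=2.0e9)
        with pytest.raises(RuntimeError):
            init_embryo(bad, z=1.0)


# --------------------------------------------------------------------------
# Larval step
# --------------------------------------------------------------------------


class TestDebStep:
    def test_starving_larva_drains_reserve_keeps_structure(self, deb_params):
        st = init_embryo(deb_params, z=1.0)
        E_prev, V_prev = st.E, st.V
        for _ in range(30):
            st = deb_step(st, deb_params, assimilated=0.0)
            assert st.E < E_prev  # reserve strictly decreases
            assert st.V >= V_prev  # no shrinking, ever
            E_prev, V_prev = st.E, st.V
        assert st.E > 0.0  # exponential-type decay never reaches zero

    def test_energy_closure_each_step(self, deb_params):
        """assimilated - dE - pC dt = 0 to 1e-9 relative (reserve budget)."""
        p = deb_params
        st = init_embryo(p, z=1.0)
        for day in range(15):
            assim = daily_assimilation(st, p, f=0.8)
            V, E, EH, ER, sM, pC_dt = deb.deb_step_arrays(
                st.V, st.E, st.EH, st.ER, st.sM, st.Lb, assim, 1.0, p)
            balance = assim - (float(E) - st.E) - float(pC_dt)
            assert abs(balance) <= 1e-9 * max(assim, st.E, 1e-12)
            st = deb_step(st, p, assim)

    @pytest.mark.parametrize("f", [0.3, 0.6, 0.9])
    def test_reserve_density_converges_to_f(self, deb_params, f):
        """e* = f: the DEB equilibrium, against a fine-step oracle."""
        p = deb_params
        st = init_embryo(p, z=1.0)
        dt = 1.0 / 2000.0
        for _ in range(2000 * 4):  # 4 days of fine steps at fixed f
            assim = daily_assimilation(st, p, f) * dt
            st = deb_step(st, p, assim, dt=dt, n_substeps=1)
        e = scaled_reserve_density(st.E, st.V, st.z, st.sM, p)
        assert e == pytest.approx(f, rel=0.01)

    def test_acceleration_monotone_then_frozen(self, deb_params):
        p = deb_params
        st = init_embryo(p, z=1.0)
        sM_prev, frozen_at = st.sM, None
        for _ in range(40):
            st = deb_step(st, p, daily_assimilation(st, p, 1.0))
            assert st.sM >= sM_prev - 1e-12
            if st.EH >= p.EHp and frozen_at is None:
                frozen_at = st.sM
            sM_prev = st.sM
        assert frozen_at is not None
        assert st.sM == pytest.approx(frozen_at, rel=1e-9)
        assert st.sM >= 1.0

    def test_development_monotone_in_food(self, deb_params):
        """Time from birth to pupation is non-increasing in f."""
        days_to_pupation = []
        for f in (0.2, 0.4, 0.6, 0.8, 1.0):
            st = init_embryo(deb_params, z=1.0)
            day = 0
            while st.ER < deb_params.ER_pup:
                st = deb_step(st, deb_params,
                              daily_assimilation(st, deb_params, f))
                day += 1
                assert day < 400, "no pupation at this food level"
            days_to_pupation.append(day)
        assert days_to_pupation == sorted(days_to_pupation, reverse=True)

    def test_invalid_inputs(self, deb_params):
        st = init_embryo(deb_params, z=1.0)
        with pytest.raises(ValueError):
            deb_step(st, deb_params, assimilated=1.0, dt=-1.0)
        with pytest.raises(ValueError):
            deb_step(st, deb_params, assimilated=-1.0)


# --------------------------------------------------------------------------
# Feeding interface
# --------------------------------------------------------------------------


class TestPotentialIngestion:
    def test_zero_at_f_zero(self, deb_params):
        st = init_embryo(deb_params, z=1.0)
        assert potential_ingestion(st, deb_params, 0.0) == 0.0

    def test_surface_area_scaling(self, deb_params):
        st = init_embryo(deb_params, z=1.0)
        big = dataclasses.replace(st, V=8 * st.V)  # L doubled, sM fixed
        assert potential_ingestion(big, deb_params, 1.0) == pytest.approx(
            4 * potential_ingestion(st, deb_params, 1.0))

    def test_hourly_partition_sums_to_daily(self, deb_params):
        st = init_embryo(deb_params, z=1.0)
        f = 0.7
        hourly = potential_ingestion(st, deb_params, f)
        daily = (st.z * deb_params.pAm_median / deb_params.kappaX
                 * st.sM * st.V ** (2 / 3) * f)
        assert 24 * hourly == pytest.approx(daily, rel=1e-12)

    def test_non_larval_stages_do_not_feed(self, deb_params):
        st = init_embryo(deb_params, z=1.0)
        pupa = dataclasses.replace(st, stage=Stage.PUPA)
        assert potential_ingestion(pupa, deb_params, 1.0) == 0.0

    def test_f_out_of_range_rejected(self, deb_params):
        st = init_embryo(deb_params, z=1.0)
        with pytest.raises(ValueError):
            potential_ingestion(st, deb_params, 1.5)


# --------------------------------------------------------------------------
# Transitions, starvation, eggs
# --------------------------------------------------------------------------


class TestTransitions:
    def test_pupation_threshold_is_sharp(self, deb_params):
        st = init_embryo(deb_params, z=1.0)
        below = dataclasses.replace(st, ER=deb_params.ER_pup - 1e-9)
        out, event = advance_stage(below, deb_params)
        assert out.stage is Stage.LARVA and event is None
        at = dataclasses.replace(st, ER=deb_params.ER_pup)
        out, event = advance_stage(at, deb_params)
        assert out.stage is Stage.PUPA and event == "pupation"

    def test_emergence_event_emitted_once(self, deb_params):
        st = init_embryo(deb_params, z=1.0)
        pupa = dataclasses.replace(st, stage=Stage.PUPA,
                                   age_in_stage=deb_params.t_pupa)
        adult, event = advance_stage(pupa, deb_params)
        assert adult.stage is Stage.ADULT and event == "emergence"
        again, event2 = advance_stage(adult, deb_params)
        assert event2 is None

    def test_starvation_threshold(self, deb_params):
        st = init_embryo(deb_params, z=1.0)  # e = 1
        assert starvation_check(st, deb_params).stage is Stage.LARVA
        Em = st.z * deb_params.pAm_median / deb_params.v_dot
        hungry = dataclasses.replace(
            st, E=0.5 * deb_params.e_starv * Em * st.V)
        dead = starvation_check(hungry, deb_params)
        assert dead.stage is Stage.DEAD
        assert dead.death_cause is DeathCause.STARVATION

    def test_eggs_from_buffer(self, deb_params):
        st = init_embryo(deb_params, z=1.0)
        adult = dataclasses.replace(st, stage=Stage.ADULT, ER=0.0)
        _, n = eggs_from_buffer(adult, deb_params)
        assert n == 0
        full = dataclasses.replace(
            adult, ER=10 * deb_params.E0 / deb_params.kappaR)
        drained, n = eggs_from_buffer(full, deb_params)
        assert n == 10
        assert drained.ER == pytest.approx(0.0, abs=1e-12)


# --------------------------------------------------------------------------
# Parameter file I/O
# --------------------------------------------------------------------------


class TestParamsIO:
    def test_round_trip(self, tmp_path, deb_params):
        path = tmp_path / "params.txt"
        dump_params(deb_params, path)
        assert load_params(path) == deb_params

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        dump_params(DEFAULT_PARAMS, path)
        path.write_text(path.read_text() + "\nmystery = 3\n")
        with pytest.raises(ValueError, match="unknown parameter"):
            load_params(path)

    @pytest.mark.parametrize("field,value", [
        ("kappa", 1.2), ("kappaX", 0.0), ("EHp", 1e-9),
        ("pM_vol", -1.0), ("e_starv", 1.5),
    ])
    def test_invariants_enforced(self, field, value):
        with pytest.raises(ValueError):
            dataclasses.replace(DEFAULT_PARAMS, **{field: value})
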
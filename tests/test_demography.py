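from dataclasses import replace

import numpy as np
import pytest

from canopyresp.canopy import annual_layer_budgets, t10_series, trim_update
from canopyresp.demography import (
    Cohort,
    Patch,
    SimSettings,
    allocate_npp,
    allometry,
    cohort_fluxes,
    merge_cohorts,
    mortality_step,
    ppa_layering,
    recruit,
    step_year,
)
from canopyresp.forcing import ClimatologyParams, ForcingSeries, generate_forcing
from canopyresp.physiology import PFTParams, build_profile, gross_assimilation


def make_cohort(pft, dbh=20.0, n=50.0, trim=1.0, layer=1, storage_frac=1.0):
    _, _, target_leaf = allometry(dbh, pft, trim)
    return Cohort(
        pft=pft.name,
        dbh=dbh,
        n_per_ha=n,
        leaf_c=target_leaf,
        struct_c=pft.s1 * dbh**pft.s2,
        storage_c=storage_frac * pft.storage_target_fraction * target_leaf,
        trim=trim,
        canopy_layer=layer,
    )


class TestAllometry:
    def test_power_laws_through_origin(self, tropical_pft):
        assert allometry(0.0, tropical_pft) == (0.0, 0.0, 0.0)

    def test_trim_scales_leaf_target_only(self, tropical_pft):
        h1, ca1, leaf1 = allometry(25.0, tropical_pft, 1.0)
        h2, ca2, leaf2 = allometry(25.0, tropical_pft, 0.5)
        assert (h1, ca1) == (h2, ca2)
        assert leaf2 == pytest.approx(0.5 * leaf1)

    def test_cohort_lai_linear_in_trim(self, tropical_pft):
        p = tropical_pft
        lais = []
        for trim in (1.0, 0.75, 0.5):
            _, ca, leaf = allometry(30.0, p, trim)
            lais.append(leaf * p.sla / ca)
        assert lais[1] == pytest.approx(0.75 * lais[0])
        assert lais[2] == pytest.approx(0.5 * lais[0])

    def test_negative_dbh_rejected(self, tropical_pft):
        with pytest.raises(ValueError):
            allometry(-1.0, tropical_pft)


class TestPPALayering:
    def test_single_small_cohort_stays_in_layer_one(self, tropical_pft):
        pfts = {tropical_pft.name: tropical_pft}
        c = make_cohort(tropical_pft, dbh=30.0, n=100.0)  # 0.7 ha of crowns
        assert c.crown_area_each(tropical_pft) * c.n_per_ha < 1e4
        patch = ppa_layering(Patch([c]), pfts)
        assert len(patch.cohorts) == 1
        assert patch.cohorts[0].canopy_layer == 1

    def test_hand_computed_split(self, tropical_pft):
        """0.7 ha of tall crowns + 0.6 ha of shorter crowns on 1 ha: the
        shorter cohort splits into a 0.3-ha layer-1 slice and a 0.3-ha
        layer-2 slice."""
        p = tropical_pft
        pfts = {p.name: p}
        tall = make_cohort(p, dbh=40.0)
        short = make_cohort(p, dbh=25.0)
        area_tall, area_short = 0.7e4, 0.6e4
        tall.n_per_ha = area_tall / tall.crown_area_each(p)
        short.n_per_ha = area_short / short.crown_area_each(p)
        patch = ppa_layering(Patch([tall, short]), pfts)
        assert [c.canopy_layer for c in patch.cohorts] == [1, 1, 2]
        slice1, slice2 = patch.cohorts[1], patch.cohorts[2]
        assert slice1.dbh == slice2.dbh == 25.0
        assert slice1.crown_area_each(p) * slice1.n_per_ha == pytest.approx(0.3e4)
        assert slice2.crown_area_each(p) * slice2.n_per_ha == pytest.approx(0.3e4)
        # densities partition exactly
        assert slice1.n_per_ha + slice2.n_per_ha == pytest.approx(short.n_per_ha)

    def test_layer_one_fills_to_patch_area_exactly(self, tropical_pft):
        p = tropical_pft
        pfts = {p.name: p}
        cohorts = [make_cohort(p, dbh=d, n=80.0) for d in (45.0, 35.0, 28.0, 22.0)]
        total = sum(c.crown_area_each(p) * c.n_per_ha for c in cohorts)
        patch = ppa_layering(Patch(cohorts), pfts)
        layer1 = sum(
            c.crown_area_each(p) * c.n_per_ha
            for c in patch.cohorts
            if c.canopy_layer == 1
        )
        assert layer1 == pytest.approx(min(total, patch.area))

    def test_no_layer_beyond_three(self, tropical_pft):
        p = tropical_pft
        pfts = {p.name: p}
        cohorts = [make_cohort(p, dbh=d, n=500.0) for d in (50, 40, 30, 20, 10, 5)]
        patch = ppa_layering(Patch(cohorts), pfts)
        assert max(c.canopy_layer for c in patch.cohorts) <= 3
        for layer in (1, 2):
            area = sum(
                c.crown_area_each(p) * c.n_per_ha
                for c in patch.cohorts
                if c.canopy_layer == layer
            )
            assert area <= patch.area * (1 + 1e-9)

    def test_taller_cohorts_never_below_shorter_ones(self, tropical_pft):
        p = tropical_pft
        pfts = {p.name: p}
        cohorts = [make_cohort(p, dbh=d, n=300.0) for d in (48, 33, 26, 14)]
        patch = ppa_layering(Patch(cohorts), pfts)
        heights = {1: [], 2: [], 3: []}
        for c in patch.cohorts:
            heights[c.canopy_layer].append(c.height(p))
        if heights[2]:
            assert min(heights[1]) >= max(heights[2]) - 1e-9


class TestCohortFluxes:
    def test_leafless_cohort(self, tropical_pft):
        c = make_cohort(tropical_pft)
        c.leaf_c = 0.0
        gpp, maint = cohort_fluxes(c, tropical_pft, 1400.0, 26.0, 26.0, 2.43)
        assert gpp == 0.0
        stem = tropical_pft.stem_maint_rate * c.struct_c / 365
        assert maint == pytest.approx(stem)

    def test_per_individual_fluxes_independent_of_density(self, tropical_pft):
        a = make_cohort(tropical_pft, n=10.0)
        b = make_cohort(tropical_pft, n=20.0)
        fa = cohort_fluxes(a, tropical_pft, 1400.0, 26.0, 26.0, 2.43)
        fb = cohort_fluxes(b, tropical_pft, 1400.0, 26.0, 26.0, 2.43)
        assert fa == fb

    def test_matches_per_layer_brute_force(self, tropical_pft):
        p = tropical_pft
        c = make_cohort(p, dbh=30.0)
        gpp, maint = cohort_fluxes(
            c, p, 900.0, 27.0, 28.0, 1.944, day_length=12.0,
            cum_lai_offset=2.0, diurnal_factor=0.8,
        )
        crown = c.crown_area_each(p)
        lai = c.leaf_c * p.sla / crown
        prof = build_profile(p, 1.944, lai, 27.0, 28.0, 900.0, cum_lai_offset=2.0)
        g = r = 0.0
        for j in range(prof.n_layers):
            a = gross_assimilation(prof.vcmax25[j], prof.apar[j], 28.0, p)
            g += a * prof.layer_thickness[j]
            r += prof.rdark[j] * prof.layer_thickness[j]
        expect_gpp = g * 12.0 * 0.8 * 3600 * 12e-9 * crown
        expect_maint = r * 24 * 3600 * 12e-9 * crown + p.stem_maint_rate * c.struct_c / 365
        assert gpp == pytest.approx(expect_gpp, rel=1e-12)
        assert maint == pytest.approx(expect_maint, rel=1e-12)


class TestAllocation:
    def test_growth_respiration_is_eleven_percent_rule(self, tropical_pft):
        c = make_cohort(tropical_pft)
        before = c.leaf_c + c.struct_c + c.storage_c
        after = allocate_npp(c, 10.0, 4.0, tropical_pft)
        gained = (after.leaf_c + after.struct_c + after.storage_c) - before
        # growth_resp = 0.11·(10−4) = 0.66 → npp = 5.34 enters the pools
        assert gained == pytest.approx(5.34)

    def test_balanced_day_changes_nothing(self, tropical_pft):
        c = make_cohort(tropical_pft)
        after = allocate_npp(c, 4.0, 4.0, tropical_pft)
        assert (after.leaf_c, after.struct_c, after.storage_c) == (
            c.leaf_c, c.struct_c, c.storage_c,
        )

    def test_sustained_deficit_drains_storage_monotonically(self, tropical_pft):
        """Ten consecutive deficit days: storage falls monotonically while
        leaf and structure stay untouched (leaves are already at target)."""
        c = make_cohort(tropical_pft)
        storages = [c.storage_c]
        for _ in range(10):
            c = allocate_npp(c, 0.0, 0.05, tropical_pft)
            storages.append(c.storage_c)
        assert all(b < a for a, b in zip(storages, storages[1:]))
        ref = make_cohort(tropical_pft)
        assert c.leaf_c == ref.leaf_c
        assert c.struct_c == ref.struct_c
        # hand simulation: 10 days × 0.05 kg deficit
        assert storages[0] - storages[-1] == pytest.approx(0.5)

    def test_leaf_replacement_flushes_from_storage(self, tropical_pft):
        c = make_cohort(tropical_pft)
        c.leaf_c *= 0.5  # half the obligatory leaf load missing
        need = make_cohort(tropical_pft).leaf_c - c.leaf_c
        after = allocate_npp(c, 0.0, 0.0, tropical_pft)
        assert after.leaf_c == pytest.approx(c.leaf_c + need)
        assert after.storage_c == pytest.approx(c.storage_c - need)

    def test_surplus_grows_structure_and_dbh(self, tropical_pft):
        c = make_cohort(tropical_pft)
        after = allocate_npp(c, 5.0, 1.0, tropical_pft)
        assert after.struct_c > c.struct_c
        assert after.dbh > c.dbh

    def test_pools_never_negative(self, tropical_pft):
        c = make_cohort(tropical_pft, storage_frac=0.01)
        for _ in range(50):
            c = allocate_npp(c, 0.0, 1.0, tropical_pft)
        assert c.storage_c >= 0
        assert c.leaf_c >= 0
        assert c.struct_c >= 0


class TestMortality:
    def test_full_storage_leaves_background_rate_only(self, tropical_pft):
        c = make_cohort(tropical_pft)
        after = mortality_step(c, tropical_pft)
        expected = np.exp(-tropical_pft.background_mort_rate)
        assert after.n_per_ha == pytest.approx(c.n_per_ha * expected)
        assert after.starv_mort_rate == 0.0

    def test_empty_storage_hits_maximum_rate(self, tropical_pft):
        c = make_cohort(tropical_pft, storage_frac=0.0)
        after = mortality_step(c, tropical_pft)
        m = tropical_pft.background_mort_rate + tropical_pft.cstarv_mort_max
        assert after.n_per_ha == pytest.approx(c.n_per_ha * np.exp(-m))
        assert after.starv_mort_rate == pytest.approx(tropical_pft.cstarv_mort_max)

    def test_half_depleted_storage_reference_value(self, tropical_pft):
        p = replace(tropical_pft, background_mort_rate=0.014, cstarv_mort_max=0.2)
        c = make_cohort(p, storage_frac=0.5)
        after = mortality_step(c, p)
        # m = 0.014 + 0.2·0.5 = 0.114 → survival e^−0.114 ≈ 0.8923
        assert after.n_per_ha / c.n_per_ha == pytest.approx(0.8923, abs=1e-4)


class TestRecruitment:
    def test_zero_rate_leaves_patch_unchanged(self, tropical_pft):
        p = replace(tropical_pft, recruitment_rate=0.0)
        patch = Patch.bare_ground()
        assert recruit(patch, {p.name: p}).cohorts == []

    def test_one_cohort_per_pft(self, tropical_pft):
        patch = recruit(Patch.bare_ground(), {tropical_pft.name: tropical_pft})
        assert len(patch.cohorts) == 1
        c = patch.cohorts[0]
        assert c.dbh == 1.0
        assert c.n_per_ha == tropical_pft.recruitment_rate

    def test_repeated_calls_accumulate_cohorts(self, tropical_pft):
        patch = Patch.bare_ground()
        pfts = {tropical_pft.name: tropical_pft}
        for _ in range(300):
            patch = recruit(patch, pfts)
        assert len(patch.cohorts) == 300

    def test_npp_mode_scales_seed_rain(self, tropical_pft):
        pfts = {tropical_pft.name: tropical_pft}
        s = SimSettings(recruitment_mode="npp", npp_ref_recruitment=0.5,
                        seed_rain_floor=0.02)
        full = recruit(Patch.bare_ground(), pfts, {tropical_pft.name: 1.0}, s)
        half = recruit(Patch.bare_ground(), pfts, {tropical_pft.name: 0.25}, s)
        floor = recruit(Patch.bare_ground(), pfts, {tropical_pft.name: 0.0}, s)
        r = tropical_pft.recruitment_rate
        assert full.cohorts[0].n_per_ha == pytest.approx(r)
        assert half.cohorts[0].n_per_ha == pytest.approx(0.5 * r)
        assert floor.cohorts[0].n_per_ha == pytest.approx(0.02 * r)


class TestMerging:
    def test_merging_conserves_carbon_and_density(self, tropical_pft):
        p = tropical_pft
        a = make_cohort(p, dbh=30.0, n=10.0)
        b = make_cohort(p, dbh=29.0, n=30.0)
        b.storage_c *= 0.5
        patch = Patch([a, b], layered=True)
        before = patch.veg_carbon()
        merged = merge_cohorts(patch, {p.name: p})
        assert len(merged.cohorts) == 1
        assert merged.cohorts[0].n_per_ha == pytest.approx(40.0)
        assert merged.veg_carbon() == pytest.approx(before, rel=1e-12)

    def test_different_layers_never_merge(self, tropical_pft):
        p = tropical_pft
        a = make_cohort(p, dbh=30.0, layer=1)
        b = make_cohort(p, dbh=30.0, layer=2)
        merged = merge_cohorts(Patch([a, b], layered=True), {p.name: p})
        assert len(merged.cohorts) == 2

    def test_distant_dbh_never_merges(self, tropical_pft):
        p = tropical_pft
        a = make_cohort(p, dbh=30.0)
        b = make_cohort(p, dbh=20.0)
        merged = merge_cohorts(Patch([a, b], layered=True), {p.name: p})
        assert len(merged.cohorts) == 2


class TestStepYear:
    def test_bare_ground_without_recruitment_stays_empty(self, quiet_year, tropical_pft):
        p = replace(tropical_pft, recruitment_rate=0.0)
        patch, ledger = step_year(Patch.bare_ground(), {p.name: p}, quiet_year, 2.43)
        assert patch.cohorts == []
        assert ledger.gpp == 0.0
        assert ledger.closure_residual == pytest.approx(0.0, abs=1e-15)

    def test_sunlit_cohort_grows_in_diameter(self, quiet_year, tropical_pft):
        p = replace(tropical_pft, recruitment_rate=0.0, background_mort_rate=0.0)
        c = make_cohort(p, dbh=15.0, n=20.0)
        patch, ledger = step_year(
            ppa_layering(Patch([c]), {p.name: p}), {p.name: p}, quiet_year, 2.43
        )
        assert patch.cohorts[0].dbh > 15.0
        assert ledger.gpp > 0

    def test_annual_carbon_closure(self, noisy_forcing, tropical_pft):
        pfts = {tropical_pft.name: tropical_pft}
        patch = Patch.bare_ground()
        for y in range(3):
            patch, ledger = step_year(patch, pfts, noisy_forcing.year(y), 2.43)
            assert ledger.closure_relative < 1e-6

    def test_kernel_matches_scalar_daily_oracle(self, tropical_pft):
        """One cohort, one year: the vectorized inner loop must reproduce a
        hand-rolled daily loop over cohort_fluxes + allocate_npp + turnover,
        followed by the annual trim from layer budgets."""
        p = replace(tropical_pft, recruitment_rate=0.0, background_mort_rate=0.0,
                    stem_maint_rate=0.0)
        pfts = {p.name: p}
        forcing = generate_forcing(ClimatologyParams(seed=9), 1)
        year = forcing.year(0)
        start = make_cohort(p, dbh=18.0, n=30.0, storage_frac=0.8)

        patch, ledger = step_year(
            ppa_layering(Patch([start]), pfts), pfts, year, 2.43
        )
        got = patch.cohorts[0]

        # --- scalar oracle -------------------------------------------------
        c = make_cohort(p, dbh=18.0, n=30.0, storage_frac=0.8)
        t10 = t10_series(year.air_temp)
        for d in range(365):
            gpp, maint = cohort_fluxes(
                c, p, year.par_top[d], t10[d], year.air_temp[d], 2.43,
                day_length=year.day_length[d],
                diurnal_factor=year.diurnal_factor,
            )
            c = allocate_npp(c, gpp, maint, p)
            c.leaf_c -= c.leaf_c / (p.leaf_lifespan * 365)
        budgets = annual_layer_budgets(
            p, 2.43, c.lai(p),
            ForcingSeries(year.air_temp, year.par_top, year.day_length,
                          diurnal_factor=year.diurnal_factor),
        )
        expected_trim = trim_update(c.trim, budgets)

        assert got.dbh == pytest.approx(c.dbh, rel=1e-9)
        assert got.leaf_c == pytest.approx(c.leaf_c, rel=1e-9)
        assert got.struct_c == pytest.approx(c.struct_c, rel=1e-9)
        assert got.storage_c == pytest.approx(c.storage_c, rel=1e-9)
        assert got.trim == pytest.approx(expected_trim)

    def test_equilibrium_independent_of_cohort_ordering(self, tropical_pft):
        pfts = {tropical_pft.name: tropical_pft}
        forcing = generate_forcing(ClimatologyParams(seed=4), 5)
        p = tropical_pft
        cohorts = [make_cohort(p, dbh=d, n=30.0) for d in (35.0, 22.0, 9.0)]
        states = []
        for order in (cohorts, cohorts[::-1]):
            patch = ppa_layering(Patch([replace(c) for c in order]), pfts)
            for y in range(5):
                patch, _ = step_year(patch, pfts, forcing.year(y), 2.43)
            states.append(
                sorted((round(c.dbh, 9), round(c.n_per_ha, 9)) for c in patch.cohorts)
            )
        assert states[0] == states[1]

    def test_wrong_forcing_length_rejected(self, tropical_pft, noisy_forcing):
        with pytest.raises(ValueError):
            step_year(
                Patch.bare_ground(), {tropical_pft.name: tropical_pft},
                noisy_forcing, 2.43,
            )
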
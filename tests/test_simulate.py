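import numpy as np
import pytest

from luxpulse.errors import ConfigurationError, DomainError
from luxpulse.scenarios import (
    PromoterSpec,
    ReporterSpec,
    RnapParams,
    Spo0AParams,
    bundled_scenario,
)
from luxpulse.simulate import (
    allocate_rnap,
    arrest_trajectory,
    promoter_activity,
    render_plate_run,
    simulate_arrest,
    simulate_diauxic_growth,
    simulate_reporter,
    simulate_spo0A_response,
)
from luxpulse.events import detect_pauses


class TestAllocateRnap:
    def test_no_growth_frees_all_polymerase(self):
        params = RnapParams(f_max=0.8, K_mu=0.2, R_total=3.0)
        f, r = allocate_rnap(0.0, params)
        assert f == 0.0 and r == 3.0

    def test_direct_formula(self):
        f, r = allocate_rnap(2.0, RnapParams(f_max=0.8, K_mu=0.2))
        assert f == pytest.approx(0.8 * 2.0 / 2.2)
        assert r == pytest.approx(1.0 - 0.8 * 2.0 / 2.2)

    def test_monotone_on_grid(self):
        # brute-force oracle: f_rrn strictly increasing, R_free strictly
        # decreasing over an exhaustive growth-rate grid
        mu = np.arange(0.0, 3.0 + 1e-9, 0.01)
        f, r = allocate_rnap(mu, RnapParams(f_max=0.9, K_mu=0.4))
        assert np.all(np.diff(f) > 0)
        assert np.all(np.diff(r) < 0)

    def test_negative_mu_rejected(self):
        with pytest.raises(DomainError):
            allocate_rnap(-0.1, RnapParams(f_max=0.5, K_mu=0.5))


class TestPromoterActivity:
    def test_activated_silent_without_spo0a_p(self):
        spec = PromoterSpec(name="spoIIG", kind="activated", strength=5.0,
                            regulator_K=0.5, hill_n=2.0)
        assert promoter_activity(spec, 0.2, 0.8, 1.0, 0.0) == 0.0

    def test_constitutive_needs_polymerase(self):
        spec = PromoterSpec(name="core", kind="constitutive", strength=1.0, K_R=0.5)
        assert promoter_activity(spec, 0.0, 0.0) == 0.0

    def test_hill_midpoint_halves_repressed_promoter(self):
        base = PromoterSpec(name="c", kind="constitutive", strength=2.0, K_R=0.5)
        rep = PromoterSpec(name="abrB", kind="repressed", strength=2.0, K_R=0.5,
                           regulator_K=0.3, hill_n=1.0)
        free = promoter_activity(base, 0.1, 0.6)
        assert promoter_activity(rep, 0.1, 0.6, 1.0, 0.3) == pytest.approx(free / 2)

    def test_initiating_nucleotide_sensitivity(self):
        # a GTP-pool dip leaves an A-initiating promoter alone but reduces
        # its G-initiating twin
        a_spec = PromoterSpec(name="pa", kind="constitutive", strength=1.0,
                              K_R=0.5, initiating_nucleotide="A")
        g_spec = PromoterSpec(name="pg", kind="constitutive", strength=1.0,
                              K_R=0.5, initiating_nucleotide="G", intp_K=0.5)
        full_a = promoter_activity(a_spec, 0.2, 0.7, 1.0)
        full_g = promoter_activity(g_spec, 0.2, 0.7, 1.0)
        assert full_g == pytest.approx(full_a)  # normalized at a full pool
        dipped_a = promoter_activity(a_spec, 0.2, 0.7, 0.5)
        dipped_g = promoter_activity(g_spec, 0.2, 0.7, 0.5)
        assert dipped_a == pytest.approx(full_a)
        assert dipped_g < full_g

    def test_gtp_factor_domain(self):
        spec = PromoterSpec(name="p", kind="constitutive", strength=1.0)
        with pytest.raises(DomainError):
            promoter_activity(spec, 0.1, 0.5, 1.5)


class TestDiauxicGrowth:
    def test_mass_balance(self, dsm_traj, diauxie_trajs):
        assert dsm_traj.mass_balance_error < 1e-6
        for traj in diauxie_trajs.values():
            assert traj.mass_balance_error < 1e-6

    def test_no_substrate_means_no_growth(self):
        sc = bundled_scenario("diauxie_low_glucose")
        subs = tuple(s.__class__(s.name, 0.0, s.mu_max, s.K_s, s.yield_od)
                     for s in sc.medium.substrates)
        sc0 = sc.with_(medium=sc.medium.__class__(
            substrates=subs, repression_order=sc.medium.repression_order))
        traj = simulate_diauxic_growth(sc0)
        assert np.all(traj.biomass == sc0.initial_biomass)
        assert np.all(traj.mu == 0.0)

    def test_single_substrate_run_has_no_pause(self, diauxie_trajs):
        traj = diauxie_trajs["diauxie_glucose_only"]
        assert detect_pauses(traj.time, traj.mu) == []

    def test_pause_shifts_later_with_more_glucose(self, diauxie_trajs):
        low = detect_pauses(*(lambda t: (t.time, t.mu))(
            diauxie_trajs["diauxie_low_glucose"]))
        mid = detect_pauses(*(lambda t: (t.time, t.mu))(
            diauxie_trajs["diauxie_mid_glucose"]))
        assert len(low) == 1 and len(mid) == 1
        assert mid[0].time > low[0].time

    def test_pause_sits_at_glucose_exhaustion(self, diauxie_trajs):
        traj = diauxie_trajs["diauxie_low_glucose"]
        pauses = detect_pauses(traj.time, traj.mu)
        glc = traj.substrates["glucose"]
        t_cross = traj.time[glc < 0.01 * glc[0]][0]
        assert abs(pauses[0].time - t_cross) <= 2 * 0.025 + 1e-9

    def test_biomass_nondecreasing_and_substrates_nonincreasing(self, dsm_traj):
        assert np.all(np.diff(dsm_traj.biomass) >= -1e-9)
        for s in dsm_traj.substrates.values():
            assert np.all(np.diff(s) <= 1e-9)

    def test_f_rrn_bounded(self, dsm_traj, dsm_scenario):
        assert np.all(dsm_traj.f_rrn >= 0)
        assert np.all(dsm_traj.f_rrn <= dsm_scenario.rnap.f_max + 1e-12)


class TestReporter:
    def test_nothing_expressed_nothing_emitted(self):
        t = np.arange(0, 2, 0.025)
        _, light = simulate_reporter(t, np.zeros_like(t), np.ones_like(t),
                                     ReporterSpec())
        assert np.all(light == 0.0)

    def test_constant_activity_closed_form(self):
        # l(t) = (a/delta)(1 - exp(-delta t)) for constant input
        rep = ReporterSpec(half_life=0.1, light_coeff=1.0)
        t = np.arange(0, 1.0, 0.025)
        a = 3.0
        per_cell, _ = simulate_reporter(t, np.full_like(t, a), np.ones_like(t), rep)
        check = np.linspace(1, len(t) - 1, 10, dtype=int)
        expected = (a / rep.delta) * (1 - np.exp(-rep.delta * t[check]))
        assert np.max(np.abs(per_cell[check] - expected)) < 1e-8

    def test_light_halves_every_half_life_after_shutoff(self):
        rep = ReporterSpec(half_life=0.1, light_coeff=1.0)
        t = np.arange(0, 3, 0.025)
        a = np.where(t < 1.0, 5.0, 0.0)
        _, light = simulate_reporter(t, a, np.ones_like(t), rep)
        i0 = np.searchsorted(t, 1.5)  # past the step transient
        for k in (1, 2, 3):
            i = np.searchsorted(t, 1.5 + k * rep.half_life)
            assert light[i] / light[i0] == pytest.approx(0.5**k, rel=0.01)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(DomainError):
            simulate_reporter(np.arange(5.0), np.arange(4.0), np.arange(5.0),
                              ReporterSpec())


class TestSpo0AResponse:
    def test_zero_activity_means_zero_phosphoform(self):
        t = np.arange(0, 5, 0.025)
        protein, sp = simulate_spo0A_response(t, np.zeros_like(t), Spo0AParams())
        assert np.all(protein == 0.0) and np.all(sp == 0.0)

    def test_growth_bursts_followed_by_spo0a_p_peaks(self, dsm_traj):
        from scipy.signal import find_peaks

        t = dsm_traj.time
        bursts, _ = find_peaks(dsm_traj.activity["spo0A"], prominence=0.05)
        burst_times = t[bursts][:2]  # the two growth-phase bursts
        sp_peaks, _ = find_peaks(dsm_traj.spo0a_p, prominence=0.005)
        sp_times = t[sp_peaks]
        for bt in burst_times:
            lags = sp_times[sp_times > bt] - bt
            assert lags.size and lags[0] > 0 and lags[0] < 0.6

    def test_abrb_dips_when_spo0a_p_exceeds_its_affinity(self, dsm_traj,
                                                         dsm_scenario):
        abrb = dsm_scenario.promoter("abrB")
        unrepressed = promoter_activity(
            PromoterSpec(name="u", kind="constitutive", strength=abrb.strength,
                         K_R=abrb.K_R),
            dsm_traj.f_rrn, dsm_traj.R_free)
        high = dsm_traj.spo0a_p > abrb.regulator_K
        assert high.any()
        ratio = dsm_traj.activity["abrB"][high] / unrepressed[high]
        assert np.all(ratio < 0.5)


class TestPlateRendering:
    def test_noiseless_rendering_is_exact(self, dsm_traj, dsm_scenario):
        sc = dsm_scenario.with_(noise_cv=0.0)
        run = render_plate_run(dsm_traj, sc, n_replicate_wells=1, seed=0)
        t, od = run.series("spo0A.1", "OD600")
        assert np.array_equal(od, sc.od_background + dsm_traj.biomass)
        _, rlu = run.series("spo0A.1", "RLU")
        assert np.array_equal(rlu, dsm_traj.light["spo0A"])

    def test_same_seed_is_bit_identical(self, dsm_traj, dsm_scenario):
        a = render_plate_run(dsm_traj, dsm_scenario, seed=7)
        b = render_plate_run(dsm_traj, dsm_scenario, seed=7)
        assert a.data.equals(b.data)

    def test_noise_cv_matches_generating_law(self, dsm_traj, dsm_scenario):
        run = render_plate_run(dsm_traj, dsm_scenario, n_replicate_wells=10,
                               seed=3)
        df = run.data
        rlu = df[(df.channel == "RLU")
                 & df.well.str.startswith("spo0A")]
        wide = rlu.pivot(index="time_h", columns="well", values="value")
        late = wide[wide.index > 2.0]  # strong signal, noise dominated by CV
        cv = (late.std(axis=1) / late.mean(axis=1)).median()
        assert 0.01 <= cv <= 0.03

    def test_well_count_validation(self, dsm_traj, dsm_scenario):
        with pytest.raises(DomainError):
            render_plate_run(dsm_traj, dsm_scenario, n_replicate_wells=0)


class TestArrest:
    def test_post_arrest_decay_is_pure_exponential(self):
        sc = bundled_scenario("arrest").with_(noise_cv=0.0)
        traj = arrest_trajectory(sc, 1.0)
        t = traj.time
        mask = t >= 1.1
        log_l = np.log(traj.light["spo0A_core"][mask])
        slope = np.polyfit(t[mask], log_l, 1)[0]
        assert slope == pytest.approx(-sc.reporter.delta, rel=1e-6)
        assert np.all(np.diff(traj.biomass[t >= 1.0]) == 0.0)

    def test_arrest_at_time_zero_is_dark(self):
        sc = bundled_scenario("arrest").with_(noise_cv=0.0)
        traj = arrest_trajectory(sc, 0.0)
        assert np.all(traj.light["spo0A_core"] == 0.0)

    def test_arrest_outside_run_rejected(self):
        sc = bundled_scenario("arrest")
        with pytest.raises(DomainError):
            simulate_arrest(sc, 99.0)

    def test_arrest_metadata_records_time(self):
        sc = bundled_scenario("arrest")
        run = simulate_arrest(sc, 1.0, seed=2)
        assert run.metadata["t_arrest_h"] == 1.0
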
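import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from luxpulse.errors import ConfigurationError, DataError, DomainError
from luxpulse.response import (
    CountData,
    ThresholdPromoter,
    TransitionModel,
    event_frequency,
    fold_change,
    molarity_from_mass_conc,
    simulate_transitions,
    sporulation_frequency,
    target_response,
)


class TestTargetResponse:
    def test_no_spo0a_p(self):
        rep = ThresholdPromoter("abrB", "repressed", K=0.1, hill_n=2)
        act = ThresholdPromoter("spoIIG", "activated", K=0.5, hill_n=2)
        assert target_response(0.0, rep) == 1.0
        assert target_response(0.0, act) == 0.0

    def test_hill_midpoint(self):
        rep = ThresholdPromoter("abrB", "repressed", K=0.3, hill_n=1)
        act = ThresholdPromoter("spoIIG", "activated", K=0.3, hill_n=1)
        assert target_response(0.3, rep) == pytest.approx(0.5)
        assert target_response(0.3, act) == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(k_lo=st.floats(0.01, 0.3), ratio=st.floats(1.5, 20.0),
           n=st.floats(1.0, 4.0))
    def test_affinity_hierarchy_on_rising_ramp(self, k_lo, ratio, n):
        # high-affinity repression (abrB-like) responds before low-affinity
        # activation (spoIIG-like) on any monotone ramp of Spo0A~P
        k_hi = k_lo * ratio
        sp = np.linspace(0.0, 2.0 * k_hi, 500)
        rep = target_response(sp, ThresholdPromoter("hi", "repressed",
                                                    K=k_lo, hill_n=n))
        act = target_response(sp, ThresholdPromoter("lo", "activated",
                                                    K=k_hi, hill_n=n))
        t_rep = sp[np.argmax(rep < 0.5)]
        t_act = sp[np.argmax(act > 0.5)]
        assert t_rep < t_act

    def test_mode_validation(self):
        with pytest.raises(ConfigurationError):
            ThresholdPromoter("x", "sideways", K=0.1)


class TestTransitions:
    def test_zero_hazard_means_no_transitions(self):
        t = np.arange(0, 5, 0.025)
        model = TransitionModel(lambda0=0.0)
        times, counts = simulate_transitions(t, np.ones_like(t), model,
                                             n_cells=100, seed=0)
        assert np.all(np.isnan(times))
        assert np.all(counts == 0)

    def test_constant_hazard_matches_survival_law(self):
        # closed-form oracle: fraction transitioned by T is 1 - exp(-lam T)
        t = np.arange(0, 4, 0.025)
        lam = 0.3
        model = TransitionModel(lambda0=lam, m=1.0, K_c=1.0)
        n = 10_000
        _, counts = simulate_transitions(t, np.ones_like(t), model,
                                         n_cells=n, seed=42,
                                         query_times=[4.0 - 0.025])
        expected = 1 - np.exp(-lam * (4.0 - 0.025))
        sd = np.sqrt(n * expected * (1 - expected))
        assert abs(counts[0] - n * expected) < 3 * sd

    def test_mean_over_seeds_matches_inhomogeneous_integral(self):
        # piecewise-constant hazard; oracle = survival integral
        t = np.arange(0, 3, 0.025)
        act = np.where(t < 1.5, 0.5, 2.0)
        model = TransitionModel(lambda0=0.2, m=2.0, K_c=1.0)
        haz = model.hazard(act)
        cum = np.trapezoid(haz, t)
        expected = 1 - np.exp(-cum)
        n = 2000
        fracs = [simulate_transitions(t, act, model, n_cells=n, seed=s,
                                      query_times=[t[-1]])[1][0] / n
                 for s in range(50)]
        se = np.sqrt(expected * (1 - expected) / n) / np.sqrt(50)
        assert abs(np.mean(fracs) - expected) < 3 * se

    def test_determinism_and_validation(self):
        t = np.arange(0, 2, 0.025)
        model = TransitionModel(lambda0=0.5)
        a = simulate_transitions(t, np.ones_like(t), model, 500, seed=9)[0]
        b = simulate_transitions(t, np.ones_like(t), model, 500, seed=9)[0]
        np.testing.assert_array_equal(a, b)
        with pytest.raises(DomainError):
            simulate_transitions(t, np.ones_like(t), model, 0, seed=1)

    def test_bundled_scenario_fraction_rises_after_bursts(self, dsm_traj):
        # sampling before the first burst vs after the second: the
        # transitioned fraction must strictly increase and stay rare
        t = dsm_traj.time
        act = np.maximum(dsm_traj.activity["comK"], 0.0)
        model = TransitionModel(lambda0=0.001, m=3.0, K_c=0.5)
        for seed in range(1, 6):
            _, counts = simulate_transitions(t, act, model, n_cells=20_000,
                                             seed=seed,
                                             query_times=[0.65, 3.4])
            early, late = counts
            assert late > early
            assert late / 20_000 < 0.01 and early / 20_000 < 0.01


class TestFrequencies:
    def test_comk_positive_cells_worked_example(self):
        res = event_frequency(30, 23_000)
        assert float(f"{res.frequency_pct:.2g}") == 0.13
        assert res.ci_low_pct < res.frequency_pct < res.ci_high_pct

    def test_rare_single_positive(self):
        res = event_frequency(1, 15_000)
        assert res.frequency_pct == pytest.approx(0.00667, rel=1e-2)
        assert res.frequency_pct < 0.01  # below 10^-2 percent

    def test_zero_positives_rule_of_three(self):
        res = event_frequency(0, 30_000)
        assert res.frequency_pct == 0.0
        assert res.ci_low_pct == 0.0
        # one-sided exact upper bound approximates 3/n
        assert res.ci_high_pct == pytest.approx(100 * 3 / 30_000, rel=0.01)

    def test_interval_contains_point_estimate(self):
        for k, n in [(0, 50), (1, 50), (25, 50), (50, 50)]:
            res = event_frequency(k, n)
            assert res.ci_low_pct <= res.frequency_pct <= res.ci_high_pct

    def test_exact_interval_coverage(self, rng):
        # nominal 95% interval must cover the truth in >= 93% of draws
        p, n, reps = 0.005, 2000, 1000
        ks = rng.binomial(n, p, size=reps)
        alpha = 0.05
        low = np.where(ks == 0, 0.0, stats.beta.ppf(alpha / 2, ks, n - ks + 1))
        high = np.where(ks == n, 1.0,
                        np.where(ks == 0, 1 - alpha ** (1 / n),
                                 stats.beta.ppf(1 - alpha / 2, ks + 1, n - ks)))
        coverage = np.mean((low <= p) & (p <= high))
        assert coverage >= 0.93
        # spot-check agreement with event_frequency on one draw
        res = event_frequency(int(ks[0]), n)
        assert res.ci_high_pct == pytest.approx(100 * high[0], rel=1e-9)

    def test_invalid_counts(self):
        with pytest.raises(DataError):
            event_frequency(5, 3)
        with pytest.raises(DataError):
            CountData(positives=-1, total=10)


class TestSporulation:
    def test_wild_type_table_row(self):
        freq = sporulation_frequency(0.16e8, 0.78e8)
        assert freq == pytest.approx(20.5, abs=0.1)

    def test_codY_table_row(self):
        freq = sporulation_frequency(7.1e6, 3.3e8)
        assert freq == pytest.approx(2.15, abs=0.05)

    def test_no_spores(self):
        assert sporulation_frequency(0.0, 0.4e7) == 0.0

    def test_count_inversion_warns(self):
        with pytest.warns(UserWarning, match="inversion"):
            sporulation_frequency(2.0, 1.0)

    def test_fold_change(self):
        wt = sporulation_frequency(0.16e8, 0.78e8)
        cody = sporulation_frequency(7.1e6, 3.3e8)
        assert fold_change(wt, cody) == pytest.approx(9.5, abs=0.2)
        assert fold_change(1.0, 1.0) == 1.0
        assert fold_change(0.0, 5.0) == 0.0
        with pytest.warns(UserWarning, match="infinite"):
            assert fold_change(5.0, 0.0) == float("inf")


class TestMolarity:
    def test_luciferin_working_concentration(self):
        assert molarity_from_mass_conc(1.5, 318.42) == pytest.approx(4.71, abs=0.01)

    def test_unit_identity_and_linearity(self):
        assert molarity_from_mass_conc(0.5, 500.0) == pytest.approx(1.0)
        assert molarity_from_mass_conc(3.0, 318.42) == \
            pytest.approx(2 * molarity_from_mass_conc(1.5, 318.42))

    def test_domain(self):
        with pytest.raises(DomainError):
            molarity_from_mass_conc(0.0, 100.0)


class TestCountTables:
    def test_bundled_table_frequencies(self):
        from luxpulse.response import bundled_spore_counts

        df = bundled_spore_counts()
        wt = df.loc[df.label == "wild_type", "freq_48h_pct"].item()
        cody = df.loc[df.label == "codY", "freq_48h_pct"].item()
        assert wt == pytest.approx(20.5, abs=0.1)
        assert cody == pytest.approx(2.2, abs=0.1)
        assert (df.loc[df.label == "sigH", "freq_48h_pct"] == 0).all()

    def test_positives_layout_round_trip(self, tmp_path):
        from luxpulse.response import read_count_table

        path = tmp_path / "counts.csv"
        path.write_text("label,positives,total\nearly,1,15000\nlate,30,23000\n")
        df = read_count_table(path)
        row = df[df.label == "late"].iloc[0]
        res = event_frequency(int(row.positives), int(row.total))
        assert float(f"{res.frequency_pct:.2g}") == 0.13

    def test_unknown_layout_rejected(self, tmp_path):
        from luxpulse.response import read_count_table

        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(DataError):
            read_count_table(path)
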
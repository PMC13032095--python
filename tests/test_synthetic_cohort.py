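import dataclasses

import numpy as np
import pandas as pd
import pytest

import painsig as ps
from painsig.exceptions import ConfigurationError, UnsupportedConditionError
from painsig.stats_core import spearman
from painsig.synthetic_cohort import DOMAINS, FACETS, PROTOTYPES

from conftest import tiny_config, zero_noise_config


class TestTraits:
    def test_determinism_and_growth_stability(self):
        cfg = tiny_config(n=5, seed=7)
        t1 = ps.traits_table(ps.sample_traits(cfg))
        t2 = ps.traits_table(ps.sample_traits(cfg))
        pd.testing.assert_frame_equal(t1, t2)
        # enlarging the cohort must not reshuffle earlier participants
        bigger = ps.traits_table(ps.sample_traits(tiny_config(n=9, seed=7)))
        pd.testing.assert_frame_equal(t1, bigger.iloc[:5].reset_index(drop=True))

    def test_domain_is_sum_of_facets_and_attachment_in_range(self):
        profiles = ps.sample_traits(tiny_config(n=40, seed=1))
        for p in profiles:
            for d in DOMAINS:
                facet_sum = sum(p.facets[f"{d}{k}"] for k in range(1, 7))
                assert p.domains[d] == pytest.approx(facet_sum)
            for proto in PROTOTYPES:
                assert 1 <= p.attachment[proto] <= 7

    def test_zero_loadings_give_null_attachment_correlation(self):
        n = 4000
        cfg = tiny_config(
            n=n, seed=11,
            attachment_loadings={p: {} for p in PROTOTYPES},
            beta_C5_secure=0.0,
        )
        df = ps.traits_table(ps.sample_traits(cfg))
        rho, _ = spearman(df["secure"], df["N"])
        assert abs(rho) < 3 / np.sqrt(n)

    def test_calibrated_secure_neuroticism_correlation(self):
        # loadings are calibrated to a population rho(secure, N) of -0.30
        df = ps.traits_table(ps.sample_traits(tiny_config(n=5000, seed=23)))
        rho, _ = spearman(df["secure"], df["N"])
        assert rho == pytest.approx(-0.30, abs=0.04)

    def test_non_positive_definite_loadings_rejected(self):
        cfg = tiny_config(
            attachment_loadings={"secure": {"N": 0.9, "E": 0.9}},
        )
        with pytest.raises(ConfigurationError, match="secure"):
            ps.sample_traits(cfg)

    def test_within_domain_correlation_structure(self):
        df = ps.traits_table(ps.sample_traits(tiny_config(n=4000, seed=3)))
        same = np.corrcoef(df["N1"], df["N2"])[0, 1]
        cross = np.corrcoef(df["N1"], df["E1"])[0, 1]
        assert same == pytest.approx(0.4, abs=0.05)
        assert abs(cross) < 0.05


class TestTraces:
    def test_constant_plateau_when_deterministic(self, protocol):
        cfg = zero_noise_config(sensitization_slope_base={
            36.0: 0.0, 44.0: 0.0, 46.0: 0.0, 48.0: 0.0})
        prof = ps.sample_traits(cfg)[0]
        trace = ps.simulate_vas_trace(prof, protocol, cfg, stimulus_index=2)  # 44 degC
        assert np.allclose(trace.vas_values, cfg.plateau_mean[44.0])

    def test_zero_noise_linear_slope_gives_tai_20s(self, protocol):
        cfg = zero_noise_config()
        prof = ps.sample_traits(cfg)[0]
        s = cfg.sensitization_slope_base[48.0]
        trace = ps.simulate_vas_trace(prof, protocol, cfg, stimulus_index=3)  # 48 degC
        em = ps.epoch_means(trace, protocol)
        assert em.mean_c - em.mean_a == pytest.approx(20.0 * s, abs=1e-12)

    def test_trace_identical_alone_or_in_cohort(self, protocol):
        cfg = tiny_config(n=3, seed=9)
        profs = ps.sample_traits(cfg)
        cohort = ps.simulate_cohort_traces(profs, protocol, cfg)
        solo = ps.simulate_vas_trace(profs[1], protocol, cfg, stimulus_index=7)
        match = [t for t in cohort
                 if t.participant_id == profs[1].participant_id and t.stimulus_index == 7]
        assert np.array_equal(solo.vas_values, match[0].vas_values)

    def test_clamping_and_range(self, small_cohort):
        _, _, traces, _ = small_cohort
        for tr in traces:
            assert tr.vas_values.min() >= 0.0
            assert tr.vas_values.max() <= 100.0

    def test_unsupported_temperature_errors(self):
        cfg = tiny_config(n=1)
        proto = ps.StimulusProtocol(sequence=(36, 50))
        prof = ps.sample_traits(cfg)[0]
        with pytest.raises(UnsupportedConditionError):
            ps.simulate_vas_trace(prof, proto, cfg, stimulus_index=2)

    def test_contrast_coupling_detectable_in_cohort(self):
        # positive N6 -> contrast coupling must surface as a positive
        # Spearman correlation well beyond Monte Carlo error (brute-force
        # check over a large simulated cohort)
        cfg = tiny_config(
            n=2000, seed=17, n_discrepant=0,
            beta_N6_contrast=5.0, beta_secure_contrast=0.0, beta_C5_secure=0.0,
        )
        traits, prof = ps.simulate_indexes(cfg)
        df = traits.merge(prof, on="participant_id")
        rho, p = spearman(df["N6"], df["contrast_magnitude"])
        assert rho > 3 / np.sqrt(len(df))
        assert p < 1e-6

    def test_contrast_shift_sign_convention(self, protocol):
        # low-contrast trials (after 36) shift up, high-contrast (after 48) down
        cfg = zero_noise_config(gamma0=10.0)
        prof = ps.sample_traits(cfg)[0]
        low = ps.simulate_vas_trace(prof, protocol, cfg, 16)
        high = ps.simulate_vas_trace(prof, protocol, cfg, 4)
        neutral = ps.simulate_vas_trace(prof, protocol, cfg, 5)  # 46 after 46
        assert low.vas_values[0] == pytest.approx(neutral.vas_values[0] + 5.0)
        assert high.vas_values[0] == pytest.approx(max(neutral.vas_values[0] - 5.0, 0.0))


class TestNRS:
    def test_exact_reports_without_noise(self, protocol):
        cfg = zero_noise_config(n=4)
        profs, traces, nrs = ps.simulate_cohort(cfg, protocol)
        by_pid = {}
        for t in traces:
            if t.target_temp_c == 46.0:
                by_pid.setdefault(t.participant_id, []).append(t.vas_values.mean())
        for _, row in nrs.iterrows():
            assert row["nrs"] == pytest.approx(
                np.mean(by_pid[row["participant_id"]]) / 10.0, abs=1e-12)

    def test_planted_discrepants_trip_filter(self, protocol):
        cfg = tiny_config(n=30, seed=5, n_discrepant=3)
        profs, traces, nrs = ps.simulate_cohort(cfg, protocol)
        epoch, _ = ps.epoch_means_table(traces, protocol)
        report = ps.exclusion_filter(ps.build_profiles(epoch, protocol), nrs)
        excluded = {e["participant_id"] for e in report.excluded}
        planted = set(nrs[nrs["planted_discrepant"]]["participant_id"])
        assert excluded == planted
        assert len(excluded) == 3

    def test_too_many_discrepants_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(n=3, n_discrepant=4).validate()

    def test_all_discrepant_empties_cohort(self, protocol):
        from painsig.exceptions import EmptyCohortError

        cfg = tiny_config(n=4, seed=2, n_discrepant=4)
        profs, traces, nrs = ps.simulate_cohort(cfg, protocol)
        with pytest.raises(EmptyCohortError):
            ps.analyze_cohort(traces, ps.traits_table(profs), nrs,
                              protocol=protocol, preprocess_window_s=None)


def test_config_validation_errors():
    with pytest.raises(ConfigurationError):
        ps.GeneratorConfig(n_participants=0).validate()
    with pytest.raises(ConfigurationError):
        ps.GeneratorConfig(noise_ar_coef=1.0).validate()
    with pytest.raises(ConfigurationError):
        ps.GeneratorConfig(trait_sd=-1.0).validate()
    with pytest.raises(ConfigurationError):
        # non-monotone plateau means
        ps.GeneratorConfig(plateau_mean={36.0: 5.0, 44.0: 1.0, 46.0: 6.0, 48.0: 7.0},
                           sensitization_slope_base={36.0: 0, 44.0: 0, 46.0: 0, 48.0: 0}
                           ).validate()


def test_written_tables_roundtrip(tmp_path, small_cohort, protocol):
    cfg, profiles, traces, nrs = small_cohort
    ps.write_traces(traces, tmp_path / "traces.csv")
    back = ps.read_traces(tmp_path / "traces.csv", protocol)
    assert len(back) == len(traces)
    key = lambda t: (t.participant_id, t.stimulus_index)
    for a, b in zip(sorted(traces, key=key), sorted(back, key=key)):
        assert np.allclose(a.vas_values, b.vas_values)
        assert np.allclose(a.sample_times_s, b.sample_times_s)
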
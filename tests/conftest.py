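import numpy as np
import pytest

import painsig as ps


@pytest.fixture(scope="session")
def protocol():
    return ps.StimulusProtocol()


def tiny_config(n=6, seed=42, **kw):
    """Small, fast cohort configuration used across tests (10 Hz traces)."""
    defaults = dict(
        n_participants=n, seed=seed, sample_rate_hz=10.0, n_discrepant=1
    )
    defaults.update(kw)
    return ps.GeneratorConfig(**defaults)


def zero_noise_config(n=3, seed=0, **kw):
    """Deterministic generator: no noise, no heterogeneity, no couplings."""
    defaults = dict(
        n_participants=n,
        seed=seed,
        sample_rate_hz=10.0,
        noise_sd_white=0.0,
        noise_sd_ar=0.0,
        subject_offset_sd=0.0,
        slope_heterogeneity=0.0,
        contrast_sd_between=0.0,
        beta_N6_tai=0.0,
        beta_C5_tai=0.0,
        beta_N6_contrast=0.0,
        beta_secure_contrast=0.0,
        beta_C5_secure=0.0,
        gamma0=0.0,
        n_discrepant=0,
        nrs_consistency_sd=0.0,
    )
    defaults.update(kw)
    return ps.GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort(protocol):
    cfg = tiny_config()
    profiles, traces, nrs = ps.simulate_cohort(cfg, protocol)
    return cfg, profiles, traces, nrs


def make_trace(values, times=None, pid="P0000", stimulus_index=2, temp=44.0):
    """Hand-built trace helper (defaults to a 44 degC stimulus slot)."""
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.linspace(0.0, 30.0, values.size)
    return ps.VASTrace(
        participant_id=pid,
        stimulus_index=stimulus_index,
        target_temp_c=temp,
        sample_times_s=np.asarray(times, dtype=float),
        vas_values=values,
    )
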
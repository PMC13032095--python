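"""Synthetic cohort generator: latent traits and continuous VAS responses.

The generator emulates the study conditions end to end: a cohort of
participants with NEO PI-R-style facet/domain structure and Relationship
Questionnaire attachment prototypes, each responding to the fixed 20-stimulus
tonic-heat protocol with a continuous 0-100 VAS rating stream, plus a
post-session 0-10 verbal NRS report used by the consistency exclusion filter.

Generative model
----------------
Facets are drawn on the T-score scale (mean 50, SD 10) with a one-factor
structure per domain producing a within-domain correlation ``within_domain_corr``
and zero cross-domain correlation.  A domain score is the sum of its six
facets.  Attachment prototype ratings arise from a unit-variance latent

    lat_p = sum_d w_pd * z(domain_d) [+ beta_C5_secure * z(C5), secure only]
            + resid * eps,

rounded to the 1-7 Likert scale.  During a stimulus at temperature T the
rating is

    vas(t) = clamp_0_100[ mu(T) + s_i * t + contrast_shift + offset_i + eps(t) ],

with participant slope  s_i = s0(T) * (1 + slope_heterogeneity * u_i)
                            + beta_N6_tai * z(N6) - beta_C5_tai * z(C5)
and, on 46 degC trials only, a contextual shift of +gamma_i/2 after a
36 degC trial and -gamma_i/2 after a 48 degC trial, where

    gamma_i = gamma0 + beta_N6_contrast * z(N6)
            + beta_secure_contrast * z(secure latent) + contrast_sd_between * eta_i.

eps(t) is stationary lag-1 autoregressive rating jitter plus white
measurement noise.  Default coupling constants are calibrated so the
population Spearman correlations between traits and the derived indexes sit
at the study's anchor values (e.g. rho(N6, contrast magnitude) = 0.15,
rho(secure, neuroticism) = -0.30).

Reproducibility: one master seed; every participant draws from streams
derived by fixed spawn keys, so enlarging the cohort never reshuffles
earlier participants.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exceptions import ConfigurationError, UnsupportedConditionError
from .protocol import StimulusProtocol
from .vas_signal import VASTrace

DOMAINS = ("N", "E", "O", "A", "C")
FACETS = tuple(f"{d}{i}" for d in DOMAINS for i in range(1, 7))
PROTOTYPES = ("secure", "dismissing", "preoccupied", "fearful")

#: Latent Pearson loadings of domain z-scores onto attachment prototypes.
#: secure-N/-E and preoccupied-N are calibrated to the study's Spearman
#: anchors (-0.30, 0.41, 0.40); dismissing/fearful values are plausible
#: defaults in the same convention (see docs/methods.md).
DEFAULT_ATTACHMENT_LOADINGS: dict[str, dict[str, float]] = {
    "secure": {"N": -0.3102, "E": 0.4356},
    "dismissing": {"E": -0.29, "A": -0.15},
    "preoccupied": {"N": 0.4309},
    "fearful": {"N": 0.33, "E": -0.27},
}

# Stream tags for per-participant substreams (spawn_key = (index, tag)).
_TRAITS_STREAM = 0
_TRACE_STREAM = 1
_NRS_STREAM = 2
_COHORT_STREAM_KEY = 1 << 20  # cohort-level draws (discrepant-id selection)


@dataclass
class GeneratorConfig:
    """All tunable knobs of the synthetic cohort, with study-condition defaults.

    Rating-model parameters are in VAS units (0-100) and seconds; trait
    couplings are per standard deviation of the (latent) trait.
    """

    n_participants: int = 538
    seed: int = 0

    # trait model
    trait_mean: float = 50.0
    trait_sd: float = 10.0
    within_domain_corr: float = 0.4
    attachment_loadings: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            p: dict(w) for p, w in DEFAULT_ATTACHMENT_LOADINGS.items()
        }
    )
    attachment_center: float = 4.0
    attachment_scale: float = 1.5
    beta_C5_secure: float = 0.30  # extra loading of facet C5 on the secure latent

    # plateau rating model: baseline level mu(T) and sensitization slope s0(T)
    plateau_mean: dict[float, float] = field(
        default_factory=lambda: {36.0: 0.5, 44.0: 4.66, 46.0: 4.70, 48.0: 13.75}
    )
    sensitization_slope_base: dict[float, float] = field(
        default_factory=lambda: {36.0: 0.0, 44.0: 0.2655, 46.0: 1.0038, 48.0: 2.2065}
    )
    slope_heterogeneity: float = 0.8   # per-participant slope factor, fraction of s0
    subject_offset_sd: float = 8.0     # rating offset SD on noxious trials
    beta_N6_tai: float = 0.1192        # slope units per z(N6)
    beta_C5_tai: float = 0.1202        # slope units per z(C5), inhibitory

    # contrast susceptibility gamma_i
    gamma0: float = 21.86
    contrast_sd_between: float = 14.0
    beta_N6_contrast: float = 1.624    # rating units per z(N6), direct path
    beta_secure_contrast: float = -1.70  # rating units per z(secure), mediated path
    beta_E5_tai: float = 0.0           # reserved; off by default

    # measurement noise
    noise_sd_white: float = 2.0
    noise_sd_ar: float = 5.0
    noise_ar_coef: float = 0.98  # lag-1 autocorrelation at the 100 Hz reference rate
    sample_rate_hz: float = 100.0

    # post-session NRS reports
    nrs_consistency_sd: float = 0.5
    n_discrepant: int = 4
    nrs_discrepancy_offset: float = 4.5

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.trait_sd < 0 or self.nrs_consistency_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        for name in ("subject_offset_sd", "contrast_sd_between", "noise_sd_white",
                     "noise_sd_ar", "attachment_scale", "slope_heterogeneity"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.within_domain_corr < 1:
            raise ConfigurationError("within_domain_corr must be in [0, 1)")
        if not 0 <= self.noise_ar_coef < 1:
            raise ConfigurationError("noise_ar_coef must be in [0, 1)")
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be positive")
        if self.n_discrepant > self.n_participants:
            raise ConfigurationError(
                f"n_discrepant ({self.n_discrepant}) exceeds n_participants "
                f"({self.n_participants})"
            )
        if set(self.plateau_mean) != set(self.sensitization_slope_base):
            raise ConfigurationError("plateau_mean / slope tables must share temperatures")
        temps = sorted(self.plateau_mean)
        mus = [self.plateau_mean[t] for t in temps]
        if any(b < a for a, b in zip(mus, mus[1:])):
            raise ConfigurationError("plateau_mean must be nondecreasing in temperature")
        for proto, w in self.attachment_loadings.items():
            if proto not in PROTOTYPES:
                raise ConfigurationError(f"unknown attachment prototype '{proto}'")
            var = sum(v * v for v in w.values())
            if proto == "secure":
                var += self.beta_C5_secure**2
            if var > 1.0:
                raise ConfigurationError(
                    f"attachment loadings for '{proto}' are non-positive-definite: "
                    f"systematic variance {var:.3f} exceeds 1"
                )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        d = self.to_dict()
        # JSON object keys must be strings
        d["plateau_mean"] = {str(k): v for k, v in d["plateau_mean"].items()}
        d["sensitization_slope_base"] = {
            str(k): v for k, v in d["sensitization_slope_base"].items()
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)


@dataclass
class TraitProfile:
    """One participant's psychometric state (generator output)."""

    index: int
    participant_id: str
    facets: dict[str, float]
    domains: dict[str, float]
    attachment: dict[str, int]
    attachment_latents: dict[str, float] = field(repr=False, default_factory=dict)

    def facet_z(self, facet: str, config: GeneratorConfig) -> float:
        return (self.facets[facet] - config.trait_mean) / config.trait_sd


def _participant_rng(seed: int, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index, stream)))


def _domain_sd(config: GeneratorConfig) -> float:
    r = config.within_domain_corr
    return config.trait_sd * np.sqrt(6 * (1 + 5 * r))


def sample_traits(config: GeneratorConfig) -> list[TraitProfile]:
    """Draw the cohort's trait profiles; deterministic under a fixed seed."""
    config.validate()
    r = config.within_domain_corr
    a, b = np.sqrt(r), np.sqrt(1 - r)
    dom_sd = _domain_sd(config)
    profiles = []
    for i in range(config.n_participants):
        rng = _participant_rng(config.seed, i, _TRAITS_STREAM)
        g = rng.standard_normal(5)            # one common factor per domain
        e = rng.standard_normal(30)
        z = a * np.repeat(g, 6) + b * e       # facet z-scores, 30 values
        scores = config.trait_mean + config.trait_sd * z
        facets = dict(zip(FACETS, scores))
        domains = {
            d: float(sum(facets[f"{d}{k}"] for k in range(1, 7))) for d in DOMAINS
        }
        dom_z = {
            d: (domains[d] - 6 * config.trait_mean) / dom_sd for d in DOMAINS
        }
        z_c5 = z[FACETS.index("C5")]
        attachment, latents = {}, {}
        eps = rng.standard_normal(len(PROTOTYPES))
        for k, proto in enumerate(PROTOTYPES):
            w = config.attachment_loadings.get(proto, {})
            lat = sum(w.get(d, 0.0) * dom_z[d] for d in DOMAINS)
            var = sum(v * v for v in w.values())
            if proto == "secure":
                lat += config.beta_C5_secure * z_c5
                var += config.beta_C5_secure**2
            lat += np.sqrt(max(0.0, 1.0 - var)) * eps[k]
            latents[proto] = float(lat)
            rating = int(np.clip(round(config.attachment_center
                                       + config.attachment_scale * lat), 1, 7))
            attachment[proto] = rating
        profiles.append(
            TraitProfile(
                index=i,
                participant_id=f"P{i:04d}",
                facets={k: float(v) for k, v in facets.items()},
                domains=domains,
                attachment=attachment,
                attachment_latents=latents,
            )
        )
    return profiles


def traits_table(profiles: list[TraitProfile]) -> pd.DataFrame:
    """Wide trait table: one row per participant, columns N1..C6, N..C, prototypes."""
    rows = []
    for p in profiles:
        row = {"participant_id": p.participant_id}
        row.update(p.facets)
        row.update(p.domains)
        row.update(p.attachment)
        rows.append(row)
    return pd.DataFrame(rows, columns=["participant_id", *FACETS, *DOMAINS, *PROTOTYPES])


def _participant_effects(profile: TraitProfile, config: GeneratorConfig):
    """Deterministic per-participant latent effects (slope factor, offset, gamma)."""
    rng = _participant_rng(config.seed, profile.index, _TRACE_STREAM)
    u, off, eta = rng.standard_normal(3)
    z_n6 = profile.facet_z("N6", config)
    z_c5 = profile.facet_z("C5", config)
    z_sec = profile.attachment_latents.get("secure", 0.0)
    offset = config.subject_offset_sd * off
    gamma = (
        config.gamma0
        + config.beta_N6_contrast * z_n6
        + config.beta_secure_contrast * z_sec
        + config.contrast_sd_between * eta
    )
    return rng, u, offset, gamma, z_n6, z_c5


def _noise_block(rng: np.random.Generator, n_stimuli: int, n_samples: int,
                 config: GeneratorConfig) -> np.ndarray:
    """Stationary AR(1) rating jitter plus white noise, one row per stimulus.

    The AR coefficient is specified as the lag-1 autocorrelation at the
    100 Hz reference rate and converted to the configured rate so that the
    noise's correlation time (hence every epoch-mean variance) is invariant
    to the simulation rate.
    """
    dt = 1.0 / config.sample_rate_hz
    phi = config.noise_ar_coef ** (dt / 0.01) if config.noise_ar_coef > 0 else 0.0
    x0 = rng.standard_normal(n_stimuli) * config.noise_sd_ar
    innov = rng.standard_normal((n_stimuli, n_samples)) * (
        config.noise_sd_ar * np.sqrt(1 - phi * phi)
    )
    white = rng.standard_normal((n_stimuli, n_samples)) * config.noise_sd_white
    if phi > 0:
        zi = (phi * x0)[:, None]
        ar, _ = lfilter([1.0], [1.0, -phi], innov, axis=1, zi=zi)
    else:
        ar = innov
    return ar + white


def _simulate_participant_matrix(
    profile: TraitProfile, protocol: StimulusProtocol, config: GeneratorConfig
) -> tuple[np.ndarray, np.ndarray]:
    """All 20 ratings traces of one participant as a (n_stimuli, n_samples) array."""
    for temp in protocol.temperatures():
        if temp not in config.plateau_mean:
            raise UnsupportedConditionError(
                f"temperature {temp} degC has no calibrated rating model"
            )
    dt = 1.0 / config.sample_rate_hz
    n_samples = int(round(protocol.stimulus_duration_s * config.sample_rate_hz))
    t = np.arange(n_samples) * dt
    rng, u, offset, gamma, z_n6, z_c5 = _participant_effects(profile, config)
    noise = _noise_block(rng, protocol.n_stimuli, n_samples, config)
    out = np.empty((protocol.n_stimuli, n_samples))
    for j, temp in enumerate(protocol.sequence):
        s0 = config.sensitization_slope_base[temp]
        slope = (
            s0 * (1.0 + config.slope_heterogeneity * u)
            + config.beta_N6_tai * z_n6
            - config.beta_C5_tai * z_c5
        )
        if temp == protocol.control_temp_c:
            slope = 0.0
        shift = 0.0
        if temp == protocol.contrast_target_temp_c:
            prev = protocol.preceding_temp(j + 1)
            if prev == protocol.low_contrast_preceding_c:
                shift = +0.5 * gamma
            elif prev == protocol.high_contrast_preceding_c:
                shift = -0.5 * gamma
        level = config.plateau_mean[temp] + shift
        if temp != protocol.control_temp_c:
            level += offset
        out[j] = np.clip(level + slope * t + noise[j], 0.0, 100.0)
    return t, out


def simulate_vas_trace(
    profile: TraitProfile,
    protocol: StimulusProtocol,
    config: GeneratorConfig,
    stimulus_index: int,
) -> VASTrace:
    """Simulate the continuous rating stream for one stimulus presentation.

    The trace covers the 30-s analysis window (plateau onset at t = 0); the
    duration of the preceding thermode ramp is recorded as ``window_onset_s``.
    Identical whether simulated alone or as part of the full cohort.
    """
    if not 1 <= stimulus_index <= protocol.n_stimuli:
        raise ConfigurationError(
            f"stimulus_index {stimulus_index} outside [1, {protocol.n_stimuli}]"
        )
    temp = protocol.temperature_at(stimulus_index)
    if temp not in config.plateau_mean:
        raise UnsupportedConditionError(
            f"temperature {temp} degC has no calibrated rating model"
        )
    t, matrix = _simulate_participant_matrix(profile, protocol, config)
    return VASTrace(
        participant_id=profile.participant_id,
        stimulus_index=stimulus_index,
        target_temp_c=temp,
        sample_times_s=t,
        vas_values=matrix[stimulus_index - 1],
        window_onset_s=protocol.ramp_duration_s(temp),
    )


def simulate_cohort_traces(
    profiles: list[TraitProfile],
    protocol: StimulusProtocol,
    config: GeneratorConfig,
) -> list[VASTrace]:
    """Simulate every stimulus of every participant (vectorized per participant)."""
    traces = []
    for profile in profiles:
        t, matrix = _simulate_participant_matrix(profile, protocol, config)
        for j in range(protocol.n_stimuli):
            temp = protocol.sequence[j]
            traces.append(
                VASTrace(
                    participant_id=profile.participant_id,
                    stimulus_index=j + 1,
                    target_temp_c=temp,
                    sample_times_s=t,
                    vas_values=matrix[j],
                    window_onset_s=protocol.ramp_duration_s(temp),
                )
            )
    return traces


def simulate_nrs_reports(
    profiles: list[TraitProfile],
    traces: list[VASTrace],
    config: GeneratorConfig,
    protocol: StimulusProtocol | None = None,
) -> pd.DataFrame:
    """Post-session 0-10 NRS reports, with planted discrepant reporters.

    Honest participants report their mean 46 degC VAS / 10 plus Gaussian
    noise (SD ``nrs_consistency_sd``).  Exactly ``n_discrepant`` participants
    (chosen deterministically from the master seed) instead report a value
    offset by ``nrs_discrepancy_offset`` NRS units, large enough to trip the
    default exclusion threshold of 3.0.
    """
    config.validate()
    protocol = protocol or StimulusProtocol()
    target = protocol.contrast_target_temp_c
    by_pid: dict[str, list[float]] = {}
    for tr in traces:
        if tr.target_temp_c == target:
            by_pid.setdefault(tr.participant_id, []).append(float(tr.vas_values.mean()))
    missing = [p.participant_id for p in profiles if p.participant_id not in by_pid]
    if missing:
        raise ConfigurationError(
            f"traces do not cover all participants (missing {missing[:3]}...)"
        )
    cohort_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_COHORT_STREAM_KEY,))
    )
    discrepant = set(
        cohort_rng.choice(len(profiles), size=config.n_discrepant, replace=False).tolist()
    ) if config.n_discrepant else set()
    rows = []
    for p in profiles:
        clean = np.mean(by_pid[p.participant_id]) / 10.0
        rng = _participant_rng(config.seed, p.index, _NRS_STREAM)
        if p.index in discrepant:
            off = config.nrs_discrepancy_offset
            nrs = clean + off if clean <= 5.0 else clean - off
            planted = True
        else:
            nrs = clean + rng.normal(0.0, config.nrs_consistency_sd)
            planted = False
        rows.append(
            {
                "participant_id": p.participant_id,
                "nrs": float(np.clip(nrs, 0.0, 10.0)),
                "planted_discrepant": planted,
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(
    config: GeneratorConfig, protocol: StimulusProtocol | None = None
) -> tuple[list[TraitProfile], list[VASTrace], pd.DataFrame]:
    """Full simulation: traits, traces, NRS table."""
    protocol = protocol or StimulusProtocol()
    profiles = sample_traits(config)
    traces = simulate_cohort_traces(profiles, protocol, config)
    nrs = simulate_nrs_reports(profiles, traces, config, protocol)
    return profiles, traces, nrs


# ---------------------------------------------------------------------------
# Scenario constructors
# ---------------------------------------------------------------------------

def null_config(n_participants: int = 100, seed: int = 0,
                sample_rate_hz: float = 10.0) -> GeneratorConfig:
    """All trait-behavior couplings zero: the null cohort for FDR calibration."""
    return GeneratorConfig(
        n_participants=n_participants,
        seed=seed,
        sample_rate_hz=sample_rate_hz,
        beta_N6_tai=0.0,
        beta_C5_tai=0.0,
        beta_N6_contrast=0.0,
        beta_secure_contrast=0.0,
        beta_C5_secure=0.0,
        attachment_loadings={p: {} for p in PROTOTYPES},
        n_discrepant=0,
    )


def stabilization_scenario(n_participants: int = 534, seed: int = 0,
                           sample_rate_hz: float = 10.0) -> GeneratorConfig:
    """Indirect-only chain C5 -> secure -> contrast susceptibility.

    Couplings are sized for a clearly detectable mediated effect at the study
    sample size (standardized a ~ 0.55, b ~ -0.40, no direct path), the
    ground truth against which the causal-steps classifier is checked.
    """
    return GeneratorConfig(
        n_participants=n_participants,
        seed=seed,
        sample_rate_hz=sample_rate_hz,
        beta_N6_tai=0.0,
        beta_C5_tai=0.0,
        beta_N6_contrast=0.0,
        beta_C5_secure=0.5532,
        beta_secure_contrast=-7.0947,
        attachment_loadings={
            "secure": {"N": -0.327, "E": 0.449},
            "dismissing": {},
            "preoccupied": {"N": 0.438},
            "fearful": {},
        },
        n_discrepant=0,
    )


def instability_scenario(n_participants: int = 534, seed: int = 0,
                         sample_rate_hz: float = 10.0) -> GeneratorConfig:
    """Direct-only path N6 -> contrast susceptibility (preoccupied is a non-mediator).

    N6 still predicts preoccupied attachment (through the neuroticism
    loading), but preoccupied has no effect of its own on the contrast
    shift, so the direct effect c' must survive adjustment.
    """
    return GeneratorConfig(
        n_participants=n_participants,
        seed=seed,
        sample_rate_hz=sample_rate_hz,
        beta_N6_tai=0.0,
        beta_C5_tai=0.0,
        beta_C5_secure=0.0,
        beta_N6_contrast=5.604,
        beta_secure_contrast=0.0,
        n_discrepant=0,
    )
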
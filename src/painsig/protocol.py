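"""Tonic-heat stimulation protocol.

The protocol is a fixed pseudorandomized sequence of 20 tonic heat stimuli
(30 s plateau each, 30 s inter-stimulus interval at a 35 degC baseline) drawn
from one non-noxious control temperature (36 degC) and three noxious levels
(44, 46, 48 degC).  The order is fixed so that the 46 degC target stimulus is
preceded sometimes by 36 degC (low-contrast condition) and sometimes by
48 degC (high-contrast condition), which is what makes the contrast effect
measurable at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ConfigurationError

#: Fixed pseudorandomized presentation order (degC), 20 stimuli, 5 per level.
DEFAULT_SEQUENCE: tuple[float, ...] = (
    36, 44, 48, 46, 46, 44, 36, 48, 46, 48,
    36, 44, 48, 44, 36, 46, 36, 44, 48, 46,
)


@dataclass(frozen=True)
class StimulusProtocol:
    """Description of the thermal stimulation session.

    Attributes
    ----------
    sequence
        Ordered target temperatures in degC, one per stimulus (1-based
        indexing is used everywhere a ``stimulus_index`` appears).
    stimulus_duration_s, isi_duration_s
        Plateau and inter-stimulus durations in seconds.
    baseline_temp_c, ramp_rate_c_per_s
        Thermode baseline and ramp rate; the ramp to target takes
        ``(T - baseline) / ramp_rate`` seconds and the 30-s analysis window
        starts at plateau onset.
    control_temp_c
        Non-noxious control level.
    contrast_target_temp_c
        The temperature whose evaluation is probed for context dependence.
    """

    sequence: tuple[float, ...] = DEFAULT_SEQUENCE
    stimulus_duration_s: float = 30.0
    isi_duration_s: float = 30.0
    baseline_temp_c: float = 35.0
    ramp_rate_c_per_s: float = 1.0
    control_temp_c: float = 36.0
    contrast_target_temp_c: float = 46.0
    low_contrast_preceding_c: float = 36.0
    high_contrast_preceding_c: float = 48.0

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ConfigurationError("protocol sequence must be nonempty")
        if self.stimulus_duration_s <= 0 or self.ramp_rate_c_per_s <= 0:
            raise ConfigurationError("durations and ramp rate must be positive")
        object.__setattr__(self, "sequence", tuple(float(t) for t in self.sequence))

    @property
    def n_stimuli(self) -> int:
        return len(self.sequence)

    def temperature_at(self, stimulus_index: int) -> float:
        """Target temperature of the 1-based ``stimulus_index``."""
        if not 1 <= stimulus_index <= self.n_stimuli:
            raise ConfigurationError(
                f"stimulus_index {stimulus_index} outside [1, {self.n_stimuli}]"
            )
        return self.sequence[stimulus_index - 1]

    def preceding_temp(self, stimulus_index: int) -> float | None:
        """Target temperature of the previous stimulus (None for the first)."""
        if stimulus_index == 1:
            return None
        return self.temperature_at(stimulus_index - 1)

    def ramp_duration_s(self, temp_c: float) -> float:
        return abs(temp_c - self.baseline_temp_c) / self.ramp_rate_c_per_s

    def temperatures(self) -> tuple[float, ...]:
        """Distinct target temperatures, ascending."""
        return tuple(sorted(set(self.sequence)))

    def stimulus_indices_at(self, temp_c: float) -> tuple[int, ...]:
        return tuple(i + 1 for i, t in enumerate(self.sequence) if t == temp_c)

    def contrast_trial_indices(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """(low-contrast, high-contrast) 1-based stimulus indices.

        A trial at the contrast target (46 degC) is low-contrast when preceded
        by 36 degC and high-contrast when preceded by 48 degC.  Trials
        preceded by any other temperature (including the first stimulus and
        46-after-46) belong to neither condition.
        """
        low, high = [], []
        for idx in self.stimulus_indices_at(self.contrast_target_temp_c):
            prev = self.preceding_temp(idx)
            if prev == self.low_contrast_preceding_c:
                low.append(idx)
            elif prev == self.high_contrast_preceding_c:
                high.append(idx)
        return tuple(low), tuple(high)
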
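"""Exception hierarchy for the painsig pipeline."""


class PainsigError(Exception):
    """Base class for all painsig errors."""


class ConfigurationError(PainsigError):
    """Invalid generator or run configuration."""


class UnsupportedConditionError(PainsigError):
    """Stimulus temperature outside the calibrated set {36, 44, 46, 48} degC."""


class TraceParseError(PainsigError):
    """Malformed trace table (missing column, out-of-range VAS, non-monotone time)."""


class SequenceMismatchError(TraceParseError):
    """Trace temperature disagrees with the protocol sequence at its stimulus index."""


class RejectedTraceError(PainsigError):
    """A 10-s epoch contains no samples; the whole stimulus is dropped and reported."""

    def __init__(self, participant_id, stimulus_index, epoch):
        self.participant_id = participant_id
        self.stimulus_index = stimulus_index
        self.epoch = epoch
        super().__init__(
            f"participant {participant_id}, stimulus {stimulus_index}: "
            f"epoch {epoch} contains no samples"
        )


class DegenerateWindowError(PainsigError):
    """Smoothing window longer than the trace span."""


class EmptyCohortError(PainsigError):
    """No participants survive exclusion; downstream analysis is impossible."""


class CollinearityError(PainsigError):
    """Design matrix is (numerically) rank deficient."""
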
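"""Exception hierarchy.

Validation problems (bad DVHs, malformed manifests) and configuration
problems (unknown model names, study combinations outside the design) are
kept distinct so the command-line layer can map them to different exit
codes.
"""


class ScrkitError(Exception):
    """Base class for all package errors."""


class DVHValidationError(ScrkitError):
    """A DVH failed one or more structural invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(str(v) for v in self.violations) or "invalid DVH"
        super().__init__(msg)


class ParameterError(ScrkitError):
    """An operation was called with out-of-range or inconsistent parameters."""


class InputError(ScrkitError):
    """Structurally invalid input data (manifests, pairings, duplicates)."""


class ConfigurationError(ScrkitError):
    """Invalid run/risk/synthetic-cohort configuration."""
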
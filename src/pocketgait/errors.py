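"""Typed exceptions for the gait-analysis pipeline.

Every failure mode the pipeline can hit maps to one of these classes so the
CLI can surface a stable exit code and a machine-readable error record.
"""

from __future__ import annotations


class PocketGaitError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(PocketGaitError):
    """A file does not conform to the expected on-disk format."""

    exit_code = 2


class DataError(PocketGaitError):
    """The data are structurally readable but violate an invariant."""

    exit_code = 3


class InsufficientDataError(PocketGaitError):
    """Too little data to produce the requested output (trial flagged)."""

    exit_code = 4


class ParameterError(PocketGaitError):
    """A configuration parameter is out of its valid range."""

    exit_code = 5


class ClassificationError(PocketGaitError):
    """Peak high/low classification is ambiguous; the trial is rejected."""

    exit_code = 6


class PairingError(PocketGaitError):
    """Trials that must form a matched pair do not."""

    exit_code = 7


class DegenerateInputError(PocketGaitError):
    """A statistic is undefined on this input (e.g. zero variance)."""

    exit_code = 8


class ConfigError(PocketGaitError):
    """A simulation or run configuration is internally inconsistent."""

    exit_code = 9
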
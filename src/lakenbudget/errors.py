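"""Exception hierarchy shared across the package.

``InputError`` marks bad data (exit code 1 at the CLI); ``ConfigError``
marks an invalid run configuration (exit code 2). ``LakeNotApplicable``
is raised when a single lake fails the stratification screen and must be
skipped rather than computed.
"""


class LakeNBudgetError(Exception):
    """Base class for all package errors."""


class InputError(LakeNBudgetError):
    """Invalid input data (bad value, malformed table, missing column)."""


class ConfigError(LakeNBudgetError):
    """Invalid run configuration (bad coefficient, out-of-range option)."""


class LakeNotApplicable(LakeNBudgetError):
    """The lake is stratified (mean depth exceeds the thermocline depth)
    and lies outside the removal model's domain."""
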
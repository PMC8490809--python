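"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A simulation or pipeline configuration is invalid."""


class InputError(ValueError):
    """An input table is missing, malformed, or lacks a required column."""


class UndefinedExposureError(ValueError):
    """A 2x2 table has an empty exposure margin (a+b = 0 or c+d = 0)."""


class EmptyStratumError(ValueError):
    """The index-drug stratum for a nested scan contains no reports."""


class NoPairsError(ValueError):
    """Sequence symmetry analysis found no drug-event pairs in the window."""
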
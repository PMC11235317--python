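"""Exception hierarchy.

Every error carries a machine-readable ``category`` so the CLI can report a
stable error class alongside the human-readable message.
"""


class SteatoquantError(Exception):
    """Base class for all package errors."""

    category = "error"


class ContractError(SteatoquantError):
    """An internal data contract was violated (e.g. fat mask not a subset of tissue)."""

    category = "contract"


class NoTissueError(SteatoquantError):
    """A field image contains no tissue pixels; no steatosis fraction is defined."""

    category = "no_tissue"


class FatFractionError(SteatoquantError):
    """The generator could not reach the requested fat fraction.

    Carries the fraction that *was* achieved when the attempt cap was hit.
    """

    category = "generation"

    def __init__(self, message: str, achieved: float):
        super().__init__(message)
        self.achieved = achieved


class TilingError(SteatoquantError):
    category = "tiling"


class SamplingError(SteatoquantError):
    """Non-overlapping field placement failed."""

    category = "sampling"


class ConfigError(SteatoquantError):
    category = "config"


class SchemaError(SteatoquantError):
    category = "schema"


class InvalidEstimateError(SteatoquantError):
    """A slide estimate could not be formed (e.g. every field was rejected)."""

    category = "invalid_estimate"
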
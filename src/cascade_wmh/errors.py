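"""Exception families raised across the pipeline.

Each family maps to a distinct process exit code in the CLI, so cohort
drivers can tell a bad input file from a degenerate image or an unusable
normal-brain model.
"""


class CascadeError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(CascadeError):
    """Unreadable, non-scalar, or otherwise corrupt input data."""

    exit_code = 2


class ConfigError(CascadeError):
    """Invalid run configuration."""

    exit_code = 3


class DegenerateVolumeError(CascadeError):
    """An image that cannot be processed, e.g. constant inside the brain."""

    exit_code = 4


class GridMismatchError(CascadeError):
    """Volumes or masks that do not share one voxel grid."""

    exit_code = 5


class UnusableNormalModelError(CascadeError):
    """The evidently-normal mask is too small to support the statistics."""

    exit_code = 6
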